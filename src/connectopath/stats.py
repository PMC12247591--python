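"""Cohort-level statistical battery.

Group contrasts (Welch's t with pooled-SD Cohen's d, one-way ANOVA,
covariate-adjusted linear-model contrasts), the Cuzick non-parametric trend
test across ordered groups, multivariable-adjusted Spearman correlations
(rank -> residualize on covariates -> correlate), Benjamini–Hochberg FDR,
standardized-beta OLS, distribution diagnostics, and the outlier-trimming
sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("connectopath")


@dataclass
class StatResult:
    """Estimate / effect-size / statistic / df / p bundle with a method label."""

    method: str
    contrast: str
    estimate: float
    effect_size: float
    statistic: float
    df: float
    p: float
    p_adjusted: float | None = None
    n: int = 0

    def __post_init__(self) -> None:
        if not (np.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value {self.p} outside [0, 1]")


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Standardized mean difference with the pooled-SD convention."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx_, ny = len(x), len(y)
    sp2 = ((nx_ - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx_ + ny - 2)
    if sp2 == 0:
        return 0.0
    return float((x.mean() - y.mean()) / np.sqrt(sp2))


def welch_t(
    x: Sequence[float], y: Sequence[float], contrast: str = "x_vs_y"
) -> StatResult:
    """Welch's unequal-variance t-test with Welch–Satterthwaite df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if np.array_equal(np.sort(x), np.sort(y)) or x.mean() == y.mean():
            return StatResult(
                "welch_t", contrast, 0.0, 0.0, 0.0, float(len(x) + len(y) - 2),
                1.0, n=len(x) + len(y),
            )
        raise ValueError("zero variance in both samples")
    res = sps.ttest_ind(x, y, equal_var=False)
    return StatResult(
        method="welch_t",
        contrast=contrast,
        estimate=float(x.mean() - y.mean()),
        effect_size=cohens_d(x, y),
        statistic=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        n=len(x) + len(y),
    )


def one_way_anova(groups: Sequence[Sequence[float]]) -> StatResult:
    """One-way fixed-effects ANOVA over k groups."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(len(g) < 2 for g in arrays):
        raise ValueError("every group needs n >= 2")
    k = len(arrays)
    n_total = sum(len(g) for g in arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in arrays)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    df1, df2 = k - 1, n_total - k
    if ss_within == 0 and ss_between == 0:
        f, p = 0.0, 1.0
    elif ss_within == 0:
        f, p = np.inf, 0.0
    else:
        f = (ss_between / df1) / (ss_within / df2)
        p = float(sps.f.sf(f, df1, df2))
    eta_sq = ss_between / (ss_between + ss_within) if ss_between + ss_within else 0.0
    return StatResult(
        method="anova",
        contrast="between_groups",
        estimate=float(ss_between / df1),
        effect_size=float(eta_sq),
        statistic=float(f),
        df=float(df1),
        p=float(p),
        n=n_total,
    )


def _encode_covariates(covariates: pd.DataFrame | None) -> np.ndarray:
    """Dummy-encode categoricals, drop constant columns (logged)."""
    if covariates is None or covariates.shape[1] == 0:
        return np.empty((0 if covariates is None else len(covariates), 0))
    enc = pd.get_dummies(covariates, drop_first=True, dtype=float)
    keep = enc.columns[enc.nunique() > 1]
    dropped = [c for c in enc.columns if c not in set(keep)]
    if dropped:
        logger.info("dropping constant covariate columns: %s", dropped)
    return enc[keep].to_numpy(dtype=float)


def adjusted_group_contrast(
    metric: Sequence[float],
    group: Sequence[str],
    covariates: pd.DataFrame | None = None,
    contrasts: Sequence[tuple[str, str]] | None = None,
) -> list[StatResult]:
    """Covariate-adjusted pairwise group contrasts from one linear model.

    Fits ``metric ~ group + covariates`` (Gaussian, identity link) and tests
    each pairwise group difference with a t contrast.  ``effect_size`` is the
    contrast estimate divided by the residual SD (an adjusted analogue of
    Cohen's d).
    """
    y = np.asarray(metric, dtype=float)
    group = pd.Categorical(group)
    levels = [g for g in group.categories if (group == g).sum() > 0]
    if len(levels) < 2:
        raise ValueError("need at least two non-empty groups")
    gdum = np.column_stack(
        [(group == g).astype(float) for g in levels[1:]]
    )  # reference = first level
    cov = _encode_covariates(covariates)
    X = np.column_stack([np.ones(len(y)), gdum] + ([cov] if cov.size else []))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    if len(y) <= X.shape[1]:
        raise ValueError("more parameters than observations")
    fit = sm.OLS(y, X).fit()
    sigma = float(np.sqrt(fit.mse_resid))
    if contrasts is None:
        contrasts = [
            (levels[j], levels[i])
            for i in range(len(levels))
            for j in range(i + 1, len(levels))
        ]
    out = []
    for a, b in contrasts:
        vec = np.zeros(X.shape[1])
        for lvl, sign in ((a, 1.0), (b, -1.0)):
            if lvl not in levels:
                raise ValueError(f"unknown group {lvl!r}")
            if lvl != levels[0]:
                vec[1 + levels[1:].index(lvl)] = sign
        tt = fit.t_test(vec)
        est = float(np.ravel(tt.effect)[0])
        out.append(
            StatResult(
                method="adjusted_contrast",
                contrast=f"{a}_vs_{b}",
                estimate=est,
                effect_size=est / sigma if sigma > 0 else 0.0,
                statistic=float(np.ravel(tt.tvalue)[0]),
                df=float(fit.df_resid),
                p=float(np.ravel(tt.pvalue)[0]),
                n=len(y),
            )
        )
    return out


def trend_test(
    metric: Sequence[float],
    ordered_group: Sequence[str],
    order: Sequence[str] | None = None,
) -> StatResult:
    """Cuzick's non-parametric (Wilcoxon-type) test for trend across ordered groups.

    Group scores are the ordinal positions 0, 1, 2, ...; the statistic is the
    score-weighted rank sum, standardized with the tie-corrected null
    variance and referred to the standard normal.
    """
    y = np.asarray(metric, dtype=float)
    g = pd.Categorical(ordered_group, categories=order) if order else pd.Categorical(
        ordered_group
    )
    levels = [lvl for lvl in g.categories if (g == lvl).sum() > 0]
    if len(levels) < 2:
        raise ValueError("trend test needs at least two non-empty groups")
    if np.all(y == y[0]):
        raise ValueError("all metric values tied; trend undefined")
    n_total = len(y)
    ranks = sps.rankdata(y)
    scores = {lvl: float(i) for i, lvl in enumerate(levels)}
    li = np.array([scores[lvl] for lvl in np.asarray(g)])
    ni = np.array([(g == lvl).sum() for lvl in levels], dtype=float)
    lvals = np.array([scores[lvl] for lvl in levels])
    t_stat = float((li * ranks).sum())
    e_t = (n_total + 1) / 2.0 * float((lvals * ni).sum())
    var_t = (n_total + 1) / 12.0 * (
        n_total * float((lvals**2 * ni).sum()) - float((lvals * ni).sum()) ** 2
    )
    # tie correction on the rank variance
    _, counts = np.unique(y, return_counts=True)
    tie_corr = 1.0 - (counts**3 - counts).sum() / (n_total**3 - n_total)
    var_t *= tie_corr
    if var_t <= 0:
        raise ValueError("degenerate trend-test variance (all values tied?)")
    z = (t_stat - e_t) / np.sqrt(var_t)
    return StatResult(
        method="cuzick_trend",
        contrast="->".join(levels),
        estimate=float(t_stat - e_t),
        effect_size=float(z / np.sqrt(n_total)),
        statistic=float(z),
        df=np.inf,
        p=float(2.0 * sps.norm.sf(abs(z))),
        n=n_total,
    )


def adjusted_spearman(
    x: Sequence[float],
    y: Sequence[float],
    covariates: pd.DataFrame | None = None,
    contrast: str = "x_vs_y",
) -> StatResult:
    """Multivariable-adjusted Spearman correlation.

    Both variables are rank-transformed, each rank vector is residualized on
    the covariates by least squares, and rho is the Pearson correlation of
    the residuals.  The p-value uses the t approximation
    ``t = rho * sqrt((n - 2 - q) / (1 - rho^2))`` with q adjusted-for
    covariate columns (q = 0 for the plain Spearman).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    cov = _encode_covariates(covariates)
    q = cov.shape[1] if cov.size else 0
    if n < q + 3:
        raise ValueError(f"n = {n} too small for {q} covariates")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        raise ValueError("constant variable after ranking")
    if q:
        design = np.column_stack([np.ones(n), cov])
        rx = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
        ry = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
        if np.allclose(rx, 0) or np.allclose(ry, 0):
            raise ValueError("variable fully explained by covariates")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - q
    if abs(rho) >= 1.0:
        rho = float(np.clip(rho, -1.0, 1.0))
        t, p = np.inf * np.sign(rho), 0.0
    else:
        t = rho * np.sqrt(df / (1.0 - rho**2))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return StatResult(
        method="adjusted_spearman" if q else "spearman",
        contrast=contrast,
        estimate=rho,
        effect_size=rho,
        statistic=float(t),
        df=float(df),
        p=p,
        n=n,
    )


def bh_fdr(
    pvals: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up FDR control.

    Returns (rejected flags, adjusted p-values); adjusted p-values are
    monotone non-decreasing in the raw p-values and order-invariant.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    rejected, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return rejected, p_adj


def ols_standardized(y: Sequence[float], X: pd.DataFrame) -> list[StatResult]:
    """OLS with standardized (z-scored) outcome and continuous predictors.

    Binary/dummy columns are left on their original scale; every other
    column and the outcome are z-scored, so coefficients are standardized
    betas.  Raises on rank deficiency or zero-variance predictors.
    """
    y = np.asarray(y, dtype=float)
    X = pd.DataFrame(X).copy()
    if X.shape[1] == 0:
        raise ValueError("empty design")
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        if v.std(ddof=1) == 0:
            raise ValueError(f"zero-variance predictor {col!r}")
        if len(np.unique(v)) > 2:
            X[col] = (v - v.mean()) / v.std(ddof=1)
    ys = (y - y.mean()) / y.std(ddof=1)
    design = np.column_stack([np.ones(len(ys)), X.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design matrix")
    if len(ys) <= design.shape[1]:
        raise ValueError("more parameters than observations")
    fit = sm.OLS(ys, design).fit()
    out = []
    for i, col in enumerate(X.columns, start=1):
        out.append(
            StatResult(
                method="ols_standardized",
                contrast=str(col),
                estimate=float(fit.params[i]),
                effect_size=float(fit.params[i]),
                statistic=float(fit.tvalues[i]),
                df=float(fit.df_resid),
                p=float(fit.pvalues[i]),
                n=len(ys),
            )
        )
    return out


@dataclass
class DistributionDiagnostics:
    """Sample skewness and kurtosis under both common conventions."""

    skew: float
    kurtosis_excess: float
    kurtosis_pearson: float


def distribution_diagnostics(x: Sequence[float]) -> DistributionDiagnostics:
    """Sample skewness (g1) plus excess (g2) and Pearson (g2 + 3) kurtosis."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.all(x == x[0]):
        raise ValueError("constant vector")
    skew = float(sps.skew(x, bias=True))
    kurt_ex = float(sps.kurtosis(x, fisher=True, bias=True))
    return DistributionDiagnostics(skew, kurt_ex, kurt_ex + 3.0)


@dataclass
class SensitivityResult:
    """Paired full-vs-trimmed analysis results for the outlier sensitivity check."""

    full: list[StatResult]
    trimmed: list[StatResult]
    removed_subjects: list[str]
    n_above_threshold: int | None = None
    threshold: float | None = None
    group_counts_trimmed: dict[str, int] = field(default_factory=dict)


def outlier_sensitivity(
    metrics: pd.DataFrame,
    group: str,
    k: int,
    analysis: Callable[[pd.DataFrame], list[StatResult]],
    metric_col: str = "wcpl",
    group_col: str = "group",
    id_col: str = "subject_id",
    threshold: float | None = None,
) -> SensitivityResult:
    """Re-run an analysis after removing the k highest-metric subjects of one group.

    Only the named group is trimmed; all other groups are untouched.  When a
    reporting ``threshold`` is given, the count of subjects (full table)
    above it is included.
    """
    in_group = metrics[metrics[group_col] == group]
    if len(in_group) == 0:
        raise ValueError(f"no subjects in group {group!r}")
    if k >= len(in_group):
        raise ValueError(f"k = {k} >= group size {len(in_group)}")
    removed = (
        in_group.sort_values(metric_col, ascending=False).head(k)[id_col].tolist()
    )
    trimmed = metrics[~metrics[id_col].isin(removed)].reset_index(drop=True)
    full_res = analysis(metrics)
    trimmed_res = analysis(trimmed)
    n_above = (
        int((metrics[metric_col] > threshold).sum()) if threshold is not None else None
    )
    counts = trimmed[group_col].value_counts().to_dict()
    return SensitivityResult(
        full=list(full_res),
        trimmed=list(trimmed_res),
        removed_subjects=removed,
        n_above_threshold=n_above,
        threshold=threshold,
        group_counts_trimmed={str(k_): int(v) for k_, v in counts.items()},
    )


def fdr_by_family(
    results: Sequence[StatResult],
    families: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> list[StatResult]:
    """Apply BH-FDR within families of results (e.g. per subgroup column)."""
    results = list(results)
    fams = list(families) if families is not None else ["all"] * len(results)
    for fam in set(fams):
        idx = [i for i, f in enumerate(fams) if f == fam]
        _, p_adj = bh_fdr([results[i].p for i in idx], alpha=alpha)
        for i, pa in zip(idx, p_adj):
            results[i].p_adjusted = float(pa)
    return results
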