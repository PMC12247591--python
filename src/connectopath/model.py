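"""Study-level modelling interface.

:class:`ConnectomeStudy` is built from a cohort (subject metadata plus
connectivity matrices, simulated or read from disk); :meth:`ConnectomeStudy.fit`
computes per-subject global network metrics and the full statistical battery,
returning a :class:`StudyResults` object that carries the result tables and
renders a text summary.

The table-building helpers (``contrasts_table`` etc.) are also usable
directly on a merged metrics+metadata DataFrame, which is how the CLI
subcommands drive them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import graph, roc as roc_mod, simulate, stats
from .io import (
    CohortTable,
    GROUPS,
    SYMPTOM_COLUMNS,
    read_matrix,
    read_metadata,
    records_to_frame,
)

logger = logging.getLogger("connectopath")

DEFAULT_COVARIATES = ("age", "sex", "education", "body_mass")
DEFAULT_METRICS = ("wcpl", "cc", "ge", "swn", "log_swn")
SUBGROUPS = ("no_mdd", "ptsd", "ptsd_mdd")


def _covariate_frame(df: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    return df[list(covariates)] if covariates else pd.DataFrame(index=df.index)


def _result_rows(results, metric: str, extra: dict | None = None) -> list[dict]:
    rows = []
    for r in results:
        d = vars(r).copy()
        d["metric"] = metric
        if extra:
            d.update(extra)
        rows.append(d)
    return rows


def subgroup_mask(df: pd.DataFrame, name: str) -> pd.Series:
    """Clinical subgroup masks mirroring the correlation-table columns."""
    if name == "no_mdd":
        return ~df["mdd"].astype(bool)
    if name == "ptsd":
        return df["group"].astype(str) == "ptsd"
    if name == "ptsd_mdd":
        return (df["group"].astype(str) == "ptsd") & df["mdd"].astype(bool)
    raise ValueError(f"unknown subgroup {name!r}")


def contrasts_table(
    df: pd.DataFrame,
    metrics: Sequence[str] = DEFAULT_METRICS,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Welch, ANOVA, trend and covariate-adjusted contrasts per metric.

    Pairwise group contrasts plus the case-vs-rest contrast; groups absent
    from the data are skipped with a logged reason.
    """
    rows: list[dict] = []
    present = [g for g in GROUPS if (df["group"].astype(str) == g).sum() >= 2]
    skipped = [g for g in GROUPS if g not in present]
    if skipped:
        logger.warning("skipping contrasts for empty/singleton groups: %s", skipped)
    for metric in metrics:
        y = df[metric].to_numpy(dtype=float)
        gser = df["group"].astype(str)
        samples = {g: y[gser == g] for g in present}
        if len(present) >= 2:
            for i, a in enumerate(present):
                for b in present[:i]:
                    # report higher-ordered group first (case minus comparison)
                    rows += _result_rows(
                        [stats.welch_t(samples[a], samples[b], f"{a}_vs_{b}")], metric
                    )
            rows += _result_rows(
                [stats.one_way_anova([samples[g] for g in present])], metric
            )
            keep = gser.isin(present)
            rows += _result_rows(
                [stats.trend_test(y[keep], gser[keep], order=present)], metric
            )
            rows += _result_rows(
                stats.adjusted_group_contrast(
                    y[keep],
                    pd.Categorical(gser[keep], categories=present),
                    _covariate_frame(df[keep], covariates),
                ),
                metric,
            )
        if "ptsd" in present and len(df) - len(samples["ptsd"]) >= 2:
            rest = y[gser != "ptsd"]
            rows += _result_rows(
                [stats.welch_t(samples["ptsd"], rest, "ptsd_vs_rest")], metric
            )
            binary = np.where(gser == "ptsd", "ptsd", "rest")
            rows += _result_rows(
                stats.adjusted_group_contrast(
                    y,
                    pd.Categorical(binary, categories=["rest", "ptsd"]),
                    _covariate_frame(df, covariates),
                    contrasts=[("ptsd", "rest")],
                ),
                metric,
            )
    return pd.DataFrame(rows)


def correlations_table(
    df: pd.DataFrame,
    domains: Sequence[str] = SYMPTOM_COLUMNS,
    subgroups: Sequence[str] = SUBGROUPS,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    alpha: float = 0.05,
    metric: str = "wcpl",
) -> pd.DataFrame:
    """Adjusted Spearman correlations of a metric with symptom domains.

    One row per (subgroup, domain); BH-FDR is applied within each subgroup's
    family of domain tests.
    """
    rows: list[dict] = []
    for sub in subgroups:
        mask = subgroup_mask(df, sub)
        sdf = df[mask]
        results = []
        kept_domains = []
        for dom in domains:
            try:
                res = stats.adjusted_spearman(
                    sdf[metric].to_numpy(dtype=float),
                    sdf[dom].to_numpy(dtype=float),
                    _covariate_frame(sdf, covariates),
                    contrast=f"{metric}_vs_{dom}",
                )
            except ValueError as exc:
                logger.warning("subgroup %s, domain %s skipped: %s", sub, dom, exc)
                continue
            results.append(res)
            kept_domains.append(dom)
        if not results:
            continue
        stats.fdr_by_family(results, alpha=alpha)
        for dom, res in zip(kept_domains, results):
            rows.append(
                dict(
                    subgroup=sub,
                    domain=dom,
                    rho=res.estimate,
                    statistic=res.statistic,
                    df=res.df,
                    p=res.p,
                    p_adjusted=res.p_adjusted,
                    fdr_pass=bool(res.p_adjusted is not None and res.p_adjusted <= alpha),
                    n=res.n,
                )
            )
    return pd.DataFrame(rows)


def roc_table(
    df: pd.DataFrame,
    features: Sequence[str] = ("wcpl", "cortical_complexity"),
    covariates: Sequence[str] = ("age", "education", "body_mass"),
    labels: Sequence[str] = ("ptsd", "ptsd_no_mdd"),
) -> pd.DataFrame:
    """Single-feature and combined (logistic) discrimination of PTSD status.

    ``ptsd_no_mdd`` excludes comorbid-MDD subjects before labelling, so the
    positive class is PTSD without MDD.
    """
    rows = []
    for label in labels:
        if label == "ptsd":
            sdf = df
        elif label == "ptsd_no_mdd":
            sdf = df[~df["mdd"].astype(bool)]
        else:
            raise ValueError(f"unknown label {label!r}")
        yb = (sdf["group"].astype(str) == "ptsd").to_numpy()
        if yb.all() or not yb.any():
            logger.warning("label %s: only one class present; ROC skipped", label)
            continue
        feats = [f for f in features if f in sdf.columns and sdf[f].notna().all()]
        for f in feats:
            r = roc_mod.roc_auc(sdf[f].to_numpy(dtype=float), yb, model=f)
            rows.append(dict(label=label, model=f, **_roc_dict(r)))
        if feats:
            _, r = roc_mod.combined_score(
                sdf[feats], yb, _covariate_frame(sdf, covariates)
            )
            rows.append(
                dict(label=label, model="combined:" + "+".join(feats), **_roc_dict(r))
            )
    return pd.DataFrame(rows)


def _roc_dict(r: roc_mod.RocResult) -> dict:
    return dict(
        auc=r.auc,
        ci_low=r.ci_low,
        ci_high=r.ci_high,
        n_pos=r.n_pos,
        n_neg=r.n_neg,
        apparent=r.apparent,
    )


def sensitivity_table(
    df: pd.DataFrame,
    k: int = 3,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    threshold: float = 80.0,
    group: str = "ptsd",
    metric: str = "wcpl",
) -> tuple[pd.DataFrame, stats.SensitivityResult]:
    """Outlier sensitivity: drop the k highest-metric subjects of one group.

    Re-runs the case-vs-exposed and case-vs-rest contrasts (Welch and
    covariate-adjusted) on the trimmed cohort and reports both alongside the
    count of subjects above the reporting threshold.
    """

    def battery(frame: pd.DataFrame) -> list[stats.StatResult]:
        y = frame[metric].to_numpy(dtype=float)
        gser = frame["group"].astype(str)
        out: list[stats.StatResult] = []
        if (gser == group).sum() >= 2 and (gser == "exposed_noptsd").sum() >= 2:
            out.append(
                stats.welch_t(
                    y[gser == group],
                    y[gser == "exposed_noptsd"],
                    f"{group}_vs_exposed_noptsd",
                )
            )
            binary = np.where(gser == group, group, "rest")
            out.append(
                stats.welch_t(y[gser == group], y[gser != group], f"{group}_vs_rest")
            )
            out += stats.adjusted_group_contrast(
                y,
                pd.Categorical(binary, categories=["rest", group]),
                _covariate_frame(frame, covariates),
                contrasts=[(group, "rest")],
            )
        return out

    gdf = df.copy()
    gdf["group"] = gdf["group"].astype(str)
    sens = stats.outlier_sensitivity(
        gdf, group=group, k=k, analysis=battery, metric_col=metric,
        threshold=threshold,
    )
    rows = _result_rows(sens.full, metric, {"phase": "full"}) + _result_rows(
        sens.trimmed, metric, {"phase": f"trimmed_top_{k}"}
    )
    return pd.DataFrame(rows), sens


@dataclass
class StudyResults:
    """Fitted study: metric, contrast, correlation, ROC and sensitivity tables."""

    metrics: pd.DataFrame
    contrasts: pd.DataFrame
    correlations: pd.DataFrame
    roc: pd.DataFrame
    sensitivity: pd.DataFrame
    diagnostics: pd.DataFrame
    feature_correlation: stats.StatResult | None = None
    sensitivity_detail: stats.SensitivityResult | None = None
    seed: int = 0
    settings: dict = field(default_factory=dict)

    def summary(self) -> str:
        """Human-readable report mirroring a cohort-study results section."""
        from .pipeline import render_report

        return render_report(self)

    def save(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("metrics", "contrasts", "correlations", "roc", "sensitivity",
                     "diagnostics"):
            p = out / f"{name}.csv"
            getattr(self, name).to_csv(p, index=False, float_format="%.12g")
            paths[name] = p
        return paths


class ConnectomeStudy:
    """Cohort-level analysis model for structural connectome studies.

    Parameters
    ----------
    cohort
        Subject records plus connectivity matrices.
    covariates
        Adjustment set for the linear models and partial correlations.
    trim_top
        Number of highest-wCPL case-group subjects removed in the
        sensitivity re-analysis.
    wcpl_threshold
        Reporting cutoff for the count of high-wCPL subjects.
    swn_mode, n_nulls
        Small-worldness variant (``plain`` ratio or ``normalized`` against
        degree-preserving rewired nulls) and null-ensemble size.
    """

    def __init__(
        self,
        cohort: CohortTable,
        covariates: Sequence[str] = DEFAULT_COVARIATES,
        metrics: Sequence[str] = DEFAULT_METRICS,
        fdr_alpha: float = 0.05,
        trim_top: int = 3,
        wcpl_threshold: float = 80.0,
        swn_mode: str = "plain",
        n_nulls: int = 0,
        seed: int = 0,
    ) -> None:
        self.cohort = cohort
        self.covariates = tuple(covariates)
        self.metrics = tuple(metrics)
        self.fdr_alpha = float(fdr_alpha)
        self.trim_top = int(trim_top)
        self.wcpl_threshold = float(wcpl_threshold)
        self.swn_mode = swn_mode
        self.n_nulls = int(n_nulls)
        self.seed = int(seed)

    @classmethod
    def from_simulation(
        cls,
        config: simulate.CohortConfig | dict | None = None,
        seed: int | None = None,
        **kwargs,
    ) -> "ConnectomeStudy":
        if isinstance(config, dict):
            config = simulate.CohortConfig.from_dict(config)
        config = config or simulate.CohortConfig()
        if seed is not None:
            config.seed = int(seed)
        cohort = simulate.generate_cohort(config)
        return cls(cohort, seed=config.seed, **kwargs)

    @classmethod
    def from_files(
        cls, matrices: Sequence[str | Path], metadata: str | Path, **kwargs
    ) -> "ConnectomeStudy":
        records = read_metadata(metadata)
        mats = {}
        for p in matrices:
            p = Path(p)
            mats[p.stem] = read_matrix(p)
        cohort = CohortTable(records, mats)
        return cls(cohort, **kwargs)

    def fit(self) -> StudyResults:
        """Compute metrics and run the full statistical battery."""
        mdf = graph.metrics_for_cohort(
            self.cohort, swn_mode=self.swn_mode, n_nulls=self.n_nulls, seed=self.seed
        )
        meta = records_to_frame(self.cohort.records)
        df = meta.merge(mdf, on="subject_id", validate="1:1")

        contrasts = contrasts_table(df, self.metrics, self.covariates)
        correlations = correlations_table(
            df, covariates=self.covariates, alpha=self.fdr_alpha
        )
        roc_df = roc_table(df, covariates=[c for c in ("age", "education", "body_mass") if c in df.columns])
        feat_corr = None
        if df["cortical_complexity"].notna().all():
            feat_corr = roc_mod.feature_correlation(
                df["wcpl"].to_numpy(dtype=float),
                df["cortical_complexity"].to_numpy(dtype=float),
            )
        try:
            sens_df, sens = sensitivity_table(
                df, k=self.trim_top, covariates=self.covariates,
                threshold=self.wcpl_threshold,
            )
        except ValueError as exc:
            logger.warning("sensitivity analysis skipped: %s", exc)
            sens_df, sens = pd.DataFrame(), None
        diag_rows = []
        for metric in self.metrics:
            try:
                d = stats.distribution_diagnostics(df[metric])
            except ValueError:
                continue
            diag_rows.append(dict(metric=metric, **vars(d)))
        return StudyResults(
            metrics=df,
            contrasts=contrasts,
            correlations=correlations,
            roc=roc_df,
            sensitivity=sens_df,
            diagnostics=pd.DataFrame(diag_rows),
            feature_correlation=feat_corr,
            sensitivity_detail=sens,
            seed=self.seed,
            settings=dict(
                covariates=list(self.covariates),
                metrics=list(self.metrics),
                fdr_alpha=self.fdr_alpha,
                trim_top=self.trim_top,
                wcpl_threshold=self.wcpl_threshold,
                swn_mode=self.swn_mode,
                n_nulls=self.n_nulls,
            ),
        )
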