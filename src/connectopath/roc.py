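"""Discrimination analysis: ROC / AUC with DeLong confidence intervals and
logistic combined scores.

The AUC is the Mann–Whitney estimate (ties contribute 1/2): the probability
that a randomly chosen case scores above a randomly chosen non-case.  Its
95% CI uses the DeLong structural-components variance estimator.  The
combined score is an in-sample logistic fit of the label on imaging features
plus demographic covariates; the apparent (optimistically biased) AUC of the
fitted probabilities is reported and flagged as such.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .stats import StatResult, adjusted_spearman

logger = logging.getLogger("connectopath")


@dataclass
class RocResult:
    """AUC with a DeLong 95% confidence interval."""

    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    model: str = "single_feature"
    apparent: bool = False  # in-sample fit of a multi-feature score

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.auc <= self.ci_high):
            raise ValueError("CI does not bracket the AUC")
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("both classes must be present")


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def delong_auc_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Mann–Whitney AUC and its DeLong variance.

    Uses the structural components V10 (per case) and V01 (per non-case):
    ``var = S10 / m + S01 / n`` with the sample variances of the components.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    m, n = len(pos), len(neg)
    if m < 1 or n < 1:
        raise ValueError("both classes must be present")
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n  # P(score_neg < pos_i), ties half
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def roc_auc(scores, labels, model: str = "single_feature") -> RocResult:
    """AUC by the Mann–Whitney construction with a DeLong 95% CI."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or (~labels).all():
        raise ValueError("both classes must be present")
    if np.all(scores == scores[0]):
        logger.warning("all scores tied; AUC undefined, reporting 0.5")
        m, n = int(labels.sum()), int((~labels).sum())
        return RocResult(0.5, 0.5, 0.5, m, n, model=model)
    auc, var = delong_auc_variance(scores, labels)
    half = 1.959963984540054 * np.sqrt(var)
    return RocResult(
        auc=auc,
        ci_low=float(max(0.0, auc - half)),
        ci_high=float(min(1.0, auc + half)),
        n_pos=int(labels.sum()),
        n_neg=int((~labels).sum()),
        model=model,
    )


def combined_score(
    features: pd.DataFrame,
    labels,
    covariates: pd.DataFrame | None = None,
) -> tuple[np.ndarray, RocResult]:
    """Logistic combination of features (+ covariates) scored in-sample.

    Returns the fitted probabilities and their apparent AUC.  Perfect
    separation (or non-convergence) triggers a ridge-penalized fallback fit
    with a warning; the result is still the in-sample score.
    """
    labels = np.asarray(labels).astype(int)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    parts = [pd.DataFrame(features).reset_index(drop=True)]
    if covariates is not None and pd.DataFrame(covariates).shape[1]:
        parts.append(
            pd.get_dummies(
                pd.DataFrame(covariates).reset_index(drop=True),
                drop_first=True,
                dtype=float,
            )
        )
    X = pd.concat(parts, axis=1).to_numpy(dtype=float)
    design = np.column_stack([np.ones(len(labels)), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design matrix")
    probs = None
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        try:
            fit = sm.Logit(labels, design).fit(disp=0, maxiter=200)
            if np.isfinite(fit.params).all() and np.abs(fit.params).max() < 1e3:
                probs = np.asarray(fit.predict(design))
        except Exception:
            probs = None
    if probs is None:
        logger.warning(
            "logistic fit unstable (possible perfect separation); "
            "using ridge-penalized fallback"
        )
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(C=100.0, max_iter=5000)
        clf.fit(X, labels)
        probs = clf.predict_proba(X)[:, 1]
    result = roc_auc(probs, labels, model="combined")
    result.apparent = True
    return probs, result


def feature_correlation(f1, f2) -> StatResult:
    """Spearman correlation between two imaging features (no covariates)."""
    return adjusted_spearman(f1, f2, covariates=None, contrast="feature_1_vs_feature_2")
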