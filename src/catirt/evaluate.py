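"""Efficiency and validity summaries of adaptive-test simulations.

Per-stopping-rule efficiency (item usage, mean SE, marginal reliability,
agreement with full-bank scores) and predictive utility against a binary
criterion (trapezoidal AUC with a Hanley–McNeil interval, the Youden-index
cut-off, sensitivity and specificity).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

from .engine import CATRecord


@dataclass
class EfficiencySummary:
    rule: str
    mean_items: float
    sd_items: float
    pct_of_bank: int
    mean_se: float
    marginal_reliability: float
    r_with_full_bank: float | None
    r_with_external: float | None


def percent_of_bank(mean_items: float, bank_size: int) -> int:
    """Mean items used as an integer percentage of the bank size."""
    if bank_size <= 0:
        raise ValueError("bank size must be positive")
    return int(round(100.0 * mean_items / bank_size))


def marginal_reliability(ses: Sequence[float], method: str = "mean_se2") -> float:
    """Sample-level reliability from per-person standard errors.

    ``mean_se2`` (default) is 1 - mean(SE^2), the average of the per-person
    reliabilities under the unit-variance trait scale.  ``variance_ratio``
    uses var(theta_hat) / (var(theta_hat) + mean(SE^2)) instead; it needs
    the estimates themselves, so it is exposed separately via
    :func:`variance_ratio_reliability`.
    """
    ses = np.asarray(ses, dtype=float)
    if method != "mean_se2":
        raise ValueError("use variance_ratio_reliability for the alternative form")
    return float(1.0 - np.mean(ses**2))


def variance_ratio_reliability(thetas: Sequence[float], ses: Sequence[float]) -> float:
    thetas = np.asarray(thetas, float)
    ses = np.asarray(ses, float)
    v = float(np.var(thetas, ddof=1))
    return v / (v + float(np.mean(ses**2)))


def summarize_efficiency(
    records_by_rule: Mapping[str, Sequence[CATRecord]],
    bank_size: int,
    full_bank_thetas: Sequence[float] | None = None,
    external_scores: Sequence[float] | None = None,
) -> list[EfficiencySummary]:
    """Per-rule efficiency summaries in stopping-rule order.

    Correlations with the full-bank estimates and with an external score
    are reported when those references are supplied and at least 3 persons
    are available; otherwise they are None.
    """
    out = []
    for rule, records in records_by_rule.items():
        n_items = np.array([r.n_items for r in records], dtype=float)
        ses = np.array([r.final.se for r in records], dtype=float)
        thetas = np.array([r.final.theta for r in records], dtype=float)
        r_full = r_ext = None
        if len(records) >= 3:
            if full_bank_thetas is not None:
                r_full = float(stats.pearsonr(thetas, np.asarray(full_bank_thetas))[0])
            if external_scores is not None:
                r_ext = float(stats.pearsonr(thetas, np.asarray(external_scores))[0])
        out.append(
            EfficiencySummary(
                rule=rule,
                mean_items=float(n_items.mean()),
                sd_items=float(n_items.std(ddof=1)) if len(records) > 1 else 0.0,
                pct_of_bank=percent_of_bank(float(n_items.mean()), bank_size),
                mean_se=float(ses.mean()),
                marginal_reliability=marginal_reliability(ses),
                r_with_full_bank=r_full,
                r_with_external=r_ext,
            )
        )
    return out


@dataclass
class ROCResult:
    auc: float
    auc_ci_95: tuple[float, float]
    cutoff: float
    sensitivity: float
    specificity: float

    @property
    def youden(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def youden_index(sensitivity: float, specificity: float) -> float:
    """Youden's J = sensitivity + specificity - 1."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return sensitivity + specificity - 1.0


def _hanley_mcneil_ci(auc: float, n_pos: int, n_neg: int) -> tuple[float, float]:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    se = np.sqrt(max(var, 0.0))
    return (max(auc - 1.96 * se, 0.0), min(auc + 1.96 * se, 1.0))


def roc_analysis(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """ROC curve summary of a continuous score against binary labels.

    The AUC is the trapezoidal area under the empirical ROC curve, which
    equals the tie-adjusted Mann–Whitney concordance probability.  The
    reported cut-off maximises the Youden index; among ties the lowest
    threshold is returned.  The 95% CI uses the Hanley–McNeil closed form.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"labels must contain exactly two classes, got {classes}")
    y = (labels == classes.max()).astype(int)
    fpr, tpr, thresholds = roc_curve(y, scores)
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    best = np.where(j == j.max())[0]
    # thresholds are decreasing; the last tied index is the lowest threshold
    pick = int(best[-1])
    cutoff = float(thresholds[pick])
    sens = float(tpr[pick])
    spec = float(1.0 - fpr[pick])
    ci = _hanley_mcneil_ci(auc, int(y.sum()), int((1 - y).sum()))
    return ROCResult(auc, ci, cutoff, sens, spec)


def criterion_validity(
    trait_estimates: Sequence[float], criterion_scores: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation (and two-sided p) between trait estimates and an
    external criterion score."""
    x = np.asarray(trait_estimates, float)
    y = np.asarray(criterion_scores, float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input; correlation not computable")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
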