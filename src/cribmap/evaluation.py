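"""Patient-level diagnostic performance: ROC-AUC, PR-AUC, bootstrap CIs.

ROC-AUC follows the Mann-Whitney convention (ties count one half); PR-AUC
uses the average-precision (right-step) convention, never interpolated
precision.  Confidence intervals are percentile bootstrap over patients,
with degenerate single-class resamples skipped and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = ["EvalResult", "roc_auc", "pr_auc", "bootstrap_ci", "evaluate"]


def _validate(scores, labels):
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).ravel().astype(int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    if not np.all(np.isin(y, (0, 1))):
        raise ValueError("labels must be binary 0/1")
    return s, y


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (equals P(s+ > s-) + 0.5 P(s+ = s-))."""
    s, y = _validate(scores, labels)
    if y.min() == y.max():
        raise ValueError("ROC-AUC needs both classes present")
    return float(roc_auc_score(y, s))


def pr_auc(scores, labels) -> float:
    """Area under the precision-recall curve, average-precision convention."""
    s, y = _validate(scores, labels)
    if y.sum() == 0:
        raise ValueError("PR-AUC needs at least one positive")
    return float(average_precision_score(y, s))


def bootstrap_ci(
    scores,
    labels,
    metric=roc_auc,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
):
    """Percentile bootstrap CI for a patient-level metric.

    Patients are resampled with replacement ``n_boot`` times; resamples
    with a single class (degenerate for both metrics here) are skipped and
    counted.  Returns ``(low, high, n_skipped)``.

    Raises
    ------
    ValueError
        If more than half of the resamples are degenerate — the sample is
        too small or imbalanced for a meaningful interval.
    """
    s, y = _validate(scores, labels)
    if y.min() == y.max():
        raise ValueError("bootstrap needs both classes present")
    rng = np.random.default_rng(seed)
    n = len(s)
    stats = []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if yb.min() == yb.max():
            skipped += 1
            continue
        stats.append(metric(s[idx], yb))
    if skipped > n_boot / 2:
        raise ValueError(
            f"{skipped}/{n_boot} bootstrap resamples were single-class; "
            "sample too small or imbalanced for a CI"
        )
    lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi), skipped


@dataclass
class EvalResult:
    """Point estimates plus bootstrap 95% CIs for one patient group."""

    auroc: float
    auprc: float
    prevalence: float
    auroc_ci: tuple[float, float]
    auprc_ci: tuple[float, float]
    n: int
    n_boot: int
    seed: int
    n_skipped: int = 0

    def to_dict(self) -> dict:
        return {
            "auroc": self.auroc,
            "auroc_ci": list(self.auroc_ci),
            "auprc": self.auprc,
            "auprc_ci": list(self.auprc_ci),
            "prevalence": self.prevalence,
            "n": self.n,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "n_skipped_resamples": self.n_skipped,
        }


def evaluate(scores, labels, n_boot: int = 1000, seed: int = 0) -> EvalResult:
    """Full patient-level evaluation of a score vector against labels."""
    s, y = _validate(scores, labels)
    a_lo, a_hi, sk1 = bootstrap_ci(s, y, roc_auc, n_boot=n_boot, seed=seed)
    p_lo, p_hi, sk2 = bootstrap_ci(s, y, pr_auc, n_boot=n_boot, seed=seed + 1)
    return EvalResult(
        auroc=roc_auc(s, y),
        auprc=pr_auc(s, y),
        prevalence=float(y.mean()),
        auroc_ci=(a_lo, a_hi),
        auprc_ci=(p_lo, p_hi),
        n=len(y),
        n_boot=n_boot,
        seed=seed,
        n_skipped=sk1 + sk2,
    )
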