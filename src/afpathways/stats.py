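"""Cohort comparison of PV activation flow metrics.

Responder vs non-responder groups are compared with the Wilcoxon
rank-sum (Mann-Whitney U) test — the rank test appropriate for two
independent groups of unequal size.  The AUC is the normalized U
statistic (probability that a random responder outranks a random
non-responder, ties counted half); sensitivity and specificity are
reported at the threshold maximizing Youden's J, with the threshold
echoed since the operating point is a free choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as spstats

__all__ = ["CohortResult", "compare_groups", "roc_auc"]


@dataclass
class CohortResult:
    responders: np.ndarray
    nonresponders: np.ndarray
    statistic: float
    p_value: float
    auc: float
    sensitivity: float
    specificity: float
    threshold: float

    def to_dict(self) -> dict:
        return {
            "n_responders": int(len(self.responders)),
            "n_nonresponders": int(len(self.nonresponders)),
            "median_responders": float(np.median(self.responders)),
            "median_nonresponders": float(np.median(self.nonresponders)),
            "statistic": self.statistic,
            "p_value": self.p_value,
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "threshold": self.threshold,
        }


def roc_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney U (ties count half)."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    u = spstats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u / (len(pos) * len(neg)))


def compare_groups(responders: Sequence[float], nonresponders: Sequence[float],
                   *, method: str = "auto") -> CohortResult:
    """Rank-sum comparison plus ROC operating characteristics.

    ``method`` is passed to :func:`scipy.stats.mannwhitneyu` (``exact``,
    ``asymptotic`` or ``auto``).  Responders are the positive class.
    """
    resp = np.asarray(list(responders), dtype=float)
    nonr = np.asarray(list(nonresponders), dtype=float)
    if len(resp) == 0 or len(nonr) == 0:
        raise ValueError("both groups must be nonempty")
    res = spstats.mannwhitneyu(resp, nonr, alternative="two-sided", method=method)
    auc = float(res.statistic / (len(resp) * len(nonr)))

    # Youden-optimal operating point over candidate thresholds
    values = np.unique(np.concatenate([resp, nonr]))
    best = (-np.inf, np.nan, np.nan, np.nan)
    for thr in values:
        sens = float(np.mean(resp >= thr))
        spec = float(np.mean(nonr < thr))
        j = sens + spec - 1.0
        if j > best[0]:
            best = (j, sens, spec, float(thr))
    _, sens, spec, thr = best
    return CohortResult(
        responders=resp,
        nonresponders=nonr,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        auc=auc,
        sensitivity=sens,
        specificity=spec,
        threshold=thr,
    )
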