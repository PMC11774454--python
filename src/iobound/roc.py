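"""ROC-curve construction and nonparametric AUC estimation.

The AUC estimator is the two-sample rank (Mann-Whitney) statistic with ties
counted one half; its standard error is the Hanley-McNeil closed form.  The
empirical ROC curve is built at every distinct test-statistic value, and its
trapezoidal area coincides exactly with the rank estimator (ties trace
diagonal segments).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = ["AUCResult", "ROCCurve", "estimate_auc", "roc_curve",
           "bootstrap_auc_se"]


@dataclass
class AUCResult:
    """AUC point estimate with its standard error and sample sizes."""

    auc: float
    se: float
    n_h0: int
    n_h1: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("auc must lie in [0, 1]")
        if self.se < 0:
            raise ValueError("se must be nonnegative")

    def __str__(self) -> str:
        return (f"AUC = {self.auc:.4f} +/- {self.se:.4f} "
                f"(n0={self.n_h0}, n1={self.n_h1})")


@dataclass
class ROCCurve:
    """Empirical ROC: thresholds descending, FPF/TPF non-decreasing."""

    thresholds: np.ndarray
    fpf: np.ndarray
    tpf: np.ndarray

    def area(self) -> float:
        """Trapezoidal area under the curve."""
        return float(np.trapezoid(self.tpf, self.fpf))


def estimate_auc(t_h0, t_h1) -> AUCResult:
    """Mann-Whitney AUC with ties counted 1/2, Hanley-McNeil standard error."""
    t0 = np.asarray(t_h0, dtype=float).ravel()
    t1 = np.asarray(t_h1, dtype=float).ravel()
    if t0.size == 0 or t1.size == 0:
        raise ValueError("both statistic lists must be nonempty")
    n0, n1 = t0.size, t1.size
    ranks = rankdata(np.concatenate([t0, t1]))
    auc = (ranks[n0:].sum() - n1 * (n1 + 1) / 2) / (n0 * n1)
    auc = float(min(max(auc, 0.0), 1.0))
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2)
           + (n0 - 1) * (q2 - auc**2)) / (n0 * n1)
    return AUCResult(auc=auc, se=float(np.sqrt(max(var, 0.0))),
                     n_h0=n0, n_h1=n1)


def roc_curve(t_h0, t_h1) -> ROCCurve:
    """Empirical ROC at every distinct statistic value.

    A case is called positive when its statistic is >= the threshold; the
    curve therefore starts at (0, 0) for threshold +inf and ends at (1, 1)
    for threshold -inf.
    """
    t0 = np.asarray(t_h0, dtype=float).ravel()
    t1 = np.asarray(t_h1, dtype=float).ravel()
    if t0.size == 0 or t1.size == 0:
        raise ValueError("both statistic lists must be nonempty")
    taus = np.unique(np.concatenate([t0, t1]))[::-1]
    thresholds = np.concatenate([[np.inf], taus, [-np.inf]])
    fpf = np.array([np.mean(t0 >= tau) for tau in thresholds])
    tpf = np.array([np.mean(t1 >= tau) for tau in thresholds])
    return ROCCurve(thresholds=thresholds, fpf=fpf, tpf=tpf)


def bootstrap_auc_se(t_h0, t_h1, n_boot: int = 1000, seed: int = 0) -> float:
    """Bootstrap cross-check of the closed-form AUC standard error."""
    t0 = np.asarray(t_h0, dtype=float).ravel()
    t1 = np.asarray(t_h1, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for i in range(n_boot):
        b0 = t0[rng.integers(t0.size, size=t0.size)]
        b1 = t1[rng.integers(t1.size, size=t1.size)]
        aucs[i] = estimate_auc(b0, b1).auc
    return float(aucs.std(ddof=1))
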