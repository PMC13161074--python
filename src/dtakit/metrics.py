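"""Evaluation metrics: RMSE, Pearson R, Spearman rho, concordance index.

Pearson and Spearman delegate to scipy.stats (Spearman uses mid-rank tie
handling; on tie-free data it coincides with the classical
1 - 6*sum(d^2)/(n(n^2-1)) formula).  The concordance index is implemented
here directly from its definition: over all ordered pairs with y_i > y_j,
credit 1 for a correctly ordered prediction, 0.5 for a tie, 0 otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError


@dataclass
class MetricBundle:
    rmse: float
    pearson: float
    spearman: float
    ci: float
    n: int

    def __post_init__(self):
        if self.rmse < 0 or not (0.0 <= self.ci <= 1.0):
            raise DomainError("metric out of range")

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "pearson": self.pearson,
            "spearman": self.spearman,
            "ci": self.ci,
            "n": self.n,
        }


def _check(y, y_hat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.size == 0 or y.shape != y_hat.shape:
        raise DomainError("inputs must be non-empty and of equal length")
    return y, y_hat


def rmse(y, y_hat) -> float:
    y, y_hat = _check(y, y_hat)
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def pearson(y, y_hat) -> float:
    y, y_hat = _check(y, y_hat)
    if y.size < 2 or np.ptp(y) == 0 or np.ptp(y_hat) == 0:
        raise DomainError("Pearson correlation undefined for constant input")
    return float(stats.pearsonr(y, y_hat).statistic)


def spearman(y, y_hat) -> float:
    y, y_hat = _check(y, y_hat)
    if y.size < 2 or np.ptp(y) == 0 or np.ptp(y_hat) == 0:
        raise DomainError("Spearman correlation undefined for constant input")
    return float(stats.spearmanr(y, y_hat).statistic)


def concordance_index(y, y_hat) -> float:
    """P(correct ranking) over ordered pairs with y_i > y_j; prediction ties
    count 0.5.  Errors when no pair has y_i > y_j."""
    y, y_hat = _check(y, y_hat)
    # pairwise differences, vectorized; for n<=a few thousand this is fine
    dy = y[:, None] - y[None, :]
    dyh = y_hat[:, None] - y_hat[None, :]
    valid = dy > 0
    z = int(valid.sum())
    if z == 0:
        raise DomainError("concordance index undefined: no pair with y_i > y_j")
    h = np.where(dyh > 0, 1.0, np.where(dyh == 0, 0.5, 0.0))
    return float(h[valid].sum() / z)


def metric_bundle(y, y_hat) -> MetricBundle:
    y, y_hat = _check(y, y_hat)
    return MetricBundle(
        rmse=rmse(y, y_hat),
        pearson=pearson(y, y_hat),
        spearman=spearman(y, y_hat),
        ci=concordance_index(y, y_hat),
        n=int(y.size),
    )
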