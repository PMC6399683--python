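"""Fisher's combined probability test in log/statistic space.

Local log p-values computed on independent Sample Subsets are merged into a
single global p-value via ``Statistic = -2 sum_i log p_i ~ chi2(2K)``.
Independence of the local values is ensured upstream by the random row
partition.  All arithmetic stays on the log scale: local p-values are never
exponentiated, so combining works unchanged when individual log p-values are
on the order of -1e5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2 as _chi2

from .cit import chi2_log_sf

__all__ = ["CombinedPValue", "fisher_combine", "fisher_statistic", "statistic_threshold"]

#: floor applied to a local log p-value of exactly -inf (p = 0) so a single
#: degenerate block cannot make the combination non-finite while preserving
#: its rank as "smallest possible".
LOG_P_FLOOR = -1e12


@dataclass(frozen=True)
class CombinedPValue:
    statistic: float
    K: int
    log_pvalue: float


def fisher_statistic(log_ps) -> float:
    """``-2 sum(log p_i)`` with non-finite local values floored at -1e12."""
    lp = np.asarray(log_ps, dtype=float)
    if lp.size == 0:
        raise ValueError("cannot combine an empty set of p-values")
    if np.any(lp > 0):
        raise ValueError("log p-values must be <= 0")
    lp = np.maximum(lp, LOG_P_FLOOR)
    return float(-2.0 * lp.sum())


def fisher_combine(log_ps) -> CombinedPValue:
    """Combine local log p-values into a global one via Fisher's method."""
    lp = np.asarray(log_ps, dtype=float).ravel()
    stat = fisher_statistic(lp)
    K = lp.size
    return CombinedPValue(statistic=stat, K=K, log_pvalue=chi2_log_sf(stat, 2 * K))


def statistic_threshold(alpha: float, K: int) -> float:
    """Fisher-statistic value equivalent to combined significance ``alpha``.

    Returns the upper-tail ``chi2(2K)`` quantile at ``alpha``, so that
    ``statistic >= threshold  <=>  combined p <= alpha``.  Bootstrap rounds
    compare resampled statistics against this threshold instead of
    computing a log p-value per resample.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    return float(_chi2.isf(alpha, 2 * K))
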