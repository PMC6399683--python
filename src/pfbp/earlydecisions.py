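"""Bootstrap tests for the Early Dropping / Early Stopping / Early Return decisions.

After each Group of Sample Subsets is processed, the master holds matrices
``Pi`` (local log p-values) and ``Lambda`` (local log-likelihoods) with one
row per processed Sample Subset and one column per Alive feature.  The three
pruning heuristics ask, respectively:

* **Early Dropping** -- is ``P(combined p of X_j >= alpha)`` at least
  ``P_drop``?  Then X_j is judged conditionally independent of the target
  and leaves the Run.
* **Early Stopping** -- is ``P(current best beats X_j)`` at least
  ``P_stop``?  Then X_j cannot win this Iteration and leaves it.
* **Early Return** -- is, for every alive X_j, ``P(lambda_best - lambda_j
  >= lt)`` at least ``P_return``?  Then the current best is within the
  likelihood tolerance of every competitor and is returned immediately.

Each probability is estimated by resampling the *rows* of ``Pi``/``Lambda``
with replacement ``B`` times; the indicator is also evaluated on the
original sample and the denominator is ``B + 1``.  One shared matrix of
resample indices drives all variables and all three tests in a round, and
all comparisons happen in Fisher-statistic space (larger statistic =
smaller p-value), so no log p-value is ever computed per resample.  An
upper-bound early abort skips the remaining resamples for a variable as
soon as its decision is settled; it is decision-equivalent to running all
``B`` resamples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .meta import LOG_P_FLOOR, statistic_threshold

__all__ = [
    "PiLambdaStore",
    "HeuristicConfig",
    "bootstrap_indices",
    "min_qualifying_count",
    "early_dropping",
    "early_stopping",
    "early_return",
]


@dataclass
class PiLambdaStore:
    """Growing matrices of local log p-values and log-likelihoods.

    ``Pi`` and ``Lambda`` always have identical shape ``(K, n_alive)``;
    columns are removed atomically from both when a feature stops being
    Alive.
    """

    Pi: np.ndarray
    Lambda: np.ndarray
    column_labels: list

    @classmethod
    def empty(cls, column_labels) -> "PiLambdaStore":
        m = len(column_labels)
        return cls(
            Pi=np.empty((0, m)), Lambda=np.empty((0, m)), column_labels=list(column_labels)
        )

    @property
    def K(self) -> int:
        return self.Pi.shape[0]

    @property
    def n_alive(self) -> int:
        return self.Pi.shape[1]

    def append_rows(self, pi_rows: np.ndarray, lambda_rows: np.ndarray) -> None:
        pi_rows = np.atleast_2d(pi_rows)
        lambda_rows = np.atleast_2d(lambda_rows)
        if pi_rows.shape != lambda_rows.shape or pi_rows.shape[1] != self.n_alive:
            raise ValueError("row blocks must match the store's column count")
        if np.any(pi_rows > 0):
            raise ValueError("log p-values must be <= 0")
        self.Pi = np.vstack([self.Pi, pi_rows])
        self.Lambda = np.vstack([self.Lambda, lambda_rows])

    def keep_columns(self, mask: np.ndarray) -> None:
        mask = np.asarray(mask, dtype=bool)
        self.Pi = self.Pi[:, mask]
        self.Lambda = self.Lambda[:, mask]
        self.column_labels = [c for c, m in zip(self.column_labels, mask) if m]

    def combined_statistics(self) -> np.ndarray:
        """Fisher statistic per column over all processed rows."""
        return -2.0 * np.maximum(self.Pi, LOG_P_FLOOR).sum(axis=0)

    def lambda_sums(self) -> np.ndarray:
        return self.Lambda.sum(axis=0)


@dataclass(frozen=True)
class HeuristicConfig:
    """Thresholds and bootstrap size for the early-decision tests.

    Defaults follow the recommended operating point: ``alpha = 0.01``,
    ``P_drop = P_stop = 0.99``, ``P_return = 0.95``, likelihood tolerance
    ``tol = 0.9`` (so ``lt = ln 0.9``), and ``B = 500`` resamples (500 is
    the minimum recommended value).  Setting the three probability
    thresholds above 1 disables the corresponding tests: no count can reach
    the bar.
    """

    alpha: float = 0.01
    P_drop: float = 0.99
    P_stop: float = 0.99
    P_return: float = 0.95
    tol: float = 0.9
    B: int = 500
    early_abort: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not (0.0 < self.tol <= 1.0):
            raise ValueError("tol must lie in (0, 1]")
        for name in ("P_drop", "P_stop", "P_return"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def lt(self) -> float:
        return math.log(self.tol)

    @classmethod
    def disabled(cls, alpha: float = 0.01, B: int = 1) -> "HeuristicConfig":
        """A configuration under which no bootstrap heuristic ever fires."""
        return cls(alpha=alpha, P_drop=2.0, P_stop=2.0, P_return=2.0, B=B)


def bootstrap_indices(K: int, B: int, seed) -> np.ndarray:
    """``(B, K)`` matrix of row indices sampled with replacement.

    The same matrix is reused for every variable and all three tests within
    one decision round, which both saves time and makes decisions exactly
    reproducible from the seed.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.integers(0, K, size=(B, K))


def min_qualifying_count(threshold: float, B: int) -> int:
    """Smallest count ``c`` with ``c / (B + 1) >= threshold``.

    E.g. with ``B = 999`` and a 0.99 threshold, 990 of the 1000 samples
    (original included) must satisfy the inequality.
    """
    return int(math.ceil(threshold * (B + 1) - 1e-9))


def _multiplicity(indices: np.ndarray, K: int) -> np.ndarray:
    """``(B, K)`` multiplicity matrix: how often each row enters each resample."""
    B = indices.shape[0]
    out = np.zeros((B, K), dtype=np.float64)
    rows = np.repeat(np.arange(B), indices.shape[1])
    np.add.at(out, (rows, indices.ravel()), 1.0)
    return out


def _count_qualifying(
    orig_ind: np.ndarray,
    resample_ind_chunks,
    B: int,
    required: int,
    early_abort: bool,
):
    """Count indicator successes per variable with optional early abort.

    ``orig_ind`` is the 0/1 indicator on the original sample;
    ``resample_ind_chunks`` yields 0/1 indicator arrays of shape
    ``(chunk, m)`` for consecutive resamples.  Returns a boolean
    "qualifies" mask; the abort merely stops counting once every variable's
    decision is settled, so results are identical with or without it.
    """
    m = orig_ind.size
    counts = orig_ind.astype(np.int64).copy()
    remaining = B
    undecided = np.ones(m, dtype=bool)
    for chunk in resample_ind_chunks:
        if early_abort and not undecided.any():
            break
        counts += chunk.sum(axis=0)
        remaining -= chunk.shape[0]
        if early_abort:
            # settled: already qualified, or cannot reach the bar any more
            undecided &= counts < required
            undecided &= counts + remaining >= required
    return counts >= required


def _resampled_stat_chunks(matrix: np.ndarray, indices: np.ndarray, chunk_size: int = 64):
    """Yield ``(chunk, m)`` arrays of resampled column sums of ``matrix``."""
    K = matrix.shape[0]
    B = indices.shape[0]
    for start in range(0, B, chunk_size):
        mult = _multiplicity(indices[start : start + chunk_size], K)
        yield mult @ matrix


def early_dropping(
    store: PiLambdaStore, config: HeuristicConfig, indices: np.ndarray
) -> np.ndarray:
    """Boolean mask of Alive features to Drop from the Run.

    Feature j is dropped when the estimated probability that its
    end-of-Iteration combined p-value is at least ``alpha`` reaches
    ``P_drop``.  The comparison runs in statistic space against the
    ``chi2(2K)`` quantile for ``alpha``:  ``combined p >= alpha`` is
    exactly ``statistic <= threshold``.
    """
    K = store.K
    if K < 1:
        raise ValueError("no processed rows")
    thr = statistic_threshold(config.alpha, K)
    floored = -2.0 * np.maximum(store.Pi, LOG_P_FLOOR)
    orig = floored.sum(axis=0) <= thr
    required = min_qualifying_count(config.P_drop, config.B)
    if required > config.B + 1:  # disabled: unreachable
        return np.zeros(store.n_alive, dtype=bool)
    chunks = (s <= thr for s in _resampled_stat_chunks(floored, indices))
    return _count_qualifying(orig, chunks, config.B, required, config.early_abort)


def early_stopping(
    store: PiLambdaStore,
    config: HeuristicConfig,
    indices: np.ndarray,
    reverse: bool = False,
) -> np.ndarray:
    """Boolean mask of Alive features to Stop for this Iteration.

    In a forward Iteration (``reverse=False``) feature j is stopped when
    the current best -- the feature with the smallest combined p-value on
    the rows seen so far, ties resolved toward the lowest column index --
    beats it in at least a ``P_stop`` share of resamples; the best feature
    itself is never stopped.  In a backward Iteration (``reverse=True``)
    the roles flip: features unlikely to be the *worst* (largest combined
    p) are stopped.
    """
    m = store.n_alive
    if m < 2:
        return np.zeros(m, dtype=bool)
    floored = -2.0 * np.maximum(store.Pi, LOG_P_FLOOR)
    stats = floored.sum(axis=0)
    required = min_qualifying_count(config.P_stop, config.B)
    if required > config.B + 1:
        return np.zeros(m, dtype=bool)
    if reverse:
        # pivot = current worst (smallest statistic); j stopped if pivot's
        # statistic stays below j's (j is unlikely to be removed)
        pivot = int(np.argmin(stats))
        orig = stats > stats[pivot]
        chunks = (s > s[:, [pivot]] for s in _resampled_stat_chunks(floored, indices))
    else:
        pivot = int(np.argmax(stats))
        orig = stats < stats[pivot]
        chunks = (s < s[:, [pivot]] for s in _resampled_stat_chunks(floored, indices))
    mask = _count_qualifying(orig, chunks, config.B, required, config.early_abort)
    mask[pivot] = False
    return mask


def early_return(
    store: PiLambdaStore, config: HeuristicConfig, indices: np.ndarray
) -> bool:
    """True when the current best may be returned without processing more Groups.

    The best feature (smallest combined p-value so far) is returned when,
    for *every* alive feature j, the probability that the best's summed
    log-likelihood is within ``lt = log(tol)`` of j's reaches
    ``P_return``.
    """
    m = store.n_alive
    if m < 1 or store.K < 1:
        return False
    required = min_qualifying_count(config.P_return, config.B)
    if required > config.B + 1:
        return False
    stats = store.combined_statistics()
    best = int(np.argmax(stats))
    lt = config.lt
    lam = store.lambda_sums()
    orig = lam[best] - lam >= lt
    chunks = (
        s[:, [best]] - s >= lt for s in _resampled_stat_chunks(store.Lambda, indices)
    )
    qualifies = _count_qualifying(orig, chunks, config.B, required, config.early_abort)
    return bool(qualifies.all())
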