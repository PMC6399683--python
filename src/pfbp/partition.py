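"""Row/column partitioning of the data matrix into Sample Subsets, Feature Subsets and Groups.

The partition geometry is driven by two statistical sizing rules for the
rows-per-block count ``s`` of a local logistic-regression test:

* the EPV (events-per-variable) rule ``s = c / min(p0, p1) * df``, and
* the STD rule ``s = df * c / sqrt(p0 * p1)``,

where ``df`` is the worst-case number of model parameters (``max_vars + 1``
when every feature is continuous), ``c`` a constant recommended to be at
least 10 and ``(p0, p1)`` the class proportions of the binary target.  For
balanced classes the two rules coincide; for skewed classes the STD rule
requires fewer rows.

Sample Subsets are grouped into Groups of ``C`` subsets each; the bootstrap
decision heuristics fire once per processed Group.  Feature Subsets split
the columns so that roughly ``workers ~ C * nf`` blocks can be processed
concurrently.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SizingInputs",
    "PartitionPlan",
    "block_sample_size",
    "plan_partition",
    "assign_rows",
    "DEFAULT_C",
    "MIN_RECOMMENDED_C",
]

#: Sample Subsets per Group used unless the data supports fewer.
DEFAULT_C = 30
#: Below this many subsets per Group the first round of bootstrap tests is unreliable.
MIN_RECOMMENDED_C = 15


class SizingError(ValueError):
    """Raised when no valid block size exists for the requested inputs."""


@dataclass(frozen=True)
class SizingInputs:
    """Inputs to the block sizing rules.

    Parameters
    ----------
    n_samples, n_features : int
        Shape of the data matrix.
    class_proportions : (float, float)
        Proportions ``(p0, p1)`` of the two target classes; must sum to 1.
    max_vars : int
        Maximum number of features the selection may pick; drives the
        worst-case degrees of freedom ``df = max_vars + 1``.
    epv_constant : float
        The constant ``c`` of the sizing rules (default 10; a warning is
        issued below 10).
    workers : int
        Number of concurrent block processors available.
    rule : {"STD", "EPV"}
        Which sizing rule to apply.
    df_override : int or None
        Explicit worst-case parameter count, e.g. when categorical features
        expand into dummies and enlarge the model beyond ``max_vars + 1``.
    """

    n_samples: int
    n_features: int
    class_proportions: tuple[float, float] = (0.5, 0.5)
    max_vars: int = 50
    epv_constant: float = 10.0
    workers: int = 1
    rule: str = "STD"
    df_override: int | None = None

    def __post_init__(self) -> None:
        p0, p1 = self.class_proportions
        if not (0.0 < p0 < 1.0 and 0.0 < p1 < 1.0):
            raise SizingError(
                f"degenerate class proportions ({p0}, {p1}); both classes must be present"
            )
        if abs(p0 + p1 - 1.0) > 1e-12:
            raise ValueError(f"class proportions must sum to 1, got {p0 + p1}")
        if self.max_vars < 0:
            raise ValueError("max_vars must be >= 0")
        if self.rule not in ("STD", "EPV"):
            raise ValueError(f"unknown sizing rule {self.rule!r}")
        if self.epv_constant < 10:
            warnings.warn(
                f"epv_constant={self.epv_constant} < 10 may produce unreliable local p-values",
                stacklevel=2,
            )

    @property
    def df(self) -> int:
        """Worst-case parameter count of a local model (intercept included)."""
        if self.df_override is not None:
            return self.df_override
        return self.max_vars + 1


def block_sample_size(inputs: SizingInputs) -> int:
    """Minimum rows per Sample Subset under the chosen sizing rule, rounded up."""
    p0, p1 = inputs.class_proportions
    c, df = inputs.epv_constant, inputs.df
    if inputs.rule == "STD":
        s = df * c / math.sqrt(p0 * p1)
    else:  # EPV
        s = c / min(p0, p1) * df
    return int(math.ceil(s - 1e-9))


def assign_rows(n: int, ns: int, seed) -> np.ndarray:
    """Random partition of ``n`` row indices into ``ns`` subsets of near-equal size.

    Returns an integer array ``a`` of length ``n`` with ``a[i]`` the subset
    index of row ``i``.  Subset sizes differ by at most one (the first
    ``n % ns`` subsets receive the extra row), and the assignment is a
    uniformly random set partition reproducible from ``seed``.
    """
    if ns < 1:
        raise ValueError("ns must be >= 1")
    if ns > n:
        raise ValueError(f"cannot split {n} rows into {ns} subsets")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    sizes = np.full(ns, n // ns, dtype=int)
    sizes[: n % ns] += 1
    assignment = np.empty(n, dtype=np.int64)
    start = 0
    for k, size in enumerate(sizes):
        assignment[perm[start : start + size]] = k
        start += size
    return assignment


@dataclass(frozen=True)
class PartitionPlan:
    """Concrete two-level partition of a data matrix.

    ``row_assignment[i]`` gives the Sample Subset of row ``i`` and
    ``feature_assignment[j]`` the Feature Subset of column ``j``.  Sample
    Subsets ``k`` belong to Group ``k // C`` (the final Group may be short).
    """

    s: int
    ns: int
    nf: int
    C: int
    Q: int
    row_assignment: np.ndarray
    feature_assignment: np.ndarray
    seed: int
    single_subset_fallback: bool = False
    small_group_warning: bool = False

    def group_of_subset(self, subset_index: int) -> int:
        return subset_index // self.C

    def subsets_in_group(self, q: int) -> list[int]:
        return list(range(q * self.C, min((q + 1) * self.C, self.ns)))

    def rows_of_subset(self, subset_index: int) -> np.ndarray:
        return np.flatnonzero(self.row_assignment == subset_index)

    def features_of_subset(self, feature_set_index: int) -> np.ndarray:
        return np.flatnonzero(self.feature_assignment == feature_set_index)

    def to_json(self) -> str:
        """Serialize the plan geometry (not the per-row maps) for reporting."""
        return json.dumps(
            {
                "s": self.s,
                "ns": self.ns,
                "nf": self.nf,
                "C": self.C,
                "Q": self.Q,
                "seed": self.seed,
                "single_subset_fallback": self.single_subset_fallback,
                "small_group_warning": self.small_group_warning,
            },
            indent=2,
        )


def plan_partition(
    inputs: SizingInputs,
    seed: int,
    configured_C: int = DEFAULT_C,
    nf_override: int | None = None,
) -> PartitionPlan:
    """Build a :class:`PartitionPlan` from sizing inputs.

    ``ns = floor(n / s)`` subsets of at least ``s`` rows each (remainder rows
    are spread one per subset), grouped ``C = min(configured_C, ns)`` per
    Group into ``Q = ceil(ns / C)`` Groups.  The number of Feature Subsets is
    ``nf = max(1, floor(workers / configured_C))`` unless overridden (a user
    may raise ``nf`` when a block would not fit in memory).

    If fewer than ``2 s`` rows are available a warning is issued; with fewer
    than ``s`` rows a single-subset fallback plan is returned with
    ``single_subset_fallback`` set.
    """
    n = inputs.n_samples
    s = block_sample_size(inputs)
    fallback = False
    if n < s:
        warnings.warn(
            f"only {n} rows available but the {inputs.rule} rule asks for {s}; "
            "falling back to a single Sample Subset (local p-values may be unreliable)",
            stacklevel=2,
        )
        ns = 1
        fallback = True
    else:
        if n < 2 * s:
            warnings.warn(
                f"{n} rows barely cover one block of {s}; at least {2 * s} recommended",
                stacklevel=2,
            )
        ns = n // s
    C = min(configured_C, ns)
    small_group = C < MIN_RECOMMENDED_C
    Q = math.ceil(ns / C)
    if nf_override is not None:
        nf = max(1, int(nf_override))
    else:
        nf = max(1, inputs.workers // configured_C)
    row_assignment = assign_rows(n, ns, seed)
    m = inputs.n_features
    # Features go to feature sets in order of occurrence, near-equal sizes.
    fs_sizes = np.full(nf, m // nf, dtype=int)
    fs_sizes[: m % nf] += 1
    feature_assignment = np.repeat(np.arange(nf), fs_sizes)
    return PartitionPlan(
        s=s,
        ns=ns,
        nf=nf,
        C=C,
        Q=Q,
        row_assignment=row_assignment,
        feature_assignment=feature_assignment,
        seed=int(seed),
        single_subset_fallback=fallback,
        small_group_warning=small_group,
    )
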