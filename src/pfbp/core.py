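"""The parallel forward-backward selection loop.

The algorithm runs up to ``max_runs`` *Runs*; each Run executes a forward
*Phase* (add one feature per *Iteration* while some feature is conditionally
dependent on the target given the current selection and the cap ``max_vars``
is not reached) and a backward Phase (remove, one per Iteration, features
that became redundant).  Within a forward Iteration the Sample-Subset Groups
are processed sequentially; each Group contributes one row of local log
p-values (``Pi``) and log-likelihoods (``Lambda``) per Sample Subset, after
which the bootstrap heuristics may Drop features from the Run, Stop features
for the Iteration, or Return the current best immediately.  Early-Dropped
features re-enter in the next Run, whose remaining set is re-initialized to
all non-selected features; this is what recovers spouse variables that look
marginally independent of the target.

The statistical engine is pluggable: any object with a ``process_block``
method mapping a block of rows to local log p-values and log-likelihoods can
replace the default logistic-regression tests -- the graph d-separation
oracle uses exactly this hook.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .cit import (
    DegenerateFitError,
    chi2_log_sf,
    fit_logistic,
    _fit_logistic_many,
    score_test_log_pvalues_many,
)
from .earlydecisions import (
    HeuristicConfig,
    PiLambdaStore,
    bootstrap_indices,
    early_dropping,
    early_return,
    early_stopping,
)
from .meta import statistic_threshold
from .models import CombinedModel, accuracy_trace, combine_local_models, predict_and_score
from .partition import PartitionPlan, SizingInputs, plan_partition

__all__ = [
    "LogisticBlockTest",
    "SelectionState",
    "RunConfig",
    "SelectionResult",
    "process_block",
    "run_pfbp",
    "PFBP",
    "PFBPResults",
]


class LogisticBlockTest:
    """Default pluggable test: local logistic LRT / univariate score test.

    On a block it fits the null model (intercept + selected features) once
    and reuses it for every candidate; candidates are tested by the
    likelihood-ratio statistic ``D = -2 (LL0 - LL1) ~ chi2(1)``.  When the
    conditioning set is empty the vectorized univariate score test replaces
    the LRT (no model fitting at all); its log-likelihood surrogate uses
    the asymptotic identity ``LL1 ~ LL0 + z^2 / 2`` so Early Return remains
    available in the first Iteration.  A block whose target is single-class
    is skipped (returns None) -- random row assignment makes this rare and
    unbiased.
    """

    def process_block(self, y, s_values, cand_values, s_labels, cand_labels):
        y = np.asarray(y, dtype=float).ravel()
        mean = y.mean()
        if mean <= 0.0 or mean >= 1.0:
            return None
        cand = np.asarray(cand_values, dtype=float)
        if cand.ndim == 1:
            cand = cand[:, None]
        n = y.size
        if s_values is None or np.size(s_values) == 0:
            logp, z = score_test_log_pvalues_many(y, cand)
            ll0 = n * (mean * math.log(mean) + (1 - mean) * math.log(1 - mean))
            lam = ll0 + z**2 / 2.0
            null_coefs = np.array([math.log(mean / (1.0 - mean))])
            return logp, lam, null_coefs
        S = np.asarray(s_values, dtype=float)
        if S.ndim == 1:
            S = S[:, None]
        base = np.column_stack([np.ones(n), S])
        null = fit_logistic(base, y)
        coefs, ll, _conv = _fit_logistic_many(
            base, cand, y, init=null.coefficients
        )
        D = np.maximum(-2.0 * (null.log_likelihood - ll), 0.0)
        logp = chi2_log_sf(D, 1)
        return np.atleast_1d(logp), ll, null.coefficients


def process_block(y, s_values, cand_values, s_labels=(), cand_labels=(), test=None):
    """Local tests for one data block: one (log p, log-likelihood) pair per candidate.

    Pure function of its inputs; returns ``(log_p_row, log_lik_row,
    null_coefficients)`` or ``None`` when the block's target is
    single-class and the block must be skipped.
    """
    t = test if test is not None else LogisticBlockTest()
    return t.process_block(y, s_values, cand_values, tuple(s_labels), tuple(cand_labels))


@dataclass
class SelectionState:
    """Selected / Remaining / Alive bookkeeping (column indices)."""

    selected: list[int] = field(default_factory=list)
    remaining: set[int] = field(default_factory=set)
    alive: list[int] = field(default_factory=list)
    run_index: int = 0
    phase: str = "forward"
    iteration_index: int = 0


@dataclass
class RunConfig:
    """Configuration of a selection run."""

    max_vars: int
    partition: PartitionPlan
    heuristics: HeuristicConfig = field(default_factory=HeuristicConfig)
    max_runs: int = 2
    skip_backward_if_limit_reached: bool = True
    workers: int = 1
    deterministic_drop: bool = True
    compact_after_first_run: bool = False

    def __post_init__(self) -> None:
        if self.max_runs < 1:
            raise ValueError("max_runs must be >= 1")


@dataclass
class SelectionResult:
    """Outcome of a full selection: features, models, and the decision trace."""

    selected: list[tuple[str, float]]
    per_iteration_models: list[CombinedModel]
    final_model: CombinedModel | None
    trace: pd.DataFrame
    n_local_tests: int
    n_runs: int

    @property
    def selected_labels(self) -> list[str]:
        return [s for s, _ in self.selected]


class _Engine:
    """Single-process execution engine over an in-memory data matrix."""

    def __init__(self, X, y, labels, config: RunConfig, seed: int, test=None):
        self.X = np.asarray(X)
        self.y = np.asarray(y, dtype=float).ravel()
        self.labels = list(labels)
        self.config = config
        self.seed = int(seed)
        self.test = test if test is not None else LogisticBlockTest()
        plan = config.partition
        self.plan = plan
        self.subset_rows = [plan.rows_of_subset(k) for k in range(plan.ns)]
        self.fs_cols = [plan.features_of_subset(j) for j in range(plan.nf)]
        self.trace_rows: list[dict] = []
        self.n_local_tests = 0
        self.per_iteration_models: list[CombinedModel] = []
        self.selection_logp: dict[int, float] = {}
        self.active_columns: set[int] | None = None  # compaction
        self._parallel = (
            Parallel(n_jobs=config.workers, prefer="threads")
            if config.workers > 1
            else None
        )

    # -- helpers -----------------------------------------------------------
    def _col(self, j: int) -> np.ndarray:
        col = self.X[:, j]
        return np.asarray(col.todense()).ravel() if hasattr(col, "todense") else col

    def _matrix(self, rows: np.ndarray, cols) -> np.ndarray:
        sub = self.X[np.ix_(rows, np.asarray(cols, dtype=int))]
        return np.asarray(sub.todense()) if hasattr(sub, "todense") else np.asarray(sub, dtype=float)

    def _alive_by_fs(self, alive: list[int]) -> list[tuple[np.ndarray, np.ndarray]]:
        """Split alive columns by Feature Subset, preserving alive order."""
        out = []
        alive_arr = np.asarray(alive)
        for cols in self.fs_cols:
            pos = np.flatnonzero(np.isin(alive_arr, cols))
            if pos.size:
                out.append((pos, alive_arr[pos]))
        return out

    def _process_subset(self, i: int, selected: list[int], alive: list[int]):
        rows = self.subset_rows[i]
        yb = self.y[rows]
        Sb = self._matrix(rows, selected) if selected else None
        s_labels = tuple(self.labels[j] for j in selected)
        m = len(alive)
        logp_row = np.empty(m)
        lam_row = np.empty(m)
        null_coefs = None
        for pos, cols in self._alive_by_fs(alive):
            res = self.test.process_block(
                yb,
                Sb,
                self._matrix(rows, cols),
                s_labels,
                tuple(self.labels[j] for j in cols),
            )
            if res is None:
                return None
            lp, lam, nc = res
            logp_row[pos] = lp
            lam_row[pos] = lam
            null_coefs = nc if null_coefs is None else null_coefs
        return logp_row, lam_row, null_coefs

    def _process_group(self, subset_ids, selected, alive):
        if self._parallel is not None:
            results = self._parallel(
                delayed(self._process_subset)(i, selected, alive) for i in subset_ids
            )
        else:
            results = [self._process_subset(i, selected, alive) for i in subset_ids]
        kept = [r for r in results if r is not None]
        self.n_local_tests += len(kept) * len(alive)
        return kept, len(results) - len(kept)

    def _round_seed(self, run, phase_code, iteration, round_idx):
        ss = np.random.SeedSequence(
            [self.seed, run, phase_code, iteration, round_idx]
        )
        return ss

    def _trace(self, **kw):
        kw.setdefault("n_local_tests", self.n_local_tests)
        self.trace_rows.append(kw)

    def _heuristics_enabled(self) -> bool:
        h = self.config.heuristics
        return min(h.P_drop, h.P_stop, h.P_return) <= 1.0

    # -- iterations --------------------------------------------------------
    def forward_iteration(self, state: SelectionState):
        cfg = self.config
        plan = self.plan
        h = cfg.heuristics
        alive = sorted(state.remaining)
        state.alive = list(alive)
        store = PiLambdaStore.empty(alive)
        cursor = 0
        round_idx = 0
        current_C = plan.C
        er_fired = False
        last_group_nulls = None
        while cursor < plan.ns and store.n_alive > 0:
            subset_ids = list(range(cursor, min(cursor + current_C, plan.ns)))
            kept, skipped = self._process_group(
                subset_ids, state.selected, store.column_labels
            )
            if kept:
                store.append_rows(
                    np.vstack([r[0] for r in kept]), np.vstack([r[1] for r in kept])
                )
                last_group_nulls = [r[2] for r in kept]
            cursor += len(subset_ids)
            round_idx += 1
            done_all = cursor >= plan.ns
            n_drop = n_stop = 0
            if (
                not done_all
                and store.K >= 1
                and store.n_alive >= 1
                and self._heuristics_enabled()
            ):
                idx = bootstrap_indices(
                    store.K, h.B, self._round_seed(state.run_index, 0, state.iteration_index, round_idx)
                )
                drop_mask = early_dropping(store, h, idx)
                stop_mask = early_stopping(store, h, idx, reverse=False)
                dropped_cols = [
                    c for c, d in zip(store.column_labels, drop_mask) if d
                ]
                n_drop = len(dropped_cols)
                state.remaining.difference_update(dropped_cols)
                keep = ~(drop_mask | stop_mask)
                n_stop = int(stop_mask.sum())
                store.keep_columns(keep)
                if store.n_alive >= 1:
                    er_fired = early_return(store, h, idx)
            self._trace(
                run=state.run_index,
                phase="forward",
                iteration=state.iteration_index,
                group_round=round_idx,
                subsets_processed=cursor,
                subsets_skipped=skipped,
                n_remaining=len(state.remaining),
                n_alive=store.n_alive,
                n_dropped=n_drop,
                n_stopped=n_stop,
                early_return=er_fired,
                event="",
                feature="",
            )
            if er_fired or store.n_alive <= 1:
                break
            if self._heuristics_enabled():
                progress = n_drop > 0 or n_stop > 0
                current_C = plan.C if progress else current_C * 2
        # cache the combined model over the current selection (pre-selection S)
        if last_group_nulls:
            self.per_iteration_models.append(
                combine_local_models(
                    last_group_nulls,
                    [self.labels[j] for j in state.selected],
                )
            )
        if store.n_alive == 0 or store.K == 0:
            return None
        stats = store.combined_statistics()
        K = store.K
        best_pos = int(np.argmax(stats))
        best_col = store.column_labels[best_pos]
        log_p = chi2_log_sf(stats[best_pos], 2 * K)
        completed = cursor >= self.plan.ns and not er_fired
        selected_now = log_p <= math.log(h.alpha)
        if cfg.deterministic_drop and completed:
            thr = statistic_threshold(h.alpha, K)
            for c, s in zip(store.column_labels, stats):
                if s <= thr:
                    state.remaining.discard(c)
        if not selected_now:
            return None
        state.selected.append(best_col)
        state.remaining.discard(best_col)
        self.selection_logp[best_col] = float(log_p)
        self._trace(
            run=state.run_index,
            phase="forward",
            iteration=state.iteration_index,
            group_round=round_idx,
            subsets_processed=cursor,
            subsets_skipped=0,
            n_remaining=len(state.remaining),
            n_alive=store.n_alive,
            n_dropped=0,
            n_stopped=0,
            early_return=er_fired,
            event="select",
            feature=self.labels[best_col],
            log_p=float(log_p),
        )
        return best_col

    def _backward_subset(self, i: int, selected: list[int], alive: list[int]):
        """One Pi/Lambda row for a backward Iteration: test T vs X given S \\ {X}."""
        rows = self.subset_rows[i]
        yb = self.y[rows]
        logp_row = np.empty(len(alive))
        lam_row = np.empty(len(alive))
        for a_idx, c in enumerate(alive):
            others = [s for s in selected if s != c]
            res = self.test.process_block(
                yb,
                self._matrix(rows, others) if others else None,
                self._matrix(rows, [c]),
                tuple(self.labels[j] for j in others),
                (self.labels[c],),
            )
            if res is None:
                return None
            lp, lam, _nc = res
            logp_row[a_idx] = np.atleast_1d(lp)[0]
            lam_row[a_idx] = np.atleast_1d(lam)[0]
        return logp_row, lam_row, None

    def backward_iteration(self, state: SelectionState):
        cfg = self.config
        plan = self.plan
        h = cfg.heuristics
        if not state.selected:
            return None
        alive = sorted(state.selected)
        state.alive = list(alive)
        store = PiLambdaStore.empty(alive)
        cursor = 0
        round_idx = 0
        current_C = plan.C
        while cursor < plan.ns and store.n_alive > 0:
            subset_ids = list(range(cursor, min(cursor + current_C, plan.ns)))
            if self._parallel is not None:
                results = self._parallel(
                    delayed(self._backward_subset)(i, state.selected, store.column_labels)
                    for i in subset_ids
                )
            else:
                results = [
                    self._backward_subset(i, state.selected, store.column_labels)
                    for i in subset_ids
                ]
            kept = [r for r in results if r is not None]
            self.n_local_tests += len(kept) * store.n_alive
            if kept:
                store.append_rows(
                    np.vstack([r[0] for r in kept]), np.vstack([r[1] for r in kept])
                )
            cursor += len(subset_ids)
            round_idx += 1
            done_all = cursor >= plan.ns
            n_stop = 0
            if (
                not done_all
                and store.K >= 1
                and store.n_alive >= 2
                and self._heuristics_enabled()
            ):
                idx = bootstrap_indices(
                    store.K, h.B, self._round_seed(state.run_index, 1, state.iteration_index, round_idx)
                )
                stop_mask = early_stopping(store, h, idx, reverse=True)
                n_stop = int(stop_mask.sum())
                store.keep_columns(~stop_mask)
            self._trace(
                run=state.run_index,
                phase="backward",
                iteration=state.iteration_index,
                group_round=round_idx,
                subsets_processed=cursor,
                subsets_skipped=len(subset_ids) - len(kept),
                n_remaining=len(state.remaining),
                n_alive=store.n_alive,
                n_dropped=0,
                n_stopped=n_stop,
                early_return=False,
                event="",
                feature="",
            )
            if store.n_alive <= 1 and done_all:
                break
            if self._heuristics_enabled():
                current_C = plan.C if n_stop > 0 else current_C * 2
        if store.K == 0 or store.n_alive == 0:
            return None
        stats = store.combined_statistics()
        worst_pos = int(np.argmin(stats))
        worst_col = store.column_labels[worst_pos]
        log_p = chi2_log_sf(stats[worst_pos], 2 * store.K)
        if log_p <= math.log(h.alpha):
            return None  # even the worst is dependent; phase ends
        state.selected.remove(worst_col)
        self.selection_logp.pop(worst_col, None)
        self._trace(
            run=state.run_index,
            phase="backward",
            iteration=state.iteration_index,
            group_round=round_idx,
            subsets_processed=cursor,
            subsets_skipped=0,
            n_remaining=len(state.remaining),
            n_alive=store.n_alive,
            n_dropped=0,
            n_stopped=0,
            early_return=False,
            event="remove",
            feature=self.labels[worst_col],
            log_p=float(log_p),
        )
        return worst_col

    # -- runs --------------------------------------------------------------
    def one_run(self, state: SelectionState):
        cfg = self.config
        all_cols = (
            set(range(len(self.labels)))
            if self.active_columns is None
            else set(self.active_columns)
        )
        state.remaining = all_cols - set(state.selected)
        state.phase = "forward"
        state.iteration_index = 0
        while state.remaining and len(state.selected) < cfg.max_vars:
            sel = self.forward_iteration(state)
            state.iteration_index += 1
            if sel is None:
                break
        hit_limit = len(state.selected) >= cfg.max_vars
        if not (cfg.skip_backward_if_limit_reached and hit_limit):
            state.phase = "backward"
            state.iteration_index = 0
            while state.selected:
                rem = self.backward_iteration(state)
                state.iteration_index += 1
                if rem is None:
                    break
        return state

    def run(self) -> SelectionResult:
        cfg = self.config
        state = SelectionState()
        n_runs = 0
        for run_idx in range(cfg.max_runs):
            state.run_index = run_idx
            before = list(state.selected)
            self.one_run(state)
            n_runs += 1
            if cfg.compact_after_first_run and run_idx == 0:
                self.active_columns = set(state.remaining) | set(state.selected)
            if state.selected == before:
                break
        final_model = self._fit_final_model(state.selected)
        trace = pd.DataFrame(self.trace_rows)
        selected = [
            (self.labels[c], self.selection_logp.get(c, float("nan")))
            for c in state.selected
        ]
        return SelectionResult(
            selected=selected,
            per_iteration_models=self.per_iteration_models,
            final_model=final_model,
            trace=trace,
            n_local_tests=self.n_local_tests,
            n_runs=n_runs,
        )

    def _fit_final_model(self, selected: list[int]) -> CombinedModel | None:
        if not isinstance(self.test, LogisticBlockTest):
            return None
        coefs = []
        for i in range(self.plan.ns):
            rows = self.subset_rows[i]
            yb = self.y[rows]
            if np.unique(yb).size < 2:
                continue
            design = np.column_stack(
                [np.ones(rows.size), self._matrix(rows, selected)]
            )
            try:
                coefs.append(fit_logistic(design, yb).coefficients)
            except DegenerateFitError:
                continue
        if not coefs:
            return None
        return combine_local_models(coefs, [self.labels[j] for j in selected])


def run_pfbp(X, y, config: RunConfig, seed: int, feature_labels=None, test=None) -> SelectionResult:
    """Run the full multi-Run selection on an in-memory dataset.

    ``X`` is ``(n, m)`` (dense or scipy-sparse; blocks are densified on
    demand), ``y`` a 0/1 vector.  All randomness (row partition aside,
    which lives in ``config.partition``) derives from ``seed``; results are
    identical for any worker count.
    """
    labels = (
        list(feature_labels)
        if feature_labels is not None
        else [f"X{j + 1}" for j in range(X.shape[1])]
    )
    engine = _Engine(X, y, labels, config, seed, test=test)
    return engine.run()


# ---------------------------------------------------------------------------
# model-style interface
# ---------------------------------------------------------------------------

class PFBP:
    """Forward-backward Markov-blanket feature selection for a binary target.

    Parameters
    ----------
    X : array-like or sparse, shape (n, m)
    y : array-like of 0/1, shape (n,)
    feature_names : sequence of str, optional
    max_vars : int
        Cap on the number of selected features (default 50).
    alpha : float
        Significance level of the conditional-independence decisions
        (default 0.01).
    max_runs : int
        Forward-backward Runs (default 2; two suffice for exact
        Markov-blanket recovery in faithful DAG distributions).
    rule : {"STD", "EPV"}
        Block sizing rule (default STD).
    heuristics : HeuristicConfig, optional
        Bootstrap thresholds; pass ``HeuristicConfig.disabled()`` to turn
        the three pruning heuristics off.
    workers : int
        Concurrent block processors (default 1); also feeds the
        feature-subset count of the partition plan.
    plan : PartitionPlan, optional
        Explicit partition, overriding the sizing rules.

    Examples
    --------
    >>> sel = PFBP(X, y, max_vars=10).fit(seed=0)
    >>> sel.selected_features
    ['X3', 'X17', ...]
    """

    def __init__(
        self,
        X,
        y,
        feature_names=None,
        max_vars: int = 50,
        alpha: float = 0.01,
        max_runs: int = 2,
        rule: str = "STD",
        epv_constant: float = 10.0,
        heuristics: HeuristicConfig | None = None,
        workers: int = 1,
        C: int = 30,
        plan: PartitionPlan | None = None,
        skip_backward_if_limit_reached: bool = True,
        deterministic_drop: bool = True,
        test=None,
    ):
        self.X = X
        self.y = np.asarray(y, dtype=float).ravel()
        classes = np.unique(self.y)
        if not np.all(np.isin(classes, [0.0, 1.0])):
            raise ValueError("target must be 0/1 coded")
        self.feature_names = (
            list(feature_names)
            if feature_names is not None
            else [f"X{j + 1}" for j in range(X.shape[1])]
        )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        self.max_vars = max_vars
        self.alpha = alpha
        self.max_runs = max_runs
        self.rule = rule
        self.epv_constant = epv_constant
        self.heuristics = (
            heuristics if heuristics is not None else HeuristicConfig(alpha=alpha)
        )
        if heuristics is not None and heuristics.alpha != alpha and alpha != 0.01:
            raise ValueError("pass alpha through either `alpha` or `heuristics`, not both")
        self.workers = workers
        self.C = C
        self.plan = plan
        self.skip_backward_if_limit_reached = skip_backward_if_limit_reached
        self.deterministic_drop = deterministic_drop
        self.test = test

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, target: str, **kwargs) -> "PFBP":
        if target not in df.columns:
            raise KeyError(f"target column {target!r} not in dataframe")
        y = df[target].to_numpy()
        feats = [c for c in df.columns if c != target]
        return cls(df[feats].to_numpy(dtype=float), y, feature_names=feats, **kwargs)

    def _build_plan(self, seed: int) -> PartitionPlan:
        if self.plan is not None:
            return self.plan
        n, m = self.X.shape
        p1 = float(self.y.mean())
        inputs = SizingInputs(
            n_samples=n,
            n_features=m,
            class_proportions=(1.0 - p1, p1),
            max_vars=self.max_vars,
            epv_constant=self.epv_constant,
            workers=self.workers,
            rule=self.rule,
        )
        return plan_partition(inputs, seed, configured_C=self.C)

    def fit(self, seed: int = 0, workers: int | None = None) -> "PFBPResults":
        """Run the selection; all randomness derives from ``seed``."""
        plan = self._build_plan(seed)
        config = RunConfig(
            max_vars=self.max_vars,
            partition=plan,
            heuristics=self.heuristics,
            max_runs=self.max_runs,
            skip_backward_if_limit_reached=self.skip_backward_if_limit_reached,
            workers=workers if workers is not None else self.workers,
            deterministic_drop=self.deterministic_drop,
        )
        result = run_pfbp(
            self.X, self.y, config, seed, feature_labels=self.feature_names, test=self.test
        )
        return PFBPResults(self, config, result, seed)


class PFBPResults:
    """Fitted selection: chosen features, combined models, diagnostics."""

    def __init__(self, model: PFBP, config: RunConfig, result: SelectionResult, seed: int):
        self.model = model
        self.config = config
        self.result = result
        self.seed = seed

    @property
    def selected_features(self) -> list[str]:
        return self.result.selected_labels

    @property
    def combined_log_pvalues(self) -> dict[str, float]:
        return dict(self.result.selected)

    @property
    def final_model(self) -> CombinedModel | None:
        return self.result.final_model

    @property
    def trace(self) -> pd.DataFrame:
        return self.result.trace

    def predict_proba(self, X) -> np.ndarray:
        if self.final_model is None:
            raise ValueError("no combined model available (non-logistic test?)")
        X = np.asarray(X)
        index = {f: j for j, f in enumerate(self.model.feature_names)}
        cols = [index[f] for f in self.final_model.feature_labels]
        probs, _ = predict_and_score(self.final_model, X[:, cols])
        return probs

    def score(self, X, y) -> float:
        probs = self.predict_proba(X)
        y = np.asarray(y, dtype=float).ravel()
        return float(np.mean((probs >= 0.5) == (y == 1.0)))

    def accuracy_trace(self, holdout_X, holdout_y):
        """Holdout accuracy after each forward Iteration (k features vs accuracy)."""
        index = {f: j for j, f in enumerate(self.model.feature_names)}
        return accuracy_trace(
            self.result.per_iteration_models, holdout_X, holdout_y, index
        )

    def summary(self) -> str:
        lines = [
            "PFBP feature selection",
            "=" * 54,
            f"runs executed     : {self.result.n_runs}",
            f"local tests       : {self.result.n_local_tests}",
            f"features selected : {len(self.result.selected)}",
            "-" * 54,
            f"{'rank':>4}  {'feature':<20} {'combined log10 p':>18}",
        ]
        for rank, (name, logp) in enumerate(self.result.selected, 1):
            lines.append(f"{rank:>4}  {name:<20} {logp / math.log(10):>18.3f}")
        lines.append("=" * 54)
        return "\n".join(lines)

    def save_report(self, path) -> None:
        import json

        report = {
            "seed": self.seed,
            "alpha": self.config.heuristics.alpha,
            "max_vars": self.config.max_vars,
            "runs_executed": self.result.n_runs,
            "n_local_tests": self.result.n_local_tests,
            "selected": [
                {"feature": f, "combined_log_p": lp} for f, lp in self.result.selected
            ],
            "partition": {
                "s": self.config.partition.s,
                "ns": self.config.partition.ns,
                "nf": self.config.partition.nf,
                "C": self.config.partition.C,
                "Q": self.config.partition.Q,
            },
        }
        if self.final_model is not None:
            report["combined_model"] = {
                "feature_labels": self.final_model.feature_labels,
                "coefficients": [float(c) for c in self.final_model.coefficients],
            }
        with open(path, "w") as fh:
            json.dump(report, fh, indent=2)

    def save_trace(self, path) -> None:
        self.result.trace.to_csv(path, sep="\t", index=False)

    def plot_trace(self, ax=None):
        """Remaining/Alive feature counts per group round, log scale."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        t = self.result.trace
        fwd = t[(t["phase"] == "forward") & (t["event"] == "")]
        x = np.arange(len(fwd))
        ax.step(x, fwd["n_remaining"].to_numpy(), where="mid", label="Remaining")
        ax.step(x, fwd["n_alive"].to_numpy(), where="mid", label="Alive")
        ax.set_yscale("log")
        ax.set_xlabel("group round (forward iterations, concatenated)")
        ax.set_ylabel("features")
        ax.legend()
        return ax
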