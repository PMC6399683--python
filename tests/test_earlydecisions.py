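import math

import numpy as np
import pytest

from pfbp.earlydecisions import (
    HeuristicConfig,
    PiLambdaStore,
    bootstrap_indices,
    early_dropping,
    early_return,
    early_stopping,
    min_qualifying_count,
)
from reference import enumerate_two_row_probability


def make_store(pi_rows, lam_rows=None, labels=None):
    pi = np.asarray(pi_rows, dtype=float)
    lam = np.asarray(lam_rows, dtype=float) if lam_rows is not None else np.zeros_like(pi)
    labels = labels if labels is not None else list(range(pi.shape[1]))
    return PiLambdaStore(Pi=pi, Lambda=lam, column_labels=labels)


class TestBootstrapIndices:
    def test_single_row_always_resampled(self):
        idx = bootstrap_indices(1, 50, seed=0)
        assert np.all(idx == 0)

    def test_deterministic_from_seed(self):
        a = bootstrap_indices(7, 100, seed=42)
        b = bootstrap_indices(7, 100, seed=42)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, bootstrap_indices(7, 100, seed=43))

    def test_row_frequencies_multinomial(self):
        K, B = 4, 10_000
        idx = bootstrap_indices(K, B, seed=1)
        freqs = np.bincount(idx.ravel(), minlength=K) / idx.size
        se = math.sqrt(0.25 * 0.75 / idx.size)
        assert np.all(np.abs(freqs - 1.0 / K) < 4 * se)


class TestQualifyingCount:
    def test_worked_example_b999(self):
        # with B = 999 and a 0.99 bar, 990 of the 1000 samples must qualify
        assert min_qualifying_count(0.99, 999) == 990

    def test_reaches_is_inclusive(self):
        # 990/1000 = 0.99 exactly qualifies (ties count)
        assert min_qualifying_count(0.99, 999) / 1000 == 0.99

    def test_disabled_threshold_unreachable(self):
        assert min_qualifying_count(2.0, 999) > 1000


class TestEarlyDropping:
    def test_all_pvalues_one_always_dropped(self):
        store = make_store(np.zeros((3, 2)))
        cfg = HeuristicConfig(alpha=0.05, B=50)
        idx = bootstrap_indices(3, 50, seed=0)
        assert early_dropping(store, cfg, idx).all()

    def test_strong_feature_never_dropped(self):
        store = make_store(np.full((3, 1), -50.0))
        cfg = HeuristicConfig(alpha=0.05, B=50)
        idx = bootstrap_indices(3, 50, seed=0)
        assert not early_dropping(store, cfg, idx).any()

    def test_two_row_enumeration(self):
        # local p = {0.001, 0.9} at alpha=0.05: only the (0.9, 0.9) resample
        # combines to p >= alpha, so the exact probability is 1/4
        col = [math.log(0.001), math.log(0.9)]
        from pfbp.meta import statistic_threshold

        thr = statistic_threshold(0.05, 2)

        def indicator(rows):
            stat = -2 * sum(col[r] for r in rows)
            return stat <= thr

        assert enumerate_two_row_probability(indicator) == 0.25
        store = make_store(np.array(col)[:, None])
        B = 2000
        idx = bootstrap_indices(2, B, seed=3)
        # estimate must sit within 3 binomial SEs of 0.25: a 0.2 bar is
        # reached, a 0.35 bar is not (margins ~ 5 SE away)
        below = HeuristicConfig(alpha=0.05, B=B, P_drop=0.2)
        above = HeuristicConfig(alpha=0.05, B=B, P_drop=0.35)
        assert early_dropping(store, below, idx).all()
        assert not early_dropping(store, above, idx).any()
        assert not early_dropping(store, HeuristicConfig(alpha=0.05, B=B), idx).any()


class TestEarlyStopping:
    def test_single_alive_vacuous(self):
        store = make_store(np.full((3, 1), -5.0))
        cfg = HeuristicConfig(B=50)
        idx = bootstrap_indices(3, 50, seed=0)
        assert not early_stopping(store, cfg, idx).any()

    def test_dominated_feature_stopped_best_kept(self):
        pi = np.column_stack([np.full(3, -30.0), np.full(3, -0.5)])
        store = make_store(pi)
        cfg = HeuristicConfig(B=100)
        idx = bootstrap_indices(3, 100, seed=0)
        mask = early_stopping(store, cfg, idx)
        assert mask.tolist() == [False, True]

    def test_reverse_mode_stops_strong_features(self):
        # backward: the candidate for removal is the *largest* p; a clearly
        # dependent feature is unlikely to be the worst and leaves A
        pi = np.column_stack([np.full(3, -30.0), np.full(3, -0.5)])
        store = make_store(pi)
        cfg = HeuristicConfig(B=100)
        idx = bootstrap_indices(3, 100, seed=0)
        mask = early_stopping(store, cfg, idx, reverse=True)
        assert mask.tolist() == [True, False]

    def test_two_row_enumeration(self):
        # feature 0 beats feature 1 in row 0 only; best-beats-j holds for
        # resamples containing row 0 at least... enumerate exactly
        pi = np.array([[math.log(1e-6), math.log(0.5)], [math.log(0.4), math.log(0.3)]])
        store = make_store(pi)
        stats = lambda rows, j: -2 * sum(pi[r, j] for r in rows)
        best = 0  # feature 0 has the larger total statistic

        def indicator(rows):
            return stats(rows, 1) < stats(rows, best)

        exact = enumerate_two_row_probability(indicator)
        assert exact == 0.75  # all resamples except (1, 1)
        B = 2000
        idx = bootstrap_indices(2, B, seed=5)
        below = HeuristicConfig(B=B, P_stop=0.65)
        above = HeuristicConfig(B=B, P_stop=0.85)
        assert early_stopping(store, below, idx).tolist() == [False, True]
        assert not early_stopping(store, above, idx).any()


class TestEarlyReturn:
    def test_identical_likelihood_columns_return(self):
        pi = np.column_stack([np.full(2, -3.0), np.full(2, -1.0)])
        lam = np.full((2, 2), -100.0)
        store = make_store(pi, lam)
        cfg = HeuristicConfig(B=100)
        idx = bootstrap_indices(2, 100, seed=0)
        assert early_return(store, cfg, idx)

    def test_dominating_competitor_blocks_return(self):
        pi = np.column_stack([np.full(2, -3.0), np.full(2, -1.0)])
        lam = np.column_stack([np.full(2, -100.0), np.full(2, -50.0)])
        store = make_store(pi, lam)  # competitor's likelihood far better
        cfg = HeuristicConfig(B=100)
        idx = bootstrap_indices(2, 100, seed=0)
        assert not early_return(store, cfg, idx)

    def test_two_row_enumeration(self):
        lt = math.log(0.9)
        pi = np.column_stack([np.full(2, -9.0), np.full(2, -1.0)])
        lam = np.array([[-10.0, -10.02], [-10.0, -10.2]])
        store = make_store(pi, lam)

        def indicator(rows):
            diff = sum(lam[r, 0] for r in rows) - sum(lam[r, 1] for r in rows)
            return diff >= lt
        # row pairs: (0,0): diff 0.04 >= lt; (0,1)/(1,0): 0.22 >= lt;
        # (1,1): 0.4 >= lt -- all pass, lt is negative
        assert enumerate_two_row_probability(indicator) == 1.0
        cfg = HeuristicConfig(B=500)
        idx = bootstrap_indices(2, 500, seed=1)
        assert early_return(store, cfg, idx)


class TestSharedIndicesAndAbort:
    def test_same_seed_reproduces_decisions(self, rng):
        pi = np.log(rng.uniform(size=(6, 5)))
        lam = -rng.uniform(10, 20, size=(6, 5))
        store = make_store(pi, lam)
        cfg = HeuristicConfig(B=300)
        a = bootstrap_indices(6, 300, seed=9)
        b = bootstrap_indices(6, 300, seed=9)
        assert np.array_equal(early_dropping(store, cfg, a), early_dropping(store, cfg, b))
        assert np.array_equal(early_stopping(store, cfg, a), early_stopping(store, cfg, b))
        assert early_return(store, cfg, a) == early_return(store, cfg, b)

    def test_early_abort_is_decision_equivalent(self, rng):
        # the upper-bound abort must produce identical decisions to running
        # every resample, on randomly drawn stores
        for trial in range(300):
            K = int(rng.integers(1, 7))
            m = int(rng.integers(2, 6))
            pi = np.log(rng.uniform(size=(K, m)) ** rng.uniform(0.2, 6))
            lam = -rng.uniform(1, 30, size=(K, m))
            store_a = make_store(pi.copy(), lam.copy())
            store_b = make_store(pi.copy(), lam.copy())
            idx = bootstrap_indices(K, 200, seed=trial)
            fast = HeuristicConfig(B=200, early_abort=True)
            slow = HeuristicConfig(B=200, early_abort=False)
            assert np.array_equal(
                early_dropping(store_a, fast, idx), early_dropping(store_b, slow, idx)
            )
            assert np.array_equal(
                early_stopping(store_a, fast, idx), early_stopping(store_b, slow, idx)
            )
            assert early_return(store_a, fast, idx) == early_return(store_b, slow, idx)

    def test_disabled_thresholds_never_fire(self, rng):
        pi = np.log(rng.uniform(size=(5, 4)))
        store = make_store(pi)
        cfg = HeuristicConfig.disabled(B=100)
        idx = bootstrap_indices(5, 100, seed=0)
        assert not early_dropping(store, cfg, idx).any()
        assert not early_stopping(store, cfg, idx).any()
        assert not early_return(store, cfg, idx)


class TestStore:
    def test_columns_removed_atomically(self):
        store = make_store(np.zeros((2, 3)), np.zeros((2, 3)), labels=["a", "b", "c"])
        store.keep_columns(np.array([True, False, True]))
        assert store.column_labels == ["a", "c"]
        assert store.Pi.shape == store.Lambda.shape == (2, 2)

    def test_positive_log_p_rejected(self):
        store = make_store(np.zeros((1, 2)))
        with pytest.raises(ValueError):
            store.append_rows(np.array([[0.1, 0.0]]), np.zeros((1, 2)))
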