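import math

import networkx as nx
import numpy as np
import pytest
from scipy.stats import norm

from pfbp import PFBP
from pfbp.core import LogisticBlockTest, RunConfig, process_block
from pfbp.earlydecisions import HeuristicConfig
from pfbp.meta import fisher_combine
from pfbp.synthetic import (
    BNSimSpec,
    CausalGraph,
    markov_blanket,
    random_dag,
    simulate_bn,
)
from conftest import logistic_dataset, run_with_oracle


def four_node_graph():
    g = nx.DiGraph([("X1", "T"), ("T", "X2"), ("X3", "X2")])
    return CausalGraph(graph=g, target="T")


class TestProcessBlock:
    def test_univariate_score_path_example(self):
        y = np.array([0.0, 1.0, 0.0, 1.0])
        x = np.array([[1.0], [2.0], [3.0], [4.0]])
        lp, lam, nc = process_block(y, None, x)
        z = 1.0 / math.sqrt(0.25 * 5.0)
        assert lp[0] == pytest.approx(math.log(2 * norm.sf(z)), abs=1e-10)
        assert nc[0] == pytest.approx(0.0)  # balanced intercept

    def test_duplicate_of_selected_feature_gives_p_one(self, rng):
        X, y = logistic_dataset(rng, 400, np.array([1.2]))
        lp, lam, nc = process_block(y, X[:, :1], X[:, :1])
        assert lp[0] == pytest.approx(0.0, abs=1e-4)

    def test_pure_function_of_inputs(self, rng):
        X, y = logistic_dataset(rng, 200, np.array([0.5, -0.5]))
        a = process_block(y, X[:, :1], X[:, 1:])
        b = process_block(y, X[:, :1], X[:, 1:])
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_single_class_block_skipped(self):
        y = np.ones(30)
        assert process_block(y, None, np.random.default_rng(0).normal(size=(30, 2))) is None


class TestOracleSelection:
    def test_four_node_two_runs_recover_blanket(self):
        cg = four_node_graph()
        res = run_with_oracle(cg, ["X1", "X2", "X3"], max_runs=2)
        assert set(res.selected_labels) == {"X1", "X2", "X3"}

    def test_first_run_misses_spouse(self):
        cg = four_node_graph()
        res = run_with_oracle(cg, ["X1", "X2", "X3"], max_runs=1)
        assert set(res.selected_labels) == {"X1", "X2"}

    def test_max_vars_zero_returns_empty(self):
        cg = four_node_graph()
        res = run_with_oracle(cg, ["X1", "X2", "X3"], max_vars=0)
        assert res.selected_labels == []

    def test_blanket_recovery_on_random_dags(self):
        hits = 0
        for seed in range(30):
            cg = random_dag(
                BNSimSpec(n_vars=12 + seed % 9, n_samples=10, seed=200 + seed, avg_degree=3.5)
            )
            labels = sorted(
                (v for v in cg.graph.nodes if v != "T"), key=lambda s: int(s[1:])
            )
            res = run_with_oracle(cg, labels)
            hits += set(res.selected_labels) == markov_blanket(cg)
        assert hits == 30

    def test_latent_collider_path_recovered_with_unlimited_runs(self):
        # emulates T -> A <-> B (<-> via latent L): the observable blanket
        # is {A, B} although B looks marginally independent of T
        g = nx.DiGraph([("T", "A"), ("L", "A"), ("L", "B")])
        cg = CausalGraph(graph=g, target="T")
        res = run_with_oracle(cg, ["A", "B"], max_runs=10)
        assert set(res.selected_labels) == {"A", "B"}

    def test_exact_blanket_survives_backward(self):
        cg = four_node_graph()
        res = run_with_oracle(cg, ["X1", "X2", "X3"], max_runs=3)
        assert set(res.selected_labels) == {"X1", "X2", "X3"}
        assert not any(res.trace["event"] == "remove")


@pytest.fixture(scope="module")
def small_bn():
    return simulate_bn(BNSimSpec(n_vars=20, n_samples=8000, seed=21, avg_degree=4))


class TestDataSelection:
    def test_disabled_heuristics_keep_all_alive(self, small_bn):
        ds = small_bn
        model = PFBP(
            ds.X,
            ds.y,
            feature_names=ds.feature_labels,
            max_vars=8,
            heuristics=HeuristicConfig.disabled(),
            deterministic_drop=False,
        )
        res = model.fit(seed=0)
        t = res.trace
        fwd = t[(t.phase == "forward") & (t.event == "")]
        assert (fwd.n_dropped == 0).all() and (fwd.n_stopped == 0).all()
        # every forward iteration sees the full remaining set stay alive
        per_iter = fwd.groupby(["run", "iteration"]).n_alive.nunique()
        assert (per_iter == 1).all()

    def test_heuristics_never_increase_workload(self, small_bn):
        ds = small_bn
        kw = dict(feature_names=ds.feature_labels, max_vars=8)
        full = PFBP(
            ds.X, ds.y, heuristics=HeuristicConfig.disabled(),
            deterministic_drop=False, **kw
        ).fit(seed=0)
        pruned = PFBP(ds.X, ds.y, **kw).fit(seed=0)
        assert pruned.result.n_local_tests <= full.result.n_local_tests

    def test_worker_invariance(self, small_bn):
        ds = small_bn
        kw = dict(feature_names=ds.feature_labels, max_vars=8)
        a = PFBP(ds.X, ds.y, workers=1, **kw).fit(seed=3)
        b = PFBP(ds.X, ds.y, workers=1, **kw).fit(seed=3, workers=4)
        assert a.result.selected == b.result.selected
        assert a.result.n_local_tests == b.result.n_local_tests

    def test_redundant_clone_never_kept_with_original(self):
        kept_both = 0
        for seed in range(20):
            ds = simulate_bn(BNSimSpec(n_vars=15, n_samples=6000, seed=40 + seed, avg_degree=3))
            mb = sorted(ds.markov_blanket)
            clone_of = mb[0]
            j = ds.feature_labels.index(clone_of)
            X = np.column_stack([ds.X, ds.X[:, j]])  # exact duplicate column
            labels = ds.feature_labels + ["clone"]
            res = PFBP(
                X, ds.y, feature_names=labels, max_vars=10,
                skip_backward_if_limit_reached=False,
            ).fit(seed=seed)
            sel = set(res.selected_features)
            kept_both += clone_of in sel and "clone" in sel
        assert kept_both == 0

    def test_summary_and_reports(self, small_bn, tmp_path):
        ds = small_bn
        res = PFBP(ds.X, ds.y, feature_names=ds.feature_labels, max_vars=8).fit(seed=0)
        text = res.summary()
        assert "features selected" in text
        res.save_report(tmp_path / "r.json")
        res.save_trace(tmp_path / "t.tsv")
        import json

        doc = json.loads((tmp_path / "r.json").read_text())
        assert [d["feature"] for d in doc["selected"]] == res.selected_features

    def test_accuracy_trace_monotone_start(self, small_bn):
        ds = small_bn
        n = ds.X.shape[0]
        train, hold = slice(0, n - 2000), slice(n - 2000, n)
        res = PFBP(
            ds.X[train], ds.y[train], feature_names=ds.feature_labels, max_vars=8
        ).fit(seed=1)
        curve = res.accuracy_trace(ds.X[hold], ds.y[hold])
        assert len(curve) >= 2
        ks = [k for k, _ in curve]
        assert ks == sorted(ks)
        # selecting features must beat the trivial intercept-only model
        assert curve[-1][1] > curve[0][1]


class TestOptionalFeatures:
    def test_compaction_discards_only_dropped_columns(self, small_bn):
        ds = small_bn
        kw = dict(feature_names=ds.feature_labels, max_vars=8)
        plain = PFBP(ds.X, ds.y, **kw).fit(seed=5)
        from pfbp.core import _Engine

        model = PFBP(ds.X, ds.y, **kw)
        plan = model._build_plan(5)
        config = RunConfig(
            max_vars=8, partition=plan, heuristics=model.heuristics,
            compact_after_first_run=True,
        )
        eng = _Engine(ds.X, ds.y, ds.feature_labels, config, 5)
        res = eng.run()
        # compaction may narrow run 2's candidate pool but never drops
        # anything selected in run 1
        run1 = {f for f, _ in plain.result.selected}
        assert run1 & set(res.selected_labels)

    def test_trace_plot_renders(self, small_bn):
        import matplotlib

        matplotlib.use("Agg")
        ds = small_bn
        res = PFBP(ds.X, ds.y, feature_names=ds.feature_labels, max_vars=6).fit(seed=2)
        ax = res.plot_trace()
        assert ax.get_yscale() == "log"


class TestNullBehaviour:
    def test_false_selection_rate_controlled(self, rng):
        """On pure-noise data a forward pass selects anything at most at the
        family-wise alpha * m rate."""
        m, n, reps = 5, 5000, 100
        false_sel = 0
        for _ in range(reps):
            X = rng.normal(size=(n, m))
            y = (rng.random(n) < 0.5).astype(float)
            res = PFBP(X, y, max_vars=1, alpha=0.01).fit(seed=int(rng.integers(2**31)))
            false_sel += len(res.selected_features) > 0
        # alpha*m = 5%; allow 3 binomial SEs above
        assert false_sel / reps <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / reps)


def test_best_by_combined_p_matches_full_data_lrt(rng):
    """Block-combined p-values rank the winning candidate like a full-data
    likelihood-ratio test in almost all iterations."""
    from pfbp.cit import lrt_log_pvalue

    agree, total = 0, 0
    test = LogisticBlockTest()
    for rep in range(100):
        betas = np.zeros(8)
        i, j = rng.choice(8, size=2, replace=False)
        betas[i], betas[j] = 0.25, 0.1  # one clearly best candidate
        X, y = logistic_dataset(rng, 4096, betas)
        if y.mean() in (0, 1):
            continue
        rows = [np.arange(i, 4096, 8) for i in range(8)]  # 8 blocks of 512
        combined = []
        for j in range(8):
            lps = []
            for r in rows:
                res = test.process_block(y[r], None, X[r][:, [j]], (), (j,))
                if res is not None:
                    lps.append(res[0][0])
            combined.append(fisher_combine(np.array(lps)).log_pvalue)
        full = [lrt_log_pvalue(y, None, X[:, j]).log_pvalue for j in range(8)]
        agree += int(np.argmin(combined) == int(np.argmin(full)))
        total += 1
    assert agree / total >= 0.95
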