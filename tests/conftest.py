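import numpy as np
import pytest

from pfbp.earlydecisions import HeuristicConfig
from pfbp.core import RunConfig, run_pfbp
from pfbp.partition import PartitionPlan
from pfbp.synthetic import OracleCITest


def f1_score(selected, truth) -> float:
    selected, truth = set(selected), set(truth)
    if not selected and not truth:
        return 1.0
    tp = len(selected & truth)
    return 2 * tp / (len(selected) + len(truth)) if (selected or truth) else 1.0


def single_subset_plan(n_rows: int, n_features: int) -> PartitionPlan:
    """Degenerate one-block plan used with the d-separation oracle."""
    return PartitionPlan(
        s=n_rows,
        ns=1,
        nf=1,
        C=1,
        Q=1,
        row_assignment=np.zeros(n_rows, dtype=int),
        feature_assignment=np.zeros(n_features, dtype=int),
        seed=0,
    )


def run_with_oracle(cg, labels, max_runs=2, max_vars=None):
    """Selection driven purely by graph d-separation (no data involved)."""
    n = 4
    plan = single_subset_plan(n, len(labels))
    X = np.zeros((n, len(labels)))
    y = np.array([0.0, 1.0, 0.0, 1.0])
    config = RunConfig(
        max_vars=max_vars if max_vars is not None else len(labels),
        partition=plan,
        heuristics=HeuristicConfig.disabled(),
        max_runs=max_runs,
        skip_backward_if_limit_reached=False,
    )
    return run_pfbp(X, y, config, seed=0, feature_labels=labels, test=OracleCITest(cg))


def logistic_dataset(rng, n, betas, intercept=0.0):
    """Draw (X, y) from a plain logistic model with standard-normal features."""
    from scipy.special import expit

    betas = np.asarray(betas, dtype=float)
    X = rng.normal(size=(n, betas.size))
    probs = expit(intercept + X @ betas)
    y = (rng.random(n) < probs).astype(float)
    return X, y


@pytest.fixture
def rng():
    return np.random.default_rng(0)
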