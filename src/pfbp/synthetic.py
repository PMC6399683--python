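"""Ground-truthed synthetic data: random Bayesian networks, a d-separation
oracle, and a reduced-scale SNP genotype/phenotype simulator.

The Bayesian-network generator draws a random DAG with a prescribed average
degree, places the binary target mid-order so that it has parents, children
and (with high probability) spouses, and samples linear-Gaussian structural
equations for the features with a logistic-Bernoulli target whose intercept
is calibrated to the requested class balance.  Because the graph is known,
the exact Markov blanket of the target -- parents, children and spouses --
is returned with the data, and a d-separation oracle can stand in for the
statistical conditional-independence test to check the selection logic free
of estimation error.

The SNP simulator emulates a genome-wide association layout at desk scale:
genotypes in {0, 1, 2} with per-SNP minor-allele frequencies, local linkage
disequilibrium induced by block-equicorrelated latent Gaussians, and a
binary phenotype driven by a random subset of causal SNPs whose effect
scale is calibrated by Monte Carlo to a target Bayes-optimal accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.special import expit, ndtri

__all__ = [
    "CausalGraph",
    "BNSimSpec",
    "SNPSimSpec",
    "BNDataset",
    "SNPDataset",
    "random_dag",
    "sample_bn_dataset",
    "simulate_bn",
    "d_separated",
    "markov_blanket",
    "OracleCITest",
    "simulate_snp",
]

#: local log p-value the oracle emits for a d-connected pair; any value that
#: is decisively below log(alpha) works, the magnitude is not meaningful.
ORACLE_DEPENDENT_LOG_P = -1000.0


@dataclass(frozen=True)
class BNSimSpec:
    """Bayesian-network simulation settings.

    ``avg_degree`` is the expected total vertex degree (default 10),
    ``error_variance`` the variance of the Gaussian structural noise
    (default 1), and ``class_balance`` the marginal frequency of the
    positive target class (default 0.5).  Structural coefficients are drawn
    uniformly from ``+-[coefficient_range]``.
    """

    n_vars: int
    n_samples: int
    seed: int
    avg_degree: float = 10.0
    error_variance: float = 1.0
    class_balance: float = 0.5
    coefficient_range: tuple[float, float] = (0.5, 1.5)

    def __post_init__(self) -> None:
        if self.avg_degree >= self.n_vars:
            raise ValueError("avg_degree must be below n_vars")
        if self.error_variance <= 0:
            raise ValueError("error_variance must be positive")
        if not (0.0 < self.class_balance < 1.0):
            raise ValueError("class_balance must lie in (0, 1)")


@dataclass
class CausalGraph:
    """A DAG over named variables with a designated binary target ``T``."""

    graph: nx.DiGraph
    target: str = "T"

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("graph must be acyclic")
        if self.target not in self.graph:
            raise ValueError(f"target {self.target!r} not among vertices")

    @property
    def variables(self) -> list[str]:
        return [v for v in self.graph.nodes if v != self.target]

    def parents(self, v: str) -> set[str]:
        return set(self.graph.predecessors(v))

    def children(self, v: str) -> set[str]:
        return set(self.graph.successors(v))


def random_dag(spec: BNSimSpec) -> CausalGraph:
    """Random DAG with expected vertex degree ``avg_degree``.

    Vertices are arranged in a random topological order (the target is
    placed mid-order so that it acquires both parents and children); each
    ordered pair becomes an edge independently with probability
    ``avg_degree / (n_vars - 1)``, which makes the expected total degree of
    a vertex equal to ``avg_degree``.  Acyclicity holds by construction.
    """
    rng = np.random.default_rng(spec.seed)
    labels = [f"X{i}" for i in range(1, spec.n_vars)]
    order = list(rng.permutation(labels))
    order.insert(spec.n_vars // 2, "T")
    p = spec.avg_degree / (spec.n_vars - 1)
    g = nx.DiGraph()
    g.add_nodes_from(order)
    n = spec.n_vars
    mask = rng.random((n, n)) < p
    for i in range(n):
        for j in range(i + 1, n):
            if mask[i, j]:
                g.add_edge(order[i], order[j])
    return CausalGraph(graph=g, target="T")


def d_separated(cg: CausalGraph, x: str, y: str, z) -> bool:
    """Is ``x`` d-separated from ``y`` given the set ``z``?

    A path is blocked when some non-collider on it is in ``z`` or some
    collider on it has neither itself nor any descendant in ``z``;
    d-separation holds when every path is blocked.  Evaluated via
    networkx's d-separation routine.
    """
    z = set(z)
    for v in (x, y, *z):
        if v not in cg.graph:
            raise KeyError(f"unknown vertex {v!r}")
    if x == y or x in z or y in z:
        raise ValueError("x and y must be distinct and outside z")
    return nx.is_d_separator(cg.graph, {x}, {y}, z)


def markov_blanket(cg: CausalGraph, target: str | None = None) -> set[str]:
    """Parents, children and spouses (parents of children) of the target."""
    t = target if target is not None else cg.target
    g = cg.graph
    parents = set(g.predecessors(t))
    children = set(g.successors(t))
    spouses = set()
    for c in children:
        spouses |= set(g.predecessors(c))
    return (parents | children | spouses) - {t}


class OracleCITest:
    """d-separation oracle satisfying the pluggable block-test contract.

    Emits a local log p-value of 0 (p = 1) when the candidate is
    d-separated from the target given the selected set, and a decisively
    negative constant when d-connected.  Log-likelihood surrogates are 0;
    the bootstrap heuristics are meaningless under an oracle and should be
    disabled when using it.
    """

    def __init__(self, cg: CausalGraph):
        self.cg = cg

    def process_block(self, y, s_values, cand_values, s_labels, cand_labels):
        logp = np.array(
            [
                0.0
                if d_separated(self.cg, self.cg.target, x, set(s_labels))
                else ORACLE_DEPENDENT_LOG_P
                for x in cand_labels
            ]
        )
        lam = np.zeros(len(cand_labels))
        null_coefs = np.zeros(len(s_labels) + 1)
        return logp, lam, null_coefs


# ---------------------------------------------------------------------------
# sampling from the network
# ---------------------------------------------------------------------------

@dataclass
class BNDataset:
    X: np.ndarray
    y: np.ndarray
    feature_labels: list[str]
    markov_blanket: set[str]
    graph: CausalGraph


def _calibrate_intercept(eta: np.ndarray, balance: float) -> float:
    """Solve ``mean(sigmoid(b0 + eta)) = balance`` for ``b0`` by bisection."""
    lo, hi = -30.0, 30.0
    for _ in range(100):
        mid = (lo + hi) / 2.0
        if expit(mid + eta).mean() < balance:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def sample_bn_dataset(cg: CausalGraph, spec: BNSimSpec) -> BNDataset:
    """Sample a dataset from the DAG with linear-Gaussian structural equations.

    Every non-target variable is a weighted sum of its *standardized*
    parents, rescaled to unit variance, plus Gaussian noise of variance
    ``error_variance``; weights are drawn uniformly from
    ``+-[coefficient_range]`` and fix the *relative* parent contributions.
    Scaling the total parental signal to the error variance keeps the
    signal-to-noise ratio of every structural equation at 1:1 regardless of
    depth or in-degree: marginal variances stay bounded along ancestral
    chains (so conditional tests retain power everywhere) and no variable
    becomes a near-deterministic function of its parents (which would
    break the chi-square calibration of local likelihood-ratio tests
    through quasi-separation).  The target is Bernoulli with a logistic
    link on its standardized, unit-variance parent sum, its intercept
    calibrated so the realized class balance matches ``class_balance``;
    children of the target receive its standardized 0/1 value as a regular
    parent, so the target has children and, generically, spouses.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5A11]))
    n = spec.n_samples
    order = list(nx.topological_sort(cg.graph))
    lo, hi = spec.coefficient_range
    values: dict[str, np.ndarray] = {}
    standardized: dict[str, np.ndarray] = {}
    sd = float(np.sqrt(spec.error_variance))
    y = None
    for v in order:
        parents = sorted(cg.graph.predecessors(v))
        coefs = rng.uniform(lo, hi, size=len(parents)) * rng.choice(
            [-1.0, 1.0], size=len(parents)
        )
        contrib = np.zeros(n)
        for c, pa in zip(coefs, parents):
            contrib += c * standardized[pa]
        if parents:
            sz = contrib.std()
            if sz > 0:
                contrib /= sz
        if v == cg.target:
            b0 = _calibrate_intercept(contrib, spec.class_balance)
            probs = expit(b0 + contrib)
            y = (rng.random(n) < probs).astype(np.float64)
            values[v] = y
        else:
            values[v] = contrib + rng.normal(0.0, sd, size=n)
        vv = values[v]
        svv = vv.std()
        standardized[v] = (vv - vv.mean()) / svv if svv > 0 else vv - vv.mean()
    labels = [v for v in cg.graph.nodes if v != cg.target]
    labels.sort(key=lambda s: int(s[1:]))
    X = np.column_stack([values[v] for v in labels])
    return BNDataset(
        X=X,
        y=y,
        feature_labels=labels,
        markov_blanket=markov_blanket(cg),
        graph=cg,
    )


def simulate_bn(spec: BNSimSpec, max_tries: int = 20) -> BNDataset:
    """Draw a random DAG and sample from it, regenerating while the target's
    Markov blanket is empty (an isolated target makes recovery vacuous)."""
    for attempt in range(max_tries):
        sub = BNSimSpec(
            n_vars=spec.n_vars,
            n_samples=spec.n_samples,
            seed=int(np.random.SeedSequence([spec.seed, attempt]).generate_state(1)[0] % (2**31))
            if attempt
            else spec.seed,
            avg_degree=spec.avg_degree,
            error_variance=spec.error_variance,
            class_balance=spec.class_balance,
            coefficient_range=spec.coefficient_range,
        )
        cg = random_dag(sub)
        if markov_blanket(cg):
            return sample_bn_dataset(cg, sub)
    raise RuntimeError("failed to draw a graph with a non-empty Markov blanket")


# ---------------------------------------------------------------------------
# SNP simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SNPSimSpec:
    """Reduced-scale SNP genotype/phenotype simulation settings.

    Genotypes take values {0, 1, 2} (minor-allele counts).  ``ld_rho`` is
    the latent-Gaussian correlation shared by SNPs in the same LD block of
    ``ld_block_size`` neighbouring SNPs.  ``n_causal`` SNPs (default 100)
    drive a binary phenotype through a logistic model whose effect scale is
    calibrated so the Bayes-optimal accuracy of the generating model
    approximates ``bayes_accuracy_target`` (default 0.8142).
    """

    n_individuals: int
    n_snps: int
    seed: int
    n_causal: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 10
    ld_rho: float = 0.7
    bayes_accuracy_target: float = 0.8142

    def __post_init__(self) -> None:
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal cannot exceed n_snps")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must lie in [0, 1)")
        if not (0.5 < self.bayes_accuracy_target < 1.0):
            raise ValueError("bayes_accuracy_target must lie in (0.5, 1)")


@dataclass
class SNPDataset:
    genotypes: np.ndarray
    phenotype: np.ndarray
    causal_indices: np.ndarray
    bayes_accuracy: float
    mafs: np.ndarray
    causal_weights: np.ndarray
    effect_scale: float


def _correlated_alleles(rng, n, n_snps, block, rho, thresholds) -> np.ndarray:
    """One haplotype's allele indicators with block-equicorrelated latents."""
    z = np.empty((n, n_snps))
    for start in range(0, n_snps, block):
        width = min(block, n_snps - start)
        f = rng.normal(size=(n, 1))
        eps = rng.normal(size=(n, width))
        z[:, start : start + width] = np.sqrt(rho) * f + np.sqrt(1.0 - rho) * eps
    return (z > thresholds[None, :]).astype(np.int8)


def simulate_snp(spec: SNPSimSpec) -> SNPDataset:
    """Simulate genotypes with local LD and a causal binary phenotype.

    Each SNP's minor-allele frequency is drawn uniformly from
    ``maf_range``; two independent haplotypes per individual are produced
    by thresholding block-correlated latent Gaussians and summed to a
    genotype in {0, 1, 2}.  Causal SNPs enter the phenotype's logistic
    linear predictor with random-sign weights on standardized allele
    counts; a scalar effect multiplier is found by bisection so that the
    Monte-Carlo Bayes-optimal accuracy ``E[max(p, 1-p)]`` of the generating
    model matches the target.  The realized estimate is returned.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_individuals, spec.n_snps
    mafs = rng.uniform(*spec.maf_range, size=m)
    thresholds = -ndtri(mafs)  # P(z > t) = maf
    g = _correlated_alleles(
        rng, n, m, spec.ld_block_size, spec.ld_rho, thresholds
    ) + _correlated_alleles(rng, n, m, spec.ld_block_size, spec.ld_rho, thresholds)
    g = g.astype(np.float64)
    causal = np.sort(rng.choice(m, size=spec.n_causal, replace=False))
    w = rng.uniform(0.5, 1.5, size=spec.n_causal) * rng.choice(
        [-1.0, 1.0], size=spec.n_causal
    )
    gm = 2.0 * mafs[causal]
    gs = np.sqrt(2.0 * mafs[causal] * (1.0 - mafs[causal]))
    u = ((g[:, causal] - gm) / gs) @ w

    def bayes_acc(scale: float) -> float:
        p = expit(scale * u)
        return float(np.maximum(p, 1.0 - p).mean())

    lo, hi = 0.0, 1.0
    while bayes_acc(hi) < spec.bayes_accuracy_target:
        hi *= 2.0
        if hi > 1e3:
            break
    for _ in range(60):
        mid = (lo + hi) / 2.0
        if bayes_acc(mid) < spec.bayes_accuracy_target:
            lo = mid
        else:
            hi = mid
    scale = (lo + hi) / 2.0
    probs = expit(scale * u)
    phenotype = (rng.random(n) < probs).astype(np.float64)
    return SNPDataset(
        genotypes=g,
        phenotype=phenotype,
        causal_indices=causal,
        bayes_accuracy=bayes_acc(scale),
        mafs=mafs,
        causal_weights=w,
        effect_scale=scale,
    )
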