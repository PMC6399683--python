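# Methods

## The selection procedure

`pfbp` selects a minimal, collectively predictive feature set for a binary
outcome `T` by greedy forward-backward conditional-independence testing,
organized so that every expensive computation touches only one *data block*
(a contiguous set of rows × a set of columns) at a time.

**Local tests.** On a block with rows `S_i`, the conditional independence of
a candidate `X` with `T` given the currently selected set `S` is tested with
a logistic-regression likelihood ratio: `D = -2 (LL0 - LL1) ~ chi2(df)`
where `LL0` is the null fit on `S` and `LL1` the fit on `S ∪ {X}`; `df = 1`
for a numeric candidate, `K-1` for a `K`-level categorical coded as dummies.
When `S` is empty the asymptotically equivalent univariate score
(Lagrange-multiplier) statistic

    z = Σ_j X_j (T_j - T̄) / sqrt( T̄ (1-T̄) Σ_j (X_j - X̄)² )

replaces the LRT (two-sided standard-normal reference), avoiding any model
fit in the heaviest first iteration.

**Meta-analysis.** Local log p-values `π_{i,j}` are combined per feature by
Fisher's method, `Statistic = -2 Σ_i log π_{i,j} ~ chi2(2K)` over the `K`
blocks processed so far. All arithmetic stays on the natural-log scale;
p-values are never exponentiated. The significance decision at level `α`
compares the statistic against the `chi2(2K)` upper quantile, which is
exactly equivalent and avoids tail evaluations inside the bootstrap loops.

**Control loop.** A *Run* is a forward phase (add the feature with the
smallest combined p-value while it is below `α` and fewer than `max_vars`
are selected) followed by a backward phase (repeatedly remove the feature
with the largest combined p-value given the others while it exceeds `α`).
By default two Runs execute; each Run re-initializes the remaining set to
all non-selected features, which is what lets spouse variables — marginally
independent of `T`, dependent given a common child — enter in Run 2. Under
an exact conditional-independence oracle on a faithful DAG distribution
this returns precisely the Markov blanket of `T` (parents ∪ children ∪
spouses); the test suite asserts this on 100 random DAGs, and a restricted
latent-variable variant (collider paths through unobserved parents) with
unlimited Runs.

**Early decisions.** Rows are processed in *Groups* of `C` blocks; after
each Group three bootstrap tests on the accumulated matrices `Π` (log
p-values) and `Λ` (log-likelihoods) may prune work:

* *Early Dropping*: feature `j` leaves the Run when the estimated
  probability that its combined p-value is ≥ `α` reaches `P_drop`.
* *Early Stopping*: `j` leaves the current Iteration when the probability
  that the current best feature beats it reaches `P_stop` (reversed in the
  backward phase: features unlikely to be the *worst* are stopped).
* *Early Return*: the Iteration ends, returning the current best, when for
  every alive competitor the probability that the best's summed
  log-likelihood is within `log(tol)` of it reaches `P_return`.

Each probability is estimated from `B` resamples of the rows of `Π`/`Λ`,
with the original sample included and denominator `B + 1`; one shared index
matrix drives all variables and all three tests in a round, and an
upper-bound abort stops counting for a variable once its decision is
settled (provably identical decisions, asserted on 1000 random stores).
When an Iteration completes all Groups, dropping is applied directly on the
exact combined p-values with no bootstrap. When a Group round makes no
progress, the Group size is doubled for the remainder of the Iteration.

**Combined predictive model.** Each block's null fit on the selected set is
cached; averaging the per-block coefficient vectors (equal weights, since
blocks are equal-sized random row samples) yields a global logistic model
for free. One model per forward Iteration is cached, enabling an
accuracy-versus-k curve on a holdout set without refitting.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.01 | significance level of every conditional-independence decision |
| `max_vars` | 50 | cap on selected features; also sets worst-case `df = max_vars + 1` for block sizing |
| `max_runs` | 2 | forward-backward Runs; 2 suffice for Markov-blanket recovery in faithful DAG distributions |
| `rule` | STD | rows per block: STD `s = df·c/√(p0 p1)`; EPV `s = c/min(p0,p1)·df` |
| `epv_constant` (`c`) | 10 | sizing constant; below 10 a warning is issued |
| `C` | 30 | Sample Subsets per Group (≥ 15 recommended so the first bootstrap round is meaningful; reduced to `ns` on small data) |
| `P_drop`, `P_stop` | 0.99 | bootstrap decision bars |
| `P_return`, `tol` | 0.95, 0.9 | Early-Return bar and likelihood tolerance (`lt = log tol`) |
| `B` | 500 | bootstrap resamples (recommended minimum; larger is better) |
| `workers` | 1 | concurrent block processors; also sets the number of Feature Subsets `nf = ⌊workers/C⌋` |

Thresholds above 1 disable the corresponding heuristic (no count can reach
the bar); `HeuristicConfig.disabled()` turns all three off, which together
with `deterministic_drop=False` reduces the engine to plain
forward-backward selection over Fisher-combined block p-values — the test
suite asserts exact sequence equivalence with an independent brute-force
implementation.

## Numerical choices

* **Log-space χ² tail.** `chi2_log_sf` evaluates the regularized upper
  incomplete gamma `Q(df/2, x/2)` by upward recurrence from the closed
  forms `Q(1/2,z) = erfc(√z)` (via `log_ndtr`) and `Q(1,z) = e^{-z}`,
  entirely in log space. Relative error in the log is ≤ 1e-6 (in practice
  ~1e-16) down to p ≈ 1e-100000, verified against mpmath. This matters
  because at large n genuinely dependent features produce p-values far
  below the smallest positive double, and a single p rounded to zero would
  poison the Fisher combination; local log p-values of exactly −∞ are
  floored at −1e12.
* **Newton fitter.** Custom Newton iterations with Armijo backtracking
  (slope condition 1e-4, halving steps); fallback chain when the observed
  information is (near-)singular — relative Cholesky pivot floor 1e-10 →
  fixed-Hessian direction `X'X/4` with a 1e-8 ridge (fallback only, never
  the primary path) → plain gradient ascent. Convergence: full-step
  coefficient change < 1e-8 or relative log-likelihood change < 1e-10,
  at most 100 iterations. The coefficient criterion deliberately counts
  only full Newton steps: a step crushed by backtracking on an
  ill-conditioned Hessian says nothing about stationarity, and accepting it
  silently under-fits null models and inflates every downstream LRT.
  Perfect separation (LL → 0 with exploding slopes) is flagged
  `converged=False` and returns finite coefficients rather than raising.
  Candidate fits within a block are batched across candidates (shared null
  design, vectorized Newton with per-candidate masking); any candidate the
  batch cannot handle is refit with the robust scalar path.
* **Ties.** Equal combined statistics resolve to the lowest column index,
  then insertion order — selections are deterministic and independent of
  the worker count (asserted 1 vs 4 workers).
* **Negative statistics** from roundoff are clipped to zero; magnitudes
  beyond 1e-6 raise a diagnostics warning.
* **Single-class blocks** contribute no row to `Π`/`Λ` (random row
  assignment makes this rare and unbiased); a dataset whose every block is
  single-class surfaces as a degenerate-fit error.
* **Seeds.** All randomness flows from the single `seed` passed to
  `fit`/the CLI: the row partition directly, each bootstrap round through
  `SeedSequence([seed, run, phase, iteration, round])`.

## What the synthetic generators emulate — and what they do not

**Bayesian-network data.** `random_dag` arranges `n_vars` vertices in a
random topological order (the target placed mid-order so it has parents and
children) and draws each forward edge with probability
`avg_degree/(n_vars-1)`, giving expected total degree `avg_degree`
(default 10). `sample_bn_dataset` uses linear-Gaussian structural
equations: each variable is a weighted sum of its *standardized* parents,
rescaled to unit variance, plus `N(0, error_variance)` noise (default 1);
weights are ±U[0.5, 1.5]. The target is Bernoulli-logistic on its
unit-variance parent sum with the intercept bisected to the requested class
balance (default 50/50). Keeping every structural equation at 1:1
signal-to-noise is a deliberate choice with two experimentally observed
failure modes on either side: raw (unstandardized) chains let marginal
variances grow multiplicatively with depth, diluting conditional signals
until blanket members are undetectable at any reasonable n; per-parent
standardization without total rescaling makes variables ~90% determined by
their parents, so the target becomes near-deterministic given its blanket
and small-block logistic fits quasi-separate, destroying the χ²
calibration of the local tests. The generator therefore produces redundant
and irrelevant features with uniform test power at every graph depth.
It does **not** emulate: non-linear or interaction dependencies, discrete
features, heteroscedastic noise, or sampling bias across blocks — passing
recovery tests say nothing about those regimes.

**SNP data.** `simulate_snp` draws per-SNP minor-allele frequencies from
`maf_range` (default 0.05–0.5), builds two haplotypes per individual by
thresholding block-equicorrelated latent Gaussians (`ld_block_size` = 10
SNPs, latent correlation `ld_rho` = 0.7) and sums them to genotypes in
{0, 1, 2}. A random subset of `n_causal` SNPs (default 100) drives a
logistic phenotype on standardized allele counts; a scalar effect
multiplier is bisected until the Monte-Carlo Bayes-optimal accuracy
`E[max(p, 1-p)]` of the generating model matches
`bayes_accuracy_target` (default 0.8142), and the realized estimate is
returned with the data. This emulates the *layout* of a genotype matrix —
dense {0,1,2} values, local LD, many-SNP sparse causality — at desk scale;
it does not reproduce population-genetic realism (no recombination maps,
population structure, or empirical haplotype frequencies).

**Oracle test.** `OracleCITest` answers every block query from graph
d-separation (p = 1 when separated, a decisively significant constant when
connected). It removes estimation error entirely, isolating the control
loop for the recovery theorems; the bootstrap heuristics are meaningless
under it and should be disabled.

## Known limitations

* The guarantees are asymptotic and assume faithfulness; at finite n the
  pruning heuristics trade recall for speed. In a paired study (50 seeds,
  16 variables, two Groups per Iteration) the default heuristics reproduced
  the exhaustive run's final selection in ~86% of seeds; the diffs are
  single borderline features, driven by Early Stopping/Return settling the
  winner after the first Group and Early Dropping pruning weak-but-real
  features at partial evidence — enlarging `B` does not help, because these
  are design-intended truncations, not estimation noise.
* Combining many local LRTs inherits their small-sample bias: with heavily
  collinear selected sets the χ²₁ calibration of each block degrades
  slightly and Fisher's sum amplifies the miscalibration. The sizing rules
  (`c ≥ 10`) keep this mild for well-conditioned designs; exact duplicates
  are handled (the likelihood cannot improve, so p = 1), but near-duplicates
  at correlation ≳ 0.999 can accumulate spurious significance.
* Only binary targets and the logistic test family are implemented; the
  pluggable block-test contract is the extension point for other outcome
  types.
* Categorical candidates are supported by the test layer (dummy encoding,
  `df = K-1`) but the selection loop treats matrix columns individually.
* Parallelism is in-process (threads over blocks); the partitioning layer
  computes the geometry a distributed deployment would use but no
  cross-machine execution is included.

## Problem sizes in the shipped studies

The test suite and `scripts/acceptance.py` run everything at desk scale,
chosen so each study still exercises the mechanism it checks: oracle
recovery on 100 DAGs of 12–20 nodes; data-based recovery on 50-variable
networks at n = 20 000 (STD-sized blocks, ns ≈ 38, 2 Groups); the
heuristics-agreement study at n = 12 000 with two Groups so every bootstrap
decision path fires; the SNP proof-of-concept at 24 000 individuals × 500
SNPs with 50 causal variants. The reported quantities are recomputed from
scratch on every run.
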