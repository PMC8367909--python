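# Methods

## Model

`facetlink` implements the adjacent-categories many-facet Rasch model
(MFRM) for polytomous ratings. For each observed triple (examinee j, task
i, rater r) the category probabilities depend on the linear predictor
eta = theta_j − beta_i − gamma_r through cumulative logits
psi_k = k·eta − D_k with D_k = d_1 + … + d_k. All parameters live on the
logit scale. Identification is handled structurally:

* d_1 = 0 and sum(d_2..d_K) = 0 are invariants of the parameter
  container itself, enforced at construction (tolerance 1e-12 on the sum);
* gamma_1 = 0 is an *estimation-time* constraint applied only in
  stand-alone fits. When anchors are fixed, the model is identified by
  them and gamma_1 is free — fixing it too would distort the linked scale.

Probabilities are always computed with max-subtraction before
exponentiation; |eta| near 8 occurs under extreme parameter draws and
naive evaluation of exp(K·eta) would overflow.

Missing ratings are represented by record *absence* in the in-memory
container. The conventional −1 sentinel is honored in CSV exchange only;
keeping sentinels out of the data structure removes a whole class of
sentinel-arithmetic bugs. Indices are 0-based in memory and 1-based in
all files and reports.

## Synthetic truth and what it does (not) emulate

A linking replication builds two tests with known truth:

* base test: theta, beta, gamma, d all i.i.d. N(0, 1);
* new test: drawn from configurable normal distributions. Four shift
  scenarios are predefined: a −0.5 ability shift (the hard, baseline
  case), a −0.2 shift, and −0.5 shifts combined with a +0.5 task or
  rater shift. The −0.5 baseline is calibrated to the sampling error of
  a 100-examinee mean: SEM = 1/sqrt(100) = 0.1, so observed between-test
  mean shifts rarely exceed ±2.5·SEM = 0.25, and 0.5 is a deliberately
  adversarial value.
* category parameters: K−1 draws are sorted ascending and mean-centred
  (the linear transformation that achieves a zero total while preserving
  order), then d_1 = 0 is prepended. Sorting reflects that transitions
  get harder with the category in practice.

C_R raters and C_I tasks are *embedded*: uniformly chosen base entries
overwrite uniformly chosen new-test slots, and the layout records the
mapping together with the anchor values. Anchors are fixed at the base
test's **true** generated values; the base test is never estimated in the
default pipeline. Fixing anchors at base-test *estimates* instead is
available via `ExperimentConfig(anchor_at_estimates=True)` (it samples
and fits the base test stand-alone first), but it is off by default and
outside the main study conditions.

Anchor drift, when enabled, adds a zero-mean normal fluctuation to about
half of the common entities before data sampling only: ceil(C_I/2) tasks
(SD 0.05) and ceil((C_R−1)/2) raters (SD 0.10), drawn uniformly among the
commons and re-drawn each replication. Estimation still fixes the
original anchor values — that mismatch is precisely the drift effect
being measured. The drift SDs match magnitudes reported in empirical
item-drift and rater-drift studies. theta and d never drift.

The generator emulates i.i.d. normal facets, an equal-sized base and new
test, and missingness created purely by the rater-set design. It does not
emulate correlated rater effects, non-normal ability distributions,
rater-by-task interactions, examinee-level nonresponse, or tests of
unequal size — conclusions from passing tests carry to real data only to
the extent those idealizations hold.

## Rater-set design

The generalized rater-set design enumerates all C(R, N_R) subsets of
N_R raters in lexicographic order and deals them to evaluation targets
(enumerated examinee-major) cyclically: target t gets subset
t mod C(R, N_R). This yields exactly N_R raters per target, per-rater
loads balanced within one cycle's contribution C(R−1, N_R−1), and —
whenever J·I ≥ C(R, N_R), true of every study setting — a connected
rater graph, the condition for linking to be possible at all.
Connectivity is verified explicitly via the rater co-grading graph
(networkx). When J·I < C(R, N_R) the builder warns and leaves the verdict
to `connectivity_check`. The missing rate is [1 − N_R/R]·100 exactly.

The traversal and enumeration orders are fixed by convention; any order
satisfying the same balance/coverage invariants would do, since results
are averaged over random parameter draws.

## Estimation

Parameters are estimated by EAP (posterior mean) over MCMC draws with
standard normal priors on all free parameters: every theta, the
non-anchored beta and gamma, and the K−2 free d components. d is
parameterized by d_2..d_{K−1} with d_K = −sum determined, so every draw
satisfies the identification constraints exactly — not approximately.

The sampler is Metropolis-within-Gibbs with Gaussian random-walk
proposals. theta, beta and gamma are updated as vectorized independent
single-site moves (components of a class are conditionally independent
given the others); d moves as one joint (K−2)-dimensional proposal.
Per-record log-likelihood terms are cached and updated only for accepted
components, with the hot kernel JIT-compiled (numba). Proposal SDs start
at (0.3, 0.15, 0.15, 0.08) for (theta, beta, gamma, d) and are adapted
every 100 burn-in iterations toward 40% acceptance (30% for the joint d
move), clipped to [1e-3, 10]; adaptation stops at the end of burn-in, so
retained draws come from a fixed kernel.

Defaults are 5000 iterations, 2000 burn-in, thinning 2, one chain — the
posterior has at most a few hundred coordinates and is unimodal in
practice, and convergence was verified by tripling the chain length
(mean RMSE moved by < 0.01) and by split-chain R-hat ≤ 1.02 on the study
settings. Extra chains (over-dispersed starts) are supported and pooled.
Diagnostics report per-class acceptance rates, max split-chain R-hat per
class, and batch-means Monte Carlo standard errors; parameters with no
observations trigger a prior-domination warning.

With no data the sampler reproduces the prior (EAP ≈ 0 within Monte
Carlo error), which the tests exploit as an oracle, along with a 1-D
quadrature oracle for a single free theta.

## Linking evaluation

`run_replication` composes the six steps and scores the estimates with
an error index over a scope: RMSE (default), MAE, or |mean bias|, over
all free parameters or restricted to abilities, tasks, raters, or
categories. Anchored entries are excluded by default — their deviation
is identically zero and would deflate the index; `include_anchored=True`
exposes the sensitivity check. The d parameters count as the "category"
scope (d_2..d_K) and are part of "all_free".

The threshold delta = mu_e + 2·sigma_e (sample SD, n−1) comes from
replications in which the new test's distributions are set equal to the
base test's, so the tests are trivially on one scale and the remaining
error is pure estimation noise at that data size and design. A cell
(C_R, C_I) "links accurately" when its mean error is below delta. The
threshold stage derives its own seeds from (master, C_R, C_I, rep,
stage), so delta is shared across distribution scenarios of equal data
size under a shared master seed, and depends only on data size and
design as intended.

Failed replications (non-finite error or an internal error) are retried
once on a fresh derived seed and otherwise excluded with a logged
warning; a cell needs at least two successes.

## Seeds and reproducibility

All grid randomness derives from one master seed through
`SeedPlan`: child streams are `numpy` `SeedSequence`s with spawn key
(C_R, C_I, replication, stage), with stages 0 (evaluation), 1
(threshold) and 2/3 (retries). The derivation is injective and
order-independent, so cells and replications can run in any order or in
parallel with identical results, and any single replication can be
replayed from its logged seed. Within a replication, separate child
streams drive base generation, new generation, embedding, drift,
sampling and MCMC; because data sampling inverts the model CDF against
per-record uniforms, two runs sharing a replication seed are paired
record-by-record (common random numbers) even when parameters differ
slightly — this is what makes the drift and missing-data comparisons
paired rather than independent.

## Problem sizes used in the shipped checks

The shipped test suite and the acceptance script run the mid-scale
setting (J=100, I=10, R=10, K=5) at 10 replications per condition with
the default sampler, and the qualitative trend checks at 6–10
replications (J=50 or 100) with a 2500-iteration sampler — sizes chosen
so the whole suite completes in minutes while keeping replication noise
around 0.01 on the reported means. The full 30-replication 5×5 grids
(and the J=1000 large-scale variant) are supported as configuration and
provided as `examples/05_full_grid.py`; they take hours and are not part
of the default test surface.

## Known limitations

* Only the representative MFRM parameterization is implemented — no
  per-rater thresholds, discrimination parameters, or graded-response /
  generalized-partial-credit variants.
* Linking covers exactly two tests via common raters/tasks with anchors
  fixed; scale-transformation and concurrent-calibration methods, common
  examinee designs, and simultaneous linking of more than two tests are
  out of scope.
* The sampler is a random-walk scheme; it is exact but not optimal for
  very large J. The J=1000 setting works but is slow by design.
* Posterior summaries beyond means (intervals, ESS per parameter) are
  limited to what the diagnostics dict exposes.
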