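# Methods

This note documents the models, priors, numerical choices and limitations of
`clockbench`. Symbols: a chronogram has node ages in time units with the
root age `T` fixed; a branch is identified by its child node; `dur(b)` is
its time duration; substitution rates are in expected substitutions per site
per time unit.

## Ground-truth trees

`make_three_taxon_tree()` is the fixed chronogram ((A,B),C) with root age
1.0 and internal node age 0.5. It has four rate-carrying branches — the two
cherry tips, the internal branch (all duration 0.5) and the outgroup branch
(duration 1.0) — and all four receive lineage/residual rate draws.

Two Yule (pure-birth, no extinction) simulators are provided:

* `simulate_yule_tree(n, lam, rng)` runs the process forward: while `k`
  lineages exist the wait to the next split is Exp(k·lam) and a uniformly
  chosen lineage splits. After the split that creates the `n`-th lineage one
  further Exp(n·lam) wait is appended before the present. Without that final
  wait the youngest internal node would sit at age exactly 0, producing a
  zero-duration branch, violating the strict parent-older-than-child
  invariant, and making percentage-error metrics divide by zero; the extra
  wait is the standard simple-sampling stop rule and is exact for the
  forward process.
* `simulate_yule_tree_conditioned(n, lam, rng)` samples the conditioned
  reconstructed process (uniform prior on the origin time, as TreeSim-style
  simulators do): the root age has density
  `(n−1)·lam·e^(−lam·T)·(1−e^(−lam·T))^(n−2)`, the remaining `n−2` ages are
  i.i.d. truncated-exponential `lam·e^(−lam·a)/(1−e^(−lam·T))` on `(0, T)`,
  and the ranked topology splits a uniformly chosen lineage at each age.
  The eight-taxon experiment uses this sampler: node-age summaries weighted
  by percentage error are sensitive to the ages of the youngest nodes, and
  the conditioned process is the appropriate reference distribution when the
  root age is "unfixed" but the tip count is conditioned on.

## Rate classes

All rate multipliers are lognormal, parameterized on the **log scale**
(location mu, scale sigma); `sigma = 0` is the point mass at `exp(mu)`. The
default study setting is mu = −0.01, sigma = 0.15, whose mean multiplier is
`exp(mu + sigma²/2) = 1.00125`. Composition order is pinned: lineage rates
are applied once to the species tree (one independent draw per branch, in
deterministic post-order); each locus copies that rated tree; then per locus
in index order a single gene-specific draw scales all branches, and
residual draws (one per branch per locus) are applied. Seeded runs are
bit-reproducible, and `sigma = 0` consumes the same number of rng draws as
`sigma > 0` so the draw stream is configuration-stable.

For the eight-taxon experiment lineage rates are drawn as *absolute* rates
(lognormal location −3.01 ≈ log 0.05, scale 0.15) with the JC base rate set
to 1, so a branch's effective length is `rate × duration` directly. The
no-variation control is the `sigma → 0` limit of the same distribution —
every branch evolves at exactly `exp(−3.01)`, the UCLN prior median — so
the two conditions differ only in the lineage-rate scale. (A control at the
strict rate 0.05 is also available; its ~1.4% rate offset from the prior
median adds a visible age bias of its own, confounding the lineage-rate
contrast.)

## Sequence simulation and the JC sufficient statistic

Sequences evolve under Jukes–Cantor with effective branch length
`baseRate × branchLength`, where `branchLength` already carries duration and
all multipliers and baseRate defaults to 0.05. Root states are uniform.
`simulate_alignment` samples child states per branch vectorized over sites
(distributionally identical to per-site jump simulation under JC).

Because unlinked sites are i.i.d., the site-pattern count table is a
multinomial over the `4^n` exact pattern probabilities, and it is the
sufficient statistic for the JC likelihood. `simulate_pattern_counts` draws
that multinomial directly; replicate-scale experiments use it because its
cost does not grow with alignment length. A distributional-equivalence test
compares the two routes.

The likelihood engine (`jc.py`) evaluates Felsenstein pruning vectorized
over patterns and over an arbitrary batch of branch-length vectors. Under JC
the child-to-parent message is `p_diff·S + (p_same − p_diff)·L(x)` with `S`
the sum of the child partials, so no 4×4 matrix products occur. JC is
symmetric in the four states, so patterns that induce the same partition of
taxa have identical probability; `collapse_jc_equivalent` pools counts over
canonical patterns (64 → 5 classes for three taxa) with exactly unchanged
log likelihood. Numerical guards: the exponential argument is clipped at
effective length 700; nonpositive pattern probabilities map to log 0 = −inf
and are rejected by the MCMC.

## Priors

* **Yule node-age prior.** Conditional on the root age and tip count, each
  free internal age is i.i.d. `lam·e^(−lam·a)/(1−e^(−lam·T))`, with
  topology-order constraints enforced by the proposal bounds. The
  three-taxon experiments place an Exp(10) hyperprior on `lam` (the induced
  marginal prior on the node age is uniform on (0, 1) to within ~0.01 in
  CDF, which the prior-only calibration test checks by KS); the eight-taxon
  experiments fix `lam = 1`, the generating value.
* **Strict clock.** Rate fixed (default 0.05); no free rate parameters.
* **UCLN.** One absolute rate per branch, i.i.d. lognormal(−3.01, 0.15 by
  default), shared across all loci. The location −3.01 sets the prior
  median rate to `exp(−3.01) ≈ 0.0493 ≈ 0.05·exp(−0.01)`, i.e. the base
  rate times the median lineage multiplier. `log_scale = 0` degenerates to
  a strict clock at `exp(log_location)` (used by the corrected-sigma sweep
  at sigma = 0).
* **Dirichlet rate prior.** Genome mean rate `mu_bar ~ lognormal(−3.01,
  0.15)`; proportions `p ~ Dirichlet(1, …, 1)` partition the total
  `mu_bar·L` so locus `i` has mean `m_i = mu_bar·L·p_i`; branch rates of
  locus `i` are i.i.d. lognormal(log m_i, 0.15). The per-locus UCLN is
  centered on the locus-specific mean rather than on a shared −3.01 offset;
  the alternative reading (shared location) would make the Dirichlet
  partition irrelevant to the branch-rate prior, defeating the prior's
  purpose, so the locus-specific reading is implemented.

## MCMC

Metropolis–Hastings over the free node ages and rate parameters, topology
and root age fixed. Moves:

* node-age: uniform window reflected at (max child age, parent age);
* node-age **rescale**: the same window proposal paired with deterministic
  rescaling of the three adjacent branch rates so every effective branch
  length is exactly preserved. The likelihood is untouched and the −log r
  prior terms cancel the Jacobian `∏ dur_old/dur_new`, so acceptance
  depends only on the quadratic prior terms and the Yule factor. This move
  is essential: age and rates are confounded along a likelihood ridge
  (age × rate ≈ constant), and plain single-parameter moves diffuse along
  it slowly. Under the Dirichlet prior the rescaling applies to the
  adjacent rates of every locus;
* rate multiplier moves (per branch; per branch × locus under Dirichlet,
  accepted independently per locus — valid because loci are conditionally
  independent given the ages);
* `mu_bar` scale move and disjoint pair-exchange moves on the Dirichlet
  proportions;
* `lam` scale move when the Yule rate has a hyperprior.

Proposal scales adapt every 50 sweeps during burn-in toward ~30% acceptance
(within the 20–50% band) and freeze afterwards. The default single-chain
schedule is 100,000 sweeps, 25% burn-in, thinning 10; batched experiment
runs use condition-appropriate shorter schedules (stated below). Replicate
chains with a common topology run in lockstep as one vectorized batch; a
chain that accepts no move during burn-in raises a diagnostic error (single
chain) or is flagged, excluded from summaries, and warned about (batch).

Under strict/UCLN clocks the branch rates are shared across loci, so the
multi-locus likelihood equals the likelihood of the pooled pattern counts;
the sampler pools counts up front (an exact, order-of-magnitude speedup).
The Dirichlet sampler keeps per-locus counts.

Posterior summaries: the posterior mean of the retained age samples, and
the 95% HPD as the shortest sorted window containing `ceil(0.95·n)`
samples, ties toward the lower window.

Sampler validation beyond unit tests: prior-only runs reproduce every prior
marginal (KS); on data, the posterior was cross-checked during development
against an importance-sampling estimate (single locus) and a Laplace
profile-marginal (400 loci) — both agreed with the sampler within
Monte-Carlo error.

## Experiment orchestration and problem sizes

A condition = rate-class configuration × locus count × clock prior.
Defaults follow the study design: 800 bp loci, locus grids {1, 20, 400},
200 replicates, truth 0.5. Summary statistics: RMSE of posterior means,
mean 95% HPD width, coverage percent; the eight-taxon experiment reports
the mean percentage error `100·|MPE − truth|/truth` over free nodes and
replicates, relative HPD widths, and per-node coverage.

Problem sizes used by the shipped runs (chosen to keep a single-CPU run
practical while keeping Monte-Carlo error well inside the comparison
tolerances):

* `scripts/acceptance.py`: 200 replicates per shared-rate condition with
  48,000-sweep chains (30% burn-in, 1,400 retained samples); the Dirichlet
  condition keeps all 400 loci and runs 56 replicates with 2,600-sweep
  chains (per-sweep cost scales with loci × replicates).
* the test suite: 100 replicates and 30,000-sweep chains per shared-rate
  condition; the Dirichlet-vs-UCLN contrast runs 100 loci × 12 replicates;
  the eight-taxon conditions run 5 replicates of 400-locus genomes with
  6,000-sweep chains. Test tolerances add a two-sigma Monte-Carlo allowance
  for the reduced replicate counts to the study's stated bands.

Per-replicate seeds derive from the configuration base seed; every summary
is bit-reproducible given that seed.

## Sister pairs

Only tip–tip cherries qualify as sister pairs (a clade-vs-tip sister does
not share the terminal duration). Folds use raw terminal branch lengths with
no correction for residual or gene-specific noise; on a concatenated
species tree of many loci residual noise largely averages out, but any
remaining noise inflates the empirical mean fold relative to a pure
lineage-rate expectation — the comparison against `expected_fold_lognormal`
should be read with that caveat. Zero-length terminal branches make the
fold undefined; such cherries are excluded with a warning.
`synthetic_phylogram` provides a stand-in input (Yule chronogram × lognormal
lineage rates) for pipelines whose empirical tree is not at hand.

## What the generator does and does not emulate

The synthetic data are exactly the study conditions: JC substitution, no
among-site rate heterogeneity, no indels or alignment error, unlinked sites,
known topology, a correct root-age calibration, and pure-birth trees.
Passing benchmarks therefore demonstrate properties of the inference
machinery under the stated model, not robustness to model violations
(GTR-like exchangeabilities, site rate variation, fossil-calibration error,
topology error), all of which are out of scope.

## Known limitations

* The pruning engine carries no partial-likelihood rescaling; it is
  intended for small trees (the study uses 3–8 taxa), where JC pattern
  probabilities stay far above the double-precision underflow threshold.
* Posterior means of skewed posteriors carry a small inherent bias (the
  no-variation 400-locus RMSE is bias-dominated at about 0.01); this is a
  property of the estimator under the model, not sampler error, as the
  Laplace cross-check confirms.
* The Dirichlet sampler's per-sweep cost is proportional to
  replicates × loci; its shipped replicate counts are correspondingly
  smaller, which mostly affects the Monte-Carlo precision of its coverage
  estimate.
* MCMC schedules were not studied in the original design and are the
  package's own choices; halving or doubling them moves summary statistics
  well within the stated tolerances.

## YAML schema for `clockbench experiment`

```yaml
condition: lineage           # label for the summary row
rate_classes:
  lineage: {mu: -0.01, sigma: 0.15}   # omit or null to disable a class
  gene: null
  residual: null
loci_grid: [1, 400]
clock: {kind: ucln, log_location: -3.01, log_scale: 0.15}
locus_length: 800
replicates: 200
base_seed: 1
schedule: {iterations: 40000, burnin_frac: 0.3, thin: 20}
```
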