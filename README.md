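# clockbench

Simulation benchmarks for Bayesian divergence-time estimation under three
classes of molecular-rate variation.

## The problem

The number of substitutions along a branch of a phylogeny is the product of
the branch's time duration and its substitution rate, so molecular data alone
cannot separate rates from times. How badly this hurts node-age estimation
depends on *how* rates vary across the genome:

* **lineage-specific rates** — among-branch variation that acts identically
  at every locus (a fast lineage is fast everywhere in the genome);
* **gene-specific rates** — per-locus variation in the average rate, uniform
  across branches within a locus;
* **residual rates** — among-branch variation with an independent pattern at
  every locus, which averages out as more loci are sampled.

`clockbench` rebuilds the complete simulation study around this
decomposition: ground-truth chronograms (a fixed three-taxon tree with root
age 1.0 and internal-node age 0.5, or random eight-taxon pure-birth trees),
lognormal rate multipliers (log-scale location &mu; = −0.01, scale
&sigma; = 0.15 by default), Jukes–Cantor sequence simulation (800 bp loci,
base rate 0.05 substitutions/site/time), and Bayesian MCMC inference of the
free node ages under three rate priors — a strict clock, an uncorrelated
lognormal (UCLN) relaxed clock (branch rates i.i.d. lognormal(−3.01, 0.15),
shared across loci), and a hierarchical Dirichlet rate prior that partitions
a genome-wide mean rate among loci. Replicate experiments are summarized by
RMSE of posterior-mean ages, mean 95% highest-posterior-density (HPD) width,
and HPD coverage.

The headline phenomenon: with residual or gene-specific rates, sampling 400
loci shrinks RMSE roughly eight-fold relative to a single locus; with
lineage-specific rates it barely helps, because the rate bias on each branch
is the same at every locus. Worse, confident priors (a strict clock, or a
UCLN whose variance understates the true lineage variation) yield narrow
HPDs that exclude the true age almost always once data are plentiful.

A companion module quantifies lineage-specific rates in empirical
phylograms through sister-pair fold differences: two terminal sister taxa
have identical durations, so the fold `max(lenA,lenB)/min(lenA,lenB)` of
their terminal branches reflects rate differences alone. For i.i.d.
lognormal rates the expected fold is `2·exp(σ²)·Φ(σ√2)` (≈1.19 at σ=0.15).

## Worked example

```python
import numpy as np
import clockbench as cb
from clockbench import experiment as ex, mcmc

# lineage-specific rates, 400 loci of 800 bp, UCLN inference, 50 replicates
config = ex.ExperimentConfig(
    rate_classes=cb.RateClassConfig(lineage=cb.LognormalSpec(-0.01, 0.15)),
    loci_grid=(400,),
    clock=mcmc.UCLNClock(-3.01, 0.15),
    replicates=50,
    base_seed=1,
    schedule=mcmc.MCMCSchedule(30_000, 0.3, 15),
)
summaries, row = ex.run_condition(config, 400)
print(f"RMSE={row.rmse:.4f}  mean HPD width={row.mean_hpd_width:.3f}  "
      f"coverage={row.coverage_percent:.0f}%")
```

Output from this exact snippet:

```
RMSE=0.0545  mean HPD width=0.201  coverage=98%
```

Read: averaged over 50 replicate genomes, the posterior-mean estimate of the
true age 0.5 is off by about 0.05 time units (a 10% error that more loci
will not remove), while the UCLN's honest rate variance keeps the 95% HPD
wide enough (~0.2) to cover the truth in most replicates. Running the same
condition with `clock=mcmc.StrictClock(0.05)` collapses the width to ~0.015
and the coverage to ~11%.

The sister-pair statistic on any Newick phylogram (here a 60-tip synthetic
phylogram generated with `clockbench.synthetic_phylogram(60, 0.15, rng)` at
seed 8):

```bash
clockbench sisterpairs --tree tree.nwk --out pairs.tsv --expected-sigma 0.15
# nPairs=19 meanFold=1.1627
# expected fold for lognormal sigma=0.15: 1.1946
```

Other CLI entry points: `clockbench simulate-trees`, `simulate-seqs`,
`infer`, and `experiment --config config.yaml` (YAML schema in
`docs/methods.md`).

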