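"""Metropolis-Hastings inference of node ages under three clock priors.

The sampler targets the posterior of the free internal-node ages of a fixed
rooted topology (root age conditioned on its true value) given compressed JC
site-pattern counts.  Three rate priors are supported:

* :class:`StrictClock` -- a single fixed substitution rate for every branch
  and locus; the only free parameters are node ages (and the Yule speciation
  rate when it carries a hyperprior).
* :class:`UCLNClock` -- an uncorrelated lognormal relaxed clock: one free
  absolute rate per branch, i.i.d. lognormal(``log_location``,
  ``log_scale``), shared across all loci.  Because the rates are shared, the
  multi-locus likelihood collapses onto the pooled (concatenated) pattern
  counts, which the sampler exploits.
* :class:`DirichletRateClock` -- a hierarchical multilocus prior: a
  genome-wide mean rate with a lognormal prior, partitioned among loci by a
  Dirichlet distribution, and an independent per-locus UCLN around each locus
  mean.  Per-locus structure is retained.

All samplers run an arbitrary batch of independent replicate chains in
lockstep through vectorized numpy updates; the public :func:`run_mcmc` is the
single-chain view.  Proposal scales are tuned during burn-in toward a 20-50%
acceptance rate and frozen afterwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import jc as jc_mod
from .seqsim import PatternCounts
from .trees import TimeTree

__all__ = [
    "StrictClock",
    "UCLNClock",
    "DirichletRateClock",
    "YulePrior",
    "MCMCSchedule",
    "PosteriorTrace",
    "BatchPosterior",
    "HPDInterval",
    "MCMCDiagnosticError",
    "yule_log_density",
    "clock_log_prior",
    "run_mcmc",
    "run_mcmc_batch",
    "hpd_interval",
    "posterior_mean",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


# -- priors ----------------------------------------------------------------


@dataclass(frozen=True)
class StrictClock:
    """Fixed substitution rate for all branches and loci."""

    rate: float = 0.05

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be > 0")


@dataclass(frozen=True)
class UCLNClock:
    """Uncorrelated lognormal relaxed clock on absolute per-branch rates.

    ``log_scale == 0`` degenerates to a strict clock at ``exp(log_location)``.
    """

    log_location: float = -3.01
    log_scale: float = 0.15

    def __post_init__(self) -> None:
        if self.log_scale < 0:
            raise ValueError("log_scale must be >= 0")


@dataclass(frozen=True)
class DirichletRateClock:
    """Hierarchical Dirichlet partition of a genome-wide mean rate.

    The across-loci mean rate ``mu_bar`` has a lognormal prior
    (``mean_log_location``, ``mean_log_scale``); Dirichlet(``concentration``)
    proportions ``p`` partition the total rate ``mu_bar * L`` so locus ``i``
    has mean ``m_i = mu_bar * L * p_i``; each branch rate of locus ``i`` is
    lognormal with location ``log(m_i)`` and scale ``branch_log_scale``.
    """

    mean_log_location: float = -3.01
    mean_log_scale: float = 0.15
    concentration: float = 1.0
    branch_log_scale: float = 0.15

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")
        if self.mean_log_scale < 0 or self.branch_log_scale < 0:
            raise ValueError("scales must be >= 0")


@dataclass(frozen=True)
class YulePrior:
    """Pure-birth branching prior; either a fixed rate or an Exp hyperprior.

    ``lam`` fixes the speciation rate; otherwise ``lam`` is a free parameter
    with an exponential prior of rate ``hyper_rate``.
    """

    lam: float | None = None
    hyper_rate: float | None = 10.0

    def __post_init__(self) -> None:
        if (self.lam is None) == (self.hyper_rate is None):
            raise ValueError("specify exactly one of lam / hyper_rate")
        if self.lam is not None and self.lam <= 0:
            raise ValueError("lam must be > 0")
        if self.hyper_rate is not None and self.hyper_rate <= 0:
            raise ValueError("hyper_rate must be > 0")


@dataclass(frozen=True)
class MCMCSchedule:
    iterations: int = 100_000
    burnin_frac: float = 0.25
    thin: int = 10

    def __post_init__(self) -> None:
        if self.iterations < 1 or not (0 <= self.burnin_frac < 1) or self.thin < 1:
            raise ValueError("invalid schedule")

    @property
    def burnin(self) -> int:
        return int(self.iterations * self.burnin_frac)


@dataclass(frozen=True)
class HPDInterval:
    lower: float
    upper: float
    mass: float = 0.95

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, x: float) -> bool:
        return self.lower <= x <= self.upper


class MCMCDiagnosticError(RuntimeError):
    """A chain failed basic health checks; carries per-move statistics."""

    def __init__(self, message: str, move_stats: dict):
        super().__init__(f"{message}; move statistics: {move_stats}")
        self.move_stats = move_stats


# -- prior densities -------------------------------------------------------


def _lognormal_logpdf(x, mu, sigma):
    """Elementwise lognormal log pdf; -inf at nonpositive x; sigma > 0."""
    x = np.asarray(x, dtype=np.float64)
    out = np.full(np.broadcast_shapes(x.shape, np.shape(mu)), -np.inf)
    ok = x > 0
    lx = np.log(np.where(ok, x, 1.0))
    val = -((lx - mu) ** 2) / (2.0 * sigma**2) - lx - math.log(sigma) - _LOG_SQRT_2PI
    return np.where(ok, val, out)


def yule_log_density(ages, root_age: float, lam) -> np.ndarray:
    """Log density of free internal-node ages under a conditioned Yule process.

    Conditional on the root age ``T`` and the number of tips, each non-root
    internal age is i.i.d. with density ``lam * exp(-lam * a) /
    (1 - exp(-lam * T))`` on ``(0, T)`` (topology ordering constraints are
    enforced by the caller's proposal bounds).  ``ages`` has the free node
    ages on its last axis; ``lam`` broadcasts against the leading axes.
    Ages outside ``(0, T)`` give ``-inf``; ``lam -> 0`` tends to the uniform
    density ``1/T`` per node.
    """
    ages = np.asarray(ages, dtype=np.float64)
    lam = np.asarray(lam, dtype=np.float64)
    k = ages.shape[-1]
    small = lam < 1e-12
    lam_safe = np.where(small, 1.0, lam)
    # log(lam / (1 - exp(-lam T))), stable for small lam * T
    log_norm = np.log(lam_safe) - np.log(-np.expm1(-lam_safe * root_age))
    log_norm = np.where(small, -math.log(root_age), log_norm)
    dens = k * log_norm - np.where(small, 0.0, lam) * ages.sum(axis=-1)
    bad = np.any((ages <= 0) | (ages >= root_age), axis=-1)
    return np.where(bad, -np.inf, dens)


def clock_log_prior(rates, prior) -> float:
    """Joint log prior density of the free rate parameters of a clock prior.

    ``rates`` is ``None`` for :class:`StrictClock` (no free parameters, 0 is
    returned); an array of per-branch rates for :class:`UCLNClock`; and a
    ``(mean_rate, proportions, branch_rates)`` tuple for
    :class:`DirichletRateClock` where ``branch_rates`` has shape
    ``(n_loci, n_branches)``.
    """
    if isinstance(prior, StrictClock):
        return 0.0
    if isinstance(prior, UCLNClock):
        r = np.asarray(rates, dtype=np.float64)
        if np.any(r <= 0):
            return -np.inf
        if prior.log_scale == 0:
            return 0.0 if np.allclose(r, np.exp(prior.log_location)) else -np.inf
        return float(
            _lognormal_logpdf(r, prior.log_location, prior.log_scale).sum()
        )
    if isinstance(prior, DirichletRateClock):
        mean_rate, props, branch_rates = rates
        props = np.asarray(props, dtype=np.float64)
        branch_rates = np.asarray(branch_rates, dtype=np.float64)
        L = props.size
        if mean_rate <= 0 or np.any(props <= 0) or np.any(branch_rates <= 0):
            return -np.inf
        if not math.isclose(float(props.sum()), 1.0, abs_tol=1e-8):
            return -np.inf
        a = prior.concentration
        total = math.lgamma(a * L) - L * math.lgamma(a) + (a - 1.0) * float(
            np.log(props).sum()
        )
        total += float(
            _lognormal_logpdf(mean_rate, prior.mean_log_location, prior.mean_log_scale)
        )
        locus_loc = np.log(mean_rate * L * props)[:, None]
        total += float(
            _lognormal_logpdf(branch_rates, locus_loc, prior.branch_log_scale).sum()
        )
        return total
    raise TypeError(f"unknown clock prior {type(prior)!r}")


# -- posterior summaries ---------------------------------------------------


def hpd_interval(samples, mass: float = 0.95) -> HPDInterval:
    """Shortest contiguous interval containing ``ceil(mass * n)`` samples.

    Ties are broken toward the lower interval.  Requires >= 100 samples.
    """
    s = np.sort(np.asarray(samples, dtype=np.float64))
    n = s.size
    if n < 100:
        raise ValueError("hpd_interval requires at least 100 samples")
    k = int(math.ceil(mass * n))
    widths = s[k - 1 :] - s[: n - k + 1]
    i = int(np.argmin(widths))  # argmin returns the first minimum: lower tie
    return HPDInterval(float(s[i]), float(s[i + k - 1]), mass)


def posterior_mean(trace) -> float | np.ndarray:
    """Arithmetic mean of the retained node-age samples of a trace."""
    ages = trace.node_ages if hasattr(trace, "node_ages") else np.asarray(trace)
    if ages.size == 0:
        raise ValueError("empty trace")
    m = ages.mean(axis=0)
    return float(m[0]) if m.ndim and m.shape[-1] == 1 else m


# -- traces ----------------------------------------------------------------


@dataclass
class PosteriorTrace:
    """Retained samples of one chain.

    ``node_ages`` is ``(n_kept, n_free)`` in the order of ``free_nodes``;
    ``rates`` is ``(n_kept, n_branches)`` (branch order = non-root post-order)
    or ``None`` for a strict clock; ``lam`` is ``None`` when fixed.
    """

    node_ages: np.ndarray
    free_nodes: np.ndarray
    rates: np.ndarray | None
    lam: np.ndarray | None
    log_posterior: np.ndarray
    acceptance: dict = field(default_factory=dict)


@dataclass
class BatchPosterior:
    """Retained samples of ``R`` replicate chains run in lockstep.

    ``node_ages`` is ``(R, n_kept, n_free)``.
    """

    node_ages: np.ndarray
    free_nodes: np.ndarray
    lam: np.ndarray | None
    log_posterior: np.ndarray
    acceptance: dict = field(default_factory=dict)
    rates: np.ndarray | None = None
    failed: np.ndarray | None = None

    def chain(self, r: int) -> PosteriorTrace:
        return PosteriorTrace(
            self.node_ages[r],
            self.free_nodes,
            None if self.rates is None else self.rates[r],
            None if self.lam is None else self.lam[r],
            self.log_posterior[r],
            self.acceptance,
        )

    def summaries(self, mass: float = 0.95, node: int = 0):
        """Per-chain (posterior mean, HPD) of one free node's age."""
        out = []
        for r in range(self.node_ages.shape[0]):
            s = self.node_ages[r, :, node]
            out.append((float(s.mean()), hpd_interval(s, mass)))
        return out


# -- shared-rate sampler (strict / UCLN) -----------------------------------


def _reflect(x, lo, hi):
    """Reflect proposals into (lo, hi); preserves proposal symmetry."""
    span = hi - lo
    z = np.mod(x - lo, 2.0 * span)
    return lo + np.minimum(z, 2.0 * span - z)


class _MoveStats:
    def __init__(self):
        self.acc: dict[str, float] = {}
        self.att: dict[str, float] = {}

    def add(self, name, accepted, attempted):
        self.acc[name] = self.acc.get(name, 0.0) + float(accepted)
        self.att[name] = self.att.get(name, 0.0) + float(attempted)

    def rates(self) -> dict:
        return {
            k: (self.acc[k] / self.att[k] if self.att[k] else float("nan"))
            for k in self.att
        }


class _SharedRateSampler:
    """Batched MH over node ages (+ per-branch rates, + lambda).

    ``counts`` is ``(R, P)`` pooled pattern counts aligned to ``patterns``
    (``None`` disables the likelihood for prior-only runs).
    """

    def __init__(self, tree: TimeTree, counts, patterns, clock, yule, jc_params,
                 schedule, rng, n_chains=None):
        self.tree = tree
        self.clock = clock
        self.yule = yule
        self.jc = jc_params
        self.schedule = schedule
        self.rng = rng
        internal = [v for v in range(tree.n_tips, tree.n_nodes) if v != tree.root]
        self.free_nodes = np.asarray(sorted(internal), dtype=np.int64)
        self.branches = tree.branch_nodes
        if counts is None:
            if n_chains is None:
                raise ValueError("n_chains required for prior-only runs")
            self.R = n_chains
            self.counts = None
            self.patterns = None
        else:
            counts = np.atleast_2d(np.asarray(counts, dtype=np.float64))
            self.patterns, self.counts = jc_mod.collapse_jc_equivalent(
                patterns, counts
            )
            self.R = self.counts.shape[0]

        R = self.R
        self.ages = np.tile(tree.ages, (R, 1))
        self.root_age = tree.root_age
        self.parent = tree.parent
        if isinstance(clock, UCLNClock):
            self.rates = np.full((R, tree.n_nodes), np.exp(clock.log_location))
            self.sample_rates = clock.log_scale > 0
        else:
            self.rates = None
            self.sample_rates = False
        if yule.lam is None:
            self.lam = np.full(R, 1.0 / yule.hyper_rate)
            self.sample_lam = True
        else:
            self.lam = np.full(R, yule.lam)
            self.sample_lam = False

        self.age_w = np.full((R, self.free_nodes.size), 0.05)
        self.resc_w = np.full((R, self.free_nodes.size), 0.1)
        self.rate_s = np.full((R, tree.n_nodes), 0.2)
        self.lam_s = np.full(R, 0.5)
        self.stats = _MoveStats()
        self._chain_acc = np.zeros(R)

    # likelihood ----------------------------------------------------------

    def _durations(self, ages):
        dur = ages[:, np.maximum(self.parent, 0)] - ages
        dur[:, self.tree.root] = 0.0
        return dur

    def _loglik(self, ages, rates):
        if self.counts is None:
            return np.zeros(self.R)
        dur = self._durations(ages)
        if isinstance(self.clock, StrictClock):
            eff = self.jc.rate * dur
        else:
            eff = rates * dur
        lp = jc_mod.pattern_log_probs(self.tree, eff, self.patterns)
        return np.einsum("rp,rp->r", lp, self.counts)

    # moves ---------------------------------------------------------------

    def _age_bounds(self, i):
        v = self.free_nodes[i]
        lo = self.ages[:, self.tree.children[v]].max(axis=1)
        hi = self.ages[:, self.parent[v]]
        return lo, hi

    def _move_age(self, i, loglik):
        v = self.free_nodes[i]
        lo, hi = self._age_bounds(i)
        cur = self.ages[:, v]
        prop = _reflect(cur + self.age_w[:, i] * (2 * self.rng.random(self.R) - 1),
                        lo, hi)
        new_ages = self.ages.copy()
        new_ages[:, v] = prop
        new_ll = self._loglik(new_ages, self.rates)
        d_yule = -self.lam * (prop - cur)
        log_alpha = (new_ll - loglik) + d_yule
        acc = np.log(self.rng.random(self.R)) < log_alpha
        self.ages[acc, v] = prop[acc]
        loglik = np.where(acc, new_ll, loglik)
        self._record("age", i, acc)
        return loglik

    def _move_age_rescale(self, i, loglik):
        """Node slide preserving effective branch lengths.

        The age proposal is paired with a deterministic rescaling of the
        rates on the three adjacent branches so that rate x duration stays
        exactly constant; the likelihood is untouched and mixing along the
        age/rate ridge is governed by the rate prior, not the data.  The
        -log r term of the lognormal prior cancels the Jacobian
        prod(dur_old / dur_new) exactly, leaving the quadratic prior terms
        and the Yule factor.
        """
        v = self.free_nodes[i]
        lo, hi = self._age_bounds(i)
        cur = self.ages[:, v]
        prop = _reflect(cur + self.resc_w[:, i] * (2 * self.rng.random(self.R) - 1),
                        lo, hi)
        p = self.parent[v]
        branches = [v] + list(self.tree.children[v])
        anchors = [self.ages[:, p]] + [self.ages[:, c] for c in self.tree.children[v]]
        mu, sig = self.clock.log_location, self.clock.log_scale
        d = -self.lam * (prop - cur)
        ratios = []
        ok = np.ones(self.R, dtype=bool)
        for b, a in zip(branches, anchors):
            dur_old = np.abs(cur - a)
            dur_new = np.abs(prop - a)
            ok &= dur_new > 1e-12
            rho = np.where(ok, dur_old / np.where(ok, dur_new, 1.0), 1.0)
            ratios.append(rho)
            x = np.log(self.rates[:, b])
            xn = x + np.log(rho)
            # quadratic prior terms; -log r and the Jacobian cancel
            d = d + (-((xn - mu) ** 2) + (x - mu) ** 2) / (2 * sig**2)
        acc = ok & (np.log(self.rng.random(self.R)) < d)
        self.ages[acc, v] = prop[acc]
        for b, rho in zip(branches, ratios):
            self.rates[acc, b] = self.rates[acc, b] * rho[acc]
        self._record("age_rescale", i, acc)
        return loglik

    def _move_rate(self, b, loglik):
        m = np.exp(self.rate_s[:, b] * (2 * self.rng.random(self.R) - 1))
        new_rates = self.rates.copy()
        new_rates[:, b] = self.rates[:, b] * m
        new_ll = self._loglik(self.ages, new_rates)
        mu, sig = self.clock.log_location, self.clock.log_scale
        x, xn = np.log(self.rates[:, b]), np.log(new_rates[:, b])
        d_prior = (-((xn - mu) ** 2) + (x - mu) ** 2) / (2 * sig**2) - (xn - x)
        log_alpha = (new_ll - loglik) + d_prior + np.log(m)
        acc = np.log(self.rng.random(self.R)) < log_alpha
        self.rates[acc, b] = new_rates[acc, b]
        loglik = np.where(acc, new_ll, loglik)
        self._record("rate", b, acc)
        return loglik

    def _yule_term(self, lam):
        return yule_log_density(self.ages[:, self.free_nodes], self.root_age, lam)

    def _move_lam(self, loglik):
        m = np.exp(self.lam_s * (2 * self.rng.random(self.R) - 1))
        new_lam = self.lam * m
        d = (self._yule_term(new_lam) - self._yule_term(self.lam)
             - self.yule.hyper_rate * (new_lam - self.lam) + np.log(m))
        acc = np.log(self.rng.random(self.R)) < d
        self.lam = np.where(acc, new_lam, self.lam)
        self._record("lam", None, acc)
        return loglik

    # bookkeeping ---------------------------------------------------------

    def _record(self, kind, idx, acc):
        self._chain_acc += acc
        self._acc_buf.setdefault((kind, idx), []).append(acc)
        self.stats.add(kind, acc.sum(), acc.size)

    def _adapt(self):
        for (kind, idx), accs in self._acc_buf.items():
            rate = np.mean(accs, axis=0)
            f = np.exp(0.8 * (rate - 0.3))
            if kind == "age":
                self.age_w[:, idx] = np.clip(self.age_w[:, idx] * f, 1e-5,
                                             self.root_age)
            elif kind == "age_rescale":
                self.resc_w[:, idx] = np.clip(self.resc_w[:, idx] * f, 1e-5,
                                              self.root_age)
            elif kind == "rate":
                self.rate_s[:, idx] = np.clip(self.rate_s[:, idx] * f, 1e-4, 3.0)
            elif kind == "lam":
                self.lam_s = np.clip(self.lam_s * f, 1e-3, 3.0)
        self._acc_buf = {}

    def run(self) -> BatchPosterior:
        sched = self.schedule
        n_kept = (sched.iterations - sched.burnin) // sched.thin
        kept_ages = np.empty((self.R, n_kept, self.free_nodes.size))
        kept_lp = np.empty((self.R, n_kept))
        kept_lam = np.empty((self.R, n_kept)) if self.sample_lam else None
        kept_rates = (np.empty((self.R, n_kept, self.branches.size))
                      if self.rates is not None else None)
        self._acc_buf: dict = {}
        failed = np.zeros(self.R, dtype=bool)
        loglik = self._loglik(self.ages, self.rates)
        k = 0
        for it in range(sched.iterations):
            for i in range(self.free_nodes.size):
                loglik = self._move_age(i, loglik)
            if self.sample_rates:
                for i in range(self.free_nodes.size):
                    loglik = self._move_age_rescale(i, loglik)
                for b in self.branches:
                    loglik = self._move_rate(b, loglik)
            if self.sample_lam:
                loglik = self._move_lam(loglik)
            in_burnin = it < sched.burnin
            if in_burnin and (it + 1) % 50 == 0:
                self._adapt()
            if it == sched.burnin - 1:
                failed = self._chain_acc == 0
                if np.any(failed) and self.R == 1:
                    raise MCMCDiagnosticError(
                        "chain accepted no move during burn-in",
                        self.stats.rates())
            if not in_burnin and (it - sched.burnin + 1) % sched.thin == 0:
                if k < n_kept:
                    kept_ages[:, k] = self.ages[:, self.free_nodes]
                    lp = loglik + self._yule_term(self.lam)
                    if self.rates is not None and self.clock.log_scale > 0:
                        lp = lp + np.sum(_lognormal_logpdf(
                            self.rates[:, self.branches],
                            self.clock.log_location,
                            self.clock.log_scale), axis=-1)
                    kept_lp[:, k] = lp
                    if kept_lam is not None:
                        kept_lam[:, k] = self.lam
                    if kept_rates is not None:
                        kept_rates[:, k] = self.rates[:, self.branches]
                    k += 1
        return BatchPosterior(kept_ages, self.free_nodes, kept_lam,
                              kept_lp, self.stats.rates(), kept_rates, failed)


# -- Dirichlet-rate sampler ------------------------------------------------


class _DirichletSampler:
    """Batched MH under the hierarchical Dirichlet rate prior.

    ``counts`` is ``(R, L, P)`` per-locus pattern counts aligned to
    ``patterns``; per-locus branch rates are updated with independent
    vectorized multiplier moves (valid because loci are conditionally
    independent given the shared node ages).
    """

    def __init__(self, tree, counts, patterns, clock: DirichletRateClock,
                 yule, jc_params, schedule, rng):
        self.tree = tree
        self.clock = clock
        self.yule = yule
        self.schedule = schedule
        self.rng = rng
        counts = np.asarray(counts, dtype=np.float64)
        if counts.ndim == 2:
            counts = counts[None]
        self.patterns, self.counts = jc_mod.collapse_jc_equivalent(patterns, counts)
        self.R, self.L = self.counts.shape[:2]
        internal = [v for v in range(tree.n_tips, tree.n_nodes) if v != tree.root]
        self.free_nodes = np.asarray(sorted(internal), dtype=np.int64)
        self.branches = tree.branch_nodes
        self.parent = tree.parent
        self.root_age = tree.root_age

        R, L = self.R, self.L
        self.ages = np.tile(tree.ages, (R, 1))
        self.mubar = np.full(R, np.exp(clock.mean_log_location))
        self.props = np.full((R, L), 1.0 / L)
        self.rates = np.full((R, L, tree.n_nodes), np.exp(clock.mean_log_location))
        if yule.lam is None:
            self.lam = np.full(R, 1.0 / yule.hyper_rate)
            self.sample_lam = True
        else:
            self.lam = np.full(R, yule.lam)
            self.sample_lam = False

        self.age_w = np.full((R, self.free_nodes.size), 0.05)
        self.resc_w = np.full((R, self.free_nodes.size), 0.1)
        self.rate_s = np.full((R, 1), 0.3)
        self.mubar_s = np.full(R, 0.1)
        self.prop_d = np.full(R, 1.0 / L)
        self.lam_s = np.full(R, 0.5)
        self.stats = _MoveStats()
        self._chain_acc = np.zeros(R)

    def _durations(self, ages):
        dur = ages[:, np.maximum(self.parent, 0)] - ages
        dur[:, self.tree.root] = 0.0
        return dur

    def _loglik_loc(self, ages, rates):
        """(R, L) per-locus log likelihoods."""
        eff = rates * self._durations(ages)[:, None, :]
        lp = jc_mod.pattern_log_probs(self.tree, eff, self.patterns)
        return np.einsum("rlp,rlp->rl", lp, self.counts)

    def _locus_loc(self):
        """log locus means log(m_i) = log(mubar * L * p_i), shape (R, L)."""
        return np.log(self.mubar[:, None] * self.L * self.props)

    # moves ---------------------------------------------------------------

    def _record(self, kind, acc_sum, att):
        self.stats.add(kind, acc_sum, att)

    def _move_age(self, i, ll_loc):
        v = self.free_nodes[i]
        lo = self.ages[:, self.tree.children[v]].max(axis=1)
        hi = self.ages[:, self.parent[v]]
        cur = self.ages[:, v]
        prop = _reflect(cur + self.age_w[:, i] * (2 * self.rng.random(self.R) - 1),
                        lo, hi)
        new_ages = self.ages.copy()
        new_ages[:, v] = prop
        new_ll = self._loglik_loc(new_ages, self.rates)
        log_alpha = (new_ll.sum(1) - ll_loc.sum(1)) - self.lam * (prop - cur)
        acc = np.log(self.rng.random(self.R)) < log_alpha
        self.ages[acc, v] = prop[acc]
        ll_loc[acc] = new_ll[acc]
        self._chain_acc += acc
        self._record("age", acc.sum(), acc.size)
        self._age_acc.append(acc)
        return ll_loc

    def _move_age_rescale(self, i, ll_loc):
        """Node slide preserving every locus's effective branch lengths.

        As in the shared-rate sampler, the rates of the three adjacent
        branches are rescaled at every locus so the likelihood is untouched;
        the -log r prior terms cancel the Jacobian (duration ratio per locus
        per branch), leaving quadratic prior terms summed over loci.
        """
        v = self.free_nodes[i]
        lo = self.ages[:, self.tree.children[v]].max(axis=1)
        hi = self.ages[:, self.parent[v]]
        cur = self.ages[:, v]
        prop = _reflect(cur + self.resc_w[:, i] * (2 * self.rng.random(self.R) - 1),
                        lo, hi)
        branches = [v] + list(self.tree.children[v])
        anchors = [hi] + [self.ages[:, c] for c in self.tree.children[v]]
        sig = self.clock.branch_log_scale
        loc = self._locus_loc()  # (R, L)
        d = -self.lam * (prop - cur)
        ratios = []
        ok = np.ones(self.R, dtype=bool)
        for b, a in zip(branches, anchors):
            dur_old = np.abs(cur - a)
            dur_new = np.abs(prop - a)
            ok &= dur_new > 1e-12
            rho = np.where(ok, dur_old / np.where(ok, dur_new, 1.0), 1.0)
            ratios.append(rho)
            x = np.log(self.rates[:, :, b])  # (R, L)
            xn = x + np.log(rho)[:, None]
            d = d + np.sum(-((xn - loc) ** 2) + (x - loc) ** 2, axis=1) / (2 * sig**2)
        acc = ok & (np.log(self.rng.random(self.R)) < d)
        self.ages[acc, v] = prop[acc]
        for b, rho in zip(branches, ratios):
            self.rates[acc, :, b] = self.rates[acc, :, b] * rho[acc, None]
        self._chain_acc += acc
        self._record("age_rescale", acc.sum(), acc.size)
        self._resc_acc.append(acc)
        return ll_loc

    def _move_rates(self, b, ll_loc):
        """Multiplier move on branch b of every locus, accepted per (R, L)."""
        sig = self.clock.branch_log_scale
        m = np.exp(self.rate_s * (2 * self.rng.random((self.R, self.L)) - 1))
        new_rates = self.rates.copy()
        new_rates[:, :, b] = self.rates[:, :, b] * m
        new_ll = self._loglik_loc(self.ages, new_rates)
        loc = self._locus_loc()
        x, xn = np.log(self.rates[:, :, b]), np.log(new_rates[:, :, b])
        d_prior = (-((xn - loc) ** 2) + (x - loc) ** 2) / (2 * sig**2) - (xn - x)
        log_alpha = (new_ll - ll_loc) + d_prior + np.log(m)
        acc = np.log(self.rng.random((self.R, self.L))) < log_alpha
        self.rates[:, :, b] = np.where(acc, new_rates[:, :, b], self.rates[:, :, b])
        ll_loc = np.where(acc, new_ll, ll_loc)
        self._chain_acc += acc.any(axis=1)
        self._record("rate", acc.sum(), acc.size)
        self._rate_acc.append(acc.mean(axis=1))
        return ll_loc

    def _move_mubar(self):
        """Scale mubar; changes the location of every branch-rate prior."""
        sig = self.clock.branch_log_scale
        m = np.exp(self.mubar_s * (2 * self.rng.random(self.R) - 1))
        delta = np.log(m)
        x = np.log(self.rates[:, :, self.branches])
        loc = self._locus_loc()[:, :, None]
        d_rates = np.sum((-((x - loc - delta[:, None, None]) ** 2)
                          + (x - loc) ** 2), axis=(1, 2)) / (2 * sig**2)
        mu0, s0 = self.clock.mean_log_location, self.clock.mean_log_scale
        y, yn = np.log(self.mubar), np.log(self.mubar * m)
        d_hyper = (-((yn - mu0) ** 2) + (y - mu0) ** 2) / (2 * s0**2) - (yn - y)
        acc = np.log(self.rng.random(self.R)) < d_rates + d_hyper + delta
        self.mubar = np.where(acc, self.mubar * m, self.mubar)
        self._chain_acc += acc
        self._record("mubar", acc.sum(), acc.size)
        self._mubar_acc.append(acc)

    def _move_props(self):
        """Disjoint pair-exchange moves on the Dirichlet proportions."""
        sig = self.clock.branch_log_scale
        a = self.clock.concentration
        perm = self.rng.permutation(self.L)
        n_pairs = self.L // 2
        i, j = perm[:n_pairs], perm[n_pairs : 2 * n_pairs]
        delta = self.prop_d[:, None] * (2 * self.rng.random((self.R, n_pairs)) - 1)
        pi, pj = self.props[:, i], self.props[:, j]
        pin, pjn = pi + delta, pj - delta
        valid = (pin > 0) & (pjn > 0)
        x_i = np.log(self.rates[:, i][:, :, self.branches])
        x_j = np.log(self.rates[:, j][:, :, self.branches])
        base = np.log(self.mubar[:, None] * self.L)

        def quad(x, p):
            loc = (base[:, :, None] + np.log(p)[:, :, None])
            return -np.sum((x - loc) ** 2, axis=2) / (2 * sig**2)

        d = (quad(x_i, np.where(valid, pin, pi)) - quad(x_i, pi)
             + quad(x_j, np.where(valid, pjn, pj)) - quad(x_j, pj))
        if a != 1.0:
            d = d + (a - 1.0) * (np.log(np.where(valid, pin, pi)) - np.log(pi)
                                 + np.log(np.where(valid, pjn, pj)) - np.log(pj))
        acc = valid & (np.log(self.rng.random((self.R, n_pairs))) < d)
        rows = np.arange(self.R)[:, None]
        self.props[rows, i] = np.where(acc, pin, pi)
        self.props[rows, j] = np.where(acc, pjn, pj)
        self._chain_acc += acc.any(axis=1)
        self._record("props", acc.sum(), acc.size)
        self._prop_acc.append(acc.mean(axis=1))

    def _yule_term(self, lam):
        return yule_log_density(self.ages[:, self.free_nodes], self.root_age, lam)

    def _move_lam(self):
        m = np.exp(self.lam_s * (2 * self.rng.random(self.R) - 1))
        new_lam = self.lam * m
        d = (self._yule_term(new_lam) - self._yule_term(self.lam)
             - self.yule.hyper_rate * (new_lam - self.lam) + np.log(m))
        acc = np.log(self.rng.random(self.R)) < d
        self.lam = np.where(acc, new_lam, self.lam)
        self._chain_acc += acc
        self._record("lam", acc.sum(), acc.size)

    def run(self) -> BatchPosterior:
        sched = self.schedule
        n_kept = (sched.iterations - sched.burnin) // sched.thin
        kept_ages = np.empty((self.R, n_kept, self.free_nodes.size))
        kept_lp = np.empty((self.R, n_kept))
        kept_lam = np.empty((self.R, n_kept)) if self.sample_lam else None
        self._age_acc: list = []
        self._resc_acc: list = []
        self._rate_acc: list = []
        self._mubar_acc: list = []
        self._prop_acc: list = []
        failed = np.zeros(self.R, dtype=bool)
        ll_loc = self._loglik_loc(self.ages, self.rates)
        k = 0
        for it in range(sched.iterations):
            for i in range(self.free_nodes.size):
                ll_loc = self._move_age(i, ll_loc)
                ll_loc = self._move_age_rescale(i, ll_loc)
            for b in self.branches:
                ll_loc = self._move_rates(b, ll_loc)
            self._move_mubar()
            self._move_props()
            if self.sample_lam:
                self._move_lam()
            in_burnin = it < sched.burnin
            if in_burnin and (it + 1) % 50 == 0:
                self._adapt()
            if it == sched.burnin - 1:
                failed = self._chain_acc == 0
                if np.any(failed) and self.R == 1:
                    raise MCMCDiagnosticError(
                        "chain accepted no move during burn-in",
                        self.stats.rates())
            if not in_burnin and (it - sched.burnin + 1) % sched.thin == 0:
                if k < n_kept:
                    kept_ages[:, k] = self.ages[:, self.free_nodes]
                    kept_lp[:, k] = ll_loc.sum(1) + self._yule_term(self.lam)
                    if kept_lam is not None:
                        kept_lam[:, k] = self.lam
                    k += 1
        return BatchPosterior(kept_ages, self.free_nodes, kept_lam,
                              kept_lp, self.stats.rates(), None, failed)

    def _adapt(self):
        def factor(accs):
            return np.exp(0.8 * (np.mean(accs, axis=0) - 0.3))

        if self._age_acc:
            self.age_w = np.clip(
                self.age_w * factor(self._age_acc)[:, None], 1e-5, self.root_age)
        if self._resc_acc:
            self.resc_w = np.clip(
                self.resc_w * factor(self._resc_acc)[:, None], 1e-5, self.root_age)
        if self._rate_acc:
            self.rate_s = np.clip(
                self.rate_s * factor(self._rate_acc)[:, None], 1e-4, 3.0)
        if self._mubar_acc:
            self.mubar_s = np.clip(self.mubar_s * factor(self._mubar_acc),
                                   1e-4, 3.0)
        if self._prop_acc:
            self.prop_d = np.clip(self.prop_d * factor(self._prop_acc),
                                  1e-3 / self.L, 0.5)
        self._age_acc, self._rate_acc = [], []
        self._resc_acc = []
        self._mubar_acc, self._prop_acc = [], []


# -- public entry points ---------------------------------------------------


def _pool_counts(data) -> PatternCounts:
    if isinstance(data, PatternCounts):
        return data
    pooled = data[0]
    for c in data[1:]:
        pooled = pooled.pooled_with(c)
    return pooled


def run_mcmc(data, tree: TimeTree, clock, yule: YulePrior,
             jc_params: jc_mod.JCParams = jc_mod.JCParams(),
             schedule: MCMCSchedule = MCMCSchedule(),
             seed: int = 0) -> PosteriorTrace:
    """Run one MH chain over node ages (and rates) on a fixed topology.

    ``data`` is a :class:`PatternCounts`, a list of per-locus
    :class:`PatternCounts`, or ``None`` for a prior-only run.  Under strict
    and UCLN clocks (rates shared across loci) per-locus data are pooled into
    concatenated pattern counts, which leaves the likelihood unchanged.  The
    root age is fixed at the input tree's root age and the topology is never
    altered.  Identical seeds give identical traces.
    """
    rng = np.random.default_rng(seed)
    if isinstance(clock, DirichletRateClock):
        if data is None:
            raise ValueError("prior-only Dirichlet runs are not supported")
        counts_list = [data] if isinstance(data, PatternCounts) else list(data)
        for c in counts_list:
            jc_mod._check_taxa(c.taxa, tree)
        pats = counts_list[0].patterns
        full = jc_mod.pattern_matrix(tree.n_tips)
        # align every locus onto the full pattern table
        idx = {tuple(p): i for i, p in enumerate(full)}
        arr = np.zeros((1, len(counts_list), full.shape[0]))
        for l, c in enumerate(counts_list):
            for p, n in zip(c.patterns, c.counts):
                arr[0, l, idx[tuple(p)]] = n
        sampler = _DirichletSampler(tree, arr, full, clock, yule, jc_params,
                                    schedule, rng)
        return sampler.run().chain(0)
    if data is None:
        sampler = _SharedRateSampler(tree, None, None, clock, yule, jc_params,
                                     schedule, rng, n_chains=1)
    else:
        pooled = _pool_counts(data)
        jc_mod._check_taxa(pooled.taxa, tree)
        sampler = _SharedRateSampler(tree, pooled.counts[None, :],
                                     pooled.patterns, clock, yule, jc_params,
                                     schedule, rng)
    return sampler.run().chain(0)


def run_mcmc_batch(counts, patterns, tree, clock, yule,
                   jc_params=jc_mod.JCParams(), schedule=MCMCSchedule(),
                   seed: int = 0, per_locus: bool = False) -> BatchPosterior:
    """Run ``R`` replicate chains in lockstep.

    For strict/UCLN clocks ``counts`` is ``(R, P)`` pooled pattern counts; for
    the Dirichlet clock (``per_locus=True``) it is ``(R, L, P)`` per-locus
    counts.  ``patterns`` is the shared ``(P, n_tips)`` pattern table.
    """
    rng = np.random.default_rng(seed)
    if isinstance(clock, DirichletRateClock) or per_locus:
        sampler = _DirichletSampler(tree, counts, patterns, clock, yule,
                                    jc_params, schedule, rng)
    else:
        sampler = _SharedRateSampler(tree, counts, patterns, clock, yule,
                                     jc_params, schedule, rng)
    return sampler.run()
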