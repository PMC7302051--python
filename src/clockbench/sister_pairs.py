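"""Sister-pair branch-length fold differences on a phylogram.

Two terminal taxa forming a cherry diverged at the same moment, so their
terminal branch durations are identical and any difference in their terminal
branch lengths on a phylogram (substitutions/site) reflects a difference in
substitution rate.  The per-pair statistic is the fold difference
``max(lenA, lenB) / min(lenA, lenB)``; its mean over all cherries measures
the magnitude of lineage-specific rate variation in the tree.

For rates i.i.d. lognormal with log-scale ``sigma`` the expected fold is
available in closed form (the location parameter cancels in the ratio):

    E[max(R1, R2) / min(R1, R2)] = 2 * exp(sigma^2) * Phi(sigma * sqrt(2)),

which benchmarks an empirical mean fold against a simulated rate regime.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.stats import norm

from .trees import LognormalSpec, apply_lineage_rates, simulate_yule_tree

__all__ = [
    "SisterPair",
    "extract_sister_pairs",
    "mean_fold",
    "expected_fold_lognormal",
    "synthetic_phylogram",
]


@dataclass(frozen=True)
class SisterPair:
    """A cherry: two terminal taxa with their phylogram branch lengths."""

    tip_a: str
    tip_b: str
    len_a: float
    len_b: float

    @property
    def fold(self) -> float:
        return max(self.len_a, self.len_b) / min(self.len_a, self.len_b)


def _as_dendropy(tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return dendropy.Tree.get(data=str(tree), schema="newick",
                             preserve_underscores=True)


def extract_sister_pairs(tree) -> list[SisterPair]:
    """All tip-tip cherries of a phylogram (dendropy tree or Newick string).

    Only internal nodes whose two children are both tips qualify; a cherry
    with a zero-length terminal branch has an undefined fold and is excluded
    with a warning.  Output order follows a fixed preorder traversal, so it
    is invariant to ladderization.
    """
    t = _as_dendropy(tree)
    pairs = []
    for node in t.preorder_node_iter():
        kids = node.child_nodes()
        if len(kids) == 2 and all(k.is_leaf() for k in kids):
            (a, b) = sorted(kids, key=lambda k: k.taxon.label)
            la = a.edge.length or 0.0
            lb = b.edge.length or 0.0
            if la <= 0 or lb <= 0:
                warnings.warn(
                    f"cherry ({a.taxon.label},{b.taxon.label}) has a "
                    "zero-length terminal branch; fold undefined, excluded")
                continue
            pairs.append(SisterPair(a.taxon.label, b.taxon.label, la, lb))
    return pairs


def mean_fold(pairs) -> float:
    """Arithmetic mean of sister-pair fold differences."""
    if not pairs:
        raise ValueError("no valid sister pairs")
    return float(np.mean([p.fold for p in pairs]))


def expected_fold_lognormal(sigma: float) -> float:
    """Expected fold between two i.i.d. lognormal rates with log-scale sigma."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    return float(2.0 * math.exp(sigma**2) * norm.cdf(sigma * math.sqrt(2.0)))


def synthetic_phylogram(n_taxa: int, sigma: float, rng,
                        lam: float = 1.0, base_rate: float = 0.05) -> dendropy.Tree:
    """A stand-in phylogram: Yule chronogram with lognormal lineage rates.

    Branch lengths are duration x rate with rates lognormal(log(base_rate),
    sigma), emulating a concatenated species tree shaped purely by
    lineage-specific rate variation.
    """
    tree = simulate_yule_tree(n_taxa, lam, rng)
    rated = apply_lineage_rates(tree, LognormalSpec(math.log(base_rate), sigma), rng)
    return rated.tree.to_dendropy(rated.branch_lengths)
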