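"""Exact Jukes-Cantor likelihood of site-pattern counts on a rooted tree.

The likelihood is computed by Felsenstein pruning, vectorized both over site
patterns and over an arbitrary batch of branch-length vectors (the batch axis
is what makes hundreds of replicate MCMC chains cheap to run in lockstep).
Under JC the per-branch transition matrix has only two distinct entries,

    p_same(v) = 1/4 + 3/4 exp(-4v/3),    p_diff(v) = 1/4 - 1/4 exp(-4v/3),

for effective branch length ``v`` in expected substitutions per site, so the
message a child passes to its parent reduces to a rank-one update and no 4x4
matrix products are needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "JCParams",
    "jc_transition",
    "pattern_matrix",
    "pattern_log_probs",
    "log_likelihood",
    "multi_locus_log_likelihood",
    "collapse_jc_equivalent",
]

#: largest exp argument we allow; beyond this the transition is stationary
_EFFLEN_CLIP = 700.0


@dataclass(frozen=True)
class JCParams:
    """Base substitution rate (expected substitutions/site per unit branch length)."""

    rate: float = 0.05

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be > 0")


def jc_transition(eff_len):
    """JC transition probabilities ``(p_same, p_diff)`` for a branch.

    ``eff_len`` may be a scalar or array of expected substitutions per site;
    negative values raise.  ``p_same + 3 * p_diff == 1`` identically.
    """
    eff_len = np.asarray(eff_len, dtype=np.float64)
    if np.any(eff_len < 0):
        raise ValueError("effective branch length must be >= 0")
    e = np.exp(-(4.0 / 3.0) * np.minimum(eff_len, _EFFLEN_CLIP))
    return 0.25 + 0.75 * e, 0.25 - 0.25 * e


def pattern_matrix(n_taxa: int) -> np.ndarray:
    """All ``4**n_taxa`` site patterns, lexicographic, as a ``(4^n, n)`` array.

    States are encoded 0..3 = A, C, G, T.
    """
    idx = np.arange(4**n_taxa)
    cols = [(idx // 4 ** (n_taxa - 1 - j)) % 4 for j in range(n_taxa)]
    return np.stack(cols, axis=1).astype(np.uint8)


def _check_taxa(taxa, tree) -> None:
    if list(taxa) != list(tree.labels):
        raise ValueError(
            f"pattern taxa {list(taxa)} do not match tree tips {list(tree.labels)}"
        )


def pattern_log_probs(tree, eff_lens, patterns) -> np.ndarray:
    """Log probability of each site pattern under JC with uniform root states.

    Parameters
    ----------
    tree : TimeTree (supplies topology; ages are ignored).
    eff_lens : array ``(..., n_nodes)`` of effective branch lengths indexed by
        child node id; leading axes are a batch over independent length sets.
    patterns : ``(P, n_tips)`` integer array of states 0..3, columns in tip
        node order.

    Returns ``(..., P)`` log probabilities.
    """
    eff_lens = np.asarray(eff_lens, dtype=np.float64)
    patterns = np.asarray(patterns)
    batch = eff_lens.shape[:-1]
    P = patterns.shape[0]
    p_same, p_diff = jc_transition(eff_lens)  # (..., n_nodes)
    eye = np.eye(4)
    partial = {}
    for v in tree.postorder:
        if not tree.children[v]:
            continue
        msg_prod = np.ones(batch + (P, 4))
        for c in tree.children[v]:
            ps = p_same[..., c][..., None, None]
            pd = p_diff[..., c][..., None, None]
            if not tree.children[c]:  # tip: message is a row of the P matrix
                onehot = eye[patterns[:, c]]  # (P, 4)
                msg = pd + (ps - pd) * onehot
            else:
                part = partial.pop(c)  # (..., P, 4)
                tot = part.sum(axis=-1, keepdims=True)
                msg = pd * tot + (ps - pd) * part
            msg_prod = msg_prod * msg
        partial[v] = msg_prod
    probs = partial[tree.root].sum(axis=-1) * 0.25  # uniform root frequencies
    with np.errstate(divide="ignore"):
        return np.log(np.maximum(probs, 0.0))


def log_likelihood(counts, tree, eff_lens) -> np.ndarray:
    """JC log likelihood of compressed pattern counts on ``tree``.

    ``counts`` is a :class:`~clockbench.seqsim.PatternCounts` (its taxa must
    match the tree tip labels); ``eff_lens`` as in :func:`pattern_log_probs`
    (a batch axis gives a batch of log likelihoods).
    """
    _check_taxa(counts.taxa, tree)
    lp = pattern_log_probs(tree, eff_lens, counts.patterns)
    return lp @ np.asarray(counts.counts, dtype=np.float64)


def multi_locus_log_likelihood(per_locus_counts, tree, per_locus_lens) -> float:
    """Sum of independent per-locus JC log likelihoods.

    When all loci share identical branch lengths this equals the likelihood of
    the pooled (concatenated) pattern counts.
    """
    if len(per_locus_counts) != len(per_locus_lens):
        raise ValueError("one branch-length vector required per locus")
    total = 0.0
    for counts, lens in zip(per_locus_counts, per_locus_lens):
        total += float(log_likelihood(counts, tree, lens))
    return total


def collapse_jc_equivalent(patterns, counts):
    """Pool site patterns that are probability-equivalent under JC.

    JC is fully symmetric in the four states, so a pattern's probability
    depends only on which taxa share a state, not on the states themselves.
    Relabeling states by order of first appearance canonicalizes each pattern;
    pooling counts over canonical patterns leaves any JC log likelihood
    unchanged while shrinking the pattern table (e.g. 64 -> 5 for 3 taxa).

    Returns ``(canonical_patterns (Q, n), pooled_counts (..., Q))`` where a
    leading batch axis on ``counts`` is preserved.
    """
    patterns = np.asarray(patterns)
    counts = np.asarray(counts, dtype=np.float64)
    P, n = patterns.shape
    canon = np.empty_like(patterns)
    for i in range(P):
        seen: dict[int, int] = {}
        for j in range(n):
            s = int(patterns[i, j])
            canon[i, j] = seen.setdefault(s, len(seen))
    uniq, inverse = np.unique(canon, axis=0, return_inverse=True)
    pooled = np.zeros(counts.shape[:-1] + (uniq.shape[0],))
    for q in range(uniq.shape[0]):
        pooled[..., q] = counts[..., inverse == q].sum(axis=-1)
    return uniq, pooled
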