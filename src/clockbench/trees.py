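"""Time trees, Yule simulation, and the three classes of branch-rate variation.

A :class:`TimeTree` is an ultrametric chronogram: tips at age 0, internal
nodes at positive ages, branch durations measured in the same time units as
the root age.  Rate variation is overlaid on a chronogram to produce per-locus
:class:`RatedTree` objects whose branch lengths are the product of the time
duration and every rate multiplier applied to that branch:

* **lineage-specific** rates -- one multiplier per branch, shared by every
  locus in the genome;
* **gene-specific** rates -- one multiplier per locus, shared by every branch
  of that locus;
* **residual** rates -- an independent multiplier per branch *and* per locus,
  so the pattern of among-branch variation averages out across many loci.

Multipliers are drawn from a lognormal distribution parameterized on the log
scale (location ``mu``, scale ``sigma``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np

__all__ = [
    "LognormalSpec",
    "TimeTree",
    "RatedTree",
    "RateClassConfig",
    "make_three_taxon_tree",
    "simulate_yule_tree",
    "simulate_yule_tree_conditioned",
    "apply_lineage_rates",
    "apply_gene_rate",
    "apply_residual_rates",
    "generate_gene_trees",
]


@dataclass(frozen=True)
class LognormalSpec:
    """Log-scale location/scale of a lognormal rate-multiplier distribution.

    ``sigma == 0`` degenerates to the point mass at ``exp(mu)``.
    """

    mu: float = -0.01
    sigma: float = 0.15

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def draw(self, rng: np.random.Generator, size) -> np.ndarray:
        if self.sigma == 0.0:
            # consume draws anyway so the rng stream does not depend on sigma
            rng.standard_normal(size)
            return np.full(size, np.exp(self.mu))
        return np.exp(self.mu + self.sigma * rng.standard_normal(size))

    @property
    def mean(self) -> float:
        """Expected multiplier exp(mu + sigma^2 / 2)."""
        return float(np.exp(self.mu + self.sigma**2 / 2.0))


class TimeTree:
    """Rooted binary ultrametric tree stored in flat arrays.

    Nodes are indexed ``0 .. n_nodes-1`` with tips first (``0 .. n_tips-1``).
    Every non-root node identifies the branch to its parent, so branch arrays
    are indexed by child node id.

    Parameters
    ----------
    labels : tip labels, one per tip, in tip-index order.
    parent : integer parent index per node, ``-1`` at the root.
    ages : node age per node (time before present); tips must be at 0.
    """

    def __init__(self, labels, parent, ages):
        self.labels = list(labels)
        self.parent = np.asarray(parent, dtype=np.int64)
        self.ages = np.asarray(ages, dtype=np.float64)
        n = self.parent.size
        if self.ages.size != n:
            raise ValueError("parent and ages must have equal length")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise ValueError("tree must have exactly one root")
        self.root = int(roots[0])
        self.n_tips = len(self.labels)
        self.n_nodes = n
        self.children: list[list[int]] = [[] for _ in range(n)]
        for v in range(n):
            p = self.parent[v]
            if p >= 0:
                self.children[p].append(v)
        for v in range(self.n_tips):
            if self.children[v]:
                raise ValueError("tips must be the first n_tips node indices")
        self._validate()
        self.postorder = self._postorder()

    def _validate(self) -> None:
        if np.any(np.abs(self.ages[: self.n_tips]) > 1e-12):
            raise ValueError("tips must all be at age 0 (ultrametric tree)")
        for v in range(self.n_nodes):
            p = self.parent[v]
            if p >= 0 and not self.ages[p] > self.ages[v]:
                raise ValueError("every parent age must exceed its child age")

    def _postorder(self) -> np.ndarray:
        order: list[int] = []
        stack = [(self.root, False)]
        while stack:
            v, done = stack.pop()
            if done:
                order.append(v)
            else:
                stack.append((v, True))
                # push children reversed so the left child is visited first
                for c in reversed(self.children[v]):
                    stack.append((c, False))
        return np.asarray(order, dtype=np.int64)

    @property
    def root_age(self) -> float:
        return float(self.ages[self.root])

    @property
    def branch_nodes(self) -> np.ndarray:
        """Child node id of each branch, in deterministic post-order."""
        return self.postorder[self.postorder != self.root]

    def branch_durations(self) -> np.ndarray:
        """Time duration of every branch, indexed by child node (root slot 0)."""
        dur = np.zeros(self.n_nodes)
        nz = self.parent >= 0
        dur[nz] = self.ages[self.parent[nz]] - self.ages[nz]
        return dur

    def with_ages(self, ages) -> "TimeTree":
        return TimeTree(self.labels, self.parent, ages)

    # -- Newick interoperability ------------------------------------------

    def to_dendropy(self, branch_lengths=None) -> dendropy.Tree:
        """Convert to a dendropy tree; default branch lengths are durations."""
        if branch_lengths is None:
            branch_lengths = self.branch_durations()
        taxon_ns = dendropy.TaxonNamespace(self.labels)
        nodes = [dendropy.Node() for _ in range(self.n_nodes)]
        for i, lab in enumerate(self.labels):
            nodes[i].taxon = taxon_ns.get_taxon(lab)
        for v in range(self.n_nodes):
            for c in self.children[v]:
                nodes[v].add_child(nodes[c])
                nodes[c].edge.length = float(branch_lengths[c])
        tree = dendropy.Tree(taxon_namespace=taxon_ns)
        tree.seed_node = nodes[self.root]
        tree.is_rooted = True
        return tree

    def to_newick(self, branch_lengths=None) -> str:
        tree = self.to_dendropy(branch_lengths)
        return tree.as_string(schema="newick", suppress_rooting=False).strip()

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree, tol: float = 1e-6) -> "TimeTree":
        """Build a TimeTree from an ultrametric dendropy tree.

        Edge lengths are read as time durations; node ages are recovered from
        root-to-node depths and tips are snapped to age 0 (depth differences
        beyond ``tol`` raise).
        """
        nodes = list(tree.preorder_node_iter())
        depths = {}
        for nd in nodes:
            p = nd.parent_node
            depths[nd] = (depths[p] + (nd.edge.length or 0.0)) if p else 0.0
        height = max(depths[nd] for nd in nodes if nd.is_leaf())
        tips = [nd for nd in nodes if nd.is_leaf()]
        internals = [nd for nd in nodes if not nd.is_leaf()]
        for nd in tips:
            if abs(depths[nd] - height) > tol * max(height, 1.0):
                raise ValueError("tree is not ultrametric")
        index = {nd: i for i, nd in enumerate(tips)}
        index.update({nd: len(tips) + j for j, nd in enumerate(reversed(internals))})
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        ages = np.zeros(n)
        for nd in nodes:
            i = index[nd]
            ages[i] = 0.0 if nd.is_leaf() else height - depths[nd]
            if nd.parent_node is not None:
                parent[i] = index[nd.parent_node]
        labels = [t.taxon.label for t in tips]
        return cls(labels, parent, ages)

    @classmethod
    def from_newick(cls, source: str) -> "TimeTree":
        """Parse a rooted ultrametric Newick string or file path."""
        import os

        kwargs = {"path": source} if os.path.exists(source) else {"data": source}
        tree = dendropy.Tree.get(schema="newick", preserve_underscores=True,
                                 **kwargs)
        return cls.from_dendropy(tree)


@dataclass
class RatedTree:
    """A locus tree: the chronogram topology with rate-scaled branch lengths.

    ``branch_lengths[v]`` is duration x (product of rate multipliers) for the
    branch above node ``v``; the root slot is 0.  With no rate variation the
    branch lengths equal the time durations exactly.
    """

    tree: TimeTree
    branch_lengths: np.ndarray
    locus_id: int | None = None

    def __post_init__(self) -> None:
        self.branch_lengths = np.asarray(self.branch_lengths, dtype=np.float64)
        if self.branch_lengths.shape != (self.tree.n_nodes,):
            raise ValueError("branch_lengths must have one entry per node")
        nonroot = np.arange(self.tree.n_nodes) != self.tree.root
        if np.any(self.branch_lengths[nonroot] <= 0):
            raise ValueError("branch lengths must be positive")

    def to_newick(self) -> str:
        return self.tree.to_newick(self.branch_lengths)


@dataclass(frozen=True)
class RateClassConfig:
    """Which rate classes to simulate, and how many loci."""

    lineage: LognormalSpec | None = None
    gene: LognormalSpec | None = None
    residual: LognormalSpec | None = None
    n_loci: int = 1

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")


def make_three_taxon_tree() -> TimeTree:
    """The fixed three-taxon chronogram ((A,B),C): root age 1.0, node age 0.5.

    Four branches carry rates: the two cherry tips (duration 0.5 each), the
    internal branch (0.5), and the outgroup branch C (1.0).
    """
    labels = ["A", "B", "C"]
    parent = [3, 3, 4, 4, -1]
    ages = [0.0, 0.0, 0.0, 0.5, 1.0]
    return TimeTree(labels, parent, ages)


def simulate_yule_tree(n_taxa: int, lam: float, rng: np.random.Generator) -> TimeTree:
    """Simulate a pure-birth (Yule) tree conditioned on ``n_taxa`` extant tips.

    While ``k`` lineages exist the waiting time to the next speciation is
    exponential with rate ``k * lam`` and the splitting lineage is uniform.
    After the split creating the ``n``-th lineage, one further Exp(n*lam)
    waiting time is appended before the present, so the youngest divergence
    has strictly positive age.  The root age is random (unconditioned).
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if lam <= 0:
        raise ValueError("lam must be > 0")
    # event times measured forward from the root at time 0
    split_times = [0.0]
    t = 0.0
    for k in range(2, n_taxa):
        t += rng.exponential(1.0 / (k * lam))
        split_times.append(t)
    present = t + rng.exponential(1.0 / (n_taxa * lam))

    n_nodes = 2 * n_taxa - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    ages = np.zeros(n_nodes)
    root = n_nodes - 1
    ages[root] = present - split_times[0]
    # each alive lineage is a slot holding the node id it descends from;
    # splits attach a new internal node, the present attaches the tips
    parent_slot = [root, root]
    internal_pool = list(range(n_nodes - 2, n_taxa - 1, -1))  # below the root
    for s in split_times[1:]:
        i = rng.integers(len(parent_slot))
        node = internal_pool.pop(0)
        ages[node] = present - s
        parent[node] = parent_slot[i]
        parent_slot[i] = node
        parent_slot.append(node)
    for tip, p in enumerate(parent_slot):
        parent[tip] = p
    labels = [f"t{i + 1}" for i in range(n_taxa)]
    return TimeTree(labels, parent, ages)


def simulate_yule_tree_conditioned(n_taxa: int, lam: float,
                                   rng: np.random.Generator) -> TimeTree:
    """Yule tree conditioned on ``n_taxa`` tips with a random root age.

    Samples from the conditioned reconstructed pure-birth process (a uniform
    prior on the time of origin, as in TreeSim-style simulators): the root
    age ``T`` has density ``(n-1) lam exp(-lam T)(1 - exp(-lam T))^(n-2)``;
    the other ``n-2`` node ages are i.i.d. ``lam exp(-lam a)/(1-exp(-lam T))``
    on ``(0, T)``; the ranked topology is built by splitting a uniformly
    chosen lineage at each age.  Complements :func:`simulate_yule_tree`,
    which runs the forward process with exponential waiting times.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if lam <= 0:
        raise ValueError("lam must be > 0")
    root_age = -np.log1p(-rng.random() ** (1.0 / (n_taxa - 1))) / lam
    z = 1.0 - np.exp(-lam * root_age)
    inner = -np.log1p(-rng.random(n_taxa - 2) * z) / lam
    ages_sorted = np.concatenate([[root_age], np.sort(inner)[::-1]])

    n_nodes = 2 * n_taxa - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    ages = np.zeros(n_nodes)
    root = n_nodes - 1
    ages[root] = root_age
    parent_slot = [root, root]
    internal_pool = list(range(n_nodes - 2, n_taxa - 1, -1))
    for a in ages_sorted[1:]:
        i = rng.integers(len(parent_slot))
        node = internal_pool.pop(0)
        ages[node] = a
        parent[node] = parent_slot[i]
        parent_slot[i] = node
        parent_slot.append(node)
    for tip, p in enumerate(parent_slot):
        parent[tip] = p
    labels = [f"t{i + 1}" for i in range(n_taxa)]
    return TimeTree(labels, parent, ages)


def _branch_draws(tree: TimeTree, spec: LognormalSpec, rng) -> np.ndarray:
    """One multiplier per branch, drawn in pinned post-order."""
    mult = np.ones(tree.n_nodes)
    order = tree.branch_nodes
    mult[order] = spec.draw(rng, order.size)
    return mult


def apply_lineage_rates(tree: TimeTree, spec: LognormalSpec, rng) -> RatedTree:
    """Scale each branch duration by an independent lineage-specific rate.

    The result is the rated species tree that every locus inherits; draws are
    consumed in deterministic post-order (one per branch, root excluded).
    """
    mult = _branch_draws(tree, spec, rng)
    lengths = tree.branch_durations() * mult
    return RatedTree(tree, lengths)


def apply_gene_rate(gene_tree: RatedTree, spec: LognormalSpec, rng) -> RatedTree:
    """Scale every branch of one locus tree by a single gene-specific rate."""
    g = float(spec.draw(rng, ()))
    return replace(gene_tree, branch_lengths=gene_tree.branch_lengths * g)


def apply_residual_rates(gene_tree: RatedTree, spec: LognormalSpec, rng) -> RatedTree:
    """Scale each branch of one locus tree by an independent residual rate."""
    mult = _branch_draws(gene_tree.tree, spec, rng)
    return replace(gene_tree, branch_lengths=gene_tree.branch_lengths * mult)


def generate_gene_trees(
    tree: TimeTree, config: RateClassConfig, rng: np.random.Generator
) -> list[RatedTree]:
    """Produce ``n_loci`` rated gene trees under the configured rate classes.

    Composition order: lineage-specific rates are applied once to the species
    tree; every locus starts as a copy of that rated tree; then per locus (in
    index order) a gene-specific rate and residual rates are applied.  Omitted
    classes contribute a multiplier of 1.
    """
    if config.lineage is not None:
        base = apply_lineage_rates(tree, config.lineage, rng)
    else:
        base = RatedTree(tree, tree.branch_durations())
    loci = []
    for i in range(config.n_loci):
        gt = replace(base, locus_id=i)
        if config.gene is not None:
            gt = apply_gene_rate(gt, config.gene, rng)
        if config.residual is not None:
            gt = apply_residual_rates(gt, config.residual, rng)
        loci.append(gt)
    return loci
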