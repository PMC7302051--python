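"""JC sequence simulation along rated trees, and site-pattern compression.

Two distributionally identical simulation routes are provided:

* :func:`simulate_alignment` evolves explicit nucleotide sequences branch by
  branch (root states uniform, per-site JC transitions), returning an
  :class:`Alignment`;
* :func:`simulate_pattern_counts` draws the compressed site-pattern count
  table directly from a multinomial over the exact JC pattern probabilities.
  Since unlinked sites are i.i.d. across patterns, this is the same sampling
  distribution as simulate-then-compress, and it is the fast path used for
  large replicate batches.

The effective branch length fed to JC is ``base_rate x branch_length`` where
``branch_length`` already carries the time duration and all rate multipliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import jc
from .trees import RatedTree

__all__ = [
    "Alignment",
    "PatternCounts",
    "simulate_alignment",
    "simulate_pattern_counts",
    "compress_patterns",
    "concatenate",
    "read_fasta",
    "write_fasta",
    "write_nexus",
]

_ALPHABET = np.array(list("ACGT"))


@dataclass
class Alignment:
    """Equal-length nucleotide sequences with per-locus boundaries."""

    taxa: list[str]
    sequences: list[str]
    locus_lengths: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        lens = {len(s) for s in self.sequences}
        if len(lens) > 1:
            raise ValueError("all sequences must have equal length")
        if not self.locus_lengths:
            self.locus_lengths = [self.length]
        if sum(self.locus_lengths) != self.length:
            raise ValueError("locus lengths must sum to the alignment length")

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def to_array(self) -> np.ndarray:
        """(length, n_taxa) array of states 0..3."""
        lut = np.zeros(256, dtype=np.uint8)
        for i, b in enumerate(b"ACGT"):
            lut[b] = i
        cols = [lut[np.frombuffer(s.encode(), dtype=np.uint8)] for s in self.sequences]
        return np.stack(cols, axis=1)


@dataclass
class PatternCounts:
    """Compressed site-pattern counts: the JC sufficient statistic.

    ``patterns`` is ``(P, n_taxa)`` with states 0..3, rows in deterministic
    lexicographic order; ``counts`` sums to the alignment length.
    """

    taxa: list[str]
    patterns: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=np.uint8)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.patterns.shape[0] != self.counts.shape[0]:
            raise ValueError("one count per pattern required")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n_sites(self) -> int:
        return int(self.counts.sum())

    def pooled_with(self, other: "PatternCounts") -> "PatternCounts":
        if self.taxa != other.taxa:
            raise ValueError("taxa mismatch")
        allpat = np.vstack([self.patterns, other.patterns])
        allcnt = np.concatenate([self.counts, other.counts])
        uniq, inv = np.unique(allpat, axis=0, return_inverse=True)
        cnt = np.zeros(uniq.shape[0], dtype=np.int64)
        np.add.at(cnt, inv, allcnt)
        return PatternCounts(self.taxa, uniq, cnt)


def simulate_alignment(
    rated: RatedTree, length: int, params: jc.JCParams, rng: np.random.Generator
) -> Alignment:
    """Simulate a JC alignment of ``length`` sites along a rated tree.

    Root states are uniform over {A,C,G,T}; each branch substitutes sites
    independently with JC transition probabilities at effective length
    ``params.rate x branch_length``.  Sampling is vectorized over sites per
    branch (equivalent to a per-site exponential-jump simulation under JC).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    tree = rated.tree
    eff = params.rate * rated.branch_lengths
    p_same, _ = jc.jc_transition(eff)
    states = np.empty((tree.n_nodes, length), dtype=np.uint8)
    states[tree.root] = rng.integers(0, 4, size=length)
    for v in tree.postorder[::-1]:  # preorder: parents before children
        if v == tree.root:
            continue
        parent_states = states[tree.parent[v]]
        change = rng.random(length) >= p_same[v]
        shift = rng.integers(1, 4, size=length)
        states[v] = np.where(change, (parent_states + shift) % 4, parent_states)
    seqs = ["".join(_ALPHABET[states[i]]) for i in range(tree.n_tips)]
    return Alignment(list(tree.labels), seqs, [length])


def simulate_pattern_counts(
    rated: RatedTree, length: int, params: jc.JCParams, rng: np.random.Generator
) -> PatternCounts:
    """Draw pattern counts directly: multinomial over exact JC pattern probs.

    Identical in distribution to ``compress_patterns(simulate_alignment(...))``
    but independent of alignment length in cost once the ``4^n`` pattern
    probabilities are computed; intended for small numbers of taxa.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    tree = rated.tree
    pats = jc.pattern_matrix(tree.n_tips)
    probs = np.exp(jc.pattern_log_probs(tree, params.rate * rated.branch_lengths, pats))
    probs = probs / probs.sum()
    counts = rng.multinomial(length, probs)
    return PatternCounts(list(tree.labels), pats, counts)


def compress_patterns(aln: Alignment) -> PatternCounts:
    """Count distinct alignment columns; rows in lexicographic pattern order."""
    arr = aln.to_array()
    uniq, counts = np.unique(arr, axis=0, return_counts=True)
    return PatternCounts(list(aln.taxa), uniq, counts)


def concatenate(alignments: list[Alignment]) -> Alignment:
    """Concatenate loci over identical taxon sets, recording locus boundaries."""
    if not alignments:
        raise ValueError("need at least one alignment")
    taxa = alignments[0].taxa
    for a in alignments[1:]:
        if a.taxa != taxa:
            raise ValueError("all alignments must share the same taxa in order")
    seqs = [
        "".join(a.sequences[i] for a in alignments) for i in range(len(taxa))
    ]
    lengths = [n for a in alignments for n in a.locus_lengths]
    return Alignment(list(taxa), seqs, lengths)


# -- standard formats -----------------------------------------------------


def write_fasta(aln: Alignment, path) -> None:
    records = [
        SeqRecord(Seq(s), id=t, description="")
        for t, s in zip(aln.taxa, aln.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> Alignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    return Alignment([r.id for r in records], [str(r.seq).upper() for r in records])


def write_nexus(aln: Alignment, path) -> None:
    """NEXUS with a sets block marking locus boundaries as charsets."""
    out = StringIO()
    out.write("#NEXUS\n\nBEGIN DATA;\n")
    out.write(f"  DIMENSIONS NTAX={len(aln.taxa)} NCHAR={aln.length};\n")
    out.write("  FORMAT DATATYPE=DNA MISSING=? GAP=-;\n  MATRIX\n")
    for t, s in zip(aln.taxa, aln.sequences):
        out.write(f"    {t}  {s}\n")
    out.write("  ;\nEND;\n\nBEGIN SETS;\n")
    start = 1
    for i, n in enumerate(aln.locus_lengths):
        out.write(f"  CHARSET locus{i + 1} = {start}-{start + n - 1};\n")
        start += n
    out.write("END;\n")
    with open(path, "w") as fh:
        fh.write(out.getvalue())
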