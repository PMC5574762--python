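"""Finite-sites Jukes–Cantor sequence evolution along local genealogies.

Each site evolves independently down the genealogy of its segment: the root
base is drawn uniformly from {A,C,G,T} (the JC69 stationary distribution),
substitutions arrive as a Poisson process at rate ``mu`` per site per
generation along every branch, and each substitution replaces the current
base with one of the three alternatives uniformly.  Multiple hits per site
are allowed, as in finite-sites simulators; at the scaled diversity used in
this study (4Nmu = 0.02/site) they are rare within species but matter for
deep between-species divergence.

Two engines are provided.  :func:`evolve_sequences` is this module's own
implementation operating on explicit :class:`~divergenome.trees.Tree`
genealogies; it is the engine used for the selection pipeline and for all
oracle tests.  :func:`mutate_tree_sequence` applies the identical JC69
process to an msprime tree sequence via msprime's C mutation generator,
which the neutral pipeline uses for speed; the test suite checks the two
against the JC69 closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import msprime
import numpy as np
import tskit

from .trees import GenealogySegment, check_partition

__all__ = [
    "HaplotypeAlignment",
    "evolve_sequences",
    "mutate_tree_sequence",
    "alignment_from_tree_sequence",
    "BASES",
]

BASES = np.frombuffer(b"ACGT", dtype="S1")
_CODE = {b: i for i, b in enumerate("ACGT")}


@dataclass
class HaplotypeAlignment:
    """Sampled haplotype sequences with population labels.

    ``sequences`` is an (n_samples, L) uint8 matrix of base codes 0..3
    (A,C,G,T); ``pop_labels`` assigns each row to a species.  Windows are
    0-based and half-open throughout.
    """

    sequences: np.ndarray
    pop_labels: np.ndarray

    def __post_init__(self) -> None:
        self.sequences = np.asarray(self.sequences, dtype=np.uint8)
        self.pop_labels = np.asarray(self.pop_labels, dtype=object)
        if self.sequences.ndim != 2:
            raise ValueError("sequences must be a 2-D matrix")
        if self.pop_labels.shape[0] != self.sequences.shape[0]:
            raise ValueError("one population label per sequence row required")
        if self.sequences.size and self.sequences.max() > 3:
            raise ValueError("base codes must be in 0..3")

    @property
    def n_samples(self) -> int:
        return self.sequences.shape[0]

    @property
    def length_bp(self) -> int:
        return self.sequences.shape[1]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for lab in self.pop_labels:
            seen.setdefault(lab, None)
        return list(seen)

    def rows_for(self, pop: str) -> np.ndarray:
        return np.flatnonzero(self.pop_labels == pop)

    def slice(self, start_bp: int, end_bp: int) -> "HaplotypeAlignment":
        return HaplotypeAlignment(self.sequences[:, start_bp:end_bp], self.pop_labels)

    def to_strings(self) -> list[str]:
        return [
            BASES[row].tobytes().decode("ascii") for row in self.sequences
        ]

    @classmethod
    def from_strings(
        cls, seqs: list[str], pop_labels: list[str]
    ) -> "HaplotypeAlignment":
        if not seqs:
            return cls(np.zeros((0, 0), dtype=np.uint8), np.array([], dtype=object))
        L = len(seqs[0])
        mat = np.zeros((len(seqs), L), dtype=np.uint8)
        for i, s in enumerate(seqs):
            if len(s) != L:
                raise ValueError(f"ragged alignment: row {i} has length {len(s)}")
            try:
                mat[i] = [_CODE[c] for c in s.upper()]
            except KeyError as exc:
                raise ValueError(f"non-ACGT base {exc} in row {i}") from exc
        return cls(mat, np.array(pop_labels, dtype=object))


def _evolve_tree(
    seg: GenealogySegment, mu: float, rng: np.random.Generator
) -> np.ndarray:
    """JC69-evolve one segment; returns (n_leaves, length) base codes."""
    tree = seg.tree
    length = seg.length_bp
    lengths = tree.branch_lengths()
    seqs: dict[int, np.ndarray] = {
        tree.root: rng.integers(0, 4, size=length, dtype=np.uint8)
    }
    for node in tree.preorder():
        if node == tree.root:
            continue
        seq = seqs[int(tree.parent[node])].copy()
        n_hits = rng.poisson(mu * lengths[node] * length)
        if n_hits:
            sites = rng.integers(0, length, size=n_hits)
            shifts = rng.integers(1, 4, size=n_hits, dtype=np.uint8)
            if np.unique(sites).size == n_hits:  # no repeated hits: vectorized
                seq[sites] = (seq[sites] + shifts) % 4
            else:  # apply sequentially so multiple hits compose
                for s, d in zip(sites, shifts):
                    seq[s] = (seq[s] + d) % 4
        seqs[node] = seq
    return np.stack([seqs[i] for i in range(tree.n_leaves)])


def evolve_sequences(
    segments: list[GenealogySegment], mu: float, rng_seed: int
) -> HaplotypeAlignment:
    """Evolve nucleotide sequences along a partition of local genealogies.

    The segments must tile [0, L); all trees must have the same leaves in
    the same order.  Returns the (n_leaves, L) alignment with population
    labels taken from the leaf labels (``species|index`` convention).
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    L = segments[-1].interval_bp[1] if segments else 0
    check_partition(segments, L)
    rng = np.random.default_rng(rng_seed)
    n = segments[0].tree.n_leaves
    out = np.empty((n, L), dtype=np.uint8)
    for seg in segments:
        start, end = seg.interval_bp
        out[:, start:end] = _evolve_tree(seg, mu, rng)
    pops = np.array(segments[0].pop_labels, dtype=object)
    return HaplotypeAlignment(out, pops)


def mutate_tree_sequence(
    ts: tskit.TreeSequence, mu: float, rng_seed: int
) -> tskit.TreeSequence:
    """Overlay finite-sites JC69 mutations on an ancestry tree sequence."""
    return msprime.sim_mutations(
        ts, rate=mu, model=msprime.JC69(), random_seed=rng_seed
    )


def variant_matrix(mts: tskit.TreeSequence) -> tuple[np.ndarray, np.ndarray]:
    """(positions, genotype matrix) of the segregating sites.

    Genotypes are per-site allele indices; the statistics downstream depend
    only on the equality pattern, not on base identity.
    """
    positions = mts.sites_position.astype(np.int64)
    geno = mts.genotype_matrix()
    return positions, geno


def alignment_from_tree_sequence(
    mts: tskit.TreeSequence, pop_labels: list[str], rng_seed: int = 1
) -> HaplotypeAlignment:
    """Full finite-length alignment from a mutated tree sequence.

    Invariant sites carry a uniform-random base (their identity is
    irrelevant to every statistic); variant columns are decoded from the
    recorded alleles.
    """
    L = int(mts.sequence_length)
    n = mts.num_samples
    rng = np.random.default_rng(rng_seed)
    out = np.broadcast_to(
        rng.integers(0, 4, size=L, dtype=np.uint8), (n, L)
    ).copy()
    positions, geno = variant_matrix(mts)
    for k, var in enumerate(mts.variants()):
        codes = np.array([_CODE[a] for a in var.alleles], dtype=np.uint8)
        out[:, positions[k]] = codes[geno[k]]
    return HaplotypeAlignment(out, np.array(pop_labels, dtype=object))
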