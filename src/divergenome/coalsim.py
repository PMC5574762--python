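"""Two-population coalescent with recombination and epoch-limited gene flow.

This module generates the neutral genealogies of a pair of sister species
under an isolation(-with-migration) model: both species have constant
diploid effective size ``N_e``, split from a panmictic ancestral population
(also of size ``N_e``) ``pair_age`` generations ago, and may exchange
migrants during a single epoch of length ``2 N_e`` generations placed either
immediately after the split ("early" gene flow: divergence with gene flow
followed by complete isolation) or immediately before the present ("recent"
gene flow: secondary contact).  The scaled migration rate is given as
4Nm, the classical parameter governing equilibrium differentiation.

Sister pairs are simulated independently of one another: under neutrality
with gene flow restricted to within-pair exchange, the history of non-sister
species cannot affect within-pair genealogies, and all downstream statistics
are computed within pairs only.

The recombining ancestry itself is generated by msprime's exact coalescent-
with-recombination engine; this module owns the demographic model, the seed
discipline, and the conversion to explicit per-interval genealogies.  A
small independently written single-locus structured-coalescent simulator
(:mod:`divergenome.selsim`) is used in the test suite to cross-validate the
two engines against each other.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Any

import msprime
import numpy as np
import tskit

from ._seeds import derive_seed
from .trees import GenealogySegment, Tree

__all__ = [
    "ScenarioSpec",
    "MigrationEpoch",
    "DEFAULT_PAIR_AGE_FACTORS",
    "simulate_pair",
    "simulate_pair_ts",
    "simulate_replicate",
    "simulate_replicate_ts",
    "segments_from_tree_sequence",
]

#: Divergence times of the eight sister pairs, in units of N generations.
DEFAULT_PAIR_AGE_FACTORS = (2, 4, 6, 8, 10, 12, 14, 16)

GENE_FLOW_MODES = ("none", "early", "recent")
DIRECTIONS = ("unidirectional", "bidirectional")


@dataclass(frozen=True)
class MigrationEpoch:
    """A single window of gene flow, in generations before present.

    ``rate_4Nm_12`` is the scaled rate at which lineages of species 1 move
    (backward in time) into species 2, and vice versa for ``rate_4Nm_21``.
    """

    start_gen: float
    end_gen: float
    rate_4Nm_12: float
    rate_4Nm_21: float

    def __post_init__(self) -> None:
        if not 0 <= self.start_gen < self.end_gen:
            raise ValueError(f"bad epoch [{self.start_gen}, {self.end_gen})")
        if self.rate_4Nm_12 < 0 or self.rate_4Nm_21 < 0:
            raise ValueError("negative migration rate")


@dataclass(frozen=True)
class ScenarioSpec:
    """Full parameterization of one simulation scenario.

    Defaults reproduce the headline study conditions: N_e = 10**6 diploids,
    eight pair ages 2N..16N generations, 10 haploid sequences per species,
    100 kbp sequences, mu = 5e-9 and rec = 1e-8 per site per generation.
    Use :meth:`rescaled` for desk-scale runs that preserve 4Nmu, 4Nrec,
    T/N and 4Nm.
    """

    label: str = "scenario"
    N_e: int = 1_000_000
    pair_age_factors: tuple[float, ...] = DEFAULT_PAIR_AGE_FACTORS
    samples_per_species: int = 10
    seq_length_bp: int = 100_000
    mu: float = 5e-9
    rec: float = 1e-8
    gene_flow_mode: str = "none"
    migration_4Nm: float = 0.0
    direction: str = "unidirectional"
    selection: Any = None  # selsim.SelectionSpec | None
    n_replicates: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N_e <= 0:
            raise ValueError("N_e must be positive")
        ages = self.pair_ages
        if len(ages) == 0 or any(a <= 0 for a in ages):
            raise ValueError("pair ages must be strictly positive")
        if list(ages) != sorted(ages):
            raise ValueError("pair ages must be sorted ascending")
        if self.gene_flow_mode not in GENE_FLOW_MODES:
            raise ValueError(f"gene_flow_mode must be one of {GENE_FLOW_MODES}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if self.migration_4Nm < 0:
            raise ValueError("migration_4Nm must be >= 0")
        if self.gene_flow_mode == "none" and self.migration_4Nm != 0:
            raise ValueError("migration_4Nm must be 0 when gene_flow_mode is 'none'")
        if self.samples_per_species < 2:
            raise ValueError("need at least 2 sequences per species")
        if self.seq_length_bp <= 0:
            raise ValueError("seq_length_bp must be positive")
        if self.mu < 0 or self.rec < 0:
            raise ValueError("rates must be >= 0")

    @property
    def pair_ages(self) -> tuple[float, ...]:
        """Divergence times in generations."""
        return tuple(f * self.N_e for f in self.pair_age_factors)

    def check_window(self, window_bp: int) -> None:
        if self.seq_length_bp % window_bp != 0:
            warnings.warn(
                f"seq_length_bp={self.seq_length_bp} is not divisible by the "
                f"{window_bp} bp window; the last window will be short",
                stacklevel=2,
            )

    def rescaled(self, c: float) -> "ScenarioSpec":
        """Desk-scale version: N -> N/c, rates x c, ages fixed in N units.

        Holds 4Nmu, 4Nrec, T/N and 4Nm (which is dimensionless already)
        constant, so every statistic computed downstream is unchanged in
        distribution.
        """
        if c <= 0:
            raise ValueError("scale factor must be positive")
        selection = self.selection.scaled(c) if self.selection is not None else None
        return dataclasses.replace(
            self,
            N_e=max(2, round(self.N_e / c)),
            mu=self.mu * c,
            rec=self.rec * c,
            selection=selection,
        )

    def migration_epoch(self, pair_age: float) -> MigrationEpoch | None:
        """The gene-flow epoch for a pair of the given age, or None."""
        if self.gene_flow_mode == "none" or self.migration_4Nm == 0:
            return None
        span = 2 * self.N_e
        if self.gene_flow_mode == "recent":
            start, end = 0.0, min(span, pair_age)
        else:  # early
            start, end = max(0.0, pair_age - span), pair_age
        # Backward-in-time lineage movement from species 2 into species 1
        # (= forward-in-time migrants from species 1 into species 2) is the
        # convention for "unidirectional".
        m21 = self.migration_4Nm
        m12 = self.migration_4Nm if self.direction == "bidirectional" else 0.0
        return MigrationEpoch(start, end, rate_4Nm_12=m12, rate_4Nm_21=m21)


def _pair_demography(spec: ScenarioSpec, pair_age: float) -> msprime.Demography:
    N = spec.N_e
    dem = msprime.Demography()
    dem.add_population(name="sp1", initial_size=N)
    dem.add_population(name="sp2", initial_size=N)
    dem.add_population(name="anc", initial_size=N)

    epoch = spec.migration_epoch(pair_age)
    if epoch is not None:
        m12 = epoch.rate_4Nm_12 / (4 * N)  # per-generation lineage rate
        m21 = epoch.rate_4Nm_21 / (4 * N)
        if epoch.start_gen == 0:
            if m21 > 0:
                dem.set_migration_rate(source="sp2", dest="sp1", rate=m21)
            if m12 > 0:
                dem.set_migration_rate(source="sp1", dest="sp2", rate=m12)
        else:
            if m21 > 0:
                dem.add_migration_rate_change(
                    time=epoch.start_gen, source="sp2", dest="sp1", rate=m21
                )
            if m12 > 0:
                dem.add_migration_rate_change(
                    time=epoch.start_gen, source="sp1", dest="sp2", rate=m12
                )
        if epoch.end_gen < pair_age and epoch.start_gen == 0:
            dem.add_migration_rate_change(time=epoch.end_gen, rate=0)
    dem.add_population_split(time=pair_age, derived=["sp1", "sp2"], ancestral="anc")
    dem.sort_events()
    return dem


def simulate_pair_ts(
    spec: ScenarioSpec, pair_age: float, rng_seed: int
) -> tskit.TreeSequence:
    """Ancestry of one sister pair as a tskit tree sequence.

    Samples are haploid: the first ``samples_per_species`` sample nodes
    belong to species 1, the rest to species 2.  Times are in generations.
    """
    if pair_age <= 0:
        raise ValueError("pair_age must be positive")
    if rng_seed <= 0:
        raise ValueError("rng_seed must be a positive integer")
    n = spec.samples_per_species
    return msprime.sim_ancestry(
        samples=[
            msprime.SampleSet(n, population="sp1", ploidy=1),
            msprime.SampleSet(n, population="sp2", ploidy=1),
        ],
        demography=_pair_demography(spec, pair_age),
        sequence_length=spec.seq_length_bp,
        recombination_rate=spec.rec,
        ploidy=2,
        random_seed=rng_seed,
    )


def leaf_labels(spec: ScenarioSpec) -> list[str]:
    n = spec.samples_per_species
    return [f"sp1|{i}" for i in range(n)] + [f"sp2|{i}" for i in range(n)]


def segments_from_tree_sequence(
    ts: tskit.TreeSequence, labels: list[str] | None = None
) -> list[GenealogySegment]:
    """Convert a tree sequence into explicit per-interval genealogies."""
    if labels is None:
        labels = [f"n|{i}" for i in range(ts.num_samples)]
    node_times = ts.nodes_time
    samples = ts.samples()
    sample_index = {int(node): i for i, node in enumerate(samples)}
    segments = []
    for tree in ts.trees():
        order = list(tree.nodes(order="preorder"))
        local = {}
        # samples keep their sample order as leaf ids 0..n-1
        internal = ts.num_samples
        for node in order:
            if node in sample_index:
                local[node] = sample_index[node]
            else:
                local[node] = internal
                internal += 1
        parent = np.full(internal, -1, dtype=np.int64)
        time = np.zeros(internal)
        for node in order:
            i = local[node]
            time[i] = node_times[node]
            par = tree.parent(node)
            parent[i] = local[par] if par != tskit.NULL else -1
        left, right = tree.interval
        segments.append(
            GenealogySegment(
                interval_bp=(int(left), int(right)),
                tree=Tree(parent, time, ts.num_samples, list(labels)),
            )
        )
    return segments


def simulate_pair(
    spec: ScenarioSpec, pair_age: float, rng_seed: int
) -> list[GenealogySegment]:
    """Local genealogies of one sister pair along the chromosome.

    The segments partition [0, seq_length_bp); adjacent segments differ only
    through recombination events.  Leaf labels are ``sp1|i`` / ``sp2|i``.
    """
    ts = simulate_pair_ts(spec, pair_age, rng_seed)
    return segments_from_tree_sequence(ts, leaf_labels(spec))


def pair_seeds(spec: ScenarioSpec, rng_seed: int) -> dict[float, int]:
    """Per-pair ancestry seeds derived from the replicate seed."""
    seeds = {
        age: derive_seed(rng_seed, "pair", i, "ancestry")
        for i, age in enumerate(spec.pair_ages)
    }
    if len(set(seeds.values())) != len(seeds):
        raise RuntimeError("seed collision between pairs within a replicate")
    return seeds


def simulate_replicate_ts(
    spec: ScenarioSpec, rng_seed: int
) -> dict[float, tskit.TreeSequence]:
    """One replicate: independent ancestries for all pairs, keyed by age."""
    return {
        age: simulate_pair_ts(spec, age, seed)
        for age, seed in pair_seeds(spec, rng_seed).items()
    }


def simulate_replicate(
    spec: ScenarioSpec, rng_seed: int
) -> dict[float, list[GenealogySegment]]:
    """Like :func:`simulate_replicate_ts` but as explicit genealogies."""
    labels = leaf_labels(spec)
    return {
        age: segments_from_tree_sequence(ts, labels)
        for age, ts in simulate_replicate_ts(spec, rng_seed).items()
    }
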