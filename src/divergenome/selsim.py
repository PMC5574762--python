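"""Linked divergent selection: trajectories and conditioned genealogies.

The selection model is a single biallelic locus adjacent to the neutral
region, with mirror-image semidominant fitnesses: allele A has genotype
fitnesses (1+s_hom, 1+s_het, 1+s_other) in species 1 and the reverse order
in species 2.  At the species split the two demes carry alternative alleles
fixed (divergence from a standing difference).  Without gene flow such a
locus leaves the linked neutral region indistinguishable from neutrality —
no within-deme polymorphism exists for selection to act on — which is why
the interesting scenarios combine selection with migration.

Two engines live here:

* :func:`simulate_trajectory` — a forward Wright-Fisher frequency
  simulation of the selected locus in both demes (selection, epoch-limited
  migration, binomial drift), typically run at a rescaled population size.

* :func:`simulate_selected_pair` — a backward structured coalescent for the
  neutral region conditioned on the selected-locus dynamics.  Lineages
  carry a (deme, allelic background) state; recombination at rate
  rec x distance moves a lineage between backgrounds, and backward
  migration is weighted by the background frequencies, so the selected
  locus acts as a barrier whose strength decays with distance.  At the
  study's parameters selection is far stronger than drift and migration
  (2Ns >> 1, m << s), so background frequencies sit at the deterministic
  migration-selection balance q* = m/s_het and the process is a
  time-homogeneous Markov chain within each gene-flow epoch; the engine
  uses that regime and refuses parameters outside it rather than silently
  extrapolating.  Each nonoverlapping window of the neutral region is
  simulated as one non-recombining locus at its midpoint distance from the
  selected site; recombination between windows and the locus is what
  shapes the F_ST gradient along the region.

With all selection coefficients zero the engine reduces exactly to the
neutral two-deme coalescent, which the test suite exploits to
cross-validate it against the recombining neutral simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .coalsim import ScenarioSpec
from ._seeds import derive_seed
from .trees import GenealogySegment, Tree

__all__ = [
    "SelectionSpec",
    "AlleleTrajectory",
    "simulate_trajectory",
    "simulate_selected_pair",
    "wright_fisher_path",
]


@dataclass(frozen=True)
class SelectionSpec:
    """Fitness scheme of the divergently selected locus.

    ``s_hom`` is the advantage of the locally favored homozygote, ``s_het``
    of the heterozygote, ``s_other`` of the disfavored homozygote (0 =
    neutral).  ``locus_position`` places the selected site relative to the
    neutral region's coordinate 0 (negative or 0 = adjacent to the left
    edge).
    """

    s_hom: float = 0.01
    s_het: float = 0.005
    s_other: float = 0.0
    locus_position: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.s_other <= self.s_het <= self.s_hom:
            raise ValueError("need 0 <= s_other <= s_het <= s_hom")

    @property
    def neutral(self) -> bool:
        return self.s_hom == self.s_het == self.s_other

    def scaled(self, c: float) -> "SelectionSpec":
        """Rescale coefficients by c, preserving 2Ns when N is divided by c.

        The conditioned coalescent depends on selection only through the
        dimensionless ratios 2Ns, m/s and r d/s, all preserved jointly with
        the rest of :meth:`ScenarioSpec.rescaled`.
        """
        return SelectionSpec(
            self.s_hom * c, self.s_het * c, self.s_other * c, self.locus_position
        )


@dataclass
class AlleleTrajectory:
    """Per-generation frequency of allele A in each deme, split -> present."""

    freq_deme1: np.ndarray
    freq_deme2: np.ndarray
    N: int  # the (possibly rescaled) population size simulated

    def __post_init__(self) -> None:
        self.freq_deme1 = np.asarray(self.freq_deme1, float)
        self.freq_deme2 = np.asarray(self.freq_deme2, float)
        if self.freq_deme1.shape != self.freq_deme2.shape:
            raise ValueError("deme trajectories must have equal length")
        for arr in (self.freq_deme1, self.freq_deme2):
            if arr.size and (arr.min() < 0 or arr.max() > 1):
                raise ValueError("frequencies must lie in [0, 1]")

    @property
    def n_generations(self) -> int:
        return self.freq_deme1.size - 1

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("generation\tfreq_deme1\tfreq_deme2\n")
            for g, (p1, p2) in enumerate(zip(self.freq_deme1, self.freq_deme2)):
                fh.write(f"{g}\t{p1:.6g}\t{p2:.6g}\n")


def _select(p: np.ndarray, w_AA: float, w_Aa: float, w_aa: float) -> np.ndarray:
    """Deterministic one-generation selection update of freq(A)."""
    wbar = p * p * w_AA + 2 * p * (1 - p) * w_Aa + (1 - p) * (1 - p) * w_aa
    with np.errstate(invalid="ignore"):
        out = np.where(wbar > 0, p * (p * w_AA + (1 - p) * w_Aa) / np.where(wbar > 0, wbar, 1), p)
    return out


def wright_fisher_path(
    N: int,
    fitnesses: tuple[float, float, float],
    p0: float | np.ndarray,
    n_generations: int,
    rng: np.random.Generator,
    n_replicates: int = 1,
) -> np.ndarray:
    """Single-deme Wright-Fisher frequency paths of allele A.

    ``fitnesses`` = (w_AA, w_Aa, w_aa).  Returns an
    (n_generations + 1, n_replicates) array; replicates are vectorized so
    diffusion-oracle tests at n = 10**4 are cheap.
    """
    if N <= 0:
        raise ValueError("N must be positive")
    w_AA, w_Aa, w_aa = fitnesses
    p = np.full(n_replicates, p0, dtype=float) if np.isscalar(p0) else np.asarray(p0, float)
    out = np.empty((n_generations + 1, p.size))
    out[0] = p
    for g in range(1, n_generations + 1):
        p_sel = _select(p, w_AA, w_Aa, w_aa)
        p = rng.binomial(2 * N, p_sel) / (2 * N)
        out[g] = p
    return out


def simulate_trajectory(
    spec: ScenarioSpec,
    pair_age: float,
    rng_seed: int,
    N_prime: int = 1000,
    rescale_selection: bool = True,
) -> AlleleTrajectory:
    """Forward WF trajectory of the selected locus in both demes.

    Run at population size ``N_prime`` with time, migration and (optionally)
    selection rescaled to preserve T/N, 4Nm and 2Ns.  Starts from the
    standing difference (deme 1 fixed for A, deme 2 for a) at the split.
    Absorption (loss or fixation in both demes) is allowed and simply
    reported by the trajectory itself.
    """
    sel = spec.selection
    if sel is None:
        raise ValueError("scenario has no selection specified")
    c = spec.N_e / N_prime if rescale_selection else 1.0
    s_hom, s_het, s_other = sel.s_hom * c, sel.s_het * c, sel.s_other * c
    if max(s_hom, s_het, s_other) > 1:
        raise ValueError(
            f"rescaled selection coefficient {max(s_hom, s_het, s_other):.3g} > 1: "
            "this regime is effectively deterministic; use "
            "simulate_selected_pair, whose strong-selection engine handles it"
        )
    n_gen = int(round(pair_age / spec.N_e * N_prime))
    m = spec.migration_4Nm / (4 * N_prime)
    rng = np.random.default_rng(rng_seed)

    p1, p2 = np.array([1.0]), np.array([0.0])
    out1 = np.empty(n_gen + 1)
    out2 = np.empty(n_gen + 1)
    out1[0], out2[0] = p1[0], p2[0]
    epoch = spec.migration_epoch(pair_age)
    for g in range(1, n_gen + 1):
        # deme 1 favors A, deme 2 favors a (mirror-image fitnesses)
        q1 = _select(p1, 1 + s_hom, 1 + s_het, 1 + s_other)
        q2 = _select(p2, 1 + s_other, 1 + s_het, 1 + s_hom)
        backward_gen = (n_gen - g) / N_prime * spec.N_e  # gens before present
        if epoch is not None and epoch.start_gen <= backward_gen < epoch.end_gen:
            # forward migration is the reverse of the backward lineage rates
            m12_fwd = m if epoch.rate_4Nm_21 > 0 else 0.0  # deme1 -> deme2
            m21_fwd = m if epoch.rate_4Nm_12 > 0 else 0.0
            q1, q2 = (
                (1 - m21_fwd) * q1 + m21_fwd * q2,
                (1 - m12_fwd) * q2 + m12_fwd * q1,
            )
        p1 = rng.binomial(2 * N_prime, q1) / (2 * N_prime)
        p2 = rng.binomial(2 * N_prime, q2) / (2 * N_prime)
        out1[g], out2[g] = p1[0], p2[0]
    return AlleleTrajectory(out1, out2, N_prime)


# ---------------------------------------------------------------------------
# Conditioned structured coalescent (strong-selection regime)
# ---------------------------------------------------------------------------


class _Lineage:
    __slots__ = ("node", "deme", "bg")

    def __init__(self, node: int, deme: int, bg: int):
        self.node = node
        self.deme = deme  # 0 = species 1, 1 = species 2
        self.bg = bg  # 0 = allele A, 1 = allele a; -1 = unstructured


class _TreeBuilder:
    def __init__(self, n_leaves: int, labels: list[str]):
        self.parent = [-1] * n_leaves
        self.time = [0.0] * n_leaves
        self.n_leaves = n_leaves
        self.labels = labels

    def merge(self, a: int, b: int, t: float) -> int:
        node = len(self.parent)
        self.parent.append(-1)
        self.time.append(t)
        self.parent[a] = node
        self.parent[b] = node
        return node

    def tree(self) -> Tree:
        return Tree(
            np.array(self.parent), np.array(self.time), self.n_leaves, self.labels
        )


def _phases(spec: ScenarioSpec, pair_age: float):
    """Backward-time phases [(t0, t1, migration_on, collapse_at_end)]."""
    epoch = spec.migration_epoch(pair_age)
    T = pair_age
    if epoch is None:
        return [(0.0, T, False, False)]
    if epoch.start_gen == 0:  # recent gene flow
        if epoch.end_gen >= T:
            return [(0.0, T, True, False)]
        return [(0.0, epoch.end_gen, True, True), (epoch.end_gen, T, False, False)]
    # early gene flow: migration in [T - 2N, T); the purge of immigrant
    # alleles after forward cessation sits just below start_gen and has a
    # negligible (O(rd q*/s)) effect on lineages crossing it backward.
    return [(0.0, epoch.start_gen, False, False), (epoch.start_gen, T, True, False)]


def _equilibrium_freqs(spec: ScenarioSpec) -> np.ndarray:
    """x[deme, bg]: background frequencies at migration-selection balance."""
    sel = spec.selection
    epoch_dirs = spec.direction == "bidirectional"
    m = spec.migration_4Nm / (4 * spec.N_e)
    if sel.neutral:
        raise AssertionError("neutral path should bypass backgrounds")
    two_Ns = 2 * spec.N_e * sel.s_het
    if two_Ns < 50:
        raise ValueError(
            f"2N s_het = {two_Ns:.3g} < 50: selection is not strong relative to "
            "drift, outside the deterministic-frequency regime this engine models"
        )
    q_star = m / sel.s_het if sel.s_het > 0 else 0.0
    if q_star > 0.2:
        raise ValueError(
            f"migration-selection balance q* = {q_star:.3g} > 0.2: migration "
            "overwhelms selection at the locus; outside the modeled regime"
        )
    x = np.zeros((2, 2))
    # deme 0 resident allele A (bg 0), deme 1 resident allele a (bg 1).
    # unidirectional: forward migrants flow species1 -> species2 only.
    x[0, 0], x[0, 1] = 1.0, 0.0
    x[1, 0], x[1, 1] = q_star, 1.0 - q_star
    if epoch_dirs:
        x[0, 0], x[0, 1] = 1.0 - q_star, q_star
    return x


def _forward_m(spec: ScenarioSpec) -> np.ndarray:
    """m_fwd[j, i]: forward migrant fraction from deme j into deme i."""
    m = spec.migration_4Nm / (4 * spec.N_e)
    out = np.zeros((2, 2))
    out[0, 1] = m  # species1 -> species2 forward (backward lineages 2 -> 1)
    if spec.direction == "bidirectional":
        out[1, 0] = m
    return out


def _gillespie_phase(
    lineages: list[_Lineage],
    builder: _TreeBuilder,
    t: float,
    t_end: float,
    spec: ScenarioSpec,
    rho_d: float,
    migration_on: bool,
    structured: bool,
    rng: np.random.Generator,
) -> float:
    """Advance the coalescent to t_end (or full coalescence); returns time."""
    N = spec.N_e
    x = _equilibrium_freqs(spec) if (migration_on and structured) else None
    m_fwd = _forward_m(spec) if migration_on else None
    if x is not None:
        # a deme is fixed for its resident allele outside gene-flow epochs,
        # so every lineage enters the epoch on the resident background
        for lin in lineages:
            lin.bg = lin.deme
    while len(lineages) > 1 and t < t_end:
        events = []  # (rate, kind, class key)
        by_class: dict[tuple[int, int], list[int]] = {}
        for idx, lin in enumerate(lineages):
            key = (lin.deme, lin.bg) if x is not None else (lin.deme, -1)
            by_class.setdefault(key, []).append(idx)
        for (deme, bg), members in by_class.items():
            if x is not None:
                freq = x[deme, bg]
                if freq <= 0:
                    raise AssertionError("lineage on an empty background")
                coal = 1.0 / (2 * N * freq)
            else:
                coal = 1.0 / (2 * N)
            k = len(members)
            if k >= 2:
                events.append((k * (k - 1) / 2 * coal, "coal", (deme, bg)))
            if x is not None and rho_d > 0 and x[deme, 1 - bg] > 0:
                events.append((k * rho_d * x[deme, 1 - bg], "rec", (deme, bg)))
            if m_fwd is not None:
                src = 1 - deme
                if x is None:
                    rate = m_fwd[src, deme]
                elif x[deme, bg] > 0:
                    rate = m_fwd[src, deme] * x[src, bg] / x[deme, bg]
                else:
                    rate = 0.0
                if rate > 0:
                    events.append((k * rate, "mig", (deme, bg)))
        total = sum(r for r, _, _ in events)
        if total == 0:
            return t_end
        dt = rng.exponential(1.0 / total)
        if t + dt >= t_end:
            return t_end
        t += dt
        pick = rng.uniform(0, total)
        acc = 0.0
        for rate, kind, key in events:
            acc += rate
            if pick <= acc:
                members = by_class[key]
                if kind == "coal":
                    i, j = rng.choice(len(members), size=2, replace=False)
                    a, b = members[int(i)], members[int(j)]
                    node = builder.merge(lineages[a].node, lineages[b].node, t)
                    lineages[a].node = node
                    lineages.pop(b)
                elif kind == "rec":
                    lin = lineages[members[rng.integers(len(members))]]
                    lin.bg = 1 - lin.bg
                else:  # mig: backward move to the source deme, same background
                    lin = lineages[members[rng.integers(len(members))]]
                    lin.deme = 1 - lin.deme
                break
    return t


def _collapse_immigrant_background(
    lineages: list[_Lineage],
    builder: _TreeBuilder,
    t_edge: float,
    spec: ScenarioSpec,
    rho_d: float,
    rng: np.random.Generator,
) -> float:
    """Resolve lineages stranded on an immigrant background at epoch entry.

    Backward past the onset of a recent-gene-flow epoch the immigrant
    background frequency decays as q(u) = q* e^{-s u}; a lineage on it must
    either recombine onto the resident background (constant hazard r d),
    coalesce with another stranded lineage (hazard growing like e^{su}) or
    trace back to a founding migrant (hazard s e^{su}).  Hazards are
    sampled exactly by inversion of their integrated forms.
    """
    sel = spec.selection
    s = sel.s_het
    x = _equilibrium_freqs(spec)
    m_fwd = _forward_m(spec)
    t_max = t_edge
    for deme in (0, 1):
        imm_bg = 1 - deme  # background of the non-resident allele
        q_star = x[deme, imm_bg]
        src = 1 - deme
        if q_star <= 0 or m_fwd[src, deme] <= 0:
            continue
        # per-lineage trace-to-migrant hazard at epoch entry (grows e^{su})
        mig0 = m_fwd[src, deme] * x[src, imm_bg] / q_star
        stranded = [lin for lin in lineages if lin.deme == deme and lin.bg == imm_bg]
        u = 0.0
        while stranded:
            k = len(stranded)
            u_rec = (
                u + rng.exponential(1.0 / (rho_d * k)) if rho_d > 0 else math.inf
            )
            e = rng.exponential(1.0)
            u_mig = math.log(math.exp(s * u) + s * e / (k * mig0)) / s
            if k >= 2:
                pair_rate = k * (k - 1) / 2 / (2 * spec.N_e * q_star)
                e = rng.exponential(1.0)
                u_coal = math.log(math.exp(s * u) + s * e / pair_rate) / s
            else:
                u_coal = math.inf
            u = min(u_rec, u_mig, u_coal)
            if u == u_rec:
                lin = stranded.pop(rng.integers(len(stranded)))
                lin.bg = 1 - lin.bg
            elif u == u_mig:
                lin = stranded.pop(rng.integers(len(stranded)))
                lin.deme = src  # its allele is the resident background there
            else:
                i, j = rng.choice(len(stranded), size=2, replace=False)
                a, b = stranded[int(i)], stranded[int(j)]
                node = builder.merge(a.node, b.node, t_edge + u)
                a.node = node
                stranded.remove(b)
                lineages.remove(b)
            t_max = max(t_max, t_edge + u)
    return t_max


def _simulate_window_tree(
    spec: ScenarioSpec,
    pair_age: float,
    rho_d: float,
    labels: list[str],
    rng: np.random.Generator,
) -> Tree:
    n = spec.samples_per_species
    sel = spec.selection
    structured = sel is not None and not sel.neutral and spec.migration_4Nm > 0
    builder = _TreeBuilder(2 * n, labels)
    # resident backgrounds: deme 0 carries A (bg 0), deme 1 carries a (bg 1)
    lineages = [_Lineage(i, 0, 0) for i in range(n)] + [
        _Lineage(n + i, 1, 1) for i in range(n)
    ]
    t = 0.0
    for t0, t1, mig_on, collapse in _phases(spec, pair_age):
        t = _gillespie_phase(
            lineages, builder, max(t, t0), t1, spec, rho_d, mig_on, structured, rng
        )
        if collapse and structured:
            t = max(
                t,
                _collapse_immigrant_background(
                    lineages, builder, t1, spec, rho_d, rng
                ),
            )
    # ancestral panmictic phase: pairwise coalescence at rate 1/(2N)
    N = spec.N_e
    t = max(t, pair_age)
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(2 * N / (k * (k - 1) / 2))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = lineages[int(i)], lineages[int(j)]
        node = builder.merge(a.node, b.node, t)
        a.node = node
        lineages.remove(b)
    return builder.tree()


def simulate_single_locus_genealogy(
    spec: ScenarioSpec,
    pair_age: float,
    rng: np.random.Generator | int,
    rho_d: float = 0.0,
) -> Tree:
    """One non-recombining genealogy under the structured coalescent.

    With no selection in ``spec`` this is an independent implementation of
    the two-deme isolation(-with-migration) coalescent (used to
    cross-validate the recombining engine); with selection it is one
    window's conditioned genealogy at locus distance ``rho_d = rec x d``.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    n = spec.samples_per_species
    labels = [f"sp1|{i}" for i in range(n)] + [f"sp2|{i}" for i in range(n)]
    return _simulate_window_tree(spec, pair_age, rho_d, labels, rng)


def simulate_selected_pair(
    spec: ScenarioSpec,
    pair_age: float,
    rng_seed: int,
    window_bp: int = 500,
) -> list[GenealogySegment]:
    """Genealogies of the neutral region linked to the selected locus.

    Each nonoverlapping window of the region is simulated as a single
    non-recombining locus at its midpoint distance from the selected site;
    with rec = 0 the whole region is perfectly linked to the locus and is
    returned as one segment.  Output matches :func:`coalsim.simulate_pair`
    in shape and labeling and feeds the same mutation/scan stages.
    """
    if spec.selection is None:
        raise ValueError("scenario has no selection specified")
    if pair_age <= 0:
        raise ValueError("pair_age must be positive")
    L = spec.seq_length_bp
    labels = [f"sp1|{i}" for i in range(spec.samples_per_species)] + [
        f"sp2|{i}" for i in range(spec.samples_per_species)
    ]
    rng = np.random.default_rng(derive_seed(rng_seed, "selsim", pair_age))
    if spec.rec == 0:
        bounds = [(0, L)]
    else:
        n_windows = int(np.ceil(L / window_bp))
        bounds = [
            (w * window_bp, min((w + 1) * window_bp, L)) for w in range(n_windows)
        ]
    segments = []
    locus = spec.selection.locus_position
    for start, end in bounds:
        midpoint = 0.5 * (start + end)
        rho_d = spec.rec * abs(midpoint - locus)
        tree = _simulate_window_tree(spec, pair_age, rho_d, labels, rng)
        segments.append(GenealogySegment((start, end), tree))
    return segments
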