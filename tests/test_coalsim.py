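"""Neutral coalescent engine: analytic oracles and engine cross-validation."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from divergenome import ScenarioSpec, coalsim, selsim
from divergenome.trees import check_partition


def cross_tmrca(ts):
    """TMRCA of the first sample of each species at the first tree."""
    tree = ts.first()
    n = ts.num_samples // 2
    return tree.tmrca(0, n)


def test_spec_validation_errors():
    with pytest.raises(ValueError, match="positive"):
        ScenarioSpec(N_e=0)
    with pytest.raises(ValueError, match="sorted"):
        ScenarioSpec(pair_age_factors=(4, 2))
    with pytest.raises(ValueError, match="migration_4Nm must be 0"):
        ScenarioSpec(gene_flow_mode="none", migration_4Nm=1.0)
    with pytest.raises(ValueError, match="gene_flow_mode"):
        ScenarioSpec(gene_flow_mode="late")


def test_short_window_warning(tiny_spec):
    spec = dataclasses.replace(tiny_spec, seq_length_bp=10_001)
    with pytest.warns(UserWarning, match="not divisible"):
        spec.check_window(500)


def test_migration_epoch_placement():
    spec = ScenarioSpec(
        N_e=1000, gene_flow_mode="recent", migration_4Nm=1.0, mu=5e-6, rec=1e-5
    )
    recent = spec.migration_epoch(8000)
    assert (recent.start_gen, recent.end_gen) == (0.0, 2000.0)
    early = dataclasses.replace(spec, gene_flow_mode="early").migration_epoch(8000)
    assert (early.start_gen, early.end_gen) == (6000.0, 8000.0)
    # youngest pair: the two modes coincide
    youngest_recent = spec.migration_epoch(2000)
    youngest_early = dataclasses.replace(spec, gene_flow_mode="early").migration_epoch(2000)
    assert (youngest_recent.start_gen, youngest_recent.end_gen) == (0.0, 2000.0)
    assert (youngest_early.start_gen, youngest_early.end_gen) == (0.0, 2000.0)
    # unidirectional = backward movement of species-2 lineages into species 1
    assert recent.rate_4Nm_21 == 1.0 and recent.rate_4Nm_12 == 0.0


def test_no_recombination_single_segment(tiny_spec):
    spec = dataclasses.replace(tiny_spec, rec=0.0, seq_length_bp=2000)
    segments = coalsim.simulate_pair(spec, spec.pair_ages[0], rng_seed=3)
    assert len(segments) == 1
    assert segments[0].interval_bp == (0, 2000)
    assert segments[0].tree.n_leaves == 20


def test_segments_partition_and_leaf_structure(tiny_spec):
    spec = dataclasses.replace(tiny_spec, seq_length_bp=5000)
    segments = coalsim.simulate_pair(spec, spec.pair_ages[2], rng_seed=4)
    check_partition(segments, 5000)
    assert all(seg.tree.n_leaves == 20 for seg in segments)
    assert segments[0].pop_labels == ["sp1"] * 10 + ["sp2"] * 10
    assert all(seg.tree.height() < np.inf for seg in segments)


def test_replicate_has_eight_pairs_and_is_deterministic(tiny_spec):
    spec = dataclasses.replace(tiny_spec, seq_length_bp=1000)
    rep1 = coalsim.simulate_replicate(spec, rng_seed=9)
    rep2 = coalsim.simulate_replicate(spec, rng_seed=9)
    assert list(rep1) == [f * spec.N_e for f in (2, 4, 6, 8, 10, 12, 14, 16)]
    for age in rep1:
        assert len(rep1[age]) == len(rep2[age])
        assert rep1[age][0].tree.to_newick() == rep2[age][0].tree.to_newick()


def test_different_seeds_give_different_genealogies(tiny_spec):
    spec = dataclasses.replace(tiny_spec, seq_length_bp=1000)
    age = spec.pair_ages[0]
    differing = sum(
        coalsim.simulate_pair(spec, age, seed)[0].tree.to_newick()
        != coalsim.simulate_pair(spec, age, seed + 1000)[0].tree.to_newick()
        for seed in range(1, 11)
    )
    assert differing == 10


def test_isolation_mean_cross_coalescence_matches_analytic():
    """Isolation model: E[cross-species pairwise TMRCA] = T + 2N."""
    N, T = 1000, 2000
    spec = ScenarioSpec(
        N_e=N, pair_age_factors=(T / N,), samples_per_species=2,
        seq_length_bp=100, mu=0.0, rec=0.0,
    )
    times = np.array(
        [cross_tmrca(coalsim.simulate_pair_ts(spec, T, 1 + i)) for i in range(1500)]
    )
    expected = T + 2 * N
    se = times.std(ddof=1) / np.sqrt(times.size)
    assert abs(times.mean() - expected) < 3 * se


def test_panmictic_limit_mean_pairwise_coalescence():
    """pair_age -> 0: mean pairwise coalescence ~ 2N (so dxy -> 4 N mu)."""
    N = 1000
    spec = ScenarioSpec(
        N_e=N, pair_age_factors=(1e-6,), samples_per_species=2,
        seq_length_bp=100, mu=0.0, rec=0.0,
    )
    times = np.array(
        [
            cross_tmrca(coalsim.simulate_pair_ts(spec, spec.pair_ages[0], 1 + i))
            for i in range(1500)
        ]
    )
    se = times.std(ddof=1) / np.sqrt(times.size)
    assert abs(times.mean() - 2 * N) < 3 * se


def test_cross_engine_tmrca_distribution():
    """Recombining engine vs the independent single-locus Gillespie engine:
    cross-species TMRCA distributions agree (KS) under recent gene flow."""
    N = 500
    spec = ScenarioSpec(
        N_e=N, pair_age_factors=(4,), samples_per_species=2,
        seq_length_bp=100, mu=0.0, rec=0.0,
        gene_flow_mode="recent", migration_4Nm=1.0,
    )
    age = spec.pair_ages[0]
    n = 4000
    msp = np.array(
        [cross_tmrca(coalsim.simulate_pair_ts(spec, age, 1 + i)) for i in range(n)]
    )
    rng = np.random.default_rng(123)
    own = np.array(
        [
            selsim.simulate_single_locus_genealogy(spec, age, rng).tmrca(0, 2)
            for _ in range(n)
        ]
    )
    res = stats.ks_2samp(msp, own)
    assert res.pvalue > 0.01


def test_scale_invariance_of_coalescence_distribution():
    """c-fold rescaling leaves TMRCA/N invariant in distribution (c = 10)."""
    base = ScenarioSpec(
        N_e=2000, pair_age_factors=(4,), samples_per_species=2,
        seq_length_bp=100, mu=2.5e-6, rec=5e-6,
    )
    scaled = base.rescaled(10)
    t1 = np.array(
        [
            cross_tmrca(coalsim.simulate_pair_ts(base, base.pair_ages[0], 1 + i))
            / base.N_e
            for i in range(600)
        ]
    )
    t2 = np.array(
        [
            cross_tmrca(coalsim.simulate_pair_ts(scaled, scaled.pair_ages[0], 1 + i))
            / scaled.N_e
            for i in range(600)
        ]
    )
    assert stats.ks_2samp(t1, t2).pvalue > 0.01
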