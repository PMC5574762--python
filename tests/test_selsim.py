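"""Selection engines: WF diffusion oracles and coalescent reductions."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from divergenome import ScenarioSpec, SelectionSpec, jcmut, selsim, winstats


def test_selection_spec_ordering_enforced():
    with pytest.raises(ValueError):
        SelectionSpec(s_hom=0.001, s_het=0.005)
    with pytest.raises(ValueError):
        SelectionSpec(s_hom=0.01, s_het=0.005, s_other=0.007)


def test_neutral_wf_frequency_is_a_martingale():
    rng = np.random.default_rng(0)
    paths = selsim.wright_fisher_path(
        N=200, fitnesses=(1, 1, 1), p0=0.3, n_generations=100, rng=rng,
        n_replicates=1000,
    )
    final = paths[-1]
    se = final.std(ddof=1) / np.sqrt(final.size)
    assert abs(final.mean() - 0.3) < 3 * se


def test_fixation_probability_matches_kimura_diffusion():
    """New semidominant beneficial allele: u ~ (1-e^{-2s})/(1-e^{-4Ns})."""
    N, s_het = 100, 0.005
    rng = np.random.default_rng(1)
    paths = selsim.wright_fisher_path(
        N=N, fitnesses=(1 + 2 * s_het, 1 + s_het, 1.0), p0=1 / (2 * N),
        n_generations=3000, rng=rng, n_replicates=10_000,
    )
    final = paths[-1]
    absorbed = (final == 0) | (final == 1)
    assert absorbed.mean() > 0.999  # essentially all absorbed by 3000 gens
    p_fix = (final == 1).mean()
    expected = (1 - np.exp(-2 * s_het)) / (1 - np.exp(-4 * N * s_het))
    tol = 3 * np.sqrt(expected * (1 - expected) / 10_000)
    assert abs(p_fix - expected) < tol


def test_trajectory_pinned_without_migration(selection_spec):
    spec = ScenarioSpec(
        label="sel", N_e=2000, selection=selection_spec, mu=2.5e-6, rec=5e-6
    )
    traj = selsim.simulate_trajectory(spec, spec.pair_ages[0], rng_seed=2, N_prime=1000)
    assert np.all(traj.freq_deme1 == 1.0)
    assert np.all(traj.freq_deme2 == 0.0)
    assert traj.n_generations == 2 * 1000


def test_trajectory_requires_selection(tiny_spec):
    with pytest.raises(ValueError, match="no selection"):
        selsim.simulate_trajectory(tiny_spec, tiny_spec.pair_ages[0], 1)


def test_trajectory_refuses_super_unit_rescaled_coefficients():
    spec = ScenarioSpec(N_e=1_000_000, selection=SelectionSpec())
    with pytest.raises(ValueError, match="> 1"):
        selsim.simulate_trajectory(spec, spec.pair_ages[0], 1, N_prime=1000)


def test_trajectory_tsv_round_trip(tmp_path, selection_spec):
    spec = ScenarioSpec(label="sel", N_e=1000, selection=selection_spec)
    traj = selsim.simulate_trajectory(spec, spec.pair_ages[0], 3, N_prime=100)
    path = tmp_path / "traj.tsv"
    traj.to_tsv(path)
    lines = path.read_text().splitlines()
    assert lines[0] == "generation\tfreq_deme1\tfreq_deme2"
    assert len(lines) == traj.n_generations + 2


def test_selected_pair_requires_selection(tiny_spec):
    with pytest.raises(ValueError, match="no selection"):
        selsim.simulate_selected_pair(tiny_spec, tiny_spec.pair_ages[0], 1)


def test_complete_linkage_single_segment(selection_spec):
    spec = ScenarioSpec(
        label="sel", N_e=1000, rec=0.0, mu=5e-6, seq_length_bp=5000,
        selection=dataclasses.replace(selection_spec, s_hom=1.0, s_het=0.5),
        gene_flow_mode="recent", migration_4Nm=0.1,
    )
    segments = selsim.simulate_selected_pair(spec, spec.pair_ages[0], 7)
    assert len(segments) == 1
    assert segments[0].interval_bp == (0, 5000)


def test_neutral_coefficients_reduce_to_neutral_coalescent():
    """With s = 0 everywhere the conditioned engine must be the plain
    two-deme coalescent: TMRCA distribution matches the neutral engine."""
    from divergenome import coalsim

    N = 500
    neutral_sel = ScenarioSpec(
        label="s0", N_e=N, pair_age_factors=(4,), samples_per_species=2,
        seq_length_bp=100, mu=0.0, rec=0.0, gene_flow_mode="early",
        migration_4Nm=1.0, selection=SelectionSpec(0.0, 0.0, 0.0),
    )
    rng = np.random.default_rng(5)
    own = np.array(
        [
            selsim.simulate_single_locus_genealogy(
                neutral_sel, neutral_sel.pair_ages[0], rng
            ).tmrca(0, 2)
            for _ in range(3000)
        ]
    )
    msp = np.array(
        [
            coalsim.simulate_pair_ts(
                dataclasses.replace(neutral_sel, selection=None),
                neutral_sel.pair_ages[0],
                10 + i,
            )
            .first()
            .tmrca(0, 2)
            for i in range(3000)
        ]
    )
    assert stats.ks_2samp(own, msp).pvalue > 0.01


def test_fst_declines_with_distance_from_selected_locus(selection_spec):
    """Linked selection with recent gene flow protects nearby windows:
    mean F_ST next to the locus exceeds the farthest window's."""
    spec = ScenarioSpec(
        label="sel", N_e=10_000, mu=5e-7, rec=1e-6, seq_length_bp=50_000,
        gene_flow_mode="recent", migration_4Nm=1.0,
        selection=dataclasses.replace(selection_spec, s_hom=1.0, s_het=0.5),
    )
    age = 8 * spec.N_e
    near, far = [], []
    for rep in range(30):
        segments = selsim.simulate_selected_pair(spec, age, 100 + rep)
        aln = jcmut.evolve_sequences(segments, spec.mu, 900 + rep)
        scan = winstats.window_table(aln, window_bp=500)
        fst = scan.fst
        near.append(np.nanmean(fst[:5]))
        far.append(np.nanmean(fst[-5:]))
    near, far = np.array(near), np.array(far)
    res = stats.ttest_ind(near, far, alternative="greater")
    assert res.pvalue < 0.01
    assert np.nanmean(near) > np.nanmean(far)


def test_strong_selection_guard_rejects_weak_selection():
    spec = ScenarioSpec(
        label="weak", N_e=1000, gene_flow_mode="recent", migration_4Nm=1.0,
        selection=SelectionSpec(s_hom=2e-3, s_het=1e-3), mu=5e-6, rec=1e-5,
    )
    with pytest.raises(ValueError, match="not strong"):
        selsim.simulate_selected_pair(spec, spec.pair_ages[0], 1)
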