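"""Window statistics against brute-force pairwise-difference oracles."""

import itertools

import numpy as np
import pytest

from divergenome.jcmut import HaplotypeAlignment
from divergenome.winstats import (
    dxy,
    fixed_differences,
    hudson_fst,
    scan_variants,
    window_table,
)


def brute_force_stats(aln, pops=("p1", "p2")):
    """All-pairs difference counter: (sum_Hw, sum_Hb_poly, dxy, n_fixed).

    Hw averages the two within-population mean pairwise differences per
    site; sums run over polymorphic sites only for the F_ST components.
    """
    r1, r2 = aln.rows_for(pops[0]), aln.rows_for(pops[1])
    s = aln.sequences
    sum_hw = sum_hb = 0.0
    dxy_total = 0.0
    n_fixed = 0
    for j in range(aln.length_bp):
        col = s[:, j]
        hw_vals = []
        for rows in (r1, r2):
            pairs = list(itertools.combinations(rows, 2))
            hw_vals.append(
                np.mean([col[a] != col[b] for a, b in pairs]) if pairs else 0.0
            )
        hb = np.mean([col[a] != col[b] for a in r1 for b in r2])
        dxy_total += hb
        poly = len(set(col[np.concatenate([r1, r2])])) > 1
        if poly:
            sum_hw += 0.5 * (hw_vals[0] + hw_vals[1])
            sum_hb += hb
        set1, set2 = set(col[r1]), set(col[r2])
        if len(set1) == 1 and len(set2) == 1 and set1 != set2:
            n_fixed += 1
    return sum_hw, sum_hb, dxy_total / aln.length_bp, n_fixed


def test_single_fixed_difference_gives_fst_one():
    aln = HaplotypeAlignment.from_strings(["A", "A", "T", "T"], ["p1", "p1", "p2", "p2"])
    assert hudson_fst(aln) == pytest.approx(1.0)
    assert dxy(aln) == pytest.approx(1.0)
    assert fixed_differences(aln) == 1


def test_monomorphic_window_is_undefined():
    aln = HaplotypeAlignment.from_strings(["AAA"] * 4, ["p1", "p1", "p2", "p2"])
    assert np.isnan(hudson_fst(aln))
    assert dxy(aln) == 0.0
    assert fixed_differences(aln) == 0


def test_toy_alignment_matches_brute_force(toy_alignment):
    sum_hw, sum_hb, d, n_fixed = brute_force_stats(toy_alignment)
    assert hudson_fst(toy_alignment) == pytest.approx(1 - sum_hw / sum_hb)
    assert dxy(toy_alignment) == pytest.approx(d)
    assert fixed_differences(toy_alignment) == n_fixed == 2


def test_random_alignment_matches_brute_force():
    rng = np.random.default_rng(7)
    seqs = rng.integers(0, 4, size=(8, 40)).astype(np.uint8)
    aln = HaplotypeAlignment(seqs, np.array(["p1"] * 4 + ["p2"] * 4, dtype=object))
    sum_hw, sum_hb, d, n_fixed = brute_force_stats(aln)
    assert hudson_fst(aln) == pytest.approx(1 - sum_hw / sum_hb)
    assert dxy(aln) == pytest.approx(d)
    assert fixed_differences(aln) == n_fixed


def test_identical_frequency_pops_near_zero_fst_at_large_n():
    # with identical allele frequencies the estimator sits near 0; the
    # small-sample value is slightly negative (n vs n-1 denominators)
    col = np.array([0] * 50 + [3] * 50 + [0] * 50 + [3] * 50, dtype=np.uint8)
    aln = HaplotypeAlignment(
        col[:, None], np.array(["p1"] * 100 + ["p2"] * 100, dtype=object)
    )
    assert abs(hudson_fst(aln)) < 0.02


def test_within_pop_polymorphism_excludes_fixed_difference():
    aln = HaplotypeAlignment.from_strings(
        ["A", "A", "A", "T", "C", "C", "C", "C"], ["p1"] * 4 + ["p2"] * 4
    )
    assert fixed_differences(aln) == 0


def test_window_count_100kb():
    rng = np.random.default_rng(1)
    seqs = rng.integers(0, 4, size=(4, 100_000)).astype(np.uint8)
    aln = HaplotypeAlignment(seqs, np.array(["p1", "p1", "p2", "p2"], dtype=object))
    scan = window_table(aln, window_bp=500)
    assert len(scan.windows) == 200
    assert scan.windows["end_bp"].iloc[-1] == 100_000


def test_two_windows_for_1kb():
    rng = np.random.default_rng(2)
    seqs = rng.integers(0, 4, size=(4, 1000)).astype(np.uint8)
    aln = HaplotypeAlignment(seqs, np.array(["p1", "p1", "p2", "p2"], dtype=object))
    scan = window_table(aln, window_bp=500)
    assert list(scan.windows["start_bp"]) == [0, 500]
    assert list(scan.windows["end_bp"]) == [500, 1000]


def test_row_permutation_leaves_table_unchanged():
    rng = np.random.default_rng(3)
    seqs = rng.integers(0, 4, size=(8, 2000)).astype(np.uint8)
    pops = np.array(["p1"] * 4 + ["p2"] * 4, dtype=object)
    aln = HaplotypeAlignment(seqs, pops)
    perm = rng.permutation(8)
    aln2 = HaplotypeAlignment(seqs[perm], pops[perm])
    t1 = window_table(aln).windows
    t2 = window_table(aln2).windows
    np.testing.assert_allclose(
        t1["fst"].to_numpy(), t2["fst"].to_numpy(), equal_nan=True
    )
    np.testing.assert_array_equal(t1["n_fixed"], t2["n_fixed"])


def test_windowed_dxy_averages_to_global_dxy():
    rng = np.random.default_rng(4)
    seqs = rng.integers(0, 4, size=(8, 3000)).astype(np.uint8)
    aln = HaplotypeAlignment(seqs, np.array(["p1"] * 4 + ["p2"] * 4, dtype=object))
    scan = window_table(aln, window_bp=500)
    lengths = (scan.windows["end_bp"] - scan.windows["start_bp"]).to_numpy()
    recomposed = float((scan.windows["dxy"].to_numpy() * lengths).sum() / 3000)
    assert recomposed == pytest.approx(dxy(aln), abs=1e-12)


def test_scan_variants_matches_window_table():
    """The variant-matrix fast path must agree with the alignment path."""
    rng = np.random.default_rng(5)
    seqs = rng.integers(0, 2, size=(8, 4000)).astype(np.uint8)  # many invariant
    seqs[:, rng.random(4000) < 0.9] = 0
    aln = HaplotypeAlignment(seqs, np.array(["p1"] * 4 + ["p2"] * 4, dtype=object))
    full = window_table(aln, window_bp=500)
    variable = np.flatnonzero((seqs != seqs[0]).any(axis=0))
    fast = scan_variants(variable, seqs[:, variable].T, 4, 4, 4000, 500)
    np.testing.assert_allclose(
        full.windows["fst"], fast.windows["fst"], equal_nan=True
    )
    np.testing.assert_allclose(full.windows["dxy"], fast.windows["dxy"])
    assert full.global_fst == pytest.approx(fast.global_fst, nan_ok=True)


def test_requires_exactly_two_populations():
    aln = HaplotypeAlignment.from_strings(["AC", "AG", "CT"], ["a", "b", "c"])
    with pytest.raises(ValueError, match="two populations"):
        hudson_fst(aln)
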