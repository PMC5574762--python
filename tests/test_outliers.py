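"""Outlier thresholds and the bridged calling rule, with run-scanner oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from divergenome.outliers import (
    OutlierThresholds,
    call_outliers,
    divergent_genome_series,
    pooled_thresholds,
)

THR = OutlierThresholds(q75=0.75, q80=0.80, q95=0.95, q99=0.99)


def brute_force_bridge(fst, q95, q75):
    """Independent run-scanner: strict 95% hits, then promote any maximal
    gap between two hits whose windows all have defined F_ST > q75."""
    n = len(fst)
    flags = [f > q95 if not np.isnan(f) else False for f in fst]
    out = list(flags)
    hits = [i for i, f in enumerate(flags) if f]
    for a, b in zip(hits, hits[1:]):
        gap = list(range(a + 1, b))
        if gap and all(
            (not np.isnan(fst[i])) and fst[i] > q75 for i in gap
        ):
            for i in gap:
                out[i] = True
    return np.array(out)


def test_quantiles_match_order_statistic_interpolation():
    values = np.arange(1.0, 101.0)
    thr = pooled_thresholds([values])
    # linear interpolation of order statistics: position (n-1)*q
    for q, got in [(0.75, thr.q75), (0.80, thr.q80), (0.95, thr.q95), (0.99, thr.q99)]:
        pos = (values.size - 1) * q
        lo, frac = int(np.floor(pos)), pos - int(np.floor(pos))
        expected = values[lo] * (1 - frac) + values[min(lo + 1, 99)] * frac
        assert got == pytest.approx(expected)


def test_constant_pool_gives_equal_quantiles_and_no_outliers():
    vals = np.full(50, 0.3)
    thr = pooled_thresholds([vals, vals])
    assert thr.q75 == thr.q80 == thr.q95 == thr.q99 == pytest.approx(0.3)
    calls = call_outliers(vals, thr, "p95")
    assert calls.count == 0  # strict inequality: ties are not outliers


def test_pooling_is_pair_blind():
    rng = np.random.default_rng(0)
    vals = rng.random(300)
    thr1 = pooled_thresholds([vals[:100], vals[100:200], vals[200:]])
    shuffled = rng.permutation(vals)
    thr2 = pooled_thresholds([shuffled[:50], shuffled[50:]])
    assert thr1 == thr2


def test_undefined_windows_are_rejected_when_nothing_defined():
    with pytest.raises(ValueError):
        pooled_thresholds([np.array([np.nan, np.nan])])


def test_bridge_promotes_fully_supported_gap():
    fst = np.array([0.96, 0.85, 0.85, 0.96])
    calls = call_outliers(fst, THR, "p95_bridge75")
    assert calls.flags.tolist() == [True, True, True, True]
    assert calls.count == 4


def test_bridge_broken_by_low_window():
    fst = np.array([0.96, 0.5, 0.96])
    calls = call_outliers(fst, THR, "p95_bridge75")
    assert calls.flags.tolist() == [True, False, True]


def test_bridge_needs_closing_outlier_at_sequence_end():
    fst = np.array([0.96, 0.85])
    calls = call_outliers(fst, THR, "p95_bridge75")
    assert calls.flags.tolist() == [True, False]


def test_undefined_fst_breaks_bridge():
    fst = np.array([0.96, 0.85, np.nan, 0.85, 0.96])
    calls = call_outliers(fst, THR, "p95_bridge75")
    assert calls.flags.tolist() == [True, False, False, False, True]


@settings(derandomize=True, max_examples=200)
@given(
    st.lists(
        st.one_of(st.floats(0, 1), st.just(float("nan"))), min_size=1, max_size=40
    )
)
def test_bridge_matches_run_scanner_oracle(fst_list):
    fst = np.array(fst_list)
    calls = call_outliers(fst, THR, "p95_bridge75")
    np.testing.assert_array_equal(
        calls.flags, brute_force_bridge(fst, THR.q95, THR.q75)
    )


@settings(derandomize=True, max_examples=200)
@given(st.lists(st.floats(-0.5, 1), min_size=1, max_size=60))
def test_threshold_nesting(fst_list):
    fst = np.array(fst_list)
    p80 = call_outliers(fst, THR, "p80").flags
    p95 = call_outliers(fst, THR, "p95").flags
    p99 = call_outliers(fst, THR, "p99").flags
    bridged = call_outliers(fst, THR, "p95_bridge75").flags
    assert np.all(p99 <= p95) and np.all(p95 <= p80)
    assert np.all(p95 <= bridged)


def test_thresholds_must_be_ordered():
    with pytest.raises(ValueError):
        OutlierThresholds(q75=0.9, q80=0.8, q95=0.95, q99=0.99)


def test_series_axis_in_N_units():
    calls = {
        age: call_outliers(np.array([0.96] * (i + 1)), THR, "p95")
        for i, age in enumerate([2000, 4000, 6000, 8000, 10000, 12000, 14000, 16000])
    }
    x, y = divergent_genome_series(calls, N_e=1000)
    np.testing.assert_allclose(x, [2, 4, 6, 8, 10, 12, 14, 16])
    np.testing.assert_allclose(y, np.arange(1, 9))
    # insertion order of the mapping is irrelevant
    x2, y2 = divergent_genome_series(dict(reversed(list(calls.items()))), 1000)
    np.testing.assert_allclose(y2, y)
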