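"""Pooled-threshold F_ST outlier calling and divergent-genome-size counts.

Thresholds are empirical percentiles (75/80/95/99) of the per-window F_ST
values pooled over *all* sister pairs of one replicate.  A single absolute
threshold shared across pairs is essential: it preserves the effect of
divergence time on F_ST, which is exactly the signal the growth curves
measure.  Setting per-pair thresholds would flatten that signal away.

Rules:

* ``p80`` / ``p95`` / ``p99`` — a window is an outlier iff its F_ST is
  strictly greater than the corresponding pooled percentile.
* ``p95_bridge75`` — the relaxed rule: windows above the 95th percentile
  are outliers, and every maximal run of windows lying between two such
  outliers of the same pair is promoted to outlier status iff all of its
  windows have defined F_ST above the 75th percentile.  Bridges never cross
  pair boundaries and never extend beyond a pair's first or last 95%
  outlier; undefined-F_ST windows break bridges.

Quantiles use linear interpolation of the order statistics (numpy default,
R type 7); the qualitative growth results are threshold-robust, which the
test suite checks at all three strict thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .winstats import WindowScan

__all__ = [
    "OutlierThresholds",
    "OutlierCalls",
    "RULES",
    "pooled_thresholds",
    "call_outliers",
    "divergent_genome_series",
]

RULES = ("p80", "p95", "p99", "p95_bridge75")


@dataclass(frozen=True)
class OutlierThresholds:
    q75: float
    q80: float
    q95: float
    q99: float

    def __post_init__(self) -> None:
        if not self.q75 <= self.q80 <= self.q95 <= self.q99:
            raise ValueError("quantiles must be nondecreasing")


@dataclass
class OutlierCalls:
    flags: np.ndarray  # bool per window
    rule: str

    @property
    def count(self) -> int:
        return int(self.flags.sum())


def _pooled_values(tables: Iterable) -> np.ndarray:
    vals = []
    for t in tables:
        fst = t.defined_fst if isinstance(t, WindowScan) else np.asarray(t, float)
        fst = fst[~np.isnan(fst)]
        vals.append(fst)
    return np.concatenate(vals) if vals else np.array([])


def pooled_thresholds(tables: Iterable) -> OutlierThresholds:
    """Percentile thresholds from the pooled defined F_ST of one replicate.

    ``tables`` may hold :class:`WindowScan` objects or raw F_ST arrays; the
    pooling is pair-blind by construction.
    """
    pooled = _pooled_values(tables)
    if pooled.size == 0:
        raise ValueError("no defined F_ST values to pool")
    q75, q80, q95, q99 = np.quantile(pooled, [0.75, 0.80, 0.95, 0.99])
    return OutlierThresholds(float(q75), float(q80), float(q95), float(q99))


def call_outliers(table, thr: OutlierThresholds, rule: str) -> OutlierCalls:
    """Flag outlier windows of one pair under the given rule."""
    if rule not in RULES:
        raise ValueError(f"rule must be one of {RULES}")
    fst = table.fst if isinstance(table, WindowScan) else np.asarray(table, float)
    with np.errstate(invalid="ignore"):
        if rule == "p80":
            flags = fst > thr.q80
        elif rule == "p99":
            flags = fst > thr.q99
        else:
            flags = fst > thr.q95
    if rule == "p95_bridge75":
        flags = _bridge(fst, flags, thr.q75)
    return OutlierCalls(flags=flags, rule=rule)


def _bridge(fst: np.ndarray, strict: np.ndarray, q75: float) -> np.ndarray:
    """Promote runs between strict outliers whose windows all exceed q75."""
    out = strict.copy()
    hits = np.flatnonzero(strict)
    with np.errstate(invalid="ignore"):
        above75 = fst > q75  # NaN compares False: undefined breaks bridges
    for left, right in zip(hits[:-1], hits[1:]):
        gap = slice(left + 1, right)
        if right - left > 1 and above75[gap].all():
            out[gap] = True
    return out


def divergent_genome_series(
    calls: Mapping[float, OutlierCalls], N_e: float
) -> tuple[np.ndarray, np.ndarray]:
    """(divergence time / N, outlier-window count) for one replicate's pairs.

    The x axis is divergence time in units of N generations (2..16 under the
    default pair ages); growth-curve coefficients are reported on this scale.
    """
    ages = sorted(calls)
    x = np.array([age / N_e for age in ages])
    y = np.array([calls[age].count for age in ages], dtype=float)
    return x, y
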