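"""Windowed population-genetic statistics for one sister pair.

Computes Hudson's F_ST, Nei's d_xy and fixed-difference counts for
nonoverlapping windows (500 bp by default) tiling the sequence, plus the
whole-sequence ("global") F_ST and the mean per-window F_ST.

Hudson's estimator is used in its ratio-of-sums form: within each window,
F_ST = 1 - sum(H_w) / sum(H_b) over the polymorphic sites of the window,
where per site H_w is the mean pairwise difference within populations
(averaging the two within-population values) and H_b the mean pairwise
difference between populations.  Windows with no polymorphic sites, or
where sum(H_b) = 0, have undefined F_ST (NaN); such windows never enter the
pooled outlier-threshold distribution.  Negative F_ST values are retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .jcmut import HaplotypeAlignment

__all__ = [
    "WindowScan",
    "hudson_fst",
    "dxy",
    "fixed_differences",
    "window_table",
    "scan_variants",
]


@dataclass
class WindowScan:
    """Per-window statistics plus the sequence-wide summaries."""

    windows: pd.DataFrame  # window_index, start_bp, end_bp, n_poly, fst, dxy, n_fixed
    global_fst: float
    mean_window_fst: float
    n_undefined: int

    @property
    def fst(self) -> np.ndarray:
        return self.windows["fst"].to_numpy()

    @property
    def defined_fst(self) -> np.ndarray:
        vals = self.fst
        return vals[~np.isnan(vals)]


def _two_pop_rows(aln: HaplotypeAlignment, pops=None):
    labels = list(aln.populations) if pops is None else list(pops)
    if len(labels) != 2:
        raise ValueError(f"exactly two populations required, got {labels}")
    r1, r2 = aln.rows_for(labels[0]), aln.rows_for(labels[1])
    if r1.size == 0 or r2.size == 0:
        raise ValueError("a population has no sampled sequences")
    return r1, r2


def _site_components(seq1: np.ndarray, seq2: np.ndarray):
    """Per-site H_w, H_b and polymorphism/fixed-difference masks.

    seq1/seq2 are (n_i, n_sites) integer matrices (any allele coding).
    """
    n1, n2 = seq1.shape[0], seq2.shape[0]
    n_sites = seq1.shape[1]
    c1 = np.zeros((4, n_sites))
    c2 = np.zeros((4, n_sites))
    # allele codes may exceed 3 for tskit multi-mutation sites; remap lazily
    max_code = int(max(seq1.max(initial=0), seq2.max(initial=0)))
    if max_code > 3:
        c1 = np.zeros((max_code + 1, n_sites))
        c2 = np.zeros((max_code + 1, n_sites))
    for b in range(c1.shape[0]):
        c1[b] = (seq1 == b).sum(axis=0)
        c2[b] = (seq2 == b).sum(axis=0)
    hw1 = 1.0 - (c1 * (c1 - 1)).sum(axis=0) / (n1 * (n1 - 1))
    hw2 = 1.0 - (c2 * (c2 - 1)).sum(axis=0) / (n2 * (n2 - 1))
    hw = 0.5 * (hw1 + hw2)
    hb = 1.0 - (c1 * c2).sum(axis=0) / (n1 * n2)
    pooled = c1 + c2
    poly = (pooled > 0).sum(axis=0) > 1
    mono1 = c1.max(axis=0) == n1
    mono2 = c2.max(axis=0) == n2
    fixed = mono1 & mono2 & (c1.argmax(axis=0) != c2.argmax(axis=0))
    return hw, hb, poly, fixed


def hudson_fst(aln: HaplotypeAlignment, pops=None) -> float:
    """Hudson F_ST of the whole (sliced) alignment; NaN when undefined."""
    r1, r2 = _two_pop_rows(aln, pops)
    hw, hb, poly, _ = _site_components(aln.sequences[r1], aln.sequences[r2])
    denom = hb[poly].sum()
    if denom == 0:
        return float("nan")
    return float(1.0 - hw[poly].sum() / denom)


def dxy(aln: HaplotypeAlignment, pops=None) -> float:
    """Mean per-site between-population divergence of the alignment."""
    r1, r2 = _two_pop_rows(aln, pops)
    _, hb, _, _ = _site_components(aln.sequences[r1], aln.sequences[r2])
    return float(hb.sum() / aln.length_bp) if aln.length_bp else 0.0


def fixed_differences(aln: HaplotypeAlignment, pops=None, region=None) -> int:
    """Sites monomorphic within each species but for different bases."""
    if region is not None:
        aln = aln.slice(*region)
    r1, r2 = _two_pop_rows(aln, pops)
    _, _, _, fixed = _site_components(aln.sequences[r1], aln.sequences[r2])
    return int(fixed.sum())


def scan_variants(
    positions: np.ndarray,
    genotypes: np.ndarray,
    n1: int,
    n2: int,
    seq_length_bp: int,
    window_bp: int = 500,
) -> WindowScan:
    """Windowed scan from segregating sites only (fast path).

    ``genotypes`` is (n_sites, n1+n2) with species-1 haplotypes in the first
    ``n1`` columns.  Sites absent from ``positions`` are treated as
    monomorphic, which contributes nothing to any statistic except the d_xy
    denominator (the window length).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    n_windows = int(np.ceil(seq_length_bp / window_bp))
    starts = np.arange(n_windows, dtype=np.int64) * window_bp
    ends = np.minimum(starts + window_bp, seq_length_bp)

    if positions.size:
        hw, hb, poly, fixed = _site_components(
            genotypes[:, :n1].T, genotypes[:, n1:].T
        )
        win = positions // window_bp
        sum_hw = np.bincount(
            win[poly], weights=hw[poly], minlength=n_windows
        )
        sum_hb = np.bincount(
            win[poly], weights=hb[poly], minlength=n_windows
        )
        sum_hb_all = np.bincount(win, weights=hb, minlength=n_windows)
        n_poly = np.bincount(win[poly], minlength=n_windows)
        n_fixed = np.bincount(win[fixed], minlength=n_windows)
        tot_hw, tot_hb = hw[poly].sum(), hb[poly].sum()
    else:
        sum_hw = sum_hb = sum_hb_all = np.zeros(n_windows)
        n_poly = n_fixed = np.zeros(n_windows, dtype=np.int64)
        tot_hw = tot_hb = 0.0

    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(sum_hb > 0, 1.0 - sum_hw / np.where(sum_hb > 0, sum_hb, 1), np.nan)
    dxy_w = sum_hb_all / (ends - starts)
    global_fst = float(1.0 - tot_hw / tot_hb) if tot_hb > 0 else float("nan")

    table = pd.DataFrame(
        {
            "window_index": np.arange(n_windows),
            "start_bp": starts,
            "end_bp": ends,
            "n_poly": n_poly.astype(np.int64),
            "fst": fst,
            "dxy": dxy_w,
            "n_fixed": n_fixed.astype(np.int64),
        }
    )
    defined = fst[~np.isnan(fst)]
    return WindowScan(
        windows=table,
        global_fst=global_fst,
        mean_window_fst=float(defined.mean()) if defined.size else float("nan"),
        n_undefined=int(np.isnan(fst).sum()),
    )


def window_table(
    aln: HaplotypeAlignment, pops=None, window_bp: int = 500
) -> WindowScan:
    """Windowed F_ST / d_xy / fixed-difference scan of an alignment."""
    r1, r2 = _two_pop_rows(aln, pops)
    seqs = aln.sequences[np.concatenate([r1, r2])]
    variable = (seqs != seqs[0]).any(axis=0)
    positions = np.flatnonzero(variable)
    genotypes = seqs[:, positions].T
    return scan_variants(
        positions, genotypes, r1.size, r2.size, aln.length_bp, window_bp
    )
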