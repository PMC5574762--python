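"""Cross-scenario statistics on exponential growth coefficients.

One-way fixed-effects ANOVA compares the fitted coefficients b among
gene-flow scenarios; Tukey's honestly-significant-difference test provides
all-pairs comparisons with family-wise error control (reported both as
adjusted p-values and as compact "significance letters": scenarios sharing
a letter are not significantly different); bias-corrected and accelerated
(BCa) bootstrap intervals summarize each scenario's mean coefficient.
Scenarios where the exponential fit mostly failed to converge (high recent
gene flow) are excluded from these comparisons by the caller, with counts
kept in the scenario summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ScenarioSummary",
    "anova_coefficients",
    "tukey_hsd",
    "TukeyResult",
    "bca_ci",
    "summarize_scenario",
]


@dataclass
class ScenarioSummary:
    label: str
    b_values: np.ndarray
    mean: float
    sd: float
    bca_ci_95: tuple[float, float]
    n_converged: int
    n_total: int

    def __post_init__(self) -> None:
        lo, hi = self.bca_ci_95
        if lo > hi:
            raise ValueError("interval endpoints out of order")
        if self.n_converged > self.n_total:
            raise ValueError("n_converged cannot exceed n_total")


def _check_groups(groups: Mapping[str, Sequence[float]]):
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {}
    for label, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {label!r} has fewer than 2 values")
        arrays[label] = arr
    return arrays


def anova_coefficients(groups: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA over scenario coefficient groups.

    Returns (F, p).  When the within-group mean square is exactly zero but
    groups differ, F is reported as +inf with p = 0 (perfect separation).
    """
    arrays = _check_groups(groups)
    vals = list(arrays.values())
    within_ss = sum(((v - v.mean()) ** 2).sum() for v in vals)
    grand = np.concatenate(vals).mean()
    between_ss = sum(v.size * (v.mean() - grand) ** 2 for v in vals)
    if within_ss == 0:
        if between_ss == 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f, p = stats.f_oneway(*vals)
    return float(f), float(p)


@dataclass
class TukeyResult:
    labels: list[str]
    p_adjusted: dict[tuple[str, str], float]
    letters: dict[str, str]

    def significant_pairs(self, alpha: float = 0.05) -> list[tuple[str, str]]:
        return [pair for pair, p in self.p_adjusted.items() if p < alpha]


def _compact_letters(
    labels: list[str], not_different: dict[tuple[str, str], bool]
) -> dict[str, str]:
    """Compact letter display: maximal cliques of the 'not significantly
    different' graph, one letter per clique, in group order."""
    n = len(labels)
    adj = [set() for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if not_different[(labels[i], labels[j])]:
                adj[i].add(j)
                adj[j].add(i)

    cliques: list[set[int]] = []

    def bron_kerbosch(r: set[int], p: set[int], x: set[int]) -> None:
        if not p and not x:
            cliques.append(r)
            return
        for v in list(p):
            bron_kerbosch(r | {v}, p & adj[v], x & adj[v])
            p.remove(v)
            x.add(v)

    bron_kerbosch(set(), set(range(n)), set())
    cliques.sort(key=lambda c: min(c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lab: "" for lab in labels}
    for letter, clique in zip(alphabet, cliques):
        for i in sorted(clique):
            out[labels[i]] += letter
    return out


def tukey_hsd(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> TukeyResult:
    """All-pairs Tukey HSD with adjusted p-values and significance letters."""
    arrays = _check_groups(groups)
    labels = list(arrays)
    vals = [arrays[lab] for lab in labels]
    if np.ptp(np.concatenate(vals)) == 0:
        # identical constant data: nothing distinguishes any pair
        p_adj = {
            (labels[i], labels[j]): 1.0
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        }
    else:
        res = stats.tukey_hsd(*vals)
        p_adj = {
            (labels[i], labels[j]): float(res.pvalue[i, j])
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        }
    not_diff = {pair: p >= alpha for pair, p in p_adj.items()}
    letters = _compact_letters(labels, not_diff)
    return TukeyResult(labels=labels, p_adjusted=p_adj, letters=letters)


def bca_ci(
    values: Sequence[float],
    n_boot: int = 10_000,
    level: float = 0.95,
    rng_seed: int | None = None,
    accelerated: bool = True,
) -> tuple[float, float]:
    """Bias-corrected (and optionally accelerated) bootstrap CI of the mean.

    ``accelerated=False`` gives the plain bias-corrected (BC) interval.
    Constant input yields the degenerate zero-width interval at the value.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 3:
        raise ValueError("need at least 3 values")
    if np.ptp(vals) == 0:
        v = float(vals[0])
        return v, v
    rng = np.random.default_rng(rng_seed)
    n = vals.size
    theta_hat = vals.mean()
    boot = vals[rng.integers(0, n, size=(n_boot, n))].mean(axis=1)

    prop = (np.sum(boot < theta_hat) + 0.5 * np.sum(boot == theta_hat)) / n_boot
    prop = min(max(prop, 1.0 / (2 * n_boot)), 1 - 1.0 / (2 * n_boot))
    z0 = stats.norm.ppf(prop)

    if accelerated:
        jack = (vals.sum() - vals) / (n - 1)  # leave-one-out means
        d = jack.mean() - jack
        denom = (d**2).sum() ** 1.5
        a = (d**3).sum() / (6 * denom) if denom > 0 else 0.0
    else:
        a = 0.0

    alpha = 1 - level
    out = []
    for z_alpha in (stats.norm.ppf(alpha / 2), stats.norm.ppf(1 - alpha / 2)):
        adj = stats.norm.cdf(z0 + (z0 + z_alpha) / (1 - a * (z0 + z_alpha)))
        out.append(float(np.quantile(boot, adj)))
    lo, hi = sorted(out)
    return lo, hi


def summarize_scenario(
    label: str,
    b_values: Sequence[float],
    n_total: int,
    n_boot: int = 10_000,
    rng_seed: int | None = None,
) -> ScenarioSummary:
    vals = np.asarray(b_values, dtype=float)
    ci = bca_ci(vals, n_boot=n_boot, rng_seed=rng_seed) if vals.size >= 3 else (
        float("nan"),
        float("nan"),
    )
    return ScenarioSummary(
        label=label,
        b_values=vals,
        mean=float(vals.mean()) if vals.size else float("nan"),
        sd=float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
        bca_ci_95=ci,
        n_converged=int(vals.size),
        n_total=int(n_total),
    )
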