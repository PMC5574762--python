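"""End-to-end experiment harness: simulate -> mutate -> scan -> count -> fit.

A replicate simulates all eight sister pairs of one scenario, overlays
finite-sites JC69 mutations, computes 500-bp-window Hudson F_ST scans,
pools the windows of all pairs to set percentile outlier thresholds, counts
outlier windows per pair (default rule: 95th percentile with 75th-percentile
bridging), and fits the linear and exponential growth curves to the
(divergence time / N, count) series.  A scenario is ``n_replicates`` such
replicates; an experiment is a set of scenarios compared with ANOVA /
Tukey HSD / BCa intervals on the exponential coefficients.

Everything is deterministic given the configuration and master seed: every
stage of every (scenario, replicate, pair) derives its own seed by hashing,
so any subset reruns identically.  A failed replicate is recorded and
skipped, never imputed.

Desk scaling: scenarios are specified at their nominal parameters
(N = 10**6 by default) and rescaled by the configuration's scale factor c
(N/c, mutation and recombination rates x c), which preserves 4Nmu, 4Nrec,
T/N, 4Nm and the selection ratios, and therefore the distribution of every
statistic computed here.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coalsim, compare, formats, growthfit, jcmut, outliers, selsim, winstats
from ._seeds import derive_seed
from .coalsim import ScenarioSpec
from .selsim import SelectionSpec

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "ReplicateResult",
    "ScenarioResult",
    "ExperimentResult",
    "run_replicate",
    "run_scenario",
    "run_experiment",
    "paper_scenario",
]


@dataclass(frozen=True)
class ExperimentConfig:
    scenarios: tuple[ScenarioSpec, ...]
    window_bp: int = 500
    rule: str = "p95_bridge75"
    master_seed: int = 1
    scale: float = 100.0
    out_dir: str | None = None
    write_alignments: bool = False

    def __post_init__(self) -> None:
        labels = [s.label for s in self.scenarios]
        if len(set(labels)) != len(labels):
            raise ValueError("scenario labels must be unique")
        if self.scale <= 0:
            raise ValueError("scale factor must be positive")
        if self.rule not in outliers.RULES:
            raise ValueError(f"rule must be one of {outliers.RULES}")


@dataclass
class ReplicateResult:
    index: int
    thresholds: outliers.OutlierThresholds | None
    pair_scans: dict[float, winstats.WindowScan]
    calls: dict[float, outliers.OutlierCalls]
    x: np.ndarray
    y: np.ndarray
    fit_linear: growthfit.GrowthFit | None
    fit_exponential: growthfit.GrowthFit | None
    error: str | None = None

    @property
    def delta_aic(self) -> float | None:
        if (
            self.fit_linear is None
            or self.fit_exponential is None
            or not (self.fit_linear.converged and self.fit_exponential.converged)
        ):
            return None
        return growthfit.compare_aic(self.fit_linear, self.fit_exponential)


@dataclass
class ScenarioResult:
    spec: ScenarioSpec
    replicates: list[ReplicateResult] = field(default_factory=list)

    @property
    def label(self) -> str:
        return self.spec.label

    @property
    def ok_replicates(self) -> list[ReplicateResult]:
        return [r for r in self.replicates if r.error is None]

    @property
    def b_values(self) -> np.ndarray:
        """Exponential coefficients of the converged fits."""
        return np.array(
            [
                r.fit_exponential.params["b"]
                for r in self.ok_replicates
                if r.fit_exponential is not None and r.fit_exponential.converged
            ]
        )

    @property
    def delta_aics(self) -> np.ndarray:
        return np.array(
            [r.delta_aic for r in self.ok_replicates if r.delta_aic is not None]
        )

    @property
    def n_nonconverged(self) -> int:
        return sum(
            1
            for r in self.ok_replicates
            if r.fit_exponential is not None and not r.fit_exponential.converged
        )

    @property
    def n_saturating(self) -> int:
        return sum(
            1
            for r in self.ok_replicates
            if r.fit_exponential is not None and r.fit_exponential.saturating
        )

    def summary(self, rng_seed: int | None = None) -> compare.ScenarioSummary:
        return compare.summarize_scenario(
            self.label, self.b_values, len(self.ok_replicates), rng_seed=rng_seed
        )


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    scenarios: dict[str, ScenarioResult]
    anova: tuple[float, float] | None = None
    tukey: compare.TukeyResult | None = None
    summaries: dict[str, compare.ScenarioSummary] = field(default_factory=dict)


def _scan_pair(
    spec: ScenarioSpec,
    pair_age: float,
    window_bp: int,
    seed_ancestry: int,
    seed_mutation: int,
    keep_alignment: bool = False,
):
    """Simulate and scan one sister pair; returns (scan, alignment|None)."""
    n = spec.samples_per_species
    if spec.selection is not None:
        segments = selsim.simulate_selected_pair(
            spec, pair_age, seed_ancestry, window_bp=window_bp
        )
        aln = jcmut.evolve_sequences(segments, spec.mu, seed_mutation)
        scan = winstats.window_table(aln, window_bp=window_bp)
        return scan, (aln if keep_alignment else None)
    ts = coalsim.simulate_pair_ts(spec, pair_age, seed_ancestry)
    mts = jcmut.mutate_tree_sequence(ts, spec.mu, seed_mutation)
    positions, geno = jcmut.variant_matrix(mts)
    scan = winstats.scan_variants(
        positions, geno, n, n, spec.seq_length_bp, window_bp
    )
    aln = None
    if keep_alignment:
        aln = jcmut.alignment_from_tree_sequence(
            mts, coalsim.leaf_labels(spec), seed_mutation
        )
    return scan, aln


def run_replicate(
    spec: ScenarioSpec,
    rep_index: int,
    master_seed: int,
    window_bp: int = 500,
    rule: str = "p95_bridge75",
    keep_alignments: bool = False,
) -> tuple[ReplicateResult, dict[float, object]]:
    """One full replicate of one scenario; returns (result, alignments)."""
    scans: dict[float, winstats.WindowScan] = {}
    alignments: dict[float, object] = {}
    for pair_idx, age in enumerate(spec.pair_ages):
        seed_anc = derive_seed(master_seed, spec.label, rep_index, pair_idx, "ancestry")
        seed_mut = derive_seed(master_seed, spec.label, rep_index, pair_idx, "mutation")
        scan, aln = _scan_pair(
            spec, age, window_bp, seed_anc, seed_mut, keep_alignment=keep_alignments
        )
        scans[age] = scan
        if aln is not None:
            alignments[age] = aln
    thresholds = outliers.pooled_thresholds(scans.values())
    calls = {
        age: outliers.call_outliers(scan, thresholds, rule)
        for age, scan in scans.items()
    }
    x, y = outliers.divergent_genome_series(calls, spec.N_e)
    fit_lin = growthfit.fit_linear_origin(x, y)
    fit_exp = growthfit.fit_exponential_origin(x, y)
    result = ReplicateResult(
        index=rep_index,
        thresholds=thresholds,
        pair_scans=scans,
        calls=calls,
        x=x,
        y=y,
        fit_linear=fit_lin,
        fit_exponential=fit_exp,
    )
    return result, alignments


def run_scenario(
    spec: ScenarioSpec,
    master_seed: int,
    window_bp: int = 500,
    rule: str = "p95_bridge75",
    n_replicates: int | None = None,
) -> ScenarioResult:
    """All replicates of one scenario (already at the desired scale)."""
    n_reps = spec.n_replicates if n_replicates is None else n_replicates
    out = ScenarioResult(spec=spec)
    t0 = time.time()
    for rep in range(n_reps):
        try:
            result, _ = run_replicate(spec, rep, master_seed, window_bp, rule)
        except Exception as exc:  # record-and-skip policy for partial failure
            logger.exception("replicate %d of %s failed", rep, spec.label)
            result = ReplicateResult(
                index=rep,
                thresholds=None,
                pair_scans={},
                calls={},
                x=np.array([]),
                y=np.array([]),
                fit_linear=None,
                fit_exponential=None,
                error=f"{type(exc).__name__}: {exc}",
            )
        out.replicates.append(result)
    logger.info(
        "scenario %s: %d replicates in %.1fs; %d b-values, %d nonconverged",
        spec.label,
        n_reps,
        time.time() - t0,
        out.b_values.size,
        out.n_nonconverged,
    )
    return out


def replicate_frame(spec: ScenarioSpec, rep: ReplicateResult) -> pd.DataFrame:
    """Window table of one replicate with scenario/pair annotations."""
    frames = []
    for age, scan in rep.pair_scans.items():
        df = scan.windows.copy()
        df.insert(0, "scenario", spec.label)
        df.insert(1, "replicate", rep.index)
        df.insert(2, "pair_age_N", age / spec.N_e)
        df["outlier"] = rep.calls[age].flags if age in rep.calls else False
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def fits_frame(result: ScenarioResult) -> pd.DataFrame:
    rows = []
    for rep in result.ok_replicates:
        for fit in (rep.fit_linear, rep.fit_exponential):
            if fit is None:
                continue
            rows.append(
                {
                    "scenario": result.label,
                    "replicate": rep.index,
                    "model": fit.model,
                    "a": fit.params.get("a", np.nan),
                    "b": fit.params.get("b", np.nan),
                    "c": fit.params.get("c", np.nan),
                    "rss": fit.rss,
                    "aic": fit.aic if fit.converged else np.nan,
                    "converged": fit.converged,
                }
            )
    return pd.DataFrame(rows)


def series_frame(result: ScenarioResult) -> pd.DataFrame:
    rows = []
    for rep in result.ok_replicates:
        for xi, yi in zip(rep.x, rep.y):
            rows.append(
                {
                    "scenario": result.label,
                    "replicate": rep.index,
                    "age_N": xi,
                    "outlier_windows": int(yi),
                }
            )
    return pd.DataFrame(rows)


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run every scenario of the experiment and the cross-scenario stats.

    Scenarios are rescaled by ``config.scale`` before simulation.  When
    ``out_dir`` is set, window tables, growth series, fits, outlier BED
    tracks and scenario summaries are written as text files (FASTA
    alignments too when ``write_alignments`` is on).
    """
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    results: dict[str, ScenarioResult] = {}
    for spec in config.scenarios:
        scaled = spec.rescaled(config.scale)
        scaled.check_window(config.window_bp)
        res = run_scenario(
            scaled, config.master_seed, config.window_bp, config.rule
        )
        results[spec.label] = res
        if out_dir:
            _write_scenario(out_dir, res, config)

    summaries = {
        label: res.summary(rng_seed=derive_seed(config.master_seed, label, "bca"))
        for label, res in results.items()
    }
    groups = {
        label: res.b_values
        for label, res in results.items()
        # scenarios with majority nonconvergence are excluded, as the
        # coefficient is not meaningfully defined there
        if res.b_values.size >= 2
        and res.b_values.size >= 0.5 * max(len(res.ok_replicates), 1)
    }
    anova = tukey = None
    if len(groups) >= 2:
        anova = compare.anova_coefficients(groups)
        tukey = compare.tukey_hsd(groups)
    exp_result = ExperimentResult(
        config=config,
        scenarios=results,
        anova=anova,
        tukey=tukey,
        summaries=summaries,
    )
    if out_dir:
        _write_summary(out_dir, exp_result)
    return exp_result


def _write_scenario(
    out_dir: Path, res: ScenarioResult, config: ExperimentConfig
) -> None:
    sdir = out_dir / res.label
    sdir.mkdir(parents=True, exist_ok=True)
    windows = [replicate_frame(res.spec, rep) for rep in res.ok_replicates]
    if windows:
        pd.concat(windows, ignore_index=True).to_csv(
            sdir / "windows.tsv", sep="\t", index=False
        )
    fits_frame(res).to_csv(sdir / "fits.tsv", sep="\t", index=False)
    series_frame(res).to_csv(sdir / "series.tsv", sep="\t", index=False)
    for rep in res.ok_replicates:
        for age, scan in rep.pair_scans.items():
            calls = rep.calls[age]
            if calls.count:
                formats.write_outliers_bed(
                    scan,
                    calls,
                    sdir / f"rep{rep.index}_age{age / res.spec.N_e:g}N_outliers.bed",
                )
    if config.write_alignments:
        for rep_idx in range(len(res.replicates)):
            _, alns = run_replicate(
                res.spec,
                rep_idx,
                config.master_seed,
                config.window_bp,
                config.rule,
                keep_alignments=True,
            )
            for age, aln in alns.items():
                formats.write_fasta(
                    aln, sdir / f"rep{rep_idx}_age{age / res.spec.N_e:g}N.fasta"
                )


def _write_summary(out_dir: Path, result: ExperimentResult) -> None:
    rows = []
    for label, summ in result.summaries.items():
        res = result.scenarios[label]
        rows.append(
            {
                "scenario": label,
                "n_replicates": len(res.ok_replicates),
                "n_converged": summ.n_converged,
                "n_nonconverged": res.n_nonconverged,
                "n_saturating": res.n_saturating,
                "b_mean": summ.mean,
                "b_sd": summ.sd,
                "b_ci_lo": summ.bca_ci_95[0],
                "b_ci_hi": summ.bca_ci_95[1],
                "letters": result.tukey.letters.get(label, "")
                if result.tukey
                else "",
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "summary.tsv", sep="\t", index=False)
    if result.anova is not None:
        with open(out_dir / "anova.txt", "w") as fh:
            fh.write(f"F = {result.anova[0]:.4g}\np = {result.anova[1]:.4g}\n")


def paper_scenario(
    gene_flow_mode: str,
    migration_4Nm: float = 0.0,
    selection: bool = False,
    label: str | None = None,
    n_replicates: int = 30,
    seq_length_bp: int = 100_000,
    direction: str = "unidirectional",
) -> ScenarioSpec:
    """A scenario of the headline study grid at nominal parameters.

    N = 10**6, eight pair ages 2N..16N, 10 sequences per species,
    mu = 5e-9, rec = 1e-8; selection (when on) is the semidominant
    divergent scheme s = 0.01 / 0.005 / 0 at a locus adjacent to the
    region.  Rescale via :meth:`ScenarioSpec.rescaled` or let
    :func:`run_experiment` do it.
    """
    if label is None:
        label = gene_flow_mode
        if migration_4Nm:
            label += f"_4Nm{migration_4Nm:g}"
        if selection:
            label += "_sel"
    return ScenarioSpec(
        label=label,
        gene_flow_mode=gene_flow_mode,
        migration_4Nm=migration_4Nm,
        selection=SelectionSpec() if selection else None,
        n_replicates=n_replicates,
        seq_length_bp=seq_length_bp,
        direction=direction,
    )
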