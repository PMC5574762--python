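"""Readers and writers for the interchange formats of the pipeline.

FASTA carries alignments (headers encode the population as
``species|sample_index``); ms-style 0/1 blocks carry biallelic haplotype
matrices for interoperability with classic popgen tooling; Newick carries
per-interval genealogies; BED carries window scans and outlier tracks; YAML
carries scenario configuration.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .jcmut import BASES, HaplotypeAlignment
from .trees import GenealogySegment

logger = logging.getLogger(__name__)

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_ms",
    "write_newick",
    "write_windows_bed",
    "write_outliers_bed",
    "scenario_to_yaml",
    "scenario_from_yaml",
]


def write_fasta(aln: HaplotypeAlignment, path) -> None:
    """Write an alignment with ``species|index`` headers."""
    counters: dict[str, int] = {}
    records = []
    for row, pop in zip(aln.sequences, aln.pop_labels):
        idx = counters.get(pop, 0)
        counters[pop] = idx + 1
        seq = BASES[row].tobytes().decode("ascii")
        records.append(SeqRecord(Seq(seq), id=f"{pop}|{idx}", description=""))
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> HaplotypeAlignment:
    """Read an alignment written by :func:`write_fasta` (lossless round
    trip; lowercase bases are normalized to uppercase)."""
    seqs: list[str] = []
    pops: list[str] = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        s = str(rec.seq).upper()
        if seqs and len(s) != len(seqs[0]):
            raise ValueError(
                f"ragged alignment in {path}: record {i} ({rec.id!r}) has "
                f"length {len(s)}, expected {len(seqs[0])}"
            )
        seqs.append(s)
        pops.append(rec.id.split("|")[0])
    if not seqs:
        return HaplotypeAlignment(
            np.zeros((0, 0), dtype=np.uint8), np.array([], dtype=object)
        )
    return HaplotypeAlignment.from_strings(seqs, pops)


def write_ms(aln: HaplotypeAlignment, path, command: str = "divergenome") -> int:
    """Write the biallelic segregating sites as an ms-style block.

    Sites with more than two alleles cannot be represented in the 0/1
    matrix; they are dropped with a logged count (returned for inspection).
    The ancestral (0) state is the first population's majority base.
    """
    seqs = aln.sequences
    L = aln.length_bp
    present = np.stack([(seqs == b).any(axis=0) for b in range(4)])
    n_alleles = present.sum(axis=0)
    biallelic = np.flatnonzero(n_alleles == 2)
    dropped = int((n_alleles > 2).sum())
    if dropped:
        logger.info("write_ms: dropped %d sites with >2 alleles", dropped)
    with open(path, "w") as fh:
        fh.write(f"{command}\n1 2 3\n\n//\n")
        fh.write(f"segsites: {biallelic.size}\n")
        if biallelic.size:
            positions = (biallelic + 0.5) / L
            fh.write(
                "positions: " + " ".join(f"{p:.6f}" for p in positions) + "\n"
            )
            sub = seqs[:, biallelic]
            ref = sub[0]
            for row in sub:
                fh.write("".join("01"[int(b != r)] for b, r in zip(row, ref)) + "\n")
        else:
            fh.write("positions:\n")
    return dropped


def write_newick(segments: Iterable[GenealogySegment], path) -> None:
    """One newick per line, branch lengths in generations, with the
    half-open bp interval in a leading comment field."""
    with open(path, "w") as fh:
        for seg in segments:
            start, end = seg.interval_bp
            fh.write(f"[&interval={start}-{end}]" + seg.tree.to_newick() + "\n")


def write_windows_bed(scan, path, chrom: str = "sim") -> None:
    """Windows as BED (0-based half-open) with F_ST x 1000 in the score."""
    with open(path, "w") as fh:
        for row in scan.windows.itertuples(index=False):
            score = 0 if np.isnan(row.fst) else int(round(row.fst * 1000))
            fh.write(
                f"{chrom}\t{row.start_bp}\t{row.end_bp}\t"
                f"window_{row.window_index}\t{score}\t+\n"
            )


def write_outliers_bed(scan, calls, path, chrom: str = "sim") -> None:
    """Outlier calls as merged BED intervals."""
    win = scan.windows
    flags = np.asarray(calls.flags, dtype=bool)
    with open(path, "w") as fh:
        start = None
        prev_end = None
        for i, flag in enumerate(flags):
            if flag and start is None:
                start = int(win["start_bp"].iloc[i])
            if flag:
                prev_end = int(win["end_bp"].iloc[i])
            if not flag and start is not None:
                fh.write(f"{chrom}\t{start}\t{prev_end}\t{calls.rule}\n")
                start = None
        if start is not None:
            fh.write(f"{chrom}\t{start}\t{prev_end}\t{calls.rule}\n")


def scenario_to_yaml(spec, path) -> None:
    from .coalsim import ScenarioSpec  # noqa: F401 (documentation import)

    data = {
        "label": spec.label,
        "N_e": spec.N_e,
        "pair_age_factors": list(spec.pair_age_factors),
        "samples_per_species": spec.samples_per_species,
        "seq_length_bp": spec.seq_length_bp,
        "mu": spec.mu,
        "rec": spec.rec,
        "gene_flow_mode": spec.gene_flow_mode,
        "migration_4Nm": spec.migration_4Nm,
        "direction": spec.direction,
        "n_replicates": spec.n_replicates,
        "seed": spec.seed,
    }
    if spec.selection is not None:
        sel = spec.selection
        data["selection"] = {
            "s_hom": sel.s_hom,
            "s_het": sel.s_het,
            "s_other": sel.s_other,
            "locus_position": sel.locus_position,
        }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def scenario_from_yaml(path):
    from .coalsim import ScenarioSpec
    from .selsim import SelectionSpec

    with open(path) as fh:
        data = yaml.safe_load(fh)
    sel = data.pop("selection", None)
    if sel is not None:
        data["selection"] = SelectionSpec(**sel)
    if "pair_age_factors" in data:
        data["pair_age_factors"] = tuple(data["pair_age_factors"])
    return ScenarioSpec(**data)
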