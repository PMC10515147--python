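"""Readers/writers for the standard formats plus population summaries.

Coordinates are 1-based in the pileup-style TSV and in VCF, and 0-based
half-open in BED output.  The mutation catalog is written as a single VCF
per population with the carrier line and call annotations as INFO fields:
per-line mutation sets are sparse, so one record per (line, site) instance
is far more compact than a population-wide genotype matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import stats

from .calling import EMS_TRANSITION, HET, NONEMS_TRANSITION, OBSERVATION_COLUMNS
from .errors import InputError, UndefinedStatisticError
from .saturation import MappingSpace

logger = logging.getLogger(__name__)

CALL_COLUMNS = (*OBSERVATION_COLUMNS, "mclass", "oxo", "zygosity", "max_tier")


def read_observations(path) -> pd.DataFrame:
    """Read a pileup-style observation TSV (header line required)."""
    obs = pd.read_csv(path, sep="\t", dtype={"line_id": str, "contig": str})
    missing = [c for c in OBSERVATION_COLUMNS if c not in obs.columns]
    if missing:
        raise InputError(f"observation file {path} missing columns: {missing}")
    return obs


def write_observations(obs: pd.DataFrame, path) -> None:
    obs.to_csv(path, sep="\t", index=False)


def read_calls(path) -> pd.DataFrame:
    calls = pd.read_csv(path, sep="\t", dtype={"line_id": str, "contig": str})
    if "oxo" in calls.columns:
        calls["oxo"] = calls["oxo"].astype(bool)
    return calls


def write_calls(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", index=False)


def write_reference_fasta(reference: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=contig, description="")
        for contig, seq in reference.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_reference_fasta(path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def _vcf_header(contig_lengths: Mapping[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for contig, length in contig_lengths.items():
        header.contigs.add(contig, length=int(length))
    header.info.add("LINE", 1, "String", "Mutant line carrying the call")
    header.info.add("ZYG", 1, "String", "Zygosity after reclassification (het/hom)")
    header.info.add("MCLASS", 1, "String", "Mutation class label")
    header.info.add("TIER", 1, "Integer", "Highest accepting stringency-ladder index")
    header.info.add("AD", 1, "Integer", "Mutant-allele read depth")
    header.info.add("WD", 1, "Integer", "Wild-type-allele read depth")
    return header


def write_vcf(
    calls: pd.DataFrame,
    path,
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> None:
    """Write calls to an uncompressed VCF 4.2 file, sorted by contig/pos."""
    if contig_lengths is None:
        contig_lengths = (
            calls.groupby("contig")["pos"].max().astype(int).to_dict()
            if len(calls)
            else {}
        )
    header = _vcf_header(contig_lengths)
    ordered = calls.sort_values(["contig", "pos", "line_id"], kind="stable")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for row in ordered.itertuples(index=False):
            rec = vcf.new_record(
                contig=str(row.contig),
                start=int(row.pos) - 1,
                alleles=(str(row.ref), str(row.alt)),
            )
            rec.info["LINE"] = str(row.line_id)
            rec.info["ZYG"] = str(row.zygosity)
            rec.info["MCLASS"] = str(row.mclass)
            rec.info["TIER"] = int(row.max_tier)
            rec.info["AD"] = int(row.alt_depth)
            rec.info["WD"] = int(row.wt_depth)
            vcf.write(rec)
    logger.info("write_vcf: wrote %d records to %s", len(calls), path)


def read_vcf(path) -> pd.DataFrame:
    """Read a catalog VCF written by :func:`write_vcf` back into a frame."""
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for i, rec in enumerate(vcf.fetch() if vcf.index else vcf):
            if len(rec.alts or ()) != 1:
                raise InputError(f"record {i + 1} in {path} is not biallelic")
            info = rec.info
            rows.append(
                {
                    "line_id": str(info["LINE"]),
                    "contig": rec.contig,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alts[0],
                    "alt_depth": int(info["AD"]),
                    "wt_depth": int(info["WD"]),
                    "mclass": str(info["MCLASS"]),
                    "oxo": f"{rec.ref}>{rec.alts[0]}" in ("C>A", "G>T"),
                    "zygosity": str(info["ZYG"]),
                    "max_tier": int(info["TIER"]),
                }
            )
    return pd.DataFrame(rows, columns=list(CALL_COLUMNS))


def write_bed(windows: pd.DataFrame, path) -> None:
    """Flagged windows as BED (0-based half-open), one row per window."""
    flagged = windows[windows["flagged"]] if "flagged" in windows.columns else windows
    with open(path, "w") as fh:
        for row in flagged.itertuples(index=False):
            name = getattr(row, "line_id", ".")
            fh.write(f"{row.contig}\t{int(row.start) - 1}\t{int(row.end)}\t{name}\n")


@dataclass(frozen=True)
class PopulationSummary:
    """Table-style population summary with one-decimal printed precision
    for densities and percentages."""

    n_lines: int
    total_snps: int
    total_ems: int
    percent_ems: float
    per_kb_density: float
    per_line_mean: float
    percent_het_ems: Optional[float]
    percent_het_nonems: Optional[float]
    est_error_percent: float
    rh_snp_count: int
    rh_snp_percent: float
    eliminated_libraries: int

    def as_dict(self) -> dict:
        return asdict(self)


def summary_from_counts(
    total_ems: int,
    n_lines: int,
    space: MappingSpace,
) -> dict[str, float]:
    """Density arithmetic from headline counts alone (per-kb over the
    population and mean per line), rounded to printed precision."""
    if n_lines <= 0 or total_ems < 0:
        raise InputError("need a positive line count and non-negative total")
    per_kb = 1000.0 * total_ems / space.space_bp
    per_line = total_ems / n_lines
    return {
        "per_kb_density": round(per_kb, 1),
        "per_line_mean": round(per_line, 1),
    }


def summarize(
    calls: pd.DataFrame,
    n_lines: int,
    space: MappingSpace,
    rh_snp_count: int = 0,
    eliminated_libraries: int = 0,
) -> PopulationSummary:
    """Summarize a post-QC call set (RH-masked, non-EMS still present)."""
    if len(calls) == 0:
        raise UndefinedStatisticError("cannot summarize an empty call set")
    total = len(calls)
    ems_mask = calls["mclass"] == EMS_TRANSITION
    nonems_mask = ~ems_mask
    total_ems = int(ems_mask.sum())
    het = calls["zygosity"] == HET

    def _pct(mask_num, mask_den) -> Optional[float]:
        den = int(mask_den.sum())
        if den == 0:
            return None
        return round(100.0 * int((mask_num & mask_den).sum()) / den, 2)

    per_kb = 1000.0 * total_ems / space.space_bp
    return PopulationSummary(
        n_lines=n_lines,
        total_snps=total + rh_snp_count,
        total_ems=total_ems,
        percent_ems=round(100.0 * total_ems / total, 1),
        per_kb_density=round(per_kb, 1),
        per_line_mean=round(total_ems / n_lines, 1),
        percent_het_ems=_pct(het, ems_mask),
        percent_het_nonems=_pct(het, nonems_mask),
        est_error_percent=round(
            100.0 * int((calls["mclass"] == NONEMS_TRANSITION).sum()) / total, 2
        ),
        rh_snp_count=rh_snp_count,
        rh_snp_percent=round(100.0 * rh_snp_count / (total + rh_snp_count), 2),
        eliminated_libraries=eliminated_libraries,
    )


def per_line_stats(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-line statistics used for cross-capture comparison."""
    if len(calls) == 0:
        raise UndefinedStatisticError("per-line stats undefined on an empty set")
    grouped = calls.groupby("line_id")
    out = pd.DataFrame(
        {
            "n_calls": grouped.size(),
            "percent_ems": 100.0
            * grouped["mclass"].apply(lambda s: (s == EMS_TRANSITION).mean()),
            "nonems_rate": 100.0
            * grouped["mclass"].apply(lambda s: (s == NONEMS_TRANSITION).mean()),
        }
    )
    return out


def compare_captures(
    stats_a: pd.DataFrame,
    stats_b: pd.DataFrame,
    columns: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Pearson correlations of per-line statistics over shared lines.

    Both inputs are indexed by line ID.  A statistic with zero variance in
    either capture is reported with a NaN correlation.
    """
    shared = stats_a.index.intersection(stats_b.index)
    if len(shared) < 3:
        raise UndefinedStatisticError(
            f"only {len(shared)} shared lines; need at least 3"
        )
    if columns is None:
        columns = [c for c in stats_a.columns if c in stats_b.columns]
    rows = []
    for col in columns:
        a = stats_a.loc[shared, col].to_numpy(dtype=float)
        b = stats_b.loc[shared, col].to_numpy(dtype=float)
        if np.std(a) == 0 or np.std(b) == 0:
            r, p = float("nan"), float("nan")
        else:
            r, p = stats.pearsonr(a, b)
    # one row per statistic; n_shared repeated for convenience
        rows.append({"statistic": col, "r": r, "p_value": p, "n_shared": len(shared)})
    return pd.DataFrame(rows)


def parse_config_text(text: str) -> dict:
    """Flat ``key = value`` configuration parser.

    Values are parsed as Python literals when possible (ints, floats,
    dicts for the per-class error rates) and kept as strings otherwise.
    ``#`` starts a comment.
    """
    import ast

    out: dict = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise InputError(f"config line {lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        try:
            out[key] = ast.literal_eval(value)
        except (ValueError, SyntaxError):
            out[key] = value
    return out
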