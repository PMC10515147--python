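"""Per-library quality control and the adaptive EMS98% tier selection.

Sequencing libraries differ in quality, and a single stringency level for
the whole population either discards good calls from clean libraries or
admits errors from noisy ones.  The adaptive strategy implemented here
("EMS98%") picks, for every library independently, the lowest stringency
level at which at least 98% of the accepted calls are EMS-type (G>A/C>T)
transitions; libraries that never reach 98% even at the highest level are
eliminated.

Because false G>A/C>T calls cannot be told apart from real EMS mutations,
the residual error rate after filtering is estimated from the reciprocal
A>G/T>C transitions, which occur among random errors at about the same
frequency as false G>A/C>T calls but are never induced by EMS.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .calling import (
    CANONICAL_LADDER,
    EMS_TRANSITION,
    HET,
    NONEMS_TRANSITION,
)
from .errors import UndefinedStatisticError

logger = logging.getLogger(__name__)

#: Sentinel chosen-tier value for libraries that never reach the threshold.
ELIMINATED = "ELIMINATED"

DEFAULT_EMS_THRESHOLD = 98.0
DEFAULT_EXCESS_HET_CUTOFF = 90.0

#: Site identity used when comparing mutations across lines.
SITE_KEY = ("contig", "pos", "alt")


def _require_nonempty(calls: pd.DataFrame, what: str) -> None:
    if len(calls) == 0:
        raise UndefinedStatisticError(f"{what} is undefined on an empty call set")


def percent_ems(calls: pd.DataFrame) -> float:
    """Percentage of calls that are EMS-type transitions."""
    _require_nonempty(calls, "percent_ems")
    return 100.0 * float((calls["mclass"] == EMS_TRANSITION).mean())


def estimate_error(calls: pd.DataFrame) -> float:
    """Estimated false-EMS rate: % of reciprocal A>G/T>C transitions.

    Must be computed on the call set *before* non-EMS classes are removed.
    """
    _require_nonempty(calls, "estimate_error")
    return 100.0 * float((calls["mclass"] == NONEMS_TRANSITION).mean())


def percent_het(calls: pd.DataFrame) -> float:
    """Percentage of calls with heterozygous (final) zygosity."""
    _require_nonempty(calls, "percent_het")
    return 100.0 * float((calls["zygosity"] == HET).mean())


def flag_excess_het(
    percent: float, cutoff: float = DEFAULT_EXCESS_HET_CUTOFF
) -> bool:
    """True iff a line's heterozygous percentage exceeds ``cutoff``.

    Lines far above the 2/3 expectation for a selfed generation most
    likely arose from the fusion of two independently mutagenized gametes,
    so every mutation is heterozygous.
    """
    return percent > cutoff


def filter_to_ems(calls: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep only EMS-type calls; report removed counts by class."""
    keep = calls["mclass"] == EMS_TRANSITION
    removed = calls.loc[~keep, "mclass"].value_counts().to_dict()
    removed = {str(k): int(v) for k, v in removed.items()}
    logger.info(
        "filter_to_ems: in=%d removed=%d out=%d", len(calls), int((~keep).sum()),
        int(keep.sum()),
    )
    return calls[keep].reset_index(drop=True), removed


def select_tier(
    tier_percent_ems: Sequence[Optional[float]],
    threshold: float = DEFAULT_EMS_THRESHOLD,
) -> Optional[int]:
    """Lowest ladder index whose %-EMS meets ``threshold`` (inclusive).

    ``None`` entries mark tiers with no calls, which cannot qualify.
    Returns ``None`` when no tier qualifies (library eliminated).
    """
    for t, p in enumerate(tier_percent_ems):
        if p is not None and p >= threshold:
            return t
    return None


def ems98_select(
    calls: pd.DataFrame,
    ladder_len: int = len(CANONICAL_LADDER),
    threshold: float = DEFAULT_EMS_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the per-library adaptive tier cascade.

    ``calls`` is the output of :func:`~emspop.calling.call_all_tiers`
    (optionally RH-masked).  Returns the selected calls (each stamped with
    its line's ``chosen_tier``) and a per-line QC table with per-tier call
    counts, %-EMS per tier and the chosen tier (or ``ELIMINATED``).
    """
    selected_parts: list[pd.DataFrame] = []
    qc_rows: list[dict] = []
    for line_id, grp in calls.groupby("line_id", sort=True):
        percents: list[Optional[float]] = []
        counts: list[int] = []
        for t in range(ladder_len):
            sub = grp[grp["max_tier"] >= t]
            counts.append(len(sub))
            percents.append(percent_ems(sub) if len(sub) else None)
        chosen = select_tier(percents, threshold)
        row = {"line_id": line_id, "chosen_tier": ELIMINATED if chosen is None else chosen}
        for t in range(ladder_len):
            row[f"n_calls_tier{t}"] = counts[t]
            row[f"percent_ems_tier{t}"] = percents[t]
        qc_rows.append(row)
        if chosen is not None:
            part = grp[grp["max_tier"] >= chosen].copy()
            part["chosen_tier"] = chosen
            selected_parts.append(part)
    qc = pd.DataFrame(qc_rows)
    if selected_parts:
        selected = pd.concat(selected_parts, ignore_index=True)
    else:
        selected = calls.iloc[0:0].copy()
        selected["chosen_tier"] = pd.Series(dtype=int)
    n_elim = int((qc["chosen_tier"] == ELIMINATED).sum()) if len(qc) else 0
    logger.info(
        "ems98_select: lines=%d eliminated=%d selected_calls=%d",
        len(qc), n_elim, len(selected),
    )
    return selected, qc


def library_qc(
    calls: pd.DataFrame,
    ladder_len: int = len(CANONICAL_LADDER),
    threshold: float = DEFAULT_EMS_THRESHOLD,
    excess_het_cutoff: float = DEFAULT_EXCESS_HET_CUTOFF,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full per-library QC: tier cascade plus error and zygosity statistics.

    Returns ``(selected_calls, qc_table)`` where the QC table adds, for the
    selected tier of each retained line, the estimated error (% non-EMS
    transitions), %-EMS, % heterozygous among EMS calls and the
    excess-heterozygosity flag.
    """
    selected, qc = ems98_select(calls, ladder_len, threshold)
    stats = []
    for line_id, grp in selected.groupby("line_id", sort=True):
        ems_grp = grp[grp["mclass"] == EMS_TRANSITION]
        p_het = percent_het(ems_grp) if len(ems_grp) else None
        stats.append(
            {
                "line_id": line_id,
                "est_error_percent": estimate_error(grp),
                "percent_ems": percent_ems(grp),
                "percent_het": p_het,
                "excess_het_flag": (
                    flag_excess_het(p_het, excess_het_cutoff)
                    if p_het is not None
                    else False
                ),
            }
        )
    if stats:
        qc = qc.merge(pd.DataFrame(stats), on="line_id", how="left")
    else:
        for col in ("est_error_percent", "percent_ems", "percent_het"):
            qc[col] = np.nan
        qc["excess_het_flag"] = False
    qc["excess_het_flag"] = (
        qc["excess_het_flag"].map(lambda v: bool(v) if pd.notna(v) else False)
    )
    return selected, qc


def _site_set(calls: pd.DataFrame) -> set[tuple]:
    return set(map(tuple, calls[list(SITE_KEY)].itertuples(index=False)))


def shared_fraction(focal: pd.DataFrame, other: pd.DataFrame) -> float:
    """Fraction of the focal line's mutation sites also present in ``other``.

    Asymmetric by design (denominator is the focal set); two full sibling
    lines derived from the same mutagenized parent are expected to share
    about half of their mutations, unrelated lines essentially none.
    """
    a = _site_set(focal)
    if not a:
        raise UndefinedStatisticError("shared_fraction undefined for empty focal set")
    b = _site_set(other)
    return len(a & b) / len(a)


def jaccard(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> float:
    """Symmetric Jaccard similarity of two lines' mutation-site sets."""
    a, b = _site_set(calls_a), _site_set(calls_b)
    union = a | b
    if not union:
        raise UndefinedStatisticError("jaccard undefined for two empty sets")
    return len(a & b) / len(union)


def m2_expected_het_percent() -> float:
    """Expected % heterozygous among detected mutations in a selfed M2.

    Selfing a heterozygous M1 gives 1/4 homozygous wild type, 1/2
    heterozygous and 1/4 homozygous mutant; only mutation carriers are
    detectable, hence het / (het + hom mutant).
    """
    p_het, p_hom_mut = 0.5, 0.25
    return 100.0 * p_het / (p_het + p_hom_mut)


def cascade_bookkeeping(
    tier_ems_counts: Sequence[int],
    n_sequenced: int,
    n_eliminated: int,
) -> dict[str, float]:
    """Totals for a completed cascade.

    ``tier_ems_counts`` are the EMS-call yields contributed by the
    libraries choosing each ladder level (lowest first).  Returns the total
    yield, the percentage contributed by the lowest level, and the number
    of retained libraries.
    """
    total = int(sum(tier_ems_counts))
    if total <= 0:
        raise UndefinedStatisticError("cascade totals undefined without calls")
    return {
        "total_ems": total,
        "percent_lowest_tier": 100.0 * tier_ems_counts[0] / total,
        "retained_lines": int(n_sequenced - n_eliminated),
    }
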