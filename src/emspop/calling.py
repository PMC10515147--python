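"""Mutation classification, stringency-ladder calling and zygosity assignment.

EMS mutagenesis induces almost exclusively G>A and C>T transitions, so every
candidate base change is first placed into one of three classes:

* ``EMS_TRANSITION`` -- G>A or C>T, the signal class;
* ``NONEMS_TRANSITION`` -- A>G or T>C, the reciprocal transitions whose
  frequency proxies the rate of false calls that mimic EMS changes;
* ``TRANSVERSION`` -- the remaining eight changes.  C>A and G>T
  transversions additionally carry an ``oxo`` flag because guanine
  oxidation (8-oxoG) during library preparation produces exactly those
  changes.

Calls are accepted against a ladder of stringency levels.  Each level is a
pair ``(het_min, hom_min)``: the minimum number of mutant reads required to
accept a heterozygous or a homozygous call.  A site with at least one
wild-type read is provisionally heterozygous (even a single wild-type read
makes the caller treat the site as heterozygous); a site with no wild-type
reads is provisionally homozygous.  After acceptance, provisional
heterozygotes whose wild-type allele is supported by less than 15% of the
reads are reclassified as homozygous -- the wild-type reads at such sites
are typically mis-mapped homeolog reads rather than evidence of a real
wild-type allele.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InputError

VALID_BASES = frozenset("ACGT")

EMS_TRANSITION = "EMS_TRANSITION"
NONEMS_TRANSITION = "NONEMS_TRANSITION"
TRANSVERSION = "TRANSVERSION"

HET = "het"
HOM = "hom"

#: Default wild-type read fraction below which a heterozygous call is
#: reclassified as homozygous (strict less-than).
DEFAULT_MAX_WT_FRACTION = 0.15

#: Columns every observation table must carry.
OBSERVATION_COLUMNS = (
    "line_id",
    "contig",
    "pos",
    "ref",
    "alt",
    "alt_depth",
    "wt_depth",
)


@dataclass(frozen=True)
class MutationClass:
    """Class label for a single-base change plus the oxidation flag."""

    label: str
    oxo_flag: bool

    def __post_init__(self) -> None:
        if self.oxo_flag and self.label != TRANSVERSION:
            raise InputError("oxo_flag is only defined for transversions")


class StringencyLevel(NamedTuple):
    """Minimum mutant-read depth for heterozygous / homozygous acceptance."""

    het_min: int
    hom_min: int


#: The canonical four-level ladder, ordered lowest to highest stringency.
CANONICAL_LADDER: tuple[StringencyLevel, ...] = (
    StringencyLevel(3, 2),
    StringencyLevel(4, 3),
    StringencyLevel(5, 3),
    StringencyLevel(6, 4),
)


def _build_class_table() -> dict[str, MutationClass]:
    table: dict[str, MutationClass] = {}
    for ref in "ACGT":
        for alt in "ACGT":
            if ref == alt:
                continue
            key = f"{ref}>{alt}"
            if key in ("G>A", "C>T"):
                table[key] = MutationClass(EMS_TRANSITION, False)
            elif key in ("A>G", "T>C"):
                table[key] = MutationClass(NONEMS_TRANSITION, False)
            else:
                table[key] = MutationClass(TRANSVERSION, key in ("C>A", "G>T"))
    return table


_CLASS_TABLE = _build_class_table()
_LABEL_TABLE = {k: v.label for k, v in _CLASS_TABLE.items()}
_OXO_TABLE = {k: v.oxo_flag for k, v in _CLASS_TABLE.items()}


def classify_change(ref: str, alt: str) -> MutationClass:
    """Classify a single base change.

    Raises :class:`~emspop.errors.InputError` for invalid bases or
    ``ref == alt``.
    """
    if ref not in VALID_BASES or alt not in VALID_BASES:
        raise InputError(f"invalid base in change {ref!r}>{alt!r}")
    if ref == alt:
        raise InputError(f"ref and alt are identical: {ref!r}")
    return _CLASS_TABLE[f"{ref}>{alt}"]


def classify_frame(obs: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of ``obs`` with ``mclass`` and ``oxo`` columns added."""
    key = obs["ref"].astype(str) + ">" + obs["alt"].astype(str)
    bad = ~key.isin(_LABEL_TABLE)
    if bad.any():
        raise InputError(
            f"invalid ref/alt pairs in observations: {sorted(key[bad].unique())}"
        )
    out = obs.copy()
    out["mclass"] = key.map(_LABEL_TABLE)
    out["oxo"] = key.map(_OXO_TABLE)
    return out


def validate_ladder(ladder: Sequence[StringencyLevel]) -> tuple[StringencyLevel, ...]:
    """Check ladder monotonicity (non-decreasing het_min and hom_min)."""
    ladder = tuple(StringencyLevel(*lv) for lv in ladder)
    if not ladder:
        raise InputError("ladder must contain at least one level")
    for lv in ladder:
        if not (lv.het_min >= lv.hom_min >= 1):
            raise InputError(f"level {lv} violates het_min >= hom_min >= 1")
    for lo, hi in zip(ladder, ladder[1:]):
        if hi.het_min < lo.het_min or hi.hom_min < lo.hom_min:
            raise InputError("ladder must be non-decreasing in both components")
    return ladder


def call_site(
    alt_depth: int, wt_depth: int, level: StringencyLevel
) -> Optional[str]:
    """Provisional zygosity of one site at one stringency level.

    Returns ``"het"`` / ``"hom"`` for an accepted call, or ``None`` for a
    no-call (a normal outcome, not an error).
    """
    if alt_depth < 1 or wt_depth < 0:
        raise InputError("alt_depth must be >= 1 and wt_depth >= 0")
    if wt_depth > 0:
        return HET if alt_depth >= level.het_min else None
    return HOM if alt_depth >= level.hom_min else None


def reclassify_zygosity(
    zygosity: str,
    alt_depth: int,
    wt_depth: int,
    max_wt_fraction: float = DEFAULT_MAX_WT_FRACTION,
) -> str:
    """Apply the wild-type-fraction rule to a provisional call.

    A heterozygous call becomes homozygous iff the wild-type allele is
    supported by strictly less than ``max_wt_fraction`` of the reads.
    """
    if zygosity == HOM:
        return HOM
    wt_fraction = wt_depth / (wt_depth + alt_depth)
    return HOM if wt_fraction < max_wt_fraction else HET


def call_all_tiers(
    obs: pd.DataFrame,
    ladder: Sequence[StringencyLevel] = CANONICAL_LADDER,
    max_wt_fraction: float = DEFAULT_MAX_WT_FRACTION,
) -> pd.DataFrame:
    """Accept observations against every ladder level at once.

    Because the ladder is non-decreasing, the accepted sets are nested, so
    a single integer per observation suffices: ``max_tier`` is the highest
    ladder index at which the observation is accepted; the calls at tier
    ``t`` are exactly the rows with ``max_tier >= t``.  Rows not accepted at
    any level are dropped.

    The returned frame carries ``mclass``, ``oxo``, ``provisional_zygosity``,
    final (reclassified) ``zygosity`` and ``max_tier``.
    """
    ladder = validate_ladder(ladder)
    missing = [c for c in OBSERVATION_COLUMNS if c not in obs.columns]
    if missing:
        raise InputError(f"observations missing columns: {missing}")
    if len(obs) and (obs["alt_depth"] < 1).any():
        raise InputError("every observation must have alt_depth >= 1")

    calls = classify_frame(obs)
    alt = calls["alt_depth"].to_numpy()
    wt = calls["wt_depth"].to_numpy()
    prov_het = wt > 0

    accepted = np.zeros((len(calls), len(ladder)), dtype=bool)
    for t, lv in enumerate(ladder):
        accepted[:, t] = np.where(prov_het, alt >= lv.het_min, alt >= lv.hom_min)
    # nested by ladder monotonicity, so the count of accepting tiers - 1
    # equals the highest accepting index
    max_tier = accepted.sum(axis=1) - 1

    calls["provisional_zygosity"] = np.where(prov_het, HET, HOM)
    wt_fraction = np.divide(wt, wt + alt, out=np.zeros(len(calls)), where=(wt + alt) > 0)
    calls["zygosity"] = np.where(
        ~prov_het | (wt_fraction < max_wt_fraction), HOM, HET
    )
    calls["max_tier"] = max_tier
    calls = calls[calls["max_tier"] >= 0].reset_index(drop=True)
    return calls


def calls_at_tier(calls: pd.DataFrame, tier: int) -> pd.DataFrame:
    """Subset of accepted calls at ladder index ``tier``."""
    if tier < 0:
        raise InputError("tier must be >= 0")
    return calls[calls["max_tier"] >= tier]


def tier_call_counts(calls: pd.DataFrame, n_tiers: int) -> list[int]:
    """Number of accepted calls at each ladder level (non-increasing)."""
    return [int((calls["max_tier"] >= t).sum()) for t in range(n_tiers)]
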