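"""Sequence-context profiling of mutation flanks.

EMS does not mutate every G equally: the bases flanking a mutated G bias
its accessibility (e.g. a C immediately downstream is over-represented).
Profiling is done in a common strand frame: G>A calls are read as-is and
C>T calls are reverse-complemented, so every site is analyzed as a mutated
G with its true upstream/downstream neighbours.  The same machinery,
oriented to the C strand, profiles C>A/G>T oxidation artifacts, whose
characteristic context is (G/C)CG around the damaged base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .calling import EMS_TRANSITION
from .errors import InputError, UndefinedStatisticError

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 10
BASE_ORDER = "ACGT"
_CODE = {b: i for i, b in enumerate(BASE_ORDER)}


@dataclass(frozen=True)
class ContextMatrix:
    """Per-position base frequencies around oriented mutation sites.

    ``freq`` and ``enrichment`` are indexed by offset (-flank..flank, 0 is
    the mutated base) with one column per base; ``background`` holds the
    genome-wide base frequencies used for the enrichment ratios.
    """

    freq: pd.DataFrame
    background: pd.Series
    enrichment: pd.DataFrame
    n_sites: int
    n_skipped: int


def encode_sequence(seq: str) -> np.ndarray:
    """Uppercase ACGT string to uint8 codes (A=0, C=1, G=2, T=3)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, 255, dtype=np.uint8)
    for base, code in _CODE.items():
        codes[arr == ord(base)] = code
    if (codes == 255).any():
        raise InputError("reference contains non-ACGT characters")
    return codes


def _background(refs: Mapping[str, np.ndarray]) -> pd.Series:
    counts = np.zeros(4, dtype=np.int64)
    for codes in refs.values():
        counts += np.bincount(codes, minlength=4)
    return pd.Series(counts / counts.sum(), index=list(BASE_ORDER))


def _profile(
    calls: pd.DataFrame,
    refs: Mapping[str, np.ndarray],
    flank: int,
    forward_ref: str,
    reverse_ref: str,
) -> ContextMatrix:
    if len(calls) == 0:
        raise UndefinedStatisticError("context profile undefined on an empty call set")
    offsets = np.arange(-flank, flank + 1)
    totals = np.zeros((len(offsets), 4), dtype=np.int64)
    n_sites = 0
    n_skipped = 0
    for contig, grp in calls.groupby("contig", sort=True):
        if contig not in refs:
            raise InputError(f"reference lacks contig {contig!r}")
        codes = refs[contig]
        pos0 = grp["pos"].to_numpy() - 1
        is_fwd = (grp["ref"] == forward_ref).to_numpy()
        is_rev = (grp["ref"] == reverse_ref).to_numpy()
        if not (is_fwd | is_rev).all():
            raise InputError(
                f"calls must have ref {forward_ref} or {reverse_ref} for this profile"
            )
        in_bounds = (pos0 - flank >= 0) & (pos0 + flank < len(codes))
        n_skipped += int((~in_bounds).sum())
        pos0, is_fwd = pos0[in_bounds], is_fwd[in_bounds]
        if len(pos0) == 0:
            continue
        win = codes[pos0[:, None] + offsets[None, :]].astype(np.int64)
        # reverse strand: complement (A<->T, C<->G is 3 - code) and mirror
        rev = ~is_fwd
        win[rev] = 3 - win[rev, ::-1]
        n_sites += len(pos0)
        for j in range(len(offsets)):
            totals[j] += np.bincount(win[:, j], minlength=4)
    if n_sites == 0:
        raise UndefinedStatisticError(
            "all sites too close to contig edges for the requested flank"
        )
    if n_skipped:
        logger.info("context profile skipped %d edge-proximal sites", n_skipped)
    freq = pd.DataFrame(
        totals / n_sites, index=offsets, columns=list(BASE_ORDER)
    )
    background = _background(refs)
    enrichment = freq / background
    return ContextMatrix(
        freq=freq,
        background=background,
        enrichment=enrichment,
        n_sites=n_sites,
        n_skipped=n_skipped,
    )


def context_profile(
    calls: pd.DataFrame,
    reference: Mapping[str, str],
    flank: int = DEFAULT_FLANK,
) -> ContextMatrix:
    """Flank profile of EMS-type calls in the mutated-G frame.

    G>A calls are used as-is; C>T calls are reverse-complemented so that
    position 0 is always the mutated G.
    """
    ems = calls[calls["mclass"] == EMS_TRANSITION]
    refs = {c: encode_sequence(s) for c, s in reference.items()}
    return _profile(ems, refs, flank, forward_ref="G", reverse_ref="C")


def top_oxo_lines(calls: pd.DataFrame, n: int = 60) -> list[str]:
    """Line IDs ranked by their fraction of C>A/G>T calls, highest first."""
    frac = calls.groupby("line_id")["oxo"].mean().sort_values(
        ascending=False, kind="stable"
    )
    return list(frac.index[:n])


def oxo_context_profile(
    calls: pd.DataFrame,
    reference: Mapping[str, str],
    flank: int = DEFAULT_FLANK,
    top_n: int | None = None,
) -> ContextMatrix:
    """Flank profile of C>A/G>T calls in the damaged-C frame.

    C>A calls are used as-is; G>T calls are reverse-complemented so that
    position 0 is always the oxidized C.  With ``top_n`` set, only the
    lines with the highest C>A/G>T fraction contribute, mirroring how the
    artifact is concentrated in a minority of libraries.
    """
    oxo = calls[calls["oxo"].astype(bool)]
    if top_n is not None:
        keep = set(top_oxo_lines(calls, top_n))
        oxo = oxo[oxo["line_id"].isin(keep)]
    if len(oxo) == 0:
        raise UndefinedStatisticError("no C>A/G>T calls to profile")
    refs = {c: encode_sequence(s) for c, s in reference.items()}
    return _profile(oxo, refs, flank, forward_ref="C", reverse_ref="G")
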