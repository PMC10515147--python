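"""Residual-heterogeneity (RH) detection and masking.

Mutagenized seed stocks are rarely perfectly inbred: blocks of pre-existing
polymorphism segregate in a fraction of the lines.  Calls inside such a
block are not induced mutations and must be removed before any
population-genetic accounting.  RH blocks betray themselves through four
signatures relative to genuine EMS mutations:

1. a high local SNP density,
2. a high proportion of non-EMS changes (natural polymorphism has no G>A
   /C>T bias),
3. a high proportion of homozygous calls (the polymorphisms are old and
   mostly fixed within a line), and
4. the presence of the *same* SNPs in multiple lines (the block descends
   from one contaminating haplotype).

The four features are computed in sliding windows per line, min-max
normalized against the pooled window distribution of the whole
population, and averaged into a single index; windows at or above the
cutoff are flagged and every call inside a flagged window is masked.
Normalization is population-wide rather than per line because the RH
contrast is population-wide: a block descends from one contaminating
haplotype shared across carrier lines, whereas per-line normalization
would rescale the noise of RH-free lines so that some clean window always
reaches the feature maximum.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .calling import EMS_TRANSITION, HOM
from .errors import InputError

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 2_000_000
DEFAULT_STEP_BP = 1_000_000
DEFAULT_CUTOFF = 0.5

FEATURES = ("snp_density", "frac_nonems", "frac_hom", "sharing")

#: Full site identity used for the cross-line sharing feature.
SHARING_KEY = ("contig", "pos", "ref", "alt")


def sharing_counts(calls: pd.DataFrame) -> pd.Series:
    """Per call, the number of *other* lines carrying the identical SNP."""
    key = list(SHARING_KEY)
    n_lines_per_site = calls.groupby(key)["line_id"].transform("nunique")
    return n_lines_per_site - 1


def window_features(
    line_calls: pd.DataFrame,
    window_bp: int,
    step_bp: int,
    sharing: pd.Series,
) -> pd.DataFrame:
    """Sliding-window RH features for a single line.

    ``line_calls`` must be sorted by (contig, pos); ``sharing`` is the
    per-call other-line count aligned to ``line_calls``.  Windows are
    1-based closed intervals; empty windows are skipped.
    """
    if window_bp < step_bp or step_bp <= 0:
        raise InputError("require window_bp >= step_bp > 0")
    rows = []
    for contig, grp in line_calls.groupby("contig", sort=True):
        pos = grp["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise InputError(f"calls for contig {contig} are not sorted by position")
        nonems = (grp["mclass"] != EMS_TRANSITION).to_numpy()
        hom = (grp["zygosity"] == HOM).to_numpy()
        share = sharing.loc[grp.index].to_numpy()
        max_pos = int(pos[-1])
        start = 1
        while start <= max_pos:
            end = start + window_bp - 1
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="right")
            n = hi - lo
            if n > 0:
                rows.append(
                    {
                        "line_id": grp["line_id"].iloc[0],
                        "contig": contig,
                        "start": start,
                        "end": end,
                        "n_snps": int(n),
                        "snp_density": 1000.0 * n / window_bp,
                        "frac_nonems": float(nonems[lo:hi].mean()),
                        "frac_hom": float(hom[lo:hi].mean()),
                        "sharing": float(share[lo:hi].mean()),
                    }
                )
            start += step_bp
    return pd.DataFrame(
        rows,
        columns=["line_id", "contig", "start", "end", "n_snps", *FEATURES],
    )


def rh_index(windows: pd.DataFrame, cutoff: float = DEFAULT_CUTOFF) -> pd.DataFrame:
    """Combine the four window features into a single index.

    Each feature is min-max normalized against the window distribution of
    the supplied table (normally the pooled windows of the whole
    population); a feature that is constant across windows carries no
    information and contributes 0.  The index is the mean of the four
    normalized features, and ``flagged`` is ``index >= cutoff``.
    """
    out = windows.copy()
    norm_cols = []
    for feat in FEATURES:
        x = out[feat].to_numpy(dtype=float)
        lo, hi = x.min(), x.max()
        norm = np.zeros_like(x) if hi == lo else (x - lo) / (hi - lo)
        out[f"{feat}_norm"] = norm
        norm_cols.append(f"{feat}_norm")
    out["index"] = out[norm_cols].mean(axis=1)
    out["flagged"] = out["index"] >= cutoff
    return out


def detect_rh(
    calls: pd.DataFrame,
    window_bp: int = DEFAULT_WINDOW_BP,
    step_bp: int = DEFAULT_STEP_BP,
    cutoff: float = DEFAULT_CUTOFF,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag RH calls across a whole population.

    Returns ``(calls_with_rh_flag, windows)``: a copy of ``calls`` with a
    boolean ``rh_flag`` column (true for calls inside any flagged window of
    their line) and the per-line window table with features, index and
    flag.  Detection runs on whatever call set is supplied; the lowest
    stringency tier is the natural choice because it is the most sensitive
    to the dense block signal.
    """
    calls = calls.sort_values(["line_id", "contig", "pos"], kind="stable")
    share = sharing_counts(calls)
    window_parts = [
        window_features(grp, window_bp, step_bp, share)
        for _, grp in calls.groupby("line_id", sort=True)
    ]
    window_parts = [w for w in window_parts if len(w)]
    if window_parts:
        windows = rh_index(pd.concat(window_parts, ignore_index=True), cutoff)
    else:
        windows = pd.DataFrame(columns=["line_id", "contig", "start", "end",
                                        "n_snps", *FEATURES, "index", "flagged"])
    flagged_mask = pd.Series(False, index=calls.index)
    flagged_windows = windows[windows["flagged"]]
    for line_id, grp in calls.groupby("line_id", sort=True):
        for _, w in flagged_windows[flagged_windows["line_id"] == line_id].iterrows():
            in_win = (
                (grp["contig"] == w["contig"])
                & (grp["pos"] >= w["start"])
                & (grp["pos"] <= w["end"])
            )
            flagged_mask.loc[grp.index[in_win]] = True
    out = calls.copy()
    out["rh_flag"] = flagged_mask
    out = out.reset_index(drop=True)
    logger.info(
        "detect_rh: in=%d flagged=%d windows=%d flagged_windows=%d",
        len(out), int(out["rh_flag"].sum()), len(windows),
        int(windows["flagged"].sum()) if len(windows) else 0,
    )
    return out, windows


def mask_rh(calls: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop RH-flagged calls; surviving records are returned unmodified."""
    if "rh_flag" not in calls.columns:
        raise InputError("calls carry no rh_flag column; run detect_rh first")
    keep = ~calls["rh_flag"]
    removed = int((~keep).sum())
    logger.info("mask_rh: in=%d removed=%d out=%d", len(calls), removed, int(keep.sum()))
    return calls[keep].reset_index(drop=True), removed
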