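"""End-to-end orchestration of the post-processing stages.

The canonical order is: classify and accept candidates at every stringency
level; detect and mask residual-heterogeneity regions on the
lowest-stringency (most sensitive) call set; run the per-library EMS98%
tier cascade on the masked calls; compute per-library error and zygosity
QC on the selected calls; and finally restrict to EMS-type calls for the
population-genetic accounting.  Error and %-EMS denominators therefore
exclude RH calls but still include the non-EMS classes, which are removed
only in the last step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from . import calling, libqc, rhfilter
from .calling import CANONICAL_LADDER, StringencyLevel

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    calls_all_tiers: pd.DataFrame
    rh_windows: pd.DataFrame
    rh_removed: int
    masked: pd.DataFrame
    selected: pd.DataFrame
    qc: pd.DataFrame
    ems_calls: pd.DataFrame
    removed_by_class: dict
    eliminated_lines: list


def run_pipeline(
    observations: pd.DataFrame,
    ladder: Sequence[StringencyLevel] = CANONICAL_LADDER,
    max_wt_fraction: float = calling.DEFAULT_MAX_WT_FRACTION,
    rh_window_bp: int = rhfilter.DEFAULT_WINDOW_BP,
    rh_step_bp: int = rhfilter.DEFAULT_STEP_BP,
    rh_cutoff: float = rhfilter.DEFAULT_CUTOFF,
    ems_threshold: float = libqc.DEFAULT_EMS_THRESHOLD,
    excess_het_cutoff: float = libqc.DEFAULT_EXCESS_HET_CUTOFF,
) -> PipelineResult:
    """Run calling, RH masking, the EMS98% cascade and the EMS filter."""
    ladder = calling.validate_ladder(ladder)
    calls = calling.call_all_tiers(observations, ladder, max_wt_fraction)
    flagged, windows = rhfilter.detect_rh(calls, rh_window_bp, rh_step_bp, rh_cutoff)
    masked, rh_removed = rhfilter.mask_rh(flagged)
    selected, qc = libqc.library_qc(
        masked, len(ladder), ems_threshold, excess_het_cutoff
    )
    eliminated = (
        qc.loc[qc["chosen_tier"] == libqc.ELIMINATED, "line_id"].tolist()
        if len(qc)
        else []
    )
    ems_calls, removed = libqc.filter_to_ems(selected)
    return PipelineResult(
        calls_all_tiers=calls,
        rh_windows=windows,
        rh_removed=rh_removed,
        masked=masked,
        selected=selected,
        qc=qc,
        ems_calls=ems_calls,
        removed_by_class=removed,
        eliminated_lines=eliminated,
    )
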