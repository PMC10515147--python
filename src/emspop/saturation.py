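"""Population-level mutation accounting under a two-class Poisson model.

Not every G/C position is equally mutable by EMS; as a tractable
simplification the genome's GC sites are split into an "accessible" class,
hit at a common rate, and an inaccessible remainder.  If the population
carries ``M`` EMS mutation instances spread over ``N`` accessible sites,
the number of lines hitting any one site is approximately Poisson with
mean ``lambda = M / N``.  The observable signature is the duplicate
spectrum: ``n_k`` sites mutated in exactly ``k`` distinct lines.  Fitting
``lambda`` to the multi-hit counts yields

* the accessible-site count ``N = M / lambda``,
* the saturation ``1 - exp(-lambda)`` -- the probability that a newly
  observed mutation lands on an already-mutated site, and
* an independent empirical check: the fraction of mutation instances at
  multi-hit sites, which under an exact Poisson spectrum equals
  ``1 - exp(-lambda)`` identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import EstimationError, InputError, UndefinedStatisticError

#: Grid and multi-hit orders used by the least-squares lambda fit.  Only
#: k = 2..4 enter the objective: higher orders are rare and dominated by
#: accessibility heterogeneity rather than Poisson sampling.
LAMBDA_GRID = (0.001, 1.0, 0.001)
FIT_KS = (2, 3, 4)


@dataclass(frozen=True)
class DuplicateSpectrum:
    """Counts of sites by multiplicity plus the instance total.

    ``n_k[k]`` is the number of sites mutated in exactly ``k`` distinct
    lines; ``M`` is the total number of mutation instances,
    ``sum_k k * n_k[k]``.
    """

    n_k: Mapping[int, int]
    M: int

    def __post_init__(self) -> None:
        if any(k < 1 or v < 0 for k, v in self.n_k.items()):
            raise InputError("spectrum requires k >= 1 and counts >= 0")
        total = sum(k * v for k, v in self.n_k.items())
        if total != self.M:
            raise InputError(f"M={self.M} inconsistent with spectrum total {total}")

    def count(self, k: int) -> int:
        return int(self.n_k.get(k, 0))


@dataclass(frozen=True)
class MappingSpace:
    """Valid mapping space (bp) and its GC fraction."""

    space_bp: int
    gc_fraction: float

    def __post_init__(self) -> None:
        if self.space_bp <= 0:
            raise InputError("space_bp must be positive")
        if not (0.0 < self.gc_fraction < 1.0):
            raise InputError("gc_fraction must be in (0, 1)")


@dataclass(frozen=True)
class SaturationEstimate:
    lam: float
    n_accessible: int
    saturation: float
    empirical_dup_fraction: float
    accessible_fraction_of_gc: Optional[float] = None


def duplicate_spectrum(calls: pd.DataFrame) -> DuplicateSpectrum:
    """Duplicate spectrum of an RH-masked, EMS-only population call set.

    Sites are identified by (contig, pos, alt); each line contributes at
    most one instance per site.
    """
    if len(calls) == 0:
        return DuplicateSpectrum(n_k={}, M=0)
    per_site = (
        calls.groupby(["contig", "pos", "alt"])["line_id"].nunique().to_numpy()
    )
    ks, counts = np.unique(per_site, return_counts=True)
    n_k = {int(k): int(c) for k, c in zip(ks, counts)}
    return DuplicateSpectrum(n_k=n_k, M=int(per_site.sum()))


def expected_spectrum(lam: float, M: int, ks: Sequence[int]) -> dict[int, float]:
    """Poisson expectation E_k = (M/lam) * exp(-lam) * lam^k / k!."""
    if lam <= 0:
        raise InputError("lambda must be positive")
    N = M / lam
    return {k: N * math.exp(-lam) * lam**k / math.factorial(k) for k in ks}


def fit_lambda(
    spectrum: DuplicateSpectrum,
    ks: Sequence[int] = FIT_KS,
    grid: tuple[float, float, float] = LAMBDA_GRID,
) -> float:
    """Grid-search the Poisson mean against the multi-hit counts.

    Minimizes sum_k (n_k - E_k)^2 / E_k over an inclusive grid; ties go to
    the smaller lambda.  Requires at least one doubleton site.
    """
    if spectrum.M <= 0 or spectrum.count(2) == 0:
        raise EstimationError("cannot fit lambda without duplicated sites")
    lo, hi, step = grid
    lams = np.arange(lo, hi + step / 2, step)
    obs = np.array([spectrum.count(k) for k in ks], dtype=float)
    N = spectrum.M / lams  # per-lambda accessible sites
    best_lam, best_obj = None, math.inf
    log_fact = np.array([math.lgamma(k + 1) for k in ks])
    for lam, n_sites in zip(lams, N):
        ek = n_sites * np.exp(-lam + np.array(ks) * math.log(lam) - log_fact)
        obj = float(((obs - ek) ** 2 / ek).sum())
        if obj < best_obj:
            best_obj, best_lam = obj, float(lam)
    if best_lam is None:
        raise EstimationError("lambda fit failed on the supplied spectrum")
    return best_lam


def accessible_sites(M: int, lam: float) -> int:
    """Estimated accessible-site count, the nearest integer to M / lambda."""
    if lam <= 0:
        raise InputError("lambda must be positive")
    if M < 0:
        raise InputError("M must be non-negative")
    return round(M / lam)


def saturation_fraction(lam: float) -> float:
    """Poisson probability of at least one hit, 1 - exp(-lambda)."""
    if lam < 0:
        raise InputError("lambda must be non-negative")
    return 1.0 - math.exp(-lam)


def empirical_saturation(spectrum: DuplicateSpectrum) -> float:
    """Fraction of mutation instances at sites hit in two or more lines."""
    if spectrum.M <= 0:
        raise UndefinedStatisticError("empirical saturation undefined for M = 0")
    dup_instances = sum(k * v for k, v in spectrum.n_k.items() if k >= 2)
    return dup_instances / spectrum.M


def gc_sites(space: MappingSpace) -> int:
    """Predicted number of G/C positions in the mapping space."""
    return round(space.space_bp * space.gc_fraction)


def density_stats(M: int, n_lines: int, space: MappingSpace) -> tuple[float, float]:
    """(population mutations per kb, mean mutations per line)."""
    if n_lines <= 0:
        raise InputError("n_lines must be positive")
    if M < 0:
        raise InputError("M must be non-negative")
    per_kb = 1000.0 * M / space.space_bp
    per_line = M / n_lines
    return per_kb, per_line


def estimate_saturation(
    spectrum: DuplicateSpectrum,
    space: Optional[MappingSpace] = None,
    lam: Optional[float] = None,
) -> SaturationEstimate:
    """One-stop estimate: fit lambda (unless given), then derive N,
    saturation, the empirical duplicate fraction and, when a mapping space
    is supplied, the accessible fraction of its GC sites."""
    if lam is None:
        lam = fit_lambda(spectrum)
    n_acc = accessible_sites(spectrum.M, lam)
    frac_gc = None
    if space is not None:
        frac_gc = n_acc / gc_sites(space)
    return SaturationEstimate(
        lam=lam,
        n_accessible=n_acc,
        saturation=saturation_fraction(lam),
        empirical_dup_fraction=empirical_saturation(spectrum),
        accessible_fraction_of_gc=frac_gc,
    )
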