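"""Duplicate spectrum, Poisson fit, accessible sites and saturation."""

import math

import numpy as np
import pandas as pd
import pytest

import emspop
from emspop import saturation
from emspop.errors import EstimationError, InputError, UndefinedStatisticError
from emspop.saturation import (
    DuplicateSpectrum,
    MappingSpace,
    accessible_sites,
    density_stats,
    duplicate_spectrum,
    empirical_saturation,
    expected_spectrum,
    fit_lambda,
    gc_sites,
    saturation_fraction,
)

# Headline published inputs used as fixed test vectors: instance totals,
# multi-hit site counts, line counts and mapping spaces of the promoter
# (PC) and exome (EC) captures.
PC_M, PC_LINES, PC_SPACE = 4_287_361, 1_513, 102_378_005
EC_M, EC_LINES, EC_SPACE = 4_690_454, 1_521, 131_190_164
PC_MULTI = {2: 291_577, 3: 31_539, 4: 4_503}


def pc_spectrum():
    n1 = PC_M - sum(k * v for k, v in PC_MULTI.items())
    return DuplicateSpectrum(n_k={1: n1, **PC_MULTI}, M=PC_M)


def poisson_spectrum(lam, n_sites, kmax=10):
    n_k = {
        k: round(n_sites * math.exp(-lam) * lam**k / math.factorial(k))
        for k in range(1, kmax + 1)
    }
    n_k = {k: v for k, v in n_k.items() if v > 0}
    return DuplicateSpectrum(n_k=n_k, M=sum(k * v for k, v in n_k.items()))


def test_duplicate_spectrum_counts_lines_per_site():
    calls = pd.DataFrame(
        {
            "line_id": ["A", "B", "C"],
            "contig": "c",
            "pos": [100, 100, 100],
            "alt": "A",
        }
    )
    spec = duplicate_spectrum(calls)
    assert spec.n_k == {3: 1}
    assert spec.M == 3


def test_duplicate_spectrum_all_private():
    calls = pd.DataFrame(
        {"line_id": "A", "contig": "c", "pos": range(10), "alt": "A"}
    )
    spec = duplicate_spectrum(calls)
    assert spec.n_k == {1: 10} and spec.M == 10


def test_duplicate_spectrum_against_bruteforce_oracle():
    """Spectrum equals an O(sites x lines) double-loop recount."""
    rng = np.random.default_rng(5)
    calls = pd.DataFrame(
        {
            "line_id": rng.choice([f"L{i}" for i in range(12)], 300),
            "contig": "c",
            "pos": rng.integers(1, 120, 300),
            "alt": "A",
        }
    ).drop_duplicates(["line_id", "pos"])
    spec = duplicate_spectrum(calls)
    brute = {}
    for site in sorted(calls["pos"].unique()):
        k = 0
        for line in calls["line_id"].unique():
            if len(calls[(calls["pos"] == site) & (calls["line_id"] == line)]):
                k += 1
        brute[k] = brute.get(k, 0) + 1
    assert spec.n_k == brute
    assert spec.M == len(calls)


def test_spectrum_invariant_enforced():
    with pytest.raises(InputError):
        DuplicateSpectrum(n_k={1: 10, 2: 5}, M=10)


def test_fit_lambda_recovers_analytic_spectrum():
    """A spectrum set exactly to the Poisson expectation is recovered to
    the grid step."""
    spec = poisson_spectrum(lam=0.2, n_sites=5_000_000)
    assert fit_lambda(spec) == pytest.approx(0.2, abs=1e-3)


def test_fit_lambda_degenerate_spectrum_raises():
    with pytest.raises(EstimationError):
        fit_lambda(DuplicateSpectrum(n_k={1: 100}, M=100))


def test_fit_lambda_on_published_promoter_spectrum():
    """The printed multi-hit counts give a mean within 0.03 of 0.182 (the
    published fitting objective is not fully specified, hence the slack)."""
    lam = fit_lambda(pc_spectrum())
    assert lam == pytest.approx(0.182, abs=0.03)


def test_expected_spectrum_matches_closed_form():
    ek = expected_spectrum(0.2, M=1_000_000, ks=(2, 3))
    n = 1_000_000 / 0.2
    assert ek[2] == pytest.approx(n * math.exp(-0.2) * 0.2**2 / 2)
    assert ek[3] == pytest.approx(n * math.exp(-0.2) * 0.2**3 / 6)


@pytest.mark.parametrize(
    "M,lam,expected",
    [
        (PC_M, 0.182, 23_556_929),  # published accessible-site estimate
        (100, 1.0, 100),
        (EC_M, 0.153, 30_656_562),
    ],
)
def test_accessible_sites(M, lam, expected):
    assert accessible_sites(M, lam) == expected


def test_accessible_sites_rejects_bad_lambda():
    with pytest.raises(InputError):
        accessible_sites(100, 0.0)


def test_accessible_sites_roundtrip_within_rounding():
    for lam in (0.05, 0.153, 0.182, 0.4):
        n = accessible_sites(PC_M, lam)
        assert abs(n * lam - PC_M) <= 0.5


@pytest.mark.parametrize(
    "lam,expected",
    [(0.182, 0.166), (0.153, 0.142), (0.0, 0.0)],
)
def test_saturation_fraction(lam, expected):
    assert saturation_fraction(lam) == pytest.approx(expected, abs=5e-4)


def test_saturation_fraction_monotone_bounded():
    lams = np.linspace(0, 5, 200)
    vals = np.array([saturation_fraction(l) for l in lams])
    assert (np.diff(vals) > 0).all()
    assert vals[0] == 0.0 and vals[-1] < 1.0


def test_empirical_saturation_published_and_trivial():
    assert empirical_saturation(pc_spectrum()) == pytest.approx(0.162, abs=5e-4)
    assert empirical_saturation(DuplicateSpectrum(n_k={1: 5}, M=5)) == 0.0
    with pytest.raises(UndefinedStatisticError):
        empirical_saturation(DuplicateSpectrum(n_k={}, M=0))


def test_empirical_saturation_equals_poisson_identity():
    """On an exact Poisson spectrum the duplicate-instance fraction equals
    1 - exp(-lambda) (integer rounding of the counts sets the tolerance)."""
    lam = 0.25
    spec = poisson_spectrum(lam, n_sites=10_000_000, kmax=12)
    assert empirical_saturation(spec) == pytest.approx(
        saturation_fraction(lam), abs=1e-4
    )


def test_gc_sites_and_accessible_fraction():
    assert gc_sites(MappingSpace(PC_SPACE, 0.468)) == 47_912_906
    assert gc_sites(MappingSpace(1000, 0.5)) == 500
    frac = 23_556_929 / gc_sites(MappingSpace(PC_SPACE, 0.468))
    assert frac == pytest.approx(0.492, abs=5e-4)  # "approximately half"


@pytest.mark.parametrize(
    "M,n_lines,space,per_kb,per_line",
    [
        (PC_M, PC_LINES, PC_SPACE, 41.9, 2833.7),
        (EC_M, EC_LINES, EC_SPACE, 35.8, 3083.8),
        (1000, 10, 1_000_000, 1.0, 100.0),
    ],
)
def test_density_stats_published_values(M, n_lines, space, per_kb, per_line):
    got_kb, got_line = density_stats(M, n_lines, MappingSpace(space, 0.5))
    assert round(got_kb, 1) == per_kb
    assert round(got_line, 1) == per_line


def test_density_stats_rejects_zero_lines():
    with pytest.raises(InputError):
        density_stats(10, 0, MappingSpace(1000, 0.5))


@pytest.mark.parametrize("genome_size", [2_000_000, 4_000_000])
def test_accessible_site_recovery_from_simulated_truth(genome_size):
    """fit_lambda + accessible_sites recover the simulated accessible-site
    count within 5% for lambda in the working range at M >= 1e5."""
    cfg = emspop.SimConfig(genome_size=genome_size, seed=13)
    truth, _, _ = emspop.simulate_population(cfg)
    spec = duplicate_spectrum(
        truth.mutations.assign(alt=truth.mutations["alt"])
    )
    assert spec.M >= 1e5
    lam = fit_lambda(spec)
    assert 0.05 <= truth.lambda_true <= 0.4
    n_est = accessible_sites(spec.M, lam)
    assert abs(n_est - truth.accessible_count) / truth.accessible_count <= 0.05


def test_empirical_and_fitted_saturation_agree_on_simulation(default_sim):
    _, truth, _, _ = default_sim
    spec = duplicate_spectrum(truth.mutations)
    est = saturation.estimate_saturation(spec)
    assert abs(est.empirical_dup_fraction - est.saturation) <= 0.01
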