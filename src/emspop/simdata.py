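"""Synthetic mutagenized-population generator.

Emulates the data structure the downstream estimators assume, at a scale
that runs in seconds: an i.i.d. reference with a configurable GC fraction;
a subset of GC sites accessible to EMS; per-line Poisson mutation loads
placed uniformly (optionally context-biased) on accessible sites; M2
zygosity (2/3 heterozygous) with binomial allele depths on overdispersed
coverage; per-library error channels (false EMS-type calls, reciprocal
A>G/T>C transitions, context-biased C>A/G>T oxidation artifacts and other
transversions) whose intensity varies log-normally across libraries;
shared residual-heterogeneity blocks carried by a subset of lines; and a
minority of lines built as the union of two independent gamete mutation
sets, hence almost entirely heterozygous.

Every observation row mimics a pileup-derived candidate: line, contig,
1-based position, ref, alt, mutant-read depth and wild-type-read depth.
A fixed seed yields byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError

CONTIG = "sim1"

ERROR_CLASSES = ("ems", "nonems_transition", "oxo", "transversion_other")

#: Transversion partners per ref base, excluding the oxidation pair C>A/G>T.
_OTHER_TRANSVERSIONS = {"A": "CT", "C": "G", "G": "C", "T": "AG"}

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Population, sequencing and artifact parameters.

    Defaults follow the study design they emulate at reduced scale: a GC
    fraction of 0.468 with half of the GC sites accessible, 2/3 expected
    heterozygosity at M2, non-EMS artifact rates totalling ~1.3% of the
    mutation load with C>A/G>T making up about half of them, roughly 1.5%
    of calls inside residual-heterogeneity blocks, and 6.5% of lines
    arising from two-gamete fusion.
    """

    n_lines: int = 400
    genome_size: int = 2_000_000
    gc_fraction: float = 0.468
    accessible_fraction: float = 0.5
    mean_mutations_per_line: float = 250.0
    het_fraction_expected: float = 2.0 / 3.0
    depth_mean: float = 25.0
    depth_dispersion: float = 5.0
    contamination_rate: float = 0.05
    error_rate_per_class: Mapping[str, float] = field(
        default_factory=lambda: {
            "ems": 0.5,
            "nonems_transition": 0.5,
            "oxo": 1.6,
            "transversion_other": 0.8,
        }
    )
    library_quality_sigma: float = 1.0
    oxo_context_bias: float = 8.0
    ems_context_bias: float = 0.0
    rh_block_count: int = 2
    rh_block_length_bp: int = 10_000
    rh_snps_per_kb: float = 2.0
    rh_carrier_fraction: float = 0.1
    rh_hom_fraction: float = 0.85
    rh_class_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "ems": 0.17,
            "nonems_transition": 0.25,
            "transversion": 0.58,
        }
    )
    excess_het_line_fraction: float = 0.065
    excess_het_gamete_mean_factor: float = 0.585
    error_alt_depth_base: int = 2
    error_alt_depth_mean_extra: float = 1.2
    seed: int = 0

    def validate(self) -> "SimConfig":
        fractions = {
            "gc_fraction": self.gc_fraction,
            "accessible_fraction": self.accessible_fraction,
            "het_fraction_expected": self.het_fraction_expected,
            "contamination_rate": self.contamination_rate,
            "rh_carrier_fraction": self.rh_carrier_fraction,
            "rh_hom_fraction": self.rh_hom_fraction,
            "excess_het_line_fraction": self.excess_het_line_fraction,
        }
        for name, value in fractions.items():
            if not (math.isfinite(value) and 0.0 <= value <= 1.0):
                raise ConfigError(f"{name}={value} must be a fraction in [0, 1]")
        positives = {
            "n_lines": self.n_lines,
            "genome_size": self.genome_size,
            "mean_mutations_per_line": self.mean_mutations_per_line,
            "depth_mean": self.depth_mean,
            "depth_dispersion": self.depth_dispersion,
        }
        for name, value in positives.items():
            if not (math.isfinite(value) and value > 0):
                raise ConfigError(f"{name}={value} must be positive and finite")
        for name in ("library_quality_sigma", "oxo_context_bias", "ems_context_bias",
                     "rh_snps_per_kb", "excess_het_gamete_mean_factor"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value >= 0):
                raise ConfigError(f"{name}={value} must be non-negative and finite")
        for cls, rate in self.error_rate_per_class.items():
            if cls not in ERROR_CLASSES:
                raise ConfigError(f"unknown error class {cls!r}")
            if not (math.isfinite(rate) and rate >= 0):
                raise ConfigError(f"error rate for {cls!r} must be non-negative")
        if self.genome_size * self.gc_fraction * self.accessible_fraction < 1:
            raise ConfigError("configuration yields no accessible GC sites")
        if self.rh_block_count < 0 or self.rh_block_length_bp <= 0:
            raise ConfigError("invalid residual-heterogeneity block parameters")
        if self.rh_block_count * self.rh_block_length_bp > self.genome_size // 2:
            raise ConfigError("residual-heterogeneity blocks cover too much genome")
        return self


@dataclass
class SimTruth:
    """Ground truth for one simulated population."""

    config: SimConfig
    mutations: pd.DataFrame  # line_id, contig, pos, ref, alt, zygosity
    accessible_pos: np.ndarray  # 1-based positions of accessible GC sites
    errors: pd.DataFrame  # line_id, contig, pos, ref, alt, error_class
    rh_blocks: pd.DataFrame  # contig, start, end (1-based closed)
    rh_snps: pd.DataFrame  # block, contig, pos, ref, alt, zygosity
    rh_carriers: dict[int, np.ndarray]  # block index -> line ids
    excess_het_lines: list[str]
    line_quality: pd.Series  # per-line error intensity multiplier

    @property
    def accessible_count(self) -> int:
        return len(self.accessible_pos)

    @property
    def lambda_true(self) -> float:
        if self.accessible_count == 0:
            return 0.0
        return len(self.mutations) / self.accessible_count


def _line_ids(n: int) -> list[str]:
    return [f"L{i + 1:04d}" for i in range(n)]


def _weighted_draw(rng: np.random.Generator, cumw: np.ndarray, n: int) -> np.ndarray:
    """n indices drawn with replacement proportional to the weights."""
    u = rng.random(n) * cumw[-1]
    return np.searchsorted(cumw, u, side="right")


def _nb_depth(rng: np.random.Generator, cfg: SimConfig, n: int) -> np.ndarray:
    r = cfg.depth_dispersion
    p = r / (r + cfg.depth_mean)
    return rng.negative_binomial(r, p, size=n)


def _emit_reads(
    rng: np.random.Generator, cfg: SimConfig, zygosity: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Allele depths for true-variant sites; alt may be 0 (site missed)."""
    n = len(zygosity)
    depth = _nb_depth(rng, cfg, n)
    het = zygosity == "het"
    alt = np.where(
        het,
        rng.binomial(depth, 0.5),
        depth - rng.binomial(depth, cfg.contamination_rate),
    )
    wt = depth - alt
    return alt, wt


def simulate_population(
    config: SimConfig,
) -> tuple[SimTruth, pd.DataFrame, dict[str, str]]:
    """Generate (truth, observation table, reference).

    Observations carry ``line_id contig pos ref alt alt_depth wt_depth``
    with 1-based positions; rows whose mutant allele attracted no reads
    are omitted (a site with no mutant reads is undetectable).
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)
    lines = _line_ids(cfg.n_lines)

    # --- reference sequence, i.i.d. with the configured GC fraction ---
    at = (1.0 - cfg.gc_fraction) / 2.0
    gc = cfg.gc_fraction / 2.0
    codes = rng.choice(4, size=cfg.genome_size, p=[at, gc, gc, at]).astype(np.uint8)
    seq = "".join(_BASES[codes])
    reference = {CONTIG: seq}

    is_g = codes == 2
    is_c = codes == 1
    gc_pos0 = np.flatnonzero(is_g | is_c)
    at_pos0 = np.flatnonzero(~(is_g | is_c))

    # --- accessibility, i.i.d. per GC site ---
    acc_mask = rng.random(len(gc_pos0)) < cfg.accessible_fraction
    acc_pos0 = gc_pos0[acc_mask]
    acc_ref = np.where(codes[acc_pos0] == 2, "G", "C")

    # optional EMS context preference: G with downstream C (or the
    # reverse-complement equivalent, C with upstream G)
    acc_w = np.ones(len(acc_pos0))
    if cfg.ems_context_bias > 0:
        nxt = np.where(acc_pos0 + 1 < cfg.genome_size, acc_pos0 + 1, acc_pos0)
        prv = np.where(acc_pos0 - 1 >= 0, acc_pos0 - 1, acc_pos0)
        pref_g = (codes[acc_pos0] == 2) & (codes[nxt] == 1)
        pref_c = (codes[acc_pos0] == 1) & (codes[prv] == 2)
        acc_w[pref_g | pref_c] += cfg.ems_context_bias
    acc_cumw = np.cumsum(acc_w)

    # oxidation-artifact site pools: damaged C in a C_CG-like context, i.e.
    # upstream C and downstream G on the damaged strand
    c_pos0 = np.flatnonzero(is_c)
    g_pos0 = np.flatnonzero(is_g)

    def _oxo_cumw(pool: np.ndarray) -> np.ndarray:
        w = np.ones(len(pool))
        if cfg.oxo_context_bias > 0 and len(pool):
            prv = np.where(pool - 1 >= 0, pool - 1, pool)
            nxt = np.where(pool + 1 < cfg.genome_size, pool + 1, pool)
            # plus-strand C>A wants C at -1 and G at +1; minus-strand
            # (G>T) wants the mirrored genome pattern C at -1, G at +1
            # relative to the damaged base read on its own strand
            pref = (codes[prv] == 1) & (codes[nxt] == 2)
            w[pref] += cfg.oxo_context_bias
        return np.cumsum(w) if len(pool) else np.array([])

    c_cumw = _oxo_cumw(c_pos0)
    g_cumw = _oxo_cumw(g_pos0)

    # --- excess-heterozygosity (gamete fusion) lines ---
    n_excess = int(round(cfg.excess_het_line_fraction * cfg.n_lines))
    excess_idx = set(
        rng.choice(cfg.n_lines, size=n_excess, replace=False).tolist()
        if n_excess
        else []
    )
    excess_lines = [lines[i] for i in sorted(excess_idx)]

    # --- true EMS mutations per line ---
    mut_rows: list[pd.DataFrame] = []
    for i, line in enumerate(lines):
        if i in excess_idx:
            gamete_mean = cfg.mean_mutations_per_line * cfg.excess_het_gamete_mean_factor
            n1 = rng.poisson(gamete_mean)
            n2 = rng.poisson(gamete_mean)
            idx = np.unique(_weighted_draw(rng, acc_cumw, n1 + n2))
            zyg = np.full(len(idx), "het")
        else:
            n_mut = rng.poisson(cfg.mean_mutations_per_line)
            idx = np.unique(_weighted_draw(rng, acc_cumw, n_mut))
            zyg = np.where(
                rng.random(len(idx)) < cfg.het_fraction_expected, "het", "hom"
            )
        ref = acc_ref[idx]
        mut_rows.append(
            pd.DataFrame(
                {
                    "line_id": line,
                    "contig": CONTIG,
                    "pos": acc_pos0[idx] + 1,
                    "ref": ref,
                    "alt": np.where(ref == "G", "A", "T"),
                    "zygosity": zyg,
                }
            )
        )
    mutations = pd.concat(mut_rows, ignore_index=True)

    # --- per-library error channel ---
    sigma = cfg.library_quality_sigma
    quality = pd.Series(
        rng.lognormal(-sigma**2 / 2.0, sigma, size=cfg.n_lines), index=lines
    )
    err_rows: list[pd.DataFrame] = []
    for line in lines:
        q = quality[line]
        for cls in ERROR_CLASSES:
            rate = cfg.error_rate_per_class.get(cls, 0.0)
            n_err = rng.poisson(rate * q)
            if n_err == 0:
                continue
            if cls == "ems":
                p0 = gc_pos0[rng.integers(0, len(gc_pos0), n_err)]
                ref = np.where(codes[p0] == 2, "G", "C")
                alt = np.where(ref == "G", "A", "T")
            elif cls == "nonems_transition":
                p0 = at_pos0[rng.integers(0, len(at_pos0), n_err)]
                ref = np.where(codes[p0] == 0, "A", "T")
                alt = np.where(ref == "A", "G", "C")
            elif cls == "oxo":
                strand_c = rng.random(n_err) < 0.5
                p0 = np.empty(n_err, dtype=np.int64)
                n_c = int(strand_c.sum())
                if n_c:
                    p0[strand_c] = c_pos0[_weighted_draw(rng, c_cumw, n_c)]
                if n_err - n_c:
                    p0[~strand_c] = g_pos0[_weighted_draw(rng, g_cumw, n_err - n_c)]
                ref = np.where(strand_c, "C", "G")
                alt = np.where(strand_c, "A", "T")
            else:  # transversion_other
                p0 = rng.integers(0, cfg.genome_size, n_err)
                ref = _BASES[codes[p0]]
                alt = np.array(
                    [
                        _OTHER_TRANSVERSIONS[r][
                            rng.integers(0, len(_OTHER_TRANSVERSIONS[r]))
                        ]
                        for r in ref
                    ]
                )
            err_rows.append(
                pd.DataFrame(
                    {
                        "line_id": line,
                        "contig": CONTIG,
                        "pos": p0 + 1,
                        "ref": ref,
                        "alt": alt,
                        "error_class": cls,
                    }
                )
            )
    errors = (
        pd.concat(err_rows, ignore_index=True)
        if err_rows
        else pd.DataFrame(
            columns=["line_id", "contig", "pos", "ref", "alt", "error_class"]
        )
    )

    # --- residual-heterogeneity blocks shared verbatim by carriers ---
    rh_blocks_rows, rh_snp_rows, rh_carriers = [], [], {}
    occupied: list[tuple[int, int]] = []
    n_carriers = int(round(cfg.rh_carrier_fraction * cfg.n_lines))
    for b in range(cfg.rh_block_count):
        for _ in range(1000):
            start0 = int(rng.integers(0, cfg.genome_size - cfg.rh_block_length_bp))
            end0 = start0 + cfg.rh_block_length_bp - 1
            if all(end0 < s or start0 > e for s, e in occupied):
                break
        else:  # pragma: no cover - pathological configs rejected by validate
            raise ConfigError("could not place non-overlapping RH blocks")
        occupied.append((start0, end0))
        rh_blocks_rows.append(
            {"block": b, "contig": CONTIG, "start": start0 + 1, "end": end0 + 1}
        )
        n_snps = int(round(cfg.rh_block_length_bp / 1000.0 * cfg.rh_snps_per_kb))
        block_gc = gc_pos0[(gc_pos0 >= start0) & (gc_pos0 <= end0)]
        block_at = at_pos0[(at_pos0 >= start0) & (at_pos0 <= end0)]
        mix = cfg.rh_class_mix
        n_ems, n_trans, n_tv = rng.multinomial(
            n_snps,
            [mix.get("ems", 0.0), mix.get("nonems_transition", 0.0),
             mix.get("transversion", 0.0)],
        )
        pos_list, ref_list, alt_list = [], [], []
        take_ems = rng.choice(block_gc, size=min(n_ems, len(block_gc)), replace=False)
        for p0 in take_ems:
            r = "G" if codes[p0] == 2 else "C"
            pos_list.append(p0)
            ref_list.append(r)
            alt_list.append("A" if r == "G" else "T")
        take_tr = rng.choice(block_at, size=min(n_trans, len(block_at)), replace=False)
        for p0 in take_tr:
            r = "A" if codes[p0] == 0 else "T"
            pos_list.append(p0)
            ref_list.append(r)
            alt_list.append("G" if r == "A" else "C")
        take_tv = rng.integers(start0, end0 + 1, n_tv)
        for p0 in take_tv:
            r = str(_BASES[codes[p0]])
            choices = _OTHER_TRANSVERSIONS[r] + ("A" if r == "C" else "T" if r == "G" else "")
            pos_list.append(p0)
            ref_list.append(r)
            alt_list.append(choices[rng.integers(0, len(choices))])
        zyg = np.where(
            rng.random(len(pos_list)) < cfg.rh_hom_fraction, "hom", "het"
        )
        block_snps = pd.DataFrame(
            {
                "block": b,
                "contig": CONTIG,
                "pos": np.asarray(pos_list) + 1,
                "ref": ref_list,
                "alt": alt_list,
                "zygosity": zyg,
            }
        ).drop_duplicates(["contig", "pos"])
        rh_snp_rows.append(block_snps)
        carriers = rng.choice(cfg.n_lines, size=n_carriers, replace=False)
        rh_carriers[b] = np.array(sorted(lines[i] for i in carriers))
    rh_blocks = pd.DataFrame(
        rh_blocks_rows, columns=["block", "contig", "start", "end"]
    )
    rh_snps = (
        pd.concat(rh_snp_rows, ignore_index=True)
        if rh_snp_rows
        else pd.DataFrame(
            columns=["block", "contig", "pos", "ref", "alt", "zygosity"]
        )
    )

    # --- read-level evidence ---
    obs_parts: list[pd.DataFrame] = []

    alt_d, wt_d = _emit_reads(rng, cfg, mutations["zygosity"].to_numpy())
    obs_parts.append(
        mutations[["line_id", "contig", "pos", "ref", "alt"]].assign(
            alt_depth=alt_d, wt_depth=wt_d
        )
    )

    if len(errors):
        depth = _nb_depth(rng, cfg, len(errors))
        alt_e = cfg.error_alt_depth_base + rng.poisson(
            cfg.error_alt_depth_mean_extra, len(errors)
        )
        # errors always look heterozygous: plenty of wild-type reads
        wt_e = np.maximum(depth - alt_e, 2 * alt_e)
        obs_parts.append(
            errors[["line_id", "contig", "pos", "ref", "alt"]].assign(
                alt_depth=alt_e, wt_depth=wt_e
            )
        )

    for b, carriers in rh_carriers.items():
        snps = rh_snps[rh_snps["block"] == b]
        if len(snps) == 0:
            continue
        rep = pd.DataFrame(
            {
                "line_id": np.repeat(carriers, len(snps)),
                "contig": np.tile(snps["contig"].to_numpy(), len(carriers)),
                "pos": np.tile(snps["pos"].to_numpy(), len(carriers)),
                "ref": np.tile(snps["ref"].to_numpy(), len(carriers)),
                "alt": np.tile(snps["alt"].to_numpy(), len(carriers)),
            }
        )
        zyg = np.tile(snps["zygosity"].to_numpy(), len(carriers))
        alt_r, wt_r = _emit_reads(rng, cfg, zyg)
        obs_parts.append(rep.assign(alt_depth=alt_r, wt_depth=wt_r))

    obs = pd.concat(obs_parts, ignore_index=True)
    obs = obs[obs["alt_depth"] >= 1]
    obs = obs.drop_duplicates(["line_id", "contig", "pos"], keep="first")
    obs = obs.sort_values(["line_id", "contig", "pos"], kind="stable").reset_index(
        drop=True
    )
    obs["pos"] = obs["pos"].astype(np.int64)
    obs["alt_depth"] = obs["alt_depth"].astype(np.int64)
    obs["wt_depth"] = obs["wt_depth"].astype(np.int64)

    truth = SimTruth(
        config=cfg,
        mutations=mutations,
        accessible_pos=acc_pos0 + 1,
        errors=errors,
        rh_blocks=rh_blocks,
        rh_snps=rh_snps,
        rh_carriers=rh_carriers,
        excess_het_lines=excess_lines,
        line_quality=quality,
    )
    return truth, obs, reference


def truth_report(truth: SimTruth) -> dict:
    """Summary of injected quantities.

    ``lambda_true`` is exactly the number of true mutation instances
    divided by the accessible-site count.
    """
    muts = truth.mutations
    per_line = (
        muts.groupby("line_id").size().reindex(
            _line_ids(truth.config.n_lines), fill_value=0
        )
    )
    het_frac = float((muts["zygosity"] == "het").mean()) if len(muts) else 0.0
    return {
        "n_lines": truth.config.n_lines,
        "accessible_sites": truth.accessible_count,
        "total_instances": int(len(muts)),
        "lambda_true": truth.lambda_true,
        "per_line_counts": per_line,
        "mean_per_line": float(per_line.mean()) if len(per_line) else 0.0,
        "het_fraction": het_frac,
        "n_error_observations": int(len(truth.errors)),
        "n_rh_snps": int(len(truth.rh_snps)),
        "excess_het_lines": list(truth.excess_het_lines),
    }
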