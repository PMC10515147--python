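"""Format round-trips, population summary, cross-capture comparison, CLI."""

import json
import math

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import emspop
from emspop import calling, libqc, report_io
from emspop.cli import main as cli_main
from emspop.errors import UndefinedStatisticError
from emspop.report_io import (
    CALL_COLUMNS,
    compare_captures,
    parse_config_text,
    per_line_stats,
    read_vcf,
    summarize,
    summary_from_counts,
    write_vcf,
)
from emspop.saturation import MappingSpace
from conftest import make_calls


def _roundtrip(calls, tmp_path):
    path = tmp_path / "calls.vcf"
    write_vcf(calls, path)
    back = read_vcf(path)
    want = (
        calls[list(CALL_COLUMNS)]
        .sort_values(["contig", "pos", "line_id"], kind="stable")
        .reset_index(drop=True)
    )
    got = (
        back.sort_values(["contig", "pos", "line_id"], kind="stable")
        .reset_index(drop=True)
        .astype(want.dtypes.to_dict())
    )
    pd.testing.assert_frame_equal(got, want)


def test_vcf_roundtrip_toy_set(tmp_path):
    calls = make_calls(n_ems=2, n_nonems=1, het_fraction=0.5, seed=2)
    _roundtrip(calls, tmp_path)


def test_vcf_empty_set_is_valid_header_only(tmp_path):
    calls = make_calls(n_ems=1).iloc[0:0]
    path = tmp_path / "empty.vcf"
    write_vcf(calls, path, contig_lengths={"sim1": 1000})
    text = path.read_text()
    assert text.startswith("##fileformat=VCF")
    assert len(read_vcf(path)) == 0


def test_vcf_roundtrip_simulated_records(tmp_path, pipeline_result):
    calls = pipeline_result.ems_calls.head(10_000)
    _roundtrip(calls, tmp_path)


def test_vcf_records_sorted_by_position(tmp_path):
    calls = make_calls(n_ems=50, seed=3).sample(frac=1.0, random_state=0)
    path = tmp_path / "sorted.vcf"
    write_vcf(calls, path)
    back = read_vcf(path)
    assert back["pos"].is_monotonic_increasing


def test_bed_output_is_zero_based_half_open(tmp_path):
    windows = pd.DataFrame(
        {
            "line_id": ["L1"],
            "contig": ["c"],
            "start": [1001],
            "end": [2000],
            "flagged": [True],
        }
    )
    path = tmp_path / "rh.bed"
    report_io.write_bed(windows, path)
    fields = path.read_text().strip().split("\t")
    assert fields[:3] == ["c", "1000", "2000"]


def test_observation_tsv_roundtrip(tmp_path, default_sim):
    _, _, obs, _ = default_sim
    path = tmp_path / "obs.tsv"
    report_io.write_observations(obs.head(500), path)
    back = report_io.read_observations(path)
    pd.testing.assert_frame_equal(back, obs.head(500).reset_index(drop=True))


def test_summary_from_counts_published_inputs():
    pc = summary_from_counts(4_287_361, 1_513, MappingSpace(102_378_005, 0.468))
    assert pc == {"per_kb_density": 41.9, "per_line_mean": 2833.7}
    ec = summary_from_counts(4_690_454, 1_521, MappingSpace(131_190_164, 0.468))
    assert ec == {"per_kb_density": 35.8, "per_line_mean": 3083.8}


def test_summarize_single_call():
    calls = make_calls(n_ems=1, het_fraction=1.0)
    s = summarize(calls, n_lines=1, space=MappingSpace(1000, 0.5))
    assert s.total_ems == 1 and s.percent_ems == 100.0
    assert s.percent_het_ems == 100.0 and s.percent_het_nonems is None


def test_summarize_matches_independent_recomputation(pipeline_result, default_sim):
    cfg, _, _, _ = default_sim
    calls = pipeline_result.selected
    space = MappingSpace(cfg.genome_size, cfg.gc_fraction)
    s = summarize(calls, cfg.n_lines, space, rh_snp_count=pipeline_result.rh_removed)
    # second path: plain pandas tallies
    ems = calls[calls["mclass"] == "EMS_TRANSITION"]
    assert s.total_ems == len(ems)
    assert s.percent_ems == round(100 * len(ems) / len(calls), 1)
    assert s.per_kb_density == round(1000 * len(ems) / cfg.genome_size, 1)
    assert s.per_line_mean == round(len(ems) / cfg.n_lines, 1)
    assert s.percent_het_ems == round(
        100 * (ems["zygosity"] == "het").mean(), 2
    )
    assert s.est_error_percent == round(
        100 * (calls["mclass"] == "NONEMS_TRANSITION").mean(), 2
    )


def test_summarize_empty_raises():
    with pytest.raises(UndefinedStatisticError):
        summarize(make_calls(n_ems=1).iloc[0:0], 1, MappingSpace(1000, 0.5))


def test_compare_captures_identities():
    idx = [f"L{i}" for i in range(10)]
    a = pd.DataFrame({"n_calls": np.arange(10.0)}, index=idx)
    out = compare_captures(a, a.copy())
    assert out.loc[out["statistic"] == "n_calls", "r"].iloc[0] == pytest.approx(1.0)
    const = pd.DataFrame({"n_calls": np.ones(10)}, index=idx)
    out2 = compare_captures(a, const)
    assert math.isnan(out2["r"].iloc[0])
    with pytest.raises(UndefinedStatisticError):
        compare_captures(a.head(2), a.head(2))


def test_compare_captures_shared_load_independent_errors():
    """Two captures of the same lines correlate strongly in mutation load
    but not in their library-specific error rates."""
    rng = np.random.default_rng(9)
    n = 300
    load = rng.gamma(20, 120, n)
    idx = [f"L{i:04d}" for i in range(n)]
    a = pd.DataFrame(
        {
            "n_calls": rng.poisson(load),
            "nonems_rate": rng.exponential(0.3, n),
        },
        index=idx,
    )
    b = pd.DataFrame(
        {
            "n_calls": rng.poisson(load),
            "nonems_rate": rng.exponential(0.3, n),
        },
        index=idx,
    )
    out = compare_captures(a, b).set_index("statistic")
    assert out.loc["n_calls", "r"] > 0.8
    assert abs(out.loc["nonems_rate", "r"]) < 0.2


def test_per_line_stats_tallies():
    calls = pd.concat(
        [
            make_calls(n_ems=8, n_nonems=2, line_id="A"),
            make_calls(n_ems=5, line_id="B", start_pos=9000),
        ],
        ignore_index=True,
    )
    stats = per_line_stats(calls)
    assert stats.loc["A", "n_calls"] == 10
    assert stats.loc["A", "percent_ems"] == pytest.approx(80.0)
    assert stats.loc["A", "nonems_rate"] == pytest.approx(20.0)
    assert stats.loc["B", "percent_ems"] == 100.0


def test_parse_config_text():
    text = """
    # comment
    n_lines = 40
    gc_fraction = 0.5  # inline comment
    error_rate_per_class = {'ems': 0.1}
    label = plain-string
    """
    cfg = parse_config_text(text)
    assert cfg == {
        "n_lines": 40,
        "gc_fraction": 0.5,
        "error_rate_per_class": {"ems": 0.1},
        "label": "plain-string",
    }


def test_cli_end_to_end(tmp_path):
    """simulate -> call -> filter-rh -> qc -> saturate -> report -> context."""
    runner = CliRunner()
    cfg_file = tmp_path / "sim.cfg"
    cfg_file.write_text(
        "n_lines = 30\n"
        "genome_size = 200000\n"
        "mean_mutations_per_line = 60.0\n"
        "rh_block_count = 1\n"
        "rh_block_length_bp = 5000\n"
        "excess_het_line_fraction = 0.0\n"
    )
    simdir = tmp_path / "sim"
    r = runner.invoke(
        cli_main,
        ["simulate", "--config", str(cfg_file), "--seed", "4", "--out", str(simdir)],
    )
    assert r.exit_code == 0, r.output
    r = runner.invoke(
        cli_main,
        ["call", "--in", str(simdir / "observations.tsv"),
         "--out", str(tmp_path / "calls.tsv")],
    )
    assert r.exit_code == 0, r.output
    r = runner.invoke(
        cli_main,
        ["filter-rh", "--calls", str(tmp_path / "calls.tsv"),
         "--out", str(tmp_path / "rh"), "--window", "20000", "--step", "10000"],
    )
    assert r.exit_code == 0, r.output
    r = runner.invoke(
        cli_main,
        ["qc", "--calls", str(tmp_path / "rh" / "calls_rh_masked.tsv"),
         "--out", str(tmp_path / "qc")],
    )
    assert r.exit_code == 0, r.output
    r = runner.invoke(
        cli_main,
        ["saturate", "--calls", str(tmp_path / "qc" / "calls_selected.tsv"),
         "--space-bp", "200000", "--gc-fraction", "0.468",
         "--out", str(tmp_path / "sat.json")],
    )
    assert r.exit_code == 0, r.output
    sat = json.loads((tmp_path / "sat.json").read_text())
    assert 0.0 < sat["lambda"] < 1.0
    assert sat["n_accessible"] > 0
    r = runner.invoke(
        cli_main,
        ["report", "--calls", str(tmp_path / "qc" / "calls_selected.tsv"),
         "--n-lines", "30", "--space-bp", "200000", "--gc-fraction", "0.468",
         "--out", str(tmp_path / "summary.json")],
    )
    assert r.exit_code == 0, r.output
    summary = json.loads((tmp_path / "summary.json").read_text())
    assert summary["percent_ems"] >= 98.0
    r = runner.invoke(
        cli_main,
        ["context", "--calls", str(tmp_path / "qc" / "calls_selected.tsv"),
         "--reference", str(simdir / "reference.fasta"),
         "--out", str(tmp_path / "context.tsv")],
    )
    assert r.exit_code == 0, r.output
    matrix = pd.read_csv(tmp_path / "context.tsv", sep="\t", index_col=0)
    assert matrix.loc[0, "freq_G"] == 1.0
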