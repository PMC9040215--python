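"""End-to-end pipeline runs, file outputs, determinism, and the CLI."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from dlbclcea.calibration import EfficacyParams, RelativeRisk
from dlbclcea.cli import main
from dlbclcea.economics import StateCostProfile
from dlbclcea.parameters import (
    ModelParameters,
    config_digest,
    default_parameters,
    load_config,
    params_from_dict,
    params_to_dict,
    save_config,
)
from dlbclcea.reporting import run_base_case, run_bia, run_psa_analysis, simulate_data
from dlbclcea.synthetic import estimate_state_parameters, estimate_utilities
from dlbclcea.economics import CostComponent, StateCosts, UtilityProfile
from dlbclcea.synthetic import generate_cost_records, generate_eq5d_records


class TestBaseCaseReport:
    def test_two_arms_and_two_icers(self, params, tmp_path):
        res = run_base_case(params, tmp_path)
        assert set(res.summaries) == {"R-CHOP", "CHOP"}
        assert res.icer_qaly.icer is not None
        assert res.icer_lyg.icer is not None
        assert res.icer_lyg.icer < res.icer_qaly.icer  # LY gains exceed QALY gains
        for name in (
            "trace_rchop.csv",
            "trace_chop.csv",
            "calibration_report.csv",
            "outcomes_usd_years.csv",
            "icer.json",
            "manifest.json",
        ):
            assert (tmp_path / name).exists()
        payload = json.loads((tmp_path / "icer.json").read_text())
        assert payload["icer_usd_per_qaly"] == pytest.approx(res.icer_qaly.icer)

    def test_rituximab_arm_lives_longer_and_costs_more(self, params):
        res = run_base_case(params)
        rchop, chop = res.summaries["R-CHOP"], res.summaries["CHOP"]
        assert rchop.life_years > chop.life_years
        assert rchop.qalys > chop.qalys
        assert rchop.total_cost > chop.total_cost
        for s in (rchop, chop):
            assert s.total_cost < s.total_cost_undiscounted
            assert s.qalys < s.life_years

    def test_null_effect_yields_non_comparable_verdict(self, params):
        params.efficacy = EfficacyParams(
            rr_progression_free=RelativeRisk(1.0, 0.5, 2.0),
            rr_overall_survival=RelativeRisk(1.0, 0.5, 2.0),
        )
        res = run_base_case(params)
        assert res.icer_qaly.icer is None
        # arms differ only in costs -> dominance label, never a numeric ICER
        assert res.icer_qaly.label in {"dominated", "dominant", "equivalent"}

    def test_zero_discount_collapses_discounted_columns(self, params):
        from dlbclcea.model import ModelConfig

        params.config = ModelConfig(
            discount_rate_costs=0.0, discount_rate_effects=0.0
        )
        res = run_base_case(params)
        for s in res.summaries.values():
            assert s.total_cost == pytest.approx(s.total_cost_undiscounted)
            assert s.qalys == pytest.approx(s.qalys_undiscounted)

    def test_manifest_records_policy_and_digest(self, params, tmp_path):
        run_base_case(params, tmp_path)
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["calibration_policy"] == "anchor_to_cycle"
        assert manifest["config_digest"] == config_digest(params)

    def test_byte_identical_reruns(self, params, tmp_path):
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        run_base_case(params, d1)
        run_base_case(params, d2)
        for name in ("trace_rchop.csv", "outcomes_usd_years.csv", "icer.json"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()


class TestPSAReport:
    def test_outputs_and_summary(self, params, tmp_path):
        res, curve, summary = run_psa_analysis(
            params, n_iterations=10, seed=9, outdir=tmp_path
        )
        assert len(res.draws) == 10
        assert (tmp_path / "psa_draws.csv").exists()
        assert (tmp_path / "ice_plane.csv").exists()
        assert (tmp_path / "ceac.csv").exists()
        specs = json.loads((tmp_path / "psa_specs.json").read_text())
        assert specs["seed"] == 9
        assert 0.0 <= summary["probability_cost_effective_at_3x_gdp"] <= 1.0

    def test_ceac_file_spans_threshold_grid(self, params, tmp_path):
        import pandas as pd

        run_psa_analysis(params, n_iterations=5, seed=1, outdir=tmp_path)
        ceac_df = pd.read_csv(tmp_path / "ceac.csv")
        assert ceac_df["threshold_usd_per_qaly"].min() == 0.0
        assert ceac_df["threshold_usd_per_qaly"].max() == 30000.0
        assert 11538.0 in set(ceac_df["threshold_usd_per_qaly"])

    def test_seeded_reruns_are_byte_identical(self, params, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        run_psa_analysis(params, n_iterations=10, seed=2, outdir=d1)
        run_psa_analysis(params, n_iterations=10, seed=2, outdir=d2)
        for name in ("psa_draws.csv", "ice_plane.csv", "ceac.csv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()


class TestBIAReport:
    def test_six_rows_ordered(self, params, tmp_path):
        table = run_bia(params, outdir=tmp_path)
        assert list(table["scenario"]) == ["S1", "S2", "S3", "S4", "S5", "S6"]
        assert (tmp_path / "bia_scenarios_usd.csv").exists()

    def test_doubled_population_doubles_totals(self, params):
        from dlbclcea.budget import synthetic_population

        pop = synthetic_population()
        t1 = run_bia(params, pop)["five_year_total_usd"]
        t2 = run_bia(params, pop.scaled(2.0))["five_year_total_usd"]
        assert np.allclose(t2, 2 * t1)


class TestConfigRoundTrip:
    def test_yaml_round_trip_preserves_everything(self, params, tmp_path):
        path = tmp_path / "config.yaml"
        save_config(params, path)
        back = load_config(path)
        assert config_digest(back) == config_digest(params)
        assert back.policy == params.policy
        assert back.costs["CHOP"].progression_free.dmc.mean == 368.5

    def test_partial_config_falls_back_to_defaults(self, tmp_path):
        path = tmp_path / "partial.yaml"
        path.write_text("calibration:\n  policy: annual_to_cycle\n")
        p = load_config(path)
        assert p.policy.interpretation == "annual_to_cycle"
        assert p.gdp_per_capita == 3846.0  # untouched default

    def test_dict_round_trip(self, params):
        d = params_to_dict(params)
        back = params_from_dict(d)
        assert config_digest(back) == config_digest(params)


def test_full_pipeline_parameter_recovery():
    """generate -> estimate -> calibrate -> run reproduces the base case
    built from the published summaries, within large-n sampling tolerance."""
    base_params = default_parameters()
    base = run_base_case(base_params)

    n = 30_000
    targets = {
        "progression_free": base_params.costs["R-CHOP"].progression_free,
        "progressive": base_params.costs["R-CHOP"].progressive,
    }
    cost_records = generate_cost_records(n, n, targets, cpi=base_params.cpi, seed=8)
    est = estimate_state_parameters(cost_records, cpi=base_params.cpi)
    eq5d = generate_eq5d_records(n, n, seed=9)
    est_u = estimate_utilities(eq5d)

    def cell(state, comp):
        row = est[(est["state"] == state) & (est["component"] == comp)].iloc[0]
        return CostComponent(row["mean"], row["sd"])

    recovered = default_parameters()
    recovered.costs = dict(recovered.costs)
    recovered.costs["R-CHOP"] = StateCostProfile(
        arm="R-CHOP",
        progression_free=StateCosts(
            **{c: cell("progression_free", c) for c in ("dmc", "drug", "dnmc", "ic")}
        ),
        progressive=StateCosts(
            **{c: cell("progressive", c) for c in ("dmc", "drug", "dnmc", "ic")}
        ),
    )
    u = {row["state"]: row["mean"] for _, row in est_u.iterrows()}
    recovered.utilities = UtilityProfile(
        progression_free=u["progression_free"], progressive=u["progressive"]
    )
    res = run_base_case(recovered)
    assert res.summaries["R-CHOP"].total_cost == pytest.approx(
        base.summaries["R-CHOP"].total_cost, rel=0.02
    )
    assert res.summaries["R-CHOP"].qalys == pytest.approx(
        base.summaries["R-CHOP"].qalys, rel=0.02
    )


class TestCLI:
    def test_run_base_case_command(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "out"
        result = runner.invoke(main, ["run-base-case", "-o", str(out)])
        assert result.exit_code == 0, result.output
        assert "USD/QALY" in result.output
        assert (out / "icer.json").exists()

    def test_run_psa_command_deterministic(self, tmp_path):
        runner = CliRunner()
        d1, d2 = tmp_path / "a", tmp_path / "b"
        for d in (d1, d2):
            result = runner.invoke(
                main, ["run-psa", "-o", str(d), "-n", "10", "-s", "4"]
            )
            assert result.exit_code == 0, result.output
        assert (d1 / "psa_draws.csv").read_bytes() == (d2 / "psa_draws.csv").read_bytes()

    def test_run_psa_rejects_bad_iteration_count(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(
            main, ["run-psa", "-o", str(tmp_path / "x"), "-n", "0"]
        )
        assert result.exit_code != 0
        assert "error:" in result.output

    def test_run_bia_command(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(main, ["run-bia", "-o", str(tmp_path / "bia")])
        assert result.exit_code == 0, result.output
        assert "S6" in result.output

    def test_simulate_data_command(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "data"
        result = runner.invoke(main, ["simulate-data", "-o", str(out), "-s", "7"])
        assert result.exit_code == 0, result.output
        assert (out / "synthetic_cost_records.csv").exists()
        assert (out / "synthetic_eq5d_records.csv").exists()

    def test_config_option_respected(self, params, tmp_path):
        cfg = tmp_path / "cfg.yaml"
        save_config(params, cfg)
        runner = CliRunner()
        result = runner.invoke(
            main,
            ["run-base-case", "-c", str(cfg), "-o", str(tmp_path / "out")],
        )
        assert result.exit_code == 0, result.output
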