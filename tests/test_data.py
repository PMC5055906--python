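"""Bundled data, synthetic generation, CSV round-trips and the pipeline."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from ast120ddi import (
    DissolutionFit,
    SyntheticDissolutionSpec,
    SyntheticPKSpec,
    fit_dissolution,
    fit_pk,
    generate_dissolution_curve,
    generate_pk_curve,
    load_fixtures,
    run_pipeline,
)
from ast120ddi import io as tables
from ast120ddi.cli import main as cli_main
from ast120ddi.errors import InputDataError
from ast120ddi.pipeline import PipelineConfig
from conftest import one_compartment_truth


class TestFixtures:
    def test_counts_and_interval_domain(self, fixture_set):
        assert len(fixture_set.results) == 14
        assert len(fixture_set.profiles) == 6
        assert {r.interval_min for r in fixture_set.results} <= {1, 30, 60, 90, 120, 240}
        assert sum(r.observed == "E" for r in fixture_set.results) == 7

    def test_spot_rows(self, fixture_set):
        aml = [r for r in fixture_set.results if r.drug_id == "amlodipine" and r.interval_min == 1][0]
        assert (aml.rd, aml.ra, aml.observed) == (14.2, 1.0, "NE")
        tri = [r for r in fixture_set.results if r.drug_id == "triazolam"][0]
        assert tri.ra == 0.0

    def test_governing_kd_is_the_larger_medium(self, fixture_set):
        assert fixture_set.profile("amlodipine").kd == 25.54e-4
        assert fixture_set.profile("bufferin").kd == 27.64e-4  # pH 6.8 governs


class TestSyntheticGenerators:
    def test_noise_free_dissolution_matches_model(self):
        spec = SyntheticDissolutionSpec(kd=5e-4, xe=90.0, times_min=(10, 20, 40, 80))
        c = generate_dissolution_curve(spec)
        expected = 90.0 * (1 - np.exp(-5e-4 * c.times * 60))
        np.testing.assert_allclose(c.values, expected, rtol=1e-12)

    def test_same_seed_reproduces_curves_bit_for_bit(self):
        spec = SyntheticDissolutionSpec(kd=5e-4, noise_sd_pct=2.0, seed=42)
        a, b = generate_dissolution_curve(spec), generate_dissolution_curve(spec)
        assert np.array_equal(a.values, b.values)
        pk = SyntheticPKSpec(fit=one_compartment_truth(), noise_sd_frac_of_peak=0.05, seed=7)
        assert np.array_equal(
            generate_pk_curve(pk).concentrations, generate_pk_curve(pk).concentrations
        )

    def test_dissolution_monte_carlo_recovery_unbiased(self):
        kd = 25.54e-4
        errors = []
        for seed in range(200):
            spec = SyntheticDissolutionSpec(
                kd=kd, noise_sd_pct=2.0, seed=seed, times_min=(5, 10, 15, 30, 45, 60)
            )
            fit = fit_dissolution(generate_dissolution_curve(spec))
            errors.append((fit.kd - kd) / kd)
        assert abs(float(np.mean(errors))) <= 0.01

    def test_pk_monte_carlo_recovery_small_bias(self):
        truth = one_compartment_truth(ka=1.55, ke=0.25)
        errors = []
        for seed in range(30):
            curve = generate_pk_curve(
                SyntheticPKSpec(fit=truth, noise_sd_frac_of_peak=0.05, seed=seed)
            )
            errors.append((fit_pk(curve, 1).ka - 1.55) / 1.55)
        assert abs(float(np.mean(errors))) <= 0.02


def write_fixture_inputs(tmp_path, noise=0.0):
    """Noise-free measured curves for the six bundled drugs, as CSVs."""
    import pandas as pd

    fx = load_fixtures()
    from ast120ddi.fixtures import DISSOLUTION_RATE_CONSTANTS

    diss_rows, pk_rows = [], []
    for p in fx.profiles:
        for medium, kd in DISSOLUTION_RATE_CONSTANTS[p.drug_id].items():
            c = generate_dissolution_curve(
                SyntheticDissolutionSpec(
                    kd=kd, xe=100.0, tlagd=p.tlagd, noise_sd_pct=noise,
                    # long enough for the slowest bundled formulation to
                    # reach completeness in at least one fluid
                    times_min=(5, 10, 15, 30, 45, 60, 90, 120, 180, 240, 360, 480, 720),
                    drug_id=p.drug_id, medium=medium,
                )
            )
            for t, v in zip(c.times, c.values):
                diss_rows.append(
                    {"drug_id": p.drug_id, "medium": medium, "time_min": t, "dissolved_pct": v}
                )
        truth = one_compartment_truth(ka=p.ka, ke=p.ka / 5, tlaga=p.tlaga, scale=8.0)
        c = generate_pk_curve(
            SyntheticPKSpec(
                fit=truth, drug_id=p.drug_id,
                times_h=tuple(np.linspace(0.25, 24, 12)),
            )
        )
        for t, v in zip(c.times, c.concentrations):
            pk_rows.append({"drug_id": p.drug_id, "time_h": t, "conc": v})

    diss_csv = tmp_path / "dissolution.csv"
    pk_csv = tmp_path / "pk.csv"
    pd.DataFrame(diss_rows).to_csv(diss_csv, index=False)
    pd.DataFrame(pk_rows).to_csv(pk_csv, index=False)
    outcomes_csv = tmp_path / "outcomes.csv"
    tables.write_outcomes_csv(list(fx.results), outcomes_csv)
    return diss_csv, pk_csv, outcomes_csv


class TestCSVRoundTrips:
    def test_fixture_outcome_round_trip_is_exact(self, tmp_path, fixture_results):
        path = tmp_path / "outcomes.csv"
        tables.write_outcomes_csv(fixture_results, path)
        back = tables.outcomes_to_results(tables.read_outcomes_csv(path))
        assert back == fixture_results

    def test_profile_round_trip_is_exact(self, tmp_path, fixture_set):
        path = tmp_path / "profiles.csv"
        tables.write_profiles_csv(list(fixture_set.profiles), path)
        assert tuple(tables.read_profiles_csv(path)) == fixture_set.profiles

    def test_simultaneous_alias_accepted(self, tmp_path):
        path = tmp_path / "o.csv"
        path.write_text(
            "drug_id,interval_min,observed\namlodipine,simultaneous,NE\n"
        )
        rows = tables.read_outcomes_csv(path)
        assert rows[0]["interval_min"] == 1

    def test_malformed_observed_label_rejected(self, tmp_path):
        path = tmp_path / "o.csv"
        path.write_text("drug_id,interval_min,observed\nx,30,maybe\n")
        with pytest.raises(InputDataError):
            tables.read_outcomes_csv(path)


class TestPipeline:
    def test_fixtures_end_to_end_reproduce_region_maximum(self, tmp_path):
        diss_csv, pk_csv, outcomes_csv = write_fixture_inputs(tmp_path)
        report = run_pipeline(
            diss_csv, pk_csv, outcomes_csv, out_dir=tmp_path / "out"
        )
        assert round(report.region.max_predictive_value, 1) == 85.7
        assert report.region.n_consistent == 12
        assert round(report.operating_predictive_value, 1) == 85.7
        doc = json.loads((tmp_path / "out" / "region.json").read_text())
        assert doc["max_predictive_value_pct"] == 85.7
        # six drugs, all classified at the default six intervals
        assert len(report.assignments) == 36

    def test_empty_outcomes_gives_classification_only_run(self, tmp_path):
        diss_csv, pk_csv, _ = write_fixture_inputs(tmp_path)
        empty = tmp_path / "empty.csv"
        empty.write_text("drug_id,interval_min,observed\n")
        report = run_pipeline(diss_csv, pk_csv, empty, out_dir=tmp_path / "out2")
        assert report.region is None
        assert (tmp_path / "out2" / "risk.csv").exists()
        assert not (tmp_path / "out2" / "region.json").exists()

    def test_rerun_is_byte_identical(self, tmp_path):
        diss_csv, pk_csv, outcomes_csv = write_fixture_inputs(tmp_path)
        outs = []
        for name in ("a", "b"):
            out = tmp_path / name
            run_pipeline(diss_csv, pk_csv, outcomes_csv, out_dir=out)
            outs.append(
                {p.name: p.read_bytes() for p in sorted(out.iterdir())}
            )
        assert outs[0] == outs[1]

    def test_outcome_rows_without_profiles_are_listed(self, tmp_path):
        diss_csv, pk_csv, _ = write_fixture_inputs(tmp_path)
        bad = tmp_path / "bad.csv"
        bad.write_text("drug_id,interval_min,observed\nghost_drug,30,E\n")
        with pytest.raises(InputDataError, match="ghost_drug"):
            run_pipeline(diss_csv, pk_csv, bad)


class TestCLI:
    def test_run_subcommand_end_to_end(self, tmp_path):
        diss_csv, pk_csv, outcomes_csv = write_fixture_inputs(tmp_path)
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            [
                "run", "--dissolution", str(diss_csv), "--pk", str(pk_csv),
                "--outcomes", str(outcomes_csv), "--out-dir", str(tmp_path / "cli_out"),
            ],
        )
        assert result.exit_code == 0, result.output
        assert "85.7%" in result.output

    def test_thresholds_subcommand(self, tmp_path, fixture_results):
        outcomes = tmp_path / "outcomes.csv"
        tables.write_outcomes_csv(fixture_results, outcomes)
        out_json = tmp_path / "region.json"
        result = CliRunner().invoke(
            cli_main, ["thresholds", str(outcomes), "--out", str(out_json)]
        )
        assert result.exit_code == 0, result.output
        doc = json.loads(out_json.read_text())
        assert doc["rdth"]["low"] == 84.8
        assert doc["rdth"]["high"] == 95.8
        assert doc["rath"]["low"] == 21.7
        assert doc["rath"]["high"] == 41.6

    def test_simulate_then_fit_recovers_kd(self, tmp_path):
        curve_csv = tmp_path / "sim.csv"
        fits_csv = tmp_path / "fits.csv"
        runner = CliRunner()
        r1 = runner.invoke(
            cli_main,
            ["simulate", "--kd", "0.002554", "--out", str(curve_csv), "--seed", "3"],
        )
        assert r1.exit_code == 0, r1.output
        r2 = runner.invoke(
            cli_main, ["fit-dissolution", str(curve_csv), "--out", str(fits_csv)]
        )
        assert r2.exit_code == 0, r2.output
        import pandas as pd

        df = pd.read_csv(fits_csv)
        assert df.loc[0, "kd_per_s"] == pytest.approx(0.002554, rel=1e-6)
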