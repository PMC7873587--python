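"""Configuration, CSV round-trips, and end-to-end pipeline runs."""

import filecmp

import numpy as np
import pandas as pd
import pytest

from cltsce import datasets
from cltsce.config import AnalysisConfig
from cltsce.io import (
    SchemaError,
    read_ledger_csv,
    read_outcomes_csv,
    read_survey_csv,
    write_ledger_csv,
    write_outcomes_csv,
    write_survey_csv,
)
from cltsce.outcomes import OutcomeChange
from cltsce.pipeline import run_pipeline
from cltsce.synthetic import generate_households


class TestSurveyCSV:
    def test_round_trip_lossless(self, tmp_path, oromia_profile):
        df = generate_households(oromia_profile, 1000, seed=5)
        path = tmp_path / "survey.csv"
        write_survey_csv(df, path)
        back = read_survey_csv(path)
        pd.testing.assert_frame_equal(back, df, check_dtype=False)

    def test_empty_file_warns(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.warns(UserWarning, match="empty"):
            assert len(read_survey_csv(path)) == 0

    def test_missing_column_named(self, tmp_path, oromia_profile):
        df = generate_households(oromia_profile, 5, seed=0).drop(columns=["region"])
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="region"):
            read_survey_csv(path)

    def test_unknown_column_warns(self, tmp_path, oromia_profile):
        df = generate_households(oromia_profile, 5, seed=0)
        df["gps"] = 1.0
        path = tmp_path / "extra.csv"
        df.to_csv(path, index=False)
        with pytest.warns(UserWarning, match="gps"):
            read_survey_csv(path)

    def test_non_numeric_value_names_column_and_row(self, tmp_path, oromia_profile):
        df = generate_households(oromia_profile, 3, seed=0)
        df["n_members"] = df["n_members"].astype(object)
        df.loc[1, "n_members"] = "many"
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match=r"n_members.*row 1"):
            read_survey_csv(path)


class TestLedgerCSV:
    def test_bundled_fixture_parses_fifteen_ledgers(self):
        ledgers = read_ledger_csv(datasets.load_reference_costs_path())
        assert len(ledgers) == 15

    def test_round_trip(self, tmp_path):
        ledgers = list(datasets.load_reference_ledgers().values())
        path = tmp_path / "ledgers.csv"
        write_ledger_csv(ledgers, path)
        back = read_ledger_csv(path)
        assert [lg.amounts() for lg in back] == [lg.amounts() for lg in ledgers]

    def test_unknown_category_names_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "arm,region,category,amount_usd\nA,R,management,10\nA,R,overheads,5\n"
        )
        with pytest.raises(SchemaError, match=r"overheads.*row 1"):
            read_ledger_csv(path)

    def test_empty_file_warns(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.warns(UserWarning, match="empty"):
            assert read_ledger_csv(path) == []

    def test_hours_rate_rows(self, tmp_path):
        path = tmp_path / "hr.csv"
        path.write_text(
            "arm,region,category,amount_usd,hours,rate_usd_per_hour\n"
            "A,R,community_time,,120,0.5\n"
        )
        (lg,) = read_ledger_csv(path)
        assert lg.community_time == 60.0


class TestOutcomesCSV:
    def test_round_trip(self, tmp_path):
        changes = list(datasets.load_reference_outcomes().values())
        path = tmp_path / "outcomes.csv"
        write_outcomes_csv(changes, path)
        assert read_outcomes_csv(path) == changes


class TestConfig:
    def test_defaults_are_valid(self):
        cfg = AnalysisConfig()
        assert set(cfg.outcome_measures) == {"stopped_od", "gained_ownership"}

    def test_no_outcome_measure_rejected(self):
        with pytest.raises(ValueError, match="outcome measure"):
            AnalysisConfig(outcome_measures=())

    def test_missing_path_rejected(self):
        with pytest.raises(FileNotFoundError):
            AnalysisConfig(ledger_path="/nonexistent/ledgers.csv")

    def test_from_file_json_and_unknown_key(self, tmp_path):
        good = tmp_path / "cfg.json"
        good.write_text('{"outcome_measures": ["stopped_od"]}')
        assert AnalysisConfig.from_file(good).outcome_measures == ["stopped_od"]
        bad = tmp_path / "bad.yaml"
        bad.write_text("discounting: 0.03\n")
        with pytest.raises(ValueError, match="discounting"):
            AnalysisConfig.from_file(bad)


class TestPipeline:
    def test_single_column_filter(self):
        cfg = AnalysisConfig(
            arms=["Teacher CLTS"], regions=["Oromia"],
            psa={"enabled": False},
        )
        bundle = run_pipeline(cfg)
        assert len(bundle.cost_table) == 1
        assert len(bundle.ce_table) == 2  # two outcome measures
        row = bundle.ce_table.iloc[0]
        assert row["ce_per_household"] == pytest.approx(30239 / 895, abs=0.01)

    def test_no_overlap_rejected(self):
        with pytest.raises(ValueError, match="no .* column"):
            run_pipeline(AnalysisConfig(arms=["Nonexistent"]))

    def test_suppressed_cells_logged(self):
        bundle = run_pipeline(AnalysisConfig(psa={"enabled": False}))
        assert len(bundle.suppressed) == 4  # two SNNP arms × two measures
        assert all("SNNP" in s for s in bundle.suppressed)

    def test_end_to_end_determinism(self, tmp_path):
        """Identical config and seed give byte-identical report bundles."""
        cfg = AnalysisConfig(psa={"n_draws": 200, "seed": 7})
        run_pipeline(cfg).write(tmp_path / "a")
        run_pipeline(cfg).write(tmp_path / "b")
        for name in (
            "outcome_table.csv",
            "cost_table.csv",
            "ce_table.csv",
            "psa_table.csv",
            "suppressed_cells.log",
        ):
            assert filecmp.cmp(
                tmp_path / "a" / name, tmp_path / "b" / name, shallow=False
            ), name

    def test_survey_mode(self, tmp_path, oromia_profile):
        """The pipeline classifies a synthetic survey and reports CE on
        the classified outcome counts."""
        survey = generate_households(oromia_profile, 800, seed=21, arm="HEW CLTS")
        survey_path = tmp_path / "survey.csv"
        write_survey_csv(survey, survey_path)
        write_ledger_csv(
            [datasets.load_reference_ledgers()[("HEW CLTS", "Oromia")]],
            tmp_path / "ledgers.csv",
        )
        cfg = AnalysisConfig(
            ledger_path=str(tmp_path / "ledgers.csv"),
            survey_path=str(survey_path),
            psa={"enabled": False},
        )
        bundle = run_pipeline(cfg)
        assert len(bundle.ce_table) == 2
        assert bundle.ce_table["defined"].all()


def test_profile_for_pilot_arm():
    with pytest.warns(UserWarning, match="clamped"):
        p = datasets.profile_for("Oromia", "Teacher CLTS")
    assert p.delta_od == pytest.approx(-0.56)
    assert p.baseline_ownership == pytest.approx(0.51)
    # +53% ownership on a 51% region-wide baseline is infeasible; clamped
    assert p.delta_ownership == pytest.approx(0.49)
    q = datasets.profile_for("Volta", "NGO CLTS")
    assert q.delta_od == pytest.approx(-0.09)
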