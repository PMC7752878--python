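import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import survodds as so
from survodds.cli import main as cli_main
from survodds.study import (
    AnalysisPlan,
    DEFAULT_ADJUSTMENT,
    OR_TABLE_COLUMNS,
    OR_TABLE_ROWS,
    run_study,
)

from conftest import make_cohort


@pytest.fixture(scope="module")
def study_cohort():
    return so.assemble_cohort(so.default_config(n=600, seed=77))


@pytest.fixture(scope="module")
def study_report(study_cohort, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("report")
    report = run_study(study_cohort, AnalysisPlan(), outdir, seed=77)
    return report, outdir


def test_report_bundle_files_exist(study_report):
    report, outdir = study_report
    expected = {
        "descriptive_summary.csv",
        "descriptive_summary.json",
        "aic_log.csv",
        "manifest.json",
        "or_table_d90_all_cause.csv",
        "or_table_y5_all_cause.csv",
        "or_table_y5_disease_specific.csv",
        "curves_d90_all_cause.csv",
        "curves_y5_all_cause.csv",
        "curves_y5_disease_specific.csv",
        "stratified_d90_all_cause.csv",
        "stratified_y5_all_cause.csv",
    }
    assert expected <= {p.name for p in outdir.iterdir()}
    for ep, r in report["endpoints"].items():
        assert r["status"] == "ok", (ep, r["status"])


def test_or_table_layout_conforms(study_report):
    """Every endpoint OR table has exactly the published layout: linear age,
    <70 reference, 70-74 and >=75 contrasts; unadjusted and adjusted."""
    _, outdir = study_report
    for ep in ("d90_all_cause", "y5_all_cause", "y5_disease_specific"):
        table = pd.read_csv(outdir / f"or_table_{ep}.csv")
        assert list(table.columns) == list(OR_TABLE_COLUMNS)
        assert list(table["term"]) == list(OR_TABLE_ROWS)
        ref = table.set_index("term").loc["age[<70]"]
        assert ref["or_unadjusted"] == 1.0 and ref["or_adjusted"] == 1.0
        est = table.set_index("term").loc[["age_linear", "age[70-74]", "age[>=75]"]]
        assert (est["ci_low_adjusted"] <= est["or_adjusted"]).all()
        assert (est["or_adjusted"] <= est["ci_high_adjusted"]).all()
        assert (est[["or_unadjusted", "or_adjusted"]] > 0).all().all()


def test_adjustment_sets_match_design(study_report):
    assert DEFAULT_ADJUSTMENT["d90_all_cause"] == (
        "sex", "education", "cci", "histology", "stage", "margin")
    assert DEFAULT_ADJUSTMENT["y5_disease_specific"] == (
        "sex", "education", "neoadjuvant", "histology", "stage", "margin")


def test_aic_log_records_candidates_and_selection(study_report):
    _, outdir = study_report
    log = pd.read_csv(outdir / "aic_log.csv")
    for ep in ("d90_all_cause", "y5_all_cause", "y5_disease_specific"):
        sub = log[log["endpoint"] == ep]
        assert len(sub) >= 2
        assert sub["selected"].sum() == 1
        chosen = sub[sub["selected"]].iloc[0]
        assert chosen["aic"] == sub[sub["converged"]]["aic"].min()


def test_stratified_tables_cover_all_strata(study_report):
    _, outdir = study_report
    table = pd.read_csv(outdir / "stratified_y5_all_cause.csv")
    assert set(table["stratifier"]) == {"sex", "histology", "stage", "margin"}
    for strat, levels in (("sex", 2), ("stage", 2)):
        assert table[table["stratifier"] == strat]["stratum"].nunique() == levels
    estimable = table[table["estimable"] & table["ci_low"].notna()]
    assert (estimable["or"] >= estimable["ci_low"] - 1e-12).all()
    assert (estimable["or"] <= estimable["ci_high"] + 1e-12).all()


def test_curves_are_valid_probability_and_survival(study_report):
    _, outdir = study_report
    curves = pd.read_csv(outdir / "curves_y5_all_cause.csv")
    assert set(curves["age_profile"]) == {60.0, 70.0, 80.0}
    for _, grp in curves.groupby("age_profile"):
        assert grp["S"].iloc[0] == pytest.approx(1.0, abs=1e-9)
        assert (grp["S"].diff().dropna() <= 1e-9).all()
        assert grp["g"].between(0, 1).all()


def test_manifest_has_seed_and_hashes_no_timestamps(study_report):
    _, outdir = study_report
    manifest = json.loads((outdir / "manifest.json").read_text())
    assert manifest["seed"] == 77
    assert len(manifest["cohort_sha256"]) == 64
    assert manifest["version"] == so.__version__
    assert "time" not in " ".join(manifest.keys()).lower()


def test_rerun_is_byte_identical(study_cohort, tmp_path):
    a, b = tmp_path / "a", tmp_path / "b"
    run_study(study_cohort, AnalysisPlan(), a, seed=77)
    run_study(study_cohort, AnalysisPlan(), b, seed=77)
    files = sorted(p.name for p in a.iterdir())
    assert files == sorted(p.name for p in b.iterdir())
    for name in files:
        assert (a / name).read_bytes() == (b / name).read_bytes(), name


def test_cohort_without_deaths_reports_but_does_not_crash(tmp_path):
    coh = make_cohort(
        n=5,
        followup_days=(2000,) * 5,
        dead=(0,) * 5,
        cancer_death=(0,) * 5,
        ages=(60.0, 65.0, 70.0, 75.0, 80.0),
    )
    report = run_study(coh, AnalysisPlan(), tmp_path)
    assert (tmp_path / "descriptive_summary.csv").exists()
    for ep, r in report["endpoints"].items():
        assert "no events" in r["status"]


def test_zero_event_stratum_marked_non_estimable(study_cohort, tmp_path):
    coh = study_cohort.copy()
    # wipe out all deaths among R1-R2 subjects: that stratum becomes empty
    mask = coh["margin"] == "R1-R2"
    coh.loc[mask, "dead"] = 0
    coh.loc[mask, "cancer_death"] = 0
    coh.loc[mask, "followup_days"] = 2200
    report = run_study(coh, AnalysisPlan(), tmp_path)
    strat = report["endpoints"]["y5_all_cause"]["stratified"]
    r12 = strat[(strat["stratifier"] == "margin") & (strat["stratum"] == "R1-R2")]
    assert (~r12["estimable"]).all()
    assert report["endpoints"]["y5_all_cause"]["status"] == "ok"


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


def test_cli_simulate_validate_roundtrip(tmp_path):
    runner = CliRunner()
    out = tmp_path / "cohort.csv"
    res = runner.invoke(cli_main, ["simulate", "--n", "120", "--seed", "4",
                                   "--out", str(out)])
    assert res.exit_code == 0, res.output
    res = runner.invoke(cli_main, ["validate", str(out)])
    assert res.exit_code == 0
    assert "120 valid rows" in res.output


def test_cli_validate_rejects_bad_rows(tmp_path):
    coh = make_cohort()
    coh.loc[0, "cancer_death"] = 1
    coh.loc[0, "dead"] = 0
    path = tmp_path / "bad.csv"
    coh.to_csv(path, index=False)
    res = CliRunner().invoke(cli_main, ["validate", str(path)])
    assert res.exit_code == 2
    assert "cancer_death" in res.output


def test_cli_fit_reports_estimates(tmp_path):
    coh = so.assemble_cohort(so.default_config(n=400, seed=19))
    path = tmp_path / "cohort.csv"
    coh.to_csv(path, index=False)
    res = CliRunner().invoke(
        cli_main,
        ["fit", str(path), "--endpoint", "y5_all_cause", "--adjust", "sex,stage"],
    )
    assert res.exit_code == 0, res.output
    assert "converged=True" in res.output
    assert "age" in res.output
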