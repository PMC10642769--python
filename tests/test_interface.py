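"""CSV I/O, schema validation, fixtures and the command-line layer."""
import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import espd
from espd.cli import main as cli_main
from espd.interface import MELANOMA_SCHEMA, DatasetSchema
from espd.model import INTERCEPT, DataError

STAGE_SCHEMA = DatasetSchema(
    factor_covariates={"stage": (("IA", "IB", "II"), "IA")},
    numeric_covariates=("age_c",))


def test_read_small_wellformed_csv(tmp_path):
    p = tmp_path / "d.csv"
    p.write_text("time,event,stage,age_c\n1.5,recur,IA,0.3\n"
                 "2.0,death,IB,-1.2\n0.7,cens,II,2.0\n")
    data = espd.read_dataset(p, STAGE_SCHEMA)
    assert data.n == 3
    np.testing.assert_array_equal(data.X[INTERCEPT], 1.0)
    np.testing.assert_array_equal(data.X["stageIB"], [0.0, 1.0, 0.0])
    np.testing.assert_array_equal(data.X["stageII"], [0.0, 0.0, 1.0])


def test_unknown_label_and_negative_time_are_labelled_errors(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("time,event,stage,age_c\n1.0,dead,IA,0\n")
    with pytest.raises(DataError, match="dead"):
        espd.read_dataset(p, STAGE_SCHEMA)
    p.write_text("time,event,stage,age_c\n-1.0,recur,IA,0\n")
    with pytest.raises(DataError, match="negative"):
        espd.read_dataset(p, STAGE_SCHEMA)
    p.write_text("time,event,stage,age_c\n1.0,recur,III,0\n")
    with pytest.raises(DataError, match="III"):
        espd.read_dataset(p, STAGE_SCHEMA)


def test_write_read_roundtrip_preserves_typed_content(tmp_path, population):
    sample = population.subset(range(50))
    p = tmp_path / "roundtrip.csv"
    espd.write_dataset(sample, p)
    back = espd.read_dataset(p, STAGE_SCHEMA)
    np.testing.assert_allclose(back.time, sample.time)
    np.testing.assert_array_equal(back.event, sample.event)
    for col in ("stageIB", "stageII", "age_c"):
        np.testing.assert_allclose(back.X[col], sample.X[col], atol=1e-12)


def test_melanoma_like_marginals_match_published_summary():
    data = espd.make_melanoma_like(100_000, seed=2)
    X = data.X
    assert np.mean(X["male"]) == pytest.approx(0.39, abs=0.03)
    assert np.mean(X["ulcer"]) == pytest.approx(0.44, abs=0.03)
    assert np.median(np.exp(X["log_thickness"])) == pytest.approx(1.94,
                                                                  rel=0.15)
    assert np.median(X["age"]) == pytest.approx(54, abs=3)
    assert np.mean(data.event == "cens") == pytest.approx(0.068, abs=0.02)
    assert np.mean(data.event == "recur") == pytest.approx(0.65, abs=0.03)
    assert np.mean(data.event == "death") == pytest.approx(0.28, abs=0.03)
    assert np.median(data.time) == pytest.approx(5.5, rel=0.15)


def test_melanoma_like_single_row():
    data = espd.make_melanoma_like(1, seed=0)
    assert data.n == 1
    assert data.event[0] in {"recur", "death", "cens"}
    assert data.time[0] >= 0


def test_melanoma_loader_recodes_status(tmp_path):
    p = tmp_path / "mel.csv"
    p.write_text("time,status,sex,age,thickness,ulcer\n"
                 "730.5,1,1,50,2.0,1\n365.25,2,0,60,1.0,0\n"
                 "1826.25,3,1,70,5.0,1\n")
    data = espd.load_melanoma(p, status_map={1: "death", 2: "cens",
                                             3: "recur"})
    np.testing.assert_allclose(data.time, [2.0, 1.0, 5.0])
    np.testing.assert_array_equal(data.event, ["death", "cens", "recur"])
    with pytest.raises(DataError, match="status"):
        espd.load_melanoma(p, status_map={1: "death"})


def test_runconfig_yaml_roundtrip(tmp_path):
    p = tmp_path / "cfg.yaml"
    p.write_text("seed: 3\nmode: mle\n"
                 "numeric_covariates: [age_c]\n"
                 "factor_covariates:\n  stage: [[IA, IB, II], IA]\n"
                 "pi_covariates: [intercept, stageIB, stageII]\n")
    cfg = espd.RunConfig.from_yaml(p)
    assert cfg.seed == 3
    assert cfg.factor_covariates["stage"] == (("IA", "IB", "II"), "IA")
    assert cfg.spec().n_coefficients > 0
    assert len(cfg.digest()) == 12
    p.write_text("sneaky_key: 1\n")
    with pytest.raises(ValueError, match="unknown config key"):
        espd.RunConfig.from_yaml(p)


# -- command line -----------------------------------------------------------

@pytest.fixture()
def runner():
    return CliRunner()


def test_cli_simulate_then_fit_is_reproducible(runner, tmp_path):
    cfg = tmp_path / "cfg.yaml"
    cfg.write_text(
        "mode: mle\n"
        "numeric_covariates: [age_c]\n"
        "factor_covariates:\n  stage: [[IA, IB, II], IA]\n"
        "pi_covariates: [intercept, stageIB, stageII]\n"
        "theta_covariates:\n"
        "  recur: {scale: [intercept, stageIB, stageII]}\n"
        "  death: {rate: [intercept, age_c]}\n")
    sim_csv = tmp_path / "sim.csv"
    r = runner.invoke(cli_main, ["simulate", "--n", "800", "--seed", "4",
                                 "--out", str(sim_csv)])
    assert r.exit_code == 0, r.output
    assert sim_csv.exists()

    outs = []
    for name in ("fit1.json", "fit2.json"):
        out = tmp_path / name
        r = runner.invoke(cli_main, ["fit", str(sim_csv), "--config",
                                     str(cfg), "--seed", "9", "--out",
                                     str(out)])
        assert r.exit_code == 0, r.output
        outs.append(out.read_bytes())
    assert outs[0] == outs[1]
    payload = json.loads(outs[0])
    assert payload["converged"] is True
    assert "pi.recur.intercept" in payload["coefficients"]


def test_cli_censor_roundtrip(runner, tmp_path):
    sim_csv = tmp_path / "sim.csv"
    runner.invoke(cli_main, ["simulate", "--n", "500", "--seed", "1",
                             "--out", str(sim_csv)])
    out_csv = tmp_path / "cens.csv"
    r = runner.invoke(cli_main, ["censor", str(sim_csv), "--p-censored",
                                 "0.3", "--seed", "2", "--out",
                                 str(out_csv)])
    assert r.exit_code == 0, r.output
    df = pd.read_csv(out_csv)
    assert np.mean(df["event"] == "cens") == pytest.approx(0.3, abs=0.05)


def test_cli_study_writes_table_and_log(runner, tmp_path):
    out_csv = tmp_path / "study.csv"
    r = runner.invoke(cli_main, ["study", "--n-run", "2", "--n-sim", "2000",
                                 "--scenario", "0.0,100", "--seed", "3",
                                 "--out", str(out_csv)])
    assert r.exit_code == 0, r.output
    assert out_csv.exists()
    log = (tmp_path / "espd.log").read_text()
    assert "seed=3" in log and "espd 0.1" in log
    wide = pd.read_csv(out_csv)
    assert "prob_recur.RAE" in wide.columns


def test_cli_invalid_config_fails_before_computation(runner, tmp_path):
    cfg = tmp_path / "bad.yaml"
    cfg.write_text("no_such_option: true\n")
    csv = tmp_path / "d.csv"
    csv.write_text("time,event\n1.0,recur\n")
    r = runner.invoke(cli_main, ["fit", str(csv), "--config", str(cfg)])
    assert r.exit_code != 0
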