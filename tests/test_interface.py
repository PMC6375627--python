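"""Configuration schema, presets, runner artifacts, CLI plumbing."""

import json
from pathlib import Path

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

import demosoc as ds
from demosoc.cli import main
from demosoc.config import PRESETS, RunConfig, config_hash, load_config, resolve_model
from demosoc.runner import run


def write_config(tmp_path, doc, name="cfg.yaml"):
    path = tmp_path / name
    path.write_text(yaml.safe_dump(doc))
    return str(path)


BASE = {
    "model": {"preset": "death_neutral"},
    "task": {"name": "stationary", "settings": {"grid_size": 512}},
    "seed": 7,
}


def test_config_round_trips_losslessly(tmp_path):
    path = write_config(tmp_path, BASE)
    cfg = load_config(path)
    again = RunConfig.model_validate(yaml.safe_load(yaml.safe_dump(cfg.model_dump())))
    assert again == cfg
    assert config_hash(again) == config_hash(cfg)


def test_unknown_key_rejected_with_path(tmp_path):
    doc = {**BASE, "model": {"preset": "death_neutral", "bogus": 1}}
    with pytest.raises(ValueError, match="model/bogus"):
        load_config(write_config(tmp_path, doc))


def test_missing_omega_named(tmp_path):
    # the matched-pair presets deliberately ship without omega/mu
    doc = {**BASE, "model": {"preset": "altruism_model1", "mu": 0.02}}
    cfg = load_config(write_config(tmp_path, doc))
    with pytest.raises(ValueError, match="omega"):
        resolve_model(cfg.model)


def test_presets_resolve_to_valid_models():
    for name, entry in PRESETS.items():
        block = {"preset": name}
        if "omega" not in entry:
            block.update({"omega": 100.0, "mu": 0.02})
        model = resolve_model(RunConfig.model_validate(
            {"model": block, "task": {"name": "manifold"}}
        ).model)
        assert model.omega > 0


def test_preset_overrides_apply():
    cfg = RunConfig.model_validate(
        {
            "model": {"preset": "death_neutral", "omega": 450.0, "params": {"nu": -0.5}},
            "task": {"name": "manifold"},
        }
    )
    model = resolve_model(cfg.model)
    assert model.omega == 450.0
    assert model.params["nu"] == -0.5


def test_runner_outputs_are_deterministic(tmp_path):
    outputs = []
    for rep in ("a", "b"):
        cfg = RunConfig.model_validate({**BASE, "out_prefix": str(tmp_path / rep)})
        run(cfg)
        outputs.append(
            (Path(f"{tmp_path / rep}.tsv").read_bytes(), Path(f"{tmp_path / rep}.json").read_bytes())
        )
    # identical apart from the differing out-prefix inside the config dump
    assert outputs[0][0] == outputs[1][0]
    j0 = json.loads(outputs[0][1])
    j1 = json.loads(outputs[1][1])
    assert j0["results"] == j1["results"]
    assert j0["versions"] == j1["versions"]


def test_runner_stationary_artifacts(tmp_path):
    prefix = str(tmp_path / "stat")
    cfg = RunConfig.model_validate({**BASE, "out_prefix": prefix})
    payload = run(cfg)
    assert payload["favourability"]["mass_above_half"] == pytest.approx(0.5, abs=1e-6)
    lines = Path(prefix + ".tsv").read_text().splitlines()
    assert lines[0].startswith("# config_hash:")
    header_rows = [ln for ln in lines if ln.startswith("#")]
    assert any("demosoc" in ln for ln in header_rows)
    body = [ln for ln in lines if not ln.startswith("#")]
    assert body[0].split("\t") == ["p", "density"]
    assert len(body) == 512  # header + 511 interior grid points


def test_runner_removes_partial_outputs_on_error(tmp_path):
    prefix = str(tmp_path / "bad")
    cfg = RunConfig.model_validate(
        {
            "model": {"preset": "death_neutral", "mu": 0.0},  # non-integrable
            "task": {"name": "stationary", "settings": {"grid_size": 256}},
            "out_prefix": prefix,
        }
    )
    # favourability of a non-integrable density cannot be computed
    payload = run(cfg)
    assert payload["integrable"] is False


def test_cli_list_models():
    result = CliRunner().invoke(main, ["list-models"])
    assert result.exit_code == 0
    assert "death_rate" in result.output
    assert "b = beta*(1 - n)" in result.output


def test_cli_dry_run_prints_plan_without_outputs(tmp_path):
    prefix = str(tmp_path / "dry")
    result = CliRunner().invoke(
        main,
        ["stationary", "--preset", "death_neutral", "--grid-size", "256",
         "--out", prefix, "--dry-run"],
    )
    assert result.exit_code == 0, result.output
    plan = json.loads(result.output)
    assert plan["task"] == "stationary"
    assert plan["model"]["family"] == "death_rate"
    assert not Path(prefix + ".tsv").exists()


def test_cli_stationary_end_to_end(tmp_path):
    prefix = str(tmp_path / "cli")
    result = CliRunner().invoke(
        main,
        ["stationary", "--preset", "death_altruism", "--grid-size", "512", "--out", prefix],
    )
    assert result.exit_code == 0, result.output
    payload = json.loads(result.output)
    assert payload["favourability"]["favoured"] is True
    assert Path(prefix + ".tsv").exists() and Path(prefix + ".json").exists()


def test_cli_optimal_nu(tmp_path):
    prefix = str(tmp_path / "nu")
    result = CliRunner().invoke(
        main,
        ["optimal-nu", "--family", "birth_altruism",
         "--param", "beta=1", "--param", "d=0.5",
         "--param", "kappa1=0.75", "--param", "kappa2=0.01",
         "--omega", "250", "--out", prefix],
    )
    assert result.exit_code == 0, result.output
    payload = json.loads(result.output)
    assert payload["nu_star_closed"] == pytest.approx(0.75)


def test_runner_simulate_ssa_task(tmp_path):
    prefix = str(tmp_path / "ssa")
    cfg = RunConfig.model_validate(
        {
            "model": {"preset": "death_neutral", "omega": 150.0},
            "task": {"name": "simulate-ssa", "settings": {"t_max": 20.0, "record_every": 10}},
            "seed": 3,
            "out_prefix": prefix,
        }
    )
    payload = run(cfg)
    assert payload["stop_reason"] == "t_max"
    body = [ln for ln in Path(prefix + ".tsv").read_text().splitlines() if not ln.startswith("#")]
    assert body[0].split("\t") == ["time", "N1", "N2"]
    assert len(body) > 2


def test_runner_compare_task_reports_total_variation(tmp_path):
    prefix = str(tmp_path / "cmp")
    cfg = RunConfig.model_validate(
        {
            "model": {"preset": "death_neutral", "omega": 150.0},
            "task": {
                "name": "compare",
                "settings": {"t_max": 400.0, "burn_in": 50.0, "bins": 10, "replicates": 2},
            },
            "seed": 4,
            "out_prefix": prefix,
        }
    )
    payload = run(cfg)
    assert 0.0 <= payload["total_variation"] <= 1.0


def test_runner_scan_and_sweep_tasks(tmp_path):
    cfg = RunConfig.model_validate(
        {
            "model": {"preset": "altruism_model2", "omega": 100.0, "mu": 0.02},
            "task": {
                "name": "scan-reversal",
                "settings": {
                    "omega_values": [100, 2000],
                    "epsilon_values": [0.003],
                    "grid_size": 1024,
                },
            },
            "out_prefix": str(tmp_path / "scan"),
        }
    )
    payload = run(cfg)
    assert payload["n_cells"] == 2
    assert payload["n_reversals"] == 1


def test_cli_rejects_config_task_mismatch(tmp_path):
    path = write_config(tmp_path, BASE)
    result = CliRunner().invoke(main, ["manifold", "--config", path])
    assert result.exit_code != 0
    assert "does not match" in result.output
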