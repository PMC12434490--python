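import json

import numpy as np
import pytest

from flowamide import (Campaign, PAPER_WEIGHTS, StyInputs, compute_sty,
                       default_config, observe, read_campaign, run_full_study,
                       scalarize, stratified_lhc, write_campaign)
from flowamide.campaign import load_config, save_config, space_from_config


class TestComputeSty:
    def test_batch_literature_entry(self):
        # 125 mM, 89% yield, 18 h, MW 191.23 -> 1.18 g/L/h
        sty = compute_sty(StyInputs(0.125, 0.89, 18.0, 191.23))
        assert round(sty, 2) == 1.18

    def test_zero_yield_gives_zero(self):
        assert compute_sty(StyInputs(0.125, 0.0, 18.0, 191.23)) == 0.0

    def test_flow_optimum_productivity(self):
        # 209 mM, 94%, 8.4 min residence time
        sty = compute_sty(StyInputs(0.209, 0.94, 8.4 / 60.0, 191.23))
        assert sty == pytest.approx(268.3, abs=0.2)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            StyInputs(0.125, 0.89, 0.0, 191.23)
        with pytest.raises(ValueError):
            StyInputs(0.125, 1.2, 1.0, 191.23)


def _campaign(space, params, n=8, seed=0):
    camp = Campaign(stage="stage2", seed=seed)
    for i, c in enumerate(stratified_lhc(space, n, seed=seed)):
        obs = observe(c, params, seed=i)
        camp.append(c, obs, objective_f=scalarize(obs, PAPER_WEIGHTS))
    return camp


class TestCampaignCsv:
    def test_lossless_round_trip(self, space, params, tmp_path):
        camp = _campaign(space, params)
        path = tmp_path / "c.csv"
        write_campaign(camp, path)
        back = read_campaign(path, space)
        assert back.stage == camp.stage and back.seed == camp.seed
        for a, b in zip(camp.experiments, back.experiments):
            assert np.allclose(a.conditions.as_array(), b.conditions.as_array(),
                               rtol=1e-9)
            assert a.conditions.solvent == b.conditions.solvent
            assert a.observation.product_norm == pytest.approx(
                b.observation.product_norm, rel=1e-9)
            assert a.objective_f == pytest.approx(b.objective_f, rel=1e-9)

    def test_unknown_solvent_reported_with_line(self, space, params, tmp_path):
        camp = _campaign(space, params)
        path = tmp_path / "c.csv"
        write_campaign(camp, path)
        text = path.read_text().replace("anisole", "DMSO")
        path.write_text(text)
        with pytest.raises(ValueError, match=r"c\.csv:\d+.*DMSO"):
            read_campaign(path, space)

    def test_empty_file_warns(self, space, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.warns(UserWarning, match="empty"):
            camp = read_campaign(path, space)
        assert len(camp) == 0

    def test_unknown_version_rejected(self, space, tmp_path):
        path = tmp_path / "v.csv"
        path.write_text("# other-schema-v9\na,b\n")
        with pytest.raises(ValueError, match="version"):
            read_campaign(path, space)


class TestConfig:
    def test_default_budget_is_108_experiments(self):
        cfg = default_config()
        total = (cfg["stage1"]["n_init"] + cfg["stage1"]["n_iter"]
                 + cfg["stage2"]["n_init"] + cfg["stage2"]["n_iter"])
        assert total == 108

    def test_yaml_round_trip_and_overrides(self, tmp_path):
        cfg = default_config()
        cfg["stage1"]["n_iter"] = 5
        path = tmp_path / "cfg.yaml"
        save_config(cfg, path)
        back = load_config(path)
        assert back["stage1"]["n_iter"] == 5
        assert back["stage2"]["n_iter"] == 27  # untouched default retained
        space = space_from_config(back)
        assert space.levels == ("MeCN", "2-MeTHF", "anisole", "dioxane")

    def test_unknown_section_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("reactor:\n  volume: 2\n")
        with pytest.raises(ValueError, match="unknown config section"):
            load_config(path)


def _tiny_config():
    cfg = default_config()
    cfg["stage1"].update(n_iter=3, population=30, generations=15, n_features=200)
    cfg["stage2"].update(n_iter=2, n_starts=5)
    cfg["gp"]["n_restarts"] = 2
    cfg["stability"]["samples_per_hour"] = 1
    return cfg


@pytest.fixture(scope="module")
def run_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("study")
    summary = run_full_study(_tiny_config(), seed=7, out_dir=out)
    return out, summary


class TestRunFullStudy:
    def test_all_artifacts_written(self, run_dir):
        out, _ = run_dir
        expected = {"simulator_params.json", "stability.csv", "stage1.csv",
                    "stage2.csv", "weights.json", "summary.json",
                    "manifest.json", "pareto_front.csv", "latent_coords.csv",
                    "lengthscales_product.csv", "lengthscales_impurity.csv",
                    "partial_dependence.csv", "best_by_solvent.csv"}
        assert expected <= {p.name for p in out.iterdir()}

    def test_campaign_sizes_match_config(self, run_dir, space):
        out, summary = run_dir
        assert len(read_campaign(out / "stage1.csv", space)) == 12
        assert len(read_campaign(out / "stage2.csv", space)) == 14
        assert summary["manifest"]["total_optimisation_experiments"] == 26

    def test_same_seed_reproduces_campaigns_byte_for_byte(self, run_dir,
                                                          tmp_path):
        out, _ = run_dir
        rerun = tmp_path / "again"
        run_full_study(_tiny_config(), seed=7, out_dir=rerun)
        for name in ("stage1.csv", "stage2.csv", "stability.csv",
                     "weights.json", "summary.json"):
            assert (out / name).read_bytes() == (rerun / name).read_bytes()

    def test_manifest_records_config_and_seed(self, run_dir):
        out, summary = run_dir
        with open(out / "manifest.json") as fh:
            manifest = json.load(fh)
        assert manifest["seed"] == 7
        assert len(manifest["config_sha256"]) == 64
        assert manifest == summary["manifest"]

    def test_failure_names_the_stage(self, tmp_path):
        cfg = _tiny_config()
        cfg["stability"]["total_hours"] = 7.0  # not a multiple of the cycle
        with pytest.raises(RuntimeError, match="stability"):
            run_full_study(cfg, seed=1, out_dir=tmp_path / "failing")
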