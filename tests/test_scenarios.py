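"""Scenario orchestration: configs, determinism, metrics, meshes, reports."""

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
import yaml

from pouchsim import Component, GridCoord, Lineage
from pouchsim.scenarios_io import (
    ScenarioConfig,
    build_simulation,
    compute_metrics,
    default_config,
    export_mesh,
    load_dump,
    pouchitis_gradient_report,
    read_mesh,
    run_scenario,
    terminal_metaplastic_fraction,
)
from tests.conftest import small_config


# ----------------------------------------------------------------------
# configuration


def test_config_roundtrips_losslessly_through_yaml(tmp_path):
    cfg = default_config("pouchitis", seed=7)
    cfg.rules.theta_wnt = 0.123
    cfg.signaling.w_stat3 = 0.7
    p = tmp_path / "cfg.yaml"
    cfg.to_yaml(p)
    back = ScenarioConfig.from_yaml(p)
    assert back.to_dict() == cfg.to_dict()


def test_shipped_parameter_file_matches_code_defaults():
    from pouchsim.scenarios_io import shipped_defaults

    d = default_config("homeostasis").to_dict()
    shipped = shipped_defaults()
    for block in ("geometry", "rules", "signaling", "stool", "perturbation"):
        assert shipped[block] == d[block]


def test_invalid_configs_rejected_before_compute():
    with pytest.raises(ValueError, match="unknown scenario"):
        default_config("volvulus")
    cfg = default_config("homeostasis")
    cfg.rules.shed_prob = 2.0
    with pytest.raises(ValueError, match="shed_prob"):
        cfg.validate()
    cfg = default_config("homeostasis")
    cfg.n_steps = 0
    with pytest.raises(ValueError, match="n_steps"):
        cfg.validate()


def test_pouchitis_config_constructs_anatomic_cylinder(tmp_path):
    cfg = small_config("pouchitis", n_steps=2, out_dir=str(tmp_path))
    cfg.geometry.diameter_cm = 3.5
    cfg.geometry.length_cm = 6.0
    run_scenario(cfg)
    resolved = yaml.safe_load((tmp_path / "resolved_config.yaml").read_text())
    assert resolved["geometry"]["diameter_cm"] == 3.5
    assert resolved["geometry"]["length_cm"] == 6.0
    anat = resolved["anatomic_geometry"]
    assert anat["n_circ"] == 219 and anat["n_axial"] == 120


# ----------------------------------------------------------------------
# determinism


def test_same_config_and_seed_give_byte_identical_outputs(tmp_path):
    outs = []
    for sub in ("a", "b"):
        cfg = small_config("homeostasis", seed=5, n_steps=60,
                           out_dir=str(tmp_path / sub), dump_every=30)
        run_scenario(cfg)
        outs.append(tmp_path / sub)
    for name in ("timeseries.csv", "state_000030.csv", "state_final.csv",
                 "tissue_final.ply", "metrics.json"):
        assert (outs[0] / name).read_bytes() == (outs[1] / name).read_bytes()


def test_worker_counts_give_identical_outputs(tmp_path):
    outs = []
    for p in (1, 4):
        cfg = small_config("homeostasis", seed=5, n_steps=60,
                           workers=p, out_dir=str(tmp_path / f"p{p}"))
        run_scenario(cfg)
        outs.append(tmp_path / f"p{p}")
    for name in ("timeseries.csv", "state_final.csv"):
        assert (outs[0] / name).read_bytes() == (outs[1] / name).read_bytes()


# ----------------------------------------------------------------------
# metrics


def _hand_built_sim(n_villus: int, n_crypt: int):
    sim = build_simulation(small_config("homeostasis"))
    sim._clear_sites(np.arange(sim.index.n_sites))
    vill = np.flatnonzero(sim.index.site_comp == int(Component.VILLUS))
    crypt = np.flatnonzero(sim.index.site_comp == int(Component.CRYPT))
    sim.lineage[vill[:n_villus]] = Lineage.ENTEROCYTE
    sim.lineage[crypt[:n_crypt]] = Lineage.STEM
    return sim


def test_metrics_ratio_arithmetic():
    m = compute_metrics(_hand_built_sim(40, 10))
    assert m.villus_crypt_ratio == 4.0


def test_metrics_empty_villus_gives_zero_ratio():
    m = compute_metrics(_hand_built_sim(0, 10))
    assert m.villus_crypt_ratio == 0.0


def test_metrics_zero_crypt_population_is_sentinel(caplog):
    with caplog.at_level("WARNING", logger="pouchsim"):
        m = compute_metrics(_hand_built_sim(40, 0))
    assert math.isnan(m.villus_crypt_ratio)
    assert "undefined" in caplog.text
    assert m.to_dict()["villus_crypt_ratio"] is None  # JSON-safe sentinel


def test_metrics_axial_bins_cover_the_axis():
    m = compute_metrics(_hand_built_sim(40, 10))
    geom_axial = 3  # small_config lattice
    assert m.axial_bin_edges[0] == 0.0
    assert m.axial_bin_edges[-1] == float(geom_axial)
    assert len(m.mean_villus_height) == len(m.metaplastic_unit_fraction)


# ----------------------------------------------------------------------
# meshes


def test_empty_tissue_writes_valid_header_only_mesh(tmp_path):
    sim = build_simulation(small_config("homeostasis"))
    sim._clear_sites(np.arange(sim.index.n_sites))
    p = export_mesh(sim.index, sim.lineage, tmp_path / "empty.ply")
    coords, colors = read_mesh(p)
    assert coords.shape == (0, 3)
    assert p.read_text().startswith("ply\nformat ascii 1.0\n")


def test_mesh_vertex_count_and_roundtrip(tmp_path):
    sim = build_simulation(small_config("homeostasis"))
    sim.run(5)
    p = export_mesh(sim.index, sim.lineage, tmp_path / "t.ply")
    coords, colors = read_mesh(p)
    assert coords.shape[0] == int(sim.occupied.sum())
    from pouchsim.geometry import positions_3d

    expect = positions_3d(sim.index)[sim.occupied]
    assert np.max(np.abs(coords - expect)) <= 1e-5
    assert set(map(tuple, np.unique(colors, axis=0))).issubset(
        {(46, 134, 193), (244, 208, 63), (88, 214, 141), (231, 76, 60)}
    )


def test_mesh_readable_by_independent_parser(tmp_path):
    trimesh = pytest.importorskip("trimesh")
    sim = build_simulation(small_config("homeostasis"))
    sim.run(3)
    p = export_mesh(sim.index, sim.lineage, tmp_path / "t.ply")
    cloud = trimesh.load(str(p))
    assert cloud.vertices.shape[0] == int(sim.occupied.sum())
    own, _ = read_mesh(p)
    assert np.max(np.abs(np.asarray(cloud.vertices) - own)) <= 1e-5


def test_mesh_subregion_selection(tmp_path):
    sim = build_simulation(small_config("homeostasis"))
    sim.run(3)
    p = export_mesh(sim.index, sim.lineage, tmp_path / "s.ply", units=[0, 1])
    coords, _ = read_mesh(p)
    sel = sim.occupied & np.isin(sim.index.site_unit, [0, 1])
    assert coords.shape[0] == int(sel.sum())


# ----------------------------------------------------------------------
# dumps


def test_state_dump_roundtrip(tmp_path):
    cfg = small_config("homeostasis", n_steps=30, out_dir=str(tmp_path))
    paths = run_scenario(cfg)
    sim = paths["simulation"]
    df, index = load_dump(tmp_path / "state_final.csv")
    assert index.n_sites == sim.index.n_sites
    assert np.array_equal(df["lineage"].to_numpy(), sim.lineage)
    assert np.allclose(df["WNT"].to_numpy(), sim.conc[0])


# ----------------------------------------------------------------------
# pouchitis gradient report


def test_zero_inflammation_gives_flat_profile_and_no_gradient_flag():
    sim = build_simulation(small_config("homeostasis"))
    sim.run(100)
    df, flags = pouchitis_gradient_report(sim)
    assert df["mean_villus_height"].nunique() == 1
    assert flags["monotone_decreasing_toward_terminal"] is False


def _mini_pouchitis(terminal_first: bool, n_axial=6):
    cfg = small_config("pouchitis", seed=4)
    cfg.geometry.sim_n_axial = n_axial
    cfg.geometry.sim_n_circ = 2
    cfg.stool.terminal_first = terminal_first
    cfg.stool.delta_ip = 0.08
    cfg.rules.metaplasia_exposure_threshold = 30.0
    cfg.rules.metaplasia_height_per_exposure = 4.0
    cfg.rules.villus_min_height = 3
    sim = build_simulation(cfg)
    sim.run(700)
    return sim


def test_pouchitis_gradient_direction_follows_fill_order():
    sim_t = _mini_pouchitis(terminal_first=True)
    df_t, flags_t = pouchitis_gradient_report(sim_t)
    assert flags_t["monotone_decreasing_toward_terminal"] is True
    assert flags_t["spearman_rho"] < 0

    sim_p = _mini_pouchitis(terminal_first=False)
    _, flags_p = pouchitis_gradient_report(sim_p)
    assert flags_p["spearman_rho"] > 0  # gradient reverses
    assert flags_p["monotone_decreasing_toward_terminal"] is False


def test_wnt_knockout_extinguishes_proliferative_drive():
    from pouchsim.signaling import MediatorId, proliferation_drive

    cfg = small_config("knockout", seed=2, n_steps=1)
    cfg.perturbation.knockout_step = 300
    sim = build_simulation(cfg)
    crypt = sim.index.site_comp == int(Component.CRYPT)
    drive = []
    for t in range(1, 501):
        sim.step()
        if t >= 290:
            drive.append(
                float(proliferation_drive(sim.conc, sim.signaling)[crypt].mean())
            )
    pre = drive[:10]
    post = drive[10:]
    # crypt proliferation drive falls monotonically to the no-Wnt baseline
    assert all(b <= a + 1e-12 for a, b in zip(post, post[1:]))
    assert post[-1] < 0.01 * pre[-1]
    assert sim.signaling.knockouts == ("WNT",)
    assert sim.series["births"].tail(50).sum() == 0  # below theta_wnt


def test_cli_run_metrics_and_mesh(tmp_path):
    from click.testing import CliRunner

    from pouchsim.scenarios_io import cli

    cfg = small_config("homeostasis", n_steps=20, out_dir=str(tmp_path / "run"))
    cfg_path = tmp_path / "cfg.yaml"
    cfg.to_yaml(cfg_path)
    runner = CliRunner()
    res = runner.invoke(
        cli,
        ["run", "--config", str(cfg_path), "--seed", "2", "--workers", "2",
         "--check-equivalence"],
    )
    assert res.exit_code == 0, res.output
    assert "equivalence verified" in res.output
    dump = tmp_path / "run" / "state_final.csv"
    res = runner.invoke(cli, ["metrics", str(dump)])
    assert res.exit_code == 0
    assert "villus_crypt_ratio" in res.output
    res = runner.invoke(
        cli, ["mesh", str(dump), "--out", str(tmp_path / "m.ply")]
    )
    assert res.exit_code == 0
    coords, _ = read_mesh(tmp_path / "m.ply")
    assert coords.shape[0] > 0


def test_terminal_quartile_fraction_bounds():
    sim = _mini_pouchitis(terminal_first=True)
    f = terminal_metaplastic_fraction(sim)
    assert 0.0 <= f <= 1.0
    assert f > 0.0
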