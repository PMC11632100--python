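"""Experiment layer: mask fixtures, the 4f oracle, presets, robustness,
solution persistence, and the CLI."""

import json
import os

import numpy as np
import pytest

from diffoptix.field import make_grid
from diffoptix.experiments import (MaskSpec, make_mask, ideal_4f_target,
                                   make_4f_dataset, FourFSystem,
                                   run_4f_reference, PRESET_NAMES, get_preset,
                                   run_preset, noise_levels, run_robustness,
                                   save_solution, load_solution)
from diffoptix.ansatz import build_ansatz

G64 = make_grid(64, 64, 8.0)


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def test_triangle_mask_area_and_centroid():
    g = make_grid(256, 256, 4.0)
    m = make_mask(MaskSpec("triangle", 0.4), g)
    ex, ey = g.extent
    base, height = 0.4 * ex, 0.4 * ey
    area = m.sum() * g.pitch ** 2
    assert abs(area - 0.5 * base * height) / (0.5 * base * height) < 0.03
    tot = m.sum()
    assert abs((m * g.xx).sum() / tot) < 2 * g.pitch
    assert abs((m * g.yy).sum() / tot) < 2 * g.pitch


def test_delta_mask_single_center_pixel():
    m = make_mask(MaskSpec("delta"), G64)
    assert m.sum() == 1.0
    iy, ix = np.unravel_index(np.argmax(m), m.shape)
    assert abs(G64.x[ix]) <= G64.pitch / 2 and abs(G64.y[iy]) <= G64.pitch / 2


def test_seeded_masks_deterministic_and_distinct():
    for kind in ("blob_logo", "random_shapes"):
        a = make_mask(MaskSpec(kind, 0.3, seed=7), G64)
        b = make_mask(MaskSpec(kind, 0.3, seed=7), G64)
        c = make_mask(MaskSpec(kind, 0.3, seed=8), G64)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)
        assert set(np.unique(a)) <= {0.0, 1.0}
        assert a.sum() > 0


def test_mask_spec_validation():
    with pytest.raises(ValueError):
        MaskSpec("square")
    with pytest.raises(ValueError):
        MaskSpec("triangle", fraction=1.5)


# ---------------------------------------------------------------------------
# ideal 4f map and the physical oracle
# ---------------------------------------------------------------------------

def test_ideal_4f_target_minus_one_is_identity():
    m = make_mask(MaskSpec("random_shapes", 0.3, seed=3), G64)
    out = ideal_4f_target(m, -1.0, G64)
    assert np.allclose(out, m, atol=1e-12)


def test_ideal_4f_target_delta_maps_to_reflected_pixel():
    r = np.zeros((65, 65))
    r[32 + 10, 32 + 4] = 1.0
    g = make_grid(65, 65, 8.0)
    out = ideal_4f_target(r, -2.0, g)
    iy, ix = np.unravel_index(np.argmax(out), out.shape)
    # M = −2: the output at +2x comes from the input at +x (no extra flip)
    assert (iy, ix) == (32 + 20, 32 + 8)
    # the delta magnifies onto ~M² pixels at 1/M² each: total is conserved
    assert np.isclose(out.sum(), 1.0)
    with pytest.raises(ValueError):
        ideal_4f_target(r, 0.0, g)


def test_run_4f_reference_unit_relay_inverts():
    g = make_grid(128, 128, 8.0)
    lam = 650.0
    f = 1.25 * g.pitch * (128 * g.pitch) / (lam * 1e-3)
    mask = make_mask(MaskSpec("triangle", 0.3), g)
    image, mag = run_4f_reference(f, f, mask, g, lam, estimator="moment")
    assert mag < 0  # inverted image
    assert abs(abs(mag) - 1.0) < 0.05
    assert image.shape == g.shape
    with pytest.raises(ValueError):
        run_4f_reference(-1.0, f, mask, g)
    with pytest.raises(ValueError):
        run_4f_reference(f, f, mask, g, estimator="bogus")


def test_make_4f_dataset_shapes_and_targets():
    pairs = make_4f_dataset(3, 2.0, G64, seed=1)
    assert len(pairs) == 3
    for inp, tgt in pairs:
        assert inp.shape == G64.shape and tgt.shape == G64.shape
        assert np.allclose(tgt, ideal_4f_target(inp, 2.0, G64))
    with pytest.raises(ValueError):
        make_4f_dataset(0, 2.0, G64)


def test_fourf_system_parameter_count_and_ideal_params():
    g = make_grid(32, 32, 8.0)
    sysf = FourFSystem(g)
    assert sysf.n_parameters() == 2 * 32 * 32 + 3
    f = 1.25 * g.pitch * (32 * g.pitch) / (650.0 * 1e-3)
    p = sysf.ideal_params(f, 2 * f)
    assert set(p) == {"slm1", "slm2", "d1", "d2", "d3"}
    assert np.isclose(np.logaddexp(0, p["d1"]), f)
    assert np.isclose(np.logaddexp(0, p["d2"]), 3 * f)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def test_preset_registry_and_validation():
    assert set(PRESET_NAMES) == {"magnifier_4f", "sted_topology",
                                 "sharp_focus_topology", "sted_parameterized",
                                 "sharp_focus_parameterized", "blueprint"}
    with pytest.raises(ValueError):
        get_preset("nope")
    with pytest.raises(ValueError):
        get_preset("sted_topology", resolution=8)


def test_preset_components_and_wavelengths():
    p = get_preset("sharp_focus_topology")
    assert p.component == "longitudinal" and len(p.wavelengths) == 1
    p = get_preset("sted_topology")
    assert p.component == "transverse" and len(p.wavelengths) == 2
    p = get_preset("blueprint")
    assert p.component == "total"


def test_topology_preset_parameter_count():
    # 9 splitter ratios + 8 distances + 4 wave plates (η, θ) on the central
    # cross = 25 continuous parameters with all phase masks fixed
    anz = build_ansatz(get_preset("sted_topology", resolution=32).ansatz_spec())
    assert anz.count_parameters() == 25


def test_run_preset_zero_steps_emits_artifacts(tmp_path):
    p = get_preset("sted_topology", resolution=32, steps=0)
    out = tmp_path / "run"
    res, report = run_preset(p, out_dir=str(out))
    assert report["parameters"] == 25
    assert report["best_detector"] in {"T0", "T1", "T2"}
    for key in ("excitation", "depletion", "effective"):
        assert {"fwhm_x", "fwhm_y", "phi"} <= set(report[key])
    for fname in ("topology.json", "report.json", "loss.csv",
                  "solution.h5", "manifest.json", "effective.png",
                  "effective_cross.csv"):
        assert (out / fname).exists(), fname
    saved = json.loads((out / "report.json").read_text())
    assert saved["preset"] == "sted_topology"


def test_magnifier_preset_trains(tmp_path):
    p = get_preset("magnifier_4f", resolution=32, steps=8)
    p.n_pairs, p.batch = 6, 3
    res, report = run_preset(p, out_dir=str(tmp_path))
    assert report["val_mse_final"] < report["val_mse_init"]
    assert set(report["distances_um"]) == {"d1", "d2", "d3"}
    assert (tmp_path / "holdout_image.png").exists()
    assert (tmp_path / "loss.csv").exists()


# ---------------------------------------------------------------------------
# robustness and persistence
# ---------------------------------------------------------------------------

def test_noise_levels_registry():
    lv = noise_levels()
    assert set(lv) == {"none", "standard", "stress", "stress8bit"}
    nm, bits = lv["stress8bit"]
    assert bits == 8
    assert lv["stress"][0].phase_noise > lv["standard"][0].phase_noise


def test_run_robustness_structure():
    p = get_preset("sted_topology", resolution=32)
    anz = build_ansatz(p.ansatz_spec())
    params = anz.init_params(seed=0)
    lv = noise_levels()
    table = run_robustness(anz, params,
                           {"none": lv["none"], "standard": lv["standard"]},
                           seed=2, n_trials=1)
    assert table["none"]["nmse"] == 0.0
    assert table["standard"]["nmse"] > 0.0
    assert table["standard"]["n"] == 1


def test_save_load_solution_roundtrip(tmp_path):
    p = get_preset("sted_topology", resolution=32, steps=0, seed=4)
    anz = build_ansatz(p.ansatz_spec())
    params = anz.init_params(seed=4).arrays
    save_solution(str(tmp_path), p, params)
    preset2, params2 = load_solution(str(tmp_path))
    assert preset2.name == "sted_topology"
    assert preset2.resolution == 32 and preset2.seed == 4
    assert set(params2) == set(params)
    for k in params:
        assert np.allclose(params2[k], params[k])


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def test_cli_simulate_and_bench(tmp_path):
    from click.testing import CliRunner
    from diffoptix.cli import main
    cfg = tmp_path / "sim.yaml"
    g_width = 64 * 8.0
    cfg.write_text(
        "resolution: 64\npitch: 8.0\nwavelength: 650.0\n"
        "elements:\n  - kind: spiral\n    charge: 1\n"
        f"z: {1.5 * 8.0 * g_width / 0.65:.1f}\n")
    out = tmp_path / "sim_out"
    runner = CliRunner()
    r = runner.invoke(main, ["simulate", "--config", str(cfg), "--out", str(out)])
    assert r.exit_code == 0, r.output
    for fname in ("field.h5", "intensity.png", "cross_sections.csv",
                  "manifest.json"):
        assert (out / fname).exists()
    r = runner.invoke(main, ["bench", "--sizes", "32", "--repeats", "1"])
    assert r.exit_code == 0, r.output
    assert "32,rs," in r.output and "32,czt," in r.output


def test_cli_discover_then_robustness(tmp_path):
    from click.testing import CliRunner
    from diffoptix.cli import main
    out = tmp_path / "run"
    runner = CliRunner()
    r = runner.invoke(main, ["discover", "--preset", "sted_topology",
                             "--resolution", "32", "--steps", "0",
                             "--out", str(out)])
    assert r.exit_code == 0, r.output
    r = runner.invoke(main, ["robustness", "--run", str(out),
                             "--levels", "standard", "--trials", "1"])
    assert r.exit_code == 0, r.output
    table = json.loads((out / "robustness.json").read_text())
    assert set(table) == {"none", "standard"}
    assert table["standard"]["nmse"] > 0.0
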