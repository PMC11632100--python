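"""Optical elements: SLMs, wave plates, beam splitters, noise model."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from diffoptix import autodiff as ad
from diffoptix.field import make_grid, VectorField, gaussian_source, wrap_phase
from diffoptix.elements import (PhaseMask, WavePlateParams, BeamSplitterParams,
                                NoiseModel, NO_NOISE, apply_slm, super_slm,
                                wave_plate, beam_splitter, spiral_mask,
                                lens_mask, radial_converter, quantize_phase,
                                _fourier_shift)

G = make_grid(32, 32, 4.0)
LAM = 650.0


def _field(pol=(1.0, 0.0)):
    return gaussian_source(G, LAM, polarization=pol)


def test_apply_slm_imprints_phase():
    f = _field()
    phase = wrap_phase(G.xx / 20.0)
    out = apply_slm(f, phase)
    ratio = out.ex.detach() / f.ex.detach()
    assert np.allclose(ratio, np.exp(1j * phase))
    assert np.allclose(out.ey.detach(), 0.0)


def test_apply_slm_component_selectivity():
    f = gaussian_source(G, LAM, polarization=(0.6, 0.8))
    phase = np.full(G.shape, 0.7)
    h = apply_slm(f, phase, "H")
    assert np.allclose(h.ey.detach(), f.ey.detach())
    assert not np.allclose(h.ex.detach(), f.ex.detach())
    v = apply_slm(f, phase, "V")
    assert np.allclose(v.ex.detach(), f.ex.detach())


def test_super_slm_independent_panels():
    f = gaussian_source(G, LAM, polarization=(0.6, 0.8))
    ph, pv = np.full(G.shape, 0.5), np.full(G.shape, -1.0)
    out = super_slm(f, ph, pv)
    assert np.allclose(out.ex.detach(), f.ex.detach() * np.exp(0.5j))
    assert np.allclose(out.ey.detach(), f.ey.detach() * np.exp(-1.0j))


def test_slm_preserves_power():
    f = _field()
    out = apply_slm(f, spiral_mask(G, 2))
    assert np.isclose(out.power(), f.power(), rtol=1e-12)


def test_wave_plate_is_unitary():
    f = gaussian_source(G, LAM, polarization=(0.6, 0.8))
    out = wave_plate(f, (1.1, 0.4))
    assert np.isclose(out.power(), f.power(), rtol=1e-12)


def test_half_wave_plate_at_45_swaps_polarization():
    f = _field((1.0, 0.0))
    out = wave_plate(f, WavePlateParams(np.pi, np.pi / 4))
    ix = np.abs(out.ex.detach()) ** 2
    iy = np.abs(out.ey.detach()) ** 2
    assert ix.max() < 1e-20 * iy.max()


def test_zero_retardance_is_identity_up_to_phase():
    f = gaussian_source(G, LAM, polarization=(0.6, 0.8))
    out = wave_plate(f, (0.0, 1.234))
    assert np.allclose(out.ex.detach(), f.ex.detach())
    assert np.allclose(out.ey.detach(), f.ey.detach())


def test_beam_splitter_energy_conserving():
    a = _field((1.0, 0.0))
    b = gaussian_source(G, LAM, polarization=(0.0, 1.0))
    for t in (0.0, 0.3, 0.5, 1.0):
        oc, od = beam_splitter(a, b, (t, 1.0 - t))
        assert np.isclose(oc.power() + od.power(), a.power() + b.power(),
                          rtol=1e-12)


def test_beam_splitter_extremes_route_cleanly():
    a = _field()
    b = VectorField(G, np.zeros(G.shape), np.zeros(G.shape), None, LAM)
    oc, od = beam_splitter(a, b, (1.0, 0.0))
    assert np.isclose(oc.power(), a.power(), rtol=1e-12)
    assert od.power() < 1e-20
    oc, od = beam_splitter(a, b, (0.0, 1.0))
    assert oc.power() < 1e-20
    assert np.isclose(od.power(), a.power(), rtol=1e-12)


def test_beam_splitter_grid_mismatch_raises():
    a = _field()
    g2 = make_grid(16, 16, 4.0)
    b = VectorField(g2, np.zeros(g2.shape), np.zeros(g2.shape), None, LAM)
    with pytest.raises(ValueError):
        beam_splitter(a, b, (0.5, 0.5))


def test_spiral_mask_charge_winding():
    m = spiral_mask(G, 3)
    # phase winds 3·2π around the axis
    iy = G.ny // 2 + 4
    ring = m.values[iy, :]
    assert m.values.shape == G.shape
    assert np.isclose(m.values[G.ny // 2 + 5, G.nx // 2],
                      wrap_phase(3 * np.arctan2(G.y[G.ny // 2 + 5], G.x[G.nx // 2])))


def test_lens_mask_quadratic():
    f = 50000.0
    m = lens_mask(G, f, LAM)
    k = 2 * np.pi / (LAM * 1e-3)
    expected = wrap_phase(-k * (G.xx ** 2 + G.yy ** 2) / (2 * f))
    assert np.allclose(m.values, expected)
    assert np.allclose(lens_mask(G, np.inf, LAM).values, 0.0)


def test_radial_converter_geometry():
    f = _field()
    out = radial_converter(f)
    # polarization points radially: ey/ex = tan(azimuth) off the axes
    phi = np.arctan2(G.yy, G.xx)
    r = np.sqrt(G.xx ** 2 + G.yy ** 2)
    sel = (r > 3 * G.pitch) & (r < 8 * G.pitch) & (np.abs(np.cos(phi)) > 0.3)
    ex, ey = out.ex.detach(), out.ey.detach()
    assert np.allclose((ey / ex)[sel].real, np.tan(phi)[sel], atol=1e-9)
    assert np.isclose(out.power(), f.power(), rtol=0.05)  # on-axis pixel zeroed


def test_quantize_phase_levels():
    phase = np.linspace(-np.pi + 1e-6, np.pi, 1000)
    q = quantize_phase(phase, bits=3)
    assert len(np.unique(np.round(q, 12))) <= 8
    assert np.max(np.abs(wrap_phase(q - phase))) <= np.pi / 8 + 1e-9


def test_phase_mask_hdf5_roundtrip(tmp_path):
    m = spiral_mask(G, 1)
    p = tmp_path / "m.h5"
    m.to_hdf5(p)
    m2 = PhaseMask.from_hdf5(p)
    # π and −π are the same phase; the re-wrap on load may flip the boundary
    assert np.allclose(wrap_phase(m.values - m2.values), 0.0, atol=1e-12)
    assert m2.grid == G


def test_noise_draws_are_tag_and_seed_deterministic():
    nm = NoiseModel(0.05, 0.05, 0.01, seed=7)
    a = nm.rng(("slm", "u_B0")).uniform(size=4)
    b = NoiseModel(0.05, 0.05, 0.01, seed=7).rng(("slm", "u_B0")).uniform(size=4)
    c = nm.rng(("slm", "u_B1")).uniform(size=4)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)


def test_noisy_slm_bit_reproducible():
    f = _field()
    nm = NoiseModel(0.05, 0.05, 0.01, seed=3)
    o1 = apply_slm(f, spiral_mask(G, 1), noise=nm, tag="x")
    o2 = apply_slm(f, spiral_mask(G, 1), noise=nm, tag="x")
    assert np.array_equal(o1.ex.detach(), o2.ex.detach())


def test_no_noise_is_noise_free():
    f = _field()
    clean = apply_slm(f, np.zeros(G.shape))
    noisy = apply_slm(f, np.zeros(G.shape), noise=NO_NOISE, tag="y")
    assert np.array_equal(clean.ex.detach(), noisy.ex.detach())


def test_fourier_shift_translates_without_wrap():
    # a blob shifted by +5 px appears at +5 px; a shift larger than the
    # window pushes it out instead of wrapping around
    from diffoptix.autodiff import Tensor
    bump = np.exp(-(G.xx ** 2 + G.yy ** 2) / 100.0)   # phase bump transmission
    t = Tensor(np.exp(1j * bump))
    s = _fourier_shift(t, G, 5 * G.pitch, 0.0).detach()
    iy, ix = np.unravel_index(np.argmax(np.angle(s)), s.shape)
    iy0, ix0 = np.unravel_index(np.argmax(bump), bump.shape)
    assert ix - ix0 == 5 and iy == iy0
    far = _fourier_shift(t, G, 3 * 32 * G.pitch, 0.0).detach()
    assert np.max(np.abs(far - 1.0)) < 0.05  # element slid out of the window


def test_bs_imperfection_renormalizes():
    a = _field()
    b = VectorField(G, np.zeros(G.shape), np.zeros(G.shape), None, LAM)
    nm = NoiseModel(0.0, 0.0, 0.01, seed=1)
    oc, od = beam_splitter(a, b, (0.5, 0.5), noise=nm, tag="bs")
    assert np.isclose(oc.power() + od.power(), a.power(), rtol=1e-12)


def test_noise_model_validation():
    with pytest.raises(ValueError):
        NoiseModel(-0.1, 0.0, 0.0)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.floats(0.0, 2 * np.pi), st.floats(-np.pi, np.pi))
def test_wave_plate_unitary_for_any_setting(eta, theta):
    f = gaussian_source(G, LAM, polarization=(0.6, 0.8))
    out = wave_plate(f, (eta, theta))
    assert np.isclose(out.power(), f.power(), rtol=1e-10)
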