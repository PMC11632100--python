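"""Closed-form optics oracles: Gaussian spreading, CZT/RS congruence,
vectorial divergence, vortex null, Airy focusing, radial-polarization focus."""

import warnings

import numpy as np
import pytest

from diffoptix import autodiff as ad
from diffoptix.field import (make_grid, ScalarField, VectorField,
                             gaussian_source, plane_wave, spot_metrics)
from diffoptix.propagation import (OutputWindow, propagate_rs, propagate_czt,
                                   propagate_vrs, propagate_vczt,
                                   focus_high_na, SamplingWarning)
from diffoptix.elements import spiral_mask, apply_slm, radial_converter

LAM = 650.0
LAM_UM = LAM * 1e-3


def _beam_radius(inten, grid):
    """1/e² radius from the second moment of a Gaussian intensity."""
    tot = inten.sum()
    r2 = (inten * (grid.xx ** 2 + grid.yy ** 2)).sum() / tot
    return np.sqrt(2.0 * r2)


def test_gaussian_spreading_within_1pct():
    g = make_grid(128, 128, 4.0)
    w0 = 40.0
    src = gaussian_source(g, LAM, waist=w0)
    sf = ScalarField(g, src.ex.detach(), LAM)
    zr = np.pi * w0 ** 2 / LAM_UM
    for z in (zr, 1.5 * zr):
        out = propagate_rs(sf, z)
        w_meas = _beam_radius(out.intensity(), out.grid)
        w_theory = w0 * np.sqrt(1 + (z / zr) ** 2)
        assert np.isclose(w_meas, w_theory, rtol=0.01), (z, w_meas, w_theory)


def test_propagation_z0_is_identity():
    g = make_grid(32, 32, 4.0)
    sf = ScalarField(g, np.exp(1j * g.xx / 50.0), LAM)
    out = propagate_rs(sf, 0.0)
    assert np.allclose(out.data.detach(), sf.data.detach())


def test_back_propagation_inverts():
    g = make_grid(128, 128, 4.0)
    src = gaussian_source(g, LAM, waist=40.0)
    sf = ScalarField(g, src.ex.detach(), LAM)
    z = 4000.0
    back = propagate_rs(propagate_rs(sf, z), -z)
    err = np.max(np.abs(back.data.detach() - sf.data.detach()))
    assert err < 1e-3 * np.max(np.abs(sf.data.detach()))


def test_power_conserved_for_contained_beam():
    g = make_grid(128, 128, 4.0)
    src = gaussian_source(g, LAM, waist=30.0)
    sf = ScalarField(g, src.ex.detach(), LAM)
    out = propagate_rs(sf, 4000.0)
    assert out.power() <= sf.power() * (1 + 1e-6)
    assert out.power() > 0.99 * sf.power()


def test_sampling_warning_when_too_close():
    g = make_grid(64, 64, 8.0)
    sf = ScalarField(g, gaussian_source(g, LAM).ex.detach(), LAM)
    with pytest.warns(SamplingWarning):
        warnings.simplefilter("always")
        propagate_rs(sf, 100.0)  # far below pitch·width/λ


def test_czt_equals_rs_on_congruent_window():
    g = make_grid(64, 64, 8.0)
    src = gaussian_source(g, LAM, waist=60.0)
    sf = ScalarField(g, src.ex.detach() * np.exp(1j * g.xx / 100.0), LAM)
    z = 1.2 * g.pitch * (64 * g.pitch) / LAM_UM
    ref = propagate_rs(sf, z).data.detach()
    win = OutputWindow.from_grid(g)
    out = propagate_czt(sf, z, win).data.detach()
    scale = np.max(np.abs(ref))
    assert np.max(np.abs(out - ref)) < 1e-6 * scale


def test_vczt_equals_vrs_on_congruent_window():
    g = make_grid(64, 64, 8.0)
    src = gaussian_source(g, LAM, waist=60.0)
    z = 1.2 * g.pitch * (64 * g.pitch) / LAM_UM
    ref = propagate_vrs(src, z)
    out = propagate_vczt(src, z, OutputWindow.from_grid(g))
    for a, b in zip(ref.components(), out.components()):
        scale = max(np.max(np.abs(a.detach())), 1e-300)
        assert np.max(np.abs(a.detach() - b.detach())) < 1e-6 * scale


def test_czt_zoom_window_resolves_focus():
    # focusing lens phase: the zoomed window sees the focal spot at high
    # resolution and the spot sits at the window center
    g = make_grid(128, 128, 8.0)
    f = 1.3 * g.pitch * (128 * g.pitch) / LAM_UM
    from diffoptix.elements import lens_mask
    src = plane_wave(g, LAM)
    sf = ScalarField(g, src.ex.detach() * np.exp(1j * lens_mask(g, f, LAM).values), LAM)
    win = OutputWindow(65, 65, 40.0, 40.0)
    out = propagate_czt(sf, f, win)
    inten = out.intensity()
    iy, ix = np.unravel_index(np.argmax(inten), inten.shape)
    assert (iy, ix) == (32, 32)


def _divergence_residual(field):
    g = field.grid
    fx = np.fft.fftfreq(g.nx, g.pitch)[None, :]
    fy = np.fft.fftfreq(g.ny, g.pitch)[:, None]
    fz2 = (1.0 / (field.wavelength * 1e-3)) ** 2 - fx ** 2 - fy ** 2
    prop = fz2 > 0
    fz = np.sqrt(np.where(prop, fz2, 0.0))
    Ex = np.fft.fft2(field.ex.detach())
    Ey = np.fft.fft2(field.ey.detach())
    Ez = np.fft.fft2(field.ez.detach())
    div = np.abs(fx * Ex + fy * Ey + fz * Ez)[prop]
    norm = np.sqrt(np.abs(Ex) ** 2 + np.abs(Ey) ** 2 + np.abs(Ez) ** 2)[prop]
    scale = np.sqrt(fx ** 2 + fy ** 2 + fz ** 2)[prop]
    return float(div.sum() / (norm * scale).sum())


def test_vrs_output_divergence_free():
    # mixed polarization with different smooth phase structure per component;
    # a spiral mask is avoided here because its singularity aliases near
    # Nyquist where the sampled spatial kernel departs from the analytic one
    from diffoptix.elements import super_slm, lens_mask
    g = make_grid(128, 128, 4.0)
    src = gaussian_source(g, LAM, waist=40.0, polarization=(0.6, 0.8))
    f = 3.0 * g.pitch * (128 * g.pitch) / LAM_UM
    tilt = (g.xx + 0.5 * g.yy) * 2 * np.pi / (64 * g.pitch)
    src = super_slm(src, lens_mask(g, f, LAM).values, tilt)
    z = 1.2 * g.pitch * (128 * g.pitch) / LAM_UM
    out = propagate_vrs(src, z)
    assert _divergence_residual(out) < 1e-3


def test_vrs_plain_gaussian_divergence_machine_precision():
    g = make_grid(128, 128, 4.0)
    src = gaussian_source(g, LAM, waist=40.0, polarization=(0.6, 0.8))
    out = propagate_vrs(src, 1.2 * g.pitch * (128 * g.pitch) / LAM_UM)
    assert _divergence_residual(out) < 1e-10


def test_vrs_rejects_nonzero_ez_input():
    g = make_grid(32, 32, 4.0)
    f = VectorField(g, np.ones(g.shape), np.zeros(g.shape), np.ones(g.shape), LAM)
    with pytest.raises(ValueError):
        propagate_vrs(f, 1000.0)


def test_high_na_focus_airy_fwhm():
    # uniformly filled low-NA pupil → Airy spot, FWHM = 1.03 λ f / D within 3%
    g = make_grid(128, 128, 8.0)
    na = 0.05
    f = (64 * g.pitch) / na          # pupil fills the full aperture radius
    src = plane_wave(g, LAM)
    win = OutputWindow(129, 129, 16.0, 16.0)
    out = focus_high_na(src, na, f, win)
    sm = spot_metrics(out.intensity("total"), out.grid)
    d = 2 * 64 * g.pitch
    expected = 1.03 * LAM_UM * f / d
    assert np.isclose(sm.fwhm_x, expected, rtol=0.03)
    assert np.isclose(sm.fwhm_y, expected, rtol=0.03)


def test_high_na_x_polarized_focus_elongated_along_x():
    g = make_grid(128, 128, 8.0)
    na = 0.9
    f = (64 * g.pitch) / na
    src = gaussian_source(g, LAM, waist=300.0)
    win = OutputWindow(129, 129, 1.5, 1.5)
    out = focus_high_na(src, na, f, win)
    sm = spot_metrics(out.intensity("total"), out.grid)
    assert sm.fwhm_x > sm.fwhm_y  # Richards–Wolf anisotropy for linear x-pol


def test_vortex_on_axis_null():
    g = make_grid(128, 128, 8.0)
    na = 0.9
    f = (64 * g.pitch) / na
    src = gaussian_source(g, LAM, waist=250.0)
    src = apply_slm(src, spiral_mask(g, 1))
    win = OutputWindow(129, 129, 2.0, 2.0)   # odd window: pixel exactly on axis
    out = focus_high_na(src, na, f, win)
    inten = out.intensity("transverse")
    on_axis = inten[64, 64]
    assert on_axis < 1e-4 * inten.max()


def test_radial_polarization_focus_ez_dominant_on_axis():
    g = make_grid(128, 128, 8.0)
    na = 0.9
    f = (64 * g.pitch) / na
    src = gaussian_source(g, LAM, waist=350.0)
    src = radial_converter(src)
    win = OutputWindow(129, 129, 2.0, 2.0)
    out = focus_high_na(src, na, f, win)
    iz = out.intensity("longitudinal")
    it = out.intensity("transverse")
    iy, ix = np.unravel_index(np.argmax(iz), iz.shape)
    assert (iy, ix) == (64, 64)              # |Ez|² maximized on axis
    assert it[64, 64] < 1e-6 * it.max()       # transverse null on axis
    assert iz[64, 64] > it.max()              # longitudinally dominated spot


def test_focus_high_na_validates_inputs():
    g = make_grid(32, 32, 8.0)
    src = gaussian_source(g, LAM)
    win = OutputWindow(17, 17, 2.0, 2.0)
    with pytest.raises(ValueError):
        focus_high_na(src, 1.5, 1000.0, win)
    bad = VectorField(g, np.ones(g.shape), np.zeros(g.shape), np.ones(g.shape), LAM)
    with pytest.raises(ValueError):
        focus_high_na(bad, 0.9, 1000.0, win)


def test_propagation_is_differentiable_in_z():
    g = make_grid(64, 64, 8.0)
    src = gaussian_source(g, LAM, waist=60.0)
    sf = ScalarField(g, src.ex.detach(), LAM)
    z0 = 1.3 * g.pitch * (64 * g.pitch) / LAM_UM

    def loss(zv):
        z = ad.Tensor(np.asarray(zv), requires_grad=True)
        out = propagate_rs(sf, z)
        l = ad.tsum(ad.abs2(out.data) * (g.xx ** 2 + g.yy ** 2))
        return z, l

    z, l = loss(z0)
    ad.backward(l)
    h = z0 * 1e-5
    fd = (float(loss(z0 + h)[1].value) - float(loss(z0 - h)[1].value)) / (2 * h)
    assert np.isclose(float(z.grad), fd, rtol=1e-4)
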