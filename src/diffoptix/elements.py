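"""Parametric optical elements with realistic imperfection models.

Implements the building blocks of the virtual optical table: phase-only
spatial light modulators (SLM), the polarization-resolved super-SLM (two
stacked panels addressing H and V independently), variable wave plates
(Jones retarder), tunable lossless beam splitters, canonical phase masks
(spiral vortex, quadratic lens), and the azimuthal polarization converter
used for sharp-focus experiments.

Imperfections follow a uniform-noise model: per-pixel phase noise on SLMs and
wave plates, transverse misalignment applied as a band-limited (Fourier)
translation of the element's transmission, and a relative perturbation of
beam-splitter transmittance/reflectance.  All draws are reproducible from the
noise model's seed plus a per-element tag.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, as_tensor
from .field import Grid, VectorField, wrap_phase

__all__ = [
    "PhaseMask", "WavePlateParams", "BeamSplitterParams", "NoiseModel",
    "apply_slm", "super_slm", "wave_plate", "beam_splitter",
    "spiral_mask", "lens_mask", "radial_converter", "quantize_phase",
]


@dataclasses.dataclass
class PhaseMask:
    """A static phase raster in radians, wrapped to (−π, π]."""

    values: np.ndarray
    grid: Grid

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != self.grid.shape:
            raise ValueError(f"mask shape {v.shape} != grid shape {self.grid.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("mask values must be finite")
        self.values = wrap_phase(v)

    def to_hdf5(self, path):
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("phase", data=self.values)
            f.attrs["nx"], f.attrs["ny"], f.attrs["pitch"] = \
                self.grid.nx, self.grid.ny, self.grid.pitch

    @classmethod
    def from_hdf5(cls, path):
        import h5py
        with h5py.File(path, "r") as f:
            grid = Grid(int(f.attrs["nx"]), int(f.attrs["ny"]), float(f.attrs["pitch"]))
            return cls(f["phase"][...], grid)

    def to_png(self, path):
        """8-bit preview: (−π, π] mapped linearly to 0–255."""
        from PIL import Image
        img = np.round((self.values + np.pi) / (2 * np.pi) * 255.0).astype(np.uint8)
        Image.fromarray(img, mode="L").save(path)


@dataclasses.dataclass(frozen=True)
class WavePlateParams:
    """Retardance η and fast-axis orientation θ, both in radians."""

    eta: float = 0.0
    theta: float = 0.0


@dataclasses.dataclass(frozen=True)
class BeamSplitterParams:
    """Transmittance/reflectance pair; lossless mode enforces T + R = 1."""

    t: float = 0.5
    r: float = 0.5
    lossless: bool = True

    def __post_init__(self):
        if not (0 <= self.t <= 1 and 0 <= self.r <= 1):
            raise ValueError("T and R must lie in [0, 1]")
        if self.t + self.r > 1 + 1e-12:
            raise ValueError("T + R must not exceed 1")
        if self.lossless and abs(self.t + self.r - 1.0) > 1e-9:
            raise ValueError("lossless beam splitter requires T + R = 1")


@dataclasses.dataclass(frozen=True)
class NoiseModel:
    """Uniform imperfection envelope.

    phase_noise : half-range of per-pixel SLM / wave-plate phase noise (rad);
    misalign    : half-range of transverse element misalignment (mm);
    bs_imperfection : relative beam-splitter T/R perturbation (fraction);
    seed        : base seed; the same seed and element tag reproduce the draw.

    Defaults are the midpoints of the "standard experimental conditions"
    envelope: ±0.05 rad, ±0.05 mm, 1% splitter imperfection.
    """

    phase_noise: float = 0.05
    misalign: float = 0.05
    bs_imperfection: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if min(self.phase_noise, self.misalign, self.bs_imperfection) < 0:
            raise ValueError("noise half-ranges must be non-negative")

    def rng(self, tag=0) -> np.random.Generator:
        import zlib
        # crc32 of the tag repr: stable across processes (unlike hash())
        salt = zlib.crc32(repr(tag).encode()) & 0x7FFFFFFF
        return np.random.default_rng([int(self.seed) & 0x7FFFFFFF, salt])

    @classmethod
    def none(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0)


NO_NOISE = NoiseModel.none()


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _fourier_shift(t: Tensor, grid: Grid, dx_um: float, dy_um: float) -> Tensor:
    """Band-limited translation of a transmission raster by (dx, dy) µm.

    The raster is zero-padded (around a unit baseline, i.e. transmission 1
    outside the device aperture) by at least the displacement before the
    FFT-domain shift, so large misalignments slide the element out of the
    window instead of wrapping around it periodically.
    """
    if dx_um == 0.0 and dy_um == 0.0:
        return t
    m = int(np.ceil(max(abs(dx_um), abs(dy_um)) / grid.pitch)) + 2
    ny, nx = grid.ny + 2 * m, grid.nx + 2 * m
    tp = ad.pad2(t - 1.0, ny, nx) + 1.0
    fx = np.fft.fftfreq(nx, grid.pitch)[None, :]
    fy = np.fft.fftfreq(ny, grid.pitch)[:, None]
    ramp = np.exp(-2j * np.pi * (fx * (dx_um + m * grid.pitch)
                                 + fy * (dy_um + m * grid.pitch)))
    ts = ad.ifft2(ad.fft2(tp) * ramp)
    return ad.crop2(ts, grid.ny, grid.nx, m, m)


def _mask_values(mask) -> "Tensor | np.ndarray":
    if isinstance(mask, PhaseMask):
        return mask.values
    return mask  # Tensor or ndarray of phases (optimizable rasters)


def quantize_phase(phase: np.ndarray, bits: int = 8) -> np.ndarray:
    """Quantize wrapped phases to 2**bits uniform levels over (−π, π]."""
    levels = 2 ** bits
    step = 2 * np.pi / levels
    return wrap_phase(np.round((np.asarray(phase) + np.pi) / step) * step - np.pi)


def _transmission(mask, grid: Grid, noise: NoiseModel, tag) -> Tensor:
    """exp(i·(mask + u)) with per-pixel uniform noise, Fourier-shifted by the
    sampled misalignment."""
    vals = _mask_values(mask)
    shape = vals.shape if hasattr(vals, "shape") else np.shape(vals)
    if tuple(shape) != grid.shape:
        raise ValueError("mask grid does not match field grid")
    rng = noise.rng(tag)
    phase = as_tensor(vals)
    if noise.phase_noise > 0:
        u = rng.uniform(-noise.phase_noise, noise.phase_noise, size=grid.shape)
        phase = phase + u
    t = ad.exp(phase * 1j)
    if noise.misalign > 0:
        dx, dy = rng.uniform(-noise.misalign, noise.misalign, size=2) * 1000.0  # mm → µm
        t = _fourier_shift(t, grid, dx, dy)
    return t


# ---------------------------------------------------------------------------
# elements
# ---------------------------------------------------------------------------

def apply_slm(field: VectorField, mask, component: str = "both",
              noise: NoiseModel = NO_NOISE, tag=0) -> VectorField:
    """Imprint a phase raster on the selected polarization component(s).

    ``mask`` may be a :class:`PhaseMask`, a numpy phase raster, or an autodiff
    Tensor of phases (the optimizable case).
    """
    t = _transmission(mask, field.grid, noise, tag)
    if component in ("H", "h", "x"):
        return field.replace(ex=field.ex * t)
    if component in ("V", "v", "y"):
        return field.replace(ey=field.ey * t)
    if component == "both":
        return field.replace(ex=field.ex * t, ey=field.ey * t)
    raise ValueError(f"unknown component {component!r}")


def super_slm(field: VectorField, mask_h, mask_v,
              noise: NoiseModel = NO_NOISE, tag=0) -> VectorField:
    """Two stacked SLM panels addressing H and V independently."""
    out = apply_slm(field, mask_h, "H", noise, (tag, "H"))
    return apply_slm(out, mask_v, "V", noise, (tag, "V"))


def wave_plate(field: VectorField, wp, noise: NoiseModel = NO_NOISE,
               tag=0) -> VectorField:
    """General retarder J = R(θ)·diag(e^{−iη/2}, e^{+iη/2})·R(−θ).

    ``wp`` is a :class:`WavePlateParams` or an ``(eta, theta)`` pair whose
    entries may be scalar Tensors (optimizable).  Phase noise perturbs η only.
    """
    if isinstance(wp, WavePlateParams):
        eta, theta = wp.eta, wp.theta
    else:
        eta, theta = wp
    eta = as_tensor(eta)
    theta = as_tensor(theta)
    if noise.phase_noise > 0:
        eta = eta + noise.rng(tag).uniform(-noise.phase_noise, noise.phase_noise)
    c, s = ad.cos(theta), ad.sin(theta)
    em = ad.exp(eta * (-0.5j))
    ep = ad.exp(eta * (0.5j))
    a = c * c * em + s * s * ep
    b = c * s * (em - ep)
    d = s * s * em + c * c * ep
    ex = field.ex * a + field.ey * b
    ey = field.ex * b + field.ey * d
    return field.replace(ex=ex, ey=ey)


def beam_splitter(in_a: VectorField, in_b: VectorField, bs,
                  noise: NoiseModel = NO_NOISE, tag=0):
    """Lossless 2×2 splitter: out_c = √T·a + i√R·b, out_d = i√R·a + √T·b.

    ``bs`` is a :class:`BeamSplitterParams` or (t, r) whose entries may be
    Tensors.  The effective (T, R) is perturbed multiplicatively by up to
    ``bs_imperfection`` and renormalized to T + R = 1.
    """
    if in_a.grid != in_b.grid:
        raise ValueError("beam splitter inputs must share a grid")
    if isinstance(bs, BeamSplitterParams):
        t, r = bs.t, bs.r
    else:
        t, r = bs
    t, r = as_tensor(t), as_tensor(r)
    if noise.bs_imperfection > 0:
        d1, d2 = noise.rng(tag).uniform(-noise.bs_imperfection, noise.bs_imperfection, 2)
        t = t * (1.0 + d1)
        r = r * (1.0 + d2)
        tot = t + r
        t, r = t / tot, r / tot
    st = ad.sqrt(ad.clip_min(t, 0.0))
    sr = ad.sqrt(ad.clip_min(r, 0.0))
    irt = sr * 1j
    out_c = VectorField(in_a.grid,
                        in_a.ex * st + in_b.ex * irt,
                        in_a.ey * st + in_b.ey * irt,
                        None, in_a.wavelength)
    out_d = VectorField(in_a.grid,
                        in_a.ex * irt + in_b.ex * st,
                        in_a.ey * irt + in_b.ey * st,
                        None, in_a.wavelength)
    return out_c, out_d


# ---------------------------------------------------------------------------
# canonical masks and the polarization converter
# ---------------------------------------------------------------------------

def spiral_mask(grid: Grid, charge: int = 1) -> PhaseMask:
    """Vortex phase ℓ·atan2(y, x): the doughnut-generating depletion mask."""
    return PhaseMask(wrap_phase(charge * np.arctan2(grid.yy, grid.xx)), grid)


def lens_mask(grid: Grid, focal: float, wavelength: float) -> PhaseMask:
    """Quadratic (thin-lens) phase −k(x²+y²)/(2f); wavelength in nm, f in µm."""
    if focal == np.inf:
        return PhaseMask(np.zeros(grid.shape), grid)
    k = 2 * np.pi / (wavelength * 1e-3)
    return PhaseMask(wrap_phase(-k * (grid.xx ** 2 + grid.yy ** 2) / (2.0 * focal)), grid)


def radial_converter(field: VectorField, polarization=(1.0, 0.0)) -> VectorField:
    """Rotate a linearly polarized field into local radial polarization.

    Models the segmented azimuthal half-wave-plate converter: the complex
    amplitude along the input polarization is redirected radially at each
    pixel, preserving the pixel-wise amplitude.  The on-axis pixel (undefined
    azimuth) is zeroed.
    """
    g = field.grid
    phi_az = np.arctan2(g.yy, g.xx)
    r = np.sqrt(g.xx ** 2 + g.yy ** 2)
    valid = (r > g.pitch / 2.0).astype(np.float64)
    px, py = complex(polarization[0]), complex(polarization[1])
    amp = field.ex * np.conj(px) + field.ey * np.conj(py)
    return field.replace(ex=amp * (np.cos(phi_az) * valid),
                         ey=amp * (np.sin(phi_az) * valid),
                         ez=None)
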