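"""Wavefields, sampling grids, sources, and focal-spot metrics.

Physical conventions used throughout the package:

* transverse coordinates are centered, x rightward / y upward, in micrometres;
* phases are radians wrapped to (−π, π];
* wavelengths are given in nanometres at the interface and converted to
  micrometres internally (``k = 2π/λ``);
* a freshly created source is transverse (``ez ≡ 0``) and normalized to unit
  total power.
"""

from __future__ import annotations

import dataclasses
import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, as_tensor

__all__ = [
    "Grid", "ScalarField", "VectorField", "SpotMetrics",
    "make_grid", "gaussian_source", "plane_wave", "spot_metrics",
    "wrap_phase", "save_field", "load_field", "export_png", "export_cross_sections",
    "UnresolvedSpotError",
]


def wrap_phase(phi):
    """Wrap phases to (−π, π]."""
    phi = np.asarray(phi, dtype=np.float64)
    out = np.angle(np.exp(1j * phi))
    # np.angle returns [−π, π); map −π to +π for the (−π, π] convention
    out = np.where(out == -np.pi, np.pi, out)
    return out


class UnresolvedSpotError(ValueError):
    """Raised when an intensity profile has no central lobe above half max."""


@dataclasses.dataclass(frozen=True)
class Grid:
    """Uniform sampling lattice: pixel counts and physical pitch (µm)."""

    nx: int
    ny: int
    pitch: float

    def __post_init__(self):
        if self.nx < 8 or self.ny < 8:
            raise ValueError(f"grid must be at least 8x8, got {self.nx}x{self.ny}")
        if not self.pitch > 0:
            raise ValueError(f"pitch must be positive, got {self.pitch}")

    @property
    def x(self) -> np.ndarray:
        return (np.arange(self.nx) - (self.nx - 1) / 2.0) * self.pitch

    @property
    def y(self) -> np.ndarray:
        return (np.arange(self.ny) - (self.ny - 1) / 2.0) * self.pitch

    @property
    def xx(self) -> np.ndarray:
        return np.broadcast_to(self.x[None, :], (self.ny, self.nx))

    @property
    def yy(self) -> np.ndarray:
        return np.broadcast_to(self.y[:, None], (self.ny, self.nx))

    @property
    def shape(self):
        return (self.ny, self.nx)

    @property
    def extent(self):
        """Physical half-widths (µm)."""
        return (self.nx * self.pitch / 2.0, self.ny * self.pitch / 2.0)

    def __eq__(self, other):
        return (isinstance(other, Grid) and self.nx == other.nx
                and self.ny == other.ny and np.isclose(self.pitch, other.pitch))

    def __hash__(self):
        return hash((self.nx, self.ny, round(self.pitch, 12)))


def make_grid(nx: int, ny: int, pitch: float) -> Grid:
    """Create a centered sampling grid (pixel counts, pitch in µm)."""
    return Grid(int(nx), int(ny), float(pitch))


def _check_same_grid(a: Grid, b: Grid):
    if a != b:
        raise ValueError(f"mixed-grid arithmetic rejected: {a} vs {b}")


class ScalarField:
    """A single complex field raster on a grid (one polarization component)."""

    def __init__(self, grid: Grid, data, wavelength: float):
        self.grid = grid
        self.data = data if isinstance(data, Tensor) else \
            Tensor(np.asarray(data, dtype=np.complex128))
        if self.data.shape != grid.shape:
            raise ValueError(f"raster shape {self.data.shape} != grid shape {grid.shape}")
        self.wavelength = float(wavelength)  # nm

    @property
    def k(self) -> float:
        """Vacuum wavenumber in rad/µm."""
        return 2.0 * np.pi / (self.wavelength * 1e-3)

    def intensity(self) -> np.ndarray:
        return np.abs(self.data.detach()) ** 2

    def power(self) -> float:
        return float(self.intensity().sum() * self.grid.pitch ** 2)


class VectorField:
    """Three complex component rasters (ex, ey, ez) sharing a grid."""

    def __init__(self, grid: Grid, ex, ey, ez=None, wavelength: float = 650.0):
        self.grid = grid
        self.ex = _lift(ex, grid)
        self.ey = _lift(ey, grid)
        self.ez = _lift(ez if ez is not None else np.zeros(grid.shape), grid)
        self.wavelength = float(wavelength)

    @property
    def k(self) -> float:
        return 2.0 * np.pi / (self.wavelength * 1e-3)

    def components(self):
        return (self.ex, self.ey, self.ez)

    def intensity(self, component: str = "total") -> np.ndarray:
        """Detached intensity raster: 'transverse' |ex|²+|ey|², 'longitudinal' |ez|², or 'total'."""
        ix = np.abs(self.ex.detach()) ** 2
        iy = np.abs(self.ey.detach()) ** 2
        iz = np.abs(self.ez.detach()) ** 2
        if component == "transverse":
            return ix + iy
        if component == "longitudinal":
            return iz
        if component == "total":
            return ix + iy + iz
        raise ValueError(f"unknown component selector {component!r}")

    def power(self) -> float:
        return float(self.intensity("total").sum() * self.grid.pitch ** 2)

    def replace(self, ex=None, ey=None, ez=None) -> "VectorField":
        return VectorField(self.grid,
                           ex if ex is not None else self.ex,
                           ey if ey is not None else self.ey,
                           ez if ez is not None else self.ez,
                           self.wavelength)

    def __add__(self, other: "VectorField") -> "VectorField":
        _check_same_grid(self.grid, other.grid)
        if not np.isclose(self.wavelength, other.wavelength):
            raise ValueError("cannot superpose fields of different wavelengths")
        return VectorField(self.grid, self.ex + other.ex, self.ey + other.ey,
                           self.ez + other.ez, self.wavelength)


def _lift(data, grid: Grid) -> Tensor:
    t = data if isinstance(data, Tensor) else Tensor(np.asarray(data, dtype=np.complex128))
    if t.shape != grid.shape:
        raise ValueError(f"component shape {t.shape} != grid shape {grid.shape}")
    return t


def zero_field(grid: Grid, wavelength: float) -> VectorField:
    z = np.zeros(grid.shape, dtype=np.complex128)
    return VectorField(grid, z, z.copy(), z.copy(), wavelength)


def gaussian_source(grid: Grid, wavelength: float, waist: float | None = None,
                    polarization=(1.0, 0.0)) -> VectorField:
    """Linearly polarized Gaussian beam, unit power, transverse (ez ≡ 0).

    Parameters
    ----------
    wavelength : vacuum wavelength in nm.
    waist : 1/e² intensity radius in µm.  Defaults to a quarter of the grid
        half-width, which keeps the beam well contained for FFT propagation.
    polarization : normalized Jones pair (px, py).
    """
    if waist is None:
        waist = 0.25 * min(grid.extent)
    if not waist > 2.0 * grid.pitch:
        raise ValueError(f"waist {waist} µm unresolvable on pitch {grid.pitch} µm")
    px, py = complex(polarization[0]), complex(polarization[1])
    norm = abs(px) ** 2 + abs(py) ** 2
    if not np.isclose(norm, 1.0, atol=1e-6):
        raise ValueError("Jones pair must be normalized")
    env = np.exp(-(grid.xx ** 2 + grid.yy ** 2) / waist ** 2).astype(np.complex128)
    p = np.sqrt((np.abs(env) ** 2).sum() * grid.pitch ** 2)
    env /= p
    return VectorField(grid, env * px, env * py, None, wavelength)


def plane_wave(grid: Grid, wavelength: float, amplitude=None,
               polarization=(1.0, 0.0)) -> VectorField:
    """Uniform (or amplitude-masked) transverse plane-wave illumination."""
    amp = np.ones(grid.shape) if amplitude is None else np.asarray(amplitude, dtype=np.float64)
    px, py = complex(polarization[0]), complex(polarization[1])
    p = np.sqrt(((np.abs(amp) ** 2).sum() * grid.pitch ** 2) * (abs(px) ** 2 + abs(py) ** 2))
    amp = amp.astype(np.complex128) / max(p, 1e-300)
    return VectorField(grid, amp * px, amp * py, None, wavelength)


# ---------------------------------------------------------------------------
# spot metrics
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class SpotMetrics:
    """FWHMs (µm), spot size φ = (π/4)·FWHMₓ·FWHM_y (µm²), and peak info."""

    fwhm_x: float
    fwhm_y: float
    phi: float
    peak_xy: tuple
    on_axis: float


def _fwhm_1d(profile: np.ndarray, coords: np.ndarray, ipk: int) -> float:
    """FWHM of a 1-D cross-section by linear interpolation of the half-max
    crossings on each side of the peak sample."""
    half = profile[ipk] / 2.0
    # walk left
    i = ipk
    while i > 0 and profile[i] > half:
        i -= 1
    if profile[i] > half:
        raise UnresolvedSpotError("profile never falls below half max (left)")
    f = (half - profile[i]) / (profile[i + 1] - profile[i])
    xl = coords[i] + f * (coords[i + 1] - coords[i])
    # walk right
    j = ipk
    n = len(profile)
    while j < n - 1 and profile[j] > half:
        j += 1
    if profile[j] > half:
        raise UnresolvedSpotError("profile never falls below half max (right)")
    f = (half - profile[j - 1]) / (profile[j] - profile[j - 1])
    xr = coords[j - 1] + f * (coords[j] - coords[j - 1])
    return float(xr - xl)


def spot_metrics(intensity: np.ndarray, grid: Grid) -> SpotMetrics:
    """Spot metrics from the cross-sections through the peak pixel.

    Raises :class:`UnresolvedSpotError` if either cross-section never falls
    below half of the peak inside the window (e.g. for a doughnut's central
    null region, or a beam overfilling the window).
    """
    inten = np.asarray(intensity, dtype=np.float64)
    if inten.shape != grid.shape:
        raise ValueError("intensity shape does not match grid")
    if np.any(inten < 0):
        raise ValueError("intensity must be non-negative")
    if not np.any(inten > 0):
        raise ValueError("intensity is identically zero")
    iy, ix = np.unravel_index(np.argmax(inten), inten.shape)
    fwhm_x = _fwhm_1d(inten[iy, :], grid.x, ix)
    fwhm_y = _fwhm_1d(inten[:, ix], grid.y, iy)
    phi = (np.pi / 4.0) * fwhm_x * fwhm_y
    jy = int(np.argmin(np.abs(grid.y)))
    jx = int(np.argmin(np.abs(grid.x)))
    on_axis = float(inten[jy, jx] / inten[iy, ix])
    return SpotMetrics(fwhm_x, fwhm_y, float(phi),
                       (float(grid.x[ix]), float(grid.y[iy])), on_axis)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_field(path, field: VectorField) -> None:
    """Write a vector field to HDF5 (complex ex/ey/ez + grid attributes)."""
    import h5py

    with h5py.File(path, "w") as f:
        for name, comp in zip(("ex", "ey", "ez"), field.components()):
            f.create_dataset(name, data=comp.detach())
        f.attrs["nx"] = field.grid.nx
        f.attrs["ny"] = field.grid.ny
        f.attrs["pitch"] = field.grid.pitch
        f.attrs["wavelength"] = field.wavelength


def load_field(path) -> VectorField:
    import h5py

    with h5py.File(path, "r") as f:
        grid = Grid(int(f.attrs["nx"]), int(f.attrs["ny"]), float(f.attrs["pitch"]))
        return VectorField(grid, f["ex"][...], f["ey"][...], f["ez"][...],
                           float(f.attrs["wavelength"]))


def export_png(path, raster: np.ndarray) -> None:
    """16-bit grayscale PNG of a non-negative raster (linear scaling to peak)."""
    from PIL import Image

    r = np.asarray(raster, dtype=np.float64)
    peak = r.max()
    img = np.zeros(r.shape, dtype=np.uint16) if peak <= 0 else \
        np.round(r / peak * 65535.0).astype(np.uint16)
    Image.fromarray(img).save(path)


def export_cross_sections(path, intensity: np.ndarray, grid: Grid) -> None:
    """CSV of the horizontal and vertical cross-sections through the peak."""
    iy, ix = np.unravel_index(np.argmax(intensity), intensity.shape)
    rows = np.column_stack([grid.x, intensity[iy, :], grid.y, intensity[:, ix]])
    np.savetxt(path, rows, delimiter=",",
               header="x_um,I_horizontal,y_um,I_vertical", comments="")
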