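"""Reproducible experiment presets, synthetic fixtures, and the robustness
study.

This module bundles everything above the physics layer: programmatic
amplitude-mask generators (triangle, blob silhouette, random shapes, delta),
the ideal-imaging dataset generator and the physical two-lens 4f reference it
must agree with, the data-driven magnifier setup (two phase rasters + three
distances), named discovery presets over the grid ansatz, and the noise /
misalignment / quantization robustness table.

All presets run at reduced resolution (default 64², configurable) so a full
discovery loop completes in CPU-minutes; distances are chosen to respect the
spatial-kernel sampling criterion z ≥ pitch·width/λ at that resolution.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import os

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, as_tensor
from .field import (Grid, make_grid, ScalarField, VectorField, spot_metrics,
                    export_png, export_cross_sections, SpotMetrics,
                    UnresolvedSpotError)
from .propagation import OutputWindow, propagate_czt, focus_high_na
from .elements import (NoiseModel, NO_NOISE, PhaseMask, lens_mask, spiral_mask,
                       quantize_phase)
from .objectives import (LossConfig, StedParams, DetectorReadout, density_loss,
                         softmin, mse_loss, sted_effective)
from .ansatz import AnsatzSpec, SourceSpec, DetectorSpec, GridAnsatz, build_ansatz
from .optimize import OptimizerConfig, RunResult, optimize, train_data_driven

__all__ = [
    "MaskSpec", "make_mask", "make_4f_dataset", "ideal_4f_target",
    "FourFSystem", "run_4f_reference", "ExperimentPreset", "PRESET_NAMES",
    "get_preset", "run_preset", "noise_levels", "run_robustness",
    "save_solution", "load_solution",
]


# ---------------------------------------------------------------------------
# amplitude-mask fixtures
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class MaskSpec:
    """Synthetic binary amplitude mask: kind, linear size fraction, seed."""

    kind: str  # triangle | blob_logo | random_shapes | delta
    fraction: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("triangle", "blob_logo", "random_shapes", "delta"):
            raise ValueError(f"unknown mask kind {self.kind!r}")
        if not 0.0 < self.fraction < 1.0:
            raise ValueError("size fraction must lie in (0, 1)")


def make_mask(spec: MaskSpec, grid: Grid) -> np.ndarray:
    """Binary amplitude raster in {0, 1}, deterministic per (spec, grid)."""
    ex, ey = grid.extent
    xx, yy = grid.xx, grid.yy
    if spec.kind == "delta":
        out = np.zeros(grid.shape)
        out[np.argmin(np.abs(grid.y)), np.argmin(np.abs(grid.x))] = 1.0
        return out
    if spec.kind == "triangle":
        # solid isoceles triangle, apex up, centroid on the optical axis
        base = spec.fraction * ex
        height = spec.fraction * ey
        yc = yy + height / 3.0           # centroid at origin → apex at 2h/3
        inside = (yc >= 0.0) & (yc <= height) & \
                 (np.abs(xx) <= (base / 2.0) * (1.0 - yc / height))
        return inside.astype(np.float64)
    rng = np.random.default_rng([spec.seed, {"blob_logo": 1, "random_shapes": 2}[spec.kind]])
    out = np.zeros(grid.shape, dtype=bool)
    if spec.kind == "blob_logo":
        # seeded multi-component blob silhouette (logo-like evaluation mask)
        n_blobs = 6
        r0 = 0.5 * spec.fraction * min(ex, ey)
        for _ in range(n_blobs):
            cx, cy = rng.uniform(-0.25, 0.25, 2) * np.array([ex, ey])
            a = rng.uniform(0.2, 0.5) * r0
            b = rng.uniform(0.2, 0.5) * r0
            th = rng.uniform(0, np.pi)
            xr = (xx - cx) * np.cos(th) + (yy - cy) * np.sin(th)
            yr = -(xx - cx) * np.sin(th) + (yy - cy) * np.cos(th)
            out |= (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
        return out.astype(np.float64)
    # random_shapes: union of a few random rectangles and ellipses
    n_shapes = int(rng.integers(2, 5))
    r0 = 0.5 * spec.fraction * min(ex, ey)
    for _ in range(n_shapes):
        cx, cy = rng.uniform(-0.3, 0.3, 2) * np.array([ex, ey])
        a = rng.uniform(0.3, 1.0) * r0
        b = rng.uniform(0.3, 1.0) * r0
        if rng.uniform() < 0.5:
            out |= (np.abs(xx - cx) <= a) & (np.abs(yy - cy) <= b)
        else:
            out |= ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
    return out.astype(np.float64)


def ideal_4f_target(raster: np.ndarray, magnification: float, grid: Grid) -> np.ndarray:
    """Ideal f₂/f₁ imaging map applied to an intensity raster.

    The image is the input point-reflected through the axis, scaled by |M|,
    and attenuated by 1/M² (energy conservation of the magnified image).
    Interpolation is bilinear on the point-reflected source coordinates.
    """
    from scipy.ndimage import map_coordinates
    m = float(magnification)
    if m == 0:
        raise ValueError("magnification must be non-zero")
    # output pixel at x maps back to the input point −x/M
    cy, cx = (grid.ny - 1) / 2.0, (grid.nx - 1) / 2.0
    iy, ix = np.meshgrid(np.arange(grid.ny), np.arange(grid.nx), indexing="ij")
    src_y = cy - (iy - cy) / m
    src_x = cx - (ix - cx) / m
    out = map_coordinates(np.asarray(raster, dtype=np.float64),
                          [src_y, src_x], order=1, mode="constant", cval=0.0)
    return out / m ** 2


def make_4f_dataset(n: int, magnification: float, grid: Grid, seed: int = 0):
    """``n`` (input amplitude, target intensity) pairs for the data-driven
    magnifier.  Inputs are random-shape masks; the held-out triangle and
    blob-silhouette evaluation masks are never emitted (their seeds are
    reserved and the kinds differ)."""
    if n < 1:
        raise ValueError("need at least one pair")
    pairs = []
    for i in range(n):
        inp = make_mask(MaskSpec("random_shapes", 0.3, seed=seed * 100003 + i), grid)
        tgt = ideal_4f_target(inp, magnification, grid)
        pairs.append((inp, tgt))
    return pairs


# ---------------------------------------------------------------------------
# the 4f system (reference relay and data-driven trainable setup)
# ---------------------------------------------------------------------------

class FourFSystem:
    """Two phase rasters ("SLM1", "SLM2") separated by three free-space
    distances; scalar propagation at a single wavelength.

    With quadratic lens phases f₁, f₂ at spacings (f₁, f₁+f₂, f₂) this is the
    classical 4f relay with magnification −f₂/f₁.  The same object backs the
    trainable data-driven magnifier: ``simulate(params, input)`` is fully
    differentiable in both rasters and all three distances (softplus-encoded,
    as elsewhere).
    """

    def __init__(self, grid: Grid, wavelength: float = 650.0):
        self.grid = grid
        self.wavelength = float(wavelength)

    def n_parameters(self) -> int:
        """Exact optimizable count: two phase rasters + three distances."""
        return 2 * self.grid.nx * self.grid.ny + 3

    def simulate(self, params: dict, input_raster) -> Tensor:
        g = self.grid
        field = ScalarField(g, np.asarray(input_raster, dtype=np.complex128),
                            self.wavelength)
        win = OutputWindow.from_grid(g)
        d1 = ad.softplus(as_tensor(params["d1"]))
        d2 = ad.softplus(as_tensor(params["d2"]))
        d3 = ad.softplus(as_tensor(params["d3"]))
        field = propagate_czt(field, d1, win)
        field = ScalarField(g, field.data * ad.exp(as_tensor(params["slm1"]) * 1j),
                            self.wavelength)
        field = propagate_czt(field, d2, win)
        field = ScalarField(g, field.data * ad.exp(as_tensor(params["slm2"]) * 1j),
                            self.wavelength)
        field = propagate_czt(field, d3, win)
        return ad.abs2(field.data)

    @staticmethod
    def _raw_distance(z: float) -> float:
        return float(np.log(np.expm1(z))) if z < 700.0 else float(z)

    def ideal_params(self, f1: float, f2: float) -> dict:
        """Exact relay: lens phases f₁, f₂ at spacings f₁, f₁+f₂, f₂."""
        g, lam = self.grid, self.wavelength
        return {"slm1": lens_mask(g, f1, lam).values.copy(),
                "slm2": lens_mask(g, f2, lam).values.copy(),
                "d1": np.asarray(self._raw_distance(f1)),
                "d2": np.asarray(self._raw_distance(f1 + f2)),
                "d3": np.asarray(self._raw_distance(f2))}

    def init_params(self, f1: float, f2: float, seed: int = 0,
                    phase_scale: float = 0.5, distance_jitter: float = 0.2) -> dict:
        """Training initialization: flat rasters with small random phase and
        distances jittered around the geometric spacings."""
        rng = np.random.default_rng(seed)
        g = self.grid
        spacings = (f1, f1 + f2, f2)
        out = {"slm1": rng.uniform(-phase_scale, phase_scale, g.shape),
               "slm2": rng.uniform(-phase_scale, phase_scale, g.shape)}
        for name, z in zip(("d1", "d2", "d3"), spacings):
            zj = z * (1.0 + rng.uniform(-distance_jitter, distance_jitter))
            out[name] = np.asarray(self._raw_distance(zj))
        return out


def _moment_radius(raster: np.ndarray, grid: Grid, floor: float = 0.02) -> float:
    """RMS radius of the intensity pattern about its centroid, with pixels
    below ``floor``·max excluded to suppress the diffraction halo."""
    w = np.asarray(raster, dtype=np.float64).copy()
    w[w < floor * w.max()] = 0.0
    tot = w.sum()
    if tot <= 0:
        raise ValueError("empty raster")
    cx = (w * grid.xx).sum() / tot
    cy = (w * grid.yy).sum() / tot
    r2 = (w * ((grid.xx - cx) ** 2 + (grid.yy - cy) ** 2)).sum() / tot
    return float(np.sqrt(r2))


def _vertex_distance(raster: np.ndarray, grid: Grid, thresh: float = 0.5) -> float:
    """Farthest above-half-max pixel from the pattern centroid (µm)."""
    w = np.asarray(raster, dtype=np.float64)
    m = w > thresh * w.max()
    tot = w[m].sum()
    cx = (w * grid.xx)[m].sum() / tot
    cy = (w * grid.yy)[m].sum() / tot
    return float(np.sqrt((grid.xx[m] - cx) ** 2 + (grid.yy[m] - cy) ** 2).max())


def run_4f_reference(f1: float, f2: float, mask: np.ndarray, grid: Grid,
                     wavelength: float = 650.0, estimator: str = "moment"):
    """Propagate an amplitude mask through the ideal (f₁, f₂) relay.

    Returns ``(image, magnification)`` where ``image`` is the detected
    intensity raster and ``magnification`` is signed: |M| from the ratio of
    RMS radii ('moment' estimator) or of vertex-to-centroid distances
    ('vertex' — suited to the triangle) of output versus input, negative when
    the inversion check (image matches the point-reflected scaled input
    better than the upright one) fires.
    """
    if f1 <= 0 or f2 <= 0:
        raise ValueError("focal lengths must be positive")
    sys4f = FourFSystem(grid, wavelength)
    image = sys4f.simulate(sys4f.ideal_params(f1, f2), mask).detach()
    inp = np.abs(mask) ** 2
    if estimator == "vertex":
        m_abs = _vertex_distance(image, grid) / _vertex_distance(inp, grid)
    elif estimator == "moment":
        m_abs = _moment_radius(image, grid) / _moment_radius(inp, grid)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    # inversion check: compare against the ideal map with +M and −M
    err_inv = float(np.mean((image - ideal_4f_target(np.abs(mask) ** 2, m_abs, grid)) ** 2))
    err_up = float(np.mean((image - ideal_4f_target(np.abs(mask) ** 2, -m_abs, grid)) ** 2))
    inverted = err_inv < err_up
    return image, (-m_abs if inverted else m_abs)


# ---------------------------------------------------------------------------
# discovery presets
# ---------------------------------------------------------------------------

PRESET_NAMES = ("magnifier_4f", "sted_topology", "sharp_focus_topology",
                "sted_parameterized", "sharp_focus_parameterized", "blueprint")

EXCITATION_NM = 650.0
DEPLETION_NM = 532.0


@dataclasses.dataclass
class ExperimentPreset:
    """A named, fully specified experiment at configurable resolution."""

    name: str
    resolution: int = 64
    pitch: float = 8.0            # µm
    rows: int = 3
    cols: int = 3
    wavelengths: tuple = (EXCITATION_NM,)
    component: str = "total"
    loss: LossConfig = dataclasses.field(default_factory=LossConfig)
    sted: StedParams = dataclasses.field(default_factory=StedParams)
    noise: NoiseModel = NO_NOISE
    optimizer: OptimizerConfig = dataclasses.field(default_factory=lambda: OptimizerConfig(
        steps=50, restarts=1, learning_rate=1e-1, raster_learning_rate=3e-1))
    seed: int = 0
    # data-driven magnifier settings
    magnification: float = 2.0
    n_pairs: int = 20
    batch: int = 10

    def __post_init__(self):
        if self.name not in PRESET_NAMES:
            raise ValueError(f"unknown preset {self.name!r}")
        if self.resolution < 16 or self.resolution > 1024:
            raise ValueError("resolution out of supported range")

    def grid(self) -> Grid:
        return make_grid(self.resolution, self.resolution, self.pitch)

    def min_distance(self) -> float:
        """Smallest spatial-kernel-compliant hop: z ≥ pitch·width/λ."""
        lam_um = min(self.wavelengths) * 1e-3
        return self.pitch * (self.resolution * self.pitch) / lam_um

    def _central_cross_units(self) -> list:
        """The four internal edges adjacent to the central lattice node —
        the documented placement of the scalar-active wave plates/distances
        in the fixed-mask topology presets."""
        i, j = self.rows // 2, self.cols // 2
        units = []
        if i > 0:
            units.append(f"u_v_{i - 1}_{j}")
        if i < self.rows - 1:
            units.append(f"u_v_{i}_{j}")
        if j > 0:
            units.append(f"u_h_{i}_{j - 1}")
        if j < self.cols - 1:
            units.append(f"u_h_{i}_{j}")
        return units

    def ansatz_spec(self) -> AnsatzSpec:
        g = self.grid()
        z0 = 1.25 * self.min_distance()
        cross = self._central_cross_units()
        topology_active = {
            "bs": "all",
            "distances": [f"z1_{u}" for u in cross] + [f"z2_{u}" for u in cross],
            "waveplates": [f"wp_{u}" for u in cross],
        }
        waist = 0.18 * g.extent[0]
        if self.name in ("sted_topology", "sted_parameterized", "blueprint"):
            sources = (SourceSpec("B0", EXCITATION_NM, (1.0, 0.0), waist),
                       SourceSpec("B1", DEPLETION_NM, (1.0, 0.0), waist))
            fixed = {"u_B1": "spiral"}
        elif self.name in ("sharp_focus_topology", "sharp_focus_parameterized"):
            sources = (SourceSpec("B1", EXCITATION_NM, (1.0, 0.0), waist),)
            fixed = {"u_B1": "radial_converter"}
        else:
            raise ValueError(f"preset {self.name!r} has no ansatz")
        detectors = tuple(DetectorSpec(f"T{j}", na=0.9, n_pixels=65,
                                       pixel_pitch=0.04, component=self.component)
                          for j in range(self.cols))
        if self.name.endswith("parameterized") or self.name == "blueprint":
            active = dict(topology_active, distances="all", waveplates="all",
                          masks="all")
            mode = "full"
        else:
            active = topology_active
            mode = "fixed_masks"
        return AnsatzSpec(grid=g, rows=self.rows, cols=self.cols, mode=mode,
                          sources=sources, detectors=detectors,
                          fixed_masks=fixed, active=active,
                          z1_default=z0, z2_default=z0)


def get_preset(name: str, resolution: int = 64, steps: int | None = None,
               restarts: int | None = None, seed: int = 0,
               noise: NoiseModel = NO_NOISE) -> ExperimentPreset:
    """Named preset with its documented defaults."""
    p = ExperimentPreset(name=name, resolution=resolution, seed=seed, noise=noise)
    if name in ("sharp_focus_topology", "sharp_focus_parameterized"):
        p.component = "longitudinal"
        p.wavelengths = (EXCITATION_NM,)
    elif name in ("sted_topology", "sted_parameterized"):
        p.component = "transverse"
        p.wavelengths = (EXCITATION_NM, DEPLETION_NM)
    elif name == "blueprint":
        p.component = "total"
        p.wavelengths = (EXCITATION_NM, DEPLETION_NM)
    if steps is not None:
        p.optimizer = dataclasses.replace(p.optimizer, steps=steps)
    if restarts is not None:
        p.optimizer = dataclasses.replace(p.optimizer, restarts=restarts)
    p.optimizer = dataclasses.replace(p.optimizer, seed=seed)
    return p


def _sted_pairing(readouts):
    """Group readouts by detector port into (excitation, depletion) pairs."""
    by_port: dict = {}
    for r in readouts:
        by_port.setdefault(r.port, {})[r.wavelength] = r
    return by_port


def _preset_losses(preset: ExperimentPreset, readouts):
    """Per-detector losses for the preset's objective; returns (losses, tags)."""
    if preset.name in ("sharp_focus_topology", "sharp_focus_parameterized"):
        pairs = [(r.port, density_loss(r, preset.loss)) for r in readouts
                 if float(r.raster.max()) > 0]
    else:  # STED-style: effective beam per detector port
        pairs = []
        for port, group in _sted_pairing(readouts).items():
            exc = group.get(EXCITATION_NM)
            dep = group.get(DEPLETION_NM)
            if exc is None or float(exc.raster.max()) == 0:
                continue
            if dep is None or float(dep.raster.max()) == 0:
                continue
            eff = sted_effective(exc.intensity, dep.intensity, preset.sted)
            pairs.append((port, density_loss(eff, preset.loss)))
    if not pairs:
        raise ValueError("no detector received signal")
    return [p[1] for p in pairs], [p[0] for p in pairs]


def _report_spot(raster: np.ndarray, grid: Grid) -> dict:
    try:
        sm = spot_metrics(raster, grid)
        return {"fwhm_x": sm.fwhm_x, "fwhm_y": sm.fwhm_y, "phi": sm.phi,
                "peak_xy": sm.peak_xy, "on_axis": sm.on_axis}
    except UnresolvedSpotError:
        return {"fwhm_x": float("nan"), "fwhm_y": float("nan"),
                "phi": float("nan"), "peak_xy": (float("nan"), float("nan")),
                "on_axis": float("nan")}


def _side_lobe_fraction(raster: np.ndarray, grid: Grid) -> float:
    """Largest local maximum outside the central lobe, as a fraction of peak."""
    r = np.asarray(raster)
    pk = r.max()
    iy, ix = np.unravel_index(np.argmax(r), r.shape)
    half = r >= 0.5 * pk
    # flood-fill the central lobe from the peak
    from scipy.ndimage import label
    lab, _ = label(half)
    central = lab == lab[iy, ix]
    from scipy.ndimage import binary_dilation
    excl = binary_dilation(central, iterations=2)
    rest = r[~excl]
    return float(rest.max() / pk) if rest.size else 0.0


def _run_magnifier_preset(preset: ExperimentPreset, out_dir=None):
    g = preset.grid()
    sysf = FourFSystem(g, EXCITATION_NM)
    f1 = 1.25 * preset.min_distance()
    f2 = preset.magnification * f1
    dataset = make_4f_dataset(preset.n_pairs, preset.magnification, g, preset.seed)
    holdout_in = make_mask(MaskSpec("triangle", 0.3), g)
    holdout_tgt = ideal_4f_target(holdout_in, preset.magnification, g)
    init = sysf.init_params(f1, f2, seed=preset.seed)
    cfg = dataclasses.replace(preset.optimizer, seed=preset.seed)
    res = train_data_driven(sysf.simulate, dataset, preset.batch, cfg, init,
                            validation=(holdout_in, holdout_tgt))
    image = sysf.simulate({k: Tensor(v) for k, v in res.best_params.items()},
                          holdout_in).detach()
    report = {
        "preset": preset.name,
        "val_mse_init": float(res.val_trace[0]),
        "val_mse_final": float(res.val_trace[-1]),
        "distances_um": {k: float(np.log1p(np.exp(res.best_params[k])))
                         if res.best_params[k] < 700 else float(res.best_params[k])
                         for k in ("d1", "d2", "d3")},
        "spot": _report_spot(image, g),
    }
    if out_dir is not None:
        _emit_common(out_dir, preset, res, report,
                     masks={"slm1": res.best_params["slm1"],
                            "slm2": res.best_params["slm2"]},
                     rasters={"holdout_image": image}, grid=g)
    return res, report


def run_preset(preset: ExperimentPreset, out_dir=None):
    """Run a preset end to end; returns (RunResult, report dict).

    Emits (when ``out_dir`` is given) the pruned topology JSON, phase-mask
    PNGs, the loss-trace CSV, detector cross-sections, and a JSON report with
    the figure observables (per-axis FWHM and spot size φ = (π/4)·FWHMₓ·FWHM_y).
    """
    if preset.name == "magnifier_4f":
        return _run_magnifier_preset(preset, out_dir)
    spec = preset.ansatz_spec()
    anz = build_ansatz(spec)
    zr = (spec.z1_default, 2.0 * spec.z1_default)

    def loss_fn(leaves):
        readouts = anz.forward(leaves, preset.noise)
        losses, tags = _preset_losses(preset, readouts)
        if len(losses) == 1:
            total = losses[0]
        else:
            total = softmin(losses, preset.loss.beta)
        return total, int(np.argmin([float(l.value) for l in losses]))

    init = anz.init_params(seed=preset.seed, distance_range=zr)

    def sampler(s):
        return anz.init_params(seed=s, distance_range=zr)

    cfg = dataclasses.replace(preset.optimizer, seed=preset.seed)
    if cfg.steps == 0:
        # report on the random initialization only
        res = RunResult(best_params=init.arrays, best_loss=float("nan"),
                        loss_trace=np.zeros(0), argmin_detector=np.zeros(0, int),
                        all_final_losses=[], seed=preset.seed)
    else:
        res = optimize(loss_fn, init.arrays, cfg, init_sampler=sampler)

    readouts = anz.forward(res.best_params, preset.noise)
    losses, ports = _preset_losses(preset, readouts)
    best_idx = int(np.argmin([float(l.value) for l in losses]))
    best_port = ports[best_idx]
    report = {"preset": preset.name, "parameters": anz.count_parameters(),
              "best_detector": best_port,
              "per_detector_loss": {p: float(l.value) for p, l in zip(ports, losses)}}
    rasters = {}
    cam = None
    if preset.name.startswith("sted") or preset.name == "blueprint":
        group = _sted_pairing(readouts)[best_port]
        exc, dep = group[EXCITATION_NM], group[DEPLETION_NM]
        eff = sted_effective(exc.intensity, dep.intensity, preset.sted).detach()
        cam = exc.grid
        report["excitation"] = _report_spot(exc.raster, cam)
        report["depletion"] = _report_spot(dep.raster, cam)
        report["effective"] = _report_spot(eff, cam)
        rasters = {"excitation": exc.raster, "depletion": dep.raster,
                   "effective": eff}
    else:  # sharp focus
        ro = [r for r in readouts if r.port == best_port][0]
        cam = ro.grid
        report["longitudinal"] = _report_spot(ro.raster, cam)
        report["side_lobe_fraction"] = _side_lobe_fraction(ro.raster, cam)
        rasters = {"longitudinal": ro.raster}
    if res.loss_trace.size:
        report["loss_initial"] = float(res.loss_trace[0])
        report["loss_final"] = float(res.loss_trace[-1])
    if out_dir is not None:
        topo = anz.extract_topology(res.best_params, preset.noise)
        os.makedirs(out_dir, exist_ok=True)
        topo.to_json(os.path.join(out_dir, "topology.json"))
        save_solution(out_dir, preset, res.best_params)
        masks = {}
        if spec.mode == "full":
            for k, v in res.best_params.items():
                if k.startswith("slm_"):
                    masks[k] = v
        _emit_common(out_dir, preset, res, report, masks=masks,
                     rasters=rasters, grid=cam)
    return res, report


def _emit_common(out_dir, preset, res: RunResult, report: dict,
                 masks: dict, rasters: dict, grid: Grid):
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "loss.csv"), "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["step", "loss", "argmin_detector"])
        for i, (l, a) in enumerate(zip(res.loss_trace, res.argmin_detector)):
            w.writerow([i, repr(float(l)), int(a)])
    for name, phase in masks.items():
        export_png(os.path.join(out_dir, f"mask_{name}.png"),
                   np.mod(np.asarray(phase) + np.pi, 2 * np.pi))
    for name, r in rasters.items():
        export_png(os.path.join(out_dir, f"{name}.png"), np.asarray(r))
        export_cross_sections(os.path.join(out_dir, f"{name}_cross.csv"),
                              np.asarray(r), grid)
    with open(os.path.join(out_dir, "report.json"), "w") as f:
        json.dump(report, f, indent=2, default=float)


# ---------------------------------------------------------------------------
# run persistence (for the robustness CLI)
# ---------------------------------------------------------------------------

def save_solution(out_dir, preset: ExperimentPreset, params: dict) -> None:
    """Persist the solved parameters (HDF5) and a hashed run manifest."""
    import h5py
    import hashlib
    os.makedirs(out_dir, exist_ok=True)
    with h5py.File(os.path.join(out_dir, "solution.h5"), "w") as f:
        for k, v in params.items():
            f.create_dataset(k, data=np.asarray(v))
    manifest = {"preset": preset.name, "resolution": preset.resolution,
                "pitch": preset.pitch, "rows": preset.rows, "cols": preset.cols,
                "seed": preset.seed, "component": preset.component,
                "wavelengths": list(preset.wavelengths),
                "steps": preset.optimizer.steps,
                "restarts": preset.optimizer.restarts}
    payload = json.dumps(manifest, sort_keys=True)
    manifest["manifest_sha256"] = hashlib.sha256(payload.encode()).hexdigest()
    with open(os.path.join(out_dir, "manifest.json"), "w") as f:
        json.dump(manifest, f, indent=2)


def load_solution(run_dir):
    """Rebuild (preset, params) from a saved discovery run directory."""
    import h5py
    with open(os.path.join(run_dir, "manifest.json")) as f:
        man = json.load(f)
    preset = get_preset(man["preset"], resolution=man["resolution"],
                        steps=man["steps"], restarts=man["restarts"],
                        seed=man["seed"])
    with h5py.File(os.path.join(run_dir, "solution.h5"), "r") as f:
        params = {k: f[k][...] for k in f}
    return preset, params


# ---------------------------------------------------------------------------
# robustness study
# ---------------------------------------------------------------------------

def noise_levels() -> dict:
    """Named robustness levels: envelope midpoints of the standard and stress
    conditions, plus the 8-bit-quantized stress level."""
    return {
        "none": (NO_NOISE, None),
        "standard": (NoiseModel(0.05, 0.05, 0.01, 0), None),
        "stress": (NoiseModel(0.5, 0.5, 0.01, 0), None),
        "stress8bit": (NoiseModel(0.5, 0.5, 0.01, 0), 8),
    }


def _quantize_setup(anz: GridAnsatz, params: dict, bits: int):
    """8-bit SLM discretization: quantize optimizable phase rasters and the
    preset's fixed phase masks (converters are untouched)."""
    qparams = {k: (quantize_phase(v, bits) if k.startswith("slm_") else np.asarray(v))
               for k, v in params.items()}
    spec = anz.spec
    fixed = {}
    for unit, fm in spec.fixed_masks.items():
        if fm == "radial_converter":
            fixed[unit] = fm
            continue
        kind, h, v = anz._fixed_element(unit)
        fixed[unit] = (PhaseMask(quantize_phase(h, bits), spec.grid),
                       PhaseMask(quantize_phase(v, bits), spec.grid))
    qspec = dataclasses.replace(spec, fixed_masks=fixed)
    return build_ansatz(qspec), qparams


def run_robustness(anz: GridAnsatz, params, levels=None, seed: int = 0,
                   n_trials: int = 3) -> dict:
    """Re-simulate a solved setup under each noise level.

    Returns ``{level: {"nmse": mean normalized MSE, "n": trials}}`` where the
    normalized MSE of a detector raster I against the noiseless baseline I₀
    is mean((I−I₀)²)/mean(I₀²), averaged over detectors and trials.
    """
    if hasattr(params, "arrays"):
        params = params.arrays
    if levels is None:
        levels = noise_levels()
    base = anz.forward(params, NO_NOISE)
    base_r = [r.raster for r in base]
    table = {}
    for name, (nm, bits) in levels.items():
        use_anz, use_params = anz, params
        if bits is not None:
            use_anz, use_params = _quantize_setup(anz, params, bits)
        errs = []
        for t in range(n_trials):
            if nm.phase_noise == 0 and nm.misalign == 0 and nm.bs_imperfection == 0 \
                    and bits is None:
                out_r = base_r
            else:
                nm_t = dataclasses.replace(nm, seed=seed * 1000 + t)
                out_r = [r.raster for r in use_anz.forward(use_params, nm_t)]
            for i0, i1 in zip(base_r, out_r):
                denom = float(np.mean(i0 ** 2))
                errs.append(0.0 if denom == 0 else float(np.mean((i1 - i0) ** 2)) / denom)
        table[name] = {"nmse": float(np.mean(errs)), "n": n_trials}
    return table
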