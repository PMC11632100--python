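"""The quasi-universal grid ansatz: a lattice of tunable beam splitters
interconnected by "building units" (super-SLM + wave plate), whose continuous
parameters can switch optical paths on and off, turning discrete topology
search into continuous optimization.

Geometry
--------
Beam-splitter nodes sit on a rows×cols lattice.  Every internal lattice edge
and every external stub hosts exactly one building unit (sSLM → z₁ → wave
plate → z₂).  Light flows bottom-left to top-right: sources feed the bottom
and left stubs, detectors (high-NA objective + camera) terminate the top and
right stubs.  For the default 3×3 grid this yields 9 BS nodes, 12 internal
edges + 12 external stubs = 24 building units (48 SLM panels, 24 wave
plates), 6 source ports and 6 detector ports.

Every forward evaluation is built from autodiff primitives, so gradients
reach each active parameter family: splitter ratios (logit-parameterized on
the T+R=1 simplex), distances (softplus-parameterized, always positive),
wave-plate angles, and — in ``full`` mode — every SLM phase pixel.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, as_tensor
from .field import Grid, VectorField, gaussian_source, zero_field
from .propagation import OutputWindow, propagate_vrs, focus_high_na
from .elements import (NoiseModel, NO_NOISE, PhaseMask, spiral_mask,
                       super_slm, wave_plate, beam_splitter, radial_converter)
from .objectives import DetectorReadout, detect

__all__ = [
    "SourceSpec", "DetectorSpec", "AnsatzSpec", "ParameterVector",
    "TopologyGraph", "GridAnsatz", "build_ansatz", "count_parameters",
    "count_discrete_layouts",
]

DEFAULT_WAVELENGTHS = (625.0, 530.0, 470.0)


@dataclasses.dataclass(frozen=True)
class SourceSpec:
    port: str
    wavelength: float = 650.0
    polarization: tuple = (1.0, 0.0)
    waist: float | None = None


@dataclasses.dataclass(frozen=True)
class DetectorSpec:
    port: str
    na: float = 0.9
    n_pixels: int = 65
    pixel_pitch: float = 0.05  # µm on the focal camera
    component: str = "total"


@dataclasses.dataclass
class AnsatzSpec:
    """Configuration of the grid ansatz.

    ``mode`` is ``fixed_masks`` (SLM rasters frozen to supplied patterns,
    only scalars optimizable) or ``full`` (SLM rasters optimizable).
    ``active`` selects the optimizable families: keys 'bs', 'distances',
    'waveplates', 'masks', each either "all" or a list of element names.
    ``fixed_masks`` maps unit names to 'zero', 'spiral', ('spiral', charge),
    'radial_converter', a PhaseMask, or an (H, V) pair of PhaseMasks.
    """

    grid: Grid
    rows: int = 3
    cols: int = 3
    mode: str = "fixed_masks"
    sources: tuple = ()
    detectors: tuple = ()
    fixed_masks: dict = dataclasses.field(default_factory=dict)
    active: dict = dataclasses.field(default_factory=dict)
    z1_default: float = 10_000.0   # µm
    z2_default: float = 10_000.0
    focal: float | None = None     # detector objective focal length (µm)

    def __post_init__(self):
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must be at least 1×1")
        if self.mode not in ("fixed_masks", "full"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.sources:
            self.sources = tuple(
                SourceSpec(port, DEFAULT_WAVELENGTHS[i % 3])
                for i, port in enumerate(self.default_source_ports()))
        if not self.detectors:
            self.detectors = tuple(DetectorSpec(p) for p in self.default_detector_ports())
        ports = self.external_ports()
        used = [s.port for s in self.sources] + [d.port for d in self.detectors]
        if len(set(used)) != len(used):
            raise ValueError("source/detector ports must be distinct")
        for p in used:
            if p not in ports:
                raise ValueError(f"unknown external port {p!r}")

    # -- port / edge bookkeeping ------------------------------------------
    def default_source_ports(self):
        return [f"B{j}" for j in range(self.cols)] + [f"L{i}" for i in range(self.rows)]

    def default_detector_ports(self):
        return [f"T{j}" for j in range(self.cols)] + [f"R{i}" for i in range(self.rows)]

    def external_ports(self):
        return self.default_source_ports() + self.default_detector_ports()

    def internal_edges(self):
        edges = []
        for i in range(self.rows):
            for j in range(self.cols - 1):
                edges.append(("h", i, j))
        for i in range(self.rows - 1):
            for j in range(self.cols):
                edges.append(("v", i, j))
        return edges

    def unit_names(self):
        names = [f"u_{e[0]}_{e[1]}_{e[2]}" for e in self.internal_edges()]
        names += [f"u_{p}" for p in self.external_ports()]
        return names

    def audit(self) -> dict:
        n_internal = self.rows * (self.cols - 1) + self.cols * (self.rows - 1)
        n_stubs = 4 * self.rows * self.cols - 2 * n_internal
        n_units = n_internal + n_stubs
        return {
            "bs_nodes": self.rows * self.cols,
            "internal_edges": n_internal,
            "external_stubs": n_stubs,
            "building_units": n_units,
            "sslm": n_units,
            "slm_panels": 2 * n_units,
            "wave_plates": n_units,
            "sources": len(self.sources),
            "detectors": len(self.detectors),
        }


class ParameterVector:
    """Named parameter set with a flat pack/unpack round trip."""

    def __init__(self, arrays: dict):
        self.arrays = {k: np.asarray(v, dtype=np.float64) for k, v in arrays.items()}

    def __len__(self):
        return sum(v.size for v in self.arrays.values())

    def names(self):
        return list(self.arrays)

    def pack(self) -> np.ndarray:
        if not self.arrays:
            return np.zeros(0)
        return np.concatenate([v.ravel() for v in self.arrays.values()])

    def unpack(self, flat: np.ndarray) -> "ParameterVector":
        out, i = {}, 0
        for k, v in self.arrays.items():
            out[k] = np.asarray(flat[i:i + v.size]).reshape(v.shape).copy()
            i += v.size
        if i != len(np.asarray(flat).ravel()):
            raise ValueError("flat vector length does not match parameter count")
        return ParameterVector(out)

    def copy(self) -> "ParameterVector":
        return ParameterVector({k: v.copy() for k, v in self.arrays.items()})


@dataclasses.dataclass
class TopologyGraph:
    """Pruned blueprint: nodes and directed edges with surviving power."""

    nodes: list
    edges: list  # (src, dst, power_fraction, via_unit)

    def to_json(self, path=None):
        payload = {"nodes": self.nodes,
                   "edges": [{"from": a, "to": b, "power_fraction": p, "unit": u}
                             for a, b, p, u in self.edges]}
        s = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as f:
                f.write(s)
        return s


# ---------------------------------------------------------------------------


def count_discrete_layouts(n_bs: int, n_slm: int, n_wp: int, bs_states: int = 3) -> int:
    """Number of discrete layouts reachable by snapping each splitter to one
    of ``bs_states`` settings and toggling each SLM panel / wave plate ON or
    OFF.  Exact arbitrary-precision integer."""
    if min(n_bs, n_slm, n_wp) < 0:
        raise ValueError("element counts must be non-negative")
    return bs_states ** n_bs * 2 ** n_slm * 2 ** n_wp


class GridAnsatz:
    """Wired instance of an :class:`AnsatzSpec`, ready for forward evaluation."""

    def __init__(self, spec: AnsatzSpec):
        self.spec = spec
        self.audit = spec.audit()
        self.units = spec.unit_names()
        self.last_propagation_count = 0

    # -- parameter machinery ----------------------------------------------
    def _active_names(self, family: str, all_names: list) -> list:
        sel = self.spec.active.get(family, None)
        if sel is None:
            return []
        if sel == "all":
            return list(all_names)
        return [n for n in all_names if n in set(sel)]

    def bs_names(self):
        return [f"bs_{i}_{j}" for i in range(self.spec.rows) for j in range(self.spec.cols)]

    def distance_names(self):
        out = []
        for u in self.units:
            out += [f"z1_{u}", f"z2_{u}"]
        return out

    def waveplate_names(self):
        return [f"wp_{u}" for u in self.units]

    def mask_names(self):
        return [f"slm_{u}" for u in self.units]

    def parameter_template(self) -> dict:
        """name → shape of every active scalar family."""
        shapes = {}
        for n in self._active_names("bs", self.bs_names()):
            shapes[n] = ()
        for n in self._active_names("distances", self.distance_names()):
            shapes[n] = ()
        for n in self._active_names("waveplates", self.waveplate_names()):
            shapes[n + "_eta"] = ()
            shapes[n + "_theta"] = ()
        if self.spec.mode == "full":
            g = self.spec.grid
            for n in self._active_names("masks", self.mask_names()):
                shapes[n + "_H"] = g.shape
                shapes[n + "_V"] = g.shape
        return shapes

    def count_parameters(self) -> int:
        return int(sum(int(np.prod(s)) if s else 1 for s in self.parameter_template().values()))

    def init_params(self, seed: int = 0, distance_range=(10_000.0, 1_000_000.0),
                    mask_scale: float = np.pi) -> ParameterVector:
        """Random initialization within documented bounds: splitter ratios
        uniform on the T+R=1 simplex, distances uniform in ``distance_range``
        (µm; default 1–100 cm), phases and wave-plate angles uniform."""
        rng = np.random.default_rng(seed)
        arrays = {}
        for name, shape in self.parameter_template().items():
            if name.startswith("bs_"):
                u = rng.uniform(0.02, 0.98)
                arrays[name] = np.log(u / (1 - u))       # logit of T
            elif name.startswith("z"):
                z = rng.uniform(*distance_range)
                arrays[name] = np.log(np.expm1(np.clip(z, 1e-6, 700.0))) if z < 700 else z
            elif name.startswith("wp_"):
                arrays[name] = rng.uniform(-np.pi, np.pi)
            elif name.startswith("slm_"):
                arrays[name] = rng.uniform(-mask_scale, mask_scale, size=shape)
            else:
                arrays[name] = np.zeros(shape)
        return ParameterVector(arrays)

    # -- physical values from raw parameters ------------------------------
    @staticmethod
    def _bs_ratio(raw):
        t = ad.sigmoid(as_tensor(raw))
        return t, 1.0 - t

    @staticmethod
    def _distance(raw):
        return ad.softplus(as_tensor(raw))

    def _get(self, params: dict, name: str, default=None):
        if name in params:
            return params[name]
        return default

    def _fixed_element(self, unit: str):
        spec = self.spec.fixed_masks.get(unit, "zero")
        g = self.spec.grid
        if isinstance(spec, PhaseMask):
            return ("masks", spec.values, np.zeros(g.shape))
        if isinstance(spec, tuple) and spec and spec[0] == "spiral":
            return ("masks", spiral_mask(g, spec[1]).values, np.zeros(g.shape))
        if isinstance(spec, tuple) and len(spec) == 2:
            h = spec[0].values if isinstance(spec[0], PhaseMask) else np.asarray(spec[0])
            v = spec[1].values if isinstance(spec[1], PhaseMask) else np.asarray(spec[1])
            return ("masks", h, v)
        if spec == "spiral":
            return ("masks", spiral_mask(g, 1).values, np.zeros(g.shape))
        if spec == "radial_converter":
            return ("converter", None, None)
        if spec == "zero":
            return ("masks", np.zeros(g.shape), np.zeros(g.shape))
        raise ValueError(f"unknown fixed mask spec {spec!r} for unit {unit}")

    # -- forward ----------------------------------------------------------
    def _through_unit(self, field: VectorField, unit: str, params: dict,
                      noise: NoiseModel) -> VectorField:
        kind, mh, mv = ("masks", None, None)
        if self.spec.mode == "full" and f"slm_{unit}_H" in params:
            mh, mv = params[f"slm_{unit}_H"], params[f"slm_{unit}_V"]
        else:
            kind, mh, mv = self._fixed_element(unit)
        # network convention: elements act on the transverse components and
        # each hop re-synthesizes ez, so strip ez before every propagation
        field = VectorField(field.grid, field.ex, field.ey, None, field.wavelength)
        if kind == "converter":
            field = radial_converter(field)
        else:
            field = super_slm(field, mh, mv, noise, tag=("slm", unit))
        z1 = self._distance(params[f"z1_{unit}"]) if f"z1_{unit}" in params \
            else self.spec.z1_default
        field = propagate_vrs(field, z1)
        self.last_propagation_count += 1
        field = VectorField(field.grid, field.ex, field.ey, None, field.wavelength)
        wpn = f"wp_{unit}"
        if wpn + "_eta" in params:
            field = wave_plate(field, (params[wpn + "_eta"], params[wpn + "_theta"]),
                               noise, tag=("wp", unit))
        else:
            field = wave_plate(field, (0.0, 0.0), noise, tag=("wp", unit))
        z2 = self._distance(params[f"z2_{unit}"]) if f"z2_{unit}" in params \
            else self.spec.z2_default
        field = propagate_vrs(field, z2)
        self.last_propagation_count += 1
        return field

    def forward(self, params, noise: NoiseModel = NO_NOISE,
                record_powers: dict | None = None):
        """Propagate every source to every detector.

        ``params`` is a ParameterVector, a dict of arrays, or a dict of
        Tensors (for gradient-based optimization).  Returns a list of
        :class:`DetectorReadout` (one per detector per wavelength group, in
        detector order) with ``port`` and ``wavelength`` attributes set.
        """
        if isinstance(params, ParameterVector):
            params = params.arrays
        params = {k: as_tensor(v) for k, v in params.items()}
        spec = self.spec
        self.last_propagation_count = 0
        readouts = []
        wavelengths = sorted({s.wavelength for s in spec.sources})
        src_power = {lam: sum(1.0 for s in spec.sources if s.wavelength == lam)
                     for lam in wavelengths}
        for lam in wavelengths:
            det_fields = self._forward_single_wavelength(lam, params, noise,
                                                         record_powers)
            for d in spec.detectors:
                fld = det_fields.get(d.port)
                if fld is None:
                    continue
                win = OutputWindow(d.n_pixels, d.n_pixels,
                                  d.n_pixels * d.pixel_pitch / 2.0,
                                  d.n_pixels * d.pixel_pitch / 2.0)
                focal = spec.focal or spec.grid.extent[0] / d.na
                fld = VectorField(fld.grid, fld.ex, fld.ey, None, fld.wavelength)
                focused = focus_high_na(fld, d.na, focal, win)
                self.last_propagation_count += 1
                inten = detect(focused, d.component)
                ro = DetectorReadout(inten, win.grid(), d.component)
                ro.port, ro.wavelength = d.port, lam
                ro.incident_power = fld.power()
                ro.source_power = src_power[lam]
                readouts.append(ro)
        return readouts

    def _forward_single_wavelength(self, lam: float, params: dict,
                                   noise: NoiseModel,
                                   record_powers: dict | None = None) -> dict:
        spec = self.spec
        g = spec.grid
        rows, cols = spec.rows, spec.cols
        in_b = {}  # (i, j) -> field arriving from below
        in_l = {}
        for s in spec.sources:
            if s.wavelength != lam:
                continue
            field = gaussian_source(g, lam, s.waist, s.polarization)
            field = self._through_unit(field, f"u_{s.port}", params, noise)
            if record_powers is not None:
                record_powers[(f"src:{s.port}", lam)] = field.power()
            if s.port.startswith("B"):
                j = int(s.port[1:])
                in_b[(0, j)] = field if (0, j) not in in_b else in_b[(0, j)] + field
            else:
                i = int(s.port[1:])
                in_l[(i, 0)] = field if (i, 0) not in in_l else in_l[(i, 0)] + field
        det_fields = {}
        for i in range(rows):
            for j in range(cols):
                a = in_b.get((i, j))
                b = in_l.get((i, j))
                if a is None and b is None:
                    continue
                a = a if a is not None else zero_field(g, lam)
                b = b if b is not None else zero_field(g, lam)
                name = f"bs_{i}_{j}"
                if name in params:
                    t, r = self._bs_ratio(params[name])
                else:
                    t, r = 0.5, 0.5
                out_t, out_r = beam_splitter(a, b, (t, r), noise, tag=("bs", i, j))
                # upward output
                if i < rows - 1:
                    unit = f"u_v_{i}_{j}"
                    fld = self._through_unit(out_t, unit, params, noise)
                    if record_powers is not None:
                        record_powers[(f"bs:{i},{j}", f"bs:{i + 1},{j}", lam)] = fld.power()
                    in_b[(i + 1, j)] = fld if (i + 1, j) not in in_b else in_b[(i + 1, j)] + fld
                else:
                    port = f"T{j}"
                    fld = self._through_unit(out_t, f"u_{port}", params, noise)
                    if record_powers is not None:
                        record_powers[(f"bs:{i},{j}", f"det:{port}", lam)] = fld.power()
                    det_fields[port] = fld if port not in det_fields else det_fields[port] + fld
                # rightward output
                if j < cols - 1:
                    unit = f"u_h_{i}_{j}"
                    fld = self._through_unit(out_r, unit, params, noise)
                    if record_powers is not None:
                        record_powers[(f"bs:{i},{j}", f"bs:{i},{j + 1}", lam)] = fld.power()
                    in_l[(i, j + 1)] = fld if (i, j + 1) not in in_l else in_l[(i, j + 1)] + fld
                else:
                    port = f"R{i}"
                    fld = self._through_unit(out_r, f"u_{port}", params, noise)
                    if record_powers is not None:
                        record_powers[(f"bs:{i},{j}", f"det:{port}", lam)] = fld.power()
                    det_fields[port] = fld if port not in det_fields else det_fields[port] + fld
        return det_fields

    # -- topology extraction ----------------------------------------------
    def extract_topology(self, params, noise: NoiseModel = NO_NOISE,
                         prune_threshold: float = 0.01) -> TopologyGraph:
        """Re-simulate, record the power surviving on every connection, and
        return the blueprint graph with edges below ``prune_threshold``
        (fraction of total injected power) removed."""
        if not 0.0 < prune_threshold < 1.0:
            raise ValueError("prune threshold must lie in (0, 1)")
        powers: dict = {}
        self.forward(params, noise, record_powers=powers)
        total = sum(v for k, v in powers.items() if len(k) == 2)  # source injections
        total = total if total > 0 else 1.0
        # aggregate over wavelength groups: one edge per physical connection
        agg: dict = {}
        for key, p in powers.items():
            if len(key) == 2:  # source → entry node
                srcname, lam = key
                port = srcname.split(":")[1]
                if port.startswith("B"):
                    dst = f"bs:0,{int(port[1:])}"
                else:
                    dst = f"bs:{int(port[1:])},0"
                a, b, unit = srcname, dst, f"u_{port}"
            else:
                a, b, lam = key
                unit = ""
            frac, _ = agg.get((a, b), (0.0, unit))
            agg[(a, b)] = (frac + p / total, unit)
        edges, nodes = [], set()
        for (a, b), (frac, unit) in agg.items():
            if frac >= prune_threshold:
                edges.append((a, b, float(frac), unit))
                nodes.add(a)
                nodes.add(b)
        return TopologyGraph(sorted(nodes), edges)

    def to_networkx(self, topology: TopologyGraph):
        import networkx as nx
        gph = nx.DiGraph()
        gph.add_nodes_from(topology.nodes)
        for a, b, p, u in topology.edges:
            gph.add_edge(a, b, power_fraction=p, unit=u)
        return gph


def build_ansatz(spec: AnsatzSpec) -> GridAnsatz:
    """Wire a grid ansatz; wiring is deterministic for equal specs."""
    return GridAnsatz(spec)


def count_parameters(spec: AnsatzSpec, active: dict | None = None) -> int:
    """Exact number of scalar degrees of freedom of the active families."""
    if active is not None:
        spec = dataclasses.replace(spec, active=active)
    return build_ansatz(spec).count_parameters()
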