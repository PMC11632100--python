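"""Loss functions and detector statistics for automated optical design.

The central objective is the inverse intensity *density*
``L = Area / I_ε``: the number of camera pixels whose intensity exceeds
ε·i_max, divided by the summed intensity of those pixels.  Minimizing L
drives the optimizer toward small, bright spots.  The thresholding is a hard
select evaluated on both branches, so gradients flow through the retained
pixel values while the Area factor enters as the piecewise-constant scale
that adapts the gradient magnitude to the current spot size.  A smooth
sigmoid-thresholded variant is available behind a flag.

Detector-level losses are aggregated with a smooth soft-minimum
(−logsumexp(−β·l)/β), so the parameter update is driven by the best detector
while remaining differentiable everywhere.

The stimulated-depletion effective beam follows a Beer–Lambert attenuation
model: the excitation profile is damped exponentially by the normalized
depletion profile, which mimics how a doughnut depletion beam confines the
effective response to the doughnut's central null without simulating
time-dependent fluorophore kinetics.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, as_tensor
from .field import Grid, VectorField

__all__ = [
    "DetectorReadout", "LossConfig", "StedParams",
    "detect", "density_loss", "softmin", "mse_loss", "sted_effective",
    "NoSignalError",
]


class NoSignalError(ValueError):
    """Raised when a detector raster carries no signal above threshold."""


@dataclasses.dataclass(frozen=True)
class LossConfig:
    """Density-loss settings: threshold fraction ε and softmin sharpness β."""

    epsilon: float = 0.5
    beta: float = 100.0
    soft_threshold: bool = False
    soft_temperature: float = 0.01

    def __post_init__(self):
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")
        if not self.beta > 0:
            raise ValueError("beta must be positive")


@dataclasses.dataclass(frozen=True)
class StedParams:
    """Depletion strength α (dimensionless) and emission wavelength metadata."""

    alpha: float = 10.0
    emission_wavelength: float = 560.0

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")


class DetectorReadout:
    """Detected intensity raster with threshold statistics.

    Holds the differentiable intensity tensor; ``i_max``, ``i_eps`` (I_ε) and
    ``area`` are exposed as detached floats for reporting.
    """

    def __init__(self, intensity: Tensor, grid: Grid, component: str = "total",
                 epsilon: float = 0.5):
        self.intensity = as_tensor(intensity)
        self.grid = grid
        self.component = component
        self.epsilon = float(epsilon)

    @property
    def raster(self) -> np.ndarray:
        return self.intensity.detach()

    @property
    def i_max(self) -> float:
        return float(self.raster.max())

    def _mask(self) -> np.ndarray:
        return self.raster > self.epsilon * self.i_max

    @property
    def i_eps(self) -> float:
        return float(self.raster[self._mask()].sum())

    @property
    def area(self) -> int:
        return int(self._mask().sum())


def detect(field: VectorField, component: str = "total") -> Tensor:
    """Differentiable detected intensity.

    'transverse' → |ex|²+|ey|² ; 'longitudinal' → |ez|² ; 'total' → all three.
    """
    if component == "transverse":
        return ad.abs2(field.ex) + ad.abs2(field.ey)
    if component == "longitudinal":
        return ad.abs2(field.ez)
    if component == "total":
        return ad.abs2(field.ex) + ad.abs2(field.ey) + ad.abs2(field.ez)
    raise ValueError(f"unknown component selector {component!r}")


def density_loss(readout, cfg: LossConfig = LossConfig()) -> Tensor:
    """Inverse intensity density L = Area / I_ε of a detector raster.

    ``readout`` may be a :class:`DetectorReadout`, a Tensor, or a numpy
    raster.  Pixels strictly above ε·i_max are retained; I_ε is their sum and
    Area their count.  The returned Tensor is differentiable through the
    retained pixel values; Area contributes the piecewise-constant scale.
    """
    raster = readout.intensity if isinstance(readout, DetectorReadout) else as_tensor(readout)
    vals = raster.detach()
    if np.any(vals < 0):
        raise ValueError("intensity raster must be non-negative")
    imax = ad.tmax(raster)
    if cfg.soft_threshold:
        # smooth gate: sigmoid((i − ε·i_max)/(T·i_max))
        gate = ad.sigmoid((raster - imax * cfg.epsilon) / (imax * cfg.soft_temperature))
        i_eps = ad.tsum(raster * gate)
        area = ad.tsum(gate)
        return area / i_eps
    mask = vals > cfg.epsilon * vals.max()
    if not mask.any():
        raise NoSignalError("no signal above threshold")
    zero = np.zeros_like(vals)
    i_eps = ad.tsum(ad.where(mask, raster, zero))
    area = float(mask.sum())  # piecewise-constant numerator
    return (1.0 / i_eps) * area


def softmin(losses, beta: float) -> Tensor:
    """Smooth minimum −logsumexp(−β·l)/β over per-detector losses."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    if isinstance(losses, (list, tuple)):
        if len(losses) == 0:
            raise ValueError("softmin needs at least one loss")
        losses = ad.stack([as_tensor(l) for l in losses])
    else:
        losses = as_tensor(losses)
        if losses.size == 0:
            raise ValueError("softmin needs at least one loss")
    return ad.logsumexp(losses, scale=-beta)


def mse_loss(detected, target) -> Tensor:
    """Mean squared error between a detected and a target intensity raster."""
    detected = as_tensor(detected)
    tv = target.detach() if isinstance(target, Tensor) else np.asarray(target)
    if detected.shape != tv.shape:
        raise ValueError(f"shape mismatch: {detected.shape} vs {tv.shape}")
    d = detected - tv
    return ad.tmean(d * d)


def sted_effective(excitation, depletion, p: StedParams = StedParams()):
    """Beer–Lambert effective beam I_exc · exp(−α·I_dep/max(I_dep)).

    Accepts Tensors or numpy rasters; with an identically zero depletion beam
    the excitation is returned unchanged.
    """
    exc = as_tensor(excitation)
    dep = as_tensor(depletion)
    if exc.shape != dep.shape:
        raise ValueError("excitation and depletion rasters must share a grid")
    if np.any(exc.detach() < 0) or np.any(dep.detach() < 0):
        raise ValueError("intensity rasters must be non-negative")
    dmax = float(dep.detach().max())
    if dmax == 0.0:
        return exc
    return exc * ad.exp(dep * (-p.alpha / dmax))
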