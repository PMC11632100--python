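# Methods

Physical models, default parameters, and numerical limits of `diffoptix`.
Units: lengths in micrometres (µm), wavelengths in nanometres (nm) at the
API surface (converted internally), angles in radians.

## Fields and grids

A `Grid(nx, ny, pitch)` is a uniform camera/SLM pixel lattice centred on the
optical axis; `Grid.extent` returns **half**-widths. Fields are Jones vectors
`(Ex, Ey)` (plus `Ez` after vectorial propagation) of complex amplitudes per
pixel; intensity components are `transverse = |Ex|²+|Ey|²`,
`longitudinal = |Ez|²`, `total` their sum. Sources are Gaussian beams with a
normalized Jones polarization and waist (default: a quarter of the grid
half-width in the experiment presets, where `waist = 0.18 · half-width`).

## Propagation models

**Rayleigh–Sommerfeld (RS).** Exact scalar first-kind RS integral as a
discrete convolution of the field with the sampled spatial kernel, computed
with 2× zero-padded FFTs. Valid when the kernel is adequately sampled:

```
z ≥ pitch · width / λ        (width = n · pitch)
```

Propagating closer than this bound raises a `SamplingWarning`; preset hop
distances default to `1.25 ×` the bound. Negative `z` back-propagates.

**Chirp-z zoom (CZT).** Bluestein's algorithm evaluates the same integral on
an arbitrary rectangular output window (`OutputWindow`), decoupling camera
resolution from SLM resolution. On a window congruent with the input grid the
CZT and RS results agree to 10⁻⁶ relative (tested).

**Vectorial RS / CZT (VRS/VCZT).** `Ex` and `Ey` propagate with the scalar
kernel; `Ez` is synthesized from dedicated kernels so the output angular
spectrum satisfies `k·E = 0`. The input must have `Ez = 0`: intermediate
hops inside setups strip `Ez` (paraxial re-collimation assumption between
elements). *Limit:* the divergence residual is at machine precision for
smooth fields but degrades to ~10⁻³–10⁻² for fields whose phase varies near
the Nyquist frequency (e.g. the core of a spiral mask), where the sampled
spatial kernel departs from the analytic one; the closed-form oracle uses a
smooth structured beam.

**High-NA focusing.** Richards–Wolf vector diffraction of an aplanatic
objective with apodization `√cosθ`, evaluated on a zoomed focal window.
Oracles: Airy FWHM `1.03 λf/D` within 3% for a uniform low-NA pupil; on-axis
vortex null < 10⁻⁴; radially polarized input gives an `|Ez|²` maximum on
axis with a transverse null.

## Elements

- **SLM / super-SLM:** phase-only rasters; the super-SLM (`sSLM`) carries two
  independent panels acting on the H and V components.
- **Wave plate:** retarder Jones matrix with retardance η and fast-axis θ.
- **Beam splitter:** continuous power ratio `t ∈ (0,1)` (sigmoid-encoded when
  optimized) mixing two input arms unitarily.
- **Fixed converters:** spiral phase mask (integer charge) and an ideal
  radial-polarization converter.
- **Distances:** free-space hops, softplus-encoded when optimized so they
  stay positive.

**Noise model** (`NoiseModel(phase_noise, misalign, bs_imperfection, seed)`):
per-element Gaussian phase error on each SLM panel (rad), random transverse
misalignment (mm) applied as a band-limited FFT shift of the element's
complex transmission, and a renormalized perturbation of each splitting
ratio. The transmission is zero-padded around a **unit baseline** by at least
the drawn displacement before the FFT shift, so large misalignments slide an
element out of the aperture instead of wrapping periodically. Noise draws are
keyed deterministically per element tag and seed (CRC32 of the tag), so runs
are bit-reproducible across processes. 8-bit operation quantizes phase
rasters to 256 levels over 2π.

Named robustness levels: `standard` (0.05 rad, 0.05 mm, 1%), `stress`
(0.5 rad, 0.5 mm, 1%), `stress8bit` (stress + 8-bit quantization) — the
midpoints of the ±0.01–0.1 and ±0.1–1 envelopes of the protocol. The study
reports the normalized MSE `mean((I−I₀)²)/mean(I₀²)` against the noiseless
baseline, averaged over detectors and trials. *Limit:* absolute nmse values
at reduced grid scale are large (a 0.05 mm shift is a sizeable fraction of a
0.26 mm window); the scale-robust observable is the ordering
`standard < stress`, which is what the acceptance suite asserts.

## Objectives

- **Density loss** `L = Area / I_ε`: pixels above `ε · max(I)` (default
  `ε = 0.5`) counted and divided by the intensity they collect. The
  threshold selection is a hard gate (gradients flow only through retained
  pixels); an optional sigmoid soft threshold (`soft_temperature`) smooths
  it. Analytic anchors: uniform raster → 1; a single delta pixel of value
  `v` → `1/v`.
- **Softmin** `−log Σ exp(−β l_i) / β` (default `β = 100`) aggregates
  per-detector losses; bounded by `[min − ln(k)/β, min]`.
- **MSE** for the data-driven magnifier.
- **STED effective beam** `I_eff = I_exc · exp(−α · I_dep / max(I_dep))`
  (Beer–Lambert surrogate for depletion, default `α = 10`): preserves the
  exact doughnut null, never exceeds the excitation.

## Grid ansatz

`rows × cols` beam-splitter lattice; every internal edge and every external
stub carries a building unit `sSLM → z₁ → wave plate → z₂`. Sources attach to
bottom/left stubs, detectors to top (`T*`) and right (`R*`) stubs. Each
wavelength propagates coherently through the lattice and detectors sum
wavelengths incoherently. Audit for 3×3: 9 splitters, 12 internal edges, 12
stubs, 24 units, 48 SLM panels, 24 wave plates, 6 detectors. The discrete
layout count `3^9 · 2^48 · 2^24` is exposed by `count_discrete_layouts`.

Parameter encodings: splitting ratios by sigmoid, distances by softplus,
phases unconstrained. `extract_topology` prunes edges below a relative power
threshold (aggregated over wavelengths) and exports JSON or a networkx graph.

**Fixed-mask topology presets (25 scalars).** Phase masks are frozen; the
optimizable scalars are the 9 splitter ratios plus `z₁, z₂` and the wave
plate `(η, θ)` of the four internal edges adjacent to the central lattice
node (8 + 8). Documented placement of the fixed converters (the stub
assignment is otherwise under-determined): STED presets put a charge-1 spiral
on the depletion source stub (`u_B1`, 532 nm) with plain excitation at B0
(650 nm); sharp-focus presets put the radial converter on their single source
stub.

## 4f magnifier

`FourFSystem`: two trainable phase rasters separated by three softplus-encoded
distances, scalar CZT propagation at 650 nm; `2·n² + 3` parameters. With
quadratic phases `f₁, f₂` at spacings `(f₁, f₁+f₂, f₂)` it is the classical
relay with magnification `−f₂/f₁`.

Magnification estimators: `moment` (ratio of RMS radii about the centroid,
2%-of-peak floor to suppress the diffraction halo) and `vertex` (ratio of
farthest above-half-max pixel distances; suited to the triangle fixture).
Inversion is detected by comparing the image against the ideal map with `+M`
and `−M`. *Limit:* the ideal-map target has sharp edges while the physical
image is band-limited, so dataset/oracle agreement is resolution-dependent:
relative MSE ≈ 2.4% at 256² and ≈ 1.2% at 512²; the 2% acceptance
measurement runs at 512².

Training data: random-shape binary masks with targets produced by the ideal
imaging map (point reflection, scale `|M|`, energy factor `1/M²`, bilinear
resampling). The triangle and blob-silhouette evaluation masks use reserved
kinds/seeds and never appear in training.

## Optimization

Custom reverse-mode autodiff over complex numpy arrays using Wirtinger
calculus (cotangent `g = 2 ∂L/∂z̄`; real part taken at complex→real
boundaries), with FFT/CZT adjoints verified against central finite
differences (relative error < 10⁻⁴ through full setups, < 10⁻⁷ for smooth
scalar chains). AdamW (decoupled weight decay) with two learning-rate groups:
scalars 10⁻² and rasters 10⁻¹ by default (arrays of ndim ≥ 2 are treated as
rasters). Random restarts ranked by final loss; convergence declared when the
windowed best loss improves by less than `rtol` over 50 steps; every run can
write a resumable HDF5 checkpoint, and `resume` extends the stored trace
exactly.

Distance initialization defaults to uniform in [1, 100] cm at the engine
level; the reduced-resolution presets override the range to
`[z₀, 2 z₀]` with `z₀ = 1.25 ×` the sampling bound so beams stay contained on
the scaled grids (full-scale runs retain the wide default).

## Scaled study conditions

Presets default to 64–128² grids with 8 µm pitch (experiment scale:
824–1024², overridable via `--resolution`). At this scale the acceptance
smoke runs are: single-SLM focusing (density loss ≥ 10× reduction in 30
steps), STED topology (effective FWHM < excitation FWHM after 10 steps),
sharp focus (`|Ez|²`-dominated on-axis spot), and the 32² magnifier (held-out
MSE ≥ 5× reduction in 30 steps). Deterministic given the seeds; all run on
one CPU in well under their stated budgets.
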