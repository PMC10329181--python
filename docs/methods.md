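# Methods

## Model and estimator

The forward model is the homogeneous-medium time of flight
`t = ‖x − x′‖/c` between a point source at `x′` (stage frame, mm) and a
transducer at `x` (mm), with `c` in mm/µs. Differencing squared ranges
over source pairs linearizes the problem in `x`:

```
(x′ⱼ − x′ᵢ)·x = (dᵢ² − dⱼ² + r′ⱼ² − r′ᵢ²)/2,   d = c t,  r′² = ‖x′‖².
```

Each transducer is solved independently by SVD-based least squares.
Assumptions: a homogeneous, stationary sound speed (deionized water whose
temperature is measured); source positions known exactly from the stage
(bidirectional repeatability is orders of magnitude below the acoustic
wavelength); receive delays either zero, already subtracted, or supplied.

Numerical choices: all C(M,2) pairs by default (an anchored mode with
M−1 pairs bounds memory for large M and agrees to < 1e-9 mm in the
noiseless case); rank decided at 1e-8 relative singular-value threshold;
condition numbers above 1e4 warn and above 1e6 (configurable) raise a
degenerate-geometry error naming the unconstrained axis, as happens
whenever all sources are coplanar. Transducers whose system is degenerate
keep their designed coordinates and are flagged, so reconstruction always
receives a full coordinate set. Canonical units are mm/µs/MHz throughout;
m/s values are converted at the boundary.

## Sound speed from temperature

Marczak's fifth-order pure-water polynomial (0–95 °C) is the default
relation, with Greenspan–Tschiegg selectable; no salinity or pressure
terms, matching a deionized-water bath at ambient pressure. The inverse
is solved by bisection on the strictly increasing branch (0–74 °C).
Uncertainty is propagated locally, `δc = |dc/dT| δT`, with δT defaulting
to a 0.1 °C thermometer resolution — about 0.3 m/s near 20 °C.

## Arrival-time estimation

Per-record threshold picking fails at low SNR, so the estimator uses the
repeated pulse shape: locate each record's maximum, align maxima by
integer shifts, average (noise drops by √M), pick the averaged signal's
first crossing of 3× its pre-arrival noise standard deviation, convert
the crossing-to-maximum gap into a pulse delay, and subtract that delay
from every record's own maximum time. Records below `min_snr = 5`
(peak over own-noise std) are masked invalid. The noise window defaults
to the first 10% of samples; averaging pools all records or groups per
transducer (both interpretations of "average all signals" are exposed).

Two arrival conventions are explicit at both ends of the synthetic loop.
`"onset"` is the causal convention: the simulated wavelet is delayed so
its onset (3 envelope σ before the peak) sits at the geometric arrival,
and the picker's threshold crossing approximates that onset up to a
threshold-dependent bias — the same sub-period systematic a real
threshold pick incurs, which the error budget's 0.45 µs term represents.
`"peak"` is the zero-phase convention: the wavelet is centered on the
arrival and the picker returns (optionally spline-refined) peak times;
it is exact on noiseless sampled data and is what the exact-recovery
tests and the imaging simulations use. Sub-sample refinement offers a
three-point parabola or a local cubic-spline maximization; the latter
reaches ~1e-4 samples on noiseless band-limited records.

## Error propagation and grid design

Input errors perturb only the right-hand side at first order:
`δb_ij = dᵢδdᵢ − dⱼδdⱼ` with `δd = c δt + (d/c) δc`, mapped through the
pseudo-inverse. The sound-speed term comes from a single thermometer
reading and is always fully coherent. The ToA term supports two models —
a systematic per-transducer offset (one δt shared by all of an element's
records, the threshold bias above) and independent per-measurement
errors — combined with either of two correlation treatments:

* `full` keeps exact cross-equation correlations. A strictly common
  offset then produces an almost pure radial displacement of magnitude
  `c δt` (the pair differences `dᵢ − dⱼ` shrink δb, but the
  pseudo-inverse amplifies exactly that range direction back), which no
  grid refinement can reduce.
* `per_equation` (default) treats each pair equation's error as
  independent with the magnitude the model implies — the ordinary
  least-squares standard-error assumption. This isolates the
  geometry-dependent uncertainty that experiment design can act on: it
  shrinks as sources are added, scales with the grid's per-axis extent,
  and yields the anisotropy pattern (σx = σy < σz for a grid with fewer
  z planes) that motivates choosing pitch and count against a tolerance
  such as λ₀/5.

A vectorized Monte Carlo (noise in the right-hand side only; one
pseudo-inverse, trials processed in memory-bounded blocks) verifies every
analytic configuration to within sampling error (< 5% at 10⁴ trials).
`design_grid` ranks candidate arrangements by source count (ties to the
smaller pitch) and returns the first whose worst-case per-axis error over
sampled nominal element positions meets the tolerance.

Defaults for design studies: budget 0.3 m/s and 0.45 µs systematic,
nominal element at 120 mm range in the arc-midpoint direction (45°
elevation) — a representative hemispherical-array element; the radius is
an assumption, and the predicted per-axis errors depend only weakly on it
under the default model.

## Synthetic data

The simulator is a delay-and-sum of band-limited kernels with 1/r
spherical spreading — it reproduces exactly the quantity calibration
consumes (arrival times) plus realistic nuisance terms (additive white
noise relative to the set's peak amplitude, per-channel receive delays,
per-record ToA jitter), not a full wave solution: no heterogeneity,
attenuation, dispersion, element apertures or directivity (elements are
isotropic points). Consequently, passing tests demonstrate correctness of
the estimation pipeline under the stated error models, not robustness to
acoustically heterogeneous media.

The pulse is a Gaussian-envelope wavelet whose one-way 6 dB fractional
bandwidth fixes the envelope width (`σ_f = (fbw·f₀/2)/√(2 ln 2)`); a
cosine carrier (`gaussian_modulated`) peaks at the arrival and suits
picking, while a negative-sine carrier (`n_shape_bandpassed`) is the
band-passed N-wave a small absorber emits (compression first) and is the
imaging default: the UBP filter `2p − 2t ∂p/∂t` is derivative-dominated
at imaging depths (the `t` factor is tens of µs), so only the bipolar
wavelet reconstructs to a positive, centered point response. Kernels are
evaluated in ±8σ windows (truncation below 1e-14), which makes a
single-voxel phantom exactly equal a scaled point simulation.

Array builders cover rings, pole-to-equator arcs (elements at midpoints
of equal polar-angle bins, so multi-arc assemblies share no pole
element) and rotated-arc hemispheres where each rotation stop contributes
virtual element positions. Geometric perturbation applies independent
uniform offsets in chosen axes, seeded. The vessel phantom grows
connected quadratic-Bezier branches with parabolic cross-sections;
centerlines are returned on request so tests can verify support widths
by distance query.

## Reconstruction and metrics

UBP back-projects `2p − 2t ∂p/∂t` (central differences; one-sided at
boundaries) along spherical shells with linear temporal interpolation and
no apodization. Solid-angle weights are uniform by default (uniformly
spaced rings); an explicit per-channel weight array accepts
`solid_angle_weights` (∝ sin θ) for arcs laid out uniformly in polar
angle, and a cosine-obliquity mode exists. Voxels whose arrival falls
outside the record contribute zero under a coverage warning.

Point-target quality uses the squared volume as an (unnormalized)
density: `Σ_V²` is its covariance over voxel centers, size = √det Σ_V²
(mm³), spread = √tr Σ_V² (mm). Both are axis-invariant and polarity-free;
negative lobes are squared, not clipped, and the density support is the
analyzed region, so both metrics grow with region size as artifact tails
enter — the region is therefore part of any quoted number. CNR is
(signal mean − background mean)/background std over explicit disjoint
masks; for synthetic phantoms the masks come from ground truth (support
vs voxels ≥ 1 mm away). FWHM interpolates the half-maximum crossings
nearest the profile peak.

## Reference studies

`pactcal.studies` pins the two reference computations.

*Predicted calibration errors*: 6×6×3 sources at 0.254 mm pitch,
c = 1.4829 mm/µs, default budget and nominal element. Result:
0.026 / 0.026 / 0.038 mm (x/y/z), all within λ₀/5 ≈ 0.132 mm at
2.25 MHz. The z error exceeds x/y because the grid has 3 z planes
against 6 positions in x/y; the exact anisotropy ratio depends on the
unreported nominal element direction.

*Simulated arc point source*: one 256-element pole-to-equator arc at an
assumed 120 mm radius, swept over 90° in 16 rotation stops (32 stops
changes the metrics by < 1%), 2.25 MHz / 98% bandwidth N-wave records at
20 MHz sampling, UBP with sin θ weights onto 64³ voxels of 0.1 mm
(~λ₀/6) centered on the source. Result: size 0.070 mm³, spread
0.719 mm. Problem sizes were chosen so the full study runs in tens of
seconds on one CPU.

## Known limitations

* The threshold-bias systematic of onset picking is represented in the
  error budget, not removed; only a reference measurement with known
  absolute timing could remove it.
* Spatial impulse response variation for out-of-plane sources (relevant
  when calibrating 2D arrays in 3D) is out of scope.
* The vessel phantom is a stand-in: CNR/FWHM comparisons demonstrate the
  qualitative calibration benefit, not any specific published value.
* Full-wave propagation effects (diffraction from finite apertures,
  heterogeneity) are not modeled.
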