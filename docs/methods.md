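# Methods

This note documents the models and procedures implemented in `bonepore`,
the defaults and why they were chosen, what the synthetic-data generators
do and do not emulate, and the numerical decisions that matter.

## Image-processing protocol

The segmentation chain targets confocal micrographs of stained,
demineralized cortical bone sections: bright collagenous tissue, dark
non-collagenous spaces (vascular canals, lacunae, fissures, fracture
spaces — pooled as "objects" without classifying their origin).

1. **Median denoising**, 5×5 window, reflect padding. Reflect padding
   avoids the artificial dark rim that zero padding would create, which
   would otherwise segment as fake border objects.
2. **Brightness equalization by division.** Each pixel is divided by the
   corresponding pixel of a strongly Gaussian-blurred copy of the image
   (blurred values floored at 1 to avoid division by zero on pure-black
   regions). The ratio is mapped so that ratio 1.0 → gray 128, then
   rounded and clipped to [0, 255]. This choice of output scale keeps the
   fixed threshold of 50 meaningful: it selects pixels darker than ~39%
   of their local background. The blur sigma defaults to 50 px —
   much larger than the pore scale, much smaller than the 2048 px field —
   and is configurable; it only needs to be "strong" enough that the
   blurred image carries illumination, not pore detail.
3. **Fixed-threshold segmentation** at 50 (dark objects by default;
   polarity configurable), 8-connected labeling (4-connectivity
   available), removal and counting of components touching the raster
   border (objects visible only in part), sequential relabeling. No
   minimum-size filter is applied by default; single-pixel objects are
   retained.

The protocol is fully deterministic, and equalization is idempotent on
flat fields (a constant image maps to 128, and 128/128 → 128 again).

## Morphometry

Per object, with pixel-area calibration `s` (µm²/pixel, default 2.971):

- **A** = pixel count × s, exactly.
- **E** = √(λ₁/λ₂) of the eigenvalues of the pixel-coordinate covariance
  matrix — the axis ratio of the ellipse with the same second central
  moments as the region. Degenerate sets use conventions: E = 1 for a
  single pixel, E = pixel count for perfectly collinear pixels (the
  ellipse degenerates to a segment); both are flagged.
- **C** = 1 − 4π·A/P², clamped below at 0 (digitized near-circles can
  push 4πA/P² marginally above 1). C is 0 for a circle and grows toward
  1 for elongated or ragged outlines.
- **SR** = ∛( med(d)·min(d)/max(d)² ), where d ranges over the distances
  from every vertex of the traced boundary polygon to the object
  centroid. SR = 1 exactly when min, median and max coincide (a circle);
  boundary irregularity drives it down. The median of an even count is
  the mean of the two central values.

**Perimeter estimation.** P is the arc length of a sub-pixel contour
traced at the 0.5 iso-level of the binary object (marching squares),
with the polygon vertices smoothed by a short circular moving average
(window 5). The smoothing matters: the raw marching-squares polygon
follows the pixel staircase and overestimates the perimeter of a
digitized disk by ~6%, which alone would push the disk's C to ~0.11;
after smoothing the perimeter error is ~0.3% for radii 10–80 px and the
digitized-disk C stays below 0.01. Contours with fewer than 8 vertices
are left unsmoothed (averaging would collapse a tiny polygon toward its
centroid); one-pixel objects use the conventions A = s, P = 4√s, C = 0,
SR = 1, E = 1. The same smoothed contour vertices supply the SR radius
set, so SR and C describe the same boundary.

E, C and SR are invariant to the calibration constant; A scales linearly
with it. On rasterized ellipses with axes ≥ 20 px, all three shape
descriptors vary by < 3% across orientations.

**Per-slice aggregation.** Total pore fraction = Σ object areas / full
field area (the full observed raster, not the field minus excluded
border objects). Histograms use fixed right-open bins of width 60 µm²
(A), 0.1 (E), 0.02 (C), 0.02 (SR), starting at 0 for A, C, SR and at
1.0 (the lower bound) for E. Group summaries pool objects across slices
within each histology × treatment cell (objects as independent
observations — faithful to how object-level group sizes are usually
reported, though it ignores within-slice clustering; slice-level
statistics are reported alongside for the pore fraction).

## Mechanics

**Fatigue.** Each three-point-bending cycle is summarized by the secant
modulus at its peak-force point via the Euler–Bernoulli formula
E_sec = (F/δ)·L³/(48·I), I = w·h³/12, with the 32 mm span and the slab
cross-section as defaults. The cycle-level formula is a convention (a
linear-fit slope would be an alternative); only the *relative* change
matters for the fatigue criterion, and the percent change
100·(M_first − M_last)/M_first is invariant to force-unit rescaling. A
sample failing mid-protocol contributes its last complete cycle (one
that still reaches the 0.9 mm target deflection within tolerance) and is
flagged.

**Compression.** Engineering stress (force / initial cross-section) and
engineering strain (displacement / initial post-demineralization height)
are used throughout; reported strains of ~50% make no true-strain claim.
Recording starts at the 0.1 N force trigger. Transverse (T) records are
evaluated at the ultimate point, defined as the *global* force maximum
(a single dominant failure event); a record whose maximum sits at the
boundary carries no failure and is rejected. Longitudinal (L) records
never fracture in range and are evaluated at exactly 50% strain, with
the evaluation point linearly interpolated into the series. Work is the
trapezoidal integral of force over displacement (N·mm = mJ) from the
trigger to the evaluation point; for polynomial force curves sampled at
≥ 500 points it matches the closed-form integral within 0.1%.

The **95%-of-max-load point** used by the AE cutoff is the last
rising-branch crossing of 0.95·F_max before the peak (linearly
interpolated), which excludes emission generated by the final fracture
itself; it is invariant to samples appended after the peak.

## Acoustic emission

Hit detection is standard threshold logic, config-exposed because the
exact operationalization varies across laboratories: the threshold is
`threshold_factor` (default 5) × baseline RMS, where the baseline is
estimated from the quietest decile of 0.1 s bins (robust when emission
starts immediately). An event opens at a threshold crossing of |v| and
closes when the signal stays below threshold for `dead_time_s` (default
2 ms); closer bursts merge. Event energy is Σv² over the event's samples
(arbitrary units). Counts and energies are binned every 0.1 s;
cumulative descriptors sum events with onset before the cutoff time, so
cumulative energy is exactly additive over member events and cumulative
values at any cutoff are bounded by the full-record values. With
Gaussian noise, a factor-5 threshold yields well under one false event
per 10 s at 44 kS/s; an event rate above 50/s triggers a warning that
the threshold sits in the noise floor. No band-pass filtering is applied
by default (the physical sensor band is hardware).

## Statistics

- **Paired t-test** on per-sample differences, two-sided; zero-variance
  differences are rejected as degenerate rather than returning an
  infinite statistic.
- **Two-way fixed-effects ANOVA with interaction**, Type III (partial)
  sums of squares under sum-to-zero contrasts — appropriate for the
  unbalanced cell sizes typical of these designs (e.g. 12 vs 16 slices
  per histology). Each effect is computed as the residual-sum-of-squares
  increase when its columns are dropped from the full model, by direct
  least squares on explicit contrast-coded design matrices; Type II is
  available for comparison. Every cell must be occupied with ≥ 2
  observations; an empty cell is reported by name.
- **Tukey–Kramer post-hoc** among the four design cells, using the
  residual mean square of the cell-means model and the harmonic-mean
  standard error √(MSE/2·(1/nᵢ + 1/nⱼ)) for unequal n; adjusted p-values
  come from the studentized-range distribution. Stars mark p < 0.05,
  < 0.02, < 0.01.

Only the reference distributions (t, F, studentized range) come from
scipy; the decompositions themselves are computed in-package, which lets
the test suite compare them against an independent reference
implementation (statsmodels) to 1e−8 and verify the 5% type-I-error
calibration on 2000 null replicates.

## Synthetic data: what it emulates, and what it does not

**Images.** Dark elliptical objects (axis ratio and size configurable)
on a bright background at the study's acquisition geometry (nominally
2048×2048 at 2.971 µm²/pixel; tests use 512 px fields for speed — all
descriptors are resolution-local, so nothing but object count per field
changes). Boundary roughness is a radial perturbation
r(θ) = r₀(θ)·(1 + a·Σₖ aₖcos(kθ+φₖ)) with harmonics k = 3..8 and the aₖ
normalized to unit absolute sum, so the relative perturbation is bounded
by the amplitude and the boundary never self-intersects for a < 0.5 —
this tunes SR smoothly downward (and C upward) without pathologies.
Objects are rasterized by pixel-center inclusion, so the true area is
πab exactly for smooth ellipses and a 720-point quadrature of ½∫r(θ)²dθ
for roughened ones. Illumination is a mean-one low-order polynomial
surface of bounded relative amplitude multiplying the clean image;
salt-and-pepper noise replaces a fixed fraction of pixels with 0 or 255.
Placement is rejection sampling with 1000 attempts per object
(overcrowded specs raise an error); object boundaries keep a minimum
gap (default 5 px, wider than the median footprint) so neighbouring
pores remain resolvable after denoising, and non-border objects stay
≥ 2 px inside the field.

Not emulated: histological texture (lamellae, osteon walls), stain
variability, partial-volume boundary gradients, out-of-focus blur, and
touching/overlapping pores. Passing recovery tests therefore show the
protocol's correctness on well-resolved pores, not segmentation accuracy
on contacting structures or textured backgrounds.

The ground-truth recovery benchmark uses pores with semi-major axes
18–32 px and axis ratios ≤ 1.4 (semi-minor ≳ 13 px). At these sizes the
protocol's residual bias is at the digitization level (the 5×5 median
erodes high-curvature boundary regions by roughly κ px, so thin slivers
with a tip-curvature radius of a few pixels lose several percent of
their area — a real property of the protocol, visible in the generator
by lowering the axis-ratio bound).

**Compression curves.** Stress = scale·strainᵖ (p ≥ 1), with a ≥ 50%
force drop within 2% strain past the failure strain for T, and monotone
hardening through 60% strain for L. Force noise is Gaussian; the L curve
is kept monotone non-decreasing by a running maximum (the monotonicity
is a declared property of the L fixture, and a running maximum is the
simplest noise model that preserves it), and the T failure peak is kept
the unique global maximum. The T strain grid contains the failure strain
exactly so closed-form work checks are grid-bias-free. Records start at
the 0.1 N trigger, like the instrument.

**AE waveforms.** Gaussian baseline noise plus exponentially decaying
sinusoidal bursts (decay 3 ms, frequency 2–8 kHz within the sensor band)
at homogeneous-Poisson onset times; a configurable fraction of bursts
carries energy multiplied by a factor drawn uniformly from 5–15,
mirroring the observed ratio of high-energy emissions to the basic
signal. Burst amplitudes are set so that each burst's noiseless Σv²
equals its ground-truth energy. Not emulated: sensor transfer function,
reflections, overlapping bursts' interference, nonstationary noise.

All generators are bitwise reproducible under a fixed seed
(`numpy.random.default_rng`).

## Numerical choices and degenerate inputs

- Blurred-image floor of 1 before division; equalized output rounded,
  clipped to [0, 255].
- C clamped at 0; SR uses contour vertices only (not interior pixels).
- Eigenvalue ratio guarded: the smaller covariance eigenvalue below
  1e−12× the larger triggers the degenerate-object conventions.
- Work/cutoff interpolations are linear between bracketing samples.
- ANOVA sums of squares are floored at 0 against round-off; a
  zero-residual model yields NaN F and p rather than infinities.
- Tukey comparisons with zero standard error report p = 1 for zero
  difference and p = 0 otherwise.

## Problem sizes used in the shipped tests

Recovery benchmarks run 20 seeded 512×512 fields of 30 pores; the
statistics oracle compares 50 seeded datasets and 2000 null replicates;
AE checks use 3–5 s records at 44 kS/s. These sizes were chosen so the
full suite documents the claims at desk scale while remaining quick to
run; all generators scale to the full 2048 px acquisition geometry
unchanged.

## Known limitations

- Touching pores are not split (no watershed); the protocol pools them,
  as does the fixed-threshold design it implements.
- Object-level ANOVA treats objects as independent observations;
  within-slice correlation is not modeled (no mixed effects).
- Absolute AE energies are arbitrary units; they are comparable within a
  configuration, not across hardware.
- The secant-modulus beam formula ignores shear deformation and local
  indentation at the supports; it is a comparative, not absolute,
  stiffness measure.
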