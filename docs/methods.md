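# Methods

This note documents the models, parameters and design choices behind
`conemap`, including what the synthetic data do and do not establish.

## Spacing estimation in the Fourier domain

A healthy cone mosaic approximates a jittered triangular lattice. Its power
spectrum shows an annulus (Yellott's ring) at the lattice row frequency
f₀ = 1/row-spacing; with rows √3/2 of the inter-cell distance (ICD) apart,
ICD = (2/√3)/f₀, and density follows from triangular packing,
D = 2×10⁶/(√3·s²) cones/mm² for s in µm.

Per ROI the pipeline computes `log(1 + |DFT|²)` after removing the mean and
applying a separable Hann window (suppresses edge ringing), resamples it
onto a pseudopolar grid (90 angle bins over [0°, 180°), side/2 radial bins
over (0, 0.5] cycles/px, bilinear sampling with periodic wrap at Nyquist),
and averages the log power over a 90° wedge centred on the horizontal
frequency axis. The DC bin is excluded by construction and the lowest two
radial bins are excluded from fitting.

Two nested models are fitted to the radial profile:

* single: `b(f) = c·exp(−d·f) + e` — the smooth spectral background;
* dual: the same background joined at a knot frequency f_k to a two-sided
  first-order exponential bump `A·exp(−|f − f_p|/w)` (zero below the
  knot) — background plus a modal peak.

The modal frequency is the arg-max of (dual − single) on a 4096-point grid
over the fitted range, ties resolving to the lowest frequency; confidence
is `clamp(1 − RSS_dual/RSS_single, 0, 1)`, which is ≈0 for profiles the
plain background already explains (flat images, white noise) and →1 when a
peak clearly exists. An estimate whose peak pins to the grid boundary, or
whose optimisation fails, carries confidence 0.

Numerical choices that matter:

* Both fits use a soft-L1 loss (f_scale 0.5). With a plain quadratic loss
  the background fit is dragged through the modal bump and the residual
  peak loses definition; with soft-L1 on the dual fit alone the sharp ring
  tip is treated as an outlier. Soft-L1 on both is the stable combination.
* The bump width is bounded above by 0.04 cycles/px — the maximum
  plausible fractional width of a mosaic's spectral annulus over the
  frequency range of interest. Without the bound the bump absorbs broad
  background mismatch (e.g. the PSF envelope of diffuse scatter) and the
  apex drifts off the ring by up to tens of percent.
* Multi-starts are placed deterministically: candidate peaks from local
  maxima of the (lightly smoothed) single-fit residual, crossed with two
  knot positions and two widths; starts are ranked by initial cost and the
  best four optimised (analytic Jacobians). The whole estimate is
  therefore bit-reproducible without any RNG.
* Tolerances ftol = xtol = gtol = 1e-6, far below the profile noise.

What the estimator reports is the location of the modal spectral peak. On
an ideal lattice this equals the ICD; on a disordered mosaic the mean
nearest-neighbour (NN) distance is a few percent below the lattice
constant (a minimum over ~6 jittered neighbours is biased short), and the
broadened ring plus diffuse halo move the fitted apex down with it, so the
estimate tracks mean NN distance within ~10 % up to 15 % jitter.

## ROI tiling and map assembly

ROI side grows exponentially with eccentricity, 128 px at 1° to 384 px at
10°, clamped outside — fine sampling where density changes fastest,
coarser (more lattice periods) where it is flat. Grid stride is 50 % of the
local ROI size; this overlap fraction is a design choice balancing
coverage against cost. Edge ROIs are shrunk (kept square) until inside the
image; post-shrink sides under 64 px are skipped (too few spectral bins),
as are ROIs more than 25 % NaN (others are mean-filled). Each pixel is the
confidence-weighted mean over covering ROIs — confidence is the only
per-ROI quality signal the method defines. Before a fovea exists, a fixed
256-px bootstrap pass is used.

Angular↔linear unit scaling assumes 291 µm/deg at 24 mm axial length,
scaled linearly by axial length. Both unit systems are supported
end-to-end in the mapping stage; converting angular densities with
(µm/deg)² reproduces linear densities within 1 %.

## Foveal localisation

On the bootstrap density map: binary mask above the 85th percentile of
finite values (percentiles use finite pixels only, linear interpolation);
largest 8-connected component's bounding box; within the box Gaussian
smoothing with σ = 8 px at the map's native scale; contour at the
box-local 85th percentile (marching squares; among multiple closed
contours the one enclosing the maximum-density pixel); convex hull;
least-squares ellipse; the ellipse centre is the foveal estimate. If any
other component exceeds 40 % of the largest's area the case is flagged
ambiguous and a manual rectangular search region must be supplied, inside
which the same smoothing/contour/ellipse steps run. The 40 % comparison is
made over the full-map mask, before the bounding-box restriction.

## Modality fusion

Density/confidence pairs from both modalities are resampled (NaN-aware
bilinear) to the smaller µm/px scale, their radial confidence profiles
(50 µm bins) are compared, and the seam radius is the first sign flip of
the confidence difference that persists ≥3 bins (guarding against noise
micro-crossings). The blend band is the contiguous region around the seam
where |Δconfidence| < 0.2 — absolute units, since confidence is already
normalised to [0, 1]. Inside the band a linear radial ramp mixes the two
datasets; one dataset dominating everywhere uses that dataset with the
other filling coverage gaps; globally similar confidences place the seam
at the most similar radius. The blend is a function of radius only — the
seam is explicitly a radius, not a per-pixel decision. A separately
analysed foveal image enters as the inner dataset of a second, identical
blend.

## Per-participant filtering and cohort aggregation

Filtering removes pixels with confidence below the montage's 5th
percentile and pixels beyond 400 µm whose density exceeds the median
density of the central 400-µm disc. Left eyes are mirrored to right-eye
orientation; maps are co-aligned on their foveal centres (nasal = +x,
superior = −y after alignment), down-sampled 4× by NaN-aware block means,
and stacked: per-pixel overlap count, mean, sample SD (NaN below two
contributors), mean confidence. Cohort summaries exclude pixels with fewer
than 10 participants; the overlap map itself is never masked.

Meridian profiles average 1°-wide axis-aligned strips along each cardinal
meridian (NaN-aware mean across the short axis, 1-px eccentricity bins).
Because strips have finite width, opposite-axis falloff enters near the
centre; horizontal/vertical ordering comparisons are meaningful beyond
roughly the strip half-width. Where foveal cones were unresolved the
central bins show spuriously low density; scanning inward from a 0.5 mm
anchor, bins that fail to increase monotonically toward the centre (2 %
per-step tolerance) are excluded. Both anchor and tolerance are
configurable; the values are this package's choice.

The dual-Cauchy fit shares the two amplitudes between meridians (equal
peaks, PCD = A₁+A₂) with per-meridian widths, by bounded least squares
from a small deterministic start grid, weighted by per-bin confidence
where available. Components are ordered so component 1 is the narrower
(foveal) one. The minimum density is the fitted model's minimum over the
fitted eccentricity range — the paper-level definition is not operational,
and the model minimum is the least arbitrary reading. Total cones
accumulate over annuli of width ≈7 µm: each annulus is split into
horizontal wedges (|polar angle| ≤ 45° from the horizontal axis, both
sides) and vertical wedges, wedge mean density × wedge area (mm²), summed
and cumulated; the fitted model substitutes for excluded (NaN) pixels.
Pearson correlations between summary columns carry Fisher-z 95 % CIs.

## Synthetic mosaics

The generator builds a uniform triangular lattice at the profile's peak
density, warps it radially so the enclosed-count function matches the
bivariate dual-Cauchy target exactly (equal-measure warp, so local count
density is exact by construction), applies an area-preserving anisotropic
stretch for the horizontal/vertical width ratio, then jitters each point
with Gaussian noise whose 2-D rms displacement is `jitter_frac` × local
spacing. A hard-core repair then pushes apart any pair closer than 0.8× the
local spacing: cone inner segments are contact-packed, with diameters
≈0.8× the centre-to-centre spacing across the retina, so closer centres
would mean overlapping cells. Rendering splats sub-pixel impulses
(bilinear) with per-cone brightness jitter and blurs each cone to the
larger of its emitter width and the optical PSF: the confocal spot is the
waveguided outer-segment reflectance, an extended source whose
Gaussian-equivalent σ is ≈0.18× the local spacing (a diameter of about
0.4× the spacing — half the inner-segment width), so spots scale with the
mosaic everywhere rather than rendering as PSF-width points. The result
is used directly (confocal) or as its horizontal gradient
(split-detection relief), plus additive Gaussian noise.

Default conditions: profile widths follow adult human cone topography
(γ₁ ≈ 0.10 mm — density near half-peak by 0.1 mm — and γ₂ ≈ 1.05 mm,
giving the observed ~8× falloff of the shallow component between 1 and
3 mm), axial lengths N(24.34, 1.35) mm clipped to [22.11, 27.52] mm, eye
laterality 50/50. The `easy` preset (default) draws peak densities
lognormally around 60,000 ± 15,000 cones/mm² at 1 µm/px with a 1 µm PSF —
a mosaic whose fovea is resolvable (≈4.4 px spacing), for validating
estimator accuracy. The `hard` preset uses the adult human PCD
distribution (152,906 ± 53,209 cones/mm²) at 1.1 µm/px, putting foveal
spacing at ≈2.5 px — at the resolution limit, reproducing the
unresolvable-fovea regime. The `rods` preset sprinkles smaller, dimmer
rod-like spots between cones beyond a 250 µm rod-free zone, an adversarial
fixture for the single-peak spectral model. Default montages are 2×2
overlapping tiles of 640 px (≈1.15×1.15 mm): large enough that the top-15 %
density region used for foveal localisation is a single central blob well
clear of noisy edge-of-montage estimates, and small enough that a 10-eye
cohort runs end-to-end in minutes on one CPU. Real montages are several
times larger; nothing in the pipeline depends on this size.

What the synthetic data do not emulate: optical aberrations and their
spatial variation, eye-motion and desinusoiding artefacts, vasculature
shadows, registration seams between montage pieces, and the correlated
(non-independent) disorder of real mosaics. Passing tests establish that
the estimator recovers known geometry under controlled disorder and noise,
not that it is robust to every real-world artefact.

## Known limitations

* The spectral model fits a single modal peak; resolved rods add a second
  ring that can capture the fit (the `rods` preset reproduces this known
  outlier mechanism; handling it is future work).
* Near the montage edge, shrunk ROIs and weak rings make estimates noisy;
  the confidence weighting and the outlier filter mitigate but do not
  remove this, exactly as reflected in lower edge confidence.
* Peak-density localisation assumes the fovea is the global density peak
  of the map; fields so small that peripheral noise reaches the
  85th-percentile threshold can trigger the (intended) ambiguity flag.
* Meridian strips follow the cardinal axes of the aligned frame, not any
  participant-specific acquisition rotation.
* At the default synthetic scale (1 µm/px) the smallest ROI (128 px) is
  comparable to the foveal peak's half-width (≈0.1 mm), so mapped foveal
  densities are flattened by ROI averaging: meridian fits on such maps
  underestimate the generator's point peak density by tens of percent
  even when the map's overall relative RMS error is below 10 %. Finer
  pixel scales (hence smaller physical ROIs) reduce this, at a
  proportional compute cost.
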