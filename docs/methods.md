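# Methods

This note documents the models, estimators and numerical choices behind
`ringcurv`, and what the synthetic-data validation does and does not show.

## The measurement problem

A contracting actomyosin ring appears in a confocal z-stack as a closed,
sub-resolution tube, often tilted against the optical axis, with micron-scale
actin/myosin bundles attached to and expelled from it late in contraction.
The pipeline extracts, per time point: the ring centreline (skeleton), its
perimeter and diameter, the local curvature along it, the attached bundles
with their origin curvature class, and fluorescence-intensity bookkeeping
that attributes the ring's intensity loss to expelled bundles.

## Segmentation

1. **Denoising.** Non-local means, plane by plane; the filter strength is
   0.8× the wavelet-estimated noise sd of each plane. Planes whose estimated
   noise is below 0.2% of the image peak pass through unchanged, so clean
   input is returned identically — important for validation runs without
   noise.
2. **Ring plane.** The plane through the Otsu-foreground centroid whose
   normal is the smallest principal axis of the foreground coordinate
   covariance (in physical units). A middle-to-smallest principal-sd ratio
   below 1.2 signals a degenerate (near-isotropic) object. A manual normal
   can always be supplied instead.
3. **Projection.** Maximum-intensity projection along the fitted normal on
   an isotropic grid at the lateral pixel size (trilinear resampling); a
   `sum` mode exists for intensity bookkeeping, which uses plain z-sum
   projections so that ROI coordinates match the unrotated frame.
4. **Thresholding.** Otsu's method on a 256-bin histogram, implemented
   directly so its contract is fixed: the threshold is the lowest bin index
   maximising the between-class variance (ties → lowest), and foreground is
   *strictly above* the threshold. A property test checks equivalence with
   exhaustive search; skimage's implementation serves as an independent
   cross-check.
5. **Bundle inclusion (hysteresis).** Expelled bundles carry roughly a tenth
   of the ring's fluorescence per unit length, so a single global Otsu
   threshold keeps the ring but loses bundles. The mask therefore keeps
   every pixel above 10% of the Otsu threshold that is 8-connected to the
   Otsu foreground; disconnected noise blobs never join. For very small
   rings this permissive mask can flood the centre hole, in which case the
   plain Otsu mask is used instead. A binary closing (disk radius 1)
   bridges 1-pixel noise breaks.
6. **Skeleton tracing.** `skimage` thinning; the 8-connected pixel graph
   (edge weights 1 and √2 px) is traced with networkx. The ring is the
   longest simple cycle (the 2-core of the graph); cycles shorter than 8 px
   are skeletonization artifacts and rejected. Branches are maximal paths
   from cycle nodes to skeleton endpoints, pruned below `prune_len`
   (default 0.4 µm — skeleton spurs are a few pixels, real bundles are
   micron-scale). The cycle is ordered counter-clockwise (positive shoelace
   area) starting at its topmost-then-leftmost point.
7. **Sub-pixel refinement.** Raw pixel-centre cycles overestimate arc length
   by ≈5% (diagonal jaggedness), so coordinates are smoothed with a 5-point
   circular moving average; each cycle point is then moved to the intensity
   centroid along its local normal (±0.35 µm window, shift clamped to
   0.15 µm), which removes the inward bias of thinned small rings. Branch
   tips are extended halfway to the mask boundary, compensating the
   half-width erosion of thinning at open tube ends; walks longer than 8 px
   indicate the "tip" sits inside a wide blob and are not applied.

Digital circles of radius ≥ 20 px recover 2πR within 0.5% after refinement;
the acceptance band is 5%.

## Local curvature

The cycle is resampled uniformly (step 0.2 µm). For each POI the two
neighbours sit at ± one arc offset along the cycle (wrapping); the curvature
is that of the circumscribed circle of the triple,

    κ = 4·|area| / (|p₁p₂|·|p₂p₃|·|p₁p₃|),

exact for points on a circle (tested to 1e-9) and 0 for collinear points.
κ is unsigned; the smoothed profile is a centred circular moving average
over 10 resampled points (2 µm), which conserves the mean to machine
precision.

**Arc offset.** The offset convention in the source workflow is ambiguous
(a 10-pixel-point count versus a 2 µm distance, and per-side versus total);
we keep 2.0 µm per side as the default, specified in physical arc length on
the resampled cycle so the estimator is resolution-independent. High-level
helpers cap the effective offset at 20% of the perimeter so that small
rings remain measurable (for a circle the circumcircle estimate is exact at
any offset, so the cap costs nothing). For compressed rings the offset must
resolve the smallest feature: with 2 µm flats, an offset of 0.6 µm and a
5-point smoothing window keep the flat-region estimate below 0.05 µm⁻¹
while the caps read 2/h within a few percent; the 2 µm default would blur
the flats into the caps. Analyses of stadium-shaped rings therefore use
0.6 µm / 5 points; both parameters are plain arguments.

**Classification and compression.** A point is *curved* iff κ strictly
exceeds the mean κ (factor configurable). A profile whose κ spread is below
30% of its mean is treated as an uncompressed circle (compression factor
h/(perimeter/π) ≈ 1 with h the maximal extent); otherwise the circular runs
of the labels must form two flat and two curved runs (runs below 5% of the
perimeter are ignored), from which d = mean flat-run arc length, the flat
direction is the principal axis of the flat-run points (each run centred on
its own mean — the two flats are parallel but offset), and h = the extent
perpendicular to it. For the d=2, h=2 µm stadium the closed form gives
factor h/(P/π) = 2π/(4+2π) ≈ 0.611; the pipeline recovers it within 2%.

## Kinetics

Perimeter = closed polygon length of the cycle (µm); diameter =
perimeter/π. All rates are |slope| of an ordinary-least-squares line versus
time with a t-based 95% CI — OLS to match the standard linear-model fit of
such data; at least 3 frames are required. Bundle travel is the distance of
the tip from the attachment point frozen at first detection; tracks with
frame gaps are split with a warning.

## Bundles and expulsion onset

A bundle record is a branch of arc length ≥ `min_len` (default 0.5 µm, the
detectability floor — separate from skeleton spur pruning). Its origin is
the nearest resampled profile point to the attachment; the origin keeps the
label from first detection. Onset is the first frame with a detected
bundle; because a bundle must grow to ≈0.7–0.9 µm before the skeleton
resolves it, the report also carries a latency-corrected onset diameter:
the longest-bundle length is regressed over the frames after detection,
extrapolated back to zero length, and the ring-diameter trend evaluated at
that earlier time. On synthetic time-lapses with onset programmed at 2.0 µm
the corrected estimate recovers 1.96–1.99 µm where the raw first-detection
diameter reads ≈1.78 µm.

## Intensity bookkeeping

Sum-intensity z-projections only (max projections are for geometry). A
scalar background per frame is the mean over background pixels (everything
below median + 3 robust sigma, dilated, is excluded); the mean over many
pure-background pixels is used rather than the full-frame median because a
median error of even 0.3% of the offset multiplies across the large ROI
areas. The ring ROI is the band within `width_px` of the cycle. With
attached bundles two regimes apply:

- *thin-annulus* (band width < 0.8× ring radius): band sectors within one
  band-width of a branch are contaminated by the bundle crossing; the sum
  is the clean-sector mean scaled to the full band area.
- *disc-like* (small late-stage rings): pixels go to the nearer structure
  (cycle versus branch), with branch paths trimmed to beyond 0.35 µm
  (≈2× the effective tube sigma) of the cycle so the ring keeps its width
  near attachments.

The box ROI is the bounding box of cycle ∪ branches plus a margin.
Photobleaching is corrected by a log-linear mono-exponential fit; in
expulsion-fraction runs the fit uses only the pre-expulsion frames, where
the true total intensity is conserved, so real intensity loss is not
mistaken for bleaching. The expulsion fraction is
Actin^Bundle / (Actin^Early ring − Actin^Late ring) with
Actin^Bundle = box − ring at the late frame. End-to-end this recovers a
programmed fraction of 0.68 within 3% noiselessly and within 10% (ensemble
mean) at the default noise level.

## Width profiling

The selected path is resampled at one-pixel arc steps; rows sample the
local perpendicular (bilinear). One transverse profile is taken per 200 nm
(the spacing used for such measurements); each is fitted to
a·exp(−(x−µ)²/2σ²) + b by least squares, initialised from the peak and the
second moment, and FWHM = 2√(2 ln 2)·σ. The baseline term is on by default
(reconstructed images have nonzero background); a baseline-free mode
exists. Fits whose σ exceeds the profile extent are rejected. The synthetic
filament generator renders the profile window to ±8σ so the baseline is
identifiable; at an SNR of 10 the recovered FWHM is unbiased within 1% and
77 nm versus 52 nm populations separate cleanly.

## Synthetic data: what it emulates, and what it does not

The generator renders centrelines (circle/stadium, optional tilt about x)
as Gaussian tubes: the intensity field is the line integral of an
anisotropic Gaussian kernel, the convolution of the sub-resolution physical
cross-section (σ 0.1 µm, matching measured ring widths) with a Gaussian PSF
(defaults σ 0.1 µm lateral / 0.3 µm axial — plausible spinning-disk values,
configurable, as no measured PSF is available). Kernels are unit-integral,
so total intensity is exactly the bookkeeping total. Noise is
scaled-photon (Poisson) plus Gaussian read noise over a camera offset; all
randomness flows through one seeded generator per call, and identical
spec + seed gives bit-identical stacks.

Time-lapses contract the perimeter linearly; stadiums shed flat length and
height at the measured ≈2.3:1 anisotropy until the flats are exhausted. The
ring conserves its total fluorescence until the onset diameter (density
rises as it contracts), then sheds at frozen linear density, a fraction
`expelled_fraction` of the loss reappearing in bundles — with fraction 1,
no noise and no bleaching, the total image intensity is conserved to 1e-6.
Bundles start elongating at the exact onset-crossing time, at fixed
per-length brightness, planted with a configurable curved-origin
probability and a 1.2 µm minimum arc separation plus a 0.5 µm minimum
segment distance (closer pairs merge in the mask and cannot be counted as
individual bundles by any skeleton-based detector).

Default validation conditions: 80 nm pixels, 0.2 µm z-step, contraction
1.26 µm/min, onset 2.0 µm, elongation 2.19 µm/min, expelled fraction 0.68,
read noise 2% of a.u. scale with ~4% peak shot noise. Recovery ensembles use
20 seeds; time-lapses start at 2.8 µm diameter with 16 frames at 0.25 min
so runs stay lightweight while spanning several pre- and post-onset frames.

Not emulated: membrane/cytoplasm background structure, bundle bending or
rotation, single-molecule blinking, depth-dependent PSF aberrations, or any
mechanical force balance. Passing recovery tests therefore demonstrates
that the estimators are correct and unbiased under the stated imaging
model, not that they are robust to every artifact of real microscopy.

## Degenerate inputs and tie-breaks

Constant images are unthresholdable (error); coincident points in the
circle fit, offsets beyond half the perimeter, open skeletons, series with
fewer than 3 frames, and rings that never lose intensity all raise typed
errors rather than returning silent defaults. Otsu ties take the lowest
threshold; the cycle start point ties break topmost-then-leftmost; bundles
attach to the nearest profile point. Frames whose ring has disintegrated
(no resolvable cycle) are recorded as missing in time-lapse series and
excluded from regressions.
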