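# ringcurv

Quantification of contracting actomyosin rings in fluorescence microscopy.

During cytokinesis, the actomyosin ring constricts and — as live imaging of
fission-yeast spheroplasts shows — sheds micron-scale actin/myosin bundles
from its most highly curved regions. `ringcurv` implements the image-analysis
pipeline needed to quantify this process from confocal z-stacks and
time-lapses:

- **Segmentation** — non-local-means denoising, automatic ring-plane fitting
  and maximum-intensity projection along the ring normal, Otsu
  auto-thresholding, skeletonization, and tracing of the skeleton pixel graph
  into one closed ring cycle plus open branch paths (candidate bundles).
- **Local curvature** — at each point of interest (POI) on the resampled
  ring, two neighbours are taken at a fixed arc offset to either side along
  the skeleton; the circle through the three points has radius *R* and the
  local curvature is κ = 1/*R* (µm⁻¹), smoothed with a circular moving
  average. A compressed "stadium" ring (two flat segments of length *d*
  joined by semicircular caps of height *h*) has cap curvature 2/*h*, flat
  curvature 0, and compression factor *h*/(perimeter/π).
- **Kinetics** — ring perimeter as total skeleton length, diameter =
  perimeter/π, and contraction / flat-shortening / bundle-travel rates as
  |OLS slope| versus time with 95% confidence intervals.
- **Bundles** — branch detection, counts and lengths, curved-versus-flat
  origin classification (κ > mean κ), and expulsion-onset statistics.
- **Intensity bookkeeping** — ring-line and bounding-box ROI sums,
  mono-exponential photobleaching correction and control ratios, and the
  expulsion fraction Actin^Bundle / (Actin^Early ring − Actin^Late ring).
- **Width profiling** — straighten a ring or bundle from a reconstructed
  super-resolution image, draw perpendicular profiles every 200 nm, fit each
  to a Gaussian and report FWHM = 2√(2 ln 2)·σ.
- **Synthetic data** — a first-class generator of ring stacks and
  time-lapses (circle and stadium geometry, attached elongating bundles, PSF
  blur, shot/read noise, photobleaching) with complete ground truth, used to
  validate every stage end to end.

## Worked example

```python
import ringcurv as rc

# a contracting 5.5 µm ring that starts expelling bundles below 2 µm
stack, truth = rc.generate_timelapse(
    rc.circle(5.5 / 2), contraction_rate=1.26, bundle_onset_diameter=2.0,
    n_frames=12, dt=1.0, expelled_fraction=0.68)

from ringcurv.pipeline import analyze_timelapse, measure_expulsion_fraction
res = analyze_timelapse(stack)
rate = res["contraction_rate"]
onset = res["onset"]
frac = measure_expulsion_fraction(stack)["fraction"]
print(f"contraction rate {rate.rate:.2f} um/min "
      f"[95% CI {rate.ci_low:.2f}, {rate.ci_high:.2f}]")
print(f"onset diameter {onset.onset_diameter:.2f} um "
      f"(latency-corrected {onset.extrapolated_onset_diameter:.2f} um)")
print(f"expelled intensity fraction {frac:.2f}")
```

prints (noiseless defaults):

```
contraction rate 1.27 um/min [95% CI 1.26, 1.27]
onset diameter 1.87 um (latency-corrected 1.97 um)
expelled intensity fraction 0.68
```

The recovered contraction rate matches the programmed 1.26 µm/min within
1%; the latency-corrected onset diameter recovers the programmed 2.0 µm
onset (a bundle must grow to a detectable length before it first appears,
so the uncorrected first-detection diameter lags); and the intensity
bookkeeping recovers the programmed 68% expulsion fraction.

The same stages are exposed on the command line:

```bash
ringcurv simulate --geometry stadium --d 2 --h 2 --out ring.tiff
ringcurv segment --in ring.tiff --out skel.csv
ringcurv curvature --skeleton skel.csv --arc-offset 0.6 --window 5 --out curv.csv
ringcurv run --out results/ ring.tiff
```

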