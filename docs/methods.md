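# Methods

## Coordinate conventions

Images are `(channel, row, column)` arrays. The column axis is the
anterior–posterior (A/P) embryonic axis with anterior at low x; the row axis
is dorsal–ventral (D-V), with the ventral midline running horizontally
through the image center (ventral-view projection). Pixel coordinates are
0-based `(row=y, col=x)`. The survival model works in segment-width units
(boundary *i* at x = *i*), independent of pixel scale.

## Synthetic embryos

The generator emulates the statistical structure the analysis assumes, not
microscopy optics (no point-spread function, no 3D geometry, no
photorealism). One `SyntheticEmbryoSpec` fixes everything, including the
seed; identical specs give bit-identical images and ground truth.

- **Landmark channel**: vertical stripes of configurable width (default 6 px)
  and spacing (default 60 px) at 14 boundary positions — the full trunk
  complement of En stripes. An optional sinusoidal wiggle
  (`stripe_wiggle_amplitude_px`) curves the stripes so that nearest-boundary
  distance mapping is exercised as a genuinely 2D problem, as with real,
  curved stripes.
- **Event channel**: `event_count` disks (default radius 3 px). An event's
  y is uniform over the image; events landing inside the midline band
  (central `midline_fraction` of the D-V extent, default 20%) are flagged
  `is_midline` and placed uniformly in x — positive test material for the
  exclusion step. All other events pick a segment uniformly and an
  intra-segment relative position from the configured law (`uniform` or
  `beta(α, β)`; default beta(2, 2), the mid-segment-enriched shape observed
  for epidermal apoptosis). Ground truth records exact centers, relative
  positions, segment indices and midline flags.
- **Signal channel**: a segment-warped cosine — the phase advances by 2π
  between consecutive boundaries — so its smooth peaks sit exactly on the
  boundaries regardless of local segment width. Baseline 150, amplitude 100.
- **Noise**: additive Gaussian, clipped at zero, default SD 20 (10% of the
  stripe intensity of 200); the simplest model sufficient to stress
  thresholding. Real-data nuisances it does not emulate: uneven
  illumination, background autofluorescence gradients, out-of-focus light,
  stain variability between embryos. Passing tests therefore demonstrate the
  correctness of the computation, not robustness to arbitrary acquisition
  artifacts — for real images the thresholds are explicit parameters.

A guard band: event y-coordinates within 0.75 px of the midline-band edge
are resampled. Detected centroids are rounded to integer pixels, so an event
hugging the band edge could otherwise change classification between the
generator's label and the pipeline's exclusion test; the guard makes midline
classification exact without altering the band geometry.

1D profile samples are generated directly (landmark trace with Gaussian
peaks at per-sample jittered boundary positions; the same warped-cosine
signal peaked at the jittered positions; optionally a perfectly
anticorrelated reporter `2·baseline − signal`). The jitter (default SD 2 px,
clipped to ±35% of the stripe spacing to preserve ordering) emulates the
segment-width variation between samples that registration must remove.

## Segmentation

Stripes: global intensity threshold (default half the stripe intensity) →
8-connected components → area filter → labels ordered by median column.
Events: the same, with components reduced to centroids rounded to the
nearest pixel; centroid is used rather than a brightest-pixel rule because it
is stable under noise. Default `min_area_px` 4 rejects single-pixel specks;
an optional `max_area_px` rejects fused doublets (a rendered radius-3 disk
occupies 26–32 px, so a cap of 35 cleanly separates singles from fusions).

Skeletonization uses morphological thinning (`skimage.morphology.thin`),
which reduces a symmetric vertical bar exactly to its center column, followed
by pruning: if any skeleton pixel has ≥3 neighbors, the skeleton is reduced
to its longest geodesic path (double breadth-first search between the two
mutually farthest pixels). A shortest 8-connected path contains no chords, so
the result is provably branch-free; removal of any side piece longer than
`prune_len_px` (default 10) is logged as a possible genuine fork.
Components thinning to fewer than 2 pixels are dropped with a warning.
Thinning is idempotent on single-pixel lines, so re-skeletonizing a skeleton
is a no-op.

## Event mapping

Boundaries must number ≥2 and be separated by ≥1 px in median x (else the
order is ambiguous and mapping refuses to guess). An event's flanking pair is
the consecutive boundary pair whose median x brackets the event's x; its
distances are exact nearest-pixel Euclidean distances to those two full
skeletons, computed with a k-d tree (k = 1) and verified in the tests against
an exhaustive scan over every skeleton pixel. `rel_pos = 100·d_ant/(d_ant +
d_post)` reduces to the exact linear coordinate for straight parallel
boundaries and stays in [0, 100] for curved ones. Events at or beyond the
first/last boundary are flagged unmappable and excluded from tabulation; an
event exactly on a boundary skeleton maps to position 0 of the segment
posterior to it. Distances are planar Euclidean in the projection plane (not
geodesic on the embryo surface).

The midline band is centered on mid-y by default (overridable via explicit
D-V limits) and uses a strict inequality, mirroring the generator. The
histogram uses 10 bins on [0, 100] by default (configurable), half-open with
the last bin closed. Per-embryo counts are converted to fractions of that
embryo's retained events before the cross-embryo mean and SD, so embryos
with different apoptotic loads weigh equally; raw-count averaging is
available (`normalize=False`). Conservation — retained + midline-excluded +
unmappable = detected — is asserted on every pipeline run.

Group comparisons of mean intensities use the classical unpaired
equal-variance two-sample t test (two-sided), returning group means and SDs
alongside t and p.

## Profile registration

ROI traces are column means over the ROI rows. Landmark peaks are detected on
a lightly smoothed trace (moving average, default 5 px window) as local
maxima with a prominence floor and a minimum separation (defaults: a quarter
of the stripe intensity; half the stripe spacing); fewer than two peaks is a
registration failure. Each inter-peak interval is linearly resampled onto 50
evenly spaced, left-closed positions (a segment's right peak is bin 0 of the
next segment), giving `n_segments × 50` bins; trace outside [first, last]
peak is discarded. Linear interpolation is the minimal assumption for
"evenly spaced intervals"; registration is invariant to uniform axis
stretching and linear in the trace values. Averaging requires ≥2 samples
(SEM is undefined for one) and reports per-bin mean and `sd(ddof=1)/√n`.
Optional per-sample intensity normalization is deliberately not applied by
default. In batch runs, per-sample registration failures are logged and
skipped; samples spanning different peak counts are cropped to the common
segment count before averaging.

## Survival model

`S(x) = Σ_s A_s·exp(−|x − p_s|/λ_s)` — symmetric exponential decay is the
minimal spread model for a locally produced, dispersing prosurvival ligand.
Per boundary *i* (at x = *i*): a Vein-like source at *i* − 0.1 (in segment
*i*−1) and a Rhomboid/Spitz-like source at *i* + 0.1 (in segment *i*), all
with equal amplitude — the relative strength of the two classes is unknown,
so the defaults keep them symmetric and exposed as parameters.

Calibration (fixed defaults: A = 1, λ = 0.15 segment widths, threshold
0.06) was chosen analytically to realize the qualitative regime the biology
specifies, which is the testable object:

- wild-type mid-segment signal ≈ 2e^(−0.4/λ) + 2e^(−0.6/λ) ≈ 0.18 > 0.06 —
  no death in normally patterned segments;
- either ligand class alone ≈ 0.07–0.09 > 0.06 — single ligand-class
  mutants survive (redundancy), while the double mutant equals the *EGFR*
  null;
- a segment stripped of both its sources dips to ≈ 0.04 < 0.06 at
  mid-segment — one death band per mispatterned segment.

With 14 boundaries the interior segments number 13; the pair-rule-dependent
(alternate) segments are the even-indexed ones, 7 in total, so the *ftz*
scenario yields exactly 7 bands. The *ptc* scenario adds one mid-segment
Rhomboid-like source per segment; since sources only ever add signal,
sub-threshold area is monotone under source addition/removal, and *ptc* can
never exceed the wild-type band count. The landscape is static: timing of
death onset is not modeled. The grid resolution is 0.01 segment widths;
bands are maximal contiguous sub-threshold runs reported as grid-coordinate
intervals.

## Pipeline and reproducibility

One top-level seed is fanned out to per-embryo streams via
`numpy.random.SeedSequence` spawning; re-running a configuration produces
byte-identical CSVs. Summaries embed the full configuration echo. Test and
acceptance problem sizes (6–7-stripe embryos for unit tests; 20 embryos ×
500 events for end-to-end distribution recovery; 20 curved-stripe embryos ×
80 events for the exhaustive-distance check) were chosen so the full suite
runs in well under a minute while keeping sampling error far below the
tolerances being asserted.

## Known limitations

- Global thresholding stands in for interactive pixel classification; images
  with strong illumination gradients need per-image thresholds or external
  preprocessing.
- Median-x bracketing of flanking boundaries assumes stripes do not overlap
  in x more than half a segment; pathological curvature would need
  per-segment masks.
- Overlapping apoptotic figures fuse into one component; the area cap can
  reject fusions but does not split them (no watershed separation).
- The survival model is phenomenological: it reproduces the spatial regime,
  not absolute signaling levels, kinetics, or ligand identity.
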