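# apomap

Spatial quantification of apoptosis and signaling in the segmented embryonic
epidermis of *Drosophila*.

During segmentation, mispatterning triggers bands of apoptosis in the
embryonic epidermis. Quantifying *where* cells die within a segment requires a
coordinate system that is comparable across segments and embryos. `apomap`
implements that analysis as a reusable, tested pipeline for anyone working
with projected 2D micrographs of striped epithelia:

- **Segmental event mapping.** Engrailed (En) stripes — the periodic landmark
  channel — are thresholded, reduced to single-pixel skeletons, and ordered
  along the anterior–posterior (A/P) axis. Each punctate event (a cleaved
  Dcp1-positive apoptotic cell) is reduced to a centroid and mapped to its
  flanking boundary pair; with `d_ant` and `d_post` the Euclidean distances to
  the nearest pixel of the anterior and posterior boundary skeleton, its
  position is expressed as a percentage of segment width,

  ```
  rel_pos = 100 · d_ant / (d_ant + d_post)
  ```

  Events within a band around the ventral midline (default 20% of the
  dorsal–ventral extent) are excluded, and per-embryo positions are tabulated
  into a frequency histogram with a cross-embryo mean and SD.

- **Landmark-registered intensity profiles.** Rectangular ROIs (fixed 75 µm
  height) spanning several contiguous segments are collapsed to per-channel
  A/P traces; each trace is registered to its En peaks by resampling every
  inter-peak interval onto 50 evenly spaced bins, normalizing away
  segment-width variation; registered samples are averaged per bin with SEM.

- **Threshold-survival model.** Each boundary is flanked by two prosurvival
  EGFR-ligand sources (Vein-like and Rhomboid/Spitz-like) spreading with
  symmetric exponential decay, `S(x) = Σ A·exp(−|x − p|/λ)`. Cells survive
  where `S` exceeds a survival threshold; sub-threshold regions derepress the
  proapoptotic gene *hid* and die. Genotype scenario presets edit the source
  list: a pair-rule (*ftz*) mutant deletes the sources of alternate segments,
  *ptc* adds ectopic mid-segment sources, an *EGFR* null removes everything,
  and single/double ligand-class mutants drop one or both classes.

- **Synthetic embryos.** A generator renders multi-channel embryos (striped
  landmark channel with optional curvature, punctate events with a
  configurable intra-segment position distribution, periodic signal channel,
  midline band, Gaussian noise) together with exact ground truth, so every
  stage of the pipeline is testable without microscopy data.

## Worked example

Simulate the *ftz* scenario on the standard 14-boundary trunk:

```bash
$ apomap simulate --scenario ftz --segments 14
{
  "scenario": "ftz",
  "n_boundaries": 14,
  "threshold": 0.06,
  "band_count": 7,
  "bands": [[0.34, 0.66], [2.34, 2.66], ...],
  "subthreshold_fraction": 0.1776,
  "subthreshold_area_segments": 2.31
}
```

Deleting the ligand sources of alternate segments leaves exactly **7
sub-threshold bands** (one per mispatterned segment, each ≈0.3 segment widths
wide, centered mid-segment) — the alternating death pattern of pair-rule
mutants — while the wild-type configuration (`--scenario wildtype`) yields 0
bands.

Map apoptotic events on a batch of five synthetic embryos:

```bash
$ apomap map --n-embryos 5 --seed 1 --out out/
{
  "n_embryos": 5,
  "events_detected": 942,
  "events_retained": 743,
  "events_midline_excluded": 199,
  "events_unmappable": 0
}
```

The counts always conserve (retained + midline-excluded + unmappable =
detected). `out/` receives `events.csv` (per-event coordinates, boundary
distances, `rel_pos_pct`, segment index, exclusion flags), `histogram.csv`
(mean ± SD frequency per position bin) and `summary.json` (counts plus the
full configuration echo). With the default mid-segment-enriched event
distribution, the histogram peaks in the central bins and falls toward the
segment boundaries.

Other subcommands: `apomap generate` (synthetic TIFFs + ground-truth JSON),
`apomap profile` (registered intensity profiles with SEM), `apomap run-all`.
All parameters can come from a YAML config; CLI flags override it. The same
functionality is available as a library (`apomap.segmentation`,
`apomap.mapping`, `apomap.profiles`, `apomap.model`, `apomap.pipeline`).

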