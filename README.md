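# myolapse

Quantitative time-lapse morphometry of remodelling muscles.

During *Drosophila* metamorphosis, the persistent dorsal internal oblique
muscles (DIOMs) of the pupal abdomen are not destroyed but *remodelled*: they
atrophy roughly threefold over the first two days after head eversion (HE),
then regrow during the second half of pupation, while their myonuclei migrate
from an even basal distribution into central clusters and finally into a
single row along the fibre midline. Time-lapse confocal imaging of pupae
expressing a cytoplasmic and a nuclear fluorescent reporter, combined with
targeted RNAi, turns this into a quantitative genetic assay for atrophy and
hypertrophy pathways (TOR/Rheb/Tsc, autophagy, *yorkie*, Cathepsin L).

`myolapse` is a tested, reusable implementation of the analysis that such
experiments need, for developmental biologists and bioimage analysts:

* **morphometry** — shape features of manually annotated muscle ROIs on
  maximum-intensity projections. A closed contour polygon gives the area
  (shoelace, μm²); an open medial-axis (MA) polyline inside it gives the
  length (arc length, μm); the *mean diameter* is the average of orthogonal
  chords sampled every 5 px along the MA, each chord running to the nearest
  contour intersection on both sides.
* **imaging** — multi-page TIFF time-lapse I/O, stack concatenation,
  maximum-intensity projection, and orthogonal reslices of z-stacks with
  half-maximum depth profiles.
* **store** — alignment of all series to head eversion as time zero
  (signed "hours aHE"), the canonical 13-point analysis grid
  (5, 10, 15, 20, 25, 30, 40, 50, 60, 70, 80, 90, 100 h aHE), and an embedded
  SQLite store of experiments, ROIs, features and nuclei.
* **stats** — per-timepoint medians with 25/75 percentiles, per-muscle
  normalization to a reference time, explicit-direction fold changes, and a
  Mann–Whitney U test with a documented contract: midranks for ties, exact
  null distribution for small tie-free samples, minimum group size 5, p
  clipped to [0.0001, 1], left/right/two-sided tails.
* **nuclei** — nuclear centroid detection in the second channel (Otsu +
  connected components), decomposition into axial/lateral MA coordinates, and
  rule-based classification of the distribution patterns (uniform basal,
  central cluster, midline row, scattered) with phase-transition timelines.
* **synthetic** — a seeded two-channel movie generator with exact ground
  truth. Muscles are capsules (stadium shapes), so area, length and diameter
  have closed form (`area = L·D + π(D/2)²`); genotype presets pin the control
  median trajectory to the reference values (17 925 → 6 038 → 15 719 μm²
  area, 84.4 → 24.4 μm diameter at +5/+50/+100 h) and encode the perturbation
  phenotypes. Every downstream stage is testable without any image download.

## Worked example

Simulate a control and a *TOR*-knockdown cohort (6 pupae each, 384×384
fast profile covering the 13 canonical time points), measure every ROI with
the chord-profile morphometry, and compare areas per grid time with
right-tailed MWU tests (control > TOR):

```python
from myolapse.pipeline import RunConfig, run_all

cfg = RunConfig(preset_a="control", preset_b="TOR_shRNA", n_samples=6,
                feature="area_um2", tail="right", seed=5, outdir="demo_run")
summary = run_all(cfg)
print(summary["fold_changes"])
print(summary["median_area_anchors"])
print(summary["significant_grid_times"])
print(summary["phase_timelines"]["control_000/DIOM 3L"])
```

prints

```
{'area_decline_5_to_50': 2.967, 'area_regrowth_50_to_100': 2.603}
{'5': 17909.733, '50': 6036.807, '100': 15711.426}
[15, 20, 25, 30, 40, 50, 60, 70, 80, 90, 100]
[[5.0, 'uniform'], [40.0, 'central_cluster'], [60.0, 'midline_row']]
```

Reading: the measured control cohort atrophies 2.97-fold from +5 h to +50 h
and regrows 2.60-fold by +100 h (medians 17 910 → 6 037 → 15 711 μm²,
recovering the preset anchors to ≈0.1 %); TOR-deficient muscles are
significantly smaller at every grid time from +15 h on (p < 0.05); and the
control myonuclei pass from uniform through a central cluster (+40 h) to the
midline row (+60 h). `demo_run/` also contains the per-ROI feature CSVs, the
comparison table, a median±IQR / log₁₀-p two-panel plot, and the SQLite
store. Re-running with the same seed reproduces `summary.json` byte for
byte.

The same stages are scriptable from the shell:

```bash
myolapse simulate --preset control --n-samples 6 --seed 5 --out cohort/
myolapse measure --rois cohort/control_000/rois.json --pixel-size 1.25 --out features.csv
myolapse report --seed 5 --out run/
```

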