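# Methods

## The measurement model

A muscle at one time point is represented by two hand-drawn (or generated)
vector annotations on a 2-D maximum-intensity projection: a closed simple
polygon (the contour) and an open polyline strictly inside it (the medial
axis, MA). Three features are derived, all in micrometres:

* **area** — exact shoelace area of the polygon × pixel_size². The polygon is
  vector data, so no rasterization is involved; orientation is ignored.
* **length** — sum of Euclidean MA segment lengths × pixel_size.
* **mean diameter** — sample points are placed at arc positions
  0, s, 2s, … along the MA (default s = 5 px), up to the last multiple of s
  not exceeding the total arc length. At each sample the tangent is the
  central difference of the arc-length parameterization (one-sided at the MA
  ends, half-step offset h = s/2); a ray is cast along each of the two
  orthogonal directions and the chord is the sum of the distances to the
  *nearest contour intersection* on each side. The mean diameter is the
  arithmetic mean of the chords. "Nearest on each side" is read as nearest
  intersection along the orthogonal ray, not nearest contour vertex in any
  direction.

Coordinates are 0-based pixel indices, x rightward, y downward, sub-pixel
values allowed. A ray that fails to hit the contour (MA leaving the polygon)
is an error naming the sample point, not a silent NaN. Features are invariant
to rigid transforms to within sub-pixel sampling effects (≤ 0.1 % in tests),
and the chord mean at step 1 px differs from step 5 px by < 2 % on capsules.

## Time model and grid

All series are aligned to the onset of head eversion (HE): hours aHE =
(frame − he_frame) × interval / 60, signed. HE detection is an annotation
input; none is automated. Group comparisons run on the canonical 13-point
grid (5–100 h aHE). Observations are snapped to grid times by nearest
neighbour within a tolerance of 0.25 h — half the 30-min acquisition
interval, which guarantees a unique nearest frame — and are never
interpolated; a grid slot with no observation stays absent. Synthetic "fast
profile" movies sample exactly the 13 canonical times, which is a non-uniform
frame grid; experiment metadata therefore accepts an explicit per-frame hours
table that overrides the affine clock.

The store is a single-file SQLite database (tables `experiments`, `rois`,
`features`, `nuclei`, with primary/foreign keys enforced). A client–server
database would add deployment burden without changing the contract
(relational queries, referential integrity, round-trip identity).

## Statistics

Per-timepoint summaries are medians with 25/75 percentiles (linear
interpolation between order statistics). The two-sample test is the
Mann–Whitney U with an explicit software contract:

* minimum group size 5 per group, enforced as an error, and grid times
  failing it reported as *untested* rather than p = 1;
* midranks for ties;
* exact permutation null distribution of U (dynamic programming over rank
  subsets) when the combined sample is ≤ 20 and tie-free, otherwise the
  normal approximation with continuity correction and tie correction;
* p clipped to [0.0001, 1];
* tails: left = "A below B", right = "A above B", two = 2·min(left, right).

The duality p_left(a, b) = p_right(b, a) holds exactly in both branches, and
the approximation stays within 0.01 of the exact tail probability on tie-free
samples ≤ 20. No multiple-testing correction is applied: comparisons report
raw per-timepoint p against a 0.05 threshold, which inflates the family-wise
error over the 13 grid times and should be kept in mind when reading the
significance flags.

Normalization to a reference time (e.g. +5 h or +50 h) is computed per muscle
*before* any aggregation — each trajectory is expressed as percent of its own
reference value — and series without a usable reference are excluded with a
warning record. Fold changes carry an explicit direction (increase = to/from,
decline = from/to). Eclosion summaries use h.min notation (108.22 = 108 h
22 min); the cohort mean weights each genotype mean by its n and rounds to
the nearest minute.

## Nuclear distribution metrics

Each nucleus is reduced to the arc position of its nearest MA point
(axial_u ∈ [0, 1]), its distance to that point (lateral_d, μm) and the local
fibre radius (half chord at the nearest profile sample). Metrics per
muscle/frame: SD of axial positions (sample SD, ddof 1), central fraction
(|axial_u − 0.5| < 0.15), and midline score = median(lateral_d / local
radius). The classifier is deliberately simple and its thresholds explicit
defaults, configurable:

1. axial_sd < 0.15 → `central_cluster`;
2. else midline_score < 0.25 → `midline_row`;
3. else, when depth information is present and axial_sd ≥ 0.2: nuclei
   predominantly on the basal side (≥ 60 % with z > 0.3 × local radius) →
   `uniform`, otherwise `scattered`;
4. without depth information, `uniform` is unreachable and both spread-out
   patterns report `scattered` — a real limitation of 2-D projections, since
   basal attachment is a z property.

Phase timelines apply a sliding majority vote (window 3, ties keep the
previous label) over per-frame pattern labels and report the label-change
times. Detection in channel 2 is Otsu thresholding restricted to the ROI,
8-connected components, a minimum-size filter (4 px) and intensity-weighted
centroids; nuclei closer than the spot width merge into one detection, and no
splitting of merged blobs is attempted. Classifier tests feed ground-truth
centroids directly so they do not depend on detector quality.

## The synthetic generator

The generator's purpose is to make every downstream stage testable against
exact truth, not to imitate confocal images photorealistically. Muscles are
capsules (stadium shapes): with shaft length L and diameter D, area =
L·D + π(D/2)², the MA is the shaft centreline, and every orthogonal chord
along it equals D. Real DIOMs are irregular; the capsule trades realism for
closed-form truth.

Trajectories are keyframed in hours aHE with geometric (log-linear)
interpolation for area and diameter; the shaft length is derived as
(area − π(D/2)²)/D and must stay positive. Control keyframes pin the
reference medians: area (+5 h, 17 925), (+50 h, 6 038), (+100 h, 15 719) μm²;
diameter (+5 h, 84.4), (+50 h, 24.4), (+100 h, 59.9) μm — the +100 h diameter
encodes the reported 71 % recovery. HE is modelled as a length contraction by
the factor 0.53 over one frame (fibres are longer by 1/0.53 before t = 0)
plus a rotation toward the image midline between +5 h and +25 h (default
18° → 0°). Genotype presets (control, TOR_shRNA, Rheb_shRNA, Tsc2_1_shRNA,
Atg_shRNA, yki_shRNA, Cp1_shRNA) differ in their area/diameter keyframes,
nuclei programs, and — for Cp1 — premature death: two-thirds of muscles
(exact count rounded, chosen by the seeded RNG) receive a death time drawn
from N(55.3 h, 13.4 h), after which they disappear from renders and truth.

Per-sample cohort variation is multiplicative log-normal with σ = 0.1 on the
area and diameter multipliers, constant per muscle, truncated at ±2σ, and
*median-centred* across the cohort (the sample median of the log-multipliers
is subtracted), so the cohort median trajectory equals the preset keyframes
by construction rather than only in expectation. The σ value is a stand-in
matching the visible spread of per-muscle trajectories, not an inference from
data. Nuclei follow per-phase layouts drawn once per muscle — uniform basal
(axial grid, lateral offsets 0.3–0.8 of the radius, strongly basal depth),
central cluster (axial σ 0.05 around the centre), midline row (axial grid,
lateral σ 0.06 of the radius), scattered (lateral offsets 0.35–0.85 of the
radius, interior depth, not basally re-attached) — and move between phases by
linear interpolation over 10 h, since phase timing is known but kinematics
are not. `frozen` re-uses the first layout (no migration).

Rendering: channel 1 is the filled capsule at a constant foreground level,
channel 2 a sum of Gaussian spots (σ = nucleus radius / 2) at the programmed
centroids; optional background, Gaussian and scaled-Poisson noise; clipped
and quantized to 8 bit. All randomness derives from the scene seed (and frame
index), so identical specs give bit-identical files. Profiles: *full* —
1024×1024 px at 1.25 μm/px, 240 frames at 30-min intervals, HE at frame 24;
*fast* — 384×384 px, the 13 canonical frames only. The fast frame is sized so
that the worst-case sample (multipliers at ±2σ) of every preset stays inside
the field of view at every grid time; muscles leaving the frame are an error
naming the muscle and frame, never a silent crop. An optional z-stack render
gives each frame a depth extent of 2·sqrt(r² − d²) (capsule depth = diameter
over the MA) for exercising orthogonal reslices.

What passing tests on synthetic cohorts do *not* show: robustness to manual
segmentation error, irregular fibre shapes, photobleaching, stage drift,
autofluorescence, or nucleus detection in low-contrast images — none of which
the generator emulates.

## Imaging

Only generic multi-page TIFF is supported (pages ordered t → channel → z,
channels interleaved), with a JSON sidecar declaring axis lengths and
spacing. Orthogonal reslices sample the x-y polyline at 1-px arc steps with
bilinear interpolation per z-slice; the depth of a column is the z extent at
or above half its maximum × z spacing. Half-maximum is a choice — the
boundary criterion of a fibre in z is not otherwise defined — and with
13.2-μm optical sections the depth is quantized to about one slice, so depth
estimates of thin fibres (D ≲ 2 slices) are coarse by construction.

## Problem sizes

Default test and demonstration cohorts use the fast profile with n = 6–15
samples per genotype; the recovery analysis uses n = 15, matching the
10–20-muscle groups typical of such screens. The full 1024²×240-frame profile
is supported but not exercised in routine tests, where the canonical-grid
sampling already covers the analysis contract.
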