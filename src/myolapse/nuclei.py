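"""Detection and quantification of myonuclear distribution patterns.

During remodelling, myonuclei of persistent muscles progress through
reproducible localization phases: evenly spread along the basal side of the
fibre, then anti-polar migration into one or two central clusters around
+40 h aHE, then polar migration back outward to settle in a single row along
the fibre midline.  Perturbations deviate: autophagy knockdown scatters
nuclei off the midline during polar migration; Cathepsin-L (Cp1) knockdown
freezes nuclei in place.

Each nucleus is reduced to two coordinates relative to the muscle's medial
axis (MA): a normalized axial position ``axial_u`` ∈ [0, 1] along the MA and
an unsigned lateral distance ``lateral_d`` (μm) from it.  Pattern metrics:

* ``axial_sd`` — SD of axial positions (≈ 0.289 for a uniform spread, small
  for a central cluster);
* ``central_fraction`` — fraction of nuclei with |axial_u − 0.5| < 0.15;
* ``midline_score`` — median of lateral_d / local fibre radius;
* ``pattern`` — rule-based label (thresholds explicit and configurable).

On 2-D projections the uniform basal pattern is distinguishable from
scattering only when depth (z) information is available; without it the
classifier reports ``scattered`` for both (documented limitation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString, Point, Polygon
from skimage.draw import polygon2mask
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .morphometry import MuscleROI, diameter_profile

__all__ = [
    "NucleusObservation",
    "DistributionMetrics",
    "PatternThresholds",
    "detect_nuclei",
    "localize",
    "distribution_metrics",
    "phase_timeline",
]


@dataclass(frozen=True)
class NucleusObservation:
    """One nucleus located relative to its muscle's medial axis."""

    muscle_id: str
    frame: int
    x_px: float
    y_px: float
    axial_u: float        # normalized arc position along MA, in [0, 1]
    lateral_d_um: float   # unsigned distance to MA
    local_radius_um: float
    z_um: float | None = None   # signed depth offset; + = basal side


@dataclass(frozen=True)
class PatternThresholds:
    """Decision thresholds of the rule-based pattern classifier."""

    central_sd: float = 0.15      # axial_sd below → central_cluster
    midline: float = 0.25         # midline_score below → midline_row
    uniform_sd: float = 0.2       # axial_sd at/above, with basal side → uniform
    basal_fraction: float = 0.6   # fraction of nuclei on the basal side
    basal_offset: float = 0.3     # z threshold as fraction of local radius


@dataclass(frozen=True)
class DistributionMetrics:
    n_nuclei: int
    axial_sd: float          # NaN when n < 2
    central_fraction: float
    midline_score: float
    pattern: str


def detect_nuclei(image: np.ndarray, contour_vertices, min_size: int = 4) -> np.ndarray:
    """Intensity-weighted nuclear centroids inside an ROI polygon.

    Otsu threshold computed from the ROI pixels, 8-connected components,
    minimum size filter.  Returns an ``(n, 2)`` array of (x, y); zero nuclei
    is a valid result (blank or constant channel).  Two spots merged below
    the resolution limit yield a single detection (no over-splitting).
    """
    image = np.asarray(image, dtype=float)
    verts = np.asarray(contour_vertices, dtype=float)
    mask = polygon2mask(image.shape, verts[:, ::-1])  # polygon2mask wants (row, col)
    pixels = image[mask]
    if pixels.size == 0 or np.ptp(pixels) == 0:
        return np.zeros((0, 2))
    th = threshold_otsu(pixels)
    bw = (image > th) & mask
    labels = label(bw, connectivity=2)
    centroids = []
    for region in regionprops(labels, intensity_image=image):
        if region.area < min_size:
            continue
        cy, cx = region.centroid_weighted
        centroids.append((cx, cy))
    return np.asarray(centroids, dtype=float).reshape(-1, 2)


def localize(centroids, roi: MuscleROI, chord_profile=None, pixel_size: float = 1.25,
             z_um=None) -> list:
    """Decompose centroids into (axial, lateral) MA coordinates.

    ``axial_u`` is the arc position of the nearest MA point divided by the MA
    length; ``lateral_d`` the distance to that point (μm); the local radius is
    half the chord at the nearest profile sample.  Centroids outside the
    contour are excluded with a warning.  ``chord_profile`` defaults to a
    fresh 5-px diameter profile of the ROI.
    """
    if chord_profile is None:
        chord_profile, _ = diameter_profile(roi.contour, roi.axis,
                                            pixel_size=pixel_size)
    arcs = np.array([a for a, _ in chord_profile])
    radii = np.array([c / 2.0 for _, c in chord_profile])
    line = LineString(roi.axis.vertices)
    poly = Polygon(roi.contour.vertices)
    total = line.length
    out = []
    centroids = np.asarray(centroids, dtype=float).reshape(-1, 2)
    for k, (x, y) in enumerate(centroids):
        pt = Point(x, y)
        if not poly.covers(pt):
            warnings.warn(
                f"nucleus at ({x:.1f}, {y:.1f}) lies outside the contour of "
                f"{roi.muscle_id!r}; excluded", stacklevel=2,
            )
            continue
        s = line.project(pt)
        nearest = line.interpolate(s)
        arc_um = s * pixel_size
        out.append(
            NucleusObservation(
                muscle_id=roi.muscle_id, frame=roi.frame_index, x_px=x, y_px=y,
                axial_u=float(s / total),
                lateral_d_um=float(pt.distance(nearest)) * pixel_size,
                local_radius_um=float(radii[np.argmin(np.abs(arcs - arc_um))]),
                z_um=None if z_um is None else float(z_um[k]),
            )
        )
    return out


def distribution_metrics(observations, thresholds: PatternThresholds = PatternThresholds()
                         ) -> DistributionMetrics:
    """Summary metrics and rule-based pattern label for one muscle/frame."""
    obs = list(observations)
    n = len(obs)
    if n == 0:
        return DistributionMetrics(0, float("nan"), float("nan"), float("nan"), "undefined")
    u = np.array([o.axial_u for o in obs])
    d = np.array([o.lateral_d_um for o in obs])
    r = np.array([max(o.local_radius_um, 1e-9) for o in obs])
    axial_sd = float(np.std(u, ddof=1)) if n >= 2 else float("nan")
    central_fraction = float(np.mean(np.abs(u - 0.5) < 0.15))
    midline_score = float(np.median(d / r))

    if n < 2:
        pattern = "undefined"
    elif axial_sd < thresholds.central_sd:
        pattern = "central_cluster"
    elif midline_score < thresholds.midline:
        pattern = "midline_row"
    else:
        zs = [o.z_um for o in obs]
        if all(z is not None for z in zs) and axial_sd >= thresholds.uniform_sd:
            basal = np.mean(
                np.asarray(zs, dtype=float) > thresholds.basal_offset * r
            )
            pattern = "uniform" if basal >= thresholds.basal_fraction else "scattered"
        else:
            pattern = "scattered"
    return DistributionMetrics(n, axial_sd, central_fraction, midline_score, pattern)


def phase_timeline(entries, window: int = 3) -> list:
    """Majority-smoothed pattern sequence with transition times.

    ``entries`` is a list of ``(hours aHE, DistributionMetrics)`` in time
    order (>= 2 points).  A sliding majority vote of width ``window`` (ties
    keep the previous label) suppresses single-frame flicker.  Returns
    ``[(hours, pattern), …]`` with one entry per segment start.
    """
    entries = list(entries)
    if len(entries) < 2:
        raise ValueError("phase_timeline needs at least 2 time points")
    hours = [h for h, _ in entries]
    raw = [m.pattern for _, m in entries]
    half = window // 2
    smoothed = []
    for i in range(len(raw)):
        votes = raw[max(0, i - half): i + half + 1]
        counts = {}
        for v in votes:
            counts[v] = counts.get(v, 0) + 1
        best = max(counts.values())
        winners = [k for k, c in counts.items() if c == best]
        if len(winners) == 1:
            smoothed.append(winners[0])
        else:
            prev = smoothed[-1] if smoothed else raw[i]
            smoothed.append(prev if prev in winners else winners[0])
    timeline = [(hours[0], smoothed[0])]
    for h, pat in zip(hours[1:], smoothed[1:]):
        if pat != timeline[-1][1]:
            timeline.append((h, pat))
    return timeline
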