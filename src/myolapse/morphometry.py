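"""Medial-axis morphometry of muscle regions of interest.

A muscle at one time point is annotated with two vector objects drawn on a
maximum-intensity projection: a closed *contour* polygon around the fibre and
an open *medial axis* (MA) polyline inside it.  Three shape features are
derived:

* ``area`` — shoelace area of the contour polygon, in μm²;
* ``length`` — arc length of the MA, in μm;
* ``mean diameter`` — the average length of chords orthogonal to the MA,
  sampled at equidistant arc positions (default every 5 px), where each chord
  runs from the nearest contour intersection on one side of the MA to the
  nearest intersection on the other side.

Coordinates are 0-based pixel indices (x rightward, y downward) and may be
sub-pixel; areas and lengths are computed on the exact polygon/polyline, not
on a rasterization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from shapely.geometry import LineString, Point, Polygon

__all__ = [
    "Contour",
    "MedialAxis",
    "MuscleROI",
    "FeatureRecord",
    "MorphometryError",
    "polygon_area",
    "polyline_length",
    "diameter_profile",
    "extract_features",
    "track",
    "load_rois",
    "save_rois",
]


class MorphometryError(ValueError):
    """Invalid annotation geometry or a failed feature computation."""


def _as_points(vertices, min_points: int, what: str) -> np.ndarray:
    arr = np.asarray(vertices, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise MorphometryError(f"{what} vertices must be an (N, 2) array of x, y")
    if len(arr) < min_points:
        raise MorphometryError(f"{what} needs at least {min_points} vertices, got {len(arr)}")
    if not np.all(np.isfinite(arr)):
        raise MorphometryError(f"{what} contains non-finite coordinates")
    return arr


@dataclass(frozen=True)
class Contour:
    """Closed simple polygon around one muscle fibre (implicitly closed)."""

    vertices: np.ndarray

    def __post_init__(self):
        arr = _as_points(self.vertices, 3, "contour")
        object.__setattr__(self, "vertices", arr)
        if not self.polygon.is_valid:
            raise MorphometryError("contour polygon is self-intersecting or degenerate")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass(frozen=True)
class MedialAxis:
    """Open polyline drawn inside the contour; its arc length is the muscle length."""

    vertices: np.ndarray

    def __post_init__(self):
        arr = _as_points(self.vertices, 2, "medial axis")
        object.__setattr__(self, "vertices", arr)

    @property
    def line(self) -> LineString:
        return LineString(self.vertices)


@dataclass(frozen=True)
class MuscleROI:
    """One segmented muscle at one frame, identified for tracking."""

    muscle_id: str
    frame_index: int
    contour: Contour
    axis: MedialAxis

    def __post_init__(self):
        if not self.muscle_id:
            raise MorphometryError("muscle_id must be non-empty")
        poly = self.contour.polygon
        for v in self.axis.vertices:
            if not poly.contains(Point(v)):
                raise MorphometryError(
                    f"medial-axis vertex {tuple(v)} of {self.muscle_id!r} "
                    f"(frame {self.frame_index}) is not strictly inside the contour"
                )


@dataclass(frozen=True)
class FeatureRecord:
    """Derived shape features of one ROI, all in micrometres."""

    area_um2: float
    length_um: float
    mean_diameter_um: float
    #: (arc position along MA in μm, orthogonal chord length in μm)
    chord_profile: tuple = field(default_factory=tuple)


def polygon_area(contour: Contour, pixel_size: float) -> float:
    """Shoelace area of the contour polygon scaled to μm².

    Orientation-independent; raises :class:`MorphometryError` for
    self-intersecting polygons (already rejected by :class:`Contour`).
    """
    return float(contour.polygon.area) * pixel_size**2


def polyline_length(axis: MedialAxis, pixel_size: float) -> float:
    """Sum of Euclidean segment lengths of the MA polyline, in μm."""
    seg = np.diff(axis.vertices, axis=0)
    return float(np.hypot(seg[:, 0], seg[:, 1]).sum()) * pixel_size


def _arc_parameterize(vertices: np.ndarray):
    """Cumulative arc length per vertex and a point-at-arc interpolator."""
    seg = np.diff(vertices, axis=0)
    lens = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(lens)])

    def point_at(s: float) -> np.ndarray:
        s = min(max(s, 0.0), cum[-1])
        return np.array(
            [np.interp(s, cum, vertices[:, 0]), np.interp(s, cum, vertices[:, 1])]
        )

    return cum, point_at


def _ray_distance(origin: np.ndarray, direction: np.ndarray, boundary, reach: float) -> float:
    """Distance from origin to the nearest boundary intersection along +direction."""
    ray = LineString([origin, origin + direction * reach])
    hit = ray.intersection(boundary)
    if hit.is_empty:
        return np.nan
    pts = []
    for geom in getattr(hit, "geoms", [hit]):
        if geom.geom_type == "Point":
            pts.append((geom.x, geom.y))
        else:  # collinear overlap: take its endpoints
            pts.extend(np.asarray(geom.coords))
    d = np.hypot(*(np.asarray(pts) - origin).T)
    d = d[d > 1e-9]
    return float(d.min()) if d.size else np.nan


def diameter_profile(
    contour: Contour,
    axis: MedialAxis,
    step_px: float = 5.0,
    pixel_size: float = 1.0,
):
    """Orthogonal chord profile along the MA and its arithmetic mean.

    Sample points sit at arc positions 0, ``step_px``, 2·``step_px``, … up to
    the last multiple not exceeding the total MA arc length.  At each sample
    the local tangent is estimated by central differences on the arc-length
    parameterization (one-sided at the MA ends); rays are cast along both
    orthogonal directions and the chord is the sum of the distances to the
    nearest contour intersection on each side.

    Returns ``(chord_profile, mean_diameter_um)`` where ``chord_profile`` is a
    tuple of ``(arc position μm, chord μm)`` pairs.
    """
    if step_px <= 0:
        raise MorphometryError("step_px must be positive")
    cum, point_at = _arc_parameterize(axis.vertices)
    total = cum[-1]
    if total <= 0:
        raise MorphometryError("medial axis has zero length")
    positions = np.arange(0.0, total + 1e-9, step_px)

    poly = contour.polygon
    boundary = poly.exterior
    minx, miny, maxx, maxy = poly.bounds
    reach = 2.0 * float(np.hypot(maxx - minx, maxy - miny)) + 1.0
    h = min(step_px, total) / 2.0

    profile = []
    for s in positions:
        p = point_at(s)
        tangent = point_at(min(s + h, total)) - point_at(max(s - h, 0.0))
        norm = np.hypot(*tangent)
        if norm < 1e-12:
            raise MorphometryError(f"degenerate tangent at arc position {s:.2f} px")
        tangent /= norm
        normal = np.array([-tangent[1], tangent[0]])
        d_pos = _ray_distance(p, normal, boundary, reach)
        d_neg = _ray_distance(p, -normal, boundary, reach)
        if not np.isfinite(d_pos) or not np.isfinite(d_neg) or not poly.contains(Point(p)):
            raise MorphometryError(
                f"orthogonal ray at arc position {s:.2f} px failed to hit the "
                "contour; is the medial axis inside the contour?"
            )
        profile.append((s * pixel_size, (d_pos + d_neg) * pixel_size))

    chords = np.array([c for _, c in profile])
    return tuple(profile), float(chords.mean())


def extract_features(roi: MuscleROI, pixel_size: float, step_px: float = 5.0) -> FeatureRecord:
    """Bundle area, length and chord-profile diameter for one ROI."""
    profile, mean_diam = diameter_profile(roi.contour, roi.axis, step_px, pixel_size)
    return FeatureRecord(
        area_um2=polygon_area(roi.contour, pixel_size),
        length_um=polyline_length(roi.axis, pixel_size),
        mean_diameter_um=mean_diam,
        chord_profile=profile,
    )


def track(rois: Sequence[MuscleROI]) -> dict:
    """Group ROIs by muscle id into frame-sorted series.

    Gaps (missing frames) are preserved as absent entries, never interpolated.
    Duplicate ``(muscle_id, frame_index)`` pairs raise.  Output order is
    independent of input order (ids sorted, frames ascending).
    """
    seen = set()
    series: dict[str, list] = {}
    for roi in rois:
        key = (roi.muscle_id, roi.frame_index)
        if key in seen:
            raise MorphometryError(f"duplicate ROI for muscle {key[0]!r} at frame {key[1]}")
        seen.add(key)
        series.setdefault(roi.muscle_id, []).append(roi)
    return {
        mid: sorted(items, key=lambda r: r.frame_index)
        for mid, items in sorted(series.items())
    }


# --- ROI annotation file (JSON) -------------------------------------------

def save_rois(rois: Sequence[MuscleROI], path) -> None:
    """Write ROIs as a JSON list of {muscle_id, frame_index, contour, axis}."""
    doc = [
        {
            "muscle_id": r.muscle_id,
            "frame_index": int(r.frame_index),
            "contour": np.round(r.contour.vertices, 4).tolist(),
            "axis": np.round(r.axis.vertices, 4).tolist(),
        }
        for r in rois
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


def load_rois(path) -> list:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    return [
        MuscleROI(
            muscle_id=item["muscle_id"],
            frame_index=int(item["frame_index"]),
            contour=Contour(np.asarray(item["contour"], dtype=float)),
            axis=MedialAxis(np.asarray(item["axis"], dtype=float)),
        )
        for item in doc
    ]
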