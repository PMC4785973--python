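"""Seeded synthetic two-channel time-lapse generator with exact ground truth.

Emulates remodelling of persistent abdominal muscles (DIOMs) across fly
metamorphosis as imaged by time-lapse confocal microscopy: channel 1 carries a
cytoplasmic reporter (filled muscle bodies), channel 2 a nuclear reporter
(Gaussian spots).  Muscle geometry is a *capsule* (stadium: rectangle with
semicircular caps) so that area, length and diameter have closed-form ground
truth:

    area = shaft_length · diameter + π · (diameter / 2)²

The shaft length is derived from the keyframed area and diameter trajectories;
the medial axis runs along the shaft centreline, so the true mean orthogonal
chord equals the diameter everywhere along it.

Time is measured in hours after head eversion (aHE).  Head eversion itself is
modelled as an abrupt length contraction (default factor 0.53 over one frame)
plus a rotation toward the image midline between +5 h and +25 h.

Genotype presets pin the control median trajectory to the reference medians
(area 17 925 → 6 038 → 15 719 μm² at +5/+50/+100 h, diameter 84.4 → 24.4 μm)
and encode the perturbation phenotypes (deeper atrophy with weak regrowth for
TOR/Rheb knockdown, suppressed atrophy for Tsc2, attenuated atrophy with
scattered nuclei for Atg, longer/thinner fibres for yki, frozen nuclei and
premature death of two-thirds of fibres for Cp1).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .imaging import write_tiff
from .morphometry import Contour, MedialAxis, MuscleROI, save_rois
from .store import CANONICAL_GRID_H

__all__ = [
    "SceneSpec",
    "MuscleSpec",
    "NucleiProgram",
    "NoiseSpec",
    "SceneError",
    "Capsule",
    "render_frame",
    "render_zstack",
    "generate_sample",
    "generate_cohort",
    "preset_names",
    "build_preset",
    "nuclei_positions",
    "PATTERNS",
]

PATTERNS = ("uniform_basal", "central_cluster", "midline_row", "scattered", "frozen")

#: transition time between nuclear phase patterns (linear centroid interpolation)
PHASE_BLEND_H = 10.0


class SceneError(ValueError):
    """Inconsistent scene description or a muscle leaving the field of view."""


def _check_keyframes(kf, what):
    times = [t for t, _ in kf]
    if len(kf) == 0:
        raise SceneError(f"{what} keyframes must not be empty")
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise SceneError(f"{what} keyframe times must be strictly increasing")


def _interp(kf, t, log=False):
    """Piecewise-linear keyframe interpolation, clamped outside the range."""
    times = np.array([p[0] for p in kf], dtype=float)
    vals = np.array([p[1] for p in kf], dtype=float)
    if log:
        return float(np.exp(np.interp(t, times, np.log(vals))))
    return float(np.interp(t, times, vals))


@dataclass
class NucleiProgram:
    """Programmed myonuclear localization phases for one muscle.

    ``phases`` is an ordered list of ``(start hours aHE, pattern)``; between
    consecutive phases nucleus positions are linearly interpolated over
    ``PHASE_BLEND_H`` hours.  The ``frozen`` pattern re-uses the positions of
    the first phase (no migration).
    """

    n_nuclei: int = 10
    phases: tuple = (( -100.0, "uniform_basal"),)
    lateral_jitter_um: float = 1.0
    nucleus_radius_um: float = 5.0

    def __post_init__(self):
        if self.n_nuclei < 0:
            raise SceneError("n_nuclei must be >= 0")
        starts = [s for s, _ in self.phases]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise SceneError("phase start times must be increasing")
        for _, pat in self.phases:
            if pat not in PATTERNS:
                raise SceneError(f"unknown nuclei pattern {pat!r}; valid: {PATTERNS}")


@dataclass
class NoiseSpec:
    """Additive/counting noise applied after rendering; all levels in 8-bit DN."""

    background_level: float = 0.0
    gaussian_sd: float = 0.0
    poisson_scaling: float = 0.0
    bit_depth: int = 8

    def __post_init__(self):
        if min(self.background_level, self.gaussian_sd, self.poisson_scaling) < 0:
            raise SceneError("noise levels must be >= 0")


@dataclass
class MuscleSpec:
    """Trajectory of one capsule-shaped muscle, keyframed in hours aHE."""

    muscle_id: str
    area_keyframes: list          # (h aHE, μm²)
    diameter_keyframes: list      # (h aHE, μm)
    orientation_keyframes: list = field(default_factory=lambda: [(5.0, 0.0)])  # degrees
    centroid_keyframes: list = field(default_factory=list)  # (h aHE, (x px, y px))
    he_contraction_factor: float = 0.53
    nuclei: NucleiProgram = field(default_factory=NucleiProgram)
    death_time: float | None = None   # hours aHE; None = survives

    def __post_init__(self):
        _check_keyframes(self.area_keyframes, "area")
        _check_keyframes(self.diameter_keyframes, "diameter")
        _check_keyframes(self.orientation_keyframes, "orientation")
        if any(v <= 0 for _, v in self.area_keyframes):
            raise SceneError("areas must be > 0")
        if any(v <= 0 for _, v in self.diameter_keyframes):
            raise SceneError("diameters must be > 0")
        if not 0 < self.he_contraction_factor <= 1:
            raise SceneError("he_contraction_factor must be in (0, 1]")

    def alive_at(self, t: float) -> bool:
        return self.death_time is None or t < self.death_time

    def capsule_at(self, t: float, spec: "SceneSpec") -> "Capsule":
        area = _interp(self.area_keyframes, t, log=True)
        diam = _interp(self.diameter_keyframes, t, log=True)
        r = diam / 2.0
        shaft = (area - math.pi * r * r) / diam
        if shaft <= 0:
            raise SceneError(
                f"muscle {self.muscle_id!r}: area {area:.0f} μm² inconsistent with "
                f"diameter {diam:.1f} μm (non-positive shaft length) at {t:+.1f} h"
            )
        if t < 0:
            # pre-head-eversion: fibre has not yet contracted
            shaft = shaft / self.he_contraction_factor
        theta = math.radians(_interp(self.orientation_keyframes, t))
        if self.centroid_keyframes:
            times = [p[0] for p in self.centroid_keyframes]
            xs = [p[1][0] for p in self.centroid_keyframes]
            ys = [p[1][1] for p in self.centroid_keyframes]
            cx = float(np.interp(t, times, xs))
            cy = float(np.interp(t, times, ys))
        else:
            cx, cy = spec.image_size[0] / 2.0, spec.image_size[1] / 2.0
        return Capsule(cx, cy, shaft, diam, theta, spec.pixel_size)


@dataclass
class SceneSpec:
    """Full generative description of one synthetic pupa time-lapse."""

    image_size: tuple = (1024, 1024)     # (w, h) px
    pixel_size: float = 1.25             # μm / px
    frame_interval: float = 30.0         # minutes
    n_frames: int = 240
    he_frame: int = 24
    muscles: list = field(default_factory=list)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0
    #: explicit hours aHE per frame; overrides the affine frame clock when set
    frame_hours: tuple | None = None
    foreground_level: int = 160
    nucleus_amplitude: int = 220

    def __post_init__(self):
        if self.frame_hours is not None:
            self.frame_hours = tuple(float(h) for h in self.frame_hours)
            self.n_frames = len(self.frame_hours)
        if self.n_frames < 1:
            raise SceneError("n_frames must be >= 1")
        if not 0 <= self.he_frame < self.n_frames:
            raise SceneError("he_frame must lie in [0, n_frames)")
        if self.pixel_size <= 0:
            raise SceneError("pixel_size must be > 0")

    def hours_of_frame(self, frame_index: int) -> float:
        if self.frame_hours is not None:
            return self.frame_hours[frame_index]
        return (frame_index - self.he_frame) * self.frame_interval / 60.0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), default=_json_default, indent=1)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(type(obj))


# --- capsule geometry ------------------------------------------------------

@dataclass(frozen=True)
class Capsule:
    """Stadium shape in pixel space with closed-form μm features."""

    cx: float
    cy: float
    shaft_um: float
    diameter_um: float
    theta: float          # radians, x-axis convention, y downward
    pixel_size: float

    @property
    def radius_px(self) -> float:
        return self.diameter_um / 2.0 / self.pixel_size

    @property
    def shaft_px(self) -> float:
        return self.shaft_um / self.pixel_size

    @property
    def area_um2(self) -> float:
        r = self.diameter_um / 2.0
        return self.shaft_um * self.diameter_um + math.pi * r * r

    @property
    def length_um(self) -> float:
        """Ground-truth muscle length = medial-axis (shaft centreline) length."""
        return self.shaft_um

    def endpoints(self) -> tuple:
        u = np.array([math.cos(self.theta), math.sin(self.theta)])
        c = np.array([self.cx, self.cy])
        half = self.shaft_px / 2.0
        return c - u * half, c + u * half

    def contains_margin(self, w: int, h: int, margin: float = 1.0) -> bool:
        e0, e1 = self.endpoints()
        r = self.radius_px + margin
        for e in (e0, e1):
            if not (r <= e[0] <= w - 1 - r and r <= e[1] <= h - 1 - r):
                return False
        return True

    def mask(self, shape_hw: tuple) -> np.ndarray:
        """Boolean raster: pixel centres within radius of the shaft segment."""
        hgt, wid = shape_hw
        yy, xx = np.mgrid[0:hgt, 0:wid]
        e0, e1 = self.endpoints()
        d = _dist_to_segment(xx.astype(float), yy.astype(float), e0, e1)
        return d <= self.radius_px

    def contour_vertices(self, n_arc: int = 24) -> np.ndarray:
        """Sub-pixel stadium polygon: two semicircular caps joined by the shaft."""
        e0, e1 = self.endpoints()
        r = self.radius_px
        th = self.theta
        a1 = np.linspace(th - math.pi / 2, th + math.pi / 2, n_arc)   # cap at e1
        a0 = np.linspace(th + math.pi / 2, th + 3 * math.pi / 2, n_arc)  # cap at e0
        pts1 = e1 + r * np.column_stack([np.cos(a1), np.sin(a1)])
        pts0 = e0 + r * np.column_stack([np.cos(a0), np.sin(a0)])
        return np.vstack([pts1, pts0])

    def axis_vertices(self, step_px: float = 2.0) -> np.ndarray:
        e0, e1 = self.endpoints()
        n = max(2, int(math.ceil(self.shaft_px / step_px)) + 1)
        ts = np.linspace(0.0, 1.0, n)
        return e0 + np.outer(ts, e1 - e0)

    def local_frame(self):
        u = np.array([math.cos(self.theta), math.sin(self.theta)])
        n = np.array([-u[1], u[0]])
        e0, _ = self.endpoints()
        return e0, u, n


def _dist_to_segment(px, py, a, b):
    abx, aby = b[0] - a[0], b[1] - a[1]
    denom = abx * abx + aby * aby
    if denom < 1e-12:
        return np.hypot(px - a[0], py - a[1])
    t = np.clip(((px - a[0]) * abx + (py - a[1]) * aby) / denom, 0.0, 1.0)
    return np.hypot(px - (a[0] + t * abx), py - (a[1] + t * aby))


# --- nuclei programs -------------------------------------------------------

def _pattern_coords(pattern: str, n: int, rng: np.random.Generator) -> np.ndarray:
    """Local nucleus coordinates (u axial ∈ [0,1], v lateral, w depth; v, w as
    fractions of the local radius, w > 0 = basal side)."""
    if n == 0:
        return np.zeros((0, 3))
    u_grid = (np.arange(n) + 0.5) / n
    if pattern == "uniform_basal":
        u = np.clip(u_grid + rng.normal(0, 0.02, n), 0.02, 0.98)
        v = rng.uniform(0.3, 0.8, n) * rng.choice([-1.0, 1.0], n)
        w = rng.normal(0.7, 0.1, n)
    elif pattern == "central_cluster":
        u = np.clip(0.5 + rng.normal(0, 0.05, n), 0.05, 0.95)
        v = rng.normal(0, 0.12, n)
        w = rng.normal(0.0, 0.15, n)
    elif pattern == "midline_row":
        u = np.clip(np.linspace(0.08, 0.92, n) + rng.normal(0, 0.02, n), 0.02, 0.98)
        v = rng.normal(0, 0.06, n)
        w = rng.normal(0.0, 0.1, n)
    elif pattern == "scattered":
        # displaced from the midline within the fibre interior, not re-attached
        # to the basal surface
        u = np.clip(u_grid + rng.normal(0, 0.04, n), 0.02, 0.98)
        v = rng.uniform(0.35, 0.85, n) * rng.choice([-1.0, 1.0], n)
        w = rng.uniform(-0.5, 0.25, n)
    else:
        raise SceneError(f"pattern {pattern!r} has no generative rule")
    return np.column_stack([u, v, w])


def _phase_positions(program: NucleiProgram, rng: np.random.Generator) -> list:
    """One fixed local-coordinate array per declared phase (frozen = first)."""
    out = []
    for _, pat in program.phases:
        if pat == "frozen":
            if not out:
                raise SceneError("'frozen' cannot be the first phase")
            out.append(out[0].copy())
        else:
            out.append(_pattern_coords(pat, program.n_nuclei, rng))
    return out


def nuclei_positions(program: NucleiProgram, t: float, rng_muscle: np.random.Generator):
    """Local nucleus coordinates and the active pattern label at time ``t``.

    Positions blend linearly from the previous phase over ``PHASE_BLEND_H``
    hours after each phase start.  ``rng_muscle`` must be a generator seeded
    per muscle; the per-phase layouts are drawn once from it.
    """
    positions = _phase_positions(program, rng_muscle)
    starts = [s for s, _ in program.phases]
    idx = 0
    for i, s in enumerate(starts):
        if t >= s:
            idx = i
    label = program.phases[idx][1]
    if label == "frozen":
        label = program.phases[0][1]
    coords = positions[idx]
    if idx > 0:
        dt = t - starts[idx]
        if dt < PHASE_BLEND_H:
            frac = dt / PHASE_BLEND_H
            coords = (1 - frac) * positions[idx - 1] + frac * positions[idx]
    return coords.copy(), label


def _nuclei_px(muscle: MuscleSpec, cap: Capsule, t: float, scene: SceneSpec, frame_index: int):
    """Pixel/μm coordinates of all nuclei of one muscle at one frame."""
    mseed = _muscle_seed(scene.seed, muscle.muscle_id)
    coords, label = nuclei_positions(muscle.nuclei, t, np.random.default_rng(mseed))
    if len(coords) == 0:
        return np.zeros((0, 2)), np.zeros(0), coords, label
    e0, u_vec, n_vec = cap.local_frame()
    r_px = cap.radius_px
    jitter_px = muscle.nuclei.lateral_jitter_um / scene.pixel_size
    rng_f = np.random.default_rng([scene.seed & 0x7FFFFFFF, 911, frame_index,
                                   _muscle_seed(0, muscle.muscle_id)])
    xy = (
        e0[None, :]
        + np.outer(coords[:, 0] * cap.shaft_px, u_vec)
        + np.outer(coords[:, 1] * r_px, n_vec)
        + rng_f.normal(0, jitter_px, (len(coords), 2))
    )
    z_um = coords[:, 2] * cap.diameter_um / 2.0
    return xy, z_um, coords, label


def _muscle_seed(base: int, muscle_id: str) -> int:
    h = 2166136261
    for ch in muscle_id:
        h = ((h ^ ord(ch)) * 16777619) & 0x7FFFFFFF
    return (base + h) & 0x7FFFFFFF


# --- rendering -------------------------------------------------------------

def _render_channels(spec: SceneSpec, frame_index: int):
    w, h = spec.image_size
    t = spec.hours_of_frame(frame_index)
    ch1 = np.zeros((h, w), dtype=float)
    ch2 = np.zeros((h, w), dtype=float)
    truth_rows, nuc_rows = [], []
    yy, xx = np.mgrid[0:h, 0:w]

    for muscle in spec.muscles:
        if not muscle.alive_at(t):
            continue
        cap = muscle.capsule_at(t, spec)
        if not cap.contains_margin(w, h):
            raise SceneError(
                f"muscle {muscle.muscle_id!r} extends outside the {w}x{h} image "
                f"at frame {frame_index} ({t:+.1f} h aHE)"
            )
        ch1[cap.mask((h, w))] = spec.foreground_level
        xy, z_um, coords, label = _nuclei_px(muscle, cap, t, spec, frame_index)
        sigma = muscle.nuclei.nucleus_radius_um / spec.pixel_size / 2.0
        for k in range(len(xy)):
            dx, dy = xx - xy[k, 0], yy - xy[k, 1]
            ch2 += spec.nucleus_amplitude * np.exp(-(dx * dx + dy * dy) / (2 * sigma**2))
            nuc_rows.append(
                dict(
                    muscle_id=muscle.muscle_id, frame=frame_index, hours_ahe=t,
                    nucleus=k, x_px=xy[k, 0], y_px=xy[k, 1], z_um=z_um[k],
                    axial_u=coords[k, 0], lateral_frac=coords[k, 1],
                    lateral_d_um=abs(coords[k, 1]) * cap.diameter_um / 2.0,
                    pattern=label,
                )
            )
        truth_rows.append(
            dict(
                muscle_id=muscle.muscle_id, frame=frame_index, hours_ahe=t,
                area_um2=cap.area_um2, length_um=cap.length_um,
                diameter_um=cap.diameter_um, centroid_x_px=cap.cx,
                centroid_y_px=cap.cy, orientation_deg=math.degrees(cap.theta),
                alive=True, n_nuclei=muscle.nuclei.n_nuclei,
            )
        )
    return ch1, ch2, truth_rows, nuc_rows


def _apply_noise(img: np.ndarray, noise: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    out = img + noise.background_level
    if noise.poisson_scaling > 0:
        out = rng.poisson(np.maximum(out, 0) * noise.poisson_scaling) / noise.poisson_scaling
    if noise.gaussian_sd > 0:
        out = out + rng.normal(0, noise.gaussian_sd, out.shape)
    top = 2**noise.bit_depth - 1
    return np.clip(np.rint(out), 0, top).astype(np.uint8 if noise.bit_depth <= 8 else np.uint16)


def render_frame(spec: SceneSpec, frame_index: int):
    """Render one two-channel frame plus its ground-truth slice.

    Returns ``(image (2, h, w) uint8, truth DataFrame, nuclei DataFrame)``.
    Identical ``(spec, seed, frame_index)`` produce bit-identical output.
    """
    if not 0 <= frame_index < spec.n_frames:
        raise SceneError(f"frame_index {frame_index} outside [0, {spec.n_frames})")
    ch1, ch2, truth_rows, nuc_rows = _render_channels(spec, frame_index)
    rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, frame_index])
    img = np.stack([_apply_noise(ch1, spec.noise, rng), _apply_noise(ch2, spec.noise, rng)])
    return img, pd.DataFrame(truth_rows), pd.DataFrame(nuc_rows)


def render_zstack(spec: SceneSpec, frame_index: int, n_slices: int = 35,
                  z_spacing_um: float = 13.2):
    """Render one frame as a z-stack ``(2, z, h, w)``; capsule depth = diameter.

    The muscle occupies, at in-plane distance d from its axis, the z extent
    2·sqrt(r² − d²) centred mid-stack, so the true depth over the medial axis
    equals the diameter.  Nuclei are placed at their programmed z offsets.
    """
    if not 0 <= frame_index < spec.n_frames:
        raise SceneError(f"frame_index {frame_index} outside [0, {spec.n_frames})")
    w, h = spec.image_size
    t = spec.hours_of_frame(frame_index)
    vol = np.zeros((2, n_slices, h, w), dtype=float)
    z_centers = (np.arange(n_slices) - (n_slices - 1) / 2.0) * z_spacing_um
    yy, xx = np.mgrid[0:h, 0:w]
    for muscle in spec.muscles:
        if not muscle.alive_at(t):
            continue
        cap = muscle.capsule_at(t, spec)
        if not cap.contains_margin(w, h):
            raise SceneError(
                f"muscle {muscle.muscle_id!r} extends outside the {w}x{h} image "
                f"at frame {frame_index} ({t:+.1f} h aHE)"
            )
        e0, e1 = cap.endpoints()
        d_px = _dist_to_segment(xx.astype(float), yy.astype(float), e0, e1)
        d_um = d_px * spec.pixel_size
        r_um = cap.diameter_um / 2.0
        inside = d_um <= r_um
        half_depth = np.zeros_like(d_um)
        half_depth[inside] = np.sqrt(np.maximum(r_um**2 - d_um[inside] ** 2, 0.0))
        for iz, zc in enumerate(z_centers):
            vol[0, iz][inside & (np.abs(zc) <= half_depth)] = spec.foreground_level
        xy, z_um, _, _ = _nuclei_px(muscle, cap, t, spec, frame_index)
        sigma = muscle.nuclei.nucleus_radius_um / spec.pixel_size / 2.0
        for k in range(len(xy)):
            iz = int(np.argmin(np.abs(z_centers - z_um[k])))
            dx, dy = xx - xy[k, 0], yy - xy[k, 1]
            vol[1, iz] += spec.nucleus_amplitude * np.exp(-(dx * dx + dy * dy) / (2 * sigma**2))
    rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, 7, frame_index])
    out = np.empty_like(vol, dtype=np.uint8)
    for c in range(2):
        for iz in range(n_slices):
            out[c, iz] = _apply_noise(vol[c, iz], spec.noise, rng)
    return out


# --- genotype presets ------------------------------------------------------

#: reference control medians: (h aHE, area μm²) and (h aHE, diameter μm)
CONTROL_AREA_KEYFRAMES = [(5.0, 17925.0), (50.0, 6038.0), (100.0, 15719.0)]
CONTROL_DIAMETER_KEYFRAMES = [(5.0, 84.4), (50.0, 24.4), (100.0, 59.9)]

_PRESETS = {
    "control": dict(
        area=CONTROL_AREA_KEYFRAMES,
        diameter=CONTROL_DIAMETER_KEYFRAMES,
        phases=((-100.0, "uniform_basal"), (30.0, "central_cluster"), (52.0, "midline_row")),
    ),
    # deeper atrophy, weak regrowth; nuclei behave like control
    "TOR_shRNA": dict(
        area=[(5.0, 16500.0), (50.0, 3400.0), (100.0, 5400.0)],
        diameter=[(5.0, 80.0), (50.0, 14.0), (100.0, 22.0)],
        phases=((-100.0, "uniform_basal"), (30.0, "central_cluster"), (52.0, "midline_row")),
    ),
    "Rheb_shRNA": dict(
        area=[(5.0, 17500.0), (50.0, 3675.0), (100.0, 6825.0)],
        diameter=[(5.0, 80.0), (50.0, 15.0), (100.0, 24.0)],
        phases=((-100.0, "uniform_basal"), (30.0, "central_cluster"), (52.0, "midline_row")),
    ),
    # suppressed atrophy (strong Tsc2 allele): larger mid-pupation sizes
    "Tsc2_1_shRNA": dict(
        area=[(5.0, 18500.0), (50.0, 15100.0), (100.0, 17000.0)],
        diameter=[(5.0, 86.0), (50.0, 63.0), (100.0, 62.0)],
        phases=((-100.0, "uniform_basal"), (30.0, "central_cluster"), (52.0, "midline_row")),
    ),
    # attenuated atrophy; nuclei scatter during polar migration
    "Atg_shRNA": dict(
        area=[(5.0, 17925.0), (50.0, 9300.0), (100.0, 15000.0)],
        diameter=[(5.0, 84.0), (50.0, 44.4), (100.0, 58.0)],
        phases=((-100.0, "uniform_basal"), (30.0, "central_cluster"), (52.0, "scattered")),
    ),
    # longer and thinner fibres, growth inhibited late
    "yki_shRNA": dict(
        area=[(5.0, 17925.0), (50.0, 6038.0), (100.0, 11000.0)],
        diameter=[(5.0, 70.0), (50.0, 22.0), (100.0, 40.0)],
        phases=((-100.0, "uniform_basal"), (30.0, "central_cluster"), (52.0, "midline_row")),
        he_contraction_factor=0.578,
    ),
    # atrophy proceeds, nuclei never migrate, 2/3 of fibres die near +55 h
    "Cp1_shRNA": dict(
        area=CONTROL_AREA_KEYFRAMES,
        diameter=CONTROL_DIAMETER_KEYFRAMES,
        phases=((-100.0, "uniform_basal"), (40.0, "frozen")),
        death_fraction=2.0 / 3.0,
        death_mean_h=55.3,
        death_sd_h=13.4,
    ),
}

FAST_PROFILE = dict(image_size=(384, 384), he_frame=0,
                    frame_hours=tuple(float(h) for h in CANONICAL_GRID_H))
FULL_PROFILE = dict(image_size=(1024, 1024), n_frames=240, he_frame=24, frame_interval=30.0)


def preset_names() -> tuple:
    return tuple(_PRESETS)


def build_preset(
    preset: str,
    muscle_id: str = "DIOM 3L",
    area_mult: float = 1.0,
    diam_mult: float = 1.0,
    death_time: float | None = None,
    n_nuclei: int = 10,
) -> MuscleSpec:
    """One muscle following a genotype preset, optionally size-scaled."""
    if preset not in _PRESETS:
        raise SceneError(
            f"unknown preset {preset!r}; valid presets: {', '.join(sorted(_PRESETS))}"
        )
    p = _PRESETS[preset]
    return MuscleSpec(
        muscle_id=muscle_id,
        area_keyframes=[(t, v * area_mult) for t, v in p["area"]],
        diameter_keyframes=[(t, v * diam_mult) for t, v in p["diameter"]],
        orientation_keyframes=[(5.0, 18.0), (25.0, 0.0)],
        he_contraction_factor=p.get("he_contraction_factor", 0.53),
        nuclei=NucleiProgram(n_nuclei=n_nuclei, phases=p["phases"]),
        death_time=death_time,
    )


def generate_sample(spec: SceneSpec, outdir) -> dict:
    """Render every frame of one scene to disk; returns output paths.

    Writes a multi-page two-channel TIFF (pages t0c0, t0c1, t1c0, …) with a
    JSON metadata sidecar, the ROI annotation file, the scene echo and the
    per-frame ground-truth tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames, truths, nucs, rois = [], [], [], []
    for f in range(spec.n_frames):
        img, truth, nuc = render_frame(spec, f)
        frames.append(img)
        truths.append(truth)
        if len(nuc):
            nucs.append(nuc)
        t = spec.hours_of_frame(f)
        for muscle in spec.muscles:
            if muscle.alive_at(t):
                cap = muscle.capsule_at(t, spec)
                rois.append(
                    MuscleROI(
                        muscle_id=muscle.muscle_id, frame_index=f,
                        contour=Contour(cap.contour_vertices()),
                        axis=MedialAxis(cap.axis_vertices()),
                    )
                )
    stack = np.stack(frames)  # (t, 2, h, w)
    meta = dict(
        pixel_size_um=spec.pixel_size, frame_interval_min=spec.frame_interval,
        he_frame=spec.he_frame,
        frame_hours=list(spec.frame_hours) if spec.frame_hours is not None else None,
    )
    paths = dict(
        tiff=outdir / "movie.tif", rois=outdir / "rois.json",
        truth=outdir / "truth_muscles.csv", nuclei=outdir / "truth_nuclei.csv",
        scene=outdir / "scene.json",
    )
    write_tiff(paths["tiff"], stack, meta)
    save_rois(rois, paths["rois"])
    pd.concat(truths, ignore_index=True).to_csv(paths["truth"], index=False)
    nuc_df = pd.concat(nucs, ignore_index=True) if nucs else pd.DataFrame()
    nuc_df.to_csv(paths["nuclei"], index=False)
    paths["scene"].write_text(spec.to_json(), encoding="utf-8")
    return paths


def generate_cohort(
    preset: str,
    n_samples: int,
    seed: int,
    outdir,
    profile: str = "fast",
    noise: NoiseSpec | None = None,
    sigma_log: float = 0.1,
) -> dict:
    """Generate a seeded cohort of samples following one genotype preset.

    Per-sample variation is multiplicative log-normal (σ = ``sigma_log``,
    truncated at ±2σ) on the area and diameter trajectories, drawn once per
    muscle and median-centred across the cohort so the cohort median trajectory
    equals the preset keyframes by construction.

    Returns a manifest dict with per-sample paths, genotype and the
    ground-truth tables concatenated across samples.
    """
    if preset not in _PRESETS:
        raise SceneError(
            f"unknown preset {preset!r}; valid presets: {', '.join(sorted(_PRESETS))}"
        )
    if n_samples < 1:
        raise SceneError("n_samples must be >= 1")
    profile_kw = dict(FAST_PROFILE if profile == "fast" else FULL_PROFILE)
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 101])
    la = np.clip(rng.normal(0, sigma_log, n_samples), -2 * sigma_log, 2 * sigma_log)
    ld = np.clip(rng.normal(0, sigma_log, n_samples), -2 * sigma_log, 2 * sigma_log)
    la -= np.median(la)
    ld -= np.median(ld)

    death_times = [None] * n_samples
    pconf = _PRESETS[preset]
    if "death_fraction" in pconf:
        n_dead = int(round(pconf["death_fraction"] * n_samples))
        dead_idx = rng.permutation(n_samples)[:n_dead]
        for i in dead_idx:
            death_times[i] = float(
                np.clip(rng.normal(pconf["death_mean_h"], pconf["death_sd_h"]), 25.0, 95.0)
            )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_rows, sample_paths, truth_frames, nuc_frames = [], [], [], []
    for i in range(n_samples):
        sample_id = f"{preset}_{i:03d}"
        muscle = build_preset(
            preset, muscle_id="DIOM 3L",
            area_mult=float(np.exp(la[i])), diam_mult=float(np.exp(ld[i])),
            death_time=death_times[i],
        )
        spec = SceneSpec(
            muscles=[muscle],
            noise=noise if noise is not None else NoiseSpec(),
            seed=int((seed * 10007 + 13 * i + 1) & 0x7FFFFFFF),
            **profile_kw,
        )
        paths = generate_sample(spec, outdir / sample_id)
        sample_paths.append(paths)
        truth = pd.read_csv(paths["truth"])
        truth.insert(0, "sample_id", sample_id)
        truth.insert(1, "genotype", preset)
        truth_frames.append(truth)
        nuc = pd.read_csv(paths["nuclei"])
        if len(nuc):
            nuc.insert(0, "sample_id", sample_id)
            nuc.insert(1, "genotype", preset)
            nuc_frames.append(nuc)
        manifest_rows.append(
            dict(sample_id=sample_id, genotype=preset, directory=str(outdir / sample_id),
                 death_time=death_times[i], area_mult=float(np.exp(la[i])),
                 diam_mult=float(np.exp(ld[i])))
        )
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return dict(
        preset=preset,
        manifest=manifest,
        samples=sample_paths,
        truth=pd.concat(truth_frames, ignore_index=True),
        nuclei=pd.concat(nuc_frames, ignore_index=True) if nuc_frames else pd.DataFrame(),
        outdir=outdir,
    )
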