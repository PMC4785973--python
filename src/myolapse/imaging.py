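"""Time-lapse stack I/O, concatenation, projections and orthogonal reslices.

In-memory contracts:

* :class:`TimeLapseVolume` — 5-D intensity array ``(t, channel, z, y, x)``
  with voxel spacing in μm and the acquisition interval in minutes.
* :class:`ProjectedSeries` — 4-D array ``(t, channel, y, x)`` produced by a
  projection, with provenance recorded.

On disk only generic multi-page TIFF is supported, pages ordered
``t0c0, t0c1, t1c0, …`` (channels interleaved within each time point, z fastest
within a channel when present), with a JSON sidecar (``<file>.meta.json``)
declaring the axis lengths and spacing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

__all__ = [
    "TimeLapseVolume",
    "ProjectedSeries",
    "concatenate",
    "max_project",
    "orthogonal_reslice",
    "write_tiff",
    "read_tiff",
]

_AXES = {"z": 2, "y": 3, "x": 4}


@dataclass
class TimeLapseVolume:
    """5-D fluorescence time lapse ``(t, channel, z, y, x)``."""

    voxels: np.ndarray
    spacing_um: tuple = (13.2, 1.25, 1.25)   # (z, y, x)
    frame_interval_min: float = 30.0

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 5:
            raise ValueError("voxels must be 5-D (t, channel, z, y, x)")
        if min(self.voxels.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        if min(self.spacing_um) <= 0:
            raise ValueError("spacing must be > 0")

    @property
    def n_frames(self) -> int:
        return self.voxels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[1]


@dataclass
class ProjectedSeries:
    """4-D projected time lapse ``(t, channel, y, x)`` with provenance."""

    frames: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4:
            raise ValueError("frames must be 4-D (t, channel, y, x)")

    def to_volume(self, spacing_um=(13.2, 1.25, 1.25), frame_interval_min=30.0):
        """Re-wrap as a single-slice volume (useful for reslicing MIPs)."""
        return TimeLapseVolume(
            self.frames[:, :, None, :, :], spacing_um, frame_interval_min
        )


def concatenate(stacks) -> TimeLapseVolume:
    """Join acquisitions along time, order preserved.

    All stacks must agree in channel/z/y/x dimensions and spacing; the
    offending stack is named otherwise.
    """
    stacks = list(stacks)
    if not stacks:
        raise ValueError("no stacks to concatenate")
    ref = stacks[0]
    for i, s in enumerate(stacks[1:], start=1):
        if s.voxels.shape[1:] != ref.voxels.shape[1:]:
            raise ValueError(
                f"stack {i} has shape {s.voxels.shape[1:]} (channel, z, y, x), "
                f"expected {ref.voxels.shape[1:]}"
            )
        if tuple(s.spacing_um) != tuple(ref.spacing_um):
            raise ValueError(f"stack {i} spacing {s.spacing_um} != {ref.spacing_um}")
    return TimeLapseVolume(
        np.concatenate([s.voxels for s in stacks], axis=0),
        ref.spacing_um,
        ref.frame_interval_min,
    )


def max_project(volume: TimeLapseVolume, axis: str = "z") -> ProjectedSeries:
    """Maximum-intensity projection along a spatial axis (default z).

    Each output pixel is the maximum over the projected axis; idempotent on
    data whose projected axis has length 1.
    """
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {sorted(_AXES)}, got {axis!r}")
    frames = volume.voxels.max(axis=_AXES[axis])
    return ProjectedSeries(frames, provenance={"projection": "max", "axis": axis})


def orthogonal_reslice(volume: TimeLapseVolume, polyline, frame: int, channel: int = 0):
    """Cross-section through a z-stack along an x-y polyline, plus depth.

    The polyline (pixel coordinates ``[[x, y], …]``) is sampled at 1-px arc
    steps; each sample contributes one column of the returned section image
    ``(z, arc)``.  ``depth_profile[j]`` is the z extent (μm, using the z
    spacing) over which column ``j`` stays at or above half its maximum; 0 for
    empty columns.
    """
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("polyline must be an (N>=2, 2) array of x, y")
    t, c, nz, ny, nx = volume.voxels.shape
    if not 0 <= frame < t:
        raise ValueError(f"frame {frame} outside [0, {t})")
    if np.any(pts[:, 0] < 0) or np.any(pts[:, 0] > nx - 1) or \
       np.any(pts[:, 1] < 0) or np.any(pts[:, 1] > ny - 1):
        raise ValueError("polyline extends outside the image bounds")

    seg = np.diff(pts, axis=0)
    lens = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(lens)])
    arc = np.arange(0.0, cum[-1] + 1e-9, 1.0)
    xs = np.interp(arc, cum, pts[:, 0])
    ys = np.interp(arc, cum, pts[:, 1])

    section = np.empty((nz, len(arc)), dtype=float)
    data = volume.voxels[frame, channel].astype(float)
    for iz in range(nz):
        section[iz] = ndimage.map_coordinates(
            data[iz], np.vstack([ys, xs]), order=1, mode="nearest"
        )
    z_um = volume.spacing_um[0]
    col_max = section.max(axis=0)
    depth = np.zeros(len(arc))
    nonzero = col_max > 0
    if np.any(nonzero):
        above = section[:, nonzero] >= col_max[nonzero] / 2.0
        depth[nonzero] = above.sum(axis=0) * z_um
    return section, depth


# --- TIFF round trip -------------------------------------------------------

def write_tiff(path, frames: np.ndarray, meta: dict | None = None) -> None:
    """Write a ``(t, c, y, x)`` or ``(t, c, z, y, x)`` array as multi-page TIFF.

    Pages are ordered t → channel (→ z); axis lengths and any extra metadata
    go to the ``<file>.meta.json`` sidecar.
    """
    frames = np.asarray(frames)
    if frames.ndim not in (4, 5):
        raise ValueError("frames must be (t, c, y, x) or (t, c, z, y, x)")
    pages = frames.reshape((-1,) + frames.shape[-2:])
    tifffile.imwrite(Path(path), pages)
    sidecar = dict(meta or {})
    sidecar["shape"] = list(frames.shape)
    sidecar["axes"] = "TCYX" if frames.ndim == 4 else "TCZYX"
    Path(str(path) + ".meta.json").write_text(
        json.dumps(sidecar, indent=1), encoding="utf-8"
    )


def read_tiff(path):
    """Read a TIFF written by :func:`write_tiff`; returns ``(array, meta)``."""
    pages = tifffile.imread(Path(path))
    sidecar_path = Path(str(path) + ".meta.json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text(encoding="utf-8"))
        shape = tuple(meta["shape"])
        return pages.reshape(shape), meta
    # no sidecar: assume single-channel 2-D time series
    if pages.ndim == 2:
        pages = pages[None]
    return pages[:, None, :, :], {}
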