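"""Experiment metadata, head-eversion time alignment and a relational store.

All series are aligned to the onset of head eversion (HE) as time zero, so
feature trajectories from different pupae are comparable on a common clock of
signed "hours aHE".  Genotype comparisons are made on a canonical 13-point
analysis grid (5–100 h aHE).  Records persist in an embedded single-file
SQLite database with tables ``experiments``, ``rois``, ``features`` and
``nuclei``.
"""

from __future__ import annotations

import json
import sqlite3
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_GRID_H",
    "ExperimentMeta",
    "AlignedSeries",
    "canonical_grid",
    "frame_to_hours_aHE",
    "snap_to_grid",
    "expected_frame_count",
    "ExperimentDB",
]

#: the 13 analysis time points in hours aHE
CANONICAL_GRID_H = (5, 10, 15, 20, 25, 30, 40, 50, 60, 70, 80, 90, 100)


def canonical_grid() -> list:
    """The canonical analysis grid: [5, 10, 15, 20, 25, 30, 40, ..., 100] h aHE."""
    return list(CANONICAL_GRID_H)


@dataclass
class ExperimentMeta:
    """Acquisition parameters of one sample (pupa)."""

    sample_id: str
    genotype: str
    pixel_size_um: float = 1.25
    frame_interval_min: float = 30.0
    he_frame: int = 24
    temperature: str | None = "22C"
    #: explicit hours aHE per frame; overrides the affine clock when set
    frame_hours: tuple | None = None

    def __post_init__(self):
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be > 0")
        if self.he_frame < 0:
            raise ValueError("he_frame must be >= 0")
        if self.frame_hours is not None:
            self.frame_hours = tuple(float(h) for h in self.frame_hours)


def frame_to_hours_aHE(frame_index: int, meta: ExperimentMeta) -> float:
    """Signed hours after head eversion of a frame; negative before HE."""
    if meta.frame_hours is not None:
        return meta.frame_hours[frame_index]
    return (frame_index - meta.he_frame) * meta.frame_interval_min / 60.0


def expected_frame_count(duration_days: float, interval_min: float) -> int:
    """Number of time points in an acquisition, floored (5 d @ 30 min → 240)."""
    if duration_days <= 0 or interval_min <= 0:
        raise ValueError("duration and interval must be positive")
    return int(duration_days * 24 * 60 // interval_min)


@dataclass
class AlignedSeries:
    """Per-muscle feature trajectory on the aHE clock.

    ``points`` is a list of ``(hours aHE, value-or-record)`` with strictly
    increasing hours.
    """

    muscle_id: str
    genotype: str = ""
    points: list = field(default_factory=list)

    def __post_init__(self):
        hours = [h for h, _ in self.points]
        if any(b <= a for a, b in zip(hours, hours[1:])):
            raise ValueError("hours must be strictly increasing")

    @property
    def hours(self) -> np.ndarray:
        return np.array([h for h, _ in self.points], dtype=float)


def snap_to_grid(series: AlignedSeries, tolerance_h: float = 0.25) -> dict:
    """Map observations onto the canonical grid by nearest time within tolerance.

    Returns ``{grid hour: observed value}``; grid slots with no observation
    within ``tolerance_h`` are absent.  Values are never interpolated or
    fabricated — every output value is one of the input values.
    """
    if not series.points:
        raise ValueError("series is empty")
    hours = series.hours
    out = {}
    for g in CANONICAL_GRID_H:
        i = int(np.argmin(np.abs(hours - g)))
        if abs(hours[i] - g) <= tolerance_h:
            out[g] = series.points[i][1]
    return out


# --- embedded relational store --------------------------------------------

_SCHEMA = """
CREATE TABLE IF NOT EXISTS experiments (
    sample_id TEXT PRIMARY KEY,
    genotype TEXT NOT NULL,
    pixel_size_um REAL NOT NULL,
    frame_interval_min REAL NOT NULL,
    he_frame INTEGER NOT NULL,
    temperature TEXT,
    frame_hours TEXT
);
CREATE TABLE IF NOT EXISTS rois (
    sample_id TEXT NOT NULL REFERENCES experiments(sample_id),
    muscle_id TEXT NOT NULL,
    frame INTEGER NOT NULL,
    contour TEXT NOT NULL,
    axis TEXT NOT NULL,
    PRIMARY KEY (sample_id, muscle_id, frame)
);
CREATE TABLE IF NOT EXISTS features (
    sample_id TEXT NOT NULL REFERENCES experiments(sample_id),
    muscle_id TEXT NOT NULL,
    frame INTEGER NOT NULL,
    hours_ahe REAL NOT NULL,
    area_um2 REAL,
    length_um REAL,
    diameter_um REAL,
    PRIMARY KEY (sample_id, muscle_id, frame)
);
CREATE TABLE IF NOT EXISTS nuclei (
    sample_id TEXT NOT NULL REFERENCES experiments(sample_id),
    muscle_id TEXT NOT NULL,
    frame INTEGER NOT NULL,
    nucleus INTEGER NOT NULL,
    x_px REAL, y_px REAL,
    axial_u REAL, lateral_d_um REAL,
    PRIMARY KEY (sample_id, muscle_id, frame, nucleus)
);
"""

FEATURE_COLUMNS = ("area_um2", "length_um", "diameter_um")


class ExperimentDB:
    """Single-file SQLite store for experiments, ROIs, features and nuclei."""

    def __init__(self, path=":memory:"):
        self.path = str(path)
        self.conn = sqlite3.connect(self.path)
        self.conn.execute("PRAGMA foreign_keys = ON")
        self.conn.executescript(_SCHEMA)

    def close(self):
        self.conn.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    # -- writes -------------------------------------------------------------

    def add_experiment(self, meta: ExperimentMeta) -> None:
        fh = json.dumps(list(meta.frame_hours)) if meta.frame_hours is not None else None
        with self.conn:
            self.conn.execute(
                "INSERT INTO experiments VALUES (?,?,?,?,?,?,?)",
                (meta.sample_id, meta.genotype, meta.pixel_size_um,
                 meta.frame_interval_min, meta.he_frame, meta.temperature, fh),
            )

    def add_features(self, frame_df: pd.DataFrame) -> None:
        """Insert feature rows: columns sample_id, muscle_id, frame, hours_ahe,
        area_um2, length_um, diameter_um."""
        cols = ["sample_id", "muscle_id", "frame", "hours_ahe", *FEATURE_COLUMNS]
        rows = frame_df[cols].itertuples(index=False, name=None)
        with self.conn:
            self.conn.executemany(
                "INSERT INTO features VALUES (?,?,?,?,?,?,?)", rows
            )

    def add_roi(self, sample_id, muscle_id, frame, contour, axis) -> None:
        with self.conn:
            self.conn.execute(
                "INSERT INTO rois VALUES (?,?,?,?,?)",
                (sample_id, muscle_id, int(frame),
                 json.dumps(np.asarray(contour).tolist()),
                 json.dumps(np.asarray(axis).tolist())),
            )

    def add_nuclei(self, nuc_df: pd.DataFrame) -> None:
        cols = ["sample_id", "muscle_id", "frame", "nucleus",
                "x_px", "y_px", "axial_u", "lateral_d_um"]
        with self.conn:
            self.conn.executemany(
                "INSERT INTO nuclei VALUES (?,?,?,?,?,?,?,?)",
                nuc_df[cols].itertuples(index=False, name=None),
            )

    # -- queries ------------------------------------------------------------

    def experiments(self) -> pd.DataFrame:
        return pd.read_sql_query("SELECT * FROM experiments", self.conn)

    def query_features(
        self,
        genotype: str | None = None,
        muscle_id: str | None = None,
        grid_time: float | None = None,
        tolerance_h: float = 0.25,
    ) -> pd.DataFrame:
        q = ("SELECT f.*, e.genotype FROM features f "
             "JOIN experiments e ON f.sample_id = e.sample_id WHERE 1=1")
        args = []
        if genotype is not None:
            q += " AND e.genotype = ?"
            args.append(genotype)
        if muscle_id is not None:
            q += " AND f.muscle_id = ?"
            args.append(muscle_id)
        if grid_time is not None:
            q += " AND f.hours_ahe BETWEEN ? AND ?"
            args += [grid_time - tolerance_h, grid_time + tolerance_h]
        return pd.read_sql_query(q, self.conn, params=args)

    def feature_values(self, genotype: str, feature: str, grid_time: float,
                       tolerance_h: float = 0.25) -> np.ndarray:
        if feature not in FEATURE_COLUMNS:
            raise ValueError(f"feature must be one of {FEATURE_COLUMNS}")
        df = self.query_features(genotype=genotype, grid_time=grid_time,
                                 tolerance_h=tolerance_h)
        return df[feature].to_numpy(dtype=float)

    def counts_by_genotype_and_grid(self, tolerance_h: float = 0.25) -> pd.DataFrame:
        """Tally of scored ROIs per genotype and canonical grid time."""
        rows = []
        for genotype in self.experiments()["genotype"].unique():
            for g in CANONICAL_GRID_H:
                n = len(self.query_features(genotype=genotype, grid_time=g,
                                            tolerance_h=tolerance_h))
                rows.append(dict(genotype=genotype, grid_h=g, n=n))
        return pd.DataFrame(rows)

    def aligned_series(self, genotype: str, feature: str) -> list:
        """One AlignedSeries per (sample, muscle) of a genotype."""
        df = self.query_features(genotype=genotype)
        out = []
        for (sid, mid), grp in df.groupby(["sample_id", "muscle_id"]):
            grp = grp.sort_values("hours_ahe")
            out.append(
                AlignedSeries(
                    muscle_id=f"{sid}/{mid}", genotype=genotype,
                    points=list(zip(grp["hours_ahe"], grp[feature])),
                )
            )
        return out

    def export_features_csv(self, path) -> None:
        self.query_features().to_csv(path, index=False)

    def import_features_csv(self, path) -> None:
        self.add_features(pd.read_csv(path))
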