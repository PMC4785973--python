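"""Group statistics for head-eversion-aligned muscle feature trajectories.

The statistical surface deliberately mirrors a small, documented contract:

* per-timepoint medians with 25/75 percentiles;
* two-sample Mann–Whitney U rank-sum tests with midranks for ties, an exact
  null distribution for small tie-free samples, a minimum group size of 5 and
  p-values clipped to [0.0001, 1];
* per-muscle normalization to a reference time point (value at the reference
  is 100 %), performed before any group aggregation;
* explicit-direction fold changes, Pearson trajectory correlations, and
  n-weighted means of times written in h.min (hours.minutes) notation.

No multiple-testing correction is applied: comparisons report raw
per-timepoint p-values against a 0.05 threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "P_FLOOR",
    "MIN_GROUP_SIZE",
    "MinimumSampleSizeError",
    "median_iqr",
    "mwu_test",
    "normalize_to_reference",
    "normalize_cohort",
    "fold_change",
    "trajectory_correlation",
    "weighted_mean_time",
    "GroupSummary",
    "GroupComparison",
    "compare_genotypes",
]

P_FLOOR = 1e-4
MIN_GROUP_SIZE = 5
EXACT_LIMIT = 20  # exact null distribution up to this combined sample size


class MinimumSampleSizeError(ValueError):
    """Raised when a group is below the documented minimum sample size of 5."""


def median_iqr(values):
    """Median with 25/75 percentiles (linear interpolation between order stats)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("median_iqr of an empty sample")
    med, q25, q75 = np.percentile(values, [50, 25, 75])
    return float(med), float(q25), float(q75)


def _u_distribution(n: int, m: int) -> np.ndarray:
    """Exact null distribution counts of the U statistic for group sizes (n, m).

    counts[u] = number of the C(n+m, n) equally likely rank assignments whose
    rank-sum statistic U equals u, computed by dynamic programming over
    f[k][s] = number of size-k subsets of ranks {1..N} with rank sum s.
    """
    umax = n * m
    N = n + m
    smax = N * (N + 1) // 2
    f = np.zeros((n + 1, smax + 1), dtype=float)
    f[0, 0] = 1.0
    for r in range(1, N + 1):
        for k in range(min(n, r), 0, -1):
            f[k, r:] += f[k - 1, :-r] if r > 0 else f[k - 1, :]
    sums = np.arange(smax + 1)
    counts = np.zeros(umax + 1)
    smin = n * (n + 1) // 2
    valid = (sums >= smin) & (sums - smin <= umax)
    counts[(sums[valid] - smin)] = f[n, valid]
    return counts


def mwu_test(a, b, tail: str = "two", method: str = "auto") -> float:
    """Mann–Whitney U test p-value with the documented software contract.

    Tails: ``left`` tests the alternative "A below B", ``right`` "A above B",
    ``two`` is two-sided.  Ties receive midranks.  With ``method='auto'``,
    tie-free samples with ``len(a) + len(b) <= 20`` use the exact permutation
    null distribution of U; otherwise the normal approximation with
    continuity and tie correction (``'exact'``/``'approx'`` force a method;
    ``'exact'`` rejects ties).  Each group must contain at least 5 values;
    the returned p is clipped to [0.0001, 1].
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < MIN_GROUP_SIZE or len(b) < MIN_GROUP_SIZE:
        raise MinimumSampleSizeError(
            f"the Mann-Whitney U test requires a minimum sample size of "
            f"{MIN_GROUP_SIZE} per group (got {len(a)} and {len(b)})"
        )
    if tail not in ("left", "right", "two"):
        raise ValueError("tail must be 'left', 'right' or 'two'")
    if method not in ("auto", "exact", "approx"):
        raise ValueError("method must be 'auto', 'exact' or 'approx'")
    n, m = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    has_ties = len(np.unique(pooled)) < n + m
    u_a = float(ranks[:n].sum()) - n * (n + 1) / 2.0

    if method == "exact" and has_ties:
        raise ValueError("exact method requires tie-free samples")
    use_exact = (method == "exact") or (
        method == "auto" and n + m <= EXACT_LIMIT and not has_ties
    )
    if use_exact:
        counts = _u_distribution(n, m)
        total = counts.sum()
        k = int(round(u_a))
        p_left = counts[: k + 1].sum() / total
        p_right = counts[k:].sum() / total
    else:
        mu = n * m / 2.0
        N = n + m
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (N * (N - 1))
        var = n * m / 12.0 * ((N + 1) - tie_term)
        if var <= 0:
            p_left = p_right = 1.0
        else:
            sd = math.sqrt(var)
            p_left = float(norm.cdf((u_a - mu + 0.5) / sd))
            p_right = float(norm.sf((u_a - mu - 0.5) / sd))

    if tail == "left":
        p = p_left
    elif tail == "right":
        p = p_right
    else:
        p = min(1.0, 2.0 * min(p_left, p_right))
    return float(min(1.0, max(P_FLOOR, p)))


@dataclass
class NormalizedSeries:
    """Per-muscle trajectory expressed as % of its value at a reference time."""

    muscle_id: str
    ref_time_h: float
    points: list  # (hours aHE, percent of reference)


def normalize_to_reference(series, ref_time_h: float, muscle_id: str = "",
                           tolerance_h: float = 0.25) -> NormalizedSeries:
    """Express one series as percent of its own value at ``ref_time_h``.

    ``series`` is a list of ``(hours, value)``.  The reference value is the
    observation nearest to ``ref_time_h`` within ``tolerance_h``; a missing or
    non-positive reference raises ``ValueError`` (callers aggregating cohorts
    should exclude such series with a warning, see :func:`normalize_cohort`).
    """
    pts = [(float(h), float(v)) for h, v in series]
    if not pts:
        raise ValueError("empty series")
    hours = np.array([h for h, _ in pts])
    i = int(np.argmin(np.abs(hours - ref_time_h)))
    if abs(hours[i] - ref_time_h) > tolerance_h:
        raise ValueError(f"no observation within {tolerance_h} h of {ref_time_h} h")
    ref = pts[i][1]
    if ref <= 0:
        raise ValueError("reference value must be positive")
    return NormalizedSeries(
        muscle_id=muscle_id, ref_time_h=ref_time_h,
        points=[(h, 100.0 * v / ref) for h, v in pts],
    )


def normalize_cohort(cohort: dict, ref_time_h: float, tolerance_h: float = 0.25):
    """Normalize every series of ``{muscle_id: [(h, v), …]}``; skip + warn.

    Returns ``(normalized dict, warnings list)`` where warnings name the
    excluded muscles (no usable reference value).  Normalization is per muscle,
    before any group aggregation.
    """
    out, warnings = {}, []
    for mid, series in cohort.items():
        try:
            out[mid] = normalize_to_reference(series, ref_time_h, muscle_id=mid,
                                              tolerance_h=tolerance_h)
        except ValueError as exc:
            warnings.append(f"{mid}: excluded from normalization ({exc})")
    return out, warnings


def fold_change(v_from: float, v_to: float, direction: str = "auto",
                ndigits: int | None = None) -> float:
    """Fold change between two positive values with explicit direction.

    ``increase`` returns v_to / v_from, ``decline`` returns v_from / v_to;
    ``auto`` picks the direction that yields a fold >= 1.  Optional rounding
    to ``ndigits`` decimals.
    """
    if v_from <= 0 or v_to <= 0:
        raise ValueError("fold_change requires positive values")
    if direction == "auto":
        direction = "increase" if v_to >= v_from else "decline"
    if direction == "increase":
        fold = v_to / v_from
    elif direction == "decline":
        fold = v_from / v_to
    else:
        raise ValueError("direction must be 'auto', 'increase' or 'decline'")
    return round(fold, ndigits) if ndigits is not None else fold


def trajectory_correlation(medians_a, medians_b) -> float:
    """Pearson r between two median trajectories on a shared grid.

    Requires at least 3 shared points; returns NaN (flagged undefined) when
    either input has zero variance.
    """
    x = np.asarray(medians_a, dtype=float)
    y = np.asarray(medians_b, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need >= 3 paired grid points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def _parse_hmin(value) -> int:
    """Parse h.min notation (e.g. '108.22' = 108 h 22 min) into minutes."""
    text = f"{float(value):.2f}" if not isinstance(value, str) else value
    if "." not in text:
        text += ".00"
    hours_s, minutes_s = text.split(".")
    try:
        hours, minutes = int(hours_s), int(minutes_s.ljust(2, "0")[:2])
    except ValueError as exc:
        raise ValueError(f"malformed h.min value {value!r}") from exc
    if not 0 <= minutes < 60:
        raise ValueError(f"minutes out of range in h.min value {value!r}")
    return hours * 60 + minutes


def weighted_mean_time(rows) -> str:
    """n-weighted mean of times in h.min notation, rounded to the minute.

    ``rows`` is an iterable of ``(h.min, n)``.  Returns the mean formatted in
    the same notation, e.g. ``'107.04'``.
    """
    total_minutes, total_n = 0, 0
    for value, n in rows:
        if n < 1:
            raise ValueError("each row needs n >= 1")
        total_minutes += _parse_hmin(value) * n
        total_n += n
    if total_n == 0:
        raise ValueError("no rows")
    mean = round(total_minutes / total_n)
    return f"{mean // 60}.{mean % 60:02d}"


# --- genotype comparison ---------------------------------------------------

@dataclass
class GroupSummary:
    genotype: str
    grid_h: float
    n: int
    median: float
    q25: float
    q75: float


@dataclass
class GroupComparison:
    """Per-grid-time summaries of two genotypes with tail-specific MWU p-values.

    Grid times where either group is below the minimum sample size are
    reported as untested (p is None), never as p = 1.
    """

    feature: str
    genotype_a: str
    genotype_b: str
    tail: str
    rows: list = field(default_factory=list)
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for g, sa, sb, p in self.rows:
            recs.append(dict(
                grid_h=g,
                nA=sa.n if sa else 0, medianA=sa.median if sa else np.nan,
                q25A=sa.q25 if sa else np.nan, q75A=sa.q75 if sa else np.nan,
                nB=sb.n if sb else 0, medianB=sb.median if sb else np.nan,
                q25B=sb.q25 if sb else np.nan, q75B=sb.q75 if sb else np.nan,
                tail=self.tail, p=p,
                significant=(p is not None and p < self.alpha),
                tested=p is not None,
            ))
        return pd.DataFrame(recs)

    def significant_times(self) -> list:
        return [g for g, _, _, p in self.rows if p is not None and p < self.alpha]

    def plot(self, path) -> None:
        """Two-panel figure: median ± IQR over time, and log10 p with the
        significance threshold line."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        df = self.to_frame()
        fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(7, 6),
                                       height_ratios=[2, 1])
        for side, label in (("A", self.genotype_a), ("B", self.genotype_b)):
            sub = df[df[f"n{side}"] > 0]
            med = sub[f"median{side}"].to_numpy()
            ax1.errorbar(
                sub["grid_h"].to_numpy(), med,
                yerr=[med - sub[f"q25{side}"].to_numpy(),
                      sub[f"q75{side}"].to_numpy() - med],
                marker="o", capsize=3, label=label,
            )
        ax1.set_ylabel(self.feature)
        ax1.legend()
        tested = df[df["tested"]]
        ax2.plot(tested["grid_h"], np.log10(tested["p"].astype(float)), "ko-")
        ax2.axhline(np.log10(self.alpha), linestyle="--", color="grey")
        ax2.set_xlabel("hours aHE")
        ax2.set_ylabel("log10 p (MWU)")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def compare_genotypes(db, feature: str, genotype_a: str, genotype_b: str,
                      tail: str = "two", tolerance_h: float = 0.25,
                      alpha: float = 0.05) -> GroupComparison:
    """Per-canonical-grid-time comparison of two genotypes from the store.

    For each grid time both groups are summarized (median, 25/75 %-tiles);
    the MWU p-value is computed when both groups meet the minimum sample size,
    otherwise the time point is flagged untested.
    """
    from .store import CANONICAL_GRID_H

    comparison = GroupComparison(feature=feature, genotype_a=genotype_a,
                                 genotype_b=genotype_b, tail=tail, alpha=alpha)
    any_tested = False
    for g in CANONICAL_GRID_H:
        va = db.feature_values(genotype_a, feature, g, tolerance_h)
        vb = db.feature_values(genotype_b, feature, g, tolerance_h)
        sa = GroupSummary(genotype_a, g, len(va), *median_iqr(va)) if len(va) else None
        sb = GroupSummary(genotype_b, g, len(vb), *median_iqr(vb)) if len(vb) else None
        if len(va) >= MIN_GROUP_SIZE and len(vb) >= MIN_GROUP_SIZE:
            p = mwu_test(va, vb, tail)
            any_tested = True
        else:
            p = None
        comparison.rows.append((g, sa, sb, p))
    if not any_tested:
        raise MinimumSampleSizeError(
            f"no grid time has n >= {MIN_GROUP_SIZE} in both "
            f"{genotype_a!r} and {genotype_b!r}"
        )
    return comparison
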