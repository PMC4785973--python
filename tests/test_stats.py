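"""Rank statistics, normalization, fold changes and weighted-mean summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from myolapse import reference
from myolapse.stats import (
    MinimumSampleSizeError,
    compare_genotypes,
    fold_change,
    median_iqr,
    mwu_test,
    normalize_cohort,
    normalize_to_reference,
    trajectory_correlation,
    weighted_mean_time,
)
from myolapse.store import ExperimentDB, ExperimentMeta

import pandas as pd


class TestMedianIqr:
    def test_one_to_five(self):
        assert median_iqr([1, 2, 3, 4, 5]) == (3, 2, 4)

    def test_degenerate_single(self):
        assert median_iqr([7]) == (7, 7, 7)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_iqr([])

    def test_order_statistics_oracle(self, rng):
        """Linear-interpolation percentiles vs an explicit sort-and-index oracle."""
        values = rng.uniform(0, 1, 1000)
        med, q25, q75 = median_iqr(values)
        s = np.sort(values)

        def percentile(q):
            pos = q * (len(s) - 1)
            lo, frac = int(pos), pos - int(pos)
            return s[lo] * (1 - frac) + s[min(lo + 1, len(s) - 1)] * frac

        assert med == pytest.approx(percentile(0.50), abs=1e-12)
        assert q25 == pytest.approx(percentile(0.25), abs=1e-12)
        assert q75 == pytest.approx(percentile(0.75), abs=1e-12)


class TestMwu:
    def test_exact_extreme_left(self):
        """Fully separated 5v5: exact left p = 1/C(10,5) = 1/252."""
        p = mwu_test([1, 2, 3, 4, 5], [6, 7, 8, 9, 10], "left")
        assert p == pytest.approx(1 / 252, abs=1e-12)

    def test_exact_ceiling(self):
        p = mwu_test([6, 7, 8, 9, 10], [1, 2, 3, 4, 5], "left")
        assert p == 1.0

    def test_floor_clipping(self):
        a = np.arange(50, dtype=float)
        b = a + 1000.0
        assert mwu_test(a, b, "left") == 0.0001

    def test_minimum_sample_size_enforced(self):
        with pytest.raises(MinimumSampleSizeError, match="minimum sample size"):
            mwu_test([1, 2, 3, 4], [5, 6, 7, 8, 9], "two")

    def test_scipy_oracle_exact(self, rng):
        """Exact tail probabilities agree with the scipy reference."""
        for _ in range(20):
            a = rng.permutation(np.arange(40.0))[:7]
            b = rng.permutation(np.arange(100.0, 140.0))[:8]
            pooled = np.concatenate([a, b])
            if len(np.unique(pooled)) < 15:
                continue
            ours = mwu_test(a, b, "left", method="exact")
            ref = sps.mannwhitneyu(a, b, alternative="less", method="exact").pvalue
            assert ours == pytest.approx(max(min(ref, 1.0), 1e-4), abs=1e-12)

    def test_exact_vs_normal_approximation(self, rng):
        """For tie-free samples ≤ 20 the approximation stays within 0.01."""
        for _ in range(25):
            pool = rng.permutation(np.arange(200.0))
            a, b = pool[:9], pool[9:19]
            for tail in ("left", "right", "two"):
                pe = mwu_test(a, b, tail, method="exact")
                pa = mwu_test(a, b, tail, method="approx")
                assert abs(pe - pa) < 0.01

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        a=st.lists(st.floats(-50, 50, allow_nan=False), min_size=5, max_size=12),
        b=st.lists(st.floats(-50, 50, allow_nan=False), min_size=5, max_size=12),
    )
    def test_duality_and_clipping(self, a, b):
        """p_left(a,b) = p_right(b,a) exactly; sum ≥ 1; p within [1e-4, 1]."""
        pl = mwu_test(a, b, "left")
        pr_swapped = mwu_test(b, a, "right")
        pr = mwu_test(a, b, "right")
        assert pl == pytest.approx(pr_swapped, abs=1e-12)
        assert pl + pr >= 1.0 - 1e-9
        for p in (pl, pr, mwu_test(a, b, "two")):
            assert 1e-4 <= p <= 1.0


class TestNormalization:
    SERIES = [(5.0, 200.0), (50.0, 100.0), (100.0, 260.0)]

    def test_reference_is_100(self):
        norm = normalize_to_reference(self.SERIES, 5.0)
        assert dict(norm.points)[5.0] == 100.0

    def test_halving_is_50(self):
        assert dict(normalize_to_reference(self.SERIES, 5.0).points)[50.0] == 50.0

    def test_scale_invariance(self):
        scaled = [(h, v * 7.3) for h, v in self.SERIES]
        a = normalize_to_reference(self.SERIES, 5.0).points
        b = normalize_to_reference(scaled, 5.0).points
        assert a == pytest.approx(b)

    def test_missing_reference_excluded_with_warning(self):
        cohort = {"ok": self.SERIES, "bad": [(50.0, 1.0)]}
        normed, warnings = normalize_cohort(cohort, 5.0)
        assert set(normed) == {"ok"}
        assert len(warnings) == 1 and "bad" in warnings[0]

    def test_control_cohort_drops_to_about_a_third(self, control_features):
        """Per-muscle normalized control areas: median ≈ 34% at +50 h."""
        cohort = {
            sid: list(zip(grp.hours_ahe, grp.area_um2))
            for sid, grp in control_features.groupby("sample_id")
        }
        normed, warnings = normalize_cohort(cohort, 5.0)
        assert not warnings
        at50 = [dict(n.points)[50.0] for n in normed.values()]
        assert np.median(at50) == pytest.approx(100 * 6038 / 17925, rel=0.05)


class TestFoldChange:
    def test_regrowth_example(self):
        assert fold_change(6038, 15719, "increase", ndigits=1) == 2.6

    def test_decline_example(self):
        assert fold_change(8755, 3596, "decline", ndigits=1) == 2.4

    def test_identity(self):
        assert fold_change(5.0, 5.0) == 1.0

    def test_auto_direction(self):
        assert fold_change(10, 30) == pytest.approx(3.0)
        assert fold_change(30, 10) == pytest.approx(3.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fold_change(0, 5)


class TestTrajectoryCorrelation:
    def test_self_correlation(self):
        x = [1.0, 2.0, 5.0, 3.0]
        assert trajectory_correlation(x, x) == pytest.approx(1.0)

    def test_negation(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert trajectory_correlation(x, -x) == pytest.approx(-1.0)

    def test_covariance_formula_oracle(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        r = trajectory_correlation(x, y)
        expected = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert r == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_flagged_nan(self):
        assert np.isnan(trajectory_correlation([1, 1, 1], [1, 2, 3]))

    def test_area_diameter_strongly_correlated(self, control_features):
        """Median area and diameter trajectories co-vary (r close to 1)."""
        med = control_features.groupby("hours_ahe")[["area_um2", "diameter_um"]].median()
        r = trajectory_correlation(med.area_um2, med.diameter_um)
        assert r > 0.9


class TestWeightedMeanTime:
    def test_eclosion_summary_total(self):
        assert weighted_mean_time(reference.eclosion_rows()) == "107.04"

    def test_single_row(self):
        assert weighted_mean_time([("108.22", 5)]) == "108.22"

    def test_midpoint_carries_minutes(self):
        assert weighted_mean_time([("100.00", 1), ("101.00", 1)]) == "100.30"

    def test_malformed_minutes_rejected(self):
        with pytest.raises(ValueError, match="h.min"):
            weighted_mean_time([("100.75", 2)])

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            weighted_mean_time([("100.00", 0)])


class TestCompareGenotypes:
    def _db(self, values_by_genotype, hours=50.0):
        db = ExperimentDB()
        rows = []
        for genotype, values in values_by_genotype.items():
            for i, v in enumerate(values):
                sid = f"{genotype}_{i}"
                db.add_experiment(ExperimentMeta(sample_id=sid, genotype=genotype))
                rows.append(dict(sample_id=sid, muscle_id="m", frame=0,
                                 hours_ahe=hours, area_um2=v, length_um=v,
                                 diameter_um=v))
        db.add_features(pd.DataFrame(rows))
        return db

    def test_identical_cohorts_never_significant(self):
        values = list(np.linspace(10, 20, 8))
        db = self._db({"A": values, "B": values})
        comp = compare_genotypes(db, "area_um2", "A", "B", tail="two")
        assert comp.significant_times() == []
        db.close()

    def test_small_group_untested_not_p1(self):
        db = self._db({"A": [1, 2, 3, 4], "B": [5, 6, 7, 8, 9]})
        db2 = self._db({"A": [1, 2, 3, 4, 5], "B": [6, 7, 8, 9, 10]})
        with pytest.raises(MinimumSampleSizeError):
            compare_genotypes(db, "area_um2", "A", "B")
        comp = compare_genotypes(db2, "area_um2", "A", "B", tail="left")
        df = comp.to_frame()
        tested = df[df.tested]
        assert list(tested.grid_h) == [50]
        assert (~df[df.grid_h != 50].tested).all()
        db.close()
        db2.close()

    def test_export_and_plot(self, tmp_path):
        db = self._db({"A": list(range(5)), "B": list(range(10, 15))})
        comp = compare_genotypes(db, "area_um2", "A", "B", tail="left")
        df = comp.to_frame()
        assert {"grid_h", "nA", "medianA", "q25A", "q75A", "nB", "tail", "p"} <= set(df.columns)
        comp.plot(tmp_path / "cmp.png")
        assert (tmp_path / "cmp.png").stat().st_size > 0
        db.close()
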