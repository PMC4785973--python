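"""Generator contracts: rendering, determinism, closed-form truth, presets."""

import math

import numpy as np
import pytest

from myolapse.synthetic import (
    Capsule,
    MuscleSpec,
    NoiseSpec,
    NucleiProgram,
    SceneError,
    SceneSpec,
    build_preset,
    generate_cohort,
    nuclei_positions,
    preset_names,
    render_frame,
)


def one_muscle_scene(**kw):
    muscle = MuscleSpec(
        muscle_id="DIOM 3L",
        area_keyframes=[(5.0, 4000.0), (100.0, 4000.0)],
        diameter_keyframes=[(5.0, 30.0), (100.0, 30.0)],
        orientation_keyframes=[(5.0, 20.0)],
        nuclei=NucleiProgram(n_nuclei=kw.pop("n_nuclei", 0)),
    )
    return SceneSpec(image_size=(256, 256), he_frame=0, frame_hours=(5.0,),
                     muscles=[muscle], **kw)


class TestRenderFrame:
    def test_noiseless_foreground_background(self):
        spec = one_muscle_scene()
        img, truth, _ = render_frame(spec, 0)
        cap = spec.muscles[0].capsule_at(5.0, spec)
        yy, xx = np.mgrid[0:256, 0:256]
        e0, e1 = cap.endpoints()
        seg = e1 - e0
        tt = np.clip(((xx - e0[0]) * seg[0] + (yy - e0[1]) * seg[1]) / (seg @ seg), 0, 1)
        d = np.hypot(xx - (e0[0] + tt * seg[0]), yy - (e0[1] + tt * seg[1]))
        assert np.all(img[0][d <= cap.radius_px - 1] == spec.foreground_level)
        assert np.all(img[0][d >= cap.radius_px + 1] == 0)

    def test_determinism(self):
        spec = one_muscle_scene(n_nuclei=8, seed=123,
                                noise=NoiseSpec(background_level=10, gaussian_sd=3,
                                                poisson_scaling=0.5))
        img1, _, _ = render_frame(spec, 0)
        img2, _, _ = render_frame(spec, 0)
        np.testing.assert_array_equal(img1, img2)

    def test_out_of_range_frame(self):
        with pytest.raises(SceneError):
            render_frame(one_muscle_scene(), 1)

    def test_muscle_outside_image_named(self):
        muscle = MuscleSpec(
            muscle_id="DIOM 2R",
            area_keyframes=[(5.0, 90000.0)],
            diameter_keyframes=[(5.0, 80.0)],
        )
        spec = SceneSpec(image_size=(256, 256), he_frame=0, frame_hours=(5.0,),
                         muscles=[muscle])
        with pytest.raises(SceneError, match="DIOM 2R.*frame 0"):
            render_frame(spec, 0)

    def test_truth_consistency_raster_vs_analytic(self):
        """Noiseless rendered foreground area within 2% of analytic truth."""
        spec = one_muscle_scene()
        img, truth, _ = render_frame(spec, 0)
        raster_area = (img[0] > 0).sum() * spec.pixel_size**2
        assert raster_area == pytest.approx(truth.area_um2.iloc[0], rel=0.02)


class TestCapsule:
    def test_closed_form_area(self):
        cap = Capsule(cx=0, cy=0, shaft_um=100, diameter_um=25, theta=0.0,
                      pixel_size=1.25)
        expected = 100 * 25 + math.pi * 12.5**2  # ≈ 2990.87
        assert cap.area_um2 == pytest.approx(expected, abs=1e-6)
        assert cap.length_um == pytest.approx(100.0)

    def test_shaft_derived_from_area_and_diameter(self):
        spec = one_muscle_scene()
        cap = spec.muscles[0].capsule_at(5.0, spec)
        # invert: shaft·D + πr² must reproduce the keyframed area
        assert cap.area_um2 == pytest.approx(4000.0, rel=1e-9)

    def test_he_contraction_lengthens_pre_he_fibre(self):
        muscle = build_preset("control")
        spec = SceneSpec(muscles=[muscle])  # full profile clock, he_frame 24
        pre = muscle.capsule_at(-3.0, spec)
        post = muscle.capsule_at(3.0, spec)
        assert post.length_um / pre.length_um == pytest.approx(0.53, rel=1e-6)


class TestPresets:
    def test_unknown_preset_lists_valid(self):
        with pytest.raises(SceneError, match="control"):
            build_preset("nonsense_shRNA")

    def test_control_keyframes_pinned(self):
        m = build_preset("control")
        assert dict(m.area_keyframes) == {5.0: 17925.0, 50.0: 6038.0, 100.0: 15719.0}
        assert dict(m.diameter_keyframes)[5.0] == 84.4
        assert dict(m.diameter_keyframes)[50.0] == 24.4

    def test_all_presets_render_everywhere(self):
        """Every preset stays inside the fast-profile frame at every grid time."""
        for name in preset_names():
            spec = SceneSpec(image_size=(384, 384), he_frame=0,
                             frame_hours=tuple(float(h) for h in
                                               (5, 10, 15, 20, 25, 30, 40, 50,
                                                60, 70, 80, 90, 100)),
                             muscles=[build_preset(name)])
            for f in range(spec.n_frames):
                cap = spec.muscles[0].capsule_at(spec.hours_of_frame(f), spec)
                assert cap.contains_margin(384, 384), (name, f)


class TestCohort:
    def test_cohort_median_matches_preset(self, control_cohort):
        truth = control_cohort["truth"]
        for hours, expected in [(5, 17925.0), (50, 6038.0), (100, 15719.0)]:
            at = truth[np.isclose(truth.hours_ahe, hours)]
            assert len(at) == 15
            assert np.median(at.area_um2) == pytest.approx(expected, rel=0.03)
        at5 = truth[np.isclose(truth.hours_ahe, 5)]
        assert np.median(at5.diameter_um) == pytest.approx(84.4, rel=0.03)

    def test_per_sample_variation_present(self, control_cohort):
        at5 = control_cohort["truth"]
        at5 = at5[np.isclose(at5.hours_ahe, 5)]
        assert at5.area_um2.std() > 0

    def test_cp1_death_fraction(self, tmp_path):
        cohort = generate_cohort("Cp1_shRNA", 12, seed=3, outdir=tmp_path,
                                 profile="fast")
        n_dead = cohort["manifest"].death_time.notna().sum()
        assert n_dead == round(12 * 2 / 3)
        # dead muscles vanish from the truth at late frames
        truth = cohort["truth"]
        assert len(truth[np.isclose(truth.hours_ahe, 100)]) < 12

    def test_truth_one_record_per_living_muscle(self, control_cohort):
        truth = control_cohort["truth"]
        counts = truth.groupby(["sample_id", "frame"]).size()
        assert (counts == 1).all()

    def test_unknown_preset_cohort(self, tmp_path):
        with pytest.raises(SceneError, match="valid presets"):
            generate_cohort("no_such", 3, seed=1, outdir=tmp_path)


class TestNucleiPrograms:
    def test_axial_sd_by_construction(self):
        """Central cluster keeps axial SD < 0.1; uniform spread exceeds 0.2."""
        sds = {"central_cluster": [], "uniform_basal": []}
        for pattern, bucket in sds.items():
            for seed in range(12):
                prog = NucleiProgram(n_nuclei=10, phases=((-100.0, pattern),))
                coords, _ = nuclei_positions(prog, 50.0,
                                             np.random.default_rng(seed))
                bucket.append(np.std(coords[:, 0], ddof=1))
        assert all(sd < 0.1 for sd in sds["central_cluster"])
        assert all(sd > 0.2 for sd in sds["uniform_basal"])

    def test_frozen_keeps_first_phase_positions(self):
        prog = NucleiProgram(
            n_nuclei=8,
            phases=((-100.0, "uniform_basal"), (40.0, "frozen")),
        )
        early, _ = nuclei_positions(prog, 5.0, np.random.default_rng(1))
        late, _ = nuclei_positions(prog, 90.0, np.random.default_rng(1))
        np.testing.assert_allclose(early, late)

    def test_frozen_first_rejected(self):
        prog = NucleiProgram(n_nuclei=4, phases=((-100.0, "frozen"),))
        with pytest.raises(SceneError):
            nuclei_positions(prog, 5.0, np.random.default_rng(0))


def test_sample_outputs_deterministic(tmp_path):
    """Identical (spec, seed) produce bit-identical TIFF bytes on disk."""
    from myolapse.synthetic import generate_sample

    spec = one_muscle_scene(n_nuclei=5, seed=99)
    p1 = generate_sample(spec, tmp_path / "a")
    spec2 = one_muscle_scene(n_nuclei=5, seed=99)
    p2 = generate_sample(spec2, tmp_path / "b")
    assert p1["tiff"].read_bytes() == p2["tiff"].read_bytes()
    assert p1["truth"].read_bytes() == p2["truth"].read_bytes()
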