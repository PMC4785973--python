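"""Shared fixtures: synthetic cohorts generated once per session."""

import numpy as np
import pytest

from myolapse import pipeline, synthetic


@pytest.fixture(scope="session")
def control_cohort(tmp_path_factory):
    """Control-preset cohort, n=15, fast profile (the parameter-recovery cohort)."""
    outdir = tmp_path_factory.mktemp("control_cohort")
    return synthetic.generate_cohort("control", 15, seed=11, outdir=outdir,
                                     profile="fast")


@pytest.fixture(scope="session")
def control_features(control_cohort):
    """Morphometry-core measurements of every ROI of the control cohort."""
    return pipeline.measure_cohort(control_cohort, pixel_size_um=1.25, step_px=5.0)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """Full fast-profile pipeline: autophagy-knockdown vs control diameters."""
    outdir = tmp_path_factory.mktemp("pipeline_run")
    cfg = pipeline.RunConfig(
        preset_a="Atg_shRNA", preset_b="control", n_samples=6,
        feature="diameter_um", tail="right", seed=7, outdir=str(outdir),
    )
    summary = pipeline.run_all(cfg)
    return cfg, summary


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
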