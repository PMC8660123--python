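import numpy as np
import pytest

import polarslice as ps


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noise_free_config():
    """Deterministic phantom regime: flat discs, no pixel noise."""
    return ps.SynthConfig(
        normal_intensity_sd=0.0,
        pixel_noise_sd=0.0,
        defect_severity_range=(1.0, 1.0),
        defect_count_range=(1, 1),
        defect_angular_extent_range=(90.0, 90.0),
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A 12-normal / 28-abnormal dataset for quick pipeline tests."""
    return ps.generate_dataset(12, 28, seed=2024)


@pytest.fixture(scope="session")
def full_run():
    """One full-size run: 108/899 maps, stratified 10-fold, random forest.

    Session-scoped because several tests interrogate different aspects of
    the same cross-validation (leakage audit, training saturation, fold
    bookkeeping).
    """
    images = ps.generate_dataset(108, 899, seed=20240917)
    config = ps.PipelineConfig(
        k=10,
        seed=7,
        model_specs=(ps.ModelSpec("random_forest", seed=7),),
    )
    report = ps.run_cv(images, config)
    return images, config, report
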