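import numpy as np
import pytest

from painfuse import preprocess, synthetic


@pytest.fixture(scope="session")
def tiny_cohort():
    """3 subjects x 3 channels, 5 levels x 3 reps, strong effect."""
    spec = synthetic.CohortSpec(
        n_subjects=3, n_levels=5, reps_per_level=3, effect_size=3.0,
        rate=512.0, seed=42,
    )
    return spec, synthetic.generate_cohort(spec)


@pytest.fixture(scope="session")
def tiny_segments(tiny_cohort):
    """Short-window segment dataset from the tiny cohort (m = 256)."""
    _, recs = tiny_cohort
    return preprocess.preprocess_recordings(recs, dataset="biovid",
                                            window_s=1.0)


@pytest.fixture
def toy_dataset(rng_factory):
    """Small random two-class multi-modal dataset (m = 32)."""
    rng = rng_factory()
    n, m = 12, 32
    X = {mod: rng.random((n, m)) for mod in ("EDA", "ECG")}
    y = np.tile([0, 4], n // 2)
    subjects = np.array(["sA", "sB"] * (n // 2), dtype=object)
    return preprocess.SegmentDataset(X, y, subjects, np.zeros(n, dtype=int))


@pytest.fixture
def rng_factory():
    return lambda seed=0: np.random.default_rng(seed)
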