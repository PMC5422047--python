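import numpy as np
import pytest

import wearact as w


@pytest.fixture(scope="session")
def small_cohort():
    """Three-subject, short-duration cohort at 15 Hz in the reference frame."""
    spec = w.CohortSpec(
        n_subjects=3,
        activities=w.default_profiles(duration_s=6.0),
        seed=7,
    )
    return spec, w.generate_cohort(spec)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    _, recs = small_cohort
    cfg = w.HarmonizationConfig()
    return w.build_feature_table([w.harmonize(r, cfg)[0] for r in recs])


@pytest.fixture(scope="session")
def default_table():
    """Feature table of the full default cohort (12 subjects, 7 activities)."""
    recs = w.generate_cohort(w.CohortSpec(n_subjects=12, seed=0))
    cfg = w.HarmonizationConfig()
    return w.build_feature_table([w.harmonize(r, cfg)[0] for r in recs])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
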