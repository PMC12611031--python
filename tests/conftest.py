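import numpy as np
import pytest

from ecgms.synthetic import CohortSpec, GroupEffects, generate_cohort, generate_record


@pytest.fixture(scope="session")
def clean_record():
    """One clean 10 s, 1 kHz record at exactly 60 bpm with no dispersion."""
    spec = CohortSpec(
        duration=10.0, base_heart_rate=60.0, hr_sd=0.0, rr_cv=0.0, amp_jitter=0.0, seed=5
    )
    return generate_record(spec, "s01", "control", "basal")


@pytest.fixture(scope="session")
def small_cohort():
    """25 subjects, one stage, 20 s at 250 Hz: quick but representative."""
    spec = CohortSpec(duration=20.0, sample_rate=250.0, stages=("basal",), seed=42)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    from ecgms.features import cohort_features

    return cohort_features(small_cohort, from_annotations=True)


@pytest.fixture(scope="session")
def separable_xy():
    """Two tight, well-separated 2-D Gaussian clouds (n=40)."""
    rng = np.random.default_rng(7)
    x = np.vstack([rng.normal(-1.0, 0.1, (20, 2)), rng.normal(1.0, 0.1, (20, 2))])
    y = np.array(["control"] * 20 + ["ms"] * 20)
    return x, y
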