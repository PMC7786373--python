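import numpy as np
import pytest

from lesionview.io_formats import SubjectRecord, Volume
from lesionview.models import CompressionConfig, ModelSpec
from lesionview.synthetic_data import PhantomParams, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_subject(rng) -> SubjectRecord:
    """A 24³ subject with a bright block on a noisy background."""
    side = 24
    flair = rng.uniform(0.0, 0.05, (side,) * 3).astype(np.float32)
    flair[6:18, 4:16, 8:20] += 0.8
    mask = np.zeros((side,) * 3, dtype=np.uint8)
    mask[10:14, 8:12, 12:16] = 1
    return SubjectRecord(
        "s0",
        Volume(flair, subject_id="s0", modality="flair"),
        Volume(mask, subject_id="s0", modality="wmh_mask"),
        "MS",
    )


@pytest.fixture(scope="session")
def tiny_spec() -> ModelSpec:
    """A two-view spec for 24³ cubes (22 per-view channels)."""
    return ModelSpec(family="two_view_2d", depth=18,
                     compression=CompressionConfig(per_view_in_channels=22))


@pytest.fixture(scope="session")
def tiny_easy_cohort():
    """16 strongly separated 24³ phantoms (8 per class)."""
    params = PhantomParams.easy(side=24, seed=5)
    cohort, _ = generate_cohort(params, n_ms=8, n_nmosd=8, seed=5)
    return cohort
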