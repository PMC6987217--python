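import numpy as np
import pytest

from hmpkit.cartilage import REGIONS
from hmpkit.synthetic import CohortConfig, SubjectTruth, TruthParams, generate_cohort


def make_subject(
    subject_id="S01",
    baseline_frontal=3.0,
    baseline_transverse=-2.0,
    shoe_offsets=None,
    alpha=3.0,
    beta=0.3,
    reduction_noise=0.0,
    angle_noise=0.0,
):
    if shoe_offsets is None:
        shoe_offsets = {
            "neutral": (3.0, 2.0),
            "lateral_post": (5.0, 4.0),
            "medial_post": (1.0, 0.5),
        }
    return SubjectTruth(
        subject_id=subject_id,
        body_mass_kg=70.0,
        body_height_m=1.77,
        baseline_frontal_deg=baseline_frontal,
        baseline_transverse_deg=baseline_transverse,
        shoe_offsets=shoe_offsets,
        coupling_alpha_pct={r: alpha for r in REGIONS},
        coupling_beta_pct_per_deg={r: beta for r in REGIONS},
        reduction_noise_sd_pct=reduction_noise,
        angle_noise_sd_deg=angle_noise,
    )


@pytest.fixture
def subject():
    return make_subject()


@pytest.fixture
def small_cfg():
    return CohortConfig(
        n_subjects=4,
        n_squats_per_subject=3,
        n_strides_per_condition=2,
        seed=11,
    )


@pytest.fixture
def noiseless_dataset(small_cfg):
    return generate_cohort(small_cfg, TruthParams())


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
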