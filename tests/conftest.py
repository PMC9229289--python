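import numpy as np
import pytest

from ecgid.detect import detect_fiducials
from ecgid.pipeline import RunConfig, run_pipeline
from ecgid.simulate import SimOptions, make_cohort

COHORT_SEED = 101


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free cohort: 20 subjects x 10 cycles at 360 Hz."""
    return make_cohort(20, 10, SimOptions(fs=360.0), seed=COHORT_SEED)


@pytest.fixture(scope="session")
def clean_detections(clean_cohort):
    return [detect_fiducials(rec.signal) for rec in clean_cohort]


@pytest.fixture(scope="session")
def noisy_cohort():
    """Same cohort conditions with 20 dB additive white noise."""
    return make_cohort(20, 10, SimOptions(fs=360.0, noise_snr_db=20.0),
                       seed=COHORT_SEED)


@pytest.fixture(scope="session")
def pipeline_report():
    """End-to-end run on the 20-subject cohort, classifier stage isolated.

    Screening is disabled here: the mean-impact-value cutoff is an absolute
    label-unit threshold whose bite depends on the number of classes, and
    at 20 subjects it prunes far harder than at full corpus size; the
    parameter-recovery check targets delineation + features + WOA-PNN.
    """
    return run_pipeline(RunConfig(seed=COHORT_SEED, use_miv=False))
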