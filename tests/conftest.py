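import numpy as np
import pytest

from bpci import pipeline, synth
from bpci.records_io import extract_window


@pytest.fixture(scope="session")
def clean_profile():
    return synth.SubjectProfile(hr_bpm=60.0, hr_jitter=0.0, noise_sd={})


@pytest.fixture(scope="session")
def clean_record(clean_profile):
    return synth.generate_record(clean_profile, duration_s=20.0, fs=125.0, seed=42)


@pytest.fixture(scope="session")
def cohort_small():
    """Six clean subjects, long enough for the default 60 s + 20 s window."""
    return synth.generate_cohort(6, seed=11)


@pytest.fixture(scope="session")
def e2e_result():
    """Full pipeline over the 50-subject study cohort (shared across tests)."""
    records = synth.generate_cohort(50, seed=7, bp_noise_sd=2.0)
    result = pipeline.run_pipeline(records, pipeline.PipelineConfig(), seed=7)
    truth = {}
    for rec in records:
        t = extract_window(rec).truth
        truth[rec.record_id] = {"sbp": float(np.mean(t.sbp)), "dbp": float(np.mean(t.dbp))}
    return result, truth
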