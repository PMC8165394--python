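import numpy as np
import pytest

import rpecg as r


@pytest.fixture(scope="session")
def normal_record():
    """12-lead 10 s Normal record at 500 Hz."""
    return r.synth_record(r.SynthSpec("Normal", 10.0, 500.0, 12, seed=1))


@pytest.fixture(scope="session")
def normal_record_200hz(normal_record):
    return r.resample_record(normal_record)


@pytest.fixture(scope="session")
def segment_1000(normal_record_200hz):
    """One 1,000-sample (5 s at 200 Hz) lead-II segment."""
    segs = r.augment_segments(normal_record_200hz)
    return next(s for s in segs if s.lead_name == "II")


@pytest.fixture(scope="session")
def toy_records():
    """Small 3-class set for split/experiment tests (2 leads, 10 s)."""
    return r.synth_dataset(r.TOY3_CLASSES, 10, duration_s=10.0, fs=500.0,
                           n_leads=2, seed=3)
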