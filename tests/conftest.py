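import numpy as np
import pytest

from afscreen.pipeline import RunConfig, process_records
from afscreen.preprocessing import FilterSpec, remove_baseline
from afscreen.synthetic import (CohortSpec, RhythmClass, RhythmSpec,
                                WaveformParams, generate_cohort, generate_record)


@pytest.fixture(scope="session")
def wf():
    return WaveformParams()


@pytest.fixture(scope="session")
def make_record(wf):
    """Factory for clean (noise-free) records of any rhythm class."""

    def _make(rhythm=RhythmClass.SINUS, mean_hr=70.0, seed=42, ectopy_rate=None,
              wf_override=None, **kw):
        if ectopy_rate is None:
            ectopy_rate = 3.0 if RhythmClass(rhythm).ectopic_type else 0.0
        spec = RhythmSpec(rhythm_class=rhythm, mean_hr=mean_hr,
                          ectopy_rate=ectopy_rate, seed=seed)
        return generate_record(spec, wf_override or wf, **kw)

    return _make


@pytest.fixture(scope="session")
def sinus_record(make_record):
    return make_record(RhythmClass.SINUS, mean_hr=60.0, seed=42)


@pytest.fixture(scope="session")
def af_record(make_record):
    return make_record(RhythmClass.AF, mean_hr=90.0, seed=42)


@pytest.fixture(scope="session")
def filtered_sinus(sinus_record):
    return remove_baseline(sinus_record)


@pytest.fixture(scope="session")
def small_cohort():
    """120-subject synthetic screening cohort shared across test modules."""
    spec = CohortSpec(n_subjects=120, seed=7)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_cohort_features(small_cohort):
    records, manifest = small_cohort
    return process_records(records, manifest, FilterSpec())
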