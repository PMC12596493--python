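import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from multimorbnet.ingest import AdmissionRecord, CohortStratum

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_records(code_sets, sex="male", ages=None, patient_prefix="p"):
    """Admission records from an iterable of code collections."""
    ages = ages or [45] * len(code_sets)
    return [
        AdmissionRecord(
            record_id=f"r{i}",
            patient_id=f"{patient_prefix}{i}",
            sex=sex,
            age_years=ages[i],
            admission_date=dt.date(2010, 1, 1),
            codes=frozenset(codes),
        )
        for i, codes in enumerate(code_sets)
    ]


def make_stratum(code_sets, sex="male", band=(40, 59), label="test"):
    return CohortStratum(
        label=label, sex=sex, age_band=band, records=tuple(make_records(code_sets, sex=sex))
    )


@pytest.fixture
def tiny_stratum():
    """Four records exercising single, pair and complex multimorbidity."""
    return make_stratum([{"I10"}, {"I10", "E11"}, {"I10", "E11", "K29", "N40"}, {"E11"}])
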