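from datetime import date

import pytest

from diagtraj import (
    CategoryTaxonomy,
    DiagnosisRecord,
    SyntheticCohortConfig,
    generate_cohort,
    identify_d1,
)


@pytest.fixture(scope="session")
def taxonomy():
    return CategoryTaxonomy.default()


def make_record(
    person_id="P1",
    sex="F",
    birth=date(1990, 5, 1),
    event=date(2002, 5, 1),
    event_type="DIAGNOSIS",
    icd10="F43.2",
    education="MEDIUM",
):
    return DiagnosisRecord(person_id, sex, birth, event, event_type,
                           icd10 if event_type == "DIAGNOSIS" else "", education)


@pytest.fixture(scope="session")
def small_cohort(taxonomy):
    """A 400-person synthetic cohort with its ground truth."""
    config = SyntheticCohortConfig.default(n_persons=400, seed=20260927)
    records, truth = generate_cohort(config, taxonomy)
    return records, truth, identify_d1(records)
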