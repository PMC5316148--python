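import numpy as np
import pytest

from growthscreen import build_screening_table, synthetic_reference_pair


@pytest.fixture(scope="session")
def refs():
    """(bmi_for_age, height_for_age) synthetic month-by-month references."""
    return synthetic_reference_pair()


@pytest.fixture(scope="session")
def bmi_ref(refs):
    return refs[0]


@pytest.fixture(scope="session")
def height_ref(refs):
    return refs[1]


@pytest.fixture(scope="session")
def tables(refs):
    bmi, height = refs
    return {sex: build_screening_table(bmi, height, sex) for sex in ("male", "female")}


@pytest.fixture()
def small_reference_csv(tmp_path):
    """Tiny 2-sex x 3-age LMS fixture file in the canonical dialect."""
    path = tmp_path / "lms_small.csv"
    path.write_text(
        "sex,age_months,L,M,S\n"
        "male,118,-1.2,16.6,0.115\n"
        "male,120,-1.2,16.7,0.116\n"
        "male,122,-1.2,16.8,0.117\n"
        "female,118,-1.3,16.9,0.118\n"
        "female,120,-1.3,17.0,0.119\n"
        "female,122,-1.3,17.1,0.120\n"
    )
    return path
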