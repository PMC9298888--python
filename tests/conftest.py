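import numpy as np
import pytest

from trustnet import fixture_suite


@pytest.fixture(scope="session")
def fixtures():
    return fixture_suite()


@pytest.fixture()
def rng():
    return np.random.default_rng(20210801)


@pytest.fixture()
def survey_csv(tmp_path):
    """A tiny valid survey file: two respondents, three organizations."""
    lines = [
        "respondent_id,alter_id,collaboration,trust_1,trust_2,trust_3,trust_4,trust_5,trust_6,trust_7",
        "A,B,5,4,5,3,2,1,4,5",
        "A,C,2,3,3,3,3,3,3,3",
        "B,A,4,5,5,5,5,5,5,5",
    ]
    p = tmp_path / "survey.csv"
    p.write_text("\n".join(lines) + "\n")
    return p
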