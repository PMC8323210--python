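import numpy as np
import pytest

from emrsim import Patient, TextSchema, build_fragment_corpus


@pytest.fixture
def schema5():
    """Minimal schema with the required five independent phrases."""
    return TextSchema(
        independent=("arterial phase", "lower density than spleen",
                     "no abnormal density", "uniform liver parenchyma density",
                     "retroperitoneal lymph node enlargement"),
        set_features=("cyst", "calcification", "fatty infiltration", "nodule"),
    )


def _patient(pid, age, sex=1, allergy=0, admission=1, codes=(), labs=None,
             tokens=()):
    return Patient(id=pid, age=age, sex=sex, drug_allergy=allergy,
                   admission_source=admission, comorbidities=set(codes),
                   labs=dict(labs or {}), report_tokens=set(tokens))


@pytest.fixture
def make_patient():
    return _patient


@pytest.fixture
def micro_cohort():
    """Three patients holding one code each: the {K269, K293, K761} corpus
    (12 fragments; count(K) = 3, count(K2) = 2)."""
    return [
        _patient("a", 50, codes={"K269"}, labs={"alt": 0}, tokens={"cyst"}),
        _patient("b", 50, codes={"K293"}, labs={"alt": 0}, tokens={"cyst"}),
        _patient("c", 50, codes={"K761"}, labs={"alt": 0}, tokens={"cyst"}),
    ]


@pytest.fixture
def micro_corpus(micro_cohort):
    return build_fragment_corpus(micro_cohort)


@pytest.fixture
def tiny_cohort():
    """Five handmade patients with binarized labs, for pair-table oracles."""
    return [
        _patient("p0", 40, sex=1, allergy=0, admission=1,
                 codes={"K269", "K293"}, labs={"alt": 1, "ast": 0, "ggt": 1},
                 tokens={"arterial phase", "cyst", "nodule"}),
        _patient("p1", 60, sex=0, allergy=0, admission=1,
                 codes={"K761"}, labs={"alt": 0, "ast": 0, "ggt": 1},
                 tokens={"cyst"}),
        _patient("p2", 40, sex=1, allergy=1, admission=0,
                 codes={"E116", "K269"}, labs={"alt": 1, "ast": 1, "ggt": 0},
                 tokens={"no abnormal density", "calcification"}),
        _patient("p3", 80, sex=0, allergy=0, admission=1,
                 codes=set(), labs={"alt": 0, "ast": 0, "ggt": 0},
                 tokens=set()),
        _patient("p4", 40, sex=1, allergy=0, admission=1,
                 codes={"K269", "K293"}, labs={"alt": 1, "ast": 0, "ggt": 1},
                 tokens={"arterial phase", "cyst", "nodule"}),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
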