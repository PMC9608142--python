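import numpy as np
import pytest

from pmbpk.data import DoseEvent, EventTable, Observation, SubjectRecord
from pmbpk.estimation import PopPKModel
from pmbpk.synthetic import StudyDesign, fixture_final_model, generate_study


@pytest.fixture(scope="session")
def final_model():
    return fixture_final_model()


@pytest.fixture(scope="session")
def study34(final_model):
    """A study-sized synthetic table (34 subjects, 4 samples each)."""
    return generate_study(StudyDesign(n_subjects=34), final_model, seed=3)


@pytest.fixture(scope="session")
def fit34(study34, final_model):
    """FOCE-I fit of the final model to the 34-subject table."""
    return PopPKModel(study34, final_model).fit(init=final_model, compute_se=False)


@pytest.fixture()
def toy_subject():
    """One subject, one 100 mg 1-h infusion, two post-infusion samples."""
    return SubjectRecord(
        id="T1",
        doses=(DoseEvent(0.0, 100.0, 1.0),),
        observations=(Observation(2.0, 4.0), Observation(6.0, 2.0)),
        covariates={"crcl": 80.0},
    )


def make_table(records):
    return EventTable(tuple(records))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
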