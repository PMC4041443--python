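import numpy as np
import pytest

from pisurvey.contacts import ValidityCriteria
from pisurvey.structure_io import extract_moieties
from pisurvey.synth import build_pi_dimer


@pytest.fixture(scope="session")
def criteria():
    return ValidityCriteria()


@pytest.fixture(scope="session")
def small_corpus():
    """A 30-structure corpus shared by aggregation/CLI tests."""
    from pisurvey.synth import build_survey_corpus
    return build_survey_corpus(30, seed=42, decoy_fraction=0.2)


@pytest.fixture()
def stacked_dimer_moieties():
    records, _ = build_pi_dimer("A", "PHE", omega=5.0, rise=3.5)
    moieties, _ = extract_moieties(records)
    return moieties


def rigid_motion(rng: np.random.Generator):
    """A random proper rotation + translation, for invariance tests."""
    from pisurvey.geometry import random_rotation
    rot = random_rotation(rng)
    trans = rng.uniform(-20.0, 20.0, size=3)
    return rot, trans


def apply_rigid(records, rot, trans):
    from pisurvey.structure_io import AtomRecord
    return [AtomRecord(
        atom_name=r.atom_name, element=r.element, residue_name=r.residue_name,
        chain_id=r.chain_id, residue_number=r.residue_number,
        insertion_code=r.insertion_code, position=rot @ r.position + trans)
        for r in records]
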