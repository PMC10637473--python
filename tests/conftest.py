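import pytest

from pvstrat.icsr_model import CaseReport, Dataset, ReactionTerm, Sex


@pytest.fixture
def toy_term_map():
    return {
        "X": ReactionTerm("X", "Reaction X", "SOC1", "Organ class one"),
        "Y": ReactionTerm("Y", "Reaction Y", "SOC1", "Organ class one"),
        "Z": ReactionTerm("Z", "Reaction Z", "SOC2", "Organ class two"),
    }


@pytest.fixture
def toy_dataset(toy_term_map):
    """Six hand-enumerable reports: (drug, reaction, sex) one mention each.

    (D,X,m) (D,Y,m) (D,X,f) (E,X,m) (E,Y,f) (E,Z,m)
    """
    spec = [
        ("c1", "D", "X", Sex.MALE),
        ("c2", "D", "Y", Sex.MALE),
        ("c3", "D", "X", Sex.FEMALE),
        ("c4", "E", "X", Sex.MALE),
        ("c5", "E", "Y", Sex.FEMALE),
        ("c6", "E", "Z", Sex.MALE),
    ]
    reports = [
        CaseReport(cid, sex, frozenset((drug,)), frozenset((pt,)))
        for cid, drug, pt, sex in spec
    ]
    return Dataset(reports, toy_term_map)
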