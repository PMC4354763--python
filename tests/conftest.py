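"""Shared fixtures: the five-workflow example collection and its four
published encodings (rows -> (counts per W1..W5, weight)), frozen as
expected values."""

import pytest
from hypothesis import settings

from wfclust import KeywordRule, figure1_fixture

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

# Type I: presence/absence of task-instance slots, execution-time weights.
TABLE_TYPE1 = {
    "Blast (NCBI)":               ((0, 0, 0, 1, 0), 0.35),
    "ClustalW2":                  ((0, 1, 0, 0, 1), 0.49),
    "HGT Detector 3.2":           ((1, 1, 1, 0, 1), 0.88),
    "Muscle":                     ((1, 0, 0, 0, 1), 0.41),
    "PROTML (Phylip)":            ((1, 0, 0, 0, 0), 0.68),
    "PhyML (1)":                  ((0, 1, 1, 0, 1), 1.13),
    "PhyML (2)":                  ((0, 0, 0, 0, 1), 1.13),
    "Probcons":                   ((0, 0, 1, 0, 0), 0.55),
    "Robinson & Foulds distance": ((0, 0, 0, 1, 0), 0.25),
    "SEQBOOT (Phylip)":           ((1, 0, 0, 0, 0), 0.14),
    "Seq-Gen":                    ((0, 1, 0, 1, 0), 0.43),
}

# Type II: occurrence counts, keyword "HGT" weighting 1.0 / 0.1.
TABLE_TYPE2 = {
    "Blast (NCBI)":               ((0, 0, 0, 1, 0), 0.10),
    "ClustalW2":                  ((0, 1, 0, 0, 1), 0.10),
    "HGT Detector 3.2":           ((1, 1, 1, 0, 1), 1.00),
    "Muscle":                     ((1, 0, 0, 0, 1), 0.10),
    "PROTML (Phylip)":            ((1, 0, 0, 0, 0), 0.10),
    "PhyML":                      ((0, 1, 1, 0, 2), 0.10),
    "Probcons":                   ((0, 0, 1, 0, 0), 0.10),
    "Robinson & Foulds distance": ((0, 0, 0, 1, 0), 0.10),
    "SEQBOOT (Phylip)":           ((1, 0, 0, 0, 0), 0.10),
    "Seq-Gen":                    ((0, 1, 0, 1, 0), 0.10),
}

# Type III: pair-of-tasks counts + terminal singletons, summed-time weights.
# (The "Probcons → PhyML" row uses the self-consistent value for W4: the
# occurrence encodings show W4 contains neither Probcons nor PhyML.)
TABLE_TYPE3 = {
    "Blast (NCBI)":                        ((0, 0, 0, 1, 0), 0.35),
    "HGT Detector 3.2":                    ((1, 1, 1, 0, 1), 0.88),
    "Robinson & Foulds distance":          ((0, 0, 0, 1, 0), 0.25),
    "ClustalW2 → PhyML":                   ((0, 1, 0, 0, 1), 1.62),
    "Muscle → PhyML":                      ((0, 0, 0, 0, 1), 1.54),
    "Muscle → SEQBOOT (Phylip)":           ((1, 0, 0, 0, 0), 0.55),
    "PROTML (Phylip) → HGT Detector 3.2":  ((1, 0, 0, 0, 0), 1.56),
    "PhyML → HGT Detector 3.2":            ((0, 1, 1, 0, 2), 2.01),
    "Probcons → PhyML":                    ((0, 0, 1, 0, 0), 1.68),
    "SEQBOOT (Phylip) → PROTML (Phylip)":  ((1, 0, 0, 0, 0), 0.82),
    "Seq-Gen → Blast (NCBI)":              ((0, 0, 0, 1, 0), 0.78),
    "Seq-Gen → ClustalW2":                 ((0, 1, 0, 0, 0), 0.92),
}

# Type IV: Type III variables re-weighted by keyword "HGT" + IO ports.
TABLE_TYPE4 = {
    "Blast (NCBI)":                        ((0, 0, 0, 1, 0), 0.10),
    "HGT Detector 3.2":                    ((1, 1, 1, 0, 1), 1.00),
    "Robinson & Foulds distance":          ((0, 0, 0, 1, 0), 0.10),
    "ClustalW2 → PhyML":                   ((0, 1, 0, 0, 1), 0.10),
    "Muscle → PhyML":                      ((0, 0, 0, 0, 1), 0.10),
    "Muscle → SEQBOOT (Phylip)":           ((1, 0, 0, 0, 0), 0.10),
    "PROTML (Phylip) → HGT Detector 3.2":  ((1, 0, 0, 0, 0), 1.00),
    "PhyML → HGT Detector 3.2":            ((0, 1, 1, 0, 2), 1.00),
    "Probcons → PhyML":                    ((0, 0, 1, 0, 0), 0.10),
    "SEQBOOT (Phylip) → PROTML (Phylip)":  ((1, 0, 0, 0, 0), 0.10),
    "Seq-Gen → Blast (NCBI)":              ((0, 0, 0, 1, 0), 0.10),
    "Seq-Gen → ClustalW2":                 ((0, 1, 0, 0, 0), 0.10),
    "INPUT_Sequences":                     ((1, 0, 1, 0, 1), 1.00),
    "INPUT_Tree":                          ((1, 1, 1, 2, 0), 1.00),
    "OUTPUT_Blast (NCBI)":                 ((0, 0, 0, 1, 0), 1.00),
    "OUTPUT_Matrix":                       ((1, 1, 1, 1, 1), 1.00),
    "OUTPUT_MultipleTrees":                ((0, 0, 0, 1, 0), 1.00),
    "OUTPUT_OutputText":                   ((1, 1, 1, 2, 1), 1.00),
    "OUTPUT_Results":                      ((1, 1, 1, 1, 1), 1.00),
}

EXPECTED_ENCODINGS = {
    "I": TABLE_TYPE1,
    "II": TABLE_TYPE2,
    "III": TABLE_TYPE3,
    "IV": TABLE_TYPE4,
}


@pytest.fixture(scope="session")
def fixture_ws():
    return figure1_fixture()


@pytest.fixture(scope="session")
def hgt_rule():
    return KeywordRule("HGT", match_weight=1.0, default_weight=0.1)
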