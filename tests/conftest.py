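import pandas as pd
import pytest

from phenokit import default_lexicon, empty_bundle
from phenokit.emr_tables import TableBundle


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


def _with_rows(table_name: str, rows: list[dict]) -> pd.DataFrame:
    empty = empty_bundle().table(table_name)
    if not rows:
        return empty
    return pd.DataFrame(rows, columns=list(empty.columns))


def make_bundle(**tables) -> TableBundle:
    """Bundle from per-table row dicts; unspecified tables are empty."""
    return TableBundle(**{
        name: _with_rows(name, tables.get(name, []))
        for name in empty_bundle().__dataclass_fields__
    })


@pytest.fixture
def hand_bundle():
    """Five encounters with hand-set child rows covering all seven criteria.

    Expected flags (c1..c7) per encounter:
      E1: 1010011 (score 4)   E2: 0000000   E3: 0100100 (score 2)
      E4: 0101000 (score 2)   E5: 0000010 (score 1)
    """
    return make_bundle(
        encounters=[
            {"encounter_key": "E1", "person_key": "P1", "facility_id": "F01",
             "lhd": "LHD1", "admit_ts": "2017-03-05T10:00:00", "year": 2017},
            {"encounter_key": "E2", "person_key": "P1", "facility_id": "F01",
             "lhd": "LHD1", "admit_ts": "2005-06-01T08:30:00", "year": 2005},
            {"encounter_key": "E3", "person_key": "P2", "facility_id": "F05",
             "lhd": "LHD2", "admit_ts": "2016-11-20T23:15:00", "year": 2016},
            {"encounter_key": "E4", "person_key": "P3", "facility_id": "F02",
             "lhd": "LHD1", "admit_ts": "2015-01-02T06:00:00", "year": 2015},
            {"encounter_key": "E5", "person_key": "P4", "facility_id": "F06",
             "lhd": "LHD2", "admit_ts": "2017-07-14T14:45:00", "year": 2017},
        ],
        reason_for_visit=[
            {"encounter_key": "E1", "free_text": "central chest pain radiating"},
            {"encounter_key": "E2", "free_text": "ankle sprain"},
        ],
        forms=[
            {"encounter_key": "E1", "form_type": "ed_triage",
             "free_text": "fall at home", "cardiac_pathway_flag": False},
            {"encounter_key": "E3", "form_type": "ed_triage",
             "free_text": "c/o sob on exertion", "cardiac_pathway_flag": False},
            {"encounter_key": "E4", "form_type": "other",
             "free_text": "", "cardiac_pathway_flag": True},
            {"encounter_key": "E4", "form_type": "cardiac_monitoring",
             "free_text": "", "cardiac_pathway_flag": False},
        ],
        orders=[
            {"encounter_key": "E1", "order_name": "TROPONIN I LEVEL", "order_category": "troponin"},
            {"encounter_key": "E2", "order_name": "FBC", "order_category": "other"},
        ],
        procedure_results=[
            {"encounter_key": "E3", "result_modality": "sestamibi", "result_present": True},
            {"encounter_key": "E2", "result_modality": "ct_aortic_angiogram", "result_present": False},
        ],
        diagnoses=[
            {"encounter_key": "E1", "code_system": "icd10am", "code": "I21.4", "description": ""},
            {"encounter_key": "E2", "code_system": "icd10am", "code": "I30.0", "description": ""},
            {"encounter_key": "E5", "code_system": "snomedct", "code": "",
             "description": "Unstable angina"},
        ],
        documents=[
            {"encounter_key": "E1", "doc_type": "scanned_ecg"},
            {"encounter_key": "E2", "doc_type": "other"},
        ],
    )


HAND_EXPECTED = {
    "E1": [1, 0, 1, 0, 0, 1, 1],
    "E2": [0, 0, 0, 0, 0, 0, 0],
    "E3": [0, 1, 0, 0, 1, 0, 0],
    "E4": [0, 1, 0, 1, 0, 0, 0],
    "E5": [0, 0, 0, 0, 0, 1, 0],
}
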