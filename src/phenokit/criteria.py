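"""Evaluation of the seven per-encounter inclusion criteria.

Each criterion is an OR over rows of one child table of the extract:

1. keyword match in the Reason-for-Visit free text,
2. cardiac-pathway care plan flag OR keyword match in the ED triage text,
3. a relevant order (troponin, 12-lead ECG, or a listed investigation),
4. presence of a Cardiac Monitoring form,
5. a recorded result from a relevant imaging procedure,
6. an ICD-10-AM code with prefix I21-I25 OR a listed SNOMED CT diagnosis
   phrase in the description,
7. presence of a scanned 12-lead ECG image.

An encounter's score is the number of criteria met (0-7); any score >= 1
makes the encounter eligible for the index cohort.
"""

from __future__ import annotations

import pandas as pd

from .emr_tables import TableBundle
from .lexicon import Lexicon, match_text

FLAG_COLUMNS = ["c1", "c2", "c3", "c4", "c5", "c6", "c7"]

CRITERION_LABELS = {
    "c1": "Presenting problem keyword match",
    "c2": "Triage information keyword match",
    "c3": "Related order",
    "c4": "Cardiac monitoring form",
    "c5": "Related procedure",
    "c6": "ICD-10/SNOMED CT",
    "c7": "Scanned ECG image",
}

QUALIFYING_ORDER_CATEGORIES = frozenset({
    "troponin",
    "ecg_12_lead",
    "coronary_angiogram",
    "exercise_stress_test",
    "stress_echocardiogram",
    "sestamibi",
    "ct_coronary_angiogram",
    "ct_pulmonary_angiogram",
})

QUALIFYING_RESULT_MODALITIES = frozenset({
    "sestamibi",
    "ct_coronary_angiogram",
    "ct_aortic_angiogram",
    "ct_pulmonary_angiogram",
})

ICD_PREFIXES = ("I21", "I22", "I23", "I24", "I25")

SNOMED_PHRASES = (
    "acute myocardial infarction",
    "acute non-st segment elevation",
    "acute st segment elevation",
    "acute non-q wave infarction",
    "angina",
)


def eval_c1_reason_for_visit(rfv_rows: pd.DataFrame, lexicon: Lexicon) -> bool:
    return any(bool(match_text(t, lexicon)) for t in rfv_rows["free_text"])


def eval_c2_triage(form_rows: pd.DataFrame, lexicon: Lexicon) -> bool:
    if form_rows["cardiac_pathway_flag"].any():
        return True
    triage = form_rows.loc[form_rows["form_type"] == "ed_triage", "free_text"]
    return any(bool(match_text(t, lexicon)) for t in triage)


def eval_c3_orders(order_rows: pd.DataFrame) -> bool:
    return order_rows["order_category"].isin(QUALIFYING_ORDER_CATEGORIES).any()


def eval_c4_cardiac_monitoring(form_rows: pd.DataFrame) -> bool:
    return (form_rows["form_type"] == "cardiac_monitoring").any()


def eval_c5_scan_results(result_rows: pd.DataFrame) -> bool:
    return (
        result_rows["result_present"]
        & result_rows["result_modality"].isin(QUALIFYING_RESULT_MODALITIES)
    ).any()


def normalise_icd(code: str) -> str:
    """Upper-case and strip dots/whitespace before prefix matching."""
    return "".join(code.split()).replace(".", "").upper()


def eval_c6_diagnosis(dx_rows: pd.DataFrame) -> bool:
    for _, row in dx_rows.iterrows():
        if row["code_system"] == "icd10am":
            code = normalise_icd(row["code"])
            if not code:
                continue  # malformed empty code: skip row
            if code.startswith(ICD_PREFIXES):
                return True
        elif row["code_system"] == "snomedct":
            desc = row["description"].lower()
            if any(p in desc for p in SNOMED_PHRASES):
                return True
    return False


def eval_c7_ecg_image(doc_rows: pd.DataFrame) -> bool:
    return (doc_rows["doc_type"] == "scanned_ecg").any()


def _match_series(texts: pd.Series, lexicon: Lexicon) -> pd.Series:
    return texts.map(lambda t: bool(match_text(t, lexicon)))


def _flag_keys(child: pd.DataFrame, hit_mask) -> set:
    return set(child.loc[hit_mask, "encounter_key"])


def evaluate_all(bundle: TableBundle, lexicon: Lexicon) -> pd.DataFrame:
    """Flag every encounter against all seven criteria.

    Returns one row per encounter with columns ``encounter_key``, ``c1``..
    ``c7`` (bool), ``score`` (0-7) and ``eligible`` (score >= 1).  Criteria
    are evaluated table-at-a-time (vectorised) rather than per encounter; the
    result is identical to applying the per-criterion evaluators to each
    encounter's rows in turn.
    """
    hits: dict[str, set] = {}
    rfv = bundle.reason_for_visit
    hits["c1"] = _flag_keys(rfv, _match_series(rfv["free_text"], lexicon))

    forms = bundle.forms
    triage_hit = (forms["form_type"] == "ed_triage") & _match_series(forms["free_text"], lexicon)
    hits["c2"] = _flag_keys(forms, forms["cardiac_pathway_flag"] | triage_hit)
    hits["c4"] = _flag_keys(forms, forms["form_type"] == "cardiac_monitoring")

    orders = bundle.orders
    hits["c3"] = _flag_keys(orders, orders["order_category"].isin(QUALIFYING_ORDER_CATEGORIES))

    results = bundle.procedure_results
    hits["c5"] = _flag_keys(
        results,
        results["result_present"] & results["result_modality"].isin(QUALIFYING_RESULT_MODALITIES),
    )

    dx = bundle.diagnoses
    icd = (dx["code_system"] == "icd10am") & dx["code"].map(
        lambda c: normalise_icd(c).startswith(ICD_PREFIXES) if normalise_icd(c) else False
    )
    snomed = (dx["code_system"] == "snomedct") & dx["description"].map(
        lambda d: any(p in d.lower() for p in SNOMED_PHRASES)
    )
    hits["c6"] = _flag_keys(dx, icd | snomed)

    docs = bundle.documents
    hits["c7"] = _flag_keys(docs, docs["doc_type"] == "scanned_ecg")

    flags = pd.DataFrame({"encounter_key": bundle.encounters["encounter_key"].to_numpy()})
    for c in FLAG_COLUMNS:
        flags[c] = flags["encounter_key"].isin(hits[c])
    flags["score"] = flags[FLAG_COLUMNS].sum(axis=1).astype("int64")
    flags["eligible"] = flags["score"] >= 1
    return flags


def write_flags(flags: pd.DataFrame, path) -> None:
    """Write the flag table with 0/1-coded booleans."""
    out = flags.copy()
    for c in FLAG_COLUMNS + ["eligible"]:
        out[c] = out[c].astype(int)
    out.to_csv(path, index=False)


def read_flags(path) -> pd.DataFrame:
    flags = pd.read_csv(path, dtype={"encounter_key": str})
    for c in FLAG_COLUMNS + ["eligible"]:
        flags[c] = flags[c].astype(bool)
    flags["score"] = flags["score"].astype("int64")
    return flags
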