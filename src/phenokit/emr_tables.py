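"""Flat-table data model for de-identified EMR extracts.

A production EMR extract arrives as a set of delimited text tables linked by an
encounter key (and, for encounters, a person key): one encounters table plus
child tables for reason-for-visit text, clinical forms, orders, procedure
results, diagnoses and scanned documents.  This module defines the schema of
each table, the :class:`TableBundle` container holding one linked extract, and
CSV round-trip I/O with referential-integrity checking.

Conventions
-----------
* Files are UTF-8, comma-delimited, RFC-4180 quoted, with a mandatory header.
* Free-text absence is the empty string, never NaN; matching on "" is
  vacuously false downstream.
* ``year`` is derived from ``admit_ts`` (ISO-8601); ``lhd`` is derived from
  ``facility_id`` through a configurable facility->district map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

# table name -> ordered column list
TABLE_SCHEMAS: dict[str, list[str]] = {
    "encounters": ["encounter_key", "person_key", "facility_id", "lhd", "admit_ts", "year"],
    "reason_for_visit": ["encounter_key", "free_text"],
    "forms": ["encounter_key", "form_type", "free_text", "cardiac_pathway_flag"],
    "orders": ["encounter_key", "order_name", "order_category"],
    "procedure_results": ["encounter_key", "result_modality", "result_present"],
    "diagnoses": ["encounter_key", "code_system", "code", "description"],
    "documents": ["encounter_key", "doc_type"],
}

CHILD_TABLES = [t for t in TABLE_SCHEMAS if t != "encounters"]

FORM_TYPES = {"ed_triage", "cardiac_monitoring", "other"}

ORDER_CATEGORIES = {
    "troponin",
    "ecg_12_lead",
    "coronary_angiogram",
    "exercise_stress_test",
    "stress_echocardiogram",
    "sestamibi",
    "ct_coronary_angiogram",
    "ct_pulmonary_angiogram",
    "other",
}

RESULT_MODALITIES = {
    "sestamibi",
    "ct_coronary_angiogram",
    "ct_aortic_angiogram",
    "ct_pulmonary_angiogram",
    "other",
}

CODE_SYSTEMS = {"icd10am", "snomedct"}
DOC_TYPES = {"scanned_ecg", "other"}

_BOOL_COLUMNS = {
    "forms": ["cardiac_pathway_flag"],
    "procedure_results": ["result_present"],
}
_TEXT_COLUMNS = {
    "reason_for_visit": ["free_text"],
    "forms": ["free_text"],
    "diagnoses": ["code", "description"],
}


@dataclass
class SchemaConfig:
    """Catalogue maps used when deriving columns from raw extract fields.

    ``facility_lhd_map`` sends a facility code to its local health district
    label; ``order_catalogue`` sends a raw order-name string to one of the
    recognised order categories (unmapped names fall through to ``other``).
    ``orphan_policy`` controls what happens to child rows whose encounter key
    is not in the encounters table: ``"drop"`` (default) warns and removes
    them, ``"error"`` raises, ``"keep"`` retains them.
    """

    facility_lhd_map: dict[str, str] = field(default_factory=dict)
    order_catalogue: dict[str, str] = field(default_factory=dict)
    orphan_policy: str = "drop"

    def lhd_for(self, facility_id: str) -> str:
        return self.facility_lhd_map.get(str(facility_id), "unknown")

    def category_for(self, order_name: str) -> str:
        return self.order_catalogue.get(str(order_name), "other")


@dataclass
class TableBundle:
    """One linked EMR extract: seven pandas tables sharing ``encounter_key``."""

    encounters: pd.DataFrame
    reason_for_visit: pd.DataFrame
    forms: pd.DataFrame
    orders: pd.DataFrame
    procedure_results: pd.DataFrame
    diagnoses: pd.DataFrame
    documents: pd.DataFrame

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    @property
    def n_encounters(self) -> int:
        return len(self.encounters)

    def validate(self) -> None:
        """Check column schemas, key uniqueness and enum domains."""
        for name, cols in TABLE_SCHEMAS.items():
            df = self.table(name)
            if list(df.columns) != cols:
                raise ValueError(f"{name}: columns {list(df.columns)} != schema {cols}")
        if self.encounters["encounter_key"].duplicated().any():
            dups = self.encounters.loc[self.encounters["encounter_key"].duplicated(), "encounter_key"]
            raise ValueError(f"duplicate encounter_key values: {sorted(set(dups))[:5]}")
        _check_domain(self.forms, "form_type", FORM_TYPES)
        _check_domain(self.orders, "order_category", ORDER_CATEGORIES)
        _check_domain(self.procedure_results, "result_modality", RESULT_MODALITIES)
        _check_domain(self.diagnoses, "code_system", CODE_SYSTEMS)
        _check_domain(self.documents, "doc_type", DOC_TYPES)

    def orphan_rows(self) -> dict[str, pd.Index]:
        """Index of child rows whose encounter_key is absent from encounters."""
        keys = set(self.encounters["encounter_key"])
        return {
            name: self.table(name).index[~self.table(name)["encounter_key"].isin(keys)]
            for name in CHILD_TABLES
        }

    def sorted_copy(self) -> "TableBundle":
        """Copy with every table sorted by its full column tuple (canonical order)."""
        out = {}
        for name in TABLE_SCHEMAS:
            df = self.table(name)
            out[name] = df.sort_values(list(df.columns), kind="mergesort").reset_index(drop=True)
        return TableBundle(**out)

    def restrict(self, encounter_keys) -> "TableBundle":
        """New bundle containing only the given encounters (and their child rows)."""
        keys = set(encounter_keys)
        out = {}
        for name in TABLE_SCHEMAS:
            df = self.table(name)
            out[name] = df[df["encounter_key"].isin(keys)].reset_index(drop=True)
        return TableBundle(**out)


def _check_domain(df: pd.DataFrame, col: str, allowed: set[str]) -> None:
    bad = set(df[col]) - allowed
    if bad:
        raise ValueError(f"column {col}: values outside {sorted(allowed)}: {sorted(bad)[:5]}")


def empty_bundle() -> TableBundle:
    return TableBundle(**{
        name: pd.DataFrame({c: pd.Series(dtype=_dtype_for(name, c)) for c in cols})
        for name, cols in TABLE_SCHEMAS.items()
    })


def _dtype_for(table: str, col: str) -> str:
    if col in _BOOL_COLUMNS.get(table, []):
        return "bool"
    if col == "year":
        return "int64"
    return "object"


def derive_year(admit_ts: pd.Series) -> pd.Series:
    """Calendar year of the ISO-8601 admission timestamp."""
    return pd.to_datetime(admit_ts, format="ISO8601").dt.year.astype("int64")


def read_bundle(directory: str | Path, schema_config: SchemaConfig | None = None) -> TableBundle:
    """Read one extract directory (one CSV per table) into a validated bundle.

    Missing table files and unknown columns are fatal.  Orphan child rows are
    handled per ``schema_config.orphan_policy`` (default: warn and drop).
    """
    directory = Path(directory)
    config = schema_config or SchemaConfig()
    tables: dict[str, pd.DataFrame] = {}
    for name, cols in TABLE_SCHEMAS.items():
        path = directory / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"required table file missing: {path}")
        df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
        if list(df.columns) != cols:
            raise ValueError(f"{path.name}: header {list(df.columns)} != schema {cols}")
        for col in _BOOL_COLUMNS.get(name, []):
            df[col] = df[col].map({"True": True, "False": False, "true": True, "false": False,
                                   "1": True, "0": False})
            if df[col].isna().any():
                raise ValueError(f"{path.name}: column {col} has non-boolean values")
            df[col] = df[col].astype(bool)
        if name == "encounters" and len(df):
            df["year"] = df["year"].astype("int64")
        elif name == "encounters":
            df["year"] = df["year"].astype("int64")
        tables[name] = df

    bundle = TableBundle(**tables)
    orphans = bundle.orphan_rows()
    n_orphans = {name: len(idx) for name, idx in orphans.items() if len(idx)}
    if n_orphans:
        if config.orphan_policy == "error":
            raise ValueError(f"orphan child rows (encounter_key not in encounters): {n_orphans}")
        if config.orphan_policy == "drop":
            for name, idx in orphans.items():
                if len(idx):
                    logger.warning("dropping %d orphan row(s) from %s", len(idx), name)
                    tables[name] = tables[name].drop(index=idx).reset_index(drop=True)
            bundle = TableBundle(**tables)
        else:
            logger.warning("keeping orphan rows per policy: %s", n_orphans)
    bundle.validate()
    return bundle


def write_bundle(bundle: TableBundle, directory: str | Path) -> Path:
    """Write every table as UTF-8 CSV; inverse of :func:`read_bundle`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    bundle.validate()
    for name in TABLE_SCHEMAS:
        bundle.table(name).to_csv(directory / f"{name}.csv", index=False, encoding="utf-8")
    return directory
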