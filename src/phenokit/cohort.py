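"""Index/reference cohort split and historical-record attachment.

Eligible encounters (score >= 1) form the index cohort; score-0 encounters
are reference encounters.  For every person with at least one index
encounter, their reference encounters admitted on or after a configurable
epoch (default 2002-01-01, the EMR system go-live) are co-extracted as
history.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .emr_tables import TableBundle, write_bundle

DEFAULT_EPOCH = "2002-01-01"


@dataclass
class CohortResult:
    index_keys: set = field(default_factory=set)
    reference_keys: set = field(default_factory=set)
    history_keys: set = field(default_factory=set)

    def __post_init__(self):
        assert not (self.index_keys & self.reference_keys), "index/reference overlap"
        assert self.history_keys <= self.reference_keys, "history outside reference"

    @property
    def extraction_keys(self) -> set:
        """Encounters whose full records are extracted: index plus history."""
        return self.index_keys | self.history_keys


def split_cohort(flags: pd.DataFrame) -> CohortResult:
    """Partition encounters into index (eligible) and reference (score 0)."""
    if flags["encounter_key"].duplicated().any():
        raise ValueError("duplicate encounter_key in flags table")
    index = set(flags.loc[flags["eligible"], "encounter_key"])
    reference = set(flags.loc[~flags["eligible"], "encounter_key"])
    return CohortResult(index_keys=index, reference_keys=reference)


def attach_history(
    cohort: CohortResult,
    encounters: pd.DataFrame,
    epoch: str = DEFAULT_EPOCH,
) -> CohortResult:
    """Add reference encounters of index persons admitted on/after ``epoch``.

    The epoch bound is inclusive at 00:00 of the epoch date.  Idempotent:
    reapplying with the same inputs leaves the result unchanged.
    """
    epoch_ts = pd.Timestamp(epoch)
    enc = encounters
    index_persons = set(enc.loc[enc["encounter_key"].isin(cohort.index_keys), "person_key"])
    admit = pd.to_datetime(enc["admit_ts"], format="ISO8601")
    mask = (
        enc["encounter_key"].isin(cohort.reference_keys)
        & enc["person_key"].isin(index_persons)
        & (admit >= epoch_ts)
    )
    return CohortResult(
        index_keys=set(cohort.index_keys),
        reference_keys=set(cohort.reference_keys),
        history_keys=set(enc.loc[mask, "encounter_key"]),
    )


def extract_cohort(
    bundle: TableBundle,
    cohort: CohortResult,
    out_dir: str | Path,
) -> Path:
    """Write key lists and the bundle filtered to index + history encounters."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, keys in [("index_keys", cohort.index_keys), ("history_keys", cohort.history_keys)]:
        pd.DataFrame({"encounter_key": sorted(keys)}).to_csv(out_dir / f"{name}.csv", index=False)
    write_bundle(bundle.restrict(cohort.extraction_keys), out_dir / "extract")
    return out_dir
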