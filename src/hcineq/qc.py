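"""Exclusion cascade and duplicate detection for raw survey records.

The cascade mirrors the study's participant flow, applied in a fixed order:

1. remove non-consenting records and records whose age is unconfirmed
   (missing/non-numeric) or under 16;
2. remove incomplete responses — respondents who answered *no* question in
   any of the eight completeness-defining sections (sensory, communication,
   anxiety, access-advocacy, system-problems, shutdowns, meltdowns,
   autism-specific);
3. remove suspected duplicate responses: any record whose 12-field match
   key equals that of an earlier record (first occurrence kept);
4. remove records whose autism status cannot be confirmed (self-diagnosed,
   suspected, awaiting assessment, or a reported diagnosis without its
   confirmation details).

Each removed pid is logged under exactly one reason and the ledger
conserves counts: input total = output total + sum of exclusions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import schema
from .catalog import AUTISM_QUESTIONS, ItemCatalog, default_catalog

__all__ = [
    "ExclusionLedger",
    "SchemaError",
    "apply_exclusions",
    "detect_duplicates",
    "classify_autism_status",
    "classify_autism_status_frame",
    "match_key",
]

log = logging.getLogger(__name__)

REASONS = ("no_consent_or_age", "incomplete", "duplicate", "unconfirmed_status")


class SchemaError(KeyError):
    """A required QC column is absent from the input table."""


@dataclass
class ExclusionLedger:
    """Counts and pids removed per reason, in cascade order."""

    input_total: int = 0
    output_total: int = 0
    excluded: dict[str, list[str]] = field(
        default_factory=lambda: {r: [] for r in REASONS})

    def counts(self) -> dict[str, int]:
        return {r: len(p) for r, p in self.excluded.items()}

    @property
    def total_excluded(self) -> int:
        return sum(len(p) for p in self.excluded.values())

    def is_conserved(self) -> bool:
        return self.input_total == self.output_total + self.total_excluded

    def to_frame(self) -> pd.DataFrame:
        rows = [{"reason": r, "n": len(p), "pids": ";".join(p)}
                for r, p in self.excluded.items()]
        rows.append({"reason": "retained", "n": self.output_total, "pids": ""})
        return pd.DataFrame(rows)


_REQUIRED = (
    schema.PID, schema.CONSENTED, schema.AGE, schema.AUTISM_DIAGNOSIS,
    schema.SELF_IDENTIFICATION, schema.DIAGNOSIS_LABEL,
    schema.PRACTITIONER_TYPE, schema.DIAGNOSIS_YEAR,
)


def _require_columns(records: pd.DataFrame, names) -> None:
    for name in names:
        if name not in records.columns:
            raise SchemaError(f"required column missing: {name!r}")


# ---------------------------------------------------------------------------
# duplicate detection
# ---------------------------------------------------------------------------

_MISSING = "\x00missing"


def match_key(record: pd.Series) -> tuple:
    """The 12-criteria match key of one record (missing == missing)."""
    out = []
    for f in schema.MATCH_KEY_FIELDS:
        v = record[f]
        out.append(_MISSING if pd.isna(v) else str(v))
    return tuple(out)


def detect_duplicates(records: pd.DataFrame) -> set[str]:
    """Pids of records matching ANY earlier record on all 12 criteria.

    Input order is arrival order; the first occurrence of each key is kept.
    """
    _require_columns(records, (schema.PID,) + schema.MATCH_KEY_FIELDS)
    parts = []
    for f in schema.MATCH_KEY_FIELDS:
        col = records[f]
        parts.append(col.astype(object).where(col.notna(), _MISSING).astype(str))
    keys = pd.Series(list(zip(*parts)), index=records.index)
    flagged = keys.duplicated(keep="first")
    return set(records.loc[flagged, schema.PID])


# ---------------------------------------------------------------------------
# autism-status confirmation
# ---------------------------------------------------------------------------

def classify_autism_status(record: pd.Series) -> str:
    """Confirm one record's autism status from its diagnosis fields.

    ``confirmed-autistic`` needs a reported clinical diagnosis plus all
    three confirmation fields (specific diagnosis, practitioner type, year);
    an explicit no-diagnosis with no self-identification is
    ``confirmed-non-autistic``; anything else (self-diagnosed, suspected,
    awaiting assessment, missing confirmations, contradictory fields) is
    ``unconfirmed``.
    """
    diagnosis = record.get(schema.AUTISM_DIAGNOSIS)
    self_id = record.get(schema.SELF_IDENTIFICATION)
    confirmations = [record.get(schema.DIAGNOSIS_LABEL),
                     record.get(schema.PRACTITIONER_TYPE),
                     record.get(schema.DIAGNOSIS_YEAR)]
    has_all = all(pd.notna(v) for v in confirmations)
    has_any = any(pd.notna(v) for v in confirmations)

    if pd.isna(diagnosis):
        return schema.UNCONFIRMED
    if diagnosis == "yes":
        return schema.CONFIRMED_AUTISTIC if has_all else schema.UNCONFIRMED
    if pd.notna(self_id) and self_id != "none":
        return schema.UNCONFIRMED
    if has_any:
        # diagnosis == "no" but confirmation details present
        log.warning("contradictory diagnosis fields for pid %s; "
                    "status left unconfirmed", record.get(schema.PID))
        return schema.UNCONFIRMED
    return schema.CONFIRMED_NON_AUTISTIC


def classify_autism_status_frame(records: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`classify_autism_status` over a cohort table."""
    _require_columns(records, _REQUIRED[3:])
    diag = records[schema.AUTISM_DIAGNOSIS]
    self_id = records[schema.SELF_IDENTIFICATION].fillna("none")
    has_all = (records[schema.DIAGNOSIS_LABEL].notna()
               & records[schema.PRACTITIONER_TYPE].notna()
               & records[schema.DIAGNOSIS_YEAR].notna())
    has_any = (records[schema.DIAGNOSIS_LABEL].notna()
               | records[schema.PRACTITIONER_TYPE].notna()
               | records[schema.DIAGNOSIS_YEAR].notna())

    status = pd.Series(schema.UNCONFIRMED, index=records.index, dtype=object)
    status[(diag == "yes") & has_all] = schema.CONFIRMED_AUTISTIC
    clean_no = (diag == "no") & (self_id == "none") & ~has_any
    status[clean_no] = schema.CONFIRMED_NON_AUTISTIC
    contradictory = (diag == "no") & (self_id == "none") & has_any
    if contradictory.any():
        log.warning("%d records with contradictory diagnosis fields; "
                    "status left unconfirmed", int(contradictory.sum()))
    return status


# ---------------------------------------------------------------------------
# completeness
# ---------------------------------------------------------------------------

def _is_incomplete(records: pd.DataFrame, catalog: ItemCatalog) -> pd.Series:
    """True where a record answered nothing in any of the eight sections."""
    answered = pd.Series(False, index=records.index)
    for item in catalog.scored_items():
        col = schema.item_col(item.id)
        if col in records.columns:
            answered |= records[col].notna()
    for sid in catalog.situations:
        for col in (schema.shutdown_col(sid), schema.meltdown_col(sid)):
            if col in records.columns:
                answered |= records[col].fillna(False).astype(bool)
    for q in AUTISM_QUESTIONS:
        col = schema.autism_q_col(q)
        if col in records.columns:
            answered |= records[col].notna()
    return ~answered


# ---------------------------------------------------------------------------
# the cascade
# ---------------------------------------------------------------------------

def apply_exclusions(records: pd.DataFrame,
                     catalog: ItemCatalog | None = None,
                     ) -> tuple[pd.DataFrame, ExclusionLedger]:
    """Run the four-step exclusion cascade.

    Returns the analysis cohort (with a derived ``autism_status`` column)
    and the :class:`ExclusionLedger`.  Reasons are applied in the fixed
    order consent/age -> incomplete -> duplicate -> unconfirmed, and each
    pid appears under at most one reason.
    """
    catalog = catalog if catalog is not None else default_catalog()
    _require_columns(records, _REQUIRED)
    ledger = ExclusionLedger(input_total=len(records))
    kept = records

    age = pd.to_numeric(kept[schema.AGE], errors="coerce")
    bad = ~kept[schema.CONSENTED].fillna(False).astype(bool) | age.isna() | (age < 16)
    ledger.excluded["no_consent_or_age"] = list(kept.loc[bad, schema.PID])
    kept = kept.loc[~bad]

    inc = _is_incomplete(kept, catalog)
    ledger.excluded["incomplete"] = list(kept.loc[inc, schema.PID])
    kept = kept.loc[~inc]

    dup_pids = detect_duplicates(kept)
    is_dup = kept[schema.PID].isin(dup_pids)
    ledger.excluded["duplicate"] = list(kept.loc[is_dup, schema.PID])
    kept = kept.loc[~is_dup]

    status = classify_autism_status_frame(kept)
    unc = status == schema.UNCONFIRMED
    ledger.excluded["unconfirmed_status"] = list(kept.loc[unc, schema.PID])
    kept = kept.loc[~unc].copy()
    kept[schema.AUTISM_STATUS] = status.loc[kept.index]

    ledger.output_total = len(kept)
    assert ledger.is_conserved()
    log.info("exclusion cascade: %s -> %s kept (%s)",
             ledger.input_total, ledger.output_total, ledger.counts())
    return kept.reset_index(drop=True), ledger
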