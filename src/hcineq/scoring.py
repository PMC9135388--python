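"""Likert binarization, item polarity, and healthcare-inequality scores.

Each 4-level Likert response collapses to endorse/reject; the item's
polarity flag then codes the response as 1 point (the negative experience)
or 0 points (the positive experience).  A section score is the proportion
of answered items in that section scored 1, so it lives in [0, 1]; the
total score pools all answered items across the five scored sections
(31 items).  Unanswered items never enter the denominator, and a
participant who answered nothing in a section has an undefined score
(``None``), excluded from downstream models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import schema
from .catalog import SCORED_SECTIONS, ItemCatalog, default_catalog

__all__ = [
    "ScoreEntry",
    "binarize_likert",
    "item_inequality_point",
    "section_score",
    "total_score",
    "score_frame",
    "shutdown_meltdown_flags",
    "TOTAL",
]

#: Key used for the pooled all-sections score.
TOTAL = "total"


@dataclass(frozen=True)
class ScoreEntry:
    """One participant's score for one section (or the total)."""

    points: int
    answered: int
    score: float | None

    def __post_init__(self):
        if self.answered < 0 or not (0 <= self.points <= max(self.answered, 0)):
            raise ValueError("points must lie in [0, answered]")


def binarize_likert(response) -> str | None:
    """Collapse a 4-level Likert label to ``endorse``/``reject``/missing."""
    if response is None or (isinstance(response, float) and np.isnan(response)):
        return None
    if response in schema.LIKERT_ENDORSE:
        return schema.ENDORSE
    if response in schema.LIKERT_REJECT:
        return schema.REJECT
    raise ValueError(f"unknown Likert label: {response!r}")


def item_inequality_point(binary: str | None, endorse_is_negative: bool) -> int | None:
    """1 iff the response expresses the negative experience; missing propagates."""
    if binary is None:
        return None
    if binary == schema.ENDORSE:
        return 1 if endorse_is_negative else 0
    if binary == schema.REJECT:
        return 0 if endorse_is_negative else 1
    raise ValueError(f"unknown binary value: {binary!r}")


def _entry_from_points(points_list) -> ScoreEntry:
    answered = sum(1 for p in points_list if p is not None)
    points = sum(p for p in points_list if p is not None)
    score = points / answered if answered else None
    return ScoreEntry(points=points, answered=answered, score=score)


def section_score(record: pd.Series, catalog: ItemCatalog,
                  section: str) -> ScoreEntry:
    """Score one participant on one of the five scored sections."""
    if section not in SCORED_SECTIONS:
        raise ValueError(f"{section!r} is not a scored section")
    pts = [
        item_inequality_point(
            binarize_likert(record.get(schema.item_col(it.id))),
            it.endorse_is_negative)
        for it in catalog.section_items(section)
    ]
    return _entry_from_points(pts)


def total_score(record: pd.Series, catalog: ItemCatalog) -> ScoreEntry:
    """Score one participant across all answered scored items (31)."""
    pts = [
        item_inequality_point(
            binarize_likert(record.get(schema.item_col(it.id))),
            it.endorse_is_negative)
        for it in catalog.scored_items()
    ]
    return _entry_from_points(pts)


def score_frame(records: pd.DataFrame,
                catalog: ItemCatalog | None = None) -> pd.DataFrame:
    """Per-participant section and total scores for a whole cohort.

    Returns a frame indexed like ``records`` with, per section and for the
    total: ``<name>_points``, ``<name>_answered``, ``<name>_score`` (NaN
    where the participant answered no item of the section).
    """
    catalog = catalog if catalog is not None else default_catalog()
    out: dict[str, np.ndarray] = {}
    if schema.PID in records.columns:
        out[schema.PID] = records[schema.PID].to_numpy()

    point_cols: dict[str, pd.DataFrame] = {}
    for sec in SCORED_SECTIONS:
        cols = {}
        for it in catalog.section_items(sec):
            col = records.get(schema.item_col(it.id))
            if col is None:
                continue
            endorsed = col.isin(schema.LIKERT_ENDORSE)
            rejected = col.isin(schema.LIKERT_REJECT)
            unknown = col.notna() & ~endorsed & ~rejected
            if unknown.any():
                bad = col[unknown].iloc[0]
                raise ValueError(f"unknown Likert label: {bad!r}")
            neg = endorsed if it.endorse_is_negative else rejected
            pts = pd.Series(np.where(col.notna(), neg.astype(float), np.nan),
                            index=records.index)
            cols[it.id] = pts
        point_cols[sec] = pd.DataFrame(cols, index=records.index)

    total_pts = pd.concat(point_cols.values(), axis=1)
    for name, block in [*point_cols.items(), (TOTAL, total_pts)]:
        answered = block.notna().sum(axis=1)
        points = block.sum(axis=1, min_count=1).fillna(0).astype(int)
        score = points.where(answered > 0) / answered.replace(0, np.nan)
        out[f"{name}_points"] = points.to_numpy()
        out[f"{name}_answered"] = answered.to_numpy()
        out[f"{name}_score"] = score.to_numpy()
    return pd.DataFrame(out, index=records.index)


def shutdown_meltdown_flags(record: pd.Series,
                            situations) -> tuple[np.ndarray, np.ndarray]:
    """Independent shutdown and meltdown flags per situation.

    Both flags may be set for the same situation; returns two binary
    vectors ordered like ``situations``.
    """
    sd = np.array([bool(record.get(schema.shutdown_col(s), False))
                   for s in situations], dtype=int)
    md = np.array([bool(record.get(schema.meltdown_col(s), False))
                   for s in situations], dtype=int)
    return sd, md
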