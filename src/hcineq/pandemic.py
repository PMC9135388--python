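"""Pandemic-era assignment and before/during healthcare-quality contrasts.

The most recent appointment is assigned to the 'during pandemic' era iff
its full date falls on or after the WHO pandemic declaration (2020-03-11);
earlier full dates are 'pre'.  Partial dates (missing day and/or month)
and unparseable text are excluded — only respondents who gave complete
date information enter the era analyses.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from datetime import date

import pandas as pd

from . import schema
from .catalog import SECTION_RECENT, ItemCatalog, default_catalog
from .stats import (DegenerateTableError, OddsRatioEstimate, build_two_by_two,
                    is_case, odds_ratio, _binarize_column)

__all__ = [
    "PANDEMIC_CUTOFF",
    "ERA_PRE",
    "ERA_DURING",
    "ERA_EXCLUDED",
    "EraAssignment",
    "parse_survey_date",
    "assign_era",
    "assign_era_frame",
    "era_contrasts",
]

log = logging.getLogger(__name__)

PANDEMIC_CUTOFF = date(2020, 3, 11)
ERA_PRE = "pre"
ERA_DURING = "during"
ERA_EXCLUDED = "excluded"

_ISO_FULL = re.compile(r"^(\d{4})-(\d{1,2})-(\d{1,2})$")
_ISO_MONTH = re.compile(r"^(\d{4})-(\d{1,2})$")
_ISO_YEAR = re.compile(r"^(\d{4})$")
_DMY = re.compile(r"^(\d{1,2})/(\d{1,2})/(\d{4})$")
_MY = re.compile(r"^(\d{1,2})/(\d{4})$")


@dataclass(frozen=True)
class EraAssignment:
    pid: str
    era: str
    appointment_date: str | None


def parse_survey_date(value) -> tuple[int | None, int | None, int | None]:
    """Parse an appointment date into (year, month, day), None per missing part.

    Accepts ISO dialects (YYYY-MM-DD, YYYY-MM, YYYY) and day-first slash
    dialects (DD/MM/YYYY, MM/YYYY).  Two-digit years are rejected rather
    than guessed; unparseable text raises ValueError.
    """
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return (None, None, None)
    s = str(value).strip()
    if not s:
        return (None, None, None)
    if m := _ISO_FULL.match(s):
        y, mo, d = (int(g) for g in m.groups())
    elif m := _ISO_MONTH.match(s):
        y, mo, d = int(m.group(1)), int(m.group(2)), None
    elif m := _ISO_YEAR.match(s):
        y, mo, d = int(m.group(1)), None, None
    elif m := _DMY.match(s):
        d, mo, y = (int(g) for g in m.groups())
    elif m := _MY.match(s):
        y, mo, d = int(m.group(2)), int(m.group(1)), None
    else:
        raise ValueError(f"unparseable appointment date: {value!r}")
    if d is not None:
        date(y, mo, d)  # range check
    elif mo is not None and not (1 <= mo <= 12):
        raise ValueError(f"month out of range in {value!r}")
    return (y, mo, d)


def assign_era(appointment_date, cutoff: date = PANDEMIC_CUTOFF) -> str:
    """Era of one appointment: ``during`` iff the full date >= cutoff,
    ``pre`` iff the full date < cutoff, ``excluded`` for partial, missing,
    or unparseable dates."""
    try:
        y, mo, d = parse_survey_date(appointment_date)
    except ValueError:
        log.warning("unparseable appointment date %r; excluded",
                    appointment_date)
        return ERA_EXCLUDED
    if y is None or mo is None or d is None:
        return ERA_EXCLUDED
    return ERA_DURING if date(y, mo, d) >= cutoff else ERA_PRE


def assign_era_frame(records: pd.DataFrame,
                     cutoff: date = PANDEMIC_CUTOFF) -> pd.Series:
    """Vectorized era assignment over a cohort table."""
    return records[schema.APPOINTMENT_DATE].map(
        lambda v: assign_era(v, cutoff))


def _contrast_rows(records: pd.DataFrame, items, case_mask: pd.Series,
                   label: str, or_method: str) -> list[dict]:
    rows = []
    for item in items:
        col = records[schema.item_col(item.id)]
        try:
            t = build_two_by_two(_binarize_column(col), case_mask)
        except DegenerateTableError:
            log.info("contrast %s / item %s skipped: empty cell", label, item.id)
            continue
        est = odds_ratio(t, method=or_method)
        rows.append({
            "contrast": label, "item": item.id,
            "exposed_n": t.a, "exposed_pct": 100.0 * t.a / t.n_case,
            "reference_n": t.c, "reference_pct": 100.0 * t.c / t.n_control,
            "or": est.or_point, "ci_low": est.ci_low, "ci_high": est.ci_high,
            "p_value": est.p_value, "sig": est.sig_label,
        })
    return rows


def era_contrasts(records: pd.DataFrame, catalog: ItemCatalog | None = None,
                  cutoff: date = PANDEMIC_CUTOFF,
                  or_method: str = "cross-product") -> pd.DataFrame:
    """The four era contrasts on the most-recent-appointment items.

    Using only era-assigned (full-date) records: (1) case vs control within
    the pre era; (2) case vs control within the during era; (3) during vs
    pre within cases; (4) during vs pre within controls.  For the within-
    group contrasts the OR is odds(endorse | during) / odds(endorse | pre).
    """
    catalog = catalog if catalog is not None else default_catalog()
    items = catalog.section_items(SECTION_RECENT)
    era = assign_era_frame(records, cutoff)
    case = is_case(records)

    rows: list[dict] = []
    for era_label in (ERA_PRE, ERA_DURING):
        sub = records[era == era_label]
        rows += _contrast_rows(sub, items, case.loc[sub.index],
                               f"{era_label}:case-vs-control", or_method)
    for group_label, flag in (("case", True), ("control", False)):
        sub = records[(case == flag) & era.isin([ERA_PRE, ERA_DURING])]
        during_mask = era.loc[sub.index] == ERA_DURING
        rows += _contrast_rows(sub, items, during_mask,
                               f"{group_label}:during-vs-pre", or_method)
    return pd.DataFrame(rows)
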