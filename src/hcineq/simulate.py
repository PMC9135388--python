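"""Seeded synthetic-cohort generator.

The respondent-level survey data behind the healthcare-inequality analysis
are not publicly shareable, so every downstream stage here is exercised on
synthetic cohorts with the same statistical structure: two groups (autistic
cases, non-autistic controls), group-dependent item endorsement rates with
known (planted) odds ratios, demographic marginals matching the published
demographics table, missing-completely-at-random covariates and item
nonresponse, plus planted duplicates, incomplete responses, and
unconfirmed-diagnosis records for the QC cascade to find.

Item endorsement is calibrated by inverting the odds-ratio definition: given
a control endorsement probability ``p0`` and a target OR, the case
probability is ``p1 = OR*p0 / (1 - p0 + OR*p0)``, so the population
cross-product OR of the generated tables equals the planted OR.  Items are
conditionally independent given group; real survey items are correlated
within section, so the generator is a calibration tool, not a portrait of
the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from scipy.special import expit as _expit, logit as _logit

from . import published, schema
from .catalog import (
    AUTISM_QUESTIONS,
    AUTISM_Q_LEVELS,
    ItemCatalog,
    default_catalog,
)

__all__ = [
    "GeneratorConfig",
    "SyntheticCohort",
    "CohortManifest",
    "endorsement_probability_from_or",
    "score_calibrated_config",
    "generate_cohort",
    "plant_duplicates",
    "write_cohort",
    "read_cohort",
]


def endorsement_probability_from_or(p0: float, or_target: float) -> float:
    """Case endorsement probability giving odds(p1)/odds(p0) = ``or_target``.

    Parameters
    ----------
    p0
        Control endorsement probability, strictly inside (0, 1).
    or_target
        Target odds ratio, strictly positive.
    """
    if not (0.0 < p0 < 1.0):
        raise ValueError(f"p0 must be in (0, 1), got {p0!r}")
    if not (or_target > 0.0):
        raise ValueError(f"or_target must be positive, got {or_target!r}")
    return or_target * p0 / (1.0 - p0 + or_target * p0)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def _default_item_effects() -> dict[str, tuple[float, float]]:
    return {
        r.key: (r.control_pct / 100.0, r.or_unadjusted)
        for r in published.EXPERIENCE_ROWS + published.RECENT_PRE_ROWS
    }


def _default_shutdown_effects() -> dict[str, tuple[float, float]]:
    return {r.key: (r.control_pct / 100.0, r.or_unadjusted)
            for r in published.SHUTDOWN_ROWS}


def _default_meltdown_effects() -> dict[str, tuple[float, float]]:
    return {r.key: (r.control_pct / 100.0, r.or_unadjusted)
            for r in published.MELTDOWN_ROWS}


def _default_condition_effects() -> dict[str, dict[str, tuple[float, float]]]:
    # Published sex-specific ORs; control base rates are not published, so
    # plausible lifetime prevalences are assumed (see docs/methods.md).
    return {
        "arthritis":         {"F": (0.12, 1.883), "M": (0.08, 1.833)},
        "breathing_concern": {"F": (0.12, 1.617), "M": (0.10, 1.678)},
        "adhd":              {"F": (0.04, 3.352), "M": (0.05, 3.227)},
        "anxiety":           {"F": (0.25, 4.289), "M": (0.20, 4.000)},
        "depression":        {"F": (0.30, 4.097), "M": (0.25, 3.318)},
        "insomnia":          {"F": (0.12, 2.667), "M": (0.10, 2.903)},
    }


def _default_covariate_dists() -> dict[str, dict[str, dict[str, float]]]:
    def norm(d):
        s = sum(d.values())
        return {k: v / s for k, v in d.items()}

    return {
        "sex_at_birth": {
            "case": norm({"F": 816, "M": 465, "Other": 4}),
            "control": norm({"F": 864, "M": 500, "Other": 0}),
        },
        "gender": {
            "case": norm({"female": 60.04, "male": 35.78,
                          "non-binary": 2.64, "other": 1.54}),
            "control": norm({"female": 52.06, "male": 33.93,
                             "non-binary": 9.49, "other": 4.36}),
        },
        "ethnicity": {
            "case": norm({"white": 1098, "non-white": 179}),
            "control": norm({"white": 1059, "non-white": 299}),
        },
        "education": {
            "case": norm({
                "No formal qualifications": 60,
                "Secondary School/High School": 220,
                "Further vocational qualifications": 200,
                "University Undergraduate": 400,
                "University Postgraduate": 405,
            }),
            "control": norm({
                "No formal qualifications": 30,
                "Secondary School/High School": 250,
                "Further vocational qualifications": 152,
                "University Undergraduate": 405,
                "University Postgraduate": 524,
            }),
        },
        "country": {
            "case": norm({
                "United Kingdom": 839, "United States": 141, "Germany": 40,
                "Australia": 20, "Canada": 41, "Netherlands": 25, "Other": 177,
            }),
            "control": norm({
                "United Kingdom": 589, "United States": 153, "Germany": 29,
                "Australia": 37, "Canada": 52, "Netherlands": 34, "Other": 467,
            }),
        },
    }


@dataclass
class GeneratorConfig:
    """Study-condition defaults for the synthetic cohort.

    The defaults emulate the published study: 1285 cases and 1364 controls
    in the analysis cohort, plus 1371 incomplete, 112 duplicate, and 26
    unconfirmed-status records (4158 survey accesses in total); covariate
    marginals from the published demographics; covariate missingness 5.29% /
    1.13% / 1.89% for ethnicity / education / country; item nonresponse 5%
    per question; appointment dates spanning 2019-07-01 to 2021-01-31.
    """

    n_case: int = 1285
    n_control: int = 1364
    covariate_dists: dict = field(default_factory=_default_covariate_dists)
    age_dist: dict = field(default_factory=lambda: {
        "case": (41.26, 14.48), "control": (38.40, 16.06)})
    aq10_dist: dict = field(default_factory=lambda: {
        "case": (8.02, 1.88), "control": (3.78, 2.60)})
    item_effects: Mapping[str, tuple[float, float]] = field(
        default_factory=_default_item_effects)
    shutdown_effects: Mapping[str, tuple[float, float]] = field(
        default_factory=_default_shutdown_effects)
    meltdown_effects: Mapping[str, tuple[float, float]] = field(
        default_factory=_default_meltdown_effects)
    condition_effects: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=_default_condition_effects)
    likert_split: float = 0.5
    latent_trait_sd: float = 0.0
    response_style_sd: float = 0.0
    covariate_missing_rates: Mapping[str, float] = field(default_factory=lambda: {
        schema.ETHNICITY: 0.0529,
        schema.EDUCATION: 0.0113,
        schema.COUNTRY: 0.0189,
    })
    item_missing_rate: float = 0.05
    n_duplicates: int = 112
    n_incomplete: int = 1371
    n_unconfirmed: int = 26
    appointment_date_range: tuple[str, str] = ("2019-07-01", "2021-01-31")
    partial_date_fraction: float = 0.15
    missing_date_fraction: float = 0.05
    family_autism_rates: Mapping[str, float] = field(default_factory=lambda: {
        "case": 0.40, "control": 0.15})
    catalog: ItemCatalog = field(default_factory=default_catalog)
    seed: int = 0

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.n_case < 0 or self.n_control < 0:
            raise ValueError("group sizes must be non-negative")
        for nm in ("n_duplicates", "n_incomplete", "n_unconfirmed"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be non-negative")
        if self.n_duplicates + self.n_incomplete + self.n_unconfirmed > (
                self.n_case + self.n_control):
            raise ValueError(
                "planted extras exceed the core cohort size "
                "(n_duplicates + n_incomplete + n_unconfirmed "
                "must be <= n_case + n_control)")
        if not (0.0 <= self.likert_split <= 1.0):
            raise ValueError("likert_split must be in [0, 1]")
        if self.latent_trait_sd < 0 or self.response_style_sd < 0:
            raise ValueError("heterogeneity SDs must be non-negative")
        if not (0.0 <= self.item_missing_rate <= 0.1):
            raise ValueError("item_missing_rate must be in [0, 0.1]")
        for cov, rate in self.covariate_missing_rates.items():
            if not (0.0 <= rate < 1.0):
                raise ValueError(f"missing rate for {cov} must be in [0, 1)")
        for table in self.covariate_dists.values():
            for group, probs in table.items():
                total = sum(probs.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(
                        f"categorical table for group {group!r} sums to "
                        f"{total}, not 1")
                if any(p < 0 or p > 1 for p in probs.values()):
                    raise ValueError("categorical probabilities must be in [0, 1]")
        for item_id, (p0, or_t) in self.item_effects.items():
            if not (0.0 < p0 < 1.0) or or_t <= 0:
                raise ValueError(f"invalid effect for item {item_id!r}")
        lo, hi = (date.fromisoformat(d) for d in self.appointment_date_range)
        if lo > hi:
            raise ValueError("appointment_date_range is reversed")

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        payload.pop("catalog")
        payload["item_effects"] = {k: list(v) for k, v in self.item_effects.items()}
        payload["shutdown_effects"] = {k: list(v) for k, v in self.shutdown_effects.items()}
        payload["meltdown_effects"] = {k: list(v) for k, v in self.meltdown_effects.items()}
        payload["condition_effects"] = {
            k: {s: list(e) for s, e in v.items()}
            for k, v in self.condition_effects.items()}
        payload["appointment_date_range"] = list(self.appointment_date_range)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path, catalog: ItemCatalog | None = None):
        payload = yaml.safe_load(Path(path).read_text())
        payload["item_effects"] = {
            k: tuple(v) for k, v in payload["item_effects"].items()}
        payload["shutdown_effects"] = {
            k: tuple(v) for k, v in payload["shutdown_effects"].items()}
        payload["meltdown_effects"] = {
            k: tuple(v) for k, v in payload["meltdown_effects"].items()}
        payload["condition_effects"] = {
            k: {s: tuple(e) for s, e in v.items()}
            for k, v in payload["condition_effects"].items()}
        payload["appointment_date_range"] = tuple(payload["appointment_date_range"])
        if catalog is not None:
            payload["catalog"] = catalog
        return cls(**payload)


def score_calibrated_config(seed: int = 0) -> GeneratorConfig:
    """Study-scale configuration calibrated to the published total-score
    separation.

    The default (conditionally independent) configuration reproduces the
    published per-item odds ratios but makes the pooled score almost
    perfectly separating, unlike the published classification results.
    Here respondent-level response-style heterogeneity (an acquiescence
    random intercept, SD 4.5 on the logit scale) spreads the score
    distributions until score-based classification accuracy matches the
    published ~72%; the published qualitative pattern — high sensitivity,
    poor specificity for the total score — then emerges as well.
    """
    return GeneratorConfig(seed=seed, response_style_sd=4.5)


@dataclass
class CohortManifest:
    """Ground truth for the planted QC challenges."""

    duplicates: list[str] = field(default_factory=list)
    incomplete: list[str] = field(default_factory=list)
    unconfirmed: list[str] = field(default_factory=list)
    n_case: int = 0
    n_control: int = 0


@dataclass
class SyntheticCohort:
    frame: pd.DataFrame
    manifest: CohortManifest
    config: GeneratorConfig


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, lo, hi, n):
    out = np.empty(n)
    remaining = np.arange(n)
    while remaining.size:
        draw = rng.normal(mean, sd, remaining.size)
        ok = (draw >= lo) & (draw <= hi)
        out[remaining[ok]] = draw[ok]
        remaining = remaining[~ok]
    return out


def _categorical(rng, probs: Mapping[str, float], n: int) -> np.ndarray:
    levels = list(probs)
    p = np.asarray([probs[k] for k in levels], dtype=float)
    p = p / p.sum()
    return rng.choice(np.asarray(levels, dtype=object), size=n, p=p)


_ETHNICITY_DETAILS = {
    "white": ("White",),
    "non-white": ("African", "Arab", "Caribbean", "Hispanic", "Jewish",
                  "Mixed Race", "Turkish", "Other"),
}
_DIAGNOSIS_LABELS = ("autism spectrum disorder", "Asperger's", "atypical autism")
_PRACTITIONERS = ("psychiatrist", "clinical psychologist", "pediatrician", "other")


def _likert_column(rng, endorsed: np.ndarray, split: float,
                   missing_rate: float) -> np.ndarray:
    n = endorsed.size
    strongly = rng.random(n) < split
    col = np.where(
        endorsed,
        np.where(strongly, "Strongly Agree", "Somewhat Agree"),
        np.where(strongly, "Strongly Disagree", "Somewhat Disagree"),
    ).astype(object)
    if missing_rate > 0:
        col[rng.random(n) < missing_rate] = None
    return col


def _appointment_dates(rng, cfg: GeneratorConfig, n: int) -> np.ndarray:
    lo, hi = (date.fromisoformat(d) for d in cfg.appointment_date_range)
    span = (hi - lo).days
    offsets = rng.integers(0, span + 1, size=n)
    dates = np.array([(lo + timedelta(days=int(o))).isoformat() for o in offsets],
                     dtype=object)
    u = rng.random(n)
    partial = u < cfg.partial_date_fraction
    year_only = u < cfg.partial_date_fraction / 2.0  # half of partials drop month too
    missing = (u >= cfg.partial_date_fraction) & (
        u < cfg.partial_date_fraction + cfg.missing_date_fraction)
    dates[partial] = [d[:7] for d in dates[partial]]
    dates[year_only] = [d[:4] for d in dates[year_only]]
    dates[missing] = None
    return dates


def _core_records(cfg: GeneratorConfig, rng: np.random.Generator,
                  group: str, n: int) -> pd.DataFrame:
    """Complete, consenting records for one group ('case'/'control')."""
    is_case = group == "case"
    cols: dict[str, object] = {}
    cols[schema.CONSENTED] = np.ones(n, dtype=bool)
    mean, sd = cfg.age_dist[group]
    cols[schema.AGE] = np.round(_truncated_normal(rng, mean, sd, 16, 96, n))
    for cov, key in ((schema.SEX_AT_BIRTH, "sex_at_birth"),
                     (schema.GENDER, "gender"),
                     (schema.ETHNICITY, "ethnicity"),
                     (schema.EDUCATION, "education"),
                     (schema.COUNTRY, "country")):
        cols[cov] = _categorical(rng, cfg.covariate_dists[key][group], n)
    detail = np.empty(n, dtype=object)
    for binv, options in _ETHNICITY_DETAILS.items():
        mask = cols[schema.ETHNICITY] == binv
        detail[mask] = rng.choice(np.asarray(options, dtype=object),
                                  size=int(mask.sum()))
    cols[schema.ETHNICITY_DETAIL] = detail
    mean, sd = cfg.aq10_dist[group]
    cols[schema.AQ10] = np.clip(np.round(rng.normal(mean, sd, n)), 0, 10).astype(int)
    cols[schema.FAMILY_AUTISM] = rng.random(n) < cfg.family_autism_rates[group]

    if is_case:
        cols[schema.AUTISM_DIAGNOSIS] = np.full(n, "yes", dtype=object)
        cols[schema.DIAGNOSIS_LABEL] = rng.choice(
            np.asarray(_DIAGNOSIS_LABELS, dtype=object), size=n)
        cols[schema.PRACTITIONER_TYPE] = rng.choice(
            np.asarray(_PRACTITIONERS, dtype=object), size=n)
        cols[schema.DIAGNOSIS_YEAR] = rng.integers(1980, 2021, size=n).astype(float)
    else:
        cols[schema.AUTISM_DIAGNOSIS] = np.full(n, "no", dtype=object)
        cols[schema.DIAGNOSIS_LABEL] = np.full(n, None, dtype=object)
        cols[schema.PRACTITIONER_TYPE] = np.full(n, None, dtype=object)
        cols[schema.DIAGNOSIS_YEAR] = np.full(n, np.nan)
    cols[schema.SELF_IDENTIFICATION] = np.full(n, "none", dtype=object)

    # Respondent-level heterogeneity (both default to 0, i.e. items are
    # conditionally independent given group):
    #   * latent_trait_sd — a negative-experience propensity, a random
    #     intercept on the logit scale signed by item polarity;
    #   * response_style_sd — acquiescence, an unsigned random intercept
    #     raising agreement with every Likert statement regardless of
    #     polarity (checkbox sections are exempt).
    # Either induces within-respondent item correlation and spreads the
    # inequality-score distributions the way real survey data do.
    trait = (rng.normal(0.0, cfg.latent_trait_sd, n)
             if cfg.latent_trait_sd > 0 else None)
    style = (rng.normal(0.0, cfg.response_style_sd, n)
             if cfg.response_style_sd > 0 else None)

    def endorse_prob(p: float, endorse_is_negative: bool,
                     likert: bool = True) -> np.ndarray:
        if trait is None and (style is None or not likert):
            return np.full(n, p)
        eta = np.full(n, _logit(p))
        if trait is not None:
            eta += (1.0 if endorse_is_negative else -1.0) * trait
        if style is not None and likert:
            eta += style
        return _expit(eta)

    # Likert items (experience + most-recent-appointment sections)
    for item in cfg.catalog:
        p0, or_t = cfg.item_effects.get(item.id, (0.5, 1.0))
        p = endorsement_probability_from_or(p0, or_t) if is_case else p0
        endorsed = rng.random(n) < endorse_prob(p, item.endorse_is_negative)
        if item.id == "cb_insurance":
            cols[schema.INSURANCE] = endorsed.copy()
        cols[schema.item_col(item.id)] = _likert_column(
            rng, endorsed, cfg.likert_split, cfg.item_missing_rate)
    if schema.INSURANCE not in cols:
        cols[schema.INSURANCE] = rng.random(n) < 0.8

    # shutdown / meltdown checkboxes (independently settable per situation;
    # always a negative experience, so the trait enters positively)
    for sid in cfg.catalog.situations:
        for effects, col in ((cfg.shutdown_effects, schema.shutdown_col(sid)),
                             (cfg.meltdown_effects, schema.meltdown_col(sid))):
            p0, or_t = effects.get(sid, (0.05, 1.0))
            p = endorsement_probability_from_or(p0, or_t) if is_case else p0
            cols[col] = rng.random(n) < endorse_prob(p, True, likert=False)

    # lifetime condition flags (sex-specific effects; 'Other' uses 'F')
    for cond, by_sex in cfg.condition_effects.items():
        flags = np.zeros(n, dtype=bool)
        for sex in ("F", "M", "Other"):
            p0, or_t = by_sex.get(sex, by_sex["F"])
            p = endorsement_probability_from_or(p0, or_t) if is_case else p0
            mask = cols[schema.SEX_AT_BIRTH] == sex
            flags[mask] = rng.random(int(mask.sum())) < p
        cols[schema.condition_col(cond)] = flags

    # autism-specific follow-ups (asked only when a diagnosis is reported)
    for q in AUTISM_QUESTIONS:
        col = np.full(n, None, dtype=object)
        if is_case:
            col[:] = rng.choice(np.asarray(AUTISM_Q_LEVELS, dtype=object),
                                size=n, p=[0.55, 0.25, 0.20])
            col[rng.random(n) < cfg.item_missing_rate] = None
        cols[schema.autism_q_col(q)] = col

    cols[schema.APPOINTMENT_DATE] = _appointment_dates(rng, cfg, n)

    # covariate missingness (completely at random)
    for cov, rate in cfg.covariate_missing_rates.items():
        if rate <= 0 or cov not in cols:
            continue
        mask = rng.random(n) < rate
        col = np.asarray(cols[cov], dtype=object)
        col[mask] = None
        cols[cov] = col
        if cov == schema.ETHNICITY:
            detail = np.asarray(cols[schema.ETHNICITY_DETAIL], dtype=object)
            detail[mask] = None
            cols[schema.ETHNICITY_DETAIL] = detail
    return pd.DataFrame(cols)


def _blank_sections(df: pd.DataFrame, catalog: ItemCatalog) -> None:
    """Erase every answer in the eight completeness-defining sections
    (the five scored sections, shutdowns, meltdowns, autism-specific)."""
    for item in catalog.scored_items():
        df[schema.item_col(item.id)] = None
    for sid in catalog.situations:
        df[schema.shutdown_col(sid)] = False
        df[schema.meltdown_col(sid)] = False
    for q in AUTISM_QUESTIONS:
        df[schema.autism_q_col(q)] = None


def _degrade_to_unconfirmed(df: pd.DataFrame, rng: np.random.Generator) -> None:
    """Turn records into unconfirmable autism statuses: either a reported
    diagnosis missing its confirmation fields, or a self-identified label
    (suspected / awaiting assessment / self-diagnosed) without a diagnosis."""
    n = len(df)
    kind = rng.integers(0, 4, size=n)
    as_diag = kind == 0
    df[schema.AUTISM_DIAGNOSIS] = np.where(as_diag, "yes", "no")
    df[schema.DIAGNOSIS_LABEL] = None
    df[schema.PRACTITIONER_TYPE] = None
    df[schema.DIAGNOSIS_YEAR] = np.nan
    labels = np.asarray(["none", "suspected", "awaiting-assessment",
                         "self-diagnosed"], dtype=object)
    df[schema.SELF_IDENTIFICATION] = labels[np.where(as_diag, 0, kind)]


def _match_key_series(frame: pd.DataFrame) -> pd.Series:
    """Hashable 12-field match key per record; missing == missing."""
    sentinel = "\x00missing"
    parts = []
    for f in schema.MATCH_KEY_FIELDS:
        col = frame[f]
        col = col.astype(object).where(col.notna(), sentinel)
        parts.append(col.astype(str))
    return pd.Series(list(zip(*parts)), index=frame.index)


def _decollide_originals(frame: pd.DataFrame, cfg: GeneratorConfig,
                         rng: np.random.Generator) -> None:
    """Redraw age for any *accidental* 12-criteria collision among the
    generated originals, so the planted duplicates are the exact ground
    truth for duplicate detection.  (With tens of thousands of random pairs,
    chance collisions on the 12 fields are otherwise expected.)"""
    mean, sd = cfg.age_dist["case"]
    for _ in range(100):
        dup = _match_key_series(frame).duplicated(keep="first")
        if not dup.any():
            return
        frame.loc[dup, schema.AGE] = np.round(
            _truncated_normal(rng, mean, sd, 16, 96, int(dup.sum())))
    raise RuntimeError("could not resolve accidental match-key collisions")


def plant_duplicates(frame: pd.DataFrame, k: int,
                     seed: int | np.random.Generator,
                     eligible: pd.Index | None = None,
                     ) -> tuple[pd.DataFrame, list[str]]:
    """Append ``k`` records equal to randomly chosen originals on all 12
    duplicate-matching criteria and return (frame, manifest of planted pids).

    The planted rows are full copies apart from a fresh ``pid`` (matching on
    the 12 criteria is what the detector requires; the other fields are free
    to differ but are simply copied here).
    """
    if k < 0 or k > len(frame):
        raise ValueError(f"cannot plant {k} duplicates into {len(frame)} records")
    if k == 0:
        return frame, []
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    pool = frame.index if eligible is None else eligible
    chosen = rng.choice(np.asarray(pool), size=k, replace=len(pool) < k)
    copies = frame.loc[chosen].copy().reset_index(drop=True)
    start = len(frame)
    new_pids = [f"R{start + i + 1:05d}" for i in range(k)]
    copies[schema.PID] = new_pids
    out = pd.concat([frame, copies], ignore_index=True)
    return out, new_pids


def generate_cohort(config: GeneratorConfig | None = None) -> SyntheticCohort:
    """Generate a full synthetic survey table plus its planting manifest.

    Record order (arrival order for duplicate detection): cases, controls,
    unconfirmed, incomplete, then planted duplicates of the complete
    confirmed records.  Identical config and seed reproduce the table
    byte-for-byte.
    """
    cfg = config if config is not None else GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    parts = [
        _core_records(cfg, rng, "case", cfg.n_case),
        _core_records(cfg, rng, "control", cfg.n_control),
    ]
    n_core = cfg.n_case + cfg.n_control

    if cfg.n_unconfirmed:
        unc = _core_records(cfg, rng, "case", cfg.n_unconfirmed)
        _degrade_to_unconfirmed(unc, rng)
        parts.append(unc)
    if cfg.n_incomplete:
        half = cfg.n_incomplete // 2
        inc = pd.concat(
            [_core_records(cfg, rng, "case", half),
             _core_records(cfg, rng, "control", cfg.n_incomplete - half)],
            ignore_index=True)
        _blank_sections(inc, cfg.catalog)
        parts.append(inc)

    frame = pd.concat(parts, ignore_index=True)
    _decollide_originals(frame, cfg, rng)
    frame.insert(0, schema.PID, [f"R{i + 1:05d}" for i in range(len(frame))])

    manifest = CohortManifest(n_case=cfg.n_case, n_control=cfg.n_control)
    n_unc = cfg.n_unconfirmed
    manifest.unconfirmed = list(frame[schema.PID].iloc[n_core:n_core + n_unc])
    manifest.incomplete = list(frame[schema.PID].iloc[n_core + n_unc:])

    frame, manifest.duplicates = plant_duplicates(
        frame, cfg.n_duplicates, rng, eligible=frame.index[:n_core])
    return SyntheticCohort(frame=frame, manifest=manifest, config=cfg)


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------

def _bool_columns(df: pd.DataFrame) -> list[str]:
    fixed = [schema.CONSENTED, schema.FAMILY_AUTISM, schema.INSURANCE]
    prefixed = [c for c in df.columns
                if c.startswith((schema.SHUTDOWN_PREFIX, schema.MELTDOWN_PREFIX,
                                 schema.CONDITION_PREFIX))]
    return [c for c in fixed if c in df.columns] + prefixed


def write_cohort(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table as UTF-8 CSV (header row, no index)."""
    frame.to_csv(path, index=False, encoding="utf-8")


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort`, restoring dtypes."""
    df = pd.read_csv(path, encoding="utf-8", dtype={schema.PID: str})
    for col in _bool_columns(df):
        if df[col].dtype != bool:
            df[col] = df[col].map({"True": True, "False": False,
                                   True: True, False: False})
    if schema.AQ10 in df.columns:
        df[schema.AQ10] = df[schema.AQ10].astype("int64", errors="ignore")
    # pandas reads all-missing object columns as float NaN; coerce to object
    for col in df.columns:
        if df[col].dtype == float and col.startswith(
                (schema.ITEM_PREFIX, schema.AUTISM_Q_PREFIX)):
            df[col] = df[col].astype(object).where(df[col].notna(), None)
    return df
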