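"""End-to-end pipeline: QC -> scoring -> statistics -> prediction -> eras.

``run_pipeline`` takes a cohort CSV (or generates a synthetic cohort from a
generator config), applies the exclusion cascade, computes inequality
scores, runs the demographic, item-level, condition, score-association,
classification, and pandemic-era analyses, and writes everything as plain
TSV/CSV plus a JSON run manifest.  All randomness is seeded through the
config, so a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__, schema
from .catalog import CONDITIONS, AUTISM_QUESTIONS, ItemCatalog, default_catalog
from .pandemic import PANDEMIC_CUTOFF, era_contrasts
from .predict import evaluate_score_classifiers
from .qc import apply_exclusions
from .scoring import score_frame
from .simulate import GeneratorConfig, generate_cohort, read_cohort, write_cohort
from .stats import (demographic_comparison, is_case, odds_ratio,
                    score_association_models, sex_stratified_condition_analysis,
                    two_by_two_for_item)

__all__ = ["PipelineConfig", "run_pipeline", "summarize_autism_specific"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a reproducible run needs; echoed into the output directory."""

    cohort_csv: str | None = None       # input table; None -> synthetic
    output_dir: str = "hcineq_out"
    catalog_path: str | None = None     # YAML catalog; None -> shipped default
    or_method: str = "cross-product"
    score_scale: str = "proportion"
    m_imputations: int = 5
    seed: int = 0
    train_fraction: float = 0.2
    threshold: float = 0.5
    repeats: int = 1
    cutoff_date: str = PANDEMIC_CUTOFF.isoformat()
    generator: GeneratorConfig | None = None
    verbosity: str = "INFO"


def summarize_autism_specific(records: pd.DataFrame) -> pd.DataFrame:
    """Descriptive counts for the autism-specific follow-up questions.

    Only respondents reporting an autism diagnosis were asked these
    questions, so only their (non-missing) answers contribute; no
    hypothesis tests are run.  An empty cohort yields an empty table.
    """
    rows = []
    if len(records):
        eligible = records[schema.AUTISM_DIAGNOSIS] == "yes"
        if schema.AUTISM_STATUS in records.columns:
            eligible &= is_case(records)
        sub = records[eligible]
        for q in AUTISM_QUESTIONS:
            col = schema.autism_q_col(q)
            if col not in records.columns:
                continue
            answered = sub[col].dropna()
            counts = answered.value_counts()
            for level, n in counts.items():
                rows.append({"question": q, "response": level, "n": int(n),
                             "pct": 100.0 * n / len(answered)})
    return pd.DataFrame(rows, columns=["question", "response", "n", "pct"])


def _item_contrast_table(cohort, catalog, or_method) -> pd.DataFrame:
    from .stats import DegenerateTableError, build_two_by_two

    case = is_case(cohort)
    rows = []
    for item in catalog:
        col = schema.item_col(item.id)
        if col not in cohort.columns:
            continue
        try:
            t = two_by_two_for_item(cohort, item.id, case)
        except DegenerateTableError:
            log.info("item %s skipped: degenerate table", item.id)
            continue
        est = odds_ratio(t, method=or_method)
        rows.append({
            "item": item.id, "section": item.section,
            "case_n": t.a, "case_pct": 100.0 * t.a / t.n_case,
            "control_n": t.c, "control_pct": 100.0 * t.c / t.n_control,
            "or": est.or_point, "ci_low": est.ci_low, "ci_high": est.ci_high,
            "p_value": est.p_value, "sig": est.sig_label,
        })
    # shutdown / meltdown checkbox contrasts
    import pandas as _pd

    from .stats import TwoByTwoTable

    for kind, colf in (("shutdown", schema.shutdown_col),
                       ("meltdown", schema.meltdown_col)):
        for sid in catalog.situations:
            col = colf(sid)
            if col not in cohort.columns:
                continue
            flags = cohort[col].astype(bool)
            t = TwoByTwoTable(a=int((flags & case).sum()),
                              b=int((~flags & case).sum()),
                              c=int((flags & ~case).sum()),
                              d=int((~flags & ~case).sum()))
            est = odds_ratio(t, method=or_method)
            rows.append({
                "item": f"{kind}:{sid}", "section": kind,
                "case_n": t.a, "case_pct": 100.0 * t.a / t.n_case,
                "control_n": t.c, "control_pct": 100.0 * t.c / t.n_control,
                "or": est.or_point, "ci_low": est.ci_low,
                "ci_high": est.ci_high, "p_value": est.p_value,
                "sig": est.sig_label,
            })
    return _pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write the output directory; returns its path."""
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), 20))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalog = (ItemCatalog.from_yaml(config.catalog_path)
               if config.catalog_path else default_catalog())

    stage = "input"
    try:
        if config.cohort_csv is not None:
            raw = read_cohort(config.cohort_csv)
            manifest_planted = None
        else:
            gen_cfg = config.generator or GeneratorConfig(seed=config.seed)
            cohort_bundle = generate_cohort(gen_cfg)
            raw = cohort_bundle.frame
            manifest_planted = asdict(cohort_bundle.manifest)
            write_cohort(raw, out / "synthetic_cohort.csv")

        stage = "qc"
        cohort, ledger = apply_exclusions(raw, catalog)
        ledger.to_frame().to_csv(out / "exclusion_ledger.csv", index=False)

        stage = "scoring"
        scores = score_frame(cohort, catalog)
        scores.to_csv(out / "participant_scores.csv", index=False)
        dist = pd.DataFrame({
            schema.PID: cohort[schema.PID],
            "group": is_case(cohort).map({True: "case", False: "control"}),
            "total_score": scores["total_score"],
        })
        dist.to_csv(out / "score_distribution.csv", index=False)

        stage = "stats"
        demographic_comparison(cohort).to_csv(
            out / "demographics.tsv", sep="\t", index=False)
        _item_contrast_table(cohort, catalog, config.or_method).to_csv(
            out / "item_contrasts.tsv", sep="\t", index=False)
        conds = [c for c in CONDITIONS
                 if schema.condition_col(c) in cohort.columns]
        sex_stratified_condition_analysis(
            cohort, conds, m=config.m_imputations, seed=config.seed,
            or_method=config.or_method).to_csv(
            out / "conditions_sex_stratified.tsv", sep="\t", index=False)
        score_models = score_association_models(
            scores, cohort, scale=config.score_scale,
            m=config.m_imputations, seed=config.seed, stratify=True)
        score_models[score_models.stratum == "all"].to_csv(
            out / "score_models.tsv", sep="\t", index=False)
        score_models[score_models.stratum != "all"].to_csv(
            out / "score_models_by_sex.tsv", sep="\t", index=False)

        stage = "prediction"
        evaluate_score_classifiers(
            cohort, scores, train_fraction=config.train_fraction,
            threshold=config.threshold, seed=config.seed,
            repeats=config.repeats).to_csv(
            out / "classification.tsv", sep="\t", index=False)

        stage = "pandemic"
        from datetime import date as _date

        era_contrasts(cohort, catalog,
                      cutoff=_date.fromisoformat(config.cutoff_date),
                      or_method=config.or_method).to_csv(
            out / "pandemic_contrasts.tsv", sep="\t", index=False)

        stage = "reporting"
        summarize_autism_specific(cohort).to_csv(
            out / "autism_specific_summary.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "or_method": config.or_method,
        "score_scale": config.score_scale,
        "m_imputations": config.m_imputations,
        "cutoff_date": config.cutoff_date,
        "input_records": int(len(raw)),
        "analysis_cohort": int(len(cohort)),
        "exclusions": ledger.counts(),
        "planted": manifest_planted,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    cfg_echo = asdict(config)
    if cfg_echo.get("generator") is not None:
        cfg_echo["generator"] = {
            k: v for k, v in cfg_echo["generator"].items() if k != "catalog"}
    (out / "config_echo.json").write_text(json.dumps(cfg_echo, indent=2, default=str))
    return out
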