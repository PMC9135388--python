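"""Case-control statistics: exact 2x2 contrasts, covariate-adjusted
logistic models with multiple imputation, stratified prevalence, score
associations, and demographic comparisons.

Unadjusted contrasts are 2x2 tables of endorsement (missing responses
excluded) tested with Fisher's exact test; the odds ratio is the
cross-product (a*d)/(b*c) with a Wald CI by default, or the conditional
maximum-likelihood estimate of the noncentral hypergeometric model.
Adjusted models are binomial logistic regressions controlling for age,
ethnicity (binary), education (5 levels), and country (7 levels); the
three covariates may be missing and are completed by chained-equation
multiple imputation (categorical conditional models), with estimates
pooled across the m completed tables by Rubin's rules.  A fixed p < 0.001
significance threshold is used throughout (no FDR), with extra stars at
p < 1e-4 and p < 1e-5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from scipy.stats.contingency import odds_ratio as _scipy_cond_or

from . import schema

__all__ = [
    "TwoByTwoTable",
    "OddsRatioEstimate",
    "AdjustedModelResult",
    "ImputationSet",
    "DegenerateTableError",
    "build_two_by_two",
    "two_by_two_for_item",
    "odds_ratio",
    "fisher_p",
    "significance_label",
    "impute_covariates",
    "fit_adjusted_logistic",
    "sex_stratified_condition_analysis",
    "score_association_models",
    "demographic_comparison",
    "format_p",
    "is_case",
]

log = logging.getLogger(__name__)

ADJUSTMENT_COVARIATES = (schema.AGE, schema.ETHNICITY, schema.EDUCATION,
                         schema.COUNTRY)
IMPUTABLE = (schema.ETHNICITY, schema.EDUCATION, schema.COUNTRY)

#: p-values below double precision resolution are displayed as a bound.
P_FLOOR = 2.22e-16


class DegenerateTableError(ValueError):
    """A 2x2 contrast with an empty margin (no answering respondents)."""


def is_case(records: pd.DataFrame) -> pd.Series:
    """Boolean case indicator from the derived autism-status column."""
    return records[schema.AUTISM_STATUS] == schema.CONFIRMED_AUTISTIC


# ---------------------------------------------------------------------------
# 2x2 machinery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoByTwoTable:
    """Endorsement counts: a/b cases endorsing/rejecting, c/d controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n_case(self) -> int:
        return self.a + self.b

    @property
    def n_control(self) -> int:
        return self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class OddsRatioEstimate:
    or_point: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str
    sig_label: str
    continuity_corrected: bool = False


def build_two_by_two(binary: pd.Series, case_mask: pd.Series) -> TwoByTwoTable:
    """Count endorse/reject over non-missing responses, split by group.

    ``binary`` holds ``endorse``/``reject``/missing per respondent;
    ``case_mask`` is the boolean case indicator on the same index.
    """
    endorse = binary == schema.ENDORSE
    reject = binary == schema.REJECT
    case_mask = case_mask.astype(bool)
    t = TwoByTwoTable(
        a=int((endorse & case_mask).sum()),
        b=int((reject & case_mask).sum()),
        c=int((endorse & ~case_mask).sum()),
        d=int((reject & ~case_mask).sum()),
    )
    if t.n_case == 0 or t.n_control == 0:
        raise DegenerateTableError(
            f"empty margin in 2x2 table: {t} (all responses missing "
            "or an empty group)")
    return t


def _binarize_column(col: pd.Series) -> pd.Series:
    endorse = col.isin(schema.LIKERT_ENDORSE)
    reject = col.isin(schema.LIKERT_REJECT)
    unknown = col.notna() & ~endorse & ~reject
    if unknown.any():
        raise ValueError(f"unknown Likert label: {col[unknown].iloc[0]!r}")
    out = pd.Series(None, index=col.index, dtype=object)
    out[endorse] = schema.ENDORSE
    out[reject] = schema.REJECT
    return out


def two_by_two_for_item(records: pd.DataFrame, item_id: str,
                        case_mask: pd.Series | None = None) -> TwoByTwoTable:
    """2x2 endorsement table for one Likert item of a cohort."""
    if case_mask is None:
        case_mask = is_case(records)
    col = records[schema.item_col(item_id)]
    return build_two_by_two(_binarize_column(col), case_mask)


def fisher_p(table: TwoByTwoTable) -> float:
    """Two-sided Fisher exact p (hypergeometric tail summation)."""
    return float(scipy.stats.fisher_exact(table.as_array(),
                                          alternative="two-sided")[1])


def significance_label(p: float) -> str:
    """Star coding at the study's thresholds: * p<1e-3, ** p<1e-4, *** p<1e-5."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value out of range: {p!r}")
    if p < 1e-5:
        return "***"
    if p < 1e-4:
        return "**"
    if p < 1e-3:
        return "*"
    return ""


def format_p(p: float) -> str:
    """Display convention: values below double resolution shown as a bound."""
    if p < P_FLOOR:
        return "< 2.22e-16"
    return f"{p:.3g}"


def odds_ratio(table: TwoByTwoTable, method: str = "cross-product",
               alpha: float = 0.05) -> OddsRatioEstimate:
    """Odds ratio with CI and Fisher p for a 2x2 endorsement table.

    ``cross-product`` is (a*d)/(b*c) with the Wald interval
    exp(ln OR +/- z*sqrt(1/a+1/b+1/c+1/d)); any zero cell triggers the
    Haldane–Anscombe 0.5 continuity correction, flagged on the estimate.
    ``conditional-mle`` maximizes the noncentral hypergeometric likelihood
    (as exact-test routines report) with its exact interval.
    """
    p = fisher_p(table)
    if method == "cross-product":
        a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
        corrected = min(a, b, c, d) == 0
        if corrected:
            log.warning("zero cell in %s; applying 0.5 continuity correction",
                        table)
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        point = (a * d) / (b * c)
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        z = scipy.stats.norm.ppf(1 - alpha / 2)
        lo, hi = np.exp(np.log(point) + np.array([-z, z]) * se)
        return OddsRatioEstimate(float(point), float(lo), float(hi), p,
                                 "cross-product", significance_label(p),
                                 continuity_corrected=corrected)
    if method == "conditional-mle":
        res = _scipy_cond_or(table.as_array(), kind="conditional")
        ci = res.confidence_interval(confidence_level=1 - alpha)
        return OddsRatioEstimate(float(res.statistic), float(ci.low),
                                 float(ci.high), p, "conditional-mle",
                                 significance_label(p))
    raise ValueError(f"unknown odds-ratio method: {method!r}")


# ---------------------------------------------------------------------------
# multiple imputation by chained equations (categorical covariates)
# ---------------------------------------------------------------------------

@dataclass
class ImputationSet:
    """m completed copies of the cohort's covariate columns."""

    tables: list[pd.DataFrame]
    seed: int
    n_cycles: int
    variables: tuple[str, ...]

    @property
    def m(self) -> int:
        return len(self.tables)


def _imputation_design(records: pd.DataFrame, current: dict[str, pd.Series],
                       target: str, variables, categories) -> np.ndarray:
    """Predictor matrix for one chained-equation step: age, the case
    indicator when present, and one-hot codes of the other covariates'
    current completed values."""
    blocks = []
    age = pd.to_numeric(records[schema.AGE], errors="coerce")
    blocks.append(((age - age.mean()) / (age.std() or 1.0))
                  .fillna(0.0).to_numpy()[:, None])
    if schema.AUTISM_STATUS in records.columns:
        blocks.append(is_case(records).to_numpy(dtype=float)[:, None])
    elif schema.AUTISM_DIAGNOSIS in records.columns:
        blocks.append((records[schema.AUTISM_DIAGNOSIS] == "yes")
                      .to_numpy(dtype=float)[:, None])
    for other in variables:
        if other == target:
            continue
        vals = current[other]
        for level in categories[other][:-1]:
            blocks.append((vals == level).to_numpy(dtype=float)[:, None])
    return np.hstack(blocks)


def impute_covariates(records: pd.DataFrame, m: int = 5, seed: int = 0,
                      n_cycles: int = 3) -> ImputationSet:
    """Complete ethnicity/education/country by chained multinomial draws.

    Each incomplete covariate is imputed from a multinomial logistic model
    conditional on age, the case indicator, and the other covariates,
    cycling ``n_cycles`` times per table; ``m`` completed tables are
    produced.  Non-missing cells are never altered and outcomes are never
    imputed.  With no missingness the result is m identical copies.
    """
    from sklearn.linear_model import LogisticRegression

    variables = tuple(v for v in IMPUTABLE if v in records.columns)
    for v in variables:
        frac = records[v].isna().mean()
        if frac > 0.5:
            raise ValueError(
                f"covariate {v!r} is {frac:.0%} missing; refusing to impute")

    missing = {v: records[v].isna() for v in variables}
    if not any(mk.any() for mk in missing.values()):
        return ImputationSet([records.copy() for _ in range(m)],
                             seed=seed, n_cycles=n_cycles, variables=variables)

    categories = {v: sorted(records[v].dropna().unique()) for v in variables}
    rng = np.random.default_rng(seed)
    tables: list[pd.DataFrame] = []
    for _ in range(m):
        current = {}
        for v in variables:
            col = records[v].copy()
            k = int(missing[v].sum())
            if k:
                observed = records[v].dropna()
                col.loc[missing[v]] = rng.choice(observed.to_numpy(), size=k)
            current[v] = col
        for _cycle in range(n_cycles):
            for v in variables:
                mask = missing[v]
                if not mask.any():
                    continue
                X = _imputation_design(records, current, v, variables, categories)
                obs = (~mask).to_numpy()
                model = LogisticRegression(max_iter=200)
                model.fit(X[obs], current[v].to_numpy()[obs])
                proba = model.predict_proba(X[mask.to_numpy()])
                cum = np.cumsum(proba, axis=1)
                draws = (rng.random(proba.shape[0])[:, None] > cum).sum(axis=1)
                current[v].loc[mask] = np.asarray(model.classes_,
                                                  dtype=object)[draws]
        table = records.copy()
        for v in variables:
            table[v] = current[v]
        tables.append(table)
    return ImputationSet(tables, seed=seed, n_cycles=n_cycles,
                         variables=variables)


# ---------------------------------------------------------------------------
# adjusted logistic models with Rubin pooling
# ---------------------------------------------------------------------------

@dataclass
class AdjustedModelResult:
    """Pooled covariate-adjusted logistic model for one exposure.

    ``terms`` holds, per model term, the pooled OR, 95% CI, and p-value;
    the exposure's row is mirrored in the scalar fields.  When any
    imputed-data fit shows separation or fails to converge the estimates
    are withheld (NaN) and ``separation_flag`` is set.
    """

    exposure: str
    or_point: float
    ci_low: float
    ci_high: float
    p_value: float
    m: int
    separation_flag: bool
    terms: pd.DataFrame = field(repr=False, default=None)

    @property
    def sig_label(self) -> str:
        return "" if np.isnan(self.p_value) else significance_label(self.p_value)


_SE_SEPARATION_LIMIT = 10.0  # log-odds scale; diverging Wald SEs


def _design_matrix(records: pd.DataFrame, exposure: pd.Series,
                   covariates) -> pd.DataFrame:
    cols = {"const": np.ones(len(records)), "exposure": exposure.to_numpy(dtype=float)}
    for cov in covariates:
        if cov == schema.AGE:
            cols[schema.AGE] = pd.to_numeric(records[schema.AGE]).to_numpy()
        else:
            vals = records[cov]
            levels = sorted(vals.dropna().unique())
            for level in levels[1:]:  # first level is the reference
                cols[f"{cov}[{level}]"] = (vals == level).to_numpy(dtype=float)
    return pd.DataFrame(cols, index=records.index)


def _rubin_pool(params: np.ndarray, variances: np.ndarray,
                alpha: float = 0.05) -> tuple[np.ndarray, ...]:
    """Rubin's rules over m fits: pooled estimate, SE, CI, p (t reference)."""
    m = params.shape[0]
    qbar = params.mean(axis=0)
    w = variances.mean(axis=0)
    b = params.var(axis=0, ddof=1) if m > 1 else np.zeros_like(qbar)
    t_var = w + (1 + 1 / m) * b
    se = np.sqrt(t_var)
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = (1 + 1 / m) * b / t_var
        df = np.where(lam > 1e-12, (m - 1) / np.maximum(lam, 1e-300) ** 2,
                      np.inf)
    tcrit = scipy.stats.t.ppf(1 - alpha / 2, df)
    stat = np.where(se > 0, qbar / np.where(se > 0, se, 1.0), np.inf)
    pvals = 2 * scipy.stats.t.sf(np.abs(stat), df)
    return qbar, se, qbar - tcrit * se, qbar + tcrit * se, pvals


def fit_adjusted_logistic(outcome: pd.Series, exposure: pd.Series,
                          records: pd.DataFrame,
                          imputations: ImputationSet | None = None,
                          covariates=ADJUSTMENT_COVARIATES,
                          exposure_name: str = "exposure",
                          ) -> AdjustedModelResult:
    """Binomial logistic model of ``outcome`` on ``exposure`` plus the
    adjustment covariates, fitted on each imputed table and pooled by
    Rubin's rules.  Perfect separation (diverging Wald errors) or
    non-convergence withholds the estimates and sets ``separation_flag``.
    """
    if imputations is None:
        imputations = ImputationSet([records], seed=0, n_cycles=0,
                                    variables=())
    keep = outcome.notna() & exposure.notna()
    if schema.AGE in covariates:
        keep &= pd.to_numeric(records[schema.AGE], errors="coerce").notna()
    y = outcome[keep].astype(float)

    params, variances, names = [], [], None
    separated = False
    for table in imputations.tables:
        X = _design_matrix(table.loc[keep.index[keep]], exposure[keep],
                           covariates)
        names = list(X.columns)
        try:
            fit = sm.GLM(y.to_numpy(), X.to_numpy(),
                         family=sm.families.Binomial()).fit(maxiter=200)
        except Exception:  # IRLS blow-up on separated data
            separated = True
            break
        bse = np.asarray(fit.bse)
        if not np.all(np.isfinite(bse)) or bse.max() > _SE_SEPARATION_LIMIT:
            separated = True
            break
        params.append(np.asarray(fit.params))
        variances.append(bse ** 2)

    if separated or not params:
        nan = float("nan")
        return AdjustedModelResult(exposure_name, nan, nan, nan, nan,
                                   imputations.m, True,
                                   terms=pd.DataFrame(index=names or []))

    qbar, se, lo, hi, pvals = _rubin_pool(np.vstack(params),
                                          np.vstack(variances))
    terms = pd.DataFrame(
        {"or": np.exp(qbar), "ci_low": np.exp(lo), "ci_high": np.exp(hi),
         "p_value": pvals, "log_or": qbar, "se": se},
        index=names)
    row = terms.loc["exposure"]
    return AdjustedModelResult(
        exposure_name, float(row["or"]), float(row["ci_low"]),
        float(row["ci_high"]), float(row["p_value"]),
        imputations.m, False, terms=terms)


# ---------------------------------------------------------------------------
# analysis-level operations
# ---------------------------------------------------------------------------

def sex_stratified_condition_analysis(records: pd.DataFrame, conditions,
                                      m: int = 5, seed: int = 0,
                                      or_method: str = "cross-product",
                                      ) -> pd.DataFrame:
    """Per-stratum (assigned F / assigned M) condition prevalence contrasts.

    Respondents with sex assigned at birth 'Other' are excluded from these
    stratified analyses only.  Each condition gets an unadjusted 2x2 OR
    (condition endorsement by group) and an adjusted logistic model of the
    condition on the case indicator; conditions absent in a stratum cell
    are skipped with a log entry.
    """
    rows = []
    for stratum in ("F", "M"):
        sub = records[records[schema.SEX_AT_BIRTH] == stratum]
        if sub.empty:
            log.info("stratum %s empty; skipped", stratum)
            continue
        imputations = impute_covariates(sub, m=m, seed=seed)
        case = is_case(sub)
        for cond in conditions:
            col = sub[schema.condition_col(cond)].astype(bool)
            t = TwoByTwoTable(
                a=int((col & case).sum()), b=int((~col & case).sum()),
                c=int((col & ~case).sum()), d=int((~col & ~case).sum()))
            if t.a + t.c == 0 or min(t.n_case, t.n_control) == 0:
                log.info("condition %s absent in stratum %s; skipped",
                         cond, stratum)
                continue
            unadj = odds_ratio(t, method=or_method)
            adj = fit_adjusted_logistic(
                outcome=col.astype(float), exposure=case.astype(float),
                records=sub, imputations=imputations, exposure_name=cond)
            rows.append({
                "stratum": stratum, "condition": cond,
                "case_n": t.a, "case_pct": 100.0 * t.a / t.n_case,
                "control_n": t.c, "control_pct": 100.0 * t.c / t.n_control,
                "or_unadj": unadj.or_point, "ci_low_unadj": unadj.ci_low,
                "ci_high_unadj": unadj.ci_high, "p_unadj": unadj.p_value,
                "sig_unadj": unadj.sig_label,
                "or_adj": adj.or_point, "ci_low_adj": adj.ci_low,
                "ci_high_adj": adj.ci_high, "p_adj": adj.p_value,
                "sig_adj": adj.sig_label,
                "separation_flag": adj.separation_flag,
            })
    return pd.DataFrame(rows)


def score_association_models(scores: pd.DataFrame, records: pd.DataFrame,
                             scale: str = "proportion", m: int = 5,
                             seed: int = 0, stratify: bool = True,
                             score_names=None) -> pd.DataFrame:
    """Logistic models of autism status on each inequality score.

    For each section score and the total: an unadjusted single-predictor
    logistic model and a covariate-adjusted model (age, ethnicity,
    education, country; MICE-pooled), run overall and — when ``stratify``
    — within each assigned sex.  ``scale`` selects the predictor units:
    ``proportion`` (score in [0,1]; OR per full 0-to-1 sweep) or ``points``
    (raw negative-experience count; OR per additional point).
    """
    if scale not in {"proportion", "points"}:
        raise ValueError(f"unknown score scale: {scale!r}")
    if score_names is None:
        score_names = [c[:-len("_score")] for c in scores.columns
                       if c.endswith("_score")]
    strata = [("all", pd.Series(True, index=records.index))]
    if stratify:
        for s in ("F", "M"):
            strata.append((s, records[schema.SEX_AT_BIRTH] == s))

    rows = []
    for label, mask in strata:
        sub = records[mask]
        if sub.empty:
            continue
        imputations = impute_covariates(sub, m=m, seed=seed)
        case = is_case(sub).astype(float)
        for name in score_names:
            col = f"{name}_score" if scale == "proportion" else f"{name}_points"
            x = scores.loc[sub.index, col].astype(float)
            if scale == "points":
                x = x.where(scores.loc[sub.index, f"{name}_answered"] > 0)
            if x.notna().sum() == 0:
                raise ValueError(f"score {name!r} undefined for every record")
            unadj = fit_adjusted_logistic(case, x, sub, covariates=(),
                                          exposure_name=name)
            adj = fit_adjusted_logistic(case, x, sub, imputations=imputations,
                                        exposure_name=name)
            rows.append({
                "stratum": label, "score": name, "scale": scale,
                "or_unadj": unadj.or_point, "ci_low_unadj": unadj.ci_low,
                "ci_high_unadj": unadj.ci_high, "p_unadj": unadj.p_value,
                "sig_unadj": unadj.sig_label,
                "or_adj": adj.or_point, "ci_low_adj": adj.ci_low,
                "ci_high_adj": adj.ci_high, "p_adj": adj.p_value,
                "sig_adj": adj.sig_label,
                "separation_flag": adj.separation_flag or unadj.separation_flag,
            })
    return pd.DataFrame(rows)


_CATEGORICAL_DEMOGRAPHICS = (schema.SEX_AT_BIRTH, schema.GENDER,
                             schema.ETHNICITY, schema.EDUCATION,
                             schema.COUNTRY)
_CONTINUOUS_DEMOGRAPHICS = (schema.AGE, schema.AQ10)


def demographic_comparison(records: pd.DataFrame) -> pd.DataFrame:
    """Group comparison of covariates: chi-square tests for categorical
    variables (counts and percentages per level), Mann-Whitney U for age
    and the autistic-traits score (means and SDs)."""
    case = is_case(records)
    rows = []
    for var in _CONTINUOUS_DEMOGRAPHICS:
        vals = pd.to_numeric(records[var], errors="coerce")
        x, y = vals[case].dropna(), vals[~case].dropna()
        p = float(scipy.stats.mannwhitneyu(x, y, alternative="two-sided")[1]) \
            if len(x) and len(y) and (x.nunique() > 1 or y.nunique() > 1) else 1.0
        rows.append({"variable": var, "level": "mean (SD)",
                     "case_value": float(x.mean()), "case_spread": float(x.std()),
                     "control_value": float(y.mean()),
                     "control_spread": float(y.std()),
                     "test": "mann-whitney", "p_value": p,
                     "sig": significance_label(p)})
    for var in _CATEGORICAL_DEMOGRAPHICS:
        vals = records[var]
        ok = vals.notna()
        tab = pd.crosstab(vals[ok], case[ok]).reindex(
            columns=[True, False], fill_value=0)
        nonzero = tab.loc[(tab.sum(axis=1) > 0)]
        if nonzero.shape[0] > 1 and (nonzero.to_numpy().sum(axis=0) > 0).all():
            stat, p = scipy.stats.chi2_contingency(
                nonzero.to_numpy(), correction=False)[:2]
        else:
            stat, p = 0.0, 1.0
        n_case, n_ctrl = tab[True].sum(), tab[False].sum()
        rows.append({"variable": var, "level": "(chi-square)",
                     "case_value": float(n_case), "case_spread": np.nan,
                     "control_value": float(n_ctrl), "control_spread": np.nan,
                     "test": "chi-square", "p_value": float(p),
                     "sig": significance_label(float(p))})
        for level, (a, c) in tab.iterrows():
            rows.append({
                "variable": var, "level": str(level),
                "case_value": float(a),
                "case_spread": 100.0 * a / n_case if n_case else np.nan,
                "control_value": float(c),
                "control_spread": 100.0 * c / n_ctrl if n_ctrl else np.nan,
                "test": "count (pct)", "p_value": np.nan, "sig": ""})
    return pd.DataFrame(rows)
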