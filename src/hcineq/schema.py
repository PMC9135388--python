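"""Column names and coding conventions for the cohort table.

A cohort is an ordinary :class:`pandas.DataFrame` with one row per
respondent.  Input order is arrival order (duplicate detection keeps the
first occurrence).  Missing values are ``NaN``/``None`` throughout; Likert
responses are stored as the four verbatim labels.
"""

from __future__ import annotations

# -- Likert coding ----------------------------------------------------------

LIKERT_LEVELS = (
    "Strongly Agree",
    "Somewhat Agree",
    "Somewhat Disagree",
    "Strongly Disagree",
)
LIKERT_ENDORSE = frozenset({"Strongly Agree", "Somewhat Agree"})
LIKERT_REJECT = frozenset({"Strongly Disagree", "Somewhat Disagree"})

ENDORSE = "endorse"
REJECT = "reject"

# -- autism-status coding ---------------------------------------------------

CONFIRMED_AUTISTIC = "confirmed-autistic"
CONFIRMED_NON_AUTISTIC = "confirmed-non-autistic"
UNCONFIRMED = "unconfirmed"

SELF_ID_LEVELS = ("none", "suspected", "awaiting-assessment", "self-diagnosed")

# -- covariate levels -------------------------------------------------------

SEX_LEVELS = ("F", "M", "Other")
GENDER_LEVELS = ("female", "male", "non-binary", "other")
ETHNICITY_LEVELS = ("white", "non-white")
EDUCATION_LEVELS = (
    "No formal qualifications",
    "Secondary School/High School",
    "Further vocational qualifications",
    "University Undergraduate",
    "University Postgraduate",
)
COUNTRY_LEVELS = (
    "United Kingdom",
    "United States",
    "Germany",
    "Australia",
    "Canada",
    "Netherlands",
    "Other",
)

# -- column names -----------------------------------------------------------

PID = "pid"
CONSENTED = "consented"
AGE = "age"
AUTISM_DIAGNOSIS = "autism_diagnosis"          # "yes" / "no" / NaN
SELF_IDENTIFICATION = "self_identification"    # SELF_ID_LEVELS
DIAGNOSIS_LABEL = "diagnosis_label"
PRACTITIONER_TYPE = "practitioner_type"
DIAGNOSIS_YEAR = "diagnosis_year"
FAMILY_AUTISM = "family_autism"
SEX_AT_BIRTH = "sex_at_birth"
GENDER = "gender"
ETHNICITY = "ethnicity"                        # binary white / non-white
ETHNICITY_DETAIL = "ethnicity_detail"
EDUCATION = "education"
COUNTRY = "country"
AQ10 = "aq10"
INSURANCE = "insurance"
APPOINTMENT_DATE = "appointment_date"          # "YYYY-MM-DD" / partial / NaN
AUTISM_STATUS = "autism_status"                # derived by cohort_qc

ITEM_PREFIX = "item_"
SHUTDOWN_PREFIX = "shutdown_"
MELTDOWN_PREFIX = "meltdown_"
CONDITION_PREFIX = "cond_"
AUTISM_Q_PREFIX = "aut_"


def item_col(item_id: str) -> str:
    return ITEM_PREFIX + item_id


def shutdown_col(situation_id: str) -> str:
    return SHUTDOWN_PREFIX + situation_id


def meltdown_col(situation_id: str) -> str:
    return MELTDOWN_PREFIX + situation_id


def condition_col(condition_id: str) -> str:
    return CONDITION_PREFIX + condition_id


def autism_q_col(question_id: str) -> str:
    return AUTISM_Q_PREFIX + question_id


# The 12 exact-match duplicate criteria (anonymous respondents; equality is
# field-wise with missing == missing).
MATCH_KEY_FIELDS = (
    AUTISM_DIAGNOSIS,
    DIAGNOSIS_LABEL,
    PRACTITIONER_TYPE,
    DIAGNOSIS_YEAR,
    FAMILY_AUTISM,
    AGE,
    COUNTRY,
    SEX_AT_BIRTH,
    GENDER,
    EDUCATION,
    ETHNICITY,
    AQ10,
)
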