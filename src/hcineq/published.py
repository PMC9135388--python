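"""Published group-level summary rows from the healthcare-experiences survey.

The underlying respondent-level data are not publicly shareable, but the
study released group-level counts: for each survey item, the number (and
percentage) of autistic and non-autistic respondents endorsing it, together
with the unadjusted odds ratio.  These rows serve two purposes here:

* they calibrate the synthetic-cohort generator (control endorsement rate
  ``p0`` = published control percentage; planted effect = published OR), and
* each row's 2x2 table can be reconstructed exactly — the answering
  denominator is ``round(n / (pct / 100))`` — which lets the odds-ratio
  code be checked against the published point estimates.

Percentages are percentages of respondents *answering* that item, so the
reconstructed denominators differ item to item (item nonresponse).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PublishedRow:
    """One published contrast row: endorsement counts and unadjusted OR."""

    key: str
    case_n: int
    case_pct: float
    control_n: int
    control_pct: float
    or_unadjusted: float

    def reconstruct_counts(self) -> tuple[int, int, int, int]:
        """Rebuild (a, b, c, d) = (cases endorsing, cases rejecting,
        controls endorsing, controls rejecting) from counts and percentages.
        """
        n_case = round(self.case_n / (self.case_pct / 100.0))
        n_control = round(self.control_n / (self.control_pct / 100.0))
        return (
            self.case_n,
            n_case - self.case_n,
            self.control_n,
            n_control - self.control_n,
        )


def _row(key, case_n, case_pct, control_n, control_pct, or_):
    return PublishedRow(key, case_n, case_pct, control_n, control_pct, or_)


#: Experience items (keys match the default catalog ids).
EXPERIENCE_ROWS: tuple[PublishedRow, ...] = (
    _row("cb_see_often", 693, 54.14, 1041, 76.38, 0.365),
    _row("cb_insurance", 991, 78.78, 1095, 82.89, 0.766),
    _row("se_any_difference", 1199, 93.31, 609, 44.65, 17.263),
    _row("se_describe_symptoms", 707, 55.58, 1174, 87.35, 0.181),
    _row("se_describe_pain", 650, 51.06, 1129, 84.00, 0.199),
    _row("se_describe_sensory", 496, 41.96, 355, 59.97, 0.483),
    _row("se_waiting_room", 896, 70.44, 420, 31.37, 5.211),
    _row("se_office", 745, 58.66, 343, 25.56, 4.131),
    _row("se_overwhelm_focus", 801, 62.97, 240, 17.87, 7.809),
    _row("co_explain_symptoms", 848, 66.93, 1213, 91.27, 0.194),
    _row("co_understand_professional", 957, 75.47, 1251, 94.20, 0.190),
    _row("co_not_ask_questions", 983, 77.71, 745, 56.31, 2.703),
    _row("co_bring_up_concern", 704, 55.65, 1019, 76.96, 0.376),
    _row("co_know_expectations", 665, 52.45, 1099, 82.82, 0.229),
    _row("ax_idea", 1044, 82.79, 813, 61.73, 2.981),
    _row("ax_environment", 1003, 79.67, 602, 45.75, 4.644),
    _row("ax_different_professional", 1053, 83.70, 595, 45.28, 6.202),
    _row("ax_setup", 1053, 83.70, 715, 54.37, 4.308),
    _row("ax_prescription", 716, 57.05, 320, 24.37, 4.119),
    _row("ax_no_help", 786, 62.43, 428, 32.55, 3.442),
    _row("aa_chosen_not_go", 996, 79.30, 850, 65.69, 2.000),
    _row("aa_know_contact", 951, 75.84, 1120, 86.49, 0.491),
    _row("aa_can_get_there", 1017, 81.30, 1215, 93.82, 0.286),
    _row("aa_bring_support", 432, 34.45, 267, 20.65, 2.019),
    _row("aa_pharmacy", 1101, 87.87, 1252, 96.75, 0.243),
    _row("aa_follow_procedure", 1009, 80.59, 1188, 91.88, 0.367),
    _row("aa_make_appointments", 1022, 81.56, 1188, 92.09, 0.380),
    _row("aa_wait_emergency", 815, 64.99, 673, 52.09, 1.707),
    _row("sp_enough_time", 515, 41.47, 880, 69.79, 0.307),
    _row("sp_see_specialist", 762, 61.55, 1011, 80.17, 0.396),
    _row("sp_avoid_referral", 702, 56.57, 494, 39.24, 2.016),
    _row("sp_next_steps", 839, 67.66, 1052, 83.76, 0.406),
    _row("sp_support_after_diagnosis", 474, 38.23, 920, 73.25, 0.226),
)

#: Shutdown trigger rows, keyed by situation id.
SHUTDOWN_ROWS: tuple[PublishedRow, ...] = (
    _row("idea_of_going", 498, 40.65, 138, 11.06, 5.506),
    _row("setting_up_appointment", 470, 38.37, 129, 10.50, 5.305),
    _row("waiting_room_sensory", 538, 43.95, 134, 10.84, 6.445),
    _row("office_sensory", 457, 37.49, 98, 7.96, 6.934),
    _row("different_professional", 467, 38.15, 94, 7.62, 7.475),
    _row("talking_to_professional", 504, 41.14, 130, 10.53, 5.937),
    _row("picking_up_prescription", 204, 16.68, 46, 3.74, 5.145),
    _row("many_professionals_before_specialist", 510, 41.53, 148, 11.98, 5.213),
    _row("after_diagnosis_no_followup", 589, 48.52, 179, 14.55, 5.529),
)

#: Meltdown trigger rows, keyed by situation id.
MELTDOWN_ROWS: tuple[PublishedRow, ...] = (
    _row("idea_of_going", 209, 17.06, 55, 4.41, 4.460),
    _row("setting_up_appointment", 194, 15.84, 49, 3.99, 4.529),
    _row("waiting_room_sensory", 218, 17.81, 39, 3.16, 6.648),
    _row("office_sensory", 160, 13.13, 27, 2.19, 6.738),
    _row("different_professional", 215, 17.57, 38, 3.08, 6.701),
    _row("talking_to_professional", 198, 16.16, 42, 3.40, 5.473),
    _row("picking_up_prescription", 116, 9.49, 20, 1.63, 6.330),
    _row("many_professionals_before_specialist", 317, 25.81, 84, 6.80, 4.765),
    _row("after_diagnosis_no_followup", 394, 32.46, 110, 8.94, 4.889),
)

#: Most-recent-appointment items, split by pandemic era.
RECENT_PRE_ROWS: tuple[PublishedRow, ...] = (
    _row("re_understood_questions", 777, 88.60, 700, 96.82, 0.256),
    _row("re_enough_time", 630, 71.84, 617, 85.34, 0.438),
    _row("re_understood_symptoms", 616, 70.24, 628, 86.86, 0.357),
    _row("re_attempted_help", 675, 76.97, 629, 87.00, 0.500),
    _row("re_not_cared", 224, 25.54, 135, 18.67, 1.494),
)

RECENT_DURING_ROWS: tuple[PublishedRow, ...] = (
    _row("re_understood_questions", 242, 88.97, 401, 97.09, 0.242),
    _row("re_enough_time", 200, 73.53, 363, 87.89, 0.383),
    _row("re_understood_symptoms", 196, 72.06, 369, 89.35, 0.308),
    _row("re_attempted_help", 211, 77.57, 377, 91.28, 0.331),
    _row("re_not_cared", 54, 19.85, 79, 19.13, 1.047),
)


def rows_by_key(rows: tuple[PublishedRow, ...]) -> dict[str, PublishedRow]:
    return {r.key: r for r in rows}


#: Rows whose published unadjusted OR is exactly reproduced (3 dp) by the
#: cross-product estimator on the reconstructed counts.  The remaining rows
#: differ in the third decimal, consistent with conditional-MLE estimation
#: in the original analysis; for those the conditional-MLE method applies.
CROSS_PRODUCT_EXACT_KEYS: tuple[str, ...] = (
    "cb_see_often",
    "se_describe_symptoms",
    "se_describe_pain",
    "co_explain_symptoms",
    "co_know_expectations",
    "meltdown:picking_up_prescription",
    "pre:re_understood_symptoms",
    "pre:re_enough_time",
    "during:re_understood_symptoms",
)


def reference_contrasts() -> dict[str, PublishedRow]:
    """All published contrast rows under namespaced keys.

    Experience items keep their catalog id; shutdown/meltdown rows are
    prefixed ``shutdown:``/``meltdown:``; recent-appointment rows are
    prefixed by era (``pre:``/``during:``).
    """
    out: dict[str, PublishedRow] = {r.key: r for r in EXPERIENCE_ROWS}
    out.update({f"shutdown:{r.key}": r for r in SHUTDOWN_ROWS})
    out.update({f"meltdown:{r.key}": r for r in MELTDOWN_ROWS})
    out.update({f"pre:{r.key}": r for r in RECENT_PRE_ROWS})
    out.update({f"during:{r.key}": r for r in RECENT_DURING_ROWS})
    return out
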