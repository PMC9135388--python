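import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hcineq.schema as schema
from hcineq import (GeneratorConfig, binarize_likert, generate_cohort,
                    item_inequality_point, score_frame, section_score,
                    shutdown_meltdown_flags, total_score)
from hcineq.catalog import SCORED_SECTIONS, default_catalog

CATALOG = default_catalog()
LIKERT = list(schema.LIKERT_LEVELS)


def brute_force_recount(record: pd.Series, items) -> tuple[int, int]:
    """Independent oracle: re-derive points/answered item by item from the
    raw labels, without the scoring module's vectorized path."""
    points = answered = 0
    for it in items:
        value = record.get(schema.item_col(it.id))
        if value is None or (isinstance(value, float) and np.isnan(value)):
            continue
        answered += 1
        agreed = value in ("Strongly Agree", "Somewhat Agree")
        negative_experience = agreed if it.endorse_is_negative else not agreed
        points += int(negative_experience)
    return points, answered


class TestBinarize:
    @pytest.mark.parametrize("label,expected", [
        ("Strongly Agree", "endorse"), ("Somewhat Agree", "endorse"),
        ("Strongly Disagree", "reject"), ("Somewhat Disagree", "reject"),
        (None, None), (float("nan"), None),
    ])
    def test_mapping(self, label, expected):
        assert binarize_likert(label) == expected

    def test_unknown_label_named_in_error(self):
        with pytest.raises(ValueError, match="Neutral"):
            binarize_likert("Neutral")


class TestItemPoint:
    @pytest.mark.parametrize("binary,neg,expected", [
        ("endorse", True, 1), ("endorse", False, 0),
        ("reject", True, 0), ("reject", False, 1),
        (None, True, None), (None, False, None),
    ])
    def test_polarity_coding(self, binary, neg, expected):
        assert item_inequality_point(binary, neg) == expected


def _record_with(section, labels):
    items = CATALOG.section_items(section)
    data = {}
    for it, lab in zip(items, labels):
        data[schema.item_col(it.id)] = lab
    return pd.Series(data)


class TestSectionScore:
    def test_three_negative_of_five_answered_two_blank(self):
        items = CATALOG.section_items("access-advocacy")  # 8 items
        labels = []
        for i, it in enumerate(items):
            if i >= 5:
                labels.append(None)  # unanswered items never enter the denominator
            else:
                negative = i < 3
                agree = negative == it.endorse_is_negative
                labels.append("Somewhat Agree" if agree else "Somewhat Disagree")
        entry = section_score(_record_with("access-advocacy", labels),
                              CATALOG, "access-advocacy")
        assert (entry.points, entry.answered) == (3, 5)
        assert entry.score == pytest.approx(0.6)

    @pytest.mark.parametrize("all_negative,expected", [(True, 1.0), (False, 0.0)])
    def test_bounds(self, all_negative, expected):
        items = CATALOG.section_items("sensory")
        labels = ["Strongly Agree" if it.endorse_is_negative == all_negative
                  else "Strongly Disagree" for it in items]
        entry = section_score(_record_with("sensory", labels), CATALOG, "sensory")
        assert entry.score == expected

    def test_unanswered_section_is_undefined(self):
        entry = section_score(pd.Series(dtype=object), CATALOG, "anxiety")
        assert entry.answered == 0 and entry.score is None

    def test_unknown_section_rejected(self):
        with pytest.raises(ValueError, match="not a scored section"):
            section_score(pd.Series(dtype=object), CATALOG, "recent-experience")


class TestTotalScore:
    def test_all_31_negative_gives_one(self):
        data = {}
        for it in CATALOG.scored_items():
            data[schema.item_col(it.id)] = ("Strongly Agree"
                                            if it.endorse_is_negative
                                            else "Strongly Disagree")
        entry = total_score(pd.Series(data), CATALOG)
        assert (entry.points, entry.answered, entry.score) == (31, 31, 1.0)

    def test_additive_over_sections(self, cohort):
        rec = cohort.iloc[0]
        sections = [section_score(rec, CATALOG, s) for s in SCORED_SECTIONS]
        tot = total_score(rec, CATALOG)
        assert tot.points == sum(e.points for e in sections)
        assert tot.answered == sum(e.answered for e in sections)


@settings(max_examples=40, deadline=None)
@given(data=st.data())
def test_monotonicity_flipping_one_item(data):
    """Flipping one answered item from positive to negative raises the
    section score by exactly 1/answered."""
    items = CATALOG.section_items("anxiety")
    labels = data.draw(st.lists(
        st.sampled_from(LIKERT), min_size=len(items), max_size=len(items)))
    rec = _record_with("anxiety", labels)
    base = section_score(rec, CATALOG, "anxiety")
    flip = data.draw(st.integers(0, len(items) - 1))
    it = items[flip]
    rec[schema.item_col(it.id)] = ("Strongly Agree" if it.endorse_is_negative
                                   else "Strongly Disagree")
    high = section_score(rec, CATALOG, "anxiety")
    was_negative = item_inequality_point(
        binarize_likert(labels[flip]), it.endorse_is_negative) == 1
    expected_delta = 0.0 if was_negative else 1.0 / base.answered
    assert high.score - base.score == pytest.approx(expected_delta)


def test_deleting_positive_item_weakly_increases_score():
    items = CATALOG.section_items("sensory")
    labels = []
    for i, it in enumerate(items):
        negative = i % 2 == 0
        labels.append("Strongly Agree" if negative == it.endorse_is_negative
                      else "Strongly Disagree")
    rec = _record_with("sensory", labels)
    base = section_score(rec, CATALOG, "sensory")
    positive_idx = next(i for i in range(len(items)) if i % 2 == 1)
    rec[schema.item_col(items[positive_idx].id)] = None
    assert section_score(rec, CATALOG, "sensory").score >= base.score
    rec = _record_with("sensory", labels)
    rec[schema.item_col(items[0].id)] = None  # a negative item
    assert section_score(rec, CATALOG, "sensory").score <= base.score


class TestScoreFrame:
    def test_matches_brute_force_recount(self, cohort):
        frame = score_frame(cohort, CATALOG)
        sample = cohort.sample(n=min(200, len(cohort)), random_state=0)
        for idx, rec in sample.iterrows():
            for sec in SCORED_SECTIONS:
                pts, ans = brute_force_recount(rec, CATALOG.section_items(sec))
                assert frame.loc[idx, f"{sec}_points"] == pts
                assert frame.loc[idx, f"{sec}_answered"] == ans
            pts, ans = brute_force_recount(rec, CATALOG.scored_items())
            assert frame.loc[idx, "total_points"] == pts
            assert frame.loc[idx, "total_answered"] == ans

    def test_complete_responders_equal_complete_case(self, cohort):
        """On participants who answered everything, the missingness-aware
        score equals the straightforward all-items score."""
        frame = score_frame(cohort, CATALOG)
        complete = frame["total_answered"] == 31
        assert complete.any()
        assert np.allclose(frame.loc[complete, "total_score"],
                           frame.loc[complete, "total_points"] / 31)


def test_shutdown_meltdown_flags_independent(catalog):
    sid = catalog.situations[0]
    rec = pd.Series({schema.shutdown_col(sid): True,
                     schema.meltdown_col(sid): True})
    sd, md = shutdown_meltdown_flags(rec, catalog.situations)
    assert len(sd) == len(md) == 9
    assert sd[0] == 1 and md[0] == 1
    empty_sd, empty_md = shutdown_meltdown_flags(pd.Series(dtype=object),
                                                 catalog.situations)
    assert empty_sd.sum() == 0 and empty_md.sum() == 0
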