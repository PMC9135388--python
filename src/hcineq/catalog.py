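"""Survey item catalog: sections, polarity, and score inclusion.

The survey's experience block has 33 Likert items across six categories;
five of the categories (31 items) enter the healthcare-inequality scores.
Each item carries a polarity flag ``endorse_is_negative``: agreeing with a
negatively phrased statement ("The process of picking up a prescription
makes me anxious") is the negative experience, while agreeing with a
positively phrased one ("I am able to describe how bad my pain feels") is
the positive experience.  Polarity is data, not code — it is read off each
item's phrasing and shipped in the default catalog below, and alternative
catalogs can be loaded from YAML or CSV.

A further five Likert items about the most recent appointment feed the
pandemic-era contrasts, and nine healthcare situations carry independent
shutdown/meltdown checkboxes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

SECTION_CURRENT_BEHAVIOR = "current-behavior"
SECTION_SENSORY = "sensory"
SECTION_COMMUNICATION = "communication"
SECTION_ANXIETY = "anxiety"
SECTION_ACCESS = "access-advocacy"
SECTION_SYSTEM = "system-problems"
SECTION_RECENT = "recent-experience"

#: The five sections whose items are pooled into inequality scores.
SCORED_SECTIONS = (
    SECTION_SENSORY,
    SECTION_COMMUNICATION,
    SECTION_ANXIETY,
    SECTION_ACCESS,
    SECTION_SYSTEM,
)

ALL_SECTIONS = (
    SECTION_CURRENT_BEHAVIOR,
    *SCORED_SECTIONS,
    SECTION_RECENT,
)


@dataclass(frozen=True)
class Item:
    """One survey item: identity, section, phrasing, and polarity."""

    id: str
    section: str
    text: str
    endorse_is_negative: bool
    in_score: bool

    def __post_init__(self) -> None:
        if self.section not in ALL_SECTIONS:
            raise ValueError(f"unknown section {self.section!r} for item {self.id!r}")
        if self.in_score and self.section not in SCORED_SECTIONS:
            raise ValueError(
                f"item {self.id!r}: section {self.section!r} is never scored"
            )


@dataclass(frozen=True)
class ItemCatalog:
    """Immutable collection of survey items plus the checkbox situations."""

    items: tuple[Item, ...]
    situations: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for it in self.items:
            if it.id in seen:
                raise ValueError(f"duplicate item id {it.id!r}")
            seen.add(it.id)

    def __iter__(self):
        return iter(self.items)

    def __len__(self) -> int:
        return len(self.items)

    def get(self, item_id: str) -> Item:
        for it in self.items:
            if it.id == item_id:
                return it
        raise KeyError(item_id)

    def section_items(self, section: str) -> tuple[Item, ...]:
        if section not in ALL_SECTIONS:
            raise ValueError(f"unknown section {section!r}")
        return tuple(it for it in self.items if it.section == section)

    def scored_items(self) -> tuple[Item, ...]:
        return tuple(it for it in self.items if it.in_score)

    # -- serialization ------------------------------------------------------

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "id": it.id,
                    "section": it.section,
                    "text": it.text,
                    "endorse_is_negative": it.endorse_is_negative,
                    "in_score": it.in_score,
                }
                for it in self.items
            ]
        )

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "items": [
                {
                    "id": it.id,
                    "section": it.section,
                    "text": it.text,
                    "endorse_is_negative": it.endorse_is_negative,
                    "in_score": it.in_score,
                }
                for it in self.items
            ],
            "situations": list(self.situations),
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ItemCatalog":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(
            items=tuple(Item(**row) for row in payload["items"]),
            situations=tuple(payload.get("situations", ())),
        )

    @classmethod
    def from_csv(cls, path: str | Path, situations: Iterable[str] = ()) -> "ItemCatalog":
        def as_bool(v: str) -> bool:
            return str(v).strip().lower() in {"1", "true", "yes"}

        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        return cls(
            items=tuple(
                Item(
                    id=r["id"],
                    section=r["section"],
                    text=r.get("text", ""),
                    endorse_is_negative=as_bool(r["endorse_is_negative"]),
                    in_score=as_bool(r["in_score"]),
                )
                for r in rows
            ),
            situations=tuple(situations),
        )


# ---------------------------------------------------------------------------
# Default catalog
# ---------------------------------------------------------------------------

def _item(id: str, section: str, text: str, neg: bool) -> Item:
    return Item(
        id=id,
        section=section,
        text=text,
        endorse_is_negative=neg,
        in_score=section in SCORED_SECTIONS,
    )


_DEFAULT_ITEMS: tuple[Item, ...] = (
    # current healthcare behavior (descriptive; never scored)
    _item("cb_see_often", SECTION_CURRENT_BEHAVIOR,
          "Able to see healthcare professionals as often as they would like", False),
    _item("cb_insurance", SECTION_CURRENT_BEHAVIOR,
          "Has health insurance or is part of a national healthcare program", False),
    # sensory experience (7)
    _item("se_any_difference", SECTION_SENSORY,
          "Reported at least one sensory difference (hyper- or hyposensitivity)", True),
    _item("se_describe_symptoms", SECTION_SENSORY,
          "I am able to describe how my symptoms feel in my body", False),
    _item("se_describe_pain", SECTION_SENSORY,
          "I am able to describe how bad my pain feels", False),
    _item("se_describe_sensory", SECTION_SENSORY,
          "I am able to describe my sensory processing differences to healthcare professionals", False),
    _item("se_waiting_room", SECTION_SENSORY,
          "The sensory environment of the waiting room is more overwhelming than other environments", True),
    _item("se_office", SECTION_SENSORY,
          "The sensory environment of the office is more overwhelming than other environments", True),
    _item("se_overwhelm_focus", SECTION_SENSORY,
          "My senses frequently overwhelm me so that I have trouble focusing on conversations with healthcare professionals", True),
    # communication (5)
    _item("co_explain_symptoms", SECTION_COMMUNICATION,
          "I am usually able to explain what my symptoms are", False),
    _item("co_understand_professional", SECTION_COMMUNICATION,
          "I usually understand what my healthcare professional means when they discuss my health", False),
    _item("co_not_ask_questions", SECTION_COMMUNICATION,
          "I do not usually ask all the questions I would like to about my health", True),
    _item("co_bring_up_concern", SECTION_COMMUNICATION,
          "I can bring up a health concern even if my healthcare professional doesn't ask about it", False),
    _item("co_know_expectations", SECTION_COMMUNICATION,
          "I know what is expected of me when I go to see my healthcare professional", False),
    # anxiety (6)
    _item("ax_idea", SECTION_ANXIETY,
          "The idea of going to see a healthcare professional makes me feel anxious", True),
    _item("ax_environment", SECTION_ANXIETY,
          "The environment of the waiting room or office makes me feel anxious", True),
    _item("ax_different_professional", SECTION_ANXIETY,
          "I feel anxious when I see a different healthcare professional to whom I expect", True),
    _item("ax_setup", SECTION_ANXIETY,
          "The process of setting up an appointment makes me anxious", True),
    _item("ax_prescription", SECTION_ANXIETY,
          "The process of picking up a prescription makes me anxious", True),
    _item("ax_no_help", SECTION_ANXIETY,
          "I frequently leave my healthcare professional's office feeling as though I did not receive any help at all", True),
    # access and advocacy (8)
    _item("aa_chosen_not_go", SECTION_ACCESS,
          "Chosen not to go in to see a healthcare professional", True),
    _item("aa_know_contact", SECTION_ACCESS,
          "I know who to contact if I have a healthcare concern", False),
    _item("aa_can_get_there", SECTION_ACCESS,
          "If I need to go see a healthcare professional, I am able to get there", False),
    _item("aa_bring_support", SECTION_ACCESS,
          "I usually bring someone along to help support me in my appointments", True),
    _item("aa_pharmacy", SECTION_ACCESS,
          "If I need to go to the pharmacy, I am able to get there", False),
    _item("aa_follow_procedure", SECTION_ACCESS,
          "I am able to follow a procedure for next steps if asked", False),
    _item("aa_make_appointments", SECTION_ACCESS,
          "I am able to make appointments for myself", False),
    _item("aa_wait_emergency", SECTION_ACCESS,
          "I will wait until it is an emergency before I go to see a healthcare professional", True),
    # system problems (5)
    _item("sp_enough_time", SECTION_SYSTEM,
          "In most appointments, I have enough time to discuss my concerns with healthcare professionals", False),
    _item("sp_see_specialist", SECTION_SYSTEM,
          "If I need to go to see a specialist for a healthcare concern, I am able to do so", False),
    _item("sp_avoid_referral", SECTION_SYSTEM,
          "I often choose not to go to the doctor with concerns if I need to see a specialist", True),
    _item("sp_next_steps", SECTION_SYSTEM,
          "I usually leave my appointments knowing what the next steps are", False),
    _item("sp_support_after_diagnosis", SECTION_SYSTEM,
          "I am provided with appropriate support after I receive a diagnosis of any kind", False),
    # most recent appointment (pandemic-era contrasts; never scored)
    _item("re_understood_questions", SECTION_RECENT,
          "I understood the questions my healthcare professional asked", False),
    _item("re_enough_time", SECTION_RECENT,
          "The healthcare professional gave me enough time", False),
    _item("re_understood_symptoms", SECTION_RECENT,
          "The healthcare professional understood me when I described my symptoms", False),
    _item("re_attempted_help", SECTION_RECENT,
          "The healthcare professional attempted to help me with my symptoms", False),
    _item("re_not_cared", SECTION_RECENT,
          "I do not think that the healthcare professional cared about my wellbeing", True),
)

#: The nine healthcare situations with independent shutdown and meltdown
#: checkboxes (both may be ticked for the same situation).
SITUATIONS: tuple[str, ...] = (
    "idea_of_going",
    "setting_up_appointment",
    "waiting_room_sensory",
    "office_sensory",
    "different_professional",
    "talking_to_professional",
    "picking_up_prescription",
    "many_professionals_before_specialist",
    "after_diagnosis_no_followup",
)

#: Lifetime condition flags tracked by the sex-stratified prevalence analysis.
CONDITIONS: tuple[str, ...] = (
    "arthritis",
    "breathing_concern",
    "adhd",
    "anxiety",
    "depression",
    "insomnia",
)

#: Autism-specific follow-up questions (asked only of respondents reporting
#: an autism diagnosis; summarized descriptively, never tested).
AUTISM_QUESTIONS: tuple[str, ...] = (
    "provider_knows_diagnosis",
    "provider_understands_autism",
    "provider_makes_adjustments",
)

#: Response levels for the autism-specific questions.
AUTISM_Q_LEVELS: tuple[str, ...] = ("yes", "no", "unsure")


def default_catalog() -> ItemCatalog:
    """The shipped catalog: 33 experience items + 5 recent-appointment items,
    section counts sensory 7 / communication 5 / anxiety 6 /
    access-advocacy 8 / system-problems 5, and the nine checkbox situations.
    """
    return ItemCatalog(items=_DEFAULT_ITEMS, situations=SITUATIONS)
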