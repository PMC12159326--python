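"""Registry of the 11 risk-score predictors and their categorical encodings.

The risk score uses three kinds of predictors: inherent characteristics
(sex, ethnic group), problematic-behaviour flags (school disengagement,
loneliness, fights, running away, substance use, traumatic events) and
household-dysfunction scales (relationship with each caregiver and family
conflict, each split into quintiles labelled 1 = best / least conflict).

Every categorical predictor carries an explicit reference level that never
receives a coefficient; design matrices and coefficient files are keyed by
``(predictor, level)`` pairs, not positional dummies, so column order is
stable under reordering of inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator


@dataclass(frozen=True)
class PredictorDef:
    """One predictor: its name, admissible levels and reference level."""

    name: str
    levels: tuple[int, ...]
    reference: int
    label: str

    @property
    def non_reference_levels(self) -> tuple[int, ...]:
        return tuple(l for l in self.levels if l != self.reference)


QUINTILES = (1, 2, 3, 4, 5)

#: Fixed model encoding. Quintile scales are coded 1..5 with 1 = best
#: relationship / least conflict as the reference.
PREDICTORS: tuple[PredictorDef, ...] = (
    PredictorDef("sex_female", (0, 1), 0, "Female sex"),
    PredictorDef("nonwhite", (0, 1), 0, "Non-white ethnicity"),
    PredictorDef("trauma", (0, 1, 2), 0, "Traumatic events (0/one/multiple)"),
    PredictorDef("school_disengaged", (0, 1), 0, "School disengagement"),
    PredictorDef("loneliness", (0, 1), 0, "Complains of loneliness"),
    PredictorDef("fights", (0, 1), 0, "Gets in fights"),
    PredictorDef("ran_away", (0, 1), 0, "Runs away from home"),
    PredictorDef("substance_ever", (0, 1), 0, "Ever tried alcohol/tobacco/drugs"),
    PredictorDef("caregiver1_q", QUINTILES, 1, "Relationship with caregiver 1"),
    PredictorDef("caregiver2_q", QUINTILES, 1, "Relationship with caregiver 2"),
    PredictorDef("family_conflict_q", QUINTILES, 1, "Family conflict"),
)

PREDICTOR_NAMES: tuple[str, ...] = tuple(p.name for p in PREDICTORS)
PREDICTOR_MAP: dict[str, PredictorDef] = {p.name: p for p in PREDICTORS}


def dummy_terms() -> Iterator[tuple[str, int]]:
    """Yield (predictor, level) pairs for every non-reference level, in
    registry order then ascending level — the canonical design-column order
    (21 terms)."""
    for p in PREDICTORS:
        for level in p.non_reference_levels:
            yield p.name, level


def term_name(predictor: str, level: int) -> str:
    return f"{predictor}={level}"


def parse_term(name: str) -> tuple[str, int]:
    predictor, _, level = name.partition("=")
    if predictor not in PREDICTOR_MAP:
        raise KeyError(f"unknown predictor {predictor!r}")
    return predictor, int(level)


N_DUMMY_TERMS = sum(len(p.non_reference_levels) for p in PREDICTORS)  # 21
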