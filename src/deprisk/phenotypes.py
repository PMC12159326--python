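"""Symptom-level depression phenotyping and cohort preparation.

Codes major depressive disorder (MDD) and ordinal depression-symptom (DS)
severity from item-level data, derives the two incident outcomes between
assessment waves, builds the 11 model predictors from raw measures
(including quintile splits of the caregiver-relationship and family-conflict
scales), runs the staged exclusion cascade, and computes chance-corrected
reporter agreement.

Diagnosis rule (DSM-5 style): a participant is an MDD case iff at least one
core symptom (depressed or — for children/adolescents — irritable mood;
anhedonia) is present AND the total symptom count (cores counted
individually plus secondary symptoms) is at least five.  DS severity grades:

* severe   — both cores with ≥3 secondary symptoms, or any suicidality
* moderate — 7–8 total symptoms, or ≥1 core with ≥2 secondary
* mild     — 5–6 total symptoms, or ≥1 core with ≥1 secondary

Grades are evaluated severe → moderate → mild and the highest satisfied
grade is returned, which makes the scale monotone in the symptom pattern.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .predictors import PREDICTOR_NAMES

REPORTERS = ("youth", "parent")
WAVES = ("baseline", "followup")

DS_NONE, DS_MILD, DS_MODERATE, DS_SEVERE = 0, 1, 2, 3


class PhenotypeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# symptom records and diagnosis coding
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SymptomRecord:
    """Per-participant, per-wave, per-reporter depression item endorsements.

    ``lifetime_flag`` is the current-or-past union the items were coded
    from; it is carried for provenance and does not enter the rules below.
    """

    participant_id: str
    wave: str
    reporter: str
    core_depressed_or_irritable: bool
    core_anhedonia: bool
    secondary_count: int
    suicidality: bool = False
    lifetime_flag: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.secondary_count <= 7):
            raise PhenotypeError("secondary_count must be in [0, 7]")
        if self.reporter not in REPORTERS or self.wave not in WAVES:
            raise PhenotypeError("invalid reporter or wave")


@dataclass(frozen=True)
class DiagnosisStatus:
    participant_id: str
    wave: str
    reporter: str
    mdd: bool
    ds_grade: int


def _counts(record: SymptomRecord) -> tuple[int, int]:
    cores = int(record.core_depressed_or_irritable) + int(record.core_anhedonia)
    return cores, cores + record.secondary_count


def code_mdd_diagnosis(record: SymptomRecord) -> bool:
    """MDD case iff ≥1 core symptom and total symptom count ≥ 5."""
    cores, total = _counts(record)
    return cores >= 1 and total >= 5


def grade_ds(record: SymptomRecord) -> int:
    """Ordinal DS severity; highest satisfied grade wins."""
    cores, total = _counts(record)
    sec = record.secondary_count
    if (cores == 2 and sec >= 3) or record.suicidality:
        return DS_SEVERE
    if 7 <= total <= 8 or (cores >= 1 and sec >= 2):
        return DS_MODERATE
    if 5 <= total <= 6 or (cores >= 1 and sec >= 1):
        return DS_MILD
    return DS_NONE


def diagnose(record: SymptomRecord) -> DiagnosisStatus:
    return DiagnosisStatus(
        participant_id=record.participant_id,
        wave=record.wave,
        reporter=record.reporter,
        mdd=code_mdd_diagnosis(record),
        ds_grade=grade_ds(record),
    )


# vectorized forms used by the cohort coder ---------------------------------


def mdd_flags(core_mood, core_anhedonia, secondary) -> np.ndarray:
    cores = np.asarray(core_mood, dtype=int) + np.asarray(core_anhedonia, dtype=int)
    total = cores + np.asarray(secondary, dtype=int)
    return (cores >= 1) & (total >= 5)


def ds_grades(core_mood, core_anhedonia, secondary, suicidality) -> np.ndarray:
    cores = np.asarray(core_mood, dtype=int) + np.asarray(core_anhedonia, dtype=int)
    sec = np.asarray(secondary, dtype=int)
    total = cores + sec
    grade = np.zeros(total.shape, dtype=int)
    grade[((total >= 5) & (total <= 6)) | ((cores >= 1) & (sec >= 1))] = DS_MILD
    grade[((total >= 7) & (total <= 8)) | ((cores >= 1) & (sec >= 2))] = DS_MODERATE
    grade[((cores == 2) & (sec >= 3)) | np.asarray(suicidality, dtype=bool)] = DS_SEVERE
    return grade


def derive_incident_outcomes(
    baseline: DiagnosisStatus, followup: DiagnosisStatus
) -> tuple[bool, bool]:
    """(incident MDD, increased DS) between the two waves.

    Incident MDD = no MDD at baseline and MDD at follow-up; increased DS =
    at least a one-step rise in the severity grade.  Baseline cases are not
    filtered here — the exclusion cascade removes them beforehand.
    """
    if (
        baseline.participant_id != followup.participant_id
        or baseline.reporter != followup.reporter
    ):
        raise PhenotypeError("baseline/followup statuses refer to different records")
    incident_mdd = (not baseline.mdd) and followup.mdd
    increased_ds = followup.ds_grade >= baseline.ds_grade + 1
    return incident_mdd, increased_ds


# ---------------------------------------------------------------------------
# predictors
# ---------------------------------------------------------------------------


def quintile_split(
    scores: Sequence[float],
    orientation: Literal["higher_is_worse", "higher_is_better"] = "higher_is_worse",
) -> np.ndarray:
    """Split a continuous score into quintile categories 1..5.

    Categories are assigned by the empirical 20/40/60/80 percentile-rank cut
    points.  With ``higher_is_worse`` (family conflict) a larger score maps
    to a larger category; with ``higher_is_better`` (caregiver acceptance,
    where 1 = best relationship) a larger score maps to a smaller category.
    Tied scores at a boundary share one category — the lower one, by the
    min-rank convention.
    """
    x = np.asarray(scores, dtype=float)
    if np.isnan(x).any():
        raise PhenotypeError("quintile_split requires non-missing scores")
    if len(x) < 5:
        raise PhenotypeError("need at least 5 scores to form quintiles")
    if np.ptp(x) == 0:
        raise PhenotypeError("all scores identical; quintiles undefined")
    if orientation == "higher_is_better":
        x = -x
    elif orientation != "higher_is_worse":
        raise PhenotypeError(f"unknown orientation {orientation!r}")
    ranks = rankdata(x, method="min")
    cats = np.ceil(ranks / len(x) * 5).astype(int)
    return np.clip(cats, 1, 5)


#: raw columns consumed by derive_predictors (besides precomputed quintiles)
RAW_PREDICTOR_COLUMNS = (
    "sex",
    "ethnicity_white",
    "trauma_count",
    "school_bores",
    "grades_unimportant",
    "lonely_item",
    "fights_item",
    "ran_away_item",
    "alcohol_ever",
    "tobacco_ever",
    "cannabis_ever",
    "other_drug_ever",
)
QUINTILE_COLUMNS = ("caregiver1_q", "caregiver2_q", "family_conflict_q")
SCORE_COLUMNS = ("caregiver1_score", "caregiver2_score", "family_conflict_score")


def derive_predictor_table(raw: pd.DataFrame) -> pd.DataFrame:
    """Map raw measures to the 11-predictor model encoding (one row per
    participant).

    Rules: trauma count → 0 none / 1 one / 2 multiple; school disengagement
    requires BOTH school items endorsed; the three CBCL-style items are
    positive when endorsed "sometimes or often" (value ≥ 1); substance use
    is the union over all substances; caregiver/conflict scales are taken
    from precomputed quintile columns when present, otherwise quintile-split
    from the continuous summary scores (caregiver acceptance oriented so a
    better relationship gets a lower category).

    Missing raw fields propagate as NaN in the derived column so the
    exclusion cascade can listwise-delete them.
    """
    out = pd.DataFrame(index=raw.index)
    sex = raw["sex"]
    out["sex_female"] = sex.map({"F": 1, "M": 0, 1: 1, 0: 0})
    out["nonwhite"] = 1.0 - raw["ethnicity_white"]
    out["trauma"] = raw["trauma_count"].clip(upper=2)
    school = raw["school_bores"] * raw["grades_unimportant"]
    out["school_disengaged"] = school
    out["loneliness"] = (raw["lonely_item"] >= 1).astype(float).where(
        raw["lonely_item"].notna()
    )
    out["fights"] = (raw["fights_item"] >= 1).astype(float).where(
        raw["fights_item"].notna()
    )
    out["ran_away"] = (raw["ran_away_item"] >= 1).astype(float).where(
        raw["ran_away_item"].notna()
    )
    subst = raw[["alcohol_ever", "tobacco_ever", "cannabis_ever", "other_drug_ever"]]
    out["substance_ever"] = (subst.max(axis=1) >= 1).astype(float).where(
        subst.notna().all(axis=1)
    )
    for qcol, scol, orient in zip(
        QUINTILE_COLUMNS,
        SCORE_COLUMNS,
        ("higher_is_better", "higher_is_better", "higher_is_worse"),
    ):
        if qcol in raw.columns:
            out[qcol] = raw[qcol]
        else:
            scores = raw[scol]
            cats = pd.Series(np.nan, index=raw.index)
            ok = scores.notna()
            cats[ok] = quintile_split(scores[ok].to_numpy(), orient)
            out[qcol] = cats
    return out


def derive_predictors(row: pd.Series | dict) -> dict:
    """Single-row form of :func:`derive_predictor_table`; NaN marks missing."""
    frame = pd.DataFrame([row])
    return derive_predictor_table(frame).iloc[0].to_dict()


# ---------------------------------------------------------------------------
# cohort coding: item-level long table -> per-participant analytic table
# ---------------------------------------------------------------------------


def code_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Collapse a participant×wave item table into one analytic row per
    participant: coded diagnoses and DS grades per wave and reporter, the
    two incident outcomes per reporter, derived predictors, and the
    identifiers the cascade needs.

    Expects columns ``{reporter}_core_mood``, ``{reporter}_core_anhedonia``,
    ``{reporter}_secondary``, ``{reporter}_suicidality`` on each wave row,
    plus raw predictor columns (constant within participant).
    """
    base = cohort[cohort["wave"] == "baseline"].set_index("participant_id")
    fup = cohort[cohort["wave"] == "followup"].set_index("participant_id")
    ids = base.index
    out = pd.DataFrame(index=ids)
    out["family_id"] = base["family_id"]
    out["site_id"] = base["site_id"]
    out["attended_both"] = ids.isin(fup.index) & base.get(
        "attended_followup", pd.Series(True, index=ids)
    ).astype(bool)
    fup = fup.reindex(ids)
    for rep in REPORTERS:
        cols = [f"{rep}_core_mood", f"{rep}_core_anhedonia", f"{rep}_secondary",
                f"{rep}_suicidality"]
        if not all(c in cohort.columns for c in cols):
            continue
        for wave, tab in (("baseline", base), ("followup", fup)):
            cm, ca, sec, sui = (tab[c].fillna(0) for c in cols)
            out[f"{rep}_mdd_{wave}"] = mdd_flags(cm, ca, sec)
            out[f"{rep}_ds_{wave}"] = ds_grades(cm, ca, sec, sui)
        out[f"incident_mdd_{rep}"] = (
            ~out[f"{rep}_mdd_baseline"] & out[f"{rep}_mdd_followup"]
        ).astype(int)
        out[f"increased_ds_{rep}"] = (
            out[f"{rep}_ds_followup"] >= out[f"{rep}_ds_baseline"] + 1
        ).astype(int)
    preds = derive_predictor_table(base)
    out = out.join(preds)
    return out.reset_index().rename(columns={"index": "participant_id"})


# ---------------------------------------------------------------------------
# exclusion cascade
# ---------------------------------------------------------------------------


@dataclass
class CascadeStage:
    label: str
    n_before: int
    n_excluded: int
    n_after: int


@dataclass
class CascadeReport:
    stages: list[CascadeStage] = field(default_factory=list)

    def add(self, label: str, n_before: int, n_after: int) -> None:
        self.stages.append(CascadeStage(label, n_before, n_before - n_after, n_after))

    def to_dict(self) -> dict:
        return {
            "stages": [
                {
                    "label": s.label,
                    "n_before": s.n_before,
                    "n_excluded": s.n_excluded,
                    "n_after": s.n_after,
                }
                for s in self.stages
            ]
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def stard_text(self) -> str:
        """Staged inclusion/exclusion accounting as an indented text block."""
        lines = []
        for s in self.stages:
            lines.append(f"n = {s.n_before}")
            lines.append(f"  excluded at '{s.label}': {s.n_excluded}")
        if self.stages:
            lines.append(f"analytic sample n = {self.stages[-1].n_after}")
        return "\n".join(lines)


def apply_exclusion_cascade(
    analytic: pd.DataFrame,
    seed: int,
    reporter: str = "youth",
) -> tuple[pd.DataFrame, CascadeReport]:
    """Run the four-stage exclusion cascade on a coded per-participant table.

    Stages, in order: (1) keep both-wave attendees; (2) keep one randomly
    sampled participant per family (seeded); (3) drop participants who were
    already MDD cases at baseline per the active reporter; (4) listwise-
    delete rows with any missing predictor.
    """
    if reporter not in REPORTERS:
        raise PhenotypeError(f"unknown reporter {reporter!r}")
    report = CascadeReport()
    df = analytic

    n0 = len(df)
    df = df[df["attended_both"].astype(bool)]
    report.add("did not attend both waves", n0, len(df))
    if df.empty:
        raise PhenotypeError("cascade empty after stage 'did not attend both waves'")

    # one participant per family: seeded uniform draw
    shuffled = df.sample(frac=1.0, random_state=np.random.RandomState(seed))
    kept = shuffled.drop_duplicates(subset="family_id", keep="first")
    df2 = df.loc[df.index.isin(kept.index)]
    report.add("sibling in sampled family", len(df), len(df2))
    df = df2
    if df.empty:
        raise PhenotypeError("cascade empty after family sampling")

    baseline_col = f"{reporter}_mdd_baseline"
    df2 = df[~df[baseline_col].astype(bool)]
    report.add("MDD case at baseline", len(df), len(df2))
    df = df2
    if df.empty:
        raise PhenotypeError("cascade empty after baseline-case exclusion")

    complete = df[list(PREDICTOR_NAMES)].notna().all(axis=1)
    df2 = df[complete]
    report.add("missing predictor data", len(df), len(df2))
    df = df2
    if df.empty:
        raise PhenotypeError("cascade empty after listwise deletion")

    df = df.copy()
    for name in PREDICTOR_NAMES:
        df[name] = df[name].astype(int)
    return df, report


# ---------------------------------------------------------------------------
# reporter agreement
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgreementTable:
    """2×2 agreement counts between two binary raters (row = rater A)."""

    both_pos: int
    row_only: int
    col_only: int
    both_neg: int

    def __post_init__(self) -> None:
        if min(self.both_pos, self.row_only, self.col_only, self.both_neg) < 0:
            raise PhenotypeError("negative cell count")
        if self.total == 0:
            raise PhenotypeError("empty agreement table")

    @property
    def total(self) -> int:
        return self.both_pos + self.row_only + self.col_only + self.both_neg


def cohen_kappa(table: AgreementTable) -> float:
    """Chance-corrected agreement κ = (p_o − p_e) / (1 − p_e)."""
    n = table.total
    p_o = (table.both_pos + table.both_neg) / n
    row_pos = (table.both_pos + table.row_only) / n
    col_pos = (table.both_pos + table.col_only) / n
    p_e = row_pos * col_pos + (1 - row_pos) * (1 - col_pos)
    if p_e >= 1.0:
        raise PhenotypeError("degenerate marginals: chance agreement is 1")
    return (p_o - p_e) / (1 - p_e)
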