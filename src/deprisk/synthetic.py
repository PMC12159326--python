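"""Seeded synthetic longitudinal cohorts with known generating truth.

Emulates the structure the downstream analysis assumes: ~7,700 unrelated
early adolescents after exclusions, nested in 21 recruitment sites, two
assessment waves two years apart, item-level depression symptoms from two
reporters with very low agreement, eleven categorical predictors with
realistic marginals, and an incident-MDD outcome generated from a known
logistic model with Gaussian site-level random intercepts — so every
pipeline stage can be tested against ground truth without any data access.

The generator is a pure function of (config, seed): identical inputs give
byte-identical cohorts.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .phenotypes import DS_MILD, DS_MODERATE, DS_NONE, DS_SEVERE, ds_grades, mdd_flags
from .predictors import PREDICTOR_MAP, PREDICTOR_NAMES, PREDICTORS
from .risk import RiskModel, score_cohort


class SyntheticConfigError(ValueError):
    pass


#: Control-column-like marginal category probabilities; quintile scales get
#: 20% mass per level by construction.
DEFAULT_MARGINALS: dict[str, dict[int, float]] = {
    "sex_female": {0: 0.527, 1: 0.473},
    "nonwhite": {0: 0.565, 1: 0.435},
    "trauma": {0: 0.655, 1: 0.257, 2: 0.088},
    "school_disengaged": {0: 0.938, 1: 0.062},
    "loneliness": {0: 0.879, 1: 0.121},
    "fights": {0: 0.966, 1: 0.034},
    "ran_away": {0: 0.996, 1: 0.004},
    "substance_ever": {0: 0.768, 1: 0.232},
    "caregiver1_q": {q: 0.2 for q in range(1, 6)},
    "caregiver2_q": {q: 0.2 for q in range(1, 6)},
    "family_conflict_q": {q: 0.2 for q in range(1, 6)},
}

#: DS-grade distribution for participants without MDD at a wave (mostly
#: asymptomatic, occasional sub-threshold symptoms); chosen so chance
#: baseline→follow-up increases give an increased-DS prevalence of a few
#: percent, the order observed in low-prevalence early-adolescent samples.
DEFAULT_CONTROL_DS_DIST: dict[int, float] = {
    DS_NONE: 0.955,
    DS_MILD: 0.030,
    DS_MODERATE: 0.010,
    DS_SEVERE: 0.005,
}
#: DS-grade distribution for MDD cases; MDD implies ≥1 core and ≥3 secondary
#: symptoms, so a case's grade is at least moderate.
CASE_DS_DIST: dict[int, float] = {DS_MODERATE: 0.6, DS_SEVERE: 0.4}


@dataclass
class SyntheticConfig:
    """Data-generating assumptions for one synthetic cohort."""

    n_participants: int = 11800
    n_sites: int = 21
    n_families: int = 11166
    true_model: Optional[RiskModel] = None
    site_sd: float = 0.3
    predictor_marginals: dict[str, dict[int, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MARGINALS.items()}
    )
    reporter_agreement: float = 0.05
    missing_rate: float = 0.015
    seed: int = 0
    attendance_rate: float = 0.88
    baseline_mdd_rate: float = 0.015
    control_ds_dist: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTROL_DS_DIST)
    )
    #: log-odds tilt linking non-case symptom worsening at follow-up to the
    #: same risk score (0 = worsening independent of predictors)
    ds_risk_link: float = 0.5

    def __post_init__(self) -> None:
        if self.true_model is None:
            self.true_model = default_true_model()
        if self.n_sites < 1:
            raise SyntheticConfigError("n_sites must be >= 1")
        if self.n_participants < 1:
            raise SyntheticConfigError("n_participants must be >= 1")
        if self.site_sd < 0:
            raise SyntheticConfigError("site_sd must be >= 0")
        for prob, name in (
            (self.reporter_agreement, "reporter_agreement"),
            (self.attendance_rate, "attendance_rate"),
            (self.baseline_mdd_rate, "baseline_mdd_rate"),
        ):
            if not 0.0 <= prob <= 1.0:
                raise SyntheticConfigError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise SyntheticConfigError("missing_rate must be in [0, 1)")
        for pred in PREDICTOR_NAMES:
            if pred not in self.predictor_marginals:
                raise SyntheticConfigError(f"missing marginals for predictor {pred!r}")
            marg = self.predictor_marginals[pred]
            if set(marg) != set(PREDICTOR_MAP[pred].levels):
                raise SyntheticConfigError(f"marginals for {pred!r} mislabel levels")
            if any(not 0.0 <= p <= 1.0 for p in marg.values()):
                raise SyntheticConfigError(f"marginals for {pred!r} outside [0, 1]")
            if abs(sum(marg.values()) - 1.0) > 1e-9:
                raise SyntheticConfigError(f"marginals for {pred!r} do not sum to 1")

    def to_dict(self) -> dict:
        return {
            "n_participants": self.n_participants,
            "n_sites": self.n_sites,
            "n_families": self.n_families,
            "true_model": self.true_model.to_dict(),
            "site_sd": self.site_sd,
            "predictor_marginals": {
                k: {str(l): p for l, p in v.items()}
                for k, v in self.predictor_marginals.items()
            },
            "reporter_agreement": self.reporter_agreement,
            "missing_rate": self.missing_rate,
            "seed": self.seed,
            "attendance_rate": self.attendance_rate,
            "baseline_mdd_rate": self.baseline_mdd_rate,
            "control_ds_dist": {str(k): v for k, v in self.control_ds_dist.items()},
            "ds_risk_link": self.ds_risk_link,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        d["true_model"] = RiskModel.from_dict(d["true_model"])
        d["predictor_marginals"] = {
            k: {int(l): p for l, p in v.items()}
            for k, v in d["predictor_marginals"].items()
        }
        d["control_ds_dist"] = {int(k): v for k, v in d["control_ds_dist"].items()}
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def default_true_model() -> RiskModel:
    """The in-repo known-truth coefficient set used by default configs."""
    with resources.files("deprisk.data").joinpath("synthetic_truth.json").open() as fh:
        return RiskModel.from_dict(json.load(fh))


def solve_intercept(
    main_effects: dict[str, dict[int, float]],
    marginals: dict[str, dict[int, float]],
    target_prevalence: float,
) -> float:
    """Intercept giving an exact marginal outcome prevalence under
    independent predictors (site effects ignored).

    Enumerates the joint distribution of the non-intercept linear predictor
    (a discrete convolution over the 11 independent predictors) and solves
    E[expit(intercept + lp)] = target by root finding.
    """
    vals = np.array([0.0])
    probs = np.array([1.0])
    for pred in PREDICTOR_NAMES:
        coefs = main_effects.get(pred, {})
        ref = PREDICTOR_MAP[pred].reference
        contrib = np.array(
            [coefs.get(l, 0.0) if l != ref else 0.0 for l in PREDICTOR_MAP[pred].levels]
        )
        weight = np.array([marginals[pred][l] for l in PREDICTOR_MAP[pred].levels])
        vals = (vals[:, None] + contrib[None, :]).ravel()
        probs = (probs[:, None] * weight[None, :]).ravel()

    def prevalence(intercept: float) -> float:
        return float(probs @ expit(intercept + vals)) - target_prevalence

    return brentq(prevalence, -30.0, 10.0, xtol=1e-12)


# ---------------------------------------------------------------------------
# item-pattern inventory: every (cores, secondary, suicidality) combination,
# grouped by the (MDD, DS grade) phenotype it codes back to
# ---------------------------------------------------------------------------


def _pattern_inventory() -> dict[tuple[bool, int], np.ndarray]:
    inventory: dict[tuple[bool, int], list] = {}
    for cm, ca, sec, sui in itertools.product((0, 1), (0, 1), range(8), (0, 1)):
        mdd = bool(mdd_flags([cm], [ca], [sec])[0])
        grade = int(ds_grades([cm], [ca], [sec], [sui])[0])
        inventory.setdefault((mdd, grade), []).append((cm, ca, sec, sui))
    return {k: np.array(v, dtype=int) for k, v in inventory.items()}


_PATTERNS = _pattern_inventory()

#: latent phenotype classes the generator draws from
REALIZABLE_CASE_GRADES = tuple(
    sorted(g for (mdd, g) in _PATTERNS if mdd)
)  # (2, 3): an MDD pattern always has >=1 core and >=3 secondary symptoms


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

_RAW_FROM_CATEGORY_COLUMNS = (
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
    "caregiver1_q",
    "caregiver2_q",
    "family_conflict_q",
)


def _raw_from_categories(cats: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Construct raw measure columns whose derived encoding equals ``cats``."""
    n = len(cats)
    raw = pd.DataFrame(index=cats.index)
    raw["sex"] = np.where(cats["sex_female"] == 1, "F", "M")
    raw["ethnicity_white"] = 1 - cats["nonwhite"].to_numpy()
    count = cats["trauma"].to_numpy().astype(int).copy()
    multi = count == 2
    count[multi] = 2 + rng.poisson(1.0, multi.sum())
    raw["trauma_count"] = count
    # school disengagement requires both items endorsed
    disengaged = cats["school_disengaged"].to_numpy() == 1
    alt = rng.integers(0, 3, n)  # 0=(0,0), 1=(1,0), 2=(0,1)
    raw["school_bores"] = np.where(disengaged, 1, (alt == 1).astype(int))
    raw["grades_unimportant"] = np.where(disengaged, 1, (alt == 2).astype(int))
    for cat_col, item_col in (
        ("loneliness", "lonely_item"),
        ("fights", "fights_item"),
        ("ran_away", "ran_away_item"),
    ):
        pos = cats[cat_col].to_numpy() == 1
        raw[item_col] = np.where(pos, rng.integers(1, 3, n), 0)
    used = cats["substance_ever"].to_numpy() == 1
    flags = rng.integers(0, 2, (n, 4))
    none = flags.sum(axis=1) == 0
    flags[none, 0] = 1  # at least one substance for users
    for j, col in enumerate(("alcohol_ever", "tobacco_ever", "cannabis_ever", "other_drug_ever")):
        raw[col] = np.where(used, flags[:, j], 0)
    for col in ("caregiver1_q", "caregiver2_q", "family_conflict_q"):
        raw[col] = cats[col].to_numpy()
    return raw


def generate_cohort(config: SyntheticConfig) -> pd.DataFrame:
    """Generate the cohort skeleton: identifiers, raw predictors, attendance,
    site effects and latent outcome/grade states for both reporters and
    waves (two rows per participant, one per wave).

    Follow-up incident MDD is Bernoulli(expit(intercept + Σ coefficients +
    site effect)) under the configured true model.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    pid = np.array([f"P{i:06d}" for i in range(n)])
    site = rng.integers(0, config.n_sites, n)
    # family structure: n_families distinct families; when n_families < n the
    # surplus participants are siblings placed into randomly chosen families
    n_fam = min(config.n_families, n)
    family = np.arange(n_fam)
    if n > n_fam:
        family = np.concatenate([family, rng.integers(0, n_fam, n - n_fam)])
    family = rng.permutation(family)
    attended = rng.random(n) < config.attendance_rate

    cats = pd.DataFrame(index=range(n))
    for pred in PREDICTOR_NAMES:
        marg = config.predictor_marginals[pred]
        levels = np.array(sorted(marg))
        cats[pred] = rng.choice(levels, size=n, p=[marg[l] for l in levels])

    site_effects = rng.normal(0.0, config.site_sd, config.n_sites)
    profile = cats.copy()
    profile["participant_id"] = pid
    scores = score_cohort(config.true_model, profile)
    lp = scores["lp"].to_numpy() + site_effects[site]
    p_true = expit(lp)

    ctrl_grades = np.array(sorted(config.control_ds_dist))
    ctrl_probs = np.array([config.control_ds_dist[g] for g in ctrl_grades])
    elevated = ctrl_grades != 0
    q0 = float(ctrl_probs[elevated].sum())  # marginal sub-threshold rate
    cond_elev = ctrl_probs[elevated] / q0 if q0 > 0 else ctrl_probs[elevated]
    lp_centered = lp - lp.mean()

    def draw_grades(mdd: np.ndarray, risk_tilt: bool) -> np.ndarray:
        """Non-case grades from the control distribution; at follow-up the
        odds of any sub-threshold symptoms are tilted by the participant's
        risk score (ds_risk_link), so symptom worsening tracks the same
        predictors as incident MDD."""
        grades = np.zeros(len(mdd), dtype=int)
        if risk_tilt and config.ds_risk_link != 0.0 and 0.0 < q0 < 1.0:
            q = expit(logit(q0) + config.ds_risk_link * lp_centered)
            elev = rng.random(n) < q
        else:
            elev = rng.random(n) < q0
        n_elev = int(elev.sum())
        if n_elev:
            grades[elev] = rng.choice(ctrl_grades[elevated], n_elev, p=cond_elev)
        n_cases = int(mdd.sum())
        if n_cases:
            grades[mdd] = rng.choice(
                list(CASE_DS_DIST), size=n_cases, p=list(CASE_DS_DIST.values())
            )
        return grades

    def draw_latents() -> dict[str, np.ndarray]:
        mdd_base = rng.random(n) < config.baseline_mdd_rate
        incident = rng.random(n) < p_true
        mdd_fup = mdd_base | incident
        return {
            "mdd_baseline": mdd_base,
            "ds_baseline": draw_grades(mdd_base, risk_tilt=False),
            "mdd_followup": mdd_fup,
            "ds_followup": draw_grades(mdd_fup, risk_tilt=True),
        }

    youth = draw_latents()
    parent_own = draw_latents()
    latent = {f"latent_{k}_youth": v for k, v in youth.items()}
    for wave in ("baseline", "followup"):
        agree = rng.random(n) < config.reporter_agreement
        for kind in ("mdd", "ds"):
            key = f"{kind}_{wave}"
            latent[f"latent_{key}_parent"] = np.where(
                agree, youth[key], parent_own[key]
            ).astype(youth[key].dtype)

    raw = _raw_from_categories(cats, rng)
    per_participant = pd.DataFrame(
        {
            "participant_id": pid,
            "family_id": [f"F{f:06d}" for f in family],
            "site_id": [f"S{s:02d}" for s in site],
            "attended_followup": attended,
            "true_p": p_true,
        }
    )
    per_participant = pd.concat([per_participant, raw, pd.DataFrame(latent)], axis=1)

    rows = []
    for wave in ("baseline", "followup"):
        block = per_participant.copy()
        block.insert(3, "wave", wave)
        rows.append(block)
    cohort = pd.concat(rows, ignore_index=True)
    return cohort


def generate_symptoms(cohort: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    """Fill item-level symptom columns for both reporters, consistent with
    each row's latent (MDD, DS grade) state — coding the generated items
    reproduces the latent phenotype exactly (round-trip property)."""
    rng = np.random.default_rng(config.seed + 1)
    cohort = cohort.copy()
    for rep in ("youth", "parent"):
        n = len(cohort)
        cm = np.zeros(n, dtype=int)
        ca = np.zeros(n, dtype=int)
        sec = np.zeros(n, dtype=int)
        sui = np.zeros(n, dtype=int)
        wave_key = cohort["wave"].map({"baseline": "baseline", "followup": "followup"})
        mdd = np.zeros(n, dtype=bool)
        grade = np.zeros(n, dtype=int)
        for wave in ("baseline", "followup"):
            sel = (wave_key == wave).to_numpy()
            mdd[sel] = cohort.loc[sel, f"latent_mdd_{wave}_{rep}"].to_numpy()
            grade[sel] = cohort.loc[sel, f"latent_ds_{wave}_{rep}"].to_numpy()
        for (is_mdd, g), patterns in _PATTERNS.items():
            sel = (mdd == is_mdd) & (grade == g)
            k = int(sel.sum())
            if k == 0:
                continue
            pick = patterns[rng.integers(0, len(patterns), k)]
            cm[sel], ca[sel], sec[sel], sui[sel] = pick.T
        cohort[f"{rep}_core_mood"] = cm
        cohort[f"{rep}_core_anhedonia"] = ca
        cohort[f"{rep}_secondary"] = sec
        cohort[f"{rep}_suicidality"] = sui
    return cohort


def inject_missingness(cohort: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """Independently blank each baseline-wave raw predictor cell with
    probability ``rate`` (predictors are baseline measures; coding reads
    them from the baseline rows)."""
    if not 0.0 <= rate < 1.0:
        raise SyntheticConfigError("missingness rate must be in [0, 1)")
    cohort = cohort.copy()
    if rate == 0.0:
        return cohort
    rng = np.random.default_rng(seed)
    rows = cohort.index[cohort["wave"] == "baseline"]
    for col in _RAW_FROM_CATEGORY_COLUMNS:
        mask = rng.random(len(rows)) < rate
        if mask.any():
            if cohort[col].dtype.kind in "iub":
                cohort[col] = cohort[col].astype(float)
            cohort.loc[rows[mask], col] = np.nan
    return cohort


def simulate(config: SyntheticConfig) -> pd.DataFrame:
    """Full generator: skeleton + symptoms + configured missingness."""
    cohort = generate_symptoms(generate_cohort(config), config)
    return inject_missingness(cohort, config.missing_rate, config.seed + 2)


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def continuous_scale_fixture(
    n: int, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Continuous caregiver-acceptance and family-conflict scores for
    exercising the quintile split (scores drawn within category bands so the
    intended category is recoverable)."""
    rng = np.random.default_rng(seed)
    cats = rng.integers(1, 6, n)
    accept = (6 - cats) + rng.random(n)  # higher acceptance = better = lower cat
    conflict = cats + rng.random(n)  # higher conflict = worse = higher cat
    return accept, conflict, cats
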