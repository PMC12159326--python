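"""Risk-score engine: apply a fixed-coefficient logistic model to predictor
profiles, producing linear predictors (log-odds) and probabilities.

A :class:`RiskModel` is an intercept plus a sparse map of per-level
log-odds weights; reference levels implicitly carry weight 0.  Models may
come from an external publication (``provenance="external"``), from
intercept recalibration, or from a penalized refit (which records its
penalty and may include pairwise interaction terms).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit  # noqa: F401  (logit re-exported for callers)

from .predictors import PREDICTOR_MAP, PREDICTOR_NAMES, parse_term, term_name

PROVENANCES = ("external", "recalibrated", "refitted")

#: interaction key: ((predictor_a, level_a), (predictor_b, level_b)), a < b
InteractionKey = tuple[tuple[str, int], tuple[str, int]]


class RiskModelError(ValueError):
    """Invalid coefficient set or profile/model mismatch."""


@dataclass
class RiskModel:
    intercept: float
    main_effects: dict[str, dict[int, float]]
    interactions: dict[InteractionKey, float] = field(default_factory=dict)
    provenance: str = "external"
    penalty: Optional[float] = None
    outcome_label: str = "incident_mdd"

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCES:
            raise RiskModelError(f"unknown provenance {self.provenance!r}")
        if (self.penalty is not None) != (self.provenance == "refitted"):
            raise RiskModelError("penalty must be present iff provenance='refitted'")
        for pred, levels in self.main_effects.items():
            if pred not in PREDICTOR_MAP:
                raise RiskModelError(f"unknown predictor {pred!r} in coefficients")
            pdef = PREDICTOR_MAP[pred]
            for level in levels:
                if level == pdef.reference:
                    raise RiskModelError(
                        f"reference level {pred}={level} must not carry a coefficient"
                    )
                if level not in pdef.levels:
                    raise RiskModelError(f"unknown level {pred}={level}")
        for (a, b) in self.interactions:
            for pred, level in (a, b):
                pdef = PREDICTOR_MAP.get(pred)
                if pdef is None or level not in pdef.levels or level == pdef.reference:
                    raise RiskModelError(f"bad interaction term {pred}={level}")
            if a[0] == b[0]:
                raise RiskModelError("interaction within a single predictor")

    def coefficient(self, predictor: str, level: int) -> float:
        """Log-odds weight for one level (0 for the reference level)."""
        pdef = PREDICTOR_MAP[predictor]
        if level == pdef.reference:
            return 0.0
        try:
            return self.main_effects[predictor][level]
        except KeyError:
            raise RiskModelError(
                f"no coefficient for non-reference level {predictor}={level}"
            ) from None

    # --- serialization (versioned JSON schema) -------------------------------

    def to_dict(self) -> dict:
        return {
            "schema": "deprisk-riskmodel-1",
            "outcome_label": self.outcome_label,
            "provenance": self.provenance,
            "penalty": self.penalty,
            "intercept": self.intercept,
            "coefficients": {
                term_name(p, l): v
                for p, levels in self.main_effects.items()
                for l, v in levels.items()
            },
            "interactions": {
                f"{term_name(*a)}:{term_name(*b)}": v
                for (a, b), v in self.interactions.items()
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RiskModel":
        main: dict[str, dict[int, float]] = {}
        for key, value in d.get("coefficients", {}).items():
            pred, level = parse_term(key)
            main.setdefault(pred, {})[level] = float(value)
        inter: dict[InteractionKey, float] = {}
        for key, value in d.get("interactions", {}).items():
            a, b = key.split(":")
            inter[(parse_term(a), parse_term(b))] = float(value)
        return cls(
            intercept=float(d["intercept"]),
            main_effects=main,
            interactions=inter,
            provenance=d.get("provenance", "external"),
            penalty=d.get("penalty"),
            outcome_label=d.get("outcome_label", "incident_mdd"),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RiskModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def linear_predictor(model: RiskModel, profile: Mapping[str, int]) -> float:
    """Intercept plus the sum of matched main-effect (and interaction)
    log-odds weights for one predictor profile."""
    lp = model.intercept
    for pred in PREDICTOR_NAMES:
        if pred not in profile:
            raise RiskModelError(f"profile missing predictor {pred!r}")
        lp += model.coefficient(pred, int(profile[pred]))
    for ((pa, la), (pb, lb)), beta in model.interactions.items():
        if int(profile[pa]) == la and int(profile[pb]) == lb:
            lp += beta
    return lp


def predicted_probability(lp: float | np.ndarray) -> float | np.ndarray:
    """Back-transform log-odds to the probability scale (overflow-safe)."""
    arr = np.asarray(lp, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite linear predictor")
    out = expit(arr)
    return float(out) if np.isscalar(lp) or arr.ndim == 0 else out


def score_cohort(model: RiskModel, cohort: pd.DataFrame) -> pd.DataFrame:
    """Score every row of a cascaded cohort table.

    Returns a DataFrame (participant_id, lp, p, coef_sum) aligned with the
    input row order, where ``coef_sum`` is the intercept-free part of the
    linear predictor (the offset used in recalibration; models differing
    only in intercept produce bitwise-identical coef_sum, so rank-based
    statistics computed on it are exactly preserved). Vectorized over
    participants; raises naming the offending level (with a participant id)
    if a profile carries a non-reference level the model does not cover.
    """
    if len(cohort) == 0:
        return pd.DataFrame(columns=["participant_id", "lp", "p", "coef_sum"])
    lp = np.zeros(len(cohort), dtype=float)
    for pdef in (PREDICTOR_MAP[n] for n in PREDICTOR_NAMES):
        values = cohort[pdef.name].to_numpy()
        coefs = model.main_effects.get(pdef.name, {})
        for level in pdef.non_reference_levels:
            mask = values == level
            if not mask.any():
                continue
            if level not in coefs:
                pid = cohort.loc[cohort[pdef.name] == level, "participant_id"].iloc[0]
                raise RiskModelError(
                    f"participant {pid}: no coefficient for {pdef.name}={level}"
                )
            lp[mask] += coefs[level]
        bad = ~np.isin(values, pdef.levels)
        if bad.any():
            pid = cohort.loc[bad, "participant_id"].iloc[0]
            raise RiskModelError(f"participant {pid}: invalid {pdef.name} value")
    for ((pa, la), (pb, lb)), beta in model.interactions.items():
        both = (cohort[pa].to_numpy() == la) & (cohort[pb].to_numpy() == lb)
        lp[both] += beta
    coef_sum = lp
    lp = coef_sum + model.intercept
    return pd.DataFrame(
        {
            "participant_id": cohort["participant_id"].to_numpy(),
            "lp": lp,
            "p": expit(lp),
            "coef_sum": coef_sum,
        }
    )
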