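"""Discrimination, overall-fit and calibration metrics for one
model × outcome pair, and deltas between model variants.

The battery: AUC (Mann–Whitney concordance, ties ½) with a DeLong normal
interval, Brier score, calibration-in-the-large (intercept of a logistic
model with the predicted logit as a fixed offset; 0 means predictions are
correct on average), calibration slope (coefficient of the predicted logit
in a free logistic re-fit; <1 flags overly extreme predictions) and an
equal-count-bin calibration curve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import logit
from scipy.stats import norm
from sklearn.metrics import roc_auc_score

_P_EPS = 1e-15


class MetricError(ValueError):
    pass


def _check_binary(p: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=int)
    if p.shape != y.shape:
        raise MetricError("predictions and outcomes differ in length")
    if not set(np.unique(y)) <= {0, 1}:
        raise MetricError("outcomes must be binary 0/1")
    if y.min() == y.max():
        raise MetricError("both outcome classes must be present")
    return p, y


def auc(predictions: Sequence[float], outcomes: Sequence[int]) -> float:
    """Probability a random case outranks a random control (ties count ½)."""
    p, y = _check_binary(np.asarray(predictions, float), np.asarray(outcomes))
    return float(roc_auc_score(y, p))


def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    z = x[order]
    n = len(x)
    t = np.zeros(n)
    i = 0
    while i < n:
        j = i
        while j < n and z[j] == z[i]:
            j += 1
        t[i:j] = 0.5 * (i + j - 1) + 1
        i = j
    out = np.empty(n)
    out[order] = t
    return out


def delong_variance(predictions, outcomes) -> tuple[float, float]:
    """(AUC, DeLong variance) via the midrank formulation."""
    p, y = _check_binary(np.asarray(predictions, float), np.asarray(outcomes))
    pos, neg = p[y == 1], p[y == 0]
    m, n = len(pos), len(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    tx, ty = _midrank(pos), _midrank(neg)
    a = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
    v01 = (tz[:m] - tx) / n
    v10 = 1.0 - (tz[m:] - ty) / m
    var = 0.0
    if m > 1:
        var += np.var(v01, ddof=1) / m
    if n > 1:
        var += np.var(v10, ddof=1) / n
    return float(a), float(var)


def auc_ci(
    predictions,
    outcomes,
    level: float = 0.95,
    method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Confidence interval for the AUC, truncated to [0, 1].

    ``method="delong"`` (default) uses the DeLong variance with a normal
    interval; ``method="bootstrap"`` resamples stratified by outcome as an
    independent cross-check.
    """
    if not 0.0 < level < 1.0:
        raise MetricError("level must be in (0, 1)")
    p, y = _check_binary(np.asarray(predictions, float), np.asarray(outcomes))
    if method == "delong":
        a, var = delong_variance(p, y)
        z = norm.ppf(0.5 + level / 2)
        half = z * np.sqrt(var)
        return max(0.0, a - half), min(1.0, a + half)
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        pos, neg = p[y == 1], p[y == 0]
        stats = []
        for _ in range(n_boot):
            bp = pos[rng.integers(0, len(pos), len(pos))]
            bn = neg[rng.integers(0, len(neg), len(neg))]
            stats.append(
                roc_auc_score(
                    np.r_[np.ones(len(bp)), np.zeros(len(bn))], np.r_[bp, bn]
                )
            )
        lo, hi = np.quantile(stats, [(1 - level) / 2, 0.5 + level / 2])
        return float(lo), float(hi)
    raise MetricError(f"unknown CI method {method!r}")


def brier(predictions, outcomes) -> float:
    """Mean squared difference between predicted probability and outcome."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise MetricError("probabilities must lie in [0, 1]")
    return float(np.mean((p - y) ** 2))


def _safe_logit(p: np.ndarray) -> np.ndarray:
    return logit(np.clip(p, _P_EPS, 1 - _P_EPS))


def calibration_intercept(predictions, outcomes) -> float:
    """Calibration-in-the-large: intercept of a one-parameter logistic fit
    with logit(p) as a fixed offset."""
    p, y = _check_binary(np.asarray(predictions, float), np.asarray(outcomes))
    lp = _safe_logit(p)
    res = sm.GLM(
        y, np.ones((len(y), 1)), family=sm.families.Binomial(), offset=lp
    ).fit(tol=1e-12)
    if not res.converged:
        raise MetricError("calibration-intercept fit did not converge")
    return float(res.params[0])


def calibration_slope(predictions, outcomes) -> float:
    """Slope of a logistic regression of outcomes on logit(p), intercept free."""
    p, y = _check_binary(np.asarray(predictions, float), np.asarray(outcomes))
    lp = _safe_logit(p)
    if np.ptp(lp) == 0:
        raise MetricError("constant predictions: calibration slope undefined")
    X = np.column_stack([np.ones(len(y)), lp])
    res = sm.GLM(y, X, family=sm.families.Binomial()).fit(tol=1e-12)
    if not res.converged:
        raise MetricError("calibration-slope fit did not converge")
    return float(res.params[1])


def calibration_curve(predictions, outcomes, n_bins: int = 10) -> list[dict]:
    """Equal-count calibration curve: per predicted-probability bin, the
    mean prediction, observed event rate and bin size.  Bins partition the
    sample (sizes differ by at most one)."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if n_bins < 2:
        raise MetricError("n_bins must be >= 2")
    if n_bins > len(p):
        raise MetricError("n_bins exceeds the number of observations")
    order = np.argsort(p, kind="mergesort")
    curve = []
    for idx in np.array_split(order, n_bins):
        curve.append(
            {
                "mean_predicted": float(p[idx].mean()),
                "observed_rate": float(y[idx].mean()),
                "n": int(len(idx)),
            }
        )
    return curve


@dataclass
class ValidationReport:
    """The full metric battery for one model × outcome pair."""

    auc: float
    auc_ci: tuple[float, float]
    brier: float
    citl: float
    slope: float
    curve: list[dict]
    n_cases: int
    n_controls: int
    outcome_label: str
    provenance: str

    def __post_init__(self) -> None:
        lo, hi = self.auc_ci
        if not (lo <= self.auc <= hi):
            raise MetricError("AUC outside its own confidence interval")
        if self.brier > 1:
            raise MetricError("Brier score above 1")
        if self.n_cases < 1 or self.n_controls < 1:
            raise MetricError("both classes required")

    def to_dict(self) -> dict:
        return {
            "outcome_label": self.outcome_label,
            "provenance": self.provenance,
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "auc_percent": f"{100 * self.auc:.1f}%",
            "brier": self.brier,
            "calibration_in_the_large": self.citl,
            "calibration_slope": self.slope,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "curve": self.curve,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ValidationReport":
        return cls(
            auc=d["auc"],
            auc_ci=tuple(d["auc_ci"]),
            brier=d["brier"],
            citl=d["calibration_in_the_large"],
            slope=d["calibration_slope"],
            curve=d["curve"],
            n_cases=d["n_cases"],
            n_controls=d["n_controls"],
            outcome_label=d["outcome_label"],
            provenance=d["provenance"],
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.curve)


def validation_report(
    predictions,
    outcomes,
    outcome_label: str,
    provenance: str,
    level: float = 0.95,
    n_bins: int = 10,
    ci_method: str = "delong",
    linear_predictors=None,
) -> ValidationReport:
    """Assemble the full battery for one scored cohort.

    When ``linear_predictors`` is given, ranking metrics (AUC and its CI)
    are computed on the log-odds scale: the AUC is invariant under the
    monotone back-transform, and ranking on lp avoids spurious ties from
    probability-scale rounding — intercept-only updates then leave the AUC
    bit-for-bit unchanged.
    """
    p, y = _check_binary(np.asarray(predictions, float), np.asarray(outcomes))
    rank_scores = (
        np.asarray(linear_predictors, float) if linear_predictors is not None else p
    )
    return ValidationReport(
        auc=auc(rank_scores, y),
        auc_ci=auc_ci(rank_scores, y, level=level, method=ci_method),
        brier=brier(p, y),
        citl=calibration_intercept(p, y),
        slope=calibration_slope(p, y),
        curve=calibration_curve(p, y, n_bins=min(n_bins, max(2, len(p)))),
        n_cases=int(y.sum()),
        n_controls=int((1 - y).sum()),
        outcome_label=outcome_label,
        provenance=provenance,
    )


@dataclass(frozen=True)
class MetricDelta:
    """Elementwise differences b − a between two reports on one outcome.
    AUC is reported in percentage points to match the convention of
    presenting discrimination as a percentage."""

    outcome_label: str
    from_provenance: str
    to_provenance: str
    auc_points: float
    brier: float
    citl: float
    slope: float

    def to_dict(self) -> dict:
        return {
            "outcome_label": self.outcome_label,
            "from": self.from_provenance,
            "to": self.to_provenance,
            "delta_auc_points": self.auc_points,
            "delta_brier": self.brier,
            "delta_calibration_in_the_large": self.citl,
            "delta_calibration_slope": self.slope,
        }


def compare_reports(a: ValidationReport, b: ValidationReport) -> MetricDelta:
    if a.outcome_label != b.outcome_label:
        raise MetricError(
            f"cannot compare reports for different outcomes "
            f"({a.outcome_label!r} vs {b.outcome_label!r})"
        )
    return MetricDelta(
        outcome_label=a.outcome_label,
        from_provenance=a.provenance,
        to_provenance=b.provenance,
        auc_points=round((b.auc - a.auc) * 100, 10),
        brier=b.brier - a.brier,
        citl=b.citl - a.citl,
        slope=b.slope - a.slope,
    )
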