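"""Two-stage model updating for an externally derived risk score.

Stage one re-estimates only the intercept ("recalibration"): outcomes are
regressed on a constant with the original linear predictor (minus its
intercept) as a fixed offset, so the slope of the old score is 1 by
construction and discrimination is untouched.  Stage two fully refits all
predictor weights by ridge-penalized maximum likelihood — the binomial
log-likelihood minus (λ/2)·Σβ² over non-intercept coefficients — with the
scalar penalty λ chosen as the median of per-replicate optima over
bootstrap resamples, each replicate scored by an effective-AIC criterion
(log-likelihood minus effective degrees of freedom, the trace of the ridge
hat-type matrix).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .predictors import PREDICTOR_NAMES, dummy_terms, term_name
from .risk import InteractionKey, RiskModel, score_cohort

DEFAULT_GRID: tuple[float, ...] = tuple(np.logspace(-2, 2, 15))


class FitError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# recalibration
# ---------------------------------------------------------------------------


def recalibrate_intercept(
    model: RiskModel, cohort: pd.DataFrame, outcome_label: str
) -> RiskModel:
    """Re-estimate only the intercept, holding all weights fixed.

    One-parameter logistic MLE with the coefficient part of the linear
    predictor as offset; returns a copy of the model with the new intercept
    and ``provenance="recalibrated"``.
    """
    y = cohort[outcome_label].to_numpy(dtype=int)
    if y.min() == y.max():
        raise FitError("single-class outcome: cannot recalibrate")
    offset = score_cohort(model, cohort)["coef_sum"].to_numpy()
    res = sm.GLM(
        y, np.ones((len(y), 1)), family=sm.families.Binomial(), offset=offset
    ).fit(tol=1e-12)
    if not res.converged:
        raise FitError("intercept recalibration did not converge")
    return RiskModel(
        intercept=float(res.params[0]),
        main_effects={k: dict(v) for k, v in model.main_effects.items()},
        interactions=dict(model.interactions),
        provenance="recalibrated",
        penalty=None,
        outcome_label=outcome_label,
    )


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------


@dataclass
class DesignMatrix:
    """Dummy-coded design: no intercept column, no reference-level columns,
    deterministic column order (registry order, then all pairwise
    interaction products of dummy columns from distinct predictors)."""

    columns: list[str]
    matrix: np.ndarray
    main_terms: list[tuple[str, int]]
    interaction_terms: list[InteractionKey] = field(default_factory=list)

    @property
    def n_main(self) -> int:
        return len(self.main_terms)


def build_design_matrix(
    cohort: pd.DataFrame, include_interactions: bool = False
) -> DesignMatrix:
    main_terms = list(dummy_terms())
    cols = []
    names = []
    for pred, level in main_terms:
        cols.append((cohort[pred].to_numpy() == level).astype(float))
        names.append(term_name(pred, level))
    inter_terms: list[InteractionKey] = []
    if include_interactions:
        base = {t: c for t, c in zip(main_terms, cols)}
        for i, a in enumerate(main_terms):
            for b in main_terms[i + 1 :]:
                if a[0] == b[0]:
                    continue
                inter_terms.append((a, b))
                cols.append(base[a] * base[b])
                names.append(f"{term_name(*a)}:{term_name(*b)}")
    return DesignMatrix(
        columns=names,
        matrix=np.column_stack(cols),
        main_terms=main_terms,
        interaction_terms=inter_terms,
    )


# ---------------------------------------------------------------------------
# ridge-penalized logistic regression (damped Newton / IRLS)
# ---------------------------------------------------------------------------


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # numerically stable binomial log-likelihood
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_penalized_logistic(
    X: DesignMatrix | np.ndarray,
    y: Sequence[int],
    lam: float,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> tuple[float, np.ndarray]:
    """Maximize loglik − (λ/2)·Σβ² (intercept unpenalized) by damped Newton.

    Returns ``(intercept, slopes)``.  Converged when the gradient max-norm
    drops below ``tol``.  With λ > 0 estimates stay finite even under
    complete separation; λ = 0 on separable data raises with advice.
    """
    if lam < 0:
        raise ValueError("penalty must be >= 0")
    mat = X.matrix if isinstance(X, DesignMatrix) else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise FitError("single-class outcome")
    n, k = mat.shape
    Xa = np.column_stack([np.ones(n), mat])
    pen = np.r_[0.0, np.full(k, lam)]  # intercept unpenalized
    beta = np.zeros(k + 1)
    beta[0] = np.log(y.mean() / (1 - y.mean()))

    def objective(b: np.ndarray) -> float:
        return _loglik(Xa @ b, y) - 0.5 * float(pen @ (b**2))

    obj = objective(beta)
    for _ in range(max_iter):
        eta = Xa @ beta
        mu = expit(eta)
        grad = Xa.T @ (y - mu) - pen * beta
        gnorm = np.abs(grad).max()
        if lam == 0.0 and np.abs(beta[1:]).max() > 1e2:
            # saturated probabilities make the gradient vanish spuriously
            raise FitError(
                "unpenalized fit diverging (likely complete separation); "
                "use a penalty λ > 0"
            )
        if gnorm < tol:
            return float(beta[0]), beta[1:].copy()
        w = mu * (1 - mu)
        H = (Xa * w[:, None]).T @ Xa + np.diag(pen)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise FitError(f"singular Hessian in penalized fit: {exc}") from exc
        # step halving keeps the penalized log-likelihood non-decreasing
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            cand_obj = objective(cand)
            if cand_obj >= obj - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        obj = objective(beta)
    raise FitError(f"no convergence in {max_iter} iterations (|grad|={gnorm:.2e})")


def effective_df(mat: np.ndarray, beta: np.ndarray, lam: float) -> float:
    """Effective model dimension of the ridge fit: trace of
    (XᵀWX)(XᵀWX + λD)⁻¹ with D zero on the intercept."""
    n = mat.shape[0]
    Xa = np.column_stack([np.ones(n), mat])
    mu = expit(Xa @ beta)
    w = mu * (1 - mu)
    info = (Xa * w[:, None]).T @ Xa
    pen = np.diag(np.r_[0.0, np.full(mat.shape[1], lam)])
    return float(np.trace(np.linalg.solve((info + pen).T, info.T).T))


# ---------------------------------------------------------------------------
# bootstrap penalty selection
# ---------------------------------------------------------------------------


@dataclass
class PenaltySelection:
    grid: list[float]
    n_boot: int
    per_replicate_optima: list[float]
    selected: float
    criterion_label: str
    seed: int

    def to_dict(self) -> dict:
        return {
            "grid": self.grid,
            "n_boot": self.n_boot,
            "per_replicate_optima": self.per_replicate_optima,
            "selected": self.selected,
            "criterion_label": self.criterion_label,
            "seed": self.seed,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _lower_median(values: np.ndarray) -> float:
    """Median taking the lower of the two middle values for even counts, so
    the selection always lies on the grid."""
    s = np.sort(values)
    return float(s[(len(s) - 1) // 2])


def _replicate_criterion(
    mat: np.ndarray, y: np.ndarray, lam: float, criterion: str
) -> float:
    intercept, slopes = fit_penalized_logistic(mat, y, lam)
    beta = np.r_[intercept, slopes]
    eta = np.column_stack([np.ones(len(y)), mat]) @ beta
    ll = _loglik(eta, y)
    if criterion == "aic_penalized":
        ll -= 0.5 * lam * float(slopes @ slopes)
    elif criterion != "aic":
        raise ValueError(f"unknown criterion {criterion!r}")
    return ll - effective_df(mat, beta, lam)


def select_penalty(
    X: DesignMatrix | np.ndarray,
    y: Sequence[int],
    grid: Sequence[float] = DEFAULT_GRID,
    n_boot: int = 1000,
    seed: int = 0,
    criterion: str = "aic",
    max_redraws: int = 100,
) -> PenaltySelection:
    """Median-of-bootstraps penalty selection.

    For each resample (with replacement, seeded) the whole grid is fit and
    scored by the effective-AIC criterion; the per-replicate argmax λ is
    recorded and the selected penalty is the (lower-)median over replicates.
    Single-class resamples are redrawn with a warning, up to a cap.
    """
    grid = list(grid)
    if not grid or sorted(grid) != grid:
        raise ValueError("penalty grid must be non-empty and sorted")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    mat = X.matrix if isinstance(X, DesignMatrix) else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(seed)
    n = len(y)
    optima = []
    for _ in range(n_boot):
        for attempt in range(max_redraws + 1):
            idx = rng.integers(0, n, n)
            yb = y[idx]
            if yb.min() != yb.max():
                break
            warnings.warn("single-class bootstrap resample redrawn", stacklevel=2)
        else:
            raise FitError("could not draw a two-class bootstrap resample")
        crits = [_replicate_criterion(mat[idx], yb, lam, criterion) for lam in grid]
        optima.append(grid[int(np.argmax(crits))])
    return PenaltySelection(
        grid=grid,
        n_boot=n_boot,
        per_replicate_optima=optima,
        selected=_lower_median(np.array(optima)),
        criterion_label=criterion,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# full refit
# ---------------------------------------------------------------------------


@dataclass
class RefitOptions:
    include_interactions: bool = True
    grid: tuple[float, ...] = DEFAULT_GRID
    n_boot: int = 1000
    seed: int = 0
    criterion: str = "aic"
    penalty: Optional[float] = None  # skip selection when given


def refit_model(
    cohort: pd.DataFrame,
    outcome_label: str,
    options: RefitOptions | None = None,
) -> tuple[RiskModel, Optional[PenaltySelection]]:
    """Re-estimate all predictor weights by penalized maximum likelihood.

    Builds the dummy design (optionally with all pairwise interactions),
    selects the penalty per outcome by the bootstrap-median rule unless a
    fixed penalty is supplied, fits, and returns a refitted
    :class:`RiskModel` (penalty recorded) plus the selection audit record.
    """
    options = options or RefitOptions()
    design = build_design_matrix(cohort, options.include_interactions)
    y = cohort[outcome_label].to_numpy(dtype=int)
    selection: Optional[PenaltySelection] = None
    if options.penalty is not None:
        lam = float(options.penalty)
    else:
        selection = select_penalty(
            design,
            y,
            grid=options.grid,
            n_boot=options.n_boot,
            seed=options.seed,
            criterion=options.criterion,
        )
        lam = selection.selected
    intercept, slopes = fit_penalized_logistic(design, y, lam)
    main_effects: dict[str, dict[int, float]] = {p: {} for p in PREDICTOR_NAMES}
    for (pred, level), b in zip(design.main_terms, slopes[: design.n_main]):
        main_effects[pred][level] = float(b)
    interactions = {
        key: float(b)
        for key, b in zip(design.interaction_terms, slopes[design.n_main :])
    }
    model = RiskModel(
        intercept=float(intercept),
        main_effects={k: v for k, v in main_effects.items() if v},
        interactions=interactions,
        provenance="refitted",
        penalty=lam,
        outcome_label=outcome_label,
    )
    return model, selection


def coefficient_keys(model: RiskModel) -> list[str]:
    """Flat term names of a model's coefficients, in serialization order."""
    keys = [
        term_name(p, l) for p, levels in model.main_effects.items() for l in levels
    ]
    keys += [f"{term_name(*a)}:{term_name(*b)}" for a, b in model.interactions]
    return keys
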