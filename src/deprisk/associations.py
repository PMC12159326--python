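"""Per-predictor associations with incident outcomes via random-intercept
logistic regression, with Benjamini–Hochberg false-discovery-rate control.

The mixed model accounts for nesting of participants within recruitment
sites: logit P(y=1) = Xβ + u_g with u_g ~ N(0, σ²).  Fitting uses the
Laplace approximation to the marginal likelihood in its profiled form: for
a candidate σ, the joint penalized log-likelihood is maximized over (β, u)
by penalized IRLS, and σ is optimized on the one-dimensional Laplace
criterion.  Wald standard errors come from the fixed-effect block of the
inverse joint penalized Fisher information — adequate for a single random
intercept with moderately sized groups; accuracy degrades for very small
groups (see the package methods note).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.special import expit
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .predictors import PREDICTOR_MAP, dummy_terms
from .updating import DesignMatrix, build_design_matrix, _loglik


class AssociationError(RuntimeError):
    pass


@dataclass
class MixedLogisticFit:
    """Fixed effects (intercept first), Wald inference and the random-
    intercept SD from one Laplace-approximated fit."""

    columns: list[str]
    coef: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    sigma: float
    loglik: float
    n_groups: int
    converged: bool


def _pirls(
    A: np.ndarray, y: np.ndarray, pen_diag: np.ndarray, max_iter: int = 200,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Penalized IRLS: maximize loglik(Aθ) − ½ θᵀ diag(pen) θ.

    Returns (θ, working weights, penalized loglik at the mode)."""
    theta = np.zeros(A.shape[1])
    theta[0] = np.log(max(y.mean(), 1e-9) / max(1 - y.mean(), 1e-9))

    def objective(t: np.ndarray) -> float:
        return _loglik(A @ t, y) - 0.5 * float(pen_diag @ (t**2))

    obj = objective(theta)
    w = None
    for _ in range(max_iter):
        mu = expit(A @ theta)
        grad = A.T @ (y - mu) - pen_diag * theta
        if np.abs(grad).max() < tol * max(1.0, np.abs(obj)):
            w = mu * (1 - mu)
            return theta, w, obj
        w = mu * (1 - mu)
        H = (A * w[:, None]).T @ A + np.diag(pen_diag)
        step = np.linalg.solve(H, grad)
        scale = 1.0
        for _ in range(40):
            cand = theta + scale * step
            cand_obj = objective(cand)
            if cand_obj >= obj - 1e-12:
                break
            scale *= 0.5
        theta = theta + scale * step
        obj = cand_obj
    raise AssociationError("penalized IRLS did not converge")


def fit_random_intercept_logistic(
    X: DesignMatrix | np.ndarray,
    y: Sequence[int],
    group_ids: Sequence,
    columns: Optional[list[str]] = None,
    sigma_max: float = 5.0,
) -> MixedLogisticFit:
    """Laplace-approximated ML fit of a random-intercept logistic model.

    ``X`` carries the fixed-effect columns (no intercept; one is added).
    With a single group the model degenerates: a plain logistic regression
    is fit instead with a logged warning and σ = 0.
    """
    if isinstance(X, DesignMatrix):
        columns = ["(intercept)"] + X.columns
        mat = X.matrix
    else:
        mat = np.asarray(X, dtype=float)
        columns = columns or ["(intercept)"] + [f"x{i}" for i in range(mat.shape[1])]
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise AssociationError("both outcome classes must be present")
    groups, ginv = np.unique(np.asarray(group_ids), return_inverse=True)
    G = len(groups)
    n, k = mat.shape
    Xa = np.column_stack([np.ones(n), mat])

    if G < 2:
        warnings.warn("single group: falling back to plain logistic regression")
        res = sm.GLM(y, Xa, family=sm.families.Binomial()).fit(tol=1e-10)
        se = np.asarray(res.bse)
        z = np.asarray(res.params) / se
        return MixedLogisticFit(
            columns=columns,
            coef=np.asarray(res.params),
            se=se,
            z=z,
            p=2 * norm.sf(np.abs(z)),
            sigma=0.0,
            loglik=float(res.llf),
            n_groups=1,
            converged=bool(res.converged),
        )

    Z = np.zeros((n, G))
    Z[np.arange(n), ginv] = 1.0
    A = np.column_stack([Xa, Z])

    def laplace_loglik(sigma: float) -> tuple[float, np.ndarray, np.ndarray]:
        pen = np.r_[np.zeros(k + 1), np.full(G, 1.0 / sigma**2)]
        theta, w, pen_ll = _pirls(A, y, pen)
        # per-group curvature of the conditional log-likelihood in u_g
        h = np.bincount(ginv, weights=w, minlength=G)
        # marginal ll ≈ ll(mode) − |u|²/2σ² − ½ Σ log(σ² h_g + 1)
        ll = pen_ll - 0.5 * float(np.sum(np.log(sigma**2 * h + 1.0)))
        return ll, theta, w

    def negative(log_sigma: float) -> float:
        return -laplace_loglik(float(np.exp(log_sigma)))[0]

    opt = minimize_scalar(
        negative, bounds=(np.log(1e-4), np.log(sigma_max)), method="bounded",
        options={"xatol": 1e-4},
    )
    sigma = float(np.exp(opt.x))
    ll_mixed = -float(opt.fun)

    # compare against the σ → 0 limit (plain logistic)
    glm = sm.GLM(y, Xa, family=sm.families.Binomial()).fit(tol=1e-10)
    if float(glm.llf) >= ll_mixed or sigma <= 2e-4:
        se = np.asarray(glm.bse)
        z = np.asarray(glm.params) / se
        return MixedLogisticFit(
            columns=columns,
            coef=np.asarray(glm.params),
            se=se,
            z=z,
            p=2 * norm.sf(np.abs(z)),
            sigma=0.0,
            loglik=float(glm.llf),
            n_groups=G,
            converged=bool(glm.converged),
        )

    ll, theta, w = laplace_loglik(sigma)
    pen = np.r_[np.zeros(k + 1), np.full(G, 1.0 / sigma**2)]
    H = (A * w[:, None]).T @ A + np.diag(pen)
    cov = np.linalg.inv(H)[: k + 1, : k + 1]
    coef = theta[: k + 1]
    se = np.sqrt(np.diag(cov))
    z = coef / se
    return MixedLogisticFit(
        columns=columns,
        coef=coef,
        se=se,
        z=z,
        p=2 * norm.sf(np.abs(z)),
        sigma=sigma,
        loglik=ll,
        n_groups=G,
        converged=True,
    )


# ---------------------------------------------------------------------------
# odds ratios and FDR
# ---------------------------------------------------------------------------


@dataclass
class AssociationResult:
    predictor: str
    level: int
    reference: int
    odds_ratio: float
    ci: tuple[float, float]
    p: float
    p_fdr: Optional[float] = None
    significant_fdr: Optional[bool] = None

    def to_dict(self) -> dict:
        def finite(x: float) -> Optional[float]:
            return float(x) if np.isfinite(x) else None

        return {
            "predictor": self.predictor,
            "level": self.level,
            "reference": self.reference,
            "odds_ratio": self.odds_ratio,
            "ci_low": finite(self.ci[0]),
            "ci_high": finite(self.ci[1]),
            "p": self.p,
            "p_fdr": self.p_fdr,
            "significant_fdr": self.significant_fdr,
        }


def odds_ratios(
    fit: MixedLogisticFit,
    terms: Sequence[tuple[str, int]],
    level: float = 0.95,
) -> list[AssociationResult]:
    """Exponentiate fixed-effect coefficients into OR (95% CI by default).
    ``terms`` aligns the non-intercept columns with (predictor, level)."""
    z = norm.ppf(0.5 + level / 2)
    results = []
    with np.errstate(over="ignore"):  # rare levels can have unbounded CIs
        for i, (pred, lev) in enumerate(terms, start=1):
            beta, se, p = fit.coef[i], fit.se[i], fit.p[i]
            results.append(
                AssociationResult(
                    predictor=pred,
                    level=lev,
                    reference=PREDICTOR_MAP[pred].reference,
                    odds_ratio=float(np.exp(beta)),
                    ci=(float(np.exp(beta - z * se)), float(np.exp(beta + z * se))),
                    p=float(p),
                )
            )
    return results


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise AssociationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def association_table(
    cohort: pd.DataFrame,
    outcome_label: str,
    group_col: str = "site_id",
    level: float = 0.95,
    fdr_alpha: float = 0.05,
) -> list[AssociationResult]:
    """One joint main-effects mixed model of all 11 predictors against the
    outcome; BH-FDR across the 21 term p-values of this table."""
    design = build_design_matrix(cohort, include_interactions=False)
    fit = fit_random_intercept_logistic(
        design, cohort[outcome_label].to_numpy(dtype=int), cohort[group_col]
    )
    results = odds_ratios(fit, design.main_terms, level=level)
    adjusted = fdr_adjust([r.p for r in results])
    for r, q in zip(results, adjusted):
        r.p_fdr = float(q)
        r.significant_fdr = bool(q < fdr_alpha)
    return results


def association_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])


def write_association_table(
    results: Sequence[AssociationResult], path: str | Path
) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps([r.to_dict() for r in results], indent=2))
    else:
        association_frame(results).to_csv(path, index=False)
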