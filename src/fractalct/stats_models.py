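"""Logistic model building: univariable screen, multivariable fit, VIF,
risk scoring and Youden cut-off selection.

Fitting is plain maximum likelihood via iteratively reweighted least squares
(IRLS) with Wald standard errors from the inverse observed information.
Separation is detected by diverging coefficients and reported through the
``converged`` flag rather than by raising.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "LogisticFit",
    "RiskScore",
    "CutoffResult",
    "fit_logistic",
    "fit_univariable",
    "select_variables",
    "fit_multivariable",
    "compute_vif",
    "predict_risk",
    "youden_cutoff",
]

MAX_ABS_COEF = 30.0  # |beta| beyond this is treated as separation
IRLS_TOL = 1e-8
IRLS_MAX_ITER = 100


@dataclass
class LogisticFit:
    variables: tuple[str, ...]
    coef: np.ndarray  # per-variable, excludes intercept
    se: np.ndarray
    intercept: float
    intercept_se: float
    converged: bool
    n_used: int
    loglik: float

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    def ci(self, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        z = norm.ppf(0.5 + level / 2)
        with np.errstate(over="ignore"):  # separated fits have huge SEs
            return np.exp(self.coef - z * self.se), np.exp(self.coef + z * self.se)

    @property
    def p_values(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(self.se > 0, self.coef / self.se, np.inf)
        return 2 * norm.sf(np.abs(z))

    def to_dict(self) -> dict:
        lo, hi = self.ci()
        return {
            "variables": list(self.variables),
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "coef": self.coef.tolist(),
            "se": self.se.tolist(),
            "odds_ratio": self.odds_ratios.tolist(),
            "or_ci_low": lo.tolist(),
            "or_ci_high": hi.tolist(),
            "p_value": self.p_values.tolist(),
            "converged": bool(self.converged),
            "n_used": int(self.n_used),
            "loglik": self.loglik,
        }


@dataclass
class RiskScore:
    patient_id: str
    linear_predictor: float
    probability: float
    model: str = ""


@dataclass
class CutoffResult:
    threshold: float
    youden_j: float
    sensitivity: float
    specificity: float


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable: -sum log(1 + exp(-(2y-1) eta))
    s = (2 * y - 1) * eta
    return float(-np.sum(np.logaddexp(0.0, -s)))


def fit_logistic(X: np.ndarray, y: np.ndarray, variables: tuple[str, ...]) -> LogisticFit:
    """IRLS maximum-likelihood logistic regression with an intercept column.

    ``X`` excludes the intercept; it is prepended internally.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    design = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(design) < p + 1:
        offenders = _rank_deficient_columns(design, variables)
        raise ValueError(f"design matrix is rank deficient; offending columns: {offenders}")
    beta = np.zeros(p + 1)
    converged = False
    # separation is judged on the scale of each predictor, not the intercept
    col_sd = np.concatenate([[0.0], design[:, 1:].std(axis=0)])
    for _ in range(IRLS_MAX_ITER):
        eta = design @ beta
        mu = expit(eta)
        if np.all(np.abs(y - mu) < 1e-6):  # perfect prediction: separation
            break
        w = np.clip(mu * (1 - mu), 1e-12, None)
        xtwx = design.T @ (design * w[:, None])
        grad = design.T @ (y - mu)
        try:
            delta = np.linalg.solve(xtwx, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + delta
        if np.max(np.abs(beta * col_sd)) > MAX_ABS_COEF:  # diverging slope
            break
        if np.max(np.abs(delta)) < IRLS_TOL:
            converged = True
            break
    eta = design @ beta
    mu = expit(eta)
    w = np.clip(mu * (1 - mu), 1e-12, None)
    xtwx = design.T @ (design * w[:, None])
    try:
        cov = np.linalg.inv(xtwx)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p + 1, np.nan)
    return LogisticFit(
        variables=tuple(variables),
        coef=beta[1:].copy(),
        se=se[1:].copy(),
        intercept=float(beta[0]),
        intercept_se=float(se[0]),
        converged=converged,
        n_used=n,
        loglik=_loglik(y, eta),
    )


def _rank_deficient_columns(design: np.ndarray, variables) -> list[str]:
    names = ["(intercept)"] + list(variables)
    bad = []
    kept = [0]
    for j in range(1, design.shape[1]):
        sub = design[:, kept + [j]]
        if np.linalg.matrix_rank(sub) < len(kept) + 1:
            bad.append(names[j])
        else:
            kept.append(j)
    return bad


def fit_univariable(table: pd.DataFrame, variable: str, outcome: str = "mvi") -> LogisticFit:
    """Single-predictor logistic fit of the outcome with Wald inference."""
    x = table[variable].to_numpy(dtype=float)
    y = table[outcome].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"predictor {variable!r} is constant")
    return fit_logistic(x[:, None], y, (variable,))


def select_variables(fits: list[LogisticFit], alpha: float = 0.05) -> list[str]:
    """Variables with Wald p strictly below alpha, in input order.

    Non-converged fits are excluded (their Wald statistics are meaningless
    under separation); a warning naming them is emitted.
    """
    import warnings

    selected = []
    for fit in fits:
        if len(fit.variables) != 1:
            raise ValueError("select_variables expects univariable fits")
        if not fit.converged:
            warnings.warn(
                f"excluding non-converged univariable fit for {fit.variables[0]!r}",
                stacklevel=2,
            )
            continue
        if fit.p_values[0] < alpha:
            selected.append(fit.variables[0])
    return selected


def fit_multivariable(
    table: pd.DataFrame, variables: list[str], outcome: str = "mvi"
) -> LogisticFit:
    """Joint maximum-likelihood logistic fit with per-variable Wald ORs."""
    if not variables:
        raise ValueError("at least one variable is required")
    X = table[list(variables)].to_numpy(dtype=float)
    y = table[outcome].to_numpy(dtype=float)
    return fit_logistic(X, y, tuple(variables))


def compute_vif(table: pd.DataFrame, variables: list[str]) -> dict[str, float]:
    """Variance inflation factors 1 / (1 - R^2_j) among the predictors."""
    if len(variables) < 2:
        raise ValueError("VIF requires at least 2 variables")
    X = table[list(variables)].to_numpy(dtype=float)
    n = X.shape[0]
    out: dict[str, float] = {}
    for j, name in enumerate(variables):
        yj = X[:, j]
        if np.ptp(yj) == 0:
            raise ValueError(f"variable {name!r} is constant")
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        ss_tot = float(np.sum((yj - yj.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
        out[name] = math.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def predict_risk(
    fit: LogisticFit, table: pd.DataFrame, model: str = "", allow_nonconverged: bool = False
) -> pd.DataFrame:
    """Per-patient linear predictor and logistic probability.

    A non-converged (separated) fit is refused unless ``allow_nonconverged``
    is set: its ranking is still usable but the probabilities saturate.
    """
    if not fit.converged and not allow_nonconverged:
        raise ValueError("cannot score with a non-converged fit")
    missing = [v for v in fit.variables if v not in table.columns]
    if missing:
        raise KeyError(f"table is missing model variables: {missing}")
    X = table[list(fit.variables)].to_numpy(dtype=float)
    eta = fit.intercept + X @ fit.coef
    ids = (
        table["patient_id"].astype(str).to_numpy()
        if "patient_id" in table.columns
        else np.array([str(i) for i in range(len(table))])
    )
    return pd.DataFrame(
        {
            "patient_id": ids,
            "linear_predictor": eta,
            "probability": expit(eta),
            "model": model or "+".join(fit.variables),
        }
    )


def youden_cutoff(scores, labels) -> CutoffResult:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Candidates are the midpoints between adjacent distinct score values
    (classification rule: ``score >= threshold`` is positive); ties in J are
    broken towards the lower threshold.  With all scores identical there is
    no informative threshold and J = 0 is returned at that score.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be 0/1")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    distinct = np.unique(scores)
    if len(distinct) == 1:
        return CutoffResult(
            threshold=float(distinct[0]), youden_j=0.0, sensitivity=1.0, specificity=0.0
        )
    # midpoints plus the two trivial rules (everyone / no-one positive),
    # so J never falls below 0 for anti-informative scores
    candidates = np.concatenate(
        [[distinct[0] - 1.0], (distinct[:-1] + distinct[1:]) / 2.0, [distinct[-1] + 1.0]]
    )
    best = None
    for t in candidates:
        pos = scores >= t
        sens = float((pos & (labels == 1)).sum()) / n_pos
        spec = float((~pos & (labels == 0)).sum()) / n_neg
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, t, sens, spec)
    return CutoffResult(
        threshold=float(best[1]),
        youden_j=float(best[0]),
        sensitivity=float(best[2]),
        specificity=float(best[3]),
    )
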