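"""Logistic model of amorphous solid dispersion formation in PVPVA.

Maps a molecule's R3m value (or its conformational distribution) to the
probability of forming a single-phase dispersion with PVPVA by melt-quench:

    logit P(Y) = beta0 + beta1 * R3m

The published coefficients are beta0 = -46.79, beta1 = 74.01, giving a 50%
classification boundary at R3m = -beta0/beta1 = 0.632. Earlier single-
conformation datasets were completely separated, where maximum likelihood
diverges; there the boundary is the midpoint between the highest failing and
lowest dispersing value (the legacy 0.65 rule).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats as _stats
from scipy.special import expit, logit as _logit

__all__ = [
    "LogisticModel",
    "FitDiagnostics",
    "SeparationWarning",
    "NotSeparatedError",
    "PUBLISHED_INTERCEPT",
    "PUBLISHED_SLOPE",
    "published_model",
    "predict_probability",
    "r3m_at_probability",
    "fit_logistic",
    "midpoint_boundary",
    "classify",
    "save_model",
    "load_model",
]

# Coefficients of the published melt-quench PVPVA model (logit scale).
PUBLISHED_INTERCEPT = -46.79
PUBLISHED_SLOPE = 74.01

# Legacy boundary from the completely separated single-conformation dataset.
LEGACY_BOUNDARY = 0.65


class SeparationWarning(UserWarning):
    """Complete separation detected during a logistic fit."""


class NotSeparatedError(ValueError):
    """Midpoint rule called on overlapping classes; fit a logistic model."""


@dataclass(frozen=True)
class FitDiagnostics:
    log_likelihood: float
    null_log_likelihood: float
    pseudo_r2: float          # McFadden: 1 - LL/LL0
    chi_square: float         # likelihood-ratio statistic, 1 df
    p_value: float
    n: int
    separated: bool
    iterations: int = 0
    se_intercept: float = float("nan")
    se_slope: float = float("nan")


@dataclass(frozen=True)
class LogisticModel:
    intercept: float
    slope: float
    fitted: bool = False
    diagnostics: FitDiagnostics | None = field(default=None, compare=False)

    @property
    def boundary(self) -> float:
        """R3m at 50% probability: -intercept/slope."""
        if self.slope == 0:
            raise ValueError("slope is zero; no classification boundary")
        return -self.intercept / self.slope


def published_model() -> LogisticModel:
    """The published model with printed (rounded) coefficients."""
    return LogisticModel(PUBLISHED_INTERCEPT, PUBLISHED_SLOPE, fitted=False)


def predict_probability(r3m_value, model: LogisticModel):
    """Dispersion probability P = expit(beta0 + beta1 * x); overflow-safe."""
    x = np.asarray(r3m_value, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite descriptor value")
    if not (math.isfinite(model.intercept) and math.isfinite(model.slope)):
        raise ValueError("model coefficients are not finite")
    p = expit(model.intercept + model.slope * x)
    return float(p) if np.isscalar(r3m_value) else p


def r3m_at_probability(p: float, model: LogisticModel) -> float:
    """Invert the model: the R3m value at which P(Y) equals ``p``."""
    if not 0.0 < p < 1.0:
        raise ValueError("probability must lie strictly between 0 and 1")
    if model.slope == 0:
        raise ValueError("slope is zero; the model cannot be inverted")
    return float((_logit(p) - model.intercept) / model.slope)


def _log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    # numerically stable Bernoulli log-likelihood: sum y*eta - log(1+e^eta)
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _is_perfectly_separated(x: np.ndarray, y: np.ndarray) -> bool:
    return float(x[y == 0].max()) < float(x[y == 1].min())


def fit_logistic(values, labels, max_iter: int = 100, tol: float = 1e-10) -> LogisticModel:
    """Maximum-likelihood univariate logistic fit by IRLS.

    Convergence when the log-likelihood change drops below ``tol``.
    Complete separation (perfect in-sample classification, or coefficient
    norm exceeding 1e3 during the iterations) flags the model
    ``separated=True`` with a :class:`SeparationWarning`, returning the
    coefficients from the last stable iteration; such data should use
    :func:`midpoint_boundary` instead. Non-convergence without separation
    raises.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("values and labels must be matching 1-D arrays")
    if x.size < 2:
        raise ValueError("need at least two observations")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("labels must be 0/1")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")

    design = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    eta = design @ beta
    ll = _log_likelihood(eta, y)
    separated = False
    last_stable = beta.copy()
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        mu = expit(eta)
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-12)
        # weighted least squares on the working response
        z = eta + (y - mu) / w
        wd = design * w[:, None]
        try:
            beta_new = np.linalg.solve(design.T @ wd, design.T @ (w * z))
        except np.linalg.LinAlgError:
            separated = True
            break
        if not np.all(np.isfinite(beta_new)) or np.linalg.norm(beta_new) > 1e3:
            separated = True
            break
        eta_new = design @ beta_new
        ll_new = _log_likelihood(eta_new, y)
        beta, eta = beta_new, eta_new
        last_stable = beta.copy()
        if abs(ll_new - ll) < tol:
            ll = ll_new
            break
        ll = ll_new
    else:
        raise RuntimeError(f"IRLS did not converge in {max_iter} iterations")

    if not separated and _is_perfectly_separated(x, y):
        separated = True
    if separated:
        warnings.warn(
            "complete separation detected; coefficients are from the last "
            "stable iteration — use midpoint_boundary for separated data",
            SeparationWarning,
            stacklevel=2,
        )
        beta = last_stable
        eta = design @ beta
        ll = _log_likelihood(eta, y)

    # diagnostics
    p_bar = y.mean()
    ll0 = float(
        y.sum() * math.log(p_bar) + (y.size - y.sum()) * math.log(1.0 - p_bar)
    )
    chi2 = 2.0 * (ll - ll0)
    p_value = float(_stats.chi2.sf(chi2, df=1))
    mu = expit(eta)
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    try:
        cov = np.linalg.inv(design.T @ (design * w[:, None]))
        se0, se1 = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    except np.linalg.LinAlgError:
        se0 = se1 = float("nan")
    diag = FitDiagnostics(
        log_likelihood=ll, null_log_likelihood=ll0,
        pseudo_r2=max(0.0, 1.0 - ll / ll0), chi_square=chi2, p_value=p_value,
        n=int(y.size), separated=separated, iterations=n_iter,
        se_intercept=se0, se_slope=se1,
    )
    return LogisticModel(float(beta[0]), float(beta[1]), fitted=True, diagnostics=diag)


def midpoint_boundary(values, labels) -> float:
    """Boundary for completely separated data.

    The midpoint between the highest value in the failure class and the
    lowest value in the success class — the rule behind the legacy 0.65
    boundary. Raises :class:`NotSeparatedError` on overlapping classes.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=float)
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    hi_fail = float(x[y == 0].max())
    lo_pass = float(x[y == 1].min())
    if hi_fail >= lo_pass:
        raise NotSeparatedError(
            "classes overlap (max failure value >= min success value); "
            "use fit_logistic instead of the midpoint rule"
        )
    return (hi_fail + lo_pass) / 2.0


def classify(
    r3m_value: float,
    model: LogisticModel | None = None,
    boundary_override: float | None = None,
) -> tuple[str, float | None]:
    """Classify a value as ``"disperses"`` / ``"fails"`` with its probability.

    The label is "disperses" iff the value lies strictly above the boundary
    (override when given, else the model's 50% point). The probability is
    attached whenever a model is supplied.
    """
    if model is None and boundary_override is None:
        raise ValueError("provide a model or a boundary_override")
    boundary = boundary_override if boundary_override is not None else model.boundary
    label = "disperses" if r3m_value > boundary else "fails"
    prob = predict_probability(r3m_value, model) if model is not None else None
    return label, prob


def save_model(model: LogisticModel, path: str | Path) -> Path:
    """Serialize a model (and diagnostics, if present) to JSON."""
    path = Path(path)
    payload: dict = {
        "intercept": model.intercept,
        "slope": model.slope,
        "fitted": model.fitted,
        "boundary": model.boundary,
    }
    if model.diagnostics is not None:
        payload["diagnostics"] = {
            k: (None if isinstance(v, float) and math.isnan(v) else v)
            for k, v in asdict(model.diagnostics).items()
        }
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def load_model(path: str | Path) -> LogisticModel:
    payload = json.loads(Path(path).read_text())
    diag = None
    if "diagnostics" in payload:
        d = {
            k: (float("nan") if v is None else v)
            for k, v in payload["diagnostics"].items()
        }
        diag = FitDiagnostics(**d)
    return LogisticModel(
        float(payload["intercept"]), float(payload["slope"]),
        fitted=bool(payload.get("fitted", False)), diagnostics=diag,
    )
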