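"""Weighted least-squares / MAP estimation for time-course models.

The objective is a Gaussian -2 log-likelihood with the residual-error
scale profiled out: observation i has variance ``sigma^2 / w_i`` with
weights from the observed values (equal, 1/y or 1/y^2), and the MLE
``sigma_hat^2 = (1/n) sum w_i (y_i - yhat_i)^2`` is substituted back:

    -2LL = n ln(2 pi sigma_hat^2) + sum ln(1/w_i) + n

Informative priors enter as squared standardised deviations (a Gaussian
MAP penalty), mirroring the penalised / Bayesian least-squares machinery
of classical PK/PD fitting software.

Model classes follow the statsmodels convention: build a model from
data, call :meth:`TimeCourseModel.fit`, get a
:class:`TimeCourseResults` carrying estimates, asymptotic standard
errors from the numerical curvature at the optimum, -2LL/AIC/SBIC,
weighted residuals, and a ``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "WEIGHT_SCHEMES",
    "Prior",
    "FitError",
    "weights",
    "neg2ll",
    "map_objective",
    "turnover_half_life",
    "half_life_from_lifespan",
    "TimeCourseModel",
    "TimeCourseResults",
    "read_observations",
    "write_observations",
]

WEIGHT_SCHEMES = ("equal", "inv_y", "inv_y2")

_OBS_COLUMNS = ["arm", "endpoint", "time_h", "value", "unit"]


class FitError(RuntimeError):
    """Optimizer failed to converge; the message carries the trace tail."""


@dataclass(frozen=True)
class Prior:
    """Gaussian prior on one free parameter (penalty ((theta-mean)/sd)^2)."""

    parameter: str
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("prior sd must be > 0")


def weights(y: np.ndarray, scheme: str) -> np.ndarray:
    """Per-observation weights from observed values."""
    y = np.asarray(y, dtype=float)
    if scheme == "equal":
        return np.ones_like(y)
    if scheme in ("inv_y", "inv_y2"):
        if np.any(y <= 0):
            raise ValueError(f"{scheme} weighting requires positive observations")
        return 1.0 / y if scheme == "inv_y" else 1.0 / y**2
    raise ValueError(f"unknown weighting scheme {scheme!r}")


def neg2ll(predictions: np.ndarray, observations: np.ndarray, scheme: str = "equal") -> float:
    """Profiled-variance Gaussian -2 log-likelihood.

    A perfect fit (sigma_hat^2 = 0) is floored at the smallest positive
    float, so the value is a large negative number rather than -inf.
    """
    yhat = np.asarray(predictions, dtype=float)
    y = np.asarray(observations, dtype=float)
    if yhat.shape != y.shape:
        raise ValueError("predictions and observations must be aligned")
    n = y.size
    w = weights(y, scheme)
    s2 = float(np.sum(w * (y - yhat) ** 2)) / n
    s2 = max(s2, np.finfo(float).tiny)
    return n * np.log(2.0 * np.pi * s2) + float(np.sum(np.log(1.0 / w))) + n


def map_objective(
    neg2ll_value: float, estimates: dict[str, float], priors: Sequence[Prior]
) -> float:
    """-2LL plus the Gaussian prior penalty sum ((theta-mu)/sd)^2."""
    penalty = 0.0
    for pr in priors:
        if pr.parameter not in estimates:
            raise KeyError(
                f"prior on {pr.parameter!r}, which is not a free parameter"
            )
        penalty += ((estimates[pr.parameter] - pr.mean) / pr.sd) ** 2
    return neg2ll_value + penalty


def turnover_half_life(kout: float) -> float:
    """Turnover half-life 0.693/kout, in hours."""
    if kout <= 0:
        raise ValueError(f"kout must be > 0, got {kout}")
    return 0.693 / kout


def half_life_from_lifespan(lifespan_days: float) -> float:
    """Turnover half-life (days) implied by a cell lifespan: 0.693 x lifespan."""
    if lifespan_days <= 0:
        raise ValueError("lifespan must be > 0")
    return 0.693 * lifespan_days


def read_observations(path) -> pd.DataFrame:
    """Observation CSV: columns arm, endpoint, time_h, value, unit."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _OBS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"observation file missing columns {missing}")
    return df


def write_observations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=_OBS_COLUMNS)


class TimeCourseModel:
    """Base class for models fitted to tabular time-course observations.

    Subclasses implement :meth:`predict`, mapping a full parameter dict
    to predictions aligned row-by-row with ``data``.

    Parameters
    ----------
    data : DataFrame with at least ``time_h`` and ``value`` columns.
    start : full parameter dict (free and fixed values).
    free : names of parameters to estimate; the rest stay fixed.
    priors : Gaussian priors on free parameters.
    weighting : 'equal', 'inv_y' or 'inv_y2' (weights from observed values).
    positive : names constrained positive (fitted on the log scale);
        defaults to every free parameter with a positive start value.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        start: dict[str, float],
        free: Sequence[str],
        priors: Sequence[Prior] = (),
        weighting: str = "equal",
        positive: Sequence[str] | None = None,
    ) -> None:
        if data.empty:
            raise ValueError("no observations")
        if weighting not in WEIGHT_SCHEMES:
            raise ValueError(f"unknown weighting scheme {weighting!r}")
        unknown = [p for p in free if p not in start]
        if unknown:
            raise ValueError(f"free parameters missing start values: {unknown}")
        for pr in priors:
            if pr.parameter not in free:
                raise ValueError(
                    f"prior on {pr.parameter!r}, which is not free"
                )
        self.data = data.reset_index(drop=True)
        self.start = dict(start)
        self.free = list(free)
        self.fixed = {k: v for k, v in start.items() if k not in free}
        self.priors = tuple(priors)
        self.weighting = weighting
        if positive is None:
            positive = [p for p in free if start[p] > 0]
        self.positive = set(positive) & set(free)
        self._y = self.data["value"].to_numpy(dtype=float)
        self._w = weights(self._y, weighting)

    # -- subclass API ---------------------------------------------------
    def predict(self, params: dict[str, float]) -> np.ndarray:
        raise NotImplementedError

    # -- objective ------------------------------------------------------
    def _full(self, theta: np.ndarray) -> dict[str, float]:
        full = dict(self.fixed)
        for name, v in zip(self.free, theta):
            full[name] = v
        return full

    def objective(self, theta: np.ndarray) -> float:
        full = self._full(theta)
        try:
            yhat = self.predict(full)
        except (ValueError, FloatingPointError):
            return 1e12
        if not np.all(np.isfinite(yhat)):
            return 1e12
        value = neg2ll(yhat, self._y, self.weighting)
        free_vals = {p: full[p] for p in self.free}
        return map_objective(value, free_vals, self.priors)

    def _to_internal(self, theta: np.ndarray) -> np.ndarray:
        z = np.array(theta, dtype=float)
        for i, name in enumerate(self.free):
            if name in self.positive:
                z[i] = np.log(z[i])
        return z

    def _from_internal(self, z: np.ndarray) -> np.ndarray:
        theta = np.array(z, dtype=float)
        for i, name in enumerate(self.free):
            if name in self.positive:
                theta[i] = np.exp(theta[i])
        return theta

    def fit(
        self,
        n_starts: int = 4,
        jitter: float = 0.2,
        seed: int = 0,
        maxiter: int = 400,
    ) -> "TimeCourseResults":
        """Minimise the MAP objective.

        Derivative-free simplex from ``n_starts`` jittered initial points
        (fixed seed), each followed by a gradient-based polish of the
        simplex optimum; positivity is enforced by log-transforming the
        parameters in ``positive``.  The simplex stage is capped at
        ``maxiter`` iterations — it only needs to land in the right
        basin, the polish supplies the precision.
        """
        rng = np.random.default_rng(seed)
        theta0 = np.array([self.start[p] for p in self.free], dtype=float)
        z0 = self._to_internal(theta0)
        trace: list[float] = []

        def f(z: np.ndarray) -> float:
            val = self.objective(self._from_internal(z))
            if not trace or val < trace[-1]:
                trace.append(val)
            return val

        best = None
        for k in range(n_starts):
            zk = z0 if k == 0 else z0 + rng.normal(0.0, jitter, size=z0.size)
            res = minimize(
                f, zk, method="Nelder-Mead",
                options={"maxiter": maxiter, "xatol": 1e-6, "fatol": 1e-8},
            )
            polished = minimize(f, res.x, method="L-BFGS-B")
            cand = polished if polished.fun <= res.fun else res
            if best is None or cand.fun < best.fun:
                best = cand
        polished = minimize(f, best.x, method="L-BFGS-B")
        if polished.fun <= best.fun:
            best = polished
        if not np.isfinite(best.fun) or best.fun >= 1e12:
            raise FitError(f"fit did not converge; trace tail {trace[-5:]}")
        theta_hat = self._from_internal(best.x)
        return self._results(theta_hat, float(best.fun), trace)

    # -- results assembly ----------------------------------------------
    def _results(self, theta: np.ndarray, fun: float, trace: list[float]):
        full = self._full(theta)
        yhat = self.predict(full)
        n = self._y.size
        p = len(self.free)
        value = neg2ll(yhat, self._y, self.weighting)
        estimates = {name: float(v) for name, v in zip(self.free, theta)}
        bse = self._standard_errors(theta)
        s2 = max(float(np.sum(self._w * (self._y - yhat) ** 2)) / n,
                 np.finfo(float).tiny)
        resid = np.sqrt(self._w) * (self._y - yhat) / np.sqrt(s2)
        return TimeCourseResults(
            model=self,
            params=estimates,
            bse=bse,
            fixed=dict(self.fixed),
            neg2ll=value,
            aic=value + 2 * p,
            sbic=value + p * np.log(n),
            objective=fun,
            nobs=n,
            resid=resid,
            fittedvalues=yhat,
            trace=np.asarray(trace),
        )

    def _standard_errors(self, theta: np.ndarray) -> dict[str, float]:
        """Asymptotic SEs: cov = 2 H^-1 with H the numerical Hessian of
        the -2 log-posterior at the optimum; NaN when the curvature is
        singular or non-positive."""
        p = theta.size
        h = np.maximum(np.abs(theta), 1e-8) * 1e-4
        H = np.empty((p, p))
        f0 = self.objective(theta)

        def fp(shift):
            return self.objective(theta + shift)

        for i in range(p):
            ei = np.zeros(p); ei[i] = h[i]
            H[i, i] = (fp(ei) - 2 * f0 + fp(-ei)) / h[i] ** 2
            for j in range(i + 1, p):
                ej = np.zeros(p); ej[j] = h[j]
                H[i, j] = H[j, i] = (
                    fp(ei + ej) - fp(ei - ej) - fp(-ei + ej) + fp(-ei - ej)
                ) / (4 * h[i] * h[j])
        try:
            cov = 2.0 * np.linalg.inv(H)
            se = np.sqrt(np.diag(cov))
            if not np.all(np.isfinite(se)):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            se = np.full(p, np.nan)
        return {name: float(s) for name, s in zip(self.free, se)}


@dataclass
class TimeCourseResults:
    """Fit results: estimates, SEs, information criteria, residuals.

    ``aic = -2LL + 2p`` and ``sbic = -2LL + p ln(n)`` with p free
    parameters and n observations; ``objective`` includes the prior
    penalty, ``neg2ll`` does not.
    """

    model: TimeCourseModel
    params: dict[str, float]
    bse: dict[str, float]
    fixed: dict[str, float]
    neg2ll: float
    aic: float
    sbic: float
    objective: float
    nobs: int
    resid: np.ndarray
    fittedvalues: np.ndarray
    trace: np.ndarray

    def summary(self) -> str:
        lines = [
            f"{type(self.model).__name__} fit",
            f"  n obs: {self.nobs}   weighting: {self.model.weighting}",
            f"  -2LL: {self.neg2ll:.3f}   AIC: {self.aic:.3f}   SBIC: {self.sbic:.3f}",
            "  parameter         estimate      std err",
        ]
        for name, v in self.params.items():
            se = self.bse.get(name, np.nan)
            se_s = f"{se:.4g}" if np.isfinite(se) else "n/a"
            lines.append(f"  {name:<16} {v:>10.5g}   {se_s:>10}")
        for name, v in self.fixed.items():
            lines.append(f"  {name:<16} {v:>10.5g}      (fixed)")
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        payload = {
            "params": self.params,
            "bse": self.bse,
            "fixed": self.fixed,
            "neg2ll": self.neg2ll,
            "aic": self.aic,
            "sbic": self.sbic,
            "nobs": self.nobs,
            "weighting": self.model.weighting,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text
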