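"""Logistic psychometric-function fitting and criterion thresholds.

Performance as a function of stimulus level ``x`` is modelled as

    p(x) = gamma + (1 - gamma - lambda) / (1 + exp(-beta * (x - alpha)))

with guess rate ``gamma`` fixed at the task's chance level (0.5 for the
single-interval orientation tasks, 0.25 for 4AFC stereo, 0 for the
appearance-based balance-point task), lapse rate ``lambda`` fixed by policy
(0 by default, optionally 0.02), and location/slope (``alpha``, ``beta``)
estimated by maximum likelihood.  The slope sign is free so that masking
data (performance falling with mask contrast) fit without relabelling.

Thresholds are read off the fitted function at a criterion probability:
75% correct for the single-interval tasks, 62.5% for 4AFC.  The balance
point is the 50% point of a full-range logistic fitted to the proportion of
left-eye-dominant reports versus interocular ratio (dB).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "PsychometricModel",
    "PsychometricFit",
    "BalancePointResult",
    "pf_evaluate",
    "fit_pf",
    "threshold_from_fit",
    "fit_balance_point",
]


@dataclass(frozen=True)
class PsychometricModel:
    """Location/slope/guess/lapse description of performance vs level."""

    alpha: float
    beta: float
    gamma: float = 0.5
    lapse: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.gamma < 1.0 - self.lapse <= 1.0):
            raise ValueError("need 0 <= gamma < 1 - lapse <= 1")

    def __call__(self, x):
        return pf_evaluate(self, x)


def pf_evaluate(model: PsychometricModel, x):
    """Probability of the indexed response at level(s) ``x``."""
    x = np.asarray(x, dtype=float)
    core = 1.0 / (1.0 + np.exp(-model.beta * (x - model.alpha)))
    p = model.gamma + (1.0 - model.gamma - model.lapse) * core
    return p if p.ndim else float(p)


def threshold_from_fit(model: PsychometricModel, criterion: float) -> float:
    """Level at which the fitted function crosses ``criterion``.

    Closed-form inverse of the logistic; for a zero lapse rate and a
    criterion at the midpoint of the response range this is ``alpha``.
    """
    lo, hi = model.gamma, 1.0 - model.lapse
    if not (lo < criterion < hi):
        raise ValueError(f"criterion {criterion} outside attainable range ({lo}, {hi})")
    if model.beta == 0:
        raise ValueError("zero slope: criterion level undefined")
    ratio = (1.0 - model.gamma - model.lapse) / (criterion - model.gamma) - 1.0
    return model.alpha - math.log(ratio) / model.beta


@dataclass(frozen=True)
class PsychometricFit:
    model: PsychometricModel
    converged: bool
    loglik: float
    n_trials: int


def _aggregate(levels, outcomes):
    levels = np.asarray(levels, dtype=float)
    outcomes = np.asarray(outcomes)
    if levels.shape != outcomes.shape:
        raise ValueError("levels and outcomes must have equal length")
    if not np.isin(outcomes, (0, 1, True, False)).all():
        raise ValueError("outcomes must be binary")
    outcomes = outcomes.astype(float)
    uniq, inv = np.unique(levels, return_inverse=True)
    n = np.bincount(inv).astype(float)
    k = np.bincount(inv, weights=outcomes)
    return uniq, n, k


def _nll(alpha, beta, gamma, lapse, x, n, k):
    p = gamma + (1.0 - gamma - lapse) / (1.0 + np.exp(-beta * (x - alpha)))
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return -float(np.sum(k * np.log(p) + (n - k) * np.log(1.0 - p)))


def _nll_grad(theta, gamma, lapse, x, n, k):
    """Negative log-likelihood and its gradient wrt (alpha, beta)."""
    alpha, beta = theta
    rng_ = 1.0 - gamma - lapse
    with np.errstate(over="ignore"):
        s = 1.0 / (1.0 + np.exp(-beta * (x - alpha)))
    p = np.clip(gamma + rng_ * s, 1e-12, 1.0 - 1e-12)
    nll = -float(np.sum(k * np.log(p) + (n - k) * np.log(1.0 - p)))
    w = (k / p - (n - k) / (1.0 - p)) * rng_ * s * (1.0 - s)
    return nll, np.array([float(np.sum(w) * beta), -float(np.sum(w * (x - alpha)))])


def fit_pf(
    levels,
    outcomes,
    guess: float = 0.5,
    lapse: float = 0.0,
    slope_sign: int | None = None,
) -> PsychometricFit:
    """Maximum-likelihood logistic fit with fixed guess and lapse rates.

    ``slope_sign`` may force the slope direction (+1 performance improves
    with level, -1 degrades); by default both directions are tried.  Data
    showing no variation in outcome (all correct / all incorrect) are
    flagged as non-converged rather than silently extrapolated.
    """
    x, n, k = _aggregate(levels, outcomes)
    n_trials = int(n.sum())
    if len(x) < 2 or k.sum() == 0 or k.sum() == n.sum():
        nan_model = PsychometricModel(alpha=math.nan, beta=1.0, gamma=guess, lapse=lapse)
        return PsychometricFit(model=nan_model, converged=False, loglik=math.nan,
                               n_trials=n_trials)

    span = max(x.max() - x.min(), 1e-6)
    signs = (1.0, -1.0) if slope_sign is None else (float(slope_sign),)

    # coarse grid scan for robust starts, then gradient refinement
    alpha_grid = np.linspace(x.min() - 0.25 * span, x.max() + 0.25 * span, 15)
    beta_grid = np.array([s * c / span for s in signs for c in (0.5, 2.0, 8.0)])
    with np.errstate(over="ignore"):
        core = 1.0 / (1.0 + np.exp(
            -beta_grid[:, None, None] * (x[None, None, :] - alpha_grid[None, :, None])
        ))
    pg = np.clip(guess + (1.0 - guess - lapse) * core, 1e-12, 1.0 - 1e-12)
    nll_grid = -np.sum(k * np.log(pg) + (n - k) * np.log(1.0 - pg), axis=2)
    starts = [
        (float(alpha_grid[int(np.argmin(nll_grid[i]))]), float(b0))
        for i, b0 in enumerate(beta_grid)
    ]

    best = None
    for a0, b0 in starts:
        res = optimize.minimize(
            _nll_grad,
            np.array([a0, b0]),
            args=(guess, lapse, x, n, k),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 300},
        )
        if best is None or res.fun < best.fun:
            best = res
    model = PsychometricModel(alpha=float(best.x[0]), beta=float(best.x[1]),
                              gamma=guess, lapse=lapse)
    # a location estimate far outside the sampled range signals separation
    margin = 3.0 * span
    inside = x.min() - margin <= best.x[0] <= x.max() + margin
    return PsychometricFit(
        model=model,
        converged=math.isfinite(best.fun) and math.isfinite(best.x[0]) and inside,
        loglik=-float(best.fun),
        n_trials=n_trials,
    )


@dataclass(frozen=True)
class BalancePointResult:
    """Fitted balance point (dB) with slope and fit diagnostics."""

    bp: float
    slope: float
    loglik: float
    converged: bool


def fit_balance_point(ratio_db, left_dominant) -> BalancePointResult:
    """Balance point from binocular-combination data.

    ``ratio_db`` is the interocular contrast ratio (left/right) in dB and
    ``left_dominant`` the binary report that the fused percept followed the
    left eye's tilt.  A full-range logistic (gamma = lambda = 0) is fitted;
    the balance point is its 50% midpoint, i.e. the fitted ``alpha``.
    """
    fit = fit_pf(ratio_db, left_dominant, guess=0.0, lapse=0.0, slope_sign=+1)
    return BalancePointResult(
        bp=fit.model.alpha,
        slope=fit.model.beta,
        loglik=fit.loglik,
        converged=fit.converged,
    )
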