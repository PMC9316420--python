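"""Synthetic right-censored survival data with known ground truth.

Event times are drawn from proportional-hazards families with closed-form
survival ``S(t | x) = exp(-H_0(t) exp(eta(x)))`` (exponential, Weibull, or
piecewise-constant baseline hazard), or natively in discrete time from
specified per-interval hazards.  Censoring times are drawn independently of
the event times, with the censoring-distribution parameter calibrated by
root-finding so the expected censored proportion hits a requested target.
The generator retains the uncensored event times and exposes the true
survival function and true per-interval discrete hazards for any grid, so
model estimates can be checked against their exact estimands.

Default conditions mirror a mid-sized clinical prognosis study: 1000
subjects, five baseline covariates (three standard-normal, two balanced
binary) with moderate effects on the log-hazard scale, a Weibull baseline
with gently increasing hazard, and 50% independent uniform censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .data import SurvivalData
from .person_period import IntervalGrid

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate",
    "true_discrete_hazards",
    "threshold_effect",
]

_DEFAULT_BETA = (0.5, -0.5, 0.25, 0.5, -0.25)


def threshold_effect(column: int = 0, threshold: float = 0.0,
                     effect: float = 1.0) -> Callable[[np.ndarray], np.ndarray]:
    """Nonlinear scenario: a step effect ``effect * I(x[column] > threshold)``.

    Invisible to a linear model of the raw covariate, so flexible
    classifiers should beat the linear-logit hazard model on data generated
    with it.
    """
    def f(x: np.ndarray) -> np.ndarray:
        return effect * (x[:, column] > threshold)
    return f


@dataclass
class SimulationConfig:
    """Generator settings.

    Parameters
    ----------
    n
        Number of subjects.
    n_normal, n_binary
        Independent standard-normal and Bernoulli(0.5) covariates.
    family
        ``exponential`` | ``weibull_ph`` | ``piecewise_constant_hazard`` |
        ``discrete_native``.
    beta
        Log-hazard-scale covariate effects (logit scale for
        ``discrete_native``); truncated/zero-padded to the covariate count.
    nonlinear
        Optional extra term added to the linear predictor, as a function of
        the covariate matrix (see :func:`threshold_effect`).
    rate, shape, scale, breakpoints, rates
        Baseline parameters: exponential rate; Weibull shape/scale with
        ``H_0(t) = (t/scale)^shape``; piecewise-constant hazard
        ``rates[k]`` on ``[breakpoints[k], breakpoints[k+1])``.
    cut_points, baseline_hazards
        Grid and per-interval baseline hazards for ``discrete_native``.
    censoring_rate, censoring_family
        Target censored proportion and the censoring-time family
        (``uniform`` on (0, b), ``exponential``, or ``administrative`` at a
        fixed time); the family parameter is calibrated to the target.
    """

    n: int = 1000
    n_normal: int = 3
    n_binary: int = 2
    family: str = "weibull_ph"
    beta: tuple = _DEFAULT_BETA
    nonlinear: Callable[[np.ndarray], np.ndarray] | None = None
    rate: float = 0.1
    shape: float = 1.5
    scale: float = 8.0
    breakpoints: tuple = (0.0, 2.0, 5.0)
    rates: tuple = (0.05, 0.1, 0.2)
    cut_points: tuple | None = None
    baseline_hazards: tuple | None = None
    censoring_rate: float = 0.5
    censoring_family: str = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")
        if self.family not in ("exponential", "weibull_ph",
                               "piecewise_constant_hazard", "discrete_native"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.censoring_family not in ("uniform", "exponential",
                                         "administrative"):
            raise ValueError(f"unknown censoring family "
                             f"{self.censoring_family!r}")
        if self.family == "discrete_native":
            if self.cut_points is None or self.baseline_hazards is None:
                raise ValueError("discrete_native requires cut_points and "
                                 "baseline_hazards")
            if len(self.baseline_hazards) != len(self.cut_points) - 1:
                raise ValueError("need one baseline hazard per interval")

    @property
    def n_covariates(self) -> int:
        return self.n_normal + self.n_binary

    def effective_beta(self) -> np.ndarray:
        b = np.zeros(self.n_covariates)
        vals = np.asarray(self.beta, dtype=float)[: self.n_covariates]
        b[: vals.shape[0]] = vals
        return b


# -- baseline cumulative hazards and inverses -------------------------------


def _cum_hazard(config: SimulationConfig, t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if config.family == "exponential":
        return config.rate * t
    if config.family == "weibull_ph":
        return (t / config.scale) ** config.shape
    if config.family == "piecewise_constant_hazard":
        bp = np.asarray(config.breakpoints, dtype=float)
        r = np.asarray(config.rates, dtype=float)
        seg_end = np.concatenate([bp[1:], [np.inf]])
        overlap = np.clip(t[..., None], bp, seg_end) - bp
        return np.sum(r * overlap, axis=-1)
    raise ValueError(config.family)


def _inv_cum_hazard(config: SimulationConfig, u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    if config.family == "exponential":
        return u / config.rate
    if config.family == "weibull_ph":
        return config.scale * u ** (1.0 / config.shape)
    if config.family == "piecewise_constant_hazard":
        bp = np.asarray(config.breakpoints, dtype=float)
        r = np.asarray(config.rates, dtype=float)
        cum_at_bp = _cum_hazard(config, bp)
        seg = np.clip(np.searchsorted(cum_at_bp, u, side="right") - 1,
                      0, bp.shape[0] - 1)
        return bp[seg] + (u - cum_at_bp[seg]) / r[seg]
    raise ValueError(config.family)


def _linear_predictor(config: SimulationConfig, X: np.ndarray) -> np.ndarray:
    eta = X @ config.effective_beta()
    if config.nonlinear is not None:
        eta = eta + np.asarray(config.nonlinear(X), dtype=float)
    return eta


@dataclass
class SimulatedDataset:
    """A generated dataset plus oracle access to its ground truth."""

    data: SurvivalData
    config: SimulationConfig
    true_event_times: np.ndarray = field(repr=False)
    censoring_times: np.ndarray = field(repr=False)

    def uncensored(self) -> SurvivalData:
        """The same subjects with their true event times fully observed."""
        return SurvivalData(time=self.true_event_times,
                            event=np.ones(len(self.true_event_times), dtype=int),
                            covariates=self.data.covariates,
                            subject_id=self.data.subject_id)

    def true_survival(self, t, X=None) -> np.ndarray:
        """Closed-form ``S(t | x)``, shape (n_subjects, n_times)."""
        X = self.data.covariates.to_numpy(dtype=float) if X is None \
            else np.asarray(X, dtype=float)
        t = np.atleast_1d(np.asarray(t, dtype=float))
        eta = _linear_predictor(self.config, X)
        if self.config.family == "discrete_native":
            grid = IntervalGrid(np.asarray(self.config.cut_points, dtype=float))
            lam = self._native_hazards(X)
            # right-continuous step: S(t) = prod over completed intervals
            completed = np.searchsorted(grid.upper, t, side="right")
            padded = np.concatenate(
                [np.ones((X.shape[0], 1)), np.cumprod(1 - lam, axis=1)], axis=1)
            return padded[:, completed]
        H0 = _cum_hazard(self.config, t)
        return np.exp(-np.outer(np.exp(eta), H0))

    def _native_hazards(self, X: np.ndarray) -> np.ndarray:
        base = logit(np.asarray(self.config.baseline_hazards, dtype=float))
        eta = _linear_predictor(self.config, X)
        return expit(base[None, :] + eta[:, None])

    def true_discrete_hazards(self, grid: IntervalGrid, X=None) -> np.ndarray:
        """True per-interval hazards ``lambda_j(x)`` implied by ``S``.

        ``lambda_j(x) = [S(t_{j-1}|x) - S(t_j|x)] / S(t_{j-1}|x)`` — the
        exact discrete-time estimand that a hazard model fitted on this
        generator's data targets.
        """
        X = self.data.covariates.to_numpy(dtype=float) if X is None \
            else np.asarray(X, dtype=float)
        if self.config.family == "discrete_native":
            native = IntervalGrid(np.asarray(self.config.cut_points, dtype=float))
            if np.array_equal(native.cut_points, grid.cut_points):
                return self._native_hazards(X)
        S = np.column_stack([
            np.ones(X.shape[0]),
            self.true_survival(grid.upper, X),
        ])
        S_lo, S_hi = S[:, :-1], S[:, 1:]
        if np.any(S_lo <= 0):
            raise ValueError("survival reaches 0 inside the grid; hazards "
                             "are undefined there")
        return (S_lo - S_hi) / S_lo


def true_discrete_hazards(dataset: SimulatedDataset, grid: IntervalGrid,
                          covariates=None) -> np.ndarray:
    """Operation form of :meth:`SimulatedDataset.true_discrete_hazards`."""
    return dataset.true_discrete_hazards(grid, covariates)


# -- censoring calibration ---------------------------------------------------


def _calibrate_censoring(config: SimulationConfig, T: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    """Draw censoring times whose expected censored fraction hits the target.

    Given the realized event times, the probability that an independent
    censoring time undercuts each is analytic in the family parameter;
    ``brentq`` solves for the parameter matching the mean to the target.
    """
    q = config.censoring_rate
    n = T.shape[0]
    if q == 0:
        return np.full(n, np.inf)
    if config.censoring_family == "administrative":
        c = np.quantile(T, 1 - q)
        if c <= 0:
            raise ValueError("administrative censoring target unattainable: "
                             "cut time would be nonpositive")
        return np.full(n, c)
    if config.censoring_family == "uniform":
        def censored_frac(b):  # P(C < T) = min(T/b, 1)
            return np.mean(np.minimum(T / b, 1.0)) - q
        lo, hi = 1e-9, 1e9 * max(T.max(), 1.0)
        if censored_frac(hi) > 0:
            raise ValueError("uniform censoring target unattainable")
        b = brentq(censored_frac, lo, hi)
        return rng.uniform(0, b, size=n)
    # exponential
    def censored_frac(theta):  # P(C < T) = 1 - exp(-theta T)
        return np.mean(-np.expm1(-theta * T)) - q
    lo, hi = 1e-12, 1e12
    if censored_frac(hi) < 0:
        raise ValueError("exponential censoring target unattainable")
    theta = brentq(censored_frac, lo, hi)
    return rng.exponential(1.0 / theta, size=n)


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Generate a dataset under ``config``; fully reproducible by seed."""
    rng = np.random.default_rng(config.seed)
    parts = []
    if config.n_normal:
        parts.append(rng.standard_normal((config.n, config.n_normal)))
    if config.n_binary:
        parts.append(rng.binomial(1, 0.5, (config.n, config.n_binary))
                     .astype(float))
    X = np.column_stack(parts) if parts else np.empty((config.n, 0))
    eta = _linear_predictor(config, X)

    if config.family == "discrete_native":
        grid = IntervalGrid(np.asarray(config.cut_points, dtype=float))
        base = logit(np.asarray(config.baseline_hazards, dtype=float))
        lam = expit(base[None, :] + eta[:, None])
        # sequential Bernoulli trials over intervals; survivors of all J
        # land just beyond the horizon (administratively censored later)
        u = rng.uniform(size=(config.n, grid.n_intervals))
        fails = u < lam
        first = np.argmax(fails, axis=1)
        any_fail = fails.any(axis=1)
        T = np.where(any_fail, grid.upper[first], grid.horizon * (1 + 1e-9))
    else:
        u = rng.uniform(size=config.n)
        T = _inv_cum_hazard(config, -np.log(u) / np.exp(eta))

    C = _calibrate_censoring(config, T, rng)
    time = np.minimum(T, C)
    event = (T <= C).astype(int)
    names = [f"x{k + 1}" for k in range(config.n_covariates)]
    data = SurvivalData(time=time, event=event,
                        covariates=pd.DataFrame(X, columns=names))
    return SimulatedDataset(data=data, config=config, true_event_times=T,
                            censoring_times=C)
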