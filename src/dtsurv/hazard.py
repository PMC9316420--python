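"""Discrete-time hazard models and survival-curve composition.

The discrete-time hazard ``lambda_j(x)`` is the conditional probability of
the event in interval ``A_j = (t_{j-1}, t_j]`` given survival to ``t_{j-1}``.
On a person-period table the survival likelihood factorises into independent
Bernoulli contributions, one per row, so the hazard can be estimated with

* a parametric link model ``g(lambda_j | x) = alpha_j + beta x`` — the
  continuation-ratio model for the logit link, the grouped proportional
  hazards model for the complementary log-log link — fitted by maximum
  likelihood through a binomial GLM; or
* any binary classifier exposing ``fit`` / ``predict_probability``, fitted
  to the row-level event indicator with the interval identity as an extra
  categorical feature.

Predicted survival is composed by the product rule
``S(t | x) = prod_{j: t_j <= t} (1 - lambda_j(x))``, a right-continuous
step function on the grid.

:class:`DiscreteTimeHazardModel` / :class:`DiscreteTimeHazardResults` are
the model/results pair; :func:`fit_link_model` and
:func:`fit_classifier_model` fit directly from a person-period table.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import clone as sk_clone
from statsmodels.genmod.families import Binomial, links
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .data import SurvivalData
from .person_period import (CensoringRule, IntervalGrid, PersonPeriodTable,
                            expand_for_prediction, expand_train,
                            make_quantile_grid)

__all__ = [
    "LINKS",
    "ClassifierContract",
    "SklearnClassifier",
    "DiscreteTimeHazardModel",
    "DiscreteTimeHazardResults",
    "SurvivalCurves",
    "fit_link_model",
    "fit_classifier_model",
    "predict_hazards",
    "predict_survival",
    "log_likelihood",
]

#: Hazard-probability clipping for survival composition — keeps a single
#: overconfident classifier prediction from collapsing S to exactly 0.
HAZARD_EPS = 1e-6
#: Probability clipping for likelihood evaluation.
LIK_EPS = 1e-12

LINKS = {
    "logit": links.Logit,
    "cloglog": links.CLogLog,
    "probit": links.Probit,
    "loglog": links.LogLog,
    "log": links.Log,
}


@runtime_checkable
class ClassifierContract(Protocol):
    """Minimal contract a pluggable binary classifier must satisfy."""

    def fit(self, features: np.ndarray, labels: np.ndarray) -> "ClassifierContract": ...

    def predict_probability(self, features: np.ndarray) -> np.ndarray: ...


class SklearnClassifier:
    """Adapt a scikit-learn classifier to the hazard-model contract.

    Parameters
    ----------
    estimator
        Any scikit-learn classifier with ``predict_proba``.
    param_space
        Optional hyperparameter search space ``{name: candidate values}``,
        consumed by the tuning module.
    seed
        Threaded into ``random_state`` when the estimator accepts one, so a
        fixed seed reproduces identical hazards.
    """

    def __init__(self, estimator, param_space: dict | None = None,
                 seed: int | None = None):
        self.estimator = estimator
        self.param_space = dict(param_space or {})
        self.seed = seed
        self.fitted_ = None

    def with_params(self, seed: int | None = None, **params) -> "SklearnClassifier":
        est = sk_clone(self.estimator)
        if params:
            est.set_params(**params)
        return SklearnClassifier(est, self.param_space,
                                 seed if seed is not None else self.seed)

    def fit(self, features, labels):
        est = sk_clone(self.estimator)
        if self.seed is not None and "random_state" in est.get_params():
            est.set_params(random_state=int(self.seed))
        try:
            est.fit(np.asarray(features), np.asarray(labels))
        except Exception as exc:  # surface classifier failures with context
            raise RuntimeError(
                f"classifier {type(est).__name__} failed during fit: {exc}"
            ) from exc
        self.fitted_ = est
        return self

    def predict_probability(self, features):
        if self.fitted_ is None:
            raise RuntimeError("classifier is not fitted")
        proba = self.fitted_.predict_proba(np.asarray(features))
        pos = list(self.fitted_.classes_).index(1)
        p = np.asarray(proba)[:, pos]
        if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
            raise ValueError("classifier returned probabilities outside [0, 1]")
        return p


# ---------------------------------------------------------------------------
# preprocessing helpers


@dataclass(frozen=True)
class _Scaler:
    """Per-covariate centering/scaling constants (possibly the identity)."""

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def identity(cls, k: int) -> "_Scaler":
        return cls(np.zeros(k), np.ones(k))

    @classmethod
    def from_table(cls, table: PersonPeriodTable) -> "_Scaler":
        # Constants come from unique subjects, not rows: covariates are
        # time-fixed, and row-level moments would weight subjects by their
        # follow-up length.
        unique = table.table.drop_duplicates("subject_id")
        x = unique[table.covariate_names].to_numpy(dtype=float)
        mean = x.mean(axis=0) if x.size else np.zeros(x.shape[1])
        scale = x.std(axis=0, ddof=0) if x.size else np.ones(x.shape[1])
        scale = np.where(scale > 0, scale, 1.0)
        return cls(mean, scale)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean) / self.scale


def _features(table: PersonPeriodTable, covariate_names: list[str],
              scaler: _Scaler, encoding: str, J: int) -> np.ndarray:
    """Design matrix: interval encoding columns then (scaled) covariates."""
    interval = table.table["interval"].to_numpy()
    x = scaler.transform(table.table[covariate_names].to_numpy(dtype=float))
    if encoding == "onehot":
        dummies = np.zeros((len(interval), J))
        dummies[np.arange(len(interval)), interval - 1] = 1.0
        return np.column_stack([dummies, x])
    if encoding == "ordinal":
        return np.column_stack([interval.astype(float), x])
    raise ValueError(f"unknown interval encoding {encoding!r}")


def _check_schema(covariates: pd.DataFrame, expected: list[str]) -> pd.DataFrame:
    covariates = pd.DataFrame(covariates)
    missing = [c for c in expected if c not in covariates.columns]
    if missing:
        raise ValueError(f"covariates are missing training columns: {missing}")
    return covariates[expected]


# ---------------------------------------------------------------------------
# results


class SurvivalCurves:
    """Per-subject discrete survival curves composed from hazards.

    ``S(t | x) = prod_{j: t_j <= t} (1 - lambda_j(x))`` — a right-continuous
    step function equal to 1 on ``[0, t_1)`` and stepping down at each cut
    point.  Event probabilities ``p(t) = 1 - S(t)`` are a derived view.
    """

    def __init__(self, grid: IntervalGrid, hazards: np.ndarray):
        hazards = np.atleast_2d(np.asarray(hazards, dtype=float))
        if hazards.shape[1] != grid.n_intervals:
            raise ValueError("hazard matrix width must equal the number of intervals")
        if np.any(hazards < 0) or np.any(hazards > 1):
            raise ValueError("hazards must lie in [0, 1]")
        self.grid = grid
        self.hazards = hazards

    @property
    def n_subjects(self) -> int:
        return self.hazards.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Grid cut points ``t_1..t_J`` at which the curve steps."""
        return self.grid.upper

    @property
    def survival(self) -> np.ndarray:
        """``S(t_j)`` for each subject at each cut point, shape (n, J)."""
        return np.cumprod(1.0 - self.hazards, axis=1)

    def evaluate(self, eval_times) -> np.ndarray:
        """Step-function evaluation ``S(t)``, shape (n, len(eval_times))."""
        t = np.atleast_1d(np.asarray(eval_times, dtype=float))
        if np.any(t < 0) or np.any(t > self.grid.horizon):
            raise ValueError("evaluation times must lie in [0, horizon]; "
                             "extrapolation beyond the horizon is refused")
        completed = np.searchsorted(self.grid.upper, t, side="right")
        padded = np.concatenate(
            [np.ones((self.n_subjects, 1)), self.survival], axis=1)
        return padded[:, completed]

    def event_probability(self, eval_times) -> np.ndarray:
        """``p(t) = 1 - S(t)``, the probability of the event by ``t``."""
        return 1.0 - self.evaluate(eval_times)


class DiscreteTimeHazardResults:
    """Fitted discrete-time hazard model.

    Carries everything needed to predict: the interval grid, preprocessing
    constants, the interval encoding, and either GLM coefficients
    (``params`` indexed by interval labels then covariates, with standard
    errors in ``bse``) or an opaque fitted classifier.
    """

    def __init__(self, *, grid: IntervalGrid, covariate_names: list[str],
                 scaler: _Scaler, encoding: str, link: str | None = None,
                 glm_results=None, classifier=None,
                 rule: CensoringRule | None = None):
        self.grid = grid
        self.covariate_names = list(covariate_names)
        self.scaler = scaler
        self.encoding = encoding
        self.link = link
        self.glm_results = glm_results
        self.classifier = classifier
        self.rule = rule
        self.model: "DiscreteTimeHazardModel | None" = None

    # -- parametric accessors ---------------------------------------------
    @property
    def is_parametric(self) -> bool:
        return self.glm_results is not None

    def _param_index(self) -> list[str]:
        return self.grid.labels() + self.covariate_names

    @property
    def params(self) -> pd.Series:
        if not self.is_parametric:
            raise AttributeError("coefficients are only defined for link models")
        return pd.Series(self.glm_results.params, index=self._param_index())

    @property
    def bse(self) -> pd.Series:
        if not self.is_parametric:
            raise AttributeError("standard errors are only defined for link models")
        return pd.Series(self.glm_results.bse, index=self._param_index())

    @property
    def alpha(self) -> pd.Series:
        """Interval-specific intercepts (baseline hazard on the link scale)."""
        return self.params.iloc[: self.grid.n_intervals]

    @property
    def beta(self) -> pd.Series:
        """Covariate effects on the link scale."""
        return self.params.iloc[self.grid.n_intervals:]

    # -- prediction --------------------------------------------------------
    def predict_hazards(self, covariates) -> np.ndarray:
        """Per-interval conditional failure probabilities, shape (n, J).

        Applies the stored preprocessing, expands each subject to one row
        per interval, and evaluates the fitted predictor; outputs are
        clipped to ``(1e-6, 1 - 1e-6)``.
        """
        covariates = _check_schema(covariates, self.covariate_names)
        table = expand_for_prediction(covariates, self.grid)
        X = _features(table, self.covariate_names, self.scaler,
                      self.encoding, self.grid.n_intervals)
        if self.is_parametric:
            p = self.glm_results.predict(X)
        else:
            p = self.classifier.predict_probability(X)
        p = np.clip(np.asarray(p, dtype=float), HAZARD_EPS, 1.0 - HAZARD_EPS)
        return p.reshape(len(covariates), self.grid.n_intervals)

    def predict_survival(self, covariates, eval_times=None):
        """Survival curves per subject; optionally evaluated at times.

        Returns :class:`SurvivalCurves` when ``eval_times`` is None, else
        the (n, len(eval_times)) matrix ``S(t)``.
        """
        curves = SurvivalCurves(self.grid, self.predict_hazards(covariates))
        if eval_times is None:
            return curves
        return curves.evaluate(eval_times)

    def predict_event_probability(self, covariates, eval_times) -> np.ndarray:
        return 1.0 - self.predict_survival(covariates, eval_times)

    # -- likelihood --------------------------------------------------------
    def log_likelihood(self, table: PersonPeriodTable) -> float:
        """Binomial log-likelihood of a person-period table under the fit.

        ``sum_rows d log(lambda) + (1 - d) log(1 - lambda)`` — identical to
        the subject-level discrete survival likelihood.
        """
        X = _features(table, self.covariate_names, self.scaler,
                      self.encoding, self.grid.n_intervals)
        if self.is_parametric:
            lam = np.asarray(self.glm_results.predict(X), dtype=float)
        else:
            lam = np.asarray(self.classifier.predict_probability(X), dtype=float)
        n_clipped = int(np.sum((lam <= 0) | (lam >= 1)))
        if n_clipped:
            warnings.warn(f"{n_clipped} hazard value(s) clipped to "
                          f"({LIK_EPS}, 1-{LIK_EPS}) in the likelihood",
                          UserWarning, stacklevel=2)
        lam = np.clip(lam, LIK_EPS, 1.0 - LIK_EPS)
        d = table.table["d"].to_numpy(dtype=float)
        return float(np.sum(d * np.log(lam) + (1 - d) * np.log1p(-lam)))

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        lines = ["Discrete-time hazard model",
                 "=" * 40,
                 f"Intervals (J):      {self.grid.n_intervals}",
                 f"Horizon:            {self.grid.horizon:g}",
                 f"Censoring rule:     {self.rule.value if self.rule else '-'}",
                 f"Interval encoding:  {self.encoding}"]
        if self.is_parametric:
            lines.append(f"Link:               {self.link}")
            lines.append("-" * 40)
            tab = pd.DataFrame({"coef": self.params, "std err": self.bse})
            lines.append(tab.to_string(float_format=lambda v: f"{v: .4f}"))
        else:
            lines.append(f"Classifier:         "
                         f"{type(self.classifier.fitted_).__name__}")
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        """Serialize the fitted model (grid, preprocessing, predictor)."""
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "DiscreteTimeHazardResults":
        with open(path, "rb") as fh:
            obj = pickle.load(fh)
        if not isinstance(obj, DiscreteTimeHazardResults):
            raise TypeError("file does not contain a fitted hazard model")
        return obj


# ---------------------------------------------------------------------------
# table-level fitting operations


def _require_all_intervals(table: PersonPeriodTable) -> None:
    J = table.grid.n_intervals
    present = np.unique(table.table["interval"].to_numpy())
    missing = sorted(set(range(1, J + 1)) - set(present.tolist()))
    if missing:
        raise ValueError(
            f"interval(s) {missing} have no person-period rows; the "
            f"corresponding baseline hazards are not identifiable — "
            f"refit with fewer intervals")


def fit_link_model(table: PersonPeriodTable, link: str = "logit",
                   standardize: bool = False) -> DiscreteTimeHazardResults:
    """Maximum-likelihood fit of ``g(lambda_j | x) = alpha_j + beta x``.

    Fits a binomial GLM on the person-period rows with one dummy per
    interval (no global intercept, so ``alpha_j`` is each interval's
    baseline-hazard coefficient directly) plus linear covariate effects.
    ``link='logit'`` is the continuation-ratio model; ``'cloglog'`` the
    grouped proportional-hazards model.
    """
    if link not in LINKS:
        raise ValueError(f"unknown link {link!r}; choose from {sorted(LINKS)}")
    if table.n_rows == 0:
        raise ValueError("person-period table is empty")
    d = table.table["d"].to_numpy(dtype=float)
    if d.sum() == 0:
        raise ValueError("no events in the person-period table; nothing to fit")
    _require_all_intervals(table)
    scaler = (_Scaler.from_table(table) if standardize
              else _Scaler.identity(len(table.covariate_names)))
    X = _features(table, table.covariate_names, scaler, "onehot",
                  table.grid.n_intervals)
    glm = sm.GLM(d, X, family=Binomial(link=LINKS[link]()))
    try:
        with warnings.catch_warnings():
            # non-canonical binomial links trigger a domain warning only
            warnings.simplefilter("ignore")
            res = glm.fit(maxiter=200)
    except PerfectSeparationError as exc:
        raise RuntimeError(
            "hazard model did not converge: perfect separation in the "
            "person-period data (a covariate or interval fully determines "
            "the outcome)") from exc
    if not res.converged:
        raise RuntimeError(
            f"hazard model IRLS did not converge for link {link!r}; "
            f"final deviance {res.deviance:.4g}")
    # a diverging coefficient (|coef| far beyond any plausible link-scale
    # value) or an unusable standard error signals (quasi-)separation
    if np.any(~np.isfinite(res.bse)) or np.max(np.abs(res.params)) > 30:
        raise RuntimeError(
            "hazard model estimates diverged (complete or quasi-complete "
            "separation in the person-period data): a covariate or interval "
            "fully determines the outcome")
    return DiscreteTimeHazardResults(
        grid=table.grid, covariate_names=table.covariate_names,
        scaler=scaler, encoding="onehot", link=link, glm_results=res,
        rule=table.rule)


def fit_classifier_model(table: PersonPeriodTable,
                         classifier: ClassifierContract,
                         encoding: str = "onehot",
                         standardize: bool = True) -> DiscreteTimeHazardResults:
    """Fit a pluggable binary classifier as the hazard function.

    Covariates are standardized by training-set mean/sd (computed over
    unique subjects); the interval identity enters as one-hot dummies by
    default, or a single ordinal column for tree-based learners.
    """
    if table.n_rows == 0:
        raise ValueError("person-period table is empty")
    _require_all_intervals(table)
    scaler = (_Scaler.from_table(table) if standardize
              else _Scaler.identity(len(table.covariate_names)))
    X = _features(table, table.covariate_names, scaler, encoding,
                  table.grid.n_intervals)
    d = table.table["d"].to_numpy()
    classifier.fit(X, d)
    p = np.asarray(classifier.predict_probability(X), dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("classifier violates the probability contract")
    return DiscreteTimeHazardResults(
        grid=table.grid, covariate_names=table.covariate_names,
        scaler=scaler, encoding=encoding, classifier=classifier,
        rule=table.rule)


def predict_hazards(results: DiscreteTimeHazardResults, covariates) -> np.ndarray:
    """Operation form of :meth:`DiscreteTimeHazardResults.predict_hazards`."""
    return results.predict_hazards(covariates)


def predict_survival(results: DiscreteTimeHazardResults, covariates,
                     eval_times=None):
    """Operation form of :meth:`DiscreteTimeHazardResults.predict_survival`."""
    return results.predict_survival(covariates, eval_times)


def log_likelihood(results: DiscreteTimeHazardResults,
                   table: PersonPeriodTable) -> float:
    """Operation form of :meth:`DiscreteTimeHazardResults.log_likelihood`."""
    return results.log_likelihood(table)


# ---------------------------------------------------------------------------
# model class


class DiscreteTimeHazardModel:
    """Discrete-time survival model over subject-level data.

    Orchestrates the full pipeline: administrative censoring at the
    horizon, quantile interval grid, person-period expansion under the
    chosen censoring rule, and hazard fitting with either a parametric
    link model or a pluggable classifier.

    Parameters
    ----------
    data
        Subject-level right-censored records.
    horizon
        Prediction horizon ``w``; follow-up beyond it is administratively
        censored.
    n_intervals
        Requested number of intervals ``J``; interior cut points are event
        -time quantiles.  Ignored when an explicit ``grid`` is given.
    link, classifier
        Exactly one of: a link name (parametric model) or a
        :class:`ClassifierContract` object.
    censoring_rule
        How censored subjects contribute partial intervals.
    interval_encoding
        ``'onehot'`` (default) or ``'ordinal'`` — classifier models only.
    standardize
        Center/scale covariates by training moments; defaults to True for
        classifier models and False for link models (where raw-scale
        coefficients stay interpretable).

    Examples
    --------
    >>> model = DiscreteTimeHazardModel(data, horizon=5.0, n_intervals=10,
    ...                                 link="cloglog")
    >>> results = model.fit()
    >>> results.predict_survival(new_covariates, eval_times=[1.0, 3.0])
    """

    def __init__(self, data: SurvivalData, horizon: float,
                 n_intervals: int | None = None,
                 grid: IntervalGrid | None = None,
                 link: str | None = "logit",
                 classifier: ClassifierContract | None = None,
                 censoring_rule: CensoringRule | str = CensoringRule.OBSERVED_ANY,
                 interval_encoding: str = "onehot",
                 standardize: bool | None = None):
        if (link is None) == (classifier is None):
            raise ValueError("specify exactly one of link= or classifier=")
        if grid is None and n_intervals is None:
            raise ValueError("specify n_intervals or an explicit grid")
        if grid is not None and abs(grid.horizon - horizon) > 1e-12:
            raise ValueError("grid horizon must equal the model horizon")
        self.data = data
        self.horizon = float(horizon)
        self.n_intervals = n_intervals
        self.grid = grid
        self.link = link
        self.classifier = classifier
        self.censoring_rule = CensoringRule(censoring_rule)
        self.interval_encoding = interval_encoding
        self.standardize = standardize

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, horizon: float,
                       time_col: str = "time", event_col: str = "event",
                       covariate_cols=None, **kwargs) -> "DiscreteTimeHazardModel":
        """Build a model from a subject-level DataFrame."""
        if covariate_cols is None:
            covariate_cols = [c for c in df.columns
                              if c not in (time_col, event_col)]
        data = SurvivalData(time=df[time_col].to_numpy(dtype=float),
                            event=df[event_col].to_numpy(),
                            covariates=df[covariate_cols])
        return cls(data, horizon, **kwargs)

    def build_table(self) -> PersonPeriodTable:
        """Grid construction + person-period expansion (training layout)."""
        censored = self.data.administratively_censor(self.horizon)
        grid = self.grid if self.grid is not None else make_quantile_grid(
            censored, self.horizon, self.n_intervals)
        return expand_train(censored, grid, self.censoring_rule)

    def fit(self) -> DiscreteTimeHazardResults:
        table = self.build_table()
        if self.link is not None:
            std = bool(self.standardize) if self.standardize is not None else False
            results = fit_link_model(table, self.link, standardize=std)
        else:
            std = bool(self.standardize) if self.standardize is not None else True
            results = fit_classifier_model(table, self.classifier,
                                           self.interval_encoding,
                                           standardize=std)
        results.model = self
        return results
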