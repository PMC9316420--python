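"""Censoring-adjusted predictive-performance metrics.

Time-dependent discrimination and calibration metrics for survival
predictions, model-free: they consume only a matrix of predicted event
probabilities ``p_i(t) = 1 - S_i(t)``, so discrete-time, continuous-time or
external predictions are evaluated identically.

Censoring removes the outcome status of some subjects by time ``t``;
contributions are reweighted by the inverse of the Kaplan–Meier estimate of
the censoring survival function ``G(u) = Pr(C > u)`` (IPCW).  At a time
``t``:

* subjects still under observation (``T > t``) get weight ``1 / G(t)``;
* subjects with an observed event by ``t`` get weight ``1 / G(T-)`` (the
  left limit, so a subject's own censoring mass never enters its weight);
* subjects censored by ``t`` get weight 0.

The metrics are the cumulative/dynamic time-dependent AUC (cases are events
by ``t``, controls are event-free at ``t``), the time-dependent Brier score
``(1/n) sum_i W_i(t) (D_i(t) - p_i(t))^2``, its null-model scaling
``R^2(t) = 1 - BS(t)/BS_0(t)`` where the null predictor assigns everyone
the marginal Kaplan–Meier event probability, and the integrated Brier
score over ``[0, t*]`` against the weight function ``W(t) = t / t*``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .data import SurvivalData

__all__ = [
    "StepSurvivalEstimate",
    "PredictionMatrix",
    "MetricResult",
    "kaplan_meier",
    "ipcw_weights",
    "td_auc",
    "td_brier",
    "r_squared",
    "integrated_brier",
    "evaluate_predictions",
    "plot_prediction_error",
]


class UndefinedMetricError(ValueError):
    """A metric is requested where it is not identifiable (e.g., no cases)."""


@dataclass(frozen=True)
class StepSurvivalEstimate:
    """Right-continuous step survival function with left limits.

    ``jump_times`` are the sorted times at which the estimate changes;
    ``values[k]`` is the estimate just after ``jump_times[k]``.  Before the
    first jump the value is 1.
    """

    jump_times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        jt = np.asarray(self.jump_times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if jt.shape != v.shape or jt.ndim != 1:
            raise ValueError("jump_times and values must be 1-d and equal length")
        if np.any(np.diff(jt) < 0):
            raise ValueError("jump_times must be sorted")
        if np.any(v < 0) or np.any(v > 1) or np.any(np.diff(v) > 1e-12):
            raise ValueError("values must be a nonincreasing sequence in [0, 1]")
        object.__setattr__(self, "jump_times", jt)
        object.__setattr__(self, "values", v)

    def __call__(self, t) -> np.ndarray:
        """S(t), right-continuous."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.jump_times, t_arr, side="right")
        padded = np.concatenate([[1.0], self.values])
        out = padded[idx]
        return out if np.ndim(t) else float(out[0])

    def left_limit(self, t) -> np.ndarray:
        """S(t-), the value just before ``t``."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.jump_times, t_arr, side="left")
        padded = np.concatenate([[1.0], self.values])
        out = padded[idx]
        return out if np.ndim(t) else float(out[0])


def kaplan_meier(times, events, flip_events: bool = False) -> StepSurvivalEstimate:
    """Product-limit estimate of a survival function.

    With ``flip_events`` the event/censoring roles are exchanged, giving
    the Kaplan–Meier estimate of the censoring survival ``G(u) = Pr(C>u)``.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValueError("cannot estimate a survival function from no data")
    if flip_events:
        events = 1 - events
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_.iloc[:, 0]
    jt = sf.index.to_numpy(dtype=float)
    vals = sf.to_numpy(dtype=float)
    keep = jt > 0
    return StepSurvivalEstimate(jump_times=jt[keep], values=vals[keep])


def ipcw_weights(t: float, dataset: SurvivalData,
                 G: StepSurvivalEstimate | None = None) -> np.ndarray:
    """Inverse-probability-of-censoring weights at time ``t``.

    ``G`` defaults to the censoring Kaplan–Meier estimated on ``dataset``
    itself; pass a training-split estimate to override.
    """
    if G is None:
        G = kaplan_meier(dataset.time, dataset.event, flip_events=True)
    time, event = dataset.time, dataset.event
    w = np.zeros(dataset.n)

    at_risk = time > t
    if np.any(at_risk):
        g_t = G(t)
        if g_t <= 0:
            raise UndefinedMetricError(
                f"censoring survival G({t:g}) = 0; time {t:g} is beyond the "
                f"censoring support")
        w[at_risk] = 1.0 / g_t

    case = (time <= t) & (event == 1)
    if np.any(case):
        g_left = np.atleast_1d(G.left_limit(time[case]))
        bad = g_left <= 0
        if np.any(bad):
            t_bad = time[case][bad][0]
            raise UndefinedMetricError(
                f"censoring survival G({t_bad:g}-) = 0 for an event subject; "
                f"weights are undefined there")
        w[case] = 1.0 / g_left
    # censored by t: weight stays 0
    return w


def _event_status(t: float, dataset: SurvivalData) -> np.ndarray:
    """Observed event-by-t status ``D_i(t) = I(T_i <= t, delta_i = 1)``."""
    return ((dataset.time <= t) & (dataset.event == 1)).astype(float)


def td_auc(t: float, predictions, dataset: SurvivalData,
           weights: np.ndarray | None = None,
           G: StepSurvivalEstimate | None = None,
           tie_credit: float = 0.0) -> float:
    """IPCW cumulative/dynamic time-dependent AUC at ``t``.

    The weighted probability that a case's predicted event probability
    exceeds a control's, over all weighted case–control pairs.  Ties
    contribute ``tie_credit`` (0 by default, matching the strict
    inequality; 0.5 gives the usual half-credit convention).

    ``predictions`` is the vector ``p_i(t)`` of event probabilities by ``t``.
    """
    p = np.asarray(predictions, dtype=float)
    if p.shape != (dataset.n,):
        raise ValueError("predictions must be one value per subject")
    if weights is None:
        weights = ipcw_weights(t, dataset, G)
    status = _event_status(t, dataset)
    case = (status == 1) & (weights > 0)
    control = (dataset.time > t) & (weights > 0)
    if not np.any(case) or not np.any(control):
        raise UndefinedMetricError(
            f"AUC({t:g}) undefined: {case.sum()} weighted case(s) and "
            f"{control.sum()} weighted control(s)")
    p_case, w_case = p[case], weights[case]
    p_ctrl, w_ctrl = p[control], weights[control]
    greater = (p_case[:, None] > p_ctrl[None, :]).astype(float)
    if tie_credit:
        greater += tie_credit * (p_case[:, None] == p_ctrl[None, :])
    pair_w = w_case[:, None] * w_ctrl[None, :]
    return float(np.sum(greater * pair_w) / np.sum(pair_w))


def td_brier(t: float, predictions, dataset: SurvivalData,
             weights: np.ndarray | None = None,
             G: StepSurvivalEstimate | None = None) -> float:
    """IPCW time-dependent Brier score at ``t``.

    ``(1/n) sum_i W_i(t) (D_i(t) - p_i(t))^2`` — the mean squared error of
    the predicted event probability against the event-by-``t`` status, with
    censored-by-``t`` subjects contributing through the reweighting of the
    observed ones.
    """
    p = np.asarray(predictions, dtype=float)
    if p.shape != (dataset.n,):
        raise ValueError("predictions must be one value per subject")
    if weights is None:
        weights = ipcw_weights(t, dataset, G)
    status = _event_status(t, dataset)
    return float(np.mean(weights * (status - p) ** 2))


def r_squared(bs: float, bs_null: float) -> float:
    """Explained-residual-variation scaling ``1 - BS / BS_0``."""
    if bs_null <= 0:
        raise UndefinedMetricError("null-model Brier score is 0; R^2 undefined")
    return 1.0 - bs / bs_null


def integrated_brier(bs_values, eval_times, t_star: float) -> float:
    """Integrate a Brier curve against ``W(t) = t / t*``.

    ``IBS = (1/t*) \\int_0^{t*} BS(s) ds`` by the trapezoidal rule over the
    evaluation grid, with the curve extended as constant from the first and
    last evaluated times to the ends of the range.
    """
    bs = np.asarray(bs_values, dtype=float)
    times = np.asarray(eval_times, dtype=float)
    if bs.shape != times.shape or bs.ndim != 1:
        raise ValueError("bs_values and eval_times must be 1-d and equal length")
    if times.size < 2:
        raise ValueError("need at least two evaluation times to integrate")
    if np.any(np.diff(times) <= 0):
        raise ValueError("eval_times must be strictly increasing")
    if times[0] < 0 or times[-1] > t_star:
        raise ValueError("eval_times must lie within [0, t_star]")
    t_ext = np.concatenate([[0.0], times, [t_star]])
    bs_ext = np.concatenate([[bs[0]], bs, [bs[-1]]])
    return float(np.trapezoid(bs_ext, t_ext) / t_star)


@dataclass(frozen=True)
class PredictionMatrix:
    """Subjects x times matrix of predicted event probabilities.

    Rows must be nondecreasing in time (event probability accumulates) and
    every entry must be a probability.  ``model`` is a provenance tag.
    """

    values: np.ndarray
    times: np.ndarray
    model: str = ""

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        t = np.asarray(self.times, dtype=float)
        if v.shape[1] != t.shape[0]:
            raise ValueError("values must have one column per evaluation time")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("event probabilities must lie in [0, 1]")
        if np.any(np.diff(v, axis=1) < -1e-9):
            raise ValueError("event probabilities must be nondecreasing in time")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "times", t)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]


@dataclass
class MetricResult:
    """Per-time metrics plus the machinery that produced them.

    ``table`` has one row per evaluation time with columns ``time``,
    ``auc``, ``brier``, ``brier_null``, ``r2``, ``n_cases``, ``n_controls``,
    ``n_zero_weight``.  ``weights`` and ``status`` (subjects x times) are
    kept for audit.  ``ibs`` integrates the Brier curve over
    ``[0, max(times)]``; ``r2_ibs = 1 - ibs / ibs_null``.
    """

    table: pd.DataFrame
    ibs: float | None = None
    ibs_null: float | None = None
    r2_ibs: float | None = None
    model: str = ""
    weights: np.ndarray | None = field(default=None, repr=False)
    status: np.ndarray | None = field(default=None, repr=False)

    def to_tidy(self) -> pd.DataFrame:
        """Long-format metric table (model, time, metric, value)."""
        rows = []
        for _, r in self.table.iterrows():
            for metric in ("auc", "brier", "brier_null", "r2"):
                rows.append((self.model, r["time"], metric, r[metric]))
        if self.ibs is not None:
            rows.append((self.model, self.table["time"].max(), "ibs", self.ibs))
            rows.append((self.model, self.table["time"].max(), "r2_ibs",
                         self.r2_ibs))
        return pd.DataFrame(rows, columns=["model", "time", "metric", "value"])

    def to_csv(self, path) -> None:
        self.to_tidy().to_csv(path, index=False)

    def to_dict(self) -> dict:
        out = {
            "model": self.model,
            "times": self.table["time"].tolist(),
            "auc": self.table["auc"].tolist(),
            "brier": self.table["brier"].tolist(),
            "brier_null": self.table["brier_null"].tolist(),
            "r2": self.table["r2"].tolist(),
        }
        if self.ibs is not None:
            out.update(ibs=self.ibs, ibs_null=self.ibs_null, r2_ibs=self.r2_ibs)
        return out


def evaluate_predictions(predictions: PredictionMatrix, dataset: SurvivalData,
                         G: StepSurvivalEstimate | None = None,
                         tie_credit: float = 0.0) -> MetricResult:
    """Score a prediction matrix against observed outcomes.

    Computes AUC(t), BS(t), the Kaplan–Meier null-model BS_0(t) and R²(t)
    at every prediction time, and the integrated Brier score (with its null
    scaling) when two or more times are given.  ``G`` defaults to the
    censoring Kaplan–Meier of ``dataset``.
    """
    if predictions.n_subjects != dataset.n:
        raise ValueError("prediction matrix and dataset sizes differ")
    if G is None:
        G = kaplan_meier(dataset.time, dataset.event, flip_events=True)
    km_event = kaplan_meier(dataset.time, dataset.event)  # null model
    times = predictions.times
    n, T = dataset.n, times.shape[0]
    weights = np.zeros((n, T))
    status = np.zeros((n, T))
    rows = []
    for k, t in enumerate(times):
        w = ipcw_weights(t, dataset, G)
        weights[:, k] = w
        status[:, k] = _event_status(t, dataset)
        p = predictions.values[:, k]
        p_null = np.full(n, 1.0 - km_event(t))
        auc = td_auc(t, p, dataset, weights=w, tie_credit=tie_credit)
        bs = td_brier(t, p, dataset, weights=w)
        bs0 = td_brier(t, p_null, dataset, weights=w)
        rows.append({
            "time": t, "auc": auc, "brier": bs, "brier_null": bs0,
            "r2": r_squared(bs, bs0),
            "n_cases": int(np.sum((status[:, k] == 1) & (w > 0))),
            "n_controls": int(np.sum((dataset.time > t) & (w > 0))),
            "n_zero_weight": int(np.sum(w == 0)),
        })
    table = pd.DataFrame(rows)
    result = MetricResult(table=table, model=predictions.model,
                          weights=weights, status=status)
    if T >= 2:
        t_star = float(times[-1])
        result.ibs = integrated_brier(table["brier"].to_numpy(), times, t_star)
        result.ibs_null = integrated_brier(table["brier_null"].to_numpy(),
                                           times, t_star)
        result.r2_ibs = r_squared(result.ibs, result.ibs_null)
    return result


def plot_prediction_error(results: dict[str, MetricResult], metric: str = "r2",
                          ax=None):
    """Prediction-error curves (one line per model) for a per-time metric."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for name, res in results.items():
        ax.plot(res.table["time"], res.table[metric], marker="o", label=name)
    ax.set_xlabel("time")
    ax.set_ylabel({"r2": "$R^2$ (Brier)", "brier": "Brier score",
                   "auc": "AUC(t)"}.get(metric, metric))
    ax.legend()
    return ax
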