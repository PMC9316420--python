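"""Model building and testing: splits, hyperparameter search, benchmarking.

The build/test pipeline for discrete-time survival prediction: split the
data at the subject level (holdout or K-fold, stratified by event status),
search the hyperparameter space — which for discrete-time methods always
includes the number of intervals ``J`` — by minimizing a censoring-adjusted
Brier objective on validation data, refit with the selected configuration,
and score the refitted model on held-out data with the evaluation module.

All randomness flows from a single root seed, expanded deterministically per
method and per fold through ``numpy.random.SeedSequence``, so a benchmark
re-run with the same configuration reproduces its report byte for byte.
"""

from __future__ import annotations

import itertools
import json
import time as _time
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .data import SurvivalData
from .evaluation import (MetricResult, PredictionMatrix, evaluate_predictions,
                         integrated_brier, kaplan_meier, td_brier)
from .hazard import DiscreteTimeHazardModel, SklearnClassifier
from .person_period import CensoringRule

__all__ = [
    "SplitPlan",
    "HoldoutSplit",
    "KFoldSplits",
    "make_splits",
    "Objective",
    "SearchSpace",
    "MethodSpec",
    "KaplanMeierPredictor",
    "TuneResult",
    "tune",
    "BenchmarkConfig",
    "BenchmarkReport",
    "run_benchmark",
]


# ---------------------------------------------------------------------------
# splitting


@dataclass(frozen=True)
class SplitPlan:
    """Subject-level data-splitting scheme.

    ``holdout`` uses ``train/validation/test`` fractions (default 60/20/20);
    ``kfold`` uses ``k`` folds, optionally repeated.  Splits are stratified
    by the event indicator by default so small data cannot produce
    event-free folds.
    """

    scheme: str = "holdout"
    train_frac: float = 0.6
    val_frac: float = 0.2
    test_frac: float = 0.2
    k: int = 5
    repeats: int = 1
    seed: int = 0
    stratify: bool = True

    def __post_init__(self) -> None:
        if self.scheme not in ("holdout", "kfold"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.scheme == "holdout":
            fr = (self.train_frac, self.val_frac, self.test_frac)
            if any(f <= 0 for f in fr) or abs(sum(fr) - 1) > 1e-9:
                raise ValueError("holdout fractions must be positive and sum to 1")
        if self.k < 2 or self.repeats < 1:
            raise ValueError("need k >= 2 folds and repeats >= 1")


@dataclass(frozen=True)
class HoldoutSplit:
    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray


@dataclass(frozen=True)
class KFoldSplits:
    """``folds[r][k]`` holds the validation indices of fold k in repeat r."""

    folds: tuple


def _stratified_order(dataset: SurvivalData, rng: np.random.Generator,
                      stratify: bool) -> np.ndarray:
    """Shuffled subject order in which strata are evenly interleaved.

    Within each event stratum subjects are shuffled and given a fractional
    rank; sorting all subjects by that rank interleaves the strata, so any
    contiguous or round-robin slicing of the order is near-proportionally
    stratified while keeping exact global split sizes.
    """
    n = dataset.n
    if not stratify:
        return rng.permutation(n)
    key = np.empty(n)
    for value in (0, 1):
        idx = np.flatnonzero(dataset.event == value)
        if idx.size == 0:
            continue
        perm = rng.permutation(idx)
        key[perm] = (np.arange(idx.size) + rng.uniform(0, 1)) / idx.size
    return np.argsort(key, kind="stable")


def _apportion(n: int, fracs: Sequence[float]) -> list[int]:
    """Largest-remainder rounding of ``n * fracs`` to integers summing to n."""
    raw = np.asarray(fracs) * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    for i in order[:rem]:
        base[i] += 1
    return base.tolist()


def make_splits(dataset: SurvivalData, plan: SplitPlan):
    """Deterministic subject-level split assignments under ``plan``."""
    rng = np.random.default_rng(plan.seed)
    if plan.scheme == "holdout":
        order = _stratified_order(dataset, rng, plan.stratify)
        sizes = _apportion(dataset.n,
                           (plan.train_frac, plan.val_frac, plan.test_frac))
        if min(sizes) == 0:
            raise ValueError("a holdout split is empty; use a larger dataset")
        bounds = np.cumsum(sizes)
        return HoldoutSplit(train=np.sort(order[: bounds[0]]),
                            validation=np.sort(order[bounds[0]:bounds[1]]),
                            test=np.sort(order[bounds[1]:]))
    repeats = []
    for r in range(plan.repeats):
        fold_rng = np.random.default_rng(
            np.random.SeedSequence([plan.seed, r]).generate_state(1)[0] % 2**31)
        order = _stratified_order(dataset, fold_rng, plan.stratify)
        folds = tuple(np.sort(order[k::plan.k]) for k in range(plan.k))
        if any(f.size == 0 for f in folds):
            raise ValueError("an empty fold was produced; use fewer folds")
        repeats.append(folds)
    return KFoldSplits(folds=tuple(repeats))


# ---------------------------------------------------------------------------
# methods and objectives


class KaplanMeierPredictor:
    """Null model: every subject gets the marginal Kaplan–Meier prediction."""

    def fit(self, data: SurvivalData) -> "KaplanMeierPredictor":
        self.km_ = kaplan_meier(data.time, data.event)
        return self

    def predict_event_probability(self, covariates, eval_times) -> np.ndarray:
        p = 1.0 - np.atleast_1d(self.km_(np.asarray(eval_times, dtype=float)))
        return np.tile(p, (len(covariates), 1))


@dataclass(frozen=True)
class Objective:
    """Tuning objective: Brier score at one time, or IBS over several."""

    kind: str = "brier_at"
    times: tuple = (1.0,)

    def __post_init__(self) -> None:
        if self.kind not in ("brier_at", "ibs"):
            raise ValueError(f"unknown objective {self.kind!r}")
        if self.kind == "brier_at" and len(self.times) != 1:
            raise ValueError("brier_at takes exactly one time")
        if self.kind == "ibs" and len(self.times) < 2:
            raise ValueError("ibs needs at least two times")

    def __call__(self, predictor, data: SurvivalData) -> float:
        times = np.asarray(self.times, dtype=float)
        p = np.atleast_2d(
            predictor.predict_event_probability(data.covariates, times))
        bs = [td_brier(t, p[:, k], data) for k, t in enumerate(times)]
        if self.kind == "brier_at":
            return bs[0]
        return integrated_brier(bs, times, float(times[-1]))


@dataclass(frozen=True)
class SearchSpace:
    """Hyperparameter ranges searched during tuning.

    ``n_intervals`` is always part of the space for discrete-time methods
    (default grid 2..25); ``params`` maps classifier hyperparameter names
    to candidate values.  ``strategy`` is ``grid`` or ``random`` with a
    trial ``budget`` (grid search ignores the budget).
    """

    n_intervals: tuple = tuple(range(2, 26))
    params: dict = field(default_factory=dict)
    strategy: str = "random"
    budget: int = 20

    def __post_init__(self) -> None:
        if self.strategy == "model_based":
            raise NotImplementedError(
                "model-based (Bayesian) search has no backend here; use "
                "'grid' or 'random'")
        if self.strategy not in ("grid", "random"):
            raise ValueError(f"unknown search strategy {self.strategy!r}")
        if len(self.n_intervals) < 1 or self.budget < 1:
            raise ValueError("need at least one n_intervals candidate and "
                             "a positive budget")

    def configurations(self, seed: int) -> list[dict]:
        """The ordered list of configurations to try."""
        axes = {"n_intervals": list(self.n_intervals),
                **{k: list(v) for k, v in self.params.items()}}
        names = list(axes)
        if self.strategy == "grid":
            return [dict(zip(names, combo))
                    for combo in itertools.product(*axes.values())]
        rng = np.random.default_rng(seed)
        return [{name: axes[name][rng.integers(len(axes[name]))]
                 for name in names} for _ in range(self.budget)]


@dataclass
class MethodSpec:
    """A candidate prediction method entering the benchmark.

    ``kind`` is ``link`` (parametric hazard model), ``classifier``
    (pluggable binary classifier), ``null`` (Kaplan–Meier predictor), or
    ``external`` (any ``builder(data, horizon, seed)`` returning an object
    with ``predict_event_probability`` — e.g. a wrapped continuous-time
    model).
    """

    name: str
    kind: str = "link"
    link: str = "logit"
    classifier: SklearnClassifier | None = None
    censoring_rule: CensoringRule | str = CensoringRule.OBSERVED_ANY
    interval_encoding: str = "onehot"
    search: SearchSpace = field(default_factory=SearchSpace)
    builder: Callable | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("link", "classifier", "null", "external"):
            raise ValueError(f"unknown method kind {self.kind!r}")
        if self.kind == "classifier" and self.classifier is None:
            raise ValueError("classifier methods need a classifier")
        if self.kind == "external" and self.builder is None:
            raise ValueError("external methods need a builder")

    def build(self, data: SurvivalData, horizon: float, config: dict,
              seed: int):
        """Fit this method on ``data`` under one configuration."""
        if self.kind == "null":
            return KaplanMeierPredictor().fit(data)
        if self.kind == "external":
            return self.builder(data, horizon, seed)
        n_intervals = int(config.get("n_intervals", 10))
        if self.kind == "link":
            model = DiscreteTimeHazardModel(
                data, horizon, n_intervals=n_intervals, link=self.link,
                censoring_rule=self.censoring_rule)
        else:
            params = {k: v for k, v in config.items() if k != "n_intervals"}
            clf = self.classifier.with_params(seed=seed, **params)
            model = DiscreteTimeHazardModel(
                data, horizon, n_intervals=n_intervals, link=None,
                classifier=clf, censoring_rule=self.censoring_rule,
                interval_encoding=self.interval_encoding)
        return model.fit()


@dataclass
class TuneResult:
    best_config: dict
    best_objective: float
    trials: list = field(default_factory=list)


def tune(method: MethodSpec, train: SurvivalData, validation: SurvivalData,
         objective: Objective, horizon: float, seed: int = 0) -> TuneResult:
    """Select the configuration minimizing the validation objective.

    Every sampled configuration (classifier hyperparameters x number of
    intervals) is fitted on ``train`` only and scored on ``validation``;
    preprocessing constants, interval grids and censoring weights are all
    computed inside that loop, so held-out test data is never touched.
    Failed trials are logged and skipped; if every trial fails the
    aggregated diagnostics are raised.
    """
    if method.kind in ("null", "external"):
        predictor = method.build(train, horizon, {}, seed)
        value = objective(predictor, validation)
        return TuneResult(best_config={}, best_objective=value,
                          trials=[{"config": {}, "objective": value,
                                   "status": "ok"}])
    trials = []
    best: tuple[float, dict] | None = None
    for config in method.search.configurations(seed):
        try:
            predictor = method.build(train, horizon, config, seed)
            value = objective(predictor, validation)
            trials.append({"config": config, "objective": value,
                           "status": "ok"})
            if best is None or value < best[0]:
                best = (value, config)
        except Exception as exc:
            trials.append({"config": config, "status": "failed",
                           "error": f"{type(exc).__name__}: {exc}"})
    if best is None:
        errors = "; ".join(t["error"] for t in trials)
        raise RuntimeError(f"all {len(trials)} tuning trials failed: {errors}")
    return TuneResult(best_config=best[1], best_objective=best[0],
                      trials=trials)


# ---------------------------------------------------------------------------
# benchmark


@dataclass
class BenchmarkConfig:
    """Full pipeline configuration: methods, split plan, times, objective."""

    methods: list
    horizon: float
    eval_times: tuple
    plan: SplitPlan = field(default_factory=SplitPlan)
    objective: Objective | None = None
    seed: int = 0
    refit_on: str = "train"  # or "train+validation" (holdout only)
    tune_frac: float = 0.25  # inner validation share within a k-fold fold

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("benchmark needs at least one method")
        if self.objective is None:
            times = tuple(float(t) for t in self.eval_times)
            self.objective = (Objective("ibs", times) if len(times) > 1
                              else Objective("brier_at", times))
        if self.refit_on not in ("train", "train+validation"):
            raise ValueError("refit_on must be 'train' or 'train+validation'")


@dataclass
class BenchmarkReport:
    """Per-method tuned configurations and held-out metrics.

    The canonical JSON serialization is deterministic: keys are sorted and
    wall-clock timings are excluded unless explicitly requested.
    """

    results: dict
    config_summary: dict

    def to_json(self, include_timing: bool = False, indent: int = 2) -> str:
        payload = {"config": self.config_summary, "methods": {}}
        for name, res in self.results.items():
            entry = {k: v for k, v in res.items() if k != "seconds"}
            if include_timing:
                entry["seconds"] = res.get("seconds")
            payload["methods"][name] = entry
        return json.dumps(payload, sort_keys=True, indent=indent)

    def save(self, path, include_timing: bool = False) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json(include_timing=include_timing))

    def metric_frame(self) -> pd.DataFrame:
        """Tidy per-method, per-time metric table."""
        rows = []
        for name, res in self.results.items():
            if res.get("status") != "ok":
                continue
            m = res["metrics"]
            for k, t in enumerate(m["times"]):
                for metric in ("auc", "brier", "brier_null", "r2"):
                    rows.append((name, t, metric, m[metric][k]))
        return pd.DataFrame(rows, columns=["model", "time", "metric", "value"])


def _method_seed(root: int, *key: int) -> int:
    return int(np.random.SeedSequence([root, *key]).generate_state(1)[0] % 2**31)


def _average_metrics(fold_metrics: list[MetricResult],
                     eval_times) -> dict:
    """Arithmetic mean of per-fold metric curves (and IBS summaries)."""
    out = {"times": [float(t) for t in eval_times]}
    for metric in ("auc", "brier", "brier_null", "r2"):
        stacked = np.array([m.table[metric].to_numpy() for m in fold_metrics])
        out[metric] = stacked.mean(axis=0).tolist()
    if fold_metrics[0].ibs is not None:
        out["ibs"] = float(np.mean([m.ibs for m in fold_metrics]))
        out["r2_ibs"] = float(np.mean([m.r2_ibs for m in fold_metrics]))
    return out


def _score_on(predictor, data: SurvivalData, eval_times, name: str,
              tie_credit: float = 0.0) -> MetricResult:
    times = np.asarray(eval_times, dtype=float)
    values = np.atleast_2d(
        predictor.predict_event_probability(data.covariates, times))
    pm = PredictionMatrix(values=values, times=times, model=name)
    return evaluate_predictions(pm, data, tie_credit=tie_credit)


def run_benchmark(config: BenchmarkConfig, dataset: SurvivalData,
                  ) -> BenchmarkReport:
    """Execute tune → refit → predict → score for every method.

    Under a holdout plan each method is tuned on train/validation, refitted
    on the training data (or train+validation if configured) and scored on
    the test split.  Under K-fold, each fold's training portion is split
    internally for tuning, the method is refitted on the full fold-training
    portion, scored on the fold, and metrics are averaged across folds.
    Failing methods are recorded as failed; the others continue.
    """
    splits = make_splits(dataset, config.plan)
    results: dict = {}
    for m_idx, method in enumerate(config.methods):
        t0 = _time.perf_counter()
        seed = _method_seed(config.seed, m_idx)
        try:
            if isinstance(splits, HoldoutSplit):
                train = dataset.subset(splits.train)
                val = dataset.subset(splits.validation)
                test = dataset.subset(splits.test)
                tuned = tune(method, train, val, config.objective,
                             config.horizon, seed)
                refit_data = (dataset.subset(
                    np.sort(np.concatenate([splits.train, splits.validation])))
                    if config.refit_on == "train+validation" else train)
                predictor = method.build(refit_data, config.horizon,
                                         tuned.best_config, seed)
                metrics = _score_on(predictor, test, config.eval_times,
                                    method.name)
                entry_metrics = metrics.to_dict()
                entry_metrics.pop("model", None)
                fold_log = [{"tuned_config": tuned.best_config,
                             "objective": tuned.best_objective,
                             "trials": tuned.trials}]
            else:
                fold_results, fold_log = [], []
                for r, folds in enumerate(splits.folds):
                    for k, val_idx in enumerate(folds):
                        fold_seed = _method_seed(config.seed, m_idx, r, k)
                        train_idx = np.sort(np.concatenate(
                            [f for j, f in enumerate(folds) if j != k]))
                        fold_train = dataset.subset(train_idx)
                        inner = make_splits(
                            fold_train,
                            SplitPlan("holdout",
                                      train_frac=1 - config.tune_frac,
                                      val_frac=config.tune_frac / 2,
                                      test_frac=config.tune_frac / 2,
                                      seed=fold_seed,
                                      stratify=config.plan.stratify))
                        tune_val_idx = np.sort(np.concatenate(
                            [inner.validation, inner.test]))
                        tuned = tune(method, fold_train.subset(inner.train),
                                     fold_train.subset(tune_val_idx),
                                     config.objective, config.horizon,
                                     fold_seed)
                        predictor = method.build(fold_train, config.horizon,
                                                 tuned.best_config, fold_seed)
                        metrics = _score_on(predictor,
                                            dataset.subset(val_idx),
                                            config.eval_times, method.name)
                        fold_results.append(metrics)
                        fold_log.append({"repeat": r, "fold": k,
                                         "tuned_config": tuned.best_config,
                                         "objective": tuned.best_objective,
                                         "metrics": {
                                             kk: vv for kk, vv in
                                             metrics.to_dict().items()
                                             if kk != "model"}})
                entry_metrics = _average_metrics(fold_results,
                                                 config.eval_times)
                tuned = None
            results[method.name] = {
                "status": "ok",
                "kind": method.kind,
                "tuned_config": fold_log[0]["tuned_config"]
                if isinstance(splits, HoldoutSplit)
                else [f["tuned_config"] for f in fold_log],
                "metrics": entry_metrics,
                "folds": fold_log,
                "seed": seed,
                "seconds": _time.perf_counter() - t0,
            }
        except Exception as exc:
            results[method.name] = {
                "status": "failed",
                "kind": method.kind,
                "error": f"{type(exc).__name__}: {exc}",
                "seed": seed,
                "seconds": _time.perf_counter() - t0,
            }
    summary = {
        "scheme": config.plan.scheme,
        "seed": config.seed,
        "horizon": config.horizon,
        "eval_times": [float(t) for t in config.eval_times],
        "objective": {"kind": config.objective.kind,
                      "times": list(config.objective.times)},
        "n_subjects": dataset.n,
        "refit_on": config.refit_on,
    }
    return BenchmarkReport(results=results, config_summary=summary)
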