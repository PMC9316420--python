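"""Interval grids and person-period expansion.

Discrete-time survival models divide the follow-up range ``(0, horizon]``
into ``J`` contiguous intervals ``A_j = (t_{j-1}, t_j]`` and fit a binary
model to an expanded *person-period* table: one row per subject per interval
at which the subject is still at risk at the interval's start, carrying the
subject's covariates, a categorical interval label and a within-interval
event indicator ``d``.  This module builds the grids (quantile-based cut
points of the observed event times), performs the expansion for training
(under three conventions for how censored subjects contribute) and for
prediction (all intervals for every subject), and maps continuous times to
interval indices.

The interval convention is left-open/right-closed throughout: a time equal
to a cut point ``t_j`` belongs to interval ``j``, and a subject censored at
exactly ``t_j`` has survived interval ``j`` in full under every convention.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import SurvivalData

__all__ = [
    "IntervalGrid",
    "CensoringRule",
    "PersonPeriodTable",
    "make_quantile_grid",
    "apply_administrative_censoring",
    "expand_train",
    "expand_for_prediction",
    "interval_index",
]


@dataclass(frozen=True)
class IntervalGrid:
    """Cut points ``t_0 = 0 < t_1 < ... < t_J = horizon``."""

    cut_points: np.ndarray

    def __post_init__(self) -> None:
        cuts = np.asarray(self.cut_points, dtype=float)
        if cuts.ndim != 1 or cuts.shape[0] < 2:
            raise ValueError("need at least two cut points (0 and the horizon)")
        if cuts[0] != 0:
            raise ValueError("first cut point must be exactly 0")
        if np.any(np.diff(cuts) <= 0):
            raise ValueError("cut points must be strictly increasing")
        object.__setattr__(self, "cut_points", cuts)

    @property
    def horizon(self) -> float:
        return float(self.cut_points[-1])

    @property
    def n_intervals(self) -> int:
        return self.cut_points.shape[0] - 1

    @property
    def lower(self) -> np.ndarray:
        """Left endpoints ``t_0..t_{J-1}``."""
        return self.cut_points[:-1]

    @property
    def upper(self) -> np.ndarray:
        """Right endpoints ``t_1..t_J``."""
        return self.cut_points[1:]

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.lower + self.upper)

    def labels(self) -> list[str]:
        """Categorical interval identifiers ``A1..AJ``."""
        return [f"A{j}" for j in range(1, self.n_intervals + 1)]

    def index(self, t) -> np.ndarray:
        """Interval index ``j`` with ``t_{j-1} < t <= t_j`` (1-based)."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t_arr <= 0) or np.any(t_arr > self.horizon):
            raise ValueError("times must lie in (0, horizon]")
        idx = np.searchsorted(self.cut_points, t_arr, side="left")
        return idx if np.ndim(t) else int(idx[0])


def interval_index(t, grid: IntervalGrid):
    """Map time(s) in ``(0, horizon]`` to 1-based interval indices."""
    return grid.index(t)


def make_quantile_grid(dataset: SurvivalData, horizon: float,
                       n_intervals: int) -> IntervalGrid:
    """Build a grid whose interior cuts are event-time quantiles.

    The interior cut points are the ``k/J`` (``k = 1..J-1``) empirical
    quantiles of the observed event times within the horizon, taken as
    order statistics (inverted-CDF definition) so every interior cut
    coincides with an observed event time; ``t_0 = 0`` and
    ``t_J = horizon`` are forced.  With heavily tied event times some
    quantiles coincide; duplicates are collapsed with a warning, so the
    realized grid may have fewer intervals than requested.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if n_intervals < 1:
        raise ValueError("n_intervals must be at least 1")
    event_times = dataset.time[(dataset.event == 1) & (dataset.time <= horizon)]
    if event_times.size == 0:
        raise ValueError("no events observed within the horizon; "
                         "cannot place interval cut points")
    probs = np.arange(1, n_intervals) / n_intervals
    interior = np.quantile(event_times, probs, method="inverted_cdf")
    interior = interior[(interior > 0) & (interior < horizon)]
    cuts = np.unique(np.concatenate([[0.0], interior, [horizon]]))
    realized = cuts.shape[0] - 1
    if realized < n_intervals:
        warnings.warn(
            f"tied event-time quantiles collapsed the grid from {n_intervals} "
            f"to {realized} intervals", UserWarning, stacklevel=2)
    return IntervalGrid(cuts)


def apply_administrative_censoring(dataset: SurvivalData,
                                   horizon: float) -> SurvivalData:
    """Censor every subject still under observation at the horizon."""
    return dataset.administratively_censor(horizon)


class CensoringRule(str, enum.Enum):
    """How a censored subject's partial last interval is counted.

    ``observed_any``
        The subject contributes every interval during which they were
        observed at all (at risk at the interval's start).
    ``half_interval``
        The subject contributes an interval only if they survived at least
        half of it.
    ``full_interval``
        The subject contributes an interval only if they survived it
        entirely — equivalent to moving the censoring time back to the
        previous cut point.

    Event subjects contribute identically under all three rules.
    """

    OBSERVED_ANY = "observed_any"
    HALF_INTERVAL = "half_interval"
    FULL_INTERVAL = "full_interval"


@dataclass
class PersonPeriodTable:
    """Long-format expansion of survival data over an interval grid.

    ``table`` has columns ``subject_id``, ``interval`` (1-based index),
    ``interval_label``, ``t_lo``, ``t_hi``, the covariates, and — for
    training tables — the binary event-history indicator ``d``.
    """

    table: pd.DataFrame
    grid: IntervalGrid
    covariate_names: list[str]
    rule: CensoringRule | None = None
    dropped_subjects: list = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return len(self.table)

    @property
    def n_subjects(self) -> int:
        return self.table["subject_id"].nunique()

    @property
    def has_outcome(self) -> bool:
        return "d" in self.table.columns

    def to_csv(self, path) -> None:
        cols = ["subject_id", "interval", "interval_label", "t_lo", "t_hi"]
        cols += self.covariate_names
        if self.has_outcome:
            cols.append("d")
        self.table[cols].to_csv(path, index=False)


def _n_contributed_intervals(time: np.ndarray, event: np.ndarray,
                             grid: IntervalGrid,
                             rule: CensoringRule) -> np.ndarray:
    """Number of person-period rows each subject contributes.

    Event subjects always contribute through the interval containing the
    event.  Censored subjects contribute per the rule; the counts are
    computed by searching the relevant threshold sequence (interval starts,
    midpoints, or ends).
    """
    n_obs = np.searchsorted(grid.cut_points[:-1], time, side="left")  # t_{j-1} < T
    n_half = np.searchsorted(grid.midpoints, time, side="right")      # T >= mid_j
    n_full = np.searchsorted(grid.upper, time, side="right")          # T >= t_j
    if rule is CensoringRule.OBSERVED_ANY:
        censored_count = n_obs
    elif rule is CensoringRule.HALF_INTERVAL:
        censored_count = n_half
    elif rule is CensoringRule.FULL_INTERVAL:
        censored_count = n_full
    else:  # pragma: no cover - exhaustive enum
        raise ValueError(f"unknown censoring rule {rule!r}")
    return np.where(event == 1, n_obs, censored_count)


def expand_train(dataset: SurvivalData, grid: IntervalGrid,
                 rule: CensoringRule | str = CensoringRule.OBSERVED_ANY,
                 ) -> PersonPeriodTable:
    """Expand subject-level data into the person-period training table.

    The dataset is administratively censored at the grid horizon first
    (a no-op if already done).  An event subject whose event time falls in
    interval ``j_i`` contributes rows ``1..j_i`` with ``d`` zero except in
    the last row.  A censored subject contributes all-zero ``d`` rows for
    the intervals selected by ``rule``; a subject whose rule yields zero
    intervals contributes no rows and is recorded in ``dropped_subjects``.
    """
    rule = CensoringRule(rule)
    dataset = dataset.administratively_censor(grid.horizon)
    counts = _n_contributed_intervals(dataset.time, dataset.event, grid, rule)

    keep = counts > 0
    dropped = dataset.subject_id[~keep].tolist()
    if dropped:
        warnings.warn(f"{len(dropped)} subject(s) contribute no person-period "
                      f"rows under rule {rule.value!r} and were dropped",
                      UserWarning, stacklevel=2)
    counts_k = counts[keep]
    subj_rows = np.repeat(np.arange(dataset.n)[keep], counts_k)
    # interval index within each subject: 1..count
    interval = np.concatenate([np.arange(1, c + 1) for c in counts_k]) \
        if counts_k.size else np.empty(0, dtype=int)
    d = np.zeros(interval.shape[0], dtype=np.int8)
    if counts_k.size:
        last_row = np.cumsum(counts_k) - 1
        is_event = dataset.event[keep] == 1
        d[last_row[is_event]] = 1

    table = pd.DataFrame({
        "subject_id": dataset.subject_id[subj_rows],
        "interval": interval,
        "interval_label": pd.Categorical.from_codes(
            interval - 1, categories=grid.labels()),
        "t_lo": grid.lower[interval - 1],
        "t_hi": grid.upper[interval - 1],
    })
    cov = dataset.covariates.iloc[subj_rows].reset_index(drop=True)
    table = pd.concat([table, cov], axis=1)
    table["d"] = d
    return PersonPeriodTable(table=table, grid=grid,
                             covariate_names=dataset.covariate_names,
                             rule=rule, dropped_subjects=dropped)


def expand_for_prediction(covariates: pd.DataFrame,
                          grid: IntervalGrid,
                          subject_id=None) -> PersonPeriodTable:
    """Expand prediction subjects to one row per interval (all ``J`` rows).

    Hazards must be predicted for every interval to compose a survival
    curve, so unlike training expansion every subject gets the full grid.
    """
    covariates = pd.DataFrame(covariates).reset_index(drop=True)
    n, J = len(covariates), grid.n_intervals
    if subject_id is None:
        subject_id = np.arange(n)
    subj_rows = np.repeat(np.arange(n), J)
    interval = np.tile(np.arange(1, J + 1), n)
    table = pd.DataFrame({
        "subject_id": np.asarray(subject_id)[subj_rows],
        "interval": interval,
        "interval_label": pd.Categorical.from_codes(
            interval - 1, categories=grid.labels()),
        "t_lo": grid.lower[interval - 1],
        "t_hi": grid.upper[interval - 1],
    })
    cov = covariates.iloc[subj_rows].reset_index(drop=True)
    table = pd.concat([table, cov], axis=1)
    return PersonPeriodTable(table=table, grid=grid,
                             covariate_names=list(covariates.columns))
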