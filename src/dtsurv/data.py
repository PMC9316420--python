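"""Subject-level right-censored survival data.

The basic observational unit is a subject with a follow-up time
``T = min(event time, censoring time)``, a binary event indicator
``delta = I(event observed)`` and a fixed vector of baseline covariates.
:class:`SurvivalData` holds one row per subject and validates the usual
requirements (nonnegative follow-up, binary indicator, unique ids, complete
covariates) at construction, so downstream code can assume a clean table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["SurvivalData", "load_csv"]


@dataclass(frozen=True)
class SurvivalData:
    """Right-censored survival records, one row per subject.

    Parameters
    ----------
    time
        Observed follow-up times ``T_i = min(T_event, C)``, nonnegative.
    event
        Event indicators ``delta_i``; 1 means the event was observed at
        ``time``, 0 means the subject was censored then.
    covariates
        Numeric covariate frame, one row per subject.  Categorical columns
        must be encoded before construction (see :func:`load_csv`).
    subject_id
        Unique identifiers; defaults to ``0..n-1``.
    """

    time: np.ndarray
    event: np.ndarray
    covariates: pd.DataFrame
    subject_id: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event)
        object.__setattr__(self, "time", time)
        if time.ndim != 1:
            raise ValueError("time must be one-dimensional")
        n = time.shape[0]
        if event.shape != (n,):
            raise ValueError("event must match time in length")
        if not np.all(np.isin(event, (0, 1))):
            raise ValueError("event indicator must be binary (0/1)")
        object.__setattr__(self, "event", event.astype(np.int8))
        if np.any(~np.isfinite(time)) or np.any(time < 0):
            raise ValueError("followup times must be finite and nonnegative")
        # An observed event at exactly t=0 cannot be placed in any
        # left-open interval (0, t_1]; reject at load.
        if np.any((time == 0) & (event == 1)):
            raise ValueError("event at time 0 cannot be represented; remove or shift")
        cov = pd.DataFrame(self.covariates).reset_index(drop=True)
        if len(cov) != n:
            raise ValueError("covariates must have one row per subject")
        if cov.isna().any().any():
            raise ValueError("missing covariate values are not supported; "
                             "provide complete cases")
        non_numeric = [c for c in cov.columns
                       if not np.issubdtype(cov[c].dtype, np.number)]
        if non_numeric:
            raise ValueError(f"covariate columns must be numeric; encode {non_numeric}")
        object.__setattr__(self, "covariates", cov)
        if self.subject_id is None:
            object.__setattr__(self, "subject_id", np.arange(n))
        else:
            sid = np.asarray(self.subject_id)
            if sid.shape != (n,):
                raise ValueError("subject_id must match time in length")
            if len(np.unique(sid)) != n:
                raise ValueError("subject_id values must be unique")
            object.__setattr__(self, "subject_id", sid)

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return self.time.shape[0]

    @property
    def n(self) -> int:
        return len(self)

    @property
    def covariate_names(self) -> list[str]:
        return list(self.covariates.columns)

    def subset(self, index) -> "SurvivalData":
        """Positional subset (a new object; subject ids are preserved)."""
        index = np.asarray(index)
        return SurvivalData(
            time=self.time[index],
            event=self.event[index],
            covariates=self.covariates.iloc[index],
            subject_id=self.subject_id[index],
        )

    def administratively_censor(self, horizon: float) -> "SurvivalData":
        """Truncate follow-up at ``horizon``.

        Subjects whose follow-up exceeds the horizon are returned with
        ``time = horizon`` and ``event = 0`` — they are known to be
        event-free at the horizon, which is all the discretized model can
        use.  Subjects at or before the horizon are unchanged.
        """
        if horizon <= 0:
            raise ValueError("horizon must be positive")
        beyond = self.time > horizon
        time = np.where(beyond, horizon, self.time)
        event = np.where(beyond, 0, self.event).astype(np.int8)
        return SurvivalData(time=time, event=event,
                            covariates=self.covariates,
                            subject_id=self.subject_id)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"subject_id": self.subject_id,
                           "time": self.time, "event": self.event})
        return pd.concat([df, self.covariates.reset_index(drop=True)], axis=1)


def _one_hot(series: pd.Series, name: str,
             vocabulary: Sequence | None = None) -> tuple[pd.DataFrame, list]:
    """Dummy-encode one categorical column with a persisted level set."""
    levels = list(vocabulary) if vocabulary is not None else sorted(
        series.dropna().unique().tolist())
    unseen = set(series.unique()) - set(levels)
    if unseen:
        raise ValueError(f"column {name!r} has levels outside the vocabulary: {unseen}")
    out = pd.DataFrame(
        {f"{name}={lv}": (series == lv).astype(float) for lv in levels[1:]})
    return out, levels


def load_csv(
    path,
    time_col: str = "time",
    event_col: str = "event",
    covariate_cols: Sequence[str] | None = None,
    categorical: Mapping[str, Sequence] | Sequence[str] | None = None,
    id_col: str | None = None,
) -> SurvivalData:
    """Read subject-level survival data from a delimited text file.

    Parameters
    ----------
    time_col, event_col
        Column names for follow-up time and event indicator.
    covariate_cols
        Covariate columns to keep; default is every remaining column.
    categorical
        Either a list of column names to one-hot encode (vocabulary learned
        from the file, first level dropped as reference), or a mapping
        ``{column: [levels...]}`` pinning the vocabulary explicitly.
    id_col
        Optional subject-identifier column.
    """
    df = pd.read_csv(path)
    for col in (time_col, event_col):
        if col not in df.columns:
            raise ValueError(f"required column {col!r} not found in {path}")
    if covariate_cols is None:
        reserved = {time_col, event_col} | ({id_col} if id_col else set())
        covariate_cols = [c for c in df.columns if c not in reserved]
    cat_map: dict[str, Sequence | None] = {}
    if categorical is not None:
        if isinstance(categorical, Mapping):
            cat_map = dict(categorical)
        else:
            cat_map = {c: None for c in categorical}
    pieces = []
    for col in covariate_cols:
        if col in cat_map:
            encoded, _ = _one_hot(df[col], col, cat_map[col])
            pieces.append(encoded)
        else:
            pieces.append(df[[col]].astype(float))
    covariates = pd.concat(pieces, axis=1) if pieces else pd.DataFrame(index=df.index)
    return SurvivalData(
        time=df[time_col].to_numpy(dtype=float),
        event=df[event_col].to_numpy(),
        covariates=covariates,
        subject_id=df[id_col].to_numpy() if id_col else None,
    )
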