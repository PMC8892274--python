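"""Outcome and covariate construction: the regression-ready analysis table.

One row per alert instance, carrying

* outcomes — ``dismiss`` (the action was a dismissal) and the nested
  automaticity outcomes ``dismiss1/2/3`` (dismissed in strictly under
  1/2/3 seconds);
* pre-action habit strengths ``H_0.01``, ``H_0.05``, ``H_0.1``;
* exposure covariates — ``P_C_total``/``P_C_ward`` (cumulative alerts, and
  alerts during ward rounds, this physician has received for this patient,
  including the current one), ``C_total`` (cumulative alerts hospital-wide
  for the physician), ``C_PatNum`` (distinct catheterised patients the
  physician encountered on the current calendar day), ``day_lag`` (whole
  days since the physician's first alert for the patient);
* timing covariates — day of week and month.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .event_log import EventLog
from .habit_model import DEFAULT_ALPHAS, HabitStrengthTransformer

OUTCOME_COLUMNS = ["dismiss", "dismiss1", "dismiss2", "dismiss3"]
EXPOSURE_COLUMNS = ["P_C_total", "P_C_ward", "C_total", "C_PatNum", "day_lag"]
TIMING_COLUMNS = ["day_of_week", "month"]

_DAY_NAMES = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")
_MONTH_NAMES = ("Jan", "Feb", "Mar", "Apr", "May", "Jun",
                "Jul", "Aug", "Sep", "Oct", "Nov", "Dec")


def _sorted_frame(log: EventLog | pd.DataFrame) -> pd.DataFrame:
    df = log.events if isinstance(log, EventLog) else log
    return df.sort_values(
        ["physician_id", "timestamp", "alert_id"], kind="mergesort"
    ).reset_index(drop=True)


def build_outcomes(
    log: EventLog | pd.DataFrame, thresholds: Sequence[float] = (1, 2, 3)
) -> pd.DataFrame:
    """Binary dismissal outcomes per event.

    ``dismiss`` is 1 iff the action was a dismissal; ``dismiss<K>`` is 1
    iff additionally processing_time < K seconds (strict inequality).
    """
    if any(t <= 0 for t in thresholds):
        raise ValueError("outcome thresholds must be positive seconds")
    df = log.events if isinstance(log, EventLog) else log
    out = pd.DataFrame(index=df.index)
    out["dismiss"] = (df["action"] == "dismiss").astype(int)
    for k in thresholds:
        out[f"dismiss{k:g}"] = (
            out["dismiss"].astype(bool) & (df["processing_time"] < k)
        ).astype(int)
    return out


def build_exposure_covariates(log: EventLog | pd.DataFrame) -> pd.DataFrame:
    """Cumulative exposure counters over the chronologically sorted log.

    Counters include the current event (a physician's first alert has
    C_total = P_C_total = 1), matching summary minima of 1 rather than 0.
    """
    df = _sorted_frame(log)
    out = pd.DataFrame(index=df.index)
    dyad = df.groupby(["physician_id", "patient_id"], sort=False)
    out["P_C_total"] = dyad.cumcount() + 1
    out["P_C_ward"] = (
        df.assign(_w=df["ward_round"].astype(int))
        .groupby(["physician_id", "patient_id"], sort=False)["_w"]
        .cumsum()
    )
    out["C_total"] = df.groupby("physician_id", sort=False).cumcount() + 1

    date = df["timestamp"].dt.normalize()
    n_pat = (
        df.assign(date=date)
        .groupby(["physician_id", "date"], sort=False)["patient_id"]
        .transform("nunique")
    )
    out["C_PatNum"] = n_pat.astype(int)

    first_date = (
        df.assign(date=date)
        .groupby(["physician_id", "patient_id"], sort=False)["date"]
        .transform("min")
    )
    out["day_lag"] = (date - first_date).dt.days.astype(int)
    return out


def build_timing_covariates(log: EventLog | pd.DataFrame) -> pd.DataFrame:
    """Day-of-week and month labels from the timestamps as recorded."""
    df = log.events if isinstance(log, EventLog) else log
    ts = df["timestamp"]
    out = pd.DataFrame(index=df.index)
    out["day_of_week"] = ts.dt.dayofweek.map(dict(enumerate(_DAY_NAMES)))
    out["month"] = (ts.dt.month - 1).map(dict(enumerate(_MONTH_NAMES)))
    return out


class AnalysisTableBuilder(BaseEstimator, TransformerMixin):
    """Transform an event log into the regression-ready analysis table.

    Sorts the log into the canonical (physician, timestamp, alert_id)
    order, attaches pre-action habit strengths for each learning rate,
    and joins the outcome, exposure and timing columns.  Row count is
    conserved: one analysis row per alert event.
    """

    def __init__(
        self,
        alphas: Iterable[float] = DEFAULT_ALPHAS,
        h0: float = 0.0,
        thresholds: Sequence[float] = (1, 2, 3),
    ):
        self.alphas = alphas
        self.h0 = h0
        self.thresholds = thresholds

    def fit(self, X, y=None) -> "AnalysisTableBuilder":
        self.habit_ = HabitStrengthTransformer(tuple(self.alphas), self.h0).fit(
            X.events if isinstance(X, EventLog) else X
        )
        return self

    def transform(self, X: EventLog | pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "habit_"):
            self.fit(X)
        df = self.habit_.transform(X.events if isinstance(X, EventLog) else X)
        parts = [
            df,
            build_outcomes(df, self.thresholds),
            build_exposure_covariates(df),
            build_timing_covariates(df),
        ]
        table = pd.concat(parts, axis=1)
        _audit(table)
        return table


def _audit(table: pd.DataFrame) -> None:
    """Cheap internal consistency checks on every assembled table."""
    d = table
    if ((d["dismiss1"] > d["dismiss2"]) | (d["dismiss2"] > d["dismiss3"])
            | (d["dismiss3"] > d["dismiss"])).any():
        raise AssertionError("nested-outcome invariant violated")
    if (d["P_C_ward"] > d["P_C_total"]).any() or (d["P_C_total"] > d["C_total"]).any():
        raise AssertionError("exposure-counter ordering violated")
    if (d["day_lag"] < 0).any():
        raise AssertionError("negative day_lag")


def assemble_analysis_table(
    log: EventLog,
    alphas: Iterable[float] = DEFAULT_ALPHAS,
    h0: float = 0.0,
    thresholds: Sequence[float] = (1, 2, 3),
) -> pd.DataFrame:
    """One-call construction of the analysis table from a validated log."""
    return AnalysisTableBuilder(tuple(alphas), h0, thresholds).fit(log).transform(log)
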