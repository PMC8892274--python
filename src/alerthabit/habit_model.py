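"""Hebbian habit-strength model for repeated alert exposures.

Habit strength H is a latent state in [0, 1] tracking a physician's
accumulated tendency to dismiss the alert.  After each exposure it moves a
fraction ``alpha`` (the learning rate) toward the action just taken::

    H_{t+1} = H_t + alpha * (a_t - H_t),    a_t = 1 iff the alert was dismissed

Under constant dismissal from H_0 = 0 this integrates to the closed form
1 - (1 - alpha)^t, which serves as the analytic oracle.  The habit stream
runs per physician across all of their patients, in chronological order,
and the value attached to an event is the PRE-action strength: habit
accumulated from exposures 1..k-1 only, so the current outcome never leaks
into its own predictor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from sklearn.base import BaseEstimator, TransformerMixin

from .event_log import EventLog

#: learning rates used throughout the analysis battery
DEFAULT_ALPHAS = (0.01, 0.05, 0.1)


def habit_column(alpha: float) -> str:
    """Column name carrying pre-action habit strength for ``alpha``."""
    return f"H_{alpha:g}"


@dataclass(frozen=True)
class HabitParams:
    """Learning rate ``alpha`` in (0,1) and initial strength ``h0`` in [0,1]."""

    alpha: float
    h0: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0,1), got {self.alpha}")
        if not 0.0 <= self.h0 <= 1.0:
            raise ValueError(f"h0 must lie in [0,1], got {self.h0}")


@dataclass
class HabitTrajectory:
    physician_id: str
    alpha: float
    pre_action_h: np.ndarray
    post_action_h: np.ndarray


def update_habit(h: float, action: int, params: HabitParams) -> float:
    """One habit update: move ``h`` a fraction alpha toward ``action``."""
    if not 0.0 <= h <= 1.0:
        raise ValueError(f"habit strength must lie in [0,1], got {h}")
    if action not in (0, 1):
        raise ValueError(f"action must be binary, got {action}")
    return h + params.alpha * (action - h)


def habit_trajectory(
    actions: Sequence[int] | np.ndarray,
    params: HabitParams,
    physician_id: str = "",
) -> HabitTrajectory:
    """Iterate the update over a binary action stream.

    Returns pre- and post-action strengths, one per event; the recursion
    H_post = (1-alpha) H_pre + alpha a is an exponentially weighted moving
    average, evaluated here as a linear filter.
    """
    a = np.asarray(actions, dtype=float)
    if a.size == 0:
        raise ValueError("action stream must be non-empty")
    if not np.isin(a, (0.0, 1.0)).all():
        raise ValueError("actions must be binary 0/1")
    alpha = params.alpha
    # y[k] = (1-alpha) y[k-1] + alpha a[k], seeded at h0
    zi = np.array([(1.0 - alpha) * params.h0])
    post, _ = lfilter([alpha], [1.0, -(1.0 - alpha)], a, zi=zi)
    pre = np.concatenate([[params.h0], post[:-1]])
    return HabitTrajectory(physician_id, alpha, pre, post)


def closed_form_constant_action(t: int, params: HabitParams) -> float:
    """Habit strength after ``t`` consecutive dismissals from h0 = 0.

    Analytic solution 1 - (1-alpha)^t of the update under constant a = 1;
    used as a brute-force-free oracle.
    """
    if t < 0:
        raise ValueError(f"exposure count must be >= 0, got {t}")
    return 1.0 - (1.0 - params.alpha) ** t


class HabitStrengthTransformer(BaseEstimator, TransformerMixin):
    """Attach pre-action habit-strength columns to an event-log DataFrame.

    For each learning rate in ``alphas`` the transformer adds a column
    ``H_<alpha>`` holding, per event, the physician's habit strength
    accumulated over all of their earlier alerts (any patient), with
    dismissal coded 1 and acknowledge/remove_order coded 0.

    Parameters
    ----------
    alphas : sequence of float, default (0.01, 0.05, 0.1)
        Learning rates; one output column per value.
    h0 : float, default 0.0
        Initial habit strength (0 when no physician has prior exposure to
        the alert, as for a newly deployed alert stream).
    """

    def __init__(self, alphas: Iterable[float] = DEFAULT_ALPHAS, h0: float = 0.0):
        self.alphas = alphas
        self.h0 = h0

    def fit(self, X: pd.DataFrame, y=None) -> "HabitStrengthTransformer":
        self.params_ = [HabitParams(a, self.h0) for a in self.alphas]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """X: event-log DataFrame; returns a copy, sorted by
        (physician_id, timestamp, alert_id), with habit columns added."""
        if not hasattr(self, "params_"):
            self.fit(X)
        df = X.sort_values(
            ["physician_id", "timestamp", "alert_id"], kind="mergesort"
        ).reset_index(drop=True)
        actions = (df["action"] == "dismiss").to_numpy(dtype=float)
        group_codes, _ = pd.factorize(df["physician_id"], sort=False)
        for params in self.params_:
            pre = np.empty(len(df))
            for g in np.unique(group_codes):
                idx = np.flatnonzero(group_codes == g)
                traj = habit_trajectory(actions[idx], params)
                pre[idx] = traj.pre_action_h
            df[habit_column(params.alpha)] = pre
        return df


def attach_habit(
    log: EventLog, alphas: Iterable[float] = DEFAULT_ALPHAS, h0: float = 0.0
) -> EventLog:
    """Return a new EventLog whose frame carries H_<alpha> columns."""
    tr = HabitStrengthTransformer(alphas=tuple(alphas), h0=h0).fit(log.events)
    return EventLog(tr.transform(log.events), dict(log.provenance))
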