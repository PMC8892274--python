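"""Synthetic alert event-log generator with known ground truth.

The generative process mirrors the structure the analysis assumes:

* physicians (with rank, specialty, department and a normal random
  intercept u_j) see repeated alerts for the patients assigned to them
  (physician-patient dyads, right-skewed alert counts per dyad);
* each physician carries a latent habit strength H, updated after every
  alert by the Hebbian rule with learning rate ``alpha_true`` using the
  REALISED action — dismissal reinforces the habit, making the loop
  self-reinforcing;
* an alert is dismissed with probability
  logistic(beta0 + beta_H * H_pre + gamma' x + u_j);
* processing time is lognormal with log-mean theta0 - theta1 * H_pre, so
  responses get faster as the habit consolidates.

Default parameter values emulate the marginal structure of a large
hospital deployment of a catheter-reminder alert: about 90% of alerts
dismissed, 45.6% during ward rounds, ~8 alerts per dyad (SD ~12), ~57
alerts per physician, patient age ~ N(68, 16) truncated to [16, 105],
mean length of stay ~38 days, and mean processing time falling from
roughly 5.9 s at first exposure toward ~2.4 s by the 60th.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .event_log import EventLog, RANKS

_SPECIALTIES = ("General Medicine", "Geriatrics", "Cardiology", "Surgery",
                "Orthopaedics", "Urology", "Renal")
_DEPARTMENTS = ("Ward A", "Ward B", "Ward C", "Ward D", "ICU")
_RACES = ("Chinese", "Malay", "Indian", "Other")


@dataclass
class SimulationConfig:
    """Ground-truth parameters of the synthetic generative process."""

    n_physicians: int = 200
    n_patients: int = 400
    rank_distribution: dict = field(default_factory=lambda: {
        "intern": 0.25, "resident": 0.40, "fellow": 0.10, "attending": 0.25,
    })
    #: negative-binomial alerts per dyad: mean ~8, dispersion k (var = m + m^2/k)
    alerts_per_dyad_mean: float = 8.0
    alerts_per_dyad_dispersion: float = 0.5
    alerts_per_dyad_max: int = 120
    dyads_per_physician_mean: float = 7.0
    alpha_true: float = 0.05
    h0: float = 0.0
    beta0: float = 1.5
    beta_H: float = 1.0
    #: covariate effects on the dismissal log-odds (continuous ones apply
    #: to centred values so beta0 keeps its interpretation)
    gamma: dict = field(default_factory=lambda: {
        "ward_round": 0.3,
        "patient_age": -0.005,   # per year, centred at 68
        "length_of_stay": 0.002,  # per day, centred at 38
        "rank": {"intern": 0.0, "resident": 0.1, "fellow": 0.15, "attending": 0.2},
    })
    sigma_u: float = 1.0
    #: lognormal latency: log(seconds) = theta0 - theta1 * H_pre + N(0, sigma_e)
    theta0: float = 1.65
    theta1: float = 0.9
    sigma_e: float = 0.5
    ward_prob: float = 0.456
    date_start: str = "2017-03-01"
    date_end: str = "2018-12-31"
    seed: int = 0

    def validate(self) -> None:
        probs = np.array(list(self.rank_distribution.values()), dtype=float)
        if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
            raise ValueError("rank_distribution must be a normalised distribution")
        if not 0.0 < self.alpha_true < 1.0:
            raise ValueError("alpha_true must lie in (0,1)")
        if self.sigma_u < 0 or self.sigma_e < 0:
            raise ValueError("sigma_u and sigma_e must be non-negative")
        if not 0.0 <= self.ward_prob <= 1.0:
            raise ValueError("ward_prob must lie in [0,1]")
        if min(self.n_physicians, self.n_patients) < 1:
            raise ValueError("need at least one physician and one patient")


@dataclass
class GroundTruth:
    """Everything latent: parameters, physician intercepts, per-event H."""

    config: SimulationConfig
    u: pd.Series                 # physician_id -> random intercept
    latent: pd.DataFrame         # per alert_id: H_pre, dismiss_prob, dismissed

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "config": asdict(self.config),
            "u": {k: float(v) for k, v in self.u.items()},
            "latent": {
                "alert_id": self.latent["alert_id"].tolist(),
                "H_pre": [round(float(v), 12) for v in self.latent["H_pre"]],
                "dismiss_prob": [round(float(v), 12) for v in self.latent["dismiss_prob"]],
                "dismissed": [int(v) for v in self.latent["dismissed"]],
            },
        }
        path.write_text(json.dumps(payload))
        return path


def _truncated_normal(rng, mean, sd, low, high, size):
    x = rng.normal(mean, sd, size)
    while True:
        bad = (x < low) | (x > high)
        if not bad.any():
            return x
        x[bad] = rng.normal(mean, sd, bad.sum())


def simulate_log(config: SimulationConfig) -> tuple[EventLog, GroundTruth]:
    """Draw a synthetic event log and its ground truth.

    Identical config (including seed) yields an identical log.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    # physicians
    phys_ids = [f"P{i:04d}" for i in range(1, config.n_physicians + 1)]
    ranks = list(config.rank_distribution)
    rank_p = np.array([config.rank_distribution[r] for r in ranks])
    phys_rank = rng.choice(ranks, size=config.n_physicians, p=rank_p)
    phys_spec = rng.choice(_SPECIALTIES, size=config.n_physicians)
    phys_dept = rng.choice(_DEPARTMENTS, size=config.n_physicians)
    u = rng.normal(0.0, config.sigma_u, config.n_physicians)

    # patients
    pat_ids = [f"PT{i:04d}" for i in range(1, config.n_patients + 1)]
    pat_age = np.round(
        _truncated_normal(rng, 68.0, 16.0, 16, 105, config.n_patients)
    ).astype(int)
    pat_gender = rng.choice(["F", "M"], size=config.n_patients, p=[0.558, 0.442])
    pat_race = rng.choice(_RACES, size=config.n_patients, p=[0.6, 0.15, 0.12, 0.13])
    pat_los = np.minimum(
        np.maximum(np.round(rng.lognormal(3.2, 1.0, config.n_patients)), 1), 357
    ).astype(int)
    pat_diag = 1 + rng.binomial(2, 0.022, config.n_patients)

    t_start = pd.Timestamp(config.date_start)
    t_end = pd.Timestamp(config.date_end)
    window_days = (t_end - t_start).days

    rows = []
    for j in range(config.n_physicians):
        n_dyads = 1 + rng.poisson(max(config.dyads_per_physician_mean - 1.0, 0.0))
        n_dyads = min(n_dyads, config.n_patients)
        patients = rng.choice(config.n_patients, size=n_dyads, replace=False)
        for pidx in patients:
            m, k = config.alerts_per_dyad_mean, config.alerts_per_dyad_dispersion
            n_alerts = int(rng.negative_binomial(k, k / (k + m))) + 1
            n_alerts = min(n_alerts, config.alerts_per_dyad_max)
            start_day = rng.uniform(0, max(window_days - 30, 1))
            gaps = rng.exponential(0.5, n_alerts)  # days between alerts
            gaps[0] = 0.0
            offsets = start_day + np.cumsum(gaps)
            for o in offsets:
                ts = t_start + pd.Timedelta(seconds=round(o * 86400))
                rows.append((j, pidx, ts))

    df = pd.DataFrame(rows, columns=["j", "pidx", "timestamp"])
    # unique second-resolution timestamps per physician so the
    # (physician, timestamp) order is total without id tie-breaks
    df = df.sort_values(["j", "timestamp"], kind="mergesort").reset_index(drop=True)
    for j, idx in df.groupby("j").groups.items():
        ts = df.loc[idx, "timestamp"].values
        for i in range(1, len(ts)):
            if ts[i] <= ts[i - 1]:
                ts[i] = ts[i - 1] + np.timedelta64(1, "s")
        df.loc[idx, "timestamp"] = ts

    n = len(df)
    df["alert_id"] = [f"A{i:06d}" for i in range(1, n + 1)]
    df["ward_round"] = rng.random(n) < config.ward_prob

    # habit loop per physician: realised dismissals feed back into H
    gamma = config.gamma
    rank_offset = np.array([gamma["rank"][r] for r in phys_rank])
    j_arr = df["j"].to_numpy()
    p_arr = df["pidx"].to_numpy()
    ward_arr = df["ward_round"].to_numpy()
    eta_cov = (
        gamma["ward_round"] * ward_arr.astype(float)
        + gamma["patient_age"] * (pat_age[p_arr] - 68.0)
        + gamma["length_of_stay"] * (pat_los[p_arr] - 38.0)
        + rank_offset[j_arr]
        + u[j_arr]
    )
    unif_y = rng.random(n)
    eps = rng.normal(0.0, config.sigma_e, n)
    other_action = rng.random(n) < 0.5  # acknowledge vs remove_order

    H_pre = np.empty(n)
    prob = np.empty(n)
    dismissed = np.empty(n, dtype=bool)
    starts = set(np.flatnonzero(np.diff(j_arr, prepend=-1)).tolist())
    h = config.h0
    for i in range(n):
        if i in starts:
            h = config.h0
        H_pre[i] = h
        eta = config.beta0 + config.beta_H * h + eta_cov[i]
        p = 1.0 / (1.0 + np.exp(-eta))
        prob[i] = p
        a = unif_y[i] < p
        dismissed[i] = a
        h = h + config.alpha_true * (float(a) - h)

    pt = np.exp(config.theta0 - config.theta1 * H_pre + eps)
    pt = np.round(np.maximum(pt, 0.05), 3)

    events = pd.DataFrame({
        "alert_id": df["alert_id"],
        "physician_id": [phys_ids[j] for j in j_arr],
        "patient_id": [pat_ids[p] for p in p_arr],
        "timestamp": df["timestamp"],
        "action": np.where(
            dismissed, "dismiss",
            np.where(other_action, "acknowledge", "remove_order"),
        ),
        "processing_time": pt,
        "ward_round": ward_arr,
        "physician_rank": [phys_rank[j] for j in j_arr],
        "specialty": [phys_spec[j] for j in j_arr],
        "department": [phys_dept[j] for j in j_arr],
        "patient_age": pat_age[p_arr],
        "patient_gender": [pat_gender[p] for p in p_arr],
        "patient_race": [pat_race[p] for p in p_arr],
        "length_of_stay": pat_los[p_arr],
        "diagnosis_count": pat_diag[p_arr],
    })

    log = EventLog(events, provenance={"source": "synthetic", "seed": config.seed})
    truth = GroundTruth(
        config=config,
        u=pd.Series(u, index=phys_ids),
        latent=pd.DataFrame({
            "alert_id": df["alert_id"],
            "H_pre": H_pre,
            "dismiss_prob": prob,
            "dismissed": dismissed.astype(int),
        }),
    )
    return log, truth


def fixture_from_counts(
    total: int,
    dismissed: int,
    under1: int,
    under2: int,
    under3: int,
    seed: int = 0,
    n_physicians: int = 100,
) -> EventLog:
    """Deterministic log realising exact marginal counts.

    Exactly ``dismissed`` events carry action=dismiss; of those,
    ``under1`` get processing times in [0.5, 1), ``under2 - under1`` in
    [1.5, 2), ``under3 - under2`` in [2.5, 3) and the rest >= 3 s, so the
    under-1/2/3-second dismissal counts match the inputs exactly.
    Non-dismissed events alternate acknowledge / remove_order.
    """
    if not 0 <= under1 <= under2 <= under3 <= dismissed <= total:
        raise ValueError("counts must satisfy under1 <= under2 <= under3 <= dismissed <= total")
    rng = np.random.default_rng(seed)
    n = total
    pt = np.empty(n)
    nd = dismissed
    pt[:under1] = 0.5 + 0.4 * rng.random(under1)
    pt[under1:under2] = 1.5 + 0.4 * rng.random(under2 - under1)
    pt[under2:under3] = 2.5 + 0.4 * rng.random(under3 - under2)
    pt[under3:nd] = 3.5 + 4.0 * rng.random(nd - under3)
    pt[nd:] = 6.0 + 6.0 * rng.random(n - nd)
    pt = np.round(pt, 3)

    action = np.empty(n, dtype=object)
    action[:nd] = "dismiss"
    rest = np.arange(nd, n)
    action[rest] = np.where((rest - nd) % 2 == 0, "acknowledge", "remove_order")

    phys = np.arange(n) % n_physicians
    pat = np.arange(n) % max(n_physicians * 2, 1)
    t0 = pd.Timestamp("2017-03-01 08:00:00")
    ts = t0 + pd.to_timedelta(np.arange(n) * 60, unit="s")

    events = pd.DataFrame({
        "alert_id": [f"F{i:06d}" for i in range(1, n + 1)],
        "physician_id": [f"P{j:04d}" for j in phys],
        "patient_id": [f"PT{j:04d}" for j in pat],
        "timestamp": ts,
        "action": action,
        "processing_time": pt,
        "ward_round": (np.arange(n) % 2 == 0),
        "physician_rank": [RANKS[j % 4] for j in phys],
        "specialty": "General Medicine",
        "department": "Ward A",
        "patient_age": 68,
        "patient_gender": np.where(np.arange(n) % 2 == 0, "F", "M"),
        "patient_race": "Chinese",
        "length_of_stay": 38,
        "diagnosis_count": 1,
    })
    return EventLog(events, provenance={
        "source": "fixture_from_counts", "seed": seed,
        "counts": {"total": total, "dismissed": dismissed,
                   "under1": under1, "under2": under2, "under3": under3},
    })


def ground_truth_report(truth: GroundTruth) -> dict:
    """Machine-readable truth for parameter-recovery harnesses."""
    cfg = truth.config
    return {
        "seed": cfg.seed,
        "alpha_true": cfg.alpha_true,
        "beta0": cfg.beta0,
        "beta_H": cfg.beta_H,
        "sigma_u": cfg.sigma_u,
        "theta0": cfg.theta0,
        "theta1": cfg.theta1,
        "sigma_e": cfg.sigma_e,
        "latent_icc": cfg.sigma_u**2 / (cfg.sigma_u**2 + np.pi**2 / 3),
        "n_events": len(truth.latent),
        "n_physicians": cfg.n_physicians,
        "mean_H_pre": float(truth.latent["H_pre"].mean()),
        "dismissal_rate": float(truth.latent["dismissed"].mean()),
    }
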