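import numpy as np
import pandas as pd
import pytest

from alerthabit.event_log import COLUMNS, EventLog
from alerthabit.features import assemble_analysis_table
from alerthabit.simulate import SimulationConfig, simulate_log


def make_events(rows):
    """Build an event-log frame from (alert_id, physician, patient,
    timestamp, action, processing_time) tuples, filling covariates."""
    recs = []
    if not rows:
        df = pd.DataFrame({c: pd.Series(dtype=object) for c in COLUMNS})
        df["timestamp"] = pd.Series(dtype="datetime64[ns]")
        df["processing_time"] = pd.Series(dtype=float)
        df["ward_round"] = pd.Series(dtype=bool)
        for c in ("patient_age", "length_of_stay", "diagnosis_count"):
            df[c] = pd.Series(dtype=int)
        return EventLog(df[COLUMNS])
    for alert_id, phys, pat, ts, action, pt in rows:
        recs.append({
            "alert_id": alert_id, "physician_id": phys, "patient_id": pat,
            "timestamp": pd.Timestamp(ts), "action": action,
            "processing_time": float(pt), "ward_round": False,
            "physician_rank": "resident", "specialty": "General Medicine",
            "department": "Ward A", "patient_age": 68, "patient_gender": "F",
            "patient_race": "Chinese", "length_of_stay": 38,
            "diagnosis_count": 1,
        })
    return EventLog(pd.DataFrame(recs))


def random_log(rng: np.random.Generator, n_events: int, n_phys: int = 8,
               n_pat: int = 12) -> EventLog:
    """Small random log for brute-force cross-checks."""
    t0 = pd.Timestamp("2017-03-01")
    df = pd.DataFrame({
        "alert_id": [f"A{i:05d}" for i in range(n_events)],
        "physician_id": [f"P{j}" for j in rng.integers(0, n_phys, n_events)],
        "patient_id": [f"PT{j}" for j in rng.integers(0, n_pat, n_events)],
        "timestamp": t0 + pd.to_timedelta(
            rng.integers(0, 90 * 86400, n_events), unit="s"),
        "action": rng.choice(["dismiss", "acknowledge", "remove_order"],
                             n_events, p=[0.8, 0.1, 0.1]),
        "processing_time": np.round(rng.exponential(3.0, n_events), 3),
        "ward_round": rng.random(n_events) < 0.5,
        "physician_rank": rng.choice(
            ["intern", "resident", "fellow", "attending"], n_events),
        "specialty": "General Medicine",
        "department": "Ward A",
        "patient_age": rng.integers(16, 100, n_events),
        "patient_gender": rng.choice(["F", "M"], n_events),
        "patient_race": "Chinese",
        "length_of_stay": rng.integers(1, 60, n_events),
        "diagnosis_count": rng.integers(1, 3, n_events),
    })
    return EventLog(df)


@pytest.fixture(scope="session")
def small_sim():
    """One modest simulated dataset shared across read-only tests."""
    config = SimulationConfig(n_physicians=40, n_patients=80, seed=11)
    log, truth = simulate_log(config)
    return config, log, truth


@pytest.fixture(scope="session")
def small_table(small_sim):
    _, log, _ = small_sim
    return assemble_analysis_table(log)
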