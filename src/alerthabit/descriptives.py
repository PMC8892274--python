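"""Descriptive surface of the analysis: summary statistics, processing-time
distributions, mean processing time by exposure number, and analytic
habit-strength curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .habit_model import DEFAULT_ALPHAS, HabitParams, closed_form_constant_action, habit_column

#: variables summarised with mean/SD/min/max, where present
SUMMARY_VARIABLES = [
    "dismiss", "dismiss1", "dismiss2", "dismiss3",
    "H_0.01", "H_0.05", "H_0.1",
    "ward", "P_C_total", "P_C_ward", "C_total", "C_PatNum", "day_lag",
    "age", "gender", "los", "Diagnosis_count", "processing_time",
]

# analysis-table column -> conventional variable label
_ALIASES = {
    "ward": "ward_round",
    "age": "patient_age",
    "los": "length_of_stay",
    "Diagnosis_count": "diagnosis_count",
}


@dataclass
class SummaryTable:
    """Per-variable mean/SD/min/max plus dismissal-share percentages.

    ``percentages`` holds, on the 0-100 scale:
    ``pct_dismissed``; ``pct_under{K}_of_all`` and
    ``pct_under{K}_of_dismissed`` for each threshold K.
    """

    variables: pd.DataFrame
    percentages: dict = field(default_factory=dict)

    def rounded(self, decimals: int = 1) -> dict:
        """Percentages rounded for reporting (1 dp by convention)."""
        return {k: round(v, decimals) for k, v in self.percentages.items()}


def summarize_log(table: pd.DataFrame) -> SummaryTable:
    """Summary statistics and dismissal percentages for an analysis table."""
    if len(table) == 0:
        raise ValueError("cannot summarise an empty analysis table")
    rows = {}
    for name in SUMMARY_VARIABLES:
        col = _ALIASES.get(name, name)
        if col not in table.columns:
            continue
        x = pd.to_numeric(table[col].astype(float) if table[col].dtype == bool
                          else table[col], errors="coerce")
        rows[name] = {
            "mean": float(x.mean()),
            "sd": float(x.std(ddof=1)),
            "min": float(x.min()),
            "max": float(x.max()),
        }
    if "gender" not in rows and "patient_gender" in table.columns:
        g = (table["patient_gender"] == "F").astype(float)
        rows["gender"] = {"mean": float(g.mean()), "sd": float(g.std(ddof=1)),
                          "min": float(g.min()), "max": float(g.max())}
    variables = pd.DataFrame.from_dict(rows, orient="index")

    n = len(table)
    n_dismissed = int(table["dismiss"].sum())
    pct = {"pct_dismissed": 100.0 * n_dismissed / n}
    for k in (1, 2, 3):
        col = f"dismiss{k}"
        if col not in table.columns:
            continue
        n_k = int(table[col].sum())
        pct[f"pct_under{k}_of_all"] = 100.0 * n_k / n
        pct[f"pct_under{k}_of_dismissed"] = (
            100.0 * n_k / n_dismissed if n_dismissed else float("nan")
        )
    return SummaryTable(variables, pct)


def time_by_exposure(table: pd.DataFrame, max_exposure: int = 60) -> pd.DataFrame:
    """Mean processing time at each exposure number with a 95% CI.

    Exposure number is ``C_total``, the physician's k-th alert overall.
    The CI is the normal approximation mean +/- 1.96*SE; cells with a
    single observation report a missing CI, empty cells a missing mean.
    """
    rows = []
    grouped = table.groupby("C_total")["processing_time"]
    stats = grouped.agg(["mean", "std", "count"])
    for k in range(1, max_exposure + 1):
        if k in stats.index:
            m, s, c = stats.loc[k]
            se = s / np.sqrt(c) if c > 1 else np.nan
            rows.append({"exposure": k, "mean": m, "n": int(c),
                         "ci_low": m - 1.96 * se, "ci_high": m + 1.96 * se})
        else:
            rows.append({"exposure": k, "mean": np.nan, "n": 0,
                         "ci_low": np.nan, "ci_high": np.nan})
    return pd.DataFrame(rows)


def habit_curves(
    alphas: Iterable[float] = DEFAULT_ALPHAS, n_exposures: int = 120
) -> pd.DataFrame:
    """Analytic constant-dismissal habit curves 1-(1-alpha)^t, t=0..n."""
    t = np.arange(n_exposures + 1)
    out = pd.DataFrame({"exposure": t})
    for a in alphas:
        params = HabitParams(a)
        out[habit_column(a)] = [closed_form_constant_action(int(k), params) for k in t]
    return out


def time_distribution(
    table: pd.DataFrame,
    by: str | None = None,
    bin_width: float = 1.0,
    max_seconds: float = 10.0,
) -> pd.DataFrame:
    """Histogram of processing time among dismissed alerts.

    Fixed-width bins (default 1 s) up to ``max_seconds`` with an
    open-ended last bin; optionally stratified by a column such as
    ``physician_rank``.  Bin counts sum to the dismissed-alert count in
    every stratum, including empty strata.
    """
    dismissed = table[table["dismiss"] == 1]
    edges = np.arange(0.0, max_seconds + bin_width, bin_width)

    def _hist(x: pd.Series) -> pd.DataFrame:
        counts, _ = np.histogram(x, bins=edges)
        open_count = int((x >= edges[-1]).sum())
        labels = [f"[{edges[i]:g},{edges[i+1]:g})" for i in range(len(edges) - 1)]
        labels.append(f"[{edges[-1]:g},inf)")
        return pd.DataFrame({"bin": labels, "count": list(counts) + [open_count]})

    if by is None:
        return _hist(dismissed["processing_time"])
    frames = []
    if by == "physician_rank":
        from .event_log import RANKS
        categories = list(RANKS)  # absent ranks get zero-count bins
    else:
        categories = sorted(map(str, table[by].dropna().unique()))
    for cat in categories:
        sub = dismissed[dismissed[by].astype(str) == cat]
        h = _hist(sub["processing_time"])
        h.insert(0, by, cat)
        frames.append(h)
    return pd.concat(frames, ignore_index=True)


def plot_figures(
    table: pd.DataFrame, outdir, alphas: Sequence[float] = DEFAULT_ALPHAS
) -> list:
    """Write the figure analogues (PNG): processing-time histogram, mean
    time by exposure, distribution by rank, analytic habit curves."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    fig, ax = plt.subplots()
    ax.hist(table.loc[table["dismiss"] == 1, "processing_time"].clip(upper=15),
            bins=np.arange(0, 15.5, 0.5), color="steelblue")
    ax.set_xlabel("processing time (s)"); ax.set_ylabel("dismissed alerts")
    written.append(outdir / "processing_time_distribution.png")
    fig.savefig(written[-1], dpi=120); plt.close(fig)

    tbe = time_by_exposure(table)
    fig, ax = plt.subplots()
    ax.errorbar(tbe["exposure"], tbe["mean"],
                yerr=1.96 * np.nan_to_num((tbe["ci_high"] - tbe["mean"]) / 1.96),
                fmt="o-", ms=3, lw=1)
    ax.set_xlabel("alert exposure number"); ax.set_ylabel("mean processing time (s)")
    written.append(outdir / "time_by_exposure.png")
    fig.savefig(written[-1], dpi=120); plt.close(fig)

    curves = habit_curves(alphas)
    fig, ax = plt.subplots()
    for a in alphas:
        ax.plot(curves["exposure"], curves[habit_column(a)], label=f"alpha={a:g}")
    ax.set_xlabel("alert exposures"); ax.set_ylabel("habit strength"); ax.legend()
    written.append(outdir / "habit_curves.png")
    fig.savefig(written[-1], dpi=120); plt.close(fig)

    if "physician_rank" in table.columns:
        fig, ax = plt.subplots()
        for rank, sub in table[table["dismiss"] == 1].groupby("physician_rank"):
            ax.hist(sub["processing_time"].clip(upper=15), bins=30, alpha=0.5,
                    label=str(rank), density=True)
        ax.set_xlabel("processing time (s)"); ax.legend()
        written.append(outdir / "time_by_rank.png")
        fig.savefig(written[-1], dpi=120); plt.close(fig)
    return written
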