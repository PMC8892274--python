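"""Simulation-based validation studies: parameter recovery, null
calibration, ICC recovery, and latency-model sign checks.

Each study repeatedly draws synthetic logs from :mod:`alerthabit.simulate`,
runs the full analysis path (habit attachment, feature building, model
fit), and summarises how well the fitted quantities recover the
generator's ground truth.  The fits control for the covariates the
generator actually uses (ward round, patient age, length of stay;
physician rank is group-constant and absorbed by the grouping).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .features import assemble_analysis_table
from .regression import (
    ModelSpec,
    fit_fe_logit,
    fit_processing_time,
    fit_re_logit,
)
from .simulate import SimulationConfig, simulate_log

#: covariates with true nonzero effects in the generator
RECOVERY_COVARIATES = ["ward_round", "patient_age", "length_of_stay"]


def _one_dataset(seed: int, **config_kwargs) -> pd.DataFrame:
    log, _ = simulate_log(SimulationConfig(seed=seed, **config_kwargs))
    return assemble_analysis_table(log)


def fe_recovery_study(
    seeds: Sequence[int],
    beta_H: float = 1.0,
    habit: str = "H_0.05",
    **config_kwargs,
) -> pd.DataFrame:
    """Fixed-effects logistic recovery of the habit coefficient.

    One simulated dataset per seed at the default generative conditions
    (overridable); returns per-seed estimate, standard error, 95% CI and
    whether the CI covers the true value.
    """
    rows = []
    for seed in seeds:
        table = _one_dataset(seed, beta_H=beta_H, **config_kwargs)
        res = fit_fe_logit(table, ModelSpec(
            habit=habit, covariates=RECOVERY_COVARIATES))
        t = res.terms.loc[habit]
        rows.append({
            "seed": seed,
            "beta_hat": t["coef"], "se": t["se"],
            "ci_low": t["ci_low"], "ci_high": t["ci_high"],
            "pvalue": t["pvalue"],
            "covers_truth": bool(t["ci_low"] <= beta_H <= t["ci_high"]),
            "converged": res.converged,
        })
    return pd.DataFrame(rows)


def summarize_recovery(study: pd.DataFrame, truth: float) -> dict:
    return {
        "truth": truth,
        "n_replicates": len(study),
        "mean_estimate": float(study["beta_hat"].mean()),
        "mean_bias": float(study["beta_hat"].mean() - truth),
        "mean_bias_pct": (float("nan") if truth == 0 else
                          100.0 * float(study["beta_hat"].mean() - truth) / truth),
        "ci_coverage_pct": 100.0 * float(study["covers_truth"].mean()),
        "rejection_rate_pct": 100.0 * float((study["pvalue"] < 0.05).mean()),
    }


def null_calibration_study(seeds: Sequence[int], **config_kwargs) -> dict:
    """Rejection rate of the habit coefficient's nominal-5% Wald test
    when the generator's habit effect is exactly zero."""
    study = fe_recovery_study(seeds, beta_H=0.0, **config_kwargs)
    return {
        "n_replicates": len(study),
        "rejection_rate_pct": 100.0 * float((study["pvalue"] < 0.05).mean()),
        "mean_estimate": float(study["beta_hat"].mean()),
    }


def icc_recovery_study(
    seed: int = 7,
    n_physicians: int = 300,
    target_icc: float = 0.5,
    **config_kwargs,
) -> dict:
    """Random-effects logistic recovery of the latent-threshold ICC.

    The generator's intercept SD is chosen so the true latent ICC equals
    ``target_icc`` (sigma_u^2 = icc/(1-icc) * pi^2/3).
    """
    sigma_u = math.sqrt(target_icc / (1.0 - target_icc) * math.pi**2 / 3.0)
    table = _one_dataset(seed, n_physicians=n_physicians, sigma_u=sigma_u,
                         **config_kwargs)
    res = fit_re_logit(table, ModelSpec(
        covariates=RECOVERY_COVARIATES, estimator="random_effects"))
    return {
        "target_icc": target_icc,
        "sigma_u_true": sigma_u,
        "icc_hat": float(res.icc),
        "sigma_u2_hat": float(res.sigma_u2),
        "beta_H_hat": float(res.terms.loc["H_0.05", "coef"]),
        "converged": bool(res.converged),
    }


def latency_recovery_study(
    seeds: Sequence[int],
    habit: str = "H_0.05",
    **config_kwargs,
) -> dict:
    """Sign recovery in the fixed-effects processing-time model.

    With the generator shortening latency as habit grows (theta1 > 0),
    counts how often the fitted habit coefficient is negative with a 95%
    CI excluding zero.
    """
    neg, neg_excl = 0, 0
    coefs = []
    for seed in seeds:
        table = _one_dataset(seed, **config_kwargs)
        res = fit_processing_time(table, estimator="fixed_effects",
                                  habit=habit, covariates=RECOVERY_COVARIATES)
        t = res.terms.loc[habit]
        coefs.append(t["coef"])
        neg += t["coef"] < 0
        neg_excl += (t["coef"] < 0) and (t["ci_high"] < 0)
    n = len(seeds)
    return {
        "n_replicates": n,
        "negative_pct": 100.0 * neg / n,
        "negative_ci_excluding_zero_pct": 100.0 * neg_excl / n,
        "mean_coefficient": float(np.mean(coefs)),
    }
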