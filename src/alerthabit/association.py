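"""Pairwise correlations between outcomes and habit-strength predictors.

Binary-vs-continuous pairs use the point-biserial correlation (computed
from the class-means formula, numerically identical to Pearson on the 0/1
coding); continuous pairs use Pearson; binary-binary pairs use the phi
coefficient (Pearson on 0/1).  Two-sided p-values come from the
t-distribution with n-2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CorrelationMatrix:
    variables: list[str]
    values: pd.DataFrame    # symmetric coefficients, diagonal 1
    pvalues: pd.DataFrame
    methods: pd.DataFrame   # per-cell label: point_biserial | pearson | phi

    def to_long(self) -> pd.DataFrame:
        """Long-format (var1, var2, r, p, method), upper triangle."""
        rows = []
        for i, v1 in enumerate(self.variables):
            for v2 in self.variables[i + 1:]:
                rows.append({
                    "var1": v1, "var2": v2,
                    "r": self.values.loc[v1, v2],
                    "p": self.pvalues.loc[v1, v2],
                    "method": self.methods.loc[v1, v2],
                })
        return pd.DataFrame(rows)


def _corr_pvalue(r: float, n: int) -> float:
    if n < 3:
        return float("nan")  # t test has 0 degrees of freedom
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def point_biserial(binary, continuous) -> tuple[float, float]:
    """Point-biserial correlation and its two-sided p-value.

    r = (m1 - m0)/s * sqrt(n1*n0/n^2) with s the population SD of the
    continuous variable; the significance test is the usual t with n-2 df.

    Raises if the binary vector is single-class or the continuous vector
    is constant (the correlation is undefined).
    """
    b = np.asarray(binary, dtype=float)
    x = np.asarray(continuous, dtype=float)
    if b.shape != x.shape or b.ndim != 1:
        raise ValueError("inputs must be 1-d vectors of equal length")
    n = b.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    if not np.isin(b, (0.0, 1.0)).all():
        raise ValueError("binary vector must be 0/1 coded")
    n1 = int(b.sum())
    n0 = n - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("binary vector has a single class; correlation undefined")
    s = x.std(ddof=0)
    if s == 0:
        raise ValueError("continuous vector is constant; correlation undefined")
    m1 = x[b == 1].mean()
    m0 = x[b == 0].mean()
    r = (m1 - m0) / s * np.sqrt(n1 * n0 / n**2)
    r = float(np.clip(r, -1.0, 1.0))
    return r, _corr_pvalue(r, n)


def _is_binary(x: pd.Series) -> bool:
    vals = pd.unique(pd.to_numeric(x, errors="coerce").dropna())
    return len(vals) <= 2 and np.isin(vals, (0, 1)).all()


def correlation_matrix(
    table: pd.DataFrame,
    variables: Sequence[str],
    binary: Sequence[str] | None = None,
) -> CorrelationMatrix:
    """Symmetric correlation matrix over ``variables``.

    ``binary`` names the 0/1 columns; by default they are auto-detected.
    Exactly-one-binary pairs are labelled point_biserial, two-binary pairs
    phi, others pearson.  Cells involving a constant column are NaN.
    """
    variables = list(variables)
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise KeyError(f"variables not in table: {missing}")
    if binary is None:
        binary = [v for v in variables if _is_binary(table[v])]
    binary = set(binary)

    k = len(variables)
    vals = pd.DataFrame(np.eye(k), index=variables, columns=variables)
    pvs = pd.DataFrame(np.zeros((k, k)), index=variables, columns=variables)
    methods = pd.DataFrame("", index=variables, columns=variables)
    n = len(table)
    for i, v1 in enumerate(variables):
        methods.loc[v1, v1] = "identity"
        for v2 in variables[i + 1:]:
            x1 = pd.to_numeric(table[v1], errors="coerce").to_numpy(dtype=float)
            x2 = pd.to_numeric(table[v2], errors="coerce").to_numpy(dtype=float)
            b1, b2 = v1 in binary, v2 in binary
            method = ("phi" if b1 and b2
                      else "point_biserial" if b1 or b2
                      else "pearson")
            try:
                if method == "point_biserial":
                    bvec, cvec = (x1, x2) if b1 else (x2, x1)
                    r, p = point_biserial(bvec, cvec)
                else:
                    if x1.std() == 0 or x2.std() == 0:
                        raise ValueError("constant column")
                    r, p = stats.pearsonr(x1, x2)
            except ValueError:
                r, p = np.nan, np.nan
            vals.loc[v1, v2] = vals.loc[v2, v1] = r
            pvs.loc[v1, v2] = pvs.loc[v2, v1] = p
            methods.loc[v1, v2] = methods.loc[v2, v1] = method
    return CorrelationMatrix(variables, vals, pvs, methods)
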