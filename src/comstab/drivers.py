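"""Environmental driver screening: Spearman correlation tables between
environmental variables and community responses (diversity, cohesion,
stability), plus simple linear regressions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import EnvMatrix
from .network import _bh_adjust

__all__ = ["DriverTable", "driver_correlations", "simple_regression", "significance_stars"]


def significance_stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class DriverTable:
    """Long-format table of (variable, response) Spearman correlations."""

    frame: pd.DataFrame  # columns: variable, response, rho, p, q, stars

    def pivot(self, value: str = "rho") -> pd.DataFrame:
        return self.frame.pivot(index="variable", columns="response", values=value)


def driver_correlations(env: EnvMatrix, responses: pd.DataFrame,
                        correction: str = "none") -> DriverTable:
    """Spearman rho and p for every (environmental variable, response) pair.

    ``responses`` is a samples x responses DataFrame indexed by sample id.
    With ``correction="BH"`` q-values are adjusted within each response
    column and stars follow q; with ``"none"`` stars follow raw p (the
    convention of most published heatmaps). Constant variables yield NaN
    cells flagged not-computable rather than an error.
    """
    if correction not in ("none", "BH"):
        raise ValueError(f"unknown correction {correction!r}")
    env_df = env.to_frame().loc[list(responses.index)]
    rows = []
    for resp in responses.columns:
        y = responses[resp].to_numpy(dtype=float)
        if np.std(y) == 0:
            raise ValueError(f"response {resp!r} has zero variance")
        ps = []
        for var in env_df.columns:
            x = env_df[var].to_numpy(dtype=float)
            if np.std(x) == 0:
                rows.append({"variable": var, "response": resp,
                             "rho": np.nan, "p": np.nan})
                ps.append(np.nan)
                continue
            rho, p = stats.spearmanr(x, y)
            rows.append({"variable": var, "response": resp, "rho": float(rho), "p": float(p)})
            ps.append(float(p))
        ps = np.asarray(ps)
        ok = ~np.isnan(ps)
        q = np.full(ps.size, np.nan)
        if ok.any():
            q[ok] = _bh_adjust(ps[ok]) if correction == "BH" else ps[ok]
        for row, qv in zip(rows[-ps.size:], q):
            row["q"] = float(qv) if not np.isnan(qv) else np.nan
            row["stars"] = significance_stars(qv if correction == "BH" else row["p"])
    return DriverTable(pd.DataFrame(rows, columns=["variable", "response", "rho", "p", "q", "stars"]))


def simple_regression(x, y):
    """Ordinary least squares of y on x.

    Returns (slope, intercept, r_squared, p) with p the two-sided t-test on
    the slope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0:
        raise ValueError("x has zero variance")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2), float(res.pvalue)
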