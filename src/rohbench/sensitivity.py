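"""Sensitivity analysis of window-scan parameters via standardized
regression coefficients.

For each individual, the grid of tested parameter combinations yields a
response vector of called F_ROH values. Each varied parameter and the
response are standardized to zero mean and unit variance (SRC), or replaced
by their ranks before standardization (SRRC), and an OLS fit of the
standardized response on the standardized parameters gives one coefficient
per parameter — its sensitivity index. Parameters tested at a single value
are excluded and reported as fixed.

The per-parameter recommendation aggregates indices across individuals:
if the median index and its interquartile range are both below a tolerance,
the parameter can stay at its default; otherwise it is worth exploring, in
the direction of the index's sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["SRCResult", "src", "recommend"]

#: Parameter columns understood as grid axes in a grid_call frame.
PARAM_COLUMNS = ("phwh", "phwm", "phws", "phzd", "phzg", "phwt", "phzs", "phzk")


@dataclass(frozen=True)
class SRCResult:
    individual: int
    method: str                       # "SRC" | "SRRC"
    coefficients: dict[str, float]    # per varied parameter
    intercept: float
    weights: dict[str, float]         # unstandardized OLS weights
    fixed_parameters: tuple[str, ...]


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def src(grid_result: pd.DataFrame, individual: int,
        method: str = "SRC") -> SRCResult:
    """Standardized (rank) regression coefficients for one individual.

    ``grid_result`` is the tidy frame from ``winroh.grid_call``: one row per
    (combination, individual) with the parameter values and the called
    F_ROH response.
    """
    if method not in ("SRC", "SRRC"):
        raise ValueError("method must be 'SRC' or 'SRRC'")
    sub = grid_result[grid_result["individual"] == individual]
    if sub.empty:
        raise ValueError(f"no grid rows for individual {individual}")
    params = [c for c in PARAM_COLUMNS if c in sub.columns]
    varied = [c for c in params if sub[c].nunique() > 1]
    fixed = tuple(c for c in params if c not in varied)
    if not varied:
        raise ValueError("grid varies no parameter")
    if len(sub) < len(varied) + 1:
        raise ValueError(
            f"{len(sub)} combinations cannot identify {len(varied)} "
            "parameters plus an intercept")

    X = sub[varied].to_numpy(dtype=float)
    y = sub["froh"].to_numpy(dtype=float)
    if y.std(ddof=1) == 0:
        coeffs = {c: 0.0 for c in varied}
        return SRCResult(individual, method, coeffs, float(y.mean()),
                         {c: 0.0 for c in varied}, fixed)

    if method == "SRRC":
        X = np.column_stack([rankdata(X[:, k]) for k in range(X.shape[1])])
        y = rankdata(y)
    Xz = np.column_stack([_zscore(X[:, k]) for k in range(X.shape[1])])
    yz = _zscore(y)
    A = np.column_stack([np.ones(len(yz)), Xz])
    beta, *_ = np.linalg.lstsq(A, yz, rcond=None)
    coeffs = dict(zip(varied, beta[1:].tolist()))

    # unstandardized model F_ROH = a + sum b_i x_i on the same scale
    Araw = np.column_stack([np.ones(len(y)), X])
    braw, *_ = np.linalg.lstsq(Araw, y, rcond=None)
    return SRCResult(individual, method, coeffs, float(braw[0]),
                     dict(zip(varied, braw[1:].tolist())), fixed)


def recommend(src_results: list[SRCResult], tol: float = 0.05) -> pd.DataFrame:
    """Per-parameter recommendation from per-individual sensitivity indices.

    A parameter is recommended to stay at its "default" when the absolute
    median index and the interquartile range across individuals are both
    below ``tol``; otherwise it is marked "explore" with the direction in
    which increasing the parameter moves F_ROH.
    """
    if not src_results:
        raise ValueError("need at least one individual's SRC result")
    params = sorted({p for r in src_results for p in r.coefficients})
    rows = []
    for p in params:
        vals = np.array([r.coefficients[p] for r in src_results
                         if p in r.coefficients])
        med = float(np.median(vals))
        q1, q3 = np.percentile(vals, [25, 75])
        iqr = float(q3 - q1)
        if abs(med) < tol and iqr < tol:
            rec, direction = "default", "none"
        else:
            rec = "explore"
            direction = "positive" if med > 0 else ("negative" if med < 0 else "flat")
        rows.append({"parameter": p, "median_src": med, "iqr": iqr,
                     "recommendation": rec, "direction": direction,
                     "n_individuals": len(vals)})
    return pd.DataFrame(rows)
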