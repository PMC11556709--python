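"""Sliding-window ROH scanner in the style of PLINK ``--homozyg``.

The scan proceeds in four steps for one individual:

1. every window of ``phws`` consecutive sites (by SNP index; a chromosome
   with fewer sites yields a single truncated window) is *homozygous* iff
   it contains at most ``phwh`` heterozygous and at most ``phwm`` missing
   calls;
2. each site's hit fraction is the share of the windows containing it that
   are homozygous (edge sites are contained in fewer windows); a site is
   in-ROH iff its fraction is >= ``phwt``;
3. maximal runs of consecutive in-ROH sites are split wherever two adjacent
   sites lie more than ``phzg`` kb apart;
4. a run is reported iff it has >= ``phzs`` sites, spans >= ``phzk`` kb,
   and its span per site is <= ``phzd`` kb (minimum SNP density).

All threshold comparisons are closed as written; the reported interval runs
from the first to the last site of the run (half-open end = last + 1).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, fields, replace

import numpy as np
import pandas as pd

from .intervals import ROHInterval, ROHSet
from .hmmroh import ROHCall
from .seqemu import MISSING, VariantTable
from .simdemog import MIN_ROH_LEN

logger = logging.getLogger(__name__)

__all__ = ["WindowParams", "window_call", "grid_call", "initial_grid",
           "calls_to_rohset"]


@dataclass(frozen=True)
class WindowParams:
    """Sliding-window scan parameters (kb units where noted)."""

    phwh: int = 1        # max het calls per window
    phwm: int = 5        # max missing calls per window
    phws: int = 50       # window length in SNPs
    phzd: float = 50.0   # max kb per variant (inverse density)
    phzg: float = 1000.0  # max gap in kb before splitting a run
    phwt: float = 0.05   # min proportion of overlapping homozygous windows
    phzs: int = 100      # min SNPs per reported ROH
    phzk: float = 1000.0  # min ROH span in kb

    def __post_init__(self):
        if self.phws < 1:
            raise ValueError("phws (window length in SNPs) must be >= 1")
        if not 0 <= self.phwt <= 1:
            raise ValueError("phwt must be in [0, 1]")
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")


#: The initial grid of tested value sets (varied parameters only; phzd and
#: phzk are held at a single value).
INITIAL_GRID_VALUES = {
    "phwh": (0, 1, 2),
    "phwm": (2, 5, 50),
    "phws": (50, 100, 1000),
    "phzd": (50.0,),
    "phzg": (500.0, 1000.0),
    "phwt": (0.01, 0.05, 0.1),
    "phzs": (10, 100, 1000),
    "phzk": (100.0,),
}


def initial_grid(values: dict | None = None) -> list[WindowParams]:
    """Cartesian product of tested parameter value sets (486 combinations
    for the default value sets)."""
    values = values or INITIAL_GRID_VALUES
    names = list(values)
    combos = []
    for combo in itertools.product(*(values[n] for n in names)):
        combos.append(WindowParams(**dict(zip(names, combo))))
    return combos


def _moving_sum(x: np.ndarray, w: int) -> np.ndarray:
    c = np.concatenate([[0], np.cumsum(x)])
    return c[w:] - c[:-w]


def window_call(vt: VariantTable, individual: int,
                p: WindowParams = WindowParams()) -> list[ROHCall]:
    """Run the four-step window scan for one individual."""
    n = vt.n_sites
    if n == 0:
        logger.warning("no sites; window scan returns no calls")
        return []
    gt = vt.gt[individual]
    pos = vt.positions
    het = (gt == 1).astype(np.int64)
    miss = (gt == MISSING).astype(np.int64)

    w = min(p.phws, n)
    hom_win = ((_moving_sum(het, w) <= p.phwh)
               & (_moving_sum(miss, w) <= p.phwm)).astype(np.int64)
    n_win = n - w + 1
    # windows containing site i: indices [max(0, i-w+1), min(i, n_win-1)]
    i = np.arange(n)
    lo = np.maximum(0, i - w + 1)
    hi = np.minimum(i, n_win - 1)
    cum = np.concatenate([[0], np.cumsum(hom_win)])
    hits = cum[hi + 1] - cum[lo]
    denom = hi - lo + 1
    in_roh = hits / denom >= p.phwt

    calls: list[ROHCall] = []
    # maximal runs of in-ROH sites, split at big gaps
    gap_split = np.zeros(n, dtype=bool)
    gap_split[1:] = np.diff(pos) > p.phzg * 1000
    run_start = None
    for j in range(n + 1):
        boundary = j == n or not in_roh[j] or (run_start is not None and gap_split[j])
        if run_start is not None and boundary:
            first, last = run_start, j - 1
            count = last - first + 1
            span = int(pos[last]) - int(pos[first]) + 1
            if (count >= p.phzs and span >= p.phzk * 1000
                    and span / count <= p.phzd * 1000):
                calls.append(ROHCall(ROHInterval(int(pos[first]), int(pos[last]) + 1),
                                     n_sites=count, method="window"))
            run_start = None
        if j < n and in_roh[j] and run_start is None:
            run_start = j
    return calls


def calls_to_rohset(calls: list[ROHCall], min_len: int = 0) -> ROHSet:
    """Collect calls into a disjoint ROHSet, merging any overlapping
    intervals and applying a closed length filter."""
    from .intervals import merge

    if not calls:
        return ROHSet(min_len=min_len)
    arr = merge([(c.interval.start, c.interval.end) for c in calls])
    keep = arr[:, 1] - arr[:, 0] >= min_len
    return ROHSet(arr[keep], min_len=min_len)


def grid_call(vt: VariantTable, grid: list[WindowParams],
              L: int | None = None, min_len: int = MIN_ROH_LEN) -> pd.DataFrame:
    """Run :func:`window_call` for every (combination, individual).

    Returns a tidy frame with one row per pair: the combination id, the
    parameter values, and the individual's called F_ROH after the global
    ``min_len`` filter. ``L`` defaults to (last position + 1).
    """
    if not grid:
        raise ValueError("parameter grid is empty")
    if len(set(grid)) < len(grid):
        logger.warning("duplicate parameter combinations in grid; duplicate "
                       "result rows will be produced")
    if L is None:
        L = int(vt.positions[-1]) + 1 if vt.n_sites else 1
    rows = []
    for cid, p in enumerate(grid):
        for ind in range(vt.n_individuals):
            calls = window_call(vt, ind, p)
            fr = calls_to_rohset(calls, min_len=min_len).total_length / L
            row = {"combination": cid, "individual": ind, "froh": fr}
            row.update({f.name: getattr(p, f.name) for f in fields(p)})
            rows.append(row)
    return pd.DataFrame(rows)
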