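"""Accuracy evaluation of called ROHs against the simulated truth.

Per-base error rates use exact interval arithmetic:

* false negative rate = bp covered by true ROHs but not by called ROHs,
  divided by the total length of true ROHs (undefined when there are no
  true ROHs);
* false positive rate = bp covered by called ROHs but not by true ROHs,
  divided by the chromosomal length not covered by true ROHs (undefined
  when truth covers the whole chromosome).

Undefined rates are reported as NaN and excluded from medians downstream.

F_ROH is additionally decomposed into four ROH length bins (short
[100 kb, 500 kb), intermediate [500 kb, 1 Mb), long [1 Mb, 2 Mb), very long
[2 Mb, inf)), each ROH assigned whole to the bin of its own length, and
called-minus-true per-bin differences are summarized by their mean and a
2.5%/97.5% percentile interval across individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .intervals import ROHSet, intersect, subtract, total_length

__all__ = [
    "LengthBins",
    "AccuracyResult",
    "LumpingRecord",
    "RegressionFit",
    "fn_fp_rates",
    "binned_froh",
    "lumping_counts",
    "fit_true_vs_called",
    "bin_error_summary",
]


@dataclass(frozen=True)
class LengthBins:
    """Half-open ROH length bins; the last bin is unbounded."""

    edges: tuple[float, ...] = (100_000, 500_000, 1_000_000, 2_000_000, np.inf)
    labels: tuple[str, ...] = ("short", "intermediate", "long", "very_long")

    def __post_init__(self):
        if len(self.edges) != len(self.labels) + 1:
            raise ValueError("need one more edge than labels")
        if list(self.edges) != sorted(self.edges):
            raise ValueError("edges must increase")

    def assign(self, lengths: np.ndarray) -> np.ndarray:
        """Bin index per length; -1 for lengths below the first edge."""
        idx = np.searchsorted(np.asarray(self.edges), lengths, side="right") - 1
        idx[idx >= len(self.labels)] = len(self.labels) - 1
        return idx


@dataclass(frozen=True)
class AccuracyResult:
    fn_rate: float
    fp_rate: float

    def __post_init__(self):
        for v in (self.fn_rate, self.fp_rate):
            if not np.isnan(v) and not 0 <= v <= 1:
                raise ValueError("rates must lie in [0, 1] (or NaN)")


@dataclass(frozen=True)
class LumpingRecord:
    """Overlap tabulation between true and called ROHs (>=1 shared bp).

    ``true_per_called`` holds, for every called ROH, the number of true ROHs
    it overlaps, alongside the called ROH's length bin; ``called_per_true``
    holds the converse count per true ROH. ``n_split`` counts true ROHs that
    overlap two or more called ROHs.
    """

    true_per_called: np.ndarray
    called_bin: np.ndarray
    called_per_true: np.ndarray
    n_split: int

    @property
    def mean_true_per_called(self) -> float:
        return float(np.mean(self.true_per_called)) if len(self.true_per_called) else np.nan


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    n: int
    #: whether the 95% CI for the intercept excludes 0 / the slope excludes 1
    intercept_differs_from_zero: bool = False
    slope_differs_from_one: bool = False

    def __post_init__(self):
        if not (self.slope_ci[0] <= self.slope <= self.slope_ci[1]
                and self.intercept_ci[0] <= self.intercept <= self.intercept_ci[1]):
            raise ValueError("estimate outside its confidence interval")


def fn_fp_rates(true_set: ROHSet, called_set: ROHSet, L: int) -> AccuracyResult:
    """Per-base false negative and false positive rates by exact interval
    arithmetic on a chromosome of length ``L``."""
    t = true_set.intervals
    c = called_set.intervals
    len_true = total_length(t)
    if len_true == 0:
        fn = np.nan
    else:
        fn = total_length(subtract(t, c)) / len_true
    if len_true == L:
        fp = np.nan
    else:
        fp = total_length(subtract(c, t)) / (L - len_true)
    return AccuracyResult(fn_rate=fn, fp_rate=fp)


def binned_froh(rohs: ROHSet, bins: LengthBins, L: int) -> np.ndarray:
    """Per-bin F_ROH: each ROH contributes its whole length to the single
    bin matching that length. The bin values sum to the overall F_ROH."""
    out = np.zeros(len(bins.labels))
    if len(rohs) == 0:
        return out
    lengths = rohs.intervals[:, 1] - rohs.intervals[:, 0]
    idx = bins.assign(lengths)
    if np.any(idx < 0):
        raise ValueError("ROH shorter than the first bin edge; filter first")
    np.add.at(out, idx, lengths)
    return out / L


def lumping_counts(true_set: ROHSet, called_set: ROHSet,
                   bins: LengthBins | None = None) -> LumpingRecord:
    """How many true ROHs each called ROH overlaps, and vice versa."""
    bins = bins or LengthBins()
    t = true_set.intervals
    c = called_set.intervals
    true_per_called = np.zeros(len(c), dtype=np.int64)
    called_per_true = np.zeros(len(t), dtype=np.int64)
    for i, (cs, ce) in enumerate(c):
        lo = np.searchsorted(t[:, 1], cs, side="right") if len(t) else 0
        k = lo
        while k < len(t) and t[k, 0] < ce:
            true_per_called[i] += 1
            called_per_true[k] += 1
            k += 1
    called_bin = (bins.assign(c[:, 1] - c[:, 0]) if len(c)
                  else np.empty(0, np.int64))
    return LumpingRecord(true_per_called, called_bin, called_per_true,
                         n_split=int(np.sum(called_per_true >= 2)))


def fit_true_vs_called(pairs) -> RegressionFit:
    """OLS of called F_ROH on true F_ROH with Student-t 95% CIs.

    Flags whether the intercept CI excludes 0 and the slope CI excludes 1.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (true, called) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: true F_ROH has zero variance")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    intercept_ci = (float(ci[0, 0]), float(ci[0, 1]))
    slope_ci = (float(ci[1, 0]), float(ci[1, 1]))
    return RegressionFit(
        slope=float(model.params[1]), intercept=float(model.params[0]),
        slope_ci=slope_ci, intercept_ci=intercept_ci, n=len(x),
        intercept_differs_from_zero=not intercept_ci[0] <= 0 <= intercept_ci[1],
        slope_differs_from_one=not slope_ci[0] <= 1 <= slope_ci[1])


def bin_error_summary(differences: np.ndarray) -> dict:
    """Mean and 2.5%/97.5% percentile interval of per-individual
    called-minus-true bin F_ROH differences (negative = underestimation)."""
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise ValueError("need >= 2 individuals")
    lo, hi = np.percentile(d, [2.5, 97.5])
    return {"mean": float(d.mean()), "lo": float(lo), "hi": float(hi)}


def bootstrap_mean_ci(values: np.ndarray, n_boot: int = 1000,
                      seed: int = 0, alpha: float = 0.05) -> tuple[float, float, float]:
    """Percentile bootstrap CI for a mean (seeded, 1,000 resamples)."""
    v = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    boots = rng.choice(v, size=(n_boot, v.size), replace=True).mean(axis=1)
    lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(v.mean()), float(lo), float(hi)
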