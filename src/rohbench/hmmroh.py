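"""Two-state autozygosity HMM caller with Viterbi decoding and Viterbi
training, in the style of likelihood-based ROH callers for multi-sample VCFs.

Hidden states are HW (Hardy–Weinberg, non-autozygous) and AZ (autozygous).
At a site with sample alternate-allele frequency ``p`` the emission
distributions over called genotypes are

* HW: ``{(1-p)^2, 2p(1-p), p^2}`` (Hardy–Weinberg proportions),
* AZ: ``{(1-p)(1-leak), leak, p(1-leak)}`` where ``leak`` absorbs
  genotyping errors observed as heterozygotes inside autozygous tracts.

``genotypes`` mode scores the called genotype; ``likelihoods`` mode scores
``sum_g P(reads|g) P(g|state)`` using the de-phredded PL triple. Transitions
between adjacent retained sites a distance ``d`` bp apart switch state with
probability ``1 - exp(-rate * d)``; missing genotypes are skipped while
distance keeps accumulating. Decoding is exact Viterbi in log space.

Viterbi training re-estimates the two per-bp switch rates from hard state
assignments: rate = (# observed switches out of a state) / (total bp
traversed while in that state), iterated to a fixed point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .intervals import ROHInterval
from .seqemu import MISSING, VariantTable

logger = logging.getLogger(__name__)

__all__ = ["HMMParams", "ROHCall", "TrainedParams", "hmm_call", "viterbi_train"]

#: Lower floor for trained per-bp transition rates (degenerate counts).
RATE_FLOOR = 1e-12

#: Default per-bp transition rates (HW->AZ, AZ->HW).
DEFAULT_HW_TO_AZ = 6.7e-8
DEFAULT_AZ_TO_HW = 5e-9


@dataclass(frozen=True)
class HMMParams:
    hw_to_az: float = DEFAULT_HW_TO_AZ
    az_to_hw: float = DEFAULT_AZ_TO_HW
    mode: str = "genotypes"              # "genotypes" | "likelihoods"
    az_het_leak: float = 1e-4
    start_probs: tuple[float, float] = (0.5, 0.5)   # (P(HW), P(AZ))
    train: bool = False
    convergence: float = 1e-10
    max_iter: int = 100

    def __post_init__(self):
        if self.hw_to_az <= 0 or self.az_to_hw <= 0:
            raise ValueError("transition rates must be > 0")
        if self.mode not in ("genotypes", "likelihoods"):
            raise ValueError("mode must be 'genotypes' or 'likelihoods'")
        if not (0 < self.az_het_leak < 1):
            raise ValueError("az_het_leak must be in (0, 1)")
        if not all(0 < q < 1 for q in self.start_probs):
            raise ValueError("start probabilities must be in (0, 1)")


@dataclass(frozen=True)
class ROHCall:
    """A called ROH spanning the first to last AZ-labelled site."""

    interval: ROHInterval
    n_sites: int
    method: str = "hmm"

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("an ROH call must contain at least one site")


@dataclass(frozen=True)
class TrainedParams:
    hw_to_az: float
    az_to_hw: float
    iterations: int
    converged: bool
    #: total Viterbi log-score after each iteration's decode
    score_history: tuple[float, ...] = ()
    excluded_individuals: tuple[int, ...] = ()


@njit(cache=True)
def _viterbi_core(log_em, dists, r01, r10, ls0, ls1):
    """Exact 2-state Viterbi with distance-dependent transitions.

    Returns (states, score): the argmax state path and its log probability.
    """
    n = log_em.shape[0]
    back = np.empty((n, 2), np.int8)
    v0 = ls0 + log_em[0, 0]
    v1 = ls1 + log_em[0, 1]
    for i in range(1, n):
        d = dists[i - 1]
        stay0 = -r01 * d                      # log exp(-r*d)
        stay1 = -r10 * d
        sw01 = np.log(-np.expm1(-r01 * d))    # log(1 - exp(-r*d))
        sw10 = np.log(-np.expm1(-r10 * d))
        a0 = v0 + stay0
        b0 = v1 + sw10
        if a0 >= b0:
            nv0 = a0 + log_em[i, 0]
            back[i, 0] = 0
        else:
            nv0 = b0 + log_em[i, 0]
            back[i, 0] = 1
        a1 = v0 + sw01
        b1 = v1 + stay1
        if b1 >= a1:
            nv1 = b1 + log_em[i, 1]
            back[i, 1] = 1
        else:
            nv1 = a1 + log_em[i, 1]
            back[i, 1] = 0
        v0, v1 = nv0, nv1
    states = np.empty(n, np.int8)
    if v1 > v0:
        states[n - 1] = 1
        score = v1
    else:
        states[n - 1] = 0
        score = v0
    for i in range(n - 1, 0, -1):
        states[i - 1] = back[i, states[i]]
    return states, score


def _log_emissions(gt: np.ndarray, pl: np.ndarray, af: np.ndarray,
                   mode: str, leak: float) -> np.ndarray:
    """Natural-log emission matrix (n_sites, 2) for one individual's
    non-missing sites."""
    p = np.clip(af, 1e-12, 1.0 - 1e-12)
    probs_hw = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p ** 2], axis=1)
    probs_az = np.stack([(1 - p) * (1 - leak),
                         np.full_like(p, leak),
                         p * (1 - leak)], axis=1)
    if mode == "genotypes":
        idx = gt.astype(np.int64)
        e_hw = probs_hw[np.arange(len(gt)), idx]
        e_az = probs_az[np.arange(len(gt)), idx]
    else:
        read_lik = np.power(10.0, -pl.astype(np.float64) / 10.0)  # (n, 3)
        e_hw = (read_lik * probs_hw).sum(axis=1)
        e_az = (read_lik * probs_az).sum(axis=1)
    with np.errstate(divide="ignore"):
        return np.log(np.stack([e_hw, e_az], axis=1))


def _individual_sites(vt: VariantTable, individual: int):
    mask = vt.gt[individual] != MISSING
    return (vt.positions[mask], vt.gt[individual, mask],
            vt.pl[individual, mask], vt.af[mask])


def _decode(vt: VariantTable, individual: int, params: HMMParams):
    pos, gt, pl, af = _individual_sites(vt, individual)
    if pos.size == 0:
        return pos, None, 0.0
    log_em = _log_emissions(gt, pl, af, params.mode, params.az_het_leak)
    dists = np.diff(pos).astype(np.float64)
    states, score = _viterbi_core(
        log_em, dists, params.hw_to_az, params.az_to_hw,
        np.log(params.start_probs[0]), np.log(params.start_probs[1]))
    return pos, states, score


def _calls_from_states(pos: np.ndarray, states: np.ndarray,
                       method: str) -> list[ROHCall]:
    calls = []
    in_az = states == 1
    if not np.any(in_az):
        return calls
    # run boundaries of consecutive AZ-labelled sites
    edges = np.flatnonzero(np.diff(np.concatenate([[0], in_az.view(np.int8), [0]])))
    for lo, hi in zip(edges[::2], edges[1::2]):
        calls.append(ROHCall(
            ROHInterval(int(pos[lo]), int(pos[hi - 1]) + 1),
            n_sites=int(hi - lo), method=method))
    return calls


def hmm_call(vt: VariantTable, individual: int,
             params: HMMParams = HMMParams()) -> list[ROHCall]:
    """Viterbi-decode one individual and return maximal AZ runs as ROH calls.

    Sites with a missing genotype are skipped; an individual with no
    informative site yields an empty call list (with a warning).
    """
    pos, states, _ = _decode(vt, individual, params)
    if states is None:
        logger.warning("individual %d has no informative sites; no ROH calls",
                       individual)
        return []
    tag = f"hmm_{params.mode}"
    return _calls_from_states(pos, states, tag)


def viterbi_train(vt: VariantTable, params: HMMParams = HMMParams()) -> TrainedParams:
    """Estimate the two per-bp switch rates by iterated Viterbi decoding.

    Individuals with fewer than 2 non-missing sites or zero called
    heterozygosity are excluded from training (and reported); if no
    individual remains, an error is raised.
    """
    eligible, excluded = [], []
    for i in range(vt.n_individuals):
        mask = vt.gt[i] != MISSING
        if mask.sum() >= 2 and np.any(vt.gt[i, mask] == 1):
            eligible.append(i)
        else:
            excluded.append(i)
    if excluded:
        logger.warning("excluding %d individual(s) with <2 sites or zero "
                       "heterozygosity from Viterbi training: %s",
                       len(excluded), excluded)
    if not eligible:
        raise ValueError(
            "Viterbi training requires at least one individual with >= 2 "
            "non-missing sites and nonzero heterozygosity")

    site_data = {}
    for i in eligible:
        pos, gt, pl, af = _individual_sites(vt, i)
        log_em = _log_emissions(gt, pl, af, params.mode, params.az_het_leak)
        site_data[i] = (pos, np.diff(pos).astype(np.float64), log_em)

    r01, r10 = params.hw_to_az, params.az_to_hw
    scores: list[float] = []
    converged = False
    it = 0
    for it in range(1, params.max_iter + 1):
        sw01 = sw10 = 0
        bp0 = bp1 = 0.0
        total = 0.0
        for i in eligible:
            pos, dists, log_em = site_data[i]
            states, score = _viterbi_core(
                log_em, dists, r01, r10,
                np.log(params.start_probs[0]), np.log(params.start_probs[1]))
            total += score
            s = states.astype(np.int8)
            from_hw = s[:-1] == 0
            bp0 += dists[from_hw].sum()
            bp1 += dists[~from_hw].sum()
            sw01 += int(np.sum(from_hw & (s[1:] == 1)))
            sw10 += int(np.sum(~from_hw & (s[1:] == 0)))
        scores.append(total)
        new01 = max(sw01 / bp0, RATE_FLOOR) if bp0 > 0 else r01
        new10 = max(sw10 / bp1, RATE_FLOOR) if bp1 > 0 else r10
        rel = max(abs(new01 - r01) / r01, abs(new10 - r10) / r10)
        r01, r10 = new01, new10
        if rel < params.convergence:
            converged = True
            break
    return TrainedParams(r01, r10, iterations=it, converged=converged,
                         score_history=tuple(scores),
                         excluded_individuals=tuple(excluded))


def write_roh_tsv(calls_by_individual: dict[int, list[ROHCall]], path,
                  header_comment: str | None = None) -> None:
    """Per-individual ROH TSV: individual, start, end, length, n_sites, method."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("individual\tstart\tend\tlength\tn_sites\tmethod\n")
        for ind, calls in calls_by_individual.items():
            for c in calls:
                iv = c.interval
                fh.write(f"ind{ind}\t{iv.start}\t{iv.end}\t{iv.length}\t"
                         f"{c.n_sites}\t{c.method}\n")
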