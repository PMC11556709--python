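"""High-level benchmark drivers.

These compose the library into the study design used throughout the
analyses: simulate the four demographic presets at a desk-scale rescaling,
emulate genotype observation at several depths, call ROHs with the three
methods (HMM in genotypes and likelihoods modes, sliding-window scan), and
tabulate per-individual accuracy.

The four presets share an identical burn-in epoch, so one burn-in per
replicate seed is evolved once and each scenario's post-burn-in epochs are
branched from it. Rescaled final populations can be smaller than the target
sample size; in that case several independent tail replicates are branched
from the same burn-in and their final generations are pooled until the
target number of individuals is reached.
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict

import numpy as np
import pandas as pd

from .hmmroh import HMMParams, hmm_call, viterbi_train
from .pipeline import derive_seed
from .rohmetrics import LengthBins, binned_froh, fn_fp_rates, lumping_counts
from .seqemu import ObservationModel, observe_genotypes
from .simdemog import (GenomeModel, Population, PopulationSample, Scenario,
                       extract_true_rohs, froh, heterozygosity, MIN_ROH_LEN)
from .winroh import WindowParams, calls_to_rohset, window_call

logger = logging.getLogger(__name__)

__all__ = ["PRESET_LABELS", "BENCH_WINDOW", "shared_scenario_samples",
           "evaluate_sample", "true_froh_table"]

PRESET_LABELS = ("large", "small", "bottlenecked", "declining")

#: Window-scan parameterization used for benchmark runs: defaults except the
#: minimum reported span, which matches the 100-kb ROH length filter applied
#: to every caller's output (the grid's tested value).
BENCH_WINDOW = WindowParams(phzk=100.0)

ALL_METHODS = ("hmm_genotypes", "hmm_likelihoods", "window")


def shared_scenario_samples(genome: GenomeModel, seed: int,
                            labels=PRESET_LABELS,
                            n_target: int = 50) -> dict[str, PopulationSample]:
    """One burn-in, four scenario branches, ~``n_target`` individuals each.

    Returns one :class:`PopulationSample` per scenario label. Deterministic
    given (genome, seed, labels, n_target).
    """
    scens = {lab: Scenario.preset(lab) for lab in labels}
    rescaled = {lab: genome.rescaled_epochs(s) for lab, s in scens.items()}
    burn_ins = {eps[0] for eps in rescaled.values()}
    if len(burn_ins) != 1:
        raise ValueError("scenarios do not share a common burn-in epoch")
    burn = burn_ins.pop()

    rng = np.random.default_rng(derive_seed(seed, "burnin"))
    base = Population(burn.size, genome)
    base.evolve([burn], rng)

    out = {}
    for lab in labels:
        tail = rescaled[lab][1:]
        final_size = tail[-1].size if tail else burn.size
        per_tail = min(n_target, final_size)
        n_tails = math.ceil(n_target / per_tail)
        individuals = []
        for t in range(n_tails):
            r2 = np.random.default_rng(derive_seed(seed, "tail", lab, t))
            branch = base.copy()
            branch.evolve(tail, r2)
            individuals.extend(branch.sample_individuals(per_tail, r2))
        out[lab] = PopulationSample(tuple(individuals[:n_target]),
                                    scens[lab], genome, seed)
        logger.info("scenario %s: %d individuals from %d tail replicate(s)",
                    lab, len(out[lab]), n_tails)
    return out


def true_froh_table(samples: dict[str, PopulationSample],
                    bins: LengthBins | None = None) -> pd.DataFrame:
    """Per-individual true F_ROH (overall and per length bin) and
    heterozygosity for each scenario."""
    bins = bins or LengthBins()
    rows = []
    for lab, pop in samples.items():
        L = pop.genome.length_bp
        for i, g in enumerate(pop.individuals):
            rohs = extract_true_rohs(g, L)
            row = {"scenario": lab, "individual": i,
                   "heterozygosity": heterozygosity(g, L),
                   "true_froh": froh(rohs, L)}
            row.update({f"froh_{name}": v for name, v in
                        zip(bins.labels, binned_froh(rohs, bins, L))})
            rows.append(row)
    return pd.DataFrame(rows)


def evaluate_sample(pop: PopulationSample, depths, seed: int,
                    epsilon: float = 0.005,
                    hmm: HMMParams = HMMParams(),
                    window: WindowParams = BENCH_WINDOW,
                    methods=ALL_METHODS,
                    train: bool = True,
                    min_len: int = MIN_ROH_LEN,
                    bins: LengthBins | None = None) -> pd.DataFrame:
    """Emulate observation at each depth and score every caller against the
    simulated truth.

    Returns one row per (depth, method, individual) with called F_ROH,
    per-base FN/FP rates, per-bin called-minus-true F_ROH differences, and
    the lumping tabulation.
    """
    bins = bins or LengthBins()
    L = pop.genome.length_bp
    true_sets = [extract_true_rohs(g, L, min_len) for g in pop.individuals]
    true_fr = [froh(t, L) for t in true_sets]
    true_bins = [binned_froh(t, bins, L) for t in true_sets]
    rows = []
    for depth in depths:
        obs_seed = derive_seed(seed, "emulate", pop.scenario.label, depth)
        vt = observe_genotypes(pop, ObservationModel(
            mean_depth=depth, epsilon=epsilon, seed=obs_seed))
        for method in methods:
            if method.startswith("hmm_"):
                mode = method.removeprefix("hmm_")
                params = HMMParams(**{**asdict(hmm), "mode": mode})
                if train:
                    try:
                        tp = viterbi_train(vt, params)
                        params = HMMParams(**{**asdict(params),
                                              "hw_to_az": tp.hw_to_az,
                                              "az_to_hw": tp.az_to_hw})
                    except ValueError as exc:
                        logger.warning("training failed at %sx (%s); "
                                       "default rates kept", depth, exc)
                caller = lambda i: hmm_call(vt, i, params)
            elif method == "window":
                caller = lambda i: window_call(vt, i, window)
            else:
                raise ValueError(f"unknown method {method!r}")
            for i in range(len(pop)):
                cs = calls_to_rohset(caller(i), min_len=min_len)
                acc = fn_fp_rates(true_sets[i], cs, L)
                lr = lumping_counts(true_sets[i], cs, bins)
                diffs = binned_froh(cs, bins, L) - true_bins[i]
                row = {"scenario": pop.scenario.label, "depth": depth,
                       "method": method, "individual": i,
                       "true_froh": true_fr[i], "called_froh": froh(cs, L),
                       "fn_rate": acc.fn_rate, "fp_rate": acc.fp_rate,
                       "n_called": len(cs),
                       "mean_true_per_called": lr.mean_true_per_called,
                       "n_split": lr.n_split}
                row.update({f"diff_{lab}": d
                            for lab, d in zip(bins.labels, diffs)})
                rows.append(row)
    return pd.DataFrame(rows)
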