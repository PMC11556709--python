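#!/usr/bin/env python
"""Simulate the four demographic scenarios and summarize ground truth.

Runs the shared-burn-in study at a desk-scale rescaling (lambda=20 by
default), writes per-individual truth tables (heterozygosity, overall and
per-length-bin true F_ROH) under results/, and prints the scenario means.
"""

import argparse
from pathlib import Path

import pandas as pd

from rohbench.benchmark import shared_scenario_samples, true_froh_table
from rohbench.pipeline import derive_seed
from rohbench.simdemog import GenomeModel

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--replicates", type=int, default=3)
parser.add_argument("--scale", type=float, default=20.0)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

genome = GenomeModel(scale=args.scale)
tables = []
for rep in range(args.replicates):
    rep_seed = derive_seed(args.seed, "replicate", rep)
    print(f"replicate {rep}: simulating (lambda={args.scale}, seed {rep_seed})")
    samples = shared_scenario_samples(genome, rep_seed)
    t = true_froh_table(samples)
    t.insert(0, "replicate", rep)
    tables.append(t)

truth = pd.concat(tables, ignore_index=True)
args.out.mkdir(parents=True, exist_ok=True)
truth.to_csv(args.out / "true_froh_by_individual.tsv", sep="\t", index=False)

summary = truth.groupby("scenario").agg(
    mean_heterozygosity=("heterozygosity", "mean"),
    sd_heterozygosity=("heterozygosity", "std"),
    mean_true_froh=("true_froh", "mean"),
    sd_true_froh=("true_froh", "std"),
    n=("true_froh", "size"))
summary.to_csv(args.out / "true_froh_summary.tsv", sep="\t")

print(f"\nScenario means over {args.replicates} replicate(s):")
print(summary.round(5).to_string())
print("\nHigher inbreeding tracks smaller long-term population size; the "
      "large scenario is the extreme on both axes (highest heterozygosity, "
      "lowest F_ROH). Tables written to", args.out)
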