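"""End-to-end benchmark orchestration.

``run_pipeline`` composes the stages: simulate a scenario, emulate genotype
observation at each requested depth, call ROHs with the HMM caller (both
modes, optionally with Viterbi-trained transition rates) and the
sliding-window scanner, evaluate accuracy against the simulated truth, and
optionally run the window-parameter sensitivity analysis. Every output
table carries a header comment with the config hash; every stochastic stage
consumes a seed derived deterministically from the master seed and the
stage's identity, so identical configs reproduce byte-identical outputs and
individual stages can be re-derived independently.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import simdemog
from .hmmroh import HMMParams, viterbi_train, hmm_call, write_roh_tsv
from .intervals import ROHSet
from .rohmetrics import (LengthBins, binned_froh, fit_true_vs_called,
                         fn_fp_rates, lumping_counts)
from .seqemu import ObservationModel, observe_genotypes, site_filters, write_vcf
from .simdemog import (GenomeModel, Scenario, extract_true_rohs, froh,
                       heterozygosity, simulate_population,
                       write_individual_summary, write_true_roh_bed,
                       write_truth_vcf)
from .winroh import WindowParams, calls_to_rohset, grid_call, window_call
from .sensitivity import recommend, src

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "derive_seed"]


def derive_seed(master_seed: int, *tags) -> int:
    """Stable per-stage seed below 2**31, derived from the master seed and
    the stage identity tags."""
    key = ":".join([str(master_seed)] + [str(t) for t in tags])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class RunConfig:
    """Configuration of one benchmark run."""

    scenario: str = "large"
    custom_epochs: list[tuple[int, int]] | None = None
    genome: GenomeModel = field(default_factory=GenomeModel)
    n_sample: int = 50
    depths: tuple[float, ...] = (5, 10, 15, 30, 50)
    epsilon: float = 0.005
    hmm: HMMParams = field(default_factory=HMMParams)
    viterbi_training: bool = True
    window: WindowParams = field(default_factory=WindowParams)
    window_grid: list[WindowParams] | None = None
    min_roh_len: int = simdemog.MIN_ROH_LEN
    min_maf: float = 0.0
    max_missing: float = 1.0
    out_dir: str = "results/run"
    master_seed: int = 1

    def validate(self) -> None:
        if not self.depths:
            raise ValueError("config error: empty depth list")
        if self.n_sample < 1:
            raise ValueError("config error: n_sample must be >= 1")
        self.resolve_scenario()  # raises on unknown preset

    def resolve_scenario(self) -> Scenario:
        if self.custom_epochs is not None:
            return Scenario.custom([simdemog.Epoch(*e) for e in self.custom_epochs],
                                   label=self.scenario)
        return Scenario.preset(self.scenario)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["genome"] = asdict(self.genome)
        d["hmm"] = asdict(self.hmm)
        d["window"] = asdict(self.window)
        if self.window_grid is not None:
            d["window_grid"] = [asdict(w) for w in self.window_grid]
        return d

    @property
    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # hash covers the science, not the destination
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "genome" in kwargs:
            kwargs["genome"] = GenomeModel(**kwargs["genome"])
        if "hmm" in kwargs:
            kwargs["hmm"] = HMMParams(**kwargs["hmm"])
        if "window" in kwargs:
            kwargs["window"] = WindowParams(**kwargs["window"])
        if kwargs.get("window_grid") is not None:
            kwargs["window_grid"] = [WindowParams(**w) for w in kwargs["window_grid"]]
        if "depths" in kwargs:
            kwargs["depths"] = tuple(kwargs["depths"])
        known = {f.name for f in fields(cls)}
        unknown = set(kwargs) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)


def _write_df(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    from . import __version__

    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash} rohbench={__version__}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.8g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full benchmark for one config; returns the artifact
    manifest (name -> path). Any stage failure aborts with the stage name
    and the config hash."""
    config.validate()
    chash = config.config_hash
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    bins = LengthBins()
    L = config.genome.length_bp
    stage = "init"
    try:
        # -- simulate ------------------------------------------------------
        stage = "simulate"
        scenario = config.resolve_scenario()
        sim_seed = derive_seed(config.master_seed, "simulate", scenario.label)
        logger.info("stage=%s seed=%d", stage, sim_seed)
        pop = simulate_population(scenario, config.genome, config.n_sample,
                                  seed=sim_seed)
        true_sets = [extract_true_rohs(g, L, config.min_roh_len)
                     for g in pop.individuals]
        true_froh = np.array([froh(t, L) for t in true_sets])
        het = np.array([heterozygosity(g, L) for g in pop.individuals])
        n_zero_het = int(np.sum(het == 0))
        if n_zero_het:
            logger.warning("%d individual(s) with zero heterozygosity",
                           n_zero_het)

        stage = "write-truth"
        write_true_roh_bed(true_sets, out / "true_rohs.bed")
        manifest["true_rohs_bed"] = str(out / "true_rohs.bed")
        write_individual_summary(pop, out / "individual_summary.tsv", bins)
        manifest["individual_summary"] = str(out / "individual_summary.tsv")
        write_truth_vcf(pop, out / "truth.vcf")
        manifest["truth_vcf"] = str(out / "truth.vcf")

        roh_rows, fit_rows, rate_rows, bin_rows, lump_rows, trained_rows = \
            [], [], [], [], [], []
        for depth in config.depths:
            # -- emulate ---------------------------------------------------
            stage = f"emulate-{depth}x"
            obs_seed = derive_seed(config.master_seed, "emulate",
                                   scenario.label, depth)
            logger.info("stage=%s seed=%d", stage, obs_seed)
            vt = observe_genotypes(pop, ObservationModel(
                mean_depth=depth, epsilon=config.epsilon, seed=obs_seed))
            if config.min_maf > 0 or config.max_missing < 1:
                vt = site_filters(vt, config.min_maf, config.max_missing)
            vcf_path = out / f"calls_{depth}x.vcf"
            write_vcf(vt, vcf_path, contig_length=L)
            manifest[f"vcf_{depth}x"] = str(vcf_path)

            # -- call ------------------------------------------------------
            stage = f"call-{depth}x"
            called: dict[str, list[ROHSet]] = {}
            for mode in ("genotypes", "likelihoods"):
                hmm = HMMParams(**{**asdict(config.hmm), "mode": mode})
                if config.viterbi_training:
                    try:
                        tp = viterbi_train(vt, hmm)
                        hmm = HMMParams(**{**asdict(hmm),
                                           "hw_to_az": tp.hw_to_az,
                                           "az_to_hw": tp.az_to_hw})
                        trained_rows.append({
                            "scenario": scenario.label, "depth": depth,
                            "mode": mode, "hw_to_az": tp.hw_to_az,
                            "az_to_hw": tp.az_to_hw,
                            "iterations": tp.iterations,
                            "converged": tp.converged,
                            "n_excluded": len(tp.excluded_individuals)})
                    except ValueError as exc:
                        logger.warning("Viterbi training failed (%s); "
                                       "using default rates", exc)
                method = f"hmm_{mode}"
                called[method] = [
                    calls_to_rohset(hmm_call(vt, i, hmm), config.min_roh_len)
                    for i in range(len(pop))]
            called["window"] = [
                calls_to_rohset(window_call(vt, i, config.window),
                                config.min_roh_len)
                for i in range(len(pop))]

            # -- metrics ---------------------------------------------------
            stage = f"metrics-{depth}x"
            for method, sets in called.items():
                for i, cs in enumerate(sets):
                    for iv in cs:
                        roh_rows.append({
                            "scenario": scenario.label, "depth": depth,
                            "method": method, "individual": i,
                            "start": iv.start, "end": iv.end,
                            "length": iv.length})
                    acc = fn_fp_rates(true_sets[i], cs, L)
                    rate_rows.append({
                        "scenario": scenario.label, "depth": depth,
                        "method": method, "individual": i,
                        "true_froh": true_froh[i],
                        "called_froh": froh(cs, L),
                        "fn_rate": acc.fn_rate, "fp_rate": acc.fp_rate})
                    diffs = (binned_froh(cs, bins, L)
                             - binned_froh(true_sets[i], bins, L))
                    for lab, d in zip(bins.labels, diffs):
                        bin_rows.append({
                            "scenario": scenario.label, "depth": depth,
                            "method": method, "individual": i,
                            "bin": lab, "called_minus_true": d})
                    lr = lumping_counts(true_sets[i], cs, bins)
                    lump_rows.append({
                        "scenario": scenario.label, "depth": depth,
                        "method": method, "individual": i,
                        "n_called": len(cs.intervals),
                        "mean_true_per_called": lr.mean_true_per_called,
                        "n_split": lr.n_split})
                pairs = [(true_froh[i], froh(cs, L))
                         for i, cs in enumerate(sets)]
                try:
                    fit = fit_true_vs_called(pairs)
                    fit_rows.append({
                        "scenario": scenario.label, "depth": depth,
                        "method": method, "slope": fit.slope,
                        "intercept": fit.intercept,
                        "slope_lo": fit.slope_ci[0], "slope_hi": fit.slope_ci[1],
                        "intercept_lo": fit.intercept_ci[0],
                        "intercept_hi": fit.intercept_ci[1], "n": fit.n})
                except ValueError as exc:
                    logger.warning("regression skipped for %s %sx: %s",
                                   method, depth, exc)

        stage = "write-metrics"
        for name, rows in (("called_rohs", roh_rows), ("rates", rate_rows),
                           ("regressions", fit_rows), ("bin_errors", bin_rows),
                           ("lumping", lump_rows),
                           ("trained_params", trained_rows)):
            _write_df(pd.DataFrame(rows), out / f"{name}.tsv", chash)
            manifest[name] = str(out / f"{name}.tsv")

        # -- sensitivity ---------------------------------------------------
        if config.window_grid:
            stage = "sensitivity"
            depth = config.depths[-1]
            obs_seed = derive_seed(config.master_seed, "emulate",
                                   scenario.label, depth)
            vt = observe_genotypes(pop, ObservationModel(
                mean_depth=depth, epsilon=config.epsilon, seed=obs_seed))
            gr = grid_call(vt, config.window_grid, L=L,
                           min_len=config.min_roh_len)
            _write_df(gr, out / "grid_froh.tsv", chash)
            manifest["grid_froh"] = str(out / "grid_froh.tsv")
            results = [src(gr, i) for i in range(len(pop))]
            src_df = pd.DataFrame([
                {"individual": r.individual, **r.coefficients}
                for r in results])
            _write_df(src_df, out / "src.tsv", chash)
            manifest["src"] = str(out / "src.tsv")
            _write_df(recommend(results), out / "recommendations.tsv", chash)
            manifest["recommendations"] = str(out / "recommendations.tsv")

        stage = "report"
        with open(out / "summary.txt", "w") as fh:
            fh.write(f"rohbench run {chash}\n"
                     f"scenario={scenario.label} lambda={config.genome.scale} "
                     f"n={len(pop)} depths={list(config.depths)}\n"
                     f"mean heterozygosity={het.mean():.6g}\n"
                     f"mean true F_ROH={true_froh.mean():.4f}\n"
                     f"zero-heterozygosity individuals={n_zero_het}\n")
        manifest["summary"] = str(out / "summary.txt")
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage '{stage}' failed for config {chash}: {exc}") from exc

    missing = [k for k, v in manifest.items() if not Path(v).exists()]
    if missing:
        raise RuntimeError(f"manifest incomplete for config {chash}: {missing}")
    with open(out / "manifest.json", "w") as fh:
        json.dump({"config_hash": chash, "config": config.to_dict(),
                   "artifacts": manifest}, fh, indent=2, default=str)
    return manifest
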