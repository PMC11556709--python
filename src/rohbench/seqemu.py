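"""Depth-dependent genotype observation emulator and multi-sample VCF I/O.

Instead of simulating reads, alignment and a full variant-calling stack,
sequencing is emulated parametrically: at every segregating site each
individual receives a Poisson number of reads, each read samples one of the
two haplotypes uniformly and reports its allele with a per-read miscall
probability ``epsilon``. Genotypes are then called by maximum likelihood
from the read counts, yielding exactly the depth-dependent genotype errors
and missingness that drive coverage effects in ROH calling.

The interchange object is :class:`VariantTable`: positions, a per-individual
matrix of called genotypes with depths and phred-scaled genotype likelihoods
(PL), and sample allele frequencies recomputed from the non-missing calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .simdemog import PopulationSample

logger = logging.getLogger(__name__)

__all__ = [
    "MISSING",
    "ObservationModel",
    "VariantTable",
    "observe_genotypes",
    "site_filters",
    "write_vcf",
    "read_vcf",
]

#: Genotype code for a missing call (depth 0).
MISSING = -1
#: Cap on phred-scaled genotype likelihoods, as emitted by common callers.
PL_CAP = 255

#: Mean-depth presets used throughout the benchmark.
DEPTH_PRESETS = (5, 10, 15, 30, 50)


@dataclass(frozen=True)
class ObservationModel:
    """Parametric model of genotype observation.

    Parameters
    ----------
    mean_depth
        Expected reads per site per individual (Poisson).
    epsilon
        Per-read allele miscall probability (ref<->alt flips).
    seed
        Seed for the observation RNG.
    """

    mean_depth: float = 30.0
    epsilon: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if not 0 <= self.epsilon < 0.5:
            raise ValueError("epsilon must be in [0, 0.5)")


@dataclass
class VariantTable:
    """Called genotypes at polymorphic sites for a sample of individuals.

    Attributes
    ----------
    positions
        Increasing 0-based bp coordinates, shape ``(n_sites,)``.
    gt
        Genotype matrix ``(n_individuals, n_sites)``: 0 hom-ref, 1 het,
        2 hom-alt, ``MISSING`` (-1) for no call.
    dp
        Read depths, same shape as ``gt``.
    pl
        Phred-scaled genotype likelihoods, min-normalized to 0, shape
        ``(n_individuals, n_sites, 3)``.
    af
        Alternate-allele frequency per site from non-missing calls.
    """

    positions: np.ndarray
    gt: np.ndarray
    dp: np.ndarray
    pl: np.ndarray
    af: np.ndarray = field(default=None)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.gt = np.asarray(self.gt, dtype=np.int8)
        self.dp = np.asarray(self.dp, dtype=np.int32)
        self.pl = np.asarray(self.pl, dtype=np.int32)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.af is None:
            self.af = compute_af(self.gt)
        else:
            self.af = np.asarray(self.af, dtype=float)

    @property
    def n_individuals(self) -> int:
        return self.gt.shape[0]

    @property
    def n_sites(self) -> int:
        return self.gt.shape[1]

    def equals(self, other: "VariantTable") -> bool:
        return (np.array_equal(self.positions, other.positions)
                and np.array_equal(self.gt, other.gt)
                and np.array_equal(self.dp, other.dp)
                and np.array_equal(self.pl, other.pl)
                and np.allclose(self.af, other.af))


def compute_af(gt: np.ndarray) -> np.ndarray:
    """Alternate-allele frequency per site from non-missing called genotypes."""
    called = gt != MISSING
    alt = np.where(called, gt, 0).sum(axis=0)
    denom = 2 * called.sum(axis=0)
    with np.errstate(invalid="ignore"):
        af = np.where(denom > 0, alt / np.maximum(denom, 1), np.nan)
    return af


def _true_genotype_matrix(pop: PopulationSample) -> tuple[np.ndarray, np.ndarray]:
    """Union of mutated positions across the sample and the true 0/1/2 matrix."""
    haps = [(g.hapA, g.hapB) for g in pop.individuals]
    parts = [np.concatenate([a, b]) for a, b in haps]
    all_pos = np.unique(np.concatenate(parts)) if parts else np.empty(0, np.int64)
    true_gt = np.zeros((len(haps), all_pos.size), dtype=np.int8)
    for i, (a, b) in enumerate(haps):
        true_gt[i] = (np.isin(all_pos, a, assume_unique=True).astype(np.int8)
                      + np.isin(all_pos, b, assume_unique=True).astype(np.int8))
    return all_pos, true_gt


def _call_from_reads(dp: np.ndarray, alt_reads: np.ndarray,
                     epsilon: float) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood genotype call and PL triple from read counts.

    Per-read likelihoods: a homozygote emits the matching allele with
    probability ``1 - epsilon``; a heterozygote emits either allele with
    probability 1/2. Ties are broken toward the homozygote matching the
    majority read allele, then toward hom-ref.
    """
    d = dp.astype(np.float64)
    a = alt_reads.astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_e = np.log10(epsilon) if epsilon > 0 else -np.inf
        log_1e = np.log10(1.0 - epsilon)
        ll0 = (d - a) * log_1e + a * log_e
        ll2 = a * log_1e + (d - a) * log_e
    ll0 = np.where(a == 0, (d - a) * log_1e, ll0)      # avoid 0 * -inf
    ll2 = np.where(d - a == 0, a * log_1e, ll2)
    ll1 = d * np.log10(0.5)
    ll = np.stack([ll0, ll1, ll2], axis=-1)            # (..., 3)

    best = ll.max(axis=-1, keepdims=True)
    is_max = ll >= best - 1e-12
    n_max = is_max.sum(axis=-1)
    gt = np.argmax(ll, axis=-1).astype(np.int8)
    tie = n_max > 1
    if np.any(tie):
        maj_alt = a > d - a
        hom_major = np.where(maj_alt, 2, 0).astype(np.int8)
        hom_major_ok = np.take_along_axis(
            is_max, hom_major[..., None].astype(np.int64), axis=-1)[..., 0]
        homref_ok = is_max[..., 0]
        choice = np.where(hom_major_ok, hom_major,
                          np.where(homref_ok, 0, np.where(is_max[..., 2], 2, 1)))
        gt = np.where(tie, choice.astype(np.int8), gt)

    pl = -10.0 * (ll - best)
    pl = np.where(np.isfinite(pl), pl, PL_CAP)
    pl = np.minimum(np.rint(pl), PL_CAP).astype(np.int32)
    gt = np.where(dp == 0, np.int8(MISSING), gt)
    pl = np.where(dp[..., None] == 0, 0, pl)
    return gt, pl


def observe_genotypes(pop: PopulationSample, model: ObservationModel) -> VariantTable:
    """Emulate genotype observation for every individual at every segregating
    site of the sample.

    Sites where no alternate allele or no reference allele remains among the
    calls are dropped (they would be absent from, or unusable in, a called
    multi-sample VCF). Deterministic given ``model.seed``.
    """
    if len(pop) == 0:
        raise ValueError("population sample is empty")
    rng = np.random.default_rng(model.seed)
    positions, true_gt = _true_genotype_matrix(pop)
    n_ind, n_sites = true_gt.shape

    dp = rng.poisson(model.mean_depth, size=(n_ind, n_sites)).astype(np.int32)
    # P(read reports alt) given true genotype: 0 -> eps, 1 -> 1/2, 2 -> 1-eps
    p_alt = np.choose(true_gt, [model.epsilon, 0.5, 1.0 - model.epsilon])
    alt_reads = rng.binomial(dp, p_alt).astype(np.int32)

    gt, pl = _call_from_reads(dp, alt_reads, model.epsilon)

    called = gt != MISSING
    alt_alleles = np.where(called, np.maximum(gt, 0), 0).sum(axis=0)
    ref_alleles = np.where(called, 2 - np.maximum(gt, 0), 0).sum(axis=0)
    keep = (alt_alleles > 0) & (ref_alleles > 0)
    return VariantTable(positions[keep], gt[:, keep], dp[:, keep], pl[:, keep])


def site_filters(vt: VariantTable, min_maf: float = 0.0,
                 max_missing: float = 1.0) -> VariantTable:
    """Retain sites with MAF >= ``min_maf`` (closed) and a missing-call
    fraction strictly below ``max_missing``.

    Off by default for simulated data; intended for empirical VCF input.
    Allele frequencies are recomputed on the retained sites.
    """
    if not (0 <= min_maf <= 1 and 0 <= max_missing <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    maf = np.minimum(vt.af, 1.0 - vt.af)
    missing_frac = (vt.gt == MISSING).mean(axis=0)
    keep = (maf >= min_maf) & (missing_frac < max_missing)
    return VariantTable(vt.positions[keep], vt.gt[:, keep],
                        vt.dp[:, keep], vt.pl[:, keep, :])


# -- VCF I/O ----------------------------------------------------------------

_VCF_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(vt: VariantTable, path, chrom: str = "chr1",
              sample_ids=None, contig_length: int | None = None) -> None:
    """Serialize a :class:`VariantTable` as VCF 4.2 (GT:DP:PL).

    POS is the 0-based position + 1; REF/ALT are placeholder single bases.
    """
    if sample_ids is None:
        sample_ids = [f"ind{i}" for i in range(vt.n_individuals)]
    clen = contig_length if contig_length is not None else (
        int(vt.positions[-1]) + 1 if vt.n_sites else 1)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={clen}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=PL,Number=G,Type=Integer,Description='
                 '"Phred-scaled genotype likelihoods">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for j in range(vt.n_sites):
            cols = [chrom, str(int(vt.positions[j]) + 1), ".", "A", "T", ".",
                    "PASS", ".", "GT:DP:PL"]
            for i in range(vt.n_individuals):
                g = _VCF_GT[int(vt.gt[i, j])]
                p = vt.pl[i, j]
                cols.append(f"{g}:{int(vt.dp[i, j])}:{p[0]},{p[1]},{p[2]}")
            fh.write("\t".join(cols) + "\n")


def read_vcf(path) -> VariantTable:
    """Parse a multi-sample VCF with GT (and optionally DP/PL) into a
    :class:`VariantTable`. Raises a descriptive error naming the offending
    line on malformed input."""
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare Exceptions on bad headers
        raise ValueError(f"cannot open VCF {path}: {exc}") from exc
    positions, gts, dps, pls = [], [], [], []
    n_samples = len(vcf.samples)
    lineno = 0
    try:
        for var in vcf:
            lineno += 1
            positions.append(var.POS - 1)
            # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            gt = np.array(var.gt_types, dtype=np.int8)
            gt = np.where(gt == 2, np.int8(MISSING), np.where(gt == 3, 2, gt))
            gts.append(gt)
            dp = var.format("DP")
            dps.append(dp[:, 0].astype(np.int32) if dp is not None
                       else np.full(n_samples, -1, np.int32))
            pl = var.format("PL")
            pls.append(pl.astype(np.int32) if pl is not None
                       else np.zeros((n_samples, 3), np.int32))
    except Exception as exc:
        raise ValueError(f"malformed VCF {path} at record {lineno + 1}: {exc}") from exc
    if not positions:
        return VariantTable(np.empty(0, np.int64),
                            np.empty((n_samples, 0), np.int8),
                            np.empty((n_samples, 0), np.int32),
                            np.empty((n_samples, 0, 3), np.int32))
    dp = np.stack(dps, axis=1)
    gt = np.stack(gts, axis=1)
    dp = np.where(dp < 0, np.where(gt == MISSING, 0, 1), dp)
    pl = np.stack(pls, axis=1)
    pl = np.where(gt[:, :, None] == MISSING, 0, pl)
    return VariantTable(np.asarray(positions, np.int64), gt, dp, pl)
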