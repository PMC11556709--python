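"""Forward-in-time Wright–Fisher simulation with recombination and
infinite-sites mutation under preset demographic scenarios.

The simulator tracks each haplotype as a sorted integer array of derived
mutation positions on a single chromosome of length ``L``. Populations are
founded monomorphic, evolve neutrally epoch by epoch (each offspring draws
two parents uniformly at random, with incidental selfing allowed as in the
standard Wright–Fisher model), and diploid individuals are sampled without
replacement from the final generation.

Four demographic presets are provided. All begin with a 10,000-generation
burn-in at 10,000 diploids and then diverge:

* ``large`` — 1,000 further generations at 1,000 diploids
* ``small`` — 1,000 further generations at 250 diploids
* ``bottlenecked`` — 900 at 1,000, then 50 at 50, then 50 at 250
* ``declining`` — 850 at 1,000, then 50 each at 500, 250, 50

A diffusion-preserving rescaling factor ``scale`` (lambda) shrinks census
sizes and epoch durations by lambda while multiplying the per-bp mutation
and recombination rates by lambda, preserving N*mu, N*r and epoch lengths
in units of N generations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numba import njit

from .intervals import ROHSet

logger = logging.getLogger(__name__)

__all__ = [
    "Epoch",
    "Scenario",
    "GenomeModel",
    "DiploidGenome",
    "PopulationSample",
    "Population",
    "simulate_population",
    "extract_true_rohs",
    "froh",
    "heterozygosity",
    "write_true_roh_bed",
    "write_truth_vcf",
    "write_individual_summary",
]

#: Mutation rate per site per generation (Tasmanian devil estimate).
DEFAULT_MU = 1.39e-8
#: Recombination rate per site per generation (Tasmanian devil estimate).
DEFAULT_REC = 9.15e-9
#: Chromosome length in bp.
DEFAULT_LENGTH = 30_000_000
#: Minimum ROH length retained in all downstream analyses.
MIN_ROH_LEN = 100_000


@dataclass(frozen=True)
class Epoch:
    """A constant-size interval of a demographic history."""

    size: int       # diploid population size
    duration: int   # generations

    def __post_init__(self):
        if self.size < 1 or self.duration < 1:
            raise ValueError("Epoch size and duration must be >= 1")


_BURN_IN = Epoch(10_000, 10_000)

_PRESET_EPOCHS = {
    "large": (_BURN_IN, Epoch(1_000, 1_000)),
    "small": (_BURN_IN, Epoch(250, 1_000)),
    "bottlenecked": (_BURN_IN, Epoch(1_000, 900), Epoch(50, 50), Epoch(250, 50)),
    "declining": (_BURN_IN, Epoch(1_000, 850), Epoch(500, 50), Epoch(250, 50), Epoch(50, 50)),
}


@dataclass(frozen=True)
class Scenario:
    """An ordered population-size history."""

    label: str
    epochs: tuple[Epoch, ...]

    @classmethod
    def preset(cls, label: str) -> "Scenario":
        if label not in _PRESET_EPOCHS:
            raise KeyError(f"unknown scenario preset {label!r}; "
                           f"choose from {sorted(_PRESET_EPOCHS)}")
        return cls(label, _PRESET_EPOCHS[label])

    @classmethod
    def custom(cls, epochs: Sequence[Epoch], label: str = "custom") -> "Scenario":
        return cls(label, tuple(epochs))

    @property
    def final_size(self) -> int:
        return self.epochs[-1].size


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome length, per-bp rates, and the rescaling factor lambda."""

    length_bp: int = DEFAULT_LENGTH
    mu: float = DEFAULT_MU
    rec: float = DEFAULT_REC
    scale: float = 1.0

    def __post_init__(self):
        if self.scale < 1:
            raise ValueError("scale (lambda) must be >= 1")
        if self.length_bp < 1 or self.mu < 0 or self.rec < 0:
            raise ValueError("invalid genome model")

    @property
    def mu_eff(self) -> float:
        return self.mu * self.scale

    @property
    def rec_eff(self) -> float:
        return self.rec * self.scale

    def rescaled_epochs(self, scenario: Scenario) -> tuple[Epoch, ...]:
        """Epochs with sizes and durations divided by lambda.

        Sizes round to the nearest integer; a size that rounds below 2
        diploids is an error (the scenario cannot be represented at this
        lambda). Durations round to the nearest integer with a floor of 1.
        """
        out = []
        for ep in scenario.epochs:
            size = round(ep.size / self.scale)
            if size < 2:
                raise ValueError(
                    f"lambda={self.scale} rescales epoch size {ep.size} below 2 "
                    f"diploids; use a smaller lambda")
            out.append(Epoch(size, max(1, round(ep.duration / self.scale))))
        return tuple(out)


@dataclass(frozen=True)
class DiploidGenome:
    """Two haplotypes, each a strictly increasing int64 array of mutated
    positions in ``[0, L)``. The heterozygous-site set is the symmetric
    difference of the two position sets."""

    hapA: np.ndarray
    hapB: np.ndarray

    def het_positions(self) -> np.ndarray:
        return np.setxor1d(self.hapA, self.hapB, assume_unique=True)


@dataclass(frozen=True)
class PopulationSample:
    individuals: tuple[DiploidGenome, ...]
    scenario: Scenario
    genome: GenomeModel
    seed: int

    def __len__(self) -> int:
        return len(self.individuals)


@njit(cache=True)
def _assemble_gametes(flat, offs, parents, starts, n_x, all_breaks,
                      n_mut, all_mut):
    """Build all gametes of one generation from CSR-packed parent haplotypes.

    For gamete g, crossovers at sorted ``all_breaks`` slice g switch the
    template (haplotypes 2*parents[g] / 2*parents[g]+1) for positions >= the
    breakpoint; new mutations (pre-drawn, globally unique) are merged in.
    Returns the CSR-packed offspring haplotypes.
    """
    n_gam = parents.shape[0]
    # upper bound on output size
    cap = 0
    for g in range(n_gam):
        p = parents[g]
        cap += offs[2 * p + 2] - offs[2 * p]
    cap += len(all_mut)
    out = np.empty(cap, np.int64)
    out_offs = np.empty(n_gam + 1, np.int64)
    out_offs[0] = 0
    huge = np.int64(2 ** 62)
    x_pos = 0
    m_pos = 0
    w = 0
    for g in range(n_gam):
        p = parents[g]
        k = n_x[g]
        breaks = np.sort(all_breaks[x_pos:x_pos + k])
        x_pos += k
        m = n_mut[g]
        muts = np.sort(all_mut[m_pos:m_pos + m])
        m_pos += m
        ia = offs[2 * p]
        a1 = offs[2 * p + 1]
        ib = offs[2 * p + 1]
        b1 = offs[2 * p + 2]
        cur = starts[g]
        j = 0
        for s in range(k + 1):
            end = breaks[s] if s < k else huge
            # index range of the active template within this position segment
            if cur == 0:
                i_end = ia + np.searchsorted(flat[ia:a1], end)
                src_lo, src_hi = ia, i_end
                ia = i_end
                ib = ib + np.searchsorted(flat[ib:b1], end)
            else:
                i_end = ib + np.searchsorted(flat[ib:b1], end)
                src_lo, src_hi = ib, i_end
                ib = i_end
                ia = ia + np.searchsorted(flat[ia:a1], end)
            # copy the segment, merging in mutations below `end`
            i = src_lo
            while j < m and muts[j] < end:
                split = i + np.searchsorted(flat[i:src_hi], muts[j])
                n_chunk = split - i
                out[w:w + n_chunk] = flat[i:split]
                w += n_chunk
                i = split
                out[w] = muts[j]
                w += 1
                j += 1
            n_chunk = src_hi - i
            out[w:w + n_chunk] = flat[i:src_hi]
            w += n_chunk
            cur ^= 1
        out_offs[g + 1] = w
    return out[:w], out_offs


def _recombine(hapA: np.ndarray, hapB: np.ndarray, breaks: np.ndarray,
               start: int) -> np.ndarray:
    """Gamete from two parental haplotypes with crossovers at ``breaks``.

    A crossover at position b switches the template for all positions >= b.
    """
    if len(breaks) == 0:
        return (hapA if start == 0 else hapB).copy()
    ia = np.searchsorted(hapA, breaks)
    ib = np.searchsorted(hapB, breaks)
    haps = (hapA, hapB)
    idxs = (ia, ib)
    segs = []
    cur = start
    nb = len(breaks)
    for j in range(nb + 1):
        hap = haps[cur]
        lo = idxs[cur][j - 1] if j > 0 else 0
        hi = idxs[cur][j] if j < nb else len(hap)
        if hi > lo:
            segs.append(hap[lo:hi])
        cur ^= 1
    if not segs:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(segs)


class Population:
    """Mutable population state: a flat list of 2N haplotype arrays.

    Haplotypes ``2i`` and ``2i+1`` belong to diploid individual ``i``.
    Mutation positions are unique across the population at any time
    (infinite-sites: proposed positions already in use are re-drawn).
    Sites fixed in the whole population are stripped periodically; they
    contribute nothing to heterozygosity or ROH structure.
    """

    #: generations between fixed-site sweeps
    STRIP_EVERY = 50

    def __init__(self, n_diploids: int, genome: GenomeModel):
        self.genome = genome
        # CSR-packed haplotypes: positions of haplotype h are
        # _flat[_offs[h]:_offs[h+1]]; haplotypes 2i, 2i+1 belong to diploid i
        self._flat: np.ndarray = np.empty(0, dtype=np.int64)
        self._offs: np.ndarray = np.zeros(2 * n_diploids + 1, dtype=np.int64)
        # sorted array of positions in use (segregating, or mutated since
        # the last fixed-site sweep)
        self._used: np.ndarray = np.empty(0, dtype=np.int64)

    @property
    def n_diploids(self) -> int:
        return (len(self._offs) - 1) // 2

    @property
    def haplotypes(self) -> list[np.ndarray]:
        """Per-haplotype position arrays (views into packed storage)."""
        return [self._flat[self._offs[h]:self._offs[h + 1]]
                for h in range(len(self._offs) - 1)]

    def copy(self) -> "Population":
        new = Population.__new__(Population)
        new.genome = self.genome
        new._flat = self._flat.copy()
        new._offs = self._offs.copy()
        new._used = self._used.copy()
        return new

    # -- internals ---------------------------------------------------------

    def _draw_unused_positions(self, count: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform positions not currently in use, in draw order
        (infinite-sites: collisions with used positions are re-drawn)."""
        L = self.genome.length_bp
        out = np.empty(count, dtype=np.int64)
        filled = 0

        def in_sorted(sorted_arr, values):
            if sorted_arr.size == 0:
                return np.zeros(values.size, dtype=bool)
            idx = np.searchsorted(sorted_arr, values)
            idx[idx == sorted_arr.size] = 0
            return sorted_arr[idx] == values

        while filled < count:
            cand = rng.integers(0, L, size=count - filled)
            # drop intra-batch duplicates (keep first occurrence, original order)
            srt = np.argsort(cand, kind="stable")
            dup = np.zeros(cand.size, dtype=bool)
            dup[srt[1:][cand[srt[1:]] == cand[srt[:-1]]]] = True
            keep = ~dup
            keep &= ~in_sorted(self._used, cand)
            keep &= ~in_sorted(np.sort(out[:filled]), cand)
            accepted = cand[keep]
            out[filled:filled + accepted.size] = accepted
            filled += accepted.size
        acc_sorted = np.sort(out)
        self._used = np.insert(self._used,
                               np.searchsorted(self._used, acc_sorted), acc_sorted)
        return out

    def _strip_fixed(self) -> None:
        nh = len(self._offs) - 1
        if self._flat.size == 0:
            self._used = np.empty(0, dtype=np.int64)
            return
        vals, counts = np.unique(self._flat, return_counts=True)
        fixed = vals[counts == nh]
        if fixed.size:
            idx = np.searchsorted(fixed, self._flat)
            idx[idx == fixed.size] = 0
            keep = fixed[idx] != self._flat
            kept_prefix = np.concatenate([[0], np.cumsum(keep)])
            self._offs = kept_prefix[self._offs]
            self._flat = self._flat[keep]
            vals = vals[counts < nh]
        self._used = vals

    def _next_generation(self, n_next: int, rng: np.random.Generator) -> None:
        n_par = self.n_diploids
        L = self.genome.length_bp
        n_gam = 2 * n_next

        parents = rng.integers(0, n_par, size=n_gam)   # gamete g from parent[g]
        n_x = rng.poisson(self.genome.rec_eff * L, size=n_gam)
        starts = rng.integers(0, 2, size=n_gam)
        all_breaks = rng.integers(0, L, size=int(n_x.sum()))
        n_mut = rng.poisson(self.genome.mu_eff * L, size=n_gam)
        all_mut = self._draw_unused_positions(int(n_mut.sum()), rng)

        self._flat, self._offs = _assemble_gametes(
            self._flat, self._offs, parents.astype(np.int64),
            starts.astype(np.int64), n_x.astype(np.int64),
            all_breaks.astype(np.int64), n_mut.astype(np.int64), all_mut)

    # -- public API --------------------------------------------------------

    def evolve(self, epochs: Sequence[Epoch], rng: np.random.Generator) -> None:
        """Run Wright–Fisher generations epoch by epoch."""
        gen = 0
        for ep in epochs:
            for _ in range(ep.duration):
                self._next_generation(ep.size, rng)
                gen += 1
                if gen % self.STRIP_EVERY == 0:
                    self._strip_fixed()
        self._strip_fixed()

    def sample_individuals(self, n: int, rng: np.random.Generator) -> tuple[DiploidGenome, ...]:
        """Draw ``n`` diploid individuals without replacement."""
        if n > self.n_diploids:
            raise ValueError(
                f"cannot sample {n} individuals from a final population of "
                f"{self.n_diploids} without replacement")
        idx = rng.choice(self.n_diploids, size=n, replace=False)
        return tuple(
            DiploidGenome(self.haplotypes[2 * i].copy(), self.haplotypes[2 * i + 1].copy())
            for i in idx
        )


def simulate_population(scenario: Scenario, genome: GenomeModel,
                        n_sample: int = 50, seed: int = 0) -> PopulationSample:
    """Simulate a scenario from a monomorphic founder population and sample
    ``n_sample`` diploid individuals from the final generation.

    Deterministic given all arguments: the same (scenario, genome, n_sample,
    seed) always yields a bit-identical sample.
    """
    epochs = genome.rescaled_epochs(scenario)
    if n_sample > epochs[-1].size:
        raise ValueError(
            f"n_sample={n_sample} exceeds the final epoch size "
            f"{epochs[-1].size} after rescaling (lambda={genome.scale})")
    rng = np.random.default_rng(seed)
    pop = Population(epochs[0].size, genome)
    pop.evolve(epochs, rng)
    individuals = pop.sample_individuals(n_sample, rng)
    return PopulationSample(individuals, scenario, genome, seed)


def extract_true_rohs(genome: DiploidGenome, L: int,
                      min_len: int = MIN_ROH_LEN) -> ROHSet:
    """Maximal runs of homozygosity of a diploid genome.

    Candidate intervals lie strictly between consecutive heterozygous
    positions: between het sites ``h_k < h_{k+1}`` the run is
    ``[h_k + 1, h_{k+1})``; chromosome ends contribute ``[0, h_1)`` and
    ``[h_m + 1, L)``. A genome with no heterozygous site yields ``[0, L)``.
    Runs shorter than ``min_len`` bp are dropped (closed threshold).
    """
    het = genome.het_positions()
    if het.size == 0:
        ivals = np.array([[0, L]], dtype=np.int64)
    else:
        starts = np.concatenate([[0], het + 1])
        ends = np.concatenate([het, [L]])
        ivals = np.stack([starts, ends], axis=1)
    # adjacent het positions leave empty candidates; drop them along with
    # anything below the length threshold
    keep = (ivals[:, 1] - ivals[:, 0]) >= max(min_len, 1)
    return ROHSet(ivals[keep], min_len=min_len)


def froh(rohs: ROHSet, L: int) -> float:
    """Fraction of the chromosome covered by the (disjoint) ROH set."""
    return rohs.total_length / L


def heterozygosity(genome: DiploidGenome, L: int) -> float:
    """Per-bp heterozygosity: count of heterozygous sites divided by L."""
    return genome.het_positions().size / L


# -- writers ---------------------------------------------------------------

def write_true_roh_bed(rohsets: Sequence[ROHSet], path,
                       individual_ids: Sequence[str] | None = None,
                       chrom: str = "chr1") -> None:
    """BED (0-based half-open): chrom, start, end, individual."""
    if individual_ids is None:
        individual_ids = [f"ind{i}" for i in range(len(rohsets))]
    with open(path, "w") as fh:
        for ind, rs in zip(individual_ids, rohsets):
            for iv in rs:
                fh.write(f"{chrom}\t{iv.start}\t{iv.end}\t{ind}\n")


def write_individual_summary(sample: PopulationSample, path,
                             bins=None) -> None:
    """Per-individual TSV: heterozygosity, true F_ROH, per-bin F_ROH."""
    from .rohmetrics import LengthBins, binned_froh

    bins = bins or LengthBins()
    L = sample.genome.length_bp
    with open(path, "w") as fh:
        labels = "\t".join(f"froh_{lab}" for lab in bins.labels)
        fh.write(f"individual\theterozygosity\ttrue_froh\t{labels}\n")
        for i, g in enumerate(sample.individuals):
            rohs = extract_true_rohs(g, L)
            bf = binned_froh(rohs, bins, L)
            bcols = "\t".join(f"{v:.6g}" for v in bf)
            fh.write(f"ind{i}\t{heterozygosity(g, L):.6g}\t"
                     f"{froh(rohs, L):.6g}\t{bcols}\n")


def write_truth_vcf(sample: PopulationSample, path, chrom: str = "chr1") -> None:
    """Exact phased genotypes at all segregating sites, as VCF 4.2."""
    import pysam

    L = sample.genome.length_bp
    haps = [(g.hapA, g.hapB) for g in sample.individuals]
    all_pos = np.unique(np.concatenate([np.concatenate([a, b]) for a, b in haps])
                        if haps else np.empty(0, np.int64))
    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    header.contigs.add(chrom, length=L)
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    names = [f"ind{i}" for i in range(len(haps))]
    for n in names:
        header.add_sample(n)
    membership = np.zeros((len(haps), 2, all_pos.size), dtype=bool)
    for i, (a, b) in enumerate(haps):
        membership[i, 0] = np.isin(all_pos, a, assume_unique=True)
        membership[i, 1] = np.isin(all_pos, b, assume_unique=True)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j, pos in enumerate(all_pos):
            rec = vcf.new_record(contig=chrom, start=int(pos), stop=int(pos) + 1,
                                 alleles=("A", "T"))
            for i, n in enumerate(names):
                rec.samples[n]["GT"] = (int(membership[i, 0, j]), int(membership[i, 1, j]))
                rec.samples[n].phased = True
            vcf.write(rec)
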