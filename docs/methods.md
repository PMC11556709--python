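# Methods

`rohbench` benchmarks two runs-of-homozygosity (ROH) callers on simulated
populations whose ROH ground truth is known exactly. This note documents the
models, the choices that were genuinely open, and what the synthetic data do
and do not establish about real data.

## Forward simulation (`simdemog`)

Diploid individuals carry a homologous pair of 30-Mb chromosomes. Each
haplotype is the set of derived-mutation positions under an infinite-sites
model (a proposed mutation position already in use is re-drawn), so
heterozygous sites are exactly the symmetric difference of an individual's
two position sets. Populations are founded monomorphic and evolve as neutral
Wright–Fisher generations: every offspring draws two parents uniformly at
random (incidental selfing allowed); each gamete receives
Poisson(r·L) crossovers at uniform positions and Poisson(mu·L) new
mutations. Defaults are the Tasmanian-devil rate estimates,
mu = 1.39e-8 and r = 9.15e-9 per site per generation.

Four demographic presets share a 10,000-generation burn-in at 10,000
diploids and then diverge: **large** (1,000 generations at 1,000),
**small** (1,000 at 250), **bottlenecked** (900 at 1,000; 50 at 50; 50 at
250) and **declining** (850 at 1,000; then 50 each at 500, 250, 50). Fifty
individuals are sampled without replacement from the final generation.

**Rescaling.** A factor lambda divides census sizes and epoch durations and
multiplies both per-bp rates, preserving N·mu, N·r and epoch lengths in
coalescent units. lambda = 1 is the nominal configuration; desk-scale runs
use lambda = 20 (a 30-Mb burn-in in ~15 s) or lambda = 5 (~3 min; exact
integer rescaling of every preset epoch). Durations round to the nearest
integer with a floor of one generation; a size that rounds below two
diploids is an error rather than silently floored. Known limitation:
because coalescence happens at integer generations, scenarios whose recent
history consists of very short epochs lose the most recent (longest-ROH)
coalescences as lambda grows. For the declining preset the mean true F_ROH
is ~0.58 at full scale, ~0.55 at lambda=5, ~0.52 at lambda=10 and ~0.45 at
lambda=20; the other presets are insensitive. Where scaled results are
compared against full-size reference values this bias must be kept in mind;
the headline quantities are therefore recomputed at lambda=5.

Replicate study runs exploit that all presets share the burn-in epoch: one
burn-in per seed is branched into each scenario's tail. When a rescaled
final population is smaller than the 50-individual target, several
independent tail replicates are branched from the same burn-in and pooled.
Pooled individuals share ancestral (burn-in) variation but are conditionally
independent given it; scenario means are unbiased, with less between-
individual independence than distinct full runs would give.

**True ROHs.** Maximal runs without heterozygous sites. Between consecutive
het positions h_k < h_{k+1} the run is [h_k + 1, h_{k+1}); chromosome ends
close the first and last runs. Heterozygous sites themselves are excluded —
the convention is arbitrary at the bp level and immaterial beyond it. Runs
>= 100 kb (closed threshold) constitute the truth set everywhere, matching
the length filter applied to every caller's output; F_ROH is their total
length divided by L.

## Genotype observation emulator (`seqemu`)

Read simulation, alignment and a full variant-calling stack are replaced by
a parametric model whose only purpose is depth-dependent genotype error and
missingness. At each segregating site of the sample, an individual receives
d ~ Poisson(mean_depth) reads (presets 5/10/15/30/50X); d = 0 is a missing
call. Each read samples one haplotype uniformly and reports its allele,
flipped with probability epsilon (default 0.005, a typical short-read
substitution rate). Genotypes are called by maximum likelihood with a flat
prior — per read, a homozygote emits the matching allele with probability
1 - epsilon and a heterozygote either allele with probability 1/2 — ties
broken toward the homozygote matching the majority read allele, then
hom-ref. PL values are the phred-scaled, min-normalized likelihoods, capped
at 255. Sites left without both alleles among the calls are dropped, and
allele frequencies are recomputed from the calls after every filter.

Analytics used as checks: with epsilon = 0, a true heterozygote at depth d
is mis-called homozygous iff all reads sample one haplotype, probability
2·(1/2)^d (0.0625 at d = 5), monotone decreasing in depth.

What the emulator does **not** model: coverage autocorrelation, mapping
bias, indels, multi-allelic sites, and the site-level filtering of a real
GATK-style pipeline. Emulated genotypes at >= 10X are consequently much
cleaner than real pipeline output (per-base false-negative rates of a few
percent rather than tens of percent). Passing benchmarks here demonstrate
the callers' behaviour on well-called data; they deliberately understate
error regimes real low-coverage studies face, and benchmark properties that
hinge on pipeline-induced noise (e.g. heavy false-negative regimes at all
depths) will not reproduce under this emulator.

MAF and missingness site filters (closed >= for MAF, strict < for
missingness) are available but off by default for simulated data.

VCF 4.2 is the interchange format (contig `chr1`, FORMAT GT:DP:PL, missing
genotype `./.`), written directly and read back via cyvcf2 with a verified
field-for-field round trip.

## Autozygosity HMM (`hmmroh`)

Two hidden states: HW (Hardy–Weinberg) and AZ (autozygous). With sample
alternate-allele frequency p at a site, emissions over genotypes are
HW: {(1-p)^2, 2p(1-p), p^2}; AZ: {(1-p)(1-leak), leak, p(1-leak)}. The
`az_het_leak` (default 1e-4) absorbs genotyping errors inside autozygous
tracts. `genotypes` mode scores the called genotype; `likelihoods` mode
scores sum_g P(reads|g)·P(g|state) with P(reads|g) de-phredded from PL.
Between adjacent retained sites d bp apart the switch probability is
1 - exp(-rate·d) (exponential interarrival — the standard scaling for
per-bp rates; the defaults 6.7e-8 and 5e-9 for HW->AZ and AZ->HW match this
magnitude). Missing genotypes are skipped while distance accumulates; start
probabilities are uniform. Decoding is exact Viterbi in log space (verified
against exhaustive path enumeration up to 12 sites); maximal AZ runs become
calls spanning first to last site.

**Viterbi training** re-estimates both rates from hard assignments:
rate = (# switches out of a state) / (bp traversed in that state), iterated
(floor 1e-12, convergence 1e-10 relative, max 100 iterations); individuals
with fewer than two usable sites or zero called heterozygosity are excluded
and logged rather than failing the run. The counting re-estimator is the
small-rate approximation of the exact MLE under the exponential transition
law, so the Viterbi score is monotone non-decreasing up to that
approximation; tests assert monotonicity with a 1e-6 relative tolerance.

## Sliding-window scanner (`winroh`)

The scan follows the classic window-voting design: (1) windows of `phws`
consecutive SNPs are homozygous iff they contain <= `phwh` het and <=
`phwm` missing calls (a chromosome with fewer sites yields one truncated
window); (2) a site is in-ROH iff the fraction of windows containing it
that are homozygous is >= `phwt`, the denominator counting only windows
that exist (edge correction); (3) runs of in-ROH sites split where adjacent
sites are > `phzg` kb apart; (4) a run is reported iff it has >= `phzs`
sites, spans >= `phzk` kb and has span/site count <= `phzd` kb. All
comparisons are closed as written; a brute-force re-implementation of these
four steps defines the semantics and the production scanner is tested
against it on random instances. A het site can itself be in-ROH: smoothing
is per-window voting, not per-site gating.

Defaults mirror the upstream tool (phwh 1, phwm 5, phws 50, phzd 50,
phzg 1000, phwt 0.05, phzs 100, phzk 1000). Benchmark runs set
phzk = 100 kb — the grid's tested value — so the scanner's reporting floor
matches the global 100-kb analysis filter. The initial exploration grid
varies six parameters (3·3·3·2·3·3 = 486 combinations) with phzd and phzk
held fixed.

## Accuracy metrics (`rohmetrics`)

Per-base rates by exact interval arithmetic on 0-based half-open intervals:
FN = |true \ called| / |true| (undefined when no true ROHs);
FP = |called \ true| / (L - |true|) (undefined when truth covers the
chromosome). Undefined rates are NaN and excluded from medians. Length bins
are short [100, 500) kb, intermediate [500 kb, 1 Mb), long [1, 2) Mb, very
long >= 2 Mb; each ROH contributes wholly to its own length's bin, so bin
F_ROH values sum to overall F_ROH. Lumping counts overlaps (>= 1 bp) in
both directions: true ROHs per called ROH and the converse, plus the count
of true ROHs overlapping >= 2 called ROHs ("splits"). True-vs-called F_ROH
relationships use OLS (true as predictor) with Student-t 95% CIs, flagging
whether the intercept excludes 0 and the slope excludes 1. Bootstrap CIs
are percentile with 1,000 seeded resamples.

## Sensitivity analysis (`sensitivity`)

For each individual, the grid response (called F_ROH across all
combinations) and each varied parameter are z-scored and fit by OLS; the
coefficients are standardized regression coefficients (SRC), equal to
correlation(x_i, y) on an orthogonal grid. SRRC applies the same machinery
to ranks. SRC is the default: the upstream description conflates the two
names, both are implemented, and outputs record which was used. Parameters
tested at a single value are excluded and reported as fixed. The
per-parameter recommendation uses the median and IQR of indices across
individuals with tolerance 0.05 for "approximately zero": below tolerance
on both means keep the default; otherwise explore in the direction of the
median's sign. One model per individual (rather than one per combination)
resolves the ambiguity in the loop's description: the response of a single
individual across combinations is the quantity the loop inspects.

## Orchestration and reproducibility (`pipeline`, `benchmark`)

Every stochastic stage consumes a seed derived by SHA-256 from the master
seed and the stage identity (stage name, scenario, depth), all below 2^31;
identical configs produce byte-identical outputs and any stage can be
re-derived in isolation. Output tables are TSV with a header comment
carrying a hash of the scientific config; `run_pipeline` validates its
manifest after every run. The `benchmark` module holds the study design
shared by the analysis scripts and the acceptance evaluation (shared
burn-ins, tail pooling, caller scoring).

## Known limitations

* Neutral simulation only: no selection, no deleterious-mutation load.
  Published simulations in this design space derive from scripts that carry
  deleterious mutations; their reported heterozygosity (2.4–3.2e-5 across
  scenarios) is several-fold below the neutral expectation at these rates
  (0.4–1.5e-4 here), which makes true ROHs here shorter-gapped and denser
  in het sites. Quantities that depend on het density (lumping ratios,
  split counts) differ accordingly.
* Forward-WF rescaling bias for recently crashed populations (above).
* Single chromosome, diallelic SNPs, no recombination map.
* The observation emulator's error profile is a qualitative stand-in for a
  read-level pipeline (above); coverage-trend results that depend on
  pipeline-specific 5X artefacts reproduce only partially.

## Problem sizes used in the shipped runs

Test-suite study: lambda = 20, three burn-in seeds, four scenarios,
depths {5, 10, 15, 30, 50}, ~50 individuals per scenario. Acceptance
evaluation: lambda = 5, three burn-in seeds, depths {10, 15, 30, 50} for
slope targets and 30X for the lumping target. Both choices are the
package's own balance of statistical resolution against a desk-scale
footprint.
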