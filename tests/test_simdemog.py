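import numpy as np
import pytest

from rohbench.intervals import ROHSet
from rohbench.simdemog import (DiploidGenome, Epoch, GenomeModel,
                               PopulationSample, Population, Scenario,
                               _recombine, extract_true_rohs, froh,
                               heterozygosity, simulate_population,
                               write_true_roh_bed, write_truth_vcf)


def make_genome(hapA, hapB):
    return DiploidGenome(np.asarray(hapA, np.int64), np.asarray(hapB, np.int64))


class TestPresets:
    def test_presets_match_published_histories(self):
        burn = Epoch(10_000, 10_000)
        assert Scenario.preset("large").epochs == (burn, Epoch(1000, 1000))
        assert Scenario.preset("small").epochs == (burn, Epoch(250, 1000))
        assert Scenario.preset("bottlenecked").epochs == (
            burn, Epoch(1000, 900), Epoch(50, 50), Epoch(250, 50))
        assert Scenario.preset("declining").epochs == (
            burn, Epoch(1000, 850), Epoch(500, 50), Epoch(250, 50), Epoch(50, 50))

    def test_unknown_preset_raises(self):
        with pytest.raises(KeyError):
            Scenario.preset("exponential")

    def test_rescaling_preserves_diffusion_units(self):
        g = GenomeModel(scale=10.0)
        eps = g.rescaled_epochs(Scenario.preset("declining"))
        assert eps == (Epoch(1000, 1000), Epoch(100, 85), Epoch(50, 5),
                       Epoch(25, 5), Epoch(5, 5))
        # N*mu and N*rec preserved
        assert g.mu_eff == pytest.approx(10 * g.mu)
        assert g.rec_eff == pytest.approx(10 * g.rec)

    def test_rescaling_below_two_diploids_raises(self):
        g = GenomeModel(scale=40.0)
        with pytest.raises(ValueError, match="below 2"):
            g.rescaled_epochs(Scenario.preset("declining"))


class TestExtractTrueRohs:
    def test_no_heterozygous_sites_yields_whole_chromosome(self):
        rs = extract_true_rohs(make_genome([5, 9], [5, 9]), L=1_000_000)
        assert [tuple(iv) for iv in rs] == [(0, 1_000_000)]

    def test_boundary_convention_and_length_filter(self):
        # het positions split the chromosome; het sites excluded from runs
        g = make_genome([100_000, 450_000, 460_000], [])
        rs = extract_true_rohs(g, L=1_000_000, min_len=100_000)
        assert [tuple(iv) for iv in rs] == [
            (0, 100_000), (100_001, 450_000), (460_001, 1_000_000)]

    def test_min_len_above_l_gives_empty_set(self):
        rs = extract_true_rohs(make_genome([], []), L=1000, min_len=2000)
        assert len(rs) == 0

    def test_unfiltered_rohs_complement_het_sites_exactly(self, rng):
        L = 100_000
        hapA = np.sort(rng.choice(L, 200, replace=False))
        hapB = np.sort(rng.choice(L, 200, replace=False))
        g = DiploidGenome(hapA, hapB)
        rs = extract_true_rohs(g, L, min_len=0)
        n_het = g.het_positions().size
        assert rs.total_length + n_het == L
        ivals = rs.intervals
        assert np.all(ivals[1:, 0] >= ivals[:-1, 1])


class TestFrohHeterozygosity:
    def test_froh_basic_values(self):
        L = 30_000_000
        assert froh(ROHSet(), L) == 0
        assert froh(ROHSet(np.array([[0, L]])), L) == 1
        rs = ROHSet(np.array([[0, 3_000_000], [10_000_000, 16_000_000]]))
        assert froh(rs, L) == pytest.approx(0.3)

    def test_heterozygosity_is_symmetric_difference_density(self):
        assert heterozygosity(make_genome([1, 2], [2, 3]), L=10) == pytest.approx(0.2)
        assert heterozygosity(make_genome([7], [7]), L=10) == 0
        assert heterozygosity(make_genome(range(300), []), L=30_000_000) == pytest.approx(1e-5)


class TestSimulation:
    def test_zero_mutation_rate_forces_total_homozygosity(self):
        g = GenomeModel(length_bp=200_000, mu=0.0)
        sc = Scenario.custom([Epoch(20, 15)])
        pop = simulate_population(sc, g, n_sample=10, seed=1)
        for ind in pop.individuals:
            assert heterozygosity(ind, g.length_bp) == 0
            rs = extract_true_rohs(ind, g.length_bp)
            assert [tuple(iv) for iv in rs] == [(0, g.length_bp)]

    def test_determinism_bit_identical(self):
        g = GenomeModel(length_bp=500_000)
        sc = Scenario.custom([Epoch(30, 25)])
        a = simulate_population(sc, g, n_sample=5, seed=42)
        b = simulate_population(sc, g, n_sample=5, seed=42)
        for x, y in zip(a.individuals, b.individuals):
            assert np.array_equal(x.hapA, y.hapA)
            assert np.array_equal(x.hapB, y.hapB)

    def test_oversampling_raises(self):
        g = GenomeModel(length_bp=100_000)
        with pytest.raises(ValueError, match="exceeds the final epoch size"):
            simulate_population(Scenario.custom([Epoch(5, 3)]), g, n_sample=10, seed=0)

    def test_haplotypes_sorted_unique_in_range(self):
        g = GenomeModel(length_bp=500_000)
        pop = simulate_population(Scenario.custom([Epoch(25, 40)]), g,
                                  n_sample=10, seed=7)
        for ind in pop.individuals:
            for h in (ind.hapA, ind.hapB):
                assert np.all(np.diff(h) > 0)
                if h.size:
                    assert 0 <= h.min() and h.max() < g.length_bp

    def test_equilibrium_heterozygosity_matches_neutral_theory(self):
        # theta = 4*N*mu at mutation-drift equilibrium (infinite sites)
        N, L = 100, 2_000_000
        g = GenomeModel(length_bp=L, mu=5e-7, rec=1e-8)
        sc = Scenario.custom([Epoch(N, 12 * N)])
        theta = 4 * N * g.mu
        hets = []
        for seed in range(5):
            pop = simulate_population(sc, g, n_sample=20, seed=seed)
            hets.append(np.mean([heterozygosity(i, L) for i in pop.individuals]))
        assert np.mean(hets) == pytest.approx(theta, rel=0.15)


class TestRecombineReference:
    def test_recombine_switches_template_at_breakpoints(self):
        hapA = np.array([10, 20, 30, 40], dtype=np.int64)
        hapB = np.array([15, 35], dtype=np.int64)
        out = _recombine(hapA, hapB, np.array([25], dtype=np.int64), start=0)
        assert out.tolist() == [10, 20, 35]
        out = _recombine(hapA, hapB, np.array([25], dtype=np.int64), start=1)
        assert out.tolist() == [15, 30, 40]
        out = _recombine(hapA, hapB, np.empty(0, dtype=np.int64), start=0)
        assert out.tolist() == hapA.tolist()


class TestWriters:
    def test_true_roh_bed_roundtrip(self, tmp_path):
        sets = [ROHSet(np.array([[0, 150_000], [200_000, 400_000]])),
                ROHSet()]
        path = tmp_path / "true.bed"
        write_true_roh_bed(sets, path)
        lines = path.read_text().splitlines()
        assert lines == ["chr1\t0\t150000\tind0", "chr1\t200000\t400000\tind0"]

    def test_truth_vcf_has_exact_phased_genotypes(self, tmp_path):
        g = GenomeModel(length_bp=100_000)
        pop = simulate_population(Scenario.custom([Epoch(10, 30)]), g,
                                  n_sample=4, seed=3)
        path = tmp_path / "truth.vcf"
        write_truth_vcf(pop, path)
        import pysam
        with pysam.VariantFile(str(path)) as vcf:
            recs = list(vcf)
        all_pos = np.unique(np.concatenate(
            [np.concatenate([i.hapA, i.hapB]) for i in pop.individuals]))
        assert [r.start for r in recs] == all_pos.tolist()
        for r in recs:
            for i, ind in enumerate(pop.individuals):
                gt = r.samples[f"ind{i}"]["GT"]
                assert gt == (int(r.start in ind.hapA), int(r.start in ind.hapB))
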