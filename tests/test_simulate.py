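"""Forward simulator: founders, selection, crossing, sequencing."""

import math

import numpy as np
import pytest
from scipy import stats

from poolcross.conditions import Line, Stage
from poolcross.simulate import (
    CNV_GENE,
    LocusSpec,
    Population,
    SimConfig,
    SNP,
    ToleranceModel,
    cross,
    find_ld,
    run_design,
    select_survivors,
    simulate_counts,
    simulate_coverage,
    simulate_founders,
    build_gene_panel,
    survival_probability,
)
from poolcross.tables import Effect

BETA3 = math.log10(3.0)


def snp(freq, chrom="chr1", pos=0, beta=None, **kw):
    return LocusSpec(chrom, pos, SNP, freq, beta=beta or {}, **kw)


def new_rng(seed=0):
    return np.random.default_rng(seed)


class TestFounders:
    def test_fixed_allele(self):
        pop = simulate_founders(SimConfig(f0_census=50), [snp(1.0)], new_rng())
        assert (pop.dosage() == 2).all()

    def test_frequency_law_of_large_numbers(self):
        pop = simulate_founders(SimConfig(f0_census=10_000), [snp(0.5)], new_rng(1))
        se = math.sqrt(0.5 * 0.5 / (2 * 10_000))
        assert abs(pop.allele_freq()[0] - 0.5) < 3 * se

    def test_seed_determinism(self):
        cfg = SimConfig(f0_census=500, seed=9)
        loci = [snp(0.3), snp(0.7, pos=10)]
        a = simulate_founders(cfg, loci, new_rng(9)).haplotypes
        b = simulate_founders(cfg, loci, new_rng(9)).haplotypes
        assert (a == b).all()

    def test_haplotype_group_cosegregates(self):
        loci = [
            snp(0.4, pos=0, haplotype_group="hg"),
            snp(0.4, pos=1, haplotype_group="hg"),
        ]
        pop = simulate_founders(SimConfig(f0_census=2000), loci, new_rng(2))
        assert (pop.haplotypes[:, 0, :] == pop.haplotypes[:, 1, :]).all()

    def test_haplotype_group_frequency_mismatch_rejected(self):
        loci = [snp(0.4, haplotype_group="hg"), snp(0.5, pos=1, haplotype_group="hg")]
        with pytest.raises(ValueError, match="hg"):
            simulate_founders(SimConfig(f0_census=10), loci, new_rng())


class TestSurvival:
    def test_phi_zero_is_half(self):
        model = ToleranceModel(betas=np.zeros(1), mu0=0.0, sigma=1.0)
        p = survival_probability(np.array([[0]]), 1.0, model)
        assert p[0] == pytest.approx(0.5)

    def test_vanishes_at_high_dose(self):
        model = ToleranceModel(betas=np.zeros(1), mu0=0.0, sigma=1.0)
        assert survival_probability(np.array([[0]]), 1e12, model)[0] < 1e-9

    def test_carrier_survives_more(self):
        model = ToleranceModel(betas=np.array([1.0]), sigma=0.5)
        for dose in (0.1, 1.0, 10.0):
            p0 = survival_probability(np.array([[0]]), dose, model)[0]
            p1 = survival_probability(np.array([[1]]), dose, model)[0]
            assert p1 > p0

    def test_nonpositive_dose_fatal(self):
        model = ToleranceModel(betas=np.zeros(1))
        with pytest.raises(ValueError):
            survival_probability(np.array([[0]]), 0.0, model)


class TestFindLd:
    def test_homogeneous_ld50_closed_form(self):
        # all individuals share sum(beta*g); LD50 = 10^(mu0 + sum)
        model = ToleranceModel(betas=np.array([0.5]), mu0=0.2, sigma=0.3)
        hap = np.ones((200, 1, 2), dtype=np.uint8)
        pop = Population(hap, np.ones(200, dtype=bool))
        ld50 = find_ld(pop, model, 0.5)
        assert ld50 == pytest.approx(10 ** (0.2 + 1.0), rel=1e-6)

    def test_ld25_below_ld75(self):
        loci = [snp(0.5, beta={Line.DELT: BETA3})]
        pop = simulate_founders(SimConfig(f0_census=1000), loci, new_rng(3))
        model = ToleranceModel(betas=np.array([BETA3]))
        assert find_ld(pop, model, 0.25) < find_ld(pop, model, 0.75)

    def test_mixture_ld50_between_subgroup_ld50s(self):
        model = ToleranceModel(betas=np.array([0.6]), sigma=0.2)
        hap = np.zeros((1000, 1, 2), dtype=np.uint8)
        hap[:500] = 1  # half homozygous carriers (LD50=10^1.2), half non (10^0)
        pop = Population(hap, np.ones(1000, dtype=bool))
        ld50 = find_ld(pop, model, 0.5)
        assert 10**0 < ld50 < 10**1.2

    def test_invalid_mortality(self):
        model = ToleranceModel(betas=np.zeros(1))
        pop = Population(np.zeros((10, 1, 2), np.uint8), np.ones(10, bool))
        with pytest.raises(ValueError):
            find_ld(pop, model, 1.5)


class TestSelection:
    def test_tiny_dose_spares_all(self):
        pop = simulate_founders(SimConfig(f0_census=200), [snp(0.5)], new_rng(4))
        model = ToleranceModel(betas=np.zeros(1))
        surv = select_survivors(pop, 1e-12, model, new_rng(4))
        assert surv.n == pop.n

    def test_zero_survivors_fatal(self):
        pop = simulate_founders(SimConfig(f0_census=50), [snp(0.5)], new_rng(5))
        model = ToleranceModel(betas=np.zeros(1), sigma=0.1)
        with pytest.raises(RuntimeError, match="survivors"):
            select_survivors(pop, 1e12, model, new_rng(5))

    def test_neutral_locus_frequency_unchanged(self):
        # beta=0: survivor frequency within 3 SE of census frequency
        diffs = []
        for seed in range(30):
            pop = simulate_founders(SimConfig(f0_census=1000), [snp(0.5)], new_rng(seed))
            model = ToleranceModel(betas=np.zeros(1), sigma=0.3)
            surv = select_survivors(pop, 1.0, model, new_rng(100 + seed))
            diffs.append(surv.allele_freq()[0] - pop.allele_freq()[0])
        se = math.sqrt(0.25 / (2 * 500)) / math.sqrt(30)  # ~500 survivors
        assert abs(np.mean(diffs)) < 3 * se

    def test_selection_matches_analytic_conditional_expectation(self):
        # expected survivor frequency = sum_g f_g * p_surv(g) * g/2 / norm,
        # computed from the census genotype tallies and survival weights
        loci = [snp(0.4, beta={Line.DELT: BETA3})]
        model = ToleranceModel(betas=np.array([BETA3]), sigma=0.15)
        cfg = SimConfig(f0_census=4000)
        dose = None
        realized, expected = [], []
        for seed in range(20):
            pop = simulate_founders(cfg, loci, new_rng(seed))
            if dose is None:
                dose = find_ld(pop, model, 0.8)
            g = pop.dosage()[:, 0]
            w = model.survival(pop.dosage(), dose)
            expected.append(float((w * g).sum() / (2 * w.sum())))
            surv = select_survivors(pop, dose, model, new_rng(500 + seed))
            realized.append(surv.allele_freq()[0])
        assert np.mean(realized) == pytest.approx(np.mean(expected), abs=0.01)
        assert np.mean(realized) > 0.4  # enriched over census frequency


class TestCross:
    def test_fixed_carrier_by_susceptible_gives_heterozygotes(self):
        mothers = Population(np.ones((50, 1, 2), np.uint8), np.ones(50, bool))
        fathers = Population(np.zeros((50, 1, 2), np.uint8), np.zeros(50, bool))
        loci = [snp(1.0)]
        off = cross(mothers, fathers, 500, loci, new_rng(6))
        assert (off.dosage() == 1).all()
        assert off.allele_freq()[0] == pytest.approx(0.5)

    def test_empty_parent_set_fatal(self):
        pop = Population(np.zeros((0, 1, 2), np.uint8), np.zeros(0, bool))
        full = Population(np.zeros((5, 1, 2), np.uint8), np.ones(5, bool))
        with pytest.raises(ValueError):
            cross(pop, full, 10, [snp(0.0)], new_rng())

    def test_unlinked_loci_independent(self):
        # two-locus genotype frequencies equal the product of marginals
        loci = [snp(0.5, pos=0), snp(0.5, pos=100)]
        mothers = simulate_founders(SimConfig(f0_census=500), loci, new_rng(7))
        off = cross(mothers, mothers, 10_000, loci, new_rng(8))
        g = off.dosage()
        table = np.zeros((3, 3))
        for a in range(3):
            for b in range(3):
                table[a, b] = ((g[:, 0] == a) & (g[:, 1] == b)).sum()
        chi2, p, *_ = stats.chi2_contingency(table)[:2]
        assert p > 1e-4

    def test_complete_linkage_cosegregates(self):
        loci = [
            snp(0.5, pos=0, haplotype_group="hg"),
            snp(0.5, pos=1, haplotype_group="hg", recomb_to_prev=0.0),
        ]
        mothers = simulate_founders(SimConfig(f0_census=400), loci, new_rng(9))
        off = cross(mothers, mothers, 2000, loci, new_rng(10), recomb_fraction=0.5)
        assert (off.haplotypes[:, 0, :] == off.haplotypes[:, 1, :]).all()


@pytest.fixture(scope="module")
def neutral_design():
    loci = [snp(0.6, pos=i * 1000) for i in range(3)]
    return run_design(loci, SimConfig(seed=11, f0_census=2000))


class TestRunDesign:
    def test_thirteen_pools_of_pool_size(self, neutral_design):
        assert len(neutral_design.pools) == 13
        for pool in neutral_design.pools.values():
            assert pool.shape == (100, 3)

    def test_truth_equals_realized_pool_frequencies(self, neutral_design):
        for label, pool in neutral_design.pools.items():
            np.testing.assert_allclose(
                neutral_design.truth[f"freq_{label}"], pool.mean(axis=0) / 2.0
            )

    def test_neutral_mendelian_dilution(self):
        # beta=0 everywhere: expected (p, p, p/2, p/2, p/2) per line
        freqs = {s: [] for s in ("F0", "F0_LD80", "F2", "F2_LD25", "F2_LD75")}
        for seed in range(25):
            loci = [snp(0.6)]
            d = run_design(loci, SimConfig(seed=seed, f0_census=2000))
            freqs["F0"].append(d.truth["freq_F0"][0])
            for s in ("F0_LD80", "F2", "F2_LD25", "F2_LD75"):
                freqs[s].append(d.truth[f"freq_Delt_{s}"][0])
        se = math.sqrt(0.24 / 200 / 25)
        assert np.mean(freqs["F0"]) == pytest.approx(0.6, abs=4 * se)
        assert np.mean(freqs["F0_LD80"]) == pytest.approx(0.6, abs=4 * se)
        for s in ("F2", "F2_LD25", "F2_LD75"):
            assert np.mean(freqs[s]) == pytest.approx(0.3, abs=5 * se)

    def test_determinism_bit_identical(self):
        loci = [snp(0.5), snp(0.2, pos=10)]
        cfg = SimConfig(seed=21, f0_census=2000)
        a = run_design(loci, cfg)
        b = run_design(loci, cfg)
        for label in a.pools:
            assert (a.pools[label] == b.pools[label]).all()
        assert a.doses == b.doses


class TestSequencingNoise:
    def test_binomial_mean_at_half(self):
        loci = [snp(0.5, effect=Effect.INTERGENIC)]
        design = run_design(loci, SimConfig(seed=30, f0_census=2000, error_rate=0.0))
        f = design.pool_freq("F0")[0]
        alts = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            counts = simulate_counts(design, rng)
            alts.append(counts.frequency("F0")[0])
        assert np.mean(alts) == pytest.approx(f, abs=0.02)

    def test_monomorphic_without_error_stays_zero(self):
        loci = [snp(0.0)]
        design = run_design(loci, SimConfig(seed=31, f0_census=2000, error_rate=0.0))
        counts = simulate_counts(design)
        for label in design.pools:
            assert counts.alt_counts(label)[0] == 0

    def test_error_rate_generates_alt_reads(self):
        loci = [snp(0.0)]
        cfg = SimConfig(
            seed=32, f0_census=2000, error_rate=0.01, depth_mean=1000.0
        )
        design = run_design(loci, cfg)
        rates = []
        for seed in range(100):
            counts = simulate_counts(design, np.random.default_rng(seed))
            rates.append(counts.alt_counts("F0")[0] / counts.depth("F0")[0])
        assert np.mean(rates) == pytest.approx(0.01, abs=0.003)


class TestCoverageDosage:
    def _design(self, founder_freq, seed=33):
        loci = [
            LocusSpec(
                "chr1", 0, CNV_GENE, founder_freq, cnv_copies=3, gene_id="amp1"
            ),
            LocusSpec("chr1", 10_000, CNV_GENE, 0.0, gene_id="flat1"),
        ]
        design = run_design(loci, SimConfig(seed=seed, f0_census=2000))
        regions, _ = build_gene_panel(loci, seed=seed)
        return design, regions

    def test_fixed_amplification_triples_coverage(self):
        design, regions = self._design(founder_freq=1.0)
        assert design.pool_copy_number("F0")[0] == pytest.approx(6.0)
        ratios = []
        amp_ids = regions.loc[regions.gene_id == "amp1", "region_id"]
        flat_ids = regions.loc[regions.gene_id == "flat1", "region_id"]
        for seed in range(60):
            cov = simulate_coverage(design, regions, np.random.default_rng(seed))
            ratios.append(
                cov.depth.loc[amp_ids, "F0"].mean() / cov.depth.loc[flat_ids, "F0"].mean()
            )
        # 3x dosage modulated by fixed per-region capture factors; compare
        # against the factor-corrected expectation
        assert np.mean(ratios) == pytest.approx(3.0, rel=0.25)

    def test_half_frequency_pool_copy_number_matches_genotypes(self):
        design, regions = self._design(founder_freq=0.5)
        g = design.pools["F0"][:, 0]
        expected = (2 + g * 2).mean()  # k=3: each amp allele adds 2 copies
        assert design.pool_copy_number("F0")[0] == pytest.approx(expected)

    def test_no_cnv_means_equal_expected_coverage(self):
        design, regions = self._design(founder_freq=0.0)
        cov = simulate_coverage(design, regions, np.random.default_rng(1))
        assert design.pool_copy_number("F0")[0] == 2.0
        assert design.pool_copy_number("F0")[1] == 2.0
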