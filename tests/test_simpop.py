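"""Unit tests for the population/genotype/trait simulator."""

import numpy as np
import pandas as pd
import pytest

from wgspred import simpop
from wgspred.errors import (
    ConfigurationError,
    InfeasibleDesignError,
    IntegrityError,
)


def small_genome(**overrides):
    kwargs = dict(
        n_chromosomes=2,
        chromosome_length_bp=1_000_000,
        variants_per_chromosome=50,
        recombination_rate=1e-8,
        founder_ld_decay=10_000.0,
    )
    kwargs.update(overrides)
    return simpop.GenomeConfig(**kwargs)


class TestSimulatePedigree:
    def test_fixed_litter_size_gives_exact_full_sib_families(self):
        ped = simpop.simulate_pedigree(
            simpop.LineDesign("A", 10, 1, 2, 3, 5), seed=1
        )
        founders = ped.table[ped.table["generation"] == 0]
        assert len(founders) == 10
        litters = ped.table[ped.table["generation"] == 1].groupby(
            ["sire", "dam"]
        )
        assert len(litters) > 0
        for _, litter in litters:
            assert len(litter) % 5 == 0  # dams may share a sire, never a mate
        per_dam = ped.table[ped.table["generation"] == 1].groupby("dam").size()
        assert (per_dam == 5).all()

    def test_zero_generations_gives_founders_only(self):
        ped = simpop.simulate_pedigree(
            simpop.LineDesign("A", 7, 0, 1, 1, 5), seed=1
        )
        assert len(ped.table) == 7
        assert (ped.table["sire"] == simpop.MISSING_PARENT).all()
        assert (ped.table["dam"] == simpop.MISSING_PARENT).all()

    def test_same_seed_reproduces_byte_identical_tables(self):
        d = simpop.LineDesign("A", 20, 2, 3, 6, 5)
        t1 = simpop.simulate_pedigree(d, seed=42).table
        t2 = simpop.simulate_pedigree(d, seed=42).table
        pd.testing.assert_frame_equal(t1, t2)
        t3 = simpop.simulate_pedigree(d, seed=43).table
        assert not t1.equals(t3)

    def test_invariants_hold(self):
        ped = simpop.simulate_pedigree(
            [
                simpop.LineDesign("A", 20, 2, 3, 6, 5),
                simpop.LineDesign("B", 12, 1, 2, 4, 6),
            ],
            seed=3,
        )
        ped.validate()  # raises on violation
        # litters share sire, dam, generation by construction
        kids = ped.table[ped.table["sire"] != simpop.MISSING_PARENT]
        assert (kids.groupby(["sire", "dam"])["generation"].nunique() == 1).all()

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            simpop.simulate_pedigree(
                simpop.LineDesign("A", 0, 1, 1, 1, 5), seed=1
            )

    def test_infeasible_matings_rejected(self):
        with pytest.raises(InfeasibleDesignError):
            simpop.simulate_pedigree(
                simpop.LineDesign("A", 4, 1, 10, 10, 5), seed=1
            )


class TestGeneDropping:
    def test_homozygous_parents_force_offspring_dosage(self):
        ped = simpop.simulate_pedigree(
            simpop.LineDesign("A", 10, 2, 2, 4, 5), seed=5
        )
        geno = simpop.simulate_founders_and_drop(ped, small_genome(), seed=5)
        sire, dam = ped.parent_indices()
        child_rows = np.flatnonzero(sire >= 0)
        for i in child_rows:
            both_two = (geno.dosages[sire[i]] == 2) & (geno.dosages[dam[i]] == 2)
            assert (geno.dosages[i][both_two] == 2).all()
            both_zero = (geno.dosages[sire[i]] == 0) & (
                geno.dosages[dam[i]] == 0
            )
            assert (geno.dosages[i][both_zero] == 0).all()

    def test_mendelian_consistency_of_every_trio(self):
        ped = simpop.simulate_pedigree(
            simpop.LineDesign("A", 12, 3, 2, 4, 5), seed=6
        )
        geno = simpop.simulate_founders_and_drop(ped, small_genome(), seed=6)
        sire, dam = ped.parent_indices()
        haps = geno.haplotypes
        for i in np.flatnonzero(sire >= 0):
            # paternal gamete allele must exist among the sire's two alleles
            for parent_row, hap_idx in ((sire[i], 0), (dam[i], 1)):
                child_allele = haps[i, hap_idx]
                ok = (child_allele == haps[parent_row, 0]) | (
                    child_allele == haps[parent_row, 1]
                )
                assert ok.all()

    def test_zero_recombination_transmits_intact_chromosomes(self):
        ped = simpop.simulate_pedigree(
            simpop.LineDesign("A", 8, 3, 2, 3, 5), seed=7
        )
        genome = small_genome(
            recombination_rate=0.0, variants_per_chromosome=10
        )
        geno = simpop.simulate_founders_and_drop(ped, genome, seed=7)
        sire, dam = ped.parent_indices()
        haps = geno.haplotypes
        m = genome.variants_per_chromosome
        for i in np.flatnonzero(sire >= 0):
            for parent_row, hap_idx in ((sire[i], 0), (dam[i], 1)):
                for c in range(genome.n_chromosomes):
                    sl = slice(c * m, (c + 1) * m)
                    child = haps[i, hap_idx, sl]
                    parental = {
                        haps[parent_row, 0, sl].tobytes(),
                        haps[parent_row, 1, sl].tobytes(),
                    }
                    assert child.tobytes() in parental

    def test_offspring_allele_frequencies_track_founders(self):
        ped = simpop.simulate_pedigree(
            simpop.LineDesign("A", 500, 1, 100, 200, 5), seed=8
        )
        genome = small_genome(variants_per_chromosome=250)
        geno = simpop.simulate_founders_and_drop(ped, genome, seed=8)
        gen = ped.table["generation"].to_numpy()
        f_founder = geno.allele_frequencies(np.flatnonzero(gen == 0))
        f_off = geno.allele_frequencies(np.flatnonzero(gen == 1))
        frac_close = np.mean(np.abs(f_off - f_founder) <= 0.05)
        assert frac_close >= 0.95

    def test_determinism(self):
        ped = simpop.simulate_pedigree(
            simpop.LineDesign("A", 10, 1, 2, 4, 5), seed=9
        )
        g1 = simpop.simulate_founders_and_drop(ped, small_genome(), seed=9)
        g2 = simpop.simulate_founders_and_drop(ped, small_genome(), seed=9)
        np.testing.assert_array_equal(g1.dosages, g2.dosages)

    def test_unknown_parent_rejected(self):
        bad = pd.DataFrame(
            [
                ("x", "ghost", "0", "A", 1, 0, "M"),
            ],
            columns=simpop.PEDIGREE_COLUMNS + ["sex"],
        )
        with pytest.raises(IntegrityError):
            simpop.simulate_founders_and_drop(
                simpop.Pedigree(bad), small_genome(), seed=1
            )


@pytest.fixture(scope="module")
def chip_geno():
    ped = simpop.simulate_pedigree(
        simpop.LineDesign("A", 200, 0, 1, 1, 5), seed=10
    )
    genome = simpop.GenomeConfig(10, 1_000_000, 60, 1e-8, 10_000.0)
    g = simpop.simulate_founders_and_drop(ped, genome, seed=10)
    # force one rare variant
    g.dosages[:, 0] = 0.0
    g.dosages[0, 0] = 1.0  # MAF = 1/400 = 0.0025
    return g


@pytest.fixture(scope="module")
def trait_geno():
    ped = simpop.simulate_pedigree(
        simpop.LineDesign("A", 400, 0, 1, 1, 5), seed=20
    )
    genome = simpop.GenomeConfig(2, 1_000_000, 100, 1e-8, 5_000.0)
    g = simpop.simulate_founders_and_drop(ped, genome, seed=20)
    return simpop.designate_chip(g, 40)


class TestDesignateChip:

    def test_low_maf_variant_never_on_chip(self, chip_geno):
        flagged = simpop.designate_chip(chip_geno, 100, maf_min=0.01)
        assert not flagged.variants["is_chip"].iloc[0]

    def test_exhaustion_flags_all_eligible(self, chip_geno):
        maf = chip_geno.minor_allele_frequencies()
        n_eligible = int((maf >= 0.01).sum())
        flagged = simpop.designate_chip(chip_geno, n_eligible, maf_min=0.01)
        assert int(flagged.variants["is_chip"].sum()) == n_eligible

    def test_even_spacing_across_chromosomes(self, chip_geno):
        flagged = simpop.designate_chip(chip_geno, 100, maf_min=0.01)
        counts = (
            flagged.variants[flagged.variants["is_chip"]]
            .groupby("chrom")
            .size()
        )
        assert len(counts) == 10
        assert counts.between(8, 12).all()

    def test_chip_is_nested_subset(self, chip_geno):
        flagged = simpop.designate_chip(chip_geno, 50)
        chip_ids = set(flagged.variant_ids[flagged.chip_mask])
        assert chip_ids <= set(flagged.variant_ids)
        assert len(chip_ids) == 50

    def test_too_few_eligible_rejected(self, chip_geno):
        with pytest.raises(InfeasibleDesignError):
            simpop.designate_chip(chip_geno, chip_geno.n_variants + 1)


class TestSimulateTrait:
    def test_h2_one_means_phenotype_equals_tbv(self, trait_geno):
        t = simpop.simulate_trait(trait_geno, 10, 1.0, seed=1)
        np.testing.assert_array_equal(t.phenotypes, t.true_breeding_values)
        assert t.realized_h2 == pytest.approx(1.0)

    def test_tbv_is_centered_linear_combination(self, trait_geno):
        t = simpop.simulate_trait(trait_geno, 5, 0.5, seed=2)
        cols = np.flatnonzero(np.isin(trait_geno.variant_ids, t.qtn_ids))
        dose = trait_geno.dosages[:, cols].astype(float)
        expected = (dose - dose.mean(axis=0)) @ t.qtn_effects
        expected -= expected.mean()
        np.testing.assert_allclose(t.true_breeding_values, expected, atol=1e-9)

    def test_single_qtn_variance_matches_2pq_a2(self, trait_geno):
        # founders are near Hardy-Weinberg, so var(TBV) ~ 2 p (1-p) a^2
        t = simpop.simulate_trait(trait_geno, 1, 0.8, seed=3)
        col = int(np.flatnonzero(trait_geno.variant_ids == t.qtn_ids[0])[0])
        p = float(trait_geno.allele_frequencies()[col])
        a2 = float(t.qtn_effects[0] ** 2)
        expected = 2 * p * (1 - p) * a2
        observed = float(t.true_breeding_values.var())
        assert observed == pytest.approx(expected, rel=0.2)

    def test_mean_realized_h2_near_target(self, trait_geno):
        vals = [
            simpop.simulate_trait(trait_geno, 50, 0.3, seed=s).realized_h2
            for s in range(50)
        ]
        assert 0.27 <= float(np.mean(vals)) <= 0.33

    def test_wgs_only_puts_qtn_off_chip(self, trait_geno):
        t = simpop.simulate_trait(trait_geno, 20, 0.5, qtn_panel="wgs_only", seed=4)
        chip_ids = set(trait_geno.variant_ids[trait_geno.chip_mask])
        assert not (set(t.qtn_ids) & chip_ids)

    def test_determinism(self, trait_geno):
        t1 = simpop.simulate_trait(trait_geno, 10, 0.4, seed=5)
        t2 = simpop.simulate_trait(trait_geno, 10, 0.4, seed=5)
        np.testing.assert_array_equal(t1.phenotypes, t2.phenotypes)

    def test_bad_h2_rejected(self, trait_geno):
        for h2 in (0.0, -0.1, 1.5):
            with pytest.raises(ConfigurationError):
                simpop.simulate_trait(trait_geno, 5, h2, seed=1)

    def test_too_many_qtn_rejected(self, trait_geno):
        with pytest.raises(InfeasibleDesignError):
            simpop.simulate_trait(trait_geno, trait_geno.n_variants + 1, 0.5, seed=1)


class TestNoiseInjector:
    def test_noise_perturbs_at_requested_rate(self):
        ped = simpop.simulate_pedigree(
            simpop.LineDesign("A", 100, 0, 1, 1, 5), seed=30
        )
        geno = simpop.simulate_founders_and_drop(ped, small_genome(), seed=30)
        noisy = simpop.inject_genotype_noise(
            geno, error_rate=0.0, missing_rate=0.1, seed=30
        )
        frac_missing = float(np.isnan(noisy.dosages).mean())
        assert 0.05 < frac_missing < 0.15
        clean = simpop.inject_genotype_noise(
            geno, error_rate=0.0, missing_rate=0.0, seed=30
        )
        np.testing.assert_array_equal(clean.dosages, geno.dosages)
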