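"""Generator checks: genome layout, mating design, transmission, phenotypes."""

import math

import numpy as np
import pandas as pd
import pytest

from carpgs.genotypes import MISSING, GenotypeMatrix
from carpgs.pedigree import Pedigree
from carpgs.simdata import (
    CARP_LINKAGE_MAP,
    GenomeTemplate,
    SimConfig,
    apply_genotyping_noise,
    build_genome_template,
    gene_drop,
    mate_partial_factorial,
    residual_correlation,
    simulate_bivariate_phenotypes,
    simulate_founders,
    simulate_population,
)


class TestGenomeTemplate:
    def test_linkage_map_totals(self):
        genome = build_genome_template(n_markers=12311, n_qtl=0, seed=0)
        # published per-group lengths sum to 3,946 while the printed map
        # total is 3,944 cM -- per-group rounding; the groups are operative
        assert abs(genome.lengths_cm.sum() - 3944) <= 2
        assert len(genome.lengths_cm) == 50
        assert genome.n_markers == 12311
        # proportional allocation tracks the published per-group counts
        counts = np.bincount(genome.marker_lg, minlength=51)[1:]
        published = np.array([c for _, c in CARP_LINKAGE_MAP])
        assert np.abs(counts - published).max() <= 2
        assert abs(counts[0] - 350) <= 2

    def test_minimal_allocation(self):
        genome = build_genome_template(n_markers=50, n_qtl=0, seed=1)
        assert np.bincount(genome.marker_lg, minlength=51)[1:].tolist() == [1] * 50
        assert genome.n_qtl == 0

    def test_positions_sorted_and_bounded(self):
        genome = build_genome_template(n_markers=500, n_qtl=100, seed=2)
        for g in range(1, 51):
            for lg_arr, pos_arr in ((genome.marker_lg, genome.marker_pos),
                                    (genome.qtl_lg, genome.qtl_pos)):
                p = pos_arr[lg_arr == g]
                assert np.all(np.diff(p) >= 0)
                if p.size:
                    assert p.min() >= 0 and p.max() <= genome.lengths_cm[g - 1]

    def test_too_few_markers_rejected(self):
        with pytest.raises(ValueError):
            build_genome_template(n_markers=49)


class TestFounders:
    def test_dimensions(self):
        cfg = SimConfig(founder_model="unrelated", seed=3)
        genome = build_genome_template(n_markers=200, n_qtl=50, seed=3)
        haps = simulate_founders(cfg, genome)
        assert haps.shape == (60, 2, 250)

    def test_heterozygosity_at_half(self):
        cfg = SimConfig(founder_model="unrelated", maf_low=0.5, maf_high=0.5, seed=4)
        genome = build_genome_template(n_markers=2000, n_qtl=0, seed=4)
        haps = simulate_founders(cfg, genome)
        het = (haps[:, 0, :] != haps[:, 1, :]).mean()
        assert het == pytest.approx(0.5, abs=0.01)

    def test_realized_maf_matches_monte_carlo_oracle(self):
        """Fraction of loci with realized MAF > 0.3 under binomial sampling
        of 120 alleles, checked against an independent Monte-Carlo oracle."""
        rng = np.random.default_rng(99)
        n_mc = 40_000
        freqs = rng.uniform(0.01, 0.5, size=n_mc)
        counts = rng.binomial(120, freqs)
        p_real = counts / 120
        oracle = float((np.minimum(p_real, 1 - p_real) > 0.3).mean())

        cfg = SimConfig(founder_model="unrelated", seed=5)
        genome = build_genome_template(n_markers=8000, n_qtl=0, seed=5)
        haps = simulate_founders(cfg, genome)
        p = haps.reshape(120, -1).mean(axis=0)
        frac = float((np.minimum(p, 1 - p) > 0.3).mean())
        assert frac == pytest.approx(oracle, abs=0.03)

    def test_pool_founders_are_related(self):
        """Ancestral-pool founders show a wide spread of pairwise genomic
        relationships (sibs, cousins...), unlike unrelated/LE founders."""
        genome = build_genome_template(n_markers=1000, n_qtl=0, seed=6)

        def offdiag_sd(cfg):
            haps = simulate_founders(cfg, genome)
            dos = haps.sum(axis=1).astype(float)
            p = dos.mean(axis=0) / 2
            keep = (p > 0.05) & (p < 0.95)
            z = dos[:, keep] - 2 * p[keep]
            g = z @ z.T / (2 * np.sum(p[keep] * (1 - p[keep])))
            return g[~np.eye(60, dtype=bool)].std()

        sd_pool = offdiag_sd(SimConfig(seed=6))
        sd_le = offdiag_sd(SimConfig(seed=6, founder_model="unrelated"))
        assert sd_pool > 2 * sd_le


class TestMating:
    def test_design_counts(self):
        cfg = SimConfig(seed=7)
        ped = mate_partial_factorial(cfg)
        assert len(ped.founders()) == 60
        assert len(ped.offspring()) == 1425
        fam = ped.family_sizes()
        assert len(fam) <= 200
        t = ped.table
        off = t[t["sire"] != "0"]
        assert off["sire"].nunique() == 40 and off["dam"].nunique() == 20

    def test_offspring_parents_within_block(self):
        cfg = SimConfig(seed=8)
        ped = mate_partial_factorial(cfg)
        t = ped.table.set_index("id")
        for row in ped.table.itertuples():
            if row.sire != "0":
                assert t.loc[row.sire, "block"] == t.loc[row.dam, "block"] == row.block

    def test_concentration_limit_equalizes_families(self):
        even = mate_partial_factorial(SimConfig(seed=9, family_concentration=math.inf))
        over = mate_partial_factorial(SimConfig(seed=9, family_concentration=3.0))
        assert even.family_sizes().var() < over.family_sizes().var()

    def test_default_family_sizes_span_study_range(self):
        fam = mate_partial_factorial(SimConfig(seed=10)).family_sizes()
        assert fam.min() <= 2 and 18 <= fam.max() <= 40
        assert fam.mean() == pytest.approx(7.1, abs=1.0)

    def test_too_few_offspring_rejected(self):
        with pytest.raises(ValueError):
            mate_partial_factorial(SimConfig(n_offspring=2, seed=0))


def _two_locus_genome(distance_cm: float) -> GenomeTemplate:
    return GenomeTemplate(
        lengths_cm=np.array([100.0]),
        marker_lg=np.array([1, 1]),
        marker_pos=np.array([10.0, 10.0 + distance_cm]),
        qtl_lg=np.empty(0, dtype=int),
        qtl_pos=np.empty(0, dtype=float),
    )


def _phased_parent_cross(n_offspring: int) -> Pedigree:
    rows = [("P1", "0", "0", 1), ("P2", "0", "0", 1)]
    rows += [(f"O{i}", "P1", "P2", 1) for i in range(n_offspring)]
    return Pedigree(pd.DataFrame(rows, columns=["id", "sire", "dam", "block"]))


class TestGeneDrop:
    def test_zero_distance_cotransmits(self):
        genome = _two_locus_genome(0.0)
        ped = _phased_parent_cross(500)
        # sire doubly heterozygous in coupling; dam homozygous null
        haps = np.zeros((2, 2, 2), dtype=np.int8)
        haps[0, 0] = [1, 1]
        geno, _ = gene_drop(ped, haps, genome, seed=11)
        d = geno.dosages[2:]
        assert np.all(d[:, 0] == d[:, 1])

    def test_haldane_recombination_fraction(self):
        """r = (1 - exp(-2d/100))/2 at d = 10 cM, recovered over meioses."""
        d_cm = 10.0
        expected = (1 - math.exp(-2 * d_cm / 100)) / 2
        genome = _two_locus_genome(d_cm)
        n = 8000
        ped = _phased_parent_cross(n)
        haps = np.zeros((2, 2, 2), dtype=np.int8)
        haps[0, 0] = [1, 1]
        geno, _ = gene_drop(ped, haps, genome, seed=12)
        d = geno.dosages[2:]
        recomb = float((d[:, 0] != d[:, 1]).mean())
        tol = 4 * math.sqrt(expected * (1 - expected) / n)
        assert abs(recomb - expected) < tol
        assert expected == pytest.approx(0.0906, abs=0.0001)

    def test_allele_frequencies_preserved(self, le_pop):
        founders = le_pop.genotypes_clean.subset_samples(le_pop.parent_ids)
        offspring = le_pop.genotypes_clean.subset_samples(le_pop.offspring_ids)
        pf = founders.dosages.mean(axis=0) / 2
        po = offspring.dosages.mean(axis=0) / 2
        assert np.abs(pf - po).mean() < 0.03  # drift only, no selection

    def test_midparent_regression_slope_near_one(self, small_pop):
        tbv = small_pop.true_breeding_values.set_index("id")["length_mm"]
        ped = small_pop.pedigree.table.set_index("id")
        off = small_pop.offspring_ids
        mid = np.array([(tbv[ped.loc[o, "sire"]] + tbv[ped.loc[o, "dam"]]) / 2 for o in off])
        slope = np.polyfit(mid, tbv.loc[off].to_numpy(), 1)[0]
        assert slope == pytest.approx(1.0, abs=0.15)

    def test_missing_founder_haplotypes_rejected(self):
        genome = _two_locus_genome(1.0)
        rows = [("P1", "0", "0", 1), ("O1", "P1", "PX", 1), ("PX", "0", "0", 1)]
        ped = Pedigree(pd.DataFrame(rows, columns=["id", "sire", "dam", "block"]))
        with pytest.raises(ValueError):
            gene_drop(ped, np.zeros((1, 2, 2), dtype=np.int8), genome, seed=0)


class TestPhenotypes:
    def test_residual_correlation_matches_algebraic_oracle(self):
        cfg = SimConfig()
        # direct arithmetic from the covariance decomposition
        num = 0.93 * 4.6 * 7.1 - 0.94 * math.sqrt(0.26) * 4.6 * math.sqrt(0.33) * 7.1
        den = math.sqrt(0.74) * 4.6 * math.sqrt(0.67) * 7.1
        assert residual_correlation(cfg) == pytest.approx(num / den, abs=1e-12)

    def test_inconsistent_triple_rejected(self):
        cfg = SimConfig(rp_target=0.99, rg=-0.9)
        with pytest.raises(ValueError, match="rg"):
            residual_correlation(cfg)

    def test_realized_phenotypic_correlation(self, small_pop):
        ph = small_pop.phenotypes
        r = np.corrcoef(ph["weight_g"], ph["length_mm"])[0, 1]
        assert r == pytest.approx(0.93, abs=0.03)

    def test_realized_genetic_variance_is_exact(self, small_pop):
        tbv = small_pop.true_breeding_values.set_index("id")
        off = small_pop.offspring_ids
        cfg = small_pop.config
        assert tbv.loc[off, "length_mm"].to_numpy().var() == pytest.approx(
            cfg.h2_length * cfg.sd_length ** 2, rel=1e-6)
        assert tbv.loc[off, "weight_g"].to_numpy().var() == pytest.approx(
            cfg.h2_weight * cfg.sd_weight ** 2, rel=1e-6)

    def test_zero_heritability_gives_zero_breeding_values(self):
        cfg = SimConfig(n_blocks=1, n_offspring=80, h2_weight=0.0, h2_length=0.0,
                        rg=0.0, rp_target=0.5, n_qtl=50, seed=13)
        pop = simulate_population(cfg, n_markers=100)
        assert np.allclose(pop.true_breeding_values[["weight_g", "length_mm"]], 0.0)


class TestGenotypingNoise:
    def test_identity_at_zero_rates(self, small_pop):
        g = small_pop.genotypes_clean
        out = apply_genotyping_noise(g, 0.0, 0.0, seed=1)
        assert np.array_equal(out.dosages, g.dosages)

    def test_missing_fraction(self, small_pop):
        g = small_pop.genotypes_clean
        out = apply_genotyping_noise(g, 0.0, 0.05, seed=2)
        frac = (out.dosages == MISSING).mean()
        assert frac == pytest.approx(0.05, abs=0.005)
        assert not np.shares_memory(out.dosages, g.dosages)

    def test_errors_change_to_valid_other_dosage(self, small_pop):
        g = small_pop.genotypes_clean
        out = apply_genotyping_noise(g, 0.1, 0.0, seed=3)
        changed = out.dosages != g.dosages
        assert changed.mean() == pytest.approx(0.1, abs=0.01)
        assert set(np.unique(out.dosages[changed])) <= {0, 1, 2}


def test_simulation_is_deterministic(small_cfg):
    a = simulate_population(small_cfg, n_markers=300)
    b = simulate_population(small_cfg, n_markers=300)
    assert np.array_equal(a.genotypes_observed.dosages, b.genotypes_observed.dosages)
    assert a.phenotypes.equals(b.phenotypes)
    assert a.pedigree.table.equals(b.pedigree.table)
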