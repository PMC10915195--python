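"""Generator correctness: Mendelian consistency, moments, determinism."""

import numpy as np
import pytest

import ssgwas as sg
from ssgwas.io import DataError
from ssgwas.simulate import (SimulationSpec, compute_heterozygosity,
                             simulate_dataset, simulate_genotypes,
                             simulate_pedigree, simulate_phenotypes)


class TestHeterozygosity:
    @pytest.mark.parametrize("fs,fd,expected", [
        (1.0, 0.0, 1.0),      # purebred x other
        (1.0, 1.0, 0.0),      # no heterosis within breed
        (0.5, 0.5, 0.5),
        (0.625, 1.0, 0.375),
    ])
    def test_formula(self, fs, fd, expected):
        assert compute_heterozygosity(fs, fd) == pytest.approx(expected)

    def test_out_of_range_fatal(self):
        with pytest.raises(DataError):
            compute_heterozygosity(1.2, 0.5)


class TestPedigree:
    def test_zero_generations_founders_only(self):
        spec = SimulationSpec(n_sires=5, n_dams=5, n_generations=0,
                              n_bulls_phenotyped=4, seed=1)
        ped, meta = simulate_pedigree(spec)
        assert len(ped) == 10
        assert all(s == "0" for s in ped.sires)
        lo, hi = spec.holstein_fraction_range
        assert ((ped.breed_fractions["holstein"] >= lo)
                & (ped.breed_fractions["holstein"] <= hi)).all()

    def test_offspring_fraction_is_parent_midpoint(self):
        spec = SimulationSpec(n_sires=3, n_dams=3, n_bulls_phenotyped=10, seed=2)
        ped, meta = simulate_pedigree(spec)
        parents = ped.parent_indices()
        f = ped.breed_fractions["holstein"].to_numpy()
        for i, (s, d) in enumerate(parents):
            if s >= 0 and d >= 0:
                assert f[i] == pytest.approx(0.5 * (f[s] + f[d]))

    def test_same_seed_same_pedigree(self):
        spec = SimulationSpec(n_sires=4, n_dams=6, n_bulls_phenotyped=8, seed=9)
        p1, m1 = simulate_pedigree(spec)
        p2, m2 = simulate_pedigree(spec)
        assert p1.animals == p2.animals and p1.sires == p2.sires
        assert m1 == m2
        np.testing.assert_array_equal(p1.breed_fractions.to_numpy(),
                                      p2.breed_fractions.to_numpy())


class TestGeneDrop:
    def test_founder_allele_frequency(self):
        # degenerate frequency window at 0.5: empirical freq within 3 SE
        spec = SimulationSpec(n_sires=100, n_dams=100, n_generations=0,
                              n_bulls_phenotyped=10, n_chromosomes=1,
                              markers_per_chromosome=200, maf_low=0.5,
                              maf_high=0.5, seed=3)
        ped, _ = simulate_pedigree(spec)
        g = simulate_genotypes(spec, ped)
        freq = g.allele_frequencies()
        se = np.sqrt(0.25 / (2 * 200))
        assert abs(freq.mean() - 0.5) < 3 * se / np.sqrt(200) * 10  # loose overall
        assert (np.abs(freq - 0.5) < 5 * se).mean() > 0.95

    def test_mendelian_consistency(self):
        spec = SimulationSpec(n_sires=6, n_dams=10, n_bulls_phenotyped=40,
                              n_chromosomes=1, markers_per_chromosome=60, seed=4)
        ped, _ = simulate_pedigree(spec)
        g = simulate_genotypes(spec, ped)
        parents = ped.parent_indices()
        codes = g.codes
        for i, (s, d) in enumerate(parents):
            if s < 0 or d < 0:
                continue
            # offspring of two homozygotes is fully determined
            both0 = (codes[s] == 0) & (codes[d] == 0)
            both2 = (codes[s] == 2) & (codes[d] == 2)
            assert (codes[i][both0] == 0).all()
            assert (codes[i][both2] == 2).all()
            # opposite homozygotes force heterozygous offspring
            opp = ((codes[s] == 0) & (codes[d] == 2)) | ((codes[s] == 2) & (codes[d] == 0))
            assert (codes[i][opp] == 1).all()

    def test_parent_offspring_transmission(self):
        # replicated trios at one locus: offspring gets exactly one parental
        # allele, so corr(parent code, offspring code) ~ 0.5 at p = 0.5
        rng = np.random.default_rng(5)
        n = 10_000
        sire = rng.binomial(2, 0.5, size=n)
        # independent oracle: explicit transmission
        sire_allele = np.where(sire == 1, rng.integers(0, 2, n), sire // 2)
        dam = rng.binomial(2, 0.5, size=n)
        dam_allele = np.where(dam == 1, rng.integers(0, 2, n), dam // 2)
        off_oracle = sire_allele + dam_allele
        r_oracle = np.corrcoef(sire, off_oracle)[0, 1]
        # generator: many independent markers in a single trio pedigree
        spec = SimulationSpec(n_sires=1, n_dams=1, n_bulls_phenotyped=1,
                              n_chromosomes=1, markers_per_chromosome=n,
                              maf_low=0.5, maf_high=0.5, seed=6)
        ped, _ = simulate_pedigree(spec)
        g = simulate_genotypes(spec, ped)
        codes = g.codes
        r_sim = np.corrcoef(codes[0], codes[2])[0, 1]
        assert r_sim == pytest.approx(r_oracle, abs=0.05)
        assert r_sim == pytest.approx(0.5, abs=0.05)

    def test_positions_increasing_within_chromosome(self, small_sim):
        mm = small_sim.genotypes.marker_map
        for _, sub in mm.groupby("chrom"):
            assert sub["pos"].is_monotonic_increasing


class TestPhenotypes:
    def test_pure_noise_limit(self):
        # Va = Vp = 0, Ve = I, no fixed effects: records are standard normal
        spec = SimulationSpec(n_sires=20, n_dams=20, n_generations=0,
                              n_bulls_phenotyped=40, records_per_bull=90,
                              n_chromosomes=1, markers_per_chromosome=10,
                              Va=np.zeros((3, 3)), Vp=np.zeros((3, 3)),
                              Ve=np.eye(3), trait_means=(0, 0, 0), cg_sd=0.0,
                              ejaculate_effect=0.0, age_slope=0.0,
                              temp_slope=0.0, heterosis_effect=0.0, seed=7)
        data = simulate_dataset(spec)
        from scipy.stats import kstest
        y = data.phenotypes.df[data.phenotypes.traits].to_numpy().ravel()
        assert kstest(y, "norm").pvalue > 0.01

    def test_breeding_value_variance_matches_Va(self):
        # founders only: BV covariance should be Va (A = I); 2000 founders
        spec = SimulationSpec(n_sires=1000, n_dams=1000, n_generations=0,
                              n_bulls_phenotyped=5, records_per_bull=1,
                              n_chromosomes=1, markers_per_chromosome=10, seed=8)
        ped, meta = simulate_pedigree(spec)
        g = simulate_genotypes(spec, ped)
        _, truth = simulate_phenotypes(spec, ped, g, meta["bulls"])
        bv = truth.breeding_values.to_numpy()
        emp = bv.var(axis=0, ddof=1)
        se = np.sqrt(2.0 / (len(bv) - 1)) * np.diag(spec.Va)
        assert (np.abs(emp - np.diag(spec.Va)) < 3 * se).all()

    def test_missing_rate_never_empties_record(self):
        spec = SimulationSpec(n_sires=4, n_dams=4, n_bulls_phenotyped=10,
                              records_per_bull=10, n_chromosomes=1,
                              markers_per_chromosome=10,
                              missing_rate=(0.5, 0.5, 0.5), seed=10)
        data = simulate_dataset(spec)
        obs = data.phenotypes.df[data.phenotypes.traits].notna()
        assert obs.any(axis=1).all()
        assert obs.to_numpy().mean() < 0.8    # missingness actually applied

    def test_same_seed_identical_dataset(self):
        spec = SimulationSpec(n_sires=4, n_dams=6, n_bulls_phenotyped=10,
                              records_per_bull=4, n_chromosomes=1,
                              markers_per_chromosome=30, seed=11)
        d1, d2 = simulate_dataset(spec), simulate_dataset(spec)
        assert d1.phenotypes.df.equals(d2.phenotypes.df)
        np.testing.assert_array_equal(d1.genotypes.codes, d2.genotypes.codes)

    def test_qtl_raises_realized_additive_variance(self):
        spec = SimulationSpec(n_sires=10, n_dams=10, n_bulls_phenotyped=30,
                              records_per_bull=2, n_chromosomes=1,
                              markers_per_chromosome=50, seed=12)
        spec.qtl_spec = sg.default_qtl_spec(spec, fraction=0.5, n_per_chromosome=2)
        ped, meta = simulate_pedigree(spec)
        g = simulate_genotypes(spec, ped)
        _, truth = simulate_phenotypes(spec, ped, g, meta["bulls"])
        assert (truth.va_total > np.diag(spec.Va)).all()
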