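"""F2 genotype simulation, trait architectures and their aggregate variances."""

import numpy as np
import pytest
from scipy import stats

from binsel import (
    design_preset,
    f2_covariance,
    haldane,
    heritability,
    simulate_dataset,
    simulate_f2,
    simulate_phenotype,
)
from binsel.simulate import SimDesign, evenly_spaced_map


class TestHaldane:
    def test_limits(self):
        assert haldane(0.0) == 0.0
        assert haldane(1e9) == pytest.approx(0.5)

    def test_fifty_cM_maps_to_standard_value(self):
        assert haldane(50.0) == pytest.approx(0.5 * (1 - np.exp(-1.0)))


class TestF2Genotypes:
    def test_mendelian_1_2_1_ratio(self):
        mm = evenly_spaced_map(100.0, 50.0)
        G = simulate_f2(8000, mm, seed=3)
        for j in range(G.n_markers):
            counts = [(G.values[:, j] == v).sum() for v in (-1, 0, 1)]
            p = stats.chisquare(counts, f_exp=[2000, 4000, 2000]).pvalue
            assert p > 0.001

    def test_marker_variance_is_half(self):
        mm = evenly_spaced_map(100.0, 25.0)
        G = simulate_f2(20000, mm, seed=5)
        v = G.values.var(axis=0, ddof=1)
        np.testing.assert_allclose(v, 0.5, atol=0.02)

    def test_correlation_matches_recombination_theory(self):
        # corr(Z_h, Z_l) = 1 - 2 r at 10 cM, within 3 SE at n = 20000
        mm = evenly_spaced_map(10.0, 10.0)
        G = simulate_f2(20000, mm, seed=11)
        rho_emp = np.corrcoef(G.values[:, 0], G.values[:, 1])[0, 1]
        rho = 1.0 - 2.0 * haldane(10.0)
        se = (1 - rho**2) / np.sqrt(20000)
        assert abs(rho_emp - rho) < 3 * se

    def test_covariance_derivation_monte_carlo(self):
        # Cov(Z_h, Z_l) = (1 - 2 r)/2 across a range of distances
        mm = evenly_spaced_map(120.0, 30.0)
        G = simulate_f2(20000, mm, seed=17)
        C = np.cov(G.values.T)
        for h in range(5):
            for l in range(h + 1, 5):
                d = 30.0 * (l - h)
                assert C[h, l] == pytest.approx(f2_covariance(d), abs=0.02)

    def test_seed_reproducibility_bitwise(self, small_map):
        G1 = simulate_f2(50, small_map, seed=9)
        G2 = simulate_f2(50, small_map, seed=9)
        np.testing.assert_array_equal(G1.values, G2.values)

    def test_requires_genetic_positions(self):
        from binsel import MarkerMap

        mm = MarkerMap(["a", "b"], ["1", "1"], physical_pos=[0.0, 100.0])
        with pytest.raises(ValueError, match="genetic"):
            simulate_f2(10, mm, seed=0)

    def test_ld_decay_monotone_in_distance(self):
        mm = evenly_spaced_map(200.0, 10.0)
        G = simulate_f2(20000, mm, seed=23)
        Z = G.values
        # mean |corr| binned by map distance must be non-increasing
        cors = []
        for lag in (1, 4, 8, 16):
            c = [
                np.corrcoef(Z[:, j], Z[:, j + lag])[0, 1]
                for j in range(0, Z.shape[1] - lag, 3)
            ]
            cors.append(np.mean(c))
        assert all(a >= b - 0.02 for a, b in zip(cors, cors[1:]))


class TestPhenotype:
    def test_pure_noise_variance(self):
        mm = evenly_spaced_map(50.0, 25.0)
        G = simulate_f2(10000, mm, seed=2)
        d = SimDesign(n=10000, genome_length=50.0, marker_spacing=25.0,
                      sigma2_e=4.0)
        y, info = simulate_phenotype(G, mm, d, seed=4)
        assert y.variance == pytest.approx(4.0, rel=0.1)
        assert info["var_main"] == 0.0

    def test_single_qtl_variance_is_half_effect_squared(self):
        mm = evenly_spaced_map(100.0, 10.0)
        G = simulate_f2(20000, mm, seed=6)
        a = 3.0
        d = SimDesign(n=20000, genome_length=100.0, marker_spacing=10.0,
                      qtl=((50.0, a),), sigma2_e=0.0)
        y, _ = simulate_phenotype(G, mm, d, seed=8)
        assert y.variance == pytest.approx(a**2 / 2, rel=0.05)

    def test_epistatic_term_is_product_of_indicators(self):
        mm = evenly_spaced_map(100.0, 50.0)
        G = simulate_f2(200, mm, seed=10)
        d = SimDesign(n=200, genome_length=100.0, marker_spacing=50.0,
                      epistatic_pairs=((0.0, 100.0, 2.0),), sigma2_e=0.0)
        y, _ = simulate_phenotype(G, mm, d, seed=1)
        np.testing.assert_allclose(
            y.values, 2.0 * G.values[:, 0] * G.values[:, 2]
        )

    def test_qtl_outside_genome_is_error(self):
        with pytest.raises(ValueError, match="outside genome"):
            SimDesign(n=10, genome_length=100.0, marker_spacing=10.0,
                      qtl=((150.0, 1.0),))


class TestHeritabilityAlgebra:
    @pytest.mark.parametrize(
        "s2e, expected", [(10, 0.64), (20, 0.58), (40, 0.49), (100, 0.34)]
    )
    def test_oligogenic_levels(self, s2e, expected):
        # main 64.12 + epistatic 26.52 going to residual
        assert round(heritability(64.12, 26.52, s2e), 2) == expected

    @pytest.mark.parametrize(
        "s2e, expected", [(10, 0.89), (20, 0.80), (50, 0.62), (100, 0.45)]
    )
    def test_polygenic_levels(self, s2e, expected):
        assert round(heritability(81.94, 0.0, s2e), 2) == expected


class TestDesignPresets:
    def test_design_I_full_scale_dimensions(self):
        d = design_preset("I", scale=1.0)
        assert d.marker_map().n_markers == 120_001
        assert d.genome_length == 2400.0
        assert d.marker_spacing == pytest.approx(0.02)
        assert len(d.qtl) == 20 and len(d.epistatic_pairs) == 20

    def test_design_II_cluster_structure(self):
        d = design_preset("II", scale=0.02)
        assert len(d.qtl) == 20 * 10  # clusters of round(500 * scale)
        pos = np.array([q[0] for q in d.qtl])
        eff = np.array([q[1] for q in d.qtl])
        # equal magnitudes within (and across) clusters; sign constant within
        assert np.allclose(np.abs(eff), np.abs(eff[0]))
        for centre in np.unique(np.round(pos / 120) * 120):
            members = np.abs(pos - centre) <= 6.0
            if members.sum() > 1:
                assert len(np.unique(np.sign(eff[members]))) == 1

    def test_design_II_realized_total_variance(self):
        ds = simulate_dataset(design_preset("II", scale=0.02, n=4000), seed=9)
        assert ds.var_main == pytest.approx(81.94, rel=0.06)

    def test_design_III_sign_structure(self):
        d = design_preset("III", scale=1.0)
        eff = [q[1] for q in d.qtl]
        assert len(eff) == 1000
        assert all(e > 0 for e in eff[:500]) and all(e < 0 for e in eff[500:])

    def test_design_IV_no_ld_geometry(self):
        d = design_preset("IV", scale=1.0)
        assert d.marker_map().n_markers == 120_001
        assert d.genome_length == 12_000_000.0
        assert d.marker_spacing == 100.0
        assert len(d.epistatic_pairs) == 0

    def test_unknown_design_rejected(self):
        with pytest.raises(ValueError, match="unknown design"):
            design_preset("V")

    def test_design_I_realized_main_variance_matches_target(self):
        ds = simulate_dataset(design_preset("I", scale=0.02, n=4000), seed=7)
        # analytic calibration targets 64.12; Monte-Carlo check at n = 4000
        assert ds.var_main == pytest.approx(64.12, rel=0.05)

    def test_design_IV_markers_effectively_unlinked(self):
        """At 100 cM spacing adjacent markers keep only the weak Haldane
        correlation exp(-2) ~ 0.135; ten intervals away the correlation is
        statistically indistinguishable from zero."""
        d = design_preset("IV", scale=0.005, n=2000)
        G = simulate_f2(2000, d.marker_map(), seed=13)
        Z = G.values
        adj = np.mean(
            [np.corrcoef(Z[:, j], Z[:, j + 1])[0, 1] for j in range(100)]
        )
        assert adj == pytest.approx(np.exp(-2.0), abs=0.02)
        far = [np.corrcoef(Z[:, j], Z[:, j + 10])[0, 1] for j in range(100)]
        assert np.mean(np.abs(far)) < 2.5 / np.sqrt(2000)

    def test_realized_h2_approaches_expected(self):
        ds = simulate_dataset(design_preset("I", scale=0.02, n=5000), seed=3)
        assert ds.h2_realized == pytest.approx(ds.h2_expected, abs=0.04)

    def test_dataset_reproducible(self):
        d = design_preset("I", scale=0.005, n=40)
        a = simulate_dataset(d, seed=1)
        b = simulate_dataset(d, seed=1)
        np.testing.assert_array_equal(a.genotypes.values, b.genotypes.values)
        np.testing.assert_array_equal(a.phenotypes.values, b.phenotypes.values)
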