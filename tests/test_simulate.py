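"""Simulator tests: spectrum, LD, penetrance models, sampling."""

import math

import numpy as np
import pytest

from igof.simulate import (MafSpectrum, PenetranceModel, SimScenario,
                           calibrate_alpha0, generate_haplotype_pool,
                           interaction_coding, lf_effect_size, penetrance,
                           power_pair_class, read_penetrance_table,
                           sample_case_control, sample_genotypes,
                           stratified_sample, write_penetrance_table)


def small_pool(seed=0, n_sites=60, n_hap=2000, ld="none"):
    return generate_haplotype_pool(n_sites, n_hap, MafSpectrum(),
                                   ld_profile=ld, seed=seed)


class TestHaplotypePool:
    def test_rare_fraction_matches_spectrum(self):
        for seed in (1, 2, 3):
            pool = generate_haplotype_pool(600, 10_000, MafSpectrum(),
                                           "none", seed=seed)
            frac = float((pool.mafs < 0.01).mean())
            assert 0.7 <= frac <= 0.9

    def test_no_ld_profile_leaves_distant_sites_uncorrelated(self):
        pool = generate_haplotype_pool(100, 10_000, MafSpectrum(),
                                       "none", seed=4)
        h = pool.haplotypes.astype(np.float64)
        poly = pool.mafs > 0.02
        idx = np.nonzero(poly)[0]
        g1, g2 = idx[: len(idx) // 2], idx[len(idx) // 2:]
        r = np.corrcoef(h[:, g1].T, h[:, g2].T)[: len(g1), len(g1):]
        assert float(np.nanmean(r ** 2)) < 0.01

    def test_strong_ld_induces_adjacent_correlation(self):
        pool = generate_haplotype_pool(100, 10_000, MafSpectrum(),
                                       "strong", seed=4)
        h = pool.haplotypes.astype(np.float64)
        poly = np.nonzero(pool.mafs > 0.05)[0]
        rs = [np.corrcoef(h[:, a], h[:, b])[0, 1] ** 2
              for a, b in zip(poly[:-1], poly[1:]) if b - a <= 5]
        assert np.mean(rs) > 0.2

    def test_identical_seed_identical_pool(self):
        p1 = small_pool(seed=9)
        p2 = small_pool(seed=9)
        assert np.array_equal(p1.haplotypes, p2.haplotypes)

    def test_mafs_oriented_to_minor(self):
        pool = small_pool(seed=5)
        assert pool.mafs.max() <= 0.5
        assert np.allclose(pool.haplotypes.mean(axis=0), pool.mafs)


class TestSampleGenotypes:
    def test_monomorphic_pool_gives_zero_counts(self):
        pool = small_pool(seed=1)
        pool.haplotypes[:] = 0
        g = sample_genotypes(pool, 50, np.random.default_rng(0))
        assert not g.any()

    def test_sample_frequency_converges_to_pool_maf(self):
        pool = small_pool(seed=2, n_sites=30, n_hap=5000)
        rng = np.random.default_rng(1)
        g = sample_genotypes(pool, 10_000, rng)
        freq = g.mean(axis=0) / 2
        se = np.sqrt(pool.mafs * (1 - pool.mafs) / (2 * 10_000))
        ok = np.abs(freq - pool.mafs) <= 3 * se + 1e-9
        assert ok.mean() > 0.95  # 3-sigma bound holds for nearly all sites

    def test_seeded_reproducibility(self):
        pool = small_pool(seed=3)
        g1 = sample_genotypes(pool, 20, np.random.default_rng(5))
        g2 = sample_genotypes(pool, 20, np.random.default_rng(5))
        assert np.array_equal(g1, g2)


class TestInteractionCoding:
    def test_additive_is_count_product(self):
        assert interaction_coding(1, 1, "additive") == 1
        assert interaction_coding(2, 2, "additive") == 4
        assert interaction_coding(0, 2, "additive") == 0

    def test_xor_zero_set(self):
        zero = [(0, 0), (0, 2), (1, 1), (2, 0), (2, 2)]
        for a, b in zero:
            assert interaction_coding(a, b, "xor") == 0
        one = [(0, 1), (1, 0), (1, 2), (2, 1)]
        for a, b in one:
            assert interaction_coding(a, b, "xor") == 1

    def test_classical_one_set(self):
        for a, b in [(0, 2), (1, 1), (2, 0)]:
            assert interaction_coding(a, b, "classical") == 1
        assert interaction_coding(0, 0, "classical") == 0

    def test_color_one_set(self):
        for a, b in [(0, 1), (0, 2), (1, 0), (2, 0)]:
            assert interaction_coding(a, b, "color") == 1
        for a, b in [(0, 0), (1, 1), (2, 2), (1, 2)]:
            assert interaction_coding(a, b, "color") == 0

    def test_unknown_coding_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            interaction_coding(1, 1, "dominant")


class TestEffectSizes:
    def test_lf_effect_size_printed_rule(self):
        assert lf_effect_size(0.01, 0.01) == pytest.approx(1.2)
        assert lf_effect_size(0.1, 0.1) == pytest.approx(0.6)
        assert lf_effect_size(0.01, 0.05) > lf_effect_size(0.05, 0.05)
        with pytest.raises(ValueError):
            lf_effect_size(0.0, 0.1)

    def test_power_pair_class_rule(self):
        assert power_pair_class(0.05, 0.05, 1000) == "LF"  # 0.00625 < 5
        assert power_pair_class(0.3, 0.3, 1000) == "common"  # 8.1 >= 5
        # boundary exactly 5 counts as common (strict < for LF)
        assert power_pair_class(0.5, 0.5, 80) == "common"


class TestPenetrance:
    def test_null_model_is_flat_prevalence(self):
        model = PenetranceModel()
        g = np.array([[0, 0], [1, 2], [2, 2]])
        assert np.allclose(penetrance(g, model), 0.05)

    def test_xor_effect_doubles_odds(self):
        model = PenetranceModel(
            interaction_effects=[(0, 1, math.log(2), "xor")])
        p0 = penetrance(np.array([[0, 0]]), model)[0]  # x = 0
        p1 = penetrance(np.array([[1, 0]]), model)[0]  # x = 1
        odds = lambda p: p / (1 - p)
        assert odds(p1) / odds(p0) == pytest.approx(2.0)

    def test_table_lookup_is_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        tab = rng.random((3, 3)) * 0.2
        path = tmp_path / "pen.tsv"
        write_penetrance_table(tab, path)
        back = read_penetrance_table(path)
        assert np.allclose(back, tab)
        model = PenetranceModel(table=back, table_variants=[0, 1])
        g = np.array([[1, 2], [0, 0]])
        assert penetrance(g, model)[0] == tab[1, 2]
        assert penetrance(g, model)[1] == tab[0, 0]

    def test_missing_causal_genotype_rejected(self):
        model = PenetranceModel(main_effects=[(0, 0.5)])
        with pytest.raises(ValueError, match="missing"):
            penetrance(np.array([[-1, 0]]), model)

    def test_calibrated_prevalence_hits_target(self):
        pool = small_pool(seed=6, n_sites=10)
        model = PenetranceModel(
            main_effects=[(0, math.log(3))],
            interaction_effects=[(1, 2, math.log(2), "additive")])
        rng = np.random.default_rng(2)
        model = calibrate_alpha0(pool, model, 0.05, rng)
        g = sample_genotypes(pool, 100_000, rng)
        assert penetrance(g, model).mean() == pytest.approx(0.05, abs=0.002)


class TestCaseControlSampling:
    def test_null_model_gives_exchangeable_groups(self):
        pool = small_pool(seed=7, n_sites=100)
        rng = np.random.default_rng(3)
        cases, controls = sample_case_control(pool, PenetranceModel(),
                                              1000, 1000, rng)
        fc = cases.mean(axis=0) / 2
        fm = controls.mean(axis=0) / 2
        pooled = (fc + fm) / 2
        se = np.sqrt(np.maximum(pooled * (1 - pooled), 1e-9) / 1000)
        z = (fc - fm) / se
        # two-sample frequency differences behave like noise:
        # sites exceeding the 0.001 two-sided bound should be rare
        assert (np.abs(z) > 3.29).sum() <= 3

    def test_risk_model_enriches_minor_pairs_in_cases(self):
        pool = small_pool(seed=8, n_sites=10, n_hap=4000)
        common = np.argsort(pool.mafs)[-2:]
        model = PenetranceModel(interaction_effects=[
            (int(common[0]), int(common[1]), math.log(6), "additive")])
        model = calibrate_alpha0(pool, model, 0.05)
        wins = 0
        seeds = 30
        for s in range(seeds):
            rng = np.random.default_rng(100 + s)
            ca, co = sample_case_control(pool, model, 150, 150, rng)
            stat = lambda g: (g[:, common[0]] * g[:, common[1]]).sum()
            wins += stat(ca) > stat(co)
        # sign test: under no enrichment wins ~ Binomial(30, 0.5)
        assert wins >= 22

    def test_seed_reproducibility(self):
        pool = small_pool(seed=9, n_sites=20)
        out1 = sample_case_control(pool, PenetranceModel(), 30, 30,
                                   np.random.default_rng(4))
        out2 = sample_case_control(pool, PenetranceModel(), 30, 30,
                                   np.random.default_rng(4))
        assert np.array_equal(out1[0], out2[0])
        assert np.array_equal(out1[1], out2[1])

    def test_degenerate_penetrance_guard(self):
        pool = small_pool(seed=10, n_sites=5)
        model = PenetranceModel(alpha0=-60.0)  # essentially no cases
        with pytest.raises(RuntimeError, match="did not terminate"):
            sample_case_control(pool, model, 10, 10,
                                np.random.default_rng(0), batch=512,
                                max_draws=5_000)


class TestStratifiedSampling:
    def test_single_population_limit_matches_plain_sampling(self):
        pool = small_pool(seed=11, n_sites=20)
        rng1 = np.random.default_rng(5)
        rng2 = np.random.default_rng(5)
        a = stratified_sample([pool, small_pool(seed=12, n_sites=20)],
                              (1.0, 0.0), PenetranceModel(), 40, 40, rng1)
        b = sample_case_control(pool, PenetranceModel(), 40, 40, rng2)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_diverged_pools_show_differentiation(self):
        # Hudson-style F_ST from the two pools' frequencies
        for seed in (1, 2):
            p1 = generate_haplotype_pool(300, 8000, MafSpectrum(),
                                         "none", seed=seed)
            p2 = generate_haplotype_pool(300, 8000, MafSpectrum(),
                                         "none", seed=seed + 100)
            a, b = p1.mafs, p2.mafs
            num = np.mean((a - b) ** 2)
            den = np.mean(a * (1 - b) + b * (1 - a))
            assert num / den > 0.05

    def test_mismatched_sites_rejected(self):
        with pytest.raises(ValueError, match="site count"):
            stratified_sample([small_pool(seed=1, n_sites=10),
                               small_pool(seed=2, n_sites=12)],
                              (0.5, 0.5), PenetranceModel(), 10, 10,
                              np.random.default_rng(0))


class TestScenario:
    def test_yaml_round_trip(self, tmp_path):
        sc = SimScenario(n_cases=200, variants_per_gene=10,
                         ld_profile="weak", stratification=(0.8, 0.2),
                         seed=5)
        path = tmp_path / "sc.yaml"
        sc.to_yaml(path)
        back = SimScenario.from_yaml(path)
        assert back == sc

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "sc.yaml"
        path.write_text("n_cases: 100\nbogus_key: 1\n")
        with pytest.raises(ValueError, match="bogus_key"):
            SimScenario.from_yaml(path)
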