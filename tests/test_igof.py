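"""Gene-pair statistic tests: selection, combination, permutation engine."""

import itertools
import math

import numpy as np
import pytest
from scipy.special import ndtri

from igof.genotypes import GenotypeMatrix, Phenotype
from igof.gof_pair import AlleleTable
from igof.igof import (IgofConfig, _FastEvaluator, _ReferenceEvaluator,
                       combine_pvalues, i_common, i_lf, select_common_pairs,
                       select_lf_pairs)
from igof.igof import test_gene_pair as run_gene_pair  # avoid test collection


class FakeGof:
    def __init__(self, p):
        self.p_chi2 = p


def make_dataset(counts, status, genes):
    counts = np.asarray(counts, dtype=np.int8)
    samples = [f"s{i}" for i in range(counts.shape[0])]
    variants = [f"v{i}" for i in range(counts.shape[1])]
    geno = GenotypeMatrix(samples=samples, variants=variants, counts=counts)
    phen = Phenotype(samples=samples, status=np.asarray(status, dtype=bool))
    gene_map = {g: [variants[i] for i in idx] for g, idx in genes.items()}
    return geno, phen, gene_map


def random_dataset(rng, ns=40, v1=3, v2=3, maf=0.35):
    counts = rng.binomial(2, maf, size=(ns, v1 + v2)).astype(np.int8)
    status = np.zeros(ns, dtype=bool)
    status[: ns // 2] = True
    rng.shuffle(status)
    return make_dataset(counts, status,
                        {"G1": range(v1), "G2": range(v1, v1 + v2)})


class TestSelection:
    def test_truncation_is_strict(self):
        results = [FakeGof(p) for p in (0.01, 0.04, 0.2)]
        assert select_common_pairs(results, 0.05) == [0, 1]
        assert select_common_pairs([FakeGof(0.05)], 0.05) == []
        assert select_common_pairs([], 0.05) == []

    def test_i_common_values(self):
        assert i_common([0.5]) == pytest.approx(0.0, abs=1e-12)
        # Phi^-1(0.99) + Phi^-1(0.96)
        expected = float(-ndtri(0.01) - ndtri(0.04))
        assert i_common([0.01, 0.04]) == pytest.approx(expected)
        assert expected == pytest.approx(4.0770, abs=5e-4)
        # adding a smaller p strictly increases the statistic
        assert i_common([0.01, 0.04, 0.02]) > i_common([0.01, 0.04])
        with pytest.raises(ValueError, match="empty"):
            i_common([])

    def test_lf_selection_strictly_more_minor_alleles_in_cases(self):
        tables = [
            AlleleTable(case=(0, 0, 0, 3), control=(0, 0, 0, 1)),  # in
            AlleleTable(case=(0, 0, 0, 0), control=(0, 0, 0, 0)),  # tie: out
            AlleleTable(case=(0, 0, 0, 1), control=(0, 0, 0, 2)),  # out
        ]
        assert select_lf_pairs(tables) == [0]

    def test_i_lf_sums(self):
        assert i_lf([0.0]) == 0.0
        assert i_lf([2.5, 3.5]) == pytest.approx(6.0)
        with pytest.raises(ValueError, match="empty"):
            i_lf([])


class TestCombine:
    @pytest.mark.parametrize("pc,pl,expected", [
        (0.04, 0.5, 0.08),
        (1.0, 1.0, 1.0),
        (0.001, 0.002, 0.002),
        (0.5, 0.04, 0.08),
    ])
    def test_extended_simes_examples(self, pc, pl, expected):
        assert combine_pvalues(pc, pl) == pytest.approx(expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            combine_pvalues(0.0, 0.5)


class TestEngines:
    def test_fast_matches_reference_on_random_data(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            ns = int(rng.integers(24, 80))
            v1, v2 = int(rng.integers(1, 5)), int(rng.integers(1, 5))
            G1 = rng.integers(0, 3, size=(ns, v1)).astype(np.int8)
            G2 = rng.integers(0, 3, size=(ns, v2)).astype(np.int8)
            labels = np.zeros(ns, dtype=bool)
            labels[: ns // 2] = True
            rng.shuffle(labels)
            fast = _FastEvaluator(G1, G2, labels, 0.05)
            ref = _ReferenceEvaluator(G1, G2, labels, 0.05)
            ofast, oref = fast.observed(), ref.observed()
            for key, a in ofast.items():
                b = oref[key]
                if isinstance(a, float) and np.isnan(a):
                    assert np.isnan(b)
                else:
                    assert a == pytest.approx(b, rel=1e-4, abs=1e-6), key
            S = np.stack([rng.permutation(labels) for _ in range(6)])
            for got, want in zip(fast.perm_stats(S), ref.perm_stats(S)):
                assert np.allclose(got, want, rtol=1e-4, atol=1e-6)

    def test_adaptive_p_matches_exhaustive_enumeration(self):
        # 8 individuals, 4 cases: 70 distinct label arrangements; the
        # adaptive estimate must converge to the exhaustive exceedance
        # probability within Monte-Carlo error.
        rng = np.random.default_rng(12)
        geno, phen, gm = random_dataset(rng, ns=8, v1=2, v2=2, maf=0.4)
        labels = phen.status
        G1 = geno.columns(gm["G1"])
        G2 = geno.columns(gm["G2"])
        ev = _ReferenceEvaluator(G1, G2, labels, 0.05)
        obs = ev.observed()
        if not obs["l"]:
            pytest.skip("degenerate draw: no selected LF pairs")
        arrangements = np.array([
            [i in combo for i in range(8)]
            for combo in itertools.combinations(range(8), 4)
        ])
        _, il = ev.perm_stats(arrangements)
        q_exact = float((il > obs["i_lf"]).mean())

        cfg = IgofConfig(tau=0.05, m=1e9, alpha=0.01, b=4000, r=4000,
                         sw_permutations=50, seed=9)
        res = run_gene_pair(geno, phen, gm, "G1", "G2", cfg)
        se = math.sqrt(q_exact * (1 - q_exact) / cfg.b)
        assert res.p_lf == pytest.approx(q_exact, abs=4 * se + 2 / cfg.b)

    def test_empty_selections_give_unit_pvalues_without_permutation(self):
        counts = np.zeros((12, 4), dtype=np.int8)  # monomorphic everywhere
        status = [1] * 6 + [0] * 6
        geno, phen, gm = make_dataset(counts, status,
                                      {"G1": [0, 1], "G2": [2, 3]})
        res = run_gene_pair(geno, phen, gm, "G1", "G2", IgofConfig(seed=1))
        assert res.k == 0 and res.l == 0
        assert res.p_common == res.p_lf == res.p_combined == 1.0
        assert res.perms_common == res.perms_lf == 0

    def test_bit_identical_determinism(self):
        rng = np.random.default_rng(8)
        geno, phen, gm = random_dataset(rng, ns=60, v1=4, v2=4)
        cfg = IgofConfig(m=1e6, b=500, r=20, sw_permutations=100, seed=4)
        r1 = run_gene_pair(geno, phen, gm, "G1", "G2", cfg)
        r2 = run_gene_pair(geno, phen, gm, "G1", "G2", cfg)
        assert r1 == r2

    def test_sample_order_invariance_of_observed_statistics(self):
        rng = np.random.default_rng(21)
        ns = 50
        counts = rng.binomial(2, 0.3, size=(ns, 6)).astype(np.int8)
        status = np.zeros(ns, dtype=bool)
        status[:25] = True
        perm = rng.permutation(ns)
        ev1 = _FastEvaluator(counts[:, :3], counts[:, 3:], status, 0.05)
        ev2 = _FastEvaluator(counts[perm][:, :3], counts[perm][:, 3:],
                             status[perm], 0.05)
        o1, o2 = ev1.observed(), ev2.observed()
        for key in o1:
            a, b = o1[key], o2[key]
            if isinstance(a, float) and np.isnan(a):
                assert np.isnan(b)
            else:
                assert a == pytest.approx(b, rel=1e-5)

    def test_missing_genotypes_use_pairwise_deletion(self):
        rng = np.random.default_rng(6)
        geno, phen, gm = random_dataset(rng, ns=30, v1=2, v2=2)
        counts = geno.counts.copy()
        counts[0, 0] = -1
        counts[5, 3] = -1
        geno2 = GenotypeMatrix(samples=geno.samples, variants=geno.variants,
                               counts=counts)
        cfg = IgofConfig(m=1e6, b=200, r=200, sw_permutations=50, seed=2)
        res = run_gene_pair(geno2, phen, gm, "G1", "G2", cfg)
        assert 0 < res.p_combined <= 1
        # deterministic repeat
        assert res == run_gene_pair(geno2, phen, gm, "G1", "G2", cfg)

    def test_unknown_gene_raises(self):
        rng = np.random.default_rng(1)
        geno, phen, gm = random_dataset(rng)
        with pytest.raises(KeyError, match="G9"):
            run_gene_pair(geno, phen, gm, "G1", "G9", IgofConfig())

    def test_allele_flip_leaves_statistics_unchanged(self):
        # recoding one variant to the other allele (0 <-> 2) permutes
        # categories only; observed statistics are unchanged end-to-end
        rng = np.random.default_rng(33)
        geno, phen, gm = random_dataset(rng, ns=80, v1=3, v2=3, maf=0.5)
        flipped = geno.counts.copy()
        flipped[:, 0] = 2 - flipped[:, 0]
        ev1 = _FastEvaluator(geno.counts[:, :3], geno.counts[:, 3:],
                             phen.status, 0.05)
        ev2 = _FastEvaluator(flipped[:, :3], flipped[:, 3:],
                             phen.status, 0.05)
        o1, o2 = ev1.observed(), ev2.observed()
        assert o1["n_common"] == o2["n_common"]
        assert o1["k"] == o2["k"]
        if not np.isnan(o1["i_common"]):
            assert o1["i_common"] == pytest.approx(o2["i_common"], rel=1e-5)
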