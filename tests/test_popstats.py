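"""Population-genetic statistics against closed forms and independent oracles."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pseudodrift import popstats, synth
from pseudodrift.genotypes import GenotypeMatrix
from pseudodrift.popstats import (
    PopAlleleFreqs,
    heterozygosity,
    hwe_exact_distribution,
    hwe_exact_test,
    inbreeding_f,
    mantel,
    pop_allele_freqs,
    weir_cockerham_fst,
    wright_fst,
)


def _matrix_from_counts(hom_ref, het, hom_alt):
    codes = np.array([0.0] * hom_ref + [1.0] * het + [2.0] * hom_alt)[:, None]
    return GenotypeMatrix([f"s{i}" for i in range(len(codes))], ["l"], codes)


class TestHeterozygosity:
    def test_observed_and_expected(self):
        res = heterozygosity(_matrix_from_counts(2, 6, 4))
        assert res["h_obs"][0] == pytest.approx(0.5)
        assert res["h_exp"][0] == pytest.approx(2 * (14 / 24) * (10 / 24))

    def test_monomorphic_locus(self):
        res = heterozygosity(_matrix_from_counts(5, 0, 0))
        assert res["h_obs"][0] == 0.0 and res["h_exp"][0] == 0.0

    def test_all_heterozygous(self):
        assert heterozygosity(_matrix_from_counts(0, 7, 0))["h_obs"][0] == 1.0


def _freqs(p1, p2):
    return PopAlleleFreqs(
        ["A", "B"], ["l"], np.array([[p1], [p2]]), np.array([[10.0], [10.0]])
    )


class TestWrightFst:
    @pytest.mark.parametrize(
        "p1,p2,expected", [(0.5, 0.0, 1 / 3), (0.4, 0.4, 0.0), (1.0, 0.0, 1.0)]
    )
    def test_closed_forms(self, p1, p2, expected):
        assert wright_fst(_freqs(p1, p2))["per_locus"][0] == pytest.approx(expected)

    def test_single_population_rejected(self):
        with pytest.raises(ValueError):
            wright_fst(_freqs(0.5, 0.0), pops=["A"])

    @given(
        p1=st.floats(0, 1), p2=st.floats(0, 1), p3=st.floats(0, 1)
    )
    @settings(max_examples=200, deadline=None)
    def test_bounded_in_unit_interval(self, p1, p2, p3):
        """Concavity of 2p(1-p) keeps H_S <= H_T, so F_ST lies in [0, 1]."""
        freqs = PopAlleleFreqs(
            ["A", "B", "C"],
            ["l"],
            np.array([[p1], [p2], [p3]]),
            np.ones((3, 1)) * 5,
        )
        f = wright_fst(freqs)["per_locus"][0]
        assert -1e-12 <= f <= 1 + 1e-12


class TestWeirCockerham:
    def test_worked_instance_matches_fraction_oracle(self, toy_matrix):
        """2 pops x 4 individuals x 2 loci, frozen from exact Fraction arithmetic."""
        res = weir_cockerham_fst(toy_matrix)
        assert res["per_locus"][0] == pytest.approx(17 / 33)
        assert res["per_locus"][1] == pytest.approx(0.0, abs=1e-12)
        assert res["global"] == pytest.approx(0.2982456140350877)

    def test_fixed_difference_gives_one(self):
        codes = np.array([[0.0]] * 4 + [[2.0]] * 4)
        m = GenotypeMatrix(
            [f"s{i}" for i in range(8)], ["l"], codes,
            np.array(["A"] * 4 + ["B"] * 4, dtype=object),
        )
        assert weir_cockerham_fst(m)["per_locus"][0] == pytest.approx(1.0)

    def test_null_theta_near_zero(self):
        cfg = synth.SynthConfig(n_individuals=1000, n_loci=50, allele_freqs=0.3, seed=5)
        m = synth.generate_hwe_population(cfg)
        m.populations = np.array(["A"] * 500 + ["B"] * 500, dtype=object)
        assert abs(weir_cockerham_fst(m)["global"]) <= 0.05

    def test_island_model_recovery(self):
        """theta recovers a simulated F_ST of 0.1 within 0.03."""
        rng = np.random.default_rng(17)
        F = 0.1
        n_loci, n_per = 1000, 100
        anc = rng.uniform(0.2, 0.8, n_loci)
        a, b = anc * (1 - F) / F, (1 - anc) * (1 - F) / F
        codes = []
        for _ in range(2):
            p = rng.beta(a, b)
            codes.append(rng.binomial(2, p[None, :], size=(n_per, n_loci)))
        m = GenotypeMatrix(
            [f"s{i}" for i in range(2 * n_per)],
            [f"l{j}" for j in range(n_loci)],
            np.vstack(codes).astype(float),
            np.array(["A"] * n_per + ["B"] * n_per, dtype=object),
        )
        assert weir_cockerham_fst(m)["global"] == pytest.approx(0.1, abs=0.03)

    def test_single_individual_population_excluded(self):
        codes = np.array([[0.0], [1.0], [2.0]])
        m = GenotypeMatrix(
            ["a", "b", "c"], ["l"], codes, np.array(["A", "A", "B"], dtype=object)
        )
        res = weir_cockerham_fst(m)
        assert res["excluded_loci"] == ["l"]


def _hwe_oracle(n_hom_ref, n_het, n_hom_alt):
    """Brute-force exact conditional p-value with Fraction arithmetic."""
    from math import factorial

    n = n_hom_ref + n_het + n_hom_alt
    n_alt = n_het + 2 * n_hom_alt
    n_ref = 2 * n - n_alt

    def prob(h):
        ha, hr = (n_alt - h) // 2, (n_ref - h) // 2
        return Fraction(
            2**h * factorial(n) * factorial(n_alt) * factorial(n_ref),
            factorial(hr) * factorial(h) * factorial(ha) * factorial(2 * n),
        )

    rare = min(n_alt, n_ref)
    hets = range(rare % 2, rare + 1, 2)
    probs = {h: prob(h) for h in hets}
    assert sum(probs.values()) == 1
    obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= obs))


class TestHweExact:
    def test_similipal_counts_give_p_one(self):
        assert hwe_exact_test(2, 6, 4) == pytest.approx(1.0)

    def test_monomorphic_is_one(self):
        assert hwe_exact_test(9, 0, 0) == 1.0

    @pytest.mark.parametrize(
        "counts", [(5, 0, 5), (2, 6, 4), (1, 1, 8), (10, 2, 0), (0, 4, 0)]
    )
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(_hwe_oracle(*counts), rel=1e-9)

    @pytest.mark.parametrize("n,n_alt", [(10, 10), (25, 13), (50, 3)])
    def test_conditional_distribution_sums_to_one(self, n, n_alt):
        _, probs = hwe_exact_distribution(n, n_alt)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)


class TestInbreedingF:
    def test_fully_homozygous_is_one(self):
        codes = np.array([[0.0, 2.0, 0.0, 2.0]])
        m = GenotypeMatrix(["s"], [f"l{j}" for j in range(4)], codes)
        f = inbreeding_f(m, ref_freqs=np.full(4, 0.5), ref_n=1e9)
        assert f[0] == pytest.approx(1.0, abs=1e-6)

    def test_fully_heterozygous_is_negative(self):
        codes = np.array([[1.0] * 4])
        m = GenotypeMatrix(["s"], [f"l{j}" for j in range(4)], codes)
        f = inbreeding_f(m, ref_freqs=np.full(4, 0.5), ref_n=1e9)
        assert f[0] < 0

    def test_hwe_population_mean_near_zero(self):
        cfg = synth.SynthConfig(n_individuals=1000, n_loci=200, allele_freqs=0.4, seed=9)
        m = synth.generate_hwe_population(cfg)
        assert abs(np.nanmean(inbreeding_f(m))) < 0.02


class TestMantel:
    def _random_distance(self, rng, n):
        x = rng.random((n, 2))
        return np.linalg.norm(x[:, None] - x[None, :], axis=-1)

    def test_identical_matrices(self):
        d = self._random_distance(np.random.default_rng(1), 12)
        res = mantel(d, d.copy(), permutations=199, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 200)

    def test_p_value_never_below_floor(self):
        d = self._random_distance(np.random.default_rng(2), 10)
        res = mantel(d, d + 0.01, permutations=99, seed=0)
        assert res.p_value >= 1 / 100

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            mantel(np.zeros((5, 5)), np.ones((5, 5)) - np.eye(5), permutations=99)

    def test_null_pvalues_uniform(self):
        """Independent matrices: permutation p is valid and ~ Uniform."""
        pvals = []
        for seed in range(300):
            rng = np.random.default_rng(seed)
            a = self._random_distance(rng, 15)
            b = self._random_distance(rng, 15)
            pvals.append(mantel(a, b, permutations=99, seed=seed).p_value)
        assert min(pvals) >= 1 / 100
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_agrees_with_skbio(self):
        """Cross-check the statistic and p-value against scikit-bio's Mantel."""
        from skbio.stats.distance import DistanceMatrix, mantel as sk_mantel

        rng = np.random.default_rng(3)
        a = self._random_distance(rng, 15)
        b = a + rng.random((15, 15)) * 0.3
        b = (b + b.T) / 2
        np.fill_diagonal(b, 0)
        res = mantel(a, b, permutations=999, seed=1)
        r_sk, p_sk, _ = sk_mantel(
            DistanceMatrix(a), DistanceMatrix(b), method="pearson",
            permutations=999, alternative="greater",
        )
        assert res.r == pytest.approx(float(r_sk), abs=1e-12)
        assert res.p_value == pytest.approx(float(p_sk), abs=0.03)

    def test_correlogram_classes(self):
        """Short-distance classes carry the positive IBD signal."""
        m, d = synth.generate_ibd_landscape(
            9, None, decay=25, n_per_pop=20, n_loci=60, seed=4
        )
        gd = popstats.pairwise_fst_matrix(pop_allele_freqs(m))
        edges = np.quantile(d[np.triu_indices(9, 1)], [0, 0.33, 0.66, 1.0])
        res = mantel(gd, d, permutations=199, classes=edges, seed=4)
        assert len(res.classes) == 3
        for cls in res.classes:
            assert np.isnan(cls["p_value"]) or cls["p_value"] >= 1 / 200


def test_fst_rank():
    per_locus = np.array([0.1, 0.5, np.nan, 0.3])
    assert popstats.fst_rank(per_locus, 3) == 2
    assert popstats.fst_rank(per_locus, 1) == 1
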