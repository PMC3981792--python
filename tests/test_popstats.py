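import numpy as np
import pandas as pd
import pytest

from msatpop.bruvo import DistanceMatrix, distance_matrix
from msatpop.genotype_io import to_repeat_table
from msatpop.popstats import (
    amova,
    count_alleles,
    diploid_compatible_strains,
    hwe_test,
    locus_summary,
    observed_heterozygosity,
    weir_cockerham,
)

from conftest import amova_sigma2_among_oracle, make_table


class TestHeterozygosity:
    def test_basic_fraction(self):
        table = make_table(
            {
                "a": {"X": (10,)},
                "b": {"X": (10, 11)},
                "c": {"X": (10, 11, 12)},
                "d": {"X": ()},
            }
        )
        # 2 of 3 scored strains carry >= 2 distinct alleles
        assert observed_heterozygosity(table, "X") == pytest.approx(2 / 3)

    def test_all_missing_warns_nan(self):
        table = make_table({"a": {"X": ()}, "b": {"X": ()}})
        with pytest.warns(UserWarning, match="no scored strains"):
            assert np.isnan(observed_heterozygosity(table, "X"))

    def test_count_alleles(self):
        table = make_table({"a": {"X": (10, 14)}, "b": {"X": (12,)}})
        n, rng = count_alleles(table, "X")
        assert n == 3
        assert rng == (10, 14)


class TestHWE:
    def hw_table(self, seed, n=200, freqs=(0.5, 0.3, 0.2)):
        """Sample genotypes exactly at Hardy-Weinberg proportions."""
        rng = np.random.default_rng(seed)
        alleles = [10, 12, 14]
        draws = rng.choice(alleles, size=(n, 2), p=list(freqs))
        cells = {
            f"s{i}": {"X": tuple(sorted(set(draws[i])))} for i in range(n)
        }
        return make_table(cells)

    def test_null_chi2_p_uniformish(self):
        """Under HWE, asymptotic p should not be tiny."""
        ps = []
        for seed in range(20):
            chi2, df, p = hwe_test(self.hw_table(seed), "X")
            assert df == 3
            ps.append(p)
        assert min(ps) > 1e-4
        assert 0.2 < np.mean(ps) < 0.8

    def test_detects_heterozygote_deficit(self):
        """A fully selfed (all-homozygote) sample is wildly out of HWE."""
        cells = {f"s{i}": {"X": (10 if i % 2 else 14,)} for i in range(60)}
        table = make_table(cells)
        chi2, df, p = hwe_test(table, "X")
        assert p < 1e-6
        _, _, p_mc = hwe_test(table, "X", n_mc=199, seed=3)
        assert p_mc == pytest.approx(1 / 200)

    def test_mc_matches_asymptotic_roughly(self):
        table = self.hw_table(5)
        _, _, p_asym = hwe_test(table, "X")
        _, _, p_mc = hwe_test(table, "X", n_mc=999, seed=11)
        assert abs(p_mc - p_asym) < 0.15

    def test_monomorphic_warns(self):
        table = make_table({f"s{i}": {"X": (10,)} for i in range(5)})
        with pytest.warns(UserWarning, match="monomorphic"):
            chi2, df, p = hwe_test(table, "X")
        assert np.isnan(p)


class TestWeirCockerham:
    def two_pop_table(self, seed, fst_strength=4.0, n=80):
        """Two demes with shifted allele frequencies (random mating within)."""
        rng = np.random.default_rng(seed)
        cells = {}
        for pop, shift in (("A", 0.0), ("B", fst_strength)):
            base = np.array([0.6, 0.3, 0.1])
            w = base * np.exp(shift * np.array([0.0, 0.5, 1.0]))
            w = w / w.sum()
            for i in range(n):
                g = tuple(sorted(set(rng.choice([10, 12, 14], size=2, p=w))))
                cells[f"{pop}{i}"] = {"X": g}
        table = make_table(cells)
        grouping = pd.Series(
            {s: s[0] for s in cells}, name="pop"
        )
        return table, grouping

    def test_panmictic_fst_near_zero(self):
        table, grouping = self.two_pop_table(1, fst_strength=0.0, n=300)
        res = weir_cockerham(table, grouping)
        assert abs(res.overall["F_ST"]) < 0.02
        assert abs(res.overall["F_IS"]) < 0.08

    def test_divergent_pops_positive_fst(self):
        table, grouping = self.two_pop_table(2, fst_strength=4.0, n=200)
        res = weir_cockerham(table, grouping)
        assert res.overall["F_ST"] > 0.1
        # random mating within pops: F_IS should stay near 0
        assert abs(res.overall["F_IS"]) < 0.08

    def test_all_homozygotes_fis_one(self):
        cells = {}
        rng = np.random.default_rng(3)
        for pop in ("A", "B"):
            for i in range(40):
                cells[f"{pop}{i}"] = {"X": (int(rng.choice([10, 12, 14])),)}
        table = make_table(cells)
        grouping = pd.Series({s: s[0] for s in cells}, name="pop")
        res = weir_cockerham(table, grouping)
        assert res.overall["F_IS"] == pytest.approx(1.0)
        assert res.overall["F_IT"] == pytest.approx(1.0)

    def test_matches_hierfstat_style_known_case(self):
        """Small fixed dataset cross-checked against a hand computation of the
        Weir-Cockerham components (two pops, two alleles)."""
        # pop A: 3x (10,10), 1x (10,12); pop B: 1x (10,12), 3x (12,12)
        cells = {
            "A1": {"X": (10,)}, "A2": {"X": (10,)}, "A3": {"X": (10,)},
            "A4": {"X": (10, 12)},
            "B1": {"X": (10, 12)}, "B2": {"X": (12,)}, "B3": {"X": (12,)},
            "B4": {"X": (12,)},
        }
        table = make_table(cells)
        grouping = pd.Series({s: s[0] for s in cells}, name="pop")
        res = weir_cockerham(table, grouping)
        # hand computation: n_i = (4,4), nbar=4, nc=4, r=2
        # allele 10: p = (7/8, 1/8), pbar=0.5, s2=(4*(3/8)^2*2)/(1*4)=0.28125
        # hbar = (1/4 + 1/4)/2 = 0.25
        # a = 1*(0.28125 - (0.25 - 0.140625 - 0.0625)/3) = 0.265625
        # b = (4/3)*(0.25 - 0.140625 - (7/16)*0.25) = 0.25/1.5 ... compute:
        #    0.25 - 0.140625 - 0.109375 = 0.0 -> b = 0.0
        # c = 0.125; allele 12 symmetric (doubles all components)
        A = res.components.loc["X", "a"]
        B = res.components.loc["X", "b"]
        C = res.components.loc["X", "c"]
        assert A == pytest.approx(2 * 0.265625)
        assert B == pytest.approx(0.0, abs=1e-12)
        assert C == pytest.approx(0.25)
        assert res.overall["F_ST"] == pytest.approx(0.53125 / 0.78125)

    def test_triploid_strains_excluded(self):
        cells = {
            "a": {"X": (10, 11, 12)},
            "b": {"X": (10,)},
            "c": {"X": (10, 11)},
        }
        table = make_table(cells)
        assert diploid_compatible_strains(table) == ["b", "c"]


class TestAmova:
    def random_dm(self, seed, n):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        return DistanceMatrix([f"s{i}" for i in range(n)], d)

    def test_sigma2_matches_oracle(self):
        for seed in range(5):
            n = 12
            dm = self.random_dm(seed, n)
            labels = ["g1"] * 4 + ["g2"] * 5 + ["g3"] * 3
            groups = pd.Series(dict(zip(dm.labels, labels)), name="g")
            res = amova(dm, groups, n_perm=10, seed=0)
            want = amova_sigma2_among_oracle(dm.values, labels)
            assert res.sigma2_among == pytest.approx(want)

    def test_random_labels_large_p(self):
        dm = self.random_dm(10, 30)
        rng = np.random.default_rng(0)
        groups = pd.Series(
            dict(zip(dm.labels, rng.choice(["a", "b", "c"], size=30))), name="g"
        )
        res = amova(dm, groups, n_perm=499, seed=1)
        assert res.p_value > 0.01

    def test_structured_labels_small_p(self):
        rng = np.random.default_rng(4)
        pts = np.concatenate(
            [rng.normal(0, 1, size=(15, 3)), rng.normal(6, 1, size=(15, 3))]
        )
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dm = DistanceMatrix([f"s{i}" for i in range(30)], d)
        groups = pd.Series(
            {f"s{i}": ("a" if i < 15 else "b") for i in range(30)}, name="g"
        )
        res = amova(dm, groups, n_perm=999, seed=2)
        assert res.p_value <= 0.005
        assert res.percent_among > 50

    def test_single_group_trivial(self):
        dm = self.random_dm(1, 6)
        groups = pd.Series({lab: "only" for lab in dm.labels}, name="g")
        res = amova(dm, groups, n_perm=99, seed=0)
        assert res.sigma2_among == 0.0
        assert res.percent_among == 0.0
        assert res.p_value == 1.0

    def test_deterministic_given_seed(self):
        dm = self.random_dm(2, 15)
        groups = pd.Series(
            {lab: ("a" if i % 2 else "b") for i, lab in enumerate(dm.labels)},
            name="g",
        )
        r1 = amova(dm, groups, n_perm=199, seed=42)
        r2 = amova(dm, groups, n_perm=199, seed=42)
        assert r1.p_value == r2.p_value


class TestLocusSummary:
    def test_columns_and_bonferroni(self, sim_default):
        table, truth = sim_default
        reps = to_repeat_table(table)
        grouping = pd.Series(
            {s: f"pop{k}" for s, k in truth.labels.items()}, name="pop"
        )
        out = locus_summary(reps, grouping=grouping)
        assert set(
            ["n_alleles", "Ho", "hwe_p", "hwe_p_bonferroni", "F_ST", "F_IS"]
        ) <= set(out.columns)
        ok = out["hwe_p"].notna()
        assert (
            out.loc[ok, "hwe_p_bonferroni"]
            >= out.loc[ok, "hwe_p"] - 1e-12
        ).all()
        assert (out.loc[ok, "hwe_p_bonferroni"] <= 1.0).all()

    def test_selfing_signature_on_simulated_data(self, sim_default):
        """The default generator is highly selfing: Ho should be low and
        multilocus F_IS strongly positive."""
        table, truth = sim_default
        reps = to_repeat_table(table)
        grouping = pd.Series(
            {s: f"pop{k}" for s, k in truth.labels.items()}, name="pop"
        )
        res = weir_cockerham(reps, grouping)
        assert res.overall["F_IS"] > 0.5
        ho = np.nanmean(
            [observed_heterozygosity(reps, l) for l in reps.locus_names]
        )
        assert ho < 0.3
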