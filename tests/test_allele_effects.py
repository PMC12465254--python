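import numpy as np
import pandas as pd
import pytest

from antapleio import allele_effects as ae

from conftest import make_genotypes


def _assoc(traits_betas, neg_log10_p=6.0):
    """One association frame per trait from (beta, significant?) specs."""
    out = {}
    for trait, betas in traits_betas.items():
        betas = np.asarray(betas, float)
        out[trait] = pd.DataFrame({
            "chrom": "1A",
            "pos": 1000 + 1000 * np.arange(len(betas)),
            "ref": "A",
            "alt": "G",
            "beta": betas,
            "se": 0.1,
            "p": 10.0 ** -neg_log10_p,
            "neg_log10_p": neg_log10_p,
            "maf": 0.3,
            "n": 100,
        })
    return out


class TestAssignFavorableAlleles:
    def test_direction_conventions(self):
        fav = ae.assign_favorable_alleles(
            _assoc({"GP3D": [4.0, -2.0], "TKW": [1.2, -0.8]})
        )
        gp = fav[fav["trait"] == "GP3D"].set_index("variant")["favorable"]
        tkw = fav[fav["trait"] == "TKW"].set_index("variant")["favorable"]
        assert gp[0] == "ref"    # +4% GP per alt copy -> alt is unfavorable
        assert gp[1] == "alt"    # GP-reducing alt is favorable (dormancy)
        assert tkw[0] == "alt"   # +1.2 g per alt copy -> alt favorable
        assert tkw[1] == "ref"

    def test_subthreshold_snps_excluded_and_zero_beta_skipped(self):
        assoc = _assoc({"TKW": [1.0, 0.0, 2.0]})
        assoc["TKW"].loc[2, "neg_log10_p"] = 3.0
        with pytest.warns(UserWarning, match="beta == 0"):
            fav = ae.assign_favorable_alleles(assoc)
        assert fav["variant"].tolist() == [0]


class TestFafShift:
    @staticmethod
    def _panel():
        # variant 0: landrace alt 0.30, cultivar alt 0.50; variant 1 equal
        lr = np.column_stack([
            np.repeat([0, 1], [7, 3]),      # alt freq 0.15? -> use dosage sums
            np.repeat([1, 1], [5, 5]),
        ]).astype(float)
        lr[:, 0] = np.array([0, 0, 0, 0, 1, 1, 1, 1, 1, 2])  # freq 0.35
        cv = lr.copy()
        cv[:, 0] = np.array([1, 1, 1, 1, 1, 1, 1, 1, 1, 2])  # freq 0.55
        dosage = np.vstack([lr, cv])
        return make_genotypes(dosage,
                              groups=["landrace"] * 10 + ["cultivar"] * 10)

    def test_direction_and_antisymmetry(self):
        G = self._panel()
        fav = ae.assign_favorable_alleles(_assoc({"TKW": [1.0, 1.0]}))
        shift = ae.compute_faf_shift(G, fav)
        assert shift["direction"].tolist() == ["up", "unchanged"]
        swapped = ae.compute_faf_shift(G, fav, group_a="cultivar",
                                       group_b="landrace")
        assert swapped["direction"].tolist() == ["down", "unchanged"]
        assert np.allclose(shift["faf_a"], swapped["faf_b"])

    def test_summary_percentages(self):
        G = self._panel()
        fav = ae.assign_favorable_alleles(_assoc({"TKW": [1.0, 1.0]}))
        summ = ae.faf_summary(ae.compute_faf_shift(G, fav))
        row = summ.set_index("trait").loc["TKW"]
        assert row["pct_up"] == 50.0
        assert row["pct_unchanged"] == 50.0


class TestCountFavorableAlleles:
    def test_carriage_rule(self):
        # 12 loci: hom favorable at 10, het at 1, missing at 1 -> count 11
        dosage = np.full((1, 12), 2.0)
        dosage[0, 10] = 1.0
        dosage[0, 11] = np.nan
        G = make_genotypes(dosage, groups=["cultivar"])
        fav = ae.assign_favorable_alleles(_assoc({"TKW": [1.0] * 12}))
        counts = ae.count_favorable_alleles(G, fav)
        assert counts["size"].iloc[0] == 11
        assert counts["dormancy"].iloc[0] == 0
        assert counts["total"].iloc[0] == 11

    def test_zero_favorable(self):
        G = make_genotypes(np.zeros((1, 3)), groups=["cultivar"])
        fav = ae.assign_favorable_alleles(_assoc({"TKW": [1.0] * 3}))
        counts = ae.count_favorable_alleles(G, fav)
        assert counts["total"].iloc[0] == 0

    def test_histogram_bins(self):
        counts = pd.Series([25, 61, 61, 120, 139])
        hist = ae.count_histogram(counts)
        assert hist["20-60"] == 1
        assert hist["60-100"] == 2
        assert hist["100-140"] == 2


class TestTrendFit:
    def test_exactly_linear_bins_give_unit_r2(self):
        x = np.repeat(np.arange(10.0), 10)
        y = 3.0 - 0.5 * x
        fit = ae.trend_fit(x, y, n_bins=5)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.slope < 0

    def test_null_relationship_has_low_r2(self):
        r2s = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0, 1, 1000)
            y = rng.normal(size=1000)
            r2s.append(ae.trend_fit(x, y, n_bins=20).r2)
        assert np.mean(r2s) < 0.3

    def test_constant_x_errors(self):
        with pytest.raises(ValueError, match="spread"):
            ae.trend_fit(np.ones(50), np.arange(50.0))

    def test_sparse_bins_merged(self):
        x = np.concatenate([np.zeros(20), np.ones(20), np.full(20, 2.0),
                            np.full(2, 10.0)])
        y = x.copy()
        fit = ae.trend_fit(x, y, n_bins=10)
        assert fit.bin_n.min() >= 2  # tail merged, no empty bin fitted
        assert fit.slope > 0


class TestClassifyPleiotropy:
    @staticmethod
    def _panel(gp_effect, tkw_effect, seed=0, n=120):
        rng = np.random.default_rng(seed)
        dos = rng.binomial(2, 0.5, size=(n, 3)).astype(float)
        G = make_genotypes(dos)
        gp = pd.Series(50 + gp_effect * dos[:, 0] + rng.normal(0, 1, n),
                       index=G.samples)
        tkw = pd.Series(40 + tkw_effect * dos[:, 0] + rng.normal(0, 0.5, n),
                        index=G.samples)
        return G, gp, tkw

    def test_single_trait_snp_is_independent(self):
        G, gp, tkw = self._panel(gp_effect=-4.0, tkw_effect=0.0)
        cl = ae.classify_pleiotropy(G, gp, tkw, mta_gp=[0], mta_tkw=[])
        assert cl["snp_class"].iloc[0] == "independent"

    def test_high_tkw_low_gp_is_synergistic(self):
        G, gp, tkw = self._panel(gp_effect=-4.0, tkw_effect=2.0)
        cl = ae.classify_pleiotropy(G, gp, tkw, mta_gp=[0], mta_tkw=[0])
        assert cl["snp_class"].iloc[0] == "synergistic"

    def test_high_tkw_high_gp_is_antagonistic(self):
        G, gp, tkw = self._panel(gp_effect=4.0, tkw_effect=2.0)
        cl = ae.classify_pleiotropy(G, gp, tkw, mta_gp=[0], mta_tkw=[0])
        assert cl["snp_class"].iloc[0] == "antagonistic"

    def test_orientation_invariant_to_allele_coding(self):
        # same biology coded on the other allele: low TKW with low GP
        G, gp, tkw = self._panel(gp_effect=-4.0, tkw_effect=-2.0)
        cl = ae.classify_pleiotropy(G, gp, tkw, mta_gp=[0], mta_tkw=[0])
        assert cl["snp_class"].iloc[0] == "antagonistic"

    def test_rare_homozygote_uses_regression_fallback(self):
        rng = np.random.default_rng(1)
        n = 80
        dos = rng.binomial(2, 0.08, size=(n, 1)).astype(float)
        G = make_genotypes(dos)
        gp = pd.Series(50 - 4 * dos[:, 0] + rng.normal(0, 1, n), index=G.samples)
        tkw = pd.Series(40 + rng.normal(0, 1, n), index=G.samples)
        cl = ae.classify_pleiotropy(G, gp, tkw, mta_gp=[0], mta_tkw=[])
        assert bool(cl["fallback"].iloc[0])

    def test_percentages_partition_the_union(self):
        rng = np.random.default_rng(2)
        n = 150
        dos = rng.binomial(2, 0.5, size=(n, 6)).astype(float)
        G = make_genotypes(dos)
        gp = pd.Series(50 - 3 * dos[:, 0] + 3 * dos[:, 1] + rng.normal(0, 1, n),
                       index=G.samples)
        tkw = pd.Series(40 + 2 * dos[:, 1] + 2 * dos[:, 2] + rng.normal(0, 1, n),
                        index=G.samples)
        cl = ae.classify_pleiotropy(G, gp, tkw, mta_gp=[0, 1], mta_tkw=[1, 2])
        assert len(cl) == 3  # union of {0,1} and {1,2}
        pct = ae.class_percentages(cl)
        assert pct.sum() == pytest.approx(100.0)


class TestPve:
    def test_noise_free_single_snp_explains_everything(self):
        rng = np.random.default_rng(3)
        dos = rng.binomial(2, 0.5, size=(60, 1)).astype(float)
        G = make_genotypes(dos)
        y = pd.Series(2.0 * dos[:, 0] + 5.0, index=G.samples)
        res = ae.pve_of_set(G, [0], y)
        assert res.pve == pytest.approx(1.0)

    def test_null_set_explains_little(self):
        low = 0
        for seed in range(10):
            rng = np.random.default_rng(30 + seed)
            dos = rng.binomial(2, 0.5, size=(500, 10)).astype(float)
            G = make_genotypes(dos)
            y = pd.Series(rng.normal(size=500), index=G.samples)
            if ae.pve_of_set(G, range(10), y).pve < 0.05:
                low += 1
        assert low >= 9

    def test_monotone_when_adding_a_variant(self):
        rng = np.random.default_rng(4)
        dos = rng.binomial(2, 0.5, size=(100, 5)).astype(float)
        G = make_genotypes(dos)
        y = pd.Series(dos[:, 0] - dos[:, 3] + rng.normal(0, 1, 100),
                      index=G.samples)
        pves = [ae.pve_of_set(G, list(range(k + 1)), y).pve for k in range(5)]
        assert all(b >= a - 1e-12 for a, b in zip(pves, pves[1:]))

    def test_ld_pruning_reduces_fitted_set(self):
        rng = np.random.default_rng(5)
        col = rng.binomial(2, 0.5, size=100).astype(float)
        dos = np.column_stack([col, col, rng.binomial(2, 0.5, 100)])
        G = make_genotypes(dos)
        y = pd.Series(col + rng.normal(0, 1, 100), index=G.samples)
        res = ae.pve_of_set(G, [0, 1, 2], y, p_values=[1e-8, 1e-7, 1e-3])
        assert res.n_snps_fitted == 2  # duplicated column pruned
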