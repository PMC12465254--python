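import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from antapleio import pheno_models as pm
from antapleio.io_core import PhenotypeTable

from conftest import balanced_phenotypes


class TestHeritability:
    def test_analytic_case(self):
        vc = pm.VarianceComponents(3, 2, 3, 12, n_locations=2, n_years=3,
                                   n_replicates=2)
        assert pm.estimate_h2(vc) == pytest.approx(0.5, abs=1e-15)

    def test_no_nongenetic_variance_gives_one(self):
        vc = pm.VarianceComponents(2.5, 0, 0, 0, 2, 3, 2)
        assert pm.estimate_h2(vc) == 1.0

    def test_zero_genetic_variance_warns_and_returns_zero(self):
        vc = pm.VarianceComponents(0, 1, 1, 1, 2, 3, 2)
        with pytest.warns(UserWarning):
            assert pm.estimate_h2(vc) == 0.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        g=st.floats(0.01, 1e3), gl=st.floats(0, 1e3), gy=st.floats(0, 1e3),
        e=st.floats(0, 1e3), L=st.integers(1, 5), Y=st.integers(1, 5),
        R=st.integers(1, 4), k=st.floats(0.01, 100),
    )
    def test_matches_hand_formula_and_scale_invariance(self, g, gl, gy, e, L,
                                                       Y, R, k):
        vc = pm.VarianceComponents(g, gl, gy, e, L, Y, R)
        by_hand = g / (g + gl / L + gy / Y + e / (Y * R * L))
        h2 = pm.estimate_h2(vc)
        assert h2 == pytest.approx(by_hand, abs=1e-12)
        scaled = pm.VarianceComponents(k * g, k * gl, k * gy, k * e, L, Y, R)
        assert pm.estimate_h2(scaled) == pytest.approx(h2, rel=1e-9)


def _simulated_table(n_acc, sg, sgl, sgy, se, rng, n_loc=2, n_yr=2, n_rep=2):
    samples = [f"S{i:03d}" for i in range(n_acc)]
    g = rng.normal(0, np.sqrt(sg), n_acc)
    gl = rng.normal(0, np.sqrt(sgl), (n_acc, n_loc))
    gy = rng.normal(0, np.sqrt(sgy), (n_acc, n_yr))
    rows = []
    for li, loc in enumerate(["ZX", "BJ"][:n_loc]):
        for yi, yr in enumerate(range(2021, 2021 + n_yr)):
            for rep in range(1, n_rep + 1):
                vals = 50 + g + gl[:, li] + gy[:, yi] + rng.normal(0, np.sqrt(se), n_acc)
                rows.append(pd.DataFrame({
                    "accession": samples, "trait": "GP3D",
                    "environment": f"{loc}{yr}", "replicate": rep,
                    "value": np.clip(vals, 0, 100),
                }))
    return PhenotypeTable(pd.concat(rows, ignore_index=True)), g


class TestVarianceComponents:
    def test_noise_free_genetic_only(self):
        rng = np.random.default_rng(0)
        pheno, g = _simulated_table(80, 9.0, 0, 0, 0, rng)
        vc = pm.estimate_variance_components(pheno, "GP3D")
        assert vc.sigma2_gl == pytest.approx(0.0, abs=1e-8)
        assert vc.sigma2_gy == pytest.approx(0.0, abs=1e-8)
        assert vc.sigma2_e == pytest.approx(0.0, abs=1e-8)
        assert vc.sigma2_g == pytest.approx(np.var(g, ddof=1), rel=1e-6)

    def test_pure_noise_gives_near_zero_genetic_variance(self):
        rng = np.random.default_rng(1)
        pheno, _ = _simulated_table(200, 0.0, 0, 0, 4.0, rng)
        vc = pm.estimate_variance_components(pheno, "GP3D")
        assert vc.sigma2_g < 0.5
        assert vc.sigma2_e == pytest.approx(4.0, rel=0.25)

    def test_recovery_within_20pct_over_seeds(self):
        # (s2G, s2GL, s2GY, s2E) = (4, 1, 1, 4), n = 300 accessions
        truth = np.array([4.0, 1.0, 1.0, 4.0])
        est = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            pheno, _ = _simulated_table(300, *truth, rng)
            vc = pm.estimate_variance_components(pheno, "GP3D")
            est.append([vc.sigma2_g, vc.sigma2_gl, vc.sigma2_gy, vc.sigma2_e])
        mean_est = np.mean(est, axis=0)
        assert np.all(np.abs(mean_est - truth) / truth < 0.2)

    def test_single_location_component_unestimable(self):
        rng = np.random.default_rng(2)
        pheno, _ = _simulated_table(50, 4.0, 1.0, 1.0, 2.0, rng, n_loc=1)
        with pytest.warns(UserWarning, match="not estimable"):
            vc = pm.estimate_variance_components(pheno, "GP3D")
        assert vc.sigma2_gl == 0.0
        assert vc.n_locations == 1


class TestBlue:
    def test_balanced_noise_free_equals_accession_means(self):
        rng = np.random.default_rng(3)
        g = rng.normal(0, 3, 40)
        pheno = balanced_phenotypes(g, envs=("ZX2021", "ZX2022", "BJ2021"),
                                    env_offsets={"ZX2021": 2.0, "ZX2022": -1.0,
                                                 "BJ2021": 0.5})
        blue = pm.fit_blue(pheno, "GP3D")
        means = pheno.data.groupby("accession")["value"].mean()
        assert np.allclose(blue.sort_index(), means.sort_index(), atol=1e-8)

    def test_adding_constant_shifts_blues_by_constant(self):
        rng = np.random.default_rng(4)
        g = rng.normal(0, 3, 30)
        pheno = balanced_phenotypes(g, noise=2.0, rng=rng)
        shifted = PhenotypeTable(
            pheno.data.assign(value=pheno.data["value"] + 7.5)
        )
        b0 = pm.fit_blue(pheno, "GP3D")
        b1 = pm.fit_blue(shifted, "GP3D")
        assert np.allclose(b1.sort_index() - b0.sort_index(), 7.5, atol=1e-6)

    def test_single_environment_falls_back_to_means(self):
        rng = np.random.default_rng(5)
        pheno = balanced_phenotypes(rng.normal(0, 3, 20), envs=("ZX2021",))
        with pytest.warns(UserWarning, match="single environment"):
            blue = pm.fit_blue(pheno, "GP3D")
        means = pheno.data.groupby("accession")["value"].mean()
        assert np.allclose(blue.sort_index(), means.sort_index())

    def test_tracks_true_genetic_values_on_simulated_panel(self, small_sim):
        blue = pm.fit_blue(small_sim.phenotypes, "GP3D")
        truth = pd.Series(small_sim.genetic_values["GP3D"],
                          index=small_sim.genotypes.samples)
        joined = pd.concat([blue, truth], axis=1).dropna()
        r = np.corrcoef(joined.iloc[:, 0], joined.iloc[:, 1])[0, 1]
        assert r >= 0.95

    def test_missing_trait_errors(self, small_sim):
        with pytest.raises(ValueError, match="absent"):
            pm.fit_blue(small_sim.phenotypes, "NOPE")


class TestCorrelations:
    def test_duplicated_and_negated_traits(self):
        rng = np.random.default_rng(6)
        x = pd.Series(rng.normal(size=50), index=[f"S{i}" for i in range(50)])
        r, p = pm.phenotypic_correlation({"a": x, "b": x.copy(), "c": -x})
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert r.loc["a", "c"] == pytest.approx(-1.0)
        assert np.allclose(r, r.T)
        assert np.allclose(np.diag(r), 1.0)

    def test_antagonistic_architecture_gives_positive_gp_tkw_correlation(self):
        # all shared QTLs antagonistic: the TKW-raising allele raises GP too
        from antapleio.synth import QTL, SimulationConfig, simulate_dataset

        qtls = [QTL(i * 20, "antagonistic", s * 5.0, s * 1.5)
                for i, s in enumerate([1, -1, 1, -1, 1])]
        ds = simulate_dataset(SimulationConfig(
            n_landrace=120, n_cultivar=120, n_other=0, n_variants=200,
            qtls=qtls, selection_shift=0.0, seed=8))
        blues = {t: pm.fit_blue(ds.phenotypes, t) for t in ("GP3D", "TKW")}
        r, _ = pm.phenotypic_correlation(blues)
        assert r.loc["GP3D", "TKW"] > 0


class TestGeneticCorrelation:
    @staticmethod
    def _panel(rng, n=300, m=400, n_qtl=30, rho=1.0):
        X = rng.binomial(2, rng.uniform(0.1, 0.9, m), size=(n, m)).astype(float)
        Z = (X - X.mean(0)) / np.maximum(X.std(0), 1e-9)
        K = Z @ Z.T / m
        qtl = rng.choice(m, n_qtl, replace=False)
        b1 = rng.normal(0, 1, n_qtl)
        b2 = rho * b1 + np.sqrt(max(1 - rho**2, 0)) * rng.normal(0, 1, n_qtl)
        g1, g2 = Z[:, qtl] @ b1, Z[:, qtl] @ b2
        y1 = g1 + rng.normal(0, g1.std(), n)
        y2 = g2 + rng.normal(0, g2.std(), n)
        idx = [f"S{i}" for i in range(n)]
        return (pd.Series(y1, idx), pd.Series(y2, idx), K, idx)

    def test_identical_traits_give_unit_correlation(self):
        rng = np.random.default_rng(10)
        y1, _, K, idx = self._panel(rng)
        res = pm.genetic_correlation(y1, y1.copy(), K, idx)
        assert res.r_g == pytest.approx(1.0, abs=max(3 * res.se, 0.05))

    def test_disjoint_architectures_give_near_zero(self):
        rng = np.random.default_rng(11)
        y1, y2, K, idx = self._panel(rng, rho=0.0)
        res = pm.genetic_correlation(y1, y2, K, idx)
        assert abs(res.r_g) < 0.25

    def test_shared_architecture_recovered(self):
        rng = np.random.default_rng(12)
        y1, y2, K, idx = self._panel(rng, n=500, rho=0.6)
        res = pm.genetic_correlation(y1, y2, K, idx)
        assert res.r_g == pytest.approx(0.6, abs=0.2)


class TestGroupCompare:
    @staticmethod
    def _series(a, b):
        vals = pd.Series(np.concatenate([a, b]),
                         index=[f"S{i}" for i in range(len(a) + len(b))])
        grp = pd.Series(["x"] * len(a) + ["y"] * len(b), index=vals.index)
        return vals, grp

    def test_identical_groups(self):
        a = np.arange(10.0)
        vals, grp = self._series(a, a)
        res = pm.group_compare(vals, grp, "x", "y")
        assert res.difference == 0.0
        assert res.p == pytest.approx(1.0)

    def test_label_swap_flips_sign_only(self):
        rng = np.random.default_rng(13)
        vals, grp = self._series(rng.normal(0, 1, 30), rng.normal(1, 1, 30))
        r1 = pm.group_compare(vals, grp, "x", "y")
        r2 = pm.group_compare(vals, grp, "y", "x")
        assert r1.difference == pytest.approx(-r2.difference)
        assert r1.p == pytest.approx(r2.p)

    def test_power_at_two_sigma_separation(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            vals, grp = self._series(rng.normal(0, 1, 100), rng.normal(2, 1, 100))
            if pm.group_compare(vals, grp, "x", "y").p < 0.001:
                hits += 1
        assert hits == 20

    def test_small_group_errors(self):
        vals, grp = self._series(np.array([1.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="n >= 2"):
            pm.group_compare(vals, grp, "x", "y")
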