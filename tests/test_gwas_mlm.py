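import numpy as np
import pandas as pd
import pytest
from scipy import stats

from antapleio import gwas_mlm
from antapleio.synth import QTL, SimulationConfig, simulate_dataset

from conftest import make_genotypes


class TestGrm:
    def test_matches_brute_force_on_tiny_matrix(self):
        dosage = np.array(
            [[0, 1, 2, 1], [1, 1, 0, 2], [2, 0, 1, 0]], dtype=float
        )
        G = make_genotypes(dosage)
        K = gwas_mlm.compute_grm(G)
        # brute force: loop over variants
        p = dosage.mean(axis=0) / 2
        Z = dosage - 2 * p
        expected = np.zeros((3, 3))
        for a in range(3):
            for b in range(3):
                expected[a, b] = sum(Z[a, j] * Z[b, j] for j in range(4))
        expected /= 2 * sum(pj * (1 - pj) for pj in p)
        assert np.allclose(K, expected, atol=1e-10)

    def test_identical_accessions_share_rows(self):
        rng = np.random.default_rng(0)
        base = rng.binomial(2, 0.4, size=(5, 30)).astype(float)
        dosage = np.vstack([base, base[0]])
        K = gwas_mlm.compute_grm(make_genotypes(dosage))
        assert np.allclose(K[0], K[5])
        assert K[0, 5] == pytest.approx(K[0, 0])

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        dosage = rng.binomial(2, 0.3, size=(8, 40)).astype(float)
        K = gwas_mlm.compute_grm(make_genotypes(dosage))
        perm = rng.permutation(8)
        Kp = gwas_mlm.compute_grm(make_genotypes(dosage[perm]))
        assert np.allclose(Kp, K[np.ix_(perm, perm)])

    def test_all_monomorphic_errors(self):
        with pytest.raises(ValueError, match="monomorphic"):
            gwas_mlm.compute_grm(make_genotypes(np.full((4, 5), 2.0)))


class TestPca:
    def test_separates_balding_nichols_subpopulations(self):
        ds = simulate_dataset(SimulationConfig(
            n_landrace=80, n_cultivar=80, n_other=0, n_variants=500,
            divergence_f=0.1, seed=2))
        scores = gwas_mlm.compute_pca(ds.genotypes, k=2)
        grp = (ds.genotypes.metadata["group"] == "cultivar").to_numpy(float)
        r = np.corrcoef(scores[:, 0], grp)[0, 1]
        assert abs(r) > 0.9

    def test_duplicated_samples_get_identical_scores(self):
        rng = np.random.default_rng(3)
        base = rng.binomial(2, 0.4, size=(10, 50)).astype(float)
        dosage = np.vstack([base, base[3]])
        scores = gwas_mlm.compute_pca(make_genotypes(dosage), k=2)
        assert np.allclose(scores[3], scores[10], atol=1e-8)

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(4)
        dosage = rng.binomial(2, 0.4, size=(30, 100)).astype(float)
        s = gwas_mlm.compute_pca(make_genotypes(dosage), k=3)
        s = s / np.linalg.norm(s, axis=0)
        assert abs(s[:, 0] @ s[:, 1]) < 1e-8

    def test_invalid_k_errors(self):
        G = make_genotypes(np.random.default_rng(5).binomial(2, 0.5, (6, 10)).astype(float))
        with pytest.raises(ValueError):
            gwas_mlm.compute_pca(G, k=0)


class TestMlmScan:
    def test_matches_ols_with_identity_kinship(self):
        rng = np.random.default_rng(6)
        n, m = 50, 40
        dosage = rng.binomial(2, rng.uniform(0.2, 0.8, m), size=(n, m)).astype(float)
        G = make_genotypes(dosage)
        y = pd.Series(rng.normal(size=n), index=G.samples)
        assoc = gwas_mlm.mlm_scan(G, y, grm=np.eye(n), n_pcs=0)
        # independent OLS oracle per variant
        for j in range(m):
            x = dosage[:, j]
            res = stats.linregress(x, y.to_numpy())
            assert assoc["p"].iloc[j] == pytest.approx(res.pvalue, abs=1e-6)
            assert assoc["beta"].iloc[j] == pytest.approx(res.slope, rel=1e-6)

    def test_beta_sign_convention_alt_increases_trait(self):
        rng = np.random.default_rng(7)
        n = 200
        dosage = rng.binomial(2, rng.uniform(0.2, 0.8, 50), size=(n, 50)).astype(float)
        G = make_genotypes(dosage)
        y = pd.Series(2.0 * dosage[:, 10] + rng.normal(0, 0.5, n), index=G.samples)
        assoc = gwas_mlm.mlm_scan(G, y, n_pcs=0)
        assert assoc["beta"].iloc[10] > 0
        assert assoc["neg_log10_p"].iloc[10] > 5

    def test_planted_qtl_power_in_structured_panel(self):
        hits = 0
        for seed in range(3):
            ds = simulate_dataset(SimulationConfig(
                n_landrace=200, n_cultivar=200, n_other=0, n_variants=500,
                qtls=[QTL(250, "independent-dormancy", -8.0, 0.0)],
                var_gl={"GP3D": 1.0}, var_gy={"GP3D": 1.0},
                var_e={"GP3D": 4.0},
                trait_means={"GP3D": 55.0}, seed=40 + seed))
            blue = ds.phenotypes.data.query("trait == 'GP3D'") \
                .groupby("accession")["value"].mean()
            assoc = gwas_mlm.mlm_scan(ds.genotypes, blue)
            if assoc["neg_log10_p"].iloc[250] > 5:
                hits += 1
        assert hits == 3

    def test_too_few_phenotyped_accessions_errors(self):
        rng = np.random.default_rng(8)
        G = make_genotypes(rng.binomial(2, 0.5, (40, 20)).astype(float))
        y = pd.Series(rng.normal(size=10), index=G.samples[:10])
        with pytest.raises(ValueError, match="fewer than 30"):
            gwas_mlm.mlm_scan(G, y)


def _assoc_frame(positions, neg_log10_ps, chrom="1A"):
    return pd.DataFrame({
        "chrom": chrom,
        "pos": positions,
        "ref": "A",
        "alt": "G",
        "beta": 1.0,
        "se": 0.1,
        "p": 10.0 ** (-np.asarray(neg_log10_ps, float)),
        "neg_log10_p": neg_log10_ps,
        "maf": 0.3,
        "n": 100,
    })


class TestCallRegions:
    def test_seven_close_snps_form_one_region_with_min_p_lead(self):
        pos = [1_000_000 + i * 70_000 for i in range(7)]
        logs = [6, 7, 9, 6.5, 8, 6.2, 7.7]
        regions = gwas_mlm.call_regions(_assoc_frame(pos, logs), merge_bp=1_000_000)
        assert len(regions) == 1
        assert regions[0].n_snps == 7
        assert regions[0].lead_pos == pos[2]

    def test_five_snps_are_not_enough(self):
        pos = [1_000_000 + i * 50_000 for i in range(5)]
        regions = gwas_mlm.call_regions(_assoc_frame(pos, [6] * 5))
        assert regions == []

    def test_two_distant_clusters_give_two_regions(self):
        pos = [1_000_000 + i * 50_000 for i in range(6)] + \
              [4_500_000 + i * 50_000 for i in range(6)]
        regions = gwas_mlm.call_regions(_assoc_frame(pos, [6] * 12),
                                        merge_bp=1_000_000)
        assert len(regions) == 2

    def test_regions_disjoint_and_members_unique(self):
        rng = np.random.default_rng(9)
        pos = np.sort(rng.choice(50_000_000, 200, replace=False))
        logs = rng.uniform(3, 9, 200)
        regions = gwas_mlm.call_regions(_assoc_frame(pos, logs), merge_bp=500_000)
        seen = set()
        for i, r in enumerate(regions):
            assert not (set(r.member_index) & seen)
            seen |= set(r.member_index)
            for other in regions[i + 1:]:
                if other.chrom == r.chrom:
                    assert other.start > r.end or r.start > other.end


class TestLdDecay:
    def test_duplicated_variant_pair_has_unit_r2(self):
        rng = np.random.default_rng(10)
        col = rng.binomial(2, 0.5, 50).astype(float)
        dosage = np.column_stack([col, col])
        G = make_genotypes(dosage, spacing=10_000)
        table, _ = gwas_mlm.ld_decay(G, max_dist_bp=100_000, bin_bp=20_000)
        first = table[table["n_pairs"] > 0].iloc[0]
        assert first["mean_r2"] == pytest.approx(1.0)
        assert first["n_pairs"] == 1

    def test_independent_variants_match_null_expectation(self):
        rng = np.random.default_rng(11)
        n = 100
        dosage = rng.binomial(2, 0.5, size=(n, 120)).astype(float)
        G = make_genotypes(dosage, spacing=5_000)
        table, half = gwas_mlm.ld_decay(G, max_dist_bp=200_000, bin_bp=50_000)
        null = 1.0 / (n - 1)
        filled = table.dropna(subset=["mean_r2"])
        assert (filled["mean_r2"] < 3 * null).all()
        assert half == pytest.approx(25_000)  # first bin midpoint

    def test_founder_block_ld_decays_with_distance(self):
        ds = simulate_dataset(SimulationConfig(
            n_landrace=150, n_cultivar=0, n_other=0, n_variants=400,
            block_size=20, flip_prob=0.1,
            chromosome_lengths={"1A": 2_000_000}, seed=12))
        table, _ = gwas_mlm.ld_decay(ds.genotypes, max_dist_bp=200_000,
                                     bin_bp=25_000)
        means = table.dropna(subset=["mean_r2"])["mean_r2"].to_numpy()
        slope = np.polyfit(np.arange(len(means)), means, 1)[0]
        assert slope < 0

    def test_no_pairs_errors(self):
        rng = np.random.default_rng(13)
        G = make_genotypes(rng.binomial(2, 0.5, (10, 2)).astype(float),
                           spacing=5_000_000)
        with pytest.raises(ValueError, match="no SNP pair"):
            gwas_mlm.ld_decay(G, max_dist_bp=1_000_000)
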