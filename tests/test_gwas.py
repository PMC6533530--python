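import numpy as np
import numpy.linalg as la
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mycogrid import gwas
from mycogrid.gwas import (GenotypeMatrix, bh_adjust, call_qtls, cluster_positions,
                           compute_kinship, compute_maf, emma_null, snp_scan)


def _toy_genotypes(rng, n=120, m=400, n_chrom=4):
    dos = 2.0 * (rng.random((n, m)) < rng.uniform(0.1, 0.9, m))
    per = m // n_chrom
    chrom = np.repeat([str(c + 1) for c in range(n_chrom)], per)
    pos = np.tile(np.arange(per) * 50_000 + 1, n_chrom)
    return GenotypeMatrix(snp_ids=np.array([f"s{i}" for i in range(m)]),
                          chrom=chrom, pos=pos, dosages=dos,
                          samples=[f"a{i}" for i in range(n)])


class TestMAF:
    @pytest.mark.parametrize("dosages,expected", [
        ([0, 0, 2, 2, 2], 0.4),
        ([2, 2, 2, 2], 0.0),
        ([0, 2, np.nan, 2], 1 / 3),
    ])
    def test_values(self, dosages, expected):
        assert compute_maf(dosages) == pytest.approx(expected)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            compute_maf([np.nan, np.nan])


class TestKinship:
    def test_identical_accessions_maximal(self, rng):
        G = _toy_genotypes(rng, n=30)
        G.dosages[1] = G.dosages[0]
        K = compute_kinship(G)
        off = K - np.diag(np.diag(K))
        assert K[0, 1] == pytest.approx(off.max())

    def test_independent_accessions_near_zero_offdiagonal(self, rng):
        G = _toy_genotypes(rng, n=60, m=5000, n_chrom=10)
        K = compute_kinship(G)
        off = K[~np.eye(60, dtype=bool)]
        assert abs(off.mean()) < 0.05

    def test_snp_order_invariance(self, rng):
        G = _toy_genotypes(rng, n=25)
        K1 = compute_kinship(G)
        perm = rng.permutation(G.n_snps)
        G2 = GenotypeMatrix(snp_ids=G.snp_ids[perm], chrom=G.chrom[perm],
                            pos=G.pos[perm], dosages=G.dosages[:, perm],
                            samples=G.samples)
        assert np.allclose(K1, compute_kinship(G2), atol=1e-10)

    def test_psd_and_unit_mean_diagonal(self, rng):
        K = compute_kinship(_toy_genotypes(rng))
        assert np.diag(K).mean() == pytest.approx(1.0, abs=1e-6)
        assert la.eigvalsh(K).min() > -1e-9


class TestEmmaNull:
    def test_reml_matches_dense_restricted_likelihood(self, rng):
        n = 50
        G = _toy_genotypes(rng, n=n, m=300)
        K = compute_kinship(G)
        u = la.cholesky(K + 1e-6 * np.eye(n)) @ rng.normal(size=n)
        y = 2 + u + rng.normal(0, 0.8, n)
        X = np.ones((n, 1))
        null = emma_null(y, X, K)
        # dense Harville restricted likelihood at the fitted parameters
        V = null.sigma2_g * K + null.sigma2_e * np.eye(n)
        Vi = la.inv(V)
        XVX = X.T @ Vi @ X
        P = Vi - Vi @ X @ la.inv(XVX) @ X.T @ Vi
        dense = -0.5 * (la.slogdet(V)[1] + la.slogdet(XVX)[1]
                        + y @ P @ y + (n - 1) * np.log(2 * np.pi))
        assert null.reml_loglik == pytest.approx(dense, abs=1e-6)

    def test_no_genetic_signal_gives_small_genetic_fraction(self):
        # families of related accessions give K real structure; the phenotype
        # ignores it, so the fitted genetic fraction should collapse
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            m, fam, size = 600, 30, 6
            founders = 2.0 * (r.random((fam, m)) < r.uniform(0.1, 0.9, m))
            rows = []
            for f in range(fam):
                for _ in range(size):
                    flip = r.random(m) < 0.05
                    child = founders[f].copy()
                    child[flip] = 2.0 * (r.random(flip.sum()) < 0.5)
                    rows.append(child)
            G = GenotypeMatrix(snp_ids=np.array([f"s{i}" for i in range(m)]),
                               chrom=np.repeat("1", m),
                               pos=np.arange(1, m + 1) * 1000,
                               dosages=np.array(rows),
                               samples=[f"a{i}" for i in range(fam * size)])
            K = compute_kinship(G)
            y = r.normal(size=fam * size)  # independent of K
            null = emma_null(y, np.ones((fam * size, 1)), K)
            frac = null.sigma2_g / (null.sigma2_g + null.sigma2_e)
            hits += frac < 0.1
        assert hits >= 18

    def test_identity_kinship_recovers_total_variance(self):
        for seed in range(5):
            r = np.random.default_rng(seed)
            n = 80
            y = r.normal(0, 2.0, n)
            null = emma_null(y, np.ones((n, 1)), np.eye(n))
            total = null.sigma2_g + null.sigma2_e
            assert total == pytest.approx(np.var(y, ddof=1), rel=0.10)

    def test_nan_phenotype_rejected(self, rng):
        G = _toy_genotypes(rng, n=20)
        y = np.ones(20)
        y[3] = np.nan
        with pytest.raises(ValueError):
            emma_null(y, np.ones((20, 1)), compute_kinship(G))


class TestSnpScan:
    def test_null_calibration_pooled(self):
        # permuted phenotypes: p<0.05 fraction near nominal
        fracs = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            G = _toy_genotypes(r, n=100, m=500)
            K = compute_kinship(G)
            y = r.normal(size=100)
            res = snp_scan(y, np.ones((100, 1)), G, K)
            p = res["p"].dropna()
            fracs.append((p < 0.05).mean())
        assert np.mean(fracs) == pytest.approx(0.05, abs=0.02)

    def test_causal_snp_ranks_high(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            n = 300
            G = _toy_genotypes(r, n=n, m=400)
            K = compute_kinship(G)
            g = np.nan_to_num(G.dosages[:, 37])
            beta = np.sqrt(0.15 / 0.85) / max(np.std(g), 1e-9)
            y = beta * g + r.normal(0, 1, n)  # SNP explains ~15% of variance
            res = snp_scan(y, np.ones((n, 1)), G, K)
            rank = (res["p"] < res["p"][37]).sum()
            hits += rank < 10
        assert hits >= 16

    def test_monomorphic_snp_excluded(self, rng):
        G = _toy_genotypes(rng, n=50)
        G.dosages[:, 5] = 2.0
        res = snp_scan(rng.normal(size=50), np.ones((50, 1)), G)
        assert np.isnan(res["p"][5])

    def test_invariance_to_phenotype_location_scale(self, rng):
        G = _toy_genotypes(rng, n=60, m=200)
        K = compute_kinship(G)
        y = rng.normal(size=60)
        p1 = snp_scan(y, np.ones((60, 1)), G, K)["p"]
        p2 = snp_scan(5 * y - 3, np.ones((60, 1)), G, K)["p"]
        assert np.allclose(p1.dropna(), p2.dropna(), rtol=1e-6)

    def test_invariance_to_kinship_rescaling(self, rng):
        G = _toy_genotypes(rng, n=60, m=200)
        K = compute_kinship(G)
        y = K @ rng.normal(size=60) + rng.normal(size=60)
        p1 = snp_scan(y, np.ones((60, 1)), G, K)["p"]
        p2 = snp_scan(y, np.ones((60, 1)), G, 3.7 * K)["p"]
        assert np.allclose(p1.dropna(), p2.dropna(), rtol=1e-4)

    def test_exact_mode_agrees_with_p3d_at_desk_scale(self, rng):
        G = _toy_genotypes(rng, n=60, m=40)
        K = compute_kinship(G)
        y = np.nan_to_num(G.dosages[:, 7]) * 0.5 + rng.normal(size=60)
        p3d = snp_scan(y, np.ones((60, 1)), G, K, method="p3d")
        exact = snp_scan(y, np.ones((60, 1)), G, K, method="exact")
        ok = p3d["p"].notna() & exact["p"].notna()
        lp1 = -np.log10(p3d.loc[ok, "p"])
        lp2 = -np.log10(exact.loc[ok, "p"])
        assert np.corrcoef(lp1, lp2)[0, 1] > 0.99


class TestBH:
    @pytest.mark.parametrize("p,expected", [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.5], [0.5]),
        ([0.005, 0.04, 0.05], [0.015, 0.05, 0.05]),
    ])
    def test_hand_computed_step_up(self, p, expected):
        assert np.allclose(bh_adjust(p), expected)

    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=100))
    def test_matches_independent_implementation(self, p):
        from statsmodels.stats.multitest import multipletests
        ours = bh_adjust(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, ref, atol=1e-12)

    def test_nan_passthrough(self):
        out = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1]) and np.isfinite(out[0])


def _assoc(rows):
    return pd.DataFrame(rows, columns=["snp", "chrom", "pos", "p", "maf", "effect"])


class TestCallQtls:
    def test_seed_plus_support_pair_is_one_qtl(self):
        res = _assoc([("a", "1", 100_000, 5e-5, 0.2, 1.0),
                      ("b", "1", 250_000, 5e-4, 0.3, 0.5)])
        (q,) = call_qtls(res)
        assert q.top_snp == "a" and q.n_members == 2
        assert q.window == (1, 300_000)

    def test_lone_significant_snp_is_not_a_qtl(self):
        res = _assoc([("a", "1", 100_000, 1e-6, 0.3, 1.0)])
        assert call_qtls(res) == []

    def test_low_maf_seed_disqualified(self):
        res = _assoc([("a", "1", 100_000, 5e-5, 0.03, 1.0),
                      ("b", "1", 250_000, 5e-4, 0.3, 0.5)])
        assert call_qtls(res) == []

    def test_gap_over_window_splits_clusters(self):
        res = _assoc([("a", "1", 100_000, 5e-5, 0.2, 1.0),
                      ("b", "1", 250_000, 5e-4, 0.3, 0.5),
                      ("c", "1", 600_000, 5e-5, 0.2, 1.0),
                      ("d", "1", 700_000, 5e-4, 0.3, 0.5)])
        qtls = call_qtls(res)
        assert len(qtls) == 2

    def test_top_snp_tie_broken_by_position(self):
        res = _assoc([("b", "1", 250_000, 5e-5, 0.3, 1.0),
                      ("a", "1", 100_000, 5e-5, 0.2, 1.0)])
        (q,) = call_qtls(res)
        assert q.top_pos == 100_000

    def test_window_clipped_at_one(self):
        res = _assoc([("a", "1", 50_000, 5e-5, 0.2, 1.0),
                      ("b", "1", 150_000, 5e-4, 0.3, 0.5)])
        (q,) = call_qtls(res)
        assert q.window[0] == 1

    def test_order_invariance_and_idempotence(self, rng):
        rows = [(f"s{i}", str(1 + i % 3), int(p), float(pv), 0.2, 1.0)
                for i, (p, pv) in enumerate(zip(
                    rng.integers(1, 5_000_000, 60),
                    10 ** rng.uniform(-8, -2.5, 60)))]
        res = _assoc(rows)
        q1 = gwas.qtls_to_frame(call_qtls(res))
        q2 = gwas.qtls_to_frame(call_qtls(res.sample(frac=1, random_state=1)))
        pd.testing.assert_frame_equal(q1, q2)

    def test_member_span_and_separation(self, rng):
        rows = [(f"s{i}", "1", int(p), float(pv), 0.2, 1.0)
                for i, (p, pv) in enumerate(zip(
                    sorted(rng.integers(1, 10_000_000, 80)),
                    10 ** rng.uniform(-8, -2.5, 80)))]
        qtls = call_qtls(_assoc(rows))
        for q in qtls:
            span = q.members["pos"].max() - q.members["pos"].min()
            assert span <= (q.n_members - 1) * 200_000
        for i in range(len(qtls)):
            for j in range(i + 1, len(qtls)):
                gap = min(abs(a - b) for a in qtls[i].members["pos"]
                          for b in qtls[j].members["pos"])
                assert gap > 200_000

    def test_cluster_positions_single_linkage(self):
        clusters = cluster_positions([100, 150_000, 300_000, 900_000], 200_000)
        sizes = sorted(len(c) for c in clusters)
        assert sizes == [1, 3]


class TestGenotypeIO:
    def test_tsv_roundtrip(self, rng, tmp_path):
        G = _toy_genotypes(rng, n=10, m=32)
        G.dosages[0, 0] = np.nan
        path = tmp_path / "geno.tsv"
        G.to_tsv(path)
        back = gwas.read_genotype_tsv(path)
        assert back.samples == G.samples
        assert np.allclose(back.dosages, G.dosages, equal_nan=True)

    def test_vcf_read(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC\n"
            "1\t100\trs1\tA\tT\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
            "1\t200\trs2\tG\tC\t.\t.\t.\tGT\t./.\t0/0\t1/1\n")
        G = gwas.read_vcf(vcf)
        assert G.samples == ["A", "B", "C"]
        assert np.allclose(G.dosages[:, 0], [0, 1, 2])
        assert np.isnan(G.dosages[0, 1]) and G.dosages[2, 1] == 2
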