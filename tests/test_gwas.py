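"""Mixed-model scan, SUPER, thresholds, flanking genes, regions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import supergs as sg


@pytest.fixture(scope="module")
def scan_data():
    """Structured panel with a sparse simulated trait and its kinship."""
    gm, _, _ = sg.simulate_genotypes(
        n=150, m=1000, K=2, alpha_admix=0.2, fst=0.2, seed=20
    )
    rng = np.random.default_rng(21)
    X = gm.dosages()
    Xc = X - X.mean(axis=0)
    causal = np.sort(rng.choice(1000, 5, replace=False))
    g = Xc[:, causal] @ rng.normal(0, 1, 5)
    g = g / g.std()
    y = pd.Series(g + rng.normal(0, 1.5, 150), index=gm.samples)
    km = sg.vanraden_kinship(gm)
    return gm, y, km, causal


class TestEmmaReml:
    def test_identity_kinship_total_variance(self):
        rng = np.random.default_rng(0)
        y = rng.normal(0, 2.0, 300)
        res = sg.emma_reml(y, np.ones((300, 1)), np.eye(300))
        total = res.sigma2_g + res.sigma2_e
        assert total == pytest.approx(y.var() * 300 / 299, rel=0.05)

    def test_variance_recovery_on_random_psd_kinship(self):
        rng = np.random.default_rng(1)
        n = 400
        A = rng.normal(size=(n, 2 * n))
        K = A @ A.T / (2 * n)
        S, U = np.linalg.eigh(K)
        est = []
        for s in range(15):
            rng_s = np.random.default_rng(100 + s)
            u = U @ (np.sqrt(np.clip(S, 0, None)) * rng_s.normal(size=n))
            y = np.sqrt(2.0) * u + rng_s.normal(0, 1.0, n)
            res = sg.emma_reml(y, np.ones((n, 1)), K)
            est.append([res.sigma2_g, res.sigma2_e])
        mean = np.mean(est, axis=0)
        np.testing.assert_allclose(mean, [2.0, 1.0], rtol=0.15)

    def test_no_grid_point_beats_optimum(self, scan_data):
        gm, y, km, _ = scan_data
        yv = y.to_numpy()
        n = len(yv)
        X = np.ones((n, 1))
        res = sg.emma_reml(yv, X, km.G)
        # dense grid over log delta: the optimiser's likelihood must dominate
        S, U = res.S, res.U
        yt = U.T @ yv
        Xt = U.T @ X

        def neg2(ld):
            D = S + np.exp(ld)
            w = 1.0 / D
            A = (Xt * w[:, None]).T @ Xt
            b = (Xt * w[:, None]).T @ yt
            beta = np.linalg.solve(A, b)
            rss = float(yt @ (w * yt) - b @ beta)
            return (n - 1) * np.log(rss / (n - 1)) + np.log(D).sum() + np.linalg.slogdet(A)[1]

        grid = np.linspace(-12, 12, 1000)
        best_grid = min(neg2(g) for g in grid)
        opt = neg2(np.log(res.delta))
        assert opt <= best_grid + 1e-6

    def test_constant_y_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            sg.emma_reml(np.ones(50), np.ones((50, 1)), np.eye(50))


class TestMlmScan:
    def test_zero_kinship_matches_ols(self, scan_data):
        gm, y, _, _ = scan_data
        scan = sg.mlm_scan(y, gm, None)
        X = gm.dosages()
        Xc = X - X.mean(axis=0)
        rng = np.random.default_rng(2)
        for j in rng.choice(gm.n_markers, 25, replace=False):
            if not scan.table["tested"][j]:
                continue
            res = stats.linregress(Xc[:, j], y.to_numpy())
            assert scan.table["p"][j] == pytest.approx(res.pvalue, abs=1e-8)
            assert scan.table["effect"][j] == pytest.approx(res.slope, abs=1e-8)

    def test_large_effect_qtl_is_top_hit(self):
        hits = 0
        for s in range(10):
            gm, _, _ = sg.simulate_genotypes(n=150, m=500, K=1, seed=300 + s)
            rng = np.random.default_rng(400 + s)
            X = gm.dosages()
            j_star = int(rng.integers(0, 500))
            x = X[:, j_star] - X[:, j_star].mean()
            if x.std() == 0:
                continue
            y = pd.Series(
                2.0 * x / x.std() + rng.normal(0, 1.0, 150), index=gm.samples
            )
            km = sg.vanraden_kinship(gm)
            scan = sg.mlm_scan(y, gm, km)
            p = scan.table["p"].to_numpy()
            top = np.nanargmin(p)
            r2_top = sg.pairwise_r2(X[:, [top, j_star]])[0, 1]
            hits += (top == j_star) or (r2_top > 0.8)
        assert hits >= 9

    def test_pvalues_invariant_to_marker_permutation(self, scan_data):
        gm, y, km, _ = scan_data
        scan = sg.mlm_scan(y, gm, km)
        rng = np.random.default_rng(3)
        # permute by chromosome-preserving reordering is not possible for
        # arbitrary permutations (positions must stay sorted), so compare a
        # marker-subset scan against the full scan instead
        keep = np.sort(rng.choice(gm.n_markers, 400, replace=False))
        scan_sub = sg.mlm_scan(y, gm.subset(marker_idx=keep), km)
        np.testing.assert_allclose(
            scan_sub.table["p"].to_numpy(),
            scan.table["p"].to_numpy()[keep],
            atol=1e-10,
        )

    def test_p3d_off_agrees_on_null_markers(self, scan_data):
        gm, y, km, _ = scan_data
        sub = gm.subset(marker_idx=np.arange(0, 1000, 5))
        fast = sg.mlm_scan(y, sub, km, p3d=True)
        slow = sg.mlm_scan(y, sub, km, p3d=False)
        lp_f = -np.log10(fast.table["p"].to_numpy(dtype=float))
        lp_s = -np.log10(slow.table["p"].to_numpy(dtype=float))
        ok = np.isfinite(lp_f) & np.isfinite(lp_s)
        assert np.median(np.abs(lp_f[ok] - lp_s[ok])) < 0.2

    def test_sparse_marker_flagged_untested(self, scan_data):
        gm, y, km, _ = scan_data
        calls = gm.calls.copy()
        calls[:-3, 0] = -1  # only 3 non-missing calls at marker 0
        gm2 = sg.GenotypeMatrix(samples=gm.samples, markers=gm.markers, calls=calls)
        scan = sg.mlm_scan(y, gm2, km)
        assert not scan.table["tested"][0]
        assert np.isnan(scan.table["p"][0])


class TestSuper:
    def test_identical_pseudo_qtn_excluded(self, scan_data):
        gm, y, km, _ = scan_data
        scan = sg.mlm_scan(y, gm, km)
        qtns = sg.select_pseudo_qtns(scan, gm, y, n_bins=20, n_qtn_max=10)
        result = sg.super_scan(y, gm, qtns, ld_exclude_r2=0.1)
        # a pseudo-QTN tested against itself has r²=1 with itself, so its own
        # kinship omits it: its p-value must not be degenerate at ~0
        for j in qtns.indices:
            if result.table["tested"][j]:
                assert result.table["p"][j] > 1e-300

    def test_degenerate_setting_reproduces_mlm(self, scan_data):
        gm, y, km, _ = scan_data
        mlm = sg.mlm_scan(y, gm, km)
        all_qtns = sg.PseudoQTNSet(
            indices=np.arange(gm.n_markers), n_bins=1, bin_count=1, loglik=0.0
        )
        sup = sg.super_scan(y, gm, all_qtns, ld_exclude_r2=1.0)
        a = mlm.table["p"].to_numpy(dtype=float)
        b = sup.table["p"].to_numpy(dtype=float)
        ok = np.isfinite(a) & np.isfinite(b)
        np.testing.assert_allclose(b[ok], a[ok], atol=1e-6)

    def test_super_gains_power_at_causal_markers(self):
        gains = []
        for s in range(12):
            gm, _, _ = sg.simulate_genotypes(n=150, m=800, K=1, seed=600 + s)
            rng = np.random.default_rng(700 + s)
            X = gm.dosages()
            Xc = X - X.mean(axis=0)
            causal = np.sort(rng.choice(800, 5, replace=False))
            g = Xc[:, causal] @ rng.normal(0, 1, 5)
            g = g / g.std()
            y = pd.Series(g + rng.normal(0, 1.2, 150), index=gm.samples)
            km = sg.vanraden_kinship(gm)
            mlm = sg.mlm_scan(y, gm, km)
            qtns = sg.select_pseudo_qtns(mlm, gm, y, n_bins=40, n_qtn_max=15)
            sup = sg.super_scan(y, gm, qtns, ld_exclude_r2=0.1)
            lp_m = -np.log10(mlm.table["p"].to_numpy(dtype=float)[causal])
            lp_s = -np.log10(sup.table["p"].to_numpy(dtype=float)[causal])
            gains.append(np.nanmedian(lp_s) - np.nanmedian(lp_m))
        assert np.median(gains) > 0

    def test_planted_qtl_selected_first(self):
        gm, _, _ = sg.simulate_genotypes(n=120, m=400, K=1, rho_ld=1e-3, seed=30)
        rng = np.random.default_rng(31)
        X = gm.dosages()
        x = X[:, 200] - X[:, 200].mean()
        y = pd.Series(3.0 * x / x.std() + rng.normal(0, 1, 120), index=gm.samples)
        km = sg.vanraden_kinship(gm)
        scan = sg.mlm_scan(y, gm, km)
        qtns = sg.select_pseudo_qtns(scan, gm, y, n_bins=50, n_qtn_max=10)
        p = scan.table["p"].to_numpy()
        assert np.nanargmin(p) in qtns.indices

    def test_single_bin_gives_single_global_minimum(self, scan_data):
        gm, y, km, _ = scan_data
        scan = sg.mlm_scan(y, gm, km)
        qtns = sg.select_pseudo_qtns(scan, gm, y, n_bins=1, n_qtn_max=10)
        assert len(qtns.indices) == 1
        p = scan.table["p"].to_numpy(dtype=float)
        assert qtns.indices[0] == np.nanargmin(p)

    def test_selection_deterministic(self, scan_data):
        gm, y, km, _ = scan_data
        scan = sg.mlm_scan(y, gm, km)
        a = sg.select_pseudo_qtns(scan, gm, y, n_bins=30, n_qtn_max=10)
        b = sg.select_pseudo_qtns(scan, gm, y, n_bins=30, n_qtn_max=10)
        np.testing.assert_array_equal(a.indices, b.indices)


class TestBonferroni:
    def test_study_scale_threshold(self):
        cut = sg.bonferroni_threshold(0.05, 144_777)
        assert cut == pytest.approx(3.45e-07, rel=5e-3)

    @pytest.mark.parametrize("alpha,m,expected", [(0.05, 1, 0.05), (0.05, 100, 5e-4)])
    def test_simple_cases(self, alpha, m, expected):
        assert sg.bonferroni_threshold(alpha, m) == pytest.approx(expected)

    def test_product_recovers_alpha(self):
        for m in (3, 7, 144_777):
            assert sg.bonferroni_threshold(0.05, m) * m == pytest.approx(0.05, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sg.bonferroni_threshold(0.0, 10)
        with pytest.raises(ValueError):
            sg.bonferroni_threshold(0.05, 0)


class TestFlankingGenes:
    def _genes(self):
        return [
            sg.GeneModel(chrom="c1", start=1_000, end=1_900, strand="+", gene_id="gL"),
            sg.GeneModel(chrom="c1", start=12_000, end=13_000, strand="+", gene_id="gR"),
            sg.GeneModel(chrom="c1", start=20_000, end=25_000, strand="-", gene_id="gC"),
        ]

    def test_left_right_with_distances(self):
        fl = sg.flanking_genes(("c1", 2_000), self._genes())
        assert fl.left.gene_id == "gL" and fl.right.gene_id == "gR"
        assert fl.left_dist == 100 and fl.right_dist == 10_000
        assert fl.containing is None

    def test_containing_gene_flagged(self):
        fl = sg.flanking_genes(("c1", 22_000), self._genes())
        assert fl.containing.gene_id == "gC"
        assert fl.left.gene_id == "gR"
        assert fl.right is None

    def test_matches_linear_scan_oracle(self):
        rng = np.random.default_rng(8)
        genes = []
        start = 100
        for i in range(200):
            start += int(rng.integers(500, 3_000))
            end = start + int(rng.integers(100, 400))
            genes.append(
                sg.GeneModel(chrom="c1", start=start, end=end, strand="+", gene_id=f"g{i}")
            )
            start = end
        for pos in rng.integers(1, genes[-1].end + 5_000, size=300):
            pos = int(pos)
            fl = sg.flanking_genes(("c1", pos), genes)
            lefts = [g for g in genes if g.end < pos]
            rights = [g for g in genes if g.start > pos]
            contain = [g for g in genes if g.start <= pos <= g.end]
            assert (fl.left.gene_id if fl.left else None) == (
                max(lefts, key=lambda g: g.end).gene_id if lefts else None
            )
            assert (fl.right.gene_id if fl.right else None) == (
                min(rights, key=lambda g: g.start).gene_id if rights else None
            )
            assert (fl.containing.gene_id if fl.containing else None) == (
                contain[0].gene_id if contain else None
            )

    def test_absent_chromosome_rejected(self):
        with pytest.raises(KeyError):
            sg.flanking_genes(("c9", 100), self._genes())


class TestRegions:
    def test_chickpea_region_widths(self):
        snps = pd.DataFrame(
            {
                "chrom": ["Ca4", "Ca4", "Ca5", "Ca5"],
                "pos": [35_589_599, 36_026_910, 11_580_061, 12_166_907],
                "trait": ["EM", "100SW", "100SW", "MA"],
                "p": [1e-8, 1e-8, 1e-8, 1e-8],
            }
        )
        regions = sg.pleiotropic_regions(snps, merge_dist_bp=1_000_000)
        widths = {r.chrom: r.width_bp for r in regions}
        assert widths["Ca4"] == 437_311
        assert widths["Ca5"] == 586_846
        assert all(r.pleiotropic for r in regions)

    def test_single_snp_zero_width(self):
        snps = pd.DataFrame(
            {"chrom": ["c1"], "pos": [500], "trait": ["t"], "p": [1e-9]}
        )
        (region,) = sg.pleiotropic_regions(snps, merge_dist_bp=1_000)
        assert region.width_bp == 0
        assert not region.pleiotropic

    def test_merge_distance_splits_regions(self):
        snps = pd.DataFrame(
            {
                "chrom": ["c1"] * 3,
                "pos": [1_000, 1_500, 100_000],
                "trait": ["a", "b", "a"],
                "p": [1e-9] * 3,
            }
        )
        regions = sg.pleiotropic_regions(snps, merge_dist_bp=10_000)
        assert len(regions) == 2
        assert regions[0].pleiotropic and not regions[1].pleiotropic
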