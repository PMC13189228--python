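"""Polygenic tests: LD stats, clumping, PGS, gamma LMM, sign-flip."""

import numpy as np
import pandas as pd
import pytest

from paleoselect import polygenic as pg
from paleoselect import simulate as sim
from paleoselect import structure
from paleoselect.cohort_io import CohortGenotypes, GwasSummary, align_gwas, to_time
from paleoselect.polygenic import (
    GammaLmm,
    SnpSet,
    compute_pgs,
    drop_priority,
    fit_gamma,
    ld_stats,
    polygenic_test,
    signflip_inflation,
    two_step_clump,
    windowed_gamma,
)


class TestLdStats:
    def test_complete_ld(self):
        rng = np.random.default_rng(0)
        h = (rng.random(400) < 0.3).astype(float)
        H = np.column_stack([h, h])
        g = H[0::2] + H[1::2]
        r2, dp = ld_stats(g, 0, 1)
        assert r2 == pytest.approx(1.0, abs=1e-9)
        assert dp == pytest.approx(1.0, abs=1e-6)

    def test_independent_pair(self):
        rng = np.random.default_rng(1)
        g = np.column_stack([rng.binomial(2, 0.4, 10000),
                             rng.binomial(2, 0.3, 10000)]).astype(float)
        r2, dp = ld_stats(g, 0, 1)
        assert r2 < 0.01

    def test_hand_haplotype_example(self):
        # AB=40, Ab=10, aB=10, ab=40 -> D' = 0.6, r2 = 0.36
        hap = np.zeros((100, 2))
        hap[:40] = [1, 1]
        hap[40:50] = [1, 0]
        hap[50:60] = [0, 1]
        r2, dp = ld_stats(None, 0, 1, haplotypes=hap)
        assert dp == pytest.approx(0.6)
        assert r2 == pytest.approx(0.36)

    def test_em_agrees_with_phased_truth(self):
        hap = np.zeros((200, 2))
        hap[:80] = [1, 1]
        hap[80:100] = [1, 0]
        hap[100:120] = [0, 1]
        rng = np.random.default_rng(2)
        perm = rng.permutation(200)
        hap = hap[perm]
        g = hap[0::2] + hap[1::2]
        r2_em, dp_em = ld_stats(g, 0, 1)
        assert dp_em == pytest.approx(0.6, abs=0.08)

    def test_monomorphic_errors(self):
        g = np.column_stack([np.ones(50) * 2, np.random.default_rng(3).binomial(2, 0.5, 50)]).astype(float)
        with pytest.raises(ValueError, match="monomorphic"):
            ld_stats(g, 0, 1)


def _gwas(rows):
    return GwasSummary(pd.DataFrame(
        rows, columns=["id", "chrom", "pos", "effect_allele", "other_allele",
                       "beta", "se", "p"]))


def _panel_with_ld(rng, n, layout):
    """Build dosage columns: layout entries are ('free', f) or ('copy', j, fidelity)."""
    haps = []
    for entry in layout:
        if entry[0] == "free":
            haps.append((rng.random(2 * n) < entry[1]).astype(float))
        else:
            src = haps[entry[1]]
            keep = rng.random(2 * n) < entry[2]
            haps.append(np.where(keep, src, (rng.random(2 * n) < 0.4)).astype(float))
    H = np.column_stack(haps)
    return H[0::2] + H[1::2]


class TestTwoStepClump:
    def test_single_snp_retained(self):
        rng = np.random.default_rng(4)
        panel = _panel_with_ld(rng, 200, [("free", 0.4)])
        gwas = _gwas([("v0", "1", 1000, "G", "A", 0.2, 0.05, 1e-4)])
        out = two_step_clump(gwas, panel)
        assert len(out) == 1

    def test_ld_pair_keeps_smaller_p(self):
        rng = np.random.default_rng(5)
        panel = _panel_with_ld(rng, 400, [("free", 0.4), ("copy", 0, 0.97)])
        gwas = _gwas([
            ("v0", "1", 100_000, "G", "A", 0.2, 0.05, 1e-6),
            ("v1", "1", 200_000, "G", "A", 0.3, 0.05, 1e-4),
        ])
        out = two_step_clump(gwas, panel)
        assert out.table["id"].tolist() == ["v0"]

    def test_p_threshold_filters(self):
        rng = np.random.default_rng(6)
        panel = _panel_with_ld(rng, 200, [("free", 0.4), ("free", 0.3)])
        gwas = _gwas([
            ("v0", "1", 1000, "G", "A", 0.2, 0.05, 0.5),
            ("v1", "1", 900_000, "G", "A", 0.3, 0.05, 1e-5),
        ])
        out = two_step_clump(gwas, panel)
        assert out.table["id"].tolist() == ["v1"]

    def test_matches_brute_force_on_six_snps(self):
        rng = np.random.default_rng(7)
        panel = _panel_with_ld(rng, 500, [
            ("free", 0.5), ("copy", 0, 0.98), ("free", 0.3),
            ("copy", 2, 0.9), ("free", 0.25), ("copy", 4, 0.7),
        ])
        pos = [100_000, 150_000, 300_000, 360_000, 1_000_000, 1_050_000]
        ps = [1e-6, 1e-4, 1e-5, 1e-7, 1e-4, 1e-5]
        gwas = _gwas([(f"v{i}", "1", pos[i], "G", "A", 0.1, 0.05, ps[i])
                      for i in range(6)])
        out = two_step_clump(gwas, panel)

        # brute force: step 1 greedy r2 clump, step 2 greedy D' prune
        def pair(i, j):
            return ld_stats(panel, i, j)

        def greedy(idx, check):
            idx = sorted(idx, key=lambda k: ps[k])
            alive, kept = set(idx), []
            for k in idx:
                if k not in alive:
                    continue
                kept.append(k)
                alive.discard(k)
                for m in list(alive):
                    if abs(pos[m] - pos[k]) <= 500_000 and check(*pair(k, m)):
                        alive.discard(m)
            return kept

        s1 = greedy(range(6), lambda r2, dp: r2 >= 0.05)
        s2 = greedy(s1, lambda r2, dp: dp > 0.2)
        assert sorted(out.table["id"]) == sorted(f"v{k}" for k in s2)

    def test_output_satisfies_invariant(self):
        rng = np.random.default_rng(8)
        panel = _panel_with_ld(rng, 500, [("free", 0.4)] * 4 + [("copy", 0, 0.85)])
        pos = [10_000, 60_000, 110_000, 400_000, 15_000]
        gwas = _gwas([(f"v{i}", "1", pos[i], "G", "A", 0.1, 0.05, 10 ** -(4 + i))
                      for i in range(5)])
        out = two_step_clump(gwas, panel)
        idx = {r["id"]: i for i, r in gwas.table.iterrows()}
        kept = [idx[i] for i in out.table["id"]]
        for a in kept:
            for b in kept:
                if a < b and abs(pos[a] - pos[b]) <= 500_000:
                    r2, dp = ld_stats(panel, a, b)
                    assert r2 < 0.05 and dp <= 0.2 + 1e-9

    def test_empty_below_threshold_warns(self):
        rng = np.random.default_rng(9)
        panel = _panel_with_ld(rng, 100, [("free", 0.4)])
        gwas = _gwas([("v0", "1", 1000, "G", "A", 0.2, 0.05, 0.9)])
        out = two_step_clump(gwas, panel)
        assert len(out) == 0


def _snpset(cohort, cols, betas, ps=None):
    tab = cohort.variants.iloc[cols][["chrom", "pos"]].copy()
    tab["id"] = [f"v{c}" for c in cols]
    tab["beta"] = betas
    tab["se"] = 0.05
    tab["p"] = ps if ps is not None else 1e-5
    tab["cohort_index"] = cols
    return SnpSet(tab.reset_index(drop=True), 1e-3, 0.05, 0.2, 500)


class TestComputePgs:
    def test_direct_weighted_sum(self, small_cohort):
        ss = _snpset(small_cohort, [0, 1, 2], [0.5, -1.0, 2.0])
        pgs = compute_pgs(small_cohort, ss, mode="beta")
        G = np.nan_to_num(small_cohort.G[:, :3])
        expected0 = G[0] @ np.array([0.5, -1.0, 2.0])
        assert pgs.raw[0] == pytest.approx(expected0)

    def test_zero_weights(self, small_cohort):
        ss = _snpset(small_cohort, [0, 1], [0.3, 0.4])
        pgs = compute_pgs(small_cohort, ss, weights=np.zeros(2))
        np.testing.assert_array_equal(pgs.raw, 0)

    def test_modern_scaling_invariant(self, small_cohort):
        ss = _snpset(small_cohort, [0, 1, 2], [1.0, 0.5, -0.2])
        pgs = compute_pgs(small_cohort, ss, mode="beta")
        modern = small_cohort.samples["is_modern"].to_numpy()
        assert pgs.scaled[modern].mean() == pytest.approx(0.0, abs=1e-10)
        assert pgs.scaled[modern].std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_sign_mode(self, small_cohort):
        ss = _snpset(small_cohort, [0, 1], [0.3, -0.4])
        np.testing.assert_array_equal(ss.weights("sign"), [1.0, -1.0])

    def test_no_modern_samples_errors(self, small_cohort):
        ancient = ~small_cohort.samples["is_modern"].to_numpy()
        sub = small_cohort.subset_samples(ancient)
        ss = _snpset(sub, [0, 1], [0.3, 0.4])
        with pytest.raises(ValueError, match="modern"):
            compute_pgs(sub, ss)


class TestFitGamma:
    def test_constant_score_zero_slope(self, small_cohort, small_grm):
        ss = _snpset(small_cohort, [0], [1.0])
        pgs = compute_pgs(small_cohort, ss)
        pgs.scaled[:] = 0.0
        fit = fit_gamma(pgs, small_cohort.dates_bp, small_grm)
        assert fit.gamma_hat == pytest.approx(0.0, abs=1e-10)

    def test_ols_limit(self, small_cohort, small_grm):
        ss = _snpset(small_cohort, [0, 1, 2], [0.5, 1.0, -0.3])
        pgs = compute_pgs(small_cohort, ss)
        fit = fit_gamma(pgs, small_cohort.dates_bp, small_grm, fix_sigma_g2=0.0)
        t = to_time(small_cohort.dates_bp, convention="per_10ky")
        X = np.column_stack([np.ones(t.size), t])
        ols = np.linalg.lstsq(X, pgs.scaled, rcond=None)[0]
        assert fit.gamma_hat == pytest.approx(ols[1], abs=1e-6)

    def test_equivariance_date_shift_and_scale(self, small_cohort, small_grm):
        ss = _snpset(small_cohort, [0, 1, 2], [0.5, 1.0, -0.3])
        pgs = compute_pgs(small_cohort, ss)
        solver = GammaLmm(small_grm.A, to_time(small_cohort.dates_bp, convention="per_10ky"))
        g1, *_ = solver.fit(pgs.scaled)
        g2, *_ = solver.fit(2.5 * pgs.scaled)
        assert g2 == pytest.approx(2.5 * g1, rel=1e-6)
        # shifting all dates by a constant changes the intercept only
        shifted = to_time(small_cohort.dates_bp + 1000, convention="per_10ky")
        g3, *_ = GammaLmm(small_grm.A, shifted).fit(pgs.scaled)
        assert g3 == pytest.approx(g1, rel=1e-5)

    def test_constant_t_errors(self, small_grm):
        with pytest.raises(ValueError, match="constant"):
            GammaLmm(small_grm.A, np.zeros(small_grm.n))

    def test_injected_slope_recovery(self):
        """gamma recovered without bias under GRM-structured noise."""
        rng = np.random.default_rng(12)
        n = 150
        B = rng.normal(size=(n, 3))
        K = B @ B.T / 3 + np.eye(n)
        dates = np.concatenate([rng.uniform(500, 9500, n - 30), np.zeros(30)])
        t = -dates / 10000
        L = np.linalg.cholesky(K + 1e-8 * np.eye(n))
        solver = GammaLmm(K, t)
        gammas = []
        for _ in range(100):
            y = 1.0 * t + 0.4 * (L @ rng.standard_normal(n)) + rng.normal(0, 0.5, n)
            g, se, *_ = solver.fit(y)
            gammas.append(g)
        gammas = np.asarray(gammas)
        sem = gammas.std(ddof=1) / 10
        assert abs(gammas.mean() - 1.0) < 2.5 * sem


class TestSignflip:
    def test_lambda_bounds_and_determinism(self, small_cohort, small_grm):
        ss = _snpset(small_cohort, list(range(10)), np.linspace(-1, 1, 10))
        lam1 = signflip_inflation(ss, small_cohort, small_grm, n_rand=20, seed=3)
        lam2 = signflip_inflation(ss, small_cohort, small_grm, n_rand=20, seed=3)
        assert lam1 == lam2
        assert 1.0 <= lam1 <= pg.DEFAULT_LAMBDA_CAP

    def test_clamps(self):
        # the clip rule itself
        assert np.clip(0.1 / pg.CHI2_1_MEDIAN, 1, 3.16) == 1.0
        assert np.clip(10 / pg.CHI2_1_MEDIAN, 1, 3.16) == 3.16
        assert np.clip(0.455 / pg.CHI2_1_MEDIAN, 1, 3.16) == 1.0

    def test_iid_null_lambda_near_one(self):
        """With i.i.d. genotypes, no structure, and enough SNPs that the
        mean per-SNP trend chi-square concentrates at 1, lambda -> 1."""
        rng = np.random.default_rng(13)
        n = 300
        m = 200
        dates = np.concatenate([rng.uniform(500, 9000, n - 20), np.zeros(20)])
        G = rng.binomial(2, 0.4, size=(n, m)).astype(float)
        variants = pd.DataFrame({"chrom": "1", "pos": np.arange(1, m + 1) * 1000,
                                 "ref": "A", "alt": "G"})
        samples = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)],
                                "date_bp": dates, "is_modern": dates == 0})
        cohort = CohortGenotypes(G, variants, samples)
        grm = structure.Grm(np.eye(n), list(samples["sample_id"]), M=m)
        ss = _snpset(cohort, list(range(m)), rng.normal(0, 0.1, m))
        lam = signflip_inflation(ss, cohort, grm, n_rand=500, seed=1)
        assert lam <= 1.15


class TestPolygenicTest:
    @pytest.fixture(scope="class")
    def trend_setup(self):
        """Cohort whose causal alleles all drift upward through time,
        embedded among neutral background variants; the GRM comes from
        the background only (as with a genome-wide GRM), so the random
        effect cannot absorb the causal trend itself."""
        rng = np.random.default_rng(20)
        n, m, m_bg = 250, 30, 300
        dates = np.concatenate([rng.uniform(500, 9500, n - 40), np.zeros(40)])
        t = -dates / 10000
        f0 = rng.uniform(0.3, 0.7, m)
        slope = 1.2  # logit per 10 ky, shared orientation
        p = 1 / (1 + np.exp(-(np.log(f0 / (1 - f0))[None, :] + slope * t[:, None])))
        G_causal = rng.binomial(2, p).astype(float)
        G_bg = rng.binomial(2, rng.uniform(0.1, 0.9, m_bg), size=(n, m_bg)).astype(float)
        G = np.concatenate([G_causal, G_bg], axis=1)
        variants = pd.DataFrame({"chrom": "1",
                                 "pos": (np.arange(m + m_bg) * 2_000_000 + 1),
                                 "ref": "A", "alt": "G"})
        samples = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)],
                                "date_bp": dates, "is_modern": dates == 0})
        cohort = CohortGenotypes(G, variants, samples)
        grm = structure.compute_grm(cohort.subset_variants(np.arange(m, m + m_bg)))
        gwas = _gwas([(f"v{j}", "1", int(variants['pos'][j]), "G", "A",
                       abs(rng.normal(0.3, 0.05)), 0.05, 1e-5) for j in range(m)])
        return cohort, grm, gwas

    def test_trend_detected_both_modes_concordant(self, trend_setup):
        cohort, grm, gwas = trend_setup
        fits = polygenic_test(cohort, gwas, grm, n_rand=30, seed=2)
        assert set(fits) == {"beta", "sign"}
        # all true effects share orientation: both modes positive gamma
        assert fits["beta"].Z_adj > 2
        assert fits["sign"].Z_adj > 2
        assert np.sign(fits["beta"].Z_adj) == np.sign(fits["sign"].Z_adj)
        for f in fits.values():
            assert 1.0 <= f.lambda_inflation <= pg.DEFAULT_LAMBDA_CAP
            assert f.Z_adj == pytest.approx(f.Z_raw / np.sqrt(f.lambda_inflation))

    def test_exclusion_regions_honored(self, trend_setup):
        cohort, grm, gwas = trend_setup
        bed = pd.DataFrame({"chrom": ["1"], "start": [0], "end": [10**9]})
        with pytest.raises(ValueError, match="remain"):
            polygenic_test(cohort, gwas, grm, exclude_regions=bed, n_rand=10)

    def test_windowed_gamma_runs(self, trend_setup):
        cohort, grm, gwas = trend_setup
        aligned = align_gwas(gwas, cohort)
        panel = cohort.G[:, aligned.table["cohort_index"].to_numpy()]
        ss = two_step_clump(aligned, panel)
        pgs = compute_pgs(cohort, ss)
        series = windowed_gamma(pgs, cohort, grm, window_years=4000,
                                step_years=1000, min_people=50)
        assert len(series) >= 2
        assert "gamma_smoothed" in series.columns


class TestDropLoci:
    def test_priority_formula(self):
        p = drop_priority(np.array([0.0, 0.5]), np.array([0.02, 0.02]),
                          np.array([0.3, 0.3]))
        assert p[0] == 0.0
        assert p[1] == pytest.approx(abs(0.5 * 0.02 * 0.3 * 0.7))

    def test_single_locus_signal_dies_after_one_drop(self):
        """One strongly selected SNP among neutral ones: dropping its
        region kills the trait signal."""
        rng = np.random.default_rng(30)
        n, m = 220, 12
        dates = np.concatenate([rng.uniform(500, 9500, n - 30), np.zeros(30)])
        t = -dates / 10000
        p0 = np.full(m, 0.5)
        eta = np.log(p0 / (1 - p0))[None, :] + np.where(np.arange(m) == 0, 4.0, 0.0) * t[:, None]
        G = rng.binomial(2, 1 / (1 + np.exp(-eta))).astype(float)
        variants = pd.DataFrame({"chrom": "1", "pos": np.arange(m) * 3_000_000 + 1,
                                 "ref": "A", "alt": "G"})
        samples = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)],
                                "date_bp": dates, "is_modern": dates == 0})
        cohort = CohortGenotypes(G, variants, samples)
        grm = structure.Grm(np.eye(n), list(samples["sample_id"]), M=m)
        gwas = _gwas([(f"v{j}", "1", int(variants['pos'][j]), "G", "A",
                       1.0 if j == 0 else 0.05, 0.05, 1e-5) for j in range(m)])
        s_hat = np.where(np.arange(m) == 0, 0.05, 0.0)
        curve = pg.drop_loci_curve(gwas, cohort, grm, s_hat=s_hat,
                                   n_rand=10, p_stop=0.05, seed=4)
        assert len(curve) >= 1
        if curve["p"].iloc[0] < 0.05:  # signal present at n_dropped = 0
            assert curve["p"].iloc[-1] > 0.05
            assert len(curve) <= 3
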