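"""Trait-level (polygenic) selection tests.

A trait's polygenic score is PGS_i = sum_j w_j G_ij over an
approximately independent SNP set chosen by two-step clumping of the
trait's own GWAS (P < 1e-3; within 500 kb every retained pair has
r^2 < 0.05 and D' < 0.2). Scores are centered on the modern samples and
scaled by their standard deviation, then regressed on time with a
linear mixed model

    y_i = alpha + t_i * gamma + g_i + e_i,
    g ~ MVN(0, sigma_g^2 K),  e ~ MVN(0, sigma_e^2 I),

where t_i = -date_bp/10000, so gamma is the change of the score per ten
millennia in modern-SD units and K is the GRM. Weights are either the
GWAS betas or only their signs (robust to effect-size errors).

Because residual structure inflates Z_gamma, each trait gets a
sign-flip calibration: the PGS is recomputed with random +/-1 weights
(which should carry no temporal signal if the trait signal is truly
polygenic), and the inflation factor is the ratio of the median
randomized Z_gamma^2 to the chi-square(1) median 0.455, clamped to
[1, cap]. The adjusted statistic is Z_adj = Z_raw / sqrt(lambda).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from paleoselect.cohort_io import (
    CohortGenotypes,
    GwasSummary,
    TimeScale,
    align_gwas,
    to_time,
)
from paleoselect.structure import Grm

logger = logging.getLogger(__name__)

#: Median of the chi-square distribution with 1 df, at the printed
#: precision used to define the inflation factor.
CHI2_1_MEDIAN = 0.455

#: Default cap on the sign-flip inflation factor (an across-trait
#: median from a large real cohort; data-derived, hence configurable).
DEFAULT_LAMBDA_CAP = 3.16


# ---------------------------------------------------------------------------
# LD statistics
# ---------------------------------------------------------------------------


def _haplotype_dprime_r2(pAB: float, pA: float, pB: float) -> tuple[float, float]:
    D = pAB - pA * pB
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    dprime = abs(D) / dmax if dmax > 0 else 0.0
    denom = pA * (1 - pA) * pB * (1 - pB)
    r2 = D**2 / denom if denom > 0 else 0.0
    return float(np.clip(dprime, 0, 1)), float(np.clip(r2, 0, 1))


def _em_haplotype_freqs(ga: np.ndarray, gb: np.ndarray,
                        max_iter: int = 50, tol: float = 1e-8) -> tuple[float, float, float]:
    """EM estimate of the two-locus haplotype frequency p_AB from
    unphased hard-call dosages (only double heterozygotes are phase
    ambiguous)."""
    ok = np.isfinite(ga) & np.isfinite(gb)
    ga = np.rint(ga[ok]).astype(int)
    gb = np.rint(gb[ok]).astype(int)
    n = ga.size
    if n == 0:
        raise ValueError("no complete genotype pairs")
    pA = ga.mean() / 2.0
    pB = gb.mean() / 2.0
    dh = (ga == 1) & (gb == 1)
    n_dh = int(dh.sum())
    # AB haplotypes from phase-unambiguous pairs: outside the double het,
    # an individual with (ga, gb) carries min over the homozygous locus:
    # (2,2) -> 2; (2,1)/(1,2) -> 1; anything with a 0 -> 0.
    a_, b_ = ga[~dh], gb[~dh]
    n_AB_fixed = float(np.sum(np.where((a_ == 2) & (b_ == 2), 2,
                       np.where(((a_ == 2) & (b_ == 1)) | ((a_ == 1) & (b_ == 2)), 1, 0))))
    pAB = pA * pB
    for _ in range(max_iter):
        # E-step: among double hets, P(phase AB/ab) vs (Ab/aB)
        pAb = max(pA - pAB, 0.0)
        paB = max(pB - pAB, 0.0)
        pab = max(1 - pA - pB + pAB, 0.0)
        num = pAB * pab
        den = num + pAb * paB
        frac = num / den if den > 0 else 0.5
        pAB_new = (n_AB_fixed + n_dh * frac) / (2.0 * n)
        if abs(pAB_new - pAB) < tol:
            pAB = pAB_new
            break
        pAB = pAB_new
    return float(pAB), float(pA), float(pB)


def ld_stats(
    panel: np.ndarray,
    i: int,
    j: int,
    haplotypes: np.ndarray | None = None,
) -> tuple[float, float]:
    """(r^2, D') between two variants.

    With phased ``haplotypes`` (2n x variants, 0/1) both statistics come
    from directly counted haplotype frequencies; otherwise r^2 is the
    squared dosage correlation and D' is estimated by EM from genotypes.
    """
    if haplotypes is not None:
        ha = haplotypes[:, i].astype(float)
        hb = haplotypes[:, j].astype(float)
        ok = np.isfinite(ha) & np.isfinite(hb)
        ha, hb = ha[ok], hb[ok]
        pA, pB = ha.mean(), hb.mean()
        if pA in (0.0, 1.0) or pB in (0.0, 1.0):
            raise ValueError("monomorphic variant in panel")
        pAB = (ha * hb).mean()
        dprime, r2 = _haplotype_dprime_r2(pAB, pA, pB)
        return r2, dprime
    ga = np.asarray(panel[:, i], dtype=float)
    gb = np.asarray(panel[:, j], dtype=float)
    ok = np.isfinite(ga) & np.isfinite(gb)
    if np.nanstd(ga[ok]) == 0 or np.nanstd(gb[ok]) == 0:
        raise ValueError("monomorphic variant in panel")
    r = np.corrcoef(ga[ok], gb[ok])[0, 1]
    pAB, pA, pB = _em_haplotype_freqs(ga, gb)
    dprime, _ = _haplotype_dprime_r2(pAB, pA, pB)
    return float(r**2), dprime


# ---------------------------------------------------------------------------
# Clumping
# ---------------------------------------------------------------------------


@dataclass
class SnpSet:
    """Approximately independent trait SNPs with clumping provenance."""

    table: pd.DataFrame  # id, chrom, pos, beta, se, p [, cohort_index]
    p_threshold: float
    r2_threshold: float
    dprime_threshold: float
    window_kb: float

    def __len__(self) -> int:
        return len(self.table)

    def weights(self, mode: str) -> np.ndarray:
        beta = self.table["beta"].to_numpy(dtype=float)
        if mode == "beta":
            return beta
        if mode == "sign":
            return np.sign(beta)
        raise ValueError(f"unknown weighting mode {mode!r}")


def two_step_clump(
    gwas: GwasSummary,
    panel: np.ndarray,
    p_threshold: float = 1e-3,
    r2_threshold: float = 0.05,
    dprime_threshold: float = 0.2,
    window_kb: float = 500.0,
    haplotypes: np.ndarray | None = None,
) -> SnpSet:
    """Two-step clumping and thresholding of a GWAS.

    Step 1: greedy clumping by ascending P among P < threshold,
    excluding variants with r^2 >= r2_threshold within the window of a
    retained index SNP. Step 2: greedy D' pruning of the survivors
    (index = smallest P; remove D' > threshold within the window).
    ``panel`` columns align with GWAS rows. Ties broken by (chrom, pos).
    """
    t = gwas.table.reset_index(drop=True)
    cand = t.index[t["p"] < p_threshold].to_numpy()
    if cand.size == 0:
        logger.warning("no SNP below P < %g; empty set", p_threshold)
        return SnpSet(t.iloc[[]].copy(), p_threshold, r2_threshold,
                      dprime_threshold, window_kb)
    window_bp = window_kb * 1000.0
    chrom = t["chrom"].astype(str).to_numpy()
    pos = t["pos"].to_numpy(dtype=float)

    def greedy(indices: np.ndarray, prune_fn) -> list[int]:
        order = sorted(indices, key=lambda k: (t["p"].iloc[k], chrom[k], pos[k]))
        alive = set(order)
        kept: list[int] = []
        for k in order:
            if k not in alive:
                continue
            kept.append(k)
            alive.discard(k)
            near = [m for m in alive
                    if chrom[m] == chrom[k] and abs(pos[m] - pos[k]) <= window_bp]
            for m in near:
                if prune_fn(k, m):
                    alive.discard(m)
        return kept

    def r2_prune(k: int, m: int) -> bool:
        r2, _ = ld_stats(panel, k, m, haplotypes)
        return r2 >= r2_threshold

    def dprime_prune(k: int, m: int) -> bool:
        _, dp = ld_stats(panel, k, m, haplotypes)
        return dp > dprime_threshold

    step1 = greedy(cand, r2_prune)
    step2 = greedy(np.asarray(step1), dprime_prune)
    kept = sorted(step2, key=lambda k: (chrom[k], pos[k]))
    return SnpSet(t.iloc[kept].reset_index(drop=True), p_threshold,
                  r2_threshold, dprime_threshold, window_kb)


# ---------------------------------------------------------------------------
# Polygenic scores
# ---------------------------------------------------------------------------


@dataclass
class PgsResult:
    """Per-individual polygenic scores (raw, and scaled on moderns)."""

    raw: np.ndarray
    scaled: np.ndarray
    snpset: SnpSet
    mode: str

    @property
    def n_snps(self) -> int:
        return len(self.snpset)


def compute_pgs(
    cohort: CohortGenotypes,
    snpset: SnpSet,
    mode: str = "beta",
    weights: np.ndarray | None = None,
) -> PgsResult:
    """Polygenic score: weighted dosage sum over the SNP set.

    Missing dosages are replaced by the variant's modern-sample mean
    (overall mean if no modern sample has data). Scores are centered at
    the modern-sample mean and scaled by the modern-sample SD.
    """
    if len(snpset) == 0:
        raise ValueError("empty SNP set")
    if "cohort_index" not in snpset.table.columns:
        raise ValueError("SNP set lacks cohort_index; align the GWAS to the cohort first")
    idx = snpset.table["cohort_index"].to_numpy(dtype=int)
    w = snpset.weights(mode) if weights is None else np.asarray(weights, dtype=float)
    if w.size != idx.size:
        raise ValueError("weights length mismatch")
    modern = cohort.samples["is_modern"].astype(bool).to_numpy()
    if not modern.any():
        raise ValueError("no modern samples: cannot scale the PGS")
    G = cohort.G[:, idx]
    n_missing = int(np.isnan(G).sum())
    if n_missing:
        col_mod = np.nanmean(np.where(modern[:, None], G, np.nan), axis=0)
        col_all = np.nanmean(G, axis=0)
        fill = np.where(np.isfinite(col_mod), col_mod, col_all)
        G = np.where(np.isnan(G), fill, G)
        logger.info("imputed %d missing dosages with modern means", n_missing)
    raw = G @ w
    mu = raw[modern].mean()
    sd = raw[modern].std(ddof=1)
    if sd == 0:
        sd = 1.0
        logger.warning("modern PGS has zero spread; scaling by 1")
    return PgsResult(raw, (raw - mu) / sd, snpset, mode)


# ---------------------------------------------------------------------------
# The gamma LMM
# ---------------------------------------------------------------------------


@dataclass
class PolygenicFit:
    """Trait-level temporal-trend fit."""

    gamma_hat: float
    se: float
    Z_raw: float
    lambda_inflation: float
    Z_adj: float
    p_adj: float
    sigma_g2: float
    sigma_e2: float
    n_snps: int
    mode: str
    n_samples: int = 0


class GammaLmm:
    """REML solver for y = alpha + t*gamma + g + e with g ~ N(0, sg2 K).

    The GRM eigendecomposition is computed once at construction so
    repeated fits with new responses (sign-flip randomizations, window
    refits) cost only a bounded 1-D REML search each.
    """

    def __init__(self, K: np.ndarray, t: np.ndarray):
        K = np.asarray(K, dtype=float)
        t = np.asarray(t, dtype=float)
        if np.ptp(t) == 0:
            raise ValueError("t is constant; the trend is unidentifiable")
        self.n = t.size
        lam, U = np.linalg.eigh((K + K.T) / 2.0)
        self.lam = np.clip(lam, 0.0, None)
        self.U = U
        X = np.column_stack([np.ones(self.n), t])
        self.Xt = U.T @ X
        self.p = 2

    def _neg_reml(self, log_delta: float, yt: np.ndarray) -> float:
        delta = np.exp(log_delta)
        D = 1.0 + delta * self.lam
        XtD = self.Xt / D[:, None]
        info = self.Xt.T @ XtD
        b = np.linalg.solve(info, XtD.T @ yt)
        r = yt - self.Xt @ b
        rss = max(float(r @ (r / D)), 1e-300)  # guard exact fits
        _, logdet_info = np.linalg.slogdet(info)
        nf = self.n - self.p
        return nf * np.log(rss / nf) + float(np.sum(np.log(D))) + logdet_info

    def fit(self, y: np.ndarray, fix_sigma_g2: float | None = None):
        yt = self.U.T @ np.asarray(y, dtype=float)
        if fix_sigma_g2 == 0.0:
            delta = 0.0
        elif fix_sigma_g2 is None:
            res = optimize.minimize_scalar(
                self._neg_reml, args=(yt,), bounds=(-12.0, 12.0),
                method="bounded", options={"xatol": 1e-8},
            )
            delta = float(np.exp(res.x))
            # compare against the boundary delta = 0 (pure OLS)
            if self._neg_reml(-30.0, yt) < res.fun:
                delta = 0.0
        else:
            raise NotImplementedError("only fix_sigma_g2=0 or free is supported")
        D = 1.0 + delta * self.lam
        XtD = self.Xt / D[:, None]
        info = self.Xt.T @ XtD
        cov_unscaled = np.linalg.inv(info)
        b = cov_unscaled @ (XtD.T @ yt)
        r = yt - self.Xt @ b
        sigma_e2 = float(r @ (r / D)) / (self.n - self.p)
        sigma_g2 = delta * sigma_e2
        se = float(np.sqrt(sigma_e2 * cov_unscaled[1, 1]))
        gamma = float(b[1])
        return gamma, se, sigma_g2, sigma_e2


def fit_gamma(
    pgs: PgsResult,
    dates_bp: np.ndarray,
    grm: Grm,
    scale: TimeScale = TimeScale(),
    fix_sigma_g2: float | None = None,
    solver: GammaLmm | None = None,
) -> PolygenicFit:
    """REML LMM fit of the scaled PGS on time (per ten millennia).

    With sigma_g2 fixed at 0 the estimate equals OLS of y on (1, t).
    The inflation fields are filled by :func:`signflip_inflation` /
    :func:`polygenic_test`; here lambda = 1.
    """
    t = to_time(dates_bp, scale, "per_10ky")
    if solver is None:
        solver = GammaLmm(grm.A, t)
    gamma, se, sg2, se2 = solver.fit(pgs.scaled, fix_sigma_g2=fix_sigma_g2)
    z = gamma / se if se > 0 else np.nan
    return PolygenicFit(
        gamma_hat=gamma, se=se, Z_raw=z, lambda_inflation=1.0, Z_adj=z,
        p_adj=float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan,
        sigma_g2=sg2, sigma_e2=se2, n_snps=pgs.n_snps, mode=pgs.mode,
        n_samples=t.size,
    )


def signflip_inflation(
    snpset: SnpSet,
    cohort: CohortGenotypes,
    grm: Grm,
    n_rand: int = 100,
    cap: float = DEFAULT_LAMBDA_CAP,
    seed: int = 0,
    scale: TimeScale = TimeScale(),
    solver: GammaLmm | None = None,
) -> float:
    """Sign-flip inflation factor for one trait's SNP set.

    lambda = clip(median(Z_gamma^2 over random +/-1-weight scores)
    / 0.455, 1, cap). Deterministic given the seed.
    """
    if n_rand < 2:
        raise ValueError("n_rand must be >= 2")
    rng = np.random.default_rng(seed)
    t = to_time(cohort.dates_bp, scale, "per_10ky")
    if solver is None:
        solver = GammaLmm(grm.A, t)
    z2 = np.empty(n_rand)
    for k in range(n_rand):
        w = rng.choice([-1.0, 1.0], size=len(snpset))
        pgs = compute_pgs(cohort, snpset, mode="sign", weights=w)
        gamma, se, *_ = solver.fit(pgs.scaled)
        z2[k] = (gamma / se) ** 2 if se > 0 else np.nan
    lam = float(np.nanmedian(z2) / CHI2_1_MEDIAN)
    return float(np.clip(lam, 1.0, cap))


def _in_regions(chrom: np.ndarray, pos: np.ndarray, regions: pd.DataFrame) -> np.ndarray:
    """Mask of variants inside BED-style regions (0-based half-open)."""
    mask = np.zeros(chrom.size, dtype=bool)
    for _, r in regions.iterrows():
        mask |= (chrom == str(r["chrom"])) & (pos - 1 >= r["start"]) & (pos - 1 < r["end"])
    return mask


def polygenic_test(
    cohort: CohortGenotypes,
    gwas: GwasSummary,
    grm: Grm,
    panel: np.ndarray | None = None,
    modes: tuple[str, ...] = ("beta", "sign"),
    exclude_regions: pd.DataFrame | None = None,
    p_threshold: float = 1e-3,
    r2_threshold: float = 0.05,
    dprime_threshold: float = 0.2,
    window_kb: float = 500.0,
    n_rand: int = 100,
    cap: float = DEFAULT_LAMBDA_CAP,
    seed: int = 0,
    scale: TimeScale = TimeScale(),
) -> dict[str, PolygenicFit]:
    """Full trait-level test: align, exclude, clump, score, fit, adjust.

    ``panel`` (LD reference dosages, columns aligned to the *aligned*
    GWAS rows) defaults to the cohort's own dosages. ``exclude_regions``
    is a BED-like frame (chrom, start, end), e.g. the HLA region.
    Returns one :class:`PolygenicFit` per weighting mode, with
    Z_adj = Z_raw / sqrt(lambda).
    """
    aligned = gwas if "cohort_index" in gwas.table.columns else align_gwas(gwas, cohort)
    tab = aligned.table.reset_index(drop=True)
    if exclude_regions is not None and len(exclude_regions):
        drop = _in_regions(tab["chrom"].astype(str).to_numpy(),
                           tab["pos"].to_numpy(dtype=float), exclude_regions)
        if drop.any():
            logger.info("excluding %d GWAS variants in masked regions", int(drop.sum()))
        tab = tab.loc[~drop].reset_index(drop=True)
    if tab.empty:
        raise ValueError("no GWAS variants remain after exclusions")
    aligned = GwasSummary(tab, aligned.n_dropped_ambiguous)
    if panel is None:
        panel = cohort.G[:, tab["cohort_index"].to_numpy(dtype=int)]
    snpset = two_step_clump(aligned, panel, p_threshold, r2_threshold,
                            dprime_threshold, window_kb)
    if len(snpset) == 0:
        logger.warning("clumping retained no SNPs; no test performed")
        return {}
    t = to_time(cohort.dates_bp, scale, "per_10ky")
    solver = GammaLmm(grm.A, t)
    lam = signflip_inflation(snpset, cohort, grm, n_rand=n_rand, cap=cap,
                             seed=seed, scale=scale, solver=solver)
    out: dict[str, PolygenicFit] = {}
    for mode in modes:
        pgs = compute_pgs(cohort, snpset, mode=mode)
        fit = fit_gamma(pgs, cohort.dates_bp, grm, scale=scale, solver=solver)
        z_adj = fit.Z_raw / np.sqrt(lam)
        out[mode] = PolygenicFit(
            gamma_hat=fit.gamma_hat, se=fit.se, Z_raw=fit.Z_raw,
            lambda_inflation=lam, Z_adj=z_adj,
            p_adj=float(2 * stats.norm.sf(abs(z_adj))),
            sigma_g2=fit.sigma_g2, sigma_e2=fit.sigma_e2,
            n_snps=len(snpset), mode=mode, n_samples=fit.n_samples,
        )
    return out


def windowed_gamma(
    pgs: PgsResult,
    cohort: CohortGenotypes,
    grm: Grm,
    window_years: float = 2000.0,
    step_years: float = 100.0,
    min_people: int = 2000,
    scale: TimeScale = TimeScale(),
    gp_nugget: float = 1e-3,
    gp_ls_bounds: tuple[float, float] = (1.0, 1e6),
) -> pd.DataFrame:
    """Refit the gamma LMM in sliding date windows (modern samples
    excluded; windows below ``min_people`` skipped; x = median window
    date; GP-smoothed point estimates in ``gamma_smoothed``)."""
    if not (window_years > step_years > 0):
        raise ValueError("require window_years > step_years > 0")
    from paleoselect.trajectories import _gp_smooth_xy

    dates = cohort.dates_bp
    ancient = ~cohort.samples["is_modern"].astype(bool).to_numpy()
    if not ancient.any():
        return pd.DataFrame(columns=["window_date_bp", "gamma_hat", "se", "Z", "n_people"])
    lo, hi = dates[ancient].min(), dates[ancient].max()
    centers = np.arange(lo + window_years / 2, hi - window_years / 2 + step_years, step_years)
    rows = []
    for c in centers:
        in_win = ancient & (dates >= c - window_years / 2) & (dates < c + window_years / 2)
        n_people = int(in_win.sum())
        if n_people < min_people:
            continue
        idx = np.flatnonzero(in_win)
        t = to_time(dates[idx], scale, "per_10ky")
        if np.ptp(t) == 0:
            continue
        solver = GammaLmm(grm.A[np.ix_(idx, idx)], t)
        try:
            gamma, se, *_ = solver.fit(pgs.scaled[idx])
        except np.linalg.LinAlgError:
            continue
        rows.append({"window_date_bp": float(np.median(dates[in_win])),
                     "gamma_hat": gamma, "se": se,
                     "Z": gamma / se if se > 0 else np.nan,
                     "n_people": n_people})
    out = pd.DataFrame(rows)
    if out.empty:
        logger.warning("no window met min_people=%d", min_people)
        return out
    out = out.sort_values("window_date_bp").reset_index(drop=True)
    smoothed, _ = _gp_smooth_xy(out["window_date_bp"].to_numpy(),
                                out["gamma_hat"].to_numpy(),
                                nugget=gp_nugget, ls_bounds=gp_ls_bounds)
    out["gamma_smoothed"] = smoothed
    return out


def drop_priority(beta: np.ndarray, s_hat: np.ndarray, freq: np.ndarray) -> np.ndarray:
    """Locus-dropping priority |beta * s * f * (1 - f)| (the magnitude of
    a SNP's expected contribution to the PGS trend)."""
    return np.abs(np.asarray(beta) * np.asarray(s_hat)
                  * np.asarray(freq) * (1 - np.asarray(freq)))


def drop_loci_curve(
    gwas: GwasSummary,
    cohort: CohortGenotypes,
    grm: Grm,
    s_hat: np.ndarray,
    panel: np.ndarray | None = None,
    mode: str = "beta",
    radius_bp: float = 1e6,
    genetic_map: pd.DataFrame | None = None,
    radius_cm: float = 1.0,
    p_stop: float = 0.05,
    max_drops: int = 100,
    n_rand: int = 100,
    seed: int = 0,
    **test_kwargs,
) -> pd.DataFrame:
    """Robustness-to-single-loci curve for a polygenic signal.

    Iteratively drops the region around the highest-priority SNP
    (priority |beta * s * f * (1-f)|; radius ``radius_cm`` with a
    genetic map, else ``radius_bp`` under the 1 cM/Mb convention) and
    re-runs the polygenic test, recording (n_dropped, n_snps, Z, p)
    until no SNPs remain, p exceeds ``p_stop``, or ``max_drops``.
    """
    aligned = gwas if "cohort_index" in gwas.table.columns else align_gwas(gwas, cohort)
    tab = aligned.table.reset_index(drop=True).copy()
    s_hat = np.asarray(s_hat, dtype=float)
    if s_hat.size != len(tab):
        raise ValueError("s_hat must align with the (aligned) GWAS rows")
    f = cohort.allele_frequencies()[tab["cohort_index"].to_numpy(dtype=int)]
    tab["_priority"] = drop_priority(tab["beta"].to_numpy(), s_hat, f)

    def cm_window(chrom: str, pos: float) -> tuple[float, float]:
        if genetic_map is None:
            return pos - radius_bp, pos + radius_bp
        gm = genetic_map[genetic_map["chrom"].astype(str) == chrom]
        cm = np.interp(pos, gm["pos"], gm["cm"])
        lo = np.interp(cm - radius_cm, gm["cm"], gm["pos"])
        hi = np.interp(cm + radius_cm, gm["cm"], gm["pos"])
        return float(lo), float(hi)

    rows = []
    current = tab
    for n_dropped in range(max_drops + 1):
        if current.empty:
            break
        sub = GwasSummary(current.drop(columns=["_priority"]).reset_index(drop=True),
                          aligned.n_dropped_ambiguous)
        fits = polygenic_test(cohort, sub, grm, panel=panel, modes=(mode,),
                              n_rand=n_rand, seed=seed, **test_kwargs)
        if not fits:
            break
        fit = fits[mode]
        rows.append({"n_dropped": n_dropped, "n_snps": fit.n_snps,
                     "Z": fit.Z_adj, "p": fit.p_adj})
        if fit.p_adj > p_stop:
            break
        top = current["_priority"].idxmax()
        chrom = str(current.loc[top, "chrom"])
        lo, hi = cm_window(chrom, float(current.loc[top, "pos"]))
        keep = ~((current["chrom"].astype(str) == chrom)
                 & (current["pos"] >= lo) & (current["pos"] <= hi))
        current = current.loc[keep]
    return pd.DataFrame(rows)
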