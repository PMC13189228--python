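"""Per-variant binomial GLMM selection scan.

Model (one variant at a time): cluster m contributes an allele count
y_m ~ Binomial(d_m, p_m) with

    logit(p_m) = alpha + s * t_m + g_m,      g ~ MVN(0, sigma2 * K),

where t_m is cluster time (negative in the past, in units of twice the
generation interval so s reads per generation), K is the cluster-level
GRM block average, and sigma2 absorbs drift and residual structure.
sigma2 is re-estimated per variant, with an optional lower bound (the
"variance floor") estimated genome-wide conditional on MAF so the model
cannot buy an inflated s by setting drift implausibly low.

Fitting is penalized quasi-likelihood (PQL): iterate the working linear
mixed model

    z = eta + (y/d - mu) / (mu (1 - mu)),   W = d mu (1 - mu),
    z = X b + g + e,   e ~ N(0, W^-1),      V = W^-1 + sigma2 K,

solving GLS for b = (alpha, s) and maximizing the REML likelihood in
sigma2 by bounded scalar optimization on the spectrum of
W^(1/2) K W^(1/2). With sigma2 = 0 and K = I the iteration reduces
exactly to Fisher scoring for ordinary logistic regression. Standard
errors are Wald, from the inverse expected information of the working
LMM at convergence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from paleoselect.cohort_io import CohortGenotypes, TimeScale, to_time
from paleoselect.structure import ClusterSet, Grm, cluster_covariance, pool_counts

logger = logging.getLogger(__name__)

_MU_EPS = 1e-10
_SIGMA2_MAX = 50.0


@dataclass
class SelectionFit:
    """Result of a single-variant GLMM fit."""

    alpha_hat: float
    s_hat: float
    se_s: float
    Z: float
    sigma2_hat: float
    floor_applied: bool
    converged: bool
    n_clusters_used: int
    status: str = "ok"
    n_iter: int = 0

    @property
    def pvalue(self) -> float:
        """Two-sided normal p-value for s = 0."""
        if not np.isfinite(self.Z):
            return np.nan
        return 2.0 * stats.norm.sf(abs(self.Z))


@dataclass
class VarianceFloor:
    """MAF-binned lower bounds for the drift variance sigma2."""

    bin_edges: np.ndarray  # length n_bins + 1, covering (0, 0.5]
    floors: np.ndarray  # length n_bins

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.floors = np.asarray(self.floors, dtype=float)
        if self.floors.size != self.bin_edges.size - 1:
            raise ValueError("floors must have len(bin_edges) - 1 entries")
        if (self.floors < 0).any():
            raise ValueError("floors must be non-negative")

    def floor_for(self, maf: float) -> float:
        idx = int(np.clip(np.searchsorted(self.bin_edges, maf, side="right") - 1,
                          0, self.floors.size - 1))
        return float(self.floors[idx])


def _resolve_floor(floor, maf: float | None) -> float:
    if floor is None:
        return 0.0
    if isinstance(floor, VarianceFloor):
        if maf is None:
            raise ValueError("MAF required to resolve a binned variance floor")
        return floor.floor_for(maf)
    return float(floor)


def fit_binomial_glmm(
    counts: pd.DataFrame,
    K: np.ndarray,
    floor: "VarianceFloor | float | None" = None,
    maf: float | None = None,
    fix_sigma2: float | None = None,
    max_iter: int = 100,
    tol: float = 1e-5,
) -> SelectionFit:
    """Fit the binomial GLMM to pooled cluster counts.

    Parameters
    ----------
    counts
        DataFrame with columns ``count``, ``denom``, ``t`` (one row per
        cluster with data). Rows must correspond to rows/columns of K.
    K
        Cluster covariance matrix (symmetric PSD), same order as counts.
    floor
        Lower bound for sigma2: scalar, :class:`VarianceFloor` (requires
        ``maf``), or None (effectively 0).
    fix_sigma2
        If given, sigma2 is held at this value (no REML step); used for
        the logistic-regression limit and for diagnostics.
    """
    y = counts["count"].to_numpy(dtype=float)
    d = counts["denom"].to_numpy(dtype=float)
    t = counts["t"].to_numpy(dtype=float)
    m = y.size
    if m < 3:
        raise ValueError("need >= 3 clusters with data")
    K = np.asarray(K, dtype=float)
    if K.shape != (m, m):
        raise ValueError(f"K shape {K.shape} does not match {m} clusters")
    if (d <= 0).any():
        raise ValueError("all denominators must be positive")

    if y.sum() == 0 or (d - y).sum() == 0:
        return SelectionFit(np.nan, np.nan, np.nan, np.nan, np.nan,
                            False, False, m, status="monomorphic")

    floor_val = _resolve_floor(floor, maf)
    X = np.column_stack([np.ones(m), t])

    # Haldane-corrected pooled frequency for the intercept start.
    p0 = (y.sum() + 0.5) / (d.sum() + 1.0)
    alpha, s = float(logit(p0)), 0.0
    sigma2 = floor_val if fix_sigma2 is None else float(fix_sigma2)
    g = np.zeros(m)

    converged = False
    cov_b = np.full((2, 2), np.nan)
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ np.array([alpha, s]) + g
        mu = np.clip(expit(eta), _MU_EPS, 1 - _MU_EPS)
        w = d * mu * (1 - mu)
        if not np.isfinite(w).all() or (w <= 0).any():
            raise FloatingPointError(
                f"non-finite working weights at iteration {it} "
                f"(eta range [{eta.min():.3g}, {eta.max():.3g}])"
            )
        z = eta + (y / d - mu) / (mu * (1 - mu))
        sw = np.sqrt(w)

        # spectrum of W^(1/2) K W^(1/2): V = W^(-1/2)(I + sigma2 B)W^(-1/2)
        B = (sw[:, None] * K) * sw[None, :]
        lam, U = np.linalg.eigh(B)
        lam = np.clip(lam, 0.0, None)
        zt = U.T @ (sw * z)
        Xt = U.T @ (sw[:, None] * X)

        def neg_reml(s2: float) -> float:
            Dinv = 1.0 / (1.0 + s2 * lam)
            XtD = Xt * Dinv[:, None]
            info = Xt.T @ XtD
            b = np.linalg.solve(info, XtD.T @ zt)
            r = zt - Xt @ b
            sign, logdet_info = np.linalg.slogdet(info)
            return float(np.sum(np.log1p(s2 * lam)) + logdet_info + r @ (Dinv * r))

        if fix_sigma2 is not None:
            sigma2_new = float(fix_sigma2)
        else:
            res = optimize.minimize_scalar(
                neg_reml, bounds=(floor_val, _SIGMA2_MAX), method="bounded",
                options={"xatol": 1e-8},
            )
            sigma2_new = float(res.x)

        Dinv = 1.0 / (1.0 + sigma2_new * lam)
        XtD = Xt * Dinv[:, None]
        info = Xt.T @ XtD
        cov_b = np.linalg.inv(info)
        b = cov_b @ (XtD.T @ zt)
        r = zt - Xt @ b
        # BLUP of the random effect: g = sigma2 K V^-1 (z - X b)
        u = sw * (U @ (Dinv * r))
        g_new = sigma2_new * (K @ u)

        alpha_new, s_new = float(b[0]), float(b[1])

        denom_scale = np.array([1.0 + abs(alpha), 1.0 + abs(s), 1.0 + sigma2])
        delta = np.array([alpha_new - alpha, s_new - s, sigma2_new - sigma2])
        alpha, s, sigma2, g = alpha_new, s_new, sigma2_new, g_new
        if np.max(np.abs(delta) / denom_scale) < tol:
            converged = True
            break

    se_s = float(np.sqrt(cov_b[1, 1]))
    floor_applied = (
        fix_sigma2 is None and floor_val > 0 and sigma2 <= floor_val * (1 + 1e-6)
    )
    return SelectionFit(
        alpha_hat=alpha,
        s_hat=s,
        se_s=se_s,
        Z=s / se_s if se_s > 0 else np.nan,
        sigma2_hat=sigma2,
        floor_applied=bool(floor_applied),
        converged=bool(converged),
        n_clusters_used=m,
        n_iter=it,
    )


def estimate_variance_floor(
    cohort: CohortGenotypes,
    clusters: ClusterSet,
    grm: Grm,
    n_random_snps: int = 1000,
    n_bins: int = 10,
    seed: int = 0,
    scale: TimeScale = TimeScale(),
) -> VarianceFloor:
    """Estimate MAF-conditional lower bounds for sigma2.

    Fits the GLMM without a floor at ``n_random_snps`` randomly drawn
    variants, bins the unconstrained sigma2 estimates into equal-count
    MAF bins, takes the per-bin median, and smooths monotonically across
    bins (isotonic regression; direction chosen by rank correlation).
    Empty bins are merged into their neighbor.
    """
    if n_random_snps < 100:
        raise ValueError("n_random_snps must be >= 100")
    rng = np.random.default_rng(seed)
    f = cohort.allele_frequencies()
    poly = np.flatnonzero((f > 0) & (f < 1))
    take = min(n_random_snps, poly.size)
    chosen = rng.choice(poly, size=take, replace=False)
    K = cluster_covariance(grm, clusters)

    mafs, sig2 = [], []
    for v in chosen:
        counts = pool_counts(cohort, clusters, v, scale)
        if len(counts) < 3:
            continue
        idx = counts["cluster_id"].to_numpy()
        try:
            fit = fit_binomial_glmm(counts, K[np.ix_(idx, idx)], floor=None)
        except (FloatingPointError, np.linalg.LinAlgError):
            continue
        if fit.status != "ok":
            continue
        mafs.append(min(f[v], 1 - f[v]))
        sig2.append(fit.sigma2_hat)
    mafs = np.asarray(mafs)
    sig2 = np.asarray(sig2)
    if mafs.size == 0:
        raise ValueError("no usable variants for floor estimation")

    # equal-count bins on (0, 0.5]
    qs = np.quantile(mafs, np.linspace(0, 1, n_bins + 1))
    edges = np.concatenate([[0.0], qs[1:-1], [0.5]])
    edges = np.unique(edges)
    medians, mids = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = (mafs > lo) & (mafs <= hi)
        if not in_bin.any():
            logger.info("empty MAF bin (%g, %g] merged with neighbor", lo, hi)
            continue
        medians.append(np.median(sig2[in_bin]))
        mids.append((lo + hi) / 2.0)
    if len(medians) < edges.size - 1:
        # rebuild edges around surviving bins
        keep_edges = [edges[0]]
        k = 0
        for lo, hi in zip(edges[:-1], edges[1:]):
            if ((mafs > lo) & (mafs <= hi)).any():
                keep_edges.append(hi)
                k += 1
            else:
                keep_edges[-1] = hi
        edges = np.asarray(keep_edges)
    medians = np.asarray(medians)
    mids = np.asarray(mids)

    if medians.size > 1:
        from sklearn.isotonic import IsotonicRegression

        rho = stats.spearmanr(mids, medians).statistic
        increasing = bool(rho >= 0) if np.isfinite(rho) else True
        iso = IsotonicRegression(increasing=increasing, out_of_bounds="clip")
        medians = iso.fit_transform(mids, medians)
    return VarianceFloor(edges, np.clip(medians, 0.0, None))


def scan(
    cohort: CohortGenotypes,
    clusters: ClusterSet,
    grms: "dict[str, Grm] | Grm",
    floor: "VarianceFloor | float | None" = None,
    scale: TimeScale = TimeScale(),
) -> pd.DataFrame:
    """Fit the GLMM at every variant, using each chromosome's LOCO GRM.

    Returns a table in input variant order with columns chrom, pos, ref,
    alt, maf, s_hat, se_s, Z, sigma2, floor_applied, converged, status.
    Per-variant failures are recorded in ``status``, never fatal.
    """
    if isinstance(grms, Grm):
        K_by_chrom = {None: cluster_covariance(grms, clusters)}
    else:
        K_by_chrom = {c: cluster_covariance(g, clusters) for c, g in grms.items()}
    f = cohort.allele_frequencies()
    rows = []
    for v in range(cohort.n_variants):
        chrom = str(cohort.variants["chrom"].iloc[v])
        K = K_by_chrom.get(chrom, K_by_chrom.get(None))
        if K is None:
            raise ValueError(f"no GRM provided for chromosome {chrom}")
        maf = float(min(f[v], 1 - f[v])) if np.isfinite(f[v]) else np.nan
        counts = pool_counts(cohort, clusters, v, scale)
        base = {
            "chrom": chrom,
            "pos": int(cohort.variants["pos"].iloc[v]),
            "ref": cohort.variants["ref"].iloc[v],
            "alt": cohort.variants["alt"].iloc[v],
            "maf": maf,
        }
        if len(counts) < 3:
            rows.append({**base, "s_hat": np.nan, "se_s": np.nan, "Z": np.nan,
                         "sigma2": np.nan, "floor_applied": False,
                         "converged": False, "status": "too_few_clusters"})
            continue
        idx = counts["cluster_id"].to_numpy()
        try:
            fit = fit_binomial_glmm(counts, K[np.ix_(idx, idx)], floor=floor, maf=maf)
        except (FloatingPointError, np.linalg.LinAlgError) as exc:
            logger.warning("variant %d failed: %s", v, exc)
            rows.append({**base, "s_hat": np.nan, "se_s": np.nan, "Z": np.nan,
                         "sigma2": np.nan, "floor_applied": False,
                         "converged": False, "status": "failed"})
            continue
        rows.append({**base, "s_hat": fit.s_hat, "se_s": fit.se_s, "Z": fit.Z,
                     "sigma2": fit.sigma2_hat, "floor_applied": fit.floor_applied,
                     "converged": fit.converged, "status": fit.status})
    return pd.DataFrame(rows)


def variance_explained(fit: SelectionFit, t: np.ndarray) -> float:
    """Proportion of logit-scale allele-frequency variance attributable
    to directional selection: s^2 var(t) / (s^2 var(t) + sigma2)."""
    if not fit.converged:
        raise ValueError("fit did not converge")
    var_t = float(np.var(np.asarray(t, dtype=float)))
    num = fit.s_hat**2 * var_t
    den = num + fit.sigma2_hat
    if den == 0:
        return np.nan  # s = 0 and sigma2 = 0: undefined
    return num / den


def windowed_selection(
    cohort: CohortGenotypes,
    clusters: ClusterSet,
    grm: Grm,
    variant: int,
    window_years: float = 2000.0,
    step_years: float = 100.0,
    min_people: int = 2000,
    floor: "VarianceFloor | float | None" = None,
    scale: TimeScale = TimeScale(),
    gp_nugget: float = 1e-5,
    gp_ls_bounds: tuple[float, float] = (1.0, 1e6),
) -> pd.DataFrame:
    """Refit the selection model in sliding date windows.

    Windows of ``window_years`` advance by ``step_years``; windows with
    fewer than ``min_people`` ancient samples are skipped. Modern
    samples are excluded (their density would pin window medians to 0).
    The x-value of each window is the median sample date within it.
    Smoothed point estimates (column ``s_smoothed``) come from a
    rational-quadratic GP over the window series.
    """
    if not (window_years > step_years > 0):
        raise ValueError("require window_years > step_years > 0")
    from paleoselect.trajectories import _gp_smooth_xy

    dates = cohort.dates_bp
    ancient = ~cohort.samples["is_modern"].astype(bool).to_numpy()
    if not ancient.any():
        logger.warning("no ancient samples; empty window series")
        return pd.DataFrame(columns=["window_date_bp", "s_hat", "se_s", "Z", "n_people"])
    lo, hi = dates[ancient].min(), dates[ancient].max()
    centers = np.arange(lo + window_years / 2, hi - window_years / 2 + step_years, step_years)

    rows = []
    for c in centers:
        in_win = ancient & (dates >= c - window_years / 2) & (dates < c + window_years / 2)
        n_people = int(in_win.sum())
        if n_people < min_people:
            continue
        idx = np.flatnonzero(in_win)
        sub = cohort.subset_samples(idx)
        sub_clusters = ClusterSet(
            clusters.assignment[idx],
            [clusters.sample_ids[i] for i in idx],
            clusters.max_date_gap,
            clusters.dates_bp[idx],
        )
        sub_ids = {s: i for i, s in enumerate(grm.sample_ids)}
        rowsel = np.array([sub_ids[s] for s in sub_clusters.sample_ids])
        sub_grm = Grm(grm.A[np.ix_(rowsel, rowsel)], list(sub_clusters.sample_ids),
                      grm.M, grm.excluded_chrom)
        counts = pool_counts(sub, sub_clusters, variant, scale)
        if len(counts) < 3:
            continue
        K = cluster_covariance(sub_grm, sub_clusters)
        cidx = counts["cluster_id"].to_numpy()
        try:
            fit = fit_binomial_glmm(counts, K[np.ix_(cidx, cidx)], floor=floor)
        except (FloatingPointError, np.linalg.LinAlgError):
            continue
        if fit.status != "ok":
            continue
        rows.append(
            {
                "window_date_bp": float(np.median(dates[in_win])),
                "s_hat": fit.s_hat,
                "se_s": fit.se_s,
                "Z": fit.Z,
                "n_people": n_people,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        logger.warning("no window met min_people=%d", min_people)
        return out
    out = out.sort_values("window_date_bp").reset_index(drop=True)
    smoothed, _ = _gp_smooth_xy(
        out["window_date_bp"].to_numpy(), out["s_hat"].to_numpy(),
        nugget=gp_nugget, ls_bounds=gp_ls_bounds,
    )
    out["s_smoothed"] = smoothed
    return out
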