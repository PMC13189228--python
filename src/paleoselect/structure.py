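"""Population-structure machinery.

The genetic relationship matrix (GRM) is the empirical covariance of
standardized genotypes,

    A_ij = (1/M) sum_k (G_ik - 2 f_k)(G_jk - 2 f_k) / (2 f_k (1 - f_k)),

with f_k computed in-sample; leave-one-chromosome-out (LOCO) variants
avoid proximal contamination when a variant is tested against its own
chromosome's relatedness. Individuals are grouped into ancestry-date
clusters (agglomerative clustering on top PCs, then on dates with a
maximum within-cluster date gap G), and the GLMM's cluster-level
covariance is the block average of the GRM,

    K_mn = (1 / (N_m N_n)) sum_{i in c_m} sum_{j in c_n} A_ij.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AgglomerativeClustering

from paleoselect.cohort_io import CohortGenotypes, TimeScale, to_time

logger = logging.getLogger(__name__)


@dataclass
class Grm:
    """Genetic relationship matrix with sample ids and LOCO provenance."""

    A: np.ndarray
    sample_ids: list[str]
    M: int
    excluded_chrom: str | None = None

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        n = self.A.shape[0]
        if self.A.shape != (n, n):
            raise ValueError("GRM must be square")
        if not np.allclose(self.A, self.A.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")
        if not np.isfinite(np.diag(self.A)).all():
            raise ValueError("GRM diagonal must be finite")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length must match GRM dimension")

    @property
    def n(self) -> int:
        return self.A.shape[0]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.A, columns=self.sample_ids).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, M: int = 0, excluded_chrom: str | None = None) -> "Grm":
        tab = pd.read_csv(path, sep="\t")
        return cls(tab.to_numpy(dtype=float), list(tab.columns), M, excluded_chrom)


@dataclass
class ClusterSet:
    """Ancestry-date clusters: assignment, sizes, mean dates.

    ``assignment`` maps each sample (row order of the cohort it was
    built from) to a cluster id in ``range(n_clusters)``.
    """

    assignment: np.ndarray
    sample_ids: list[str]
    max_date_gap: float
    dates_bp: np.ndarray

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        self.dates_bp = np.asarray(self.dates_bp, dtype=float)
        if len(self.sample_ids) != self.assignment.size:
            raise ValueError("assignment and sample_ids lengths differ")
        # relabel to contiguous 0..n_clusters-1 preserving first-appearance order
        _, self.assignment = np.unique(self.assignment, return_inverse=True)
        for cid in range(self.n_clusters):
            d = self.dates_bp[self.assignment == cid]
            if d.size and (d.max() - d.min()) > self.max_date_gap + 1e-9:
                raise ValueError(
                    f"cluster {cid} violates max date gap {self.max_date_gap}"
                )

    @property
    def n_clusters(self) -> int:
        return int(self.assignment.max()) + 1 if self.assignment.size else 0

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.n_clusters)

    @property
    def mean_dates_bp(self) -> np.ndarray:
        out = np.zeros(self.n_clusters)
        np.add.at(out, self.assignment, self.dates_bp)
        return out / self.sizes

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == cluster_id)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster_id": np.arange(self.n_clusters),
                "n": self.sizes,
                "mean_date_bp": self.mean_dates_bp,
            }
        )


def compute_grm(cohort: CohortGenotypes, exclude_chrom: str | None = None) -> Grm:
    """GRM from all polymorphic variants, optionally excluding one
    chromosome (LOCO). Missing dosages are mean-imputed (G <- 2 f_k),
    which zeroes their centered contribution."""
    G = cohort.G
    keep = np.ones(cohort.n_variants, dtype=bool)
    if exclude_chrom is not None:
        keep &= cohort.variants["chrom"].astype(str).to_numpy() != str(exclude_chrom)
    f = cohort.allele_frequencies()
    keep &= (f > 0) & (f < 1)
    if not keep.any():
        raise ValueError("no polymorphic variants available for the GRM")
    Gk = G[:, keep]
    fk = f[keep]
    X = np.where(np.isnan(Gk), 2 * fk, Gk) - 2 * fk
    X /= np.sqrt(2 * fk * (1 - fk))
    M = int(keep.sum())
    A = (X @ X.T) / M
    return Grm(A, list(cohort.samples["sample_id"]), M, exclude_chrom)


def loco_grms(cohort: CohortGenotypes) -> dict[str, Grm]:
    """One GRM per chromosome, each built without that chromosome."""
    chroms = pd.unique(cohort.variants["chrom"].astype(str))
    if len(chroms) < 2:
        raise ValueError(
            "LOCO requires >= 2 chromosomes; use compute_grm for a single-chromosome cohort"
        )
    return {c: compute_grm(cohort, exclude_chrom=c) for c in chroms}


def top_pcs(grm: Grm | CohortGenotypes, n_pcs: int) -> np.ndarray:
    """Principal components from the GRM eigendecomposition, scaled by
    sqrt(eigenvalue); equivalent to PCA of standardized genotypes.

    Sign convention: the largest-magnitude loading of each PC is made
    positive, so results are deterministic.
    """
    if isinstance(grm, CohortGenotypes):
        grm = compute_grm(grm)
    n = grm.n
    if n_pcs > n - 1:
        raise ValueError(f"n_pcs={n_pcs} exceeds n-1={n - 1}")
    vals, vecs = np.linalg.eigh(grm.A)
    order = np.argsort(vals)[::-1][:n_pcs]
    vals = np.clip(vals[order], 0, None)
    vecs = vecs[:, order]
    flip = np.sign(vecs[np.abs(vecs).argmax(axis=0), np.arange(n_pcs)])
    flip[flip == 0] = 1.0
    return vecs * flip * np.sqrt(vals)


def mahalanobis_outliers(
    pcs: np.ndarray, n_pcs: int | None = None, alpha: float = 0.05, n_tests: int | None = None
) -> np.ndarray:
    """Flag samples whose squared Mahalanobis distance on the top PCs
    exceeds the chi-square quantile at the Bonferroni-corrected level
    alpha / n_tests (n_tests defaults to the number of samples).

    Returns a boolean mask over samples.
    """
    pcs = np.asarray(pcs, dtype=float)
    if n_pcs is not None:
        pcs = pcs[:, :n_pcs]
    n, k = pcs.shape
    if n_tests is None:
        n_tests = n
    sd = pcs.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("constant PC column; covariance singular — use fewer PCs")
    Z = (pcs - pcs.mean(axis=0)) / sd
    cov = np.cov(Z, rowvar=False)
    if k == 1:
        cov = cov.reshape(1, 1)
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0 or not np.isfinite(logdet):
        raise ValueError("singular PC covariance — use fewer PCs")
    centered = Z - Z.mean(axis=0)
    d2 = np.einsum("ij,jk,ik->i", centered, np.linalg.inv(cov), centered)
    threshold_p = alpha / n_tests
    cutoff = stats.chi2.isf(threshold_p, df=k)
    return d2 > cutoff


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance level alpha / n_tests."""
    return alpha / n_tests


def cluster_ancestry_date(
    pcs: np.ndarray,
    dates_bp: np.ndarray,
    sample_ids: list[str] | None = None,
    target: int = 2000,
    max_gap: float = 500.0,
) -> ClusterSet:
    """Cluster samples by ancestry (PCs) then date, targeting ``target``
    clusters under a hard within-cluster date-gap bound ``max_gap``.

    Binary search on the number m of PC clusters: Ward agglomerative
    clustering on the PCs into m groups, then within each group
    complete-linkage agglomerative clustering on dates with distance
    threshold ``max_gap``. The search interval (l, r) starts at
    (2, target) and narrows until the total cluster count falls in
    [target-1, target+1] or the interval collapses, in which case the
    best clustering seen is returned with a warning.

    Complete linkage on dates guarantees the max-gap invariant.
    """
    pcs = np.asarray(pcs, dtype=float)
    dates_bp = np.asarray(dates_bp, dtype=float)
    n = pcs.shape[0]
    if target < 2:
        raise ValueError("target must be >= 2")
    if target > n:
        raise ValueError(f"target={target} exceeds number of samples ({n})")
    if max_gap <= 0:
        raise ValueError("max_gap must be positive")
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(n)]

    def split(m: int) -> np.ndarray:
        if m >= n:
            pc_labels = np.arange(n)
        else:
            pc_labels = AgglomerativeClustering(n_clusters=m, linkage="ward").fit_predict(pcs)
        out = np.full(n, -1, dtype=int)
        next_id = 0
        for g in np.unique(pc_labels):
            idx = np.flatnonzero(pc_labels == g)
            d = dates_bp[idx].reshape(-1, 1)
            if idx.size == 1 or d.max() - d.min() <= max_gap:
                sub = np.zeros(idx.size, dtype=int)
            else:
                sub = AgglomerativeClustering(
                    n_clusters=None, distance_threshold=max_gap, linkage="complete"
                ).fit_predict(d)
            out[idx] = sub + next_id
            next_id += sub.max() + 1
        return out

    lo, hi = 2, target
    best: np.ndarray | None = None
    best_dist = np.inf
    while True:
        m = (lo + hi) // 2
        labels = split(m)
        total = labels.max() + 1
        dist = abs(total - target)
        if dist < best_dist:
            best, best_dist = labels, dist
        if target - 1 <= total <= target + 1:
            break
        if lo >= hi or hi - lo <= 1:
            logger.warning(
                "cluster search interval collapsed at m=%d (got %d clusters, "
                "target %d); returning best seen", m, total, target,
            )
            break
        if total > target + 1:
            hi = m
        else:
            lo = m
    assert best is not None
    return ClusterSet(best, list(sample_ids), max_gap, dates_bp)


def cluster_covariance(grm: Grm, clusters: ClusterSet) -> np.ndarray:
    """Cluster-level covariance: block average of the GRM over cluster
    membership pairs."""
    id_to_row = {s: i for i, s in enumerate(grm.sample_ids)}
    missing = [s for s in clusters.sample_ids if s not in id_to_row]
    if missing:
        raise ValueError(f"clustered samples absent from GRM: {missing[:5]}")
    rows = np.array([id_to_row[s] for s in clusters.sample_ids])
    n_c = clusters.n_clusters
    # indicator matrix (samples-in-grm-order x clusters), scaled by 1/N
    P = np.zeros((grm.n, n_c))
    P[rows, clusters.assignment] = 1.0
    P /= P.sum(axis=0, keepdims=True)
    K = P.T @ grm.A @ P
    return (K + K.T) / 2.0


def pool_counts(
    cohort: CohortGenotypes,
    clusters: ClusterSet,
    variant: int,
    scale: TimeScale = TimeScale(),
    convention: str = "per_generation2",
) -> pd.DataFrame:
    """Pooled per-cluster allele counts at one variant.

    Returns a DataFrame with one row per cluster that has at least one
    non-missing dosage: cluster_id, count (rounded summed dosage),
    denom (2 x non-missing members), t (mean member date converted).
    Entirely-missing clusters are dropped with a log entry.
    """
    g = cohort.G[:, variant]
    n_c = clusters.n_clusters
    a = clusters.assignment
    ok = np.isfinite(g)
    count = np.zeros(n_c)
    np.add.at(count, a[ok], g[ok])
    denom = np.zeros(n_c)
    np.add.at(denom, a[ok], 2.0)
    mean_date = clusters.mean_dates_bp
    t = to_time(mean_date, scale, convention)
    keep = denom > 0
    if not keep.all():
        logger.info(
            "variant %d: dropping %d all-missing clusters", variant, int((~keep).sum())
        )
    return pd.DataFrame(
        {
            "cluster_id": np.arange(n_c)[keep],
            "count": np.rint(count[keep]).astype(int),
            "denom": denom[keep].astype(int),
            "t": t[keep],
        }
    )
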