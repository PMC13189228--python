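"""Synthetic cohorts and matched simulations.

Two generators back the test battery:

:func:`synth_cohort` builds a structured, dated cohort. Per-population
allele frequencies follow the Balding-Nichols model (Beta-distributed
around a shared ancestral frequency with an FST-like divergence
parameter), each population's frequency then drifts across dated epochs
as a logit-scale random walk, optional admixture events mix source
frequencies, and selected variants receive a deterministic logit-linear
trend of slope s per generation. Samples carry dates drawn uniformly
over the configured range (plus optional moderns at date 0) and
genotypes are binomial draws from their population-epoch frequency.

:func:`simulate_variant` is the GRM-matched single-variant generator
used for parameter-recovery and power studies: given a cluster
covariance K, cluster times t and sizes, it draws g ~ MVN(0, sigma2 K),
sets p = logistic(logit(f0) + s t + g), and draws binomial counts —
exactly the generative form of the scan's GLMM, so fitting recovers
(alpha, s, sigma2) when the engine is correct.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from paleoselect.cohort_io import CohortGenotypes, TimeScale, to_time

logger = logging.getLogger(__name__)


@dataclass
class AdmixtureEvent:
    """At ``time_bp``, population ``target`` becomes a mixture of
    ``sources`` with the given fractions (summing to 1)."""

    time_bp: float
    target: int
    sources: tuple[int, ...]
    fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.sources) != len(self.fractions):
            raise ValueError("sources and fractions must have equal length")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("admixture fractions must sum to 1")
        if self.time_bp < 0:
            raise ValueError("admixture time must be >= 0 BP")


@dataclass
class SimulationConfig:
    """Stated world for the cohort generator.

    Defaults describe a desk-scale analogue of a West-Eurasian ancient
    time transect: a handful of diverged source populations sampled over
    ten millennia, with moderate divergence (FST 0.05), logit-scale
    drift per millennium, and ancestral frequencies drawn uniformly at
    MAF 0.05-0.5 with random allele orientation.
    """

    n_pops: int = 3
    n_samples: int = 300
    n_modern: int = 30
    n_variants: int = 200
    n_chrom: int = 2
    date_range: tuple[float, float] = (500.0, 10000.0)
    fst: float = 0.05
    drift_per_ky: float = 0.05  # logit-scale random-walk SD per 1000 years
    epoch_years: float = 1000.0
    admixture: tuple[AdmixtureEvent, ...] = ()
    s_values: dict[int, float] = field(default_factory=dict)  # variant -> s
    maf_range: tuple[float, float] = (0.05, 0.5)
    generation_years: float = 29.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pops < 1 or self.n_samples < 1 or self.n_variants < 1:
            raise ValueError("counts must be positive")
        if self.date_range[0] < 0 or self.date_range[1] <= self.date_range[0]:
            raise ValueError("invalid date range")
        for ev in self.admixture:
            if ev.target >= self.n_pops or any(s >= self.n_pops for s in ev.sources):
                raise ValueError("admixture event references unknown population")


@dataclass
class SyntheticCohort:
    """Cohort plus ground-truth labels."""

    cohort: CohortGenotypes
    true_s: np.ndarray  # per variant
    true_f0: np.ndarray  # ancestral frequency per variant
    population: np.ndarray  # per sample
    config: SimulationConfig


def synth_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a structured dated cohort (see module docstring)."""
    rng = np.random.default_rng(config.seed)
    n_anc, n_mod = config.n_samples, config.n_modern
    n = n_anc + n_mod
    m = config.n_variants
    lo, hi = config.date_range

    # ancestral frequencies: uniform MAF folded to random orientation
    maf = rng.uniform(*config.maf_range, size=m)
    flip = rng.random(m) < 0.5
    f_anc = np.where(flip, 1 - maf, maf)

    # Balding-Nichols per-population baseline frequencies
    F = config.fst
    if F > 0:
        a = f_anc * (1 - F) / F
        b = (1 - f_anc) * (1 - F) / F
        p_pop = rng.beta(a, b, size=(config.n_pops, m))
    else:
        p_pop = np.tile(f_anc, (config.n_pops, 1))
    p_pop = np.clip(p_pop, 1e-4, 1 - 1e-4)

    # epochs from oldest to youngest; drift is a logit random walk
    edges = np.arange(hi, lo - config.epoch_years, -config.epoch_years)
    n_epochs = max(len(edges), 1)
    sd = config.drift_per_ky * np.sqrt(config.epoch_years / 1000.0)
    logit_p = np.empty((n_epochs, config.n_pops, m))
    logit_p[0] = logit(p_pop)
    for e in range(1, n_epochs):
        logit_p[e] = logit_p[e - 1] + rng.normal(0, sd, size=(config.n_pops, m))
        for ev in config.admixture:
            if edges[e] <= ev.time_bp < edges[e - 1]:
                mix = sum(frac * expit(logit_p[e, src])
                          for src, frac in zip(ev.sources, ev.fractions))
                logit_p[e, ev.target] = logit(np.clip(mix, 1e-6, 1 - 1e-6))

    # selection: deterministic logit trend, slope s per generation
    s = np.zeros(m)
    for v, sv in config.s_values.items():
        s[v] = sv
    gen2 = 2.0 * config.generation_years

    dates = np.concatenate([
        np.round(rng.uniform(lo, hi, size=n_anc)),
        np.zeros(n_mod),
    ])
    pops = rng.integers(config.n_pops, size=n)
    epoch_of = np.clip(np.searchsorted(-edges, -dates, side="right") - 1, 0, n_epochs - 1)

    G = np.empty((n, m))
    for i in range(n):
        e = epoch_of[i] if dates[i] > 0 else n_epochs - 1
        t_i = -dates[i] / gen2
        eta = logit_p[e, pops[i]] + s * t_i
        G[i] = rng.binomial(2, expit(eta))

    chroms = np.repeat([f"{c + 1}" for c in range(config.n_chrom)],
                       int(np.ceil(m / config.n_chrom)))[:m]
    pos = np.concatenate([
        np.sort(rng.choice(np.arange(1, 10_000_000), size=(chroms == c).sum(), replace=False))
        for c in pd.unique(chroms)
    ])
    variants = pd.DataFrame({
        "chrom": chroms, "pos": pos,
        "ref": "A", "alt": "G",
        "ancestral_is_ref": True,
        "maf": np.minimum(G.mean(axis=0) / 2, 1 - G.mean(axis=0) / 2),
    })
    samples = pd.DataFrame({
        "sample_id": [f"S{i}" for i in range(n)],
        "date_bp": dates,
        "region": [f"pop{p}" for p in pops],
        "is_modern": dates == 0,
    })
    cohort = CohortGenotypes(G, variants, samples)
    return SyntheticCohort(cohort, s, f_anc, pops, config)


def check_psd(K: np.ndarray, tol_scale: float = 1e-8) -> np.ndarray:
    """Validate positive semidefiniteness (small negative eigenvalues,
    bounded by tol_scale * trace / n, are clipped to 0)."""
    K = np.asarray(K, dtype=float)
    vals, vecs = np.linalg.eigh((K + K.T) / 2.0)
    floor = -tol_scale * np.trace(K) / K.shape[0]
    if vals.min() < floor:
        raise ValueError(f"K is not PSD (min eigenvalue {vals.min():.3g})")
    vals = np.clip(vals, 0.0, None)
    return (vecs * vals) @ vecs.T


def simulate_variant(
    K: np.ndarray,
    t: np.ndarray,
    s: float,
    sigma2: float,
    f0: float,
    denom: np.ndarray,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate pooled cluster counts under the scan's generative model.

    alpha = logit(f0); g ~ MVN(0, sigma2 K); p = logistic(alpha + s t + g);
    count ~ Binomial(denom, p). Returns a counts frame consumable by
    :func:`paleoselect.glmm_scan.fit_binomial_glmm`.
    """
    if not 0 < f0 < 1:
        raise ValueError("f0 must lie in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.asarray(t, dtype=float)
    denom = np.asarray(denom, dtype=int)
    m = t.size
    Kc = check_psd(K)
    if sigma2 > 0:
        vals, vecs = np.linalg.eigh(Kc)
        g = vecs @ (np.sqrt(np.clip(vals, 0, None) * sigma2) * rng.standard_normal(m))
    else:
        g = np.zeros(m)
    p = expit(logit(f0) + s * t + g)
    counts = rng.binomial(denom, p)
    return pd.DataFrame({"cluster_id": np.arange(m), "count": counts,
                         "denom": denom, "t": t})


def power_curve(
    K: np.ndarray,
    t: np.ndarray,
    denom: np.ndarray,
    s_grid: np.ndarray,
    n_reps: int = 500,
    alpha: float = 5e-8,
    sigma2: float = 0.05,
    f0_sampler=None,
    floor: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Power (fraction of two-sided P < alpha) per selection coefficient.

    ``f0_sampler(rng)`` draws the present-day frequency per replicate;
    the default draws MAF uniform on [0.05, 0.5] with random orientation.
    Monte-Carlo SE is reported per grid point.
    """
    from paleoselect.glmm_scan import fit_binomial_glmm

    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    rng = np.random.default_rng(seed)
    if f0_sampler is None:
        def f0_sampler(r):
            maf = r.uniform(0.05, 0.5)
            return 1 - maf if r.random() < 0.5 else maf

    rows = []
    for s in np.asarray(s_grid, dtype=float):
        hits = 0
        used = 0
        for _ in range(n_reps):
            counts = simulate_variant(K, t, s, sigma2, f0_sampler(rng), denom, rng)
            try:
                fit = fit_binomial_glmm(counts, K, floor=floor)
            except (FloatingPointError, np.linalg.LinAlgError):
                continue
            if fit.status != "ok":
                continue
            used += 1
            if fit.pvalue < alpha:
                hits += 1
        p = hits / used if used else np.nan
        rows.append({"s": s, "power": p,
                     "mc_se": np.sqrt(p * (1 - p) / used) if used else np.nan,
                     "n_used": used})
    return pd.DataFrame(rows)


def null_battery(
    config: SimulationConfig,
    n_variants: int | None = None,
    gw_z: float | None = None,
) -> dict:
    """Structured null cohort (drift and admixture, s = 0 everywhere)
    plus a calibration report: scan type-I error at |Z| > 1.96, count
    beyond the genome-wide threshold, and flatness of the enrichment
    curve under independently assigned GWAS-hit labels."""
    from paleoselect import calibration
    from paleoselect.glmm_scan import scan
    from paleoselect.structure import cluster_ancestry_date, compute_grm, loco_grms, top_pcs

    if any(v != 0 for v in config.s_values.values()):
        raise ValueError("null battery requires s = 0 everywhere")
    if n_variants is not None and n_variants != config.n_variants:
        config = SimulationConfig(**{**config.__dict__, "n_variants": n_variants})
    sim = synth_cohort(config)
    cohort = sim.cohort
    grms = loco_grms(cohort) if config.n_chrom > 1 else compute_grm(cohort)
    pcs = top_pcs(compute_grm(cohort), min(10, cohort.n_samples - 1))
    clusters = cluster_ancestry_date(
        pcs, cohort.dates_bp, list(cohort.samples["sample_id"]),
        target=max(10, cohort.n_samples // 4), max_gap=500.0,
    )
    table = scan(cohort, clusters, grms)
    ok = table["status"] == "ok"
    z = table.loc[ok, "Z"].to_numpy()
    if gw_z is None:
        gw_z = calibration.gw_threshold(5e-8)
    x = calibration.x_statistic(z)
    rng = np.random.default_rng(config.seed + 1)
    hits = rng.random(ok.sum()) < 0.1  # labels independent of Z
    curve = calibration.enrichment_curve(
        x, hits, table.loc[ok, "maf"].to_numpy(),
        n_maf_bins=5, grid=np.linspace(0, np.quantile(np.abs(x), 0.95), 8),
        min_variants=20,
    )
    return {
        "simulation": sim,
        "scan": table,
        "type1_at_1.96": float((np.abs(z) > 1.96).mean()),
        "n_beyond_gw": int((np.abs(z) > gw_z).sum()),
        "n_tested": int(ok.sum()),
        "enrichment_curve": curve,
    }


def sweep_windows(
    n_haplotypes: int = 100,
    n_sites: int = 40,
    window_bp: float = 200_000.0,
    scenario: str = "neutral",
    sweep_freq: float = 0.9,
    decay_sites: float = 10.0,
    seed: int = 0,
) -> np.ndarray:
    """Phased, derived-oriented haplotype windows for HAF testing.

    ``neutral``: per-site derived counts from the standard neutral SFS
    (P(k) proportional to 1/k) placed on exchangeable haplotypes.
    ``sweep``: a focal site at the window center segregates at
    ``sweep_freq`` (a partial logistic sweep); nearby sites hitchhike
    with probability decaying in site distance, their derived alleles
    concentrated on sweep haplotypes — the haplotype structure that
    raises HAF. Returns a (n_haplotypes x n_sites) 0/1 matrix.
    """
    if n_haplotypes < 10 or n_haplotypes % 2:
        raise ValueError("n_haplotypes must be even and >= 10")
    if scenario not in ("neutral", "sweep"):
        raise ValueError(f"unknown scenario {scenario!r}")
    rng = np.random.default_rng(seed)
    n = n_haplotypes
    ks = np.arange(1, n)
    sfs = (1.0 / ks) / np.sum(1.0 / ks)

    H = np.zeros((n, n_sites), dtype=np.int8)
    focal = n_sites // 2
    if scenario == "sweep":
        n_car = int(round(sweep_freq * n))
        carriers = rng.choice(n, size=n_car, replace=False)
        H[carriers, focal] = 1
    for site in range(n_sites):
        if scenario == "sweep" and site == focal:
            continue
        k = int(rng.choice(ks, p=sfs))
        if scenario == "sweep":
            w = np.exp(-abs(site - focal) / decay_sites)
            if rng.random() < w:
                # hitchhiker: rides the sweep, frequency pulled toward the
                # carrier class and alleles placed on carrier haplotypes
                k = int(round((1 - w) * k + w * sweep_freq * n))
                k = max(1, min(k, n - 1))
                order = np.concatenate([
                    rng.permutation(np.flatnonzero(H[:, focal] == 1)),
                    rng.permutation(np.flatnonzero(H[:, focal] == 0)),
                ])
                H[order[:k], site] = 1
                continue
        H[rng.choice(n, size=k, replace=False), site] = 1
    return H
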