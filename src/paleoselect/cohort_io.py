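"""Cohort genotypes, sample metadata and GWAS summary statistics I/O.

The universal container is :class:`CohortGenotypes`: a dosage matrix
(individuals x variants, entries in [0, 2], ``NaN`` = missing) together
with variant and sample metadata tables. Sample dates are stored in
years before present (BP, modern = 0) and converted to model time with
:func:`to_time` under one of two conventions:

``per_generation2``
    t = -date_bp / (2 * generation_years). The logit-scale slope of
    allele frequency per unit of this time is the per-generation
    selection coefficient s (the factor two arises because a diploid
    transmits two allele copies per generation).
``per_10ky``
    t = -date_bp / 10000, used by the polygenic trend model so the
    slope gamma reads as change per ten millennia.

Both conventions put modern samples at t = 0 and ancient samples at
t < 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Columns of the variant metadata table.
VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "ancestral_is_ref", "maf"]
#: Columns of the sample metadata table.
SAMPLE_COLUMNS = ["sample_id", "date_bp", "region", "is_modern"]

#: Strand-ambiguous allele pairs (indistinguishable after strand flip).
_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass(frozen=True)
class TimeScale:
    """Time-unit conventions for converting dates BP into model time."""

    generation_years: float = 29.0

    def __post_init__(self) -> None:
        if self.generation_years <= 0:
            raise ValueError("generation_years must be positive")


@dataclass
class CohortGenotypes:
    """Dosage matrix plus variant and sample metadata.

    Parameters
    ----------
    G
        Array (n_samples, n_variants) of diploid dosages in [0, 2];
        missing entries are ``NaN``. Never silently zero-filled.
    variants
        DataFrame with columns ``chrom, pos, ref, alt`` and optionally
        ``ancestral_is_ref, maf``; one row per column of ``G``.
    samples
        DataFrame with columns ``sample_id, date_bp, region, is_modern``;
        one row per row of ``G``.
    haplotypes
        Optional phased matrix (2 * n_samples, n_variants) in {0, 1}.
    """

    G: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        if self.G.ndim != 2:
            raise ValueError("G must be 2-dimensional (samples x variants)")
        n, m = self.G.shape
        self.variants = self.variants.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        if len(self.variants) != m:
            raise ValueError(
                f"variant table has {len(self.variants)} rows but G has {m} columns"
            )
        if len(self.samples) != n:
            raise ValueError(
                f"sample table has {len(self.samples)} rows but G has {n} rows"
            )
        for col in ("chrom", "pos", "ref", "alt"):
            if col not in self.variants.columns:
                raise ValueError(f"variant table missing column {col!r}")
        for col in ("sample_id", "date_bp"):
            if col not in self.samples.columns:
                raise ValueError(f"sample table missing column {col!r}")
        if "is_modern" not in self.samples.columns:
            self.samples["is_modern"] = self.samples["date_bp"] == 0
        if "region" not in self.samples.columns:
            self.samples["region"] = pd.NA
        _validate_samples(self.samples)
        _validate_variants(self.variants)
        vals = self.G[np.isfinite(self.G)]
        if vals.size and (vals.min() < 0 or vals.max() > 2):
            raise ValueError("dosages must lie in [0, 2] (NaN = missing)")
        if self.haplotypes is not None:
            H = np.asarray(self.haplotypes)
            if H.shape != (2 * n, m):
                raise ValueError("haplotypes must have shape (2*n_samples, n_variants)")
            if not np.isin(H[np.isfinite(H.astype(float))], [0, 1]).all():
                raise ValueError("haplotype entries must be 0/1")
            self.haplotypes = H

    @property
    def n_samples(self) -> int:
        return self.G.shape[0]

    @property
    def n_variants(self) -> int:
        return self.G.shape[1]

    @property
    def dates_bp(self) -> np.ndarray:
        return self.samples["date_bp"].to_numpy(dtype=float)

    def allele_frequencies(self) -> np.ndarray:
        """ALT allele frequency per variant, ignoring missing dosages."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.G, axis=0) / 2.0

    def variant_key(self) -> pd.Index:
        """``chrom:pos:ref:alt`` identifier per variant."""
        v = self.variants
        return pd.Index(
            v["chrom"].astype(str)
            + ":"
            + v["pos"].astype(int).astype(str)
            + ":"
            + v["ref"].astype(str)
            + ":"
            + v["alt"].astype(str)
        )

    def subset_samples(self, index: np.ndarray) -> "CohortGenotypes":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        hap = None
        if self.haplotypes is not None:
            hidx = np.stack([2 * index, 2 * index + 1], axis=1).ravel()
            hap = self.haplotypes[hidx]
        return CohortGenotypes(
            self.G[index],
            self.variants.copy(),
            self.samples.iloc[index].reset_index(drop=True),
            hap,
        )

    def subset_variants(self, index: np.ndarray) -> "CohortGenotypes":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        hap = self.haplotypes[:, index] if self.haplotypes is not None else None
        return CohortGenotypes(
            self.G[:, index],
            self.variants.iloc[index].reset_index(drop=True),
            self.samples.copy(),
            hap,
        )


@dataclass
class GwasSummary:
    """Per-variant GWAS summary statistics.

    ``table`` columns: id, chrom, pos, effect_allele, other_allele,
    beta, se, p. ``n_dropped_ambiguous`` counts strand-ambiguous (A/T,
    C/G) variants removed during alignment.
    """

    table: pd.DataFrame
    n_dropped_ambiguous: int = 0

    def __post_init__(self) -> None:
        required = ["id", "chrom", "pos", "effect_allele", "other_allele", "beta", "se", "p"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"GWAS table missing columns: {missing}")
        t = self.table
        if (t["se"] <= 0).any():
            raise ValueError("GWAS se must be positive")
        if ((t["p"] <= 0) | (t["p"] > 1)).any():
            raise ValueError("GWAS p-values must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.table)


def _validate_samples(samples: pd.DataFrame) -> None:
    dates = pd.to_numeric(samples["date_bp"], errors="raise")
    if (dates < 0).any():
        bad = samples.loc[dates < 0, "sample_id"].tolist()
        raise ValueError(f"negative date_bp for samples: {bad}")
    modern = samples["is_modern"].astype(bool)
    if (modern & (dates != 0)).any():
        bad = samples.loc[modern & (dates != 0), "sample_id"].tolist()
        raise ValueError(f"is_modern samples must have date_bp == 0: {bad}")
    if samples["sample_id"].duplicated().any():
        dup = samples.loc[samples["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids: {dup}")


def _validate_variants(variants: pd.DataFrame) -> None:
    if (variants["pos"] < 1).any():
        raise ValueError("variant positions must be >= 1 (1-based)")
    if (variants["ref"].astype(str) == variants["alt"].astype(str)).any():
        raise ValueError("ref and alt alleles must differ")
    if "maf" in variants.columns:
        maf = variants["maf"].dropna()
        if ((maf < 0) | (maf > 0.5)).any():
            raise ValueError("maf must lie in [0, 0.5]")


def to_time(
    dates_bp: Sequence[float] | pd.DataFrame,
    scale: TimeScale = TimeScale(),
    convention: Literal["per_generation2", "per_10ky"] = "per_generation2",
) -> np.ndarray:
    """Convert dates BP to model time (0 for modern, negative in the past).

    ``per_generation2`` divides by twice the generation interval so the
    selection-model slope is per generation; ``per_10ky`` divides by
    10000 years so the polygenic-model slope is per ten millennia.
    """
    if isinstance(dates_bp, pd.DataFrame):
        dates_bp = dates_bp["date_bp"]
    d = np.asarray(dates_bp, dtype=float)
    if (d < 0).any():
        raise ValueError("date_bp must be >= 0")
    if convention == "per_generation2":
        return -d / (2.0 * scale.generation_years)
    if convention == "per_10ky":
        return -d / 10000.0
    raise ValueError(f"unknown time convention {convention!r}")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_sample_metadata(meta_path: str | Path) -> pd.DataFrame:
    """Read the sample metadata TSV (sample_id, date_bp, region, is_modern)."""
    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "date_bp"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    try:
        meta["date_bp"] = pd.to_numeric(meta["date_bp"], errors="raise")
    except (ValueError, TypeError):
        bad = pd.to_numeric(meta["date_bp"], errors="coerce")
        lines = (np.flatnonzero(bad.isna()) + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"malformed date_bp at line(s) {lines} of {meta_path}")
    if "is_modern" not in meta.columns:
        meta["is_modern"] = meta["date_bp"] == 0
    meta["is_modern"] = meta["is_modern"].astype(bool)
    if "region" not in meta.columns:
        meta["region"] = pd.NA
    _validate_samples(meta)
    return meta[SAMPLE_COLUMNS]


def read_cohort(vcf_path: str | Path, meta_path: str | Path) -> CohortGenotypes:
    """Read a VCF (GT and/or DS) plus sample metadata into a cohort.

    Samples are intersected by id between the VCF and the metadata; a
    VCF sample absent from the metadata is an error. Variants are
    ordered by (chrom, pos). Missing genotypes become ``NaN``.
    """
    from cyvcf2 import VCF

    meta = read_sample_metadata(meta_path)
    vcf = VCF(str(vcf_path))
    vcf_samples = list(vcf.samples)
    known = set(meta["sample_id"])
    unknown = [s for s in vcf_samples if s not in known]
    if unknown:
        raise ValueError(f"VCF samples absent from metadata: {unknown}")

    rows = []
    dosages = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            logger.warning("skipping non-biallelic record at %s:%d", rec.CHROM, rec.POS)
            continue
        ds = None
        try:
            ds_field = rec.format("DS")
            if ds_field is not None:
                ds = np.asarray(ds_field, dtype=float).reshape(-1)
        except KeyError:
            ds = None
        if ds is None:
            gt = np.asarray(rec.genotype.array(), dtype=float)
            alleles = gt[:, :2]
            ds = np.where((alleles < 0).any(axis=1), np.nan, alleles.clip(min=0).sum(axis=1))
        ds = np.where((ds < 0) | (ds > 2), np.nan, ds)
        dosages.append(ds)
        aa = rec.INFO.get("AA")
        ancestral_is_ref = None
        if aa is not None:
            ancestral_is_ref = str(aa).upper() == str(rec.REF).upper()
        rows.append(
            {
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": rec.ALT[0],
                "ancestral_is_ref": ancestral_is_ref,
                "maf": np.nan,
            }
        )
    if not rows:
        raise ValueError(f"no biallelic variants in {vcf_path}")

    variants = pd.DataFrame(rows)
    G = np.stack(dosages, axis=1)  # samples x variants

    # order samples as in metadata (restricted to those present in the VCF)
    meta_sub = meta[meta["sample_id"].isin(vcf_samples)].reset_index(drop=True)
    pos_in_vcf = {s: i for i, s in enumerate(vcf_samples)}
    G = G[[pos_in_vcf[s] for s in meta_sub["sample_id"]]]

    order = variants.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
    variants = variants.iloc[order].reset_index(drop=True)
    G = G[:, order]
    f = np.nanmean(G, axis=0) / 2.0
    variants["maf"] = np.minimum(f, 1 - f)
    return CohortGenotypes(G, variants, meta_sub)


def read_matrix_cohort(matrix_path: str | Path, meta_path: str | Path) -> CohortGenotypes:
    """Read the plain-matrix dialect: TSV with columns chrom, pos, ref,
    alt then one column per sample id; one variant per row. Missing
    dosages are encoded as ``NA`` or any value outside [0, 2]."""
    meta = read_sample_metadata(meta_path)
    tab = pd.read_csv(matrix_path, sep="\t")
    for col in ("chrom", "pos", "ref", "alt"):
        if col not in tab.columns:
            raise ValueError(f"matrix dialect requires column {col!r}")
    sample_cols = [c for c in tab.columns if c not in ("chrom", "pos", "ref", "alt")]
    unknown = [s for s in sample_cols if s not in set(meta["sample_id"])]
    if unknown:
        raise ValueError(f"matrix samples absent from metadata: {unknown}")
    meta_sub = meta[meta["sample_id"].isin(sample_cols)].reset_index(drop=True)
    G = tab[list(meta_sub["sample_id"])].to_numpy(dtype=float).T
    G = np.where((G < 0) | (G > 2), np.nan, G)
    variants = tab[["chrom", "pos", "ref", "alt"]].copy()
    variants = variants.assign(ancestral_is_ref=None, maf=np.nan)
    order = variants.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
    variants = variants.iloc[order].reset_index(drop=True)
    G = G[:, order]
    f = np.nanmean(G, axis=0) / 2.0
    variants["maf"] = np.minimum(f, 1 - f)
    return CohortGenotypes(G, variants, meta_sub)


def write_matrix_cohort(cohort: CohortGenotypes, matrix_path: str | Path, meta_path: str | Path) -> None:
    """Write a cohort in the matrix dialect plus metadata TSV (round-trips
    hard calls bit-exactly)."""
    tab = cohort.variants[["chrom", "pos", "ref", "alt"]].copy()
    for i, sid in enumerate(cohort.samples["sample_id"]):
        tab[sid] = cohort.G[i, :]
    tab.to_csv(matrix_path, sep="\t", index=False, na_rep="NA")
    cohort.samples[SAMPLE_COLUMNS].to_csv(meta_path, sep="\t", index=False)


def read_gwas(path: str | Path) -> GwasSummary:
    """Read a GWAS summary TSV (id, chrom, pos, effect_allele,
    other_allele, beta, se, p)."""
    return GwasSummary(pd.read_csv(path, sep="\t", dtype={"id": str, "chrom": str}))


def align_gwas(gwas: GwasSummary, cohort: CohortGenotypes) -> GwasSummary:
    """Align GWAS effects to the cohort's tested (ALT) allele.

    Effects whose effect allele is the cohort REF are sign-flipped;
    strand-ambiguous A/T and C/G variants are dropped and counted; rows
    with no matching cohort variant are dropped.
    """
    cohort_v = cohort.variants.assign(_col=np.arange(cohort.n_variants))
    merged = gwas.table.merge(
        cohort_v[["chrom", "pos", "ref", "alt", "_col"]],
        on=["chrom", "pos"],
        how="inner",
        suffixes=("", "_cohort"),
    )
    if merged.empty:
        raise ValueError("no overlapping variants between GWAS and cohort")

    ea = merged["effect_allele"].astype(str).str.upper()
    oa = merged["other_allele"].astype(str).str.upper()
    ref = merged["ref"].astype(str).str.upper()
    alt = merged["alt"].astype(str).str.upper()

    palin = [(a, b) in _PALINDROMIC for a, b in zip(ea, oa)]
    palin = np.asarray(palin)
    n_ambiguous = int(palin.sum())

    same = (ea == alt) & (oa == ref)
    flipped = (ea == ref) & (oa == alt)
    keep = (~palin) & (same | flipped)
    out = merged.loc[keep].copy()
    out.loc[flipped[keep], "beta"] = -out.loc[flipped[keep], "beta"]
    out.loc[flipped[keep], ["effect_allele", "other_allele"]] = out.loc[
        flipped[keep], ["other_allele", "effect_allele"]
    ].to_numpy()
    out = out.drop(columns=["ref", "alt"]).rename(columns={"_col": "cohort_index"})
    logger.info(
        "aligned %d GWAS variants (%d strand-ambiguous dropped)", len(out), n_ambiguous
    )
    return GwasSummary(out.reset_index(drop=True), n_dropped_ambiguous=n_ambiguous)


SCAN_COLUMNS = [
    "chrom", "pos", "ref", "alt", "maf",
    "s_hat", "se_s", "Z", "X", "sigma2", "floor_applied", "converged",
]


def write_scan(table: pd.DataFrame, path: str | Path) -> None:
    """Write a selection-scan result table as TSV."""
    cols = [c for c in SCAN_COLUMNS if c in table.columns]
    table[cols].to_csv(path, sep="\t", index=False)


def read_scan(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
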