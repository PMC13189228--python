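# paleoselect

Directional-selection inference from ancient-DNA time series.

Ancient genomes sampled across thousands of years let us watch allele
frequencies move in real time — but population structure, migration and
admixture move frequencies too. `paleoselect` implements a scan that
separates a sustained directional trend from structured drift, plus the
calibration, trait-level and visualization machinery around it:

- **Per-variant selection scan.** For each variant *j*, cluster-pooled
  allele counts follow a binomial GLMM with logit link,

  ```
  logit(p_ij) = alpha_j + s_j * t_i + g_i,    g ~ MVN(0, sigma_j^2 K)
  ```

  where `t_i` is the (negative) sampling date in units of twice the
  generation interval — so `s_j` is the per-generation selection
  coefficient — and `K` is the cluster-averaged genetic relationship
  matrix (GRM, computed leave-one-chromosome-out). `sigma_j^2` is
  re-estimated per variant with a MAF-conditional lower bound, so drift
  and background selection cannot masquerade as a trend. Fitting is
  penalized quasi-likelihood (`glmm_scan`).
- **Empirical calibration.** Naive Z-scores are rescaled into an
  X-statistic (default `X = Z/1.51`) and mapped to a posterior
  probability of selection / FDR via the enrichment of GWAS hits beyond
  each threshold, conditioned on MAF (`calibration`). Greedy r²-pruned
  independent loci, HAF haplotype scores and background-selection
  residuals live here too.
- **Polygenic trend tests.** Two-step clumping (P < 1e-3, r² < 0.05,
  D' < 0.2 within 500 kb), polygenic scores scaled on modern samples,
  an LMM for the score's change per 10 millennia (gamma), and a
  sign-flip inflation correction `Z_adj = Z / sqrt(lambda)` with
  `lambda = clip(median(Z_rand^2)/0.455, 1, 3.16)` (`polygenic`).
- **Trajectories.** Sliding-window binomial frequency estimates with
  Jeffreys intervals and Gaussian-process smoothing (`trajectories`).
- **Simulator.** Balding–Nichols structured, dated cohorts with drift,
  admixture and injected selection; a GRM-matched single-variant
  generator that is exactly the scan's generative model; power curves;
  null batteries; sweep/neutral haplotype windows (`simulate`).

## Worked example

```python
import numpy as np
from paleoselect import simulate as sim, structure, glmm_scan, calibration

# a structured cohort of 300 ancient + 40 modern samples; variant 0
# carries selection s = 0.03 per generation
cfg = sim.SimulationConfig(n_pops=3, n_samples=300, n_modern=40,
                           n_variants=200, n_chrom=2, fst=0.05,
                           s_values={0: 0.03}, seed=1)
sc = sim.synth_cohort(cfg)

grms = structure.loco_grms(sc.cohort)                      # LOCO GRMs
pcs = structure.top_pcs(structure.compute_grm(sc.cohort), 30)
clusters = structure.cluster_ancestry_date(
    pcs, sc.cohort.dates_bp, list(sc.cohort.samples["sample_id"]),
    target=80, max_gap=500)

table = glmm_scan.scan(sc.cohort, clusters, grms)
table["X"] = calibration.x_statistic(table["Z"].to_numpy())
print(table.loc[0, ["s_hat", "se_s", "Z", "X"]])
```

prints (seed 1)

```
s_hat    0.028707
se_s     0.004285
Z        6.698777
X        4.436276
```

i.e. the injected coefficient is recovered (ŝ = 0.029 ± 0.004 against a
truth of 0.03), the naive trend is 6.7 standard errors from zero, and
after rescaling the calibrated X-statistic is 4.4 — strong but just shy
of the genome-wide significance threshold of 5.45 at this desk-scale
sample size.

The same pipeline is available from the shell:

```bash
paleoselect simulate --n-samples 300 --n-variants 200 --seed 1 --out sim/
paleoselect scan --genotypes sim/genotypes.tsv --meta sim/samples.tsv \
    --target-clusters 80 --out scan/
paleoselect trajectory --genotypes sim/genotypes.tsv --meta sim/samples.tsv \
    --variant 0 --out traj/
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's end-to-end pipeline from scratch — simulates a
structured cohort, builds LOCO GRMs and ancestry-date clusters, runs the
selection scan, calibrates an enrichment curve on a synthetic mixture,
runs the polygenic trend test with sign-flip inflation, and extracts a
frequency trajectory — printing a run summary and writing the results
JSON to `--out`.

## Layout

```
src/paleoselect/
  cohort_io.py     data model, VCF/TSV/GWAS I/O, time conventions
  structure.py     GRM, LOCO, PCA, outliers, ancestry-date clustering
  glmm_scan.py     PQL binomial GLMM, variance floors, scan, windows
  calibration.py   X-statistic, enrichment -> pi/FDR, loci, HAF
  polygenic.py     clumping, PGS, gamma LMM, sign-flip inflation
  trajectories.py  windowed frequencies, GP smoothing, group points
  simulate.py      cohort + variant simulators, power, null battery
  cli.py           `paleoselect` subcommands
```

See `docs/methods.md` for the model details, parameter defaults and
known limitations.
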