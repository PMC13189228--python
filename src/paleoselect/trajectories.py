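"""Allele-frequency trajectories over time.

A trajectory is a moving-average sliding window over sample dates
(default 1000-year windows stepping by 100 years). Within each window
the allele frequency is the binomial MLE from pooled dosages, with
SE = sqrt(p(1-p)/(2n)) and a Jeffreys (Beta(1/2, 1/2) posterior)
credible interval. The windowed means and SEs are optionally smoothed
with a Gaussian process (rational-quadratic kernel, small observation
nugget) and clipped to [0, 1]. Trajectories deliberately apply no
structure correction: they visualize the raw data the GLMM models.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from paleoselect.cohort_io import CohortGenotypes

logger = logging.getLogger(__name__)


@dataclass
class TrajectoryTrack:
    """Windowed frequency series for one variant."""

    table: pd.DataFrame  # center_bp_date, n, freq, se, ci_lo, ci_hi [, smoothed, smoothed_se]
    window_years: float
    step_years: float

    def __post_init__(self) -> None:
        t = self.table
        if not t["center_bp_date"].is_monotonic_increasing:
            raise ValueError("window grid must be strictly ordered")
        for col in ("freq", "ci_lo", "ci_hi"):
            if ((t[col] < -1e-12) | (t[col] > 1 + 1e-12)).any():
                raise ValueError(f"{col} outside [0, 1]")

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _jeffreys_interval(count: float, denom: float, level: float = 0.95) -> tuple[float, float]:
    a = count + 0.5
    b = denom - count + 0.5
    lo = stats.beta.ppf((1 - level) / 2, a, b) if count > 0 else 0.0
    hi = stats.beta.ppf(1 - (1 - level) / 2, a, b) if count < denom else 1.0
    return float(lo), float(hi)


def trajectory(
    cohort: CohortGenotypes,
    variant: int,
    window_years: float = 1000.0,
    step_years: float = 100.0,
    ci_level: float = 0.95,
    smooth: bool = True,
    nugget: float = 1e-4,
    ls_bounds: tuple[float, float] = (10.0, 1e6),
) -> TrajectoryTrack:
    """Windowed binomial frequency track for one variant.

    A sample belongs to the window centered at c if its date lies in
    [c - window/2, c + window/2). Empty windows are omitted.
    """
    g = cohort.G[:, variant]
    dates = cohort.dates_bp
    ok = np.isfinite(g)
    if not ok.any():
        raise ValueError("variant has no non-missing dosages")
    lo, hi = dates[ok].min(), dates[ok].max()
    centers = np.arange(lo, hi + step_years, step_years)

    rows = []
    half = window_years / 2.0
    for c in centers:
        in_win = ok & (dates >= c - half) & (dates < c + half)
        n = int(in_win.sum())
        if n == 0:
            continue
        count = float(g[in_win].sum())
        denom = 2.0 * n
        p = count / denom
        se = float(np.sqrt(p * (1 - p) / denom))
        ci_lo, ci_hi = _jeffreys_interval(count, denom, ci_level)
        rows.append({"center_bp_date": float(c), "n": n, "freq": p, "se": se,
                     "ci_lo": ci_lo, "ci_hi": ci_hi})
    if not rows:
        raise ValueError("no window contains a sample")
    table = pd.DataFrame(rows).sort_values("center_bp_date").reset_index(drop=True)
    track = TrajectoryTrack(table, window_years, step_years)
    if smooth and len(table) >= 3:
        track = gp_smooth(track, nugget=nugget, ls_bounds=ls_bounds)
    return track


def _gp_smooth_xy(
    x: np.ndarray,
    y: np.ndarray,
    nugget: float = 1e-4,
    ls_bounds: tuple[float, float] = (10.0, 1e6),
) -> tuple[np.ndarray, np.ndarray]:
    """GP posterior mean/SD on the observation grid.

    Rational-quadratic kernel under a constant amplitude, observation
    noise ``nugget``; hyperparameters by marginal-likelihood
    maximization from a fixed start (deterministic). On optimizer
    failure the raw series is returned with a warning.
    """
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import ConstantKernel, RationalQuadratic

    x = np.asarray(x, dtype=float).reshape(-1, 1)
    y = np.asarray(y, dtype=float)
    kernel = ConstantKernel(1.0) * RationalQuadratic(
        length_scale=float(np.sqrt(ls_bounds[0] * ls_bounds[1])),
        length_scale_bounds=ls_bounds,
    )
    gp = GaussianProcessRegressor(kernel=kernel, alpha=nugget, normalize_y=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(x, y)
        mean, sd = gp.predict(x, return_std=True)
    except Exception as exc:  # optimizer failure: fall back to raw values
        logger.warning("GP smoothing failed (%s); returning unsmoothed series", exc)
        return y.copy(), np.zeros_like(y)
    return mean, sd


def gp_smooth(
    track: TrajectoryTrack,
    nugget: float = 1e-4,
    ls_bounds: tuple[float, float] = (10.0, 1e6),
) -> TrajectoryTrack:
    """Smooth a track's mean and SE with a GP; clip results to [0, 1]."""
    t = track.table
    if len(t) < 3:
        raise ValueError("need >= 3 grid points to smooth")
    x = t["center_bp_date"].to_numpy()
    mean, _ = _gp_smooth_xy(x, t["freq"].to_numpy(), nugget, ls_bounds)
    se_sm, _ = _gp_smooth_xy(x, t["se"].to_numpy(), nugget, ls_bounds)
    out = t.copy()
    out["smoothed"] = np.clip(mean, 0.0, 1.0)
    out["smoothed_se"] = np.clip(se_sm, 0.0, None)
    return TrajectoryTrack(out, track.window_years, track.step_years)


def group_frequencies(
    cohort: CohortGenotypes,
    variant: int,
    groups: dict[str, list[str]],
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Binomial frequency point estimate + Jeffreys CI per named sample
    group (e.g. archaeologically defined source populations)."""
    ids = {s: i for i, s in enumerate(cohort.samples["sample_id"])}
    g = cohort.G[:, variant]
    rows = []
    for name, members in groups.items():
        if not members:
            raise ValueError(f"group {name!r} is empty")
        unknown = [m for m in members if m not in ids]
        if unknown:
            raise ValueError(f"group {name!r} has unknown samples: {unknown}")
        idx = np.array([ids[m] for m in members])
        vals = g[idx]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            rows.append({"group": name, "n": 0, "freq": np.nan,
                         "ci_lo": np.nan, "ci_hi": np.nan})
            continue
        denom = 2.0 * vals.size
        count = float(vals.sum())
        lo, hi = _jeffreys_interval(count, denom, ci_level)
        rows.append({"group": name, "n": int(vals.size), "freq": count / denom,
                     "ci_lo": lo, "ci_hi": hi})
    return pd.DataFrame(rows)


def plot_trajectory(track: TrajectoryTrack, ax=None, label: str | None = None):
    """Plot a trajectory (raw windowed means with CI band, smoothed line)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.5))
    t = track.table
    ax.fill_between(t["center_bp_date"], t["ci_lo"], t["ci_hi"], alpha=0.2)
    ax.plot(t["center_bp_date"], t["freq"], ".", ms=4, alpha=0.6)
    if "smoothed" in t.columns:
        ax.plot(t["center_bp_date"], t["smoothed"], "-", lw=2, label=label)
    ax.set_xlabel("date (years BP)")
    ax.set_ylabel("allele frequency")
    ax.set_ylim(0, 1)
    ax.invert_xaxis()
    if label:
        ax.legend()
    return ax
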