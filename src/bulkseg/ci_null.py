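"""Monte-Carlo null distribution of delta SNP-index and confidence bands.

Under the null (no linked locus) each bulk is an independent draw of
``bulk_size`` F2 genotypes with probabilities (1/4, 1/2, 1/4); the bulk's
true female-allele frequency is (2*n_PP + n_PH) / (2*bulk_size) and reads
are Binomial(depth, freq).  The two-sided band at a confidence level is the
pair of ((1-level)/2, 1-(1-level)/2) quantiles of the simulated delta,
tabulated per depth — thresholds shrink as depth grows because read
sampling noise shrinks, while the bulk-composition noise floor remains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

F2_GENOTYPE_PROBS = (0.25, 0.5, 0.25)  # PP, PH, HH


@dataclass(frozen=True)
class NullParams:
    bulk_size: int = 30
    n_reps: int = 10_000
    levels: tuple[float, ...] = (0.95, 0.99)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 1000:
            raise ValueError("n_reps must be >= 1000 for stable quantiles")
        if not all(0 < lv < 1 for lv in self.levels):
            raise ValueError("levels must lie in (0, 1)")


def simulate_null_delta(
    params: NullParams, depth: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """n_reps null deltas at one read depth (same depth in both bulks).

    Bulk composition is re-drawn every replicate: the null models both the
    multinomial sampling of which F2 plants enter each bulk and the binomial
    sampling of reads from the pooled DNA.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(params.seed) if rng is None else rng
    counts = rng.multinomial(params.bulk_size, F2_GENOTYPE_PROBS,
                             size=(params.n_reps, 2))
    freq = (2 * counts[..., 0] + counts[..., 1]) / (2 * params.bulk_size)
    alt = rng.binomial(depth, freq)
    idx = alt / depth
    return idx[:, 0] - idx[:, 1]


def _calibrated_cut(samples: np.ndarray, tail: float) -> float:
    """Upper cut point whose strict null exceedance is closest to ``tail``.

    Delta at finite depth is discrete (a lattice of read-count differences),
    so a plain interpolated quantile systematically under-covers the nominal
    exceedance when compared with strict inequality.  Instead the cut is
    placed midway between the adjacent attainable values whose empirical
    tail probability is nearest the target.
    """
    v = np.unique(samples)
    cum = np.searchsorted(np.sort(samples), v, side="right")
    exceed = 1.0 - cum / len(samples)          # P(X > v[j])
    j = int(np.argmin(np.abs(exceed - tail)))
    above = v[j + 1] if j + 1 < len(v) else v[j] + np.finfo(float).eps
    return float((v[j] + above) / 2)


def _calibrated_band(samples: np.ndarray, level: float) -> tuple[float, float]:
    a = (1 - level) / 2
    upper = _calibrated_cut(samples, a)
    lower = -_calibrated_cut(-samples, a)
    return lower, upper


def simulate_null_sites(
    params: NullParams, mean_depth: float, n_sites: int,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Independent no-signal sites in the per-site index-table layout.

    Each site draws its own read depth (Poisson, shared by both bulks, floored
    at 1) and its own pair of independent bulk compositions — the exact model
    the threshold table is built from, for calibration checks.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    depth = np.maximum(rng.poisson(mean_depth, size=n_sites), 1)
    counts = rng.multinomial(params.bulk_size, F2_GENOTYPE_PROBS, size=(n_sites, 2))
    freq = (2 * counts[..., 0] + counts[..., 1]) / (2 * params.bulk_size)
    alt = rng.binomial(depth[:, None], freq)
    idx = alt / depth[:, None]
    return pd.DataFrame({
        "chrom": "null", "pos": np.arange(1, n_sites + 1),
        "depth_low": depth, "depth_high": depth,
        "index_low": idx[:, 0], "index_high": idx[:, 1],
        "delta": idx[:, 0] - idx[:, 1],
    })


def build_threshold_table(params: NullParams, depths: list[int]) -> pd.DataFrame:
    """Tabulate (lower, upper) null cut points per depth and confidence level."""
    rng = np.random.default_rng(params.seed)
    rows = []
    for depth in sorted(depths):
        deltas = simulate_null_delta(params, depth, rng)
        for level in params.levels:
            lower, upper = _calibrated_band(deltas, level)
            rows.append({"depth": depth, "level": level,
                         "lower": lower, "upper": upper})
    return pd.DataFrame(rows)


def threshold_at(
    table: pd.DataFrame, depth: float, level: float
) -> tuple[float, float]:
    """Band at an arbitrary depth, linearly interpolated between tabulated depths.

    Depths below the smallest tabulated depth clamp to it with a warning;
    above the largest they clamp silently (the band only narrows with depth).
    """
    sub = table[np.isclose(table["level"], level)].sort_values("depth")
    if sub.empty:
        raise KeyError(f"level {level} not tabulated")
    d = sub["depth"].to_numpy(dtype=float)
    if depth < d[0]:
        warnings.warn(
            f"depth {depth} below smallest tabulated depth {d[0]:.0f}; clamping",
            stacklevel=2,
        )
    lower = float(np.interp(depth, d, sub["lower"].to_numpy()))
    upper = float(np.interp(depth, d, sub["upper"].to_numpy()))
    return lower, upper


def thresholds_for_depths(
    table: pd.DataFrame, depths: np.ndarray, level: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized threshold_at over an array of site depths."""
    sub = table[np.isclose(table["level"], level)].sort_values("depth")
    if sub.empty:
        raise KeyError(f"level {level} not tabulated")
    d = sub["depth"].to_numpy(dtype=float)
    lower = np.interp(depths, d, sub["lower"].to_numpy())
    upper = np.interp(depths, d, sub["upper"].to_numpy())
    return lower, upper
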