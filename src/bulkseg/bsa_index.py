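"""Per-site SNP-index, delta SNP-index, and sliding-window averages.

The SNP-index of a bulk at a site is the fraction of its reads carrying the
female-parent allele (the alt allele under this package's polarization);
delta is the low-bulk index minus the high-bulk index, so a recessive locus
fixed in the low bulk produces a positive peak (low bulk -> 1, high bulk ->
1/3 in an F2).  Window means are unweighted averages over member sites,
plotted over 1 Mb windows advanced in 50 kb steps by default.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def snp_index(ad_ref: int, ad_alt: int) -> float:
    """Fraction of reads carrying the alt (female-parent) allele."""
    total = ad_ref + ad_alt
    if total <= 0:
        raise ValueError("snp_index undefined at zero depth; exclude the site upstream")
    return ad_alt / total


def delta_index(index_low: float, index_high: float, sign: int = 1) -> float:
    """index_low - index_high (optionally flipped via sign=-1)."""
    return sign * (index_low - index_high)


def compute_indices(
    df: pd.DataFrame,
    bulk_low: str = "K21",
    bulk_high: str = "K5",
    parents: tuple[str, str] = ("KF", "KM"),
    require_informative: bool = True,
    delta_sign: int = 1,
) -> pd.DataFrame:
    """Per-site index table (chrom, pos, depths, indices, delta).

    Sites with zero depth in either bulk are excluded (no data).  When
    parental genotypes are present and ``require_informative`` is set, sites
    where the parents are not opposite homozygotes are dropped as
    uninformative; where the female parent is homozygous *reference* the
    polarity is flipped so the index always counts the female-parent allele.
    """
    female, male = parents
    dl = (df[f"{bulk_low}_ad_ref"] + df[f"{bulk_low}_ad_alt"]).to_numpy()
    dh = (df[f"{bulk_high}_ad_ref"] + df[f"{bulk_high}_ad_alt"]).to_numpy()
    keep = (dl > 0) & (dh > 0)

    alt_is_female = np.ones(len(df), dtype=bool)
    if f"{female}_gt" in df.columns and f"{male}_gt" in df.columns:
        fgt = df[f"{female}_gt"].to_numpy()
        mgt = df[f"{male}_gt"].to_numpy()
        fwd = (fgt == "1/1") & (mgt == "0/0")
        rev = (fgt == "0/0") & (mgt == "1/1")
        alt_is_female = fwd
        if require_informative:
            keep &= fwd | rev
        alt_is_female = np.where(rev, False, alt_is_female)

    sub = df[keep]
    dl, dh = dl[keep], dh[keep]
    alt_is_female = alt_is_female[keep]
    alt_l = sub[f"{bulk_low}_ad_alt"].to_numpy()
    alt_h = sub[f"{bulk_high}_ad_alt"].to_numpy()
    idx_l = np.where(alt_is_female, alt_l / dl, 1 - alt_l / dl)
    idx_h = np.where(alt_is_female, alt_h / dh, 1 - alt_h / dh)
    return pd.DataFrame({
        "chrom": sub["chrom"].to_numpy(),
        "pos": sub["pos"].to_numpy(),
        "depth_low": dl,
        "depth_high": dh,
        "index_low": idx_l,
        "index_high": idx_h,
        "delta": delta_sign * (idx_l - idx_h),
    })


def make_windows(
    chrom_length: int, window_bp: int = 1_000_000, step_bp: int = 50_000
) -> list[tuple[int, int]]:
    """Sliding windows (1-based inclusive) covering every base of a chromosome.

    Starts are 1, 1+step, 1+2*step, ...; each window spans ``window_bp``
    bases, truncated at the chromosome end.
    """
    if chrom_length < 1:
        raise ValueError("chrom_length must be >= 1")
    if not window_bp >= step_bp >= 1:
        raise ValueError("require window_bp >= step_bp >= 1")
    return [
        (start, min(start + window_bp - 1, chrom_length))
        for start in range(1, chrom_length + 1, step_bp)
    ]


def window_average(
    sites: pd.DataFrame,
    chrom_lengths: dict[str, int],
    window_bp: int = 1_000_000,
    step_bp: int = 50_000,
) -> pd.DataFrame:
    """Unweighted per-window means of both indices and delta.

    ``sites`` is a compute_indices table.  Windows with no member sites get
    NaN means and n_variants = 0.
    """
    rows = []
    for chrom, length in chrom_lengths.items():
        sub = sites[sites["chrom"] == chrom].sort_values("pos")
        pos = sub["pos"].to_numpy()
        arrays = {c: sub[c].to_numpy() for c in ("index_low", "index_high", "delta")}
        for start, end in make_windows(length, window_bp, step_bp):
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="right")
            n = hi - lo
            row = {"chrom": chrom, "start": start, "end": end, "n_variants": int(n)}
            for name, key in (("mean_index_low", "index_low"),
                              ("mean_index_high", "index_high"),
                              ("mean_delta", "delta")):
                row[name] = float(arrays[key][lo:hi].mean()) if n else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def plot_index_tracks(
    sites: pd.DataFrame,
    windows: pd.DataFrame,
    thresholds: pd.DataFrame | None,
    path: str | Path,
    chrom: str | None = None,
) -> None:
    """Three-panel track plot: low-bulk index, high-bulk index, delta.

    Horizontal lines on the delta panel mark the tabulated confidence bands
    (at the median tabulated depth) when a threshold table is given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if chrom is None:
        chrom = sites["chrom"].iloc[0]
    s = sites[sites["chrom"] == chrom]
    w = windows[windows["chrom"] == chrom]
    mid = (w["start"] + w["end"]) / 2
    fig, axes = plt.subplots(3, 1, figsize=(10, 7), sharex=True)
    panels = [("index_low", "mean_index_low", "SNP-index (low bulk)"),
              ("index_high", "mean_index_high", "SNP-index (high bulk)"),
              ("delta", "mean_delta", "delta SNP-index")]
    for ax, (scol, wcol, label) in zip(axes, panels):
        ax.plot(s["pos"] / 1e6, s[scol], ".", ms=2, alpha=0.3, color="grey")
        ax.plot(mid / 1e6, w[wcol], "-", color="crimson", lw=1.5)
        ax.set_ylabel(label)
    if thresholds is not None and len(thresholds):
        med_depth = thresholds["depth"].median()
        for level, color in ((0.95, "green"), (0.99, "gold")):
            t = thresholds[(thresholds["level"] == level)
                           & (thresholds["depth"] == med_depth)]
            for _, r in t.iterrows():
                axes[2].axhline(r["upper"], color=color, lw=1)
                axes[2].axhline(r["lower"], color=color, lw=1)
    axes[2].axhline(0, color="black", lw=0.5)
    axes[2].set_xlabel(f"{chrom} position (Mb)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
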