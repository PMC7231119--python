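"""Candidate-region calling from above-threshold delta SNP-index sites.

Sites whose delta exceeds the (by default upper, one-sided) 99% confidence
threshold at their depth are clustered per chromosome: neighbours within
``merge_gap_bp`` join one region, whose bounds are the outermost member
sites.  Coordinates are 1-based inclusive; the span of (start, end) is
end - start + 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ci_null import thresholds_for_depths


def region_span(start: int, end: int) -> int:
    """Inclusive 1-based span in bp; e.g. (5999388, 6856630) -> 857243."""
    if start > end:
        raise ValueError(f"start {start} > end {end}")
    return end - start + 1


@dataclass
class CandidateRegion:
    chrom: str
    start: int
    end: int
    n_sites: int
    mean_delta: float
    max_delta: float
    sites: pd.DataFrame = field(repr=False, default=None)

    @property
    def span_bp(self) -> int:
        return region_span(self.start, self.end)

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos <= self.end


def above_threshold(
    sites: pd.DataFrame,
    thresholds: pd.DataFrame,
    level: float = 0.99,
    two_sided: bool = False,
) -> pd.Series:
    """Boolean mask of sites exceeding the band at their own depth.

    The lookup depth is the smaller of the two bulk depths (conservative:
    the noisier bulk sets the band).  One-sided by default — the recessive
    design puts the causal excursion on the positive side.
    """
    depth = np.minimum(sites["depth_low"].to_numpy(), sites["depth_high"].to_numpy())
    lower, upper = thresholds_for_depths(thresholds, depth, level)
    delta = sites["delta"].to_numpy()
    mask = delta > upper
    if two_sided:
        mask |= delta < lower
    return pd.Series(mask, index=sites.index)


def call_regions(
    sites: pd.DataFrame,
    thresholds: pd.DataFrame,
    level: float = 0.99,
    merge_gap_bp: int = 1_000_000,
    two_sided: bool = False,
) -> list[CandidateRegion]:
    """Cluster above-threshold sites into candidate regions (see module doc)."""
    hits = sites[above_threshold(sites, thresholds, level, two_sided)]
    regions: list[CandidateRegion] = []
    for chrom, sub in hits.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > merge_gap_bp) + 1
        for chunk in np.split(np.arange(len(pos)), breaks):
            members = sub.iloc[chunk]
            regions.append(CandidateRegion(
                chrom=chrom,
                start=int(members["pos"].min()),
                end=int(members["pos"].max()),
                n_sites=len(members),
                mean_delta=float(members["delta"].mean()),
                max_delta=float(members["delta"].max()),
                sites=members.reset_index(drop=True),
            ))
    return regions


def top_region(regions: list[CandidateRegion]) -> CandidateRegion | None:
    """The region with the highest mean delta among its member sites."""
    return max(regions, key=lambda r: r.mean_delta) if regions else None


def write_regions(
    regions: list[CandidateRegion], tsv_path: str | Path, bed_path: str | Path | None = None
) -> None:
    rows = [{"chrom": r.chrom, "start": r.start, "end": r.end, "span_bp": r.span_bp,
             "n_sites": r.n_sites, "mean_delta": r.mean_delta, "max_delta": r.max_delta}
            for r in regions]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "span_bp",
                                "n_sites", "mean_delta", "max_delta"]
                 ).to_csv(tsv_path, sep="\t", index=False)
    if bed_path is not None:
        lines = ["# BED6: 0-based half-open (internal coordinates are 1-based inclusive)"]
        for i, r in enumerate(regions):
            score = min(1000, int(round(1000 * abs(r.mean_delta))))
            lines.append(f"{r.chrom}\t{r.start - 1}\t{r.end}\tregion{i + 1}\t{score}\t+")
        Path(bed_path).write_text("\n".join(lines) + "\n")
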