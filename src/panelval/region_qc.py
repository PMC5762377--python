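"""Per-region capture performance, GC diagnostics and sample-level QC.

Hybrid-capture panels lose depth in GC-rich targets (inefficient
hybridization and amplification), so the first validation question is
which of the panel's regions reliably reach depth.  A region is called
*underperforming* when its log2 mean depth falls more than two standard
deviations below the cohort log2 mean:

    fail  iff  log2(depth) < mean(log2 depths) - 2 * SD(log2 depths)

The SD is the sample SD (n-1 denominator); zero-depth regions fail
unconditionally and are excluded from the moments.  By default the rule
runs on per-region depths averaged across the cohort's samples; a
per-sample mode flags the union of per-sample failures instead.

Sample-level metrics mirror standard capture QC: total reads, % mapped,
% duplicates (of mapped), % unique bases on target, mean deduplicated
depth, and % of targeted positions at or above fixed depth thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PanelRegion",
    "RegionDepth",
    "SampleQC",
    "InsufficientDataError",
    "gc_fraction",
    "flag_underperforming",
    "coverage_at_thresholds",
    "sample_qc",
    "read_bed",
    "write_bed",
    "read_depth_track",
    "read_region_depth_tsv",
    "write_region_depth_tsv",
    "gc_barplot",
]


class InsufficientDataError(ValueError):
    """Too few informative regions to estimate the depth distribution."""


@dataclass(frozen=True)
class PanelRegion:
    """One captured interval (0-based half-open) with its gene and GC."""

    chrom: str
    start: int
    end: int
    gene: str = ""
    gc_fraction: float = float("nan")

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        gc = self.gc_fraction
        if gc == gc and not 0.0 <= gc <= 1.0:
            raise ValueError("gc_fraction must lie in [0, 1]")

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RegionDepth:
    """Mean depth of one region in one sample."""

    region: PanelRegion
    sample_id: str
    mean_depth: float

    def __post_init__(self) -> None:
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be non-negative")


@dataclass
class SampleQC:
    """Capture QC metrics for one sample; percentages on a 0-100 scale."""

    sample_id: str
    total_reads: int
    pct_mapped: float
    pct_duplicates: float
    pct_unique_on_target: float
    mean_depth: float
    pct_positions_ge: dict[int, float]


def gc_fraction(seq: str) -> float:
    """(#G + #C) / (#A + #C + #G + #T); N bases are excluded entirely."""
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    counts = {b: seq.count(b) for b in "ACGTN"}
    if len(seq) != sum(counts.values()):
        raise ValueError("sequence contains symbols outside {A,C,G,T,N}")
    denom = len(seq) - counts["N"]
    if denom == 0:
        raise ValueError("sequence is all N: GC content undefined")
    return (counts["G"] + counts["C"]) / denom


def _flags_for(depths: np.ndarray) -> np.ndarray:
    positive = depths > 0
    if positive.sum() < 3:
        raise InsufficientDataError(
            f"need >= 3 regions with positive depth, got {int(positive.sum())}"
        )
    log2 = np.log2(depths[positive])
    threshold = log2.mean() - 2.0 * log2.std(ddof=1)
    fails = np.zeros(len(depths), dtype=bool)
    fails[~positive] = True
    fails[positive] = np.log2(depths[positive]) < threshold
    return fails


def flag_underperforming(
    depths: Sequence[RegionDepth],
    mode: str = "cohort_mean",
) -> pd.DataFrame:
    """Classify regions as passing or underperforming by the 2-SD log2 rule.

    ``mode='cohort_mean'`` (default) averages each region's depth across
    the cohort's samples before applying the rule once; ``mode='per_sample'``
    applies the rule within each sample and fails a region if it fails in
    any sample.  Returns a DataFrame with columns region, gene,
    gc_fraction, mean_depth, fail.
    """
    if mode not in ("cohort_mean", "per_sample"):
        raise ValueError(f"unknown mode {mode!r}")
    frame = pd.DataFrame(
        {
            "region": [d.region.name for d in depths],
            "gene": [d.region.gene for d in depths],
            "gc_fraction": [d.region.gc_fraction for d in depths],
            "sample_id": [d.sample_id for d in depths],
            "depth": [d.mean_depth for d in depths],
        }
    )
    per_region = (
        frame.groupby("region", sort=False)
        .agg(gene=("gene", "first"), gc_fraction=("gc_fraction", "first"),
             mean_depth=("depth", "mean"))
        .reset_index()
    )
    if mode == "cohort_mean":
        per_region["fail"] = _flags_for(per_region["mean_depth"].to_numpy(float))
    else:
        failed: set[str] = set()
        for _, sample_frame in frame.groupby("sample_id", sort=False):
            flags = _flags_for(sample_frame["depth"].to_numpy(float))
            failed.update(sample_frame.loc[flags, "region"])
        per_region["fail"] = per_region["region"].isin(failed)
    return per_region


def coverage_at_thresholds(
    depth_track: Mapping[str, np.ndarray] | pd.DataFrame,
    regions: Sequence[PanelRegion],
    thresholds: Sequence[int] = (50, 100, 250),
) -> dict[int, float]:
    """Percentage of targeted positions with depth >= each threshold.

    ``depth_track`` is either a mapping chrom -> per-base depth array
    (index 0 = position 1) or a samtools-depth-style DataFrame with
    columns chrom, pos (1-based), depth; positions absent from the track
    count as depth 0.
    """
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be ascending")
    if not regions:
        raise ValueError("empty target")

    if isinstance(depth_track, pd.DataFrame):
        track: dict[str, np.ndarray] = {}
        for chrom, sub in depth_track.groupby("chrom", sort=False):
            size = int(sub["pos"].max())
            arr = np.zeros(size, dtype=float)
            arr[sub["pos"].to_numpy(int) - 1] = sub["depth"].to_numpy(float)
            track[str(chrom)] = arr
    else:
        track = {k: np.asarray(v, dtype=float) for k, v in depth_track.items()}

    targeted: list[np.ndarray] = []
    for region in regions:
        arr = track.get(region.chrom)
        if arr is None:
            targeted.append(np.zeros(region.length))
            continue
        piece = arr[region.start:region.end]
        if len(piece) < region.length:
            piece = np.pad(piece, (0, region.length - len(piece)))
        targeted.append(piece)
    depths = np.concatenate(targeted)
    return {t: 100.0 * float((depths >= t).mean()) for t in thresholds}


def sample_qc(
    sample_id: str,
    total_reads: int,
    mapped_reads: int,
    duplicate_reads: int,
    on_target_unique_bases: int,
    total_unique_bases: int,
    depth_track: Mapping[str, np.ndarray] | pd.DataFrame,
    regions: Sequence[PanelRegion],
    thresholds: Sequence[int] = (50, 100, 250),
) -> SampleQC:
    """Assemble per-sample QC metrics on the standard denominators.

    % mapped = mapped/total; % duplicates = duplicates/mapped; % unique on
    target = on-target unique bases / all unique bases; mean depth and the
    threshold coverages come from the deduplicated depth track over the
    panel target.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if mapped_reads > total_reads:
        raise ValueError("mapped_reads cannot exceed total_reads")
    if duplicate_reads > mapped_reads:
        raise ValueError("duplicate_reads cannot exceed mapped_reads")

    pct_at = coverage_at_thresholds(depth_track, regions, thresholds)
    # mean depth over targeted positions
    all_depths: list[np.ndarray] = []
    if isinstance(depth_track, pd.DataFrame):
        expanded: dict[str, np.ndarray] = {}
        for chrom, sub in depth_track.groupby("chrom", sort=False):
            size = int(sub["pos"].max())
            arr = np.zeros(size, dtype=float)
            arr[sub["pos"].to_numpy(int) - 1] = sub["depth"].to_numpy(float)
            expanded[str(chrom)] = arr
        source = expanded
    else:
        source = {k: np.asarray(v, dtype=float) for k, v in depth_track.items()}
    for region in regions:
        arr = source.get(region.chrom)
        piece = np.zeros(region.length) if arr is None else arr[region.start:region.end]
        if len(piece) < region.length:
            piece = np.pad(piece, (0, region.length - len(piece)))
        all_depths.append(piece)
    mean_depth = float(np.concatenate(all_depths).mean())

    pct_unique_on_target = (
        100.0 * on_target_unique_bases / total_unique_bases if total_unique_bases else 0.0
    )
    return SampleQC(
        sample_id=sample_id,
        total_reads=total_reads,
        pct_mapped=100.0 * mapped_reads / total_reads,
        pct_duplicates=100.0 * duplicate_reads / mapped_reads if mapped_reads else 0.0,
        pct_unique_on_target=pct_unique_on_target,
        mean_depth=mean_depth,
        pct_positions_ge=pct_at,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[PanelRegion]:
    """Read a BED file (chrom, start, end[, gene[, gc_fraction]])."""
    frame = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "gene", "gc_fraction"],
        dtype={"chrom": str}, usecols=range(5), engine="python",
    )
    regions = []
    for row in frame.itertuples(index=False):
        gc = row.gc_fraction
        regions.append(
            PanelRegion(
                chrom=row.chrom, start=int(row.start), end=int(row.end),
                gene="" if pd.isna(row.gene) else str(row.gene),
                gc_fraction=float("nan") if pd.isna(gc) else float(gc),
            )
        )
    return regions


def write_bed(regions: Sequence[PanelRegion], path: str | Path) -> None:
    with open(path, "w") as handle:
        for r in regions:
            gc = f"{r.gc_fraction:.4f}" if r.gc_fraction == r.gc_fraction else "."
            handle.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene}\t{gc}\n")


def read_depth_track(path: str | Path) -> pd.DataFrame:
    """Read a samtools-depth-style TSV (chrom, 1-based pos, depth)."""
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "pos", "depth"], dtype={"chrom": str})


def read_region_depth_tsv(
    path: str | Path, regions: Sequence[PanelRegion], sample_id: str = ""
) -> list[RegionDepth]:
    """Read a per-region depth TSV (chrom, start, end, mean_depth)."""
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    lookup = {(r.chrom, r.start, r.end): r for r in regions}
    out = []
    for row in frame.itertuples(index=False):
        key = (row.chrom, int(row.start), int(row.end))
        region = lookup.get(key)
        if region is None:
            region = PanelRegion(chrom=row.chrom, start=int(row.start), end=int(row.end))
        out.append(RegionDepth(region=region, sample_id=sample_id,
                               mean_depth=float(row.mean_depth)))
    return out


def write_region_depth_tsv(depths: Sequence[RegionDepth], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {"chrom": d.region.chrom, "start": d.region.start, "end": d.region.end,
             "gene": d.region.gene, "mean_depth": d.mean_depth}
            for d in depths
        ]
    )
    frame.to_csv(path, sep="\t", index=False)


def gc_barplot(performance: pd.DataFrame, path: str | Path) -> None:
    """Bar plot of region GC ordered low-to-high, failing regions in red."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = performance.sort_values("gc_fraction").reset_index(drop=True)
    colors = np.where(ordered["fail"], "crimson", "steelblue")
    fig, ax = plt.subplots(figsize=(12, 3))
    ax.bar(range(len(ordered)), ordered["gc_fraction"], width=1.0, color=colors)
    ax.set_xlabel("panel regions (ordered by GC content)")
    ax.set_ylabel("GC fraction")
    ax.set_title("Region GC content; underperforming regions highlighted")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
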