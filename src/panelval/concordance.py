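"""Paired FFPE-vs-fresh-frozen call-set concordance.

Formalin fixation degrades DNA and introduces deamination artefacts, so
the same tumour sequenced from an FFPE block and a fresh-frozen (FF)
piece yields overlapping but not identical call sets — most of the
disagreement sits below or near the assay's 5% VAF detection floor.
This module partitions each pair's variant union into shared, FF-only
and FFPE-only, stratifies the unique calls by VAF (<5%, 5-10%, >=10%),
and correlates the VAFs of the shared calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .validation_stats import CorrelationResult, percent, vaf_correlation
from .variants import Variant

__all__ = [
    "PairedVariantTable",
    "build_pairs",
    "discordance_breakdown",
    "paired_vaf_correlation",
    "read_manifest",
    "scatter_plot",
]

DEFAULT_VAF_BINS = (0.05, 0.10)


@dataclass
class PairedVariantTable:
    """Union of variant keys across pairs with per-source VAFs.

    ``frame`` columns: sample_pair_id, chrom, pos, ref, alt, vaf_ffpe,
    vaf_ff (NaN marks absence from that source; every row has at least
    one VAF present).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        both_absent = self.frame["vaf_ffpe"].isna() & self.frame["vaf_ff"].isna()
        if both_absent.any():
            raise ValueError("every row needs a VAF from at least one source")


def read_manifest(path: str | Path) -> list[tuple[str, str]]:
    """Read a pairing manifest TSV with columns ffpe_sample, ff_sample."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return [(row.ffpe_sample, row.ff_sample) for row in frame.itertuples(index=False)]


def build_pairs(
    calls_ffpe: Mapping[str, Sequence[Variant]],
    calls_ff: Mapping[str, Sequence[Variant]],
    manifest: Sequence[tuple[str, str]],
) -> PairedVariantTable:
    """Join per-sample call lists into one paired variant table.

    ``manifest`` maps each FFPE sample to exactly one FF sample; a sample
    named in the manifest but missing from the call sets is an error.
    Calls are assumed normalized.
    """
    rows: list[dict] = []
    for ffpe_id, ff_id in manifest:
        if ffpe_id not in calls_ffpe:
            raise ValueError(f"manifest FFPE sample {ffpe_id!r} has no call set")
        if ff_id not in calls_ff:
            raise ValueError(f"manifest FF sample {ff_id!r} has no call set")
        pair_id = f"{ffpe_id}|{ff_id}"
        ffpe = {v.key: v.vaf for v in calls_ffpe[ffpe_id]}
        ff = {v.key: v.vaf for v in calls_ff[ff_id]}
        for key in sorted(set(ffpe) | set(ff)):
            chrom, pos, ref, alt = key
            rows.append(
                {
                    "sample_pair_id": pair_id, "chrom": chrom, "pos": pos,
                    "ref": ref, "alt": alt,
                    "vaf_ffpe": ffpe.get(key, np.nan),
                    "vaf_ff": ff.get(key, np.nan),
                }
            )
    frame = pd.DataFrame(
        rows,
        columns=["sample_pair_id", "chrom", "pos", "ref", "alt", "vaf_ffpe", "vaf_ff"],
    )
    return PairedVariantTable(frame=frame)


def _stratify(vafs: np.ndarray, bins: tuple[float, float]) -> dict[str, int]:
    low, high = bins
    return {
        f"below_{low:g}": int((vafs < low).sum()),
        f"{low:g}_to_{high:g}": int(((vafs >= low) & (vafs < high)).sum()),
        f"at_least_{high:g}": int((vafs >= high).sum()),
    }


def discordance_breakdown(
    table: PairedVariantTable,
    vaf_bins: tuple[float, float] = DEFAULT_VAF_BINS,
) -> dict:
    """Shared / FF-only / FFPE-only partition with VAF stratification.

    Within each unique set the present-source VAF is stratified into
    (<5%), [5-10%), (>=10%) by default; percentages are reported to one
    decimal.
    """
    if sorted(vaf_bins) != list(vaf_bins) or not all(0 < b < 1 for b in vaf_bins):
        raise ValueError("vaf_bins must be ascending inside (0, 1)")
    frame = table.frame
    if frame.empty:
        raise ValueError("empty paired table")

    ff_only = frame[frame["vaf_ffpe"].isna()]
    ffpe_only = frame[frame["vaf_ff"].isna()]
    shared = frame[frame["vaf_ffpe"].notna() & frame["vaf_ff"].notna()]
    union = len(frame)

    def unique_block(sub: pd.DataFrame, column: str) -> dict:
        vafs = sub[column].to_numpy(float)
        strata = _stratify(vafs, vaf_bins)
        n = len(sub)
        return {
            "count": n,
            "pct_of_union": percent(n / union),
            "vaf_strata": strata,
            "vaf_strata_pct": {
                k: (percent(v / n) if n else None) for k, v in strata.items()
            },
        }

    return {
        "union": union,
        "shared": {"count": len(shared), "pct_of_union": percent(len(shared) / union)},
        "ff_only": unique_block(ff_only, "vaf_ff"),
        "ffpe_only": unique_block(ffpe_only, "vaf_ffpe"),
    }


def paired_vaf_correlation(
    table: PairedVariantTable,
    alpha: float = 0.05,
    include_absent_as_zero: bool = False,
) -> CorrelationResult:
    """Pearson r^2 of FFPE-vs-FF VAFs over shared variants.

    Variants absent from one source are excluded by default (the
    correlation is over variants found in both members of the pair); the
    ``include_absent_as_zero`` option codes absence as VAF 0 for
    sensitivity analysis.
    """
    frame = table.frame
    if include_absent_as_zero:
        frame = frame.fillna({"vaf_ffpe": 0.0, "vaf_ff": 0.0})
    shared = frame[frame["vaf_ffpe"].notna() & frame["vaf_ff"].notna()]
    if len(shared) < 3:
        raise ValueError("need >= 3 variants shared by both sources")
    pairs = list(zip(shared["vaf_ffpe"], shared["vaf_ff"]))
    return vaf_correlation(pairs, alpha=alpha, label="ffpe-vs-ff")


def scatter_plot(table: PairedVariantTable, path: str | Path) -> None:
    """FFPE-vs-FF VAF scatter of shared variants."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shared = table.frame.dropna(subset=["vaf_ffpe", "vaf_ff"])
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(shared["vaf_ffpe"], shared["vaf_ff"], s=6, alpha=0.4)
    ax.plot([0, 1], [0, 1], color="grey", lw=0.8)
    ax.set_xlabel("VAF (FFPE)")
    ax.set_ylabel("VAF (fresh frozen)")
    ax.set_title("Shared variant allele fractions, FFPE vs FF")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
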