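"""GC-normalized tumour/control depth-ratio copy-number flagging.

Capture depth depends on region GC content, so raw tumour/control depth
ratios confound copy number with GC bias.  Each cohort's per-region
depths are first divided by a GC-trend expectation (median depth within
GC bins of width 0.05, linearly interpolated between bin centres) and
rescaled so the cohort median is exactly 1.  The per-region ratio
tumour/control then flags a potential deletion below 0.65 and a
potential amplification above 2.4; regions with zero control depth are
uncallable and never labelled.

For an event at tumour purity ``p`` and copy number ``CN`` on a diploid
background the expected ratio is ``(p*CN + (1-p)*2) / 2``: a 30-copy
amplification is still flagged at 30% purity (ratio 6.2 -> 5.2 after
accounting for the diploid fraction), while a one-copy arm loss needs
roughly 70% purity to cross 0.65.

Gene-level calls are a majority vote over the gene's regions;
chromosome/arm losses are read off the gene summary of the genes on
that chromosome (no segmentation is attempted at panel scale).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .region_qc import PanelRegion

__all__ = [
    "CnvCall",
    "DEL_THRESHOLD",
    "AMP_THRESHOLD",
    "gc_normalize",
    "call_cnv",
    "gene_level_summary",
    "write_cnv_tsv",
    "write_gene_summary_json",
]

logger = logging.getLogger(__name__)

DEL_THRESHOLD = 0.65
AMP_THRESHOLD = 2.4
_GC_BIN_WIDTH = 0.05


@dataclass
class CnvCall:
    """Per-region tumour/control ratio with its copy-number label."""

    region: PanelRegion
    ratio: float | None
    label: str  # deletion | neutral | amplification | uncallable
    tumour_norm_depth: float
    control_norm_depth: float


def gc_normalize(
    depths: Sequence[float],
    gc: Sequence[float],
    bin_width: float = _GC_BIN_WIDTH,
) -> np.ndarray:
    """Remove the depth-vs-GC trend and rescale the cohort median to 1.

    The trend is the median depth within GC bins of width ``bin_width``,
    linearly interpolated between occupied bin centres (flat beyond the
    outermost occupied bins).  Requires >= 20 regions so the binned
    medians are estimable.
    """
    depths = np.asarray(depths, dtype=float)
    gc = np.asarray(gc, dtype=float)
    if depths.shape != gc.shape:
        raise ValueError("depths and gc must align region-for-region")
    if len(depths) < 20:
        raise ValueError("need >= 20 regions for GC-trend fitting")
    if not (depths > 0).any():
        raise ValueError("all depths are zero")

    bins = np.floor(gc / bin_width).astype(int)
    centres: list[float] = []
    medians: list[float] = []
    for b in np.unique(bins):
        members = depths[bins == b]
        med = float(np.median(members))
        if med > 0:
            centres.append((b + 0.5) * bin_width)
            medians.append(med)
    if not centres:
        raise ValueError("no GC bin has positive median depth")
    expected = np.interp(gc, centres, medians)
    normalized = depths / expected
    median = float(np.median(normalized[normalized > 0]))
    normalized = normalized / median
    return normalized


def call_cnv(
    regions: Sequence[PanelRegion],
    tumour_norm: Sequence[float],
    control_norm: Sequence[float],
    del_threshold: float = DEL_THRESHOLD,
    amp_threshold: float = AMP_THRESHOLD,
) -> list[CnvCall]:
    """Label each region by its tumour/control normalized depth ratio.

    ratio < del_threshold -> deletion; ratio > amp_threshold ->
    amplification; otherwise neutral.  A zero control depth makes the
    region uncallable (ratio None).
    """
    if del_threshold >= amp_threshold:
        raise ValueError("del_threshold must be below amp_threshold")
    if not (len(regions) == len(tumour_norm) == len(control_norm)):
        raise ValueError("regions, tumour and control must align")
    calls: list[CnvCall] = []
    for region, t, c in zip(regions, tumour_norm, control_norm):
        if c <= 0:
            calls.append(CnvCall(region=region, ratio=None, label="uncallable",
                                 tumour_norm_depth=float(t), control_norm_depth=float(c)))
            continue
        ratio = float(t) / float(c)
        if ratio < del_threshold:
            label = "deletion"
        elif ratio > amp_threshold:
            label = "amplification"
        else:
            label = "neutral"
        calls.append(CnvCall(region=region, ratio=ratio, label=label,
                             tumour_norm_depth=float(t), control_norm_depth=float(c)))
    return calls


def gene_level_summary(
    calls: Sequence[CnvCall],
    known_genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Majority-vote gene labels with per-gene median ratio.

    A gene is amplified (deleted) iff more than 50% of its callable
    regions carry that label; otherwise neutral.  When ``known_genes`` is
    given, calls on other gene symbols are skipped with a warning.
    """
    rows: dict[str, list[CnvCall]] = {}
    known = set(known_genes) if known_genes is not None else None
    for call in calls:
        gene = call.region.gene
        if not gene or (known is not None and gene not in known):
            logger.warning("skipping region %s: unknown gene %r", call.region.name, gene)
            continue
        rows.setdefault(gene, []).append(call)

    out: list[dict] = []
    for gene in sorted(rows):
        callable_calls = [c for c in rows[gene] if c.ratio is not None]
        n = len(callable_calls)
        if n == 0:
            label, median_ratio = "uncallable", None
        else:
            n_amp = sum(c.label == "amplification" for c in callable_calls)
            n_del = sum(c.label == "deletion" for c in callable_calls)
            if n_amp > n / 2:
                label = "amplification"
            elif n_del > n / 2:
                label = "deletion"
            else:
                label = "neutral"
            median_ratio = float(np.median([c.ratio for c in callable_calls]))
        out.append(
            {
                "gene": gene, "label": label, "median_ratio": median_ratio,
                "n_regions": len(rows[gene]), "n_callable": n,
            }
        )
    return pd.DataFrame(out, columns=["gene", "label", "median_ratio",
                                      "n_regions", "n_callable"])


def write_cnv_tsv(calls: Sequence[CnvCall], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "chrom": c.region.chrom, "start": c.region.start, "end": c.region.end,
                "gene": c.region.gene, "tumour_norm_depth": c.tumour_norm_depth,
                "control_norm_depth": c.control_norm_depth,
                "ratio": c.ratio, "label": c.label,
            }
            for c in calls
        ]
    )
    frame.to_csv(path, sep="\t", index=False)


def write_gene_summary_json(summary: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as handle:
        json.dump(summary.to_dict(orient="records"), handle, indent=2)
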