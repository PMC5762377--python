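"""End-to-end orchestration: simulate inputs, run every validation stage,
assemble the consolidated report.

The pipeline mirrors how a clinical validation is actually run: generate
(or load) the panel and its material, QC the capture, filter and match
variant calls against the truth sets, compute the accuracy statistics,
flag copy-number events, compare the paired FFPE/FF cohort, and write a
single JSON validation report whose every percentage can be recomputed
from its own counts (checked at write time).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cnv import call_cnv, gc_normalize, gene_level_summary, write_cnv_tsv
from .concordance import (PairedVariantTable, build_pairs,
                          discordance_breakdown, paired_vaf_correlation)
from .region_qc import (PanelRegion, RegionDepth, flag_underperforming,
                        read_bed, read_region_depth_tsv, write_region_depth_tsv)
from .synthetic import (BlendSimulation, CnvCohort, PairedCohort, Panel,
                        SimConfig, simulate_blends, simulate_cnv_cohort,
                        simulate_depth, simulate_paired_cohort,
                        simulate_read_stats)
from .validation_stats import (MetricWithCI, bin_by_vaf, confusion_metrics,
                               limit_of_detection, percent, precision_analysis,
                               vaf_correlation)
from .variants import (Variant, apply_call_filters, match_to_truth,
                       mask_contains, normalize_variant, read_truth_tsv,
                       read_true_negative_tsv, read_vcf, reportable_mask,
                       write_truth_tsv, write_vcf)

__all__ = [
    "DEFAULT_CNV_EVENTS",
    "simulate_inputs",
    "run_pipeline",
    "validate_blend_calls",
    "verify_report",
]

logger = logging.getLogger(__name__)

# Default injected copy-number events: a high-level MYCN amplification, a
# moderate CDK4 amplification, and a one-copy 9q arm loss (PTCH1, TSC1).
DEFAULT_CNV_EVENTS: dict[str, float] = {"MYCN": 30, "CDK4": 8, "PTCH1": 1, "TSC1": 1}
DEFAULT_CNV_PURITY = 0.8


def default_cnv_events(panel: Panel) -> dict[str, float]:
    """The default event set, restricted to genes the panel actually carries
    (scaled-down panels may lack the canonical loci)."""
    genes = panel.genes
    events = {g: cn for g, cn in DEFAULT_CNV_EVENTS.items() if g in genes}
    if not events:
        events = {genes[0]: 30, genes[1]: 8, genes[2]: 1, genes[3]: 1}
    return events


def _metric_dict(metric: MetricWithCI | None) -> dict | None:
    if metric is None:
        return None
    return {
        "point": metric.point,
        "pct": percent(metric.point),
        "ci_low": metric.ci_low,
        "ci_high": metric.ci_high,
        "n_success": metric.n_success,
        "n_total": metric.n_total,
        "method": metric.method,
    }


def normalize_calls(calls: Sequence[Variant], panel: Panel,
                    flank: int = 40) -> list[Variant]:
    """Left-align and trim every call against the panel reference."""
    out = []
    for call in calls:
        chrom_seq = panel.reference.get(call.chrom)
        if chrom_seq is None:
            out.append(call)
            continue
        start = max(1, call.pos - flank)
        window = chrom_seq[start - 1: call.pos + len(call.ref) + flank - 1]
        out.append(normalize_variant(call, window, start))
    return out


def normalize_truth(records, panel: Panel, flank: int = 40):
    """Left-align truth records against the panel reference so matching is
    representation-independent on both sides."""
    out = []
    for rec in records:
        chrom_seq = panel.reference.get(rec.chrom)
        if chrom_seq is None:
            out.append(rec)
            continue
        start = max(1, rec.pos - flank)
        window = chrom_seq[start - 1: rec.pos + len(rec.ref) + flank - 1]
        proxy = Variant(chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=rec.alt)
        norm = normalize_variant(proxy, window, start)
        out.append(dataclasses.replace(rec, pos=norm.pos, ref=norm.ref, alt=norm.alt))
    return out


def validate_blend_calls(
    sim: BlendSimulation,
    config: SimConfig,
    run_id: str = "run1",
) -> dict:
    """Filter, mask and truth-match one run's blend calls.

    Calls are normalized, passed through the VAF/alt-read filter and
    restricted to the exon +/-2 bp reportable footprint; truth records are
    kept over the full +/-5 bp capture footprint, so a truth indel in the
    3-5 bp intronic fringe counts as a false negative (it is captured but
    never reportable).
    """
    mask = reportable_mask(sim.panel.regions, capture_pad=5, report_pad=2)
    capture = reportable_mask(sim.panel.regions, capture_pad=5, report_pad=5)

    pooled = {"SNV": {"tp": 0, "fp": 0, "fn": 0, "tn": 0},
              "indel": {"tp": 0, "fp": 0, "fn": 0, "tn": None},
              "all": {"tp": 0, "fp": 0, "fn": 0, "tn": 0}}
    vaf_pairs: list[tuple[float, float]] = []
    detected_vafs: dict[str, list[float]] = {"SNV": [], "indel": []}
    lod_vafs: list[float] = []
    lod_flags: list[bool] = []
    per_blend: dict[str, dict] = {}

    for blend, calls in sim.calls[run_id].items():
        calls = normalize_calls(calls, sim.panel)
        kept, _removed = apply_call_filters(calls, config.min_vaf, config.min_alt_reads)
        kept = [c for c in kept if mask_contains(mask, c.chrom, c.pos)]
        truth = [t for t in normalize_truth(sim.truth[blend], sim.panel)
                 if mask_contains(capture, t.chrom, t.pos)]
        negatives = [n for n in sim.negatives if n.blend_id == blend]
        result = match_to_truth(kept, truth, negatives)
        per_blend[blend] = {
            cls: dataclasses.asdict(cc) for cls, cc in result.counts.items()
        }
        for cls in ("SNV", "indel", "all"):
            cc = result.counts[cls]
            pooled[cls]["tp"] += cc.tp
            pooled[cls]["fp"] += cc.fp
            pooled[cls]["fn"] += cc.fn
            if pooled[cls]["tn"] is not None and cc.tn is not None:
                pooled[cls]["tn"] += cc.tn
        vaf_pairs.extend(result.vaf_pairs)
        matched = result.table[result.table["status"] == "TP"]
        for cls in ("SNV", "indel"):
            detected_vafs[cls].extend(
                matched.loc[matched["variant_class"] == cls, "observed_vaf"].tolist()
            )
        cancer = result.table[result.table["category"] == "cancer_specific"]
        lod_vafs.extend(cancer["expected_vaf"].tolist())
        lod_flags.extend((cancer["status"] == "TP").tolist())

    return {
        "pooled_counts": pooled,
        "per_blend_counts": per_blend,
        "vaf_pairs": vaf_pairs,
        "detected_vafs": detected_vafs,
        "lod_expected_vafs": lod_vafs,
        "lod_detected": lod_flags,
    }


# ---------------------------------------------------------------------------
# Simulation to disk
# ---------------------------------------------------------------------------

def simulate_inputs(config: SimConfig, outdir: str | Path) -> Path:
    """Generate every pipeline input under ``outdir`` (text formats only)."""
    outdir = Path(outdir)
    for sub in ("blends", "paired", "cnv", "qc"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    panel = simulate_panel_cached(config)
    panel.write_fasta(outdir / "reference.fa")
    panel.write_bed(outdir / "panel.bed")

    sim = simulate_blends(panel, config, n_runs=2)
    for blend, records in sim.truth.items():
        write_truth_tsv(records, outdir / "blends" / f"truth_{blend}.tsv")
    pd.DataFrame(
        [{"chrom": n.chrom, "pos": n.pos, "ref": n.ref, "blend_id": n.blend_id}
         for n in sim.negatives]
    ).to_csv(outdir / "blends" / "negatives.tsv", sep="\t", index=False)
    contigs = {c: len(s) for c, s in panel.reference.items()}
    for run_id, blends in sim.calls.items():
        for blend, calls in blends.items():
            write_vcf(calls, outdir / "blends" / f"calls_{run_id}_{blend}.vcf",
                      sample_id=blend, contigs=contigs)
    for blend, depths in sim.region_depths.items():
        write_region_depth_tsv(depths, outdir / "blends" / f"depth_{blend}.tsv")

    cohort = simulate_paired_cohort(panel, config)
    pd.DataFrame(cohort.manifest, columns=["ffpe_sample", "ff_sample"]).to_csv(
        outdir / "paired" / "manifest.tsv", sep="\t", index=False)
    for sample, calls in cohort.calls_ffpe.items():
        write_vcf(calls, outdir / "paired" / f"calls_{sample}.vcf",
                  sample_id=sample, contigs=contigs)
    for sample, calls in cohort.calls_ff.items():
        write_vcf(calls, outdir / "paired" / f"calls_{sample}.vcf",
                  sample_id=sample, contigs=contigs)

    cnv = simulate_cnv_cohort(panel, default_cnv_events(panel),
                              DEFAULT_CNV_PURITY, config)
    write_region_depth_tsv(cnv.tumour, outdir / "cnv" / "tumour.tsv")
    write_region_depth_tsv(cnv.control, outdir / "cnv" / "control.tsv")
    with open(outdir / "cnv" / "truth.json", "w") as handle:
        json.dump(cnv.truth_labels, handle, indent=2)

    stats = pd.concat([
        simulate_read_stats(config, "FFPE", config.n_pairs),
        simulate_read_stats(config, "FF", config.n_pairs),
    ])
    stats.to_csv(outdir / "qc" / "read_stats.tsv", sep="\t", index=False)
    return outdir


_PANEL_CACHE: dict[tuple, Panel] = {}


def simulate_panel_cached(config: SimConfig) -> Panel:
    from .synthetic import simulate_panel

    key = (config.seed, config.n_regions, config.n_genes,
           config.target_footprint, config.high_gc_tail)
    if key not in _PANEL_CACHE:
        _PANEL_CACHE[key] = simulate_panel(config)
    return _PANEL_CACHE[key]


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(
    config: SimConfig,
    outdir: str | Path,
    stages: Sequence[str] = ("qc", "variants", "stats", "cnv", "concordance"),
    cnv_events: Mapping[str, float] | None = None,
    cnv_purity: float = DEFAULT_CNV_PURITY,
    ci_method: str = "wilson",
    concordance_fixture: str | None = None,
) -> dict:
    """Run the selected validation stages on synthetic inputs and write
    ``report.json`` under ``outdir``.  Returns the report dictionary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = simulate_panel_cached(config)
    report: dict = {"provenance": _provenance(config)}

    sim: BlendSimulation | None = None
    if {"variants", "stats", "qc"} & set(stages):
        sim = simulate_blends(panel, config, n_runs=2)

    if "qc" in stages:
        depths = [rd for blend in sim.region_depths.values() for rd in blend]
        performance = flag_underperforming(depths, mode="cohort_mean")
        n_fail = int(performance["fail"].sum())
        stats = pd.concat([
            simulate_read_stats(config, "FFPE", config.n_pairs),
            simulate_read_stats(config, "FF", config.n_pairs),
        ])
        stats["pct_duplicates"] = 100.0 * stats["duplicate_reads"] / stats["mapped_reads"]
        report["region_qc"] = {
            "n_regions": len(performance),
            "n_underperforming": n_fail,
            "pct_underperforming": percent(n_fail / len(performance)),
            "mean_pct_duplicates": {
                cohort: float(sub["pct_duplicates"].mean())
                for cohort, sub in stats.groupby("cohort")
            },
        }
        performance.to_csv(outdir / "region_performance.tsv", sep="\t", index=False)

    matching: dict | None = None
    if "variants" in stages or "stats" in stages:
        matching = validate_blend_calls(sim, config, run_id="run1")
        report["confusion"] = {
            "pooled_counts": matching["pooled_counts"],
            "per_blend_counts": matching["per_blend_counts"],
        }

    if "stats" in stages:
        metrics: dict[str, dict] = {}
        for cls in ("SNV", "indel", "all"):
            counts = matching["pooled_counts"][cls]
            m = confusion_metrics(counts["tp"], counts["fp"], counts["fn"],
                                  counts["tn"], method=ci_method)
            metrics[cls] = {name: _metric_dict(v) for name, v in m.items()}
        report["metrics"] = metrics

        runs_map: dict[str, dict[str, dict[tuple, float]]] = {}
        background_keys = {
            rec.key for records in sim.truth.values() for rec in records
            if rec.category == "background"
        }
        for run_id, blends in sim.calls.items():
            runs_map[run_id] = {
                blend: {c.key: c.vaf for c in calls if c.key in background_keys}
                for blend, calls in blends.items()
            }
        within = precision_analysis(runs_map, scheme="within_run")
        between = precision_analysis(runs_map, scheme="between_run")
        report["precision"] = {
            "within_run": [dataclasses.asdict(r) for r in within],
            "between_run": [dataclasses.asdict(r) for r in between],
        }

        lod = limit_of_detection(matching["lod_expected_vafs"], matching["lod_detected"])
        report["limit_of_detection"] = {
            "strata": lod.strata, "lod_stratum": lod.lod_stratum, "note": lod.note,
        }
        bins = bin_by_vaf(matching["detected_vafs"]["SNV"])
        report["vaf_bins"] = {
            "edges": list(bins.edges),
            "counts": bins.counts,
            "total": bins.total,
            "pct": [None if f is None else percent(f, 0) for f in bins.fractions],
        }

    if "cnv" in stages:
        if cnv_events is None:
            cnv_events = default_cnv_events(panel)
        cohort = simulate_cnv_cohort(panel, cnv_events, cnv_purity, config)
        gc = [rd.region.gc_fraction for rd in cohort.tumour]
        t_norm = gc_normalize([rd.mean_depth for rd in cohort.tumour], gc)
        c_norm = gc_normalize([rd.mean_depth for rd in cohort.control], gc)
        calls = call_cnv([rd.region for rd in cohort.tumour], t_norm, c_norm)
        summary = gene_level_summary(calls)
        write_cnv_tsv(calls, outdir / "cnv_calls.tsv")
        events = summary[summary["label"] != "neutral"]
        truth = cohort.truth_labels
        correct = int(sum(truth.get(r.gene, "neutral") == r.label
                          for r in summary.itertuples()))
        report["cnv"] = {
            "events": events.to_dict(orient="records"),
            "n_genes": len(summary),
            "n_concordant_with_truth": correct,
            "truth_labels": {g: l for g, l in truth.items() if l != "neutral"},
        }

    if "concordance" in stages:
        if concordance_fixture == "exact-counts":
            from .synthetic import exact_counts_table

            table = PairedVariantTable(frame=exact_counts_table())
        elif concordance_fixture is not None:
            raise ValueError(f"unknown concordance fixture {concordance_fixture!r}")
        else:
            cohort = simulate_paired_cohort(panel, config)
            table = build_pairs(cohort.calls_ffpe, cohort.calls_ff, cohort.manifest)
        breakdown = discordance_breakdown(table)
        corr = paired_vaf_correlation(table)
        report["concordance"] = {
            "breakdown": breakdown,
            "r_squared": corr.r_squared,
            "ci": [corr.ci_low, corr.ci_high],
            "n_shared": corr.n_pairs,
        }

    verify_report(report)
    with open(outdir / "report.json", "w") as handle:
        json.dump(report, handle, indent=2, default=_json_default)
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _provenance(config: SimConfig) -> dict:
    blob = yaml.safe_dump(dataclasses.asdict(config), sort_keys=True)
    return {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "panelval_version": __version__,
    }


def verify_report(report: dict) -> None:
    """Check that every derived percentage matches its own counts."""
    def close(a: float, b: float, tol: float = 0.051) -> bool:
        return abs(a - b) <= tol

    confusion = report.get("metrics") or {}
    for cls, metrics in confusion.items():
        for name, m in metrics.items():
            if m is None:
                continue
            if not close(m["point"], m["n_success"] / m["n_total"], 1e-9):
                raise AssertionError(f"{cls}/{name}: point != ratio")
    conc = report.get("concordance")
    if conc:
        b = conc["breakdown"]
        union = b["union"]
        for key in ("ff_only", "ffpe_only"):
            block = b[key]
            if not close(block["pct_of_union"], 100.0 * block["count"] / union):
                raise AssertionError(f"{key} percentage inconsistent")
            total = block["count"]
            if total:
                for stratum, count in block["vaf_strata"].items():
                    if not close(block["vaf_strata_pct"][stratum],
                                 100.0 * count / total):
                        raise AssertionError(f"{key}/{stratum} percentage inconsistent")
    qc = report.get("region_qc")
    if qc and not close(qc["pct_underperforming"],
                        100.0 * qc["n_underperforming"] / qc["n_regions"]):
        raise AssertionError("region QC percentage inconsistent")
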