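"""Accuracy statistics for panel validation.

All of the headline validation numbers are simple ratios of confusion
counts, but a clinical validation reports each with a 95% confidence
interval and stratifies detection by expected variant allele fraction:

* sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
  PPV = TP/(TP+FP), NPV = TN/(TN+FN) -- all binomial proportions,
  interval by Wilson (default) or Clopper-Pearson;
* precision (repeatability within a run, intermediate precision between
  runs) as pairwise Pearson r^2 of the VAFs of shared background
  variants, with a Fisher-z interval;
* limit of detection: the lowest expected-VAF stratum in which every
  truth variant was detected;
* the VAF spectrum of detected variants binned at 20% and 50%.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "MetricWithCI",
    "CorrelationResult",
    "VafBinSummary",
    "LodReport",
    "binomial_metric",
    "confusion_metrics",
    "vaf_correlation",
    "precision_analysis",
    "limit_of_detection",
    "bin_by_vaf",
    "percent",
]

logger = logging.getLogger(__name__)

DEFAULT_LOD_STRATA: tuple[tuple[float, float], ...] = ((0.04, 0.05), (0.05, 0.10), (0.10, 1.0))


@dataclass
class MetricWithCI:
    """A binomial proportion with its confidence interval."""

    point: float
    ci_low: float
    ci_high: float
    n_success: int
    n_total: int
    method: str = "wilson"

    def __post_init__(self) -> None:
        if not self.ci_low <= self.point <= self.ci_high:
            raise ValueError("interval must bracket the point estimate")
        for value in (self.point, self.ci_low, self.ci_high):
            if not 0.0 <= value <= 1.0:
                raise ValueError("proportions must lie in [0, 1]")


@dataclass
class CorrelationResult:
    """Squared Pearson correlation with Fisher-z interval on r^2 scale."""

    r_squared: float
    ci_low: float
    ci_high: float
    n_pairs: int
    label: str = ""


@dataclass
class VafBinSummary:
    """Counts and fractions of VAFs in [0, e1), [e1, e2), [e2, 1]."""

    edges: tuple[float, ...]
    counts: list[int]
    fractions: list[float | None]
    total: int


@dataclass
class LodReport:
    """Per-stratum detection fractions and the limit-of-detection stratum.

    The LoD is the lowest expected-VAF stratum with 100% detection; a 5%
    VAF analytic floor corresponds to detecting a heterozygous mutation
    when more than 10% of cells in the specimen are neoplastic.
    """

    strata: list[dict]
    lod_stratum: str | None
    note: str = (
        "a 5% VAF floor allows detection of a heterozygous mutation "
        "when >10% neoplastic cells are present"
    )


def binomial_metric(
    n_success: int,
    n_total: int,
    alpha: float = 0.05,
    method: str = "wilson",
) -> MetricWithCI:
    """Binomial proportion with a Wilson or Clopper-Pearson interval."""
    if n_total <= 0:
        raise ValueError("metric undefined: n_total must be >= 1")
    if not 0 <= n_success <= n_total:
        raise ValueError("need 0 <= n_success <= n_total")
    sm_method = {"wilson": "wilson", "clopper-pearson": "beta"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown CI method {method!r}")
    low, high = proportion_confint(n_success, n_total, alpha=alpha, method=sm_method)
    point = n_success / n_total
    # guard floating round-off at the boundaries (e.g. upper 1 + 2e-16)
    low = min(max(float(low), 0.0), point)
    high = max(min(float(high), 1.0), point)
    return MetricWithCI(
        point=point,
        ci_low=low,
        ci_high=high,
        n_success=n_success,
        n_total=n_total,
        method=method,
    )


def confusion_metrics(
    tp: int, fp: int, fn: int, tn: int | None,
    alpha: float = 0.05, method: str = "wilson",
) -> dict[str, MetricWithCI | None]:
    """Sensitivity/specificity/PPV/NPV from confusion counts.

    Metrics whose denominator is zero (or needs an unknown TN) are None.
    """
    def safe(successes: int | None, total: int | None) -> MetricWithCI | None:
        if successes is None or total is None or total == 0:
            return None
        return binomial_metric(successes, total, alpha=alpha, method=method)

    has_tn = tn is not None
    return {
        "sensitivity": safe(tp, tp + fn),
        "specificity": safe(tn, tn + fp) if has_tn else None,
        "ppv": safe(tp, tp + fp),
        "npv": safe(tn, tn + fn) if has_tn else None,
    }


def vaf_correlation(
    pairs: Sequence[tuple[float, float]],
    alpha: float = 0.05,
    label: str = "",
) -> CorrelationResult:
    """Pearson r^2 of paired VAFs with a Fisher-z confidence interval.

    The interval is computed on r (arctanh transform, SE 1/sqrt(n-3)) and
    the endpoints squared, re-ordered so ci_low <= ci_high.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    a = np.asarray([p[0] for p in pairs], dtype=float)
    b = np.asarray([p[1] for p in pairs], dtype=float)
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite VAF values")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined: zero variance in one margin")
    r = float(stats.pearsonr(a, b).statistic)
    n = len(pairs)
    if n > 3 and abs(r) < 1.0:
        z = math.atanh(r)
        half = stats.norm.ppf(1 - alpha / 2) / math.sqrt(n - 3)
        r_low, r_high = math.tanh(z - half), math.tanh(z + half)
    else:  # degenerate: n == 3 or |r| == 1
        r_low = r_high = r
    lo, hi = sorted((r_low * r_low, r_high * r_high))
    if not lo <= r * r <= hi:  # interval straddling zero on the r scale
        lo = min(lo, 0.0)
    return CorrelationResult(r_squared=r * r, ci_low=lo, ci_high=hi,
                             n_pairs=n, label=label)


def _shared_pairs(
    table_a: Mapping[tuple, float], table_b: Mapping[tuple, float]
) -> list[tuple[float, float]]:
    keys = sorted(set(table_a) & set(table_b))
    return [(table_a[k], table_b[k]) for k in keys]


def precision_analysis(
    runs: Mapping[str, Mapping[str, Mapping[tuple, float]]],
    scheme: str = "between_run",
    alpha: float = 0.05,
) -> list[CorrelationResult]:
    """Repeatability / intermediate-precision correlations of background VAFs.

    ``runs`` maps run_id -> blend_id -> {variant key: VAF} restricted to
    the shared background variants.

    * ``within_run``: for every run, all pairwise correlations across the
      blends of that run (repeatability);
    * ``between_run``: for every blend, the correlation of the same
      variants across each pair of runs, plus a pooled "overall" result
      (intermediate precision).

    Pairs sharing fewer than 3 variants are skipped with a warning.
    """
    if scheme not in ("within_run", "between_run"):
        raise ValueError(f"unknown scheme {scheme!r}")
    results: list[CorrelationResult] = []

    if scheme == "within_run":
        for run_id, blends in runs.items():
            for blend_a, blend_b in itertools.combinations(sorted(blends), 2):
                pairs = _shared_pairs(blends[blend_a], blends[blend_b])
                if len(pairs) < 3:
                    logger.warning(
                        "skipping %s %s-vs-%s: only %d shared variants",
                        run_id, blend_a, blend_b, len(pairs),
                    )
                    continue
                results.append(
                    vaf_correlation(pairs, alpha=alpha,
                                    label=f"{run_id}:{blend_a}-vs-{blend_b}")
                )
        return results

    pooled: list[tuple[float, float]] = []
    for run_a, run_b in itertools.combinations(sorted(runs), 2):
        common_blends = sorted(set(runs[run_a]) & set(runs[run_b]))
        missing = set(runs[run_a]) ^ set(runs[run_b])
        if missing:
            logger.warning("blends %s absent from one of %s/%s", sorted(missing), run_a, run_b)
        for blend in common_blends:
            pairs = _shared_pairs(runs[run_a][blend], runs[run_b][blend])
            if len(pairs) < 3:
                logger.warning("skipping blend %s across %s/%s: only %d shared variants",
                               blend, run_a, run_b, len(pairs))
                continue
            pooled.extend(pairs)
            results.append(
                vaf_correlation(pairs, alpha=alpha, label=f"{blend}:{run_a}-vs-{run_b}")
            )
    if len(pooled) >= 3:
        results.append(vaf_correlation(pooled, alpha=alpha, label="overall"))
    return results


def limit_of_detection(
    expected_vafs: Sequence[float],
    detected: Sequence[bool],
    strata: Sequence[tuple[float, float]] = DEFAULT_LOD_STRATA,
) -> LodReport:
    """Stratify detection by expected VAF and find the LoD stratum.

    Strata are [low, high) intervals (the last is inclusive of its upper
    edge); the LoD is the lowest stratum with a 100% detection fraction.
    """
    if len(expected_vafs) == 0:
        raise ValueError("empty truth set")
    if len(expected_vafs) != len(detected):
        raise ValueError("expected_vafs and detected must align")
    strata = sorted(strata)
    rows: list[dict] = []
    lod: str | None = None
    for index, (low, high) in enumerate(strata):
        last = index == len(strata) - 1
        members = [
            d for v, d in zip(expected_vafs, detected)
            if (low <= v < high) or (last and v == high)
        ]
        n_total = len(members)
        n_detected = sum(members)
        name = f"{low:g}-{high:g}"
        rows.append(
            {
                "stratum": name, "vaf_low": low, "vaf_high": high,
                "n_total": n_total, "n_detected": n_detected,
                "fraction_detected": (n_detected / n_total) if n_total else None,
            }
        )
    for row in rows:
        if row["n_total"] and row["fraction_detected"] == 1.0:
            lod = row["stratum"]
            break
    return LodReport(strata=rows, lod_stratum=lod)


def bin_by_vaf(
    vafs: Sequence[float],
    edges: tuple[float, float] = (0.20, 0.50),
) -> VafBinSummary:
    """Bin VAFs into [0, e1), [e1, e2), [e2, 1]; boundaries belong upward."""
    e1, e2 = edges
    if not 0 < e1 < e2 < 1:
        raise ValueError("edges must be ascending inside (0, 1)")
    counts = [0, 0, 0]
    for v in vafs:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"VAF {v} outside [0, 1]")
        counts[0 if v < e1 else 1 if v < e2 else 2] += 1
    total = len(vafs)
    fractions: list[float | None] = [
        (c / total) if total else None for c in counts
    ]
    return VafBinSummary(edges=(0.0, e1, e2, 1.0), counts=counts,
                         fractions=fractions, total=total)


def percent(x: float, decimals: int = 1) -> float:
    """Round a fraction to a percentage with half-up rounding."""
    scaled = x * 100.0 * 10 ** decimals
    return math.floor(scaled + 0.5) / 10 ** decimals
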