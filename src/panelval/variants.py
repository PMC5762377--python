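"""Variant representation, normalization, call filtering and truth-set matching.

A targeted-panel validation run compares the variants a pipeline calls
against a reference material with known content (engineered cell blends
carrying background variants shared by every blend plus blend-unique
cancer variants spiked at known allele fraction).  This module owns the
variant data model and the bookkeeping that turns call sets plus truth
tables into confusion counts:

* :func:`normalize_variant` -- parsimonious, left-aligned representation so
  that matching is independent of how a caller wrote an indel;
* :func:`apply_call_filters` -- the pipeline's minimum-VAF / minimum
  variant-read filter;
* :func:`reportable_mask` -- the exon +/- pad footprint inside which calls
  are reportable (the capture footprint is wider than the reportable one,
  which is why truth indels sitting 3-5 bp into an intron are captured but
  never reported);
* :func:`match_to_truth` -- exact-key truth matching producing TP/FP/FN/TN
  counts per variant class plus observed-vs-expected VAF pairs.

Calls travel as VCF 4.2 (FORMAT ``AD`` and ``DP``; VAF is taken from an
``AF``/``VF`` FORMAT field when present, else derived as ``AD_alt/DP``);
truth sets are TSV tables.  Matching is exact on the normalized
``(chrom, pos, ref, alt)`` key -- no fuzzy indel window.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

__all__ = [
    "Variant",
    "TruthRecord",
    "TrueNegativeSite",
    "ConfusionCounts",
    "MatchResult",
    "ReferenceMismatchError",
    "DuplicateCallError",
    "normalize_variant",
    "apply_call_filters",
    "reportable_mask",
    "mask_contains",
    "match_to_truth",
    "read_vcf",
    "write_vcf",
    "read_truth_tsv",
    "write_truth_tsv",
    "read_true_negative_tsv",
]

_BASES = set("ACGT")


class ReferenceMismatchError(ValueError):
    """The variant's ref allele disagrees with the reference window."""


class DuplicateCallError(ValueError):
    """The same normalized variant key appears twice in one sample."""


@dataclass(frozen=True)
class Variant:
    """One normalized allele substitution, insertion or deletion.

    ``pos`` is the 1-based position of the first reference base.  ``vaf``
    is the variant allele fraction in [0, 1]; ``alt_reads`` and
    ``total_depth`` carry the supporting read counts.  A variant is an SNV
    iff both alleles have length 1; anything else (including an MNV or a
    duplication) is indel-class.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float = float("nan")
    alt_reads: int = 0
    total_depth: int = 0
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) is not a variant")
        for allele in (self.ref, self.alt):
            if set(allele) - _BASES:
                raise ValueError(f"allele {allele!r} contains non-ACGT symbols")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if self.alt_reads < 0 or self.total_depth < 0:
            raise ValueError("read counts must be non-negative")
        if self.vaf == self.vaf and not 0.0 <= self.vaf <= 1.0:  # NaN-safe
            raise ValueError(f"vaf {self.vaf} outside [0, 1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def variant_class(self) -> str:
        return "SNV" if self.is_snv else "indel"


@dataclass(frozen=True)
class TruthRecord:
    """An expected variant from the reference material.

    ``category`` separates background variants (natural, shared by all
    blends) from cancer-specific variants spiked at a known fraction.
    ``expected_vaf`` may be None when unknown.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    expected_vaf: float | None = None
    category: str = "background"
    blend_id: str = ""

    def __post_init__(self) -> None:
        if self.expected_vaf is not None and not 0.0 < self.expected_vaf <= 1.0:
            raise ValueError("expected_vaf must lie in (0, 1]")
        if self.category not in ("background", "cancer_specific"):
            raise ValueError(f"unknown truth category {self.category!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def variant_class(self) -> str:
        return "SNV" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"


@dataclass(frozen=True)
class TrueNegativeSite:
    """A wild-type position in one blend where another blend is mutant."""

    chrom: str
    pos: int
    ref: str
    blend_id: str = ""


@dataclass
class ConfusionCounts:
    """TP/FP/FN/TN counts for one variant class (tn may be unknown)."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int | None = 0
    variant_class: str = "all"

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tn is not None and self.tn < 0:
            raise ValueError("tn must be non-negative or None")


@dataclass
class MatchResult:
    """Truth-matching outcome: counts per class plus the per-record table.

    ``table`` has one row per truth record and per negative site with its
    status (TP/FN/TN/FP) and, for matched records, the observed VAF.
    ``vaf_pairs`` lists (expected_vaf, observed_vaf) for matched records
    whose expected VAF is known.
    """

    counts: dict[str, ConfusionCounts]
    table: pd.DataFrame
    vaf_pairs: list[tuple[float, float]]


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_variant(v: Variant, ref_window: str, window_start: int) -> Variant:
    """Return the parsimonious, left-aligned representation of ``v``.

    ``ref_window`` is reference sequence starting at 1-based coordinate
    ``window_start``; it must cover the variant and enough left flank for
    the indel to shift into (30 bp is ample for panel-scale indels).

    The procedure is the standard one: repeatedly trim a shared last base
    (extending both alleles leftwards by one reference base whenever one
    allele would empty), then trim shared leading bases.  SNVs and
    untrimmable MNVs are returned unchanged.

    Raises :class:`ReferenceMismatchError` when ``v.ref`` disagrees with
    the window.
    """
    window = ref_window.upper()

    def base_at(pos: int) -> str:
        idx = pos - window_start
        if idx < 0 or idx >= len(window):
            raise ValueError(
                f"reference window [{window_start}, {window_start + len(window)})"
                f" does not cover position {pos}"
            )
        return window[idx]

    ref_in_window = "".join(base_at(v.pos + i) for i in range(len(v.ref)))
    if ref_in_window != v.ref.upper():
        raise ReferenceMismatchError(
            f"{v.chrom}:{v.pos} ref {v.ref!r} != reference {ref_in_window!r}"
        )

    pos, ref, alt = v.pos, v.ref.upper(), v.alt.upper()
    if len(ref) == 1 and len(alt) == 1:
        return v

    changed = True
    while changed:
        changed = False
        # trim identical trailing base; re-anchor left if an allele empties
        if ref and alt and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
            changed = True
            if not ref or not alt:
                left = base_at(pos - 1)
                pos -= 1
                ref, alt = left + ref, left + alt
        # trim identical leading base while both alleles stay non-empty
        if len(ref) >= 2 and len(alt) >= 2 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1
            changed = True

    return dataclasses.replace(v, pos=pos, ref=ref, alt=alt)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def apply_call_filters(
    calls: Sequence[Variant],
    min_vaf: float = 0.05,
    min_alt_reads: int = 10,
) -> tuple[list[Variant], list[Variant]]:
    """Split calls into (kept, removed) by the VAF / variant-read filter.

    A call is kept iff ``vaf >= min_vaf`` and ``alt_reads >= min_alt_reads``
    (defaults: 5% VAF and 10 variant reads).  Order is preserved and the
    two lists partition the input.
    """
    if not 0.0 <= min_vaf <= 1.0:
        raise ValueError("min_vaf must lie in [0, 1]")
    if min_alt_reads < 0:
        raise ValueError("min_alt_reads must be >= 0")
    kept: list[Variant] = []
    removed: list[Variant] = []
    for call in calls:
        if call.vaf >= min_vaf and call.alt_reads >= min_alt_reads:
            kept.append(call)
        else:
            removed.append(call)
    return kept, removed


# ---------------------------------------------------------------------------
# Reportable footprint
# ---------------------------------------------------------------------------

def reportable_mask(
    regions: Iterable,
    capture_pad: int = 5,
    report_pad: int = 2,
) -> dict[str, list[tuple[int, int]]]:
    """Union of panel regions extended by ``report_pad`` on both sides.

    Regions are 0-based half-open intervals carrying ``chrom``, ``start``
    and ``end`` attributes (or 3-tuples).  ``capture_pad`` is the wider
    padding already baked into the capture design; it only bounds
    ``report_pad``.  Returns merged intervals per chromosome, 0-based
    half-open.
    """
    if capture_pad < 0 or report_pad < 0:
        raise ValueError("pads must be non-negative")
    if report_pad > capture_pad:
        raise ValueError("report_pad cannot exceed capture_pad")

    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for region in regions:
        if hasattr(region, "chrom"):
            chrom, start, end = region.chrom, region.start, region.end
        else:
            chrom, start, end = region
        per_chrom.setdefault(chrom, []).append(
            (max(0, start - report_pad), end + report_pad)
        )

    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivals in per_chrom.items():
        ivals.sort()
        out = [list(ivals[0])]
        for start, end in ivals[1:]:
            if start <= out[-1][1]:
                out[-1][1] = max(out[-1][1], end)
            else:
                out.append([start, end])
        merged[chrom] = [(s, e) for s, e in out]
    return merged


def mask_contains(mask: Mapping[str, list[tuple[int, int]]], chrom: str, pos: int) -> bool:
    """True iff 1-based position ``pos`` lies inside the mask."""
    zero = pos - 1
    for start, end in mask.get(chrom, ()):
        if start <= zero < end:
            return True
    return False


# ---------------------------------------------------------------------------
# Truth matching
# ---------------------------------------------------------------------------

def match_to_truth(
    calls: Sequence[Variant],
    truth: Sequence[TruthRecord],
    negatives: Sequence[TrueNegativeSite] = (),
) -> MatchResult:
    """Compare normalized calls against a truth set at exact keys.

    TP: truth record with an exactly matching call key.  FN: truth record
    with none.  FP: a call sitting at a designated true-negative position
    whose alt differs from the reference.  TN: negative site with no call.
    Counts are returned per variant class (SNV / indel) and pooled; the
    negative sites are SNV sites, so indel TN is unknown (None).

    Raises :class:`DuplicateCallError` when one sample contributes the
    same variant key twice.
    """
    by_key: dict[tuple, Variant] = {}
    seen: set[tuple] = set()
    for call in calls:
        sample_key = (call.sample_id,) + call.key
        if sample_key in seen:
            raise DuplicateCallError(f"duplicate call key {call.key} in sample {call.sample_id!r}")
        seen.add(sample_key)
        by_key[call.key] = call

    call_positions: dict[tuple[str, int], list[Variant]] = {}
    for call in calls:
        call_positions.setdefault((call.chrom, call.pos), []).append(call)

    rows: list[dict] = []
    vaf_pairs: list[tuple[float, float]] = []
    counts = {
        "SNV": ConfusionCounts(variant_class="SNV"),
        "indel": ConfusionCounts(tn=None, variant_class="indel"),
    }

    for record in truth:
        cls = record.variant_class
        hit = by_key.get(record.key)
        if hit is not None:
            counts[cls].tp += 1
            status = "TP"
            if record.expected_vaf is not None and hit.vaf == hit.vaf:
                vaf_pairs.append((record.expected_vaf, hit.vaf))
        else:
            counts[cls].fn += 1
            status = "FN"
        rows.append(
            {
                "chrom": record.chrom,
                "pos": record.pos,
                "ref": record.ref,
                "alt": record.alt,
                "variant_class": cls,
                "category": record.category,
                "blend_id": record.blend_id,
                "expected_vaf": record.expected_vaf,
                "observed_vaf": hit.vaf if hit is not None else None,
                "status": status,
            }
        )

    for site in negatives:
        here = [
            c for c in call_positions.get((site.chrom, site.pos), []) if c.alt != site.ref
        ]
        if here:
            counts["SNV"].fp += 1
            status, observed = "FP", here[0].vaf
        else:
            counts["SNV"].tn += 1
            status, observed = "TN", None
        rows.append(
            {
                "chrom": site.chrom,
                "pos": site.pos,
                "ref": site.ref,
                "alt": None,
                "variant_class": "SNV",
                "category": "true_negative_site",
                "blend_id": site.blend_id,
                "expected_vaf": None,
                "observed_vaf": observed,
                "status": status,
            }
        )

    pooled = ConfusionCounts(
        tp=counts["SNV"].tp + counts["indel"].tp,
        fp=counts["SNV"].fp + counts["indel"].fp,
        fn=counts["SNV"].fn + counts["indel"].fn,
        tn=counts["SNV"].tn,
        variant_class="all",
    )
    counts["all"] = pooled
    table = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "variant_class", "category",
            "blend_id", "expected_vaf", "observed_vaf", "status",
        ],
    )
    return MatchResult(counts=counts, table=table, vaf_pairs=vaf_pairs)


# ---------------------------------------------------------------------------
# I/O: VCF 4.2 and TSV truth tables
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, sample_id: str | None = None) -> list[Variant]:
    """Read calls from a VCF 4.2 file, splitting multi-allelic records.

    VAF is taken from a per-sample ``AF``/``VF`` FORMAT field when present,
    else derived as ``AD[alt]/DP``.
    """
    variants: list[Variant] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if sample_id is None:
            sample_id = samples[0] if samples else ""
        for rec in vcf:
            sample = rec.samples[sample_id] if samples else None
            alts = rec.alts or ()
            for alt_index, alt in enumerate(alts):
                if alt is None or set(alt) - _BASES or set(rec.ref) - _BASES:
                    continue  # symbolic/spanning alleles are out of scope
                vaf = float("nan")
                alt_reads = 0
                depth = 0
                if sample is not None:
                    ad = sample.get("AD")
                    depth = int(sample.get("DP") or 0)
                    if ad is not None and ad[alt_index + 1] is not None:
                        alt_reads = int(ad[alt_index + 1])
                    for field in ("AF", "VF"):
                        value = sample.get(field)
                        if value is not None:
                            vaf = float(value[alt_index] if isinstance(value, tuple) else value)
                            break
                    else:
                        if depth > 0:
                            vaf = alt_reads / depth
                variants.append(
                    Variant(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        vaf=vaf,
                        alt_reads=alt_reads,
                        total_depth=depth,
                        sample_id=sample_id,
                    )
                )
    return variants


def write_vcf(
    calls: Sequence[Variant],
    path: str | Path,
    sample_id: str | None = None,
    contigs: Mapping[str, int] | None = None,
) -> None:
    """Write calls as an uncompressed VCF 4.2 file with AD/DP/AF fields."""
    if sample_id is None:
        sample_id = calls[0].sample_id if calls else "sample"
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line('##FORMAT=<ID=AF,Number=A,Type=Float,Description="Allele fraction">')
    names = contigs or {c: None for c in dict.fromkeys(v.chrom for v in calls)}
    for name, length in names.items():
        if length:
            header.add_line(f"##contig=<ID={name},length={length}>")
        else:
            header.add_line(f"##contig=<ID={name}>")
    header.add_sample(sample_id)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call in sorted(calls, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
            rec = out.new_record(
                contig=call.chrom,
                start=call.pos - 1,
                alleles=(call.ref, call.alt),
            )
            ref_reads = max(call.total_depth - call.alt_reads, 0)
            rec.samples[sample_id]["AD"] = (ref_reads, call.alt_reads)
            rec.samples[sample_id]["DP"] = call.total_depth
            rec.samples[sample_id]["AF"] = call.vaf if call.vaf == call.vaf else None
            out.write(rec)


_TRUTH_COLUMNS = ["chrom", "pos", "ref", "alt", "expected_vaf", "category", "blend_id"]


def read_truth_tsv(path: str | Path) -> list[TruthRecord]:
    """Read a TSV truth table (chrom, pos, ref, alt, expected_vaf, category, blend_id)."""
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str, "blend_id": str})
    records = []
    for row in frame.itertuples(index=False):
        expected = getattr(row, "expected_vaf", None)
        if expected is not None and expected != expected:
            expected = None
        records.append(
            TruthRecord(
                chrom=row.chrom,
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                expected_vaf=expected,
                category=getattr(row, "category", "background"),
                blend_id=str(getattr(row, "blend_id", "")),
            )
        )
    return records


def write_truth_tsv(records: Sequence[TruthRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt,
                "expected_vaf": r.expected_vaf, "category": r.category,
                "blend_id": r.blend_id,
            }
            for r in records
        ],
        columns=_TRUTH_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)


def read_true_negative_tsv(path: str | Path) -> list[TrueNegativeSite]:
    """Read a TSV of true-negative sites (chrom, pos, ref, blend_id)."""
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str, "blend_id": str})
    return [
        TrueNegativeSite(chrom=row.chrom, pos=int(row.pos), ref=row.ref,
                         blend_id=str(getattr(row, "blend_id", "")))
        for row in frame.itertuples(index=False)
    ]
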