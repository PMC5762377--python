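"""Seeded generators for every input the validation pipeline consumes.

No public data accompanies the assay this package validates, so the
pipeline is exercised end-to-end on synthetic material built at a
realistic clinical validation design scale:

* a hybrid-capture panel of 901 regions over 78 paediatric-cancer genes
  spanning ~311 kb, with region GC content spread over 0.25-0.85 and a
  configurable high-GC tail;
* log-normal region depths with depth suppression above a GC knee
  (capture chemistry loses efficiency in GC-rich targets);
* four reference cell blends sharing 163 background SNVs and 34
  background indels, plus 61 cancer SNVs and 17 cancer indels unique to
  individual blends at known expected VAF, with read support drawn
  binomially from region depth and true-negative sites derived from
  cross-blend cancer variants;
* paired FFPE/fresh-frozen call sets whose disagreement concentrates at
  low VAF (deamination-style C>T artefacts on the FFPE side);
* tumour/control depth tables with amplification and deletion events
  scaled by ``(purity * CN + (1 - purity) * 2) / 2``.

Every generator is deterministic under a fixed seed; generators draw
from independent streams so adding a call does not perturb the others.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import binom

from .region_qc import PanelRegion, RegionDepth, gc_fraction
from .variants import TrueNegativeSite, TruthRecord, Variant

__all__ = [
    "SimConfig",
    "Panel",
    "BlendSimulation",
    "PairedCohort",
    "CnvCohort",
    "PANEL_GENES",
    "simulate_panel",
    "simulate_depth",
    "simulate_per_base_depth",
    "simulate_blends",
    "simulate_paired_cohort",
    "exact_counts_table",
    "simulate_cnv_cohort",
    "simulate_read_stats",
    "detection_probability",
]

# The 78 genes recurrently altered in paediatric solid tumours that the
# panel targets.  A few loci whose chromosome matters downstream (MYCN
# amplification on 2p, CDK4 on 12q, the 9q PTCH1/TSC1 arm-loss genes...)
# are pinned to their true chromosomes; the rest are laid out round-robin.
PANEL_GENES: tuple[str, ...] = (
    "ACVR1", "AKT1", "ALK", "AMER1", "APC", "ARID1A", "ARID1B", "ASXL1",
    "ATM", "ATRX", "BARD1", "BCOR", "BRAF", "CASC15", "CDK4", "CDK6",
    "CDKN2A", "CDKN2B", "CFL1", "CHEK2", "CTNNB1", "DDR2", "DDX3X",
    "DICER1", "EGFR", "ERBB2", "ERG", "ETV6", "EWSR1", "FBXW7", "FGFR1",
    "FGFR2", "FGFR3", "FGFR4", "FUS", "H3F3A", "HIST1H3B", "HIST1H3C",
    "HRAS", "IDH1", "IL3", "IL6", "KIT", "KMT2D", "KRAS", "LMO1",
    "MAP2K1", "MAP2K2", "MDM2", "MYCN", "MYOD1", "NCOA2", "NF1", "NRAS",
    "PAX3", "PAX7", "PDGFRA", "PHOX2B", "PIK3CA", "PIK3R1", "PPM1D",
    "PTCH1", "PTEN", "PTPN11", "PTPRD", "RB1", "RET", "ROS1", "SETD2",
    "SMARCA4", "SMARCB1", "SS18", "SUFU", "TENM3", "TP53", "TSC1",
    "WT1", "ZHX2",
)

_GENE_CHROM: dict[str, str] = {
    "ALK": "chr2", "MYCN": "chr2", "IDH1": "chr2", "ACVR1": "chr2",
    "CTNNB1": "chr3", "SETD2": "chr3", "PIK3CA": "chr3",
    "PDGFRA": "chr4", "KIT": "chr4",
    "APC": "chr5", "FGFR4": "chr5",
    "HIST1H3B": "chr6", "HIST1H3C": "chr6", "ROS1": "chr6", "ARID1B": "chr6",
    "BRAF": "chr7", "EGFR": "chr7",
    "PTCH1": "chr9", "TSC1": "chr9", "CDKN2A": "chr9", "CDKN2B": "chr9",
    "PTEN": "chr10", "SUFU": "chr10", "FGFR2": "chr10", "RET": "chr10",
    "ATM": "chr11", "HRAS": "chr11", "WT1": "chr11",
    "CDK4": "chr12", "KMT2D": "chr12", "MDM2": "chr12", "KRAS": "chr12",
    "RB1": "chr13",
    "TP53": "chr17", "NF1": "chr17", "PPM1D": "chr17", "ERBB2": "chr17",
    "SMARCB1": "chr22", "EWSR1": "chr22", "CHEK2": "chr22",
    "DDX3X": "chrX", "ATRX": "chrX", "BCOR": "chrX",
}
_OTHER_CHROMS = tuple(f"chr{c}" for c in (1, 8, 14, 15, 16, 18, 19, 20, 21))

_FLANK = 120  # intergenic spacer between placed regions, bp


@dataclass
class SimConfig:
    """All knobs of the synthetic validation material.

    The defaults are the design conditions of the emulated clinical
    validation: 901 regions / 78 genes
    / ~311 kb; four blends sharing 163 background SNVs + 34 background
    indels with 61 + 17 blend-unique cancer variants; 87 true-negative
    sites; 15 FFPE/FF pairs.  Cancer expected VAFs default to
    0.05-0.30 so a default run is consistent with the pipeline's own 5%
    VAF floor; the ``reference`` preset lowers the floor to 0.04 and places
    33 SNVs in the 4-5% stratum, which makes sub-threshold dropout
    possible by construction.
    """

    seed: int = 0
    # panel
    n_regions: int = 901
    n_genes: int = 78
    target_footprint: int = 311_000
    high_gc_tail: float = 0.10
    # depth model
    depth_sigma: float = 0.25           # log-normal sigma (natural log)
    gc_knee: float = 0.72               # suppression starts above this GC
    gc_floor: float = 0.02              # minimum suppression multiplier
    gc_max: float = 0.85
    gc_suppression: bool = True
    mean_depth_blend: float = 700.0
    mean_depth_ffpe: float = 785.0
    mean_depth_ff: float = 977.0
    # blend design
    n_blends: int = 4
    n_background_snvs: int = 163
    n_background_indels: int = 34
    n_cancer_snvs: int = 61
    n_cancer_indels: int = 17
    cancer_vaf_min: float = 0.05
    cancer_vaf_max: float = 0.30
    n_low_vaf_snvs: int = 0             # cancer SNVs forced into [0.04, 0.05)
    n_true_negatives: int = 87
    indel_exon4_fraction: float = 0.10  # truth indels placed 4 bp into the intron
    min_vaf: float = 0.05
    min_alt_reads: int = 10
    # paired FFPE/FF cohort
    n_pairs: int = 15
    pair_shared: int = 433
    pair_ff_only: int = 371
    pair_ffpe_only: int = 72
    ff_only_strata: tuple[float, float, float] = (0.781, 0.176, 0.043)
    ffpe_only_strata: tuple[float, float, float] = (0.508, 0.332, 0.160)
    ffpe_noise_sd: float = 0.02
    ffpe_ct_fraction: float = 0.80      # deamination-style C>T/G>A artefact share
    # tumour/control pairs share region capture efficiency; this is the
    # residual per-sample log-normal sigma of the depth ratio
    cnv_sample_sigma: float = 0.05
    # read-level QC stats
    total_reads_ffpe: float = 8.8e6
    total_reads_ff: float = 7.9e6
    dup_rate_ffpe: float = 0.545
    dup_rate_ff: float = 0.299

    @classmethod
    def preset(cls, name: str, seed: int = 0) -> "SimConfig":
        """Named configurations: ``reference`` (design scale, 4% VAF floor with
        33 low-VAF SNVs) and ``small`` (fast, scaled-down smoke runs)."""
        if name == "reference":
            return cls(seed=seed, cancer_vaf_min=0.04, n_low_vaf_snvs=33)
        if name == "small":
            return cls(
                seed=seed, n_regions=80, n_genes=12, target_footprint=28_000,
                n_background_snvs=40, n_background_indels=10,
                n_cancer_snvs=16, n_cancer_indels=4, n_true_negatives=20,
                n_pairs=3, pair_shared=60, pair_ff_only=40, pair_ffpe_only=10,
            )
        raise ValueError(f"unknown preset {name!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("ff_only_strata", "ffpe_only_strata"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        for key in ("ff_only_strata", "ffpe_only_strata"):
            data[key] = list(data[key])
        with open(path, "w") as handle:
            yaml.safe_dump(data, handle, sort_keys=False)


@dataclass
class Panel:
    """A simulated capture panel: regions plus the reference they live on."""

    regions: list[PanelRegion]
    reference: dict[str, str]

    def write_bed(self, path: str | Path) -> None:
        from .region_qc import write_bed

        write_bed(self.regions, path)

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as handle:
            for chrom in self.reference:
                handle.write(f">{chrom}\n")
                seq = self.reference[chrom]
                for i in range(0, len(seq), width):
                    handle.write(seq[i:i + width] + "\n")

    @property
    def genes(self) -> list[str]:
        return sorted({r.gene for r in self.regions})


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stream])


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


def simulate_panel(config: SimConfig) -> Panel:
    """Build the reference FASTA and panel BED with GC-spread regions."""
    if config.n_regions < 10:
        raise ValueError("need at least 10 regions")
    rng = _rng(config, 1)
    genes = list(PANEL_GENES[: config.n_genes])
    if config.n_genes > len(PANEL_GENES):
        genes += [f"GENE{i}" for i in range(len(PANEL_GENES), config.n_genes)]

    # regions per gene: at least one each, remainder multinomial
    base = np.ones(len(genes), dtype=int)
    extra = rng.multinomial(config.n_regions - len(genes),
                            np.full(len(genes), 1.0 / len(genes)))
    per_gene = base + extra

    mean_len = config.target_footprint / config.n_regions
    chrom_of = {
        gene: _GENE_CHROM.get(gene, _OTHER_CHROMS[i % len(_OTHER_CHROMS)])
        for i, gene in enumerate(genes)
    }

    # GC targets: broad beta body over 0.25-0.70 plus a uniform high tail
    n_tail = int(round(config.high_gc_tail * config.n_regions))
    body = 0.25 + 0.45 * rng.beta(2.0, 2.0, size=config.n_regions - n_tail)
    tail = rng.uniform(0.70, config.gc_max, size=n_tail)
    gc_targets = rng.permutation(np.concatenate([body, tail]))

    lengths = np.clip(
        rng.normal(mean_len, mean_len * 0.25, size=config.n_regions), 60, None
    ).astype(int)

    chrom_seqs: dict[str, list[str]] = {}
    chrom_cursor: dict[str, int] = {}
    regions: list[PanelRegion] = []
    index = 0
    for gene, count in zip(genes, per_gene):
        chrom = chrom_of[gene]
        for _ in range(count):
            parts = chrom_seqs.setdefault(chrom, [])
            cursor = chrom_cursor.get(chrom, 0)
            flank = _random_seq(rng, _FLANK, 0.5)
            parts.append(flank)
            start = cursor + _FLANK
            seq = _random_seq(rng, int(lengths[index]), float(gc_targets[index]))
            parts.append(seq)
            end = start + len(seq)
            chrom_cursor[chrom] = end
            regions.append(
                PanelRegion(chrom=chrom, start=start, end=end, gene=gene,
                            gc_fraction=gc_fraction(seq))
            )
            index += 1
    reference = {}
    for chrom, parts in chrom_seqs.items():
        parts.append(_random_seq(rng, _FLANK, 0.5))
        reference[chrom] = "".join(parts)
    regions.sort(key=lambda r: (r.chrom, r.start))
    return Panel(regions=regions, reference=reference)


def _suppression(gc: np.ndarray, config: SimConfig) -> np.ndarray:
    if not config.gc_suppression:
        return np.ones_like(gc)
    span = max(config.gc_max - config.gc_knee, 1e-9)
    factor = 1.0 - (1.0 - config.gc_floor) * (gc - config.gc_knee) / span
    return np.clip(np.where(gc > config.gc_knee, factor, 1.0), config.gc_floor, 1.0)


def simulate_depth(
    panel: Panel,
    config: SimConfig,
    mean_depth: float | None = None,
    sample_id: str = "sample",
    stream: int = 2,
) -> list[RegionDepth]:
    """Log-normal region depths with GC suppression above the knee.

    ``region depth = mean_depth * LogNormal(-sigma^2/2, sigma) * s(gc)``
    where the suppression ``s`` is 1 up to the GC knee and declines
    linearly to the floor at ``gc_max``, so the multiplier has expectation
    ``mean_depth`` wherever suppression is off.
    """
    if mean_depth is None:
        mean_depth = config.mean_depth_blend
    if mean_depth <= 0:
        raise ValueError("mean depth must be positive")
    rng = _rng(config, stream)
    gc = np.array([r.gc_fraction for r in panel.regions])
    noise = rng.lognormal(-config.depth_sigma**2 / 2, config.depth_sigma,
                          size=len(panel.regions))
    depths = mean_depth * noise * _suppression(gc, config)
    return [
        RegionDepth(region=r, sample_id=sample_id, mean_depth=float(d))
        for r, d in zip(panel.regions, depths)
    ]


def simulate_per_base_depth(
    depths: Sequence[RegionDepth],
    config: SimConfig,
    stream: int = 3,
) -> pd.DataFrame:
    """Poisson per-base jitter around each region's mean depth.

    Returns a samtools-depth-style frame (chrom, 1-based pos, depth)
    covering every targeted base.
    """
    rng = _rng(config, stream)
    chroms: list[np.ndarray] = []
    positions: list[np.ndarray] = []
    values: list[np.ndarray] = []
    for rd in depths:
        n = rd.region.length
        chroms.append(np.full(n, rd.region.chrom, dtype=object))
        positions.append(np.arange(rd.region.start + 1, rd.region.end + 1))
        values.append(rng.poisson(max(rd.mean_depth, 0.0), size=n))
    return pd.DataFrame(
        {
            "chrom": np.concatenate(chroms),
            "pos": np.concatenate(positions),
            "depth": np.concatenate(values),
        }
    )


# ---------------------------------------------------------------------------
# Cell blends
# ---------------------------------------------------------------------------

def detection_probability(
    depth: int, true_vaf: float, min_vaf: float = 0.05, min_alt_reads: int = 10
) -> float:
    """P(a variant at this depth/VAF survives the call filters).

    The observed alt count is Binomial(depth, true_vaf); the call passes
    iff alt/depth >= min_vaf and alt >= min_alt_reads, i.e. alt >=
    max(ceil(min_vaf * depth), min_alt_reads).
    """
    if depth <= 0:
        return 0.0
    k = max(int(math.ceil(min_vaf * depth - 1e-9)), min_alt_reads)
    return float(binom.sf(k - 1, depth, true_vaf))


@dataclass
class BlendSimulation:
    """Generated blend material plus everything needed to audit recovery."""

    panel: Panel
    truth: dict[str, list[TruthRecord]]             # blend_id -> records
    calls: dict[str, dict[str, list[Variant]]]      # run_id -> blend_id -> calls
    negatives: list[TrueNegativeSite]
    region_depths: dict[str, list[RegionDepth]]     # blend_id -> depths
    # per (blend_id, variant key): filter-survival probability under the
    # generating model (0 for truth records outside the reportable mask)
    expected_detection: dict[tuple[str, tuple], float]
    true_vafs: dict[tuple, float]                   # variant key -> true VAF


def _background_vaf(rng: np.random.Generator) -> float:
    """Beta mixture spanning ~5-100%: low-fraction, heterozygous, homozygous."""
    u = rng.random()
    if u < 0.30:
        return 0.05 + 0.15 * rng.beta(2.0, 2.0)
    if u < 0.80:
        return float(np.clip(rng.beta(40, 40), 0.3, 0.7))
    return float(np.clip(rng.beta(45, 5), 0.8, 1.0))


def _pick_sites(
    panel: Panel,
    rng: np.random.Generator,
    count: int,
    used: set[tuple[str, int]],
    min_flank: int = 35,
) -> list[tuple[PanelRegion, int]]:
    """Sample distinct in-exon 1-based positions with clear left flank."""
    sites: list[tuple[PanelRegion, int]] = []
    attempts = 0
    while len(sites) < count:
        attempts += 1
        if attempts > 200 * count:
            raise ValueError("panel too small for the requested variant count")
        region = panel.regions[rng.integers(len(panel.regions))]
        if region.length < 12:
            continue
        pos = int(rng.integers(region.start + 5, region.end - 5)) + 1  # 1-based
        if region.start + 1 < min_flank:
            continue
        key = (region.chrom, pos)
        if any((region.chrom, p) in used for p in range(pos - 6, pos + 7)):
            continue
        used.add(key)
        sites.append((region, pos))
    return sites


def _make_snv(panel: Panel, region: PanelRegion, pos: int,
              rng: np.random.Generator) -> tuple[str, str]:
    ref = panel.reference[region.chrom][pos - 1]
    alt = str(rng.choice([b for b in "ACGT" if b != ref]))
    return ref, alt


def _make_indel(panel: Panel, region: PanelRegion, pos: int,
                rng: np.random.Generator) -> tuple[str, str]:
    anchor = panel.reference[region.chrom][pos - 1]
    size = int(rng.integers(1, 4))
    if rng.random() < 0.5:  # insertion
        return anchor, anchor + _random_seq(rng, size, 0.5)
    deleted = panel.reference[region.chrom][pos:pos + size]
    if len(deleted) < size:
        return anchor, anchor + _random_seq(rng, size, 0.5)
    return anchor + deleted, anchor


def simulate_blends(
    panel: Panel,
    config: SimConfig,
    n_runs: int = 1,
) -> BlendSimulation:
    """Generate blend truth sets and observed (filter-passing) call sets.

    Background variants are shared by all blends at a common true VAF;
    cancer variants are unique to one blend at a configured expected VAF.
    Observed alt reads are Binomial(region depth, true VAF) per blend and
    per run; a call is emitted iff it passes the VAF / alt-read filters.
    True-negative sites are sampled from cross-blend cancer SNV
    positions.  A configurable fraction of truth indels is anchored 4 bp
    into the intron: captured, but outside the exon +/-2 bp reportable
    footprint, hence structurally undetectable by a masked pipeline.
    """
    n_variants = (config.n_background_snvs + config.n_background_indels
                  + config.n_cancer_snvs + config.n_cancer_indels)
    footprint = sum(r.length for r in panel.regions)
    if n_variants * 13 > footprint:
        raise ValueError("more variants requested than the panel can host")

    rng = _rng(config, 4)
    blends = [f"blend{i + 1}" for i in range(config.n_blends)]
    used: set[tuple[str, int]] = set()

    def exon4_count(total: int) -> int:
        return int(round(config.indel_exon4_fraction * total))

    # --- background variants (shared by every blend) ---
    bg_records: list[tuple[str, int, str, str, float]] = []
    for region, pos in _pick_sites(panel, rng, config.n_background_snvs, used):
        ref, alt = _make_snv(panel, region, pos, rng)
        bg_records.append((region.chrom, pos, ref, alt, _background_vaf(rng)))
    n_bg_exon4 = exon4_count(config.n_background_indels)
    bg_indel_sites = _pick_sites(panel, rng, config.n_background_indels - n_bg_exon4, used)
    for region, pos in bg_indel_sites:
        ref, alt = _make_indel(panel, region, pos, rng)
        bg_records.append((region.chrom, pos, ref, alt, _background_vaf(rng)))
    for region, pos in _intronic_sites(panel, rng, n_bg_exon4, used):
        ref, alt = _make_indel(panel, region, pos, rng)
        bg_records.append((region.chrom, pos, ref, alt, _background_vaf(rng)))

    # --- cancer variants (unique per blend) ---
    def split(total: int) -> list[int]:
        base, rem = divmod(total, config.n_blends)
        return [base + (1 if i < rem else 0) for i in range(config.n_blends)]

    cancer_vafs = list(
        rng.uniform(max(config.cancer_vaf_min, 0.04), 0.05, size=config.n_low_vaf_snvs)
    ) + list(
        rng.uniform(max(config.cancer_vaf_min, 0.05) if config.n_low_vaf_snvs else config.cancer_vaf_min,
                    config.cancer_vaf_max,
                    size=config.n_cancer_snvs - config.n_low_vaf_snvs)
    )
    cancer_vafs = [float(v) for v in rng.permutation(cancer_vafs)]

    snv_split = split(config.n_cancer_snvs)
    indel_split = split(config.n_cancer_indels)
    cancer: dict[str, list[tuple[str, int, str, str, float]]] = {b: [] for b in blends}
    cancer_snv_sites: list[tuple[str, int, str, str]] = []  # for TN derivation
    vaf_iter = iter(cancer_vafs)
    for blend, n_snv in zip(blends, snv_split):
        for region, pos in _pick_sites(panel, rng, n_snv, used):
            ref, alt = _make_snv(panel, region, pos, rng)
            vaf = next(vaf_iter)
            cancer[blend].append((region.chrom, pos, ref, alt, vaf))
            cancer_snv_sites.append((region.chrom, pos, ref, blend))
    for blend, n_indel in zip(blends, indel_split):
        n_e4 = exon4_count(n_indel)
        for region, pos in _pick_sites(panel, rng, n_indel - n_e4, used):
            ref, alt = _make_indel(panel, region, pos, rng)
            vaf = float(rng.uniform(config.cancer_vaf_min, config.cancer_vaf_max))
            cancer[blend].append((region.chrom, pos, ref, alt, vaf))
        for region, pos in _intronic_sites(panel, rng, n_e4, used):
            ref, alt = _make_indel(panel, region, pos, rng)
            vaf = float(rng.uniform(config.cancer_vaf_min, config.cancer_vaf_max))
            cancer[blend].append((region.chrom, pos, ref, alt, vaf))

    # --- true-negative sites: wild-type blends at cancer SNV positions ---
    tn_pool = [
        (chrom, pos, ref, other)
        for chrom, pos, ref, carrier in cancer_snv_sites
        for other in blends if other != carrier
    ]
    n_tn = min(config.n_true_negatives, len(tn_pool))
    tn_index = rng.choice(len(tn_pool), size=n_tn, replace=False)
    negatives = [
        TrueNegativeSite(chrom=tn_pool[i][0], pos=tn_pool[i][1],
                         ref=tn_pool[i][2], blend_id=tn_pool[i][3])
        for i in sorted(tn_index)
    ]

    # --- assemble truth sets and sample observed calls ---
    truth: dict[str, list[TruthRecord]] = {}
    true_vafs: dict[tuple, float] = {}
    for blend in blends:
        records = [
            TruthRecord(chrom=c, pos=p, ref=r, alt=a, expected_vaf=v,
                        category="background", blend_id=blend)
            for c, p, r, a, v in bg_records
        ] + [
            TruthRecord(chrom=c, pos=p, ref=r, alt=a, expected_vaf=v,
                        category="cancer_specific", blend_id=blend)
            for c, p, r, a, v in cancer[blend]
        ]
        truth[blend] = records
        for rec in records:
            true_vafs[rec.key] = rec.expected_vaf

    from .variants import reportable_mask, mask_contains

    mask = reportable_mask(panel.regions, capture_pad=5, report_pad=2)
    region_of: dict[tuple[str, int], PanelRegion] = {}

    region_depths: dict[str, list[RegionDepth]] = {}
    depth_of: dict[str, dict[str, float]] = {}
    for i, blend in enumerate(blends):
        rds = simulate_depth(panel, config, config.mean_depth_blend,
                             sample_id=blend, stream=10 + i)
        region_depths[blend] = rds
        depth_of[blend] = {rd.region.name: rd.mean_depth for rd in rds}

    def region_for(chrom: str, pos: int) -> PanelRegion | None:
        for r in panel.regions:
            if r.chrom == chrom and r.start - 5 <= pos - 1 < r.end + 5:
                return r
        return None

    calls: dict[str, dict[str, list[Variant]]] = {}
    expected_detection: dict[tuple[str, tuple], float] = {}
    call_rng = _rng(config, 5)
    for run_index in range(n_runs):
        run_id = f"run{run_index + 1}"
        calls[run_id] = {}
        for blend in blends:
            blend_calls: list[Variant] = []
            for rec in truth[blend]:
                region = region_of.get((rec.chrom, rec.pos))
                if region is None:
                    region = region_for(rec.chrom, rec.pos)
                    region_of[(rec.chrom, rec.pos)] = region
                depth = int(round(depth_of[blend][region.name])) if region else 0
                depth = max(depth, 1)
                alt_reads = int(call_rng.binomial(depth, rec.expected_vaf))
                vaf_obs = alt_reads / depth
                if run_index == 0:
                    in_mask = mask_contains(mask, rec.chrom, rec.pos)
                    expected_detection[(blend, rec.key)] = (
                        detection_probability(depth, rec.expected_vaf,
                                              config.min_vaf, config.min_alt_reads)
                        if in_mask else 0.0
                    )
                if vaf_obs >= config.min_vaf and alt_reads >= config.min_alt_reads:
                    blend_calls.append(
                        Variant(chrom=rec.chrom, pos=rec.pos, ref=rec.ref,
                                alt=rec.alt, vaf=vaf_obs, alt_reads=alt_reads,
                                total_depth=depth, sample_id=blend)
                    )
            calls[run_id][blend] = blend_calls

    return BlendSimulation(
        panel=panel, truth=truth, calls=calls, negatives=negatives,
        region_depths=region_depths, expected_detection=expected_detection,
        true_vafs=true_vafs,
    )


def _intronic_sites(
    panel: Panel,
    rng: np.random.Generator,
    count: int,
    used: set[tuple[str, int]],
    offset: int = 4,
) -> list[tuple[PanelRegion, int]]:
    """Anchor positions ``offset`` bp past the exon end (captured at +/-5,
    outside the +/-2 reportable footprint)."""
    sites: list[tuple[PanelRegion, int]] = []
    attempts = 0
    while len(sites) < count:
        attempts += 1
        if attempts > 500 * max(count, 1):
            raise ValueError("could not place intronic indels")
        region = panel.regions[rng.integers(len(panel.regions))]
        pos = region.end + offset  # 1-based: exon last base is region.end
        if pos + 5 > len(panel.reference[region.chrom]):
            continue
        if (region.chrom, pos) in used:
            continue
        used.add((region.chrom, pos))
        sites.append((region, pos))
    return sites


# ---------------------------------------------------------------------------
# Paired FFPE / FF cohort
# ---------------------------------------------------------------------------

@dataclass
class PairedCohort:
    calls_ffpe: dict[str, list[Variant]]
    calls_ff: dict[str, list[Variant]]
    manifest: list[tuple[str, str]]


def _shared_vaf(rng: np.random.Generator) -> float:
    u = rng.random()
    if u < 0.40:
        return float(rng.uniform(0.05, 0.20))
    if u < 0.80:
        return float(np.clip(rng.normal(0.5, 0.05), 0.25, 0.75))
    return float(rng.uniform(0.90, 1.0))


def _stratum_vaf(rng: np.random.Generator, probs: Sequence[float]) -> float:
    stratum = rng.choice(3, p=np.asarray(probs) / np.sum(probs))
    if stratum == 0:
        return float(rng.uniform(0.01, 0.0499))
    if stratum == 1:
        return float(rng.uniform(0.05, 0.0999))
    return float(rng.uniform(0.10, 0.35))


def simulate_paired_cohort(panel: Panel, config: SimConfig) -> PairedCohort:
    """Paired FFPE/FF call sets with low-VAF-dominated discordance.

    Shared variants carry correlated VAFs (FFPE adds Gaussian noise);
    FF-only calls are subclonal low-VAF variants lost in the degraded
    FFPE library; FFPE-only calls are artefacts, mostly deamination-like
    C>T / G>A changes, concentrated below 5% VAF.
    """
    rng = _rng(config, 6)
    calls_ffpe: dict[str, list[Variant]] = {}
    calls_ff: dict[str, list[Variant]] = {}
    manifest: list[tuple[str, str]] = []

    for pair_index in range(config.n_pairs):
        ffpe_id = f"FFPE{pair_index + 1:02d}"
        ff_id = f"FF{pair_index + 1:02d}"
        manifest.append((ffpe_id, ff_id))
        used: set[tuple[str, int]] = set()
        total = config.pair_shared + config.pair_ff_only + config.pair_ffpe_only
        sites = _pick_sites(panel, rng, total, used, min_flank=0)

        ffpe_list: list[Variant] = []
        ff_list: list[Variant] = []
        cursor = 0
        for _ in range(config.pair_shared):
            region, pos = sites[cursor]; cursor += 1
            ref, alt = _make_snv(panel, region, pos, rng)
            vaf_ff = _shared_vaf(rng)
            vaf_ffpe = float(np.clip(vaf_ff + rng.normal(0, config.ffpe_noise_sd), 0.01, 1.0))
            depth_ff = max(int(rng.poisson(config.mean_depth_ff)), 1)
            depth_ffpe = max(int(rng.poisson(config.mean_depth_ffpe)), 1)
            ff_list.append(Variant(region.chrom, pos, ref, alt, vaf=vaf_ff,
                                   alt_reads=int(round(vaf_ff * depth_ff)),
                                   total_depth=depth_ff, sample_id=ff_id))
            ffpe_list.append(Variant(region.chrom, pos, ref, alt, vaf=vaf_ffpe,
                                     alt_reads=int(round(vaf_ffpe * depth_ffpe)),
                                     total_depth=depth_ffpe, sample_id=ffpe_id))
        for _ in range(config.pair_ff_only):
            region, pos = sites[cursor]; cursor += 1
            ref, alt = _make_snv(panel, region, pos, rng)
            vaf = _stratum_vaf(rng, config.ff_only_strata)
            depth = max(int(rng.poisson(config.mean_depth_ff)), 1)
            ff_list.append(Variant(region.chrom, pos, ref, alt, vaf=vaf,
                                   alt_reads=int(round(vaf * depth)),
                                   total_depth=depth, sample_id=ff_id))
        for _ in range(config.pair_ffpe_only):
            region, pos = sites[cursor]; cursor += 1
            ref = panel.reference[region.chrom][pos - 1]
            if rng.random() < config.ffpe_ct_fraction and ref in "CG":
                alt = "T" if ref == "C" else "A"
            else:
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            vaf = _stratum_vaf(rng, config.ffpe_only_strata)
            depth = max(int(rng.poisson(config.mean_depth_ffpe)), 1)
            ffpe_list.append(Variant(region.chrom, pos, ref, alt, vaf=vaf,
                                     alt_reads=int(round(vaf * depth)),
                                     total_depth=depth, sample_id=ffpe_id))
        calls_ffpe[ffpe_id] = ffpe_list
        calls_ff[ff_id] = ff_list

    return PairedCohort(calls_ffpe=calls_ffpe, calls_ff=calls_ff, manifest=manifest)


def exact_counts_table() -> "pd.DataFrame":
    """Deterministic paired table carrying the reference discordance
    profile as fixed counts.

    13,146 rows pooled over the cohort: 6,500 shared, 5,562 FF-only
    (4,346 below 5% VAF, 982 in 5-10%, 234 at or above 10%) and 1,084
    FFPE-only (551 / 360 / 173 in the same strata).  Shared VAFs are an
    evenly spaced grid so correlations are well-defined.  Synthetic:
    keys are placeholders, only the counts and VAF strata are meaningful.
    """
    rows: list[dict] = []

    def add(count: int, vaf: float | None, which: str, start: int) -> int:
        for i in range(count):
            vaf_ff = vaf if which in ("ff", "both") else np.nan
            vaf_ffpe = vaf if which in ("ffpe", "both") else np.nan
            rows.append({
                "sample_pair_id": "pooled", "chrom": "chrS",
                "pos": start + i, "ref": "A", "alt": "T",
                "vaf_ffpe": vaf_ffpe, "vaf_ff": vaf_ff,
            })
        return start + count

    cursor = 1
    shared_vafs = np.linspace(0.05, 0.95, 6500)
    for i, v in enumerate(shared_vafs):
        rows.append({
            "sample_pair_id": "pooled", "chrom": "chrS", "pos": cursor + i,
            "ref": "A", "alt": "T", "vaf_ffpe": float(v), "vaf_ff": float(v),
        })
    cursor += 6500
    cursor = add(4346, 0.03, "ff", cursor)
    cursor = add(982, 0.07, "ff", cursor)
    cursor = add(234, 0.15, "ff", cursor)
    cursor = add(551, 0.03, "ffpe", cursor)
    cursor = add(360, 0.07, "ffpe", cursor)
    cursor = add(173, 0.15, "ffpe", cursor)
    return pd.DataFrame(rows, columns=["sample_pair_id", "chrom", "pos",
                                       "ref", "alt", "vaf_ffpe", "vaf_ff"])


# ---------------------------------------------------------------------------
# CNV cohorts
# ---------------------------------------------------------------------------

@dataclass
class CnvCohort:
    tumour: list[RegionDepth]
    control: list[RegionDepth]
    truth_labels: dict[str, str]  # gene -> deletion | neutral | amplification


def simulate_cnv_cohort(
    panel: Panel,
    events: Mapping[str, float],
    purity: float = 1.0,
    config: SimConfig | None = None,
) -> CnvCohort:
    """Tumour/control depth tables with copy-number events injected.

    ``events`` maps gene symbols to integer copy numbers on a diploid
    background; event-gene regions in the tumour are scaled by
    ``(purity * CN + (1 - purity) * 2) / 2``.
    """
    config = config or SimConfig()
    genes = {r.gene for r in panel.regions}
    unknown = set(events) - genes
    if unknown:
        raise ValueError(f"events reference genes absent from the panel: {sorted(unknown)}")
    if not 0.0 < purity <= 1.0:
        raise ValueError("purity must lie in (0, 1]")

    # Capture efficiency is a property of the region (bait performance, GC),
    # shared by the tumour and control libraries; only a small per-sample
    # term differs.  The tumour/control ratio therefore cancels the region
    # effect -- the premise of ratio-based copy-number calling.
    rng = _rng(config, 20)
    gc = np.array([r.gc_fraction for r in panel.regions])
    efficiency = (rng.lognormal(-config.depth_sigma**2 / 2, config.depth_sigma,
                                size=len(panel.regions))
                  * _suppression(gc, config))
    sigma = config.cnv_sample_sigma
    control_noise = rng.lognormal(-sigma**2 / 2, sigma, size=len(panel.regions))
    tumour_noise = rng.lognormal(-sigma**2 / 2, sigma, size=len(panel.regions))

    control: list[RegionDepth] = []
    tumour: list[RegionDepth] = []
    for i, region in enumerate(panel.regions):
        base = config.mean_depth_blend * efficiency[i]
        control.append(RegionDepth(region=region, sample_id="control",
                                   mean_depth=float(base * control_noise[i])))
        cn = events.get(region.gene)
        scale = 1.0 if cn is None else (purity * cn + (1.0 - purity) * 2.0) / 2.0
        tumour.append(RegionDepth(region=region, sample_id="tumour",
                                  mean_depth=float(base * tumour_noise[i] * scale)))
    truth_labels = {}
    for gene in sorted(genes):
        cn = events.get(gene, 2)
        expected_ratio = (purity * cn + (1.0 - purity) * 2.0) / 2.0
        if cn < 2:
            truth_labels[gene] = "deletion"
        elif cn > 2:
            truth_labels[gene] = "amplification"
        else:
            truth_labels[gene] = "neutral"
    return CnvCohort(tumour=tumour, control=control, truth_labels=truth_labels)


# ---------------------------------------------------------------------------
# Read-level QC statistics
# ---------------------------------------------------------------------------

def simulate_read_stats(
    config: SimConfig,
    cohort: str,
    n_samples: int,
    stream: int = 30,
) -> pd.DataFrame:
    """Per-sample read counts for sample-level QC (FFPE vs FF cohorts).

    FFPE libraries duplicate more (degraded input, more PCR) and map
    slightly worse than fresh-frozen ones.
    """
    if cohort not in ("FFPE", "FF"):
        raise ValueError("cohort must be 'FFPE' or 'FF'")
    rng = _rng(config, stream + (0 if cohort == "FFPE" else 1))
    total_mean = config.total_reads_ffpe if cohort == "FFPE" else config.total_reads_ff
    dup_rate = config.dup_rate_ffpe if cohort == "FFPE" else config.dup_rate_ff
    map_rate = 0.961 if cohort == "FFPE" else 0.973
    on_target = 0.459 if cohort == "FFPE" else 0.427
    rows = []
    for i in range(n_samples):
        total = int(max(rng.normal(total_mean, 0.3 * total_mean), 1e5))
        mapped = int(total * np.clip(rng.normal(map_rate, 0.01), 0.5, 1.0))
        duplicates = int(mapped * np.clip(rng.normal(dup_rate, 0.05), 0.0, 0.99))
        unique_bases = (mapped - duplicates) * 75
        on_target_bases = int(unique_bases * np.clip(rng.normal(on_target, 0.02), 0.1, 0.9))
        rows.append({
            "sample_id": f"{cohort}{i + 1:02d}", "cohort": cohort,
            "total_reads": total, "mapped_reads": mapped,
            "duplicate_reads": duplicates,
            "total_unique_bases": unique_bases,
            "on_target_unique_bases": on_target_bases,
        })
    return pd.DataFrame(rows)
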