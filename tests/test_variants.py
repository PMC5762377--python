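"""Variant model, normalization, filtering and truth matching."""

import numpy as np
import pytest

from panelval.variants import (
    DuplicateCallError,
    ReferenceMismatchError,
    TruthRecord,
    TrueNegativeSite,
    Variant,
    apply_call_filters,
    match_to_truth,
    mask_contains,
    normalize_variant,
    read_vcf,
    reportable_mask,
    write_vcf,
)


def brute_force_normalize(pos, ref, alt, window, window_start):
    """Oracle: enumerate every equivalent (pos, ref, alt) representation in
    the window and return the parsimonious one with minimal position.

    A representation is equivalent iff applying it to the window yields the
    same edited sequence and it shifts the same net length.  Parsimony first
    (minimal total allele length), leftmost position second.
    """
    target = (
        window[: pos - window_start]
        + alt
        + window[pos - window_start + len(ref):]
    )
    candidates = []
    for p in range(window_start, window_start + len(window)):
        i = p - window_start
        for rlen in range(0, len(window) - i + 1):
            r = window[i:i + rlen]
            alen = len(target) - (len(window) - rlen)
            if alen < 0 or i + alen > len(target):
                continue
            a = target[i:i + alen]
            edited = window[:i] + a + window[i + rlen:]
            if edited != target:
                continue
            if not r or not a or r == a:
                continue
            candidates.append((len(r) + len(a), p, r, a))
    assert candidates, "no equivalent representation found"
    _, p, r, a = min(candidates)
    return p, r, a


class TestNormalize:
    def test_snv_unchanged(self):
        v = Variant("chr1", 100, "A", "T")
        assert normalize_variant(v, "GGAGG", 98) == v

    def test_mnv_without_shared_bases_unchanged(self):
        v = Variant("chr1", 100, "AT", "GC")
        out = normalize_variant(v, "GGATGG", 98)
        assert (out.pos, out.ref, out.alt) == (100, "AT", "GC")

    def test_homopolymer_deletion_left_aligned(self):
        # deleting one A of the run AAAAA written at its right edge must
        # shift to the run's left edge, anchored on the preceding T
        window, start = "TTAAAAACAGGT", 98
        v = Variant("chr1", 103, "AA", "A")
        out = normalize_variant(v, window, start)
        expected = brute_force_normalize(103, "AA", "A", window, start)
        assert (out.pos, out.ref, out.alt) == expected == (99, "TA", "T")

    def test_shared_suffix_trimmed(self):
        window, start = "TTAAAAACAGGT", 98
        v = Variant("chr1", 105, "CAG", "CG")  # deletion of A written with suffix
        out = normalize_variant(v, window, start)
        expected = brute_force_normalize(105, "CAG", "CG", window, start)
        assert (out.pos, out.ref, out.alt) == expected

    def test_reference_mismatch_raises(self):
        with pytest.raises(ReferenceMismatchError):
            normalize_variant(Variant("chr1", 100, "C", "T"), "GGAGG", 98)

    def test_matches_enumeration_oracle_on_random_indels(self):
        # random indels re-expressed with random padding must normalize to
        # the exhaustive-enumeration minimum
        rng = np.random.default_rng(42)
        bases = "ACGT"
        for _ in range(500):
            window = "".join(rng.choice(list(bases), size=int(rng.integers(20, 51))))
            start = int(rng.integers(1, 1000))
            i = int(rng.integers(5, len(window) - 8))
            pos = start + i
            if rng.random() < 0.5:  # deletion
                size = int(rng.integers(1, 4))
                ref = window[i:i + 1 + size]
                alt = window[i]
            else:  # insertion
                ref = window[i]
                alt = ref + "".join(rng.choice(list(bases), size=int(rng.integers(1, 4))))
            # pad with shared reference suffix to fake a denormalized caller
            pad = int(rng.integers(0, 3))
            suffix_start = i + len(ref)
            if suffix_start + pad <= len(window):
                ref_p = ref + window[suffix_start:suffix_start + pad]
                alt_p = alt + window[suffix_start:suffix_start + pad]
            else:
                ref_p, alt_p = ref, alt
            out = normalize_variant(Variant("chrT", pos, ref_p, alt_p), window, start)
            expected = brute_force_normalize(pos, ref_p, alt_p, window, start)
            assert (out.pos, out.ref, out.alt) == expected


class TestVariantModel:
    def test_class_assignment(self):
        assert Variant("chr1", 5, "A", "T").variant_class == "SNV"
        assert Variant("chr1", 5, "A", "AT").variant_class == "indel"
        # a duplication is an insertion, hence indel-class
        assert Variant("chr1", 5, "T", "TACG").variant_class == "indel"
        assert Variant("chr1", 5, "AT", "GC").variant_class == "indel"

    @pytest.mark.parametrize("kwargs", [
        dict(ref="A", alt="A"),
        dict(ref="", alt="T"),
        dict(ref="N", alt="T"),
        dict(ref="A", alt="T", vaf=1.5),
        dict(ref="A", alt="T", alt_reads=-1),
    ])
    def test_invalid_variants_rejected(self, kwargs):
        with pytest.raises(ValueError):
            Variant("chr1", 10, **{"vaf": 0.5, "alt_reads": 5,
                                   "total_depth": 10, **kwargs})


class TestCallFilters:
    def test_threshold_boundaries(self):
        low_vaf = Variant("chr1", 1, "A", "T", vaf=0.04, alt_reads=40, total_depth=1000)
        low_reads = Variant("chr1", 2, "A", "T", vaf=0.20, alt_reads=8, total_depth=40)
        good = Variant("chr1", 3, "A", "T", vaf=0.50, alt_reads=100, total_depth=200)
        kept, removed = apply_call_filters([low_vaf, low_reads, good], 0.05, 10)
        assert kept == [good]
        assert removed == [low_vaf, low_reads]

    def test_partition_preserves_order_and_idempotence(self):
        rng = np.random.default_rng(0)
        calls = [
            Variant("chr1", int(p), "A", "T", vaf=float(v), alt_reads=int(a),
                    total_depth=200)
            for p, v, a in zip(range(1, 101), rng.uniform(0, 1, 100),
                               rng.integers(0, 40, 100))
        ]
        kept, removed = apply_call_filters(calls)
        assert kept + removed and sorted(kept + removed, key=calls.index) == calls
        assert apply_call_filters(kept) == (kept, [])

    def test_empty_input(self):
        assert apply_call_filters([]) == ([], [])


class TestReportableMask:
    def test_single_exon_extension(self):
        mask = reportable_mask([("chr1", 100, 200)], capture_pad=5, report_pad=2)
        assert mask == {"chr1": [(98, 202)]}

    def test_abutting_exons_merge(self):
        mask = reportable_mask([("chr1", 100, 200), ("chr1", 200, 300)],
                               capture_pad=5, report_pad=2)
        assert mask == {"chr1": [(98, 302)]}

    def test_intronic_fringe_outside_report_inside_capture(self):
        # a variant 4 bp past the exon end: captured (pad 5) but unreportable (pad 2)
        region = [("chr1", 100, 200)]
        report = reportable_mask(region, capture_pad=5, report_pad=2)
        capture = reportable_mask(region, capture_pad=5, report_pad=5)
        pos = 204  # 1-based: exon last base is 200, +4 into the intron
        assert not mask_contains(report, "chr1", pos)
        assert mask_contains(capture, "chr1", pos)

    def test_pad_validation(self):
        with pytest.raises(ValueError):
            reportable_mask([("chr1", 0, 10)], capture_pad=2, report_pad=5)
        with pytest.raises(ValueError):
            reportable_mask([("chr1", 0, 10)], capture_pad=5, report_pad=-1)


class TestMatchToTruth:
    def _truth(self, n, blend="b1"):
        return [TruthRecord("chr1", 10 * (i + 1), "A", "T", expected_vaf=0.5,
                            blend_id=blend) for i in range(n)]

    def test_all_detected(self):
        truth = self._truth(5)
        calls = [Variant("chr1", t.pos, "A", "T", vaf=0.48, alt_reads=50,
                         total_depth=100, sample_id="b1") for t in truth]
        result = match_to_truth(calls, truth)
        assert result.counts["SNV"].tp == 5
        assert result.counts["SNV"].fn == 0
        assert len(result.vaf_pairs) == 5

    def test_nothing_called(self):
        result = match_to_truth([], self._truth(3))
        cc = result.counts["SNV"]
        assert (cc.tp, cc.fn, cc.fp) == (0, 3, 0)

    def test_negative_sites_partition(self):
        negatives = [TrueNegativeSite("chr1", 100, "G", "b1"),
                     TrueNegativeSite("chr1", 200, "G", "b1")]
        fp_call = Variant("chr1", 100, "G", "A", vaf=0.2, alt_reads=20,
                          total_depth=100, sample_id="b1")
        result = match_to_truth([fp_call], [], negatives)
        cc = result.counts["SNV"]
        assert (cc.fp, cc.tn) == (1, 1)

    def test_counts_partition_truth_and_negatives(self, blend_sim, small_config):
        blend = "blend1"
        truth = blend_sim.truth[blend]
        negatives = [n for n in blend_sim.negatives if n.blend_id == blend]
        result = match_to_truth(blend_sim.calls["run1"][blend], truth, negatives)
        pooled = result.counts["all"]
        assert pooled.tp + pooled.fn == len(truth)
        assert pooled.fp + pooled.tn == len(negatives)

    def test_duplicate_call_key_rejected(self):
        call = Variant("chr1", 10, "A", "T", vaf=0.5, alt_reads=50,
                       total_depth=100, sample_id="b1")
        with pytest.raises(DuplicateCallError):
            match_to_truth([call, call], self._truth(1))


class TestVcfRoundTrip:
    def test_keys_and_vafs_survive(self, tmp_path, blend_sim):
        calls = blend_sim.calls["run1"]["blend1"]
        path = tmp_path / "calls.vcf"
        contigs = {c: len(s) for c, s in blend_sim.panel.reference.items()}
        write_vcf(calls, path, sample_id="blend1", contigs=contigs)
        back = read_vcf(path, "blend1")
        assert {c.key for c in back} == {c.key for c in calls}
        vafs_in = {c.key: c.vaf for c in calls}
        for c in back:
            assert abs(c.vaf - vafs_in[c.key]) < 5e-5
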