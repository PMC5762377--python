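"""Synthetic-data generators: design scale, determinism, generating models."""

import math

import numpy as np
import pytest
from scipy.stats import pearsonr

from panelval.synthetic import (
    SimConfig,
    detection_probability,
    exact_counts_table,
    simulate_blends,
    simulate_cnv_cohort,
    simulate_depth,
    simulate_paired_cohort,
    simulate_panel,
    simulate_per_base_depth,
)


class TestPanel:
    def test_design_scale_defaults(self, design_panel):
        assert len(design_panel.regions) == 901
        footprint = sum(r.length for r in design_panel.regions)
        assert abs(footprint - 311_000) / 311_000 < 0.10
        assert len({r.gene for r in design_panel.regions}) == 78

    def test_gc_spread_with_high_tail(self, design_panel):
        gc = np.array([r.gc_fraction for r in design_panel.regions])
        assert gc.min() < 0.35 and gc.max() > 0.75
        assert (gc > 0.70).mean() > 0.05

    def test_minimum_region_count(self):
        with pytest.raises(ValueError):
            simulate_panel(SimConfig(seed=1, n_regions=5))

    def test_small_panel_regions_covered_by_reference(self, small_panel):
        for region in small_panel.regions:
            seq = small_panel.reference[region.chrom]
            assert len(seq) >= region.end

    def test_same_seed_byte_identical_outputs(self, tmp_path):
        config = SimConfig.preset("small", seed=123)
        for name in ("a", "b"):
            panel = simulate_panel(config)
            panel.write_fasta(tmp_path / f"{name}.fa")
            panel.write_bed(tmp_path / f"{name}.bed")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()
        assert (tmp_path / "a.bed").read_bytes() == (tmp_path / "b.bed").read_bytes()


class TestDepth:
    def test_no_suppression_uncorrelated_with_gc(self, design_panel):
        config = SimConfig(seed=11, gc_suppression=False)
        depths = simulate_depth(design_panel, config, 700)
        gc = [d.region.gc_fraction for d in depths]
        values = [d.mean_depth for d in depths]
        assert abs(pearsonr(values, gc).statistic) < 0.1

    def test_ff_deeper_than_ffpe(self, design_panel, design_config):
        ffpe = simulate_depth(design_panel, design_config,
                              design_config.mean_depth_ffpe, "ffpe", stream=40)
        ff = simulate_depth(design_panel, design_config,
                            design_config.mean_depth_ff, "ff", stream=41)
        assert np.mean([d.mean_depth for d in ff]) > np.mean([d.mean_depth for d in ffpe])

    def test_high_gc_regions_dominate_depth_floor(self, design_panel, design_config):
        depths = simulate_depth(design_panel, design_config, 700)
        values = np.array([d.mean_depth for d in depths])
        gc = np.array([d.region.gc_fraction for d in depths])
        bottom = np.argsort(values)[: max(int(0.03 * len(values)), 1)]
        assert (gc[bottom] > 0.8).mean() > 0.5

    def test_per_base_track_covers_target(self, small_panel, small_config):
        depths = simulate_depth(small_panel, small_config, 300)
        track = simulate_per_base_depth(depths, small_config)
        assert len(track) == sum(r.length for r in small_panel.regions)
        assert (track["depth"] >= 0).all()


class TestBlends:
    def test_design_counts(self, design_panel, design_config):
        sim = simulate_blends(design_panel, design_config)
        assert set(sim.truth) == {"blend1", "blend2", "blend3", "blend4"}
        for records in sim.truth.values():
            background = [r for r in records if r.category == "background"]
            snvs = [r for r in background if r.variant_class == "SNV"]
            indels = [r for r in background if r.variant_class == "indel"]
            assert len(snvs) == 163 and len(indels) == 34
        cancer = [r for records in sim.truth.values() for r in records
                  if r.category == "cancer_specific"]
        assert sum(r.variant_class == "SNV" for r in cancer) == 61
        assert sum(r.variant_class == "indel" for r in cancer) == 17
        assert len(sim.negatives) == 87

    def test_cancer_variants_unique_across_blends(self, blend_sim):
        seen = {}
        for blend, records in blend_sim.truth.items():
            for r in records:
                if r.category != "cancer_specific":
                    continue
                assert r.key not in seen, "cancer variant shared between blends"
                seen[r.key] = blend

    def test_negatives_sit_at_other_blends_cancer_sites(self, blend_sim):
        cancer_sites = {
            (r.chrom, r.pos): blend
            for blend, records in blend_sim.truth.items()
            for r in records if r.category == "cancer_specific"
        }
        for site in blend_sim.negatives:
            carrier = cancer_sites.get((site.chrom, site.pos))
            assert carrier is not None and carrier != site.blend_id

    def test_observed_calls_respect_filters(self, blend_sim, small_config):
        for blends in blend_sim.calls.values():
            for calls in blends.values():
                for c in calls:
                    assert c.vaf >= small_config.min_vaf
                    assert c.alt_reads >= small_config.min_alt_reads

    def test_detection_probability_matches_monte_carlo(self):
        # P(Bin(700, v)/700 >= 0.05 and >= 10 reads) against simulation
        rng = np.random.default_rng(77)
        for vaf, tol in ((0.04, 0.01), (0.10, 0.005), (0.5, 1e-12)):
            p = detection_probability(700, vaf)
            draws = rng.binomial(700, vaf, 100_000)
            mc = np.mean((draws / 700 >= 0.05) & (draws >= 10))
            assert abs(p - mc) < max(tol, 3 * math.sqrt(p * (1 - p) / 100_000) + 1e-3)
        assert detection_probability(700, 0.5) == pytest.approx(1.0)
        assert abs(detection_probability(700, 0.04) - 0.08) < 0.04

    def test_noiseless_limit_detects_everything(self, small_panel):
        # pushing depth up makes binomial sampling negligible: every >=5%
        # variant passes the filters
        config = SimConfig.preset("small", seed=5)
        config.mean_depth_blend = 2_000_000
        config.depth_sigma = 1e-6
        sim = simulate_blends(small_panel, config)
        for blend, records in sim.truth.items():
            called = {c.key for c in sim.calls["run1"][blend]}
            for rec in records:
                if rec.expected_vaf >= 0.051:
                    assert rec.key in called


class TestPairedCohortGenerator:
    def test_zero_artefact_rates_fully_shared(self, small_panel):
        config = SimConfig.preset("small", seed=9)
        config.pair_ff_only = 0
        config.pair_ffpe_only = 0
        cohort = simulate_paired_cohort(small_panel, config)
        for (ffpe_id, ff_id) in cohort.manifest:
            keys_ffpe = {c.key for c in cohort.calls_ffpe[ffpe_id]}
            keys_ff = {c.key for c in cohort.calls_ff[ff_id]}
            assert keys_ffpe == keys_ff

    def test_default_band_properties(self, design_panel, design_config):
        cohort = simulate_paired_cohort(design_panel, design_config)
        n_ff_only = n_union = n_ff_only_low = 0
        for (ffpe_id, ff_id) in cohort.manifest:
            ffpe = {c.key: c.vaf for c in cohort.calls_ffpe[ffpe_id]}
            ff = {c.key: c.vaf for c in cohort.calls_ff[ff_id]}
            only = set(ff) - set(ffpe)
            n_ff_only += len(only)
            n_union += len(set(ff) | set(ffpe))
            n_ff_only_low += sum(ff[k] < 0.05 for k in only)
        assert 0.35 <= n_ff_only / n_union <= 0.50
        assert n_ff_only_low / n_ff_only > 0.70

    def test_exact_counts_fixture_row_counts(self):
        frame = exact_counts_table()
        assert len(frame) == 13146
        ff_only = frame[frame["vaf_ffpe"].isna()]
        ffpe_only = frame[frame["vaf_ff"].isna()]
        assert len(ff_only) == 5562
        assert (ff_only["vaf_ff"] < 0.05).sum() == 4346
        assert len(ffpe_only) == 1084


class TestCnvCohort:
    def test_event_scaling(self, small_panel):
        config = SimConfig.preset("small", seed=13)
        genes = small_panel.genes
        cohort = simulate_cnv_cohort(small_panel, {genes[0]: 30}, purity=1.0,
                                     config=config)
        t = {rd.region.name: rd.mean_depth for rd in cohort.tumour}
        c = {rd.region.name: rd.mean_depth for rd in cohort.control}
        for rd in cohort.tumour:
            ratio = t[rd.region.name] / c[rd.region.name]
            if rd.region.gene == genes[0]:
                assert 10 < ratio < 22  # expected x15 within sampling noise
            else:
                assert 0.7 < ratio < 1.4

    def test_arm_loss_scale_at_partial_purity(self, small_panel):
        # CN=1 at purity 0.8: expected scale (0.8 + 0.4)/2 = 0.6
        config = SimConfig.preset("small", seed=13)
        gene = small_panel.genes[1]
        cohort = simulate_cnv_cohort(small_panel, {gene: 1}, purity=0.8,
                                     config=config)
        t = {rd.region.name: rd.mean_depth for rd in cohort.tumour}
        c = {rd.region.name: rd.mean_depth for rd in cohort.control}
        ratios = [t[rd.region.name] / c[rd.region.name]
                  for rd in cohort.tumour if rd.region.gene == gene]
        assert 0.5 < np.median(ratios) < 0.7

    def test_unknown_gene_rejected(self, small_panel):
        with pytest.raises(ValueError):
            simulate_cnv_cohort(small_panel, {"NOT_A_GENE": 8}, purity=1.0)

    def test_neutral_everywhere(self, small_panel):
        config = SimConfig.preset("small", seed=13)
        cohort = simulate_cnv_cohort(small_panel, {}, purity=1.0, config=config)
        assert set(cohort.truth_labels.values()) == {"neutral"}


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        config = SimConfig.preset("small", seed=42)
        config.to_yaml(tmp_path / "c.yaml")
        back = SimConfig.from_yaml(tmp_path / "c.yaml")
        assert back == config

    def test_unknown_keys_rejected(self, tmp_path):
        (tmp_path / "bad.yaml").write_text("seed: 1\nnot_a_knob: 2\n")
        with pytest.raises(ValueError):
            SimConfig.from_yaml(tmp_path / "bad.yaml")

    def test_reference_preset_places_low_vaf_snvs(self):
        config = SimConfig.preset("reference", seed=1)
        assert config.cancer_vaf_min == 0.04
        assert config.n_low_vaf_snvs == 33
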