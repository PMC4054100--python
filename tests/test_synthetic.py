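"""Synthetic scene generator: determinism, planted expectations, controls."""
import dataclasses
import filecmp
import json

import numpy as np
import pandas as pd
import pytest

import retrocount as rc
from retrocount.synthetic import (ConfigError, PlacementError, Scene,
                                  SyntheticConfig, SyntheticTruth, build_truth,
                                  generate_annotation, place_ccgg_sites,
                                  simulate_help_tags, simulate_rna_reads,
                                  simulate_scene, write_scene)


def small_config(**overrides) -> SyntheticConfig:
    """A fast, reduced scene for generator unit tests."""
    base = dict(
        chrom_sizes={"chr1": 2_000_000, "chr2": 1_500_000},
        n_loci_per_class={"LINE": 30, "LTR": 20, "SINE": 30,
                          "Satellite": 10, "tRNA": 10},
        library_depth={"hpaii": 5_000, "mspi": 5_000},
        base_expression=10.0, gene_expression=20.0, n_genes=30,
    )
    base.update(overrides)
    return SyntheticConfig(**base).validate()


class TestAnnotationGeneration:
    def test_zero_loci_gives_empty_valid_annotation(self, tmp_path):
        cfg = small_config(n_loci_per_class={"LTR": 0})
        scene = simulate_scene(cfg, seed=1)
        assert scene.annotation.empty
        paths = write_scene(scene, tmp_path)
        from retrocount.annotation import parse_repeatmasker_out
        assert parse_repeatmasker_out(paths["repeats_out"]).empty

    def test_same_seed_identical_files(self, tmp_path):
        cfg = small_config()
        write_scene(simulate_scene(cfg, seed=7), tmp_path / "a")
        write_scene(simulate_scene(cfg, seed=7), tmp_path / "b")
        for name in ["repeats.out", "repeats.bed", "genes.bed", "truth.json",
                     "hpaii_control.bed", "hpaii_mutant.bed",
                     "mspi_control.bed", "mspi_mutant.bed",
                     "rna_control.bed", "rna_mutant.bed", "config.json"]:
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name,
                               shallow=False), name

    def test_impossible_placement_names_class(self):
        cfg = small_config(
            chrom_sizes={"chr1": 10_000},
            n_loci_per_class={"LTR": 50},
            locus_length_range=(1_000, 1_000))
        with pytest.raises(PlacementError, match="LTR"):
            generate_annotation(cfg)

    def test_loci_non_overlapping_and_within_bounds(self):
        cfg = small_config()
        ann, genes = generate_annotation(cfg)
        assert (ann["start"] < ann["end"]).all()
        for chrom, sub in ann.groupby("chrom"):
            sub = sub.sort_values("start")
            assert (sub["start"].to_numpy()[1:] >=
                    sub["end"].to_numpy()[:-1]).all()
            assert sub["end"].max() <= cfg.chrom_sizes[chrom]
        assert ann["locus_id"].is_unique
        # class/family/name hierarchy is consistent
        assert (ann.groupby("rep_name")["rep_family"].nunique() == 1).all()
        assert (ann.groupby("rep_family")["rep_class"].nunique() == 1).all()

    def test_gene_offset_placement(self):
        # each gene is anchored at the configured gap from some repeat
        cfg = small_config(gene_offset_from_repeats=5_000, n_genes=10)
        ann, genes = generate_annotation(cfg)
        for _, g in genes.iterrows():
            gaps = [
                max(0, max(r["start"] - g["end"], g["start"] - r["end"]))
                for _, r in ann[ann["chrom"] == g["chrom"]].iterrows()]
            assert min(gaps) <= 5_000


class TestCcggSites:
    def test_zero_rates_give_empty_table(self):
        cfg = small_config(ccgg_rate=0.0, ccgg_background_rate=0.0)
        ann, _ = generate_annotation(cfg)
        assert place_ccgg_sites(ann, cfg).empty

    def test_containment(self):
        cfg = small_config()
        ann, _ = generate_annotation(cfg)
        sites = place_ccgg_sites(ann, cfg)
        by_id = ann.set_index("locus_id")
        inside = sites[sites["locus_id"].notna()]
        starts = by_id.loc[inside["locus_id"], "start"].to_numpy()
        ends = by_id.loc[inside["locus_id"], "end"].to_numpy()
        assert ((inside["pos"].to_numpy() >= starts)
                & (inside["pos"].to_numpy() < ends)).all()
        # background sites fall outside every locus
        outside = sites[sites["locus_id"].isna()]
        for _, s in outside.head(50).iterrows():
            hits = ann[(ann["chrom"] == s["chrom"]) & (ann["start"] <= s["pos"])
                       & (s["pos"] < ann["end"])]
            assert hits.empty

    def test_poisson_rate_recovered(self):
        """A 10 kb locus at 2 sites/kb averages 20 sites (3 s.e. band)."""
        from conftest import make_repeats
        ann = make_repeats([("chr1", 0, 10_000, "+", "IAPEz-int", "ERVK", "LTR")])
        cfg = small_config(ccgg_background_rate=0.0)
        n = 200
        counts = [len(place_ccgg_sites(ann, cfg, np.random.default_rng(s)))
                  for s in range(n)]
        se = np.sqrt(20 / n)
        assert abs(np.mean(counts) - 20) < 3 * se + 0.05  # duplicate-pos loss


class TestHelpTags:
    def make_sites(self, cfg, seed=0):
        ann, _ = generate_annotation(cfg, np.random.default_rng(seed))
        return ann, place_ccgg_sites(ann, cfg, np.random.default_rng(seed + 1))

    def test_fully_methylated_emits_no_hpaii(self):
        cfg = small_config(ccgg_background_rate=0.0)
        for cls in cfg.meth_prob:
            cfg.meth_prob[cls] = {"control": 1.0, "mutant": 1.0}
        ann, sites = self.make_sites(cfg)
        hpaii, mspi = simulate_help_tags(sites, cfg, "control")
        assert hpaii.total_count == 0
        assert mspi.total_count == cfg.library_depth["mspi"]

    def test_fully_unmethylated_equals_mspi_depth(self):
        cfg = small_config()
        for cls in cfg.meth_prob:
            cfg.meth_prob[cls] = {"control": 0.0, "mutant": 0.0}
        cfg.background_meth_prob = {"control": 0.0, "mutant": 0.0}
        ann, sites = self.make_sites(cfg)
        hpaii, mspi = simulate_help_tags(sites, cfg, "control")
        assert hpaii.total_count == mspi.total_count

    def test_missing_class_probability_is_config_error(self):
        cfg = small_config()
        ann, sites = self.make_sites(cfg)
        del cfg.meth_prob["LTR"]
        with pytest.raises(ConfigError, match="LTR"):
            simulate_help_tags(sites, cfg, "control")

    def test_planted_delta_tag_ratio(self):
        """LTR methylation 0.9 -> 0.4 multiplies the odds of an HpaII tag
        falling in the LTR class by exactly (1-0.4)/(1-0.9) = 6 (the
        non-LTR weights cancel between genotypes); 3 s.e. over 100 draws."""
        cfg = rc.ltr_delta_config()
        cfg.library_depth = {"hpaii": 20_000, "mspi": 20_000}
        ann, sites = self.make_sites(cfg)
        cls = ann.set_index("locus_id")["rep_class"]
        ratios = []
        for s in range(100):
            rng = np.random.default_rng(700 + s)
            hp_m, _ = simulate_help_tags(sites, cfg, "mutant", rng)
            hp_c, _ = simulate_help_tags(sites, cfg, "control", rng)

            def ltr_odds(ts):
                share = (ts.records["locus_id"].map(cls) == "LTR").mean()
                return share / (1 - share)

            ratios.append(ltr_odds(hp_m) / ltr_odds(hp_c))
        se = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
        assert abs(np.mean(ratios) - 6.0) < 3 * se + 0.1

    def test_mspi_counts_independent_of_genotype(self):
        """MspI per-class counts are a pure copy-number readout: a 2x2 test
        of class split between genotypes rejects at the nominal rate only."""
        from retrocount.methylation import fisher_exact_2x2
        cfg = rc.default_config()
        cfg.library_depth = {"hpaii": 5_000, "mspi": 5_000}
        ann, sites = self.make_sites(cfg)
        rejections = 0
        n_seeds = 40
        for s in range(n_seeds):
            rng = np.random.default_rng(900 + s)
            _, ms_m = simulate_help_tags(sites, cfg, "mutant", rng)
            _, ms_c = simulate_help_tags(sites, cfg, "control", rng)
            cls = ann.set_index("locus_id")["rep_class"]
            in_m = (ms_m.records["locus_id"].map(cls) == "LTR").sum()
            in_c = (ms_c.records["locus_id"].map(cls) == "LTR").sum()
            p = fisher_exact_2x2(int(in_m), ms_m.total_count - int(in_m),
                                 int(in_c), ms_c.total_count - int(in_c))
            rejections += p < 0.01
        assert rejections / n_seeds <= 0.1


class TestRnaReads:
    def test_zero_expression_empty(self):
        cfg = small_config(base_expression=0.0, gene_expression=0.0)
        ann, genes = generate_annotation(cfg)
        truth = build_truth(ann, cfg)
        reads = simulate_rna_reads(ann, truth, cfg, "control", genes=genes)
        assert reads.total_count == 0

    def test_planted_fold_change_ratio(self):
        """A +5 log2FC locus yields a mutant/control mean count ratio of
        about 32 (3 s.e. over 100 draws)."""
        cfg = small_config(gene_expression=0.0, readthrough_fraction=0.0)
        ann, _ = generate_annotation(cfg)
        truth = build_truth(ann, cfg)
        planted = [l for l, f in truth.locus_expr_log2fc.items() if f == 5.0]
        assert planted
        ratios = []
        for s in range(100):
            rng = np.random.default_rng(1100 + s)
            m = simulate_rna_reads(ann, truth, cfg, "mutant", rng)
            c = simulate_rna_reads(ann, truth, cfg, "control", rng)
            cm = m.records["locus_id"].value_counts()
            cc = c.records["locus_id"].value_counts()
            ratios.append(sum(cm.get(l, 0) for l in planted)
                          / max(1, sum(cc.get(l, 0) for l in planted)))
        se = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
        assert abs(np.mean(ratios) - 32.0) < 3 * se + 0.3

    def test_readthrough_reads_cover_upstream_window(self):
        cfg = small_config(readthrough_fraction=1.0)
        ann, _ = generate_annotation(cfg)
        truth = build_truth(ann, cfg)
        assert truth.readthrough_loci
        reads = simulate_rna_reads(ann, truth, cfg, "mutant",
                                   np.random.default_rng(3))
        by_id = ann.set_index("locus_id")
        for locus in truth.readthrough_loci:
            start = by_id.loc[locus, "start"]
            sub = reads.records[reads.records["locus_id"] == locus]
            assert (sub["start"] < start).any()  # reads upstream of the locus
            assert (sub["end"] > start).size  # and reads within it

    def test_reads_on_locus_strand(self):
        cfg = small_config(gene_expression=0.0, readthrough_fraction=0.0)
        ann, _ = generate_annotation(cfg)
        truth = build_truth(ann, cfg)
        reads = simulate_rna_reads(ann, truth, cfg, "control",
                                   np.random.default_rng(4))
        strands = ann.set_index("locus_id")["strand"]
        assert (reads.records["strand"]
                == reads.records["locus_id"].map(strands)).all()


class TestTruth:
    def test_round_trip_and_consistency(self, tmp_path):
        cfg = small_config()
        ann, _ = generate_annotation(cfg)
        truth = build_truth(ann, cfg)
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = SyntheticTruth.from_json(path)
        assert back.locus_expr_log2fc == truth.locus_expr_log2fc
        assert back.readthrough_loci == truth.readthrough_loci
        assert back.class_meth_delta == truth.class_meth_delta
        # every planted locus exists in the annotation
        ids = set(ann["locus_id"])
        assert set(truth.locus_expr_log2fc) <= ids
        assert truth.readthrough_loci <= ids
        # deltas equal the configured probabilities exactly
        for cls, (p0, p1) in truth.class_meth_delta.items():
            assert p0 == cfg.meth_prob[cls]["control"]
            assert p1 == cfg.meth_prob[cls]["mutant"]

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(readthrough_fraction=1.5).validate()
        with pytest.raises(ConfigError):
            SyntheticConfig(locus_length_range=(0, 10)).validate()
        cfg = SyntheticConfig()
        cfg.meth_prob["LTR"]["mutant"] = 1.2
        with pytest.raises(ConfigError):
            cfg.validate()
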