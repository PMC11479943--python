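"""Generator correctness: determinism, planted truth, conservation laws."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from xdamp import (
    DomainSpec,
    build_genome,
    fish_dispersion,
    get_preset,
    simulate_allelic_dataset,
    simulate_coverage,
    simulate_expression_matrix,
    simulate_fish_mask,
    simulate_variant_records,
)
from xdamp.dosage import cpm_normalize, x_to_autosome_ratio
from xdamp.genotyping import filter_heterozygous
from xdamp.synthetic import (
    AllelicPreset,
    GenomeSizingError,
    UnknownPresetError,
    write_pileup,
)


class TestBuildGenome:
    def test_counts_forced_by_arguments(self, genome150):
        assert len(genome150.genes) == 450
        assert len(genome150.snps) == 900
        x = genome150.x_genes
        assert (genome150.snps.groupby("gene_id").size() == 2).all()
        assert len(x) == 150

    def test_deterministic_for_fixed_seed(self):
        a = build_genome(20, 20, 1e7, 1e7, 2, seed=3)
        b = build_genome(20, 20, 1e7, 1e7, 2, seed=3)
        pd.testing.assert_frame_equal(a.genes, b.genes)
        pd.testing.assert_frame_equal(a.snps, b.snps)

    def test_infeasible_placement_raises(self):
        with pytest.raises(GenomeSizingError):
            build_genome(10, 10, 1e4, 1e4, 1, seed=1, gene_length=1000)

    def test_genes_do_not_overlap(self, genome150):
        for _, sub in genome150.genes.groupby("chrom"):
            sub = sub.sort_values("start")
            assert (sub["start"].to_numpy()[1:] >= sub["end"].to_numpy()[:-1]).all()


class TestVariantRecords:
    def test_all_hets_pass_downstream_filter(self, tiny_genome):
        rec = simulate_variant_records(tiny_genome, het_fraction=1.0, seed=2)
        kept = filter_heterozygous(rec)
        assert len(kept) == len(rec)

    def test_het_fraction_recovered_within_binomial_band(self, genome150):
        # 900 sites at het_fraction 0.8: central 99.9% binomial band is
        # [680, 758] passing sites (exact binomial oracle, frozen)
        rec = simulate_variant_records(genome150, het_fraction=0.8, seed=2)
        kept = filter_heterozygous(rec)
        assert 680 <= len(kept) <= 758
        assert (rec["truth"] == "het").sum() == len(kept)

    def test_decoys_each_violate_exactly_one_criterion(self, tiny_genome):
        rec = simulate_variant_records(tiny_genome, het_fraction=1.0, noise=0.5, seed=4)
        decoys = rec[rec["truth"].str.startswith("decoy")]
        assert len(decoys) == 20
        minor = np.minimum(decoys["ad_ref"], decoys["ad_alt"]) / (
            decoys["ad_ref"] + decoys["ad_alt"]
        )
        fails = (
            (decoys["qual"] < 50).astype(int)
            + (decoys["depth"] < 10).astype(int)
            + (minor < 0.25).astype(int)
        )
        assert (fails == 1).all()
        kept_decoys = filter_heterozygous(decoys.reset_index(drop=True))
        assert kept_decoys.empty


class TestAllelicDataset:
    def test_counts_conserve_depth(self, tiny_genome):
        ds = simulate_allelic_dataset(tiny_genome, "naive_pxgl_wt_v1", seed=5)
        c = ds.counts
        assert ((c["ref_count"] + c["alt_count"]) == c["depth"]).all()
        assert ((c["pxi_count"] >= 0) & (c["pxi_count"] <= c["depth"])).all()

    def test_pileup_files_byte_identical_for_fixed_seed(self, tiny_genome, tmp_path):
        for i in (1, 2):
            ds = simulate_allelic_dataset(tiny_genome, "primed_v1", seed=6)
            write_pileup(ds, tiny_genome, "primed_rep1", tmp_path / f"p{i}.pileup")
        assert (tmp_path / "p1.pileup").read_bytes() == (tmp_path / "p2.pileup").read_bytes()

    def test_pure_xa_preset_emits_no_pxi_bases(self, tiny_genome):
        preset = dataclasses.replace(
            get_preset("primed_v1"),
            name="all_xa",
            classes=(("silenced", 1.0),),
            conditions={"primed": {"silenced": 0.0}},
        )
        ds = simulate_allelic_dataset(tiny_genome, preset, seed=7)
        x = ds.counts[ds.counts["chrom"] == "chrX"]
        assert (x["pxi_count"] == 0).all()

    def test_unknown_preset_error_lists_catalog(self, tiny_genome):
        with pytest.raises(UnknownPresetError, match="primed_v1"):
            simulate_allelic_dataset(tiny_genome, "nope_v9", seed=1)

    def test_deep_depth_gene_ratios_converge_to_preset_p(self, genome150):
        # at depth 1e4 per SNP, >= 99% of genes sit within 3 binomial SEs
        # of their true p, and none strays beyond 0.02 of p = 0.5
        preset = dataclasses.replace(
            get_preset("naive_ko_v1"), name="deep", depth_mean=1e4, n_replicates=1
        )
        ds = simulate_allelic_dataset(genome150, preset, seed=8)
        c = ds.counts[ds.counts["chrom"] == "chrX"]
        g = c.groupby("gene_id")[["pxi_count", "depth"]].sum()
        frac = g["pxi_count"] / g["depth"]
        se = np.sqrt(0.25 / g["depth"])
        assert (np.abs(frac - 0.5) < 3 * se).mean() >= 0.99
        assert np.abs(frac - 0.5).max() < 0.02


class TestExpressionMatrix:
    @staticmethod
    def _xa(genome, p, seed=9):
        preset = dataclasses.replace(
            get_preset("naive_ko_v1"),
            name="flat",
            classes=(("sensitive", 1.0),),
            conditions={"cond": {"sensitive": p}},
        )
        tab = simulate_expression_matrix(genome, preset, seed=seed)
        cpm = cpm_normalize(tab)
        return float(x_to_autosome_ratio(cpm, genome.gene_chromosomes()).mean())

    def test_dose_model_closed_forms(self):
        """X:A follows (1 + d)/2 with d = p/(1-p).

        On a single genome the finite gene sample contributes a common
        multiplicative factor to every condition's X:A (the X and
        autosomal median genes are different random draws), so the closed
        form is asserted tightly on paired condition ratios — where that
        factor cancels, exactly as in the KO/WT fold statistic — and
        loosely on the absolute value.
        """
        genome = build_genome(400, 800, 1.5e8, 1.5e8, 2, seed=9)
        xa_half = self._xa(genome, 0.5)  # d = 1: dose equals diploid autosomes
        assert xa_half == pytest.approx(1.0, abs=0.15)
        assert self._xa(genome, 0.0) / xa_half == pytest.approx(0.5, abs=0.02)
        assert self._xa(genome, 0.31) / xa_half == pytest.approx(
            0.7246376811594203, abs=0.02  # (1 + 0.31/0.69) / 2
        )


class TestCoverage:
    def test_truth_union_consistent_with_track(self, tiny_genome):
        target, control, truth = simulate_coverage(
            tiny_genome, DomainSpec(n_domains=5, length_mean=5e4, chromosome="chrX"), seed=10
        )
        assert truth["union_length"] == sum(e - s for s, e in truth["intervals"])
        # domain intervals carry fold >= 2 x control; background is 1 x control
        dom = target.merge(
            pd.DataFrame(truth["intervals"], columns=["start", "end"]), on=["start", "end"]
        )
        assert (dom["value"] >= 2.0).all()

    def test_zero_domains_gives_flat_background(self, tiny_genome):
        target, control, truth = simulate_coverage(
            tiny_genome, DomainSpec(n_domains=0, chromosome="chrX"), seed=11
        )
        assert truth["union_length"] == 0
        assert (target["value"] == control["value"].iloc[0]).all()


class TestFishMasks:
    def test_compact_ball_is_one_component(self):
        mask = simulate_fish_mask("compact", {"radius": 8}, seed=12)
        assert mask.n_signal() > 1000

    def test_dispersed_speckles_score_far_above_compact(self):
        compact = simulate_fish_mask("compact", {"radius": 10}, seed=13)
        dispersed = simulate_fish_mask(
            "dispersed", {"n_speckles": 8, "bounding_radius": 20}, seed=13
        )
        assert fish_dispersion(dispersed) > 10 * fish_dispersion(compact)

    def test_empty_mask_is_degenerate_downstream(self):
        mask = simulate_fish_mask("dispersed", {"n_speckles": 0}, seed=14)
        with pytest.raises(ValueError, match="empty"):
            fish_dispersion(mask)

    def test_unknown_kind_raises(self):
        with pytest.raises(ValueError, match="kind"):
            simulate_fish_mask("blob", {}, seed=1)


def test_preset_class_counts_are_exact():
    assert get_preset("classification_v1").class_counts() == {"sensitive": 47, "resistant": 13}
    assert get_preset("spen_kd_v1").class_counts() == {
        "sens_both": 20,
        "sens_one": 12,
        "sens_none": 9,
        "resistant": 13,
    }
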