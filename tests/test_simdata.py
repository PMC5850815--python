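"""Generator ground truth: planted rates, conservation, determinism."""

import numpy as np
import pandas as pd
import pytest

from zwscan.simdata import (SimConfig, SimConfigError, simulate_dna_profiles,
                            simulate_expression, simulate_genome)

from conftest import rna_config, small_config


def _het_rate(truth, individual, scaffolds):
    het = total = 0
    for scaf in scaffolds:
        haps = truth.haplotypes[individual][scaf]
        het += int((haps[0] != haps[1]).sum())
        total += haps.shape[1]
    return het / total


class TestSimulateGenome:
    def test_scaffolds_tile_without_overlap(self, small_truth):
        for chrom, grp in small_truth.scaffold_table.groupby("chromosome"):
            grp = grp.sort_values("start")
            assert grp["start"].iloc[0] == 0
            assert (grp["end"].iloc[:-1].to_numpy()
                    == grp["start"].iloc[1:].to_numpy()).all()

    def test_planted_heterozygosity_rates(self):
        # theta 0.01, d_zw 0.01: female SD het/site ~ 0.01 + 0.01*0.99,
        # male SD ~ 0.0075, counted directly on the emitted haplotypes
        cfg = small_config(n_chromosomes=2, scaffolds_per_chromosome=10,
                           scaffold_length=5000, sd_chromosome="chr2",
                           sd_interval=(0, 50000), seed=3)
        truth = simulate_genome(cfg)
        sd = sorted(truth.sd_scaffolds)
        n_sites = len(sd) * cfg.scaffold_length
        for ind, expected in [("F1", 0.01 + 0.01 * 0.99), ("M1", 0.0075)]:
            rate = _het_rate(truth, ind, sd)
            se = np.sqrt(expected * (1 - expected) / n_sites)
            assert abs(rate - expected) < 3 * se

    def test_no_divergence_leaves_only_diversity_factor(self):
        cfg = small_config(d_zw=0.0, seed=5, scaffold_length=5000,
                           scaffolds_per_chromosome=10,
                           sd_interval=(0, 50000))
        truth = simulate_genome(cfg)
        sd = sorted(truth.sd_scaffolds)
        f = np.mean([_het_rate(truth, i, sd) for i in ("F1", "F2")])
        m = np.mean([_het_rate(truth, i, sd) for i in ("M1", "M2")])
        # ratio M/F ~ z_diversity_factor
        assert f == pytest.approx(cfg.theta_auto, rel=0.25)
        assert m / f == pytest.approx(cfg.z_diversity_factor, rel=0.3)

    def test_same_seed_is_bit_identical(self):
        a = simulate_genome(small_config())
        b = simulate_genome(small_config())
        assert all((a.reference[s] == b.reference[s]).all() for s in a.reference)
        for ind in a.haplotypes:
            for scaf in a.haplotypes[ind]:
                assert (a.haplotypes[ind][scaf]
                        == b.haplotypes[ind][scaf]).all()
        pd.testing.assert_frame_equal(a.hits, b.hits)
        pd.testing.assert_frame_equal(a.genes, b.genes)

    def test_w_scaffolds_only_in_females(self, small_truth):
        for w in small_truth.w_scaffolds:
            assert w in small_truth.haplotypes["F1"]
            assert w not in small_truth.haplotypes["M1"]

    def test_impossible_tiling_rejected(self):
        with pytest.raises(SimConfigError):
            small_config(genes_per_scaffold=100, gene_length=300).validate()
        with pytest.raises(SimConfigError):
            small_config(sd_interval=(0, 10**9)).validate()
        with pytest.raises(SimConfigError):
            small_config(theta_auto=1.5).validate()

    def test_config_file_round_trip(self, tmp_path):
        cfg = small_config(seed=99)
        cfg.to_file(tmp_path / "cfg.yaml")
        assert SimConfig.from_file(tmp_path / "cfg.yaml") == cfg


class TestDnaProfiles:
    def test_counts_confined_to_haplotype_alleles_without_error(self):
        cfg = small_config(error_rate=0.0, n_chromosomes=1,
                           scaffolds_per_chromosome=2, sd_chromosome="chr1",
                           sd_interval=(0, 2000), n_w_scaffolds=0)
        truth = simulate_genome(cfg)
        mats = simulate_dna_profiles(truth, cfg)
        for ind in ("F1", "M1"):
            for scaf, counts in mats[ind].counts.items():
                haps = truth.haplotypes[ind][scaf]
                allowed = np.zeros_like(counts, dtype=bool)
                L = counts.shape[0]
                allowed[np.arange(L), haps[0]] = True
                allowed[np.arange(L), haps[1]] = True
                assert counts[~allowed].sum() == 0
                # homozygous sites have a single nonzero base
                hom = haps[0] == haps[1]
                assert ((counts[hom] > 0).sum(axis=1) <= 1).all()

    def test_heterozygous_minor_fraction_approaches_half(self):
        cfg = small_config(depth_mean=2000.0, error_rate=0.0, n_chromosomes=1,
                           scaffolds_per_chromosome=1, sd_chromosome="chr1",
                           sd_interval=(0, 1000), scaffold_length=2000,
                           n_w_scaffolds=0, theta_auto=0.05)
        truth = simulate_genome(cfg)
        mats = simulate_dna_profiles(truth, cfg)
        haps = truth.haplotypes["F1"]["chr1_s1"]
        counts = mats["F1"].counts["chr1_s1"]
        het = np.flatnonzero(haps[0] != haps[1])
        # share of reads carrying the second haplotype's allele: Binomial(d, 1/2)
        fracs = [counts[i, haps[1][i]] / counts[i].sum() for i in het]
        mean = np.mean(fracs)
        se = np.sqrt(0.25 / (2000 * len(het)))
        assert abs(mean - 0.5) < 3 * se

    def test_base_counts_sum_to_depth_conservation(self, small_truth,
                                                   small_profiles):
        # with miscalls on, per-site totals are still the drawn Poisson depth:
        # mean ~ depth_mean, and no counts appear where no haplotype exists
        cov = small_profiles["F1"].coverage("chr1_s1")
        assert cov.mean() == pytest.approx(small_truth.config.depth_mean,
                                           rel=0.05)

    def test_w_scaffold_coverage_by_sex(self, small_truth, small_profiles):
        w = small_truth.w_scaffolds[0]
        assert small_profiles["M1"].coverage(w).sum() == 0
        fcov = small_profiles["F1"].coverage(w).mean()
        # hemizygous: one haplotype's worth of depth
        assert fcov == pytest.approx(small_truth.config.depth_mean / 2,
                                     rel=0.1)


class TestExpression:
    def test_null_configuration_is_unbiased(self):
        cfg = rna_config(seed=4, frac_masculinized=0.0, bias_fold=1.0)
        truth = simulate_genome(cfg)
        fpkm, rna = simulate_expression(truth, cfg)
        f = fpkm["catkin"].filter(regex="^F").mean(axis=1)
        m = fpkm["catkin"].filter(regex="^M").mean(axis=1)
        assert np.log2(f / m).mean() == pytest.approx(0.0, abs=0.05)

    def test_planted_fourfold_male_bias(self):
        cfg = rna_config(seed=8)
        truth = simulate_genome(cfg)
        fpkm, _ = simulate_expression(truth, cfg)
        planted = truth.biased_genes["gene"]
        f = fpkm["catkin"].loc[planted].filter(regex="^F").mean(axis=1)
        m = fpkm["catkin"].loc[planted].filter(regex="^M").mean(axis=1)
        assert np.log2(f / m).mean() == pytest.approx(-2.0, abs=0.15)
        # leaves untouched
        fl = fpkm["leaf"].loc[planted].filter(regex="^F").mean(axis=1)
        ml = fpkm["leaf"].loc[planted].filter(regex="^M").mean(axis=1)
        assert np.log2(fl / ml).mean() == pytest.approx(0.0, abs=0.15)

    def test_silenced_w_gives_monoallelic_female_rna(self):
        cfg = rna_config(seed=9, w_expression_ratio=0.0)
        truth = simulate_genome(cfg)
        _, rna = simulate_expression(truth, cfg)
        sd_scafs = truth.sd_scaffolds
        for ind in ("F1", "F2", "F3"):
            sub = rna[(rna["individual"] == ind)
                      & (rna["scaffold"].isin(sd_scafs))]
            for row in sub.itertuples(index=False):
                div = truth.div_sites.get((ind, row.scaffold))
                if div is None or (row.pos - 1) not in div:
                    continue
                counts = np.array([row.A, row.C, row.G, row.T])
                assert (counts > 0).sum() == 1

    def test_rna_depth_tracks_fpkm(self, small_truth, small_expression):
        fpkm, rna = small_expression
        cfg = small_truth.config
        row = rna.iloc[0]
        expected = round(fpkm[row["tissue"]].at[
            _gene_at(small_truth, row["scaffold"], row["pos"]),
            row["individual"]] * cfg.rna_depth_scale)
        assert row[["A", "C", "G", "T"]].sum() == expected


def _gene_at(truth, scaffold, pos1):
    g = truth.genes
    hit = g[(g["scaffold"] == scaffold) & (g["cds_start"] < pos1)
            & (g["cds_end"] >= pos1)]
    return hit["gene"].iloc[0]
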