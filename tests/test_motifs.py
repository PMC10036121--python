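"""Shuffles, overlap enrichment, and TSS-relative motif density."""

import numpy as np
import pytest
from scipy import stats

from nutrichrom import (
    GenomeModel,
    IntervalSet,
    SimConfig,
    ValidationError,
    make_genes,
    make_genome,
    merge_motif_hits,
    overlap_enrichment,
    pick_target_genes,
    plant_motifs,
    shuffle_intervals,
    summarize_window,
    tss_density_profile,
)
from nutrichrom.simulate import stage_rng
from tests.conftest import ivset


class TestMergeMotifHits:
    def test_q_filter_and_union(self):
        v1 = IntervalSet.from_arrays(["c", "c"], [10, 100], [20, 110], score=[0.05, 0.2])
        v2 = IntervalSet.from_arrays(["c", "c"], [10, 300], [20, 310], score=[0.01, 0.08])
        merged = merge_motif_hits([v1, v2], q_threshold=0.1)
        spans = [(iv.start, iv.end) for iv in merged]
        assert spans == [(10, 20), (300, 310)]  # q=0.2 hit excluded, duplicates unioned

    def test_missing_q_rejected_when_filtering(self):
        with pytest.raises(ValidationError):
            merge_motif_hits([ivset(("c", 0, 10))], q_threshold=0.1)

    def test_no_filter_pools_everything(self):
        merged = merge_motif_hits([ivset(("c", 0, 10)), ivset(("c", 5, 15))], q_threshold=None)
        assert [(iv.start, iv.end) for iv in merged] == [(0, 15)]


class TestShuffleIntervals:
    def test_lengths_and_per_chromosome_counts_preserved(self, bare_genome):
        ivs = IntervalSet.from_arrays(
            ["chr1", "chr1", "chr2"], [0, 100, 0], [25, 140, 10]
        )
        out = shuffle_intervals(ivs, bare_genome, seed=3)
        assert sorted(out.df["end"] - out.df["start"]) == [10, 25, 40]
        assert dict(out.df["chrom"].value_counts()) == {"chr1": 2, "chr2": 1}
        out.validate(bare_genome)

    def test_non_overlap_enforced(self, bare_genome):
        ivs = IntervalSet.from_arrays(["chr2"] * 20, [0] * 20, [20] * 20)
        out = shuffle_intervals(ivs, bare_genome, seed=4).normalize()
        starts, ends = out.arrays("chr2")
        assert (starts[1:] >= ends[:-1]).all()

    def test_infeasible_placement_errors(self):
        g = GenomeModel({"c": 50}, {})
        ivs = IntervalSet.from_arrays(["c"] * 3, [0] * 3, [20] * 3)
        with pytest.raises(ValidationError):
            shuffle_intervals(ivs, g, seed=1)

    def test_single_interval_start_uniform(self):
        g = GenomeModel({"c": 1000}, {})
        ivs = ivset(("c", 0, 10))
        rng = stage_rng(0, "uniformity")
        starts = [
            int(shuffle_intervals(ivs, g, rng=rng).df["start"].iloc[0]) for _ in range(2000)
        ]
        assert min(starts) >= 0 and max(starts) <= 990
        counts, _ = np.histogram(starts, bins=10, range=(0, 991))
        p = stats.chisquare(counts).pvalue
        assert p > 0.01

    def test_determinism_given_seed(self, bare_genome):
        ivs = IntervalSet.from_arrays(["chr1"] * 5, [0] * 5, [30] * 5)
        a = shuffle_intervals(ivs, bare_genome, seed=9)
        b = shuffle_intervals(ivs, bare_genome, seed=9)
        assert a == b


class TestOverlapEnrichment:
    def test_maximal_observed_hits_addone_floor(self):
        g = GenomeModel({"chr1": 100_000}, {})
        rng = np.random.default_rng(1)
        starts = np.sort(rng.choice(100_000 - 10, size=30, replace=False))
        hits = IntervalSet.from_arrays(["chr1"] * 30, starts, starts + 10)
        res = overlap_enrichment(hits, hits, g, n_resamples=100, seed=3)
        assert res.observed_overlap == 30
        assert res.permuted_overlaps.max() < 30
        assert np.isclose(res.p_emp, 1 / 101)
        assert round(res.p_emp, 4) == 0.0099

    def test_anticorrelated_features_give_negative_l2fc(self):
        g = GenomeModel({"chr1": 10_000}, {})
        hits = ivset(("chr1", 0, 5000))
        feats = IntervalSet.from_arrays(["chr1"] * 20, range(6000, 10000, 200),
                                        range(6050, 10050, 200))
        res = overlap_enrichment(feats, hits, g, n_resamples=50, seed=2)
        assert res.observed_overlap == 0
        assert res.l2fc < 0

    def test_zero_features_rejected(self, bare_genome):
        with pytest.raises(ValidationError):
            overlap_enrichment(IntervalSet(), ivset(("chr1", 0, 10)), bare_genome)

    def test_shuffle_motifs_mode_runs(self, bare_genome):
        feats = ivset(("chr1", 100, 200), ("chr2", 100, 200))
        hits = ivset(("chr1", 150, 160), ("chr2", 400, 410))
        res = overlap_enrichment(feats, hits, bare_genome, n_resamples=20,
                                 mode="shuffle_motifs", seed=5)
        assert res.mode == "shuffle_motifs"
        assert res.observed_overlap == 1
        assert 0 < res.p_emp <= 1


class TestTssDensityProfile:
    def _genome_genes_hits(self, seed, enrichment, rate=1 / 1000, n_genes=400):
        cfg = SimConfig(
            seed=seed, n_chroms=2, chrom_length=2_000_000, n_genes=n_genes,
            motif_tss_enrichment=enrichment, motif_background_rate=rate,
        )
        g = make_genome(cfg)
        genes = make_genes(g, cfg)
        targets = pick_target_genes(genes, 100, seed) if enrichment != 1 else set()
        hits, _ = plant_motifs(g, genes, targets, cfg)
        return cfg, g, genes, targets, hits

    def test_uniform_hits_average_to_one(self):
        _, g, genes, _, hits = self._genome_genes_hits(31, 1.0)
        prof = tss_density_profile(genes, hits, g)
        assert abs(float(np.nanmean(prof.normalized_density)) - 1.0) < 0.05

    def test_no_hits_give_zero_profile(self, bare_genome):
        genes = make_genes(make_genome(SimConfig(seed=1, n_chroms=2, chrom_length=100_000, n_genes=20)),
                           SimConfig(seed=1, n_chroms=2, chrom_length=100_000, n_genes=20))
        g = GenomeModel({"chr1": 100_000, "chr2": 100_000}, {})
        prof = tss_density_profile(genes, IntervalSet(), g, flank=1000, binsize=100)
        assert (prof.observed_bp == 0).all()

    def test_planted_upstream_enrichment_recovered(self):
        cfg, g, genes, targets, hits = self._genome_genes_hits(32, 10.0)
        subset = [x for x in genes if x.gene_id in targets]
        prof = tss_density_profile(subset, hits, g)
        up = summarize_window(prof, (-500, 0))
        distal = summarize_window(prof, (-2500, -1000))
        assert up > 5 * distal
        assert 6 < up < 12

    def test_observed_bp_conservation(self):
        _, g, genes, _, hits = self._genome_genes_hits(33, 1.0, n_genes=50)
        prof = tss_density_profile(genes, hits, g, flank=1000, binsize=100)
        # brute-force total covered bp over all gene windows
        from nutrichrom.peaks import merge_intervals

        union = merge_intervals(hits, 0)
        total = 0
        for gene in genes:
            L = g.chromosomes[gene.chrom]
            if gene.strand == "+":
                lo, hi = gene.tss - 1000, gene.tss + 1000
            else:
                lo, hi = gene.tss - 1000 + 1, gene.tss + 1000 + 1
            lo, hi = max(0, lo), min(L, hi)
            starts, ends = union.arrays(gene.chrom)
            total += int(np.maximum(0, np.minimum(ends, hi) - np.maximum(starts, lo)).sum())
        assert int(prof.observed_bp.sum()) == total

    def test_flank_binsize_mismatch_rejected(self, bare_genome):
        from nutrichrom import GeneModel

        with pytest.raises(ValidationError):
            tss_density_profile(
                [GeneModel("g", "chr1", 10, 20, "+")], IntervalSet(), bare_genome,
                flank=250, binsize=100,
            )

    def test_summarize_window_totality_and_bounds(self):
        _, g, genes, _, hits = self._genome_genes_hits(34, 1.0, n_genes=100)
        prof = tss_density_profile(genes, hits, g)
        full = summarize_window(prof, (-2500, 2500))
        assert np.isclose(full, float(np.nanmean(prof.normalized_density)))
        with pytest.raises(ValidationError):
            summarize_window(prof, (-3000, 0))

    def test_subset_profile_consistent_with_full_gene_set(self):
        # a uniform random gene subset estimates the same profile in expectation
        _, g, genes, _, hits = self._genome_genes_hits(35, 1.0, rate=1 / 500)
        full = tss_density_profile(genes, hits, g)
        rng = np.random.default_rng(35)
        sub = [genes[i] for i in rng.choice(len(genes), 150, replace=False)]
        part = tss_density_profile(sub, hits, g)
        assert abs(np.nanmean(part.normalized_density) - np.nanmean(full.normalized_density)) < 0.1

    def test_strand_mirroring_puts_upstream_enrichment_at_negative_offsets(self):
        # single minus-strand gene with hits genomically downstream of its TSS
        g = GenomeModel({"c": 20_000}, {})
        from nutrichrom import GeneModel

        gene = GeneModel("g", "c", 5_000, 10_000, "-")  # TSS at 9_999, upstream = larger coords
        hits = IntervalSet.from_arrays(["c"] * 10, range(10_100, 11_100, 100),
                                       range(10_110, 11_110, 100))
        prof = tss_density_profile([gene], hits, g, flank=1500, binsize=100)
        upstream = prof.normalized_density[prof.offsets < 0]
        downstream = prof.normalized_density[prof.offsets > 0]
        assert np.nansum(upstream) > 0 and np.nansum(downstream) == 0
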