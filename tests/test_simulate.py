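"""Generator determinism, distributional checks, and ground-truth bookkeeping."""

import numpy as np
import pytest

from nutrichrom import (
    SimConfig,
    ValidationError,
    make_domains,
    make_genes,
    make_genome,
    make_planted_peaks,
    pick_target_genes,
    plant_motifs,
    simulate_damid_counts,
    simulate_de_table,
)


class TestMakeGenome:
    def test_same_seed_identical_sites(self):
        cfg = SimConfig(seed=11, n_chroms=2, chrom_length=100_000)
        a, b = make_genome(cfg), make_genome(cfg)
        assert a == b

    def test_site_count_near_poisson_expectation(self):
        cfg = SimConfig(seed=5, n_chroms=1, chrom_length=1_000_000, gatc_rate=1 / 256)
        g = make_genome(cfg)
        n = g.gatc_sites["chr1"].size
        expect = 1_000_000 / 256
        assert abs(n - expect) < 3 * np.sqrt(expect)

    def test_minimum_spacing_enforced_at_high_rate(self):
        cfg = SimConfig(seed=1, n_chroms=1, chrom_length=10_000, gatc_rate=0.5)
        g = make_genome(cfg)
        assert np.diff(g.gatc_sites["chr1"]).min() >= 4

    def test_too_short_chromosome_errors(self):
        with pytest.raises(ValidationError):
            make_genome(SimConfig(seed=1, n_chroms=1, chrom_length=6))


class TestMakeGenes:
    def test_genes_pairwise_disjoint_and_deterministic(self):
        cfg = SimConfig(seed=2, n_chroms=2, chrom_length=300_000, n_genes=120)
        g = make_genome(cfg)
        genes = make_genes(g, cfg)
        assert genes == make_genes(g, cfg)
        by_chrom: dict = {}
        for gene in genes:
            by_chrom.setdefault(gene.chrom, []).append((gene.start, gene.end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_strand_fraction_near_half(self):
        cfg = SimConfig(seed=3, n_chroms=3, chrom_length=1_000_000, n_genes=300)
        genes = make_genes(make_genome(cfg), cfg)
        frac = np.mean([g.strand == "+" for g in genes])
        assert abs(frac - 0.5) < 3 * 0.5 / np.sqrt(len(genes))


class TestMakeDomains:
    def test_domains_tile_genome_exactly(self):
        cfg = SimConfig(seed=4, n_chroms=2, chrom_length=200_000)
        g = make_genome(cfg)
        dom = make_domains(g, mean_len=10_000, seed=4)
        for c, length in g.chromosomes.items():
            starts, ends = dom.normalize().arrays(c)
            assert starts[0] == 0 and ends[-1] == length
            assert (starts[1:] == ends[:-1]).all()

    def test_block_lengths_and_color_marginals(self):
        cfg = SimConfig(seed=5, n_chroms=4, chrom_length=500_000)
        g = make_genome(cfg)
        mean_len = 5_000
        dom = make_domains(g, mean_len=mean_len, seed=5)
        # drop chromosome-final truncated blocks from the length check
        lens = []
        for c, length in g.chromosomes.items():
            starts, ends = dom.normalize().arrays(c)
            lens.extend((ends - starts)[ends < length])
        lens = np.asarray(lens, dtype=float)
        assert abs(lens.mean() - mean_len) < 3 * mean_len / np.sqrt(lens.size)
        counts = dom.df["label"].value_counts(normalize=True)
        assert counts.size == 5
        assert counts.max() < 0.2 + 3 * np.sqrt(0.2 * 0.8 / len(dom.df))

    def test_consecutive_blocks_differ_in_color(self):
        cfg = SimConfig(seed=6, n_chroms=1, chrom_length=300_000)
        dom = make_domains(make_genome(cfg), mean_len=5_000, seed=6).normalize()
        labels = list(dom.df["label"])
        assert all(a != b for a, b in zip(labels, labels[1:]))


class TestDamidCounts:
    def test_counts_are_nonnegative_integers_and_deterministic(self):
        cfg = SimConfig(seed=7, n_chroms=1, chrom_length=200_000, sequencing_depth=20_000)
        g = make_genome(cfg)
        planted = make_planted_peaks(g, cfg)
        fusion, dam, truth = simulate_damid_counts(g, planted, cfg)
        fusion2, _, _ = simulate_damid_counts(g, planted, cfg)
        assert len(fusion) == len(dam) == cfg.n_replicates
        for t in fusion + dam:
            assert (t.values >= 0).all() and (t.values == np.floor(t.values)).all()
        assert np.array_equal(fusion[0].values, fusion2[0].values)
        assert truth.planted_peaks is not None and len(truth.planted_peaks) == len(planted)

    def test_fusion_dam_ratio_matches_enrichment_inside_peaks(self):
        cfg = SimConfig(
            seed=8, n_chroms=1, chrom_length=1_000_000,
            sequencing_depth=200_000, peak_enrichment=4.0, n_peaks=13,
        )
        g = make_genome(cfg)
        planted = make_planted_peaks(g, cfg)
        fusion, dam, _ = simulate_damid_counts(g, planted, cfg)
        from nutrichrom.simulate import _fragment_in_planted

        inside = _fragment_in_planted(g, planted)
        ratio = fusion[0].values[inside].sum() / dam[0].values[inside].sum()
        assert abs(ratio - 4.0) < 0.4

    def test_null_enrichment_makes_tracks_exchangeable(self):
        # with peak_enrichment=1 fusion and dam are draws from one distribution
        from scipy import stats

        rejections = 0
        for seed in range(20):
            cfg = SimConfig(
                seed=seed, n_chroms=1, chrom_length=100_000,
                sequencing_depth=20_000, peak_enrichment=1.0, n_peaks=5,
            )
            g = make_genome(cfg)
            planted = make_planted_peaks(g, cfg)
            fusion, dam, _ = simulate_damid_counts(g, planted, cfg)
            p = stats.ks_2samp(fusion[0].values, dam[0].values).pvalue
            rejections += p < 0.01
        assert rejections <= 2

    def test_zero_depth_errors(self):
        with pytest.raises(ValidationError):
            SimConfig(seed=1, sequencing_depth=0)


class TestPlantMotifs:
    def _setup(self, seed, enrichment):
        cfg = SimConfig(
            seed=seed, n_chroms=2, chrom_length=1_000_000, n_genes=300,
            motif_tss_enrichment=enrichment, motif_background_rate=1 / 1000,
        )
        g = make_genome(cfg)
        genes = make_genes(g, cfg)
        targets = pick_target_genes(genes, 80, seed)
        hits, truth = plant_motifs(g, genes, targets, cfg)
        return cfg, g, genes, targets, hits, truth

    @staticmethod
    def _window_hit_count(genes, gene_ids, hits, window):
        count = 0
        df = hits.df
        for g in genes:
            if g.gene_id not in gene_ids:
                continue
            if g.strand == "+":
                lo, hi = g.tss - window, g.tss
            else:
                lo, hi = g.tss + 1, g.tss + 1 + window
            sel = (df["chrom"] == g.chrom) & (df["start"] >= lo) & (df["start"] < hi)
            count += int(sel.sum())
        return count

    def test_same_seed_identical_hits(self):
        _, _, _, _, a, _ = self._setup(9, 10.0)
        _, _, _, _, b, _ = self._setup(9, 10.0)
        assert a == b

    def test_target_windows_carry_planted_fold(self):
        cfg, g, genes, targets, hits, truth = self._setup(10, 10.0)
        assert truth.target_genes == targets
        others = {x.gene_id for x in genes} - targets
        n_t = self._window_hit_count(genes, targets, hits, cfg.tss_window)
        n_o = self._window_hit_count(genes, others, hits, cfg.tss_window)
        rate_t = n_t / (len(targets) * cfg.tss_window)
        rate_o = n_o / (len(others) * cfg.tss_window)
        assert 6 < rate_t / rate_o < 15

    def test_unit_enrichment_matches_background(self):
        cfg, g, genes, targets, hits, _ = self._setup(11, 1.0)
        n_t = self._window_hit_count(genes, targets, hits, cfg.tss_window)
        rate_t = n_t / (len(targets) * cfg.tss_window)
        expect = cfg.motif_background_rate
        assert abs(rate_t - expect) < 4 * np.sqrt(expect / (len(targets) * cfg.tss_window))

    def test_unknown_target_gene_rejected(self):
        cfg, g, genes, *_ = self._setup(12, 1.0)
        with pytest.raises(ValidationError):
            plant_motifs(g, genes, {"nonexistent"}, cfg)


class TestSimulateDeTable:
    def test_truth_labels_partition_de_genes(self):
        cfg = SimConfig(seed=13)
        baseline, treatment, truth = simulate_de_table(cfg)
        t = truth.de_truth
        de = t[t["label"] != "unchanged"]
        assert len(de) == cfg.n_de
        counts = de["label"].value_counts()
        assert counts.get("reverted", 0) == round(cfg.frac_reverted * cfg.n_de)
        assert counts.get("restored", 0) == round(cfg.frac_restored * cfg.n_de)
        assert set(baseline["gene_id"]) == set(t["gene_id"])

    def test_restored_genes_center_on_zero_under_treatment(self):
        cfg = SimConfig(seed=14)
        _, treatment, truth = simulate_de_table(cfg)
        t = truth.de_truth.set_index("gene_id")
        obs = treatment.set_index("gene_id").loc[t.index[t["label"] == "restored"]]
        m = obs["log2FoldChange"].mean()
        assert abs(m) < 3 * obs["log2FoldChange"].std() / np.sqrt(len(obs))

    def test_noise_free_limit_recovers_truth(self):
        cfg = SimConfig(seed=15, se_min=1e-9, se_max=1e-8)
        baseline, _, truth = simulate_de_table(cfg)
        assert np.allclose(
            baseline["log2FoldChange"], truth.de_truth["true_l2fc_baseline"], atol=1e-6
        )

    def test_reverted_flips_and_still_changed_keeps_sign(self):
        cfg = SimConfig(seed=16)
        _, _, truth = simulate_de_table(cfg)
        t = truth.de_truth
        rev = t[t["label"] == "reverted"]
        assert (rev["true_l2fc_treatment"] == -rev["true_l2fc_baseline"]).all()
        still = t[t["label"] == "still_changed"]
        assert (still["true_l2fc_treatment"] == still["true_l2fc_baseline"]).all()
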