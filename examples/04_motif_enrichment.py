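"""Permutation motif-overlap enrichment and the TSS-relative density profile.

Motif hits are planted tenfold-enriched in the 500 bp upstream of target-gene
TSSs.  The overlap test shuffles intervals (lengths preserved, chromosome
preserved, non-overlapping) and reports an add-one empirical p; the TSS
profile normalizes hit density by the genome-wide expectation, so 1.0 means
genome-average.
"""

import numpy as np

from nutrichrom import (
    IntervalSet, SimConfig, make_genes, make_genome, overlap_enrichment,
    pick_target_genes, plant_motifs, summarize_window, tss_density_profile,
)

cfg = SimConfig(seed=9, n_chroms=2, chrom_length=2_000_000, n_genes=400,
                motif_background_rate=1 / 1000, motif_tss_enrichment=10.0)
genome = make_genome(cfg)
genes = make_genes(genome, cfg)
targets = pick_target_genes(genes, 80, seed=9)
hits, _ = plant_motifs(genome, genes, targets, cfg)

# regulatory windows of the target genes vs the motif hits
windows = []
for g in genes:
    if g.gene_id not in targets:
        continue
    lo, hi = (g.tss - 500, g.tss) if g.strand == "+" else (g.tss + 1, g.tss + 501)
    windows.append(("" + g.chrom, max(0, lo), min(genome.chromosomes[g.chrom], hi)))
features = IntervalSet.from_arrays(*zip(*windows))

enr = overlap_enrichment(features, hits, genome, n_resamples=100, seed=9)
print(f"observed {enr.observed_overlap}/{len(features)} windows overlap a hit; "
      f"expected {enr.expected_mean:.1f} under shuffling")
print(f"l2fc = {enr.l2fc:.3f}, empirical p = {enr.p_emp:.4f} "
      f"(floor at 100 resamplings: {1 / 101:.4f})")

subset = [g for g in genes if g.gene_id in targets]
prof = tss_density_profile(subset, hits, genome, flank=2500, binsize=100)
up = summarize_window(prof, (-500, 0))
distal = summarize_window(prof, (-2500, -1000))
overall = float(np.nanmean(prof.normalized_density))
print(f"normalized density: {up:.2f} in the 500 bp pre-TSS window, "
      f"{distal:.2f} distal, {overall:.2f} overall")
# The pre-TSS window recovers roughly the planted tenfold enrichment while
# distal bins stay near the genome-average score of 1.0.
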