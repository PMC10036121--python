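"""Call FDR-controlled peaks from log2 ratio tracks and build a consensus.

Per replicate: counts -> log2(fusion/Dam) ratio -> shuffle-FDR peak calls.
Replicate peak sets are then reduced to segments supported by at least two
replicates, and the consensus is compared with the planted truth.
"""

from nutrichrom import (
    PeakCallParams, SimConfig, call_peaks, compute_log2_ratio,
    consensus_peaks, make_genome, make_planted_peaks, match_reciprocal,
    simulate_damid_counts,
)

cfg = SimConfig(seed=7, n_chroms=1, chrom_length=1_000_000,
                sequencing_depth=80_000, n_peaks=13)
genome = make_genome(cfg)
planted = make_planted_peaks(genome, cfg)
fusion, dam, _ = simulate_damid_counts(genome, planted, cfg)

replicate_sets = []
for i, (f, d) in enumerate(zip(fusion, dam)):
    ratio = compute_log2_ratio(f, d)
    result = call_peaks(ratio, PeakCallParams(fdr_threshold=0.01, seed=100 + i))
    print(f"replicate {i + 1}: {len(result.candidates)} candidate runs, "
          f"{len(result.peaks)} peaks at FDR < 0.01")
    replicate_sets.append(result.to_interval_set())

consensus = consensus_peaks(replicate_sets, min_support=2, max_gap=50)
called_hit, truth_hit = match_reciprocal(consensus, planted, min_fraction=0.5)
print(f"consensus: {len(consensus)} peaks; "
      f"recall {truth_hit / len(planted):.2f}, "
      f"precision {called_hit / len(consensus):.2f}")
# Recall/precision use 50% reciprocal overlap against the planted regions;
# both sit near 1.0 at fourfold enrichment and ~20 counts per fragment.
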