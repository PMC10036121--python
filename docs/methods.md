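# Methods

This note documents the models, statistics, and numerical choices behind
nutrichrom, and what the synthetic generators do and do not emulate.

## Coordinate model and the GATC fragment lattice

All coordinates are 0-based, half-open.  BED is native; GFF3 is converted at
the boundary (1-based closed start *s* becomes *s* − 1) and converted back on
write, so the round trip is the identity.  A gene's TSS is its strand-aware
start: `start` on the plus strand, `end − 1` on the minus strand.

DamID signal is carried per GATC fragment.  Fragments are cut at GATC motif
*starts*; the 4-bp motif belongs to the downstream fragment.  Any fixed
convention works — this one keeps fragments half-open and contiguous, and the
fragment lattice exactly tiles every chromosome (asserted in tests).
bedGraph tracks are written at 6 significant digits, one record per fragment
by default (run-length merging of equal values is available but off, so
write→read round trips are bit-exact at the printed precision).

## Signal tracks

**log2 ratio.**  `r_i = log2((f_i + ψ)/(d_i + ψ))` with ψ = 0.5 by default.
Under `library_size` normalization both libraries are scaled to the mean of
the two totals before ψ is added.  Scaling both sides (rather than only the
Dam track) makes the transform exactly antisymmetric under swapping the two
tracks for any ψ — a property we assert — while agreeing with the one-sided
convention whenever totals are equal.  This is a deliberate simplification
relative to the kernel-density ratio matching used by the original DamID
ratio tool; it is deterministic and adequate on synthetic data, and parity
with that tool is not claimed.  ψ applied to both numerator and denominator
keeps zero-count fragments finite and unbiased in sign; at ψ = 0 the 0/0
fragment is defined as ratio 0 (the symmetric empty case).

**1× coverage.**  Accessibility counts are converted to a per-bp density
`count × read_len / fragment_length` (read_len 300, echoing the read
extension used in DamID processing; it only acts as a constant here) and
rescaled so the length-weighted genome mean is exactly 1.  The output is
invariant to scaling all counts by a constant.

**Metaprofiles.**  The anchor point is the interval midpoint.  Each bin's
per-anchor value is the length-weighted mean of fragment values overlapping
the bin (the track is piecewise constant, so this is an exact integral);
bins extending past a chromosome end are excluded for that anchor and the
per-bin `n_anchors_used` records it.  The profile is the unweighted mean over
contributing anchors, which makes it exactly linear in the track.

## Peak calling

Candidates are maximal runs of at least `min_fragments` = 2 consecutive
fragments with value ≥ T, where T is the `quantile_threshold` = 0.95 quantile
of all fragment values (ties at T are included).  The null permutes fragment
values uniformly within each chromosome (a genome-wide option exists),
`n_shuffles` = 100 times, re-detecting runs each time.  For a test statistic
*s*, `FDR(s) = mean #{null runs with statistic ≥ s} / #{observed runs with
statistic ≥ s}`, capped at 1 and monotonized (non-increasing in *s*); peaks
with FDR < 0.01 are retained, spanning the first fragment start to the last
fragment end of the run.

The default statistic is the **run sum** of ratio values (mean × length), not
the run mean.  The distinction matters: permutation preserves the genome's
high values, so shuffled data readily produce *short* chance runs whose mean
matches a genuine peak's mean, but essentially never reproduce the long
contiguous runs that true binding creates.  The sum separates the two; with
the mean alone, any track in which bound fragments occupy a nontrivial share
of the upper tail yields FDR estimates near 1 for real peaks.  A
`statistic="mean"` option retains the simpler variant.  Reported peak scores
are always the run mean.

Consensus peaks use multi-intersect semantics: the genome is segmented at all
replicate peak boundaries, segments covered by ≥ `min_support` = 2 replicate
sets are kept, and kept segments are merged with the standard 50-bp gap rule
(`end_a + 50 ≥ start_b`, strict beyond).  Segment coverage rather than
whole-interval identity is used because replicate peak boundaries never match
exactly.

## Annotation

A gene is a target of a factor iff a peak overlaps [start, end) by ≥ 1 bp —
intronic binding counts.  Peak feature categories are decided by the peak
midpoint with priority promoter-TSS (−1000/+100 bp around the TSS, the
common annotator default) > gene body > TTS (−100/+1000 bp around the gene
end) > intergenic, so category fractions sum to 1.

For chromatin-domain allocation each gene takes the color covering the
largest share of its span (ties break deterministically toward the
alphabetically first color); single assignment keeps the observed and
expected proportions interpretable.  TSS-based assignment is a reasonable
alternative not currently exposed.  The null resamples equally sized gene
sets uniformly without replacement; per-color p-values use the add-one
estimator `(r + 1)/(n + 1)` and therefore never report 0.

## Motif statistics

**Shuffles.**  `shuffle_intervals` re-places intervals uniformly at random
with lengths preserved, on their own chromosome by default, and
non-overlapping by default.  Non-overlapping placement uses an exact
sequential-gap construction — anchors drawn uniformly in the
length-reduced space `[0, L − Σ lengths]`, sorted, and intervals laid down in
a random order — rather than rejection sampling; it is equivalent in
distribution for the statistics computed here, deterministic given the seed,
and succeeds whenever the intervals fit (an infeasible chromosome raises an
error naming it).

**Overlap enrichment.**  The observed statistic is the count of feature
intervals overlapping ≥ 1 bp of any motif hit (binary per feature; a
bp-weighted variant is deliberately not the default since the reference
statistic is a feature count).  The set named by `mode` is shuffled per
resample; `l2fc = log2((obs + ε)/(mean_perm + ε))` with ε = 0.5 guarding
division by zero, and the one-sided enrichment p is add-one, with floor
`1/(n_resamples + 1)` — 0.0099 at 100 resamplings.

**TSS density.**  Hit intervals are unioned first (avoiding double-counting
where hits overlap), then hit-covered bp are accumulated in strand-aware
100-bp bins across ±2500 bp of each gene's TSS, mirrored on the minus strand
so negative offsets are always upstream.  The expectation per bin is
`Σ_genes (in-bounds bin width) × genome_motif_fraction`; bins truncated by a
chromosome end contribute only their covered width.  Normalization is per
bin, which reduces to a single constant when bins are equal width; a value
of 1.0 is genome-average density.  `summarize_window` averages bins inside an
aligned window, e.g. the 500 bp immediately upstream of the TSS.

## Equivalence testing and rescue classification

The region of practical equivalence is ±Δ with Δ = log2(1.5) ≈ 0.585.
Assuming the observed l2fc is normal with its gene-wise standard error, the
two one-sided tests give `p = max(1 − Φ((l2fc + Δ)/SE), Φ((l2fc − Δ)/SE))`;
at l2fc = ±Δ the value is exactly 0.5, and the boundary type-I error at
α = 0.05 is controlled (asserted over 10⁴ simulated genes).  TOST is the
standard operationalization of testing the null of a change larger than
1.5-fold; a single folded test would be the alternative reading.

Rescue classification takes the baseline-DEG set (Wald BH q < 0.1 computed
table-wide) and, per DEG: *reverted* iff the treatment contrast is
significant (q < 0.1) with sign opposite the baseline sign — significance is
required by default and can be relaxed; *restored* iff the equivalence BH q,
computed **within the baseline-DEG set** (that is the population being
classified; table-wide adjustment is available), is < 0.05.  A gene carrying
both flags is labelled reverted — a sign-flipped significant change is the
stronger statement — and both flags are always reported.  Wald and
equivalence calls cannot both fire when SE is large relative to Δ; a gene
with |l2fc| just under Δ and a tiny SE can legitimately be both significantly
non-zero and within ±1.5-fold, which is correct behavior, not a bug.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of (config, seed); per-stage RNG streams are
derived from the master seed by stable labels, so adding a stage never
perturbs earlier draws.  Defaults describe the study conditions the tests
run under:

- genome: 3 × 1 Mbp chromosomes, GATC sites as a hard-core point process
  (gaps 4 + Exp(256) bp), fly-like density;
- genes: 300 non-overlapping stranded spans, lognormal lengths (mean 3 kb);
- domains: alternating exponential blocks (mean 20 kb), five colors,
  consecutive blocks always differing, marginally uniform;
- counts: negative binomial, variance μ + 0.02 μ², mean proportional to
  (fragment length + 300 bp); the 300-bp term mirrors how extended reads
  give even short GATC fragments substantial coverage and keeps the
  per-fragment ratio informative at ~20 expected counts per fragment.
  Dispersion is a testability choice — no DamID dispersion estimates exist
  to calibrate against;
- planted peaks: 40 regions of ~10 consecutive fragments, fourfold fusion
  enrichment, about 13 peaks per Mbp (the order of magnitude of genome-wide
  DamID peak sets);
- motifs: 10-bp hits (a typical zinc-finger motif width) at 1/2000 bp
  background, tenfold rate in the 500-bp strand-aware window upstream of
  target TSSs only (the upstream-only bias is intentional);
- DE tables: 2000 genes, 300 true DE with |l2fc| ~ U(1.5, 3), SE ~
  U(0.05, 0.15), and 30% / 30% / 40% of DE genes planted as reverted /
  restored / still-changed under treatment.

Not emulated: sequence (no FASTA, no reads), mappability and copy-number
artifacts, GC or accessibility bias in Dam methylation, correlated
replicates, dispersion trends in DE standard errors, and the spatial
clustering of real chromatin domains.  Passing recovery tests therefore
demonstrates the correctness and calibration of the statistics under the
stated model, not robustness to every artifact of real libraries.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale chosen as the package's
own operating points: peak-caller characteristics on twenty seeded 1-Mbp
genomes (3 replicates, 4× enrichment, FDR 0.01); permutation-p calibration
on 200 null datasets of 30 features × 100 hits at 50 resamples; the TSS
density check on a 5-Mbp genome with 800 genes and ~10,000 uniform hits
(Monte-Carlo SD of the profile mean ≈ 0.008, well inside the ±0.05 check).
Empirical p-values always use add-one estimators; FDR curves are
monotonized; interval ties (fragments exactly at the peak threshold,
touching intervals in shuffles) are inclusive; all stochastic outputs record
their seeds.

## Known limitations

The peak caller reconstructs a shuffle-FDR approach from its description;
parity with any specific published implementation is not claimed.  The
consensus operation works on peak extents only and does not refine boundaries
by signal.  The feature annotator uses gene spans without exon models
(gene body stands in for intron).  bigwig output is not produced — bedGraph
conversion is left to external tools.  The motif layer consumes hit
intervals; PWM scanning and per-hit q-values are upstream concerns.
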