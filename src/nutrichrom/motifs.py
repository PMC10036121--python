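"""Permutation-based motif-overlap enrichment and TSS-relative motif density.

Enrichment compares the observed count of feature intervals overlapping
at least one motif hit against the mean overlap across seeded random
re-placements (length-preserving, non-overlapping, chromosome-preserving
by default) of either the features or the hits.  The empirical p-value
uses the add-one estimator (r + 1) / (n + 1), so its floor at 100
resamplings is 1/101 ~ 0.0099.

The TSS density profile counts motif-covered bp in strand-aware bins
around gene TSSs and normalizes by the genome-wide expectation — the
number of genes times the fractional motif coverage of the genome times
the bin width — so a score of 1.0 means genome-average density.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import GeneModel, GenomeModel, IntervalSet, ValidationError
from .peaks import merge_intervals, overlap_mask
from .simulate import stage_rng


@dataclass
class EnrichmentResult:
    observed_overlap: int
    permuted_overlaps: np.ndarray
    expected_mean: float
    l2fc: float
    p_emp: float
    n_resamples: int
    seed: int
    mode: str


@dataclass
class TssDensityProfile:
    """Normalized motif density per bin around TSSs (negative = upstream)."""

    offsets: np.ndarray
    normalized_density: np.ndarray
    observed_bp: np.ndarray
    expected_bp: np.ndarray
    n_genes: int
    genome_motif_fraction: float


def merge_motif_hits(
    hit_sets: Sequence[IntervalSet], q_threshold: Optional[float] = 0.1
) -> IntervalSet:
    """Pool per-motif-variant hits passing the q-value filter and union overlaps.

    Per-hit q-values are read from the interval score column; pass
    ``q_threshold=None`` to pool without filtering.
    """
    frames = []
    for hs in hit_sets:
        df = hs.df
        if q_threshold is not None:
            if df["score"].isna().any():
                raise ValidationError("q-value filtering requested but hits lack q scores")
            df = df[df["score"] <= q_threshold]
        frames.append(df[["chrom", "start", "end"]])
    pooled = IntervalSet(pd.concat(frames, ignore_index=True)) if frames else IntervalSet()
    if len(pooled) == 0:
        return pooled
    return merge_intervals(pooled, max_gap=0)


def shuffle_intervals(
    intervals: IntervalSet,
    genome: GenomeModel,
    preserve_chromosome: bool = True,
    forbid_overlap: bool = True,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
    max_retries: int = 100,
) -> IntervalSet:
    """Re-place every interval uniformly at random, preserving lengths.

    With ``preserve_chromosome`` each interval stays on its own
    chromosome.  Non-overlapping placement uses an exact sequential-gap
    construction (uniform in the length-reduced space, random interval
    order), so placement succeeds whenever the intervals fit.
    """
    if rng is None:
        rng = stage_rng(seed, "shuffle")
    df = intervals.df
    lengths = (df["end"] - df["start"]).to_numpy(np.int64)
    new_chrom = df["chrom"].to_numpy(object).copy()
    if not preserve_chromosome:
        chroms = list(genome.chromosomes)
        sizes = np.array([genome.chromosomes[c] for c in chroms], dtype=float)
        for attempt in range(max_retries):
            assignment = rng.choice(len(chroms), size=len(df), p=sizes / sizes.sum())
            ok = True
            if forbid_overlap:
                for ci, c in enumerate(chroms):
                    need = lengths[assignment == ci].sum()
                    if need > genome.chromosomes[c]:
                        ok = False
                        break
            else:
                for ci, c in enumerate(chroms):
                    sel = lengths[assignment == ci]
                    if sel.size and sel.max() > genome.chromosomes[c]:
                        ok = False
                        break
            if ok:
                new_chrom = np.array([chroms[i] for i in assignment], dtype=object)
                break
        else:
            raise ValidationError("could not assign intervals to chromosomes without overfill")

    new_start = np.empty(len(df), dtype=np.int64)
    for chrom in dict.fromkeys(new_chrom):
        idx = np.flatnonzero(new_chrom == chrom)
        L = genome.chromosomes.get(chrom)
        if L is None:
            raise ValidationError(f"interval on unknown chromosome {chrom!r}")
        lens = lengths[idx]
        if forbid_overlap:
            total = int(lens.sum())
            slack = L - total
            if slack < 0:
                raise ValidationError(
                    f"intervals do not fit on chromosome {chrom} without overlap"
                )
            order = rng.permutation(idx.size)
            anchors = np.sort(rng.integers(0, slack + 1, size=idx.size))
            lens_ord = lens[order]
            offsets = np.concatenate(([0], np.cumsum(lens_ord[:-1])))
            new_start[idx[order]] = anchors + offsets
        else:
            if np.any(lens > L):
                raise ValidationError(f"interval longer than chromosome {chrom}")
            new_start[idx] = rng.integers(0, L - lens + 1)
    out = df.copy()
    out["chrom"] = new_chrom
    out["start"] = new_start
    out["end"] = new_start + lengths
    return IntervalSet(out)


def _union_by_chrom(ivs: IntervalSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome sorted disjoint union of an interval set (numpy only)."""
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    df = ivs.df
    chrom = df["chrom"].to_numpy(object)
    start = df["start"].to_numpy(np.int64)
    end = df["end"].to_numpy(np.int64)
    for c in dict.fromkeys(chrom):
        sel = chrom == c
        s, e = start[sel], end[sel]
        o = np.argsort(s, kind="stable")
        s, e = s[o], e[o]
        run_max = np.maximum.accumulate(e)
        new_block = np.concatenate(([True], s[1:] > run_max[:-1]))
        ustarts = s[new_block]
        uends = np.maximum.reduceat(e, np.flatnonzero(new_block))
        out[c] = (ustarts, uends)
    return out


def _count_overlapping(ivs: IntervalSet, union: dict[str, tuple[np.ndarray, np.ndarray]]) -> int:
    """Number of intervals overlapping >= 1 bp of the unioned subject set."""
    df = ivs.df
    chrom = df["chrom"].to_numpy(object)
    start = df["start"].to_numpy(np.int64)
    end = df["end"].to_numpy(np.int64)
    n = 0
    for c in dict.fromkeys(chrom):
        arr = union.get(c)
        if arr is None:
            continue
        s_starts, s_ends = arr
        sel = chrom == c
        k = np.searchsorted(s_ends, start[sel], side="right")
        ok = (k < s_starts.size) & (s_starts[np.minimum(k, s_starts.size - 1)] < end[sel])
        n += int(ok.sum())
    return n


def overlap_enrichment(
    features: IntervalSet,
    hits: IntervalSet,
    genome: GenomeModel,
    n_resamples: int = 100,
    mode: str = "shuffle_features",
    seed: int = 0,
    preserve_chromosome: bool = True,
    epsilon: float = 0.5,
) -> EnrichmentResult:
    """Permutation test for enrichment of features overlapping motif hits.

    ``mode`` names the set that is shuffled per resample
    (``shuffle_features`` or ``shuffle_motifs``).  l2fc =
    log2((observed + eps) / (expected_mean + eps)); one-sided add-one
    p-value for enrichment.
    """
    if len(features) == 0:
        raise ValidationError("no feature intervals provided")
    if mode not in ("shuffle_features", "shuffle_motifs"):
        raise ValidationError(f"unknown mode {mode!r}")
    features = features.normalize().validate(genome)
    hits = hits.normalize().validate(genome)
    observed = int(overlap_mask(features, hits).sum())
    rng = stage_rng(seed, f"enrichment-{mode}")
    permuted = np.empty(n_resamples, dtype=np.int64)
    if mode == "shuffle_features":
        hit_union = _union_by_chrom(hits)
        for r in range(n_resamples):
            shuffled = shuffle_intervals(
                features, genome, preserve_chromosome=preserve_chromosome, rng=rng
            )
            permuted[r] = _count_overlapping(shuffled, hit_union)
    else:
        for r in range(n_resamples):
            shuffled = shuffle_intervals(
                hits, genome, preserve_chromosome=preserve_chromosome, rng=rng
            )
            permuted[r] = _count_overlapping(features, _union_by_chrom(shuffled))
    expected = float(permuted.mean())
    l2fc = float(np.log2((observed + epsilon) / (expected + epsilon)))
    p_emp = (1 + int((permuted >= observed).sum())) / (n_resamples + 1)
    return EnrichmentResult(
        observed_overlap=observed,
        permuted_overlaps=permuted,
        expected_mean=expected,
        l2fc=l2fc,
        p_emp=p_emp,
        n_resamples=n_resamples,
        seed=seed,
        mode=mode,
    )


def _coverage_fn(starts: np.ndarray, ends: np.ndarray):
    """Covered-bp prefix function C(x) for sorted disjoint intervals."""
    cum = np.concatenate(([0], np.cumsum(ends - starts)))

    def C(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.int64)
        k = np.searchsorted(starts, x, side="right")
        base = cum[k]
        # subtract the part of the last-started interval lying at/after x
        last = np.maximum(k - 1, 0)
        over = np.where(k > 0, np.maximum(0, ends[last] - np.maximum(x, starts[last])), 0)
        return base - over

    return C


def tss_density_profile(
    genes_subset: Sequence[GeneModel],
    hits: IntervalSet,
    genome: GenomeModel,
    flank: int = 2500,
    binsize: int = 100,
) -> TssDensityProfile:
    """Motif-hit density around TSSs, normalized to genome-wide expectation.

    Hit-covered bp are counted per strand-aware bin in [-flank, +flank)
    around each gene's TSS (mirrored on the minus strand so negative
    offsets are upstream) and summed over genes.  The expectation per bin
    is the genome motif-coverage fraction times the summed in-bounds bin
    width, so bins truncated at chromosome ends contribute only their
    covered width.
    """
    if not genes_subset:
        raise ValidationError("genes_subset must be non-empty")
    if flank % binsize != 0:
        raise ValidationError("flank must be a multiple of binsize")
    union = merge_intervals(hits, max_gap=0) if len(hits) else IntervalSet()
    union.validate(genome)
    frac = union.total_bp() / genome.total_length
    nbins = 2 * flank // binsize
    offsets = -flank + binsize * (np.arange(nbins) + 0.5)
    observed = np.zeros(nbins)
    expected_width = np.zeros(nbins)

    cov_by_chrom = {}
    for c in union.chroms():
        s, e = union.arrays(c)
        cov_by_chrom[c] = _coverage_fn(s, e)

    bin_lo = -flank + binsize * np.arange(nbins)
    for g in genes_subset:
        L = genome.chromosomes[g.chrom]
        if g.strand == "+":
            lo = g.tss + bin_lo
            hi = lo + binsize
        else:
            # offset of base p is (tss - p); bin [o, o+bs) maps to [tss-o-bs+1, tss-o+1)
            hi = g.tss - bin_lo + 1
            lo = hi - binsize
        lo_c = np.clip(lo, 0, L)
        hi_c = np.clip(hi, 0, L)
        width = hi_c - lo_c
        expected_width += width
        C = cov_by_chrom.get(g.chrom)
        if C is not None:
            observed += C(hi_c) - C(lo_c)
    expected = expected_width * frac
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.where(expected > 0, observed / expected, np.nan)
    return TssDensityProfile(
        offsets=offsets,
        normalized_density=norm,
        observed_bp=observed,
        expected_bp=expected,
        n_genes=len(genes_subset),
        genome_motif_fraction=float(frac),
    )


def summarize_window(profile: TssDensityProfile, window: tuple[int, int]) -> float:
    """Mean normalized density over the bins inside [from_bp, to_bp)."""
    lo, hi = window
    binsize = int(round(profile.offsets[1] - profile.offsets[0])) if len(profile.offsets) > 1 else 0
    flank = int(round(-(profile.offsets[0] - binsize / 2)))
    if lo < -flank or hi > flank:
        raise ValidationError(f"window {window} outside +/-{flank} bp profile span")
    if (lo + flank) % binsize or (hi + flank) % binsize:
        raise ValidationError("window must align to bin boundaries")
    centers = profile.offsets
    mask = (centers > lo) & (centers < hi)
    return float(np.nanmean(profile.normalized_density[mask]))
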