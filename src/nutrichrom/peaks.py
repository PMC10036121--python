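"""FDR-controlled peak calling on log2 ratio tracks and interval set algebra.

Peak calling reconstructs the shuffle-based FDR approach used for DamID
ratio files: candidate peaks are maximal runs of consecutive
high-quantile fragments, the null is obtained by permuting fragment
values within each chromosome, and the FDR at statistic s is the mean
number of null candidates with statistic >= s divided by the number of
observed candidates with statistic >= s (capped at 1, monotonized in s).
The default test statistic is the run *sum* of ratio values (mean x run
length): permuted data readily produce short chance runs of high values
but essentially never the long contiguous runs that genuine binding
produces, so the sum separates the two where the mean alone cannot.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import FragmentTrack, GenomeModel, Interval, IntervalSet, ValidationError
from .simulate import stage_rng


@dataclass
class PeakCallParams:
    fdr_threshold: float = 0.01
    quantile_threshold: float = 0.95
    min_fragments: int = 2
    n_shuffles: int = 100
    seed: int = 0
    per_chromosome_shuffle: bool = True
    statistic: str = "sum"  # FDR test statistic: "sum" or "mean" of run values

    def __post_init__(self) -> None:
        if not (0 < self.fdr_threshold < 1):
            raise ValidationError("fdr_threshold must be in (0, 1)")
        if not (0 < self.quantile_threshold < 1):
            raise ValidationError("quantile_threshold must be in (0, 1)")
        if self.min_fragments < 1 or self.n_shuffles < 1:
            raise ValidationError("min_fragments and n_shuffles must be >= 1")
        if self.statistic not in ("sum", "mean"):
            raise ValidationError("statistic must be 'sum' or 'mean'")


@dataclass
class Peak:
    """A called peak: genomic extent, mean ratio score, run size, and FDR."""

    interval: Interval
    score: float
    n_fragments: int
    fdr: float


@dataclass
class PeakCallResult:
    peaks: list[Peak]
    candidates: list[Peak]

    def to_interval_set(self) -> IntervalSet:
        rows = [
            (p.interval.chrom, p.interval.start, p.interval.end, p.score, f"peak{i + 1}")
            for i, p in enumerate(self.peaks)
        ]
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "score", "label"])
        return IntervalSet(df).normalize()


def _runs_above(values: np.ndarray, threshold: float, min_fragments: int):
    """(start_idx, end_idx_exclusive, mean, sum) of maximal runs with value >= threshold."""
    mask = values >= threshold
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    out = []
    csum = np.concatenate(([0.0], np.cumsum(values)))
    for s, e in zip(starts, ends):
        if e - s >= min_fragments:
            total = float(csum[e] - csum[s])
            out.append((int(s), int(e), total / (e - s), total))
    return out


def call_peaks(track: FragmentTrack, params: Optional[PeakCallParams] = None) -> PeakCallResult:
    """Call peaks from a log2 ratio track with a permutation-based FDR.

    The score threshold is the ``quantile_threshold`` quantile of all
    fragment values (fragments exactly at the threshold are included).
    Returns both the FDR-filtered peaks and the full candidate list with
    their FDR estimates.
    """
    params = params or PeakCallParams()
    genome = track.genome
    if track.values.size == 0:
        return PeakCallResult([], [])
    T = float(np.quantile(track.values, params.quantile_threshold))

    stat_idx = 3 if params.statistic == "sum" else 2
    chroms = list(genome.chromosomes)
    obs: list[tuple[str, int, int, float, float]] = []
    for c in chroms:
        for run in _runs_above(track.chrom_values(c), T, params.min_fragments):
            obs.append((c, run[0], run[1], run[2], run[stat_idx]))
    if not obs:
        return PeakCallResult([], [])

    rng = stage_rng(params.seed, "callpeaks")
    null_stats: list[float] = []
    for _ in range(params.n_shuffles):
        if params.per_chromosome_shuffle:
            for c in chroms:
                perm = rng.permutation(track.chrom_values(c))
                null_stats.extend(
                    run[stat_idx] for run in _runs_above(perm, T, params.min_fragments)
                )
        else:
            perm = rng.permutation(track.values)
            null_stats.extend(run[stat_idx] for run in _runs_above(perm, T, params.min_fragments))
    null_sorted = np.sort(np.asarray(null_stats))

    stats = np.array([o[4] for o in obs])
    order = np.argsort(-stats, kind="stable")
    ranked = stats[order]
    n_null_ge = null_sorted.size - np.searchsorted(null_sorted, ranked, side="left")
    mean_null_ge = n_null_ge / params.n_shuffles
    # observed candidates with statistic >= s, for s along the descending ranking
    n_obs_ge = np.searchsorted(-ranked, -ranked, side="right")
    raw = np.minimum(1.0, mean_null_ge / n_obs_ge)
    fdr_ranked = np.maximum.accumulate(raw)  # monotone non-increasing in the statistic
    fdr = np.empty_like(fdr_ranked)
    fdr[order] = fdr_ranked

    candidates: list[Peak] = []
    for (c, s, e, score, _), q in zip(obs, fdr):
        b = genome.fragment_boundaries(c)
        iv = Interval(c, int(b[s]), int(b[e]), score=score)
        candidates.append(Peak(iv, score, e - s, float(q)))
    peaks = [p for p in candidates if p.fdr < params.fdr_threshold]
    return PeakCallResult(peaks, candidates)


# -- interval set algebra -------------------------------------------------------


def merge_intervals(intervals: IntervalSet, max_gap: int = 50) -> IntervalSet:
    """Transitively union same-chromosome intervals with gaps <= max_gap.

    Two intervals merge when end_a + max_gap >= start_b; the operation is
    idempotent.
    """
    norm = intervals.normalize()
    rows = []
    for chrom in norm.chroms():
        starts, ends = norm.arrays(chrom)
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            if cur_e + max_gap >= s:
                cur_e = max(cur_e, int(e))
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        rows.append((chrom, cur_s, cur_e))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return IntervalSet(df, sorted=True)


def consensus_peaks(
    replicates: Sequence[IntervalSet], min_support: int = 2, max_gap: int = 50
) -> IntervalSet:
    """Genomic segments covered by at least ``min_support`` replicates.

    Multi-intersect semantics: the genome is segmented at all replicate
    interval boundaries, segments covered by >= min_support replicate
    sets are kept, then merged with ``max_gap``.
    """
    if min_support > len(replicates):
        raise ValidationError(
            f"min_support {min_support} exceeds number of replicates {len(replicates)}"
        )
    # union within each replicate so a replicate counts once per base
    unions = [merge_intervals(r, max_gap=0) for r in replicates if len(r) > 0]
    chroms: list[str] = []
    for u in unions:
        for c in u.chroms():
            if c not in chroms:
                chroms.append(c)
    rows = []
    for chrom in sorted(chroms):
        delta: dict[int, int] = {}
        for u in unions:
            starts, ends = u.arrays(chrom)
            for s in starts:
                delta[int(s)] = delta.get(int(s), 0) + 1
            for e in ends:
                delta[int(e)] = delta.get(int(e), 0) - 1
        if not delta:
            continue
        positions = sorted(delta)
        depth = 0
        for p, nxt in zip(positions[:-1], positions[1:]):
            depth += delta[p]
            if depth >= min_support:
                rows.append((chrom, p, nxt))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return merge_intervals(IntervalSet(df), max_gap=max_gap) if len(df) else IntervalSet(df)


def _overlaps_any(
    starts: np.ndarray, ends: np.ndarray, q_start: int, q_end: int
) -> bool:
    """Does [q_start, q_end) overlap any of the sorted disjoint intervals?"""
    k = int(np.searchsorted(ends, q_start, side="right"))
    return k < starts.size and starts[k] < q_end


def overlap_mask(queries: IntervalSet, subjects: IntervalSet) -> np.ndarray:
    """Boolean per query row: overlaps >= 1 bp of some subject interval."""
    union = merge_intervals(subjects, max_gap=0) if len(subjects) else subjects
    mask = np.zeros(len(queries), dtype=bool)
    df = queries.df
    for chrom in queries.chroms():
        s_starts, s_ends = (union.arrays(chrom) if len(union) else (np.array([]), np.array([])))
        idx = np.flatnonzero((df["chrom"] == chrom).to_numpy())
        if s_starts.size == 0 or idx.size == 0:
            continue
        q_start = df["start"].to_numpy()[idx]
        q_end = df["end"].to_numpy()[idx]
        k = np.searchsorted(s_ends, q_start, side="right")
        ok = (k < s_starts.size) & (s_starts[np.minimum(k, s_starts.size - 1)] < q_end)
        mask[idx] = ok
    return mask


def intersect_sets(a: IntervalSet, b: IntervalSet) -> dict:
    """Classify intervals of each set by >= 1 bp overlap with the other.

    Returns shared (intervals of a overlapping b), a_only, b_only, and
    Venn-style counts per set.
    """
    a_norm, b_norm = a.normalize(), b.normalize()
    a_hits = overlap_mask(a_norm, b_norm)
    b_hits = overlap_mask(b_norm, a_norm)
    return {
        "shared": a_norm.subset(a_hits),
        "a_only": a_norm.subset(~a_hits),
        "b_only": b_norm.subset(~b_hits),
        "counts": {
            "a_shared": int(a_hits.sum()),
            "a_only": int((~a_hits).sum()),
            "b_shared": int(b_hits.sum()),
            "b_only": int((~b_hits).sum()),
        },
    }


def match_reciprocal(
    called: IntervalSet, truth: IntervalSet, min_fraction: float = 0.5
) -> tuple[int, int]:
    """Count reciprocal-overlap matches between called and true intervals.

    A pair matches when the overlap covers >= min_fraction of both
    intervals.  Returns (number of called intervals matching some true
    interval, number of true intervals matched by some called interval);
    recall and precision follow by dividing by the set sizes.
    """

    def hits(src: IntervalSet, dst: IntervalSet) -> int:
        n = 0
        dst_by_chrom = {c: dst.arrays(c) for c in dst.chroms()}
        for iv in src:
            arr = dst_by_chrom.get(iv.chrom)
            if arr is None:
                continue
            starts, ends = arr
            ov = np.minimum(ends, iv.end) - np.maximum(starts, iv.start)
            lens = ends - starts
            good = (ov >= min_fraction * iv.length) & (ov >= min_fraction * lens)
            if good.any():
                n += 1
        return n

    return hits(called.normalize(), truth.normalize()), hits(truth.normalize(), called.normalize())
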