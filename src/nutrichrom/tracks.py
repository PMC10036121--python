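"""Fragment-track transformations: log2 Dam-fusion/Dam ratios, 1x-normalized
accessibility coverage, and average signal metaprofiles around anchor points.

The log2 ratio per GATC fragment i is

    r_i = log2((f_i + psi) / (d'_i + psi))

where f_i and d_i are fusion and Dam-only counts, d' is the Dam track
rescaled to the fusion library size, and psi is a pseudocount keeping
zero-count fragments finite and unbiased in sign.

The 1x coverage normalization converts counts to a per-bp density
(count x read_len / fragment_length) and rescales so the length-weighted
genome mean equals exactly 1 — the "reads per genome coverage" convention
used for accessibility tracks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model import FragmentTrack, GenomeModel, IntervalSet, ValidationError


@dataclass
class RatioParams:
    """Pseudocount and normalization for log2 ratio tracks."""

    pseudocount: float = 0.5
    normalization: str = "library_size"  # or "none"

    def __post_init__(self) -> None:
        if self.pseudocount < 0:
            raise ValidationError("pseudocount must be >= 0")
        if self.normalization not in ("library_size", "none"):
            raise ValidationError(f"unknown normalization {self.normalization!r}")


@dataclass
class Metaprofile:
    """Mean signal per bin at fixed offsets around a set of anchor points.

    ``offsets`` are bin centers relative to the anchor (negative =
    upstream); ``n_anchors_used`` counts anchors whose bin lay fully
    inside its chromosome.  Bins no anchor contributes to carry NaN.
    """

    offsets: np.ndarray
    mean_signal: np.ndarray
    n_anchors_used: np.ndarray


def compute_log2_ratio(
    fusion: FragmentTrack, dam: FragmentTrack, params: Optional[RatioParams] = None
) -> FragmentTrack:
    """Per-fragment log2(fusion/Dam) ratio track.

    With library-size normalization both libraries are scaled to the
    mean of the two totals before the pseudocount is added, so the ratio
    is invariant to sequencing-depth differences and exactly antisymmetric
    under swapping the two tracks for any pseudocount.
    """
    params = params or RatioParams()
    if fusion.genome is not dam.genome and fusion.genome != dam.genome:
        raise ValidationError("fusion and Dam tracks are on different genomes")
    if fusion.kind != "count" or dam.kind != "count":
        raise ValidationError("log2 ratio requires count tracks")
    f = fusion.values.astype(float)
    d = dam.values.astype(float)
    if params.normalization == "library_size":
        total_f, total_d = f.sum(), d.sum()
        if total_d == 0 or total_f == 0:
            raise ValidationError("cannot library-size normalize a zero-total track")
        target = 0.5 * (total_f + total_d)
        f = f * (target / total_f)
        d = d * (target / total_d)
    psi = params.pseudocount
    num, den = f + psi, d + psi
    with np.errstate(divide="ignore", invalid="ignore"):
        # 0/0 (possible only at psi=0) is the symmetric empty case -> ratio 0
        r = np.where((num == 0) & (den == 0), 0.0, np.log2(num) - np.log2(den))
    return FragmentTrack(fusion.genome, r, "log2ratio")


def normalize_coverage_1x(counts: FragmentTrack, read_len: int = 300) -> FragmentTrack:
    """Convert a count track to 1x-normalized coverage density.

    The per-fragment density count x read_len / fragment_length is
    rescaled so the length-weighted genome mean equals 1; scaling all
    counts by a constant therefore leaves the output unchanged.
    """
    if counts.kind != "count":
        raise ValidationError("1x normalization requires a count track")
    if counts.values.sum() == 0:
        raise ValidationError("cannot normalize an all-zero track")
    frag_len = counts.genome.fragment_lengths().astype(float)
    density = counts.values * read_len / frag_len
    total = float((density * frag_len).sum())
    scaled = density * (counts.genome.total_length / total)
    return FragmentTrack(counts.genome, scaled, "coverage")


def _prefix_weighted(genome: GenomeModel, values: np.ndarray, chrom: str):
    """Prefix sums of value x length along fragment boundaries of one chromosome."""
    off = genome.fragment_offset(chrom)
    v = values[off : off + genome.n_fragments_chrom(chrom)]
    b = genome.fragment_boundaries(chrom)
    cum = np.concatenate(([0.0], np.cumsum(v * np.diff(b))))
    return b, v, cum


def _weighted_sum(b: np.ndarray, v: np.ndarray, cum: np.ndarray, a: np.ndarray, c: np.ndarray):
    """Integral of the piecewise-constant track over [a, c), vectorized."""

    def S(x: np.ndarray) -> np.ndarray:
        k = np.clip(np.searchsorted(b, x, side="right") - 1, 0, len(v) - 1)
        return cum[k] + v[k] * (x - b[k])

    return S(c) - S(a)


def metaprofile(
    track: FragmentTrack,
    anchors: IntervalSet,
    flank: int = 2500,
    binsize: int = 50,
) -> Metaprofile:
    """Average signal in fixed bins around anchor-interval midpoints.

    Each bin's per-anchor value is the length-weighted mean of the
    fragment values overlapping the bin; bins extending past chromosome
    ends are excluded for that anchor.  The profile is the unweighted
    mean across contributing anchors.
    """
    if len(anchors) == 0:
        raise ValidationError("anchors must be non-empty")
    if flank % binsize != 0:
        raise ValidationError("flank must be a multiple of binsize")
    nbins = 2 * flank // binsize
    offsets = -flank + binsize * (np.arange(nbins) + 0.5)
    sums = np.zeros(nbins)
    used = np.zeros(nbins, dtype=np.int64)
    genome = track.genome
    for chrom in anchors.chroms():
        if chrom not in genome.chromosomes:
            raise ValidationError(f"anchor on unknown chromosome {chrom!r}")
        starts, ends = anchors.arrays(chrom)
        mids = (starts + ends) // 2
        L = genome.chromosomes[chrom]
        b, v, cum = _prefix_weighted(genome, track.values, chrom)
        for m in mids:
            lo = m - flank + binsize * np.arange(nbins)
            hi = lo + binsize
            ok = (lo >= 0) & (hi <= L)
            if not ok.any():
                continue
            w = _weighted_sum(b, v, cum, lo[ok].astype(float), hi[ok].astype(float))
            sums[ok] += w / binsize
            used[ok] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(used > 0, sums / np.maximum(used, 1), np.nan)
    return Metaprofile(offsets=offsets, mean_signal=mean, n_anchors_used=used)
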