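"""Peak-to-gene assignment, genomic feature annotation, and chromatin-color
allocation of target genes with a resampling test.

A gene is a target of a profiled factor when a peak overlaps its span by
at least one base — anywhere on its length, intronic binding included.
Domain allocation compares target-gene counts per chromatin color
(observed) against the whole-genome gene proportions (expected) and
attaches an add-one permutation p-value per color from uniform
resampling of equally sized gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import GeneModel, IntervalSet, ValidationError, genes_to_frame
from .peaks import overlap_mask
from .simulate import stage_rng


def assign_targets(peaks: IntervalSet, genes: Sequence[GeneModel]) -> set[str]:
    """Gene ids whose span [start, end) overlaps >= 1 bp of some peak."""
    gdf = genes_to_frame(list(genes))
    gene_set = IntervalSet.from_arrays(gdf["chrom"], gdf["start"], gdf["end"], label=gdf["gene_id"])
    mask = overlap_mask(gene_set, peaks)
    return set(gene_set.df.loc[mask, "label"])


#: midpoint category priority: promoter-TSS > gene body > TTS > intergenic
FEATURE_CATEGORIES = ("promoter-TSS", "gene_body", "TTS", "intergenic")


def annotate_peak_features(
    peaks: IntervalSet,
    genes: Sequence[GeneModel],
    promoter_window: tuple[int, int] = (-1000, 100),
    tts_window: tuple[int, int] = (-100, 1000),
) -> tuple[list[str], dict[str, float]]:
    """Classify each peak midpoint into a genomic feature category.

    Windows are strand-aware offsets around the TSS (promoter) and the
    strand-aware gene end (TTS).  Without an exon model the gene body
    stands in for intron/body.  Fractions over all peaks sum to 1.
    """
    promoters, bodies, tts_regions = [], [], []
    for g in genes:
        if g.strand == "+":
            promoters.append((g.chrom, g.tss + promoter_window[0], g.tss + promoter_window[1]))
            tts_regions.append((g.chrom, g.end - 1 + tts_window[0], g.end - 1 + tts_window[1]))
        else:
            promoters.append((g.chrom, g.tss - promoter_window[1] + 1, g.tss - promoter_window[0] + 1))
            tts_regions.append((g.chrom, g.start - tts_window[1] + 1, g.start - tts_window[0] + 1))
        bodies.append((g.chrom, g.start, g.end))

    def region_lookup(regions):
        by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        df = pd.DataFrame(regions, columns=["chrom", "start", "end"])
        df["start"] = df["start"].clip(lower=0)
        df = df[df["end"] > df["start"]]
        for chrom, sub in df.groupby("chrom", sort=False):
            sub = sub.sort_values("start")
            by_chrom[chrom] = (sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64))
        return by_chrom

    lookups = [region_lookup(promoters), region_lookup(bodies), region_lookup(tts_regions)]

    def contains(lookup, chrom: str, pos: int) -> bool:
        arr = lookup.get(chrom)
        if arr is None:
            return False
        starts, ends = arr
        k = np.searchsorted(starts, pos, side="right")
        return bool(k > 0 and np.any(ends[:k][starts[:k] <= pos] > pos))

    categories: list[str] = []
    for iv in peaks:
        mid = iv.midpoint
        if contains(lookups[0], iv.chrom, mid):
            categories.append("promoter-TSS")
        elif contains(lookups[1], iv.chrom, mid):
            categories.append("gene_body")
        elif contains(lookups[2], iv.chrom, mid):
            categories.append("TTS")
        else:
            categories.append("intergenic")
    n = max(1, len(categories))
    fractions = {c: categories.count(c) / n for c in FEATURE_CATEGORIES}
    return categories, fractions


@dataclass
class DomainAllocation:
    """Observed vs expected chromatin-color allocation of a target gene set.

    ``table`` has one row per color: observed_count, observed_proportion,
    expected_proportion (whole-genome gene proportions), ratio =
    observed/expected, and the add-one permutation p-value for
    enrichment.
    """

    table: pd.DataFrame
    n_targets: int
    n_resamples: int
    seed: int


def gene_colors(genes: Sequence[GeneModel], domains: IntervalSet) -> pd.Series:
    """Assign each gene the color covering the largest share of its span.

    Ties break toward the color sorted first, deterministically.
    """
    norm = domains.normalize()
    by_chrom = {
        c: (
            norm.df[norm.df["chrom"] == c]["start"].to_numpy(np.int64),
            norm.df[norm.df["chrom"] == c]["end"].to_numpy(np.int64),
            norm.df[norm.df["chrom"] == c]["label"].to_numpy(object),
        )
        for c in norm.chroms()
    }
    out = {}
    for g in genes:
        arr = by_chrom.get(g.chrom)
        if arr is None:
            raise ValidationError(f"gene {g.gene_id}: no domains on chromosome {g.chrom}")
        starts, ends, labels = arr
        ov = np.minimum(ends, g.end) - np.maximum(starts, g.start)
        hit = ov > 0
        if not hit.any():
            raise ValidationError(f"gene {g.gene_id} not assignable to any domain")
        cover: dict[str, int] = {}
        for lab, o in zip(labels[hit], ov[hit]):
            cover[lab] = cover.get(lab, 0) + int(o)
        best = max(sorted(cover), key=lambda lab: cover[lab])
        out[g.gene_id] = best
    return pd.Series(out, name="color")


def domain_allocation(
    target_genes: set[str],
    all_genes: Sequence[GeneModel],
    domains: IntervalSet,
    n_resamples: int = 1000,
    seed: int = 0,
) -> DomainAllocation:
    """Observed/expected chromatin-color allocation with a permutation test.

    The null resamples ``len(target_genes)`` genes uniformly without
    replacement from all genes ``n_resamples`` times; the per-color
    p-value is (1 + #{resamples with count >= observed}) / (n_resamples + 1).
    """
    if not target_genes:
        raise ValidationError("empty target gene set")
    colors = gene_colors(all_genes, domains)
    unknown = target_genes - set(colors.index)
    if unknown:
        raise ValidationError(f"target genes not in gene list: {sorted(unknown)[:5]}")
    palette = sorted(colors.unique())
    color_arr = colors.to_numpy(object)
    ids = colors.index.to_numpy(object)
    target_mask = np.isin(ids, sorted(target_genes))
    n_t = int(target_mask.sum())

    observed = {c: int((color_arr[target_mask] == c).sum()) for c in palette}
    expected_prop = {c: float((color_arr == c).mean()) for c in palette}

    rng = stage_rng(seed, "domain-allocation")
    null_counts = np.zeros((n_resamples, len(palette)), dtype=np.int64)
    n_all = len(ids)
    for r in range(n_resamples):
        pick = rng.choice(n_all, size=n_t, replace=False)
        sub = color_arr[pick]
        for j, c in enumerate(palette):
            null_counts[r, j] = (sub == c).sum()

    rows = []
    for j, c in enumerate(palette):
        obs = observed[c]
        obs_prop = obs / n_t
        exp = expected_prop[c]
        ratio = obs_prop / exp if exp > 0 else np.nan
        p = (1 + int((null_counts[:, j] >= obs).sum())) / (n_resamples + 1)
        rows.append((c, obs, obs_prop, exp, ratio, p))
    table = pd.DataFrame(
        rows,
        columns=[
            "color",
            "observed_count",
            "observed_proportion",
            "expected_proportion",
            "ratio",
            "permutation_p",
        ],
    )
    return DomainAllocation(table=table, n_targets=n_t, n_resamples=n_resamples, seed=seed)
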