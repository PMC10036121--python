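"""Seeded generators for synthetic DamID study data with known ground truth.

The generators emulate the statistical structure the downstream analysis
assumes: a multi-chromosome genome carrying a GATC fragment lattice,
non-overlapping stranded gene models, a five-color chromatin-domain
tiling, replicate Dam-fusion / Dam-only fragment counts with planted
enriched regions, motif-hit intervals with controllable TSS-proximal
enrichment in a designated target gene set, and paired baseline/treatment
differential-expression tables with known rescue labels.

Every generator is a pure function of its configuration and seed; RNG
streams are derived per stage from the master seed by stable labels so
adding a stage never perturbs earlier stages' draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    FragmentTrack,
    GeneModel,
    GenomeModel,
    IntervalSet,
    ValidationError,
    genes_to_frame,
)

CHROMATIN_COLORS = ("BLACK", "GREEN", "BLUE", "YELLOW", "RED")

RESCUE_LABELS = ("reverted", "restored", "still_changed", "unchanged")


def stage_rng(seed: int, label: str) -> np.random.Generator:
    """A reproducible RNG stream for one pipeline stage.

    Derived from (seed, crc32(label)) so streams for different stages are
    independent and adding stages never shifts existing draws.
    """
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode())])


@dataclass
class SimConfig:
    """Study conditions for the synthetic generators.

    Defaults describe a desk-scale fly-like setup: three 1-Mbp
    chromosomes with GATC sites at ~1/256 bp, three replicates per Dam
    construct at an expected ~20 counts per fragment, fourfold Dam-fusion
    enrichment inside planted peaks, motif hits of 10 bp at a background
    rate of 1/2000 bp with tenfold enrichment in the 500 bp upstream of
    target-gene TSSs, and DE effects of at least 1.5 (log2) with
    per-gene standard errors of 0.05-0.15.
    """

    seed: int = 0
    # genome
    n_chroms: int = 3
    chrom_length: int = 1_000_000
    gatc_rate: float = 1.0 / 256.0
    # genes
    n_genes: int = 300
    gene_mean_length: float = 3000.0
    gene_sigma_log: float = 0.4
    # domains
    domain_mean_length: float = 20_000.0
    # DamID counts
    n_replicates: int = 3
    sequencing_depth: int = 240_000  # reads per sample (~20 per fragment on 3 Mbp)
    read_extension: int = 300  # reads this far upstream still hit a fragment
    peak_enrichment: float = 4.0
    nb_dispersion: float = 0.02
    n_peaks: int = 40
    peak_mean_fragments: int = 10
    # motifs
    motif_background_rate: float = 1.0 / 2000.0  # hits per bp
    motif_width: int = 10
    motif_tss_enrichment: float = 10.0
    tss_window: int = 500
    # DE tables
    n_genes_de: int = 2000
    n_de: int = 300
    effect_min: float = 1.5
    effect_max: float = 3.0
    se_min: float = 0.05
    se_max: float = 0.15
    frac_reverted: float = 0.3
    frac_restored: float = 0.3

    def __post_init__(self) -> None:
        if self.gatc_rate <= 0 or self.motif_background_rate <= 0:
            raise ValidationError("rates must be positive")
        if self.peak_enrichment <= 0 or self.motif_tss_enrichment <= 0:
            raise ValidationError("enrichment folds must be positive")
        if self.frac_reverted + self.frac_restored > 1:
            raise ValidationError("rescue fractions must sum to at most 1")
        if self.sequencing_depth <= 0:
            raise ValidationError("sequencing depth must be positive")


@dataclass
class SimTruth:
    """Ground truth recorded by the generators for parameter-recovery tests."""

    planted_peaks: Optional[IntervalSet] = None
    target_genes: set[str] = field(default_factory=set)
    de_truth: Optional[pd.DataFrame] = None


# -- genome -----------------------------------------------------------------


def make_genome(cfg: SimConfig) -> GenomeModel:
    """Draw GATC sites as a homogeneous point process with 4-bp hard-core spacing.

    Successive gaps are 4 + Exponential(1/gatc_rate) bp, which keeps the
    empirical rate within a few percent of ``gatc_rate`` at fly-like
    densities while guaranteeing the minimum motif spacing.
    """
    rng = stage_rng(cfg.seed, "genome")
    L = int(cfg.chrom_length)
    if L < 8:
        raise ValidationError(f"chromosome length {L} too short to host a GATC site")
    chroms = {f"chr{i + 1}": L for i in range(cfg.n_chroms)}
    sites: dict[str, np.ndarray] = {}
    mean_gap = 1.0 / cfg.gatc_rate
    for c in chroms:
        est = int(L / (mean_gap + 4) * 1.3) + 16
        gaps = 4.0 + rng.exponential(mean_gap, size=est)
        pos = np.floor(np.cumsum(gaps)).astype(np.int64)
        while pos.size and pos[-1] <= L - 4:
            extra = np.floor(pos[-1] + np.cumsum(4.0 + rng.exponential(mean_gap, size=16)))
            pos = np.concatenate([pos, extra.astype(np.int64)])
        pos = pos[pos <= L - 4]
        if pos.size == 0:
            raise ValidationError(f"chromosome {c} too short to host any GATC site")
        sites[c] = pos
    return GenomeModel(chroms, sites)


# -- genes ------------------------------------------------------------------


def _place_nonoverlapping(
    rng: np.random.Generator, lengths: np.ndarray, chrom_length: int
) -> np.ndarray:
    """Place intervals of the given lengths uniformly without overlap.

    Sequential-gap construction: positions are drawn in the space reduced
    by the total interval length, sorted, and intervals are laid down in a
    random order.  Exact (no rejection) and uniform for each interval.
    """
    n = len(lengths)
    total = int(lengths.sum())
    slack = chrom_length - total
    if slack < 0:
        raise ValidationError(
            f"cannot place {n} intervals totalling {total} bp on a "
            f"{chrom_length} bp chromosome without overlap"
        )
    order = rng.permutation(n)
    anchors = np.sort(rng.integers(0, slack + 1, size=n))
    starts = np.empty(n, dtype=np.int64)
    cum = 0
    for k in range(n):
        i = order[k]
        starts[i] = anchors[k] + cum
        cum += lengths[i]
    return starts


def make_genes(genome: GenomeModel, cfg: SimConfig) -> list[GeneModel]:
    """Place non-overlapping stranded genes uniformly across the genome."""
    rng = stage_rng(cfg.seed, "genes")
    chroms = list(genome.chromosomes)
    lens = np.array([genome.chromosomes[c] for c in chroms], dtype=float)
    assignment = rng.choice(len(chroms), size=cfg.n_genes, p=lens / lens.sum())
    mu = np.log(cfg.gene_mean_length) - cfg.gene_sigma_log**2 / 2
    lengths = np.maximum(
        200, rng.lognormal(mu, cfg.gene_sigma_log, size=cfg.n_genes)
    ).astype(np.int64)
    strands = np.where(rng.random(cfg.n_genes) < 0.5, "+", "-")
    genes: list[GeneModel] = []
    for ci, c in enumerate(chroms):
        idx = np.flatnonzero(assignment == ci)
        if idx.size == 0:
            continue
        starts = _place_nonoverlapping(rng, lengths[idx], genome.chromosomes[c])
        for j, i in enumerate(idx):
            genes.append(
                GeneModel(
                    f"g{i + 1:05d}", c, int(starts[j]), int(starts[j] + lengths[i]), strands[i]
                )
            )
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


# -- chromatin domains --------------------------------------------------------


def make_domains(
    genome: GenomeModel,
    colors: Sequence[str] = CHROMATIN_COLORS,
    mean_len: float = 20_000.0,
    seed: int = 0,
) -> IntervalSet:
    """Tile every chromosome with alternating exponential-length colored blocks.

    Consecutive blocks always differ in color; each color is marginally
    uniform.  The tiling is exact (no gaps or overlaps).
    """
    if len(colors) < 2:
        raise ValidationError("need at least two domain colors")
    rng = stage_rng(seed, "domains")
    rows = []
    colors = list(colors)
    for c, L in genome.chromosomes.items():
        pos = 0
        prev = None
        while pos < L:
            block = max(1, int(round(rng.exponential(mean_len))))
            end = min(L, pos + block)
            choices = [col for col in colors if col != prev]
            color = choices[rng.integers(0, len(choices))]
            rows.append((c, pos, end, color))
            prev = color
            pos = end
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    return IntervalSet(df, sorted=True)


# -- DamID counts -------------------------------------------------------------


def make_planted_peaks(genome: GenomeModel, cfg: SimConfig) -> IntervalSet:
    """Plant non-overlapping true enriched regions aligned to fragment boundaries.

    Each planted region spans roughly ``peak_mean_fragments`` consecutive
    GATC fragments; regions are spread across chromosomes in proportion
    to their fragment counts.
    """
    rng = stage_rng(cfg.seed, "planted-peaks")
    chroms = list(genome.chromosomes)
    nfr = np.array([genome.n_fragments_chrom(c) for c in chroms], dtype=float)
    assignment = rng.choice(len(chroms), size=cfg.n_peaks, p=nfr / nfr.sum())
    rows = []
    for ci, c in enumerate(chroms):
        n_here = int((assignment == ci).sum())
        if n_here == 0:
            continue
        nf = genome.n_fragments_chrom(c)
        widths = np.maximum(
            2, rng.poisson(cfg.peak_mean_fragments, size=n_here)
        ).astype(np.int64)
        # place peak fragment-index spans without overlap via the gap trick
        starts_idx = _place_nonoverlapping(rng, widths, nf)
        b = genome.fragment_boundaries(c)
        for s, w in zip(starts_idx, widths):
            rows.append((c, int(b[s]), int(b[s + w])))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return IntervalSet(df).normalize()


def _fragment_in_planted(genome: GenomeModel, planted: IntervalSet) -> np.ndarray:
    """Boolean mask over genome fragments: fragment midpoint inside a planted region."""
    mask = np.zeros(genome.n_fragments, dtype=bool)
    for c in genome.chromosomes:
        starts, ends = planted.normalize().arrays(c)
        if starts.size == 0:
            continue
        mids = (genome.fragment_starts(c) + genome.fragment_ends(c)) // 2
        k = np.searchsorted(ends, mids, side="right")
        inside = (k < starts.size) & (starts[np.minimum(k, starts.size - 1)] <= mids)
        off = genome.fragment_offset(c)
        mask[off : off + mids.size] = inside
    return mask


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2 (Poisson when 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_damid_counts(
    genome: GenomeModel,
    planted: IntervalSet,
    cfg: SimConfig,
) -> tuple[list[FragmentTrack], list[FragmentTrack], SimTruth]:
    """Replicate Dam-fusion and Dam-only fragment counts with planted enrichment.

    Per replicate, counts are negative binomial with mean proportional to
    (fragment length + read_extension) times sequencing depth — extended
    reads give even short GATC fragments substantial coverage, as in real
    DamID read processing.  The fusion mean is multiplied by
    ``peak_enrichment`` inside planted fragments.  Replicates are
    independent.
    """
    planted.validate(genome)
    rng = stage_rng(cfg.seed, "damid-counts")
    eff_len = genome.fragment_lengths().astype(float) + cfg.read_extension
    base_mean = cfg.sequencing_depth * eff_len / eff_len.sum()
    inside = _fragment_in_planted(genome, planted)
    fusion_mean = base_mean * np.where(inside, cfg.peak_enrichment, 1.0)
    fusion, dam = [], []
    for _ in range(cfg.n_replicates):
        fusion.append(FragmentTrack(genome, _nb_draw(rng, fusion_mean, cfg.nb_dispersion), "count"))
        dam.append(FragmentTrack(genome, _nb_draw(rng, base_mean, cfg.nb_dispersion), "count"))
    return fusion, dam, SimTruth(planted_peaks=planted)


# -- motif hits ----------------------------------------------------------------


def plant_motifs(
    genome: GenomeModel,
    genes: Sequence[GeneModel],
    target_genes: set[str],
    cfg: SimConfig,
) -> tuple[IntervalSet, SimTruth]:
    """Background motif hits plus TSS-proximal enrichment in target genes.

    Background hits (width ``motif_width``) fall uniformly at
    ``motif_background_rate`` per bp genome-wide.  Additional hits at
    ``(motif_tss_enrichment - 1) x background`` rate fall in the
    strand-aware ``tss_window`` bp immediately upstream of each target
    gene's TSS, so total density there is ``motif_tss_enrichment``-fold
    the background.  Hits are clipped to chromosome bounds.
    """
    known = {g.gene_id for g in genes}
    if not target_genes <= known:
        raise ValidationError("target_genes must be a subset of the gene list")
    rng = stage_rng(cfg.seed, "motifs")
    w = int(cfg.motif_width)
    rows: list[tuple[str, int, int]] = []
    for c, L in genome.chromosomes.items():
        n_bg = rng.poisson(cfg.motif_background_rate * L)
        starts = rng.integers(0, L, size=n_bg)
        for s in starts:
            rows.append((c, int(s), int(min(L, s + w))))
    extra_rate = (cfg.motif_tss_enrichment - 1.0) * cfg.motif_background_rate
    if extra_rate > 0:
        for g in genes:
            if g.gene_id not in target_genes:
                continue
            L = genome.chromosomes[g.chrom]
            if g.strand == "+":
                lo, hi = g.tss - cfg.tss_window, g.tss
            else:
                lo, hi = g.tss + 1, g.tss + 1 + cfg.tss_window
            lo, hi = max(0, lo), min(L, hi)
            if hi <= lo:
                continue
            n_extra = rng.poisson(extra_rate * (hi - lo))
            for s in rng.integers(lo, hi, size=n_extra):
                rows.append((g.chrom, int(s), int(min(L, s + w))))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    hits = IntervalSet(df).normalize()
    return hits, SimTruth(target_genes=set(target_genes))


# -- DE tables -----------------------------------------------------------------


def simulate_de_table(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Paired baseline/treatment DE tables with known rescue labels.

    Baseline true log2 fold changes are 0 for non-DE genes and drawn from
    a signed uniform effect distribution for ``n_de`` genes.  Under
    treatment the true effect becomes 0 for *restored* genes, flips sign
    for *reverted* genes, and is unchanged for *still_changed* genes.
    Observed l2fc = true + Normal(0, SE) with per-gene SE drawn from the
    SE distribution; the Wald p-value is plumbing computed from z.
    """
    from .equivalence import wald_p

    rng = stage_rng(cfg.seed, "de-table")
    n, n_de = cfg.n_genes_de, cfg.n_de
    if n_de > n:
        raise ValidationError("n_de exceeds number of genes")
    gene_ids = [f"g{i + 1:05d}" for i in range(n)]
    true_base = np.zeros(n)
    de_idx = rng.choice(n, size=n_de, replace=False)
    magnitudes = rng.uniform(cfg.effect_min, cfg.effect_max, size=n_de)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    true_base[de_idx] = magnitudes * signs

    labels = np.array(["unchanged"] * n, dtype=object)
    n_rev = int(round(cfg.frac_reverted * n_de))
    n_res = int(round(cfg.frac_restored * n_de))
    shuffled = rng.permutation(de_idx)
    labels[shuffled[:n_rev]] = "reverted"
    labels[shuffled[n_rev : n_rev + n_res]] = "restored"
    labels[shuffled[n_rev + n_res :]] = "still_changed"

    true_treat = true_base.copy()
    true_treat[labels == "reverted"] *= -1.0
    true_treat[labels == "restored"] = 0.0

    def observe(true_l2fc: np.ndarray, stream: str) -> pd.DataFrame:
        r = stage_rng(cfg.seed, stream)
        se = r.uniform(cfg.se_min, cfg.se_max, size=n)
        obs = true_l2fc + r.normal(0.0, 1.0, size=n) * se
        return pd.DataFrame(
            {
                "gene_id": gene_ids,
                "log2FoldChange": obs,
                "lfcSE": se,
                "pvalue": wald_p(obs, se),
            }
        )

    baseline = observe(true_base, "de-observe-baseline")
    treatment = observe(true_treat, "de-observe-treatment")
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "true_l2fc_baseline": true_base,
            "true_l2fc_treatment": true_treat,
            "label": labels,
        }
    )
    return baseline, treatment, SimTruth(de_truth=truth)


def pick_target_genes(genes: Sequence[GeneModel], n_targets: int, seed: int) -> set[str]:
    """Choose a uniform random target-gene subset (stage 'targets')."""
    rng = stage_rng(seed, "targets")
    ids = [g.gene_id for g in genes]
    if n_targets > len(ids):
        raise ValidationError("more targets requested than genes available")
    chosen = rng.choice(len(ids), size=n_targets, replace=False)
    return {ids[i] for i in chosen}
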