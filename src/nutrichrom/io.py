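"""Readers and writers for the plain-text genomic formats the pipeline consumes.

Formats: UCSC chrom.sizes (two-column TSV), BED3/BED6 (0-based half-open),
bedGraph fragment tracks, GFF3 or BED6 gene models, and DESeq2-style
differential-expression TSV tables (gene_id, log2FoldChange, lfcSE, pvalue).
"""

from __future__ import annotations

import os
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    FragmentTrack,
    GeneModel,
    GenomeModel,
    Interval,
    IntervalSet,
    ValidationError,
)


class ParseError(ValueError):
    """Raised for malformed input files; names the offending line."""


# bedGraph values are written with 6 significant digits.
_BG_FMT = "%.6g"


def read_chrom_sizes(path: str) -> dict[str, int]:
    """Read a UCSC-style chrom.sizes file (name, length)."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{i}: expected two tab-separated columns")
            try:
                sizes[parts[0]] = int(parts[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{i}: bad length {parts[1]!r}") from exc
    return sizes


def read_gatc_bed(path: str) -> dict[str, np.ndarray]:
    """Read GATC motif positions from a BED file of 4-bp motif intervals."""
    sites: dict[str, list[int]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            try:
                sites.setdefault(parts[0], []).append(int(parts[1]))
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}:{i}: malformed BED line") from exc
    return {c: np.asarray(sorted(v), dtype=np.int64) for c, v in sites.items()}


def read_genome(chrom_sizes_path: str, gatc_bed_path: str) -> GenomeModel:
    return GenomeModel(read_chrom_sizes(chrom_sizes_path), read_gatc_bed(gatc_bed_path))


def write_genome(genome: GenomeModel, chrom_sizes_path: str, gatc_bed_path: str) -> None:
    with open(chrom_sizes_path, "w") as fh:
        for c, n in genome.chromosomes.items():
            fh.write(f"{c}\t{n}\n")
    with open(gatc_bed_path, "w") as fh:
        for c in genome.chromosomes:
            for p in genome.gatc_sites[c]:
                fh.write(f"{c}\t{p}\t{p + 4}\tGATC\n")


# -- BED ------------------------------------------------------------------


def read_bed(path: str, genome: Optional[GenomeModel] = None) -> IntervalSet:
    """Read a 3+ column BED file into a sorted, validated IntervalSet.

    Column 4 is kept as the label, column 5 as the score, column 6 as the
    strand, when present.
    """
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{i}: BED line has fewer than 3 columns")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{i}: non-integer coordinates") from exc
            label = parts[3] if len(parts) > 3 and parts[3] != "." else None
            score = None
            if len(parts) > 4 and parts[4] not in (".", ""):
                try:
                    score = float(parts[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{i}: bad score {parts[4]!r}") from exc
            strand = parts[5] if len(parts) > 5 else None
            if start < 0 or start >= end:
                raise ParseError(f"{path}:{i}: invalid interval {chrom}:{start}-{end}")
            rows.append((chrom, start, end, score, label, strand))
    ivs = IntervalSet(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "score", "label", "strand"])
    ).normalize()
    if genome is not None:
        ivs.validate(genome)
    return ivs


def write_bed(intervals: IntervalSet, path: str) -> None:
    """Write BED6 when any annotation is present, BED3 otherwise."""
    df = intervals.df
    bare = df["score"].isna().all() and df["label"].isna().all() and df["strand"].isna().all()
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            if bare:
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\n")
            else:
                label = row.label if isinstance(row.label, str) else "."
                score = _BG_FMT % row.score if pd.notna(row.score) else "."
                strand = row.strand if isinstance(row.strand, str) else "."
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{label}\t{score}\t{strand}\n")


# -- gene models -----------------------------------------------------------


def read_genes(path: str, genome: Optional[GenomeModel] = None, dialect: str = "gff3") -> list[GeneModel]:
    """Read gene models from GFF3 (``gene`` features) or BED6.

    GFF3 coordinates are 1-based closed and converted to 0-based
    half-open at the boundary; BED is native.  Genes without a strand are
    rejected: the TSS is undefined.
    """
    genes: list[GeneModel] = []
    if dialect == "gff3":
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 9:
                    raise ParseError(f"{path}:{i}: GFF3 line does not have 9 columns")
                if parts[2] != "gene":
                    continue
                chrom, start1, end1, strand = parts[0], parts[3], parts[4], parts[6]
                if strand not in ("+", "-"):
                    raise ParseError(f"{path}:{i}: gene lacks a strand; TSS undefined")
                attrs = dict(
                    kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
                )
                gene_id = attrs.get("ID") or attrs.get("gene_id")
                if gene_id is None:
                    raise ParseError(f"{path}:{i}: gene feature lacks an ID attribute")
                try:
                    start, end = int(start1) - 1, int(end1)
                except ValueError as exc:
                    raise ParseError(f"{path}:{i}: non-integer coordinates") from exc
                genes.append(GeneModel(gene_id, chrom, start, end, strand))
    elif dialect == "bed6":
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track")):
                    continue
                parts = line.split("\t")
                if len(parts) < 6:
                    raise ParseError(f"{path}:{i}: BED6 line has fewer than 6 columns")
                strand = parts[5]
                if strand not in ("+", "-"):
                    raise ParseError(f"{path}:{i}: gene lacks a strand; TSS undefined")
                genes.append(
                    GeneModel(parts[3], parts[0], int(parts[1]), int(parts[2]), strand)
                )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if genome is not None:
        for g in genes:
            if g.chrom not in genome.chromosomes or g.end > genome.chromosomes[g.chrom]:
                raise ValidationError(f"gene {g.gene_id} outside genome bounds")
    return genes


def write_genes_gff3(genes: Sequence[GeneModel], path: str, source: str = "nutrichrom") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


# -- bedGraph fragment tracks ----------------------------------------------


def write_bedgraph(track: FragmentTrack, path: str, merge_equal: bool = False) -> None:
    """Write one bedGraph record per fragment.

    With ``merge_equal`` adjacent equal-valued fragments are run-length
    merged; the default keeps one record per fragment for bit-exact
    round-trips.
    """
    genome = track.genome
    with open(path, "w") as fh:
        fh.write('track type=bedGraph\n')
        for chrom in genome.chromosomes:
            starts = genome.fragment_starts(chrom)
            ends = genome.fragment_ends(chrom)
            vals = track.chrom_values(chrom)
            i = 0
            n = len(vals)
            while i < n:
                j = i + 1
                if merge_equal:
                    while j < n and vals[j] == vals[i]:
                        j += 1
                fh.write(f"{chrom}\t{starts[i]}\t{ends[j - 1]}\t{_BG_FMT % vals[i]}\n")
                i = j


def read_bedgraph(path: str, genome: GenomeModel, kind: str) -> FragmentTrack:
    """Read a bedGraph written on the genome's fragment lattice.

    Records must align to fragment boundaries; run-length merged records
    are expanded back to fragments.
    """
    values = np.zeros(genome.n_fragments, dtype=np.float64)
    seen = np.zeros(genome.n_fragments, dtype=bool)
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{i}: bedGraph line has fewer than 4 columns")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if chrom not in genome.chromosomes:
                raise ParseError(f"{path}:{i}: unknown chromosome {chrom!r}")
            b = genome.fragment_boundaries(chrom)
            i0 = int(np.searchsorted(b, start))
            i1 = int(np.searchsorted(b, end))
            if i0 >= len(b) or b[i0] != start or i1 >= len(b) or b[i1] != end:
                raise ParseError(
                    f"{path}:{i}: record {chrom}:{start}-{end} not aligned to GATC fragments"
                )
            off = genome.fragment_offset(chrom)
            values[off + i0 : off + i1] = value
            seen[off + i0 : off + i1] = True
    return FragmentTrack(genome, values, kind)


# -- DE tables --------------------------------------------------------------

DE_COLUMNS = ["gene_id", "log2FoldChange", "lfcSE", "pvalue"]


def read_de_table(path: str) -> pd.DataFrame:
    """Read a DESeq2-style results TSV; extra columns are ignored."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return df[DE_COLUMNS].copy()


def write_de_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
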