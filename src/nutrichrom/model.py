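"""Core genomic data model for GATC-fragment-resolution DamID analysis.

All coordinates are 0-based, half-open, on a fixed :class:`GenomeModel`.
The native resolution unit of DamID signal is the *GATC fragment*: the
interval between consecutive GATC motif starts.  Fragments are cut at
motif starts, so the 4-bp motif belongs to the downstream fragment and
fragments exactly tile each chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an object violates the genomic data model invariants."""


GATC_LEN = 4

#: Track kinds a FragmentTrack may carry.
TRACK_KINDS = ("count", "coverage", "log2ratio")


class GenomeModel:
    """Chromosome lengths plus GATC site positions defining the fragment lattice.

    Parameters
    ----------
    chromosomes
        Ordered mapping of chromosome name to length in bp.
    gatc_sites
        Per-chromosome sorted array of GATC motif start positions
        (0-based).  Every position ``p`` must satisfy
        ``0 <= p <= length - 4`` and positions must be strictly
        increasing within a chromosome.
    """

    def __init__(
        self,
        chromosomes: Mapping[str, int],
        gatc_sites: Mapping[str, Sequence[int]],
    ) -> None:
        self.chromosomes: dict[str, int] = {str(c): int(n) for c, n in chromosomes.items()}
        if not self.chromosomes:
            raise ValidationError("genome must have at least one chromosome")
        for c, n in self.chromosomes.items():
            if n <= 0:
                raise ValidationError(f"chromosome {c} has non-positive length {n}")
        unknown = set(gatc_sites) - set(self.chromosomes)
        if unknown:
            raise ValidationError(f"GATC sites given for unknown chromosomes: {sorted(unknown)}")
        self.gatc_sites: dict[str, np.ndarray] = {}
        for c in self.chromosomes:
            sites = np.asarray(gatc_sites.get(c, ()), dtype=np.int64)
            length = self.chromosomes[c]
            if sites.size:
                if np.any(np.diff(sites) <= 0):
                    raise ValidationError(f"GATC positions not strictly increasing on {c}")
                if sites[0] < 0 or sites[-1] > length - GATC_LEN:
                    raise ValidationError(
                        f"GATC position out of range on {c} (length {length})"
                    )
            self.gatc_sites[c] = sites

        # Fragment lattice: boundaries at chromosome start, each GATC start,
        # and chromosome end (deduplicated when a site sits at position 0).
        self._boundaries: dict[str, np.ndarray] = {}
        self._offsets: dict[str, int] = {}
        offset = 0
        for c, length in self.chromosomes.items():
            sites = self.gatc_sites[c]
            b = np.concatenate(([0], sites, [length]))
            b = np.unique(b)
            self._boundaries[c] = b
            self._offsets[c] = offset
            offset += len(b) - 1
        self._n_fragments = offset

    # -- fragment lattice ------------------------------------------------

    @property
    def n_fragments(self) -> int:
        """Total number of GATC fragments across all chromosomes."""
        return self._n_fragments

    def fragment_boundaries(self, chrom: str) -> np.ndarray:
        """Sorted fragment boundary positions on ``chrom`` (0 and length included)."""
        return self._boundaries[chrom]

    def fragment_offset(self, chrom: str) -> int:
        """Index of the first fragment of ``chrom`` in genome fragment order."""
        return self._offsets[chrom]

    def n_fragments_chrom(self, chrom: str) -> int:
        return len(self._boundaries[chrom]) - 1

    def fragment_starts(self, chrom: str) -> np.ndarray:
        return self._boundaries[chrom][:-1]

    def fragment_ends(self, chrom: str) -> np.ndarray:
        return self._boundaries[chrom][1:]

    def fragment_lengths(self, chrom: Optional[str] = None) -> np.ndarray:
        """Fragment lengths, per chromosome or genome-wide in fragment order."""
        if chrom is not None:
            return np.diff(self._boundaries[chrom])
        return np.concatenate([np.diff(self._boundaries[c]) for c in self.chromosomes])

    @property
    def total_length(self) -> int:
        return sum(self.chromosomes.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromosomes

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeModel):
            return NotImplemented
        return self.chromosomes == other.chromosomes and all(
            np.array_equal(self.gatc_sites[c], other.gatc_sites[c]) for c in self.chromosomes
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"GenomeModel({len(self.chromosomes)} chromosomes, "
            f"{self.total_length} bp, {self.n_fragments} fragments)"
        )


@dataclass(frozen=True)
class Interval:
    """A genomic interval, 0-based half-open, with optional annotations."""

    chrom: str
    start: int
    end: int
    score: Optional[float] = None
    label: Optional[str] = None
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )
        if self.strand not in (None, "+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


_IVSET_COLUMNS = ["chrom", "start", "end", "score", "label", "strand"]


class IntervalSet:
    """A collection of genomic intervals backed by a pandas DataFrame.

    Rows carry chrom/start/end plus optional score, label (e.g. chromatin
    color or motif name) and strand.  ``normalize()`` sorts rows by
    (chrom, start, end); sorting is stable and idempotent.
    """

    def __init__(self, df: Optional[pd.DataFrame] = None, *, sorted: bool = False) -> None:
        if df is None:
            df = pd.DataFrame({c: [] for c in _IVSET_COLUMNS})
        df = df.copy()
        for col in _IVSET_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan if col == "score" else None
        df = df[_IVSET_COLUMNS].reset_index(drop=True)
        df["chrom"] = df["chrom"].astype(str) if len(df) else df["chrom"]
        df["start"] = df["start"].astype(np.int64) if len(df) else df["start"]
        df["end"] = df["end"].astype(np.int64) if len(df) else df["end"]
        self.df = df
        self.is_sorted = bool(sorted)

    # -- construction ----------------------------------------------------

    @classmethod
    def from_intervals(cls, intervals: Iterable[Interval]) -> "IntervalSet":
        rows = [
            (iv.chrom, iv.start, iv.end, iv.score, iv.label, iv.strand) for iv in intervals
        ]
        df = pd.DataFrame(rows, columns=_IVSET_COLUMNS)
        return cls(df)

    @classmethod
    def from_arrays(
        cls,
        chrom: Sequence[str],
        start: Sequence[int],
        end: Sequence[int],
        score: Optional[Sequence[float]] = None,
        label: Optional[Sequence[str]] = None,
        strand: Optional[Sequence[str]] = None,
    ) -> "IntervalSet":
        df = pd.DataFrame({"chrom": list(chrom), "start": start, "end": end})
        if score is not None:
            df["score"] = score
        if label is not None:
            df["label"] = label
        if strand is not None:
            df["strand"] = strand
        return cls(df)

    # -- basics ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[Interval]:
        for row in self.df.itertuples(index=False):
            yield Interval(
                row.chrom,
                int(row.start),
                int(row.end),
                None if pd.isna(row.score) else float(row.score),
                None if row.label is None or (isinstance(row.label, float) and np.isnan(row.label)) else row.label,
                None if row.strand is None or (isinstance(row.strand, float) and np.isnan(row.strand)) else row.strand,
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        a, b = self.df, other.df
        if len(a) != len(b):
            return False
        return all(
            list(a[c].fillna("__na__") if c in ("label", "strand") else a[c])
            == list(b[c].fillna("__na__") if c in ("label", "strand") else b[c])
            for c in _IVSET_COLUMNS
            if c != "score"
        ) and np.allclose(
            a["score"].fillna(np.inf), b["score"].fillna(np.inf), equal_nan=True
        )

    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) for one chromosome, in current row order."""
        sub = self.df[self.df["chrom"] == chrom]
        return sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64)

    def total_bp(self) -> int:
        """Sum of interval lengths (overlaps counted multiply)."""
        return int((self.df["end"] - self.df["start"]).sum())

    # -- normalization & validation ---------------------------------------

    def normalize(self) -> "IntervalSet":
        """Return a copy sorted by (chrom, start, end); stable and idempotent."""
        df = self.df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
        return IntervalSet(df, sorted=True)

    def validate(self, genome: GenomeModel) -> "IntervalSet":
        for row in self.df.itertuples():
            if row.chrom not in genome.chromosomes:
                raise ValidationError(f"interval on unknown chromosome {row.chrom!r}")
            length = genome.chromosomes[row.chrom]
            if not (0 <= row.start < row.end <= length):
                raise ValidationError(
                    f"interval {row.chrom}:{row.start}-{row.end} outside chromosome "
                    f"bounds [0, {length})"
                )
        return self

    def subset(self, mask) -> "IntervalSet":
        return IntervalSet(self.df[mask].reset_index(drop=True), sorted=self.is_sorted)


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene span with its derived transcription start site.

    The TSS is the strand-aware start of the span: ``start`` on the
    plus strand and ``end - 1`` on the minus strand.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"gene {self.gene_id}: start >= end")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or - (TSS undefined)")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


def genes_to_frame(genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Tabulate genes (gene_id, chrom, start, end, strand, tss)."""
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "start": np.array([g.start for g in genes], dtype=np.int64),
            "end": np.array([g.end for g in genes], dtype=np.int64),
            "strand": [g.strand for g in genes],
            "tss": np.array([g.tss for g in genes], dtype=np.int64),
        }
    )


class FragmentTrack:
    """One real value per GATC fragment, in genome fragment order.

    ``kind`` is one of ``count`` (non-negative integers), ``coverage``
    (1x-normalized density) or ``log2ratio``.
    """

    def __init__(self, genome: GenomeModel, values: Sequence[float], kind: str) -> None:
        if kind not in TRACK_KINDS:
            raise ValidationError(f"unknown track kind {kind!r}")
        values = np.asarray(values, dtype=np.float64)
        if values.shape != (genome.n_fragments,):
            raise ValidationError(
                f"track has {values.size} values but genome has {genome.n_fragments} fragments"
            )
        if kind == "count":
            if np.any(values < 0) or np.any(values != np.floor(values)):
                raise ValidationError("count track values must be non-negative integers")
        self.genome = genome
        self.values = values
        self.kind = kind

    def chrom_values(self, chrom: str) -> np.ndarray:
        off = self.genome.fragment_offset(chrom)
        return self.values[off : off + self.genome.n_fragments_chrom(chrom)]

    def with_values(self, values: Sequence[float], kind: Optional[str] = None) -> "FragmentTrack":
        return FragmentTrack(self.genome, values, kind or self.kind)

    def __len__(self) -> int:
        return self.values.size
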