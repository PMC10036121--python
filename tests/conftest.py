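import numpy as np
import pytest

from nutrichrom import FragmentTrack, GenomeModel, IntervalSet


@pytest.fixture
def tiny_genome() -> GenomeModel:
    """100-bp chromosome with GATC sites at 20, 50, 70 -> 4 fragments."""
    return GenomeModel({"chr1": 100}, {"chr1": [20, 50, 70]})


@pytest.fixture
def two_chrom_genome() -> GenomeModel:
    return GenomeModel(
        {"chr1": 1000, "chr2": 500},
        {"chr1": [100, 300, 600, 900], "chr2": [50, 200]},
    )


@pytest.fixture
def bare_genome() -> GenomeModel:
    """Two chromosomes without GATC sites (interval work only)."""
    return GenomeModel({"chr1": 1000, "chr2": 500}, {})


def make_track(genome: GenomeModel, values, kind="count") -> FragmentTrack:
    return FragmentTrack(genome, np.asarray(values, dtype=float), kind)


def ivset(*triples) -> IntervalSet:
    chroms = [t[0] for t in triples]
    starts = [t[1] for t in triples]
    ends = [t[2] for t in triples]
    return IntervalSet.from_arrays(chroms, starts, ends)
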