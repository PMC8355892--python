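import numpy as np
import pytest

from scna_atlas.classify import ClassificationParams
from scna_atlas.genome import ArmInterval, GenomeBuild


@pytest.fixture(scope="session")
def params():
    return ClassificationParams()


@pytest.fixture()
def toy_build():
    """Small two-chromosome genome plus an acrocentric-style chromosome.

    chr1/chr2: 10 Mb with p [0, 4.5 Mb), centromere gap, q [5 Mb, 10 Mb).
    chr13: 6 Mb with an acrocentric short p arm [0, 1 Mb) and q [2 Mb, 6 Mb).
    """
    chroms = [("chr1", 10_000_000), ("chr2", 10_000_000), ("chr13", 6_000_000)]
    arms = [
        ArmInterval("chr1", "p", 0, 4_500_000),
        ArmInterval("chr1", "q", 5_000_000, 10_000_000),
        ArmInterval("chr2", "p", 0, 4_500_000),
        ArmInterval("chr2", "q", 5_000_000, 10_000_000),
        ArmInterval("chr13", "p", 0, 1_000_000, acrocentric_short=True),
        ArmInterval("chr13", "q", 2_000_000, 6_000_000),
    ]
    return GenomeBuild(chromosomes=chroms, arms=arms)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def raster_arm_fraction(seg, arm):
    """Brute-force oracle: count shared integer positions with numpy."""
    if seg.chrom != arm.chrom:
        return 0.0
    positions = np.arange(seg.start, seg.end)
    inside = (positions >= arm.start) & (positions < arm.end)
    return int(inside.sum()) / (arm.end - arm.start)


def raster_union_bp(spans, genome_lengths):
    """Brute-force union oracle: boolean coverage mask per chromosome."""
    masks = {c: np.zeros(l, dtype=bool) for c, l in genome_lengths.items()}
    for chrom, start, end in spans:
        masks[chrom][start:end] = True
    return int(sum(m.sum() for m in masks.values()))
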