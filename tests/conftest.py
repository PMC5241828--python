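"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from perichrom.intervals import Genome, GenomicInterval, IntervalSet


@pytest.fixture
def toy_genome() -> Genome:
    return Genome([("chr1", 1000), ("chr2", 800)])


@pytest.fixture
def kb10_genome() -> Genome:
    return Genome([("chr1", 10_000)])


# ---------------------------------------------------------------------------
# Per-base boolean oracle: the independent route for all interval algebra
# ---------------------------------------------------------------------------

def perbase(genome: Genome, ivs) -> dict[str, np.ndarray]:
    """Explicit per-base coverage arrays, one bool array per chromosome."""
    arrays = {c: np.zeros(l, dtype=bool) for c, l in genome.chromosomes}
    for iv in ivs:
        arrays[iv.chrom][iv.start : iv.end] = True
    return arrays


def perbase_to_intervals(genome: Genome, arrays: dict[str, np.ndarray]) -> list:
    """Convert per-base coverage back to a sorted merged interval list."""
    out = []
    for chrom, _ in genome.chromosomes:
        a = arrays[chrom]
        diff = np.diff(a.astype(np.int8))
        starts = list(np.flatnonzero(diff == 1) + 1)
        ends = list(np.flatnonzero(diff == -1) + 1)
        if a[0]:
            starts = [0] + starts
        if a[-1]:
            ends = ends + [len(a)]
        out.extend((chrom, int(s), int(e)) for s, e in zip(starts, ends))
    return out


def as_tuples(ivs) -> list[tuple[str, int, int]]:
    return [(iv.chrom, iv.start, iv.end) for iv in ivs]


def oracle_consensus_union(genome, rep1, rep2, min_overlap_bp=1):
    """Brute-force replicate consensus: union spans of all overlapping pairs."""
    spans = []
    for i in rep1:
        for j in rep2:
            if i.chrom != j.chrom:
                continue
            ov = min(i.end, j.end) - max(i.start, j.start)
            if ov >= min_overlap_bp:
                spans.append(
                    GenomicInterval(i.chrom, min(i.start, j.start), max(i.end, j.end))
                )
    return perbase_to_intervals(genome, perbase(genome, spans))


def random_interval_set(
    rng: np.random.Generator, genome: Genome, n: int, max_len: int = 200
) -> IntervalSet:
    ivs = []
    chroms = genome.chromosomes
    for _ in range(n):
        chrom, clen = chroms[rng.integers(len(chroms))]
        length = int(rng.integers(1, min(max_len, clen) + 1))
        start = int(rng.integers(0, clen - length + 1))
        ivs.append(GenomicInterval(chrom, start, start + length))
    return IntervalSet(genome, ivs)
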