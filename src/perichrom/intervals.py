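"""Genome model, BED-family I/O, and exact genomic-interval algebra.

Coordinates are 0-based half-open throughout (BED convention).  Interval sets
are strandless: every consumed track (peak calls, histone-mark regions, LADs,
CpG islands) is treated as a plain set of genomic segments on an explicit
:class:`Genome`, which fixes chromosome names, lengths and sort order.

Beyond plain set algebra (merge / intersect / coverage), the module provides
the two peak-level operators used to turn raw replicate peak calls into a
final binding-site list:

* :func:`subtract_control` — drop every peak that overlaps a control
  (e.g. bait-only pulldown) peak;
* :func:`consensus_union` — keep the sites supported by both replicates,
  emitting the union span of each reciprocally overlapping replicate pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Genome",
    "GenomicInterval",
    "IntervalSet",
    "BedParseError",
    "read_chrom_sizes",
    "read_bed",
    "write_bed",
    "merge",
    "intersect",
    "subtract_control",
    "consensus_union",
    "overlap_counts",
    "coverage_fraction",
]


class BedParseError(ValueError):
    """Raised for malformed BED-family input; carries the 1-based line number."""


@dataclass(frozen=True)
class Genome:
    """Ordered chromosome names and lengths; the coordinate frame for all intervals.

    Parameters
    ----------
    chromosomes
        Sequence of ``(name, length_bp)`` pairs.  Names must be unique and
        non-empty, lengths positive.  The given order defines the canonical
        chromosome sort order.
    """

    chromosomes: tuple[tuple[str, int], ...]

    def __init__(self, chromosomes: Iterable[tuple[str, int]]):
        chroms = tuple((str(n), int(l)) for n, l in chromosomes)
        names = [n for n, _ in chroms]
        if len(names) != len(set(names)):
            raise ValueError("chromosome names must be unique")
        if any(not n for n in names):
            raise ValueError("chromosome names must be non-empty")
        if any(l <= 0 for _, l in chroms):
            raise ValueError("chromosome lengths must be positive")
        object.__setattr__(self, "chromosomes", chroms)
        object.__setattr__(self, "_lengths", dict(chroms))
        object.__setattr__(self, "_order", {n: i for i, (n, _) in enumerate(chroms)})

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    @property
    def size(self) -> int:
        """Total genome size in bp."""
        return sum(l for _, l in self.chromosomes)

    def length(self, chrom: str) -> int:
        return self._lengths[chrom]

    def order(self, chrom: str) -> int:
        """Canonical sort index of a chromosome."""
        return self._order[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __len__(self) -> int:
        return len(self.chromosomes)


@dataclass(frozen=True)
class GenomicInterval:
    """One 0-based half-open interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class IntervalSet:
    """A set of genomic intervals on one :class:`Genome`, kept in canonical order.

    Canonical order is (chromosome order in the genome, start, end).  An
    IntervalSet may contain overlapping intervals (e.g. raw peak calls); call
    :func:`merge` for the minimal non-overlapping representation.
    """

    def __init__(self, genome: Genome, intervals: Iterable[GenomicInterval]):
        self.genome = genome
        ivs = list(intervals)
        for iv in ivs:
            if iv.chrom not in genome:
                raise ValueError(f"chromosome {iv.chrom!r} not in genome")
            if iv.end > genome.length(iv.chrom):
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                    f"chromosome length {genome.length(iv.chrom)}"
                )
        ivs.sort(key=lambda iv: (genome.order(iv.chrom), iv.start, iv.end))
        self.intervals: list[GenomicInterval] = ivs

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return (
            self.genome == other.genome
            and [(i.chrom, i.start, i.end) for i in self]
            == [(i.chrom, i.start, i.end) for i in other]
        )

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} intervals on {len(self.genome)} chromosomes)"

    def total_bases(self) -> int:
        """Number of distinct bases covered (merged base count)."""
        return sum(len(iv) for iv in merge(self))

    def by_chrom(self) -> dict[str, np.ndarray]:
        """Per-chromosome ``(n, 2)`` start/end arrays in canonical order."""
        out: dict[str, list[tuple[int, int]]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append((iv.start, iv.end))
        return {
            c: np.asarray(v, dtype=np.int64).reshape(-1, 2) for c, v in out.items()
        }


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_chrom_sizes(path: str | Path) -> Genome:
    """Read a two-column ``chrom.sizes`` TSV (name, length) into a Genome."""
    chroms = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise BedParseError(f"{path}:{ln}: expected 2 tab-separated columns")
            try:
                chroms.append((parts[0], int(parts[1])))
            except ValueError as e:
                raise BedParseError(f"{path}:{ln}: bad length {parts[1]!r}") from e
    return Genome(chroms)


_BED_MIN_COLS = {"bed3": 3, "bed6": 3, "narrowPeak": 10}


def read_bed(
    path: str | Path,
    genome: Genome,
    format: Literal["bed3", "bed6", "narrowPeak"] = "bed3",
    on_unknown_chrom: Literal["drop", "strict"] = "drop",
) -> IntervalSet:
    """Read a BED3/BED6/narrowPeak file into an :class:`IntervalSet`.

    Intervals on chromosomes absent from *genome* (e.g. unlocalized contigs)
    are dropped with a logged count under the default ``on_unknown_chrom=
    "drop"`` policy, or raise under ``"strict"``.

    Raises
    ------
    BedParseError
        On malformed lines (with line number) or failed validation.
    """
    if format not in _BED_MIN_COLS:
        raise ValueError(f"unknown BED dialect {format!r}")
    min_cols = _BED_MIN_COLS[format]
    intervals: list[GenomicInterval] = []
    n_dropped = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < min_cols:
                raise BedParseError(
                    f"{path}:{ln}: expected >= {min_cols} columns for {format}, "
                    f"got {len(parts)}"
                )
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as e:
                raise BedParseError(f"{path}:{ln}: non-integer coordinates") from e
            if start >= end or start < 0:
                raise BedParseError(
                    f"{path}:{ln}: invalid interval [{start}, {end})"
                )
            if chrom not in genome:
                if on_unknown_chrom == "strict":
                    raise BedParseError(
                        f"{path}:{ln}: unknown chromosome {chrom!r}"
                    )
                n_dropped += 1
                continue
            name = score = None
            if format in ("bed6", "narrowPeak") and len(parts) > 3:
                name = parts[3] if parts[3] != "." else None
                if len(parts) > 4 and parts[4] != ".":
                    try:
                        score = float(parts[4])
                    except ValueError as e:
                        raise BedParseError(f"{path}:{ln}: bad score {parts[4]!r}") from e
            if format == "narrowPeak":
                # column 7 (signalValue) is the quantitative score of record
                try:
                    score = float(parts[6])
                except ValueError as e:
                    raise BedParseError(
                        f"{path}:{ln}: bad narrowPeak signalValue {parts[6]!r}"
                    ) from e
            intervals.append(GenomicInterval(chrom, start, end, name, score))
    if n_dropped:
        logger.warning(
            "%s: dropped %d interval(s) on chromosomes absent from the genome",
            path,
            n_dropped,
        )
    return IntervalSet(genome, intervals)


def write_bed(ivs: IntervalSet, path: str | Path, header: Sequence[str] = ()) -> None:
    """Write an IntervalSet as 6-column BED (tab-separated, no column header).

    *header* lines, if any, are written first as ``#``-prefixed comments.
    """
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        for iv in ivs:
            name = iv.name if iv.name is not None else "."
            score = f"{iv.score:g}" if iv.score is not None else "0"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t.\n")


# ---------------------------------------------------------------------------
# Algebra
# ---------------------------------------------------------------------------

def _check_same_genome(a: IntervalSet, b: IntervalSet) -> None:
    if a.genome != b.genome:
        raise ValueError("interval sets are on different genomes")


def merge(a: IntervalSet) -> IntervalSet:
    """Minimal non-overlapping, non-abutting interval set covering the same bases.

    Abutting intervals coalesce: under half-open coordinates [0,100) and
    [100,200) are contiguous and merge to [0,200).
    """
    out: list[GenomicInterval] = []
    for chrom, arr in a.by_chrom().items():
        # canonical order => already sorted by (start, end)
        cur_s, cur_e = arr[0]
        for s, e in arr[1:]:
            if s <= cur_e:  # overlap or abut
                cur_e = max(cur_e, e)
            else:
                out.append(GenomicInterval(chrom, int(cur_s), int(cur_e)))
                cur_s, cur_e = s, e
        out.append(GenomicInterval(chrom, int(cur_s), int(cur_e)))
    return IntervalSet(a.genome, out)


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Bases present in both sets, in merged form."""
    _check_same_genome(a, b)
    ma, mb = merge(a), merge(b)
    bya, byb = ma.by_chrom(), mb.by_chrom()
    out: list[GenomicInterval] = []
    for chrom in bya:
        if chrom not in byb:
            continue
        xs, ys = bya[chrom], byb[chrom]
        i = j = 0
        while i < len(xs) and j < len(ys):
            s = max(xs[i, 0], ys[j, 0])
            e = min(xs[i, 1], ys[j, 1])
            if s < e:
                out.append(GenomicInterval(chrom, int(s), int(e)))
            if xs[i, 1] < ys[j, 1]:
                i += 1
            else:
                j += 1
    return IntervalSet(a.genome, out)


def _overlap_bp_with_merged(iv: GenomicInterval, merged: np.ndarray) -> int:
    """Total bases of *iv* covered by a merged (sorted, disjoint) array."""
    if merged.size == 0:
        return 0
    lo = np.clip(merged[:, 0], iv.start, iv.end)
    hi = np.clip(merged[:, 1], iv.start, iv.end)
    return int(np.maximum(hi - lo, 0).sum())


def subtract_control(
    peaks: IntervalSet, control: IntervalSet, min_overlap_bp: int = 1
) -> IntervalSet:
    """Peak-level control subtraction: drop peaks overlapping control regions.

    A peak is removed whole if it shares >= *min_overlap_bp* bases with the
    merged control set; surviving peaks are returned unmodified.  This mirrors
    subtracting a bait-only (e.g. GST-alone) pulldown from a peak list when
    only peak calls, not reads, are available.
    """
    _check_same_genome(peaks, control)
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    byc = merge(control).by_chrom()
    empty = np.empty((0, 2), dtype=np.int64)
    kept = [
        iv
        for iv in peaks
        if _overlap_bp_with_merged(iv, byc.get(iv.chrom, empty)) < min_overlap_bp
    ]
    return IntervalSet(peaks.genome, kept)


def consensus_union(
    rep1: IntervalSet,
    rep2: IntervalSet,
    min_overlap_bp: int = 1,
    mode: Literal["union", "intersection", "rep1", "rep2"] = "union",
) -> IntervalSet:
    """Replicate-consensus sites: merged spans of reciprocally overlapping pairs.

    For every pair ``(i in rep1, j in rep2)`` overlapping by at least
    *min_overlap_bp*, a span is emitted and the emitted spans are merged:

    * ``union`` (default) — the union span ``[min(starts), max(ends))``;
    * ``intersection`` — the overlap span only;
    * ``rep1`` / ``rep2`` — the coordinates of the supporting interval from
      that replicate.

    ``consensus_union(a, a) == merge(a)`` and the operator is symmetric in
    its arguments under the ``union`` and ``intersection`` modes.
    """
    _check_same_genome(rep1, rep2)
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    by1, by2 = rep1.by_chrom(), rep2.by_chrom()
    out: list[GenomicInterval] = []
    for chrom in by1:
        if chrom not in by2:
            continue
        xs, ys = by1[chrom], by2[chrom]
        y_starts = ys[:, 0]  # sorted (canonical order)
        y_ends = ys[:, 1]
        for s, e in xs:
            # candidate ys have y_start < e; filter on y_end > s below
            j_hi = int(np.searchsorted(y_starts, e, side="left"))
            for j in range(j_hi):
                if y_ends[j] <= s:
                    continue
                ov = min(e, y_ends[j]) - max(s, y_starts[j])
                if ov >= min_overlap_bp:
                    if mode == "union":
                        span = (min(s, y_starts[j]), max(e, y_ends[j]))
                    elif mode == "intersection":
                        span = (max(s, y_starts[j]), min(e, y_ends[j]))
                    elif mode == "rep1":
                        span = (s, e)
                    elif mode == "rep2":
                        span = (y_starts[j], y_ends[j])
                    else:
                        raise ValueError(f"unknown consensus mode {mode!r}")
                    out.append(GenomicInterval(chrom, int(span[0]), int(span[1])))
    return merge(IntervalSet(rep1.genome, out)) if out else IntervalSet(rep1.genome, [])


def overlap_counts(
    query: IntervalSet, reference: IntervalSet, min_overlap_bp: int = 1
) -> tuple[int, int]:
    """``(n_overlapping, n_total)``: query intervals with >= min_overlap_bp
    bases of overlap with the merged reference."""
    _check_same_genome(query, reference)
    byr = merge(reference).by_chrom()
    empty = np.empty((0, 2), dtype=np.int64)
    n = sum(
        1
        for iv in query
        if _overlap_bp_with_merged(iv, byr.get(iv.chrom, empty)) >= min_overlap_bp
    )
    return n, len(query)


def coverage_fraction(regions: IntervalSet, genome: Genome | None = None) -> float:
    """Merged base count of *regions* divided by total genome size."""
    g = genome if genome is not None else regions.genome
    if len(regions) == 0:
        return 0.0
    return regions.total_bases() / g.size
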