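"""Genomic enrichment statistics for peak sets.

The question throughout is: do binding sites fall inside a class of regions
(subtelomeric windows, gene features, histone-mark domains) more often than
expected by chance?  "Expected by chance" is the base-pair coverage fraction
of the target regions; significance comes from

* a permutation null that redraws every peak uniformly at random on its own
  chromosome (length preserved), with the add-one p-value rule
  ``p = (1 + #{null >= obs}) / (1 + n_perm)``;
* a binomial upper tail at the coverage-fraction success probability; and
* Fisher exact tests on 2x2 tables built from observed peaks versus an
  equal-size pool of length-matched, same-chromosome shuffled peaks.

Subtelomeric regions are operationalized as fixed-width windows adjacent to
each chromosome end (default 500 kb), clipped and merged on short
chromosomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping, NamedTuple

import numpy as np
from scipy import stats

from perichrom.intervals import (
    Genome,
    GenomicInterval,
    IntervalSet,
    coverage_fraction,
    merge,
    overlap_counts,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "CooccurrenceResult",
    "subtelomeric_windows",
    "fold_enrichment",
    "permutation_test",
    "fisher_exact",
    "shuffle_peaks",
    "annotate_features",
    "cooccurrence",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed/expected peak fractions in a region class with null p-values.

    ``fold = f_obs / f_exp`` where ``f_exp`` is the coverage fraction of the
    regions.  ``p_perm`` and ``p_binom`` are ``None`` when only the point
    estimate was computed (no permutations run).
    """

    n_obs: int
    n_total: int
    f_obs: float
    f_exp: float
    fold: float
    p_perm: float | None = None
    p_binom: float | None = None
    n_perm: int = 0
    seed: int | None = None
    null_mean: float | None = None
    null_sd: float | None = None


class CooccurrenceResult(NamedTuple):
    """Peaks overlapping two mark tracks simultaneously, vs shuffled peaks."""

    n_both: int
    n_total: int
    fraction: float
    fold: float
    fisher_p: float
    odds_ratio: float


# ---------------------------------------------------------------------------
# Subtelomeric windows
# ---------------------------------------------------------------------------

def subtelomeric_windows(
    genome: Genome,
    window_bp: int = 500_000,
    ends: Literal["both", "left", "right"] = "both",
) -> IntervalSet:
    """Fixed-width windows adjacent to chromosome ends (merged, clipped).

    For a chromosome of length ``L`` the windows are ``[0, min(window_bp, L))``
    and/or ``[max(0, L - window_bp), L)``.  Chromosomes shorter than
    ``2 * window_bp`` yield a single merged window covering min(2*window_bp, L)
    bases.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    out = []
    for chrom, length in genome.chromosomes:
        if ends in ("both", "left"):
            out.append(GenomicInterval(chrom, 0, min(window_bp, length)))
        if ends in ("both", "right"):
            out.append(GenomicInterval(chrom, max(0, length - window_bp), length))
    return merge(IntervalSet(genome, out))


# ---------------------------------------------------------------------------
# Membership machinery (global-coordinate region index)
# ---------------------------------------------------------------------------

class _RegionIndex:
    """Merged regions flattened into one global coordinate axis.

    Chromosomes are laid end to end in genome order; regions never cross a
    chromosome boundary, so midpoint membership reduces to a parity test on
    the sorted boundary array and any-overlap to a searchsorted lookup.
    """

    def __init__(self, regions: IntervalSet, genome: Genome):
        offsets = {}
        off = 0
        for chrom, length in genome.chromosomes:
            offsets[chrom] = off
            off += length
        self.offsets = offsets
        starts, ends = [], []
        for iv in merge(regions):
            starts.append(offsets[iv.chrom] + iv.start)
            ends.append(offsets[iv.chrom] + iv.end)
        self.r_starts = np.asarray(starts, dtype=np.int64)
        self.r_ends = np.asarray(ends, dtype=np.int64)
        self.bounds = np.empty(2 * len(starts), dtype=np.int64)
        self.bounds[0::2] = self.r_starts
        self.bounds[1::2] = self.r_ends

    def midpoint_inside(self, gpos: np.ndarray) -> np.ndarray:
        """Boolean: is each global position inside a region (parity rule)."""
        return np.searchsorted(self.bounds, gpos, side="right") % 2 == 1

    def any_overlap(self, gstart: np.ndarray, gend: np.ndarray) -> np.ndarray:
        """Boolean: does [gstart, gend) overlap any region by >= 1 bp."""
        if len(self.r_starts) == 0:
            return np.zeros(np.shape(gstart), dtype=bool)
        k = np.searchsorted(self.r_ends, gstart, side="right")
        ok = k < len(self.r_starts)
        res = np.zeros(gstart.shape, dtype=bool)
        res[ok] = self.r_starts[np.minimum(k, len(self.r_starts) - 1)][ok] < gend[ok]
        return res


def _peak_arrays(peaks: IntervalSet, index: _RegionIndex):
    """Global starts, lengths, chromosome lengths, per peak (canonical order)."""
    g = peaks.genome
    gstarts = np.array([index.offsets[iv.chrom] + iv.start for iv in peaks], np.int64)
    lengths = np.array([len(iv) for iv in peaks], np.int64)
    chrom_len = np.array([g.length(iv.chrom) for iv in peaks], np.int64)
    chrom_off = np.array([index.offsets[iv.chrom] for iv in peaks], np.int64)
    return gstarts, lengths, chrom_len, chrom_off


def _observed_count(
    peaks: IntervalSet, index: _RegionIndex, membership: str
) -> int:
    gstarts, lengths, _, _ = _peak_arrays(peaks, index)
    if membership == "midpoint":
        return int(index.midpoint_inside(gstarts + lengths // 2).sum())
    elif membership == "any_overlap":
        return int(index.any_overlap(gstarts, gstarts + lengths).sum())
    raise ValueError(f"unknown membership rule {membership!r}")


# ---------------------------------------------------------------------------
# Fold enrichment and permutation test
# ---------------------------------------------------------------------------

def fold_enrichment(
    peaks: IntervalSet,
    regions: IntervalSet,
    genome: Genome | None = None,
    membership: Literal["midpoint", "any_overlap"] = "midpoint",
) -> EnrichmentResult:
    """Observed vs coverage-expected fraction of peaks inside *regions*.

    Under ``midpoint`` membership a peak counts if its midpoint base lies in
    the merged regions (unambiguous single assignment); under ``any_overlap``
    if it shares >= 1 bp.
    """
    g = genome if genome is not None else peaks.genome
    if len(peaks) == 0:
        raise ValueError("peaks are empty")
    f_exp = coverage_fraction(regions, g)
    if f_exp == 0:
        raise ValueError("regions are empty")
    index = _RegionIndex(regions, g)
    n_obs = _observed_count(peaks, index, membership)
    f_obs = n_obs / len(peaks)
    return EnrichmentResult(
        n_obs=n_obs,
        n_total=len(peaks),
        f_obs=f_obs,
        f_exp=f_exp,
        fold=f_obs / f_exp,
    )


def permutation_test(
    peaks: IntervalSet,
    regions: IntervalSet,
    genome: Genome | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    placement: Literal["same_chrom", "genome_wide"] = "same_chrom",
    membership: Literal["midpoint", "any_overlap"] = "midpoint",
) -> EnrichmentResult:
    """Permutation null for peak enrichment in a region class.

    Each permutation redraws every peak uniformly at random with its length
    preserved — on its own chromosome (default, preserving chromosome
    composition) or genome-wide with chromosomes weighted by length.  The
    permutation p-value uses the add-one rule, so ``p_perm >= 1/(1+n_perm)``;
    a binomial upper-tail p at the coverage fraction is reported alongside.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    g = genome if genome is not None else peaks.genome
    base = fold_enrichment(peaks, regions, g, membership)
    index = _RegionIndex(regions, g)
    gstarts, lengths, chrom_len, chrom_off = _peak_arrays(peaks, index)
    n = len(peaks)
    rng = np.random.default_rng(seed)

    if placement == "same_chrom":
        high = chrom_len - lengths + 1  # number of valid start positions
        if np.any(high < 1):
            bad = int(np.argmin(high))
            raise ValueError(
                f"peak of length {lengths[bad]} cannot be placed on its "
                f"chromosome (length {chrom_len[bad]})"
            )
        starts = rng.integers(0, high, size=(n_perm, n))
        goffs = chrom_off
    elif placement == "genome_wide":
        clens = np.array([l for _, l in g.chromosomes], dtype=np.int64)
        coffs = np.array([index.offsets[c] for c, _ in g.chromosomes], np.int64)
        starts = np.empty((n_perm, n), dtype=np.int64)
        goffs = np.empty((n_perm, n), dtype=np.int64)
        for i in range(n):
            valid = clens - lengths[i] + 1
            w = np.maximum(valid, 0).astype(float)
            if w.sum() == 0:
                raise ValueError(f"peak of length {lengths[i]} fits no chromosome")
            ci = rng.choice(len(clens), size=n_perm, p=w / w.sum())
            starts[:, i] = rng.integers(0, valid[ci])
            goffs[:, i] = coffs[ci]
    else:
        raise ValueError(f"unknown placement {placement!r}")

    g0 = goffs + starts
    if membership == "midpoint":
        null_counts = index.midpoint_inside(g0 + lengths // 2).sum(axis=1)
    else:
        null_counts = index.any_overlap(g0, g0 + lengths).sum(axis=1)

    p_perm = (1 + int((null_counts >= base.n_obs).sum())) / (1 + n_perm)
    p_binom = float(stats.binom.sf(base.n_obs - 1, base.n_total, base.f_exp))
    return EnrichmentResult(
        n_obs=base.n_obs,
        n_total=base.n_total,
        f_obs=base.f_obs,
        f_exp=base.f_exp,
        fold=base.fold,
        p_perm=p_perm,
        p_binom=p_binom,
        n_perm=n_perm,
        seed=seed,
        null_mean=float(null_counts.mean()),
        null_sd=float(null_counts.std(ddof=1)) if n_perm > 1 else 0.0,
    )


# ---------------------------------------------------------------------------
# Fisher exact test
# ---------------------------------------------------------------------------

_TIE_REL_TOL = 1e-7  # relative slack for point-probability ties (R convention)


def fisher_exact(
    table,
    alternative: Literal["two_sided", "greater", "less"] = "two_sided",
) -> float:
    """Exact hypergeometric p-value for a 2x2 contingency table.

    The two-sided p sums the probabilities of all tables (with the observed
    margins) whose point probability is at most that of the observed table,
    with relative tolerance 1e-7 for ties — the standard convention of exact
    test implementations.  One-sided alternatives sum the corresponding
    hypergeometric tail.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("table entries must be non-negative")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    if n == 0:
        raise ValueError("all-zero table")
    row1 = a + b
    col1 = a + c
    k_lo = max(0, row1 + col1 - n)
    k_hi = min(row1, col1)
    ks = np.arange(k_lo, k_hi + 1)
    pmf = stats.hypergeom.pmf(ks, n, col1, row1)
    p_obs = pmf[a - k_lo]
    if alternative == "greater":
        p = pmf[ks >= a].sum()
    elif alternative == "less":
        p = pmf[ks <= a].sum()
    elif alternative == "two_sided":
        p = pmf[pmf <= p_obs * (1 + _TIE_REL_TOL)].sum()
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(min(p, 1.0))


# ---------------------------------------------------------------------------
# Length-matched peak shuffles, annotation, co-occurrence
# ---------------------------------------------------------------------------

def shuffle_peaks(
    peaks: IntervalSet,
    genome: Genome | None = None,
    n_copies: int = 1,
    seed: int | np.random.Generator = 0,
) -> IntervalSet:
    """Pool of ``n_copies * len(peaks)`` length-matched, same-chromosome
    uniformly redrawn peaks — the chance baseline for Fisher-table tests."""
    g = genome if genome is not None else peaks.genome
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for iv in peaks:
        L = len(iv)
        high = g.length(iv.chrom) - L + 1
        if high < 1:
            raise ValueError(f"peak of length {L} cannot be placed on {iv.chrom}")
        for s in rng.integers(0, high, size=n_copies):
            out.append(GenomicInterval(iv.chrom, int(s), int(s) + L))
    return IntervalSet(g, out)


def _expand(ivs: IntervalSet, flank_bp: int) -> IntervalSet:
    g = ivs.genome
    out = [
        GenomicInterval(
            iv.chrom,
            max(0, iv.start - flank_bp),
            min(g.length(iv.chrom), iv.end + flank_bp),
            iv.name,
            iv.score,
        )
        for iv in ivs
    ]
    return IntervalSet(g, out)


def annotate_features(
    peaks: IntervalSet,
    features: Mapping[str, IntervalSet],
    genome: Genome | None = None,
    tss_flank_bp: int = 2000,
    n_shuffle: int = 10,
    seed: int = 0,
    flank_features: tuple[str, ...] = ("TSS", "TES"),
):
    """Annotate peaks against named feature tracks (genes, exons, TSS, LADs...).

    For each feature track, counts peaks with any overlap, compares against a
    pooled shuffle of ``n_shuffle * n_peaks`` length-matched random peaks, and
    reports fraction, expected fraction, fold, a Fisher p on the 2x2
    observed-vs-shuffled table and Benjamini-Hochberg adjusted values.
    Feature tracks named in *flank_features* (point features such as TSS/TES)
    are expanded by *tss_flank_bp* on each side first.  Empty tracks are
    skipped with a warning.

    Returns a pandas DataFrame, one row per feature.
    """
    import pandas as pd

    g = genome if genome is not None else peaks.genome
    if len(peaks) == 0:
        raise ValueError("peaks are empty")
    rng = np.random.default_rng(seed)
    pool = shuffle_peaks(peaks, g, n_copies=n_shuffle, seed=rng)
    rows = []
    for name, track in features.items():
        if track is None or len(track) == 0:
            logger.warning("feature track %r is empty; skipped", name)
            continue
        t = _expand(track, tss_flank_bp) if name in flank_features else track
        n_obs, n_tot = overlap_counts(peaks, t)
        n_exp, n_pool = overlap_counts(pool, t)
        f_obs = n_obs / n_tot
        f_exp = n_exp / n_pool if n_pool else 0.0
        fold = f_obs / f_exp if f_exp > 0 else np.inf if f_obs > 0 else np.nan
        p = fisher_exact([[n_obs, n_tot - n_obs], [n_exp, n_pool - n_exp]])
        rows.append(
            dict(
                feature=name,
                n_obs=n_obs,
                n_total=n_tot,
                frac_obs=f_obs,
                frac_exp=f_exp,
                fold=fold,
                fisher_p=p,
            )
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["fisher_q"] = stats.false_discovery_control(df["fisher_p"].to_numpy())
    return df


def cooccurrence(
    peaks: IntervalSet,
    markA: IntervalSet,
    markB: IntervalSet,
    genome: Genome | None = None,
    n_shuffle: int = 1,
    seed: int = 0,
) -> CooccurrenceResult:
    """Peaks overlapping two histone-mark tracks simultaneously.

    ``n_both`` counts peaks sharing >= 1 bp with each of the merged mark
    tracks; the chance expectation comes from ``n_shuffle`` length-matched
    same-chromosome shuffles of the peaks, and significance from a Fisher
    exact test on the observed-vs-shuffled 2x2 table.  The returned
    ``odds_ratio`` is the sample odds ratio of the per-peak (A, B) overlap
    indicators (an estimate of the planted association between the marks at
    peaks).
    """
    g = genome if genome is not None else peaks.genome
    if len(markA) == 0 or len(markB) == 0:
        raise ValueError("mark track is empty")
    if len(peaks) == 0:
        raise ValueError("peaks are empty")
    iA = _RegionIndex(markA, g)
    iB = _RegionIndex(markB, g)
    gstarts, lengths, _, _ = _peak_arrays(peaks, iA)
    inA = iA.any_overlap(gstarts, gstarts + lengths)
    inB = iB.any_overlap(gstarts, gstarts + lengths)
    n = len(peaks)
    n_both = int((inA & inB).sum())
    n11 = n_both
    n10 = int((inA & ~inB).sum())
    n01 = int((~inA & inB).sum())
    n00 = n - n11 - n10 - n01
    if n10 > 0 and n01 > 0:
        odds = (n11 * n00) / (n10 * n01)
    else:
        odds = np.inf if n11 * n00 > 0 else np.nan

    pool = shuffle_peaks(peaks, g, n_copies=n_shuffle, seed=seed)
    pstarts, plens, _, _ = _peak_arrays(pool, iA)
    pinA = iA.any_overlap(pstarts, pstarts + plens)
    pinB = iB.any_overlap(pstarts, pstarts + plens)
    n_exp = int((pinA & pinB).sum())
    n_pool = len(pool)
    fraction = n_both / n
    f_exp = n_exp / n_pool if n_pool else 0.0
    fold = fraction / f_exp if f_exp > 0 else np.inf if fraction > 0 else np.nan
    p = fisher_exact([[n_both, n - n_both], [n_exp, n_pool - n_exp]])
    return CooccurrenceResult(
        n_both=n_both,
        n_total=n,
        fraction=fraction,
        fold=fold,
        fisher_p=p,
        odds_ratio=float(odds),
    )
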