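"""Synthetic data with recorded ground truth for both pipeline halves.

Two generators emulate the study's data modalities:

* **Peak sets on a toy genome** — peak midpoints fall in subtelomeric windows
  with probability ``fold x coverage`` (so the planted fold enrichment is
  exactly recoverable in expectation), and histone-mark tracks carry a
  planted per-peak co-occurrence odds ratio.  At odds ratio 1 the mark
  tracks are placed uniformly at random, independent of the peaks, so the
  co-occurrence test's null distribution is exact by construction;
  association is created by relocating marks between peaks in a way that
  preserves both marginal hit counts.

* **Nucleus images** — elliptical nuclei with a uniform nucleoplasm level, a
  Gaussian rim of signal at a chosen distance from the mask boundary
  (emulating envelope-bound protein), diffraction-limited Gaussian spots
  planted at controlled radial distance quantiles, and additive Gaussian or
  Poisson noise.

Every generator takes an explicit seed, uses one local RNG (no global
state), and returns a truth record sufficient to compute the expected value
of every downstream statistic.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from perichrom.intervals import Genome, GenomicInterval, IntervalSet
from perichrom.enrichment import subtelomeric_windows
from perichrom.intervals import coverage_fraction, merge
from perichrom.geometry import NucleusMask
from perichrom.spots import SpotSet

__all__ = [
    "PeakSimTruth",
    "EllipseSpec",
    "SpotSpec",
    "ImageSimTruth",
    "simulate_genome",
    "simulate_peaks",
    "simulate_mark_tracks",
    "simulate_nucleus_image",
    "plackett_joint",
]


# ---------------------------------------------------------------------------
# Genome and peaks
# ---------------------------------------------------------------------------

def simulate_genome(n_chrom: int, lengths: Sequence[int], seed: int = 0) -> Genome:
    """Deterministic toy genome chr1..chrN with the given lengths (bp)."""
    if len(lengths) != n_chrom:
        raise ValueError("need one length per chromosome")
    return Genome([(f"chr{i + 1}", int(l)) for i, l in enumerate(lengths)])


@dataclass
class PeakSimTruth:
    """Ground truth of a simulated peak / mark-track data set."""

    seed: int
    n_peaks: int = 0
    subtel_fold: float | None = None
    window_bp: int | None = None
    window_coverage: float | None = None
    p_in_window: float | None = None
    n_planted_in_windows: int | None = None
    length_mean: int | None = None
    odds_ratio: float | None = None
    mark_density: float | None = None
    mark_length: int | None = None
    realized_odds_ratio: float | None = None
    joint_counts: dict | None = None  # {"n11":..,"n10":..,"n01":..,"n00":..}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


class _BaseSampler:
    """Uniform sampling of single bases from an interval set (global coords)."""

    def __init__(self, regions: IntervalSet):
        ivs = list(merge(regions))
        self.chroms = [iv.chrom for iv in ivs]
        self.starts = np.array([iv.start for iv in ivs], dtype=np.int64)
        lens = np.array([len(iv) for iv in ivs], dtype=np.int64)
        self.cum = np.concatenate(([0], np.cumsum(lens)))
        self.total = int(self.cum[-1])

    def sample(self, rng: np.random.Generator, n: int):
        u = rng.integers(0, self.total, size=n)
        idx = np.searchsorted(self.cum, u, side="right") - 1
        pos = self.starts[idx] + (u - self.cum[idx])
        return [(self.chroms[i], int(p)) for i, p in zip(idx, pos)]


def _complement(regions: IntervalSet) -> IntervalSet:
    g = regions.genome
    byc = merge(regions).by_chrom()
    out = []
    for chrom, length in g.chromosomes:
        prev = 0
        for s, e in byc.get(chrom, np.empty((0, 2), dtype=np.int64)):
            if s > prev:
                out.append(GenomicInterval(chrom, prev, int(s)))
            prev = int(e)
        if prev < length:
            out.append(GenomicInterval(chrom, prev, length))
    return IntervalSet(g, out)


def simulate_peaks(
    genome: Genome,
    n_peaks: int,
    length_mean: int = 200,
    subtel_fold: float = 1.0,
    window_bp: int = 500_000,
    seed: int = 0,
    length_mode: str = "geometric",
) -> tuple[IntervalSet, PeakSimTruth]:
    """Peak set with a planted subtelomeric fold enrichment.

    Each peak's midpoint falls in the subtelomeric windows with probability
    ``p = subtel_fold * coverage_fraction(windows)`` (uniform within the
    windows), otherwise uniformly in the complement, so the midpoint-based
    fold estimator recovers *subtel_fold* in expectation.  Lengths are
    geometric with the given mean (or constant with ``length_mode=
    "constant"``), clipped to chromosome bounds.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    if subtel_fold < 0:
        raise ValueError("subtel_fold must be >= 0")
    windows = subtelomeric_windows(genome, window_bp)
    cov = coverage_fraction(windows, genome)
    p = subtel_fold * cov
    if p > 1:
        raise ValueError(
            f"infeasible fold: {subtel_fold} x coverage {cov:.3g} exceeds 1"
        )
    rng = np.random.default_rng(seed)
    in_win = rng.random(n_peaks) < p
    win_sampler = _BaseSampler(windows)
    out_sampler = _BaseSampler(_complement(windows))
    mids = [None] * n_peaks
    win_idx = np.flatnonzero(in_win)
    out_idx = np.flatnonzero(~in_win)
    for i, cp in zip(win_idx, win_sampler.sample(rng, len(win_idx))):
        mids[i] = cp
    for i, cp in zip(out_idx, out_sampler.sample(rng, len(out_idx))):
        mids[i] = cp
    if length_mode == "geometric":
        lengths = rng.geometric(1.0 / length_mean, size=n_peaks)
    elif length_mode == "constant":
        lengths = np.full(n_peaks, length_mean, dtype=np.int64)
    else:
        raise ValueError(f"unknown length_mode {length_mode!r}")
    ivs = []
    for (chrom, mid), L in zip(mids, lengths):
        clen = genome.length(chrom)
        L = int(min(L, clen))
        start = int(np.clip(mid - L // 2, 0, clen - L))
        ivs.append(GenomicInterval(chrom, start, start + L))
    peaks = IntervalSet(genome, ivs)
    truth = PeakSimTruth(
        seed=seed,
        n_peaks=n_peaks,
        subtel_fold=subtel_fold,
        window_bp=window_bp,
        window_coverage=cov,
        p_in_window=p,
        n_planted_in_windows=int(in_win.sum()),
        length_mean=length_mean,
    )
    return peaks, truth


def simulate_replicate_peaks(
    genome: Genome,
    n_sites: int,
    length_mean: int = 200,
    subtel_fold: float = 1.0,
    window_bp: int = 500_000,
    retention: float = 0.9,
    jitter_bp: int = 50,
    n_noise: int = 0,
    seed: int = 0,
) -> tuple[IntervalSet, IntervalSet, PeakSimTruth]:
    """Two replicate peak sets observing one underlying binding-site set.

    A true site set with the planted subtelomeric fold is drawn once; each
    replicate keeps each site with probability *retention*, jitters its
    boundaries by up to *jitter_bp*, and adds *n_noise* uniformly placed
    false-positive peaks.  Replicate consensus then recovers the shared true
    sites (and their planted fold), while noise peaks rarely reproduce.
    """
    rng = np.random.default_rng(seed)
    true_sites, truth = simulate_peaks(
        genome, n_sites, length_mean, subtel_fold, window_bp,
        seed=int(rng.integers(2**31)),
    )

    def one_replicate() -> IntervalSet:
        ivs = []
        for iv in true_sites:
            if rng.random() > retention:
                continue
            clen = genome.length(iv.chrom)
            s = int(np.clip(iv.start + rng.integers(-jitter_bp, jitter_bp + 1),
                            0, clen - 1))
            e = int(np.clip(iv.end + rng.integers(-jitter_bp, jitter_bp + 1),
                            s + 1, clen))
            ivs.append(GenomicInterval(iv.chrom, s, e))
        if n_noise:
            noise, _ = simulate_peaks(
                genome, n_noise, length_mean, 1.0, window_bp,
                seed=int(rng.integers(2**31)),
            )
            ivs.extend(noise)
        return IntervalSet(genome, ivs)

    return one_replicate(), one_replicate(), truth


# ---------------------------------------------------------------------------
# Mark tracks with a planted co-occurrence odds ratio
# ---------------------------------------------------------------------------

def plackett_joint(p_a: float, p_b: float, odds_ratio: float) -> float:
    """Joint probability P(A=1, B=1) with given marginals and odds ratio."""
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be positive")
    if odds_ratio == 1.0:
        return p_a * p_b
    th = odds_ratio
    s = 1 + (p_a + p_b) * (th - 1)
    disc = s * s - 4 * th * (th - 1) * p_a * p_b
    if disc < 0:
        raise ValueError("marginals incompatible with odds ratio")
    p11 = (s - math.sqrt(disc)) / (2 * (th - 1))
    lo, hi = max(0.0, p_a + p_b - 1.0), min(p_a, p_b)
    if not (lo - 1e-12 <= p11 <= hi + 1e-12):
        raise ValueError("marginals incompatible with odds ratio")
    return float(np.clip(p11, lo, hi))


def _uniform_marks(
    genome: Genome, n_marks: int, mark_length: int, rng: np.random.Generator
) -> list[list]:
    """Uniformly placed fixed-length intervals, one list entry per mark:
    mutable [chrom, start] records (fixed length)."""
    clens = np.array([l for _, l in genome.chromosomes], dtype=np.int64)
    names = [c for c, _ in genome.chromosomes]
    valid = clens - mark_length + 1
    if np.all(valid < 1):
        raise ValueError("mark_length exceeds every chromosome")
    w = np.maximum(valid, 0).astype(float)
    ci = rng.choice(len(clens), size=n_marks, p=w / w.sum())
    starts = rng.integers(0, valid[ci])
    return [[names[c], int(s)] for c, s in zip(ci, starts)]


def _peak_hits(peaks: list[tuple[str, int, int]], marks: list[list], W: int):
    """For each peak, indices of marks overlapping it; and per-mark peak lists."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for mi, (chrom, s) in enumerate(marks):
        by_chrom.setdefault(chrom, []).append((s, mi))
    for v in by_chrom.values():
        v.sort()
    peak_marks: list[set[int]] = []
    mark_peaks: dict[int, set[int]] = {mi: set() for mi in range(len(marks))}
    for pi, (chrom, ps, pe) in enumerate(peaks):
        hits = set()
        lst = by_chrom.get(chrom, [])
        starts = [s for s, _ in lst]
        import bisect

        lo = bisect.bisect_left(starts, ps - W + 1)
        hi = bisect.bisect_left(starts, pe)
        for s, mi in lst[lo:hi]:
            if s < pe and s + W > ps:
                hits.add(mi)
                mark_peaks[mi].add(pi)
        peak_marks.append(hits)
    return peak_marks, mark_peaks


def simulate_mark_tracks(
    genome: Genome,
    peaks: IntervalSet,
    odds_ratio: float = 1.0,
    mark_density: float = 0.3,
    mark_length: int = 5000,
    seed: int = 0,
    max_iter: int | None = None,
) -> tuple[IntervalSet, IntervalSet, PeakSimTruth]:
    """Two mark tracks with a planted per-peak co-occurrence odds ratio.

    Both tracks start as uniformly placed fixed-length intervals at the
    requested genome-wide density — independent of the peaks and of each
    other, which IS the odds-ratio-1 case.  For ``odds_ratio != 1`` marks of
    track B are relocated between peaks (from a B-only peak onto an A-only
    peak to raise the odds ratio, or from a double-positive peak onto a
    double-negative one to lower it) until the per-peak joint hit count
    reaches the target implied by the realized marginals and the requested
    odds ratio.  Each relocation preserves both tracks' marginal hit counts,
    so only the association is planted.

    ``mark_density=1`` tiles the genome completely with both marks.
    """
    if not (0 < mark_density <= 1):
        raise ValueError("mark_density must be in (0, 1]")
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be positive")
    rng = np.random.default_rng(seed)
    g = genome
    W = int(mark_length)

    if mark_density == 1.0:
        full = [GenomicInterval(c, 0, l) for c, l in g.chromosomes]
        markA = IntervalSet(g, full)
        markB = IntervalSet(g, list(full))
        truth = PeakSimTruth(
            seed=seed,
            n_peaks=len(peaks),
            odds_ratio=odds_ratio,
            mark_density=1.0,
            mark_length=W,
            realized_odds_ratio=float("nan"),
            joint_counts={"n11": len(peaks), "n10": 0, "n01": 0, "n00": 0},
        )
        return markA, markB, truth

    n_marks = max(1, round(mark_density * g.size / W))
    marksA = _uniform_marks(g, n_marks, W, rng)
    marksB = _uniform_marks(g, n_marks, W, rng)
    plist = [(iv.chrom, iv.start, iv.end) for iv in peaks]
    n = len(plist)
    hitsA, _ = _peak_hits(plist, marksA, W)
    hitsB, markB_peaks = _peak_hits(plist, marksB, W)
    hA = np.array([len(h) > 0 for h in hitsA])
    hB = np.array([len(h) > 0 for h in hitsB])

    if odds_ratio != 1.0 and n > 0:
        pa, pb = float(hA.mean()), float(hB.mean())
        target_n11 = round(plackett_joint(pa, pb, odds_ratio) * n)
        fails = 0
        limit = max_iter if max_iter is not None else 50 * n
        while fails < limit:
            n11 = int((hA & hB).sum())
            if odds_ratio > 1 and n11 >= target_n11:
                break
            if odds_ratio < 1 and n11 <= target_n11:
                break
            if odds_ratio > 1:
                donors = np.flatnonzero(~hA & hB)  # B-only: take their B mark
                recips = np.flatnonzero(hA & ~hB)  # A-only: give them a B mark
            else:
                donors = np.flatnonzero(hA & hB)
                recips = np.flatnonzero(~hA & ~hB)
            if len(donors) == 0 or len(recips) == 0:
                raise ValueError(
                    "requested odds ratio infeasible for these marginals"
                )
            di = int(rng.choice(donors))
            ri = int(rng.choice(recips))
            # choose a B mark on the donor peak that touches no other peak
            cand = [mi for mi in hitsB[di] if markB_peaks[mi] == {di}]
            if not cand:
                fails += 1  # try another donor next round
                continue
            mi = cand[rng.integers(len(cand))]
            chrom, ps, pe = plist[ri]
            mid = (ps + pe) // 2
            clen = g.length(chrom)
            new_start = int(np.clip(mid - W // 2, 0, max(0, clen - W)))
            # relocation must not graze any third peak
            grazed = [
                k
                for k, (c2, s2, e2) in enumerate(plist)
                if k != ri and c2 == chrom and s2 < new_start + W and e2 > new_start
            ]
            if grazed:
                fails += 1
                continue
            # detach from donor, attach to recipient
            hitsB[di].discard(mi)
            markB_peaks[mi] = {ri}
            marksB[mi] = [chrom, new_start]
            hitsB[ri].add(mi)
            hB[di] = len(hitsB[di]) > 0
            hB[ri] = True
        else:
            raise ValueError(
                "could not reach requested odds ratio: peaks too dense "
                "relative to mark length for marginal-preserving relocation"
            )

    n11 = int((hA & hB).sum())
    n10 = int((hA & ~hB).sum())
    n01 = int((~hA & hB).sum())
    n00 = n - n11 - n10 - n01
    if n10 > 0 and n01 > 0 and n11 > 0 and n00 > 0:
        realized = (n11 * n00) / (n10 * n01)
    else:
        realized = float("nan")

    def _as_set(marks):
        return merge(
            IntervalSet(
                g,
                [
                    GenomicInterval(c, s, min(s + W, g.length(c)))
                    for c, s in marks
                ],
            )
        )

    truth = PeakSimTruth(
        seed=seed,
        n_peaks=n,
        odds_ratio=odds_ratio,
        mark_density=mark_density,
        mark_length=W,
        realized_odds_ratio=float(realized),
        joint_counts={"n11": n11, "n10": n10, "n01": n01, "n00": n00},
    )
    return _as_set(marksA), _as_set(marksB), truth


# ---------------------------------------------------------------------------
# Nucleus images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EllipseSpec:
    """Elliptical nucleus: center (cx, cy) in pixels, semi-axes a >= b, and
    rotation *theta* in radians (counter-clockwise from the x axis)."""

    cx: float
    cy: float
    a: float
    b: float
    theta: float = 0.0


@dataclass
class SpotSpec:
    """Spots to plant per nucleus.

    ``radial_quantile``: None for uniform placement over in-mask pixels, a
    float in [0, 1] to place every spot on that distance-quantile contour
    (0 = at the boundary/outermost, 1 = deepest), or a sequence cycled over
    the spots.
    """

    n: int = 0
    sigma: float = 2.0
    amplitude: float = 100.0
    radial_quantile: float | Sequence[float] | None = None
    min_separation_px: float | None = None  # default 4*sigma: spots resolvable


@dataclass
class ImageSimTruth:
    """Everything planted into a simulated image, sufficient to predict every
    downstream statistic."""

    seed: int
    nuclei: list[EllipseSpec]
    rim_amplitude: float
    rim_sigma: float
    rim_offset: float
    nucleoplasm: float
    noise: dict | None
    spots: list[dict] = field(default_factory=list)

    @property
    def planted_profile_ratio(self) -> float:
        """Expected edge-maxima / plateau ratio of a noise-free line profile.

        The rim peak along a chord reaches ``nucleoplasm + rim_amplitude *
        g(d*)`` where d* is the in-mask distance closest to the rim offset
        (boundary pixels sit at distance 1), and the plateau is the
        nucleoplasm level.
        """
        if self.nucleoplasm <= 0:
            raise ValueError("undefined for nucleoplasm <= 0")
        d_star = max(self.rim_offset, 1.0)
        gpeak = math.exp(
            -((d_star - self.rim_offset) ** 2) / (2 * self.rim_sigma**2)
        )
        return 1.0 + self.rim_amplitude * gpeak / self.nucleoplasm

    def spot_set(self) -> SpotSet:
        return SpotSet(
            x=np.array([s["x"] for s in self.spots]),
            y=np.array([s["y"] for s in self.spots]),
            sigma=np.array([s["sigma"] for s in self.spots]),
            amplitude=np.array([s["amplitude"] for s in self.spots]),
            provenance="planted",
        )

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        d["nuclei"] = [dataclasses.asdict(e) for e in self.nuclei]
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)


def ellipse_mask(shape: tuple[int, int], spec: EllipseSpec) -> np.ndarray:
    """Boolean mask of one ellipse in an image of the given (height, width)."""
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    dx, dy = xx - spec.cx, yy - spec.cy
    ct, st = math.cos(spec.theta), math.sin(spec.theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (u / spec.a) ** 2 + (v / spec.b) ** 2 <= 1.0


def _quantile_pixel(
    d_in: np.ndarray, rows: np.ndarray, cols: np.ndarray, q: float,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Pick a random in-mask pixel on the q-th distance-quantile contour."""
    order = np.argsort(d_in, kind="stable")
    rank = int(round(q * (len(d_in) - 1)))
    target = d_in[order[rank]]
    tie = np.flatnonzero(d_in == target)
    k = tie[rng.integers(len(tie))]
    return int(rows[k]), int(cols[k])


def simulate_nucleus_image(
    width: int,
    height: int,
    nuclei: Sequence[EllipseSpec],
    rim_amplitude: float = 0.0,
    rim_sigma: float = 3.0,
    rim_offset: float = 0.0,
    nucleoplasm: float = 100.0,
    spots: SpotSpec | None = None,
    noise: dict | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, NucleusMask, ImageSimTruth]:
    """Render a synthetic multi-nucleus fluorescence image with ground truth.

    Pixel model inside each nucleus mask::

        I = nucleoplasm
          + rim_amplitude * exp(-(d - rim_offset)^2 / (2 rim_sigma^2))
          + sum of planted Gaussian spots

    where ``d`` is the Euclidean distance of the pixel to the mask boundary.
    *noise* is ``{"gaussian": sigma}`` for additive Gaussian noise,
    ``{"poisson": True}`` for Poisson shot noise on the rendered intensity,
    or None.  Returns ``(image, masks, truth)``; the label mask and the
    planted spot list are the ground truth for segmentation, shell
    positioning, profile and spot statistics.
    """
    if rim_amplitude < 0 or nucleoplasm < 0:
        raise ValueError("amplitudes must be >= 0")
    rng = np.random.default_rng(seed)
    img = np.zeros((height, width), dtype=float)
    labels = np.zeros((height, width), dtype=np.int32)
    truth = ImageSimTruth(
        seed=seed,
        nuclei=list(nuclei),
        rim_amplitude=rim_amplitude,
        rim_sigma=rim_sigma,
        rim_offset=rim_offset,
        nucleoplasm=nucleoplasm,
        noise=noise,
    )
    for k, spec in enumerate(nuclei, start=1):
        m = ellipse_mask((height, width), spec)
        if not m.any():
            raise ValueError(f"ellipse {k} lies outside the frame")
        if np.any(labels[m] > 0):
            raise ValueError(f"ellipse {k} overlaps an earlier nucleus")
        labels[m] = k
        img[m] += nucleoplasm
        if rim_amplitude > 0:
            d = ndimage.distance_transform_edt(m)
            img[m] += rim_amplitude * np.exp(
                -((d[m] - rim_offset) ** 2) / (2 * rim_sigma**2)
            )
        if spots is not None and spots.n > 0:
            rows, cols = np.nonzero(m)
            d_in = ndimage.distance_transform_edt(m)[m]
            qs = spots.radial_quantile
            if qs is not None and np.ndim(qs) == 0:
                qs = [float(qs)] * spots.n
            min_sep = (
                spots.min_separation_px
                if spots.min_separation_px is not None
                else 4.0 * spots.sigma
            )
            placed: list[tuple[int, int]] = []
            for i in range(spots.n):
                q_used = None
                if qs is not None:
                    q_used = float(qs[i % len(qs)])
                    if not (0.0 <= q_used <= 1.0):
                        raise ValueError("radial quantile outside [0, 1]")
                for _attempt in range(200):
                    if q_used is None:
                        j = rng.integers(len(rows))
                        r, c = int(rows[j]), int(cols[j])
                    else:
                        r, c = _quantile_pixel(d_in, rows, cols, q_used, rng)
                    if all(
                        (r - r0) ** 2 + (c - c0) ** 2 >= min_sep**2
                        for r0, c0 in placed
                    ):
                        break
                else:
                    raise ValueError(
                        "could not place spots with the requested separation"
                    )
                placed.append((r, c))
                _add_gaussian_spot(img, c, r, spots.sigma, spots.amplitude)
                truth.spots.append(
                    dict(
                        x=float(c),
                        y=float(r),
                        sigma=float(spots.sigma),
                        amplitude=float(spots.amplitude),
                        nucleus=k,
                        radial_quantile=q_used,
                    )
                )
    if noise:
        if "gaussian" in noise:
            img = img + rng.normal(0.0, float(noise["gaussian"]), size=img.shape)
        elif noise.get("poisson"):
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        else:
            raise ValueError(f"unknown noise spec {noise!r}")
    return img, NucleusMask(labels), truth


def _add_gaussian_spot(
    img: np.ndarray, x: float, y: float, sigma: float, amplitude: float
) -> None:
    r = int(math.ceil(4 * sigma))
    y0, y1 = max(0, int(y) - r), min(img.shape[0], int(y) + r + 1)
    x0, x1 = max(0, int(x) - r), min(img.shape[1], int(x) + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += amplitude * np.exp(
        -((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2)
    )
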