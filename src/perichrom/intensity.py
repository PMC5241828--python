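"""Intensity readouts: line-profile periphery ratios, nuclear means, the
three-circle tethered-spot ratio, and per-compartment particle densities.

The peripheral-enrichment statistic quantifies rim-like signal at the nuclear
envelope from a 1-D intensity profile sampled along a chord through the
nucleus: the two edge maxima (Max1, Max2 — one near each end of the in-mask
profile) are averaged and divided by the median of the central plateau,

    ratio = 0.5 * (max1 + max2) / median(plateau).

A uniformly distributed (rim-free) signal gives ratio ~ 1; a peripheral rim
gives ratio >> 1.  The statistic is a ratio of intensities, so it is
invariant under multiplicative rescaling but NOT under additive offsets:
background must be subtracted before it is computed.

The three-circle spot ratio quantifies recruitment of a signal to a tethered
locus: mean intensities are read in equal circles at the spot, at a nuclear
reference position and outside the cell, and

    ratio = (mean_spot - mean_outside) / (mean_nuclear - mean_outside).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "LineProfile",
    "PeripheralEnrichment",
    "line_profile",
    "peripheral_enrichment",
    "nuclear_mean_intensity",
    "spot_enrichment",
    "particle_density",
]


@dataclass
class LineProfile:
    """Intensity samples at unit-pixel spacing along a segment.

    ``positions`` are pixel offsets along the segment (strictly increasing,
    unit spacing); ``in_mask`` flags samples inside the nucleus mask.
    """

    positions: np.ndarray
    values: np.ndarray
    in_mask: np.ndarray

    def masked_values(self) -> np.ndarray:
        return self.values[self.in_mask]


@dataclass(frozen=True)
class PeripheralEnrichment:
    max1: float
    max2: float
    plateau_median: float
    ratio: float


def _mask_axes(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centroid (row, col), major- and minor-axis unit vectors of a mask."""
    rows, cols = np.nonzero(mask)
    centroid = np.array([rows.mean(), cols.mean()])
    dr, dc = rows - centroid[0], cols - centroid[1]
    cov = np.array([[np.mean(dr * dr), np.mean(dr * dc)],
                    [np.mean(dr * dc), np.mean(dc * dc)]])
    evals, evecs = np.linalg.eigh(cov)
    return centroid, evecs[:, 1], evecs[:, 0]  # major, minor (row, col) vectors


def line_profile(
    image: np.ndarray,
    mask: np.ndarray,
    axis: Literal["major", "minor", "segment"] = "major",
    endpoints: tuple[tuple[float, float], tuple[float, float]] | None = None,
    background: float = 0.0,
    margin_px: int = 2,
    line_width_px: int = 1,
) -> LineProfile:
    """Sample an intensity profile along a chord through the nucleus.

    ``axis="major"`` (default) or ``"minor"`` take the chord through the mask
    centroid along the corresponding principal axis; ``axis="segment"``
    requires explicit ``endpoints`` as ``((x0, y0), (x1, y1))`` in image
    (x = column) coordinates.  Intensities are sampled by bilinear
    interpolation at unit-pixel steps, clipped to the mask extent plus a
    *margin_px* margin; *background* is subtracted and negatives clamped to 0.

    *line_width_px* > 1 averages that many parallel lines offset
    perpendicular to the chord (integration width, as in standard profile
    tools); mask membership is always taken from the central line.
    """
    if line_width_px < 1 or line_width_px % 2 == 0:
        raise ValueError("line_width_px must be an odd positive integer")
    img = np.asarray(image, dtype=float)
    m = np.asarray(mask).astype(bool)
    area = int(m.sum())
    if area < 16:
        raise ValueError(f"degenerate mask (area {area} < 16 px)")

    if axis == "segment":
        if endpoints is None:
            raise ValueError("axis='segment' requires endpoints")
        (x0, y0), (x1, y1) = endpoints
        p0 = np.array([y0, x0], dtype=float)
        p1 = np.array([y1, x1], dtype=float)
        length = float(np.hypot(*(p1 - p0)))
        n = int(np.floor(length)) + 1
        t = np.arange(n, dtype=float)
        direction = (p1 - p0) / length
        coords = p0[:, None] + direction[:, None] * t[None, :]
    else:
        centroid, major, minor = _mask_axes(m)
        direction = major if axis == "major" else minor
        # span the full bounding diagonal both ways, then trim to the mask
        T = int(np.ceil(np.hypot(*m.shape)))
        t = np.arange(-T, T + 1, dtype=float)
        coords = centroid[:, None] + direction[:, None] * t[None, :]

    inside_img = (
        (coords[0] >= 0)
        & (coords[0] <= img.shape[0] - 1)
        & (coords[1] >= 0)
        & (coords[1] <= img.shape[1] - 1)
    )
    coords = coords[:, inside_img]
    t = t[inside_img]
    in_mask = (
        ndimage.map_coordinates(m.astype(np.uint8), coords, order=0, mode="constant")
        > 0
    )
    if not in_mask.any():
        raise ValueError("profile does not intersect the mask")
    first, last = np.flatnonzero(in_mask)[[0, -1]]
    lo = max(0, first - margin_px)
    hi = min(len(t), last + margin_px + 1)
    coords = coords[:, lo:hi]
    t = t[lo:hi]
    in_mask = in_mask[lo:hi]
    if line_width_px == 1:
        vals = ndimage.map_coordinates(img, coords, order=1, mode="constant")
    else:
        normal = np.array([-direction[1], direction[0]])
        half = (line_width_px - 1) // 2
        acc = np.zeros(coords.shape[1])
        for off in range(-half, half + 1):
            c = coords + normal[:, None] * float(off)
            acc += ndimage.map_coordinates(img, c, order=1, mode="constant")
        vals = acc / line_width_px
    vals = np.clip(vals - background, 0.0, None)
    return LineProfile(positions=t - t[0], values=vals, in_mask=in_mask)


def peripheral_enrichment(
    profile: LineProfile, edge_fraction: float = 0.25
) -> PeripheralEnrichment:
    """Edge-maxima-over-plateau ratio of a nuclear line profile.

    max1/max2 are the maxima over the first/last *edge_fraction* of in-mask
    samples; the plateau is the central 50% of in-mask samples.  Requires at
    least 8 in-mask samples and a strictly positive plateau median.
    """
    if not (0 < edge_fraction <= 0.5):
        raise ValueError("edge_fraction must be in (0, 0.5]")
    v = profile.masked_values()
    n = len(v)
    if n < 8:
        raise ValueError(f"need >= 8 in-mask samples, got {n}")
    k = max(1, int(round(edge_fraction * n)))
    max1 = float(v[:k].max())
    max2 = float(v[-k:].max())
    lo, hi = n // 4, n - n // 4
    plateau_median = float(np.median(v[lo:hi]))
    if plateau_median <= 0:
        raise ValueError("flat/empty plateau (median <= 0)")
    ratio = 0.5 * (max1 + max2) / plateau_median
    return PeripheralEnrichment(max1, max2, plateau_median, ratio)


def nuclear_mean_intensity(
    image: np.ndarray,
    mask,
    background: Literal["median_outside"] | float = "median_outside",
) -> dict[int, float]:
    """Background-subtracted mean intensity per nucleus.

    *mask* is a :class:`~perichrom.geometry.NucleusMask` or a label array.
    Background is the median of out-of-mask pixels (default) or an explicit
    constant; per-nucleus means are clamped at 0 after subtraction.
    """
    labels = getattr(mask, "labels", mask)
    labels = np.asarray(labels)
    img = np.asarray(image, dtype=float)
    if img.shape != labels.shape:
        raise ValueError("image and mask shapes differ")
    if background == "median_outside":
        outside = img[labels == 0]
        bg = float(np.median(outside)) if outside.size else 0.0
    else:
        bg = float(background)
    out = {}
    for lab in np.unique(labels[labels > 0]):
        out[int(lab)] = max(0.0, float(img[labels == lab].mean()) - bg)
    return out


def _circle_mask(shape: tuple[int, int], center: tuple[float, float], r: float):
    """Boolean disk at (x, y) center with radius r pixels."""
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= r * r


def spot_enrichment(
    image: np.ndarray,
    spot_center: tuple[float, float],
    nuclear_ref_center: tuple[float, float],
    outside_center: tuple[float, float],
    radius_px: int = 3,
) -> float:
    """Three-circle ratio quantifying signal recruitment at a tethered spot.

    Mean intensities are read in equal circles of *radius_px* at the spot, a
    nuclear reference position and an out-of-cell background position; the
    background mean is subtracted from both the spot and nuclear means, and
    the spot signal is normalized to the nuclear signal:
    ``(mean_spot - mean_outside) / (mean_nuclear - mean_outside)``.
    """
    img = np.asarray(image, dtype=float)
    circles = [
        _circle_mask(img.shape, c, radius_px)
        for c in (spot_center, nuclear_ref_center, outside_center)
    ]
    for i in range(3):
        for j in range(i + 1, 3):
            if np.any(circles[i] & circles[j]):
                raise ValueError("the three circles must be disjoint")
    m_spot, m_nuc, m_out = (float(img[c].mean()) for c in circles)
    denom = m_nuc - m_out
    if denom <= 0:
        raise ValueError("non-positive nuclear signal after background subtraction")
    return (m_spot - m_out) / denom


def particle_density(
    points: Sequence[tuple[float, float]],
    compartment_masks: Mapping[str, np.ndarray],
    pixel_size_um: float,
) -> dict[str, float]:
    """Point density per compartment, in counts per square micrometre.

    *points* are (x, y) positions (e.g. immunogold particles); compartment
    masks must be mutually disjoint boolean images.  Density is
    ``count_in_mask / (mask_area_px * pixel_size_um**2)``.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    names = list(compartment_masks)
    masks = [np.asarray(compartment_masks[n]).astype(bool) for n in names]
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            if np.any(masks[i] & masks[j]):
                raise ValueError(
                    f"compartments {names[i]!r} and {names[j]!r} overlap"
                )
    out = {}
    for name, m in zip(names, masks):
        area_px = int(m.sum())
        if area_px == 0:
            raise ValueError(f"compartment {name!r} has zero area")
        count = 0
        h, w = m.shape
        for x, y in points:
            r, c = int(round(y)), int(round(x))
            if 0 <= r < h and 0 <= c < w and m[r, c]:
                count += 1
        out[name] = count / (area_px * pixel_size_um**2)
    return out
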