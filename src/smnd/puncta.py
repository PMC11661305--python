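"""Puncta segmentation, Rab5⁺ ROI selection and per-ROI localization density.

Endocytic hot spots are segmented from a diffraction-limited marker channel
(Rab5 immunofluorescence, or WGA for global endocytosis): rolling-ball
background subtraction, moment-preserving ("Moments") auto-thresholding,
8-connected labeling, and particle filtering by area (0.12–4 µm²) and
circularity (0.04–1.00). Rab5⁺ regions of interest are the puncta smaller
than 0.3 µm²; each is paired with a congruent Rab5⁻ control region — the same
pixel footprint translated to a random non-overlapping spot inside the cell
mask — so positive and negative ROI sets have equal counts and exactly equal
areas. Localization density is the number of localizations falling in the
ROI footprint divided by its area.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.restoration import rolling_ball

log = logging.getLogger(__name__)

__all__ = [
    "Punctum",
    "Roi",
    "RoiSet",
    "threshold_moments",
    "segment_puncta",
    "intensity_size_profile",
    "select_rab5_positive",
    "sample_negative_rois",
    "roi_density",
    "build_roi_set",
]


@dataclass
class Punctum:
    """A segmented punctum with its measurements and pixel footprint."""

    label: int
    area_um2: float
    centroid_nm: tuple[float, float]        # (x, y)
    mean_intensity: float
    circularity: float                      # 4πA/P², clipped to (0, 1]
    equivalent_diameter_nm: float
    pixels: np.ndarray = field(repr=False)  # (n, 2) of (row, col)
    pixel_size_um: float = 0.1


@dataclass
class Roi:
    label: int
    kind: str                               # "+" or "-"
    pixels: np.ndarray                      # (n, 2) of (row, col)
    pixel_size_um: float

    @property
    def area_um2(self) -> float:
        return self.pixels.shape[0] * self.pixel_size_um ** 2


@dataclass
class RoiSet:
    positives: list[Roi]
    negatives: list[Roi]

    def __post_init__(self) -> None:
        if len(self.positives) != len(self.negatives):
            raise ValueError("positive and negative ROI counts must match")


def threshold_moments(image: np.ndarray, n_bins: int = 256) -> float:
    """Moment-preserving (Tsai) bilevel threshold.

    Finds the threshold such that the binarized image preserves the first
    three gray-level moments of the input — the algorithm behind the
    'Moments' auto-threshold of common image-analysis software.
    """
    pix = np.asarray(image, dtype=float).ravel()
    lo, hi = float(pix.min()), float(pix.max())
    if hi <= lo:
        return hi
    hist, edges = np.histogram(pix, bins=n_bins, range=(lo, hi))
    p = hist / hist.sum()
    levels = 0.5 * (edges[:-1] + edges[1:])
    # normalized gray values on [0, 1] keep the cubic well-conditioned
    g = (levels - lo) / (hi - lo)
    m1 = float(np.sum(p * g))
    m2 = float(np.sum(p * g ** 2))
    m3 = float(np.sum(p * g ** 3))
    cd = m2 - m1 * m1
    if cd <= 0:
        return lo
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (-m3 + m2 * m1) / cd
    disc = c1 * c1 - 4.0 * c0
    if disc < 0:
        return lo
    z0 = 0.5 * (-c1 - math.sqrt(disc))
    z1 = 0.5 * (-c1 + math.sqrt(disc))
    if z1 == z0:
        return lo
    p0 = (z1 - m1) / (z1 - z0)              # fraction of pixels below threshold
    p0 = min(max(p0, 0.0), 1.0)
    cum = np.cumsum(p)
    k = int(np.searchsorted(cum, p0))
    k = min(k, n_bins - 1)
    return float(edges[k + 1])


def segment_puncta(image: np.ndarray, pixel_size_um: float = 0.1,
                   rolling_ball_radius: float = 50.0,
                   area_range_um2: tuple[float, float] = (0.12, 4.0),
                   circularity_range: tuple[float, float] = (0.04, 1.0),
                   threshold: str | float = "moments") -> list[Punctum]:
    """Segment diffraction-limited puncta from a marker-channel image.

    Rolling-ball background subtraction (radius in pixels), global Moments
    threshold, 8-connected components, then particle filters on area and
    circularity. Pass a float ``threshold`` to override the auto-threshold.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        return []
    background = rolling_ball(img, radius=rolling_ball_radius)
    sub = img - background
    if isinstance(threshold, str):
        if threshold != "moments":
            raise ValueError(f"unknown threshold method {threshold!r}")
        thr = threshold_moments(sub)
    else:
        thr = float(threshold)
    mask = sub > thr
    labels = sk_label(mask, connectivity=2)

    out: list[Punctum] = []
    n_area = n_circ = 0
    px_area = pixel_size_um ** 2
    for rp in regionprops(labels, intensity_image=sub):
        area = rp.area * px_area
        perim = rp.perimeter_crofton     # boundary-length estimate, ~2πr for disks
        circ = 1.0 if perim <= 0 else min(4.0 * math.pi * rp.area / perim ** 2, 1.0)
        if not (area_range_um2[0] <= area <= area_range_um2[1]):
            n_area += 1
            continue
        if not (circularity_range[0] <= circ <= circularity_range[1]):
            n_circ += 1
            continue
        cy, cx = rp.centroid
        out.append(Punctum(
            label=rp.label,
            area_um2=area,
            centroid_nm=(cx * pixel_size_um * 1e3, cy * pixel_size_um * 1e3),
            mean_intensity=float(rp.intensity_mean),
            circularity=circ,
            equivalent_diameter_nm=2.0 * math.sqrt(area / math.pi) * 1e3,
            pixels=rp.coords.copy(),
            pixel_size_um=pixel_size_um,
        ))
    log.info("segment_puncta: kept %d, removed %d by area, %d by circularity",
             len(out), n_area, n_circ)
    return out


def intensity_size_profile(puncta: list[Punctum], bin_edges_um2) -> pd.DataFrame:
    """Normalized mean intensity as a function of punctum area.

    Mean of per-punctum mean intensities within each area bin, normalized to
    the maximum occupied bin; bins with fewer than 3 puncta are flagged.
    """
    if not puncta:
        raise ValueError("no puncta")
    areas = np.array([p.area_um2 for p in puncta])
    inten = np.array([p.mean_intensity for p in puncta])
    edges = np.asarray(bin_edges_um2, dtype=float)
    idx = np.digitize(areas, edges) - 1
    rows = []
    for b in range(edges.size - 1):
        sel = idx == b
        if not sel.any():
            continue
        rows.append({"area_lo_um2": edges[b], "area_hi_um2": edges[b + 1],
                     "mean_intensity": float(inten[sel].mean()),
                     "n": int(sel.sum()), "low_n": bool(sel.sum() < 3)})
    prof = pd.DataFrame(rows)
    prof["normalized_intensity"] = prof["mean_intensity"] / prof["mean_intensity"].max()
    return prof


def select_rab5_positive(puncta: list[Punctum], max_area_um2: float = 0.3) -> list[Roi]:
    """Rab5⁺ ROIs: puncta strictly smaller than ``max_area_um2`` (0.3 µm²)."""
    rois = []
    for i, p in enumerate(p for p in puncta if p.area_um2 < max_area_um2):
        rois.append(Roi(label=i, kind="+", pixels=p.pixels, pixel_size_um=p.pixel_size_um))
    return rois


def sample_negative_rois(cell_mask: np.ndarray, positives: list[Roi], seed: int = 0,
                         max_attempts: int = 1000) -> tuple[list[Roi], list[Roi]]:
    """Matched Rab5⁻ control regions: congruent, non-overlapping, random.

    For every positive ROI, its exact pixel footprint is translated to a
    uniformly random position inside ``cell_mask``, rejecting placements that
    leave the mask or overlap any positive or previously placed negative ROI.
    Returns ``(kept_positives, negatives)``; pairs that cannot be placed after
    ``max_attempts`` tries are dropped from BOTH sides (with a warning) so the
    sets stay matched in count and total area.
    """
    mask = np.asarray(cell_mask, dtype=bool)
    rng = np.random.default_rng(seed)
    occupied = np.zeros_like(mask)
    for roi in positives:
        occupied[roi.pixels[:, 0], roi.pixels[:, 1]] = True

    kept, negatives = [], []
    ny, nx = mask.shape
    for roi in positives:
        base = roi.pixels - roi.pixels.min(axis=0)
        h, w = base.max(axis=0) + 1
        placed = False
        for _ in range(max_attempts):
            r0 = rng.integers(0, ny - h + 1)
            c0 = rng.integers(0, nx - w + 1)
            pix = base + (r0, c0)
            if not mask[pix[:, 0], pix[:, 1]].all():
                continue
            if occupied[pix[:, 0], pix[:, 1]].any():
                continue
            occupied[pix[:, 0], pix[:, 1]] = True
            negatives.append(Roi(label=roi.label, kind="-", pixels=pix,
                                 pixel_size_um=roi.pixel_size_um))
            kept.append(roi)
            placed = True
            break
        if not placed:
            warnings.warn(f"could not place a matched control for ROI {roi.label}; pair dropped")
    return kept, negatives


def roi_density(roi: Roi, localizations) -> float:
    """Localizations per µm² inside the ROI's pixel footprint.

    Positions are mapped to pixels by flooring ``coord / pixel_size``; a
    localization exactly on a pixel boundary is counted if either adjacent
    pixel belongs to the ROI (closed-region convention).
    """
    if isinstance(localizations, pd.DataFrame):
        xy = localizations[["x_nm", "y_nm"]].to_numpy(dtype=float)
    else:
        xy = np.asarray(localizations, dtype=float).reshape(-1, 2)
    px_nm = roi.pixel_size_um * 1e3
    pixset = {(int(r), int(c)) for r, c in roi.pixels}

    count = 0
    for x, y in xy:
        fx, fy = x / px_nm, y / px_nm
        cols = {int(math.floor(fx))}
        rows = {int(math.floor(fy))}
        if fx == math.floor(fx):
            cols.add(int(fx) - 1)
        if fy == math.floor(fy):
            rows.add(int(fy) - 1)
        if any((r, c) in pixset for r in rows for c in cols):
            count += 1
    return count / roi.area_um2


def build_roi_set(puncta: list[Punctum], cell_mask: np.ndarray, localizations,
                  max_area_um2: float = 0.3, seed: int = 0) -> tuple[RoiSet, pd.DataFrame]:
    """Select Rab5⁺ ROIs, sample matched controls and tabulate densities."""
    positives = select_rab5_positive(puncta, max_area_um2=max_area_um2)
    kept, negatives = sample_negative_rois(cell_mask, positives, seed=seed)
    rows = []
    for roi in kept + negatives:
        rows.append({"id": roi.label, "type": roi.kind, "area_um2": roi.area_um2,
                     "density_per_um2": roi_density(roi, localizations)})
    return RoiSet(positives=kept, negatives=negatives), pd.DataFrame(rows)
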