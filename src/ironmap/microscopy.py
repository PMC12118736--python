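"""Microscopy quantifiers: IF coverage, MPIO spot counting, proximity binding.

Immunofluorescence coverage follows the remote-calibrated protocol: the
stain threshold is the percentile of pooled nonzero red-channel intensities
over remote (uninjured) sections that eliminates ~95% of them; coverage on a
sample is then the fraction of autofluorescence-positive (tissue) pixels
whose red intensity strictly exceeds that threshold.

Spot counting detects dark ~1 um particles on bright-field images by
inversion, background subtraction, thresholding and connected-component
area filtering (optionally watershed-splitting touching particles).  The
incubation binding rule counts a particle as bound when its center lies on
or within one adjacency radius of a cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology, segmentation
from skimage.feature import peak_local_max

from .phantom import IFImagePair

__all__ = [
    "CoverageResult",
    "SpotCountResult",
    "calibrate_threshold",
    "tissue_mask",
    "coverage",
    "count_spots",
    "count_spot_fields",
    "incubation_bound_count",
]


@dataclass
class CoverageResult:
    """P-selectin coverage of one sample image."""

    threshold: float
    tissue_pixels: int
    positive_pixels: int
    coverage: float
    calibration_images: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "tissue_pixels": self.tissue_pixels,
            "positive_pixels": self.positive_pixels,
            "coverage": self.coverage,
            "calibration_images": list(self.calibration_images),
        }


@dataclass
class SpotCountResult:
    """Per-field particle counts with the detection parameters used."""

    counts: list[int]
    parameters: dict = field(default_factory=dict)

    @property
    def total(self) -> int:
        return int(sum(self.counts))

    def to_dict(self) -> dict:
        return {"counts": self.counts, "total": self.total,
                "parameters": self.parameters}


def calibrate_threshold(
    remote_images: Sequence[IFImagePair] | Sequence[np.ndarray],
    percentile: float = 0.95,
) -> float:
    """Stain-intensity threshold from remote (uninjured) sections.

    Pools all NONZERO red-channel intensities across the remote images and
    returns their ``percentile`` quantile (linear interpolation between
    order statistics).  Applied as a strict ``>`` cut this eliminates
    approximately that fraction of the unspecific background fluorescence.
    """
    if not 0.0 < percentile <= 1.0:
        raise ValueError("percentile must be in (0, 1]")
    if len(remote_images) == 0:
        raise ValueError("need at least one remote image")
    reds = []
    for img in remote_images:
        red = img.red_channel if isinstance(img, IFImagePair) else np.asarray(img)
        reds.append(red[red > 0].ravel())
    pooled = np.concatenate(reds)
    if pooled.size < 100:
        raise ValueError("need >= 100 pooled nonzero red pixels to calibrate")
    return float(np.quantile(pooled, percentile, method="linear"))


def tissue_mask(
    green_channel: np.ndarray,
    method: str = "otsu",
    fixed_value: float | None = None,
) -> np.ndarray:
    """Tissue area from the autofluorescence (green) channel.

    ``method="otsu"`` thresholds with Otsu's criterion; ``method="fixed"``
    uses ``fixed_value`` (mask = green > value).
    """
    green = np.asarray(green_channel, dtype=float)
    if method == "otsu":
        if np.ptp(green) == 0:
            raise ValueError("green channel has no contrast (all values equal)")
        thr = filters.threshold_otsu(green)
        return green > thr
    if method == "fixed":
        if fixed_value is None:
            raise ValueError("fixed method requires fixed_value")
        return green > float(fixed_value)
    raise ValueError(f"unknown tissue_mask method {method!r}")


def coverage(
    pair: IFImagePair,
    threshold: float,
    *,
    tissue_method: str = "otsu",
    tissue_fixed_value: float | None = None,
    calibration_images: Sequence[str] = (),
) -> CoverageResult:
    """P-selectin coverage: positive-and-tissue pixels over tissue pixels.

    A pixel is positive when its red intensity strictly exceeds the
    calibrated ``threshold`` AND it lies inside the autofluorescence tissue
    mask; coverage = positive_pixels / tissue_pixels.
    """
    tis = tissue_mask(pair.green_channel, method=tissue_method,
                      fixed_value=tissue_fixed_value)
    n_tissue = int(tis.sum())
    if n_tissue == 0:
        raise ValueError("empty tissue mask")
    positive = (pair.red_channel > threshold) & tis
    n_pos = int(positive.sum())
    return CoverageResult(
        threshold=float(threshold),
        tissue_pixels=n_tissue,
        positive_pixels=n_pos,
        coverage=n_pos / n_tissue,
        calibration_images=tuple(calibration_images),
    )


def count_spots(
    image: np.ndarray,
    expected_radius_px: float = 3.0,
    *,
    polarity: str = "dark",
    min_area_factor: float = 0.3,
    max_area_factor: float = 3.0,
    split_touching: bool = False,
) -> int:
    """Count particle spots in one high-power field.

    Pipeline: invert (for dark spots), subtract a median-filtered background,
    Otsu-threshold the residual, label connected components and keep those
    whose area lies within ``[min_area_factor, max_area_factor]`` times the
    nominal spot area pi*r^2.  ``split_touching=True`` additionally splits
    merged components by a distance-transform watershed; with the default
    ``False`` two touching particles count as one component.

    Detection is invariant to global intensity scaling (Otsu operates on the
    background-subtracted residual).
    """
    img = np.asarray(image, dtype=float)
    if polarity not in ("dark", "bright"):
        raise ValueError("polarity must be 'dark' or 'bright'")
    work = -img if polarity == "dark" else img
    bg_size = int(max(3, round(4 * expected_radius_px + 1)))
    if bg_size % 2 == 0:
        bg_size += 1
    background = ndimage.median_filter(work, size=bg_size)
    resid = work - background
    # robust noise floor: spots must rise well above the residual noise,
    # otherwise a pure-background field would be segmented into false spots
    mad = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    resid = np.clip(resid, 0.0, None)
    if np.ptp(resid) == 0:
        return 0
    thr = max(filters.threshold_otsu(resid), 6.0 * mad)
    binary = resid > thr
    if not binary.any():
        return 0
    binary = morphology.remove_small_objects(binary, max_size=1)
    if not binary.any():
        return 0

    if split_touching:
        distance = ndimage.distance_transform_edt(binary)
        coords = peak_local_max(
            distance, min_distance=int(max(1, round(expected_radius_px))),
            labels=binary,
        )
        markers = np.zeros(binary.shape, dtype=int)
        for i, (r, c) in enumerate(coords, start=1):
            markers[r, c] = i
        labels = segmentation.watershed(-distance, markers, mask=binary)
    else:
        labels = measure.label(binary)

    nominal = np.pi * expected_radius_px**2
    lo, hi = min_area_factor * nominal, max_area_factor * nominal
    count = sum(1 for region in measure.regionprops(labels)
                if lo <= region.area <= hi)
    return count


def count_spot_fields(
    images: Sequence[np.ndarray],
    expected_radius_px: float = 3.0,
    **kwargs,
) -> SpotCountResult:
    """Count spots over a set of high-power fields (20 per slide typically)."""
    counts = [count_spots(img, expected_radius_px, **kwargs) for img in images]
    return SpotCountResult(
        counts=counts,
        parameters={"expected_radius_px": expected_radius_px, **kwargs},
    )


def incubation_bound_count(
    spot_centers: np.ndarray,
    cells: np.ndarray,
    adjacency_radius: float,
    *,
    cells_are_centers: bool = False,
    cell_radius: float = 0.0,
    pixel_size: float = 1.0,
) -> tuple[int, np.ndarray]:
    """Count particles bound to a cell layer by the proximity rule.

    A particle is bound when its center lies on a cell or within
    ``adjacency_radius`` of one ("exactly next to or on top of").  ``cells``
    is either a boolean cell mask (distance computed via an exact Euclidean
    distance transform, in pixel units scaled by ``pixel_size``) or, with
    ``cells_are_centers=True``, an (m, 2) array of cell centers with radius
    ``cell_radius`` (same units as the centers).

    Returns (bound count, boolean per-spot bound flags).
    """
    if adjacency_radius < 0:
        raise ValueError("adjacency_radius must be >= 0")
    spots = np.asarray(spot_centers, dtype=float).reshape(-1, 2)
    if spots.shape[0] == 0:
        return 0, np.zeros(0, dtype=bool)

    if cells_are_centers:
        centers = np.asarray(cells, dtype=float).reshape(-1, 2)
        if centers.shape[0] == 0:
            return 0, np.zeros(spots.shape[0], dtype=bool)
        d = np.sqrt(((spots[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2))
        bound = (d.min(axis=1) <= cell_radius + adjacency_radius)
    else:
        mask = np.asarray(cells, dtype=bool)
        # distance from every pixel to the nearest cell pixel, physical units
        dist = ndimage.distance_transform_edt(~mask) * pixel_size
        rows = np.clip(np.round(spots[:, 0]).astype(int), 0, mask.shape[0] - 1)
        cols = np.clip(np.round(spots[:, 1]).astype(int), 0, mask.shape[1] - 1)
        bound = dist[rows, cols] <= adjacency_radius
    return int(bound.sum()), bound
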