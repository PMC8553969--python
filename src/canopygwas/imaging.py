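"""Per-plot canopy height, vegetation fraction and leaf colour extraction.

Canopy height is the per-pixel difference between the observation DSM and
the pre-transplant baseline DSM, summarised per plot (default: 95th
percentile of within-plot differences, robust to soil gaps).  Vegetation
segmentation thresholds the CIELAB a* channel with Otsu's method, per
plot; pixels on the greener (more negative a*) side of the threshold are
plant.  Leaf colour is the mean of -a* over plant pixels only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skimage import color as skcolor

__all__ = [
    "DegenerateHistogramError",
    "rgb_to_lab",
    "otsu_threshold",
    "vegetation_fraction",
    "leaf_colour",
    "canopy_height",
    "measure_plots",
]

OTSU_BINS = 256


class DegenerateHistogramError(ValueError):
    """Raised when the value histogram cannot be split into two classes."""


def rgb_to_lab(rgb: np.ndarray) -> np.ndarray:
    """Convert an 8-bit sRGB image (H x W x 3) to CIELAB (D65)."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 RGB image, got shape {rgb.shape}")
    if rgb.dtype != np.uint8:
        if np.issubdtype(rgb.dtype, np.floating) and rgb.max() <= 1.0:
            return skcolor.rgb2lab(rgb)
        rgb = np.clip(rgb, 0, 255).astype(np.uint8)
    return skcolor.rgb2lab(rgb.astype(np.float64) / 255.0)


def otsu_threshold(values: np.ndarray) -> float:
    """Otsu threshold of a value array (any shape), 256-bin histogram.

    The histogram spans the observed value range; the returned threshold
    is the boundary between the two bins whose split maximises the
    between-class variance, with ties broken toward the lower threshold.
    Classify as ``value < threshold`` (lower class) vs the rest.

    Raises
    ------
    DegenerateHistogramError
        If the input is constant (single occupied bin).
    """
    vals = np.asarray(values, dtype=np.float64).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise DegenerateHistogramError("no finite values")
    lo, hi = vals.min(), vals.max()
    if lo == hi:
        raise DegenerateHistogramError("constant input: histogram has a single bin")
    hist, edges = np.histogram(vals, bins=OTSU_BINS, range=(lo, hi))
    hist = hist.astype(np.float64)
    total = hist.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0

    w0 = np.cumsum(hist)[:-1]                       # weight of bins 0..t
    w1 = total - w0
    m0 = np.cumsum(hist * centers)[:-1]
    m1 = m0[-1] + hist[-1] * centers[-1] - m0
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = np.where(w0 > 0, m0 / w0, 0.0)
        mu1 = np.where(w1 > 0, m1 / w1, 0.0)
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b[(w0 == 0) | (w1 == 0)] = -np.inf
    if not np.isfinite(sigma_b).any():
        raise DegenerateHistogramError("constant input: histogram has a single bin")
    t = int(np.argmax(sigma_b))                     # argmax takes the first (lowest) tie
    return float(edges[t + 1])


def vegetation_fraction(
    rgb: np.ndarray,
    plot_region: tuple[int, int, int, int] | None = None,
    *,
    fallback_a_cutoff: float = -10.0,
    min_class_separation: float = 5.0,
) -> tuple[float, np.ndarray]:
    """Vegetation fraction (percent) and plant mask of one plot.

    Pixels with a* below the per-plot Otsu threshold are plant; if the
    lower-a* class is actually the less green one the classes are swapped.
    When the a* histogram is degenerate (uniform colour) or the two Otsu
    classes are closer than ``min_class_separation`` a* units, the
    absolute cutoff ``a* < fallback_a_cutoff`` is used instead and a
    warning is issued.
    """
    crop = _crop(rgb, plot_region)
    a_star = rgb_to_lab(crop)[..., 1]
    try:
        threshold = otsu_threshold(a_star)
        mask = a_star < threshold
        low_mean = a_star[mask].mean() if mask.any() else np.inf
        high_mean = a_star[~mask].mean() if (~mask).any() else -np.inf
        if low_mean > high_mean:     # inverted scene: greener side is above
            mask = ~mask
            low_mean, high_mean = high_mean, low_mean
        if high_mean - low_mean < min_class_separation:
            raise DegenerateHistogramError(
                f"Otsu classes separated by only {high_mean - low_mean:.2f} a* units"
            )
    except DegenerateHistogramError as exc:
        warnings.warn(
            f"degenerate a* histogram ({exc}); falling back to absolute "
            f"cutoff a* < {fallback_a_cutoff}",
            stacklevel=2,
        )
        mask = a_star < fallback_a_cutoff
    vf = 100.0 * mask.mean()
    return float(vf), mask


def leaf_colour(lab: np.ndarray, plant_mask: np.ndarray,
                plot_region: tuple[int, int, int, int] | None = None) -> float:
    """Mean -a* over plant pixels; NaN with a warning when the mask is empty."""
    a_star = _crop(lab, plot_region)[..., 1]
    if plant_mask.shape != a_star.shape:
        raise ValueError(
            f"plant mask shape {plant_mask.shape} != plot shape {a_star.shape}"
        )
    if not plant_mask.any():
        warnings.warn("empty plant mask: leaf colour undefined", stacklevel=2)
        return float("nan")
    return float(np.mean(-a_star[plant_mask]))


def canopy_height(
    dsm: np.ndarray,
    baseline_dsm: np.ndarray,
    plot_region: tuple[int, int, int, int] | None = None,
    plant_mask: np.ndarray | None = None,
    *,
    stat: str = "p95",
) -> float:
    """Per-plot canopy height from the DSM difference (observation - baseline).

    ``stat`` selects the per-plot summary: ``"p95"`` (default, 95th
    percentile of all in-plot differences), or ``"mean"`` / ``"median"``
    over the plant mask when one is supplied (over all plot pixels
    otherwise).  Negative values are permitted and reported.  Note only
    the mean summary is antisymmetric under swapping the two DSMs.
    """
    dsm = np.asarray(dsm, dtype=np.float64)
    baseline_dsm = np.asarray(baseline_dsm, dtype=np.float64)
    if dsm.shape != baseline_dsm.shape:
        raise ValueError(
            f"misaligned rasters: dsm {dsm.shape} vs baseline {baseline_dsm.shape}"
        )
    diff = _crop(dsm - baseline_dsm, plot_region)
    if plant_mask is not None:
        if plant_mask.shape != diff.shape:
            raise ValueError(
                f"plant mask shape {plant_mask.shape} != plot shape {diff.shape}"
            )
        if stat in ("mean", "median") and plant_mask.any():
            diff = diff[plant_mask]
    if stat == "p95":
        return float(np.percentile(diff, 95))
    if stat == "mean":
        return float(np.mean(diff))
    if stat == "median":
        return float(np.median(diff))
    raise ValueError(f"unknown summary statistic {stat!r}")


def measure_plots(
    rgb: np.ndarray,
    dsm: np.ndarray,
    baseline_dsm: np.ndarray,
    layout: pd.DataFrame | Sequence,
    *,
    stat: str = "p95",
    fallback_a_cutoff: float = -10.0,
) -> pd.DataFrame:
    """Extract CH (m), VF (%) and -a* for every plot in a layout.

    ``layout`` is a DataFrame with columns plot_id, row0, col0, row1, col1
    (0-based half-open) or a sequence of objects with those attributes.
    """
    if rgb.shape[:2] != dsm.shape or dsm.shape != baseline_dsm.shape:
        raise ValueError("rgb, dsm and baseline_dsm must share dimensions")
    if not isinstance(layout, pd.DataFrame):
        layout = pd.DataFrame(
            [(p.plot_id, p.row0, p.col0, p.row1, p.col1) for p in layout],
            columns=["plot_id", "row0", "col0", "row1", "col1"],
        )
    lab = rgb_to_lab(rgb)
    records = []
    for row in layout.itertuples(index=False):
        region = (row.row0, row.col0, row.row1, row.col1)
        vf, mask = vegetation_fraction(rgb, region, fallback_a_cutoff=fallback_a_cutoff)
        ch = canopy_height(dsm, baseline_dsm, region, mask, stat=stat)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            minus_a = leaf_colour(lab, mask, region)
        records.append((row.plot_id, ch, vf, minus_a, int(mask.sum())))
    return pd.DataFrame(
        records, columns=["plot_id", "CH_m", "VF_pct", "minus_a_star", "n_plant_pixels"]
    )


def _crop(image: np.ndarray, region: tuple[int, int, int, int] | None) -> np.ndarray:
    if region is None:
        return image
    row0, col0, row1, col1 = region
    if not (0 <= row0 < row1 <= image.shape[0] and 0 <= col0 < col1 <= image.shape[1]):
        raise ValueError(f"plot region {region} outside image of shape {image.shape[:2]}")
    return image[row0:row1, col0:col1]
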