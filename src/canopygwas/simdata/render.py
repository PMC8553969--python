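"""Render synthetic orthomosaic + DSM scenes from per-plot trait values.

Plant canopies are drawn as unions of disks around a 3 x 11 planting grid
inside each plot rectangle; the disk radius is chosen from the in-plot
distance transform so the rendered plant-pixel fraction matches the
requested vegetation fraction up to pixel quantisation.  Colours are
composed in CIELAB (plant a* = -requested -a*, soil a* mildly positive)
and converted to 8-bit sRGB.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import color as skcolor


@dataclass(frozen=True)
class PlotRect:
    """Axis-aligned plot rectangle, 0-based half-open pixel coordinates."""

    plot_id: str
    row0: int
    col0: int
    row1: int
    col1: int

    def __post_init__(self):
        if self.row1 <= self.row0 or self.col1 <= self.col0:
            raise ValueError(f"empty plot rectangle {self.plot_id!r}")

    @property
    def shape(self):
        return (self.row1 - self.row0, self.col1 - self.col0)

    def slices(self):
        return (slice(self.row0, self.row1), slice(self.col0, self.col1))


@dataclass
class RasterScene:
    """An RGB orthomosaic, observation DSM and pre-transplant baseline DSM."""

    rgb: np.ndarray            # H x W x 3 uint8
    dsm: np.ndarray            # H x W metres
    baseline_dsm: np.ndarray   # H x W metres
    resolution_m: float
    plots: Sequence[PlotRect]
    truth: pd.DataFrame | None = None  # per-plot requested values + masks stats

    def __post_init__(self):
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError("rgb must be H x W x 3")
        if self.rgb.shape[:2] != self.dsm.shape or self.dsm.shape != self.baseline_dsm.shape:
            raise ValueError("rgb, dsm and baseline_dsm must share dimensions")
        for plot in self.plots:
            if plot.row1 > self.dsm.shape[0] or plot.col1 > self.dsm.shape[1]:
                raise ValueError(f"plot {plot.plot_id!r} extends outside the raster")

    def layout_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.plot_id, p.row0, p.col0, p.row1, p.col1) for p in self.plots],
            columns=["plot_id", "row0", "col0", "row1", "col1"],
        )


def grid_layout(
    n_plots: int,
    plot_shape: tuple[int, int],
    *,
    margin: int = 10,
    n_cols: int | None = None,
    plot_ids: Sequence[str] | None = None,
) -> tuple[list[PlotRect], tuple[int, int]]:
    """Lay out ``n_plots`` rectangles on a grid; returns (plots, canvas shape)."""
    ph, pw = plot_shape
    if n_cols is None:
        n_cols = int(np.ceil(np.sqrt(n_plots)))
    n_rows = int(np.ceil(n_plots / n_cols))
    plots = []
    for k in range(n_plots):
        r, c = divmod(k, n_cols)
        row0 = margin + r * (ph + margin)
        col0 = margin + c * (pw + margin)
        pid = plot_ids[k] if plot_ids is not None else f"P{k + 1:03d}"
        plots.append(PlotRect(pid, row0, col0, row0 + ph, col0 + pw))
    shape = (margin + n_rows * (ph + margin), margin + n_cols * (pw + margin))
    return plots, shape


def _plant_mask(shape: tuple[int, int], vf_pct: float, n_rows: int = 3, n_cols: int = 11) -> np.ndarray:
    """Disk-union canopy mask covering ~vf_pct% of the plot."""
    h, w = shape
    if vf_pct <= 0:
        return np.zeros(shape, bool)
    if vf_pct >= 100:
        return np.ones(shape, bool)
    # plant centres: planting grid, rows along the shorter plot axis
    if h <= w:
        rr = (np.arange(n_rows) + 0.5) * h / n_rows
        cc = (np.arange(n_cols) + 0.5) * w / n_cols
    else:
        rr = (np.arange(n_cols) + 0.5) * h / n_cols
        cc = (np.arange(n_rows) + 0.5) * w / n_rows
    seeds = np.zeros(shape, bool)
    for r in rr:
        for c in cc:
            seeds[min(int(r), h - 1), min(int(c), w - 1)] = True
    dist = ndimage.distance_transform_edt(~seeds)
    radius = np.quantile(dist, vf_pct / 100.0)
    return dist <= radius


def render_scene(
    plot_values: pd.DataFrame,
    *,
    plots: Sequence[PlotRect] | None = None,
    resolution_m: float = 0.002,
    plant_spacing_m: tuple[float, float] = (0.30, 0.18),
    base_elevation_m: float = 10.0,
    terrain_noise_sd_m: float = 0.0,
    canopy_noise_sd_m: float = 0.0,
    soil_lab: tuple[float, float, float] = (55.0, 8.0, 18.0),
    plant_lightness: float = 45.0,
    plant_b_star: float = 35.0,
    colour_noise_sd: float = 0.0,
    seed: int,
) -> RasterScene:
    """Render one observation scene.

    Parameters
    ----------
    plot_values
        One row per plot with columns ``plot_id``, ``ch_m`` (canopy height,
        metres), ``vf_pct`` (0-100) and ``minus_a_star``.
    plots
        Plot rectangles; by default a grid layout sized for a 3-row x
        11-plant plot at ``resolution_m`` (0.90 m x 1.98 m footprint).
    terrain_noise_sd_m
        Amplitude of smooth low-frequency noise added to the baseline DSM.
    """
    required = {"plot_id", "ch_m", "vf_pct", "minus_a_star"}
    missing = required - set(plot_values.columns)
    if missing:
        raise ValueError(f"plot_values is missing columns {sorted(missing)}")
    bad_vf = plot_values[(plot_values["vf_pct"] < 0) | (plot_values["vf_pct"] > 100)]
    if len(bad_vf):
        raise ValueError(
            f"requested VF outside [0, 100] for plot {bad_vf['plot_id'].iloc[0]!r}"
        )

    rng = np.random.default_rng(seed)
    if plots is None:
        row_pitch, plant_pitch = plant_spacing_m
        ph = max(int(round(3 * row_pitch / resolution_m)), 8)
        pw = max(int(round(11 * plant_pitch / resolution_m)), 8)
        plots, shape = grid_layout(len(plot_values), (ph, pw),
                                   plot_ids=list(plot_values["plot_id"]))
    else:
        plots = list(plots)
        shape = (max(p.row1 for p in plots) + 10, max(p.col1 for p in plots) + 10)
    if len(plots) != len(plot_values):
        raise ValueError("one value set per plot is required")

    h, w = shape
    baseline = np.full(shape, base_elevation_m, dtype=np.float64)
    if terrain_noise_sd_m > 0:
        rough = rng.normal(0.0, 1.0, shape)
        smooth = ndimage.gaussian_filter(rough, sigma=8.0)
        sd = smooth.std()
        if sd > 0:
            baseline += terrain_noise_sd_m * smooth / sd

    dsm = baseline.copy()
    lab = np.empty((h, w, 3), dtype=np.float64)
    lab[..., 0] = soil_lab[0] + (rng.normal(0, 1.5, shape) if colour_noise_sd >= 0 else 0)
    lab[..., 1] = soil_lab[1]
    lab[..., 2] = soil_lab[2]

    values = plot_values.set_index("plot_id")
    truth_rows = []
    for plot in plots:
        row = values.loc[plot.plot_id]
        mask = _plant_mask(plot.shape, float(row["vf_pct"]))
        sl = plot.slices()
        region_dsm = dsm[sl]
        region_dsm[mask] = baseline[sl][mask] + float(row["ch_m"])
        if canopy_noise_sd_m > 0 and mask.any():
            region_dsm[mask] += rng.normal(0.0, canopy_noise_sd_m, int(mask.sum()))
        region_lab = lab[sl]
        a_star = -float(row["minus_a_star"])
        region_lab[..., 0][mask] = plant_lightness
        region_lab[..., 1][mask] = a_star
        region_lab[..., 2][mask] = plant_b_star
        if colour_noise_sd > 0 and mask.any():
            region_lab[..., 1][mask] += rng.normal(0.0, colour_noise_sd, int(mask.sum()))
        truth_rows.append(
            (plot.plot_id, float(row["ch_m"]), float(row["vf_pct"]),
             float(row["minus_a_star"]), 100.0 * mask.mean(), int(mask.sum()))
        )

    rgb = np.clip(skcolor.lab2rgb(lab) * 255.0, 0, 255).round().astype(np.uint8)
    truth = pd.DataFrame(
        truth_rows,
        columns=["plot_id", "ch_m", "vf_pct", "minus_a_star", "rendered_vf_pct", "n_plant_pixels"],
    )
    return RasterScene(rgb, dsm, baseline, resolution_m, plots, truth)
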