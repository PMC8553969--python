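"""Validated readers and writers for the pipeline's tabular and raster formats.

Conventions
-----------
* Genomic positions are 1-based inclusive base pairs.
* Pixel rectangles are 0-based, half-open ``(row0, col0, row1, col1)``.
* Missing values are written as empty fields; lines starting with ``#``
  are treated as comments on read (used to carry the run-config hash).
* Haplotype matrices are TSV with lines as rows and SNPs as columns;
  entries are founder labels 1..8 or empty for missing.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from canopygwas.constants import FOUNDER_LABELS

PANEL_COLUMNS = ("snp_id", "chromosome", "position_bp")
TRAIT_COLUMNS = ("line_id", "trait", "year", "dat", "value")
LAYOUT_COLUMNS = ("plot_id", "row0", "col0", "row1", "col1")


class FormatError(ValueError):
    """A file failed schema validation; the message names the offender."""


# ---------------------------------------------------------------------------
# SNP panel
# ---------------------------------------------------------------------------

def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Check sortedness and per-chromosome position uniqueness."""
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise FormatError(f"panel is missing columns: {missing}")
    if panel["snp_id"].duplicated().any():
        dup = panel.loc[panel["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise FormatError(f"duplicate snp_id {dup!r} in panel")
    for chrom, grp in panel.groupby("chromosome", sort=False):
        pos = grp["position_bp"].to_numpy()
        bad = np.nonzero(np.diff(pos) <= 0)[0]
        if bad.size:
            snp = grp["snp_id"].iloc[bad[0] + 1]
            raise FormatError(
                f"panel positions not strictly increasing on chromosome {chrom}: "
                f"SNP {snp!r} at {pos[bad[0] + 1]} follows {pos[bad[0]]}"
            )
    chroms = panel["chromosome"].to_numpy()
    order = np.lexsort((panel["position_bp"].to_numpy(), chroms))
    if not np.array_equal(order, np.arange(len(panel))):
        raise FormatError("panel is not sorted by (chromosome, position_bp)")
    return panel


def read_panel(path: str | os.PathLike) -> pd.DataFrame:
    panel = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        dtype={"snp_id": str, "chromosome": int, "position_bp": int},
    )
    return validate_panel(panel)


def write_panel(panel: pd.DataFrame, path: str | os.PathLike, *, header_comment: str | None = None) -> None:
    validate_panel(panel)
    _write_table(panel[list(PANEL_COLUMNS)], path, sep="\t", header_comment=header_comment)


# ---------------------------------------------------------------------------
# Haplotype matrix
# ---------------------------------------------------------------------------

def validate_haplotypes(hap: pd.DataFrame) -> pd.DataFrame:
    values = hap.to_numpy(dtype=float)
    finite = values[np.isfinite(values)]
    bad = ~np.isin(finite, FOUNDER_LABELS)
    if bad.any():
        offender = finite[bad][0]
        raise FormatError(
            f"unknown founder label {offender!r}; expected one of {FOUNDER_LABELS}"
        )
    if hap.index.duplicated().any():
        dup = hap.index[hap.index.duplicated()][0]
        raise FormatError(f"duplicate line_id {dup!r} in haplotype matrix")
    return hap


def read_haplotypes(path: str | os.PathLike) -> pd.DataFrame:
    hap = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    hap.index = hap.index.astype(str)
    hap.index.name = "line_id"
    return validate_haplotypes(hap.astype(float))


def write_haplotypes(hap: pd.DataFrame, path: str | os.PathLike, *, header_comment: str | None = None) -> None:
    validate_haplotypes(hap)
    out = hap.copy()
    # integers with empty cells for missing
    out = out.astype(object)
    mask = pd.isna(hap)
    out = out.where(mask, hap.astype("Int64"))
    out[mask] = ""
    out.index.name = "line_id"
    _write_table(out, path, sep="\t", index=True, header_comment=header_comment)


# ---------------------------------------------------------------------------
# Trait table (long format)
# ---------------------------------------------------------------------------

def validate_traits(traits: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRAIT_COLUMNS if c not in traits.columns]
    if missing:
        raise FormatError(f"trait table is missing columns: {missing}")
    key = traits[["line_id", "trait", "year", "dat"]].astype(object)
    dup = key.duplicated()
    if dup.any():
        row = key[dup].iloc[0]
        raise FormatError(
            "duplicate trait key (line_id={line_id!r}, trait={trait!r}, "
            "year={year!r}, dat={dat!r})".format(**row.to_dict())
        )
    return traits


def read_traits(path: str | os.PathLike) -> pd.DataFrame:
    traits = pd.read_csv(
        path,
        comment="#",
        dtype={"line_id": str, "trait": str, "year": str},
    )
    traits["dat"] = traits["dat"].astype("Int64")
    return validate_traits(traits)


def write_traits(traits: pd.DataFrame, path: str | os.PathLike, *, header_comment: str | None = None) -> None:
    validate_traits(traits)
    out = traits[list(TRAIT_COLUMNS)].copy()
    out["dat"] = out["dat"].astype("Int64")
    _write_table(out, path, sep=",", header_comment=header_comment)


# ---------------------------------------------------------------------------
# Scan / QTL / effect tables
# ---------------------------------------------------------------------------

def write_scan(scan: pd.DataFrame, path: str | os.PathLike, *, header_comment: str | None = None) -> None:
    """Per-SNP scan TSV (snp_id, chromosome, position_bp, H, df, k, n, p)."""
    out = scan.reset_index() if scan.index.name == "snp_id" else scan
    _write_table(out, path, sep="\t", header_comment=header_comment)


def read_scan(path: str | os.PathLike) -> pd.DataFrame:
    scan = pd.read_csv(path, sep="\t", comment="#", dtype={"snp_id": str})
    return scan.set_index("snp_id")


def write_qtl_table(qtls: pd.DataFrame, path: str | os.PathLike, *, header_comment: str | None = None) -> None:
    _write_table(qtls, path, sep="\t", header_comment=header_comment)


def read_qtl_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_effects(effects: pd.DataFrame, path: str | os.PathLike, *, header_comment: str | None = None) -> None:
    _write_table(effects, path, sep=",", header_comment=header_comment)


def read_effects(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# Plot layout
# ---------------------------------------------------------------------------

def write_layout(layout: pd.DataFrame, path: str | os.PathLike, *, header_comment: str | None = None) -> None:
    missing = [c for c in LAYOUT_COLUMNS if c not in layout.columns]
    if missing:
        raise FormatError(f"layout is missing columns: {missing}")
    _write_table(layout[list(LAYOUT_COLUMNS)], path, sep="\t", header_comment=header_comment)


def read_layout(path: str | os.PathLike) -> pd.DataFrame:
    layout = pd.read_csv(path, sep="\t", comment="#", dtype={"plot_id": str})
    for col in ("row0", "col0", "row1", "col1"):
        layout[col] = layout[col].astype(int)
    bad = layout[(layout["row1"] <= layout["row0"]) | (layout["col1"] <= layout["col0"])]
    if len(bad):
        raise FormatError(f"empty/inverted plot rectangle for plot {bad['plot_id'].iloc[0]!r}")
    return layout


# ---------------------------------------------------------------------------
# Rasters
# ---------------------------------------------------------------------------

def write_raster_scene(scene, prefix: str | os.PathLike) -> dict:
    """Write a RasterScene as ``<prefix>_rgb.png`` + float32 TIFF DSMs + layout TSV."""
    prefix = str(prefix)
    paths = {
        "rgb": prefix + "_rgb.png",
        "dsm": prefix + "_dsm.tif",
        "baseline_dsm": prefix + "_baseline_dsm.tif",
        "layout": prefix + "_layout.tsv",
    }
    iio.imwrite(paths["rgb"], scene.rgb)
    tifffile.imwrite(paths["dsm"], scene.dsm.astype(np.float32))
    tifffile.imwrite(paths["baseline_dsm"], scene.baseline_dsm.astype(np.float32))
    write_layout(scene.layout_frame(), paths["layout"])
    return paths


def read_raster_parts(rgb_path, dsm_path, baseline_path, layout_path):
    rgb = np.asarray(iio.imread(rgb_path))
    dsm = tifffile.imread(dsm_path)
    baseline = tifffile.imread(baseline_path)
    layout = read_layout(layout_path)
    if rgb.shape[:2] != dsm.shape or dsm.shape != baseline.shape:
        raise FormatError(
            f"raster shapes disagree: rgb {rgb.shape[:2]}, dsm {dsm.shape}, "
            f"baseline {baseline.shape}"
        )
    return rgb, dsm, baseline, layout


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def linkage_to_newick(linkage: np.ndarray, labels: Sequence[str]) -> str:
    """Serialise a scipy linkage matrix as a Newick tree with branch lengths."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}

    def build(node: int) -> str:
        if node < n:
            return str(labels[node])
        row = linkage[node - n]
        left, right, height = int(row[0]), int(row[1]), float(row[2])
        parts = []
        for child in (left, right):
            subtree = build(child)
            length = max(height - heights[child], 0.0)
            parts.append(f"{subtree}:{length:.6g}")
        heights[node] = height
        return "(" + ",".join(parts) + ")"

    return build(2 * n - 2) + ";"


def write_newick(linkage: np.ndarray, labels: Sequence[str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(linkage_to_newick(linkage, labels) + "\n")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _write_table(df: pd.DataFrame, path, *, sep: str, index: bool = False,
                 header_comment: str | None = None) -> None:
    with open(path, "w", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep=sep, index=index, lineterminator="\n")
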