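"""Protein distribution maps: construction on the grid, rendering, completeness.

A :class:`ProteinMap` places one protein's (normalized or z-scored) values onto
the occupied wells of the micro-scaffold grid.  Rendering follows the familiar
green-to-red display convention for tissue maps (z-scale maps clip to
[-1, 1] by default); missing measurements render light gray and unoccupied
wells stay background white, so off-tissue grid positions are visually empty.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .gridio import QuantMatrix, SpatialGrid, Well, match_samples

#: three-anchor green -> yellow -> red gradient (position, RGB), fixed for
#: reproducibility; low abundance green, high abundance red
GREEN_RED_ANCHORS = ((0.0, (0, 150, 0)), (0.5, (255, 235, 59)), (1.0, (220, 0, 0)))
MISSING_RGB = (211, 211, 211)  # light gray: well occupied but value missing
BACKGROUND_RGB = (255, 255, 255)  # white: well not on tissue
DEFAULT_BLOCK_PX = 16


@dataclass
class ProteinMap:
    """One protein's values on the occupied wells of a grid."""

    grid: SpatialGrid
    protein_id: str
    cell_values: dict[Well, float]  # NaN marks an occupied-but-missing well
    scale_tag: str

    def __post_init__(self) -> None:
        if set(self.cell_values) != set(self.grid.wells):
            raise ValueError("cell_values keys must equal the grid's occupied wells")
        for w, v in self.cell_values.items():
            if v is not None and np.isinf(v):
                raise ValueError(f"non-finite value at well {w}")

    def values_vector(self) -> np.ndarray:
        """Values in row-major well order (NaN where missing)."""
        return np.array([self.cell_values[w] for w in self.grid.sorted_wells()], dtype=float)

    @property
    def n_observed(self) -> int:
        return int(np.sum(~np.isnan(self.values_vector())))

    def observed_fraction(self) -> float:
        return self.n_observed / self.grid.n_wells


def build_map(q: QuantMatrix, g: SpatialGrid, protein: str) -> ProteinMap:
    """Place one protein's per-specimen values onto the grid.

    A pure re-indexing: each occupied well receives the value measured in the
    specimen cut from that well; an unmeasured specimen yields a missing cell.
    """
    if protein not in set(q.feature_ids):
        near = difflib.get_close_matches(protein, q.feature_ids, n=5)
        hint = f"; did you mean {near}?" if near else ""
        raise KeyError(f"protein {protein!r} not in matrix{hint}")
    qg = match_samples(q, g)
    col = qg.values[protein]
    cells: dict[Well, float] = {}
    for w in g.sorted_wells():
        sid = g.specimen_at(w)
        cells[w] = float(col[sid]) if sid in col.index and pd.notna(col.get(sid)) else np.nan
    return ProteinMap(grid=g, protein_id=protein, cell_values=cells, scale_tag=q.scale_tag)


def _interp_anchor_colormap(t: np.ndarray) -> np.ndarray:
    """Map t in [0,1] through the green->yellow->red anchors; returns uint8 RGB."""
    pos = np.array([p for p, _ in GREEN_RED_ANCHORS])
    cols = np.array([c for _, c in GREEN_RED_ANCHORS], dtype=float)
    out = np.empty(t.shape + (3,), dtype=float)
    for ch in range(3):
        out[..., ch] = np.interp(t, pos, cols[:, ch])
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def map_to_rgb(
    m: ProteinMap,
    clip: tuple[float, float] | None = None,
    colormap: str = "green-red",
    block_px: int = DEFAULT_BLOCK_PX,
) -> np.ndarray:
    """Rasterize a map to an RGB array (one block of pixels per well)."""
    if clip is None:
        clip = (-1.0, 1.0) if m.scale_tag == "zscore" else _data_range(m)
    lo, hi = clip
    if not lo < hi:
        raise ValueError(f"clip range must satisfy lo < hi, got {clip}")
    img = np.full((m.grid.n_rows, m.grid.n_cols, 3), BACKGROUND_RGB, dtype=np.uint8)
    vals = m.values_vector()
    wells = m.grid.sorted_wells()
    t = np.clip((vals - lo) / (hi - lo), 0.0, 1.0)
    if colormap == "green-red":
        rgb = _interp_anchor_colormap(np.nan_to_num(t))
    else:  # any matplotlib colormap name
        import matplotlib.pyplot as plt

        rgb = (np.asarray(plt.get_cmap(colormap)(np.nan_to_num(t)))[:, :3] * 255).astype(np.uint8)
    for k, (r, c) in enumerate(wells):
        img[r, c] = MISSING_RGB if np.isnan(vals[k]) else rgb[k]
    return np.kron(img, np.ones((block_px, block_px, 1), dtype=np.uint8))


def render_map(
    m: ProteinMap,
    out: str | Path,
    clip: tuple[float, float] | None = None,
    colormap: str = "green-red",
    block_px: int = DEFAULT_BLOCK_PX,
) -> None:
    """Write the map as a PNG raster (one ``block_px`` square per well)."""
    Image.fromarray(map_to_rgb(m, clip=clip, colormap=colormap, block_px=block_px)).save(
        Path(out), format="PNG"
    )


def _data_range(m: ProteinMap) -> tuple[float, float]:
    v = m.values_vector()
    if np.all(np.isnan(v)):
        return (0.0, 1.0)
    lo, hi = float(np.nanmin(v)), float(np.nanmax(v))
    return (lo, hi) if lo < hi else (lo - 0.5, hi + 0.5)


def map_completeness(q: QuantMatrix, g: SpatialGrid) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-protein observed-well fractions plus the two headline summaries.

    Returns a table (``observed_fraction`` per protein, over the grid's
    occupied wells) and the fractions of proteins with a complete map
    (observed at every location) and with ≥95 % of locations observed.
    """
    qg = match_samples(q, g)
    n_wells = g.n_wells  # specimens absent from the matrix count as missing wells
    observed = qg.values.notna().sum(axis=0)
    frac = (observed / n_wells).rename("observed_fraction")
    table = frac.to_frame().rename_axis("protein_id")
    summary = {
        "complete_fraction": float((frac == 1.0).mean()),
        "fraction_ge_95": float((frac >= 0.95).mean()),
    }
    return table, summary
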