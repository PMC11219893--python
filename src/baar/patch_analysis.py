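"""Contiguous forest / deforestation patch extraction.

Two minimum-size filters drive the pipeline: eligible forest keeps only
contiguous forest blocks of at least 5,000 ha, and deforestation patches
below 0.18 ha (two 30 m pixels) are discarded before risk buffering.
Connected components come from ``scipy.ndimage``; connectivity defaults to
8 (diagonal pairs count, so a two-pixel diagonal patch passes the 0.18 ha
threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .landscape_io import ForestHistory, GridLayer

#: Minimum contiguous forest block retained for risk mapping (ha).
MIN_FOREST_HA = 5000.0
#: Minimum deforestation patch area (ha) — two 30 m pixels.
MIN_PATCH_HA = 0.18
DEFAULT_CONNECTIVITY = 8


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    if connectivity == 8:
        return ndimage.generate_binary_structure(2, 2)
    raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")


@dataclass(frozen=True)
class Patch:
    """One contiguous deforestation region.

    ``cells`` holds (row, col) grid indices; ``a_p`` is the patch area in
    hectares (cell count times cell area).
    """

    patch_id: int
    cells: frozenset[tuple[int, int]]
    a_p: float

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass
class PatchSet:
    patches: list[Patch] = field(default_factory=list)
    cell_area_ha: float = 0.0
    labels: np.ndarray | None = None  # same shape as source mask, 0=background

    def __iter__(self):
        return iter(self.patches)

    def __len__(self) -> int:
        return len(self.patches)

    @property
    def total_area_ha(self) -> float:
        return float(sum(p.a_p for p in self.patches))

    def to_frame(self, grid: GridLayer | None = None) -> pd.DataFrame:
        """Patch table (id, cell count, area, centroid in map coordinates)."""
        rows = []
        for p in self.patches:
            rr = np.array([c[0] for c in p.cells], dtype=float)
            cc = np.array([c[1] for c in p.cells], dtype=float)
            if grid is not None:
                cx = grid.origin_x + (cc.mean() + 0.5) * grid.pixel_size
                cy = grid.origin_y - (rr.mean() + 0.5) * grid.pixel_size
            else:
                cx, cy = cc.mean(), rr.mean()
            rows.append((p.patch_id, p.n_cells, p.a_p, cx, cy))
        return pd.DataFrame(
            rows, columns=["patch_id", "n_cells", "a_p_ha", "centroid_x", "centroid_y"]
        )

    def to_csv(self, path: str | Path, grid: GridLayer | None = None) -> Path:
        self.to_frame(grid).to_csv(path, index=False)
        return Path(path)


def extract_eligible_forest(
    forest_t0: GridLayer, min_area_ha: float = MIN_FOREST_HA,
    connectivity: int = DEFAULT_CONNECTIVITY,
) -> GridLayer:
    """Drop contiguous forest blocks smaller than ``min_area_ha``.

    Returns a binary layer keeping only components whose area is at least
    the threshold; an empty result is valid.
    """
    mask = forest_t0.values == 1
    labels, n = ndimage.label(mask, structure=_structure(connectivity))
    if n == 0:
        return forest_t0.like(np.zeros_like(forest_t0.values, dtype=np.int32))
    counts = np.bincount(labels.ravel())
    min_cells = min_area_ha / forest_t0.cell_area_ha
    keep = counts >= min_cells
    keep[0] = False
    out = keep[labels].astype(np.int32)
    return forest_t0.like(out)


def label_patches(
    defor_mask: GridLayer,
    connectivity: int = DEFAULT_CONNECTIVITY,
    min_area_ha: float = MIN_PATCH_HA,
) -> PatchSet:
    """Label contiguous deforestation patches, dropping sub-threshold ones.

    The default threshold keeps patches of at least 0.18 ha, so a pair of
    30 m pixels passes (with 8-connectivity even a diagonal pair).
    Patch ids are assigned in scan order and are 1-based.
    """
    mask = defor_mask.values == 1
    labels, n = ndimage.label(mask, structure=_structure(connectivity))
    cell_area = defor_mask.cell_area_ha
    min_cells = min_area_ha / cell_area

    patches: list[Patch] = []
    out_labels = np.zeros_like(labels)
    next_id = 1
    if n:
        objects = ndimage.find_objects(labels)
        for lab, sl in enumerate(objects, start=1):
            if sl is None:
                continue
            local = labels[sl] == lab
            count = int(local.sum())
            if count < min_cells:
                continue
            rr, cc = np.nonzero(local)
            cells = frozenset(
                (int(r + sl[0].start), int(c + sl[1].start)) for r, c in zip(rr, cc)
            )
            patches.append(Patch(next_id, cells, count * cell_area))
            out_labels[sl][local] = next_id
            next_id += 1
    return PatchSet(patches=patches, cell_area_ha=cell_area, labels=out_labels)


def period_defor_mask(
    history: ForestHistory, start_year: int, end_year: int
) -> GridLayer:
    """Binary mask of cells lost in the half-open window (start_year, end_year].

    Half-open windows let calibration and validation share a boundary year
    without double counting.
    """
    if start_year >= end_year:
        raise ValueError("start_year must be < end_year")
    if start_year < history.calib_start or end_year > history.valid_end:
        raise ValueError(
            f"window ({start_year}, {end_year}] outside history coverage "
            f"[{history.calib_start}, {history.valid_end}]"
        )
    years = history.defor_year
    lost = years.mask() & (years.values > start_year) & (years.values <= end_year)
    return years.like(lost.astype(np.int32), nodata=-9999)
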