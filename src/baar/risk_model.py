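"""High/low deforestation-risk stratification via dynamic area-multiple buffers.

Each historical deforestation patch of area ``a_p`` is buffered outward by

    r_high = sqrt((a_p * m + a_p) / pi) - sqrt(a_p / pi)

(the ring width that multiplies the equivalent circle's area by ``m``), so
larger patches — stronger deforestation frontiers — project risk further
into the surrounding forest.  Forest within any patch's buffer is high risk;
the rest of the eligible forest is low risk.  The multiple ``m`` is the
dial: the canonical exploratory series spans m = 1 to 120.

The canonical buffer is vector-based: the patch's pixel footprint is
polygonised and cells are selected by exact Euclidean distance from their
centre to the polygon.  A pure-raster Euclidean-distance-transform mode is
provided as a non-canonical alternative (distances measured centre-to-centre).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from scipy import ndimage

from .landscape_io import GridLayer, M2_PER_HA, layer_area, require_aligned, write_raster
from .patch_analysis import Patch, PatchSet

logger = logging.getLogger(__name__)

#: Exploratory series of area multiples.
DEFAULT_M_LIST = (1, 2, 3, 6, 9, 12, 15, 30, 45, 60, 75, 90, 105, 120)

#: Risk-map raster codes.
CODE_OUTSIDE, CODE_LOW, CODE_HIGH = 0, 1, 2


def buffer_radius(a_p: float, m: float) -> float:
    """Buffer distance (m) giving a ring of ``m`` times the patch area.

    Parameters
    ----------
    a_p
        Patch area in hectares; must be positive.
    m
        Dimensionless area multiple; must be >= 0 (m = 0 gives r = 0).
    """
    if a_p <= 0:
        raise ValueError(f"patch area must be positive, got {a_p} ha")
    if m < 0:
        raise ValueError(f"area multiple must be >= 0, got {m}")
    a = a_p * M2_PER_HA  # to square metres
    return math.sqrt((a * m + a) / math.pi) - math.sqrt(a / math.pi)


@dataclass(frozen=True)
class RiskBufferSpec:
    """Per-patch buffer log entry."""

    patch_id: int
    m: float
    r_high: float


@dataclass
class RiskMap:
    """Binary high/low risk stratification of the eligible forest."""

    high_mask: GridLayer
    low_mask: GridLayer
    m: float
    period: str = ""
    buffer_specs: list[RiskBufferSpec] = field(default_factory=list)

    @property
    def A_high(self) -> float:
        return layer_area(self.high_mask)

    @property
    def A_low(self) -> float:
        return layer_area(self.low_mask)

    def codes(self) -> GridLayer:
        """Single-layer encoding: 0 outside, 1 low risk, 2 high risk."""
        out = np.full(self.high_mask.shape, CODE_OUTSIDE, dtype=np.int32)
        out[self.low_mask.values == 1] = CODE_LOW
        out[self.high_mask.values == 1] = CODE_HIGH
        return self.high_mask.like(out)


def _patch_footprint(patch: Patch, grid: GridLayer) -> shapely.Geometry:
    """Polygonised pixel footprint of a patch (union of cell squares)."""
    px = grid.pixel_size
    rows = np.array([c[0] for c in patch.cells])
    cols = np.array([c[1] for c in patch.cells])
    x0 = grid.origin_x + cols * px
    y1 = grid.origin_y - rows * px
    boxes = shapely.box(x0, y1 - px, x0 + px, y1)
    return shapely.unary_union(boxes)


def _window(grid: GridLayer, rows: np.ndarray, cols: np.ndarray,
            pad_cells: int) -> tuple[slice, slice]:
    nrows, ncols = grid.shape
    r0 = max(int(rows.min()) - pad_cells, 0)
    r1 = min(int(rows.max()) + pad_cells + 1, nrows)
    c0 = max(int(cols.min()) - pad_cells, 0)
    c1 = min(int(cols.max()) + pad_cells + 1, ncols)
    return slice(r0, r1), slice(c0, c1)


def _buffer_cells_vector(patch: Patch, grid: GridLayer, r: float) -> tuple[slice, slice, np.ndarray]:
    """Cells whose centres lie within distance r of the patch footprint."""
    rows = np.array([c[0] for c in patch.cells])
    cols = np.array([c[1] for c in patch.cells])
    pad = int(math.ceil(r / grid.pixel_size)) + 1
    rsl, csl = _window(grid, rows, cols, pad)
    footprint = _patch_footprint(patch, grid)
    shapely.prepare(footprint)
    xs = grid.x_centers()[csl]
    ys = grid.y_centers()[rsl]
    xg, yg = np.meshgrid(xs, ys)
    pts = shapely.points(xg.ravel(), yg.ravel())
    hit = shapely.dwithin(footprint, pts, r).reshape(xg.shape)
    return rsl, csl, hit


def _buffer_cells_raster(patch: Patch, grid: GridLayer, r: float) -> tuple[slice, slice, np.ndarray]:
    """Cells within Euclidean centre-to-centre distance r of patch cells."""
    rows = np.array([c[0] for c in patch.cells])
    cols = np.array([c[1] for c in patch.cells])
    pad = int(math.ceil(r / grid.pixel_size)) + 1
    rsl, csl = _window(grid, rows, cols, pad)
    local = np.ones((rsl.stop - rsl.start, csl.stop - csl.start), dtype=bool)
    local[rows - rsl.start, cols - csl.start] = False
    dist = ndimage.distance_transform_edt(local, sampling=grid.pixel_size)
    return rsl, csl, dist <= r


def build_risk_map(
    patches: PatchSet,
    eligible_forest_now: GridLayer,
    m: float,
    mode: str = "vector",
    period: str = "",
) -> RiskMap:
    """Stratify the eligible forest into high and low risk for one multiple.

    ``eligible_forest_now`` must be the binary mask of eligible forest still
    standing at the prediction start (already-deforested cells excluded).
    The patch footprints themselves are not forest and never count as high
    risk.  Buffers are unioned across patches, then clipped to the eligible
    forest; buffers running past the grid edge are clipped to the grid.
    """
    if mode not in {"vector", "raster"}:
        raise ValueError(f"mode must be 'vector' or 'raster', got {mode!r}")
    eligible = eligible_forest_now.values == 1
    high = np.zeros(eligible_forest_now.shape, dtype=bool)
    specs: list[RiskBufferSpec] = []
    select = _buffer_cells_vector if mode == "vector" else _buffer_cells_raster
    for patch in patches:
        r = buffer_radius(patch.a_p, m)
        specs.append(RiskBufferSpec(patch.patch_id, m, r))
        if r <= 0:
            continue
        rsl, csl, hit = select(patch, eligible_forest_now, r)
        high[rsl, csl] |= hit
    high &= eligible
    if patches.labels is not None:
        high &= patches.labels == 0  # defensive: footprints are not forest
    low = eligible & ~high
    logger.info(
        "risk map m=%s: %d patches, A_high=%.2f ha, A_low=%.2f ha",
        m, len(patches), high.sum() * eligible_forest_now.cell_area_ha,
        low.sum() * eligible_forest_now.cell_area_ha,
    )
    return RiskMap(
        high_mask=eligible_forest_now.like(high.astype(np.int32)),
        low_mask=eligible_forest_now.like(low.astype(np.int32)),
        m=m,
        period=period,
        buffer_specs=specs,
    )


def risk_map_series(
    patches: PatchSet,
    eligible_forest_now: GridLayer,
    m_list: list[float],
    mode: str = "vector",
    period: str = "",
) -> list[RiskMap]:
    """One RiskMap per multiple; ``m_list`` must be ascending and unique."""
    if not m_list:
        raise ValueError("m_list must be nonempty")
    if len(set(m_list)) != len(m_list):
        raise ValueError("duplicate m values in m_list")
    if list(m_list) != sorted(m_list):
        raise ValueError("m_list must be ascending")
    return [
        build_risk_map(patches, eligible_forest_now, m, mode=mode, period=period)
        for m in m_list
    ]


def write_risk_map(risk_map: RiskMap, path: str | Path) -> Path:
    """Write the coded raster plus a JSON sidecar with m, areas and period."""
    path = Path(path)
    write_raster(risk_map.codes(), path)
    meta = {
        "m": risk_map.m,
        "A_high_ha": risk_map.A_high,
        "A_low_ha": risk_map.A_low,
        "period": risk_map.period,
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1) + "\n")
    return path


def read_risk_map(path: str | Path) -> RiskMap:
    from .landscape_io import read_raster

    codes = read_raster(path)
    meta = json.loads(Path(str(path) + ".meta.json").read_text())
    return RiskMap(
        high_mask=codes.like((codes.values == CODE_HIGH).astype(np.int32)),
        low_mask=codes.like((codes.values == CODE_LOW).astype(np.int32)),
        m=meta["m"],
        period=meta.get("period", ""),
    )
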