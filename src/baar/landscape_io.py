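"""Raster/vector/table I/O and exact area accounting for the BAAR pipeline.

All maps are carried by :class:`GridLayer`, a georeferenced categorical cell
grid in an equal-area projected CRS.  Rasters are stored as ESRI ASCII grids
(``.asc``) with a small JSON sidecar for the CRS identifier — a plain-text
format every GIS reads.  Vectors are GeoJSON handled through ``shapely``;
lookup tables are CSV.

Area accounting is exact cell counting: a cell covers ``pixel_size**2 / 1e4``
hectares and categorical values are never interpolated.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

M2_PER_HA = 10_000.0

#: CRS identifiers that are known to be geographic (degree units).  Area
#: accounting is meaningless on these grids, so they are rejected outright.
GEOGRAPHIC_CRS_IDS = frozenset(
    {"EPSG:4326", "EPSG:4269", "EPSG:4267", "OGC:CRS84", "CRS84"}
)
_GEOGRAPHIC_MARKERS = ("longlat", "degree", "4326")

SIDECAR_SUFFIX = ".aux.json"


def _check_equal_area_crs(crs_id: str | None) -> None:
    if not crs_id:
        raise ValueError(
            "equal-area CRS required: the grid has no CRS identifier; area "
            "accounting needs a projected equal-area CRS in metres"
        )
    canon = str(crs_id).strip().upper()
    if canon in GEOGRAPHIC_CRS_IDS or any(
        marker in str(crs_id).lower() for marker in _GEOGRAPHIC_MARKERS
    ):
        raise ValueError(
            f"equal-area CRS required: {crs_id!r} is a geographic "
            "(degree-unit) CRS; reproject to an equal-area projection first"
        )


@dataclass
class GridLayer:
    """A georeferenced 2-D integer cell grid.

    Row 0 is the top (northern) row; ``origin_x``/``origin_y`` locate the
    outer corner of cell (0, 0), i.e. the north-west corner of the grid, in
    map units (metres).  A cell is identified by its centre.

    Parameters
    ----------
    values
        2-D integer array of categorical codes.
    origin_x, origin_y
        Map coordinates (m) of the grid's north-west corner.
    pixel_size
        Side length of a cell in metres; must be positive.
    crs_id
        Identifier of an equal-area projected CRS (e.g. ``"ESRI:54034"``).
        Geographic CRS identifiers are refused.
    nodata
        Integer code marking cells with no data.
    """

    values: np.ndarray
    origin_x: float
    origin_y: float
    pixel_size: float
    crs_id: str
    nodata: int = -9999

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("GridLayer values must be a 2-D array")
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError(
                f"GridLayer holds categorical integer codes, got dtype "
                f"{self.values.dtype}"
            )
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        _check_equal_area_crs(self.crs_id)

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_area_ha(self) -> float:
        return self.pixel_size**2 / M2_PER_HA

    def x_centers(self) -> np.ndarray:
        """x map coordinate of every column's cell centres."""
        cols = np.arange(self.shape[1])
        return self.origin_x + (cols + 0.5) * self.pixel_size

    def y_centers(self) -> np.ndarray:
        """y map coordinate of every row's cell centres (descending)."""
        rows = np.arange(self.shape[0])
        return self.origin_y - (rows + 0.5) * self.pixel_size

    def center_meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x_centers(), self.y_centers())

    def same_grid(self, other: "GridLayer") -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.origin_x, other.origin_x, abs_tol=1e-6)
            and math.isclose(self.origin_y, other.origin_y, abs_tol=1e-6)
            and math.isclose(self.pixel_size, other.pixel_size, abs_tol=1e-9)
            and self.crs_id == other.crs_id
        )

    def like(self, values: np.ndarray, nodata: int | None = None) -> "GridLayer":
        """New layer with the same grid geometry but different values."""
        return replace(
            self,
            values=np.asarray(values),
            nodata=self.nodata if nodata is None else nodata,
        )

    def mask(self) -> np.ndarray:
        """Boolean array of valid (non-nodata) cells."""
        return self.values != self.nodata


def require_aligned(*layers: GridLayer) -> None:
    """Raise if the layers do not share one grid geometry.

    Resampling is deliberately out of scope: mismatched grids are errors,
    never silent warps.
    """
    first = layers[0]
    for other in layers[1:]:
        if not first.same_grid(other):
            raise ValueError(
                "grid geometry mismatch: all input layers must share shape, "
                f"origin, pixel size and CRS (got {first.shape}@"
                f"{first.pixel_size} m {first.crs_id} vs {other.shape}@"
                f"{other.pixel_size} m {other.crs_id})"
            )


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class ForestHistory:
    """Forest benchmark plus per-cell deforestation year.

    ``forest_t0`` is the binary forest mask at the start of the reference
    period; ``defor_year`` holds the year each cell was lost (nodata = never
    lost).  Two-epoch activity data degrade gracefully: encode each epoch's
    loss with its end year.
    """

    forest_t0: GridLayer
    defor_year: GridLayer
    calib_start: int
    calib_end: int
    valid_end: int

    def __post_init__(self) -> None:
        require_aligned(self.forest_t0, self.defor_year)
        if not (self.calib_start < self.calib_end <= self.valid_end):
            raise ValueError(
                "period years must satisfy calib_start < calib_end <= valid_end"
            )
        lost = self.defor_year.mask()
        if np.any(lost & (self.forest_t0.values != 1)):
            raise ValueError(
                "inconsistent history: cells with a deforestation year must "
                "be forest in the benchmark map"
            )

    def forest_remaining(self, year: int) -> GridLayer:
        """Binary mask of benchmark forest not yet lost by the end of `year`."""
        lost = self.defor_year.mask() & (self.defor_year.values <= year)
        remaining = (self.forest_t0.values == 1) & ~lost
        return self.forest_t0.like(remaining.astype(np.int32), nodata=-9999)


@dataclass
class CarbonStratumLayer:
    """Forest-type codes with a carbon-stock lookup (tCO2e/ha)."""

    strata: GridLayer
    lookup: dict[int, tuple[str, float]]

    def __post_init__(self) -> None:
        codes = np.unique(self.strata.values[self.strata.mask()])
        missing = [int(c) for c in codes if int(c) not in self.lookup]
        if missing:
            raise ValueError(f"stratum codes without a lookup entry: {missing}")
        for code, (name, stock) in self.lookup.items():
            if stock < 0:
                raise ValueError(
                    f"mean carbon stock must be >= 0 (code {code} '{name}': {stock})"
                )

    def stock_map(self) -> np.ndarray:
        """Per-cell mean carbon stock (tCO2e/ha); NaN on nodata cells."""
        out = np.full(self.strata.shape, np.nan)
        for code, (_, stock) in self.lookup.items():
            out[self.strata.values == code] = stock
        out[~self.strata.mask()] = np.nan
        return out


@dataclass(frozen=True)
class Project:
    project_id: int
    geometry: BaseGeometry
    start_year: int


@dataclass
class ProjectSet:
    projects: list[Project] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.project_id for p in self.projects]
        if len(ids) != len(set(ids)):
            raise ValueError("project ids must be unique")
        if any(i == 0 for i in ids):
            raise ValueError("project id 0 is reserved for background")
        bad = [p.project_id for p in self.projects if not p.geometry.is_valid]
        if bad:
            raise ValueError(f"invalid (self-intersecting?) polygons for ids: {bad}")

    def __iter__(self):
        return iter(self.projects)

    def __len__(self) -> int:
        return len(self.projects)


# ---------------------------------------------------------------------------
# Raster I/O (ESRI ASCII grid + JSON sidecar)
# ---------------------------------------------------------------------------


def write_raster(layer: GridLayer, path: str | Path) -> Path:
    """Write a GridLayer as an ESRI ASCII grid with a CRS sidecar."""
    path = Path(path)
    nrows, ncols = layer.shape
    yll = layer.origin_y - nrows * layer.pixel_size
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {layer.origin_x!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {layer.pixel_size!r}\n"
        f"NODATA_value {layer.nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, layer.values, fmt="%d")
    sidecar = {"crs_id": layer.crs_id, "nodata": int(layer.nodata)}
    Path(str(path) + SIDECAR_SUFFIX).write_text(json.dumps(sidecar) + "\n")
    return path


def read_raster(path: str | Path, band: int = 1) -> GridLayer:
    """Read an ESRI ASCII grid written by :func:`write_raster`.

    ASCII grids are single-band; ``band`` must be 1.  The CRS identifier is
    taken from the JSON sidecar and must name an equal-area projected CRS.
    """
    if band != 1:
        raise ValueError("ASCII grids are single-band; band must be 1")
    path = Path(path)
    header: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner",
                "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = parts[1]
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        values = np.loadtxt(fh, dtype=np.int64, ndmin=2)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if values.shape != (nrows, ncols):
        raise ValueError(f"raster body {values.shape} does not match header "
                         f"({nrows}, {ncols})")
    pixel = float(header["cellsize"])
    nodata = int(header.get("nodata_value", -9999))

    sidecar_path = Path(str(path) + SIDECAR_SUFFIX)
    if not sidecar_path.exists():
        raise ValueError(
            "equal-area CRS required: missing sidecar "
            f"{sidecar_path.name}; cannot verify the grid's projection"
        )
    sidecar = json.loads(sidecar_path.read_text())
    return GridLayer(
        values=values,
        origin_x=float(header["xllcorner"]),
        origin_y=float(header["yllcorner"]) + nrows * pixel,
        pixel_size=pixel,
        crs_id=sidecar["crs_id"],
        nodata=int(sidecar.get("nodata", nodata)),
    )


# ---------------------------------------------------------------------------
# Vector and table I/O
# ---------------------------------------------------------------------------


def write_projects(project_set: ProjectSet, path: str | Path,
                   crs_id: str | None = None) -> Path:
    features = [
        {
            "type": "Feature",
            "properties": {"project_id": p.project_id, "start_year": p.start_year},
            "geometry": mapping(p.geometry),
        }
        for p in project_set
    ]
    doc = {"type": "FeatureCollection", "features": features}
    if crs_id:
        doc["crs"] = {"type": "name", "properties": {"name": crs_id}}
    path = Path(path)
    path.write_text(json.dumps(doc, indent=1) + "\n")
    return path


def read_projects(path: str | Path) -> ProjectSet:
    doc = json.loads(Path(path).read_text())
    projects = [
        Project(
            project_id=int(f["properties"]["project_id"]),
            geometry=shape(f["geometry"]),
            start_year=int(f["properties"]["start_year"]),
        )
        for f in doc["features"]
    ]
    return ProjectSet(projects)


def read_carbon_table(path: str | Path) -> dict[int, tuple[str, float]]:
    """Read a carbon-stock lookup CSV with columns code,name,stock_tco2e_ha."""
    df = pd.read_csv(path)
    required = {"code", "name", "stock_tco2e_ha"}
    if not required.issubset(df.columns):
        raise ValueError(f"carbon table needs columns {sorted(required)}, "
                         f"got {list(df.columns)}")
    return {
        int(row.code): (str(row.name_), float(row.stock_tco2e_ha))
        for row in df.rename(columns={"name": "name_"}).itertuples()
    }


def write_carbon_table(lookup: dict[int, tuple[str, float]],
                       path: str | Path) -> Path:
    df = pd.DataFrame(
        [(code, name, stock) for code, (name, stock) in sorted(lookup.items())],
        columns=["code", "name", "stock_tco2e_ha"],
    )
    df.to_csv(path, index=False)
    return Path(path)


# ---------------------------------------------------------------------------
# Rasterization and area accounting
# ---------------------------------------------------------------------------


def rasterize_polygons(project_set: ProjectSet, template: GridLayer) -> GridLayer:
    """Label each cell with the id of the project polygon covering its centre.

    Cells outside every polygon get 0.  Overlapping project polygons are an
    error: a cell can belong to at most one project accounting area.
    """
    out = np.zeros(template.shape, dtype=np.int64)
    xs, ys = template.center_meshgrid()
    claimed = np.zeros(template.shape, dtype=bool)
    overlapping: set[int] = set()
    for project in project_set:
        inside = shapely.contains_xy(project.geometry, xs, ys)
        clash = inside & claimed
        if np.any(clash):
            overlapping.add(project.project_id)
            overlapping.update(int(i) for i in np.unique(out[clash]) if i != 0)
        out[inside] = project.project_id
        claimed |= inside
    if overlapping:
        raise ValueError(
            f"overlapping project polygons (share covered cells): "
            f"{sorted(overlapping)}"
        )
    return template.like(out, nodata=-9999)


def layer_area(mask: GridLayer) -> float:
    """Area in hectares of the 1-cells of a binary mask layer."""
    vals = mask.values[mask.mask()]
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("layer_area expects a binary (0/1) mask")
    return float(np.count_nonzero(mask.values == 1)) * mask.cell_area_ha
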