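"""Seeded synthetic landscapes with the spatial structure the risk model assumes.

The generator emulates the inputs the pipeline needs — a forest benchmark
mask, per-cell deforestation years split into calibration and validation
periods, contiguous forest-type zones with carbon stocks, and rectangular
project polygons — on the premise that near-term loss clusters around past
loss.  Calibration-period patches are grown at random seeds with log-normal
sizes; validation-period loss is then drawn cell-by-cell with probability
proportional to exp(-d / lambda), d being the distance to the nearest
calibration patch, scaled to hit a target loss fraction in expectation.

A single ``numpy.random.default_rng`` stream, seeded once, drives placement,
sizes and loss draws in a fixed order, so one seed fixes the full output
bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage

from .landscape_io import (
    CarbonStratumLayer,
    ForestHistory,
    GridLayer,
    Project,
    ProjectSet,
)

#: Carbon stocks (tCO2e/ha) typical of a Congo-basin forest-type mosaic:
#: dense humid forest, secondary forest, dry/open forest.
DEFAULT_STOCKS = (747.0, 409.0, 245.0)
DEFAULT_CRS = "ESRI:54034"  # World Cylindrical Equal Area

NODATA_YEAR = -9999


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for one synthetic landscape.

    Defaults give a 200 x 200 grid of 1-ha cells (40,000 ha) with a mostly
    forested, connected landscape, 25 calibration patches of log-normal
    sizes (median 8 ha), a 300 m frontier decay length, and 3% of the
    remaining forest lost in the validation period.  The period split is the
    canonical 10-year calibration (2000-2010) / 4-year validation
    (2010-2014) window.
    """

    rows: int = 200
    cols: int = 200
    pixel_size: float = 100.0
    forest_fraction: float = 0.85
    n_calib_patches: int = 25
    patch_median_ha: float = 8.0
    patch_sigma: float = 0.8
    frontier_decay_m: float = 300.0
    validation_loss_fraction: float = 0.03
    n_forest_types: int = 3
    stocks: tuple[float, ...] = DEFAULT_STOCKS
    n_projects: int = 5
    seed: int = 0
    calib_start: int = 2000
    calib_end: int = 2010
    valid_end: int = 2014
    crs_id: str = DEFAULT_CRS

    def __post_init__(self) -> None:
        if not (0 < self.forest_fraction <= 1):
            raise ValueError("forest_fraction must be in (0, 1]")
        if not (0 <= self.validation_loss_fraction <= 1):
            raise ValueError("validation_loss_fraction must be in [0, 1]")
        if self.frontier_decay_m <= 0:
            raise ValueError("frontier_decay_m must be positive")
        if self.n_forest_types > len(self.stocks):
            raise ValueError("need a stock value per forest type")


def _forest_mask(params: SimulationParams, rng: np.random.Generator) -> np.ndarray:
    """Patchy but mostly-connected forest from thresholded smoothed noise."""
    noise = rng.normal(size=(params.rows, params.cols))
    field_ = ndimage.gaussian_filter(noise, sigma=6.0)
    cut = np.quantile(field_, 1.0 - params.forest_fraction)
    return field_ >= cut


def _grow_patch(
    seed_cell: tuple[int, int],
    target_cells: int,
    allowed: np.ndarray,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Random region growth from a seed, restricted to ``allowed`` cells."""
    nrows, ncols = allowed.shape
    taken = {seed_cell}
    frontier = [seed_cell]
    while len(taken) < target_cells and frontier:
        idx = rng.integers(len(frontier))
        r, c = frontier[idx]
        neighbours = [
            (r + dr, c + dc)
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1))
            if 0 <= r + dr < nrows and 0 <= c + dc < ncols
            and allowed[r + dr, c + dc] and (r + dr, c + dc) not in taken
        ]
        if neighbours:
            new = neighbours[rng.integers(len(neighbours))]
            taken.add(new)
            frontier.append(new)
        else:
            frontier.pop(idx)
    return sorted(taken)


def _voronoi_codes(params: SimulationParams, rng: np.random.Generator) -> np.ndarray:
    """Contiguous forest-type zones: nearest-seed (Voronoi) partition."""
    k = params.n_forest_types
    seeds_r = rng.integers(params.rows, size=k)
    seeds_c = rng.integers(params.cols, size=k)
    rr, cc = np.meshgrid(np.arange(params.rows), np.arange(params.cols), indexing="ij")
    d2 = (rr[..., None] - seeds_r) ** 2 + (cc[..., None] - seeds_c) ** 2
    return np.argmin(d2, axis=-1).astype(np.int32) + 1


def generate(
    params: SimulationParams,
) -> tuple[ForestHistory, CarbonStratumLayer, ProjectSet]:
    """Generate one seeded landscape: history, carbon strata and projects."""
    rng = np.random.default_rng(params.seed)
    px = params.pixel_size
    cell_area = px**2 / 1e4

    forest = _forest_mask(params, rng)

    # calibration patches: seeded region growth with log-normal target sizes
    sizes_ha = np.exp(
        rng.normal(np.log(params.patch_median_ha), params.patch_sigma,
                   size=params.n_calib_patches)
    )
    target_cells = np.maximum(2, np.round(sizes_ha / cell_area)).astype(int)
    if target_cells.sum() > 0.5 * forest.sum():
        raise ValueError(
            "infeasible params: calibration patches would consume more than "
            "half the forest"
        )
    defor_year = np.full((params.rows, params.cols), NODATA_YEAR, dtype=np.int32)
    available = forest.copy()
    forest_idx = np.flatnonzero(forest)
    calib_years = rng.integers(params.calib_start + 1, params.calib_end + 1,
                               size=params.n_calib_patches)
    for i in range(params.n_calib_patches):
        for _ in range(100):  # retry seeds landing on already-taken cells
            flat = int(forest_idx[rng.integers(len(forest_idx))])
            seed_cell = (flat // params.cols, flat % params.cols)
            if available[seed_cell]:
                break
        else:
            raise ValueError("infeasible params: no free forest cell for a patch seed")
        cells = _grow_patch(seed_cell, int(target_cells[i]), available, rng)
        for r, c in cells:
            defor_year[r, c] = calib_years[i]
            available[r, c] = False

    # validation loss: Bernoulli per remaining forest cell, p ~ exp(-d/lambda)
    calib_mask = defor_year != NODATA_YEAR
    remaining = forest & ~calib_mask
    dist = ndimage.distance_transform_edt(~calib_mask, sampling=px)
    # shift by the minimum distance among candidate cells before
    # exponentiating: proportionality is unchanged but tiny decay lengths
    # no longer underflow, so lambda -> 0 degrades to adjacent-cell loss
    weight = np.zeros_like(dist)
    if remaining.any():
        rel = dist[remaining] - dist[remaining].min()
        weight[remaining] = np.exp(-rel / params.frontier_decay_m)
    n_target = params.validation_loss_fraction * remaining.sum()
    total_w = weight.sum()
    if total_w > 0 and n_target > 0:
        p = np.minimum(1.0, weight * (n_target / total_w))
        draws = rng.random(size=p.shape) < p
        draws &= remaining
        valid_years = rng.integers(params.calib_end + 1, params.valid_end + 1,
                                   size=int(draws.sum()))
        defor_year[draws] = valid_years

    def layer(values: np.ndarray, nodata: int = -9999) -> GridLayer:
        return GridLayer(
            values=values, origin_x=0.0, origin_y=params.rows * px,
            pixel_size=px, crs_id=params.crs_id, nodata=nodata,
        )

    history = ForestHistory(
        forest_t0=layer(forest.astype(np.int32)),
        defor_year=layer(defor_year, nodata=NODATA_YEAR),
        calib_start=params.calib_start,
        calib_end=params.calib_end,
        valid_end=params.valid_end,
    )

    codes = _voronoi_codes(params, rng)
    lookup = {
        i + 1: (f"type_{i + 1}", float(params.stocks[i]))
        for i in range(params.n_forest_types)
    }
    carbon = CarbonStratumLayer(strata=layer(codes), lookup=lookup)

    # rectangular projects dropped on forest, non-overlapping
    projects: list[Project] = []
    occupied = np.zeros_like(forest)
    pid = 1
    attempts = 0
    while len(projects) < params.n_projects and attempts < 200:
        attempts += 1
        h = int(rng.integers(10, max(11, params.rows // 6)))
        w = int(rng.integers(10, max(11, params.cols // 6)))
        r0 = int(rng.integers(0, params.rows - h))
        c0 = int(rng.integers(0, params.cols - w))
        window = forest[r0 : r0 + h, c0 : c0 + w]
        if window.mean() < 0.6 or occupied[r0 : r0 + h, c0 : c0 + w].any():
            continue
        x0 = c0 * px
        x1 = (c0 + w) * px
        y1 = params.rows * px - r0 * px
        y0 = params.rows * px - (r0 + h) * px
        projects.append(
            Project(project_id=pid, geometry=shapely.box(x0, y0, x1, y1),
                    start_year=params.valid_end + 1)
        )
        occupied[r0 : r0 + h, c0 : c0 + w] = True
        pid += 1
    if len(projects) < params.n_projects:
        raise ValueError("infeasible params: could not place the requested projects")
    return history, carbon, ProjectSet(projects)


# ---------------------------------------------------------------------------
# Hand-checkable fixture
# ---------------------------------------------------------------------------

def fixture_small() -> tuple[ForestHistory, CarbonStratumLayer, ProjectSet, dict]:
    """A deterministic 80 x 80 toy landscape with four hand-placed patches.

    All 6,400 one-hectare cells are forest.  Four calibration patches (lost
    in 2005) of 4, 9, 2 and 16 ha sit well apart; ten validation-period
    cells (lost 2012) comprise two edge-adjacent cells per patch plus two
    isolated cells far from any patch, so the share of validation loss
    captured by the high-risk stratum is knowable by hand (40% at m = 1,
    80% once every buffer reaches its neighbours).  The western half is
    dense humid forest (747 tCO2e/ha), the eastern half secondary forest
    (409 tCO2e/ha); two 20 x 20-cell projects start in 2015.

    Returns the landscape plus a dictionary of hand-derived per-stage
    expectations used as the end-to-end regression baseline.
    """
    rows = cols = 80
    px = 100.0  # 1 ha cells
    forest = np.ones((rows, cols), dtype=np.int32)
    defor = np.full((rows, cols), NODATA_YEAR, dtype=np.int32)

    patches = {
        1: [(r, c) for r in (10, 11) for c in (10, 11)],            # 4 ha
        2: [(r, c) for r in (10, 11, 12) for c in (50, 51, 52)],    # 9 ha
        3: [(50, 15), (50, 16)],                                    # 2 ha
        4: [(r, c) for r in range(55, 59) for c in range(55, 59)],  # 16 ha
    }
    for cells in patches.values():
        for r, c in cells:
            defor[r, c] = 2005

    near = [(9, 10), (12, 11),      # beside patch 1
            (9, 51), (13, 52),      # beside patch 2
            (49, 15), (51, 16),     # beside patch 3
            (54, 56), (59, 57)]     # beside patch 4
    far = [(75, 2), (2, 75)]
    for r, c in near + far:
        defor[r, c] = 2012

    def layer(values, nodata=-9999):
        return GridLayer(values=values, origin_x=0.0, origin_y=rows * px,
                         pixel_size=px, crs_id=DEFAULT_CRS, nodata=nodata)

    history = ForestHistory(
        forest_t0=layer(forest),
        defor_year=layer(defor, nodata=NODATA_YEAR),
        calib_start=2000, calib_end=2010, valid_end=2014,
    )

    codes = np.ones((rows, cols), dtype=np.int32)
    codes[:, cols // 2 :] = 2
    carbon = CarbonStratumLayer(
        strata=layer(codes),
        lookup={1: ("dense_humid", 747.0), 2: ("secondary", 409.0)},
    )

    projects = ProjectSet([
        Project(1, shapely.box(500.0, 5500.0, 2500.0, 7500.0), 2015),   # rows 5-25, cols 5-25
        Project(2, shapely.box(4500.0, 500.0, 6500.0, 2500.0), 2015),   # rows 55-75, cols 45-65
    ])

    expected = {
        "patch_areas_ha": [4.0, 9.0, 2.0, 16.0],
        "n_patches": 4,
        "eligible_forest_ha": 6400.0,
        "A_def_validation_ha": 10.0,
        # PP by multiple: at m=1 the 4- and 2-ha patch buffers (46.7 m and
        # 33.0 m) fall short of the 50 m centre-to-edge gap, so only the two
        # neighbours of each of the 9- and 16-ha patches are captured.
        "pp_percent": {1: 40.0, 6: 80.0, 45: 80.0},
        "pps_percent": {1: 100.0, 6: 200.0, 45: 200.0},  # 10-yr calib / 4-yr valid
        # Buffer radii (m) per patch from the equivalent-circle ring formula.
        "r_high_m": {
            6: [185.7031, 278.5547, 131.3120, 371.4063],
            45: [652.4661, 978.6991, 461.3632, 1304.9321],
        },
        "paa_areas_ha": {1: 394.0, 2: 383.0},
        # Vector-mode high-risk areas, verified against a brute-force
        # point-to-rectangle distance oracle.
        "A_high_ha": {1: 32.0, 6: 206.0, 45: 1462.0},
        "eligible_at_2010_ha": 6369.0,  # 6400 minus the 31 patch cells
        # End-to-end allocation regression: m=6 map, FREL 10,000 tCO2e/yr,
        # 90:10 split, carbon-weighted (747 vs 409 tCO2e/ha halves).
        "allocation_m6": {
            "frel": 10000.0,
            "split_high": 90.0,
            "baseline_weighted": {1: 1876.850761, 2: 2651.599767},
            "baseline_unweighted": {1: 1195.633510, 2: 3065.512320},
        },
    }
    return history, carbon, projects, expected
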