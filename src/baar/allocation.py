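"""FREL distribution to risk strata, forest types and nested project areas.

The jurisdictional FREL (annual business-as-usual emissions, tCO2e/yr) is
split between the high- and low-risk strata by a policy ratio (e.g. 90:10),
spread uniformly per hectare within each stratum, and optionally re-weighted
by the relative carbon stock of each forest type so that carbon-dense forest
draws a proportionally larger share.  The weighting is mean-preserving
within each stratum: per-stratum totals — and hence the jurisdictional
FREL — are untouched.

Each project is credited over its project accounting area (PAA): the subset
of the project polygon that was continuously forest for the ten years before
the project started.  A project's nested baseline is the sum of the per-cell
densities over its PAA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely

from .landscape_io import (
    CarbonStratumLayer,
    ForestHistory,
    GridLayer,
    Project,
    layer_area,
    require_aligned,
)
from .risk_model import RiskMap

PAA_LOOKBACK_YEARS = 10


@dataclass(frozen=True)
class AllocationConfig:
    frel_annual: float
    split_high: float
    split_low: float
    carbon_weighting: bool = True
    m: float | None = None

    def __post_init__(self) -> None:
        if self.split_high < 0 or self.split_low < 0:
            raise ValueError("splits must be >= 0")
        if abs(self.split_high + self.split_low - 100.0) > 1e-9:
            raise ValueError("split_high + split_low must equal 100")
        if self.frel_annual <= 0:
            raise ValueError("frel_annual must be positive")


@dataclass
class StratumDensity:
    """Per-stratum (and optionally per forest-type) FREL densities.

    ``d_high``/``d_low`` are the uniform unweighted densities in
    tCO2e/ha/yr.  After carbon weighting, ``weighted[(stratum, code)]``
    holds the per-forest-type density within each risk stratum.
    """

    d_high: float
    d_low: float
    A_high: float
    A_low: float
    weighted: dict[tuple[str, int], float] | None = None
    strata: CarbonStratumLayer | None = None

    def density_map(self, risk_map: RiskMap, weighted: bool = False) -> np.ndarray:
        """Per-cell density surface (tCO2e/ha/yr); 0 outside eligible forest."""
        high = risk_map.high_mask.values == 1
        low = risk_map.low_mask.values == 1
        out = np.zeros(risk_map.high_mask.shape, dtype=float)
        if not weighted:
            out[high] = self.d_high
            out[low] = self.d_low
            return out
        if self.weighted is None or self.strata is None:
            raise ValueError("no carbon-weighted densities available; "
                             "run carbon_weighted_densities first")
        codes = self.strata.strata.values
        for (stratum, code), dens in self.weighted.items():
            zone = (high if stratum == "high" else low) & (codes == code)
            out[zone] = dens
        return out


def stratum_densities(config: AllocationConfig, risk_map: RiskMap) -> StratumDensity:
    """Uniform per-hectare densities from the high:low FREL split."""
    A_high, A_low = risk_map.A_high, risk_map.A_low
    if config.split_high > 0 and A_high <= 0:
        raise ValueError("nonzero high-risk split but the high-risk stratum is empty")
    if config.split_low > 0 and A_low <= 0:
        raise ValueError("nonzero low-risk split but the low-risk stratum is empty")
    d_high = (config.split_high / 100.0) * config.frel_annual / A_high if A_high > 0 else 0.0
    d_low = (config.split_low / 100.0) * config.frel_annual / A_low if A_low > 0 else 0.0
    return StratumDensity(d_high=d_high, d_low=d_low, A_high=A_high, A_low=A_low)


def carbon_weighted_densities(
    density: StratumDensity,
    strata: CarbonStratumLayer,
    risk_map: RiskMap,
) -> StratumDensity:
    """Re-weight each stratum's density by relative forest-type carbon stock.

    Within stratum ``s``, forest type ``t`` receives
    ``d_{s,t} = d_s * stock_t / stock_bar_s`` with ``stock_bar_s`` the
    area-weighted mean stock over the stratum — exactly mean-preserving, so
    the stratum total ``d_s * A_s`` (and the jurisdictional FREL) is
    conserved.
    """
    require_aligned(strata.strata, risk_map.high_mask)
    codes = strata.strata.values
    cell_area = strata.strata.cell_area_ha
    weighted: dict[tuple[str, int], float] = {}
    for name, mask, d_s in (
        ("high", risk_map.high_mask.values == 1, density.d_high),
        ("low", risk_map.low_mask.values == 1, density.d_low),
    ):
        if not mask.any():
            continue
        if np.any(codes[mask] == strata.strata.nodata):
            raise ValueError(f"{name}-risk forest cells without a stratum code")
        present = np.unique(codes[mask])
        areas = {int(c): float((mask & (codes == c)).sum()) * cell_area for c in present}
        A_s = sum(areas.values())
        mean_stock = sum(strata.lookup[c][1] * a for c, a in areas.items()) / A_s
        if mean_stock == 0:
            raise ValueError(f"area-weighted mean stock of the {name}-risk "
                             "stratum is zero; cannot weight")
        for c in areas:
            weighted[(name, c)] = d_s * strata.lookup[c][1] / mean_stock
    return StratumDensity(
        d_high=density.d_high,
        d_low=density.d_low,
        A_high=density.A_high,
        A_low=density.A_low,
        weighted=weighted,
        strata=strata,
    )


def derive_paa(project: Project, history: ForestHistory) -> GridLayer:
    """Project accounting area: project cells continuously forest for the
    ten years before the project's start year.

    With monotone forest loss this is every benchmark-forest cell inside the
    polygon not deforested by the start year; the history must reach back at
    least ten years before the start.
    """
    if project.start_year - PAA_LOOKBACK_YEARS < history.calib_start:
        raise ValueError(
            f"history starts {history.calib_start}, too shallow for the "
            f"{PAA_LOOKBACK_YEARS}-year lookback before {project.start_year}"
        )
    grid = history.forest_t0
    xs, ys = grid.center_meshgrid()
    inside = shapely.contains_xy(project.geometry, xs, ys)
    years = history.defor_year
    lost_by_start = years.mask() & (years.values <= project.start_year)
    paa = inside & (grid.values == 1) & ~lost_by_start
    return grid.like(paa.astype(np.int32), nodata=-9999)


@dataclass
class ProjectBaseline:
    project_id: int
    paa_area: float
    baseline_unweighted: float
    baseline_weighted: float
    per_ha: float


def allocate_project(
    paa: GridLayer,
    risk_map: RiskMap,
    densities: StratumDensity,
    project_id: int = 0,
) -> ProjectBaseline:
    """Nested annual baseline for one PAA: per-cell density times cell area.

    Both the uniform and (when available) carbon-weighted variants are
    reported; ``per_ha`` is the weighted baseline per PAA hectare (falling
    back to the unweighted one when no weighting was computed).  An empty
    PAA yields a zero baseline.
    """
    require_aligned(paa, risk_map.high_mask)
    area = layer_area(paa)
    sel = paa.values == 1
    cell_area = paa.cell_area_ha
    unweighted = float(
        densities.density_map(risk_map, weighted=False)[sel].sum() * cell_area
    )
    if densities.weighted is not None:
        weighted = float(
            densities.density_map(risk_map, weighted=True)[sel].sum() * cell_area
        )
    else:
        weighted = unweighted
    per_ha = weighted / area if area > 0 else 0.0
    return ProjectBaseline(
        project_id=project_id,
        paa_area=area,
        baseline_unweighted=unweighted,
        baseline_weighted=weighted,
        per_ha=per_ha,
    )


def simple_area_allocation(
    frel_annual: float, total_forest_area: float, paa_area: float
) -> float:
    """Risk-blind allocation: the PAA's pro-rata share of the FREL."""
    if total_forest_area <= 0 or paa_area < 0:
        raise ValueError("areas must be positive")
    return frel_annual / total_forest_area * paa_area


def sensitivity_summary(
    scenario_baselines: Mapping[tuple[float, float], Sequence[ProjectBaseline]],
) -> pd.DataFrame:
    """Spread of each project's baseline across (m, split) scenarios.

    ``scenario_baselines`` maps ``(m, split_high)`` to that scenario's
    project baselines (weighted).  Reports per-project mean, SD and relative
    SD (population SD / mean, in %), plus — when several splits are present —
    the mean change from the largest to the smallest high-risk share.
    """
    if len(scenario_baselines) < 2:
        raise ValueError("need at least two scenarios for a sensitivity summary")
    records = []
    for (m, split_high), baselines in scenario_baselines.items():
        for b in baselines:
            records.append(
                {"project_id": b.project_id, "m": m, "split_high": split_high,
                 "baseline": b.baseline_weighted}
            )
    long = pd.DataFrame(records)
    rows = []
    splits = sorted(long["split_high"].unique())
    for pid, grp in long.groupby("project_id"):
        vals = grp["baseline"].to_numpy(dtype=float)
        mean = vals.mean()
        sd = vals.std(ddof=0)  # population SD: rSD of {90, 110} is 10%
        row = {
            "project_id": pid,
            "n_scenarios": len(vals),
            "mean": mean,
            "sd": sd,
            "rsd_percent": 100.0 * sd / mean if mean != 0 else float("nan"),
        }
        if len(splits) >= 2:
            hi = grp.loc[grp["split_high"] == splits[-1], "baseline"].mean()
            lo = grp.loc[grp["split_high"] == splits[0], "baseline"].mean()
            row["delta_maxsplit_vs_minsplit_percent"] = (
                100.0 * (hi - lo) / lo if lo != 0 else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)
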