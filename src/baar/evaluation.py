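"""Validation-period scoring of candidate risk maps and map selection.

A candidate map is judged by how much of the deforestation that actually
happened in the validation period falls inside its high-risk stratum:

* predictive power        PP  = 100 * A_def_high / A_def
* scaled predictive power PPs = PP * n_years_calibration / n_years_validation
* precision               Pr  = 100 * A_def / A_high
* minimum project efficacy MPE = NDC / PPs  (both as fractions, reported in %)

MPE is the share of the high-risk area that must remain forest for the
jurisdiction to meet its NDC reduction target given the map's (scaled)
predictive power: a perfect map gives MPE = NDC, weaker maps demand more of
each project.  The printed formula for MPE uses plain PP, but the published
worked values (NDC 21%, PPs 164.5% -> 12.8%; PPs 195% -> 10.8%) are only
consistent with the scaled predictive power in the denominator, so that is
what this module uses; the two coincide when the periods are equal length.

The efficiency column of the canonical results table has no published
formula; it is reconstructed here as PP * Pr (as fractions, reported in %),
which reproduces the published values to within rounding.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .landscape_io import GridLayer, layer_area, require_aligned
from .risk_model import RiskMap


@dataclass(frozen=True)
class PeriodConfig:
    """Calibration / validation period lengths in years."""

    n_years_calibration: float
    n_years_validation: float

    def __post_init__(self) -> None:
        if self.n_years_calibration <= 0 or self.n_years_validation <= 0:
            raise ValueError("period lengths must be positive")


@dataclass(frozen=True)
class PolicyConfig:
    """National policy inputs: NDC reduction target (%) and annual FREL."""

    ndc_percent: float
    frel_annual: float

    def __post_init__(self) -> None:
        if not (0 < self.ndc_percent <= 100):
            raise ValueError("ndc_percent must be in (0, 100]")
        if self.frel_annual <= 0:
            raise ValueError("frel_annual must be positive")


@dataclass
class EvaluationResult:
    m: float
    A_def: float
    A_def_high: float
    A_high: float
    A_low: float
    A_def_hist: float
    pp: float
    pps: float
    pr: float
    mpe: float
    efficiency: float
    aggregate_multiple: float


def predictive_power(A_def_high: float, A_def: float) -> float:
    """Percent of validation deforestation captured by the high-risk area."""
    if A_def <= 0:
        raise ValueError("no validation deforestation (A_def = 0)")
    if A_def_high > A_def * (1 + 1e-12):
        raise ValueError("A_def_high cannot exceed A_def")
    return 100.0 * A_def_high / A_def


def scaled_predictive_power(pp: float, periods: PeriodConfig) -> float:
    """PP rescaled by the calibration/validation period-length ratio."""
    if pp < 0:
        raise ValueError("pp must be >= 0")
    return pp * (periods.n_years_calibration / periods.n_years_validation)


def precision(A_def: float, A_high: float) -> float:
    """Validation deforestation as a percent of the high-risk area."""
    if A_high <= 0:
        raise ValueError("A_high must be positive")
    return 100.0 * A_def / A_high


def minimum_project_efficacy(policy: PolicyConfig, pps: float) -> float:
    """Percent of the high-risk area that must stay forest to meet the NDC.

    Both NDC and the scaled predictive power enter as fractions; the result
    is reported as a percentage.  With a perfect map (PPs = 100%) the MPE
    equals the NDC target.
    """
    if pps <= 0:
        raise ValueError("scaled predictive power must be positive")
    return 100.0 * (policy.ndc_percent / 100.0) / (pps / 100.0)


def efficiency(pp: float, pr: float) -> float:
    """Reconstructed efficiency: product of PP and Pr as fractions, in %."""
    if pp < 0 or pr < 0:
        raise ValueError("pp and pr must be >= 0")
    return (pp / 100.0) * (pr / 100.0) * 100.0


def evaluate(
    risk_map: RiskMap,
    validation_defor: GridLayer,
    hist_defor_area: float,
    periods: PeriodConfig,
    policy: PolicyConfig | None = None,
) -> EvaluationResult:
    """Score one risk map against the validation-period deforestation mask.

    ``validation_defor`` must be disjoint from the calibration deforestation
    the map was built from; ``hist_defor_area`` is the calibration-period
    patch area total used for the aggregate multiple A_high / A_def_hist.
    """
    require_aligned(risk_map.high_mask, validation_defor)
    defor = validation_defor.values == 1
    high = risk_map.high_mask.values == 1
    cell_area = validation_defor.cell_area_ha
    A_def = float(defor.sum()) * cell_area
    A_def_high = float((defor & high).sum()) * cell_area
    A_high = risk_map.A_high
    A_low = risk_map.A_low

    pp = predictive_power(A_def_high, A_def)
    pps = scaled_predictive_power(pp, periods)
    pr = precision(A_def, A_high)
    mpe = minimum_project_efficacy(policy, pps) if policy is not None else float("nan")
    return EvaluationResult(
        m=risk_map.m,
        A_def=A_def,
        A_def_high=A_def_high,
        A_high=A_high,
        A_low=A_low,
        A_def_hist=hist_defor_area,
        pp=pp,
        pps=pps,
        pr=pr,
        mpe=mpe,
        efficiency=efficiency(pp, pr),
        aggregate_multiple=A_high / hist_defor_area if hist_defor_area > 0 else float("nan"),
    )


def select_m(results: list[EvaluationResult], rule="median_mpe") -> EvaluationResult:
    """Pick the map whose MPE is the median among feasible candidates.

    Candidates are results with MPE < 100% (an MPE of 100%+ would demand
    more than total forest retention).  The default rule ranks candidates by
    MPE and takes the middle rank; with an even count the lower-middle rank
    is used, and exact MPE ties break toward the smaller m.  ``rule`` may be
    a callable ``(candidates) -> EvaluationResult`` for custom policies.
    """
    if not results:
        raise ValueError("results must be nonempty")
    candidates = [r for r in results if np.isfinite(r.mpe) and r.mpe < 100.0]
    if not candidates:
        raise ValueError("no candidate maps with MPE < 100%")
    if callable(rule):
        return rule(candidates)
    if rule != "median_mpe":
        raise ValueError(f"unknown selection rule {rule!r}")
    ranked = sorted(candidates, key=lambda r: (r.mpe, r.m))
    median_mpe = ranked[(len(ranked) - 1) // 2].mpe
    return min((r for r in ranked if r.mpe == median_mpe), key=lambda r: r.m)


def evaluate_series(
    risk_maps: list[RiskMap],
    validation_defor: GridLayer,
    hist_defor_area: float,
    periods: PeriodConfig,
    policy: PolicyConfig | None = None,
) -> list[EvaluationResult]:
    return [
        evaluate(rm, validation_defor, hist_defor_area, periods, policy)
        for rm in risk_maps
    ]


def results_table(
    results: list[EvaluationResult], split_high: float | None = None
) -> pd.DataFrame:
    """Summary table, one row per multiple, mirroring the canonical columns."""
    df = pd.DataFrame(
        [
            {
                "m": r.m,
                "aggregate_multiple": r.aggregate_multiple,
                "pp": r.pp,
                "pps": r.pps,
                "pr": r.pr,
                "efficiency": r.efficiency,
                "frel_high_share": split_high,
                "mpe": r.mpe,
            }
            for r in results
        ]
    )
    return df


def write_results(
    results: list[EvaluationResult],
    csv_path: str | Path | None = None,
    json_path: str | Path | None = None,
    split_high: float | None = None,
) -> pd.DataFrame:
    df = results_table(results, split_high=split_high)
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    if json_path is not None:
        Path(json_path).write_text(
            json.dumps([asdict(r) for r in results], indent=1) + "\n"
        )
    return df
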