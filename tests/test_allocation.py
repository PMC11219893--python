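"""FREL distribution: stratum densities, carbon weighting, PAAs, baselines."""

import numpy as np
import pytest
import shapely

import baar
import baar.allocation as al
import baar.risk_model as rm
from baar.landscape_io import CarbonStratumLayer, Project

from conftest import grid


def make_risk_map(high, low):
    """RiskMap directly from boolean arrays (1-ha cells)."""
    return rm.RiskMap(
        high_mask=grid(high.astype(np.int32)),
        low_mask=grid(low.astype(np.int32)),
        m=45,
    )


@pytest.fixture()
def simple_risk_map():
    # 100 ha high-risk strip, 900 ha low-risk remainder of a landscape
    high = np.zeros((40, 25), dtype=bool)
    high[:4, :] = True
    low = ~high
    return make_risk_map(high, low)


class TestStratumDensities:
    def test_direct_arithmetic(self, simple_risk_map):
        config = al.AllocationConfig(frel_annual=1000.0, split_high=90.0,
                                     split_low=10.0)
        d = al.stratum_densities(config, simple_risk_map)
        assert d.d_high == pytest.approx(9.0)           # 900 / 100 ha
        assert d.d_low == pytest.approx(10.0 / 90.0)    # 100 / 900 ha

    def test_area_proportional_split_is_uniform(self, simple_risk_map):
        config = al.AllocationConfig(frel_annual=5000.0, split_high=10.0,
                                     split_low=90.0)
        d = al.stratum_densities(config, simple_risk_map)
        assert d.d_high == pytest.approx(d.d_low) == pytest.approx(5.0)

    def test_conservation_on_random_configs(self, simple_risk_map):
        rng = np.random.default_rng(31)
        for _ in range(20):
            split = float(rng.uniform(0, 100))
            frel = float(rng.uniform(1e3, 1e9))
            config = al.AllocationConfig(frel_annual=frel, split_high=split,
                                         split_low=100 - split)
            d = al.stratum_densities(config, simple_risk_map)
            total = d.d_high * d.A_high + d.d_low * d.A_low
            assert total == pytest.approx(frel, rel=1e-12)

    def test_zero_area_stratum_with_split_errors(self):
        empty_high = make_risk_map(np.zeros((10, 10), dtype=bool),
                                   np.ones((10, 10), dtype=bool))
        config = al.AllocationConfig(frel_annual=100.0, split_high=90.0,
                                     split_low=10.0)
        with pytest.raises(ValueError, match="high-risk"):
            al.stratum_densities(config, empty_high)

    def test_split_must_sum_to_100(self):
        with pytest.raises(ValueError, match="100"):
            al.AllocationConfig(frel_annual=1.0, split_high=90.0, split_low=20.0)


class TestCarbonWeighting:
    def _carbon(self, codes, lookup):
        return CarbonStratumLayer(strata=grid(codes), lookup=lookup)

    def test_uniform_stock_leaves_densities_unchanged(self, simple_risk_map):
        codes = np.ones((40, 25), dtype=np.int32)
        carbon = self._carbon(codes, {1: ("only", 500.0)})
        config = al.AllocationConfig(frel_annual=1000.0, split_high=90.0,
                                     split_low=10.0)
        d = al.stratum_densities(config, simple_risk_map)
        w = al.carbon_weighted_densities(d, carbon, simple_risk_map)
        assert w.weighted[("high", 1)] == pytest.approx(d.d_high)
        assert w.weighted[("low", 1)] == pytest.approx(d.d_low)

    def test_two_type_closed_form(self, simple_risk_map):
        # equal areas of dense humid (747) and secondary (409) forest in each
        # stratum: densities split in the 747:409 ratio around the mean
        # strata cover 24 columns so each holds 12 columns of either type
        high = np.zeros((40, 25), dtype=bool)
        high[:4, :24] = True
        low = np.zeros((40, 25), dtype=bool)
        low[4:, :24] = True
        risk = make_risk_map(high, low)
        codes = np.ones((40, 25), dtype=np.int32)
        codes[:, 12:] = 2
        carbon = self._carbon(codes, {1: ("dense_humid", 747.0),
                                      2: ("secondary", 409.0)})
        config = al.AllocationConfig(frel_annual=1000.0, split_high=90.0,
                                     split_low=10.0)
        d = al.stratum_densities(config, risk)
        w = al.carbon_weighted_densities(d, carbon, risk)
        mean = (747.0 + 409.0) / 2
        for stratum, d_s in (("high", d.d_high), ("low", d.d_low)):
            assert w.weighted[(stratum, 1)] == pytest.approx(d_s * 747.0 / mean)
            assert w.weighted[(stratum, 2)] == pytest.approx(d_s * 409.0 / mean)
            ratio = w.weighted[(stratum, 1)] / w.weighted[(stratum, 2)]
            assert ratio == pytest.approx(747.0 / 409.0)

    def test_random_mosaic_mean_preserving(self, simple_risk_map):
        rng = np.random.default_rng(37)
        codes = rng.integers(1, 4, size=(40, 25)).astype(np.int32)
        carbon = self._carbon(codes, {1: ("a", 747.0), 2: ("b", 409.0),
                                      3: ("c", 87.0)})
        config = al.AllocationConfig(frel_annual=123456.0, split_high=70.0,
                                     split_low=30.0)
        d = al.stratum_densities(config, simple_risk_map)
        w = al.carbon_weighted_densities(d, carbon, simple_risk_map)
        cell = 1.0  # ha
        for stratum, mask, d_s, A_s in (
            ("high", simple_risk_map.high_mask.values == 1, d.d_high, d.A_high),
            ("low", simple_risk_map.low_mask.values == 1, d.d_low, d.A_low),
        ):
            total = sum(
                w.weighted[(stratum, c)] * (mask & (codes == c)).sum() * cell
                for c in (1, 2, 3)
            )
            assert total == pytest.approx(d_s * A_s, rel=1e-9)

    def test_zero_mean_stock_errors(self, simple_risk_map):
        codes = np.ones((40, 25), dtype=np.int32)
        carbon = self._carbon(codes, {1: ("bare", 0.0)})
        config = al.AllocationConfig(frel_annual=1.0, split_high=50.0,
                                     split_low=50.0)
        d = al.stratum_densities(config, simple_risk_map)
        with pytest.raises(ValueError, match="mean stock"):
            al.carbon_weighted_densities(d, carbon, simple_risk_map)


class TestDerivePaa:
    def test_matches_per_cell_year_scan(self, toy_stage):
        history = toy_stage["history"]
        for project in toy_stage["projects"]:
            paa = al.derive_paa(project, history)
            # brute-force oracle: cell in polygon, forest at t0, and no loss
            # year at or before the project start
            g = history.forest_t0
            expected = np.zeros(g.shape, dtype=bool)
            for r in range(g.shape[0]):
                for c in range(g.shape[1]):
                    x = g.origin_x + (c + 0.5) * g.pixel_size
                    y = g.origin_y - (r + 0.5) * g.pixel_size
                    if not project.geometry.contains(shapely.Point(x, y)):
                        continue
                    if g.values[r, c] != 1:
                        continue
                    year = history.defor_year.values[r, c]
                    if year != history.defor_year.nodata and year <= project.start_year:
                        continue
                    expected[r, c] = True
            assert np.array_equal(paa.values.astype(bool), expected)
            assert baar.layer_area(paa) == toy_stage["expected"]["paa_areas_ha"][
                project.project_id
            ]

    def test_cell_lost_before_start_excluded(self, toy_stage):
        history = toy_stage["history"]
        project = toy_stage["projects"].projects[0]  # rows 5-24, cols 5-24
        paa = al.derive_paa(project, history)
        assert paa.values[10, 10] == 0  # patch cell lost 2005
        assert paa.values[9, 10] == 0   # validation cell lost 2012
        assert paa.values[7, 7] == 1    # never-deforested forest inside

    def test_insufficient_history_depth_errors(self, toy_stage):
        history = toy_stage["history"]
        early = Project(7, shapely.box(0, 0, 500, 500), 2005)
        with pytest.raises(ValueError, match="lookback"):
            al.derive_paa(early, history)


class TestAllocateProject:
    def test_low_risk_uniform_paa(self, simple_risk_map):
        config = al.AllocationConfig(frel_annual=1000.0, split_high=90.0,
                                     split_low=10.0)
        d = al.stratum_densities(config, simple_risk_map)
        paa = np.zeros((40, 25), dtype=np.int32)
        paa[10:20, :10] = 1  # 100 ha entirely low-risk
        b = al.allocate_project(grid(paa), simple_risk_map, d)
        assert b.paa_area == 100.0
        assert b.baseline_unweighted == pytest.approx(d.d_low * 100.0)
        assert b.per_ha == pytest.approx(d.d_low)

    def test_half_high_half_low(self, simple_risk_map):
        config = al.AllocationConfig(frel_annual=1000.0, split_high=90.0,
                                     split_low=10.0)
        d = al.stratum_densities(config, simple_risk_map)
        paa = np.zeros((40, 25), dtype=np.int32)
        paa[2:6, :10] = 1  # rows 2-3 high, rows 4-5 low: 40 ha split evenly
        b = al.allocate_project(grid(paa), simple_risk_map, d)
        assert b.baseline_unweighted == pytest.approx(
            (d.d_high + d.d_low) / 2 * 40.0
        )

    def test_empty_paa_zero_baseline(self, simple_risk_map):
        config = al.AllocationConfig(frel_annual=1000.0, split_high=90.0,
                                     split_low=10.0)
        d = al.stratum_densities(config, simple_risk_map)
        b = al.allocate_project(grid(np.zeros((40, 25), dtype=np.int32)),
                                simple_risk_map, d)
        assert b.paa_area == 0.0
        assert b.baseline_unweighted == 0.0
        assert b.per_ha == 0.0

    def test_random_paa_per_cell_oracle(self, simple_risk_map):
        rng = np.random.default_rng(43)
        codes = rng.integers(1, 3, size=(40, 25)).astype(np.int32)
        carbon = CarbonStratumLayer(
            strata=grid(codes), lookup={1: ("a", 747.0), 2: ("b", 409.0)}
        )
        config = al.AllocationConfig(frel_annual=9999.0, split_high=80.0,
                                     split_low=20.0)
        d = al.carbon_weighted_densities(
            al.stratum_densities(config, simple_risk_map), carbon,
            simple_risk_map,
        )
        paa = (rng.random((40, 25)) < 0.4).astype(np.int32)
        b = al.allocate_project(grid(paa), simple_risk_map, d, project_id=3)
        expected = 0.0
        for r in range(40):
            for c in range(25):
                if not paa[r, c]:
                    continue
                stratum = "high" if simple_risk_map.high_mask.values[r, c] else "low"
                expected += d.weighted[(stratum, int(codes[r, c]))] * 1.0
        assert b.baseline_weighted == pytest.approx(expected, rel=1e-12)
        assert b.project_id == 3


class TestSimpleAreaAllocation:
    def test_drc_benchmark_density(self):
        # the risk-blind national benchmark: FREL over eligible forest area
        density = al.simple_area_allocation(1_078_235_018.0, 140_861_872.0, 1.0)
        assert round(density, 2) == 7.65

    def test_full_area_gets_full_frel(self):
        assert al.simple_area_allocation(500.0, 200.0, 200.0) == pytest.approx(500.0)

    def test_linear_in_paa_area(self):
        one = al.simple_area_allocation(1000.0, 400.0, 10.0)
        three = al.simple_area_allocation(1000.0, 400.0, 30.0)
        assert three == pytest.approx(3 * one)


class TestSensitivitySummary:
    def _baseline(self, pid, value):
        return al.ProjectBaseline(project_id=pid, paa_area=1.0,
                                  baseline_unweighted=value,
                                  baseline_weighted=value, per_ha=value)

    def test_identical_scenarios_zero_rsd(self):
        scenarios = {
            (45.0, 90.0): [self._baseline(1, 100.0)],
            (60.0, 90.0): [self._baseline(1, 100.0)],
        }
        df = al.sensitivity_summary(scenarios)
        assert df.loc[0, "rsd_percent"] == 0.0

    def test_population_sd_convention(self):
        # two scenarios 90 and 110: mean 100, population SD 10 -> rSD 10%
        scenarios = {
            (45.0, 90.0): [self._baseline(1, 90.0)],
            (45.0, 50.0): [self._baseline(1, 110.0)],
        }
        df = al.sensitivity_summary(scenarios)
        assert df.loc[0, "rsd_percent"] == pytest.approx(10.0)

    def test_three_by_three_matches_direct_recomputation(self):
        rng = np.random.default_rng(47)
        ms = (30.0, 45.0, 60.0)
        splits = (90.0, 70.0, 50.0)
        values = {pid: rng.uniform(50, 150, size=9) for pid in (1, 2, 3)}
        scenarios = {}
        for i, m in enumerate(ms):
            for j, s in enumerate(splits):
                scenarios[(m, s)] = [
                    self._baseline(pid, values[pid][i * 3 + j]) for pid in (1, 2, 3)
                ]
        df = al.sensitivity_summary(scenarios).set_index("project_id")
        for pid in (1, 2, 3):
            v = values[pid]
            assert df.loc[pid, "mean"] == pytest.approx(v.mean())
            assert df.loc[pid, "sd"] == pytest.approx(v.std(ddof=0))
            assert df.loc[pid, "rsd_percent"] == pytest.approx(
                100 * v.std(ddof=0) / v.mean()
            )

    def test_needs_two_scenarios(self):
        with pytest.raises(ValueError, match="two scenarios"):
            al.sensitivity_summary({(45.0, 90.0): [self._baseline(1, 1.0)]})


def test_global_conservation_over_paa_partition(toy_stage, toy_risk_maps):
    """Allocating every eligible-forest cell to some PAA returns the FREL."""
    risk = toy_risk_maps[6]
    config = al.AllocationConfig(frel_annual=10_000.0, split_high=90.0,
                                 split_low=10.0)
    d = al.carbon_weighted_densities(
        al.stratum_densities(config, risk), toy_stage["carbon"], risk
    )
    eligible = (risk.high_mask.values | risk.low_mask.values).astype(bool)
    # split the eligible forest into 4 disjoint quadrant "projects"
    total_w = total_u = 0.0
    for rs in (slice(0, 40), slice(40, 80)):
        for cs in (slice(0, 40), slice(40, 80)):
            part = np.zeros_like(eligible)
            part[rs, cs] = eligible[rs, cs]
            b = al.allocate_project(grid(part.astype(np.int32)), risk, d)
            total_w += b.baseline_weighted
            total_u += b.baseline_unweighted
    assert total_w == pytest.approx(10_000.0, rel=1e-9)
    assert total_u == pytest.approx(10_000.0, rel=1e-9)


def test_degenerate_equivalence_with_simple_allocation(toy_risk_maps):
    """Area-proportional split + uniform stock makes the risk-based
    allocation coincide with the risk-blind pro-rata allocation."""
    risk = toy_risk_maps[6]
    total = risk.A_high + risk.A_low
    frel = 77_777.0
    config = al.AllocationConfig(
        frel_annual=frel,
        split_high=100.0 * risk.A_high / total,
        split_low=100.0 * risk.A_low / total,
    )
    d = al.stratum_densities(config, risk)
    paa = np.zeros(risk.high_mask.shape, dtype=np.int32)
    paa[20:50, 20:50] = (risk.high_mask.values | risk.low_mask.values)[20:50, 20:50]
    b = al.allocate_project(grid(paa), risk, d)
    expected = al.simple_area_allocation(frel, total, b.paa_area)
    assert b.baseline_unweighted == pytest.approx(expected, rel=1e-12)
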