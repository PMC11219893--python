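"""Shared fixtures: the hand-checkable toy landscape and its derived stages."""

from __future__ import annotations

import numpy as np
import pytest

import baar
import baar.patch_analysis as pa
import baar.risk_model as rm

CRS = "ESRI:54034"


@pytest.fixture(scope="session")
def toy():
    """(history, carbon, projects, expected) for the 80x80 4-patch fixture."""
    return baar.fixture_small()


@pytest.fixture(scope="session")
def toy_stage(toy):
    """Derived stages of the toy landscape shared across tests."""
    history, carbon, projects, expected = toy
    calib = pa.period_defor_mask(history, history.calib_start, history.calib_end)
    patches = pa.label_patches(calib)
    eligible = pa.extract_eligible_forest(history.forest_t0)
    eligible_now = eligible.like(
        (
            eligible.values.astype(bool)
            & (history.forest_remaining(history.calib_end).values == 1)
        ).astype(np.int32)
    )
    valid = pa.period_defor_mask(history, history.calib_end, history.valid_end)
    return {
        "history": history,
        "carbon": carbon,
        "projects": projects,
        "expected": expected,
        "calib_mask": calib,
        "patches": patches,
        "eligible": eligible,
        "eligible_now": eligible_now,
        "valid_mask": valid,
    }


@pytest.fixture(scope="session")
def toy_risk_maps(toy_stage):
    """Vector-mode risk maps of the toy landscape for m = 1, 6, 45."""
    return {
        m: rm.build_risk_map(
            toy_stage["patches"], toy_stage["eligible_now"], m, mode="vector"
        )
        for m in (1, 6, 45)
    }


def grid(values, pixel_size=100.0, nodata=-9999, crs=CRS):
    """Convenience GridLayer constructor used across the test modules."""
    values = np.asarray(values, dtype=np.int32)
    return baar.GridLayer(
        values=values,
        origin_x=0.0,
        origin_y=values.shape[0] * pixel_size,
        pixel_size=pixel_size,
        crs_id=crs,
        nodata=nodata,
    )
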