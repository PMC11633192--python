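"""Per-bottle nitrogen accounting: units, ratios, closure, association."""

import numpy as np
import pandas as pd
import pytest

from n2oiso.errors import (
    ConfigError,
    DegenerateInputError,
    UndefinedRatioError,
    ValidationError,
)
from n2oiso.gas_partition import VesselGeometry
from n2oiso.nitrogen_budget import (
    CultureTimeSeries,
    amounts_as_n,
    conversion_ratio,
    end_stage_composition,
    production_association,
    yield_estimates,
)


def make_series(rows, substrate="NO3", geometry=VesselGeometry(), **kw):
    df = pd.DataFrame(rows, columns=["time_h", "od600", "no3_mM", "no2_mM", "nh4_mM", "n2o_umol"])
    return CultureTimeSeries(
        bottle_id=kw.pop("bottle_id", "b1"),
        strain="test",
        substrate=substrate,
        data=df,
        geometry=geometry,
        **kw,
    )


def test_amounts_unit_arithmetic():
    ts = make_series([[0, 0.02, 8.0, 0.0, 0.0, 0.0], [24, 0.1, 4.0, 1.0, 0.5, 1.0]])
    am = amounts_as_n(ts)
    assert am["no3_N"].iloc[0] == pytest.approx(160.0)  # 8 mM x 20 mL
    assert am["n2o_N"].iloc[1] == pytest.approx(2.0)  # 1 µmol N2O = 2 µmol N
    assert am["no2_N"].iloc[0] == 0.0
    # linearity in concentration
    ts2 = make_series([[0, 0.02, 16.0, 0.0, 0.0, 0.0], [24, 0.1, 8.0, 2.0, 1.0, 2.0]])
    assert (amounts_as_n(ts2)[["no3_N", "no2_N", "nh4_N", "n2o_N"]].to_numpy()
            == 2 * am[["no3_N", "no2_N", "nh4_N", "n2o_N"]].to_numpy()).all()


def test_amounts_require_geometry():
    ts = make_series([[0, 0, 8, 0, 0, 0], [1, 0, 7, 1, 0, 0]])
    ts.geometry = None
    with pytest.raises(ConfigError):
        amounts_as_n(ts)


def test_conversion_ratio_and_guards():
    ts = make_series([[0, 0.02, 8.0, 0.0, 0.0, 0.0], [24, 0.1, 4.0, 1.0, 2.0, 0.4]])
    # NH4: 2 mM * 20 = 40 µmol N over 80 µmol consumed
    assert conversion_ratio(ts, "NH4") == pytest.approx(0.5)
    # constant product -> ratio 0
    assert conversion_ratio(ts, "N2O", t_end=24) == pytest.approx(0.8 / 80)
    flat = make_series([[0, 0.02, 8.0, 0.0, 0.0, 0.0], [24, 0.1, 8.0, 0.0, 0.0, 0.0]])
    with pytest.raises(UndefinedRatioError):
        conversion_ratio(flat, "NH4")


def test_end_stage_composition_sums_to_one_and_reports_overclosure():
    ts = make_series([[0, 0.02, 8.0, 0.0, 0.0, 0.0], [24, 0.1, 2.0, 1.0, 4.0, 1.0]])
    comp = end_stage_composition(ts)
    assert sum(comp.values()) == pytest.approx(1.0, abs=1e-12)
    assert comp["NO3"] == pytest.approx(0.25)
    assert comp["N2O-N"] == pytest.approx(2.0 / 160.0)
    # over-closure is reported negative, not clipped
    over = make_series([[0, 0.02, 8.0, 0.0, 0.0, 0.0], [24, 0.1, 8.0, 1.0, 1.0, 0.0]])
    assert end_stage_composition(over)["unrecovered"] < 0


def test_substrate_unchanged_composition_is_all_substrate():
    ts = make_series([[0, 0.0, 8.0, 0.0, 0.0, 0.0], [24, 0.0, 8.0, 0.0, 0.0, 0.0]])
    comp = end_stage_composition(ts)
    assert comp["NO3"] == pytest.approx(1.0)
    assert comp["unrecovered"] == pytest.approx(0.0, abs=1e-12)


def test_zero_initial_substrate_rejected():
    ts = make_series([[0, 0, 0.0, 1.0, 0, 0], [1, 0, 0.0, 0.5, 0, 0]])
    with pytest.raises(ValidationError):
        end_stage_composition(ts)


def test_association_exact_line():
    # y = 2x in N units: n2o_N = 2 * no2_N  =>  n2o_umol = no2_mM * 20
    rows = [[t, 0.1, 8 - x, x, 0.0, x * 20] for t, x in [(0, 0), (12, 1), (24, 2)]]
    fit = production_association(make_series(rows))
    assert fit.slope == pytest.approx(2.0)
    assert fit.r_squared == pytest.approx(1.0)


def test_association_three_point_ols_oracle():
    """Hand OLS on (0,0),(1,1),(2,3): slope 3/2, r^2 = 27/28."""
    rows = [[0, 0.1, 8, 0.0, 0, 0.0], [12, 0.1, 7, 1 / 20, 0, 0.5], [24, 0.1, 6, 2 / 20, 0, 1.5]]
    fit = production_association(make_series(rows))
    assert fit.slope == pytest.approx(1.5)
    assert fit.intercept == pytest.approx(-1 / 6)
    assert fit.r_squared == pytest.approx(27 / 28, abs=1e-12)


def test_association_constant_regressor_rejected():
    rows = [[0, 0.1, 8, 0, 0, 0], [12, 0.1, 8, 0, 0, 1], [24, 0.1, 8, 0, 0, 2]]
    with pytest.raises(DegenerateInputError):
        production_association(make_series(rows))


def test_association_needs_three_points():
    rows = [[0, 0.1, 8, 0, 0, 0], [12, 0.1, 7, 1, 0, 1]]
    with pytest.raises(ValidationError):
        production_association(make_series(rows))


def test_time_regression_names_bottle():
    with pytest.raises(ValidationError, match="b7"):
        make_series([[0, 0, 8, 0, 0, 0], [24, 0, 7, 1, 0, 0], [12, 0, 6, 2, 0, 0]], bottle_id="b7")


def test_yield_estimates_normalise_by_reduced_nitrite():
    # consumed 80 µmol N, 20 still as NO2 -> reduced 60; NH4 39, N2O-N 0.6
    ts = make_series([[0, 0.02, 8.0, 0.0, 0.0, 0.0], [24, 0.1, 4.0, 1.0, 1.95, 0.3]])
    y = yield_estimates(ts)
    assert y["reduced_share"] == pytest.approx(60 / 80)
    assert y["y_nh4"] == pytest.approx(39 / 60)
    assert y["y_n2o"] == pytest.approx(0.6 / 60)
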