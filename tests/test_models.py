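"""Vocalization model specs and p_v prediction."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adaptsample.models import (
    ModelSpecificationError,
    ModelTerm,
    PvGrid,
    build_model,
    default_models,
    linear_predictor,
    predict_grid,
    predict_pv,
)

ROW = {
    "day_of_year": 75,
    "day_of_year_equinox": 56,
    "hour_of_day": 7,
    "time_to_sunrise": 30.0,
    "time_to_sunset": 700.0,
    "temperature": 18.0,
    "wind_speed": 5.0,
    "lunar_phase": 0.25,
    "rain_accum_24h": 0.0,
}


class TestBuildModel:
    def test_constant_model_is_valid(self):
        m = build_model({"species_code": "X", "intercept": 0.0, "terms": []})
        assert m.intercept == 0.0
        assert m.terms == ()

    def test_unknown_covariate_rejected(self):
        with pytest.raises(ModelSpecificationError, match="humidity"):
            build_model(
                {
                    "species_code": "X",
                    "intercept": 0.0,
                    "terms": [{"covariate": "humidity", "coefficient": 1.0}],
                }
            )

    def test_unknown_transform_rejected(self):
        with pytest.raises(ModelSpecificationError, match="exp"):
            ModelTerm("temperature", "exp", 1.0)

    def test_periodic_transform_requires_period(self):
        with pytest.raises(ModelSpecificationError, match="period"):
            ModelTerm("day_of_year", "sin_period", 1.0)

    def test_shipped_collared_dove_model(self):
        ecdo = {m.species_code: m for m in default_models()}["ECDO"]
        assert ecdo.intercept == pytest.approx(-1.4)
        assert len(ecdo.terms) == 6
        kinds = {(t.covariate, t.transform, t.period) for t in ecdo.terms}
        assert ("day_of_year", "sin_period", 366.0) in kinds
        assert ("hour_of_day", "cos_period", 12.0) in kinds

    def test_all_nine_species_ship(self):
        codes = [m.species_code for m in default_models()]
        assert codes == [
            "BTGN", "COPO", "TOAD", "COYOTE", "ECDO", "GAQU", "LENI", "PHAI",
            "VERD",
        ]


class TestLinearPredictor:
    def test_constant_model(self):
        m = build_model({"species_code": "X", "intercept": 0.0})
        assert linear_predictor(m, ROW) == 0.0

    def test_single_cosine_term(self):
        m = build_model(
            {
                "species_code": "X",
                "intercept": 0.0,
                "terms": [
                    {
                        "covariate": "hour_of_day",
                        "transform": "cos_period",
                        "period": 12,
                        "coefficient": 1.0,
                    }
                ],
            }
        )
        # hour 6 on a 12-h scale: cos(pi) = -1
        assert linear_predictor(m, {**ROW, "hour_of_day": 6}) == pytest.approx(-1.0)

    def test_collared_dove_term_by_term_oracle(self, model_by_code):
        # independent evaluation of the printed coefficients
        expected = (
            -1.4
            + 1.0 * math.sin(2 * math.pi * 75 / 366)
            - 2.0 * math.cos(2 * math.pi * 7 / 12)
            - 0.000005 * 30.0**2
            + 0.009 * 18.0
            - 0.000001 * 18.0**3
            - 0.25 * 5.0
        )
        got = linear_predictor(model_by_code["ECDO"], ROW)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_missing_covariate_is_data_error(self, model_by_code):
        row = dict(ROW)
        del row["wind_speed"]
        with pytest.raises(KeyError, match="wind_speed"):
            linear_predictor(model_by_code["ECDO"], row)


class TestPredictPv:
    def test_zero_linear_predictor_gives_half(self):
        m = build_model({"species_code": "X", "intercept": 0.0})
        assert predict_pv(m, ROW) == pytest.approx(0.5)

    def test_saturation_at_large_negative_intercept(self):
        m = build_model({"species_code": "X", "intercept": -50.0})
        assert predict_pv(m, ROW) < 1e-20

    def test_wind_strictly_decreases_collared_dove_pv(self, model_by_code):
        ecdo = model_by_code["ECDO"]
        pvs = [
            predict_pv(ecdo, {**ROW, "wind_speed": w}) for w in (0, 5, 15, 40)
        ]
        assert all(a > b for a, b in zip(pvs, pvs[1:]))

    @given(st.floats(-30, 30))
    @settings(deadline=None, max_examples=50)
    def test_logistic_monotone_and_bounded(self, m_val):
        model = build_model({"species_code": "X", "intercept": m_val})
        p = predict_pv(model, ROW)
        assert 0.0 < p < 1.0
        p2 = predict_pv(
            build_model({"species_code": "X", "intercept": m_val + 1.0}), ROW
        )
        assert p2 > p


class TestPredictGrid:
    def test_one_species_one_site_one_day(self, models, march_cov):
        one = march_cov[
            (march_cov["site_id"] == march_cov["site_id"].iloc[0])
            & (pd.DatetimeIndex(march_cov["date"]) == "2016-03-05")
        ]
        grid = predict_grid([models[0]], one)
        assert grid.n_records == 24

    def test_grid_size_exact(self, march_grid, sites3):
        assert march_grid.n_records == 9 * len(sites3) * 31 * 24
        assert march_grid.values.shape == (9, len(sites3), 31, 24)

    def test_random_subsample_matches_rowwise_oracle(self, models, march_cov, rng):
        grid = predict_grid(models, march_cov)
        rows = march_cov.sample(100, random_state=7)
        for model in (models[2], models[4]):  # TOAD, ECDO
            for _, row in rows.iterrows():
                expected = predict_pv(model, row)
                got = grid.sel(
                    model.species_code, row["site_id"], row["date"]
                )[int(row["hour_of_day"])]
                assert got == pytest.approx(expected, abs=1e-12)

    def test_incomplete_lattice_rejected(self, models, march_cov):
        broken = march_cov.iloc[:-1]
        with pytest.raises(ValueError, match="incomplete"):
            predict_grid(models, broken)

    def test_pv_bounds(self, march_grid):
        assert march_grid.values.min() >= 0.0
        assert march_grid.values.max() <= 1.0

    def test_frame_round_trip(self, models, march_cov):
        one_site = march_cov[march_cov["site_id"] == march_cov["site_id"].iloc[0]]
        grid = predict_grid(models[:2], one_site)
        back = PvGrid.from_frame(grid.to_frame())
        np.testing.assert_allclose(back.values, grid.values)
        assert back.species == grid.species
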