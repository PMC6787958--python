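"""The daily adaptive loop and the factorial comparison."""

import numpy as np
import pandas as pd
import pytest

from adaptsample.experiment import (
    TreatmentResult,
    achievement_dates,
    auc,
    default_durations,
    paired_comparison,
    run_factorial,
    run_treatment,
)
from adaptsample.models import PvGrid


def _grid(values, species=None, sites=None, start="2016-03-01"):
    values = np.asarray(values, dtype=float)
    k, r, d, _ = values.shape
    return PvGrid(
        values,
        species or [f"sp{i}" for i in range(k)],
        sites or [f"S{i}" for i in range(r)],
        pd.date_range(start, periods=d, freq="D"),
    )


class TestRunTreatment:
    def test_certain_vocalizer_saturates_day_one(self):
        grid = _grid(np.ones((1, 2, 5, 24)))
        res = run_treatment(grid, 2, "optimized")
        assert res.p_star[0].min() == pytest.approx(1.0)
        assert res.stopped_early_on == 0
        assert (res.achieved_day == 0).all()
        # forward fill keeps the series complete
        assert res.p_star.shape[0] == 5
        assert res.p_star[-1].min() == pytest.approx(1.0)

    def test_silent_species_never_achieves(self):
        grid = _grid(np.zeros((1, 2, 4, 24)))
        res = run_treatment(grid, 5, "fixed")
        assert (res.p_star == 0).all()
        assert (res.achieved_day == -1).all()

    def test_paired_treatments_read_identical_grid(self, march_grid):
        opt = run_treatment(march_grid, 5, "optimized")
        fix = run_treatment(march_grid, 5, "fixed")
        assert opt.species == fix.species
        assert opt.dates.equals(fix.dates)

    def test_p_star_monotone_in_days(self, march_grid):
        res = run_treatment(march_grid, 10, "optimized")
        assert (np.diff(res.p_star, axis=0) >= -1e-15).all()

    def test_single_day_p_star_monotone_in_effort(self, march_grid):
        # With no weight feedback (a single day), greedy allocations are
        # nested in S, so every species' capture probability is monotone.
        day = PvGrid(
            march_grid.values[:, :, :1, :],
            march_grid.species,
            march_grid.sites,
            march_grid.dates[:1],
        )
        finals = [
            run_treatment(day, s, "optimized").final_p_star()
            for s in (2, 5, 10, 20, 30, 40)
        ]
        for a, b in zip(finals, finals[1:]):
            assert (b - a >= -1e-12).all()

    def test_unknown_treatment_rejected(self, march_grid):
        with pytest.raises(ValueError, match="treatment"):
            run_treatment(march_grid, 5, "random")

    def test_threshold_above_one_needs_relaxed_mode(self, march_grid):
        with pytest.raises(ValueError, match="expected_captures"):
            run_treatment(march_grid, 5, "optimized", p_star_max=2.0)
        res = run_treatment(
            march_grid, 5, "optimized", p_star_max=2.0, expected_captures=True
        )
        assert (res.p_star <= 1.0).all()

    def test_hand_traced_toy_loop(self):
        """2 sites x 2 species x 3 days matches a scalar re-implementation."""
        rng = np.random.default_rng(42)
        pv = rng.uniform(0.0, 0.6, size=(2, 2, 3, 24))
        grid = _grid(pv)
        effort, thr = 3, 0.95
        res = run_treatment(grid, effort, "optimized", p_star_max=thr)

        # --- independent scalar trace of the daily loop ---
        w0 = [[0.5, 0.5], [0.5, 0.5]]          # [site][species]
        w = [row[:] for row in w0]
        p_star = [[0.0, 0.0], [0.0, 0.0]]
        for d in range(3):
            for r in range(2):
                scores = [
                    w[r][0] * pv[0, r, d, h] + w[r][1] * pv[1, r, d, h]
                    for h in range(24)
                ]
                ranked = sorted(range(24), key=lambda h: (-scores[h], h))
                counts = [0] * 24
                left = effort
                for h in ranked:
                    take = min(30, left)
                    counts[h] = take
                    left -= take
                for k in range(2):
                    miss = 1.0
                    for h in range(24):
                        p_min = 1 - (1 - pv[k, r, d, h]) ** (1 / 60)
                        miss *= (1 - p_min) ** counts[h]
                    p_d = 1 - miss
                    p_star[r][k] = 1 - (1 - p_star[r][k]) * (1 - p_d)
                    assert res.p_star[d, k, r] == pytest.approx(
                        p_star[r][k], abs=1e-9
                    )
                raw = [
                    w0[r][k] * max(0.0, 1 - p_star[r][k] / thr)
                    for k in range(2)
                ]
                tot = sum(raw)
                w[r] = [x / tot if tot > 0 else 0.0 for x in raw]
            if d + 1 < 3:
                for r in range(2):
                    for k in range(2):
                        assert res.weights[d + 1, k, r] == pytest.approx(
                            w[r][k], abs=1e-9
                        )

    def test_state_snapshot_frame(self, march_grid):
        res = run_treatment(march_grid, 2, "optimized")
        df = res.to_frame()
        assert set(df.columns) == {
            "species_code", "site_id", "date", "p_star_d", "p_star", "weight",
            "achieved",
        }
        assert len(df) == 31 * 9 * len(res.sites)


class TestAuc:
    def test_constant_one_series(self):
        assert auc(np.ones(100)) == 1.0

    def test_constant_zero_series(self):
        assert auc(np.zeros(50)) == 0.0

    def test_linear_ramp_closed_form(self):
        for D in (5, 31, 366):
            series = np.arange(1, D + 1) / D
            assert auc(series) == pytest.approx((D + 1) / (2 * D))

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            auc(np.array([]))

    def test_monotone_under_pointwise_dominance(self, rng):
        b = rng.random(60)
        a = np.clip(b + rng.random(60) * 0.1, 0, 1)
        assert auc(a) >= auc(b)


class TestAchievementDates:
    def _result(self, achieved_day, n_days=10):
        k, r = achieved_day.shape
        return TreatmentResult(
            treatment="fixed",
            effort=2,
            species=[f"sp{i}" for i in range(k)],
            sites=[f"S{i}" for i in range(r)],
            dates=pd.date_range("2016-03-01", periods=n_days, freq="D"),
            p_star=np.zeros((n_days, k, r)),
            p_star_d=np.zeros((n_days, k, r)),
            weights=np.zeros((n_days, k, r)),
            achieved_day=achieved_day,
        )

    def test_first_crossing_day_reported(self):
        res = self._result(np.array([[9, -1]]))
        summary = achievement_dates(res)
        # day index 9 of a March 1 start = March 10 = day-of-year 70 (leap)
        assert summary.loc[0, "mean_achievement_doy"] == pytest.approx(70.0)
        assert summary.loc[0, "n_sites_achieved"] == 1

    def test_no_site_achieving_gives_nan(self):
        summary = achievement_dates(self._result(np.array([[-1, -1]])))
        assert np.isnan(summary.loc[0, "mean_achievement_doy"])

    def test_mean_over_achieving_subset_matches_scan(self, rng):
        achieved = rng.integers(-1, 10, size=(3, 20))
        res = self._result(achieved)
        summary = achievement_dates(res)
        doy = res.dates.dayofyear.to_numpy()
        for k in range(3):
            hits = [doy[d] for d in achieved[k] if d >= 0]
            expected = np.mean(hits) if hits else np.nan
            got = summary.loc[k, "mean_achievement_doy"]
            if hits:
                assert got == pytest.approx(expected)
            else:
                assert np.isnan(got)


@pytest.fixture(scope="module")
def small_factorial(models):
    from adaptsample.covariates import default_sites

    sites = default_sites(3, seed=8)
    dates = pd.date_range("2016-03-01", "2016-03-21", freq="D")
    mods = [m for m in models if m.species_code in ("ECDO", "GAQU", "COPO")]
    durations = {"short": (dates, mods)}
    return run_factorial(sites, durations, efforts=(2, 10), seed=21)


class TestFactorial:
    def test_structure(self, small_factorial):
        # 1 duration x 2 efforts x 2 treatments x 3 species
        assert len(small_factorial) == 12
        assert set(small_factorial["treatment"]) == {"fixed", "optimized"}

    def test_paired_comparison_table(self, small_factorial):
        cmp = paired_comparison(small_factorial)
        assert len(cmp) == 6
        assert {"AUC_fixed", "AUC_optimized", "days_earlier"} <= set(cmp.columns)
        assert cmp["AUC_fixed"].between(0, 1).all()

    def test_march_duration_drops_spadefoot(self, models):
        durations = default_durations(models)
        full_models = [m.species_code for m in durations["full_year"][1]]
        march_models = [m.species_code for m in durations["march_only"][1]]
        assert "TOAD" in full_models
        assert "TOAD" not in march_models
        assert len(full_models) == 9
        assert len(march_models) == 8
        assert len(durations["full_year"][0]) == 366
        assert len(durations["march_only"][0]) == 31
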