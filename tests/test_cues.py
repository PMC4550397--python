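"""Cue bearings, across-run orientation, regressions and comparisons."""

import numpy as np
import pandas as pd
import pytest

from discorient.circular import vm_sample
from discorient.cues import (
    across_run,
    across_run_table,
    coast_cue,
    directionality_regression,
    dispersion_comparison,
    drift_cue,
    great_circle,
    read_coastline_csv,
    species_comparison,
)


class TestGeodesy:
    def test_point_due_south_of_single_vertex(self):
        # 0.01 deg of latitude = 0.01/360 of Earth's circumference = 1112 m
        bearing, dist = coast_cue(43.0, 7.0, [[43.01, 7.0]])
        assert bearing == pytest.approx(0.0, abs=1e-6)
        assert dist == pytest.approx(2 * np.pi * 6371008.8 * 0.01 / 360.0, rel=1e-6)

    def test_coincident_vertex_distance_zero_bearing_undefined(self):
        bearing, dist = coast_cue(43.0, 7.0, [[43.0, 7.0]])
        assert dist == 0.0 and np.isnan(bearing)

    def test_equidistant_tie_takes_first_in_file_order(self):
        coast = [[43.01, 7.0], [42.99, 7.0]]  # north and south, same distance
        bearing, _ = coast_cue(43.0, 7.0, coast)
        assert bearing == pytest.approx(0.0, abs=1e-6)

    def test_empty_coastline_errors(self):
        with pytest.raises(ValueError):
            coast_cue(43.0, 7.0, np.empty((0, 2)))

    def test_drift_bearing_and_speed(self):
        fixes = pd.DataFrame({
            "t": pd.to_datetime(["2014-06-01T08:00:00Z", "2014-06-01T08:15:00Z"]),
            "lat": [43.0, 43.0 + 100.0 / 111194.9],  # 100 m north
            "lon": [7.0, 7.0],
        })
        bearing, speed = drift_cue(fixes)
        assert bearing == pytest.approx(0.0, abs=1e-6)
        assert speed == pytest.approx(100.0 / 900.0, rel=1e-3)
        # drifting the opposite way (positions swapped) flips the bearing
        swapped = fixes.assign(lat=fixes["lat"].iloc[::-1].to_numpy())
        rev_bearing, _ = drift_cue(swapped)
        assert rev_bearing == pytest.approx(180.0, abs=1e-6)

    def test_stationary_fix_flagged(self):
        fixes = pd.DataFrame({
            "t": pd.to_datetime(["2014-06-01T08:00:00Z", "2014-06-01T08:15:00Z"]),
            "lat": [43.0, 43.0], "lon": [7.0, 7.0]})
        bearing, speed = drift_cue(fixes)
        assert speed == 0.0 and np.isnan(bearing)

    def test_drift_contract_errors(self):
        one = pd.DataFrame({"t": [pd.Timestamp("2014-06-01T08:00:00Z")],
                            "lat": [43.0], "lon": [7.0]})
        with pytest.raises(ValueError):
            drift_cue(one)

    def test_bearing_symmetry(self):
        _, fwd = great_circle(43.0, 7.0, 43.2, 7.4)
        _, back = great_circle(43.2, 7.4, 43.0, 7.0)
        assert 150.0 < abs(fwd - back) < 210.0  # near-antipodal on short arcs


def results_frame(bearings, species="sp", p=1e-4):
    n = len(bearings)
    return pd.DataFrame({
        "deployment_id": [f"D{i}" for i in range(n)],
        "species": species,
        "directionality_p_value": p,
        "r": 0.5,
        "mean_bearing": bearings,
        "artifact": False,
        "qc_excluded": False,
    })


def cues_frame(n, species="sp", sun=180.0):
    return pd.DataFrame({
        "deployment_id": [f"D{i}" for i in range(n)],
        "species": species,
        "sun_azimuth": sun,
        "coast_bearing": 10.0,
        "wind_bearing": 90.0,
        "current_bearing": 270.0,
    })


class TestAcrossRun:
    def test_shared_bearing_gives_r_one(self):
        res = across_run(results_frame([100.0] * 35), cues_frame(35), "sp", "north")
        assert res.mean_angle == pytest.approx(100.0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value < 1e-10

    def test_sun_relative_reference(self):
        res = across_run(results_frame([190.0] * 35), cues_frame(35, sun=180.0),
                         "sp", "sun")
        assert res.mean_angle == pytest.approx(10.0)

    def test_insufficient_n_refused(self):
        res = across_run(results_frame([0.0] * 29), cues_frame(29), "sp", "north",
                         min_n=30)
        assert res.status == "insufficient_n"
        assert np.isnan(res.r)

    def test_directional_basis_counts_directional_only(self):
        frame = results_frame([0.0] * 35)
        frame.loc[:9, "directionality_p_value"] = 0.9  # 10 non-directional
        res = across_run(frame, cues_frame(35), "sp", "north", min_n=30,
                         basis="directional")
        assert res.status == "insufficient_n"
        res2 = across_run(frame, cues_frame(35), "sp", "north", min_n=30,
                          basis="tested")
        assert res2.status == "ok" and res2.n == 25

    def test_unknown_reference_errors(self):
        with pytest.raises(ValueError):
            across_run(results_frame([0.0] * 35), cues_frame(35), "sp", "moon")

    def test_global_rotation_invariance(self, rng):
        bearings = rng.uniform(0, 360, 40)
        suns = rng.uniform(0, 360, 40)
        base = across_run(results_frame(bearings), cues_frame(40, sun=suns), "sp", "sun")
        shifted = across_run(results_frame((bearings + 73.0) % 360),
                             cues_frame(40, sun=(suns + 73.0) % 360), "sp", "sun")
        assert shifted.r == pytest.approx(base.r, abs=1e-9)
        assert shifted.p_value == pytest.approx(base.p_value, abs=1e-9)

    def test_table_covers_species_by_reference(self):
        res = results_frame([10.0] * 35)
        table = across_run_table(res, cues_frame(35))
        assert set(table["reference"]) == {"north", "sun", "coast", "wind", "current"}
        assert len(table) == 5


class TestRegression:
    def test_noiseless_linear_fit_is_perfect(self):
        x = np.linspace(0, 1, 30)
        logit_r = -1.0 + 2.0 * x
        r = 1.0 / (1.0 + np.exp(-logit_r))
        res = directionality_regression(r, x)
        assert res.r2_adj == pytest.approx(1.0, abs=1e-9)
        assert res.p_value < 1e-10

    def test_quadratic_term_reported(self):
        x = np.linspace(0, 1, 40)
        logit_r = 1.0 - 4.0 * (x - 0.5) ** 2
        r = 1.0 / (1.0 + np.exp(-logit_r))
        res = directionality_regression(r, x, quadratic=True)
        assert res.model == "quadratic"
        assert res.quadratic_term_p < 0.001

    def test_null_calibration(self, rng):
        """Independent covariate rejected at roughly the nominal 5% rate."""
        hits = 0
        reps = 400
        for _ in range(reps):
            r = rng.beta(2, 3, 40)
            x = rng.normal(size=40)
            hits += directionality_regression(r, x).p_value < 0.05
        assert 0.02 < hits / reps < 0.08

    def test_contract_errors(self):
        with pytest.raises(ValueError):
            directionality_regression([0.5] * 10, [1.0] * 10)  # constant covariate
        with pytest.raises(ValueError):
            directionality_regression([0.5, 0.6], [0.1, 0.2])  # too few


class TestSpeciesComparison:
    def test_identical_distributions_not_significant(self, rng):
        base = rng.beta(2, 2, 30)
        out = species_comparison({"a": base, "b": base.copy(), "c": base.copy()})
        assert out["kruskal_p"] > 0.9

    def test_detects_shifted_species(self, rng):
        out = species_comparison({
            "weak": rng.beta(2, 6, 40), "strong": rng.beta(6, 2, 40)})
        assert out["kruskal_p"] < 0.001

    def test_bh_adjustment_never_below_raw(self, rng):
        out = species_comparison({k: rng.beta(2, 2, 20) for k in "abcd"})
        pw = out["pairwise"]
        assert (pw["p_adjusted"] >= pw["p_raw"] - 1e-12).all()
        assert len(pw) == 6

    def test_small_species_dropped_with_warning(self, rng):
        out = species_comparison({"a": rng.beta(2, 2, 20), "b": rng.beta(2, 2, 20),
                                  "tiny": [0.5]})
        assert out["dropped"] == ["tiny"]


class TestDispersion:
    def test_set_against_itself_not_significant(self):
        a = vm_sample(0.0, 2.0, 30, seed=21)
        out = dispersion_comparison({"x": a, "y": a.copy()})
        assert out["omnibus"].p_value > 0.9

    def test_tight_versus_diffuse_significant(self):
        out = dispersion_comparison({
            "tight": vm_sample(0.0, 20.0, 40, seed=22),
            "diffuse": vm_sample(0.0, 0.3, 40, seed=23)})
        assert out["omnibus"].p_value < 0.01
        assert out["pairwise"]["p_value"].iloc[0] < 0.01


class TestCoastlineIO:
    def test_read_lon_lat_csv(self, tmp_path):
        p = tmp_path / "coast.csv"
        p.write_text("lon,lat\n7.0,43.2\n7.1,43.21\n")
        coast = read_coastline_csv(p)
        assert coast.shape == (2, 2)
        assert coast[0, 0] == 43.2  # (lat, lon) ordering in memory

    def test_missing_columns_error(self, tmp_path):
        p = tmp_path / "coast.csv"
        p.write_text("x,y\n1,2\n")
        with pytest.raises(ValueError):
            read_coastline_csv(p)
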