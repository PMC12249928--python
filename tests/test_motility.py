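"""MSD/MAD estimators, motility regressions, and their invariants."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import pbmquant as pq
from pbmquant.errors import FitError, InsufficientDataError, ValidationError
from conftest import make_track
from oracles import msd_mad_naive, ols_naive


def _stats(table: pq.TrajectoryTable, tid=None) -> pq.LagStatistics:
    tid = tid if tid is not None else table.track_ids[0]
    return pq.lag_statistics(table.track(tid), track_id=tid)


class TestLagStatistics:
    def test_collinear_hand_enumeration(self, collinear_track):
        s = _stats(collinear_track)
        np.testing.assert_allclose(s.msd, [1, 4, 9])
        np.testing.assert_allclose(s.mad, [1, 2, 3])
        np.testing.assert_array_equal(s.n_pairs, [3, 2, 1])
        np.testing.assert_allclose(s.lag_time, [1, 2, 3])

    def test_stationary_all_zero(self):
        s = _stats(make_track([(2.0, 3.0)] * 10))
        assert (s.msd == 0).all() and (s.mad == 0).all()

    def test_matches_naive_oracle_on_random_tracks(self, rng):
        for _ in range(100):
            n = rng.integers(3, 51)
            xy = rng.normal(size=(n, 2)) * 5
            s = _stats(make_track(xy))
            msd, mad, n_pairs = msd_mad_naive(xy[:, 0], xy[:, 1])
            np.testing.assert_allclose(s.msd, msd, rtol=0, atol=1e-12)
            np.testing.assert_allclose(s.mad, mad, rtol=0, atol=1e-12)
            np.testing.assert_array_equal(s.n_pairs, n_pairs)

    def test_pair_count_conservation(self, rng):
        n = 23
        s = _stats(make_track(rng.normal(size=(n, 2))))
        assert s.n_pairs.sum() == n * (n - 1) // 2

    def test_single_point_track_rejected(self):
        with pytest.raises(InsufficientDataError):
            pq.lag_statistics(
                pd.DataFrame({"track_id": "a", "frame": [0], "t": [0.0],
                              "x": [0.0], "y": [0.0]})
            )

    def test_nonuniform_spacing_rejected(self):
        df = pd.DataFrame(
            {"track_id": "a", "frame": [0, 1, 2], "t": [0.0, 1.0, 3.0],
             "x": [0.0, 1, 2], "y": [0.0, 0, 0]}
        )
        with pytest.raises(ValidationError):
            pq.lag_statistics(df)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        angle=st.floats(0, 2 * math.pi),
        shift=st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
    )
    def test_rigid_motion_invariance(self, seed, angle, shift):
        """Rotating + translating every point leaves MSD/MAD unchanged."""
        rng = np.random.default_rng(seed)
        xy = rng.normal(size=(15, 2)) * 3
        rot = np.array([[math.cos(angle), -math.sin(angle)],
                        [math.sin(angle), math.cos(angle)]])
        moved = xy @ rot.T + np.asarray(shift)
        a, b = _stats(make_track(xy)), _stats(make_track(moved))
        np.testing.assert_allclose(a.msd, b.msd, rtol=0, atol=1e-9)
        np.testing.assert_allclose(a.mad, b.mad, rtol=0, atol=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_jensen_msd_dominates_mad_squared(self, seed):
        rng = np.random.default_rng(seed)
        s = _stats(make_track(rng.normal(size=(20, 2))))
        assert (s.msd >= s.mad ** 2 - 1e-12).all()


class TestFitMotility:
    def test_collinear_closed_form(self, collinear_track):
        est = pq.fit_motility(_stats(collinear_track))
        assert est.slope_mad == pytest.approx(1.0, abs=1e-12)
        assert est.V == pytest.approx(1.0, abs=1e-12)
        assert est.r2_mad == pytest.approx(1.0, abs=1e-12)
        assert est.slope_msd == pytest.approx(4.0, abs=1e-12)
        assert est.intercept_msd == pytest.approx(-10 / 3, abs=1e-12)
        assert est.D == pytest.approx(1.0, abs=1e-12)
        # SSres = 2/3, SStot = 294/9 -> R² = 48/49
        assert est.r2_msd == pytest.approx(48 / 49, abs=1e-12)

    def test_matches_naive_ols(self, rng):
        xy = rng.normal(size=(30, 2)).cumsum(axis=0)
        s = _stats(make_track(xy))
        est = pq.fit_motility(s, pq.FitPolicy(max_lag_frac=0.25))
        sel = slice(0, est.fit_lag_max)  # lags 1..max
        slope, intercept, r2 = ols_naive(
            list(s.lag_time[sel]), list(s.msd[sel])
        )
        assert est.slope_msd == pytest.approx(slope, rel=1e-12)
        assert est.intercept_msd == pytest.approx(intercept, rel=1e-12)
        assert est.r2_msd == pytest.approx(r2, rel=1e-12)

    def test_stationary_track_r2_undefined(self):
        est = pq.fit_motility(_stats(make_track([(1.0, 1.0)] * 12)))
        assert est.D == 0 and est.V == 0
        assert not est.r2_msd_defined and not est.r2_mad_defined

    def test_ballistic_velocity_exact(self):
        t = pq.simulate_tracks(
            pq.MotilityModelParams(model="ballistic", speed=2.0, delta_t=10,
                                   n_steps=20, n_tracks=1, seed=7)
        )
        est = pq.fit_motility(_stats(t))
        assert est.V == pytest.approx(2.0, abs=1e-9)
        assert est.r2_mad == pytest.approx(1.0, abs=1e-9)

    def test_too_few_lags_raises(self):
        with pytest.raises(FitError):
            pq.fit_motility(_stats(make_track([(0, 0), (1, 0), (2, 0)])))

    def test_time_unit_coherence(self, rng):
        """Same point set at doubled δt: V and D both halve."""
        xy = rng.normal(size=(25, 2)).cumsum(axis=0)
        e1 = pq.fit_motility(_stats(make_track(xy, delta_t=1.0)))
        e2 = pq.fit_motility(_stats(make_track(xy, delta_t=2.0)))
        assert e2.V == pytest.approx(e1.V / 2, rel=1e-12)
        assert e2.D == pytest.approx(e1.D / 2, rel=1e-12)


class TestModelResults:
    def test_brownian_recovery(self):
        table = pq.simulate_tracks(
            pq.MotilityModelParams(model="brownian", step_sigma=1.0, delta_t=1.0,
                                   n_steps=72, n_tracks=200, seed=11)
        )
        res = pq.MotilityModel(table).fit()
        med = float(np.median(res.per_track["D_um2_per_min"]))
        assert med == pytest.approx(0.5, rel=0.10)

    def test_determinism_identical_cohorts(self):
        p = pq.MotilityModelParams(model="prw", speed=0.5, n_tracks=5, seed=3)
        r1 = pq.cohort_summary(pq.simulate_tracks(p))
        r2 = pq.cohort_summary(pq.simulate_tracks(p))
        pd.testing.assert_frame_equal(r1.per_track, r2.per_track)

    def test_single_track_sem_undefined(self):
        t = pq.simulate_tracks(
            pq.MotilityModelParams(model="brownian", n_tracks=1, seed=1)
        )
        res = pq.cohort_summary(t)
        assert math.isnan(res.by_condition["D_um2_per_min_sem"].iloc[0])

    def test_empty_condition_rejected(self):
        with pytest.raises(ValidationError):
            pq.MotilityModel({}).fit()

    def test_summary_mentions_conditions(self):
        t = pq.simulate_tracks(
            pq.MotilityModelParams(model="brownian", n_tracks=4, seed=2)
        )
        text = pq.MotilityModel({"control": t, "treated": t}).fit().summary()
        assert "control" in text and "treated" in text


class TestRosePlotData:
    def test_translation_to_origin(self):
        t = make_track([(5.0, 7.0), (6.0, 7.0), (6.0, 8.0)])
        d = pq.trajectory_rose_plot_data(t)
        assert d.loc[0, "x"] == 0 and d.loc[0, "y"] == 0
        np.testing.assert_allclose(d["x"], [0, 1, 1])
        np.testing.assert_allclose(d["y"], [0, 0, 1])

    def test_ballistic_segment_speeds(self):
        t = pq.simulate_tracks(
            pq.MotilityModelParams(model="ballistic", speed=2.0, delta_t=10,
                                   n_steps=5, n_tracks=2, seed=0)
        )
        d = pq.trajectory_rose_plot_data(t)
        speeds = d["step_speed_um_per_min"].dropna()
        np.testing.assert_allclose(speeds, 2.0, atol=1e-9)

    def test_stationary_speeds_zero(self):
        t = pq.simulate_tracks(
            pq.MotilityModelParams(model="stationary", n_steps=5, n_tracks=1, seed=0)
        )
        d = pq.trajectory_rose_plot_data(t)
        assert (d["step_speed_um_per_min"].dropna() == 0).all()
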