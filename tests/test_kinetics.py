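"""Kinetics tests: frequency series, additivity, fits, area windows."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import rifdyn
from rifdyn import kinetics, simulate
from rifdyn.kinetics import (FrequencySeries, KineticsError,
                             additivity_prediction, area_window_fit,
                             fit_area_polynomial, fit_linear,
                             focus_frequency_series, relative_area,
                             relative_intensity_series,
                             total_intensity_series)


def _series(t, mean, sem=None, n=10, condition=""):
    mean = np.asarray(mean, dtype=float)
    sem = np.zeros_like(mean) if sem is None else np.asarray(sem, dtype=float)
    return FrequencySeries(np.asarray(t, dtype=float), mean, sem, n, condition)


class TestFrequencySeries:
    def test_mean_over_all_imaged_nuclei(self):
        obs = pd.DataFrame({
            "nucleus_id": [0] * 3 + [1] * 5,
            "t_min": [10.0] * 8,
        })
        s = focus_frequency_series(obs, n_nuclei=2)
        assert s.mean[0] == 4.0

    def test_nuclei_without_foci_count_as_zero(self):
        obs = pd.DataFrame({"nucleus_id": [0, 0], "t_min": [10.0, 10.0]})
        s = focus_frequency_series(obs, n_nuclei=4)
        assert s.mean[0] == 0.5

    def test_empty_observations_with_grid_give_zero(self):
        obs = pd.DataFrame({"nucleus_id": [], "t_min": []})
        s = focus_frequency_series(obs, n_nuclei=3, t_grid=np.array([5.0, 6.0]))
        assert np.all(s.mean == 0)
        assert np.all(s.sem == 0)

    def test_control_simulation_recovers_preset_mean(self):
        # stochastic recovery of the unirradiated background focus frequency
        cfg = rifdyn.make_condition_preset("control", n_nuclei=200, n_frames=2, seed=8)
        counts = []
        rng = np.random.default_rng(cfg.seed)
        for _ in range(cfg.n_nuclei):
            geom = simulate.sample_nucleus_geometry(cfg, rng)
            counts.append(len(simulate.sample_focus_field(cfg, geom, rng)))
        obs = pd.DataFrame({
            "nucleus_id": np.repeat(np.arange(cfg.n_nuclei), counts),
            "t_min": 5.0,
        })
        s = focus_frequency_series(obs, n_nuclei=cfg.n_nuclei)
        assert abs(s.mean[0] - 1.0) <= 3 * max(s.sem[0], 1e-9)

    def test_conservation_total_counts(self, gamma_detections):
        # sum over nuclei of per-nucleus counts equals total observations
        _, _, nuclei, obs = gamma_detections
        n_nuclei = obs.nucleus_id.nunique()
        s = focus_frequency_series(obs, n_nuclei=n_nuclei)
        totals = obs.groupby("t_min").size().reindex(s.t_min).to_numpy()
        assert np.allclose(s.mean * n_nuclei, totals)

    def test_time_outside_recording_rejected(self):
        obs = pd.DataFrame({"nucleus_id": [0], "t_min": [10.0]})
        with pytest.raises(KineticsError):
            focus_frequency_series(obs, 1, t_grid=np.array([99.0]))


class TestAdditivity:
    def test_identical_series_collapse_to_common_curve(self):
        t = np.arange(0, 100, 10.0)
        c = _series(t, np.full(len(t), 7.5))
        pred = additivity_prediction(c, c, c)
        assert np.allclose(pred.mean, 7.5)

    def test_constant_series_arithmetic(self):
        # dose-fraction weights: 0.83/1.7 * 17.1 + 1.02/2.0 * 30.9 = 24.108
        t = np.array([0.0, 100.0])
        pred = additivity_prediction(
            _series(t, [17.1, 17.1]), _series(t, [30.9, 30.9]), _series(t, [0.0, 0.0]))
        assert pred.mean == pytest.approx([24.107823529411768] * 2)

    def test_doubling_component_doses_doubles_excess(self):
        t = np.array([0.0, 50.0])
        a, g, c = _series(t, [10.0, 10.0]), _series(t, [20.0, 20.0]), _series(t, [2.0, 2.0])
        p1 = additivity_prediction(a, g, c)
        p2 = additivity_prediction(a, g, c, dose_alpha_pair=(1.66, 1.7),
                                   dose_gamma_pair=(2.04, 2.0))
        assert np.allclose(p2.mean - c.mean, 2 * (p1.mean - c.mean))

    def test_sem_propagated_in_quadrature(self):
        t = np.array([0.0, 10.0])
        a = _series(t, [10, 10], sem=[1.0, 1.0])
        g = _series(t, [20, 20], sem=[2.0, 2.0])
        c = _series(t, [1, 1], sem=[0.5, 0.5])
        pred = additivity_prediction(a, g, c)
        w_a, w_g = 0.83 / 1.7, 1.02 / 2.0
        expected = np.sqrt(((1 - w_a - w_g) * 0.5) ** 2 + (w_a * 1.0) ** 2
                           + (w_g * 2.0) ** 2)
        assert pred.sem == pytest.approx([expected] * 2)


class TestLinearFit:
    def test_exact_line_recovered(self):
        t = np.arange(0, 91, 10.0)
        s = _series(t, -0.2 * t + 30.0)
        fit = fit_linear(s, (0, 90))
        assert fit.slope == pytest.approx(-0.2, abs=1e-12)
        assert fit.intercept == pytest.approx(30.0, abs=1e-10)

    def test_constant_series_zero_slope(self):
        t = np.arange(0, 50, 5.0)
        fit = fit_linear(_series(t, np.full(len(t), 4.0)), (0, 50))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_too_few_points_rejected(self):
        s = _series([0.0, 1.0, 2.0, 50.0], [1, 2, 3, 4])
        with pytest.raises(KineticsError):
            fit_linear(s, (0.0, 1.5))

    def test_simulated_decay_slope_ratio(self):
        """Two conditions built with early decay rates in ratio 2:1 yield
        fitted 90-min decay slopes whose ratio is ~2 (within 15%)."""
        rng = np.random.default_rng(17)
        n_nuclei, n0 = 25, 30.0
        series = []
        # rates slow enough that the 90-min decay is in the linear regime
        for lam in (0.001, 0.002):
            rows = []
            for nid in range(n_nuclei):
                k = rng.poisson(n0)
                deaths = rng.exponential(1.0 / lam, k)
                for t in np.arange(1.0, 91.0):
                    rows.append({"nucleus_id": nid, "t_min": t,
                                 "count": int((deaths > t).sum())})
            df = pd.DataFrame(rows)
            obs = df.loc[df.index.repeat(df["count"])]
            series.append(focus_frequency_series(obs[["nucleus_id", "t_min"]],
                                                 n_nuclei=n_nuclei))
        slope_1 = fit_linear(series[0], (0, 90)).slope
        slope_2 = fit_linear(series[1], (0, 90)).slope
        assert abs(slope_2 / slope_1 - 2.0) < 0.15 * 2.0


class TestRelativeArea:
    def test_normalised_by_maximum(self):
        assert np.allclose(relative_area([0.2, 0.4, 0.8]), [0.25, 0.5, 1.0])

    def test_all_equal_gives_ones(self):
        assert np.allclose(relative_area([0.3, 0.3]), 1.0)

    @given(st.floats(min_value=0.1, max_value=100.0))
    def test_scale_invariance(self, k):
        areas = np.array([0.1, 0.25, 0.6])
        assert np.allclose(relative_area(areas * k), relative_area(areas))

    def test_empty_rejected(self):
        with pytest.raises(KineticsError):
            relative_area([])


class TestPolynomialFits:
    def test_degree_nesting_reproduces_cubic(self):
        t = np.linspace(0, 300, 40)
        y = 1e-6 * t**3 - 3e-4 * t**2 + 0.05 * t + 2.0
        fit = fit_area_polynomial(t, y, order=8)
        assert np.allclose(fit.predict(t), y, atol=1e-6)

    def test_residuals_orthogonal_to_basis(self):
        rng = np.random.default_rng(3)
        t = np.linspace(0, 300, 60)
        y = np.sin(t / 40.0) + rng.normal(0, 0.1, len(t))
        fit = fit_area_polynomial(t, y, order=8)
        s = 2 * (t - t.min()) / (t.max() - t.min()) - 1
        resid = y - fit.predict(t)
        for power in range(9):
            assert abs(np.dot(resid, s**power)) < 1e-9 * len(t)

    def test_high_order_fits_stay_finite(self, gamma_detections):
        _, _, _, obs = gamma_detections
        mean_area = obs.groupby("t_min")["area_um2"].mean()
        fit = fit_area_polynomial(mean_area.index.to_numpy(),
                                  mean_area.to_numpy(), order=8)
        assert np.all(np.isfinite(fit.coeffs))

    def test_insufficient_points_rejected(self):
        with pytest.raises(KineticsError):
            fit_area_polynomial(np.arange(5.0), np.arange(5.0), order=8)


class TestAreaWindows:
    def test_normal_recovery_within_two_percent(self):
        # stochastic recovery of the early-window area distribution
        rng = np.random.default_rng(4)
        obs = pd.DataFrame({
            "t_min": rng.uniform(0, 99, 10_000),
            "area_um2": rng.normal(0.513, 0.045, 10_000),
        })
        fit = area_window_fit(obs, (0.0, 99.0))
        assert abs(fit.mu_um2 - 0.513) / 0.513 < 0.02
        assert abs(fit.sigma_um2 - 0.045) / 0.045 < 0.05

    def test_constant_areas_flagged_degenerate(self):
        obs = pd.DataFrame({"t_min": np.full(20, 10.0), "area_um2": np.full(20, 0.3)})
        fit = area_window_fit(obs, (0.0, 99.0))
        assert fit.degenerate

    def test_empty_window_rejected(self):
        obs = pd.DataFrame({"t_min": [150.0] * 20, "area_um2": [0.3] * 20})
        with pytest.raises(KineticsError):
            area_window_fit(obs, (0.0, 99.0))


class TestIntensitySeries:
    def _tables(self, i_focus, i_nucleus, frames=4):
        nuclei = pd.DataFrame({
            "nucleus_id": 0, "frame": np.arange(1, frames + 1),
            "t_min": 10.0 + np.arange(frames), "i_nucleus": i_nucleus,
        })
        obs = pd.DataFrame({
            "nucleus_id": 0, "frame": np.arange(1, frames + 1),
            "t_min": 10.0 + np.arange(frames), "intensity_au": i_focus,
        })
        return obs, nuclei

    def test_constant_focus_gives_flat_series(self):
        obs, nuclei = self._tables(50.0, 500.0)
        total = total_intensity_series(obs, nuclei)
        rel = relative_intensity_series(obs, nuclei)
        assert np.allclose(total.mean, 50.0)
        assert np.allclose(rel.mean, 50.0 / 450.0)

    def test_ratio_invariant_to_intensity_rescaling(self):
        obs, nuclei = self._tables(50.0, 500.0)
        rel_1 = relative_intensity_series(obs, nuclei)
        obs2, nuclei2 = self._tables(100.0, 1000.0)
        rel_2 = relative_intensity_series(obs2, nuclei2)
        assert np.allclose(rel_1.mean, rel_2.mean)

    def test_overflowing_focus_intensity_skips_frame_with_warning(self):
        obs, nuclei = self._tables(np.array([50.0, 600.0, 50.0, 50.0]), 500.0)
        with pytest.warns(RuntimeWarning):
            rel = relative_intensity_series(obs, nuclei)
        assert len(rel.t_min) == 3

    def test_pixel_sum_oracle(self, gamma_detections):
        """Series bookkeeping equals brute-force pixel arithmetic on one frame."""
        cfg, res, nuclei, obs = gamma_detections
        nid, frame = 0, 1
        sel_o = obs[(obs.nucleus_id == nid) & (obs.frame == frame)]
        sel_n = nuclei[(nuclei.nucleus_id == nid) & (nuclei.frame == frame)]
        total = total_intensity_series(obs[obs.nucleus_id == nid],
                                       nuclei[nuclei.nucleus_id == nid])
        t0 = float(sel_n.t_min.iloc[0])
        value = total.mean[np.argmin(np.abs(total.t_min - t0))]
        assert value == pytest.approx(sel_o.intensity_au.sum(), rel=1e-12)
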