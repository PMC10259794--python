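"""Generator tests: presets, field sampling, lifetimes, motion, rendering."""

import numpy as np
import pandas as pd
import pytest

import rifdyn
from rifdyn import simulate
from rifdyn.mobility import confined_msd_model
from rifdyn.simulate import SimulationError


class TestPresets:
    @pytest.mark.parametrize("condition,mean", [
        ("control", 1.0), ("alpha", 17.1), ("gamma", 30.9),
        ("alpha_then_gamma", 28.3), ("gamma_then_alpha", 25.2),
    ])
    def test_initial_counts(self, condition, mean):
        assert rifdyn.make_condition_preset(condition).initial_count_mean == mean

    def test_alpha_motion_parameters(self):
        cfg = rifdyn.make_condition_preset("alpha")
        motion = cfg.subpopulations[0].motion
        assert motion.d_c == 242.1
        assert motion.r_c == 980.5

    def test_mixed_recording_starts_at_minute_16(self):
        cfg = rifdyn.make_condition_preset("gamma_then_alpha")
        assert cfg.frame_times_min()[0] == pytest.approx(16.0)

    def test_unknown_condition_rejected(self):
        with pytest.raises(SimulationError):
            rifdyn.make_condition_preset("xray")

    def test_weights_sum_to_one(self):
        for condition in simulate.CONDITIONS:
            cfg = rifdyn.make_condition_preset(condition)
            assert sum(s.weight for s in cfg.subpopulations) == pytest.approx(1.0)

    def test_invalid_config_rejected(self):
        cfg = rifdyn.make_condition_preset("gamma")
        with pytest.raises(SimulationError):
            cfg.replace(n_frames=1)
        with pytest.raises(SimulationError):
            cfg.replace(initial_count_mean=-1.0)


class TestFocusField:
    def test_zero_mean_gives_empty_field(self, rng):
        cfg = rifdyn.make_condition_preset("gamma", initial_count_mean=0.0)
        geom = simulate.sample_nucleus_geometry(cfg, rng)
        field = simulate.sample_focus_field(cfg, geom, rng)
        assert len(field) == 0

    @pytest.mark.parametrize("condition", ["gamma", "alpha", "gamma_then_alpha"])
    def test_mean_count_matches_preset(self, condition):
        # Poisson law: the sampled mean must sit within 3 SE of the preset.
        rng = np.random.default_rng(5)
        cfg = rifdyn.make_condition_preset(condition)
        geom = simulate.NucleusGeometry(*cfg.nucleus_semi_axes_nm)
        n = 10_000
        counts = np.array([
            len(simulate.sample_focus_field(cfg, geom, rng)) for _ in range(n)])
        se = counts.std(ddof=1) / np.sqrt(n)
        assert abs(counts.mean() - cfg.initial_count_mean) < 3 * se

    def test_alpha_foci_collinear_within_chords(self, rng):
        cfg = rifdyn.make_condition_preset("alpha", initial_count_mean=40.0)
        geom = simulate.NucleusGeometry(*cfg.nucleus_semi_axes_nm)
        field = simulate.sample_focus_field(cfg, geom, rng)
        for chord, grp in field[field.chord_id >= 0].groupby("chord_id"):
            if len(grp) < 3:
                continue
            xy = grp[["x_nm", "y_nm"]].to_numpy()
            d = xy - xy[0]
            cross = d[1:, 0] * d[-1, 1] - d[1:, 1] * d[-1, 0]
            norm = np.linalg.norm(d[-1]) * np.linalg.norm(d[1:], axis=1) + 1e-9
            assert np.all(np.abs(cross) / norm < 1e-6)

    def test_positions_inside_nucleus(self, rng):
        for condition in ("gamma", "alpha"):
            cfg = rifdyn.make_condition_preset(condition)
            geom = simulate.sample_nucleus_geometry(cfg, rng)
            field = simulate.sample_focus_field(cfg, geom, rng)
            axis = simulate._rotate(field[["x_nm", "y_nm"]].to_numpy(), -geom.phi_rad)
            rho = (axis[:, 0] / geom.a_nm) ** 2 + (axis[:, 1] / geom.b_nm) ** 2
            assert np.all(rho <= 1.0 + 1e-9)

    def test_mixed_condition_keeps_component_labels(self, rng):
        cfg = rifdyn.make_condition_preset("alpha_then_gamma", initial_count_mean=60.0)
        geom = simulate.NucleusGeometry(*cfg.nucleus_semi_axes_nm)
        field = simulate.sample_focus_field(cfg, geom, rng)
        assert {"gamma_simple", "alpha_complex"} <= set(field.subpop)
        # clustered component rides on chords, dispersed does not
        assert (field.loc[field.subpop == "alpha_complex", "chord_id"] >= 0).all()
        assert (field.loc[field.subpop == "gamma_simple", "chord_id"] == -1).all()


class TestLifetimes:
    def _single_pop_config(self, rate):
        cfg = rifdyn.make_condition_preset("control")
        sub = cfg.subpopulations[0]
        return cfg.replace(subpopulations=(
            simulate.SubpopulationParams(sub.label, 1.0, rate, sub.motion,
                                         sub.placement, sub.area_mean_um2,
                                         sub.area_sd_um2, sub.optics),))

    def test_zero_rate_persists_forever(self, rng):
        cfg = self._single_pop_config(0.0)
        field = pd.DataFrame({"subpop": ["background"] * 5, "birth_min": 4.0})
        out = simulate.assign_lifetimes(field, cfg, rng)
        assert np.all(np.isinf(out.death_min))

    def test_exponential_survival(self):
        # Exponential law: surviving fraction at t = 1/lambda is e^-1.
        rng = np.random.default_rng(11)
        lam, n = 0.01, 10_000
        cfg = self._single_pop_config(lam)
        field = pd.DataFrame({"subpop": ["background"] * n, "birth_min": 0.0})
        out = simulate.assign_lifetimes(field, cfg, rng)
        surv = (out.death_min > 100.0).mean()
        se = np.sqrt(np.e**-1 * (1 - np.e**-1) / n)
        assert abs(surv - np.exp(-1)) < 3 * se

    def test_biphasic_mixture_survival(self):
        # Brute-force sampled survival matches the two-population mixture law.
        rng = np.random.default_rng(13)
        n = 20_000
        cfg = rifdyn.make_condition_preset("gamma")
        sub = cfg.subpopulations[0]
        cfg = cfg.replace(subpopulations=(
            simulate.SubpopulationParams("simple", 0.5, 0.05, sub.motion),
            simulate.SubpopulationParams("complex", 0.5, 0.001, sub.motion),
        ))
        labels = np.where(np.arange(n) < n // 2, "simple", "complex")
        field = pd.DataFrame({"subpop": labels, "birth_min": 0.0})
        out = simulate.assign_lifetimes(field, cfg, rng)
        for t in (20.0, 100.0, 300.0):
            expected = 0.5 * np.exp(-0.05 * t) + 0.5 * np.exp(-0.001 * t)
            observed = (out.death_min > t).mean()
            assert abs(observed - expected) < 3 * np.sqrt(expected * (1 - expected) / n)

    def test_negative_rate_rejected(self, rng):
        with pytest.raises(SimulationError):
            simulate.SubpopulationParams("x", 1.0, -0.1, simulate.MotionParams(1, 1))


class TestConfinedWalk:
    def test_zero_diffusion_is_static(self, rng):
        pos = simulate.simulate_confined_walk(0.0, 500.0, 50, 60.0, rng, n_tracks=4)
        assert np.allclose(pos, pos[:, :1, :])

    def test_degenerate_confinement_rejected(self, rng):
        with pytest.raises(SimulationError):
            simulate.simulate_confined_walk(100.0, 0.0, 10, 60.0, rng)

    def test_ensemble_msd_matches_closed_form(self):
        # Motion fidelity: empirical MSD within 2% of the confined-diffusion
        # model at every lag up to 100 min (closed-form oracle).
        rng = np.random.default_rng(21)
        d_c, r_c = 349.0, 1014.0
        # 3e4 tracks keep the per-lag sampling SEM (~0.6%) well inside the 2%
        # band so the check probes generator exactness, not Monte Carlo noise
        pos = simulate.simulate_confined_walk(d_c, r_c, 101, 60.0, rng, n_tracks=30_000)
        disp = pos[:, 1:, :] - pos[:, :1, :]
        emp = np.einsum("tkc,tkc->tk", disp, disp).mean(axis=0)
        lags = np.arange(1, 101) * 60.0
        expected = confined_msd_model(lags, d_c, r_c)
        assert np.all(np.abs(emp / expected - 1.0) < 0.02)

    def test_msd_plateau_reaches_confinement_radius(self):
        # Stationarity: MSD approaches r_c^2 at long lags.
        rng = np.random.default_rng(22)
        d_c, r_c = 242.1, 980.5
        pos = simulate.simulate_confined_walk(d_c, r_c, 400, 60.0, rng, n_tracks=4000)
        disp = pos[:, -1, :] - pos[:, 0, :]
        plateau = np.einsum("tc,tc->t", disp, disp).mean()
        assert abs(plateau / r_c**2 - 1.0) < 0.05


class TestRendering:
    def test_no_foci_no_noise_gives_constant_background(self):
        cfg = rifdyn.make_condition_preset(
            "control", initial_count_mean=0.0, n_frames=4, poisson_noise=False,
            read_noise_sd=0.0, nucleus_drift_step_nm=0.0, seed=3)
        res = simulate.simulate_experiment(cfg.replace(n_nuclei=1))
        stack = res.movies[0]
        assert len(res.truth) == 0
        assert all(np.array_equal(stack[0], stack[k]) for k in range(1, 4))

    def test_static_focus_conserves_integrated_intensity(self, rng):
        cfg = rifdyn.make_condition_preset(
            "gamma", n_frames=5, poisson_noise=False, read_noise_sd=0.0,
            nucleus_drift_step_nm=0.0)
        geom = simulate.NucleusGeometry(*cfg.nucleus_semi_axes_nm)
        field = pd.DataFrame({
            "focus_id": [0], "subpop": ["simple"], "chord_id": [-1],
            "x_nm": [0.0], "y_nm": [0.0], "area_um2": [0.2],
            "psf_sigma_nm": [80.0], "amplitude": [300.0],
            "birth_min": [cfg.recording_start_offset_min]})
        # zero diffusion so the focus is rendered identically in every frame
        sub = cfg.subpopulations[0]
        cfg = cfg.replace(subpopulations=tuple(
            simulate.SubpopulationParams(s.label, s.weight, 0.0,
                                         simulate.MotionParams(0.0, s.motion.r_c),
                                         s.placement, s.area_mean_um2,
                                         s.area_sd_um2, s.optics)
            for s in cfg.subpopulations))
        field["death_min"] = np.inf
        stack, truth = simulate.render_movie(cfg, geom, field, rng)
        sums = stack.reshape(cfg.n_frames, -1).sum(axis=1).astype(float)
        assert np.ptp(sums) / sums.mean() < 1e-6

    def test_reproducibility_bit_identical(self):
        cfg = rifdyn.make_condition_preset("alpha", n_nuclei=2, n_frames=3, seed=77)
        a = simulate.simulate_experiment(cfg)
        b = simulate.simulate_experiment(cfg)
        for ma, mb in zip(a.movies, b.movies):
            assert np.array_equal(ma, mb)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_live_counts_non_increasing_without_births(self):
        cfg = rifdyn.make_condition_preset("gamma", n_nuclei=2, n_frames=30, seed=5)
        res = simulate.simulate_experiment(cfg)
        counts = res.truth.groupby("frame").size().reindex(
            range(1, cfg.n_frames + 1), fill_value=0)
        assert np.all(np.diff(counts.to_numpy()) <= 0)

    def test_expected_count_curve(self):
        cfg = rifdyn.make_condition_preset("gamma")
        t = np.array([0.0, 300.0])
        vals = simulate.expected_count(cfg, t)
        assert vals[0] == pytest.approx(30.9)
        assert vals[1] < vals[0]
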