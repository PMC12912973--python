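"""Tests for segmentation, exponential fits, rates and sigmoid fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_events, make_trajectory, simulate_set
from rodletkit.errors import UndefinedRateError, ValidationError
from rodletkit.kinetics import (
    HeightTrace,
    apparent_elongation_rate,
    correct_missed_events,
    detect_phases,
    equilibrium_constant,
    fit_exponential,
    fit_exponential_counts,
    fit_sigmoid_plateau,
    mean_window_height,
    pooled_interior_phases,
    step_rate,
    summarize_group,
)
from rodletkit.synthetic import TrajectoryParams, gen_end_trajectory


class TestDetectPhases:
    def test_constant_track_single_censored_dwell(self):
        ev = detect_phases(make_trajectory(np.full(20, 5.0)), threshold_nm=0.5)
        assert len(ev.phases) == 1
        assert ev.phases[0].kind == "dwell"
        assert ev.phases[0].duration == pytest.approx(19 * 12.75)
        assert ev.censored_first and ev.censored_last
        assert len(ev.step_phases(include_censored=True)) == 0

    def test_linear_ramp_single_censored_step(self):
        ev = detect_phases(make_trajectory(np.arange(20) * 5.0), threshold_nm=0.5)
        assert len(ev.phases) == 1
        assert ev.phases[0].kind == "step"
        assert ev.is_censored(0)

    def test_too_few_samples(self):
        with pytest.raises(ValidationError):
            make_trajectory([0.0, 1.0])

    def test_bad_threshold(self):
        with pytest.raises(ValidationError):
            detect_phases(make_trajectory(np.zeros(5)), threshold_nm=0.0)

    @staticmethod
    def _piecewise_trajectory(phase_spec, dt=12.75):
        """Noiseless trajectory from an explicit (kind, duration, delta) list."""
        knot_t, knot_y = [0.0], [0.0]
        latent = []
        t = 0.0
        for kind, duration, delta in phase_spec:
            latent.append((kind, t, duration, delta))
            t += duration
            knot_t.append(t)
            knot_y.append(knot_y[-1] + delta)
        times = np.arange(0.0, t, dt)
        positions = np.interp(times, knot_t, knot_y)
        return make_trajectory(positions, dt=dt), latent

    PHASE_SPEC = [
        ("dwell", 100.0, 0.0),
        ("step", 61.3, 42.0),
        ("dwell", 83.0, 0.0),
        ("step", 47.9, 18.5),
        ("dwell", 151.0, 0.0),
        ("step", 95.2, 61.0),
        ("dwell", 120.0, 0.0),
    ]

    @pytest.mark.parametrize("min_frames", [1, 2])
    def test_noiseless_recovery_within_one_frame(self, min_frames):
        traj, latent = self._piecewise_trajectory(self.PHASE_SPEC)
        ev = detect_phases(traj, threshold_nm=1e-3, min_frames=min_frames)
        det = ev.step_phases(include_censored=True)
        lat = [p for p in latent if p[0] == "step"]
        assert len(det) == len(lat)
        for dp, (_, start, duration, _delta) in zip(det, lat):
            assert abs(dp.start - start) <= 12.75
            assert abs(dp.end - (start + duration)) <= 12.75

    def test_noiseless_refined_boundaries_are_nearly_exact(self):
        # every step here spans >= 2 interior frames, so the line-fit
        # refinement recovers the true breakpoints essentially exactly
        traj, latent = self._piecewise_trajectory(self.PHASE_SPEC)
        ev = detect_phases(traj, threshold_nm=1e-3, min_frames=1)
        det = ev.step_phases(include_censored=True)
        for dp, (_, start, duration, delta) in zip(
            det, [p for p in latent if p[0] == "step"]
        ):
            assert dp.start == pytest.approx(start, abs=0.01)
            assert dp.duration == pytest.approx(duration, abs=0.02)
            assert dp.delta == pytest.approx(delta, abs=0.01)

    def test_phases_alternate_and_tile_record(self):
        params = TrajectoryParams(60.0, 30.0, 25.0, noise_sigma=0.3, duration=3000.0, seed=11)
        sim = gen_end_trajectory(params)
        ev = detect_phases(sim.trajectory, threshold_nm=0.6, min_frames=1)
        kinds = [p.kind for p in ev.phases]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))
        for a, b in zip(ev.phases, ev.phases[1:]):
            assert b.start == pytest.approx(a.end, abs=1e-6)
        assert all(p.duration > 0 for p in ev.phases)

    def test_min_dwell_enforcement_merges_short_dwells(self):
        params = TrajectoryParams(30.0, 15.0, 30.0, noise_sigma=0.3, duration=3000.0, seed=5)
        sim = gen_end_trajectory(params)
        ev = detect_phases(sim.trajectory, 0.6, min_frames=1, min_dwell_s=12.75)
        interior = [p for i, p in enumerate(ev.phases) if not ev.is_censored(i)]
        assert all(p.duration >= 12.75 for p in interior if p.kind == "dwell")


class TestFitExponential:
    def test_constant_values_mle(self):
        fit = fit_exponential([10.0, 10.0, 10.0])
        assert fit.tau == 10.0
        assert fit.method == "mle"

    def test_mle_recovers_exponential_mean(self, rng):
        draws = rng.exponential(43.6, 5000)
        fit = fit_exponential(draws)
        assert fit.tau == pytest.approx(43.6, rel=0.03)
        assert fit.tau == np.mean(draws)  # exact identity
        assert fit.ci95[0] < 43.6 < fit.ci95[1]

    def test_histogram_fit_on_exact_counts(self):
        t = np.arange(0.0, 101.0, 10.0)
        counts = 100.0 * np.exp(-t / 30.0)
        fit = fit_exponential_counts(t, counts)
        assert fit.tau == pytest.approx(30.0, rel=1e-6)
        assert fit.A == pytest.approx(100.0, rel=1e-6)

    def test_histogram_method_on_draws(self, rng):
        draws = rng.exponential(30.0, 4000)
        fit = fit_exponential(draws, method="histogram_lsq", bin_width=10.0)
        assert fit.tau == pytest.approx(30.0, rel=0.15)
        assert fit.method == "histogram_lsq"

    @given(st.lists(st.floats(min_value=0.01, max_value=1e4), min_size=2, max_size=50))
    def test_mle_tau_equals_sample_mean(self, values):
        assert fit_exponential(values).tau == pytest.approx(np.mean(values), rel=1e-12)

    def test_nonpositive_value_rejected(self):
        with pytest.raises(ValidationError):
            fit_exponential([1.0, 0.0])

    def test_too_few_values(self):
        with pytest.raises(ValidationError):
            fit_exponential([1.0])


class TestApparentElongationRate:
    def test_single_step(self):
        ev = make_events([("step", 0.0, 600.0, 100.0)])
        assert apparent_elongation_rate(ev) == pytest.approx(10.0)

    def test_two_steps_endpoints_only(self):
        ev = make_events(
            [
                ("step", 0.0, 300.0, 50.0),
                ("dwell", 300.0, 600.0, 0.0),
                ("step", 900.0, 300.0, 50.0),
            ]
        )
        assert apparent_elongation_rate(ev) == pytest.approx(5.0)

    def test_no_step_raises(self):
        ev = make_events([("dwell", 0.0, 100.0, 0.0)])
        with pytest.raises(UndefinedRateError):
            apparent_elongation_rate(ev)

    def test_ensemble_matches_renewal_reward_oracle(self):
        # long-run growth rate = mean step size / (tau_dwell + tau_step)
        td, ts, ms = 57.6, 27.6, 21.7
        sims = simulate_set(td, ts, ms, n=200, seed=21, duration=3000.0)
        rates = []
        for sim in sims:
            ev = detect_phases(sim.trajectory, 0.6, min_frames=1)
            try:
                rates.append(apparent_elongation_rate(ev))
            except UndefinedRateError:
                pass
        oracle = ms / (td + ts) * 60.0
        assert np.mean(rates) == pytest.approx(oracle, rel=0.15)


class TestStepRate:
    def test_single_step(self):
        ev = make_events([("step", 0.0, 60.0, 30.0)])
        mean, se = step_rate(ev)
        assert mean == pytest.approx(30.0)
        assert se == 0.0

    def test_two_steps_mean(self):
        ev = make_events(
            [
                ("step", 0.0, 60.0, 30.0),
                ("dwell", 60.0, 60.0, 0.0),
                ("step", 120.0, 60.0, 10.0),
            ]
        )
        mean, _ = step_rate(ev)
        assert mean == pytest.approx(20.0)

    def test_mean_of_ratios_differs_from_ratio_of_means(self, rng):
        sizes = rng.exponential(26.5, 1000)
        times = rng.exponential(29.7, 1000)
        mean_of_ratios = np.mean(sizes / times)
        ratio_of_means = np.mean(sizes) / np.mean(times)
        assert mean_of_ratios > ratio_of_means * 1.2  # skewed draws separate the two

    def test_censored_steps_excluded(self):
        ev = make_events(
            [("step", 0.0, 60.0, 30.0), ("dwell", 60.0, 60.0, 0.0), ("step", 120.0, 60.0, 10.0)],
            censored_first=True,
        )
        mean, _ = step_rate(ev)
        assert mean == pytest.approx(10.0)


class TestEquilibriumConstant:
    def test_bundled_printed_value(self):
        assert round(equilibrium_constant(43.6, 20.6), 2) == 2.12

    def test_single_printed_value(self):
        assert round(equilibrium_constant(67.1, 31.2), 2) == 2.15

    def test_symmetry(self):
        assert equilibrium_constant(37.0, 37.0) == pytest.approx(1.0)

    @given(
        st.floats(min_value=1e-3, max_value=1e3),
        st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_reciprocal_identity(self, a, b):
        assert equilibrium_constant(a, b) * equilibrium_constant(b, a) == pytest.approx(1.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            equilibrium_constant(-1.0, 2.0)


class TestSigmoidPlateau:
    @staticmethod
    def _logistic_trace(plateau, mid, width, noise=0.0, seed=0, t_max=1800.0):
        t = np.arange(0.0, t_max, 12.75)
        h = plateau / (1.0 + np.exp(-(t - mid) / width))
        if noise:
            h = h + np.random.default_rng(seed).normal(0.0, noise, t.size)
        return HeightTrace(t, h, converts=True)

    def test_noiseless_exact_recovery(self):
        trace = self._logistic_trace(2.3, 600.0, 120.0)
        assert fit_sigmoid_plateau(trace) == pytest.approx(2.3, abs=1e-6)

    def test_mean_recovery_over_17_noisy_traces(self):
        plateaus = [
            fit_sigmoid_plateau(self._logistic_trace(2.3, 600.0, 120.0, noise=0.2, seed=s))
            for s in range(17)
        ]
        assert np.mean(plateaus) == pytest.approx(2.3, abs=0.1)

    def test_constant_trace_degenerate(self):
        trace = HeightTrace(np.arange(10.0), np.full(10, 1.7), converts=False)
        assert fit_sigmoid_plateau(trace) == pytest.approx(1.7)

    def test_too_few_samples(self):
        trace = HeightTrace(np.arange(4.0), np.arange(4.0), converts=True)
        with pytest.raises(ValidationError):
            fit_sigmoid_plateau(trace)


class TestMeanWindowHeight:
    def test_constant_trace(self):
        t = np.arange(0.0, 2000.0, 12.75)
        trace = HeightTrace(t, np.full(t.size, 3.1), converts=False)
        assert mean_window_height(trace, 1600.0, 1800.0) == pytest.approx(3.1)

    def test_three_point_mean(self):
        trace = HeightTrace([1600.0, 1700.0, 1800.0], [1.0, 2.0, 3.0], converts=False)
        assert mean_window_height(trace, 1600.0, 1800.0) == pytest.approx(2.0)

    def test_window_outside_trace(self):
        trace = HeightTrace([0.0, 1.0, 2.0], [1.0, 1.0, 1.0], converts=False)
        with pytest.raises(ValidationError):
            mean_window_height(trace, 10.0, 20.0)


class TestSummarizeGroup:
    def test_single_trajectory_composition_identity(self):
        sims = simulate_set(61.0, 29.7, 26.5, n=1, seed=31, duration=3000.0)
        traj = sims[0].trajectory
        table = summarize_group([traj], grouping="context", threshold_nm=0.6, min_frames=1)
        ev = detect_phases(traj, 0.6, min_frames=1)
        row = table.loc["single"]
        assert row["tau_dwell"] == pytest.approx(fit_exponential(ev.dwell_durations()).tau)
        assert row["tau_step"] == pytest.approx(fit_exponential(ev.step_durations()).tau)
        assert row["apparent_rate"] == pytest.approx(apparent_elongation_rate(ev))
        assert row["K_d"] == pytest.approx(row["tau_dwell"] / row["tau_step"])

    def test_group_ordering_preserved(self):
        bundled = simulate_set(43.6, 20.6, 36.4, n=150, seed=41, duration=2000.0,
                               context="bundled")
        single = simulate_set(67.1, 31.2, 22.2, n=150, seed=42, duration=2000.0,
                              context="single")
        trajs = [s.trajectory for s in bundled + single]
        table = summarize_group(trajs, grouping="context", threshold_nm=0.6, min_frames=1)
        assert table.loc["bundled", "tau_dwell"] < table.loc["single", "tau_dwell"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            summarize_group([])

    def test_unknown_grouping_rejected(self):
        sims = simulate_set(61.0, 29.7, 26.5, n=1, seed=31)
        with pytest.raises(ValidationError):
            summarize_group([sims[0].trajectory], grouping="nope")


@pytest.mark.parametrize(
    "name", ["preexisting", "de_novo", "fast", "slow", "bundled", "single"]
)
def test_pipeline_parameter_recovery_within_10_percent(name):
    """generate -> detect -> corrected fit recovers the printed parameter sets."""
    from conftest import PRINTED_SETS
    from rodletkit.kinetics import recalibrate_kinetics

    td, ts, ms = PRINTED_SETS[name]
    sims = simulate_set(td, ts, ms, n=200, seed=7, duration=3000.0)
    events = [
        detect_phases(s.trajectory, 0.6, min_frames=1, min_dwell_s=12.75) for s in sims
    ]
    dw, st_, sz, total = pooled_interior_phases(events)
    est = correct_missed_events(dw, st_, sz, total)
    est = recalibrate_kinetics(est, duration=3000.0, n_sim=150, seed=13)
    assert est.tau_dwell == pytest.approx(td, rel=0.10)
    assert est.tau_step == pytest.approx(ts, rel=0.10)
    assert est.mean_step_size == pytest.approx(ms, rel=0.10)
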