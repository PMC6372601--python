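"""Burst detection, IBI statistics, and the square-root interburst law."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sacburst import (
    BurstConfig,
    BurstEvent,
    ModelParameters,
    detect_bursts,
    fit_ibi_distribution,
    fit_sqrt_law,
    ibi_ensemble,
    ibi_heatmap,
    ibi_vs_iext,
    interburst_intervals,
)
from conftest import make_calcium_trace


def square_wave(levels_and_durations, sample_dt=100.0):
    """Piecewise-constant calcium trace; durations in ms."""
    parts = [
        np.full(int(round(d / sample_dt)), level)
        for level, d in levels_and_durations
    ]
    return make_calcium_trace(np.concatenate(parts), sample_dt)


class TestDetectBursts:
    def test_single_supra_threshold_excursion(self):
        trace = square_wave([(100, 5000), (200, 2000), (100, 5000)])
        events = detect_bursts(trace)
        assert len(events) == 1
        assert events[0].duration == pytest.approx(2000.0, abs=200.0)

    def test_short_excursion_is_not_a_burst(self):
        trace = square_wave([(100, 5000), (200, 500), (100, 5000)])
        assert detect_bursts(trace) == []

    def test_sub_threshold_dip_splits_bursts(self):
        trace = square_wave(
            [(100, 3000), (200, 1500), (100, 300), (200, 1500), (100, 3000)]
        )
        assert len(detect_bursts(trace)) == 2

    def test_boundary_touching_runs_discarded(self):
        trace = square_wave([(200, 3000), (100, 3000), (200, 3000)])
        assert detect_bursts(trace) == []

    def test_empty_trace_rejected(self):
        trace = make_calcium_trace(np.array([100.0]))
        with pytest.raises(ValueError):
            detect_bursts(trace)

    def test_count_invariant_under_oversampling(self):
        spec = [(100, 4000), (200, 1800), (100, 2000), (200, 3100), (100, 4000)]
        coarse = square_wave(spec, sample_dt=100.0)
        fine = square_wave(spec, sample_dt=10.0)
        assert len(detect_bursts(coarse)) == len(detect_bursts(fine)) == 2

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.sampled_from([80.0, 120.0, 180.0, 250.0]),
                      st.floats(200.0, 4000.0)),
            min_size=2, max_size=12,
        )
    )
    def test_detected_events_satisfy_definition(self, segments):
        cfg = BurstConfig()
        trace = square_wave(segments, sample_dt=100.0)
        if trace.states.shape[0] < 2:
            return
        events = detect_bursts(trace, cfg)
        onsets = [e.t_onset for e in events]
        assert onsets == sorted(onsets)
        for a, b in zip(events, events[1:]):
            assert a.t_offset <= b.t_onset  # disjoint
        C, t = trace.C, trace.times
        for e in events:
            inside = (t >= e.t_onset) & (t < e.t_offset)
            assert np.all(C[inside] > cfg.calcium_threshold)
            assert e.duration >= cfg.min_duration
            assert e.t_onset > t[0] and e.t_offset < t[-1]


class TestInterburstIntervals:
    def test_onset_to_onset(self):
        events = [BurstEvent(10_000.0, 12_000.0), BurstEvent(70_000.0, 73_000.0),
                  BurstEvent(130_000.0, 131_500.0)]
        assert interburst_intervals(events) == pytest.approx([60_000.0, 60_000.0])

    def test_single_event_gives_empty(self):
        assert interburst_intervals([BurstEvent(0.0, 2000.0)]).size == 0

    def test_order_invariance(self):
        events = [BurstEvent(50_000.0, 52_000.0), BurstEvent(10_000.0, 12_000.0),
                  BurstEvent(90_000.0, 93_000.0)]
        assert np.array_equal(
            interburst_intervals(events), interburst_intervals(events[::-1])
        )


class TestIbiEnsemble:
    def test_noise_driven_bursting_present(self, defaults):
        p = defaults.replace(I_ext_baseline=-4.0, sigma=4.0)
        stats = ibi_ensemble(p, n_traj=2, T=400_000.0, base_seed=0)
        assert stats.n_bursts >= 1

    def test_silent_below_fold_without_noise(self, defaults):
        p = defaults.replace(I_ext_baseline=-10.0, sigma=0.0)
        stats = ibi_ensemble(p, n_traj=1, T=200_000.0, base_seed=0)
        assert stats.n_bursts == 0
        assert stats.n_silent_trajectories == 1

    def test_seeded_reproducibility(self, defaults):
        a = ibi_ensemble(defaults, n_traj=2, T=100_000.0, base_seed=3)
        b = ibi_ensemble(defaults, n_traj=2, T=100_000.0, base_seed=3)
        assert np.array_equal(a.ibis, b.ibis)


class TestHeatmapAndSweep:
    def test_silent_cell_is_missing_not_zero(self, defaults):
        p = defaults.replace(I_ext_baseline=-4.0, sigma=4.0)
        grid = ibi_heatmap(
            np.array([3.0]), np.array([20.0]), p, n_traj=2, T=150_000.0, base_seed=0
        )
        assert np.isnan(grid[0, 0])

    def test_bursting_cell_has_finite_mean(self, defaults):
        grid = ibi_heatmap(
            np.array([12.0]), np.array([10.0]), defaults,
            n_traj=2, T=150_000.0, base_seed=0,
        )
        assert np.isfinite(grid[0, 0]) and grid[0, 0] > 0

    def test_sweep_zero_convention_below_critical_current(self, defaults):
        curve = ibi_vs_iext([-20.0], defaults, n_traj=1, T=150_000.0, base_seed=0)
        assert curve[0, 1] == 0.0

    def test_sweep_zero_convention_in_tonic_regime(self, defaults):
        curve = ibi_vs_iext([60.0], defaults, n_traj=1, T=150_000.0, base_seed=0)
        assert curve[0, 1] == 0.0


class TestSqrtLawFit:
    @pytest.mark.parametrize("form", ["plain", "halved"])
    def test_exact_recovery_on_noiseless_curve(self, form):
        K_true, I_c_true = 0.657, -5.0
        I = np.linspace(-4.0, 40.0, 30)
        denom = 2.0 if form == "halved" else 1.0
        tau_ms = 1000.0 * K_true / (denom * np.sqrt(I - I_c_true))
        fit = fit_sqrt_law(np.column_stack([I, tau_ms]), form=form)
        assert fit.K == pytest.approx(K_true, abs=1e-6)
        assert fit.I_c == pytest.approx(I_c_true, abs=1e-6)

    def test_factor_two_relation_between_forms(self):
        I = np.linspace(-4.0, 40.0, 25)
        tau_ms = 1000.0 * 0.5 / np.sqrt(I + 5.0)
        curve = np.column_stack([I, tau_ms])
        k9 = fit_sqrt_law(curve, form="plain").K
        k6 = fit_sqrt_law(curve, form="halved").K
        assert k6 == pytest.approx(2.0 * k9, rel=1e-9)

    def test_recovery_under_multiplicative_noise(self):
        rng = np.random.default_rng(11)
        K_true, I_c_true = 0.657, -5.0
        I = np.linspace(-4.0, 40.0, 30)
        tau_ms = 1000.0 * K_true / np.sqrt(I - I_c_true)
        tau_noisy = tau_ms * (1 + 0.05 * rng.standard_normal(I.size))
        fit = fit_sqrt_law(np.column_stack([I, tau_noisy]))
        assert fit.K == pytest.approx(K_true, rel=0.10)
        assert fit.I_c == pytest.approx(I_c_true, abs=1.0)

    def test_estimator_is_unbiased(self):
        rng = np.random.default_rng(99)
        K_true, I_c_true = 0.657, -5.0
        I = np.linspace(-4.0, 40.0, 30)
        tau_ms = 1000.0 * K_true / np.sqrt(I - I_c_true)
        Ks = []
        for _ in range(100):
            noisy = tau_ms * (1 + 0.05 * rng.standard_normal(I.size))
            Ks.append(fit_sqrt_law(np.column_stack([I, noisy])).K)
        assert np.mean(Ks) == pytest.approx(K_true, rel=0.02)

    def test_too_few_points_rejected(self):
        curve = np.array([[0.0, 1000.0], [5.0, 800.0], [10.0, 0.0], [20.0, 0.0]])
        with pytest.raises(ValueError, match=">= 4"):
            fit_sqrt_law(curve)

    def test_window_excludes_outside_points(self):
        I = np.concatenate([np.linspace(-4.0, 40.0, 20), [200.0]])
        tau_ms = 1000.0 * 0.657 / np.sqrt(I + 5.0)
        tau_ms[-1] = 1e6  # corrupted point far outside the fit window
        fit = fit_sqrt_law(np.column_stack([I, tau_ms]))
        assert fit.K == pytest.approx(0.657, abs=1e-6)
        assert fit.n_points == 20


class TestDistributionFit:
    def test_gaussian_samples_select_gaussian(self):
        rng = np.random.default_rng(5)
        ibis = rng.normal(20_000.0, 2000.0, size=400)
        fit = fit_ibi_distribution(np.abs(ibis), "gaussian")
        assert fit.selected

    def test_mixture_selects_composite(self):
        rng = np.random.default_rng(6)
        gauss = rng.normal(25_000.0, 2000.0, size=300)
        expo = rng.exponential(6000.0, size=300)
        fit = fit_ibi_distribution(
            np.abs(np.concatenate([gauss, expo])), "gaussian_plus_exponential"
        )
        assert fit.selected

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 20"):
            fit_ibi_distribution(np.ones(10) * 1000.0)
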