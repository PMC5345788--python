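"""Mean-event averaging, exponential fits, F-test selection and tau_w."""

import numpy as np
import pytest

from minikin.detect import SweepTrace, detect_events
from minikin.kinetics import (
    InsufficientEventsError,
    MeanEvent,
    analyze_cell,
    average_events,
    cell_summary,
    fit_decay,
    fit_mean_event,
    select_model,
    weighted_tau,
)
from minikin.simulate import EventKinetics, SimConfig, simulate_sweep

FS = 10_000.0
DT = 1e3 / FS


def _sweep_with_events(kinetics, onsets_s, amp=-40.0, n_samples=200_000):
    from minikin.simulate import _eval_event

    x = np.zeros(n_samples)
    for o in onsets_s:
        i0 = int(np.ceil(o * FS))
        m = min(n_samples - i0, 4000)
        t_ms = (np.arange(i0, i0 + m) / FS - o) * 1e3
        x[i0 : i0 + m] += _eval_event(kinetics, amp, t_ms)
    return SweepTrace(x, FS)


class TestAverageEvents:
    def test_idempotence_identical_events(self):
        """Averaging N copies of one waveform reproduces that waveform."""
        k = EventKinetics.from_tau_w(18.0)
        onsets = [1.0, 2.0, 3.0, 4.0, 5.0]
        tr = _sweep_with_events(k, onsets, n_samples=70_000)
        z = np.zeros(len(tr.samples))
        events = detect_events(tr, baseline=z, pre_exclusion_ms=400, post_window_ms=150)
        me = average_events(tr, events, baseline=z)
        assert me.n_events == len(onsets)
        peak = me.waveform.min()
        assert peak == pytest.approx(-40.0, rel=0.01)
        # post-peak decay matches the injected biexponential
        p = me.peak_index
        t = np.arange(len(me.waveform) - p) * DT
        expected = peak * (
            k.p_fast * np.exp(-t / k.tau_fast) + (1 - k.p_fast) * np.exp(-t / k.tau_slow)
        )
        np.testing.assert_allclose(me.waveform[p:], expected, atol=0.25)

    def test_two_tau_mean_is_average_of_exponentials(self):
        """Mean of tau=10 and tau=30 mono events is the two-term average."""
        k10 = EventKinetics(tau_fast=10.0, tau_slow=10.0, p_fast=1.0)
        k30 = EventKinetics(tau_fast=30.0, tau_slow=30.0, p_fast=1.0)
        x = np.zeros(60_000)
        tr = SweepTrace(x, FS)
        from minikin.simulate import _eval_event

        for k, o in ((k10, 1.0), (k30, 3.0)):
            i0 = int(np.ceil(o * FS))
            t_ms = (np.arange(i0, i0 + 4000) / FS - o) * 1e3
            tr.samples[i0 : i0 + 4000] += _eval_event(k, -40.0, t_ms)
        z = np.zeros(len(tr.samples))
        events = detect_events(tr, baseline=z, pre_exclusion_ms=400)
        me = average_events(tr, events, baseline=z)
        p = me.peak_index
        t = np.arange(len(me.waveform) - p) * DT
        expected = -20.0 * (np.exp(-t / 10.0) + np.exp(-t / 30.0))
        np.testing.assert_allclose(me.waveform[p:], expected, atol=0.3)

    def test_subsample_alignment_recovers_jitter_free_mean(self):
        """Events at arbitrary sub-sample onsets average to the clean shape."""
        k = EventKinetics.from_tau_w(20.0)
        rng = np.random.default_rng(5)
        onsets = np.arange(1.0, 25.0, 0.8) + rng.uniform(0, 2 * DT / 1e3 * 10, 30)
        tr = _sweep_with_events(k, onsets, n_samples=300_000)
        z = np.zeros(len(tr.samples))
        events = detect_events(tr, baseline=z, pre_exclusion_ms=400, post_window_ms=150)
        me = average_events(tr, events, baseline=z)
        p = me.peak_index
        t = np.arange(len(me.waveform) - p) * DT
        expected = me.waveform[p] * (
            k.p_fast * np.exp(-t / k.tau_fast) + (1 - k.p_fast) * np.exp(-t / k.tau_slow)
        )
        np.testing.assert_allclose(me.waveform[p:], expected, atol=0.3)

    def test_too_few_events_errors(self):
        k = EventKinetics.from_tau_w(20.0)
        tr = _sweep_with_events(k, [1.0], n_samples=40_000)
        z = np.zeros(len(tr.samples))
        events = detect_events(tr, baseline=z)
        with pytest.raises(InsufficientEventsError):
            average_events(tr, events, baseline=z)


def _mean_event_from(y, dt=DT, n_events=60):
    return MeanEvent(waveform=np.asarray(y, float), dt=dt, n_events=n_events)


class TestFitDecay:
    def test_mono_exact_recovery(self):
        t = np.arange(1500) * DT
        me = _mean_event_from(-40.0 * np.exp(-t / 18.0))
        (a, tau), sd, n = fit_decay(me, "mono")
        assert a == pytest.approx(-40.0, rel=1e-3)
        assert tau == pytest.approx(18.0, rel=1e-3)
        assert sd < 1e-6

    def test_bi_noiseless_recovery(self):
        t = np.arange(1500) * DT
        y = -30.0 * np.exp(-t / 6.0) - 10.0 * np.exp(-t / 45.0)
        (a1, t1, a2, t2), sd, n = fit_decay(_mean_event_from(y), "bi")
        assert a1 == pytest.approx(-30.0, rel=0.01)
        assert t1 == pytest.approx(6.0, rel=0.01)
        assert a2 == pytest.approx(-10.0, rel=0.01)
        assert t2 == pytest.approx(45.0, rel=0.01)
        assert t1 < t2

    def test_nested_models_mono_sd_not_smaller(self):
        rng = np.random.default_rng(7)
        t = np.arange(1200) * DT
        y = -30.0 * np.exp(-t / 6.0) - 10.0 * np.exp(-t / 45.0) + rng.normal(0, 0.2, len(t))
        me = _mean_event_from(y)
        _, sd_m, _ = fit_decay(me, "mono")
        _, sd_b, _ = fit_decay(me, "bi")
        assert sd_m > sd_b

    def test_grid_search_oracle_agrees(self):
        """Coarse brute-force grid over (tau_f, tau_s, p1) agrees with the fit."""
        t = np.arange(800) * DT
        truth = (-24.0, 5.0, -16.0, 40.0)
        y = truth[0] * np.exp(-t / truth[1]) + truth[2] * np.exp(-t / truth[3])
        (a1, t1, a2, t2), _, _ = fit_decay(_mean_event_from(y), "bi")

        best = None
        a_tot = y[0]
        for tf in np.linspace(2, 12, 21):
            for ts in np.linspace(20, 60, 21):
                for p1 in np.linspace(0.1, 0.9, 17):
                    model = a_tot * (p1 * np.exp(-t / tf) + (1 - p1) * np.exp(-t / ts))
                    sse = np.sum((y - model) ** 2)
                    if best is None or sse < best[0]:
                        best = (sse, tf, ts, p1)
        _, tf_g, ts_g, p1_g = best
        assert t1 == pytest.approx(tf_g, abs=0.5)
        assert t2 == pytest.approx(ts_g, abs=2.0)
        assert a1 / (a1 + a2) == pytest.approx(p1_g, abs=0.05)


class TestSelectModel:
    def test_equal_residuals_select_mono(self):
        c = select_model(0.5, 0.5, 500)
        assert c.model == "mono"
        assert c.f_pvalue == 1.0

    def test_perfect_bi_fit_infinite_f(self):
        c = select_model(0.5, 0.0, 500)
        assert c.model == "bi"
        assert np.isinf(c.f_statistic)

    def test_clear_improvement_selects_bi(self):
        c = select_model(1.0, 0.5, 500)
        assert c.model == "bi"
        assert c.f_pvalue < 1e-6

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            select_model(1.0, 0.5, 4)


class TestWeightedTau:
    def test_arithmetic_mean_case(self):
        tau_w, p1 = weighted_tau(-10.0, 10.0, -10.0, 30.0)
        assert tau_w == pytest.approx(20.0)
        assert p1 == pytest.approx(0.5)

    def test_single_component_identity(self):
        tau_w, p1 = weighted_tau(-20.0, 10.0, 0.0, 30.0)
        assert tau_w == pytest.approx(10.0)
        assert p1 == pytest.approx(1.0)

    def test_printed_formula_direct_evaluation(self):
        tau_w, p1 = weighted_tau(-30.0, 5.0, -10.0, 40.0)
        assert p1 == pytest.approx(0.75)
        assert tau_w == pytest.approx(13.75)

    def test_area_fraction_variant(self):
        tau_w, p1 = weighted_tau(-30.0, 5.0, -10.0, 40.0, area_fractions=True)
        assert p1 == pytest.approx(150.0 / 550.0)
        assert min(5.0, 40.0) <= tau_w <= max(5.0, 40.0)

    def test_degenerate_amplitudes_raise(self):
        with pytest.raises(ValueError):
            weighted_tau(-10.0, 5.0, 10.0, 40.0)

    def test_tau_w_between_components(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a1, a2 = -rng.uniform(1, 50, 2)
            t1 = rng.uniform(1, 20)
            t2 = t1 + rng.uniform(0.1, 50)
            tau_w, _ = weighted_tau(a1, t1, a2, t2)
            assert t1 - 1e-9 <= tau_w <= t2 + 1e-9


class TestFitMeanEventAndSummary:
    def test_mono_generated_takes_mono_path(self):
        """On clean mono data with noise the pipeline reports the mono tau."""
        rng = np.random.default_rng(3)
        t = np.arange(1200) * DT
        y = -40.0 * np.exp(-t / 20.0) + rng.normal(0, 0.15, len(t))
        fit = fit_mean_event(_mean_event_from(y))
        if fit.model == "mono":  # the F test keeps mono with ~95% probability
            assert fit.tau_w == pytest.approx(fit.tau, rel=1e-12)
            assert fit.p1 == 1.0
        else:
            assert fit.tau_w == pytest.approx(20.0, rel=0.15)

    def test_t67_close_to_tau_w(self):
        """Decay-by-67% time of the mean event stays within 25% of tau_w."""
        k = EventKinetics.from_tau_w(24.8)
        t = np.arange(1500) * DT
        y = -45.0 * (k.p_fast * np.exp(-t / k.tau_fast) + (1 - k.p_fast) * np.exp(-t / k.tau_slow))
        fit = fit_mean_event(_mean_event_from(y))
        # interpolated time to decay to 33% of the peak
        frac = y / y[0]
        i = np.nonzero(frac <= 0.33)[0][0]
        t67 = np.interp(0.33, [frac[i], frac[i - 1]], [t[i], t[i - 1]])
        assert abs(t67 - fit.tau_w) / fit.tau_w <= 0.25

    def test_cell_summary_enforces_event_minimum(self, noisy_sweep):
        trace, _ = noisy_sweep
        events = detect_events(trace)
        me = average_events(trace, events)
        fit = fit_mean_event(me)
        with pytest.raises(InsufficientEventsError):
            cell_summary(events, fit, cell_id="c", min_events=10_000)
        cs = cell_summary(events, fit, cell_id="c")
        assert cs.n_events >= 50
        assert cs.tau_w == pytest.approx(fit.tau_w)

    def test_closed_loop_single_cell(self):
        """Full pipeline on one noiseless cell recovers the generator tau_w."""
        k = EventKinetics.from_tau_w(24.8)
        cfg = SimConfig(
            kinetics=k,
            event_rate=1.2,
            sweep_duration=70.0,
            noise_sd=0.0,
            filter_cutoff=None,
            seed=3,
        )
        tr, _ = simulate_sweep(cfg)
        cs = analyze_cell(tr, cell_id="cl")
        assert cs.model == "bi"
        assert cs.tau_w == pytest.approx(24.8, rel=0.03)
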