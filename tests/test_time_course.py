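"""Time-course simulation, mono-exponential fitting and integrator checks."""

import numpy as np
import pytest

from girkcascade import (
    CurrentTrace,
    FitError,
    StimulusProtocol,
    fit_monoexponential,
    simulate_activation,
    solve_preagonist,
)
from girkcascade.time_course import read_trace, write_trace
from tests.conftest import CHANNEL_DENSITY


@pytest.fixture(scope="module")
def init_state(full_network, hd_totals):
    gbg, ga = hd_totals
    return solve_preagonist(
        full_network,
        {"receptor": 31.25 / CHANNEL_DENSITY, "Galpha": ga, "Gbg": gbg},
    )


class TestSimulateActivation:
    def test_no_agonist_current_stays_basal(self, full_network, init_state,
                                            gating, ctx):
        proto = StimulusProtocol(agonist=0.0, onset=0.5, duration=5.0)
        trace = simulate_activation(full_network, init_state, gating, ctx, proto,
                                    sample_rate=200)
        assert np.ptp(trace.current) < 1e-3 * trace.current[0]

    def test_agonist_step_rises_to_plateau(self, full_network, init_state,
                                           gating, ctx):
        proto = StimulusProtocol(duration=30.0)
        trace = simulate_activation(full_network, init_state, gating, ctx, proto,
                                    sample_rate=200)
        base = trace.current[trace.time < proto.onset].mean()
        evoked = trace.current[-1] - base
        assert evoked > 0
        # smoothness: the rise is monotone after onset at this resolution
        post = trace.current[trace.time >= proto.onset + 0.1]
        assert np.all(np.diff(post) > -1e-4 * evoked)

    def test_exchange_filter_slows_onset(self, full_network, init_state,
                                         gating, ctx):
        fast = simulate_activation(full_network, init_state, gating, ctx,
                                   StimulusProtocol(duration=5.0), sample_rate=500)
        slow = simulate_activation(
            full_network, init_state, gating, ctx,
            StimulusProtocol(duration=5.0, tau_exchange=0.0886), sample_rate=500,
        )
        sel = (fast.time > 1.05) & (fast.time < 2.0)
        assert np.all(slow.current[sel] <= fast.current[sel] + 1e-9)

    def test_rk4_agrees_with_adaptive(self, full_network, init_state, gating, ctx):
        """Fixed-step RK4 (1 ms) and the stiff solver give the same tau within 1%."""
        proto = StimulusProtocol(onset=0.2, duration=12.0)
        t_ad = simulate_activation(full_network, init_state, gating, ctx, proto,
                                   sample_rate=500)
        t_rk = simulate_activation(full_network, init_state, gating, ctx, proto,
                                   method="RK4", sample_rate=500, rk4_step=1e-3)
        tau_ad = fit_monoexponential(t_ad).tau_act
        tau_rk = fit_monoexponential(t_rk).tau_act
        assert tau_rk == pytest.approx(tau_ad, rel=0.01)

    def test_rk4_step_halving_converged(self, full_network, init_state, gating, ctx):
        proto = StimulusProtocol(onset=0.1, duration=4.0)
        coarse = simulate_activation(full_network, init_state, gating, ctx, proto,
                                     method="RK4", sample_rate=100, rk4_step=1e-3)
        fine = simulate_activation(full_network, init_state, gating, ctx, proto,
                                   method="RK4", sample_rate=100, rk4_step=5e-4)
        scale = np.abs(fine.current).max()
        assert np.max(np.abs(coarse.current - fine.current)) < 1e-4 * scale


class TestMonoExponentialFit:
    def test_exact_exponential_recovered(self):
        t = np.arange(0, 10, 1e-3)
        tau, base, amp, onset = 0.5, 2.0, 5.0, 1.0
        i = base + amp * (1 - np.exp(-np.clip(t - onset, 0, None) / tau))
        fit = fit_monoexponential(CurrentTrace(t, i, {"onset": onset}))
        assert fit.tau_act == pytest.approx(tau, abs=1e-6)
        assert fit.i_evoked == pytest.approx(amp, rel=1e-6)
        assert fit.i_basal == pytest.approx(base, rel=1e-6)

    def test_noisy_exponential_monte_carlo(self):
        """2% amplitude noise: tau recovered within 5% across 100 seeds."""
        t = np.arange(0, 10, 1e-3)
        tau, base, amp, onset = 0.5, 2.0, 5.0, 1.0
        clean = base + amp * (1 - np.exp(-np.clip(t - onset, 0, None) / tau))
        errs = []
        rng = np.random.default_rng(42)
        for _ in range(100):
            noisy = clean + rng.normal(0, 0.02 * amp, t.shape)
            fit = fit_monoexponential(CurrentTrace(t, noisy, {"onset": onset}))
            errs.append(abs(fit.tau_act - tau) / tau)
        assert np.median(errs) < 0.05

    def test_flat_trace_raises(self):
        t = np.arange(0, 5, 1e-3)
        with pytest.raises(FitError):
            fit_monoexponential(CurrentTrace(t, np.full_like(t, 3.0), {"onset": 1.0}))

    def test_cascade_trace_reports_residual(self, full_network, init_state,
                                            gating, ctx):
        """The simulated cascade is not exactly exponential; the fit says so."""
        trace = simulate_activation(full_network, init_state, gating, ctx,
                                    StimulusProtocol(duration=20.0), sample_rate=200)
        fit = fit_monoexponential(trace)
        assert fit.tau_act > 0 and fit.i_evoked > 0
        assert fit.residual_norm > 0  # honest lack-of-fit measure


class TestTraceIO:
    def test_round_trip(self, tmp_path, full_network, init_state, gating, ctx):
        trace = simulate_activation(full_network, init_state, gating, ctx,
                                    StimulusProtocol(duration=2.0), sample_rate=100)
        path = tmp_path / "trace.csv"
        write_trace(trace, path)
        back = read_trace(path)
        assert np.allclose(back.time, trace.time)
        assert np.allclose(back.current, trace.current)
        assert back.metadata["onset"] == trace.metadata["onset"]


def test_diagnostic_plots_render(tmp_path):
    import pandas as pd

    from girkcascade.plotting import plot_sweep, plot_trace

    t = np.arange(0, 5, 0.01)
    i = 2.0 + 3.0 * (1 - np.exp(-np.clip(t - 1.0, 0, None) / 0.4))
    trace = CurrentTrace(t, i, {"onset": 1.0})
    ax = plot_trace(trace, fit=fit_monoexponential(trace))
    ax.figure.savefig(tmp_path / "trace.png")
    table = pd.DataFrame({
        "receptor_density": [1.0, 10.0, 100.0],
        "tau_act_ms": [3000.0, 800.0, 550.0],
        "i_evoked_uA": [2.0, 3.5, 3.7],
    })
    ax2 = plot_sweep(table)
    ax2.figure.savefig(tmp_path / "sweep.png")
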