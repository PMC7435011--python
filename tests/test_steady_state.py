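"""Pre-agonist steady states, current inversion and gating calibration."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from girkcascade import (
    InitialConditionSpec,
    ParameterError,
    SteadyStateError,
    UnitConversion,
    activation_capacity_current,
    attach_channel,
    basal_current,
    build_tandem_network,
    invert_basal_currents,
    solve_preagonist,
)
from girkcascade.steady_state import LEGEND_TARGETS, _steady_residual, calibrate_gating
from tests.conftest import CHANNEL_DENSITY


class TestSolvePreagonist:
    def test_no_gbg_all_channels_empty(self, full_network, gating):
        state = solve_preagonist(full_network, {"Galpha": 0.5, "Gbg": 0.0})
        assert state["C0"] == pytest.approx(1.0)
        assert state.open_probability(gating) == gating.po_vector[0]

    def test_fixed_point_of_the_ode(self, full_network):
        """Time integration from the algebraic state changes nothing over 100 s."""
        state = solve_preagonist(
            full_network, {"receptor": 1.4, "Galpha": 0.38, "Gbg": 3.62}
        )
        sol = solve_ivp(lambda _t, y: full_network.rhs(y, 0.0), (0, 100), state.y,
                        method="LSODA", rtol=1e-10, atol=1e-14)
        scale = np.maximum(np.abs(state.y), 1e-3)
        assert np.max(np.abs(sol.y[:, -1] - state.y) / scale) < 1e-6

    def test_saturating_gbg_reaches_po_max(self, full_network, gating):
        state = solve_preagonist(full_network, {"Galpha": 0.0, "Gbg": 500.0})
        assert state.open_probability(gating) == pytest.approx(0.105, rel=1e-3)

    def test_conservation_totals_exact(self, full_network):
        totals = {"receptor": 0.7, "Galpha": 0.45, "Gbg": 3.23}
        state = solve_preagonist(full_network, totals)
        got = state.conservation_totals()
        for key, want in totals.items():
            assert got[key] == pytest.approx(want, rel=1e-10)
        assert got["channel"] == pytest.approx(1.0, rel=1e-12)

    def test_tandem_steady_state_is_fixed_point(self, rates, gating):
        conv = UnitConversion.from_channel_density(9.7)
        net = attach_channel(build_tandem_network(rates, conv, 1), gating, conv)
        state = solve_preagonist(net, {"receptor": 2.0, "Gbg": 3.5})
        assert _steady_residual(net, state.y) < 1e-9

    def test_negative_totals_rejected(self, full_network):
        with pytest.raises(ParameterError):
            solve_preagonist(full_network, {"Gbg": -1.0})


class TestInversion:
    def test_round_trip_recovers_known_totals(self, gating, conv, ctx, rates):
        """Currents generated from known totals invert back within 1%."""
        true_gbg, true_ga = 3.4, 0.5
        i_total = activation_capacity_current(true_gbg, gating, conv, ctx)
        i_basal = basal_current(true_gbg, true_ga, gating, conv, ctx, rates)
        inv = invert_basal_currents(
            InitialConditionSpec(CHANNEL_DENSITY, i_basal, i_total), gating, conv, rates
        )
        assert inv.gbg_total == pytest.approx(true_gbg, rel=1e-2)
        assert inv.ga_total == pytest.approx(true_ga, rel=1e-2)

    def test_zero_basal_means_fully_sequestered_pool(self, gating, conv, ctx, rates):
        i_total = activation_capacity_current(2.0, gating, conv, ctx)
        inv = invert_basal_currents(
            InitialConditionSpec(CHANNEL_DENSITY, 0.0, i_total), gating, conv, rates
        )
        state_free_gbg = basal_current(inv.gbg_total, inv.ga_total, gating, conv,
                                       ctx, rates)
        assert state_free_gbg < 1e-3  # uA: essentially no basal activity

    def test_infeasible_current_raises(self, gating, conv, rates, ctx):
        with pytest.raises(SteadyStateError):
            invert_basal_currents(
                InitialConditionSpec(CHANNEL_DENSITY, 1.0, ctx.i_max * 1.01),
                gating, conv, rates,
            )

    def test_recovered_gbg_monotone_in_basal(self, gating, conv, rates):
        """At fixed I_total, more basal current means more free Gbg (less Ga)."""
        gbgs, gas = [], []
        for i_basal in (8.0, 11.0, 14.0):
            inv = invert_basal_currents(
                InitialConditionSpec(CHANNEL_DENSITY, i_basal, 17.2),
                gating, conv, rates,
            )
            gbgs.append(inv.gbg_total)
            gas.append(inv.ga_total)
        assert gbgs[0] == pytest.approx(gbgs[-1], rel=1e-6)  # set by I_total alone
        assert gas[0] > gas[1] > gas[2]

    def test_capacity_monotone_in_gbg(self, gating, conv, ctx):
        pools = np.linspace(0.1, 6.0, 12)
        caps = [activation_capacity_current(b, gating, conv, ctx) for b in pools]
        assert np.all(np.diff(caps) > 0)


@pytest.fixture(scope="module")
def calibration():
    return calibrate_gating()


class TestCalibration:
    def test_printed_currents_reproduced(self, calibration):
        """Joint (p1..p3, kappa) fit matches both cells' printed currents."""
        assert np.max(np.abs(calibration.residuals)) < 0.01

    def test_p_vector_monotone(self, calibration):
        p = calibration.p_vector
        assert all(p[i] <= p[i + 1] for i in range(4))
        assert p[4] == pytest.approx(0.105)

    def test_single_target_fits_exactly(self, rates):
        cal = calibrate_gating(targets=LEGEND_TARGETS[:1],
                               structural_models=["4KFM"], rates=rates)
        assert np.max(np.abs(cal.residuals)) < 1e-6

    def test_kappa_smooth_under_target_perturbation(self):
        """+5% on the printed currents shifts kappa smoothly, no jumps."""
        from dataclasses import replace

        kappas = []
        for eps in (1.0, 1.025, 1.05):
            targets = [replace(t, I_basal=t.I_basal * eps, I_total=t.I_total * eps)
                       for t in LEGEND_TARGETS]
            kappas.append(calibrate_gating(targets=targets).kappa_area)
        steps = np.diff(np.log(kappas))
        assert np.all(np.isfinite(steps))
        assert abs(steps[1] - steps[0]) < 0.5 * max(abs(steps[0]), 1e-6) + 0.05

    def test_legend_orderings_reported(self):
        """Both published orderings of each pair are exposed, flagged not resolved."""
        tgt = LEGEND_TARGETS[0]
        orderings = tgt.orderings("4KFM")
        assert orderings["as_printed"] == (3.23, 0.45)
        assert orderings["excess_gbg"] == (3.23, 0.45)  # larger value first
        tgt_hd = LEGEND_TARGETS[1]
        assert tgt_hd.orderings("BS")["as_printed"] == (3.65, 0.39)
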