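"""Reaction-network construction, mass action, conservation, thermodynamics."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from girkcascade import (
    ParameterError,
    RateConstants,
    UnitConversion,
    build_tandem_network,
    build_wt_network,
    detailed_balance_audit,
    mass_action_rhs,
)
from girkcascade.network import Reaction, ReactionNetwork, tandem_gbg_total


class TestWildTypeConstruction:
    def test_reaction_and_species_counts(self, wt_network):
        assert len(wt_network.reactions) == 10
        assert wt_network.n_species == 11
        assert sum(not r.reversible for r in wt_network.reactions) == 1

    def test_hydrolysis_is_the_irreversible_step(self, wt_network):
        (irr,) = [r for r in wt_network.reactions if not r.reversible]
        assert irr.name == "9"
        assert irr.reactants == {"Ga_GTP": 1} and irr.products == {"Ga_GDP": 1}

    def test_zero_hydrolysis_rejected(self):
        with pytest.raises(ParameterError):
            RateConstants(k9f=0.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ParameterError):
            RateConstants(k2f=-1.0)

    def test_heterotrimer_equilibrium_constant(self, rates):
        # reaction 10 dissociation constant k10b/k10f ~ 1.86 nM
        kd = rates.k10b / rates.k10f
        assert kd == pytest.approx(1.857e-9, rel=1e-3)

    def test_bimolecular_rates_scaled_by_kappa(self, rates):
        conv = UnitConversion(kappa=2.0e-6)
        net = build_wt_network(rates, conv)
        r2 = next(r for r in net.reactions if r.name == "2")
        assert r2.kf == pytest.approx(rates.k2f * conv.kappa)
        # agonist binding stays in molar units (concentration applied at runtime)
        r1 = next(r for r in net.reactions if r.name == "1")
        assert r1.kf == rates.k1f and r1.agonist_order == 1

    def test_export_lists_every_reaction(self, wt_network):
        text = wt_network.to_text()
        assert text.count("<->") == 9 and text.count(" -> ") == 1


class TestMassActionRhs:
    def test_zero_state_zero_derivative(self, full_network):
        y = np.zeros(full_network.n_species)
        assert np.all(mass_action_rhs(full_network, y, 1e-5) == 0.0)

    def test_dimension_mismatch_raises(self, full_network):
        with pytest.raises(ParameterError):
            mass_action_rhs(full_network, np.zeros(3), 0.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1), st.floats(0.0, 1e-4))
    def test_conservation_groups_closed(self, full_network, seed, agonist):
        """Every conservation group's derivative sums to zero at any state."""
        y = np.random.default_rng(seed).uniform(0.0, 5.0, full_network.n_species)
        dy = mass_action_rhs(full_network, y, agonist)
        for name, total_rate in full_network.conservation_totals(dy).items():
            assert abs(total_rate) < 1e-9 * max(np.abs(dy).max(), 1.0), name

    def test_single_reaction_zero_flux_at_equilibrium(self):
        rxn = Reaction("bind", {"A1": 1, "B1": 1}, {"C1": 1}, kf=3.0, kb=0.5)
        net = ReactionNetwork("pair", ["A1", "B1", "C1"], [rxn], {})
        a, b = 0.7, 1.3
        c = (rxn.kf / rxn.kb) * a * b   # kf*a*b == kb*c
        dy = net.rhs(np.array([a, b, c]))
        assert np.allclose(dy, 0.0, atol=1e-12)


class TestDetailedBalance:
    def test_wild_type_cycle_residual(self, wt_network, rates):
        reports = detailed_balance_audit(wt_network)
        assert len(reports) == 1
        expected = (rates.k1f / rates.k1b) * (rates.k4f / rates.k4b) \
            / ((rates.k2f / rates.k2b) * (rates.k3f / rates.k3b))
        res = reports[0].residual
        res = res if res >= 1 else 1.0 / res
        assert res == pytest.approx(max(expected, 1 / expected), rel=1e-9)
        assert 0.9 <= res <= 1.2

    def test_forced_closure_gives_unit_residual(self, rates, conv):
        expected = (rates.k1f / rates.k1b) * (rates.k4f / rates.k4b) \
            / ((rates.k2f / rates.k2b) * (rates.k3f / rates.k3b))
        closed = replace(rates, k4b=rates.k4b * expected)
        (report,) = detailed_balance_audit(build_wt_network(closed, conv))
        assert report.residual == pytest.approx(1.0, abs=1e-9)

    def test_hydrolysis_never_audited(self, full_network):
        for report in detailed_balance_audit(full_network):
            assert "9" not in report.reactions

    def test_channel_ladder_adds_no_cycle(self, wt_network, full_network):
        assert len(detailed_balance_audit(full_network)) == \
            len(detailed_balance_audit(wt_network))


class TestTandemNetwork:
    def test_unknown_scenario_rejected(self, rates, conv):
        with pytest.raises(ParameterError):
            build_tandem_network(rates, conv, 4)

    def test_fused_ga_never_dissociates(self, rates, conv):
        """No reaction moves Ga off the receptor in the tandem network."""
        net = build_tandem_network(rates, conv, 1)
        tandem_species = set(net.conserved["tandem"])
        for rxn in net.reactions:
            in_t = sum(c for s, c in rxn.reactants.items() if s in tandem_species)
            out_t = sum(c for s, c in rxn.products.items() if s in tandem_species)
            assert in_t == out_t, rxn.name

    def test_gbg_pool_per_scenario(self):
        assert tandem_gbg_total(1, 3.5, 2.0) == 3.5
        assert tandem_gbg_total(2, 3.5, 2.0) == 5.5
        assert tandem_gbg_total(3, 3.5, 2.0) == 3.5

    def test_scenario3_kd_ten_fold_with_same_on_rate(self, rates, conv):
        net1 = build_tandem_network(rates, conv, 1)
        net3 = build_tandem_network(rates, conv, 3)
        r1 = next(r for r in net1.reactions if r.name == "t10")
        r3 = next(r for r in net3.reactions if r.name == "t10")
        assert r3.kf == r1.kf
        kd1, kd3 = r1.kb / r1.kf, r3.kb / r3.kf
        assert kd3 / kd1 == pytest.approx(10.0)

    def test_in_situ_hydrolysis_is_irreversible(self, rates, conv):
        net = build_tandem_network(rates, conv, 2)
        (irr,) = [r for r in net.reactions if not r.reversible]
        assert irr.reactants == {"TA_GTP": 1} and irr.products == {"TA_GDP": 1}
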