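"""Channel gating: binding ladders, open probability, currents, occupancy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from girkcascade import (
    CellContext,
    ChannelState,
    GatingParams,
    ParameterError,
    binding_rates,
    current_from_state,
    equilibrium_occupancy,
    open_probability,
)
from girkcascade.gating import occupancy_relaxation


class TestBindingRates:
    @pytest.mark.parametrize(
        "n, model, kon, koff",
        [
            (0, "4KFM", 4 * 1.01e6, 1 * 0.14),
            (3, "BS", 1 * 0.23e6, 4 * 0.037),
            (1, "4KFM", 3 * 1.01e6, 2 * 0.14),
            (2, "BS", 2 * 0.23e6, 3 * 0.037),
        ],
    )
    def test_statistical_factors(self, n, model, kon, koff):
        got = binding_rates(n, GatingParams.graded(model))
        assert got == pytest.approx((kon, koff))

    def test_occupancy_step_out_of_range(self, gating):
        with pytest.raises(ParameterError):
            binding_rates(4, gating)

    @pytest.mark.parametrize("model", ["BS", "4KFM"])
    def test_per_site_kd_in_published_range(self, model):
        kd = GatingParams.graded(model).site_kd
        assert 100e-9 <= kd <= 200e-9

    def test_cooperative_kd_ladder(self):
        params = GatingParams.cooperative(KD1=60e-6, mu=0.3)
        assert np.allclose(params.stepwise_kd(),
                           [60e-6, 18e-6, 5.4e-6, 1.62e-6])
        # fixed on-rate convention: koff carries the whole ladder
        for n in range(4):
            kon, koff = binding_rates(n, params)
            assert kon == params.kon_unit
            assert koff / kon == pytest.approx(params.stepwise_kd()[n])


class TestOpenProbability:
    def test_fully_occupied_graded_reaches_po_max(self, gating):
        state = ChannelState((0, 0, 0, 0, 1.0))
        assert open_probability(state, gating) == pytest.approx(0.105)

    def test_empty_channels_closed(self, gating):
        state = ChannelState((1.0, 0, 0, 0, 0))
        assert open_probability(state, gating) == 0.0
        assert open_probability(state, GatingParams.cooperative()) == 0.0

    def test_cooperative_is_linear_in_c4(self):
        coop = GatingParams.cooperative()
        half = ChannelState((0.5, 0, 0, 0, 0.5))
        assert open_probability(half, coop) == pytest.approx(0.0525)

    def test_zero_total_raises(self, gating):
        with pytest.raises(ParameterError):
            open_probability(ChannelState((0, 0, 0, 0, 0)), gating)

    def test_graded_dominates_cooperative_at_any_state(self, rng):
        """With identical ladders and p4 = Po_max, graded Po >= cooperative."""
        graded = GatingParams.graded()
        coop = GatingParams.cooperative(po_max=graded.po_max)
        for _ in range(20):
            occ = rng.uniform(0, 1, 5)
            state = ChannelState(tuple(occ))
            assert open_probability(state, graded) >= \
                open_probability(state, coop) - 1e-15

    def test_nonmonotone_po_vector_rejected(self):
        with pytest.raises(ParameterError):
            GatingParams.graded(po_vector=(0, 0.05, 0.02, 0.06, 0.105))


class TestCurrent:
    def test_ruler_round_trip(self, gating):
        """Density from a 1 uA Gbg-saturated current closes the current law."""
        ctx = CellContext(channel_density=0.79)  # density for I_bg = 1 uA
        state = ChannelState((0, 0, 0, 0, 1.0))
        assert current_from_state(state, ctx, gating) == pytest.approx(1.0, rel=1e-12)

    def test_zero_po_zero_current(self, ctx, gating):
        assert current_from_state(ChannelState((1, 0, 0, 0, 0)), ctx, gating) == 0.0

    def test_current_linear_in_channel_number(self, gating):
        state = ChannelState((0.2, 0.2, 0.2, 0.2, 0.2))
        one = current_from_state(state, CellContext(channel_density=10.0), gating)
        two = current_from_state(state, CellContext(channel_density=20.0), gating)
        assert two == pytest.approx(2 * one, rel=1e-12)


class TestEquilibriumOccupancy:
    def test_zero_gbg_all_empty(self, gating):
        f = equilibrium_occupancy(0.0, gating)
        assert f[0] == 1.0 and np.all(f[1:] == 0.0)

    def test_saturation_fills_all_sites(self, gating):
        f = equilibrium_occupancy(1.0, gating)  # 1 M >> KD
        assert f[4] > 0.999

    def test_negative_input_rejected(self, gating):
        with pytest.raises(ParameterError):
            equilibrium_occupancy(-1.0, gating)

    @pytest.mark.parametrize("conc", [5e-8, 1.39e-7, 1e-6])
    def test_binomial_with_statistical_factors_only(self, gating, conc):
        """Equal per-site KD makes the occupancy binomial in site probability."""
        theta = conc / (conc + gating.site_kd)
        from math import comb
        expected = [comb(4, n) * theta**n * (1 - theta)**(4 - n) for n in range(5)]
        assert np.allclose(equilibrium_occupancy(conc, gating), expected, atol=1e-12)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.floats(1e-9, 1e-5))
    def test_occupancy_normalised(self, gating, conc):
        assert equilibrium_occupancy(conc, gating).sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("model_kind", ["graded", "cooperative"])
    def test_po_monotone_in_free_gbg(self, model_kind):
        params = (GatingParams.graded() if model_kind == "graded"
                  else GatingParams.cooperative())
        concs = np.geomspace(1e-9, 1e-3, 40)
        po = [open_probability(ChannelState(tuple(equilibrium_occupancy(c, params))),
                               params) for c in concs]
        assert np.all(np.diff(po) >= -1e-15)

    def test_kinetic_relaxation_matches_algebraic_equilibrium(self, gating, rng):
        """Long-time binding ODE limit agrees with the closed-form ladder."""
        for conc in rng.uniform(2e-8, 8e-7, 5):
            alg = equilibrium_occupancy(conc, gating)
            kin = occupancy_relaxation(conc, gating)
            assert np.allclose(kin, alg, atol=1e-6)
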