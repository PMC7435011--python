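"""GIRK1/2 gating: from Gbg occupancy to open probability and current.

Two gating models are implemented.  In the graded contribution model every
Gbg-occupied state of the tetrameric channel contributes to opening, with a
non-decreasing ladder of open probabilities p0..p4 (p4 = Po_max = 0.105 at
full occupancy).  In the cooperative model Gbg binds with progressively
higher affinity (stepwise KD reduced by the cooperativity factor mu at each
site) and only the fully occupied channel can open.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .params import CellContext, GatingModel, GatingParams, ParameterError

__all__ = [
    "ChannelState",
    "binding_rates",
    "open_probability",
    "current_from_state",
    "equilibrium_occupancy",
    "occupancy_relaxation",
]


@dataclass(frozen=True)
class ChannelState:
    """Counts of channels carrying 0..4 bound Gbg molecules."""

    occupancy: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        occ = tuple(float(c) for c in self.occupancy)
        if len(occ) != 5:
            raise ParameterError("occupancy must list the five states C0..C4")
        if any(c < 0 for c in occ):
            raise ParameterError("channel state counts must be non-negative")
        object.__setattr__(self, "occupancy", occ)

    @property
    def total(self) -> float:
        return float(sum(self.occupancy))

    def fractions(self) -> np.ndarray:
        if self.total == 0:
            raise ParameterError("channel state has zero total count")
        return np.asarray(self.occupancy) / self.total


def binding_rates(n: int, params: GatingParams) -> tuple[float, float]:
    """Association/dissociation rates for the step C_n + Gbg <-> C_{n+1}.

    Returns molar-unit rates (kon in M^-1 s^-1 applying to state ``n``,
    koff in s^-1 applying to state ``n+1``).  Graded model: statistical
    factors (4-n) and (n+1) on a common per-site pair.  Cooperative model:
    fixed on-rate, off-rate derived from the stepwise KD ladder.
    """
    if n not in (0, 1, 2, 3):
        raise ParameterError(f"occupancy step must be 0..3, got {n!r}")
    if params.model_kind is GatingModel.COOPERATIVE:
        kd = params.stepwise_kd()[n]
        return params.kon_unit, params.kon_unit * kd
    return (4 - n) * params.kon_unit, (n + 1) * params.koff_unit


def open_probability(state: ChannelState, params: GatingParams) -> float:
    """Population-average open probability of a channel ensemble.

    Graded: sum of occupancy fractions weighted by p0..p4.  Cooperative:
    only fully occupied channels open, at Po_max.
    """
    f = state.fractions()
    if params.model_kind is GatingModel.COOPERATIVE:
        return float(f[4] * params.po_max)
    return float(f @ np.asarray(params.po_vector))


def current_from_state(state: ChannelState, ctx: CellContext,
                       params: GatingParams) -> float:
    """Macroscopic GIRK current (uA): I = i_single * Po * N.

    ``N`` is the functional channel count (density times surface area);
    the inward current magnitude is reported positive.
    """
    return ctx.i_single * open_probability(state, params) * ctx.n_channels


def equilibrium_occupancy(free_gbg: float, params: GatingParams,
                          kd_scale: float = 1.0) -> np.ndarray:
    """Equilibrium occupancy fractions f0..f4 at a fixed free Gbg level.

    ``free_gbg`` is expressed in the same units as the stepwise KDs after
    division by ``kd_scale`` — pass the count-to-molar conversion ``kappa``
    as ``kd_scale`` to work in molecules/channel, or leave 1.0 for molar.
    The fractions follow the detailed-balance ladder of the binding scheme
    and sum to one; with statistical factors only (graded model) they are
    binomial in the per-site occupancy probability.
    """
    if free_gbg < 0:
        raise ParameterError("free Gbg must be non-negative")
    b = free_gbg * kd_scale
    kds = params.stepwise_kd()
    w = np.ones(5)
    for n in range(4):
        w[n + 1] = w[n] * (b / kds[n])
    return w / w.sum()


def occupancy_relaxation(
    free_gbg: float,
    params: GatingParams,
    kd_scale: float = 1.0,
    t_end: float = 5e4,
    rtol: float = 1e-10,
) -> np.ndarray:
    """Long-time limit of the kinetic binding ladder at clamped free Gbg.

    Independent kinetic route to :func:`equilibrium_occupancy`, used as a
    cross-check: integrates dC/dt for the four sequential binding steps
    until relaxation and returns the final fractions.
    """
    b = free_gbg * kd_scale
    kon = np.array([binding_rates(n, params)[0] for n in range(4)])
    koff = np.array([binding_rates(n, params)[1] for n in range(4)])

    def rhs(_t, c):
        up = kon * b * c[:4]
        down = koff * c[1:]
        dc = np.zeros(5)
        dc[:4] -= up
        dc[1:] += up
        dc[1:] -= down
        dc[:4] += down
        return dc

    c0 = np.array([1.0, 0, 0, 0, 0])
    sol = solve_ivp(rhs, (0.0, t_end), c0, method="LSODA", rtol=rtol, atol=1e-14)
    f = sol.y[:, -1]
    return f / f.sum()
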