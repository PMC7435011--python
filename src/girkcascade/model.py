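"""Model/Results interface for fitting the cascade to one cell's recordings.

:class:`CascadeModel` bundles the kinetic network, gating model and cell
context for a single oocyte; :meth:`CascadeModel.fit` estimates the
quantities the recordings constrain — the per-channel Gbg and Galpha
availabilities from the measured I_basal/I_total pair and, when a current
trace is attached, the activation time constant — and returns a
:class:`CascadeResults` carrying estimates, standard errors and a summary
table.  Forward simulation hangs off both objects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import (
    DEFAULT_KAPPA_AREA,
    CellContext,
    GatingParams,
    ParameterError,
    RateConstants,
    UnitConversion,
)
from .network import ReactionNetwork, attach_channel, build_wt_network
from .steady_state import (
    CascadeState,
    InitialConditionSpec,
    activation_capacity_current,
    basal_current,
    invert_basal_currents,
    solve_preagonist,
)
from .time_course import (
    CurrentTrace,
    FitError,
    StimulusProtocol,
    fit_monoexponential,
    simulate_activation,
)

__all__ = ["CascadeModel", "CascadeResults"]


class CascadeModel:
    """Kinetic cascade model for one cell.

    Parameters
    ----------
    channel_density : channels/um^2 (from the current/fluorescence ruler).
    I_basal, I_total : measured currents in uA; required for :meth:`fit`.
    receptor_density : receptors/um^2 (from the RNA-dose calibration).
    trace : optional recorded/simulated current trace for tau extraction.
    gating, rates : kinetic parameter sets (calibrated defaults).
    kappa_area : count-to-molar bridge, M per (molecule/um^2).
    """

    def __init__(
        self,
        channel_density: float,
        I_basal: float | None = None,
        I_total: float | None = None,
        receptor_density: float = 0.0,
        trace: CurrentTrace | None = None,
        gating: GatingParams | None = None,
        rates: RateConstants | None = None,
        kappa_area: float = DEFAULT_KAPPA_AREA,
    ) -> None:
        self.gating = gating or GatingParams.graded()
        self.rates = rates or RateConstants()
        self.conversion = UnitConversion.from_channel_density(channel_density, kappa_area)
        self.ctx = CellContext(channel_density=channel_density)
        self.receptor_density = receptor_density
        self.I_basal = I_basal
        self.I_total = I_total
        self.trace = trace
        self.network: ReactionNetwork = attach_channel(
            build_wt_network(self.rates, self.conversion), self.gating, self.conversion
        )

    @classmethod
    def from_trace(
        cls,
        trace: CurrentTrace,
        channel_density: float,
        plateau_window_s: float = 5.0,
        **kwargs,
    ) -> "CascadeModel":
        """Build a model from a trace, measuring I_basal/I_total from it."""
        t, i = trace.time, trace.current
        onset = trace.onset
        i_basal = float(i[t < onset].mean()) if (t < onset).any() else float(i[0])
        i_total = float(i[t >= t[-1] - plateau_window_s].mean())
        return cls(channel_density, I_basal=min(i_basal, i_total),
                   I_total=i_total, trace=trace, **kwargs)

    # -- forward machinery --------------------------------------------------
    def initial_state(self, gbg_total: float, ga_total: float) -> CascadeState:
        return solve_preagonist(
            self.network,
            {
                "receptor": self.receptor_density / self.ctx.channel_density,
                "Galpha": ga_total,
                "Gbg": gbg_total,
            },
        )

    def simulate(
        self,
        gbg_total: float,
        ga_total: float,
        protocol: StimulusProtocol = StimulusProtocol(),
        **kwargs,
    ) -> CurrentTrace:
        init = self.initial_state(gbg_total, ga_total)
        return simulate_activation(self.network, init, self.gating, self.ctx,
                                   protocol, **kwargs)

    # -- estimation ---------------------------------------------------------
    def fit(self, current_rel_error: float = 0.02) -> "CascadeResults":
        """Estimate per-channel G-protein totals (and tau_act if a trace is set).

        ``current_rel_error`` is the assumed relative measurement error of
        I_basal/I_total; it is propagated through the numerically evaluated
        inverse Jacobian to standard errors on the totals.
        """
        if self.I_basal is None or self.I_total is None:
            raise ParameterError("fit requires measured I_basal and I_total")
        spec = InitialConditionSpec(self.ctx.channel_density, self.I_basal,
                                    self.I_total, self.receptor_density)
        inv = invert_basal_currents(spec, self.gating, self.conversion, self.rates)
        gbg_se, ga_se = self._totals_se(inv.gbg_total, inv.ga_total, current_rel_error)

        tau = tau_se = None
        fit_diag = None
        if self.trace is not None:
            try:
                fr = fit_monoexponential(self.trace)
                tau, fit_diag = fr.tau_act, fr
                # crude scale-free error from the residual-to-amplitude ratio
                tau_se = fr.tau_act * fr.residual_norm / max(fr.i_evoked, 1e-12)
            except FitError:
                pass
        return CascadeResults(
            model=self,
            gbg_total=inv.gbg_total,
            ga_total=inv.ga_total,
            gbg_se=gbg_se,
            ga_se=ga_se,
            tau_act=tau,
            tau_se=tau_se,
            i_basal_model=inv.I_basal_model,
            i_total_model=inv.I_total_model,
            near_infeasible=inv.near_infeasible,
            fit_diagnostics=fit_diag,
        )

    def _totals_se(self, gbg: float, ga: float, rel_err: float) -> tuple[float, float]:
        """Propagate current measurement error through the forward Jacobian."""
        sigma = np.array([rel_err * max(self.I_basal, 1e-9),
                          rel_err * max(self.I_total, 1e-9)])

        def forward(x):
            g, a = x
            ib = basal_current(g, a, self.gating, self.conversion, self.ctx,
                               self.rates,
                               self.receptor_density / self.ctx.channel_density)
            it = activation_capacity_current(g, self.gating, self.conversion, self.ctx)
            return np.array([ib, it])

        x0 = np.array([gbg, ga])
        J = np.empty((2, 2))
        for j in range(2):
            h = max(1e-6, 1e-4 * abs(x0[j]))
            xp, xm = x0.copy(), x0.copy()
            xp[j] += h
            xm[j] = max(xm[j] - h, 0.0)
            J[:, j] = (forward(xp) - forward(xm)) / (xp[j] - xm[j])
        try:
            Jinv = np.linalg.inv(J)
        except np.linalg.LinAlgError:
            return float("nan"), float("nan")
        cov = Jinv @ np.diag(sigma**2) @ Jinv.T
        return float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))


@dataclass
class CascadeResults:
    """Estimates and diagnostics from :meth:`CascadeModel.fit`."""

    model: CascadeModel
    gbg_total: float
    ga_total: float
    gbg_se: float
    ga_se: float
    i_basal_model: float
    i_total_model: float
    tau_act: float | None = None
    tau_se: float | None = None
    near_infeasible: bool = False
    fit_diagnostics: object = None

    def params(self) -> pd.Series:
        out = {"gbg_total": self.gbg_total, "ga_total": self.ga_total}
        if self.tau_act is not None:
            out["tau_act_s"] = self.tau_act
        return pd.Series(out)

    def simulate(self, protocol: StimulusProtocol = StimulusProtocol(), **kw) -> CurrentTrace:
        """Forward-simulate the fitted cell."""
        return self.model.simulate(self.gbg_total, self.ga_total, protocol, **kw)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Cascade inversion results",
            "=" * 58,
            f"channel density        {m.ctx.channel_density:10.3f}  channels/um^2",
            f"receptor density       {m.receptor_density:10.3f}  receptors/um^2",
            f"measured I_basal       {m.I_basal:10.3f}  uA",
            f"measured I_total       {m.I_total:10.3f}  uA",
            "-" * 58,
            f"Gbg / channel          {self.gbg_total:10.4f}  +/- {self.gbg_se:.4f}",
            f"Galpha / channel       {self.ga_total:10.4f}  +/- {self.ga_se:.4f}",
        ]
        if self.tau_act is not None:
            se = f"+/- {self.tau_se:.4f}" if self.tau_se is not None else ""
            lines.append(f"tau_act                {self.tau_act:10.4f}  s {se}")
        lines += [
            "-" * 58,
            f"model I_basal          {self.i_basal_model:10.3f}  uA",
            f"model I_total          {self.i_total_model:10.3f}  uA",
            f"gating model           {m.gating.model_kind.value:>10s}"
            f"  ({m.gating.structural_model.value})",
        ]
        if self.near_infeasible:
            lines.append("WARNING: I_basal within 1% of I_total (near-infeasible cell)")
        return "\n".join(lines)
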