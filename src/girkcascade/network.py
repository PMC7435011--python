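"""Mass-action reaction networks for the G-protein cycle.

Two cascade variants are provided:

* the wild-type cycle, in which receptor (R), heterotrimeric G protein
  (G_GDP = Ga_GDP.Gbg) and channel all diffuse freely and interact by
  collision (a complete ternary-complex formulation of the
  receptor-agonist-G-protein interaction), and
* the tandem variant, in which Ga is covalently fused to the receptor,
  emulating a preformed receptor-G-protein complex.

State variables are dimensionless molecule counts ("molecules per
channel"); bimolecular rate constants are pre-multiplied by the
:class:`~girkcascade.params.UnitConversion` factor ``kappa`` at build time.
Agonist, GDP and GTP are external species held at fixed concentration (the
free-ligand approximation): GDP/GTP concentrations are absorbed into the
rates, while the agonist concentration is supplied at evaluation time so
that stimulus protocols can vary it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping

import numpy as np
import sympy

from .params import GatingParams, ParameterError, RateConstants, UnitConversion

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "CycleReport",
    "build_wt_network",
    "build_tandem_network",
    "attach_channel",
    "mass_action_rhs",
    "detailed_balance_audit",
    "tandem_gbg_total",
    "WT_SPECIES",
    "TANDEM_SPECIES",
    "CHANNEL_SPECIES",
]

# Wild-type G-protein-cycle species.
WT_SPECIES = (
    "R",          # free receptor
    "RA",         # agonist-bound receptor
    "RG_GDP",     # receptor . heterotrimer (no agonist)
    "RAG_GDP",    # agonist . receptor . heterotrimer
    "RAG0",       # nucleotide-free ternary complex (GaGbg, empty pocket)
    "RAG_GTP",    # GTP-loaded ternary complex
    "RAGa_GTP",   # receptor-bound Ga_GTP after Gbg release
    "Ga_GTP",     # free activated Ga
    "Ga_GDP",     # free deactivated Ga
    "Gbg",        # free Gbg
    "G_GDP",      # free heterotrimer
)

# Tandem (receptor-fused Ga) species.  The fused Ga never dissociates from
# the receptor; Gbg assembles on and releases from the fusion protein.
TANDEM_SPECIES = (
    "T_GDP",      # fused R-Ga_GDP, no Gbg, no agonist
    "TG_GDP",     # fused heterotrimer R-Ga_GDP.Gbg
    "TA_GDP",     # agonist-bound fused R-Ga_GDP
    "TAG_GDP",    # agonist-bound fused heterotrimer
    "TAG0",       # nucleotide-free fused ternary complex
    "TAG_GTP",    # GTP-loaded fused ternary complex
    "TA_GTP",     # agonist-bound fused R-Ga_GTP after Gbg release
    "Gbg",
)

CHANNEL_SPECIES = ("C0", "C1", "C2", "C3", "C4")


@dataclass(frozen=True)
class Reaction:
    """One (possibly reversible) mass-action reaction in count units.

    ``kf`` applies to the reactant side and is additionally multiplied by
    ``agonist**agonist_order`` at evaluation time (agonist in molar).
    ``kb`` is ``None`` for an irreversible reaction.
    """

    name: str
    reactants: Mapping[str, int]
    products: Mapping[str, int]
    kf: float
    kb: float | None = None
    agonist_order: int = 0
    #: external fixed-concentration species consumed on the forward side
    #: (their concentration is already absorbed into ``kf``), e.g. GDP/GTP.
    externals: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kf < 0 or (self.kb is not None and self.kb < 0):
            raise ParameterError(f"reaction {self.name!r} has a negative rate constant")
        if self.kb is not None and (self.kf == 0 or self.kb == 0):
            raise ParameterError(
                f"reversible reaction {self.name!r} requires both rates > 0"
            )

    @property
    def reversible(self) -> bool:
        return self.kb is not None

    def equilibrium_constant(self) -> float:
        """kf/kb in count units (nucleotide concentrations absorbed)."""
        if self.kb is None:
            raise ParameterError(f"reaction {self.name!r} is irreversible")
        return self.kf / self.kb


@dataclass(frozen=True)
class CycleReport:
    """Wegscheider condition for one independent cycle of reversible reactions.

    ``residual`` is the product of equilibrium constants around the cycle
    (each raised to its signed multiplicity); microscopic reversibility
    requires it to equal 1.
    """

    reactions: tuple[str, ...]
    coefficients: tuple[int, ...]
    residual: float


class ReactionNetwork:
    """Species list plus mass-action reactions, with conservation bookkeeping."""

    def __init__(
        self,
        name: str,
        species: Iterable[str],
        reactions: Iterable[Reaction],
        conserved: Mapping[str, Mapping[str, int]],
        scenario: int | None = None,
    ) -> None:
        self.name = name
        self.species = tuple(species)
        self.reactions = tuple(reactions)
        self.conserved = {k: dict(v) for k, v in conserved.items()}
        self.scenario = scenario
        self._index = {s: i for i, s in enumerate(self.species)}
        for rxn in self.reactions:
            for sp in (*rxn.reactants, *rxn.products):
                if sp not in self._index:
                    raise ParameterError(
                        f"reaction {rxn.name!r} references unknown species {sp!r}"
                    )

    # -- structural queries -------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    def species_index(self, name: str) -> int:
        return self._index[name]

    @cached_property
    def _matrices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        n_r, n_s = len(self.reactions), self.n_species
        react = np.zeros((n_r, n_s))
        prod = np.zeros((n_r, n_s))
        kf = np.zeros(n_r)
        kb = np.zeros(n_r)
        order = np.zeros(n_r)
        for j, rxn in enumerate(self.reactions):
            for sp, c in rxn.reactants.items():
                react[j, self._index[sp]] += c
            for sp, c in rxn.products.items():
                prod[j, self._index[sp]] += c
            kf[j] = rxn.kf
            kb[j] = 0.0 if rxn.kb is None else rxn.kb
            order[j] = rxn.agonist_order
        net = prod - react
        return react, prod, net, kf, kb, order

    @cached_property
    def conservation_matrix(self) -> np.ndarray:
        """Rows are conservation groups, columns species (moiety counts)."""
        mat = np.zeros((len(self.conserved), self.n_species))
        for i, comp in enumerate(self.conserved.values()):
            for sp, c in comp.items():
                mat[i, self._index[sp]] = c
        return mat

    def conservation_totals(self, y: np.ndarray) -> dict[str, float]:
        vals = self.conservation_matrix @ np.asarray(y, dtype=float)
        return dict(zip(self.conserved, vals))

    # -- dynamics -----------------------------------------------------------
    def rhs(self, y: np.ndarray, agonist: float = 0.0) -> np.ndarray:
        """Time derivatives of all species by mass action (counts per second)."""
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n_species,):
            raise ParameterError(
                f"state vector has shape {y.shape}, expected ({self.n_species},)"
            )
        if agonist < 0:
            raise ParameterError("agonist concentration must be non-negative")
        react, prod, net, kf, kb, order = self._matrices
        yc = np.clip(y, 0.0, None)  # guard tiny integrator undershoots
        fwd = kf * np.where(order > 0, agonist**order, 1.0) * np.prod(yc**react, axis=1)
        back = kb * np.prod(yc**prod, axis=1)
        return net.T @ (fwd - back)

    # -- export -------------------------------------------------------------
    def to_text(self) -> str:
        """Human-readable reaction list, one reaction per line with rates."""
        lines = [f"# network: {self.name} ({len(self.reactions)} reactions, "
                 f"{self.n_species} species; rates in count units)"]
        for rxn in self.reactions:
            lhs = " + ".join(
                (f"{c} {s}" if c != 1 else s) for s, c in rxn.reactants.items()
            )
            rhs_ = " + ".join(
                (f"{c} {s}" if c != 1 else s) for s, c in rxn.products.items()
            )
            if rxn.agonist_order:
                lhs = f"{lhs} + {rxn.agonist_order} A" if lhs else "A"
            arrow = "<->" if rxn.reversible else "->"
            rate = f"kf={rxn.kf:.6g}"
            if rxn.reversible:
                rate += f", kb={rxn.kb:.6g}"
            lines.append(f"{rxn.name}: {lhs} {arrow} {rhs_}   [{rate}]")
        return "\n".join(lines) + "\n"


def mass_action_rhs(
    network: ReactionNetwork, state: np.ndarray, agonist: float = 0.0
) -> np.ndarray:
    """Functional alias for :meth:`ReactionNetwork.rhs`."""
    return network.rhs(state, agonist)


# ---------------------------------------------------------------------------
# network builders
# ---------------------------------------------------------------------------

def _wt_reactions(rates: RateConstants, kappa: float) -> list[Reaction]:
    return [
        Reaction("1", {"R": 1}, {"RA": 1}, rates.k1f, rates.k1b, agonist_order=1),
        Reaction("2", {"R": 1, "G_GDP": 1}, {"RG_GDP": 1}, rates.k2f * kappa, rates.k2b),
        Reaction("3", {"RG_GDP": 1}, {"RAG_GDP": 1}, rates.k3f, rates.k3b, agonist_order=1),
        Reaction("4", {"RA": 1, "G_GDP": 1}, {"RAG_GDP": 1}, rates.k4f * kappa, rates.k4b),
        # GDP/GTP exchange is split into two reversible steps through the
        # nucleotide-free ternary complex; nucleotide concentrations are
        # absorbed into the association rates (unlimited supply).
        Reaction("5", {"RAG0": 1}, {"RAG_GDP": 1}, rates.k5_on * rates.gdp,
                 rates.k5_off, externals={"GDP": 1}),
        Reaction("6", {"RAG0": 1}, {"RAG_GTP": 1}, rates.k6_on * rates.gtp,
                 rates.k6_off, externals={"GTP": 1}),
        Reaction("7", {"RAGa_GTP": 1, "Gbg": 1}, {"RAG_GTP": 1}, rates.k7_on * kappa, rates.k7_off),
        Reaction("8", {"RA": 1, "Ga_GTP": 1}, {"RAGa_GTP": 1}, rates.k8_on * kappa, rates.k8_off),
        Reaction("9", {"Ga_GTP": 1}, {"Ga_GDP": 1}, rates.k9f, None),
        Reaction("10", {"Ga_GDP": 1, "Gbg": 1}, {"G_GDP": 1}, rates.k10f * kappa, rates.k10b),
    ]


_WT_CONSERVED = {
    "receptor": {s: 1 for s in ("R", "RA", "RG_GDP", "RAG_GDP", "RAG0", "RAG_GTP", "RAGa_GTP")},
    "Galpha": {s: 1 for s in ("RG_GDP", "RAG_GDP", "RAG0", "RAG_GTP", "RAGa_GTP",
                              "Ga_GTP", "Ga_GDP", "G_GDP")},
    "Gbg": {s: 1 for s in ("RG_GDP", "RAG_GDP", "RAG0", "RAG_GTP", "Gbg", "G_GDP")},
}


def build_wt_network(rates: RateConstants, conversion: UnitConversion) -> ReactionNetwork:
    """Build the wild-type (collision-coupling) G-protein cycle network.

    Ten reactions over eleven species; GTP hydrolysis (reaction 9) is the
    single irreversible step and sits outside the reversible cycle, which
    preserves microscopic reversibility of the circular part of the scheme.
    """
    return ReactionNetwork(
        "wild-type G-protein cycle",
        WT_SPECIES,
        _wt_reactions(rates, conversion.kappa),
        _WT_CONSERVED,
    )


def _tandem_reactions(rates: RateConstants, kappa: float, scenario: int) -> list[Reaction]:
    # Scenario 3: the fused Ga has 10-fold lower Gbg affinity, implemented as
    # a 10-fold faster heterotrimer off-rate with unchanged on-rate.
    k10b = rates.k10b * (10.0 if scenario == 3 else 1.0)
    return [
        # Agonist binding.  The fused receptor is permanently G-protein
        # coupled, so both Gbg-bound and Gbg-free states use the coupled
        # (high-affinity) agonist constants.
        Reaction("t1", {"T_GDP": 1}, {"TA_GDP": 1}, rates.k3f, rates.k3b, agonist_order=1),
        Reaction("t3", {"TG_GDP": 1}, {"TAG_GDP": 1}, rates.k3f, rates.k3b, agonist_order=1),
        # Heterotrimer assembly on the fusion protein (reaction-10 analogue).
        # As in the wild-type scheme, where heterotrimer re-assembly happens
        # only on free Ga_GDP, re-assembly is restricted to the resting
        # (agonist-free) fusion protein; the agonist-bound Ga_GDP state has
        # no wild-type counterpart and is given no direct Gbg capture step.
        Reaction("t10", {"T_GDP": 1, "Gbg": 1}, {"TG_GDP": 1}, rates.k10f * kappa, k10b),
        # Nucleotide exchange on the agonist-bound fused ternary complex.
        Reaction("t5", {"TAG0": 1}, {"TAG_GDP": 1}, rates.k5_on * rates.gdp,
                 rates.k5_off, externals={"GDP": 1}),
        Reaction("t6", {"TAG0": 1}, {"TAG_GTP": 1}, rates.k6_on * rates.gtp,
                 rates.k6_off, externals={"GTP": 1}),
        # Gbg release from the GTP-loaded fused complex (reaction-7 analogue).
        Reaction("t7", {"TA_GTP": 1, "Gbg": 1}, {"TAG_GTP": 1}, rates.k7_on * kappa, rates.k7_off),
        # In-situ GTP hydrolysis on the fused Ga (reaction-9 analogue); the
        # fused Ga cannot leave the receptor, so there is no reaction-8 step.
        Reaction("t9", {"TA_GTP": 1}, {"TA_GDP": 1}, rates.k9f, None),
    ]


_TANDEM_CONSERVED = {
    "tandem": {s: 1 for s in ("T_GDP", "TG_GDP", "TA_GDP", "TAG_GDP", "TAG0",
                              "TAG_GTP", "TA_GTP")},
    "Gbg": {s: 1 for s in ("TG_GDP", "TAG_GDP", "TAG0", "TAG_GTP", "Gbg")},
}


def build_tandem_network(
    rates: RateConstants, conversion: UnitConversion, scenario: int
) -> ReactionNetwork:
    """Build the receptor-Ga fusion (preformed-complex) network.

    The tandem reaction set is a reconstruction from the wild-type scheme:
    fused-Ga analogues of nucleotide exchange, Gbg release and hydrolysis,
    plus heterotrimer assembly directly on the fusion protein.  Endogenous
    free Ga is absent (pertussis-toxin silenced), so the network carries no
    free Ga pools.

    Scenarios: 1 - wild-type Gbg affinity, Gbg pool unchanged by tandem
    expression; 2 - as 1, but the Gbg total grows 1:1 with the tandem
    amount (see :func:`tandem_gbg_total`); 3 - 10-fold lower tandem-Gbg
    affinity (off-rate scaled), pool unchanged.
    """
    if scenario not in (1, 2, 3):
        raise ParameterError(f"unknown tandem scenario {scenario!r}; expected 1, 2 or 3")
    return ReactionNetwork(
        f"M2R-Ga tandem (scenario {scenario})",
        TANDEM_SPECIES,
        _tandem_reactions(rates, conversion.kappa, scenario),
        _TANDEM_CONSERVED,
        scenario=scenario,
    )


def tandem_gbg_total(scenario: int, base_gbg: float, tandem_count: float) -> float:
    """Total Gbg (molecules/channel) available under a tandem scenario."""
    if scenario not in (1, 2, 3):
        raise ParameterError(f"unknown tandem scenario {scenario!r}; expected 1, 2 or 3")
    return base_gbg + (tandem_count if scenario == 2 else 0.0)


def attach_channel(
    network: ReactionNetwork, gating: GatingParams, conversion: UnitConversion
) -> ReactionNetwork:
    """Append the four sequential GIRK-Gbg binding reactions to a network.

    Channel occupancy states C0..C4 are counts normalised per channel
    (their conserved total is typically 1).  Rates follow the configured
    gating model; see :func:`girkcascade.gating.binding_rates`.
    """
    from .gating import binding_rates  # local import to avoid a cycle

    reactions = list(network.reactions)
    for n in range(4):
        kon, koff = binding_rates(n, gating)
        reactions.append(
            Reaction(
                f"ch{n}",
                {f"C{n}": 1, "Gbg": 1},
                {f"C{n+1}": 1},
                kon * conversion.kappa,
                koff,
            )
        )
    conserved = {k: dict(v) for k, v in network.conserved.items()}
    conserved["channel"] = {s: 1 for s in CHANNEL_SPECIES}
    gbg = conserved.setdefault("Gbg", {})
    for n, s in enumerate(CHANNEL_SPECIES):
        if n:
            gbg[s] = n
    return ReactionNetwork(
        network.name + " + channel",
        (*network.species, *CHANNEL_SPECIES),
        reactions,
        conserved,
        scenario=network.scenario,
    )


# ---------------------------------------------------------------------------
# thermodynamic audit
# ---------------------------------------------------------------------------

def detailed_balance_audit(network: ReactionNetwork) -> list[CycleReport]:
    """Audit every independent closed cycle of reversible reactions.

    Builds the net stoichiometry matrix of the reversible reactions
    (including the external agonist as a balance row), computes an integer
    basis of its right null space, and reports the product of equilibrium
    constants along each basis cycle.  Irreversible reactions (GTP
    hydrolysis) are excluded, mirroring the exclusion of hydrolysis from
    the thermodynamically closed part of the cycle.
    """
    rev = [rxn for rxn in network.reactions if rxn.reversible]
    if not rev:
        return []
    externals = sorted({e for rxn in rev for e in rxn.externals} | {"A"})
    rows = list(network.species) + externals
    idx = {s: i for i, s in enumerate(rows)}
    S = sympy.zeros(len(rows), len(rev))
    for j, rxn in enumerate(rev):
        for sp, c in rxn.reactants.items():
            S[idx[sp], j] -= c
        for sp, c in rxn.products.items():
            S[idx[sp], j] += c
        for sp, c in rxn.externals.items():
            S[idx[sp], j] -= c
        if rxn.agonist_order:
            S[idx["A"], j] -= rxn.agonist_order
    reports = []
    for vec in S.nullspace():
        denoms = [sympy.fraction(x)[1] for x in vec]
        scale = sympy.lcm(denoms) if denoms else 1
        coeffs = [int(x * scale) for x in vec]
        residual = 1.0
        names, used = [], []
        for rxn, c in zip(rev, coeffs):
            if c:
                residual *= rxn.equilibrium_constant() ** c
                names.append(rxn.name)
                used.append(c)
        reports.append(CycleReport(tuple(names), tuple(used), float(residual)))
    return reports
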