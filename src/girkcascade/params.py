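"""Parameter containers for the M2R - Gi/o - GIRK1/2 cascade model.

All kinetic constants are given in molar units (M^-1 s^-1 for association,
s^-1 for dissociation).  State variables of the model are dimensionless
counts, "molecules per channel"; the :class:`UnitConversion` bridge turns a
count into an effective molar concentration so that literature rate
constants can be applied unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from enum import Enum
from typing import Sequence

__all__ = [
    "RateConstants",
    "UnitConversion",
    "StructuralModel",
    "GatingModel",
    "GatingParams",
    "CellContext",
    "ParameterError",
]


class ParameterError(ValueError):
    """Raised when a kinetic or structural parameter is invalid."""


# Effective molar concentration of one molecule per um^2 of oocyte membrane,
# assuming the reactants are confined to a thin shell at the inner membrane
# face.  The default is the value obtained by the joint gating calibration
# (see girkcascade.steady_state.calibrate_gating); it corresponds to a shell
# of a few tens of nanometres, consistent with membrane-delimited signalling.
DEFAULT_KAPPA_AREA = 1.7759e-07  # M per (molecule/um^2)


@dataclass(frozen=True)
class RateConstants:
    """Rate constants of the G-protein cycle.

    Naming follows the reaction numbering of the cycle scheme:

    1.  R + A <-> RA                    (agonist binding, uncoupled receptor)
    2.  R + G_GDP <-> R.G_GDP           (heterotrimer binding, no agonist)
    3.  R.G_GDP + A <-> RA.G_GDP        (agonist binding, coupled receptor)
    4.  RA + G_GDP <-> RA.G_GDP         (heterotrimer binding, agonist bound)
    5.  RA.G_0 + GDP <-> RA.G_GDP       (GDP rebinding / release)
    6.  RA.G_0 + GTP <-> RA.G_GTP       (GTP binding / release)
    7.  RA.Ga_GTP + Gbg <-> RA.G_GTP    (Gbg re-association / release)
    8.  RA + Ga_GTP <-> RA.Ga_GTP       (Ga_GTP unbinding from receptor)
    9.  Ga_GTP -> Ga_GDP                (GTP hydrolysis, irreversible)
    10. Ga_GDP + Gbg <-> G_GDP          (heterotrimer re-assembly)

    Association constants (``*f``/``*_on``) are per-molar per-second;
    dissociation constants (``*b``/``*_off``) are per-second.  GDP and GTP
    are treated in the free-ligand approximation at fixed cytosolic
    concentrations ``gdp`` and ``gtp`` (molar).
    """

    k1f: float = 3.33e2
    k1b: float = 7e-3
    k2f: float = 5.51e6
    k2b: float = 1.6e-1
    k3f: float = 4.5e6
    k3b: float = 4.87e-1
    k4f: float = 3.68e8
    k4b: float = 5e-2
    k5_on: float = 1e6
    k5_off: float = 5.0
    k6_on: float = 1e6
    k6_off: float = 0.1
    k7_on: float = 1e6
    k7_off: float = 15.0
    k8_on: float = 1e7
    k8_off: float = 2.0
    k9f: float = 0.02
    k10f: float = 0.7e6
    k10b: float = 0.0013
    gdp: float = 10e-6
    gtp: float = 100e-6

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v is None or v < 0:
                raise ParameterError(f"rate constant {f.name!r} must be non-negative, got {v!r}")
        if self.k9f <= 0:
            raise ParameterError("GTP hydrolysis rate k9f must be strictly positive")

    def with_fast_hydrolysis(self, factor: float = 100.0) -> "RateConstants":
        """Return a copy with the hydrolysis rate multiplied by ``factor``.

        A 100-fold faster hydrolysis emulates the presence of RGS proteins
        (e.g. in cardiomyocytes); Xenopus oocytes lack RGS, hence the slow
        default of 0.02 s^-1.
        """
        return replace(self, k9f=self.k9f * factor)


@dataclass(frozen=True)
class UnitConversion:
    """Bridge between per-channel molecule counts and molar concentration.

    ``kappa`` is the effective molar concentration contributed by one
    molecule per channel.  Every bimolecular rate constant is multiplied by
    ``kappa`` when the network is expressed in count units, so that
    ``k_on * kappa`` has units of per-count per-second.
    """

    kappa: float

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ParameterError(f"kappa must be positive, got {self.kappa!r}")

    @classmethod
    def from_channel_density(
        cls, channel_density: float, kappa_area: float = DEFAULT_KAPPA_AREA
    ) -> "UnitConversion":
        """Build the conversion for a cell with ``channel_density`` channels/um^2.

        One molecule per channel at density ``rho`` corresponds to ``rho``
        molecules/um^2; ``kappa_area`` converts an areal density into an
        effective molar concentration.
        """
        if channel_density <= 0:
            raise ParameterError("channel density must be positive")
        return cls(kappa=kappa_area * channel_density)


class StructuralModel(str, Enum):
    """Structural source of the GIRK-Gbg binding parameters."""

    BS = "BS"      # docking model of the GIRK1-Gbg complex ("best scoring")
    KFM = "4KFM"   # crystal structure of GIRK2 bound to Gbg


class GatingModel(str, Enum):
    GRADED = "graded"          # each occupied state contributes to opening
    COOPERATIVE = "cooperative"  # only the fully occupied channel opens


# Per-site GIRK-Gbg rate constants by structural model (kon M^-1 s^-1, koff s^-1).
_STRUCTURAL_RATES = {
    StructuralModel.BS: (0.23e6, 0.037),
    StructuralModel.KFM: (1.01e6, 0.14),
}

# Open-probability ladder of the graded contribution model.  p0 and p4 are
# fixed (closed when empty, Po_max = 0.105 when fully occupied); the interior
# values are the defaults produced by the joint calibration against the
# printed per-channel G-protein availabilities (calibrate_gating).
DEFAULT_PO_VECTOR = (0.0, 0.0, 8.181e-03, 2.617e-02, 0.105)


@dataclass(frozen=True)
class GatingParams:
    """Parameters mapping Gbg occupancy of the four GIRK sites to opening.

    For the graded model the per-site rates carry statistical factors:
    association into occupancy ``n+1`` proceeds at ``(4-n)*kon_unit`` and
    dissociation out of it at ``(n+1)*koff_unit``.  For the cooperative
    model the stepwise macroscopic dissociation constants form a geometric
    ladder ``KD_{i+1} = mu * KD_i`` starting from ``KD1``; the on-rate is
    held fixed at ``kon_unit`` for every site and the off-rates are derived
    from the ladder (only equilibrium ratios are constrained).
    """

    model_kind: GatingModel = GatingModel.GRADED
    structural_model: StructuralModel = StructuralModel.KFM
    kon_unit: float = _STRUCTURAL_RATES[StructuralModel.KFM][0]
    koff_unit: float = _STRUCTURAL_RATES[StructuralModel.KFM][1]
    po_vector: Sequence[float] = DEFAULT_PO_VECTOR
    KD1: float = 60e-6
    mu: float = 0.3

    @classmethod
    def graded(
        cls,
        structural_model: StructuralModel | str = StructuralModel.KFM,
        po_vector: Sequence[float] = DEFAULT_PO_VECTOR,
    ) -> "GatingParams":
        structural_model = StructuralModel(structural_model)
        kon, koff = _STRUCTURAL_RATES[structural_model]
        return cls(
            model_kind=GatingModel.GRADED,
            structural_model=structural_model,
            kon_unit=kon,
            koff_unit=koff,
            po_vector=tuple(po_vector),
        )

    @classmethod
    def cooperative(
        cls, KD1: float = 60e-6, mu: float = 0.3, kon_unit: float = 1e6,
        po_max: float = 0.105,
    ) -> "GatingParams":
        return cls(
            model_kind=GatingModel.COOPERATIVE,
            kon_unit=kon_unit,
            koff_unit=KD1 * kon_unit,
            po_vector=(0.0, 0.0, 0.0, 0.0, po_max),
            KD1=KD1,
            mu=mu,
        )

    def __post_init__(self) -> None:
        po = tuple(float(p) for p in self.po_vector)
        if len(po) != 5:
            raise ParameterError("po_vector must have five entries (occupancy 0..4)")
        if any(p < 0 or p > 1 for p in po):
            raise ParameterError("open probabilities must lie in [0, 1]")
        if any(po[i] > po[i + 1] for i in range(4)):
            raise ParameterError(
                "po_vector must be non-decreasing: higher Gbg occupancy cannot "
                "lower the open probability"
            )
        if self.kon_unit <= 0 or self.koff_unit <= 0:
            raise ParameterError("per-site binding rates must be positive")
        if self.model_kind is GatingModel.COOPERATIVE:
            if self.KD1 <= 0 or not (0 < self.mu <= 1):
                raise ParameterError("cooperative ladder requires KD1 > 0 and 0 < mu <= 1")
        object.__setattr__(self, "po_vector", po)

    @property
    def po_max(self) -> float:
        return self.po_vector[4]

    @property
    def site_kd(self) -> float:
        """Intrinsic per-site dissociation constant (molar, graded model)."""
        return self.koff_unit / self.kon_unit

    def stepwise_kd(self) -> tuple[float, float, float, float]:
        """Macroscopic stepwise dissociation constants KD1..KD4 (molar).

        Graded model: statistical-factor ladder of the common per-site KD.
        Cooperative model: geometric ladder KD_{i+1} = mu * KD_i.
        """
        if self.model_kind is GatingModel.COOPERATIVE:
            return tuple(self.KD1 * self.mu**i for i in range(4))
        kd = self.site_kd
        return tuple(kd * (n + 1) / (4 - n) for n in range(4))


@dataclass(frozen=True)
class CellContext:
    """Whole-oocyte context for translating open probability into current.

    Currents are measured by two-electrode voltage clamp at -80 mV in 24 mM
    external K+; magnitudes of the inward current are reported positive, in uA.
    """

    channel_density: float            # channels/um^2
    surface_area: float = 2e7         # um^2, from ~200 nF membrane capacitance
    po_max: float = 0.105             # saturating open probability
    c_ibg: float = 0.79               # channels/um^2 per uA of I_bg

    def __post_init__(self) -> None:
        if self.channel_density <= 0 or self.surface_area <= 0:
            raise ParameterError("channel density and surface area must be positive")

    @property
    def n_channels(self) -> float:
        return self.channel_density * self.surface_area

    @property
    def i_single(self) -> float:
        """Single-channel current in uA (~0.60 pA), from the current/density ruler."""
        return 1.0 / (self.po_max * self.c_ibg * self.surface_area)

    @property
    def i_max(self) -> float:
        """Current at saturating Gbg (all channels at Po_max), uA."""
        return self.i_single * self.po_max * self.n_channels
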