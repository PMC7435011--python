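"""The molecular ruler: conversions among currents, fluorescence, RNA dose
and membrane surface densities.

A fluorescently tagged GIRK1 channel of known current-to-density relation
calibrates confocal fluorescence into absolute surface density, which in
turn converts injected receptor RNA doses into receptors per square
micrometre.  All relations are linear and pass through the origin:

* density(channels/um^2) = 0.79 * I_bg(uA) = 1.58 * I_total(uA)
* 1 channel/um^2 = 4 AU of fluorescence; with two tagged subunits per
  heterotetramer, 1 fluorophore/um^2 = 2 AU
* receptor density(/um^2) = 62.5 * RNA dose(ng)
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .params import ParameterError

__all__ = [
    "CalibrationConstants",
    "CurrentKind",
    "FluorescenceTarget",
    "density_from_current",
    "current_from_density",
    "single_channel_current",
    "density_from_fluorescence",
    "fluorescence_from_density",
    "receptor_density_from_rna",
    "rna_from_receptor_density",
]


class CurrentKind(str, Enum):
    I_BG = "I_bg"        # maximal current under saturating coexpressed Gbg
    I_TOTAL = "I_total"  # basal + agonist-evoked current


class FluorescenceTarget(str, Enum):
    CHANNEL = "channel"
    YFP_MOLECULE = "yfp_molecule"


@dataclass(frozen=True)
class CalibrationConstants:
    """Coefficients of the molecular ruler.

    ``c_itotal`` is pinned at twice ``c_ibg`` (the evoked response reaches
    half the Gbg-saturated maximum on average), and ``au_per_yfp`` at
    ``au_per_channel / yfp_per_channel`` (two tagged GIRK1 subunits per
    heterotetramer).  ``inhomogeneity`` is an optional factor (>= 1) for
    non-uniform surface distribution; the default assumes homogeneity,
    which is accurate to at most two-fold.
    """

    c_ibg: float = 0.79            # channels/um^2 per uA of I_bg
    au_per_channel: float = 4.0    # fluorescence AU per channel/um^2
    yfp_per_channel: float = 2.0   # tagged subunits per channel
    rna_slope: float = 62.5        # receptors/um^2 per ng injected RNA
    po_max: float = 0.105
    surface_area: float = 2e7      # um^2
    inhomogeneity: float = 1.0

    def __post_init__(self) -> None:
        for name in ("c_ibg", "au_per_channel", "yfp_per_channel", "rna_slope",
                     "po_max", "surface_area"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"calibration constant {name!r} must be positive")
        if self.inhomogeneity < 1.0:
            raise ParameterError("inhomogeneity factor must be >= 1")

    @property
    def c_itotal(self) -> float:
        """channels/um^2 per uA of I_total (exactly 2 * c_ibg)."""
        return 2.0 * self.c_ibg

    @property
    def au_per_yfp(self) -> float:
        """AU per fluorophore/um^2."""
        return self.au_per_channel / self.yfp_per_channel


def density_from_current(
    current: float,
    which: CurrentKind | str = CurrentKind.I_TOTAL,
    consts: CalibrationConstants = CalibrationConstants(),
) -> float:
    """Channel surface density (channels/um^2) from a measured current (uA)."""
    if current < 0:
        raise ParameterError("current magnitude must be non-negative")
    coef = consts.c_ibg if CurrentKind(which) is CurrentKind.I_BG else consts.c_itotal
    return coef * current * consts.inhomogeneity


def current_from_density(
    density: float,
    which: CurrentKind | str = CurrentKind.I_TOTAL,
    consts: CalibrationConstants = CalibrationConstants(),
) -> float:
    """Inverse of :func:`density_from_current`."""
    if density < 0:
        raise ParameterError("density must be non-negative")
    coef = consts.c_ibg if CurrentKind(which) is CurrentKind.I_BG else consts.c_itotal
    return density / (coef * consts.inhomogeneity)


def single_channel_current(consts: CalibrationConstants = CalibrationConstants()) -> float:
    """Single-channel current i_single in pA (~0.60 pA at defaults).

    From I_bg = i_single * Po_max * N with N = c_ibg * I_bg * S:
    i_single = 1 / (Po_max * c_ibg * S), converted from uA to pA.
    """
    return 1e6 / (consts.po_max * consts.c_ibg * consts.surface_area)


def density_from_fluorescence(
    au: float,
    target: FluorescenceTarget | str = FluorescenceTarget.CHANNEL,
    consts: CalibrationConstants = CalibrationConstants(),
) -> float:
    """Surface density (per um^2) of channels or fluorophores from AU."""
    if au < 0:
        raise ParameterError("fluorescence must be non-negative")
    per_au = (consts.au_per_channel
              if FluorescenceTarget(target) is FluorescenceTarget.CHANNEL
              else consts.au_per_yfp)
    return au / per_au


def fluorescence_from_density(
    density: float,
    target: FluorescenceTarget | str = FluorescenceTarget.CHANNEL,
    consts: CalibrationConstants = CalibrationConstants(),
) -> float:
    """Inverse of :func:`density_from_fluorescence`."""
    if density < 0:
        raise ParameterError("density must be non-negative")
    per_au = (consts.au_per_channel
              if FluorescenceTarget(target) is FluorescenceTarget.CHANNEL
              else consts.au_per_yfp)
    return density * per_au


def receptor_density_from_rna(
    dose_ng: float, consts: CalibrationConstants = CalibrationConstants()
) -> float:
    """Receptor surface density (/um^2) from the injected RNA dose (ng)."""
    if dose_ng < 0:
        raise ParameterError("RNA dose must be non-negative")
    return consts.rna_slope * dose_ng


def rna_from_receptor_density(
    density: float, consts: CalibrationConstants = CalibrationConstants()
) -> float:
    """Inverse of :func:`receptor_density_from_rna`."""
    if density < 0:
        raise ParameterError("density must be non-negative")
    return density / consts.rna_slope
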