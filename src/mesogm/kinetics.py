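"""FvCB C3 biochemistry on a chloroplast-CO2 basis.

Net assimilation is the minimum of the Rubisco-limited and electron-transport
limited rates, each a rectangular hyperbola in the chloroplast CO2 partial
pressure Cc:

    Vc = x1 * Cc / (Cc + x2)          gross carboxylation
    F  = Vc * Gamma* / Cc             photorespiratory CO2 release
    A  = Vc - F - Rd = (Cc - Gamma*) * x1 / (Cc + x2) - Rd

with (x1, x2) = (Vcmax, KmC*(1 + O/KmO)) under Rubisco limitation and
(J/4, 2*Gamma*) under NADPH-limited electron transport.  An ATP-limited
variant (J/4.5, 10.5*Gamma*/4.5) is available but not the default.

Unit convention: partial pressures (Cc, KmC, x2, Gamma*) in ubar; O and KmO
in mbar; fluxes in umol m-2 s-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Limitation",
    "ElectronTransportForm",
    "PhotoParams",
    "LimitationState",
    "gamma_star",
    "limitation_params",
    "carboxylation",
    "photorespiratory_release",
    "net_assimilation",
    "colimited_assimilation",
]


class Limitation(str, Enum):
    """Which FvCB rate limits net assimilation."""

    RUBISCO = "rubisco"
    ELECTRON_TRANSPORT = "electron_transport"


class ElectronTransportForm(str, Enum):
    """Stoichiometry of the electron-transport-limited rate."""

    NADPH = "nadph"  # x1 = J/4,   x2 = 2*Gamma*
    ATP = "atp"      # x1 = J/4.5, x2 = 10.5*Gamma*/4.5


def gamma_star(Sco: float, O: float) -> float:
    """CO2 compensation point in the absence of day respiration, ubar.

    Gamma* = 0.5 * O / Sco, with O in mbar and the Rubisco specificity
    Sco in mbar ubar-1, so the result lands in ubar.
    """
    if Sco <= 0:
        raise ValueError(f"Rubisco specificity must be positive, got Sco={Sco}")
    if np.any(np.asarray(O) < 0):
        raise ValueError(f"O2 partial pressure must be non-negative, got O={O}")
    return 0.5 * O / Sco


@dataclass(frozen=True)
class PhotoParams:
    """FvCB biochemical parameter set.

    Parameters
    ----------
    Vcmax : maximum carboxylation rate, umol m-2 s-1
    J : linear electron transport rate, umol m-2 s-1
    Rd : day respiration, umol m-2 s-1
    KmC : Rubisco Michaelis constant for CO2, ubar
    KmO : Rubisco Michaelis constant for O2, mbar
    Sco : Rubisco CO2/O2 specificity, mbar ubar-1
    O : oxygen partial pressure, mbar (ambient default 210)
    et_form : electron-transport stoichiometry (NADPH-limited default)
    """

    Vcmax: float
    J: float
    Rd: float
    KmC: float
    KmO: float
    Sco: float
    O: float = 210.0
    et_form: ElectronTransportForm = ElectronTransportForm.NADPH

    def __post_init__(self) -> None:
        for name in ("Vcmax", "J", "Rd", "KmC", "KmO", "Sco", "O"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                if name == "Rd" and v == 0:
                    continue  # zero respiration is a legitimate idealisation
                if name == "O" and v == 0:
                    continue  # photorespiration-free limit
                raise ValueError(f"{name} must be positive and finite, got {v}")
        if self.Rd >= self.Vcmax:
            raise ValueError(
                f"Rd={self.Rd} must be below Vcmax={self.Vcmax}: "
                "respiration cannot exceed carboxylation capacity"
            )
        gs = gamma_star(self.Sco, self.O)
        if gs >= self.KmC * (1.0 + self.O / self.KmO):
            raise ValueError(
                f"Gamma*={gs:.3g} ubar must stay below the effective Michaelis "
                "constant KmC*(1+O/KmO); check Sco, KmC, KmO, O"
            )

    @property
    def gamma_star(self) -> float:
        """Derived Gamma* = 0.5*O/Sco, ubar."""
        return gamma_star(self.Sco, self.O)


@dataclass(frozen=True)
class LimitationState:
    """Hyperbola coefficients (x1, x2) for one limitation kind.

    x1 is a flux (umol m-2 s-1); x2 a partial pressure (ubar). Under Rubisco
    limitation x1=Vcmax, x2=KmC*(1+O/KmO); under electron-transport
    limitation (NADPH form) x1=J/4, x2=2*Gamma*.
    """

    kind: Limitation
    x1: float
    x2: float


def limitation_params(p: PhotoParams, kind: Limitation | str) -> LimitationState:
    """Build the (x1, x2) pair for the requested limitation."""
    kind = Limitation(kind)
    if kind is Limitation.RUBISCO:
        return LimitationState(kind, p.Vcmax, p.KmC * (1.0 + p.O / p.KmO))
    gs = p.gamma_star
    if p.et_form is ElectronTransportForm.ATP:
        return LimitationState(kind, p.J / 4.5, 10.5 * gs / 4.5)
    return LimitationState(kind, p.J / 4.0, 2.0 * gs)


def _check_cc(Cc) -> np.ndarray:
    Cc = np.asarray(Cc, dtype=float)
    if np.any(Cc <= 0):
        raise ValueError(f"Cc must be positive (ubar), got {Cc}")
    return Cc


def carboxylation(Cc, s: LimitationState):
    """Gross carboxylation Vc = x1*Cc/(Cc+x2), umol m-2 s-1."""
    Cc = _check_cc(Cc)
    return s.x1 * Cc / (Cc + s.x2)


def photorespiratory_release(Cc, s: LimitationState, gstar: float):
    """Photorespiratory CO2 release F = Vc*Gamma*/Cc = x1*Gamma*/(Cc+x2)."""
    Cc = _check_cc(Cc)
    return s.x1 * gstar / (Cc + s.x2)


def net_assimilation(Cc, s: LimitationState, gstar: float, Rd: float):
    """Net assimilation A = (Cc-Gamma*)*x1/(Cc+x2) - Rd."""
    Cc = _check_cc(Cc)
    return (Cc - gstar) * s.x1 / (Cc + s.x2) - Rd


def colimited_assimilation(Cc, p: PhotoParams) -> tuple[float, LimitationState]:
    """Net assimilation at Cc as min(Ac, Aj), with the achieving limitation.

    Ties are reported as Rubisco-limited so the label is deterministic.
    """
    gs = p.gamma_star
    sc = limitation_params(p, Limitation.RUBISCO)
    sj = limitation_params(p, Limitation.ELECTRON_TRANSPORT)
    if np.ndim(Cc) != 0:
        raise TypeError("colimited_assimilation takes a scalar Cc; map over grids")
    ac = net_assimilation(Cc, sc, gs, p.Rd)
    aj = net_assimilation(Cc, sj, gs, p.Rd)
    return (ac, sc) if ac <= aj else (aj, sj)
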