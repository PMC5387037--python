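"""Generalized two-component mesophyll-resistance model.

Total mesophyll diffusion resistance r_m,dif = 1/g_m,dif is split into a
cell-wall/plasmalemma part r_wp = (1-omega)*r_m,dif and a chloroplast part
r_ch = omega*r_m,dif.  A fraction sigma of mitochondria-released CO2 must
additionally cross r_ch on its way out of the leaf; sigma = k*lambda when
expressed through the inner-mitochondria fraction lambda and the
chloroplast-gap factor k.  The chloroplast CO2 drawdown then reads

    Cc = Ci - A*r_m,dif - omega*(1-sigma)*(F + Rd)*r_m,dif

and the apparent mesophyll conductance A/(Ci - Cc) becomes

    g_m,app = g_m,dif / [1 + omega*(1-sigma)*(F + Rd)/A].

sigma = 1 (or omega = 0) recovers the classical one-resistance model with
g_m,app = g_m,dif; sigma = 0 recovers the Tholen two-resistance model.
Coupled with the FvCB hyperbola A = (Cc-Gamma*)*x1/(Cc+x2) - Rd the
drawdown equation closes to a quadratic in Cc, solved here in closed form.

Units: pressures in ubar, fluxes in umol m-2 s-1, conductances in
mol m-2 s-1 bar-1, resistances in bar m2 s mol-1 (resistance times flux is
then directly ubar).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import (
    Limitation,
    LimitationState,
    PhotoParams,
    limitation_params,
    net_assimilation,
    photorespiratory_release,
)

__all__ = [
    "ResistanceParams",
    "OperatingPoint",
    "effective_sensitivity",
    "solve_cc",
    "operating_point",
    "gm_app",
    "a_ci_curve",
    "co2_compensation",
]


def effective_sensitivity(omega: float, sigma: float) -> float:
    """Composite sensitivity factor omega*(1-sigma) in [0, 1].

    This is the single combination through which the organelle arrangement
    enters the drawdown and apparent-conductance equations: 0 means the
    classical model, omega itself the Tholen model.
    """
    if not (0.0 <= omega <= 1.0):
        raise ValueError(f"omega must lie in [0, 1], got {omega}")
    if not (0.0 <= sigma <= 1.0):
        raise ValueError(f"sigma must lie in [0, 1], got {sigma}")
    return omega * (1.0 - sigma)


@dataclass(frozen=True)
class ResistanceParams:
    """CO2 diffusion network of the mesophyll.

    Parameters
    ----------
    gm_dif : intrinsic mesophyll conductance, mol m-2 s-1 bar-1
    omega : fraction of r_m,dif contributed by the chloroplast component
    sigma : fraction of (photo)respired CO2 that crosses r_ch on escape;
        may be omitted when `lam` (and optionally `k`) is given, in which
        case sigma = k*lam (k defaults to 1, i.e. continuous chloroplasts)
    lam : fraction of mitochondria in the inner cytosol (optional)
    k : chloroplast-gap diffusion factor (optional, requires lam)
    rsc : stomatal + boundary-layer resistance, bar m2 s mol-1; defaults
        to r_m,dif itself when omitted
    """

    gm_dif: float
    omega: float
    sigma: float | None = None
    lam: float | None = None
    k: float | None = None
    rsc: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.gm_dif) or self.gm_dif <= 0:
            raise ValueError(f"gm_dif must be positive, got {self.gm_dif}")
        if not (0.0 <= self.omega <= 1.0):
            raise ValueError(f"omega must lie in [0, 1], got {self.omega}")
        if self.k is not None and self.lam is None:
            raise ValueError("gap factor k requires the inner fraction lam")
        if self.lam is not None and not (0.0 <= self.lam <= 1.0):
            raise ValueError(f"lam must lie in [0, 1], got {self.lam}")
        if self.sigma is None:
            if self.lam is None:
                raise ValueError("either sigma or lam must be specified")
            k = 1.0 if self.k is None else self.k
            object.__setattr__(self, "sigma", k * self.lam)
        elif self.lam is not None:
            k = 1.0 if self.k is None else self.k
            if abs(self.sigma - k * self.lam) > 1e-12:
                raise ValueError(
                    f"inconsistent inputs: sigma={self.sigma} but k*lam={k * self.lam}"
                )
        if not (0.0 <= self.sigma <= 1.0):
            raise ValueError(f"sigma (= k*lam) must lie in [0, 1], got {self.sigma}")
        if self.rsc is None:
            object.__setattr__(self, "rsc", 1.0 / self.gm_dif)
        elif self.rsc <= 0:
            raise ValueError(f"rsc must be positive, got {self.rsc}")

    @property
    def rm_dif(self) -> float:
        """Total mesophyll resistance 1/gm_dif, bar m2 s mol-1."""
        return 1.0 / self.gm_dif

    @property
    def rch(self) -> float:
        """Chloroplast-component resistance omega*r_m,dif."""
        return self.omega * self.rm_dif

    @property
    def rwp(self) -> float:
        """Cell-wall/plasmalemma resistance (1-omega)*r_m,dif."""
        return (1.0 - self.omega) * self.rm_dif

    @property
    def omega_eff(self) -> float:
        """Effective sensitivity omega*(1-sigma)."""
        return effective_sensitivity(self.omega, self.sigma)


@dataclass(frozen=True)
class OperatingPoint:
    """Solved gas-exchange state of the leaf at one Ci.

    Cm_outer is the CO2 partial pressure in the outer cytosol facing the
    chloroplast envelope, Ci - A*r_wp.  gm_app is A/(Ci-Cc), reported as
    NaN at or below the compensation point where the ratio loses meaning.
    """

    Ci: float
    Cc: float
    Cm_outer: float
    A: float
    Vc: float
    F: float
    limitation: Limitation
    gm_app: float


def _cc_root(Ci, x1, x2, gstar, Rd, rm, beta):
    """Positive root of the drawdown/FvCB quadratic (broadcasts).

    Cc**2 + b*Cc + c = 0 with b = x2 - Ci + rm*x1 - rm*beta*Rd and
    c = -Ci*x2 - rm*beta*(x1*gstar + Rd*x2), beta = 1 - omega*(1-sigma).
    c < 0 for all valid inputs, so the roots straddle zero and the
    physical (positive) root is unambiguous.
    """
    b = x2 - Ci + rm * x1 - rm * beta * Rd
    c = -Ci * x2 - rm * beta * (x1 * gstar + Rd * x2)
    disc = b * b - 4.0 * c
    if np.any(disc <= 0) or np.any(c >= 0):
        raise ArithmeticError(
            f"no positive Cc root: b={b}, c={c}, disc={disc}; "
            "inputs violate the model's validity domain"
        )
    return 0.5 * (-b + np.sqrt(disc))


def solve_cc(Ci, p: PhotoParams, r: ResistanceParams, s: LimitationState):
    """Chloroplast CO2 pressure consistent with the drawdown equation.

    Solves Cc = Ci - [A + omega*(1-sigma)*(F+Rd)]*r_m,dif jointly with the
    FvCB hyperbola for the given limitation state.  Broadcasts over Ci.
    """
    Ci = np.asarray(Ci, dtype=float)
    if np.any(Ci <= 0):
        raise ValueError(f"Ci must be positive (ubar), got {Ci}")
    beta = 1.0 - r.omega_eff
    out = _cc_root(Ci, s.x1, s.x2, p.gamma_star, p.Rd, r.rm_dif, beta)
    return float(out) if out.ndim == 0 else out


def gm_app(A: float, F: float, Rd: float, r: ResistanceParams) -> float:
    """Apparent mesophyll conductance g_m,dif / [1 + omega*(1-sigma)*(F+Rd)/A]."""
    if A == 0:
        raise ZeroDivisionError(
            "g_m,app is undefined at the CO2 compensation point (A = 0)"
        )
    return r.gm_dif / (1.0 + r.omega_eff * (F + Rd) / A)


def operating_point(Ci: float, p: PhotoParams, r: ResistanceParams) -> OperatingPoint:
    """Solve the coupled diffusion/biochemistry system at one Ci.

    Both limitation states are solved self-consistently and the one giving
    the smaller net assimilation wins (ties go to Rubisco).
    """
    gs = p.gamma_star
    best = None
    for kind in (Limitation.RUBISCO, Limitation.ELECTRON_TRANSPORT):
        s = limitation_params(p, kind)
        cc = solve_cc(Ci, p, r, s)
        a = net_assimilation(cc, s, gs, p.Rd)
        if best is None or a < best[0]:  # tie keeps Rubisco (first)
            best = (a, cc, s)
    a, cc, s = best
    f = photorespiratory_release(cc, s, gs)
    vc = a + f + p.Rd
    gm = gm_app(a, f, p.Rd, r) if a > 0 else float("nan")
    return OperatingPoint(
        Ci=float(Ci),
        Cc=cc,
        Cm_outer=float(Ci) - a * r.rwp,
        A=a,
        Vc=vc,
        F=f,
        limitation=s.kind,
        gm_app=gm,
    )


def a_ci_curve(ci_grid, p: PhotoParams, r: ResistanceParams) -> list[OperatingPoint]:
    """Operating points along a strictly increasing Ci grid."""
    ci_grid = np.asarray(ci_grid, dtype=float)
    if ci_grid.ndim != 1 or len(ci_grid) == 0:
        raise ValueError("ci_grid must be a non-empty 1-D sequence")
    if np.any(ci_grid <= 0) or np.any(np.diff(ci_grid) <= 0):
        raise ValueError("ci_grid values must be positive and strictly increasing")
    return [operating_point(ci, p, r) for ci in ci_grid]


def co2_compensation(
    p: PhotoParams, r: ResistanceParams, s: LimitationState
) -> tuple[float, float]:
    """CO2 compensation point (Ci_Gamma, Cc_Gamma) for one limitation state.

    At A = 0 the hyperbola gives Cc_Gamma = (Gamma**x1 + Rd*x2)/(x1 - Rd);
    since F + Rd = Vc there, the drawdown adds
    Ci_Gamma = Cc_Gamma + omega*(1-sigma)*Vc(Cc_Gamma)*r_m,dif.
    """
    if s.x1 <= p.Rd:
        raise ValueError(
            f"no compensation point: x1={s.x1} must exceed Rd={p.Rd} "
            "(assimilation can never reach zero from below)"
        )
    gs = p.gamma_star
    cc_g = (gs * s.x1 + p.Rd * s.x2) / (s.x1 - p.Rd)
    vc = s.x1 * cc_g / (cc_g + s.x2)
    ci_g = cc_g + r.omega_eff * vc * r.rm_dif
    return ci_g, cc_g
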