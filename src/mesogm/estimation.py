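"""Estimation-side computations for mesophyll conductance.

The classical drawdown definition g_m = A/(Ci - Cc), the variable-J
inversion of the electron-transport-limited FvCB equation, back-calculation
of the intrinsic conductance g_m,dif from measured fluxes, and bounded
least-squares fitting of (g_m,dif, omega*(1-sigma)) to multi-O2 gas
exchange data.

The variable-J method inverts A = (Cc - Gamma*)*(J/4)/(Cc + 2*Gamma*) - Rd:

    Cc = Gamma* * (J + 8*(A + Rd)) / (J - 4*(A + Rd))

This is exact while assimilation really is electron-transport limited but
biased low once Rubisco takes over (the fluorescence J then overstates the
electron flux serving carboxylation), which drags the back-calculated
g_m,dif below its true value at low Ci.

omega and sigma are not separately identifiable from gas exchange: only the
product omega*(1-sigma) enters the drawdown.  The fitter therefore
estimates this composite (omega_eff); `sigma_from_omega` converts it to
sigma given an anatomically measured omega.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .kinetics import (
    ElectronTransportForm,
    Limitation,
    PhotoParams,
    gamma_star,
    limitation_params,
    net_assimilation,
)
from .network import ResistanceParams, _cc_root

__all__ = [
    "GasExchangeRecord",
    "FitResult",
    "gm_from_drawdown",
    "variable_j_cc",
    "variable_j_gm_app",
    "backcalc_gm_dif",
    "fit_multi_o2",
    "sigma_from_omega",
]


@dataclass(frozen=True)
class GasExchangeRecord:
    """One observed or simulated gas-exchange measurement.

    Ci in ubar, A and J and Rd in umol m-2 s-1, O in mbar.  true_Cc and
    noise_sd are metadata carried only by synthetic records.
    """

    Ci: float
    A: float
    J: float
    O: float = 210.0
    Rd: float = 0.0
    true_Cc: float | None = None
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.Ci <= 0:
            raise ValueError(f"Ci must be positive, got {self.Ci}")
        if self.J <= 0:
            raise ValueError(f"J must be positive, got {self.J}")
        if self.Rd < 0:
            raise ValueError(f"Rd must be non-negative, got {self.Rd}")


@dataclass(frozen=True)
class FitResult:
    """Estimated (g_m,dif, omega_eff) with fit diagnostics."""

    gm_dif_hat: float
    omega_eff_hat: float
    residual_norm: float
    converged: bool
    n_obs: int


def gm_from_drawdown(A: float, Ci: float, Cc: float) -> float:
    """Classical mesophyll conductance g_m = A/(Ci - Cc)."""
    if Ci == Cc:
        raise ZeroDivisionError("Ci = Cc: drawdown conductance is undefined")
    return A / (Ci - Cc)


def variable_j_cc(A: float, J: float, Rd: float, gstar: float) -> float:
    """Chloroplast CO2 from the variable-J inversion, ubar.

    Requires J > 4*(A + Rd): the fluorescence-derived electron flux must be
    able to support the observed assimilation under NADPH stoichiometry.
    """
    denom = J - 4.0 * (A + Rd)
    if denom <= 0:
        raise ValueError(
            f"infeasible fluxes: J={J} cannot support A+Rd={A + Rd} "
            "(need J > 4*(A+Rd))"
        )
    return gstar * (J + 8.0 * (A + Rd)) / denom


def variable_j_gm_app(rec: GasExchangeRecord, gstar: float) -> float:
    """Apparent g_m from one record via the variable-J method."""
    cc = variable_j_cc(rec.A, rec.J, rec.Rd, gstar)
    return gm_from_drawdown(rec.A, rec.Ci, cc)


def backcalc_gm_dif(
    rec: GasExchangeRecord,
    Cc: float,
    omega: float,
    sigma: float,
    gstar: float,
) -> float:
    """Invert the drawdown equation for the intrinsic conductance.

    F is not observable, so it is inferred from the same Cc under test,
    F_hat = (A + Rd)*Gamma*/(Cc - Gamma*), keeping the estimation pathway
    self-consistent.  With the true Cc this recovers the configured
    g_m,dif exactly; with a variable-J Cc it inherits that method's bias.
    """
    if Cc <= gstar:
        raise ValueError(
            f"Cc={Cc} must exceed Gamma*={gstar} for a non-negative inferred F"
        )
    f_hat = (rec.A + rec.Rd) * gstar / (Cc - gstar)
    num = rec.A + omega * (1.0 - sigma) * (f_hat + rec.Rd)
    if num == 0:
        raise ZeroDivisionError("zero total flux: g_m,dif is undefined")
    return num / (rec.Ci - Cc)


def sigma_from_omega(omega_eff: float, omega: float) -> float:
    """Recover sigma = 1 - omega_eff/omega given an anatomical omega."""
    if omega <= 0:
        raise ValueError("omega must be positive to separate sigma")
    sigma = 1.0 - omega_eff / omega
    if not (-1e-9 <= sigma <= 1.0 + 1e-9):
        raise ValueError(
            f"omega_eff={omega_eff} inconsistent with omega={omega}: "
            f"implied sigma={sigma} outside [0, 1]"
        )
    return min(max(sigma, 0.0), 1.0)


def _forward_a(ci, o, gm_dif, omega_eff, known) -> np.ndarray:
    """Vectorised forward model A(Ci, O; g_m,dif, omega_eff).

    Solves both limitation quadratics per record and takes the minimum.
    `known` holds the fixed biochemistry (Vcmax, J, Rd, KmC, KmO, Sco).
    """
    gs = gamma_star(known["Sco"], o)
    rm = 1.0 / gm_dif
    beta = 1.0 - omega_eff
    rd = known["Rd"]
    x2c = known["KmC"] * (1.0 + o / known["KmO"])
    cc_c = _cc_root(ci, known["Vcmax"], x2c, gs, rd, rm, beta)
    a_c = (cc_c - gs) * known["Vcmax"] / (cc_c + x2c) - rd
    x1j, x2j = known["J"] / 4.0, 2.0 * gs
    cc_j = _cc_root(ci, x1j, x2j, gs, rd, rm, beta)
    a_j = (cc_j - gs) * x1j / (cc_j + x2j) - rd
    return np.minimum(a_c, a_j)


# Fixed multi-start grid keeps the fit deterministic and dodges the shallow
# local minima of the (gm_dif, omega_eff) surface.
_GM_STARTS = (0.05, 0.2, 0.5, 1.5, 5.0)
_OMEGA_STARTS = (0.05, 0.275, 0.5, 0.725, 0.95)


def fit_multi_o2(
    records: Sequence[GasExchangeRecord], p_known: PhotoParams
) -> FitResult:
    """Fit (g_m,dif, omega_eff) to gas exchange at several O2 levels.

    Bounded least squares on the A residuals, gm_dif in (0, 10],
    omega_eff in [0, 1], from a fixed 5x5 start grid.  `p_known` supplies
    the biochemistry (its O field is ignored; each record carries its own).
    Needs at least two distinct O2 levels and six records — a single O2
    level cannot separate the diffusional drawdown from the
    (F + Rd)/A sensitivity.
    """
    records = list(records)
    o_levels = {round(rec.O, 6) for rec in records}
    if len(o_levels) < 2:
        raise ValueError(
            f"need records at >= 2 distinct O2 levels, got {sorted(o_levels)}"
        )
    if len(records) < 6:
        raise ValueError(f"need >= 6 records, got {len(records)}")

    ci = np.array([rec.Ci for rec in records])
    a_obs = np.array([rec.A for rec in records])
    o = np.array([rec.O for rec in records])
    known = {
        "Vcmax": p_known.Vcmax,
        "J": p_known.J,
        "Rd": p_known.Rd,
        "KmC": p_known.KmC,
        "KmO": p_known.KmO,
        "Sco": p_known.Sco,
    }

    def resid(theta):
        return _forward_a(ci, o, theta[0], theta[1], known) - a_obs

    best = None
    for g0 in _GM_STARTS:
        for w0 in _OMEGA_STARTS:
            sol = least_squares(
                resid,
                x0=[g0, w0],
                bounds=([1e-4, 0.0], [10.0, 1.0]),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
            if best is None or sol.cost < best.cost:
                best = sol
    return FitResult(
        gm_dif_hat=float(best.x[0]),
        omega_eff_hat=float(best.x[1]),
        residual_norm=float(np.linalg.norm(best.fun)),
        converged=bool(best.success),
        n_obs=len(records),
    )
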