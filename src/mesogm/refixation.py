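"""Refixation fraction of (photo)respired CO2 under the resistance model.

Of the CO2 released in mitochondria, a fraction f_refix diffuses back to
Rubisco and is refixed; the rest escapes through the stomata.  Both routes
are resistor chains, so f_refix is a ratio of conductances.  The general
form, parameterised by sigma (the fraction of released CO2 that must cross
the chloroplast resistance r_ch to escape), is

              sigma/r_cx + (1-sigma)/(r_ch + r_cx)
  f_refix = ------------------------------------------------------------
            sigma/r_cx + (1-sigma)/(r_ch+r_cx)
              + sigma/(r_ch+r_wp+r_sc) + (1-sigma)/(r_wp+r_sc)

where r_cx = (Cc + x2)/x1 converts the carboxylation flux into an
effective resistance.  sigma = 0 gives the outer-mitochondria case
(continuous chloroplasts, mitochondria between plasmalemma and envelope),
sigma = 1 the inner-mitochondria case, and sigma = lambda the mixed case
with an inner fraction lambda.  The flux-to-pressure factor that converts
(F + Rd) to a partial pressure cancels in every ratio and never appears.

The reference evaluation point for worked tables puts Cc at Gamma* with
the Rubisco-limited (x1, x2): see `reference_refix_inputs`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import Limitation, LimitationState, PhotoParams, limitation_params
from .network import ResistanceParams

__all__ = [
    "RefixInputs",
    "rcx",
    "frefix_general",
    "frefix_case1",
    "frefix_case2",
    "frefix_case3",
    "reference_refix_inputs",
]


@dataclass(frozen=True)
class RefixInputs:
    """Resistance chain (bar m2 s mol-1) plus arrangement fraction sigma."""

    rwp: float
    rch: float
    rsc: float
    rcx: float
    sigma: float

    def __post_init__(self) -> None:
        for name in ("rwp", "rch", "rsc", "rcx"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite, got {v}")
        if not (0.0 <= self.sigma <= 1.0):
            raise ValueError(f"sigma must lie in [0, 1], got {self.sigma}")


def rcx(Cc: float, s: LimitationState) -> float:
    """Carboxylation resistance (Cc + x2)/x1, bar m2 s mol-1."""
    if np.any(np.asarray(Cc) <= 0):
        raise ValueError(f"Cc must be positive (ubar), got {Cc}")
    return (Cc + s.x2) / s.x1


def frefix_general(inp: RefixInputs) -> float:
    """Refixed fraction of mitochondrial CO2 for any organelle arrangement."""
    refix = inp.sigma / inp.rcx + (1.0 - inp.sigma) / (inp.rch + inp.rcx)
    escape = inp.sigma / (inp.rch + inp.rwp + inp.rsc) + (1.0 - inp.sigma) / (
        inp.rwp + inp.rsc
    )
    return refix / (refix + escape)


def frefix_case1(rwp: float, rch: float, rsc: float, rcx_: float) -> float:
    """Outer-mitochondria case: (r_sc+r_wp)/(r_sc+r_wp+r_ch+r_cx).

    Equals the general form at sigma = 0.
    """
    return (rsc + rwp) / (rsc + rwp + rch + rcx_)


def frefix_case2(rwp: float, rch: float, rsc: float, rcx_: float) -> float:
    """Inner-mitochondria case: (r_sc+r_wp+r_ch)/(r_sc+r_wp+r_ch+r_cx).

    Equals the general form at sigma = 1 and always exceeds case 1.
    """
    return (rsc + rwp + rch) / (rsc + rwp + rch + rcx_)


def frefix_case3(lam: float, rwp: float, rch: float, rsc: float, rcx_: float) -> float:
    """Mixed arrangement with inner-mitochondria fraction lambda.

    Identical to the general form with sigma = lambda; reduces to case 1
    at lambda = 0 and case 2 at lambda = 1.
    """
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lam must lie in [0, 1], got {lam}")
    return frefix_general(RefixInputs(rwp=rwp, rch=rch, rsc=rsc, rcx=rcx_, sigma=lam))


def reference_refix_inputs(
    p: PhotoParams, r: ResistanceParams, Cc: float | None = None
) -> RefixInputs:
    """Assemble RefixInputs at the reference evaluation point.

    r_cx is evaluated at Cc = Gamma* (unless an explicit Cc is given) with
    the Rubisco-limited (x1, x2); r_sc defaults inside ResistanceParams to
    r_m,dif when not specified.
    """
    s = limitation_params(p, Limitation.RUBISCO)
    cc = p.gamma_star if Cc is None else Cc
    return RefixInputs(rwp=r.rwp, rch=r.rch, rsc=r.rsc, rcx=rcx(cc, s), sigma=r.sigma)
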