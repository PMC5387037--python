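"""Simulate low-Ci assimilation curves for three organelle arrangements.

Holds the intrinsic mesophyll conductance fixed (g_m,dif = 0.4) and varies
sigma, the fraction of (photo)respired CO2 that must cross the chloroplast
resistance to escape: sigma = 0 puts all mitochondria in the outer cytosol,
sigma = 1 behind a continuous chloroplast layer.  More inner mitochondria
means more refixation, hence higher net assimilation at low Ci and a lower
Ci compensation point.
"""

import numpy as np

from mesogm import (
    Limitation,
    PhotoParams,
    ResistanceParams,
    a_ci_curve,
    co2_compensation,
    limitation_params,
)

photo = PhotoParams(Vcmax=80.0, J=125.0, Rd=1.0, KmC=291.0, KmO=194.0, Sco=3.1)
ci = np.arange(60.0, 201.0, 20.0)

print("Net assimilation A (umol m-2 s-1) at low Ci, omega = 0.5:")
header = "Ci_ubar " + "  ".join(f"sigma={s:g}" for s in (0.0, 0.5, 1.0))
print(header)
curves = {
    s: a_ci_curve(ci, photo, ResistanceParams(gm_dif=0.4, omega=0.5, sigma=s))
    for s in (0.0, 0.5, 1.0)
}
for i, c in enumerate(ci):
    row = "  ".join(f"{curves[s][i].A:7.3f}" for s in (0.0, 0.5, 1.0))
    print(f"{c:7.0f} {row}")

s_rub = limitation_params(photo, Limitation.RUBISCO)
print("\nCi compensation point (ubar):")
for s in (0.0, 0.5, 1.0):
    r = ResistanceParams(gm_dif=0.4, omega=0.5, sigma=s)
    ci_g, cc_g = co2_compensation(photo, r, s_rub)
    print(f"  sigma={s:g}: Ci_comp={ci_g:6.2f}, Cc_comp={cc_g:6.2f}")

print(
    "\nAt each Ci the sigma=1 curve sits highest: refixed photorespiratory\n"
    "CO2 subsidises assimilation most when mitochondria hide behind the\n"
    "chloroplast layer, and the compensation point drops accordingly."
)
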