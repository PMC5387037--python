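"""Estimate (g_m,dif, omega*(1-sigma)) from noisy multi-O2 gas exchange.

Only the composite omega*(1-sigma) is identifiable from gas exchange — the
arrangement parameter sigma can be separated afterwards if anatomy supplies
omega.  Varying the O2 level changes photorespiration and hence the
(F + Rd)/A leverage that pins the composite down.
"""

from mesogm import (
    PhotoParams,
    ResistanceParams,
    ScenarioConfig,
    fit_multi_o2,
    generate_synthetic,
    sigma_from_omega,
)

photo = PhotoParams(Vcmax=80.0, J=125.0, Rd=1.0, KmC=291.0, KmO=194.0, Sco=3.1)
truth = ResistanceParams(gm_dif=0.4, omega=0.5, sigma=0.5)  # omega_eff = 0.25

cfg = ScenarioConfig(
    photo=photo,
    resistance=truth,
    ci_start=50.0,
    ci_stop=400.0,
    ci_step=27.0,
    o2_levels=(20.0, 210.0, 400.0),
    noise_sd=0.2,
    seed=42,
)
records = generate_synthetic(cfg)
fit = fit_multi_o2(records, photo)

print(f"records: {fit.n_obs} at O2 levels {cfg.o2_levels} mbar, noise sd 0.2")
print(f"g_m,dif   : true 0.400, fitted {fit.gm_dif_hat:.3f} mol m-2 s-1 bar-1")
print(f"omega_eff : true 0.250, fitted {fit.omega_eff_hat:.3f}")
print(f"residual norm {fit.residual_norm:.3f}, converged: {fit.converged}")
print(
    f"with anatomical omega = 0.5, implied sigma = "
    f"{sigma_from_omega(fit.omega_eff_hat, 0.5):.3f} (true 0.5)"
)
print(
    "\nBoth parameters land near truth: O2 contrast separates the physical\n"
    "drawdown (g_m,dif) from the photorespiration sensitivity (omega_eff)."
)
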