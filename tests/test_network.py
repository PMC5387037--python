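"""Coupled drawdown/biochemistry solver against independent oracles.

The closed-form quadratic root is cross-checked with bisection on the
drawdown residual, and the sigma = 0 and sigma = 1 limits are checked
against independently coded versions of the Tholen two-resistance model
and the classical one-resistance model.
"""

import numpy as np
import pytest
from scipy.optimize import brentq

from mesogm import (
    Limitation,
    PhotoParams,
    ResistanceParams,
    a_ci_curve,
    co2_compensation,
    effective_sensitivity,
    gm_app,
    limitation_params,
    net_assimilation,
    operating_point,
    photorespiratory_release,
    solve_cc,
)


def drawdown_residual(cc, ci, p, r, s):
    """Eq.-13 residual: Cc - [Ci - (A + w(1-s)(F+Rd))*r_m,dif]."""
    a = net_assimilation(cc, s, p.gamma_star, p.Rd)
    f = photorespiratory_release(cc, s, p.gamma_star)
    return cc - (ci - (a + r.omega_eff * (f + p.Rd)) * r.rm_dif)


def bisect_cc(ci, p, r, s):
    """Independent oracle: root-bracketing on the drawdown residual."""
    return brentq(drawdown_residual, 1e-9, 10.0 * ci + 1e4, args=(ci, p, r, s), xtol=1e-12)


class TestEffectiveSensitivity:
    def test_literature_composite(self):
        """omega=0.65 with sigma=0.8 collapses to ~0.13."""
        assert effective_sensitivity(0.65, 0.8) == pytest.approx(0.13)

    def test_classical_and_tholen_limits(self):
        assert effective_sensitivity(0.7, 1.0) == 0.0
        assert effective_sensitivity(0.5, 0.0) == 0.5

    @pytest.mark.parametrize("omega,sigma", [(-0.1, 0.5), (1.1, 0.5), (0.5, -0.1), (0.5, 2.0)])
    def test_out_of_range_rejected(self, omega, sigma):
        with pytest.raises(ValueError):
            effective_sensitivity(omega, sigma)


class TestResistanceParams:
    def test_decomposition(self, make_resistance):
        r = make_resistance(omega=0.5, sigma=0.5)
        assert r.rm_dif == pytest.approx(2.5)
        assert r.rwp == pytest.approx(1.25)
        assert r.rch == pytest.approx(1.25)
        assert r.rsc == pytest.approx(2.5)  # defaults to r_m,dif

    def test_sigma_from_k_lambda(self):
        r = ResistanceParams(gm_dif=0.4, omega=0.5, lam=0.8, k=0.5)
        assert r.sigma == pytest.approx(0.4)
        r2 = ResistanceParams(gm_dif=0.4, omega=0.5, lam=0.8)  # k defaults to 1
        assert r2.sigma == pytest.approx(0.8)

    def test_inconsistent_or_invalid_inputs(self):
        with pytest.raises(ValueError, match="inconsistent"):
            ResistanceParams(gm_dif=0.4, omega=0.5, sigma=0.9, lam=0.8, k=0.5)
        with pytest.raises(ValueError):
            ResistanceParams(gm_dif=0.4, omega=0.5, lam=0.8, k=2.0)  # k*lam > 1
        with pytest.raises(ValueError):
            ResistanceParams(gm_dif=0.4, omega=1.2, sigma=0.5)
        with pytest.raises(ValueError):
            ResistanceParams(gm_dif=0.4, omega=0.5)  # neither sigma nor lam


class TestSolveCc:
    def test_reference_point(self, photo, make_resistance):
        """Ci=100, sigma=1, omega=0.5 under the reference biochemistry."""
        r = make_resistance(omega=0.5, sigma=1.0)
        s = limitation_params(photo, Limitation.RUBISCO)
        cc = solve_cc(100.0, photo, r, s)
        assert cc == pytest.approx(87.1, abs=0.05)
        assert cc == pytest.approx(bisect_cc(100.0, photo, r, s), abs=1e-9)

    def test_quadratic_matches_bisection_200_draws(self):
        """Closed form vs root bracketing over random parameter draws."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            p = PhotoParams(
                Vcmax=rng.uniform(20, 150),
                J=rng.uniform(40, 300),
                Rd=rng.uniform(0.1, 3.0),
                KmC=rng.uniform(150, 450),
                KmO=rng.uniform(100, 400),
                Sco=rng.uniform(2.0, 4.5),
                O=rng.uniform(20, 400),
            )
            r = ResistanceParams(
                gm_dif=rng.uniform(0.05, 2.0),
                omega=rng.uniform(0, 1),
                sigma=rng.uniform(0, 1),
            )
            ci = rng.uniform(20, 800)
            kind = Limitation.RUBISCO if rng.random() < 0.5 else Limitation.ELECTRON_TRANSPORT
            s = limitation_params(p, kind)
            cc = solve_cc(ci, p, r, s)
            assert cc > 0
            assert abs(cc - bisect_cc(ci, p, r, s)) < 1e-6
            assert abs(drawdown_residual(cc, ci, p, r, s)) < 1e-6

    def test_depends_only_on_omega_eff(self, photo):
        """omega=0 at any sigma equals sigma=1 at any omega (both give 0)."""
        s = limitation_params(photo, Limitation.RUBISCO)
        cc1 = solve_cc(250.0, photo, ResistanceParams(gm_dif=0.4, omega=0.0, sigma=0.3), s)
        cc2 = solve_cc(250.0, photo, ResistanceParams(gm_dif=0.4, omega=0.8, sigma=1.0), s)
        assert cc1 == pytest.approx(cc2, rel=1e-12)

    def test_no_drawdown_limit(self, photo):
        s = limitation_params(photo, Limitation.RUBISCO)
        r = ResistanceParams(gm_dif=1e9, omega=0.5, sigma=0.5)
        assert solve_cc(300.0, photo, r, s) == pytest.approx(300.0, abs=1e-4)


def tholen_gm_app(ci, p, r):
    """Independently coded two-resistance model (sigma = 0 special case).

    Solves Cc = Ci - A*(r_wp + r_ch) - (F + Rd)*r_ch by bracketing, then
    g_m = 1/[r_m,dif*(1 + omega*(F+Rd)/A)].
    """
    gs = p.gamma_star
    best = None
    for kind in Limitation:
        s = limitation_params(p, kind)

        def resid(cc):
            a = (cc - gs) * s.x1 / (cc + s.x2) - p.Rd
            f = s.x1 * gs / (cc + s.x2)
            return cc - (ci - a * (r.rwp + r.rch) - (f + p.Rd) * r.rch)

        cc = brentq(resid, 1e-9, 10.0 * ci + 1e4, xtol=1e-12)
        a = (cc - gs) * s.x1 / (cc + s.x2) - p.Rd
        f = s.x1 * gs / (cc + s.x2)
        if best is None or a < best[0]:
            best = (a, f, cc)
    a, f, cc = best
    return 1.0 / (r.rm_dif * (1.0 + r.omega * (f + p.Rd) / a)), a, cc


class TestReductions:
    def test_sigma_one_recovers_classical_constant_gm(self, photo, make_resistance):
        """sigma=1: apparent conductance is flat at g_m,dif across Ci."""
        r = make_resistance(omega=0.5, sigma=1.0)
        for pt in a_ci_curve(np.arange(60.0, 401.0, 20.0), photo, r):
            assert pt.gm_app == pytest.approx(0.4, rel=1e-9)
            assert pt.A / (pt.Ci - pt.Cc) == pytest.approx(0.4, rel=1e-9)

    def test_sigma_zero_matches_tholen_oracle(self, photo, make_resistance):
        """sigma=0 reproduces the independently coded two-resistance model."""
        r = make_resistance(omega=0.5, sigma=0.0)
        for ci in (80.0, 150.0, 250.0, 400.0):
            gm_oracle, a_oracle, cc_oracle = tholen_gm_app(ci, photo, r)
            pt = operating_point(ci, photo, r)
            assert pt.Cc == pytest.approx(cc_oracle, abs=1e-8)
            assert pt.A == pytest.approx(a_oracle, rel=1e-9)
            assert pt.gm_app == pytest.approx(gm_oracle, rel=1e-9)


class TestOperatingPoint:
    def test_gm_app_identity_with_drawdown(self, photo, make_resistance):
        """Closed-form Eq.-14 conductance equals A/(Ci-Cc) when A > 0."""
        r = make_resistance(omega=0.5, sigma=0.5)
        for ci in (60.0, 120.0, 300.0, 500.0):
            pt = operating_point(ci, photo, r)
            assert pt.A > 0
            assert pt.gm_app == pytest.approx(pt.A / (pt.Ci - pt.Cc), rel=1e-9)
            assert pt.gm_app == pytest.approx(
                gm_app(pt.A, pt.F, photo.Rd, r), rel=1e-12
            )

    def test_limitation_transition(self, photo, make_resistance):
        r = make_resistance()
        assert operating_point(150.0, photo, r).limitation is Limitation.RUBISCO
        assert operating_point(450.0, photo, r).limitation is Limitation.ELECTRON_TRANSPORT

    def test_cm_outer_between_cc_and_ci(self, photo):
        """With 0 < omega < 1 the outer-cytosol pressure is intermediate."""
        r = ResistanceParams(gm_dif=0.4, omega=0.5, sigma=0.5)
        for ci in (100.0, 200.0, 350.0):
            pt = operating_point(ci, photo, r)
            assert pt.Cc < pt.Cm_outer < pt.Ci
            assert pt.Cm_outer == pytest.approx(pt.Ci - pt.A * r.rwp, rel=1e-12)

    def test_flux_bookkeeping(self, photo, make_resistance):
        pt = operating_point(250.0, photo, make_resistance())
        assert pt.Vc == pytest.approx(pt.A + pt.F + photo.Rd, rel=1e-12)

    def test_gm_app_nan_below_compensation(self, photo, make_resistance):
        r = make_resistance(sigma=0.0)
        s = limitation_params(photo, Limitation.RUBISCO)
        ci_g, _ = co2_compensation(photo, r, s)
        pt = operating_point(0.5 * ci_g, photo, r)
        assert pt.A < 0
        assert np.isnan(pt.gm_app)


class TestCurveShape:
    def test_a_increases_with_sigma_decreases_with_omega_at_low_ci(self, photo):
        """Ordering of the simulated low-Ci assimilation curves."""
        ci = np.arange(60.0, 161.0, 20.0)
        curves_sigma = {
            s: [pt.A for pt in a_ci_curve(ci, photo, ResistanceParams(gm_dif=0.4, omega=0.5, sigma=s))]
            for s in (0.0, 0.5, 1.0)
        }
        for lo, hi in ((0.0, 0.5), (0.5, 1.0)):
            assert all(a < b for a, b in zip(curves_sigma[lo], curves_sigma[hi]))
        curves_omega = {
            w: [pt.A for pt in a_ci_curve(ci, photo, ResistanceParams(gm_dif=0.4, omega=w, sigma=0.5))]
            for w in (0.0, 0.5, 0.9)
        }
        for lo, hi in ((0.5, 0.0), (0.9, 0.5)):
            assert all(a < b for a, b in zip(curves_omega[lo], curves_omega[hi]))

    def test_curves_converge_at_high_ci(self, photo):
        """Refixation matters less as Ci rises: sigma curves approach."""
        gap = {}
        for ci in (80.0, 800.0):
            a0 = operating_point(ci, photo, ResistanceParams(gm_dif=0.4, omega=0.5, sigma=0.0)).A
            a1 = operating_point(ci, photo, ResistanceParams(gm_dif=0.4, omega=0.5, sigma=1.0)).A
            gap[ci] = abs(a1 - a0)
        assert gap[800.0] < 0.1 * gap[80.0]

    def test_a_nondecreasing_along_grid(self, photo, make_resistance):
        pts = a_ci_curve(np.arange(50.0, 601.0, 10.0), photo, make_resistance())
        a = [pt.A for pt in pts]
        assert all(b >= a_ for a_, b in zip(a, a[1:]))

    def test_gm_app_strictly_increasing_below_crossover(self, photo, make_resistance):
        """Declining apparent conductance at low Ci when omega*(1-sigma) > 0."""
        r = make_resistance(omega=0.5, sigma=0.5)
        s = limitation_params(photo, Limitation.RUBISCO)
        ci_g, _ = co2_compensation(photo, r, s)
        # find the Ac->Aj transition along Ci
        ci_grid = np.arange(ci_g + 2.0, 500.0, 2.0)
        pts = [operating_point(ci, photo, r) for ci in ci_grid]
        kinds = [pt.limitation for pt in pts]
        cross_idx = kinds.index(Limitation.ELECTRON_TRANSPORT)
        gm = [pt.gm_app for pt in pts[:cross_idx]]
        assert len(gm) > 10
        assert all(b > a_ for a_, b in zip(gm, gm[1:]))


class TestCompensationPoint:
    def test_closed_form_and_zero_assimilation(self, photo, make_resistance):
        r = make_resistance(omega=0.5, sigma=0.5)
        s = limitation_params(photo, Limitation.RUBISCO)
        ci_g, cc_g = co2_compensation(photo, r, s)
        gs = photo.gamma_star
        assert cc_g == pytest.approx((gs * s.x1 + photo.Rd * s.x2) / (s.x1 - photo.Rd), rel=1e-12)
        assert abs(operating_point(ci_g, photo, r).A) < 1e-6

    def test_sigma_one_means_no_offset(self, photo, make_resistance):
        r = make_resistance(sigma=1.0)
        s = limitation_params(photo, Limitation.RUBISCO)
        ci_g, cc_g = co2_compensation(photo, r, s)
        assert ci_g == pytest.approx(cc_g, rel=1e-12)

    def test_sigma_ordering_of_ci_compensation(self, photo):
        s = limitation_params(photo, Limitation.RUBISCO)
        ci0, _ = co2_compensation(photo, ResistanceParams(gm_dif=0.4, omega=0.5, sigma=0.0), s)
        ci1, _ = co2_compensation(photo, ResistanceParams(gm_dif=0.4, omega=0.5, sigma=1.0), s)
        assert ci0 > ci1

    def test_no_compensation_when_x1_below_rd(self, photo, make_resistance):
        from dataclasses import replace

        p = replace(photo, J=2.0)  # x1 = 0.5 < Rd = 1
        s = limitation_params(p, Limitation.ELECTRON_TRANSPORT)
        with pytest.raises(ValueError, match="compensation"):
            co2_compensation(p, make_resistance(), s)
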