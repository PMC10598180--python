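"""Sarcomere laws, TriSeg geometry/tension balance, pericardium."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from murinecv import heart, nominal_parameters
from murinecv._core import cap_geometry, cap_height


# --- sarcomere length / velocity -------------------------------------------

def test_sarcomere_length_closed_form():
    assert heart.sarcomere_length(0.0) == pytest.approx(2.0)
    assert heart.sarcomere_length(0.1) == pytest.approx(2.2103418361512954,
                                                        rel=1e-9)
    assert heart.sarcomere_length(-0.1) == pytest.approx(1.809674836071919,
                                                         rel=1e-9)


@given(st.floats(-0.5, 0.5), st.floats(-0.5, 0.5))
def test_sarcomere_length_monotone(e1, e2):
    if e1 + 1e-12 < e2:
        assert heart.sarcomere_length(e1) < heart.sarcomere_length(e2)


def test_contractile_velocity():
    # isometric fixed point: series stretch equals its isometric length
    assert heart.contractile_velocity(1.99, 1.95, 0.04, 12.0) == \
        pytest.approx(0.0, abs=1e-12)
    assert heart.contractile_velocity(2.0, 1.95, 0.04, 12.0) == \
        pytest.approx(3.0, rel=1e-9)
    # zero series stretch collapses at the unloaded shortening velocity
    assert heart.contractile_velocity(1.9, 1.9, 0.04, 12.0) == -12.0


# --- activation -------------------------------------------------------------

def test_rise_activation_calcium_pulse():
    assert heart.calcium_pulse(0.0, 0.009) == 0.0
    assert heart.calcium_pulse(0.009, 0.009) == \
        pytest.approx(0.3605218523480135, rel=1e-9)
    # clamp: the pulse is identically zero from 8*tau_rise onward
    assert heart.calcium_pulse(8 * 0.009, 0.009) == 0.0
    assert heart.calcium_pulse(0.1, 0.009) == 0.0


def test_rise_activation_length_gate():
    assert heart.rise_activation(0.005, L_sc=1.51) == 0.0  # C_L = 0
    c_l = math.tanh(4.0 * 0.25)
    assert c_l == pytest.approx(0.7615941559557649, rel=1e-12)
    full = heart.rise_activation(0.005, L_sc=1.51 + 0.5)
    bare = heart.calcium_pulse(0.005, 0.009) / 0.009
    assert full == pytest.approx(c_l * bare, rel=1e-12)


def test_decay_activation():
    # rest fixed point
    assert heart.decay_activation(0.05, 1.8, Gamma=0.02) == 0.0
    # length-dependent systole duration
    t_sys = 0.038 * (0.29 + 0.3 * 1.51)
    assert t_sys == pytest.approx(0.028234, rel=1e-9)
    # logistic midpoint: gate = 1/2 exactly at t = T(L_sc)
    psi = heart.decay_activation(t_sys, 1.51, Gamma=1.0)
    assert psi == pytest.approx((0.02 - 1.0) / (2 * 0.009), rel=1e-9)
    # far past systole the gate saturates toward 1
    late = heart.decay_activation(0.2, 1.51, Gamma=1.0)
    assert late == pytest.approx((0.02 - 1.0) / 0.009, rel=1e-3)


# --- stresses ----------------------------------------------------------------

def test_active_stress():
    assert heart.active_stress(0.0, 2.0, 1.8) == 0.0
    assert heart.active_stress(1.0, 1.65, 1.61, sigma_act=75.0) == \
        pytest.approx(7.5, rel=1e-9)
    assert heart.active_stress(0.7, 1.55, 1.51) == 0.0  # L_sc at slack
    assert heart.active_stress(0.7, 1.8, 1.8) == 0.0    # no series stretch


def test_passive_stress():
    g_ecm, g_titin = heart.passive_stress(math.log(1.8 / 2.0))
    assert g_ecm == pytest.approx(0.0, abs=1e-12)
    assert g_titin == pytest.approx(0.0, abs=1e-12)
    g_ecm, g_titin = heart.passive_stress(0.0)
    assert g_ecm == pytest.approx(0.14943775926339542, rel=1e-9)
    assert g_titin == pytest.approx(0.22041910578973029, rel=1e-9)


# --- cap geometry ------------------------------------------------------------

def test_cap_height_closed_form_roots():
    # hemisphere: x = y, V = (pi/6) x (x^2 + 3 y^2) = (2pi/3) x^3
    v = 2.0 * math.pi / 3.0
    assert cap_height(v, 1.0) == pytest.approx(1.0, rel=1e-12)
    assert cap_height(-v, 1.0) == pytest.approx(-1.0, rel=1e-12)
    assert cap_height(0.0, 0.7) == 0.0


@given(st.floats(-1.5, 1.5), st.floats(0.05, 1.5))
def test_cap_height_inverts_cap_volume(x, y):
    v = math.pi / 6.0 * x * (x * x + 3 * y * y)
    assert cap_height(v, y) == pytest.approx(x, abs=1e-9)


def test_wall_geometry_flat_and_hemisphere():
    flat = heart.wall_geometry(0.0, 0.5, V_wall=0.02, A_m_ref=0.5)
    assert flat.C_m == 0.0
    assert flat.z == 0.0
    assert flat.eps_f == pytest.approx(
        0.5 * math.log(flat.A_m / 0.5), rel=1e-12)
    hemi = heart.wall_geometry(2 * math.pi / 3, 1.0, V_wall=0.02,
                               A_m_ref=1.0)
    assert hemi.A_m == pytest.approx(2.0 * math.pi, rel=1e-12)
    assert hemi.C_m == pytest.approx(1.0, rel=1e-12)


def test_wall_geometry_reference_state():
    g = heart.wall_geometry(0.0, 0.5, V_wall=1e-9, A_m_ref=math.pi * 0.25)
    # A_m = pi y^2 at zero cap volume; with A_m_ref equal, eps_f ~ 0
    assert g.eps_f == pytest.approx(0.0, abs=1e-6)


def test_wall_tension_flat_and_decomposition():
    flat = heart.wall_geometry(0.0, 0.5, V_wall=0.02, A_m_ref=0.5)
    t_m, t_x, t_y = heart.wall_tension(flat, 10.0, 0.02)
    assert t_x == 0.0
    assert t_y == pytest.approx(t_m, rel=1e-12)
    t_m0, t_x0, t_y0 = heart.wall_tension(flat, 0.0, 0.02)
    assert (t_m0, t_x0, t_y0) == (0.0, 0.0, 0.0)
    # brute-force decomposition oracle: components rotate with the
    # cap-opening angle phi (sin = 2xy/(x^2+y^2), cos = (y^2-x^2)/(x^2+y^2))
    hemi = heart.wall_geometry(2 * math.pi / 3, 1.0, V_wall=0.02,
                               A_m_ref=1.0)
    t_m, t_x, t_y = heart.wall_tension(hemi, 10.0, 0.02)
    assert t_x == pytest.approx(t_m, rel=1e-12)        # sin = 1 at x = y
    assert t_y == pytest.approx(0.0, abs=1e-12)        # cos = 0 at x = y
    assert math.hypot(t_x, t_y) == pytest.approx(abs(t_m), rel=1e-12)


def test_spherical_thin_wall_matches_laplace():
    """Thin-shell sphere: p_trans ~ 2 h G / r within 5% for h/r <= 0.1."""
    p = nominal_parameters()
    for h_over_r in (0.02, 0.05, 0.1):
        r = 0.2
        v_cav = 4.0 * math.pi / 3.0 * r ** 3
        v_wall = 4.0 * math.pi * r ** 2 * (h_over_r * r)
        # choose a passive state with known uniform stress
        l_sc, gam = 1.8, 0.0
        a_m_ref = 4.0 * math.pi * (r * 1.0) ** 2  # reference at this radius
        # evaluate the wall's own stress at its geometry
        vm = v_cav + 0.5 * v_wall
        rm = (3.0 * vm / (4.0 * math.pi)) ** (1.0 / 3.0)
        eps = 0.5 * math.log(4.0 * math.pi * rm * rm / a_m_ref)
        g_act = heart.active_stress(gam, heart.sarcomere_length(eps), l_sc,
                                    sigma_act=p.sigma_act_a)
        g_pas = sum(heart.passive_stress(eps))
        g = g_act + g_pas
        p_trans = heart.spherical_wall_pressure(v_cav, v_wall, a_m_ref,
                                                l_sc, gam, p)
        h = v_wall / (4.0 * math.pi * rm * rm)
        laplace = 2.0 * h * g / rm
        assert p_trans == pytest.approx(laplace, rel=0.05)


# --- TriSeg balance ----------------------------------------------------------

def _mirror_params():
    p = nominal_parameters()
    return p.replace(A_m_ref_rv=p.A_m_ref_lv, V_wall_rv=p.V_wall_lv)


def test_triseg_mirror_symmetry_flat_septum():
    """Identical left/right walls and volumes balance at a flat septum."""
    p = _mirror_params()
    l_sc = np.full(5, 1.9)
    gam = np.full(5, 0.1)
    v = 0.03
    rx, ry = heart.triseg_residual((0.0, 0.28), v, v, l_sc, gam, p)
    assert rx == pytest.approx(0.0, abs=1e-12)
    vms, ym = heart.solve_triseg(v, v, l_sc, gam, p)
    assert vms == pytest.approx(0.0, abs=1e-8)
    rx, ry = heart.triseg_residual((vms, ym), v, v, l_sc, gam, p)
    assert math.hypot(rx, ry) <= 1e-9


def test_triseg_solver_contract(nominal_params):
    p = nominal_params
    l_sc = np.array([1.9, 1.95, 1.9, 1.93, 1.92])
    gam = np.array([0.02, 0.4, 0.02, 0.4, 0.4])
    vms, ym = heart.solve_triseg(0.035, 0.04, l_sc, gam, p)
    rx, ry = heart.triseg_residual((vms, ym), 0.035, 0.04, l_sc, gam, p)
    assert math.hypot(rx, ry) <= 1e-9
    assert ym > 0
    # bracketing: R_y changes sign across the solved junction radius
    _, ry_lo = heart.triseg_residual((vms, 0.9 * ym), 0.035, 0.04,
                                     l_sc, gam, p)
    _, ry_hi = heart.triseg_residual((vms, 1.1 * ym), 0.035, 0.04,
                                     l_sc, gam, p)
    assert ry_lo * ry_hi < 0


def test_chamber_pressures_zero_stress_reduces_to_pericardium():
    """With zero total wall stress all cavity pressures equal p_peri."""
    p = nominal_parameters()
    # zero active (Gamma=0, but also L_sc at slack) and zero passive
    p = p.replace(sigma_ecm_a=1e-12, sigma_ecm_v=1e-12,
                  sigma_titin_a=1e-12, sigma_titin_v=1e-12,
                  gamma_rest=0.0)
    l_sc = np.full(5, 1.51)
    gam = np.zeros(5)
    v = np.array([0.01, 0.035, 0.01, 0.04])
    p_lv, p_rv, p_la, p_ra = heart.chamber_pressures(v, l_sc, gam, p)
    p_peri = heart.pericardial_pressure(v.sum(), p.V0_peri, p.k_peri)
    for val in (p_lv, p_rv, p_la, p_ra):
        assert val == pytest.approx(p_peri, abs=1e-6)


def test_pericardial_pressure():
    assert heart.pericardial_pressure(0.159, 0.159) == pytest.approx(1.0)
    assert heart.pericardial_pressure(0.159 * 1.1, 0.159, 10.0) == \
        pytest.approx(math.e, rel=1e-9)
    assert heart.pericardial_pressure(0.159 * 1.05, 0.159, 10.0) == \
        pytest.approx(1.6487212707001282, rel=1e-9)
    # strictly increasing
    vals = [heart.pericardial_pressure(v, 0.159) for v in (0.1, 0.15, 0.2)]
    assert vals == sorted(vals)
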