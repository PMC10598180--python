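"""Sarcomere mechanics, activation dynamics, TriSeg wall geometry, and the
pericardial constraint.

The contractile machinery follows a modified Hill scheme: sarcomere length
``L_s`` maps exponentially from myofiber strain, a contractile element of
length ``L_sc`` shortens against an elastic series element, and activation
``Gamma`` rises with an empirical intracellular-calcium pulse and decays
through a logistic gate toward its resting value.  Total wall stress is the
sum of the active stress and two passive constituents (extracellular matrix
and titin), each a power law in the passive stretch.

Ventricular geometry is the three-wall spherical-cap (TriSeg) construction:
LV free wall, septum, and RV free wall share a junction circle of radius
``y_m``; the septal cap volume ``V_m_S`` and ``y_m`` are determined by
axial and radial tension balance at the junction.  Atria are single
spherical walls with the same sarcomere law on an advanced activation
clock.  The pericardium applies a common external pressure that grows
exponentially with total heart blood volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from . import _core
from .registry import ModelParameters, IV_AMREF, IV_VWALL

__all__ = [
    "sarcomere_length", "contractile_velocity", "rise_activation",
    "decay_activation", "active_stress", "passive_stress",
    "WallGeometry", "wall_geometry", "wall_tension",
    "triseg_residual", "solve_triseg", "chamber_pressures",
    "spherical_wall_pressure", "pericardial_pressure", "TriSegError",
]


class TriSegError(RuntimeError):
    """Raised when the ventricular tension balance cannot be solved."""


def sarcomere_length(eps_f: float, Ls_ref: float = 2.0) -> float:
    """Sarcomere length L_s = L_s,ref * exp(eps_f) (um)."""
    return Ls_ref * math.exp(eps_f)


def contractile_velocity(L_s: float, L_sc: float, Ls_iso: float = 0.04,
                         v0: float = 12.0) -> float:
    """Contractile-element shortening rate dL_sc/dt (um/s).

    Zero exactly when the series-element stretch L_s - L_sc equals its
    isometric length; equals -v0 at zero series stretch.
    """
    return ((L_s - L_sc) / Ls_iso - 1.0) * v0


def calcium_pulse(t_beat: float, tau_rise: float) -> float:
    """Dimensionless calcium transient F_rise(t) = 0.02 x^3 (8-x)^2 e^-x,
    x = min(8, t/tau_rise); identically zero once t >= 8 tau_rise."""
    x = min(8.0, t_beat / tau_rise)
    return 0.02 * x ** 3 * (8.0 - x) ** 2 * math.exp(-x)


def rise_activation(t_beat: float, L_sc: float, tau_rise: float = 0.009,
                    Lsc_0: float = 1.51, gamma_mi: float = 1.0) -> float:
    """Activation rise rate Psi_rise = C_L(L_sc) F_rise / tau_rise (1/s).

    ``gamma_mi`` scales the calcium pulse multiplicatively (ischemia).
    """
    c_l = math.tanh(4.0 * (L_sc - Lsc_0) ** 2)
    return c_l * gamma_mi * calcium_pulse(t_beat, tau_rise) / tau_rise


def decay_activation(t_beat: float, L_sc: float, Gamma: float,
                     tau_decay: float = 0.009, tau_sys: float = 0.038,
                     gamma_rest: float = 0.02) -> float:
    """Activation decay rate toward the resting value (1/s).

    The logistic gate opens around the length-dependent systole duration
    T(L_sc) = tau_sys (0.29 + 0.3 L_sc).
    """
    t_sys = tau_sys * (0.29 + 0.3 * L_sc)
    arg = max(-60.0, min(60.0, (t_sys - t_beat) / tau_decay))
    gate = 1.0 / (1.0 + math.exp(arg))
    return (gamma_rest - Gamma) * gate / tau_decay


def active_stress(Gamma: float, L_s: float, L_sc: float,
                  sigma_act: float = 75.0, Lsc_0: float = 1.51,
                  Lse_iso: float = 0.04) -> float:
    """Active myofiber stress G_act (kPa)."""
    return sigma_act * Gamma * (L_sc - Lsc_0) * ((L_s - L_sc) / Lse_iso)


def passive_stress(eps_f: float, Ls_ref: float = 2.0, Ls_pas_ref: float = 1.8,
                   sigma_ecm: float = 0.08, k_ecm: float = 10.0,
                   sigma_titin: float = 0.25, k_titin: float = 6.0
                   ) -> Tuple[float, float]:
    """Passive ECM and titin stresses (kPa); both vanish at unit passive
    stretch lambda = (L_s,ref/L_s,pas,ref) exp(eps_f) = 1."""
    lam = (Ls_ref / Ls_pas_ref) * math.exp(eps_f)
    return (sigma_ecm * (lam ** k_ecm - 1.0),
            sigma_titin * (lam ** k_titin - 1.0))


# ---------------------------------------------------------------------------
# TriSeg kinematics
# ---------------------------------------------------------------------------

@dataclass
class WallGeometry:
    """Spherical-cap midwall kinematics of one wall segment.

    ``x_m`` is the signed cap height along the junction axis, ``z`` the
    dimensionless curvature-thickness ratio; ``eps_f`` the natural myofiber
    strain relative to the reference midwall area.
    """

    V_m: float
    y_m: float
    x_m: float
    A_m: float
    C_m: float
    z: float
    eps_f: float


def wall_geometry(V_m: float, y_m: float, V_wall: float,
                  A_m_ref: float) -> WallGeometry:
    """Cap kinematics from signed midwall volume and junction radius.

    A flat wall (V_m = 0) has zero curvature and zero z; eps_f then reduces
    to the pure areal strain 0.5*ln(A_m/A_m,ref).
    """
    if y_m <= 0:
        raise ValueError("junction radius must be positive")
    x_m, a_m, c_m = _core.cap_geometry(V_m, y_m)
    if a_m <= 0:
        raise TriSegError("non-physical wall geometry (A_m <= 0)")
    z = 3.0 * c_m * V_wall / (2.0 * a_m)
    eps_f = 0.5 * math.log(a_m / A_m_ref) - z * z / 12.0 - 0.019 * z ** 4
    return WallGeometry(V_m, y_m, x_m, a_m, c_m, z, eps_f)


def wall_tension(geometry: WallGeometry, G_total: float,
                 V_wall: float) -> Tuple[float, float, float]:
    """Representative midwall tension and its junction components (kPa*cm).

    T_m is the membrane tension sigma*h in the thin-wall limit with a
    thick-wall correction in even powers of z; T_x (axial) vanishes for a
    flat wall, and (T_x, T_y) rotate with the cap opening angle.
    """
    z2 = geometry.z * geometry.z
    t_m = (V_wall * G_total / geometry.A_m) * (1.0 + z2 / 3.0 + z2 * z2 / 5.0)
    s = geometry.x_m ** 2 + geometry.y_m ** 2
    t_x = t_m * 2.0 * geometry.x_m * geometry.y_m / s
    t_y = t_m * (geometry.y_m ** 2 - geometry.x_m ** 2) / s
    return t_m, t_x, t_y


def triseg_residual(u, V_LV: float, V_RV: float, L_sc, Gamma,
                    params: ModelParameters) -> Tuple[float, float]:
    """Junction tension-balance residual (R_x, R_y) in kPa*cm.

    ``u = (V_m_S, y_m)``; ``L_sc`` and ``Gamma`` are the five per-wall
    sarcomere states (wall order LA, LV, RA, RV, S).  Both residuals are
    exactly zero at mechanical equilibrium.
    """
    if V_LV <= 0 or V_RV <= 0:
        raise ValueError("cavity volumes must be positive")
    pv = params.to_vector()
    out = np.empty(12)
    return _core.triseg_residual(np.asarray(u, dtype=float), V_LV, V_RV,
                                 np.asarray(L_sc, dtype=float),
                                 np.asarray(Gamma, dtype=float), pv, out)


def solve_triseg(V_LV: float, V_RV: float, L_sc, Gamma,
                 params: ModelParameters,
                 warm_start: Optional[Tuple[float, float]] = None,
                 tol: float = 1.0e-9) -> Tuple[float, float]:
    """Solve the two TriSeg constraints; returns (V_m_S, y_m).

    Warm-started Newton with damping; falls back to a flat-septum initial
    guess.  Raises :class:`TriSegError` on non-convergence.
    """
    pv = params.to_vector()
    if warm_start is None:
        u = np.array([0.0, math.sqrt(params.A_m_ref_s / math.pi)])
    else:
        u = np.array([warm_start[0], warm_start[1]], dtype=float)
    out = np.empty(12)
    status = _core.solve_triseg(u, V_LV, V_RV,
                                np.asarray(L_sc, dtype=float),
                                np.asarray(Gamma, dtype=float),
                                pv, out, tol, 50, np.zeros(5))
    if status != 0:
        raise TriSegError("TriSeg Newton iteration did not converge")
    return float(u[0]), float(u[1])


def chamber_pressures(V, L_sc, Gamma, params: ModelParameters,
                      warm_start: Optional[Tuple[float, float]] = None):
    """Cavity pressures (p_LV, p_RV, p_LA, p_RA) in kPa.

    ``V`` holds the four cavity volumes (LA, LV, RA, RV) in mL.  Each
    cavity pressure is its transmural pressure plus the shared pericardial
    pressure.
    """
    v_la, v_lv, v_ra, v_rv = (float(V[i]) for i in range(4))
    pv = params.to_vector()
    p_peri = pericardial_pressure(v_la + v_lv + v_ra + v_rv,
                                  params.V0_peri, params.k_peri)
    if warm_start is None:
        u = np.array([0.0, math.sqrt(params.A_m_ref_s / math.pi)])
    else:
        u = np.array(warm_start, dtype=float)
    out = np.empty(12)
    status = _core.solve_triseg(u, v_lv, v_rv,
                                np.asarray(L_sc, dtype=float),
                                np.asarray(Gamma, dtype=float),
                                pv, out, 1.0e-9, 50, np.zeros(5))
    if status != 0:
        raise TriSegError("TriSeg Newton iteration did not converge")
    p_lv = p_peri - 2.0 * out[0] / u[1]
    p_rv = p_peri + 2.0 * out[8] / u[1]
    ptr_la, _, _ = _core.sphere_wall(v_la, params.V_wall_la, params.A_m_ref_la,
                                     L_sc[0], Gamma[0], 0, pv)
    ptr_ra, _, _ = _core.sphere_wall(v_ra, params.V_wall_ra, params.A_m_ref_ra,
                                     L_sc[2], Gamma[2], 0, pv)
    return p_lv, p_rv, p_peri + ptr_la, p_peri + ptr_ra


def spherical_wall_pressure(V_cav: float, V_wall: float, A_m_ref: float,
                            L_sc: float, Gamma: float,
                            params: ModelParameters,
                            atrial: bool = True) -> float:
    """Transmural pressure (kPa) of a single spherical wall chamber.

    In the thin-wall limit this reproduces the Laplace law
    p = 2 h G / r for uniform wall stress G.
    """
    pv = params.to_vector()
    gp = 0 if atrial else 10
    p_trans, _, _ = _core.sphere_wall(V_cav, V_wall, A_m_ref, L_sc, Gamma,
                                      gp, pv)
    return float(p_trans)


def pericardial_pressure(V_heart: float, V0_peri: float,
                         k_peri: float = 10.0) -> float:
    """Pericardial pressure p_peri = exp(k_peri (V_heart/V0_peri - 1)) kPa.

    Strictly increasing in heart volume; equals 1 kPa at the reference
    volume.  ``V_heart`` is the total blood volume of the four chambers.
    """
    if V0_peri <= 0:
        raise ValueError("V0_peri must be positive")
    return math.exp(k_peri * (V_heart / V0_peri - 1.0))
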