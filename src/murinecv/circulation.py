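"""Closed-loop 0D circulation: assembly, steady-state integration, metrics.

Eight compliant/contractile compartments (LA, LV, RA, RV, systemic arteries
and veins, pulmonary arteries and veins) exchange blood through resistors;
the four cardiac valves and the vena-cava inlet are diodes that only carry
flow down a positive pressure gradient.  Vascular pressures are linear in
stressed volume, chamber pressures come from the wall mechanics in
:mod:`murinecv.heart`.  The resulting 18-state system is integrated with a
fixed-step RK4 scheme, beat by beat, until the state at beat onset is
periodic; the TriSeg tension balance is solved by warm-started Newton
inside every right-hand-side evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from . import _core
from .registry import (COMPARTMENTS, WALLS, KPA_TO_MMHG, HemoSummary,
                       ModelParameters)

__all__ = [
    "SolverConfig", "SimulationResult", "SimulationError",
    "compartment_pressure", "resistive_flow", "system_rhs",
    "initial_state", "simulate", "beat_metrics",
    "upstroke_phase", "circular_shift", "align_streams_to_upstroke",
]

FLOW_NAMES = ("mitral", "aortic", "systemic", "vena_cava", "tricuspid",
              "pulmonic", "pulmonary", "pulm_venous")

#: Calibration streams (order matches the data vector of the likelihood).
CALIBRATION_STREAMS = ("p_RV", "V_RV", "p_LV", "V_LV", "p_SA")


class SimulationError(RuntimeError):
    """Raised when the forward integration fails (geometry or blow-up)."""


def upstroke_phase(p: np.ndarray) -> float:
    """Fractional sample index of the maximal circular derivative of p.

    Used as an operational beat-phase anchor (the ventricular-pressure
    upstroke): the discrete argmax of dp is refined by parabolic
    interpolation so the anchor moves smoothly with the waveform.
    """
    dp = np.roll(p, -1) - np.roll(p, 1)
    i = int(np.argmax(dp))
    n = p.size
    a, b, c = dp[(i - 1) % n], dp[i], dp[(i + 1) % n]
    denom = a - 2.0 * b + c
    off = 0.0 if denom == 0 else 0.5 * (a - c) / denom
    return (i + float(np.clip(off, -0.5, 0.5))) % n


def circular_shift(x: np.ndarray, shift: float) -> np.ndarray:
    """Circularly shift a periodic signal by a fractional number of samples
    (positive = later content moves toward index 0) via linear interpolation."""
    n = x.size
    pos = (np.arange(n) + shift) % n
    i0 = np.floor(pos).astype(int)
    w = pos - i0
    return (1.0 - w) * x[i0] + w * x[(i0 + 1) % n]


def align_streams_to_upstroke(streams, anchor: str = "p_LV"):
    """Rotate all beat streams so the anchor-pressure upstroke sits at
    phase zero.  Returns (aligned streams, applied shift in samples).

    Applying the same operational phase origin to measured and simulated
    beats removes the arbitrary segmentation phase before comparing them.
    """
    shift = upstroke_phase(np.asarray(streams[anchor]))
    return ({k: circular_shift(np.asarray(v), shift)
             for k, v in streams.items()}, shift)


def compartment_pressure(V: float, V_un: float, C: float) -> float:
    """Linear vascular pressure p = (V - V_un)/C (kPa)."""
    if C <= 0:
        raise ValueError("compliance must be positive")
    return (V - V_un) / C


def resistive_flow(p_up: float, p_down: float, R: float,
                   is_valve: bool = False) -> float:
    """Flow down the pressure gradient, q = (p_up - p_down)/R (mL/s).

    Valves are diodes: flow is clamped at zero for adverse gradients.
    """
    if R <= 0:
        raise ValueError("resistance must be positive")
    q = (p_up - p_down) / R
    if is_valve and q < 0.0:
        return 0.0
    return q


@dataclass
class SolverConfig:
    """Numerical configuration of the beat-periodic integration."""

    steps_per_beat: int = 800
    samples_per_beat: int = 200
    max_beats: int = 100
    steady_tol: float = 1.0e-4
    triseg_tol: float = 1.0e-9
    #: run early transient beats at half the step count (the recorded beat
    #: and the convergence check always use the full resolution)
    coarse_transient: bool = True

    def validate(self) -> None:
        if self.steps_per_beat % self.samples_per_beat:
            raise ValueError("steps_per_beat must be a multiple of "
                             "samples_per_beat")
        if min(self.steady_tol, self.triseg_tol) <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class SimulationResult:
    """One converged (or final) beat of the closed-loop model.

    Arrays are sampled on a uniform beat-local time grid.  Volumes in mL,
    pressures in kPa, flows in mL/s, sarcomere lengths in um.
    """

    time: np.ndarray                # (n,)
    volumes: np.ndarray             # (n, 8) compartment order
    pressures: np.ndarray           # (n, 8)
    flows: np.ndarray               # (n, 8) FLOW_NAMES order
    L_s: np.ndarray                 # (n, 5) wall order
    L_sc: np.ndarray                # (n, 5)
    Gamma: np.ndarray               # (n, 5)
    eps_f: np.ndarray               # (n, 5)
    p_peri: np.ndarray              # (n,)
    n_beats: int
    converged: bool
    final_state: np.ndarray         # (18,)
    final_u: np.ndarray             # (2,)
    params: ModelParameters

    def stream(self, name: str) -> np.ndarray:
        """One calibration stream (kPa or mL) on the beat grid."""
        comp = {"p_RV": ("pressures", 3), "V_RV": ("volumes", 3),
                "p_LV": ("pressures", 1), "V_LV": ("volumes", 1),
                "p_SA": ("pressures", 4)}[name]
        return getattr(self, comp[0])[:, comp[1]]

    def calibration_vector(self, aligned: bool = False) -> np.ndarray:
        """The five stacked calibration streams (internal units).

        With ``aligned=True`` the beat is first rotated to the operational
        phase origin (LV-pressure upstroke), the convention used when
        comparing against segmented measured beats.
        """
        streams = {s: self.stream(s) for s in CALIBRATION_STREAMS}
        if aligned:
            streams, _ = align_streams_to_upstroke(streams)
        return np.concatenate([streams[s] for s in CALIBRATION_STREAMS])

    def to_frame(self) -> pd.DataFrame:
        """Beat traces in reporting units (mmHg, uL)."""
        data = {"time_s": self.time}
        for i, c in enumerate(COMPARTMENTS):
            data[f"p_{c}_mmHg"] = self.pressures[:, i] * KPA_TO_MMHG
        for i, c in enumerate(COMPARTMENTS):
            data[f"V_{c}_uL"] = self.volumes[:, i] * 1000.0
        for i, w in enumerate(WALLS):
            data[f"eps_f_{w}"] = self.eps_f[:, i]
        for i, w in enumerate(WALLS):
            data[f"L_s_{w}_um"] = self.L_s[:, i]
        data["p_peri_mmHg"] = self.p_peri * KPA_TO_MMHG
        for i, q in enumerate(FLOW_NAMES):
            data[f"q_{q}_mL_s"] = self.flows[:, i]
        return pd.DataFrame(data)


def system_rhs(t: float, state: np.ndarray, params: ModelParameters,
               warm_u: Optional[np.ndarray] = None) -> np.ndarray:
    """Time derivative of the 18-state vector at one instant.

    Convenience wrapper over the compiled kernel (solves the TriSeg
    constraints internally).  The sum of the eight volume derivatives is
    zero to round-off: the loop is closed.
    """
    pv = params.to_vector()
    if warm_u is None:
        warm_u = np.array([0.0, math.sqrt(params.A_m_ref_s / math.pi)])
    dy = np.empty(_core.NSTATE)
    obs = np.empty(_core.NOBS)
    status = _core.rhs(float(t), np.asarray(state, dtype=float), pv, warm_u,
                       dy, obs, False, np.zeros(5))
    if status != 0:
        raise SimulationError("right-hand-side evaluation failed")
    return dy


def _hemisphere_volume(a_m: float) -> float:
    """Cap volume of a hemisphere with midwall area a_m."""
    r = math.sqrt(a_m / (2.0 * math.pi))
    return 2.0 * math.pi * r ** 3 / 3.0


def initial_state(params: ModelParameters,
                  summary: Optional[HemoSummary] = None
                  ) -> Tuple[np.ndarray, np.ndarray]:
    """Initial (state, triseg) guess for the beat iteration.

    Vascular volumes sit at their nominal operating pressures; ventricles
    start near end-diastolic cap volumes consistent with their reference
    areas (moderately stretched); the volume balance against ``V_total``
    is assigned to the systemic veins.
    """
    summary = summary if summary is not None else HemoSummary()
    y = np.zeros(_core.NSTATE)
    # chambers: cap/sphere volumes at ~15-20% areal stretch
    vm_lv = _hemisphere_volume(params.A_m_ref_lv * 1.35)
    vm_rv = _hemisphere_volume(params.A_m_ref_rv * 1.35)
    y[1] = max(0.012, vm_lv - 0.5 * (params.V_wall_lv + params.V_wall_s))
    y[3] = max(0.012, vm_rv - 0.5 * (params.V_wall_rv + params.V_wall_s))
    for idx, (amref, vwall) in ((0, (params.A_m_ref_la, params.V_wall_la)),
                                (2, (params.A_m_ref_ra, params.V_wall_ra))):
        r = math.sqrt(amref * 1.2 / (4.0 * math.pi))
        y[idx] = max(0.004, 4.0 * math.pi * r ** 3 / 3.0 - 0.5 * vwall)
    # keep the initial four-chamber blood volume inside the pericardium
    budget = 0.92 * params.V0_peri
    cav = y[0] + y[1] + y[2] + y[3]
    if cav > budget:
        y[0:4] *= budget / cav
    # vasculature at nominal pressures (mean-ish arterial values)
    y[4] = params.V_un_sa + params.C_sa * 0.85 * summary.P_sa_max
    y[6] = params.V_un_pa + params.C_pa * 0.85 * summary.P_pa_max
    y[7] = params.V_un_pv + params.C_pv * summary.P_pv_bar
    y[5] = params.V_total - y[:5].sum() - y[6] - y[7]
    if y[5] <= 0.5 * params.V_un_sv:
        raise SimulationError("total blood volume too small for the "
                              "requested initialization")
    y[8:13] = params.Ls_pas_ref
    y[13:18] = params.gamma_rest
    u = np.array([0.0, math.sqrt(params.A_m_ref_s / math.pi)])
    return y, u


def simulate(params: ModelParameters,
             config: Optional[SolverConfig] = None,
             init: Optional[Tuple[np.ndarray, np.ndarray]] = None,
             summary: Optional[HemoSummary] = None) -> SimulationResult:
    """Integrate to a beat-periodic steady state and return the final beat.

    ``init`` may carry a (state, triseg) pair from a previous, nearby
    solution to warm-start the beat iteration.  Raises
    :class:`SimulationError` if the integration itself fails; a run that
    merely fails to meet the periodicity tolerance within ``max_beats`` is
    returned with ``converged=False``.
    """
    config = config or SolverConfig()
    config.validate()
    pv = params.to_vector()
    attempts = []
    if init is not None:
        attempts.append((init[0].copy(), init[1].copy(), config.steps_per_beat))
    y0, u0 = initial_state(params, summary)
    attempts.append((y0, u0, config.steps_per_beat))
    attempts.append((y0.copy(), u0.copy(), 2 * config.steps_per_beat))
    status = 1
    n_beats = 0
    for y, u, nsub in attempts:
        status, converged, n_beats, times, YR, OB, yf, uf = \
            _core.integrate_beats(pv, y, u, nsub, config.samples_per_beat,
                                  config.max_beats, config.steady_tol,
                                  not config.coarse_transient)
        if status == 0:
            break
    if status != 0:
        raise SimulationError(
            f"integration failed after {n_beats} complete beats")
    return SimulationResult(
        time=times.copy(),
        volumes=YR[:, 0:8].copy(),
        pressures=OB[:, _core.OBS_P:_core.OBS_P + 8].copy(),
        flows=OB[:, _core.OBS_Q:_core.OBS_Q + 8].copy(),
        L_s=OB[:, _core.OBS_LS:_core.OBS_LS + 5].copy(),
        L_sc=YR[:, 8:13].copy(),
        Gamma=YR[:, 13:18].copy(),
        eps_f=OB[:, _core.OBS_EPS:_core.OBS_EPS + 5].copy(),
        p_peri=OB[:, _core.OBS_PPERI].copy(),
        n_beats=int(n_beats),
        converged=bool(converged),
        final_state=yf.copy(),
        final_u=uf.copy(),
        params=params,
    )


def _shoelace(x: np.ndarray, y: np.ndarray) -> float:
    """Signed polygon area (closing the loop)."""
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def beat_metrics(result: SimulationResult, chamber: str = "LV"
                 ) -> Dict[str, float]:
    """Beat-level indices of one chamber from the converged beat.

    Returns EDV/ESV/SV in uL, EF (dimensionless), stroke work in mmHg*uL
    (signed shoelace area of the pressure-volume loop; positive for the
    physiologic counter-clockwise traversal in the (V, p) plane), and
    pressure extrema in mmHg.
    """
    if not result.converged:
        raise SimulationError("beat metrics require a converged beat")
    ci = COMPARTMENTS.index(chamber)
    v = result.volumes[:, ci] * 1000.0           # uL
    p = result.pressures[:, ci] * KPA_TO_MMHG    # mmHg
    edv = float(v.max())
    esv = float(v.min())
    return {
        "EDV": edv,
        "ESV": esv,
        "SV": edv - esv,
        "EF": (edv - esv) / edv,
        "stroke_work": _shoelace(v, p),
        "p_max": float(p.max()),
        "p_min": float(p.min()),
    }
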