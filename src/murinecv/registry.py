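"""Parameter registry, nominal-value rules, and unit handling.

The closed-loop heart/circulation model is governed by 53 scalar parameters:
25 sarcomere parameters (10 per activation group, atrial and ventricular,
plus 5 shared globals), 12 cardiac/TriSeg parameters (5 wall volumes, 5
reference midwall areas, 2 pericardial), and 16 vascular parameters (8
resistances, 4 compliances, 4 unstressed volumes).  Fifteen of these are
fixed before any sensitivity analysis: the starred sarcomere reference
lengths/constants, the five wall volumes (set by dissected chamber mass),
and the four unstressed volumes.  The remaining 38 are free.

Nominal values for the vascular parameters follow simple hemodynamic rules
(e.g. ``R_sys = (P_sa_max - P_sys_cap)/CO``) evaluated on a per-animal
summary of cardiac output, characteristic pressures, and stressed volumes.

Internal computation units are kPa, mL, cm (um in the sarcomere), and s;
reporting units at file boundaries are mmHg, uL, and mm.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

__all__ = [
    "KPA_TO_MMHG",
    "MYOCARDIAL_DENSITY",
    "WALLS",
    "COMPARTMENTS",
    "ParameterSpec",
    "HemoSummary",
    "ModelParameters",
    "build_registry",
    "free_parameter_names",
    "nominal_parameters",
    "wall_volume_from_mass",
    "convert_units",
    "InvalidSummaryError",
]

#: kPa -> mmHg conversion factor.
KPA_TO_MMHG = 7.50062

#: Myocardial tissue density (g/cm^3) used to convert chamber mass to wall volume.
MYOCARDIAL_DENSITY = 1.053

#: Wall ordering used throughout the package (index into per-wall arrays).
WALLS = ("LA", "LV", "RA", "RV", "S")

#: Compartment ordering for the eight blood volumes.
COMPARTMENTS = ("LA", "LV", "RA", "RV", "SA", "SV", "PA", "PV")


class InvalidSummaryError(ValueError):
    """Raised when a hemodynamic summary violates its physiologic ordering."""


class UnknownUnitError(ValueError):
    """Raised for an unrecognized unit conversion pair."""


# ---------------------------------------------------------------------------
# unit conversion
# ---------------------------------------------------------------------------

_CONVERSIONS = {
    ("kPa", "mmHg"): KPA_TO_MMHG,
    ("mmHg", "kPa"): 1.0 / KPA_TO_MMHG,
    ("mL", "uL"): 1000.0,
    ("uL", "mL"): 1.0e-3,
    ("cm", "mm"): 10.0,
    ("mm", "cm"): 0.1,
}


def convert_units(value, from_unit: str, to_unit: str):
    """Convert ``value`` between recognized unit pairs.

    Supported pairs: kPa<->mmHg, mL<->uL, cm<->mm (and identity).
    Round trips are exact to floating-point reciprocal error (<1e-12 relative).
    """
    if from_unit == to_unit:
        return value
    try:
        factor = _CONVERSIONS[(from_unit, to_unit)]
    except KeyError:
        raise UnknownUnitError(f"no conversion from {from_unit!r} to {to_unit!r}")
    return value * factor


def wall_volume_from_mass(mass_g: float, split_left_heart: bool = False):
    """Convert chamber mass (g) to wall volume (cm^3) at myocardial density.

    With ``split_left_heart=True`` the mass is the combined LV + septum mass;
    the septum is taken as one third of the total left-heart wall volume and
    the LV free wall as the remaining two thirds.  Returns either a scalar
    volume or a ``(lv_free_wall, septum)`` pair.
    """
    if mass_g <= 0:
        raise ValueError(f"chamber mass must be positive, got {mass_g}")
    volume = mass_g / MYOCARDIAL_DENSITY
    if not split_left_heart:
        return volume
    septum = volume / 3.0
    return volume - septum, septum


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterSpec:
    """Static description of one scalar model parameter."""

    name: str
    group: str          # sarcomere | cardiac | vascular | global
    scope: str          # per-activation-group | per-wall | per-compartment | scalar
    units: str
    fixed: bool
    nominal_rule: str


def _sarcomere_specs() -> List[ParameterSpec]:
    rows = [
        # (stem, units, fixed, atrial rule, ventricular rule)
        ("Ls_ref", "um", True, "2.0", "2.0"),
        ("v0", "um/s", False, "24", "12"),
        ("tau_rise", "s", False, "0.0375*T", "0.009"),
        ("tau_decay", "s", False, "0.005*T", "0.009"),
        ("tau_sys", "s", False, "0.15*T", "0.038"),
        ("k_ecm", "-", False, "10", "10"),
        ("k_titin", "-", False, "6", "6"),
        ("sigma_ecm", "kPa", False, "0.08", "0.08"),
        ("sigma_titin", "kPa", False, "0.25", "0.25"),
        ("sigma_act", "kPa", False, "35", "75"),
    ]
    specs = []
    for stem, units, fixed, rule_a, rule_v in rows:
        specs.append(ParameterSpec(f"{stem}_a", "sarcomere", "per-activation-group",
                                   units, fixed, rule_a))
        specs.append(ParameterSpec(f"{stem}_v", "sarcomere", "per-activation-group",
                                   units, fixed, rule_v))
    specs += [
        ParameterSpec("Ls_iso", "sarcomere", "scalar", "um", True, "0.04"),
        ParameterSpec("Ls_pas_ref", "sarcomere", "scalar", "um", True, "1.8"),
        ParameterSpec("Lsc_0", "sarcomere", "scalar", "um", True, "1.51"),
        ParameterSpec("gamma_rest", "sarcomere", "scalar", "-", True, "0.02"),
        ParameterSpec("tau_offset_a", "sarcomere", "scalar", "s", False, "0.18*T"),
    ]
    return specs


def _cardiac_specs() -> List[ParameterSpec]:
    specs = [
        ParameterSpec(f"V_wall_{w.lower()}", "cardiac", "per-wall", "cm^3",
                      True, "chamber_mass/1.053")
        for w in WALLS
    ]
    area_defaults = {"LA": "0.15", "LV": "[0.50,0.70,0.50]", "RA": "0.15",
                     "RV": "[0.55,0.80,0.50]", "S": "[0.25,0.35,0.35]"}
    specs += [
        ParameterSpec(f"A_m_ref_{w.lower()}", "cardiac", "per-wall", "cm^2",
                      False, area_defaults[w])
        for w in WALLS
    ]
    specs += [
        ParameterSpec("V0_peri", "cardiac", "scalar", "mL", False,
                      "[0.159,0.178,0.165]"),
        ParameterSpec("k_peri", "cardiac", "scalar", "-", False, "10"),
    ]
    return specs


def _vascular_specs() -> List[ParameterSpec]:
    r_rules = {
        "R_a_val": "0.1/CO",
        "R_m_val": "0.75/CO",
        "R_p_val": "0.1/CO",
        "R_t_val": "0.75/CO",
        "R_vc": "(P_sv_bar-P_ra_min)/CO",
        "R_pv": "(P_pv_bar-P_la_min)/CO",
        "R_sys": "(P_sa_max-P_sys_cap)/CO",
        "R_pulm": "(P_pa_max-P_pulm_cap)/CO",
    }
    c_rules = {
        "C_sa": "V_sa/P_sa_max",
        "C_sv": "V_sv/P_sv_bar",
        "C_pa": "V_pa/P_pa_max",
        "C_pv": "V_pv/P_pv_bar",
    }
    specs = [ParameterSpec(n, "vascular", "per-compartment", "kPa*s/mL", False, r)
             for n, r in r_rules.items()]
    specs += [ParameterSpec(n, "vascular", "per-compartment", "mL/kPa", False, r)
              for n, r in c_rules.items()]
    specs += [ParameterSpec(f"V_un_{c}", "vascular", "per-compartment", "mL",
                            True, "configuration")
              for c in ("sa", "sv", "pa", "pv")]
    return specs


def build_registry() -> List[ParameterSpec]:
    """Enumerate all 53 scalar model parameters with fixed/free status.

    Exactly 15 are fixed (11 starred constants/wall volumes plus the 4
    unstressed vascular volumes), leaving 38 free for Morris screening.
    """
    registry = _sarcomere_specs() + _cardiac_specs() + _vascular_specs()
    names = [s.name for s in registry]
    assert len(names) == len(set(names)), "registry names must be unique"
    return registry


def free_parameter_names() -> List[str]:
    """Names of the 38 free (screenable) parameters, in registry order."""
    return [s.name for s in build_registry() if not s.fixed]


# ---------------------------------------------------------------------------
# hemodynamic summary and nominal rules
# ---------------------------------------------------------------------------

@dataclass
class HemoSummary:
    """Per-animal hemodynamic summary feeding the nominal-parameter rules.

    Pressures in kPa, volumes in mL, cardiac output ``CO`` in mL/s.  The
    stressed volumes ``V_sa`` .. ``V_pv`` are the volumes above the unstressed
    volume at the corresponding characteristic pressure.  Defaults describe an
    anesthetized adult mouse.
    """

    CO: float = 0.3
    P_sa_max: float = 13.3
    P_sv_bar: float = 0.5
    P_pv_bar: float = 1.0
    P_pa_max: float = 3.3
    P_ra_min: float = 0.25
    P_la_min: float = 0.5
    P_sys_cap: float = 2.0
    P_pulm_cap: float = 1.33
    V_sa: float = 0.10
    V_sv: float = 0.05
    V_pa: float = 0.03
    V_pv: float = 0.05

    def validate(self) -> None:
        if self.CO <= 0:
            raise InvalidSummaryError("cardiac output must be positive")
        if not (self.P_sa_max > self.P_sys_cap > self.P_sv_bar):
            raise InvalidSummaryError("systemic pressures must be ordered "
                                      "P_sa_max > P_sys_cap > P_sv_bar")
        if not (self.P_pa_max > self.P_pulm_cap > self.P_pv_bar):
            raise InvalidSummaryError("pulmonary pressures must be ordered "
                                      "P_pa_max > P_pulm_cap > P_pv_bar")
        if self.P_sv_bar <= self.P_ra_min or self.P_pv_bar <= self.P_la_min:
            raise InvalidSummaryError("venous pressures must exceed atrial minima")
        for name in ("V_sa", "V_sv", "V_pa", "V_pv"):
            if getattr(self, name) <= 0:
                raise InvalidSummaryError(f"{name} must be positive")


#: Default dissected chamber masses (g); the left-heart total is split 2/3
#: LV free wall, 1/3 septum.  Overridable per animal.  Chosen so that the
#: four-chamber volume (cavity + wall) operates just below the reference
#: pericardial volume, where the pericardial constraint is active.
DEFAULT_WALL_MASSES = {"la": 0.005, "ra": 0.005, "left_heart": 0.062, "rv": 0.0174}

# Mouse-specific nominal brackets (mouse index 1..3).
_AMREF_BRACKETS = {
    "LA": (0.15, 0.15, 0.15),
    "LV": (0.50, 0.70, 0.50),
    "RA": (0.15, 0.15, 0.15),
    "RV": (0.55, 0.80, 0.50),
    "S": (0.25, 0.35, 0.35),
}
_V0PERI_BRACKET = (0.159, 0.178, 0.165)

#: Fixed unstressed vascular volumes (mL); configuration constants.
DEFAULT_UNSTRESSED = {"sa": 0.10, "sv": 0.44, "pa": 0.03, "pv": 0.05}


# --- flat simulation-vector layout (shared with the compiled kernels) -------
# group block: atrial 0-9, ventricular 10-19
IG_LS_REF, IG_V0, IG_TAU_RISE, IG_TAU_DECAY, IG_TAU_SYS = 0, 1, 2, 3, 4
IG_K_ECM, IG_K_TITIN, IG_SIG_ECM, IG_SIG_TITIN, IG_SIG_ACT = 5, 6, 7, 8, 9
IV_LS_ISO, IV_LS_PAS_REF, IV_LSC0, IV_GAMMA_REST, IV_TAU_OFFSET_A = 20, 21, 22, 23, 24
IV_VWALL = 25          # 25..29, wall order LA LV RA RV S
IV_AMREF = 30          # 30..34
IV_V0PERI, IV_KPERI = 35, 36
IV_R = 37              # 37..44: a_val, m_val, p_val, t_val, vc, pv, sys, pulm
IV_C = 45              # 45..48: sa, sv, pa, pv
IV_VUN = 49            # 49..52: sa, sv, pa, pv
IV_T, IV_VTOTAL = 53, 54
IV_GAMMA_MI = 55       # 55..59 per-wall activation scaling (1 = healthy)
NPVEC = 60

_R_NAMES = ("R_a_val", "R_m_val", "R_p_val", "R_t_val", "R_vc", "R_pv",
            "R_sys", "R_pulm")
_C_NAMES = ("C_sa", "C_sv", "C_pa", "C_pv")


@dataclass
class ModelParameters:
    """Complete scalar parameterization of the closed-loop model.

    Holds the 53 registry parameters plus the configuration constants
    ``T`` (cardiac period, s), ``V_total`` (circulating blood volume, mL),
    and the per-wall activation scaling ``gamma_mi`` used for ischemia
    (all ones at baseline).
    """

    # sarcomere, atrial / ventricular
    Ls_ref_a: float = 2.0
    Ls_ref_v: float = 2.0
    v0_a: float = 24.0
    v0_v: float = 12.0
    tau_rise_a: float = 0.0
    tau_rise_v: float = 0.009
    tau_decay_a: float = 0.0
    tau_decay_v: float = 0.009
    tau_sys_a: float = 0.0
    tau_sys_v: float = 0.038
    k_ecm_a: float = 10.0
    k_ecm_v: float = 10.0
    k_titin_a: float = 6.0
    k_titin_v: float = 6.0
    sigma_ecm_a: float = 0.08
    sigma_ecm_v: float = 0.08
    sigma_titin_a: float = 0.25
    sigma_titin_v: float = 0.25
    sigma_act_a: float = 35.0
    sigma_act_v: float = 75.0
    # sarcomere globals
    Ls_iso: float = 0.04
    Ls_pas_ref: float = 1.8
    Lsc_0: float = 1.51
    gamma_rest: float = 0.02
    tau_offset_a: float = 0.0
    # walls
    V_wall_la: float = 0.004748
    V_wall_lv: float = 0.039253
    V_wall_ra: float = 0.004748
    V_wall_rv: float = 0.016524
    V_wall_s: float = 0.019626
    A_m_ref_la: float = 0.15
    A_m_ref_lv: float = 0.50
    A_m_ref_ra: float = 0.15
    A_m_ref_rv: float = 0.55
    A_m_ref_s: float = 0.25
    # pericardium
    V0_peri: float = 0.159
    k_peri: float = 10.0
    # vasculature
    R_a_val: float = 0.0
    R_m_val: float = 0.0
    R_p_val: float = 0.0
    R_t_val: float = 0.0
    R_vc: float = 0.0
    R_pv: float = 0.0
    R_sys: float = 0.0
    R_pulm: float = 0.0
    C_sa: float = 0.0
    C_sv: float = 0.0
    C_pa: float = 0.0
    C_pv: float = 0.0
    V_un_sa: float = 0.10
    V_un_sv: float = 0.44
    V_un_pa: float = 0.03
    V_un_pv: float = 0.05
    # configuration
    T: float = 0.11
    V_total: float = 1.15
    gamma_mi: tuple = (1.0, 1.0, 1.0, 1.0, 1.0)

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        positive = [
            "v0_a", "v0_v", "tau_rise_a", "tau_rise_v", "tau_decay_a",
            "tau_decay_v", "tau_sys_a", "tau_sys_v", "sigma_ecm_a",
            "sigma_ecm_v", "sigma_titin_a", "sigma_titin_v", "sigma_act_a",
            "sigma_act_v", "V_wall_la", "V_wall_lv", "V_wall_ra", "V_wall_rv",
            "V_wall_s", "A_m_ref_la", "A_m_ref_lv", "A_m_ref_ra",
            "A_m_ref_rv", "A_m_ref_s", "V0_peri", "k_peri",
            "R_a_val", "R_m_val", "R_p_val", "R_t_val", "R_vc", "R_pv",
            "R_sys", "R_pulm", "C_sa", "C_sv", "C_pa", "C_pv",
            "T", "V_total",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be strictly positive")
        if not (self.Lsc_0 < self.Ls_pas_ref < self.Ls_ref_v):
            raise ValueError("require Lsc_0 < Ls_pas_ref < Ls_ref")
        if not (0 <= self.tau_offset_a < self.T):
            raise ValueError("atrial offset must lie within one period")
        for g in self.gamma_mi:
            if not (0 < g <= 1):
                raise ValueError("gamma_mi entries must lie in (0, 1]")

    # -- flat-vector packing ----------------------------------------------
    def to_vector(self) -> np.ndarray:
        """Pack into the flat float64 layout consumed by the compiled kernels."""
        v = np.zeros(NPVEC)
        for gi, suf in enumerate(("a", "v")):
            base = gi * 10
            v[base + IG_LS_REF] = getattr(self, f"Ls_ref_{suf}")
            v[base + IG_V0] = getattr(self, f"v0_{suf}")
            v[base + IG_TAU_RISE] = getattr(self, f"tau_rise_{suf}")
            v[base + IG_TAU_DECAY] = getattr(self, f"tau_decay_{suf}")
            v[base + IG_TAU_SYS] = getattr(self, f"tau_sys_{suf}")
            v[base + IG_K_ECM] = getattr(self, f"k_ecm_{suf}")
            v[base + IG_K_TITIN] = getattr(self, f"k_titin_{suf}")
            v[base + IG_SIG_ECM] = getattr(self, f"sigma_ecm_{suf}")
            v[base + IG_SIG_TITIN] = getattr(self, f"sigma_titin_{suf}")
            v[base + IG_SIG_ACT] = getattr(self, f"sigma_act_{suf}")
        v[IV_LS_ISO] = self.Ls_iso
        v[IV_LS_PAS_REF] = self.Ls_pas_ref
        v[IV_LSC0] = self.Lsc_0
        v[IV_GAMMA_REST] = self.gamma_rest
        v[IV_TAU_OFFSET_A] = self.tau_offset_a
        for wi, w in enumerate(WALLS):
            v[IV_VWALL + wi] = getattr(self, f"V_wall_{w.lower()}")
            v[IV_AMREF + wi] = getattr(self, f"A_m_ref_{w.lower()}")
        v[IV_V0PERI] = self.V0_peri
        v[IV_KPERI] = self.k_peri
        for i, n in enumerate(_R_NAMES):
            v[IV_R + i] = getattr(self, n)
        for i, n in enumerate(_C_NAMES):
            v[IV_C + i] = getattr(self, n)
        for i, c in enumerate(("sa", "sv", "pa", "pv")):
            v[IV_VUN + i] = getattr(self, f"V_un_{c}")
        v[IV_T] = self.T
        v[IV_VTOTAL] = self.V_total
        v[IV_GAMMA_MI:IV_GAMMA_MI + 5] = self.gamma_mi
        return v

    # -- generic name-based access ----------------------------------------
    def get(self, name: str) -> float:
        return getattr(self, name)

    def replace(self, **updates) -> "ModelParameters":
        return dataclasses.replace(self, **updates)

    def with_values(self, values: Dict[str, float]) -> "ModelParameters":
        return dataclasses.replace(self, **values)

    def to_dict(self) -> Dict[str, float]:
        d = dataclasses.asdict(self)
        d["gamma_mi"] = list(self.gamma_mi)
        return d

    @classmethod
    def from_dict(cls, d: Dict) -> "ModelParameters":
        d = dict(d)
        if "gamma_mi" in d:
            d["gamma_mi"] = tuple(d["gamma_mi"])
        return cls(**d)

    def save(self, path) -> None:
        path = str(path)
        d = self.to_dict()
        if path.endswith((".yml", ".yaml")):
            import yaml
            with open(path, "w") as fh:
                yaml.safe_dump(d, fh, sort_keys=False)
        else:
            with open(path, "w") as fh:
                json.dump(d, fh, indent=1)

    @classmethod
    def load(cls, path) -> "ModelParameters":
        path = str(path)
        if path.endswith((".yml", ".yaml")):
            import yaml
            with open(path) as fh:
                d = yaml.safe_load(fh)
        else:
            with open(path) as fh:
                d = json.load(fh)
        return cls.from_dict(d)


def nominal_parameters(summary: Optional[HemoSummary] = None,
                       T: float = 0.11,
                       wall_masses: Optional[Dict[str, float]] = None,
                       mouse: int = 1,
                       V_total: float = 1.15) -> ModelParameters:
    """Evaluate every nominal-value rule on a hemodynamic summary.

    ``wall_masses`` is a dict with keys ``la``, ``ra``, ``left_heart``
    (combined LV + septum mass, split 2/3 - 1/3), and ``rv`` in grams.
    ``mouse`` (1..3) selects the animal-specific reference-area and
    pericardial-volume brackets.
    """
    summary = summary if summary is not None else HemoSummary()
    summary.validate()
    if mouse not in (1, 2, 3):
        raise ValueError("mouse preset must be 1, 2, or 3")
    masses = dict(DEFAULT_WALL_MASSES)
    if wall_masses:
        masses.update(wall_masses)

    lv_free, septum = wall_volume_from_mass(masses["left_heart"],
                                            split_left_heart=True)
    mi = mouse - 1
    CO = summary.CO
    p = ModelParameters(
        tau_rise_a=0.0375 * T,
        tau_decay_a=0.005 * T,
        tau_sys_a=0.15 * T,
        tau_offset_a=0.18 * T,
        V_wall_la=wall_volume_from_mass(masses["la"]),
        V_wall_lv=lv_free,
        V_wall_ra=wall_volume_from_mass(masses["ra"]),
        V_wall_rv=wall_volume_from_mass(masses["rv"]),
        V_wall_s=septum,
        A_m_ref_la=_AMREF_BRACKETS["LA"][mi],
        A_m_ref_lv=_AMREF_BRACKETS["LV"][mi],
        A_m_ref_ra=_AMREF_BRACKETS["RA"][mi],
        A_m_ref_rv=_AMREF_BRACKETS["RV"][mi],
        A_m_ref_s=_AMREF_BRACKETS["S"][mi],
        V0_peri=_V0PERI_BRACKET[mi],
        k_peri=10.0,
        R_a_val=0.1 / CO,
        R_m_val=0.75 / CO,
        R_p_val=0.1 / CO,
        R_t_val=0.75 / CO,
        R_vc=(summary.P_sv_bar - summary.P_ra_min) / CO,
        R_pv=(summary.P_pv_bar - summary.P_la_min) / CO,
        R_sys=(summary.P_sa_max - summary.P_sys_cap) / CO,
        R_pulm=(summary.P_pa_max - summary.P_pulm_cap) / CO,
        C_sa=summary.V_sa / summary.P_sa_max,
        C_sv=summary.V_sv / summary.P_sv_bar,
        C_pa=summary.V_pa / summary.P_pa_max,
        C_pv=summary.V_pv / summary.P_pv_bar,
        V_un_sa=DEFAULT_UNSTRESSED["sa"],
        V_un_sv=DEFAULT_UNSTRESSED["sv"],
        V_un_pa=DEFAULT_UNSTRESSED["pa"],
        V_un_pv=DEFAULT_UNSTRESSED["pv"],
        T=T,
        V_total=V_total,
    )
    p.validate()
    return p
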