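"""Multi-compartment ODE models of CD8+ T cell control of B16F10 tumor growth.

The model tracks an anti-tumor immune response across three compartments:

* **lymph node** — adenovirus vector antigen (``LV``, RLU/mm^3) drives
  recruitment of naive CD8+ T cells and an age-structured differentiation
  chain ``TE1a -> TE1b -> TE1c -> TE1d`` (cells/mm^3) with factor-2 progeny
  bookkeeping at each division and a saturable immune-checkpoint brake,
* **blood** — naive cells ``TN`` and circulating effectors ``TE2``
  (cells/mm^3) that traffic between lymph node and tumor,
* **tumor microenvironment** — tumor mass split into MHC class I negative
  (``Cneg``) and positive (``Cpos``) volume fractions (mm^3),
  tumor-infiltrating lymphocytes (TILs, absolute cell counts), and the
  cytokines IFNG and TNFa (mol/mm^3) in a compartment whose volume changes
  with tumor burden, so the cytokine equations carry product-rule dilution
  terms.

Two variants are provided.  **V2** keeps a single TIL state ``TE3``.  **V3**
resolves TILs into four progressively deactivated states ``TE3a..TE3d``;
deactivation proceeds at a constitutive rate ``a4`` plus an IFNG-dependent
rate ``a5*IFNG/(k1+IFNG)``, and each step multiplies the cytotoxic rate and
IFNG output by a factor ``gamma`` (``c4b = gamma*c4a`` and so on).

Time is measured in days throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from numba import njit
from scipy.integrate import odeint

__all__ = [
    "B16SimError",
    "SchemaError",
    "ValidationError",
    "ConfigError",
    "IntegrationError",
    "CompartmentGeometry",
    "DEFAULT_GEOMETRY",
    "ParameterSet",
    "TreatmentProtocol",
    "Trajectory",
    "ANTIGENS",
    "VARIANTS",
    "free_parameter_names",
    "state_names",
    "build_parameters",
    "tumor_volume",
    "rhs_v2",
    "rhs_v3",
    "simulate",
]

# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class B16SimError(Exception):
    """Base class for all package errors."""


class SchemaError(B16SimError, KeyError):
    """A required name is missing or an unknown name was supplied."""


class ValidationError(B16SimError, ValueError):
    """A value violates a domain constraint (sign, range, ordering)."""


class ConfigError(B16SimError, ValueError):
    """A protocol or run configuration is internally inconsistent."""


class IntegrationError(B16SimError, RuntimeError):
    """The stiff integrator failed; ``last_time`` is the last good time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last good time t={last_time:g} d)")
        self.last_time = last_time


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompartmentGeometry:
    """Fixed compartment geometry (not calibrated).

    Attributes
    ----------
    Vb : float
        Blood volume, mm^3.  1200 mm^3 is forced by the adoptive-transfer
        dose conversion (3e6 cells <-> 2500 cells/mm^3) for a ~10 week
        old mouse.
    Vln : float
        Draining lymph node volume, mm^3.
    Vi : float
        Volume of a single T cell, mm^3.
    Vc : float
        Volume of a single tumor cell, mm^3 (converts implanted cell counts
        to the initial ``Cneg`` volume).
    eps : float
        Small stromal volume excluded from tumor and immune cells, mm^3.
        Keeps the total tumor volume strictly positive.
    """

    Vb: float = 1200.0
    Vln: float = 40.0
    Vi: float = 2e-7
    Vc: float = 1.5e-6
    eps: float = 1e-3

    def __post_init__(self):
        for name in ("Vb", "Vln", "Vi", "Vc", "eps"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"geometry field {name!r} must be > 0")
        if not self.Vi < self.Vb:
            raise ValidationError("single-cell volume Vi must be << blood volume Vb")


DEFAULT_GEOMETRY = CompartmentGeometry()

# ---------------------------------------------------------------------------
# Parameter bookkeeping
# ---------------------------------------------------------------------------

VARIANTS = ("V2", "V3")
ANTIGENS = ("hgp100", "hDCT")

#: shared kinetic rate constants, per day unless noted in the docstring table
SHARED_KINETIC = (
    "kd1",  # naive CD8 death
    "c2",   # LV-driven recruitment of naive cells to the lymph node
    "kg",   # LV half-saturation, RLU/mm^3
    "kp1",  # lymph-node proliferation
    "ka",   # checkpoint half-saturation, cells/mm^3
    "kd2",  # LV (vector antigen) decay
    "a12",  # lymph node -> blood egress
    "a21",  # blood -> lymph node return
    "kd3",  # blood effector death
    "a23",  # blood -> tumor infiltration
    "a32",  # tumor -> blood egress
    "kp2",  # tumor cell proliferation
    "c3",   # max MHC-I restoration rate
    "k1",   # IFNG half-saturation, mol/mm^3
    "kd4",  # tumor cell death (CTL-independent)
    "kc1",  # IFNG secretion, mol/cell/day
    "kd6",  # IFNG clearance
    "kc2",  # TNFa autocrine feedback max rate
    "k2",   # TNFa half-saturation, mol/mm^3
    "kc3",  # TNFa basal secretion
    "kd7",  # TNFa clearance
)

#: antigen-specific base names; one value per immunogen (hgp100, hDCT)
ANTIGEN_SPECIFIC = ("c4a", "kp3a", "kd5a")

MEASUREMENT = ("BG1", "BG2", "BG3", "beta1", "beta2", "beta3", "beta4", "beta5")

V3_ONLY = ("a4", "a5", "kp3b", "kd5b", "gamma")

INITIAL = ("TN0",)


def free_parameter_names(variant: str) -> tuple[str, ...]:
    """Canonical ordered tuple of calibrated parameter names.

    Exactly 36 names for V2 and 41 for V3.  Antigen-specific rates appear as
    ``c4a_hgp100``, ``c4a_hDCT`` etc.  The thymic production rate ``c1`` is
    never free: it is tied to ``kd1 * TN0`` so that naive CD8+ T cells sit at
    steady state before immunization.
    """
    if variant not in VARIANTS:
        raise SchemaError(f"unknown model variant {variant!r}; expected one of {VARIANTS}")
    names = list(SHARED_KINETIC)
    for base in ANTIGEN_SPECIFIC:
        for antigen in ANTIGENS:
            names.append(f"{base}_{antigen}")
    names.extend(MEASUREMENT)
    names.extend(INITIAL)
    if variant == "V3":
        names.extend(V3_ONLY)
    return tuple(names)


@dataclass(frozen=True)
class ParameterSet:
    """A complete, validated parameter table for one model variant.

    ``values`` maps every free parameter name of the variant to a
    non-negative float.  The derived thymic production rate is exposed as
    :attr:`c1` and is recomputed on any update, so it can never drift from
    ``kd1 * TN0``.
    """

    variant: str
    values: Mapping[str, float]

    @property
    def c1(self) -> float:
        return self.values["kd1"] * self.values["TN0"]

    def __getitem__(self, name: str) -> float:
        if name == "c1":
            return self.c1
        return self.values[name]

    def antigen_value(self, base: str, antigen: str) -> float:
        return self.values[f"{base}_{antigen}"]

    def replace(self, **updates: float) -> "ParameterSet":
        """Return a copy with named values replaced (revalidated)."""
        merged = dict(self.values)
        for name, value in updates.items():
            if name not in merged:
                raise SchemaError(f"unknown parameter {name!r} for variant {self.variant}")
            merged[name] = float(value)
        return build_parameters(merged, self.variant)

    def with_overrides(self, overrides: Mapping[str, float] | None) -> "ParameterSet":
        """Apply named multiplicative factors (``set:name`` entries assign).

        ``{"c3": 10.0}`` multiplies ``c3`` by 10; ``{"set:gamma": 1.0}``
        assigns ``gamma = 1`` (used e.g. to equalize the per-state cytotoxic
        rates ``c4a..c4d``).
        """
        if not overrides:
            return self
        updates: dict[str, float] = {}
        for key, factor in overrides.items():
            if key.startswith("set:"):
                updates[key[4:]] = float(factor)
            else:
                if key not in self.values:
                    raise SchemaError(f"unknown parameter {key!r} for variant {self.variant}")
                updates[key] = self.values[key] * float(factor)
        return self.replace(**updates)

    def pack(self, antigen: str, geom: CompartmentGeometry) -> np.ndarray:
        """Flatten to the dense vector consumed by the compiled RHS kernels."""
        if antigen not in ANTIGENS:
            raise SchemaError(f"unknown antigen {antigen!r}; expected one of {ANTIGENS}")
        v = self.values
        if self.variant == "V3":
            a4, a5 = v["a4"], v["a5"]
            kp3b, kd5b, gamma = v["kp3b"], v["kd5b"], v["gamma"]
        else:
            a4 = a5 = 0.0
            kp3b = v[f"kp3a_{antigen}"]
            kd5b = v[f"kd5a_{antigen}"]
            gamma = 1.0
        return np.array(
            [
                v["kd1"], self.c1, v["c2"], v["kg"], v["kp1"], v["ka"], v["kd2"],
                v["a12"], v["a21"], v["kd3"], v["a23"], v["a32"], v["kp2"],
                v["c3"], v["k1"], v["kd4"], v["kc1"], v["kd6"], v["kc2"],
                v["k2"], v["kc3"], v["kd7"],
                v[f"c4a_{antigen}"], v[f"kp3a_{antigen}"], v[f"kd5a_{antigen}"],
                a4, a5, kp3b, kd5b, gamma,
                geom.Vb, geom.Vln, geom.Vi, geom.eps,
            ],
            dtype=np.float64,
        )


def build_parameters(config: Mapping[str, float], variant: str) -> ParameterSet:
    """Validate a named-value table into a :class:`ParameterSet`.

    Raises :class:`SchemaError` for missing or unknown names and
    :class:`ValidationError` for negative values or ``gamma`` outside
    ``(0, 1]``.  The derived ``c1`` may be present in ``config`` only if it
    equals ``kd1 * TN0``; it is never stored as a free value.
    """
    expected = free_parameter_names(variant)
    config = dict(config)
    c1_given = config.pop("c1", None)
    missing = [n for n in expected if n not in config]
    if missing:
        raise SchemaError(f"missing parameter(s) for {variant}: {missing}")
    extra = [n for n in config if n not in expected]
    if extra:
        raise SchemaError(f"unknown parameter(s) for {variant}: {extra}")
    values: dict[str, float] = {}
    for name in expected:
        value = float(config[name])
        if not math.isfinite(value):
            raise ValidationError(f"parameter {name!r} must be finite, got {value!r}")
        if value < 0:
            raise ValidationError(f"parameter {name!r} must be non-negative, got {value!r}")
        values[name] = value
    if variant == "V3" and not 0.0 < values["gamma"] <= 1.0:
        raise ValidationError(f"gamma must lie in (0, 1], got {values['gamma']!r}")
    ps = ParameterSet(variant=variant, values=values)
    if c1_given is not None and not math.isclose(float(c1_given), ps.c1, rel_tol=1e-12):
        raise ValidationError(
            f"c1 is derived as kd1*TN0={ps.c1!r}; refusing inconsistent value {c1_given!r}"
        )
    return ps


# ---------------------------------------------------------------------------
# State layout
# ---------------------------------------------------------------------------

STATE_NAMES_V2 = (
    "TN", "TE1a", "TE1b", "TE1c", "TE1d", "LV", "TE2",
    "Cneg", "Cpos", "TE3", "IFNG", "TNFa",
)
STATE_NAMES_V3 = (
    "TN", "TE1a", "TE1b", "TE1c", "TE1d", "LV", "TE2",
    "Cneg", "Cpos", "TE3a", "TE3b", "TE3c", "TE3d", "IFNG", "TNFa",
)

#: initial value for unobserved states ("near zero")
NEAR_ZERO = 2e-16


def state_names(variant: str) -> tuple[str, ...]:
    if variant == "V2":
        return STATE_NAMES_V2
    if variant == "V3":
        return STATE_NAMES_V3
    raise SchemaError(f"unknown model variant {variant!r}")


def _variant_from_state(state: Sequence[float]) -> str:
    n = len(state)
    if n == len(STATE_NAMES_V2):
        return "V2"
    if n == len(STATE_NAMES_V3):
        return "V3"
    raise ValidationError(f"state vector of length {n} matches neither V2 (12) nor V3 (15)")


def tumor_volume(state: Sequence[float], geom: CompartmentGeometry) -> float:
    """Total tumor compartment volume ``Vt = eps + Cneg + Cpos + Vi*sum(TE3x)``.

    Strictly positive for any admissible state because ``eps > 0``.
    """
    state = np.asarray(state, dtype=float)
    variant = _variant_from_state(state)
    til = state[9] if variant == "V2" else state[9:13].sum()
    return float(geom.eps + state[7] + state[8] + geom.Vi * til)


# ---------------------------------------------------------------------------
# Compiled right-hand sides (odeint convention: f(y, t, p))
# ---------------------------------------------------------------------------
# Packed parameter vector layout (see ParameterSet.pack):
#  0 kd1   1 c1    2 c2    3 kg    4 kp1   5 ka    6 kd2   7 a12   8 a21
#  9 kd3  10 a23  11 a32  12 kp2  13 c3   14 k1   15 kd4  16 kc1  17 kd6
# 18 kc2  19 k2   20 kc3  21 kd7  22 c4a  23 kp3a 24 kd5a 25 a4   26 a5
# 27 kp3b 28 kd5b 29 gamma 30 Vb  31 Vln  32 Vi   33 eps


@njit(cache=True, error_model="numpy")
def _rhs_v2_nb(y, t, pp):  # pragma: no cover - exercised through wrappers
    TN, TE1a, TE1b, TE1c, TE1d, LV, TE2, Cn, Cp, TE3, IFNG, TNFa = (
        y[0], y[1], y[2], y[3], y[4], y[5], y[6], y[7], y[8], y[9], y[10], y[11]
    )
    kd1 = pp[0]; c1 = pp[1]; c2 = pp[2]; kg = pp[3]; kp1 = pp[4]; ka = pp[5]
    kd2 = pp[6]; a12 = pp[7]; a21 = pp[8]; kd3 = pp[9]; a23 = pp[10]
    a32 = pp[11]; kp2 = pp[12]; c3 = pp[13]; k1 = pp[14]; kd4 = pp[15]
    kc1 = pp[16]; kd6 = pp[17]; kc2 = pp[18]; k2 = pp[19]; kc3 = pp[20]
    kd7 = pp[21]; c4a = pp[22]; kp3a = pp[23]; kd5a = pp[24]
    Vb = pp[30]; Vln = pp[31]; Vi = pp[32]; eps = pp[33]

    H = LV / (LV + kg)                       # antigen saturation
    F = 1.0 - TE1d * TE1d / (ka * ka + TE1d * TE1d)  # checkpoint brake
    g = kp1 * H * F
    Vt = eps + Cn + Cp + Vi * TE3
    hillI = IFNG / (k1 + IFNG)

    out = np.empty(12)
    out[0] = c1 - kd1 * TN - c2 * TN * H
    out[1] = c2 * TN * (Vb / Vln) * H - g * TE1a
    out[2] = 2.0 * g * TE1a - g * TE1b
    out[3] = 2.0 * g * TE1b - g * TE1c
    out[4] = 2.0 * g * TE1c + g * TE1d - a12 * TE1d + a21 * TE2 * (Vb / Vln)
    out[5] = -kd2 * LV
    out[6] = (a12 * TE1d * (Vln / Vb) - a21 * TE2 - kd3 * TE2 - a23 * TE2
              + a32 * (Cn / Vt) * TE3 / Vb)
    kill = c4a * TE3 * Cp / Vt
    out[7] = kp2 * Cn + 2.0 * kp2 * Cp - c3 * hillI * Cn - kd4 * Cn
    out[8] = c3 * hillI * Cn - kp2 * Cp - kd4 * Cp - kill
    out[9] = (a23 * TE2 * Vb - a32 * TE3 * (Cn / Vt)
              + kp3a * TE3 * (Cp / Vt) - kd5a * TE3)
    dVt = out[7] + out[8] + Vi * out[9]
    out[10] = kc1 * TE3 / Vt - kd6 * IFNG - (IFNG / Vt) * dVt
    out[11] = ((kc2 * TNFa / (k2 + TNFa) + kc3) * TE3 / Vt
               - kd7 * TNFa - (TNFa / Vt) * dVt)
    return out


@njit(cache=True, error_model="numpy")
def _rhs_v3_nb(y, t, pp):  # pragma: no cover - exercised through wrappers
    TN, TE1a, TE1b, TE1c, TE1d, LV, TE2, Cn, Cp = (
        y[0], y[1], y[2], y[3], y[4], y[5], y[6], y[7], y[8]
    )
    T3a, T3b, T3c, T3d, IFNG, TNFa = y[9], y[10], y[11], y[12], y[13], y[14]
    kd1 = pp[0]; c1 = pp[1]; c2 = pp[2]; kg = pp[3]; kp1 = pp[4]; ka = pp[5]
    kd2 = pp[6]; a12 = pp[7]; a21 = pp[8]; kd3 = pp[9]; a23 = pp[10]
    a32 = pp[11]; kp2 = pp[12]; c3 = pp[13]; k1 = pp[14]; kd4 = pp[15]
    kc1 = pp[16]; kd6 = pp[17]; kc2 = pp[18]; k2 = pp[19]; kc3 = pp[20]
    kd7 = pp[21]; c4a = pp[22]; kp3a = pp[23]; kd5a = pp[24]; a4 = pp[25]
    a5 = pp[26]; kp3b = pp[27]; kd5b = pp[28]; gam = pp[29]
    Vb = pp[30]; Vln = pp[31]; Vi = pp[32]; eps = pp[33]

    H = LV / (LV + kg)
    F = 1.0 - TE1d * TE1d / (ka * ka + TE1d * TE1d)
    g = kp1 * H * F
    S = T3a + T3b + T3c + T3d
    W = T3a + gam * T3b + gam * gam * T3c + gam * gam * gam * T3d
    Vt = eps + Cn + Cp + Vi * S
    hillI = IFNG / (k1 + IFNG)
    D = a4 + a5 * hillI                      # per-state deactivation rate
    prolif = Cp / Vt

    out = np.empty(15)
    out[0] = c1 - kd1 * TN - c2 * TN * H
    out[1] = c2 * TN * (Vb / Vln) * H - g * TE1a
    out[2] = 2.0 * g * TE1a - g * TE1b
    out[3] = 2.0 * g * TE1b - g * TE1c
    out[4] = 2.0 * g * TE1c + g * TE1d - a12 * TE1d + a21 * TE2 * (Vb / Vln)
    out[5] = -kd2 * LV
    out[6] = (a12 * TE1d * (Vln / Vb) - a21 * TE2 - kd3 * TE2 - a23 * TE2
              + a32 * (Cn / Vt) * T3a / Vb)
    kill = c4a * W * Cp / Vt                 # c4b..c4d folded in via gamma
    out[7] = kp2 * Cn + 2.0 * kp2 * Cp - c3 * hillI * Cn - kd4 * Cn
    out[8] = c3 * hillI * Cn - kp2 * Cp - kd4 * Cp - kill
    out[9] = (a23 * TE2 * Vb - a32 * T3a * (Cn / Vt)
              + kp3a * T3a * prolif - kd5a * T3a - D * T3a)
    out[10] = D * T3a - D * T3b + kp3b * T3b * prolif - kd5b * T3b
    out[11] = D * T3b - D * T3c + kp3b * T3c * prolif - kd5b * T3c
    out[12] = D * T3c + kp3b * T3d * prolif - kd5b * T3d
    dVt = out[7] + out[8] + Vi * (out[9] + out[10] + out[11] + out[12])
    out[13] = kc1 * W / Vt - kd6 * IFNG - (IFNG / Vt) * dVt
    out[14] = ((kc2 * TNFa / (k2 + TNFa) + kc3) * S / Vt
               - kd7 * TNFa - (TNFa / Vt) * dVt)
    return out


def _check_state(state: np.ndarray, variant: str) -> None:
    if not np.all(np.isfinite(state)):
        names = state_names(variant)
        bad = [names[i] for i in np.flatnonzero(~np.isfinite(state))]
        raise ValidationError(f"non-finite state component(s): {bad}")


def rhs_v2(t: float, state: Sequence[float], p: ParameterSet,
           geom: CompartmentGeometry = DEFAULT_GEOMETRY,
           antigen: str = "hDCT") -> np.ndarray:
    """Time derivative of the 12 V2 states at time ``t`` (days).

    ``antigen`` selects which antigen-specific cytotoxic/TIL rates apply
    (immunization with hgp100 vs hDCT uses different ``c4a, kp3a, kd5a``).
    LV decay is always active here; production is zero (the immunization
    bolus is an instantaneous event handled by :func:`simulate`).
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (12,):
        raise ValidationError(f"V2 state must have 12 components, got {y.shape}")
    _check_state(y, "V2")
    return np.asarray(_rhs_v2_nb(y, float(t), p.pack(antigen, geom)))


def rhs_v3(t: float, state: Sequence[float], p: ParameterSet,
           geom: CompartmentGeometry = DEFAULT_GEOMETRY,
           antigen: str = "hDCT") -> np.ndarray:
    """Time derivative of the 15 V3 states at time ``t`` (days)."""
    y = np.asarray(state, dtype=float)
    if y.shape != (15,):
        raise ValidationError(f"V3 state must have 15 components, got {y.shape}")
    _check_state(y, "V3")
    if p.variant != "V3":
        raise SchemaError("rhs_v3 requires a V3 ParameterSet")
    return np.asarray(_rhs_v3_nb(y, float(t), p.pack(antigen, geom)))


# ---------------------------------------------------------------------------
# Treatment protocols and simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TreatmentProtocol:
    """An in-silico experiment: implant, optional immunization, optional ACT.

    Attributes
    ----------
    immunogen : str
        ``"none"``, ``"hgp100"`` or ``"hDCT"``.  A non-``none`` immunogen
        places an instantaneous vector-antigen bolus ``LV <- LV0`` in the
        lymph node at ``immunization_day``.
    immunization_day : float
        Day of the adenovirus immunization (ignored when immunogen is none).
    LV0 : float
        Vector antigen bolus, RLU/mm^3 (default 1e5).
    implant_cells : float
        Number of tumor cells implanted at t=0; converted to
        ``Cneg(0) = implant_cells * Vc``.
    act_events : tuple of (day, cells)
        Adoptive cell transfers; each adds ``cells / Vb`` to the blood
        effector pool ``TE2`` instantaneously (lymph node bypassed).
    antigen : str or None
        Which antigen-specific parameter set the transferred/expanded T
        cells use.  Defaults to the immunogen; must be set explicitly for
        ACT-only protocols (pmel-1 cells -> ``"hgp100"``, DCT cells ->
        ``"hDCT"``).
    parameter_overrides : mapping
        Named multiplicative factors applied to the parameter table before
        simulation (``set:`` prefix assigns instead of multiplying).
    """

    immunogen: str = "none"
    immunization_day: float = 5.0
    LV0: float = 1e5
    implant_cells: float = 1e6
    act_events: tuple = ()
    antigen: str | None = None
    parameter_overrides: Mapping[str, float] | None = None

    def __post_init__(self):
        if self.immunogen not in ("none",) + ANTIGENS:
            raise ConfigError(f"unknown immunogen {self.immunogen!r}")
        if self.immunization_day < 0:
            raise ConfigError("immunization_day must be >= 0")
        if self.LV0 < 0:
            raise ConfigError("LV0 must be >= 0")
        if self.implant_cells < 0:
            raise ConfigError("implant_cells must be >= 0")
        days = [float(d) for d, _ in self.act_events]
        if any(d < 0 for d in days):
            raise ConfigError("ACT event days must be >= 0")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ConfigError("ACT event days must be strictly increasing")
        if any(c < 0 for _, c in self.act_events):
            raise ConfigError("ACT cell numbers must be >= 0")
        object.__setattr__(self, "act_events", tuple((float(d), float(c)) for d, c in self.act_events))

    @property
    def effective_antigen(self) -> str:
        """Antigen-specific parameter set in force for this protocol."""
        if self.antigen is not None:
            return self.antigen
        if self.immunogen != "none":
            return self.immunogen
        # untreated: no T cells ever appear, so the choice is inert
        return "hgp100"


@dataclass
class Trajectory:
    """Dense simulated trajectory of one protocol under one parameter set."""

    t: np.ndarray
    y: np.ndarray  # shape (n_times, n_states)
    variant: str
    protocol: TreatmentProtocol
    params: ParameterSet
    geom: CompartmentGeometry

    def series(self, name: str) -> np.ndarray:
        """Time series of one named state."""
        return self.y[:, state_names(self.variant).index(name)]

    def til_total(self) -> np.ndarray:
        """Total TIL count (absolute cells) across states."""
        if self.variant == "V2":
            return self.series("TE3")
        return self.y[:, 9:13].sum(axis=1)

    def vt(self) -> np.ndarray:
        """Total tumor compartment volume Vt(t), mm^3."""
        return (self.geom.eps + self.series("Cneg") + self.series("Cpos")
                + self.geom.Vi * self.til_total())

    def ct(self) -> np.ndarray:
        """Tumor cell volume Ct(t) = Cneg + Cpos, mm^3."""
        return self.series("Cneg") + self.series("Cpos")

    def interp(self, name_or_values, days) -> np.ndarray:
        """Linear interpolation of a state (or precomputed series) at ``days``."""
        days = np.asarray(days, dtype=float)
        if days.size and (days.min() < self.t[0] - 1e-9 or days.max() > self.t[-1] + 1e-9):
            raise ConfigError(
                f"requested day(s) outside trajectory span [{self.t[0]:g}, {self.t[-1]:g}]"
            )
        values = self.series(name_or_values) if isinstance(name_or_values, str) else name_or_values
        return np.interp(days, self.t, values)

    def to_frame(self):
        """Tidy export: columns time, species, value, units."""
        import pandas as pd

        units = {"LV": "RLU/mm^3", "Cneg": "mm^3", "Cpos": "mm^3",
                 "IFNG": "mol/mm^3", "TNFa": "mol/mm^3"}
        names = state_names(self.variant)
        records = []
        for j, name in enumerate(names):
            unit = units.get(name, "cells" if name.startswith("TE3") else "cells/mm^3")
            for i, t in enumerate(self.t):
                records.append((float(t), name, float(self.y[i, j]), unit))
        return pd.DataFrame(records, columns=["time", "species", "value", "units"])


def _initial_state(variant: str, protocol: TreatmentProtocol,
                   p: ParameterSet, geom: CompartmentGeometry) -> np.ndarray:
    n = len(state_names(variant))
    y0 = np.full(n, NEAR_ZERO)
    y0[0] = p["TN0"]
    y0[7] = max(protocol.implant_cells * geom.Vc, NEAR_ZERO)
    return y0


def _event_jumps(protocol: TreatmentProtocol, geom: CompartmentGeometry):
    """Ordered (time, state_index, mode, value) jumps for a protocol."""
    jumps: list[tuple[float, int, str, float]] = []
    if protocol.immunogen != "none":
        jumps.append((float(protocol.immunization_day), 5, "set", protocol.LV0))
    for day, cells in protocol.act_events:
        jumps.append((float(day), 6, "add", cells / geom.Vb))
    jumps.sort(key=lambda j: j[0])
    return jumps


def _integrate_packed(variant: str, pp: np.ndarray, y0: np.ndarray,
                      times: np.ndarray, jumps, rtol: float, atol: float,
                      mxstep: int = 10000) -> np.ndarray:
    """Piecewise LSODA integration with instantaneous state jumps.

    Returns the state matrix on ``times``; values at an event time are
    post-event (right-continuous).  Low-level: no validation, used in the
    calibration hot path.
    """
    func = _rhs_v2_nb if variant == "V2" else _rhs_v3_nb
    t0, t_end = times[0], times[-1]
    event_ts = [tj for tj, *_ in jumps]
    # events strictly inside (t0, t_end]; the final grid point is never
    # duplicated as a segment boundary (a jump there applies exactly once)
    bounds = sorted({t for t in event_ts if t0 < t < t_end - 1e-12})
    out = np.empty((times.size, y0.size))
    y = y0.copy()
    # jumps exactly at the start apply before integration
    for tj, idx, mode, val in jumps:
        if tj <= t0:
            y[idx] = val if mode == "set" else y[idx] + val
    pos = 0
    seg_start = t0
    for seg_end in bounds + [t_end]:
        n_inside = 0
        while pos + n_inside < times.size and times[pos + n_inside] <= seg_end + 1e-12:
            n_inside += 1
        ts = np.concatenate(([seg_start], times[pos:pos + n_inside], [seg_end]))
        keep = np.concatenate(([False], np.ones(n_inside, bool), [False]))
        # drop duplicated knots (monotonicity required by lsoda)
        uniq = np.concatenate(([True], np.diff(ts) > 1e-12))
        ts_u = ts[uniq]
        if ts_u.size > 1:
            import warnings as _warnings
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                sol, info = odeint(func, y, ts_u, args=(pp,), rtol=rtol,
                                   atol=atol, mxstep=mxstep, full_output=True,
                                   printmessg=False)
            if info["message"] != "Integration successful." or not np.all(np.isfinite(sol)):
                raise IntegrationError("stiff integration failed", float(seg_start))
            # scatter solution rows back onto the original knot list
            full = np.empty((ts.size, y.size))
            full[uniq] = sol
            dup_src = np.flatnonzero(~uniq)
            for i in dup_src:
                full[i] = full[i - 1]
            y = full[-1].copy()
        else:
            full = np.tile(y, (ts.size, 1))
        if n_inside:
            out[pos:pos + n_inside] = full[keep]
            pos += n_inside
        # apply jumps scheduled at this boundary, then overwrite any output
        # row that coincides with the event time (right-continuity)
        applied = False
        for tj, idx, mode, val in jumps:
            if abs(tj - seg_end) <= 1e-12 and tj > t0:
                y[idx] = val if mode == "set" else y[idx] + val
                applied = True
        if applied and pos > 0 and abs(times[pos - 1] - seg_end) <= 1e-12:
            out[pos - 1] = y
        y = np.maximum(y, 0.0)  # scrub integrator-level negative dust
        seg_start = seg_end
    return out


def simulate(variant: str, p: ParameterSet, geom: CompartmentGeometry,
             protocol: TreatmentProtocol, t_grid: Sequence[float],
             rtol: float = 1e-6, atol: float = 1e-9) -> Trajectory:
    """Integrate a model variant under a treatment protocol.

    The stiff system is integrated piecewise between protocol events with
    LSODA; at the immunization day ``LV`` is set to ``LV0`` discontinuously
    and each adoptive transfer adds ``cells/Vb`` to ``TE2`` discontinuously.
    Initial condition: ``TN = TN0``, ``Cneg = implant_cells*Vc``, every other
    state at 2e-16.  Values reported at an event day are post-event.
    """
    if variant not in VARIANTS:
        raise SchemaError(f"unknown model variant {variant!r}")
    if p.variant != variant:
        raise SchemaError(f"parameter set is for {p.variant}, requested {variant}")
    times = np.asarray(t_grid, dtype=float)
    if times.ndim != 1 or times.size < 2 or np.any(np.diff(times) <= 0):
        raise ConfigError("t_grid must be a strictly increasing 1-D sequence")
    p_eff = p.with_overrides(protocol.parameter_overrides)
    jumps = _event_jumps(protocol, geom)
    for tj, *_ in jumps:
        if tj < times[0] - 1e-12 or tj > times[-1] + 1e-12:
            raise ConfigError(
                f"protocol event at day {tj:g} outside t_grid span "
                f"[{times[0]:g}, {times[-1]:g}]"
            )
    pp = p_eff.pack(protocol.effective_antigen, geom)
    y0 = _initial_state(variant, protocol, p_eff, geom)
    y = _integrate_packed(variant, pp, y0, times, jumps, rtol, atol)
    return Trajectory(t=times, y=y, variant=variant, protocol=protocol,
                      params=p_eff, geom=geom)
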