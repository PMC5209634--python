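"""Synthetic calibration data with the study's design and noise structure.

The original calibration set pooled 448 measurements across three treatment
groups of C57Bl/6 mice — untreated, rHuAd5-hgp100 and rHuAd5-hDCT
immunization on day 5 after subcutaneous implantation of 1e6 B16F10 cells —
over eight measurands between days 5 and 20 (TIL counts only on days 10 and
15).  The raw measurements were never deposited, so this module generates
datasets of the same shape from a known ground-truth parameter table: every
downstream stage (calibration, convergence diagnostics, model comparison,
scenario simulation) is exercised against data whose generating process is
known exactly.

The canonical replicate breakdown (only the 448 total is recorded in the
source studies) is:

=============  =================  =====================  ====  =====
group          measurand          days                   reps  count
=============  =================  =====================  ====  =====
untreated      tumor_volume       5 6 8 10 12 14 16 18    4     32
untreated      3 x mRNA           5 6 8 10 12 14 16 18    3     72
rHuAd5-hgp100  7 measurands       5 6 8 10 12 14 16 18    3    168
rHuAd5-hDCT    7 measurands       5 6 8 10 12 14 16 18    3    168
rHuAd5-hDCT    til_count          10 15                   4      8
=============  =================  =====================  ====  =====

total 448.  "7 measurands" = luciferase, ln_activated_cd8, blood_percent,
tumor_volume and the three qRT-PCR series; the untreated group has only
tumor volume and qRT-PCR (its vector/T cell readouts are structurally zero).

Replicate scatter is multiplicative lognormal for strictly positive
measurands and additive Gaussian on the percent scale for the blood
readout.  A day-8 multiplicative shift can be injected into the untreated
qRT-PCR block to emulate the outlier block found (and removed by Student's
t-test) in the original data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .model_core import (
    CompartmentGeometry,
    DEFAULT_GEOMETRY,
    ConfigError,
    ParameterSet,
    TreatmentProtocol,
    ValidationError,
    build_parameters,
    simulate,
)
from .observables import MEASURAND_UNITS, MEASURANDS, POSITIVE_MEASURANDS, predict_series

__all__ = [
    "GROUPS",
    "MRNA_MEASURANDS",
    "ObservationDesign",
    "ObservationSet",
    "NoiseModel",
    "true_parameters",
    "default_design",
    "group_protocol",
    "generate",
    "flag_day8_outliers",
]

GROUPS = ("untreated", "hgp100", "hDCT")
MRNA_MEASURANDS = ("tcra_mrna", "ifng_mrna", "tnfa_mrna")

_STANDARD_DAYS = (5.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0, 18.0)
_TREATED_MEASURANDS = (
    "luciferase", "ln_activated_cd8", "blood_percent", "tumor_volume",
    "tcra_mrna", "ifng_mrna", "tnfa_mrna",
)


# ---------------------------------------------------------------------------
# Ground-truth parameter tables
# ---------------------------------------------------------------------------
# The cytotoxic rates c4a are the published posterior medians
# (mm^6 cell^-1 day^-1): V3 0.0038 / 118.4 and V2 0.0084 / 101.8 for
# hgp100 / hDCT.  Everything else is a fixed physiological choice producing
# the study's qualitative dynamics: exponential untreated growth to a few
# hundred mm^3 by day ~20, a blood effector peak of tens of percent around
# day 11-13, hDCT (but not hgp100) tumor control, and an IFNG transcript
# peak that precedes the TCRa peak under V3 deactivation.

_TRUE_SHARED = {
    "kd1": 0.1,     # /day naive CD8 death
    "c2": 3.0,      # /day recruitment at saturating antigen
    "kg": 100.0,    # RLU/mm^3 antigen half-saturation
    "kp1": 3.0,     # /day lymph-node proliferation
    "ka": 5000.0,   # cells/mm^3 checkpoint half-saturation
    "kd2": 0.7,     # /day vector antigen decay
    "a12": 1.0,     # /day lymph node -> blood
    "a21": 0.05,    # /day blood -> lymph node
    "kd3": 0.3,     # /day blood effector death
    "a23": 0.001,   # /day blood -> tumor
    "a32": 0.1,     # /day tumor -> blood
    "kp2": 0.35,    # /day tumor proliferation
    "c3": 0.3,      # /day max MHC-I restoration
    "k1": 3e-15,    # mol/mm^3 IFNG half-saturation (saturated when TILs present)
    "kd4": 0.1,     # /day CTL-independent tumor death
    "kc1": 5e-15,   # mol/cell/day IFNG secretion
    "kd6": 2.0,     # /day IFNG clearance
    "kc2": 2e-15,   # mol/cell/day TNFa feedback max
    "k2": 5e-14,    # mol/mm^3 TNFa half-saturation
    "kc3": 5e-16,   # mol/cell/day TNFa basal secretion
    "kd7": 2.0,     # /day TNFa clearance
    "kp3a_hgp100": 0.4,    # mm^3/day TIL proliferation, antigen-sparse
    "kp3a_hDCT": 3.0,      # mm^3/day TIL proliferation, antigen-dense
    "kd5a_hgp100": 0.4,    # /day TIL death, antigen-sparse
    "kd5a_hDCT": 2.0,      # /day TIL death, antigen-dense
    "BG1": 0.5, "BG2": 0.2, "BG3": 0.3,
    "beta1": 0.1, "beta2": 0.3, "beta3": 5e13,
    "beta4": 1500.0,  # cells/mm^3 total blood CD8 for the percent readout
    "beta5": 0.01,
    "TN0": 3.0,       # cells/mm^3 antigen-specific naive CD8 at t=0
}

_TRUE_V3_EXTRA = {
    "c4a_hgp100": 0.0038,
    "c4a_hDCT": 118.4,
    "a4": 0.01,    # /day constitutive deactivation
    "a5": 2.0,     # /day IFNG-driven deactivation max
    "kp3b": 0.4,   # mm^3/day deactivated-TIL proliferation
    "kd5b": 0.6,   # /day deactivated-TIL death
    "gamma": 0.2,  # per-state killing / IFNG-output decay factor
}

_TRUE_V2_EXTRA = {
    "c4a_hgp100": 0.0084,
    "c4a_hDCT": 101.8,
}


def true_parameters(variant: str) -> ParameterSet:
    """The documented ground-truth table used by the default generator."""
    table = dict(_TRUE_SHARED)
    table.update(_TRUE_V3_EXTRA if variant == "V3" else _TRUE_V2_EXTRA)
    return build_parameters(table, variant)


# ---------------------------------------------------------------------------
# Observation design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ObservationDesign:
    """Slots of the measurement campaign: (group, measurand, day, replicates)."""

    slots: tuple  # of (group, measurand, day, n_replicates)

    def __post_init__(self):
        for group, measurand, day, reps in self.slots:
            if group not in GROUPS:
                raise ConfigError(f"unknown group {group!r}")
            if measurand not in MEASURANDS:
                raise ConfigError(f"unknown measurand {measurand!r}")
            if reps < 0:
                raise ConfigError("replicate counts must be >= 0")

    @property
    def total_count(self) -> int:
        return int(sum(reps for *_, reps in self.slots))

    @property
    def groups(self) -> tuple:
        return tuple(dict.fromkeys(g for g, *_ in self.slots))

    def measurand_days(self, group: str) -> dict[str, np.ndarray]:
        """Sorted unique observation days per measurand of one group."""
        out: dict[str, list[float]] = {}
        for g, measurand, day, reps in self.slots:
            if g == group and reps > 0:
                out.setdefault(measurand, []).append(float(day))
        return {m: np.array(sorted(set(d))) for m, d in out.items()}

    def restrict(self, groups: Iterable[str] | None = None,
                 measurands: Iterable[str] | None = None) -> "ObservationDesign":
        """Sub-design keeping only the named groups/measurands."""
        groups = set(groups) if groups is not None else set(GROUPS)
        measurands = set(measurands) if measurands is not None else set(MEASURANDS)
        kept = tuple(s for s in self.slots if s[0] in groups and s[1] in measurands)
        return ObservationDesign(slots=kept)

    def with_replicates(self, n: int) -> "ObservationDesign":
        return ObservationDesign(slots=tuple((g, m, d, n) for g, m, d, _ in self.slots))


def default_design() -> ObservationDesign:
    """The canonical 448-record design (table in the module docstring)."""
    slots: list[tuple] = []
    for day in _STANDARD_DAYS:
        slots.append(("untreated", "tumor_volume", day, 4))
        for m in MRNA_MEASURANDS:
            slots.append(("untreated", m, day, 3))
    for group in ("hgp100", "hDCT"):
        for day in _STANDARD_DAYS:
            for m in _TREATED_MEASURANDS:
                slots.append((group, m, day, 3))
    for day in (10.0, 15.0):
        slots.append(("hDCT", "til_count", day, 4))
    return ObservationDesign(slots=tuple(slots))


# ---------------------------------------------------------------------------
# Observation sets and noise
# ---------------------------------------------------------------------------


@dataclass
class ObservationSet:
    """Tidy grouped time-series measurements with replicate structure.

    ``frame`` columns: group, measurand, day, replicate, value, units.
    ``provenance`` records the generating seed and true parameters when the
    set is synthetic.
    """

    frame: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        required = ["group", "measurand", "day", "replicate", "value", "units"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"observation frame missing column(s) {missing}")
        if (self.frame["value"] < 0).any():
            raise ValidationError("observation values must be non-negative")

    def __len__(self) -> int:
        return len(self.frame)

    def subset(self, group: str | None = None,
               measurand: str | None = None) -> pd.DataFrame:
        df = self.frame
        if group is not None:
            df = df[df["group"] == group]
        if measurand is not None:
            df = df[df["measurand"] == measurand]
        return df

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, provenance: dict | None = None) -> "ObservationSet":
        return cls(frame=pd.read_csv(path), provenance=provenance or {})


@dataclass(frozen=True)
class NoiseModel:
    """Replicate-scatter model of the assays.

    ``lognormal_sigma`` is the standard deviation of the natural-log
    multiplicative error for strictly positive measurands (volumes, RLU,
    transcript levels, counts); ``percent_sigma`` is the additive Gaussian
    standard deviation, in percentage points, for the blood percent readout.
    ``outlier_factor`` > 1 turns on a multiplicative day-8 shift applied to
    the untreated qRT-PCR block.
    """

    lognormal_sigma: float = 0.3
    percent_sigma: float = 2.0
    outlier_factor: float | None = None
    outlier_group: str = "untreated"
    outlier_day: float = 8.0

    def __post_init__(self):
        if self.lognormal_sigma <= 0 or self.percent_sigma <= 0:
            raise ValidationError("noise sigmas must be > 0")


def group_protocol(group: str) -> TreatmentProtocol:
    """The calibration protocol of one treatment group.

    All groups implant 1e6 B16F10 cells at day 0; the immunized groups
    receive the adenovirus bolus (LV = 1e5 RLU/mm^3) on day 5.
    """
    if group == "untreated":
        return TreatmentProtocol(immunogen="none", implant_cells=1e6)
    if group in ("hgp100", "hDCT"):
        return TreatmentProtocol(immunogen=group, immunization_day=5.0,
                                 LV0=1e5, implant_cells=1e6)
    raise ConfigError(f"unknown group {group!r}")


def _grid_for(design_days: Iterable[float], horizon: float | None = None) -> np.ndarray:
    days = sorted(set(float(d) for d in design_days))
    t_end = max(days + [horizon or 0.0, 5.0])
    base = np.arange(0.0, t_end + 0.25, 0.25)
    return np.union1d(base, np.asarray(days))


def generate(p_true: ParameterSet, variant: str, design: ObservationDesign,
             noise: NoiseModel, seed: int,
             geom: CompartmentGeometry = DEFAULT_GEOMETRY) -> ObservationSet:
    """Simulate the three-group study and draw noisy replicate observations.

    Deterministic under a fixed seed.  With ``noise.outlier_factor`` set,
    the untreated day-8 qRT-PCR block is multiplied by that factor after
    noise is applied, emulating the outlier block of the original data.
    """
    if p_true.variant != variant:
        raise ConfigError(f"parameter set is for {p_true.variant}, requested {variant}")
    rng = np.random.default_rng(seed)
    records = []
    for group in design.groups:
        day_map = design.measurand_days(group)
        if not day_map:
            continue
        all_days = [d for days in day_map.values() for d in days]
        grid = _grid_for(all_days)
        traj = simulate(variant, p_true, geom, group_protocol(group), grid)
        pred = {m: dict(zip(days, traj.interp(predict_series(traj, p_true, m), days)))
                for m, days in day_map.items()}
        for g, measurand, day, reps in design.slots:
            if g != group:
                continue
            mu = pred[measurand][float(day)]
            for r in range(int(reps)):
                if measurand in POSITIVE_MEASURANDS:
                    value = mu * np.exp(noise.lognormal_sigma * rng.standard_normal())
                else:
                    value = np.clip(mu + noise.percent_sigma * rng.standard_normal(),
                                    0.0, 100.0)
                if (noise.outlier_factor is not None
                        and g == noise.outlier_group
                        and measurand in MRNA_MEASURANDS
                        and float(day) == noise.outlier_day):
                    value *= noise.outlier_factor
                records.append((g, measurand, float(day), r, float(value),
                                MEASURAND_UNITS[measurand]))
    frame = pd.DataFrame(records, columns=["group", "measurand", "day",
                                           "replicate", "value", "units"])
    provenance = {
        "seed": int(seed),
        "variant": variant,
        "true_parameters": dict(p_true.values),
        "noise": {"lognormal_sigma": noise.lognormal_sigma,
                  "percent_sigma": noise.percent_sigma,
                  "outlier_factor": noise.outlier_factor},
    }
    return ObservationSet(frame=frame, provenance=provenance)


def flag_day8_outliers(obs: ObservationSet, alpha: float = 1e-3,
                       day: float = 8.0) -> tuple[ObservationSet, float]:
    """Test and optionally remove the untreated day-8 qRT-PCR block.

    A two-sided two-sample Student's t-test with pooled variance compares
    the untreated day-8 values of the three transcript measurands, pooled
    as one sample, against the untreated values from all other days.  If
    ``p < alpha`` the day-8 untreated qRT-PCR records are removed.

    Returns the (possibly filtered) observation set and the p-value.
    """
    df = obs.frame
    mask_qpcr = (df["group"] == "untreated") & df["measurand"].isin(MRNA_MEASURANDS)
    block = df[mask_qpcr]
    day8 = block[block["day"] == day]["value"].to_numpy()
    others = block[block["day"] != day]["value"].to_numpy()
    if day8.size < 2 or others.size < 2:
        raise ValidationError(
            "day-8 outlier test needs >= 2 values on day 8 and >= 2 on other days"
        )
    t_stat, p_value = stats.ttest_ind(day8, others, equal_var=True)
    if p_value < alpha:
        keep = ~(mask_qpcr & (df["day"] == day))
        filtered = ObservationSet(frame=df[keep].reset_index(drop=True),
                                  provenance=dict(obs.provenance,
                                                  day8_outliers_removed=True,
                                                  day8_p_value=float(p_value)))
        return filtered, float(p_value)
    return obs, float(p_value)
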