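"""Map model trajectories onto the eight experimental measurands.

The calibration data are indirect: luciferase imaging of vector antigen,
flow cytometry of activated CD8+ T cells in lymph node and blood, caliper
tumor volumes, qRT-PCR of TCRa/IFNG/TNFa transcripts in tumor homogenate,
and TIL counts.  Each qRT-PCR readout is a linear map of model species with
an additive assay background (``BG1..BG3``) and scale (``beta1..beta3``);
the blood readout is a saturating percent-of-total-CD8 fraction with a free
total-CD8 scale ``beta4``; the lymph node readout is a linear scale
``beta5`` on the summed ``TE1`` states.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .model_core import (
    CompartmentGeometry,
    DEFAULT_GEOMETRY,
    ParameterSet,
    SchemaError,
    Trajectory,
    tumor_volume,
)

__all__ = [
    "MEASURANDS",
    "MEASURAND_UNITS",
    "PredictedSeries",
    "mrna_readout",
    "blood_percent",
    "predict_series",
    "observe",
]

MEASURANDS = (
    "luciferase",
    "ln_activated_cd8",
    "blood_percent",
    "tumor_volume",
    "tcra_mrna",
    "ifng_mrna",
    "tnfa_mrna",
    "til_count",
)

MEASURAND_UNITS: Mapping[str, str] = {
    "luciferase": "RLU/mm^3",
    "ln_activated_cd8": "a.u.",
    "blood_percent": "%",
    "tumor_volume": "mm^3",
    "tcra_mrna": "rel. expr.",
    "ifng_mrna": "rel. expr.",
    "tnfa_mrna": "rel. expr.",
    "til_count": "cells",
}

#: measurands modelled with multiplicative (lognormal) replicate scatter;
#: blood_percent is additive-Gaussian on the percent scale.
POSITIVE_MEASURANDS = tuple(m for m in MEASURANDS if m != "blood_percent")


@dataclass(frozen=True)
class PredictedSeries:
    """A noise-free model prediction for one (group, measurand) pair."""

    group: str
    measurand: str
    times: np.ndarray
    values: np.ndarray

    @property
    def units(self) -> str:
        return MEASURAND_UNITS[self.measurand]


def _til_states(state: np.ndarray, variant: str) -> np.ndarray:
    return state[..., 9:10] if variant == "V2" else state[..., 9:13]


def mrna_readout(kind: str, state: Sequence[float], p: ParameterSet,
                 variant: str, geom: CompartmentGeometry = DEFAULT_GEOMETRY) -> float:
    """qRT-PCR readout (relative expression) for a single model state.

    * ``tcra``: BG1 + beta1 * sum(TE3x) / Vt  — transcript abundance tracks
      total TIL density.
    * ``ifng``: BG2 + beta2 * (TE3a + g*TE3b + g^2*TE3c + g^3*TE3d) / Vt —
      deactivated states produce progressively less IFNG (V2: single state).
    * ``tnfa``: BG3 + beta3 * (kc2*TNFa/(k2+TNFa) + kc3) * sum(TE3x) / Vt —
      tracks the instantaneous secretion rate including autocrine feedback.
    """
    state = np.asarray(state, dtype=float)
    vt = tumor_volume(state, geom)
    til = _til_states(state, variant)
    if kind == "tcra":
        return float(p["BG1"] + p["beta1"] * til.sum() / vt)
    if kind == "ifng":
        if variant == "V3":
            g = p["gamma"]
            w = til[0] + g * til[1] + g * g * til[2] + g ** 3 * til[3]
        else:
            w = til.sum()
        return float(p["BG2"] + p["beta2"] * w / vt)
    if kind == "tnfa":
        tnfa = state[-1]
        rate = p["kc2"] * tnfa / (p["k2"] + tnfa) + p["kc3"]
        return float(p["BG3"] + p["beta3"] * rate * til.sum() / vt)
    raise SchemaError(f"unknown mRNA readout kind {kind!r}")


def blood_percent(state: Sequence[float], p: ParameterSet) -> float:
    """Activated CD8+ T cells in blood as percent of total CD8.

    ``100 * TE2 / (TE2 + beta4)`` where ``beta4`` is the (fixed-total)
    concentration of non-antigen-specific CD8+ T cells, clamped to [0, 100].
    """
    te2 = float(np.asarray(state, dtype=float)[6])
    return float(np.clip(100.0 * te2 / (te2 + p["beta4"]), 0.0, 100.0))


def predict_series(traj: Trajectory, p: ParameterSet, measurand: str) -> np.ndarray:
    """Noise-free measurand series on the trajectory's own time grid."""
    y = traj.y
    if measurand == "luciferase":
        return traj.series("LV").copy()
    if measurand == "ln_activated_cd8":
        return p["beta5"] * y[:, 1:5].sum(axis=1)
    if measurand == "blood_percent":
        te2 = traj.series("TE2")
        return np.clip(100.0 * te2 / (te2 + p["beta4"]), 0.0, 100.0)
    if measurand == "tumor_volume":
        return traj.ct()
    if measurand == "til_count":
        return traj.til_total()
    vt = traj.vt()
    til = _til_states(y, traj.variant)
    if measurand == "tcra_mrna":
        return p["BG1"] + p["beta1"] * til.sum(axis=1) / vt
    if measurand == "ifng_mrna":
        if traj.variant == "V3":
            g = p["gamma"]
            w = til @ np.array([1.0, g, g * g, g ** 3])
        else:
            w = til.sum(axis=1)
        return p["BG2"] + p["beta2"] * w / vt
    if measurand == "tnfa_mrna":
        tnfa = traj.series("TNFa")
        rate = p["kc2"] * tnfa / (p["k2"] + tnfa) + p["kc3"]
        return p["BG3"] + p["beta3"] * rate * til.sum(axis=1) / vt
    raise SchemaError(f"unknown measurand {measurand!r}")


def observe(traj: Trajectory, p: ParameterSet, design,
            group: str | None = None) -> list[PredictedSeries]:
    """Evaluate every designed measurand of a group on a trajectory.

    ``design`` is either an ``ObservationDesign`` (its slots for ``group``
    are used) or a plain mapping ``measurand -> days``.  Requested days must
    lie inside the trajectory span (linear interpolation in between grid
    points; the grids used by the pipeline always contain the design days).
    """
    if hasattr(design, "measurand_days"):
        if group is None:
            raise SchemaError("group is required when observing from an ObservationDesign")
        day_map = design.measurand_days(group)
    else:
        day_map = dict(design)
    out = []
    for measurand, days in day_map.items():
        series = predict_series(traj, p, measurand)
        days = np.asarray(days, dtype=float)
        values = traj.interp(series, days)
        out.append(PredictedSeries(group=group or "", measurand=measurand,
                                   times=days, values=values))
    return out
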