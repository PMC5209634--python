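"""Shared fixtures: parameter tables, synthetic data, and the two heavy
calibration runs (parameter recovery and model-evidence), which are session
scoped so the property tests and the end-to-end checks share one chain set.
"""

from __future__ import annotations

import numpy as np
import pytest

import b16sim as b
from b16sim import inference as inf
from b16sim import synthetic_data as sd


@pytest.fixture(scope="session")
def geom():
    return b.DEFAULT_GEOMETRY


@pytest.fixture(scope="session")
def p_v3():
    return sd.true_parameters("V3")


@pytest.fixture(scope="session")
def p_v2():
    return sd.true_parameters("V2")


@pytest.fixture(scope="session")
def hdct_traj(p_v3, geom):
    """Reference V3 trajectory of the day-5 hDCT immunization protocol."""
    grid = np.arange(0.0, 25.01, 0.25)
    return b.simulate("V3", p_v3, geom, sd.group_protocol("hDCT"), grid)


#: free parameters used by the desk-scale recovery run: the practically
#: identifiable subset (vector decay, lymph-node expansion, blood effector
#: death, tumor growth, blood-readout scale, MHC-I restoration)
RECOVERY_FREE = ["kd2", "kp1", "kd3", "kp2", "beta4", "c3"]
RECOVERY_BURN = 20_000


@pytest.fixture(scope="session")
def recovery_run(p_v3):
    """Calibrate V3 to synthetic V3 data: reduced design, 4 x 5e4 steps."""
    design = sd.default_design().restrict(groups=["untreated", "hDCT"])
    obs = sd.generate(p_v3, "V3", design, sd.NoiseModel(), seed=11)
    problem, archives = b.calibrate(
        "V3", obs, p_v3, chains=4, n_steps=50_000, learn_steps=10_000,
        free_names=RECOVERY_FREE, seed=1, bounds_halfwidth=2.0,
    )
    return problem, archives


#: desk-scale evidence run: V3-generated data with strong feedback-driven
#: TIL deactivation, fit by both variants with the TIL-compartment subset
EVIDENCE_FREE_V3 = ["c4a_hDCT", "kp3a_hDCT", "kd5a_hDCT", "kc1", "kd6",
                    "a5", "beta2"]
EVIDENCE_FREE_V2 = ["c4a_hDCT", "kp3a_hDCT", "kd5a_hDCT", "kc1", "kd6",
                    "beta2"]
EVIDENCE_BURN = 4_000


@pytest.fixture(scope="session")
def evidence_run(p_v3, p_v2):
    """Short V3-vs-V2 calibrations on data bearing the deactivation signature."""
    design = sd.default_design().restrict(
        groups=["hDCT"],
        measurands=["tumor_volume", "tcra_mrna", "ifng_mrna", "til_count"],
    )
    obs = sd.generate(p_v3, "V3", design, sd.NoiseModel(), seed=7)
    schedule = inf.AnnealSchedule(n_steps=1200, n_restarts=2)
    chains = {}
    for variant, base, free in (("V3", p_v3, EVIDENCE_FREE_V3),
                                ("V2", p_v2, EVIDENCE_FREE_V2)):
        _, chains[variant] = b.calibrate(
            variant, obs, base, chains=2, n_steps=10_000, learn_steps=3_000,
            free_names=free, seed=7, bounds_halfwidth=2.0,
            anneal_schedule=schedule,
        )
    return obs, chains
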