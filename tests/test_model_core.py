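"""Core model: parameter bookkeeping, right-hand sides, event integration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import b16sim as b
from b16sim import model_core as mc
from b16sim import synthetic_data as sd


# ---------------------------------------------------------------------------
# build_parameters
# ---------------------------------------------------------------------------


def test_free_parameter_counts():
    """The calibrated tables have exactly 36 (V2) and 41 (V3) entries."""
    assert len(b.free_parameter_names("V2")) == 36
    assert len(b.free_parameter_names("V3")) == 41
    p2 = sd.true_parameters("V2")
    p3 = sd.true_parameters("V3")
    assert len(p2.values) == 36
    assert len(p3.values) == 41


def test_c1_is_derived_from_kd1_and_tn0(p_v3):
    p = p_v3.replace(kd1=0.1, TN0=3.0)
    assert p.c1 == pytest.approx(0.3)
    # updates re-derive c1; it can never be set inconsistently
    assert p.replace(kd1=0.2).c1 == pytest.approx(0.6)
    table = dict(p.values, c1=999.0)
    with pytest.raises(mc.ValidationError):
        b.build_parameters(table, "V3")


@pytest.mark.parametrize("mutation, error", [
    ({"kc1": None}, mc.SchemaError),          # missing name
    ({"not_a_rate": 1.0}, mc.SchemaError),    # unknown name
    ({"kd3": -0.5}, mc.ValidationError),      # negative value
    ({"gamma": 1.5}, mc.ValidationError),     # gamma outside (0, 1]
])
def test_build_parameters_rejects_bad_tables(p_v3, mutation, error):
    table = dict(p_v3.values)
    for name, value in mutation.items():
        if value is None:
            del table[name]
        else:
            table[name] = value
    with pytest.raises(error):
        b.build_parameters(table, "V3")


def test_parameter_overrides_multiply_and_set(p_v3):
    p = p_v3.with_overrides({"c3": 10.0, "set:gamma": 1.0})
    assert p["c3"] == pytest.approx(10.0 * p_v3["c3"])
    assert p["gamma"] == 1.0
    with pytest.raises(mc.SchemaError):
        p_v3.with_overrides({"nope": 2.0})


# ---------------------------------------------------------------------------
# tumor_volume
# ---------------------------------------------------------------------------


def test_tumor_volume_direct_sum():
    geom = mc.CompartmentGeometry(eps=1e-3, Vi=2e-7)
    state = np.full(15, 0.0)
    state[7], state[8] = 10.0, 5.0
    state[9:13] = 0.25e6  # 1e6 TILs split over the four states
    assert b.tumor_volume(state, geom) == pytest.approx(15.201, rel=1e-12)
    assert b.tumor_volume(np.zeros(15), geom) == pytest.approx(geom.eps)


@settings(deadline=None, max_examples=50)
@given(st.lists(st.floats(0, 1e6), min_size=15, max_size=15))
def test_tumor_volume_matches_resummation(values):
    """Randomized states agree with an independent re-summation."""
    geom = mc.DEFAULT_GEOMETRY
    state = np.array(values)
    expected = geom.eps + state[7] + state[8] + geom.Vi * sum(state[9 + i] for i in range(4))
    assert b.tumor_volume(state, geom) == pytest.approx(expected, rel=1e-12)


# ---------------------------------------------------------------------------
# right-hand sides
# ---------------------------------------------------------------------------


def _base_state_v3(p, geom, **kwargs):
    y = np.zeros(15)
    y[0] = p["TN0"]
    names = mc.STATE_NAMES_V3
    for name, value in kwargs.items():
        y[names.index(name)] = value
    return y


def test_rhs_vaccine_free_steady_state(p_v3, p_v2, geom):
    """With no antigen and no tumor, TN = TN0 is a global fixed point."""
    y3 = _base_state_v3(p_v3, geom)
    assert np.allclose(b.rhs_v3(0.0, y3, p_v3, geom), 0.0, atol=1e-14)
    y2 = np.zeros(12)
    y2[0] = p_v2["TN0"]
    assert np.allclose(b.rhs_v2(0.0, y2, p_v2, geom), 0.0, atol=1e-14)


def test_rhs_untreated_exponential_growth_limit(p_v3, geom):
    """Tumor alone grows at kp2 - kd4; everything else stays put."""
    v0 = 7.5
    y = _base_state_v3(p_v3, geom, Cneg=v0)
    dy = b.rhs_v3(0.0, y, p_v3, geom)
    expected = (p_v3["kp2"] - p_v3["kd4"]) * v0
    assert dy[7] == pytest.approx(expected, rel=1e-12)
    mask = np.ones(15, bool)
    mask[7] = False
    assert np.allclose(dy[mask], 0.0, atol=1e-14)


def test_rhs_v3_reduces_to_v2_pointwise(p_v3, p_v2, geom):
    """With deactivation off and tied rates, the TE3a equation is V2's TE3."""
    table = dict(p_v3.values)
    table.update(a4=0.0, a5=0.0, gamma=1.0,
                 kp3b=table["kp3a_hDCT"], kd5b=table["kd5a_hDCT"],
                 c4a_hgp100=p_v2["c4a_hgp100"], c4a_hDCT=p_v2["c4a_hDCT"])
    p3r = b.build_parameters(table, "V3")
    p2 = p_v2.replace(**{k: table[k] for k in p_v2.values if k in table})
    rng = np.random.default_rng(0)
    y2 = rng.uniform(0.1, 100.0, 12)
    y2[10:] = rng.uniform(1e-16, 1e-13, 2)   # cytokine scale
    y3 = np.concatenate([y2[:9], [y2[9], 0.0, 0.0, 0.0], y2[10:]])
    d2 = b.rhs_v2(1.0, y2, p2, geom)
    d3 = b.rhs_v3(1.0, y3, p3r, geom)
    assert np.allclose(d3[:9], d2[:9], rtol=1e-12)
    assert d3[9] == pytest.approx(d2[9], rel=1e-12)
    assert np.allclose(d3[13:], d2[10:], rtol=1e-12)


def test_rhs_v3_deactivation_flux_zero_cytokine(p_v3, geom):
    """At IFNG = 0 the interconversion flux is the constitutive a4 only."""
    p = p_v3.replace(a4=0.13, a5=7.0)
    til = 40.0
    y = _base_state_v3(p, geom, TE3a=til, Cneg=5.0)
    dy = b.rhs_v3(0.0, y, p, geom)
    vt = b.tumor_volume(y, geom)
    # independent recomputation of the TE3a balance (no proliferation: Cpos=0)
    assert dy[9] == pytest.approx(-(p["kd5a_hDCT"] + 0.13) * til
                                  - p["a32"] * til * 5.0 / vt, rel=1e-12)
    assert dy[10] == pytest.approx(0.13 * til, rel=1e-12)


def test_rhs_rejects_non_finite_state(p_v3, geom):
    y = _base_state_v3(p_v3, geom)
    y[13] = np.nan
    with pytest.raises(mc.ValidationError, match="IFNG"):
        b.rhs_v3(0.0, y, p_v3, geom)


@pytest.mark.parametrize("variant", ["V2", "V3"])
def test_cytokine_rows_obey_product_rule(variant, p_v3, p_v2, geom):
    """dC/dt = (1/V)dN/dt - (C/V^2)dV/dt with molecule bookkeeping done
    independently of the implementation's cytokine rows."""
    p = p_v3 if variant == "V3" else p_v2
    rng = np.random.default_rng(42)
    for _ in range(20):
        n = 15 if variant == "V3" else 12
        y = rng.uniform(0.0, 50.0, n)
        y[9:n - 2] = rng.uniform(0.0, 1e5, n - 11)      # TIL counts
        y[n - 2:] = rng.uniform(0.0, 1e-12, 2)          # cytokines
        rhs = b.rhs_v3 if variant == "V3" else b.rhs_v2
        dy = rhs(1.0, y, p, geom, antigen="hDCT")
        vt = b.tumor_volume(y, geom)
        ifng, tnfa = y[n - 2], y[n - 1]
        if variant == "V3":
            g = p["gamma"]
            til = y[9:13]
            w = til[0] + g * til[1] + g * g * til[2] + g ** 3 * til[3]
            s = til.sum()
            dvt = dy[7] + dy[8] + geom.Vi * dy[9:13].sum()
        else:
            w = s = y[9]
            dvt = dy[7] + dy[8] + geom.Vi * dy[9]
        dn_ifng = p["kc1"] * w - p["kd6"] * ifng * vt
        dn_tnfa = ((p["kc2"] * tnfa / (p["k2"] + tnfa) + p["kc3"]) * s
                   - p["kd7"] * tnfa * vt)
        assert dy[n - 2] == pytest.approx(dn_ifng / vt - ifng / vt * dvt, rel=1e-9)
        assert dy[n - 1] == pytest.approx(dn_tnfa / vt - tnfa / vt * dvt, rel=1e-9)


# ---------------------------------------------------------------------------
# simulate: events and invariants
# ---------------------------------------------------------------------------


def test_immunization_event_and_exponential_decay(p_v3, geom):
    """LV jumps to 1e5 RLU/mm^3 at day 5 and decays as exp(-kd2 * dt)."""
    protocol = sd.group_protocol("hDCT")
    grid = np.array([0.0, 2.0, 5.0, 6.0, 8.0, 12.0, 20.0])
    traj = b.simulate("V3", p_v3, geom, protocol, grid)
    lv = traj.series("LV")
    assert lv[0] <= 1e-15 and lv[1] <= 1e-15
    assert lv[2] == pytest.approx(1e5)                       # post-event at day 5
    kd2 = p_v3["kd2"]
    for i, day in ((3, 6.0), (4, 8.0), (5, 12.0), (6, 20.0)):
        assert lv[i] == pytest.approx(1e5 * np.exp(-kd2 * (day - 5.0)), rel=1e-5)


def test_act_event_dose_conversion(p_v3, geom):
    """3e6 transferred cells into 1200 mm^3 of blood raise TE2 by 2500/mm^3."""
    protocol = b.TreatmentProtocol(immunogen="none", implant_cells=1e5,
                                   act_events=((10.0, 3e6),), antigen="hgp100")
    grid = np.array([0.0, 9.99, 10.0, 10.5])
    traj = b.simulate("V3", p_v3, geom, protocol, grid)
    te2 = traj.series("TE2")
    assert te2[2] - te2[1] == pytest.approx(2500.0, rel=1e-6)


def test_no_treatment_no_tumor_is_fixed_point(p_v3, geom):
    protocol = b.TreatmentProtocol(immunogen="none", implant_cells=0.0)
    grid = np.linspace(0.0, 30.0, 31)
    traj = b.simulate("V3", p_v3, geom, protocol, grid)
    assert np.allclose(traj.series("TN"), p_v3["TN0"], rtol=1e-6)
    # every other state stays at its near-zero initial value (within the
    # integrator's absolute tolerance)
    assert np.all(np.abs(traj.y[:, 1:]) <= 1e-8)


def test_untreated_growth_matches_closed_form(p_v3, geom):
    """Tumor volume grows as exp((kp2 - kd4) t); T cells stay at baseline."""
    protocol = sd.group_protocol("untreated")
    grid = np.linspace(0.0, 20.0, 41)
    traj = b.simulate("V3", p_v3, geom, protocol, grid)
    v0 = 1e6 * geom.Vc
    rate = p_v3["kp2"] - p_v3["kd4"]
    assert np.allclose(traj.ct(), v0 * np.exp(rate * grid), rtol=1e-4)
    assert np.all(traj.til_total() < 1e-10)
    assert np.allclose(traj.series("TN"), p_v3["TN0"], rtol=1e-6)


def test_trajectory_non_negativity(p_v3, geom):
    """No state falls below -10x the absolute tolerance along the way."""
    atol = 1e-9
    grid = np.arange(0.0, 30.01, 0.2)
    for group in sd.GROUPS:
        traj = b.simulate("V3", p_v3, geom, sd.group_protocol(group), grid,
                          atol=atol)
        assert traj.y.min() >= -10 * atol


def test_v3_nests_v2_trajectories(p_v3, p_v2, geom):
    """a4 = a5 = 0, gamma = 1, tied TIL rates: summed TE3a-d matches V2's TE3."""
    table = dict(p_v3.values)
    table.update(a4=0.0, a5=0.0, gamma=1.0,
                 kp3b=table["kp3a_hDCT"], kd5b=table["kd5a_hDCT"],
                 c4a_hgp100=p_v2["c4a_hgp100"], c4a_hDCT=p_v2["c4a_hDCT"])
    p3r = b.build_parameters(table, "V3")
    p2 = p_v2.replace(**{k: v for k, v in table.items() if k in p_v2.values})
    grid = np.arange(0.0, 20.01, 0.5)
    protocol = sd.group_protocol("hDCT")
    t3 = b.simulate("V3", p3r, geom, protocol, grid)
    t2 = b.simulate("V2", p2, geom, protocol, grid)
    for name in ("TN", "TE1d", "TE2", "LV", "Cneg", "Cpos", "IFNG", "TNFa"):
        a, c = t3.series(name), t2.series(name)
        scale = np.max(np.abs(c)) + 1e-30
        assert np.allclose(a, c, atol=1e-3 * scale, rtol=1e-3)
    scale = np.max(t2.series("TE3")) + 1e-30
    assert np.allclose(t3.til_total(), t2.series("TE3"),
                       atol=1e-3 * scale, rtol=1e-3)


def test_ln_chain_factor_two_progeny_conservation(p_v3, geom):
    """With trafficking off and the checkpoint disabled, each division step
    feeds state x's outflux doubled into state y."""
    p = p_v3.replace(a12=0.0, a21=0.0, ka=1e12, kd1=0.0, TN0=0.0, c2=0.0)
    y = np.zeros(15)
    y[1:5] = [11.0, 7.0, 5.0, 3.0]
    y[5] = 1e5  # saturating antigen
    dy = b.rhs_v3(6.0, y, p, geom)
    g = p["kp1"] * (1e5 / (1e5 + p["kg"]))  # checkpoint factor ~ 1
    assert dy[1] == pytest.approx(-g * 11.0, rel=1e-9)
    assert dy[2] == pytest.approx(2 * g * 11.0 - g * 7.0, rel=1e-9)
    assert dy[3] == pytest.approx(2 * g * 7.0 - g * 5.0, rel=1e-9)
    assert dy[4] == pytest.approx(2 * g * 5.0 + g * 3.0, rel=1e-9)


def test_event_outside_grid_is_config_error(p_v3, geom):
    protocol = sd.group_protocol("hDCT")  # immunization day 5
    with pytest.raises(mc.ConfigError):
        b.simulate("V3", p_v3, geom, protocol, np.linspace(0.0, 3.0, 4))


# ---------------------------------------------------------------------------
# molecule-count integration oracle (trajectory level)
# ---------------------------------------------------------------------------


def _molecule_count_rhs_v3(t, z, pv, geom):
    """Independent oracle: cytokines carried as molecule numbers N = C * Vt.

    Written directly from compartment bookkeeping (cells produce molecules,
    clearance removes them in proportion to concentration); all other state
    equations are restated from the model description.
    """
    (TN, T1a, T1b, T1c, T1d, LV, TE2, Cn, Cp, A, B, C, D, NI, NT) = z
    Vt = geom.eps + Cn + Cp + geom.Vi * (A + B + C + D)
    ifng = NI / Vt
    tnfa = NT / Vt
    h_lv = LV / (LV + pv["kg"])
    brake = 1.0 - T1d ** 2 / (pv["ka"] ** 2 + T1d ** 2)
    grow = pv["kp1"] * h_lv * brake
    h_ifng = ifng / (pv["k1"] + ifng)
    deact = pv["a4"] + pv["a5"] * h_ifng
    g = pv["gamma"]
    c4 = pv["c4a_hDCT"]
    kill = (c4 * A + c4 * g * B + c4 * g * g * C + c4 * g ** 3 * D) * Cp / Vt ** 2
    prolif = Cp / Vt
    return [
        pv["kd1"] * pv["TN0"] - pv["kd1"] * TN - pv["c2"] * TN * h_lv,
        pv["c2"] * TN * (geom.Vb / geom.Vln) * h_lv - grow * T1a,
        2 * grow * T1a - grow * T1b,
        2 * grow * T1b - grow * T1c,
        2 * grow * T1c + grow * T1d - pv["a12"] * T1d + pv["a21"] * TE2 * geom.Vb / geom.Vln,
        -pv["kd2"] * LV,
        (pv["a12"] * T1d * geom.Vln / geom.Vb - (pv["a21"] + pv["kd3"] + pv["a23"]) * TE2
         + pv["a32"] * (Cn / Vt) * A / geom.Vb),
        (pv["kp2"] * Cn + 2 * pv["kp2"] * Cp - pv["c3"] * h_ifng * Cn - pv["kd4"] * Cn),
        (pv["c3"] * h_ifng * Cn - (pv["kp2"] + pv["kd4"]) * Cp - kill * Vt),
        (pv["a23"] * TE2 * geom.Vb - pv["a32"] * A * Cn / Vt
         + pv["kp3a_hDCT"] * A * prolif - pv["kd5a_hDCT"] * A - deact * A),
        deact * A - deact * B + pv["kp3b"] * B * prolif - pv["kd5b"] * B,
        deact * B - deact * C + pv["kp3b"] * C * prolif - pv["kd5b"] * C,
        deact * C + pv["kp3b"] * D * prolif - pv["kd5b"] * D,
        pv["kc1"] * (A + g * B + g * g * C + g ** 3 * D) - pv["kd6"] * NI,
        (pv["kc2"] * tnfa / (pv["k2"] + tnfa) + pv["kc3"]) * (A + B + C + D)
        - pv["kd7"] * NT,
    ]


def test_cytokine_concentrations_match_molecule_count_oracle(p_v3, geom):
    """Over 20 treated days, IFNG*Vt and TNFa*Vt agree with an independent
    molecule-count integration to 0.1% relative error."""
    from scipy.integrate import solve_ivp

    protocol = sd.group_protocol("hDCT")
    grid = np.arange(5.0, 25.01, 0.5)
    full_grid = np.union1d([0.0], grid)
    traj = b.simulate("V3", p_v3, geom, protocol, full_grid,
                      rtol=1e-9, atol=1e-12)
    i5 = np.searchsorted(full_grid, 5.0)
    z0 = traj.y[i5].copy()                    # post-immunization state
    vt0 = b.tumor_volume(z0, geom)
    z0[13] *= vt0                             # concentrations -> counts
    z0[14] *= vt0
    pv = dict(p_v3.values)
    sol = solve_ivp(_molecule_count_rhs_v3, (5.0, 25.0), z0, t_eval=grid,
                    args=(pv, geom), method="LSODA", rtol=1e-9, atol=1e-14)
    assert sol.success
    vt_oracle = (geom.eps + sol.y[7] + sol.y[8]
                 + geom.Vi * sol.y[9:13].sum(axis=0))
    idx = np.searchsorted(full_grid, grid)
    for row, name in ((13, "IFNG"), (14, "TNFa")):
        conc_impl = traj.y[idx, row]
        conc_oracle = sol.y[row] / vt_oracle
        mask = conc_oracle > 1e-18
        rel = np.abs(conc_impl[mask] - conc_oracle[mask]) / conc_oracle[mask]
        assert rel.max() < 1e-3, f"{name} deviates by {rel.max():.2e}"
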