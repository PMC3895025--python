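import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmsbox import SulfurParams, SulfurState, run_simulation, step_euler
from dmsbox.forcing import ForcingRecord
from dmsbox.sulfur import (
    bacterial_c_uptake,
    dms_uptake,
    dmspd_uptake,
    dmspp_tendency,
    partition_dmspd,
    photooxidation,
    s_need,
)


def make_record(**kwargs) -> ForcingRecord:
    defaults = dict(
        time_h=0.0,
        B=(0.0, 0.0, 0.0),
        mu=(0.0, 0.0, 0.0),
        lysis=(0.0, 0.0, 0.0),
        grazing=(0.0, 0.0, 0.0),
        sed=(0.0, 0.0, 0.0),
        BC=50.0, SBC=100.0, bmx=0.2, k_sbc=25.0, y_BC=0.3,
        T_degC=10.0, u10=5.0, J=100.0, kD=0.5, H=17.0,
    )
    defaults.update(kwargs)
    return ForcingRecord(**defaults)


# -- dmspp_tendency -------------------------------------------------------


def test_tendency_all_zero():
    tend, *fluxes = dmspp_tendency(make_record(), SulfurParams())
    assert tend == (0.0, 0.0, 0.0)
    assert all(f == 0.0 for f in fluxes)


def test_tendency_growth_only():
    # 100 mgC m-3 h-1 of colonial growth at quota 0.00092 mmolS:mgC
    rec = make_record(mu=(0.0, 0.0, 100.0))
    tend, f1, f2, f3, f3b, f4 = dmspp_tendency(rec, SulfurParams())
    assert tend[2] == pytest.approx(0.092, rel=1e-12)
    assert f1 == f2 == f3 == f3b == f4 == 0.0


def test_tendency_lysis_split_by_algal_yield():
    rec = make_record(lysis=(0.0, 0.0, 100.0))
    _, f1, f2, _, _, _ = dmspp_tendency(rec, SulfurParams())
    assert f1 == pytest.approx(0.0092, rel=1e-12)
    assert f2 == pytest.approx(0.0828, rel=1e-12)


def test_tendency_grazing_to_dms_variant():
    rec = make_record(grazing=(100.0, 0.0, 0.0))
    params = SulfurParams(graz_to_DMS=0.3)
    _, _, _, f3, f3b, _ = dmspp_tendency(rec, params)
    total = SulfurParams().SC_DA * 100.0
    assert f3b == pytest.approx(0.3 * total, rel=1e-12)
    assert f3 == pytest.approx(0.7 * total, rel=1e-12)


def test_tendency_rejects_negative_flux():
    with pytest.raises(ValueError):
        dmspp_tendency(make_record(mu=(-1.0, 0.0, 0.0)), SulfurParams())


# -- bacterial carbon uptake ----------------------------------------------


def test_uptake_zero_substrate():
    assert bacterial_c_uptake(make_record(SBC=0.0)) == 0.0


def test_uptake_half_saturation():
    rec = make_record(SBC=25.0, k_sbc=25.0, BC=50.0, bmx=0.2)
    assert bacterial_c_uptake(rec) == pytest.approx(0.2 * 50.0 / 2.0, rel=1e-12)


def test_uptake_hand_value():
    rec = make_record(bmx=0.2, BC=50.0, SBC=100.0, k_sbc=25.0)
    assert bacterial_c_uptake(rec) == pytest.approx(8.0, rel=1e-12)


def test_uptake_rejects_bad_half_saturation():
    with pytest.raises(ValueError):
        bacterial_c_uptake(make_record(k_sbc=0.0))


# -- DMSPd uptake ---------------------------------------------------------


def test_dmspd_uptake_zero_pool():
    state = SulfurState()
    assert dmspd_uptake(make_record(), SulfurParams(), state) == 0.0


def test_dmspd_uptake_hand_value():
    state = SulfurState(DMSPd=0.1)
    rec = make_record(bmx=0.2, BC=50.0, SBC=100.0, k_sbc=25.0)
    assert dmspd_uptake(rec, SulfurParams(), state) == pytest.approx(0.008, rel=1e-12)


def test_dmspd_uptake_linear_in_ratio():
    state = SulfurState(DMSPd=0.1)
    rec = make_record(bmx=0.2, BC=50.0, SBC=100.0, k_sbc=25.0)
    half = dmspd_uptake(rec, SulfurParams(ratio_S_DMSPd=0.5), state)
    assert half == pytest.approx(0.004, rel=1e-12)


def test_dmspd_uptake_capped_by_pool():
    state = SulfurState(DMSPd=0.001)
    rec = make_record(BC=5000.0)
    uptake = dmspd_uptake(rec, SulfurParams(), state, dt=0.25)
    assert uptake * 0.25 <= state.DMSPd + 1e-15


# -- bacterial sulfur need ------------------------------------------------


def test_s_need_zero_uptake():
    assert s_need(make_record(SBC=0.0), SulfurParams()) == 0.0


def test_s_need_hand_value():
    # y_BC * uptake_C / 12 * SC_BC = 0.3 * 8 / 12 * 0.01
    rec = make_record(bmx=0.2, BC=50.0, SBC=100.0, k_sbc=25.0, y_BC=0.3)
    assert s_need(rec, SulfurParams(SC_BC=0.01)) == pytest.approx(0.002, rel=1e-12)


def test_s_need_linear_in_quota():
    rec = make_record(bmx=0.2, BC=50.0, SBC=100.0, k_sbc=25.0)
    one = s_need(rec, SulfurParams(SC_BC=0.01))
    two = s_need(rec, SulfurParams(SC_BC=0.02))
    assert two == pytest.approx(2.0 * one, rel=1e-12)


# -- DMSPd partition ------------------------------------------------------


def test_partition_surplus_hand_values():
    f5, f6, f7, deficit = partition_dmspd(0.01, 0.0002, SulfurParams(lyase_bact=0.1))
    assert f5 == pytest.approx(0.0002, rel=1e-12)
    assert f7 == pytest.approx(0.00098, rel=1e-12)
    assert f6 == pytest.approx(0.00882, rel=1e-12)
    assert deficit == 0.0


def test_partition_limited_branch():
    f5, f6, f7, deficit = partition_dmspd(0.0001, 0.0002, SulfurParams())
    assert f5 == pytest.approx(0.0001)
    assert f6 == 0.0 and f7 == 0.0
    assert deficit == pytest.approx(0.0001)


def test_partition_zero_lyase():
    _, _, f7, _ = partition_dmspd(0.05, 0.0, SulfurParams(lyase_bact=0.0))
    assert f7 == 0.0


@given(uptake=st.floats(0, 1), sneed=st.floats(0, 1),
       lyase=st.floats(0, 1))
def test_partition_conserves_uptake(uptake, sneed, lyase):
    f5, f6, f7, deficit = partition_dmspd(uptake, sneed, SulfurParams(lyase_bact=lyase))
    assert f5 + f6 + f7 == pytest.approx(uptake, rel=1e-9, abs=1e-15)
    assert min(f5, f6, f7, deficit) >= 0.0
    if deficit > 0:
        assert f7 == 0.0  # no bacterial cleavage under sulfur limitation


# -- DMS uptake -----------------------------------------------------------


def test_dms_uptake_zero_pool():
    assert dms_uptake(make_record(), SulfurParams(), SulfurState()) == 0.0


def test_dms_uptake_hand_value():
    rec = make_record(bmx=0.2, BC=50.0, SBC=100.0, k_sbc=25.0)
    state = SulfurState(DMS=0.02)
    assert dms_uptake(rec, SulfurParams(), state) == pytest.approx(0.0016, rel=1e-12)


def test_dms_uptake_linear_in_ratio():
    rec = make_record(bmx=0.2, BC=50.0, SBC=100.0, k_sbc=25.0)
    state = SulfurState(DMS=0.02)
    got = dms_uptake(rec, SulfurParams(ratio_S_DMS=0.5), state)
    assert got == pytest.approx(0.0008, rel=1e-12)


def test_dms_uptake_deficit_top_up_capped():
    rec = make_record(bmx=0.2, BC=50.0, SBC=100.0, k_sbc=25.0)
    state = SulfurState(DMS=0.001)
    f8 = dms_uptake(rec, SulfurParams(), state, s_deficit=1.0, dt=0.25)
    assert f8 * 0.25 <= state.DMS + 1e-15


# -- photooxidation -------------------------------------------------------


def test_photooxidation_zero_dms():
    assert photooxidation(make_record(), SulfurParams(), SulfurState()) == 0.0


def test_photooxidation_hand_value():
    rec = make_record(kD=0.5, H=17.0)
    state = SulfurState(DMS=0.02)
    expected = 0.09 * (1.0 - np.exp(-8.5)) / 8.5 * 0.02
    got = photooxidation(rec, SulfurParams(K0=0.09), state)
    assert got == pytest.approx(expected, rel=1e-12)
    assert got == pytest.approx(2.117e-4, rel=1e-3)


def test_photooxidation_surface_limit():
    rec = make_record(kD=1e-9, H=1e-3)
    state = SulfurState(DMS=0.02)
    got = photooxidation(rec, SulfurParams(K0=0.09), state)
    assert got == pytest.approx(0.09 * 0.02, rel=1e-6)


# -- one Euler step -------------------------------------------------------


def test_step_zero_everything():
    state, ledger = step_euler(SulfurState(), make_record(), SulfurParams(), 0.25)
    assert state.total == 0.0
    assert all(v == 0.0 for v in ledger.as_tuple()[:11])


def _oracle_step(state, rec, p, dt, k_dms_m_h):
    """Independent spreadsheet-style evaluation of one explicit step."""
    sc = (p.SC_DA, p.SC_NF, p.SC_OP)
    y = (p.y_DMS_DA, p.y_DMS_NF, p.y_DMS_OP)
    pools = list(state.dmspp)
    f1 = f2 = f3 = f3b = f4 = 0.0
    for n in range(3):
        pools[n] = pools[n] + dt * sc[n] * (rec.mu[n] - rec.lysis[n]
                                            - rec.grazing[n] - rec.sed[n])
        f1 += y[n] * sc[n] * rec.lysis[n]
        f2 += (1 - y[n]) * sc[n] * rec.lysis[n]
        f3b += p.graz_to_DMS * sc[n] * rec.grazing[n]
        f3 += (1 - p.graz_to_DMS) * sc[n] * rec.grazing[n]
        f4 += sc[n] * rec.sed[n]
    upc = rec.bmx * rec.BC * rec.SBC / (rec.SBC + rec.k_sbc)
    uptake = min(p.ratio_S_DMSPd * upc * state.DMSPd / rec.SBC, state.DMSPd / dt)
    sneed = rec.y_BC * upc / 12.0 * p.SC_BC
    f5 = min(uptake, sneed)
    resid = uptake - f5
    f7 = p.lyase_bact * resid if resid > 0 else 0.0
    f6 = resid - f7 if resid > 0 else 0.0
    deficit = max(sneed - uptake, 0.0)
    f8 = min(p.ratio_S_DMS * upc * state.DMS / rec.SBC + deficit, state.DMS / dt)
    f10 = p.K0 * (1 - np.exp(-rec.kD * rec.H)) / (rec.kD * rec.H) * state.DMS
    f9 = k_dms_m_h * state.DMS / rec.H
    dmspd = state.DMSPd + dt * (f2 + f3 - uptake)
    dms = state.DMS + dt * (f1 + f3b + f7 - f8 - f9 - f10)
    return (*pools, dmspd, dms)


def test_step_matches_independent_oracle():
    rec = make_record(mu=(10.0, 5.0, 100.0), lysis=(2.0, 1.0, 100.0),
                      grazing=(1.0, 0.5, 0.0), sed=(0.5, 0.0, 3.0),
                      bmx=0.2, BC=50.0, SBC=100.0, k_sbc=25.0, y_BC=0.3)
    state = SulfurState(0.01, 0.02, 0.5, 0.1, 0.02)
    params = SulfurParams()
    new, ledger = step_euler(state, rec, params, 0.25, _k_dms_m_h=0.05)
    expected = _oracle_step(state, rec, params, 0.25, 0.05)
    got = (new.DMSPp_DA, new.DMSPp_NF, new.DMSPp_OP, new.DMSPd, new.DMS)
    for g, e in zip(got, expected):
        assert g == pytest.approx(e, rel=1e-12, abs=1e-15)
    assert ledger.f9_emission == pytest.approx(0.05 * 0.02 / 17.0, rel=1e-12)


def test_no_dms_source_means_no_dms():
    params = SulfurParams(y_DMS_DA=0.0, y_DMS_NF=0.0, y_DMS_OP=0.0,
                          lyase_bact=0.0, graz_to_DMS=0.0)
    rec = make_record(mu=(10.0, 5.0, 100.0), lysis=(2.0, 1.0, 50.0))
    state = SulfurState(0.1, 0.1, 0.5, 0.2, 0.0)
    for _ in range(200):
        state, _ = step_euler(state, rec, params, 0.25)
    assert state.DMS == 0.0


def test_step_rejects_bad_dt():
    with pytest.raises(ValueError):
        step_euler(SulfurState(), make_record(), SulfurParams(), 0.0)


def test_step_rejects_nan_forcing():
    with pytest.raises(ValueError, match="NaN"):
        step_euler(SulfurState(), make_record(BC=float("nan")), SulfurParams(), 0.25)


def test_flux_limiter_prevents_negative_pools():
    # enormous sinks relative to the pools must be rescaled, not overdrawn
    rec = make_record(lysis=(0.0, 0.0, 1e4), BC=1e5)
    state = SulfurState(DMSPp_OP=0.001, DMSPd=0.001, DMS=0.001)
    new, ledger = step_euler(state, rec, SulfurParams(), 1.0)
    assert new.DMSPp_OP >= 0.0 and new.DMSPd >= 0.0 and new.DMS >= 0.0
    assert min(ledger.as_tuple()[:11]) >= 0.0


@settings(max_examples=50, deadline=None)
@given(
    dmspd=st.floats(0, 1), dms=st.floats(0, 1),
    mu=st.floats(0, 100), lysis=st.floats(0, 100),
    bc=st.floats(0, 500),
)
def test_step_conserves_sulfur(dmspd, dms, mu, lysis, bc):
    rec = make_record(mu=(0.0, 0.0, mu), lysis=(0.0, 0.0, lysis), BC=bc)
    state = SulfurState(0.0, 0.0, 1.0, dmspd, dms)
    params = SulfurParams()
    new, led = step_euler(state, rec, params, 0.25, _k_dms_m_h=0.05)
    production = params.SC_OP * mu
    out = (led.f4_sedimentation + led.f5_s_assimilation + led.f6_demethylation
           + led.f8_dms_bact_uptake + led.f9_emission + led.f10_photooxidation)
    resid = (new.total - state.total) + 0.25 * out - 0.25 * production
    assert abs(resid) <= 1e-10 * max(state.total, 1.0)


# -- full-year simulation -------------------------------------------------


def test_timing_structure(default_result):
    tr = default_result.trajectory
    t_pp = tr["time_h"][tr[["DMSPp_DA", "DMSPp_NF", "DMSPp_OP"]].sum(axis=1).idxmax()]
    t_pd = tr["time_h"][tr["DMSPd"].idxmax()]
    t_dms = tr["time_h"][tr["DMS"].idxmax()]
    assert t_pp < t_dms < t_pd
    assert t_pd - t_pp > 24.0  # dissolved peak lags the particulate one by days


def test_quota_equivalence(default_forcing, default_result):
    params = SulfurParams()
    for ft, sc in zip(("DA", "NF", "OP"), params.sc):
        pool = default_result.trajectory[f"DMSPp_{ft}"].to_numpy()
        ref = sc * default_forcing.column(f"B_{ft}")
        assert np.abs(pool - ref).max() <= 1e-9 * max(ref.max(), 1.0)


def test_full_year_conservation(default_result):
    tr, led = default_result.trajectory, default_result.ledger
    dt = default_result.dt_h
    total = tr[["DMSPp_DA", "DMSPp_NF", "DMSPp_OP", "DMSPd", "DMS"]].sum(axis=1).to_numpy()
    sinks = (led["f4_sedimentation"] + led["f5_s_assimilation"] + led["f6_demethylation"]
             + led["f8_dms_bact_uptake"] + led["f9_emission"]
             + led["f10_photooxidation"]).to_numpy()
    prod = (led["prod_DA"] + led["prod_NF"] + led["prod_OP"]).to_numpy()
    resid = np.diff(total) + dt * (sinks - prod)[:-1]
    assert np.abs(resid).max() <= 1e-10 * total.max()


def test_s_limitation_rule(default_result):
    led = default_result.ledger
    upt = (led["f5_s_assimilation"] + led["f6_demethylation"]
           + led["f7_bact_lyase"]).to_numpy()
    limited = led["sneed"].to_numpy() > upt + 1e-15
    assert np.all(led["f7_bact_lyase"].to_numpy()[limited] == 0.0)


def test_non_negative_trajectory_and_ledger(default_result):
    assert (default_result.trajectory.to_numpy() >= 0.0).all()
    assert (default_result.ledger.to_numpy() >= 0.0).all()


def test_doubling_quotas_doubles_dmspp(coarse_forcing):
    base = SulfurParams()
    doubled = base.replace(SC_DA=2 * base.SC_DA, SC_NF=2 * base.SC_NF,
                           SC_OP=2 * base.SC_OP)
    r1 = run_simulation(coarse_forcing, base)
    r2 = run_simulation(coarse_forcing, doubled)
    for ft in ("DA", "NF", "OP"):
        a = r1.trajectory[f"DMSPp_{ft}"].to_numpy()
        b = r2.trajectory[f"DMSPp_{ft}"].to_numpy()
        assert np.allclose(b, 2 * a, rtol=1e-9, atol=1e-15)


def test_step_halving_converges():
    from dmsbox import default_scenario, generate_forcing, integrate_budget

    blooms, env = default_scenario()
    budgets = []
    for dt in (0.25, 0.125):
        f = generate_forcing(blooms, env, dt=dt, seed=3)
        budgets.append(integrate_budget(run_simulation(f)))
    for field_name in ("production_total", "phyto_lyase", "s_assimilation",
                       "demethylation", "bact_lyase", "dms_bact_uptake",
                       "emission", "photooxidation"):
        a = getattr(budgets[0], field_name)
        b = getattr(budgets[1], field_name)
        assert a == pytest.approx(b, rel=0.01)


def test_params_yaml_round_trip(tmp_path):
    params = SulfurParams(lyase_bact=0.25, graz_to_DMS=0.3)
    path = tmp_path / "params.yaml"
    params.to_yaml(path)
    assert SulfurParams.from_yaml(path) == params


def test_params_validate_ranges():
    with pytest.raises(ValueError):
        SulfurParams(lyase_bact=1.5)
    with pytest.raises(ValueError):
        SulfurParams(SC_OP=-1.0)


def test_quota_conversion():
    assert SulfurParams.quota_from_molar(0.011) == pytest.approx(0.011 / 12.0)
    # the stored flagellate/colonial default corresponds to 0.011 molS:molC
    assert SulfurParams().SC_OP == pytest.approx(0.011 / 12.0, rel=0.005)


def test_to_dataset_units(default_result):
    xr = pytest.importorskip("xarray")
    ds = default_result.to_dataset()
    assert ds["DMS"].attrs["units"] == "mmolS m-3"
    assert ds.sizes["time"] == len(default_result.trajectory)
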