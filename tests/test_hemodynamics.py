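"""Lumped network, Windkessel outlets, transport and watershed checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aortaflow import hemodynamics as hd
from aortaflow.hemodynamics import (
    LMIN,
    MMHG,
    FlowWaveform,
    FluidProps,
    SimulationConfig,
    WindkesselParams,
    WindkesselState,
    poiseuille_resistance,
)

WK = WindkesselParams(Rp=1e7, Rd=9e7, C=1.5 / 9e7)


# ---------------------------------------------------------------------------
# fluid and resistances
# ---------------------------------------------------------------------------

def test_fluid_defaults_are_blood():
    fluid = FluidProps()
    assert fluid.density == 1060.0
    assert fluid.viscosity == 3.5e-3


def test_poiseuille_closed_form_and_r4_law():
    mu, L, r = 3.5e-3, 0.1, 0.01
    expected = 8.0 * mu * L / (np.pi * r**4)  # independent hand evaluation
    assert poiseuille_resistance(mu, L, r) == pytest.approx(expected, rel=1e-12)
    assert poiseuille_resistance(mu, L, 2 * r) == pytest.approx(expected / 16, rel=1e-12)
    with pytest.raises(ValueError):
        poiseuille_resistance(mu, L, 0.0)


# ---------------------------------------------------------------------------
# waveform scaling
# ---------------------------------------------------------------------------

def test_healthy_waveform_mean_is_exact():
    w = hd.default_cardiac_waveform(mean_lmin=5.0)
    assert w.cycle_mean_lmin == pytest.approx(5.0, rel=1e-12)
    assert w.period == 0.8


def test_shock_reduction_of_cardiac_output():
    w = hd.default_cardiac_waveform(mean_lmin=5.0)
    shock = hd.scale_waveform(w, reduction=0.70)
    assert shock.cycle_mean_lmin == pytest.approx(1.5, rel=1e-9)
    same = hd.scale_waveform(w, reduction=0.0)
    np.testing.assert_array_equal(same.q, w.q)
    with pytest.raises(ValueError):
        hd.scale_waveform(w, target_mean_lmin=-1.0)
    with pytest.raises(ValueError):
        hd.scale_waveform(w)


# ---------------------------------------------------------------------------
# Windkessel closed forms
# ---------------------------------------------------------------------------

def test_windkessel_steady_state():
    st_ = WindkesselState(WK, P_d=0.0)
    Q0, dt = 8e-5, 1e-3
    for _ in range(int(15 * WK.tau / dt)):
        P = st_.step(Q0, dt)
    assert P == pytest.approx((WK.Rp + WK.Rd) * Q0, rel=1e-3)


def test_windkessel_exponential_decay():
    P0, dt, t_end = 1.2e4, 1e-3, 2.0
    st_ = WindkesselState(WK, P_d=P0)
    n = int(t_end / dt)
    for _ in range(n):
        P = st_.step(0.0, dt)
    assert P == pytest.approx(P0 * np.exp(-n * dt / WK.tau), rel=1e-3)
    with pytest.raises(ValueError):
        st_.step(0.0, -1e-3)


@settings(deadline=None, derandomize=True, max_examples=20)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_windkessel_ode_matches_convolution(seed):
    """ODE stepping equals the convolution solution for piecewise-constant Q."""
    rng = np.random.default_rng(seed)
    n, dt = 1500, 1e-3
    Q = rng.uniform(0.0, 1e-4, n)
    P0 = rng.uniform(0.0, 2e4)
    st_ = WindkesselState(WK, P_d=P0)
    for i in range(n):
        P_ode = st_.step(Q[i], dt)
    tau, t_end = WK.tau, n * dt
    j = np.arange(n)
    integral = np.sum(Q * tau / WK.C * (np.exp(-(t_end - (j + 1) * dt) / tau)
                                        - np.exp(-(t_end - j * dt) / tau)))
    P_conv = P0 * np.exp(-t_end / tau) + WK.Rp * Q[-1] + integral
    assert P_ode == pytest.approx(P_conv, rel=1e-4)


# ---------------------------------------------------------------------------
# mean flow
# ---------------------------------------------------------------------------

def test_mean_flow_constant_and_sinusoid():
    T = 0.8
    t = np.linspace(0, 3 * T, 3000)
    q = np.full_like(t, 2.0 * LMIN)
    assert hd.mean_flow(q, t, T) == pytest.approx(2.0, rel=1e-9)
    A, B = 4.0 * LMIN, 2.5 * LMIN
    q = A + B * np.sin(2 * np.pi * t / T)
    assert hd.mean_flow(q, t, T) == pytest.approx(A / LMIN, rel=1e-6)
    with pytest.raises(ValueError):
        hd.mean_flow(q[:10], t[:10], T)


# ---------------------------------------------------------------------------
# network simulation
# ---------------------------------------------------------------------------

def test_calibration_meets_split_and_pressure_targets(calibrated_template,
                                                      healthy_waveform):
    net, wk, _ = calibrated_template
    res = hd.simulate(net, healthy_waveform)
    means = res.mean_outlet_flows_lmin()
    total = sum(means.values())
    for name, target in hd.CalibrationTargets().flow_split.items():
        assert means[name] / total == pytest.approx(target, rel=0.01)
    lo, hi = hd.CalibrationTargets().peak_pressure_band_mmhg
    assert lo <= res.peak_root_pressure_mmhg() <= hi
    for p in wk.values():
        assert p.tau == pytest.approx(1.5, rel=1e-9)


def test_total_resistance_scales_with_pressure_target(calibrated_template,
                                                      healthy_waveform):
    _, _, tracts = calibrated_template
    def total_R(band):
        net = hd.build_network(tracts)
        wk = hd.calibrate_rcr(net, healthy_waveform,
                              hd.CalibrationTargets(peak_pressure_band_mmhg=band))
        return 1.0 / sum(1.0 / (p.Rp + p.Rd + net.outlets[n].R_access)
                         for n, p in wk.items())

    base = total_R((120.0, 130.0))
    raised = total_R((132.0, 143.0))  # band center up 10%
    assert raised / base == pytest.approx(1.10, rel=0.02)


def test_simulation_time_span_is_three_cycles(calibrated_template, healthy_waveform):
    net, _, _ = calibrated_template
    res = hd.simulate(net, healthy_waveform)
    assert res.t[-1] == pytest.approx(2.4, abs=1e-9)


def test_mass_conservation(calibrated_template, healthy_waveform, ecmo_runs):
    net, _, _ = calibrated_template
    res = hd.simulate(net, healthy_waveform)
    inflow = res.cardiac_q
    total_out = sum(res.outlet_flows.values())
    assert np.abs(total_out - inflow).max() < 1e-9 * inflow.max()
    means = res.mean_outlet_flows_lmin()
    assert abs(sum(means.values()) - 5.0) / 5.0 < 1e-6
    _, runs = ecmo_runs
    for ef, r in runs.items():
        expect = 1.5 + ef
        assert abs(sum(r.mean_outlet_flows_lmin().values()) - expect) / expect < 1e-6


def test_dead_network_decays_to_rest(calibrated_template):
    net, _, _ = calibrated_template
    t = np.linspace(0, 0.8, 801)
    silent = FlowWaveform(t=t, q=np.zeros_like(t))
    res = hd.simulate(net, silent)
    m = res.final_cycle()
    for q in res.outlet_flows.values():
        assert np.abs(q[m]).max() < 1e-9


def test_pressure_drops_from_root_to_descending_at_systole(calibrated_template,
                                                           healthy_waveform):
    net, _, _ = calibrated_template
    res = hd.simulate(net, healthy_waveform)
    i = res.systolic_peak_index()
    path = [res.junction_names.index(n)
            for n in ("root", "bca_j", "lcca_j", "lsa_j", "desc_end")]
    p = res.P_junction[i, path]
    assert np.all(np.diff(p) < 0)


def test_config_validation(calibrated_template, healthy_waveform):
    net, _, _ = calibrated_template
    with pytest.raises(ValueError, match="period/200"):
        hd.simulate(net, healthy_waveform, SimulationConfig(dt=0.01))
    with pytest.raises(ValueError, match="ecmo_return"):
        hd.simulate(net, healthy_waveform, SimulationConfig(ef_lmin=4.0, mode="shock"))
    with pytest.raises(ValueError):
        SimulationConfig(n_cycles=0)


# ---------------------------------------------------------------------------
# ECMO fraction transport
# ---------------------------------------------------------------------------

def test_no_ecmo_means_no_phase2_at_ostia(ecmo_runs):
    net, runs = ecmo_runs
    res = runs[0.0]
    hd.transport_fraction(res, net)
    for v in hd.branch_fraction(res, net).values():
        assert v < 1e-3


def test_pure_ecmo_saturates_ostia(calibrated_template):
    """With no cardiac inflow every branch ends up on pure ECMO blood."""
    _, wk, tracts = calibrated_template
    net = hd.build_network(tracts, with_ecmo_return=True)
    net.windkessels = dict(wk)
    t = np.linspace(0, 0.8, 801)
    silent = FlowWaveform(t=t, q=np.zeros_like(t))
    cfg = SimulationConfig(ef_lmin=4.0, mode="shock", n_cycles=10)
    res = hd.simulate(net, silent, cfg)
    hd.transport_fraction(res, net)
    for v in hd.branch_fraction(res, net).values():
        assert v > 1.0 - 1e-3


def test_phi_bounded_and_conserved(ecmo_runs):
    """phi stays in [0,1]; phase-2 volume + outflow balances EF inflow to 1%."""
    net, runs = ecmo_runs
    res = runs[6.0]
    phi = hd.transport_fraction(res, net)
    assert phi.min() >= -1e-9 and phi.max() <= 1 + 1e-9
    dt = res.config.dt
    ds = res.phi_s[1] - res.phi_s[0]
    vol = net.area(res.phi_s) * ds
    stored = float(phi[-1] @ vol)
    uptake = 0.0
    for name in ("BCA", "LCCA", "LSA"):
        cell = min(int(net.ostia_s[name] / ds), phi.shape[1] - 1)
        uptake += float(np.sum(res.outlet_flows[name][1:] * phi[1:, cell]) * dt)
    q_abd = res.segment_flows["abdominal"]
    distal = float(np.sum(q_abd[1:] * phi[1:, -1]) * dt)
    injected = res.config.ef_lmin * LMIN * (res.t[-1] - res.t[0])
    balance = stored + uptake + distal
    assert balance == pytest.approx(injected, rel=0.01)


def test_ecmo_front_matches_particle_tracking():
    """Steady constant-flow run: the retrograde phi = 0.5 front travels as far
    as a brute-force particle advected through the same axial field, and no
    ECMO blood appears proximal of the flow stagnation point."""
    import aortaflow as af
    from aortaflow import morphometry as mm
    from aortaflow.hemodynamics import _axial_face_flows

    g = af.build_geometry(af.AortaParams(), label="t")
    tracts = mm.split_tracts(g.centerline_tree)
    net = hd.build_network(tracts, with_ecmo_return=True)
    wave = hd.default_cardiac_waveform()
    net_h = hd.build_network(tracts)
    wk = hd.calibrate_rcr(net_h, wave)
    net.windkessels = dict(wk)
    t = np.linspace(0, 0.8, 801)
    const = FlowWaveform(t=t, q=np.full_like(t, 1.5 * LMIN))
    cfg = SimulationConfig(ef_lmin=4.0, mode="shock", n_cycles=6)
    res = hd.simulate(net, const, cfg)
    phi = hd.transport_fraction(res, net)

    faces = np.linspace(0, net.total_length, phi.shape[1] + 1)
    Qf = _axial_face_flows(res, net, faces)[-1]
    area = net.area(faces)
    ds = faces[1] - faces[0]

    def velocity(s: float) -> float:
        return Qf[min(int(s / ds), Qf.size - 1)] / area[min(int(s / ds), Qf.size - 1)]

    # particle released just proximal of the ECMO entry, integrated retrograde
    # over the simulated duration
    s, dtp = net.s_ecmo - 2 * ds, 1e-4
    for _ in range(int(res.t[-1] / dtp)):
        v = velocity(s)
        if v >= 0:
            break
        s += v * dtp
    s_particle = s

    final = phi[-1]
    centers = res.phi_s
    idx = int(np.argmax(final > 0.5))
    assert abs(centers[idx] - s_particle) < 3 * ds
    # stagnation point: most proximal face with non-positive flow
    s_stag = faces[int(np.argmax(Qf <= 0))]
    assert final[centers < s_stag - 2 * ds].max() < 0.05


# ---------------------------------------------------------------------------
# watershed
# ---------------------------------------------------------------------------

def test_healthy_flow_has_no_watershed(calibrated_template, healthy_waveform):
    net, _, _ = calibrated_template
    res = hd.simulate(net, healthy_waveform)
    ws = hd.watershed_location(res, net, "systolic")
    assert ws.zone == "none"
    assert ws.s_star == pytest.approx(net.total_length)


def test_watershed_matches_cumulative_flow_oracle():
    """Constant cardiac 1.5 + EF 4 L/min: the sign change of the cumulative
    flow balance picks the watershed segment by hand."""
    import aortaflow as af
    from aortaflow import morphometry as mm

    g = af.build_geometry(af.AortaParams(), label="t")
    tracts = mm.split_tracts(g.centerline_tree)
    net_h = hd.build_network(tracts)
    wave = hd.default_cardiac_waveform()
    wk = hd.calibrate_rcr(net_h, wave)
    net = hd.build_network(tracts, with_ecmo_return=True)
    net.windkessels = dict(wk)
    t = np.linspace(0, 0.8, 801)
    const = FlowWaveform(t=t, q=np.full_like(t, 1.5 * LMIN))
    res = hd.simulate(net, const, SimulationConfig(ef_lmin=4.0, mode="shock", n_cycles=6))
    ws = hd.watershed_location(res, net, "systolic")

    # oracle: cumulative balance from the measured branch draws
    i = res.systolic_peak_index()
    draws = [res.outlet_flows[n][i] for n in ("BCA", "LCCA", "LSA")]
    cum = 1.5 * LMIN - np.cumsum([0.0, *draws])  # flow below root/BCA/LCCA/LSA
    cum[-1] -= 0.0  # descending segment carries the remainder minus nothing else
    seg_flows = list(cum)  # ascending, BCA-LCCA arch, LCCA-LSA arch, descending
    expected_zone = {0: "ascending", 1: "BCA-LCCA", 2: "LCCA-LSA", 3: "at-LSA"}
    k = next(j for j, q in enumerate(seg_flows) if q <= 0)
    assert ws.zone == expected_zone[k]
    bounds = [0.0, net.ostia_s["BCA"], net.ostia_s["LCCA"], net.ostia_s["LSA"]]
    assert ws.s_star == pytest.approx(bounds[k], abs=1e-9)


def test_watershed_orderings_with_ef_and_phase(ecmo_runs):
    """Higher support pulls the watershed proximally; diastole is at least
    as proximal as systole."""
    net, runs = ecmo_runs
    s_sys = {ef: hd.watershed_location(runs[ef], net, "systolic").s_star
             for ef in (4.0, 6.0)}
    assert s_sys[6.0] <= s_sys[4.0]
    for ef in (4.0, 6.0):
        s_dia = hd.watershed_location(runs[ef], net, "diastolic").s_star
        assert s_dia <= s_sys[ef]


def test_diastolic_mixing_reaches_the_ascending_aorta(ecmo_runs):
    net, runs = ecmo_runs
    for ef in (4.0, 6.0):
        ws = hd.watershed_location(runs[ef], net, "diastolic")
        assert ws.zone == "ascending"


# ---------------------------------------------------------------------------
# flow redistribution under support
# ---------------------------------------------------------------------------

def test_mean_outlet_flow_linear_in_ef(ecmo_runs):
    net, runs = ecmo_runs
    efs = np.array(sorted(runs))
    for branch in ("BCA", "LCCA", "LSA"):
        y = np.array([runs[ef].mean_outlet_flows_lmin()[branch] for ef in efs])
        slope, intercept = np.polyfit(efs, y, 1)
        resid = y - (slope * efs + intercept)
        r2 = 1 - resid @ resid / np.sum((y - y.mean()) ** 2)
        assert r2 > 0.99
        assert slope > 0


def test_full_support_restores_healthy_branch_flows(ecmo_runs, calibrated_template,
                                                    healthy_waveform):
    net_h, _, _ = calibrated_template
    healthy = hd.simulate(net_h, healthy_waveform).mean_outlet_flows_lmin()
    net, runs = ecmo_runs
    at0 = runs[0.0].mean_outlet_flows_lmin()
    at6 = runs[6.0].mean_outlet_flows_lmin()
    for branch in ("BCA", "LCCA", "LSA"):
        assert at6[branch] >= at0[branch]
        assert at6[branch] >= 0.95 * healthy[branch]
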