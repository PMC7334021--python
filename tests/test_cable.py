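"""Cable engine: discretization geometry, integrator accuracy, clamping."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import ttl5sim as t5
from ttl5sim.cable import CableStructureError, NumericalError
from ttl5sim.channels import channel


def test_single_compartment_area():
    m = t5.discretize([t5.SectionSpec("s", length=10, diameter=5,
                                      n_compartments=1)])
    assert m.area[0] == pytest.approx(math.pi * 5 * 10 * 1e-8)


def test_axial_conductance_symmetric():
    sec = t5.SectionSpec("c", length=100, diameter=2, n_compartments=2)
    m = t5.discretize([sec])
    # one coupling entry shared by both compartments: g(i->j) == g(j->i)
    assert m.parent[1] == 0
    assert m.gax[1] > 0


def test_cycle_detection():
    a = t5.SectionSpec("a", length=10, diameter=1, parent="b")
    b = t5.SectionSpec("b", length=10, diameter=1, parent="a")
    with pytest.raises(CableStructureError, match="cycle|root"):
        t5.discretize([a, b])


def test_invalid_geometry_rejected():
    with pytest.raises(ValueError):
        t5.SectionSpec("s", length=-5, diameter=1)
    with pytest.raises(ValueError):
        t5.SectionSpec("s", length=5, diameter=0)


def test_grid_refinement_steady_state():
    """600 µm trunk at 60 vs 120 compartments: soma voltage under fixed
    distal current differs by < 0.5%."""
    out = []
    for n in (60, 120):
        trunk = t5.SectionSpec("trunk", length=600, diameter=2.5,
                               axial_resistivity=100,
                               leak_conductance=1 / 15.0,
                               leak_reversal=-65.0, n_compartments=n)
        m = t5.discretize([trunk])
        st = t5.StimulusEvent(("trunk", 1.0), "current_step", onset=0,
                              amplitude=0.05, duration=400)
        tr = t5.simulate(m, [st], duration=300, dt=0.05,
                         record=[("v", "trunk", 0.0)])
        out.append(tr["v"][-1] + 65)
    assert abs(out[0] - out[1]) / abs(out[1]) < 0.005


def test_rc_charging_63_percent(passive_comp):
    st = t5.StimulusEvent(("soma", 0.5), "current_step", onset=10,
                          amplitude=0.1, duration=200)
    tr = t5.simulate(passive_comp, [st], duration=200, dt=0.01,
                     record=[("v", "soma", 0.5)])
    v = tr["v"]
    v_ss = v[-1] + 65
    v_tau = v[np.searchsorted(tr.time, 20.0)] + 65  # onset + tau (10 ms)
    assert v_tau / v_ss == pytest.approx(1 - math.exp(-1), abs=0.01)


def test_finite_cable_cosh_attenuation(lambda_cable):
    """Sealed cable of length lambda: distal/proximal DC ratio = 1/cosh(1)."""
    m, lam = lambda_cable
    st = t5.StimulusEvent(("cab", 0.0), "current_step", onset=0,
                          amplitude=0.05, duration=1000)
    tr = t5.simulate(m, [st], duration=400, dt=0.05,
                     record=[("p", "cab", 0.0), ("d", "cab", 1.0)])
    ratio = (tr["d"][-1] + 65) / (tr["p"][-1] + 65)
    assert ratio == pytest.approx(1 / math.cosh(1), rel=0.01)


def test_active_two_compartment_vs_dense_ode():
    """Backward Euler at dt=0.025 vs a high-order dense integration of the
    identical ODE system at tolerance ~dt/100: peak within 0.5 mV."""
    from ttl5sim.channels import _gate_rates, CHANNEL_NAMES

    sec = t5.SectionSpec(
        "s", length=30, diameter=20, leak_conductance=1 / 15.0,
        leak_reversal=-65.0, n_compartments=2,
        mechanisms=[channel("Nat", 120.0), channel("Kfast", 30.0)],
    )
    m = t5.discretize([sec])
    st = t5.StimulusEvent(("s", 0.0), "current_step", onset=5, amplitude=0.4,
                          duration=3)
    # fine step for the comparison: first-order stepping needs dt well below
    # the spike rise time to resolve the peak to sub-mV accuracy
    tr = t5.simulate(m, [st], duration=20, dt=0.002,
                     record=[("v0", "s", 0.0)])

    # dense ODE reference (voltage + gates) built from the same arrays
    nat, kf = CHANNEL_NAMES["Nat"], CHANNEL_NAMES["Kfast"]
    n = m.n

    def gbar(tid, comp):
        for k in range(len(m.ch_type)):
            if m.ch_type[k] == tid:
                for j in range(m.ch_off[k], m.ch_off[k + 1]):
                    if m.ch_comp[j] == comp:
                        return m.ch_gbar[j], m.ch_params[k]
        raise AssertionError

    def rhs(t, y):
        v = y[:n]
        mg, hg, kg = y[n:2 * n], y[2 * n:3 * n], y[3 * n:]
        dv = np.zeros(n)
        dm = np.zeros(n)
        dh = np.zeros(n)
        dk = np.zeros(n)
        for i in range(n):
            g_na, pna = gbar(nat, i)
            g_k, pk = gbar(kf, i)
            iion = (m.gpas[i] * (v[i] - m.epas[i])
                    + g_na * mg[i] ** 3 * hg[i] * (v[i] - 50.0)
                    + g_k * kg[i] * (v[i] + 85.0))
            iax = 0.0
            if m.parent[i] >= 0:
                iax += m.gax[i] * (v[i] - v[m.parent[i]])
            for c in range(n):
                if m.parent[c] == i:
                    iax += m.gax[c] * (v[i] - v[c])
            istim = 0.4 if (5 <= t < 8 and i == 0) else 0.0
            dv[i] = (istim - iion - iax) / m.cm[i]
            inf, tau = _gate_rates(nat, 0, v[i], pna, 1e-4)
            dm[i] = (inf - mg[i]) / tau
            inf, tau = _gate_rates(nat, 1, v[i], pna, 1e-4)
            dh[i] = (inf - hg[i]) / tau
            inf, tau = _gate_rates(kf, 0, v[i], pk, 1e-4)
            dk[i] = (inf - kg[i]) / tau
        return np.concatenate([dv, dm, dh, dk])

    y0 = np.concatenate([np.full(n, -65.0)] + [
        np.full(n, _gate_rates(tid, g, -65.0, m.ch_params[k], 1e-4)[0])
        for k, tid in enumerate(m.ch_type)
        for g in range((2 if tid == nat else 1))
    ])
    sol = solve_ivp(rhs, (0, 20), y0, max_step=0.025 / 4, rtol=1e-8,
                    atol=1e-8, dense_output=False, method="LSODA")
    v_ref = sol.y[0]
    assert abs(tr["v0"].max() - v_ref.max()) < 0.5


def test_passive_linearity(passive_comp):
    s1 = t5.StimulusEvent(("soma", 0.5), "current_step", onset=5,
                          amplitude=0.05, duration=20)
    s2 = t5.StimulusEvent(("soma", 0.5), "epsc_like", onset=15,
                          amplitude=0.08)
    kw = dict(duration=80, dt=0.025, record=[("v", "soma", 0.5)])
    r1 = t5.simulate(passive_comp, [s1], **kw)["v"] + 65
    r2 = t5.simulate(passive_comp, [s2], **kw)["v"] + 65
    r12 = t5.simulate(passive_comp, [s1, s2], **kw)["v"] + 65
    assert np.allclose(r12, r1 + r2, atol=1e-9)


def test_resting_stability(default_disc):
    tr = t5.simulate(default_disc, [], duration=500, dt=0.025,
                     record=[("v", "soma", 0.5)])
    v = tr["v"]
    tail = v[int(400 / 0.025):]
    dvdt = np.abs(np.diff(tail)) / 0.025
    assert dvdt.max() < 0.01


def test_clamp_tracks_command_and_rest_fixed_point(default_disc):
    cl = t5.StimulusEvent(("trunk", 1.0), "voltage_command", onset=20,
                          amplitude=30.0, duration=40)
    tr = t5.simulate_clamped(default_disc, cl, duration=100, dt=0.025,
                             record=[("c", "trunk", 1.0)])
    t = tr.time
    during = (t > 20.1) & (t < 60.0)
    assert np.all(np.abs(tr["c"][during] - (-35.0)) < 0.1)
    # command == rest -> clamp current ~0, everything stays at rest
    cl0 = t5.StimulusEvent(("trunk", 1.0), "voltage_command", onset=20,
                           amplitude=0.0, duration=40)
    tr0 = t5.simulate_clamped(default_disc, cl0, duration=100, dt=0.025,
                              record=[("soma", "soma", 0.5)])
    assert np.abs(tr0["soma"] + 65).max() < 0.01
    assert np.abs(tr0.currents["clamp"][10:]).max() < 1e-3


def test_clamp_dc_limit():
    """Very long steps converge to a width-independent tuft plateau level."""
    from ttl5sim.model import build_reduced

    disc = build_reduced(600.0, passive_tuft=True, passive_trunk=True
                         ).discretize()
    peaks = []
    for w in (200.0, 400.0):
        cl = t5.StimulusEvent(("trunk", 1.0), "voltage_command", onset=10,
                              amplitude=20.0, duration=w)
        tr = t5.simulate_clamped(disc, cl, duration=w + 20, dt=0.05,
                                 record=[("tuft", "tuft", 0.5)])
        peaks.append(tr["tuft"].max())
    assert peaks[0] == pytest.approx(peaks[1], abs=0.05)


def test_divergence_guard():
    sec = t5.SectionSpec(
        "s", length=20, diameter=20, leak_conductance=0.01,
        leak_reversal=-65.0, n_compartments=1,
        mechanisms=[channel("Nat", 5000.0, reversal_potential=2000.0)],
    )
    m = t5.discretize([sec])
    st = t5.StimulusEvent(("s", 0.5), "current_step", onset=1,
                          amplitude=5.0, duration=50)
    with pytest.raises(NumericalError, match="t ="):
        t5.simulate(m, [st], duration=100, dt=0.025,
                    record=[("v", "s", 0.5)])


def test_unknown_site_rejected(default_disc):
    with pytest.raises(CableStructureError):
        default_disc.comp_index("dendrite", 0.5)
    with pytest.raises(CableStructureError):
        default_disc.comp_index("soma", 1.5)


def test_trace_roundtrip(tmp_path, passive_comp):
    from ttl5sim.io import read_trace_csv, write_trace_csv

    st = t5.StimulusEvent(("soma", 0.5), "epsc_like", onset=5, amplitude=0.1)
    tr = t5.simulate(passive_comp, [st], duration=40, dt=0.025,
                     record=[("v", "soma", 0.5)])
    tr.meta["note"] = "roundtrip"
    path = write_trace_csv(tr, tmp_path / "trace.csv")
    back = read_trace_csv(path)
    assert back.dt == tr.dt
    assert back.sites == tr.sites
    assert np.allclose(back["v"], tr["v"], atol=1e-7)
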