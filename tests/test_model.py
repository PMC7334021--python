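"""Reduced-model construction: placements, gradients, rescaling, anchors."""

import math

import numpy as np
import pytest

import ttl5sim as t5
from ttl5sim.model import (
    DistributionProfile,
    build_reduced,
    load_default_params,
    redistribute_trunk_conductances,
    trunk_length_constant,
)


def test_build_is_deterministic():
    a = build_reduced(600.0)
    b = build_reduced(600.0)
    for sa, sb in zip(a.sections, b.sections):
        assert sa.name == sb.name
        assert np.allclose(np.atleast_1d(sa.leak_reversal),
                           np.atleast_1d(sb.leak_reversal))


def test_trunk_length_only_changes_trunk():
    a, b = build_reduced(600.0), build_reduced(200.0)
    assert b.section("trunk").length == 200.0
    for name in ("soma", "tuft", "basal"):
        sa, sb = a.section(name), b.section(name)
        assert sa.length == sb.length and sa.diameter == sb.diameter
        assert sa.specific_capacitance == sb.specific_capacitance


def test_channel_placement_invariants():
    spec = build_reduced(500.0)
    def names(sec):
        out = set()
        for m in sec.mechanisms:
            ch = m[0] if isinstance(m, tuple) else m
            out.add(ch.name)
        return out

    assert {"CaHVA", "CaLVA", "KCa"} <= names(spec.section("tuft"))
    for s in ("soma", "hillock", "ais", "basal", "trunk"):
        assert not ({"CaHVA", "CaLVA", "KCa"} & names(spec.section(s)))
        assert spec.section(s).calcium_pool is None
    assert spec.section("tuft").calcium_pool is not None
    assert names(spec.section("soma")) == {"Nat", "Nap", "Kfast", "Kslow",
                                           "Km"}
    assert names(spec.section("hillock")) == {"Nat"}
    assert names(spec.section("ais")) == {"Nat"}
    assert names(spec.section("basal")) == {"HCN"}
    assert names(spec.section("trunk")) == {"Nat", "Kfast", "Kslow", "HCN"}


def test_resting_potential_anchor(default_disc):
    tr = t5.simulate(default_disc, [], duration=300, dt=0.025,
                     record=[("soma", "soma", 0.5), ("tuft", "tuft", 0.5)])
    assert abs(tr["soma"][-1] + 65.0) < 1.0
    assert abs(tr["tuft"][-1] + 65.0) < 1.0


def test_lambda_anchor_and_closed_form(default_spec):
    assert trunk_length_constant(default_spec) == pytest.approx(1009.0,
                                                                abs=1e-6)
    sec = t5.SectionSpec("t", length=100, diameter=1.0,
                         axial_resistivity=100.0, leak_conductance=0.1)
    # d = 1 µm, R_m = 10 kΩ·cm², R_a = 100 -> 500 µm
    assert sec.length_constant() == pytest.approx(500.0, rel=1e-12)
    sec4 = t5.SectionSpec("t", length=100, diameter=4.0,
                          axial_resistivity=100.0, leak_conductance=0.1)
    assert sec4.length_constant() == pytest.approx(1000.0, rel=1e-12)


def test_profiles_pure_functions_of_distance():
    profiles = {
        "Nat": DistributionProfile("linear", anchor=120.0, slope=120.0 / 1400),
        "Kfast": DistributionProfile("exponential", anchor=60.0,
                                     decay_length=80.0),
    }
    long = redistribute_trunk_conductances(profiles, 600.0, 60)
    short = redistribute_trunk_conductances(profiles, 300.0, 30)
    # identical compartment centers -> identical densities
    assert np.allclose(long["Nat"][:30], short["Nat"])
    assert np.allclose(long["Kfast"][:30], short["Kfast"])
    # anchors at distance 0 (first center is dx/2, so extrapolate exactly)
    assert profiles["Nat"](0.0) == 120.0
    assert profiles["Kfast"](80.0) == pytest.approx(60.0 / math.e)
    # linear clips at zero
    assert profiles["Nat"](5000.0) == 0.0


def test_total_trunk_conductance_scales_with_length():
    a = build_reduced(600.0).discretize()
    b = build_reduced(300.0).discretize()
    assert a.total_conductance("trunk", "Nat") > b.total_conductance(
        "trunk", "Nat")


def test_hcn_scaling_modes():
    base = build_reduced(600.0)
    same = build_reduced(600.0, hcn_tuft_scale=1.0, hcn_trunk_mode="derived")
    for s in ("trunk", "tuft"):
        da = base.discretize().total_conductance(s, "HCN")
        db = same.discretize().total_conductance(s, "HCN")
        assert da == pytest.approx(db)

    indep = build_reduced(600.0, hcn_tuft_scale=0.0,
                          hcn_trunk_mode="independent")
    di = indep.discretize()
    assert di.total_conductance("tuft", "HCN") == 0.0
    assert di.total_conductance("trunk", "HCN") == pytest.approx(
        base.discretize().total_conductance("trunk", "HCN"))

    derived = build_reduced(600.0, hcn_tuft_scale=0.5,
                            hcn_trunk_mode="derived")
    dd = derived.discretize()
    p = load_default_params()
    prox = p["profiles"]["hcn"]["proximal"]
    tuft = p["tuft"]["hcn"]
    n = derived.section("trunk").n_compartments
    centers = (np.arange(n) + 0.5) * (600.0 / n)
    expect = prox + (0.5 * tuft - prox) * centers / 600.0
    area = math.pi * derived.section("trunk").diameter * (600.0 / n) * 1e-8
    assert dd.total_conductance("trunk", "HCN") == pytest.approx(
        float(np.sum(np.clip(expect, 0, None)) * area * 1e3), rel=1e-9)


def test_scale_hcn_api_identity():
    from ttl5sim.model import scale_hcn

    base = build_reduced(600.0)
    same = scale_hcn(base, 1.0, "derived")
    d0, d1 = base.discretize(), same.discretize()
    for s in ("trunk", "tuft"):
        assert d0.total_conductance(s, "HCN") == pytest.approx(
            d1.total_conductance(s, "HCN"))
    with pytest.raises(ValueError):
        scale_hcn(base, -1.0)


def test_unknown_knob_and_bounds():
    with pytest.raises(ValueError, match="unknown override"):
        build_reduced(600.0, nonsense_knob=2.0)
    with pytest.raises(ValueError, match="trunk_length"):
        build_reduced(10.0)
    with pytest.raises(ValueError, match="trunk_length"):
        build_reduced(5000.0)


def test_uniform_distribution_preserves_total():
    a = build_reduced(600.0).discretize()
    u = build_reduced(600.0, uniform_trunk_distributions=True).discretize()
    for chn in ("Nat", "Kfast", "Kslow", "HCN"):
        assert u.total_conductance("trunk", chn) == pytest.approx(
            a.total_conductance("trunk", chn), rel=1e-9)


@pytest.mark.parametrize("length", [200.0, 500.0, 800.0])
def test_intrinsic_properties_physiological(length):
    """R_in and sag stay in the physiological window across lengths."""
    from ttl5sim.metrics import passive_measures

    disc = build_reduced(length).discretize()
    out = passive_measures(disc)
    assert 20.0 <= out["input_resistance"] <= 150.0
    assert 0.0 <= out["sag"] <= 10.0
    assert out["rheobase"] > 0.0
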