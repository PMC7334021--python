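"""The reduced thick-tufted L5 pyramidal neuron.

Five electrotonic divisions — soma, axon (hillock + initial segment),
basal dendrite, apical trunk, apical tuft — each an equivalent cylinder.
Channel inventory and placement:

========  =========================================
channel   sections
========  =========================================
Nat       soma, hillock, AIS, trunk, tuft
Nap       soma
Kfast     soma, trunk, tuft
Kslow     soma, trunk, tuft
Km        soma
HCN       basal, trunk, tuft
CaHVA     tuft
CaLVA     tuft
KCa       tuft (driven by the tuft calcium pool)
========  =========================================

Along the apical trunk, Kfast and Kslow densities decay exponentially with
distance from the soma, Nat decays linearly (clipped at zero), and HCN
increases linearly from its proximal value to the tuft density at the
distal end of the trunk. When the trunk length changes, each trunk
compartment's density is re-evaluated at its new absolute distance from
the soma with the *same* profile parameters, so the total trunk
conductance changes with length while the spatial rule does not. Soma,
axon, basal and tuft parameters are length-invariant.

The default parameter set is the calibrated artifact shipped as
``calibrated_default.json``; the calibration procedure (resting potential,
trunk length constant, single-AP somatic pulse, BAC-firing and short-trunk
anchors) is scripted in ``scripts/calibrate.py``.

The trunk's passive DC length constant lambda = sqrt(d·R_m/(4·R_a)) is held
at its calibrated value by deriving the trunk diameter from (R_m, R_a,
lambda); trunk lengths are therefore directly comparable on the
electrotonic scale L/lambda.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from . import kernel as _kernel
from .cable import DiscretizedModel, SectionSpec, discretize
from .channels import CalciumPool, ChannelSpec

__all__ = [
    "DistributionProfile",
    "ReducedModelSpec",
    "build_reduced",
    "redistribute_trunk_conductances",
    "scale_hcn",
    "trunk_length_constant",
    "load_default_params",
    "KNOBS",
]

MIN_TRUNK_LENGTH = 50.0
MAX_TRUNK_LENGTH = 2000.0

#: recognized override knobs for :func:`build_reduced`
KNOBS = frozenset(
    {
        "g_ca_scale",
        "trunk_nat_scale",
        "hcn_tuft_scale",
        "hcn_trunk_mode",
        "trunk_ra",
        "tuft_cm",
        "uniform_trunk_distributions",
        "passive_trunk",
        "passive_tuft",
        "balance_leak",
        "v_rest",
    }
)


@dataclass(frozen=True)
class DistributionProfile:
    """Channel density as a pure function of distance from the soma (µm).

    shapes
    ------
    uniform      density(d) = anchor
    linear       density(d) = max(0, anchor - slope * d)
    exponential  density(d) = anchor * exp(-d / decay_length)
    ramp         density(d) = anchor + (distal_anchor - anchor) * d / span
                 (linear increase toward a distal target over ``span`` µm;
                 used for trunk HCN, whose distal target is the tuft value)
    """

    shape: str
    anchor: float  # mS/cm² at distance 0
    slope: float = 0.0  # mS/cm² per µm (linear)
    decay_length: float = 100.0  # µm (exponential)
    distal_anchor: float = 0.0  # mS/cm² (ramp)
    span: float = 1.0  # µm (ramp)
    floor: float = 0.0  # mS/cm² added everywhere (distance-independent)

    def __post_init__(self):
        if self.shape not in ("uniform", "linear", "exponential", "ramp"):
            raise ValueError(f"unknown profile shape {self.shape!r}")
        if self.shape == "exponential" and self.decay_length <= 0:
            raise ValueError("decay_length must be > 0")

    def __call__(self, distance) -> np.ndarray:
        d = np.asarray(distance, dtype=float)
        if self.shape == "uniform":
            out = np.full_like(d, self.anchor)
        elif self.shape == "linear":
            out = self.anchor - self.slope * d
        elif self.shape == "exponential":
            out = self.anchor * np.exp(-d / self.decay_length)
        else:
            out = self.anchor + (self.distal_anchor - self.anchor) * d / self.span
        return np.clip(out, 0.0, None) + self.floor


def load_default_params() -> dict:
    """The calibrated default parameter set (a fresh deep copy)."""
    with resources.files("ttl5sim").joinpath("calibrated_default.json").open() as f:
        return json.load(f)


def redistribute_trunk_conductances(
    profiles: dict[str, DistributionProfile],
    trunk_length: float,
    n_compartments: int,
) -> dict[str, np.ndarray]:
    """Per-compartment trunk densities after a trunk-length change.

    Each density is the profile evaluated at the compartment center's
    absolute distance from the soma, so the value at a fixed distance is
    length-invariant while the trunk's total conductance scales with its
    length.
    """
    centers = (np.arange(n_compartments) + 0.5) * (trunk_length / n_compartments)
    return {name: prof(centers) for name, prof in profiles.items()}


def scale_hcn(
    spec: "ReducedModelSpec",
    tuft_scale: float,
    trunk_mode: str = "independent",
) -> "ReducedModelSpec":
    """Rebuild a model with scaled tuft HCN density.

    In ``independent`` mode the trunk HCN ramp keeps targeting the
    unscaled (100%) tuft density; in ``derived`` mode the ramp target is
    the scaled tuft density. Other knobs of ``spec`` are preserved.
    """
    if tuft_scale < 0:
        raise ValueError("tuft_scale must be >= 0")
    knobs = dict(spec.knobs)
    knobs["hcn_tuft_scale"] = float(tuft_scale)
    knobs["hcn_trunk_mode"] = trunk_mode
    return build_reduced(spec.trunk_length, params=spec.params, **knobs)


def trunk_length_constant(spec: "ReducedModelSpec") -> float:
    """Passive DC space constant of the apical trunk, in µm."""
    return spec.section("trunk").length_constant()


@dataclass
class ReducedModelSpec:
    """A fully parameterized reduced model (sections + knob record)."""

    sections: list[SectionSpec]
    trunk_length: float
    knobs: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def section(self, name: str) -> SectionSpec:
        for s in self.sections:
            if s.name == name:
                return s
        raise KeyError(name)

    def discretize(self) -> DiscretizedModel:
        return discretize(self.sections)

    @property
    def v_rest(self) -> float:
        return self.knobs.get("v_rest", self.params.get("v_rest", -65.0))


def _trunk_profiles(p: dict, knobs: dict) -> dict[str, DistributionProfile]:
    prof = p["profiles"]
    nat_scale = knobs.get("trunk_nat_scale", 1.0)
    tuft_scale = knobs.get("hcn_tuft_scale", 1.0)
    mode = knobs.get("hcn_trunk_mode", "independent")
    if mode not in ("independent", "derived"):
        raise ValueError("hcn_trunk_mode must be 'independent' or 'derived'")
    # trunk HCN ramps from its proximal value to the tuft density at the
    # distal trunk end; in 'independent' mode the ramp target is the
    # unscaled (100%) tuft density even when the tuft itself is scaled.
    hcn_target = p["tuft"]["hcn"] * (tuft_scale if mode == "derived" else 1.0)
    trunk_length = knobs["_trunk_length"]
    return {
        "Nat": DistributionProfile(
            "linear",
            anchor=prof["nat"]["anchor"] * nat_scale,
            slope=prof["nat"]["anchor"] * nat_scale / prof["nat"]["zero_at"],
        ),
        "Kfast": DistributionProfile(
            "exponential",
            anchor=prof["kfast"]["anchor"],
            decay_length=prof["kfast"]["decay_length"],
        ),
        "Kslow": DistributionProfile(
            "exponential",
            anchor=prof["kslow"]["anchor"],
            decay_length=prof["kslow"]["decay_length"],
            floor=prof["kslow"].get("floor", 0.0),
        ),
        "HCN": DistributionProfile(
            "ramp",
            anchor=prof["hcn"]["proximal"],
            distal_anchor=hcn_target,
            span=trunk_length,
        ),
    }


def build_reduced(trunk_length: float = 600.0, **overrides) -> ReducedModelSpec:
    """Build the reduced ttL5 model at a given apical-trunk length.

    Only the trunk geometry and the redistributed trunk channel densities
    depend on ``trunk_length``; every other parameter is length-invariant.

    Overrides (knobs)
    -----------------
    g_ca_scale : float, default 1
        Scales CaHVA and CaLVA together (ratio kept constant); 1 is the
        calibrated total tuft Ca2+ density (~0.45 mS/cm²).
    trunk_nat_scale : float, default 1
        Scales the trunk Nat linear profile (0 removes trunk Na+).
    hcn_tuft_scale, hcn_trunk_mode : float / {'independent', 'derived'}
        Scale tuft HCN; the trunk HCN ramp target is the unscaled tuft
        density in 'independent' mode, the scaled one in 'derived' mode.
    trunk_ra : float
        Trunk axial resistivity override (Ω·cm); changes the trunk length
        constant accordingly.
    tuft_cm : float
        Tuft specific capacitance (µF/cm²), default ~1.75.
    uniform_trunk_distributions : bool
        Replace every trunk gradient by its spatial mean over the trunk
        (total trunk conductance preserved at this length).
    passive_trunk / passive_tuft : bool
        Remove all active conductances from the trunk / the tuft.
    balance_leak : bool, default True
        Adjust each compartment's leak reversal so the resting state is an
        exact fixed point at ``v_rest``.
    v_rest : float, default -65 mV.

    `params` may also be passed (a full parameter dict as returned by
    :func:`load_default_params`) to build from a non-default calibration.
    """
    params = overrides.pop("params", None)
    unknown = set(overrides) - KNOBS
    if unknown:
        raise ValueError(f"unknown override knob(s): {sorted(unknown)}")
    if not MIN_TRUNK_LENGTH <= trunk_length <= MAX_TRUNK_LENGTH:
        raise ValueError(
            f"trunk_length {trunk_length} outside "
            f"[{MIN_TRUNK_LENGTH}, {MAX_TRUNK_LENGTH}] µm"
        )
    p = copy.deepcopy(params) if params is not None else load_default_params()
    knobs = dict(overrides)
    knobs["_trunk_length"] = float(trunk_length)

    v_rest = knobs.get("v_rest", p["v_rest"])
    geo = p["geometry"]
    pas = p["passive"]
    dens = p["densities"]
    cpar = p.get("channel_params", {})

    tpar = p.get("trunk_channel_params", {})

    def chan(name, density):
        return ChannelSpec(name, density, params=cpar.get(name, {}))

    def trunk_chan(name, density):
        merged = {**cpar.get(name, {}), **tpar.get(name, {})}
        return ChannelSpec(name, density, params=merged)

    # trunk diameter from the calibrated length-constant target
    ra_trunk = knobs.get("trunk_ra", pas["trunk_ra"])
    lam_cm = p["trunk_lambda_target"] * 1e-4
    rm_trunk_ohm = pas["trunk_rm"] * 1e3  # kΩ·cm² -> Ω·cm²
    trunk_diam_um = 4.0 * pas["trunk_ra"] * lam_cm**2 / rm_trunk_ohm * 1e4

    n_trunk = max(1, math.ceil(trunk_length / geo["trunk"]["dx"]))
    profiles = _trunk_profiles(p, knobs)
    trunk_dens = redistribute_trunk_conductances(profiles, trunk_length, n_trunk)
    if knobs.get("uniform_trunk_distributions"):
        trunk_dens = {
            k: np.full(n_trunk, v.mean()) for k, v in trunk_dens.items()
        }
    if knobs.get("passive_trunk"):
        trunk_dens = {k: np.zeros(n_trunk) for k in trunk_dens}

    gca = knobs.get("g_ca_scale", 1.0)
    if gca < 0:
        raise ValueError("g_ca_scale must be >= 0")
    tuft = p["tuft"]
    ca_total = tuft["ca_total"]
    hva = ca_total * tuft["hva_fraction"] * gca
    lva = ca_total * (1.0 - tuft["hva_fraction"]) * gca

    tuft_mechs = [
        chan("Nat", tuft["nat"]),
        chan("Kfast", tuft["kfast"]),
        chan("Kslow", tuft["kslow"]),
        chan("HCN", tuft["hcn"] * knobs.get("hcn_tuft_scale", 1.0)),
        chan("CaHVA", hva),
        chan("CaLVA", lva),
        chan("KCa", tuft["kca"]),
    ]
    if knobs.get("passive_tuft"):
        tuft_mechs = []
    pool = CalciumPool(
        concentration=tuft["pool"]["rest"],
        resting_concentration=tuft["pool"]["rest"],
        decay_time_constant=tuft["pool"]["tau"],
        current_to_concentration_scale=tuft["pool"]["phi"],
        external_concentration=tuft["pool"].get("ca_o", 2.0),
    )

    sections = [
        SectionSpec(
            "soma",
            length=geo["soma"]["length"],
            diameter=geo["soma"]["diameter"],
            axial_resistivity=pas["ra"],
            specific_capacitance=pas["cm"],
            leak_conductance=1.0 / pas["soma_rm"],
            leak_reversal=v_rest,
            n_compartments=geo["soma"]["n"],
            mechanisms=[
                chan("Nat", dens["soma_nat"]),
                chan("Nap", dens["soma_nap"]),
                chan("Kfast", dens["soma_kfast"]),
                chan("Kslow", dens["soma_kslow"]),
                chan("Km", dens["soma_km"]),
            ],
        ),
        SectionSpec(
            "hillock",
            length=geo["hillock"]["length"],
            diameter=geo["hillock"]["diameter"],
            axial_resistivity=pas["ra"],
            specific_capacitance=pas["cm"],
            leak_conductance=1.0 / pas["axon_rm"],
            leak_reversal=v_rest,
            n_compartments=geo["hillock"]["n"],
            parent="soma",
            mechanisms=[chan("Nat", dens["hillock_nat"])],
        ),
        SectionSpec(
            "ais",
            length=geo["ais"]["length"],
            diameter=geo["ais"]["diameter"],
            axial_resistivity=pas["ra"],
            specific_capacitance=pas["cm"],
            leak_conductance=1.0 / pas["axon_rm"],
            leak_reversal=v_rest,
            n_compartments=geo["ais"]["n"],
            parent="hillock",
            mechanisms=[chan("Nat", dens["ais_nat"])],
        ),
        SectionSpec(
            "basal",
            length=geo["basal"]["length"],
            diameter=geo["basal"]["diameter"],
            axial_resistivity=pas["ra"],
            specific_capacitance=pas["cm"],
            leak_conductance=1.0 / pas["basal_rm"],
            leak_reversal=v_rest,
            n_compartments=geo["basal"]["n"],
            parent="soma",
            mechanisms=[chan("HCN", dens["basal_hcn"])],
        ),
        SectionSpec(
            "trunk",
            length=trunk_length,
            diameter=trunk_diam_um,
            axial_resistivity=ra_trunk,
            specific_capacitance=pas["cm"],
            leak_conductance=1.0 / pas["trunk_rm"],
            leak_reversal=v_rest,
            n_compartments=n_trunk,
            parent="soma",
            mechanisms=[
                (trunk_chan(name, 0.0), trunk_dens[name]) for name in trunk_dens
            ],
        ),
        SectionSpec(
            "tuft",
            length=geo["tuft"]["length"],
            diameter=geo["tuft"]["diameter"],
            axial_resistivity=pas.get("tuft_ra", pas["ra"]),
            specific_capacitance=knobs.get("tuft_cm", pas["tuft_cm"]),
            leak_conductance=1.0 / pas["tuft_rm"],
            leak_reversal=v_rest,
            n_compartments=geo["tuft"]["n"],
            parent="trunk",
            mechanisms=tuft_mechs,
            calcium_pool=pool if not knobs.get("passive_tuft") else None,
        ),
    ]

    spec = ReducedModelSpec(
        sections=sections,
        trunk_length=float(trunk_length),
        knobs={k: v for k, v in knobs.items() if not k.startswith("_")},
        params=p,
    )
    if knobs.get("balance_leak", True):
        _balance_leak(spec, v_rest)
    return spec


def _balance_leak(spec: ReducedModelSpec, v_rest: float) -> None:
    """Set per-compartment leak reversals so V = v_rest is a fixed point.

    With every gate at its steady state for v_rest and the calcium pool at
    rest, the leak is chosen to cancel the residual channel current in each
    compartment, making the uniform resting state exact (no settling
    transient, rest independent of trunk length or knob settings).
    """
    disc = spec.discretize()
    v = np.full(disc.n, v_rest)
    gstate = _kernel.init_gates(
        disc.ch_type, disc.ch_off, disc.ch_comp, disc.ch_params, v, disc.ca_rest
    )
    from .channels import CAHVA, CALVA

    residual = np.zeros(disc.n)  # nA of channel current at rest
    for k in range(len(disc.ch_type)):
        t = disc.ch_type[k]
        e = disc.ch_erev[k]
        for j in range(disc.ch_off[k], disc.ch_off[k + 1]):
            i = disc.ch_comp[j]
            ech = e
            if t in (CAHVA, CALVA) and disc.ca_out[i] > 0:
                ech = 13.27 * math.log(disc.ca_out[i] / max(disc.ca_rest[i], 1e-6))
            op = _kernel._open_fraction(t, gstate[j, 0], gstate[j, 1])
            residual[i] += disc.ch_gbar[j] * op * (v_rest - ech)
    # e_leak_i = v_rest + residual_i / g_leak_i, applied per section as a
    # per-compartment reversal (stored back on the section specs)
    for s in spec.sections:
        sl = disc.section_slice(s.name)
        gpas = disc.gpas[sl]
        epas = v_rest + residual[sl] / gpas
        s.leak_reversal = epas if len(epas) > 1 else float(epas[0])
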