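"""Membrane mechanisms for the reduced thick-tufted L5 neuron.

The channel inventory follows the model's fixed set: transient and
persistent Na+ (Nat, Nap), fast and slow voltage-gated K+ (Kfast, Kslow),
muscarinic K+ (Km), hyperpolarization-activated cation (HCN), high- and
low-voltage-activated Ca2+ (CaHVA, CaLVA), Ca2+-activated K+ (KCa), plus a
first-order intracellular calcium pool with extrusion.

Rate equations are standard Hodgkin-Huxley-style formulations for each
channel class (Hay-type for Na/Ca/Km/HCN, Kv3.1/K_Pst-style for the two K+
classes); the voltage dependence of every gate can be shifted and its
kinetics scaled through named parameters, and the model calibration pins
the behaviour to the electrophysiological anchors. Temperature dependence
is absorbed into the rate constants at the calibrated reference (q10
scaling is not exposed).

Units: mV, ms, mM, mS/cm². Gate dynamics follow
``dx/dt = (x_inf(V) - x)/tau_x(V)``, advanced by exact exponential
relaxation over a step (the voltage is held during the sub-step, i.e. the
classic staggered update).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._compat import maybe_njit

__all__ = [
    "ChannelSpec",
    "CalciumPool",
    "CHANNEL_NAMES",
    "channel",
    "gate_equilibrium",
    "advance_gates",
    "advance_calcium",
]

# integer type ids used by the integration kernel
NAT, NAP, KFAST, KSLOW, KM, HCN, CAHVA, CALVA, KCA = range(1, 10)

CHANNEL_NAMES = {
    "Nat": NAT,
    "Nap": NAP,
    "Kfast": KFAST,
    "Kslow": KSLOW,
    "Km": KM,
    "HCN": HCN,
    "CaHVA": CAHVA,
    "CaLVA": CALVA,
    "KCa": KCA,
}
_ID_TO_NAME = {v: k for k, v in CHANNEL_NAMES.items()}

# (gate names, gate exponents) per type
GATE_TABLE = {
    NAT: (("m", "h"), (3, 1)),
    NAP: (("m",), (1,)),
    KFAST: (("m",), (1,)),
    KSLOW: (("m",), (2,)),
    KM: (("m",), (1,)),
    HCN: (("m",), (1,)),
    CAHVA: (("m", "h"), (2, 1)),
    CALVA: (("m", "h"), (2, 1)),
    KCA: (("z",), (1,)),
}

MAX_GATES = 2
N_PARAMS = 4

#: default named parameters per channel class. ``vshift`` (mV) shifts every
#: gate's voltage dependence (positive = rightward/depolarized), and
#: ``rate_scale`` multiplies all rates (divides time constants). KCa instead
#: exposes its calcium dose-response: half-activation (mM), Hill coefficient
#: and a fixed time constant (ms).
DEFAULT_PARAMS = {
    "Nat": {"vshift": 0.0, "rate_scale": 1.0, "h_shift": 0.0},
    "Nap": {"vshift": 0.0, "rate_scale": 1.0},
    "Kfast": {"vshift": 0.0, "rate_scale": 1.0},
    "Kslow": {"vshift": 0.0, "rate_scale": 1.0},
    "Km": {"vshift": 0.0, "rate_scale": 1.0},
    "HCN": {"vshift": 0.0, "rate_scale": 1.0},
    "CaHVA": {"vshift": 0.0, "rate_scale": 1.0, "h_shift": 0.0},
    "CaLVA": {"vshift": 0.0, "rate_scale": 1.0, "h_shift": 0.0, "m_slope": 6.0},
    "KCa": {"ca_half": 4.3e-4, "hill": 4.8, "tau": 1.0},
}

DEFAULT_REVERSAL = {
    "Nat": 50.0,
    "Nap": 50.0,
    "Kfast": -85.0,
    "Kslow": -85.0,
    "Km": -85.0,
    "HCN": -45.0,
    "CaHVA": 120.0,  # fixed Ca reversal; not Nernst-updated
    "CaLVA": 120.0,
    "KCa": -85.0,
}

_QT = 2.95  # 2.3 ** ((34 - 21) / 10), folded into the Hay-style rates


@dataclass(frozen=True)
class ChannelSpec:
    """One membrane conductance: kinetics class + density + reversal."""

    name: str
    max_conductance_density: float  # mS/cm²
    reversal_potential: float | None = None  # mV; None -> class default
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in CHANNEL_NAMES:
            raise KeyError(
                f"unknown channel {self.name!r}; known: {sorted(CHANNEL_NAMES)}"
            )
        if self.max_conductance_density < 0:
            raise ValueError("conductance density must be >= 0")
        unknown = set(self.params) - set(DEFAULT_PARAMS[self.name])
        if unknown:
            raise KeyError(f"unknown parameter(s) for {self.name}: {sorted(unknown)}")

    @property
    def type_id(self) -> int:
        return CHANNEL_NAMES[self.name]

    @property
    def gates(self) -> tuple[str, ...]:
        return GATE_TABLE[self.type_id][0]

    @property
    def gate_exponents(self) -> tuple[int, ...]:
        return GATE_TABLE[self.type_id][1]

    @property
    def erev(self) -> float:
        if self.reversal_potential is not None:
            return float(self.reversal_potential)
        return DEFAULT_REVERSAL[self.name]

    def param_vector(self) -> np.ndarray:
        merged = {**DEFAULT_PARAMS[self.name], **self.params}
        vec = np.zeros(N_PARAMS)
        if self.name == "KCa":
            vec[0] = merged["ca_half"]
            vec[1] = merged["hill"]
            vec[2] = merged["tau"]
        else:
            vec[0] = merged["vshift"]
            vec[1] = merged["rate_scale"]
            vec[2] = merged.get("h_shift", 0.0)
            vec[3] = merged.get("m_slope", 6.0)
        return vec

    def with_density(self, density: float) -> "ChannelSpec":
        return replace(self, max_conductance_density=float(density))


def channel(name: str, density: float, **params) -> ChannelSpec:
    """Convenience constructor: ``channel("Nat", 100.0, vshift=2.0)``."""
    erev = params.pop("reversal_potential", None)
    return ChannelSpec(name, density, erev, params)


# ---------------------------------------------------------------------------
# rate functions (scalar; njit-compatible, shared by API and kernel)
# ---------------------------------------------------------------------------


@maybe_njit
def _vtrap(x, y):
    """x / (exp(x/y) - 1) with the removable singularity handled."""
    if abs(x / y) < 1e-6:
        return y * (1.0 - x / y / 2.0)
    return x / (math.exp(x / y) - 1.0)


@maybe_njit
def _gate_rates(type_id, gate_idx, v, p, ca):
    """Return (steady_state, time_constant_ms) for one gate.

    ``p`` is the 4-slot parameter vector of the channel instance and ``ca``
    the local calcium concentration in mM (used by KCa only).
    """
    if type_id == KCA:
        ca_half, hill, tau = p[0], p[1], p[2]
        c = ca if ca > 1e-12 else 1e-12
        zinf = 1.0 / (1.0 + (ca_half / c) ** hill)
        return zinf, tau

    vs = v - p[0]
    rs = p[1]
    if type_id == NAT:
        if gate_idx == 0:
            a = 0.182 * _vtrap(-(vs + 38.0), 6.0)
            b = 0.124 * _vtrap(vs + 38.0, 6.0)
            a, b = a * _QT * rs, b * _QT * rs
            return a / (a + b), 1.0 / (a + b)
        vh = vs - p[2]  # inactivation-gate shift (dendritic Na)
        a = 0.015 * _vtrap(vh + 66.0, 6.0)
        b = 0.015 * _vtrap(-(vh + 66.0), 6.0)
        a, b = a * _QT * rs, b * _QT * rs
        return a / (a + b), 1.0 / (a + b)
    if type_id == NAP:
        minf = 1.0 / (1.0 + math.exp(-(vs + 52.6) / 4.6))
        return minf, 2.0 / rs
    if type_id == KFAST:
        minf = 1.0 / (1.0 + math.exp(-(vs - 18.7) / 9.7))
        tau = 4.0 / (1.0 + math.exp((vs + 46.6) / 44.1)) / rs
        return minf, tau
    if type_id == KSLOW:
        minf = 1.0 / (1.0 + math.exp(-(vs + 11.0) / 12.0))
        if vs < -50.0:
            tau = (1.25 + 175.03 * math.exp(0.026 * vs)) / _QT / rs
        else:
            tau = (1.25 + 13.0 * math.exp(-0.026 * vs)) / _QT / rs
        return minf, tau
    if type_id == KM:
        a = 3.3e-3 * math.exp(0.1 * (vs + 35.0)) * rs
        b = 3.3e-3 * math.exp(-0.1 * (vs + 35.0)) * rs
        return a / (a + b), 1.0 / (a + b) / _QT
    if type_id == HCN:
        a = 6.43e-3 * _vtrap(vs + 154.9, 11.9) * rs
        b = 0.193 * math.exp(vs / 33.1) * rs
        return a / (a + b), 1.0 / (a + b)
    if type_id == CAHVA:
        if gate_idx == 0:
            a = 0.055 * _vtrap(-(27.0 + vs), 3.8) * rs
            b = 0.94 * math.exp((-75.0 - vs) / 17.0) * rs
            return a / (a + b), 1.0 / (a + b)
        vh = vs - p[2]  # extra inactivation-gate shift
        a = 4.57e-4 * math.exp((-13.0 - vh) / 50.0) * rs
        b = 6.5e-3 / (math.exp((-vh - 15.0) / 28.0) + 1.0) * rs
        return a / (a + b), 1.0 / (a + b)
    if type_id == CALVA:
        if gate_idx == 0:
            slope = p[3] if p[3] > 0.0 else 6.0
            minf = 1.0 / (1.0 + math.exp(-(vs + 40.0) / slope))
            tau = (5.0 + 20.0 / (1.0 + math.exp((vs + 35.0) / 5.0))) / _QT / rs
            return minf, tau
        vh = vs - p[2]
        hinf = 1.0 / (1.0 + math.exp((vh + 90.0) / 6.4))
        tau = (20.0 + 50.0 / (1.0 + math.exp((vh + 50.0) / 7.0))) / _QT / rs
        return hinf, tau
    # unreachable for valid ids; return inert values
    return 0.0, 1.0


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def gate_equilibrium(
    chan: ChannelSpec, gate: str, v: float, ca: float = 1e-4
) -> tuple[float, float]:
    """Steady state (in [0, 1]) and time constant (ms) of one gate at fixed V.

    For KCa the voltage is ignored and ``ca`` (mM) drives the gate.
    """
    if not math.isfinite(v):
        raise ValueError("V must be finite")
    try:
        gate_idx = chan.gates.index(gate)
    except ValueError:
        raise KeyError(f"channel {chan.name} has no gate {gate!r}") from None
    inf, tau = _gate_rates(chan.type_id, gate_idx, float(v), chan.param_vector(), ca)
    return float(inf), float(tau)


def advance_gates(
    state: dict[str, float], chan: ChannelSpec, v: float, dt: float, ca: float = 1e-4
) -> dict[str, float]:
    """Advance all gates of one channel by exact exponential relaxation."""
    out = {}
    for g in chan.gates:
        inf, tau = gate_equilibrium(chan, g, v, ca)
        out[g] = inf + (state[g] - inf) * math.exp(-dt / tau)
    return out


@dataclass
class CalciumPool:
    """First-order intracellular Ca2+ pool: influx from I_Ca, extrusion to rest.

    d[Ca]/dt = -scale * I_Ca - ([Ca] - resting) / tau

    ``current_to_concentration_scale`` converts an inward (negative) Ca2+
    current density in mA/cm² into a concentration rate in mM/ms; it encodes
    the effective shell depth (scale = 1 / (2 F depth) in consistent units).
    """

    concentration: float = 1e-4  # mM
    resting_concentration: float = 1e-4  # mM
    decay_time_constant: float = 80.0  # ms
    current_to_concentration_scale: float = 5.18e-3  # mM cm² / (ms mA); 0.1 µm shell
    #: extracellular Ca2+ (mM); if > 0, Ca channel reversals in pooled
    #: compartments are Nernst-derived from the pool, else fixed at the
    #: ChannelSpec reversal
    external_concentration: float = 2.0

    def __post_init__(self):
        if self.concentration < 0 or self.resting_concentration < 0:
            raise ValueError("calcium concentration must be >= 0")
        if self.decay_time_constant <= 0:
            raise ValueError("decay time constant must be > 0")


def advance_calcium(pool: CalciumPool, i_ca: float, dt: float) -> CalciumPool:
    """Advance the pool one step (exact exponential update at fixed I_Ca)."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    tau = pool.decay_time_constant
    target = pool.resting_concentration - pool.current_to_concentration_scale * tau * i_ca
    ca = target + (pool.concentration - target) * math.exp(-dt / tau)
    return replace(pool, concentration=max(ca, 0.0))
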