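"""Spatial discretization and simulation of a branched passive/active cable.

A neuron is a tree of cylindrical sections. Each section is split into
``n_compartments`` iso-potential compartments; the membrane of each carries
a leak plus any number of voltage- (or calcium-) gated conductances from
:mod:`ttl5sim.channels`, and neighbouring compartments are coupled through
axial resistances. The voltage is advanced with an implicit (backward
Euler) step and a staggered exact-exponential gate update, which is
unconditionally stable for passive membranes and robust for stiff spikes.

Unit conventions (fixed package-wide): mV, ms, nA, µm, µF/cm², mS/cm²,
Ω·cm. Internally compartment capacitance is held in nF and conductances in
µS, so that g·V is directly in nA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .channels import CalciumPool, ChannelSpec
from . import kernel as _kernel

__all__ = [
    "SectionSpec",
    "StimulusEvent",
    "Trace",
    "DiscretizedModel",
    "discretize",
    "simulate",
    "simulate_clamped",
    "CableStructureError",
    "NumericalError",
]

DEFAULT_DT = 0.025  # ms
DIVERGENCE_LIMIT = 500.0  # mV; fail fast on unstable parameter sets


class CableStructureError(ValueError):
    """Section graph is not a rooted tree, or a site cannot be resolved."""


class NumericalError(RuntimeError):
    """The integrator produced a divergent (|V| > 500 mV) or NaN state."""


@dataclass
class SectionSpec:
    """One cylindrical section of the neuron.

    ``mechanisms`` is a list of :class:`ChannelSpec`, optionally paired with
    a per-compartment density array (mS/cm²) overriding the ChannelSpec's scalar
    density: ``[nat_spec, (kfast_spec, densities)]``.
    """

    name: str
    length: float  # µm
    diameter: float  # µm
    axial_resistivity: float = 150.0  # Ω·cm
    specific_capacitance: float = 1.0  # µF/cm²
    leak_conductance: float = 1 / 15.0  # mS/cm²  (R_m = 15 kΩ·cm²)
    leak_reversal: float = -65.0  # mV
    n_compartments: int | None = None  # default: ceil(length / 10 µm)
    parent: str | None = None
    mechanisms: list = field(default_factory=list)
    calcium_pool: CalciumPool | None = None

    def __post_init__(self):
        if self.length <= 0 or self.diameter <= 0:
            raise ValueError(f"section {self.name}: geometry must be positive")
        if self.axial_resistivity <= 0 or self.specific_capacitance <= 0:
            raise ValueError(f"section {self.name}: R_a and C_m must be positive")
        if self.n_compartments is None:
            self.n_compartments = max(1, math.ceil(self.length / 10.0))
        if self.n_compartments < 1:
            raise ValueError(f"section {self.name}: n_compartments must be >= 1")

    @property
    def membrane_resistivity(self) -> float:
        """R_m in kΩ·cm² (reciprocal of the leak density)."""
        return 1.0 / self.leak_conductance

    def length_constant(self) -> float:
        """Passive DC space constant λ = sqrt(d·R_m/(4·R_a)), in µm."""
        d_cm = self.diameter * 1e-4
        rm = self.membrane_resistivity * 1e3  # Ω·cm²
        lam_cm = math.sqrt(d_cm * rm / (4.0 * self.axial_resistivity))
        return lam_cm * 1e4


@dataclass
class StimulusEvent:
    """A stimulus at a site ``(section_name, x)`` with x ∈ [0, 1] (0 =
    proximal/parent end, 1 = distal end).

    Kinds
    -----
    current_step
        Constant ``amplitude`` nA over [onset, onset + duration).
    epsc_like
        Difference-of-exponentials current, peak-normalized to ``amplitude``
        nA, with time constants ``rise`` and ``decay`` (ms).
    pulse_train
        ``count`` square pulses of width ``duration`` at ``frequency`` Hz.
    voltage_command
        Square voltage-clamp command: ``v_hold + amplitude`` mV during
        [onset, onset + duration), ``v_hold`` otherwise (``amplitude`` is
        relative to the holding/resting level).
    """

    site: tuple[str, float]
    kind: str
    onset: float  # ms
    amplitude: float  # nA (current kinds) or mV relative to hold (voltage)
    duration: float = 1.0  # ms (pulse width for pulse_train)
    rise: float = 1.0  # ms, epsc_like
    decay: float = 5.0  # ms, epsc_like
    frequency: float = 100.0  # Hz, pulse_train
    count: int = 1  # pulses, pulse_train

    _KINDS = ("current_step", "epsc_like", "pulse_train", "voltage_command")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.onset < 0 or self.duration <= 0:
            raise ValueError("onset must be >= 0 and duration > 0")
        if self.kind == "pulse_train" and (self.frequency <= 0 or self.count < 1):
            raise ValueError("pulse_train needs frequency > 0 and count >= 1")
        if self.kind == "epsc_like" and not 0 < self.rise < self.decay:
            raise ValueError("epsc_like needs 0 < rise < decay")

    def waveform(self, t: np.ndarray, v_hold: float = 0.0) -> np.ndarray:
        """Evaluate the stimulus on time grid ``t`` (ms)."""
        w = np.zeros_like(t)
        if self.kind == "current_step":
            w[(t >= self.onset) & (t < self.onset + self.duration)] = self.amplitude
        elif self.kind == "epsc_like":
            s = t - self.onset
            m = s >= 0
            tr, td = self.rise, self.decay
            shape = np.exp(-s[m] / td) - np.exp(-s[m] / tr)
            tpk = tr * td / (td - tr) * math.log(td / tr)
            peak = math.exp(-tpk / td) - math.exp(-tpk / tr)
            w[m] = self.amplitude * shape / peak
        elif self.kind == "pulse_train":
            period = 1000.0 / self.frequency
            for k in range(self.count):
                t0 = self.onset + k * period
                w[(t >= t0) & (t < t0 + self.duration)] = self.amplitude
        else:  # voltage_command
            w[:] = v_hold
            w[(t >= self.onset) & (t < self.onset + self.duration)] = (
                v_hold + self.amplitude
            )
        return w


@dataclass
class Trace:
    """Multi-site voltage time series with a fixed step."""

    dt: float
    duration: float
    sites: list[str]
    values: dict[str, np.ndarray]
    currents: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def time(self) -> np.ndarray:
        n = round(self.duration / self.dt)
        return np.arange(n + 1) * self.dt

    def __getitem__(self, site: str) -> np.ndarray:
        return self.values[site]

    def n_samples(self) -> int:
        return round(self.duration / self.dt) + 1


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------


class DiscretizedModel:
    """Flat-array form of a section tree, ready for the integration kernel."""

    def __init__(self, sections: Sequence[SectionSpec]):
        by_name = {}
        for s in sections:
            if s.name in by_name:
                raise CableStructureError(f"duplicate section name {s.name!r}")
            by_name[s.name] = s
        roots = [s for s in sections if s.parent is None]
        if len(roots) != 1:
            raise CableStructureError(
                f"need exactly one root section, found {len(roots)}"
            )
        for s in sections:
            if s.parent is not None and s.parent not in by_name:
                raise CableStructureError(
                    f"section {s.name!r} has unknown parent {s.parent!r}"
                )

        # topological order (parents first); also detects cycles
        order: list[SectionSpec] = []
        placed = set()
        pending = list(sections)
        while pending:
            progressed = False
            for s in list(pending):
                if s.parent is None or s.parent in placed:
                    order.append(s)
                    placed.add(s.name)
                    pending.remove(s)
                    progressed = True
            if not progressed:
                raise CableStructureError("cycle in section parent links")

        self.sections = {s.name: s for s in order}
        self._sec_start: dict[str, int] = {}

        n_total = sum(s.n_compartments for s in order)
        self.n = n_total
        self.parent = np.full(n_total, -1, dtype=np.int64)
        self.area = np.zeros(n_total)  # cm²
        self.cm = np.zeros(n_total)  # nF
        self.gpas = np.zeros(n_total)  # µS
        self.epas = np.zeros(n_total)  # mV
        self.gax = np.zeros(n_total)  # µS, coupling to parent compartment

        idx = 0
        for s in order:
            self._sec_start[s.name] = idx
            nc = s.n_compartments
            dx_cm = (s.length / nc) * 1e-4
            r_cm = (s.diameter / 2.0) * 1e-4
            a = math.pi * s.diameter * (s.length / nc) * 1e-8  # cm² per comp
            # half-compartment axial resistance, in MΩ (so 1/R is µS)
            r_half = s.axial_resistivity * (dx_cm / 2.0) / (math.pi * r_cm**2) * 1e-6
            for k in range(nc):
                i = idx + k
                self.area[i] = a
                self.cm[i] = s.specific_capacitance * a * 1e3
                self.gpas[i] = s.leak_conductance * a * 1e3
                erev = s.leak_reversal
                self.epas[i] = (
                    float(np.asarray(erev)[k]) if np.ndim(erev) else erev
                )
                if k > 0:
                    self.parent[i] = i - 1
                    self.gax[i] = 1.0 / (2.0 * r_half)
                elif s.parent is not None:
                    p = by_name[s.parent]
                    pi = self._sec_start[p.name] + p.n_compartments - 1
                    p_dx_cm = (p.length / p.n_compartments) * 1e-4
                    p_r_cm = (p.diameter / 2.0) * 1e-4
                    p_half = (
                        p.axial_resistivity
                        * (p_dx_cm / 2.0)
                        / (math.pi * p_r_cm**2)
                        * 1e-6
                    )
                    self.parent[i] = pi
                    self.gax[i] = 1.0 / (r_half + p_half)
            idx += nc

        # channel instances -> flat arrays
        ch_type, ch_erev, ch_params = [], [], []
        ch_off = [0]
        comp_idx, gbar, gdens = [], [], []
        for s in order:
            start = self._sec_start[s.name]
            nc = s.n_compartments
            for mech in s.mechanisms:
                if isinstance(mech, ChannelSpec):
                    spec, dens = mech, np.full(nc, mech.max_conductance_density)
                else:
                    spec, dens = mech
                    dens = np.asarray(dens, dtype=float)
                    if dens.shape != (nc,):
                        raise ValueError(
                            f"{s.name}/{spec.name}: density array must have "
                            f"length n_compartments={nc}"
                        )
                if np.any(dens < 0):
                    raise ValueError(f"{s.name}/{spec.name}: negative density")
                ch_type.append(spec.type_id)
                ch_erev.append(spec.erev)
                ch_params.append(spec.param_vector())
                for k in range(nc):
                    comp_idx.append(start + k)
                    gdens.append(dens[k])
                    gbar.append(dens[k] * self.area[start + k] * 1e3)  # µS
                ch_off.append(len(comp_idx))

        self.ch_type = np.array(ch_type, dtype=np.int64)
        self.ch_erev = np.array(ch_erev, dtype=float)
        self.ch_params = (
            np.vstack(ch_params) if ch_params else np.zeros((0, 4))
        )
        self.ch_off = np.array(ch_off, dtype=np.int64)
        self.ch_comp = np.array(comp_idx, dtype=np.int64)
        self.ch_gbar = np.array(gbar, dtype=float)
        self.ch_gdens = np.array(gdens, dtype=float)

        # calcium pools
        self.has_pool = np.zeros(n_total, dtype=np.bool_)
        self.ca_rest = np.full(n_total, 1e-4)
        self.ca_tau = np.ones(n_total)
        self.ca_phi = np.zeros(n_total)
        self.ca_out = np.zeros(n_total)  # 0 -> fixed Ca reversal
        for s in order:
            if s.calcium_pool is not None:
                pool = s.calcium_pool
                sl = slice(
                    self._sec_start[s.name],
                    self._sec_start[s.name] + s.n_compartments,
                )
                self.has_pool[sl] = True
                self.ca_rest[sl] = pool.resting_concentration
                self.ca_tau[sl] = pool.decay_time_constant
                self.ca_phi[sl] = pool.current_to_concentration_scale
                self.ca_out[sl] = pool.external_concentration

    # -- site resolution ----------------------------------------------------

    def comp_index(self, section: str, x: float) -> int:
        """Compartment whose center is nearest to normalized position x."""
        if section not in self.sections:
            raise CableStructureError(f"unknown section {section!r}")
        if not 0.0 <= x <= 1.0:
            raise CableStructureError(f"position {x} outside [0, 1]")
        nc = self.sections[section].n_compartments
        k = min(nc - 1, int(x * nc))
        return self._sec_start[section] + k

    def section_slice(self, section: str) -> slice:
        s = self.sections[section]
        start = self._sec_start[section]
        return slice(start, start + s.n_compartments)

    def total_conductance(self, section: str, channel_name: str) -> float:
        """Summed absolute conductance (µS) of one channel in one section."""
        from .channels import CHANNEL_NAMES

        tid = CHANNEL_NAMES[channel_name]
        sl = self.section_slice(section)
        total = 0.0
        for k in range(len(self.ch_type)):
            if self.ch_type[k] != tid:
                continue
            for j in range(self.ch_off[k], self.ch_off[k + 1]):
                if sl.start <= self.ch_comp[j] < sl.stop:
                    total += self.ch_gbar[j]
        return total


def discretize(sections: Sequence[SectionSpec]) -> DiscretizedModel:
    """Discretize a section tree into compartments (see DiscretizedModel)."""
    return DiscretizedModel(sections)


# ---------------------------------------------------------------------------
# simulation front end
# ---------------------------------------------------------------------------


def _resolve_records(model, record):
    if record is None:
        record = [(name, 0.5) for name in model.sections]
    names, comps = [], []
    for r in record:
        if len(r) == 3:
            label, sec, x = r
        else:
            sec, x = r
            label = f"{sec}@{x:g}"
        names.append(label)
        comps.append(model.comp_index(sec, x))
    return names, np.array(comps, dtype=np.int64)


def _run(model, stimuli, duration, dt, record, v_init, clamp):
    nsteps = round(duration / dt)
    t_rhs = (np.arange(nsteps) + 1) * dt  # implicit step targets t_{k+1}
    names, rec_comp = _resolve_records(model, record)

    stim_comp, stim_waves = [], []
    for st in stimuli:
        if st.kind == "voltage_command":
            raise ValueError("voltage_command must be passed as the clamp")
        stim_comp.append(model.comp_index(*st.site))
        stim_waves.append(st.waveform(t_rhs))
    stim_comp = np.array(stim_comp, dtype=np.int64)
    stim_wave = (
        np.vstack(stim_waves) if stim_waves else np.zeros((0, nsteps))
    )

    clamp_comp = -1
    clamp_wave = np.zeros(nsteps)
    if clamp is not None:
        if clamp.kind != "voltage_command":
            raise ValueError("clamp stimulus must have kind='voltage_command'")
        clamp_comp = model.comp_index(*clamp.site)
        clamp_wave = clamp.waveform(t_rhs, v_hold=v_init)

    v0 = np.full(model.n, float(v_init))
    gstate = _kernel.init_gates(
        model.ch_type, model.ch_off, model.ch_comp, model.ch_params,
        v0, model.ca_rest,
    )
    out = np.zeros((len(rec_comp), nsteps + 1))
    i_clamp = np.zeros(nsteps + 1)

    status, fail_step = _kernel.integrate(
        nsteps, dt, v0, model.parent, model.gax,
        model.cm, model.gpas, model.epas,
        model.ch_type, model.ch_off, model.ch_comp, model.ch_gbar,
        model.ch_gdens, model.ch_erev, model.ch_params, gstate,
        model.has_pool, model.ca_rest.copy(), model.ca_tau, model.ca_phi,
        model.ca_rest, model.ca_out,
        stim_comp, stim_wave, clamp_comp, clamp_wave,
        rec_comp, out, i_clamp, DIVERGENCE_LIMIT,
    )
    if status != 0:
        raise NumericalError(
            f"voltage diverged (|V| > {DIVERGENCE_LIMIT:g} mV) at "
            f"t = {fail_step * dt:.3f} ms"
        )

    trace = Trace(
        dt=dt,
        duration=nsteps * dt,
        sites=names,
        values={nm: out[i] for i, nm in enumerate(names)},
        meta={"dt": dt, "v_init": v_init, "n_compartments": model.n},
    )
    if clamp is not None:
        trace.currents["clamp"] = i_clamp
    return trace


def simulate(
    model: DiscretizedModel,
    stimuli: Sequence[StimulusEvent],
    duration: float,
    dt: float = DEFAULT_DT,
    record=None,
    v_init: float = -65.0,
) -> Trace:
    """Current-clamp simulation; returns voltages at the requested sites.

    ``record`` is a list of ``(label, section, x)`` (or ``(section, x)``)
    site requests; default records the center of every section. The state is
    initialized at ``v_init`` with all gates at their steady state.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    return _run(model, stimuli, duration, dt, record, v_init, clamp=None)


def simulate_clamped(
    model: DiscretizedModel,
    clamp: StimulusEvent,
    stimuli: Sequence[StimulusEvent] = (),
    duration: float = 100.0,
    dt: float = DEFAULT_DT,
    record=None,
    v_init: float = -65.0,
) -> Trace:
    """Voltage-clamp simulation: one compartment follows the command.

    The clamped compartment's voltage is constrained to the command at every
    implicit step; the returned trace carries the clamp current (nA) in
    ``trace.currents["clamp"]``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    return _run(model, stimuli, duration, dt, record, v_init, clamp=clamp)
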