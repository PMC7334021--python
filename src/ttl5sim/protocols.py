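"""In-silico stimulation protocols over the reduced ttL5 model.

Implemented experiments:

- coincidence / BAC firing: a threshold-tuned 5 ms somatic square pulse
  plus an EPSC-like tuft injection at a controlled interval delta_t
  (dendritic onset minus somatic pulse END; positive = dendrite later);
- critical-frequency trains: three 3 ms suprathreshold pulses at 50-200 Hz
  in 10 Hz steps, feeding the ADP-integral metric;
- trunk-length x g_Ca sweep of the normalized tuft voltage integral;
- per-delta_t minimal plateau-evoking dendritic current (threshold curve);
- distal-trunk voltage-clamp width x amplitude plateau maps;
- bAP waveform statistics (peak / width / integral at the distal trunk and
  tuft) across trunk lengths under channel-manipulation knobs.

Every result carries provenance metadata (model parameter digest, dt, and
the full protocol parameter set).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .cable import StimulusEvent, Trace, simulate, simulate_clamped
from .metrics import (
    ADPResult,
    adp_integral,
    classify_plateau,
    critical_frequency,
    detect_spikes,
    waveform_stats,
)
from .model import ReducedModelSpec, build_reduced

__all__ = [
    "CoincidenceProtocol",
    "CFProtocol",
    "SweepGrid",
    "CoincidenceResult",
    "ProtocolError",
    "tune_single_ap",
    "run_coincidence",
    "run_critical_frequency",
    "adp_from_traces",
    "sweep_length_gca",
    "threshold_curve",
    "vc_width_amplitude_scan",
    "bap_length_scan",
    "PLATEAU_WINDOW",
]

DT = 0.025
#: plateau indicator window: somatic-pulse onset to +100 ms
PLATEAU_WINDOW = 100.0


class ProtocolError(RuntimeError):
    """A protocol precondition failed (e.g. pulse tuning impossible)."""


def _digest(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _meta(spec: ReducedModelSpec, protocol, dt: float) -> dict:
    return {
        "model_digest": _digest(spec.params) if spec.params else "",
        "trunk_length": spec.trunk_length,
        "knobs": dict(spec.knobs),
        "dt": dt,
        "protocol": protocol,
    }


@dataclass
class CoincidenceProtocol:
    """Somatic square pulse + EPSC-like tuft input at interval delta_t."""

    soma_amplitude: float | None = None  # nA; None -> auto-tune to 1 AP
    soma_width: float = 5.0  # ms
    epsc_amplitude: float = 0.5  # nA
    epsc_rise: float = 1.0  # ms
    epsc_decay: float = 5.0  # ms
    delta_t: float = 0.0  # ms, dendritic onset minus somatic pulse end
    onset: float = 20.0  # ms
    duration: float = 200.0  # ms
    dt: float = DT

    def __post_init__(self):
        if abs(self.delta_t) > 100.0:
            raise ValueError("|delta_t| must be <= 100 ms")
        if self.epsc_amplitude < 0 or (
            self.soma_amplitude is not None and self.soma_amplitude < 0
        ):
            raise ValueError("amplitudes must be >= 0")


@dataclass
class CFProtocol:
    """Three-pulse somatic trains over an ascending frequency grid."""

    frequencies: tuple = tuple(range(50, 201, 10))  # Hz; first = reference
    pulses_per_train: int = 3
    pulse_width: float = 3.0  # ms
    pulse_amplitude: float | None = None  # nA; None -> auto-tune
    onset: float = 50.0  # ms
    duration: float = 300.0  # ms
    dt: float = DT

    def __post_init__(self):
        f = np.asarray(self.frequencies, float)
        if len(f) < 1 or np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")


@dataclass
class SweepGrid:
    """A 2-D grid of scalar indicators over two named axes."""

    axis1_name: str
    axis1: np.ndarray
    axis2_name: str
    axis2: np.ndarray
    values: np.ndarray  # shape (len(axis1), len(axis2))
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.axis1 = np.asarray(self.axis1, float)
        self.axis2 = np.asarray(self.axis2, float)
        self.values = np.asarray(self.values, float)
        if self.values.shape != (len(self.axis1), len(self.axis2)):
            raise ValueError("values shape must be (len(axis1), len(axis2))")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must be finite")


@dataclass
class CoincidenceResult:
    trace: Trace
    n_somatic_aps: int
    is_plateau: bool
    tuft_integral: float  # mV·ms above rest over the plateau window
    soma_amplitude: float  # nA actually used
    meta: dict = field(default_factory=dict)


RECORD_SITES = [
    ("soma", "soma", 0.5),
    ("trunk_end", "trunk", 1.0),
    ("tuft", "tuft", 0.5),
]


def tune_single_ap(
    disc,
    width: float = 5.0,
    onset: float = 20.0,
    v_rest: float = -65.0,
    hi: float = 3.0,
    dt: float = DT,
    rel_tol: float = 0.01,
) -> float:
    """Minimal somatic square-pulse amplitude evoking exactly one prompt AP.

    Bisection to ``rel_tol``; "prompt" means the first spike occurs within
    ``width + 3`` ms of pulse onset (delayed dendrite-driven events do not
    count as threshold crossings for the protocol's purposes).

    Raises ProtocolError when the upper bound fails to evoke a prompt
    single AP.
    """

    def response(a):
        st = StimulusEvent(("soma", 0.5), "current_step", onset=onset,
                           amplitude=a, duration=width)
        tr = simulate(disc, [st], duration=onset + 60, dt=dt,
                      record=[("soma", "soma", 0.5)], v_init=v_rest)
        sp = detect_spikes(tr["soma"], dt)
        prompt = len(sp) >= 1 and sp.spike_times[0] <= onset + width + 3
        return prompt, len(sp)

    lo = 0.0
    ok, n = response(hi)
    if not ok:
        raise ProtocolError(
            f"somatic pulse tuning failed: no prompt AP at {hi} nA"
        )
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        ok, _ = response(mid)
        if ok:
            hi = mid
        else:
            lo = mid
        if hi - lo <= rel_tol * hi:
            break
    ok, n = response(hi)
    if not ok or n != 1:
        raise ProtocolError(
            f"tuned amplitude {hi:.3f} nA evokes {n} APs (expected exactly 1)"
        )
    return hi


def run_coincidence(
    spec: ReducedModelSpec,
    p: CoincidenceProtocol | None = None,
) -> CoincidenceResult:
    """Run the coincidence (BAC-firing) protocol on a built model."""
    p = p or CoincidenceProtocol()
    disc = spec.discretize()
    amp = p.soma_amplitude
    if amp is None:
        amp = tune_single_ap(disc, width=p.soma_width, onset=p.onset,
                             v_rest=spec.v_rest, dt=p.dt)
    stims = [
        StimulusEvent(("soma", 0.5), "current_step", onset=p.onset,
                      amplitude=amp, duration=p.soma_width),
    ]
    if p.epsc_amplitude > 0:
        stims.append(
            StimulusEvent(("tuft", 0.5), "epsc_like",
                          onset=p.onset + p.soma_width + p.delta_t,
                          amplitude=p.epsc_amplitude,
                          rise=p.epsc_rise, decay=p.epsc_decay)
        )
    tr = simulate(disc, stims, duration=p.duration, dt=p.dt,
                  record=RECORD_SITES, v_init=spec.v_rest)
    n_aps = len(detect_spikes(tr["soma"], p.dt))
    is_plat, integral = classify_plateau(
        tr["tuft"], p.dt, window=(p.onset, p.onset + PLATEAU_WINDOW),
        v_rest=spec.v_rest,
        threshold=spec.params.get("plateau_threshold"),
    )
    meta = _meta(spec, {"name": "coincidence", **asdict(p)}, p.dt)
    tr.meta.update(meta)
    return CoincidenceResult(tr, n_aps, is_plat, integral, amp, meta)


def _train_stim(p: CFProtocol, freq: float, amp: float) -> StimulusEvent:
    return StimulusEvent(("soma", 0.5), "pulse_train", onset=p.onset,
                         amplitude=amp, duration=p.pulse_width,
                         frequency=freq, count=p.pulses_per_train)


def _evoked_per_pulse(trace, p: CFProtocol, freq: float) -> list[int]:
    """APs within each inter-pulse interval of the train."""
    sp = detect_spikes(trace["soma"], p.dt).spike_times
    period = 1000.0 / freq
    counts = []
    for k in range(p.pulses_per_train):
        t0 = p.onset + k * period
        t1 = t0 + period if k < p.pulses_per_train - 1 else t0 + period
        counts.append(int(np.sum((sp >= t0) & (sp < t1))))
    return counts


def run_critical_frequency(
    spec: ReducedModelSpec,
    p: CFProtocol | None = None,
) -> dict:
    """Run the cf-ADP train protocol; one trace per frequency.

    The pulse amplitude (when auto) is the smallest amplitude evoking one
    AP per pulse at every grid frequency (plus a 5% safety margin); a
    frequency at which a pulse then fails to evoke exactly one AP raises
    ProtocolError naming it. Returns {"traces": {freq: Trace},
    "amplitude": nA, "meta": ...}.
    """
    p = p or CFProtocol()
    disc = spec.discretize()
    freqs = [float(f) for f in p.frequencies]

    amp = p.pulse_amplitude
    if amp is None:
        need = p.pulses_per_train

        def n_train_aps(a, freq):
            tr = simulate(disc, [_train_stim(p, freq, a)],
                          duration=p.onset + 100, dt=p.dt,
                          record=[("soma", "soma", 0.5)], v_init=spec.v_rest)
            return sum(min(c, 1) for c in _evoked_per_pulse(tr, p, freq))

        amp = 0.0
        for freq in (freqs[0], freqs[-1]):
            lo, hi = 0.0, 4.0
            if n_train_aps(hi, freq) < need:
                raise ProtocolError(
                    f"no amplitude up to {hi} nA evokes {need} APs at "
                    f"{freq:g} Hz"
                )
            for _ in range(30):
                mid = 0.5 * (lo + hi)
                if n_train_aps(mid, freq) >= need:
                    hi = mid
                else:
                    lo = mid
                if hi - lo < 0.005 * hi:
                    break
            amp = max(amp, hi)
        amp *= 1.05

    traces = {}
    for freq in freqs:
        tr = simulate(disc, [_train_stim(p, freq, amp)], duration=p.duration,
                      dt=p.dt, record=RECORD_SITES, v_init=spec.v_rest)
        counts = _evoked_per_pulse(tr, p, freq)
        if any(c < 1 for c in counts):
            raise ProtocolError(
                f"pulse failed to evoke an AP at {freq:g} Hz "
                f"(per-pulse counts {counts})"
            )
        tr.meta.update(_meta(spec, {"name": "critical_frequency",
                                    "frequency": freq, **asdict(p),
                                    "amplitude_used": amp}, p.dt))
        traces[freq] = tr
    return {"traces": traces, "amplitude": amp,
            "meta": _meta(spec, {"name": "critical_frequency",
                                 **asdict(p)}, p.dt)}


def adp_from_traces(traces: dict, dt: float = DT) -> ADPResult:
    """ADP integrals (vs the lowest-frequency reference) and cf call."""
    freqs = sorted(traces)
    ref = traces[freqs[0]]["soma"]
    fs, integrals = [], []
    for f in freqs[1:]:
        fs.append(f)
        integrals.append(adp_integral(traces[f]["soma"], ref, dt))
    fs = np.array(fs)
    integrals = np.array(integrals)
    if len(integrals) == 0:
        return ADPResult(fs, integrals, 0.0, None)
    return ADPResult(
        fs, integrals, float(np.max(integrals)),
        critical_frequency(fs, integrals),
    )


def sweep_length_gca(
    lengths=np.arange(100.0, 801.0, 25.0),
    gca_scales=np.arange(0.0, 8.01, 0.5),
    coincidence: CoincidenceProtocol | None = None,
    params: dict | None = None,
) -> SweepGrid:
    """Normalized tuft voltage integral over trunk length x g_Ca scale.

    Each cell runs the coincidence protocol (soma pulse re-tuned per
    length) and stores the plateau-window tuft integral; the grid is
    normalized by its maximum.
    """
    p = coincidence or CoincidenceProtocol()
    vals = np.zeros((len(lengths), len(gca_scales)))
    for i, L in enumerate(lengths):
        amp = None
        for j, g in enumerate(gca_scales):
            try:
                spec = build_reduced(float(L), g_ca_scale=float(g),
                                     **({"params": params} if params else {}))
                if amp is None:
                    amp = tune_single_ap(spec.discretize(), width=p.soma_width,
                                         onset=p.onset, v_rest=spec.v_rest,
                                         dt=p.dt)
                pj = CoincidenceProtocol(**{**asdict(p),
                                            "soma_amplitude": amp})
                vals[i, j] = run_coincidence(spec, pj).tuft_integral
            except Exception as e:  # noqa: BLE001 - annotate cell coords
                raise ProtocolError(
                    f"sweep cell failed at length={L}, gca_scale={g}: {e}"
                ) from e
    vmax = np.max(np.abs(vals))
    if vmax > 0:
        vals = vals / vmax
    return SweepGrid("trunk_length_um", np.asarray(lengths, float),
                     "g_ca_scale", np.asarray(gca_scales, float), vals,
                     meta={"protocol": "coincidence", "normalized": True})


def threshold_curve(
    trunk_length: float,
    delta_ts=np.arange(-20.0, 20.5, 2.0),
    currents=np.round(np.arange(0.02, 0.51, 0.04), 3),
    params: dict | None = None,
) -> dict:
    """Minimal plateau-evoking dendritic current per delta_t (or None)."""
    currents = np.sort(np.asarray(currents, float))
    spec = build_reduced(trunk_length,
                         **({"params": params} if params else {}))
    amp = tune_single_ap(spec.discretize(), v_rest=spec.v_rest)
    out = {}
    for dt_ms in delta_ts:
        found = None
        for c in currents:
            p = CoincidenceProtocol(soma_amplitude=amp, epsc_amplitude=float(c),
                                    delta_t=float(dt_ms))
            if run_coincidence(spec, p).is_plateau:
                found = float(c)
                break
        out[float(dt_ms)] = found
    return out


def vc_width_amplitude_scan(
    spec: ReducedModelSpec,
    widths=np.arange(2.0, 61.0, 4.0),
    amplitudes=np.arange(2.0, 41.0, 2.0),
    dt: float = DT,
) -> SweepGrid:
    """Plateau map for square voltage steps clamped at the distal trunk.

    Amplitudes are mV relative to rest. Cell value is 1.0 when the tuft
    shows a plateau (voltage-integral criterion over the window starting at
    clamp onset), else 0.0.
    """
    disc = spec.discretize()
    onset = 20.0
    vals = np.zeros((len(widths), len(amplitudes)))
    for i, w in enumerate(widths):
        for j, a in enumerate(amplitudes):
            clamp = StimulusEvent(("trunk", 1.0), "voltage_command",
                                  onset=onset, amplitude=float(a),
                                  duration=float(w))
            tr = simulate_clamped(disc, clamp, duration=onset + 130, dt=dt,
                                  record=[("tuft", "tuft", 0.5)],
                                  v_init=spec.v_rest)
            is_plat, _ = classify_plateau(
                tr["tuft"], dt, window=(onset, onset + PLATEAU_WINDOW),
                v_rest=spec.v_rest,
                threshold=spec.params.get("plateau_threshold"),
            )
            vals[i, j] = 1.0 if is_plat else 0.0
    return SweepGrid("width_ms", widths, "amplitude_mV", amplitudes, vals,
                     meta=_meta(spec, {"name": "vc_scan"}, dt))


def bap_length_scan(
    lengths=(200.0, 300.0, 400.0, 500.0, 600.0),
    knobs: dict | None = None,
    params: dict | None = None,
    pulse_width: float = 3.0,
    frequency: float = 100.0,
    n_spikes: int = 3,
    dt: float = DT,
) -> dict:
    """bAP waveform statistics vs trunk length (3 spikes at 100 Hz).

    Returns {length: {"trunk_end": WaveformStats, "tuft": WaveformStats,
    "n_somatic_aps": int}}. ``knobs`` are forwarded to build_reduced
    (e.g. g_ca_scale=0, trunk_nat_scale=0, trunk_ra=..., hcn scaling,
    uniform_trunk_distributions, passive_trunk).
    """
    knobs = dict(knobs or {})
    if params:
        knobs["params"] = params
    onset = 20.0
    out = {}
    for L in lengths:
        spec = build_reduced(float(L), **knobs)
        disc = spec.discretize()

        def n_train(a):
            st = StimulusEvent(("soma", 0.5), "pulse_train", onset=onset,
                               amplitude=a, duration=pulse_width,
                               frequency=frequency, count=n_spikes)
            tr = simulate(disc, [st], duration=onset + 100, dt=dt,
                          record=[("soma", "soma", 0.5)], v_init=spec.v_rest)
            return len(detect_spikes(tr["soma"], dt))

        lo, hi = 0.0, 4.0
        if n_train(hi) < n_spikes:
            raise ProtocolError(f"cannot evoke {n_spikes} APs at L={L}")
        for _ in range(25):
            mid = 0.5 * (lo + hi)
            if n_train(mid) >= n_spikes:
                hi = mid
            else:
                lo = mid
            if hi - lo < 0.005 * hi:
                break
        st = StimulusEvent(("soma", 0.5), "pulse_train", onset=onset,
                           amplitude=hi * 1.02, duration=pulse_width,
                           frequency=frequency, count=n_spikes)
        tr = simulate(disc, [st], duration=200.0, dt=dt,
                      record=RECORD_SITES, v_init=spec.v_rest)
        out[float(L)] = {
            "trunk_end": waveform_stats(tr["trunk_end"], dt),
            "tuft": waveform_stats(tr["tuft"], dt),
            "n_somatic_aps": len(detect_spikes(tr["soma"], dt)),
        }
    return out
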