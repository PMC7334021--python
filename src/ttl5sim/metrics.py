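"""Electrophysiology metrics over voltage traces.

All measurements apply identically to simulated and synthetic traces:
spike detection, burst ratio, the critical-frequency afterdepolarization
(ADP) integral, backpropagating-AP waveform statistics, Ca2+ plateau
classification, and passive intrinsic measures.

Key definitions
---------------
ADP integral
    Area between a high-frequency-train trace and the 50 Hz reference in a
    4-24 ms window after the peaks of the last APs, aligned to sub-sample
    precision; mV·ms, may be negative.
Critical frequency (cfADP)
    Lowest train frequency whose ADP integral reaches
    ``max(theta_abs, theta_rel * max over the grid)``; absent when no
    frequency reaches it.
Burst ratio
    Largest ratio of two consecutive inter-spike intervals within one
    current step; the maximal burst ratio is its maximum across steps. A
    long ISI preceded by a short one marks the end of a burst, so higher
    values mean stronger bursting.
Waveform width
    Total time spent more than 2 mV above baseline (captures the slow
    depolarization tail without contamination by individual spikes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cable import StimulusEvent, Trace, simulate

__all__ = [
    "SpikeTrain",
    "ADPResult",
    "WaveformStats",
    "BURST_UNDEFINED",
    "detect_spikes",
    "burst_ratio",
    "max_burst_ratio",
    "adp_integral",
    "critical_frequency",
    "waveform_stats",
    "classify_plateau",
    "passive_measures",
    "MetricError",
]

SPIKE_THRESHOLD = 0.0  # mV
REFRACTORY_FLOOR = 1.0  # ms
ADP_WINDOW = (4.0, 24.0)  # ms after the aligned last-AP peak
CF_THETA_ABS = 20.0  # mV·ms
CF_THETA_REL = 0.5
WIDTH_LEVEL = 2.0  # mV above baseline


class MetricError(RuntimeError):
    """A metric's preconditions are not met (e.g. no AP in a trace)."""


class _BurstUndefined:
    """Typed sentinel: burst ratio undefined (fewer than 3 spikes)."""

    def __repr__(self):  # pragma: no cover
        return "BURST_UNDEFINED"

    def __bool__(self):
        return False


BURST_UNDEFINED = _BurstUndefined()


@dataclass
class SpikeTrain:
    spike_times: np.ndarray  # ms, strictly increasing
    source: str = ""

    def __post_init__(self):
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if np.any(np.diff(self.spike_times) <= 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self):
        return len(self.spike_times)

    @property
    def isis(self) -> np.ndarray:
        return np.diff(self.spike_times)


@dataclass
class ADPResult:
    frequencies: np.ndarray  # Hz (above the reference)
    integrals: np.ndarray  # mV·ms
    max_adp_integral: float
    critical_frequency: float | None


@dataclass
class WaveformStats:
    peak: float  # mV above baseline
    width: float  # ms above baseline + 2 mV
    integral: float  # mV·ms above baseline


def detect_spikes(
    v: np.ndarray,
    dt: float,
    threshold: float = SPIKE_THRESHOLD,
    refractory: float = REFRACTORY_FLOOR,
    source: str = "",
) -> SpikeTrain:
    """Upward threshold crossings with a refractory floor.

    Returns an empty train when nothing crosses; never raises.
    """
    v = np.asarray(v, dtype=float)
    up = np.flatnonzero((v[1:] >= threshold) & (v[:-1] < threshold))
    times = []
    for i in up:
        t = (i + 1) * dt
        if not times or t - times[-1] > refractory:
            times.append(t)
    return SpikeTrain(np.array(times), source=source)


def burst_ratio(train: SpikeTrain):
    """Largest ratio of consecutive ISIs; BURST_UNDEFINED for < 3 spikes."""
    if len(train) < 3:
        return BURST_UNDEFINED
    isis = train.isis
    return float(np.max(isis[1:] / isis[:-1]))


def max_burst_ratio(trains):
    """Maximal burst ratio across current steps (BURST_UNDEFINED if none)."""
    ratios = [burst_ratio(tr) for tr in trains]
    defined = [r for r in ratios if r is not BURST_UNDEFINED]
    if not defined:
        return BURST_UNDEFINED
    return max(defined)


def _last_peak_index(v: np.ndarray, dt: float) -> float:
    """Sub-sample index of the last AP peak (parabolic interpolation)."""
    train = detect_spikes(v, dt)
    if len(train) == 0:
        raise MetricError("no action potential detected")
    i0 = int(round(train.spike_times[-1] / dt))
    i1 = min(len(v), i0 + int(round(3.0 / dt)))
    k = i0 + int(np.argmax(v[i0:i1]))
    if 0 < k < len(v) - 1:
        y0, y1, y2 = v[k - 1], v[k], v[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            return k + 0.5 * (y0 - y2) / denom
    return float(k)


def adp_integral(
    v_f: np.ndarray,
    v_ref: np.ndarray,
    dt: float,
    window: tuple[float, float] = ADP_WINDOW,
) -> float:
    """ADP area (mV·ms) between a train trace and the 50 Hz reference.

    The last AP peaks of both traces are aligned (sub-sample, by linear
    interpolation of the shifted trace) and the difference is integrated
    over ``window`` after the peak. Negative values are possible.
    """
    pf = _last_peak_index(np.asarray(v_f, float), dt)
    pr = _last_peak_index(np.asarray(v_ref, float), dt)
    t0, t1 = window
    n = int(round((t1 - t0) / dt))
    tq = np.arange(n + 1) * dt + t0
    idx = np.arange(len(v_f)) * dt
    vf = np.interp(tq + pf * dt, idx, v_f)
    vr = np.interp(tq + pr * dt, idx, v_ref)
    return float(np.trapezoid(vf - vr, dx=dt))


def critical_frequency(
    frequencies,
    integrals,
    theta_abs: float = CF_THETA_ABS,
    theta_rel: float = CF_THETA_REL,
) -> float | None:
    """Lowest frequency whose ADP integral reaches the two-part threshold.

    Threshold = max(theta_abs, theta_rel * max(integrals)); None when no
    frequency reaches it (no cfADP).
    """
    frequencies = np.asarray(frequencies, float)
    integrals = np.asarray(integrals, float)
    if len(frequencies) == 0:
        return None
    if np.any(np.diff(frequencies) <= 0):
        raise ValueError("frequencies must be strictly increasing")
    theta = max(theta_abs, theta_rel * float(np.max(integrals)))
    hit = np.flatnonzero(integrals >= theta)
    return float(frequencies[hit[0]]) if len(hit) else None


def waveform_stats(
    v: np.ndarray,
    dt: float,
    baseline: float | None = None,
    baseline_window: float = 10.0,
    level: float = WIDTH_LEVEL,
) -> WaveformStats:
    """Peak, width (above baseline + 2 mV) and integral of a depolarization.

    ``baseline`` defaults to the mean over the first ``baseline_window`` ms
    (pre-stimulus segment).
    """
    v = np.asarray(v, float)
    if baseline is None:
        nb = max(1, int(round(baseline_window / dt)))
        baseline = float(np.mean(v[:nb]))
    d = v - baseline
    width = float(np.sum(d > level) * dt)
    return WaveformStats(
        peak=float(np.max(d)),
        width=width,
        integral=float(np.trapezoid(np.clip(d, 0.0, None), dx=dt)),
    )


def classify_plateau(
    v_tuft: np.ndarray,
    dt: float,
    window: tuple[float, float],
    v_rest: float = -65.0,
    threshold: float | None = None,
) -> tuple[bool, float]:
    """Ca2+ plateau call from the tuft voltage integral above rest.

    The integral (mV·ms) of ``v - v_rest`` over ``window`` (ms) is compared
    against ``threshold`` (strictly greater ⇒ plateau). The default
    threshold is the calibrated value frozen in the model configuration,
    chosen at the bimodal gap of the default trunk-length x g_Ca sweep.
    """
    if threshold is None:
        from .model import load_default_params

        threshold = load_default_params()["plateau_threshold"]
    v = np.asarray(v_tuft, float)
    i0 = int(round(window[0] / dt))
    i1 = min(len(v) - 1, int(round(window[1] / dt)))
    integral = float(np.trapezoid(v[i0 : i1 + 1] - v_rest, dx=dt))
    return integral > threshold, integral


def passive_measures(
    disc,
    v_rest: float = -65.0,
    dt: float = 0.025,
    target_deflection: float = 10.0,
    rheobase_bounds: tuple[float, float] | None = (0.0, 3.0),
) -> dict:
    """Input resistance, sag and rheobase of a discretized model.

    The hyperpolarizing step is sized iteratively to ~``target_deflection``
    mV steady-state deflection (sag = peak - steady hyperpolarization, per
    the standard convention); rheobase is found by bisection on a 500 ms
    step evoking at least one somatic AP.
    """
    step_dur, settle = 400.0, 410.0

    def response(amp):
        st = StimulusEvent(("soma", 0.5), "current_step", onset=20.0,
                           amplitude=amp, duration=step_dur)
        tr = simulate(disc, [st], duration=settle + 40, dt=dt,
                      record=[("soma", "soma", 0.5)], v_init=v_rest)
        v = tr["soma"]
        steady = float(np.mean(v[int(380 / dt): int(415 / dt)]))
        return v, steady

    amp = -0.05
    steady = v_rest
    for _ in range(8):
        v, steady = response(amp)
        defl = v_rest - steady
        if abs(defl - target_deflection) < 0.5:
            break
        if defl <= 0.05:
            raise MetricError("hyperpolarizing step produced no deflection")
        amp *= target_deflection / defl
    rin = (v_rest - steady) / -amp  # MΩ (mV / nA)
    sag = float(steady - np.min(v))

    if rheobase_bounds is None:
        return {"input_resistance": float(rin), "sag": sag, "rheobase": None}
    lo, hi = rheobase_bounds

    def n_spikes(a):
        st = StimulusEvent(("soma", 0.5), "current_step", onset=20.0,
                           amplitude=a, duration=500.0)
        tr = simulate(disc, [st], duration=540.0, dt=dt,
                      record=[("soma", "soma", 0.5)], v_init=v_rest)
        return len(detect_spikes(tr["soma"], dt))

    if n_spikes(hi) < 1:
        raise MetricError("rheobase upper bound evokes no spike")
    for _ in range(20):
        mid = 0.5 * (lo + hi)
        if n_spikes(mid) >= 1:
            hi = mid
        else:
            lo = mid
        if hi - lo < 0.01 * hi:
            break
    return {"input_resistance": float(rin), "sag": sag, "rheobase": float(hi)}
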