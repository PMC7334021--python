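"""Synthetic cohorts and voltage traces.

Provides downstream-testable stand-ins for the recording data: two-area
cohorts of (apical trunk length, maximum ADP integral) pairs with the
populations' published summary statistics, and spike-train voltage traces
with a parameterized afterdepolarization bump plus Gaussian noise.

Cohort defaults emulate the two visual-cortex populations: V1 trunk length
409 ± 64 µm (SD), V2m 313 ± 65 µm; maximum ADP integral 91 ± 50 mV·ms
(V1, n = 41) vs 42 ± 33 mV·ms (V2m, n = 49); a positive length-ADP
correlation (default rho = 0.4, matching in sign and magnitude the pooled
r² ≈ 0.15 of the two variables). Each area draws from a bivariate normal
truncated at zero by resampling (not clipping, preserving the continuous
shape).

All randomness uses the counter-based Philox generator so artifacts are
bit-reproducible across platforms; the seed is recorded in every output's
metadata.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from .cable import Trace
from .stats import CohortTable

__all__ = [
    "AreaParams",
    "CohortParams",
    "TraceParams",
    "gen_cohort",
    "gen_spike_trace",
    "gen_two_component_values",
]


def _rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(seed))


@dataclass(frozen=True)
class AreaParams:
    n: int
    length_mean: float  # µm
    length_sd: float
    adp_mean: float  # mV·ms
    adp_sd: float

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.length_sd <= 0 or self.adp_sd <= 0:
            raise ValueError("sds must be > 0")


#: published summary statistics of the two populations
DEFAULT_AREAS = {
    "V1": AreaParams(n=41, length_mean=409.0, length_sd=64.0,
                     adp_mean=91.0, adp_sd=50.0),
    "V2m": AreaParams(n=49, length_mean=313.0, length_sd=65.0,
                      adp_mean=42.0, adp_sd=33.0),
}


@dataclass(frozen=True)
class CohortParams:
    areas: dict = field(default_factory=lambda: dict(DEFAULT_AREAS))
    rho: float = 0.4  # length-ADP correlation, applied within each area
    seed: int = 0

    def __post_init__(self):
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must be in (-1, 1)")


def gen_cohort(p: CohortParams | None = None) -> CohortTable:
    """Draw a two-area cohort of (trunk length, max ADP integral) pairs.

    Correlated bivariate normal per area, truncated at 0 by resampling;
    deterministic under a fixed seed. Provenance (parameters + seed) is
    stored in the table's metadata.
    """
    p = p or CohortParams()
    rng = _rng(p.seed)
    rows = []
    for area, ap in p.areas.items():
        mean = np.array([ap.length_mean, ap.adp_mean])
        sd = np.array([ap.length_sd, ap.adp_sd])
        cov = np.array([
            [sd[0] ** 2, p.rho * sd[0] * sd[1]],
            [p.rho * sd[0] * sd[1], sd[1] ** 2],
        ])
        draws = np.empty((0, 2))
        # truncate at zero by resampling (keeps the distribution continuous)
        while len(draws) < ap.n:
            cand = rng.multivariate_normal(mean, cov, size=2 * ap.n)
            cand = cand[np.all(cand > 0, axis=1)]
            draws = np.vstack([draws, cand])
        draws = draws[: ap.n]
        for k, (length, adp) in enumerate(draws):
            rows.append({
                "cell_id": f"{area}_{k:03d}",
                "area": area,
                "trunk_length_um": length,
                "max_adp_integral": adp,
            })
    meta = {"generator": "gen_cohort", "seed": p.seed, "rho": p.rho,
            "areas": {a: asdict(ap) for a, ap in p.areas.items()}}
    return CohortTable(rows, meta=meta)


def gen_two_component_values(
    n: int,
    weight_high: float,
    low: tuple[float, float],
    high: tuple[float, float],
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-component normal mixture (values, true labels), truncated at 0.

    Emulates a pooled maximum-ADP distribution with a cfADP (high) and a
    non-cfADP (low) component, for testing the two-group classifier.
    """
    rng = _rng(seed)
    labels = (rng.random(n) < weight_high).astype(int)
    mus = np.where(labels == 1, high[0], low[0])
    sds = np.where(labels == 1, high[1], low[1])
    vals = rng.normal(mus, sds)
    for _ in range(100):
        neg = vals <= 0
        if not np.any(neg):
            break
        vals[neg] = rng.normal(mus[neg], sds[neg])
    return vals, labels


@dataclass(frozen=True)
class TraceParams:
    """Synthetic somatic spike-train trace.

    Spikes are Gaussian-shaped waveforms (peak at each spike time); the
    optional ADP bump starts ``adp_onset`` ms after the last spike and is
    either a square bump of ``adp_duration`` ms or an exponential decay
    with time constant ``adp_decay``.
    """

    spike_times: tuple = (20.0, 30.0, 40.0)  # ms
    spike_amplitude: float = 100.0  # mV above baseline
    spike_half_width: float = 1.0  # ms (FWHM)
    baseline: float = -65.0  # mV
    adp_amplitude: float = 0.0  # mV
    adp_onset: float = 2.0  # ms after the last spike
    adp_shape: str = "exponential"  # or "square"
    adp_decay: float = 15.0  # ms (exponential)
    adp_duration: float = 20.0  # ms (square)
    noise_sd: float = 0.0  # mV
    dt: float = 0.025  # ms
    duration: float = 100.0  # ms
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0 or self.noise_sd < 0:
            raise ValueError("dt must be > 0 and noise_sd >= 0")
        st = np.asarray(self.spike_times, float)
        if len(st) and np.any(np.diff(st) < 2.0 * self.spike_half_width):
            raise ValueError("overlapping spikes: interval < template width")
        if self.adp_shape not in ("exponential", "square"):
            raise ValueError("adp_shape must be 'exponential' or 'square'")


def gen_spike_trace(p: TraceParams) -> Trace:
    """Render the synthetic trace; detectable by the standard spike
    detector for noise sd <= 2 mV."""
    rng = _rng(p.seed)
    n = round(p.duration / p.dt)
    t = np.arange(n + 1) * p.dt
    v = np.full(n + 1, p.baseline)
    sigma = p.spike_half_width / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    for tk in p.spike_times:
        v += p.spike_amplitude * np.exp(-0.5 * ((t - tk) / sigma) ** 2)
    if p.adp_amplitude != 0 and len(p.spike_times):
        t0 = p.spike_times[-1] + p.adp_onset
        if p.adp_shape == "square":
            v += np.where((t >= t0) & (t < t0 + p.adp_duration),
                          p.adp_amplitude, 0.0)
        else:
            m = t >= t0
            v[m] += p.adp_amplitude * np.exp(-(t[m] - t0) / p.adp_decay)
    if p.noise_sd > 0:
        v = v + rng.normal(0.0, p.noise_sd, size=v.shape)
    return Trace(dt=p.dt, duration=n * p.dt, sites=["soma"],
                 values={"soma": v},
                 meta={"generator": "gen_spike_trace", **asdict(p)})
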