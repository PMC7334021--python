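# ttl5sim

Simulation and analysis toolkit for studying how **apical-trunk length
governs dendritic Ca²⁺ electrogenesis** in thick-tufted layer-5 (ttL5)
pyramidal neurons.

ttL5 neurons fire bursts when a backpropagating action potential (bAP)
coincides with distal tuft input — *BAC firing* — because the coincidence
ignites an all-or-none dendritic Ca²⁺ plateau. A companion signature is the
critical-frequency afterdepolarization (*cfADP*): a somatic ADP that appears
abruptly once a short AP train exceeds a cell-specific frequency. Both
phenomena differ sharply between cortical areas whose ttL5 cells differ
mainly in apical-trunk length. This package provides, as an importable
Python library:

- a deterministic compartmental **cable engine** (backward Euler + Hines
  solve, exact exponential gating) with current and voltage clamp;
- a **channel library** (Nat, Nap, Kfast, Kslow, Km, HCN, CaHVA, CaLVA,
  KCa, Ca²⁺ pool) with configurable kinetics;
- the calibrated **reduced ttL5 model** — soma, axon, basal, apical trunk,
  lumped tuft — whose trunk length can be varied with automatic
  conductance redistribution (trunk λ = 1009 µm, rest −65 mV);
- the **protocols**: coincidence/BAC firing with auto-tuned somatic pulses,
  critical-frequency trains, trunk-length × g_Ca sweeps, threshold curves,
  distal-trunk voltage-clamp scans, bAP waveform scans;
- **electrophysiology metrics** (spike detection, burst ratio, ADP
  integral & critical frequency, waveform stats, plateau classification,
  passive measures);
- **cohort statistics** (Fisher exact, t, Kolmogorov–Smirnov, exact 1-D
  two-group clustering, OLS + F-test) and a **synthetic-data** module
  generating two-population cohorts and spike traces.

The central quantity is the passive space constant
λ = √(d·R_m/(4·R_a)); trunk lengths map onto the electrotonic scale L/λ,
and the model reproduces the plateau onset at L ≈ 0.35 λ (≈ 350 µm).

## Worked example

```python
from ttl5sim.model import build_reduced
from ttl5sim.protocols import run_coincidence

for length in (600.0, 200.0):
    res = run_coincidence(build_reduced(length))
    print(length, res.n_somatic_aps, round(res.tuft_integral), res.is_plateau)
```

prints

```
600.0 11 3930 True
200.0 1 308 False
```

i.e. with a 600 µm trunk the threshold-tuned somatic pulse plus a 0.5 nA
EPSC-like tuft input evokes a burst of 11 somatic APs riding on a tuft
Ca²⁺ plateau (tuft voltage integral 3930 mV·ms over the 100 ms window,
far above the 1250 mV·ms plateau criterion), while the same protocol on a
200 µm trunk gives a single AP and no plateau — the BAC-firing dichotomy.

The `examples/` directory has one short narrative script per capability
(BAC firing, cfADP, length × g_Ca sweep, bAP waveforms, voltage-clamp
charging, cohort statistics); each prints its numbers with a short
explanation. A thin CLI (`ttl5 run <config.yaml>`, `ttl5 cohort-stats`,
`ttl5 synth`) wraps the library for config-driven runs with full manifest
provenance.

`docs/methods.md` documents the model, the calibration procedure
(`scripts/calibrate.py`, endpoint frozen in
`src/ttl5sim/calibrated_default.json`), all protocol conventions, and the
known limitations.

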