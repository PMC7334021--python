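# Methods

## The model

`ttl5sim` implements a reduced, conductance-based compartmental model of a
thick-tufted layer-5 (ttL5) pyramidal neuron, built to study how the length
of the apical trunk governs dendritic Ca²⁺ electrogenesis — BAC firing
(a somatic burst triggered by coincidence of a backpropagating action
potential and distal tuft input, via a dendritic Ca²⁺ plateau) and the
critical-frequency afterdepolarization (cfADP).

The neuron is a tree of equivalent cylinders: soma, axon hillock, axon
initial segment, a lumped basal dendrite, the apical trunk (the variable of
interest), and a lumped apical tuft. The membrane carries Hodgkin–Huxley
style conductances with the fixed placement

| channel | sections |
|---|---|
| transient Na⁺ (Nat) | soma, hillock, AIS, trunk, tuft |
| persistent Na⁺ (Nap) | soma |
| fast K⁺ (Kfast) | soma, trunk, tuft |
| slow K⁺ (Kslow) | soma, trunk, tuft |
| muscarinic K⁺ (Km) | soma |
| HCN (I_h) | basal, trunk, tuft |
| high-/low-voltage-activated Ca²⁺ | tuft only |
| Ca²⁺-activated K⁺ (KCa) + Ca²⁺ pool | tuft only |

Along the trunk, Kfast and Kslow decay exponentially with distance from the
soma, Nat decays linearly (clipped at zero), and HCN ramps linearly from its
proximal value to the tuft density at the distal end. These profiles are
*pure functions of absolute distance* (with the HCN ramp's span tied to the
trunk length and its target to the tuft density): when the trunk length
changes, every trunk compartment's density is re-evaluated at its new
distance, so the total trunk conductance scales with length while the
spatial rule — and every non-trunk parameter — stays fixed. This
redistribution rule is the essential modelling assumption: trunk length is
the *only* independent variable in the length experiments.

The tuft is a single iso-potential compartment (the apical tuft, holding
all the Ca²⁺ machinery, is one electrotonic division with no distinct
bifurcation section — the standard choice for this class of reduced
ttL5 models): the whole
tuft capacitance charges and discharges through the trunk's axial
resistance, which grows with trunk length. That coupling is what converts
the length-dependent *broadening* of the backpropagating AP into a
length-dependent tuft *depolarization* — the core mechanism.

### Integration

Spatial discretization is the standard compartmental scheme (≤ 10 µm
compartments by default along the trunk; cylinder areas, half-compartment
axial resistances). Time stepping is backward Euler for the voltage (exact
O(n) Hines elimination on the tree) with staggered, analytically exact
exponential gate and calcium-pool updates; default dt = 0.025 ms. The
scheme is unconditionally stable for passive membranes; convergence is
guarded by grid/step-refinement tests and a fine-step ODE oracle
(`tests/test_cable.py`). A first-order scheme underestimates sharp spike
peaks by ~1 mV at dt = 0.025 ms; peak-precision comparisons in the tests
use dt = 0.002 ms. A divergence guard aborts at |V| > 500 mV.

### Channel kinetics

The channel inventory and spatial distributions above are fixed design
constraints of this model class; the rate equations are free choices, so
standard published formulations are used
(Hay-2011-style Na⁺/Ca²⁺/Km/I_h, Kv3.1/K_Pst-style fast/slow K⁺, an
SK-style KCa driven by a first-order Ca²⁺ pool). Every class exposes named
parameters (voltage shifts, rate scales, and for the Ca²⁺ carrier also an
activation slope and a separate inactivation shift) in the model
configuration; behaviour is pinned by calibration anchors rather than by
borrowed parameter values. Two deliberate kinetic choices:

- **Slow, steep tuft Ca²⁺ activation.** The dominant tuft Ca²⁺ conductance
  activates slowly (τ ≈ 10–40 ms in the plateau voltage range) and steeply.
  Plateau ignition therefore integrates the tuft depolarization over tens
  of milliseconds instead of thresholding on its peak — matching the
  finding that the *voltage integral* at the distal trunk, not a particular
  width/amplitude combination, gates the plateau.
- **Nernst Ca²⁺ reversal.** Ca²⁺ channel reversals in pooled compartments
  are concentration-derived (E_Ca = RT/2F · ln([Ca]ₒ/[Ca]ᵢ), [Ca]ₒ = 2 mM)
  rather than fixed; a fixed reversal (set the pool's
  `external_concentration` to 0) makes high-g_Ca plateaus unphysically
  strong. This is the one place the implementation prefers the
  concentration-derived option over the simpler fixed-reversal default.
- **Dendritic Na⁺ inactivation shift.** Trunk Nat carries a +10 mV
  inactivation-gate shift (dendritic Na⁺ channels inactivate at more
  depolarized potentials than somatic ones), which lets the distal trunk
  sustain the slow depolarizing tail behind the bAP that grows with trunk
  length.

## Calibration

Passive anchors are solved in closed form: the trunk diameter follows from
the target DC length constant λ = √(d·R_m/(4·R_a)) = 1009 µm given the
chosen trunk R_m (15 kΩ·cm²) and R_a (100 Ω·cm); the resting potential
(−65 mV) is enforced exactly by per-compartment leak-reversal balancing
(each compartment's leak cancels its resting channel current, making the
uniform rest an exact fixed point — no settling transient, rest independent
of trunk length and knob settings). Densities and kinetic parameters were
then iterated against the behavioural anchor battery; the endpoint is the
versioned artifact `src/ttl5sim/calibrated_default.json`, and
`scripts/calibrate.py` re-derives the closed forms and re-verifies every
anchor (`--full` adds the 25 µm critical-length scan):

1. rest −65 ± 1 mV at all sites;
2. a threshold-tuned 5 ms somatic pulse evokes exactly one prompt AP;
3. coincidence at 600 µm: ≥ 3 somatic APs and a tuft plateau (BAC firing);
4. coincidence at 200 µm: exactly one AP, no plateau;
5. trunk λ = 1009 µm;
6. plateau onset at 350 µm in the 25 µm length scan;
7. tuft bAP peak monotone increasing over 200–600 µm at g_Ca = 0,
   abolished at zero trunk Na⁺.

Geometry values (soma 35 µm, basal 300×10 µm, tuft 900×5 µm, etc.) are
calibration constants chosen to land input resistance (≈ 35–40 MΩ), sag
and rheobase in the physiological window across trunk lengths 200–800 µm;
they are calibration choices of this package, not measurements. Tuft
C_m is 1.75 µF/cm² (spine-corrected), elsewhere 1.0.

The plateau classifier is the tuft voltage integral above rest over a
100 ms window from somatic-pulse onset; a run is a plateau when the
integral exceeds 1250 mV·ms, frozen at the bimodal gap of the default
length scan (non-plateau mode ≤ ~700, plateau mode ≥ ~1700 mV·ms). The
critical-frequency rule is the two-part threshold
max(20 mV·ms, 0.5 · grid max) on ADP integrals, a deterministic surrogate
for the "sudden increase" criterion; its parameters are exposed.

### Protocol conventions

- Coincidence: EPSC-like input (difference of exponentials, rise 1 ms,
  decay 5 ms, default 0.5 nA) at the tuft; delta_t is dendritic onset minus
  somatic-pulse *end*, positive = dendrite later. Somatic amplitude
  auto-tuning bisects to the minimal amplitude evoking exactly one *prompt*
  AP (latency ≤ pulse width + 3 ms), tolerance 1%.
- cf trains: three 3 ms pulses, 50–200 Hz grid in 10 Hz steps; the
  amplitude is the smallest evoking one AP per pulse at both grid ends
  (+5%), and every frequency is verified (a failing frequency raises a
  protocol error naming it). ADP integrals are measured in the 4–24 ms
  window after sub-sample-aligned last-AP peaks against the 50 Hz
  reference.
- Sweeps: the length × g_Ca grid normalizes tuft integrals by the grid
  maximum (the normalization constant is per-grid, a documented choice).

## Synthetic data

`ttl5sim.synth` emulates the *statistical* structure of the two recorded
populations, not their biophysics: per-area bivariate normal
(trunk length, max ADP integral) draws at the published summary statistics
(V1 409 ± 64 µm, 91 ± 50 mV·ms, n = 41; V2m 313 ± 65 µm, 42 ± 33 mV·ms,
n = 49), truncated at zero by resampling, with a within-area length–ADP
correlation ρ = 0.4 (matching the sign and magnitude of the pooled
r² ≈ 0.15; the within-area value is not published and is a modelling
choice). Spike traces are Gaussian spike templates plus a parameterized
ADP bump and Gaussian noise. All draws use the counter-based Philox
generator with recorded seeds. Passing the synthetic-cohort tests shows
the *pipeline* (metrics → tables → tests) recovers planted effects at the
published effect sizes; it says nothing about recording noise, electrode
artefacts, or cell-selection effects in real data.

## Known limitations

- **High-frequency following.** The calibrated soma follows one-AP-per-
  pulse trains only up to ~140 Hz (the fast AHP is deep and the somatic K⁺
  shunt outlasts a 5 ms inter-pulse interval). The cf protocol's default
  grid still spans 50–200 Hz and raises its per-frequency verification
  error above 140 Hz; analyses here use the followable 50–140 Hz range,
  where the 600 µm model shows a sharp cfADP onset (140 Hz) and the 200 µm
  model shows none. Real ttL5 neurons follow to 200 Hz; the model's
  critical frequencies are therefore compressed toward the top of its
  followable range.
- **Plateau boundary vs g_Ca.** At default g_Ca the plateau boundary sits
  at 350 µm and below it no plateau occurs. At strongly raised g_Ca
  (≳ 2×), models below the critical length can still ignite plateaus: the
  ignition voltage falls roughly with (slope/2)·ln g_Ca, and the
  calibrated length-leverage of the Ca²⁺-free tuft drive does not fully
  out-run it. The boundary is vertical at default densities but tilts at
  large g_Ca multiples.
- **Burst size.** BAC bursts here run 6–12 somatic APs, larger than the
  typical 3-AP experimental burst; the plateau duration (~60–90 ms) sits
  at the long end of the physiological range.
- Tuft I_h is modest in this calibration; reducing it raises (rather than
  slows) the tuft bAP peaks, although the positive length slope without
  I_h — the robust claim — holds.
- No NMDA conductances anywhere (deliberate; the phenomena studied are
  glutamate-independent), no morphological reconstructions, no
  temperature scaling (rates are fixed at the calibrated reference).
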