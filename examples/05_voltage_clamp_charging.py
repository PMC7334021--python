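"""Tuft charging under distal-trunk voltage clamp.

30 mV square commands of increasing width at the distal trunk: a short
step fails to charge the tuft to its DC level, a long one succeeds, and
raising tuft C_m (hence its time constant) slows charging further.
"""

import ttl5sim as t5
from ttl5sim.model import build_reduced

def tuft_peak(disc, width, amplitude=30.0):
    clamp = t5.StimulusEvent(("trunk", 1.0), "voltage_command", onset=20.0,
                             amplitude=amplitude, duration=width)
    tr = t5.simulate_clamped(disc, clamp, duration=140.0,
                             record=[("tuft", "tuft", 0.5)])
    return tr["tuft"].max()

disc = build_reduced(600.0).discretize()
for w in (5.0, 10.0, 20.0, 40.0, 80.0):
    print(f"step width {w:5.1f} ms -> tuft peak {tuft_peak(disc, w):7.2f} mV")

heavy = build_reduced(600.0, tuft_cm=3.0).discretize()
print(f"width 10 ms with tuft C_m = 3.0 µF/cm²: "
      f"{tuft_peak(heavy, 10.0):7.2f} mV")

print()
print("The tuft behaves as an RC load charged through the trunk: peak")
print("depolarization depends on the width of the invading waveform")
print("relative to the tuft time constant -- the mechanism linking bAP")
print("broadening to Ca2+ plateau initiation in long neurons.")
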