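"""Trunk length x g_Ca sweep of the normalized tuft voltage integral.

A coarse version of the plateau heat map (50 µm length steps, four g_Ca
scales) showing that the plateau turns on near 350 µm and, above that
length, grows with the Ca2+ channel density.
"""

import numpy as np

from ttl5sim.protocols import sweep_length_gca

lengths = np.arange(200.0, 701.0, 50.0)
scales = np.array([0.0, 1.0, 2.0, 4.0])
grid = sweep_length_gca(lengths=lengths, gca_scales=scales)

header = "len\\gCa " + "".join(f"{g:7.1f}" for g in scales)
print(header)
for i, L in enumerate(grid.axis1):
    row = "".join(f"{grid.values[i, j]:7.2f}" for j in range(len(scales)))
    print(f"{L:7.0f} {row}")

print()
print("Values are tuft voltage integrals normalized to the grid maximum.")
print("Rows below ~350 µm stay in the low mode at g_Ca = 0 and 1; above it")
print("the integral jumps to the plateau mode and scales with g_Ca.")
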