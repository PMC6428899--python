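"""Tracing through a filament crossing.

Where two flagella cross, the modal region breaks into pieces and the
skeleton gains a junction. Two refinements handle this: linear
stitching reconnects nearby segments (bounded by the approximate
flagellum width so separate structures are never merged), and
tangent-preserving branch resolution walks straight through junctions.
"""

import numpy as np

from flagtrace import StitchConfig, resolve_branches, stitch_segments
from flagtrace.medial_axis import Skeleton

# --- stitching: a 3-px break is bridged, a 20-px gap is refused ---
a = np.array([(5, c) for c in range(10)])
b = np.array([(5, 13 + c) for c in range(10)])
regions, bridges = stitch_segments([a, b], StitchConfig(radius_px=6.0))
print(f"3-px gap, radius 6:  {len(regions)} region(s), bridge {bridges[0].tolist()}")

far = np.array([(5, 30 + c) for c in range(10)])
regions, bridges = stitch_segments([a, far], StitchConfig(radius_px=6.0))
print(f"20-px gap, radius 6: {len(regions)} regions, {len(bridges)} bridges")

# --- branch resolution: two skeletons crossing at 90 degrees ---
n = 21
mask = np.zeros((25, 25), bool)
for c in range(n):
    mask[10, c] = True  # horizontal filament
    mask[c, 10] = True  # vertical filament
sk = Skeleton(mask)

path = resolve_branches(sk, start=(10, 0))
rows = set(path.points[:, 0].tolist())
print(f"horizontal trace:    {len(path)} px, rows visited = {rows}")
path = resolve_branches(sk, start=(0, 10))
cols = set(path.points[:, 1].tolist())
print(f"vertical trace:      {len(path)} px, cols visited = {cols}")
# Each filament is traced straight through the junction (a single row /
# column), rather than turning onto the other filament.
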