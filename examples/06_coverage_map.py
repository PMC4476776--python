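"""Estimate spatial AIS reception coverage from trajectory interpolation.

A reception hole is simulated over part of the region (60% message loss).
Trajectories are rebuilt from the received messages, interpolated at the
5-minute cadence, and the per-0.1-degree-cell ratio observed/expected
points estimates the local reception probability.
"""

import numpy as np
import aisfish as af

region = (10.0, 57.0, 12.5, 59.0)
# reception probability: 0.4 in the northern half, 1.0 in the south
probs = np.ones((2, 1))
probs[1, 0] = 0.4
hole = af.DropoutMap(57.0, 59.0, 10.0, 12.5, probs)

fleet = af.simulate_fleet(af.SimConfig(seed=9, dropout_map=hole))
tracks = af.build_trajectories(fleet.messages)
interp = af.interpolate_trajectories(tracks)
grid = af.coverage_grid(fleet.messages, interp)

df = grid.to_frame()
df = df[~df.indeterminate]
south = df[df.lat < 58.0]
north = df[df.lat >= 58.0]
print(f"cells with expected traffic: {len(df)}")
print(f"median coverage ratio, south (full reception): "
      f"{south.ratio.median():.2f}")
print(f"median coverage ratio, north (40% reception):  "
      f"{north.ratio.median():.2f}")
# Ratios near 1 mean messages arrive as often as the trajectories predict;
# the depressed northern ratio localises the reception hole.
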