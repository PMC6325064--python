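"""A single lazy-walk step, mass conservation, and the linear flat-surface MSD.

Builds a flat sheet, places all probability on the central node, advances the
walk and prints where the mass goes.  On a flat surface the walk is plain
Brownian motion: half the mass moves one node per iteration, so the Euclidean
MSD is exactly 0.5 * t node^2.
"""

import numpy as np

from memtopo import ProbabilityField, build_flat, msd_time_course, step

surface = build_flat(81, 81)
start = (40, 40, 0)

field = step(ProbabilityField.point_mass(surface, start))
print("after one iteration:")
print(f"  mass staying on the start node : {field.mass[surface.node_id(start)]}")
print(f"  mass on one of the 4 neighbours: {field.mass[surface.node_id((41, 40, 0))]}")
print(f"  total mass                     : {field.total_mass}")

series = msd_time_course(surface, start, 200)
for t in (10, 50, 200):
    print(f"  t={t:4d}  msd_2d={series.msd_2d[t]:8.3f}  (0.5*t = {0.5 * t})")
print("The planar MSD grows as 0.5 node^2 per iteration: simple diffusion.")
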