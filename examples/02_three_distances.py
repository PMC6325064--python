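"""The three distance notions: planar, volumetric, and within-surface.

The 2D and 3D Euclidean distances are straight lines that may leave the
surface; the shortest-within-surface distance (SWSD) is the geodesic along
face-adjacent surface nodes, one node unit per hop.  Even on a flat sheet the
SWSD is the city-block distance, so it reads 7 where the straight line reads
5 — a metric-intrinsic offset that D_rel analysis divides out.
"""

from memtopo import build_flat, build_ridges, compute_distance_maps

flat = build_flat(9, 9)
maps = compute_distance_maps(flat, (0, 0, 0))
i = flat.node_id((3, 4, 0))
print("flat sheet, node offset (3, 4):")
print(f"  2D Euclidean = {maps.d2[i]}   3D Euclidean = {maps.d3[i]}   SWSD = {maps.dswsd[i]}")

ridged = build_ridges((15, 7), ridge_height=4, ridge_width=3, spacing=5, phase=6)
maps = compute_distance_maps(ridged, (4, 3, 0))
j = ridged.node_id((10, 3, 0))
print("\nacross a 4-node-high ridge, planar offset (6, 0):")
print(f"  2D Euclidean = {maps.d2[j]:.0f}   SWSD = {maps.dswsd[j]:.0f}"
      "   (6 along the floor + 2 x 4 over the ridge)")
print("The straight line tunnels through the ridge; the SWSD climbs over it.")
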