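# Methods

## Surfaces as node graphs

All surfaces are one-node-thick sheets of 6-connected cubic nodes in a 3D
volume; the face-adjacency graph is the single definition of "within the
surface".  Coordinates are 0-based integers, `x`/`y` in the imaging plane and
`z` the height; node spacing is one distance unit everywhere, so all lengths
are in node units and all times in iterations.  Nodes at the lateral volume
rim simply have fewer neighbours — there is no wraparound and no ghost
layer; the walk operator's degree normalisation keeps mass conserved there.

Every built-in geometry is generated from a 2D integer height map
(`heights[y, x]`, row-major, origin top-left, as produced by scanning-probe
or confocal height imaging).  Each pixel contributes the node
`(x, y, h(x, y))`; wherever 4-adjacent pixels differ in height, a vertical
run of connector nodes is inserted on the **higher** pixel's column from the
lower height up to `h − 1`.  This run includes its lower endpoint — one node
per height level crossed — which is the minimal choice that leaves the sheet
face-connected (a run that excluded both endpoints would leave the step
diagonally separated).  The convention is recorded in each surface's
metadata.  Height maps cannot express overhangs; none of the modelled
topographies needs them.

Consequences worth knowing:

* a ridge of width ≥ 3 is hollow and impermeable (its two walls are separate
  columns); widths 1–2 are degenerate fins whose walls merge and become
  permeable at the base — allowed, but not folded surfaces;
* five-neighbour "internal corner" nodes arise at convex plan-view corners
  of a raised region whose flanking wall columns also reach the floor (slot
  corridor corners, non-indented pillar base corners).  Square pits have
  none: their plan corners meet only diagonally.  The default pillar builder
  indents the footprint corners and therefore shows degrees {2, 3, 4}.

## The walk

Diffusion is the lazy random walk with move probability fixed at 0.5: the
propagation operator has `D(i,i) = 0.5` and `D(i,j) = 0.5/deg(j)` for
adjacent nodes, i.e. the 50% of mass leaving a node splits equally among its
surface neighbours.  The printed matrix form of the discrete diffusion
equation is ambiguous about whether the divisor is the source or receiver
degree; receiver-degree splitting does not conserve mass on irregular
graphs, so source-degree splitting is used (columns sum to 1; total mass is
conserved to ~1e-15 per step and is asserted, never renormalised).  No free
diffusion constant is exposed: the lazy walk fixes the per-iteration rate
and time is measured in iterations.  The stationary distribution of this
operator is proportional to node degree (verified against its dominant
eigenvector), not uniform.

Long runs restrict the operator to an expanding region: nodes are ordered by
hop distance from the start, and the active prefix always covers the hop
ball of radius `t` plus a margin (default 64, grown in chunks).  Because the
support of the field can grow by at most one hop per iteration, and mass
only ever flows from the ball of radius `t−1` into the ball of radius `t`,
the restriction is *exact* — restricted and full-graph propagation agree to
the last bit, which the tests assert at 1e-12.  Arithmetic is double
precision throughout.

Single-particle tracks sample the identical process (stay with p = 0.5,
else a uniform neighbour) from a named `numpy` generator seeded by the
caller; a track set is bit-reproducible from (seed, n_tracks, n_iterations).

## Distances

`d2` and `d3` are the planar and volumetric straight lines from the start
node.  The SWSD is computed by a level-synchronous wavefront (breadth-first)
transform on the adjacency graph with every hop weighing one node unit —
orthogonal propagation, so on a flat sheet the SWSD is the city-block
distance (7 for a 3,4,5 triangle) and exceeds the Euclidean measures by a
factor approaching `1 + 2/π` in MSD terms.  That metric-intrinsic offset is
deliberate and is divided out by D_rel; a Euclidean-weighted geodesic with
diagonal steps would contradict the orthogonal-propagation definition used
throughout.  Unreachable nodes get an explicit `inf`, never a large finite
number.  Node-wise `dswsd ≥ d3 ≥ d2` holds on every surface and is asserted
per map.

## Analysis

`MSD_m(t) = Σ u_t · d_m²` for each metric; `D_rel,m(t) = MSD_m(t) /
MSD_m^flat(t)` against a flat baseline simulated with the same engine.
D_rel is a per-iteration ratio of MSDs, not of fitted slopes: the curves are
functions of iteration and their transient structure (superdiffusive peaks,
crossings of 1) is the object of interest.  A separate least-squares tangent
fit (`fit_diffusion`, window defaulting to the last half of the series)
provides MSD/t-style diffusion rates where a single number is wanted.

The flat baseline sheet is sized at half-width `4·sqrt(t_max) + 8` nodes
(eight per-axis standard deviations of the final distribution).  The
support of a walk strictly speaking grows one node per iteration, so no
affordable sheet contains it entirely; beyond 8σ, however, the mass is
below 1e-26 of the total, orders of magnitude under every tolerance used
anywhere in the package.  The same sizing rule governs the test surfaces.

Anomaly classification labels each iteration super/normal/sub against a
tolerance band (default ±0.01 around 1) and reports the raw curve's
landmarks — maximum, minimum, and the first return to 1 after the maximum —
with ties broken to the earliest iteration; the return is only reported
when a genuine super phase (max > 1) precedes it.  Distance-shell histograms
use floor binning (SWSD distances are already integers).

## Study geometries

The fixture catalog pins the conditions used by the tests and the
acceptance script:

* `ridges_folded` — ridges h4/w4/s2; default extent 275 × 637 so that a
  6000-iteration run stays ≥ 8σ from the rim.  6000 iterations (rather than
  ~3000) are used for plateau read-outs because the 3D curve approaches the
  plateau as `0.592 + c/t` with `c ≈ 14` and needs t ≳ 4600 to settle at two
  decimals.
* `ridges_control` / `ridges_slot` / `ridges_notch` — ridges h7/w3 at
  12-node period in a 1023 × 1023 × 9 volume.  The 9-node gap has an exact
  centre, so "midway between the defect and the next ridge" is the node 5
  columns from either ridge edge; the defect sits in the adjacent ridge on
  the start row.  The slot cuts the ridge to its base at one row (its base
  corners are the five-neighbour nodes that seed the superdiffusive
  transient); the notch default cuts to one node above the base (depth 6),
  the deepest non-through cut — a shallow notch produces an invisibly small
  super phase, a deep one a clearly visible phase that still orders below
  the slot.  Defect runs use 500 iterations, which covers the peak and the
  return to 1.
* `pillars` / `invaginations` / `bumps` / `quadrant_arena` — deformed
  reliefs with the pillar parameterisation (5-node base, 15 high, 12-node
  offset-row "hexagonal" grid, corners indented; pits are inverted pillars).
* `synthetic_cell` — a seeded generator emulating what high-resolution
  surface scans of live epithelial cells show: a few smooth crowns (Gaussian
  domes, amplitude 60, σ 40 nodes) carrying fold-like undulations (amplitude
  5, period 24, scaled by local body height) and ~200 microvillus-scale
  bumps (amplitude ≤ 3, σ 2), quantized to integer heights.  It reproduces
  the qualitative behaviour of cell surfaces — all metrics under-report,
  `D_rel(2D) < D_rel(3D) < D_rel(SWSD) < 1`, with the planar curve declining
  without plateau — but it is a synthetic stand-in: it has no basal
  membrane, no anisotropic microvilli, and its statistics were chosen once
  as plausible, not fitted to any measured cell.  Passing tests on it show
  the machinery behaves correctly on cell-like relief, not that any
  particular cell measurement is reproduced.

## Known limitations

* Static surfaces only; no membrane fluctuations, particle-induced
  curvature, binding kinetics, crowding, or off-lattice motion.
* The orthogonal grid quantizes all slopes to steps; sub-node geometry and
  anisotropic node spacing are out of scope.
* One-node-wide features (fins, width-2 ridges) degenerate in a one-node
  sheet representation, as noted above.
* On deformed surfaces the SWSD remains an imperfect proxy: it measures the
  single shortest route, not the ensemble of actual paths, so it still
  under-reports net movement there — this is a property of the measure, not
  a numerical artifact.
* The slot experiment's landmark iterations are read from a D_rel curve
  that is flat to ~3 × 10⁻⁴ around its maximum; their exact values are
  therefore sensitive to fine analysis conventions even though the curve
  itself is fully deterministic.
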