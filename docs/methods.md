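# Methods

`glomnet` analyzes the kidney glomerulus as a graph: branch points are nodes,
capillary segments are edges, and the afferent and efferent arterioles are two
designated degree-1 terminals. This note records the models implemented, the
parameters that matter, the numerical choices, and what the synthetic
generator does and does not emulate.

## Network model

A tuft is a geometric multigraph. Parallel segments between the same branch
points are allowed (longitudinal splitting produces exactly this), self-loops
are not. Validation enforces: unique ids, finite positions, exactly one
afferent and one efferent terminal, both of degree 1, and a connected graph.
Coordinates are right-handed and in µm; when networks are digitized from
serial sections a z step of 0.5 µm per section is the conventional scale
(documented, not enforced). A missing segment length defaults to the straight
endpoint distance, i.e. tortuosity is ignored unless lengths are supplied.

Matrix-based operations use boolean adjacency (connected-or-not): the
shortest-path argument only needs reachability, so parallel segments count
once.

### Orientation frame

The pole frame makes "vascular pole up" computable: the centroid is the mean
node position, the pole axis points from the centroid to the midpoint of the
two terminals, and the cleft normal is the afferent→efferent direction
Gram–Schmidt-orthogonalized against the pole axis. Networks whose terminals'
midpoint coincides with the centroid (e.g. perfectly collinear chains) have
no frame; `analyze` then reports the frame-dependent scores as `None` rather
than failing.

## Shortest paths by matrix powers

The geodesic length between the terminals is the smallest k for which the
boolean adjacency matrix A satisfies (A^k)[afferent, efferent] ≠ 0. Powers
are taken over the OR/AND semiring (each integer product is collapsed back to
{0,1}), so entries cannot overflow at any k. All geodesics are then
enumerated by backtracking from the efferent terminal through neighbors whose
afferent hop distance decreases by exactly 1 per step; the enumeration order
is lexicographic in node ids, so output is reproducible. A dynamic-programming
count is checked against a cap (default 10,000) before any path is
materialized.

Length convention: a path's length is its number of **segments**; the
interior branch-point count (length − 1) is reported alongside, since both
conventions appear in the literature.

Side assignment: a node is afferent-side if it is strictly closer (in hops)
to the afferent terminal, efferent-side if strictly closer to the efferent
one, and boundary on ties. Tie nodes are excluded from cross-segment
counting, avoiding arbitrary side flips. A segment violates the no-cross zone
when its endpoints carry strictly opposite sides *and* its midpoint lies on
the vascular-pole side of the centroid — such a capillary would let blood
reach the efferent arteriole largely unfiltered.

## Kirchhoff flow

Each segment is a resistor; unit current enters at the afferent terminal and
leaves at the efferent terminal, which is grounded. Node potentials solve the
weighted Laplacian system; per-segment current is g·(φ(u) − φ(v)), with
parallel segments carrying individual currents. Two conductance models:

* `unit` (default): g = 1 per segment. The topological arguments are
  weighting-free, so this is the default, and it keeps radii out of the flow
  computation (important for the flow–diameter concordance, which would
  otherwise be circular).
* `poiseuille`: g = r⁴/L, the laminar-flow scaling. The proportionality
  constant is 1 since only relative currents matter.

Numerics: the reduced symmetric system (efferent row/column removed) is
solved by a direct sparse factorization, and Kirchhoff's current law is then
verified at every internal node; a residual above 1e-8 (absolute, for unit
injection) raises rather than returning a silently bad solution. Observed
residuals are at machine precision (~1e-15). Segment depth for the profiles
is hop-based — min of the endpoint distances from the afferent terminal,
normalized by the maximum — mirroring the purely topological framing; depth
profiles report the mean |current| (or mean radius) in equally spaced bins.

## Planarity with certificates

Why planarity: repeated longitudinal splitting (intussusception) can only
produce planar networks, so a nonplanar tuft rules out splitting as the sole
branching mechanism. Because the verdict carries that argument, it is always
certified:

* planar: a rotation system (cyclic edge order per node) whose traced faces
  satisfy Euler's formula V − E + F = 2 on every component;
* nonplanar: an edge-minimal nonplanar subgraph, by Kuratowski's theorem a
  subdivision of K5 or K3,3, checked independently by `verify_kuratowski`
  (smooth degree-2 vertices, then match K5 or K3,3 exactly; smoothing that
  would create a loop or parallel edge invalidates the witness).

Algorithm choice: Demoucron–Malgrange–Pertuiset path addition, run per
biconnected block (iterative Hopcroft–Tarjan decomposition). Starting from a
cycle, each step computes the bridge fragments of the unembedded remainder,
rejects if any fragment has no face containing all its attachments, embeds a
fragment with a unique admissible face first (else any), and splits that face
along a path through the fragment. Block rotations are concatenated at cut
vertices. The method is quadratic rather than linear-time, which is
irrelevant at capillary scale (E < 500 after simplification) and buys a
construction that is simple enough to verify independently: every embedding
the package returns is re-checked by face tracing before being handed out.
Inputs are first reduced by `simplify_topology` (drop self-loops, collapse
parallels, smooth internal degree-2 nodes, prune internal dead ends — all
planarity-preserving in both directions), and graphs with E > 3V − 6 are
rejected before any embedding work. Witnesses come from deletion refinement:
scan edges in sorted order, keep a deletion whenever the remainder stays
nonplanar. Quadratic in E, deterministic, and independently checkable.

## Growth simulator

The generator emulates glomerulogenesis at the topological level: the tuft
begins as a single capillary loop and adds branches by three mechanisms —
splitting (intussusception), sprouting (angiogenesis) and condensation
(vasculogenesis) — optionally under a physical barrier and a urinary-pole
growth bias.

Initial loop: `n_loop` branch points on a circle of radius `loop_radius`
(default 20 µm, the scale of an early capillary loop) in the plane spanned by
the pole axis (+z) and cleft normal (+x); the afferent terminal attaches near
the (−1,0,1) direction and the efferent near (+1,0,1), both on the
vascular-pole side. The efferent attachment is chosen, when possible without
leaving the vascular side, so that an odd number of loop nodes lies between
the attachments across the apex: the middle node is then equidistant from
both terminals and the initial cleft is a hop-distance boundary — the loop
starts with an intact no-cross zone, reflecting the anatomy in which the
cleft exists from the outset. Attachment dot products are rounded to 9
decimals so symmetric ties break by index, keeping outputs byte-identical
across platforms.

Events (n_events i.i.d. draws of kind with probabilities p_split, p_sprout,
p_condense, defaults 1/3 each):

* **split**: a segment u–v is replaced by two subdivided parallel copies
  u–m1–v, u–m2–v, the new nodes offset ±0.15·length perpendicular to the
  vessel (+2 nodes, +3 segments). A subdivided parallel duplicate embeds in a
  face adjacent to the replaced edge, so splitting preserves planarity — the
  property the whole argument rests on. The biological pillar-formation
  detail is abstracted away.
* **sprout**: two vessels whose midpoints lie within `d_max` are subdivided
  and the subdivision points joined (+2 nodes, +3 segments).
* **condense**: as sprout, but the bridge runs through a new precursor node
  at the jittered midpoint (+3 nodes, +4 segments).

Event sites are pole-biased: segments are drawn with weight ∝ exp(β·depth),
where depth is the distance *below* the centroid along the pole axis,
normalized by `loop_radius` so that β (default 2) is dimensionless and the
weights stay in a numerically sane range. Terminal-incident segments are
never event targets (the arterioles themselves do not remodel here). The
locality radius `d_max` defaults to `loop_radius`: large enough that
neighboring arcs of the initial loop can sprout onto each other (their
midpoints sit ~0.7·loop_radius apart), small enough to forbid tuft-spanning
connections. Partner vessels may share a branch point — a sprout landing
just past a branch is biologically unremarkable.

Barrier semantics: the barrier idealizes a mesangial structure spanning the
cleft on the vascular-pole side. Two rules implement it. (1) A sprout or
condensation whose straight connector pierces the cleft plane at a point in
the vascular half is blocked outright. (2) Any event — including a split —
whose outcome would contain a vascular-half cross segment (opposite
hop-sides, midpoint above the centroid) is reverted and logged as blocked.
Rule 2 is needed because hop-side labels are global: subdividing a vessel
near the apex can flip side labels and create a cross segment without any new
connector. With both rules, barrier-on networks maintain a clean no-cross
zone at every accepted state, which is the invariant the analysis tests.

Randomness and replay: one seeded NumPy PCG64 generator drives everything;
per event, the kind is drawn first, then locations, then positional jitters
(sd 0.5 µm, which also avoids exact coincidences). The event log records the
full structural edit (removed segments, new nodes with positions, new
segments), so replaying the log onto the initial loop reconstructs the final
network exactly, with no random numbers.

Radii: r = r0·|I|^γ·(1 + ε) with unit-model current I, r0 = 3 µm (capillary
scale), Murray exponent γ = 1/3 by default (only monotone correspondence is
asserted biologically, so γ is configurable), ε zero-mean Gaussian (default
sd 0.05), floored at 0.1·r0. The floor deliberately ties near-zero-flow
segments.

### What the generator does and does not emulate

It reproduces the qualitative organization of real tufts: ~40–300 branch
points, single inlet/outlet, growth from one loop, nonplanarity when
sprouting is allowed, planarity under pure splitting, a no-cross zone under
the barrier, a geodesic length that stabilizes while the tuft keeps growing,
and flow-graded calibers. It does **not** model PDGF signaling, podocyte or
mesangial biology, hemodynamic remodeling, pulsatile or turbulent flow,
filtration leak, or realistic 3D packing (nodes can pass near each other
without colliding). Real event-type proportions and the pole-bias strength
are unknown; the defaults were chosen once to reproduce the qualitative
claims and are exposed in `GrowthConfig`. Because the simulated arterioles
both carry the full unit current, their assigned radii are nearly equal: the
simulator does not emulate the afferent/efferent caliber asymmetry of real
arterioles, so the measured area-ratio statistic is exercised on constructed
inputs, not recovered from simulation. Passing tests therefore validate the
analysis machinery and the internal consistency of the growth model — not
the biological fidelity of any particular parameter value.

## Morphometry

* Arteriole cross-sections use the radius of the single terminal-incident
  segment (area = πr²); a directly measured `area` column, when present in
  the segment table, takes precedence, since lumen areas are measured on
  sections in practice.
* Spearman concordance between |current| and radius is computed in-repo as
  the Pearson correlation of midranks (ties averaged); the unit flow model is
  used so radii play no part in the currents. Poiseuille-model concordance is
  available but circular by construction — use it knowingly.
* The geodesic-length-versus-size slope is an ordinary least-squares slope by
  the closed form. The test threshold |slope| < 0.02 steps/node for "largely
  independent of size" is a suite calibration constant, not a measured value.

## Problem sizes and defaults used in the checks

The shipped checks run the pipeline at tuft scale: growth runs of 15–120
events (final networks of roughly 40–300 branch points), 50–100 seeds per
claim, 200 random graphs for the shortest-path oracle, 2,000 sampled
connected graphs on ≤7 vertices against the exhaustive Kuratowski-subdivision
search, and 50 networks against a dense Kirchhoff solve. These sizes were
chosen to exercise every code path at the scale of real reconstructions
while keeping the whole suite fast on one CPU.

## Known limitations

* Weighted (physical-length) shortest paths are deliberately out of scope;
  the statistic is topological.
* Demoucron's algorithm is quadratic; beyond ~10⁴ edges a left-right
  implementation would be preferable.
* The witness refinement returns one edge-minimal subgraph, not all of them;
  which one depends on the (deterministic) edge order.
* The barrier's rule 2 evaluates the no-cross invariant under the network's
  own evolving pole frame; in pathological geometries (centroid drifting
  across the tuft) an early-accepted segment could only be "fixed" by
  blocking later events, which may slightly suppress late vascular-pole
  growth.
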