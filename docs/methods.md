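# Methods

## Cell shape and lattice

The basic cell is Kelvin's tetrakaidecahedron — the truncated octahedron
with vertices at all permutations of (0, ±1, ±2) — rotated so a body
diagonal (the normal of a hexagonal face) points along the stacking axis
and compressed along that axis by a flattening ratio. All combinatorics
(faces, edges, face-sharing between cells) are computed in these exact
integer coordinates; rotation, flattening and micrometre scaling are one
affine map applied last, so coincidence tests never involve floating-point
tolerance.

Cells tile space on a BCC lattice. Seen along the stacking axis the
columns form a triangular lattice whose columns fall into three height
classes offset by 0, 1/3 and 2/3 of the stacking period. Each column has
six lateral neighbour columns — three whose nearest cell sits 1/3 period
higher, three 1/3 lower — and each cell touches 14 neighbours: 2 stacked
(apical/basal hexagons), 6 through tilted hexagons (cells ±1/3 period
away) and 6 through squares (cells ±2/3 away). A periodic lattice must
have column counts divisible by 3: the torus identification has to map
height classes onto themselves, which is impossible otherwise. The default
domain is therefore 21×21 columns (441 cells in the barrier layer).

**Flattening ratio** (default 0.25, dimensionless): granular-layer cells
are conspicuously flattened but no measured aspect ratio is available;
0.25 gives a visibly flattened cell. Flattening only rescales the z axis,
so every en face (area, adjacency, coverage) statistic is independent of
it; Z orderings are invariant and only Z magnitudes scale.

**Micrometre scale**: one isotropic scale factor converts lattice units to
µm. It is calibrated so the mean single-edged polygon area equals the
905.8 µm² measured in mouse-ear whole mounts; with the default lattice
this gives ≈10.2 µm per lattice unit.

## Turnover dynamics

State per column: the height of its current barrier (SG2) cell, tracked
exactly in thirds of the stacking period (`h3 = class − 3 × turnovers`),
and a phase (STEADY / WAITING / TRANSITION). Heights of distinct
neighbouring columns can never tie (classes differ mod 3), so "locally
highest" needs no tie-breaking.

Rules per 7.2 min frame (the movie frame interval; deadlines quantize to
it):

1. *Completion.* A TRANSITION column past its deadline becomes STEADY; the
   incoming cell is now the column's only barrier cell.
2. *Firing.* A WAITING column past its deadline starts its transition: the
   cell below is promoted (two barrier cells now stack in the column), the
   exiting cell begins its SG2→SG1 differentiation, and the column's
   *visible height drops immediately* — the exiting cell is fading out of
   the barrier and no longer takes part in height comparisons. The
   transition lasts the TJ-disappearance duration, 2.4 hr.
3. *Eligibility.* A STEADY column strictly higher than all six lateral
   neighbours (transitioning neighbours counted at their incoming cell's
   height) begins WAITING, with a deadline drawn uniformly on
   [0, wait_max], wait_max = 9.6 hr. Waiting is non-preemptive; since
   neighbour heights only ever decrease, eligibility cannot be lost.

Two design points deserve emphasis because the alternatives fail
quantitatively. If the exiting cell kept its height until completion and
neighbours of a transitioning column were blocked, the neighbourhood
serializes so strongly that the mean cycle stretches to ~72 hr and the
double-edged share drops to ~3.4%. With the height drop at transition
start and no blocking, the same parameters give a ~24.2 hr mean cycle and
9.9% double-edged — the observed operating point. Adjacent columns can
then transition simultaneously; this is geometrically safe because every
lattice edge belongs to exactly three cells, so no seam can ever be shared
by more than three barrier cells.

**Initialization and burn-in**: columns start at their class heights with
desynchronized bookkeeping entry times; statistics discard a 48 hr burn-in
(about two turnover cycles; the double-edged fraction is stationary well
before that).

**Residence time**: a cell enters the barrier layer when it is promoted
(its column's transition starts) and exits when its own SG2→SG1
differentiation starts (the column's next transition start). The mean of
this interval is the turnover time, and it satisfies the renewal identity
*double-edged fraction = disappearance duration / mean residence* — the
identity behind the calibration 2.4 hr = 24 hr × 9.8/100. A
completion-inclusive variant (adds one disappearance duration, ≈26.8 hr)
is available in `residence_times(..., definition="completion")`.

**Determinism**: one `numpy` generator seeded from the config drives
every draw in a fixed column order; identical configs give byte-identical
event logs.

## Honeycomb extraction

The TJ ring of a barrier cell is determined by which of its six upper
contact faces (3 hexagons toward the up-columns, 3 squares toward the
down-columns) are still held by a neighbouring barrier cell: the ring is
the boundary of {apical hexagon} ∪ {freed upper faces}. Junctions sit at
the apical edges of the covered contacts; freed directions drop the ring
to the next contact below. The extremes are the apical hexagon alone (all
six neighbours higher; en face area 3√3 lattice units²) and the maximal
cross-section circuit (all six lower; area equal to the cell silhouette,
8√3/1 ≈ 13.86 units²). Between its own transitions a column's ring only
ever grows, face by face, as neighbours turn over — the edge-by-edge
replacement cycle.

A transitioning column shows two polygons: the exiting cell's pre-existing
ring (the *exterior*; all its neighbours are lower at firing time, so it
is the maximal circuit) and the incoming cell's apical hexagon (the
*interior*). Each seam is classified by the cells containing it: each
tessellation edge belongs to exactly three cells, and the seam's sharing
set is those of the three that are currently barrier cells — two gives a
bicellular seam, three a tricellular one. Every interior seam is shared by
incoming + exiting + one lateral barrier cell (the firing rule guarantees
the lateral slots are occupied), hence all-tTJ; exterior and single-edged
seams are bicellular. Tricellular points at the vertices of single-edged
polygons (≥3 barrier cells meeting at a vertex) are recorded on the
polygon but not displayed.

**Barrier continuity** is audited structurally: every column carries a
closed displayed polygon, and every displayed seam is shared — as an
identical 3D segment, compared in exact wrapped integer coordinates — by
exactly two displayed polygons, so the honeycomb is a seam-shared tiling
of the torus with no holes. An optional geometric audit verifies that the
en face union of displayed polygons covers the periodic domain within
1e-6 of its area (shapely union over 2 lattice images). The
hexagonal-prism comparison lattice passes the audit when static and fails
it when one column slides upward: its seams leave the shared plane while
the en face projection still covers — the 3D tear that simple columnar
packings cannot avoid during turnover.

## Morphometrics

* **Polygon area**: shoelace area of the en face projection. For
  single-edged polygons the convention *include_overlap* (the default)
  takes the full area inside the polygon's own ring, including any region
  shared with adjacent exterior polygons; *plain* clips to the polygon's
  exclusive territory. On exact lattice honeycombs the single's ring abuts
  the exterior outline edge-for-edge, so the conventions coincide; they
  differ only on jittered meshes.
* **Polygon Z**: mean of vertex Z.
* **Octets**: one double-edged pair plus its six adjacent single-edged
  polygons; relative Z subtracts the octet mean. Pairs whose neighbourhood
  is not six singles (e.g. adjacent pairs) are skipped, as in manual
  scoring. Ordering claims are made at the octet-class level — exterior
  value vs the mean of its six singles vs interior value — because exact
  per-polygon ordering provably ties: a freshly renewed single *is* an
  apical hexagon, identical in area to the interior, and a freshly renewed
  lower-class single sits above the exterior ring's mean Z. The class
  orderings hold strictly for every octet observed in the test runs. The
  model's mean relative Z is +1.6 / +0.2 / −2.8 µm
  (exterior/single/interior); in vivo magnitudes (and the slightly
  negative single-edged mean) are tissue measurements the lattice model
  does not attempt to reproduce — only signs of the extremes and the
  ordering are model claims.
* **Windows**: random axis-aligned 15,376 µm² squares on the torus;
  membership by en face centroid; each nested pair counts once through its
  exterior. An assay is one independent simulation seed with 20 windows
  drawn from random post-burn-in frames; the double-edged percentage is
  pooled within assay and reported mean ± SEM across assays (five by
  default), giving 9.3 ± 0.3%.

## Synthetic microscopy

The generator emulates segmented en face whole-mount meshes: the ideal
steady honeycomb (three polygon-size classes in the 0 / +1/3 / +2/3
height pattern), double-edged pairs planted at 9.8% of columns on the
highest class (same-class columns are never adjacent, so planted pairs are
automatically non-adjacent; the rate is capped at one column in three),
µm scale calibrated to the 905.8 µm² single-edged mean, and i.i.d.
Gaussian localization jitter applied per shared mesh vertex (0.5 µm is
typical of the imaging emulated), with optional per-class Z offsets. It
does **not** model point-spread blur, segmentation failures, tissue
curvature, or cell-shape variability — so tests passing on synthetic
meshes validate the measurement operators and detector logic, not
robustness to raw-image artefacts. Planted pairs are recovered from
geometry alone (nested, smaller, lower) with 100% agreement up to 2 µm
jitter, because the interior ring sits a full cell height (~8.6 µm) below
the exterior.

## Numerical choices and problem sizes

* All topology in integer coordinates; torus wrapping by exact integer
  division (no epsilon comparisons anywhere in lattice logic).
* dt = 7.2 min divides the 2.4 hr disappearance exactly (20 frames), so
  transition durations are exact; event times are quantized to dt.
* With wait_max = 0 the dynamics collapse to a deterministic pipelined
  wave with residence exactly disappearance + dt — used as a closed-form
  oracle in the tests.
* Default study conditions: 21×21 periodic columns, 48 hr burn-in, 480 hr
  measured, five seeds (~8,700 turnovers per run). Honeycomb-level suites
  extract frames from shorter runs (48–96 hr measured) or strided frames
  of the long runs; these sizes give stable statistics at interactive
  runtimes.

## Limitations

Basal supply is assumed inexhaustible per column (no stem-cell kinetics,
no lineage structure); there is no mechanics (no forces, no cell-shape
relaxation, no curvature); the waiting-time bound 9.6 hr is a fixed
parameter, not derived; the exterior ring is held fixed during the
disappearance period rather than deforming gradually; and shedding of the
cornified layer above the barrier is out of scope.
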