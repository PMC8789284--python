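# Methods

This note documents the models, conventions and numerical choices behind
`medconn`: what each stage computes, which parameters matter, what the
synthetic generator does and does not emulate, and where the design was
genuinely open.

## Coordinate and depth conventions

Skeletons and synapse locations are stored in nanometres, the native unit
of serial-section EM volumes. Analysis parameters are specified in
micrometres (smoothing bandwidths, lattice pitch) and converted once at
module boundaries.

Depth through a neuropil is a signed percentage along the columnar axis: 0
at the distal surface, 100 at the proximal surface, negative in the optic
chiasm (distal to M1), above 100 proximal to the neuropil. The depth axis
is a *contract*: anything providing a distal surface, a proximal surface
and a monotone linear projection rule works. The shipped backend is a
planar slab (`PlanarDepthAxis`): the medulla is modelled as a flat sheet of
default thickness 40 um with depth along the slab normal. The real neuropil
is curved and the original workflow projected against registered surface
meshes; every downstream computation here consumes only depth fractions,
so the slab stand-in changes nothing in the statistics while making the
geometry exactly testable. For measured data, `fit_lattice_plane` derives
the axis as the total-least-squares plane of the column centers.

Layers are percent-depth bands between fixed demarcations:

* medulla (M1–M10): 0, 8.2, 26.2, 36.1, 45.9, 54.1, 62.3, 67.2, 76.2, 91.0, 100
* lobula (Lo1–Lo6, with Lo5 split A/B): 0, 4.2, 11.3, 22.4, 37.4, 49.4, 64.7, 100

Band membership is half-open `[lower, upper)` with 100 included in the last
layer; this makes the bands a true partition of [0, 100]. The boundary
convention is a package choice — the demarcation lists themselves do not
prescribe one.

## Column lattice and identity assignment

A medulla column is anchored by its Mi1 cell (exactly one per column): the
column center is the unweighted center of mass of the Mi1 node positions
whose depth falls in the M5 band, projected onto the lattice plane. Any
point (synapse, arbor node) belongs to the column whose center is nearest
in that plane; ties break toward the smallest column id so that assignment
is deterministic and order-independent.

Pale/yellow identity comes from aMe12 occupancy: a column is **pale** iff
at least one aMe12 vertical process is assigned to it, otherwise
**yellow** (unless DRA). The default vertical-process detector accepts any
per-column ascending run whose depth extent reaches from the M6 band up to
at least the M3 band, so both the short (M6→M3) and long (M6→M1) process
variants qualify. No distance cutoff is applied in the nearest-center rule;
vertical processes sit well inside columns by construction. Occupancy by
multiple aMe12 cells is resolved by set union, and the provenance (which
aMe12 claimed which column) is reported alongside.

**DRA** columns are detected from photoreceptor co-termination: a column is
DRA iff both its R7 and R8 terminal depths fall in the M6 band (centrally
R8 terminates in M3, far away, so the test is sharp). Columns missing
either terminal are flagged indeterminate and excluded. DRA overrides pale:
in the source data aMe12 touched only 1 of 42 DRA columns, so a stray
aMe12 process in a DRA column is treated as noise.

## Kernel-smoothed profiles

Spatial distributions of synapses (depth, planar distance to a home
column, arc length along the dorsal rim) are presented as kernel densities
in synapses per micrometre: each synapse contributes a unit-mass Gaussian
of standard deviation σ, summed on a regular grid padded ±4σ beyond the
data. The kernel is symmetric, hence zero-phase. Bandwidths follow the
published analysis: σ = 0.4 um for depth profiles, σ = 0.6 um for radial
and arc-length profiles. The grid step defaults to 0.05 um (≪ σ) and the
sum is evaluated by direct kernel summation rather than FFT convolution —
at these problem sizes exactness is cheaper than speed. Mass conservation
(trapezoidal integral = synapse count within 1%) is enforced by test.

## Dorsal-rim linearization

The DRA forms an arc; to express positions along it on a line, an ellipse
is fitted to the DRA column centers and every synapse is projected
perpendicularly onto it. The fit is the direct algebraic least-squares
conic fit with the ellipse constraint (4AC − B² = 1), in the numerically
stable partitioned formulation, after centering the points for
conditioning. "Least squares regression" on an ellipse is underspecified;
the algebraic direct fit was chosen because it is deterministic,
standard, and exact on noise-free inputs. A geometric (orthogonal-distance)
refinement was considered and deliberately omitted.

The perpendicular projection of a point is found by bracketed 1-D
minimization of squared distance over the parametric angle (coarse 720-
point scan, then bounded refinement to 1e-12); the arc length from the
positive major-axis vertex to the foot point is computed by adaptive
quadrature of the parametric speed. The arc coordinate increases with
parametric angle and is cyclic modulo the perimeter; the reference vertex
and direction are fixed conventions stated for reproducibility. A point at
the ellipse center has no unique projection and is an error.

## Connectivity summaries

Edges are ordered (pre, post) synapse counts restricted to a seed
photoreceptor set (outputs: pre in seed; inputs: post in seed). A partner
cell is **reliable** when it has more than two synapses (≥3) with the seed
set. Summary rows group reliable cells by type label (class label for
class-only identifications); sub-threshold cells pool into
`Identified_<3` / `Unidentified_<3` and reliable unidentified cells into
`Unidentified_>=3`, so grand totals equal the seed synapse count exactly.

Derived columns per row: %R7/%R8 of the row sum, %p/%y of the row sum
(central tables only; the DRA has no pale/yellow mosaic), %Total of the
grand total, and %Total_R7/%Total_R8 of each source class's total output
(denominators include the pooled rows). All arithmetic is exact — integer
counts and rationals — and rounding happens once at presentation.

**Rounding is half-to-even** at one decimal by default. The reference
tables contain exact-tie cells (81.25 printing as 81.2, 18.75 as 18.8)
that identify the original rounding as half-even; half-up is available as
a config option. One printed cell is arithmetically inconsistent with its
own counts (a %Total_R7 cell printing 11.3 where the exact value 11.35006
rounds to 11.4); the package reports the exact result and the discrepancy
is documented rather than reproduced.

**Selectivity**: a type is R7- (R8-) selective when at least 65% of its
seed input comes from that source class, evaluated on unrounded fractions
with an inclusive threshold; likewise pale/yellow on the mosaic axis.

**Coverage**: fraction of seed synapses on identified partners, overall
and restricted to reliable partners, plus the fraction of reliable
partners identified — computable from edge lists or directly from summary
counts (pooled rows carry the needed totals).

**Compartments**: every synapse carries a compartment (medulla / chiasm /
other), set explicitly or derived from negative depth; chiasm fractions
are reported per photoreceptor subtype and per partner type, and an unset
compartment is an error listing the offending synapses.

## Synthetic medulla generator

The generator emulates exactly the statistical structure the analysis
assumes, with ground truth retained for every draw:

* **Lattice**: offset hexagonal grid (defaults 30 × 26 ≈ 780 columns,
  pitch 5 um — consistent with a dorsal rim of a few tens of columns
  spanning ~50 um). The first `n_dra` (default 42) columns along the rim
  perimeter form a contiguous DRA arc; every other column is independently
  pale with probability 0.38, else yellow.
* **Photoreceptors**: two unbranched axons per column entering at depth
  −5 um (chiasm) and terminating uniformly within their characteristic
  band — centrally R7 in M6 and R8 in M3; in the DRA both in M6, with
  R8-DRA drawn from the shallower half of the band so it always ends
  before R7-DRA (the source gives the ordering but no distribution).
* **Target cells**: per-type templates with an arbor span in column units,
  a layer profile, R7/R8 and pale/yellow weights, a home-column boost
  (Dm8-style) and a chiasm fraction. Placement tiles home columns on a
  stride-(span+1) sublattice; Mi1-like templates place one cell per
  column; an aMe12-like template emits vertical processes exactly in the
  ground-truth pale set.
* **Synapses**: counts per (rule, source column, overlapping cell) are
  Poisson with mean = rule rate × source-class weight × mosaic weight ×
  home boost. Poisson is an assumption — the source reports no count
  distribution — and overdispersion is left as a config extension. Each
  synapse sits within 0.3 × pitch of its source column center (under half
  the pitch, so the nearest lattice center is provably the true column),
  at a depth drawn from the target's layer profile, or uniformly in the
  chiasm segment with the template's/rule's chiasm fraction (0.8 for the
  inter-photoreceptor R7→R8 rule, echoing the ~80% of that input found
  outside the medulla).

All draws come from a single seeded NumPy generator; identical seeds give
byte-identical exported files. Default per-column rates are a few synapses
per column-cell pair for the strong partners, loosely scaled from the
reference per-seed-column counts.

What the generator does **not** emulate: realistic neurite geometry
(arbors are node scatters, not branched trees), neuropil curvature, the
DRA arc's curvature on the lattice (the rim is straight; curved-rim
behaviour is exercised by fixtures sampled from true ellipses), tracing
errors, and overdispersed synapse counts. Tests passing on synthetic data
therefore validate the *bookkeeping and statistics* of the pipeline, not
its behaviour under reconstruction noise.

## Problem sizes in the shipped tests

The bundled suites run on a 10 × 10 lattice (8-column rim, ~3000 synapses)
and an 8 × 8 demo config, sizes chosen so the whole suite and the
acceptance script each complete in well under a minute while every
recovery check is exact at them. The generator scales to the full ~780-
column medulla unchanged (the study-scale lattice is exercised in the
pale-mosaic binomial test).

## Known limitations

* The slab depth axis ignores curvature; per-column axes from mesh normals
  are out of scope.
* Visual identification of additional DRA columns without reconstruction
  (the source added 15 such columns) has no algorithm and is not modelled;
  detection here requires both terminals.
* The layer demarcations were refined manually in the source against
  reference arborizations; the printed percentages are taken as final.
* Pooled summary rows reproduce the reference categories verbatim; cells
  identified only to class are summarized under their class label.
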