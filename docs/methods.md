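# Methods

## Geometry and overlap semantics

All neuritic regions are axis-aligned bounding boxes with **closed**
per-dimension intervals: boxes whose faces merely touch (equal
coordinates) intersect, with zero overlap volume. Dense neural models
routinely contain colinear faces — regions generated from the same
template at regularly spaced somas — so the degenerate case must be
handled identically by every detector for them to agree exactly. Zero-
volume overlaps yield an expected synapse count of zero downstream, so
including them is harmless and keeps the equivalence between detectors a
strict set equality rather than an approximate one.

Intersection uses early exit: the test rejects on the first dimension in
which one box's minimum exceeds the other's maximum.

## The staggered walk

Both box classes are sorted by begin face along the primary dimension and
consumed as one merged event stream. Tie order is fixed for determinism:
equal begin-face coordinates process axonal before dendritic, then by
region id. At each event the opposite class's open list is first purged of
items whose end face lies **strictly before** the new begin face (so
face-touching items stay open, implementing the closed-interval
convention), then the new box is compared against every remaining open
opposite item, and finally the new box joins its own class's open list.

Because purging happens at every event, every surviving open item is
guaranteed to overlap the new box in the primary dimension; the
`comparisons_1d` counter (the cost term `K_p`) therefore equals the
`overlaps_1d` counter in this implementation. Secondary and tertiary
interval tests are lazy with early exit.

The open list is a contiguous vector kept ordered by end face (insertion
by binary search), which gives optimal data locality; the
`tail_reorderings` and `items_shifted` counters record how often
insertions land away from the tail and how many items they displace,
quantifying when a tree- or skip-list-backed open list would start to pay.
A second backend is deliberately not provided: in Python the ordered
vector *is* the natural structure, and a second implementation behind the
same contract would duplicate the algorithm without changing any
observable output.

## Primary-dimension choice (dynamic variant)

The simple walk replays the identical event stream but performs no
interval tests: it only adds the size of the opposite open list at every
event. Its total equals the full walk's `comparisons_1d` **exactly**, on
every input — not approximately — because both traversals purge and count
against the same prefix of end-face-sorted items. The dynamic variant runs
the simple walk for X, Y and Z and sweeps the cheapest axis; ties break in
fixed X < Y < Z order. The pre-pass costs two sorts and one linear
traversal per axis, the same asymptotic cost as the sorts the full walk
already needs.

Degenerate inputs: with empty input, all counters are zero and the tie
rule returns X. When all boxes span the full extent of some dimension,
a sweep along it performs exactly `n_axonal * n_dendritic` comparisons
(nothing ever closes); the pre-pass prices this at its true cost and
avoids the axis whenever any other is cheaper.

## Model pipeline

**Placement.** Cell count per type is `round(soma_density ×
layer_volume)` — deterministic rather than a Poisson draw, so a parameter
file pins the model size exactly and tests can count on it. Somas are
uniform within the type's layer bounds. Region boxes are template boxes
translated to the soma; they may extend beyond the model space
deliberately, since clipping would change overlap volumes at patch
boundaries.

**Per-rule detection.** Each synapse rule selects the axonal region
instances of its presynaptic type and the dendritic instances of its
postsynaptic type; no other polarity/type pair is ever compared. A cell's
own axonal and dendritic boxes are compared like any others; rules can opt
out with `exclude_self`, which drops same-owner pairs from the result.

**Synapse placement.** The count inside one overlap is Poisson with mean
`density × volume` — the density-consistent choice given that small
overlaps should often receive none and large ones many. A
deterministic-rounding mode was considered and rejected as a default
because it biases low-volume overlaps to exactly zero; exact-count tests
instead pin the seed. Positions are three independent uniforms scaled to
the intersection box.

**Delays.** Delay = axonal Euclidean soma→synapse distance / axonal speed
plus the dendritic Euclidean synapse→soma distance priced piecewise by the
rule's (threshold, speed) profile, the last threshold being infinite. The
model carries no dendritic branching geometry, so true path lengths do not
exist in it; straight-line distance is the documented stand-in. Units:
µm, µm/ms, ms.

## Reproducibility

All model randomness flows through a 32-bit multiply-with-carry generator
(multiplier `0xffffda61`) whose state update is pure integer arithmetic —
bit-identical across platforms. Streams are derived from the master seed
by a SplitMix64-style hash of integer indices. Soma placement uses one
stream; each overlap's synapses use a stream indexed by `(rule index,
axonal region id, dendritic region id)` and are emitted in canonical
(rule, axonal id, dendritic id) order, so the generated network is a pure
function of the parameter file: naive, fixed-axis and dynamic detection
produce byte-identical outputs. Uniform variates are `u32 / 2^32`.
Poisson draws use Knuth's product method (exact; `O(λ)` uniforms), with
large means decomposed into chunks of 500 to avoid `exp` underflow.

## Octet splitting

`octet_split` replaces each selected dendritic template box by the eight
boxes obtained by halving every dimension at its midpoint. Midpoints are
exact in binary floating point whenever bounds are representable, so
children tile the parent exactly and, for any fixed axonal set, per-pair
overlap volumes aggregated over the eight children equal the parent's
overlap volume to rounding. Children are named `parent/k`, and rules
referencing the parent match all descendants, so synapse densities need no
adjustment: expected synapse counts are conserved at the expectation level
exactly. Splitting multiplies the box count — and hence `K_p` — roughly
eightfold per dendritic class; the cost is bought back as spatial accuracy
when region shapes are not well approximated by one box.

## Synthetic populations

`generate_boxes` produces the structural stress cases: log-uniform edge
lengths (sizes varying over orders of magnitude), a nesting fraction
(boxes drawn strictly inside an earlier box — across classes, so dendritic
boxes nest inside axonal ones), a colinear fraction (boxes snapped to
share a face coordinate with an earlier box), and four anisotropy presets
— isotropic, parallel-fiber (long Y, thin X/Z), flat-plate (thin Y), and
worst-case (all boxes span one named dimension). Fractions are honored to
within integer rounding by assigning exact flag counts, not by Bernoulli
draws.

What the generator does *not* emulate: spatial correlation between box
positions and a layered tissue architecture (somas in layers, regions at
type-specific offsets), inhomogeneous densities, or realistic
region-count-per-cell distributions. Passing the oracle-equivalence and
scaling checks on these populations demonstrates correctness and
complexity on the structural degeneracies, not biological realism; the toy
cerebellum fixture covers the layered, rule-gated path end to end at small
scale.

## The toy cerebellum fixture

A 600 × 600 × 200 µm patch with three types (granule, Purkinje, Golgi) at
densities that instantiate 2 + 1 + 1 cells. Granule parallel-fiber boxes
are 6 × 600 × 10 µm (long in Y); Purkinje dendritic plates are
200 × 8 × 120 µm (thin in Y and much narrower in X than the patch), so the
granule→Purkinje sweep is cheapest along X and the dynamic walk never
chooses Y — the fixture exhibits, at toy scale, the anisotropy that makes
axis choice matter in real tissue. Synapse densities are sized so the
4-cell model carries ≈15 expected synapses (measured 14.9 averaged over
50 master seeds); the shipped master seed realizes a representative
network of 17 synapses in 2 overlaps. Propagation speeds: 300 µm/ms along
parallel fibers, dendritic profile 100 µm/ms within 100 µm of the soma and
50 µm/ms beyond; 500 µm/ms along Golgi axons with a flat 200 µm/ms
dendritic speed.

## Problem sizes and numerical choices

The shipped verification campaign uses 150–200 randomized populations of
10–1000 boxes per class and a scaling series up to 4000 boxes per class —
sizes at which the naive oracle remains exactly computable, chosen so the
whole suite verifies every structural case in minutes on one CPU. Overlap
set comparisons between detectors are exact (identical floats: both
compute `max(lo), min(hi)` of the same inputs); volume aggregation across
an octet split is compared at 1e-9 relative tolerance to absorb summation
order; statistical calibrations use fixed seeds and three-standard-error
bands. The cell-count and expected-synapse size guards refuse accidental
supercomputer-scale requests (defaults: 5 × 10⁶ cells, 2 × 10⁷ expected
synapses), overridable per run.

## Known limitations

- Regions are plain boxes: no branching morphology, no oriented boxes, no
  spheres; delays use straight-line distances.
- Synaptic attenuation is not modelled (no defensible formula without
  morphology).
- The detector is single-threaded; the algorithm parallelizes naturally
  over synapse rules, but distribution is out of scope.
- `simple_walk_count` equals the walk's comparison count by construction
  of this implementation's lazy purge; an open-list with deferred batch
  closing would make `comparisons_1d` exceed `overlaps_1d`, and the
  prediction would become an upper bound rather than an identity.
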