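"""Synthetic box populations and toy model specs for testing and benchmarks.

The detector's hard cases are structural, not statistical: boxes varying
drastically in size, boxes nested completely inside other boxes, boxes
sharing face coordinates, and strongly anisotropic boxes (the cerebellar
parallel fiber — hundreds of micrometres long in Y, a few micrometres thin
in X and Z — is the archetype).  :func:`generate_boxes` produces populations
exhibiting each of these on demand, so every algorithm is testable without
external data.

Anisotropy presets
------------------
``isotropic``
    Log-uniform edge lengths, identically distributed per dimension.
``parallel_fiber``
    Long in Y (a large fraction of the space extent), thin in X and Z.
``flat_plate``
    Thin in Y, broad in X and Z (a Purkinje dendritic plate).
``worst_case``
    Every box spans the full space extent in one named dimension — the
    degenerate input on which a sweep along that dimension performs all
    n^2 comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import List, Tuple

import numpy as np

from .geometry import AABB
from .model import ModelSpec, parse_model_spec

__all__ = [
    "BoxPopulationParams",
    "generate_boxes",
    "scaling_population",
    "toy_cerebellum_spec",
    "minimal_two_type_spec",
    "PRESETS",
]

PRESETS = ("isotropic", "parallel_fiber", "flat_plate", "worst_case")


@dataclass(frozen=True, slots=True)
class BoxPopulationParams:
    """Recipe for one randomized two-class box population.

    ``nesting_fraction`` of each class's boxes are generated strictly inside
    a previously generated box; ``colinear_fraction`` share a face coordinate
    with an existing box.  Both are honored to within integer rounding.
    Edge lengths are log-uniform between ``min_edge`` and ``max_edge``
    micrometres (per-dimension bounds adjusted by the preset).
    """

    n_axonal: int
    n_dendritic: int
    space: AABB = AABB((0.0, 0.0, 0.0), (1000.0, 1000.0, 1000.0))
    min_edge: float = 5.0
    max_edge: float = 200.0
    preset: str = "isotropic"
    worst_axis: int = 0
    nesting_fraction: float = 0.0
    colinear_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_axonal < 0 or self.n_dendritic < 0:
            raise ValueError("box counts must be >= 0")
        if not 0.0 <= self.nesting_fraction <= 1.0:
            raise ValueError("nesting_fraction must be in [0, 1]")
        if not 0.0 <= self.colinear_fraction <= 1.0:
            raise ValueError("colinear_fraction must be in [0, 1]")
        if self.preset not in PRESETS:
            raise ValueError(f"preset must be one of {PRESETS}, got {self.preset!r}")
        if not 0.0 < self.min_edge <= self.max_edge:
            raise ValueError("need 0 < min_edge <= max_edge")


def _edge_bounds(params: BoxPopulationParams) -> List[Tuple[float, float]]:
    """Per-dimension (min, max) edge-length bounds implied by the preset."""
    ext = params.space.extents
    lo, hi = params.min_edge, params.max_edge
    thin = (lo, min(hi, 4.0 * lo))
    if params.preset == "isotropic":
        return [(lo, hi)] * 3
    if params.preset == "parallel_fiber":
        long_y = (0.5 * ext[1], 0.95 * ext[1])
        return [thin, long_y, thin]
    if params.preset == "flat_plate":
        return [(lo, hi), thin, (lo, hi)]
    # worst_case: the named axis is forced to the full extent downstream.
    return [(lo, hi)] * 3


def _flags(rng: np.random.Generator, n: int, fraction: float) -> np.ndarray:
    k = int(round(fraction * n))
    flags = np.zeros(n, dtype=bool)
    flags[:k] = True
    rng.shuffle(flags)
    return flags


def generate_boxes(params: BoxPopulationParams) -> Tuple[List[AABB], List[AABB]]:
    """Generate (axonal, dendritic) box lists; deterministic per seed.

    Axonal boxes are generated first; nested boxes pick their parent from
    everything generated so far (either class), so a nested dendritic box
    may sit inside an axonal one — the configuration that defeats classical
    segment-intersection sweeps.
    """
    rng = np.random.default_rng(params.seed)
    space = params.space
    bounds = _edge_bounds(params)
    ext = space.extents

    all_boxes: List[AABB] = []

    def standard_box() -> AABB:
        lo = [0.0, 0.0, 0.0]
        hi = [0.0, 0.0, 0.0]
        for d in range(3):
            if params.preset == "worst_case" and d == params.worst_axis:
                lo[d], hi[d] = space.lo[d], space.hi[d]
                continue
            emin, emax = bounds[d]
            emax = min(emax, ext[d]) if ext[d] > 0 else emin
            emin = min(emin, emax)
            if emin == emax:
                edge = emin  # exact: log-uniform with equal bounds
            else:
                edge = math.exp(rng.uniform(math.log(emin), math.log(emax)))
            edge = min(edge, ext[d])
            lo[d] = space.lo[d] + rng.uniform(0.0, ext[d] - edge)
            hi[d] = lo[d] + edge
        return AABB(tuple(lo), tuple(hi))

    def nested_box(parent: AABB) -> AABB:
        lo = []
        hi = []
        for d in range(3):
            a = rng.uniform(parent.lo[d], parent.hi[d])
            b = rng.uniform(a, parent.hi[d])
            lo.append(a)
            hi.append(b)
        return AABB(tuple(lo), tuple(hi))

    def snap_colinear(box: AABB) -> AABB:
        other = all_boxes[int(rng.integers(len(all_boxes)))]
        d = int(rng.integers(3))
        face = other.lo[d] if rng.random() < 0.5 else other.hi[d]
        edge = box.hi[d] - box.lo[d]
        lo = list(box.lo)
        hi = list(box.hi)
        lo[d] = face
        hi[d] = face + edge
        return AABB(tuple(lo), tuple(hi))

    out: List[List[AABB]] = []
    for n in (params.n_axonal, params.n_dendritic):
        nest = _flags(rng, n, params.nesting_fraction)
        colin = _flags(rng, n, params.colinear_fraction)
        boxes: List[AABB] = []
        for i in range(n):
            if nest[i] and all_boxes:
                box = nested_box(all_boxes[int(rng.integers(len(all_boxes)))])
            else:
                box = standard_box()
                if colin[i] and all_boxes:
                    box = snap_colinear(box)
            boxes.append(box)
            all_boxes.append(box)
        out.append(boxes)
    return out[0], out[1]


def scaling_population(
    n_per_class: int,
    seed: int = 0,
    pitch: float = 4.0,
    section: float = 200.0,
    min_edge: float = 10.0,
    max_edge: float = 40.0,
) -> Tuple[List[AABB], List[AABB]]:
    """Self-similar population for scaling studies: constant box density.

    The model space grows along X in proportion to ``n_per_class`` (a strip
    ``n * pitch`` long with a fixed ``section x section`` cross-section)
    while the boxes keep a fixed size distribution, so the number of 3D
    overlaps per box — and the per-event open-list size of a sweep along X —
    stays bounded as n grows.  Naive comparison counts still grow as n^2.
    """
    space = AABB(
        (0.0, 0.0, 0.0),
        (max(n_per_class * pitch, max_edge), section, section),
    )
    params = BoxPopulationParams(
        n_axonal=n_per_class,
        n_dendritic=n_per_class,
        space=space,
        min_edge=min_edge,
        max_edge=max_edge,
        seed=seed,
    )
    return generate_boxes(params)


def _load_packaged_spec(filename: str) -> ModelSpec:
    text = resources.files("neurosweep").joinpath("data", filename).read_text()
    return parse_model_spec(text)


def toy_cerebellum_spec() -> ModelSpec:
    """The shipped three-type toy cerebellum model.

    Granule cells with long thin parallel-fiber axon boxes (long in Y),
    Purkinje cells with flat dendritic plates (thin in Y), and Golgi cells;
    densities sized so the default four-cell instantiation yields on the
    order of fifteen expected synapses.  Parses the version-controlled
    fixture file shipped with the package.
    """
    return _load_packaged_spec("toy_cerebellum.txt")


def minimal_two_type_spec() -> ModelSpec:
    """The shipped minimal two-type model: one axonal box, one dendritic
    box, one rule."""
    return _load_packaged_spec("minimal_two_type.txt")
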