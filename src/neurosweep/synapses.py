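"""Synapse placement within overlap volumes and propagation-delay assignment.

For every detected axonal-dendritic 3D overlap the expected synapse count
is ``rule.synapse_density * overlap_volume``; the realized count is a
Poisson draw with that mean (small overlaps frequently receive none, large
ones many), and each synapse is placed uniformly at random inside the
intersection box.

The random stream for each overlap is derived from the master seed, the
rule index and the two region ids involved — not from the order in which
overlaps were found — so the generated network is identical whichever
detection algorithm (naive, SW with any axis order, or SWD) produced the
overlap list.

Propagation delay is the time from the presynaptic soma along the axon to
the synapse plus the time from the synapse to the postsynaptic soma through
the dendritic tree.  The model carries no branching geometry, so both path
lengths are straight-line Euclidean soma-to-synapse distances; the dendritic
leg is priced piecewise by the rule's distance/speed profile (dendritic
conduction slows with distance from the soma).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .geometry import Point3
from .model import ModelSpec, SynapseRule
from .placement import (
    CellInstance,
    RegionInstance,
    SizeGuardError,
    place_cells,
    instantiate_regions,
)
from .rng import MarsagliaMWC, stream_seed
from .sweep import OverlapRecord, WalkStats, detect_overlaps_by_rule

__all__ = [
    "Synapse",
    "NetworkResult",
    "sample_synapse_count",
    "place_synapses",
    "compute_delay",
    "expected_synapse_count",
    "generate_network",
]

#: Stream-derivation domain tag for synapse placement draws.
_TAG_SYNAPSE = 2

DEFAULT_MAX_EXPECTED_SYNAPSES = 20_000_000.0


@dataclass(frozen=True, slots=True)
class Synapse:
    synapse_id: int
    presynaptic_cell: int
    postsynaptic_cell: int
    position: Point3          # micrometres
    sign: str
    delay: float              # milliseconds


def sample_synapse_count(volume: float, density: float, rng: MarsagliaMWC) -> int:
    """Poisson synapse count with mean ``density * volume``."""
    if volume < 0 or density < 0:
        raise ValueError("volume and density must be >= 0")
    return rng.poisson(density * volume)


def compute_delay(
    position: Point3,
    axonal_soma: Point3,
    dendritic_soma: Point3,
    rule: SynapseRule,
) -> float:
    """Propagation delay in ms through one synapse.

    Axonal leg: Euclidean distance from the presynaptic soma to the synapse
    divided by the rule's axonal speed.  Dendritic leg: the Euclidean
    distance from the synapse to the postsynaptic soma, partitioned by the
    speed profile's distance thresholds, each segment contributing
    ``segment_length / segment_speed``.
    """
    ax_dist = math.dist(position, axonal_soma)
    dend_dist = math.dist(position, dendritic_soma)

    delay = ax_dist / rule.axonal_speed
    start = 0.0
    for threshold, speed in rule.dendritic_speed_profile:
        if dend_dist <= start:
            break
        end = min(dend_dist, threshold)
        delay += (end - start) / speed
        start = end
    return delay


def place_synapses(
    overlap: OverlapRecord,
    rule: SynapseRule,
    rng: MarsagliaMWC,
    presynaptic_cell: int = -1,
    postsynaptic_cell: int = -1,
    axonal_soma: Point3 = (0.0, 0.0, 0.0),
    dendritic_soma: Point3 = (0.0, 0.0, 0.0),
    synapse_id_start: int = 0,
) -> List[Synapse]:
    """Draw a Poisson count of synapses uniformly inside an overlap box.

    Per synapse the three coordinates are independent uniforms scaled to the
    intersection box; the sign is copied from the rule and the delay computed
    from the two soma positions.  Zero-volume overlaps yield no synapses.
    """
    count = sample_synapse_count(overlap.volume, rule.synapse_density, rng)
    lo, hi = overlap.intersection.lo, overlap.intersection.hi
    out: List[Synapse] = []
    for k in range(count):
        pos = (
            rng.uniform_in(lo[0], hi[0]),
            rng.uniform_in(lo[1], hi[1]),
            rng.uniform_in(lo[2], hi[2]),
        )
        out.append(
            Synapse(
                synapse_id=synapse_id_start + k,
                presynaptic_cell=presynaptic_cell,
                postsynaptic_cell=postsynaptic_cell,
                position=pos,
                sign=rule.sign,
                delay=compute_delay(pos, axonal_soma, dendritic_soma, rule),
            )
        )
    return out


def expected_synapse_count(
    overlaps_by_rule: Dict[int, Tuple[List[OverlapRecord], WalkStats]],
    spec: ModelSpec,
) -> float:
    """Sum of density * volume over all overlaps of all rules."""
    total = 0.0
    for rix, (records, _stats) in overlaps_by_rule.items():
        density = spec.synapse_rules[rix].synapse_density
        total += density * sum(r.volume for r in records)
    return total


@dataclass(slots=True)
class NetworkResult:
    """Everything one model-generation run produces."""

    spec: ModelSpec
    cells: List[CellInstance]
    regions: List[RegionInstance]
    synapses: List[Synapse]
    overlaps_by_rule: Dict[int, List[OverlapRecord]] = field(default_factory=dict)
    stats_by_rule: Dict[int, WalkStats] = field(default_factory=dict)

    @property
    def overlap_count(self) -> int:
        return sum(len(v) for v in self.overlaps_by_rule.values())


def generate_network(
    spec: ModelSpec,
    algorithm: str = "swd",
    axis_order: Optional[Tuple[int, int, int]] = None,
    max_cells: int = 5_000_000,
    max_expected_synapses: float = DEFAULT_MAX_EXPECTED_SYNAPSES,
) -> NetworkResult:
    """End-to-end pipeline: place cells, detect overlaps, place synapses.

    The synapse output is a pure function of the spec (master seed
    included): detection algorithm and axis order affect only the
    instrumentation, never the network, because each overlap consumes a
    stream indexed by (rule, axonal region id, dendritic region id) and
    synapses are emitted in canonical (rule, axonal id, dendritic id) order.
    """
    cells = place_cells(spec, max_cells=max_cells)
    regions = instantiate_regions(cells, spec)
    detected = detect_overlaps_by_rule(regions, spec, algorithm, axis_order)

    expected = expected_synapse_count(detected, spec)
    if expected > max_expected_synapses:
        raise SizeGuardError(
            f"expected synapse count {expected:.3g} exceeds the limit of "
            f"{max_expected_synapses:.3g}"
        )

    soma_of = {c.cell_id: c.soma_position for c in cells}
    owner_of = {r.region_id: r.owner for r in regions}

    synapses: List[Synapse] = []
    sid = 0
    for rix, rule in enumerate(spec.synapse_rules):
        records, _stats = detected[rix]
        for rec in sorted(
            records, key=lambda r: (r.axonal_region, r.dendritic_region)
        ):
            pre = owner_of[rec.axonal_region]
            post = owner_of[rec.dendritic_region]
            rng = MarsagliaMWC(
                stream_seed(
                    spec.master_seed, _TAG_SYNAPSE, rix,
                    rec.axonal_region, rec.dendritic_region,
                )
            )
            placed = place_synapses(
                rec, rule, rng,
                presynaptic_cell=pre,
                postsynaptic_cell=post,
                axonal_soma=soma_of[pre],
                dendritic_soma=soma_of[post],
                synapse_id_start=sid,
            )
            sid += len(placed)
            synapses.extend(placed)

    return NetworkResult(
        spec=spec,
        cells=cells,
        regions=regions,
        synapses=synapses,
        overlaps_by_rule={rix: recs for rix, (recs, _s) in detected.items()},
        stats_by_rule={rix: s for rix, (_r, s) in detected.items()},
    )
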