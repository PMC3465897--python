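"""Cell placement and neuritic-region instantiation.

Somas are placed uniformly at random within each cell type's layer bounds,
with a deterministic count ``round(soma_density * layer_volume)`` per type.
Every instance of a type then carries the type's region template boxes
translated to its soma position, so all instances of one type have their
synaptic region boxes in identical positions relative to the soma.

Region boxes may extend beyond the model space: long axonal fibers cross
patch boundaries, and clipping them would change overlap volumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

from .geometry import AABB, Point3
from .model import ModelSpec
from .rng import MarsagliaMWC, stream_seed

__all__ = [
    "CellInstance",
    "RegionInstance",
    "SizeGuardError",
    "place_cells",
    "instantiate_regions",
]

#: Stream-derivation domain tag for soma placement draws.
_TAG_PLACEMENT = 1

#: Refuse accidental requests for more cells than a workstation can hold.
DEFAULT_MAX_CELLS = 5_000_000


class SizeGuardError(Exception):
    """A run would exceed a configured size limit."""


@dataclass(frozen=True, slots=True)
class CellInstance:
    """A placed soma: dense per-model id, type name, position in um."""

    cell_id: int
    type_name: str
    soma_position: Point3


@dataclass(frozen=True, slots=True)
class RegionInstance:
    """An absolutely positioned neuritic box belonging to one cell."""

    region_id: int
    owner: int                # cell_id
    type_name: str
    template_name: str
    polarity: str
    box: AABB


def place_cells(
    spec: ModelSpec,
    rng: Optional[MarsagliaMWC] = None,
    max_cells: int = DEFAULT_MAX_CELLS,
) -> List[CellInstance]:
    """Place ``round(density * layer_volume)`` somas per type, uniformly.

    Cell ids are dense and assigned in deterministic order: cell types in
    spec order, then draw order within a type.  When ``rng`` is omitted a
    stream derived from the spec's master seed is used, making placement a
    pure function of the spec.
    """
    if rng is None:
        rng = MarsagliaMWC(stream_seed(spec.master_seed, _TAG_PLACEMENT))

    counts: List[Tuple[str, int, AABB]] = []
    total = 0
    for ct in spec.cell_types:
        n = int(round(ct.soma_density * ct.layer_bounds.volume))
        total += n
        if total > max_cells:
            raise SizeGuardError(
                f"cell type {ct.name!r} pushes the model to {total} cells, "
                f"above the limit of {max_cells}"
            )
        counts.append((ct.name, n, ct.layer_bounds))

    cells: List[CellInstance] = []
    cid = 0
    for type_name, n, layer in counts:
        lo, hi = layer.lo, layer.hi
        for _ in range(n):
            pos = (
                rng.uniform_in(lo[0], hi[0]),
                rng.uniform_in(lo[1], hi[1]),
                rng.uniform_in(lo[2], hi[2]),
            )
            cells.append(CellInstance(cid, type_name, pos))
            cid += 1
    return cells


def instantiate_regions(
    cells: List[CellInstance],
    spec: ModelSpec,
) -> List[RegionInstance]:
    """One region instance per (cell, template), translated to the soma.

    Region ids are dense and deterministic: cells in id order, templates in
    spec order within each cell's type.
    """
    types = spec.cell_type_map()
    regions: List[RegionInstance] = []
    rid = 0
    for cell in cells:
        try:
            ct = types[cell.type_name]
        except KeyError:
            raise KeyError(
                f"cell {cell.cell_id} has unknown type {cell.type_name!r}"
            ) from None
        for template in ct.regions:
            regions.append(
                RegionInstance(
                    region_id=rid,
                    owner=cell.cell_id,
                    type_name=cell.type_name,
                    template_name=template.name,
                    polarity=template.polarity,
                    box=template.offset_box.translate(cell.soma_position),
                )
            )
            rid += 1
    return regions
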