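"""Tabular writers and readers for generated networks.

Everything is plain text: TSV with a header row for cells, regions,
overlaps and synapses, JSON for per-rule instrumentation.  Floats are
written with ``repr`` so output is byte-stable across runs with the same
seed, and every writer has a reader that round-trips it.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Sequence, Tuple, Union

from .geometry import AABB
from .placement import CellInstance, RegionInstance
from .sweep import OverlapRecord, WalkStats
from .synapses import Synapse

__all__ = [
    "write_cells_tsv", "read_cells_tsv",
    "write_regions_tsv", "read_regions_tsv",
    "write_overlaps_tsv", "read_overlaps_tsv",
    "write_synapses_tsv", "read_synapses_tsv",
    "write_edge_list", "write_stats_json", "read_stats_json",
]

PathLike = Union[str, Path]


def _f(v: float) -> str:
    return repr(float(v))


def write_cells_tsv(path: PathLike, cells: Sequence[CellInstance]) -> None:
    lines = ["cell_id\ttype\tx\ty\tz"]
    for c in cells:
        x, y, z = c.soma_position
        lines.append(f"{c.cell_id}\t{c.type_name}\t{_f(x)}\t{_f(y)}\t{_f(z)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_cells_tsv(path: PathLike) -> List[CellInstance]:
    rows = Path(path).read_text().splitlines()[1:]
    out = []
    for row in rows:
        cid, tname, x, y, z = row.split("\t")
        out.append(CellInstance(int(cid), tname, (float(x), float(y), float(z))))
    return out


def write_regions_tsv(path: PathLike, regions: Sequence[RegionInstance]) -> None:
    lines = [
        "region_id\tcell_id\ttype\ttemplate\tpolarity\t"
        "min_x\tmax_x\tmin_y\tmax_y\tmin_z\tmax_z"
    ]
    for r in regions:
        b = "\t".join(_f(v) for v in r.box.bounds)
        lines.append(
            f"{r.region_id}\t{r.owner}\t{r.type_name}\t{r.template_name}\t"
            f"{r.polarity}\t{b}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_regions_tsv(path: PathLike) -> List[RegionInstance]:
    rows = Path(path).read_text().splitlines()[1:]
    out = []
    for row in rows:
        rid, owner, tname, template, polarity, *b = row.split("\t")
        vals = [float(v) for v in b]
        out.append(
            RegionInstance(
                int(rid), int(owner), tname, template, polarity,
                AABB.from_bounds(*vals),
            )
        )
    return out


def write_overlaps_tsv(
    path: PathLike,
    overlaps_by_rule: Dict[int, List[OverlapRecord]],
) -> None:
    lines = [
        "rule_index\taxonal_region\tdendritic_region\t"
        "min_x\tmax_x\tmin_y\tmax_y\tmin_z\tmax_z\tvolume"
    ]
    for rix in sorted(overlaps_by_rule):
        records = sorted(
            overlaps_by_rule[rix],
            key=lambda r: (r.axonal_region, r.dendritic_region),
        )
        for rec in records:
            b = "\t".join(_f(v) for v in rec.intersection.bounds)
            lines.append(
                f"{rix}\t{rec.axonal_region}\t{rec.dendritic_region}\t{b}\t"
                f"{_f(rec.volume)}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_overlaps_tsv(path: PathLike) -> Dict[int, List[OverlapRecord]]:
    rows = Path(path).read_text().splitlines()[1:]
    out: Dict[int, List[OverlapRecord]] = {}
    for row in rows:
        rix, aid, did, *vals = row.split("\t")
        nums = [float(v) for v in vals]
        box = AABB.from_bounds(*nums[:6])
        out.setdefault(int(rix), []).append(
            OverlapRecord(int(aid), int(did), box, nums[6])
        )
    return out


def write_synapses_tsv(path: PathLike, synapses: Sequence[Synapse]) -> None:
    lines = ["synapse_id\tpre_cell\tpost_cell\tx\ty\tz\tsign\tdelay_ms"]
    for s in synapses:
        x, y, z = s.position
        lines.append(
            f"{s.synapse_id}\t{s.presynaptic_cell}\t{s.postsynaptic_cell}\t"
            f"{_f(x)}\t{_f(y)}\t{_f(z)}\t{s.sign}\t{_f(s.delay)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_synapses_tsv(path: PathLike) -> List[Synapse]:
    rows = Path(path).read_text().splitlines()[1:]
    out = []
    for row in rows:
        sid, pre, post, x, y, z, sign, delay = row.split("\t")
        out.append(
            Synapse(
                int(sid), int(pre), int(post),
                (float(x), float(y), float(z)), sign, float(delay),
            )
        )
    return out


def write_edge_list(path: PathLike, synapses: Sequence[Synapse]) -> None:
    """(pre, post, weight, delay) edge list for network-analysis tools."""
    lines = ["pre_cell\tpost_cell\tweight\tdelay_ms"]
    for s in synapses:
        lines.append(f"{s.presynaptic_cell}\t{s.postsynaptic_cell}\t1\t{_f(s.delay)}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_stats_json(path: PathLike, stats_by_rule: Dict[int, WalkStats]) -> None:
    doc = {str(rix): stats.as_dict() for rix, stats in sorted(stats_by_rule.items())}
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_stats_json(path: PathLike) -> Dict[int, Dict[str, object]]:
    doc = json.loads(Path(path).read_text())
    return {int(k): v for k, v in doc.items()}
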