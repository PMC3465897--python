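"""Model-specification format: cell types, neuritic regions, synapse rules.

A model is described by a plain-text parameter file that statistically
specifies the neuronal and synaptic configuration of the tissue to be
generated: the 3D model space, a list of cell types with soma densities and
per-type neuritic region boxes positioned relative to the soma, and a list
of synapse rules stating which axonal regions of which presynaptic type may
form synapses inside which dendritic regions of which postsynaptic type,
at what density per unit overlap volume, with what sign, and with what
propagation speeds.

Grammar (full reference in ``docs/model-format.md``)::

    # comments run to end of line; blank lines are ignored
    model_space XMIN XMAX YMIN YMAX ZMIN ZMAX      # micrometres
    master_seed INT

    cell_type NAME
        density FLOAT                  # somas per cubic micrometre
        layer XMIN XMAX YMIN YMAX ZMIN ZMAX
        region NAME axonal|dendritic XMIN XMAX YMIN YMAX ZMIN ZMAX
                                       # box relative to the soma

    rule PRETYPE.PREREGION -> POSTTYPE.POSTREGION
        density FLOAT                  # synapses per cubic micrometre of overlap
        sign excitatory|inhibitory
        axonal_speed FLOAT             # micrometres per millisecond
        dendritic_speed THRESHOLD|inf SPEED    # repeatable; thresholds ascending
        exclude_self true|false        # optional, default false

Region names may contain ``/`` to form a hierarchy; a rule that names a
parent region matches all of its sub-regions.  :func:`octet_split` uses
this to bisect dendritic boxes into eight exact half-size children
(``dend`` -> ``dend/0`` .. ``dend/7``) without touching the rules.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

from .geometry import AABB

__all__ = [
    "CellTypeSpec",
    "RegionTemplate",
    "SynapseRule",
    "ModelSpec",
    "parse_model_spec",
    "serialize_model_spec",
    "octet_split",
    "template_matches",
    "ModelSpecError",
    "SpecSyntaxError",
    "SpecValidationError",
    "UnknownReferenceError",
    "PolarityMismatchError",
    "NegativeValueError",
    "DuplicateNameError",
    "BoundsError",
    "SelectorError",
]


class ModelSpecError(Exception):
    """Base class for every model-specification failure."""


class SpecSyntaxError(ModelSpecError):
    """Malformed parameter-file text; carries the 1-based line number."""

    def __init__(self, line: int, message: str) -> None:
        self.line = line
        super().__init__(f"line {line}: {message}")


class SpecValidationError(ModelSpecError):
    """A structurally parsed spec violates a semantic invariant."""


class UnknownReferenceError(SpecValidationError):
    """A rule references a cell type or region that does not exist."""


class PolarityMismatchError(SpecValidationError):
    """A rule's region reference resolves to the wrong polarity."""


class NegativeValueError(SpecValidationError):
    """A density or speed that must be nonnegative/positive is not."""


class DuplicateNameError(SpecValidationError):
    """A cell type or region name is defined twice in the same scope."""


class BoundsError(SpecValidationError):
    """A layer or model-space box violates containment or volume rules."""


class SelectorError(ModelSpecError):
    """A region selector matched nothing."""


POLARITIES = ("axonal", "dendritic")
SIGNS = ("excitatory", "inhibitory")


def template_matches(template_name: str, reference: str) -> bool:
    """True when ``reference`` names the template or one of its ancestors."""
    return template_name == reference or template_name.startswith(reference + "/")


@dataclass(frozen=True, slots=True)
class RegionTemplate:
    """A neuritic region box positioned relative to the soma.

    ``offset_box`` is in micrometres relative to the soma position; every
    instance of the owning cell type carries this box translated to its
    soma (all instances of a type have identically shaped and positioned
    synaptic regions relative to their centre).
    """

    name: str
    polarity: str
    offset_box: AABB

    @property
    def root_name(self) -> str:
        return self.name.split("/", 1)[0]


@dataclass(frozen=True, slots=True)
class CellTypeSpec:
    name: str
    soma_density: float          # somas per cubic micrometre
    layer_bounds: AABB           # sub-volume of model space holding the somas
    regions: Tuple[RegionTemplate, ...]

    def region_map(self) -> Dict[str, RegionTemplate]:
        return {r.name: r for r in self.regions}


#: Sentinel distance threshold covering "all remaining dendritic distance".
INF = math.inf


@dataclass(frozen=True, slots=True)
class SynapseRule:
    """Permission for one axonal region to synapse onto one dendritic region.

    ``synapse_density`` is the expected synapse count per cubic micrometre
    of 3D overlap volume.  ``dendritic_speed_profile`` is an ordered list of
    (distance threshold in um, speed in um/ms) pairs: signal travelling a
    dendritic distance is priced segment by segment, the last threshold
    being the infinity sentinel.
    """

    presynaptic_type: str
    presyn_region: str
    postsynaptic_type: str
    postsyn_region: str
    synapse_density: float       # synapses per cubic micrometre of overlap
    sign: str
    axonal_speed: float          # micrometres per millisecond
    dendritic_speed_profile: Tuple[Tuple[float, float], ...]
    exclude_self: bool = False


@dataclass(frozen=True, slots=True)
class ModelSpec:
    model_space: AABB
    cell_types: Tuple[CellTypeSpec, ...]
    synapse_rules: Tuple[SynapseRule, ...]
    master_seed: int = 0

    def cell_type_map(self) -> Dict[str, CellTypeSpec]:
        return {ct.name: ct for ct in self.cell_types}


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_model_spec(spec: ModelSpec) -> None:
    """Check every semantic invariant; raise a named error on the first hit."""
    if spec.model_space.volume <= 0:
        raise BoundsError("model_space must have positive volume")

    seen_types: set = set()
    for ct in spec.cell_types:
        if ct.name in seen_types:
            raise DuplicateNameError(f"cell type {ct.name!r} defined twice")
        seen_types.add(ct.name)
        if ct.soma_density < 0:
            raise NegativeValueError(
                f"cell type {ct.name!r}: soma density must be >= 0, "
                f"got {ct.soma_density}"
            )
        if not spec.model_space.contains_box(ct.layer_bounds):
            raise BoundsError(
                f"cell type {ct.name!r}: layer bounds extend outside model space"
            )
        seen_regions: set = set()
        for reg in ct.regions:
            if reg.name in seen_regions:
                raise DuplicateNameError(
                    f"cell type {ct.name!r}: region {reg.name!r} defined twice"
                )
            seen_regions.add(reg.name)
            if reg.polarity not in POLARITIES:
                raise SpecValidationError(
                    f"region {reg.name!r}: polarity must be axonal or dendritic"
                )

    types = spec.cell_type_map()
    for rule in spec.synapse_rules:
        for role, tname in (
            ("presynaptic", rule.presynaptic_type),
            ("postsynaptic", rule.postsynaptic_type),
        ):
            if tname not in types:
                raise UnknownReferenceError(
                    f"rule references unknown {role} cell type {tname!r}"
                )
        _check_region_ref(
            types[rule.presynaptic_type], rule.presyn_region, "axonal"
        )
        _check_region_ref(
            types[rule.postsynaptic_type], rule.postsyn_region, "dendritic"
        )
        if rule.synapse_density < 0:
            raise NegativeValueError(
                f"rule {rule.presynaptic_type}.{rule.presyn_region} -> "
                f"{rule.postsynaptic_type}.{rule.postsyn_region}: "
                "synapse density must be >= 0"
            )
        if rule.sign not in SIGNS:
            raise SpecValidationError(
                f"rule sign must be excitatory or inhibitory, got {rule.sign!r}"
            )
        if rule.axonal_speed <= 0:
            raise NegativeValueError("axonal speed must be > 0")
        profile = rule.dendritic_speed_profile
        if not profile:
            raise SpecValidationError("dendritic speed profile must be nonempty")
        prev = -INF
        for threshold, speed in profile:
            if speed <= 0:
                raise NegativeValueError("dendritic speeds must be > 0")
            if threshold <= prev:
                raise SpecValidationError(
                    "dendritic speed thresholds must be strictly increasing"
                )
            prev = threshold
        if profile[-1][0] != INF:
            raise SpecValidationError(
                "last dendritic speed threshold must be inf to cover all distances"
            )


def _check_region_ref(ct: CellTypeSpec, ref: str, polarity: str) -> None:
    matched = [r for r in ct.regions if template_matches(r.name, ref)]
    if not matched:
        raise UnknownReferenceError(
            f"cell type {ct.name!r} has no region matching {ref!r}"
        )
    for r in matched:
        if r.polarity != polarity:
            raise PolarityMismatchError(
                f"rule expects {polarity} region but {ct.name}.{r.name} "
                f"is {r.polarity}"
            )


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _parse_floats(parts: Sequence[str], n: int, lineno: int, what: str) -> List[float]:
    if len(parts) != n:
        raise SpecSyntaxError(lineno, f"{what} needs {n} numbers, got {len(parts)}")
    out = []
    for p in parts:
        try:
            out.append(float(p))
        except ValueError:
            raise SpecSyntaxError(lineno, f"{what}: {p!r} is not a number") from None
    return out


def _parse_box(parts: Sequence[str], lineno: int, what: str) -> AABB:
    v = _parse_floats(parts, 6, lineno, what)
    try:
        return AABB.from_bounds(*v)
    except ValueError as exc:
        raise SpecSyntaxError(lineno, f"{what}: {exc}") from None


def parse_model_spec(text: str) -> ModelSpec:
    """Parse and fully validate a parameter file.

    Raises :class:`SpecSyntaxError` (with line number) for malformed text
    and a :class:`SpecValidationError` subclass for semantic violations.
    """
    model_space: Optional[AABB] = None
    master_seed = 0
    cell_types: List[CellTypeSpec] = []
    rules: List[SynapseRule] = []

    # Mutable accumulators for the block currently being parsed.
    cur_ct: Optional[dict] = None
    cur_rule: Optional[dict] = None

    def close_ct() -> None:
        nonlocal cur_ct
        if cur_ct is None:
            return
        if cur_ct["density"] is None:
            raise SpecSyntaxError(
                cur_ct["line"], f"cell type {cur_ct['name']!r} is missing 'density'"
            )
        if cur_ct["layer"] is None:
            raise SpecSyntaxError(
                cur_ct["line"], f"cell type {cur_ct['name']!r} is missing 'layer'"
            )
        cell_types.append(
            CellTypeSpec(
                name=cur_ct["name"],
                soma_density=cur_ct["density"],
                layer_bounds=cur_ct["layer"],
                regions=tuple(cur_ct["regions"]),
            )
        )
        cur_ct = None

    def close_rule() -> None:
        nonlocal cur_rule
        if cur_rule is None:
            return
        missing = [k for k in ("density", "sign", "axonal_speed") if cur_rule[k] is None]
        if missing:
            raise SpecSyntaxError(
                cur_rule["line"], f"rule is missing {', '.join(missing)}"
            )
        if not cur_rule["profile"]:
            raise SpecSyntaxError(
                cur_rule["line"], "rule needs at least one dendritic_speed line"
            )
        rules.append(
            SynapseRule(
                presynaptic_type=cur_rule["pre_type"],
                presyn_region=cur_rule["pre_region"],
                postsynaptic_type=cur_rule["post_type"],
                postsyn_region=cur_rule["post_region"],
                synapse_density=cur_rule["density"],
                sign=cur_rule["sign"],
                axonal_speed=cur_rule["axonal_speed"],
                dendritic_speed_profile=tuple(cur_rule["profile"]),
                exclude_self=cur_rule["exclude_self"],
            )
        )
        cur_rule = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        key = parts[0]

        if key == "model_space":
            close_ct(); close_rule()
            model_space = _parse_box(parts[1:], lineno, "model_space")
        elif key == "master_seed":
            close_ct(); close_rule()
            try:
                master_seed = int(parts[1])
            except (IndexError, ValueError):
                raise SpecSyntaxError(lineno, "master_seed needs one integer") from None
        elif key == "cell_type":
            close_ct(); close_rule()
            if len(parts) != 2:
                raise SpecSyntaxError(lineno, "cell_type needs exactly one name")
            cur_ct = {
                "name": parts[1], "density": None, "layer": None,
                "regions": [], "line": lineno,
            }
        elif key == "rule":
            close_ct(); close_rule()
            if len(parts) != 4 or parts[2] != "->":
                raise SpecSyntaxError(
                    lineno, "rule syntax is: rule PRE.REGION -> POST.REGION"
                )
            try:
                pre_type, pre_region = parts[1].split(".", 1)
                post_type, post_region = parts[3].split(".", 1)
            except ValueError:
                raise SpecSyntaxError(
                    lineno, "rule endpoints must be TYPE.REGION"
                ) from None
            cur_rule = {
                "pre_type": pre_type, "pre_region": pre_region,
                "post_type": post_type, "post_region": post_region,
                "density": None, "sign": None, "axonal_speed": None,
                "profile": [], "exclude_self": False, "line": lineno,
            }
        elif cur_ct is not None:
            if key == "density":
                cur_ct["density"] = _parse_floats(parts[1:], 1, lineno, "density")[0]
            elif key == "layer":
                cur_ct["layer"] = _parse_box(parts[1:], lineno, "layer")
            elif key == "region":
                if len(parts) != 9:
                    raise SpecSyntaxError(
                        lineno, "region syntax is: region NAME POLARITY plus 6 bounds"
                    )
                polarity = parts[2]
                if polarity not in POLARITIES:
                    raise SpecSyntaxError(
                        lineno, f"region polarity must be axonal or dendritic, "
                                f"got {polarity!r}"
                    )
                box = _parse_box(parts[3:], lineno, f"region {parts[1]!r}")
                cur_ct["regions"].append(RegionTemplate(parts[1], polarity, box))
            else:
                raise SpecSyntaxError(lineno, f"unknown cell_type property {key!r}")
        elif cur_rule is not None:
            if key == "density":
                cur_rule["density"] = _parse_floats(parts[1:], 1, lineno, "density")[0]
            elif key == "sign":
                if len(parts) != 2 or parts[1] not in SIGNS:
                    raise SpecSyntaxError(
                        lineno, "sign must be excitatory or inhibitory"
                    )
                cur_rule["sign"] = parts[1]
            elif key == "axonal_speed":
                cur_rule["axonal_speed"] = _parse_floats(
                    parts[1:], 1, lineno, "axonal_speed"
                )[0]
            elif key == "dendritic_speed":
                if len(parts) != 3:
                    raise SpecSyntaxError(
                        lineno, "dendritic_speed needs THRESHOLD SPEED"
                    )
                threshold = INF if parts[1] in ("inf", "Inf", "INF") else None
                if threshold is None:
                    threshold = _parse_floats(parts[1:2], 1, lineno, "threshold")[0]
                speed = _parse_floats(parts[2:3], 1, lineno, "speed")[0]
                cur_rule["profile"].append((threshold, speed))
            elif key == "exclude_self":
                if len(parts) != 2 or parts[1] not in ("true", "false"):
                    raise SpecSyntaxError(lineno, "exclude_self must be true or false")
                cur_rule["exclude_self"] = parts[1] == "true"
            else:
                raise SpecSyntaxError(lineno, f"unknown rule property {key!r}")
        else:
            raise SpecSyntaxError(lineno, f"unknown top-level keyword {key!r}")

    close_ct()
    close_rule()
    if model_space is None:
        raise SpecSyntaxError(1, "missing required model_space line")
    spec = ModelSpec(
        model_space=model_space,
        cell_types=tuple(cell_types),
        synapse_rules=tuple(rules),
        master_seed=master_seed,
    )
    validate_model_spec(spec)
    return spec


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _fmt(v: float) -> str:
    if v == INF:
        return "inf"
    return repr(v)


def _fmt_box(box: AABB) -> str:
    return " ".join(_fmt(v) for v in box.bounds)


def serialize_model_spec(spec: ModelSpec) -> str:
    """Render a spec back to the parameter-file text format (round-trips)."""
    lines = [
        f"model_space {_fmt_box(spec.model_space)}",
        f"master_seed {spec.master_seed}",
        "",
    ]
    for ct in spec.cell_types:
        lines.append(f"cell_type {ct.name}")
        lines.append(f"    density {_fmt(ct.soma_density)}")
        lines.append(f"    layer {_fmt_box(ct.layer_bounds)}")
        for reg in ct.regions:
            lines.append(
                f"    region {reg.name} {reg.polarity} {_fmt_box(reg.offset_box)}"
            )
        lines.append("")
    for rule in spec.synapse_rules:
        lines.append(
            f"rule {rule.presynaptic_type}.{rule.presyn_region} -> "
            f"{rule.postsynaptic_type}.{rule.postsyn_region}"
        )
        lines.append(f"    density {_fmt(rule.synapse_density)}")
        lines.append(f"    sign {rule.sign}")
        lines.append(f"    axonal_speed {_fmt(rule.axonal_speed)}")
        for threshold, speed in rule.dendritic_speed_profile:
            lines.append(f"    dendritic_speed {_fmt(threshold)} {_fmt(speed)}")
        if rule.exclude_self:
            lines.append("    exclude_self true")
        lines.append("")
    return "\n".join(lines)


def model_spec_to_json(spec: ModelSpec) -> str:
    """Canonical JSON form for machine round-tripping."""
    doc = {
        "model_space": spec.model_space.bounds,
        "master_seed": spec.master_seed,
        "cell_types": [
            {
                "name": ct.name,
                "soma_density": ct.soma_density,
                "layer_bounds": ct.layer_bounds.bounds,
                "regions": [
                    {
                        "name": r.name,
                        "polarity": r.polarity,
                        "offset_box": r.offset_box.bounds,
                    }
                    for r in ct.regions
                ],
            }
            for ct in spec.cell_types
        ],
        "synapse_rules": [
            {
                "presynaptic_type": r.presynaptic_type,
                "presyn_region": r.presyn_region,
                "postsynaptic_type": r.postsynaptic_type,
                "postsyn_region": r.postsyn_region,
                "synapse_density": r.synapse_density,
                "sign": r.sign,
                "axonal_speed": r.axonal_speed,
                "dendritic_speed_profile": [
                    [t if t != INF else "inf", s]
                    for t, s in r.dendritic_speed_profile
                ],
                "exclude_self": r.exclude_self,
            }
            for r in spec.synapse_rules
        ],
    }
    return json.dumps(doc, sort_keys=True)


def model_spec_from_json(text: str) -> ModelSpec:
    doc = json.loads(text)
    spec = ModelSpec(
        model_space=AABB.from_bounds(*doc["model_space"]),
        master_seed=doc["master_seed"],
        cell_types=tuple(
            CellTypeSpec(
                name=ct["name"],
                soma_density=ct["soma_density"],
                layer_bounds=AABB.from_bounds(*ct["layer_bounds"]),
                regions=tuple(
                    RegionTemplate(
                        r["name"], r["polarity"], AABB.from_bounds(*r["offset_box"])
                    )
                    for r in ct["regions"]
                ),
            )
            for ct in doc["cell_types"]
        ),
        synapse_rules=tuple(
            SynapseRule(
                presynaptic_type=r["presynaptic_type"],
                presyn_region=r["presyn_region"],
                postsynaptic_type=r["postsynaptic_type"],
                postsyn_region=r["postsyn_region"],
                synapse_density=r["synapse_density"],
                sign=r["sign"],
                axonal_speed=r["axonal_speed"],
                dendritic_speed_profile=tuple(
                    (INF if t == "inf" else float(t), float(s))
                    for t, s in r["dendritic_speed_profile"]
                ),
                exclude_self=r["exclude_self"],
            )
            for r in doc["synapse_rules"]
        ),
    )
    validate_model_spec(spec)
    return spec


# ---------------------------------------------------------------------------
# Octet splitting
# ---------------------------------------------------------------------------

def _octet_children(template: RegionTemplate) -> List[RegionTemplate]:
    lo, hi = template.offset_box.lo, template.offset_box.hi
    mid = tuple((lo[d] + hi[d]) / 2.0 for d in range(3))
    children = []
    for k in range(8):
        clo = tuple(mid[d] if (k >> d) & 1 else lo[d] for d in range(3))
        chi = tuple(hi[d] if (k >> d) & 1 else mid[d] for d in range(3))
        children.append(
            RegionTemplate(f"{template.name}/{k}", template.polarity, AABB(clo, chi))
        )
    return children


def octet_split(spec: ModelSpec, target: str = "*.*") -> ModelSpec:
    """Bisect selected dendritic region boxes into eight exact sub-boxes.

    ``target`` is ``"TYPE.REGION"`` with ``*`` wildcards; it selects
    dendritic region templates only.  Each selected box is replaced by the
    eight boxes obtained by halving every dimension at its midpoint: they
    are pairwise interior-disjoint and their union is exactly the parent.
    Children are named ``parent/0`` .. ``parent/7``, so synapse rules that
    name the parent keep matching; everything else in the spec is unchanged.
    Splitting again produces 64 grandchildren per original box.

    Midpoints are exact in binary floating point whenever the bounds are
    representable, so child volumes sum to the parent volume exactly in the
    common case.

    Raises :class:`SelectorError` when the selector matches no dendritic
    region.
    """
    try:
        type_pat, region_pat = target.split(".", 1)
    except ValueError:
        raise SelectorError(
            f"selector {target!r} must look like TYPE.REGION (wildcards allowed)"
        ) from None

    matched = 0
    new_types: List[CellTypeSpec] = []
    for ct in spec.cell_types:
        if type_pat not in ("*", ct.name):
            new_types.append(ct)
            continue
        new_regions: List[RegionTemplate] = []
        for reg in ct.regions:
            selected = reg.polarity == "dendritic" and (
                region_pat == "*" or template_matches(reg.name, region_pat)
            )
            if selected:
                matched += 1
                new_regions.extend(_octet_children(reg))
            else:
                new_regions.append(reg)
        new_types.append(replace(ct, regions=tuple(new_regions)))

    if matched == 0:
        raise SelectorError(f"selector {target!r} matched no dendritic region")

    out = replace(spec, cell_types=tuple(new_types))
    validate_model_spec(out)
    return out
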