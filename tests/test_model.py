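"""Parameter-file parsing, validation, serialization, and octet splitting."""

import math

import pytest

from neurosweep.geometry import AABB
from neurosweep.model import (
    BoundsError,
    DuplicateNameError,
    NegativeValueError,
    PolarityMismatchError,
    SelectorError,
    SpecSyntaxError,
    UnknownReferenceError,
    model_spec_from_json,
    model_spec_to_json,
    octet_split,
    parse_model_spec,
    serialize_model_spec,
    template_matches,
)
from neurosweep.sweep import naive_all_pairs

MINIMAL = """
model_space 0 10 0 10 0 10
master_seed 5

cell_type a
    density 0.001
    layer 0 10 0 10 0 10
    region ax axonal -1 1 -1 1 -1 1

cell_type b
    density 0.001
    layer 0 10 0 10 0 10
    region dn dendritic -2 2 -2 2 -2 2

rule a.ax -> b.dn
    density 0.1
    sign excitatory
    axonal_speed 100
    dendritic_speed inf 50
"""


def test_parse_minimal_two_type_spec():
    spec = parse_model_spec(MINIMAL)
    assert len(spec.cell_types) == 2
    assert len(spec.synapse_rules) == 1
    assert spec.master_seed == 5
    rule = spec.synapse_rules[0]
    assert rule.dendritic_speed_profile == ((math.inf, 50.0),)


def test_parsing_is_deterministic():
    assert parse_model_spec(MINIMAL) == parse_model_spec(MINIMAL)


def test_text_round_trip():
    spec = parse_model_spec(MINIMAL)
    assert parse_model_spec(serialize_model_spec(spec)) == spec


def test_json_round_trip():
    spec = parse_model_spec(MINIMAL)
    assert model_spec_from_json(model_spec_to_json(spec)) == spec


@pytest.mark.parametrize(
    "mutation, error, fragment",
    [
        ("rule Basket.ax -> b.dn", UnknownReferenceError, "Basket"),
        ("rule a.missing -> b.dn", UnknownReferenceError, "missing"),
        ("rule b.dn -> b.dn", PolarityMismatchError, "dendritic"),
        ("density -1", NegativeValueError, "density"),
    ],
)
def test_named_validation_failures(mutation, error, fragment):
    if mutation.startswith("rule"):
        text = MINIMAL.replace("rule a.ax -> b.dn", mutation)
    else:
        text = MINIMAL.replace("density 0.1", mutation)
    with pytest.raises(error, match=fragment):
        parse_model_spec(text)


def test_syntax_error_carries_line_number():
    text = "model_space 0 1 0 1 0 1\nbogus_keyword 3\n"
    with pytest.raises(SpecSyntaxError) as exc:
        parse_model_spec(text)
    assert exc.value.line == 2


def test_layer_outside_model_space_rejected():
    text = MINIMAL.replace("layer 0 10 0 10 0 10", "layer 0 20 0 10 0 10", 1)
    with pytest.raises(BoundsError):
        parse_model_spec(text)


def test_duplicate_region_rejected():
    text = MINIMAL.replace(
        "region ax axonal -1 1 -1 1 -1 1",
        "region ax axonal -1 1 -1 1 -1 1\n    region ax axonal 0 1 0 1 0 1",
    )
    with pytest.raises(DuplicateNameError):
        parse_model_spec(text)


def test_template_matches_hierarchy():
    assert template_matches("dend", "dend")
    assert template_matches("dend/3", "dend")
    assert template_matches("dend/3/5", "dend")
    assert not template_matches("dendrite", "dend")


class TestOctetSplit:
    def test_midpoint_bisection(self):
        spec = parse_model_spec(
            MINIMAL.replace("region dn dendritic -2 2 -2 2 -2 2",
                            "region dn dendritic 0 2 0 4 0 6")
        )
        split = octet_split(spec, "b.dn")
        regions = split.cell_type_map()["b"].regions
        assert len(regions) == 8
        assert {r.name for r in regions} == {f"dn/{k}" for k in range(8)}
        volumes = [r.offset_box.volume for r in regions]
        assert all(v == pytest.approx(6.0) for v in volumes)
        assert sum(volumes) == pytest.approx(48.0)
        assert AABB((0, 0, 0), (1, 2, 3)) in [r.offset_box for r in regions]

    def test_children_are_interior_disjoint_and_tile_parent(self):
        spec = parse_model_spec(MINIMAL)
        split = octet_split(spec)
        children = split.cell_type_map()["b"].regions
        parent = spec.cell_type_map()["b"].regions[0].offset_box
        for i, a in enumerate(children):
            assert parent.contains_box(a.offset_box)
            for b in children[i + 1:]:
                from neurosweep.geometry import aabb_intersect
                inter = aabb_intersect(a.offset_box, b.offset_box)
                assert inter is None or inter.volume == 0.0
        assert sum(c.offset_box.volume for c in children) == parent.volume

    def test_double_split_gives_64_children(self):
        spec = parse_model_spec(MINIMAL)
        twice = octet_split(octet_split(spec))
        regions = twice.cell_type_map()["b"].regions
        assert len(regions) == 64
        parent_volume = spec.cell_type_map()["b"].regions[0].offset_box.volume
        assert sum(r.offset_box.volume for r in regions) == pytest.approx(
            parent_volume, rel=1e-12
        )

    def test_rules_still_resolve_after_split(self):
        spec = octet_split(parse_model_spec(MINIMAL))
        # validation inside octet_split already checks this; be explicit
        assert spec.synapse_rules[0].postsyn_region == "dn"

    def test_selector_matching_nothing_fails(self):
        spec = parse_model_spec(MINIMAL)
        with pytest.raises(SelectorError):
            octet_split(spec, "a.*")  # type a has no dendritic region
        with pytest.raises(SelectorError):
            octet_split(spec, "b.nope")

    def test_overlap_volume_invariant_under_split(self):
        """Total 3D overlap volume against a fixed axonal set is unchanged.

        Cross-checked with the naive oracle on a 20-box fixture: each
        dendritic box is replaced by its eight children and the summed
        intersection volume must be identical.
        """
        import numpy as np
        from neurosweep.model import _octet_children, RegionTemplate

        rng = np.random.default_rng(77)
        def rand_box():
            lo = rng.uniform(0, 80, 3)
            return AABB(tuple(lo), tuple(lo + rng.uniform(1, 40, 3)))

        axonal = [rand_box() for _ in range(10)]
        dendritic = [rand_box() for _ in range(10)]

        before, _ = naive_all_pairs(axonal, dendritic)
        children = []
        for box in dendritic:
            tmpl = RegionTemplate("d", "dendritic", box)
            children.extend(c.offset_box for c in _octet_children(tmpl))
        after, _ = naive_all_pairs(axonal, children)

        assert sum(r.volume for r in after) == pytest.approx(
            sum(r.volume for r in before), rel=1e-12
        )
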