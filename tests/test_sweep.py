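"""Staggered-walk correctness against the naive all-pairs oracle."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from neurosweep.geometry import AABB
from neurosweep.sweep import (
    choose_axis_order,
    naive_all_pairs,
    run_detector,
    simple_walk_count,
    staggered_walk,
    staggered_walk_dynamic,
)
from neurosweep.synthetic import BoxPopulationParams, generate_boxes

AXIS_ORDERS = list(itertools.permutations((0, 1, 2)))


def keys(records):
    return {r.key() for r in records}


class TestNaive:
    def test_empty_inputs(self):
        records, comparisons = naive_all_pairs([], [AABB((0, 0, 0), (1, 1, 1))])
        assert records == [] and comparisons == 0

    def test_counts_every_pair(self):
        axonal = [AABB((10 * i, 0, 0), (10 * i + 1, 1, 1)) for i in range(3)]
        dendritic = [AABB((5 + 10 * j, 3, 3), (6 + 10 * j, 4, 4)) for j in range(4)]
        records, comparisons = naive_all_pairs(axonal, dendritic)
        assert comparisons == 12
        assert records == []

    def test_fully_nested_population(self):
        # every dendritic box strictly inside every axonal box: 25 overlaps
        axonal = [AABB((-i, -i, -i), (10 + i, 10 + i, 10 + i)) for i in range(5)]
        dendritic = [AABB((4, 4, 4), (5 + 0.1 * j, 5, 5)) for j in range(5)]
        records, comparisons = naive_all_pairs(axonal, dendritic)
        assert comparisons == 25 and len(records) == 25


class TestStaggeredWalk:
    def test_empty_inputs(self):
        records, stats = staggered_walk([], [], 0, 1, 2)
        assert records == []
        assert stats.comparisons_1d == 0
        assert stats.open_insertions == 0

    def test_invalid_axis_order_rejected(self):
        with pytest.raises(ValueError):
            staggered_walk([], [], 0, 0, 2)

    def test_hand_traced_fixture(self):
        """Three boxes per class, two true 3D overlaps.

        The sweep along X was traced by hand: d0 meets open a0 (one
        comparison, a 3D overlap), d1 meets open a1 (one comparison,
        rejected in Y), d2 meets open a2 (one comparison, a 3D overlap);
        every other encounter is prevented by lazy closing.  Hence exactly
        3 primary-dimension comparisons.
        """
        axonal = [
            AABB((0, 0, 0), (2, 2, 2)),
            AABB((5, 0, 0), (7, 2, 2)),
            AABB((10, 0, 0), (12, 2, 2)),
        ]
        dendritic = [
            AABB((1, 1, 1), (3, 3, 3)),
            AABB((6, 5, 0), (8, 7, 2)),
            AABB((11, 1, 1), (13, 2, 2)),
        ]
        records, stats = staggered_walk(axonal, dendritic, 0, 1, 2)
        naive_records, _ = naive_all_pairs(axonal, dendritic)
        assert keys(records) == keys(naive_records)
        assert stats.overlaps_3d == 2
        assert stats.comparisons_1d == 3
        assert {(r.axonal_region, r.dendritic_region) for r in records} == {
            (0, 0), (2, 2),
        }

    def test_face_touching_boxes_are_reported(self):
        a = [AABB((0, 0, 0), (1, 1, 1))]
        d = [AABB((1, 0, 0), (2, 1, 1))]
        for order in AXIS_ORDERS:
            records, _ = staggered_walk(a, d, *order)
            assert len(records) == 1
            assert records[0].volume == 0.0

    def test_custom_region_ids_propagate(self):
        a = [AABB((0, 0, 0), (2, 2, 2))]
        d = [AABB((1, 1, 1), (3, 3, 3))]
        records, _ = staggered_walk(a, d, 0, 1, 2, axonal_ids=[42], dendritic_ids=[7])
        assert (records[0].axonal_region, records[0].dendritic_region) == (42, 7)

    @pytest.mark.parametrize("seed", range(8))
    def test_oracle_equivalence_random_populations(self, seed):
        params = BoxPopulationParams(
            n_axonal=60, n_dendritic=60,
            preset=("isotropic", "parallel_fiber", "flat_plate", "worst_case")[seed % 4],
            nesting_fraction=0.3, colinear_fraction=0.3, seed=seed,
        )
        axonal, dendritic = generate_boxes(params)
        expected = keys(naive_all_pairs(axonal, dendritic)[0])
        for order in AXIS_ORDERS:
            records, stats = staggered_walk(axonal, dendritic, *order)
            assert keys(records) == expected
            assert stats.overlaps_3d <= stats.overlaps_1d <= stats.comparisons_1d
            assert stats.comparisons_1d <= len(axonal) * len(dendritic)
        swd_records, _ = staggered_walk_dynamic(axonal, dendritic)
        assert keys(swd_records) == expected

    def test_symmetry_swapping_classes_transposes_records(self):
        params = BoxPopulationParams(n_axonal=40, n_dendritic=50, seed=3,
                                     nesting_fraction=0.2)
        axonal, dendritic = generate_boxes(params)
        fwd, _ = staggered_walk(axonal, dendritic, 0, 1, 2)
        rev, _ = staggered_walk(dendritic, axonal, 0, 1, 2)
        assert {(r.axonal_region, r.dendritic_region, r.intersection) for r in fwd} \
            == {(r.dendritic_region, r.axonal_region, r.intersection) for r in rev}


small_boxes = st.builds(
    lambda lo, ext: AABB(tuple(lo), tuple(l + e for l, e in zip(lo, ext))),
    st.tuples(*[st.integers(0, 12) for _ in range(3)]),
    st.tuples(*[st.integers(0, 6) for _ in range(3)]),
)


@settings(max_examples=150, derandomize=True, deadline=None)
@given(
    axonal=st.lists(small_boxes, max_size=12),
    dendritic=st.lists(small_boxes, max_size=12),
)
def test_property_oracle_equivalence_with_degenerate_coordinates(axonal, dendritic):
    """Integer-grid boxes force colinear faces, nesting, and zero volumes."""
    expected = keys(naive_all_pairs(axonal, dendritic)[0])
    for order in AXIS_ORDERS:
        records, stats = staggered_walk(axonal, dendritic, *order)
        assert keys(records) == expected
        assert simple_walk_count(axonal, dendritic, order[0]) == stats.comparisons_1d
    swd, _ = staggered_walk_dynamic(axonal, dendritic)
    assert keys(swd) == expected


class TestSimpleWalk:
    def test_disjoint_along_dim_needs_no_comparisons(self):
        axonal = [AABB((4 * i, 0, 0), (4 * i + 1, 9, 9)) for i in range(5)]
        dendritic = [AABB((4 * i + 2, 0, 0), (4 * i + 3, 9, 9)) for i in range(5)]
        assert simple_walk_count(axonal, dendritic, 0) == 0

    def test_full_span_worst_case_is_n_squared(self):
        n = 20
        axonal = [AABB((0, i, 0), (100, i + 1, 1)) for i in range(n)]
        dendritic = [AABB((0, 0, i), (100, 1, i + 1)) for i in range(n)]
        assert simple_walk_count(axonal, dendritic, 0) == n * n

    @pytest.mark.parametrize("dim", [0, 1, 2])
    def test_prediction_matches_full_walk(self, dim):
        params = BoxPopulationParams(n_axonal=70, n_dendritic=80, seed=11,
                                     nesting_fraction=0.4, colinear_fraction=0.4)
        axonal, dendritic = generate_boxes(params)
        others = [d for d in (0, 1, 2) if d != dim]
        _, stats = staggered_walk(axonal, dendritic, dim, *others)
        assert simple_walk_count(axonal, dendritic, dim) == stats.comparisons_1d


class TestAxisChoice:
    def test_avoids_the_crowded_dimension(self):
        # overlapping in X for all, disjoint in Y
        axonal = [AABB((0, 10 * i, 0), (100, 10 * i + 1, 1)) for i in range(10)]
        dendritic = [AABB((0, 10 * i + 5, 0), (100, 10 * i + 6, 1)) for i in range(10)]
        primary, _, _ = choose_axis_order(axonal, dendritic)
        assert primary == 1

    def test_parallel_fiber_population_never_walks_y(self):
        params = BoxPopulationParams(n_axonal=100, n_dendritic=100,
                                     preset="parallel_fiber", seed=5)
        axonal, dendritic = generate_boxes(params)
        counts = {d: simple_walk_count(axonal, dendritic, d) for d in (0, 1, 2)}
        primary, _, _ = choose_axis_order(axonal, dendritic)
        assert primary in (0, 2)
        assert counts[primary] <= counts[1]

    def test_tie_breaks_to_x(self):
        cube = AABB((0, 0, 0), (1, 1, 1))
        assert choose_axis_order([cube] * 3, [cube] * 3) == (0, 1, 2)
        assert choose_axis_order([], []) == (0, 1, 2)

    def test_swd_equals_sw_with_chosen_order(self):
        params = BoxPopulationParams(n_axonal=50, n_dendritic=50, seed=9)
        axonal, dendritic = generate_boxes(params)
        order = choose_axis_order(axonal, dendritic)
        swd_records, swd_stats = staggered_walk_dynamic(axonal, dendritic)
        sw_records, sw_stats = staggered_walk(axonal, dendritic, *order)
        assert keys(swd_records) == keys(sw_records)
        assert swd_stats.comparisons_1d == sw_stats.comparisons_1d
        assert swd_stats.primary_dimension == order[0]


def test_run_detector_rejects_unknown_algorithm():
    with pytest.raises(ValueError, match="unknown algorithm"):
        run_detector([], [], algorithm="quadtree")
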