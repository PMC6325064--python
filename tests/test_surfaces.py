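"""Surface construction: adjacency, builders, defects, classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from memtopo import surfaces
from memtopo.errors import InvalidSpecError
from memtopo.surfaces import (
    SurfaceGraph,
    build_bumps,
    build_flat,
    build_from_height_map,
    build_invaginations,
    build_pillars,
    build_quadrant_composite,
    build_ridges,
    classify_nodes,
    insert_defect,
)

height_maps = arrays(
    dtype=np.int64,
    shape=st.tuples(st.integers(1, 6), st.integers(1, 6)),
    elements=st.integers(0, 5),
)


def brute_force_adjacency(nodes):
    """O(n^2) face-adjacency count, independent of the package's key search."""
    nodes = [tuple(n) for n in nodes]
    pairs = 0
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            if sum(abs(x - y) for x, y in zip(a, b)) == 1:
                pairs += 1
    return pairs


class TestSurfaceGraph:
    def test_single_node_has_no_neighbours(self):
        s = build_flat(1, 1)
        assert s.n_nodes == 1
        assert s.degrees.tolist() == [0]

    def test_flat_3x3_degrees(self):
        s = build_flat(3, 3)
        assert s.n_nodes == 9
        assert s.degrees[s.node_id((1, 1, 0))] == 4
        for corner in [(0, 0, 0), (2, 0, 0), (0, 2, 0), (2, 2, 0)]:
            assert s.degrees[s.node_id(corner)] == 2

    def test_flat_adjacency_count_matches_grid_formula(self):
        # w*h nodes and 2*(2wh - w - h) directed adjacencies on a w x h grid
        w, h = 57, 43
        s = build_flat(w, h)
        assert s.n_nodes == w * h
        assert s.adjacency.nnz == 2 * (2 * w * h - w - h)

    def test_adjacency_matches_brute_force_on_small_surface(self, deformed_small):
        expected = brute_force_adjacency(deformed_small.nodes)
        assert deformed_small.adjacency.nnz == 2 * expected

    def test_duplicate_nodes_rejected(self):
        with pytest.raises(InvalidSpecError):
            SurfaceGraph([(0, 0, 0), (0, 0, 0)])

    def test_negative_coordinates_rejected(self):
        with pytest.raises(InvalidSpecError):
            SurfaceGraph([(0, -1, 0)])

    def test_node_lookup_roundtrip(self, deformed_small):
        for i in range(deformed_small.n_nodes):
            assert deformed_small.node_id(tuple(deformed_small.nodes[i])) == i
        assert (99, 99, 99) not in deformed_small

    @given(height_maps)
    @settings(max_examples=60, deadline=None)
    def test_height_map_surfaces_satisfy_graph_invariants(self, hm):
        s = build_from_height_map(hm)
        A = s.adjacency
        # symmetry
        assert (A != A.T).nnz == 0
        # 6-connectivity: adjacent nodes differ by one in exactly one coordinate
        coo = A.tocoo()
        diff = np.abs(s.nodes[coo.row] - s.nodes[coo.col])
        assert (diff.sum(axis=1) == 1).all()
        # single connected component, degree bounds
        assert s.is_connected()
        assert (s.degrees <= 6).all()
        if s.n_nodes > 1:
            assert (s.degrees >= 1).all()


class TestBuilders:
    def test_flat_rejects_nonpositive_dimensions(self):
        with pytest.raises(InvalidSpecError):
            build_flat(0, 3)

    def test_height_map_rejects_negative_heights(self):
        with pytest.raises(InvalidSpecError):
            build_from_height_map(np.array([[0, -1]]))

    def test_constant_height_map_equals_flat(self):
        s = build_from_height_map(np.full((4, 6), 3))
        flat = build_flat(6, 4, z=3)
        assert s.same_nodes(flat)

    def test_height_step_connectors(self):
        # a 2x1 map with heights (0, 3): connectors fill the higher column
        s = build_from_height_map(np.array([[0, 3]]))
        expected = {(0, 0, 0), (1, 0, 0), (1, 0, 1), (1, 0, 2), (1, 0, 3)}
        assert set(map(tuple, s.nodes)) == expected
        assert s.is_connected()
        assert brute_force_adjacency(s.nodes) == len(expected) - 1  # a path

    def test_ridges_zero_height_equals_flat(self):
        r = build_ridges((7, 5), 0, 4, 2)
        assert r.same_nodes(build_flat(7, 5))

    def test_ridges_nodes_per_period(self):
        # one interior period of the h4/w4/s2 field holds 14 nodes per row:
        # 2 gap + 2x(4 wall + 1 top) + 2 inner tops
        r = build_ridges((26, 5), 4, 4, 2, phase=2)
        row = r.nodes[(r.nodes[:, 1] == 2) & np.isin(r.nodes[:, 0], range(2, 8))]
        assert len(row) == 14

    def test_folded_surface_interior_degree_is_four(self, ridged_small):
        deg, _ = classify_nodes(ridged_small)
        assert set(deg[ridged_small.interior_mask()]) == {4}

    def test_ridges_overflow_rejected(self):
        with pytest.raises(InvalidSpecError):
            build_ridges((5, 5), 4, 4, 2)  # one period does not fit

    def test_pillars_have_flat_tops_and_corner_degrees(self):
        s = build_pillars((41, 41), base_size=5, pillar_height=15, grid_spacing=12)
        top_nodes = s.nodes[s.nodes[:, 2] == 15]
        assert len(top_nodes) > 0
        deg, hist = classify_nodes(s)
        assert 3 in hist and 4 in hist and set(hist) != {4}  # deformed
        # the top rim turns at external corners of degree 3
        top_ids = np.flatnonzero(s.nodes[:, 2] == 15)
        assert (deg[top_ids] == 3).any()

    def test_square_pillar_base_corners_have_five_neighbours(self):
        # without corner indentation the pillar base corners are internal
        # corners: five neighbours, all at z = 0
        s = build_pillars((29, 29), base_size=5, pillar_height=15, grid_spacing=14,
                          indent_corners=False)
        deg, hist = classify_nodes(s)
        five = s.nodes[deg == 5]
        assert len(five) > 0
        assert (five[:, 2] == 0).all()

    def test_pillar_overlap_rejected(self):
        with pytest.raises(InvalidSpecError):
            build_pillars((41, 41), base_size=7, grid_spacing=6)

    def test_invaginations_are_deformed(self):
        # a square pit has external corners (degree 3) at its rim but, unlike
        # a slot corridor, no five-neighbour nodes: its plan-view corners meet
        # only diagonally in a 6-connected node sheet
        s = build_invaginations((41, 41), pit_size=5, pit_depth=6, grid_spacing=12)
        _, hist = classify_nodes(s)
        assert 3 in hist and 4 in hist and set(hist) != {4}
        assert 5 not in hist

    def test_bumps_surface_is_deformed(self):
        s = build_bumps((25, 25))
        _, hist = classify_nodes(s)
        assert {3, 4, 5} <= set(hist)

    def test_quadrant_composite_all_flat_equals_flat(self):
        q = surfaces.flat_height_map(8, 8, z=2)
        s = build_quadrant_composite(q, q, q, q)
        assert s.same_nodes(build_flat(16, 16, z=2))

    def test_quadrant_composite_node_count_and_connectivity(self):
        q = 16
        flat_q = surfaces.flat_height_map(q, q, z=6)
        ridges_q = surfaces.ridges_height_map((q, q), 4, 4, 2, phase=2, base=6)
        pil_q = surfaces.pillars_height_map((q, q), 5, 8, 12, base_z=6)
        inv_q = surfaces.invaginations_height_map((q, q), 5, 6, 12)
        s = build_quadrant_composite(flat_q, ridges_q, pil_q, inv_q)
        assert s.is_connected()
        _, hist = classify_nodes(s)
        assert 5 in hist  # internal corners where quadrant reliefs meet the seams
        parts = [build_from_height_map(h) for h in (flat_q, ridges_q, pil_q, inv_q)]
        # pasting can only add connector nodes along the seams
        assert s.n_nodes >= sum(p.n_nodes for p in parts)

    def test_quadrant_composite_incompatible_centre_rejected(self):
        a = surfaces.flat_height_map(8, 8, z=0)
        b = surfaces.flat_height_map(8, 8, z=5)
        with pytest.raises(InvalidSpecError):
            build_quadrant_composite(a, b, a, a)


@pytest.fixture(scope="module")
def tall_ridges():
    return build_ridges((39, 21), 7, 3, 9)


class TestDefects:
    def test_slot_creates_five_neighbour_base_corners(self, tall_ridges):
        phase = tall_ridges.metadata["phase"]
        s = insert_defect(tall_ridges, "slot", (phase + 12, 10))
        deg, hist = classify_nodes(s)
        assert hist.get(5, 0) == 4  # the four corners of the slot base
        five = s.nodes[deg == 5]
        assert (five[:, 2] == 0).all()

    def test_slot_keeps_surface_connected(self, tall_ridges):
        s = insert_defect(tall_ridges, "slot", (tall_ridges.metadata["phase"], 10))
        assert s.is_connected()

    def test_notch_depth_limits_cut(self, tall_ridges):
        phase = tall_ridges.metadata["phase"]
        s = insert_defect(tall_ridges, "notch", (phase + 12, 10), depth=2)
        assert s.height_map[10, phase + 12] == 5
        assert s.is_connected()

    def test_off_ridge_position_rejected(self, tall_ridges):
        phase = tall_ridges.metadata["phase"]
        with pytest.raises(InvalidSpecError):
            insert_defect(tall_ridges, "slot", (phase + 5, 10))  # in a gap

    def test_defect_does_not_mutate_input(self, tall_ridges):
        before = tall_ridges.nodes.copy()
        insert_defect(tall_ridges, "slot", (tall_ridges.metadata["phase"], 10))
        assert np.array_equal(tall_ridges.nodes, before)

    def test_unknown_kind_rejected(self, tall_ridges):
        with pytest.raises(InvalidSpecError):
            insert_defect(tall_ridges, "hole", (0, 0))


class TestClassification:
    def test_isolated_node_degree_zero(self):
        deg, hist = classify_nodes(build_flat(1, 1))
        assert hist == {0: 1}

    def test_flat_interior_degree_four(self, flat9):
        deg, hist = classify_nodes(flat9)
        assert hist[4] == 49  # 7x7 interior
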