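"""Active-triangle construction, complementarity, pair sampling."""

import itertools

import numpy as np
import pytest

from hopdock.surface import SurfacePoint
from hopdock.triangles import (
    Triangle,
    build_active_triangles,
    complementary,
    matching_correspondences,
    neighbors_within,
    pair_alignment,
    sample_complementary_pair,
)


def _point(pos, shape="cap", active=True, residue=("A", 1, "")):
    p = SurfacePoint(
        position=np.asarray(pos, dtype=float),
        normal=np.array([0.0, 0.0, 1.0]),
        shape=shape,
        nearest_residue=residue,
    )
    p.active = active
    return p


def _triangle(positions, shapes=("cap", "cap", "cap"), active=True):
    verts = tuple(_point(p, s) for p, s in zip(positions, shapes))
    return Triangle(vertices=verts, indices=(0, 1, 2), active=active)


def _brute_force_triangles(points, d_min=2.0, d_max=5.0, angle_min=15.0, com_res=1.0):
    """Independent enumeration: all C(n,3) triples, same rules, same scan order."""

    def min_angle(p):
        out = []
        for i in range(3):
            a = p[(i + 1) % 3] - p[i]
            b = p[(i + 2) % 3] - p[i]
            c = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
            out.append(np.degrees(np.arccos(np.clip(c, -1, 1))))
        return min(out)

    order = sorted(range(len(points)), key=lambda i: tuple(points[i].position))
    pos = {i: points[i].position for i in range(len(points))}
    claimed_cells = set()
    result = []
    for ai in range(len(order)):
        a = order[ai]
        if not points[a].active:
            continue
        found = False
        for bi, ci in itertools.combinations(range(ai + 1, len(order)), 2):
            b, c = order[bi], order[ci]
            p = np.stack([pos[a], pos[b], pos[c]])
            sides = [
                np.linalg.norm(p[0] - p[1]),
                np.linalg.norm(p[0] - p[2]),
                np.linalg.norm(p[1] - p[2]),
            ]
            if min(sides) < d_min or max(sides) > d_max:
                continue
            if min_angle(p) < angle_min:
                continue
            cell = tuple(np.floor(p.mean(axis=0) / com_res).astype(int))
            if cell in claimed_cells:
                continue
            claimed_cells.add(cell)
            result.append((a, b, c))
            found = True
            break
        del found
    return result


class TestBuildActiveTriangles:
    def test_collinear_points_give_no_triangle(self):
        points = [_point([0, 0, 0]), _point([3, 0, 0]), _point([4.5, 0, 0])]
        assert build_active_triangles(points) == []

    def test_too_close_points_give_no_triangle(self):
        points = [_point([0, 0, 0]), _point([1, 0, 0]), _point([0, 1, 0])]
        assert build_active_triangles(points) == []

    def test_no_active_points_gives_empty_list(self):
        points = [_point([0, 0, 0], active=False), _point([3, 0, 0], active=False),
                  _point([0, 3, 0], active=False)]
        assert build_active_triangles(points) == []

    def test_matches_brute_force_enumeration(self, rng):
        points = [
            _point(rng.uniform(0, 12, size=3), active=bool(rng.random() < 0.6))
            for _ in range(30)
        ]
        got = [t.indices for t in build_active_triangles(points)]
        expected = _brute_force_triangles(points)
        assert got == expected
        assert len(got) > 0

    def test_uniqueness_invariants_on_fixture(self, triangle_lists):
        for triangles in triangle_lists:
            firsts = [t.indices[0] for t in triangles]
            assert len(set(firsts)) == len(firsts)
            cells = [tuple(np.floor(t.com / 1.0).astype(int)) for t in triangles]
            assert len(set(cells)) == len(cells)
            assert all(t.vertices[0].active for t in triangles)

    def test_fewer_triangles_than_points(self, annotated_points, triangle_lists):
        for points, triangles in zip(annotated_points, triangle_lists):
            assert len(triangles) < len(points)

    def test_count_decreases_with_conservation_threshold(self, system, critical_points):
        from hopdock.conservation import annotate_critical_points

        points_a, _ = critical_points
        counts = []
        for th in (0.25, 0.5, 0.75):
            annotate_critical_points(points_a, system.scores_a, th)
            counts.append(len(build_active_triangles(points_a)))
        annotate_critical_points(points_a, system.scores_a, 0.5)  # restore
        assert counts[0] >= counts[1] >= counts[2]
        assert counts[2] < counts[0]

    def test_side_lengths_within_bounds(self, triangle_lists):
        for triangles in triangle_lists:
            for t in triangles[::7]:
                assert np.all(t.sides >= 2.0 - 1e-9)
                assert np.all(t.sides <= 5.0 + 1e-9)


class TestComplementary:
    def test_congruent_mirror_cap_pit_is_complementary(self):
        pos = np.array([[0.0, 0, 0], [3, 0, 0], [0, 4, 0]])
        mirror = pos * np.array([1.0, -1.0, 1.0])  # congruent, mirrored
        ta = _triangle(pos, ("cap", "cap", "belt"))
        tb = _triangle(mirror, ("pit", "pit", "belt"))
        assert complementary(ta, tb)

    def test_all_cap_pair_is_not_complementary(self):
        pos = np.array([[0.0, 0, 0], [3, 0, 0], [0, 4, 0]])
        ta = _triangle(pos, ("cap", "cap", "cap"))
        tb = _triangle(pos, ("cap", "cap", "cap"))
        assert not complementary(ta, tb, belt_wildcard=False)
        assert not complementary(ta, tb, belt_wildcard=True)

    def test_side_mismatch_is_not_complementary(self):
        ta = _triangle(np.array([[0.0, 0, 0], [3, 0, 0], [0, 4, 0]]), ("cap",) * 3)
        equilateral = np.array([[0.0, 0, 0], [2.2, 0, 0], [1.1, 1.905, 0]])
        tb = _triangle(equilateral, ("pit",) * 3)
        assert not complementary(ta, tb, side_tol=1.0)

    def test_matches_exhaustive_correspondence_check(self, rng):
        """Agreement with an inline brute force over all 6 correspondences."""
        shapes = ["cap", "pit", "belt"]
        for _ in range(100):
            pa = rng.uniform(0, 5, size=(3, 3))
            pb = rng.uniform(0, 5, size=(3, 3))
            sa = [shapes[i] for i in rng.integers(0, 3, size=3)]
            sb = [shapes[i] for i in rng.integers(0, 3, size=3)]
            ta = _triangle(pa, sa)
            tb = _triangle(pb, sb)

            def shape_ok(x, y):
                return "belt" in (x, y) or {x, y} == {"cap", "pit"}

            da = np.linalg.norm(pa[:, None] - pa[None, :], axis=-1)
            db = np.linalg.norm(pb[:, None] - pb[None, :], axis=-1)
            expected = False
            for perm in itertools.permutations(range(3)):
                if not all(shape_ok(sa[i], sb[perm[i]]) for i in range(3)):
                    continue
                if all(
                    abs(da[i, j] - db[perm[i], perm[j]]) <= 1.0
                    for i, j in ((0, 1), (0, 2), (1, 2))
                ):
                    expected = True
                    break
            assert complementary(ta, tb) == expected

    def test_pair_alignment_superimposes_matched_vertices(self):
        pos = np.array([[0.0, 0, 0], [3, 0, 0], [0, 4, 0]])
        mirror = pos * np.array([1.0, -1.0, 1.0]) + np.array([10.0, 0, 0])
        ta = _triangle(pos, ("cap", "cap", "belt"))
        tb = _triangle(mirror, ("pit", "pit", "belt"))
        T = pair_alignment(ta, tb)
        perms = matching_correspondences(ta, tb)
        residuals = []
        for perm in perms:
            moved = T.apply(tb.permuted(perm).vertex_positions)
            residuals.append(np.abs(moved - ta.vertex_positions).max())
        assert min(residuals) < 1e-9


class TestSampling:
    def _lists_with_pairs(self):
        """Two A-triangles and two B-triangles with exactly two complementary pairs."""
        base = np.array([[0.0, 0, 0], [3, 0, 0], [0, 4, 0]])
        ta1 = _triangle(base, ("cap",) * 3)
        ta2 = _triangle(base + 20.0, ("cap",) * 3)
        tb1 = _triangle(base, ("pit",) * 3)
        tb2 = _triangle(
            np.array([[0.0, 0, 0], [2.2, 0, 0], [1.1, 1.905, 0]]) + 40.0, ("pit",) * 3
        )
        # complementary pairs: (ta1, tb1) and (ta2, tb1) only
        assert complementary(ta1, tb1) and complementary(ta2, tb1)
        assert not complementary(ta1, tb2) and not complementary(ta2, tb2)
        return [ta1, ta2], [tb1, tb2]

    def test_single_pair_always_returned(self, rng):
        lists_a, lists_b = self._lists_with_pairs()
        lists_a = lists_a[:1]
        for _ in range(20):
            pair = sample_complementary_pair(lists_a, lists_b, rng)
            assert pair == (lists_a[0], lists_b[0])

    def test_two_pairs_sampled_uniformly(self, rng):
        lists_a, lists_b = self._lists_with_pairs()
        counts = {0: 0, 1: 0}
        n = 10_000
        for _ in range(n):
            ta, _tb = sample_complementary_pair(lists_a, lists_b, rng)
            counts[0 if ta is lists_a[0] else 1] += 1
        assert abs(counts[0] / n - 0.5) <= 0.02

    def test_no_pairs_is_an_error(self, rng):
        base = np.array([[0.0, 0, 0], [3, 0, 0], [0, 4, 0]])
        ta = [_triangle(base, ("cap",) * 3)]
        tb = [_triangle(base, ("cap",) * 3)]
        with pytest.raises(ValueError, match="no complementary pair"):
            sample_complementary_pair(ta, tb, rng, max_attempts=200)


class TestNeighborsWithin:
    def test_infinite_radius_returns_all(self, triangle_lists):
        triangles, _ = triangle_lists
        out = neighbors_within(triangles, triangles[0], np.inf)
        assert out == list(triangles)

    def test_zero_radius_returns_identical_com_only(self, triangle_lists):
        triangles, _ = triangle_lists
        out = neighbors_within(triangles, triangles[0], 0.0)
        assert out == [triangles[0]]

    def test_matches_linear_scan(self, triangle_lists):
        triangles, _ = triangle_lists
        center = triangles[len(triangles) // 2]
        out = neighbors_within(triangles, center, 5.0)
        expected = [
            t for t in triangles if np.linalg.norm(t.com - center.com) <= 5.0
        ]
        assert out == expected
        assert 0 < len(out) < len(triangles)


def test_triangle_tsv_export(triangle_lists, tmp_path):
    from hopdock.triangles import triangles_to_tsv

    triangles, _ = triangle_lists
    path = tmp_path / "triangles.tsv"
    triangles_to_tsv(triangles, path)
    lines = path.read_text().splitlines()
    assert lines[0].startswith("i1\ti2\ti3\tcom_x")
    assert len(lines) == len(triangles) + 1
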