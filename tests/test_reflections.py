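import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sxdamage.reflections import (
    Observation,
    ReflectionError,
    ReindexOperator,
    UnitCell,
    apply_reindex,
    d_spacing,
    default_reindex_operator,
    map_to_asu,
    pack_indices,
    point_group_ops,
    read_reflections,
    sym_equivalents,
    unique_reflections,
    unpack_indices,
    write_reflections,
)
from conftest import make_observations

# Independent enumeration of the 12 proper rotations of point group 23:
# the four even-sign-change diagonals plus the two cyclic permutations,
# each with the four sign patterns of determinant +1.
def _oracle_group23():
    mats = []
    perms = [
        ((1, 0, 0), (0, 1, 0), (0, 0, 1)),  # identity permutation
        ((0, 0, 1), (1, 0, 0), (0, 1, 0)),  # x<-z, y<-x, z<-y
        ((0, 1, 0), (0, 0, 1), (1, 0, 0)),  # the other 3-cycle
    ]
    for perm in perms:
        for signs in itertools.product((1, -1), repeat=3):
            m = np.array(perm) * np.array(signs)[:, None]
            if round(np.linalg.det(m)) == 1:
                mats.append(m.astype(np.int64))
    return mats


hkl_strategy = st.tuples(
    st.integers(-8, 8), st.integers(-8, 8), st.integers(-8, 8)
).filter(lambda t: t != (0, 0, 0))


class TestDSpacing:
    def test_closed_form_002(self, cell):
        assert d_spacing((0, 0, 2), cell) == pytest.approx(39.4)

    def test_closed_form_111(self, cell):
        assert d_spacing((1, 1, 1), cell) == pytest.approx(78.8 / math.sqrt(3))

    def test_zero_index_rejected(self, cell):
        with pytest.raises(ReflectionError):
            d_spacing((0, 0, 0), cell)

    def test_vectorized(self, cell):
        d = d_spacing(np.array([[0, 0, 2], [1, 1, 1]]), cell)
        assert d == pytest.approx([39.4, 78.8 / math.sqrt(3)])

    def test_invariant_under_symmetry_and_reindex(self, cell, group23):
        idx = (2, 3, 5)
        d0 = d_spacing(idx, cell)
        for img in sym_equivalents(idx, group23)[:, 0, :]:
            assert d_spacing(img, cell) == pytest.approx(d0)
        op = default_reindex_operator(group23)
        assert d_spacing(apply_reindex(idx, op), cell) == pytest.approx(d0)

    def test_bad_cell(self):
        with pytest.raises(ReflectionError):
            UnitCell(-1.0)


class TestPointGroup:
    def test_group23_matches_independent_enumeration(self, group23):
        oracle = _oracle_group23()
        assert len(oracle) == 12
        assert group23.order == 12
        found = {m.tobytes() for m in group23.rotations}
        assert found == {m.tobytes() for m in oracle}

    def test_contains_identity(self, group23):
        assert group23.contains(np.eye(3, dtype=int))

    def test_closure_all_144_products(self, group23):
        for a in group23.rotations:
            for b in group23.rotations:
                assert group23.contains(a @ b)

    def test_determinants_all_plus_one(self, group23):
        for m in group23.rotations:
            assert round(np.linalg.det(m)) == 1

    def test_group1(self, group1):
        assert group1.order == 1
        assert group1.contains(np.eye(3, dtype=int))

    def test_unknown_group(self):
        with pytest.raises(ReflectionError):
            point_group_ops("99")


class TestMapToASU:
    def test_orbit_of_123_collapses(self, group23):
        images = sym_equivalents((1, 2, 3), group23)[:, 0, :]
        reps = {map_to_asu(tuple(img), group23) for img in images}
        assert len(reps) == 1

    @settings(max_examples=200, deadline=None)
    @given(hkl_strategy)
    def test_idempotent(self, hkl):
        group = point_group_ops("23")
        rep = map_to_asu(hkl, group)
        assert map_to_asu(rep, group) == rep

    @settings(max_examples=100, deadline=None)
    @given(hkl_strategy)
    def test_friedel_mate_maps_together(self, hkl):
        group = point_group_ops("23")
        mate = tuple(-v for v in hkl)
        assert map_to_asu(hkl, group) == map_to_asu(mate, group)

    def test_identity_group_friedel_rule(self, group1):
        # canonical rule: lexicographically greatest of {(h,k,l), (-h,-k,-l)}
        assert map_to_asu((2, 0, 0), group1) == (2, 0, 0)
        assert map_to_asu((-2, 0, 0), group1) == (2, 0, 0)
        assert map_to_asu((0, 0, 4), group1) == (0, 0, 4)

    def test_zero_rejected(self, group23):
        with pytest.raises(ReflectionError):
            map_to_asu((0, 0, 0), group23)

    def test_asu_partition_ball(self, group23):
        """Orbits over max|hkl| <= 4 are disjoint with one representative each."""
        ball = [
            (h, k, l)
            for h in range(-4, 5)
            for k in range(-4, 5)
            for l in range(-4, 5)
            if (h, k, l) != (0, 0, 0)
        ]
        # brute-force orbits: index -> frozenset of all images incl. Friedel
        orbit_of = {}
        for idx in ball:
            images = sym_equivalents(idx, group23)[:, 0, :]
            orbit_of[idx] = frozenset(tuple(int(v) for v in im) for im in images)
        reps = {idx: map_to_asu(idx, group23) for idx in ball}
        # each orbit has exactly one representative, shared by all members
        for idx in ball:
            assert reps[idx] in orbit_of[idx]
            for other in orbit_of[idx]:
                assert reps[other] == reps[idx]
        # distinct orbits have distinct representatives
        by_orbit = {}
        for idx in ball:
            by_orbit.setdefault(orbit_of[idx], set()).add(reps[idx])
        rep_sets = list(by_orbit.values())
        assert all(len(s) == 1 for s in rep_sets)
        all_reps = [next(iter(s)) for s in rep_sets]
        assert len(all_reps) == len(set(all_reps))


class TestReindex:
    def test_direct_substitution(self, group23):
        op = default_reindex_operator(group23)
        assert apply_reindex((1, 2, 3), op) == (2, 1, -3)

    def test_twice_lands_in_orbit(self, group23):
        op = default_reindex_operator(group23)
        twice = apply_reindex(apply_reindex((1, 2, 3), op), op)
        assert map_to_asu(twice, group23) == map_to_asu((1, 2, 3), group23)

    def test_axis_reflection_same_asu(self, group23):
        op = default_reindex_operator(group23)
        assert apply_reindex((0, 0, 4), op) == (0, 0, -4)
        assert map_to_asu((0, 0, 4), group23) == map_to_asu((0, 0, -4), group23)

    def test_operator_not_in_laue_group(self, group23):
        op = default_reindex_operator(group23)
        assert not group23.laue_contains(op.matrix)
        assert group23.laue_contains(op.matrix @ op.matrix)

    def test_rejects_operator_inside_laue_group(self, group23):
        with pytest.raises(ReflectionError):
            ReindexOperator(np.eye(3, dtype=int), group23)

    def test_rejects_non_unimodular(self):
        with pytest.raises(ReflectionError):
            ReindexOperator(np.diag([2, 1, 1]))


class TestUniqueReflections:
    def test_matches_bruteforce_orbit_count(self, cell, group23):
        """Package enumeration equals a slow set-based orbit count (d >= 6 A)."""
        d_min = 6.0
        hmax = int(cell.a / d_min)
        seen = set()
        count = 0
        for h in range(-hmax, hmax + 1):
            for k in range(-hmax, hmax + 1):
                for l in range(-hmax, hmax + 1):
                    if (h, k, l) == (0, 0, 0) or (h + k + l) % 2:
                        continue
                    if cell.a / math.sqrt(h * h + k * k + l * l) < d_min:
                        continue
                    if (h, k, l) in seen:
                        continue
                    images = sym_equivalents((h, k, l), group23)[:, 0, :]
                    seen.update(tuple(int(v) for v in im) for im in images)
                    count += 1
        refl = unique_reflections(cell, group23, d_min)
        assert len(refl) == count

    def test_d_max_filter(self, cell, group23):
        refl = unique_reflections(cell, group23, 6.0, d_max=30.0)
        d = d_spacing(refl, cell)
        assert d.min() >= 6.0 and d.max() <= 30.0

    def test_centering_excludes_odd_sums(self, cell, group23):
        refl = unique_reflections(cell, group23, 6.0)
        assert np.all(refl.sum(axis=1) % 2 == 0)

    def test_too_coarse_warns_and_is_empty(self, cell, group23):
        with pytest.warns(UserWarning):
            refl = unique_reflections(cell, group23, 200.0)
        assert len(refl) == 0

    def test_pack_roundtrip(self):
        rng = np.random.default_rng(0)
        hkl = rng.integers(-2047, 2048, size=(500, 3))
        assert np.array_equal(unpack_indices(pack_indices(hkl)), hkl)


class TestObservationType:
    def test_zero_index_rejected(self):
        with pytest.raises(ReflectionError):
            Observation(0, 0, 0, 1.0, 1.0, 1, "a")

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ReflectionError):
            Observation(1, 0, 0, 1.0, 0.0, 1, "a")

    def test_frame_one_based(self):
        with pytest.raises(ReflectionError):
            Observation(1, 0, 0, 1.0, 1.0, 0, "a")


class TestReflectionIO:
    def test_roundtrip(self, tmp_path, cell):
        df = make_observations(
            [
                (1, 2, 3, 100.25, 3.5, 1, "xa"),
                (-4, 0, 2, 0.0078125, 0.125, 2, "xa"),
                (5, 5, 0, 1e6, 12.0, 700, "xb"),
            ]
        )
        path = tmp_path / "obs.refl"
        write_reflections(df, path, cell=cell, group_name="23", dose_per_frame=0.808)
        back, meta = read_reflections(path)
        assert meta["cell_a"] == 78.8
        assert meta["point_group"] == 23 or meta["point_group"] == "23"
        assert meta["dose_per_frame"] == 0.808
        for col in ["h", "k", "l", "frame"]:
            assert np.array_equal(back[col].to_numpy(), df[col].to_numpy())
        for col in ["intensity", "sigma"]:
            assert np.array_equal(back[col].to_numpy(), df[col].to_numpy())
        assert list(back["crystal_id"]) == list(df["crystal_id"])

    def test_empty_roundtrip(self, tmp_path):
        df = make_observations([(1, 0, 1, 1.0, 1.0, 1, "x")]).iloc[:0]
        path = tmp_path / "empty.refl"
        write_reflections(df, path)
        back, _ = read_reflections(path)
        assert len(back) == 0

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.refl"
        path.write_text("# header\n1 2 3 10.0 1.0 1 xa\n1 2 3 10.0\n")
        with pytest.raises(ReflectionError, match="line 3"):
            read_reflections(path)

    def test_negative_sigma_rejected(self, tmp_path):
        path = tmp_path / "bad.refl"
        path.write_text("1 2 3 10.0 -1.0 1 xa\n")
        with pytest.raises(ReflectionError, match="sigma"):
            read_reflections(path)
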