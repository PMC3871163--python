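import numpy as np
import pytest
from scipy import stats

from pestsamp import (
    TransectSpec,
    ordered_trajectory,
    random_trajectory,
    transect_membership,
    transect_trajectory,
)
from tests.conftest import make_site


def grid_site(nx=10, ny=6, spacing=10.0):
    coords = [(i * spacing, j * spacing) for j in range(ny) for i in range(nx)]
    pcts = [float((i * 7 + 3) % 11) for i in range(len(coords))]
    return make_site(pcts, coords=coords, site_id="grid")


class TestRandomTrajectory:
    def test_single_tree_site(self):
        site = make_site([2.0])
        traj = random_trajectory(site, n_max=5, seed=0)
        assert np.array_equal(traj.indices, np.zeros(5, int))

    def test_reproducible_from_seed_and_replicate(self, iid_site):
        a = random_trajectory(iid_site, 50, seed=9, replicate_id=3)
        b = random_trajectory(iid_site, 50, seed=9, replicate_id=3)
        c = random_trajectory(iid_site, 50, seed=9, replicate_id=4)
        assert np.array_equal(a.indices, b.indices)
        assert not np.array_equal(a.indices, c.indices)

    def test_uniform_frequencies(self, iid_site):
        draws = np.concatenate(
            [random_trajectory(iid_site, 1000, seed=1, replicate_id=r).indices
             for r in range(100)]
        )
        obs = np.bincount(draws, minlength=iid_site.n_trees)
        chi2 = (((obs - 500.0) ** 2) / 500.0).sum()
        p = stats.chi2.sf(chi2, iid_site.n_trees - 1)
        assert p > 0.001


class TestOrderedTrajectory:
    def test_identity_and_reverse(self):
        site = make_site([1, 2, 3, 4, 5])
        fwd = ordered_trajectory(site)
        rev = ordered_trajectory(site, reverse=True)
        assert np.array_equal(fwd.indices, np.arange(5))
        assert np.array_equal(rev.indices, np.arange(5)[::-1])

    def test_sorts_by_collection_index_not_storage_order(self):
        from pestsamp import SiteSample, TreeRecord

        trees = [
            TreeRecord("a", 0, 0, 1.0, collection_index=3),
            TreeRecord("b", 1, 0, 2.0, collection_index=1),
            TreeRecord("c", 2, 0, 3.0, collection_index=2),
        ]
        site = SiteSample("s", trees)
        traj = ordered_trajectory(site)
        # sort oracle: argsort of the collection numbers
        assert np.array_equal(traj.indices, np.argsort([3, 1, 2]))

    def test_duplicate_collection_index_rejected(self):
        from pestsamp import SiteSample, TreeRecord

        trees = [
            TreeRecord("a", 0, 0, 1.0, collection_index=1),
            TreeRecord("b", 1, 0, 2.0, collection_index=1),
        ]
        with pytest.raises(ValueError):
            SiteSample("s", trees)


class TestTransectMembership:
    def test_tree_at_start_is_first(self):
        site = grid_site()
        idx = transect_membership(site, (0, 0), (90, 0), width_w=10)
        assert idx[0] == 0  # the tree sitting exactly on the start point

    def test_closed_boundary_at_half_width(self):
        site = make_site([1.0, 2.0, 3.0],
                         coords=[(0, 5.0), (10, 5.000001), (20, -5.0)])
        idx = transect_membership(site, (0, 0), (30, 0), width_w=10)
        # cross-track exactly w/2 on both sides is included; just over is not
        assert set(idx.tolist()) == {0, 2}

    def test_beyond_endpoints_excluded(self):
        site = make_site([1.0, 2.0], coords=[(-1, 0), (31, 0)])
        with pytest.raises(ValueError):
            transect_trajectory(site, TransectSpec((0, 0), (30, 0), 10.0))

    def test_rotated_frame_brute_force_oracle(self, rng):
        pts = rng.uniform(-50, 150, size=(100, 2))
        site = make_site(rng.uniform(0, 10, 100).tolist(),
                         coords=[tuple(p) for p in pts])
        start, end, w = np.array([5.0, -3.0]), np.array([97.0, 61.0]), 24.0
        got = transect_membership(site, tuple(start), tuple(end), w)

        # oracle: rotate the frame so the transect lies on the x-axis and
        # apply an axis-aligned rectangle test
        axis = end - start
        theta = np.arctan2(axis[1], axis[0])
        rot = np.array([[np.cos(-theta), -np.sin(-theta)],
                        [np.sin(-theta), np.cos(-theta)]])
        local = (pts - start) @ rot.T
        length = np.hypot(*axis)
        inside = (
            (local[:, 0] >= -1e-9) & (local[:, 0] <= length + 1e-9)
            & (np.abs(local[:, 1]) <= w / 2 + 1e-9)
        )
        expected = np.nonzero(inside)[0]
        expected = expected[np.argsort(local[expected, 0], kind="stable")]
        assert np.array_equal(got, expected)

    def test_rigid_motion_invariance(self, rng):
        pts = rng.uniform(0, 100, size=(60, 2))
        vals = rng.uniform(0, 10, 60).tolist()
        start, end, w = (10.0, 20.0), (80.0, 90.0), 15.0
        base = transect_membership(make_site(vals, coords=[tuple(p) for p in pts]),
                                   start, end, w)
        for _ in range(5):
            theta = rng.uniform(0, 2 * np.pi)
            shift = rng.uniform(-500, 500, 2)
            rot = np.array([[np.cos(theta), -np.sin(theta)],
                           [np.sin(theta), np.cos(theta)]])
            moved = pts @ rot.T + shift
            ms, me = np.array(start) @ rot.T + shift, np.array(end) @ rot.T + shift
            got = transect_membership(
                make_site(vals, coords=[tuple(p) for p in moved]),
                tuple(ms), tuple(me), w,
            )
            assert np.array_equal(got, base)


class TestTransectTrajectory:
    def test_matches_rectangle_enumeration(self):
        site = grid_site(nx=10, ny=6)
        spec = TransectSpec((0, 20), (90, 20), width_w=10, jitter_j=30)
        traj = transect_trajectory(site, spec)

        # brute force: three horizontal strips (centre y=20, left y=50,
        # right y=-10), trees ordered by x within each
        coords = site.coords()

        def strip(yc):
            sel = [
                i for i in range(site.n_trees)
                if abs(coords[i, 1] - yc) <= 5 and 0 <= coords[i, 0] <= 90
            ]
            return sorted(sel, key=lambda i: coords[i, 0])

        expected = []
        for ids in (strip(20), strip(50), strip(-10)):
            expected.extend(i for i in ids if i not in expected)
        assert traj.indices.tolist() == expected

    def test_huge_jitter_leaves_centre_only(self):
        site = grid_site(nx=10, ny=6)
        spec = TransectSpec((0, 20), (90, 20), width_w=10, jitter_j=1000)
        traj = transect_trajectory(site, spec)
        centre = transect_membership(site, (0, 20), (90, 20), 10)
        assert np.array_equal(traj.indices, centre)

    def test_two_sets_interleave(self):
        site = grid_site(nx=10, ny=6)
        a = TransectSpec((0, 0), (90, 0), width_w=10, jitter_j=20)
        b = TransectSpec((0, 10), (90, 10), width_w=10, jitter_j=20)
        traj = transect_trajectory(site, [a, b])

        # manual interleaving A1, B1, A2, B2, A3, B3 with first-occurrence
        # de-duplication
        lines = [
            ((0, 0), (90, 0)), ((0, 10), (90, 10)),      # A1, B1
            ((0, 20), (90, 20)), ((0, 30), (90, 30)),    # A2 (left), B2 (left)
            ((0, -20), (90, -20)), ((0, -10), (90, -10)),  # A3, B3 (right)
        ]
        expected: list[int] = []
        for s, e in lines:
            for i in transect_membership(site, s, e, 10):
                if i not in expected:
                    expected.append(int(i))
        assert traj.indices.tolist() == expected

    def test_full_coverage_visits_each_tree_once(self):
        site = grid_site(nx=10, ny=3)  # rows y = 0, 10, 20
        spec = TransectSpec((0, 10), (90, 10), width_w=10, jitter_j=10)
        traj = transect_trajectory(site, spec)
        assert sorted(traj.indices.tolist()) == list(range(site.n_trees))
        assert len(set(traj.indices.tolist())) == site.n_trees

    def test_reverse_reverses_final_sequence(self):
        site = grid_site()
        spec = TransectSpec((0, 20), (90, 20), width_w=10, jitter_j=30)
        fwd = transect_trajectory(site, spec)
        rev = transect_trajectory(site, spec, reverse=True)
        assert np.array_equal(rev.indices, fwd.indices[::-1])

    def test_field_configuration_recorded_in_metadata(self):
        site = grid_site()
        for j in (20.0, 30.0, 40.0):
            spec = TransectSpec((0, 20), (90, 20), width_w=10.0, jitter_j=j)
            traj = transect_trajectory(site, spec)
            assert traj.metadata["width_w"] == [10.0]
            assert traj.metadata["jitter_j"] == [j]
            assert "counter-clockwise" in traj.metadata["handedness"]

    def test_deterministic(self):
        site = grid_site()
        spec = TransectSpec((0, 20), (90, 20), width_w=10, jitter_j=30)
        a = transect_trajectory(site, spec)
        b = transect_trajectory(site, spec)
        assert np.array_equal(a.indices, b.indices)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            TransectSpec((0, 0), (0, 0), width_w=10)
        with pytest.raises(ValueError):
            TransectSpec((0, 0), (1, 0), width_w=0)
        with pytest.raises(ValueError):
            TransectSpec((0, 0), (1, 0), width_w=10, jitter_j=-1)
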