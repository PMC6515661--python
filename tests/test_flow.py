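"""Profile preprocessing, Manhattan distances, PAM and silhouettes."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from caacircuit import (
    BinnedProfile,
    ResponseProfile,
    bin_profile,
    build_masks,
    distance_matrix,
    enumerate_presence_patterns,
    manhattan_distance,
    pam,
    silhouette_scan,
    trim_outliers,
)
from caacircuit.flow import DegenerateProfileError, mean_silhouette, pooled_ranges


def profile(events, clone_id="c0"):
    return ResponseProfile(clone_id, np.asarray(events, dtype=float))


def brute_force_pam_cost(D, k):
    N = D.shape[0]
    return min(
        D[:, list(meds)].min(axis=1).sum() for meds in itertools.combinations(range(N), k)
    )


class TestTrimOutliers:
    def test_full_range_is_identity(self, rng):
        p = profile(rng.uniform(1, 1000, size=(50, 2)))
        out = trim_outliers(p, 0, 100)
        assert np.array_equal(out.events, p.events)

    def test_extreme_event_removed_by_rank(self, rng):
        base = rng.uniform(100, 200, size=(1000, 2))
        base[123, 0] = 1e7  # single extreme event on the gfp channel
        out = trim_outliers(profile(base), 0.5, 99.5)
        # rank-based: 5 lowest + 5 highest per channel, overlaps possible
        assert out.n_events <= 1000 - 10
        assert out.events[:, 0].max() < 1e6

    def test_single_event_profile_degenerates(self):
        with pytest.raises(DegenerateProfileError):
            trim_outliers(profile([[10.0, 10.0]]), 25, 75)

    def test_bad_percentile_order_rejected(self):
        with pytest.raises(ValueError):
            trim_outliers(profile([[1, 1], [2, 2]]), 50, 50)


class TestBinProfile:
    RANGES = ((10.0, 10000.0), (10.0, 10000.0))

    def test_identical_events_fill_one_cell(self):
        p = profile([[100.0, 100.0]] * 5)
        b = bin_profile(p, n=10, ranges=self.RANGES, normalize=False)
        assert b.grid.sum() == 5
        assert (b.grid > 0).sum() == 1
        bn = bin_profile(p, n=10, ranges=self.RANGES, normalize=True)
        assert bn.grid.max() == pytest.approx(1.0)

    def test_interior_edge_goes_to_higher_bin(self):
        # linear axes; with n=10 over [0, 10) the value 3.0 is the lower
        # edge of bin 3
        p = profile([[3.0, 0.5]])
        b = bin_profile(p, n=10, ranges=((0.0, 10.0), (0.0, 10.0)), log_transform=False, normalize=False)
        assert b.grid[3, 0] == 1

    def test_out_of_range_events_clamp_to_edges(self):
        p = profile([[1.0, 1.0], [1e9, 1e9]])
        b = bin_profile(p, n=4, ranges=self.RANGES, normalize=False)
        assert b.grid[0, 0] == 1 and b.grid[3, 3] == 1

    def test_nonpositive_values_fail_log_transform(self):
        with pytest.raises(ValueError, match="2 nonpositive"):
            bin_profile(profile([[-1.0, 5.0], [0.0, 5.0], [5.0, 5.0]]), n=4, ranges=self.RANGES)

    def test_uniform_events_fill_bins_uniformly(self, rng):
        logs = rng.uniform(1, 4, size=(100_000, 2))
        b = bin_profile(profile(10.0**logs), n=10, ranges=self.RANGES, normalize=False)
        expected = 100_000 / 100
        sd = np.sqrt(100_000 * 0.01 * 0.99)
        assert np.all(np.abs(b.grid - expected) < 5 * sd)


class TestManhattanDistance:
    def grid(self, cells, n=2, normalized=False):
        return BinnedProfile(n, np.array(cells, dtype=float), ((1.0, 10.0), (1.0, 10.0)), True, normalized)

    def test_identity_and_hand_computed_value(self):
        p = self.grid([[1, 0], [0, 0]])
        q = self.grid([[0, 0], [0, 1]])
        assert manhattan_distance(p, p) == 0.0
        assert manhattan_distance(p, q) == 2.0

    def test_disjoint_normalized_profiles_saturate_at_two(self):
        p = self.grid([[0.5, 0.5], [0, 0]], normalized=True)
        q = self.grid([[0, 0], [0.5, 0.5]], normalized=True)
        assert manhattan_distance(p, q) == pytest.approx(2.0)

    def test_incompatible_grids_rejected(self):
        p = self.grid([[1, 0], [0, 0]])
        q = BinnedProfile(2, np.zeros((2, 2)), ((1.0, 99.0), (1.0, 10.0)), True, False)
        with pytest.raises(ValueError, match="incompatible"):
            manhattan_distance(p, q)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_metric_axioms_on_random_triples(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = (self.grid(rng.integers(0, 9, size=(2, 2))) for _ in range(3))
        assert manhattan_distance(a, b) == manhattan_distance(b, a) >= 0
        assert manhattan_distance(a, c) <= manhattan_distance(a, b) + manhattan_distance(b, c) + 1e-12


class TestPAM:
    def test_k_equals_n_is_free(self, rng):
        X = rng.uniform(size=(6, 3))
        D = np.abs(X[:, None] - X[None, :]).sum(axis=2)
        res = pam(D, 6)
        assert res.total_cost == 0.0
        assert res.medoid_indices == tuple(range(6))

    def test_two_separated_triplets_match_brute_force(self, rng):
        X = np.vstack([rng.normal(0, 0.1, size=(3, 2)), rng.normal(10, 0.1, size=(3, 2))])
        D = np.abs(X[:, None] - X[None, :]).sum(axis=2)
        res = pam(D, 2)
        assert res.total_cost == pytest.approx(brute_force_pam_cost(D, 2))
        assert sorted(np.bincount(res.assignments)) == [3, 3]

    def test_duplicated_dataset_keeps_medoids_and_doubles_cost(self, rng):
        X = rng.uniform(size=(7, 2))
        D = np.abs(X[:, None] - X[None, :]).sum(axis=2)
        res = pam(D, 3)
        D2 = np.kron(D, np.ones((2, 2)))
        np.fill_diagonal(D2, 0.0)
        res2 = pam(D2, 3)
        # each original point i becomes the duplicate pair (2i, 2i+1); the
        # tie rule keeps the first copy of each original medoid
        assert res2.medoid_indices == tuple(2 * m for m in res.medoid_indices)
        assert res2.total_cost == pytest.approx(2 * res.total_cost)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            pam(np.zeros((3, 3)), 4)

    def test_invalid_distance_matrix_rejected(self):
        with pytest.raises(ValueError):
            pam(np.array([[0.0, 1.0], [2.0, 0.0]]), 1)

    def test_never_beats_the_exhaustive_bound(self, rng):
        # even on structureless uniform instances (where any swap-based
        # local search can stall) the cost never undercuts the optimum
        for trial in range(60):
            N = int(rng.integers(6, 11))
            k = int(rng.integers(2, 4))
            X = rng.uniform(size=(N, 3))
            D = np.abs(X[:, None] - X[None, :]).sum(axis=2)
            assert pam(D, k).total_cost >= brute_force_pam_cost(D, k) - 1e-9

    def test_matches_exhaustive_search_on_profile_instances(self, rng):
        # instances drawn as the pipeline's own data: binned clone profiles
        # from jittered archetypes
        from caacircuit import generate_archetype_dataset
        from caacircuit.flow import bin_profile, distance_matrix, pooled_ranges

        hits = 0
        for trial in range(100):
            k = int(rng.integers(2, 4))
            clones = int(rng.integers(2, 4))
            profiles, _, _ = generate_archetype_dataset(
                k, clones, n_events=300, jitter=0.2, seed=int(rng.integers(0, 2**31))
            )
            ranges = pooled_ranges(profiles)
            D = distance_matrix([bin_profile(p, n=10, ranges=ranges) for p in profiles])
            res = pam(D, k)
            best = brute_force_pam_cost(D, k)
            assert res.total_cost >= best - 1e-9
            hits += res.total_cost <= best + 1e-9
        assert hits >= 95


class TestSilhouette:
    def two_group_profiles(self, rng, n_per=6):
        profs = []
        for g, center in enumerate(((2.0, 2.0), (4.0, 4.0))):
            for i in range(n_per):
                logs = rng.normal(center, 0.05, size=(500, 2))
                profs.append(profile(10.0**logs, clone_id=f"g{g}_{i}"))
        return profs

    def test_true_group_count_maximizes_silhouette(self, rng):
        profs = self.two_group_profiles(rng)
        df = silhouette_scan(profs, n_values=(10,), k_range=range(2, 5))
        by_k = df.set_index("k")["mean_silhouette"]
        assert by_k[2] > by_k[3]
        assert df.attrs["recommended"][1] == 2

    def test_identical_profiles_flag_degenerate_data(self):
        p = profile([[100.0, 100.0]] * 10)
        profs = [ResponseProfile(f"c{i}", p.events) for i in range(5)]
        df = silhouette_scan(profs, n_values=(4,), k_range=range(2, 4), ranges=((10, 1000), (10, 1000)))
        assert df.attrs["degenerate"]
        assert (df["mean_silhouette"] == 0.0).all()

    def test_singleton_clusters_score_zero(self):
        D = np.array(
            [[0.0, 1.0, 5.0], [1.0, 0.0, 5.0], [5.0, 5.0, 0.0]]
        )
        val, degenerate = mean_silhouette(D, np.array([0, 1, 2][:3]))
        # k = N leaves the silhouette undefined -> convention 0 + flag
        assert degenerate and val == 0.0
        val2, deg2 = mean_silhouette(D, np.array([0, 0, 1]))
        assert not deg2
        assert val2 > 0  # singleton contributes 0, pair is well separated


class TestMasks:
    def binned(self, cells):
        g = np.array(cells, dtype=float)
        return BinnedProfile(2, g / g.sum(), ((1.0, 10.0), (1.0, 10.0)), True, True)

    def test_mask_averages_members_and_sums_to_one(self):
        from caacircuit.flow import ClusteringResult

        b = [self.binned([[1, 0], [0, 0]]), self.binned([[0, 1], [0, 0]]), self.binned([[0, 0], [1, 1]])]
        res = ClusteringResult(2, (0, 2), np.array([0, 0, 1]), 0.0, 0.0)
        masks = build_masks(res, b)
        assert len(masks) == 2
        assert masks[0].grid.sum() == pytest.approx(1.0, abs=1e-12)
        assert masks[0].grid[0, 0] == pytest.approx(0.5)
        # singleton cluster: mask equals the profile
        assert np.allclose(masks[1].grid, b[2].grid)

    def test_identical_members_are_idempotent(self):
        from caacircuit.flow import ClusteringResult

        b = [self.binned([[2, 1], [1, 0]])] * 4
        res = ClusteringResult(1, (0,), np.zeros(4, dtype=int), 0.0, 0.0)
        (mask,) = build_masks(res, b)
        assert np.allclose(mask.grid, b[0].grid)

    def test_unnormalized_members_rejected(self):
        from caacircuit.flow import ClusteringResult

        b = [BinnedProfile(2, np.ones((2, 2)), ((1.0, 10.0), (1.0, 10.0)), True, False)]
        with pytest.raises(ValueError, match="normalized"):
            build_masks(ClusteringResult(1, (0,), np.zeros(1, dtype=int), 0.0, 0.0), b)


class TestPresencePatterns:
    @pytest.mark.parametrize("pops, expected", [(0, 1), (3, 8), (4, 16)])
    def test_counts(self, pops, expected):
        assert enumerate_presence_patterns(pops) == expected

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            enumerate_presence_patterns(-1)
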