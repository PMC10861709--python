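import numpy as np
import pytest

from rbp.channel_systems import derive_subset, project_to_2d
from rbp.montage_split import (
    DEFAULT_SPLIT_VECTORS,
    DegenerateSplitError,
    IncompatibleChannelSystemError,
    InfeasibleSplitError,
    SplitError,
    SplitVector,
    angular_partition,
    assign_channels,
    generate_montage_split,
    sample_split_vector,
    split_from_json,
    split_to_json,
)


class TestSplitVector:
    def test_elements_below_two_rejected(self):
        with pytest.raises(SplitError):
            SplitVector((3, 1))

    def test_empty_rejected(self):
        with pytest.raises(SplitError):
            SplitVector(())


class TestSampleSplitVector:
    def test_singleton_pool(self, rng):
        pool = [SplitVector((2, 2))]
        assert sample_split_vector(pool, rng) is pool[0]

    def test_empty_pool_rejected(self, rng):
        with pytest.raises(SplitError):
            sample_split_vector([], rng)

    def test_uniform_frequencies(self):
        # 70,000 draws: each of the 7 vectors within 3 binomial SEs of 1/7
        rng = np.random.default_rng(7)
        draws = [sample_split_vector(DEFAULT_SPLIT_VECTORS, rng) for _ in range(70_000)]
        p = 1.0 / 7.0
        se = np.sqrt(p * (1 - p) / 70_000)
        for v in DEFAULT_SPLIT_VECTORS:
            freq = sum(d is v for d in draws) / 70_000
            assert abs(freq - p) < 3 * se

    def test_same_seed_same_sequence(self):
        seq1 = [
            sample_split_vector(DEFAULT_SPLIT_VECTORS, np.random.default_rng(3))
            for _ in range(1)
        ]
        a = np.random.default_rng(42)
        b = np.random.default_rng(42)
        for _ in range(20):
            assert sample_split_vector(DEFAULT_SPLIT_VECTORS, a) is sample_split_vector(
                DEFAULT_SPLIT_VECTORS, b
            )


class TestAngularPartition:
    def test_compass_points_balanced(self, rng):
        pts = {
            "N": np.array([0.0, 1.0]),
            "E": np.array([1.0, 0.0]),
            "S": np.array([0.0, -1.0]),
            "W": np.array([-1.0, 0.0]),
        }
        _, groups = angular_partition(pts, 2, rng)
        assert sorted(len(g) for g in groups) == [2, 2]

    def test_group_sizes_near_equal(self, rng):
        pts = {f"p{i}": rng.normal(size=2) for i in range(20)}
        _, groups = angular_partition(pts, 3, rng)
        assert sorted(len(g) for g in groups) == [6, 7, 7]

    def test_intervals_tile_the_circle(self, rng):
        pts = {f"p{i}": rng.normal(size=2) for i in range(17)}
        constraints, _ = angular_partition(pts, 4, rng)
        assert constraints[0].lo == 0.0
        assert constraints[-1].hi == 2 * np.pi
        for a, b in zip(constraints[:-1], constraints[1:]):
            assert a.hi == b.lo

    def test_membership_matches_grouping(self, rng):
        pts = {f"p{i}": rng.normal(size=2) for i in range(30)}
        constraints, groups = angular_partition(pts, 5, rng)
        for c, grp in zip(constraints, groups):
            for label in grp:
                assert c.contains(pts[label])

    def test_too_few_points(self, rng):
        pts = {"a": np.array([1.0, 0.0]), "b": np.array([0.0, 1.0])}
        with pytest.raises(InfeasibleSplitError):
            angular_partition(pts, 3, rng)

    def test_coincident_points_degenerate(self, rng):
        pts = {f"p{i}": np.zeros(2) for i in range(5)}
        with pytest.raises(SplitError):
            angular_partition(pts, 2, rng)


class TestGenerateMontageSplit:
    def test_region_count_without_stopping(self, projected_base, projected_32, rng):
        # min_nodes=1 with a dense base: every level splits fully
        for vec in [(5, 3), (3, 3, 3), (2, 2, 2, 2, 2)]:
            split = generate_montage_split(
                projected_base, SplitVector(vec), 1, projected_base, rng
            )
            assert len(split) == int(np.prod(vec))

    def test_figure_example_five_by_three(self, projected_base, rng):
        split = generate_montage_split(
            projected_base, SplitVector((5, 3)), 1, projected_base, rng
        )
        assert len(split) == 15

    def test_partition_disjoint_and_exhaustive(self, projected_base, projected_32, rng):
        split = generate_montage_split(
            projected_base, SplitVector((3, 3, 3)), 1, projected_32, rng
        )
        memberships = np.array(
            [
                [r.contains(projected_base.points[l]) for r in split.regions]
                for l in projected_base.labels
            ]
        )
        assert np.all(memberships.sum(axis=1) == 1)

    def test_stopping_dominates(self, projected_base, projected_32, rng):
        with pytest.raises(DegenerateSplitError):
            generate_montage_split(
                projected_base,
                SplitVector((3, 3)),
                len(projected_32) + 1,
                projected_32,
                rng,
            )

    def test_min_nodes_respected_on_min_resolution(
        self, projected_base, projected_32, rng
    ):
        for seed in range(10):
            split = generate_montage_split(
                projected_base,
                SplitVector((3, 3, 3)),
                2,
                projected_32,
                np.random.default_rng(seed),
            )
            for region in split.regions:
                count = sum(
                    region.contains(projected_32.points[l])
                    for l in projected_32.labels
                )
                assert count >= 2

    def test_balance_at_first_level(self, projected_base, rng):
        split = generate_montage_split(
            projected_base, SplitVector((4,)), 1, projected_base, rng
        )
        counts = sorted(
            sum(r.contains(projected_base.points[l]) for l in projected_base.labels)
            for r in split.regions
        )
        assert max(counts) - min(counts) <= 1

    def test_determinism_and_seed_sensitivity(self, projected_base, projected_32):
        mk = lambda seed: generate_montage_split(
            projected_base,
            SplitVector((3, 3)),
            1,
            projected_32,
            np.random.default_rng(seed),
        )
        assert split_to_json(mk(5)) == split_to_json(mk(5))
        assert split_to_json(mk(5)) != split_to_json(mk(6))

    def test_membership_independent_of_query_set(self, projected_base, projected_32, rng):
        # a point's region depends only on stored geometry
        split = generate_montage_split(
            projected_base, SplitVector((3, 2)), 1, projected_32, rng
        )
        probe = np.array([0.3, -0.2])
        before = split.region_of(probe).id
        # evaluating other points must not change the answer
        for l in projected_base.labels:
            split.region_of(projected_base.points[l])
        assert split.region_of(probe).id == before


class TestAssignChannels:
    def test_base_montage_partition(self, projected_base, projected_32, rng):
        split = generate_montage_split(
            projected_base, SplitVector((3, 3)), 1, projected_32, rng
        )
        assignment = assign_channels(split, projected_base)
        all_idx = sorted(i for idx in assignment.channels.values() for i in idx)
        assert all_idx == list(range(len(projected_base)))
        assert all(len(idx) > 0 for idx in assignment.channels.values())

    def test_min_resolution_always_compatible(
        self, projected_base, projected_32, rng
    ):
        for seed in range(10):
            split = generate_montage_split(
                projected_base,
                SplitVector((3, 3)),
                1,
                projected_32,
                np.random.default_rng(seed),
            )
            assignment = assign_channels(split, projected_32)
            assert all(len(idx) >= 1 for idx in assignment.channels.values())

    def test_sparse_system_incompatible(self, base_system, projected_base, rng):
        split = generate_montage_split(
            projected_base, SplitVector((5, 3)), 1, projected_base, rng
        )
        two = derive_subset(base_system, base_system.labels[:2], "two")
        with pytest.raises(IncompatibleChannelSystemError):
            assign_channels(split, project_to_2d(two))


class TestSerialization:
    def test_json_round_trip_bit_exact(self, projected_base, projected_32, rng):
        split = generate_montage_split(
            projected_base, SplitVector((3, 2, 3)), 1, projected_32, rng
        )
        again = split_from_json(split_to_json(split))
        assert again == split
        # identical membership decisions after the round trip
        for l in projected_base.labels:
            assert (
                again.region_of(projected_base.points[l]).id
                == split.region_of(projected_base.points[l]).id
            )
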