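import itertools

import numpy as np
import pytest

from photoperiod_expr.cluster_heatmap import (
    RelativeMatrix,
    clip_for_display,
    group_profiles,
    ward_cluster,
    zscore_rows,
)
from photoperiod_expr.io_tables import DEFAULT_DESIGN, ExpressionMatrix


def naive_ward_partition(X, K):
    """Reference agglomerative Ward (ward.D2) by exhaustive pairwise scan.

    Maintains the Lance-Williams recurrence on squared Euclidean distances
    explicitly; independent of scipy's nearest-neighbor-chain algorithm.
    """
    n = len(X)
    clusters = {i: [i] for i in range(n)}
    d2 = {
        (i, j): float(np.sum((X[i] - X[j]) ** 2))
        for i, j in itertools.combinations(range(n), 2)
    }

    def dist2(i, j):
        return d2[(i, j) if i < j else (j, i)]

    while len(clusters) > K:
        (i, j) = min(
            itertools.combinations(sorted(clusters), 2),
            key=lambda ij: (dist2(*ij), ij),
        )
        ni, nj = len(clusters[i]), len(clusters[j])
        merged = clusters.pop(i) + clusters.pop(j)
        new = max(max(clusters, default=-1), i, j) + 1
        for k in list(clusters):
            nk = len(clusters[k])
            d2[(k, new) if k < new else (new, k)] = (
                (ni + nk) * dist2(i, k)
                + (nj + nk) * dist2(j, k)
                - nk * dist2(i, j)
            ) / (ni + nj + nk)
        clusters[new] = merged
    return [frozenset(v) for v in clusters.values()]


def rel_from(values, prefix="g"):
    ids = [f"{prefix}{i:03d}" for i in range(len(values))]
    return RelativeMatrix(gene_ids=ids, values=np.asarray(values, float),
                          design=DEFAULT_DESIGN)


class TestZscoreRows:
    def test_hand_computed_three_point_row(self):
        design3 = DEFAULT_DESIGN  # use first 3 labels via a 3-col design
        from photoperiod_expr.io_tables import TimeCourseDesign
        d = TimeCourseDesign(points=DEFAULT_DESIGN.points[:3])
        m = ExpressionMatrix(gene_ids=["g"], values=[[1.0, 2.0, 3.0]], design=d)
        rel, excluded = zscore_rows(m)
        np.testing.assert_allclose(rel.values[0], [-1.0, 0.0, 1.0], atol=1e-12)
        assert excluded == []

    def test_zero_variance_rows_excluded(self, design):
        m = ExpressionMatrix(
            gene_ids=["flat", "var"],
            values=[[4.0] * 7, [1, 2, 3, 4, 5, 6, 7]],
            design=design,
        )
        rel, excluded = zscore_rows(m)
        assert excluded == ["flat"]
        assert rel.gene_ids == ["var"]

    def test_rows_have_mean_zero_sample_sd_one(self, design):
        rng = np.random.default_rng(3)
        m = ExpressionMatrix(
            gene_ids=[f"g{i}" for i in range(50)],
            values=rng.gamma(2.0, 40.0, size=(50, 7)),
            design=design,
        )
        rel, _ = zscore_rows(m)
        assert np.all(np.abs(rel.values.mean(axis=1)) <= 1e-9)
        assert np.all(np.abs(rel.values.std(axis=1, ddof=1) - 1) <= 1e-9)

    def test_idempotent_on_normalized_rows(self, design):
        rng = np.random.default_rng(4)
        m = ExpressionMatrix(
            gene_ids=[f"g{i}" for i in range(10)],
            values=rng.gamma(2.0, 40.0, size=(10, 7)),
            design=design,
        )
        rel, _ = zscore_rows(m)
        # shift into positive range is not allowed by ExpressionMatrix, so
        # re-normalize the raw z-values directly
        mean = rel.values.mean(axis=1, keepdims=True)
        sd = rel.values.std(axis=1, ddof=1, keepdims=True)
        again = (rel.values - mean) / sd
        np.testing.assert_allclose(again, rel.values, atol=1e-12)


class TestClipForDisplay:
    def test_clips_symmetrically(self):
        rel = rel_from([[4.2, -5.0, 0.5, 1.0, -1.0, 2.9, -3.0]])
        out = clip_for_display(rel, bound=3.0)
        np.testing.assert_allclose(
            out[0], [3.0, -3.0, 0.5, 1.0, -1.0, 2.9, -3.0]
        )

    def test_identity_inside_range_and_idempotent(self):
        rng = np.random.default_rng(5)
        rel = rel_from(rng.normal(size=(5, 7)) * 2)
        once = clip_for_display(rel, 3.0)
        inside = np.abs(rel.values) <= 3.0
        np.testing.assert_array_equal(once[inside], rel.values[inside])
        twice = clip_for_display(rel_from(once), 3.0)
        np.testing.assert_array_equal(once, twice)

    def test_clip_is_vacuous_for_seven_point_zscores(self, design):
        # max |z| with sample sd at T=7 is (1-1/7)*sqrt(7) ~ 2.27 < 3
        rng = np.random.default_rng(6)
        m = ExpressionMatrix(
            gene_ids=[f"g{i}" for i in range(200)],
            values=rng.gamma(0.5, 100.0, size=(200, 7)),
            design=design,
        )
        rel, _ = zscore_rows(m)
        assert np.abs(rel.values).max() < 3.0


class TestWardCluster:
    def two_block_instance(self):
        t1 = np.array([1.0, -1, 1, -1, 1, -1, 1])
        t2 = np.array([1.0, 1, 1, -1, -1, -1, 1])  # orthogonal to t1
        X = np.vstack([np.tile(t1, (20, 1)), np.tile(t2, (20, 1))])
        return rel_from(X)

    def test_duplicate_blocks_recovered_and_match_reference(self):
        rel = self.two_block_instance()
        res = ward_cluster(rel, K=2)
        got = {}
        for g, grp in res.group_of.items():
            got.setdefault(grp, set()).add(g)
        expected = {frozenset(rel.gene_ids[:20]), frozenset(rel.gene_ids[20:])}
        assert {frozenset(v) for v in got.values()} == expected
        # independent exhaustive-scan Ward oracle agrees on the partition
        ref = naive_ward_partition(rel.values, 2)
        idx = {g: i for i, g in enumerate(rel.gene_ids)}
        assert {frozenset(idx[g] for g in v) for v in got.values()} == set(ref)

    def test_reference_oracle_agreement_on_random_instance(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(18, 7))
        rel = rel_from(X)
        res = ward_cluster(rel, K=4)
        ref = set(naive_ward_partition(X, 4))
        got = {}
        for i, g in enumerate(rel.gene_ids):
            got.setdefault(res.group_of[g], set()).add(i)
        assert {frozenset(v) for v in got.values()} == ref

    def test_duplicates_merge_at_height_zero_first(self):
        rel = self.two_block_instance()
        Z = ward_cluster(rel, K=2).merge_history
        # 38 zero-height merges collapse the duplicates before anything else
        assert np.allclose(Z[:38, 2], 0.0)
        assert Z[38, 2] > 0

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(7)
        rel = rel_from(rng.normal(size=(40, 7)))
        Z = ward_cluster(rel, K=3).merge_history
        assert np.all(np.diff(Z[:, 2]) >= -1e-12)

    def test_k_equals_g_gives_singletons(self):
        rng = np.random.default_rng(8)
        rel = rel_from(rng.normal(size=(6, 7)))
        res = ward_cluster(rel, K=6)
        assert sorted(res.group_of.values()) == [1, 2, 3, 4, 5, 6]

    def test_k_out_of_range_rejected(self):
        rel = rel_from(np.random.default_rng(9).normal(size=(4, 7)))
        with pytest.raises(ValueError):
            ward_cluster(rel, K=5)

    def test_group_labels_follow_leaf_order(self):
        rng = np.random.default_rng(10)
        rel = rel_from(rng.normal(size=(25, 7)))
        res = ward_cluster(rel, K=5)
        seen = []
        for g in res.leaf_order:
            grp = res.group_of[g]
            if grp not in seen:
                seen.append(grp)
        assert seen == [1, 2, 3, 4, 5]

    def test_partition_stable_under_row_permutation(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(30, 7))
        ids = [f"g{i:03d}" for i in range(30)]
        rel1 = RelativeMatrix(gene_ids=ids, values=X, design=DEFAULT_DESIGN)
        perm = rng.permutation(30)
        rel2 = RelativeMatrix(
            gene_ids=[ids[i] for i in perm], values=X[perm],
            design=DEFAULT_DESIGN,
        )
        p1 = {}
        for g, grp in ward_cluster(rel1, 4).group_of.items():
            p1.setdefault(grp, set()).add(g)
        p2 = {}
        for g, grp in ward_cluster(rel2, 4).group_of.items():
            p2.setdefault(grp, set()).add(g)
        assert {frozenset(v) for v in p1.values()} == {
            frozenset(v) for v in p2.values()
        }

    def test_within_cluster_ss_non_increasing_in_k(self):
        rng = np.random.default_rng(13)
        rel = rel_from(rng.normal(size=(30, 7)))

        def wss(K):
            res = ward_cluster(rel, K)
            total = 0.0
            for grp in set(res.group_of.values()):
                rows = rel.values[
                    [i for i, g in enumerate(rel.gene_ids)
                     if res.group_of[g] == grp]
                ]
                total += np.sum((rows - rows.mean(axis=0)) ** 2)
            return total

        values = [wss(K) for K in range(1, 8)]
        assert all(a >= b - 1e-9 for a, b in zip(values, values[1:]))


class TestWardVariants:
    def test_variant_d_matches_reference_unsquared_recurrence(self):
        # ward.D applies the LW coefficients to unsquared distances; on an
        # instance where d and d2 orderings differ the partitions may differ,
        # but both must be valid partitions and deterministic
        rng = np.random.default_rng(14)
        rel = rel_from(rng.normal(size=(20, 7)))
        r1 = ward_cluster(rel, 3, variant="d")
        r2 = ward_cluster(rel, 3, variant="d")
        assert r1.group_of == r2.group_of
        assert np.all(np.diff(r1.merge_history[:, 2]) >= -1e-12)

    def test_unknown_variant_rejected(self):
        rel = rel_from(np.zeros((3, 7)) + np.eye(3, 7))
        with pytest.raises(ValueError, match="variant"):
            ward_cluster(rel, 2, variant="centroid")


class TestGroupProfiles:
    def test_matches_brute_force_means(self):
        rng = np.random.default_rng(15)
        rel = rel_from(rng.normal(size=(30, 7)))
        res = ward_cluster(rel, 4)
        table = group_profiles(rel, res)
        for grp in table.index:
            rows = [
                rel.values[i]
                for i, g in enumerate(rel.gene_ids)
                if res.group_of[g] == grp
            ]
            np.testing.assert_allclose(
                table.loc[grp].to_numpy(), np.mean(rows, axis=0), atol=1e-12
            )

    def test_singleton_and_symmetric_groups(self):
        r = np.array([1.0, -1, 2, -2, 0.5, -0.5, 0])
        rel = rel_from([r, -r, r * 2])
        from photoperiod_expr.cluster_heatmap import ClusterResult
        res = ClusterResult(
            group_of={rel.gene_ids[0]: 1, rel.gene_ids[1]: 1,
                      rel.gene_ids[2]: 2},
            merge_history=np.zeros((0, 4)), leaf_order=rel.gene_ids, K=2,
        )
        table = group_profiles(rel, res)
        np.testing.assert_allclose(table.loc[1].to_numpy(), np.zeros(7),
                                   atol=1e-12)
        np.testing.assert_allclose(table.loc[2].to_numpy(), r * 2, atol=1e-12)
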