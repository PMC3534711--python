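import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from woodfall.community_stats import (
    TagTable,
    anosim,
    bonferroni,
    bray_curtis,
    nmds,
    pairwise_shared_fraction,
    remove_singletons,
    shared_otus,
    taxon_composition,
)
from woodfall.synthetic_data import CommunitySpec, gen_tag_table


def naive_anosim_r(dm: np.ndarray, groups) -> float:
    """Independent plain-loop ANOSIM R for oracle comparisons."""
    n = len(dm)
    pairs, labels = [], []
    for i in range(n):
        for j in range(i + 1, n):
            pairs.append(dm[i, j])
            labels.append(groups[i] == groups[j])
    ranks = rankdata(pairs)
    within = [r for r, w in zip(ranks, labels) if w]
    between = [r for r, w in zip(ranks, labels) if not w]
    M = n * (n - 1) / 2
    return (np.mean(between) - np.mean(within)) / (M / 2)


class TestBrayCurtis:
    def test_identical_rows(self):
        m = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]])
        assert bray_curtis(m).iloc[0, 1] == 0.0

    def test_disjoint_rows(self):
        m = pd.DataFrame([[1.0, 0.0], [0.0, 3.0]])
        assert bray_curtis(m).iloc[0, 1] == 1.0

    def test_hand_value(self):
        m = pd.DataFrame([[0.3, 0.7], [0.5, 0.5]])
        assert bray_curtis(m).iloc[0, 1] == pytest.approx(0.2)

    def test_zero_row_names_sample(self):
        m = pd.DataFrame([[1.0, 1.0], [0.0, 0.0]], index=["good", "empty"])
        with pytest.raises(ValueError, match="empty"):
            bray_curtis(m)

    def test_normalized_identity(self):
        """On rows summing to 1, BC = 1 − Σ min(x, y)."""
        rng = np.random.default_rng(5)
        x = rng.dirichlet(np.ones(8), size=6)
        dm = bray_curtis(pd.DataFrame(x)).values
        for i in range(6):
            for j in range(6):
                expected = 1.0 - np.minimum(x[i], x[j]).sum()
                assert dm[i, j] == pytest.approx(expected, abs=1e-12)

    def test_matrix_properties(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(rng.uniform(0, 10, (5, 7)))
        dm = bray_curtis(m).values
        assert np.allclose(dm, dm.T)
        assert np.allclose(np.diag(dm), 0.0)
        assert np.all((dm >= 0) & (dm <= 1))


class TestNMDS:
    def test_three_equidistant_points(self):
        dm = pd.DataFrame(1.0 - np.eye(3))
        res = nmds(dm, seed=0, n_starts=4)
        d01 = np.linalg.norm(res.coordinates.iloc[0] - res.coordinates.iloc[1])
        d02 = np.linalg.norm(res.coordinates.iloc[0] - res.coordinates.iloc[2])
        d12 = np.linalg.norm(res.coordinates.iloc[1] - res.coordinates.iloc[2])
        assert res.stress < 0.01 or res.degenerate
        if not res.degenerate:
            assert d01 == pytest.approx(d02, rel=0.05)
            assert d01 == pytest.approx(d12, rel=0.05)

    def test_planar_points_low_stress(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 1, (10, 2))
        dm = pd.DataFrame(
            np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        )
        res = nmds(dm, seed=0, n_starts=8)
        assert res.stress < 0.05

    def test_two_clusters_separate(self):
        rng = np.random.default_rng(2)
        x = np.vstack([rng.normal(1, 0.02, (4, 6)), rng.normal(5, 0.02, (4, 6))])
        # disjoint support in half the features makes clusters tight and far
        x[:4, :3] = 0.0
        x[4:, 3:] = 0.0
        dm = bray_curtis(pd.DataFrame(np.abs(x)))
        res = nmds(dm, seed=0, n_starts=8)
        coords = res.coordinates.values
        within = [
            np.linalg.norm(coords[i] - coords[j])
            for g in (range(4), range(4, 8))
            for i, j in itertools.combinations(g, 2)
        ]
        between = [
            np.linalg.norm(coords[i] - coords[j])
            for i in range(4) for j in range(4, 8)
        ]
        assert min(between) > max(within)

    def test_degenerate_matrix_flagged(self):
        dm = pd.DataFrame(0.5 * (1 - np.eye(4)))
        res = nmds(dm, seed=0)
        assert res.degenerate
        assert res.stress == 0.0

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.uniform(0, 5, (6, 10)))
        dm = bray_curtis(m)
        a = nmds(dm, seed=11, n_starts=4)
        b = nmds(dm, seed=11, n_starts=4)
        np.testing.assert_allclose(a.coordinates.values, b.coordinates.values)


class TestAnosim:
    def separated_matrix(self):
        rng = np.random.default_rng(4)
        x = np.vstack([rng.uniform(0, 1, (3, 5)), 100 + rng.uniform(0, 1, (3, 5))])
        return bray_curtis(pd.DataFrame(np.abs(x)))

    def test_perfect_separation_r_is_one(self):
        dm = self.separated_matrix()
        res = anosim(dm, ["a"] * 3 + ["b"] * 3, n_perm=99, seed=0)
        assert res.R == pytest.approx(1.0)

    def test_group_of_one_rejected(self):
        dm = self.separated_matrix()
        with pytest.raises(ValueError, match="size 1"):
            anosim(dm, ["a"] * 5 + ["b"], n_perm=9, seed=0)

    def test_r_in_range(self):
        rng = np.random.default_rng(8)
        dm = bray_curtis(pd.DataFrame(rng.uniform(0, 5, (8, 10))))
        res = anosim(dm, ["a", "b"] * 4, n_perm=99, seed=1)
        assert -1.0 <= res.R <= 1.0

    def test_matches_exhaustive_enumeration(self):
        """Permutation distribution equals brute-force enumeration of all
        label orderings for n = 6 (2 groups of 3)."""
        rng = np.random.default_rng(10)
        dm = bray_curtis(pd.DataFrame(rng.uniform(0.1, 5, (6, 12))))
        groups = np.array(["a", "a", "a", "b", "b", "b"])
        observed = anosim(dm, groups, n_perm=9, seed=0).R
        assert observed == pytest.approx(naive_anosim_r(dm.values, groups))
        # exact p over the 10 distinct partitions (= 720 orderings collapsed)
        exact_rs = [
            naive_anosim_r(dm.values, perm)
            for perm in set(itertools.permutations(groups))
        ]
        assert len(exact_rs) == 20  # C(6,3) labelings; partition pairs coincide
        exact_p = np.mean([r >= observed - 1e-12 for r in exact_rs])
        res = anosim(dm, groups, n_perm=4999, seed=0)
        assert res.p == pytest.approx(exact_p, abs=0.02)

    def test_null_expectation_near_zero(self):
        rng = np.random.default_rng(11)
        rs = []
        for _ in range(100):
            dm = bray_curtis(pd.DataFrame(rng.uniform(0, 5, (8, 10))))
            rs.append(anosim(dm, ["a", "b"] * 4, n_perm=0 + 9, seed=1).R)
        assert abs(np.mean(rs)) < 0.1


class TestBonferroni:
    def test_scaling(self):
        assert bonferroni(0.01, 3) == pytest.approx(0.03)

    def test_cap(self):
        assert bonferroni(0.5, 3) == 1.0

    def test_identity(self):
        assert bonferroni(0.04, 1) == pytest.approx(0.04)

    def test_vector(self):
        out = bonferroni([0.01, 0.5], 3)
        np.testing.assert_allclose(out, [0.03, 1.0])

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            bonferroni(0.1, 0)


class TestRemoveSingletons:
    def test_designed_36_percent(self):
        counts = pd.DataFrame(
            np.vstack([
                np.where(np.arange(100) < 36, 1, 5),
                np.zeros(100, dtype=int),
            ]),
            index=["s1", "s2"],
            columns=[f"o{i}" for i in range(100)],
        )
        filtered, report = remove_singletons(TagTable(counts))
        assert report.removed_fraction == pytest.approx(0.36)
        assert filtered.counts.shape[1] == 64

    def test_no_singletons_identity(self, tiny_tag_table):
        filtered, report = remove_singletons(tiny_tag_table)
        assert report.n_removed == 0
        pd.testing.assert_frame_equal(filtered.counts, tiny_tag_table.counts)

    def test_all_singletons_errors(self):
        counts = pd.DataFrame([[1, 1], [0, 0]], columns=["a", "b"], index=["s1", "s2"])
        with pytest.raises(ValueError, match="singleton"):
            remove_singletons(TagTable(counts))


class TestSharedOtus:
    def test_identical_samples(self):
        counts = pd.DataFrame([[5, 3, 2]] * 3, index=["a", "b", "c"])
        counts.columns = ["o1", "o2", "o3"]
        res = shared_otus(TagTable(counts), n_resample=10, seed=0)
        assert res.shared_pct == 100.0
        assert all(v == 0.0 for v in res.unique_pct.values())

    def test_equal_depth_matches_exhaustive(self, tiny_tag_table):
        """Equal sequencing depths make resampling a no-op, so the result
        must equal the deterministic pooled computation."""
        res = shared_otus(tiny_tag_table, n_resample=5, seed=1)
        # exhaustive: 4 pooled OTUs, otu1+otu4 shared, otu2 unique to s1
        assert res.shared_pct == pytest.approx(50.0)
        assert res.unique_pct["s1"] == pytest.approx(25.0)
        assert res.partial_pct == pytest.approx(25.0)
        shared_seq = (5 + 5 + 5 + 2 + 1 + 1) / tiny_tag_table.counts.values.sum()
        assert res.shared_seq_pct == pytest.approx(100 * shared_seq)
        assert res.shared_seq_pct_full == pytest.approx(100 * shared_seq)

    def test_empty_sample_errors(self):
        counts = pd.DataFrame([[1, 2], [0, 0]], index=["a", "b"], columns=["o1", "o2"])
        with pytest.raises(ValueError, match="empty"):
            shared_otus(TagTable(counts), n_resample=2, seed=0)

    def test_designed_core_recovered(self):
        spec = CommunitySpec(n_samples=3, n_core_otus=18, n_unique_otus_per_sample=27,
                             reads_per_sample=5000)
        table, truth = gen_tag_table(spec, seed=21)
        res = shared_otus(table, n_resample=200, seed=3)
        assert res.shared_pct == pytest.approx(
            100 * truth.designed_shared_fraction, abs=2.0
        )

    def test_seed_invariance_of_mean(self):
        spec = CommunitySpec(reads_per_sample=2000)
        table, _ = gen_tag_table(spec, seed=5)
        a = shared_otus(table, n_resample=300, seed=1).shared_pct
        b = shared_otus(table, n_resample=300, seed=2).shared_pct
        assert a == pytest.approx(b, abs=1.0)

    def test_fraction_bookkeeping_sums_to_100(self):
        spec = CommunitySpec(reads_per_sample=1000)
        table, _ = gen_tag_table(spec, seed=9)
        res = shared_otus(table, n_resample=50, seed=4)
        total = res.shared_pct + res.partial_pct + sum(res.unique_pct.values())
        assert total == pytest.approx(100.0, abs=1e-9)


class TestPairwiseShared:
    def test_disjoint(self):
        counts = pd.DataFrame(
            [[4, 4, 0, 0], [0, 0, 4, 4]], index=["a", "b"],
            columns=["o1", "o2", "o3", "o4"],
        )
        assert pairwise_shared_fraction(TagTable(counts), ("a", "b"), 10, 0) == 0.0

    def test_identical(self):
        counts = pd.DataFrame([[4, 4]] * 2, index=["a", "b"], columns=["o1", "o2"])
        assert pairwise_shared_fraction(TagTable(counts), ("a", "b"), 10, 0) == 100.0

    def test_designed_overlap(self):
        # 23 shared + 77 split-unique OTUs -> 23% of the pooled pair list
        counts = pd.DataFrame(
            0, index=["a", "b"],
            columns=[f"sh{i}" for i in range(23)]
            + [f"ua{i}" for i in range(39)] + [f"ub{i}" for i in range(38)],
        )
        counts.loc["a", [f"sh{i}" for i in range(23)]] = 50
        counts.loc["b", [f"sh{i}" for i in range(23)]] = 50
        counts.loc["a", [f"ua{i}" for i in range(39)]] = 40
        counts.loc["b", [f"ub{i}" for i in range(38)]] = 40
        got = pairwise_shared_fraction(TagTable(counts), ("a", "b"), 100, 7)
        assert got == pytest.approx(100 * 23 / 100, abs=2.0)


class TestTaxonComposition:
    def test_uniform_classes(self, tiny_tag_table):
        rel, ranked = taxon_composition(tiny_tag_table, rank="phylum")
        assert set(rel.columns) >= {"Proteobacteria", "Firmicutes", "Actinobacteria"}
        np.testing.assert_allclose(rel.sum(axis=1), 1.0)

    def test_ranking(self):
        counts = pd.DataFrame([[60, 30, 10]], index=["s"], columns=["a", "b", "c"])
        tax = pd.Series({
            "a": "Bacteria;P1;C1", "b": "Bacteria;P2;C2", "c": "Bacteria;P3;C3",
        })
        rel, ranked = taxon_composition(TagTable(counts, tax), rank="class")
        np.testing.assert_allclose(rel.loc["s", ["C1", "C2", "C3"]], [0.6, 0.3, 0.1])
        assert ranked["s"] == ["C1", "C2", "C3"]

    def test_genus_filter_shrinks_denominator(self, tiny_tag_table):
        rel_all, _ = taxon_composition(tiny_tag_table, rank="genus")
        rel_assigned, _ = taxon_composition(
            tiny_tag_table, rank="genus", assigned_only=True
        )
        assert "unassigned" in rel_all.columns
        assert "unassigned" not in rel_assigned.columns
        np.testing.assert_allclose(rel_assigned.sum(axis=1), 1.0)

    def test_rank_absent_errors(self):
        counts = pd.DataFrame([[1]], index=["s"], columns=["a"])
        tax = pd.Series({"a": "Bacteria"})
        with pytest.raises(ValueError, match="genus"):
            taxon_composition(TagTable(counts, tax), rank="genus")
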