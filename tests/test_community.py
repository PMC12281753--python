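import itertools

import numpy as np
import pandas as pd
import pytest

from nodsource.community import (
    DistanceMatrix,
    bray_curtis,
    family_aggregate,
    nmds_embed,
    observed_richness,
    permanova,
    venn_partition,
)
from nodsource.core_io import ValidationError
from tests.conftest import make_counts, make_meta, make_taxonomy


def bray_oracle(x, y):
    """Naive double-loop Bray-Curtis."""
    num = sum(abs(a - b) for a, b in zip(x, y))
    den = sum(a + b for a, b in zip(x, y))
    return num / den if den else 0.0


class TestRichness:
    def test_per_sample(self):
        ct = make_counts([[0, 1], [1, 5], [5, 0], [0, 0]])
        rich = observed_richness(ct)
        assert rich["s1"] == 2 and rich["s2"] == 2

    def test_all_zero_sample(self):
        ct = make_counts([[0, 1], [0, 2]])
        assert observed_richness(ct)["s1"] == 0

    def test_group_union_counts_distinct_asvs(self):
        meta = make_meta([("s1", "nodule", "P0", 1, 1), ("s2", "nodule", "P0", 1, 2)])
        ct = make_counts([[1, 0], [0, 2], [0, 0]])
        rich = observed_richness(ct, meta, group_by=["treatment", "block"])
        assert rich[("P0", 1)] == 2


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        ct = make_counts([[1, 1], [2, 2]])
        assert bray_curtis(ct).d[0, 1] == 0

    def test_disjoint_supports_one(self):
        ct = make_counts([[3, 0], [0, 5]])
        assert bray_curtis(ct).d[0, 1] == 1

    def test_hand_example_one_third(self):
        ct = make_counts([[1, 3], [2, 2], [3, 1]])
        assert bray_curtis(ct).d[0, 1] == pytest.approx(1 / 3, abs=1e-15)

    def test_all_zero_pair_warns_and_is_zero(self):
        ct = make_counts([[0, 0, 1], [0, 0, 2]])
        with pytest.warns(UserWarning, match="all-zero"):
            d = bray_curtis(ct)
        assert d.d[0, 1] == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mat = rng.integers(0, 40, size=(12, 6))
        mat[0] = 1
        ct = make_counts(mat)
        d = bray_curtis(ct)
        for i, j in itertools.combinations(range(6), 2):
            assert d.d[i, j] == pytest.approx(bray_oracle(mat[:, i], mat[:, j]), abs=1e-12)
        assert (d.d >= 0).all() and (d.d <= 1).all()


class TestNmds:
    def test_equilateral_triangle_perfectly_embeddable(self):
        d = DistanceMatrix(["a", "b", "c"], np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]]))
        res = nmds_embed(d, k=2, n_restarts=5, seed=0)
        assert res.stress == pytest.approx(0, abs=1e-6)

    def test_euclidean_2d_reembeds_with_zero_stress(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 2))
        from scipy.spatial.distance import pdist, squareform

        d = DistanceMatrix([f"s{i}" for i in range(10)], squareform(pdist(pts)))
        res = nmds_embed(d, k=2, n_restarts=5, seed=0)
        assert res.stress < 1e-6

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(2)
        mat = rng.integers(1, 30, size=(15, 8))
        d = bray_curtis(make_counts(mat))
        r1 = nmds_embed(d, seed=7, n_restarts=4)
        r2 = nmds_embed(d, seed=7, n_restarts=4)
        np.testing.assert_array_equal(r1.coordinates, r2.coordinates)
        assert r1.stress == r2.stress

    def test_k_too_large_rejected(self):
        d = DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]]))
        with pytest.raises(ValidationError):
            nmds_embed(d, k=2)


def two_group_distance(within=0.1, between=1.0):
    d = np.full((4, 4), between)
    d[0, 1] = d[1, 0] = within
    d[2, 3] = d[3, 2] = within
    np.fill_diagonal(d, 0)
    meta = pd.DataFrame({"group": ["g1", "g1", "g2", "g2"]}, index=list("abcd"))
    return DistanceMatrix(list("abcd"), d), meta


class TestPermanova:
    def test_worked_example_exact(self):
        d, meta = two_group_distance()
        res = permanova(d, meta, ["group"], n_perm="exhaustive")
        t = res.table
        assert t.loc["Total", "SumOfSqs"] == pytest.approx(1.005)
        assert t.loc["group", "SumOfSqs"] == pytest.approx(0.995)
        assert t.loc["group", "F"] == pytest.approx(199.0)
        assert t.loc["group", "R2"] == pytest.approx(0.995 / 1.005)
        assert t.loc["group", "p"] == pytest.approx(1 / 3)

    def test_single_level_term_rejected(self):
        d, meta = two_group_distance()
        meta["dummy"] = "x"
        with pytest.raises(ValidationError, match="dummy"):
            permanova(d, meta, ["dummy"], n_perm=9)

    def test_df_and_r2_sum_constraints(self):
        rng = np.random.default_rng(3)
        n = 24
        mat = rng.integers(1, 50, size=(40, n))
        ids = [f"s{i}" for i in range(n)]
        d = bray_curtis(make_counts(mat, sample_ids=ids))
        meta = pd.DataFrame(
            {"a": rng.choice(["x", "y", "z"], n), "b": rng.choice(["u", "v"], n)}, index=ids
        )
        res = permanova(d, meta, ["a", "b", "a:b"], n_perm=99, seed=0)
        t = res.table
        terms = ["a", "b", "a:b", "Residual"]
        assert t.loc[terms, "R2"].sum() == pytest.approx(1, abs=1e-9)
        assert t.loc[terms, "Df"].sum() == n - 1

    def test_one_way_f_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as sk_permanova

        rng = np.random.default_rng(4)
        n = 18
        mat = rng.integers(0, 30, size=(25, n)) + rng.integers(0, 2, size=(25, n))
        mat[0] = 1
        ids = [f"s{i}" for i in range(n)]
        d = bray_curtis(make_counts(mat, sample_ids=ids))
        groups = list(rng.choice(["g1", "g2", "g3"], n))
        meta = pd.DataFrame({"group": groups}, index=ids)
        ours = permanova(d, meta, ["group"], n_perm=99, seed=0)
        theirs = sk_permanova(skbio.DistanceMatrix(d.d, ids), groups, permutations=99)
        assert ours.table.loc["group", "F"] == pytest.approx(theirs["test statistic"], rel=1e-10)

    def test_null_p_roughly_uniform(self):
        # no structure: rejection rate at alpha=0.05 near nominal
        rng = np.random.default_rng(5)
        n = 12
        hits = 0
        reps = 200
        for _ in range(reps):
            mat = rng.integers(1, 40, size=(20, n))
            ids = [f"s{i}" for i in range(n)]
            d = bray_curtis(make_counts(mat, sample_ids=ids))
            meta = pd.DataFrame({"g": rng.permutation(["a"] * 6 + ["b"] * 6)}, index=ids)
            res = permanova(d, meta, ["g"], n_perm=99, seed=int(rng.integers(2**31)))
            hits += res.table.loc["g", "p"] <= 0.05
        assert 0.01 <= hits / reps <= 0.10


class TestVennPartition:
    def _meta_two_groups(self):
        return make_meta(
            [("s1", "nodule", "P0", 1, 1), ("s2", "nodule", "BC", 1, 1)]
        )

    def test_two_group_set_algebra(self):
        meta = self._meta_two_groups()
        # P0 has {A,B}, BC has {B,C}
        ct = make_counts([[1, 0], [2, 3], [0, 4]], asv_ids=["A", "B", "C"])
        part = venn_partition(ct, meta)
        assert part.cell("P0") == {"A"}
        assert part.cell("BC") == {"C"}
        assert part.cell("P0", "BC") == {"B"}
        assert part.read_share[("P0", "BC")] == pytest.approx(5 / 10)

    def test_identical_groups_all_shared(self):
        rows = [(f"s{i}", "nodule", trt, 1, 1) for i, trt in enumerate(["P0", "BC", "BCplus", "TSP"])]
        meta = make_meta(rows)
        ct = make_counts(np.ones((3, 4), dtype=int), sample_ids=[r[0] for r in rows])
        part = venn_partition(ct, meta)
        assert part.cell("P0", "BC", "BCplus", "TSP") == {"A1", "A2", "A3"}
        assert part.read_share[("P0", "BC", "BCplus", "TSP")] == pytest.approx(1.0)

    def test_fewer_than_two_groups_rejected(self):
        meta = make_meta([("s1", "nodule", "P0", 1, 1)])
        ct = make_counts([[1]])
        with pytest.raises(ValidationError):
            venn_partition(ct, meta)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bitmask_oracle(self, seed):
        rng = np.random.default_rng(seed)
        trts = ["P0", "BC", "BCplus", "TSP"]
        rows = [(f"s{i}", "nodule", trt, 1, 1) for i, trt in enumerate(trts)]
        meta = make_meta(rows)
        mat = rng.integers(0, 2, size=(30, 4)) * rng.integers(1, 9, size=(30, 4))
        keep = mat.sum(axis=1) > 0
        mat = mat[keep]
        ct = make_counts(mat, sample_ids=[r[0] for r in rows])
        part = venn_partition(ct, meta)
        # oracle: membership bitmask per ASV
        expected = {}
        for i, asv in enumerate(ct.asv_ids):
            key = tuple(t for j, t in enumerate(trts) if mat[i, j] > 0)
            expected.setdefault(key, set()).add(asv)
        assert part.cells == expected
        # partition covers every present ASV exactly once
        union = set().union(*part.cells.values())
        assert union == set(ct.asv_ids)


class TestFamilyAggregate:
    def test_family_sum(self):
        ct = make_counts([[3], [7], [2]])
        tax = make_taxonomy({"A1": "F1", "A2": "F1", "A3": "F2"})
        agg = family_aggregate(ct, tax)
        assert agg.loc["F1", "s1"] == 10 and agg.loc["F2", "s1"] == 2

    def test_absent_family_not_emitted(self):
        ct = make_counts([[3], [0]])
        tax = make_taxonomy({"A1": "F1", "A2": "F2"})
        agg = family_aggregate(ct, tax)
        assert "F2" not in agg.index

    def test_top_n_by_mean_relative_abundance(self):
        ct = make_counts([[5], [3], [1]])
        tax = make_taxonomy({"A1": "F1", "A2": "F2", "A3": "F3"})
        agg = family_aggregate(ct, tax, top_n=2)
        assert set(agg.index) == {"F1", "F2"}

    def test_unassigned_pooled(self):
        ct = make_counts([[1], [2]])
        tax = make_taxonomy({"A1": "unassigned", "A2": "unassigned"})
        agg = family_aggregate(ct, tax)
        assert agg.loc["unassigned", "s1"] == 3
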