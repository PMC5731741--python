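import numpy as np
import pytest

from fgmd import (
    Module,
    ModuleSet,
    TreeCutParams,
    extend_small_modules_with_overlap,
    filter_module_sizes,
    in_module_mean_pcc,
    merge_similar_modules,
    overlap_matrix,
    overlap_ratio,
    read_modules_tsv,
    split_large_module,
    write_modules_tsv,
)
from fgmd.corrnet import CorrelationMatrix, abs_pcc_matrix
from conftest import corr_from_pairs


def mod(name, members, stage="SPE", **kw):
    return Module(name, frozenset(members), stage, **kw)


def mset(mods, stage="SPE"):
    return ModuleSet(tuple(mods), stage)


class TestOverlapRatio:
    @pytest.mark.parametrize(
        "m1,m2,expected",
        [
            ({"A", "B", "C"}, {"B", "C", "D"}, 0.5),
            ({"A", "B"}, {"A", "B"}, 1.0),
            ({"A", "B"}, {"C", "D"}, 0.0),
        ],
    )
    def test_jaccard_values(self, m1, m2, expected):
        assert overlap_ratio(mod("x", m1), mod("y", m2)) == pytest.approx(expected)

    def test_matrix_matches_pairwise_values(self):
        mods = [
            mod("a", {"A", "B", "C"}),
            mod("b", {"B", "C", "D"}),
            mod("c", {"X", "Y"}),
            mod("d", {"A", "X", "Y", "Z"}),
        ]
        om = overlap_matrix(mods)
        assert np.allclose(np.diag(om), 1.0)
        for i, mi in enumerate(mods):
            for j, mj in enumerate(mods):
                if i != j:
                    assert om[i, j] == pytest.approx(overlap_ratio(mi, mj))

    def test_duplicated_modules_all_ones(self):
        mods = [mod(f"m{i}", {"A", "B"}) for i in range(3)]
        assert np.allclose(overlap_matrix(mods), 1.0)

    def test_one_minus_overlap_is_dissimilarity(self):
        mods = [mod("a", {"A", "B"}), mod("b", {"A", "B"}), mod("c", {"C", "D"})]
        d = 1 - overlap_matrix(mods)
        assert d.min() >= 0
        assert d[0, 1] == pytest.approx(0.0)  # identical sets
        assert d[0, 2] == pytest.approx(1.0)


class TestMergeSimilarModules:
    def test_identical_modules_merge_to_one(self):
        spe = mset([mod(f"m{i}", {"A", "B", "C"}) for i in range(12)])
        large = merge_similar_modules(spe, TreeCutParams(1.0, True, 3))
        assert len(large) == 1
        assert large.modules[0].members == {"A", "B", "C"}
        assert large.modules[0].stage == "large"

    def test_two_families_merge_to_family_unions(self, rng):
        # 60 modules per family drawn from two disjoint 30-gene pools
        pools = [[f"A{i}" for i in range(30)], [f"B{i}" for i in range(30)]]
        mods = []
        for f, pool in enumerate(pools):
            for i in range(60):
                drop = rng.choice(30, size=2, replace=False)
                members = frozenset(g for j, g in enumerate(pool) if j not in drop)
                mods.append(mod(f"f{f}m{i}", members))
        spe = mset(mods)
        large = merge_similar_modules(spe, TreeCutParams(1.0, True, 15))
        assert len(large) == 2
        assert {m.members for m in large} == {
            frozenset(pools[0]),
            frozenset(pools[1]),
        }

    def test_single_module_passes_through(self):
        spe = mset([mod("only", {"A", "B"})])
        large = merge_similar_modules(spe, TreeCutParams(1.0, True, 3))
        assert len(large) == 1
        assert "unmerged" in large.modules[0].flags

    def test_gene_union_is_preserved(self, rng):
        mods = [
            mod(f"m{i}", rng.choice([f"g{j}" for j in range(40)], size=8, replace=False))
            for i in range(30)
        ]
        spe = mset(mods)
        large = merge_similar_modules(spe, TreeCutParams(1.0, True, 5))
        assert large.all_genes == spe.all_genes


class TestSplitLargeModule:
    def make_two_block_corr(self, rng, size=20):
        genes = [f"a{i}" for i in range(size)] + [f"b{i}" for i in range(size)]
        f1, f2 = rng.standard_normal((2, 120))
        rows = []
        for i in range(size):
            rows.append(np.sqrt(0.9) * f1 + np.sqrt(0.1) * rng.standard_normal(120))
        for i in range(size):
            rows.append(np.sqrt(0.9) * f2 + np.sqrt(0.1) * rng.standard_normal(120))
        import pandas as pd

        from fgmd import ExpressionMatrix

        expr = ExpressionMatrix(
            pd.DataFrame(rows, index=genes, columns=[f"s{j}" for j in range(120)]),
            "log2_ratio",
        )
        return genes, abs_pcc_matrix(expr)

    def test_two_planted_blocks_recovered(self, rng):
        genes, c = self.make_two_block_corr(rng)
        parent = mod("L1", genes, stage="large")
        out = split_large_module(parent, c, TreeCutParams(1.0, True, 10))
        assert len(out) == 2
        found = {m.members for m in out}
        truth = [frozenset(genes[:20]), frozenset(genes[20:])]
        for t in truth:
            assert max(len(t & f) / len(t | f) for f in found) >= 0.9

    def test_perfectly_correlated_module_stays_whole(self):
        ids = [f"g{i}" for i in range(6)]
        pairs = {(a, b): 1.0 for i, a in enumerate(ids) for b in ids[i + 1 :]}
        c = corr_from_pairs(ids, pairs)
        out = split_large_module(mod("L1", ids, stage="large"), c, TreeCutParams(1.0, True, 3))
        assert len(out) == 1
        assert out.modules[0].members == set(ids)

    def test_small_parent_passed_through_flagged(self, worked_corr3):
        parent = mod("L1", ["g1", "g2"], stage="large")
        out = split_large_module(parent, worked_corr3, TreeCutParams(1.0, True, 50))
        assert len(out) == 1
        assert "unsplit" in out.modules[0].flags

    def test_children_partition_subset_of_parent_disjointly(self, rng):
        genes, c = self.make_two_block_corr(rng)
        parent = mod("L1", genes, stage="large")
        out = split_large_module(parent, c, TreeCutParams(1.0, True, 10))
        seen = set()
        for m in out:
            assert m.members <= parent.members
            assert not (m.members & seen)
            seen |= m.members


class TestOverlapExtension:
    def test_perfect_candidate_added(self):
        ids = ["m1", "m2", "m3", "x"]
        pairs = {(a, b): 0.9 for i, a in enumerate(ids[:3]) for b in ids[i + 1 : 3]}
        pairs.update({("m1", "x"): 1.0, ("m2", "x"): 1.0, ("m3", "x"): 1.0})
        c = corr_from_pairs(ids, pairs)
        parent = mod("L1", ids, stage="large")
        small = mset([mod("L1.1", ids[:3], stage="FGMD")], "FGMD")
        out = extend_small_modules_with_overlap(small, parent, c)
        assert out.modules[0].members == set(ids)

    def test_uncorrelated_candidates_not_added(self):
        ids = ["m1", "m2", "m3", "x", "y"]
        pairs = {(a, b): 0.9 for i, a in enumerate(ids[:3]) for b in ids[i + 1 : 3]}
        for g in ("x", "y"):
            for m in ("m1", "m2", "m3"):
                pairs[tuple(sorted((m, g)))] = 0.01
        pairs[("x", "y")] = 0.01
        c = corr_from_pairs(ids, pairs)
        parent = mod("L1", ids, stage="large")
        small = mset([mod("L1.1", ids[:3], stage="FGMD")], "FGMD")
        out = extend_small_modules_with_overlap(small, parent, c)
        assert out.modules[0].members == set(ids[:3])

    def test_exactly_one_gene_added(self):
        members = [f"m{i}" for i in range(5)]
        ids = members + ["good", "bad"]
        pairs = {(a, b): 0.9 for i, a in enumerate(members) for b in members[i + 1 :]}
        for m in members:
            pairs[tuple(sorted((m, "good")))] = 0.95
            pairs[tuple(sorted((m, "bad")))] = 0.3
        pairs[("bad", "good")] = 0.3
        c = corr_from_pairs(ids, pairs)
        parent = mod("L1", ids, stage="large")
        small = mset([mod("L1.1", members, stage="FGMD")], "FGMD")
        out = extend_small_modules_with_overlap(small, parent, c)
        assert out.modules[0].members == set(members) | {"good"}

    def test_mean_pcc_never_decreases(self, rng):
        n = 30
        x = rng.normal(size=(n, 15))
        a = np.abs(np.corrcoef(x))
        np.fill_diagonal(a, 1.0)
        c = CorrelationMatrix(tuple(f"g{i}" for i in range(n)), (a + a.T) / 2)
        parent = mod("L1", [f"g{i}" for i in range(n)], stage="large")
        small = mset([mod("L1.1", [f"g{i}" for i in range(6)], stage="FGMD")], "FGMD")
        before = in_module_mean_pcc(small.modules[0], c)
        out = extend_small_modules_with_overlap(small, parent, c)
        assert in_module_mean_pcc(out.modules[0], c) >= before - 1e-12

    def test_module_outside_parent_rejected(self, worked_corr3):
        parent = mod("L1", ["g1", "g2"], stage="large")
        small = mset([mod("L1.1", ["g1", "g3"], stage="FGMD")], "FGMD")
        with pytest.raises(ValueError, match="not contained"):
            extend_small_modules_with_overlap(small, parent, worked_corr3)


class TestSizeFilter:
    def test_boundary_semantics(self):
        sizes = {5: None, 10: None, 300: None, 301: None}
        mods = [
            mod(f"m{s}", {f"g{s}_{i}" for i in range(s)}, stage="FGMD")
            for s in sizes
        ]
        out = filter_module_sizes(mset(mods, "FGMD"), 10, 300)
        assert sorted(m.size for m in out) == [10, 300]

    def test_empty_and_identity(self):
        empty = mset([], "FGMD")
        assert len(filter_module_sizes(empty, 10, 300)) == 0
        ms = mset([mod("a", {"x", "y"}, stage="FGMD")], "FGMD")
        assert filter_module_sizes(ms, 2, 10).modules == ms.modules


def test_module_tsv_round_trip(tmp_path):
    ms = mset(
        [mod("L1.1", {"B", "A"}, stage="FGMD"), mod("L1.2", {"C", "D", "E"}, stage="FGMD")],
        "FGMD",
    )
    p = tmp_path / "mods.tsv"
    write_modules_tsv(ms, p)
    back = read_modules_tsv(p)
    assert {m.name: m.members for m in back} == {m.name: m.members for m in ms}
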