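import itertools

import numpy as np
import pytest

from fgmd import (
    CorrelationMatrix,
    GeneSetCollection,
    Module,
    ModuleSet,
    bh_adjust,
    bonferroni_adjust,
    gene_list_ratio,
    hypergeom_enrichment,
    in_module_mean_pcc,
    module_summary,
    permutation_battery,
    permutation_test,
)
from conftest import corr_from_pairs
from _reference import bh_step_up, hypergeom_upper_tail


def mod(name, members, stage="FGMD"):
    return Module(name, frozenset(members), stage)


def mset(mods):
    return ModuleSet(tuple(mods), "FGMD")


def noise_corr(rng, n, n_samples=30):
    x = rng.normal(size=(n, n_samples))
    a = np.abs(np.corrcoef(x))
    np.fill_diagonal(a, 1.0)
    return CorrelationMatrix(tuple(f"g{i:03d}" for i in range(n)), (a + a.T) / 2)


class TestInModuleMean:
    def test_identical_genes(self):
        ids = ["a", "b", "c"]
        pairs = {(x, y): 1.0 for i, x in enumerate(ids) for y in ids[i + 1 :]}
        c = corr_from_pairs(ids, pairs)
        assert in_module_mean_pcc(mod("m", ids), c) == pytest.approx(1.0)

    def test_three_gene_mean(self, worked_corr3):
        assert in_module_mean_pcc(mod("m", ["g1", "g2", "g3"]), worked_corr3) == pytest.approx(0.4)

    def test_two_gene_module_is_single_pair(self, worked_corr3):
        assert in_module_mean_pcc(mod("m", ["g1", "g3"]), worked_corr3) == pytest.approx(0.4)


class TestPermutationTest:
    def test_planted_perfect_module_p_zero(self, rng):
        c0 = noise_corr(rng, 100)
        a = c0.a.copy()
        block = list(range(8))
        for i, j in itertools.combinations(block, 2):
            a[i, j] = a[j, i] = 0.995
        c = CorrelationMatrix(c0.ids, a)
        m = mod("planted", [c.ids[i] for i in block])
        res = permutation_test(m, c, N=1000, seed=11)
        assert res.p == 0.0
        assert res.module_avg == pytest.approx(0.995)

    def test_module_below_every_random_gives_p_one(self, rng):
        # module members mutually uncorrelated inside an otherwise
        # perfectly correlated universe: every random draw beats it
        n = 30
        ids = [f"g{i:02d}" for i in range(n)]
        a = np.ones((n, n))
        for i, j in itertools.combinations(range(6), 2):
            a[i, j] = a[j, i] = 0.0
        c = CorrelationMatrix(tuple(ids), a)
        res = permutation_test(mod("weak", ids[:6]), c, N=200, seed=3)
        assert res.p == 1.0

    def test_bonferroni_across_battery(self, rng):
        c = noise_corr(rng, 60)
        ms = mset([mod(f"m{i}", [c.ids[3 * i], c.ids[3 * i + 1], c.ids[3 * i + 2]]) for i in range(4)])
        results = permutation_battery(ms, c, N=100, seed=5)
        for r in results:
            assert r.q == pytest.approx(min(1.0, r.p * 4))
            assert r.q >= r.p

    def test_seed_required(self, rng):
        c = noise_corr(rng, 20)
        with pytest.raises(ValueError, match="seed"):
            permutation_test(mod("m", [c.ids[0], c.ids[1]]), c, N=10)

    def test_null_modules_give_roughly_uniform_p(self, rng):
        # modules drawn the same way as the permutation null: the mean
        # p-value over replicates must sit near 1/2
        c = noise_corr(rng, 120)
        ps = []
        for _ in range(200):
            genes = rng.choice(c.ids, size=6, replace=False)
            res = permutation_test(mod("r", genes), c, N=50, rng=rng)
            ps.append(res.p)
        assert 0.40 <= float(np.mean(ps)) <= 0.60


class TestHypergeomEnrichment:
    def test_exhaustive_oracle_small_universes(self, rng):
        for _ in range(25):
            universe = int(rng.integers(8, 31))
            term = int(rng.integers(1, universe + 1))
            draws = int(rng.integers(2, universe + 1))
            ids = [f"g{i}" for i in range(universe)]
            term_genes = set(rng.choice(ids, size=term, replace=False))
            module_genes = set(rng.choice(ids, size=draws, replace=False))
            coll = GeneSetCollection({"t": frozenset(term_genes)}, "toy")
            res = hypergeom_enrichment(
                mset([mod("m", module_genes)]), coll, universe_size=universe
            )[0]
            expected = hypergeom_upper_tail(
                len(module_genes & term_genes), universe, term, draws
            )
            assert res.p == pytest.approx(expected, abs=1e-12)

    def test_full_overlap_closed_form(self):
        import math

        ids = [f"g{i}" for i in range(100)]
        coll = GeneSetCollection({"t": frozenset(ids[:5])}, "toy")
        res = hypergeom_enrichment(mset([mod("m", ids[:5])]), coll, universe_size=100)[0]
        assert res.p == pytest.approx(1 / math.comb(100, 5), rel=1e-9)

    def test_zero_overlap_and_module_equals_universe(self):
        ids = [f"g{i}" for i in range(20)]
        coll = GeneSetCollection({"t": frozenset(ids[:4])}, "toy")
        none = hypergeom_enrichment(mset([mod("m", ids[10:14])]), coll, 20)[0]
        assert none.p == pytest.approx(1.0)
        full = hypergeom_enrichment(mset([mod("m", ids)]), coll, 20)[0]
        assert full.overlap == 4
        assert full.p == pytest.approx(1.0)

    def test_bh_applied_per_module(self, rng):
        ids = [f"g{i}" for i in range(50)]
        sets = {f"t{j}": frozenset(rng.choice(ids, size=8, replace=False)) for j in range(6)}
        coll = GeneSetCollection(sets, "toy")
        ms = mset([mod("m1", ids[:10]), mod("m2", ids[20:30])])
        res = hypergeom_enrichment(ms, coll, 50)
        for name in ("m1", "m2"):
            chunk = [r for r in res if r.module == name]
            assert [r.q for r in chunk] == pytest.approx(bh_step_up([r.p for r in chunk]))


class TestPvalueAdjustment:
    def test_bh_step_up_worked_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_bh_trivials(self):
        assert bh_adjust([0.2]) == [pytest.approx(0.2)]
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_bh_matches_reference_on_random_inputs(self, rng):
        p = rng.uniform(size=25).tolist()
        assert bh_adjust(p) == pytest.approx(bh_step_up(p))

    def test_bh_monotone_and_idempotent_on_adjusted(self, rng):
        p = sorted(rng.uniform(size=15).tolist())
        q = bh_adjust(p)
        assert all(b >= a - 1e-12 for a, b in zip(q, q[1:]))
        assert all(qi >= pi for pi, qi in zip(p, q))

    def test_bonferroni(self):
        assert bonferroni_adjust([0.01, 0.4]) == pytest.approx([0.02, 0.8])
        assert bonferroni_adjust([0.9, 0.9]) == pytest.approx([1.0, 1.0])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bonferroni_adjust([-0.1])


class TestGeneListRatio:
    def test_list_covering_everything(self):
        ms = mset([mod("a", {"A", "B"}), mod("b", {"B", "C"})])
        gl = {"A", "B", "C", "D"}
        assert gene_list_ratio(ms, gl, "pooled") == 1.0
        assert gene_list_ratio(ms, gl, "unique") == 1.0

    def test_enumerated_modes(self):
        ms = mset([mod("a", {"A", "B"}), mod("b", {"B", "C"})])
        assert gene_list_ratio(ms, {"B"}, "pooled") == pytest.approx(0.5)
        assert gene_list_ratio(ms, {"B"}, "unique") == pytest.approx(1 / 3)

    def test_disjoint_list(self):
        ms = mset([mod("a", {"A", "B"})])
        assert gene_list_ratio(ms, {"Z"}, "pooled") == 0.0


class TestModuleSummary:
    def test_occurrence_enumeration(self, worked_corr3):
        ms = mset([mod("a", {"g1", "g2"}), mod("b", {"g2", "g3"})])
        s = module_summary(ms, worked_corr3)
        assert s.n_unique_genes == 3
        assert s.mean_occurrence == pytest.approx(4 / 3)
        assert s.mean_in_module_pcc == pytest.approx((0.2 + 0.6) / 2)

    def test_single_module(self, worked_corr3):
        s = module_summary(mset([mod("a", {"g1", "g2"})]), worked_corr3)
        assert s.mean_occurrence == 1.0
        assert s.duplication_ratio == 0.0

    def test_identical_modules_duplication(self, worked_corr3):
        ms = mset([mod(f"m{i}", {"g1", "g2"}) for i in range(3)])
        assert module_summary(ms, worked_corr3).duplication_ratio == pytest.approx(2 / 3)
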