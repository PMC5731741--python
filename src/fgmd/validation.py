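"""Module evaluation: coherence permutation test, enrichment, summaries.

A detected module is worth reporting only if its genes are more strongly
co-expressed than a random gene set of the same size (permutation test on
the mean in-module |PCC|, Bonferroni-corrected across modules) and if it is
enriched for known biology (one-sided hypergeometric test per gene set,
Benjamini–Hochberg corrected within a collection).  Ratio statistics against
curated gene lists (e.g. cancer genes) and per-module-set summary tables
complete the battery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .corrnet import CorrelationMatrix
from .expansion import Module
from .merge_split import ModuleSet
from .expression_io import GeneSetCollection

__all__ = [
    "PermutationResult",
    "EnrichmentResult",
    "ModuleSummary",
    "in_module_mean_pcc",
    "permutation_test",
    "permutation_battery",
    "bh_adjust",
    "bonferroni_adjust",
    "hypergeom_enrichment",
    "gene_list_ratio",
    "module_summary",
]


@dataclass(frozen=True)
class PermutationResult:
    module: str
    module_avg: float
    N: int
    p: float
    q: float  # Bonferroni-corrected across the tested modules


@dataclass(frozen=True)
class EnrichmentResult:
    module: str
    collection: str
    term: str
    overlap: int
    module_size: int
    term_size: int
    universe_size: int
    p: float
    q: float


@dataclass(frozen=True)
class ModuleSummary:
    n_modules: int
    mean_size: float
    n_unique_genes: int
    mean_occurrence: float  # total membership / unique genes
    mean_in_module_pcc: float
    duplication_ratio: float  # (modules - distinct member sets) / modules


def in_module_mean_pcc(m: Module, c: CorrelationMatrix) -> float:
    """Mean |PCC| over unordered member pairs, diagonal excluded."""
    if m.size < 2:
        raise ValueError("in-module mean needs >= 2 members")
    sub = c.submatrix(m.sorted_members())
    k = sub.shape[0]
    return float((sub.sum() - k) / (k * (k - 1)))


def _random_means(
    c: CorrelationMatrix, size: int, N: int, rng: np.random.Generator
) -> np.ndarray:
    means = np.empty(N)
    n = c.n
    denom = size * (size - 1)
    for i in range(N):
        idx = rng.choice(n, size=size, replace=False)
        sub = c.a[np.ix_(idx, idx)]
        means[i] = (sub.sum() - size) / denom
    return means


def permutation_test(
    m: Module,
    c: CorrelationMatrix,
    N: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    n_tested: int = 1,
) -> PermutationResult:
    """Coherence of a module against same-size random gene sets.

    Draws ``N`` random modules of the same size uniformly from the
    correlation universe (without replacement within a draw, independently
    across draws; the tested module's own genes are not excluded) and
    reports ``p = #{random_avg > module_avg} / N``.  ``q`` applies the
    Bonferroni correction for ``n_tested`` modules.
    """
    if m.size >= c.n:
        raise ValueError("module must be smaller than the correlation universe")
    if N < 1:
        raise ValueError("N must be >= 1")
    if rng is None:
        if seed is None:
            raise ValueError("a seed (or a Generator) is required: the test is stochastic")
        rng = np.random.default_rng(seed)
    module_avg = in_module_mean_pcc(m, c)
    rand = _random_means(c, m.size, N, rng)
    p = float((module_avg < rand).sum() / N)
    return PermutationResult(m.name, module_avg, N, p, min(1.0, p * n_tested))


def permutation_battery(
    ms: ModuleSet,
    c: CorrelationMatrix,
    N: int = 1000,
    seed: int | None = None,
) -> list[PermutationResult]:
    """Permutation test for every module, Bonferroni-corrected across them."""
    rng = np.random.default_rng(seed)
    return [
        permutation_test(m, c, N=N, rng=rng, n_tested=len(ms)) for m in ms
    ]


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return []
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return [float(q) for q in multipletests(p, method="fdr_bh")[1]]


def bonferroni_adjust(pvals: Sequence[float]) -> list[float]:
    """Bonferroni adjusted p-values: min(1, p * m)."""
    p = np.asarray(pvals, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return [float(min(1.0, x * p.size)) for x in p]


def hypergeom_enrichment(
    ms: ModuleSet,
    sets: GeneSetCollection,
    universe_size: int,
    universe: Iterable[str] | None = None,
    bh_scope: str = "per_module",
) -> list[EnrichmentResult]:
    """One-sided hypergeometric enrichment of every module in every gene set.

    For a module of size n, a term with K members in the universe of size
    ``universe_size`` and an observed overlap x, the p-value is
    P(X >= x) for X ~ Hypergeometric(universe_size, K, n).  Terms are
    BH-adjusted either across the terms tested for each module
    (``bh_scope="per_module"``, the default) or across the whole
    module × term family (``"global"``).  If ``universe`` is given, term and
    module members are first restricted to it.
    """
    if bh_scope not in ("per_module", "global"):
        raise ValueError(f"unknown bh_scope {bh_scope!r}")
    uni = frozenset(universe) if universe is not None else None
    results: list[EnrichmentResult] = []
    for m in ms:
        members = m.members if uni is None else m.members & uni
        if universe_size < len(members):
            raise ValueError(
                f"module {m.name!r} is larger than the stated universe"
            )
        for term, term_members in sets.sets.items():
            tm = term_members if uni is None else term_members & uni
            if universe_size < len(tm):
                raise ValueError(f"term {term!r} is larger than the stated universe")
            overlap = len(members & tm)
            p = float(stats.hypergeom.sf(overlap - 1, universe_size, len(tm), len(members)))
            results.append(
                EnrichmentResult(
                    m.name, sets.source_label, term, overlap, len(members),
                    len(tm), universe_size, min(1.0, p), np.nan,
                )
            )
    if not results:
        return results
    if bh_scope == "per_module":
        adjusted: list[EnrichmentResult] = []
        for m in ms:
            chunk = [r for r in results if r.module == m.name]
            qs = bh_adjust([r.p for r in chunk])
            adjusted.extend(
                EnrichmentResult(**{**r.__dict__, "q": q}) for r, q in zip(chunk, qs)
            )
        results = adjusted
    else:
        qs = bh_adjust([r.p for r in results])
        results = [
            EnrichmentResult(**{**r.__dict__, "q": q}) for r, q in zip(results, qs)
        ]
    return results


def enriched_module_ratio(results: list[EnrichmentResult], ms: ModuleSet, alpha: float = 0.05) -> float:
    """Fraction of modules with at least one term at q < alpha."""
    hit = {r.module for r in results if r.q < alpha}
    return len(hit & {m.name for m in ms}) / len(ms)


def gene_list_ratio(ms: ModuleSet, gene_list: Iterable[str], mode: str = "pooled") -> float:
    """Fraction of module gene occurrences (or unique genes) on a gene list.

    ``pooled`` counts every membership: sum over modules of the in-list
    member count, divided by the summed module sizes.  ``unique`` deduplicates
    first: |union ∩ list| / |union|.
    """
    gl = frozenset(gene_list)
    if not gl:
        raise ValueError("gene list is empty")
    if len(ms) == 0:
        raise ValueError("module set is empty")
    if mode == "pooled":
        hits = sum(len(m.members & gl) for m in ms)
        total = sum(m.size for m in ms)
        return hits / total
    if mode == "unique":
        union = ms.all_genes
        return len(union & gl) / len(union)
    raise ValueError(f"unknown mode {mode!r}")


def module_summary(ms: ModuleSet, c: CorrelationMatrix) -> ModuleSummary:
    """Headline statistics of a module set (count, sizes, overlap, coherence).

    ``duplication_ratio`` is (module count − number of distinct member
    sets) / module count: 0 when all modules differ, approaching 1 when many
    are copies.
    """
    if len(ms) == 0:
        raise ValueError("empty module set")
    sizes = [m.size for m in ms]
    union = ms.all_genes
    distinct = len({m.members for m in ms})
    return ModuleSummary(
        n_modules=len(ms),
        mean_size=float(np.mean(sizes)),
        n_unique_genes=len(union),
        mean_occurrence=float(sum(sizes) / len(union)),
        mean_in_module_pcc=float(np.mean([in_module_mean_pcc(m, c) for m in ms])),
        duplication_ratio=(len(ms) - distinct) / len(ms),
    )
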