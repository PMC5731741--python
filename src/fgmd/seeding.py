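"""Seed gene-pair extraction (pipeline step 1).

Seed pairs are the unordered gene pairs in the top *S*% of absolute-PCC
values (default S = 0.005, i.e. the top 0.005% of all pairs).  In the
network formed by those pairs, genes connected to too few partners would
only ever produce tiny modules, while hub genes connected to very many
partners would spawn a crowd of near-identical modules; both are filtered
out by a degree window [D_min, D_max], where D_max is the realized degree at
the top-0.1% rank of the degree distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import math

import numpy as np

from .corrnet import CorrelationMatrix, top_quantile_threshold

__all__ = ["SeedParams", "SeedNetwork", "extract_seed_pairs"]


@dataclass(frozen=True)
class SeedParams:
    S: float = 0.005  # top percent of pairs kept as seed candidates
    D_min: int = 5
    D_max_percent: float = 0.1  # top percent of genes defining the degree cap
    rank_over: str = "active"  # "active": genes with candidate degree > 0; "all"
    iterative: bool = False  # re-evaluate degrees after each removal pass


@dataclass(frozen=True)
class SeedNetwork:
    """Degree-filtered seed pairs with bookkeeping of the realized thresholds."""

    pairs: frozenset[tuple[str, str]]  # each pair sorted lexicographically
    degrees: Mapping[str, int]  # recounted over the retained pairs
    seed_threshold: float
    d_max: int
    params: SeedParams
    n_candidate_pairs: int = 0

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for p in self.pairs for g in p)

    def to_tsv(self, c: CorrelationMatrix, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write(
                f"# seed_threshold={self.seed_threshold!r}\tS={self.params.S!r}"
                f"\tD_min={self.params.D_min}\tD_max={self.d_max}\n"
            )
            fh.write("geneA\tgeneB\tabs_pcc\n")
            for ga, gb in sorted(self.pairs):
                fh.write(f"{ga}\t{gb}\t{c.a[c.index_of(ga), c.index_of(gb)]!r}\n")


def _degree_cap(degrees: np.ndarray, d_max_percent: float, rank_over: str) -> int:
    """Degree value at the top-``d_max_percent``% rank of the degree ordering."""
    if rank_over == "active":
        ranked = np.sort(degrees[degrees > 0])[::-1]
    elif rank_over == "all":
        ranked = np.sort(degrees)[::-1]
    else:
        raise ValueError(f"unknown rank_over {rank_over!r}")
    if ranked.size == 0:
        return 0
    rank = max(1, int(math.ceil(ranked.size * d_max_percent / 100.0)))
    return int(ranked[min(rank, ranked.size) - 1])


def extract_seed_pairs(
    c: CorrelationMatrix, params: SeedParams = SeedParams()
) -> SeedNetwork:
    """Extract the degree-filtered seed gene pairs from a correlation matrix.

    1. Candidate pairs are the off-diagonal pairs with |PCC| >= the
       top-``S``% quantile threshold (ties at the threshold all included).
    2. Gene degrees are counted in this candidate network; the cap D_max is
       the realized degree at rank ceil(n_ranked * D_max_percent / 100) of
       the decreasing degree ordering (genes tied with that degree survive).
    3. Genes with degree < D_min or > D_max are removed with their incident
       pairs; the filter is evaluated once on the original candidate degrees
       (a partner gene survives if its own original degree was in bounds).
       With ``params.iterative`` the degree filter is instead repeated on
       the surviving network until it stabilises.

    An empty result is returned as an empty network, not an error.
    """
    if not (0 < params.S <= 100):
        raise ValueError("S must be in (0, 100]")
    t = top_quantile_threshold(c, params.S)
    iu, ju = np.triu_indices(c.n, k=1)
    above = c.a[iu, ju] >= t
    pi, pj = iu[above], ju[above]
    n_candidates = int(pi.size)

    def filter_once(pi: np.ndarray, pj: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
        deg = np.bincount(np.concatenate([pi, pj]), minlength=c.n)
        cap = _degree_cap(deg, params.D_max_percent, params.rank_over)
        ok = (deg >= params.D_min) & (deg <= cap)
        keep = ok[pi] & ok[pj]
        return pi[keep], pj[keep], cap

    pi2, pj2, cap = filter_once(pi, pj)
    if params.iterative:
        while True:
            nxt_i, nxt_j, cap = filter_once(pi2, pj2)
            if nxt_i.size == pi2.size:
                break
            pi2, pj2 = nxt_i, nxt_j

    pairs = frozenset(
        tuple(sorted((c.ids[i], c.ids[j]))) for i, j in zip(pi2.tolist(), pj2.tolist())
    )
    degrees: dict[str, int] = {}
    for ga, gb in pairs:
        degrees[ga] = degrees.get(ga, 0) + 1
        degrees[gb] = degrees.get(gb, 0) + 1
    return SeedNetwork(
        pairs=pairs,
        degrees=degrees,
        seed_threshold=t,
        d_max=cap,
        params=params,
        n_candidate_pairs=n_candidates,
    )
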