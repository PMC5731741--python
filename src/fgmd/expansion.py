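"""Greedy seed-pair expansion into SPE modules (pipeline step 2).

Each seed pair is grown into a "seed gene pair expansion" (SPE) module: at
every iteration, each outside gene's similarity to the module is its minimum
absolute correlation to the current members (P_min); genes whose P_min
strictly exceeds the module threshold M (the top-1% pair quantile value) and
that pass the hub-degree cap are eligible, and the k of them with the
largest P_min join simultaneously.  Expansion stops when no gene is
eligible.  Because every seed pair is expanded independently, one gene can
end up in many SPE modules — overlap is intended, not an artefact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .corrnet import CorrelationMatrix
from .seeding import SeedNetwork

__all__ = [
    "Module",
    "ExpansionParams",
    "compute_degree_cap_exclusions",
    "candidate_pmin",
    "expand_seed_pair",
    "expand_all_seed_pairs",
]


@dataclass(frozen=True)
class Module:
    """A named gene set with a pipeline-stage tag.

    ``stage`` is one of ``"SPE"`` (seed-pair expansion), ``"large"`` (merged
    union of overlapping SPE modules) or ``"FGMD"`` (final split module).
    ``provenance`` records the originating seed pair or parent module name;
    ``flags`` carries processing annotations such as ``"unmerged"`` or
    ``"unsplit"``.
    """

    name: str
    members: frozenset[str]
    stage: str
    provenance: str = ""
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError(f"module {self.name!r} needs >= 2 members")
        if self.stage not in ("SPE", "large", "FGMD"):
            raise ValueError(f"unknown stage {self.stage!r}")

    @property
    def size(self) -> int:
        return len(self.members)

    def sorted_members(self) -> list[str]:
        return sorted(self.members)


@dataclass(frozen=True)
class ExpansionParams:
    """Parameters of the greedy expansion.

    ``M`` is the module threshold as a correlation value in [0, 1] (the
    realized top-1% quantile, not the percent); ``k`` is the number of genes
    admitted per iteration; ``max_iterations`` bounds pathological runs.
    """

    M: float
    k: int = 10
    max_iterations: int = 1000

    def __post_init__(self) -> None:
        if not (0 <= self.M <= 1):
            raise ValueError("M must be a correlation value in [0, 1]")
        if self.k < 1:
            raise ValueError("k must be >= 1")


def compute_degree_cap_exclusions(
    c: CorrelationMatrix, M: float, d_max_percent: float = 0.1
) -> frozenset[str]:
    """Genes excluded from candidacy by the hub-degree cap.

    Degrees are counted in the M-thresholded correlation graph (edges where
    a_ij >= M, diagonal excluded).  The cap is the realized degree at rank
    ceil(n_active * d_max_percent / 100) of the decreasing degree ordering
    over genes with non-zero degree; genes whose degree strictly exceeds the
    cap are excluded — admitting such promiscuous hubs everywhere would make
    every module look alike.  Genes tied with the cap degree survive.
    """
    adj = c.a >= M
    np.fill_diagonal(adj, False)
    deg = adj.sum(axis=1)
    active = np.sort(deg[deg > 0])[::-1]
    if active.size == 0:
        return frozenset()
    import math

    rank = max(1, int(math.ceil(active.size * d_max_percent / 100.0)))
    cap = int(active[min(rank, active.size) - 1])
    return frozenset(c.ids[i] for i in np.flatnonzero(deg > cap))


def candidate_pmin(c: CorrelationMatrix, module: Module, gene: str) -> float:
    """Minimum absolute correlation of ``gene`` to the current members."""
    if gene in module.members:
        raise ValueError(f"{gene!r} is already a member of {module.name!r}")
    gi = c.index_of(gene)
    idx = [c.index_of(m) for m in module.members]
    return float(c.a[gi, idx].min())


def expand_seed_pair(
    pair: tuple[str, str],
    c: CorrelationMatrix,
    params: ExpansionParams,
    excluded: frozenset[str] = frozenset(),
    name: str | None = None,
) -> Module:
    """Grow one seed pair into an SPE module by greedy min-PCC expansion.

    Maintains for every outside gene its minimum correlation to the members
    (updated incrementally as genes join).  Per iteration, all genes with
    P_min > M that are not excluded are ranked by P_min and the top ``k``
    join; genes exactly tied with the k-th P_min are all admitted so the
    result cannot depend on an arbitrary ordering of equal candidates.  A
    pair with no eligible genes yields the bare two-member module.
    """
    ga, gb = pair
    ia, ib = c.index_of(ga), c.index_of(gb)
    n = c.n
    member_mask = np.zeros(n, dtype=bool)
    member_mask[[ia, ib]] = True
    blocked = member_mask.copy()
    for g in excluded:
        blocked[c.index_of(g)] = True
    # pmin[g] = min over current members of a[g, m]
    pmin = np.minimum(c.a[:, ia], c.a[:, ib])
    for _ in range(params.max_iterations):
        eligible = np.flatnonzero((~blocked) & (pmin > params.M))
        if eligible.size == 0:
            break
        if eligible.size > params.k:
            vals = pmin[eligible]
            kth = np.sort(vals)[::-1][params.k - 1]
            chosen = eligible[vals >= kth]  # admit ties with the k-th value
        else:
            chosen = eligible
        member_mask[chosen] = True
        blocked[chosen] = True
        pmin = np.minimum(pmin, c.a[:, chosen].min(axis=1))
    else:
        raise RuntimeError(
            f"expansion of seed pair {pair} did not terminate within "
            f"{params.max_iterations} iterations"
        )
    members = frozenset(c.ids[i] for i in np.flatnonzero(member_mask))
    return Module(
        name=name or f"SPE[{ga}|{gb}]",
        members=members,
        stage="SPE",
        provenance=f"{ga}|{gb}",
    )


def expand_all_seed_pairs(
    seeds: SeedNetwork,
    c: CorrelationMatrix,
    params: ExpansionParams,
    d_max_percent: float | None = 0.1,
) -> list[Module]:
    """Expand every seed pair independently, in deterministic pair order.

    ``d_max_percent`` configures the candidate hub-degree cap (``None``
    disables it).  Expansion of each pair is pure, so sequential and any
    parallel execution yield identical modules.
    """
    excluded = (
        compute_degree_cap_exclusions(c, params.M, d_max_percent)
        if d_max_percent is not None
        else frozenset()
    )
    modules = []
    for i, pair in enumerate(sorted(seeds.pairs), start=1):
        modules.append(
            expand_seed_pair(pair, c, params, excluded, name=f"SPE{i:05d}")
        )
    return modules
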