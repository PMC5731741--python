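"""Merging overlapping SPE modules and splitting the merged result.

Step 3 of the pipeline measures the redundancy among SPE modules with the
Jaccard overlap ratio |m1 ∩ m2| / |m1 ∪ m2|, clusters the modules on the
dissimilarity 1 − overlap with average-linkage hierarchical clustering and
an adaptive tree cut, and fuses each cluster into one "large" module (the
union of its member modules' genes).  Step 4 then splits every large module
back into coherent final modules by clustering its genes on 1 − |PCC|.
Final modules from different large modules may share genes; within one
large module they are disjoint, unless the optional overlap-extension pass
re-admits strongly correlated parent genes into each small module.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .corrnet import CorrelationMatrix
from .expansion import Module
from .treecut import Dendrogram, TreeCutParams, dynamic_tree_cut, hierarchical_tree

__all__ = [
    "ModuleSet",
    "overlap_ratio",
    "overlap_matrix",
    "merge_similar_modules",
    "split_large_module",
    "split_all_large_modules",
    "extend_small_modules_with_overlap",
    "filter_module_sizes",
    "write_modules_tsv",
    "read_modules_tsv",
]


@dataclass(frozen=True)
class ModuleSet:
    """An ordered collection of modules sharing a stage tag."""

    modules: tuple[Module, ...]
    stage: str

    def __post_init__(self) -> None:
        names = [m.name for m in self.modules]
        if len(set(names)) != len(names):
            raise ValueError("module names must be unique")
        for m in self.modules:
            if m.stage != self.stage:
                raise ValueError(
                    f"module {m.name!r} has stage {m.stage!r}, set is {self.stage!r}"
                )

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self):
        return iter(self.modules)

    @property
    def all_genes(self) -> frozenset[str]:
        return frozenset(g for m in self.modules for g in m.members)


def overlap_ratio(m1: Module, m2: Module) -> float:
    """Jaccard index of two modules' member sets."""
    if not m1.members or not m2.members:
        raise ValueError("overlap ratio of an empty module is undefined")
    inter = len(m1.members & m2.members)
    union = len(m1.members | m2.members)
    return inter / union


def overlap_matrix(ms: ModuleSet | Sequence[Module]) -> np.ndarray:
    """Symmetric matrix of pairwise Jaccard overlap ratios (unit diagonal)."""
    modules = list(ms)
    if len(modules) < 2:
        raise ValueError("need at least 2 modules")
    genes = sorted({g for m in modules for g in m.members})
    gene_idx = {g: i for i, g in enumerate(genes)}
    B = np.zeros((len(modules), len(genes)), dtype=np.float64)
    for i, m in enumerate(modules):
        for g in m.members:
            B[i, gene_idx[g]] = 1.0
    inter = B @ B.T
    sizes = B.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    out = inter / union
    np.fill_diagonal(out, 1.0)
    return out


def merge_similar_modules(
    spe: ModuleSet,
    p: TreeCutParams,
    linkage_method: str = "average",
) -> ModuleSet:
    """Fuse clusters of mutually overlapping SPE modules into large modules.

    SPE modules are clustered on 1 − Jaccard with hierarchical clustering
    and the adaptive tree cut; each cluster's large module is the union of
    its modules' genes.  SPE modules the cut leaves unassigned each pass
    through as their own large module, flagged ``"unmerged"`` — discarding
    them would silently lose seed coverage.
    """
    modules = list(spe)
    if not modules:
        raise ValueError("empty SPE module set")
    if len(modules) == 1:
        only = modules[0]
        return ModuleSet(
            (
                Module(
                    "L001",
                    only.members,
                    "large",
                    provenance=only.name,
                    flags=("unmerged",),
                ),
            ),
            "large",
        )
    dissim = 1.0 - overlap_matrix(modules)
    tree = hierarchical_tree(dissim, [m.name for m in modules], linkage_method)
    labels = dynamic_tree_cut(tree, p)
    large: list[Module] = []
    for cid in sorted(set(labels) - {0}):
        members = frozenset(
            g for i in np.flatnonzero(labels == cid) for g in modules[i].members
        )
        prov = ",".join(modules[i].name for i in np.flatnonzero(labels == cid))
        large.append(Module(f"L{len(large) + 1:03d}", members, "large", provenance=prov))
    for i in np.flatnonzero(labels == 0):
        large.append(
            Module(
                f"L{len(large) + 1:03d}",
                modules[i].members,
                "large",
                provenance=modules[i].name,
                flags=("unmerged",),
            )
        )
    return ModuleSet(tuple(large), "large")


def split_large_module(
    large: Module,
    c: CorrelationMatrix,
    p: TreeCutParams,
    linkage_method: str = "average",
) -> ModuleSet:
    """Split one large module into final modules by clustering its genes.

    Genes are clustered on the dissimilarity 1 − a_ij (absolute correlation)
    with hierarchical clustering and the adaptive tree cut; each resulting
    cluster becomes a final module.  Genes the cut leaves unassigned are
    dropped — the module-size filter removes fragments anyway.  A large
    module smaller than ``min_module_size`` is passed through unsplit,
    flagged ``"unsplit"``.  Within one large module the result is a disjoint
    partition of (a subset of) the parent's genes.
    """
    genes = large.sorted_members()
    if len(genes) < p.min_module_size:
        return ModuleSet(
            (
                Module(
                    f"{large.name}.1",
                    large.members,
                    "FGMD",
                    provenance=large.name,
                    flags=("unsplit",),
                ),
            ),
            "FGMD",
        )
    dissim = 1.0 - c.submatrix(genes)
    np.fill_diagonal(dissim, 0.0)
    tree = hierarchical_tree(dissim, genes, linkage_method)
    labels = dynamic_tree_cut(tree, p)
    out: list[Module] = []
    for cid in sorted(set(labels) - {0}):
        members = frozenset(genes[i] for i in np.flatnonzero(labels == cid))
        out.append(
            Module(
                f"{large.name}.{len(out) + 1}",
                members,
                "FGMD",
                provenance=large.name,
            )
        )
    if not out:
        # cut produced no cluster of the required size: keep the parent whole
        out.append(
            Module(
                f"{large.name}.1",
                large.members,
                "FGMD",
                provenance=large.name,
                flags=("unsplit",),
            )
        )
    return ModuleSet(tuple(out), "FGMD")


def split_all_large_modules(
    larges: ModuleSet,
    c: CorrelationMatrix,
    p: TreeCutParams,
    linkage_method: str = "average",
    extend_overlap: bool = False,
) -> ModuleSet:
    """Split every large module; optionally run the overlap extension per parent."""
    out: list[Module] = []
    for lm in larges:
        sub = split_large_module(lm, c, p, linkage_method)
        if extend_overlap:
            sub = extend_small_modules_with_overlap(sub, lm, c)
        out.extend(sub.modules)
    return ModuleSet(tuple(out), "FGMD")


def extend_small_modules_with_overlap(
    fgmd_of_one_large: ModuleSet,
    parent: Module,
    c: CorrelationMatrix,
) -> ModuleSet:
    """Let small modules from the same large module overlap again.

    The split partition is disjoint within a parent, which is biologically
    too strict: a gene can belong to several functions.  For each small
    module, parent genes outside it are ranked by their mean correlation to
    the module's members, and the best one is added as long as doing so does
    not decrease the module's mean in-module |PCC| (an added gene whose mean
    correlation equals the current in-module mean leaves it unchanged and is
    still admitted).  Terminates after at most |parent| additions per
    module; the mean in-module correlation never decreases.
    """
    out: list[Module] = []
    for m in fgmd_of_one_large:
        if not m.members <= parent.members:
            raise ValueError(f"module {m.name!r} is not contained in {parent.name!r}")
        members = sorted(m.members)
        outside = sorted(parent.members - m.members)
        if not outside:
            out.append(m)
            continue
        midx = [c.index_of(g) for g in members]
        oidx = [c.index_of(g) for g in outside]
        sub = c.a[np.ix_(midx, midx)]
        k = len(midx)
        pair_sum = float((sub.sum() - k) / 2.0)  # off-diagonal upper triangle sum
        n_pairs = k * (k - 1) // 2
        cand_sum = c.a[np.ix_(oidx, midx)].sum(axis=1)  # per candidate, over members
        alive = np.ones(len(oidx), dtype=bool)
        added: list[str] = []
        while alive.any():
            cur_mean = pair_sum / n_pairs
            means = cand_sum / k
            means_alive = np.where(alive, means, -np.inf)
            best = int(np.argmax(means_alive))
            if means_alive[best] < cur_mean:
                break
            gi = oidx[best]
            added.append(outside[best])
            alive[best] = False
            pair_sum += float(cand_sum[best])
            n_pairs += k
            k += 1
            cand_sum = cand_sum + c.a[oidx, gi]
            midx.append(gi)
        out.append(replace(m, members=m.members | frozenset(added)))
    return ModuleSet(tuple(out), fgmd_of_one_large.stage)


def filter_module_sizes(ms: ModuleSet, min_size: int = 10, max_size: int = 300) -> ModuleSet:
    """Keep modules with min_size <= |members| <= max_size.

    Defaults follow the gene-level convention (10–300); isoform-level module
    sets conventionally use 10–500.
    """
    if min_size > max_size:
        raise ValueError("min_size must be <= max_size")
    kept = tuple(m for m in ms if min_size <= m.size <= max_size)
    return ModuleSet(kept, ms.stage)


def write_modules_tsv(ms: ModuleSet, path: str | Path) -> None:
    """Export modules: module_id, stage, n_genes, comma-separated members."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("module_id\tstage\tn_genes\tmembers\n")
        for m in ms:
            fh.write(f"{m.name}\t{m.stage}\t{m.size}\t{','.join(m.sorted_members())}\n")


def read_modules_tsv(path: str | Path) -> ModuleSet:
    """Read a module export written by :func:`write_modules_tsv`."""
    modules: list[Module] = []
    stage = None
    with Path(path).open("r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("module_id\t"):
            raise ValueError(f"{path}: not a module export (bad header)")
        for line in fh:
            if not line.strip():
                continue
            name, st, _n, members = line.rstrip("\n").split("\t")
            stage = st if stage is None else stage
            modules.append(Module(name, frozenset(members.split(",")), st))
    if stage is None:
        raise ValueError(f"{path}: no modules")
    return ModuleSet(tuple(modules), stage)
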