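"""Synthetic expression matrices with planted correlated gene blocks.

The generator emulates the structure the pipeline is designed to find: a
features × samples matrix in which a few gene blocks share a latent
sample-wise factor (so their pairwise correlation has a known target value
*r*) on a background of independent noise genes, with optional genes shared
between blocks — the planted analogue of a gene participating in two
pathways.  Every matrix is fully reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix, GeneSetCollection
from .merge_split import ModuleSet

__all__ = [
    "BlockSpec",
    "generate_block_expression",
    "benchmark_blocks",
    "planted_recovery_score",
    "write_truth_tsv",
    "blocks_to_gmt",
]


@dataclass(frozen=True)
class BlockSpec:
    """One planted block: its members, target correlation and noise scale."""

    name: str
    members: tuple[str, ...]
    r: float
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.r < 1):
            raise ValueError("target correlation r must be in (0, 1)")
        if len(self.members) < 2:
            raise ValueError("a block needs >= 2 members")
        if len(set(self.members)) != len(self.members):
            raise ValueError("duplicate members in block")


def generate_block_expression(
    n_genes: int,
    n_samples: int,
    blocks: Sequence[BlockSpec],
    seed: int,
    gene_prefix: str = "G",
) -> ExpressionMatrix:
    """Gaussian expression matrix with planted correlated blocks.

    Each block b has a latent factor f_b ~ N(0, 1) over samples.  A gene in
    exactly one block is sqrt(r)·f_b + sqrt(1−r)·ε; a gene shared between
    blocks sums every factor it loads on plus its noise, and is rescaled to
    unit variance (two same-block genes then correlate r by construction).
    Genes in no block are independent N(0, 1) noise.  Gene identifiers are
    ``{prefix}0001`` ...; block members must name genes in that universe.
    """
    if n_samples < 3:
        raise ValueError("need at least 3 samples")
    genes = [f"{gene_prefix}{i + 1:04d}" for i in range(n_genes)]
    gene_set = set(genes)
    for b in blocks:
        missing = set(b.members) - gene_set
        if missing:
            raise ValueError(f"block {b.name!r} names unknown genes: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)
    factors = {b.name: rng.standard_normal(n_samples) for b in blocks}
    vals = np.empty((n_genes, n_samples))
    loads: dict[str, list[BlockSpec]] = {}
    for b in blocks:
        for g in b.members:
            loads.setdefault(g, []).append(b)
    for i, g in enumerate(genes):
        eps = rng.standard_normal(n_samples)
        bs = loads.get(g)
        if not bs:
            vals[i] = eps
            continue
        mean_r = float(np.mean([b.r for b in bs]))
        sd = float(np.mean([b.noise_sd for b in bs]))
        y = np.zeros(n_samples)
        for b in bs:
            y += np.sqrt(b.r) * factors[b.name]
        y += np.sqrt(1.0 - mean_r) * sd * eps
        var = sum(b.r for b in bs) + (1.0 - mean_r) * sd * sd
        vals[i] = y / np.sqrt(var)
    df = pd.DataFrame(vals, index=genes, columns=[f"S{j + 1:03d}" for j in range(n_samples)])
    return ExpressionMatrix(df, value_kind="log2_ratio")


def benchmark_blocks(
    n_blocks: int = 5,
    block_size: int = 40,
    n_shared: int = 10,
    r: float = 0.8,
    gene_prefix: str = "G",
) -> tuple[BlockSpec, ...]:
    """The standard planted scenario used by the recovery benchmark.

    ``n_blocks`` blocks of ``block_size`` genes at target correlation ``r``;
    the first two blocks share ``n_shared`` genes, mimicking genes active in
    two pathways.  Blocks occupy the start of the gene universe, noise genes
    the rest.
    """
    blocks: list[BlockSpec] = []
    cursor = 0
    shared: tuple[str, ...] = ()
    for k in range(n_blocks):
        if k == 1 and n_shared:
            own = block_size - n_shared
            members = shared + tuple(
                f"{gene_prefix}{i + 1:04d}" for i in range(cursor, cursor + own)
            )
            cursor += own
        else:
            members = tuple(
                f"{gene_prefix}{i + 1:04d}" for i in range(cursor, cursor + block_size)
            )
            cursor += block_size
            if k == 0 and n_shared:
                shared = members[:n_shared]
        blocks.append(BlockSpec(f"B{k + 1}", members, r))
    return tuple(blocks)


def planted_recovery_score(
    found: ModuleSet | Iterable, truth: Sequence[BlockSpec]
) -> dict[str, float]:
    """Best Jaccard between each planted block and any found module."""
    found_sets = [frozenset(m.members) for m in found]
    if not found_sets or not truth:
        raise ValueError("need at least one found module and one true block")
    out: dict[str, float] = {}
    for b in truth:
        tb = frozenset(b.members)
        out[b.name] = max(len(tb & f) / len(tb | f) for f in found_sets)
    return out


def write_truth_tsv(blocks: Sequence[BlockSpec], path: str | Path) -> None:
    """Write the planted membership as (block, gene) rows."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("block\tgene\n")
        for b in blocks:
            for g in b.members:
                fh.write(f"{b.name}\t{g}\n")


def blocks_to_gmt(blocks: Sequence[BlockSpec], path: str | Path) -> None:
    """Emit the planted blocks as a toy GMT collection ("pathways" = blocks)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for b in blocks:
            fh.write(b.name + "\tplanted block\t" + "\t".join(b.members) + "\n")
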