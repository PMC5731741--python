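"""Absolute-correlation networks and their global statistics.

Every downstream stage works on the weighted co-expression network whose
edge weight between genes *i* and *j* is ``a_ij = |corr(x_i, x_j)|``, the
absolute Pearson correlation of their expression profiles.  This module
builds that matrix, selects quantile thresholds on its off-diagonal values
(the "top S% of pairs" rule used for seeding and expansion) and computes the
standard weighted-network summary statistics: per-gene connectivity
``k_i = sum_{j != i} a_ij``, density, centralization, heterogeneity, and the
per-gene coefficient of variation of connection strengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .expression_io import ExpressionMatrix

__all__ = [
    "CorrelationMatrix",
    "NetworkStats",
    "PairDifferenceSummary",
    "abs_pcc_matrix",
    "top_quantile_threshold",
    "network_stats",
    "paired_pcc_differences",
    "ggi_max_isoform_pcc",
]


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric matrix of absolute Pearson correlations with unit diagonal."""

    ids: tuple[str, ...]
    a: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.a.shape != (n, n):
            raise ValueError(f"matrix shape {self.a.shape} does not match {n} ids")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate identifiers")
        if n and not np.allclose(self.a, self.a.T, atol=1e-12):
            raise ValueError("matrix not symmetric")
        if n and (self.a.min() < -1e-12 or self.a.max() > 1 + 1e-12):
            raise ValueError("entries must lie in [0, 1]")
        if n and not np.allclose(np.diag(self.a), 1.0, atol=1e-12):
            raise ValueError("diagonal must be 1")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, gene: str) -> int:
        try:
            return self.ids.index(gene)
        except ValueError:
            raise KeyError(gene) from None

    def submatrix(self, genes: Sequence[str]) -> np.ndarray:
        idx = [self.index_of(g) for g in genes]
        return self.a[np.ix_(idx, idx)]

    def condensed(self) -> np.ndarray:
        """Upper-triangle off-diagonal values, each unordered pair once."""
        iu = np.triu_indices(self.n, k=1)
        return self.a[iu]


@dataclass(frozen=True)
class NetworkStats:
    """Global statistics of the weighted correlation network."""

    connectivity: np.ndarray  # k_i = sum_{j != i} a_ij
    cv: np.ndarray  # per-gene sd/mean of its connection strengths
    density: float
    centralization: float
    heterogeneity: float
    n: int


@dataclass(frozen=True)
class PairDifferenceSummary:
    """Summary of |a1_ij - a2_ij| over shared gene pairs of two networks."""

    mean_abs_difference: float
    count_above_cutoff: int
    cutoff: float
    n_pairs: int
    histogram_counts: tuple[int, ...]
    histogram_edges: tuple[float, ...]


def abs_pcc_matrix(m: ExpressionMatrix, on_constant: str = "error") -> CorrelationMatrix:
    """Absolute Pearson correlation between all feature pairs.

    ``on_constant`` controls zero-variance rows, for which the correlation is
    undefined: ``"error"`` raises naming the row, ``"drop"`` removes such
    rows before computing.
    """
    if m.n_samples < 3:
        raise ValueError("need at least 3 samples for meaningful correlations")
    vals = m.values
    ids = m.row_ids
    sd = vals.std(axis=1)
    if (sd == 0).any():
        bad = [ids[i] for i in np.flatnonzero(sd == 0)]
        if on_constant == "drop":
            keep = np.flatnonzero(sd > 0)
            vals = vals[keep]
            ids = [ids[i] for i in keep]
        else:
            raise ValueError(f"constant expression rows have undefined correlation: {bad[:5]}")
    if len(ids) < 2:
        raise ValueError("need at least 2 non-constant features")
    a = np.abs(np.corrcoef(vals))
    np.clip(a, 0.0, 1.0, out=a)
    np.fill_diagonal(a, 1.0)
    a = (a + a.T) / 2.0
    return CorrelationMatrix(tuple(ids), a)


def top_quantile_threshold(c: CorrelationMatrix, top_percent: float) -> float:
    """Value at the top-``top_percent``% quantile of off-diagonal pair values.

    ``top_percent`` is expressed in percent exactly as printed in parameter
    tables: 0.005 means the top 0.005% of pairs, 100 means all pairs.  With
    P = n(n-1)/2 unordered pairs, the returned threshold t is the value such
    that the ceil(P * top_percent / 100) largest pair values are >= t.
    """
    if not (0 < top_percent <= 100):
        raise ValueError("top_percent must be in (0, 100]")
    vals = c.condensed()
    if vals.size == 0:
        raise ValueError("correlation matrix has no off-diagonal pairs")
    k = int(math.ceil(vals.size * top_percent / 100.0))
    k = min(max(k, 1), vals.size)
    return float(np.partition(vals, vals.size - k)[vals.size - k])


def network_stats(c: CorrelationMatrix) -> NetworkStats:
    """Connectivity, CV, density, centralization and heterogeneity.

    With a_ij the absolute correlations and n genes::

        k_i            = sum_{j != i} a_ij
        density        = sum_{i != j} a_ij / (n (n - 1))
        centralization = max(k) / n - density
        heterogeneity  = sqrt(variance(k)) / mean(k)

    The diagonal is excluded from every sum.  Variance is the population
    (divide-by-n) form, so identical rows give heterogeneity exactly 0.
    Centralization follows the equation as printed and can be negative.
    """
    n = c.n
    if n < 2:
        raise ValueError("need at least 2 features")
    k = c.a.sum(axis=1) - np.diag(c.a)
    density = float(k.sum() / (n * (n - 1)))
    centralization = float(k.max() / n - density)
    heterogeneity = float(np.sqrt(np.var(k)) / np.mean(k))
    off = c.a.copy()
    np.fill_diagonal(off, np.nan)
    mu = np.nanmean(off, axis=1)
    sd = np.nanstd(off, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mu > 0, sd / mu, np.nan)
    return NetworkStats(
        connectivity=k,
        cv=cv,
        density=density,
        centralization=centralization,
        heterogeneity=heterogeneity,
        n=n,
    )


def paired_pcc_differences(
    c1: CorrelationMatrix,
    c2: CorrelationMatrix,
    cutoff: float = 0.5,
    intersect: bool = True,
    n_bins: int = 10,
) -> PairDifferenceSummary:
    """Per-pair |a1_ij - a2_ij| between two networks over the same genes.

    Used to compare the same gene pairs measured on two platforms (for
    example microarray versus RNA-Seq).  With ``intersect`` the comparison is
    restricted to the shared gene universe; otherwise the universes must
    match exactly.
    """
    if set(c1.ids) != set(c2.ids):
        if not intersect:
            raise ValueError("correlation matrices cover different gene universes")
        shared = sorted(set(c1.ids) & set(c2.ids))
        if len(shared) < 2:
            raise ValueError("fewer than 2 shared genes between the two networks")
        a1 = c1.submatrix(shared)
        a2 = c2.submatrix(shared)
    else:
        order = list(c1.ids)
        a1 = c1.a
        a2 = c2.submatrix(order)
    iu = np.triu_indices(a1.shape[0], k=1)
    diff = np.abs(a1[iu] - a2[iu])
    counts, edges = np.histogram(diff, bins=n_bins, range=(0.0, 1.0))
    return PairDifferenceSummary(
        mean_abs_difference=float(diff.mean()),
        count_above_cutoff=int((diff > cutoff).sum()),
        cutoff=cutoff,
        n_pairs=int(diff.size),
        histogram_counts=tuple(int(x) for x in counts),
        histogram_edges=tuple(float(x) for x in edges),
    )


def ggi_max_isoform_pcc(
    gene_pairs: Iterable[tuple[str, str]],
    iso_map: Mapping[str, Sequence[str]],
    iso_expr: ExpressionMatrix,
) -> tuple[dict[tuple[str, str], float], list[tuple[str, str]]]:
    """Best isoform-level correlation for each gene–gene interaction pair.

    For each (geneA, geneB) pair, returns the maximum absolute Pearson
    correlation over all combinations of an isoform of A with an isoform of
    B — isoform-level profiles can reveal co-expression that the summed
    gene-level profile hides.  Pairs where either gene has no isoform left in
    ``iso_expr`` are skipped and reported in the second return value.
    """
    present = set(iso_expr.row_ids)
    index = {fid: i for i, fid in enumerate(iso_expr.row_ids)}
    vals = iso_expr.values
    results: dict[tuple[str, str], float] = {}
    skipped: list[tuple[str, str]] = []
    for ga, gb in gene_pairs:
        iso_a = [i for i in iso_map.get(ga, ()) if i in present]
        iso_b = [i for i in iso_map.get(gb, ()) if i in present]
        if not iso_a or not iso_b:
            skipped.append((ga, gb))
            continue
        sub = np.vstack([vals[index[i]] for i in iso_a + iso_b])
        r = np.corrcoef(sub)
        block = np.abs(r[: len(iso_a), len(iso_a):])
        results[(ga, gb)] = float(np.nanmax(block))
    return results, skipped
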