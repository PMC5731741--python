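"""Reading, preprocessing and writing of expression matrices and gene-set inputs.

The universal input of the pipeline is a features × samples matrix of real
expression values (genes or transcript isoforms in rows, samples in columns),
stored as tab-separated text with a sample header.  Tumour profiles are
typically normalised to log2 ratios against the mean of the normal samples
before any correlation is computed; RNA-Seq matrices with many exact zeros
first have those zeros replaced by the smallest positive value observed, so
the log-ratio is defined everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "ExpressionParseError",
    "read_expression_tsv",
    "write_expression_tsv",
    "replace_zeros_with_min_nonzero",
    "log2_tumor_over_mean_normal",
    "filter_low_expression",
    "read_gmt",
    "read_gene_list",
]


class ExpressionParseError(ValueError):
    """Raised on malformed expression/GMT input, naming the offending line."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """A features × samples matrix of real expression values.

    Parameters
    ----------
    data
        DataFrame with feature identifiers as the index and sample
        identifiers as columns.  Row and column identifiers must be unique.
    value_kind
        ``"raw"`` for non-negative abundances (RSEM/RPKM-like), or
        ``"log2_ratio"`` for tumour/normal log2 ratios, which may be
        negative.
    """

    data: pd.DataFrame
    value_kind: str = "raw"

    def __post_init__(self) -> None:
        if self.value_kind not in ("raw", "log2_ratio"):
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature identifiers: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample identifiers: {dups[:5]}")
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise ValueError("expression values must all be finite")

    @property
    def row_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    @property
    def col_ids(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (e.g. one GMT collection such as KEGG or GO-BP)."""

    sets: Mapping[str, frozenset[str]]
    source_label: str = ""

    def __len__(self) -> int:
        return len(self.sets)


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Read a tab-separated expression matrix.

    The first line is the sample header; every following line is a feature
    identifier followed by one numeric field per sample.  Ragged rows,
    non-numeric cells and duplicated feature identifiers are reported as
    :class:`ExpressionParseError` with the offending line number.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise ExpressionParseError(f"{path}: line 1: empty header")
        cols = header.rstrip("\n").split("\t")
        # tolerate an optional leading label for the feature-id column
        if cols and cols[0] in ("", "id", "feature", "gene", "gene_id", "isoform"):
            cols = cols[1:]
        n_samples = len(cols)
        ids: list[str] = []
        seen: set[str] = set()
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_samples + 1:
                raise ExpressionParseError(
                    f"{path}: line {lineno}: expected {n_samples + 1} fields, got {len(parts)}"
                )
            fid = parts[0]
            if fid in seen:
                raise ExpressionParseError(
                    f"{path}: line {lineno}: duplicate feature id {fid!r}"
                )
            seen.add(fid)
            try:
                rows.append([float(x) for x in parts[1:]])
            except ValueError as exc:
                raise ExpressionParseError(
                    f"{path}: line {lineno}: non-numeric value ({exc})"
                ) from None
            ids.append(fid)
    df = pd.DataFrame(rows, index=ids, columns=cols, dtype=float)
    return ExpressionMatrix(df)


def write_expression_tsv(m: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix in the same TSV dialect ``read_expression_tsv`` reads.

    Floats are written with Python's shortest round-trip representation, so a
    read/write cycle preserves values bit for bit.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("id\t" + "\t".join(m.col_ids) + "\n")
        vals = m.values
        for i, fid in enumerate(m.row_ids):
            fh.write(fid + "\t" + "\t".join(repr(float(v)) for v in vals[i]) + "\n")


def replace_zeros_with_min_nonzero(
    m: ExpressionMatrix, per_row: bool = False
) -> ExpressionMatrix:
    """Replace exact zeros with the minimum positive value of the matrix.

    RNA-Seq abundance matrices contain many exact zeros which make log ratios
    undefined; each zero is replaced by the smallest positive value observed
    over the whole matrix (the default) or per row (``per_row=True``).
    """
    if m.value_kind != "raw":
        raise ValueError("zero replacement applies to raw abundance values only")
    vals = m.values.copy()
    if per_row:
        out = vals
        for i in range(out.shape[0]):
            row = out[i]
            pos = row[row > 0]
            if pos.size == 0:
                raise ValueError(f"row {m.row_ids[i]!r} is all zero; no replacement value")
            row[row == 0] = pos.min()
    else:
        pos = vals[vals > 0]
        if pos.size == 0:
            raise ValueError("all-zero matrix; no non-zero replacement value exists")
        vals[vals == 0] = pos.min()
        out = vals
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.data.index, columns=m.data.columns), m.value_kind
    )


def log2_tumor_over_mean_normal(
    tumor: ExpressionMatrix, normal: ExpressionMatrix
) -> ExpressionMatrix:
    """log2 ratio of each tumour value to the mean of the normal samples.

    Both matrices must carry exactly the same features (unmatched rows are an
    error, not silently dropped) and strictly positive values — apply
    :func:`replace_zeros_with_min_nonzero` first.  The normal samples are
    unmatched with the tumour samples and are averaged unweighted per gene.
    """
    if list(tumor.data.index) != list(normal.data.index):
        t, n = set(tumor.data.index), set(normal.data.index)
        raise ValueError(
            "tumor/normal feature mismatch: "
            f"{len(t - n)} only in tumor, {len(n - t)} only in normal"
            if t != n
            else "tumor/normal features agree as sets but not in order"
        )
    tv, nv = tumor.values, normal.values
    if (tv <= 0).any() or (nv <= 0).any():
        raise ValueError("non-positive values; replace zeros before taking log ratios")
    ratio = np.log2(tv / nv.mean(axis=1, keepdims=True))
    return ExpressionMatrix(
        pd.DataFrame(ratio, index=tumor.data.index, columns=tumor.data.columns),
        value_kind="log2_ratio",
    )


def filter_low_expression(m: ExpressionMatrix, drop_fraction: float) -> ExpressionMatrix:
    """Drop lowly expressed features.

    First removes the ``drop_fraction`` of rows with the lowest mean
    expression, then removes any remaining row whose value is zero in
    strictly more than half of the samples.  Surviving rows keep their
    original order.  Ties at the mean-expression boundary are broken by
    keeping the lexicographically smaller identifier.
    """
    if not (0 <= drop_fraction < 1):
        raise ValueError("drop_fraction must be in [0, 1)")
    if m.value_kind != "raw":
        raise ValueError("low-expression filtering applies to raw values only")
    vals = m.values
    n = vals.shape[0]
    n_drop = int(math.floor(n * drop_fraction))
    means = vals.mean(axis=1)
    ids = m.row_ids
    # drop the n_drop smallest means; among equal means drop the larger id first
    order = sorted(range(n), key=lambda i: (means[i], _desc_key(ids[i])))
    dropped = set(order[:n_drop])
    keep = [i for i in range(n) if i not in dropped]
    zero_frac_limit = vals.shape[1] / 2.0
    keep = [i for i in keep if (vals[i] == 0).sum() <= zero_frac_limit]
    return ExpressionMatrix(m.data.iloc[keep], m.value_kind)


class _desc_key:
    """Sort key reversing lexicographic string order."""

    __slots__ = ("s",)

    def __init__(self, s: str) -> None:
        self.s = s

    def __lt__(self, other: "_desc_key") -> bool:
        return self.s > other.s

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _desc_key) and self.s == other.s


def read_gmt(
    path: str | Path,
    universe: Iterable[str] | None = None,
    min_size: int = 3,
    max_size: int = 300,
    source_label: str | None = None,
) -> GeneSetCollection:
    """Read a GMT gene-set file, restricting members to ``universe``.

    Each line is ``name<TAB>description<TAB>member...``.  After intersecting
    with the universe, sets with fewer than ``min_size`` or more than
    ``max_size`` surviving members are dropped — functions with under three
    genes are too specific and those above three hundred too general to be
    informative in enrichment testing.
    """
    path = Path(path)
    uni = set(universe) if universe is not None else None
    sets: dict[str, frozenset[str]] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ExpressionParseError(
                    f"{path}: line {lineno}: GMT line needs name, description and >= 1 member"
                )
            name = parts[0]
            members = {g for g in parts[2:] if g}
            if uni is not None:
                members &= uni
            if min_size <= len(members) <= max_size:
                sets[name] = frozenset(members)
    return GeneSetCollection(sets, source_label or path.stem)


def read_gene_list(path: str | Path) -> frozenset[str]:
    """Read a plain gene list, one identifier per line; ``#`` starts a comment."""
    out: set[str] = set()
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            entry = line.split("#", 1)[0].strip()
            if entry:
                out.add(entry)
    return frozenset(out)
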