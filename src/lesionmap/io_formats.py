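"""Readers and writers for the on-disk formats the pipeline touches.

Count matrices follow the 10x Genomics plain-text convention: a Matrix
Market coordinate file plus ``features.tsv`` and ``barcodes.tsv``. Gene
positions use BED conventions (0-based, half-open). Dendrograms are
exported as Newick with branch lengths.

Only genomic *ordering* by (chromosome, start) is consumed downstream, so
any coordinate-convention mistakes are confined to this module.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "FormatError",
    "CountMatrix",
    "GeneTable",
    "read_counts_10x",
    "write_counts_10x",
    "read_gene_table",
    "write_gene_table",
    "linkage_to_newick",
    "write_newick",
    "natural_chromosome_key",
]


class FormatError(ValueError):
    """A file violates the expected on-disk format or an invariant."""


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Genes x columns matrix of nonnegative integer UMI counts.

    Columns are cells or spatial spots. ``values`` is a CSR sparse matrix;
    use :meth:`to_dense` for small matrices.
    """

    values: sp.csr_matrix
    gene_ids: list[str]
    column_ids: list[str]

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.column_ids = [str(c) for c in self.column_ids]
        self.validate()

    def validate(self) -> None:
        n_genes, n_cols = self.values.shape
        if len(self.gene_ids) != n_genes or len(self.column_ids) != n_cols:
            raise FormatError(
                f"identifier lengths ({len(self.gene_ids)}, {len(self.column_ids)}) "
                f"do not match matrix shape {self.values.shape}"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise FormatError("duplicate gene_ids")
        if len(set(self.column_ids)) != n_cols:
            raise FormatError("duplicate column_ids")
        if self.values.nnz and self.values.data.min() < 0:
            raise FormatError("negative count entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.values.todense(), dtype=np.int64)

    def subset_columns(self, keep: Sequence[int] | np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        return CountMatrix(
            self.values[:, keep].tocsr(),
            list(self.gene_ids),
            [self.column_ids[i] for i in keep],
        )

    def subset_genes(self, keep: Sequence[int] | np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        return CountMatrix(
            self.values[keep, :].tocsr(),
            [self.gene_ids[i] for i in keep],
            list(self.column_ids),
        )


def _find(dir_path: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = dir_path / name
        if p.exists():
            return p
    raise FormatError(f"missing {stem}[.gz] in {dir_path}")


def _read_tsv_column(path: Path) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_counts_10x(dir_path: str | Path) -> CountMatrix:
    """Read a 10x-style directory (matrix.mtx[.gz], features.tsv[.gz],
    barcodes.tsv[.gz]). Duplicate coordinate entries are summed."""
    dir_path = Path(dir_path)
    mtx_path = _find(dir_path, "matrix.mtx")
    genes = _read_tsv_column(_find(dir_path, "features.tsv"))
    barcodes = _read_tsv_column(_find(dir_path, "barcodes.tsv"))
    try:
        mat = scipy.io.mmread(str(mtx_path))
    except Exception as exc:  # pragma: no cover - scipy error text varies
        raise FormatError(f"cannot parse {mtx_path}: {exc}") from exc
    mat = sp.coo_matrix(mat)
    if mat.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"matrix header {mat.shape} does not match features ({len(genes)}) "
            f"x barcodes ({len(barcodes)})"
        )
    if mat.nnz and mat.data.min() < 0:
        raise FormatError("negative count entries")
    # tocsr() sums duplicate coordinates
    return CountMatrix(mat.tocsr().astype(np.int64), genes, barcodes)


def write_counts_10x(m: CountMatrix, dir_path: str | Path) -> None:
    """Write ``m`` as plain-text matrix.mtx / features.tsv / barcodes.tsv."""
    m.validate()
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(dir_path / "matrix.mtx"), sp.coo_matrix(m.values), field="integer")
    with open(dir_path / "features.tsv", "w") as fh:
        for g in m.gene_ids:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(dir_path / "barcodes.tsv", "w") as fh:
        for b in m.column_ids:
            fh.write(b + "\n")


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

_NAT_SPLIT = re.compile(r"(\d+)")


def natural_chromosome_key(name: str) -> tuple:
    """Sort key giving chr1 < chr2 < ... < chr10 < chrX < chrM order."""
    parts = _NAT_SPLIT.split(name)
    return tuple(int(p) if p.isdigit() else p for p in parts)


@dataclass
class GeneTable:
    """Per-gene chromosome, BED interval and mito/hemoglobin flags.

    Wraps a DataFrame indexed by ``gene_id`` with columns
    chromosome/start/end/is_mito/is_hb. ``chrom_order`` optionally pins an
    explicit chromosome ordering; otherwise natural order is used.
    """

    df: pd.DataFrame
    chrom_order: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        required = {"chromosome", "start", "end", "is_mito", "is_hb"}
        missing = required - set(self.df.columns)
        if missing:
            raise FormatError(f"gene table missing columns {sorted(missing)}")
        if self.df.index.duplicated().any():
            dups = self.df.index[self.df.index.duplicated()][:3].tolist()
            raise FormatError(f"duplicate gene_id(s): {dups}")
        bad = self.df["start"] >= self.df["end"]
        if bad.any():
            raise FormatError(
                f"start >= end for gene(s) {self.df.index[bad][:3].tolist()}"
            )
        if (self.df["start"] < 0).any():
            raise FormatError("negative start coordinate")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.df.index)

    def chromosome_rank(self) -> dict[str, int]:
        chroms = sorted(self.df["chromosome"].unique(), key=natural_chromosome_key)
        if self.chrom_order is not None:
            known = [c for c in self.chrom_order if c in set(chroms)]
            rest = [c for c in chroms if c not in set(known)]
            chroms = known + rest
        return {c: i for i, c in enumerate(chroms)}

    def genomic_order(self, gene_ids: Sequence[str] | None = None) -> list[str]:
        """Gene ids sorted by (chromosome, start), restricted to ``gene_ids``
        when given. Total order thanks to gene_id uniqueness (final tie-break
        is lexicographic on gene_id, for genes sharing a start)."""
        sub = self.df if gene_ids is None else self.df.loc[list(gene_ids)]
        rank = self.chromosome_rank()
        keys = sorted(
            sub.index,
            key=lambda g: (rank[sub.at[g, "chromosome"]], sub.at[g, "start"], g),
        )
        return keys

    def require(self, gene_ids: Sequence[str]) -> None:
        missing = [g for g in gene_ids if g not in self.df.index]
        if missing:
            raise FormatError(f"gene(s) absent from annotation: {missing[:5]}")


def read_gene_table(path: str | Path, chrom_order: list[str] | None = None) -> GeneTable:
    """Read a BED-like TSV: chrom, start, end, gene_id, flags.

    ``flags`` is a comma-separated list that may contain ``mito`` and/or
    ``hb``; ``.`` or an absent column means no flags.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    rows = []
    with opener(path, "rt") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{ln}: expected >=4 columns")
            chrom, start, end, gene_id = fields[:4]
            flags = fields[4].split(",") if len(fields) > 4 and fields[4] != "." else []
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-integer coordinates") from exc
            rows.append(
                {
                    "gene_id": gene_id,
                    "chromosome": chrom,
                    "start": start_i,
                    "end": end_i,
                    "is_mito": "mito" in flags,
                    "is_hb": "hb" in flags,
                }
            )
    if not rows:
        df = pd.DataFrame(
            columns=["chromosome", "start", "end", "is_mito", "is_hb"],
            index=pd.Index([], name="gene_id"),
        )
        return GeneTable(df, chrom_order)
    df = pd.DataFrame(rows).set_index("gene_id")
    return GeneTable(df, chrom_order)


def write_gene_table(table: GeneTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene_id, row in table.df.iterrows():
            flags = ",".join(
                f for f, on in (("mito", row["is_mito"]), ("hb", row["is_hb"])) if on
            ) or "."
            fh.write(
                f"{row['chromosome']}\t{row['start']}\t{row['end']}\t{gene_id}\t{flags}\n"
            )


# ---------------------------------------------------------------------------
# Newick export
# ---------------------------------------------------------------------------

def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Convert a scipy linkage matrix to a Newick string.

    Edge lengths follow the midpoint convention for ultrametric
    dendrograms: a child sitting at merge height ``h_c`` hanging from a
    parent at ``h_p`` gets edge length ``(h_p - h_c) / 2``, so two leaves
    merged at height 2 read ``(A:1.0,B:1.0);``.
    """
    labels = [str(l) for l in labels]
    if len(set(labels)) != len(labels):
        raise FormatError("duplicate leaf labels")
    n = len(labels)
    if n == 1:
        return f"{labels[0]};"
    Z = np.asarray(Z, dtype=float)
    if Z.shape[0] != n - 1:
        raise FormatError("linkage size does not match label count")
    heights = {i: 0.0 for i in range(n)}

    def node_str(idx: int) -> str:
        if idx < n:
            return labels[idx]
        a, b = int(Z[idx - n, 0]), int(Z[idx - n, 1])
        h = heights[idx]
        return (
            f"({node_str(a)}:{(h - heights[a]) / 2:.10g},"
            f"{node_str(b)}:{(h - heights[b]) / 2:.10g})"
        )

    for k in range(n - 1):
        heights[n + k] = float(Z[k, 2])
    return node_str(2 * n - 2) + ";"


def write_newick(Z: np.ndarray, labels: Sequence[str], path: str | Path) -> str:
    """Write the dendrogram as Newick; returns the string written."""
    nwk = linkage_to_newick(Z, labels)
    with open(path, "w") as fh:
        fh.write(nwk + "\n")
    return nwk
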