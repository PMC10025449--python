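"""Reading and writing count matrices and pipeline tables.

Count matrices travel either as MatrixMarket MTX (with ``genes.tsv`` and
``embryos.tsv`` index files next to the matrix, one id per line) or as a
single dense TSV with gene ids on rows and embryo ids on columns.  All
other tables are plain TSV with headers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .matrix import CountMatrix

__all__ = ["read_counts", "write_counts", "read_table", "write_table"]


def _read_ids(path: Path, what: str) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(f"missing {what} index file: {path}")
    ids = [line.strip().split("\t")[0] for line in path.read_text().splitlines() if line.strip()]
    return ids


def read_counts(path, fmt: str | None = None) -> CountMatrix:
    """Read a genes x embryos count matrix from MTX or dense TSV.

    ``fmt`` is inferred from the suffix when omitted.  MTX input expects
    ``genes.tsv`` and ``embryos.tsv`` alongside the matrix file.
    """
    path = Path(path)
    if fmt is None:
        fmt = "mtx" if path.suffix == ".mtx" else "tsv"
    if fmt == "mtx":
        mat = scipy.io.mmread(path)
        genes = _read_ids(path.parent / "genes.tsv", "gene")
        embryos = _read_ids(path.parent / "embryos.tsv", "embryo")
        arr = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        if arr.shape != (len(genes), len(embryos)):
            raise ValueError(
                f"matrix dimensions {arr.shape} disagree with index files "
                f"({len(genes)} genes, {len(embryos)} embryos)"
            )
        df = pd.DataFrame(arr, index=genes, columns=embryos)
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
    else:
        raise ValueError(f"unknown count-matrix format: {fmt!r}")
    return CountMatrix(df)


def write_counts(m: CountMatrix, path, fmt: str = "mtx") -> None:
    """Write a count matrix as MTX (+ index files) or dense TSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "mtx":
        sparse = scipy.sparse.csr_matrix(m.values.to_numpy())
        scipy.io.mmwrite(str(path), sparse, field="integer")
        (path.parent / "genes.tsv").write_text("\n".join(m.gene_ids) + "\n")
        (path.parent / "embryos.tsv").write_text("\n".join(m.embryo_ids) + "\n")
    elif fmt == "tsv":
        m.values.to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown count-matrix format: {fmt!r}")


def read_table(path, index_col: str | None = None) -> pd.DataFrame:
    """Read a TSV table with a header row."""
    df = pd.read_csv(path, sep="\t")
    if index_col is not None:
        df = df.set_index(index_col, drop=False)
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Write a table as TSV with header, no index column duplication."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
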