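"""Readers and writers for the matrix, gene set and result formats.

Supported formats:

* 10x-convention MatrixMarket directory: ``matrix.mtx`` (features x cells,
  transposed on load), ``features.tsv``, ``barcodes.tsv``.
* Dense delimited text (``.csv`` comma, ``.tsv``/``.txt`` tab): header row of
  feature ids, first column of cell ids.
* Gene set TSV (columns ``receptor_id, gene_id, weight, rank``) and JSON
  (mapping receptor -> ordered ``[gene, weight]`` pairs).

No numerics live here.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .types import CountMatrix, GeneSetWeights, ValidationError

__all__ = [
    "read_counts",
    "write_matrix",
    "read_matrix",
    "read_gene_sets",
    "write_gene_sets",
    "read_rename_map",
]

_MTX_NAMES = ("matrix.mtx", "features.tsv", "barcodes.tsv")


def _delimiter_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_id_column(path: Path) -> list[str]:
    # 10x features.tsv may carry extra columns (ensembl id, symbol, type);
    # the first column is the identifier.
    ids: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def read_counts(path: str | os.PathLike, format: str | None = None,
                modality: str = "rna") -> CountMatrix:
    """Read a count matrix into cells-by-features orientation.

    Parameters
    ----------
    path
        MTX directory or delimited file.
    format
        ``"mtx_dir"``, ``"csv"`` or ``"tsv"``; inferred from ``path`` when
        omitted (directory -> mtx_dir, else by extension).
    modality
        ``"rna"`` or ``"adt"``.
    """
    p = Path(path)
    if format is None:
        format = "mtx_dir" if p.is_dir() else ("csv" if p.suffix.lower() == ".csv" else "tsv")
    if format == "mtx_dir":
        if not p.is_dir():
            raise FileNotFoundError(f"MTX directory not found: {p}")
        for name in _MTX_NAMES:
            if not (p / name).exists():
                raise FileNotFoundError(f"missing {name} in {p}")
        mat = scipy.io.mmread(p / "matrix.mtx")
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        features = _read_id_column(p / "features.tsv")
        barcodes = _read_id_column(p / "barcodes.tsv")
        if mat.shape != (len(features), len(barcodes)):
            raise ValidationError(
                f"matrix.mtx is {mat.shape} but features/barcodes imply "
                f"({len(features)}, {len(barcodes)})"
            )
        # on-disk orientation is features-by-cells
        return CountMatrix(np.asarray(mat).T, barcodes, features, modality)
    if format not in ("csv", "tsv"):
        raise ValidationError(f"unknown format {format!r}")
    if not p.exists():
        raise FileNotFoundError(f"file not found: {p}")
    df = pd.read_csv(p, sep=_delimiter_for(p), index_col=0)
    return CountMatrix(
        df.to_numpy(dtype=np.float64),
        [str(c) for c in df.index],
        [str(g) for g in df.columns],
        modality,
    )


def write_matrix(values: np.ndarray, row_ids: list[str], col_ids: list[str],
                 path: str | os.PathLike, format: str | None = None) -> None:
    """Write a named numeric matrix as CSV/TSV or a 10x-style MTX directory."""
    p = Path(path)
    if format is None:
        format = "mtx_dir" if p.suffix == "" else ("csv" if p.suffix.lower() == ".csv" else "tsv")
    values = np.asarray(values)
    if values.shape != (len(row_ids), len(col_ids)):
        raise ValidationError("matrix shape inconsistent with row/column names")
    if format == "mtx_dir":
        p.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(p / "matrix.mtx", scipy.sparse.csc_matrix(values.T))
        (p / "features.tsv").write_text("".join(f"{g}\n" for g in col_ids))
        (p / "barcodes.tsv").write_text("".join(f"{c}\n" for c in row_ids))
        return
    df = pd.DataFrame(values, index=row_ids, columns=col_ids)
    df.to_csv(p, sep=_delimiter_for(p), float_format="%.17g")


def read_matrix(path: str | os.PathLike) -> tuple[np.ndarray, list[str], list[str]]:
    """Read back a delimited matrix written by :func:`write_matrix`."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"file not found: {p}")
    df = pd.read_csv(p, sep=_delimiter_for(p), index_col=0)
    return (
        df.to_numpy(dtype=np.float64),
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
    )


def write_gene_sets(sets: GeneSetWeights, path: str | os.PathLike) -> None:
    """Serialize weighted gene sets as TSV or JSON (by extension)."""
    p = Path(path)
    if p.suffix.lower() == ".json":
        payload = {rec: [[g, w] for g, w in pairs] for rec, pairs in sets.sets.items()}
        p.write_text(json.dumps(payload, indent=1) + "\n")
        return
    lines = ["receptor_id\tgene_id\tweight\trank\n"]
    for rec, pairs in sets.sets.items():
        for rank, (gene, weight) in enumerate(pairs, start=1):
            # shortest round-tripping decimal repr keeps weights bit-exact
            lines.append(f"{rec}\t{gene}\t{float(weight)!r}\t{rank}\n")
    p.write_text("".join(lines))


def read_gene_sets(path: str | os.PathLike) -> GeneSetWeights:
    """Read gene sets from TSV or JSON; gene order within a receptor preserved."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"file not found: {p}")
    sets: dict[str, list[tuple[str, float]]] = {}
    if p.suffix.lower() == ".json":
        payload = json.loads(p.read_text())
        for rec, pairs in payload.items():
            sets[rec] = []
            for gene, weight in pairs:
                w = float(weight)
                if w <= 0:
                    raise ValidationError(f"non-positive weight for {rec}/{gene}")
                sets[rec].append((str(gene), w))
    else:
        df = pd.read_csv(p, sep="\t")
        required = {"receptor_id", "gene_id", "weight", "rank"}
        if not required.issubset(df.columns):
            raise ValidationError(f"gene set TSV must have columns {sorted(required)}")
        if (df["weight"] <= 0).any():
            bad = df.loc[df["weight"] <= 0, "gene_id"].tolist()
            raise ValidationError(f"non-positive weight for genes {bad[:5]}")
        for rec, grp in df.groupby("receptor_id", sort=False):
            grp = grp.sort_values("rank")
            sets[str(rec)] = [(str(g), float(w)) for g, w in zip(grp["gene_id"], grp["weight"])]
    max_size = max((len(v) for v in sets.values()), default=0)
    return GeneSetWeights(sets, set_size_requested=max_size)


def read_rename_map(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column TSV mapping antibody/receptor id -> gene symbol.

    Antibody naming is dataset-specific; matching is exact and case-sensitive,
    so users supply their own mapping where ids differ.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"file not found: {p}")
    out: dict[str, str] = {}
    with open(p) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValidationError(f"rename map line needs 2 columns: {line!r}")
            out[parts[0]] = parts[1]
    return out
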