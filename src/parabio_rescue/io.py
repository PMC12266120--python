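"""Readers and writers for the standard formats the pipeline touches.

Counts travel as a Matrix Market bundle (matrix.mtx + genes.tsv +
cells.tsv) in the prevalent genes-x-cells orientation; gene sets as GMT;
annotations and all result tables as TSV with deterministic row order;
run metadata as JSON.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datatypes import (
    CountMatrix,
    DEGRecord,
    FormatError,
    GeneSetCollection,
    ValidationError,
    records_to_frame,
    sort_deg_frame,
)

_FLOAT_FMT = "%.12g"  # >= 10 significant digits so tables round-trip


def _read_lines(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_counts(
    matrix_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
) -> CountMatrix:
    """Read a Matrix Market counts bundle.

    The .mtx file stores genes x cells; the result is transposed to
    cells x genes.  Entries absent from the sparse body are zero.
    """
    try:
        mat = scipy.io.mmread(os.fspath(matrix_path))
    except Exception as exc:  # scipy raises plain ValueError on bad headers
        raise FormatError(f"cannot parse Matrix Market file {matrix_path}: {exc}") from exc
    genes = _read_lines(genes_path)
    cells = _read_lines(cells_path)
    n_genes, n_cells = mat.shape
    if n_genes != len(genes):
        raise FormatError(
            f"{genes_path}: header declares {n_genes} genes but file lists {len(genes)}"
        )
    if n_cells != len(cells):
        raise FormatError(
            f"{cells_path}: header declares {n_cells} cells but file lists {len(cells)}"
        )
    mat = sp.csr_matrix(mat.T)
    if mat.data.size and not np.issubdtype(mat.data.dtype, np.integer):
        if not np.allclose(mat.data, np.round(mat.data)):
            raise ValidationError(f"{matrix_path}: non-integer count entries")
        mat = mat.astype(np.int64)
    if mat.data.size and mat.data.min() < 0:
        raise ValidationError(f"{matrix_path}: negative count entries")
    return CountMatrix(cells=cells, genes=genes, counts=mat.astype(np.int64))


def write_counts(cm: CountMatrix, out_dir: str | Path) -> dict[str, Path]:
    """Write a CountMatrix as a matrix.mtx/genes.tsv/cells.tsv bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.mtx",
        "genes": out / "genes.tsv",
        "cells": out / "cells.tsv",
    }
    scipy.io.mmwrite(os.fspath(paths["matrix"]), cm.counts.T.tocoo().astype(np.int64))
    paths["genes"].write_text("".join(g + "\n" for g in cm.genes))
    paths["cells"].write_text("".join(c + "\n" for c in cm.cells))
    return paths


def read_counts_bundle(in_dir: str | Path) -> CountMatrix:
    """Read the bundle written by :func:`write_counts`."""
    d = Path(in_dir)
    return read_counts(d / "matrix.mtx", d / "genes.tsv", d / "cells.tsv")


def read_gmt(path: str | Path, name: str | None = None) -> GeneSetCollection:
    """Parse a GMT file: per line, tab-separated set name, description,
    then gene symbols.  Duplicate genes within a line are collapsed
    keeping first occurrence; empty lines are skipped."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields, got {len(fields)}"
                )
            set_name, description = fields[0], fields[1]
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {set_name!r} has no genes")
            sets[set_name] = genes
            descriptions[set_name] = description
    return GeneSetCollection(
        name=name if name is not None else Path(path).stem,
        sets=sets,
        descriptions=descriptions,
    )


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_name, genes in collection.sets.items():
            desc = collection.descriptions.get(set_name, "")
            fh.write("\t".join([set_name, desc, *genes]) + "\n")


def write_deg_table(records: Iterable[DEGRecord], path: str | Path) -> None:
    """Write DEG records as TSV in the canonical deterministic order."""
    df = sort_deg_frame(records_to_frame(records))
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_deg_table(path: str | Path) -> list[DEGRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        DEGRecord(
            gene=str(r.gene),
            cell_type=str(r.cell_type),
            contrast=str(r.contrast),
            log2fc=float(r.log2fc),
            p_value=float(r.p_value),
            p_adjusted=float(r.p_adjusted),
            direction=str(r.direction),
        )
        for r in df.itertuples()
    ]


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_annotation(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Generic deterministic TSV writer for result tables."""
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
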