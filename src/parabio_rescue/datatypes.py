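"""Shared data containers for the parabiosis rescue pipeline.

The pipeline operates on a sparse cell-by-gene raw count matrix with an
optional log-normalized dense layer, a per-cell annotation table (group,
cell type, QC metrics), named gene-set collections, and differential
expression records.  Everything downstream is a pure function of these
containers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

#: The four experimental groups of the heterochronic parabiosis design:
#: young/aged isochronic controls and young/aged heterochronic parabionts.
GROUPS_FOUR = ("Yiso", "Aiso", "Yhet", "Ahet")

#: A plain two-group aging design (no parabiosis arms).
GROUPS_TWO = ("young", "aged")

#: Sentinel cell-type label for cells that could not be assigned.
UNASSIGNED = "unassigned"

#: Required columns of a cell annotation table.
ANNOTATION_COLUMNS = ("cell_id", "group", "cell_type", "n_genes_detected", "pct_mito")


class FormatError(ValueError):
    """A file does not conform to its declared on-disk format."""


class ValidationError(ValueError):
    """An in-memory object violates a pipeline invariant."""


@dataclass
class CountMatrix:
    """Sparse raw counts (cells x genes) plus an optional normalized layer.

    Parameters
    ----------
    cells
        Ordered unique cell identifiers, one per matrix row.
    genes
        Ordered unique gene symbols, one per matrix column.
    counts
        Non-negative integer sparse matrix of shape ``(len(cells), len(genes))``.
    normalized
        Optional dense log-scale layer of the same shape (natural-log
        counts-per-scale values); all entries finite and >= 0.
    """

    cells: list[str]
    genes: list[str]
    counts: sp.csr_matrix
    normalized: np.ndarray | None = None
    _gene_index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.cells = list(self.cells)
        self.genes = list(self.genes)
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr()
        if len(set(self.cells)) != len(self.cells):
            raise ValidationError("duplicate cell ids in CountMatrix")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate gene symbols in CountMatrix")
        if self.counts.shape != (len(self.cells), len(self.genes)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cells)} cells x {len(self.genes)} genes"
            )
        data = self.counts.data
        if data.size:
            if not np.issubdtype(data.dtype, np.integer):
                if not np.allclose(data, np.round(data)):
                    raise ValidationError("counts must be integers")
                self.counts = self.counts.astype(np.int64)
                data = self.counts.data
            if data.min(initial=0) < 0:
                raise ValidationError("counts must be non-negative")
        if self.normalized is not None:
            self.normalized = np.asarray(self.normalized, dtype=np.float64)
            if self.normalized.shape != self.counts.shape:
                raise ValidationError("normalized layer shape mismatch")
            if not np.all(np.isfinite(self.normalized)):
                raise ValidationError("normalized layer contains non-finite values")
            if self.normalized.min(initial=0.0) < 0:
                raise ValidationError("normalized layer contains negative values")
        self._gene_index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene_indices(self, genes: Iterable[str], *, missing: str = "error") -> np.ndarray:
        """Column indices of ``genes``; ``missing`` is 'error' or 'drop'."""
        idx = []
        absent = []
        for g in genes:
            j = self._gene_index.get(g)
            if j is None:
                absent.append(g)
            else:
                idx.append(j)
        if absent and missing == "error":
            raise ValidationError(f"genes not in matrix: {absent[:10]}")
        return np.asarray(idx, dtype=np.intp)

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        """New CountMatrix restricted to cells selected by a boolean mask
        or integer index array; gene set and layer provenance preserved."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask.astype(np.intp)
        return CountMatrix(
            cells=[self.cells[i] for i in idx],
            genes=self.genes,
            counts=self.counts[idx],
            normalized=None if self.normalized is None else self.normalized[idx],
        )

    def require_normalized(self) -> np.ndarray:
        if self.normalized is None:
            raise ValidationError(
                "operation requires the normalized layer; call preprocess.normalize first"
            )
        return self.normalized

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        if self.cells != other.cells or self.genes != other.genes:
            return False
        if (self.counts != other.counts).nnz != 0:
            return False
        if (self.normalized is None) != (other.normalized is None):
            return False
        if self.normalized is not None:
            return bool(np.allclose(self.normalized, other.normalized))
        return True


@dataclass
class GeneSetCollection:
    """A named collection of gene sets (as parsed from a GMT file).

    ``sets`` maps set name -> ordered unique gene symbols;
    ``descriptions`` carries the GMT description field per set.
    """

    name: str
    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for set_name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {set_name!r} is empty")
            deduped = list(dict.fromkeys(genes))
            self.sets[set_name] = deduped
            self.descriptions.setdefault(set_name, "")

    def __iter__(self):
        return iter(self.sets.items())

    def __len__(self) -> int:
        return len(self.sets)

    def union(self) -> set[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out.update(genes)
        return out


@dataclass(frozen=True)
class DEGRecord:
    """One differentially expressed gene in one (cell type, contrast) stratum.

    ``direction`` is 'up' iff ``log2fc`` > 0; records exist only for genes
    passing both the fold-change and adjusted-p thresholds.
    """

    gene: str
    cell_type: str
    contrast: str
    log2fc: float
    p_value: float
    p_adjusted: float
    direction: str

    def __post_init__(self) -> None:
        expected = "up" if self.log2fc > 0 else "down"
        if self.direction != expected:
            raise ValidationError(
                f"direction {self.direction!r} inconsistent with log2fc {self.log2fc}"
            )
        if not (0.0 <= self.p_value <= 1.0 and 0.0 <= self.p_adjusted <= 1.0):
            raise ValidationError("p-values must lie in [0, 1]")
        if self.p_adjusted < self.p_value - 1e-12:
            raise ValidationError("adjusted p below raw p")


def make_annotation(
    cell_ids: Sequence[str],
    groups: Sequence[str],
    cell_types: Sequence[str] | None = None,
    n_genes_detected: Sequence[int] | None = None,
    pct_mito: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Build a cell annotation table with the pipeline's required columns."""
    n = len(cell_ids)
    df = pd.DataFrame(
        {
            "cell_id": list(cell_ids),
            "group": list(groups),
            "cell_type": list(cell_types) if cell_types is not None else [UNASSIGNED] * n,
            "n_genes_detected": (
                list(n_genes_detected) if n_genes_detected is not None else [0] * n
            ),
            "pct_mito": list(pct_mito) if pct_mito is not None else [0.0] * n,
        }
    )
    return df


def validate_annotation(
    ann: pd.DataFrame,
    cm: CountMatrix | None = None,
    allowed_groups: Sequence[str] | None = GROUPS_FOUR,
) -> None:
    """Check annotation schema, cell correspondence and group labels."""
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValidationError(f"annotation missing columns: {missing}")
    if ann["cell_id"].duplicated().any():
        raise ValidationError("duplicate cell ids in annotation")
    if cm is not None and list(ann["cell_id"]) != list(cm.cells):
        raise ValidationError("annotation cell ids do not match the count matrix")
    if allowed_groups is not None:
        bad = set(ann["group"]) - set(allowed_groups)
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")


def records_to_frame(records: Iterable[DEGRecord]) -> pd.DataFrame:
    """DEG records as a DataFrame in the canonical column order."""
    cols = ["gene", "cell_type", "contrast", "log2fc", "p_value", "p_adjusted", "direction"]
    rows = [dataclasses.asdict(r) for r in records]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows, columns=cols)


def sort_deg_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Canonical deterministic DEG ordering: cell type, contrast,
    ascending adjusted p, then gene symbol."""
    return df.sort_values(
        ["cell_type", "contrast", "p_adjusted", "gene"], kind="mergesort"
    ).reset_index(drop=True)
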