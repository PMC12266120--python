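"""Cell quality control, normalization, and marker-based cell typing.

QC keeps cells with more than ``min_genes`` and fewer than ``max_genes``
detected genes and less than ``max_pct_mito`` percent mitochondrial
counts (all inequalities strict).  Normalization is natural-log
counts-per-``scale`` (CP10K by default).  Cell types are assigned by the
argmax of per-type marker module scores with a minimum winning margin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, GeneSetCollection, UNASSIGNED, ValidationError
from .scoring import module_score


@dataclass(frozen=True)
class QCThresholds:
    """Strict cell-retention bounds on detected genes and mito fraction."""

    min_genes: int = 200
    max_genes: int = 4000
    max_pct_mito: float = 20.0
    mito_prefix: str = "mt-"

    def __post_init__(self) -> None:
        if not self.min_genes < self.max_genes:
            raise ValidationError("min_genes must be below max_genes")
        if not 0.0 < self.max_pct_mito <= 100.0:
            raise ValidationError("max_pct_mito must lie in (0, 100]")


def compute_qc_metrics(
    cm: CountMatrix, mito_prefix: str = "mt-"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell detected-gene counts and mitochondrial count percentage,
    both computed on raw counts."""
    n_detected = np.asarray((cm.counts > 0).sum(axis=1)).ravel()
    totals = np.asarray(cm.counts.sum(axis=1)).ravel().astype(np.float64)
    mito_cols = np.array([g.startswith(mito_prefix) for g in cm.genes])
    if mito_cols.any():
        mito_counts = np.asarray(cm.counts[:, mito_cols].sum(axis=1)).ravel()
    else:
        mito_counts = np.zeros(cm.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(totals > 0, 100.0 * mito_counts / totals, 0.0)
    return n_detected.astype(np.int64), pct


def qc_filter(
    cm: CountMatrix, ann: pd.DataFrame, th: QCThresholds = QCThresholds()
) -> tuple[CountMatrix, pd.DataFrame]:
    """Retain cells passing all three strict QC inequalities.

    The annotation is updated with freshly computed ``n_genes_detected``
    and ``pct_mito``; the gene set is unchanged.  Raises if no cell
    passes rather than returning an empty success.
    """
    if list(ann["cell_id"]) != list(cm.cells):
        raise ValidationError("annotation cells do not match matrix cells")
    n_detected, pct_mito = compute_qc_metrics(cm, th.mito_prefix)
    keep = (
        (n_detected > th.min_genes)
        & (n_detected < th.max_genes)
        & (pct_mito < th.max_pct_mito)
    )
    if not keep.any():
        raise ValidationError("no cells pass QC")
    ann = ann.copy()
    ann["n_genes_detected"] = n_detected
    ann["pct_mito"] = pct_mito
    ann = ann.loc[keep].reset_index(drop=True)
    return cm.subset_cells(keep), ann


def normalize(cm: CountMatrix, scale: float = 1e4) -> CountMatrix:
    """Attach the natural-log counts-per-``scale`` layer.

    normalized[c, g] = log(1 + scale * count[c, g] / total[c]); cells
    with zero total counts are rejected by name.
    """
    totals = np.asarray(cm.counts.sum(axis=1)).ravel().astype(np.float64)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = [cm.cells[i] for i in zero[:5]]
        raise ValidationError(f"cells with zero total counts: {names}")
    dense = cm.counts.toarray().astype(np.float64)
    layer = np.log1p(scale * dense / totals[:, None])
    return CountMatrix(cells=cm.cells, genes=cm.genes, counts=cm.counts, normalized=layer)


def assign_cell_types(
    cm: CountMatrix,
    markers: GeneSetCollection,
    min_margin: float = 0.05,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Assign each cell the marker set with the highest module score.

    Cells whose top score beats the runner-up by less than ``min_margin``
    are labelled unassigned; with a single candidate type the runner-up
    is -inf so every cell is assigned.  Candidate types are evaluated in
    lexicographic order, which also breaks exact ties.

    Returns a DataFrame (cell_id, cell_type, score, margin).
    """
    type_names = sorted(markers.sets)
    if not type_names:
        raise ValidationError("empty marker collection")
    score_mat = np.empty((cm.n_cells, len(type_names)))
    for j, t in enumerate(type_names):
        res = module_score(
            cm, markers.sets[t], set_name=t, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed
        )
        score_mat[:, j] = res.scores
    best = np.argmax(score_mat, axis=1)  # first max wins -> lexicographic tie-break
    best_score = score_mat[np.arange(cm.n_cells), best]
    if len(type_names) == 1:
        runner_up = np.full(cm.n_cells, -np.inf)
    else:
        tmp = score_mat.copy()
        tmp[np.arange(cm.n_cells), best] = -np.inf
        runner_up = tmp.max(axis=1)
    margin = best_score - runner_up
    assigned = np.where(
        margin >= min_margin, np.asarray(type_names, dtype=object)[best], UNASSIGNED
    )
    return pd.DataFrame(
        {
            "cell_id": cm.cells,
            "cell_type": assigned,
            "score": best_score,
            "margin": margin,
        }
    )
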