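"""Per-cell-type, per-contrast differential expression.

Each (cell type, contrast) stratum is one test family: every gene
detected in enough cells of either group is tested with the two-sided
Wilcoxon rank-sum test on normalized expression, fold changes are the
ratio of back-transformed group means with a pseudocount, and BH
adjustment is applied within the stratum.  Records are kept only when
|log2FC| > fc_threshold and adjusted p < alpha, both strict.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, DEGRecord, ValidationError
from .stats import (
    EXACT_ENUMERATION_LIMIT,
    bh_adjust,
    log2_fold_change_bulk,
    rank_sum_test,
    rank_sum_test_bulk,
)

#: The three HP contrasts: name -> (case group, control group).
CONTRASTS = {
    "Aged": ("Aiso", "Yiso"),
    "Ahet": ("Ahet", "Aiso"),
    "Yhet": ("Yhet", "Yiso"),
}


@dataclass(frozen=True)
class ContrastSpec:
    """A named case-vs-control group comparison."""

    name: str
    case_group: str
    control_group: str

    def __post_init__(self) -> None:
        if self.case_group == self.control_group:
            raise ValidationError("case and control groups must differ")

    @classmethod
    def from_name(cls, name: str) -> "ContrastSpec":
        if name not in CONTRASTS:
            raise ValidationError(
                f"unknown contrast {name!r}; expected one of {sorted(CONTRASTS)}"
            )
        case, control = CONTRASTS[name]
        return cls(name=name, case_group=case, control_group=control)


def de_stats(
    cm: CountMatrix,
    ann: pd.DataFrame,
    contrast: ContrastSpec,
    cell_type: str,
    min_cells: int = 3,
    pseudo: float = 1.0,
    exact_limit: int = EXACT_ENUMERATION_LIMIT,
) -> pd.DataFrame:
    """Full per-gene statistics for one (cell type, contrast) stratum.

    Returns a DataFrame (gene, log2fc, p_value) over all tested genes,
    i.e. genes with a positive count in at least ``min_cells`` cells of
    either group.  No thresholding, no multiplicity adjustment.
    """
    X = cm.require_normalized()
    if list(ann["cell_id"]) != list(cm.cells):
        raise ValidationError("annotation cells do not match matrix cells")
    in_type = (ann["cell_type"] == cell_type).to_numpy()
    case_mask = in_type & (ann["group"] == contrast.case_group).to_numpy()
    ctrl_mask = in_type & (ann["group"] == contrast.control_group).to_numpy()
    m, n = int(case_mask.sum()), int(ctrl_mask.sum())
    for label, count in ((contrast.case_group, m), (contrast.control_group, n)):
        if count < min_cells:
            raise ValidationError(
                f"insufficient cells: group {label!r} has {count} cells of "
                f"type {cell_type!r} (need >= {min_cells})"
            )
    counts_case = cm.counts[case_mask]
    counts_ctrl = cm.counts[ctrl_mask]
    detected = (
        (np.asarray((counts_case > 0).sum(axis=0)).ravel() >= min_cells)
        | (np.asarray((counts_ctrl > 0).sum(axis=0)).ravel() >= min_cells)
    )
    gene_idx = np.flatnonzero(detected)
    if gene_idx.size == 0:
        return pd.DataFrame(columns=["gene", "log2fc", "p_value"])
    Xc = X[np.ix_(case_mask, gene_idx)]
    Xk = X[np.ix_(ctrl_mask, gene_idx)]
    lfc = log2_fold_change_bulk(Xc, Xk, pseudo=pseudo)
    if comb(m + n, m) <= exact_limit:
        pvals = np.array(
            [rank_sum_test(Xc[:, j], Xk[:, j], exact_limit=exact_limit)[1]
             for j in range(gene_idx.size)]
        )
    else:
        _, pvals = rank_sum_test_bulk(Xc, Xk)
    return pd.DataFrame(
        {
            "gene": [cm.genes[i] for i in gene_idx],
            "log2fc": lfc,
            "p_value": pvals,
        }
    )


def find_degs(
    cm: CountMatrix,
    ann: pd.DataFrame,
    contrast: ContrastSpec | str,
    cell_type: str,
    fc_threshold: float = 0.25,
    alpha: float = 0.05,
    min_cells: int = 3,
    pseudo: float = 1.0,
    exact_limit: int = EXACT_ENUMERATION_LIMIT,
) -> list[DEGRecord]:
    """DEGs of one (cell type, contrast) stratum at the strict
    |log2FC| > fc_threshold and BH-adjusted p < alpha criteria."""
    if isinstance(contrast, str):
        contrast = ContrastSpec.from_name(contrast)
    stats = de_stats(
        cm, ann, contrast, cell_type,
        min_cells=min_cells, pseudo=pseudo, exact_limit=exact_limit,
    )
    if stats.empty:
        return []
    padj = bh_adjust(stats["p_value"].to_numpy())
    records = []
    for (gene, lfc, p), q in zip(
        stats.itertuples(index=False), padj
    ):
        if abs(lfc) > fc_threshold and q < alpha:
            records.append(
                DEGRecord(
                    gene=gene,
                    cell_type=cell_type,
                    contrast=contrast.name,
                    log2fc=float(lfc),
                    p_value=float(p),
                    p_adjusted=float(q),
                    direction="up" if lfc > 0 else "down",
                )
            )
    return records


def find_all_degs(
    cm: CountMatrix,
    ann: pd.DataFrame,
    contrasts: list[str] | None = None,
    cell_types: list[str] | None = None,
    global_correction: bool = False,
    fc_threshold: float = 0.25,
    alpha: float = 0.05,
    min_cells: int = 3,
    pseudo: float = 1.0,
) -> dict[tuple[str, str], list[DEGRecord]]:
    """DEGs for every (cell type, contrast) stratum with enough cells.

    By default BH runs within each stratum; ``global_correction`` pools
    every tested (gene, stratum) p-value into one family first.  Strata
    where either group falls below ``min_cells`` are skipped silently
    (they carry no testable information); returns a mapping
    (cell_type, contrast name) -> records.
    """
    if contrasts is None:
        contrasts = list(CONTRASTS)
    if cell_types is None:
        cell_types = sorted(t for t in ann["cell_type"].unique() if t != "unassigned")
    if not global_correction:
        out: dict[tuple[str, str], list[DEGRecord]] = {}
        for ct in cell_types:
            for cname in contrasts:
                try:
                    out[(ct, cname)] = find_degs(
                        cm, ann, cname, ct,
                        fc_threshold=fc_threshold, alpha=alpha,
                        min_cells=min_cells, pseudo=pseudo,
                    )
                except ValidationError as exc:
                    if "insufficient cells" in str(exc):
                        continue
                    raise
        return out

    stats_by_stratum: dict[tuple[str, str], pd.DataFrame] = {}
    for ct in cell_types:
        for cname in contrasts:
            try:
                stats_by_stratum[(ct, cname)] = de_stats(
                    cm, ann, ContrastSpec.from_name(cname), ct,
                    min_cells=min_cells, pseudo=pseudo,
                )
            except ValidationError as exc:
                if "insufficient cells" in str(exc):
                    continue
                raise
    pooled = np.concatenate(
        [df["p_value"].to_numpy() for df in stats_by_stratum.values()]
    ) if stats_by_stratum else np.array([])
    padj_all = bh_adjust(pooled)
    out = {}
    offset = 0
    for (ct, cname), df in stats_by_stratum.items():
        records = []
        padj = padj_all[offset : offset + len(df)]
        offset += len(df)
        for (gene, lfc, p), q in zip(df.itertuples(index=False), padj):
            if abs(lfc) > fc_threshold and q < alpha:
                records.append(
                    DEGRecord(
                        gene=gene, cell_type=ct, contrast=cname,
                        log2fc=float(lfc), p_value=float(p),
                        p_adjusted=float(q),
                        direction="up" if lfc > 0 else "down",
                    )
                )
        out[(ct, cname)] = records
    return out


def n_tested_genes(
    cm: CountMatrix,
    ann: pd.DataFrame,
    contrast: ContrastSpec | str,
    cell_type: str,
    min_cells: int = 3,
) -> int:
    """Number of genes entering the test family of a stratum (the BH
    denominator and the enrichment universe size)."""
    if isinstance(contrast, str):
        contrast = ContrastSpec.from_name(contrast)
    return len(de_stats(cm, ann, contrast, cell_type, min_cells=min_cells))
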