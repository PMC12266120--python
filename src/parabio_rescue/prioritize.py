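"""Candidate rejuvenation-gene prioritization.

Pooled PR-DEGs are intersected with curated aging gene-set collections
(verbatim symbol matching), then ranked by the number of distinct cell
types in whose DEG tables each overlapping gene appears — a gene that
recurs across many cell types is a stronger systemic candidate.  A
hypergeometric over-representation test against an expressed-gene
universe serves generic enrichment of any gene list.
"""

from __future__ import annotations

import warnings
from math import comb

import pandas as pd

from .datatypes import DEGRecord, GeneSetCollection, ValidationError


def overlap_with_collections(
    pr_genes: set[str],
    collections: list[GeneSetCollection],
) -> dict[str, list[tuple[str, str]]]:
    """Genes of ``pr_genes`` found in any collection set, with full
    provenance: gene -> [(collection name, set name), ...].

    Matching is verbatim, case-sensitive symbol equality.
    """
    if not collections:
        raise ValidationError("no collections supplied")
    if not pr_genes:
        warnings.warn("empty PR gene set; overlap is empty", stacklevel=2)
        return {}
    out: dict[str, list[tuple[str, str]]] = {}
    for coll in collections:
        for set_name, genes in coll.sets.items():
            members = set(genes)
            for g in sorted(pr_genes & members):
                out.setdefault(g, []).append((coll.name, set_name))
    return out


def frequency_rank(
    overlap: dict[str, list[tuple[str, str]]],
    deg_tables: dict[str, list[DEGRecord]],
) -> pd.DataFrame:
    """Rank overlap genes by cross-cell-type DEG frequency.

    ``deg_tables`` maps cell type -> its DEG records in the configured
    contrast scope; a gene hit in several contrasts of one cell type
    still counts that cell type once.  Ties are broken by the summed
    |log2FC| over the gene's records, then by gene symbol, so the table
    is fully deterministic.
    """
    rows = []
    for gene in sorted(overlap):
        hit_types = []
        tie_break = 0.0
        for cell_type in sorted(deg_tables):
            recs = [r for r in deg_tables[cell_type] if r.gene == gene]
            if recs:
                hit_types.append(cell_type)
                tie_break += sum(abs(r.log2fc) for r in recs)
        if not hit_types:
            continue
        rows.append(
            {
                "gene": gene,
                "n_cell_types": len(hit_types),
                "cell_types": ",".join(hit_types),
                "collections_hit": ",".join(
                    sorted({f"{coll}:{s}" for coll, s in overlap[gene]})
                ),
                "tie_break_score": tie_break,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["gene", "n_cell_types", "cell_types", "collections_hit", "tie_break_score"],
    )
    if df.empty:
        return df
    return df.sort_values(
        ["n_cell_types", "tie_break_score", "gene"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)


def hypergeom_enrich(
    query: set[str],
    annotation_set: set[str],
    universe: set[str],
) -> tuple[int, float]:
    """Upper-tail hypergeometric over-representation p-value.

    With N = |universe|, K = |annotation_set ∩ universe|, n = |query|
    and k the observed overlap, returns (k, P(X >= k)) by exact integer
    summation of the hypergeometric mass.
    """
    offenders = sorted(query - universe)
    if offenders:
        raise ValidationError(f"query genes outside the universe: {offenders[:10]}")
    N = len(universe)
    K = len(annotation_set & universe)
    n = len(query)
    k = len(query & annotation_set)
    if N == 0:
        raise ValidationError("empty universe")
    numerator = sum(
        comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1)
    )
    denominator = comb(N, n)
    return k, numerator / denominator
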