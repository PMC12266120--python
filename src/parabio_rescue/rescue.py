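"""Prorejuvenative / progeronic DEG classification and responsiveness.

A gene differentially expressed with aging (Aged-DEG, Aiso vs Yiso) is
*prorejuvenative* (PR) when heterochronic exposure moves it back — it is
also an Ahet-DEG (Ahet vs Aiso) and, in the default strict mode, with
the opposite direction.  It is *progeronic* (PG) when young parabionts
recapitulate it — also a Yhet-DEG (Yhet vs Yiso), in strict mode with
the concordant direction.  Loose mode keeps the plain intersections.
Per-cell-type percentages of PR- and PG-DEGs among Aged-DEGs quantify
each cell type's responsiveness to the shared circulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import DEGRecord, ValidationError

MODES = ("strict", "loose")


def _directions(records: list[DEGRecord]) -> dict[str, str]:
    out: dict[str, str] = {}
    for r in records:
        out[r.gene] = r.direction
    return out


def _check_same_type(*record_lists: list[DEGRecord]) -> str | None:
    types = {r.cell_type for records in record_lists for r in records}
    if len(types) > 1:
        raise ValidationError(f"mixed cell types across DEG inputs: {sorted(types)}")
    return next(iter(types)) if types else None


@dataclass
class RescueClassification:
    """PR/PG classification of one cell type's DEG tables.

    ``pr_degs``/``pg_degs`` map gene -> (aging direction, HP direction);
    percentages are relative to the Aged-DEG count and undefined (NaN,
    flagged) when there are no Aged-DEGs.
    """

    cell_type: str
    mode: str
    pr_degs: dict[str, tuple[str, str]] = field(default_factory=dict)
    pg_degs: dict[str, tuple[str, str]] = field(default_factory=dict)
    n_aged: int = 0

    @property
    def pct_pr(self) -> float:
        return 100.0 * len(self.pr_degs) / self.n_aged if self.n_aged else float("nan")

    @property
    def pct_pg(self) -> float:
        return 100.0 * len(self.pg_degs) / self.n_aged if self.n_aged else float("nan")

    @property
    def pct_defined(self) -> bool:
        return self.n_aged > 0


def classify_rescued(
    aged: list[DEGRecord],
    ahet: list[DEGRecord],
    mode: str = "strict",
) -> dict[str, tuple[str, str]]:
    """PR-DEGs: genes in both the Aged and Ahet tables.

    Strict mode additionally requires opposite directions (up with aging
    and down after HP, or vice versa); loose mode is the plain
    intersection.  Returns gene -> (aging direction, HP direction).
    """
    if mode not in MODES:
        raise ValidationError(f"mode must be one of {MODES}")
    _check_same_type(aged, ahet)
    aged_dir = _directions(aged)
    ahet_dir = _directions(ahet)
    out: dict[str, tuple[str, str]] = {}
    for gene, d_aging in aged_dir.items():
        d_hp = ahet_dir.get(gene)
        if d_hp is None:
            continue
        if mode == "loose" or d_hp != d_aging:
            out[gene] = (d_aging, d_hp)
    return out


def classify_progeronic(
    aged: list[DEGRecord],
    yhet: list[DEGRecord],
    mode: str = "strict",
) -> dict[str, tuple[str, str]]:
    """PG-DEGs: genes in both the Aged and Yhet tables; strict mode
    requires concordant directions (the young retina moves toward the
    aged state)."""
    if mode not in MODES:
        raise ValidationError(f"mode must be one of {MODES}")
    _check_same_type(aged, yhet)
    aged_dir = _directions(aged)
    yhet_dir = _directions(yhet)
    out: dict[str, tuple[str, str]] = {}
    for gene, d_aging in aged_dir.items():
        d_hp = yhet_dir.get(gene)
        if d_hp is None:
            continue
        if mode == "loose" or d_hp == d_aging:
            out[gene] = (d_aging, d_hp)
    return out


def classify_cell_type(
    aged: list[DEGRecord],
    ahet: list[DEGRecord],
    yhet: list[DEGRecord],
    mode: str = "strict",
) -> RescueClassification:
    """Full PR/PG classification for one cell type."""
    cell_type = _check_same_type(aged, ahet, yhet) or "unknown"
    return RescueClassification(
        cell_type=cell_type,
        mode=mode,
        pr_degs=classify_rescued(aged, ahet, mode),
        pg_degs=classify_progeronic(aged, yhet, mode),
        n_aged=len({r.gene for r in aged}),
    )


def responsiveness(classifications: list[RescueClassification]) -> pd.DataFrame:
    """Ranked per-cell-type responsiveness table.

    Sorted by pct_pr descending with lexicographic tie-break; cell types
    without Aged-DEGs are listed last with pct columns NaN and
    ``pct_defined`` False.
    """
    if not classifications:
        raise ValidationError("no classifications supplied")
    rows = [
        {
            "cell_type": c.cell_type,
            "n_aged": c.n_aged,
            "n_pr": len(c.pr_degs),
            "n_pg": len(c.pg_degs),
            "pct_pr": c.pct_pr,
            "pct_pg": c.pct_pg,
            "pct_defined": c.pct_defined,
            "mode": c.mode,
        }
        for c in classifications
    ]
    df = pd.DataFrame(rows)
    defined = df[df["pct_defined"]].sort_values(
        ["pct_pr", "cell_type"], ascending=[False, True], kind="mergesort"
    )
    undefined = df[~df["pct_defined"]].sort_values("cell_type", kind="mergesort")
    return pd.concat([defined, undefined]).reset_index(drop=True)


def pr_gene_union(classifications: list[RescueClassification]) -> set[str]:
    """PR-DEGs pooled over cell types (the 'whole retina' PR gene set)."""
    out: set[str] = set()
    for c in classifications:
        out.update(c.pr_degs)
    return out
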