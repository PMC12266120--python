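"""Synthetic four-group single-cell count data with planted ground truth.

The generator emulates the statistical structure of a heterochronic
parabiosis (HP) experiment: cells of several types from four groups
(Yiso, Aiso, Yhet, Ahet), cell-type marker programs, per-type aging
programs that shift expression in aged animals, a partial *rescue* of
those programs in heterochronic aged animals (Ahet) and a partial
*acceleration* in heterochronic young animals (Yhet).  A designated hub
gene recurs in the aging program of several cell types and in a planted
"aging database" gene set, so candidate prioritization has a known
answer.

Counts are gamma-Poisson (negative binomial) with a single global
inverse-dispersion; per-cell depth is log-normal; all group/type effects
are additive on log2 mean expression before depth scaling, so planted
effects are directly interpretable as expected log2 fold changes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as pio
from .datatypes import (
    CountMatrix,
    GROUPS_FOUR,
    GeneSetCollection,
    ValidationError,
    make_annotation,
)

QC_OK = "none"
QC_LOW_GENES = "low_genes"
QC_HIGH_MITO = "high_mito"


def _as_per_type(value, cell_types: Sequence[str], name: str) -> dict[str, float]:
    """Broadcast a scalar or per-type mapping/sequence to a per-type dict."""
    if isinstance(value, Mapping):
        out = {t: float(value[t]) for t in cell_types}
    elif isinstance(value, (list, tuple, np.ndarray)):
        if len(value) != len(cell_types):
            raise ValidationError(f"{name}: expected {len(cell_types)} per-type values")
        out = {t: float(v) for t, v in zip(cell_types, value)}
    else:
        out = {t: float(value) for t in cell_types}
    for t, v in out.items():
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"{name}[{t}] = {v} outside [0, 1]")
    return out


@dataclass
class GeneratorParams:
    """Configuration of the synthetic HP dataset.

    Effects are log2 offsets on mean expression.  ``rescue_fraction`` is
    the fraction of each aging program reverted in Ahet and
    ``rescue_magnitude`` the fraction of the aging effect removed on that
    subset; ``accel_*`` are the analogous Yhet knobs.  Both fractions
    accept a scalar or a per-cell-type mapping.  The hub gene is planted,
    down-regulated with aging and always rescued, in ``hub_n_types``
    cell types.
    """

    n_cell_types: int = 3
    cells_per_group_per_type: int = 200
    n_genes: int = 1500
    markers_per_type: int = 20
    marker_log2_effect: float = 2.0
    aging_genes_per_type: int = 100
    aging_log2_effect: float = 1.0
    rescue_fraction: float | Mapping[str, float] | Sequence[float] = 0.5
    rescue_magnitude: float = 1.0
    accel_fraction: float | Mapping[str, float] | Sequence[float] = 0.5
    accel_magnitude: float = 1.0
    hub_gene: str = "Hub1"
    hub_n_types: int | None = None
    n_shared_aging_genes: int = 10
    shared_gene_n_types: int = 3
    dispersion: float = 10.0
    mean_depth: float = 5000.0
    libsize_sigma: float = 0.35
    baseline_log10_cp10k: tuple[float, float] = (-1.3, 2.3)
    program_quantile_band: tuple[float, float] = (0.70, 0.98)
    mito_gene_fraction: float = 0.02
    mito_expression_fraction: float = 0.05
    lowq_cell_fraction: float = 0.0
    lowq_genes_kept: int = 150
    himito_cell_fraction: float = 0.0
    himito_boost: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cell_types < 1 or self.cells_per_group_per_type < 1:
            raise ValidationError("cell counts must be positive")
        if self.n_genes < 10:
            raise ValidationError("n_genes too small")
        if self.dispersion <= 0 or self.mean_depth <= 0 or self.libsize_sigma < 0:
            raise ValidationError("count parameters must be positive")
        if self.marker_log2_effect < 0 or self.markers_per_type < 1:
            raise ValidationError("marker configuration invalid")
        for frac in (
            self.mito_gene_fraction,
            self.mito_expression_fraction,
            self.lowq_cell_fraction,
            self.himito_cell_fraction,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValidationError("fractions must lie in [0, 1]")
        _as_per_type(self.rescue_fraction, self.cell_types, "rescue_fraction")
        _as_per_type(self.accel_fraction, self.cell_types, "accel_fraction")
        if not 0.0 <= self.rescue_magnitude <= 1.0:
            raise ValidationError("rescue_magnitude must lie in [0, 1]")
        if not 0.0 <= self.accel_magnitude <= 1.0:
            raise ValidationError("accel_magnitude must lie in [0, 1]")
        hub_k = self.hub_n_types if self.hub_n_types is not None else self.n_cell_types
        if not 0 <= hub_k <= self.n_cell_types:
            raise ValidationError("hub_n_types outside [0, n_cell_types]")

    @property
    def cell_types(self) -> list[str]:
        return [f"T{i + 1}" for i in range(self.n_cell_types)]


@dataclass
class GroundTruth:
    """Planted structure of a generated dataset.

    ``aging_effects[type][gene]`` is the signed log2 aging offset;
    ``rescued``/``accelerated`` are the per-type gene subsets whose Ahet
    (resp. Yhet) offset is the planted reversion (resp. recapitulation)
    of the aging effect.
    """

    params: GeneratorParams
    markers: dict[str, list[str]]
    aging_effects: dict[str, dict[str, float]]
    rescued: dict[str, set[str]]
    accelerated: dict[str, set[str]]
    hub_gene: str
    hub_types: list[str]
    aging_db_genes: list[str]
    cell_truth: pd.DataFrame  # cell_id, true_type, group, planted_qc_fail

    def ahet_effect(self, cell_type: str, gene: str) -> float:
        a = self.aging_effects.get(cell_type, {}).get(gene, 0.0)
        if gene in self.rescued.get(cell_type, set()):
            return -self.params.rescue_magnitude * a
        return 0.0

    def yhet_effect(self, cell_type: str, gene: str) -> float:
        a = self.aging_effects.get(cell_type, {}).get(gene, 0.0)
        if gene in self.accelerated.get(cell_type, set()):
            return self.params.accel_magnitude * a
        return 0.0

    def membership(self, cell_type: str, gene: str) -> str:
        if gene in self.markers.get(cell_type, []):
            return "marker"
        if gene in self.aging_effects.get(cell_type, {}):
            return "aging"
        return "background"

    def marker_collection(self) -> GeneSetCollection:
        return GeneSetCollection(
            name="markers",
            sets={t: list(genes) for t, genes in self.markers.items()},
            descriptions={t: f"planted markers of {t}" for t in self.markers},
        )

    def aging_collection(self, name: str = "aging_db") -> GeneSetCollection:
        return GeneSetCollection(
            name=name,
            sets={name: list(self.aging_db_genes)},
            descriptions={name: "planted aging-database gene list"},
        )

    def program_genes(self, cell_type: str, direction: str | None = None) -> list[str]:
        """Aging-program genes of a type, optionally only 'up' or 'down'."""
        effects = self.aging_effects.get(cell_type, {})
        if direction is None:
            return sorted(effects)
        want_up = direction == "up"
        return sorted(g for g, e in effects.items() if (e > 0) == want_up)

    def to_frame(self) -> pd.DataFrame:
        """Long per-(gene, cell type) table of planted memberships/effects."""
        rows = []
        for t in self.params.cell_types:
            planted = set(self.markers.get(t, [])) | set(self.aging_effects.get(t, {}))
            for g in sorted(planted):
                rows.append(
                    {
                        "gene": g,
                        "cell_type": t,
                        "membership": self.membership(t, g),
                        "aging_effect": self.aging_effects.get(t, {}).get(g, 0.0),
                        "ahet_effect": self.ahet_effect(t, g),
                        "yhet_effect": self.yhet_effect(t, g),
                    }
                )
        return pd.DataFrame(
            rows,
            columns=["gene", "cell_type", "membership", "aging_effect", "ahet_effect", "yhet_effect"],
        )


def _build_genes(params: GeneratorParams, rng: np.random.Generator):
    """Gene names, baseline relative expression, and structural gene picks."""
    G = params.n_genes
    lo, hi = params.baseline_log10_cp10k
    base_cp10k = 10.0 ** rng.uniform(lo, hi, size=G)
    names = [f"Gene{i + 1:04d}" for i in range(G)]

    n_mito = int(round(params.mito_gene_fraction * G))
    mito_idx = rng.choice(G, size=n_mito, replace=False) if n_mito else np.array([], dtype=int)
    for i in mito_idx:
        names[i] = "mt-" + names[i]
    # scale mito genes so they carry the configured share of expression
    if n_mito and params.mito_expression_fraction > 0:
        non_mito_sum = base_cp10k.sum() - base_cp10k[mito_idx].sum()
        target = non_mito_sum * params.mito_expression_fraction / (
            1.0 - params.mito_expression_fraction
        )
        base_cp10k[mito_idx] *= target / base_cp10k[mito_idx].sum()

    # rescale so baseline values are true counts-per-10k
    base_cp10k *= 1e4 / base_cp10k.sum()

    # program-eligible genes: a quantile band of baseline expression among
    # non-mito genes -- well expressed (fold changes are estimable against
    # the pseudocount) but not the extreme top of the distribution
    qlo, qhi = params.program_quantile_band
    non_mito = np.array([i for i in range(G) if i not in set(mito_idx)])
    order = non_mito[np.argsort(base_cp10k[non_mito], kind="mergesort")]
    lo, hi = int(np.floor(qlo * order.size)), int(np.ceil(qhi * order.size))
    eligible = order[lo:hi]
    return names, base_cp10k, mito_idx, eligible


def _plant_programs(params: GeneratorParams, rng: np.random.Generator, names, eligible):
    """Choose marker/aging/hub genes and their planted signed effects."""
    types = params.cell_types
    pool = list(rng.permutation(eligible))
    need_markers = params.markers_per_type * len(types)
    hub_k = params.hub_n_types if params.hub_n_types is not None else len(types)
    need_aging = params.aging_genes_per_type * len(types) + params.n_shared_aging_genes + 1
    if len(pool) < need_markers + need_aging:
        raise ValidationError(
            "not enough genes in the program expression band; increase n_genes "
            "or widen program_quantile_band"
        )

    markers: dict[str, list[str]] = {}
    for t in types:
        idx = [pool.pop() for _ in range(params.markers_per_type)]
        markers[t] = [names[i] for i in idx]

    hub_idx = pool.pop()
    names[hub_idx] = params.hub_gene
    hub_types = list(types[:hub_k])

    shared_n_types = min(params.shared_gene_n_types, len(types))
    shared: list[tuple[str, list[str]]] = []
    for _ in range(params.n_shared_aging_genes):
        i = pool.pop()
        member_types = [types[j] for j in rng.choice(len(types), size=shared_n_types, replace=False)]
        shared.append((names[i], member_types))

    aging_effects: dict[str, dict[str, float]] = {t: {} for t in types}
    sign_of: dict[str, float] = {}
    for t in types:
        own = [names[pool.pop()] for _ in range(params.aging_genes_per_type)]
        for j, g in enumerate(own):
            # 1:2 up:down mix keeps total transcriptome mass roughly constant
            # across groups (a doubled gene adds what two halved genes remove),
            # so planted offsets are realized as unbiased expected log2FC
            aging_effects[t][g] = params.aging_log2_effect * (1.0 if j % 3 == 0 else -1.0)
    for g, member_types in shared:
        s = sign_of.setdefault(g, 1.0 if rng.random() < 0.5 else -1.0)
        for t in member_types:
            aging_effects[t][g] = params.aging_log2_effect * s
    for t in hub_types:
        # the hub is a rejuvenation target: expression falls with age
        aging_effects[t][params.hub_gene] = -params.aging_log2_effect
    return markers, aging_effects, hub_types


def _plant_subsets(params: GeneratorParams, rng: np.random.Generator, aging_effects, hub_types):
    types = params.cell_types
    rescue_frac = _as_per_type(params.rescue_fraction, types, "rescue_fraction")
    accel_frac = _as_per_type(params.accel_fraction, types, "accel_fraction")
    rescued: dict[str, set[str]] = {}
    accelerated: dict[str, set[str]] = {}
    for t in types:
        genes = sorted(aging_effects[t])
        n_res = int(round(rescue_frac[t] * len(genes)))
        n_acc = int(round(accel_frac[t] * len(genes)))
        rescued[t] = set(rng.choice(genes, size=n_res, replace=False)) if n_res else set()
        accelerated[t] = set(rng.choice(genes, size=n_acc, replace=False)) if n_acc else set()
        # the hub gene is the planted rejuvenation target: always rescued
        if t in hub_types and params.hub_gene in aging_effects[t] and n_res:
            if params.hub_gene not in rescued[t]:
                dropped = sorted(rescued[t] - {params.hub_gene})[0]
                rescued[t].discard(dropped)
                rescued[t].add(params.hub_gene)
    return rescued, accelerated


def generate_dataset(
    params: GeneratorParams,
) -> tuple[CountMatrix, pd.DataFrame, GroundTruth]:
    """Draw a synthetic HP dataset; deterministic for fixed params.

    Returns the raw count matrix (cells x genes), the cell annotation
    table (group and true cell type filled in; QC metrics left for the
    preprocessing stage), and the planted ground truth.
    """
    rng = np.random.default_rng(params.seed)
    types = params.cell_types
    names, base_cp10k, mito_idx, eligible = _build_genes(params, rng)
    markers, aging_effects, hub_types = _plant_programs(params, rng, names, eligible)
    rescued, accelerated = _plant_subsets(params, rng, aging_effects, hub_types)

    name_to_idx = {g: i for i, g in enumerate(names)}
    G = params.n_genes
    base_frac = base_cp10k / base_cp10k.sum()

    # Per-(type, group) log2 offset vectors over genes.
    offsets: dict[tuple[str, str], np.ndarray] = {}
    for t in types:
        marker_off = np.zeros(G)
        for g in markers[t]:
            marker_off[name_to_idx[g]] = params.marker_log2_effect
        aging_off = np.zeros(G)
        ahet_off = np.zeros(G)
        yhet_off = np.zeros(G)
        for g, e in aging_effects[t].items():
            j = name_to_idx[g]
            aging_off[j] = e
            if g in rescued[t]:
                ahet_off[j] = -params.rescue_magnitude * e
            if g in accelerated[t]:
                yhet_off[j] = params.accel_magnitude * e
        offsets[(t, "Yiso")] = marker_off
        offsets[(t, "Aiso")] = marker_off + aging_off
        offsets[(t, "Ahet")] = marker_off + aging_off + ahet_off
        offsets[(t, "Yhet")] = marker_off + yhet_off

    n_per = params.cells_per_group_per_type
    blocks = []
    cell_ids: list[str] = []
    cell_types_col: list[str] = []
    groups_col: list[str] = []
    for t in types:
        for grp in GROUPS_FOUR:
            mean_rel = base_frac * np.exp2(offsets[(t, grp)])
            lib = params.mean_depth * np.exp(
                rng.normal(-0.5 * params.libsize_sigma**2, params.libsize_sigma, size=n_per)
            )
            mu = lib[:, None] * mean_rel[None, :]
            if np.any(mu.sum(axis=1) <= 0):
                raise ValidationError("parameters imply non-positive cell means")
            lam = rng.gamma(params.dispersion, mu / params.dispersion)
            blocks.append(rng.poisson(lam).astype(np.int64))
            start = len(cell_ids)
            cell_ids.extend(f"{t}_{grp}_c{start + i + 1:05d}" for i in range(n_per))
            cell_types_col.extend([t] * n_per)
            groups_col.extend([grp] * n_per)

    counts = np.vstack(blocks)
    n_cells = counts.shape[0]

    qc_fail = np.array([QC_OK] * n_cells, dtype=object)
    if params.lowq_cell_fraction > 0:
        n_low = int(round(params.lowq_cell_fraction * n_cells))
        low_idx = rng.choice(n_cells, size=n_low, replace=False)
        for i in low_idx:
            keep = rng.choice(G, size=min(params.lowq_genes_kept, G), replace=False)
            mask = np.ones(G, dtype=bool)
            mask[keep] = False
            counts[i, mask] = 0
            qc_fail[i] = QC_LOW_GENES
    if params.himito_cell_fraction > 0 and mito_idx.size:
        candidates = np.flatnonzero(qc_fail == QC_OK)
        n_hi = int(round(params.himito_cell_fraction * n_cells))
        hi_idx = rng.choice(candidates, size=n_hi, replace=False)
        for i in hi_idx:
            boosted = rng.poisson(counts[i, mito_idx] * params.himito_boost + 1.0)
            counts[i, mito_idx] = counts[i, mito_idx] + boosted
            qc_fail[i] = QC_HIGH_MITO

    cm = CountMatrix(cells=cell_ids, genes=names, counts=counts)
    ann = make_annotation(cell_ids, groups_col, cell_types_col)
    aging_db = _aging_db_genes(params, rng, aging_effects, names)
    truth = GroundTruth(
        params=params,
        markers=markers,
        aging_effects=aging_effects,
        rescued=rescued,
        accelerated=accelerated,
        hub_gene=params.hub_gene,
        hub_types=hub_types,
        aging_db_genes=aging_db,
        cell_truth=pd.DataFrame(
            {
                "cell_id": cell_ids,
                "true_type": cell_types_col,
                "group": groups_col,
                "planted_qc_fail": qc_fail,
            }
        ),
    )
    return cm, ann, truth


def _aging_db_genes(params, rng, aging_effects, names) -> list[str]:
    """Planted aging-database set: the hub (if planted anywhere), a sample
    of other program genes, and background padding."""
    program_union = sorted({g for d in aging_effects.values() for g in d} - {params.hub_gene})
    n_from_program = min(30, len(program_union))
    picked = (
        list(rng.choice(program_union, size=n_from_program, replace=False))
        if n_from_program
        else []
    )
    background = [g for g in names if not g.startswith("mt-")]
    pad = list(rng.choice(background, size=min(50, len(background)), replace=False))
    db = []
    hub_planted = any(params.hub_gene in d for d in aging_effects.values())
    if hub_planted:
        db.append(params.hub_gene)
    for g in picked + pad:
        if g not in db:
            db.append(g)
    return db


def null_dataset(params: GeneratorParams) -> tuple[CountMatrix, pd.DataFrame, GroundTruth]:
    """Same sampling scheme with every planted effect forced to zero.

    The ground truth marks every gene background: no markers, no aging
    programs, no hub membership.
    """
    null_params = dataclasses.replace(
        params, marker_log2_effect=0.0, aging_log2_effect=0.0
    )
    return _generate_null(null_params)


def _generate_null(params: GeneratorParams):
    rng = np.random.default_rng(params.seed)
    names, base_cp10k, mito_idx, _ = _build_genes(params, rng)
    G = params.n_genes
    base_frac = base_cp10k / base_cp10k.sum()
    n_per = params.cells_per_group_per_type
    types = params.cell_types

    blocks = []
    cell_ids: list[str] = []
    cell_types_col: list[str] = []
    groups_col: list[str] = []
    for t in types:
        for grp in GROUPS_FOUR:
            lib = params.mean_depth * np.exp(
                rng.normal(-0.5 * params.libsize_sigma**2, params.libsize_sigma, size=n_per)
            )
            mu = lib[:, None] * base_frac[None, :]
            lam = rng.gamma(params.dispersion, mu / params.dispersion)
            blocks.append(rng.poisson(lam).astype(np.int64))
            start = len(cell_ids)
            cell_ids.extend(f"{t}_{grp}_c{start + i + 1:05d}" for i in range(n_per))
            cell_types_col.extend([t] * n_per)
            groups_col.extend([grp] * n_per)
    counts = np.vstack(blocks)
    cm = CountMatrix(cells=cell_ids, genes=names, counts=counts)
    ann = make_annotation(cell_ids, groups_col, cell_types_col)
    truth = GroundTruth(
        params=params,
        markers={t: [] for t in types},
        aging_effects={t: {} for t in types},
        rescued={t: set() for t in types},
        accelerated={t: set() for t in types},
        hub_gene=params.hub_gene,
        hub_types=[],
        aging_db_genes=[],
        cell_truth=pd.DataFrame(
            {
                "cell_id": cell_ids,
                "true_type": cell_types_col,
                "group": groups_col,
                "planted_qc_fail": [QC_OK] * len(cell_ids),
            }
        ),
    )
    return cm, ann, truth


def write_dataset(
    out_dir: str | Path,
    cm: CountMatrix,
    ann: pd.DataFrame,
    truth: GroundTruth,
) -> None:
    """Write the counts bundle, annotation, ground truth and parameters."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pio.write_counts(cm, out)
    pio.write_annotation(ann, out / "annotation.tsv")
    pio.write_table(truth.to_frame(), out / "ground_truth.tsv")
    pio.write_gmt(truth.marker_collection(), out / "markers.gmt")
    if truth.aging_db_genes:
        pio.write_gmt(truth.aging_collection(), out / "aging_db.gmt")
    params_dict = dataclasses.asdict(truth.params)
    params_dict["baseline_log10_cp10k"] = list(params_dict["baseline_log10_cp10k"])
    params_dict["program_quantile_band"] = list(params_dict["program_quantile_band"])
    if isinstance(params_dict["rescue_fraction"], tuple):
        params_dict["rescue_fraction"] = list(params_dict["rescue_fraction"])
    if isinstance(params_dict["accel_fraction"], tuple):
        params_dict["accel_fraction"] = list(params_dict["accel_fraction"])
    pio.write_json(
        {
            "params": params_dict,
            "hub_gene": truth.hub_gene,
            "hub_types": truth.hub_types,
        },
        out / "params.json",
    )
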