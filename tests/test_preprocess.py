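"""QC filtering, normalization, and marker-based cell typing."""

import dataclasses

import numpy as np
import pytest

from parabio_rescue.datatypes import (
    CountMatrix,
    GeneSetCollection,
    UNASSIGNED,
    ValidationError,
    make_annotation,
)
from parabio_rescue.preprocess import (
    QCThresholds,
    assign_cell_types,
    normalize,
    qc_filter,
)
from parabio_rescue.simulate import (
    QC_OK,
    GeneratorParams,
    generate_dataset,
)
from tests.conftest import SMALL_PARAMS


def _cm_with_detected(n_detected_per_cell, n_genes=5000, mito_genes=0):
    """Cells expressing exactly the requested number of genes (count 1)."""
    genes = [f"mt-m{j}" if j < mito_genes else f"g{j}" for j in range(n_genes)]
    counts = np.zeros((len(n_detected_per_cell), n_genes), dtype=int)
    for i, k in enumerate(n_detected_per_cell):
        counts[i, :k] = 1
    cells = [f"c{i}" for i in range(len(n_detected_per_cell))]
    cm = CountMatrix(cells=cells, genes=genes, counts=counts)
    ann = make_annotation(cells, ["Yiso"] * len(cells))
    return cm, ann


class TestQCFilter:
    def test_boundaries_are_strict(self):
        # exactly 200 detected genes fails ("more than 200"); 201 passes;
        # exactly 4000 fails ("fewer than 4000")
        cm, ann = _cm_with_detected([200, 201, 3999, 4000])
        out, ann_out = qc_filter(cm, ann, QCThresholds())
        assert out.cells == ["c1", "c2"]
        assert list(ann_out["n_genes_detected"]) == [201, 3999]

    def test_zero_mito_cell_retained(self):
        cm, ann = _cm_with_detected([1000])
        out, _ = qc_filter(cm, ann, QCThresholds())
        assert out.n_cells == 1

    def test_mito_threshold_strict(self):
        # 250 mito counts of 1000 -> 25% fails; boost non-mito to pass
        genes = [f"mt-m{j}" for j in range(250)] + [f"g{j}" for j in range(1000)]
        bad = np.ones((1, 1250), dtype=int)
        good = np.ones((1, 1250), dtype=int)
        good[0, 250:] = 5  # 250/5250 = 4.8% mito
        cm = CountMatrix(["bad", "good"], genes, np.vstack([bad, good]))
        ann = make_annotation(["bad", "good"], ["Yiso", "Yiso"])
        out, ann_out = qc_filter(cm, ann, QCThresholds())
        assert out.cells == ["good"]
        assert ann_out["pct_mito"].iloc[0] == pytest.approx(100 * 250 / 5250)

    def test_no_cells_pass_is_error(self):
        cm, ann = _cm_with_detected([150, 180])
        with pytest.raises(ValidationError, match="no cells pass QC"):
            qc_filter(cm, ann, QCThresholds())

    def test_planted_failures_removed_exactly(self):
        params = dataclasses.replace(
            SMALL_PARAMS, lowq_cell_fraction=0.05, himito_cell_fraction=0.05
        )
        cm, ann, truth = generate_dataset(params)
        out, _ = qc_filter(cm, ann, QCThresholds())
        planted_ok = set(
            truth.cell_truth.loc[truth.cell_truth["planted_qc_fail"] == QC_OK, "cell_id"]
        )
        assert set(out.cells) == planted_ok

    def test_idempotent(self, small_dataset):
        cm, ann, _ = small_dataset
        once_cm, once_ann = qc_filter(cm, ann)
        twice_cm, twice_ann = qc_filter(once_cm, once_ann)
        assert twice_cm == once_cm
        assert twice_ann.equals(once_ann)


class TestNormalize:
    def test_single_gene_closed_form(self):
        cm = CountMatrix(["c"], ["g1", "g2"], np.array([[7, 0]]))
        out = normalize(cm)
        assert out.normalized[0, 0] == pytest.approx(np.log1p(1e4))
        assert out.normalized[0, 1] == 0.0

    def test_back_transform_conserves_scale(self, small_dataset):
        cm, _, _ = small_dataset
        out = normalize(cm)
        sums = np.expm1(out.normalized).sum(axis=1)
        assert sums == pytest.approx(np.full(cm.n_cells, 1e4), rel=1e-9)

    def test_depth_invariance(self):
        counts = np.array([[2, 4, 8]])
        a = normalize(CountMatrix(["c"], ["g1", "g2", "g3"], counts))
        b = normalize(CountMatrix(["c"], ["g1", "g2", "g3"], counts * 2))
        assert a.normalized == pytest.approx(b.normalized)

    def test_zero_total_cell_named(self):
        cm = CountMatrix(["empty", "ok"], ["g"], np.array([[0], [5]]))
        with pytest.raises(ValidationError, match="empty"):
            normalize(cm)


class TestAssignCellTypes:
    def test_accuracy_on_planted_markers(self):
        # 3 types x 200 cells, marker effect 2: assignment nearly perfect
        params = GeneratorParams(
            seed=0, n_cell_types=3, cells_per_group_per_type=50, n_genes=800,
            aging_genes_per_type=30, n_shared_aging_genes=0,
        )
        cm, ann, truth = generate_dataset(params)
        cm, ann = qc_filter(cm, ann)
        cm = normalize(cm)
        result = assign_cell_types(cm, truth.marker_collection())
        true_types = (
            truth.cell_truth.set_index("cell_id").loc[result["cell_id"], "true_type"]
        )
        accuracy = (result["cell_type"].to_numpy() == true_types.to_numpy()).mean()
        assert accuracy >= 0.95

    def test_identical_marker_sets_all_unassigned(self, small_processed):
        cm, _, truth = small_processed
        genes = truth.markers["T1"]
        markers = GeneSetCollection("m", {"A": list(genes), "B": list(genes)})
        result = assign_cell_types(cm, markers)
        assert (result["cell_type"] == UNASSIGNED).all()

    def test_single_candidate_always_assigned(self, small_processed):
        cm, _, truth = small_processed
        markers = GeneSetCollection("m", {"only": list(truth.markers["T1"])})
        result = assign_cell_types(cm, markers)
        assert (result["cell_type"] == "only").all()

    def test_absent_marker_set_named(self, small_processed):
        cm, _, _ = small_processed
        markers = GeneSetCollection("m", {"ghost": ["nope1", "nope2"]})
        with pytest.raises(ValidationError, match="ghost"):
            assign_cell_types(cm, markers)

    def test_accuracy_monotone_in_marker_effect(self):
        accuracies = []
        for effect in (0.5, 1.0, 2.0):
            params = GeneratorParams(
                seed=0, n_cell_types=3, cells_per_group_per_type=30, n_genes=800,
                aging_genes_per_type=20, n_shared_aging_genes=0,
                marker_log2_effect=effect,
            )
            cm, ann, truth = generate_dataset(params)
            cm, ann = qc_filter(cm, ann)
            cm = normalize(cm)
            result = assign_cell_types(cm, truth.marker_collection())
            true_types = (
                truth.cell_truth.set_index("cell_id").loc[result["cell_id"], "true_type"]
            )
            accuracies.append(
                (result["cell_type"].to_numpy() == true_types.to_numpy()).mean()
            )
        assert accuracies[0] <= accuracies[1] <= accuracies[2]
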