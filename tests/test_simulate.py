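"""Generator contracts: determinism, planted mean structure, null behavior."""

import dataclasses

import numpy as np
import pytest

from parabio_rescue.datatypes import ValidationError
from parabio_rescue.preprocess import normalize, qc_filter
from parabio_rescue.simulate import (
    GeneratorParams,
    generate_dataset,
    null_dataset,
)
from tests.conftest import SMALL_PARAMS


def group_mean_cp10k(cm, ann, group):
    mask = (ann["group"] == group).to_numpy()
    return np.expm1(cm.normalized[mask]).mean(axis=0)


class TestDeterminism:
    def test_same_seed_bitwise_identical(self):
        cm1, ann1, t1 = generate_dataset(SMALL_PARAMS)
        cm2, ann2, t2 = generate_dataset(SMALL_PARAMS)
        assert (cm1.counts != cm2.counts).nnz == 0
        assert cm1.cells == cm2.cells and cm1.genes == cm2.genes
        assert ann1.equals(ann2)
        assert t1.aging_effects == t2.aging_effects
        assert t1.rescued == t2.rescued

    def test_different_seed_differs(self):
        cm1, _, _ = generate_dataset(SMALL_PARAMS)
        cm2, _, _ = generate_dataset(dataclasses.replace(SMALL_PARAMS, seed=1))
        assert (cm1.counts != cm2.counts).nnz > 0


class TestPlantedStructure:
    def test_program_disjoint_from_markers(self, small_dataset):
        _, _, truth = small_dataset
        for t, markers in truth.markers.items():
            assert not set(markers) & set(truth.aging_effects[t])

    def test_ahet_effect_is_scaled_reversion(self, small_dataset):
        _, _, truth = small_dataset
        mag = truth.params.rescue_magnitude
        for t, effects in truth.aging_effects.items():
            for g, e in effects.items():
                expected = -mag * e if g in truth.rescued[t] else 0.0
                assert truth.ahet_effect(t, g) == pytest.approx(expected)

    def test_hub_planted_down_and_rescued(self, small_dataset):
        _, _, truth = small_dataset
        assert truth.hub_types  # defaults: hub in every type
        for t in truth.hub_types:
            assert truth.aging_effects[t][truth.hub_gene] < 0
            assert truth.hub_gene in truth.rescued[t]
        assert truth.hub_gene in truth.aging_db_genes

    def test_planted_effects_recovered_in_group_means(self):
        # one type, 500 cells/group: empirical log2 ratios approach the
        # planted +/-1 aging effect and its full rescue
        params = GeneratorParams(
            seed=0, n_cell_types=1, cells_per_group_per_type=500,
            rescue_fraction=1.0, rescue_magnitude=1.0,
        )
        cm, ann, truth = generate_dataset(params)
        cm, ann = qc_filter(cm, ann)
        cm = normalize(cm)
        gidx = {g: i for i, g in enumerate(cm.genes)}
        aiso = group_mean_cp10k(cm, ann, "Aiso")
        yiso = group_mean_cp10k(cm, ann, "Yiso")
        ahet = group_mean_cp10k(cm, ann, "Ahet")
        ups = [gidx[g] for g in truth.program_genes("T1", "up")]
        aging_ratio = np.log2(aiso[ups] / yiso[ups])
        rescue_ratio = np.log2(ahet[ups] / aiso[ups])
        assert np.mean(aging_ratio) == pytest.approx(1.0, abs=0.2)
        assert np.mean(rescue_ratio) == pytest.approx(-1.0, abs=0.2)

    def test_overdispersion_exceeds_poisson(self, small_dataset):
        cm, _, _ = small_dataset
        dense = cm.counts.toarray().astype(float)
        means = dense.mean(axis=0)
        variances = dense.var(axis=0)
        well_expressed = means > 5
        assert well_expressed.sum() > 50
        frac_over = np.mean(variances[well_expressed] > means[well_expressed])
        assert frac_over > 0.9

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ValidationError):
            GeneratorParams(mean_depth=0)
        with pytest.raises(ValidationError):
            GeneratorParams(rescue_fraction=1.5)


class TestNullDataset:
    def test_ground_truth_all_background(self):
        _, _, truth = null_dataset(SMALL_PARAMS)
        assert all(not v for v in truth.aging_effects.values())
        assert all(not v for v in truth.markers.values())
        assert truth.hub_types == []
        for t in truth.params.cell_types:
            assert truth.hub_gene not in truth.aging_effects[t]

    def test_null_group_ratios_near_zero(self):
        # with no planted effects the Aiso/Yiso mean ratio of genes at
        # program-band expression (where a ratio is estimable) is ~0
        params = GeneratorParams(seed=0, n_cell_types=1, cells_per_group_per_type=500)
        cm, ann, _ = null_dataset(params)
        cm, ann = qc_filter(cm, ann)
        cm = normalize(cm)
        aiso = group_mean_cp10k(cm, ann, "Aiso")
        yiso = group_mean_cp10k(cm, ann, "Yiso")
        keep = (aiso > 5) & (yiso > 5)
        assert keep.sum() > 300
        ratios = np.log2(aiso[keep] / yiso[keep])
        assert np.mean(np.abs(ratios) < 0.1) >= 0.95

    def test_label_permutation_indistinguishable(self):
        # permuted group labels: the rank-sum test retains the null in
        # >= 94% of genes at alpha = 0.05
        from parabio_rescue.stats import rank_sum_test_bulk

        params = GeneratorParams(seed=0, n_cell_types=1, cells_per_group_per_type=500)
        cm, ann, _ = null_dataset(params)
        cm, ann = qc_filter(cm, ann)
        cm = normalize(cm)
        mask = ann["group"].isin(["Aiso", "Yiso"]).to_numpy()
        X = cm.normalized[mask]
        rng = np.random.default_rng(0)
        perm = rng.permutation(X.shape[0])
        half = X.shape[0] // 2
        _, pvals = rank_sum_test_bulk(X[perm[:half]], X[perm[half:]])
        assert np.mean(pvals >= 0.05) >= 0.94


class TestMeanConvergence:
    def test_effect_estimates_tighten_with_more_cells(self):
        errors = []
        for n_cells in (100, 400):
            params = GeneratorParams(
                seed=0, n_cell_types=1, cells_per_group_per_type=n_cells
            )
            cm, ann, truth = generate_dataset(params)
            cm, ann = qc_filter(cm, ann)
            cm = normalize(cm)
            gidx = {g: i for i, g in enumerate(cm.genes)}
            aiso = group_mean_cp10k(cm, ann, "Aiso")
            yiso = group_mean_cp10k(cm, ann, "Yiso")
            idx = [gidx[g] for g in truth.program_genes("T1")]
            eff = np.array([truth.aging_effects["T1"][g] for g in truth.program_genes("T1")])
            est = np.log2(aiso[idx] / yiso[idx])
            errors.append(float(np.std(est - eff)))
        assert errors[1] < errors[0]
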