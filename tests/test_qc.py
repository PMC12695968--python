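"""Per-cell QC filtering, species calls and summary statistics."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse

from rockroi.qc import (FilterSpec, assign_species, detection_efficiency,
                        fold_enrichment, per_cell_qc, per_cell_qc_and_filter,
                        positive_cell_rate, pseudobulk_correlation)
from rockroi.quant import (MODE_TSO_MULTI, MODE_WTA_UNIQUE, CountMatrix,
                           FeatureInterval, FeatureModel)


def matrix_from(counts, barcodes=None, features=None, mode=MODE_WTA_UNIQUE):
    counts = np.asarray(counts)
    barcodes = barcodes or [f"bc{i}" for i in range(counts.shape[0])]
    features = features or [f"g{i}" for i in range(counts.shape[1])]
    return CountMatrix(scipy.sparse.csr_matrix(counts.astype(float)),
                       barcodes, features, "WTA", mode)


def model_with_mito():
    return FeatureModel([
        FeatureInterval("chr1", 0, 100, "+", "gene", "g0"),
        FeatureInterval("chr1", 200, 300, "+", "gene", "g1"),
        FeatureInterval("chrM", 0, 100, "+", "gene", "g2", mito=True),
    ])


class TestPerCellQCAndFilter:
    def test_umi_and_mito_bounds_select_exactly_matching_cells(self):
        # mirror the printed thresholds: counts > 3000, 2% < mito < 28%
        counts = np.array([
            [4000, 0, 400],    # 9.1% mito, keep
            [4000, 0, 1600],   # 28.6% mito, drop
            [2000, 900, 100],  # 3000 total, drop (strict >)
            [4000, 0, 50],     # 1.2% mito, drop
        ])
        m = matrix_from(counts, features=["g0", "g1", "g2"])
        spec = FilterSpec(min_umis=3000, min_mito_percent=2,
                          max_mito_percent=28)
        qc, sub = per_cell_qc_and_filter(m, model_with_mito(), spec)
        assert list(qc.retained) == [True, False, False, False]
        assert sub.barcodes == ["bc0"]

    def test_empty_spec_retains_everything(self):
        m = matrix_from(np.ones((3, 3)), features=["g0", "g1", "g2"])
        _, sub = per_cell_qc_and_filter(m, model_with_mito(), FilterSpec())
        assert sub.barcodes == m.barcodes
        assert sub.features == m.features

    def test_gene_below_total_floor_dropped(self):
        m = matrix_from([[2, 5], [0, 5]], features=["g0", "g1"])
        _, sub = per_cell_qc_and_filter(m, model_with_mito(),
                                        FilterSpec(min_gene_total=3))
        assert sub.features == ["g1"]

    def test_filtering_is_idempotent(self):
        rng = np.random.default_rng(4)
        m = matrix_from(rng.integers(0, 50, (20, 3)),
                        features=["g0", "g1", "g2"])
        spec = FilterSpec(min_umis=40, max_mito_percent=50, min_gene_total=5)
        _, once = per_cell_qc_and_filter(m, model_with_mito(), spec)
        _, twice = per_cell_qc_and_filter(once, model_with_mito(), spec)
        assert once.barcodes == twice.barcodes
        assert once.features == twice.features
        assert (once.matrix != twice.matrix).nnz == 0

    def test_zero_total_cell_flagged_with_zero_mito(self):
        m = matrix_from([[0, 0, 0]], features=["g0", "g1", "g2"])
        qc = per_cell_qc(m, ["g2"])
        assert qc.mito_percent.iloc[0] == 0.0
        assert bool(qc.zero_total.iloc[0])

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            FilterSpec(min_umis=10, max_umis=5)


class TestAssignSpecies:
    species_map = {"gA": "A", "gB": "B"}

    def test_majority_assigns_species(self):
        m = matrix_from([[60, 40], [40, 60]], features=["gA", "gB"])
        calls = assign_species(m, self.species_map)
        assert list(calls) == ["A", "B"]

    def test_exact_fifty_fifty_is_unknown(self):
        m = matrix_from([[50, 50]], features=["gA", "gB"])
        assert assign_species(m, self.species_map).iloc[0] == "unknown"

    def test_zero_count_cell_is_unknown(self):
        m = matrix_from([[0, 0]], features=["gA", "gB"])
        assert assign_species(m, self.species_map).iloc[0] == "unknown"

    def test_unmapped_feature_raises(self):
        m = matrix_from([[1, 1]], features=["gA", "gX"])
        with pytest.raises(ValueError, match="gX"):
            assign_species(m, self.species_map)

    def test_pure_species_cells_always_correct(self, small_sim):
        truth = small_sim.truth
        rng = np.random.default_rng(0)
        counts = np.zeros((40, 2))
        labels = []
        for i in range(40):
            sp = i % 2
            counts[i, sp] = rng.integers(1, 100)
            labels.append("A" if sp == 0 else "B")
        m = matrix_from(counts, features=["gA", "gB"])
        assert list(assign_species(m, self.species_map)) == labels


class TestPositiveCellRate:
    def test_all_zero_target_column_gives_zero(self):
        m = matrix_from([[0, 5], [0, 3]], features=["tgt", "other"])
        assert positive_cell_rate(m, ["tgt"]) == 0.0

    def test_fractional_count_still_positive(self):
        m = matrix_from([[0.5, 1], [0.0, 1]], features=["tgt", "other"],
                        mode=MODE_TSO_MULTI)
        assert positive_cell_rate(m, ["tgt"]) == 50.0

    def test_planted_positive_fraction_recovered(self, small_sim):
        """Multi-mode counts on a target: positive-cell rate equals the
        planted positive fraction exactly at zero error."""
        from rockroi.quant import load_features, quantify
        truth = small_sim.truth
        fm = load_features(small_sim.ref_files["gtf"],
                           on_target_ids=truth.refs.on_target_ids)
        cells = list(truth.cells.barcode)
        m = quantify(small_sim.truth_sam, fm, cells, MODE_TSO_MULTI)
        for gene in truth.refs.on_target_ids:
            expected_bcs = {
                mol.barcode for mol in truth.molecules
                if mol.feature == gene and mol.modality == "TSO"
                and mol.cls in ("tso_capture", "roi_primed")}
            got = positive_cell_rate(m, [gene])
            assert got == pytest.approx(100.0 * len(expected_bcs)
                                        / len(cells))

    def test_empty_cell_set_raises(self):
        m = matrix_from(np.zeros((0, 1)), barcodes=[], features=["tgt"])
        with pytest.raises(ValueError):
            positive_cell_rate(m, ["tgt"])


class TestDetectionEfficiency:
    def test_published_worked_examples(self):
        assert detection_efficiency(0.44, [118, 131]) == 0.35
        assert detection_efficiency(10.68, [118, 131]) == 8.58

    def test_zero_counts_give_zero(self):
        assert detection_efficiency(0.0, [118, 131]) == 0.0

    def test_scale_equivariance(self):
        a = detection_efficiency(5.0, [100, 100])
        b = detection_efficiency(10.0, [100, 100])
        assert b == pytest.approx(2 * a)

    def test_invalid_replicates_raise(self):
        with pytest.raises(ValueError):
            detection_efficiency(1.0, [])
        with pytest.raises(ValueError):
            detection_efficiency(1.0, [0.0, 100.0])


class TestPseudobulkCorrelation:
    def test_identical_matrices_correlate_perfectly(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 100, (30, 20))
        m = matrix_from(counts)
        groups = pd.Series(["a"] * 15 + ["b"] * 15, index=m.barcodes)
        out = pseudobulk_correlation(m, m, groups, groups,
                                     min_mean_logcount=0.0, min_variance=0.0)
        diag = out[out.group1 == out.group2]
        assert np.allclose(diag.pearson_r, 1.0)

    def test_independent_matrices_correlate_near_zero(self):
        rng = np.random.default_rng(2)
        m1 = matrix_from(rng.poisson(20, (40, 200)))
        m2 = matrix_from(rng.poisson(20, (40, 200)))
        groups = pd.Series(["a"] * 40, index=m1.barcodes)
        out = pseudobulk_correlation(m1, m2, groups, groups,
                                     min_mean_logcount=0.0, min_variance=0.0)
        assert abs(out.pearson_r.iloc[0]) < 0.3

    def test_constant_genes_excluded_by_variance_filter(self):
        counts = np.ones((10, 3)) * 5
        counts[:, 0] = np.arange(10) * 40
        counts[:, 1] = (10 - np.arange(10)) * 40
        m = matrix_from(counts)
        groups = pd.Series(["a"] * 5 + ["b"] * 5, index=m.barcodes)
        out = pseudobulk_correlation(m, m, groups, groups,
                                     min_mean_logcount=0.1, min_variance=0.5)
        assert not out.empty  # constant gene g2 dropped, others survive

    def test_too_few_surviving_genes_raise(self):
        m = matrix_from(np.ones((4, 2)))
        groups = pd.Series(["a"] * 4, index=m.barcodes)
        with pytest.raises(ValueError, match="2 genes"):
            pseudobulk_correlation(m, m, groups, groups)

    def test_logcpm_variant_runs(self):
        rng = np.random.default_rng(3)
        m = matrix_from(rng.poisson(30, (20, 50)))
        groups = pd.Series(["a"] * 10 + ["b"] * 10, index=m.barcodes)
        out = pseudobulk_correlation(m, m, groups, groups, method="logcpm")
        diag = out[out.group1 == out.group2]
        assert np.allclose(diag.pearson_r, 1.0)


class TestFoldEnrichment:
    def test_equal_counts_give_one(self):
        assert fold_enrichment(7.0, 7.0) == (1.0, None)

    def test_simulated_tenfold_enrichment(self):
        rng = np.random.default_rng(5)
        a = rng.poisson(5000)
        b = rng.poisson(500)
        ratio, flag = fold_enrichment(a, b)
        assert flag is None
        assert ratio == pytest.approx(10.0, rel=0.2)

    def test_zero_denominator_flagged_infinite(self):
        ratio, flag = fold_enrichment(5.0, 0.0)
        assert np.isinf(ratio) and flag == "infinite"

    def test_both_zero_flagged_undefined(self):
        ratio, flag = fold_enrichment(0.0, 0.0)
        assert np.isnan(ratio) and flag == "undefined"

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fold_enrichment(-1.0, 1.0)
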