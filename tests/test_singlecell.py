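"""Pseudobulk, TMM/log-CPM, enrichment criteria, differential expression."""

import numpy as np
import pandas as pd
import pytest

from protmr import synthdata as sd
from protmr.singlecell import (
    aggregate_pseudobulk,
    auc_single_gene,
    celltype_enrichment,
    de_disease_vs_control,
    gini,
    log_cpm,
    tmm_factors,
)

CTS = ["cardiomyocyte", "fibroblast", "endothelial", "myeloid"]


def small_dataset(seed=0, enriched=None, de=None, n_genes=40, nuclei=50,
                  donors=None):
    donors = donors or sd.make_default_donors(seed=seed)
    counts, genes, cells, donors_df = sd.simulate_singlecell_counts(
        n_genes, CTS, donors, enriched_gene_map=enriched, de_gene_map=de,
        seed=seed, nuclei_per_donor_type=nuclei)
    return counts, genes, cells, donors_df


class TestAggregate:
    def test_two_cells_sum(self):
        counts = np.array([[2, 3], [0, 5]])
        cells = pd.DataFrame({"cell_id": ["c1", "c2"],
                              "cell_type": ["ct", "ct"],
                              "donor_id": ["d1", "d1"]})
        donors = pd.DataFrame({"donor_id": ["d1"], "condition": ["NF"],
                               "age": [50.0], "sex": ["F"]})
        pb = aggregate_pseudobulk(counts, ["g1", "g2"], cells, donors)
        np.testing.assert_array_equal(pb.counts[:, 0], [5, 5])

    def test_one_cell_per_profile_identity(self):
        counts = np.array([[2, 3], [1, 5]])
        cells = pd.DataFrame({"cell_id": ["c1", "c2"],
                              "cell_type": ["a", "b"],
                              "donor_id": ["d1", "d1"]})
        donors = pd.DataFrame({"donor_id": ["d1"], "condition": ["NF"],
                               "age": [50.0], "sex": ["F"]})
        pb = aggregate_pseudobulk(counts, ["g1", "g2"], cells, donors)
        np.testing.assert_array_equal(np.sort(pb.counts, axis=1),
                                      np.sort(counts, axis=1))

    def test_total_count_conservation(self):
        counts, genes, cells, donors_df = small_dataset(seed=3, nuclei=15)
        pb = aggregate_pseudobulk(counts, genes, cells, donors_df)
        assert pb.counts.sum() == counts.sum()

    def test_unknown_donor_raises(self):
        counts = np.array([[1]])
        cells = pd.DataFrame({"cell_id": ["c1"], "cell_type": ["a"],
                              "donor_id": ["ghost"]})
        donors = pd.DataFrame({"donor_id": ["d1"], "condition": ["NF"],
                               "age": [50.0], "sex": ["F"]})
        with pytest.raises(KeyError, match="ghost"):
            aggregate_pseudobulk(counts, ["g1"], cells, donors)


class TestTMMAndLogCPM:
    def _pb(self, counts):
        n = counts.shape[1]
        cells = pd.DataFrame({"cell_id": [f"c{i}" for i in range(n)],
                              "cell_type": ["ct"] * n,
                              "donor_id": [f"d{i}" for i in range(n)]})
        donors = pd.DataFrame({"donor_id": [f"d{i}" for i in range(n)],
                               "condition": ["NF"] * n,
                               "age": [50.0] * n, "sex": ["F"] * n})
        genes = [f"g{i}" for i in range(counts.shape[0])]
        return aggregate_pseudobulk(counts, genes, cells, donors)

    def test_identical_profiles_unit_factors(self, rng):
        col = rng.integers(1, 100, 30)
        pb = self._pb(np.column_stack([col, col, col]))
        np.testing.assert_allclose(tmm_factors(pb), 1.0, atol=1e-12)

    def test_pure_depth_difference_unit_factor(self, rng):
        col = rng.integers(2, 100, 30)
        pb = self._pb(np.column_stack([col, 2 * col, col]))
        np.testing.assert_allclose(tmm_factors(pb), 1.0, atol=1e-9)

    def test_geometric_mean_one(self, rng):
        counts = rng.integers(0, 60, size=(50, 6))
        counts[:10, 3] *= 5  # composition shift
        pb = self._pb(counts + 1)
        f = tmm_factors(pb)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_log_cpm_finite_at_zero_and_monotone(self, rng):
        counts = rng.integers(0, 40, size=(20, 4))
        counts[0] = 0
        pb = self._pb(counts)
        vals = log_cpm(pb, np.ones(4))
        assert np.all(np.isfinite(vals))
        counts2 = counts.copy()
        counts2[5, 0] += 10
        pb2 = self._pb(counts2)
        assert log_cpm(pb2, np.ones(4))[5, 0] > vals[5, 0]

    def test_doubling_count_and_library_nearly_invariant(self):
        # the pseudocount perturbs log-CPM by ~pc/(2·c·ln2) under doubling,
        # so near-invariance (<1e-3) needs counts ≳ 200
        counts = np.full((30, 2), 500)
        counts[0] = [250, 300]
        pb1 = self._pb(counts)
        pb2 = self._pb(2 * counts)
        v1 = log_cpm(pb1, np.ones(2))[0, 0]
        v2 = log_cpm(pb2, np.ones(2))[0, 0]
        assert abs(v2 - v1) < 1e-3
        # and the shift shrinks as counts grow
        counts[0] = [20, 20]
        d_small = abs(log_cpm(self._pb(2 * counts), np.ones(2))[0, 0]
                      - log_cpm(self._pb(counts), np.ones(2))[0, 0])
        assert d_small > abs(v2 - v1)


class TestAUC:
    def test_perfect_separation(self):
        assert auc_single_gene([3, 4, 1, 2], [True, True, False, False]) == 1.0

    def test_all_ties(self):
        assert auc_single_gene([2, 2, 2, 2], [True, True, False, False]) == 0.5

    def test_straddling_value(self):
        assert auc_single_gene([2, 1, 3], [True, False, False]) == 0.5

    def test_one_class_empty_is_nan(self):
        assert np.isnan(auc_single_gene([1, 2], [True, True]))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        vals = rng.integers(0, 6, n).astype(float)  # many ties
        labels = rng.random(n) < 0.4
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        auc = auc_single_gene(vals, labels)
        wins = ties = 0
        for a in vals[labels]:
            for b in vals[~labels]:
                wins += a > b
                ties += a == b
        n_pairs = labels.sum() * (~labels).sum()
        assert auc == pytest.approx((wins + 0.5 * ties) / n_pairs, abs=1e-12)


class TestGini:
    def test_perfect_equality(self):
        assert gini([1, 1, 1, 1]) == pytest.approx(0.0)

    def test_point_mass(self):
        assert gini([1, 0, 0, 0]) == pytest.approx(0.75)

    def test_permutation_invariant(self, rng):
        x = rng.uniform(0, 5, 12)
        assert gini(x) == pytest.approx(gini(np.roll(x, 3)), abs=1e-12)

    def test_all_zero_undefined(self):
        assert np.isnan(gini([0.0, 0.0]))

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            gini([-1, 2])


class TestCellTypeEnrichment:
    def test_planted_gene_flagged(self):
        counts, genes, cells, donors_df = small_dataset(
            seed=11, enriched={"g0005": ("cardiomyocyte", 8.0)})
        pb = aggregate_pseudobulk(counts, genes, cells, donors_df)
        table = celltype_enrichment(pb, counts, cells)
        hit = table[(table.gene == "g0005")
                    & (table.cell_type == "cardiomyocyte")].iloc[0]
        assert hit.enriched
        assert hit.fold_one_vs_rest == pytest.approx(8.0, rel=0.3)

    def test_low_fraction_blocks_enrichment(self):
        # high fold but expression concentrated in very few nuclei:
        # emulate with a tiny base mean so the nonzero rate is far below 25%
        donors = sd.make_default_donors(seed=1)
        counts, genes, cells, donors_df = sd.simulate_singlecell_counts(
            30, CTS, donors, enriched_gene_map={"g0002": ("fibroblast", 8.0)},
            seed=12, nuclei_per_donor_type=50, base_mean=0.02)
        pb = aggregate_pseudobulk(counts, genes, cells, donors_df)
        table = celltype_enrichment(pb, counts, cells)
        row = table[(table.gene == "g0002") & (table.cell_type == "fibroblast")]
        assert row.iloc[0].fraction_nuclei < 0.25
        assert not row.iloc[0].enriched

    def test_moderate_fold_not_enriched(self):
        counts, genes, cells, donors_df = small_dataset(
            seed=13, enriched={"g0001": ("myeloid", 2.0)})
        pb = aggregate_pseudobulk(counts, genes, cells, donors_df)
        table = celltype_enrichment(pb, counts, cells)
        row = table[(table.gene == "g0001") & (table.cell_type == "myeloid")]
        assert not row.iloc[0].enriched

    def test_flag_conjunction_invariant(self):
        counts, genes, cells, donors_df = small_dataset(
            seed=14, enriched={"g0003": ("endothelial", 6.0)})
        pb = aggregate_pseudobulk(counts, genes, cells, donors_df)
        t = celltype_enrichment(pb, counts, cells)
        manual = ((t.fold_one_vs_rest > 4) & (t.fdr < 0.01)
                  & (t.fraction_nuclei >= 0.25) & (t.auc > 0.6))
        assert (t.enriched == manual).all()

    def test_invariant_to_uniform_depth_rescaling(self):
        counts, genes, cells, donors_df = small_dataset(
            seed=15, enriched={"g0004": ("cardiomyocyte", 8.0)})
        pb1 = aggregate_pseudobulk(counts, genes, cells, donors_df)
        pb3 = aggregate_pseudobulk(3 * counts, genes, cells, donors_df)
        t1 = celltype_enrichment(pb1, counts, cells)
        t3 = celltype_enrichment(pb3, 3 * counts, cells)
        pd.testing.assert_series_equal(t1.enriched, t3.enriched)


class TestDifferentialExpression:
    def test_planted_de_only_in_target_cell_type(self):
        counts, genes, cells, donors_df = small_dataset(
            seed=21, de={"g0007": ("cardiomyocyte", "DCM", 2.0)})
        pb = aggregate_pseudobulk(counts, genes, cells, donors_df)
        de = de_disease_vs_control(pb, "DCM")
        passed = de[de.passes]
        assert set(zip(passed.gene, passed.cell_type)) == {
            ("g0007", "cardiomyocyte")}

    def test_fold_below_threshold_never_passes(self):
        counts, genes, cells, donors_df = small_dataset(
            seed=22, de={"g0002": ("fibroblast", "DCM", 1.4)})
        pb = aggregate_pseudobulk(counts, genes, cells, donors_df)
        de = de_disease_vs_control(pb, "DCM")
        row = de[(de.gene == "g0002") & (de.cell_type == "fibroblast")].iloc[0]
        assert row.log2fc < np.log2(1.5)
        assert not row.passes

    def test_insufficient_donors_not_testable(self):
        donors = sd.make_default_donors(3, 2, 2, seed=0)
        counts, genes, cells, donors_df = small_dataset(
            seed=23, donors=donors, n_genes=10, nuclei=20)
        pb = aggregate_pseudobulk(counts, genes, cells, donors_df)
        de = de_disease_vs_control(pb, "DCM")
        assert not de.testable.any()

    def test_confounded_design_raises(self):
        donors = [sd.DonorSpec(f"d{i}", "DCM" if i < 4 else "NF",
                               50.0, "M" if i < 4 else "F")
                  for i in range(8)]
        counts, genes, cells, donors_df = small_dataset(
            seed=24, donors=donors, n_genes=10, nuclei=20)
        pb = aggregate_pseudobulk(counts, genes, cells, donors_df)
        with pytest.raises(ValueError, match="collinear"):
            de_disease_vs_control(pb, "DCM")

    def test_label_permutation_keeps_false_positives_low(self):
        counts, genes, cells, donors_df = small_dataset(seed=25)
        rng = np.random.default_rng(0)
        donors_df = donors_df.copy()
        donors_df["condition"] = rng.permutation(donors_df["condition"].values)
        pb = aggregate_pseudobulk(counts, genes, cells, donors_df)
        de = de_disease_vs_control(pb, "DCM")
        assert de[de.testable].passes.mean() <= 0.05
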