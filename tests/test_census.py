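import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cerna_emt.census import (
    CopyCalibration,
    anchor_census,
    candidate_regulators,
    combine_calibrations,
    copies_from_reads,
    dominant_cerna_fraction,
    estimate_mre_timecourse,
    extrapolate_from_foldchange,
    functional_mirna_filter,
    stoichiometry_ratio,
)
from cerna_emt.io_formats import ExpressionTimeCourse, SiteAnnotation, ValidationError


class TestExtrapolation:
    def test_definitional_product(self):
        base = ExpressionTimeCourse(["G"], [0.0], [[10.0]], "TPM")
        fc = ExpressionTimeCourse(["G"], [0.0, 24.0, 96.0], [[1.0, 2.0, 4.0]], "FOLD_CHANGE")
        out = extrapolate_from_foldchange(base, fc)
        np.testing.assert_allclose(out.values, [[10.0, 20.0, 40.0]])
        assert out.unit_tag == "TPM"

    def test_unit_fold_changes_reproduce_baseline(self):
        base = ExpressionTimeCourse(["G", "H"], [0.0], [[3.0], [7.0]], "TPM")
        fc = ExpressionTimeCourse(
            ["G", "H"], [0.0, 48.0], np.ones((2, 2)), "FOLD_CHANGE"
        )
        out = extrapolate_from_foldchange(base, fc)
        np.testing.assert_allclose(out.values, [[3.0, 3.0], [7.0, 7.0]])

    def test_matches_elementwise_loop_on_random_input(self):
        rng = np.random.default_rng(42)
        genes = [f"G{i}" for i in range(20)]
        base_v = rng.uniform(0.5, 100.0, (20, 1))
        fc_v = np.hstack([np.ones((20, 1)), rng.uniform(0.1, 5.0, (20, 3))])
        base = ExpressionTimeCourse(genes, [0.0], base_v, "TPM")
        fc = ExpressionTimeCourse(genes, [0.0, 12.0, 24.0, 48.0], fc_v, "FOLD_CHANGE")
        out = extrapolate_from_foldchange(base, fc)
        for i, g in enumerate(genes):
            for j in range(4):
                assert out.row(g)[j] == pytest.approx(base_v[i, 0] * fc_v[i, j])

    def test_disjoint_gene_sets_error(self):
        base = ExpressionTimeCourse(["A"], [0.0], [[1.0]], "TPM")
        fc = ExpressionTimeCourse(["B"], [0.0], [[1.0]], "FOLD_CHANGE")
        with pytest.raises(ValidationError, match="no genes shared"):
            extrapolate_from_foldchange(base, fc)


class TestCensus:
    def test_manual_sum_of_products(self, small_expression, small_sites):
        cns = estimate_mre_timecourse(small_expression, small_sites, "miR-X", "targetscan")
        # A: TPM [10,20,40] x two 8mers; B: TPM 5 x one 8mer -> 8mer totals
        pools = cns.class_pools(0.0)
        assert pools["8mer"] == pytest.approx(2 * 10 + 1 * 5)
        assert pools["7mer-m8"] == pytest.approx(3 * 5)
        assert cns.class_pools(96.0)["8mer"] == pytest.approx(2 * 40 + 5)

    def test_gene_without_sites_contributes_zero(self, small_sites):
        expr = ExpressionTimeCourse(["A", "B", "C"], [0.0], [[1.0], [1.0], [99.0]], "TPM")
        cns = estimate_mre_timecourse(expr, small_sites, "miR-X", "targetscan")
        gi = cns.gene_ids.index("C")
        assert cns.per_gene_contrib[gi].sum() == 0.0

    def test_unannotated_mirna_errors(self, small_expression, small_sites):
        with pytest.raises(ValidationError, match="no sites annotated"):
            estimate_mre_timecourse(small_expression, small_sites, "miR-none", "targetscan")

    def test_totals_equal_gene_sums(self, a549_like_synth):
        _, expr, sites, _ = a549_like_synth
        cns = estimate_mre_timecourse(expr, sites, "miR-X", "targetscan")
        np.testing.assert_allclose(
            cns.per_class_totals, cns.per_gene_contrib.sum(axis=0), rtol=1e-9
        )

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(scale=st.floats(0.1, 1000.0))
    def test_expression_scaling_scales_totals_linearly(self, scale):
        expr = ExpressionTimeCourse(
            ["A", "B"], [0.0, 24.0, 96.0], [[10.0, 20.0, 40.0], [5.0, 5.0, 5.0]], "TPM"
        )
        sites = SiteAnnotation(
            pd.DataFrame(
                [("A", "miR-X", "8mer", 2, "targetscan"), ("B", "miR-X", "8mer", 1, "targetscan")],
                columns=SiteAnnotation.COLUMNS,
            )
        )
        cns1 = estimate_mre_timecourse(expr, sites, "miR-X", "targetscan")
        scaled = ExpressionTimeCourse(expr.gene_ids, expr.times, expr.values * scale, "TPM")
        cns2 = estimate_mre_timecourse(scaled, sites, "miR-X", "targetscan")
        np.testing.assert_allclose(cns2.per_class_totals, cns1.per_class_totals * scale, rtol=1e-12)


class TestAnchoring:
    def test_unit_scale_is_identity(self, small_expression, small_sites):
        cns = estimate_mre_timecourse(small_expression, small_sites, "miR-X", "targetscan")
        calib = CopyCalibration("A", 0.0, 10.0, 10.0)
        out = anchor_census(cns, calib)
        np.testing.assert_allclose(out.per_gene_contrib, cns.per_gene_contrib)
        assert out.unit_tag == "COPIES"

    def test_published_anchor_scale(self, small_expression, small_sites):
        # 6489 copies/cell measured against 50 TPM -> scale 129.78
        calib = CopyCalibration("TGFBI", 24.0, 6489.0, 50.0)
        assert calib.scale == pytest.approx(129.78)
        cns = estimate_mre_timecourse(small_expression, small_sites, "miR-X", "targetscan")
        out = anchor_census(cns, calib)
        gi = out.gene_ids.index("A")
        # a 10-TPM one-site-unit contribution becomes 1297.8 copies
        assert out.per_gene_contrib[gi, 0, 0] / 2 == pytest.approx(1297.8)

    def test_anchor_commutes_with_summation(self, a549_like_synth):
        _, expr, sites, _ = a549_like_synth
        cns = estimate_mre_timecourse(expr, sites, "miR-X", "targetscan")
        calib = CopyCalibration("X", 0.0, 321.0, 2.5)
        anchored = anchor_census(cns, calib)
        np.testing.assert_allclose(
            anchored.per_class_totals, cns.per_class_totals * calib.scale, rtol=1e-12
        )

    def test_zero_abundance_anchor_rejected(self):
        with pytest.raises(ValidationError):
            CopyCalibration("X", 0.0, 100.0, 0.0)

    def test_multiple_anchors_combined_by_geometric_mean(self):
        c1 = CopyCalibration("A", 0.0, 100.0, 1.0)  # scale 100
        c2 = CopyCalibration("B", 0.0, 400.0, 1.0)  # scale 400
        combined = combine_calibrations([c1, c2])
        assert combined.scale == pytest.approx(200.0)  # geometric mean


class TestCopiesFromReads:
    def test_anchor_maps_to_itself(self):
        assert copies_from_reads(211178, 211178, 1396) == pytest.approx(1396)

    def test_published_read_ratio(self):
        ratio = copies_from_reads(5_886_078, 211_178, 1.0)
        assert round(ratio) == 28

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(q=st.floats(0.0, 1e7), k=st.floats(0.1, 10.0))
    def test_homogeneous_in_query_reads(self, q, k):
        assert copies_from_reads(k * q, 100.0, 7.0) == pytest.approx(
            k * copies_from_reads(q, 100.0, 7.0), rel=1e-12
        )

    def test_zero_anchor_reads_rejected(self):
        with pytest.raises(ValidationError):
            copies_from_reads(10, 0, 100)


class TestFilters:
    def test_functional_filter_empty_input(self):
        assert functional_mirna_filter({}) == []

    def test_functional_filter_cutoff_and_order(self):
        out = functional_mirna_filter({"a": 1500.0, "b": 8.0, "c": 99.0}, cutoff=100.0)
        assert out == ["a"]

    def test_all_above_cutoff_sorted_descending(self):
        out = functional_mirna_filter({"x": 200.0, "y": 900.0, "z": 150.0}, cutoff=100.0)
        assert out == ["y", "x", "z"]

    def test_candidate_regulators_intersection(self):
        de = pd.DataFrame(
            {
                "mirna": ["miR-122-5p", "miR-129-5p", "miR-200b-3p", "miR-543", "miR-21-5p", "miR-x"],
                "log2fc": [2.0, -1.5, 3.0, 1.2, 1.1, 4.0],
                "fdr": [0.001, 0.01, 0.0001, 0.02, 0.04, 0.9],
            }
        )
        predicted = {"miR-122-5p", "miR-129-5p", "miR-200b-3p", "miR-543", "miR-21-5p", "miR-y"}
        hits = candidate_regulators(de, predicted)
        assert set(hits) == {"miR-122-5p", "miR-129-5p", "miR-200b-3p", "miR-543", "miR-21-5p"}

    def test_candidate_regulators_disjoint(self):
        de = pd.DataFrame({"mirna": ["a"], "log2fc": [3.0], "fdr": [0.001]})
        assert candidate_regulators(de, {"b"}) == []

    def test_boundary_values_excluded_by_strict_inequality(self):
        de = pd.DataFrame(
            {"mirna": ["at_fdr", "at_lfc"], "log2fc": [2.0, 1.0], "fdr": [0.05, 0.001]}
        )
        assert candidate_regulators(de, {"at_fdr", "at_lfc"}) == []


class TestDominantFraction:
    def _census_from_matrix(self, genes, values):
        expr = ExpressionTimeCourse(genes, [0.0, 96.0], values, "TPM")
        sites = SiteAnnotation(
            pd.DataFrame(
                [(g, "m", "8mer", 1, "targetscan") for g in genes],
                columns=SiteAnnotation.COLUMNS,
            )
        )
        return estimate_mre_timecourse(expr, sites, "m", "targetscan")

    def test_single_increasing_gene_gets_fraction_one(self):
        cns = self._census_from_matrix(["A", "B"], [[1.0, 11.0], [5.0, 5.0]])
        frac = dominant_cerna_fraction(cns, 0.0, 96.0)
        assert frac["A"] == pytest.approx(1.0)
        assert frac["B"] == 0.0

    def test_manual_arithmetic_and_negative_deltas_zeroed(self):
        cns = self._census_from_matrix(
            ["A", "B", "C"], [[0.0, 90.0], [0.0, 10.0], [5.0, 0.0]]
        )
        frac = dominant_cerna_fraction(cns, 0.0, 96.0)
        assert frac == pytest.approx({"A": 0.9, "B": 0.1, "C": 0.0})

    def test_positive_fractions_sum_to_one(self, a549_like_synth):
        _, expr, sites, _ = a549_like_synth
        cns = estimate_mre_timecourse(expr, sites, "miR-X", "targetscan")
        frac = dominant_cerna_fraction(cns, 0.0, 96.0)
        assert all(0.0 <= v <= 1.0 for v in frac.values())
        assert sum(frac.values()) == pytest.approx(1.0)

    def test_no_expansion_errors(self):
        cns = self._census_from_matrix(["A"], [[5.0, 2.0]])
        with pytest.raises(ValidationError, match="no MRE expansion"):
            dominant_cerna_fraction(cns, 0.0, 96.0)


class TestStoichiometry:
    def test_published_ratios(self, anchors):
        ratio24, _ = stoichiometry_ratio(anchors, "TGFBI", "miR-21", 24.0)
        assert ratio24 == 1.95
        ratio96, excess96 = stoichiometry_ratio(anchors, "TGFBI", "miR-21", 96.0)
        assert ratio96 == 1.20 and excess96 == 20.0
        fn1, _ = stoichiometry_ratio(anchors, "FN1", "miR-200c", 96.0)
        assert fn1 == 2.77

    def test_equal_copies_give_unit_ratio(self, anchors):
        ratio, excess = stoichiometry_ratio(anchors, "TGFBI", "TGFBI", 24.0)
        assert ratio == 1.0 and excess == 0.0

    def test_missing_measurement_names_species_and_time(self, anchors):
        with pytest.raises(KeyError, match="miR-200c.*24"):
            stoichiometry_ratio(anchors, "TGFBI", "miR-200c", 24.0)
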