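import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ithsig import (
    AnalysisConfig,
    ExpressionMatrix,
    SampleAnnotation,
    ValidationError,
    compute_ihs,
    event_frequency,
    icc_oneway,
    select_low_ihs,
    simulate_cohort,
    SimulationParams,
)


def icc_bruteforce(groups):
    """Independent one-way ANOVA ICC oracle: explicit loops, no vectorization."""
    P = len(groups)
    N = sum(len(g) for g in groups)
    grand = sum(x for g in groups for x in g) / N
    means = [sum(g) / len(g) for g in groups]
    ssb = sum(len(g) * (m - grand) ** 2 for g, m in zip(groups, means))
    ssw = sum((x - m) ** 2 for g, m in zip(groups, means) for x in g)
    msb = ssb / (P - 1)
    msw = ssw / (N - P)
    if msb == 0 and msw == 0:
        return 1.0
    k0 = (N - sum(len(g) ** 2 for g in groups) / N) / (P - 1)
    icc = (msb - msw) / (msb + (k0 - 1) * msw)
    return min(1.0, max(0.0, icc))


class TestICCOneway:
    def test_zero_within_variance_gives_icc_one(self):
        assert icc_oneway([[2.0, 2.0], [5.0, 5.0]]) == 1.0

    def test_constant_everywhere_convention(self):
        assert icc_oneway([[3.0, 3.0], [3.0, 3.0]]) == 1.0

    def test_unbalanced_example_matches_bruteforce(self):
        groups = [[1.0, 2.0], [4.0, 6.0], [3.0, 3.0]]
        assert icc_oneway(groups) == pytest.approx(icc_bruteforce(groups), abs=1e-12)

    def test_group_size_validation(self):
        with pytest.raises(ValidationError):
            icc_oneway([[1.0, 2.0]])
        with pytest.raises(ValidationError):
            icc_oneway([[1.0, 2.0], [3.0]])

    @given(
        st.lists(
            st.lists(st.floats(-10, 10), min_size=2, max_size=6),
            min_size=2,
            max_size=8,
        )
    )
    def test_matches_bruteforce_on_random_instances(self, groups):
        assert icc_oneway(groups) == pytest.approx(
            icc_bruteforce(groups), abs=1e-10
        )


class TestEventFrequency:
    def test_threshold_counting(self):
        groups = [[0.0, 1.5], [0.0, 0.2], [0.0, 0.8]]  # ranges 1.5, 0.2, 0.8
        assert event_frequency(groups, tau=1.0) == pytest.approx(1 / 3)
        assert event_frequency(groups, tau=0.1) == 1.0

    def test_identical_regions_give_zero(self):
        assert event_frequency([[2.0, 2.0], [7.0, 7.0]], tau=1.0) == 0.0

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValidationError):
            event_frequency([[1.0, 2.0], [3.0, 4.0]], tau=0.0)


def _matrix(values, samples, genes=None):
    genes = genes or [f"G{i}" for i in range(len(values))]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), allow_negative=True
    )


def _annot(samples, patients):
    counters: dict[str, int] = {}
    regions = []
    for p in patients:
        counters[p] = counters.get(p, 0) + 1
        regions.append(f"R{counters[p]}")
    return SampleAnnotation(
        pd.DataFrame(
            {"sample_id": samples, "patient_id": patients, "region_id": regions}
        )
    )


class TestComputeIHS:
    samples = ["A1", "A2", "B1", "B2"]
    patients = ["PA", "PA", "PB", "PB"]

    def test_clonal_extreme_gets_minimal_ihs(self):
        # G0 identical within patients, distinct between; G1/G2 heterogeneous
        values = [
            [2.0, 2.0, 6.0, 6.0],
            [1.0, 5.0, 2.0, 7.0],
            [3.0, 6.0, 1.0, 4.0],
        ]
        table = compute_ihs(
            _matrix(values, self.samples), _annot(self.samples, self.patients)
        )
        assert table.loc["G0", "h1"] == 0.0
        assert table.loc["G0", "event_freq"] == 0.0
        assert table.loc["G0", "ihs"] == table["ihs"].min()

    def test_constant_gene_flagged_with_minimal_components(self):
        values = [[3.0] * 4, [1.0, 5.0, 2.0, 7.0]]
        table = compute_ihs(
            _matrix(values, self.samples), _annot(self.samples, self.patients)
        )
        assert bool(table.loc["G0", "flagged_constant"])
        assert table.loc["G0", "h1"] == 0.0 and table.loc["G0", "event_freq"] == 0.0

    def test_location_invariance(self, small_cohort):
        expr, annot, _ = small_cohort
        base = compute_ihs(expr, annot)
        shifted = ExpressionMatrix(expr.data + 5.0)
        pd.testing.assert_frame_equal(base, compute_ihs(shifted, annot))

    def test_sample_permutation_invariance(self, small_cohort):
        expr, annot, _ = small_cohort
        base = compute_ihs(expr, annot)
        rng = np.random.default_rng(0)
        perm = rng.permutation(expr.sample_ids)
        expr_p = ExpressionMatrix(expr.data[perm])
        annot_p = SampleAnnotation(
            annot.data.set_index("sample_id").loc[perm].reset_index()
        )
        pd.testing.assert_frame_equal(base, compute_ihs(expr_p, annot_p))

    def test_outlier_contamination_never_decreases_h1(self, small_cohort):
        expr, annot, _ = small_cohort
        base = compute_ihs(expr, annot)
        gene = base.index[10]
        bumped = expr.data.copy()
        bumped.loc[gene, bumped.columns[0]] += 10.0
        after = compute_ihs(ExpressionMatrix(bumped), annot)
        assert after.loc[gene, "h1"] >= base.loc[gene, "h1"]

    def test_rank_normalization_mean(self, small_cohort):
        expr, annot, _ = small_cohort
        table = compute_ihs(expr, annot)
        G = len(table)
        assert table["rank_h1"].mean() == pytest.approx((G + 1) / (2 * G), abs=1e-12)
        assert table["rank_e"].mean() == pytest.approx((G + 1) / (2 * G), abs=1e-12)

    def test_subclonal_genes_rank_above_stable(self):
        for seed in range(10):
            expr, annot, truth = simulate_cohort(
                SimulationParams(
                    n_patients=10, regions_per_patient=3, n_genes=400,
                    n_clonal_immune=20, n_subclonal_immune=20,
                    n_subclonal_background=80, seed=seed,
                )
            )
            table = compute_ihs(expr, annot)
            cat = truth.gene_category.reindex(table.index)
            assert (
                table.loc[cat == "subclonal_background", "ihs"].mean()
                > table.loc[cat == "stable_background", "ihs"].mean()
            )

    def test_single_region_patients_excluded(self, caplog):
        samples = ["A1", "A2", "B1", "B2", "C1"]
        patients = ["PA", "PA", "PB", "PB", "PC"]
        values = [[1.0, 2.0, 3.0, 4.0, 5.0], [2.0, 2.0, 6.0, 6.0, 1.0]]
        with caplog.at_level("WARNING", logger="ithsig"):
            table = compute_ihs(_matrix(values, samples), _annot(samples, patients))
        assert (table["n_patients_used"] == 2).all()
        assert any("single-region" in r.message for r in caplog.records)

    def test_expression_filter_and_empty_error(self):
        values = [[0.1, 0.2, 0.1, 0.2], [3.0, 3.5, 4.0, 4.5]]
        table = compute_ihs(
            _matrix(values, self.samples), _annot(self.samples, self.patients)
        )
        assert list(table.index) == ["G1"]
        with pytest.raises(ValidationError, match="filter"):
            compute_ihs(
                _matrix([[0.1] * 4], self.samples),
                _annot(self.samples, self.patients),
            )


class TestSelectLowIHS:
    def _table(self):
        samples, patients = ["A1", "A2", "B1", "B2"], ["PA", "PA", "PB", "PB"]
        rng = np.random.default_rng(5)
        values = rng.uniform(1, 8, size=(20, 4))
        return compute_ihs(_matrix(values, samples), _annot(samples, patients))

    def test_all_genes_is_identity(self):
        table = self._table()
        assert set(select_low_ihs(table, len(table)).genes) == set(table.index)

    def test_single_minimum(self):
        table = self._table()
        (gene,) = select_low_ihs(table, 1).genes
        assert table.loc[gene, "ihs"] == table["ihs"].min()

    def test_tie_break_prefers_smaller_h1(self):
        table = pd.DataFrame(
            {
                "h1": [0.5, 0.2, 0.0],
                "event_freq": [0.0, 0.0, 0.0],
                "rank_h1": [0.5, 0.5, 0.1],
                "rank_e": [0.5, 0.5, 0.1],
                "ihs": [0.5, 0.5, 0.1],
                "n_patients_used": 4,
                "flagged_constant": False,
            },
            index=pd.Index(["GA", "GB", "GC"], name="gene_id"),
        )
        assert select_low_ihs(table, 2).genes == ("GC", "GB")

    def test_oversized_request_reports_both_counts(self):
        table = self._table()
        with pytest.raises(ValidationError, match="20"):
            select_low_ihs(table, 21)
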