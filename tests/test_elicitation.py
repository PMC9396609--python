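"""Synthetic clinician cohorts, outlier screening, test battery, aggregation."""

import numpy as np
import pytest

from carecost import (
    ClinicianReport,
    ConfigError,
    GeneratorSpec,
    SampleSizeError,
    aggregate_reports,
    filter_outliers,
    generate_cohort,
    generate_reports,
    homogeneity_test,
    normality_test,
    ordering_tests,
)
from carecost import example as ex
from carecost.elicitation import TABLE_MEAN_FREQUENCIES


def _report(freqs, cid="c1"):
    return ClinicianReport(clinician_id=cid, state_frequencies=np.asarray(freqs, float))


class TestGenerator:
    def test_default_means_sum_to_one_with_remainder_severe(self):
        spec = GeneratorSpec()
        assert spec.mean_frequencies[:3] == TABLE_MEAN_FREQUENCIES
        # 1 - 0.54366667 - 0.31075 - 0.117333
        assert spec.mean_frequencies[3] == pytest.approx(0.02825033, abs=1e-8)
        assert sum(spec.mean_frequencies) == pytest.approx(1.0)

    def test_contamination_bookkeeping(self):
        spec = GeneratorSpec(n_clinicians=115, contamination=13 / 115, seed=5)
        reports, contaminated = generate_cohort(spec)
        assert len(reports) == 115
        assert len(contaminated) == 13 == spec.n_contaminated

    def test_high_concentration_limit_recovers_means(self):
        spec = GeneratorSpec(n_clinicians=10, contamination=0.0, dispersion=1e8, seed=1)
        for report in generate_reports(spec):
            np.testing.assert_allclose(
                report.state_frequencies, spec.mean_frequencies, atol=2e-3
            )

    def test_infeasible_means_rejected(self):
        with pytest.raises(ConfigError):
            GeneratorSpec(mean_frequencies=(0.7, 0.5, 0.1, 0.1))

    def test_same_seed_same_cohort(self):
        a = generate_reports(GeneratorSpec(n_clinicians=20, seed=9))
        b = generate_reports(GeneratorSpec(n_clinicians=20, seed=9))
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.state_frequencies, rb.state_frequencies)

    def test_matrix_estimates_preserve_structural_zeros(self):
        spec = GeneratorSpec(
            n_clinicians=5,
            contamination=0.0,
            seed=2,
            mean_accuracy=ex.cardiac_accuracy(),
            mean_transitions=ex.cardiac_raw_transitions(),
        )
        for report in generate_reports(spec):
            assert report.transition_estimates is not None
            trans = report.transition_estimates.values
            assert trans[1, 0] == trans[2, 0] == trans[2, 1] == 0.0
            # elicited row totals are preserved (moderate row sums to 0.957)
            assert trans[1].sum() == pytest.approx(0.957, abs=1e-9)
            assert report.false_treatment is not None


class TestOutlierScreen:
    def test_ordered_report_retained(self):
        retained, flagged = filter_outliers([_report([0.5, 0.3, 0.15, 0.05])])
        assert len(retained) == 1 and flagged == []

    def test_inverted_pair_flagged(self):
        retained, flagged = filter_outliers([_report([0.3, 0.5, 0.15, 0.05])])
        assert retained == [] and len(flagged) == 1

    def test_flagged_set_is_exactly_the_contaminated_set(self):
        spec = GeneratorSpec(n_clinicians=115, contamination=13 / 115, seed=17)
        reports, contaminated = generate_cohort(spec)
        retained, flagged = filter_outliers(reports)
        assert {r.clinician_id for r in flagged} == contaminated
        assert len(retained) == 102

    def test_empty_cohort_rejected(self):
        with pytest.raises(SampleSizeError):
            filter_outliers([])


class TestNormality:
    def test_dirichlet_cohorts_look_normal_in_most_replicates(self):
        passes = 0
        for seed in range(20):
            reports = generate_reports(
                GeneratorSpec(n_clinicians=100, contamination=0.0, seed=seed)
            )
            if normality_test(reports, state=0).p_value > 0.05:
                passes += 1
        assert passes >= 18  # >= 90% of seeded replicates

    def test_constant_sample_reported_undefined(self):
        reports = [_report([0.5, 0.3, 0.15, 0.05], f"c{i}") for i in range(5)]
        result = normality_test(reports, state=0)
        assert result.normal_at_05 is None and np.isnan(result.p_value)

    def test_bimodal_sample_rejected(self):
        rng = np.random.default_rng(0)
        reports = []
        for i in range(60):
            lo = 0.40 if i % 2 else 0.60
            a = lo + rng.normal(0, 0.004)
            rest = (1 - a) * np.array([0.6, 0.3, 0.1])
            reports.append(_report([a, *rest], f"c{i}"))
        assert normality_test(reports, state=0).p_value < 0.05

    def test_needs_three_reports(self):
        with pytest.raises(SampleSizeError):
            normality_test([_report([0.6, 0.4])], state=0)


class TestHomogeneity:
    def test_identical_reports_are_homogeneous(self):
        reports = [_report([0.5, 0.3, 0.15, 0.05], f"c{i}") for i in range(10)]
        result = homogeneity_test(reports)
        assert result.homogeneous
        assert all(result.band_ok.values())

    def test_default_cohort_within_two_percent_band(self):
        reports = generate_reports(
            GeneratorSpec(n_clinicians=102, contamination=0.0, seed=4)
        )
        result = homogeneity_test(reports, cutoff=0.02)
        assert result.homogeneous

    def test_dispersed_cohort_violates_band(self):
        reports = generate_reports(
            GeneratorSpec(n_clinicians=102, contamination=0.0, dispersion=50, seed=4)
        )
        result = homogeneity_test(reports, cutoff=0.02)
        assert not all(result.band_ok.values())
        assert not result.homogeneous


class TestOrdering:
    def test_emits_six_records_for_four_states(self):
        reports = generate_reports(GeneratorSpec(n_clinicians=30, seed=3))
        table = ordering_tests(reports)
        assert len(table) == 6

    def test_default_cohort_affirms_severity_ordering(self):
        reports, _ = generate_cohort(GeneratorSpec(n_clinicians=102, seed=8))
        retained, _ = filter_outliers(reports)
        table = ordering_tests(retained)
        assert table["ordered"].all()
        assert np.isfinite(table["t_stat"]).all()
        assert (table["t_critical_two_tailed"] > table["t_critical_one_tailed"]).all()

    def test_identical_columns_leave_ordering_unresolved(self):
        reports = [_report([0.3, 0.3, 0.25, 0.15], f"c{i}") for i in range(5)]
        table = ordering_tests(reports)
        first = table.iloc[0]  # states 0 vs 1 share identical values
        assert np.isnan(first["t_stat"]) and not first["ordered"]


class TestAggregate:
    def test_single_report_is_its_own_mean(self):
        report = _report([0.5, 0.3, 0.15, 0.05])
        agg = aggregate_reports([report])
        np.testing.assert_array_equal(agg.state_frequencies, report.state_frequencies)

    def test_two_report_midpoint(self):
        agg = aggregate_reports(
            [_report([0.6, 0.2, 0.15, 0.05], "a"), _report([0.5, 0.3, 0.15, 0.05], "b")]
        )
        np.testing.assert_allclose(agg.state_frequencies, [0.55, 0.25, 0.15, 0.05])

    def test_parameter_recovery_on_retained_cohort(self):
        spec = GeneratorSpec(n_clinicians=102, contamination=0.0, seed=21)
        retained, _ = filter_outliers(generate_reports(spec))
        agg = aggregate_reports(retained)
        se = np.sqrt(
            np.array(spec.mean_frequencies)
            * (1 - np.array(spec.mean_frequencies))
            / (spec.dispersion + 1)
            / len(retained)
        )
        assert np.all(
            np.abs(agg.state_frequencies - spec.mean_frequencies) <= 3 * se + 1e-12
        )
        assert np.all(np.abs(agg.state_frequencies - spec.mean_frequencies) < 0.01)

    def test_mixed_shapes_rejected(self):
        with pytest.raises(Exception):
            aggregate_reports([_report([0.6, 0.4], "a"), _report([0.5, 0.3, 0.2], "b")])

    def test_matrix_aggregation_recovers_generator_means(self):
        spec = GeneratorSpec(
            n_clinicians=60,
            contamination=0.0,
            seed=6,
            mean_accuracy=ex.cardiac_accuracy(),
            mean_transitions=ex.cardiac_raw_transitions(),
        )
        agg = aggregate_reports(generate_reports(spec))
        np.testing.assert_allclose(
            agg.accuracy.values, ex.cardiac_accuracy().values, atol=0.01
        )
        np.testing.assert_allclose(
            agg.transitions.values, ex.cardiac_raw_transitions().values, atol=0.01
        )
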