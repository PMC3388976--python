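"""Peak counting, EM mixture fitting, BIC selection and instar assignment."""

import numpy as np
import pytest

from instars.errors import (
    AnchoringConflictError,
    DegenerateDataError,
    InsufficientDataError,
    ValidationError,
)
from instars.inference import (
    AnchorSet,
    MixtureModel,
    assign_instars,
    build_anchors,
    count_modes,
    fit_mixture_em,
    select_instar_number,
)
from instars.morphdata import MeasurementRecord, SpecimenTable, Stage, Character
from instars.synthgen import default_config, sample_population


class TestCountModes:
    def test_default_population_has_three_distinct_peaks(self, default_widths):
        peaks = count_modes(default_widths)
        assert peaks.count == 3
        assert np.all(np.diff(peaks.locations) > 0)

    def test_peak_locations_near_component_means(self, default_widths):
        peaks = count_modes(default_widths)
        np.testing.assert_allclose(peaks.locations, [0.123, 0.151, 0.184], atol=0.004)

    def test_unimodal_sample_has_one_peak(self, unimodal_widths):
        assert count_modes(unimodal_widths).count == 1

    def test_density_integrates_to_one(self, default_widths):
        d = count_modes(default_widths).density
        assert abs(d.integral() - 1.0) < 1e-3
        assert np.all(d.density >= 0)

    def test_too_few_observations_rejected(self):
        with pytest.raises(InsufficientDataError):
            count_modes([0.1] * 5)
        with pytest.raises(InsufficientDataError):
            count_modes([])

    def test_non_positive_widths_rejected(self):
        with pytest.raises(ValidationError):
            count_modes([0.1, -0.2] + [0.1] * 10)

    def test_bandwidth_must_be_positive(self, default_widths):
        with pytest.raises(ValidationError):
            count_modes(default_widths, bandwidth=-0.01)


class TestFitMixtureEM:
    def test_k1_equals_closed_form_normal_mle(self, default_widths):
        """With one component EM is the exact (divisor-n) normal MLE."""
        m = fit_mixture_em(default_widths, k=1)
        assert m.means[0] == np.mean(default_widths)
        assert m.sds[0] == np.std(default_widths)
        assert m.weights[0] == 1.0
        assert m.converged

    def test_recovers_generator_component_means(self, default_mixture):
        np.testing.assert_allclose(
            default_mixture.means, [0.123, 0.151, 0.184], atol=0.003
        )
        assert default_mixture.converged

    def test_log_likelihood_is_monotone_nondecreasing(self, default_widths):
        m = fit_mixture_em(default_widths, k=3)
        path = m.log_likelihood_path
        assert np.all(np.diff(path) >= -1e-8 * np.maximum(1.0, np.abs(path[:-1])))

    def test_components_sorted_and_weights_normalized(self, default_mixture):
        assert np.all(np.diff(default_mixture.means) > 0)
        assert abs(default_mixture.weights.sum() - 1.0) < 1e-9

    def test_identical_values_are_degenerate_for_k2(self):
        with pytest.raises(DegenerateDataError):
            fit_mixture_em([0.15] * 50, k=2)

    def test_k_below_one_rejected(self, default_widths):
        with pytest.raises(ValidationError):
            fit_mixture_em(default_widths, k=0)

    def test_explicit_init_must_match_k(self, default_widths):
        with pytest.raises(ValidationError):
            fit_mixture_em(default_widths, k=3, init=[0.12, 0.18])

    def test_matches_sklearn_reference_fit(self, default_widths):
        """Independent cross-check against sklearn's GaussianMixture."""
        sklearn_mixture = pytest.importorskip("sklearn.mixture")
        ref = sklearn_mixture.GaussianMixture(
            n_components=3,
            means_init=np.array([[0.123], [0.151], [0.184]]),
            tol=1e-8,
            max_iter=500,
            reg_covar=0.0,
            random_state=0,
        ).fit(np.asarray(default_widths)[:, None])
        ours = fit_mixture_em(default_widths, k=3)
        np.testing.assert_allclose(
            ours.means, np.sort(ref.means_.ravel()), atol=1e-4
        )
        np.testing.assert_allclose(
            ours.log_likelihood, ref.score(np.asarray(default_widths)[:, None])
            * len(default_widths), rtol=1e-6,
        )


class TestSelectInstarNumber:
    def test_default_population_selects_three(self, default_selection):
        assert default_selection.k == 3

    def test_agrees_with_peak_count_on_default_population(
        self, default_widths, default_selection
    ):
        assert count_modes(default_widths).count == default_selection.k

    def test_unimodal_sample_selects_one(self, unimodal_widths):
        assert select_instar_number(unimodal_widths, k_max=4).k == 1

    def test_bic_table_is_complete(self, default_selection):
        t = default_selection.table()
        assert list(t["K"]) == [1, 2, 3, 4, 5, 6]
        assert t["bic"].idxmin() == 2  # K=3 row

    def test_kmax_zero_rejected(self, default_widths):
        with pytest.raises(ValidationError):
            select_instar_number(default_widths, k_max=0)

    def test_conflicting_anchors_raise(self, unimodal_widths):
        anchors = AnchorSet(embryo_interval=(0.50, 0.55))
        with pytest.raises(AnchoringConflictError):
            select_instar_number(unimodal_widths, k_max=2, anchors=anchors)

    @pytest.mark.parametrize("true_k", [1, 2, 3, 4])
    def test_recovers_component_count_across_seeds(self, true_k):
        """K* recovery for well-separated mixtures (>=4 sd apart), n=344."""
        sd = 0.006
        means = 0.12 * (1.3 ** np.arange(true_k))  # adjacent gaps >= 6 sd
        hits = 0
        n_rep = 25
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 * true_k + seed)
            comps = rng.integers(0, true_k, size=344)
            x = rng.normal(means[comps], sd)
            if select_instar_number(x, k_max=6).k == true_k:
                hits += 1
        assert hits >= int(0.95 * n_rep)


class TestAnchors:
    def test_intervals_are_min_max_of_stage_widths(self):
        recs = [
            MeasurementRecord(f"M{i}", Stage.EMBRYO, Character.HEAD_WIDTH, v)
            for i, v in enumerate([0.11, 0.12, 0.13])
        ]
        anchors = build_anchors(SpecimenTable.from_records(recs))
        assert anchors.embryo_interval == (0.11, 0.13)
        assert anchors.prepupa_interval is None

    def test_absent_stages_give_absent_intervals(self):
        rec = MeasurementRecord("L1", Stage.LARVA, Character.HEAD_WIDTH, 0.15)
        anchors = build_anchors(SpecimenTable.from_records([rec]))
        assert anchors.embryo_interval is None
        assert anchors.prepupa_interval is None

    def test_default_population_anchors_bracket_extreme_components(self, default_table):
        anchors = build_anchors(default_table)
        lo, hi = anchors.embryo_interval
        assert lo <= 0.123 <= hi
        lo, hi = anchors.prepupa_interval
        assert lo <= 0.184 <= hi


class TestAssignInstars:
    def test_width_at_component_mean_gets_that_component(self, default_mixture):
        a = assign_instars([0.123], default_mixture)
        assert a.labels[0] == 1

    def test_exact_posterior_tie_breaks_to_lower_instar(self):
        model = MixtureModel(
            k=2,
            means=np.array([1.0, 3.0]),
            sds=np.array([0.5, 0.5]),
            weights=np.array([0.5, 0.5]),
            log_likelihood=0.0,
            n_iterations=1,
            converged=True,
        )
        a = assign_instars([2.0], model)
        np.testing.assert_allclose(a.posteriors[0], [0.5, 0.5])
        assert a.labels[0] == 1

    def test_posterior_rows_sum_to_one(self, default_widths, default_mixture):
        a = assign_instars(default_widths, default_mixture)
        np.testing.assert_allclose(a.posteriors.sum(axis=1), 1.0, atol=1e-9)

    def test_accuracy_against_hidden_truth(self, default_table, default_widths, default_mixture):
        a = assign_instars(default_widths, default_mixture)
        truth = default_table.true_instars()
        assert np.mean(a.labels == truth) >= 0.95

    def test_far_observation_is_flagged_outlier_but_labeled(self, default_mixture):
        a = assign_instars([0.5], default_mixture)
        assert a.outlier[0]
        assert a.labels[0] == 3

    def test_empty_input_rejected(self, default_mixture):
        with pytest.raises(ValidationError):
            assign_instars([], default_mixture)

    def test_labels_invariant_under_rescaling_with_refit(self, default_widths):
        """Scaling all widths by a constant and refitting permutes nothing."""
        base = fit_mixture_em(default_widths, k=3)
        scaled = fit_mixture_em(np.asarray(default_widths) * 10.0, k=3)
        a = assign_instars(default_widths, base)
        b = assign_instars(np.asarray(default_widths) * 10.0, scaled)
        np.testing.assert_array_equal(a.labels, b.labels)
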