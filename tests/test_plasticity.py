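import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from itlearn import (
    BIG,
    MEDIUM,
    SMALL,
    ExposureEvent,
    ExposurePhaseSpec,
    ImageCondition,
    PlasticityConfig,
    apply_exposure_event,
    fit_plasticity_rate,
    generate_reference_trajectories,
    normalized_selectivity_change,
    rate_to_spikes,
    replicate_neural_exposure_design,
    run_exposure_phase,
    sample_population,
    select_P_N,
    select_subgroups,
)
from itlearn.stats import ValidationError
from .conftest import deterministic_stats


def _pop(mean=(2.0, 1.0), kernel=(1.0, 1.0, 1.0), n_sites=1):
    return sample_population(deterministic_stats(mean=mean, kernel=kernel), n_sites, seed=0)


class TestRule:
    def test_direct_substitution(self):
        pop = _pop(mean=(1.0, 0.5))
        ev = ExposureEvent(ImageCondition(0, MEDIUM), ImageCondition(1, BIG))
        apply_exposure_event(pop, ev, PlasticityConfig(alpha=0.0016))
        assert pop.base[0, 0, MEDIUM] == pytest.approx(0.9992)

    def test_equal_responses_are_fixed_point(self):
        pop = _pop(mean=(1.0, 1.0))
        before = pop.base.copy()
        ev = ExposureEvent(ImageCondition(0, MEDIUM), ImageCondition(1, BIG))
        apply_exposure_event(pop, ev, PlasticityConfig(alpha=0.2))
        assert np.array_equal(pop.base, before)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        alpha=st.floats(1e-4, 0.5),
        gap0=st.floats(-3.0, 3.0).filter(lambda g: abs(g) > 1e-3),
        k=st.integers(1, 400),
    )
    def test_gap_decay_closed_form(self, alpha, gap0, k):
        """Alternating exposure contracts the response gap by (1-alpha)/event."""
        pop = _pop(mean=(1.0 + gap0, 1.0), kernel=(1.0, 1.0, 1.0))
        a = ImageCondition(0, MEDIUM)
        b = ImageCondition(1, BIG)
        cfg = PlasticityConfig(alpha=alpha)
        for i in range(k):
            lead, lag = (a, b) if i % 2 == 0 else (b, a)
            apply_exposure_event(pop, ExposureEvent(lead, lag), cfg)
        gap = pop.base[0, 0, MEDIUM] - pop.base[0, 1, BIG]
        assert gap == pytest.approx(gap0 * (1 - alpha) ** k, abs=1e-9)

    def test_steady_state_convergence(self):
        alpha, gap0 = 0.01, 2.0
        k = int(np.ceil(np.log(1e-6) / np.log(1 - alpha))) + 10
        pop = _pop(mean=(1.0 + gap0, 1.0))
        cfg = PlasticityConfig(alpha=alpha)
        a, b = ImageCondition(0, MEDIUM), ImageCondition(1, BIG)
        for i in range(k):
            lead, lag = (a, b) if i % 2 == 0 else (b, a)
            apply_exposure_event(pop, ExposureEvent(lead, lag), cfg)
        assert abs(pop.base[0, 0, MEDIUM] - pop.base[0, 1, BIG]) < 1e-6 * gap0

    def test_event_validation(self):
        with pytest.raises(ValidationError):
            ExposureEvent(ImageCondition(0, SMALL), ImageCondition(1, BIG))
        with pytest.raises(ValidationError):
            ExposureEvent(ImageCondition(0, MEDIUM), ImageCondition(1, MEDIUM))


class TestExposurePhase:
    def test_zero_alpha_leaves_population_unchanged(self, small_pop):
        before = small_pop.base.copy()
        spec = ExposurePhaseSpec("swapped", (0, 1), n_events=100, seed=1)
        run_exposure_phase(small_pop, spec, PlasticityConfig(alpha=0.0))
        assert np.array_equal(small_pop.base, before)

    def test_locality_untouched_entries_bit_identical(self, small_pop):
        before = small_pop.base.copy()
        spec = ExposurePhaseSpec("swapped", (0, 1), (MEDIUM, BIG), 200, seed=2)
        run_exposure_phase(small_pop, spec, PlasticityConfig(alpha=0.01))
        mask = np.ones_like(before, dtype=bool)
        mask[:, [0, 1], MEDIUM] = False
        mask[:, [0, 1], BIG] = False
        assert np.array_equal(small_pop.base[mask], before[mask])

    def test_swapped_phase_reduces_selectivity(self, default_stats):
        pop = sample_population(default_stats, 300, seed=5)
        profiles = [select_P_N(s) for s in pop.sites]
        gaps0 = np.array([p.gap_by_size[BIG] for p in profiles])
        # expose each pair of objects (40, 41); measure the 40-vs-41 gap
        gap0 = pop.base[:, 40, BIG] - pop.base[:, 41, BIG]
        spec = ExposurePhaseSpec("swapped", (40, 41), (MEDIUM, BIG), 400, seed=3)
        run_exposure_phase(pop, spec, PlasticityConfig(alpha=0.0016))
        gap1 = pop.base[:, 40, BIG] - pop.base[:, 41, BIG]
        assert np.abs(gap1).mean() < np.abs(gap0).mean()

    def test_event_log_counts_and_counterbalancing(self, small_pop):
        spec = ExposurePhaseSpec("swapped", (0, 1), (MEDIUM, BIG), 400, seed=4)
        log = run_exposure_phase(small_pop, spec, PlasticityConfig(alpha=0.0))
        assert len(log) == 400
        med_first = (log["leading_size"] == MEDIUM).mean()
        assert 0.4 <= med_first <= 0.6
        # swapped flavor: leading and lagging objects always differ
        assert (log["leading_object"] != log["lagging_object"]).all()
        # both pairings occur equally often
        a_med = ((log["leading_object"] == 0) & (log["leading_size"] == MEDIUM)) | (
            (log["lagging_object"] == 0) & (log["lagging_size"] == MEDIUM)
        )
        assert a_med.sum() == 200

    def test_non_swapped_pairs_same_object(self, small_pop):
        spec = ExposurePhaseSpec("non_swapped", (0, 1), (MEDIUM, BIG), 100, seed=4)
        log = run_exposure_phase(small_pop, spec, PlasticityConfig(alpha=0.0))
        assert (log["leading_object"] == log["lagging_object"]).all()


class TestSelectivity:
    def test_two_to_one_gives_one_third(self):
        pop = _pop(mean=(2.0, 1.0))
        prof = select_P_N(pop.site(0))
        assert prof.P == 0 and prof.N == 1
        assert np.allclose(prof.selectivity_by_size, 1 / 3)

    def test_flat_site_flagged_degenerate(self):
        pop = _pop(mean=(1.0, 1.0))
        prof = select_P_N(pop.site(0))
        assert prof.degenerate.all()

    def test_P_exceeds_N_by_construction(self, small_pop):
        for site in small_pop.sites:
            prof = select_P_N(site)
            by_obj = site.base_matrix.mean(axis=1)
            assert by_obj[prof.P] >= by_obj[prof.N]

    def test_normalized_change_arithmetic(self):
        pop = _pop(mean=(2.0, 1.0))
        before = select_P_N(pop.site(0))
        pop.base[0, 0, BIG] = 1.75  # gap 1.0 -> 0.75
        after = select_P_N(pop.site(0))
        assert normalized_selectivity_change(before, after, BIG) == pytest.approx(-0.25)
        assert normalized_selectivity_change(before, before, MEDIUM) == 0.0

    def test_zero_initial_gap_excluded(self):
        pop = _pop(mean=(1.0, 1.0))
        prof = select_P_N(pop.site(0))
        assert np.isnan(normalized_selectivity_change(prof, prof, BIG))


class TestNeuralDesignReplication:
    def test_zero_alpha_flat_trajectories(self, default_stats):
        pop = sample_population(default_stats, 50, seed=1)
        traj = replicate_neural_exposure_design(
            pop, PlasticityConfig(alpha=0.0), n_events_per_arrow=50, seed=0
        )
        for v in traj.changes.values():
            assert np.allclose(v, 0.0)

    def test_rate_monotonicity(self, default_stats):
        results = {}
        for alpha in (0.0016, 0.0064):
            pop = sample_population(default_stats, 300, seed=6)
            traj = replicate_neural_exposure_design(
                pop, PlasticityConfig(alpha=alpha), n_events_per_arrow=400, seed=6
            )
            results[alpha] = traj
        # the non-swapped (building) trajectory overshoots and reverses at
        # high rates, so magnitude monotonicity holds for the conditions
        # driven monotonically toward convergence
        for k in ("swapped", "medium"):
            assert np.all(
                np.abs(results[0.0064].changes[k][1:])
                > np.abs(results[0.0016].changes[k][1:])
            )
        assert abs(results[0.0064].changes["non_swapped"][1]) > abs(
            results[0.0016].changes["non_swapped"][1]
        )

    def test_saturation_of_increments(self, default_stats):
        pop = sample_population(default_stats, 300, seed=8)
        traj = replicate_neural_exposure_design(
            pop, PlasticityConfig(alpha=0.0016), n_events_per_arrow=400, seed=8
        )
        s = traj.changes["swapped"]
        assert abs(s[-1] - s[-2]) < abs(s[1] - s[0])

    def test_directionality(self, default_stats):
        pop = sample_population(default_stats, 300, seed=9)
        traj = replicate_neural_exposure_design(
            pop, PlasticityConfig(alpha=0.0016), n_events_per_arrow=400, seed=9
        )
        assert traj.changes["swapped"][-1] < 0
        assert traj.changes["non_swapped"][-1] > 0


class TestSubgroups:
    def test_unbounded_thresholds_select_everyone(self, small_pop):
        profiles = [select_P_N(s) for s in small_pop.sites]
        groups = select_subgroups(
            profiles, {"all": {BIG: (-np.inf, np.inf)}}
        )
        assert len(groups["all"]) == small_pop.n_sites

    def test_empty_group_warns(self, small_pop):
        profiles = [select_P_N(s) for s in small_pop.sites]
        with pytest.warns(UserWarning, match="empty"):
            select_subgroups(profiles, {"none": {BIG: (np.inf, np.inf)}})

    def test_low_selectivity_sites_reverse_under_swapped_exposure(self, default_stats):
        pop = sample_population(default_stats, 1000, seed=12)
        profiles = [select_P_N(s) for s in pop.sites]
        groups = select_subgroups(
            profiles,
            {"low_at_swap": {SMALL: (0.0, 0.8)}, "moderate_at_swap": {SMALL: (1.5, 3.5)}},
        )
        P = np.array([p.P for p in profiles])
        N = np.array([p.N for p in profiles])
        rows = np.arange(pop.n_sites)
        replicate_neural_exposure_design(
            pop, PlasticityConfig(alpha=0.0016), n_events_per_arrow=400, seed=12
        )
        gap_after = pop.base[rows, P, SMALL] - pop.base[rows, N, SMALL]
        low = groups["low_at_swap"]
        moderate = groups["moderate_at_swap"]
        assert gap_after[low].mean() < 0  # preference reversal
        gap0 = np.array([p.gap_by_size[SMALL] for p in profiles])
        assert gap_after[moderate].mean() < gap0[moderate].mean()  # reduction

    def test_building_of_new_selectivity(self, default_stats):
        # strong selectivity at medium but weak at the non-swapped (big)
        # size: non-swapped arrows build selectivity at that size
        pop = sample_population(default_stats, 1000, seed=13)
        profiles = [select_P_N(s) for s in pop.sites]
        groups = select_subgroups(
            profiles,
            {"build": {MEDIUM: (3.0, np.inf), BIG: (-0.5, 1.0)}},
        )
        idx = groups["build"]
        assert len(idx) > 5
        P = np.array([p.P for p in profiles])
        N = np.array([p.N for p in profiles])
        gap0 = pop.base[np.arange(pop.n_sites), P, BIG] - pop.base[
            np.arange(pop.n_sites), N, BIG
        ]
        replicate_neural_exposure_design(
            pop, PlasticityConfig(alpha=0.0016), n_events_per_arrow=400, seed=13
        )
        gap1 = pop.base[np.arange(pop.n_sites), P, BIG] - pop.base[
            np.arange(pop.n_sites), N, BIG
        ]
        assert gap1[idx].mean() > gap0[idx].mean()


class TestRateFit:
    def test_zero_reference_picks_smallest_rate(self, default_stats):
        ref = generate_reference_trajectories(0.0, n_sites=50, seed=0, stats=default_stats)
        fit = fit_plasticity_rate(
            ref, default_stats, grid=[1e-4, 1e-3, 1e-2], n_sites=50, n_repeats=1, seed=0
        )
        assert fit.alpha_star == 1e-4
        assert np.all(np.diff(fit.loss) > 0)

    def test_single_point_grid_returns_it(self, default_stats):
        ref = generate_reference_trajectories(
            0.0016, n_sites=50, seed=0, stats=default_stats
        )
        fit = fit_plasticity_rate(
            ref, default_stats, grid=[0.0007], n_sites=50, n_repeats=1, seed=0
        )
        assert fit.alpha_star == 0.0007

    def test_empty_grid_rejected(self, default_stats):
        ref = generate_reference_trajectories(
            0.0016, n_sites=50, seed=0, stats=default_stats
        )
        with pytest.raises(ValidationError):
            fit_plasticity_rate(ref, default_stats, grid=[])


class TestRateToSpikes:
    @pytest.mark.parametrize(
        "alpha,scale,expected",
        [(0.0016, 23.0, 0.0368), (0.0, 23.0, 0.0), (0.5, 1.0, 0.5)],
    )
    def test_conversion(self, alpha, scale, expected, default_stats):
        stats = default_stats
        stats = type(stats)(
            n_objects=stats.n_objects,
            n_categories=stats.n_categories,
            object_mean=stats.object_mean,
            object_covariance=stats.object_covariance,
            size_kernel_pool=stats.size_kernel_pool,
            clutter_variance_by_object=stats.clutter_variance_by_object,
            repetition_fano=stats.repetition_fano,
            rate_scale=scale,
            rate_offset=stats.rate_offset,
        )
        assert rate_to_spikes(alpha, stats) == pytest.approx(expected)
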