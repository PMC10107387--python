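"""Decomposition operator, separability cost, and threshold search."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pretermsig as ps
from pretermsig.lsdl import DecompositionError, ThresholdCandidate, _cost_from_matrix
from oracles import brute_cost_j


class TestDecompose:
    def test_lower_first_iteration_halves_a_uniform_ramp(self):
        x = np.linspace(0.0, 1.0, 1001)  # |x| uniform on [0, A], A = 1
        kept = ps.decompose(x, "lower", 1, A=1.0)
        assert abs(kept.size / x.size - 0.5) < 0.01

    def test_upper_and_lower_first_iterations_cover_everything(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 500)
        a = float(np.max(np.abs(x)))
        lo = ps.decompose(x, "lower", 1, A=a)
        hi = ps.decompose(x, "upper", 1, A=a)
        assert lo.size + hi.size >= x.size  # boundary samples kept by both

    def test_retained_samples_keep_time_order(self):
        x = np.array([0.1, 0.9, 0.2, 0.8, 0.3] * 10)
        kept = ps.decompose(x, "lower", 1, A=1.0)
        assert np.array_equal(kept, x[np.abs(x) <= 0.5])

    def test_constant_at_reference_amplitude_fails_lower(self):
        with pytest.raises(DecompositionError):
            ps.decompose(np.ones(100), "lower", 1, A=1.0)

    def test_degenerate_reference_amplitude_rejected(self):
        with pytest.raises(ValueError):
            ps.decompose(np.ones(100), "lower", 1, A=0.0)

    def test_dyadic_thresholds(self):
        assert [ps.threshold_fraction("lower", i) for i in (1, 2, 3, 4)] == [
            0.5, 0.75, 0.875, 0.9375,
        ]
        assert [ps.threshold_fraction("upper", i) for i in (1, 2, 3, 4)] == [
            0.5, 0.25, 0.125, 0.0625,
        ]


class TestCostJ:
    def test_hand_worked_example(self):
        """Class means p=(0,0), q=(3,4): ED = 5, J = 5 / mean(sigma)."""
        f1 = np.array([[0.0, 0.0], [0.0, 0.0]])
        f2 = np.array([[3.0, 4.0], [3.0, 4.0]])
        # pooled per-feature population SDs are (1.5, 2.0) here, so
        # J = sqrt(3^2 + 4^2) / 1.75 by direct hand evaluation
        assert np.isclose(ps.cost_J(f1, f2), 5.0 / 1.75, rtol=1e-12)
        assert np.isclose(ps.cost_J(f1, f2), brute_cost_j(f1, f2), rtol=1e-12)

    def test_identical_class_means_give_zero(self):
        rng = np.random.default_rng(2)
        f1 = rng.normal(size=(4, 3))
        assert ps.cost_J(f1, f1.copy()) == 0.0

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(100):
            n1 = int(rng.integers(2, 7))
            n2 = int(rng.integers(2, 7))
            nw = int(rng.integers(1, 4))
            f1 = rng.normal(size=(n1, nw)) * rng.uniform(0.5, 10)
            f2 = rng.normal(size=(n2, nw)) * rng.uniform(0.5, 10)
            assert np.isclose(
                ps.cost_J(f1, f2), brute_cost_j(f1, f2), rtol=1e-12
            )

    @given(scale=st.floats(1e-3, 1e3), shift=st.floats(-100, 100))
    @settings(derandomize=True, max_examples=50)
    def test_scale_and_shift_invariance(self, scale, shift):
        """J is invariant under common positive rescaling and per-feature shifts."""
        rng = np.random.default_rng(7)
        f1 = rng.normal(size=(5, 4))
        f2 = rng.normal(loc=1.0, size=(6, 4))
        j0 = ps.cost_J(f1, f2)
        assert np.isclose(ps.cost_J(f1 * scale, f2 * scale), j0, rtol=1e-9)
        shifted = np.zeros(4)
        shifted[2] = shift
        assert np.isclose(ps.cost_J(f1 + shifted, f2 + shifted), j0, rtol=1e-6)

    def test_all_constant_features_rejected(self):
        f = np.ones((3, 2))
        with pytest.raises(ValueError, match="sigma_m"):
            ps.cost_J(f, f * 1.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ps.cost_J(np.ones((2, 3)), np.ones((2, 4)))


def _candidates_from_grid(upper, lower):
    cands = []
    for region, costs in (("upper", upper), ("lower", lower)):
        for i, c in enumerate(costs, start=1):
            cand = ThresholdCandidate(
                region, i, ps.threshold_fraction(region, i)
            )
            if c is None:
                cand.valid = False
            else:
                cand.cost = c
            cands.append(cand)
    return cands


class TestSelectBest:
    def test_argmax_over_candidate_grid(self):
        cands = _candidates_from_grid(
            upper=[2.1231, 2.1326, 2.1355, 2.1368],
            lower=[2.2506, 2.3212, 2.3194, 2.1926],
        )
        best = ps.select_best(cands)
        assert (best.region, best.iteration, best.cost) == ("lower", 2, 2.3212)

    def test_invalid_candidates_excluded(self):
        cands = _candidates_from_grid(
            upper=[2.0087, 2.7624, None, None], lower=[None, None, None, None]
        )
        best = ps.select_best(cands)
        assert (best.region, best.iteration, best.cost) == ("upper", 2, 2.7624)

    def test_ties_resolve_to_lower_region_smallest_iteration(self):
        cands = _candidates_from_grid(upper=[1.0] * 4, lower=[1.0] * 4)
        best = ps.select_best(cands)
        assert (best.region, best.iteration) == ("lower", 1)

    def test_no_valid_candidate_raises(self):
        cands = _candidates_from_grid(upper=[None] * 4, lower=[None] * 4)
        with pytest.raises(ValueError):
            ps.select_best(cands)


class TestSearchOptimal:
    def test_permutation_invariance_wrt_record_order(self, small_window_sets):
        m1 = ps.search_optimal(small_window_sets)
        m2 = ps.search_optimal(list(reversed(small_window_sets)))
        assert m1.best.region == m2.best.region
        assert m1.best.iteration == m2.best.iteration
        assert np.isclose(m1.best.cost, m2.best.cost, rtol=1e-9)
        assert m1.reference_amp == m2.reference_amp

    def test_best_cost_is_max_over_valid_candidates(self, small_feature_tables):
        _, _, model = small_feature_tables
        valid = [c.cost for c in model.candidates if c.valid]
        assert model.best.cost == max(valid)

    def test_single_class_training_rejected(self, small_window_sets):
        only_term = [ws for ws in small_window_sets if ws.label == "term"]
        with pytest.raises(ValueError):
            ps.search_optimal(only_term)

    def test_json_round_trip(self, small_feature_tables, tmp_path):
        _, _, model = small_feature_tables
        path = str(tmp_path / "model.json")
        model.to_json(path)
        back = ps.LSDLModel.from_json(path)
        assert back.best.region == model.best.region
        assert back.best.iteration == model.best.iteration
        assert back.reference_amp == model.reference_amp
        assert len(back.candidates) == len(model.candidates)


class TestApply:
    def test_replays_training_decomposition(self, small_window_sets, small_feature_tables):
        _, _, model = small_feature_tables
        w = small_window_sets[0].windows[0]
        direct = ps.decompose(
            w, model.best.region, model.best.iteration, model.reference_amp,
            min_samples=model.min_samples,
        )
        assert np.array_equal(model.apply_to_window(w), direct)

    def test_zero_signal_fully_retained_by_lower_rule(self):
        model = ps.LSDLModel(
            best=ThresholdCandidate("lower", 2, 0.75, cost=1.0),
            reference_amp=10.0,
            candidates=[],
        )
        x = np.zeros(100)
        assert np.array_equal(model.apply_to_window(x), x)

    def test_strict_mode_errors_when_band_empty(self):
        model = ps.LSDLModel(
            best=ThresholdCandidate("upper", 1, 0.5, cost=1.0),
            reference_amp=10.0,
            candidates=[],
        )
        x = np.full(100, 0.1)  # all |x| far below A/2
        with pytest.raises(DecompositionError):
            model.apply_to_window(x, on_failure="strict")
        # fallback mode returns the raw window
        assert np.array_equal(model.apply_to_window(x, on_failure="raw"), x)


class TestPermutationNull:
    def test_null_distribution_brackets_zero_effect(self):
        """With no class effect, the observed best J is null-consistent."""
        p = ps.CohortParams(
            n_term=6, n_preterm=6, duration=1200.0, seed=21,
            burst_amp_gain={"term": 1.0, "preterm": 1.0},
            burst_rate_per_10min={"term": 4.0, "preterm": 4.0},
        )
        cohort = ps.generate_cohort(p)
        wss = [ps.window_disjoint(r, 10) for r in cohort]
        observed, null = ps.permutation_null(wss, n_permutations=39, seed=5)
        p_value = (1 + np.sum(null >= observed)) / (1 + null.size)
        assert p_value > 0.05
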