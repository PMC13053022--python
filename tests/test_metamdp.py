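import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metasearch import (
    TERMINATE,
    BeliefState,
    Measurement,
    MetaMDPParams,
    attention_mask,
    budget_from_deadline,
    init_beliefs,
    run_episode,
    sample_measurement,
    step,
    target_posterior,
    update_beliefs,
    fixate_map_policy,
)
from conftest import make_scene
from oracles import merge_measurements, posterior_quadrature


def make_belief(F, J, f_target, phantom_mask=None):
    F = np.atleast_2d(np.asarray(F, dtype=float))
    J = np.atleast_2d(np.asarray(J, dtype=float))
    mask = (
        np.zeros(F.shape[0], dtype=bool)
        if phantom_mask is None
        else np.asarray(phantom_mask, dtype=bool)
    )
    return BeliefState(F=F, J=J, f_target=np.atleast_1d(np.asarray(f_target, float)), phantom_mask=mask)


class TestInitialization:
    def test_initial_variance_is_100(self, small_scene, small_params):
        b = init_beliefs(small_scene, small_params, 0)
        np.testing.assert_allclose(1.0 / b.J, 100.0)

    def test_symmetric_objects_get_uniform_posterior(self):
        b = make_belief([[0.0], [0.0]], [[0.01], [0.01]], [1.0])
        np.testing.assert_allclose(b.p, [0.5, 0.5])

    def test_initial_means_centered(self, small_scene, small_params):
        samples = np.concatenate(
            [init_beliefs(small_scene, small_params, s).F.ravel() for s in range(700)]
        )
        # 10^4+ draws of N(0, 0.01^2): the mean is within ~3 SEs of 0
        assert abs(samples.mean()) < 0.001
        assert samples.size > 10_000

    def test_target_vector_copied_from_scene(self, small_scene, small_params):
        b = init_beliefs(small_scene, small_params, 0)
        np.testing.assert_array_equal(b.f_target, small_scene.target_features)


class TestAttentionMask:
    def test_fixated_object_gets_full_scale(self, small_scene, small_params):
        g = attention_mask(small_scene.locations, 2, small_params)
        assert g[2] == pytest.approx(3.0)
        assert np.argmax(g) == 2

    def test_orthogonal_object_underflows_without_nan(self):
        locs = np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 0.0]])
        g = attention_mask(locs, 0, MetaMDPParams(theta=0.9))
        assert g[1] == pytest.approx(3.0 * math.exp(-200.0), abs=1e-80)
        assert np.all(np.isfinite(g)) and np.all(g >= 0)

    def test_ten_degree_offset_matches_hand_computation(self):
        ang = math.radians(10.0)
        locs = np.array([[0.0, 0.0, 1.0], [math.sin(ang), 0.0, math.cos(ang)]])
        g = attention_mask(locs, 0, MetaMDPParams(theta=0.9))
        expected = 3.0 * math.exp((math.cos(ang) - 1.0) * 200.0)
        assert g[1] == pytest.approx(expected, rel=1e-12)

    def test_non_unit_location_rejected(self, small_params):
        locs = np.array([[0.0, 0.0, 2.0], [0.0, 1.0, 0.0]])
        with pytest.raises(ValueError, match="unit"):
            attention_mask(locs, 0, small_params)


class TestMeasurement:
    def test_high_precision_limit_recovers_latent_state(self, small_scene):
        params = MetaMDPParams(theta=0.9)
        rng = np.random.default_rng(0)
        g = np.full(small_scene.n_objects, 1e8)
        m = sample_measurement(small_scene, g, params, rng)
        np.testing.assert_allclose(m.X, small_scene.features, atol=1e-3)

    def test_floor_precision_is_a_no_op(self, small_scene, small_params):
        rng = np.random.default_rng(1)
        b = init_beliefs(small_scene, small_params, 2)
        g = np.full(small_scene.n_objects, 1e-15)  # below the floor
        m = sample_measurement(small_scene, g, small_params, rng)
        b2 = update_beliefs(b, m)
        np.testing.assert_array_equal(b2.F, b.F)
        np.testing.assert_array_equal(b2.J, b.J)

    def test_measurement_variance_matches_precision(self, small_scene):
        params = MetaMDPParams(theta=0.9)
        rng = np.random.default_rng(3)
        g = np.full(small_scene.n_objects, 4.0)
        errs = np.concatenate(
            [
                (sample_measurement(small_scene, g, params, rng).X - small_scene.features).ravel()
                for _ in range(2000)
            ]
        )
        assert errs.var() == pytest.approx(0.25, rel=0.05)


class TestBeliefUpdate:
    def test_zero_precision_measurement_is_identity(self, small_scene, small_params):
        b = init_beliefs(small_scene, small_params, 0)
        m = Measurement(X=np.zeros_like(b.F), J_meas=np.zeros_like(b.J))
        b2 = update_beliefs(b, m)
        np.testing.assert_array_equal(b2.F, b.F)
        np.testing.assert_array_equal(b2.J, b.J)

    def test_single_cell_arithmetic(self):
        b = make_belief([[0.0]], [[0.01]], [0.0])
        m = Measurement(X=np.array([[1.0]]), J_meas=np.array([[3.0]]))
        b2 = update_beliefs(b, m)
        assert b2.F[0, 0] == pytest.approx(3.0 / 3.01)
        assert b2.J[0, 0] == pytest.approx(3.01)

    def test_sequential_equals_merged(self):
        """Conjugacy: applying measurements one by one equals the one-shot
        precision-weighted combination."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            n_o, n_f = rng.integers(2, 5), rng.integers(1, 4)
            b0 = make_belief(
                rng.normal(size=(n_o, n_f)),
                rng.uniform(0.01, 2.0, size=(n_o, n_f)),
                rng.normal(size=n_f),
            )
            ms = [
                Measurement(
                    X=rng.normal(size=(n_o, n_f)),
                    J_meas=np.repeat(rng.uniform(0.0, 5.0, size=(n_o, 1)), n_f, axis=1),
                )
                for _ in range(rng.integers(2, 6))
            ]
            seq = b0
            for m in ms:
                seq = update_beliefs(seq, m)
            X, Jm = merge_measurements(ms)
            merged = update_beliefs(b0, Measurement(X=X, J_meas=Jm))
            np.testing.assert_allclose(seq.F, merged.F, atol=1e-10)
            np.testing.assert_allclose(seq.J, merged.J, atol=1e-10)

    def test_order_invariance(self):
        rng = np.random.default_rng(9)
        b0 = make_belief(rng.normal(size=(3, 2)), rng.uniform(0.01, 1, (3, 2)), rng.normal(size=2))
        ms = [
            Measurement(X=rng.normal(size=(3, 2)), J_meas=np.abs(rng.normal(size=(3, 2))))
            for _ in range(4)
        ]
        fwd = b0
        for m in ms:
            fwd = update_beliefs(fwd, m)
        rev = b0
        for m in reversed(ms):
            rev = update_beliefs(rev, m)
        np.testing.assert_allclose(fwd.F, rev.F, atol=1e-10)
        np.testing.assert_allclose(fwd.J, rev.J, atol=1e-10)

    def test_negative_precision_rejected(self, small_scene, small_params):
        b = init_beliefs(small_scene, small_params, 0)
        m = Measurement(X=np.zeros_like(b.F), J_meas=np.full_like(b.J, -1.0))
        with pytest.raises(ValueError):
            update_beliefs(b, m)


class TestTargetPosterior:
    def test_identical_beliefs_give_uniform(self):
        b = make_belief(np.full((3, 2), 0.3), np.full((3, 2), 1.7), [0.5, -0.2])
        np.testing.assert_allclose(b.p, 1.0 / 3.0)

    def test_certainty_limit(self):
        """Confident match -> posterior 1; confident mismatch -> 0."""
        b = make_belief([[1.0], [5.0]], [[1e8], [1e8]], [1.0])
        np.testing.assert_allclose(b.p, [1.0, 0.0], atol=1e-12)

    def test_matches_quadrature_oracle_small(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n_o = int(rng.integers(2, 4))
            n_f = int(rng.integers(1, 3))
            b = make_belief(
                rng.normal(scale=1.5, size=(n_o, n_f)),
                rng.uniform(0.01, 8.0, size=(n_o, n_f)),
                rng.normal(size=n_f),
            )
            expected = posterior_quadrature(b.F, b.J, b.f_target, b.phantom_mask)
            np.testing.assert_allclose(b.p, expected, atol=1e-6)

    def test_phantoms_carry_zero_mass(self):
        scene = make_scene([[0.5], [0.2], [0.0]], target_index=0,
                           phantom_mask=[False, False, True])
        b = init_beliefs(scene, MetaMDPParams(theta=0.9), 0)
        assert b.p[2] == 0.0
        assert b.p.sum() == pytest.approx(1.0)

    def test_all_phantom_rejected(self):
        with pytest.raises(ValueError, match="phantom"):
            make_belief([[0.0], [0.0]], [[0.01], [0.01]], [0.0], phantom_mask=[True, True])

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_posterior_normalized_over_non_phantoms(self, seed):
        rng = np.random.default_rng(seed)
        n_o, n_f = int(rng.integers(2, 6)), int(rng.integers(1, 4))
        mask = np.zeros(n_o, dtype=bool)
        mask[int(rng.integers(1, n_o)):] = rng.random() < 0.5
        b = make_belief(
            rng.normal(size=(n_o, n_f)), rng.uniform(0.01, 20, (n_o, n_f)),
            rng.normal(size=n_f), phantom_mask=mask,
        )
        assert b.p.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(b.p[mask] == 0.0)


class TestStepAndEpisode:
    def test_fixation_costs_exactly_c(self, small_scene):
        params = MetaMDPParams(theta=0.9)
        b = init_beliefs(small_scene, params, 0)
        _, reward, done, _ = step(small_scene, b, 0, params, np.random.default_rng(0))
        assert reward == pytest.approx(-0.01)
        assert not done

    def test_terminate_rewards_correct_report(self):
        scene = make_scene([[1.0], [-1.0]], target_index=0)
        params = MetaMDPParams(theta=0.9)
        b = make_belief([[1.0], [-1.0]], [[100.0], [100.0]], [1.0])
        _, reward, done, info = step(scene, b, TERMINATE, params, np.random.default_rng(0))
        assert (reward, done, info["report"]) == (1.0, True, 0)

    def test_terminate_with_wrong_map_gets_zero(self):
        scene = make_scene([[1.0], [-1.0]], target_index=0)
        params = MetaMDPParams(theta=0.9)
        b = make_belief([[-1.0], [1.0]], [[100.0], [100.0]], [1.0])
        _, reward, _, info = step(scene, b, TERMINATE, params, np.random.default_rng(0))
        assert (reward, info["report"]) == (0.0, 1)

    def test_phantom_fixation_rejected(self):
        scene = make_scene([[1.0], [0.0]], target_index=0, phantom_mask=[False, True])
        params = MetaMDPParams(theta=0.9)
        b = init_beliefs(scene, params, 0)
        with pytest.raises(ValueError, match="phantom"):
            step(scene, b, 1, params, np.random.default_rng(0))

    def test_discriminable_target_found_quickly(self, two_object_scene):
        params = MetaMDPParams(theta=0.51, fixation_budget=22)
        wins = [
            run_episode(two_object_scene, fixate_map_policy(0.51), params, s)
            for s in range(30)
        ]
        assert np.mean([t.correct for t in wins]) > 0.8
        assert np.mean([t.n_fixations for t in wins]) < 6

    def test_budget_timeout_records_no_report(self):
        scene = make_scene([[0.1], [0.1]], target_index=0)
        params = MetaMDPParams(theta=0.999, fixation_budget=1)
        tr = run_episode(scene, fixate_map_policy(0.999), params, 0)
        assert tr.termination == "budget"
        assert tr.report is None and tr.correct == 0
        assert tr.n_fixations == 1

    def test_return_bookkeeping_identity(self, small_scene):
        params = MetaMDPParams(theta=0.9)
        for seed in range(10):
            tr = run_episode(small_scene, fixate_map_policy(0.9), params, seed)
            assert tr.return_ == pytest.approx(tr.correct - 0.01 * tr.n_fixations)

    def test_episode_reproducible(self, small_scene):
        params = MetaMDPParams(theta=0.9)
        a = run_episode(small_scene, fixate_map_policy(0.9), params, 123)
        b = run_episode(small_scene, fixate_map_policy(0.9), params, 123)
        assert a.fixations == b.fixations and a.return_ == b.return_

    def test_precision_nondecreasing_over_episode(self, small_scene):
        params = MetaMDPParams(theta=0.9)
        rng = np.random.default_rng(0)
        b = init_beliefs(small_scene, params, rng)
        policy = fixate_map_policy(0.9)
        prev_J = b.J.copy()
        for _ in range(10):
            a = policy(b, rng)
            if a == TERMINATE:
                break
            b, _, _, _ = step(small_scene, b, a, params, rng)
            assert np.all(b.J >= prev_J - 1e-12)
            prev_J = b.J.copy()

    def test_harder_discrimination_takes_longer(self):
        """Monte-Carlo trend: higher distractor similarity -> more fixations.

        Holds in the regime where confusable distractors prolong evidence
        accumulation (moderate similarity). At extreme similarity the trend
        reverses because look-alike distractors trigger early false-alarm
        terminations, so the trend is asserted over [0, 0.6].
        """
        from metasearch import SceneGeneratorConfig, generate_scene, simulate_policy

        def mean_fix(similarity):
            cfg = SceneGeneratorConfig(
                n_objects_min=10, n_objects_max=10, n_features=4,
                distractor_similarity=similarity, max_objects=10,
            )
            scenes = [generate_scene(cfg, s) for s in range(10)]
            params = MetaMDPParams(theta=0.9)
            trs = simulate_policy(scenes, lambda s: fixate_map_policy(0.9), params, 300, 5)
            return np.mean([t.n_fixations for t in trs])

        assert mean_fix(0.3) >= mean_fix(0.0)
        assert mean_fix(0.6) >= mean_fix(0.3)

    def test_budget_from_deadline(self):
        assert budget_from_deadline(8.0) == 22
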