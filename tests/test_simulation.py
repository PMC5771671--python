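"""Tests for ensemble integration, attractor geometry, and fate scoring."""

import numpy as np
import pytest

from fateplane import (CELLS, Condition, FateProportions, build_condition,
                       find_fixed_points, get_preset, integrate_ensemble,
                       run_condition, run_conditions, sample_initial_states,
                       score_fates, fate_weights)
from fateplane.core import saturate


class TestInitialStates:
    def test_noiseless_limit_is_deterministic(self, main_params, rng):
        p = main_params.replace(D=0.0)
        states = sample_initial_states(p, 7, rng)
        np.testing.assert_allclose(states, saturate(p.m0) * np.ones((7, 5, 2)))

    def test_ou_stationary_covariance(self, main_params, rng):
        # The pre-competence law is the OU stationary distribution: mean
        # sigma1(m0), isotropic covariance D*tau.  Cross-checked against a
        # long Euler-Maruyama burn-in of the f-removed dynamics.
        n = 100_000
        states = sample_initial_states(main_params, n, rng)[:, 0, :]
        np.testing.assert_allclose(states.mean(axis=0), saturate(main_params.m0),
                                   atol=4e-3)
        cov = np.cov(states.T)
        expect = main_params.D * main_params.tau
        np.testing.assert_allclose(np.diag(cov), expect, rtol=0.03)
        assert abs(cov[0, 1]) < 3e-4

        # Independent oracle: simulate dr/dt = rate (sigma1(m0) - r) + eta.
        m = saturate(main_params.m0)
        dt, n_runs = 0.01, 4000
        r = np.tile(m, (n_runs, 1))
        g = np.random.default_rng(99)
        for _ in range(800):   # 8 competence units ≈ 16 relaxation times
            r += (main_params.rate * (m - r) * dt
                  + np.sqrt(2 * main_params.D * dt) * g.standard_normal(r.shape))
        np.testing.assert_allclose(r.var(axis=0), expect, rtol=0.1)

    def test_cells_share_one_distribution(self, main_params, rng):
        states = sample_initial_states(main_params, 50_000, rng)
        means = states.mean(axis=0)
        assert np.allclose(means, means[0], atol=5e-3)


class TestFixedPoints:
    def test_main_parameters_tristable(self, main_fps):
        assert set(main_fps.attractors) == {"1", "2", "3"}
        for a in main_fps.attractors.values():
            assert np.linalg.norm(a) < 1.0
        assert len(main_fps.saddles) >= 2

    def test_labels_follow_signal_directions(self, main_params, main_fps):
        # 3deg lies along the bias direction (210deg); 1deg along the EGF
        # response; 2deg in the remaining (Notch) sector.
        ang = {f: np.rad2deg(np.arctan2(a[1], a[0]))
               for f, a in main_fps.attractors.items()}
        assert abs((ang["3"] - 210 + 180) % 360 - 180) < 30
        assert abs((ang["1"] - (-21) + 180) % 360 - 180) < 30
        assert 45 < ang["2"] < 135

    def test_zero_bias_gives_symmetric_triplet(self, main_params):
        fps = find_fixed_points(main_params.replace(m0_norm=0.0))
        radii = sorted(np.linalg.norm(a) for a in fps.attractors.values())
        assert radii[0] == pytest.approx(radii[-1], abs=1e-8)
        angs = sorted(np.rad2deg(np.arctan2(a[1], a[0])) % 360
                      for a in fps.attractors.values())
        np.testing.assert_allclose(np.diff(angs), 120.0, atol=1e-6)

    def test_attractors_are_stable_under_perturbation(self, main_params,
                                                      main_fps):
        p = main_params.replace(D=0.0)
        for a in main_fps.attractors.values():
            start = a + np.array([0.03, -0.02])
            r = np.tile(start, (1, 5, 1))
            res = integrate_ensemble(p, Condition(egf_dose=0.0,
                                                  notch_disabled=True),
                                     1, seed=0, initial=r[0], t_final=6.0)
            np.testing.assert_allclose(res.final_states[0, 0], a, atol=1e-3)


class TestIntegration:
    def test_deterministic_wild_type_p6_reaches_primary(self, main_params,
                                                        main_fps):
        p = main_params.replace(D=0.0)
        # The standard two-unit protocol leaves P6.p nearest the primary
        # attractor; extending the relaxation converges onto it tightly.
        res = integrate_ensemble(p, build_condition("WT"), 1, seed=0)
        a = np.stack(list(main_fps.attractors.values()))
        labels = list(main_fps.attractors)
        d = np.linalg.norm(res.final_states[0, 2] - a, axis=1)
        assert labels[int(np.argmin(d))] == "1"
        long = integrate_ensemble(p, build_condition("WT"), 1, seed=0,
                                  t_final=8.0)
        np.testing.assert_allclose(long.final_states[0, 2],
                                   main_fps.attractors["1"], atol=1e-3)
        # dt-refinement cross-check
        res2 = integrate_ensemble(p, build_condition("WT"), 1, seed=0,
                                  dt=0.0005)
        np.testing.assert_allclose(res.final_states, res2.final_states,
                                   atol=2e-3)

    def test_same_seed_bit_identical(self, main_params):
        a = integrate_ensemble(main_params, build_condition("WT"), 40, seed=7)
        b = integrate_ensemble(main_params, build_condition("WT"), 40, seed=7)
        np.testing.assert_array_equal(a.final_states, b.final_states)

    def test_unstable_step_rejected(self, main_params):
        with pytest.raises((FloatingPointError, ValueError)):
            integrate_ensemble(main_params.replace(rate=500.0),
                               build_condition("WT"), 5, seed=0, dt=0.1)

    def test_trajectory_recording_shape(self, main_params):
        res = integrate_ensemble(main_params, build_condition("WT"), 3,
                                 seed=0, dt=0.01, record=True)
        assert res.trajectories.shape == (201, 3, 5, 2)
        np.testing.assert_array_equal(res.trajectories[-1], res.final_states)


class TestScoring:
    def test_state_at_attractor_scores_pure(self, main_params, main_fps):
        states = np.stack([main_fps.attractor_array[j] for j in
                           [2, 1, 0, 1, 2]])[None]    # WT arrangement
        fp = score_fates(states, main_fps, main_params, mode="soft")
        assert fp.pattern() == "32123"
        assert fp.p.max(axis=1).min() > 0.999
        fp_hard = score_fates(states, main_fps, main_params, mode="hard")
        np.testing.assert_array_equal(
            fp_hard.p, np.eye(3)[[2, 1, 0, 1, 2]])

    def test_equidistant_point_splits_evenly(self, main_params, main_fps):
        a, b = main_fps.attractors["1"], main_fps.attractors["2"]
        mid = 0.5 * (a + b)
        states = np.tile(mid, (1, 5, 1))
        for mode in ("soft", "hard"):
            fp = score_fates(states, main_fps, main_params, mode=mode)
            assert fp.p[0, 0] == pytest.approx(fp.p[0, 1], abs=1e-9)
            assert fp.p[0, 2] < 0.5

    def test_weights_rows_normalized(self, main_params, main_fps, rng):
        states = rng.normal(scale=0.8, size=(11, 5, 2))
        w = fate_weights(states, main_fps, main_params)
        np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-12)

    def test_zero_noise_soft_degenerates_to_hard(self, main_fps):
        p = get_preset("main").replace(D=0.0)
        states = np.tile(main_fps.attractors["2"] + 0.05, (1, 5, 1))
        soft = score_fates(states, main_fps, p, mode="soft")
        hard = score_fates(states, main_fps, p, mode="hard")
        np.testing.assert_array_equal(soft.p, hard.p)

    def test_proportions_validation(self):
        with pytest.raises(ValueError):
            FateProportions(np.full((5, 3), 0.5))


class TestRunCondition:
    def test_wild_type_invariant_pattern(self, main_params, main_fps):
        fp = run_condition(main_params, build_condition("WT"), 2000, seed=11,
                           fps=main_fps)
        assert fp.pattern() == "32123"
        assert fp.p.max(axis=1).min() >= 0.99

    @pytest.mark.parametrize("strain, pattern", [
        ("Notch-null", "33133"),
        ("Notch-null-2AC", "31113"),
        ("let-23-mosaic", "32123"),
        ("half-dose-EGF", "32123"),
        ("half-dose-Notch", "32123"),
    ])
    def test_classical_genetics_patterns(self, main_params, main_fps, strain,
                                         pattern):
        fp = run_condition(main_params, build_condition(strain), 1000,
                           seed=5, fps=main_fps)
        assert fp.pattern() == pattern

    def test_mirror_symmetry_of_symmetric_conditions(self, main_params,
                                                     main_fps):
        fp = run_condition(main_params, build_condition("JU2092"), 4000,
                           seed=3, fps=main_fps)
        np.testing.assert_allclose(fp.p[0], fp.p[4], atol=0.04)
        np.testing.assert_allclose(fp.p[1], fp.p[3], atol=0.04)

    def test_fractions_sum_to_one_and_seed_stable(self, main_params,
                                                  main_fps):
        f1 = run_condition(main_params, build_condition("JU2039"), 1500,
                           seed=1, fps=main_fps)
        f2 = run_condition(main_params, build_condition("JU2039"), 1500,
                           seed=2, fps=main_fps)
        np.testing.assert_allclose(f1.p.sum(axis=1), 1.0, atol=1e-9)
        assert np.abs(f1.p - f2.p).max() < 0.05   # binomial error at n=1500

    def test_dt_refinement_stability(self, main_params, main_fps):
        coarse = run_condition(main_params, build_condition("WT"), 3000,
                               seed=9, dt=0.01, fps=main_fps)
        fine = run_condition(main_params, build_condition("WT"), 3000,
                             seed=9, dt=0.005, fps=main_fps)
        assert np.abs(coarse.p - fine.p).max() < 0.01

    def test_ablation_series_monotone_induction(self, main_params, main_fps):
        """Later anchor-cell ablation leaves P6.p more induced (non-3deg)."""
        times = ["ablation-L2-lethargus", "ablation-early-L3",
                 "ablation-DU-divided", "ablation-VU-divided",
                 "ablation-3-divided", "ablation-two-cell"]
        props = run_conditions(main_params,
                               [build_condition(t) for t in times],
                               n_runs=800, seed=21, fps=main_fps)
        induced = [1.0 - fp.p[2, 2] for fp in props]
        assert all(b >= a - 0.03 for a, b in zip(induced, induced[1:]))
        assert induced[0] < 0.05 and induced[-1] > 0.95

    def test_coupled_model_wild_type(self):
        p = get_preset("coupled")
        fp = run_condition(p, build_condition("WT"), 1500, seed=4)
        assert fp.pattern() == "32123"
        assert fp.p.max(axis=1).min() > 0.98

    def test_batched_matches_marginal_statistics(self, main_params, main_fps):
        conds = [build_condition("WT"), build_condition("JU2064")]
        batch = run_conditions(main_params, conds, n_runs=1500, seed=8,
                               fps=main_fps)
        single = run_condition(main_params, conds[1], 1500, seed=88,
                               fps=main_fps)
        assert np.abs(batch[1].p - single.p).max() < 0.05
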