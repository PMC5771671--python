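"""Tests for the chi-square likelihood, priors, objective, and samplers."""

import numpy as np
import pytest

from fateplane import get_preset
from fateplane.inference import (DEFAULT_FREE, FrozenNoiseObjective,
                                 GeometricFateModel, chi_square,
                                 default_priors, fit_map, load_training_set,
                                 sample_posterior)


class TestChiSquare:
    def test_zero_iff_match(self):
        p = np.array([0.2, 0.3, 0.5])
        assert chi_square(p, p, form="new") == 0.0
        assert chi_square(p, p, form="legacy") == 0.0

    def test_hand_oracle_values(self):
        # One cell, p_exp = (1,0,0), p_num = (.5,.25,.25), N = 100.
        # New form: 2500*(0.25/50.5 + 0.0625/25.5 + 0.0625/25.5) = 24.631...
        # Legacy:   100*(0.25 + 0.0625 + 0.0625) = 37.5
        p_exp = [1.0, 0.0, 0.0]
        p_num = [0.5, 0.25, 0.25]
        assert chi_square(p_exp, p_num, 100, "new") == pytest.approx(
            24.6311, abs=1e-3)
        assert chi_square(p_exp, p_num, 100, "legacy") == pytest.approx(37.5)

    def test_permutation_invariant(self, rng):
        p_exp = rng.dirichlet(np.ones(3), size=8)
        p_num = rng.dirichlet(np.ones(3), size=8)
        perm = rng.permutation(8)
        for form in ("new", "legacy"):
            assert chi_square(p_exp, p_num, form=form) == pytest.approx(
                chi_square(p_exp[perm], p_num[perm], form=form))

    def test_new_form_punishes_vanishing_model_probability(self):
        # A small observed fraction the model misses entirely costs far
        # more under the variance-normalized form than the quadratic one.
        p_exp = [0.1, 0.9, 0.0]
        p_miss = [1e-6, 1.0 - 1e-6, 0.0]
        new = chi_square(p_exp, p_miss, 100, "new")
        legacy = chi_square(p_exp, p_miss, 100, "legacy")
        assert new > 10 * legacy

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            chi_square([0.5, 0.5], [0.3, 0.3, 0.4])


class TestTrainingSet:
    def test_roster_and_normalization(self):
        ds = load_training_set()
        names = ds.names()
        assert len(ds) == 18
        for key in ("WT", "JU1107", "JU1100", "CB1417", "JU2064", "JU2095",
                    "lin-15", "ablation-two-cell"):
            assert key in names
        for rec in ds.records:
            if rec.kind == "proportions":
                rows = rec.proportions[rec.scored]
                np.testing.assert_allclose(rows.sum(axis=1), 1.0, atol=1e-9)

    def test_ablations_score_inner_cells_only(self):
        ds = load_training_set()
        rec = {r.name: r for r in ds.records}["ablation-DU-divided"]
        np.testing.assert_array_equal(rec.scored,
                                      [False, True, True, True, False])

    def test_dose_links_attached(self):
        ds = load_training_set()
        by = {r.name: r for r in ds.records}
        assert ("lam_ju1100", "egf_dose") in by["JU1100"].dose_links
        assert len(by["JU2095"].dose_links) == 2   # inherits both fits
        assert by["WT"].dose_links == ()


@pytest.fixture(scope="module")
def objective():
    return FrozenNoiseObjective(load_training_set(), n_runs=60, dt=0.02,
                                seed=17)


class TestObjective:
    def test_deterministic_under_frozen_noise(self, objective):
        th = objective.theta_from(objective.base_params)
        assert objective.log_posterior(th) == objective.log_posterior(th)
        r1, r2 = objective.residuals(th), objective.residuals(th)
        np.testing.assert_array_equal(r1, r2)

    def test_shipped_defaults_fit_training_set_well(self, objective):
        # ~220 scored entries; the shipped parameters should sit near the
        # optimum, i.e. chi2 per entry of order one.
        th = objective.theta_from(objective.base_params)
        assert objective.chi2(th) < 400

    def test_worse_proportions_lower_posterior(self, objective):
        th = objective.theta_from(objective.base_params)
        bad = th.copy()
        i = objective.free.index("gamma")
        bad[i] += 2.0     # badly distorted EGF gradient
        assert objective.log_posterior(bad) < objective.log_posterior(th)

    def test_prior_support_and_center(self, objective):
        center = objective.theta_prior_center()
        assert objective.log_prior(center) == pytest.approx(0.0)
        off = center.copy()
        off[0] += 1.0
        assert objective.log_prior(off) < 0.0

    def test_round_trip_theta(self, objective):
        th = objective.theta_from(objective.base_params,
                                  {"lam_ju1100": 3.3})
        params, doses = objective.build(th)
        assert params.gamma == pytest.approx(objective.base_params.gamma)
        assert params.rate == pytest.approx(objective.base_params.rate)
        np.testing.assert_allclose(params.m1, objective.base_params.m1)
        assert doses["lam_ju1100"] == pytest.approx(3.3)

    def test_positivity_enforced_by_transform(self, objective):
        rng = np.random.default_rng(0)
        for _ in range(10):
            params, doses = objective.build(objective.sample_prior(rng))
            assert params.rate > 0 and params.D >= 0 and 0 < params.gamma < 1
            assert all(v > 0 for v in doses.values())

    def test_missing_prior_rejected(self):
        with pytest.raises(ValueError):
            FrozenNoiseObjective(load_training_set(), free=("gamma",),
                                 priors={"n0": default_priors()["n0"]},
                                 n_runs=10, dt=0.05)


class TestFitMap:
    def test_stays_at_truth_on_synthetic_data(self):
        # Data generated at known parameters with the same frozen noise:
        # the truth is an exact stationary point of the data term, so a fit
        # started there must not drift away and must beat the start cost.
        from fateplane.inference import ExperimentDataset, Record
        from fateplane.conditions import build_condition

        base = get_preset("main")
        free = ("gamma", "n0")
        probe = FrozenNoiseObjective(load_training_set(), free=free,
                                     n_runs=50, dt=0.02, seed=3)
        th_true = probe.theta_from(base)
        p_num, _ = probe.simulate(th_true)
        records = []
        for rec, p in zip(probe.dataset.records, p_num):
            if rec.kind != "proportions":
                continue
            records.append(Record(rec.name, rec.condition,
                                  p / p.sum(axis=1, keepdims=True),
                                  rec.scored, "proportions", rec.dose_links))
        synth = ExperimentDataset(records)
        obj = FrozenNoiseObjective(synth, free=free, n_runs=50, dt=0.02,
                                   seed=3)
        res = fit_map(obj, n_starts=1, n_screen=0, x0=th_true,
                      rng=np.random.default_rng(0))
        start_cost = 0.5 * float(np.sum(obj.residuals(th_true) ** 2))
        assert res.cost <= start_cost + 1e-6
        params, _ = obj.build(res.theta)
        assert params.gamma == pytest.approx(base.gamma, abs=0.02)
        assert params.n0 == pytest.approx(base.n0, abs=0.1)


class TestSampler:
    def test_recovers_standard_gaussian(self, rng):
        # Known 2-D target: mean and covariance must come out right within
        # Monte-Carlo error.
        post = sample_posterior(lambda x: -0.5 * float(x @ x),
                                np.zeros(2), n_steps=1500, rng=rng,
                                n_walkers=12, init_scale=0.5,
                                names=("a", "b"))
        assert 0.05 <= post.acceptance <= 0.9
        mean = post.samples.mean(axis=0)
        cov = np.cov(post.samples.T)
        np.testing.assert_allclose(mean, 0.0, atol=0.15)
        np.testing.assert_allclose(np.diag(cov), 1.0, atol=0.3)

    def test_two_chains_agree(self):
        target = lambda x: -0.5 * float((x - 1.0) @ (x - 1.0))
        chains = [sample_posterior(target, np.ones(2), 1200,
                                   rng=np.random.default_rng(s),
                                   n_walkers=10, init_scale=0.5)
                  for s in (0, 1)]
        m0 = chains[0].samples.mean(axis=0)
        m1 = chains[1].samples.mean(axis=0)
        np.testing.assert_allclose(m0, m1, atol=0.25)


class TestEstimator:
    def test_sklearn_params_round_trip(self):
        est = GeometricFateModel(n_runs=30, seed=5)
        params = est.get_params()
        assert params["n_runs"] == 30
        est2 = GeometricFateModel().set_params(**params)
        assert est2.n_runs == 30 and est2.seed == 5

    def test_unfitted_predict_raises(self):
        with pytest.raises(AttributeError):
            GeometricFateModel().predict(["WT"])

    def test_fit_predict_smoke(self):
        # Tiny settings: fit only the two signal-shape parameters on the
        # packaged training set and predict the unperturbed pattern.
        est = GeometricFateModel(free=("gamma", "n0"), n_runs=40, dt=0.02,
                                 seed=0, n_starts=1, predict_n_runs=400,
                                 predict_dt=0.01)
        est.fit(load_training_set())
        assert hasattr(est, "params_") and hasattr(est, "result_")
        assert 0.1 < est.params_.gamma < 0.5
        pred = est.predict(["WT"])
        assert pred.shape == (1, 5, 3)
        assert "".join("123"[j] for j in pred[0].argmax(axis=1)) == "32123"
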