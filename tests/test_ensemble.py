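import numpy as np
import pandas as pd
import pytest

from tridacna_sdm.ensemble import (
    ALGORITHMS,
    EnsembleModel,
    LearnerSpec,
    ModellingError,
    SRELearner,
    _permutation_importance_once,
    auc_score,
    build_ensemble,
    cross_validate,
    default_specs,
    evaluate,
    fit_learner,
    response_curve,
    select_members,
    tss_at_threshold,
    variable_importance,
)


def make_table(n=200, p=3, sep=3.0, seed=0):
    """Balanced 0/1 table with classes separated along the first column."""
    rng = np.random.default_rng(seed)
    X0 = rng.standard_normal((n // 2, p))
    X1 = rng.standard_normal((n // 2, p))
    X1[:, 0] += sep
    env = pd.DataFrame(np.vstack([X0, X1]),
                       columns=[f"v{i}" for i in range(p)])
    y = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
    return env, y


class StubMember:
    """Fixed-output member for ensemble arithmetic tests."""

    def __init__(self, value):
        self.value = value
        self.spec = LearnerSpec("GLM")
        self.columns = ["v0"]

    def predict(self, env):
        return np.full(len(env), self.value)


class TestLearners:
    def test_every_algorithm_fits_and_stays_in_unit_interval(self):
        env, y = make_table(n=120, sep=2.0)
        for name in ALGORITHMS:
            fitted = fit_learner(LearnerSpec(name), env, y, seed=1)
            pred = fitted.predict(env)
            assert ((0 <= pred) & (pred <= 1)).all(), name

    def test_glm_separable_training_auc_one(self):
        env, y = make_table(n=100, sep=8.0)
        fitted = fit_learner(LearnerSpec("GLM"), env, y, seed=0)
        assert auc_score(fitted.predict(env), y) == 1.0

    def test_single_class_rejected(self):
        env, _ = make_table(60)
        with pytest.raises(ModellingError):
            fit_learner(LearnerSpec("RF"), env, np.ones(len(env), int))

    def test_sre_zero_q_is_exact_envelope(self, rng):
        X = np.column_stack([rng.uniform(0, 1, 50)])
        sre = SRELearner(q=0.0).fit(X, np.ones(50, int))
        lo, hi = X.min(), X.max()
        test = np.array([[lo], [hi], [lo - 0.01], [hi + 0.01], [(lo + hi) / 2]])
        assert list(sre.predict_suitability(test)) == [1, 1, 0, 0, 1]

    def test_sre_matches_brute_force_envelope(self, rng):
        env, y = make_table(n=100, p=4, seed=3)
        fitted = fit_learner(LearnerSpec("SRE"), env, y, seed=0)
        pres = env[y == 1]
        lo = pres.quantile(0.025)
        hi = pres.quantile(0.975)
        probe = pd.DataFrame(rng.uniform(-4, 7, size=(200, 4)),
                             columns=env.columns)
        expect = ((probe >= lo) & (probe <= hi)).all(axis=1).astype(float)
        assert np.array_equal(fitted.predict(probe), expect.to_numpy())


class TestEvaluate:
    def test_perfect_separation(self):
        pred = np.r_[np.full(20, 0.9), np.full(20, 0.1)]
        obs = np.r_[np.ones(20, int), np.zeros(20, int)]
        tss, auc, tau = evaluate(pred, obs)
        assert tss == 1.0 and auc == 1.0
        assert 0.1 < tau <= 0.9

    def test_hand_confusion_arithmetic(self):
        """TP 40, FN 10, TN 45, FP 5 gives sens 0.8, spec 0.9, TSS 0.7."""
        pred = np.r_[np.full(40, 0.9), np.full(10, 0.2),
                     np.full(45, 0.3), np.full(5, 0.95)]
        obs = np.r_[np.ones(50, int), np.zeros(50, int)]
        assert tss_at_threshold(pred, obs, 0.9) == pytest.approx(0.7)
        tss, _, tau = evaluate(pred, obs)
        assert tss == pytest.approx(0.7)
        assert tss_at_threshold(pred, obs, tau) == pytest.approx(tss)

    def test_random_predictions_auc_near_half(self, rng):
        pred = rng.random(2000)
        obs = rng.integers(0, 2, 2000)
        assert auc_score(pred, obs) == pytest.approx(0.5, abs=0.04)

    def test_max_tss_equals_dense_threshold_scan(self, rng):
        """Candidate-threshold maximum equals a brute-force scan over
        [0, 1] at 1e-4 resolution, across 50 random instances."""
        taus = np.arange(0.0, 1.0001, 1e-4)
        for _ in range(50):
            n = int(rng.integers(20, 80))
            pred = np.round(rng.random(n), 3)
            obs = rng.integers(0, 2, n)
            if obs.min() == obs.max():
                obs[0] = 1 - obs[0]
            tss, _, _ = evaluate(pred, obs)
            pos, neg = obs == 1, obs == 0
            hit = pred[None, :] >= taus[:, None]
            brute = (hit[:, pos].mean(axis=1) - hit[:, neg].mean(axis=1)).max()
            assert tss == pytest.approx(max(brute, 0.0), abs=1e-12)

    def test_rank_auc_equals_trapezoidal_roc(self, rng):
        """On tie-free data the Mann-Whitney AUC is the trapezoidal ROC area."""
        for seed in range(5):
            r = np.random.default_rng(seed)
            pred = r.permutation(np.linspace(0.01, 0.99, 60))
            obs = r.integers(0, 2, 60)
            if obs.min() == obs.max():
                obs[0] = 1 - obs[0]
            order = np.argsort(-pred)
            tps = np.cumsum(obs[order] == 1) / (obs == 1).sum()
            fps = np.cumsum(obs[order] == 0) / (obs == 0).sum()
            trap = np.trapezoid(np.r_[0, tps], np.r_[0, fps])
            assert auc_score(pred, obs) == pytest.approx(trap, abs=1e-9)

    def test_one_class_rejected(self):
        with pytest.raises(ModellingError):
            evaluate(np.array([0.1, 0.9]), np.array([1, 1]))


class TestCrossValidate:
    def test_run_count_is_folds_times_replicates(self):
        env, y = make_table(n=100, sep=3.0)
        scores = cross_validate([LearnerSpec("GLM"), LearnerSpec("CTA")],
                                env, y, folds=5, replicates=10, seed=0)
        assert (scores.table["n_runs"] == 50).all()

    def test_constant_learner_tss_near_zero(self):
        env, y = make_table(n=100, sep=0.0)
        # SRE with q=0 on overlapping classes predicts mostly 1: no skill
        scores = cross_validate([LearnerSpec("SRE", {"q": 0.0})],
                                env, y, folds=5, replicates=2, seed=0)
        assert abs(scores.table["tss_mean"].iloc[0]) < 0.25

    def test_deterministic_given_seed(self):
        env, y = make_table(n=80, sep=2.0)
        a = cross_validate([LearnerSpec("GLM")], env, y, replicates=2, seed=5)
        b = cross_validate([LearnerSpec("GLM")], env, y, replicates=2, seed=5)
        pd.testing.assert_frame_equal(a.table, b.table)


class TestSelectAndEnsemble:
    def _scores(self, rows):
        table = pd.DataFrame(rows).set_index("learner")
        from tridacna_sdm.ensemble import CvScores
        return CvScores(table=table, folds=5, replicates=10)

    def test_gates_are_strict(self):
        scores = self._scores([
            {"learner": "A", "tss_mean": 0.69, "auc_mean": 0.90},
            {"learner": "B", "tss_mean": 0.75, "auc_mean": 0.85},
            {"learner": "C", "tss_mean": 0.70, "auc_mean": 0.80},
        ])
        included, excl = select_members(scores)
        assert included == ["B"]
        assert set(excl["learner"]) == {"A", "C"}

    def test_empty_inclusion_raises(self):
        scores = self._scores([{"learner": "A", "tss_mean": 0.1, "auc_mean": 0.5}])
        with pytest.raises(ModellingError):
            select_members(scores)

    def test_equal_weight_average(self):
        ens = EnsembleModel(members=[StubMember(0.2), StubMember(0.6)],
                            weights=[1, 1], tss_min=0.7, auc_min=0.8,
                            weighting="equal")
        env = pd.DataFrame({"v0": [0.0, 1.0]})
        assert np.allclose(ens.predict(env), 0.4)

    def test_single_member_identity(self):
        ens = EnsembleModel(members=[StubMember(0.37)], weights=[1.0],
                            tss_min=0.7, auc_min=0.8, weighting="equal")
        assert np.allclose(ens.predict(pd.DataFrame({"v0": [0]})), 0.37)

    def test_tss_proportional_weights(self):
        ens = EnsembleModel(members=[StubMember(1.0), StubMember(0.0)],
                            weights=[0.8, 0.72], tss_min=0.7, auc_min=0.8,
                            weighting="tss_proportional")
        pred = ens.predict(pd.DataFrame({"v0": [0]}))
        assert pred[0] == pytest.approx(0.8 / 1.52, abs=1e-9)

    def test_refit_ensemble_is_convex_combination(self):
        env, y = make_table(n=120, sep=2.5)
        specs = default_specs(["GLM", "CTA", "RF"])
        scores = cross_validate(specs, env, y, replicates=2, seed=1)
        included, _ = select_members(scores, tss_min=0.0, auc_min=0.0)
        ens = build_ensemble(included, scores, env, y, seed=2, specs=specs)
        member_preds = np.column_stack([m.predict(env) for m in ens.members])
        pred = ens.predict(env)
        assert (pred >= member_preds.min(axis=1) - 1e-12).all()
        assert (pred <= member_preds.max(axis=1) + 1e-12).all()


@pytest.fixture(scope="module")
def fitted():
    env, y = make_table(n=300, p=3, sep=2.5, seed=7)
    specs = default_specs(["GLM", "RF"])
    scores = cross_validate(specs, env, y, replicates=2, seed=3)
    included, _ = select_members(scores, tss_min=0.0, auc_min=0.0)
    ens = build_ensemble(included, scores, env, y, seed=4, specs=specs)
    return ens, env


class TestInterpretation:
    def test_identity_permutation_zero_importance(self, fitted):
        ens, env = fitted
        base = ens.predict(env)
        imp = _permutation_importance_once(ens, env, "v0",
                                           np.arange(len(env)), base)
        assert imp == 0.0

    def test_driver_ranks_first_and_unused_near_zero(self, fitted):
        ens, env = fitted
        imp = variable_importance(ens, env, seed=0)
        assert imp["importance"].idxmax() == "v0"
        assert imp.loc["v1", "importance"] < 0.05
        assert imp.loc["v2", "importance"] < 0.05

    def test_flat_curve_for_ignored_variable(self):
        ens = EnsembleModel(members=[StubMember(0.5)], weights=[1.0],
                            tss_min=0.7, auc_min=0.8, weighting="equal")
        env = pd.DataFrame({"v0": np.linspace(0, 1, 40)})
        curve = response_curve(ens, env, "v0")
        assert curve["suitability"].max() - curve["suitability"].min() < 1e-6

    def test_monotone_logistic_truth_gives_monotone_curve(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(-3, 3, 400)
        y = (rng.random(400) < 1 / (1 + np.exp(-2 * x))).astype(int)
        env = pd.DataFrame({"x": x, "z": rng.standard_normal(400)})
        fittedm = fit_learner(LearnerSpec("GLM"), env, y, seed=0)
        ens = EnsembleModel(members=[fittedm], weights=[1.0],
                            tss_min=0.7, auc_min=0.8, weighting="equal")
        curve = response_curve(ens, env, "x")
        assert (np.diff(curve["suitability"]) > -1e-9).all()

    def test_unimodal_truth_peak_recovered(self):
        """A smooth learner on noisy unimodal data puts its response-curve
        peak within one grid step of the true optimum."""
        rng = np.random.default_rng(5)
        n = 3000
        x = rng.uniform(0, 10, n)
        p_true = 0.9 * np.exp(-0.5 * ((x - 4.0) / 1.5) ** 2) + 0.05
        y = (rng.random(n) < p_true).astype(int)
        env = pd.DataFrame({"x": x, "z": rng.standard_normal(n)})
        fittedm = fit_learner(LearnerSpec("GLM"), env, y, seed=0)
        ens = EnsembleModel(members=[fittedm], weights=[1.0],
                            tss_min=0.7, auc_min=0.8, weighting="equal")
        curve = response_curve(ens, env, "x", n_grid=50)
        step = np.diff(curve["value"]).mean()
        peak = curve.loc[curve["suitability"].idxmax(), "value"]
        assert abs(peak - 4.0) <= step
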