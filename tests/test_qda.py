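"""Quadratic-discriminant D-score classifier: identities, oracles, contracts."""

import numpy as np
import pandas as pd
import pytest

import dscore as d
from dscore import DScoreClassifier

GENES = list(d.PANEL14)


def test_mirrored_classes_give_zero_d_score(rng):
    # class B is class A reflected through its mean: identical sample mean
    # and covariance, so with equal priors every D score is ~0
    X_a = rng.normal(size=(80, 3)) @ rng.normal(size=(3, 3)) + 5.0
    X_b = 2 * X_a.mean(axis=0) - X_a
    X = np.vstack([X_a, X_b])
    y = np.array(["a"] * 80 + ["b"] * 80)
    clf = DScoreClassifier(priors="equal", shrinkage=0.0).fit(X, y)
    probes = rng.normal(5.0, 1.0, size=(50, 3))
    assert np.max(np.abs(clf.decision_function(probes))) < 1e-8


def test_one_gene_equal_variance_closed_form():
    # exact sample moments: means 0 and 1, unit variances, equal priors
    # -> D(x) = x - 0.5, boundary at 0.5
    X = np.array([[-1.0], [0.0], [1.0], [0.0], [1.0], [2.0]])
    y = np.array(["neg"] * 3 + ["pos"] * 3)
    clf = DScoreClassifier(
        priors="equal", shrinkage=0.0, positive_class="pos"
    ).fit(X, y)
    probes = np.array([[-2.0], [0.0], [0.5], [1.0], [3.0]])
    assert clf.decision_function(probes) == pytest.approx(
        probes.ravel() - 0.5, abs=1e-12
    )
    # the boundary itself (D == 0) is called negative
    assert clf.predict([[0.5]])[0] == "neg"
    assert clf.predict([[0.5000001]])[0] == "pos"


def test_expansion_identity_on_random_probes(fitted, small_cohort, rng):
    """Polynomial coefficients reproduce log prior + Gaussian log-density."""
    mu = small_cohort[GENES].mean().to_numpy()
    sd = small_cohort[GENES].std().to_numpy()
    probes = rng.normal(mu, sd, size=(100, len(GENES)))
    poly = fitted.class_scores(probes, "polynomial")
    gauss = fitted.class_scores(probes, "gaussian")
    assert np.allclose(poly, gauss, rtol=1e-8, atol=1e-8)


def test_constant_shift_leaves_calls_unchanged(fitted, small_cohort):
    model = fitted.to_panel_model(d.PANEL14)
    before = d.score_profiles(model, small_cohort)
    model.constant_h += 123.45
    model.constant_l += 123.45
    after = d.score_profiles(model, small_cohort)
    assert (before["call"] == after["call"]).all()


def test_label_swap_negates_d_scores(small_cohort):
    X = small_cohort[GENES].to_numpy()
    y = small_cohort["label"].to_numpy()
    a = DScoreClassifier(positive_class="higher_risk").fit(X, y)
    b = DScoreClassifier(positive_class="lower_risk").fit(X, y)
    assert np.allclose(a.decision_function(X), -b.decision_function(X))


def test_affine_rescaling_leaves_calls_unchanged(small_cohort):
    # ratio scale vs x1000 reporting scale: calls must be identical
    X = small_cohort[GENES].to_numpy()
    y = small_cohort["label"].to_numpy()
    kwargs = dict(positive_class="higher_risk", shrinkage=0.1)
    calls_big = DScoreClassifier(**kwargs).fit(X, y).predict(X)
    calls_small = DScoreClassifier(**kwargs).fit(X / 1000, y).predict(X / 1000)
    assert (calls_big == calls_small).all()


def test_agrees_with_reference_qda_implementation():
    from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis

    agree = []
    for seed in range(3):
        cfg = d.default_config(seed=seed).with_(
            n_group_a=200, n_group_b=100, sigma=150.0
        )
        prof = d.simulate_profiles(cfg)
        X = prof[GENES].to_numpy()
        y = prof["label"].to_numpy()
        ours = DScoreClassifier(
            priors="proportional", shrinkage=0.0, positive_class="higher_risk"
        ).fit(X, y)
        ref = QuadraticDiscriminantAnalysis().fit(X, y)
        probes = d.simulate_profiles(cfg.with_(seed=seed + 100))
        Xp = probes[GENES].to_numpy()
        agree.append(np.mean(ours.predict(Xp) == ref.predict(Xp)))
    assert np.mean(agree) >= 0.99


def test_separation_monotonicity():
    """Scaling all group shifts up never lowers resubstitution AUC."""
    base = d.default_config().delta_series()
    for seed in range(5):
        aucs = []
        for factor in (0.05, 0.1, 0.2):
            cfg = d.default_config(seed=seed).with_(delta=(base * factor).to_dict())
            prof = d.simulate_profiles(cfg)
            clf = d.fit_stratifier(prof, d.PANEL14)
            res = d.roc(
                clf.decision_function(prof[GENES].to_numpy()),
                prof["label"],
                "higher_risk",
            )
            aucs.append(res.auc)
        assert aucs == sorted(aucs)


def test_fitted_means_recover_generator_means(default_cfg):
    prof = d.simulate_profiles(default_cfg)
    clf = d.fit_stratifier(prof, d.PANEL14)
    mu_b = default_cfg.mu_b_series().to_numpy()
    delta = default_cfg.delta_series().to_numpy()
    sigma = default_cfg.sigma_series().to_numpy()
    se_a = sigma / np.sqrt(default_cfg.n_group_a)
    se_b = sigma / np.sqrt(default_cfg.n_group_b)
    assert (np.abs(clf.means_[0] - (mu_b + delta)) < 3 * se_a).all()
    assert (np.abs(clf.means_[1] - mu_b) < 3 * se_b).all()


def test_fit_error_contracts(rng):
    X = rng.normal(size=(10, 2))
    with pytest.raises(ValueError, match="two classes"):
        DScoreClassifier().fit(X, np.array(["a"] * 10))
    with pytest.raises(ValueError, match="fewer than 2"):
        DScoreClassifier().fit(X, np.array(["a"] * 9 + ["b"]))
    # a duplicated feature makes the covariance exactly singular
    Xs = np.column_stack([X[:, 0], X[:, 0]])
    y = np.array(["a"] * 5 + ["b"] * 5)
    with pytest.raises(ValueError, match="shrinkage"):
        DScoreClassifier(shrinkage=0.0).fit(Xs, y)
    DScoreClassifier(shrinkage=0.5).fit(Xs, y)  # shrinkage rescues it


def test_score_profiles_missing_gene_listing(fitted, small_cohort):
    broken = small_cohort.drop(columns=["CST3", "PTEN"])
    with pytest.raises(ValueError, match=r"CST3.*PTEN"):
        d.score_profiles(fitted, broken, d.PANEL14)


def test_score_profiles_columns_and_rule(fitted, small_cohort):
    table = d.score_profiles(fitted, small_cohort, d.PANEL14)
    assert list(table.columns) == ["c_higher", "c_lower", "d_score", "call"]
    assert np.allclose(table.d_score, table.c_higher - table.c_lower)
    assert (
        (table.d_score > 0) == (table.call == "higher_risk")
    ).all()


def test_panel_model_roundtrip(tmp_path, fitted, small_cohort):
    model = fitted.to_panel_model(d.PANEL14)
    path = tmp_path / "model.json"
    model.save(path)
    loaded = d.PanelModel.load(path)
    X = small_cohort[GENES].to_numpy()
    assert np.allclose(model.decision_function(X), loaded.decision_function(X))
    assert loaded.task == "stratification"
    assert list(loaded.panel) == GENES
    # quadratic matrices are symmetric by construction
    assert np.allclose(loaded.quad_h, loaded.quad_h.T)
    assert np.allclose(loaded.quad_l, loaded.quad_l.T)


def test_diagnosis_task_shares_the_machinery():
    cfg = d.default_config("diagnosis", seed=3).with_(n_group_a=60, n_group_b=60)
    prof = d.simulate_profiles(cfg)
    clf = d.fit_diagnoser(prof, d.PANEL14)
    assert clf.task == "diagnosis"
    assert clf.positive_class_ == "cancer"
    table = d.score_profiles(clf, prof, d.PANEL14)
    assert set(table["call"]) <= {"cancer", "benign"}


def test_sklearn_params_interface():
    clf = DScoreClassifier(shrinkage=0.3)
    assert clf.get_params()["shrinkage"] == 0.3
    clf.set_params(priors="equal")
    assert clf.get_params()["priors"] == "equal"
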