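"""Naïve Bayes and MaxEnt: hand-counted oracles, limits, cross-checks."""

import itertools

import numpy as np
import pytest

from thrombotext.classifiers import (
    TrainingError,
    maxent_objective,
    nb_joint_log_likelihood,
    predict_maxent,
    predict_maxent_many,
    predict_nb,
    predict_nb_many,
    train_maxent,
    train_nb,
)


def test_nb_laplace_smoothed_hand_count():
    """2 docs/class, one feature present only in positives, alpha=1:
    P(f|pos) = (2+1)/(2+2) = 3/4, P(f|neg) = (0+1)/(2+2) = 1/4."""
    vectors = [{0}, {0}, set(), set()]
    labels = [1, 1, 0, 0]
    model = train_nb(vectors, labels, n_features=1, alpha=1.0)
    assert np.exp(model.log_p[1, 0]) == pytest.approx(3 / 4)
    assert np.exp(model.log_p[0, 0]) == pytest.approx(1 / 4)


def test_nb_uniform_data_posterior_half():
    vectors = [{0}, {0}, {0}, {0}]
    labels = [1, 1, 0, 0]
    model = train_nb(vectors, labels, n_features=1)
    label, post = predict_nb(model, {0})
    assert label == 1  # tie broken towards positive
    assert post == pytest.approx(0.5)


def test_nb_single_class_rejected():
    with pytest.raises(TrainingError):
        train_nb([{0}, {1}], [1, 1], n_features=2)


def _brute_force_nb_posterior(model, vector):
    """Independent Bayes-rule computation over the stored tables."""
    joint = []
    for c in (0, 1):
        logp = float(model.log_prior[c])
        for f in range(model.n_features):
            if f in vector:
                logp += float(model.log_p[c, f])
            else:
                logp += float(model.log_1mp[c, f])
        joint.append(np.exp(logp))
    return joint[1] / (joint[0] + joint[1])


def test_nb_posterior_matches_brute_force_bayes():
    rng = np.random.default_rng(11)
    n_features = 6
    vectors = [set(np.flatnonzero(rng.random(n_features) < 0.4).tolist())
               for _ in range(24)]
    labels = rng.integers(0, 2, size=24).tolist()
    labels[0], labels[1] = 0, 1
    model = train_nb(vectors, labels, n_features, alpha=0.5)
    for v in vectors:
        jll = nb_joint_log_likelihood(model, v)
        post = np.exp(jll - jll.max())
        post /= post.sum()
        assert post[1] == pytest.approx(
            _brute_force_nb_posterior(model, v), abs=1e-12
        )
        assert post.sum() == pytest.approx(1.0, abs=1e-12)


def test_maxent_separable_toy_perfect_training_accuracy():
    vectors = [{0}, {0, 1}, {2}, {2, 3}]
    labels = [1, 1, 0, 0]
    model = train_maxent(vectors, labels, n_features=4, l2=1e-4)
    preds = [predict_maxent(model, v)[0] for v in vectors]
    assert preds == labels


def test_maxent_infinite_penalty_shrinks_to_prior():
    vectors = [{0}, {0, 1}, {2}, set(), {1, 2}, {1}]
    labels = [1, 1, 0, 0, 0, 0]
    model = train_maxent(vectors, labels, n_features=3, l2=1e7)
    assert np.abs(model.weights).max() < 1e-4
    # with zero weights the probability is the (bias-fitted) class prior
    _, p = predict_maxent(model, {0, 1, 2})
    assert p == pytest.approx(2 / 6, abs=1e-3)


def test_maxent_objective_monotone_and_below_zero_weights():
    rng = np.random.default_rng(4)
    vectors = [set(np.flatnonzero(rng.random(5) < 0.5).tolist())
               for _ in range(30)]
    labels = (rng.random(30) < 0.5).astype(int).tolist()
    labels[0], labels[1] = 0, 1
    model = train_maxent(vectors, labels, n_features=5, l1=0.1, l2=0.5)
    hist = model.objective_history
    assert all(b <= a + 1e-10 for a, b in zip(hist, hist[1:]))
    assert hist[-1] <= hist[0]  # objective at solution <= at zero weights


def _grid_search_maxent(X, y, l1, l2, center, width, steps):
    """Brute-force minimization of the penalized objective on a grid,
    refined around the best point (independent oracle)."""
    best = None
    for _ in range(12):
        axes = [np.linspace(c - width, c + width, steps) for c in center]
        for point in itertools.product(*axes):
            w = np.array(point[:-1])
            b = point[-1]
            obj = maxent_objective(X, y, w, b, l1, l2)
            if best is None or obj < best[0]:
                best = (obj, point)
        center = best[1]
        width /= 2.0
    return np.array(best[1])


def test_maxent_weights_match_grid_search_oracle():
    vectors = [{0}, {0, 1}, {1}, set(), {0}, set()]
    labels = [1, 1, 1, 0, 1, 0]
    l1, l2 = 0.05, 0.8
    model = train_maxent(vectors, labels, n_features=2, l1=l1, l2=l2,
                         tol=1e-12, max_iter=20000)
    X = np.zeros((len(vectors), 2))
    for i, v in enumerate(vectors):
        X[i, list(v)] = 1.0
    y = np.array(labels, dtype=float)
    opt = _grid_search_maxent(X, y, l1, l2, center=(0.0, 0.0, 0.0),
                              width=4.0, steps=9)
    assert np.allclose(
        np.r_[model.weights, model.bias], opt, atol=1e-3
    )


def test_maxent_single_class_rejected():
    with pytest.raises(TrainingError):
        train_maxent([{0}, {1}], [0, 0], n_features=2)


def _synthetic_problem(study_corpus):
    from thrombotext.experiment import (
        SplitSpec, make_split, task_label,
    )
    from thrombotext.features import FeatureConfig, FeatureSpace

    reports, annsets, labels = study_corpus
    by_id = {r.report_id: r for r in reports}
    spec = SplitSpec(n_test=100, positive_replication=3, seed=42)
    train_ids, test_ids = make_split(
        [r.report_id for r in reports], labels, "pe", spec
    )
    cfg = FeatureConfig(use_text=True, stopword_filter=True,
                        use_annotations=True)
    space = FeatureSpace(cfg).fit(
        [by_id[i] for i in sorted(set(train_ids))], annsets
    )
    tv = space.transform([by_id[i] for i in sorted(set(train_ids))], annsets)
    sv = space.transform([by_id[i] for i in test_ids], annsets)
    X_train = [tv[i] for i in train_ids]
    y_train = [task_label(labels[i], "pe") for i in train_ids]
    X_test = [sv[i] for i in test_ids]
    return X_train, y_train, X_test, space.n_features


def test_decisions_agree_with_reference_implementations(study_corpus):
    """Per-document decisions match scikit-learn's BernoulliNB and
    LogisticRegression on identical inputs for >= 99% of test points."""
    sklearn = pytest.importorskip("sklearn")  # cross-check only
    from sklearn.linear_model import LogisticRegression
    from sklearn.naive_bayes import BernoulliNB

    X_train, y_train, X_test, n_features = _synthetic_problem(study_corpus)

    def dense(vs):
        M = np.zeros((len(vs), n_features))
        for i, v in enumerate(vs):
            M[i, list(v)] = 1.0
        return M

    Xd, Xt = dense(X_train), dense(X_test)

    ours_nb = [p[0] for p in predict_nb_many(
        train_nb(X_train, y_train, n_features, alpha=1.0), X_test
    )]
    ref_nb = BernoulliNB(alpha=1.0).fit(Xd, y_train).predict(Xt)
    assert np.mean(np.array(ours_nb) == ref_nb) >= 0.99

    l2 = 1.0
    ours_me = [p[0] for p in predict_maxent_many(
        train_maxent(X_train, y_train, n_features, l2=l2), X_test
    )]
    ref_me = LogisticRegression(C=1.0 / l2, tol=1e-10, max_iter=5000).fit(
        Xd, y_train
    ).predict(Xt)
    assert np.mean(np.array(ours_me) == ref_me) >= 0.99


def test_model_serialization_round_trip(tmp_path):
    from thrombotext.classifiers import (
        read_maxent_model, read_nb_model,
        write_maxent_model, write_nb_model,
    )

    vectors = [{0}, {0, 1}, {2}, set()]
    labels = [1, 1, 0, 0]
    names = ["f0", "f1", "f2"]

    nb = train_nb(vectors, labels, 3)
    p = tmp_path / "nb.model"
    write_nb_model(p, nb, names)
    nb2, names2 = read_nb_model(p)
    assert names2 == names
    for v in vectors:
        assert predict_nb(nb2, v)[1] == pytest.approx(predict_nb(nb, v)[1])

    me = train_maxent(vectors, labels, 3)
    p = tmp_path / "me.model"
    write_maxent_model(p, me, names)
    me2, names2 = read_maxent_model(p)
    assert names2 == names
    for v in vectors:
        assert predict_maxent(me2, v)[1] == pytest.approx(
            predict_maxent(me, v)[1]
        )
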