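"""Grid-search CV classifiers, prediction and article-level aggregation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.datasets import make_blobs

from timetriage.classify import (
    ClassifierSpec,
    F1GridSearchClassifier,
    article_level_aggregate,
    grid_search_cv,
    predict_articles,
)
from timetriage.representation import DocMatrix


def blobs(n=300, seed=2):
    X, y = make_blobs(n_samples=n, centers=2, cluster_std=1.0, center_box=(-6, 6),
                      random_state=seed)
    labels = np.where(y == 1, "positive", "negative")
    return X, labels


def nearest_centroid_f1(X, labels):
    """Hand-rolled separability oracle: nearest-centroid rule, training F1."""
    pos = X[labels == "positive"].mean(axis=0)
    neg = X[labels == "negative"].mean(axis=0)
    pred = np.where(
        np.linalg.norm(X - pos, axis=1) < np.linalg.norm(X - neg, axis=1),
        "positive", "negative",
    )
    tp = np.sum((pred == "positive") & (labels == "positive"))
    fp = np.sum((pred == "positive") & (labels == "negative"))
    fn = np.sum((pred == "negative") & (labels == "positive"))
    return 2 * tp / (2 * tp + fp + fn)


def test_single_candidate_grid_is_chosen():
    X, labels = blobs()
    spec = ClassifierSpec("decision_tree", grid={"max_depth": [4]}, seed=0)
    model = grid_search_cv(X, labels, spec)
    assert model.chosen_params == {"max_depth": 4}


def test_separable_blobs_reach_high_f1():
    X, labels = blobs(n=300, seed=2)
    assert nearest_centroid_f1(X, labels) >= 0.95  # data genuinely separable
    model = grid_search_cv(X, labels, ClassifierSpec("l1_logreg", seed=0))
    assert model.cv_f1_mean >= 0.95


def test_grid_search_is_deterministic():
    X, labels = blobs()
    spec = ClassifierSpec("random_forest", grid={"n_estimators": [50]}, seed=7)
    a = grid_search_cv(X, labels, spec)
    b = grid_search_cv(X, labels, spec)
    assert a.chosen_params == b.chosen_params
    assert a.cv_f1_mean == b.cv_f1_mean


def test_single_class_labels_hard_error():
    X, _ = blobs(n=50)
    with pytest.raises(ValueError):
        grid_search_cv(X, ["positive"] * 50, ClassifierSpec("knn", seed=0))


def test_minority_class_smaller_than_folds_rejected():
    X, _ = blobs(n=20)
    labels = ["positive"] * 3 + ["negative"] * 17
    with pytest.raises(ValueError, match="cv_folds"):
        grid_search_cv(X, labels, ClassifierSpec("knn", cv_folds=5, seed=0))


def test_empty_matrix_gives_empty_prediction_table():
    X, labels = blobs(n=60)
    model = grid_search_cv(X, labels, ClassifierSpec("l1_logreg", seed=0))
    preds = predict_articles(model, np.empty((0, X.shape[1])))
    assert len(preds) == 0
    assert list(preds.columns) == ["id", "score", "predicted_label"]


def test_zero_threshold_predicts_everything_positive():
    X, labels = blobs(n=60)
    spec = ClassifierSpec("l1_logreg", seed=0, threshold=0.0)
    model = grid_search_cv(X, labels, spec)
    preds = predict_articles(model, X)
    assert (preds["predicted_label"] == "positive").all()


def test_raising_threshold_never_adds_positives():
    X, labels = blobs(n=120)
    model = grid_search_cv(X, labels, ClassifierSpec("l1_logreg", seed=0))
    clf: F1GridSearchClassifier = model.estimator
    scores = clf.decision_scores(X)
    counts = [(scores >= t).sum() for t in (0.1, 0.3, 0.5, 0.7, 0.9)]
    assert counts == sorted(counts, reverse=True)


def test_training_row_predictions_match_brute_force_refit():
    X, labels = blobs(n=150, seed=4)
    spec = ClassifierSpec("l1_logreg", seed=3)
    model = grid_search_cv(X, labels, spec)
    preds = predict_articles(model, X)

    from sklearn.linear_model import LogisticRegression

    refit = LogisticRegression(
        l1_ratio=1.0, solver="liblinear", random_state=3, max_iter=5000,
        **model.chosen_params,
    ).fit(X, labels)
    agree = (refit.predict(X) == preds["predicted_label"].to_numpy()).mean()
    assert agree == 1.0


def test_column_mismatch_names_missing_features():
    ids = [f"d{i}" for i in range(40)]
    X, labels = blobs(n=40)
    cols = [f"f{j}" for j in range(X.shape[1])]
    dm = DocMatrix(ids, cols, X)
    model = grid_search_cv(dm, labels, ClassifierSpec("l1_logreg", seed=0))
    bad = DocMatrix(ids, ["other"] * X.shape[1], X)
    with pytest.raises(ValueError, match="f0"):
        predict_articles(model, bad)


# --- article-level aggregation -------------------------------------------

def pred_table(rows):
    return pd.DataFrame(rows, columns=["id", "score", "predicted_label"])


def test_single_excerpt_per_article_is_identity_either_mode():
    t = pred_table([("a", 0.7, "positive"), ("b", 0.2, "negative")])
    pd.testing.assert_frame_equal(article_level_aggregate(t, "concat"), t)
    pd.testing.assert_frame_equal(
        article_level_aggregate(t, "max_score").reset_index(drop=True), t
    )


def test_max_score_mode_takes_article_maximum():
    t = pred_table([("a", 0.2, "negative"), ("a", 0.9, "positive")])
    out = article_level_aggregate(t, "max_score")
    assert len(out) == 1
    assert out.iloc[0]["score"] == 0.9
    assert out.iloc[0]["predicted_label"] == "positive"


def test_max_aggregation_dominates_mean_aggregation():
    rng = np.random.default_rng(0)
    rows = [
        (f"a{i//3}", float(rng.random()), "negative") for i in range(60)
    ]
    t = pred_table(rows)
    mx = article_level_aggregate(t, "max_score").set_index("id")["score"].sort_index()
    mean = t.groupby("id")["score"].mean().sort_index()
    assert (mx.to_numpy() >= mean.to_numpy() - 1e-12).all()


def test_unknown_mode_rejected():
    with pytest.raises(ValueError):
        article_level_aggregate(pred_table([("a", 0.5, "positive")]), "median")


def test_unknown_family_rejected():
    with pytest.raises(ValueError, match="family"):
        ClassifierSpec("neural_net")
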