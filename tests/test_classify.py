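"""Random-forest classifier: split protocol, training, prediction,
evaluation, PCA and class-mean analytics."""

import numpy as np
import pandas as pd
import pytest

import mitomorph as mm
from mitomorph.classify import ConfusionMatrix


def make_table(n_per_class, rng, sep=6.0, classes=("network", "unbranched",
                                                   "swollen", "punctate")):
    rows = []
    for k, cls in enumerate(classes):
        centre = np.array([k * sep, -k * sep])
        pts = rng.normal(centre, 1.0, size=(n_per_class, 2))
        for p in pts:
            rows.append({"true_class": cls, "f1": p[0], "f2": p[1]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# split
# ---------------------------------------------------------------------------

def test_split_balanced_arithmetic(rng):
    df = make_table(100, rng)
    train, test = mm.split_train_test(df, 0.8, seed=0)
    assert len(train) == 320 and len(test) == 80
    assert set(train.index).isdisjoint(test.index)
    assert set(train.index) | set(test.index) == set(df.index)


def test_split_unbalanced_ceiling_per_class(rng):
    counts = {"network": 50, "unbranched": 80, "swollen": 120, "punctate": 200}
    rows = [{"true_class": c, "f1": rng.normal(), "f2": rng.normal()}
            for c, n in counts.items() for _ in range(n)]
    df = pd.DataFrame(rows)
    train, _ = mm.split_train_test(df, 0.8, seed=1)
    for c, n in counts.items():
        assert (train["true_class"] == c).sum() == int(np.ceil(0.8 * n))


def test_split_stratified(rng):
    df = make_table(50, rng)
    _, test = mm.split_train_test(df, 0.8, seed=2)
    assert (test["true_class"].value_counts() == 10).all()


def test_split_rejects_thin_classes(rng):
    df = make_table(5, rng)
    df = df.drop(df[df["true_class"] == "network"].index[1:])
    with pytest.raises(ValueError, match="network"):
        mm.split_train_test(df, 0.8)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def test_separable_classes_train_to_perfect_resample_accuracy(rng):
    df = make_table(30, rng, sep=20.0)
    model = mm.train_random_forest(df, n_trees=50, n_repetitions=5, seed=0)
    assert model.training_accuracy == 1.0
    assert model.n_trees == 50


def test_training_deterministic(rng):
    df = make_table(20, rng, sep=2.0)
    probe = make_table(10, np.random.default_rng(9), sep=2.0).drop(
        columns=["true_class"]
    )
    m1 = mm.train_random_forest(df, n_trees=50, n_repetitions=5, seed=4)
    m2 = mm.train_random_forest(df, n_trees=50, n_repetitions=5, seed=4)
    p1, f1 = mm.predict_morphology(m1, probe)
    p2, f2 = mm.predict_morphology(m2, probe)
    assert (p1 == p2).all()
    assert np.array_equal(f1.to_numpy(), f2.to_numpy())
    assert m1.training_accuracy == m2.training_accuracy


def test_training_rejects_single_class(rng):
    df = make_table(10, rng, classes=("network",))
    with pytest.raises(ValueError, match="2 classes"):
        mm.train_random_forest(df, n_trees=10, n_repetitions=2)


def test_permuted_labels_drop_to_chance(rng):
    """With labels shuffled, resample accuracy sits at the 4-class chance
    level (~0.25)."""
    df = make_table(150, rng, sep=8.0)
    df["true_class"] = rng.permutation(df["true_class"].to_numpy())
    model = mm.train_random_forest(df, n_trees=100, n_repetitions=5, seed=0)
    assert 0.15 <= model.training_accuracy <= 0.35


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def test_prediction_votes_and_tie_break(rng):
    df = make_table(25, rng, sep=12.0)
    model = mm.train_random_forest(df, n_trees=50, n_repetitions=3, seed=0)
    exemplar = df[df["true_class"] == "swollen"].iloc[[0]].drop(
        columns=["true_class"]
    )
    pred, frac = mm.predict_morphology(model, exemplar)
    assert pred[0] == "swollen"
    assert frac.iloc[0]["swollen"] > 0.5
    probe = pd.DataFrame({"f1": rng.normal(size=200) * 30,
                          "f2": rng.normal(size=200) * 30})
    _, fr = mm.predict_morphology(model, probe)
    assert np.allclose(fr.sum(axis=1), 1.0)
    assert list(fr.columns) == ["network", "unbranched", "swollen", "punctate"]


def test_prediction_feature_mismatch_rejected(rng):
    df = make_table(10, rng)
    model = mm.train_random_forest(df, n_trees=10, n_repetitions=2, seed=0)
    with pytest.raises(ValueError, match="feature mismatch"):
        mm.predict_morphology(model, pd.DataFrame({"f1": [0.0]}))
    with pytest.raises(ValueError, match="feature mismatch"):
        mm.predict_morphology(
            model, pd.DataFrame({"f1": [0.0], "f2": [0.0], "f3": [1.0]})
        )


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def test_confusion_matrix_hand_tally(rng):
    df = make_table(25, rng, sep=25.0)
    model = mm.train_random_forest(df, n_trees=50, n_repetitions=3, seed=0)
    test = df.iloc[[0, 1, 25, 26, 50, 51, 75, 76, 2, 27]]
    cm, acc = mm.evaluate(model, test)
    # fully separable fixture: predictions match labels exactly
    expected = np.diag([3, 3, 2, 2])
    assert np.array_equal(cm.counts, expected)
    assert acc == 1.0


def test_confusion_matrix_accuracy_degenerate_cases():
    perfect = ConfusionMatrix(np.diag([5, 5, 5, 5]),
                              ("network", "unbranched", "swollen", "punctate"))
    assert perfect.accuracy == 1.0
    wrong = ConfusionMatrix(
        np.array([[0, 10], [0, 0]]), ("network", "punctate")
    )
    assert wrong.accuracy == 0.0


def test_train_accuracy_rarely_below_test_accuracy():
    """Resample (training) accuracy should usually dominate held-out
    accuracy on generator data; allow rare exceptions."""
    exceptions = 0
    for seed in range(20):
        tab = mm.sample_object_table(mm.SynthSpec2D(n_per_class=12, seed=seed))
        # add feature noise so the task is not perfectly separable
        rng = np.random.default_rng(seed)
        feats = tab.columns.drop("true_class")
        noisy = tab.copy()
        noisy[feats] = noisy[feats] * (1 + rng.normal(0, 0.35, noisy[feats].shape))
        train, test = mm.split_train_test(noisy, 0.8, seed=seed)
        model = mm.train_random_forest(train, n_trees=50, n_repetitions=5,
                                       seed=seed)
        _, test_acc = mm.evaluate(model, test)
        _, train_fit_acc = mm.evaluate(model, train)
        if train_fit_acc < test_acc:
            exceptions += 1
    assert exceptions <= 2


# ---------------------------------------------------------------------------
# analytics
# ---------------------------------------------------------------------------

def test_pca_rank_one_data(rng):
    t = rng.normal(size=60)
    X = np.outer(t, np.array([1.0, -2.0, 0.5, 3.0, 1.5]))
    coords, ev = mm.pca_embed(pd.DataFrame(X))
    assert ev[0] > 0.999
    assert ev[0] >= ev[1]
    assert ev.sum() <= 1 + 1e-12


def test_pca_matches_closed_form_eigenvectors():
    pts = np.array([[2.0, 1.0], [-2.0, -1.0], [4.0, 2.2], [-4.0, -2.2],
                    [1.0, 0.4], [-1.0, -0.4]])
    df = pd.DataFrame(pts, columns=["x", "y"])
    coords, ev = mm.pca_embed(df)
    # closed form on the z-scored 2×2 covariance
    z = (pts - pts.mean(0)) / pts.std(0, ddof=1)
    cov = z.T @ z / (len(z) - 1)
    tr, det = cov.trace(), np.linalg.det(cov)
    lam1 = tr / 2 + np.sqrt(tr**2 / 4 - det)
    lam2 = tr / 2 - np.sqrt(tr**2 / 4 - det)
    assert ev[0] == pytest.approx(lam1 / (lam1 + lam2), rel=1e-9)
    v = np.array([cov[0, 1], lam1 - cov[0, 0]])
    v /= np.linalg.norm(v)
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    assert np.allclose(coords[:, 0], z @ v, atol=1e-9)


def test_pca_needs_three_rows():
    with pytest.raises(ValueError):
        mm.pca_embed(pd.DataFrame({"a": [1.0, 2.0], "b": [0.0, 1.0]}))


def test_heatmap_null_case(rng):
    n = 400
    df = pd.DataFrame({
        "true_class": np.repeat(["network", "unbranched", "swollen",
                                 "punctate"], n),
        "f1": rng.normal(size=4 * n),
        "f2": rng.normal(size=4 * n),
    })
    hm = mm.class_mean_heatmap(df)
    assert np.abs(hm.to_numpy()).max() < 3 / np.sqrt(n)


def test_heatmap_hand_fixture():
    df = pd.DataFrame({
        "true_class": ["network", "network", "unbranched", "unbranched",
                       "swollen", "swollen", "punctate", "punctate"],
        "f": [10.0, 12.0, 6.0, 8.0, 4.0, 6.0, 1.0, 3.0],
    })
    hm = mm.class_mean_heatmap(df)
    f = df["f"]
    z = (f - f.mean()) / f.std(ddof=1)
    expected = z.groupby(df["true_class"]).mean()
    for cls in hm.index:
        assert hm.loc[cls, "f"] == pytest.approx(expected[cls], rel=1e-12)
    assert list(hm.index) == ["network", "unbranched", "swollen", "punctate"]


def test_heatmap_missing_class_listed(rng):
    df = make_table(5, rng, classes=("network", "swollen"))
    with pytest.raises(ValueError, match="unbranched"):
        mm.class_mean_heatmap(df)


def test_heatmap_network_has_largest_area(table2d_small):
    hm = mm.class_mean_heatmap(table2d_small)
    assert hm["area_um2"].idxmax() == "network"
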