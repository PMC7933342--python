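"""Random-forest morphology classification, with PCA and class-mean analytics.

The classifier follows the study protocol: a stratified 80/20 train/test
split; hyperparameter selection (features considered per split) by the best
mean accuracy over 25 bootstrap resamples of the training set, each resample
scored on its out-of-bag rows; a final 500-tree forest refitted on the full
training set; prediction by the majority vote of the trees, ties broken by
the fixed class order network < unbranched < swollen < punctate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .descriptors import scale_features
from .synthgen import CLASS_NAMES

CLASS_COLUMN = "true_class"


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """K×K tally of true (rows) versus predicted (columns) classes."""

    counts: np.ndarray
    classes: tuple[str, ...]

    @property
    def accuracy(self) -> float:
        total = self.counts.sum()
        return float(np.trace(self.counts) / total) if total else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


@dataclass
class TrainedClassifier:
    """A fitted morphology forest plus its training metadata."""

    forest: RandomForestClassifier
    feature_names: tuple[str, ...]
    classes: tuple[str, ...]
    seed: int
    n_repetitions: int
    training_accuracy: float
    chosen_max_features: int
    n_trees: int = 500
    resample_accuracies: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Split / train / predict / evaluate
# ---------------------------------------------------------------------------

def split_train_test(
    table: pd.DataFrame,
    train_fraction: float = 0.8,
    seed: int = 0,
    class_column: str = CLASS_COLUMN,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified split; per class, ceil(fraction·n) rows go to training."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    counts = table[class_column].value_counts()
    thin = counts[counts < 2]
    if len(thin):
        raise ValueError(f"classes with < 2 rows: {list(thin.index)}")
    rng = np.random.default_rng(seed)
    train_idx = []
    for cls in sorted(counts.index):
        idx = table.index[table[class_column] == cls].to_numpy()
        perm = rng.permutation(len(idx))
        n_train = int(np.ceil(train_fraction * len(idx)))
        train_idx.extend(idx[perm[:n_train]])
    train_mask = table.index.isin(train_idx)
    return table.loc[train_mask].copy(), table.loc[~train_mask].copy()


def _feature_matrix(table: pd.DataFrame, class_column: str):
    feats = [c for c in table.columns if c != class_column]
    return table[feats].to_numpy(dtype=float), table[class_column].to_numpy(), tuple(feats)


def _class_order(present) -> tuple[str, ...]:
    """Canonical morphology order first, any extra labels appended sorted."""
    present = set(present)
    ordered = [c for c in CLASS_NAMES if c in present]
    ordered += sorted(present - set(CLASS_NAMES))
    return tuple(ordered)


def train_random_forest(
    train_table: pd.DataFrame,
    n_trees: int = 500,
    n_repetitions: int = 25,
    seed: int = 0,
    class_column: str = CLASS_COLUMN,
) -> TrainedClassifier:
    """Train the 500-tree morphology forest with bootstrap model selection.

    For each candidate of features-per-split, ``n_repetitions`` bootstrap
    resamples of the training set are drawn; a forest fitted on each
    resample is scored on the rows left out of that resample, and the
    candidate with the best mean accuracy wins.  The final forest is
    refitted on the full training set with the winning candidate;
    ``training_accuracy`` is the winning mean resample accuracy.
    """
    X, y, feats = _feature_matrix(train_table, class_column)
    classes = _class_order(np.unique(y))
    if len(classes) < 2:
        raise ValueError("training requires at least 2 classes")
    p = len(feats)
    base = max(1, int(np.sqrt(p)))
    candidates = sorted({max(1, base // 2), base, min(p, 2 * base)})
    rng = np.random.default_rng(seed)
    n = len(X)
    # one shared sequence of resamples and fit seeds so candidates compete
    # on identical resampling noise
    boot_sets = [rng.integers(0, n, size=n) for _ in range(n_repetitions)]
    fit_seeds = rng.integers(0, 2**31 - 1, size=(len(candidates), n_repetitions))
    mean_acc = {}
    for ci, cand in enumerate(candidates):
        accs = []
        for rep, boot in enumerate(boot_sets):
            oob = np.setdiff1d(np.arange(n), boot)
            if len(oob) == 0 or len(np.unique(y[boot])) < 2:
                continue
            clf = RandomForestClassifier(
                n_estimators=n_trees,
                max_features=cand,
                random_state=int(fit_seeds[ci, rep]),
                n_jobs=1,
            ).fit(X[boot], y[boot])
            accs.append(float((clf.predict(X[oob]) == y[oob]).mean()))
        mean_acc[cand] = float(np.mean(accs)) if accs else 0.0
    best = max(candidates, key=lambda c: (mean_acc[c], -c))
    forest = RandomForestClassifier(
        n_estimators=n_trees, max_features=best, random_state=seed, n_jobs=1
    ).fit(X, y)
    return TrainedClassifier(
        forest=forest,
        feature_names=feats,
        classes=classes,
        seed=seed,
        n_repetitions=n_repetitions,
        training_accuracy=mean_acc[best],
        chosen_max_features=best,
        n_trees=n_trees,
        resample_accuracies=mean_acc,
    )


def predict_morphology(
    model: TrainedClassifier, rows: pd.DataFrame
) -> tuple[np.ndarray, pd.DataFrame]:
    """Majority-vote prediction; returns (classes, per-class vote fractions).

    Ties go to the earliest class in the model's fixed class order.
    """
    extra = set(rows.columns) - set(model.feature_names) - {CLASS_COLUMN}
    missing = set(model.feature_names) - set(rows.columns)
    if missing or extra:
        raise ValueError(
            f"feature mismatch: missing {sorted(missing)}, unexpected {sorted(extra)}"
        )
    X = rows[list(model.feature_names)].to_numpy(dtype=float)
    forest_classes = list(model.forest.classes_)
    votes = np.zeros((len(X), len(model.classes)), dtype=float)
    col_of = {c: model.classes.index(c) for c in forest_classes}
    for tree in model.forest.estimators_:
        pred = tree.predict(X).astype(int)  # indices into forest.classes_
        for k, cls in enumerate(forest_classes):
            votes[pred == k, col_of[cls]] += 1.0
    fractions = votes / votes.sum(axis=1, keepdims=True)
    pred_idx = np.argmax(fractions, axis=1)  # first max = fixed-order tie-break
    predicted = np.array([model.classes[i] for i in pred_idx])
    frac_df = pd.DataFrame(fractions, columns=model.classes, index=rows.index)
    return predicted, frac_df


def evaluate(
    model: TrainedClassifier,
    test_table: pd.DataFrame,
    class_column: str = CLASS_COLUMN,
) -> tuple[ConfusionMatrix, float]:
    """Confusion matrix and accuracy of the model on a labeled table."""
    if len(test_table) == 0:
        raise ValueError("test table is empty")
    feats = test_table.drop(columns=[class_column])
    predicted, _ = predict_morphology(model, feats)
    true = test_table[class_column].to_numpy()
    classes = _class_order(set(model.classes) | set(true))
    k = len(classes)
    counts = np.zeros((k, k), dtype=int)
    pos = {c: i for i, c in enumerate(classes)}
    for t, pr in zip(true, predicted):
        counts[pos[t], pos[pr]] += 1
    cm = ConfusionMatrix(counts, classes)
    return cm, cm.accuracy


# ---------------------------------------------------------------------------
# Analytics
# ---------------------------------------------------------------------------

def pca_embed(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Two-component PCA of z-scored descriptors.

    Returns (coordinates (n, 2), explained-variance fractions (2,)).  The
    sign of each axis is fixed so its largest-magnitude loading is positive.
    """
    numeric = table.select_dtypes(include=[np.number])
    if len(numeric) < 3:
        raise ValueError("PCA requires at least 3 rows")
    scaled, _ = scale_features(numeric)
    X = scaled.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    cov = X.T @ X / (len(X) - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    total = float(evals.clip(min=0).sum())
    if total == 0:
        raise ValueError("data has zero variance")
    comps = evecs[:, :2]
    for j in range(2):
        lead = np.argmax(np.abs(comps[:, j]))
        if comps[lead, j] < 0:
            comps[:, j] = -comps[:, j]
    coords = X @ comps
    explained = evals[:2].clip(min=0) / total
    return coords, explained


def class_mean_heatmap(
    table: pd.DataFrame, class_column: str = CLASS_COLUMN
) -> pd.DataFrame:
    """Class × descriptor matrix of z-scored descriptor means.

    Each descriptor is z-scored across all objects, then averaged within
    class; this is the matrix rendered as the morphology heatmap.
    """
    present = set(table[class_column])
    missing = [c for c in CLASS_NAMES if c not in present]
    if missing:
        raise ValueError(f"classes missing from table: {missing}")
    numeric = table.drop(columns=[class_column]).select_dtypes(include=[np.number])
    scaled, _ = scale_features(numeric)
    scaled[class_column] = table[class_column].to_numpy()
    means = scaled.groupby(class_column).mean()
    order = [c for c in CLASS_NAMES if c in means.index] + sorted(
        set(means.index) - set(CLASS_NAMES)
    )
    return means.loc[order]
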