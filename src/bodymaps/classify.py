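"""Complete classification of stimuli from subject-wise BSMs.

All stimuli are discriminated from each other by a single multi-class
model: pixel vectors are reduced to 30 principal components and a
linear discriminant classifier is fit, with accuracy estimated by
stratified five-fold cross-validation repeated (by default) 100 times
under reshuffled fold assignments.  Dimensionality reduction is fit
inside each training fold by default (no test-set leakage); a
global-fit compatibility mode is available.  Chance level for k
balanced classes is 100/k percent — 5% for the full 20-stimulus roster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold, StratifiedGroupKFold
from sklearn.preprocessing import StandardScaler

from .preprocess import SubjectBSM
from .template import BodyTemplate, mask_vector_index

__all__ = [
    "FeatureMatrix",
    "ClassificationReport",
    "build_feature_matrix",
    "chance_level",
    "lda_crossval",
]


@dataclass
class FeatureMatrix:
    """(subject, stimulus) samples as in-mask pixel vectors."""

    X: np.ndarray  # (n_samples, n_in_mask)
    labels: np.ndarray  # stimulus per row
    subjects: np.ndarray  # subject id per row

    def __post_init__(self) -> None:
        if not (len(self.X) == len(self.labels) == len(self.subjects)):
            raise ValueError("X, labels and subjects must have equal length")


@dataclass
class ClassificationReport:
    """Repeated-CV accuracy and aggregated confusion matrix.

    ``accuracies`` holds one overall accuracy (percent correct over all
    test rows) per iteration; ``confusion_pct`` is row-normalized to
    percentages per true class, aggregated over every iteration's test
    predictions.  Dispersion is reported as both SD and SEM across
    iterations, since either convention is used in practice.
    """

    labels: list[str]
    accuracies: np.ndarray  # percent, length = iterations
    mean_accuracy: float
    sd_accuracy: float
    sem_accuracy: float
    chance: float
    confusion_counts: np.ndarray
    confusion_pct: np.ndarray
    n_components: int
    folds: int
    iterations: int


def build_feature_matrix(bsms: list[SubjectBSM], template: BodyTemplate) -> FeatureMatrix:
    """Vectorize completed subject maps into a samples x pixels matrix."""
    if not bsms:
        raise ValueError("no subject maps to vectorize")
    idx = mask_vector_index(template)
    X = np.stack([idx.vectorize(b.values) for b in bsms])
    labels = np.array([b.stimulus for b in bsms])
    subjects = np.array([b.subject_id for b in bsms])
    return FeatureMatrix(X=X, labels=labels, subjects=subjects)


def chance_level(n_classes: int) -> float:
    """Uniform-guessing accuracy in percent: 100 / n_classes."""
    if n_classes < 2:
        raise ValueError("chance level needs at least 2 classes")
    return 100.0 / n_classes


def lda_crossval(
    features: FeatureMatrix,
    n_components: int = 30,
    folds: int = 5,
    iterations: int = 100,
    seed: int = 0,
    scale: bool = False,
    global_pca: bool = False,
    subject_blocked: bool = False,
) -> ClassificationReport:
    """PCA + LDA complete classification with repeated stratified CV.

    Each iteration reshuffles the stratified fold assignment (seeded);
    within each fold the PCA (and optional standardization) is fit on
    the training rows only, then an LDA classifier predicts the test
    rows.  ``global_pca=True`` fits the PCA once on all rows before
    cross-validation — a compatibility mode replicating analyses that
    reduce dimensionality globally, at the cost of mild leakage.
    ``subject_blocked=True`` keeps every subject's samples within a
    single fold (stratified group CV).
    """
    X, y = features.X, features.labels
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        worst = classes[counts.argmin()]
        raise ValueError(
            f"class {worst!r} has only {counts.min()} samples but {folds}-fold CV "
            "needs at least one sample per fold; reduce folds or add subjects"
        )
    max_comp = min(len(X) - 1, X.shape[1])
    if n_components > max_comp:
        raise ValueError(
            f"n_components={n_components} exceeds min(rows-1, columns)={max_comp}; "
            "reduce n_components or provide more samples"
        )

    label_to_i = {c: i for i, c in enumerate(classes)}
    y_i = np.array([label_to_i[v] for v in y])
    k = len(classes)
    confusion = np.zeros((k, k), dtype=np.int64)
    accuracies = np.empty(iterations)

    ss = np.random.SeedSequence(seed)
    iter_seeds = ss.generate_state(2 * iterations)

    if global_pca:
        global_proj = PCA(
            n_components=n_components, svd_solver="randomized",
            random_state=int(iter_seeds[-1] % (2**31)),
        ).fit(X)

    for it in range(iterations):
        fold_seed = int(iter_seeds[2 * it] % (2**31))
        pca_seed = int(iter_seeds[2 * it + 1] % (2**31))
        if subject_blocked:
            cv = StratifiedGroupKFold(n_splits=folds, shuffle=True, random_state=fold_seed)
            splits = cv.split(X, y_i, groups=features.subjects)
        else:
            cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=fold_seed)
            splits = cv.split(X, y_i)

        correct = 0
        total = 0
        for train, test in splits:
            Xtr, Xte = X[train], X[test]
            if scale:
                scaler = StandardScaler().fit(Xtr)
                Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)
            if global_pca:
                Ztr, Zte = global_proj.transform(Xtr), global_proj.transform(Xte)
            else:
                proj = PCA(
                    n_components=n_components, svd_solver="randomized",
                    random_state=pca_seed,
                ).fit(Xtr)
                Ztr, Zte = proj.transform(Xtr), proj.transform(Xte)
            clf = LinearDiscriminantAnalysis().fit(Ztr, y_i[train])
            pred = clf.predict(Zte)
            truth = y_i[test]
            correct += int((pred == truth).sum())
            total += len(test)
            np.add.at(confusion, (truth, pred), 1)
        accuracies[it] = 100.0 * correct / total

    row_sums = confusion.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        confusion_pct = np.where(row_sums > 0, 100.0 * confusion / row_sums, 0.0)

    return ClassificationReport(
        labels=list(classes),
        accuracies=accuracies,
        mean_accuracy=float(accuracies.mean()),
        sd_accuracy=float(accuracies.std(ddof=1)) if iterations > 1 else 0.0,
        sem_accuracy=(
            float(accuracies.std(ddof=1) / np.sqrt(iterations)) if iterations > 1 else 0.0
        ),
        chance=chance_level(k),
        confusion_counts=confusion,
        confusion_pct=confusion_pct,
        n_components=n_components,
        folds=folds,
        iterations=iterations,
    )
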