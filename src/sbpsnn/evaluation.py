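"""Performance metrics for the emotion decoding tasks.

Accuracy is reported in percent.  F1 is the positive-class score for the
binary emotion-vs-neutral tasks and the unweighted macro average for the
four-class task.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import accuracy_score, confusion_matrix, f1_score


@dataclass
class EvalReport:
    task: str                    # "binary" | "four_class"
    accuracy: float              # percent
    f1: float
    confusion: np.ndarray
    classes: tuple
    seeds: tuple = ()
    chance_level: float = 0.0    # percent

    def to_row(self) -> dict:
        return {"task": self.task, "accuracy": self.accuracy, "f1": self.f1,
                "chance": self.chance_level}


def evaluate(preds, labels, task: str = "binary",
             positive_class: str | None = None, classes=None) -> EvalReport:
    """Accuracy (percent), F1 and confusion matrix for a prediction set.

    Binary tasks score F1 on the positive (emotion) class; the four-class
    task uses the unweighted macro mean.
    """
    preds = list(preds)
    labels = list(labels)
    if len(preds) == 0 or len(preds) != len(labels):
        raise ValueError("predictions and labels must be equal-length and non-empty")
    if classes is None:
        classes = tuple(sorted(set(labels)))
    bad = set(labels) - set(classes)
    if bad:
        raise ValueError(f"labels outside the class set: {sorted(bad)}")
    if task not in ("binary", "four_class"):
        raise ValueError(f"unknown task {task!r}")
    if task == "binary" and len(classes) != 2:
        raise ValueError("binary task requires exactly two classes")

    acc = accuracy_score(labels, preds) * 100.0
    if task == "binary":
        if positive_class is None:
            # the emotion is whichever class is not "neutral"
            positive_class = next((c for c in classes if c != "neutral"), classes[1])
        f1 = f1_score(labels, preds, pos_label=positive_class,
                      labels=list(classes), average="binary", zero_division=0)
    else:
        f1 = f1_score(labels, preds, labels=list(classes), average="macro",
                      zero_division=0)
    cm = confusion_matrix(labels, preds, labels=list(classes))
    counts = np.bincount([list(classes).index(l) for l in labels],
                         minlength=len(classes))
    chance = counts.max() / counts.sum() * 100.0
    return EvalReport(task, float(acc), float(f1), cm, tuple(classes),
                      chance_level=float(chance))


def stratified_split(labels, test_fraction: float = 0.2, seed: int = 0):
    """Deterministic stratified train/test index split."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(len(idx))]
        n_test = max(1, int(round(test_fraction * len(idx))))
        test_idx.extend(idx[:n_test])
        train_idx.extend(idx[n_test:])
    return np.sort(train_idx), np.sort(test_idx)


def classical_baselines(X, y, seed: int = 0):
    """Optional comparison models from scikit-learn (not bespoke).

    Returns {name: cross-validated accuracy percent} for logistic
    regression, naive Bayes, SVM, random forest and k-NN on flattened
    feature matrices.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import cross_val_score
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.svm import SVC

    models = {
        "LR": LogisticRegression(max_iter=1000),
        "NB": GaussianNB(),
        "SVM": SVC(),
        "RF": RandomForestClassifier(n_estimators=100, random_state=seed),
        "KNN": KNeighborsClassifier(),
    }
    out = {}
    for name, mdl in models.items():
        out[name] = float(cross_val_score(mdl, X, y, cv=3).mean() * 100.0)
    return out
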