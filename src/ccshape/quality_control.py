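"""Automatic pass/fail quality control of midCC segmentations.

Classifies segmentations from their shape-metric feature vectors using
one of three model families:

* ``three_layer_nn`` — a sequential network with 42/22/11 hidden units;
* ``wide_deep_nn`` — six hidden layers, 80/80/80/40/40/40 units;
* ``ensemble`` — XGBoost, k-nearest neighbours, a support vector
  classifier, logistic regression and a random forest, combined by hard
  majority voting (an odd member count, so no ties).

Features are z-scored on the training split only.  The ensemble's
continuous score (for AUC) is the mean of member probabilities; its
label is the hard vote — both are reported because the two can
disagree near the decision boundary.
"""

from __future__ import annotations

import dataclasses
import pickle
from collections import Counter

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from ccshape.imaging_io import FeatureTable, ValidationError

__all__ = ["QCModelSpec", "EvalReport", "QCModel", "hard_majority_vote",
           "train_qc", "evaluate_qc", "qc_feature_importance",
           "save_qc_model", "load_qc_model"]

FAMILIES = ("three_layer_nn", "wide_deep_nn", "ensemble")


@dataclasses.dataclass
class QCModelSpec:
    family: str = "ensemble"
    three_layer_sizes: tuple[int, ...] = (42, 22, 11)
    wide_deep_sizes: tuple[int, ...] = (80, 80, 80, 40, 40, 40)
    learning_rate: float = 1e-3
    max_iter: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown family {self.family!r}")


@dataclasses.dataclass
class EvalReport:
    """Per-class precision/recall/F1, overall AUC and confusion counts."""

    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    auc: float
    confusion: dict[str, int]  # tp, fp, fn, tn (pass = positive)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def hard_majority_vote(member_labels) -> int:
    """Label held by more than half of an odd number of voters."""
    votes = list(member_labels)
    if len(votes) % 2 == 0:
        raise ValidationError("even vote counts can tie; use an odd ensemble")
    value, count = Counter(votes).most_common(1)[0]
    return value


def _make_members(spec: QCModelSpec) -> list:
    s = spec.seed
    return [
        XGBClassifier(n_estimators=100, max_depth=4, learning_rate=0.1,
                      random_state=s, eval_metric="logloss"),
        KNeighborsClassifier(n_neighbors=5),
        SVC(probability=True, random_state=s),
        LogisticRegression(max_iter=1000, random_state=s),
        RandomForestClassifier(n_estimators=200, random_state=s),
    ]


class QCModel:
    """Trained QC classifier with a unified probability/label interface."""

    def __init__(self, spec: QCModelSpec, scaler: StandardScaler,
                 members: list, feature_names: list[str]):
        self.spec = spec
        self.scaler = scaler
        self.members = members
        self.feature_names = feature_names

    def pass_probability(self, x: np.ndarray) -> np.ndarray:
        """P(pass) per example; ensemble: mean of member probabilities."""
        z = self.scaler.transform(x)
        probs = np.column_stack([m.predict_proba(z)[:, 1] for m in self.members])
        return probs.mean(axis=1)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Hard labels; ensemble uses the majority vote of members."""
        z = self.scaler.transform(x)
        if len(self.members) == 1:
            return self.members[0].predict(z).astype(int)
        votes = np.column_stack([m.predict(z).astype(int) for m in self.members])
        return np.array([hard_majority_vote(row) for row in votes])


def _as_xy(features: FeatureTable | np.ndarray, labels) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if isinstance(features, FeatureTable):
        x = features.values()
        names = features.metric_names
    else:
        x = np.asarray(features, dtype=float)
        names = [f"f{i}" for i in range(x.shape[1])]
    y = np.asarray(labels).astype(int)
    return x, y, names


def train_qc(features: FeatureTable | np.ndarray, labels,
             spec: QCModelSpec | None = None) -> QCModel:
    """Fit a QC model on (features, pass/fail labels).

    Labels are 1 = pass, 0 = fail; at least two examples of each class
    are required.
    """
    spec = spec or QCModelSpec()
    x, y, names = _as_xy(features, labels)
    counts = Counter(y)
    if len(counts) < 2 or min(counts.values()) < 2:
        raise ValidationError("need >= 2 examples of both pass and fail")
    scaler = StandardScaler().fit(x)
    z = scaler.transform(x)
    if spec.family == "ensemble":
        members = _make_members(spec)
        for m in members:
            m.fit(z, y)
    else:
        sizes = (spec.three_layer_sizes if spec.family == "three_layer_nn"
                 else spec.wide_deep_sizes)
        # small narrow MLPs occasionally start in a dead basin; retry
        # with fresh initializations and keep the best training fit
        best = None
        for attempt in range(3):
            net = MLPClassifier(hidden_layer_sizes=sizes, activation="relu",
                                solver="adam", learning_rate_init=spec.learning_rate,
                                max_iter=spec.max_iter,
                                early_stopping=len(y) >= 150,
                                n_iter_no_change=20,
                                random_state=spec.seed + 1000 * attempt)
            net.fit(z, y)
            acc = float(np.mean(net.predict(z) == y))
            if best is None or acc > best[0]:
                best = (acc, net)
            if acc >= 0.95:
                break
        members = [best[1]]
    return QCModel(spec, scaler, members, names)


def evaluate_qc(predictions, truth, scores=None) -> EvalReport:
    """Tabulate per-class precision/recall/F1 and (if scores given) AUC.

    ``predictions``/``truth`` are 0/1 labels (1 = pass); ``scores`` are
    continuous pass probabilities for the rank-based AUC.
    """
    pred = np.asarray(predictions).astype(int)
    true = np.asarray(truth).astype(int)
    if len(pred) == 0 or len(pred) != len(true):
        raise ValidationError("empty or misaligned predictions")
    tp = int(np.sum((pred == 1) & (true == 1)))
    fp = int(np.sum((pred == 1) & (true == 0)))
    fn = int(np.sum((pred == 0) & (true == 1)))
    tn = int(np.sum((pred == 0) & (true == 0)))

    def prf(tp_, fp_, fn_):
        p = tp_ / (tp_ + fp_) if tp_ + fp_ else 0.0
        r = tp_ / (tp_ + fn_) if tp_ + fn_ else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        return p, r, f

    p1, r1, f1_1 = prf(tp, fp, fn)
    p0, r0, f1_0 = prf(tn, fn, fp)
    if scores is not None and len(set(true)) == 2:
        scores = np.asarray(scores, dtype=float)
        if np.ptp(scores) == 0:
            auc = 0.5  # constant scores carry no ranking information
        else:
            auc = float(roc_auc_score(true, scores))
    else:
        auc = float("nan")
    return EvalReport(
        precision={"pass": p1, "fail": p0},
        recall={"pass": r1, "fail": r0},
        f1={"pass": f1_1, "fail": f1_0},
        auc=auc,
        confusion={"tp": tp, "fp": fp, "fn": fn, "tn": tn},
    )


def qc_feature_importance(model: QCModel, features, labels,
                          n_repeats: int = 10) -> list[tuple[str, float]]:
    """Rank features by permutation importance on held-out data."""
    x, y, _ = _as_xy(features, labels)
    z = model.scaler.transform(x)

    class _Wrapped:
        def fit(self, *a):  # pragma: no cover - required by sklearn API
            return self

        def predict(self, xx):
            votes = np.column_stack([m.predict(xx).astype(int)
                                     for m in model.members])
            if votes.shape[1] == 1:
                return votes[:, 0]
            return np.array([hard_majority_vote(row) for row in votes])

        def score(self, xx, yy):
            return float(np.mean(self.predict(xx) == yy))

    imp = permutation_importance(_Wrapped(), z, y, n_repeats=n_repeats,
                                 random_state=model.spec.seed)
    order = np.argsort(-imp.importances_mean)
    return [(model.feature_names[i], float(imp.importances_mean[i])) for i in order]


def save_qc_model(model: QCModel, path: str) -> None:
    with open(path, "wb") as fh:
        pickle.dump(model, fh)


def load_qc_model(path: str) -> QCModel:
    with open(path, "rb") as fh:
        return pickle.load(fh)
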