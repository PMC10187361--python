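"""Two-stage classification of callosal shape abnormalities.

Five classes: normal, hypoplasia (uniformly thin), dysplasia (distorted
overall shape), combined hypoplasia + dysplasia, and agenesis (part of
the structure missing).

Stage one trains a small neural network on the shape metrics and emits
a softmax probability per class (the "NN scores").  Stage two appends
those scores to the shape metrics and trains an XGBoost classifier on
the combined features.  Minority classes may be oversampled with
replacement to configured target counts — on the training split only.
"""

from __future__ import annotations

import dataclasses
import pickle
from collections import Counter

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

from ccshape.imaging_io import FeatureTable, ValidationError

__all__ = [
    "ABNORMALITY_CLASSES",
    "BalancingPlan",
    "ScoreNetwork",
    "AbnormalityClassifier",
    "train_score_nn",
    "balance_classes",
    "train_abnormality_classifier",
    "report_top_features",
]

ABNORMALITY_CLASSES = ("normal", "hypoplasia", "dysplasia",
                       "hypoplasia_dysplasia", "agenesis")

#: feature-table column names for the stage-one scores
SCORE_COLUMNS = tuple(f"{c} NN" for c in ABNORMALITY_CLASSES)


@dataclasses.dataclass
class BalancingPlan:
    """Per-class target training counts; targets below the current count
    are invalid (oversampling only, applied to the training split)."""

    targets: dict[str, int]


@dataclasses.dataclass
class ScoreNetwork:
    scaler: StandardScaler
    net: MLPClassifier
    classes: list[str]

    def scores(self, x: np.ndarray) -> np.ndarray:
        """Softmax probability per class, columns ordered like
        ``ABNORMALITY_CLASSES`` (absent classes get zero)."""
        p = self.net.predict_proba(self.scaler.transform(x))
        out = np.zeros((len(x), len(ABNORMALITY_CLASSES)))
        for j, cls in enumerate(self.net.classes_):
            out[:, ABNORMALITY_CLASSES.index(cls)] = p[:, j]
        return out


def _as_xy(features, labels):
    if isinstance(features, FeatureTable):
        x = features.values()
        names = features.metric_names
    else:
        x = np.asarray(features, dtype=float)
        names = [f"f{i}" for i in range(x.shape[1])]
    y = np.asarray(labels)
    unknown = set(y) - set(ABNORMALITY_CLASSES)
    if unknown:
        raise ValidationError(f"unknown classes {sorted(unknown)}")
    return x, y, names


def train_score_nn(features, labels, hidden=(32, 16), seed: int = 0,
                   max_iter: int = 800) -> ScoreNetwork:
    """Stage one: shape metrics -> per-class probability scores."""
    x, y, _ = _as_xy(features, labels)
    if len(set(y)) < 2:
        raise ValidationError("need at least two classes")
    scaler = StandardScaler().fit(x)
    net = MLPClassifier(hidden_layer_sizes=hidden, activation="relu",
                        solver="adam", learning_rate_init=1e-3,
                        max_iter=max_iter, random_state=seed)
    net.fit(scaler.transform(x), y)
    return ScoreNetwork(scaler=scaler, net=net, classes=list(net.classes_))


def balance_classes(features: np.ndarray, labels, plan: BalancingPlan,
                    rng: np.random.Generator):
    """Oversample minority classes with replacement to the plan's target
    counts; classes without a target (or already at target) are untouched."""
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    counts = Counter(y)
    keep_x, keep_y = [x], [y]
    for cls, target in plan.targets.items():
        current = counts.get(cls, 0)
        if target < current:
            raise ValidationError(
                f"target {target} below current count {current} for {cls!r}")
        extra = target - current
        if extra > 0:
            idx = np.nonzero(y == cls)[0]
            draw = rng.choice(idx, size=extra, replace=True)
            keep_x.append(x[draw])
            keep_y.append(y[draw])
    return np.vstack(keep_x), np.concatenate(keep_y)


@dataclasses.dataclass
class AbnormalityClassifier:
    score_net: ScoreNetwork
    booster: XGBClassifier
    feature_names: list[str]
    classes: list[str]

    def _combined(self, x: np.ndarray) -> np.ndarray:
        return np.column_stack([x, self.score_net.scores(x)])

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.booster.predict_proba(self._combined(np.asarray(x, dtype=float)))

    def predict(self, x: np.ndarray) -> np.ndarray:
        idx = self.booster.predict(self._combined(np.asarray(x, dtype=float)))
        return np.array([self.classes[i] for i in idx])

    def save(self, path: str) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str) -> "AbnormalityClassifier":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def train_abnormality_classifier(
    features, labels,
    plan: BalancingPlan | None = None,
    seed: int = 0,
    n_estimators: int = 200,
    max_depth: int = 4,
    learning_rate: float = 0.1,
) -> AbnormalityClassifier:
    """Two-stage training: score network, then XGBoost on metrics + scores.

    ``plan`` oversamples the (training) input before both stages; the
    caller is responsible for holding out a test split beforehand.
    """
    x, y, names = _as_xy(features, labels)
    rng = np.random.default_rng(seed)
    if plan is not None:
        x, y = balance_classes(x, y, plan, rng)
    score_net = train_score_nn(x, y, seed=seed)
    # stage two sees out-of-fold stage-one scores: scores predicted on
    # the rows the network trained on are nearly one-hot, and a booster
    # trained on those would ignore the shape metrics entirely
    oof = np.zeros((len(x), len(ABNORMALITY_CLASSES)))
    n_folds = 5
    fold = rng.permutation(len(x)) % n_folds
    for f in range(n_folds):
        tr = fold != f
        if len(set(y[tr])) < 2:
            oof[fold == f] = score_net.scores(x[fold == f])
            continue
        fold_net = train_score_nn(x[tr], y[tr], seed=seed + 100 + f)
        oof[fold == f] = fold_net.scores(x[fold == f])
    combined = np.column_stack([x, oof])
    classes = sorted(set(y), key=ABNORMALITY_CLASSES.index)
    y_idx = np.array([classes.index(c) for c in y])
    booster = XGBClassifier(n_estimators=n_estimators, max_depth=max_depth,
                            learning_rate=learning_rate, random_state=seed,
                            eval_metric="mlogloss")
    booster.fit(combined, y_idx)
    return AbnormalityClassifier(
        score_net=score_net, booster=booster,
        feature_names=list(names) + list(SCORE_COLUMNS),
        classes=classes)


def report_top_features(model: AbnormalityClassifier) -> pd.DataFrame:
    """Gain-based importance ranking over the combined feature set."""
    imp = model.booster.feature_importances_
    frame = pd.DataFrame({"feature": model.feature_names, "importance": imp})
    return frame.sort_values("importance", ascending=False).reset_index(drop=True)
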