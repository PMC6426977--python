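"""Linear-SVM classification of brain state from feature vectors.

Protocol: per fold, a random half of the training set fits a linear SVM
(features standardized on that half only) and the classifier predicts the
FULL validation set; the error is the percentage of wrong predictions.
Fold-to-fold variability therefore comes only from the training subsample.
ROC curves sweep the decision-function threshold over the pooled validation
scores; AUC is the trapezoid-rule area.  The ``awake`` class is treated as
positive throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn import metrics
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .io import AWAKE, FeatureSet

POSITIVE_LABEL = AWAKE


class ProtocolError(ValueError):
    pass


@dataclass
class FoldProtocol:
    """Train/validate protocol configuration.

    ``scheme`` is descriptive provenance (within_session, cross_session,
    cross_subject_pooled); the mechanics are identical — it is the caller's
    choice of train/validation sets that realizes the scheme.
    """

    n_folds: int = 100
    train_fraction: float = 0.5
    seed: int = 0
    scheme: str = "within_session"

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ProtocolError("train_fraction must be in (0, 1)")
        if self.n_folds < 1:
            raise ProtocolError("n_folds must be >= 1")


@dataclass
class EvalReport:
    """Per-fold errors plus pooled ROC/AUC for one train/validate scheme."""

    errors_pct: np.ndarray
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    auc: float
    config: dict = field(default_factory=dict)

    @property
    def median_error_pct(self) -> float:
        return float(np.median(self.errors_pct))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "errors_pct": list(map(float, self.errors_pct)),
            "roc": [[float(x), float(y)] for x, y in zip(self.roc_fpr, self.roc_tpr)],
            "auc": self.auc,
            "median_error_pct": self.median_error_pct,
            "config": self.config,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "EvalReport":
        d = json.loads(Path(path).read_text())
        roc = np.array(d["roc"]) if d["roc"] else np.zeros((0, 2))
        return cls(
            np.array(d["errors_pct"]),
            roc[:, 0] if roc.size else np.array([]),
            roc[:, 1] if roc.size else np.array([]),
            d["auc"],
            d.get("config", {}),
        )


def train_svm(
    vectors: np.ndarray,
    labels: np.ndarray,
    c: float = 1.0,
    random_state: int = 0,
) -> Pipeline:
    """Fit a standardizer + linear SVM on a training subset.

    Standardization parameters are estimated on these vectors only, so no
    validation information leaks into the decision function.
    """
    labels = np.asarray(labels)
    if len(set(labels)) < 2:
        raise ProtocolError("training subset contains a single class")
    clf = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", LinearSVC(C=c, random_state=random_state, max_iter=10000)),
        ]
    )
    clf.fit(np.asarray(vectors, dtype=float), labels)
    return clf


def _decision_scores(clf: Pipeline, vectors: np.ndarray) -> np.ndarray:
    """Scores oriented so larger means more awake-like."""
    scores = clf.decision_function(vectors)
    classes = list(clf.classes_)
    if classes[-1] != POSITIVE_LABEL:
        scores = -scores
    return scores


def evaluate(
    protocol: FoldProtocol,
    train_set: FeatureSet,
    valid_set: FeatureSet,
    c: float = 1.0,
    permute_train_labels: bool = False,
) -> EvalReport:
    """Run the fold protocol and assemble an evaluation report.

    Each fold draws ``train_fraction`` of the training vectors at random
    (redrawing in the rare case a draw is single-class), trains, and
    predicts the full validation set.  ``permute_train_labels`` shuffles
    the training labels freshly every fold — the chance-level null control.
    """
    if train_set.dim != valid_set.dim:
        raise ProtocolError(
            f"train dim {train_set.dim} != valid dim {valid_set.dim}"
        )
    rng = np.random.default_rng(protocol.seed)
    n_train = train_set.n_vectors
    n_half = max(2, int(round(protocol.train_fraction * n_train)))
    y_valid = valid_set.labels
    errors = np.empty(protocol.n_folds)
    pooled_scores, pooled_truth = [], []
    for fold in range(protocol.n_folds):
        for _ in range(100):
            idx = rng.choice(n_train, size=n_half, replace=False)
            if len(set(train_set.labels[idx])) == 2:
                break
        else:
            raise ProtocolError("could not draw a two-class training subsample")
        fold_labels = train_set.labels[idx]
        if permute_train_labels:
            fold_labels = rng.permutation(fold_labels)
        clf = train_svm(
            train_set.vectors[idx], fold_labels, c=c,
            random_state=int(rng.integers(2**31 - 1)),
        )
        pred = clf.predict(valid_set.vectors)
        errors[fold] = 100.0 * float(np.mean(pred != y_valid))
        pooled_scores.append(_decision_scores(clf, valid_set.vectors))
        pooled_truth.append(y_valid == POSITIVE_LABEL)
    scores = np.concatenate(pooled_scores)
    truth = np.concatenate(pooled_truth)
    fpr, tpr, _ = metrics.roc_curve(truth, scores)
    auc = float(metrics.auc(fpr, tpr))
    return EvalReport(
        errors_pct=errors,
        roc_fpr=fpr,
        roc_tpr=tpr,
        auc=auc,
        config={
            "n_folds": protocol.n_folds,
            "train_fraction": protocol.train_fraction,
            "seed": protocol.seed,
            "scheme": protocol.scheme,
            "C": c,
            "permuted_train_labels": permute_train_labels,
            "train_source": train_set.source,
            "train_surrogate": train_set.surrogate,
            "window_s": train_set.window_s,
        },
    )


def split_feature_set(
    fset: FeatureSet, fraction: float = 0.5, seed: int = 0
) -> tuple[FeatureSet, FeatureSet]:
    """Random stratified split into two disjoint feature sets."""
    rng = np.random.default_rng(seed)
    first, second = [], []
    for label in sorted(set(fset.labels)):
        idx = np.flatnonzero(fset.labels == label)
        rng.shuffle(idx)
        cut = int(round(fraction * len(idx)))
        first.extend(idx[:cut])
        second.extend(idx[cut:])
    return fset.subset(np.sort(first)), fset.subset(np.sort(second))


def performance_vs_window(
    windows: list[float],
    train_data,
    valid_data,
    sources: tuple[str, ...] = ("ds", "fft", "ds+phase", "ds+stagger", "ds+global_stagger"),
    n_per_interval: int = 100,
    protocol: FoldProtocol | None = None,
    seed: int = 0,
):
    """Median error and AUC per window length and feature source.

    ``train_data`` and ``valid_data`` are ``(Recording, intervals)`` pairs
    (different recordings realize cross-session validation).  Sources are
    ``ds``, ``fft``, or ``ds+<surrogate>``.
    """
    import pandas as pd

    from .ds_features import make_ds_vectors
    from .fft_features import make_fft_vectors
    from .surrogates import SurrogateSpec

    if protocol is None:
        protocol = FoldProtocol(n_folds=25, seed=seed)

    def featurize(data, window_s, source, seed_offset):
        rec, intervals = data
        if source == "fft":
            return make_fft_vectors(
                rec, intervals, window_s, n_per_interval, seed=seed + seed_offset
            )
        surrogate = None
        if source.startswith("ds+"):
            surrogate = SurrogateSpec(source[3:])
        return make_ds_vectors(
            rec, intervals, window_s, n_per_interval,
            surrogate=surrogate, seed=seed + seed_offset,
        )

    rows = []
    for window_s in windows:
        for source in sources:
            train_fs = featurize(train_data, window_s, source, 1)
            valid_fs = featurize(valid_data, window_s, source, 2)
            report = evaluate(protocol, train_fs, valid_fs)
            rows.append(
                {
                    "window_s": window_s,
                    "source": source,
                    "median_error_pct": report.median_error_pct,
                    "auc": report.auc,
                }
            )
    return pd.DataFrame(rows)
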