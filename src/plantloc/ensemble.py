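"""Heterogeneous average-voting ensemble over 11 plant compartments.

Three base classifiers — inverse-distance-weighted KNN (k = 12, on
standardized features), a 100-tree random forest, and gradient boosting
(50 rounds, depth 5, learning rate 0.1, multiclass log-loss) — are trained
on identical rows and features. Their class-probability vectors are combined
by unweighted average voting; the consensus distribution drives both the
single-label call (top class) and the dual-label rule (second-ranked class
added when its consensus probability reaches ``theta``).

Dual-location training proteins are handled by the ``duplicate`` policy
(each pair-labeled record enters the base-model training set once per
constituent compartment) or the ``pair-class`` alternative (pairs are
temporary extra classes whose probability is split back onto the
constituents at prediction time).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted
from xgboost import XGBClassifier

from .seqio import COMPARTMENTS


@dataclass(frozen=True)
class EnsembleConfig:
    """Stated base-learner hyperparameters plus the artifact's own decisions
    (the dual-label threshold ``theta`` and training policy)."""

    knn_k: int = 12
    rf_estimators: int = 100
    xgb_rounds: int = 50
    xgb_max_depth: int = 5
    xgb_eta: float = 0.1
    n_classes: int = 11
    theta: float = 0.30
    train_policy: str = "duplicate"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.theta <= 1:
            raise ValueError("theta must be in (0, 1]")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if self.n_classes != len(COMPARTMENTS):
            raise ValueError("n_classes must equal the 11-compartment universe")
        if self.train_policy not in ("duplicate", "pair-class"):
            raise ValueError(f"unknown train policy {self.train_policy!r}")


def normalize_label_sets(y) -> list[frozenset]:
    """Coerce labels (strings, iterables of strings) to frozensets of codes."""
    out = []
    for item in y:
        labels = frozenset([item]) if isinstance(item, str) else frozenset(item)
        if not labels:
            raise ValueError("every training record needs at least one label")
        if len(labels) > 2:
            raise ValueError(f"label set {sorted(labels)} has more than 2 labels")
        unknown = labels - set(COMPARTMENTS)
        if unknown:
            raise ValueError(f"labels outside the compartment universe: {sorted(unknown)}")
        out.append(labels)
    return out


def average_vote(*prob_vectors) -> np.ndarray:
    """Unweighted componentwise mean of class-probability vectors."""
    arrays = [np.asarray(p, dtype=float) for p in prob_vectors]
    if len({a.shape for a in arrays}) != 1:
        raise ValueError("probability vectors must share one shape")
    for a in arrays:
        if (a < -1e-12).any():
            raise ValueError("probabilities must be non-negative")
        sums = a.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("each probability vector must sum to 1")
    return np.mean(arrays, axis=0)


def decide_labels(consensus: np.ndarray, theta: float = 0.30) -> frozenset:
    """Label-set rule: top class always; runner-up added iff p2 >= theta.

    Rank-2 ties break by canonical compartment order.
    """
    consensus = np.asarray(consensus, dtype=float)
    order = np.lexsort((np.arange(len(consensus)), -consensus))
    labels = {COMPARTMENTS[order[0]]}
    if len(consensus) > 1 and consensus[order[1]] >= theta:
        labels.add(COMPARTMENTS[order[1]])
    return frozenset(labels)


@dataclass
class PredictionResult:
    """Consensus prediction for one protein."""

    id: str
    probabilities: np.ndarray  # 11 consensus probabilities, sum to 1
    labels: frozenset
    base_probabilities: dict
    go_evidence: dict | None = None

    def as_row(self) -> dict:
        ordered = sorted(self.labels, key=COMPARTMENTS.index)
        row = {
            "id": self.id,
            "label1": ordered[0],
            "label2": ordered[1] if len(ordered) > 1 else "NA",
        }
        row.update({f"p_{c}": float(p) for c, p in zip(COMPARTMENTS, self.probabilities)})
        if self.go_evidence:
            row.update({f"go_{k}": v for k, v in self.go_evidence.items()})
        return row


class LocalizationEnsemble(ClassifierMixin, BaseEstimator):
    """KNN + RF + XGB average-voting classifier with a dual-label decision rule.

    ``fit`` accepts label sets (strings or 1-2 element iterables). Consensus
    probabilities always span the fixed 11-compartment order in
    :data:`~plantloc.seqio.COMPARTMENTS`; compartments absent from training
    receive probability 0 (set ``require_all_classes=True`` to make absence
    an error instead).
    """

    BASE_NAMES = ("knn", "rf", "xgb")

    def __init__(self, knn_k: int = 12, rf_estimators: int = 100,
                 xgb_rounds: int = 50, xgb_max_depth: int = 5,
                 xgb_eta: float = 0.1, theta: float = 0.30,
                 train_policy: str = "duplicate", seed: int = 0,
                 require_all_classes: bool = False):
        self.knn_k = knn_k
        self.rf_estimators = rf_estimators
        self.xgb_rounds = xgb_rounds
        self.xgb_max_depth = xgb_max_depth
        self.xgb_eta = xgb_eta
        self.theta = theta
        self.train_policy = train_policy
        self.seed = seed
        self.require_all_classes = require_all_classes

    @property
    def config(self) -> EnsembleConfig:
        return EnsembleConfig(
            self.knn_k, self.rf_estimators, self.xgb_rounds, self.xgb_max_depth,
            self.xgb_eta, len(COMPARTMENTS), self.theta, self.train_policy, self.seed,
        )

    # -- training -----------------------------------------------------------

    def _expand_training(self, X: np.ndarray, label_sets: list[frozenset]):
        rows, targets = [], []
        for i, labels in enumerate(label_sets):
            if self.train_policy == "duplicate":
                for lab in sorted(labels, key=COMPARTMENTS.index):
                    rows.append(i)
                    targets.append(lab)
            else:  # pair-class
                key = "+".join(sorted(labels, key=COMPARTMENTS.index))
                rows.append(i)
                targets.append(key)
        return X[rows], np.array(targets, dtype=object)

    def fit(self, X, y):
        self.config  # validate hyperparameters
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            V = X.to_numpy(dtype=float)
        else:
            V = np.asarray(X, dtype=float)
            self.feature_names_in_ = None
        if not np.all(np.isfinite(V)):
            raise ValueError("features must be finite")
        label_sets = normalize_label_sets(y)
        counts: dict[str, int] = {}
        for s in label_sets:
            for lab in s:
                counts[lab] = counts.get(lab, 0) + 1
        rare = sorted(lab for lab, c in counts.items() if c < 2)
        if rare:
            raise ValueError(f"every class needs >= 2 training records; rare: {rare}")
        seen = set(counts)
        if self.require_all_classes and seen != set(COMPARTMENTS):
            missing = sorted(set(COMPARTMENTS) - seen)
            raise ValueError(f"classes absent from training data: {missing}")

        Xt, targets = self._expand_training(V, label_sets)
        self.train_classes_ = np.unique(targets)
        codes = np.searchsorted(self.train_classes_, targets)
        self.classes_ = np.asarray(COMPARTMENTS, dtype=object)

        self.base_models_ = {
            "knn": make_pipeline(
                StandardScaler(),
                KNeighborsClassifier(n_neighbors=min(self.knn_k, len(Xt)), weights="distance"),
            ),
            "rf": RandomForestClassifier(
                n_estimators=self.rf_estimators, random_state=self.seed, n_jobs=1
            ),
            "xgb": XGBClassifier(
                n_estimators=self.xgb_rounds,
                max_depth=self.xgb_max_depth,
                learning_rate=self.xgb_eta,
                objective="multi:softprob",
                eval_metric="mlogloss",
                num_class=len(self.train_classes_),
                random_state=self.seed,
                n_jobs=1,
                verbosity=0,
            ),
        }
        for model in self.base_models_.values():
            model.fit(Xt, codes)
        self.n_features_in_ = V.shape[1]
        return self

    # -- prediction ---------------------------------------------------------

    def _validate_X(self, X) -> np.ndarray:
        check_is_fitted(self, "base_models_")
        if isinstance(X, pd.DataFrame):
            if self.feature_names_in_ is not None:
                missing = [c for c in self.feature_names_in_ if c not in X.columns]
                if missing:
                    raise ValueError(f"missing features at predict time: {missing[:5]}")
                X = X.loc[:, list(self.feature_names_in_)]
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return X

    def _spread_to_universe(self, probs: np.ndarray) -> np.ndarray:
        """Map train-class probabilities onto the fixed 11-compartment order."""
        out = np.zeros((probs.shape[0], len(COMPARTMENTS)))
        for j, cls in enumerate(self.train_classes_):
            parts = cls.split("+")
            for part in parts:
                out[:, COMPARTMENTS.index(part)] += probs[:, j] / len(parts)
        return out

    def base_probabilities(self, X) -> dict[str, np.ndarray]:
        """Per-base-model (n, 11) probability matrices in compartment order."""
        V = self._validate_X(X)
        return {
            name: self._spread_to_universe(model.predict_proba(V))
            for name, model in self.base_models_.items()
        }

    def predict_proba(self, X) -> np.ndarray:
        probs = self.base_probabilities(X)
        return average_vote(*(probs[name] for name in self.BASE_NAMES))

    def predict(self, X) -> np.ndarray:
        """Top-consensus compartment per record."""
        consensus = self.predict_proba(X)
        order = np.argmax(consensus, axis=1)
        return self.classes_[order]

    def predict_label_sets(self, X) -> list[frozenset]:
        """Single- or dual-compartment call per record (threshold rule)."""
        return [decide_labels(row, self.theta) for row in self.predict_proba(X)]

    def predict_records(self, X, ids=None, go_evidence=None) -> list[PredictionResult]:
        base = self.base_probabilities(X)
        consensus = average_vote(*(base[name] for name in self.BASE_NAMES))
        if ids is None:
            ids = list(X.index) if isinstance(X, pd.DataFrame) else [str(i) for i in range(len(consensus))]
        results = []
        for i, rid in enumerate(ids):
            results.append(
                PredictionResult(
                    id=rid,
                    probabilities=consensus[i],
                    labels=decide_labels(consensus[i], self.theta),
                    base_probabilities={n: base[n][i] for n in self.BASE_NAMES},
                    go_evidence=(go_evidence or {}).get(rid),
                )
            )
        return results

    # -- persistence --------------------------------------------------------

    def save(self, directory) -> None:
        """Persist as a directory: config JSON + base models + feature list."""
        check_is_fitted(self, "base_models_")
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        meta = {
            "config": asdict(self.config),
            "train_classes": self.train_classes_.tolist(),
            "feature_names": None
            if self.feature_names_in_ is None
            else list(self.feature_names_in_),
            "n_features_in": int(self.n_features_in_),
            "class_order": list(COMPARTMENTS),
        }
        (d / "model.json").write_text(json.dumps(meta, indent=1))
        joblib.dump(self.base_models_, d / "base_models.joblib")

    @classmethod
    def load(cls, directory) -> "LocalizationEnsemble":
        d = Path(directory)
        meta = json.loads((d / "model.json").read_text())
        cfg = meta["config"]
        est = cls(
            knn_k=cfg["knn_k"], rf_estimators=cfg["rf_estimators"],
            xgb_rounds=cfg["xgb_rounds"], xgb_max_depth=cfg["xgb_max_depth"],
            xgb_eta=cfg["xgb_eta"], theta=cfg["theta"],
            train_policy=cfg["train_policy"], seed=cfg["seed"],
        )
        est.base_models_ = joblib.load(d / "base_models.joblib")
        est.train_classes_ = np.asarray(meta["train_classes"], dtype=object)
        est.classes_ = np.asarray(meta["class_order"], dtype=object)
        est.feature_names_in_ = (
            None if meta["feature_names"] is None
            else np.asarray(meta["feature_names"], dtype=object)
        )
        est.n_features_in_ = meta["n_features_in"]
        return est


def train(X, y, config: EnsembleConfig = EnsembleConfig()) -> LocalizationEnsemble:
    """Functional wrapper: fit a LocalizationEnsemble from a config record."""
    est = LocalizationEnsemble(
        knn_k=config.knn_k, rf_estimators=config.rf_estimators,
        xgb_rounds=config.xgb_rounds, xgb_max_depth=config.xgb_max_depth,
        xgb_eta=config.xgb_eta, theta=config.theta,
        train_policy=config.train_policy, seed=config.seed,
    )
    return est.fit(X, y)
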