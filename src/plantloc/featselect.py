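"""Feature selection: ReliefF, OneR ranking, and CFS with genetic search.

All three procedures operate on a labeled numeric feature table and are
deterministic given their seed. They are exposed both as scikit-learn
selector estimators (:class:`ReliefFSelector`, :class:`OneRSelector`,
:class:`CFSGeneticSelector`) and as thin functions returning a serializable
:class:`SelectionResult`.

Discretization for OneR and for the symmetric-uncertainty correlations
behind CFS uses equal-frequency binning (10 bins by default, degrading to
distinct-value bins for low-cardinality features).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted


@dataclass
class SelectionResult:
    """Outcome of one selection method: per-feature weights + chosen subset."""

    method: str
    weights: dict[str, float]
    selected: list[str]
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("selected feature list contains duplicates")
        unknown = set(self.selected) - set(self.weights)
        if unknown:
            raise ValueError(f"selected features missing from weights: {sorted(unknown)}")

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": self.method,
                "params": self.params,
                "weights": self.weights,
                "selected": self.selected,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "SelectionResult":
        d = json.loads(text)
        return cls(d["method"], d["weights"], d["selected"], d["params"])


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])


def select_top(result: SelectionResult, n: int) -> SelectionResult:
    """Truncate a ranking result to its top-n features.

    Ties are broken by original schema (weights-dict) order; n larger than
    the available count degrades to all features with a warning.
    """
    if n <= 0:
        raise ValueError("n must be >= 1")
    names = list(result.weights)
    if n > len(names):
        warnings.warn(f"requested top {n} of {len(names)} features; keeping all")
        n = len(names)
    # descending weight, ties broken by original schema order
    order = sorted(range(len(names)), key=lambda i: (-result.weights[names[i]], i))
    chosen = [names[i] for i in order[:n]]
    return SelectionResult(result.method, result.weights, chosen, dict(result.params, top_n=n))


# ---------------------------------------------------------------------------
# Discretization and symmetric uncertainty
# ---------------------------------------------------------------------------


def equal_frequency_bins(x: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Equal-frequency bin codes; distinct-value codes when cardinality < bins."""
    x = np.asarray(x, dtype=float)
    uniq = np.unique(x)
    if len(uniq) <= n_bins:
        return np.searchsorted(uniq, x)
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="right")


def _entropy(codes: np.ndarray) -> float:
    p = np.bincount(codes) / len(codes)
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def symmetric_uncertainty(x_codes: np.ndarray, y_codes: np.ndarray) -> float:
    """SU(X, Y) = 2 I(X;Y) / (H(X) + H(Y)); 0 when either is constant."""
    hx, hy = _entropy(x_codes), _entropy(y_codes)
    if hx == 0 or hy == 0:
        return 0.0
    joint = x_codes.astype(np.int64) * (y_codes.max() + 1) + y_codes
    hxy = _entropy(np.unique(joint, return_inverse=True)[1])
    mi = hx + hy - hxy
    return 2.0 * mi / (hx + hy)


def cfs_merit_from_correlations(rcf: np.ndarray, rff: np.ndarray, subset) -> float:
    """Merit = k r_cf / sqrt(k + k (k-1) r_ff) for a subset of feature indices."""
    subset = list(subset)
    k = len(subset)
    if k == 0:
        return 0.0
    mean_rcf = float(np.mean(rcf[subset]))
    if k == 1:
        return mean_rcf
    sub = rff[np.ix_(subset, subset)]
    mean_rff = (sub.sum() - np.trace(sub)) / (k * (k - 1))
    return k * mean_rcf / np.sqrt(k + k * (k - 1) * mean_rff)


class _CFSCorrelations:
    """Cached SU correlations (feature-class and feature-feature)."""

    def __init__(self, X: pd.DataFrame, y, n_bins: int = 10):
        self.codes = [
            equal_frequency_bins(X.iloc[:, j].to_numpy(), n_bins)
            for j in range(X.shape[1])
        ]
        self.y_codes = np.unique(np.asarray(y), return_inverse=True)[1]
        self.rcf = np.array(
            [symmetric_uncertainty(c, self.y_codes) for c in self.codes]
        )
        p = X.shape[1]
        self._rff = np.full((p, p), np.nan)
        np.fill_diagonal(self._rff, 1.0)

    @property
    def rff(self) -> np.ndarray:
        p = len(self.codes)
        for a in range(p):
            for b in range(a + 1, p):
                if np.isnan(self._rff[a, b]):
                    su = symmetric_uncertainty(self.codes[a], self.codes[b])
                    self._rff[a, b] = self._rff[b, a] = su
        return self._rff

    def merit(self, subset) -> float:
        return cfs_merit_from_correlations(self.rcf, self.rff, subset)


def cfs_merit(subset, X, y, n_bins: int = 10) -> float:
    """CFS merit of a named or indexed feature subset of a labeled table."""
    X = _as_frame(X)
    if len(subset) == 0:
        raise ValueError("subset must be non-empty")
    idx = [X.columns.get_loc(s) if isinstance(s, str) else int(s) for s in subset]
    return _CFSCorrelations(X, y, n_bins).merit(idx)


# ---------------------------------------------------------------------------
# ReliefF
# ---------------------------------------------------------------------------


class ReliefFSelector(SelectorMixin, BaseEstimator):
    """Multiclass ReliefF feature weighting.

    Weights average the near-hit / near-miss margin over sampled instances,
    with misses from each other class weighted by its prior relative to the
    instance's class complement; feature differences use values min-max
    scaled to [0, 1], so weights lie in [-1, 1] and a constant feature
    scores exactly 0.
    """

    def __init__(self, n_features: int = 95, k_neighbors: int = 10,
                 n_samples: int | None = None, seed: int = 0):
        self.n_features = n_features
        self.k_neighbors = k_neighbors
        self.n_samples = n_samples
        self.seed = seed

    def fit(self, X, y):
        X = _as_frame(X)
        y = np.asarray(y)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        classes, y_idx = np.unique(y, return_inverse=True)
        if len(classes) < 2:
            raise ValueError("ReliefF requires at least 2 classes")
        V = X.to_numpy(dtype=float)
        lo, hi = V.min(axis=0), V.max(axis=0)
        rng = hi - lo
        rng[rng == 0] = 1.0  # constant features contribute zero diff
        V = (V - lo) / rng
        n, p = V.shape
        priors = np.bincount(y_idx) / n
        rng_gen = np.random.default_rng(self.seed)
        m = n if self.n_samples is None else min(self.n_samples, n)
        sample = rng_gen.choice(n, size=m, replace=False) if m < n else np.arange(n)
        dist = cdist(V[sample], V, metric="cityblock")
        W = np.zeros(p)
        for row, i in enumerate(sample):
            d = dist[row]
            d[i] = np.inf
            ci = y_idx[i]
            for c in range(len(classes)):
                members = np.flatnonzero(y_idx == c)
                members = members[members != i]
                if len(members) == 0:
                    continue
                k = min(self.k_neighbors, len(members))
                if k < self.k_neighbors:
                    warnings.warn(
                        f"class {classes[c]!r}: only {len(members)} neighbors "
                        f"available; k reduced to {k}"
                    )
                nearest = members[np.argsort(d[members], kind="stable")[:k]]
                diff = np.abs(V[i] - V[nearest]).mean(axis=0)
                if c == ci:
                    W -= diff / m
                else:
                    W += (priors[c] / (1.0 - priors[ci])) * diff / m
        self.scores_ = W
        self.classes_ = classes
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "scores_")
        order = np.argsort(-self.scores_, kind="stable")
        mask = np.zeros(len(self.scores_), dtype=bool)
        mask[order[: min(self.n_features, len(order))]] = True
        return mask

    def result(self) -> SelectionResult:
        check_is_fitted(self, "scores_")
        weights = dict(zip(self.feature_names_in_, map(float, self.scores_)))
        order = sorted(
            range(len(weights)), key=lambda i: (-self.scores_[i], i)
        )[: min(self.n_features, len(weights))]
        return SelectionResult(
            "relieff",
            weights,
            [self.feature_names_in_[i] for i in order],
            {"k_neighbors": self.k_neighbors, "n_samples": self.n_samples,
             "seed": self.seed, "top_n": self.n_features},
        )


# ---------------------------------------------------------------------------
# OneR
# ---------------------------------------------------------------------------


class OneRSelector(SelectorMixin, BaseEstimator):
    """One-rule feature ranking: per-feature training accuracy of the rule
    'predict the majority class of the feature's (equal-frequency) bin'."""

    def __init__(self, n_features: int = 95, n_bins: int = 10):
        self.n_features = n_features
        self.n_bins = n_bins

    def fit(self, X, y):
        X = _as_frame(X)
        y_codes = np.unique(np.asarray(y), return_inverse=True)[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        n = len(y_codes)
        scores = np.empty(X.shape[1])
        for j in range(X.shape[1]):
            codes = equal_frequency_bins(X.iloc[:, j].to_numpy(), self.n_bins)
            correct = 0
            for b in np.unique(codes):
                counts = np.bincount(y_codes[codes == b])
                correct += counts.max()
            scores[j] = correct / n
        self.scores_ = scores
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "scores_")
        order = np.argsort(-self.scores_, kind="stable")
        mask = np.zeros(len(self.scores_), dtype=bool)
        mask[order[: min(self.n_features, len(order))]] = True
        return mask

    def result(self) -> SelectionResult:
        check_is_fitted(self, "scores_")
        weights = dict(zip(self.feature_names_in_, map(float, self.scores_)))
        order = sorted(
            range(len(weights)), key=lambda i: (-self.scores_[i], i)
        )[: min(self.n_features, len(weights))]
        return SelectionResult(
            "oner",
            weights,
            [self.feature_names_in_[i] for i in order],
            {"n_bins": self.n_bins, "top_n": self.n_features},
        )


# ---------------------------------------------------------------------------
# CFS + genetic search
# ---------------------------------------------------------------------------


class CFSGeneticSelector(SelectorMixin, BaseEstimator):
    """CFS merit maximized by a bitmask genetic algorithm.

    Tournament selection (size 3), uniform crossover, per-bit flip mutation,
    elitism of one; fully reproducible from ``seed``. With elitism the best
    merit is non-decreasing across generations.
    """

    def __init__(self, pop_size: int = 50, generations: int = 100,
                 crossover_p: float = 0.6, mutation_p: float = 0.02,
                 n_bins: int = 10, seed: int = 0):
        self.pop_size = pop_size
        self.generations = generations
        self.crossover_p = crossover_p
        self.mutation_p = mutation_p
        self.n_bins = n_bins
        self.seed = seed

    def fit(self, X, y):
        X = _as_frame(X)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        corr = _CFSCorrelations(X, np.asarray(y), self.n_bins)
        rng = np.random.default_rng(self.seed)
        p = X.shape[1]
        pop = rng.random((self.pop_size, p)) < 0.5
        pop[~pop.any(axis=1), rng.integers(0, p)] = True  # no empty genomes
        fitness = np.array([corr.merit(np.flatnonzero(g)) for g in pop])
        self.merit_history_ = [float(fitness.max())]
        for _ in range(self.generations):
            elite = pop[int(np.argmax(fitness))].copy()
            children = [elite]
            while len(children) < self.pop_size:
                parents = []
                for _ in range(2):
                    contenders = rng.integers(0, self.pop_size, size=3)
                    parents.append(pop[contenders[np.argmax(fitness[contenders])]])
                a, b = parents[0].copy(), parents[1].copy()
                if rng.random() < self.crossover_p:
                    swap = rng.random(p) < 0.5
                    a[swap], b[swap] = parents[1][swap], parents[0][swap]
                for child in (a, b):
                    flip = rng.random(p) < self.mutation_p
                    child ^= flip
                    if not child.any():
                        child[rng.integers(0, p)] = True
                    if len(children) < self.pop_size:
                        children.append(child)
            pop = np.array(children)
            fitness = np.array([corr.merit(np.flatnonzero(g)) for g in pop])
            self.merit_history_.append(float(fitness.max()))
        best = int(np.argmax(fitness))
        self.support_mask_ = pop[best]
        self.merit_ = float(fitness[best])
        self.rcf_ = corr.rcf
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_mask_")
        return self.support_mask_

    def result(self) -> SelectionResult:
        check_is_fitted(self, "support_mask_")
        weights = {
            str(name): float(self.support_mask_[i])
            for i, name in enumerate(self.feature_names_in_)
        }
        selected = [
            str(n) for n, m in zip(self.feature_names_in_, self.support_mask_) if m
        ]
        return SelectionResult(
            "cfs_ga",
            weights,
            selected,
            {
                "pop_size": self.pop_size,
                "generations": self.generations,
                "crossover_p": self.crossover_p,
                "mutation_p": self.mutation_p,
                "seed": self.seed,
                "merit": self.merit_,
            },
        )


# ---------------------------------------------------------------------------
# Thin functional wrappers
# ---------------------------------------------------------------------------


def relieff(X, y, k_neighbors: int = 10, n_samples: int | None = None,
            seed: int = 0, top_n: int = 95) -> SelectionResult:
    sel = ReliefFSelector(top_n, k_neighbors, n_samples, seed).fit(X, y)
    return sel.result()


def oner_rank(X, y, n_bins: int = 10, top_n: int = 95) -> SelectionResult:
    return OneRSelector(top_n, n_bins).fit(X, y).result()


def cfs_ga_search(X, y, pop_size: int = 50, generations: int = 100,
                  crossover_p: float = 0.6, mutation_p: float = 0.02,
                  seed: int = 0) -> SelectionResult:
    sel = CFSGeneticSelector(pop_size, generations, crossover_p, mutation_p, seed=seed)
    return sel.fit(X, y).result()


METHODS = {"relieff": relieff, "oner": oner_rank, "cfs_ga": cfs_ga_search}
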