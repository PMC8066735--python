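"""Evaluation: confusion-matrix metrics, ROC/AUC, cross-validation, and the
one-vs-rest Pearson feature analysis.

Conventions (documented in docs/methods.md):

* A record is *correct* iff its predicted label set equals its true label
  set exactly — a dual-location protein must have both compartments called.
* One-vs-rest tallies count a dual-label record as a positive of each of its
  true compartments.
* MCC returns 0 when any factor of its denominator is 0.
* Per-class AUC is the midrank (Mann-Whitney) statistic over one-vs-rest
  consensus scores; the macro average is reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .ensemble import LocalizationEnsemble, decide_labels, normalize_label_sets
from .seqio import COMPARTMENTS


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion counts for a single class."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def binary_metrics(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """(ACC, Sn, Sp, MCC) from one-vs-rest confusion counts.

    ACC = (TP+TN)/total; Sn = TP/(TP+FN); Sp = TN/(TN+FP);
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), 0 when any
    denominator factor vanishes. Sn/Sp are NaN when their denominator is 0.
    """
    if c.total == 0:
        raise ValueError("empty confusion counts")
    acc = (c.TP + c.TN) / c.total
    sn = c.TP / (c.TP + c.FN) if (c.TP + c.FN) else float("nan")
    sp = c.TN / (c.TN + c.FP) if (c.TN + c.FP) else float("nan")
    denom = (
        (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    mcc = (c.TP * c.TN - c.FP * c.FN) / np.sqrt(denom) if denom else 0.0
    return acc, sn, sp, float(mcc)


def roc_auc(truth: np.ndarray, scores: np.ndarray) -> float:
    """One-vs-rest AUC (midrank ties); NaN when only one class is present."""
    truth = np.asarray(truth, dtype=int)
    if len(np.unique(truth)) < 2:
        return float("nan")
    return float(roc_auc_score(truth, np.asarray(scores, dtype=float)))


@dataclass
class MetricsReport:
    """Per-class and aggregate performance of a set of label-set predictions."""

    per_class: pd.DataFrame  # index: compartment; TP TN FP FN ACC Sn Sp MCC [AUC]
    rows: pd.DataFrame  # report layout: one row per truth label-set + subtotals
    overall_acc: float
    single_acc: float
    multi_acc: float
    n_total: int
    n_single: int
    n_multi: int
    auc_macro: float = float("nan")
    base_accuracies: dict = field(default_factory=dict)
    fold_accuracies: list = field(default_factory=list)

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _set_key(labels: frozenset) -> str:
    return "+".join(sorted(labels, key=COMPARTMENTS.index))


def multiclass_report(truth, predicted, scores=None) -> MetricsReport:
    """Score predicted label sets against truth over the 11-class universe.

    ``scores`` (optional): (n, 11) consensus probabilities for per-class AUC.
    """
    truth = normalize_label_sets(truth)
    predicted = normalize_label_sets(predicted)
    if len(truth) != len(predicted):
        raise ValueError("truth and prediction lists must align")
    n = len(truth)
    correct = np.array([t == p for t, p in zip(truth, predicted)])
    is_multi = np.array([len(t) > 1 for t in truth])

    per_class = {}
    for ci, comp in enumerate(COMPARTMENTS):
        pos = np.array([comp in t for t in truth])
        pred_pos = np.array([comp in p for p in predicted])
        c = ConfusionCounts(
            TP=int((pos & pred_pos).sum()),
            TN=int((~pos & ~pred_pos).sum()),
            FP=int((~pos & pred_pos).sum()),
            FN=int((pos & ~pred_pos).sum()),
        )
        acc, sn, sp, mcc = binary_metrics(c)
        row = {"TP": c.TP, "TN": c.TN, "FP": c.FP, "FN": c.FN,
               "ACC": acc, "Sn": sn, "Sp": sp, "MCC": mcc}
        if scores is not None:
            row["AUC"] = roc_auc(pos, np.asarray(scores)[:, ci])
        per_class[comp] = row
    per_class = pd.DataFrame.from_dict(per_class, orient="index")
    auc_macro = float(np.nanmean(per_class["AUC"])) if "AUC" in per_class else float("nan")

    # report rows keyed by exact truth label-set (singles first, then pairs)
    keys = sorted(
        {_set_key(t) for t in truth},
        key=lambda k: (k.count("+"), [COMPARTMENTS.index(p) for p in k.split("+")]),
    )
    rows = []
    for key in keys:
        members = np.array([_set_key(t) == key for t in truth])
        n_k = int(members.sum())
        n_correct = int((members & correct).sum())
        # record-level MCC of the exact-set indicator
        pred_match = np.array([_set_key(p) == key for p in predicted])
        c = ConfusionCounts(
            TP=int((members & pred_match).sum()),
            TN=int((~members & ~pred_match).sum()),
            FP=int((~members & pred_match).sum()),
            FN=int((members & ~pred_match).sum()),
        )
        _, _, _, mcc = binary_metrics(c)
        rows.append(
            {"type": "multi" if "+" in key else "single", "location": key,
             "n": n_k, "correct": n_correct,
             "percent": 100.0 * n_correct / n_k, "MCC": mcc}
        )
    n_single = int((~is_multi).sum())
    n_multi = int(is_multi.sum())
    single_acc = float(correct[~is_multi].mean()) if n_single else float("nan")
    multi_acc = float(correct[is_multi].mean()) if n_multi else float("nan")
    overall = float(correct.mean())
    for label, nn, cc in (
        ("Total (single)", n_single, int(correct[~is_multi].sum())),
        ("Total (multi)", n_multi, int(correct[is_multi].sum())),
        ("Total all", n, int(correct.sum())),
    ):
        if nn:
            rows.append({"type": "subtotal", "location": label, "n": nn,
                         "correct": cc, "percent": 100.0 * cc / nn,
                         "MCC": float("nan")})
    return MetricsReport(
        per_class=per_class,
        rows=pd.DataFrame(rows),
        overall_acc=overall,
        single_acc=single_acc,
        multi_acc=multi_acc,
        n_total=n,
        n_single=n_single,
        n_multi=n_multi,
        auc_macro=auc_macro,
    )


def combined_accuracy(n_single: int, correct_single: int,
                      n_multi: int, correct_multi: int) -> float:
    """Pooled accuracy from the single- and multi-label subtotal counts."""
    total = n_single + n_multi
    if total == 0:
        raise ValueError("no records")
    return (correct_single + correct_multi) / total


def cross_validate(
    X: pd.DataFrame,
    y,
    estimator: LocalizationEnsemble | None = None,
    folds: int = 10,
    seed: int = 0,
    selector=None,
) -> MetricsReport:
    """Stratified k-fold CV of the voting ensemble on a labeled feature table.

    Stratification is on the exact label set (pairs form their own strata;
    strata smaller than ``folds`` degrade with a warning). When a selector
    estimator is given it is fitted inside each training fold only and
    applied to both partitions, so held-out rows never influence selection.

    Pooled out-of-fold label-set predictions are scored by
    :func:`multiclass_report`; per-base-model accuracies (same decision rule
    applied to each base model's probabilities) are attached for comparison
    against the consensus.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y_sets = normalize_label_sets(y)
    strata = np.array([_set_key(s) for s in y_sets])
    n = len(y_sets)
    counts = np.bincount(np.unique(strata, return_inverse=True)[1])
    if (counts < folds).all():
        # stratification impossible (e.g. leave-one-out): degrade gracefully
        warnings.warn(
            f"every stratum has fewer than {folds} members; "
            "falling back to unstratified folds"
        )
        skf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    else:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    consensus = np.zeros((n, len(COMPARTMENTS)))
    base_probs = {name: np.zeros((n, len(COMPARTMENTS))) for name in
                  LocalizationEnsemble.BASE_NAMES}
    estimator = estimator or LocalizationEnsemble(seed=seed)
    theta = estimator.theta
    fold_acc = []
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*least populated class.*")
        splits = list(skf.split(np.zeros(n), strata))
    for train_idx, test_idx in splits:
        X_tr, X_te = X.iloc[train_idx], X.iloc[test_idx]
        y_tr = [y_sets[i] for i in train_idx]
        if selector is not None:
            from sklearn.base import clone

            sel = clone(selector).fit(X_tr, strata[train_idx])
            mask = sel.get_support()
            X_tr, X_te = X_tr.loc[:, mask], X_te.loc[:, mask]
        from sklearn.base import clone

        model = clone(estimator).fit(X_tr, y_tr)
        fold_base = model.base_probabilities(X_te)
        for name in base_probs:
            base_probs[name][test_idx] = fold_base[name]
        consensus[test_idx] = model.predict_proba(X_te)
        fold_pred = [decide_labels(p, theta) for p in consensus[test_idx]]
        fold_acc.append(
            float(np.mean([y_sets[i] == p for i, p in zip(test_idx, fold_pred)]))
        )
    predicted = [decide_labels(p, theta) for p in consensus]
    report = multiclass_report(y_sets, predicted, scores=consensus)
    report.fold_accuracies = fold_acc
    for name, probs in base_probs.items():
        base_pred = [decide_labels(p, theta) for p in probs]
        report.base_accuracies[name] = float(
            np.mean([t == p for t, p in zip(y_sets, base_pred)])
        )
    return report


def pcc_feature_analysis(
    X: pd.DataFrame, y, target_class: str, top_n: int = 20
) -> pd.DataFrame:
    """One-vs-rest Pearson correlation of every feature with a compartment.

    Returns the top_n features by |PCC| as a DataFrame (feature, pcc).
    Zero-variance features get PCC 0 with a warning.
    """
    if target_class not in COMPARTMENTS:
        raise ValueError(f"unknown compartment {target_class!r}")
    y_sets = normalize_label_sets(y)
    indicator = np.array([target_class in s for s in y_sets], dtype=float)
    if indicator.std() == 0:
        raise ValueError(f"compartment {target_class!r} absent (or universal)")
    V = X.to_numpy(dtype=float)
    sd = V.std(axis=0)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance features given PCC 0")
    centered = V - V.mean(axis=0)
    ind_c = indicator - indicator.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        pcc = (centered * ind_c[:, None]).mean(axis=0) / (sd * indicator.std())
    pcc[zero] = 0.0
    out = pd.DataFrame({"feature": X.columns, "pcc": pcc})
    out = out.reindex(out["pcc"].abs().sort_values(ascending=False).index)
    return out.head(top_n).reset_index(drop=True)
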