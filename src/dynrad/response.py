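"""Leave-one-out evaluation of best-response classifiers.

Each patient is scored by a model trained on the other ``n - 1``
patients; the pooled held-out scores give a single ROC/AUC per
(feature set, classifier) cell.  With ``onepass_selection=False`` (default)
the t-test + LASSO selection is refit inside every training fold, which
is the leakage-free protocol; ``onepass_selection=True`` selects once on the
full data before cross-validation and is optimistically biased.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from dynrad.dynamic_features import build_dynamic_matrix
from dynrad.selection import SelectionConfig, select_features

__all__ = [
    "ClassifierKind",
    "FeatureSetKind",
    "EvalResult",
    "roc_auc",
    "loocv_evaluate",
    "build_feature_sets",
    "compare_feature_sets",
    "TABLE_ROW_ORDER",
]

log = logging.getLogger("dynrad")

#: row order used for the published-style comparison grids
TABLE_ROW_ORDER = ("RACR", "RCR", "SD", "DC", "P", "AP", "DP", "PP", "PVP", "Multi_static")


class ClassifierKind(str, Enum):
    LDA = "LDA"
    SVM = "SVM"
    RF = "RF"


class FeatureSetKind(str, Enum):
    PP = "PP"
    AP = "AP"
    PVP = "PVP"
    DP = "DP"
    MULTI_STATIC = "Multi_static"
    SD = "SD"
    DC = "DC"
    RCR = "RCR"
    RACR = "RACR"
    P = "P"


@dataclass
class EvalResult:
    """Pooled LOOCV evaluation of one (feature set, classifier) cell."""

    scores: pd.Series  # one held-out score per patient
    predicted: pd.Series
    labels: pd.Series
    auc: float
    accuracy: float
    fold_kept: list[list[str]] = field(default_factory=list)


def roc_auc(scores, labels) -> float:
    """AUC in Mann-Whitney form: P(score_pos > score_neg) + 0.5 P(tie)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    r = rankdata(s)
    u = r[y].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _make_classifier(kind: ClassifierKind, seed: int, rf_trees: int = 500):
    if kind is ClassifierKind.LDA:
        # lsqr + automatic shrinkage keeps the pooled covariance invertible
        # in the p > n regime typical after selection fallback
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    if kind is ClassifierKind.SVM:
        return SVC(kernel="linear", C=1.0)
    return RandomForestClassifier(
        n_estimators=rf_trees, max_features="sqrt", random_state=seed, n_jobs=1
    )


def _score_one(model, kind: ClassifierKind, x: np.ndarray) -> tuple[float, int]:
    """Held-out score and hard prediction for a single patient."""
    x = x.reshape(1, -1)
    if kind is ClassifierKind.SVM:
        s = float(model.decision_function(x)[0])
        return s, int(s > 0)
    p = float(model.predict_proba(x)[0, 1])
    return p, int(p > 0.5)


def loocv_evaluate(
    matrix: pd.DataFrame,
    labels,
    classifier: ClassifierKind | str = ClassifierKind.LDA,
    selection: SelectionConfig | None = None,
    seed: int = 0,
    rf_trees: int = 500,
    select: bool = True,
) -> EvalResult:
    """Leave-one-out evaluation with (optionally nested) selection.

    Parameters
    ----------
    matrix : DataFrame (patients x features)
    labels : binary vector (1 = objective response)
    selection : SelectionConfig
        ``selection.onepass_selection=True`` runs the t-test + LASSO screen once
        on the full data; otherwise it is refit in every training fold.
    select : bool
        Disable to use all columns as-is.
    """
    classifier = ClassifierKind(classifier)
    selection = selection or SelectionConfig(seed=seed)
    y = np.asarray(labels).astype(int)
    n = len(matrix)
    if n < 4:
        raise ValueError("need at least 4 patients for LOOCV")
    if y.sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("both classes need at least 2 members")

    kept_full: list[str] | None = None
    if select and selection.onepass_selection:
        kept_full = select_features(matrix, y, selection).kept_features

    scores = np.empty(n)
    preds = np.empty(n, dtype=int)
    fold_kept: list[list[str]] = []
    X_all = matrix.to_numpy(dtype=float)
    cols = list(matrix.columns)
    col_pos = {c: j for j, c in enumerate(cols)}
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        if not select:
            kept = cols
        elif selection.onepass_selection:
            kept = kept_full
        else:
            kept = select_features(matrix.iloc[tr], y[tr], selection).kept_features
        fold_kept.append(list(kept))
        idx = [col_pos[c] for c in kept]
        Xtr, Xte = X_all[np.ix_(tr, idx)], X_all[i, idx]
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        model = _make_classifier(classifier, seed, rf_trees)
        model.fit((Xtr - mu) / sd, y[tr])
        scores[i], preds[i] = _score_one(model, classifier, (Xte - mu) / sd)

    auc = roc_auc(scores, y)
    acc = float(np.mean(preds == y))
    index = matrix.index
    return EvalResult(
        scores=pd.Series(scores, index=index, name="score"),
        predicted=pd.Series(preds, index=index, name="predicted"),
        labels=pd.Series(y, index=index, name="label"),
        auc=auc,
        accuracy=acc,
        fold_kept=fold_kept,
    )


def build_feature_sets(
    per_phase: Mapping[str, pd.DataFrame],
    kinds: Sequence[FeatureSetKind | str],
    times: Sequence[float] | None = None,
    poly_degree: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Materialise the requested feature sets from per-phase matrices.

    Single-phase sets are the static matrices themselves; ``Multi_static``
    concatenates all phases (columns suffixed by phase); the dynamic sets
    are built through :func:`dynrad.dynamic_features.build_dynamic_matrix`.
    """
    kinds = [FeatureSetKind(k) for k in kinds]
    dynamic_needed = [k.value for k in kinds if k.value in ("SD", "DC", "RCR", "RACR", "P")]
    dyn = None
    if dynamic_needed:
        dyn = build_dynamic_matrix(per_phase, kinds=dynamic_needed, times=times, poly_degree=poly_degree)
    out: dict[str, pd.DataFrame] = {}
    for k in kinds:
        if k.value in per_phase:
            out[k.value] = per_phase[k.value]
        elif k is FeatureSetKind.MULTI_STATIC:
            parts = [m.add_suffix(f"__{ph}") for ph, m in per_phase.items()]
            out[k.value] = pd.concat(parts, axis=1)
        else:
            cols = dyn.columns_of_kind(k.value)
            out[k.value] = dyn.data[cols]
    return out


def compare_feature_sets(
    per_phase: Mapping[str, pd.DataFrame],
    labels,
    kinds: Sequence[FeatureSetKind | str] = TABLE_ROW_ORDER,
    classifiers: Sequence[ClassifierKind | str] = ("LDA", "RF", "SVM"),
    selection: SelectionConfig | None = None,
    seed: int = 0,
    rf_trees: int = 500,
    times: Sequence[float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """AUC and accuracy grids over feature sets x classifiers.

    Returns ``(auc_grid, accuracy_grid)`` with rows in the published
    comparison order and one column per classifier; logs the best cell.
    """
    classifiers = [ClassifierKind(c) for c in classifiers]
    sets = build_feature_sets(per_phase, kinds, times=times)
    rows = [FeatureSetKind(k).value for k in kinds]
    auc = pd.DataFrame(index=rows, columns=[c.value for c in classifiers], dtype=float)
    acc = pd.DataFrame(index=rows, columns=[c.value for c in classifiers], dtype=float)
    for name in rows:
        for c in classifiers:
            res = loocv_evaluate(
                sets[name], labels, c, selection=selection, seed=seed, rf_trees=rf_trees
            )
            auc.loc[name, c.value] = res.auc
            acc.loc[name, c.value] = res.accuracy
    best = auc.stack().idxmax()
    log.info("compare_feature_sets: best AUC %.3f at %s", auc.stack().max(), best)
    return auc, acc
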