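"""Model/Results facades over the response and survival workflows.

``ResponseModel`` and ``PFSModel`` follow the familiar pattern of
statistical modelling libraries: a model object is built from data,
``fit()`` runs the estimation and returns a results object carrying the
estimates, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from dynrad.response import (
    TABLE_ROW_ORDER,
    ClassifierKind,
    FeatureSetKind,
    compare_feature_sets,
)
from dynrad.selection import SelectionConfig
from dynrad.survival import RiskScoreResult, SurvivalConfig, pfs_pipeline

__all__ = ["ResponseModel", "ResponseResults", "PFSModel", "PFSResults"]


def _fmt_table(df: pd.DataFrame, title: str) -> str:
    body = df.to_string(float_format=lambda v: f"{v:.3f}")
    width = max(len(title), *(len(line) for line in body.splitlines()))
    rule = "=" * width
    return f"{rule}\n{title}\n{rule}\n{body}\n{rule}"


class ResponseModel:
    """Best-response (OR vs NOR) classification over candidate feature sets.

    Parameters
    ----------
    per_phase : mapping phase -> DataFrame
        Static feature matrix (patients x features) per acquisition phase.
    labels : array-like of {0, 1} or cohort DataFrame
        1 = objective response.  A DataFrame with a ``response`` column
        is accepted directly.
    feature_sets, classifiers : sequences
        Cells of the evaluation grid; defaults to the full published-style
        comparison (five dynamic transforms, four single-phase static
        sets and their concatenation; LDA / RF / SVM).
    selection : SelectionConfig
        t-test + LASSO screening settings, including ``onepass_selection``.
    """

    def __init__(
        self,
        per_phase: Mapping[str, pd.DataFrame],
        labels,
        feature_sets: Sequence[str] = TABLE_ROW_ORDER,
        classifiers: Sequence[str] = ("LDA", "RF", "SVM"),
        selection: SelectionConfig | None = None,
        seed: int = 0,
        rf_trees: int = 500,
        times: Sequence[float] | None = None,
    ):
        self.per_phase = dict(per_phase)
        if isinstance(labels, pd.DataFrame):
            labels = (labels["response"] == "OR").astype(int).to_numpy()
        self.labels = np.asarray(labels).astype(int)
        self.feature_sets = [FeatureSetKind(k).value for k in feature_sets]
        self.classifiers = [ClassifierKind(c).value for c in classifiers]
        self.selection = selection or SelectionConfig(seed=seed)
        self.seed = seed
        self.rf_trees = rf_trees
        self.times = times

    @classmethod
    def from_cohort(cls, cohort, **kwargs) -> "ResponseModel":
        """Build from a :class:`~dynrad.simulate.SyntheticCohort`."""
        return cls(cohort.phases, cohort.labels, **kwargs)

    def fit(self) -> "ResponseResults":
        auc, acc = compare_feature_sets(
            self.per_phase,
            self.labels,
            kinds=self.feature_sets,
            classifiers=self.classifiers,
            selection=self.selection,
            seed=self.seed,
            rf_trees=self.rf_trees,
            times=self.times,
        )
        return ResponseResults(model=self, auc=auc, accuracy=acc)


@dataclass
class ResponseResults:
    """LOOCV AUC / accuracy grids plus the winning cell."""

    model: ResponseModel
    auc: pd.DataFrame
    accuracy: pd.DataFrame

    @property
    def best_cell(self) -> tuple[str, str]:
        return self.auc.stack().idxmax()

    def summary(self) -> str:
        fs, clf = self.best_cell
        lines = [
            _fmt_table(self.auc, "Leave-one-out AUC by feature set and classifier"),
            "",
            _fmt_table(self.accuracy, "Leave-one-out accuracy by feature set and classifier"),
            "",
            f"Best cell: {fs} / {clf} "
            f"(AUC {self.auc.loc[fs, clf]:.3f}, accuracy {self.accuracy.loc[fs, clf]:.3f})",
            f"Selection: {'one-pass pre-CV' if self.model.selection.onepass_selection else 'nested (refit per fold)'}",
        ]
        return "\n".join(lines)

    def plot_auc(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        self.auc.plot.bar(ax=ax)
        ax.set_ylabel("pooled LOOCV AUC")
        ax.set_ylim(0, 1)
        return ax


class PFSModel:
    """Progression-free-survival risk scoring from dynamic features.

    Parameters
    ----------
    features : DataFrame (patients x features)
        Typically the winning dynamic feature set (RCR).
    time, event : array-like or cohort DataFrame
        PFS in days and the progression/death indicator; a DataFrame
        with ``pfs_days`` / ``event`` columns is accepted.
    config : SurvivalConfig
        Screening alpha, forest size, LOOCV switch and tdROC horizons.
    """

    def __init__(self, features: pd.DataFrame, time=None, event=None,
                 config: SurvivalConfig | None = None):
        if isinstance(time, pd.DataFrame):
            frame = time
            time, event = frame["pfs_days"], frame["event"]
        self.features = features
        self.time = np.asarray(time, dtype=float)
        self.event = np.asarray(event).astype(int)
        self.config = config or SurvivalConfig()

    def fit(self) -> "PFSResults":
        res = pfs_pipeline(self.features, self.time, self.event, self.config)
        return PFSResults(model=self, result=res)


@dataclass
class PFSResults:
    model: PFSModel
    result: RiskScoreResult

    def __getattr__(self, name):
        return getattr(self.result, name)

    def summary(self) -> str:
        r = self.result
        td = ", ".join(f"AUC({int(h)}d)={v:.3f}" for h, v in r.tdauc.items())
        n_hi = int((r.group == "high").sum())
        n_lo = int((r.group == "low").sum())
        lines = [
            "PFS risk score (random survival forest"
            + (", leave-one-out scores)" if self.model.config.loocv else ", full fit)"),
            f"  screened features ({len(r.screened_features)}): "
            + ", ".join(r.screened_features[:6]) + ("..." if len(r.screened_features) > 6 else ""),
            f"  median split: {n_hi} high-risk vs {n_lo} low-risk",
            f"  log-rank chi2 = {r.logrank_chi2:.3f}, p = {r.logrank_p:.3g}",
            f"  Harrell's C = {r.harrell_c:.3f}",
            f"  time-dependent ROC: {td}",
        ]
        return "\n".join(lines)

    def plot_km(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for name, curve in self.result.km_curves.items():
            ax.step(curve["time"], curve["survival"], where="post", label=f"{name} risk")
        ax.set_xlabel("days")
        ax.set_ylabel("PFS probability")
        ax.legend()
        return ax
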