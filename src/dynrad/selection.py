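"""Two-stage feature screening: univariate t-test filter, then LASSO.

Stage 1 keeps columns whose Welch two-sided t-test between the OR and
NOR groups has p <= alpha.  Stage 2 standardises the survivors and fits
an L1-penalised logistic regression over a fixed penalty grid, choosing
the penalty by stratified inner-CV deviance; features with nonzero
coefficients at the chosen penalty are returned.

By default selection is meant to be re-run inside every outer
cross-validation training fold (``onepass_selection=False`` downstream); the
one-pass variant that selects once on the full data before LOOCV is
available for comparison and is optimistically biased.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

__all__ = ["SelectionConfig", "SelectionResult", "ttest_screen", "lasso_select", "select_features"]

log = logging.getLogger("dynrad")


@dataclass
class SelectionConfig:
    alpha: float = 0.05
    inner_folds: int = 5
    #: inverse-penalty grid for the L1 logistic path (liblinear C values)
    c_grid: tuple[float, ...] = tuple(np.logspace(-2, 2, 9))
    seed: int = 0
    onepass_selection: bool = False


@dataclass
class SelectionResult:
    kept_features: list[str]
    t_pvalues: pd.Series
    lasso_coefficients: pd.Series
    c_used: float | None
    n_after_ttest: int = 0
    fallback_used: bool = False

    @property
    def lambda_used(self) -> float | None:
        # lambda is the reciprocal of liblinear's C
        return None if self.c_used is None else 1.0 / self.c_used


def ttest_screen(
    matrix: pd.DataFrame, labels: np.ndarray, alpha: float = 0.05
) -> tuple[list[str], pd.Series]:
    """Welch two-sided t-test per column; keep columns with p <= alpha.

    Degenerate columns where *both* groups have zero variance get p = 1
    when the group means agree and p = 0 when they differ (perfect
    separation), rather than NaN.
    """
    y = np.asarray(labels).astype(bool)
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("both groups need at least 2 members")
    X = matrix.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("feature matrix must be finite")
    a, b = X[y], X[~y]
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, equal_var=False, axis=0)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = (a.std(axis=0) == 0) & (b.std(axis=0) == 0)
    if degenerate.any():
        same = np.isclose(a.mean(axis=0), b.mean(axis=0))
        p[degenerate & same] = 1.0
        p[degenerate & ~same] = 0.0
        log.info("ttest_screen: %d zero-variance columns handled degenerately", degenerate.sum())
    pvals = pd.Series(p, index=matrix.columns, name="p")
    kept = list(matrix.columns[p <= alpha])
    log.info("ttest_screen: %d / %d columns kept at alpha=%g", len(kept), X.shape[1], alpha)
    return kept, pvals


def _cv_deviance(X: np.ndarray, y: np.ndarray, c_grid, folds: int, seed: int) -> np.ndarray:
    """Mean held-out binomial deviance per C over stratified folds."""
    n_splits = min(folds, int(np.bincount(y).min()))
    skf = StratifiedKFold(n_splits=max(2, n_splits), shuffle=True, random_state=seed)
    dev = np.zeros(len(c_grid))
    for tr, te in skf.split(X, y):
        for ci, c in enumerate(c_grid):
            m = LogisticRegression(
                l1_ratio=1, C=c, solver="liblinear", max_iter=500, random_state=seed
            ).fit(X[tr], y[tr])
            prob = m.predict_proba(X[te])[:, 1]
            dev[ci] += log_loss(y[te], prob, labels=[0, 1])
    return dev / skf.get_n_splits()


def lasso_select(
    matrix: pd.DataFrame,
    labels: np.ndarray,
    config: SelectionConfig | None = None,
) -> SelectionResult:
    """L1-penalised logistic selection with inner-CV penalty choice.

    Columns are standardised (mean 0, sd 1) before fitting; the penalty
    is the grid value minimising mean held-out deviance.  If every
    coefficient shrinks to zero at every grid value the result is an
    empty selection with a warning (downstream models fall back to the
    strongest t-filter feature).
    """
    config = config or SelectionConfig()
    y = np.asarray(labels).astype(int)
    X = matrix.to_numpy(dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Xs = (X - mu) / sd

    dev = _cv_deviance(Xs, y, config.c_grid, config.inner_folds, config.seed)
    best = int(np.argmin(dev))
    c = float(config.c_grid[best])
    model = LogisticRegression(
        l1_ratio=1, C=c, solver="liblinear", max_iter=500, random_state=config.seed
    ).fit(Xs, y)
    coefs = pd.Series(model.coef_.ravel(), index=matrix.columns)
    kept = list(coefs.index[coefs != 0.0])
    if not kept:
        log.info("lasso_select: all coefficients zero at every penalty — empty selection")
    return SelectionResult(
        kept_features=kept,
        t_pvalues=pd.Series(dtype=float),
        lasso_coefficients=coefs[coefs != 0.0],
        c_used=c,
        n_after_ttest=matrix.shape[1],
    )


def select_features(
    matrix: pd.DataFrame, labels: np.ndarray, config: SelectionConfig | None = None
) -> SelectionResult:
    """t-test filter followed by LASSO, in that order.

    If the filter leaves fewer than 2 columns, or the LASSO keeps
    nothing, the single strongest t-filter column is used as a fallback
    (flagged on the result).
    """
    config = config or SelectionConfig()
    kept_t, pvals = ttest_screen(matrix, labels, config.alpha)
    if len(kept_t) < 2:
        top = [pvals.idxmin()]
        log.info("select_features: t-filter left %d columns; falling back to top-1", len(kept_t))
        return SelectionResult(
            kept_features=top,
            t_pvalues=pvals,
            lasso_coefficients=pd.Series(dtype=float),
            c_used=None,
            n_after_ttest=len(kept_t),
            fallback_used=True,
        )
    res = lasso_select(matrix[kept_t], labels, config)
    res = SelectionResult(
        kept_features=res.kept_features,
        t_pvalues=pvals,
        lasso_coefficients=res.lasso_coefficients,
        c_used=res.c_used,
        n_after_ttest=len(kept_t),
    )
    if not res.kept_features:
        res.kept_features = [pvals[kept_t].idxmin()]
        res.fallback_used = True
    return res
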