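"""Progression-free-survival workflow.

Univariate Cox screening of the winning dynamic features, a random
survival forest risk score (optionally leave-one-out so every patient is
scored by a forest grown without them), a median split into high/low
risk groups compared by Kaplan-Meier / log-rank, and time-dependent
cumulative-case / dynamic-control ROC at fixed horizons (90, 180, 270,
360 days by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from sksurv.ensemble import RandomSurvivalForest
from sksurv.metrics import concordance_index_censored
from sksurv.util import Surv

from dynrad.response import roc_auc

__all__ = [
    "SurvivalConfig",
    "RiskScoreResult",
    "cox_univariate_screen",
    "fit_risk_score",
    "kaplan_meier",
    "logrank_test",
    "td_roc",
    "pfs_pipeline",
]

log = logging.getLogger("dynrad")

DEFAULT_HORIZONS = (90.0, 180.0, 270.0, 360.0)


@dataclass
class SurvivalConfig:
    alpha: float = 0.05
    n_trees: int = 500
    min_leaf_events: int = 3
    loocv: bool = True
    horizons: tuple[float, ...] = DEFAULT_HORIZONS
    seed: int = 0


@dataclass
class RiskScoreResult:
    """Risk scores, median-split groups and their survival comparison."""

    risk_scores: pd.Series
    group: pd.Series  # "high" / "low"
    km_curves: dict[str, pd.DataFrame]
    logrank_chi2: float
    logrank_p: float
    tdauc: dict[float, float]
    harrell_c: float
    screened_features: list[str]
    cox_table: pd.DataFrame


def cox_univariate_screen(
    features: pd.DataFrame,
    time,
    event,
    alpha: float = 0.05,
    max_iter: int = 100,
) -> tuple[list[str], pd.DataFrame]:
    """Per-feature Cox proportional-hazards fit (Efron ties), Wald p.

    Features with p < ``alpha`` are kept.  Constant or non-converging
    columns are excluded and flagged in the returned table.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event).astype(int)
    if e.sum() < 2:
        raise ValueError("need at least 2 events")
    rows = []
    kept: list[str] = []
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            rows.append({"feature": col, "beta": np.nan, "p": np.nan, "flag": "constant"})
            continue
        df = pd.DataFrame({"t": t, "e": e, "x": (x - x.mean()) / x.std()})
        try:
            cph = CoxPHFitter()
            cph.fit(df, duration_col="t", event_col="e",
                    fit_options={"max_steps": max_iter})
            beta = float(cph.params_["x"])
            p = float(cph.summary.loc["x", "p"])
        except Exception as err:  # noqa: BLE001 - convergence failures flagged, not fatal
            rows.append({"feature": col, "beta": np.nan, "p": np.nan, "flag": f"failed: {err}"})
            continue
        flag = ""
        if p < alpha:
            kept.append(col)
        rows.append({"feature": col, "beta": beta, "p": p, "flag": flag})
    table = pd.DataFrame(rows).set_index("feature")
    log.info("cox_univariate_screen: kept %d / %d features at alpha=%g",
             len(kept), features.shape[1], alpha)
    return kept, table


def fit_risk_score(
    features: pd.DataFrame,
    time,
    event,
    seed: int = 0,
    loocv: bool = True,
    n_trees: int = 500,
    min_leaf_events: int = 3,
) -> pd.Series:
    """Random-survival-forest risk score per patient.

    The score is the forest's aggregated cumulative hazard summed over
    the event-time grid (higher = higher risk).  With ``loocv=True``
    each patient's score comes from a forest grown without them.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event).astype(bool)
    if features.shape[1] < 1:
        raise ValueError("need at least one feature")
    X = features.to_numpy(dtype=float)
    n = len(X)

    def _fit(idx_tr: np.ndarray) -> RandomSurvivalForest:
        if e[idx_tr].sum() == 0:
            raise ValueError("zero events in a training fold")
        rsf = RandomSurvivalForest(
            n_estimators=n_trees,
            max_features="sqrt",
            min_samples_leaf=min_leaf_events,
            random_state=seed,
            n_jobs=1,
        )
        rsf.fit(X[idx_tr], Surv.from_arrays(e[idx_tr], t[idx_tr]))
        return rsf

    if not loocv:
        rsf = _fit(np.arange(n))
        scores = rsf.predict(X)
    else:
        scores = np.empty(n)
        for i in range(n):
            tr = np.delete(np.arange(n), i)
            scores[i] = _fit(tr).predict(X[i : i + 1])[0]
    return pd.Series(scores, index=features.index, name="risk_score")


def kaplan_meier(time, event) -> pd.DataFrame:
    """Product-limit survival estimate as a (time, survival) step table."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event).astype(int)
    if len(t) == 0:
        raise ValueError("empty survival records")
    km = KaplanMeierFitter()
    km.fit(t, e)
    sf = km.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})


def km_survival_at(time, event, horizon: float) -> float:
    """KM survival probability at a fixed horizon."""
    tab = kaplan_meier(time, event)
    below = tab[tab["time"] <= horizon]
    return float(below["survival"].iloc[-1]) if len(below) else 1.0


def logrank_test(time_high, event_high, time_low, event_low) -> tuple[float, float]:
    """Two-group log-rank test: ``(chi2, p)``.

    Returns ``(0, 1)`` with a log message when no risk set is comparable
    (zero variance).
    """
    th, eh = np.asarray(time_high, float), np.asarray(event_high).astype(int)
    tl, el = np.asarray(time_low, float), np.asarray(event_low).astype(int)
    if len(th) == 0 or len(tl) == 0:
        raise ValueError("both groups must be nonempty")
    if eh.sum() + el.sum() == 0:
        raise ValueError("need at least one event")
    res = _ll_logrank(th, tl, event_observed_A=eh, event_observed_B=el)
    chi2 = float(res.test_statistic)
    p = float(res.p_value)
    if not np.isfinite(chi2):
        log.warning("logrank_test: zero variance — no comparable risk sets; p=1")
        return 0.0, 1.0
    return chi2, p


def td_roc(scores, time, event, horizon: float) -> float:
    """Cumulative-case / dynamic-control AUC(t) with KM censoring handling.

    Kaplan-Meier-based estimator: for each threshold ``c`` the
    sensitivity and specificity are obtained from the overall KM curve
    and the KM curve restricted to markers above ``c`` via Bayes'
    theorem; the AUC is the trapezoidal area of the resulting ROC.
    Cases are events by ``t``, controls are subjects event-free beyond
    ``t``.  With no censoring before ``t`` this reduces exactly to the
    empirical ROC of the binary indicator "event by t".
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event).astype(int)
    if not ((e == 1) & (t <= horizon)).any():
        raise ValueError(f"no cases by t={horizon}")
    if not (t > horizon).any():
        raise ValueError(f"no subjects at risk beyond t={horizon}")

    order = np.argsort(s)
    s, t, e = s[order], t[order], e[order]
    n = len(s)

    def km_at(tt, ee) -> float:
        if len(tt) == 0:
            return 1.0
        km = KaplanMeierFitter().fit(tt, ee)
        return float(km.predict(horizon))

    S_all = km_at(t, e)
    # thresholds at each unique marker value (subjects with marker > c)
    uniq = np.unique(s)
    sens = [1.0]
    one_minus_spec = [1.0]
    for c in uniq:
        above = s > c
        p_above = above.mean()
        S_above = km_at(t[above], e[above]) if p_above > 0 else 1.0
        se = (1.0 - S_above) * p_above / (1.0 - S_all) if S_all < 1 else 0.0
        sp1 = S_above * p_above / S_all if S_all > 0 else 0.0
        sens.append(float(np.clip(se, 0.0, 1.0)))
        one_minus_spec.append(float(np.clip(sp1, 0.0, 1.0)))
    sens.append(0.0)
    one_minus_spec.append(0.0)
    x = np.array(one_minus_spec)[::-1]
    y = np.array(sens)[::-1]
    return float(np.trapezoid(y, x))


def pfs_pipeline(
    features: pd.DataFrame,
    time,
    event,
    config: SurvivalConfig | None = None,
) -> RiskScoreResult:
    """Screen -> forest risk score -> median split -> KM/log-rank -> tdROC.

    If no feature passes the Cox screen the single smallest-p feature is
    used (logged), so the downstream score is always defined.
    """
    config = config or SurvivalConfig()
    t = np.asarray(time, dtype=float)
    e = np.asarray(event).astype(int)
    kept, cox_table = cox_univariate_screen(features, t, e, alpha=config.alpha)
    if not kept:
        valid = cox_table["p"].dropna()
        if valid.empty:
            raise ValueError("Cox screen failed for every feature")
        kept = [valid.idxmin()]
        log.warning("pfs_pipeline: no feature passed the Cox screen; using %s", kept[0])

    scores = fit_risk_score(
        features[kept], t, e,
        seed=config.seed, loocv=config.loocv,
        n_trees=config.n_trees, min_leaf_events=config.min_leaf_events,
    )
    med = float(np.median(scores))
    # ties at the median go to the low-risk group (deterministic rule)
    group = pd.Series(np.where(scores > med, "high", "low"), index=scores.index, name="group")

    hi, lo = group == "high", group == "low"
    km_curves = {
        "high": kaplan_meier(t[hi.to_numpy()], e[hi.to_numpy()]),
        "low": kaplan_meier(t[lo.to_numpy()], e[lo.to_numpy()]),
    }
    chi2, p = logrank_test(t[hi.to_numpy()], e[hi.to_numpy()], t[lo.to_numpy()], e[lo.to_numpy()])

    tdauc = {}
    for h in config.horizons:
        try:
            tdauc[h] = td_roc(scores.to_numpy(), t, e, h)
        except ValueError as err:
            log.warning("td_roc at t=%g undefined: %s", h, err)
            tdauc[h] = float("nan")

    c_index = float(
        concordance_index_censored(e.astype(bool), t, scores.to_numpy())[0]
    )
    return RiskScoreResult(
        risk_scores=scores,
        group=group,
        km_curves=km_curves,
        logrank_chi2=chi2,
        logrank_p=p,
        tdauc=tdauc,
        harrell_c=c_index,
        screened_features=kept,
        cox_table=cox_table,
    )
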