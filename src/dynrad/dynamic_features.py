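"""Dynamic feature construction from per-phase static radiomics features.

A *static* feature is one number per image; across the ``k`` ordered
acquisition phases of a multi-phase CT study it becomes a short series
``f_1 .. f_k``.  Five transforms summarise that series into *dynamic*
features:

``SD``
    standard discrete deviation, ``(1/k) * sum_i |f_i - fbar|`` — the mean
    absolute deviation around the across-phase mean ``fbar``.
``DC``
    discrete change, ``SD / |fbar|`` — the deviation relative to the mean
    level, so it is invariant to rescaling of the base feature.
``RCR``
    relative change rate, ``|f_j - f_i| / |f_i|`` for every ordered phase
    pair ``j < i`` (``k*(k-1)/2`` values; the denominator is the later
    phase by default).
``RACR``
    relative average change rate, ``|f_j - f_i| / |fbar|`` for every
    ordered pair.
``P``
    polynomial trend: ordinary least-squares coefficients of ``f_i`` on
    ``{1, t, .., t^d}`` over the nominal phase times.

All transforms treat the series values symmetrically in sign where the
definition allows it; denominators are taken in absolute value so that
every dynamic feature is a nonnegative magnitude even for base features
that can be negative (skewness, cluster shade, ...).  Denominators whose
magnitude falls below ``eps`` yield 0 and are flagged rather than
producing infinities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PhaseSeries",
    "DynamicTransformKind",
    "PolyFit",
    "DynamicFeatureMatrix",
    "sd_feature",
    "dc_feature",
    "rcr_features",
    "racr_features",
    "poly_features",
    "build_dynamic_matrix",
    "ORDINAL_TIMES",
    "NOMINAL_SECONDS",
]

#: default nominal phase times: ordinal positions
ORDINAL_TIMES = (1.0, 2.0, 3.0, 4.0)
#: alternative nominal times in seconds post-injection (midpoints of the
#: acquisition windows: PP at injection, AP 30-35 s, PVP 60-75 s, DP 100-120 s)
NOMINAL_SECONDS = (0.0, 32.5, 67.5, 110.0)

EPS_GUARD = 1e-12


class DynamicTransformKind(str, Enum):
    """The five dynamic transform families."""

    SD = "SD"
    DC = "DC"
    RCR = "RCR"
    RACR = "RACR"
    P = "P"


@dataclass(frozen=True)
class PhaseSeries:
    """One static feature observed over ``k`` ordered phases.

    Parameters
    ----------
    values : sequence of float
        Feature values ``f_1 .. f_k`` in phase order.
    times : sequence of float, optional
        Strictly increasing nominal acquisition times ``t_1 .. t_k``;
        defaults to ordinal positions ``1 .. k``.
    """

    values: tuple[float, ...]
    times: tuple[float, ...] = ()

    def __init__(self, values: Sequence[float], times: Sequence[float] | None = None):
        values = tuple(float(v) for v in values)
        if len(values) < 2:
            raise ValueError("a phase series needs at least 2 phases")
        if not all(np.isfinite(values)):
            raise ValueError("phase series values must be finite")
        if times is None:
            times = tuple(float(i) for i in range(1, len(values) + 1))
        else:
            times = tuple(float(t) for t in times)
        if len(times) != len(values):
            raise ValueError("times and values must have equal length")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "times", times)

    @property
    def k(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class PolyFit:
    """Least-squares polynomial trend of a phase series.

    ``coefficients[m]`` multiplies ``t**m``; ``rss`` is the residual sum
    of squares of the fit.
    """

    coefficients: tuple[float, ...]
    degree: int
    rss: float


def _as_series(series) -> PhaseSeries:
    if isinstance(series, PhaseSeries):
        return series
    return PhaseSeries(series)


def sd_feature(series: PhaseSeries | Sequence[float]) -> float:
    """Mean absolute deviation of the series around its across-phase mean."""
    s = _as_series(series)
    v = np.asarray(s.values)
    return float(np.mean(np.abs(v - v.mean())))


def dc_feature(series: PhaseSeries | Sequence[float], eps: float = EPS_GUARD) -> float:
    """``SD`` relative to the magnitude of the across-phase mean.

    Returns 0 when ``|mean| < eps`` (degenerate denominator guard).
    """
    s = _as_series(series)
    v = np.asarray(s.values)
    mbar = abs(v.mean())
    if mbar < eps:
        return 0.0
    return sd_feature(s) / mbar


def _pairs(k: int) -> list[tuple[int, int]]:
    # ordered pairs (j, i), 1-based, j < i
    return [(j, i) for j in range(1, k + 1) for i in range(j + 1, k + 1)]


def rcr_features(
    series: PhaseSeries | Sequence[float],
    denominator: str = "later",
    eps: float = EPS_GUARD,
) -> dict[tuple[int, int], float]:
    """Relative change rate for every ordered phase pair ``(j, i)``, j < i.

    ``|f_j - f_i| / |f_i|`` with the *later* phase in the denominator
    (``denominator="earlier"`` switches to ``|f_j|``).  Yields
    ``k*(k-1)/2`` values keyed by 1-based pair indices.
    """
    if denominator not in ("later", "earlier"):
        raise ValueError("denominator must be 'later' or 'earlier'")
    s = _as_series(series)
    v = s.values
    out: dict[tuple[int, int], float] = {}
    for j, i in _pairs(s.k):
        den = abs(v[i - 1]) if denominator == "later" else abs(v[j - 1])
        num = abs(v[j - 1] - v[i - 1])
        out[(j, i)] = 0.0 if den < eps else num / den
    return out


def racr_features(
    series: PhaseSeries | Sequence[float], eps: float = EPS_GUARD
) -> dict[tuple[int, int], float]:
    """Relative average change rate: ``|f_j - f_i| / |fbar|`` per pair."""
    s = _as_series(series)
    v = np.asarray(s.values)
    mbar = abs(v.mean())
    out: dict[tuple[int, int], float] = {}
    for j, i in _pairs(s.k):
        num = abs(v[j - 1] - v[i - 1])
        out[(j, i)] = 0.0 if mbar < eps else num / mbar
    return out


def poly_features(series: PhaseSeries | Sequence[float], degree: int | None = None) -> PolyFit:
    """Ordinary least-squares polynomial fit of the series on its times.

    Parameters
    ----------
    degree : int, optional
        Polynomial degree ``d`` with ``1 <= d <= k - 1``; defaults to
        ``k - 1`` (interpolating fit, residual 0).
    """
    s = _as_series(series)
    d = s.k - 1 if degree is None else int(degree)
    if not 1 <= d <= s.k - 1:
        raise ValueError(f"degree must be in [1, {s.k - 1}], got {d}")
    t = np.asarray(s.times)
    if len(np.unique(t)) != len(t):
        raise ValueError("repeated times: singular design")
    y = np.asarray(s.values)
    X = np.vander(t, d + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    # snap tiny numerical residue so saturated fits report exactly 0
    rss = float(resid @ resid)
    if rss < 1e-20:
        rss = 0.0
    coef = np.where(np.abs(coef) < 1e-12, 0.0, coef)
    return PolyFit(tuple(float(c) for c in coef), d, rss)


@dataclass
class DynamicFeatureMatrix:
    """Patients x dynamic features, with per-column provenance.

    Attributes
    ----------
    data : pandas.DataFrame
        Indexed by patient id; columns named
        ``<base>__SD``, ``<base>__DC``, ``<base>__RCR_<j>to<i>``,
        ``<base>__RACR_<j>to<i>``, ``<base>__P_a<m>``.
    meta : pandas.DataFrame
        One row per column: ``base`` feature, transform ``kind``, and the
        phase ``pair`` or coefficient ``index`` where applicable, plus an
        ``eps_guarded`` flag marking columns where at least one cell hit
        the degenerate-denominator guard.
    """

    data: pd.DataFrame
    meta: pd.DataFrame
    n_guarded_cells: int = 0

    def columns_of_kind(self, kind: DynamicTransformKind | str) -> list[str]:
        kind = DynamicTransformKind(kind).value
        return list(self.meta.index[self.meta["kind"] == kind])


def _stack_phases(per_phase: Mapping[str, pd.DataFrame]) -> tuple[np.ndarray, list[str], list, list[str]]:
    """Align per-phase matrices into an (n_patients, n_features, k) cube."""
    phases = list(per_phase)
    first = per_phase[phases[0]]
    patients = list(first.index)
    features = list(first.columns)
    cube = np.empty((len(patients), len(features), len(phases)))
    for p_idx, ph in enumerate(phases):
        df = per_phase[ph]
        missing = set(patients) - set(df.index)
        if missing or list(df.columns) != features:
            raise ValueError(
                f"phase {ph!r}: patients or features do not match the first phase "
                f"(missing patients: {sorted(map(str, missing))[:5]})"
            )
        cube[:, :, p_idx] = df.loc[patients, features].to_numpy(dtype=float)
    if not np.isfinite(cube).all():
        bad = np.argwhere(~np.isfinite(cube))[0]
        raise ValueError(
            f"non-finite static feature: patient {patients[bad[0]]!r}, "
            f"feature {features[bad[1]]!r}, phase {phases[bad[2]]!r}"
        )
    return cube, phases, patients, features


def build_dynamic_matrix(
    per_phase: Mapping[str, pd.DataFrame],
    kinds: Sequence[DynamicTransformKind | str] = ("SD", "DC", "RCR", "RACR", "P"),
    times: Sequence[float] | None = None,
    poly_degree: int | None = None,
    rcr_denominator: str = "later",
    eps: float = EPS_GUARD,
) -> DynamicFeatureMatrix:
    """Apply the requested dynamic transforms feature-wise over a cohort.

    Parameters
    ----------
    per_phase : mapping phase -> DataFrame (patients x features)
        One static feature matrix per phase, in phase order.  Every
        patient must be present in every phase with the same feature set.
    kinds : sequence of transform names
        Any subset of ``{"SD", "DC", "RCR", "RACR", "P"}``.
    times : sequence of float, optional
        Nominal phase times (used by ``P`` only); defaults to ordinal.
    poly_degree : int, optional
        Degree for ``P``; defaults to ``k - 1``.

    Column counts per base feature: SD 1, DC 1, RCR and RACR
    ``k*(k-1)/2`` each, P ``degree + 1``.
    """
    kinds = [DynamicTransformKind(k) for k in kinds]
    cube, phases, patients, features = _stack_phases(per_phase)
    k = len(phases)
    if k < 2:
        raise ValueError("need at least 2 phases")
    t = np.arange(1.0, k + 1) if times is None else np.asarray(times, dtype=float)
    if len(t) != k:
        raise ValueError("times length must equal number of phases")

    mean = cube.mean(axis=2)  # (n, f)
    absmean = np.abs(mean)
    sd = np.mean(np.abs(cube - mean[:, :, None]), axis=2)
    pairs = _pairs(k)

    blocks: list[np.ndarray] = []
    names: list[str] = []
    meta_rows: list[dict] = []
    n_guarded = 0

    for kind in kinds:
        if kind is DynamicTransformKind.SD:
            blocks.append(sd.reshape(len(patients), len(features), 1))
            names.extend(f"{f}__SD" for f in features)
            meta_rows.extend({"base": f, "kind": "SD", "pair": None, "index": None} for f in features)
        elif kind is DynamicTransformKind.DC:
            guard = absmean < eps
            n_guarded += int(guard.sum())
            dc = np.where(guard, 0.0, sd / np.where(guard, 1.0, absmean))
            blocks.append(dc.reshape(len(patients), len(features), 1))
            names.extend(f"{f}__DC" for f in features)
            meta_rows.extend(
                {"base": f, "kind": "DC", "pair": None, "index": None,
                 "eps_guarded": bool(guard[:, fi].any())}
                for fi, f in enumerate(features)
            )
        elif kind in (DynamicTransformKind.RCR, DynamicTransformKind.RACR):
            vals = np.empty((len(patients), len(features), len(pairs)))
            guarded_cols = np.zeros((len(features), len(pairs)), dtype=bool)
            for pi, (j, i) in enumerate(pairs):
                num = np.abs(cube[:, :, j - 1] - cube[:, :, i - 1])
                if kind is DynamicTransformKind.RCR:
                    den = np.abs(cube[:, :, i - 1] if rcr_denominator == "later" else cube[:, :, j - 1])
                else:
                    den = absmean
                guard = den < eps
                n_guarded += int(guard.sum())
                guarded_cols[:, pi] = guard.any(axis=0)
                vals[:, :, pi] = np.where(guard, 0.0, num / np.where(guard, 1.0, den))
            blocks.append(vals)
            for fi, f in enumerate(features):
                for pi, (j, i) in enumerate(pairs):
                    names.append(f"{f}__{kind.value}_{j}to{i}")
                    meta_rows.append(
                        {"base": f, "kind": kind.value, "pair": (j, i), "index": None,
                         "eps_guarded": bool(guarded_cols[fi, pi])}
                    )
        elif kind is DynamicTransformKind.P:
            d = k - 1 if poly_degree is None else int(poly_degree)
            if not 1 <= d <= k - 1:
                raise ValueError(f"poly degree must be in [1, {k - 1}]")
            X = np.vander(t, d + 1, increasing=True)
            # solve for all (patient, feature) series at once
            flat = cube.reshape(-1, k).T  # (k, n*f)
            coef, *_ = np.linalg.lstsq(X, flat, rcond=None)
            coef = coef.T.reshape(len(patients), len(features), d + 1)
            coef[np.abs(coef) < 1e-12] = 0.0
            blocks.append(coef)
            for f in features:
                for m in range(d + 1):
                    names.append(f"{f}__P_a{m}")
                    meta_rows.append({"base": f, "kind": "P", "pair": None, "index": m})

    # blocks are (n, f, c_kind); interleave feature-major within each kind
    mats = []
    for b in blocks:
        mats.append(b.reshape(len(patients), -1))
    data = pd.DataFrame(np.concatenate(mats, axis=1), index=pd.Index(patients, name="patient_id"))
    data.columns = names
    meta = pd.DataFrame(meta_rows, index=names)
    if "eps_guarded" not in meta:
        meta["eps_guarded"] = False
    meta["eps_guarded"] = meta["eps_guarded"].map(lambda v: bool(v) if pd.notna(v) else False)
    return DynamicFeatureMatrix(data=data, meta=meta, n_guarded_cells=n_guarded)
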