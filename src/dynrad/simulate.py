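"""Synthetic multi-phase cohorts with enhancement-kinetics group structure.

The generator emulates the data model the dynamic-feature analysis
assumes: per-patient static radiomics features observed over four
contrast phases whose *change pattern across phases* — not the
single-phase level — carries the treatment-response signal.

For an informative feature ``f`` of patient ``i`` in phase ``p``::

    f_{ipf} = m_f * b_{if} * e_g(p) * exp(eps),   eps ~ N(0, noise_sd^2)

* ``m_f`` is a per-feature scale drawn log-uniformly over three orders
  of magnitude (radiomics feature scales span decades);
* ``b_{if} = exp(N(0, baseline_sd^2))`` is a per-patient baseline that
  dominates single-phase variance but cancels exactly in phase-to-phase
  ratios;
* ``e_g(p)`` is the group enhancement curve, normalised to mean 1 over
  phases so the *average* level is matched between groups; responders
  (OR) get a curve interpolated ``effect_size`` of the way from the
  shared curve towards a flatter one.

Non-informative features use the shared curve for both groups.
Progression-free survival follows a proportional-hazards Weibull whose
log-hazard is ``pfs_coef`` times the standardised per-patient dynamic
signal (the mean PP->AP log-ratio over informative features), with
independent uniform censoring calibrated to the requested censor rate.
Clinical covariates are simulated independent of outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dynrad.images import PHASES, ImageVolume, RoiMask

__all__ = [
    "SimulationConfig",
    "PhantomConfig",
    "SyntheticCohort",
    "simulate_feature_cohort",
    "simulate_phantom_images",
]

# enhancement curves before mean-1 normalisation: a typical hypervascular
# lesion profile (strong arterial uptake, washout) and a flatter profile
_SHARED_CURVE = (1.0, 1.8, 1.6, 1.3)
_FLAT_CURVE = (1.0, 1.25, 1.2, 1.1)


def _norm_curve(c: np.ndarray) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    if (c <= 0).any():
        raise ValueError("enhancement curves must be positive (degenerate curve)")
    return c / c.mean()


@dataclass
class SimulationConfig:
    """Study conditions for the feature-level cohort generator."""

    n_patients: int = 76
    n_features: int = 200
    n_informative: int = 20
    k_phases: int = 4
    #: shared (non-responder) and alternative enhancement profiles
    shared_curve: tuple[float, ...] = _SHARED_CURVE
    alt_curve: tuple[float, ...] = _FLAT_CURVE
    #: 0 = identical curves; 1 = responders fully on the alternative profile
    effect_size: float = 1.0
    #: per-phase multiplicative log-normal noise (log-scale sd)
    noise_sd: float = 0.1
    #: between-patient baseline heterogeneity (log-scale sd); this is what
    #: drowns single-phase levels while cancelling in ratios
    baseline_sd: float = 0.6
    or_fraction: float = 33.0 / 76.0
    weibull_shape: float = 1.5
    weibull_scale: float = 300.0  # days
    pfs_coef: float = 1.0
    censor_rate: float = 0.2
    noise_model: str = "lognormal"  # or "gaussian" (additive)
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.n_informative <= self.n_features:
            raise ValueError("0 < n_informative <= n_features required")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0 <= self.or_fraction <= 1:
            raise ValueError("or_fraction in [0, 1]")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate in [0, 1)")
        if self.k_phases < 2 or self.k_phases > 4:
            raise ValueError("k_phases must be 2..4")


@dataclass
class SyntheticCohort:
    """Feature matrices per phase plus the outcome/clinical table."""

    phases: dict[str, pd.DataFrame]
    cohort: pd.DataFrame
    informative_features: list[str]
    config: SimulationConfig

    @property
    def labels(self) -> np.ndarray:
        return (self.cohort["response"] == "OR").to_numpy().astype(int)


def _calibrate_uniform_censoring(t: np.ndarray, rate: float, rng: np.random.Generator):
    """Upper bound m for C ~ U(0, m) hitting the target censor fraction.

    P(C < T | m) = E[min(T, m)] / m, monotone decreasing in m; solved by
    bisection on the drawn sample.
    """
    def frac(m):
        return np.mean(np.minimum(t, m)) / m

    lo, hi = t.min() * 1e-3, t.max() * 1e3
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if frac(mid) > rate:
            lo = mid
        else:
            hi = mid
    return np.sqrt(lo * hi)


def simulate_feature_cohort(config: SimulationConfig | None = None) -> SyntheticCohort:
    """Draw a synthetic cohort under the configured study conditions."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    n, f, k = cfg.n_patients, cfg.n_features, cfg.k_phases
    phases = PHASES[:k]

    shared = _norm_curve(np.asarray(cfg.shared_curve[:k]))
    alt = _norm_curve(np.asarray(cfg.alt_curve[:k]))
    e_or = _norm_curve(shared + cfg.effect_size * (alt - shared))
    e_nor = shared

    n_or = int(round(cfg.or_fraction * n))
    labels = np.zeros(n, dtype=int)
    labels[rng.permutation(n)[:n_or]] = 1

    feature_names = [f"feat_{i:04d}" for i in range(f)]
    informative = sorted(rng.permutation(f)[: cfg.n_informative])
    informative_names = [feature_names[i] for i in informative]
    is_inf = np.zeros(f, dtype=bool)
    is_inf[informative] = True

    m_f = 10.0 ** rng.uniform(0.0, 3.0, size=f)
    b = np.exp(rng.normal(0.0, cfg.baseline_sd, size=(n, f)))

    curves = np.empty((n, f, k))
    curves[:, :, :] = shared[None, None, :]
    for g, curve in ((0, e_nor), (1, e_or)):
        rows = labels == g
        curves[np.ix_(rows, is_inf)] = curve[None, None, :]

    base = m_f[None, :, None] * b[:, :, None] * curves
    if cfg.noise_model == "lognormal":
        data = base * np.exp(rng.normal(0.0, cfg.noise_sd, size=(n, f, k)))
    elif cfg.noise_model == "gaussian":
        data = base + rng.normal(0.0, cfg.noise_sd, size=(n, f, k)) * m_f[None, :, None]
    else:
        raise ValueError("noise_model must be 'lognormal' or 'gaussian'")

    patient_ids = [f"sim_{i:04d}" for i in range(n)]
    per_phase = {
        ph: pd.DataFrame(data[:, :, pi], index=pd.Index(patient_ids, name="patient_id"),
                         columns=feature_names)
        for pi, ph in enumerate(phases)
    }

    # PFS: proportional-hazards Weibull on the standardised dynamic signal
    with np.errstate(divide="ignore"):
        logratio = np.log(data[:, is_inf, 1] / data[:, is_inf, 0]).mean(axis=1)
    z = (logratio - logratio.mean()) / (logratio.std() or 1.0)
    u = rng.exponential(1.0, size=n)
    t_event = cfg.weibull_scale * (u / np.exp(cfg.pfs_coef * z)) ** (1.0 / cfg.weibull_shape)
    if cfg.censor_rate > 0:
        m = _calibrate_uniform_censoring(t_event, cfg.censor_rate, rng)
        c = rng.uniform(0.0, m, size=n)
        pfs = np.minimum(t_event, c)
        event = (t_event <= c).astype(int)
    else:
        pfs, event = t_event, np.ones(n, dtype=int)

    cohort = pd.DataFrame(
        {
            "response": np.where(labels == 1, "OR", "NOR"),
            "pfs_days": pfs,
            "event": event,
            "age": rng.integers(36, 77, size=n),
            "sex": rng.choice(["male", "female"], size=n, p=[0.53, 0.47]),
            "site": rng.choice(["left", "rectum", "right"], size=n, p=[0.30, 0.37, 0.33]),
            "tumor_size": np.round(np.exp(rng.normal(np.log(3.8), 0.5, size=n)), 2),
            "cea": rng.choice(["normal", "high"], size=n, p=[0.12, 0.88]),
            "afp": rng.choice(["normal", "high"], size=n, p=[0.95, 0.05]),
        },
        index=pd.Index(patient_ids, name="patient_id"),
    )
    return SyntheticCohort(per_phase, cohort, informative_names, cfg)


@dataclass
class PhantomConfig:
    """Voxel-level four-phase phantom settings."""

    grid: tuple[int, int, int] = (32, 32, 32)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lesion_radii: tuple[float, float, float] = (8.0, 6.0, 5.0)  # voxels (z, y, x)
    background_hu: float = 60.0
    lesion_hu: float = 100.0  # baseline lesion mean, scaled by the phase curve
    curve: tuple[float, ...] = _SHARED_CURVE
    noise_sd: float = 0.0
    seed: int = 0


def ellipsoid_mask(grid: tuple[int, int, int], radii: tuple[float, float, float]) -> np.ndarray:
    """Lattice points inside a centred ellipsoid."""
    zz, yy, xx = np.meshgrid(*(np.arange(g) - (g - 1) / 2.0 for g in grid), indexing="ij")
    rz, ry, rx = radii
    return (zz / rz) ** 2 + (yy / ry) ** 2 + (xx / rx) ** 2 <= 1.0


def simulate_phantom_images(config: PhantomConfig | None = None) -> tuple[list[ImageVolume], RoiMask]:
    """Four-phase phantom: an enhancing ellipsoidal lesion on uniform liver.

    The lesion mean HU follows ``lesion_hu * curve[p]`` per phase, plus
    additive Gaussian noise; the mask marks the ellipsoid.
    """
    cfg = config or PhantomConfig()
    if any(2 * r >= g for r, g in zip(cfg.lesion_radii, cfg.grid)):
        raise ValueError("lesion larger than grid")
    rng = np.random.default_rng(cfg.seed)
    mask = ellipsoid_mask(cfg.grid, cfg.lesion_radii)
    vols = []
    for pi, phase in enumerate(PHASES[: len(cfg.curve)]):
        img = np.full(cfg.grid, cfg.background_hu, dtype=float)
        img[mask] = cfg.lesion_hu * cfg.curve[pi]
        if cfg.noise_sd > 0:
            img += rng.normal(0.0, cfg.noise_sd, size=cfg.grid)
        vols.append(ImageVolume(img, cfg.spacing, phase=phase))
    return vols, RoiMask(mask, cfg.spacing)
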