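"""Static radiomics extraction for one phase: first-order, shape, GLCM.

The implementation follows the IBSI reference definitions with the
settings commonly used by CT radiomics studies of this kind: z-score
normalisation of the whole volume (scaled by 100, shifted by 1000),
resampling to 1 mm isotropic voxels, and fixed-bin-width discretisation
(25 HU-equivalent units) anchored at the ROI minimum.  Texture features
use a gray-level co-occurrence matrix at distance 1 over the 13 unique
3-D directions, accumulated symmetrically and averaged across
directions.

Only the families the analysis needs in-house are implemented
(first-order, shape, GLCM); run-length, size-zone, NGTDM, GLDM and
wavelet-filtered families are expected to arrive through external
feature tables when a full extractor has been run upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import SimpleITK as sitk

from dynrad.images import ImageVolume, RoiMask

__all__ = [
    "ExtractionSettings",
    "StaticFeatureVector",
    "preprocess",
    "discretize",
    "extract_static_features",
    "extract_cohort_features",
    "drop_constant_features",
    "GLCM_DIRECTIONS",
]

log = logging.getLogger("dynrad")

# the 13 unique 3-D direction vectors (half of the 26-neighbourhood)
GLCM_DIRECTIONS: tuple[tuple[int, int, int], ...] = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
)


@dataclass
class ExtractionSettings:
    """Preprocessing and discretisation settings.

    Parameters
    ----------
    bin_width : float
        Fixed bin width for gray-level discretisation (post-normalisation
        intensity units), default 25.
    resample_spacing : tuple of float
        Target voxel spacing in mm (x, y, z); ``None`` disables resampling.
    normalize : bool
        z-score the whole volume before intensity features.
    normalize_scale : float
        Multiplier applied after z-scoring (default 100).
    voxel_array_shift : float
        Constant added after scaling so intensities are mostly positive
        (default 1000).
    """

    bin_width: float = 25.0
    resample_spacing: tuple[float, float, float] | None = (1.0, 1.0, 1.0)
    normalize: bool = True
    normalize_scale: float = 100.0
    voxel_array_shift: float = 1000.0
    interpolation: str = "bspline"  # image interpolator; mask is nearest-neighbour

    def __post_init__(self):
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if self.resample_spacing is not None and any(s <= 0 for s in self.resample_spacing):
            raise ValueError("resample_spacing must be positive")


@dataclass
class StaticFeatureVector:
    """Named feature values with family tags and degeneracy reasons."""

    values: dict[str, float]
    families: dict[str, str]
    nan_reasons: dict[str, str] = field(default_factory=dict)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values)


_INTERPOLATORS = {
    "bspline": sitk.sitkBSpline,
    "linear": sitk.sitkLinear,
    "nearest": sitk.sitkNearestNeighbor,
}


def _resample(img: sitk.Image, spacing, interpolator) -> sitk.Image:
    old_spacing = img.GetSpacing()
    old_size = img.GetSize()
    new_size = [
        int(round(osz * osp / nsp)) for osz, osp, nsp in zip(old_size, old_spacing, spacing)
    ]
    res = sitk.ResampleImageFilter()
    res.SetOutputSpacing(tuple(float(s) for s in spacing))
    res.SetSize([max(1, s) for s in new_size])
    res.SetOutputOrigin(img.GetOrigin())
    res.SetOutputDirection(img.GetDirection())
    res.SetInterpolator(interpolator)
    res.SetDefaultPixelValue(0)
    return res.Execute(img)


def preprocess(
    volume: ImageVolume, mask: RoiMask, settings: ExtractionSettings | None = None
) -> tuple[ImageVolume, RoiMask]:
    """Normalise and resample an image/mask pair.

    The image is z-scored over the *whole volume* (not the ROI), scaled
    by ``normalize_scale`` and shifted by ``voxel_array_shift``; then
    both image and mask are resampled to ``resample_spacing`` (image by
    the configured interpolator, mask by nearest neighbour, re-binarised
    at 0.5).
    """
    settings = settings or ExtractionSettings()
    vox = volume.voxels.astype(float)
    if settings.normalize:
        sd = vox.std()
        if sd == 0:
            raise ValueError("zero image variance: cannot z-normalize a constant volume")
        vox = (vox - vox.mean()) / sd * settings.normalize_scale + settings.voxel_array_shift
    out_vol = ImageVolume(vox, volume.spacing, volume.origin, volume.phase)
    out_mask = RoiMask(mask.voxels, mask.spacing, mask.origin)
    if settings.resample_spacing is not None and tuple(settings.resample_spacing) != tuple(volume.spacing):
        img = sitk.GetImageFromArray(out_vol.voxels)
        img.SetSpacing(volume.spacing)
        img.SetOrigin(volume.origin)
        m = sitk.GetImageFromArray(out_mask.voxels.astype(np.uint8))
        m.SetSpacing(mask.spacing)
        m.SetOrigin(mask.origin)
        interp = _INTERPOLATORS[settings.interpolation]
        img_r = _resample(img, settings.resample_spacing, interp)
        m_r = _resample(m, settings.resample_spacing, sitk.sitkNearestNeighbor)
        out_vol = ImageVolume(
            sitk.GetArrayFromImage(img_r), tuple(img_r.GetSpacing()), tuple(img_r.GetOrigin()), volume.phase
        )
        out_mask = RoiMask(
            sitk.GetArrayFromImage(m_r) > 0.5, tuple(m_r.GetSpacing()), tuple(m_r.GetOrigin())
        )
    return out_vol, out_mask


def discretize(intensities: np.ndarray, bin_width: float) -> np.ndarray:
    """Fixed-bin-width gray levels anchored at the minimum.

    ``level(v) = floor((v - min) / bin_width) + 1``; the number of levels
    is ``floor((max - min) / bin_width) + 1``.  A constant input maps to
    a single level 1.  Levels are translation-invariant by construction.
    """
    v = np.asarray(intensities, dtype=float)
    if v.size == 0:
        raise ValueError("empty intensity list")
    return (np.floor((v - v.min()) / float(bin_width)) + 1).astype(np.int64)


# ---------------------------------------------------------------------------
# first-order


def _first_order(roi: np.ndarray, levels: np.ndarray) -> dict[str, float]:
    n = roi.size
    mean = roi.mean()
    p25, p50, p75 = np.percentile(roi, [25, 50, 75])
    p10, p90 = np.percentile(roi, [10, 90])
    in_robust = roi[(roi >= p10) & (roi <= p90)]
    counts = np.bincount(levels)[1:]
    p = counts[counts > 0] / n
    return {
        "firstorder_Mean": float(mean),
        "firstorder_Median": float(p50),
        "firstorder_Minimum": float(roi.min()),
        "firstorder_Maximum": float(roi.max()),
        "firstorder_Range": float(roi.max() - roi.min()),
        "firstorder_Variance": float(roi.var()),
        "firstorder_Skewness": _skew(roi),
        "firstorder_Kurtosis": _kurt(roi),
        "firstorder_Energy": float(np.sum(roi**2)),
        "firstorder_Entropy": float(-np.sum(p * np.log2(p))),
        "firstorder_Uniformity": float(np.sum(p**2)),
        "firstorder_MeanAbsoluteDeviation": float(np.mean(np.abs(roi - mean))),
        "firstorder_RobustMeanAbsoluteDeviation": float(
            np.mean(np.abs(in_robust - in_robust.mean())) if in_robust.size else 0.0
        ),
        "firstorder_10Percentile": float(p10),
        "firstorder_90Percentile": float(p90),
        "firstorder_InterquartileRange": float(p75 - p25),
        "firstorder_RootMeanSquared": float(np.sqrt(np.mean(roi**2))),
    }


def _skew(x: np.ndarray) -> float:
    m = x.mean()
    s2 = np.mean((x - m) ** 2)
    if s2 == 0:
        return 0.0
    return float(np.mean((x - m) ** 3) / s2**1.5)


def _kurt(x: np.ndarray) -> float:
    m = x.mean()
    s2 = np.mean((x - m) ** 2)
    if s2 == 0:
        return 0.0
    return float(np.mean((x - m) ** 4) / s2**2)


# ---------------------------------------------------------------------------
# shape


def _shape_features(mask: np.ndarray, spacing_xyz: tuple[float, float, float]) -> dict[str, float]:
    # spacing is (x, y, z); array order is (z, y, x)
    dz, dy, dx = spacing_xyz[2], spacing_xyz[1], spacing_xyz[0]
    n = int(mask.sum())
    voxel_vol = dx * dy * dz
    volume = n * voxel_vol

    # mesh-free surface approximation: exposed voxel faces
    pad = np.pad(mask, 1)
    area = 0.0
    face = {0: dy * dx, 1: dz * dx, 2: dz * dy}  # faces normal to z, y, x
    for axis in range(3):
        diff = np.diff(pad.astype(np.int8), axis=axis)
        area += np.abs(diff).sum() * face[axis]

    coords = np.argwhere(mask).astype(float)  # (n, 3) in (z, y, x)
    phys = coords * np.array([dz, dy, dx])
    centered = phys - phys.mean(axis=0)
    cov = centered.T @ centered / n
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]  # lambda_major >= minor
    eig = np.clip(eig, 0.0, None)
    if eig[0] <= 0:
        elong = flat = 1.0  # single voxel / degenerate: isotropic by convention
    else:
        elong = float(np.sqrt(eig[1] / eig[0]))
        flat = float(np.sqrt(eig[2] / eig[0]))

    sphericity = float((36 * np.pi * volume**2) ** (1.0 / 3.0) / area) if area > 0 else np.nan

    # maximum 3-D diameter over (the hull of) the mask voxel centres
    pts = phys
    if len(pts) > 400:
        try:
            from scipy.spatial import ConvexHull

            pts = pts[ConvexHull(pts, qhull_options="QJ").vertices]
        except Exception:  # co-planar / degenerate hulls fall back to all points
            pass
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    max_diam = float(np.sqrt(d2.max()))

    return {
        "shape_VoxelVolume": float(volume),
        "shape_SurfaceArea": float(area),
        "shape_Elongation": elong,
        "shape_Flatness": flat,
        "shape_Sphericity": sphericity,
        "shape_Maximum3DDiameter": max_diam,
    }


# ---------------------------------------------------------------------------
# GLCM


def glcm_matrix(level_img: np.ndarray, mask: np.ndarray, direction: tuple[int, int, int], n_levels: int) -> np.ndarray:
    """Symmetric co-occurrence counts for one direction at distance 1.

    Counts pairs of discretised levels for voxels both inside the mask,
    accumulating each pair in both orders (symmetric GLCM).
    """
    dz, dy, dx = direction
    shape = level_img.shape

    def shifted_slices(d, size):
        if d >= 0:
            return slice(0, size - d), slice(d, size)
        return slice(-d, size), slice(0, size + d)

    sz_a, sz_b = shifted_slices(dz, shape[0])
    sy_a, sy_b = shifted_slices(dy, shape[1])
    sx_a, sx_b = shifted_slices(dx, shape[2])
    a = level_img[sz_a, sy_a, sx_a]
    b = level_img[sz_b, sy_b, sx_b]
    valid = mask[sz_a, sy_a, sx_a] & mask[sz_b, sy_b, sx_b]
    ai, bi = a[valid] - 1, b[valid] - 1
    P = np.zeros((n_levels, n_levels), dtype=float)
    np.add.at(P, (ai, bi), 1.0)
    return P + P.T


def glcm_features_from_matrix(P: np.ndarray) -> dict[str, float]:
    """IBSI GLCM statistics from one (already symmetric) count matrix."""
    total = P.sum()
    if total == 0:
        return {k: np.nan for k in _GLCM_NAMES}
    p = P / total
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mux = float(np.sum(i * px))
    muy = float(np.sum(i * py))
    sigx = float(np.sqrt(np.sum((i - mux) ** 2 * px)))
    sigy = float(np.sqrt(np.sum((i - muy) ** 2 * py)))
    ii, jj = np.meshgrid(i, i, indexing="ij")
    diff = np.abs(ii - jj)

    nz = p > 0
    ent = float(-np.sum(p[nz] * np.log2(p[nz])))

    # difference distribution p_{x-y}
    pdiff = np.array([p[diff == d].sum() for d in range(ng)])
    dz = pdiff > 0
    diff_entropy = float(-np.sum(pdiff[dz] * np.log2(pdiff[dz])))

    contrast = float(np.sum(diff**2 * p))
    if sigx * sigy > 0:
        correlation = float(np.sum((ii - mux) * (jj - muy) * p) / (sigx * sigy))
    else:
        correlation = 1.0
    idn = float(np.sum(p / (1.0 + diff / ng)))
    idmn = float(np.sum(p / (1.0 + (diff / ng) ** 2)))

    # information measures of correlation
    pxpy = np.outer(px, py)
    both = (p > 0) & (pxpy > 0)
    hxy = ent
    hxy1 = float(-np.sum(p[both] * np.log2(pxpy[both])))
    hxy2 = float(-np.sum(pxpy[pxpy > 0] * np.log2(pxpy[pxpy > 0])))
    hx = float(-np.sum(px[px > 0] * np.log2(px[px > 0])))
    hy = float(-np.sum(py[py > 0] * np.log2(py[py > 0])))
    hmax = max(hx, hy)
    imc1 = float((hxy - hxy1) / hmax) if hmax > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))) if hxy2 >= hxy else 0.0

    # maximal correlation coefficient: sqrt of 2nd-largest eigenvalue of Q
    with np.errstate(divide="ignore", invalid="ignore"):
        Q = np.zeros_like(p)
        ok = px > 0
        # Q[i, j] = sum_k p[i,k] p[j,k] / (px[i] py[k])
        w = np.where(py > 0, 1.0 / py, 0.0)
        Q[ok, :] = (p[ok, :] * w[None, :]) @ p.T / px[ok, None]
    ev = np.linalg.eigvals(Q)
    ev = np.sort(np.real(ev))[::-1]
    mcc = float(np.sqrt(max(0.0, ev[1]))) if len(ev) > 1 else 1.0

    shade = float(np.sum((ii + jj - mux - muy) ** 3 * p))
    prominence = float(np.sum((ii + jj - mux - muy) ** 4 * p))

    return {
        "glcm_Contrast": contrast,
        "glcm_Correlation": correlation,
        "glcm_JointEntropy": ent,
        "glcm_DifferenceEntropy": diff_entropy,
        "glcm_Idn": idn,
        "glcm_Idmn": idmn,
        "glcm_Imc1": imc1,
        "glcm_Imc2": imc2,
        "glcm_MCC": mcc,
        "glcm_ClusterShade": shade,
        "glcm_ClusterProminence": prominence,
    }


_GLCM_NAMES = (
    "glcm_Contrast",
    "glcm_Correlation",
    "glcm_JointEntropy",
    "glcm_DifferenceEntropy",
    "glcm_Idn",
    "glcm_Idmn",
    "glcm_Imc1",
    "glcm_Imc2",
    "glcm_MCC",
    "glcm_ClusterShade",
    "glcm_ClusterProminence",
)


def _glcm_features(level_img: np.ndarray, mask: np.ndarray, n_levels: int) -> dict[str, float]:
    per_dir = []
    for d in GLCM_DIRECTIONS:
        P = glcm_matrix(level_img, mask, d, n_levels)
        if P.sum() > 0:
            per_dir.append(glcm_features_from_matrix(P))
    if not per_dir:
        return {k: np.nan for k in _GLCM_NAMES}
    return {k: float(np.mean([f[k] for f in per_dir])) for k in _GLCM_NAMES}


# ---------------------------------------------------------------------------


def extract_static_features(
    volume: ImageVolume,
    mask: RoiMask,
    settings: ExtractionSettings | None = None,
    preprocessed: bool = False,
) -> StaticFeatureVector:
    """Extract the in-house feature families from one phase.

    Runs :func:`preprocess` first unless ``preprocessed=True``.  A
    single-voxel ROI yields NaN for shape anisotropy and GLCM features,
    with the reason recorded in ``nan_reasons`` rather than silently
    returning zeros.
    """
    settings = settings or ExtractionSettings()
    if not preprocessed:
        volume, mask = preprocess(volume, mask, settings)
    if volume.voxels.shape != mask.voxels.shape:
        raise ValueError("volume and mask shapes differ")

    roi = volume.voxels[mask.voxels]
    levels_roi = discretize(roi, settings.bin_width)
    values: dict[str, float] = {}
    families: dict[str, str] = {}
    reasons: dict[str, str] = {}

    fo = _first_order(roi, levels_roi)
    values.update(fo)
    families.update({k: "firstorder" for k in fo})

    sh = _shape_features(mask.voxels, mask.spacing)
    values.update(sh)
    families.update({k: "shape" for k in sh})
    if mask.n_voxels == 1:
        for k in ("shape_Elongation", "shape_Flatness", "shape_Sphericity"):
            values[k] = np.nan
            reasons[k] = "single-voxel ROI"

    # discretised level image over the full grid (levels valid inside ROI)
    level_img = np.ones_like(volume.voxels, dtype=np.int64)
    level_img[mask.voxels] = levels_roi
    n_levels = int(levels_roi.max())
    if mask.n_voxels == 1:
        gl = {k: np.nan for k in _GLCM_NAMES}
        reasons.update({k: "single-voxel ROI" for k in _GLCM_NAMES})
    else:
        gl = _glcm_features(level_img, mask.voxels, n_levels)
        for k, v in gl.items():
            if not np.isfinite(v):
                reasons[k] = "no valid co-occurrence pairs"
    values.update(gl)
    families.update({k: "glcm" for k in _GLCM_NAMES})

    return StaticFeatureVector(values=values, families=families, nan_reasons=reasons)


def extract_cohort_features(
    volumes: dict[str, dict[str, ImageVolume]],
    masks: dict[str, dict[str, RoiMask]],
    settings: ExtractionSettings | None = None,
) -> dict[str, pd.DataFrame]:
    """Extract features for every (patient, phase) into per-phase matrices.

    ``volumes[patient][phase]`` / ``masks[patient][phase]`` must cover the
    same keys.
    """
    per_phase: dict[str, dict[str, pd.Series]] = {}
    for pid, phases in volumes.items():
        for phase, vol in phases.items():
            fv = extract_static_features(vol, masks[pid][phase], settings)
            per_phase.setdefault(phase, {})[pid] = fv.as_series()
    return {phase: pd.DataFrame(rows).T.sort_index() for phase, rows in per_phase.items()}


def drop_constant_features(matrix: pd.DataFrame, tol: float = 1e-12) -> pd.DataFrame:
    """Drop features whose range across patients is below ``tol``.

    Mirrors the usual radiomics cleaning step of excluding features that
    take the same value in every patient.  Raises if nothing survives.
    """
    if len(matrix) < 2:
        raise ValueError("need at least 2 patients")
    rng = matrix.max(axis=0) - matrix.min(axis=0)
    keep = matrix.columns[(rng > tol).to_numpy()]
    n_dropped = matrix.shape[1] - len(keep)
    if len(keep) == 0:
        raise ValueError("no informative features: all columns are constant")
    if n_dropped:
        log.info("drop_constant_features: removed %d constant columns", n_dropped)
    return matrix[keep]
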