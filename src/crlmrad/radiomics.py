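"""Per-lesion radiomics feature extraction on CT image/mask pairs.

Preprocessing follows the fixed portal-venous CT recipe: resample to
isotropic 1 mm (B-spline for the image, nearest-neighbour for the binary
mask), clip to the [-100, 200] HU soft-tissue window, crop 1 mm around
the lesion, and discretize with a fixed 25 HU bin width (12 bins over the
default window).  Feature channels are the original image and
Laplacian-of-Gaussian filtered images at sigma 1-5 mm.

The native feature set is a verifiable subset of the standard radiomics
catalog: first-order statistics, mesh-free shape descriptors, and GLCM /
GLRLM texture families.  Externally computed full-catalog tables (e.g.
1,317-feature exports) are supported through :func:`ingest_feature_table`
rather than recomputed.

Conventions (stated because catalogs differ):
  * discretization: ``bin(v) = floor((v - clip_lo)/width) + 1`` with the
    upper clip value assigned to the top bin (no empty trailing bin);
  * GLCM: symmetric co-occurrences at distance 1 over the 13 unique 3-D
    directions, each direction's matrix normalized then the matrices
    averaged, features computed on the averaged matrix;
  * GLRLM: runs per direction restricted to in-mask voxels, feature
    values averaged over the 13 directions;
  * LoG: scale-normalized (sigma^2 x Laplacian-of-Gaussian), reflective
    boundaries, applied after resampling so sigma in mm equals sigma in
    voxels; all channels share the clip window + bin width rule.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DegenerateLesionError, IntegrityError, SchemaError
from .synthetic import LesionRecord

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "preprocess",
    "discretize",
    "log_filter",
    "first_order_features",
    "shape_features",
    "glcm_features",
    "glrlm_features",
    "extract_lesion",
    "ingest_feature_table",
    "load_nifti_pair",
    "feature_catalog",
]

# the 13 unique unit-offset directions of a 3-D 26-neighbourhood (half-space)
DIRECTIONS_13 = [
    (0, 0, 1),
    (0, 1, -1),
    (0, 1, 0),
    (0, 1, 1),
    (1, -1, -1),
    (1, -1, 0),
    (1, -1, 1),
    (1, 0, -1),
    (1, 0, 0),
    (1, 0, 1),
    (1, 1, -1),
    (1, 1, 0),
    (1, 1, 1),
]


@dataclass(frozen=True)
class PreprocessConfig:
    target_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    clip_lo_hu: float = -100.0
    clip_hi_hu: float = 200.0
    bin_width_hu: float = 25.0
    crop_margin_mm: float = 1.0
    log_sigmas_mm: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)

    def __post_init__(self):
        if not self.clip_lo_hu < self.clip_hi_hu:
            raise ValueError("clip_lo_hu must be < clip_hi_hu")
        if not self.bin_width_hu > 0:
            raise ValueError("bin_width_hu must be > 0")
        if any(s <= 0 for s in self.target_spacing_mm):
            raise ValueError("target spacing must be positive")
        if any(s <= 0 for s in self.log_sigmas_mm):
            raise ValueError("LoG sigmas must be positive")

    @property
    def n_bins(self) -> int:
        return int(np.ceil((self.clip_hi_hu - self.clip_lo_hu) / self.bin_width_hu))


def load_nifti_pair(image_path, mask_path) -> tuple[np.ndarray, np.ndarray, tuple]:
    """Read a NIfTI image/mask pair; returns arrays (z,y,x order) + spacing (z,y,x) mm."""
    import SimpleITK as sitk

    img = sitk.ReadImage(str(image_path))
    msk = sitk.ReadImage(str(mask_path))
    if img.GetSize() != msk.GetSize():
        raise SchemaError("image and mask grids differ")
    spacing = tuple(img.GetSpacing()[::-1])
    return (
        sitk.GetArrayFromImage(img).astype(float),
        (sitk.GetArrayFromImage(msk) > 0).astype(np.uint8),
        spacing,
    )


def _resample(arr: np.ndarray, spacing, target, *, is_mask: bool) -> np.ndarray:
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.asarray(arr, dtype=np.float64))
    img.SetSpacing(tuple(float(s) for s in spacing[::-1]))
    out_size = [
        max(1, int(round(n * s / t)))
        for n, s, t in zip(arr.shape[::-1], spacing[::-1], target[::-1])
    ]
    res = sitk.ResampleImageFilter()
    res.SetOutputSpacing(tuple(float(t) for t in target[::-1]))
    res.SetSize(out_size)
    res.SetOutputOrigin(img.GetOrigin())
    res.SetOutputDirection(img.GetDirection())
    res.SetInterpolator(sitk.sitkNearestNeighbor if is_mask else sitk.sitkBSpline)
    out = sitk.GetArrayFromImage(res.Execute(img))
    if is_mask:
        out = (out > 0.5).astype(np.uint8)
    return out


def preprocess(
    image: np.ndarray,
    mask: np.ndarray,
    spacing_mm,
    config: PreprocessConfig = PreprocessConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Resample, clip and crop an image/mask pair.

    B-spline interpolation for the image, nearest-neighbour for the mask
    (interpolated labels are ill-defined).  Values are clipped to
    ``[clip_lo_hu, clip_hi_hu]`` and both arrays cropped to the mask's
    bounding box dilated by ``crop_margin_mm``.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise SchemaError("image and mask shapes differ")
    if spacing_mm is None or any(s is None or s <= 0 for s in spacing_mm):
        raise SchemaError("voxel spacing metadata missing or invalid")
    if not mask.any():
        raise DegenerateLesionError("empty lesion mask")
    if tuple(spacing_mm) != tuple(config.target_spacing_mm):
        image = _resample(image, spacing_mm, config.target_spacing_mm, is_mask=False)
        mask = _resample(mask, spacing_mm, config.target_spacing_mm, is_mask=True)
        if not mask.any():
            raise DegenerateLesionError("lesion vanished during resampling")
    image = np.clip(image, config.clip_lo_hu, config.clip_hi_hu)
    margins = [
        int(round(config.crop_margin_mm / t)) for t in config.target_spacing_mm
    ]
    slices = []
    for axis, margin in enumerate(margins):
        proj = np.any(mask, axis=tuple(a for a in range(3) if a != axis))
        idx = np.where(proj)[0]
        lo = max(0, idx[0] - margin)
        hi = min(mask.shape[axis], idx[-1] + 1 + margin)
        slices.append(slice(lo, hi))
    slices = tuple(slices)
    return image[slices], mask[slices].astype(np.uint8)


def discretize(values: np.ndarray, config: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Fixed-bin-width discretization to integer labels 1..n_bins.

    ``bin(v) = floor((v - clip_lo)/width) + 1``; the right edge
    ``v == clip_hi`` falls in the top bin so the default window yields
    exactly 12 occupied-able bins.
    """
    v = np.asarray(values, dtype=float)
    bins = np.floor((v - config.clip_lo_hu) / config.bin_width_hu).astype(int) + 1
    return np.minimum(bins, config.n_bins)


def log_filter(image: np.ndarray, sigma_mm: float) -> np.ndarray:
    """Scale-normalized Laplacian-of-Gaussian response (sigma^2 * LoG).

    Assumes an isotropic 1 mm grid (run after :func:`preprocess`), so sigma
    in millimetres equals sigma in voxels.  Reflective boundary handling.
    Linear in the input; zero on constant images away from boundary effects.
    """
    if sigma_mm <= 0:
        raise ValueError("sigma must be > 0")
    smoothed = ndimage.gaussian_filter(
        np.asarray(image, dtype=float), sigma=sigma_mm, mode="reflect"
    )
    # discrete 6-point Laplacian after smoothing: exactly zero on constants,
    # unlike a truncated analytic LoG kernel
    return sigma_mm**2 * ndimage.laplace(smoothed, mode="reflect")


# ---------------------------------------------------------------------------
# feature families


def first_order_features(
    values: np.ndarray, config: PreprocessConfig = PreprocessConfig()
) -> dict[str, float]:
    """First-order statistics of the in-mask intensity sample.

    Skewness is the Fisher moment coefficient g1 and kurtosis the Pearson
    (non-excess) m4/m2^2, both 0-safe for constant samples; entropy is
    base-2 over occupied discretized bins.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise DegenerateLesionError("no in-mask voxels")
    mean = float(v.mean())
    var = float(v.var())  # population variance
    centered = v - mean
    if var > 0:
        skew = float((centered**3).mean() / var**1.5)
        kurt = float((centered**4).mean() / var**2)
    else:
        skew, kurt = 0.0, 0.0
    labels = discretize(v, config)
    counts = np.bincount(labels)[1:]
    p = counts[counts > 0] / v.size
    entropy = float(-(p * np.log2(p)).sum())
    return {
        "mean": mean,
        "median": float(np.median(v)),
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "energy": float((v**2).sum()),
        "minimum": float(v.min()),
        "maximum": float(v.max()),
        "range": float(v.max() - v.min()),
        "entropy": entropy,
    }


def shape_features(mask: np.ndarray, spacing_mm=(1.0, 1.0, 1.0)) -> dict[str, float]:
    """Voxel-based shape descriptors of a binary lesion mask.

    Volume counts voxels; surface area counts exposed voxel faces; the
    maximum 3-D diameter uses the voxel-centre convention (0 for a single
    voxel).  Sphericity = pi^(1/3) (6V)^(2/3) / A.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise DegenerateLesionError("empty lesion mask")
    sp = np.asarray(spacing_mm, dtype=float)
    voxel_vol = float(np.prod(sp))
    n_vox = int(mask.sum())
    volume = n_vox * voxel_vol
    # exposed faces: for each axis, count mask/non-mask transitions (padded)
    area = 0.0
    for axis in range(3):
        face = voxel_vol / sp[axis]
        padded = np.pad(mask.astype(np.int8), [(1, 1) if a == axis else (0, 0) for a in range(3)])
        area += float(np.count_nonzero(np.diff(padded, axis=axis))) * face
    coords = np.argwhere(mask) * sp
    if len(coords) == 1:
        diameter = 0.0
    else:
        pts = coords
        if len(pts) > 64:
            try:
                from scipy.spatial import ConvexHull

                hull = ConvexHull(pts, qhull_options="QJ")
                pts = pts[hull.vertices]
            except Exception:  # degenerate (coplanar) point sets
                pass
        diff = pts[:, None, :] - pts[None, :, :]
        diameter = float(np.sqrt((diff**2).sum(-1)).max())
    sphericity = float(np.pi ** (1 / 3) * (6 * volume) ** (2 / 3) / area)
    return {
        "volume_mm3": volume,
        "surface_area_mm2": area,
        "surface_to_volume_ratio": area / volume,
        "max_3d_diameter_mm": diameter,
        "sphericity": sphericity,
    }


def _glcm_matrix(labels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Mean of per-direction normalized symmetric co-occurrence matrices."""
    mats = []
    for d in DIRECTIONS_13:
        src = [slice(max(0, -o), labels.shape[a] - max(0, o)) for a, o in enumerate(d)]
        dst = [slice(max(0, o), labels.shape[a] - max(0, -o)) for a, o in enumerate(d)]
        src, dst = tuple(src), tuple(dst)
        ok = mask[src] & mask[dst]
        if not ok.any():
            continue
        a = labels[src][ok] - 1
        b = labels[dst][ok] - 1
        P = np.zeros((n_levels, n_levels))
        np.add.at(P, (a, b), 1.0)
        P = P + P.T
        mats.append(P / P.sum())
    if not mats:
        raise DegenerateLesionError("no in-mask voxel pairs for GLCM")
    return np.mean(mats, axis=0)


def glcm_features(
    labels: np.ndarray, mask: np.ndarray, n_levels: int | None = None
) -> dict[str, float]:
    """GLCM texture features from a discretized grid restricted to the mask."""
    labels = np.asarray(labels)
    mask = np.asarray(mask).astype(bool)
    if mask.sum() < 2:
        raise DegenerateLesionError("GLCM requires >= 2 in-mask voxels")
    if n_levels is None:
        n_levels = int(labels[mask].max())
    P = _glcm_matrix(labels, mask, n_levels)
    i = np.arange(1, n_levels + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    mu_x = float((i * px).sum())
    sigma_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    contrast = float((P * (ii - jj) ** 2).sum())
    if sigma_x > 0:
        correlation = float((P * (ii - mu_x) * (jj - mu_x)).sum() / sigma_x**2)
    else:
        correlation = 1.0  # single-level region: perfectly correlated by convention
    nz = P[P > 0]
    return {
        "contrast": contrast,
        "correlation": correlation,
        "joint_entropy": float(-(nz * np.log2(nz)).sum()),
        "energy": float((P**2).sum()),
        "homogeneity": float((P / (1.0 + np.abs(ii - jj))).sum()),
    }


def _runs_for_direction(labels, mask, d):
    """All maximal in-mask constant-label runs along direction d: (level, length)."""
    shape = labels.shape
    runs = []
    it = np.argwhere(mask)
    d = np.asarray(d)
    inside = lambda p: all(0 <= p[a] < shape[a] for a in range(3))
    mask_at = lambda p: inside(p) and bool(mask[tuple(p)])
    for p in it:
        prev = p - d
        if mask_at(prev) and labels[tuple(prev)] == labels[tuple(p)]:
            continue  # not a run start
        level = labels[tuple(p)]
        length = 1
        q = p + d
        while mask_at(q) and labels[tuple(q)] == level:
            length += 1
            q = q + d
        runs.append((int(level), length))
    return runs


def glrlm_features(
    labels: np.ndarray, mask: np.ndarray, n_levels: int | None = None
) -> dict[str, float]:
    """Run-length texture features, averaged over the 13 directions.

    Each direction contributes a run-length matrix over maximal in-mask
    runs; the five feature values (short/long-run emphasis, run-length and
    gray-level non-uniformity, run percentage) are averaged across
    directions.
    """
    labels = np.asarray(labels)
    mask = np.asarray(mask).astype(bool)
    n_vox = int(mask.sum())
    if n_vox < 2:
        raise DegenerateLesionError("GLRLM requires >= 2 in-mask voxels")
    if n_levels is None:
        n_levels = int(labels[mask].max())
    per_dir = {k: [] for k in ("sre", "lre", "rln", "gln", "rp")}
    for d in DIRECTIONS_13:
        runs = _runs_for_direction(labels, mask, d)
        lengths = np.array([r[1] for r in runs], dtype=float)
        levels = np.array([r[0] for r in runs], dtype=int)
        nr = len(runs)
        per_dir["sre"].append(float((1.0 / lengths**2).mean()))
        per_dir["lre"].append(float((lengths**2).mean()))
        _, len_counts = np.unique(lengths, return_counts=True)
        per_dir["rln"].append(float((len_counts.astype(float) ** 2).sum() / nr))
        _, lev_counts = np.unique(levels, return_counts=True)
        per_dir["gln"].append(float((lev_counts.astype(float) ** 2).sum() / nr))
        per_dir["rp"].append(nr / n_vox)
    return {
        "short_run_emphasis": float(np.mean(per_dir["sre"])),
        "long_run_emphasis": float(np.mean(per_dir["lre"])),
        "run_length_nonuniformity": float(np.mean(per_dir["rln"])),
        "gray_level_nonuniformity": float(np.mean(per_dir["gln"])),
        "run_percentage": float(np.mean(per_dir["rp"])),
    }


# ---------------------------------------------------------------------------
# lesion-level extraction


def _channel_names(config: PreprocessConfig) -> list[str]:
    names = ["original"]
    names += [f"log_sigma_{g:g}_mm" for g in config.log_sigmas_mm]
    return names


def feature_catalog(config: PreprocessConfig = PreprocessConfig()) -> list[str]:
    """Deterministic ordered list of all native feature names."""
    shape_names = [f"shape__{k}" for k in (
        "volume_mm3", "surface_area_mm2", "surface_to_volume_ratio",
        "max_3d_diameter_mm", "sphericity")]
    fo = ("mean", "median", "variance", "skewness", "kurtosis", "energy",
          "minimum", "maximum", "range", "entropy")
    glcm = ("contrast", "correlation", "joint_entropy", "energy", "homogeneity")
    glrlm = ("short_run_emphasis", "long_run_emphasis", "run_length_nonuniformity",
             "gray_level_nonuniformity", "run_percentage")
    names = list(shape_names)
    for ch in _channel_names(config):
        names += [f"{ch}__firstorder__{k}" for k in fo]
        names += [f"{ch}__glcm__{k}" for k in glcm]
        names += [f"{ch}__glrlm__{k}" for k in glrlm]
    return names


def extract_lesion(
    image: np.ndarray,
    mask: np.ndarray,
    spacing_mm,
    config: PreprocessConfig = PreprocessConfig(),
    *,
    patient_id: str = "NA",
    lesion_id: str = "NA",
) -> LesionRecord:
    """Full native extraction for one lesion.

    Preprocess, then shape features on the mask and first-order/GLCM/GLRLM
    on the original channel and each LoG channel.  Lesions of < 2 voxels
    after resampling keep shape + first-order features with texture values
    set to NaN (logged).  All channels share the clip-window + bin-width
    discretization rule; LoG responses are clipped to the same window,
    an assumption stated in the module docstring.
    """
    img, msk = preprocess(image, mask, spacing_mm, config)
    feats: dict[str, float] = {}
    shape = shape_features(msk, config.target_spacing_mm)
    feats.update({f"shape__{k}": v for k, v in shape.items()})
    degenerate = msk.sum() < 2
    if degenerate:
        logger.warning(
            "lesion %s/%s has %d voxel(s) after resampling; texture features set to NaN",
            patient_id, lesion_id, int(msk.sum()),
        )
    channels = {"original": img}
    for g in config.log_sigmas_mm:
        channels[f"log_sigma_{g:g}_mm"] = np.clip(
            log_filter(img, g), config.clip_lo_hu, config.clip_hi_hu
        )
    for ch, arr in channels.items():
        vals = arr[msk.astype(bool)]
        for k, v in first_order_features(vals, config).items():
            feats[f"{ch}__firstorder__{k}"] = v
        if degenerate:
            for fam, keys in (
                ("glcm", ("contrast", "correlation", "joint_entropy", "energy", "homogeneity")),
                ("glrlm", ("short_run_emphasis", "long_run_emphasis",
                           "run_length_nonuniformity", "gray_level_nonuniformity",
                           "run_percentage")),
            ):
                for k in keys:
                    feats[f"{ch}__{fam}__{k}"] = float("nan")
            continue
        labels = np.where(msk.astype(bool), discretize(arr, config), 0)
        for k, v in glcm_features(labels, msk, config.n_bins).items():
            feats[f"{ch}__glcm__{k}"] = v
        for k, v in glrlm_features(labels, msk, config.n_bins).items():
            feats[f"{ch}__glrlm__{k}"] = v
    return LesionRecord(
        patient_id=patient_id,
        lesion_id=lesion_id,
        volume_mm3=shape["volume_mm3"],
        features=feats,
    )


# ---------------------------------------------------------------------------
# external feature tables


def ingest_feature_table(
    path,
    *,
    patient_col: str = "patient_id",
    lesion_col: str = "lesion_id",
    volume_col: str = "volume_mm3",
    expected_features: list[str] | None = None,
    strict: bool = True,
) -> list[LesionRecord]:
    """Load an externally computed per-lesion feature table (CSV/TSV).

    Validates the key columns, rejects duplicate (patient, lesion) keys and
    non-numeric cells with row-level diagnostics.  When ``expected_features``
    is given, unknown columns raise under ``strict=True`` and warn (and pass
    through) otherwise.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    for col in (patient_col, lesion_col, volume_col):
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} missing from {path.name}")
    feature_cols = [c for c in df.columns if c not in (patient_col, lesion_col, volume_col)]
    if expected_features is not None:
        unknown = sorted(set(feature_cols) - set(expected_features))
        if unknown:
            msg = f"unknown feature columns in {path.name}: {unknown}"
            if strict:
                raise SchemaError(msg)
            warnings.warn(msg)
    dup = df.duplicated(subset=[patient_col, lesion_col])
    if dup.any():
        keys = df.loc[dup, [patient_col, lesion_col]].to_records(index=False).tolist()
        raise IntegrityError(f"duplicate lesion keys: {keys}")
    records = []
    for idx, row in df.iterrows():
        vol = row[volume_col]
        try:
            vol = float(vol)
        except (TypeError, ValueError):
            vol = float("nan")
        if not np.isfinite(vol) or vol <= 0:
            raise SchemaError(f"row {idx}: volume {row[volume_col]!r} is not a positive number")
        feats = {}
        for c in feature_cols:
            try:
                feats[c] = float(row[c])
            except (TypeError, ValueError):
                raise SchemaError(f"row {idx}: non-numeric value {row[c]!r} in column {c!r}")
            if not np.isfinite(feats[c]):
                raise SchemaError(f"row {idx}: missing/non-finite value in column {c!r}")
        records.append(
            LesionRecord(
                patient_id=str(row[patient_col]),
                lesion_id=str(row[lesion_col]),
                volume_mm3=vol,
                features=feats,
            )
        )
    return records
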