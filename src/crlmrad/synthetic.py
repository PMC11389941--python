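"""Synthetic cohort and phantom generation.

Emulates the statistical structure the downstream analysis assumes for a
colorectal-liver-metastasis (CRLM) registry: patients carry one or more
segmented lesions with per-lesion radiomics-like feature vectors and
volumes, a clinical profile sufficient for the Fong clinical risk score,
and right-censored time-to-recurrence (TTR) and disease-specific-survival
(DSS) outcomes drawn from an exponential proportional-hazards model.

The hazard signal is planted in the *largest* lesion's informative
features (log-normal volumes decide which lesion that is), mirroring the
empirical finding that largest-lesion aggregation carries most prognostic
information, so that aggregation strategies can be ranked on recovery.

Small 3-D phantoms (ellipsoidal lesion in a noisy background, NIfTI-
writable) provide a test substrate for the feature-extraction module.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigurationError, CrlmradError

__all__ = [
    "SyntheticConfig",
    "PhantomSpec",
    "LesionRecord",
    "ClinicalProfile",
    "SurvivalOutcome",
    "PatientBundle",
    "generate_cohort",
    "true_linear_predictor",
    "generate_phantom",
    "cohort_to_tables",
    "save_cohort",
    "load_cohort",
    "save_phantom",
]

INFORMATIVE_PREFIX = "texture__informative__f"
NOISE_PREFIX = "texture__noise__f"


@dataclass(frozen=True)
class LesionRecord:
    """One segmented lesion: its feature map plus volume (mm^3)."""

    patient_id: str
    lesion_id: str
    volume_mm3: float
    features: dict[str, float]

    def __post_init__(self):
        if not self.volume_mm3 > 0:
            raise ValueError(f"lesion {self.lesion_id}: volume must be positive")


@dataclass(frozen=True)
class ClinicalProfile:
    """Preoperative clinical fields feeding the Fong clinical risk score."""

    node_positive_primary: bool
    disease_free_interval_months: float
    n_crlm: int
    largest_crlm_cm: float
    cea_ng_ml: float

    def __post_init__(self):
        if self.disease_free_interval_months < 0:
            raise ValueError("disease-free interval must be >= 0")
        if self.n_crlm < 1:
            raise ValueError("n_crlm must be >= 1")
        if not self.largest_crlm_cm > 0:
            raise ValueError("largest CRLM size must be positive")
        if self.cea_ng_ml < 0:
            raise ValueError("CEA must be >= 0")


@dataclass(frozen=True)
class SurvivalOutcome:
    """Right-censored survival record: follow-up time in months + event flag."""

    time: float
    event: bool

    def __post_init__(self):
        if not (np.isfinite(self.time) and self.time > 0):
            raise ValueError("survival time must be finite and positive")


@dataclass(frozen=True)
class PatientBundle:
    """A patient's lesions, clinical profile and the two study outcomes."""

    patient_id: str
    lesions: tuple[LesionRecord, ...]
    profile: ClinicalProfile
    ttr: SurvivalOutcome
    dss: SurvivalOutcome

    @property
    def largest_lesion(self) -> LesionRecord:
        # volume ties broken by lexicographic lesion_id, matching aggregation
        return sorted(self.lesions, key=lambda r: (-r.volume_mm3, r.lesion_id))[0]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generation parameters for a synthetic CRLM cohort.

    ``true_betas`` are log-hazard coefficients per SD of the informative
    features of the largest lesion; ``crs_beta`` is the log hazard of a
    high (3-5) vs low (0-2) Fong score.  TTR times are exponential with
    rate ``baseline_hazard * exp(linear predictor)``; DSS times use
    ``dss_hazard_scale`` times the baseline rate (death accrues more
    slowly than recurrence).  Censoring combines an administrative
    follow-up horizon with an independent exponential dropout rate.
    """

    n_patients: int = 300
    lesion_count_mean_extra: float = 2.0  # lesion count = 1 + Poisson(this)
    n_features: int = 60
    n_informative: int = 3
    true_betas: tuple[float, ...] = (0.7, -0.7, 0.7)
    crs_beta: float = 0.4
    baseline_hazard: float = 0.06  # events per month for TTR
    dss_hazard_scale: float = 0.5
    censor_horizon_months: float = 84.0
    censor_rate: float = 0.03  # random dropout, events per month
    correlation: float = 0.3
    block_size: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if self.n_features < 1 or self.n_informative < 0:
            raise ConfigurationError("feature counts must be >= 1 (informative >= 0)")
        if self.n_informative > self.n_features:
            raise ConfigurationError("n_informative must be <= n_features")
        if len(self.true_betas) != self.n_informative:
            raise ConfigurationError("true_betas length must equal n_informative")
        if not self.baseline_hazard > 0:
            raise ConfigurationError("baseline_hazard must be > 0")
        if self.lesion_count_mean_extra < 0:
            raise ConfigurationError("lesion_count_mean_extra must be >= 0")
        if not 0 <= self.correlation < 1:
            raise ConfigurationError("correlation must be in [0, 1)")
        if self.censor_rate < 0 or not self.censor_horizon_months > 0:
            raise ConfigurationError("invalid censoring law")

    @property
    def feature_names(self) -> list[str]:
        inf = [f"{INFORMATIVE_PREFIX}{i:02d}" for i in range(self.n_informative)]
        noise = [
            f"{NOISE_PREFIX}{i:02d}" for i in range(self.n_features - self.n_informative)
        ]
        return inf + noise


def _draw_features(rng: np.random.Generator, n: int, cfg: SyntheticConfig) -> np.ndarray:
    """Equicorrelated Gaussian blocks: rho within blocks of ``block_size``."""
    rho = cfg.correlation
    out = np.empty((n, cfg.n_features))
    for start in range(0, cfg.n_features, cfg.block_size):
        width = min(cfg.block_size, cfg.n_features - start)
        shared = rng.standard_normal((n, 1))
        own = rng.standard_normal((n, width))
        out[:, start : start + width] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * own
    return out


def _fong_high(profile: ClinicalProfile) -> bool:
    # local copy of the dichotomized Fong rule so generation does not import
    # the analysis-side module (kept consistent by a cross-module test)
    score = (
        int(profile.node_positive_primary)
        + int(profile.disease_free_interval_months < 12)
        + int(profile.n_crlm > 1)
        + int(profile.largest_crlm_cm > 5)
        + int(profile.cea_ng_ml > 200)
    )
    return score >= 3


def _diameter_cm(volume_mm3: float) -> float:
    """Equivalent-sphere diameter in cm from a volume in mm^3."""
    return 2.0 * (3.0 * volume_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0) / 10.0


def generate_cohort(config: SyntheticConfig) -> list[PatientBundle]:
    """Generate a reproducible synthetic cohort under ``config``.

    Per patient: 1 + Poisson lesions with log-normal volumes and
    equicorrelated Gaussian feature vectors; clinical fields spanning Fong
    scores 0-5 with most mass at 2-3; TTR/DSS exponential PH times whose
    linear predictor reads the informative features off the largest lesion
    plus ``crs_beta`` for a high dichotomized Fong score.
    """
    rng = np.random.default_rng(config.seed)
    names = config.feature_names
    betas = np.asarray(config.true_betas, dtype=float)
    bundles: list[PatientBundle] = []
    for i in range(config.n_patients):
        pid = f"P{i:04d}"
        m = 1 + rng.poisson(config.lesion_count_mean_extra)
        volumes = np.exp(rng.normal(9.0, 1.2, size=m))  # mm^3, median ~8.1 cm^3
        feats = _draw_features(rng, m, config)
        lesions = tuple(
            LesionRecord(
                patient_id=pid,
                lesion_id=f"L{j:02d}",
                volume_mm3=float(volumes[j]),
                features=dict(zip(names, feats[j].tolist())),
            )
            for j in range(m)
        )
        largest_idx = int(np.argmax(volumes))  # first max = smallest lesion_id on ties
        profile = ClinicalProfile(
            node_positive_primary=bool(rng.random() < 0.6),
            disease_free_interval_months=float(rng.gamma(1.2, 12.0)),
            n_crlm=m,
            largest_crlm_cm=_diameter_cm(float(volumes.max())),
            cea_ng_ml=float(np.exp(rng.normal(3.3, 1.8))),
        )
        lp = float(feats[largest_idx, : config.n_informative] @ betas)
        lp += config.crs_beta * float(_fong_high(profile))

        outcomes = {}
        for key, rate0 in (
            ("ttr", config.baseline_hazard),
            ("dss", config.baseline_hazard * config.dss_hazard_scale),
        ):
            latent = rng.exponential(1.0 / (rate0 * np.exp(lp)))
            if config.censor_rate > 0:
                dropout = rng.exponential(1.0 / config.censor_rate)
            else:
                dropout = np.inf
            censor = min(dropout, config.censor_horizon_months)
            observed = min(latent, censor)
            outcomes[key] = SurvivalOutcome(
                time=float(max(observed, 1e-6)), event=bool(latent <= censor)
            )
        bundles.append(
            PatientBundle(
                patient_id=pid,
                lesions=lesions,
                profile=profile,
                ttr=outcomes["ttr"],
                dss=outcomes["dss"],
            )
        )
    return bundles


def true_linear_predictor(bundle: PatientBundle, config: SyntheticConfig) -> float:
    """The exact log-hazard linear predictor used at generation time.

    Serves as the oracle risk score for parameter-recovery tests: under the
    proportional-hazards generating law no scoring rule has higher expected
    concordance.
    """
    largest = bundle.largest_lesion
    lp = 0.0
    for b, name in zip(config.true_betas, config.feature_names):
        if name not in largest.features:
            raise CrlmradError(
                f"bundle {bundle.patient_id} lacks informative feature {name!r}; "
                "was it generated under this config?"
            )
        lp += b * largest.features[name]
    lp += config.crs_beta * float(_fong_high(bundle.profile))
    return float(lp)


# ---------------------------------------------------------------------------
# cohort <-> tables


def cohort_to_tables(bundles: list[PatientBundle]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten a cohort into (lesions, patients) DataFrames.

    Lesions: patient_id, lesion_id, volume_mm3, one column per feature.
    Patients: clinical fields plus ttr_months/ttr_event/dss_months/dss_event.
    """
    lesion_rows = []
    for b in bundles:
        for les in b.lesions:
            row = {
                "patient_id": les.patient_id,
                "lesion_id": les.lesion_id,
                "volume_mm3": les.volume_mm3,
            }
            row.update(les.features)
            lesion_rows.append(row)
    patient_rows = []
    for b in bundles:
        patient_rows.append(
            {
                "patient_id": b.patient_id,
                "node_positive_primary": int(b.profile.node_positive_primary),
                "disease_free_interval_months": b.profile.disease_free_interval_months,
                "n_crlm": b.profile.n_crlm,
                "largest_crlm_cm": b.profile.largest_crlm_cm,
                "cea_ng_ml": b.profile.cea_ng_ml,
                "ttr_months": b.ttr.time,
                "ttr_event": int(b.ttr.event),
                "dss_months": b.dss.time,
                "dss_event": int(b.dss.event),
            }
        )
    return pd.DataFrame(lesion_rows), pd.DataFrame(patient_rows)


def save_cohort(bundles: list[PatientBundle], outdir, config: SyntheticConfig | None = None):
    """Write lesions.csv, patients.csv and a JSON sidecar of generation parameters."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lesions, patients = cohort_to_tables(bundles)
    lesions.to_csv(outdir / "lesions.csv", index=False)
    patients.to_csv(outdir / "patients.csv", index=False)
    meta = {"n_patients": len(bundles)}
    if config is not None:
        meta["config"] = dataclasses.asdict(config)
    (outdir / "cohort.json").write_text(json.dumps(meta, indent=2, default=list))
    return outdir


def load_cohort(indir) -> list[PatientBundle]:
    """Rebuild PatientBundle objects from saved lesions.csv/patients.csv."""
    indir = Path(indir)
    lesions = pd.read_csv(indir / "lesions.csv")
    patients = pd.read_csv(indir / "patients.csv")
    feature_cols = [
        c for c in lesions.columns if c not in ("patient_id", "lesion_id", "volume_mm3")
    ]
    bundles = []
    grouped = dict(tuple(lesions.groupby("patient_id", sort=False)))
    for _, row in patients.iterrows():
        pid = row["patient_id"]
        sub = grouped[pid]
        recs = tuple(
            LesionRecord(
                patient_id=pid,
                lesion_id=str(lr["lesion_id"]),
                volume_mm3=float(lr["volume_mm3"]),
                features={c: float(lr[c]) for c in feature_cols},
            )
            for lr in sub.to_dict("records")
        )
        profile = ClinicalProfile(
            node_positive_primary=bool(row["node_positive_primary"]),
            disease_free_interval_months=float(row["disease_free_interval_months"]),
            n_crlm=int(row["n_crlm"]),
            largest_crlm_cm=float(row["largest_crlm_cm"]),
            cea_ng_ml=float(row["cea_ng_ml"]),
        )
        bundles.append(
            PatientBundle(
                patient_id=pid,
                lesions=recs,
                profile=profile,
                ttr=SurvivalOutcome(float(row["ttr_months"]), bool(row["ttr_event"])),
                dss=SurvivalOutcome(float(row["dss_months"]), bool(row["dss_event"])),
            )
        )
    return bundles


# ---------------------------------------------------------------------------
# phantoms


@dataclass(frozen=True)
class PhantomSpec:
    """A small 3-D CT-like phantom: noisy background + one textured ellipsoid."""

    grid_shape: tuple[int, int, int] = (40, 40, 40)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    background_hu: tuple[float, float] = (0.0, 10.0)  # mean, SD
    lesion_center_mm: tuple[float, float, float] = (20.0, 20.0, 20.0)
    lesion_radii_mm: tuple[float, float, float] = (8.0, 8.0, 8.0)
    lesion_mean_hu: float = 80.0
    texture_length_mm: float = 2.0  # correlation length of in-lesion noise
    texture_amplitude_hu: float = 15.0

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing_mm):
            raise ConfigurationError("spacing_mm must be positive")
        if any(r <= 0 for r in self.lesion_radii_mm):
            raise ConfigurationError("lesion radii must be positive")
        for c, r, n, sp in zip(
            self.lesion_center_mm, self.lesion_radii_mm, self.grid_shape, self.spacing_mm
        ):
            if c - r < 0 or c + r > (n - 1) * sp:
                raise ConfigurationError("lesion ellipsoid must fit inside the grid")


def generate_phantom(spec: PhantomSpec, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Return (image HU, binary mask) arrays; geometry is seed-free.

    The mask voxelizes the ellipsoid at voxel centers.  In-mask intensity is
    ``lesion_mean_hu`` plus correlated Gaussian noise (Gaussian-smoothed white
    noise rescaled to ``texture_amplitude_hu`` SD); background is independent
    Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in spec.grid_shape)
    coords = np.meshgrid(
        *(np.arange(n) * sp for n, sp in zip(shape, spec.spacing_mm)), indexing="ij"
    )
    q = sum(
        ((c - c0) / r) ** 2
        for c, c0, r in zip(coords, spec.lesion_center_mm, spec.lesion_radii_mm)
    )
    mask = q <= 1.0
    bg_mean, bg_sd = spec.background_hu
    image = rng.normal(bg_mean, bg_sd, size=shape)
    if spec.texture_amplitude_hu > 0:
        white = rng.standard_normal(shape)
        sig_vox = [spec.texture_length_mm / sp for sp in spec.spacing_mm]
        smooth = ndimage.gaussian_filter(white, sigma=sig_vox, mode="reflect")
        sd = smooth.std()
        texture = smooth / sd * spec.texture_amplitude_hu if sd > 0 else smooth
    else:
        texture = np.zeros(shape)
    image[mask] = spec.lesion_mean_hu + texture[mask]
    return image.astype(np.float64), mask.astype(np.uint8)


def save_phantom(image: np.ndarray, mask: np.ndarray, spec: PhantomSpec, outdir, stem="phantom"):
    """Write the phantom as a NIfTI image/mask pair."""
    import SimpleITK as sitk

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for arr, suffix in ((image, "image"), (mask, "mask")):
        img = sitk.GetImageFromArray(np.asarray(arr))
        img.SetSpacing(tuple(float(s) for s in spec.spacing_mm[::-1]))
        sitk.WriteImage(img, str(outdir / f"{stem}_{suffix}.nii.gz"))
    return outdir
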