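"""Multi-lesion feature aggregation and the Fong clinical risk score.

Patients often carry several liver metastases, each with its own feature
vector; survival modelling needs one vector per patient.  Seven
aggregation strategies are implemented: the single largest or smallest
lesion; unweighted and volume-weighted averages (optionally restricted to
the three largest lesions); and the largest lesion augmented with a
tumour-burden feature (lesion count or total volume).

For strategies combining several lesions, geometric (shape/size)
features are *summed* across lesions while texture and intensity
features are averaged — size adds up across the tumour burden whereas
texture describes tissue character.  The geometric/texture taxonomy
defaults to "shape family = geometric, everything else = texture" and is
overridable because first-order intensity statistics are arguably
either.

The Fong clinical risk score adds one point per adverse preoperative
criterion — node-positive primary, disease-free interval < 12 months,
more than one metastasis, largest lesion > 5 cm, CEA > 200 ng/mL — and
is dichotomized low (0-2) vs high (3-5).
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence

import numpy as np

from .errors import CrlmradError, TaxonomyError
from .synthetic import ClinicalProfile, LesionRecord, PatientBundle

__all__ = [
    "STRATEGIES",
    "default_roles",
    "aggregate",
    "aggregate_cohort",
    "fong_crs",
    "dichotomize_crs",
    "BURDEN_FEATURES",
]

STRATEGIES = (
    "largest_only",
    "smallest_only",
    "unweighted_average",
    "weighted_average",
    "weighted_average_top3",
    "largest_plus_count",
    "largest_plus_total_volume",
)

BURDEN_FEATURES = ("n_lesions", "total_volume_mm3")


def default_roles(feature_names: Iterable[str]) -> dict[str, str]:
    """Default geometric/texture taxonomy.

    Shape-family features (``shape__`` prefix) and appended burden features
    are geometric; all intensity/texture families are texture.
    """
    roles = {}
    for name in feature_names:
        if name.startswith("shape__") or name in BURDEN_FEATURES:
            roles[name] = "geometric"
        else:
            roles[name] = "texture"
    return roles


def _sorted_by_volume(lesions: Sequence[LesionRecord]) -> list[LesionRecord]:
    # decreasing volume; ties broken by lexicographic lesion_id for determinism
    return sorted(lesions, key=lambda r: (-r.volume_mm3, r.lesion_id))


def _combine(
    lesions: Sequence[LesionRecord],
    roles: Mapping[str, str],
    weights: np.ndarray | None,
) -> dict[str, float]:
    """Sum geometric features; (weighted-)average texture features."""
    names = list(lesions[0].features)
    out = {}
    if weights is None:
        weights = np.full(len(lesions), 1.0 / len(lesions))
    for name in names:
        role = roles.get(name)
        if role is None:
            raise TaxonomyError(f"feature {name!r} has no geometric/texture role")
        vals = np.array([les.features[name] for les in lesions], dtype=float)
        if role == "geometric":
            out[name] = float(vals.sum())
        elif role == "texture":
            out[name] = float((weights * vals).sum())
        else:
            raise TaxonomyError(f"unknown role {role!r} for feature {name!r}")
    return out


def aggregate(
    lesions: Sequence[LesionRecord],
    strategy: str,
    roles: Mapping[str, str] | None = None,
) -> dict[str, float]:
    """Collapse one patient's lesions into a patient-level feature map.

    ``largest_only``/``smallest_only`` copy the selected lesion verbatim;
    the averaging strategies sum geometric and average texture features,
    with volume-ratio weights (renormalized over the included lesions)
    where the strategy is weighted; the two burden strategies copy the
    largest lesion and append ``n_lesions`` or ``total_volume_mm3``.
    """
    if not lesions:
        raise CrlmradError("cannot aggregate zero lesions")
    if strategy not in STRATEGIES:
        raise CrlmradError(f"unknown aggregation strategy {strategy!r}")
    catalogs = {tuple(sorted(les.features)) for les in lesions}
    if len(catalogs) != 1:
        raise CrlmradError("lesions do not share one feature catalog")
    if roles is None:
        roles = default_roles(lesions[0].features)
    ordered = _sorted_by_volume(lesions)
    volumes = np.array([les.volume_mm3 for les in ordered], dtype=float)

    if strategy == "largest_only":
        return dict(ordered[0].features)
    if strategy == "smallest_only":
        return dict(ordered[-1].features)
    if strategy == "unweighted_average":
        return _combine(ordered, roles, None)
    if strategy == "weighted_average":
        return _combine(ordered, roles, volumes / volumes.sum())
    if strategy == "weighted_average_top3":
        top = ordered[:3]
        w = volumes[: len(top)]
        return _combine(top, roles, w / w.sum())
    out = dict(ordered[0].features)
    if strategy == "largest_plus_count":
        out["n_lesions"] = float(len(lesions))
    else:  # largest_plus_total_volume
        out["total_volume_mm3"] = float(volumes.sum())
    return out


def aggregate_cohort(bundles: Sequence[PatientBundle], strategy: str, roles=None):
    """Patient-level feature table (pandas DataFrame indexed by patient_id)."""
    import pandas as pd

    rows = {b.patient_id: aggregate(b.lesions, strategy, roles) for b in bundles}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "patient_id"
    return df


def fong_crs(profile: ClinicalProfile) -> int:
    """Fong clinical risk score (0-5), one point per adverse criterion.

    Criteria are strict as printed: DFI < 12 months, size > 5 cm,
    CEA > 200 ng/mL, node-positive primary, more than one metastasis.
    """
    return (
        int(profile.node_positive_primary)
        + int(profile.disease_free_interval_months < 12)
        + int(profile.n_crlm > 1)
        + int(profile.largest_crlm_cm > 5)
        + int(profile.cea_ng_ml > 200)
    )


def dichotomize_crs(score: int) -> str:
    """Dichotomize the Fong score: 'low' for 0-2, 'high' for 3-5."""
    if not 0 <= score <= 5:
        raise CrlmradError(f"Fong score must lie in [0, 5], got {score}")
    return "low" if score <= 2 else "high"
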