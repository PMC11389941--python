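"""Feature extraction: preprocessing arithmetic and exact texture oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from crlmrad.errors import DegenerateLesionError, IntegrityError, SchemaError
from crlmrad.radiomics import (
    DIRECTIONS_13,
    PreprocessConfig,
    discretize,
    extract_lesion,
    feature_catalog,
    first_order_features,
    glcm_features,
    glrlm_features,
    ingest_feature_table,
    log_filter,
    preprocess,
    shape_features,
)
from crlmrad.synthetic import PhantomSpec, generate_phantom

CFG = PreprocessConfig()


# ---------------------------------------------------------------------------
# independent oracles


def oracle_glcm(labels, mask, n_levels):
    """Exhaustive neighbour-pair enumeration, matrices averaged across directions."""
    mats = []
    shape = labels.shape
    for d in DIRECTIONS_13:
        P = np.zeros((n_levels, n_levels))
        for p in np.argwhere(mask):
            q = p + np.array(d)
            if all(0 <= q[a] < shape[a] for a in range(3)) and mask[tuple(q)]:
                a, b = labels[tuple(p)] - 1, labels[tuple(q)] - 1
                P[a, b] += 1
                P[b, a] += 1
        if P.sum() > 0:
            mats.append(P / P.sum())
    P = np.mean(mats, axis=0)
    lv = np.arange(1, n_levels + 1)
    px = P.sum(axis=1)
    mu = (lv * px).sum()
    var = (((lv - mu) ** 2) * px).sum()
    contrast = sum(P[i, j] * (i - j) ** 2 for i in range(n_levels) for j in range(n_levels))
    if var > 0:
        corr = sum(
            P[i, j] * (i + 1 - mu) * (j + 1 - mu)
            for i in range(n_levels) for j in range(n_levels)
        ) / var
    else:
        corr = 1.0
    ent = -sum(p * math.log2(p) for p in P.ravel() if p > 0)
    energy = (P**2).sum()
    homog = sum(
        P[i, j] / (1 + abs(i - j)) for i in range(n_levels) for j in range(n_levels)
    )
    return dict(contrast=contrast, correlation=corr, joint_entropy=ent,
                energy=energy, homogeneity=homog)


def oracle_glrlm(labels, mask, n_levels):
    """Exhaustive maximal-run scan per direction, features averaged."""
    shape = labels.shape
    n_vox = int(mask.sum())
    feats = {k: [] for k in ("sre", "lre", "rln", "gln", "rp")}
    for d in DIRECTIONS_13:
        d = np.array(d)
        runs = []
        seen = set()
        for p in sorted(map(tuple, np.argwhere(mask))):
            if p in seen:
                continue
            # walk back to the true run start
            start = np.array(p)
            while True:
                prev = start - d
                if (all(0 <= prev[a] < shape[a] for a in range(3))
                        and mask[tuple(prev)]
                        and labels[tuple(prev)] == labels[tuple(start)]):
                    start = prev
                else:
                    break
            # walk forward collecting the run
            run = []
            q = start
            while (all(0 <= q[a] < shape[a] for a in range(3))
                   and mask[tuple(q)]
                   and labels[tuple(q)] == labels[tuple(start)]):
                run.append(tuple(q))
                q = q + d
            for cell in run:
                seen.add(cell)
            runs.append((int(labels[tuple(start)]), len(run)))
        nr = len(runs)
        lengths = [r for _, r in runs]
        levels = [g for g, _ in runs]
        feats["sre"].append(sum(1.0 / r**2 for r in lengths) / nr)
        feats["lre"].append(sum(float(r**2) for r in lengths) / nr)
        feats["rln"].append(sum(lengths.count(r) ** 2 for r in set(lengths)) / nr)
        feats["gln"].append(sum(levels.count(g) ** 2 for g in set(levels)) / nr)
        feats["rp"].append(nr / n_vox)
    return {
        "short_run_emphasis": np.mean(feats["sre"]),
        "long_run_emphasis": np.mean(feats["lre"]),
        "run_length_nonuniformity": np.mean(feats["rln"]),
        "gray_level_nonuniformity": np.mean(feats["gln"]),
        "run_percentage": np.mean(feats["rp"]),
    }


def random_grid(rng, max_side=5, n_levels=4):
    shape = tuple(rng.integers(2, max_side + 1, size=3))
    labels = rng.integers(1, n_levels + 1, size=shape)
    mask = rng.random(shape) < 0.7
    if mask.sum() < 2:
        mask.flat[:2] = True
    return labels, mask, n_levels


# ---------------------------------------------------------------------------
# preprocessing


class TestPreprocess:
    def test_clipping_upper_bound(self):
        img = np.full((6, 6, 6), 300.0)
        mask = np.zeros((6, 6, 6), np.uint8)
        mask[2:4, 2:4, 2:4] = 1
        out, m = preprocess(img, mask, (1, 1, 1), CFG)
        assert np.all(out == 200.0)

    def test_resampling_doubles_grid(self):
        img = np.zeros((10, 10, 10))
        mask = np.zeros((10, 10, 10), np.uint8)
        mask[3:7, 3:7, 3:7] = 1
        out, m = preprocess(img, mask, (2.0, 2.0, 2.0), CFG)
        # the 4-voxel (8 mm) mask extent becomes ~8 voxels at 1 mm (+1 mm margin)
        assert all(7 <= s <= 11 for s in m.shape)
        assert m.any()

    def test_single_voxel_margin_box(self):
        img = np.zeros((7, 7, 7))
        mask = np.zeros((7, 7, 7), np.uint8)
        mask[3, 3, 3] = 1
        _, m = preprocess(img, mask, (1, 1, 1), CFG)
        assert m.shape == (3, 3, 3)

    def test_empty_mask_rejected(self):
        with pytest.raises(DegenerateLesionError):
            preprocess(np.zeros((4, 4, 4)), np.zeros((4, 4, 4), np.uint8), (1, 1, 1), CFG)

    def test_missing_spacing_rejected(self):
        mask = np.ones((4, 4, 4), np.uint8)
        with pytest.raises(SchemaError):
            preprocess(np.zeros((4, 4, 4)), mask, (None, 1, 1), CFG)


@pytest.mark.parametrize("value,expected", [(-100.0, 1), (200.0, 12), (-75.0, 2),
                                            (-99.9, 1), (174.99, 11), (175.0, 12)])
def test_discretize_edges(value, expected):
    assert discretize(np.array([value]), CFG)[0] == expected


class TestLogFilter:
    def test_constant_image_zero_response(self):
        img = np.full((16, 16, 16), 50.0)
        assert np.allclose(log_filter(img, 2.0), 0.0, atol=1e-9)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        img = rng.standard_normal((12, 12, 12))
        assert np.allclose(log_filter(2 * img, 1.5), 2 * log_filter(img, 1.5))

    def test_scale_space_extremum_near_blob_width(self):
        """A Gaussian blob of width sigma0 responds most strongly near sigma0."""
        sigma0 = 3.0
        ax = np.arange(33) - 16
        xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
        blob = np.exp(-(xx**2 + yy**2 + zz**2) / (2 * sigma0**2))
        responses = {
            s: abs(log_filter(blob, s)[16, 16, 16]) for s in (1.0, 2.0, 3.0, 4.0, 5.0)
        }
        best = max(responses, key=responses.get)
        assert abs(best - sigma0) <= 1.0

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            log_filter(np.zeros((4, 4, 4)), 0.0)


# ---------------------------------------------------------------------------
# feature families


class TestFirstOrder:
    def test_constant_sample(self):
        f = first_order_features(np.full(20, 42.0), CFG)
        assert f["variance"] == 0.0 and f["entropy"] == 0.0 and f["skewness"] == 0.0

    def test_two_point_sample(self):
        f = first_order_features(np.array([-100.0, 200.0]), CFG)
        assert f["range"] == 300.0 and f["mean"] == 50.0

    def test_matches_direct_formulas(self):
        rng = np.random.default_rng(4)
        v = rng.uniform(-100, 200, size=300)
        f = first_order_features(v, CFG)
        mean = v.sum() / v.size
        var = ((v - mean) ** 2).sum() / v.size
        assert abs(f["mean"] - mean) < 1e-9
        assert abs(f["variance"] - var) < 1e-9
        assert abs(f["skewness"] - ((v - mean) ** 3).mean() / var**1.5) < 1e-9
        assert abs(f["kurtosis"] - ((v - mean) ** 4).mean() / var**2) < 1e-9
        assert abs(f["energy"] - (v**2).sum()) < 1e-6
        labels = np.floor((v + 100) / 25).astype(int)
        counts = np.bincount(labels)
        p = counts[counts > 0] / v.size
        assert abs(f["entropy"] + (p * np.log2(p)).sum()) < 1e-9


class TestShape:
    def test_cube_volume_and_surface(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[1:4, 1:4, 1:4] = True
        f = shape_features(mask, (1, 1, 1))
        assert f["volume_mm3"] == 27.0
        assert f["surface_area_mm2"] == 54.0
        assert abs(f["max_3d_diameter_mm"] - 2 * np.sqrt(3)) < 1e-12

    def test_single_voxel_degenerate_diameter(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        f = shape_features(mask, (1, 1, 1))
        assert f["max_3d_diameter_mm"] == 0.0
        assert f["volume_mm3"] == 1.0

    def test_translation_invariance(self):
        base = np.zeros((12, 12, 12), bool)
        base[2:5, 3:7, 2:4] = True
        shifted = np.roll(base, (3, 2, 4), axis=(0, 1, 2))
        f1 = shape_features(base, (1, 1, 1))
        f2 = shape_features(shifted, (1, 1, 1))
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], abs=1e-12)


class TestGLCM:
    def test_uniform_region(self):
        labels = np.ones((3, 3, 3), int)
        mask = np.ones((3, 3, 3), bool)
        f = glcm_features(labels, mask, 1)
        assert f["contrast"] == 0.0 and f["energy"] == 1.0 and f["correlation"] == 1.0

    def test_2x2_patch_matches_enumeration(self):
        labels = np.array([[[1], [2]], [[2], [1]]])
        mask = np.ones((2, 2, 1), bool)
        f = glcm_features(labels, mask, 2)
        o = oracle_glcm(labels, mask, 2)
        for k in f:
            assert f[k] == pytest.approx(o[k], abs=1e-12)

    def test_level_shift_leaves_contrast_unchanged(self):
        rng = np.random.default_rng(1)
        labels, mask, n = random_grid(rng)
        f1 = glcm_features(labels, mask, n)
        f2 = glcm_features(labels + 3, mask, n + 3)
        assert f1["contrast"] == pytest.approx(f2["contrast"], abs=1e-12)

    def test_random_grids_match_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            labels, mask, n = random_grid(rng)
            f = glcm_features(labels, mask, n)
            o = oracle_glcm(labels, mask, n)
            for k in f:
                assert f[k] == pytest.approx(o[k], abs=1e-10)

    def test_too_few_voxels_rejected(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[0, 0, 0] = True
        with pytest.raises(DegenerateLesionError):
            glcm_features(np.ones((3, 3, 3), int), mask, 1)

    def test_intensity_shift_moves_mean_not_contrast(self):
        """Adding one bin width within the clip window shifts the first-order
        mean by that constant and leaves GLCM contrast unchanged."""
        rng = np.random.default_rng(6)
        vals = rng.uniform(-90, 150, size=(4, 4, 4))
        mask = np.ones((4, 4, 4), bool)
        f1 = first_order_features(vals[mask], CFG)
        f2 = first_order_features((vals + 25.0)[mask], CFG)
        assert f2["mean"] - f1["mean"] == pytest.approx(25.0, abs=1e-9)
        c1 = glcm_features(discretize(vals, CFG), mask, CFG.n_bins)
        c2 = glcm_features(discretize(vals + 25.0, CFG), mask, CFG.n_bins)
        assert c1["contrast"] == pytest.approx(c2["contrast"], abs=1e-12)


class TestGLRLM:
    def test_uniform_line_single_run(self):
        labels = np.ones((1, 1, 6), int)
        mask = np.ones((1, 1, 6), bool)
        f = glrlm_features(labels, mask, 1)
        # along the line axis: one run of length 6; the other 12 directions
        # each contribute 6 runs of length 1
        assert f["long_run_emphasis"] == pytest.approx((36 + 12 * 1) / 13)

    def test_alternating_line_short_runs(self):
        labels = np.tile(np.array([1, 2]), 4)[None, None, :]
        mask = np.ones((1, 1, 8), bool)
        f = glrlm_features(labels, mask, 2)
        assert f["short_run_emphasis"] == 1.0
        assert f["run_percentage"] == 1.0

    def test_random_grids_match_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            labels, mask, n = random_grid(rng)
            f = glrlm_features(labels, mask, n)
            o = oracle_glrlm(labels, mask, n)
            for k in f:
                assert f[k] == pytest.approx(o[k], abs=1e-10)


# ---------------------------------------------------------------------------
# lesion-level extraction


class TestExtractLesion:
    @pytest.fixture(scope="class")
    def phantom(self):
        spec = PhantomSpec(grid_shape=(24, 24, 24), lesion_center_mm=(12, 12, 12),
                           lesion_radii_mm=(5, 5, 5), texture_amplitude_hu=0.0)
        return spec, generate_phantom(spec, seed=0)

    def test_homogeneous_phantom_zero_contrast(self, phantom):
        spec, (img, mask) = phantom
        rec = extract_lesion(img, mask, spec.spacing_mm)
        assert rec.features["original__glcm__contrast"] == 0.0

    def test_catalog_arithmetic_and_stability(self, phantom):
        spec, (img, mask) = phantom
        rec = extract_lesion(img, mask, spec.spacing_mm)
        cat = feature_catalog()
        # 3 families x (10+5+5 stats) per channel, 6 channels, + 5 shape
        assert len(cat) == (10 + 5 + 5) * (1 + 5) + 5
        assert list(rec.features) == cat
        assert feature_catalog() == cat

    def test_shape_is_intensity_free(self):
        spec_a = PhantomSpec(texture_amplitude_hu=0.0)
        spec_b = PhantomSpec(texture_amplitude_hu=30.0)
        img_a, mask_a = generate_phantom(spec_a, seed=5)
        img_b, mask_b = generate_phantom(spec_b, seed=5)
        rec_a = extract_lesion(img_a, mask_a, spec_a.spacing_mm)
        rec_b = extract_lesion(img_b, mask_b, spec_b.spacing_mm)
        for k in rec_a.features:
            if k.startswith("shape__"):
                assert rec_a.features[k] == rec_b.features[k]

    def test_translation_invariance_of_features(self):
        spec = PhantomSpec(grid_shape=(30, 30, 30), lesion_center_mm=(12, 12, 12),
                           lesion_radii_mm=(4, 4, 4), texture_amplitude_hu=10.0)
        img, mask = generate_phantom(spec, seed=2)
        shift = (4, 5, 3)
        img_s = np.roll(img, shift, axis=(0, 1, 2))
        mask_s = np.roll(mask, shift, axis=(0, 1, 2))
        r1 = extract_lesion(img, mask, spec.spacing_mm)
        r2 = extract_lesion(img_s, mask_s, spec.spacing_mm)
        for k, v in r1.features.items():
            assert v == pytest.approx(r2.features[k], rel=1e-9, abs=1e-9)

    def test_degenerate_lesion_flags_texture_missing(self):
        img = np.zeros((5, 5, 5))
        mask = np.zeros((5, 5, 5), np.uint8)
        mask[2, 2, 2] = 1
        rec = extract_lesion(img, mask, (1, 1, 1))
        assert np.isnan(rec.features["original__glcm__contrast"])
        assert rec.features["shape__volume_mm3"] == 1.0


# ---------------------------------------------------------------------------
# external tables


class TestIngest:
    def _write(self, tmp_path, df, name="feat.csv"):
        p = tmp_path / name
        df.to_csv(p, index=False)
        return p

    def test_well_formed_table(self, tmp_path):
        df = pd.DataFrame({
            "patient_id": ["P1", "P1"], "lesion_id": ["L1", "L2"],
            "volume_mm3": [100.0, 50.0], "fa": [1.0, 2.0], "fb": [0.5, 0.25],
        })
        recs = ingest_feature_table(self._write(tmp_path, df))
        assert len(recs) == 2
        assert recs[0].features == {"fa": 1.0, "fb": 0.5}

    def test_duplicate_key_named_in_error(self, tmp_path):
        df = pd.DataFrame({
            "patient_id": ["P1", "P1"], "lesion_id": ["L1", "L1"],
            "volume_mm3": [100.0, 50.0], "fa": [1.0, 2.0],
        })
        with pytest.raises(IntegrityError, match="L1"):
            ingest_feature_table(self._write(tmp_path, df))

    def test_unknown_column_strict_vs_lenient(self, tmp_path):
        df = pd.DataFrame({
            "patient_id": ["P1"], "lesion_id": ["L1"], "volume_mm3": [10.0],
            "fa": [1.0], "mystery": [9.9],
        })
        path = self._write(tmp_path, df)
        with pytest.raises(SchemaError, match="mystery"):
            ingest_feature_table(path, expected_features=["fa"], strict=True)
        with pytest.warns(UserWarning, match="mystery"):
            recs = ingest_feature_table(path, expected_features=["fa"], strict=False)
        assert "mystery" in recs[0].features

    def test_non_numeric_cell_diagnosed(self, tmp_path):
        df = pd.DataFrame({
            "patient_id": ["P1"], "lesion_id": ["L1"], "volume_mm3": [10.0],
            "fa": ["oops"],
        })
        with pytest.raises(SchemaError, match="row 0"):
            ingest_feature_table(self._write(tmp_path, df))

    def test_missing_volume_rejected(self, tmp_path):
        df = pd.DataFrame({"patient_id": ["P1"], "lesion_id": ["L1"], "fa": [1.0]})
        with pytest.raises(SchemaError, match="volume"):
            ingest_feature_table(self._write(tmp_path, df))
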