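"""Radiomics: manifest counts, preprocessing, per-group oracles, invariances."""

import numpy as np
import pytest

from ufrad.radiomics import (
    GROUP_COUNTS,
    TOTAL_FEATURES,
    build_manifest,
    discretize,
    extract_all,
    extract_first_order,
    extract_shape,
    extract_texture,
    normalize_image,
    resample_isotropic,
    wavelet_features,
)
from ufrad.radiomics.texture import glcm_features, glcm_matrix
from ufrad.radiomics.wavelet import decompose


class TestManifest:
    def test_group_counts_frozen(self):
        m = build_manifest()
        assert m.group_counts() == {
            "first_order": 17,
            "shape": 7,
            "texture": 162,
            "wavelet": 1432,
        }
        assert len(m.entries) == TOTAL_FEATURES == 1618
        assert len(set(m.names)) == 1618

    def test_wavelet_arithmetic_identity(self):
        # 8 sub-bands x (17 first-order + 162 texture) = 1432
        per_band = GROUP_COUNTS["first_order"] + GROUP_COUNTS["texture"]
        assert 8 * per_band == GROUP_COUNTS["wavelet"] == 1432


class TestPreprocess:
    def test_normalize_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        v = normalize_image(rng.gamma(2.0, 5.0, size=(6, 7, 8)))
        assert abs(v.mean()) < 1e-9 and abs(v.std() - 1) < 1e-9

    def test_normalize_idempotent_and_affine_invariant(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(5, 6, 7))
        n1 = normalize_image(x)
        assert np.allclose(normalize_image(n1), n1)
        assert np.allclose(normalize_image(3.2 * x - 40.0), n1)

    def test_normalize_constant_rejected(self):
        with pytest.raises(ValueError):
            normalize_image(np.full((4, 4, 4), 3.0))

    def test_resample_identity_at_target(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=(5, 6, 7))
        m = np.zeros((5, 6, 7), bool)
        m[1:4, 1:5, 2:6] = True
        v2, m2, sp = resample_isotropic(v, m, (1.0, 1.0, 1.0))
        assert np.allclose(v2, v) and np.array_equal(m2, m) and sp == (1.0,) * 3

    def test_resample_conserves_mask_volume(self):
        # 2 mm slab upsampled to 1 mm: physical volume within one voxel layer
        m = np.zeros((8, 10, 10), bool)
        m[2:6, 2:8, 2:8] = True
        v = np.random.default_rng(3).normal(size=m.shape)
        _, m2, _ = resample_isotropic(v, m, (2.0, 1.0, 1.0))
        vol_before = m.sum() * 2.0
        vol_after = m2.sum() * 1.0
        layer = 2 * m[0].size  # one voxel layer along the resampled axis
        assert abs(vol_after - vol_before) <= layer

    def test_resample_constant_image_stays_constant(self):
        m = np.zeros((6, 6, 6), bool)
        m[2:5, 2:5, 2:5] = True
        v2, _, _ = resample_isotropic(np.full((6, 6, 6), 4.0), m, (2.0, 2.0, 2.0))
        assert np.allclose(v2, 4.0)


class TestFirstOrder:
    def test_constant_region_limits(self):
        v = np.full((4, 4, 4), 2.5)
        m = np.ones_like(v, bool)
        f = extract_first_order(v, m)
        assert f["variance"] == 0 and f["entropy"] == 0 and f["uniformity"] == 1
        assert f["skewness"] == 0 and f["kurtosis"] == 0

    def test_two_voxel_hand_arithmetic(self):
        v = np.zeros((1, 1, 2))
        v[0, 0, 1] = 2.0
        f = extract_first_order(v, np.ones_like(v, bool))
        assert f["mean"] == 1.0 and f["range"] == 2.0 and f["variance"] == 1.0

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(4)
        v = rng.normal(2.0, 3.0, size=(5, 6, 7))
        m = rng.random((5, 6, 7)) < 0.5
        f = extract_first_order(v, m, spacing_mm=(1.0, 1.0, 1.0))
        x = v[m]
        sd = x.std()
        assert f["mean"] == pytest.approx(x.mean(), abs=1e-10)
        assert f["variance"] == pytest.approx(x.var(), abs=1e-10)
        assert f["skewness"] == pytest.approx(
            np.mean((x - x.mean()) ** 3) / sd**3, abs=1e-10
        )
        assert f["energy"] == pytest.approx(np.sum(x**2), rel=1e-12)
        assert f["rms"] == pytest.approx(np.sqrt(np.mean(x**2)), rel=1e-12)
        assert f["mad"] == pytest.approx(np.mean(np.abs(x - x.mean())), rel=1e-12)
        assert f["p10"] == pytest.approx(np.percentile(x, 10), rel=1e-12)


class TestShape:
    def test_single_voxel_degenerate_values(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        f = extract_shape(m, (1.0, 1.0, 1.0))
        assert f["volume_mm3"] == 1.0
        assert f["max_3d_diameter_mm"] == 0.0
        assert np.isfinite(list(f.values())).all()

    def test_ball_sphericity_converges_to_one(self):
        sph = []
        for r in (4, 8, 14):
            n = 2 * r + 3
            zz, yy, xx = np.mgrid[:n, :n, :n]
            c = n // 2
            ball = ((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) <= r**2
            sph.append(extract_shape(ball, (1.0, 1.0, 1.0))["sphericity"])
        assert np.all(np.diff(sph) > 0) or sph[-1] > 0.95
        assert sph[-1] > 0.9

    def test_rod_more_elongated_than_cube(self):
        rod = np.zeros((3, 3, 22), bool)
        rod[1, 1, 1:21] = True
        cube = np.zeros((8, 8, 8), bool)
        cube[1:7, 1:7, 1:7] = True
        e_rod = extract_shape(rod)["elongation"]
        e_cube = extract_shape(cube)["elongation"]
        assert e_rod > 5 * e_cube
        assert e_cube == pytest.approx(1.0, abs=0.05)

    def test_rod_diameter(self):
        rod = np.zeros((3, 3, 22), bool)
        rod[1, 1, 1:21] = True
        assert extract_shape(rod)["max_3d_diameter_mm"] == pytest.approx(19.0)


class TestTexture:
    def test_toy_glcm_hand_enumeration(self):
        # image [[1,1],[1,2]], offset (0,1): ordered pairs (1,1) and (1,2);
        # symmetric counting doubles them: {(1,1): 2, (1,2): 1, (2,1): 1}.
        vol = np.array([[[1.0, 1.0], [1.0, 2.0]]])  # (z=1, y=2, x=2)
        mask = np.ones_like(vol, bool)
        levels = discretize(vol, mask, n_bins=2)
        P = glcm_matrix(levels, mask, (0, 0, 1), 2)
        assert np.allclose(P, [[0.5, 0.25], [0.25, 0.0]])
        f = glcm_features(P)
        assert f["contrast"] == pytest.approx(0.5)
        assert f["maximum_probability"] == pytest.approx(0.5)
        assert f["joint_energy"] == pytest.approx(0.25 + 2 * 0.0625)

    def test_constant_region_limits(self):
        v = np.full((3, 4, 4), 1.0)
        m = np.ones_like(v, bool)
        f = extract_texture(v, m)
        assert f["glcm_contrast_a0"] == 0.0
        assert f["glcm_joint_energy_a0"] == 1.0

    def test_feature_count_is_162(self, phantom):
        f = extract_texture(phantom.ultrafast.data[5], phantom.tumor_mask)
        assert len(f) == 162

    def test_glcm_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(6)
        vol = rng.integers(0, 5, size=(3, 5, 5)).astype(float)
        mask = rng.random((3, 5, 5)) < 0.7
        mask[0, 0, 0] = True
        n_bins = 5
        levels = discretize(vol, mask, n_bins)
        for key, off in [("a0", (0, 0, 1)), ("a45", (0, 1, 1)), ("a135", (0, 1, -1))]:
            P = glcm_matrix(levels, mask, off, n_bins)
            # brute force: enumerate every voxel pair
            C = np.zeros((n_bins, n_bins))
            dz, dy, dx = off
            for z, y, x in np.argwhere(mask):
                z2, y2, x2 = z + dz, y + dy, x + dx
                if (
                    0 <= z2 < 3 and 0 <= y2 < 5 and 0 <= x2 < 5 and mask[z2, y2, x2]
                ):
                    C[levels[z, y, x] - 1, levels[z2, y2, x2] - 1] += 1
            C = C + C.T
            if C.sum():
                C /= C.sum()
            assert np.allclose(P, C, atol=1e-12)

    def test_glrlm_runs_hand_counted(self):
        from ufrad.radiomics.texture import glrlm_matrix

        # one line: 1 1 2 2 2 1 -> runs: (1,len2), (2,len3), (1,len1)
        vol = np.array([[[1, 1, 2, 2, 2, 1]]], dtype=float)
        mask = np.ones_like(vol, bool)
        levels = discretize(vol, mask, 2)
        R = glrlm_matrix(levels, "a0", 2)
        assert R[0, 1] == 1 and R[1, 2] == 1 and R[0, 0] == 1
        assert R.sum() == 3


class TestWavelet:
    def test_eight_subbands_same_shape(self):
        v = np.random.default_rng(7).normal(size=(6, 9, 8))
        bands = decompose(v)
        assert list(bands) == ["LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH"]
        assert all(b.shape == v.shape for b in bands.values())

    def test_constant_image_highpass_vanishes(self):
        v = np.full((8, 8, 8), 5.0)
        bands = decompose(v)
        for name, band in bands.items():
            if "H" in name:
                assert np.allclose(band, 0.0, atol=1e-10)
        m = np.zeros((8, 8, 8), bool)
        m[2:6, 2:6, 2:6] = True
        f = wavelet_features(v, m)
        assert f["wav_HHH_fo_variance"] == 0.0

    def test_feature_count_is_1432(self, small_phantom):
        f = wavelet_features(small_phantom.ultrafast.data[5], small_phantom.tumor_mask)
        assert len(f) == 1432


class TestExtractAll:
    def test_vector_length_and_finiteness(self, phantom):
        fv = extract_all(phantom.ultrafast.data[5], phantom.tumor_mask)
        assert len(fv) == 1618
        assert np.isfinite(fv.to_numpy()).all()
        manifest = build_manifest()
        assert list(fv.index) == manifest.names

    def test_deterministic(self, small_phantom):
        a = extract_all(small_phantom.standard.data[1], small_phantom.tumor_mask)
        b = extract_all(small_phantom.standard.data[1], small_phantom.tumor_mask)
        assert np.array_equal(a.to_numpy(), b.to_numpy())

    def test_translation_invariance(self):
        # geometry keeps the padded bounding box inside the grid so the
        # crop around the lesion is identical up to translation
        rng = np.random.default_rng(8)
        vol = rng.normal(size=(26, 28, 28))
        mask = np.zeros((26, 28, 28), bool)
        mask[9:15, 10:17, 10:17] = True
        vol[mask] += 3.0
        shifted_vol = np.roll(vol, (2, 3, -2), axis=(0, 1, 2))
        shifted_mask = np.roll(mask, (2, 3, -2), axis=(0, 1, 2))
        a = extract_all(vol, mask)
        b = extract_all(shifted_vol, shifted_mask)
        # normalization uses whole-volume statistics which np.roll preserves
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-6)
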