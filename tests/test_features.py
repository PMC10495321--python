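"""Color features against hand arithmetic; GLCM against a brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

from leafn.features import (
    COLOR_FEATURE_NAMES,
    FEATURE_NAMES,
    GLCM_ANGLES,
    color_features,
    extract_table,
    glcm,
    glcm_stats,
    quantize_gray,
    texture_features,
)
from leafn.synthgen import generate_fixture

FULL = np.ones


# ---------------------------------------------------------------------------
# independent oracle: brute-force pair enumeration over all pixel pairs

_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def oracle_glcm(gray, valid, angle, levels, distance=1):
    dr, dc = (distance * o for o in _OFFSETS[angle])
    counts = np.zeros((levels, levels))
    h, w = gray.shape
    for i in range(h):
        for j in range(w):
            i2, j2 = i + dr, j + dc
            if 0 <= i2 < h and 0 <= j2 < w and valid[i, j] and valid[i2, j2]:
                counts[gray[i, j], gray[i2, j2]] += 1
    counts = counts + counts.T
    return counts / counts.sum()


def oracle_stats(p):
    L = p.shape[0]
    asm = idm = con = ent = sij = 0.0
    for i in range(L):
        for j in range(L):
            v = p[i, j]
            asm += v * v
            idm += v / (1 + (i - j) ** 2)
            con += (i - j) ** 2 * v
            if v > 0:
                ent -= v * np.log(v)
            sij += i * j * v
    pi, pj = p.sum(1), p.sum(0)
    u1 = sum(i * pi[i] for i in range(L))
    u2 = sum(j * pj[j] for j in range(L))
    s1 = np.sqrt(sum((i - u1) ** 2 * pi[i] for i in range(L)))
    s2 = np.sqrt(sum((j - u2) ** 2 * pj[j] for j in range(L)))
    cor = float("nan") if s1 < 1e-12 or s2 < 1e-12 else (sij - u1 * u2) / (s1 * s2)
    return {"ASM": asm, "IDM": idm, "CON": con, "ENT": ent, "COR": cor}


class TestColorFeatures:
    def test_flat_gray_hand_values(self):
        img = generate_fixture("flat", (8, 8), value=0.5)
        f = color_features(img, FULL((8, 8), bool))
        assert f["R"] == f["G"] == f["B"] == pytest.approx(0.5)
        assert f["G/R"] == pytest.approx(1.0)
        assert f["G-R"] == 0.0
        assert f["(B-G-R)/(B+G)"] == pytest.approx(-0.5)
        assert f["r"] == pytest.approx(1 / 3) and f["g"] == pytest.approx(1 / 3)
        assert f["gr"] == f["gb"] == f["br"] == pytest.approx(0.0)
        assert f["S"] == 0.0 and f["V"] == pytest.approx(0.5)
        # CIELAB lightness of sRGB 0.5 gray: 116 * (0.5^2.2-ish linearized)^(1/3) - 16
        assert f["L*"] == pytest.approx(53.39, abs=0.05)
        assert f["a*"] == pytest.approx(0.0, abs=0.05)

    def test_pure_green_chromaticity(self):
        img = np.zeros((4, 4, 3))
        img[..., 1] = 1.0
        f = color_features(img, FULL((4, 4), bool))
        assert (f["r"], f["g"], f["b"]) == pytest.approx((0.0, 1.0, 0.0))
        assert f["H"] == pytest.approx(120 / 360)
        assert f["S"] == 1.0 and f["V"] == 1.0
        assert f["G/R"] == pytest.approx(1.0 / 1e-6)  # epsilon-guarded ratio

    def test_two_tone_means(self):
        img = generate_fixture("two_tone", (4, 4), colors=((0.2, 0.6, 0.2), (0.4, 0.8, 0.4)))
        f = color_features(img, FULL((4, 4), bool))
        assert (f["R"], f["G"], f["B"]) == pytest.approx((0.3, 0.7, 0.3))
        assert f["G-R"] == pytest.approx(0.4)

    def test_normalized_group_closure_and_antisymmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            img = np.broadcast_to(rng.random(3), (4, 4, 3)).copy()
            f = color_features(img, FULL((4, 4), bool))
            assert f["r"] + f["g"] + f["b"] == pytest.approx(1.0, abs=1e-9)
            assert f["gr"] == pytest.approx(-(f["r"] - f["g"]), abs=1e-12)

    def test_mask_locality(self):
        """Changing any background pixel never changes any feature."""
        rng = np.random.default_rng(3)
        img = rng.random((10, 10, 3))
        mask = np.zeros((10, 10), bool)
        mask[2:8, 2:8] = True
        before = extract_table([img], [mask]).iloc[0]
        img2 = img.copy()
        img2[~mask] = rng.random(((~mask).sum(), 3))
        after = extract_table([img2], [mask]).iloc[0]
        pd.testing.assert_series_equal(before, after)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            color_features(np.zeros((4, 4, 3)), np.zeros((4, 4), bool))


class TestQuantizeGray:
    def test_checkerboard_two_levels(self):
        img = generate_fixture("checkerboard", (4, 4), levels=(0.0, 1.0))
        gray, valid, degenerate = quantize_gray(img, FULL((4, 4), bool), levels=2)
        assert not degenerate
        np.testing.assert_array_equal(gray[:2, :2], [[0, 1], [1, 0]])

    def test_flat_is_degenerate(self):
        img = generate_fixture("flat", (4, 4), value=0.3)
        with pytest.warns(UserWarning, match="degenerate"):
            gray, _, degenerate = quantize_gray(img, FULL((4, 4), bool))
        assert degenerate and np.all(gray == 0)

    def test_linear_ramp_maps_column_to_level(self):
        w = 64
        ramp = np.broadcast_to(np.linspace(0, 1, w)[None, :, None], (4, w, 3)).copy()
        gray, _, _ = quantize_gray(ramp, FULL((4, w), bool), levels=64)
        np.testing.assert_array_equal(gray[0], np.arange(64))

    def test_bad_levels_rejected(self):
        img = generate_fixture("flat", (4, 4))
        with pytest.raises(ValueError):
            quantize_gray(img, FULL((4, 4), bool), levels=1)


class TestGlcm:
    def test_two_row_image_horizontal(self):
        gray = np.array([[0, 0], [1, 1]])
        p = glcm(gray, FULL((2, 2), bool), angle=0, levels=2).probabilities
        np.testing.assert_allclose(p, [[0.5, 0.0], [0.0, 0.5]])

    def test_two_row_image_vertical(self):
        gray = np.array([[0, 0], [1, 1]])
        p = glcm(gray, FULL((2, 2), bool), angle=90, levels=2).probabilities
        np.testing.assert_allclose(p, [[0.0, 0.5], [0.5, 0.0]])

    def test_constant_image_single_cell(self):
        p = glcm(np.zeros((3, 3), int), FULL((3, 3), bool), angle=45, levels=1).probabilities
        np.testing.assert_allclose(p, [[1.0]])

    def test_matches_bruteforce_oracle_with_masks(self):
        """Matrix and statistics agree with pair enumeration to 1e-12 on
        random small images with random validity masks, at all four angles."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            h, w = rng.integers(2, 9, size=2)
            levels = int(rng.integers(2, 5))
            gray = rng.integers(0, levels, size=(h, w))
            valid = rng.random((h, w)) < 0.8
            for angle in GLCM_ANGLES:
                dr, dc = _OFFSETS[angle]
                shifted = np.zeros_like(valid)
                # skip configurations with no valid pair at this offset
                try:
                    m = glcm(gray, valid, angle=angle, levels=levels)
                except ValueError:
                    continue
                expected = oracle_glcm(gray, valid, angle, levels)
                np.testing.assert_allclose(m.probabilities, expected, atol=1e-12)
                got = glcm_stats(m)
                want = oracle_stats(expected)
                for k in ("ASM", "IDM", "CON", "ENT"):
                    assert got[k] == pytest.approx(want[k], abs=1e-12)
                if np.isnan(want["COR"]):
                    assert np.isnan(got["COR"])
                else:
                    assert got["COR"] == pytest.approx(want["COR"], abs=1e-12)

    def test_matches_skimage_on_full_rectangles(self):
        """Dual route: scikit-image's graycomatrix agrees on unmasked images."""
        from skimage.feature import graycomatrix

        rng = np.random.default_rng(5)
        gray = rng.integers(0, 8, size=(12, 15)).astype(np.uint8)
        # our 45/135 use image convention (row index grows downward), which
        # mirrors scikit-image's trigonometric convention: 45 deg <-> 3pi/4
        for angle, theta in zip(GLCM_ANGLES, (0, 3 * np.pi / 4, np.pi / 2, np.pi / 4)):
            ours = glcm(gray, FULL((12, 15), bool), angle=angle, levels=8).probabilities
            ref = graycomatrix(gray, [1], [theta], levels=8, symmetric=True, normed=True)
            np.testing.assert_allclose(ours, ref[:, :, 0, 0], atol=1e-12)

    def test_no_valid_pairs_raises(self):
        valid = np.zeros((3, 3), bool)
        valid[0, 0] = True  # isolated pixel: no neighbour at any offset
        with pytest.raises(ValueError):
            glcm(np.zeros((3, 3), int), valid, angle=0, levels=1)


class TestGlcmStats:
    def test_single_cell_matrix(self):
        from leafn.features import GlcmMatrix

        m = GlcmMatrix(np.array([[1.0]]), 1, 1, 0)
        s = glcm_stats(m)
        assert s["ASM"] == 1.0 and s["IDM"] == 1.0
        assert s["CON"] == 0.0 and s["ENT"] == 0.0
        assert np.isnan(s["COR"])

    def test_diagonal_half_half(self):
        from leafn.features import GlcmMatrix

        m = GlcmMatrix(np.diag([0.5, 0.5]), 2, 1, 0)
        s = glcm_stats(m)
        assert s["ASM"] == pytest.approx(0.5)
        assert s["IDM"] == pytest.approx(1.0)
        assert s["CON"] == pytest.approx(0.0)
        assert s["ENT"] == pytest.approx(np.log(2))
        assert s["COR"] == pytest.approx(1.0)

    def test_antidiagonal_half_half(self):
        from leafn.features import GlcmMatrix

        m = GlcmMatrix(np.array([[0.0, 0.5], [0.5, 0.0]]), 2, 1, 0)
        s = glcm_stats(m)
        assert s["ASM"] == pytest.approx(0.5)
        assert s["IDM"] == pytest.approx(0.5)
        assert s["CON"] == pytest.approx(1.0)
        assert s["ENT"] == pytest.approx(np.log(2))
        assert s["COR"] == pytest.approx(-1.0)

    def test_entropy_zero_iff_asm_one(self):
        rng = np.random.default_rng(8)
        from leafn.features import GlcmMatrix

        for _ in range(20):
            raw = rng.random((4, 4))
            p = raw + raw.T
            p /= p.sum()
            s = glcm_stats(GlcmMatrix(p, 4, 1, 0))
            assert (s["ENT"] == 0.0) == (s["ASM"] == pytest.approx(1.0))


class TestGlcmStatsProperties:
    """Range invariants of the five statistics over arbitrary valid matrices."""

    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra.numpy import arrays

    @given(
        arrays(
            float,
            (5, 5),
            elements=st.floats(0.0, 1.0, allow_nan=False),
        ).filter(lambda a: a.sum() > 1e-6)
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_stat_ranges(self, raw):
        from leafn.features import GlcmMatrix

        p = raw + raw.T
        p /= p.sum()
        s = glcm_stats(GlcmMatrix(p, 5, 1, 0))
        assert 0 < s["ASM"] <= 1 + 1e-12
        assert 0 < s["IDM"] <= 1 + 1e-12
        assert s["CON"] >= 0
        assert s["ENT"] >= 0
        assert np.isnan(s["COR"]) or -1 - 1e-9 <= s["COR"] <= 1 + 1e-9
        # entropy/energy duality on the boundary
        if s["ENT"] == 0.0:
            assert s["ASM"] == pytest.approx(1.0)


class TestTextureFeatures:
    def test_flat_leaf_degenerate_path(self):
        img = generate_fixture("flat", (8, 8), value=0.4)
        with pytest.warns(UserWarning, match="degenerate"):
            t = texture_features(img, FULL((8, 8), bool))
        assert (t["ASM"], t["IDM"], t["CON"], t["ENT"]) == (1.0, 1.0, 0.0, 0.0)
        assert np.isnan(t["COR"])

    def test_rotation_by_90_degrees_invariant(self):
        rng = np.random.default_rng(11)
        img = rng.random((16, 16, 3))
        mask = FULL((16, 16), bool)
        t0 = texture_features(img, mask, levels=8)
        t90 = texture_features(np.rot90(img).copy(), mask, levels=8)
        for k in ("ASM", "IDM", "CON", "ENT", "COR"):
            assert t0[k] == pytest.approx(t90[k], abs=1e-12)

    def test_checkerboard_per_angle_contrast_matches_oracle(self):
        img = generate_fixture("checkerboard", (8, 8), levels=(0.0, 1.0))
        mask = FULL((8, 8), bool)
        gray, valid, _ = quantize_gray(img, mask, levels=2)
        for angle in GLCM_ANGLES:
            got = glcm_stats(glcm(gray, valid, angle=angle, levels=2))
            want = oracle_stats(oracle_glcm(gray, valid, angle, 2))
            assert got["CON"] == pytest.approx(want["CON"], abs=1e-12)


class TestExtractTable:
    def test_shape_and_column_order(self, default_dataset):
        ds = default_dataset[:3]
        table = extract_table([s.image for s in ds], [s.true_mask for s in ds])
        assert table.shape == (3, 29)
        assert tuple(table.columns) == FEATURE_NAMES
        assert tuple(table.columns[:24]) == COLOR_FEATURE_NAMES
        assert not table.iloc[:, :28].isna().any().any()

    def test_failure_names_sample(self, default_dataset):
        s = default_dataset[0]
        with pytest.raises(RuntimeError, match="bad_sample"):
            extract_table(
                [s.image, s.image],
                [s.true_mask, np.zeros_like(s.true_mask)],
                sample_ids=["ok", "bad_sample"],
            )

    def test_duplicate_images_give_identical_rows(self, default_dataset):
        s = default_dataset[0]
        table = extract_table([s.image, s.image], [s.true_mask, s.true_mask])
        pd.testing.assert_series_equal(
            table.iloc[0], table.iloc[1], check_names=False
        )
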