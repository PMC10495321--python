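"""Color and GLCM texture features over the masked leaf region.

Color block (24 features): channel means R, G, B of the leaf pixels plus the
standard algebraic indices (ratios, differences, the (B-G-R)-type composites),
chromatic coordinates r, g, b with their pairwise differences, and the mean
color converted to HSV and CIELAB.  All values are computed from the [0,1]
channel means; H is stored as degrees/360 so every feature lives on a
comparable scale for correlation screening and PCA.

Texture block (5 features): angular second moment (ASM, energy), inverse
difference moment (IDM, homogeneity), contrast (CON), entropy (ENT) and
correlation (COR) of the symmetric, distance-1 gray-level co-occurrence
matrix, averaged over the four azimuth angles 0/45/90/135 degrees.  Gray
levels come from Rec. 709 luminance min-max quantized to 64 levels inside the
mask; background pixels never contribute to a pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import color as skcolor

from .preprocess import LeafMask, masked_pixels

__all__ = [
    "COLOR_FEATURE_NAMES",
    "TEXTURE_FEATURE_NAMES",
    "FEATURE_NAMES",
    "GLCM_ANGLES",
    "color_features",
    "quantize_gray",
    "glcm",
    "glcm_stats",
    "texture_features",
    "extract_table",
]

_EPS = 1e-6

COLOR_FEATURE_NAMES = (
    "R", "G", "B",
    "G/R", "G/B", "B/R",
    "G-R", "G-B", "B-R",
    "(B-G-R)/(B+G)", "(B-G-R)/(R+B)", "(B-G-R)/(G+R)",
    "r", "g", "b",
    "gr", "gb", "br",
    "H", "S", "V",
    "L*", "a*", "b*",
)
TEXTURE_FEATURE_NAMES = ("ASM", "IDM", "CON", "ENT", "COR")
FEATURE_NAMES = COLOR_FEATURE_NAMES + TEXTURE_FEATURE_NAMES

GLCM_ANGLES = (0, 45, 90, 135)
#: (row, col) offsets per angle at distance 1, image convention (row down)
_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

#: Rec. 709 luminance weights
_LUMA = np.array([0.2126, 0.7152, 0.0722])


def _guarded_div(num: float, den: float) -> float:
    if abs(den) < _EPS:
        den = _EPS if den >= 0 else -_EPS
    return num / den


def color_features(image: np.ndarray, mask: LeafMask | np.ndarray) -> dict[str, float]:
    """The 24 color features of the masked region, keyed by name."""
    pixels = masked_pixels(image, mask)
    R, G, B = (float(v) for v in pixels.mean(axis=0))

    total = R + G + B
    r = _guarded_div(R, total)
    g = _guarded_div(G, total)
    b = _guarded_div(B, total)

    mean_rgb = np.clip([[[R, G, B]]], 0.0, 1.0)
    hsv = skcolor.rgb2hsv(mean_rgb)[0, 0]
    lab = skcolor.rgb2lab(mean_rgb)[0, 0]

    values = {
        "R": R, "G": G, "B": B,
        "G/R": _guarded_div(G, R),
        "G/B": _guarded_div(G, B),
        "B/R": _guarded_div(B, R),
        "G-R": G - R, "G-B": G - B, "B-R": B - R,
        "(B-G-R)/(B+G)": _guarded_div(B - G - R, B + G),
        "(B-G-R)/(R+B)": _guarded_div(B - G - R, R + B),
        "(B-G-R)/(G+R)": _guarded_div(B - G - R, G + R),
        "r": r, "g": g, "b": b,
        "gr": g - r, "gb": g - b, "br": b - r,
        "H": float(hsv[0]),  # degrees / 360
        "S": float(hsv[1]),
        "V": float(hsv[2]),
        "L*": float(lab[0]), "a*": float(lab[1]), "b*": float(lab[2]),
    }
    return values


def quantize_gray(
    image: np.ndarray,
    mask: LeafMask | np.ndarray,
    levels: int = 64,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Min-max quantize foreground luminance to ``levels`` gray indices.

    Returns ``(gray, valid, degenerate)``: integer indices in {0..levels-1}
    (0 outside the mask), the validity mask, and a flag set when the
    foreground has no luminance range (all pixels then map to level 0).
    """
    if not 2 <= levels <= 256:
        raise ValueError("levels must lie in [2, 256]")
    m = mask.mask if isinstance(mask, LeafMask) else np.asarray(mask, dtype=bool)
    pixels = masked_pixels(image, m)  # validates shapes / non-empty
    luma = np.asarray(image, dtype=float) @ _LUMA
    fg = luma[m]
    lo, hi = float(fg.min()), float(fg.max())
    gray = np.zeros(m.shape, dtype=np.intp)
    degenerate = hi - lo < 1e-12
    if degenerate:
        warnings.warn("quantize_gray: degenerate (constant) foreground range", stacklevel=2)
    else:
        idx = np.floor((luma - lo) / (hi - lo) * levels).astype(np.intp)
        gray[m] = np.clip(idx[m], 0, levels - 1)
    return gray, m, degenerate


@dataclass
class GlcmMatrix:
    probabilities: np.ndarray  # L x L, symmetric, sums to 1
    levels: int
    distance: int
    angle: int


def glcm(
    gray: np.ndarray,
    valid: np.ndarray,
    distance: int = 1,
    angle: int = 0,
    levels: int | None = None,
) -> GlcmMatrix:
    """Symmetric co-occurrence matrix over pairs of valid pixels.

    Ordered pairs at the angle's offset where both endpoints are inside the
    validity mask are counted, the transpose is added, and counts are
    normalized to probabilities.
    """
    if angle not in _OFFSETS:
        raise ValueError(f"angle must be one of {GLCM_ANGLES}")
    gray = np.asarray(gray)
    valid = np.asarray(valid, dtype=bool)
    if levels is None:
        levels = int(gray[valid].max()) + 1 if valid.any() else 1
    dr, dc = (distance * o for o in _OFFSETS[angle])
    h, w = gray.shape

    # slices of the source and destination pixel of every in-bounds pair
    r0 = slice(max(0, -dr), min(h, h - dr))
    r1 = slice(max(0, dr), min(h, h + dr))
    c0 = slice(max(0, -dc), min(w, w - dc))
    c1 = slice(max(0, dc), min(w, w + dc))

    a = gray[r0, c0]
    b = gray[r1, c1]
    ok = valid[r0, c0] & valid[r1, c1]
    if not ok.any():
        raise ValueError("no valid pixel pairs at this offset")
    pairs = a[ok] * levels + b[ok]
    counts = np.bincount(pairs, minlength=levels * levels).reshape(levels, levels).astype(float)
    counts = counts + counts.T
    return GlcmMatrix(
        probabilities=counts / counts.sum(),
        levels=levels,
        distance=distance,
        angle=angle,
    )


def glcm_stats(matrix: GlcmMatrix) -> dict[str, float]:
    """ASM, IDM, CON, ENT, COR of one co-occurrence matrix.

        ASM = sum p^2                   IDM = sum p / (1 + (i-j)^2)
        CON = sum (i-j)^2 p             ENT = -sum p ln p   (0 ln 0 := 0)
        COR = (sum i j p - u1 u2) / (s1 s2)

    u/s are the marginal means/SDs of the matrix.  COR is NaN (undefined) when
    either marginal SD is below 1e-12, e.g. for a constant image.
    """
    p = matrix.probabilities
    L = p.shape[0]
    i = np.arange(L)[:, None]
    j = np.arange(L)[None, :]
    diff = i - j

    asm = float((p**2).sum())
    idm = float((p / (1.0 + diff**2)).sum())
    con = float(((diff**2) * p).sum())
    nz = p > 0
    ent = float(-(p[nz] * np.log(p[nz])).sum())

    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    u1 = float((np.arange(L) * pi).sum())
    u2 = float((np.arange(L) * pj).sum())
    s1 = float(np.sqrt(((np.arange(L) - u1) ** 2 * pi).sum()))
    s2 = float(np.sqrt(((np.arange(L) - u2) ** 2 * pj).sum()))
    if s1 < 1e-12 or s2 < 1e-12:
        cor = float("nan")
    else:
        cor = float(((i * j * p).sum() - u1 * u2) / (s1 * s2))
    return {"ASM": asm, "IDM": idm, "CON": con, "ENT": ent, "COR": cor}


def texture_features(
    image: np.ndarray,
    mask: LeafMask | np.ndarray,
    levels: int = 64,
    distance: int = 1,
) -> dict[str, float]:
    """Four-angle means of the five GLCM statistics for the masked region.

    COR is averaged over the angles where it is defined; if all four are
    undefined (degenerate texture) it stays NaN.
    """
    gray, valid, degenerate = quantize_gray(image, mask, levels=levels)
    per_angle = [glcm_stats(glcm(gray, valid, distance=distance, angle=a, levels=levels))
                 for a in GLCM_ANGLES]
    out: dict[str, float] = {}
    for name in ("ASM", "IDM", "CON", "ENT"):
        out[name] = float(np.mean([s[name] for s in per_angle]))
    cors = [s["COR"] for s in per_angle if np.isfinite(s["COR"])]
    out["COR"] = float(np.mean(cors)) if cors else float("nan")
    return out


def extract_table(
    images: list[np.ndarray],
    masks: list[LeafMask | np.ndarray],
    sample_ids: list[str] | None = None,
    levels: int = 64,
) -> pd.DataFrame:
    """Feature table, one row per sample, columns in the fixed 24+5 order."""
    if len(images) != len(masks):
        raise ValueError("images and masks must be aligned")
    ids = sample_ids or [f"sample_{i:03d}" for i in range(len(images))]
    rows = []
    for sid, img, msk in zip(ids, images, masks):
        try:
            row = color_features(img, msk)
            row.update(texture_features(img, msk, levels=levels))
        except Exception as exc:
            raise RuntimeError(f"feature extraction failed for sample {sid!r}: {exc}") from exc
        rows.append(row)
    table = pd.DataFrame(rows, index=pd.Index(ids, name="sample_id"))
    return table.loc[:, list(FEATURE_NAMES)]
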