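"""Synthetic leaf-image generator and laboratory label utilities.

The field protocol this emulates photographs a single sugarcane leaf on a
white board from a fixed height, 60 plants per growth stage, and pairs each
image with a leaf nitrogen mass fraction measured by digestion and continuous
flow analysis.  No public dataset exists for that protocol, so this module is
the canonical test input for the whole pipeline: it draws a latent N value per
plant and renders an elliptical leaf whose mean color is affine in N and whose
surface mottling (the texture signal) grows with N, on a near-white
background, optionally under a smooth multiplicative illumination field.

Every sample carries its ground-truth mask and N value, which is what lets
segmentation be scored by IoU and the regression layer by parameter recovery.
"""

from __future__ import annotations

import csv

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "GeneratorConfig",
    "SyntheticSample",
    "LabReading",
    "n_content",
    "generate_dataset",
    "generate_fixture",
    "write_dataset",
    "STAGES",
]

STAGES = ("tillering", "elongation")

#: per-stage leaf color at N = 0 (sRGB-like, [0,1]) and per-unit-N channel
#: slopes.  Higher N means more chlorophyll, hence a darker, more saturated
#: green: negative slopes on all channels, steepest on G.
_STAGE_COLOR = {
    "tillering": {
        "base": (0.46, 0.72, 0.30),
        "slopes": (-0.10, -0.12, -0.05),
    },
    "elongation": {
        "base": (0.42, 0.68, 0.27),
        "slopes": (-0.08, -0.13, -0.04),
    },
}


@dataclass(frozen=True)
class LabReading:
    """Continuous-flow analyzer reading for one digested leaf sample.

    m: instrument reading (mg/L); V: fixed digestion volume (mL);
    M: dry sample mass (g).
    """

    m: float
    V: float
    M: float

    def __post_init__(self) -> None:
        for name in ("m", "V", "M"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"LabReading.{name} must be strictly positive, got {value!r}")


def n_content(reading: LabReading) -> float:
    """Leaf N content from a lab reading: ``N = m * V / M * 1e-3``.

    Returns the raw value of the formula; unit interpretation (the mg/L * mL / g
    bookkeeping) is left to the caller, matching how the flow-analyzer
    worksheet is used in practice.
    """
    return reading.m * reading.V / reading.M * 1e-3


@dataclass(frozen=True)
class GeneratorConfig:
    """Conditions under which a synthetic stage dataset is drawn.

    The defaults are the study conditions used throughout the tests and the
    acceptance run: 60 plants per stage, 256 x 256 frames, latent N uniform on
    [0.8, 2.2] (percent dry mass, the realistic sugarcane leaf range), leaf
    mean color affine in N, N-coupled mottling, plant-to-plant color jitter,
    and a smooth multiplicative illumination field.
    """

    n_samples: int = 60
    image_size: tuple[int, int] = (256, 256)
    n_range: tuple[float, float] = (0.8, 2.2)
    stage: str = "tillering"
    #: per-channel affine slope of mean leaf color vs N; None = stage preset
    color_slopes: tuple[float, float, float] | None = None
    base_color: tuple[float, float, float] | None = None
    #: per-pixel additive Gaussian noise SD (truncated at +-2 SD)
    color_noise_sd: float = 0.02
    #: per-sample whole-leaf color jitter SD (plant-to-plant variability)
    color_sample_sd: float = 0.015
    #: mottling amplitude a(n) = a0 + a1 * n  (spatially correlated texture)
    texture_coupling: tuple[float, float] = (0.01, 0.035)
    #: correlation length (Gaussian smoothing SD, px) of the mottling field
    texture_scale: float = 2.5
    illumination: bool = True
    illumination_strength: float = 0.15
    background_value: float = 0.96
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        h, w = self.image_size
        if h < 32 or w < 32:
            raise ValueError("image dimensions must be >= 32")
        lo, hi = self.n_range
        if not lo < hi:
            raise ValueError("n_range must be a nonempty interval")
        if not 0.9 < self.background_value <= 1.0:
            raise ValueError("background_value must lie in (0.9, 1.0]")
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}")
        if self.color_noise_sd < 0 or self.color_sample_sd < 0:
            raise ValueError("noise SDs must be nonnegative")

    @property
    def effective_base_color(self) -> np.ndarray:
        base = self.base_color or _STAGE_COLOR[self.stage]["base"]
        return np.asarray(base, dtype=float)

    @property
    def effective_slopes(self) -> np.ndarray:
        slopes = self.color_slopes or _STAGE_COLOR[self.stage]["slopes"]
        return np.asarray(slopes, dtype=float)

    def noiseless(self) -> "GeneratorConfig":
        """Copy with every stochastic perturbation of the color link removed.

        Leaf-mean channels are then exact affine functions of N, which is the
        regime used to verify slope recovery end to end.
        """
        return replace(
            self,
            color_noise_sd=0.0,
            color_sample_sd=0.0,
            illumination=False,
        )


@dataclass
class SyntheticSample:
    image: np.ndarray  # H x W x 3 float in [0,1]
    true_mask: np.ndarray  # H x W bool, True on leaf
    n_value: float
    stage_label: str
    sample_id: str = ""


def _ellipse_mask(shape, center, axes, theta) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    y = yy - center[0]
    x = xx - center[1]
    ct, st = np.cos(theta), np.sin(theta)
    u = x * ct + y * st
    v = -x * st + y * ct
    return (u / axes[1]) ** 2 + (v / axes[0]) ** 2 <= 1.0


def _smooth_noise(rng, shape, sigma) -> np.ndarray:
    """Unit-variance Gaussian-filtered white noise (the mottling field)."""
    from scipy.ndimage import gaussian_filter

    field_ = gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def _illumination_field(rng, shape, strength) -> np.ndarray:
    """Smooth multiplicative field in [1-strength, 1+strength].

    A random linear ramp plus one broad Gaussian blob: the low-frequency
    vignetting/side-light pattern seen in field photographs.
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    yn = yy / (h - 1) - 0.5
    xn = xx / (w - 1) - 0.5
    angle = rng.uniform(0, 2 * np.pi)
    ramp = np.cos(angle) * xn + np.sin(angle) * yn
    cy, cx = rng.uniform(-0.3, 0.3, size=2)
    blob = np.exp(-((yn - cy) ** 2 + (xn - cx) ** 2) / (2 * 0.35**2))
    combo = ramp + 0.8 * (blob - blob.mean())
    span = np.abs(combo).max()
    if span > 0:
        combo = combo / span
    return 1.0 + strength * combo


def generate_dataset(config: GeneratorConfig) -> list[SyntheticSample]:
    """Draw a seeded stage dataset of single-leaf images with ground truth.

    Deterministic given the config (including seed).  Per sample: latent N is
    uniform on ``n_range``; the leaf is an ellipse with randomized axes and
    orientation; its color is ``base + slopes * n`` plus (optionally) a
    whole-leaf jitter, N-coupled zero-mean mottling and truncated per-pixel
    noise; the background sits at ``background_value``; when enabled, a
    multiplicative illumination field is applied last and values are clipped
    to [0,1].

    The mottling field is re-centered to mean zero over the leaf, so with the
    noise terms off the leaf-mean color is *exactly* affine in N.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.image_size
    base = config.effective_base_color
    slopes = config.effective_slopes
    a0, a1 = config.texture_coupling

    n_values = rng.uniform(*config.n_range, size=config.n_samples)
    samples: list[SyntheticSample] = []
    for i, n in enumerate(n_values):
        # leaf geometry: a long thin ellipse loosely centred in the frame
        center = (h / 2 + rng.uniform(-0.08, 0.08) * h, w / 2 + rng.uniform(-0.08, 0.08) * w)
        major = rng.uniform(0.30, 0.42) * min(h, w)
        minor = rng.uniform(0.10, 0.18) * min(h, w)
        theta = rng.uniform(0, np.pi)
        mask = _ellipse_mask((h, w), center, (major, minor), theta)

        image = np.full((h, w, 3), config.background_value, dtype=float)
        leaf_color = base + slopes * n
        if config.color_sample_sd > 0:
            leaf_color = leaf_color + rng.normal(0.0, config.color_sample_sd, size=3)
        image[mask] = leaf_color

        # N-coupled mottling: shared spatial field, per-channel gains so the
        # pattern is mostly luminance-like (what GLCM sees)
        amplitude = a0 + a1 * n
        mottle = _smooth_noise(rng, (h, w), config.texture_scale)
        mottle = mottle - mottle[mask].mean()  # exact zero mean over the leaf
        gains = np.array([0.9, 1.0, 0.8])
        image[mask] += (amplitude * mottle[mask])[:, None] * gains[None, :]

        if config.color_noise_sd > 0:
            noise = rng.normal(0.0, config.color_noise_sd, size=image.shape)
            lim = 2.0 * config.color_noise_sd
            image = image + np.clip(noise, -lim, lim)

        if config.illumination:
            field_ = _illumination_field(rng, (h, w), config.illumination_strength)
            image = image * field_[..., None]

        image = np.clip(image, 0.0, 1.0)

        frac = mask.mean()
        if not 0.01 <= frac <= 0.80:  # pragma: no cover - geometry keeps this true
            raise RuntimeError(f"leaf mask fraction {frac:.3f} outside (1%, 80%)")
        samples.append(
            SyntheticSample(
                image=image,
                true_mask=mask,
                n_value=float(n),
                stage_label=config.stage,
                sample_id=f"{config.stage}_{i:03d}",
            )
        )
    return samples


def generate_fixture(kind: str, size: tuple[int, int] = (32, 32), **params) -> np.ndarray:
    """Deterministic unit-test patterns.

    kinds: ``flat`` (constant ``value``), ``gradient`` (constant reflectance
    ``base`` under a left-to-right linear multiplicative ramp of +-``strength``),
    ``checkerboard`` (alternating ``levels``), ``two_tone`` (left/right halves
    at ``colors``).
    """
    h, w = size
    if h < 2 or w < 2:
        raise ValueError("fixture size must be at least 2x2")
    if kind == "flat":
        value = params.get("value", 0.5)
        return np.full((h, w, 3), value, dtype=float)
    if kind == "gradient":
        base = params.get("base", 0.5)
        strength = params.get("strength", 0.5)
        ramp = 1.0 + strength * (2.0 * np.arange(w) / (w - 1) - 1.0)
        return np.broadcast_to((base * ramp)[None, :, None], (h, w, 3)).copy()
    if kind == "checkerboard":
        lo, hi = params.get("levels", (0.0, 1.0))
        yy, xx = np.mgrid[0:h, 0:w]
        board = np.where((yy + xx) % 2 == 0, lo, hi).astype(float)
        return np.repeat(board[..., None], 3, axis=2)
    if kind == "two_tone":
        left, right = params.get("colors", ((0.2, 0.6, 0.2), (0.4, 0.8, 0.4)))
        img = np.empty((h, w, 3), dtype=float)
        img[:, : w // 2] = np.asarray(left, dtype=float)
        img[:, w // 2 :] = np.asarray(right, dtype=float)
        return img
    raise ValueError(f"unknown fixture kind {kind!r}")


def write_dataset(samples: list[SyntheticSample], out_dir: str | Path) -> Path:
    """Write 8-bit PNG images and {0,255} masks plus a CSV manifest.

    Returns the manifest path.  Columns: sample_id, stage, n_value,
    image_path, mask_path.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "stage", "n_value", "image_path", "mask_path"])
        for s in samples:
            img_path = out / "images" / f"{s.sample_id}.png"
            mask_path = out / "masks" / f"{s.sample_id}.png"
            Image.fromarray((np.clip(s.image, 0, 1) * 255).round().astype(np.uint8)).save(img_path)
            Image.fromarray(np.where(s.true_mask, 255, 0).astype(np.uint8)).save(mask_path)
            writer.writerow([s.sample_id, s.stage_label, f"{s.n_value:.6f}", str(img_path), str(mask_path)])
    return manifest
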