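"""Seeded unpaired chest phantoms with ground-truth structure masks.

Clinical ZTE-MRI / CT chest cohorts are access-restricted, so the package
ships a phantom generator that emulates what the translation task needs:
two *unpaired* contrast domains over the same anatomy classes.  Each sample
is a 2-D axial-chest-like scene — an elliptical body containing two lung
ellipses and a set of high-contrast bone elements (spine, ribs, humeral
heads) — rendered in one of two styles:

* ``ct_style``: bone bright, soft tissue mid, lung dark (a windowed-CT
  look), ordered bones > soft tissue > lungs > background;
* ``mri_style``: soft tissue bright, lungs mid-dark, bone and air dark
  (a ZTE-like look), additionally modulated by a smooth multiplicative
  bias field mimicking coil-sensitivity variation.

Per-sample geometric jitter, additive Gaussian noise and the bias field are
all drawn from a counter-based Philox stream keyed by ``(seed, style)``, so
samples are reproducible across platforms and the two domains use disjoint
streams (no image ever appears in both domains).  Ground-truth body / lung /
bone masks are stored pre-noise; bone elements are deliberately small and
high-contrast so mask-overlap metrics (Dice, centroid shift) stay sensitive
to misalignment even at 32–64 pixel resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = ["PhantomConfig", "PhantomSample", "generate_phantom",
           "generate_dataset", "STYLES"]

STYLES = ("mri_style", "ct_style")

# class intensities before bias/noise, per style
_CT_LEVELS = {"background": 0.0, "soft": 0.35, "lungs": 0.08, "bones": 0.90}
_MRI_LEVELS = {"background": 0.0, "soft": 0.75, "lungs": 0.25, "bones": 0.05}


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry distributions and noise levels of the phantom sampler.

    Lengths are fractions of the image side; ``*_jitter`` entries are the
    half-widths of uniform perturbations applied per sample.
    """

    size: int = 64
    body_axes: tuple[float, float] = (0.42, 0.34)     # (horizontal, vertical)
    body_jitter: float = 0.025
    lung_axes: tuple[float, float] = (0.13, 0.19)
    lung_offset: float = 0.21                          # lung centre from midline
    lung_jitter: float = 0.015
    n_ribs_range: tuple[int, int] = (3, 4)             # per side
    rib_radius: float = 0.040
    spine_radius: float = 0.055
    humerus_radius: float = 0.050
    bone_jitter: float = 0.012
    noise_std: float = 0.02
    bias_strength: float = 0.30
    bias_grid: int = 4

    def __post_init__(self):
        if self.size < 16:
            raise ValueError("phantom size must be at least 16 pixels")
        if self.noise_std < 0 or self.bias_strength < 0:
            raise ValueError("noise_std and bias_strength must be non-negative")
        if self.n_ribs_range[0] > self.n_ribs_range[1] or self.n_ribs_range[0] < 0:
            raise ValueError("n_ribs_range must be a nonempty non-negative range")
        # every structure must fit inside the frame under maximal jitter
        max_half = 0.5 + self.body_jitter
        if self.body_axes[0] + self.body_jitter >= 0.5 - 0.01 or \
           self.body_axes[1] + self.body_jitter >= 0.5 - 0.01:
            raise ValueError("body ellipse (plus jitter) does not fit in frame")
        del max_half


@dataclass
class PhantomSample:
    """One synthetic image with its ground-truth anatomy masks."""

    image: np.ndarray            # (S, S) float in [0, 1]
    body: np.ndarray             # bool masks, pre-noise geometry
    lungs: np.ndarray
    bones: np.ndarray
    style: str
    seed: int

    @property
    def masks(self) -> dict[str, np.ndarray]:
        return {"body": self.body, "lungs": self.lungs, "bones": self.bones}

    @property
    def soft_tissue(self) -> np.ndarray:
        return self.body & ~self.lungs & ~self.bones


def _rng_for(seed: int, style: str) -> np.random.Generator:
    # disjoint counter-based streams per (seed, domain)
    key = np.array([np.uint64(seed), np.uint64(STYLES.index(style) + 1)],
                   dtype=np.uint64)
    return np.random.Generator(np.random.Philox(key=key))


def _ellipse(S: int, cy: float, cx: float, ay: float, ax: float) -> np.ndarray:
    yy, xx = np.mgrid[0:S, 0:S]
    return (((yy + 0.5) / S - cy) / ay) ** 2 + (((xx + 0.5) / S - cx) / ax) ** 2 <= 1.0


def _disc(S: int, cy: float, cx: float, r: float) -> np.ndarray:
    return _ellipse(S, cy, cx, r, r)


def _smooth_field(rng: np.random.Generator, S: int, grid: int) -> np.ndarray:
    coarse = rng.normal(size=(grid, grid))
    f = _sk_resize(coarse, (S, S), order=3, mode="edge", anti_aliasing=False)
    peak = np.max(np.abs(f))
    return f / peak if peak > 0 else f


def generate_phantom(config: PhantomConfig, style: str, seed: int) -> PhantomSample:
    """Draw one phantom; deterministic in ``(config, style, seed)``."""
    if style not in STYLES:
        raise ValueError(f"style must be one of {STYLES}, got {style!r}")
    rng = _rng_for(seed, style)
    S = config.size
    j = lambda half: rng.uniform(-half, half)  # noqa: E731

    # body
    bcy = 0.5 + j(config.body_jitter)
    bcx = 0.5 + j(config.body_jitter)
    bay = config.body_axes[1] + j(config.body_jitter)
    bax = config.body_axes[0] + j(config.body_jitter)
    body = _ellipse(S, bcy, bcx, bay, bax)

    # lungs
    lay = config.lung_axes[1] + j(config.lung_jitter)
    lax = config.lung_axes[0] + j(config.lung_jitter)
    off = config.lung_offset + j(config.lung_jitter)
    lcy = bcy - 0.02 + j(config.lung_jitter)
    lungs = (_ellipse(S, lcy, bcx - off, lay, lax)
             | _ellipse(S, lcy, bcx + off, lay, lax))
    lungs &= body

    # bones: spine, two humeral heads, rib discs along the body boundary
    bones = np.zeros((S, S), dtype=bool)
    bj = config.bone_jitter
    bones |= _disc(S, bcy + 0.72 * bay + j(bj), bcx + j(bj), config.spine_radius)
    for side in (-1.0, 1.0):
        bones |= _disc(S, bcy - 0.15 * bay + j(bj),
                       bcx + side * (bax * 0.82) + j(bj), config.humerus_radius)
    n_ribs = int(rng.integers(config.n_ribs_range[0], config.n_ribs_range[1] + 1))
    for side in (-1.0, 1.0):
        for k in range(n_ribs):
            ang = np.deg2rad(25.0 + 40.0 * k / max(n_ribs - 1, 1) + 8.0 * j(1.0))
            cy = bcy - 0.72 * bay * np.cos(ang)
            cx = bcx + side * 0.80 * bax * np.sin(ang)
            bones |= _disc(S, cy + j(bj), cx + j(bj), config.rib_radius)
    bones &= body
    bones &= ~lungs

    levels = _CT_LEVELS if style == "ct_style" else _MRI_LEVELS
    image = np.full((S, S), levels["background"], dtype=np.float64)
    image[body] = levels["soft"]
    image[lungs] = levels["lungs"]
    image[bones] = levels["bones"]

    if style == "mri_style" and config.bias_strength > 0:
        bias = 1.0 + config.bias_strength * _smooth_field(rng, S, config.bias_grid)
        image = image * np.clip(bias, 0.05, None)

    if config.noise_std > 0:
        image = image + rng.normal(0.0, config.noise_std, size=(S, S))
    image = np.clip(image, 0.0, 1.0)

    return PhantomSample(image=image, body=body, lungs=lungs, bones=bones,
                         style=style, seed=seed)


def generate_dataset(config: PhantomConfig, style: str, n: int,
                     base_seed: int = 0) -> list[PhantomSample]:
    """Draw ``n`` phantoms with consecutive seeds starting at ``base_seed``."""
    return [generate_phantom(config, style, base_seed + i) for i in range(n)]
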