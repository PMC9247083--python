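"""Modality-independent neighbourhood descriptor (MIND) and its consistency loss.

MIND represents each pixel of an image by a vector of exponentiated,
variance-normalised patch self-dissimilarities

    MIND(I, x, r) = (1/n) exp(-D_p(I, x, x+r) / V(I, x)),   r in R,

where ``D_p`` is the sum of squared differences between the patch around ``x``
and the patch around ``x + r``,

    D_p(I, x, x+r) = sum_{p in P} (I(x+p) - I(x+r+p))^2,

``V`` is a local variance estimate obtained by summing ``D_p`` over the
immediate neighbourhood ``N`` of ``x``,

    V(I, x) = sum_{n in N} D_p(I, x, x+n),

and the normalisation constant ``n`` makes the maximum entry of each pixel's
descriptor equal 1.  Because ``D_p`` and ``V`` both scale with the square of
the intensities, the descriptor is invariant to affine intensity changes —
which is what makes it comparable *across* modalities (MRI vs CT): two images
of the same anatomy produce nearly identical descriptors even though their
contrasts are unrelated.

The consistency loss compares descriptors before and after translation,

    L_MIND = mean | MIND(G(I)) - MIND(I) |,

anchoring anatomical structure through an otherwise unconstrained
image-to-image translator.

Two computation paths are provided with identical semantics:

* a vectorised numpy path (``compute_mind`` and friends) built from
  edge-clamped image shifts — the "shift-and-sum" form of the convolution
  implementation; and
* a differentiable path on :class:`~mindsct.autodiff.Tensor` inputs
  (``mind_descriptor_tensor`` / ``mind_loss_tensor``) used inside the
  training objectives.

Every out-of-bounds read clamps its own index to the image border
(replicate padding), for each of the three offset sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .autodiff import Tensor, stack

__all__ = [
    "MINDConfig",
    "build_shift_set",
    "four_neighbourhood",
    "patch_distance",
    "local_variance",
    "compute_mind",
    "mind_loss",
    "mind_descriptor_tensor",
    "mind_loss_tensor",
    "MINDDescriptor",
]

Offset = tuple[int, int]

# absolute guard so a constant image (V = 0 everywhere, spatial mean 0)
# yields exp(-0/eps) = 1 instead of 0/0
_V_TINY = 1e-30


def build_shift_set(radius: int) -> list[Offset]:
    """All integer displacements ``(dy, dx)`` with ``|dy|, |dx| <= radius``.

    Ordered row-major (by dy, then dx).  ``radius=4`` yields the 81 shifts
    spanning −4..4 along both axes; ``radius=0`` yields only the zero vector.
    """
    radius = int(radius)
    if radius < 0:
        raise ValueError(f"radius must be non-negative, got {radius}")
    return [(dy, dx)
            for dy in range(-radius, radius + 1)
            for dx in range(-radius, radius + 1)]


def four_neighbourhood() -> list[Offset]:
    """The 4-connected neighbourhood, the 2-D analogue of the classical
    6-neighbourhood used for the variance estimate in 3-D."""
    return [(-1, 0), (0, -1), (0, 1), (1, 0)]


def _check_offsets(offsets, name: str) -> list[Offset]:
    offsets = [(int(dy), int(dx)) for dy, dx in offsets]
    if not offsets:
        raise ValueError(f"{name} must be nonempty")
    if len(set(offsets)) != len(offsets):
        raise ValueError(f"{name} contains duplicate offsets")
    return offsets


@dataclass(frozen=True)
class MINDConfig:
    """Offset sets and numerical policy for the descriptor.

    Parameters
    ----------
    search_offsets : sequence of (dy, dx)
        The displacements ``r in R``; one descriptor channel each.
        Default: the 81 shifts of radius 4.
    patch_offsets : sequence of (dy, dx)
        The patch window ``P`` of the distance ``D_p``. Default: 3×3.
    variance_offsets : sequence of (dy, dx)
        The neighbourhood ``N`` summed for the variance estimate.
        Default: 4-connected.
    variance_floor_fraction : float
        The variance map is clamped below at this fraction of its spatial
        mean; being mean-relative keeps the affine-intensity invariance
        exact. Default 1e-3.
    boundary_policy : str
        Only ``"replicate"`` (edge-clamped reads) is supported.
    """

    search_offsets: tuple = field(default_factory=lambda: tuple(build_shift_set(4)))
    patch_offsets: tuple = field(default_factory=lambda: tuple(build_shift_set(1)))
    variance_offsets: tuple = field(default_factory=lambda: tuple(four_neighbourhood()))
    variance_floor_fraction: float = 1e-3
    boundary_policy: str = "replicate"

    def __post_init__(self):
        object.__setattr__(self, "search_offsets",
                           tuple(_check_offsets(self.search_offsets, "search_offsets")))
        object.__setattr__(self, "patch_offsets",
                           tuple(_check_offsets(self.patch_offsets, "patch_offsets")))
        object.__setattr__(self, "variance_offsets",
                           tuple(_check_offsets(self.variance_offsets, "variance_offsets")))
        if not self.variance_floor_fraction > 0:
            raise ValueError("variance_floor_fraction must be > 0")
        if self.boundary_policy != "replicate":
            raise ValueError("only the 'replicate' boundary policy is supported")

    @classmethod
    def from_radii(cls, search_radius: int = 4, patch_radius: int = 1,
                   variance_floor_fraction: float = 1e-3) -> "MINDConfig":
        return cls(search_offsets=tuple(build_shift_set(search_radius)),
                   patch_offsets=tuple(build_shift_set(patch_radius)),
                   variance_floor_fraction=variance_floor_fraction)

    @property
    def reach(self) -> int:
        """Largest Chebyshev distance any single read can travel."""
        def cheb(offs):
            return max(max(abs(dy), abs(dx)) for dy, dx in offs)
        far = max(cheb(self.search_offsets), cheb(self.variance_offsets))
        return far + cheb(self.patch_offsets)


def _validate_image(image: np.ndarray, reach: int) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {image.shape}")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    need = 2 * reach + 1
    if image.shape[0] < need or image.shape[1] < need:
        raise ValueError(
            f"image of shape {image.shape} too small for offsets reaching "
            f"{reach} pixels (need at least {need}×{need})")
    if image.dtype.kind != "f":
        image = image.astype(np.float64)
    elif image.dtype.itemsize < 4:
        image = image.astype(np.float32)
    return image


def _shift(image: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """``image[i+dy, j+dx]`` with edge-clamped indices."""
    H, W = image.shape
    rows = np.clip(np.arange(H) + dy, 0, H - 1)
    cols = np.clip(np.arange(W) + dx, 0, W - 1)
    return image[rows[:, None], cols[None, :]]


def _patch_distance_raw(image, r: Offset, patch_offsets, cache: dict) -> np.ndarray:
    dy, dx = r
    acc = np.zeros_like(image)
    for (py, px) in patch_offsets:
        key_a = (py, px)
        key_b = (py + dy, px + dx)
        if key_a not in cache:
            cache[key_a] = _shift(image, *key_a)
        if key_b not in cache:
            cache[key_b] = _shift(image, *key_b)
        diff = cache[key_a] - cache[key_b]
        acc += diff * diff
    return acc


def patch_distance(image, r: Offset, patch_offsets=None,
                   boundary_policy: str = "replicate") -> np.ndarray:
    """Patch sum-of-squared-differences between ``x`` and ``x + r``.

    Returns a map of the same shape as ``image`` with
    ``D_p(x) = sum_{p in P} (I(x+p) - I(x+r+p))^2``, every read edge-clamped.
    """
    if boundary_policy != "replicate":
        raise ValueError("only the 'replicate' boundary policy is supported")
    if patch_offsets is None:
        patch_offsets = build_shift_set(1)
    patch_offsets = _check_offsets(patch_offsets, "patch_offsets")
    pr = max(max(abs(a), abs(b)) for a, b in patch_offsets)
    rr = max(abs(r[0]), abs(r[1]))
    image = _validate_image(image, pr + rr)
    return _patch_distance_raw(image, (int(r[0]), int(r[1])), patch_offsets, {})


def local_variance(image, patch_offsets=None, variance_offsets=None,
                   variance_floor_fraction: float = 1e-3) -> np.ndarray:
    """Local variance estimate: ``V(x) = sum_{n in N} D_p(I, x, x+n)``,
    clamped below at ``variance_floor_fraction`` × its spatial mean."""
    if patch_offsets is None:
        patch_offsets = build_shift_set(1)
    if variance_offsets is None:
        variance_offsets = four_neighbourhood()
    cfg = MINDConfig(search_offsets=tuple(variance_offsets),
                     patch_offsets=tuple(patch_offsets),
                     variance_offsets=tuple(variance_offsets),
                     variance_floor_fraction=variance_floor_fraction)
    image = _validate_image(image, cfg.reach)
    cache: dict = {}
    V = np.zeros_like(image)
    for n in cfg.variance_offsets:
        V += _patch_distance_raw(image, n, cfg.patch_offsets, cache)
    floor = variance_floor_fraction * V.mean()
    return np.maximum(np.maximum(V, floor), _V_TINY)


def compute_mind(image, config: MINDConfig | None = None) -> np.ndarray:
    """Per-pixel MIND descriptor, shape ``(H, W, len(search_offsets))``.

    Channel ``k`` holds ``exp(-D_p(x, x+r_k) / V(x))`` divided by the
    per-pixel maximum over channels, so every entry lies in (0, 1] and the
    maximum channel at each pixel is exactly 1.
    """
    config = config or MINDConfig()
    image = _validate_image(image, config.reach)
    cache: dict = {}
    V = np.zeros_like(image)
    for n in config.variance_offsets:
        V += _patch_distance_raw(image, n, config.patch_offsets, cache)
    floor = config.variance_floor_fraction * V.mean()
    V = np.maximum(np.maximum(V, floor), _V_TINY)
    channels = [np.exp(-_patch_distance_raw(image, r, config.patch_offsets, cache) / V)
                for r in config.search_offsets]
    desc = np.stack(channels, axis=-1)
    desc /= desc.max(axis=-1, keepdims=True)
    return desc


def mind_loss(image_a, image_b, config: MINDConfig | None = None) -> float:
    """Mean absolute difference between the MIND descriptors of two images.

    Symmetric, non-negative, zero for identical (or affinely related)
    images; the mean runs over pixels and channels so the value does not
    grow with image size.
    """
    image_a = np.asarray(image_a)
    image_b = np.asarray(image_b)
    if image_a.shape != image_b.shape:
        raise ValueError(
            f"image shapes differ: {image_a.shape} vs {image_b.shape}")
    config = config or MINDConfig()
    da = compute_mind(image_a, config)
    db = compute_mind(image_b, config)
    return float(np.mean(np.abs(da - db)))


# --------------------------------------------------------------------------
# differentiable path (used inside training objectives)
# --------------------------------------------------------------------------

def _patch_distance_t(x: Tensor, r: Offset, patch_offsets, cache: dict) -> Tensor:
    dy, dx = r
    acc = None
    for (py, px) in patch_offsets:
        ka, kb = (py, px), (py + dy, px + dx)
        if ka not in cache:
            cache[ka] = x.shift2d(*ka)
        if kb not in cache:
            cache[kb] = x.shift2d(*kb)
        term = (cache[ka] - cache[kb]) ** 2
        acc = term if acc is None else acc + term
    return acc


def mind_descriptor_tensor(x: Tensor, config: MINDConfig | None = None) -> Tensor:
    """Differentiable MIND descriptor of an NCHW (single-channel) tensor.

    Returns a tensor of shape ``(N, len(search_offsets), H, W)``; semantics
    match :func:`compute_mind` exactly.
    """
    config = config or MINDConfig()
    cache: dict = {}
    V = None
    for n in config.variance_offsets:
        d = _patch_distance_t(x, n, config.patch_offsets, cache)
        V = d if V is None else V + d
    floor = V.mean(axis=(-2, -1), keepdims=True) * config.variance_floor_fraction
    V = V.maximum(floor).maximum(_V_TINY)
    channels = [((_patch_distance_t(x, r, config.patch_offsets, cache) * -1.0) / V).exp()
                for r in config.search_offsets]
    desc = stack(channels, axis=1)  # (N, R, 1, H, W)
    desc = desc.reshape(desc.shape[0], len(channels), *desc.shape[-2:])
    return desc / desc.max(axis=1, keepdims=True)


def mind_loss_tensor(a: Tensor, b: Tensor, config: MINDConfig | None = None) -> Tensor:
    """Differentiable mean-absolute MIND discrepancy between two NCHW batches."""
    if a.shape != b.shape:
        raise ValueError(f"shapes differ: {a.shape} vs {b.shape}")
    config = config or MINDConfig()
    da = mind_descriptor_tensor(a, config)
    db = mind_descriptor_tensor(b, config)
    return (da - db).abs().mean()


class MINDDescriptor(TransformerMixin, BaseEstimator):
    """Scikit-learn style transformer computing MIND descriptor maps.

    Parameters
    ----------
    search_radius : int, default 4
        Radius of the square shift set ``R`` (channels); 4 gives 81 channels.
    patch_radius : int, default 1
        Radius of the patch window ``P``; 1 gives a 3×3 patch.
    variance_floor_fraction : float, default 1e-3
        Mean-relative lower clamp on the variance map.

    ``transform`` maps an array of images ``(n, H, W)`` (or a single
    ``(H, W)`` image) to descriptor maps ``(n, H, W, C)``.
    """

    def __init__(self, search_radius: int = 4, patch_radius: int = 1,
                 variance_floor_fraction: float = 1e-3):
        self.search_radius = search_radius
        self.patch_radius = patch_radius
        self.variance_floor_fraction = variance_floor_fraction

    def _config(self) -> MINDConfig:
        return MINDConfig.from_radii(self.search_radius, self.patch_radius,
                                     self.variance_floor_fraction)

    def fit(self, X, y=None):
        self.config_ = self._config()
        self.n_channels_ = len(self.config_.search_offsets)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "config_"):
            self.fit(X)
        X = np.asarray(X)
        single = X.ndim == 2
        if single:
            X = X[None]
        out = np.stack([compute_mind(img, self.config_) for img in X])
        return out[0] if single else out
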