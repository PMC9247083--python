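"""Translation networks: attention-guided generator with AdaLIN, and
patch discriminators with auxiliary CAM classifiers.

The generator follows the encoder–bottleneck–decoder layout of the
attention-guided unpaired-translation literature, scaled down for
single-channel medical images:

* encoder: 7×7 stem convolution, two stride-2 downsampling stages, residual
  bottleneck blocks with instance normalisation;
* CAM attention: an auxiliary domain classifier over globally pooled
  bottleneck features; its channel weights re-weight the feature maps
  (rectified), yielding a domain logit and an inspectable attention map;
* decoder: residual blocks normalised by AdaLIN — a learned convex mix
  ``ρ·IN(x) + (1-ρ)·LN(x)`` modulated by γ, β predicted from the attended
  features — followed by nearest-neighbour upsampling stages with
  layer-instance normalisation and a 7×7 output convolution whose tanh is
  mapped to [0, 1] so synthesised images are windowable like the inputs.

Discriminators are patch classifiers (stride-2 convolution stacks with
leaky ReLU and optional spectral normalisation) that emit a per-patch
realness map plus a CAM logit from their own auxiliary classifier; one or
two receptive-field scales (the second scale sees a 2× downsampled input).

All randomness in initialisation comes from an explicit seed, so fixed
(seed, input) pairs give byte-identical outputs.
"""

from __future__ import annotations

import warnings

import numpy as np

from .autodiff import Adam, Module, Parameter, Tensor

__all__ = [
    "Conv2d",
    "Linear",
    "instance_norm",
    "layer_norm",
    "adalin",
    "cam_attend",
    "Generator",
    "Discriminator",
    "MultiScaleDiscriminator",
    "translate",
    "discriminate",
]

NORM_EPS = 1e-5


# --------------------------------------------------------------------------
# primitive layers
# --------------------------------------------------------------------------

class Conv2d(Module):
    """Convolution with replicate padding and optional spectral norm."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad: int = 0, bias: bool = True, spectral_norm: bool = False,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = 0.02
        self.weight = Parameter(rng.normal(0.0, scale,
                                           size=(out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.stride = stride
        self.pad = pad
        self.spectral_norm = spectral_norm
        if spectral_norm:
            self._u = rng.normal(size=out_ch)
            self._u /= np.linalg.norm(self._u) + 1e-12

    def _sn_weight(self) -> Tensor:
        w2d = self.weight.data.reshape(self.weight.shape[0], -1)
        # one power-iteration step; u, v treated as constants in the graph
        v = w2d.T @ self._u
        v /= np.linalg.norm(v) + 1e-12
        u = w2d @ v
        u /= np.linalg.norm(u) + 1e-12
        self._u = u
        wmat = self.weight.reshape(self.weight.shape[0], -1)
        sigma = Tensor(u[None, :]) @ wmat @ Tensor(v[:, None])
        return self.weight / sigma.reshape(1, 1, 1, 1)

    def __call__(self, x: Tensor) -> Tensor:
        if self.pad:
            x = x.pad2d(self.pad, mode="replicate")
        w = self._sn_weight() if self.spectral_norm else self.weight
        out = x.conv2d(w, stride=self.stride)
        if self.bias is not None:
            out = out + self.bias.reshape(1, -1, 1, 1)
        return out


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(rng.normal(0.0, 0.02, size=(in_f, out_f)))
        self.bias = Parameter(np.zeros(out_f)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias.reshape(1, -1)
        return out


def instance_norm(x: Tensor, eps: float = NORM_EPS) -> Tensor:
    """Standardise each channel of each sample over its spatial extent."""
    mu = x.mean(axis=(-2, -1), keepdims=True)
    var = ((x - mu) ** 2).mean(axis=(-2, -1), keepdims=True)
    return (x - mu) / (var + eps).sqrt()


def layer_norm(x: Tensor, eps: float = NORM_EPS) -> Tensor:
    """Standardise each sample over all channels and spatial locations."""
    mu = x.mean(axis=(1, 2, 3), keepdims=True)
    var = ((x - mu) ** 2).mean(axis=(1, 2, 3), keepdims=True)
    return (x - mu) / (var + eps).sqrt()


def _as_tensor(x) -> tuple[Tensor, bool]:
    if isinstance(x, Tensor):
        return x, True
    return Tensor(np.asarray(x, dtype=np.float64)), False


def adalin(features, gamma, beta, rho, eps: float = NORM_EPS):
    """Adaptive layer-instance normalisation.

    ``out = gamma * (rho * IN(x) + (1 - rho) * LN(x)) + beta`` on NCHW
    features; ``gamma``/``beta`` broadcast per channel (shape ``(C,)`` or
    ``(N, C)``), ``rho`` is a scalar mixing weight.  Values of ``rho``
    outside [0, 1] are clamped with a warning.
    """
    x, tensor_mode = _as_tensor(features)
    rho_val = float(rho.data) if isinstance(rho, Tensor) else float(rho)
    if rho_val < 0.0 or rho_val > 1.0:
        warnings.warn(f"adalin mixing weight rho={rho_val:.4g} outside [0, 1]; "
                      "clamped", stacklevel=2)
        rho = np.clip(rho_val, 0.0, 1.0)
    if isinstance(rho, Tensor):
        rho = rho.clamp(0.0, 1.0)
    mixed = rho * instance_norm(x, eps) + (1.0 - rho) * layer_norm(x, eps)
    g, _ = _as_tensor(gamma)
    b, _ = _as_tensor(beta)
    if g.ndim == 1:
        g = g.reshape(1, -1, 1, 1)
        b = b.reshape(1, -1, 1, 1)
    else:
        g = g.reshape(g.shape[0], -1, 1, 1)
        b = b.reshape(b.shape[0], -1, 1, 1)
    out = g * mixed + b
    return out if tensor_mode else out.data


def cam_attend(features, classifier_weights):
    """Apply class-activation attention derived from classifier weights.

    ``logit = GAP(features) · w`` and ``attended = relu(features * w_c)``
    with one weight per channel.  Returns ``(attended, logit)``; the
    rectified per-location attention map is ``attended.sum(channels)``.
    """
    x, tensor_mode = _as_tensor(features)
    w, _ = _as_tensor(classifier_weights)
    if w.data.size != x.shape[1]:
        raise ValueError(f"classifier weight count {w.data.size} does not "
                         f"match channel count {x.shape[1]}")
    gap = x.mean(axis=(-2, -1))                      # (N, C)
    logit = gap @ w.reshape(-1, 1)                   # (N, 1)
    attended = (x * w.reshape(1, -1, 1, 1)).relu()
    if tensor_mode:
        return attended, logit
    return attended.data, logit.data


# --------------------------------------------------------------------------
# generator
# --------------------------------------------------------------------------

class _ResBlock(Module):
    def __init__(self, ch: int, rng):
        self.c1 = Conv2d(ch, ch, 3, pad=1, rng=rng)
        self.c2 = Conv2d(ch, ch, 3, pad=1, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = instance_norm(self.c1(x)).relu()
        h = instance_norm(self.c2(h))
        return x + h


class _AdaResBlock(Module):
    """Residual block whose normalisation is AdaLIN(γ, β) with learned ρ."""

    def __init__(self, ch: int, rng):
        self.c1 = Conv2d(ch, ch, 3, pad=1, rng=rng)
        self.c2 = Conv2d(ch, ch, 3, pad=1, rng=rng)
        self.rho1 = Parameter(np.array(0.9))
        self.rho2 = Parameter(np.array(0.9))

    def __call__(self, x: Tensor, gamma: Tensor, beta: Tensor) -> Tensor:
        h = adalin(self.c1(x), gamma, beta, self.rho1)
        h = h.relu()
        h = adalin(self.c2(h), gamma, beta, self.rho2)
        return x + h


class _LIN(Module):
    """Layer-instance normalisation with learned ρ, γ, β (per channel)."""

    def __init__(self, ch: int):
        self.rho = Parameter(np.array(0.0))
        self.gamma = Parameter(np.ones(ch))
        self.beta = Parameter(np.zeros(ch))

    def __call__(self, x: Tensor) -> Tensor:
        return adalin(x, self.gamma, self.beta, self.rho)


class Generator(Module):
    """Attention-guided encoder–bottleneck–decoder translator.

    Parameters
    ----------
    base_width : int
        Channels of the stem convolution; doubled at each downsampling
        stage.
    n_down : int
        Stride-2 downsampling stages (input sides must be divisible by
        ``2**n_down``; :func:`translate` pads and crops otherwise).
    n_res : int
        Residual blocks in the bottleneck and (adaptive) in the decoder.
    seed : int
        Seeds the weight initialisation.
    """

    def __init__(self, base_width: int = 16, n_down: int = 2, n_res: int = 2,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.base_width = base_width
        self.n_down = n_down
        self.n_res = n_res

        self.stem = Conv2d(1, base_width, 7, pad=3, rng=rng)
        ch = base_width
        self.down = []
        for _ in range(n_down):
            self.down.append(Conv2d(ch, ch * 2, 3, stride=2, pad=1, rng=rng))
            ch *= 2
        self.bottleneck = [_ResBlock(ch, rng) for _ in range(n_res)]

        # CAM auxiliary classifier + fusion
        self.cam_fc = Linear(ch, 1, bias=False, rng=rng)
        self.cam_fuse = Conv2d(ch, ch, 1, rng=rng)

        # γ/β predictor from attended, pooled features
        self.mlp_hidden = Linear(ch, ch, rng=rng)
        self.mlp_gamma = Linear(ch, ch, rng=rng)
        self.mlp_beta = Linear(ch, ch, rng=rng)

        self.dec_res = [_AdaResBlock(ch, rng) for _ in range(n_res)]
        self.up = []
        self.up_norm = []
        for _ in range(n_down):
            self.up.append(Conv2d(ch, ch // 2, 3, pad=1, rng=rng))
            self.up_norm.append(_LIN(ch // 2))
            ch //= 2
        self.head = Conv2d(ch, 1, 7, pad=3, rng=rng)

    # -- forward ----------------------------------------------------------
    def __call__(self, x: Tensor):
        """Translate an NCHW batch.  Returns (output, attention_map, logit)."""
        h = instance_norm(self.stem(x)).relu()
        for conv in self.down:
            h = instance_norm(conv(h)).relu()
        for block in self.bottleneck:
            h = block(h)

        attended, logit = cam_attend(h, self.cam_fc.weight.reshape(-1))
        attention = attended.data.sum(axis=1)       # (N, h, w), inspection only
        h = self.cam_fuse(attended).relu()

        pooled = h.mean(axis=(-2, -1))
        hid = self.mlp_hidden(pooled).relu()
        gamma = self.mlp_gamma(hid)
        beta = self.mlp_beta(hid)

        for block in self.dec_res:
            h = block(h, gamma, beta)
        for conv, norm in zip(self.up, self.up_norm):
            h = norm(conv(h.upsample_nearest(2))).relu()
        out = (self.head(h).tanh() + 1.0) * 0.5
        return out, attention, logit

    def clamp_rho(self) -> None:
        """Project every AdaLIN mixing weight back into [0, 1]."""
        for block in self.dec_res:
            for p in (block.rho1, block.rho2):
                np.clip(p.data, 0.0, 1.0, out=p.data)
        for norm in self.up_norm:
            np.clip(norm.rho.data, 0.0, 1.0, out=norm.rho.data)

    def rho_values(self) -> np.ndarray:
        vals = []
        for block in self.dec_res:
            vals += [float(block.rho1.data), float(block.rho2.data)]
        vals += [float(n.rho.data) for n in self.up_norm]
        return np.array(vals)


# --------------------------------------------------------------------------
# discriminator
# --------------------------------------------------------------------------

class Discriminator(Module):
    """Patch discriminator with an auxiliary CAM classifier.

    Emits a per-patch realness map (raw logits; the log-adversarial loss
    applies a sigmoid, the least-squares loss uses them directly) and a
    scalar CAM logit per image.
    """

    def __init__(self, base_width: int = 16, n_layers: int = 3,
                 spectral_norm: bool = True, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.base_width = base_width
        ch = base_width
        self.convs = [Conv2d(1, ch, 4, stride=2, pad=1,
                             spectral_norm=spectral_norm, rng=rng)]
        for _ in range(n_layers - 1):
            self.convs.append(Conv2d(ch, ch * 2, 4, stride=2, pad=1,
                                     spectral_norm=spectral_norm, rng=rng))
            ch *= 2
        self.cam_fc = Linear(ch, 1, bias=False, rng=rng)
        self.cam_fuse = Conv2d(ch, ch, 1, spectral_norm=spectral_norm, rng=rng)
        self.head = Conv2d(ch, 1, 4, pad=1, spectral_norm=spectral_norm, rng=rng)

    def __call__(self, x: Tensor):
        h = x
        for conv in self.convs:
            h = conv(h).leaky_relu(0.2)
        attended, logit = cam_attend(h, self.cam_fc.weight.reshape(-1))
        h = self.cam_fuse(attended).leaky_relu(0.2)
        realness = self.head(h)
        return realness, logit


def _avg_pool2(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


class MultiScaleDiscriminator(Module):
    """One or two patch discriminators at different receptive-field scales;
    the second operates on a 2× average-pooled input."""

    def __init__(self, base_width: int = 16, n_layers: int = 3, scales: int = 1,
                 spectral_norm: bool = True, seed: int = 0):
        if scales not in (1, 2):
            raise ValueError("scales must be 1 or 2")
        self.scales = scales
        self.discs = [Discriminator(base_width, n_layers, spectral_norm,
                                    seed=seed + 101 * i)
                      for i in range(scales)]

    def __call__(self, x: Tensor):
        maps, logits = [], []
        cur = x
        for i, d in enumerate(self.discs):
            if i > 0:
                cur = _avg_pool2(cur)
            m, l = d(cur)
            maps.append(m)
            logits.append(l)
        return maps, logits


# --------------------------------------------------------------------------
# functional wrappers
# --------------------------------------------------------------------------

def _to_nchw(images: np.ndarray) -> tuple[np.ndarray, bool]:
    arr = np.asarray(images, dtype=np.float32)
    if arr.ndim == 2:
        return arr[None, None], True
    if arr.ndim == 3:
        return arr[:, None], False
    raise ValueError(f"expected (H, W) or (N, H, W) images, got {arr.shape}")


def translate(generator: Generator, images):
    """Run the generator on numpy images.

    Accepts ``(H, W)`` or ``(N, H, W)`` arrays; sides not divisible by
    ``2**n_down`` are replicate-padded and the output cropped back (with a
    warning).  Returns ``(translated, attention_maps, cam_logits)`` with
    the translated images matching the input shape.
    """
    x, single = _to_nchw(images)
    n, _, H, W = x.shape
    mult = 2 ** generator.n_down
    pad_h = (-H) % mult
    pad_w = (-W) % mult
    if pad_h or pad_w:
        warnings.warn(f"input sides ({H}, {W}) not divisible by {mult}; "
                      "padding and cropping the output", stacklevel=2)
        x = np.pad(x, ((0, 0), (0, 0), (0, pad_h), (0, pad_w)), mode="edge")
    out, attention, logit = generator(Tensor(x))
    out = out.data[:, 0, :H, :W]
    logits = logit.data[:, 0]
    if single:
        return out[0], attention[0], float(logits[0])
    return out, attention, logits


def discriminate(discriminator, images, apply_sigmoid: bool = False):
    """Run a (multi-scale) discriminator on numpy images.

    Returns ``(realness_maps, cam_logits)``; with ``apply_sigmoid`` the
    realness maps are squashed to (0, 1) for the log-adversarial variant.
    """
    x, single = _to_nchw(images)
    out = discriminator(Tensor(x))
    maps, logits = out
    if not isinstance(maps, list):
        maps, logits = [maps], [logits]
    maps = [m.sigmoid() if apply_sigmoid else m for m in maps]
    maps = [m.data[:, 0] for m in maps]
    logits = [l.data[:, 0] for l in logits]
    if single:
        maps = [m[0] for m in maps]
        logits = [float(l[0]) for l in logits]
    if len(maps) == 1:
        return maps[0], logits[0]
    return maps, logits
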