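"""Objectives for unpaired translation: CycleGAN, U-GAT-IT and MIND-augmented totals.

Both frameworks train two generators (MRI→CT and CT→MRI) against two
discriminators.  CycleGAN combines a log-adversarial term with cycle and
identity consistency:

    L_CycleGAN = L_GAN(A→B) + L_GAN(B→A) + λ1·L_cyc + λ2·L_identity.

U-GAT-IT swaps the adversarial term for its least-squares form and adds
class-activation-map (CAM) losses from auxiliary domain classifiers in the
generators and discriminators:

    L_U-GAT-IT = L'_GAN(A→B) + L'_GAN(B→A) + λ1·L_cyc + λ2·L_identity
                 + λ3·(L_cam^G_ab + L_cam^G_ba + L_cam^D_b + L_cam^D_a).

The structure-constrained variants add the neighbourhood-descriptor
consistency term λ_MIND·L_MIND to either total.  Published training weights:
λ1=10, λ2=0.5, λ_MIND=20 for CycleGAN(+MIND) and λ1=λ2=λ3=100, λ_MIND=5000
for U-GAT-IT(+MIND).

All functions accept plain numpy arrays or autodiff Tensors; batch reduction
is the mean, and the two translation directions are summed.  Least-squares
terms follow the standard LSGAN targets (discriminator: real→1, fake→0;
generator: fake→1); see docs/methods.md for the sign-convention discussion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor

__all__ = [
    "LossWeights",
    "LossReport",
    "adv_loss_log",
    "adv_loss_ls",
    "cycle_loss",
    "identity_loss",
    "cam_loss_generator",
    "cam_loss_discriminator",
    "total_loss",
    "GENERATOR_COMPONENTS",
    "DISCRIMINATOR_COMPONENTS",
]

SCORE_EPS = 1e-7  # log-loss scores are clamped to [eps, 1-eps]


@dataclass(frozen=True)
class LossWeights:
    """The λ coefficients of one training objective (all non-negative)."""

    lambda_cycle: float = 10.0
    lambda_identity: float = 0.5
    lambda_cam: float = 0.0
    lambda_mind: float = 0.0

    def __post_init__(self):
        for name in ("lambda_cycle", "lambda_identity", "lambda_cam", "lambda_mind"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def cyclegan_defaults(cls, with_mind: bool = False) -> "LossWeights":
        return cls(lambda_cycle=10.0, lambda_identity=0.5, lambda_cam=0.0,
                   lambda_mind=20.0 if with_mind else 0.0)

    @classmethod
    def ugatit_defaults(cls, with_mind: bool = False) -> "LossWeights":
        return cls(lambda_cycle=100.0, lambda_identity=100.0, lambda_cam=100.0,
                   lambda_mind=5000.0 if with_mind else 0.0)

    @classmethod
    def defaults(cls, variant: str, with_mind: bool = False) -> "LossWeights":
        if variant == "cyclegan":
            return cls.cyclegan_defaults(with_mind)
        if variant == "ugatit":
            return cls.ugatit_defaults(with_mind)
        raise ValueError(f"unknown variant {variant!r}")


@dataclass
class LossReport:
    """Named scalar components of one optimisation step.

    ``adv_g``, ``adv_d``, ``cam_g`` and ``cam_d`` are already summed over
    the two translation directions.  ``total_g`` and ``total_d`` equal the
    weighted sums of the components under the report's weights.
    """

    adv_g: float = 0.0
    adv_d: float = 0.0
    cycle: float = 0.0
    identity: float = 0.0
    cam_g: float = 0.0
    cam_d: float = 0.0
    mind: float = 0.0
    total_g: float = 0.0
    total_d: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {k: float(v) for k, v in vars(self).items()}


def _is_tensor(*args) -> bool:
    return any(isinstance(a, Tensor) for a in args)


def _coerce(x) -> Tensor:
    if isinstance(x, Tensor):
        if x.data.size == 0:
            raise ValueError("empty batch of scores")
        return x
    arr = np.asarray(x, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("empty batch of scores")
    return Tensor(arr)


def _ret(value: Tensor, tensor_mode: bool):
    return value if tensor_mode else float(value.data)


def adv_loss_log(d_real, d_fake):
    """Log (non-saturating cross-entropy) adversarial terms.

    Scores must be post-sigmoid realness probabilities; they are clamped to
    ``[eps, 1-eps]`` so both terms stay finite.

    Returns ``(generator_term, discriminator_term)`` with
    ``d_term = -E[log d_real] - E[log(1 - d_fake)]`` and
    ``g_term = -E[log d_fake]``.
    """
    tensor_mode = _is_tensor(d_real, d_fake)
    dr = _coerce(d_real).clamp(SCORE_EPS, 1.0 - SCORE_EPS)
    df = _coerce(d_fake).clamp(SCORE_EPS, 1.0 - SCORE_EPS)
    d_term = -(dr.log().mean()) - ((1.0 - df).log().mean())
    g_term = -(df.log().mean())
    return _ret(g_term, tensor_mode), _ret(d_term, tensor_mode)


def adv_loss_ls(d_real, d_fake):
    """Least-squares adversarial terms (LSGAN targets: real→1, fake→0).

    Returns ``(generator_term, discriminator_term)`` with
    ``d_term = E[(d_real - 1)^2] + E[d_fake^2]`` and
    ``g_term = E[(d_fake - 1)^2]``.
    """
    tensor_mode = _is_tensor(d_real, d_fake)
    dr = _coerce(d_real)
    df = _coerce(d_fake)
    d_term = ((dr - 1.0) ** 2).mean() + (df ** 2).mean()
    g_term = ((df - 1.0) ** 2).mean()
    return _ret(g_term, tensor_mode), _ret(d_term, tensor_mode)


def _batch(images) -> np.ndarray:
    arr = np.asarray(images, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.size == 0:
        raise ValueError("empty image batch")
    return arr


def _mae(a: np.ndarray, b: np.ndarray, what: str) -> float:
    if a.shape != b.shape:
        raise ValueError(f"{what}: generator changed the image shape "
                         f"({b.shape} vs {a.shape})")
    return float(np.mean(np.abs(a - b)))


def cycle_loss(g_ab, g_ba, batch_a, batch_b) -> float:
    """Round-trip reconstruction error, summed over the two directions.

    ``mean |g_ba(g_ab(a)) - a| + mean |g_ab(g_ba(b)) - b|`` with callables
    mapping image batches to same-shaped image batches.
    """
    a = _batch(batch_a)
    b = _batch(batch_b)
    ra = np.asarray(g_ba(np.asarray(g_ab(a))))
    rb = np.asarray(g_ab(np.asarray(g_ba(b))))
    return _mae(a, ra, "cycle a->b->a") + _mae(b, rb, "cycle b->a->b")


def identity_loss(g_ab, g_ba, batch_a, batch_b) -> float:
    """Error of each generator applied to its *target* domain, summed.

    ``g_ab`` translates a→b, so it should leave a b-domain image unchanged:
    ``mean |g_ab(b) - b| + mean |g_ba(a) - a|``.
    """
    a = _batch(batch_a)
    b = _batch(batch_b)
    return (_mae(b, np.asarray(g_ab(b)), "identity on b")
            + _mae(a, np.asarray(g_ba(a)), "identity on a"))


def cam_loss_generator(eta_src, eta_tgt):
    """CAM loss of one generator's auxiliary classifier.

    The classifier should fire on source-domain inputs (η_src→1) and stay
    silent on target-domain inputs (η_tgt→0):
    ``-(E[log η_src] + E[log(1 - η_tgt)])``, with clamped probabilities.
    """
    tensor_mode = _is_tensor(eta_src, eta_tgt)
    es = _coerce(eta_src).clamp(SCORE_EPS, 1.0 - SCORE_EPS)
    et = _coerce(eta_tgt).clamp(SCORE_EPS, 1.0 - SCORE_EPS)
    out = -(es.log().mean() + (1.0 - et).log().mean())
    return _ret(out, tensor_mode)


def cam_loss_discriminator(eta_real, eta_fake):
    """Least-squares CAM loss of one discriminator's auxiliary classifier
    (real→1, fake→0): ``E[(η_real - 1)^2] + E[η_fake^2]``."""
    tensor_mode = _is_tensor(eta_real, eta_fake)
    er = _coerce(eta_real)
    ef = _coerce(eta_fake)
    out = ((er - 1.0) ** 2).mean() + (ef ** 2).mean()
    return _ret(out, tensor_mode)


GENERATOR_COMPONENTS = ("adv_g_ab", "adv_g_ba", "cycle", "identity")
DISCRIMINATOR_COMPONENTS = ("adv_d_ab", "adv_d_ba")
_CAM_G = ("cam_g_ab", "cam_g_ba")
_CAM_D = ("cam_d_ab", "cam_d_ba")


def total_loss(variant: str, with_mind: bool, components: dict,
               weights: LossWeights | None = None) -> LossReport:
    """Assemble the weighted totals of one optimisation step.

    Parameters
    ----------
    variant : {"cyclegan", "ugatit"}
    with_mind : bool
        Whether the λ_MIND·L_MIND term is included.
    components : dict
        Per-direction scalar components: ``adv_g_ab``, ``adv_g_ba``,
        ``adv_d_ab``, ``adv_d_ba``, ``cycle``, ``identity``; for the
        ugatit variant additionally ``cam_g_ab``, ``cam_g_ba``,
        ``cam_d_ab``, ``cam_d_ba``; with MIND additionally ``mind``.
        Values may be floats or autodiff Tensors.
    weights : LossWeights, optional
        Defaults to the published weights of the chosen variant.

    Returns a :class:`LossReport`; ``total_g``/``total_d`` keep the input
    type, so Tensor components yield differentiable totals.
    """
    if variant not in ("cyclegan", "ugatit"):
        raise ValueError(f"unknown variant {variant!r}")
    if weights is None:
        weights = LossWeights.defaults(variant, with_mind)

    required = list(GENERATOR_COMPONENTS + DISCRIMINATOR_COMPONENTS)
    if variant == "ugatit":
        required += list(_CAM_G + _CAM_D)
    if with_mind:
        required.append("mind")
    missing = [k for k in required if k not in components]
    if missing:
        raise KeyError(f"missing loss components for variant={variant!r}, "
                       f"with_mind={with_mind}: {missing}")
    unexpected = [k for k in (_CAM_G + _CAM_D) if k in components
                  and variant == "cyclegan"]
    if unexpected:
        raise KeyError(f"CAM components {unexpected} are only valid for the "
                       "ugatit variant")

    c = components
    adv_g = c["adv_g_ab"] + c["adv_g_ba"]
    adv_d = c["adv_d_ab"] + c["adv_d_ba"]
    total_g = (adv_g + weights.lambda_cycle * c["cycle"]
               + weights.lambda_identity * c["identity"])
    total_d = adv_d
    cam_g = cam_d = 0.0
    if variant == "ugatit":
        cam_g = c["cam_g_ab"] + c["cam_g_ba"]
        cam_d = c["cam_d_ab"] + c["cam_d_ba"]
        total_g = total_g + weights.lambda_cam * cam_g
        total_d = total_d + weights.lambda_cam * cam_d
    mind = c.get("mind", 0.0)
    if with_mind:
        total_g = total_g + weights.lambda_mind * mind

    return LossReport(adv_g=adv_g, adv_d=adv_d, cycle=c["cycle"],
                      identity=c["identity"], cam_g=cam_g, cam_d=cam_d,
                      mind=mind, total_g=total_g, total_d=total_d)
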