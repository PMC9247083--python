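"""Alternating min–max training of the four translation variants.

One optimisation step performs a discriminator update on the full
discriminator objective (adversarial terms of both directions, plus the CAM
discriminator terms for the U-GAT-IT variant), then a generator update on
the full generator objective (adversarial + λ1·cycle + λ2·identity
[+ λ3·CAM] [+ λ_MIND·MIND]).  Generators and discriminators have separate
Adam optimisers; the AdaLIN mixing weights are projected back into [0, 1]
after every generator step.

Supported variants: ``cyclegan`` (log-adversarial) and ``ugatit``
(least-squares adversarial + CAM), each with or without the MIND
consistency term.  Published clinical-scale settings: Adam, learning rate
0.0002 / 1000 epochs for the CycleGAN variants and 0.0001 / 100 epochs for
the U-GAT-IT variants, batch size 1; desk-scale defaults in
:class:`TrainingConfig` are far smaller (see docs/methods.md).

The module exposes the procedural surface (``training_step``, ``train``,
``infer``) and a scikit-learn style estimator :class:`UnpairedTranslator`
(``fit`` on two unpaired image stacks, ``transform`` = MRI→CT,
``inverse_transform`` = CT→MRI).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .autodiff import Adam, Module, Tensor, concat
from .losses import (LossReport, LossWeights, adv_loss_log, adv_loss_ls,
                     cam_loss_generator, cam_loss_discriminator, total_loss)
from .mind import MINDConfig, mind_descriptor_tensor
from .networks import Generator, MultiScaleDiscriminator

__all__ = ["TrainingConfig", "RunState", "TranslationModel", "Trainer",
           "training_step", "train", "infer", "load_checkpoint",
           "UnpairedTranslator"]

VARIANTS = ("cyclegan", "ugatit")


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of one training run.

    ``learning_rate`` defaults to 2e-4 for the CycleGAN variants and 1e-4
    for the U-GAT-IT variants when left ``None``; ``weights`` defaults to
    the published λ values of the chosen variant.
    """

    variant: str = "ugatit"
    with_mind: bool = True
    weights: LossWeights | None = None
    learning_rate: float | None = None
    adam_betas: tuple[float, float] = (0.5, 0.999)
    epochs: int = 30
    batch_size: int = 1
    image_size: int = 64
    base_width: int = 16
    n_down: int = 2
    n_res: int = 2
    disc_layers: int = 3
    disc_scales: int = 1
    spectral_norm: bool = True
    mind_search_radius: int = 4
    mind_patch_radius: int = 1
    seed: int = 0
    checkpoint_every: int = 0       # epochs between checkpoints; 0 = final only
    deterministic: bool = True
    image_pool: bool = False        # buffer past fakes for the D update
    pool_size: int = 50

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        lr = self.learning_rate
        if lr is not None and lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.image_size % (2 ** self.n_down):
            raise ValueError("image_size must be divisible by 2**n_down")

    @property
    def lr(self) -> float:
        if self.learning_rate is not None:
            return self.learning_rate
        return 2e-4 if self.variant == "cyclegan" else 1e-4

    def resolved_weights(self) -> LossWeights:
        return self.weights or LossWeights.defaults(self.variant, self.with_mind)

    def mind_config(self) -> MINDConfig:
        return MINDConfig.from_radii(self.mind_search_radius,
                                     self.mind_patch_radius)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        if self.weights is not None:
            d["weights"] = dataclasses.asdict(self.weights)
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "TrainingConfig":
        d = json.loads(text)
        if d.get("weights") is not None:
            d["weights"] = LossWeights(**d["weights"])
        d["adam_betas"] = tuple(d["adam_betas"])
        return cls(**d)


@dataclass
class RunState:
    """Mutable bookkeeping of a run: step counter, loss history, artifacts."""

    iteration: int = 0
    history: list[dict] = field(default_factory=list)
    checkpoints: list[str] = field(default_factory=list)


class TranslationModel(Module):
    """The two generators and two discriminators of one variant."""

    def __init__(self, config: TrainingConfig):
        self.config = config
        s = config.seed
        self.g_ab = Generator(config.base_width, config.n_down, config.n_res,
                              seed=s)
        self.g_ba = Generator(config.base_width, config.n_down, config.n_res,
                              seed=s + 1)
        self.d_a = MultiScaleDiscriminator(config.base_width, config.disc_layers,
                                           config.disc_scales,
                                           config.spectral_norm, seed=s + 2)
        self.d_b = MultiScaleDiscriminator(config.base_width, config.disc_layers,
                                           config.disc_scales,
                                           config.spectral_norm, seed=s + 3)

    def generator_parameters(self):
        return self.g_ab.parameters() + self.g_ba.parameters()

    def discriminator_parameters(self):
        return self.d_a.parameters() + self.d_b.parameters()


def _adv_terms(variant: str, maps_real, maps_fake):
    """Per-scale adversarial terms summed over scales."""
    g_sum = d_sum = 0.0
    for m_real, m_fake in zip(maps_real, maps_fake):
        if variant == "cyclegan":
            g, d = adv_loss_log(m_real.sigmoid(), m_fake.sigmoid())
        else:
            g, d = adv_loss_ls(m_real, m_fake)
        g_sum = g_sum + g
        d_sum = d_sum + d
    return g_sum, d_sum


def _cam_d_terms(logits_real, logits_fake):
    out = 0.0
    for lr_, lf in zip(logits_real, logits_fake):
        out = out + cam_loss_discriminator(lr_, lf)
    return out


def _check_finite(report: LossReport) -> None:
    for name, value in report.as_dict().items():
        if not np.isfinite(value):
            raise RuntimeError(f"non-finite loss component {name!r} "
                               f"({value}); aborting training step")


class _ImagePool:
    """Replay buffer of past generator outputs for the discriminator update."""

    def __init__(self, size: int, rng: np.random.Generator):
        self.size = size
        self.rng = rng
        self.buffer: list[np.ndarray] = []

    def query(self, fake: np.ndarray) -> np.ndarray:
        if self.size == 0:
            return fake
        out = []
        for img in fake:
            if len(self.buffer) < self.size:
                self.buffer.append(img.copy())
                out.append(img)
            elif self.rng.random() < 0.5:
                idx = int(self.rng.integers(len(self.buffer)))
                out.append(self.buffer[idx].copy())
                self.buffer[idx] = img.copy()
            else:
                out.append(img)
        return np.stack(out)


class Trainer:
    """Stateful training driver for one variant on in-memory image stacks."""

    def __init__(self, config: TrainingConfig):
        self.config = config
        self.model = TranslationModel(config)
        self.opt_g = Adam(self.model.generator_parameters(), lr=config.lr,
                          betas=config.adam_betas)
        self.opt_d = Adam(self.model.discriminator_parameters(), lr=config.lr,
                          betas=config.adam_betas)
        self.state = RunState()
        self.rng = np.random.Generator(np.random.Philox(
            key=np.array([np.uint64(config.seed), np.uint64(0xD1CE)],
                         dtype=np.uint64)))
        self._mind_cfg = config.mind_config()
        self._weights = config.resolved_weights()
        pool_rng = np.random.Generator(np.random.Philox(
            key=np.array([np.uint64(config.seed), np.uint64(0xB00F)],
                         dtype=np.uint64)))
        self.pool_a = _ImagePool(config.pool_size if config.image_pool else 0,
                                 pool_rng)
        self.pool_b = _ImagePool(config.pool_size if config.image_pool else 0,
                                 pool_rng)

    # ------------------------------------------------------------------ step
    def step(self, batch_a: np.ndarray, batch_b: np.ndarray) -> LossReport:
        """One discriminator update followed by one generator update."""
        cfg = self.config
        w = self._weights
        ugatit = cfg.variant == "ugatit"
        use_mind = cfg.with_mind and w.lambda_mind > 0

        xa = Tensor(np.asarray(batch_a, dtype=np.float32)[:, None])
        xb = Tensor(np.asarray(batch_b, dtype=np.float32)[:, None])
        n = xa.shape[0]

        # ---------------- discriminator update
        fake_b = self.model.g_ab(xa)[0].detach()
        fake_a = self.model.g_ba(xb)[0].detach()
        fake_b_d = Tensor(self.pool_b.query(fake_b.data))
        fake_a_d = Tensor(self.pool_a.query(fake_a.data))

        # real and fake share one discriminator pass (per-sample statistics
        # only, so this is identical to two separate passes)
        maps_b, logits_b = self.model.d_b(concat([xb, fake_b_d], axis=0))
        maps_a, logits_a = self.model.d_a(concat([xa, fake_a_d], axis=0))
        maps_real_b = [m[:n] for m in maps_b]
        maps_fake_b = [m[n:] for m in maps_b]
        maps_real_a = [m[:n] for m in maps_a]
        maps_fake_a = [m[n:] for m in maps_a]
        logits_real_b = [l[:n] for l in logits_b]
        logits_fake_b = [l[n:] for l in logits_b]
        logits_real_a = [l[:n] for l in logits_a]
        logits_fake_a = [l[n:] for l in logits_a]

        _, adv_d_ab = _adv_terms(cfg.variant, maps_real_b, maps_fake_b)
        _, adv_d_ba = _adv_terms(cfg.variant, maps_real_a, maps_fake_a)
        total_d = adv_d_ab + adv_d_ba
        cam_d_ab = cam_d_ba = 0.0
        if ugatit:
            cam_d_ab = _cam_d_terms(logits_real_b, logits_fake_b)
            cam_d_ba = _cam_d_terms(logits_real_a, logits_fake_a)
            total_d = total_d + w.lambda_cam * (cam_d_ab + cam_d_ba)

        self.opt_d.zero_grad()
        total_d.backward()
        self.opt_d.step()

        # ---------------- generator update
        self.opt_g.zero_grad()
        self.opt_d.zero_grad()  # discard the cross-grads of the G backward

        # translation and identity inputs share one pass per generator
        out_ab, _, logit_ab = self.model.g_ab(concat([xa, xb], axis=0))
        out_ba, _, logit_ba = self.model.g_ba(concat([xb, xa], axis=0))
        fake_b, ident_b = out_ab[:n], out_ab[n:]
        fake_a, ident_a = out_ba[:n], out_ba[n:]
        logit_ab_a, logit_ab_b = logit_ab[:n], logit_ab[n:]
        logit_ba_b, logit_ba_a = logit_ba[:n], logit_ba[n:]
        cyc_a = self.model.g_ba(fake_b)[0]
        cyc_b = self.model.g_ab(fake_a)[0]

        cycle = (cyc_a - xa).abs().mean() + (cyc_b - xb).abs().mean()
        identity = (ident_b - xb).abs().mean() + (ident_a - xa).abs().mean()

        # the generator's adversarial term only involves the fake maps, so the
        # real-score argument is passed detached and ignored by the G term
        maps_fb, _ = self.model.d_b(fake_b)
        maps_fa, _ = self.model.d_a(fake_a)
        adv_g_ab = 0.0
        for m in maps_fb:
            if cfg.variant == "cyclegan":
                adv_g_ab = adv_g_ab + adv_loss_log(m.sigmoid().detach(),
                                                   m.sigmoid())[0]
            else:
                adv_g_ab = adv_g_ab + adv_loss_ls(m.detach(), m)[0]
        adv_g_ba = 0.0
        for m in maps_fa:
            if cfg.variant == "cyclegan":
                adv_g_ba = adv_g_ba + adv_loss_log(m.sigmoid().detach(),
                                                   m.sigmoid())[0]
            else:
                adv_g_ba = adv_g_ba + adv_loss_ls(m.detach(), m)[0]

        total_g = adv_g_ab + adv_g_ba + w.lambda_cycle * cycle \
            + w.lambda_identity * identity
        cam_g_ab = cam_g_ba = 0.0
        if ugatit:
            cam_g_ab = cam_loss_generator(logit_ab_a.sigmoid(),
                                          logit_ab_b.sigmoid())
            cam_g_ba = cam_loss_generator(logit_ba_b.sigmoid(),
                                          logit_ba_a.sigmoid())
            total_g = total_g + w.lambda_cam * (cam_g_ab + cam_g_ba)
        mind = 0.0
        if use_mind:
            # one batched descriptor pass over all four images (per-sample
            # statistics, identical to four separate passes)
            desc = mind_descriptor_tensor(
                concat([fake_b, xa, fake_a, xb], axis=0), self._mind_cfg)
            mind = ((desc[:n] - desc[n:2 * n]).abs().mean()
                    + (desc[2 * n:3 * n] - desc[3 * n:]).abs().mean())
            total_g = total_g + w.lambda_mind * mind

        total_g.backward()
        self.opt_g.step()
        self.opt_d.zero_grad()
        self.model.g_ab.clamp_rho()
        self.model.g_ba.clamp_rho()

        def val(x):
            return float(x.data) if isinstance(x, Tensor) else float(x)

        components = {
            "adv_g_ab": val(adv_g_ab), "adv_g_ba": val(adv_g_ba),
            "adv_d_ab": val(adv_d_ab), "adv_d_ba": val(adv_d_ba),
            "cycle": val(cycle), "identity": val(identity),
        }
        if ugatit:
            components.update(cam_g_ab=val(cam_g_ab), cam_g_ba=val(cam_g_ba),
                              cam_d_ab=val(cam_d_ab), cam_d_ba=val(cam_d_ba))
        if cfg.with_mind:
            components["mind"] = val(mind)
        report = total_loss(cfg.variant, cfg.with_mind, components, w)
        _check_finite(report)
        self.state.iteration += 1
        self.state.history.append(report.as_dict())
        return report

    # ------------------------------------------------------------------ loop
    def fit(self, images_a: np.ndarray, images_b: np.ndarray,
            run_dir: str | Path | None = None,
            val_samples=None, max_steps: int | None = None) -> RunState:
        """Run the epoch loop; optionally log/checkpoint under ``run_dir``.

        ``val_samples`` is an optional list of phantom samples from domain A
        whose translations are scored (mean bone Dice) to select the best
        checkpoint.
        """
        cfg = self.config
        a = np.asarray(images_a, dtype=np.float32)
        b = np.asarray(images_b, dtype=np.float32)
        if a.ndim != 3 or b.ndim != 3 or a.shape[0] == 0 or b.shape[0] == 0:
            raise ValueError("each domain needs a nonempty (n, H, W) stack")
        run_dir = Path(run_dir) if run_dir is not None else None
        log_rows = []
        best_score = -np.inf
        steps_per_epoch = max(len(a), len(b)) // cfg.batch_size
        steps_per_epoch = max(steps_per_epoch, 1)
        done = False
        steps_here = 0
        for epoch in range(cfg.epochs):
            order_a = self.rng.permutation(len(a))
            order_b = self.rng.permutation(len(b))
            for s in range(steps_per_epoch):
                ia = order_a[(s * cfg.batch_size + np.arange(cfg.batch_size))
                             % len(a)]
                ib = order_b[(s * cfg.batch_size + np.arange(cfg.batch_size))
                             % len(b)]
                report = self.step(a[ia], b[ib])
                log_rows.append(report.as_dict())
                steps_here += 1
                if max_steps is not None and steps_here >= max_steps:
                    done = True
                    break
            if run_dir is not None and cfg.checkpoint_every and \
                    (epoch + 1) % cfg.checkpoint_every == 0:
                self.save_checkpoint(run_dir / f"checkpoint_ep{epoch + 1:04d}.npz")
            if val_samples is not None:
                score = self._validation_score(val_samples)
                if score > best_score:
                    best_score = score
                    if run_dir is not None:
                        self.save_checkpoint(run_dir / "checkpoint_best.npz")
            if done:
                break
        if run_dir is not None:
            run_dir.mkdir(parents=True, exist_ok=True)
            self.save_checkpoint(run_dir / "checkpoint_final.npz")
            (run_dir / "config.json").write_text(cfg.to_json())
            self._write_log(run_dir / "loss_log.tsv", log_rows)
        return self.state

    def _validation_score(self, val_samples) -> float:
        from .evaluation import structure_report
        from .networks import translate as _translate
        imgs = np.stack([s.image for s in val_samples]).astype(np.float32)
        synth, _, _ = _translate(self.model.g_ab, imgs)
        scores = [structure_report(s, y)["bone_dice"]
                  for s, y in zip(val_samples, synth)]
        return float(np.mean(scores))

    @staticmethod
    def _spectral_vectors(module) -> list[np.ndarray]:
        """All spectral-norm power-iteration vectors, in traversal order."""
        from .networks import Conv2d

        found: list[np.ndarray] = []

        def walk(value):
            if isinstance(value, Conv2d) and value.spectral_norm:
                found.append(value._u)
            if isinstance(value, Module):
                for v in vars(value).values():
                    walk(v)
            elif isinstance(value, (list, tuple)):
                for v in value:
                    walk(v)

        walk(module)
        return found

    @staticmethod
    def _set_spectral_vectors(module, arrays: list[np.ndarray]) -> None:
        from .networks import Conv2d

        idx = 0

        def walk(value):
            nonlocal idx
            if isinstance(value, Conv2d) and value.spectral_norm:
                value._u = arrays[idx].copy()
                idx += 1
            if isinstance(value, Module):
                for v in vars(value).values():
                    walk(v)
            elif isinstance(value, (list, tuple)):
                for v in value:
                    walk(v)

        walk(module)

    @staticmethod
    def _write_log(path: Path, rows: list[dict]) -> None:
        if not rows:
            path.write_text("")
            return
        cols = list(rows[0].keys())
        lines = ["step\t" + "\t".join(cols)]
        for i, row in enumerate(rows):
            lines.append(str(i) + "\t" + "\t".join(f"{row[c]:.6g}" for c in cols))
        path.write_text("\n".join(lines) + "\n")

    # ---------------------------------------------------------- persistence
    def save_checkpoint(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for name in ("g_ab", "g_ba", "d_a", "d_b"):
            for i, arr in enumerate(getattr(self.model, name).state_arrays()):
                arrays[f"{name}_{i}"] = arr
        for tag, opt in (("og", self.opt_g), ("od", self.opt_d)):
            st = opt.state()
            arrays[f"{tag}_t"] = np.array(st["t"])
            for i, m in enumerate(st["m"]):
                arrays[f"{tag}_m_{i}"] = m
            for i, v in enumerate(st["v"]):
                arrays[f"{tag}_v_{i}"] = v
        for i, u in enumerate(self._spectral_vectors(self.model)):
            arrays[f"sn_u_{i}"] = u
        def _np_default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, np.generic):
                return o.item()
            raise TypeError(f"not JSON-serialisable: {type(o)}")

        meta = {"config": self.config.to_json(),
                "iteration": self.state.iteration,
                "rng_state": json.dumps(self.rng.bit_generator.state,
                                        default=_np_default)}
        np.savez(path, _meta=json.dumps(meta), **arrays)
        self.state.checkpoints.append(str(path))
        return path

    @classmethod
    def from_checkpoint(cls, path: str | Path) -> "Trainer":
        path = Path(path)
        if not path.exists():
            raise IOError(f"checkpoint {path} does not exist")
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["_meta"]))
        config = TrainingConfig.from_json(meta["config"])
        trainer = cls(config)
        for name in ("g_ab", "g_ba", "d_a", "d_b"):
            module = getattr(trainer.model, name)
            n = len(module.parameters())
            module.load_state_arrays([data[f"{name}_{i}"] for i in range(n)])
        for tag, opt in (("og", trainer.opt_g), ("od", trainer.opt_d)):
            n = len(opt.params)
            opt.load_state({
                "t": int(data[f"{tag}_t"]),
                "m": [data[f"{tag}_m_{i}"] for i in range(n)],
                "v": [data[f"{tag}_v_{i}"] for i in range(n)],
            })
        n_sn = len(cls._spectral_vectors(trainer.model))
        if n_sn and f"sn_u_{0}" in data:
            cls._set_spectral_vectors(
                trainer.model, [data[f"sn_u_{i}"] for i in range(n_sn)])
        trainer.state.iteration = int(meta["iteration"])
        rng_state = json.loads(meta["rng_state"])
        # JSON round-trips the Philox counters as lists; restore dtypes
        for k in ("counter", "key"):
            rng_state["state"][k] = np.array(rng_state["state"][k],
                                             dtype=np.uint64)
        if "buffer" in rng_state:
            rng_state["buffer"] = np.array(rng_state["buffer"],
                                           dtype=np.uint64)
        trainer.rng.bit_generator.state = rng_state
        return trainer


# --------------------------------------------------------------------------
# procedural surface
# --------------------------------------------------------------------------

def training_step(trainer: Trainer, batch_a, batch_b) -> LossReport:
    """One alternating min–max step (discriminators, then generators)."""
    return trainer.step(np.asarray(batch_a), np.asarray(batch_b))


def _load_domain(path: Path) -> np.ndarray:
    from .imageio import read_image
    files = sorted(p for p in Path(path).iterdir()
                   if p.suffix.lower() in (".png", ".nii", ".dcm")
                   or p.name.lower().endswith(".nii.gz"))
    if not files:
        raise ValueError(f"no readable images found in {path}")
    return np.stack([read_image(f) for f in files])


def train(config: TrainingConfig, domain_a, domain_b,
          run_dir: str | Path = "run", val_samples=None) -> Path:
    """Train on two unpaired domains and write a run directory.

    ``domain_a`` / ``domain_b`` are directories of images or ``(n, H, W)``
    arrays.  The run directory receives checkpoints, a machine-readable
    ``loss_log.tsv`` (one row per step, one column per loss component) and
    a config snapshot.
    """
    a = _load_domain(Path(domain_a)) if isinstance(domain_a, (str, Path)) \
        else np.asarray(domain_a)
    b = _load_domain(Path(domain_b)) if isinstance(domain_b, (str, Path)) \
        else np.asarray(domain_b)
    trainer = Trainer(config)
    trainer.fit(a, b, run_dir=run_dir, val_samples=val_samples)
    return Path(run_dir)


def load_checkpoint(path) -> Trainer:
    """Restore a full training state (parameters, optimisers, RNG)."""
    return Trainer.from_checkpoint(path)


def infer(checkpoint, images, direction: str = "ab"):
    """Translate images with a trained checkpoint.

    Returns ``(synthesized, attention_maps)``; attention maps are ``None``
    for the CycleGAN variants (no attention module is part of that design's
    published form, but the generator here always computes one, so they are
    returned only for ugatit checkpoints to match the variant contract).
    """
    from .networks import translate as _translate
    trainer = checkpoint if isinstance(checkpoint, Trainer) \
        else Trainer.from_checkpoint(checkpoint)
    gen = trainer.model.g_ab if direction == "ab" else trainer.model.g_ba
    synth, attention, _ = _translate(gen, np.asarray(images, dtype=np.float32))
    if trainer.config.variant != "ugatit":
        attention = None
    return synth, attention


# --------------------------------------------------------------------------
# estimator surface
# --------------------------------------------------------------------------

class UnpairedTranslator(TransformerMixin, BaseEstimator):
    """Unpaired image-to-image translator (MRI→CT) as an estimator.

    Parameters mirror :class:`TrainingConfig`; ``fit(X, Y)`` trains on two
    unpaired stacks of ``(n, H, W)`` images in [0, 1] (X = source/MRI
    domain, Y = target/CT domain), ``transform`` maps source→target and
    ``inverse_transform`` target→source.

    Fitted attributes: ``trainer_`` (the underlying training state),
    ``history_`` (list of per-step loss-component dicts), ``n_steps_``.
    """

    def __init__(self, variant: str = "ugatit", with_mind: bool = True,
                 lambda_mind: float | None = None, epochs: int = 30,
                 batch_size: int = 1, image_size: int = 64,
                 base_width: int = 16, n_res: int = 2, disc_layers: int = 3,
                 disc_scales: int = 1, mind_search_radius: int = 4,
                 learning_rate: float | None = None, max_steps: int | None = None,
                 seed: int = 0):
        self.variant = variant
        self.with_mind = with_mind
        self.lambda_mind = lambda_mind
        self.epochs = epochs
        self.batch_size = batch_size
        self.image_size = image_size
        self.base_width = base_width
        self.n_res = n_res
        self.disc_layers = disc_layers
        self.disc_scales = disc_scales
        self.mind_search_radius = mind_search_radius
        self.learning_rate = learning_rate
        self.max_steps = max_steps
        self.seed = seed

    def _config(self) -> TrainingConfig:
        weights = None
        if self.lambda_mind is not None:
            base = LossWeights.defaults(self.variant, self.with_mind)
            weights = LossWeights(base.lambda_cycle, base.lambda_identity,
                                  base.lambda_cam, self.lambda_mind)
        return TrainingConfig(variant=self.variant, with_mind=self.with_mind,
                              weights=weights, learning_rate=self.learning_rate,
                              epochs=self.epochs, batch_size=self.batch_size,
                              image_size=self.image_size,
                              base_width=self.base_width, n_res=self.n_res,
                              disc_layers=self.disc_layers,
                              disc_scales=self.disc_scales,
                              mind_search_radius=self.mind_search_radius,
                              seed=self.seed)

    def fit(self, X, Y=None):
        if Y is None:
            raise ValueError("fit requires the second (target-domain) stack")
        config = self._config()
        self.trainer_ = Trainer(config)
        self.trainer_.fit(np.asarray(X), np.asarray(Y),
                          max_steps=self.max_steps)
        self.history_ = self.trainer_.state.history
        self.n_steps_ = self.trainer_.state.iteration
        return self

    def transform(self, X) -> np.ndarray:
        from .networks import translate as _translate
        self._check_fitted()
        out, _, _ = _translate(self.trainer_.model.g_ab,
                               np.asarray(X, dtype=np.float32))
        return out

    def inverse_transform(self, X) -> np.ndarray:
        from .networks import translate as _translate
        self._check_fitted()
        out, _, _ = _translate(self.trainer_.model.g_ba,
                               np.asarray(X, dtype=np.float32))
        return out

    def _check_fitted(self):
        if not hasattr(self, "trainer_"):
            raise RuntimeError("this UnpairedTranslator instance is not "
                               "fitted yet; call fit first")
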