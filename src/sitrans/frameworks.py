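"""Training loops for the four translation frameworks.

Each iteration performs one alternating update -- critic(s) and/or
regressor first, then the generator -- with Adam optimizers.  A master
seed fans out into independent random streams (weight init, batch
sampling, target-attribute sampling, augmentation, gradient-penalty
interpolation, the ipgan loss-splitting coin), so full runs are
bit-reproducible and checkpoints resume exactly.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .data import AugmentationConfig, ImageAttributeDataset, augment_batch
from .networks import (
    Critic,
    CriticConfig,
    GeneratorConfig,
    LatentCritic,
    Regressor,
    TransformDecomposition,
    UNetGenerator,
)
from .objectives import (
    FRAMEWORKS,
    LossWeights,
    TranslationBatch,
    adversarial_gen_loss,
    conditional_critic_terms,
    cycle_loss,
    identity_preserving_loss,
    latent_adversarial_losses,
    reconstruction_loss,
    regressor_mse,
    relative_attribute_loss,
    total_generator_loss,
    wgan_gp_critic_loss,
)

_STREAMS = ("init", "batch", "target", "augment", "gp", "coin", "prior")


class TrainingDiverged(RuntimeError):
    """Raised when a loss becomes non-finite; carries the loss record."""

    def __init__(self, iteration, record):
        super().__init__(f"non-finite loss at iteration {iteration}: {record}")
        self.iteration = iteration
        self.record = record


@dataclass
class TrainingConfig:
    framework: str = "stargan"
    parameterization: str = "sit_diff"
    max_iterations: int = 10000
    batch_size: int = 8
    lr_generator: float = 1e-3
    lr_critic: float | None = None  # default 1e-3; 1e-4 for caae critics
    lr_regressor: float = 1e-3
    adam_beta1: float = 0.5
    seed: int = 0
    generator: GeneratorConfig | None = None
    critic: CriticConfig | None = None
    weights: LossWeights | None = None
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    checkpoint_every: int = 500
    log_every: int = 1
    visualize_every: int = 0  # 0 disables fixed-batch (V, dx, output) dumps

    def __post_init__(self):
        if self.framework not in FRAMEWORKS:
            raise ValueError(f"unknown framework {self.framework!r}")
        if self.lr_critic is None:
            self.lr_critic = 1e-4 if self.framework == "caae" else 1e-3
        if self.weights is None:
            self.weights = LossWeights.defaults_for(self.framework)

    def resolved_generator(self, image_size: int, m: int) -> GeneratorConfig:
        base = self.generator or GeneratorConfig()
        return replace(
            base,
            parameterization=self.parameterization,
            image_size=image_size,
            m_attributes=m,
        )

    def resolved_critic(self, image_size: int, m: int) -> CriticConfig:
        base = self.critic or CriticConfig()
        return replace(
            base,
            image_size=image_size,
            m_attributes=m,
            shared_trunk=self.framework == "stargan",
            conditional=self.framework in ("caae", "ipgan"),
        )


class SeedStreams:
    """Named independent RNG streams fanned out from one master seed."""

    def __init__(self, master_seed: int):
        self.master_seed = master_seed
        children = np.random.SeedSequence(master_seed).spawn(len(_STREAMS))
        for name, seq in zip(_STREAMS, children):
            setattr(self, name, np.random.Generator(np.random.PCG64(seq)))

    def state(self):
        return {name: getattr(self, name).bit_generator.state for name in _STREAMS}

    def set_state(self, state):
        for name in _STREAMS:
            getattr(self, name).bit_generator.state = state[name]


@dataclass
class CheckpointState:
    iteration: int
    network_states: dict
    optimizer_states: dict
    stream_state: dict
    config: TrainingConfig
    generator_config: GeneratorConfig
    critic_config: CriticConfig
    log: list

    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path) -> "CheckpointState":
        with open(path, "rb") as fh:
            state = pickle.load(fh)
        if not isinstance(state, cls):
            raise ValueError(f"{path} is not a checkpoint file")
        return state


# ----------------------------------------------------------------------
# batch sampling
# ----------------------------------------------------------------------

def sample_translation_batch(
    dataset: ImageAttributeDataset,
    batch_size: int,
    rng_batch: np.random.Generator,
    rng_target: np.random.Generator,
) -> TranslationBatch:
    """Draw (x, y) pairs uniformly and target attributes y_tilde
    independently from the dataset's empirical attribute vectors."""
    n = len(dataset)
    if n == 0:
        raise ValueError("dataset is empty")
    vals, mask = dataset.attribute_arrays()
    idx = rng_batch.integers(0, n, size=batch_size)
    tidx = rng_target.integers(0, n, size=batch_size)
    return TranslationBatch(
        images=dataset.images[idx],
        y=vals[idx],
        y_mask=mask[idx],
        y_target=vals[tidx],
        y_target_mask=mask[tidx],
    )


# ----------------------------------------------------------------------
# network/optimizer bundles
# ----------------------------------------------------------------------

class FrameworkNetworks:
    """The framework-specific set of networks and optimizers."""

    def __init__(self, config: TrainingConfig, gen_cfg: GeneratorConfig,
                 critic_cfg: CriticConfig, streams: SeedStreams):
        fw = config.framework
        seeds = streams.init.integers(0, 2**31 - 1, size=4)
        b1 = config.adam_beta1
        self.generator = UNetGenerator(gen_cfg, seed=int(seeds[0]))
        self.opt_g = nn.Adam(self.generator.parameters(), lr=config.lr_generator, beta1=b1)
        self.critic = None
        self.regressor = None
        self.latent_critic = None
        if fw in ("caae", "ipgan", "stargan"):
            self.critic = Critic(critic_cfg, seed=int(seeds[1]))
            self.opt_d = nn.Adam(self.critic.parameters(), lr=config.lr_critic, beta1=b1)
        if fw == "rgae":
            self.regressor = Regressor(critic_cfg, seed=int(seeds[2]))
            self.opt_r = nn.Adam(self.regressor.parameters(), lr=config.lr_regressor, beta1=b1)
        if fw == "caae":
            self.latent_critic = LatentCritic(gen_cfg.latent_dim, seed=int(seeds[3]))
            self.opt_dz = nn.Adam(self.latent_critic.parameters(), lr=config.lr_critic, beta1=b1)

    def modules(self):
        out = {"generator": self.generator}
        if self.critic is not None:
            out["critic"] = self.critic
        if self.regressor is not None:
            out["regressor"] = self.regressor
        if self.latent_critic is not None:
            out["latent_critic"] = self.latent_critic
        return out

    def optimizers(self):
        out = {"generator": self.opt_g}
        if self.critic is not None:
            out["critic"] = self.opt_d
        if self.regressor is not None:
            out["regressor"] = self.opt_r
        if self.latent_critic is not None:
            out["latent_critic"] = self.opt_dz
        return out

    def state_dicts(self):
        return {k: m.state_dict() for k, m in self.modules().items()}

    def optimizer_states(self):
        return {k: o.state_dict() for k, o in self.optimizers().items()}

    def load(self, network_states, optimizer_states):
        for k, m in self.modules().items():
            m.load_state_dict(network_states[k])
        for k, o in self.optimizers().items():
            o.load_state_dict(optimizer_states[k])


# ----------------------------------------------------------------------
# per-framework updates
# ----------------------------------------------------------------------

def _regressor_or_shared(nets: FrameworkNetworks):
    if nets.regressor is not None:
        return nets.regressor
    return nets.critic.regress


def train_step(
    config: TrainingConfig,
    nets: FrameworkNetworks,
    batch: TranslationBatch,
    streams: SeedStreams,
) -> dict:
    """One alternating update; returns all component loss values."""
    fw = config.framework
    w = config.weights
    m = batch.y.shape[1]
    x = batch.image_tensor()
    dy = batch.dy
    record: dict = {}
    G = nets.generator

    # ---- critic / regressor updates ----------------------------------
    if fw == "rgae":
        r_loss = regressor_mse(nets.regressor, x, batch.y, batch.y_mask)
        record["regressor_mse"] = r_loss.item()
        nn.step_module(nets.opt_r, nets.regressor, r_loss)
    else:
        fake = Tensor(G(x, Tensor(dy)).output_image.data)  # detached
        if fw == "stargan":
            d_wgan = wgan_gp_critic_loss(
                nets.critic.discriminate, x, fake, streams.gp, w.lambda_gp
            )
            r_loss = masked_shared_regression(nets.critic, x, batch)
            d_total = d_wgan + w.lambda_r * r_loss
            record["critic_wgan"] = d_wgan.item()
            record["regressor_mse"] = r_loss.item()
        else:  # caae / ipgan: conditional critic
            d_wgan = wgan_gp_critic_loss(
                nets.critic, x, fake, streams.gp, w.lambda_gp,
                attrs_real=batch.y, attrs_fake=batch.y_target,
            )
            cond_extra, _ = conditional_critic_terms(
                nets.critic, x, fake, batch.y, batch.y_target, w
            )
            d_total = d_wgan + cond_extra
            record["critic_wgan"] = d_wgan.item()
            record["critic_cond"] = cond_extra.item()
        record["critic_total"] = d_total.item()
        nn.step_module(nets.opt_d, nets.critic, d_total)

    if fw == "caae":
        z = G.encode(x)[0]
        _enc, dz_loss = latent_adversarial_losses(z.detach(), nets.latent_critic,
                                                  streams.prior, w.lambda_gp)
        record["latent_critic"] = dz_loss.item()
        nn.step_module(nets.opt_dz, nets.latent_critic, dz_loss)

    # ---- generator update --------------------------------------------
    components: dict = {}
    dec: TransformDecomposition | None = None

    if fw == "rgae":
        dec = G(x, Tensor(dy))
        components["attr"] = relative_attribute_loss(
            nets.regressor, x, dec.output_image, dy, batch.dy_mask
        )
        components["cc"] = cycle_loss(G, x, dy, forward_image=dec.output_image)
    elif fw == "stargan":
        dec = G(x, Tensor(dy))
        components["adv"] = adversarial_gen_loss(nets.critic.discriminate, dec.output_image)
        components["cc"] = cycle_loss(G, x, dy, forward_image=dec.output_image)
        components["attr"] = relative_attribute_loss(
            nets.critic.regress, x, dec.output_image, dy, batch.dy_mask
        )
    elif fw == "caae":
        z = G.encode(x)[0]
        enc_loss, _dz = latent_adversarial_losses(z, nets.latent_critic,
                                                  streams.prior, lambda_gp=0.0)
        dec = G(x, Tensor(dy))
        components["adv"] = adversarial_gen_loss(nets.critic, dec.output_image, batch.y_target)
        components["adv_z"] = enc_loss
        _extra, gen_cond = conditional_critic_terms(
            nets.critic, x, dec.output_image, batch.y, batch.y_target, config.weights
        )
        components["cond"] = gen_cond
        components["rec"] = reconstruction_loss(G, x, m)
    elif fw == "ipgan":
        # memory-saving split: a fair coin picks either the reconstruction
        # loss or the adversarial+conditional+identity set each minibatch
        use_rec = bool(streams.coin.random() < 0.5)
        record["ipgan_branch"] = float(use_rec)
        if use_rec:
            n = x.shape[0]
            dec = G(x, Tensor(np.zeros((n, m))))
            components["rec"] = ad.tabs(dec.output_image - x).mean()
        else:
            dec = G(x, Tensor(dy))
            components["adv"] = adversarial_gen_loss(nets.critic, dec.output_image, batch.y_target)
            _extra, gen_cond = conditional_critic_terms(
                nets.critic, x, dec.output_image, batch.y, batch.y_target, config.weights
            )
            components["cond"] = gen_cond
            components["id"] = identity_preserving_loss(
                dec.output_image, x, batch.y[:, 0], batch.y_target[:, 0]
            )

    g_total = total_generator_loss(fw, config.parameterization, components, w, dec)
    for name, val in components.items():
        record[f"gen_{name}"] = val.item()
    record["gen_total"] = g_total.item()
    nn.step_module(nets.opt_g, G, g_total)

    if not all(np.isfinite(v) for v in record.values()):
        raise TrainingDiverged(-1, record)
    return record


def masked_shared_regression(critic: Critic, x: Tensor, batch: TranslationBatch):
    """Masked attribute regression through the shared trunk on real images."""
    return regressor_mse(critic.regress, x, batch.y, batch.y_mask)


# ----------------------------------------------------------------------
# fit loop
# ----------------------------------------------------------------------

def fit(
    config: TrainingConfig,
    dataset: ImageAttributeDataset,
    checkpoint_dir=None,
    resume_from: CheckpointState | None = None,
    progress: bool = False,
    viz_dir=None,
) -> CheckpointState:
    """Train to ``config.max_iterations``, returning the final state.

    With ``config.visualize_every > 0`` and a ``viz_dir`` (defaulting to
    the checkpoint directory), a fixed probe image is translated
    periodically and its (V, dx, output) decomposition saved as PNG.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    gen_cfg = config.resolved_generator(dataset.image_size, dataset.m)
    critic_cfg = config.resolved_critic(dataset.image_size, dataset.m)
    streams = SeedStreams(config.seed)
    nets = FrameworkNetworks(config, gen_cfg, critic_cfg, streams)

    log: list = []
    start = 0
    if resume_from is not None:
        nets.load(resume_from.network_states, resume_from.optimizer_states)
        streams.set_state(resume_from.stream_state)
        log = list(resume_from.log)
        start = resume_from.iteration

    for it in range(start, config.max_iterations):
        batch = sample_translation_batch(
            dataset, config.batch_size, streams.batch, streams.target
        )
        batch.images = augment_batch(batch.images, config.augmentation, streams.augment)
        try:
            record = train_step(config, nets, batch, streams)
        except TrainingDiverged as err:
            raise TrainingDiverged(it, err.record) from None
        except (ValueError, FloatingPointError) as err:
            if "non-finite" in str(err):
                raise TrainingDiverged(it, {"error": str(err)}) from None
            raise
        record["iteration"] = it
        if (it % config.log_every) == 0 or it == config.max_iterations - 1:
            log.append(record)
        if checkpoint_dir is not None and (
            (it + 1) % config.checkpoint_every == 0 or it + 1 == config.max_iterations
        ):
            _state(nets, streams, config, gen_cfg, critic_cfg, it + 1, log).save(
                Path(checkpoint_dir) / f"checkpoint_{it + 1:06d}.pkl"
            )
        viz_target = viz_dir if viz_dir is not None else checkpoint_dir
        if (
            config.visualize_every > 0
            and viz_target is not None
            and (it + 1) % config.visualize_every == 0
        ):
            _dump_visualization(nets.generator, dataset, gen_cfg, it + 1, viz_target)
        if progress and (it % 50 == 0):  # pragma: no cover - cosmetic
            print(f"iter {it}: " + ", ".join(f"{k}={v:.4g}" for k, v in record.items()))

    return _state(nets, streams, config, gen_cfg, critic_cfg, config.max_iterations, log)


def _dump_visualization(G, dataset, gen_cfg, iteration, out_dir):
    """Translate the first dataset image by +1 sd of attribute 0."""
    from .viz import plot_decomposition

    G.eval()
    x = dataset.images[:1][:, None]
    dy = np.zeros((1, gen_cfg.m_attributes))
    dy[0, 0] = 1.0
    dec = G(Tensor(x), Tensor(dy))
    G.train()
    plot_decomposition(
        x[0, 0], dec, Path(out_dir) / f"viz_{iteration:06d}.png"
    )


def _state(nets, streams, config, gen_cfg, critic_cfg, iteration, log) -> CheckpointState:
    return CheckpointState(
        iteration=iteration,
        network_states=nets.state_dicts(),
        optimizer_states=nets.optimizer_states(),
        stream_state=streams.state(),
        config=config,
        generator_config=gen_cfg,
        critic_config=critic_cfg,
        log=list(log),
    )


def log_frame(state: CheckpointState) -> pd.DataFrame:
    return pd.DataFrame(state.log)


def restore_generator(state: CheckpointState) -> UNetGenerator:
    G = UNetGenerator(state.generator_config, seed=0)
    G.load_state_dict(state.network_states["generator"])
    return G


def translate(
    state_or_generator, x, y, y_target
) -> TransformDecomposition | list[TransformDecomposition]:
    """Inference-mode translation; returns the output image together with
    the transform components (V, dx) for visualization.

    ``x`` may be one image (H, W / ScalarField2D) or a stack (N, H, W)
    with per-item attribute arrays; attributes may be AttributeVector,
    1-D arrays with NaN for missing, or 2-D batched arrays.
    """
    from .fields import ScalarField2D
    from .networks import AttributeVector, attribute_difference

    if isinstance(state_or_generator, CheckpointState):
        G = restore_generator(state_or_generator)
    else:
        G = state_or_generator
    G.eval()

    def to_av(a):
        return a if isinstance(a, AttributeVector) else AttributeVector(np.asarray(a, float))

    if isinstance(x, ScalarField2D):
        x = x.values
    x = np.asarray(x, dtype=float)
    single = x.ndim == 2
    if single:
        dy = attribute_difference(to_av(y), to_av(y_target))[None]
        xs = x[None, None]
    else:
        ys = [to_av(np.asarray(y)[i]) for i in range(x.shape[0])]
        yts = [to_av(np.asarray(y_target)[i]) for i in range(x.shape[0])]
        dy = np.stack([attribute_difference(a, b) for a, b in zip(ys, yts)])
        xs = x[:, None]
    dec = G(Tensor(xs), Tensor(dy))
    G.train()
    return dec
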