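"""Generator and critic architectures.

The generator is a 2-D U-Net conditioned on a change in attributes
``dy = y_target - y``: the bottleneck is flattened through a fully
connected layer into a 50-dimensional latent vector, ``dy`` is
concatenated to that vector, and is additionally broadcast-concatenated
as constant channels to the two coarsest decoder feature maps.  The
network's output head implements one of six parameterizations:

========== ===============================================================
base       the head emits the output image directly (unconstrained)
it         the head emits an intensity difference map added to the input
st_disp    the head emits a displacement field used to warp the input
st_diff    the head emits a stationary velocity field, integrated to a
           diffeomorphism that warps the input
sit_disp   displacement field + intensity map: warp(x + dx)
sit_diff   velocity field + intensity map: the spatial-intensity
           transform Phi_V(x + dx)
========== ===============================================================

All transform heads are parameter-free beyond the final convolution, so
forcing that convolution to zero makes every head except ``base`` the
identity map -- the robustness prior this package exists to provide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .fields import ScalarField2D, VectorField2D
from .transforms import integrate_velocity_batch, warp_batch

PARAMETERIZATIONS = ("base", "it", "st_disp", "st_diff", "sit_disp", "sit_diff")

_HEAD_CHANNELS = {
    "base": 1,
    "it": 1,
    "st_disp": 2,
    "st_diff": 2,
    "sit_disp": 3,
    "sit_diff": 3,
}


# ----------------------------------------------------------------------
# attributes
# ----------------------------------------------------------------------

@dataclass
class AttributeVector:
    """m real attributes with a per-entry observation mask.

    Values are in normalized units (zero mean, unit sd over the training
    cohort).  ``mask[k]`` is True when attribute k is observed.
    """

    values: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.atleast_1d(np.asarray(self.values, dtype=np.float64))
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        self.mask = np.atleast_1d(np.asarray(self.mask, dtype=bool))
        if self.values.shape != self.mask.shape or self.values.ndim != 1:
            raise ValueError("values and mask must be 1-D arrays of equal length")
        if self.values.size < 1:
            raise ValueError("at least one attribute is required")
        self.values = np.where(self.mask, self.values, 0.0)

    @property
    def m(self) -> int:
        return self.values.size


def attribute_difference(y: AttributeVector, y_target: AttributeVector) -> np.ndarray:
    """Masked difference ``y_target - y``; zero wherever either is missing."""
    if y.m != y_target.m:
        raise ValueError(f"attribute lengths differ: {y.m} vs {y_target.m}")
    both = y.mask & y_target.mask
    return np.where(both, y_target.values - y.values, 0.0)


def masked_difference_batch(
    y: np.ndarray, y_mask: np.ndarray, yt: np.ndarray, yt_mask: np.ndarray
) -> np.ndarray:
    """Batched masked attribute difference, (N, m)."""
    both = y_mask & yt_mask
    return np.where(both, yt - y, 0.0)


# ----------------------------------------------------------------------
# configs
# ----------------------------------------------------------------------

@dataclass
class GeneratorConfig:
    parameterization: str = "sit_diff"
    resolutions: int = 4
    bottom_channels: int = 128
    latent_dim: int = 50
    n_integration_steps: int = 7
    image_size: int = 64
    m_attributes: int = 2
    conditioned_decoder_levels: int = 2  # coarsest decoder levels receiving dy

    def __post_init__(self):
        if self.parameterization not in PARAMETERIZATIONS:
            raise ValueError(f"unknown parameterization {self.parameterization!r}")
        if self.image_size % 2 ** (self.resolutions - 1) != 0:
            raise ValueError("image_size must be divisible by 2**(resolutions-1)")

    @property
    def head_channels(self) -> int:
        return _HEAD_CHANNELS[self.parameterization]

    @property
    def channels(self) -> list[int]:
        return [
            max(1, self.bottom_channels // 2 ** (self.resolutions - 1 - i))
            for i in range(self.resolutions)
        ]


@dataclass
class CriticConfig:
    m_attributes: int = 2
    shared_trunk: bool = False
    conditional: bool = False
    n_down_blocks: int = 3
    base_channels: int = 16
    hidden_dim: int = 64
    image_size: int = 64


# ----------------------------------------------------------------------
# transform decomposition
# ----------------------------------------------------------------------

@dataclass
class TransformDecomposition:
    """A generator output: the image plus its transform components."""

    parameterization: str
    output_image: Tensor
    velocity: Tensor | None = None
    displacement: Tensor | None = None
    intensity_delta: Tensor | None = None

    def image_field(self, index: int = 0) -> ScalarField2D:
        return ScalarField2D(self.output_image.data[index, 0])

    def velocity_field(self, index: int = 0) -> VectorField2D | None:
        if self.velocity is None:
            return None
        return VectorField2D(self.velocity.data[index].transpose(1, 2, 0))

    def displacement_field(self, index: int = 0) -> VectorField2D | None:
        if self.displacement is None:
            return None
        return VectorField2D(self.displacement.data[index].transpose(1, 2, 0))

    def intensity_field(self, index: int = 0) -> ScalarField2D | None:
        if self.intensity_delta is None:
            return None
        return ScalarField2D(self.intensity_delta.data[index, 0])


def apply_parameterization(
    x: Tensor, raw: Tensor, parameterization: str, n_steps: int, clamp: bool = False
) -> TransformDecomposition:
    """Turn the head's raw channels into an output image + components."""
    if parameterization == "base":
        img = raw[:, 0:1]
        if clamp:
            img = Tensor(np.clip(img.data, 0.0, 1.0))
        return TransformDecomposition("base", img)
    if parameterization == "it":
        delta = raw[:, 0:1]
        return TransformDecomposition("it", x + delta, intensity_delta=delta)
    if parameterization == "st_disp":
        disp = raw[:, 0:2]
        return TransformDecomposition("st_disp", warp_batch(x, disp), displacement=disp)
    if parameterization == "st_diff":
        vel = raw[:, 0:2]
        disp = integrate_velocity_batch(vel, n_steps)
        return TransformDecomposition("st_diff", warp_batch(x, disp), velocity=vel)
    if parameterization == "sit_disp":
        disp, delta = raw[:, 0:2], raw[:, 2:3]
        return TransformDecomposition(
            "sit_disp", warp_batch(x + delta, disp), displacement=disp, intensity_delta=delta
        )
    if parameterization == "sit_diff":
        vel, delta = raw[:, 0:2], raw[:, 2:3]
        disp = integrate_velocity_batch(vel, n_steps)
        return TransformDecomposition(
            "sit_diff", warp_batch(x + delta, disp), velocity=vel, intensity_delta=delta
        )
    raise ValueError(f"unknown parameterization {parameterization!r}")


# ----------------------------------------------------------------------
# generator
# ----------------------------------------------------------------------

class UNetGenerator(nn.Module):
    """U-Net generator with attribute-difference conditioning."""

    def __init__(self, config: GeneratorConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        chs = config.channels
        L = config.resolutions
        self.bottom_spatial = config.image_size // 2 ** (L - 1)
        m = config.m_attributes

        in_ch = 1
        for i in range(L):
            setattr(self, f"enc{i}", nn.ConvBlock(in_ch, chs[i], rng))
            in_ch = chs[i]

        flat = chs[-1] * self.bottom_spatial**2
        self.fc_down = nn.Linear(flat, config.latent_dim, rng)
        self.fc_up = nn.Linear(config.latent_dim + m, flat, rng)

        # decoder levels L-2 .. 0; the `conditioned_decoder_levels` coarsest
        # receive dy broadcast as extra channels
        self.cond_levels = set(
            range(L - 2, L - 2 - config.conditioned_decoder_levels, -1)
        ) & set(range(L - 1))
        for i in range(L - 2, -1, -1):
            extra = m if i in self.cond_levels else 0
            setattr(self, f"dec{i}", nn.ConvBlock(chs[i + 1] + chs[i] + extra, chs[i], rng))

        self.head = nn.Conv2d(chs[0], config.head_channels, 1, rng)

    # -- pieces (also used by the adversarial-autoencoder framework) ---
    def encode(self, x: Tensor):
        """Unconditional encoder: image -> (latent vector, skip features)."""
        L = self.config.resolutions
        feats = []
        h = x
        for i in range(L - 1):
            h = getattr(self, f"enc{i}")(h)
            feats.append(h)
            h = nn.max_pool2x2(h)
        h = getattr(self, f"enc{L-1}")(h)
        n = h.shape[0]
        z = self.fc_down(h.reshape(n, -1))
        return z, feats

    def decode(self, z: Tensor, dy: Tensor, feats, x: Tensor) -> TransformDecomposition:
        """Conditional decoder: (latent, dy, skips) -> transform of ``x``."""
        L = self.config.resolutions
        n = z.shape[0]
        s = self.bottom_spatial
        h = ad.relu(self.fc_up(ad.concatenate([z, dy], axis=1)))
        h = h.reshape(n, self.config.channels[-1], s, s)
        for i in range(L - 2, -1, -1):
            h = nn.upsample_bilinear2x(h)
            parts = [h, feats[i]]
            if i in self.cond_levels:
                hh, ww = h.shape[2], h.shape[3]
                dy_maps = ad.broadcast_to(
                    dy.reshape(n, self.config.m_attributes, 1, 1),
                    (n, self.config.m_attributes, hh, ww),
                )
                parts.append(dy_maps)
            h = getattr(self, f"dec{i}")(ad.concatenate(parts, axis=1))
        raw = self.head(h)
        return apply_parameterization(
            x, raw, self.config.parameterization,
            self.config.n_integration_steps, clamp=not self.training,
        )

    def forward(self, x: Tensor, dy: Tensor | np.ndarray) -> TransformDecomposition:
        dy = ad.astensor(dy)
        z, feats = self.encode(x)
        return self.decode(z, dy, feats, x)

    def zero_head(self):
        """Force the final convolution to zero (identity for transform heads)."""
        self.head.weight.data[...] = 0.0
        self.head.bias.data[...] = 0.0


def build_generator(config: GeneratorConfig, seed: int = 0) -> UNetGenerator:
    return UNetGenerator(config, seed=seed)


def generator_translate(
    G: UNetGenerator, x, y: AttributeVector, y_target: AttributeVector
) -> TransformDecomposition:
    """Translate a single image field from attributes y to y_target."""
    dy = attribute_difference(y, y_target)
    if isinstance(x, ScalarField2D):
        x = x.values
    xt = Tensor(np.asarray(x)[None, None])
    return G(xt, Tensor(dy[None]))


def build_latent_encoder_decoder(config: GeneratorConfig, seed: int = 0):
    """Unconditional encoder + conditional decoder sharing a U-Net.

    The decoder keeps the U-Net skip connections; the latent vector is
    what the latent-space adversary of the adversarial-autoencoder
    framework regularizes.
    """
    G = UNetGenerator(config, seed=seed)

    def encoder(x: Tensor) -> Tensor:
        return G.encode(x)[0]

    def decoder(x: Tensor, dy: Tensor) -> TransformDecomposition:
        z, feats = G.encode(x)
        return G.decode(z, ad.astensor(dy), feats, x)

    return G, encoder, decoder


# ----------------------------------------------------------------------
# critics
# ----------------------------------------------------------------------

class Critic(nn.Module):
    """VGG-like critic with optional attribute conditioning / shared heads.

    ``conditional`` critics receive the attributes broadcast as constant
    input channels.  With ``shared_trunk`` the down-sampling trunk feeds
    two fully connected heads: a scalar discriminator logit and an
    m-vector attribute regression.
    """

    def __init__(self, config: CriticConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        in_ch = 1 + (config.m_attributes if config.conditional else 0)
        ch = config.base_channels
        spatial = config.image_size
        for i in range(config.n_down_blocks):
            self.__setattr__(f"conv{i}", nn.Conv2d(in_ch, ch, 3, rng))
            self.__setattr__(f"bn{i}", nn.BatchNorm2d(ch))
            in_ch = ch
            ch *= 2
            spatial //= 2
        flat = in_ch * spatial * spatial
        self.fc = nn.Linear(flat, config.hidden_dim, rng)
        self.head_disc = nn.Linear(config.hidden_dim, 1, rng)
        if config.shared_trunk:
            self.head_regr = nn.Linear(config.hidden_dim, config.m_attributes, rng)

    def trunk(self, x: Tensor, attrs: Tensor | None = None) -> Tensor:
        if self.config.conditional:
            if attrs is None:
                raise ValueError("conditional critic requires attributes")
            attrs = ad.astensor(attrs)
            n, _c, h, w = x.shape
            amap = ad.broadcast_to(
                attrs.reshape(n, self.config.m_attributes, 1, 1),
                (n, self.config.m_attributes, h, w),
            )
            x = ad.concatenate([x, amap], axis=1)
        h = x
        for i in range(self.config.n_down_blocks):
            h = ad.relu(getattr(self, f"bn{i}")(getattr(self, f"conv{i}")(h)))
            h = nn.max_pool2x2(h)
        n = h.shape[0]
        return ad.relu(self.fc(h.reshape(n, -1)))

    def forward(self, x: Tensor, attrs: Tensor | None = None):
        h = self.trunk(x, attrs)
        logits = self.head_disc(h).reshape(-1)
        if self.config.shared_trunk:
            return logits, self.head_regr(h)
        return logits

    def discriminate(self, x: Tensor, attrs: Tensor | None = None) -> Tensor:
        out = self.forward(x, attrs)
        return out[0] if self.config.shared_trunk else out

    def regress(self, x: Tensor) -> Tensor:
        if not self.config.shared_trunk:
            raise ValueError("regression head requires shared_trunk=True")
        return self.head_regr(self.trunk(x))


def build_critic(config: CriticConfig, seed: int = 0) -> Critic:
    return Critic(config, seed=seed)


class Regressor(nn.Module):
    """Stand-alone attribute regressor (VGG-like trunk, m outputs)."""

    def __init__(self, config: CriticConfig, seed: int = 0):
        super().__init__()
        cfg = CriticConfig(
            m_attributes=config.m_attributes,
            shared_trunk=False,
            conditional=False,
            n_down_blocks=config.n_down_blocks,
            base_channels=config.base_channels,
            hidden_dim=config.hidden_dim,
            image_size=config.image_size,
        )
        self.config = cfg
        rng = np.random.default_rng(seed)
        in_ch = 1
        ch = cfg.base_channels
        spatial = cfg.image_size
        for i in range(cfg.n_down_blocks):
            self.__setattr__(f"conv{i}", nn.Conv2d(in_ch, ch, 3, rng))
            self.__setattr__(f"bn{i}", nn.BatchNorm2d(ch))
            in_ch = ch
            ch *= 2
            spatial //= 2
        self.fc = nn.Linear(in_ch * spatial * spatial, cfg.hidden_dim, rng)
        self.head = nn.Linear(cfg.hidden_dim, cfg.m_attributes, rng)

    def forward(self, x: Tensor) -> Tensor:
        h = x
        for i in range(self.config.n_down_blocks):
            h = ad.relu(getattr(self, f"bn{i}")(getattr(self, f"conv{i}")(h)))
            h = nn.max_pool2x2(h)
        n = h.shape[0]
        return self.head(ad.relu(self.fc(h.reshape(n, -1))))


class LatentCritic(nn.Module):
    """MLP adversary on the 50-dimensional latent space."""

    def __init__(self, latent_dim: int = 50, hidden: int = 64, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.fc1 = nn.Linear(latent_dim, hidden, rng)
        self.fc2 = nn.Linear(hidden, hidden, rng)
        self.fc3 = nn.Linear(hidden, 1, rng)

    def forward(self, z: Tensor) -> Tensor:
        h = ad.relu(self.fc1(z))
        h = ad.relu(self.fc2(h))
        return self.fc3(h).reshape(-1)
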