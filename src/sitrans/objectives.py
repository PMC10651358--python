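"""Loss terms and their framework-specific compositions.

All losses operate on autodiff tensors and return scalar tensors.  The
generator-side compositions follow the four translation frameworks:

* ``rgae``    -- regressor-guided autoencoder: relative-attribute loss
  plus cycle consistency.
* ``caae``    -- conditional adversarial autoencoder: Wasserstein
  adversary on images and on the latent space, a conditional-critic
  correction, and a reconstruction term.
* ``ipgan``   -- identity-preserving GAN: Wasserstein adversary,
  conditional-critic correction, reconstruction, and an identity term
  whose weight decays exponentially with the requested age gap.
* ``stargan`` -- multi-attribute translation: Wasserstein adversary,
  cycle consistency and the relative-attribute loss.

Whenever the generator parameterization emits an intensity map its L1
norm is added with weight ``lambda_dx``; a raw displacement field adds
its total-variation norm with weight ``lambda_f``.  Diffeomorphic heads
need no smoothness penalty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .networks import TransformDecomposition
from .transforms import displacement_tv_batch, intensity_l1_batch

FRAMEWORKS = ("rgae", "caae", "ipgan", "stargan")


@dataclass
class LossWeights:
    """Loss weights; defaults are the package's reference training recipe."""

    lambda_cc: float = 0.1
    lambda_attr: float = 10.0
    lambda_rec: float = 0.1  # 1.0 for ipgan (see defaults_for)
    lambda_cond: float = 1.0
    lambda_id: float = 0.1
    lambda_gp: float = 1.0
    lambda_dx: float = 10.0
    lambda_f: float = 1.0
    lambda_r: float = 10.0
    lambda_adv: float = 1.0  # unit by default; exposed for ablations
    lambda_adv_z: float = 1.0
    cond_sign: float = 1.0  # +1: real image with true attributes scores higher

    def __post_init__(self):
        for name in (
            "lambda_cc", "lambda_attr", "lambda_rec", "lambda_cond",
            "lambda_id", "lambda_gp", "lambda_dx", "lambda_f", "lambda_r",
            "lambda_adv", "lambda_adv_z",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @classmethod
    def defaults_for(cls, framework: str) -> "LossWeights":
        if framework == "ipgan":
            return cls(lambda_rec=1.0)
        return cls()


@dataclass
class TranslationBatch:
    """One minibatch: images with source and independently drawn target
    attributes (targets come from the dataset's empirical attribute
    distribution, never invented values)."""

    images: np.ndarray  # (N, H, W)
    y: np.ndarray  # (N, m) with missing entries zeroed
    y_mask: np.ndarray  # (N, m) bool
    y_target: np.ndarray
    y_target_mask: np.ndarray

    @property
    def dy(self) -> np.ndarray:
        both = self.y_mask & self.y_target_mask
        return np.where(both, self.y_target - self.y, 0.0)

    @property
    def dy_mask(self) -> np.ndarray:
        return self.y_mask & self.y_target_mask

    def image_tensor(self) -> Tensor:
        return Tensor(self.images[:, None])


# ----------------------------------------------------------------------
# individual terms
# ----------------------------------------------------------------------

def masked_mse(pred: Tensor, target: np.ndarray, mask: np.ndarray) -> Tensor:
    """(1/m) * batch mean of squared residual norm, missing entries 0."""
    m = target.shape[1]
    if not mask.any():
        warnings.warn("all attributes missing in batch; regression loss is 0")
        return Tensor(0.0)
    resid = (pred - Tensor(target)) * Tensor(mask.astype(float))
    return (resid**2).sum(axis=1).mean() * (1.0 / m)


def regressor_mse(R, x: Tensor, y: np.ndarray, y_mask: np.ndarray) -> Tensor:
    """Attribute-regression loss on real image/attribute pairs."""
    return masked_mse(R(x), y, y_mask)


def cycle_loss(G, x: Tensor, dy: np.ndarray, forward_image: Tensor | None = None) -> Tensor:
    """L1 distance between x and its there-and-back translation.

    ``forward_image`` lets callers reuse an already computed G(x, dy)
    instead of running the forward translation a second time.
    """
    if forward_image is None:
        forward_image = G(x, Tensor(dy)).output_image
    back = G(forward_image, Tensor(-dy))
    return ad.tabs(back.output_image - x).mean()


def relative_attribute_loss(
    R, x: Tensor, translated: Tensor, dy: np.ndarray, dy_mask: np.ndarray
) -> Tensor:
    """Penalty on (R(G(x)) - R(x)) deviating from the requested change."""
    m = dy.shape[1]
    shift = R(translated) - R(x)
    resid = (shift - Tensor(dy)) * Tensor(dy_mask.astype(float))
    return (resid**2).sum(axis=1).mean() * (1.0 / m)


def reconstruction_loss(G, x: Tensor, m_attributes: int) -> Tensor:
    """L1 error of the zero-difference translation G(x, 0)."""
    n = x.shape[0]
    dec = G(x, Tensor(np.zeros((n, m_attributes))))
    return ad.tabs(dec.output_image - x).mean()


def adversarial_gen_loss(D, x_translated: Tensor, attrs: np.ndarray | None = None) -> Tensor:
    """Wasserstein generator loss: -E[D(translated)]."""
    scores = D(x_translated) if attrs is None else D(x_translated, Tensor(attrs))
    if isinstance(scores, tuple):
        scores = scores[0]
    return ad.neg(scores.mean())


def gradient_penalty(D, x_real: Tensor, x_fake: Tensor, rng: np.random.Generator,
                     attrs: np.ndarray | None = None) -> Tensor:
    """(||grad_x D(x_bar)|| - 1)^2 at per-sample convex interpolates."""
    n = x_real.shape[0]
    eps = rng.uniform(size=(n, 1, 1, 1))
    x_bar = Tensor(eps * x_real.data + (1 - eps) * x_fake.data, requires_grad=True)
    scores = D(x_bar) if attrs is None else D(x_bar, Tensor(attrs))
    if isinstance(scores, tuple):
        scores = scores[0]
    (gx,) = ad.grad(scores.sum(), [x_bar])
    norms = ad.sqrt((gx**2).sum(axis=(1, 2, 3)) + 1e-12)
    return ((norms - 1.0) ** 2).mean()


def wgan_gp_critic_loss(
    D,
    x_real: Tensor,
    x_fake: Tensor,
    rng: np.random.Generator,
    lambda_gp: float = 1.0,
    attrs_real: np.ndarray | None = None,
    attrs_fake: np.ndarray | None = None,
) -> Tensor:
    """Wasserstein critic loss with gradient penalty.

    Interpolates receive the real image's attributes when the critic is
    conditional (attribute interpolation is ill-defined with missing
    entries).
    """
    def score(x, attrs):
        out = D(x) if attrs is None else D(x, Tensor(attrs))
        return out[0] if isinstance(out, tuple) else out

    loss = score(x_fake, attrs_fake).mean() - score(x_real, attrs_real).mean()
    if lambda_gp > 0:
        loss = loss + lambda_gp * gradient_penalty(D, x_real, x_fake, rng, attrs_real)
    return loss


def conditional_critic_terms(
    D, x: Tensor, x_translated: Tensor,
    y: np.ndarray, y_target: np.ndarray, weights: LossWeights,
):
    """Attribute-matching corrections for conditional critics.

    Returns ``(critic_extra, gen_cond)``: the critic is pushed to score
    the real image higher with its true attributes than with the target
    attributes, and the generator to make its output score higher with
    the target attributes than with the source ones.  ``cond_sign``
    flips the convention.
    """
    s = weights.cond_sign
    critic_extra = (D(x, Tensor(y_target)) - D(x, Tensor(y))).mean() * (weights.lambda_cond * s)
    gen_cond = (D(x_translated, Tensor(y)) - D(x_translated, Tensor(y_target))).mean() * s
    return critic_extra, gen_cond


def latent_adversarial_losses(
    z: Tensor, D_z, rng: np.random.Generator, lambda_gp: float = 1.0
):
    """Wasserstein adversary driving latent vectors toward U[0,1]^d.

    Returns ``(enc_loss, dz_loss)``; the encoder minimizes ``enc_loss``,
    the latent critic ``dz_loss``.
    """
    n, d = z.shape
    prior = Tensor(rng.uniform(size=(n, d)))
    z_detached = z.detach()
    dz_loss = D_z(z_detached).mean() - D_z(prior).mean()
    if lambda_gp > 0:
        eps = rng.uniform(size=(n, 1))
        z_bar = Tensor(eps * prior.data + (1 - eps) * z_detached.data, requires_grad=True)
        (gz,) = ad.grad(D_z(z_bar).sum(), [z_bar])
        norms = ad.sqrt((gz**2).sum(axis=1) + 1e-12)
        dz_loss = dz_loss + lambda_gp * ((norms - 1.0) ** 2).mean()
    enc_loss = ad.neg(D_z(z).mean())
    return enc_loss, dz_loss


def identity_preserving_loss(
    translated: Tensor, x: Tensor, y0: np.ndarray, y0_target: np.ndarray
) -> Tensor:
    """Squared image change, down-weighted as the age gap grows:
    ||G(x) - x||^2 * exp(-|y0 - y0_target|), averaged over the batch."""
    sq = ((translated - x) ** 2).sum(axis=(1, 2, 3))
    w = Tensor(np.exp(-np.abs(np.asarray(y0) - np.asarray(y0_target))))
    return (sq * w).mean()


# ----------------------------------------------------------------------
# composition
# ----------------------------------------------------------------------

def transform_regularizers(
    decomposition: TransformDecomposition | None, weights: LossWeights
) -> Tensor:
    """Head-dependent penalties: L1 on the intensity map and TV on a raw
    displacement field.  Diffeomorphic heads add nothing."""
    total = Tensor(0.0)
    if decomposition is None:
        return total
    if decomposition.intensity_delta is not None and weights.lambda_dx > 0:
        total = total + weights.lambda_dx * intensity_l1_batch(decomposition.intensity_delta)
    if decomposition.displacement is not None and weights.lambda_f > 0:
        total = total + weights.lambda_f * displacement_tv_batch(decomposition.displacement)
    return total


_FRAMEWORK_TERMS = {
    "rgae": (("attr", 1.0), ("cc", "lambda_cc")),
    "caae": (("adv", "lambda_adv"), ("adv_z", "lambda_adv_z"),
             ("cond", "lambda_cond"), ("rec", "lambda_rec")),
    "ipgan": (("adv", "lambda_adv"), ("id", "lambda_id"),
              ("cond", "lambda_cond"), ("rec", "lambda_rec")),
    "stargan": (("adv", "lambda_adv"), ("cc", "lambda_cc"), ("attr", "lambda_attr")),
}


def total_generator_loss(
    framework: str,
    parameterization: str,
    components: dict,
    weights: LossWeights,
    decomposition: TransformDecomposition | None = None,
) -> Tensor:
    """Compose the framework's generator objective plus head penalties."""
    if framework not in _FRAMEWORK_TERMS:
        raise ValueError(f"unknown framework {framework!r}")
    from .networks import PARAMETERIZATIONS

    if parameterization not in PARAMETERIZATIONS:
        raise ValueError(f"unknown parameterization {parameterization!r}")
    total = Tensor(0.0)
    for name, weight in _FRAMEWORK_TERMS[framework]:
        if name not in components:
            continue
        w = weight if isinstance(weight, float) else getattr(weights, weight)
        if w != 0:
            total = total + w * ad.astensor(components[name])
    return total + transform_regularizers(decomposition, weights)
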