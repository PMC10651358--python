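"""Differentiable spatial and intensity transform primitives.

Two layers of API live here.  The *batched tensor* functions
(``warp_batch``, ``integrate_velocity_batch``, ...) operate on autodiff
:class:`~sitrans.autodiff.Tensor` objects with NCHW layout and are what
the generator heads and losses use during training.  The *field* API
(:func:`warp_image`, :func:`integrate_velocity`, ...) wraps single
:class:`ScalarField2D` / :class:`VectorField2D` objects and returns plain
fields; it is the user-facing surface.

The spatial transform follows the stationary-velocity-field convention:
a velocity field ``V`` (total displacement over unit time, in pixels) is
integrated by scaling and squaring -- ``V`` is scaled by ``2**-n``,
converted to a small deformation and composed with itself ``n`` times --
yielding a diffeomorphism ``exp(V)``.  All interpolation is bilinear with
replicate (clamp-to-edge) boundary handling.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .fields import DeformationField, ScalarField2D, VectorField2D

__all__ = [
    "DEFAULT_INTEGRATION_STEPS",
    "warp_batch",
    "compose_displacements_batch",
    "integrate_velocity_batch",
    "sit_output_batch",
    "intensity_l1_batch",
    "displacement_tv_batch",
    "integrate_velocity",
    "compose_deformations",
    "warp_image",
    "apply_sit",
    "intensity_l1",
    "displacement_tv",
    "jacobian_determinant",
]

DEFAULT_INTEGRATION_STEPS = 7
_TV_EPS = 1e-16  # inside the sqrt of the differentiable TV norm


def _clamp(t: Tensor, lo: float, hi: float) -> Tensor:
    t = ad.maximum(t, Tensor(lo))
    return ad.neg(ad.maximum(ad.neg(t), Tensor(-hi)))


def warp_batch(x: Tensor, disp: Tensor) -> Tensor:
    """Sample ``x`` at ``omega + disp(omega)`` with bilinear interpolation.

    Parameters
    ----------
    x : Tensor, shape (N, C, H, W)
    disp : Tensor, shape (N, 2, H, W)
        Row/column displacement in pixels.
    """
    x, disp = ad.astensor(x), ad.astensor(disp)
    n, c, h, w = x.shape
    if disp.shape != (n, 2, h, w):
        raise ValueError(f"displacement shape {disp.shape} does not match image {x.shape}")
    if not np.all(np.isfinite(disp.data)):
        raise ValueError("non-finite displacement field")

    grid_r = np.arange(h, dtype=np.float64)[None, None, :, None]
    grid_c = np.arange(w, dtype=np.float64)[None, None, None, :]
    rows = _clamp(disp[:, 0:1] + Tensor(grid_r), 0.0, float(h - 1))
    cols = _clamp(disp[:, 1:2] + Tensor(grid_c), 0.0, float(w - 1))

    r0 = np.clip(np.floor(rows.data), 0, h - 2).astype(np.int64)
    c0 = np.clip(np.floor(cols.data), 0, w - 2).astype(np.int64)
    fr = rows - Tensor(r0.astype(np.float64))
    fc = cols - Tensor(c0.astype(np.float64))

    nc_idx = (np.arange(n)[:, None, None, None] * c + np.arange(c)[None, :, None, None]) * (h * w)
    r0b = np.broadcast_to(r0, (n, c, h, w))
    c0b = np.broadcast_to(c0, (n, c, h, w))
    base = nc_idx + r0b * w + c0b
    x00 = ad.gather(x, base)
    x01 = ad.gather(x, base + 1)
    x10 = ad.gather(x, base + w)
    x11 = ad.gather(x, base + w + 1)

    one = Tensor(1.0)
    top = x00 * (one - fc) + x01 * fc
    bot = x10 * (one - fc) + x11 * fc
    return top * (one - fr) + bot * fr


def compose_displacements_batch(da: Tensor, db: Tensor) -> Tensor:
    """Displacement of ``phi_a o phi_b``: ``da(omega + db(omega)) + db(omega)``."""
    return warp_batch(da, db) + db


def integrate_velocity_batch(v: Tensor, n_steps: int = DEFAULT_INTEGRATION_STEPS) -> Tensor:
    """Scaling-and-squaring integration of a stationary velocity field.

    ``v`` has shape (N, 2, H, W); returns the displacement of ``exp(v)``.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    v = ad.astensor(v)
    disp = v * float(2.0 ** (-n_steps))
    for _ in range(n_steps):
        disp = compose_displacements_batch(disp, disp)
    return disp


def sit_output_batch(
    x: Tensor,
    v: Tensor | None,
    delta_x: Tensor | None,
    n_steps: int = DEFAULT_INTEGRATION_STEPS,
    displacement: Tensor | None = None,
) -> Tensor:
    """Apply a spatial-intensity transform ``Phi(x + delta_x)``.

    The intensity map is added *before* warping.  The spatial part is
    either the flow of a velocity field ``v`` or a raw ``displacement``.
    """
    out = x if delta_x is None else x + delta_x
    if v is not None and displacement is not None:
        raise ValueError("give either a velocity field or a displacement, not both")
    if v is not None:
        out = warp_batch(out, integrate_velocity_batch(v, n_steps))
    elif displacement is not None:
        out = warp_batch(out, displacement)
    return out


def intensity_l1_batch(delta_x: Tensor) -> Tensor:
    """Mean absolute intensity change, ``(1/|Omega|) sum |dx|``, per batch."""
    return ad.tabs(delta_x).mean()


def displacement_tv_batch(f: Tensor) -> Tensor:
    """Differentiable total-variation norm of a (N, 2, H, W) displacement.

    Forward differences with replicate edges (the last row/column
    difference is zero); the 2-norm is taken jointly over all four
    partial derivatives at each pixel, then averaged over pixels.
    """
    n, c, h, w = f.shape
    if h < 2 or w < 2:
        raise ValueError("TV norm needs a grid of at least 2x2")
    dr = ad.pad_constant(f[:, :, 1:, :] - f[:, :, :-1, :], ((0, 0), (0, 0), (0, 1), (0, 0)))
    dc = ad.pad_constant(f[:, :, :, 1:] - f[:, :, :, :-1], ((0, 0), (0, 0), (0, 0), (0, 1)))
    sq = (dr**2).sum(axis=1) + (dc**2).sum(axis=1)
    per_pixel = ad.sqrt(sq + _TV_EPS)
    return per_pixel.sum(axis=(1, 2)).mean() * (1.0 / (h * w))


# ----------------------------------------------------------------------
# field-level API
# ----------------------------------------------------------------------

def _vf_to_tensor(vf: VectorField2D) -> Tensor:
    return Tensor(vf.values.transpose(2, 0, 1)[None])


def _tensor_to_vf(t: Tensor) -> VectorField2D:
    return VectorField2D(t.data[0].transpose(1, 2, 0))


def integrate_velocity(
    v: VectorField2D, n_steps: int = DEFAULT_INTEGRATION_STEPS
) -> DeformationField:
    """Compute the diffeomorphism ``exp(V)`` by scaling and squaring."""
    if not isinstance(v, VectorField2D):
        v = VectorField2D(np.asarray(v))
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    disp = integrate_velocity_batch(_vf_to_tensor(v), n_steps)
    return DeformationField(_tensor_to_vf(disp), steps_used=n_steps)


def compose_deformations(phi_a: DeformationField, phi_b: DeformationField) -> DeformationField:
    """Composition ``phi_a o phi_b`` of two deformations on the same grid."""
    if phi_a.shape != phi_b.shape:
        raise ValueError(f"grid shapes differ: {phi_a.shape} vs {phi_b.shape}")
    da = _vf_to_tensor(phi_a.displacement)
    db = _vf_to_tensor(phi_b.displacement)
    return DeformationField(
        _tensor_to_vf(compose_displacements_batch(da, db)),
        steps_used=max(phi_a.steps_used, phi_b.steps_used),
    )


def warp_image(x: ScalarField2D, phi: DeformationField) -> ScalarField2D:
    """Resample ``x`` through ``phi`` with bilinear interpolation."""
    if not isinstance(x, ScalarField2D):
        x = ScalarField2D(np.asarray(x))
    if x.shape != phi.shape:
        raise ValueError(f"grid shapes differ: {x.shape} vs {phi.shape}")
    out = warp_batch(Tensor(x.values[None, None]), _vf_to_tensor(phi.displacement))
    return ScalarField2D(out.data[0, 0])


def apply_sit(
    x: ScalarField2D,
    v: VectorField2D,
    delta_x: ScalarField2D,
    n_steps: int = DEFAULT_INTEGRATION_STEPS,
) -> ScalarField2D:
    """Spatial-intensity transform output ``Phi_V(x + delta_x)``."""
    if not isinstance(x, ScalarField2D):
        x = ScalarField2D(np.asarray(x))
    if not isinstance(delta_x, ScalarField2D):
        delta_x = ScalarField2D(np.asarray(delta_x))
    if x.shape != delta_x.shape:
        raise ValueError("image and intensity map shapes differ")
    shifted = ScalarField2D(x.values + delta_x.values)
    return warp_image(shifted, integrate_velocity(v, n_steps))


def intensity_l1(delta_x: ScalarField2D) -> float:
    """Sparsity penalty: mean absolute value of the intensity map."""
    values = delta_x.values if isinstance(delta_x, ScalarField2D) else np.asarray(delta_x)
    if not np.all(np.isfinite(values)):
        raise ValueError("intensity map contains non-finite values")
    return float(np.abs(values).mean())


def displacement_tv(f: VectorField2D) -> float:
    """Discrete total-variation norm of a displacement field (exact)."""
    values = f.values if isinstance(f, VectorField2D) else np.asarray(f)
    h, w = values.shape[:2]
    if h < 2 or w < 2:
        raise ValueError("TV norm needs a grid of at least 2x2")
    dr = np.zeros_like(values)
    dc = np.zeros_like(values)
    dr[:-1] = values[1:] - values[:-1]
    dc[:, :-1] = values[:, 1:] - values[:, :-1]
    per_pixel = np.sqrt((dr**2).sum(axis=-1) + (dc**2).sum(axis=-1))
    return float(per_pixel.mean())


def jacobian_determinant(phi: DeformationField) -> ScalarField2D:
    """Finite-difference Jacobian determinant of ``omega -> omega + u(omega)``.

    Central differences; returned on the (H-2) x (W-2) interior grid.
    Strictly positive values certify a locally invertible (orientation
    preserving) map.
    """
    u = phi.displacement.values
    h, w = u.shape[:2]
    if h < 3 or w < 3:
        raise ValueError("Jacobian determinant needs a grid of at least 3x3")
    dur_dr, dur_dc = np.gradient(u[..., 0])
    duc_dr, duc_dc = np.gradient(u[..., 1])
    det = (1.0 + dur_dr) * (1.0 + duc_dc) - dur_dc * duc_dr
    return ScalarField2D(det[1:-1, 1:-1])
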