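"""Shared test utilities: smooth random fields and an independent flow integrator."""

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates


def smooth_velocity_field(shape, max_magnitude, rng, sigma=6.0, taper=True):
    """Random smooth (H, W, 2) velocity field with given max vector magnitude.

    By default the field tapers to zero at the image border (sine window):
    with clamp-to-edge sampling a flow that crosses the boundary is not
    invertible there, and the package's use case (anatomy inside a
    background margin) has no boundary-crossing flow either.
    """
    h, w = shape
    v = rng.normal(size=(h, w, 2))
    for k in range(2):
        v[..., k] = gaussian_filter(v[..., k], sigma=sigma, mode="nearest")
    if taper:
        wr = np.sin(np.pi * np.arange(h) / (h - 1))
        wc = np.sin(np.pi * np.arange(w) / (w - 1))
        v *= (wr[:, None] * wc[None, :])[..., None]
    mag = np.sqrt((v**2).sum(axis=-1)).max()
    if mag > 0:
        v *= max_magnitude / mag
    return v


def euler_integrate(v, n_substeps):
    """Forward-Euler flow of a stationary velocity field, independent oracle.

    Tracks each pixel's trajectory ``p' = V(p)`` with ``n_substeps``
    uniform steps, sampling V bilinearly with clamped coordinates.
    Returns the final displacement field (H, W, 2).
    """
    h, w = v.shape[:2]
    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    pr, pc = rr.copy(), cc.copy()
    dt = 1.0 / n_substeps
    for _ in range(n_substeps):
        coords = [np.clip(pr, 0, h - 1), np.clip(pc, 0, w - 1)]
        vr = map_coordinates(v[..., 0], coords, order=1, mode="nearest")
        vc = map_coordinates(v[..., 1], coords, order=1, mode="nearest")
        pr = pr + dt * vr
        pc = pc + dt * vc
    return np.stack([pr - rr, pc - cc], axis=-1)
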