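"""Attribute-conditioned phantom images with known ground truth.

The phantoms emulate axial brain slices at the level of the lateral
ventricles: an elliptical "head" filled with textured tissue, a central
dark "ventricle" whose radius grows linearly with the first (age-like)
attribute, dark radial "sulci" near the head boundary, and bright
"lesions" (white-matter-hyperintensity-like spots) adjacent to the
ventricle whose number and extent grow with the second (severity-like)
attribute.  Because the lesions sit on the ventricle border, intensity
effects and morphology effects are spatially entangled, which makes
disentangling them a non-trivial test for a generator.

All rendering is deterministic given (spec, attributes, subject seed,
noise seed).  Subject-level anatomy (head jitter, sulci layout, texture)
is constant across a subject's timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .data import AttributeScaler, ImageAttributeDataset
from .fields import DeformationField, ScalarField2D, VectorField2D

ATTR_RANGE = 2.0  # documented attribute range is [-2, 2]


@dataclass
class PhantomSpec:
    """Ground-truth rendering parameters (pixel units for a 64 px frame)."""

    image_size: int = 64
    head_semi_axes: tuple = (25.0, 21.0)  # (row, col) semi-axes, px
    head_jitter: float = 0.03  # relative subject-level jitter of the axes
    ventricle_radius: float = 6.0  # r0: radius at attribute 0, px
    radius_per_unit: float = 1.5  # alpha_r: px per unit of attribute 1
    n_sulci: int = 8
    sulcus_width: float = 1.2  # px
    lesion_base_count: float = 2.0
    lesions_per_unit: float = 1.5  # alpha_l: extra lesions per unit of attr 2
    lesion_radius: float = 1.8  # px
    lesion_intensity: float = 0.92
    texture_amplitude: float = 0.05
    texture_scale: float = 3.0  # px
    blur_sigma: float = 0.8  # px
    noise_sd: float = 0.02

    def __post_init__(self):
        if self.radius_per_unit <= 0:
            raise ValueError("radius_per_unit must be positive")
        if self.lesions_per_unit < 0:
            raise ValueError("lesions_per_unit must be nonnegative")
        max_r = self.ventricle_radius + self.radius_per_unit * ATTR_RANGE
        margin = max_r + 2 * self.lesion_radius + 2.0
        if margin >= min(self.head_semi_axes) * (1 - self.head_jitter):
            raise ValueError("structures escape the head ellipse at extreme attributes")

    @classmethod
    def scaled(cls, image_size: int, **overrides) -> "PhantomSpec":
        """A spec with pixel quantities scaled from the 64 px defaults."""
        s = image_size / 64.0
        base = cls(
            image_size=image_size,
            head_semi_axes=(25.0 * s, 21.0 * s),
            ventricle_radius=6.0 * s,
            radius_per_unit=1.5 * s,
            sulcus_width=max(1.0, 1.2 * s),
            lesion_radius=max(1.2, 1.8 * s),
            texture_scale=3.0 * s,
            blur_sigma=0.8 * max(0.6, s),
        )
        return replace(base, **overrides)


# intensities of the tissue classes
_BG = 0.05
_TISSUE = 0.55
_VENTRICLE = 0.12
_SULCUS = 0.32
_EDGE = 0.7  # softness (px) of structure boundaries before blurring


def _soft_disk(dist, radius, width=_EDGE):
    """1 inside, 0 outside, smooth ramp of ~width px at the boundary."""
    return 1.0 / (1.0 + np.exp((dist - radius) / (width / 4.0)))


def _subject_anatomy(spec: PhantomSpec, subject_seed: int):
    rng = np.random.default_rng(subject_seed)
    jr = 1.0 + spec.head_jitter * rng.uniform(-1, 1)
    jc = 1.0 + spec.head_jitter * rng.uniform(-1, 1)
    axes = (spec.head_semi_axes[0] * jr, spec.head_semi_axes[1] * jc)
    sulci_angles = rng.uniform(0, 2 * np.pi, size=spec.n_sulci)
    lesion_angles = rng.uniform(0, 2 * np.pi, size=16)  # candidate positions
    texture = rng.normal(size=(spec.image_size, spec.image_size))
    texture = gaussian_filter(texture, spec.texture_scale, mode="nearest")
    if texture.std() > 0:
        texture = texture / texture.std()
    return axes, sulci_angles, lesion_angles, texture


def render_phantom(
    spec: PhantomSpec, attrs, subject_seed: int = 0, noise_seed: int = 0
) -> ScalarField2D:
    """Render one phantom slice for raw attribute values ``attrs``.

    ``attrs`` is (a1, a2): a1 drives the ventricle radius, a2 the lesion
    load.  A missing (NaN) entry renders at its population mean of 0.
    """
    attrs = np.nan_to_num(np.asarray(attrs, dtype=float), nan=0.0)
    a1 = attrs[0]
    a2 = attrs[1] if attrs.size > 1 else 0.0
    if np.abs(attrs).max() > ATTR_RANGE + 1e-9:
        raise ValueError(f"attributes outside documented range [-2, 2]: {attrs}")

    S = spec.image_size
    axes, sulci_angles, lesion_angles, texture = _subject_anatomy(spec, subject_seed)
    cr = cc = (S - 1) / 2.0
    rr, cc_grid = np.meshgrid(np.arange(S, dtype=float), np.arange(S, dtype=float), indexing="ij")
    dr, dc = rr - cr, cc_grid - cc

    # head ellipse
    ell = np.sqrt((dr / axes[0]) ** 2 + (dc / axes[1]) ** 2)
    head = _soft_disk(ell, 1.0, width=_EDGE / min(axes))
    img = _BG + (_TISSUE - _BG) * head
    img += spec.texture_amplitude * texture * head

    # sulci: dark radial wedges in the outer tissue band
    theta = np.arctan2(dr, dc)
    for ang in sulci_angles:
        dtheta = np.angle(np.exp(1j * (theta - ang)))
        band = (ell > 0.62) & (ell < 0.95)
        line = np.exp(-0.5 * (dtheta * ell * min(axes) / spec.sulcus_width) ** 2)
        img -= (_TISSUE - _SULCUS) * line * band * head

    # ventricle: central dark disk, radius r0 + alpha_r * a1
    radius = spec.ventricle_radius + spec.radius_per_unit * a1
    dist = np.sqrt(dr**2 + dc**2)
    vent = _soft_disk(dist, radius)
    img = img * (1 - vent) + _VENTRICLE * vent

    # lesions: bright spots on a ring just outside the ventricle boundary
    n_lesions = int(round(spec.lesion_base_count + spec.lesions_per_unit * a2))
    n_lesions = int(np.clip(n_lesions, 0, lesion_angles.size))
    lesion_r = spec.lesion_radius * (1.0 + 0.15 * a2)
    ring = radius + 1.2 * spec.lesion_radius
    for ang in lesion_angles[:n_lesions]:
        lr, lc = cr + ring * np.sin(ang), cc + ring * np.cos(ang)
        ldist = np.sqrt((rr - lr) ** 2 + (cc_grid - lc) ** 2)
        blob = _soft_disk(ldist, lesion_r)
        img = img * (1 - blob) + spec.lesion_intensity * blob

    img = gaussian_filter(img, spec.blur_sigma, mode="nearest")
    if spec.noise_sd > 0:
        img = img + np.random.default_rng(noise_seed).normal(0, spec.noise_sd, img.shape)
    return ScalarField2D(np.clip(img, 0.0, 1.0))


def measure_ventricle_radius(
    image, spec: PhantomSpec, threshold: float = 0.35, softness: float = 0.15
) -> float:
    """Thresholded-area estimate of the ventricle radius (oracle).

    Smooths the image slightly, counts the area below the dark threshold
    within the central region and converts it to an equivalent-circle
    radius.  The threshold is applied softly (each pixel contributes the
    fraction by which it falls below the threshold over a ``softness``
    intensity band), giving sub-pixel resolution on blurred boundaries.
    """
    values = image.values if isinstance(image, ScalarField2D) else np.asarray(image)
    S = spec.image_size
    sm = gaussian_filter(values, 1.0, mode="nearest")
    cr = cc = (S - 1) / 2.0
    rr, ccg = np.meshgrid(np.arange(S, dtype=float), np.arange(S, dtype=float), indexing="ij")
    central = np.sqrt((rr - cr) ** 2 + (ccg - cc) ** 2) < (
        spec.ventricle_radius + spec.radius_per_unit * ATTR_RANGE + 3.0
    )
    frac = np.clip((threshold - sm) / softness + 0.5, 0.0, 1.0)
    area = float((frac * central).sum())
    return float(np.sqrt(area / np.pi))


# ----------------------------------------------------------------------
# cohorts
# ----------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """A rendered cohort with ground truth and a fitted attribute scaler."""

    images: np.ndarray  # (N, H, W)
    attributes: pd.DataFrame  # observed (NaN = missing), raw units
    true_attributes: pd.DataFrame  # complete ground truth, raw units
    subjects: np.ndarray
    timepoints: np.ndarray  # years from baseline
    scaler: AttributeScaler
    spec: PhantomSpec
    master_seed: int

    def __len__(self):
        return self.images.shape[0]

    def dataset(self, normalized: bool = True) -> ImageAttributeDataset:
        attrs = self.scaler.transform(self.attributes) if normalized else self.attributes
        return ImageAttributeDataset(
            images=self.images,
            attributes=attrs.reset_index(drop=True),
            subjects=self.subjects,
            timepoints=self.timepoints,
        )


AGING_RATE = 0.25  # attribute-1 units per year in the longitudinal trajectories


def generate_cohort(
    n_subjects: int,
    timepoints_per_subject: int = 1,
    missing_rate: float = 0.0,
    master_seed: int = 0,
    spec: PhantomSpec | None = None,
) -> SyntheticCohort:
    """Render a longitudinal cohort with per-attribute missingness.

    Each subject gets a baseline attribute pair; the age-like attribute
    increases along the subject's timepoints (about 1 year apart), the
    severity attribute stays at its subject level.
    """
    if spec is None:
        spec = PhantomSpec()
    rng = np.random.default_rng(master_seed)
    rows, imgs, subjects, times = [], [], [], []
    for s in range(n_subjects):
        subject_seed = int(rng.integers(0, 2**31 - 1))
        span = AGING_RATE * 1.1 * max(1, timepoints_per_subject - 1)
        a1 = float(np.clip(rng.normal(0.0, 0.8), -ATTR_RANGE + 0.2, ATTR_RANGE - span - 0.2))
        a2 = float(np.clip(rng.normal(0.0, 0.8), -ATTR_RANGE + 0.2, ATTR_RANGE - 0.2))
        t = 0.0
        for _k in range(timepoints_per_subject):
            noise_seed = int(rng.integers(0, 2**31 - 1))
            img = render_phantom(spec, (a1, a2), subject_seed, noise_seed)
            imgs.append(img.values)
            rows.append((a1, a2))
            subjects.append(f"S{s:04d}")
            times.append(t)
            gap = float(rng.uniform(0.6, 1.6))
            t += gap
            a1 = float(np.clip(a1 + AGING_RATE * gap, -ATTR_RANGE, ATTR_RANGE))
    true_attrs = pd.DataFrame(rows, columns=["a1", "a2"])
    observed = true_attrs.copy()
    if missing_rate > 0:
        miss = rng.random(observed.shape) < missing_rate
        observed = observed.mask(miss)
    scaler = AttributeScaler.fit(observed)
    return SyntheticCohort(
        images=np.stack(imgs),
        attributes=observed,
        true_attributes=true_attrs,
        subjects=np.array(subjects),
        timepoints=np.array(times),
        scaler=scaler,
        spec=spec,
        master_seed=master_seed,
    )


# ----------------------------------------------------------------------
# analytic ground-truth deformation
# ----------------------------------------------------------------------

def ground_truth_deformation(
    spec: PhantomSpec, attrs_from, attrs_to
) -> DeformationField:
    """Radial deformation mapping the phantom at ``attrs_from`` onto
    ``attrs_to`` (morphology only; lesions/texture held fixed).

    The pullback displacement moves the sample point at radius ``r`` to
    ``g(r)`` with ``g(r_to) = r_from``, linear inside the ventricle,
    linearly relaxing to the identity at the head boundary; its Jacobian
    stays positive for the documented attribute range.
    """
    a_from = np.nan_to_num(np.asarray(attrs_from, dtype=float), nan=0.0)
    a_to = np.nan_to_num(np.asarray(attrs_to, dtype=float), nan=0.0)
    r_from = spec.ventricle_radius + spec.radius_per_unit * a_from[0]
    r_to = spec.ventricle_radius + spec.radius_per_unit * a_to[0]
    rh = float(min(spec.head_semi_axes))

    S = spec.image_size
    cr = cc = (S - 1) / 2.0
    rr, ccg = np.meshgrid(np.arange(S, dtype=float), np.arange(S, dtype=float), indexing="ij")
    dr, dc = rr - cr, ccg - cc
    r = np.sqrt(dr**2 + dc**2)

    with np.errstate(invalid="ignore", divide="ignore"):
        inner = r * (r_from / r_to)
        slope = (rh - r_from) / (rh - r_to)
        outer = r_from + (r - r_to) * slope
        g = np.where(r <= r_to, inner, np.where(r < rh, outer, r))
    scale = np.where(r > 1e-9, g / np.maximum(r, 1e-9) - 1.0, 0.0)
    u = np.stack([dr * scale, dc * scale], axis=-1)
    return DeformationField(VectorField2D(u))
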