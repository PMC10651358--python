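"""Grid-valued field types: images, vector fields and deformations.

Conventions used throughout the package:

* grids are indexed ``(row, col)``, 0-based, origin at pixel (0, 0);
* displacement and velocity components are in pixel units along the
  (row, col) axes;
* a deformation with zero displacement is the identity map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ScalarField2D", "VectorField2D", "DeformationField"]


def _check_grid(values: np.ndarray, ndim: int, name: str) -> np.ndarray:
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != ndim:
        raise ValueError(f"{name} must be a {ndim}-D array, got shape {values.shape}")
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError(f"{name} needs a grid of at least 2x2, got {values.shape}")
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{name} contains non-finite values")
    return values


@dataclass
class ScalarField2D:
    """An H x W grid of real intensities (an image or a difference map)."""

    values: np.ndarray

    def __post_init__(self):
        self.values = _check_grid(self.values, 2, "ScalarField2D")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self):
        return self.values.shape

    def save(self, path) -> None:
        np.savez(path, values=self.values, shape=np.array(self.values.shape))

    @classmethod
    def load(cls, path) -> "ScalarField2D":
        with np.load(path) as f:
            return cls(f["values"])


@dataclass
class VectorField2D:
    """An H x W grid of 2-vectors (a velocity or displacement field).

    ``values[..., 0]`` is the row component, ``values[..., 1]`` the
    column component, both in pixels.
    """

    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3 or values.shape[2] != 2:
            raise ValueError(
                f"VectorField2D must have shape (H, W, 2), got {values.shape}"
            )
        _check_grid(values[..., 0], 2, "VectorField2D")
        self.values = values

    @property
    def shape(self):
        return self.values.shape[:2]

    @classmethod
    def zeros(cls, shape) -> "VectorField2D":
        return cls(np.zeros((shape[0], shape[1], 2)))

    def max_magnitude(self) -> float:
        return float(np.sqrt((self.values**2).sum(axis=-1)).max())

    def save(self, path) -> None:
        np.savez(path, values=self.values, shape=np.array(self.values.shape))

    @classmethod
    def load(cls, path) -> "VectorField2D":
        with np.load(path) as f:
            return cls(f["values"])


@dataclass
class DeformationField:
    """A spatial map omega -> omega + displacement(omega)."""

    displacement: VectorField2D
    steps_used: int = 0

    def __post_init__(self):
        if not isinstance(self.displacement, VectorField2D):
            self.displacement = VectorField2D(np.asarray(self.displacement))

    @property
    def shape(self):
        return self.displacement.shape

    @classmethod
    def identity(cls, shape) -> "DeformationField":
        return cls(VectorField2D.zeros(shape))
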