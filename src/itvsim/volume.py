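"""Scalar image volumes on a regular grid.

Axis convention used throughout the package: arrays are indexed ``(x, y, z)``
where ``x`` is medial--lateral, ``y`` is anterior--posterior and ``z`` is the
superior--inferior (SI) axis with +z pointing superior.  All physical lengths
are centimetres and volumes are cubic centimetres (cc); voxel positions refer
to voxel *centres*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Two grids are considered identical when spacings and origins agree to this
#: tolerance (cm).  No implicit resampling is ever performed.
GEOMETRY_TOL_CM = 1e-6


def geometry_matches(a, b, tol: float = GEOMETRY_TOL_CM) -> bool:
    """True when two gridded objects share shape, spacing and origin.

    Works for any pair of objects exposing ``shape``, ``spacing`` and
    ``origin`` (:class:`ImageVolume`, :class:`~itvsim.delineation.StructureMask`).
    """
    if tuple(a.shape) != tuple(b.shape):
        return False
    sa, sb = np.asarray(a.spacing, float), np.asarray(b.spacing, float)
    oa, ob = np.asarray(a.origin, float), np.asarray(b.origin, float)
    return bool(np.all(np.abs(sa - sb) <= tol) and np.all(np.abs(oa - ob) <= tol))


def require_same_geometry(a, b, what: str = "volumes") -> None:
    """Raise ``ValueError`` unless *a* and *b* live on the same grid."""
    if not geometry_matches(a, b):
        raise ValueError(
            f"geometry mismatch between {what}: "
            f"shape {tuple(a.shape)} / spacing {tuple(a.spacing)} / origin {tuple(a.origin)} "
            f"vs shape {tuple(b.shape)} / spacing {tuple(b.spacing)} / origin {tuple(b.origin)}"
        )


@dataclass
class ImageVolume:
    """A 3-D scalar intensity grid with uniform spacing.

    Parameters
    ----------
    values
        Array of shape ``(nx, ny, nz)`` holding CT-number-like intensities.
    spacing
        Voxel spacing ``(sx, sy, sz)`` in cm; strictly positive.
    origin
        Physical position (cm) of the centre of voxel ``(0, 0, 0)``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3-D, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        if len(self.origin) != 3:
            raise ValueError(f"origin must have three components, got {self.origin}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image contains non-finite values")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cc(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical centre coordinates (cm) of voxels along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def bounds(self) -> list[tuple[float, float]]:
        """Physical extent per axis including the half-voxel border."""
        out = []
        for ax in range(3):
            c = self.axis_coords(ax)
            h = 0.5 * self.spacing[ax]
            out.append((c[0] - h, c[-1] + h))
        return out

    def same_geometry(self, other, tol: float = GEOMETRY_TOL_CM) -> bool:
        return geometry_matches(self, other, tol)

    def copy_with(self, values: np.ndarray) -> "ImageVolume":
        """New volume with the same grid and different voxel values."""
        return ImageVolume(values=values, spacing=self.spacing, origin=self.origin)
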