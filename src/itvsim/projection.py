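"""Maximum- and average-intensity projections over a phase stack.

The MIP assigns each voxel the highest value it attains in any respiratory
phase, the AIP the arithmetic mean over all phases.  Both compress the
temporal information of the 4DCT into a single 3-D volume on the same grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import PhaseStack
from .volume import ImageVolume


@dataclass
class ProjectionVolume(ImageVolume):
    """An intensity projection; ``mode`` records how it was built."""

    mode: str = "MIP"

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.mode not in ("MIP", "AIP"):
            raise ValueError(f"mode must be 'MIP' or 'AIP', got {self.mode!r}")


def _stacked(stack: PhaseStack) -> np.ndarray:
    # PhaseStack validates the common geometry at construction.
    return np.stack([p.values for p in stack.phases], axis=0)


def build_mip(stack: PhaseStack) -> ProjectionVolume:
    """Voxelwise maximum across all phases (maximum intensity projection)."""
    geo = stack.geometry
    return ProjectionVolume(
        values=_stacked(stack).max(axis=0), spacing=geo.spacing, origin=geo.origin, mode="MIP"
    )


def build_aip(stack: PhaseStack) -> ProjectionVolume:
    """Voxelwise arithmetic mean across all phases (average intensity projection)."""
    geo = stack.geometry
    return ProjectionVolume(
        values=_stacked(stack).mean(axis=0), spacing=geo.spacing, origin=geo.origin, mode="AIP"
    )
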