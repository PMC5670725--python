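"""Overlap and volume statistics for comparing delineation strategies.

All overlap measures are computed on voxel counts over a common grid: the
Dice similarity coefficient

    DSC = 2 |V_GS intersect V_x| / (|V_GS| + |V_x|)

quantifies spatial agreement between a strategy's PTV and the gold-standard
PTV, while the PTV ratio R_x = V_x / V_GS compares volumes irrespective of
position (equal volumes with zero overlap give R = 1, DSC = 0).  Agreement
is conventionally called "good" when DSC exceeds 0.700.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .delineation import Strategy, StructureMask
from .volume import require_same_geometry

#: DSC above this value is conventionally termed good agreement (strict).
GOOD_AGREEMENT_DSC = 0.700


def volume_cc(mask: StructureMask) -> float:
    """Structure volume in cc (true-voxel count times voxel volume)."""
    return mask.volume_cc


def dice(a: StructureMask, b: StructureMask) -> float:
    """Dice similarity coefficient of two masks on one grid.

    Convention for degenerate inputs: two empty masks are identical sets and
    score 1.0; exactly one empty mask scores 0.0.
    """
    require_same_geometry(a, b, "masks")
    na = int(a.mask.sum())
    nb = int(b.mask.sum())
    if na == 0 and nb == 0:
        return 1.0
    inter = int(np.logical_and(a.mask, b.mask).sum())
    return 2.0 * inter / (na + nb)


def ptv_ratio(v_x: float, v_gs: float) -> float:
    """PTV ratio R_x = V_x / V_GS of a strategy volume to the gold standard."""
    if v_gs <= 0:
        raise ValueError(f"gold-standard volume must be positive, got {v_gs}")
    return v_x / v_gs


def motion_vector(dx: float, dy: float, dz: float) -> float:
    """Euclidean norm M of per-axis centroid displacement components (cm)."""
    if not all(math.isfinite(v) for v in (dx, dy, dz)):
        raise ValueError(f"displacement components must be finite, got {(dx, dy, dz)}")
    return math.sqrt(dx * dx + dy * dy + dz * dz)


def capsule_volume(r: float, L: float) -> float:
    """Volume (cc) of a sphere of radius ``r`` swept a distance ``L``.

    The spherocylinder (4/3) pi r^3 + pi r^2 L is the analytic oracle for the
    envelope of a sphere translating along a straight line, e.g. the ITV of
    the SI-moving phantom with L equal to the peak-to-peak range.
    """
    if r <= 0:
        raise ValueError(f"radius must be positive, got {r}")
    if L < 0:
        raise ValueError(f"sweep length must be non-negative, got {L}")
    return (4.0 / 3.0) * math.pi * r**3 + math.pi * r**2 * L


def classify_agreement(dsc: float) -> str:
    """'good' when DSC strictly exceeds 0.700, else 'poor'."""
    if not 0.0 <= dsc <= 1.0:
        raise ValueError(f"DSC must lie in [0, 1], got {dsc}")
    return "good" if dsc > GOOD_AGREEMENT_DSC else "poor"


@dataclass(frozen=True)
class OverlapResult:
    """Bundle of overlap statistics for one strategy vs the gold standard."""

    strategy: Strategy
    v_gs: float
    v_x: float
    intersection_cc: float
    dsc: float
    r_ratio: float

    @property
    def agreement(self) -> str:
        return classify_agreement(self.dsc)


def compare_masks(gs: StructureMask, other: StructureMask) -> OverlapResult:
    """Full overlap comparison of a strategy PTV against the gold standard."""
    require_same_geometry(gs, other, "masks")
    inter_cc = float(np.logical_and(gs.mask, other.mask).sum()) * gs.voxel_volume_cc
    return OverlapResult(
        strategy=other.strategy if other.strategy is not None else Strategy.GS,
        v_gs=gs.volume_cc,
        v_x=other.volume_cc,
        intersection_cc=inter_cc,
        dsc=dice(gs, other),
        r_ratio=ptv_ratio(other.volume_cc, gs.volume_cc),
    )
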