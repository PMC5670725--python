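"""Volume/mask persistence (NIfTI) and flat key-value configs.

Internally the package works in centimetres; NIfTI files are written with a
millimetre affine (diagonal, no rotation) as is conventional for medical
images.  Masks are stored with a 0/1 uint8 payload.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .delineation import StructureMask
from .volume import ImageVolume

_CM_TO_MM = 10.0


def _affine(spacing_cm, origin_cm) -> np.ndarray:
    aff = np.diag([s * _CM_TO_MM for s in spacing_cm] + [1.0])
    aff[:3, 3] = [o * _CM_TO_MM for o in origin_cm]
    return aff


def write_volume(vol: ImageVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(vol.values.astype(np.float32), _affine(vol.spacing, vol.origin))
    nib.save(img, str(path))


def write_mask(mask: StructureMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), _affine(mask.spacing, mask.origin))
    nib.save(img, str(path))


def _read_geometry(img) -> tuple[tuple, tuple]:
    aff = img.affine
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3]))):
        raise ValueError("only axis-aligned (diagonal-affine) NIfTI volumes are supported")
    spacing = tuple(float(d) / _CM_TO_MM for d in np.diag(aff[:3, :3]))
    origin = tuple(float(o) / _CM_TO_MM for o in aff[:3, 3])
    return spacing, origin


def read_volume(path: str | Path) -> ImageVolume:
    img = nib.load(str(path))
    spacing, origin = _read_geometry(img)
    return ImageVolume(np.asarray(img.dataobj, dtype=np.float64), spacing, origin)


def read_mask(path: str | Path, label: str = "GTV") -> StructureMask:
    img = nib.load(str(path))
    spacing, origin = _read_geometry(img)
    return StructureMask(np.asarray(img.dataobj) > 0.5, spacing, origin, label=label)


# -- flat key-value configuration ------------------------------------------

def save_config(cfg: dict, path: str | Path) -> None:
    """Write a flat ``key = value`` text config; sequences join with commas."""
    lines = []
    for key, value in cfg.items():
        if isinstance(value, (tuple, list)):
            value = ",".join(str(v) for v in value)
        lines.append(f"{key} = {value}")
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_scalar(text: str):
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    if text.lower() in ("true", "false"):
        return text.lower() == "true"
    return text


def load_config(path: str | Path) -> dict:
    """Read a flat ``key = value`` config; comma-separated values parse to tuples."""
    cfg: dict = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, _, rest = line.partition("=")
        rest = rest.strip()
        if "," in rest:
            cfg[key.strip()] = tuple(_parse_scalar(p.strip()) for p in rest.split(","))
        else:
            cfg[key.strip()] = _parse_scalar(rest)
    return cfg
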