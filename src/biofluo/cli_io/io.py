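"""File formats: TIFF images with JSON sidecars, NIfTI volumes, CSV
event lists and curves."""
from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from ..optical_proc import Image2D
from ..spect_proc import EventList, Volume3D

__all__ = [
    "MetadataError",
    "write_image",
    "read_image",
    "write_volume",
    "read_volume",
    "write_events",
    "read_events",
]

_SIDECAR_REQUIRED = ("pixel_size_mm", "exposure_s", "modality")


class MetadataError(ValueError):
    """Missing or inconsistent image metadata."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_image(path, image: Image2D, *, seed: int | None = None,
                dtype: str = "auto") -> None:
    """Write a TIFF plus a JSON sidecar with the acquisition metadata.

    ``dtype='auto'`` stores integer-valued images within the 16-bit
    range as uint16 and everything else as float32.
    """
    path = Path(path)
    px = image.pixels
    if dtype == "auto":
        as_int = np.all(px == np.round(px)) and px.max() <= 65535
        dtype = "uint16" if as_int else "float32"
    tifffile.imwrite(path, px.astype(dtype))
    meta = {
        "pixel_size_mm": image.pixel_size_mm,
        "exposure_s": image.exposure_s,
        "modality": image.modality,
        "saturated": bool(image.saturated),
    }
    if seed is not None:
        meta["seed"] = int(seed)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_image(path) -> Image2D:
    """Read a TIFF written by :func:`write_image`; missing sidecar
    fields are an error, never silent defaults."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MetadataError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in _SIDECAR_REQUIRED:
        if key not in meta:
            raise MetadataError(f"sidecar {sidecar} lacks required field {key!r}")
    pixels = tifffile.imread(path).astype(float)
    return Image2D(
        pixels,
        float(meta["pixel_size_mm"]),
        float(meta["exposure_s"]),
        str(meta["modality"]),
        bool(meta.get("saturated", False)),
    )


def write_volume(path, volume: Volume3D) -> None:
    """Write a NIfTI-1 volume with the isotropic voxel size in the header."""
    s = volume.voxel_size_mm
    affine = np.diag([s, s, s, 1.0])
    img = nib.Nifti1Image(volume.voxels.astype(np.float32), affine)
    img.header.set_zooms((s, s, s))
    nib.save(img, str(path))


def read_volume(path) -> Volume3D:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0], rtol=1e-5):
        raise ValueError(f"anisotropic voxels {zooms} are not supported")
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got shape {data.shape}")
    return Volume3D(np.maximum(data, 0.0), float(zooms[0]))


def write_events(path, events: EventList) -> None:
    events.to_frame().to_csv(path, index=False)


def read_events(path, n_angles: int) -> EventList:
    return EventList.from_frame(pd.read_csv(path), n_angles)
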