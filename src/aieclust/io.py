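"""TIFF image I/O.

Single-channel grayscale TIFF only (8/16-bit unsigned or 32-bit float).
The pixel size is stored in the TIFF resolution tags as pixels per
centimetre, preserving it to 0.01 nm. Float32 images round-trip losslessly.
"""

from __future__ import annotations

import numpy as np
import tifffile

from .aie_optics import MicroImage

__all__ = ["read_image", "write_image"]

_SUPPORTED_DTYPES = (np.uint8, np.uint16, np.float32)


def write_image(path, image: MicroImage, dtype: str = "float32") -> None:
    """Write a MicroImage as single-channel TIFF.

    dtype "float32" keeps photon values as-is; "uint16" rescales the image
    to the full 0–65535 range (documented lossy scaling for viewers).
    """
    px = np.asarray(image.pixels, dtype=float)
    if dtype == "float32":
        data = px.astype(np.float32)
    elif dtype == "uint16":
        top = px.max()
        data = (px / top * 65535.0).astype(np.uint16) if top > 0 else px.astype(np.uint16)
    else:
        raise ValueError("dtype must be 'float32' or 'uint16'")
    # resolution tags: pixels per centimetre, pixel size kept to 0.01 nm
    per_cm = (int(1e9), max(int(round(image.pixel_size * 100)), 1))
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        resolution=(per_cm, per_cm),
        resolutionunit="CENTIMETER",
    )


def read_image(path) -> MicroImage:
    """Read a single-channel grayscale TIFF into a MicroImage."""
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        data = page.asarray()
        if data.ndim != 2:
            raise ValueError(
                f"unsupported TIFF: expected single-channel 2D image, got shape {data.shape}"
            )
        if not any(np.issubdtype(data.dtype, d) for d in _SUPPORTED_DTYPES):
            raise ValueError(f"unsupported TIFF dtype {data.dtype}")
        pixel_size = 1000.0  # fallback when no resolution tags are present
        tags = page.tags
        if "XResolution" in tags and tags.get("ResolutionUnit") is not None:
            num, den = tags["XResolution"].value
            unit = tags["ResolutionUnit"].value
            unit = getattr(unit, "value", unit)
            if num > 0:
                per_unit = num / den
                if unit == 3:  # centimetre
                    pixel_size = 1e7 / per_unit
                elif unit == 2:  # inch
                    pixel_size = 2.54e7 / per_unit
    return MicroImage(pixels=data.astype(float), pixel_size=pixel_size)
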