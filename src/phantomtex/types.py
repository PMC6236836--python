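"""Shared domain containers for the phantom texture pipeline.

The pipeline passes around three small value objects: an :class:`ImageSlice`
(one 2-D grayscale slice plus its acquisition metadata), the
:class:`AcquisitionParams` describing how that slice was acquired, and an
:class:`ROIMask` selecting the phantom footprint on the slice.  They are plain
dataclasses; arrays inside them are ordinary NumPy arrays and are never copied
defensively.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

__all__ = ["AcquisitionParams", "ImageSlice", "ROIMask", "platform_from_manufacturer"]

#: Manufacturer strings written into simulated DICOM headers per platform.
PLATFORM_MANUFACTURER = {"A": "GE MEDICAL SYSTEMS", "B": "SIEMENS"}


def platform_from_manufacturer(manufacturer: Optional[str]) -> Optional[str]:
    """Normalize a DICOM Manufacturer string to a platform code.

    Vendor strings vary in case and wording across scanner software versions,
    so matching is case-insensitive and substring based.  Unrecognized vendors
    are returned verbatim (they still act as a valid grouping level); a missing
    tag maps to ``None``.
    """
    if manufacturer is None:
        return None
    low = manufacturer.lower()
    if "siemens" in low:
        return "B"
    if "ge med" in low or "general electric" in low or low.strip() in ("ge", "gems"):
        return "A"
    return manufacturer


@dataclass
class AcquisitionParams:
    """MR acquisition settings for one series.

    field_strength : main field in tesla (1.5 or 3.0)
    platform       : scanner platform code, "A" (GE-like) or "B" (Siemens-like)
    flip_angle     : excitation flip angle in degrees, in (0, 90]
    tr, te         : repetition / echo time in ms, 0 < TE < TR
    nex            : number of excitations (signal averages), integer >= 1
    matrix         : (rows, cols) of the reconstructed image
    slice_thickness: mm
    n_slices       : number of slices in the series

    Fields read from real DICOM headers may be ``None`` when the tag is
    absent; validation only applies to populated values.
    """

    field_strength: Optional[float] = 1.5
    platform: Optional[str] = "A"
    flip_angle: Optional[float] = 30.0
    tr: Optional[float] = 4.78
    te: Optional[float] = 1.125
    nex: Optional[int] = 1
    matrix: Tuple[int, int] = (256, 192)
    slice_thickness: float = 5.0
    n_slices: int = 1

    def __post_init__(self) -> None:
        if self.flip_angle is not None and not (0.0 < self.flip_angle <= 90.0):
            raise ValueError(f"flip_angle must be in (0, 90] deg, got {self.flip_angle}")
        if self.tr is not None and self.te is not None and not (0.0 < self.te < self.tr):
            raise ValueError(f"need 0 < TE < TR, got TE={self.te}, TR={self.tr}")
        if self.nex is not None:
            if int(self.nex) != self.nex or self.nex < 1:
                raise ValueError(f"NEX must be an integer >= 1, got {self.nex}")
            self.nex = int(self.nex)
        rows, cols = self.matrix
        if rows < 1 or cols < 1:
            raise ValueError(f"matrix must be positive, got {self.matrix}")


@dataclass
class ImageSlice:
    """One 2-D grayscale slice with pixel spacing and acquisition metadata."""

    pixels: np.ndarray  # 2-D nonnegative integer (or float after preprocessing)
    pixel_spacing: Tuple[float, float]  # (row, col) spacing in mm
    params: AcquisitionParams
    series_id: str = ""
    instance_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        if any(s <= 0 for s in self.pixel_spacing):
            raise ValueError(f"pixel_spacing must be positive, got {self.pixel_spacing}")


@dataclass
class ROIMask:
    """Boolean region-of-interest mask over one slice.

    ``source`` records provenance: ``manual_file`` for masks loaded from disk,
    ``auto_threshold`` for programmatically derived ones.
    """

    mask: np.ndarray
    source: str = "auto_threshold"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {self.mask.shape}")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())
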