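"""DICOM series reading, contrast grouping, and ROI-mask handling.

A "series" here is one directory of single-frame MR DICOM files sharing a
matrix size.  Acquisition parameters are populated from the standard tags
(FlipAngle, RepetitionTime, EchoTime, NumberOfAverages, MagneticFieldStrength,
Manufacturer); a missing optional tag is recorded as ``None``, never invented.

Masks may come from a file (PNG raster, ``.npy`` boolean array, or a JSON
polygon ``[[x, y], ...]`` in 0-based pixel coordinates with x = column) or be
derived automatically as the convex hull of above-threshold pixels — the
programmatic stand-in for a manual whole-phantom contour that includes the
tubes and the interstitial space between them.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Hashable, List, Sequence

import numpy as np

from .types import AcquisitionParams, ImageSlice, ROIMask, platform_from_manufacturer

__all__ = ["read_series", "group_by_contrast", "load_mask", "auto_mask", "CONTRASTS"]

#: Recognized grouping variables and how to read them off a slice.
CONTRASTS = {
    "field_strength": lambda s: s.params.field_strength,
    "flip_angle": lambda s: s.params.flip_angle,
    "nex": lambda s: s.params.nex,
    "platform": lambda s: s.params.platform,
}


def _tag(ds, name, cast=float):
    value = getattr(ds, name, None)
    if value in (None, ""):
        return None
    return cast(value)


def read_series(directory) -> List[ImageSlice]:
    """Read every DICOM file in ``directory`` as one series.

    Slices are sorted by InstanceNumber (file order breaks ties).  Raises if
    the directory holds no readable DICOM files or if matrix sizes differ
    within the series.
    """
    import pydicom
    from pydicom.errors import InvalidDicomError

    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"not a directory: {directory}")
    records = []
    for path in sorted(directory.iterdir()):
        if not path.is_file():
            continue
        try:
            ds = pydicom.dcmread(path)
        except (InvalidDicomError, OSError):
            continue
        records.append((path, ds))
    if not records:
        raise ValueError(f"no DICOM files found in {directory}")

    shapes = {(int(ds.Rows), int(ds.Columns)) for _, ds in records}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent matrix sizes within series: {sorted(shapes)}")

    slices: List[ImageSlice] = []
    for order, (path, ds) in enumerate(records):
        nex = _tag(ds, "NumberOfAverages")
        params = AcquisitionParams(
            field_strength=_tag(ds, "MagneticFieldStrength"),
            platform=platform_from_manufacturer(_tag(ds, "Manufacturer", str)),
            flip_angle=_tag(ds, "FlipAngle"),
            tr=_tag(ds, "RepetitionTime"),
            te=_tag(ds, "EchoTime"),
            nex=int(nex) if nex is not None else None,
            matrix=(int(ds.Rows), int(ds.Columns)),
            slice_thickness=_tag(ds, "SliceThickness") or 5.0,
            n_slices=len(records),
        )
        spacing = getattr(ds, "PixelSpacing", [1.0, 1.0])
        instance = _tag(ds, "InstanceNumber", int)
        slices.append(
            ImageSlice(
                pixels=ds.pixel_array,
                pixel_spacing=(float(spacing[0]), float(spacing[1])),
                params=params,
                series_id=str(getattr(ds, "SeriesDescription", directory.name)),
                instance_index=instance if instance is not None else order + 1,
            )
        )
    slices.sort(key=lambda s: s.instance_index)
    return slices


def group_by_contrast(
    slices: Sequence[ImageSlice], contrast: str
) -> Dict[Hashable, List[ImageSlice]]:
    """Partition slices by the observed levels of one acquisition variable."""
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; choose from {sorted(CONTRASTS)}")
    key = CONTRASTS[contrast]
    groups: Dict[Hashable, List[ImageSlice]] = {}
    for s in slices:
        level = key(s)
        if level is None:
            raise ValueError(
                f"slice {s.series_id}#{s.instance_index} is missing the {contrast} tag"
            )
        groups.setdefault(level, []).append(s)
    if len(groups) < 2:
        raise ValueError(
            f"contrast {contrast!r} needs >= 2 levels, observed {sorted(groups)}"
        )
    return groups


def load_mask(path, shape) -> ROIMask:
    """Load an ROI mask from a PNG, ``.npy``, or JSON-polygon file."""
    path = Path(path)
    shape = tuple(shape)
    if path.suffix == ".npy":
        mask = np.load(path).astype(bool)
    elif path.suffix == ".json":
        with open(path) as fh:
            poly = json.load(fh)
        from skimage.draw import polygon2mask

        # Stored as [[x, y], ...] with x = column; polygon2mask wants (row, col).
        pts = np.array([[p[1], p[0]] for p in poly], dtype=float)
        mask = polygon2mask(shape, pts)
    else:
        import imageio.v3 as iio

        raster = np.asarray(iio.imread(path))
        if raster.ndim == 3:
            raster = raster[..., 0]
        mask = raster > 0
    if mask.shape != shape:
        raise ValueError(f"mask shape {mask.shape} does not match image shape {shape}")
    return ROIMask(mask=mask, source="manual_file")


def auto_mask(slice_: ImageSlice) -> ROIMask:
    """Whole-phantom contour as the convex hull of above-threshold pixels.

    Mirrors a single manual contour around the full phantom: the hull covers
    every tube plus the negative space between the inserts.  The threshold is
    found by the iterative optimal method on log(1 + intensity): tubes of
    different doping span a wide intensity range, and on the log scale they
    collapse into one foreground mode cleanly separated from the dark
    background, so even the faintest tube stays above threshold.  Raises on
    images with no foreground (constant or empty).
    """
    from skimage.morphology import convex_hull_image

    from .preprocess import optimal_threshold

    pixels = np.asarray(slice_.pixels, dtype=float)
    result = optimal_threshold(np.log1p(np.clip(pixels, 0, None)))
    fg = np.log1p(np.clip(pixels, 0, None)) > result.threshold
    if not fg.any():
        raise ValueError("no above-threshold pixels: cannot build an automatic mask")
    return ROIMask(mask=convex_hull_image(fg), source="auto_threshold")
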