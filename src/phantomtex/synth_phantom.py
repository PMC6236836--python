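"""Synthetic phantom MRI series with the structure of a T1-calibration phantom.

The simulated object mirrors a nonanatomic quality-assurance phantom: 18
doped-gel tubes of 25 mm diameter plus one 20 mm tube of 0.25 mM Gd-DTPA,
arranged in concentric rings inside a 240 x 190 mm field of view and imaged
with a 3-D spoiled gradient-recalled echo (SPGR) sequence.  Signal per tube
follows the closed-form SPGR steady state

    S = PD * sin(a) * (1 - E1) / (1 - cos(a) * E1) * exp(-TE / T2*),
    E1 = exp(-TR / T1),

so flip angle, TR and field strength re-rank tube intensities the way they do
on a scanner.  Noise is Rician: independent complex Gaussian noise is added
per excitation, magnitudes are taken, and the NEX magnitude images are
averaged, which reproduces both the 1/sqrt(NEX) noise-SD law in the
high-SNR regime and the positive Rayleigh background floor.

Platform differences are modeled as reconstruction-filter differences (a
Gaussian post-filter of configurable FWHM plus an intensity-scale gain), and
3 T is modeled as a x2 signal gain at fixed noise.  Slices within a series
share geometry up to a small rigid per-slice position jitter emulating
repositioning across repeat sessions; setting ``sigma_base = 0`` disables
every stochastic component and yields a bit-identical noiseless series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .types import PLATFORM_MANUFACTURER, AcquisitionParams, ImageSlice

__all__ = [
    "PhantomConfig",
    "NoiseModel",
    "GeometryError",
    "render_phantom_geometry",
    "spgr_signal",
    "simulate_series",
    "write_dicom_series",
]


class GeometryError(ValueError):
    """Raised when tube circles overlap or leave the field of view."""


def _ring_layout(n_gel: int) -> List[Tuple[float, float]]:
    """Default circle packing: Gd tube at center, gel tubes on rings.

    Rings of capacity 6, 12, 18 at radii 28, 56, 84 mm keep 25 mm tubes
    pairwise disjoint (minimum center spacing 28 mm) for the default count.
    Returns gel-tube centers only, in (row_mm, col_mm) relative to FOV center.
    """
    centers: List[Tuple[float, float]] = []
    ring_caps = (6, 12, 18)
    ring_radii = (28.0, 56.0, 84.0)
    remaining = n_gel
    for cap, radius in zip(ring_caps, ring_radii):
        k = min(cap, remaining)
        for i in range(k):
            theta = 2.0 * math.pi * i / cap
            centers.append((radius * math.sin(theta), radius * math.cos(theta)))
        remaining -= k
        if remaining == 0:
            break
    if remaining > 0:
        raise GeometryError(
            f"ring layout supports at most {sum(ring_caps)} gel tubes, got {n_gel}"
        )
    return centers


def _default_t1s(n_gel: int) -> np.ndarray:
    """Log-spaced T1 ladder, 200-2000 ms, plus 686 ms for the Gd tube.

    686 ms is the T1 of 0.25 mM Gd-DTPA in water at 1.5 T from
    R1 = 1/3.0 s^-1 + 4.5 (mM s)^-1 * 0.25 mM.
    """
    gel = np.geomspace(200.0, 2000.0, n_gel) if n_gel else np.empty(0)
    return np.append(gel, 686.0)


@dataclass
class PhantomConfig:
    """Geometry and relaxometry of the synthetic phantom.

    Tubes are indexed 1..n_gel_tubes (gel) then n_gel_tubes+1 (Gd); per-tube
    arrays follow that order.  ``layout`` holds tube-center coordinates in mm
    relative to the FOV center as (row, col) pairs, gel tubes first; ``None``
    selects the default concentric-ring packing.
    """

    n_gel_tubes: int = 18
    gel_tube_diameter: float = 25.0
    gd_tube_diameter: float = 20.0
    tube_T1s: Optional[Sequence[float]] = None
    tube_T2stars: Optional[Sequence[float]] = None
    proton_densities: Optional[Sequence[float]] = None
    background_value: float = 0.0
    field_of_view: Tuple[float, float] = (240.0, 190.0)  # mm along (rows, cols)
    layout: Optional[Sequence[Tuple[float, float]]] = None

    @property
    def n_tubes(self) -> int:
        return self.n_gel_tubes + 1

    def centers(self) -> List[Tuple[float, float]]:
        if self.layout is not None:
            out = [tuple(map(float, c)) for c in self.layout]
            if len(out) != self.n_tubes:
                raise GeometryError(
                    f"layout has {len(out)} centers for {self.n_tubes} tubes"
                )
            return out
        return _ring_layout(self.n_gel_tubes) + [(0.0, 0.0)]

    def radii(self) -> np.ndarray:
        return np.array(
            [self.gel_tube_diameter / 2.0] * self.n_gel_tubes
            + [self.gd_tube_diameter / 2.0]
        )

    def t1s(self) -> np.ndarray:
        if self.tube_T1s is not None:
            return np.asarray(self.tube_T1s, dtype=float)
        return _default_t1s(self.n_gel_tubes)

    def t2stars(self) -> np.ndarray:
        if self.tube_T2stars is not None:
            return np.asarray(self.tube_T2stars, dtype=float)
        # Gels spread 40-100 ms; Gd tube shortened to 60 ms.
        gel = np.linspace(40.0, 100.0, self.n_gel_tubes) if self.n_gel_tubes else np.empty(0)
        return np.append(gel, 60.0)

    def pds(self) -> np.ndarray:
        if self.proton_densities is not None:
            return np.asarray(self.proton_densities, dtype=float)
        return np.full(self.n_tubes, 10000.0)

    def validate(self) -> None:
        if self.gel_tube_diameter <= 0 or self.gd_tube_diameter <= 0:
            raise GeometryError("tube diameters must be positive")
        if self.n_gel_tubes < 0:
            raise GeometryError("n_gel_tubes must be >= 0")
        for arr, name in ((self.t1s(), "tube_T1s"), (self.t2stars(), "tube_T2stars"),
                          (self.pds(), "proton_densities")):
            if len(arr) != self.n_tubes:
                raise GeometryError(f"{name} must have {self.n_tubes} entries, got {len(arr)}")
            if np.any(np.asarray(arr) <= 0):
                raise GeometryError(f"{name} entries must be positive")
        centers = self.centers()
        radii = self.radii()
        half = (self.field_of_view[0] / 2.0, self.field_of_view[1] / 2.0)
        for idx, ((cr, cc), r) in enumerate(zip(centers, radii), start=1):
            if abs(cr) + r > half[0] or abs(cc) + r > half[1]:
                raise GeometryError(f"tube {idx} exceeds the field of view")
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                d = math.hypot(centers[i][0] - centers[j][0], centers[i][1] - centers[j][1])
                if d < radii[i] + radii[j]:
                    raise GeometryError(f"tubes {i + 1} and {j + 1} overlap")


@dataclass
class NoiseModel:
    """Stochastic acquisition model.

    sigma_base          : complex-noise SD per excitation (signal units) at the
                          reference field strength; 0 disables all randomness
    field_snr_gain      : signal multiplier applied at 3 T relative to 1.5 T
    platform_filter_fwhm: Gaussian post-filter FWHM in pixels for platform B
                          (platform A is unfiltered)
    platform_gain       : intensity-scale gain applied on platform B
    slice_jitter_mm     : SD of the rigid per-slice phantom-position jitter,
                          emulating repositioning across repeat sessions
    rng_seed            : seed for the single generator driving the series
    """

    sigma_base: float = 20.0
    field_snr_gain: float = 2.0
    platform_filter_fwhm: float = 1.2
    platform_gain: float = 1.1
    slice_jitter_mm: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_base < 0:
            raise ValueError("sigma_base must be >= 0")
        if self.platform_filter_fwhm < 0:
            raise ValueError("platform_filter_fwhm must be >= 0")
        if self.slice_jitter_mm < 0:
            raise ValueError("slice_jitter_mm must be >= 0")


def pixel_spacing(config: PhantomConfig, matrix: Tuple[int, int]) -> Tuple[float, float]:
    """Pixel spacing in mm implied by FOV / matrix, as (row, col)."""
    rows, cols = matrix
    return (config.field_of_view[0] / rows, config.field_of_view[1] / cols)


def render_phantom_geometry(
    config: PhantomConfig,
    matrix: Tuple[int, int],
    offset_mm: Tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Rasterize the phantom into an integer label image.

    Labels are 1..n_gel_tubes for gel tubes, n_gel_tubes+1 for the Gd tube,
    0 for background.  A pixel belongs to a tube when its center lies inside
    the tube circle.  ``offset_mm`` rigidly shifts all tube centers (used for
    per-slice position jitter).
    """
    config.validate()
    rows, cols = matrix
    if rows < 32 or cols < 32:
        raise ValueError(f"matrix must be at least 32 x 32, got {matrix}")
    dr, dc = pixel_spacing(config, matrix)
    # Pixel-center coordinates in mm relative to the FOV center.
    r_mm = (np.arange(rows) + 0.5) * dr - config.field_of_view[0] / 2.0
    c_mm = (np.arange(cols) + 0.5) * dc - config.field_of_view[1] / 2.0
    labels = np.zeros((rows, cols), dtype=np.int32)
    for idx, ((cr, cc), rad) in enumerate(zip(config.centers(), config.radii()), start=1):
        dr2 = (r_mm - (cr + offset_mm[0]))[:, None] ** 2
        dc2 = (c_mm - (cc + offset_mm[1]))[None, :] ** 2
        labels[dr2 + dc2 < rad * rad] = idx
    return labels


def spgr_signal(
    proton_density: float, T1: float, T2star: float, params: AcquisitionParams
) -> float:
    """Noiseless spoiled-gradient-echo steady-state signal."""
    if params.flip_angle is None or params.flip_angle <= 0:
        raise ValueError("flip_angle must be positive")
    if T1 <= 0 or T2star <= 0:
        raise ValueError("T1 and T2* must be positive")
    alpha = math.radians(params.flip_angle)
    e1 = math.exp(-params.tr / T1)
    s = (
        proton_density
        * math.sin(alpha)
        * (1.0 - e1)
        / (1.0 - math.cos(alpha) * e1)
        * math.exp(-params.te / T2star)
    )
    return float(s)


def _noiseless_image(
    config: PhantomConfig, params: AcquisitionParams, noise: NoiseModel,
    offset_mm: Tuple[float, float],
) -> np.ndarray:
    labels = render_phantom_geometry(config, params.matrix, offset_mm)
    t1s, t2s, pds = config.t1s(), config.t2stars(), config.pds()
    lut = np.empty(config.n_tubes + 1)
    lut[0] = config.background_value
    for k in range(config.n_tubes):
        lut[k + 1] = spgr_signal(pds[k], t1s[k], t2s[k], params)
    img = lut[labels]
    if params.field_strength is not None and params.field_strength >= 2.5:
        img = img * noise.field_snr_gain
    return img


def simulate_series(
    config: PhantomConfig, params: AcquisitionParams, noise: NoiseModel
) -> List[ImageSlice]:
    """Simulate one series of ``params.n_slices`` magnitude slices.

    Each slice is rendered at a jittered phantom position, corrupted with
    per-excitation complex Gaussian noise, magnitude-detected, averaged over
    NEX excitations, platform-filtered, and quantized to 16-bit integers.
    Fully reproducible from ``noise.rng_seed``.
    """
    config.validate()
    rng = np.random.default_rng(noise.rng_seed)
    spacing = pixel_spacing(config, params.matrix)
    series_id = (
        f"sim-{params.field_strength}T-{params.platform}"
        f"-fa{params.flip_angle:g}-nex{params.nex}-seed{noise.rng_seed}"
    )
    stochastic = noise.sigma_base > 0
    slices: List[ImageSlice] = []
    base_img: Optional[np.ndarray] = None
    for k in range(params.n_slices):
        if stochastic and noise.slice_jitter_mm > 0:
            offset = tuple(rng.normal(0.0, noise.slice_jitter_mm, size=2))
            img = _noiseless_image(config, params, noise, offset)
        else:
            if base_img is None:
                base_img = _noiseless_image(config, params, noise, (0.0, 0.0))
            img = base_img
        if stochastic:
            acc = np.zeros_like(img)
            for _ in range(params.nex):
                re = img + rng.normal(0.0, noise.sigma_base, img.shape)
                im = rng.normal(0.0, noise.sigma_base, img.shape)
                acc += np.hypot(re, im)
            img = acc / params.nex
        if params.platform == "B":
            if noise.platform_filter_fwhm > 0:
                from scipy.ndimage import gaussian_filter

                img = gaussian_filter(img, noise.platform_filter_fwhm / 2.3548)
            img = img * noise.platform_gain
        pixels = np.rint(np.clip(img, 0, 65535)).astype(np.uint16)
        slices.append(
            ImageSlice(
                pixels=pixels,
                pixel_spacing=spacing,
                params=params,
                series_id=series_id,
                instance_index=k + 1,
            )
        )
    return slices


def write_dicom_series(
    slices: Sequence[ImageSlice], params: AcquisitionParams, directory
) -> List[Path]:
    """Write one DICOM file per slice; returns the written paths.

    Tags cover everything ``dicom_io.read_series`` needs to round-trip pixels
    and acquisition parameters: pixel data (16-bit), pixel spacing, slice
    thickness, flip angle, TR, TE, NEX, field strength, and manufacturer.
    """
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    if not slices:
        raise ValueError("slices must be nonempty")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    paths: List[Path] = []
    for s in slices:
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.MRImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\x00" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.SeriesDescription = s.series_id
        ds.Modality = "MR"
        ds.Manufacturer = PLATFORM_MANUFACTURER.get(params.platform, str(params.platform))
        ds.MagneticFieldStrength = params.field_strength
        ds.FlipAngle = params.flip_angle
        ds.RepetitionTime = params.tr
        ds.EchoTime = params.te
        ds.NumberOfAverages = params.nex
        ds.SliceThickness = params.slice_thickness
        ds.InstanceNumber = s.instance_index
        ds.PixelSpacing = [f"{s.pixel_spacing[0]:.6f}", f"{s.pixel_spacing[1]:.6f}"]
        ds.Rows, ds.Columns = s.pixels.shape
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = np.ascontiguousarray(s.pixels, dtype=np.uint16).tobytes()
        path = directory / f"MR_{s.instance_index:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths
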