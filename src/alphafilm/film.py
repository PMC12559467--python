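"""Film-scan reading and normalized pixel values.

Scans are 48-bit RGB TIFFs (16 bits per channel) from a flatbed scanner at
127 dpi. The response variable is the normalized pixel value of the green
channel,

    PVnorm = PV_background / PV_irradiated - 1,

computed from 5x5-pixel (1 x 1 mm^2 at 127 dpi) regions of interest on the
pre-irradiation and post-irradiation scans of the same film piece.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import tifffile

__all__ = [
    "FilmScan",
    "PVMeasurement",
    "read_scan",
    "write_scan",
    "extract_roi",
    "pv_norm",
    "find_footprint_center",
    "combine_triplicate",
    "DEFAULT_DPI",
]

log = logging.getLogger(__name__)

DEFAULT_DPI = 127.0


class ScanFormatError(ValueError):
    """Input is not an RGB TIFF of the expected kind."""


@dataclass
class FilmScan:
    """A scanner image: (rows, cols, 3) uint16 plus the scan resolution."""

    pixels: np.ndarray
    dpi: float = DEFAULT_DPI
    provenance: str = "background"  # "background" | "irradiated"

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ScanFormatError("expected an RGB image (rows x cols x 3)")
        if self.pixels.dtype != np.uint16:
            raise ScanFormatError("expected 16-bit-per-channel pixel data")
        if self.dpi <= 0:
            raise ScanFormatError("dpi must be > 0")

    @property
    def pixel_pitch_mm(self) -> float:
        return 25.4 / self.dpi

    @property
    def green(self) -> np.ndarray:
        return self.pixels[:, :, 1].astype(float)


@dataclass(frozen=True)
class PVMeasurement:
    """Green-channel ROI statistics of a background/irradiated scan pair and
    the derived normalized pixel value with its 1-sigma uncertainty."""

    pv_background: float
    pv_irradiated: float
    sigma_background: float
    sigma_irradiated: float
    pv_norm: float
    sigma_pv_norm: float


def read_scan(path, provenance: str = "background") -> FilmScan:
    """Read an RGB TIFF scan; dpi from the TIFF resolution tags (127 if absent)."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        arr = page.asarray()
        dpi = None
        tags = page.tags
        if "XResolution" in tags:
            num, den = tags["XResolution"].value
            unit = tags.get("ResolutionUnit")
            if den and (unit is None or getattr(unit.value, "value", unit.value) in (2, 1)):
                dpi = num / den
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ScanFormatError(f"{path}: not an RGB TIFF")
    if arr.dtype != np.uint16:
        raise ScanFormatError(f"{path}: expected 16-bit channels, got {arr.dtype}")
    if dpi is None or dpi <= 0:
        log.info("%s: no resolution metadata, assuming %g dpi", path, DEFAULT_DPI)
        dpi = DEFAULT_DPI
    return FilmScan(pixels=arr, dpi=float(dpi), provenance=provenance)


def write_scan(path, scan: FilmScan) -> None:
    """Write a FilmScan as an RGB TIFF with resolution metadata."""
    tifffile.imwrite(
        path,
        scan.pixels,
        photometric="rgb",
        resolution=(scan.dpi, scan.dpi),
        resolutionunit="INCH",
    )


def extract_roi(
    scan: FilmScan, center_px: tuple[int, int], size: int = 5
) -> tuple[float, float]:
    """Mean and sample standard deviation of the green channel in a
    ``size x size`` window centered on ``center_px`` = (row, col)."""
    row, col = center_px
    half = size // 2
    r0, r1 = row - half, row - half + size
    c0, c1 = col - half, col - half + size
    if r0 < 0 or c0 < 0 or r1 > scan.pixels.shape[0] or c1 > scan.pixels.shape[1]:
        raise ValueError(f"ROI at {center_px} (size {size}) outside the image")
    window = scan.green[r0:r1, c0:c1]
    return float(window.mean()), float(window.std(ddof=1))


def pv_norm(
    pv_bg: float, sigma_bg: float, pv_irr: float, sigma_irr: float
) -> PVMeasurement:
    """Normalized pixel value PV_bg/PV_irr - 1 with first-order error
    propagation.

    A brighter irradiated ROI than background (negative PVnorm) is flagged
    with a warning but not fatal: it occurs for unexposed film at noise level.
    """
    if pv_irr == 0:
        raise ZeroDivisionError("PV_irradiated must be nonzero")
    ratio = pv_bg / pv_irr
    value = ratio - 1.0
    sigma = abs(ratio) * np.sqrt((sigma_bg / pv_bg) ** 2 + (sigma_irr / pv_irr) ** 2)
    if pv_irr > pv_bg:
        warnings.warn(
            "irradiated ROI brighter than background (PVnorm < 0): "
            "film darkening expected",
            stacklevel=2,
        )
    return PVMeasurement(
        pv_background=pv_bg,
        pv_irradiated=pv_irr,
        sigma_background=sigma_bg,
        sigma_irradiated=sigma_irr,
        pv_norm=value,
        sigma_pv_norm=float(sigma),
    )


def find_footprint_center(
    background: FilmScan, irradiated: FilmScan, n_sigma: float = 3.0
) -> tuple[int, int]:
    """Centroid (row, col) of the darkened source footprint.

    Pixels darker than (background mean - n_sigma * background sd) in the
    green channel are taken as the footprint; falls back to the darkest
    pixel if the threshold selects nothing.
    """
    bg = background.green
    thresh = bg.mean() - n_sigma * bg.std(ddof=1)
    dark = irradiated.green < thresh
    if not dark.any():
        idx = np.unravel_index(np.argmin(irradiated.green), irradiated.green.shape)
        return int(idx[0]), int(idx[1])
    rows, cols = np.nonzero(dark)
    return int(round(rows.mean())), int(round(cols.mean()))


def measure_pair(
    background: FilmScan,
    irradiated: FilmScan,
    center_px: tuple[int, int] | None = None,
    size: int = 5,
) -> PVMeasurement:
    """PVnorm of a background/irradiated pair at the footprint center (or a
    manual center override), using the same ROI on both scans."""
    if center_px is None:
        center_px = find_footprint_center(background, irradiated)
    pv_bg, sd_bg = extract_roi(background, center_px, size)
    pv_irr, sd_irr = extract_roi(irradiated, center_px, size)
    return pv_norm(pv_bg, sd_bg, pv_irr, sd_irr)


def combine_triplicate(measurements: list[PVMeasurement]) -> tuple[float, float]:
    """Combine replicate PVnorm values: unweighted mean; sigma is the larger
    of the propagated per-measurement sigma (of the mean) and the sample sd
    of the replicates."""
    vals = np.array([m.pv_norm for m in measurements])
    sigs = np.array([m.sigma_pv_norm for m in measurements])
    mean = float(vals.mean())
    propagated = float(np.sqrt(np.sum(sigs**2)) / len(sigs))
    sample_sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return mean, max(propagated, sample_sd)
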