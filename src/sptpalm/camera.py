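"""Movie, calibration, mask and table I/O plus photon conversion.

Conventions used throughout the package:

* The continuous position of the centre of pixel ``(row i, col j)`` is
  ``x = (j + 0.5) * pixel_size_nm``, ``y = (i + 0.5) * pixel_size_nm``,
  with the origin at the top-left corner of the top-left pixel.  All
  coordinates in tables are nanometres.
* Frames are 1-based in every table; arrays are 0-based internally.
* TIFF metadata is never trusted: pixel size and frame interval always
  come from the caller / parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "MovieStack",
    "CameraCalibration",
    "RegionMask",
    "FormatError",
    "read_movie_stack",
    "write_movie_stack",
    "calibrate_camera",
    "adu_to_photons",
    "read_mask",
    "write_mask",
    "LOCALIZATION_COLUMNS",
    "write_localization_table",
    "read_localization_table",
]


class FormatError(ValueError):
    """Raised when an on-disk artifact does not match the expected format."""


@dataclass
class MovieStack:
    """A raw acquisition: camera counts plus the two acquisition constants."""

    frames: np.ndarray  # (n_frames, height, width), ADU
    pixel_size_nm: float
    frame_interval_s: float
    source_path: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise FormatError("frames must be a (n_frames, h, w) array with >=1 frame")
        if self.pixel_size_nm <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel_size_nm and frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        return int(self.frames.shape[1]), int(self.frames.shape[2])


@dataclass
class CameraCalibration:
    """Per-pixel (or scalar) dark offset/variance plus gain and QE."""

    offset: np.ndarray | float
    variance: np.ndarray | float
    e_per_adu: float
    qe: float = 1.0

    def __post_init__(self) -> None:
        if self.e_per_adu <= 0:
            raise ValueError("e_per_adu must be positive")
        if not (0 < self.qe <= 1):
            raise ValueError("qe must be in (0, 1]")
        if np.any(np.asarray(self.variance) < 0):
            raise ValueError("variance must be non-negative")

    def maps_for(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Offset and variance broadcast to a full-frame shape."""
        off = np.broadcast_to(np.asarray(self.offset, dtype=float), shape)
        var = np.broadcast_to(np.asarray(self.variance, dtype=float), shape)
        return off, var


@dataclass
class RegionMask:
    """Boolean include-mask aligned to the movie pixel grid."""

    include: np.ndarray

    def __post_init__(self) -> None:
        self.include = np.asarray(self.include).astype(bool)
        if self.include.ndim != 2:
            raise FormatError("mask must be 2-D")


def read_movie_stack(
    path: str | Path, pixel_size_nm: float, frame_interval_s: float
) -> MovieStack:
    """Read a single- or multi-page grayscale TIFF as a :class:`MovieStack`.

    Metadata comes from the arguments only; RGB pages or pages with
    mismatched shapes raise :class:`FormatError`.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            pages = [p.asarray() for p in tif.pages]
    except (OSError, tifffile.TiffFileError) as exc:
        raise OSError(f"could not read TIFF {path}: {exc}") from exc
    if not pages:
        raise FormatError(f"{path}: no image pages")
    shapes = {p.shape for p in pages}
    if len(shapes) != 1:
        raise FormatError(f"{path}: mixed page shapes {shapes}")
    if pages[0].ndim != 2:
        raise FormatError(f"{path}: pages are not grayscale 2-D (shape {pages[0].shape})")
    return MovieStack(
        frames=np.stack(pages),
        pixel_size_nm=pixel_size_nm,
        frame_interval_s=frame_interval_s,
        source_path=str(path),
    )


def write_movie_stack(movie: MovieStack, path: str | Path) -> None:
    tifffile.imwrite(Path(path), np.asarray(movie.frames), photometric="minisblack")


def calibrate_camera(
    dark_stack: MovieStack, e_per_adu: float, qe: float = 1.0
) -> CameraCalibration:
    """Per-pixel temporal mean/variance (unbiased) of a dark-image series."""
    if dark_stack.n_frames < 2:
        raise ValueError("camera calibration needs >=2 dark frames")
    frames = dark_stack.frames.astype(float)
    return CameraCalibration(
        offset=frames.mean(axis=0),
        variance=frames.var(axis=0, ddof=1),
        e_per_adu=e_per_adu,
        qe=qe,
    )


def adu_to_photons(
    roi: np.ndarray,
    calib: CameraCalibration,
    roi_origin: tuple[int, int] = (0, 0),
    clip_negative: bool = False,
) -> np.ndarray:
    """Convert camera counts to photons: ``(ADU - offset) * e_per_adu / qe``.

    ``roi_origin`` is the (row, col) of the ROI's top-left pixel in the
    frame, used to slice per-pixel calibration maps.  ``clip_negative``
    floors the result at zero for display; the fitter always receives the
    unclipped values.
    """
    roi = np.asarray(roi, dtype=float)
    offset = np.asarray(calib.offset, dtype=float)
    if offset.ndim == 2:
        r0, c0 = roi_origin
        if r0 < 0 or c0 < 0 or r0 + roi.shape[0] > offset.shape[0] or c0 + roi.shape[1] > offset.shape[1]:
            raise ValueError("ROI does not fit inside the calibration maps")
        offset = offset[r0 : r0 + roi.shape[0], c0 : c0 + roi.shape[1]]
    elif offset.ndim != 0:
        raise ValueError("offset map must be scalar or 2-D")
    photons = (roi - offset) * calib.e_per_adu / calib.qe
    if clip_negative:
        photons = np.clip(photons, 0.0, None)
    return photons


def read_mask(path: str | Path) -> RegionMask:
    arr = tifffile.imread(Path(path))
    if arr.ndim != 2:
        raise FormatError("mask TIFF must be a single 2-D page")
    return RegionMask(include=arr > 0)


def write_mask(mask: RegionMask, path: str | Path) -> None:
    tifffile.imwrite(
        Path(path), np.where(mask.include, 255, 0).astype(np.uint8),
        photometric="minisblack",
    )


# ---------------------------------------------------------------------------
# Localization tables

LOCALIZATION_COLUMNS = [
    "frame",
    "x_nm",
    "y_nm",
    "sigma_nm",
    "photons",
    "background_photons",
    "precision_nm",
    "converged",
]


def write_localization_table(locs, path: str | Path) -> None:
    """CSV with the fixed header; frames 1-based, coordinates in nm."""
    df = locs.df if hasattr(locs, "df") else locs
    out = pd.DataFrame({c: df[c] for c in LOCALIZATION_COLUMNS})
    out["frame"] = out["frame"].astype(int)
    out["converged"] = out["converged"].astype(bool)
    out.to_csv(Path(path), index=False, float_format="%.10g")


def read_localization_table(path: str | Path):
    from .localize import LocalizationSet

    df = pd.read_csv(Path(path))
    missing = [c for c in LOCALIZATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"localization table missing columns: {missing}")
    df = df[LOCALIZATION_COLUMNS].copy()
    df["frame"] = df["frame"].astype(int)
    df["converged"] = df["converged"].astype(bool)
    return LocalizationSet(df=df, source=str(path))
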