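"""Reading, writing and normalization of EPID portal-image frames.

The imager considered here is the amorphous-silicon panel of a gimballed
tracking linac: source-detector distance 221.2 cm, a 1024 x 1024 matrix
whose pixel pitch de-magnifies to 0.18 mm at the isocenter plane
(100 cm), and a maximum cine frame rate of 2 Hz.

Grayscale convention
--------------------
Frames are normalized to [0, 1] with **0 = white (high detector signal,
open beam)** and **1 = black (low signal: blocked by MLC, or attenuated
by an implanted marker)**.  Raw detector counts are min-max scaled and
then inverted; the inversion is a dialect switch for panels with the
opposite response.

Pixel coordinates are 0-based ``(row, col)``.  The row axis is the tilt
direction and the column axis the pan direction; both gimbal axes
project to fixed orthogonal axes on the imager plane.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image as PILImage

from .errors import (
    DegenerateImageError,
    FormatError,
    InconsistencyError,
    NoFramesError,
)

__all__ = [
    "GeometryConfig",
    "RawDialect",
    "EpidImage",
    "SeriesMetadata",
    "normalize_counts",
    "read_raw_frame",
    "write_raw_frame",
    "read_image_series",
    "write_offsets_csv",
    "OFFSETS_CSV_COLUMNS",
]


@dataclass(frozen=True)
class GeometryConfig:
    """Imaging geometry of the tracking linac's portal imager.

    Parameters
    ----------
    sdd_cm
        Source-detector distance in cm (221.2 for the panel modelled here).
    pixel_mm_at_iso
        Pixel pitch in mm after de-magnification to the isocenter plane
        (detector pitch x 100 / SDD).  1 px = 0.18 mm by default.
    frame_rate_hz
        Cine acquisition rate in Hz.
    matrix_size
        Detector matrix dimension in pixels (square).
    """

    sdd_cm: float = 221.2
    pixel_mm_at_iso: float = 0.18
    frame_rate_hz: float = 2.0
    matrix_size: int = 1024

    def __post_init__(self) -> None:
        for name in ("sdd_cm", "pixel_mm_at_iso", "frame_rate_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.matrix_size < 64:
            raise ValueError("matrix_size must be >= 64")


@dataclass(frozen=True)
class RawDialect:
    """Binary layout of a vendor ``.raw`` frame.

    The vendor format is not publicly documented, so every aspect is
    configurable.  The default is headerless 16-bit unsigned
    little-endian, row-major.

    ``invert=True`` applies the white=0 / black=1 polarity flip after
    min-max normalization (high counts = open beam = white).
    """

    bytes_per_pixel: int = 2
    header_bytes: int = 0
    little_endian: bool = True
    invert: bool = True

    @property
    def dtype(self) -> np.dtype:
        order = "<" if self.little_endian else ">"
        return np.dtype(f"{order}u{self.bytes_per_pixel}")

    @property
    def max_count(self) -> int:
        return 2 ** (8 * self.bytes_per_pixel) - 1


@dataclass
class EpidImage:
    """One normalized grayscale portal frame.

    ``pixels`` lie in [0, 1] (0 = white / open beam, 1 = black), the
    grid is square, ``index`` is 1-based within its series and
    ``time_s = (index - 1) / frame_rate``.  ``valid`` is False for
    frames that could not be normalized (flagged, not dropped, so the
    series keeps its acquisition indices).
    """

    pixels: np.ndarray
    index: int = 1
    time_s: float = 0.0
    valid: bool = True

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("pixels must be a square 2D grid")
        if self.index < 1:
            raise ValueError("index must be >= 1")
        if self.valid and (self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9):
            raise ValueError("pixel values must lie in [0, 1]")

    @property
    def matrix_size(self) -> int:
        return self.pixels.shape[0]


@dataclass
class SeriesMetadata:
    """Identity and acquisition context of one EPID cine series."""

    patient_id: str = "phantom"
    fraction_id: str = "1"
    field_id: str = "1"
    expected_markers: int = 3
    geometry: GeometryConfig = field(default_factory=GeometryConfig)

    def __post_init__(self) -> None:
        if self.expected_markers < 1:
            raise ValueError("expected_markers must be >= 1")


def normalize_counts(counts: np.ndarray, invert: bool = True) -> np.ndarray:
    """Min-max normalize raw counts to [0, 1]; optionally flip polarity.

    With ``invert=True`` high counts (open beam) map to 0 (white) and
    low counts (blocked / marker shadow) to 1 (black).

    Raises
    ------
    DegenerateImageError
        If the frame is all-constant (no contrast to normalize).
    """
    counts = np.asarray(counts, dtype=np.float64)
    lo, hi = counts.min(), counts.max()
    if hi == lo:
        raise DegenerateImageError("all-constant frame: no contrast to normalize")
    norm = (counts - lo) / (hi - lo)
    return 1.0 - norm if invert else norm


def read_raw_frame(
    path: str | os.PathLike,
    dialect: RawDialect = RawDialect(),
    matrix_size: int = 1024,
    *,
    index: int = 1,
    frame_rate_hz: float = 2.0,
) -> EpidImage:
    """Read one headered/headerless binary frame and normalize it.

    The file size must equal ``header_bytes + matrix_size**2 *
    bytes_per_pixel`` exactly; a mismatch raises :class:`FormatError`
    naming the expected and actual byte counts.
    """
    path = Path(path)
    expected = dialect.header_bytes + matrix_size * matrix_size * dialect.bytes_per_pixel
    actual = path.stat().st_size
    if actual != expected:
        raise FormatError(
            f"{path.name}: expected {expected} bytes "
            f"(header {dialect.header_bytes} + {matrix_size}^2 x "
            f"{dialect.bytes_per_pixel}), got {actual}"
        )
    raw = path.read_bytes()[dialect.header_bytes :]
    counts = np.frombuffer(raw, dtype=dialect.dtype).reshape(matrix_size, matrix_size)
    pixels = normalize_counts(counts, invert=dialect.invert)
    return EpidImage(pixels, index=index, time_s=(index - 1) / frame_rate_hz)


def write_raw_frame(
    image: EpidImage, path: str | os.PathLike, dialect: RawDialect = RawDialect()
) -> None:
    """Write a normalized frame back to raw counts (inverse of the reader).

    Quantizes to the dialect's bit depth, so a read-back agrees with the
    original within ``1 / max_count``.
    """
    gray = image.pixels
    counts = (1.0 - gray) if dialect.invert else gray
    counts = np.round(counts * dialect.max_count).astype(dialect.dtype)
    with open(path, "wb") as fh:
        if dialect.header_bytes:
            fh.write(b"\x00" * dialect.header_bytes)
        fh.write(counts.tobytes())


_IMAGE_SUFFIXES = (".raw", ".tif", ".tiff", ".png")


def _read_any_frame(
    path: Path, dialect: RawDialect, matrix_size: int
) -> np.ndarray:
    """Return normalized pixels for one frame file of any supported format."""
    suffix = path.suffix.lower()
    if suffix == ".raw":
        expected = dialect.header_bytes + matrix_size**2 * dialect.bytes_per_pixel
        actual = path.stat().st_size
        if actual != expected:
            raise FormatError(
                f"{path.name}: expected {expected} bytes, got {actual}"
            )
        raw = path.read_bytes()[dialect.header_bytes :]
        counts = np.frombuffer(raw, dtype=dialect.dtype).reshape(
            matrix_size, matrix_size
        )
    elif suffix in (".tif", ".tiff"):
        counts = tifffile.imread(path)
    elif suffix == ".png":
        counts = np.asarray(PILImage.open(path))
    else:
        raise FormatError(f"unsupported frame format: {path.name}")
    return normalize_counts(counts, invert=dialect.invert)


def _resolve_frame_paths(dir_or_manifest: Path) -> list[Path]:
    if dir_or_manifest.is_dir():
        paths = sorted(
            p
            for p in dir_or_manifest.iterdir()
            if p.suffix.lower() in _IMAGE_SUFFIXES
        )
    elif dir_or_manifest.suffix.lower() in (".yaml", ".yml"):
        doc = yaml.safe_load(dir_or_manifest.read_text())
        entries = doc["frames"] if isinstance(doc, dict) else doc
        paths = [dir_or_manifest.parent / str(e) for e in entries]
    else:  # plain-text manifest, one path per line, order is authoritative
        lines = [
            ln.strip()
            for ln in dir_or_manifest.read_text().splitlines()
            if ln.strip() and not ln.strip().startswith("#")
        ]
        paths = [dir_or_manifest.parent / ln for ln in lines]
    return paths


def read_image_series(
    dir_or_manifest: str | os.PathLike,
    metadata: SeriesMetadata,
    dialect: RawDialect = RawDialect(),
    *,
    on_error: str = "raise",
) -> list[EpidImage]:
    """Read an ordered cine series from a directory or manifest.

    A directory is read in sorted filename order; a manifest (plain text
    or YAML list) is read in manifest order.  Indices are assigned
    1..N and ``time_s = (index - 1) / frame_rate``.

    ``on_error="flag"`` turns unreadable/degenerate frames into
    placeholder images with ``valid=False`` instead of aborting, so a
    corrupt frame mid-series is flagged and excluded downstream rather
    than killing the run.
    """
    if on_error not in ("raise", "flag"):
        raise ValueError("on_error must be 'raise' or 'flag'")
    paths = _resolve_frame_paths(Path(dir_or_manifest))
    if not paths:
        raise NoFramesError(f"no readable frames under {dir_or_manifest}")
    geometry = metadata.geometry
    images: list[EpidImage] = []
    shape: tuple[int, int] | None = None
    for i, p in enumerate(paths, start=1):
        t = (i - 1) / geometry.frame_rate_hz
        try:
            pixels = _read_any_frame(p, dialect, geometry.matrix_size)
        except (FormatError, DegenerateImageError, OSError):
            if on_error == "raise":
                raise
            size = shape[0] if shape else geometry.matrix_size
            img = EpidImage(np.zeros((size, size)), index=i, time_s=t, valid=False)
            images.append(img)
            continue
        if shape is None:
            shape = pixels.shape
        elif pixels.shape != shape:
            raise InconsistencyError(
                f"{p.name}: frame shape {pixels.shape} != series shape {shape}"
            )
        images.append(EpidImage(pixels, index=i, time_s=t))
    return images


#: Fixed header of the per-image offsets CSV.
OFFSETS_CSV_COLUMNS = [
    "patient_id",
    "fraction_id",
    "field_id",
    "index",
    "time_s",
    "n_markers",
    "pan_mm",
    "tilt_mm",
    "et_pan_mm",
    "et_tilt_mm",
    "et_2d_mm",
    "included",
]


def write_offsets_csv(series, path: str | os.PathLike) -> None:
    """Write one row per frame of a :class:`~epidtrack.tracking_analysis.TrackingSeries`.

    Excluded frames keep their row but carry empty E_T cells.
    """
    md = series.metadata
    rows = []
    for k, off in enumerate(series.offsets):
        rows.append(
            {
                "patient_id": md.patient_id,
                "fraction_id": md.fraction_id,
                "field_id": md.field_id,
                "index": off.index,
                "time_s": off.time_s,
                "n_markers": off.n_markers,
                "pan_mm": off.pan_mm if off.included else np.nan,
                "tilt_mm": off.tilt_mm if off.included else np.nan,
                "et_pan_mm": series.et_pan_mm[k],
                "et_tilt_mm": series.et_tilt_mm[k],
                "et_2d_mm": series.et_2d_mm[k],
                "included": off.included,
            }
        )
    df = pd.DataFrame(rows, columns=OFFSETS_CSV_COLUMNS)
    df.to_csv(path, index=False, float_format="%.5f")


def read_offsets_csv(path: str | os.PathLike) -> pd.DataFrame:
    """Read an offsets CSV written by :func:`write_offsets_csv`."""
    return pd.read_csv(path)
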