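"""Per-frame tracking offsets, the baseline-referenced tracking error E_T,
and per-field / per-patient statistics.

For each frame the *offset* is the displacement of the marker COM
relative to the aperture center, converted to mm at the isocenter plane
(1 px = 0.18 mm for the default geometry):

    pan_mm  = (com_col - center_col) * pixel_mm_at_iso
    tilt_mm = (com_row - center_row) * pixel_mm_at_iso

The tracking error of frame i is the absolute variation of that offset
relative to the series baseline (the first included frame — image #1
when it is usable):

    et_pan(i)  = |pan(i)  - pan(baseline)|
    et_tilt(i) = |tilt(i) - tilt(baseline)|
    et_2d(i)   = sqrt(et_pan(i)^2 + et_tilt(i)^2)

The 2D error is the Euclidean norm of the baseline-subtracted (pan,
tilt) pair, which guarantees the per-frame triangle bounds
max(et_pan, et_tilt) <= et_2d <= et_pan + et_tilt.  Baseline
subtraction makes E_T invariant to any constant offset shared by all
frames.  The baseline frame's zero contributes to every statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .epid_io import GeometryConfig, SeriesMetadata
from .errors import EmptySeriesError, InsufficientDataError

__all__ = [
    "FrameOffset",
    "TrackingSeries",
    "DirectionStats",
    "FieldStats",
    "frame_offset",
    "tracking_error_series",
    "field_stats",
    "patient_stats",
]

DIRECTIONS = ("pan", "tilt", "2d")


@dataclass
class FrameOffset:
    """Signed marker-COM-minus-aperture-center offset of one frame, in mm."""

    index: int
    pan_mm: float = np.nan
    tilt_mm: float = np.nan
    included: bool = True
    n_markers: int = 0
    time_s: float = 0.0
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if self.included and not (
            np.isfinite(self.pan_mm) and np.isfinite(self.tilt_mm)
        ):
            raise ValueError("included frames must carry finite offsets")


@dataclass
class TrackingSeries:
    """Per-field time series of offsets and baseline-referenced E_T.

    The E_T arrays are aligned with ``offsets`` and hold NaN for
    excluded frames.  ``baseline_index`` is the acquisition index of
    the baseline frame, whose E_T is zero in every direction.
    """

    metadata: SeriesMetadata
    offsets: list[FrameOffset]
    baseline_index: int
    et_pan_mm: np.ndarray
    et_tilt_mm: np.ndarray
    et_2d_mm: np.ndarray

    def included_et(self, direction: str) -> np.ndarray:
        """E_T values of the included frames for 'pan', 'tilt' or '2d'."""
        arr = {
            "pan": self.et_pan_mm,
            "tilt": self.et_tilt_mm,
            "2d": self.et_2d_mm,
        }[direction]
        return arr[np.isfinite(arr)]

    @property
    def n_collected(self) -> int:
        return len(self.offsets)

    @property
    def n_analyzed(self) -> int:
        return int(sum(o.included for o in self.offsets))


@dataclass(frozen=True)
class DirectionStats:
    mean_mm: float
    sd_mm: float
    p90_mm: float
    max_mm: float


@dataclass(frozen=True)
class FieldStats:
    """Summary of E_T over the included frames of one field (or pool)."""

    pan: DirectionStats
    tilt: DirectionStats
    d2: DirectionStats
    n_analyzed: int
    n_collected: int

    @property
    def detection_rate(self) -> float:
        return self.n_analyzed / self.n_collected if self.n_collected else 0.0

    def direction(self, name: str) -> DirectionStats:
        return {"pan": self.pan, "tilt": self.tilt, "2d": self.d2}[name]


def frame_offset(
    aperture_center: tuple[float, float],
    com: tuple[float, float],
    geometry: GeometryConfig = GeometryConfig(),
    *,
    index: int = 1,
    n_markers: int = 0,
    time_s: float = 0.0,
) -> FrameOffset:
    """Convert a COM/aperture-center pair to a signed mm offset.

    Pan is along columns, tilt along rows; mm at isocenter via the
    geometry's pixel pitch.
    """
    s = geometry.pixel_mm_at_iso
    return FrameOffset(
        index=index,
        pan_mm=(com[1] - aperture_center[1]) * s,
        tilt_mm=(com[0] - aperture_center[0]) * s,
        included=True,
        n_markers=n_markers,
        time_s=time_s,
    )


def tracking_error_series(
    offsets: list[FrameOffset], metadata: SeriesMetadata | None = None
) -> TrackingSeries:
    """Compute baseline-referenced E_T for a list of per-frame offsets.

    The baseline is the first *included* frame (image #1 whenever its
    markers were detectable).  Excluded frames carry NaN.

    Raises
    ------
    EmptySeriesError
        If no frame is included.
    """
    included = [o for o in offsets if o.included]
    if not included:
        raise EmptySeriesError("series has no included frames")
    base = included[0]
    n = len(offsets)
    et_pan = np.full(n, np.nan)
    et_tilt = np.full(n, np.nan)
    et_2d = np.full(n, np.nan)
    for k, o in enumerate(offsets):
        if not o.included:
            continue
        dp = abs(o.pan_mm - base.pan_mm)
        dt = abs(o.tilt_mm - base.tilt_mm)
        et_pan[k] = dp
        et_tilt[k] = dt
        et_2d[k] = float(np.hypot(dp, dt))
    return TrackingSeries(
        metadata=metadata if metadata is not None else SeriesMetadata(),
        offsets=list(offsets),
        baseline_index=base.index,
        et_pan_mm=et_pan,
        et_tilt_mm=et_tilt,
        et_2d_mm=et_2d,
    )


def _direction_stats(values: np.ndarray) -> DirectionStats:
    return DirectionStats(
        mean_mm=float(values.mean()),
        sd_mm=float(values.std(ddof=1)),
        p90_mm=float(np.percentile(values, 90)),  # linear interpolation
        max_mm=float(values.max()),
    )


def field_stats(series: TrackingSeries) -> FieldStats:
    """Mean / SD / 90th percentile / max of E_T per direction for one field.

    The baseline frame's zero is part of the sample.  Requires at least
    two included frames (the sample SD is undefined otherwise).
    """
    vals = {d: series.included_et(d) for d in DIRECTIONS}
    if len(vals["pan"]) < 2:
        raise InsufficientDataError("need >= 2 included frames for field statistics")
    return FieldStats(
        pan=_direction_stats(vals["pan"]),
        tilt=_direction_stats(vals["tilt"]),
        d2=_direction_stats(vals["2d"]),
        n_analyzed=series.n_analyzed,
        n_collected=series.n_collected,
    )


def patient_stats(fields: list[TrackingSeries]) -> FieldStats:
    """Frame-weighted pool of E_T over all of a patient's fields/fractions.

    Concatenates the included frames of every series (each frame votes
    equally, fields are not averaged first) and summarizes the pool.

    Raises
    ------
    InsufficientDataError
        If fewer than two included frames exist in total.
    """
    if not fields:
        raise InsufficientDataError("no analyzed fields supplied")
    pools = {
        d: np.concatenate([s.included_et(d) for s in fields]) for d in DIRECTIONS
    }
    if len(pools["pan"]) < 2:
        raise InsufficientDataError("need >= 2 included frames across fields")
    return FieldStats(
        pan=_direction_stats(pools["pan"]),
        tilt=_direction_stats(pools["tilt"]),
        d2=_direction_stats(pools["2d"]),
        n_analyzed=int(sum(s.n_analyzed for s in fields)),
        n_collected=int(sum(s.n_collected for s in fields)),
    )
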