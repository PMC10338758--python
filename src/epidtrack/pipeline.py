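"""End-to-end per-frame analysis: frame -> aperture -> markers -> offset.

This is the glue the CLI and the tests drive: segment the radiation
field, trace its boundary, LoG-filter the frame, threshold and label
marker candidates inside the (eroded) aperture interior, filter them,
and convert the marker-COM-to-aperture-center displacement into a
tracking offset.  Frames where anything fails — no field, incomplete
marker set, degenerate image — are *flagged* excluded with a recorded
reason rather than dropped, so detection rates stay auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import RunConfig
from .epid_io import EpidImage, SeriesMetadata
from .errors import DegenerateContourError, NoFieldError
from .field_aperture import ApertureContour, segment_field, trace_boundary
from .marker_detection import filter_markers, label_candidates, markers_com
from .preprocessing import marker_response, response_threshold
from .tracking_analysis import (
    FrameOffset,
    TrackingSeries,
    frame_offset,
    tracking_error_series,
)

__all__ = ["FrameDiagnostics", "FrameResult", "analyze_frame", "analyze_series"]

logger = logging.getLogger(__name__)


@dataclass
class FrameDiagnostics:
    """Auditable per-frame detection record."""

    index: int
    threshold: float = float("nan")
    n_candidates: int = 0
    n_kept: int = 0
    exclusion_reason: str = ""


@dataclass
class FrameResult:
    offset: FrameOffset
    contour: ApertureContour | None
    marker_set: object | None
    diagnostics: FrameDiagnostics


def analyze_frame(
    image: EpidImage, metadata: SeriesMetadata, config: RunConfig | None = None
) -> FrameResult:
    """Run the full detection chain on one frame.

    Never raises for expected failure modes: the returned offset is
    flagged ``included=False`` with the exclusion reason in the
    diagnostics instead.
    """
    config = config or RunConfig(geometry=metadata.geometry)
    diag = FrameDiagnostics(index=image.index)

    def excluded(reason: str) -> FrameResult:
        diag.exclusion_reason = reason
        logger.info("frame %d excluded: %s", image.index, reason)
        off = FrameOffset(
            index=image.index,
            included=False,
            time_s=image.time_s,
            exclusion_reason=reason,
        )
        return FrameResult(off, None, None, diag)

    if not image.valid:
        return excluded("degenerate_image")

    try:
        mask = segment_field(
            image,
            edge_threshold=config.edge_threshold,
            min_field_area_px2=config.min_field_area_px2,
        )
        contour = trace_boundary(mask)
    except (NoFieldError, DegenerateContourError) as exc:
        return excluded(f"no_field: {exc}")

    response = marker_response(image, config.log_params)
    # Candidates must sit well inside the aperture: erosion suppresses
    # the LoG ridge along the field edge, and the same interior region
    # anchors the robust background estimate of the threshold.
    interior = ndimage.binary_erosion(
        contour.interior_mask, iterations=config.interior_erosion_px
    )
    cand_mask, thr = response_threshold(response, config.k_sigma, region=interior)
    diag.threshold = thr
    cand_mask &= interior

    blobs = label_candidates(cand_mask, response, connectivity=config.connectivity)
    diag.n_candidates = len(blobs)
    marker_set = filter_markers(
        blobs,
        contour,
        rules=config.marker_rules,
        expected_markers=metadata.expected_markers,
        geometry=metadata.geometry,
    )
    diag.n_kept = marker_set.n_detected
    logger.debug(
        "frame %d: thr=%.3g candidates=%d kept=%d",
        image.index,
        thr,
        diag.n_candidates,
        diag.n_kept,
    )

    required = metadata.expected_markers if config.marker_rules.require_complete else 1
    if marker_set.n_detected < required:
        reason = (
            "incomplete_detection"
            if marker_set.n_detected
            else "no_markers_detected"
        )
        res = excluded(reason)
        res.contour = contour  # keep for overlays even when excluded
        res.marker_set = marker_set
        return res

    off = frame_offset(
        contour.center_px,
        markers_com(marker_set),
        metadata.geometry,
        index=image.index,
        n_markers=marker_set.n_detected,
        time_s=image.time_s,
    )
    return FrameResult(off, contour, marker_set, diag)


def analyze_series(
    images: list[EpidImage],
    metadata: SeriesMetadata,
    config: RunConfig | None = None,
    *,
    collect_frames: bool = False,
) -> TrackingSeries | tuple[TrackingSeries, list[FrameResult]]:
    """Analyze a full cine series into a :class:`TrackingSeries`.

    With ``collect_frames=True`` also returns the per-frame results
    (contours, marker sets, diagnostics) for overlays and audit logs.
    """
    config = config or RunConfig(geometry=metadata.geometry)
    results = [analyze_frame(img, metadata, config) for img in images]
    series = tracking_error_series([r.offset for r in results], metadata)
    if collect_frames:
        return series, results
    return series
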