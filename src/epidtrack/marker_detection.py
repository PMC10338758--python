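"""Detection of implanted gold markers inside the MLC aperture.

Candidate blobs come from connected-component labeling of the
thresholded LoG response (8-connected by default).  Each blob carries
sub-pixel, response-weighted moments.  Plausibility filters then reject
noise specks (area), streaks (elongation) and blobs close enough to the
field edge that the MLC may partially occlude them; if more candidates
than implanted markers survive, the strongest by mean response are
kept.  The per-frame marker center-of-mass (COM) — the internal target
surrogate — is the *unweighted* mean of the surviving blob centroids,
so each marker votes equally regardless of how much anatomy overlies it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .epid_io import GeometryConfig
from .errors import UndefinedComError
from .field_aperture import ApertureContour

__all__ = [
    "MarkerBlob",
    "MarkerSet",
    "MarkerFilterRules",
    "label_candidates",
    "filter_markers",
    "markers_com",
]

_STRUCTURE_8 = np.ones((3, 3), dtype=int)
_STRUCTURE_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)


@dataclass
class MarkerBlob:
    """One connected candidate blob with response-weighted moments.

    ``elongation`` is the square root of the ratio of the principal
    second moments (major/minor axis ratio); 1 for an isotropic blob.
    """

    pixels: np.ndarray  # (n, 2) member (row, col) coordinates
    centroid_px: tuple[float, float]
    area_px2: int
    elongation: float
    mean_response: float

    def __post_init__(self) -> None:
        if self.area_px2 < 1:
            raise ValueError("blob must contain at least one pixel")
        if self.elongation < 1:
            raise ValueError("elongation is major/minor and must be >= 1")


@dataclass
class MarkerSet:
    """Surviving markers of one frame and their combined center-of-mass."""

    blobs: list[MarkerBlob]
    com_px: tuple[float, float] | None
    n_detected: int
    complete: bool

    def __post_init__(self) -> None:
        if self.n_detected != len(self.blobs):
            raise ValueError("n_detected must equal len(blobs)")
        if (self.com_px is None) != (self.n_detected == 0):
            raise ValueError("com_px is defined iff n_detected >= 1")


@dataclass(frozen=True)
class MarkerFilterRules:
    """Plausibility filters for marker candidates.

    edge_margin_mm
        Minimum distance (at the isocenter plane) from a blob centroid to
        the traced field edge; markers nearer than this may be partially
        occluded by the MLC and are rejected.  Default 1.24 mm.
    min_area_px2 / max_area_px2
        Pixel-count bounds bracketing the projected footprint of a
        3 mm x 1 mm seed across realistic magnifications (default 4–80).
    max_elongation
        Reject streaks (cables, leaf edges) with axis ratio above this.
        The default (8) leaves headroom over a 3:1 seed, whose
        thresholded LoG ridge measures more elongated than its physical
        aspect ratio.
    require_complete
        If True, frames where fewer than the expected number of markers
        survive are excluded from the error statistics downstream.
    """

    edge_margin_mm: float = 1.24
    min_area_px2: float = 4.0
    max_area_px2: float = 80.0
    max_elongation: float = 8.0
    require_complete: bool = True


def label_candidates(
    mask: np.ndarray,
    response: np.ndarray,
    connectivity: int = 8,
) -> list[MarkerBlob]:
    """Connected-component labeling of a candidate mask.

    Moments are weighted by the magnitude of the underlying LoG
    response, giving sub-pixel centroids.  An empty mask yields an
    empty list.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(mask, dtype=bool)
    response = np.asarray(response, dtype=np.float64)
    if mask.shape != response.shape:
        raise ValueError("mask and response must share a grid")
    structure = _STRUCTURE_8 if connectivity == 8 else _STRUCTURE_4
    labels, n = ndimage.label(mask, structure=structure)
    blobs: list[MarkerBlob] = []
    for lab in range(1, n + 1):
        pts = np.argwhere(labels == lab)
        w = np.abs(response[pts[:, 0], pts[:, 1]])
        wsum = w.sum()
        if wsum <= 0:
            w = np.ones(len(pts))
            wsum = float(len(pts))
        centroid = (
            float((w * pts[:, 0]).sum() / wsum),
            float((w * pts[:, 1]).sum() / wsum),
        )
        dr = pts[:, 0] - centroid[0]
        dc = pts[:, 1] - centroid[1]
        cov = np.array(
            [
                [(w * dr * dr).sum(), (w * dr * dc).sum()],
                [(w * dr * dc).sum(), (w * dc * dc).sum()],
            ]
        ) / wsum
        evals = np.linalg.eigvalsh(cov)
        lam_minor, lam_major = max(evals[0], 0.0), max(evals[1], 0.0)
        if lam_major < 1e-12:
            elong = 1.0
        elif lam_minor < 1e-12:
            elong = np.inf
        else:
            elong = float(np.sqrt(lam_major / lam_minor))
        blobs.append(
            MarkerBlob(
                pixels=pts,
                centroid_px=centroid,
                area_px2=int(len(pts)),
                elongation=elong,
                mean_response=float(response[pts[:, 0], pts[:, 1]].mean()),
            )
        )
    return blobs


def _edge_distance_px(blob: MarkerBlob, contour: ApertureContour) -> float:
    d = contour.boundary_px[:-1].astype(float) - np.asarray(blob.centroid_px)
    return float(np.sqrt((d * d).sum(axis=1)).min())


def filter_markers(
    blobs: list[MarkerBlob],
    aperture: ApertureContour,
    rules: MarkerFilterRules = MarkerFilterRules(),
    expected_markers: int = 3,
    geometry: GeometryConfig = GeometryConfig(),
) -> MarkerSet:
    """Apply plausibility filters and assemble the frame's marker set.

    Keeps blobs that (a) fall inside the aperture and farther than
    ``edge_margin_mm`` from the traced boundary, (b) have plausible
    area, and (c) are not overly elongated.  If more than
    ``expected_markers`` survive, keeps the strongest by
    ``|mean_response|`` (ties broken by larger area, then smaller row,
    then smaller col — a deterministic total order).
    """
    margin_px = rules.edge_margin_mm / geometry.pixel_mm_at_iso
    survivors = [
        b
        for b in blobs
        if aperture.contains(b.centroid_px)
        and _edge_distance_px(b, aperture) > margin_px
        and rules.min_area_px2 <= b.area_px2 <= rules.max_area_px2
        and b.elongation <= rules.max_elongation
    ]
    if len(survivors) > expected_markers:
        survivors = sorted(
            survivors,
            key=lambda b: (
                -abs(b.mean_response),
                -b.area_px2,
                b.centroid_px[0],
                b.centroid_px[1],
            ),
        )[:expected_markers]
    n = len(survivors)
    com = None
    if n:
        cents = np.asarray([b.centroid_px for b in survivors])
        com = (float(cents[:, 0].mean()), float(cents[:, 1].mean()))
    return MarkerSet(
        blobs=survivors, com_px=com, n_detected=n, complete=(n == expected_markers)
    )


def markers_com(ms: MarkerSet) -> tuple[float, float]:
    """Unweighted mean of the detected marker centroids.

    Raises
    ------
    UndefinedComError
        If the set contains no markers.
    """
    if ms.n_detected == 0 or ms.com_px is None:
        raise UndefinedComError("marker COM is undefined for an empty marker set")
    return ms.com_px
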