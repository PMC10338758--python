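"""MLC aperture detection: field segmentation, chain-code boundary tracing,
and the aperture's geometric center.

The radiation field is the bright (low grey value, white=0 convention)
region of the portal frame; everything under the MLC leaves is dark.
Segmentation uses the standard radiotherapy 50% field-edge convention:
the cut sits halfway between the modal in-field and modal blocked grey
levels.  The boundary of the largest in-field region is then traced
with a Moore-neighbor follower emitting Freeman 8-direction codes, and
the aperture center is the area centroid of the enclosed region
(robust to MLC-step pixelation of the outline, unlike a boundary-point
mean).

Freeman codes follow the y-up convention: 0=E, 1=NE, 2=N, 3=NW, 4=W,
5=SW, 6=S, 7=SE, i.e. code k is a step of 45k degrees counterclockwise
from +col, with "north" meaning decreasing row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .epid_io import EpidImage
from .errors import DegenerateContourError, NoFieldError

__all__ = [
    "ApertureContour",
    "estimate_edge_threshold",
    "segment_field",
    "trace_boundary",
    "aperture_center",
    "FREEMAN_STEPS",
]

#: Freeman code -> (drow, dcol), y-up convention.
FREEMAN_STEPS: dict[int, tuple[int, int]] = {
    0: (0, 1),
    1: (-1, 1),
    2: (-1, 0),
    3: (-1, -1),
    4: (0, -1),
    5: (1, -1),
    6: (1, 0),
    7: (1, 1),
}
_STEP_TO_CODE = {v: k for k, v in FREEMAN_STEPS.items()}

# Moore neighborhood in clockwise screen order (row increases downward),
# starting East.
_MOORE_CLOCKWISE = [
    (0, 1),
    (1, 1),
    (1, 0),
    (1, -1),
    (0, -1),
    (-1, -1),
    (-1, 0),
    (-1, 1),
]


@dataclass
class ApertureContour:
    """Closed chain-code boundary of the radiation field.

    ``boundary_px`` is the ordered closed pixel path (first == last),
    ``chain_code`` the Freeman codes of its steps, ``center_px`` the
    sub-pixel area centroid of the enclosed (hole-filled) region and
    ``area_px2`` the enclosed area in px^2 computed from the chain code.
    ``interior_mask`` caches the filled region for containment queries.
    """

    chain_code: np.ndarray
    start_px: tuple[int, int]
    boundary_px: np.ndarray
    center_px: tuple[float, float]
    area_px2: float
    interior_mask: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if len(self.boundary_px) < 2 or tuple(self.boundary_px[0]) != tuple(
            self.boundary_px[-1]
        ):
            raise DegenerateContourError("boundary is not a closed path")
        if self.chain_code.size and not np.all(
            (self.chain_code >= 0) & (self.chain_code <= 7)
        ):
            raise ValueError("chain codes must lie in 0..7")
        if self.area_px2 <= 0:
            raise DegenerateContourError("enclosed area must be positive")

    def contains(self, point: tuple[float, float]) -> bool:
        """True if a (row, col) point falls on the filled interior."""
        r, c = int(round(point[0])), int(round(point[1]))
        m = self.interior_mask
        if m is None:
            raise ValueError("contour has no cached interior mask")
        return 0 <= r < m.shape[0] and 0 <= c < m.shape[1] and bool(m[r, c])


def estimate_edge_threshold(values: np.ndarray) -> float:
    """Half-maximum field-edge threshold.

    Splits the histogram with Otsu's criterion, takes the modal
    (median) grey value of each side as the in-field and blocked
    levels, and returns their midpoint — the 50% field-edge convention.
    """
    values = np.asarray(values, dtype=np.float64)
    t = threshold_otsu(values)
    in_field = np.median(values[values <= t])
    blocked = np.median(values[values > t])
    return float(0.5 * (in_field + blocked))


def segment_field(
    image: EpidImage | np.ndarray,
    edge_threshold: float | None = None,
    min_field_area_px2: float = 400.0,
) -> np.ndarray:
    """Binary mask of the radiation field (largest open region, holes filled).

    In-field pixels are those *below* ``edge_threshold`` (bright under
    the white=0 convention).  When the threshold is None it is estimated
    per frame with :func:`estimate_edge_threshold`.  Marker shadows are
    holes in the open region and are filled, so downstream tracing sees
    a simply connected aperture.

    Raises
    ------
    NoFieldError
        If no connected region of at least ``min_field_area_px2`` exists.
    """
    values = image.pixels if isinstance(image, EpidImage) else np.asarray(image, float)
    if edge_threshold is None:
        edge_threshold = estimate_edge_threshold(values)
    candidate = values < edge_threshold
    labels, n = ndimage.label(candidate, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise NoFieldError("no in-field pixels below the edge threshold")
    sizes = ndimage.sum_labels(candidate, labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < min_field_area_px2:
        raise NoFieldError(
            f"largest open region ({sizes[best - 1]:.0f} px^2) is below "
            f"min_field_area_px2 ({min_field_area_px2:.0f})"
        )
    return ndimage.binary_fill_holes(labels == best)


def trace_boundary(mask: np.ndarray) -> ApertureContour:
    """Moore-neighbor boundary trace of a single filled region.

    Starts at the topmost-leftmost foreground pixel and walks the
    boundary clockwise (in screen orientation), emitting one Freeman
    code per step, until the walk returns to the start in its initial
    state.  The enclosed area follows from the discrete Green's-theorem
    (shoelace) accumulation over the boundary polygon plus the Pick
    correction ``n_steps/2 + 1``, which makes it agree with the interior
    *pixel count* (exact for simple rectilinear regions).

    Raises
    ------
    DegenerateContourError
        For an empty or single-pixel region.
    """
    mask = np.asarray(mask, dtype=bool)
    pts = np.argwhere(mask)
    if len(pts) == 0:
        raise DegenerateContourError("empty mask")
    if len(pts) == 1:
        raise DegenerateContourError("single-pixel region has no traceable boundary")
    filled = ndimage.binary_fill_holes(mask)

    start = (int(pts[0, 0]), int(pts[0, 1]))
    b0 = (start[0], start[1] - 1)  # west backtrack: row-major scan guarantees background
    nrow, ncol = filled.shape

    boundary = [start]
    codes: list[int] = []
    p, b = start, b0
    seen: set[tuple[tuple[int, int], tuple[int, int]]] = set()
    max_steps = 4 * int(filled.sum()) + 8
    while (p, b) not in seen:
        seen.add((p, b))
        bi = _MOORE_CLOCKWISE.index((b[0] - p[0], b[1] - p[1]))
        nxt = None
        for k in range(1, 9):
            d = _MOORE_CLOCKWISE[(bi + k) % 8]
            q = (p[0] + d[0], p[1] + d[1])
            if 0 <= q[0] < nrow and 0 <= q[1] < ncol and filled[q]:
                prev = _MOORE_CLOCKWISE[(bi + k - 1) % 8]
                nxt, b_new = q, (p[0] + prev[0], p[1] + prev[1])
                break
        if nxt is None:
            raise DegenerateContourError("isolated pixel encountered during trace")
        codes.append(_STEP_TO_CODE[(nxt[0] - p[0], nxt[1] - p[1])])
        boundary.append(nxt)
        p, b = nxt, b_new
        if len(codes) > max_steps:  # pragma: no cover - safety net
            raise DegenerateContourError("boundary trace failed to close")
    if boundary[-1] != start:  # pragma: no cover - non-simple pathologies
        raise DegenerateContourError("boundary trace did not close at start pixel")

    bp = np.asarray(boundary, dtype=np.int64)
    # Shoelace over boundary pixel centers (x=col, y=row) ...
    x, y = bp[:, 1].astype(float), bp[:, 0].astype(float)
    shoelace = 0.5 * abs(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]))
    # ... plus Pick's correction so the value matches the pixel count.
    area = shoelace + len(codes) / 2.0 + 1.0

    interior = np.argwhere(filled)
    center = (float(interior[:, 0].mean()), float(interior[:, 1].mean()))

    return ApertureContour(
        chain_code=np.asarray(codes, dtype=np.int64),
        start_px=start,
        boundary_px=bp,
        center_px=center,
        area_px2=float(area),
        interior_mask=filled,
    )


def aperture_center(contour: ApertureContour) -> tuple[float, float]:
    """Sub-pixel (row, col) area centroid of the aperture's enclosed region."""
    return contour.center_px
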