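"""QA overlay rendering (field edge, markers, aperture center)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .epid_io import EpidImage  # noqa: E402
from .pipeline import FrameResult  # noqa: E402

__all__ = ["save_overlay"]


def save_overlay(image: EpidImage, result: FrameResult, path: str | Path) -> None:
    """Write a review PNG: frame, traced field edge, marker centroids, center."""
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(image.pixels, cmap="gray_r", vmin=0, vmax=1)
    if result.contour is not None:
        bp = result.contour.boundary_px
        ax.plot(bp[:, 1], bp[:, 0], color="lime", lw=1.0, label="field edge")
        ax.plot(
            result.contour.center_px[1],
            result.contour.center_px[0],
            "s",
            color="tab:orange",
            ms=8,
            mfc="none",
            label="aperture center",
        )
    if result.marker_set is not None and result.marker_set.n_detected:
        for b in result.marker_set.blobs:
            ax.annotate(
                "",
                xy=(b.centroid_px[1], b.centroid_px[0]),
                xytext=(b.centroid_px[1] + 25, b.centroid_px[0] + 25),
                arrowprops=dict(arrowstyle="->", color="red"),
            )
        ax.plot(
            result.marker_set.com_px[1],
            result.marker_set.com_px[0],
            "+",
            color="cyan",
            ms=10,
            label="marker COM",
        )
    ax.set_title(f"frame {image.index} (t = {image.time_s:.1f} s)")
    ax.legend(loc="lower right", fontsize=8)
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
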