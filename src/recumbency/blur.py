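"""Laplacian-variance blur scoring and image quality control.

Dirty camera lenses blur the recorded frames, which corrupts both the
human labeling and the tracker's velocity signal.  Sharpness is scored as
the variance of the discrete Laplacian of the grayscale image: a sharp
image has many strong edges, hence a second-derivative response with a
large spread; a blurred image has a flat response.  Images scoring below
a configurable cutoff (default 1000 on 8-bit intensities) are excluded
before any behavioral analysis.

The numeric score depends on kernel, border handling and intensity scale,
so the cutoff is configuration, not a portable constant.  Conventions
pinned here (and by the unit tests):

* kernel: 3x3 discrete Laplacian, center -4, 4-neighbors +1, corners 0;
* border: the variance is taken over valid interior responses only
  (no padding);
* variance: population variance (ddof=0);
* intensities are promoted to float before convolving, so the -4 center
  tap cannot saturate 8-bit arithmetic;
* color input is converted to grayscale with ITU-R BT.601 luma weights
  (0.299 R + 0.587 G + 0.114 B) and the conversion is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import convolve2d

logger = logging.getLogger(__name__)

#: 3x3 discrete Laplacian stencil (4-neighbor).
LAPLACIAN_KERNEL = np.array(
    [[0.0, 1.0, 0.0],
     [1.0, -4.0, 1.0],
     [0.0, 1.0, 0.0]]
)

#: Default sharpness cutoff on 8-bit grayscale intensities.
DEFAULT_BLUR_CUTOFF = 1000.0

_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass
class ImageRecord:
    """One sampled camera frame with pen and timestamp metadata.

    ``blur_score`` is ``None`` until :func:`score_records` (or
    :func:`laplacian_variance`) has been applied.
    """

    pen_id: str
    t_s: float
    pixels: np.ndarray = field(repr=False)
    blur_score: float | None = None

    def scored(self) -> bool:
        return self.blur_score is not None


def laplacian_variance(pixels: np.ndarray) -> float:
    """Score image sharpness as the variance of the Laplacian response.

    Parameters
    ----------
    pixels
        2-D grayscale intensity grid, at least 3x3.  A 3-D ``(H, W, 3)``
        array is accepted and converted to grayscale by luma weighting.

    Returns
    -------
    float
        Population variance of the 3x3 Laplacian response over valid
        interior pixels.  Nonnegative; exactly 0 for a constant image.
    """
    arr = np.asarray(pixels, dtype=float)
    if arr.ndim == 3 and arr.shape[2] == 3:
        logger.info("color image converted to grayscale via luma weights")
        arr = arr @ _LUMA_WEIGHTS
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {arr.shape}")
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ValueError(f"image {arr.shape} smaller than the 3x3 Laplacian kernel")
    response = convolve2d(arr, LAPLACIAN_KERNEL, mode="valid")
    return float(np.var(response))


def score_records(records: Iterable[ImageRecord]) -> list[ImageRecord]:
    """Fill ``blur_score`` on every record in place; returns the list."""
    out = list(records)
    for rec in out:
        rec.blur_score = laplacian_variance(rec.pixels)
    return out


def filter_blurred(
    records: Sequence[ImageRecord],
    cutoff: float = DEFAULT_BLUR_CUTOFF,
) -> tuple[list[ImageRecord], list[ImageRecord]]:
    """Partition scored records into (kept, excluded) by sharpness.

    A record is kept iff ``blur_score >= cutoff``; strictly lower scores
    are considered blurred and excluded.  Every record must already be
    scored.
    """
    kept: list[ImageRecord] = []
    excluded: list[ImageRecord] = []
    for rec in records:
        if rec.blur_score is None:
            raise ValueError(
                f"unscored image record (pen {rec.pen_id!r}, t={rec.t_s}); "
                "run score_records first"
            )
        (kept if rec.blur_score >= cutoff else excluded).append(rec)
    logger.info(
        "blur QC: %d kept, %d excluded at cutoff %g", len(kept), len(excluded), cutoff
    )
    return kept, excluded
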