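"""Preprocessing of raw grayscale frames into single-cell binary masks.

Background subtraction uses the temporal median of the stack (the cell
moves, the background does not); for a single frame a flat field equal
to the modal intensity is used instead. Binarization is fully automatic:
a histogram threshold (Otsu by default), polarity chosen so the cell is
the minority phase touching fewer image-border pixels, followed by
small-object removal, hole filling and retention of the largest
8-connected component. Any frame where thresholding yields an
implausible foreground fraction is flagged as a segmentation failure
rather than silently producing an empty mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_holes, remove_small_objects

from .errors import SegmentationError
from .medial_axis import STRUCT_8

__all__ = ["PreprocessConfig", "subtract_background", "binarize"]


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable preprocessing parameters.

    min_object_area_px : speckle components smaller than this are removed.
    fill_hole_area_px : background holes smaller than this are filled.
    min_foreground_frac / max_foreground_frac : plausibility band for the
        thresholded foreground fraction; outside it the frame is flagged
        as a segmentation failure.
    """

    min_object_area_px: int = 9
    fill_hole_area_px: int = 9
    min_foreground_frac: float = 0.01
    max_foreground_frac: float = 0.99


def subtract_background(stack: np.ndarray) -> np.ndarray:
    """Remove the static background from a stack of frames.

    Parameters
    ----------
    stack : array, shape (n_frames, H, W)
        Raw grayscale frames with values in [0, 255].

    Returns
    -------
    array of the same shape: absolute deviation from the per-pixel
    temporal median (modal intensity for a single frame), rescaled to
    [0, 255]. A static scene therefore maps to an all-zero stack.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("stack must contain at least one 2-D frame")
    if stack.shape[0] > 1:
        background = np.median(stack, axis=0)
    else:
        values, counts = np.unique(np.rint(stack[0]), return_counts=True)
        background = np.full(stack.shape[1:], values[np.argmax(counts)])
    out = np.abs(stack - background[None])
    peak = out.max()
    if peak > 0:
        out *= 255.0 / peak
    return out


def _cell_polarity(frame: np.ndarray, threshold: float) -> np.ndarray:
    """Boolean mask with the cell as foreground.

    The cell is interior to the frame, so of the two threshold phases it
    is the one touching fewer border pixels (ties broken toward the
    minority phase).
    """
    above = frame > threshold
    border = np.zeros(frame.shape, dtype=bool)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    above_border = int((above & border).sum())
    below_border = int(border.sum()) - above_border
    if above_border != below_border:
        return above if above_border < below_border else ~above
    return above if above.sum() <= above.size / 2 else ~above


def binarize(
    frame: np.ndarray, config: PreprocessConfig = PreprocessConfig()
) -> np.ndarray:
    """Threshold a background-corrected frame into a single-cell mask.

    Returns a boolean mask with exactly one 8-connected foreground
    component (the largest after cleanup).

    Raises
    ------
    SegmentationError
        If the automatic threshold yields an implausible foreground
        fraction (no discernible cell) or cleanup removes everything.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be a 2-D grayscale image")
    if np.ptp(frame) == 0:
        raise SegmentationError("frame is constant: no foreground to segment")
    threshold = threshold_otsu(frame)
    mask = _cell_polarity(frame, threshold)

    frac = mask.mean()
    if not (config.min_foreground_frac <= frac <= config.max_foreground_frac):
        raise SegmentationError(
            f"thresholded foreground fraction {frac:.3f} outside plausible range"
        )

    mask = remove_small_objects(
        mask, max_size=config.min_object_area_px - 1, connectivity=2
    )
    mask = remove_small_holes(mask, max_size=config.fill_hole_area_px - 1)
    if not mask.any():
        raise SegmentationError("cleanup removed all foreground")
    labels, n = ndimage.label(mask, structure=STRUCT_8)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return mask
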