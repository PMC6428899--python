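"""Width-profile analysis of the medial axis transform.

The transform values read in arclength order along the skeleton form the
cell's width-profile. A flagellum — a long organelle of approximately
constant visible width — appears as a plateau in this profile and as a
sharp mode in its histogram, in contrast to the broad spread of widths
contributed by the cell body. Two identification schemes are provided:

* **modal analysis** (default): take the mode of the width
  distribution, keep skeleton pixels whose width is within a tolerance
  of it, and select the largest connected region;
* **derivative analysis**: walk the profile from the flagellar tip,
  approximate the derivative of width with respect to arclength by a
  forward difference, and flag the first outlier (relative to the
  running median + k*MAD of previous derivatives) as the point of
  flagellar attachment.

Modal analysis is the default because it is insensitive to skeleton
topology and, unlike the derivative scheme, has no step-size parameter
to which success is sharply sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import BranchedSkeletonError, IdentificationError
from .medial_axis import STRUCT_8, MedialAxisMap, Skeleton

__all__ = [
    "SkeletonPath",
    "WidthProfile",
    "ModalResult",
    "AttachmentEstimate",
    "walk_simple_path",
    "extract_width_profile",
    "width_histogram",
    "modal_segment",
    "derivative_segment",
    "attachment_from_modal",
]

# axial steps first so staircase corners are walked without skipping
_NEIGHBOR_OFFSETS = (
    (-1, 0), (0, -1), (0, 1), (1, 0),
    (-1, -1), (-1, 1), (1, -1), (1, 1),
)


@dataclass(frozen=True)
class SkeletonPath:
    """Ordered simple path of 8-connected skeleton pixels.

    ``arclength[i]`` accumulates 1 per axial step and sqrt(2) per
    diagonal step from the start of the path.
    """

    points: np.ndarray  # (n, 2) int
    arclength: np.ndarray  # (n,) float

    @classmethod
    def from_points(cls, points: np.ndarray) -> "SkeletonPath":
        points = np.asarray(points, dtype=int)
        if len(points) == 0:
            raise ValueError("path must contain at least one point")
        steps = np.abs(np.diff(points, axis=0))
        if steps.size and steps.max() > 1:
            raise ValueError("consecutive path points must be 8-neighbours")
        increments = np.where(steps.sum(axis=1) == 2, np.sqrt(2.0), 1.0)
        arclength = np.concatenate([[0.0], np.cumsum(increments)])
        return cls(points=points, arclength=arclength)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def total_arclength(self) -> float:
        return float(self.arclength[-1])


@dataclass(frozen=True)
class WidthProfile:
    """Arclength-ordered transform values along a skeleton path."""

    path: SkeletonPath
    widths: np.ndarray  # (n,) float

    def __len__(self) -> int:
        return len(self.widths)

    @property
    def arclength(self) -> np.ndarray:
        return self.path.arclength

    def reversed(self) -> "WidthProfile":
        pts = self.path.points[::-1]
        return WidthProfile(SkeletonPath.from_points(pts), self.widths[::-1].copy())


@dataclass
class ModalResult:
    """Outcome of modal width analysis.

    ``selected_mask`` marks the largest 8-connected skeleton region
    whose transform value does not exceed ``modal_width + tolerance``
    (the mode used as a simple width threshold).
    """

    modal_width: float
    bin_width: float
    tolerance: float
    selected_mask: np.ndarray  # bool image
    candidate_regions: list[np.ndarray] = field(default_factory=list)

    @property
    def selected_pixels(self) -> np.ndarray:
        return np.argwhere(self.selected_mask)


@dataclass
class AttachmentEstimate:
    """Estimated point where the flagellum joins the cell body."""

    point: tuple[int, int]
    arclength_at_attachment: float
    method: str  # "modal" or "derivative"
    low_confidence: bool = False


def walk_simple_path(
    skeleton_mask: np.ndarray, start: tuple[int, int]
) -> np.ndarray:
    """Order the pixels of an unbranched skeleton component from ``start``.

    Walks greedily (axial steps preferred, then lexicographic) without
    revisiting pixels. Raises :class:`BranchedSkeletonError` if the walk
    does not cover the whole connected component exactly once, which
    happens precisely when the component contains a junction.
    """
    mask = np.asarray(skeleton_mask, dtype=bool)
    start = (int(start[0]), int(start[1]))
    if not mask[start]:
        raise ValueError(f"start {start} is not a skeleton pixel")
    H, W = mask.shape
    visited = np.zeros_like(mask)
    path = [start]
    visited[start] = True
    current = start
    while True:
        nxt = None
        for dr, dc in _NEIGHBOR_OFFSETS:
            r, c = current[0] + dr, current[1] + dc
            if 0 <= r < H and 0 <= c < W and mask[r, c] and not visited[r, c]:
                nxt = (r, c)
                break
        if nxt is None:
            break
        visited[nxt] = True
        path.append(nxt)
        current = nxt
    labels, _ = ndimage.label(mask, structure=STRUCT_8)
    component_size = int((labels == labels[start]).sum())
    if len(path) != component_size:
        raise BranchedSkeletonError(
            "skeleton component is branched; resolve junctions first "
            "(tracing.resolve_branches)"
        )
    return np.asarray(path, dtype=int)


def extract_width_profile(
    mat: MedialAxisMap, start: tuple[int, int]
) -> WidthProfile:
    """Read the width-profile of a simple-path skeleton from an endpoint.

    The profile visits every skeleton pixel of the component exactly
    once starting at ``start``; widths are the transform values. For
    branched skeletons a :class:`BranchedSkeletonError` directs the
    caller to branch resolution.
    """
    points = walk_simple_path(mat.skeleton.mask, start)
    path = SkeletonPath.from_points(points)
    return WidthProfile(path=path, widths=mat.widths_at(points))


def width_histogram(
    widths: np.ndarray | WidthProfile, bin_width: float = 1.0
) -> tuple[np.ndarray, np.ndarray, float]:
    """Histogram of transform values and the modal width.

    Returns ``(bin_centers, counts, modal_width)``. Bins are aligned to
    multiples of ``bin_width``; ties between equally-occupied bins are
    broken toward the smaller width (the flagellum is the thin
    structure). The modal width reported is the mean of the widths
    falling in the winning bin, which for a plateau of constant width
    returns that width exactly.
    """
    if isinstance(widths, WidthProfile):
        widths = widths.widths
    widths = np.asarray(widths, dtype=float)
    if widths.size == 0:
        raise ValueError("cannot histogram an empty width set")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    idx = np.floor(widths / bin_width).astype(int)
    lo = idx.min()
    counts = np.bincount(idx - lo)
    centers = (np.arange(lo, lo + len(counts)) + 0.5) * bin_width
    winner = int(np.argmax(counts))  # first max = smallest width on ties
    modal_width = float(widths[idx - lo == winner].mean())
    return centers, counts, modal_width


def modal_segment(
    mat: MedialAxisMap,
    tolerance: float = 1.0,
    bin_width: float = 1.0,
    min_region_px: int = 5,
) -> ModalResult:
    """Isolate the flagellar region by modal width analysis.

    The modal width is used as a simple threshold: skeleton pixels with
    transform value at most ``modal_width + tolerance`` are grouped into
    8-connected candidate regions and the largest is selected (ties
    broken toward the region containing the lexicographically smallest
    pixel). The cut is one-sided because the flagellum is the *thin*
    structure — its tip may taper below the mode (especially after
    blurring), whereas anything wider than the mode by more than the
    tolerance is cell body.

    Raises
    ------
    IdentificationError
        If no skeleton pixel falls below the threshold, or the largest
        candidate is shorter than ``min_region_px`` (speckle).
    """
    skeleton = mat.skeleton.mask
    widths = mat.values[skeleton]
    if widths.size == 0:
        raise IdentificationError("medial axis transform has no skeleton pixels")
    _, _, modal_width = width_histogram(widths, bin_width=bin_width)
    near_mode = skeleton & (mat.values <= modal_width + tolerance)
    if not near_mode.any():
        raise IdentificationError(
            f"no skeleton pixels within {tolerance} px of modal width {modal_width:.2f}"
        )
    labels, n = ndimage.label(near_mode, structure=STRUCT_8)
    regions = [np.argwhere(labels == i) for i in range(1, n + 1)]
    sizes = np.array([len(r) for r in regions])
    best = sizes.max()
    # deterministic tie-break: among largest regions, the one containing
    # the lexicographically smallest pixel
    tied = [r for r in regions if len(r) == best]
    selected = min(tied, key=lambda r: min(map(tuple, r)))
    if best < min_region_px:
        raise IdentificationError(
            f"largest modal region has {best} px (< min_region_px={min_region_px})"
        )
    selected_mask = np.zeros_like(skeleton)
    selected_mask[selected[:, 0], selected[:, 1]] = True
    return ModalResult(
        modal_width=modal_width,
        bin_width=bin_width,
        tolerance=tolerance,
        selected_mask=selected_mask,
        candidate_regions=regions,
    )


def derivative_segment(
    profile: WidthProfile,
    step: int = 3,
    outlier_k: float = 3.0,
    min_history: int = 10,
    mad_floor: float = 0.05,
) -> AttachmentEstimate:
    """Locate the flagellar attachment by derivative outlier analysis.

    The profile must be ordered from the flagellar tip. The derivative
    of width with respect to arclength is approximated by a
    ``step``-sample forward difference; the first sample whose
    derivative exceeds the median + ``outlier_k`` * MAD of all previous
    derivatives is flagged as the attachment (the width starts rising
    into the body there). ``mad_floor`` (px/px) keeps the outlier
    threshold meaningful when the early profile is perfectly flat.

    Raises
    ------
    IdentificationError
        If no outlier is found (the profile may contain no body).
    """
    widths = profile.widths
    arclength = profile.arclength
    n = len(widths)
    if step < 1:
        raise ValueError("step must be a positive integer")
    if n <= step + min_history:
        raise IdentificationError(
            f"profile of {n} samples too short for step={step} with "
            f"min_history={min_history}"
        )
    deriv = (widths[step:] - widths[:-step]) / (arclength[step:] - arclength[:-step])
    for i in range(min_history, len(deriv)):
        history = deriv[:i]
        med = float(np.median(history))
        mad = float(np.median(np.abs(history - med)))
        if deriv[i] > med + outlier_k * max(mad, mad_floor):
            return AttachmentEstimate(
                point=tuple(profile.path.points[i]),
                arclength_at_attachment=float(arclength[i]),
                method="derivative",
            )
    raise IdentificationError("no derivative outlier found; profile may lack a body")


def _beyond_region_widths(
    mat: MedialAxisMap,
    region_mask: np.ndarray,
    endpoint: tuple[int, int],
    n_samples: int,
) -> np.ndarray:
    """Transform values of up to ``n_samples`` skeleton pixels reachable
    from ``endpoint`` without entering the region (BFS order)."""
    skeleton = mat.skeleton.mask
    H, W = skeleton.shape
    seen = region_mask.copy()
    frontier = [tuple(endpoint)]
    out: list[float] = []
    while frontier and len(out) < n_samples:
        nxt: list[tuple[int, int]] = []
        for (r0, c0) in frontier:
            for dr, dc in _NEIGHBOR_OFFSETS:
                r, c = r0 + dr, c0 + dc
                if 0 <= r < H and 0 <= c < W and skeleton[r, c] and not seen[r, c]:
                    seen[r, c] = True
                    out.append(float(mat.values[r, c]))
                    nxt.append((r, c))
                    if len(out) >= n_samples:
                        break
            if len(out) >= n_samples:
                break
        frontier = nxt
    return np.asarray(out)


def attachment_from_modal(
    result: ModalResult, mat: MedialAxisMap, neighborhood: int = 5
) -> AttachmentEstimate:
    """Pick the body-side endpoint of the selected modal region.

    Of the region's path endpoints, the attachment is the one whose
    skeleton neighbourhood beyond the region (next ``neighborhood``
    samples) has the larger mean transform value — i.e. the side where
    the cell widens into the body. A region shorter than
    ``neighborhood`` pixels, or with no skeleton beyond either endpoint
    (a free filament), yields a deterministic low-confidence estimate.
    """
    region = result.selected_mask
    pts = np.argwhere(region)
    if len(pts) == 0:
        raise ValueError("modal result has an empty selected region")
    if len(pts) == 1:
        p = tuple(pts[0])
        return AttachmentEstimate(p, 0.0, "modal", low_confidence=True)

    counts = (
        ndimage.convolve(region.astype(int), STRUCT_8, mode="constant", cval=0)
        - region.astype(int)
    )
    endpoints = np.argwhere(region & (counts <= 1))
    if len(endpoints) == 0:  # closed loop: fall back to lexicographic pixel
        p = tuple(pts[np.lexsort((pts[:, 1], pts[:, 0]))[0]])
        return AttachmentEstimate(p, 0.0, "modal", low_confidence=True)

    low_confidence = len(pts) < neighborhood
    best_point: tuple[int, int] | None = None
    best_mean = -np.inf
    any_beyond = False
    for ep in sorted(map(tuple, endpoints)):
        beyond = _beyond_region_widths(mat, region, ep, neighborhood)
        mean = float(beyond.mean()) if beyond.size else -np.inf
        if beyond.size:
            any_beyond = True
        if mean > best_mean:
            best_mean = mean
            best_point = ep
    if not any_beyond:
        # symmetric free filament: no body on either side
        best_point = sorted(map(tuple, endpoints))[0]
        low_confidence = True
    assert best_point is not None
    return AttachmentEstimate(
        point=best_point,
        arclength_at_attachment=0.0,
        method="modal",
        low_confidence=low_confidence,
    )
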