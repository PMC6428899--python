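"""Fully-automatic per-frame identification pipeline.

Steps, per frame and with no user interaction: (i) preprocess into a
binary mask of the whole cell, (ii) compute and analyse the medial axis
transform, isolating the flagellum by modal (default) or derivative
width analysis, (iii) trace the isolated filament into an ordered
centerline. Frames are independent — no temporal prior links them — so
a failure in one frame never affects another.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import tracing, width_analysis
from .errors import FlagtraceError
from .medial_axis import MedialAxisMap, medial_axis_transform
from .preprocess import PreprocessConfig, binarize, subtract_background
from .tracing import FlagellumTrace, StitchConfig
from .width_analysis import ModalResult

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "FrameResult", "process_frame", "process_stack"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable parameters of the identification pipeline."""

    method: str = "modal"  # "modal" or "derivative"
    background: str = "median"  # "median" (temporal) or "none"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    bin_width_px: float = 1.0
    modal_tolerance_px: float = 1.0
    min_region_px: int = 5
    derivative_step: int = 3
    outlier_k: float = 3.0
    min_history: int = 10
    stitch: bool = True
    stitch_radius_factor: float = 2.0  # radius = factor * modal half-width
    tangent_window: int = 5
    d_px: float = 3.0
    success_mdr_max: float = 10.0
    success_fdr_max: float = 10.0

    def __post_init__(self) -> None:
        if self.method not in ("modal", "derivative"):
            raise ValueError("method must be 'modal' or 'derivative'")
        if self.background not in ("median", "none"):
            raise ValueError("background must be 'median' or 'none'")


@dataclass
class FrameResult:
    """Outcome of processing one frame."""

    frame_index: int
    status: str  # "ok", "partial" or "failed"
    trace: FlagellumTrace | None = None
    failure_reason: str = ""
    modal_width_px: float = float("nan")


def _stitched_modal_result(
    result: ModalResult, config: PipelineConfig
) -> ModalResult:
    """Re-select the largest candidate after stitching nearby regions."""
    if len(result.candidate_regions) <= 1:
        return result
    radius = config.stitch_radius_factor * max(result.modal_width, 1.0)
    merged, bridges = tracing.stitch_segments(
        result.candidate_regions, StitchConfig(radius_px=radius)
    )
    if not bridges:
        return result
    best_size = max(len(r) for r in merged)
    largest = min(
        (r for r in merged if len(r) == best_size), key=lambda r: min(map(tuple, r))
    )
    selected_mask = np.zeros_like(result.selected_mask)
    selected_mask[largest[:, 0], largest[:, 1]] = True
    return replace(result, selected_mask=selected_mask, candidate_regions=merged)


def _derivative_trace(
    mat: MedialAxisMap, config: PipelineConfig, frame_index: int
) -> tuple[FlagellumTrace, float]:
    """Identification by derivative analysis of the tip-anchored profile."""
    endpoints = [tuple(p) for p in mat.skeleton.endpoints()]
    if not endpoints:
        raise FlagtraceError("skeleton has no endpoints (closed loop)")

    # the flagellar tip is the endpoint whose early profile is thinnest
    def _early_mean(ep: tuple[int, int]) -> float:
        path = tracing.resolve_branches(mat.skeleton, ep, window=config.tangent_window)
        widths = mat.widths_at(path.points[: config.min_history])
        return float(widths.mean())

    tip = min(sorted(endpoints), key=_early_mean)
    path = tracing.resolve_branches(mat.skeleton, tip, window=config.tangent_window)
    profile = width_analysis.WidthProfile(path=path, widths=mat.widths_at(path.points))
    attachment = width_analysis.derivative_segment(
        profile,
        step=config.derivative_step,
        outlier_k=config.outlier_k,
        min_history=config.min_history,
    )
    cut = int(np.flatnonzero(
        (path.points == np.asarray(attachment.point)).all(axis=1)
    )[0])
    pts = path.points[: cut + 1][::-1]  # reorder attachment -> tip
    sub = width_analysis.SkeletonPath.from_points(pts)
    return (
        FlagellumTrace(
            points=sub.points,
            arclengths=sub.arclength,
            widths_px=mat.widths_at(sub.points),
            attachment=attachment,
            frame_index=frame_index,
        ),
        float(np.median(profile.widths[: max(cut, 1)])),
    )


def process_frame(
    frame: np.ndarray, config: PipelineConfig = PipelineConfig(), frame_index: int = 0
) -> FrameResult:
    """Identify and trace the flagellum in one background-corrected frame.

    Recoverable analysis failures (no plausible mask, no modal region,
    no derivative outlier, ...) yield ``status="failed"`` with the
    reason recorded; they never raise.
    """
    try:
        mask = binarize(frame, config.preprocess)
        mat = medial_axis_transform(mask)
        if config.method == "modal":
            result = width_analysis.modal_segment(
                mat,
                tolerance=config.modal_tolerance_px,
                bin_width=config.bin_width_px,
                min_region_px=config.min_region_px,
            )
            if config.stitch:
                result = _stitched_modal_result(result, config)
            attachment = width_analysis.attachment_from_modal(result, mat)
            trace = tracing.trace_flagellum(
                result, attachment, mat,
                frame_index=frame_index, window=config.tangent_window,
            )
            modal_width = result.modal_width
        else:
            trace, modal_width = _derivative_trace(mat, config, frame_index)
    except FlagtraceError as exc:
        logger.info("frame %d failed: %s", frame_index, exc)
        return FrameResult(frame_index, "failed", failure_reason=str(exc))
    status = "partial" if trace.partial else "ok"
    logger.info(
        "frame %d %s: modal width %.2f px, trace %d px (%.1f px arclength)",
        frame_index, status, modal_width, len(trace), trace.arclength_px,
    )
    return FrameResult(frame_index, status, trace=trace, modal_width_px=modal_width)


def process_stack(
    frames: np.ndarray, config: PipelineConfig = PipelineConfig()
) -> list[FrameResult]:
    """Run the pipeline over a stack of raw frames.

    Applies temporal-median background subtraction across the stack
    (unless ``config.background == "none"``), then processes each frame
    independently. Returns one :class:`FrameResult` per input frame.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise ValueError("stack must contain at least one 2-D frame")
    if config.background == "median":
        frames = subtract_background(frames)
    return [
        process_frame(frame, config, frame_index=i)
        for i, frame in enumerate(frames)
    ]
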