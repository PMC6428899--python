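"""Reading image stacks and writing pipeline outputs.

Input stacks are multi-page TIFFs or globs of per-frame PNG/TIFF
files. The file-based pipeline streams frames one page at a time so
peak memory stays bounded by a handful of frames regardless of stack
length; the static background is estimated from a capped evenly-spaced
sample of frames.
"""

from __future__ import annotations

import dataclasses
import json
from glob import glob
from pathlib import Path
from typing import Iterator

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .pipeline import FrameResult, PipelineConfig, process_frame

__all__ = [
    "stack_frames",
    "read_stack",
    "run_pipeline",
    "write_traces_csv",
    "write_attachments_csv",
    "write_overlay_tiff",
    "write_manifest",
]

#: frames sampled for the temporal-median background estimate
BACKGROUND_SAMPLE_FRAMES = 64


def _frame_paths(path: str | Path) -> list[Path]:
    path = str(path)
    if any(ch in path for ch in "*?["):
        files = sorted(glob(path))
        if not files:
            raise FileNotFoundError(f"glob {path!r} matched no files")
        return [Path(f) for f in files]
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such file: {p}")
    return [p]


def _stack_length(paths: list[Path]) -> int:
    if len(paths) > 1:
        return len(paths)
    if paths[0].suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(paths[0]) as tf:
            return len(tf.pages)
    return 1


def stack_frames(path: str | Path) -> tuple[int, Iterator[np.ndarray]]:
    """Lazily iterate the grayscale frames of a stack.

    ``path`` is a multi-page TIFF, a single image, or a glob of
    per-frame files (sorted by name). Returns ``(n_frames, iterator)``.
    """
    paths = _frame_paths(path)
    n = _stack_length(paths)
    if n == 0:
        raise ValueError(f"stack {path!r} contains no frames")

    def _iter() -> Iterator[np.ndarray]:
        if len(paths) == 1 and paths[0].suffix.lower() in (".tif", ".tiff"):
            with tifffile.TiffFile(paths[0]) as tf:
                for page in tf.pages:
                    yield np.asarray(page.asarray(), dtype=float)
        else:
            for p in paths:
                frame = np.asarray(iio.imread(p), dtype=float)
                if frame.ndim == 3:  # collapse RGB(A) to luminance
                    frame = frame[..., :3].mean(axis=-1)
                yield frame

    return n, _iter()


def read_stack(path: str | Path) -> np.ndarray:
    """Read a whole stack into an (n, H, W) float array."""
    _, frames = stack_frames(path)
    return np.stack(list(frames))


def _sampled_background(path: str | Path, n: int) -> np.ndarray:
    """Per-pixel temporal median over <= BACKGROUND_SAMPLE_FRAMES frames."""
    keep = set(
        np.unique(
            np.linspace(0, n - 1, min(n, BACKGROUND_SAMPLE_FRAMES)).astype(int)
        ).tolist()
    )
    _, frames = stack_frames(path)
    sample = [f for i, f in enumerate(frames) if i in keep]
    return np.median(np.stack(sample), axis=0)


def run_pipeline(
    stack_path: str | Path,
    config: PipelineConfig = PipelineConfig(),
    outdir: str | Path | None = None,
) -> list[FrameResult]:
    """Run the full identification pipeline over a stack on disk.

    Processes frames independently in a streaming fashion. When
    ``outdir`` is given, writes ``traces.csv``, ``attachments.csv``, an
    ``overlay.tif`` with the identified centerline highlighted in white
    on the original frames, and a ``manifest.json`` echoing the
    configuration.
    """
    n, frames = stack_frames(stack_path)
    background = None
    if config.background == "median" and n > 1:
        background = _sampled_background(stack_path, n)

    results: list[FrameResult] = []
    originals_for_overlay: list[np.ndarray] = []
    for i, frame in enumerate(frames):
        if outdir is not None:
            originals_for_overlay.append(frame)
        corrected = frame
        if background is not None:
            corrected = np.abs(frame - background)
            peak = corrected.max()
            if peak > 0:
                corrected = corrected * (255.0 / peak)
        results.append(process_frame(corrected, config, frame_index=i))

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_traces_csv(outdir / "traces.csv", results)
        write_attachments_csv(outdir / "attachments.csv", results)
        write_overlay_tiff(
            outdir / "overlay.tif", np.stack(originals_for_overlay), results
        )
        write_manifest(outdir / "manifest.json", config, n_frames=n)
    return results


def write_traces_csv(path: str | Path, results: list[FrameResult]) -> None:
    rows = []
    for res in results:
        if res.trace is None:
            continue
        t = res.trace
        for i, ((r, c), w, s) in enumerate(
            zip(t.points, t.widths_px, t.arclengths)
        ):
            rows.append((res.frame_index, i, int(r), int(c), float(w), float(s)))
    pd.DataFrame(
        rows,
        columns=["frame", "point_index", "row", "col", "width_px", "arclength_px"],
    ).to_csv(path, index=False)


def write_attachments_csv(path: str | Path, results: list[FrameResult]) -> None:
    rows = []
    for res in results:
        if res.trace is None:
            continue
        a = res.trace.attachment
        confidence = "low" if a.low_confidence else "ok"
        rows.append((res.frame_index, a.point[0], a.point[1], confidence))
    pd.DataFrame(rows, columns=["frame", "row", "col", "confidence"]).to_csv(
        path, index=False
    )


def write_overlay_tiff(
    path: str | Path, frames: np.ndarray, results: list[FrameResult]
) -> None:
    """Original frames with the identified centerline burned in white."""
    overlay = np.clip(np.asarray(frames, dtype=float), 0, 255).astype(np.uint8)
    for res in results:
        if res.trace is None:
            continue
        pts = res.trace.points
        overlay[res.frame_index, pts[:, 0], pts[:, 1]] = 255
    tifffile.imwrite(path, overlay)


def write_manifest(
    path: str | Path, config: PipelineConfig, n_frames: int
) -> None:
    from . import __version__

    manifest = {
        "flagtrace_version": __version__,
        "n_frames": n_frames,
        "config": dataclasses.asdict(config),
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
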