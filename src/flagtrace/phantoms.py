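"""Synthetic phantoms of a flagellated swimmer with exact ground truth.

The generator draws a variable-width cell body (an ellipse, optionally
tapered) joined to a slender flagellum of constant half-width that beats
as a travelling sine wave, and records per frame the exact sampled
centerline, the body/flagellum masks and the attachment point. This is
the morphology the identification method relies on: an organelle of
approximately constant visible width attached to a body of more varied
width.

Four single-step image degradations emulating common limitations of
microscale imaging are provided: block-average downsampling, additive
Gaussian noise on the 0-255 scale, isotropic Gaussian blur, and
pixel-wise blending with a black-to-white horizontal gradient
(non-uniform illumination).

All geometry uses 0-based ``(row, col)`` coordinates with pixel centres
at integer positions; a pixel is foreground iff its centre lies within
the analytic region.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "PhantomParams",
    "PhantomTruth",
    "DegradationSpec",
    "make_phantom",
    "degrade",
    "write_phantom",
]


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, beat and imaging parameters of a synthetic swimmer.

    The body is an ellipse with semi-axis ``a`` along the flagellar axis
    (columns) and ``b`` transverse to it (rows). The flagellum attaches
    at the ``+col`` vertex of the ellipse and follows, in the body frame,

        y(x, t) = A * g(x) * sin(2*pi*x/lambda - 2*pi*f*t)

    where ``g(x) = clip(x / ramp, 0, 1)`` pins the base to the
    attachment point (a free-amplitude base would detach the filament
    from the body). The ramp length defaults to a quarter wavelength.

    The body drifts at ``body_velocity_px_per_frame``, obliquely to the
    flagellar axis as real swimmers do; at the default magnification
    this corresponds to a swimming speed of a few tens of um/s. The
    motion matters: it is what lets a temporal median over the stack
    estimate the static background, exactly as for a real
    free-swimming cell.
    """

    image_height_px: int = 130
    image_width_px: int = 280
    body_semi_axes_px: tuple[float, float] = (12.0, 7.0)  # (a along cols, b along rows)
    body_center_px: tuple[float, float] = (50.0, 30.0)  # (row, col) at frame 0
    flagellum_length_px: float = 70.0
    flagellum_halfwidth_px: float = 2.0
    wave_amplitude_px: float = 6.0
    wave_wavelength_px: float = 40.0
    wave_frequency_hz: float = 29.0
    frame_rate_hz: float = 200.0
    n_frames: int = 100
    foreground_intensity: float = 60.0
    background_intensity: float = 200.0
    body_velocity_px_per_frame: tuple[float, float] = (0.25, 1.2)
    body_taper: float = 0.0  # 0 = plain ellipse; >0 thins the rear of the body
    amplitude_ramp_px: float | None = None  # default: wavelength / 4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        a, b = self.body_semi_axes_px
        h = self.flagellum_halfwidth_px
        if h < 1:
            raise ValueError(
                "flagellum_halfwidth_px must be >= 1 px (visible width >= 2 px)"
            )
        if h >= min(a, b):
            raise ValueError(
                "flagellum_halfwidth_px must be smaller than both body semi-axes"
            )
        if min(a, b) <= 0:
            raise ValueError("body_semi_axes_px must be positive")
        if self.flagellum_length_px <= 0:
            raise ValueError("flagellum_length_px must be positive")
        if self.wave_amplitude_px < 0:
            raise ValueError("wave_amplitude_px must be non-negative")
        if self.wave_wavelength_px <= 0:
            raise ValueError("wave_wavelength_px must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be a positive integer")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if not (0 <= self.body_taper < 1):
            raise ValueError("body_taper must lie in [0, 1)")
        for name in ("foreground_intensity", "background_intensity"):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise ValueError(f"{name} must lie in [0, 255]")

    @property
    def ramp_px(self) -> float:
        if self.amplitude_ramp_px is not None:
            return self.amplitude_ramp_px
        return self.wave_wavelength_px / 4.0


@dataclass
class PhantomTruth:
    """Exact per-frame ground truth of a generated phantom.

    ``centerline_px[t]`` is an (n, 2) float array of (row, col) samples
    of the flagellar medial line, ordered from attachment to tip;
    ``attachment_px[t]`` the attachment point; masks are boolean images.
    """

    centerline_px: list[np.ndarray]
    attachment_px: np.ndarray  # (n_frames, 2)
    flagellum_mask: np.ndarray  # (n_frames, H, W) bool
    body_mask: np.ndarray  # (n_frames, H, W) bool
    halfwidth_px: float

    @property
    def n_frames(self) -> int:
        return len(self.centerline_px)

    def centerline_pixels(self, frame: int) -> np.ndarray:
        """Rasterized centerline of one frame: unique int (row, col) pixels."""
        pts = np.rint(self.centerline_px[frame]).astype(int)
        return np.unique(pts, axis=0)

    def rescaled(self, factor: int) -> "PhantomTruth":
        """Ground truth in the coordinates of a ``factor``-downsampled image.

        Block averaging maps the block of input pixels ``[k*i, k*i + k)``
        to output pixel ``i``, so coordinates transform as
        ``(c + 0.5) / k - 0.5``.
        """
        k = float(factor)
        scale = lambda c: (np.asarray(c, dtype=float) + 0.5) / k - 0.5  # noqa: E731
        return PhantomTruth(
            centerline_px=[scale(c) for c in self.centerline_px],
            attachment_px=scale(self.attachment_px),
            flagellum_mask=self.flagellum_mask,  # masks stay at native scale
            body_mask=self.body_mask,
            halfwidth_px=self.halfwidth_px / k,
        )


@dataclass(frozen=True)
class DegradationSpec:
    """A single image degradation.

    Exactly one ``kind`` applies per instance; parameters irrelevant
    to that kind are ignored.
    """

    kind: str  # downsample | gaussian_noise | gaussian_blur | gradient_blend
    factor: int = 2
    noise_sd: float = 10.0
    blur_radius_px: float = 2.0
    rng_seed: int = 0

    _KINDS = ("downsample", "gaussian_noise", "gaussian_blur", "gradient_blend")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown degradation kind {self.kind!r}")
        if self.kind == "downsample" and self.factor < 1:
            raise ValueError("downsample factor must be a positive integer")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.blur_radius_px < 0:
            raise ValueError("blur_radius_px must be non-negative")


def _flagellum_curve(params: PhantomParams, frame: int, s: np.ndarray) -> np.ndarray:
    """Body-frame flagellar curve sampled at arc parameter ``s`` (px).

    Returns (len(s), 2) array of (row, col) image coordinates for the
    given frame, including body drift.
    """
    a, _ = params.body_semi_axes_px
    vr, vc = params.body_velocity_px_per_frame
    cr = params.body_center_px[0] + vr * frame
    cc = params.body_center_px[1] + vc * frame
    t = frame / params.frame_rate_hz
    envelope = np.clip(s / params.ramp_px, 0.0, 1.0) if params.ramp_px > 0 else 1.0
    y = (
        params.wave_amplitude_px
        * envelope
        * np.sin(
            2 * np.pi * s / params.wave_wavelength_px
            - 2 * np.pi * params.wave_frequency_hz * t
        )
    )
    rows = cr + y
    cols = cc + a + s
    return np.column_stack([rows, cols])


def _body_mask(params: PhantomParams, frame: int) -> np.ndarray:
    a, b = params.body_semi_axes_px
    vr, vc = params.body_velocity_px_per_frame
    cr = params.body_center_px[0] + vr * frame
    cc = params.body_center_px[1] + vc * frame
    rows = np.arange(params.image_height_px)[:, None]
    cols = np.arange(params.image_width_px)[None, :]
    x = (cols - cc) / a
    if params.body_taper > 0:
        # transverse semi-axis shrinks linearly toward the rear (-col) end
        b_local = b * (1.0 - params.body_taper * (1.0 - (cols - cc + a) / (2 * a)))
        b_local = np.clip(b_local, 1e-6, None)
    else:
        b_local = b
    y = (rows - cr) / b_local
    return (x**2 + y**2) <= 1.0


def _flagellum_mask(
    params: PhantomParams, frame: int, body: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize the flagellar tube; returns (mask, centerline samples)."""
    h = params.flagellum_halfwidth_px
    L = params.flagellum_length_px
    ds = 0.25
    # extend slightly into the body so the junction is always connected
    s_all = np.arange(-2.0 * h, L + ds / 2, ds)
    curve = _flagellum_curve(params, frame, s_all)
    tree = cKDTree(curve)

    r0 = max(0, int(np.floor(curve[:, 0].min() - h - 1)))
    r1 = min(params.image_height_px, int(np.ceil(curve[:, 0].max() + h + 2)))
    c0 = max(0, int(np.floor(curve[:, 1].min() - h - 1)))
    c1 = min(params.image_width_px, int(np.ceil(curve[:, 1].max() + h + 2)))
    rr, cc = np.mgrid[r0:r1, c0:c1]
    pts = np.column_stack([rr.ravel(), cc.ravel()])
    dist, _ = tree.query(pts, workers=-1)
    local = (dist < h).reshape(rr.shape)  # open region: centre strictly inside

    mask = np.zeros((params.image_height_px, params.image_width_px), dtype=bool)
    mask[r0:r1, c0:c1] = local
    mask &= ~body

    s_true = np.arange(0.0, L + ds / 2, ds)
    centerline = _flagellum_curve(params, frame, s_true)
    inside = (
        (centerline[:, 0] >= 0)
        & (centerline[:, 0] <= params.image_height_px - 1)
        & (centerline[:, 1] >= 0)
        & (centerline[:, 1] <= params.image_width_px - 1)
    )
    return mask, centerline[inside]


def make_phantom(params: PhantomParams) -> tuple[np.ndarray, PhantomTruth]:
    """Generate phantom frames and exact ground truth.

    Returns
    -------
    frames : numpy.ndarray, shape (n_frames, H, W), uint8
        Foreground pixels take ``foreground_intensity``, background
        ``background_intensity`` (rounded to 8-bit).
    truth : PhantomTruth
    """
    n = params.n_frames
    H, W = params.image_height_px, params.image_width_px
    frames = np.empty((n, H, W), dtype=np.uint8)
    flag_masks = np.zeros((n, H, W), dtype=bool)
    body_masks = np.zeros((n, H, W), dtype=bool)
    centerlines: list[np.ndarray] = []
    attachments = np.empty((n, 2), dtype=float)

    fg = np.uint8(round(params.foreground_intensity))
    bg = np.uint8(round(params.background_intensity))
    a, _ = params.body_semi_axes_px
    vr, vc = params.body_velocity_px_per_frame

    for t in range(n):
        body = _body_mask(params, t)
        flag, centerline = _flagellum_mask(params, t, body)
        cell = body | flag
        frame = np.full((H, W), bg, dtype=np.uint8)
        frame[cell] = fg
        frames[t] = frame
        body_masks[t] = body
        flag_masks[t] = flag
        centerlines.append(centerline)
        attachments[t] = (
            params.body_center_px[0] + vr * t,
            params.body_center_px[1] + vc * t + a,
        )

    truth = PhantomTruth(
        centerline_px=centerlines,
        attachment_px=attachments,
        flagellum_mask=flag_masks,
        body_mask=body_masks,
        halfwidth_px=params.flagellum_halfwidth_px,
    )
    return frames, truth


def degrade(frame: np.ndarray, spec: DegradationSpec) -> np.ndarray:
    """Apply a single image degradation; returns a float image in [0, 255].

    - ``downsample``: block averaging by ``factor`` in each dimension
      (sensor-binning emulation); trailing rows/cols that do not fill a
      block are dropped.
    - ``gaussian_noise``: adds i.i.d. zero-mean Gaussian noise of
      ``noise_sd`` (0-255 scale) then clips to [0, 255]; deterministic
      given ``rng_seed``.
    - ``gaussian_blur``: isotropic Gaussian convolution,
      sigma = ``blur_radius_px``.
    - ``gradient_blend``: pixel-wise multiplication by a horizontal ramp
      from 0 (left, black) to 1 (right, white).
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("frame must be a 2-D grayscale image")
    if spec.kind == "downsample":
        k = spec.factor
        H, W = img.shape[0] // k * k, img.shape[1] // k * k
        blocks = img[:H, :W].reshape(H // k, k, W // k, k)
        return blocks.mean(axis=(1, 3))
    if spec.kind == "gaussian_noise":
        rng = np.random.default_rng(spec.rng_seed)
        return np.clip(img + rng.normal(0.0, spec.noise_sd, img.shape), 0.0, 255.0)
    if spec.kind == "gaussian_blur":
        if spec.blur_radius_px == 0:
            return img
        return ndimage.gaussian_filter(img, sigma=spec.blur_radius_px)
    if spec.kind == "gradient_blend":
        ramp = np.linspace(0.0, 1.0, img.shape[1])
        return img * ramp[None, :]
    raise AssertionError("unreachable")  # guarded by DegradationSpec


def write_phantom(
    outdir: str | Path, frames: np.ndarray, truth: PhantomTruth, params: PhantomParams
) -> None:
    """Write frames as multi-page 8-bit TIFF plus truth CSV and params JSON.

    Produces ``frames.tif``, ``centerline.csv`` with columns
    (frame, index, row, col), and ``params.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(outdir / "frames.tif", frames.astype(np.uint8))
    rows = []
    for t, cl in enumerate(truth.centerline_px):
        for i, (r, c) in enumerate(cl):
            rows.append((t, i, r, c))
    pd.DataFrame(rows, columns=["frame", "index", "row", "col"]).to_csv(
        outdir / "centerline.csv", index=False
    )
    (outdir / "params.json").write_text(
        json.dumps(dataclasses.asdict(params), indent=2) + "\n"
    )
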