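"""Beat parameters from a time series of flagellar traces.

Summarizes per-frame centerlines into the standard kinematic
descriptors of a planar flagellar beat: dominant temporal frequency,
wavelength, amplitude and flagellar length. The estimators assume the
beat is well approximated by a single-harmonic travelling wave
``y(x, t) = A sin(k x - 2 pi f t + phi)`` in a body-anchored frame —
the waveform reported for *Leishmania*-like swimmers, where Fourier
analysis shows a single prominent temporal frequency.

Estimator choices (each exactly invertible on such a wave):

* traces are aligned to a body frame with origin at the attachment
  point and x-axis along the mean attachment-to-tip direction;
* the dominant frequency is the peak of the Hann-windowed periodogram
  of the transverse displacement at the flagellar midpoint (DC bin
  excluded);
* the amplitude is sqrt(2) times the RMS of that midpoint signal;
* the wavelength comes from a least-squares fit of the travelling wave
  to the pooled (x, y, t) samples at the estimated frequency, solved by
  a golden-section scan over k with the harmonic coefficients obtained
  linearly at each k. The proximal quarter of the flagellum is excluded
  from the fit, where amplitude growth from the anchored base departs
  from the constant-amplitude model;
* the length is the mean trace arclength.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy.optimize import minimize_scalar

from .tracing import FlagellumTrace

__all__ = ["BeatParameters", "beat_parameters"]


@dataclass
class BeatParameters:
    """Kinematic summary of a flagellar beat."""

    dominant_frequency_hz: float
    wavelength_um: float
    amplitude_um: float
    flagellum_length_um: float
    pixel_size_um: float
    frame_rate_hz: float
    n_frames_used: int
    n_frames_excluded: int
    low_confidence: bool = False

    def to_frame(self) -> pd.DataFrame:
        """One-row table with the four headline beat parameters."""
        return pd.DataFrame(
            [
                {
                    "dominant_frequency_hz": self.dominant_frequency_hz,
                    "wavelength_um": self.wavelength_um,
                    "amplitude_um": self.amplitude_um,
                    "flagellum_length_um": self.flagellum_length_um,
                }
            ]
        )


def _body_frame_traces(
    traces: list[FlagellumTrace],
) -> tuple[list[np.ndarray], np.ndarray]:
    """Rotate/translate traces to the common body frame.

    Origin at the attachment point of each frame; x-axis along the mean
    attachment-to-tip unit vector over frames (in image coordinates).
    Returns per-frame (n, 2) arrays of (x, y) and the frame times index.
    """
    chords = []
    for t in traces:
        p = t.points.astype(float)
        chord = p[-1] - p[0]
        n = np.linalg.norm(chord)
        if n > 0:
            chords.append(chord / n)
    if not chords:
        raise ValueError("no usable traces")
    axis = np.mean(chords, axis=0)
    axis /= np.linalg.norm(axis)
    normal = np.array([-axis[1], axis[0]])  # 90 deg CCW in (row, col)
    out = []
    for t in traces:
        rel = t.points.astype(float) - t.points[0].astype(float)
        out.append(np.column_stack([rel @ axis, rel @ normal]))
    return out, axis


def _midpoint_signal(
    body_traces: list[np.ndarray], x_mid: float
) -> np.ndarray:
    """Transverse displacement y at fixed body-frame position x_mid."""
    ys = []
    for xy in body_traces:
        order = np.argsort(xy[:, 0])
        ys.append(float(np.interp(x_mid, xy[order, 0], xy[order, 1])))
    return np.asarray(ys)


def _fit_wavelength(
    body_traces: list[np.ndarray],
    times: np.ndarray,
    freq_hz: float,
    x_min: float,
    x_max: float,
) -> float:
    """Least-squares travelling-wave fit: returns the wavelength 2*pi/k.

    For fixed wavenumber k and frequency f the model
    A sin(kx - wt + phi) = C1 sin(kx - wt) + C2 cos(kx - wt)
    is linear in (C1, C2); k is found by golden-section refinement of a
    coarse scan of the residual.
    """
    xs, ys, ts = [], [], []
    for xy, t in zip(body_traces, times):
        keep = (xy[:, 0] >= x_min) & (xy[:, 0] <= x_max)
        xs.append(xy[keep, 0])
        ys.append(xy[keep, 1])
        ts.append(np.full(keep.sum(), t))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    t = np.concatenate(ts)
    omega = 2 * np.pi * freq_hz

    def sse(k: float) -> float:
        phase = k * x - omega * t
        design = np.column_stack([np.sin(phase), np.cos(phase)])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        return float(np.sum((design @ coef - y) ** 2))

    span = x_max - x_min
    k_grid = 2 * np.pi / np.linspace(max(4.0, span / 20), 4 * span, 200)
    k_grid.sort()
    coarse = min(k_grid, key=sse)
    lo = coarse / 1.3
    hi = coarse * 1.3
    res = minimize_scalar(sse, bounds=(lo, hi), method="bounded")
    return float(2 * np.pi / res.x)


def beat_parameters(
    traces: list[FlagellumTrace | None],
    pixel_size_um: float = 1.0,
    frame_rate_hz: float = 1.0,
) -> BeatParameters:
    """Estimate beat parameters from per-frame flagellar traces.

    ``traces`` is indexed by frame; entries may be ``None`` for
    untraceable frames, which are excluded (their count is reported).
    The result is flagged low-confidence when fewer than two beat
    periods are covered or no spectral peak rises clearly above the
    background.
    """
    if pixel_size_um <= 0 or frame_rate_hz <= 0:
        raise ValueError("pixel_size_um and frame_rate_hz must be positive")
    usable = [(i, t) for i, t in enumerate(traces) if t is not None and len(t) >= 2]
    n_excluded = len(traces) - len(usable)
    if len(usable) < 4:
        raise ValueError("need at least 4 usable traces for spectral analysis")
    indices = np.array([i for i, _ in usable])
    used = [t for _, t in usable]
    times = indices / frame_rate_hz

    body_traces, _ = _body_frame_traces(used)
    length_px = float(np.mean([t.arclength_px for t in used]))
    x_max = float(np.mean([xy[:, 0].max() for xy in body_traces]))
    x_mid = 0.5 * x_max

    y_mid = _midpoint_signal(body_traces, x_mid)
    y_mid = y_mid - y_mid.mean()

    freqs, power = _signal.periodogram(
        y_mid, fs=frame_rate_hz, window="hann", detrend="constant"
    )
    nonzero = freqs > 0
    freqs, power = freqs[nonzero], power[nonzero]
    peak = int(np.argmax(power))
    freq_hz = float(freqs[peak])

    amplitude_px = float(np.sqrt(2.0) * np.sqrt(np.mean(y_mid**2)))

    low_confidence = False
    others = np.delete(power, peak)
    if amplitude_px < 0.5 or (
        others.size and power[peak] < 5.0 * np.median(others)
    ):
        low_confidence = True  # no clear beat above the noise floor
    duration = (times[-1] - times[0]) if len(times) > 1 else 0.0
    if freq_hz * duration < 2.0:
        low_confidence = True  # fewer than two beat periods observed

    if low_confidence and amplitude_px < 0.5:
        wavelength_px = float("nan")
    else:
        wavelength_px = _fit_wavelength(
            body_traces, times, freq_hz, x_min=0.25 * x_max, x_max=x_max
        )

    return BeatParameters(
        dominant_frequency_hz=freq_hz,
        wavelength_um=wavelength_px * pixel_size_um,
        amplitude_um=amplitude_px * pixel_size_um,
        flagellum_length_um=length_px * pixel_size_um,
        pixel_size_um=pixel_size_um,
        frame_rate_hz=frame_rate_hz,
        n_frames_used=len(used),
        n_frames_excluded=n_excluded,
        low_confidence=low_confidence,
    )
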