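"""Ingest fingertip-video frame stacks or raw traces into clean PPG signals.

The camera records fingertip video while the flashlight illuminates the
finger; blood-volume pulsations modulate the light transmitted through the
tissue, so the spatial mean intensity of each frame carries the pulse. The
pipeline is: YUV->RGB conversion, per-channel spatial means combined by an
SD-weighted average (channels with more temporal variance carry more pulse),
linear resampling onto a uniform grid (camera frame rates jitter), and a
zero-phase band-pass that removes baseline drift and high-frequency noise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

logger = logging.getLogger("pulsewave")

# Band-pass for detrending, Hz.  0.5 Hz keeps HR >= 30 bpm; 8 Hz retains the
# harmonics that shape the dicrotic notch while rejecting sensor noise.
DEFAULT_BAND_HZ = (0.5, 8.0)
# Wider band for morphology measurement: the gentler low-pass edge denoises
# without materially shifting summit timing the way the detection band does.
ANALYSIS_BAND_HZ = (0.5, 12.0)
DEFAULT_FILTER_ORDER = 3
# Default uniform resampling rate, matching typical smartphone frame rates.
DEFAULT_FS = 30.0

# BT.601 full-range YUV -> RGB matrix (applied to [Y, U-128, V-128]).
_BT601 = np.array(
    [
        [1.0, 0.0, 1.402],
        [1.0, -0.344136, -0.714136],
        [1.0, 1.772, 0.0],
    ]
)


@dataclass
class FrameStack:
    """Timestamped stack of fingertip video frames.

    frames has shape (T, H, W, 3) with intensities in [0, 255]; timestamps
    are seconds, strictly increasing, one per frame.
    """

    frames: np.ndarray
    timestamps: np.ndarray
    color_space: str = "RGB"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError("frames must have shape (T, H, W, 3)")
        if self.frames.shape[0] < 2:
            raise ValueError("need at least 2 frames")
        if self.timestamps.shape != (self.frames.shape[0],):
            raise ValueError("one timestamp per frame required")
        if not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.color_space not in ("YUV", "RGB"):
            raise ValueError(f"unknown color space {self.color_space!r}")


@dataclass
class PPGSignal:
    """Uniformly sampled single-channel pulse trace."""

    values: np.ndarray
    fs: float
    t0: float = 0.0
    source: str = "synthetic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signal values must be finite")

    @property
    def duration(self) -> float:
        return len(self.values) / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) / self.fs


class RawTrace(NamedTuple):
    """Possibly non-uniformly sampled trace, pre-resampling."""

    values: np.ndarray
    timestamps: np.ndarray


def convert_yuv_to_rgb(stack: FrameStack, max_rejected_frac: float = 0.10) -> FrameStack:
    """Convert a YUV frame stack to RGB with the BT.601 full-range matrix.

    Frames containing non-finite pixels are dropped; more than
    ``max_rejected_frac`` dropped frames is an error.  An already-RGB stack
    is returned unchanged with a warning.
    """
    if stack.color_space == "RGB":
        warnings.warn("stack is already RGB; conversion skipped", stacklevel=2)
        return stack

    finite = np.isfinite(stack.frames).all(axis=(1, 2, 3))
    n_bad = int((~finite).sum())
    if n_bad > max_rejected_frac * len(finite):
        raise ValueError(
            f"{n_bad}/{len(finite)} frames contain non-finite pixels "
            f"(> {max_rejected_frac:.0%} allowed)"
        )
    frames = stack.frames[finite]
    ts = stack.timestamps[finite]

    yuv = frames.copy()
    yuv[..., 1] -= 128.0
    yuv[..., 2] -= 128.0
    rgb = yuv @ _BT601.T
    np.clip(rgb, 0.0, 255.0, out=rgb)
    return FrameStack(frames=rgb, timestamps=ts, color_space="RGB")


def frames_to_ppg(stack: FrameStack) -> RawTrace:
    """Collapse an RGB stack to one trace via the SD-weighted channel average.

    Each frame is reduced to its three spatial channel means; the three mean
    series are combined with weights proportional to each series' temporal
    standard deviation (normalised to sum to 1), so channels carrying more
    pulsatile variance dominate.
    """
    if stack.color_space != "RGB":
        raise ValueError("frames_to_ppg requires an RGB stack")
    means = stack.frames.mean(axis=(1, 2))  # (T, 3)
    sds = means.std(axis=0, ddof=0)
    total = sds.sum()
    if total == 0:
        raise ValueError("no pulsatile content: all channel series are constant")
    weights = sds / total
    logger.debug("SD channel weights: %s", weights)
    values = means @ weights
    return RawTrace(values=values, timestamps=stack.timestamps.copy())


def resample_uniform(
    values: np.ndarray,
    timestamps: np.ndarray,
    fs_target: float = DEFAULT_FS,
    source: str = "video",
) -> PPGSignal:
    """Linearly interpolate a trace onto a uniform grid at ``fs_target``.

    The grid spans [first, last] timestamp.
    """
    values = np.asarray(values, dtype=float)
    timestamps = np.asarray(timestamps, dtype=float)
    if len(values) < 2 or len(values) != len(timestamps):
        raise ValueError("need >=2 paired (timestamp, value) samples")
    if np.any(np.diff(timestamps) <= 0):
        raise ValueError("timestamps must be strictly increasing (no duplicates)")
    if fs_target <= 0:
        raise ValueError("fs_target must be positive")
    t0, t1 = timestamps[0], timestamps[-1]
    n = int(np.floor((t1 - t0) * fs_target)) + 1
    grid = t0 + np.arange(n) / fs_target
    out = np.interp(grid, timestamps, values)
    return PPGSignal(values=out, fs=fs_target, t0=t0, source=source)


def detrend_filter(
    sig: PPGSignal,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
    order: int = DEFAULT_FILTER_ORDER,
    auto_flip: bool = True,
) -> PPGSignal:
    """Zero-phase band-pass a signal, preserving length.

    Removes baseline drift (high-pass edge) and high-frequency noise
    (low-pass edge).  When ``auto_flip`` is set, polarity is oriented so
    systolic upstrokes are maxima using the skewness sign (transmissive
    smartphone PPG is frequently inverted); a flip is logged.
    """
    lo, hi = band_hz
    nyq = sig.fs / 2
    if not 0 < lo < hi < nyq:
        raise ValueError(f"band {band_hz} invalid for fs={sig.fs}")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=sig.fs, output="sos")
    # sosfiltfilt needs more samples than its reflective padding length
    padlen = 3 * (2 * sos.shape[0] + 1)
    if len(sig.values) <= padlen:
        raise ValueError(
            f"signal too short for filtering ({len(sig.values)} <= padlen {padlen})"
        )
    out = sps.sosfiltfilt(sos, sig.values)
    if auto_flip and spstats.skew(out) < 0:
        logger.info("polarity flip applied (negative skew)")
        out = -out
    return PPGSignal(values=out, fs=sig.fs, t0=sig.t0, source=sig.source)


def remove_baseline(
    sig: PPGSignal,
    cutoff_hz: float = DEFAULT_BAND_HZ[0],
    order: int = DEFAULT_FILTER_ORDER,
    flip: bool | None = None,
) -> PPGSignal:
    """Zero-phase high-pass that removes drift without smoothing morphology.

    Unlike :func:`detrend_filter`, no low-pass edge is applied, so sharp
    systolic upstrokes and diastolic summits keep their exact timing; use
    this for waveform measurement and the band-pass for beat detection.
    ``flip`` forces polarity (True inverts); None applies the skewness
    heuristic.
    """
    if not 0 < cutoff_hz < sig.fs / 2:
        raise ValueError(f"cutoff {cutoff_hz} invalid for fs={sig.fs}")
    sos = sps.butter(order, cutoff_hz, btype="highpass", fs=sig.fs, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)
    if len(sig.values) <= padlen:
        raise ValueError("signal too short for filtering")
    out = sps.sosfiltfilt(sos, sig.values)
    if flip is None:
        flip = bool(spstats.skew(out) < 0)
    if flip:
        logger.info("polarity flip applied")
        out = -out
    return PPGSignal(values=out, fs=sig.fs, t0=sig.t0, source=sig.source)


def ingest_frames(
    stack: FrameStack, fs_target: float = DEFAULT_FS, band_hz: tuple[float, float] = DEFAULT_BAND_HZ
) -> PPGSignal:
    """Full frame-stack pipeline: convert, SD-average, resample, detrend."""
    if stack.color_space == "YUV":
        stack = convert_yuv_to_rgb(stack)
    trace = frames_to_ppg(stack)
    sig = resample_uniform(trace.values, trace.timestamps, fs_target, source="video")
    return detrend_filter(sig, band_hz=band_hz)


def load_trace(path) -> RawTrace:
    """Read a 2-column delimited text trace (time_s, value) with header."""
    import pandas as pd

    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("trace file needs (time_s, value) columns")
    return RawTrace(
        values=df.iloc[:, 1].to_numpy(float), timestamps=df.iloc[:, 0].to_numpy(float)
    )


def save_signal(sig: PPGSignal, path) -> None:
    """Write a signal as delimited text (time_s, value)."""
    import pandas as pd

    pd.DataFrame({"time_s": sig.times, "value": sig.values}).to_csv(path, index=False)
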