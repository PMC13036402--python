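"""Locate waveform landmarks within each beat.

Primary landmarks on the waveform itself: left/right valley (LV/RV), early
systolic peak (ESP), dicrotic notch (DN), diastolic peak (DP) and inflection
point (IP).  Secondary landmarks A-H are the alternating extrema of the
second derivative (the acceleration plethysmogram): A/B before the systolic
peak, E/F around the notch, G/H on the diastolic tail; C and D sit between B
and E but are frequently unidentifiable and are therefore optional.

Fallback rules: when no second (diastolic) peak exists — no positive-to-
negative first-derivative crossing after the systolic peak — the DP is taken
as the second-derivative minimum between ESP and RV and the IP is designated
as the DN.  Both fallbacks are flagged so downstream code can count them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .beat_segmentation import BeatSegment

# Savitzky-Golay defaults: cubic fit, ~80 ms window for derivatives and
# height readout; peak/notch amplitude decisions use a wider window so
# noise bumps cannot masquerade as dicrotic structure.
SAVGOL_POLYORDER = 3
SAVGOL_WINDOW_S = 0.08
SAVGOL_WINDOW_AMP_S = 0.15


# Minimum notch dip (fraction of beat amplitude) for an "obvious" second peak.
DIP_FRAC = 0.02


class BeatRejected(ValueError):
    """Raised when a beat's morphology precludes landmark detection."""


@dataclass
class BeatFiducials:
    """Landmark sample indices within one beat (0 = LV sample)."""

    lv: int
    esp: int
    dn: int
    dp: int
    ip: int
    rv: int
    a: int | None = None
    b: int | None = None
    c_pt: int | None = None
    d_pt: int | None = None
    e: int | None = None
    f: int | None = None
    g: int | None = None
    h: int | None = None
    has_second_peak: bool = True
    used_ip_as_dn: bool = False
    # sub-sample refinements (fractional indices) for timing-sensitive
    # intervals; None when refinement was degenerate
    esp_sub: float | None = None
    dp_sub: float | None = None


def _savgol_window(n: int, fs: float, window_s: float = SAVGOL_WINDOW_S) -> int:
    win = int(round(window_s * fs))
    win = max(win, SAVGOL_POLYORDER + 2)
    if win % 2 == 0:
        win += 1
    if win > n:
        win = n if n % 2 == 1 else n - 1
    return win

def smooth_derivatives(beat: BeatSegment) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed first and second derivatives on the beat's sample grid.

    Savitzky-Golay differentiation: a local cubic is fit in a sliding
    ~100 ms window and differentiated analytically, which suppresses the
    noise amplification of finite differences.
    """
    n = len(beat.values)
    if n < 7:
        raise BeatRejected(f"beat too short for differentiation ({n} samples)")
    win = _savgol_window(n, beat.fs)
    delta = 1.0 / beat.fs
    d1 = savgol_filter(beat.values, win, SAVGOL_POLYORDER, deriv=1, delta=delta)
    d2 = savgol_filter(beat.values, win, SAVGOL_POLYORDER, deriv=2, delta=delta)
    return d1, d2


def smooth_values(beat: BeatSegment, window_s: float = SAVGOL_WINDOW_S) -> np.ndarray:
    """Savitzky-Golay smoothed beat amplitudes.

    Amplitude decisions (peak heights, notch dips) are made on smoothed
    series so single-sample noise neither biases height ratios nor fakes
    peaks; ``window_s`` picks the smoothing strength.
    """
    win = _savgol_window(len(beat.values), beat.fs, window_s)
    return savgol_filter(beat.values, win, SAVGOL_POLYORDER)


def _parabolic_vertex(y: np.ndarray, i: int) -> float:
    """Sub-sample extremum position from a 3-point parabola, clamped to +/-1."""
    if i <= 0 or i >= len(y) - 1:
        return float(i)
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom == 0:
        return float(i)
    shift = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return i + float(np.clip(shift, -1.0, 1.0))


def _down_crossings(d1: np.ndarray, lo: int, hi: int) -> list[float]:
    """Fractional indices in (lo, hi) where d1 crosses from >0 to <=0."""
    out = []
    for i in range(lo, hi):
        if d1[i] > 0 and d1[i + 1] <= 0:
            frac = d1[i] / (d1[i] - d1[i + 1]) if d1[i] != d1[i + 1] else 0.0
            out.append(i + frac)
    return out


def _argmax_in(arr: np.ndarray, lo: int, hi: int) -> int | None:
    """Earliest argmax of arr on the inclusive window [lo, hi]."""
    if lo > hi or lo < 0 or hi >= len(arr):
        return None
    return lo + int(np.argmax(arr[lo : hi + 1]))


def _argmin_in(arr: np.ndarray, lo: int, hi: int) -> int | None:
    if lo > hi or lo < 0 or hi >= len(arr):
        return None
    return lo + int(np.argmin(arr[lo : hi + 1]))


def locate_primary_fiducials(
    beat: BeatSegment, d1: np.ndarray, d2: np.ndarray
) -> BeatFiducials:
    """Find LV, ESP, DN, DP, IP, RV for one valley-delimited beat.

    ESP is the global beat maximum; the DP is the first zero crossing of the
    first derivative (positive to negative, with negative curvature) after
    ESP, with sub-sample refinement by linear interpolation.  An "obvious"
    second peak must sit at or below the systolic peak and rise out of a
    preceding notch by at least 2% of the beat amplitude (smoothing-residual
    ripple on flat summits would otherwise fake crossings).  Without such a crossing
    the beat has no obvious second peak: DP falls back to the second-
    derivative minimum on (ESP, RV) and IP to the DN.
    """
    # light smoothing for landmark positions/heights; heavy smoothing for
    # the dip test, where noise bumps must not fake dicrotic structure
    x = smooth_values(beat)
    xa = smooth_values(beat, SAVGOL_WINDOW_AMP_S)
    n = len(x)
    rv = n - 1
    esp = int(np.argmax(x))
    if esp <= 0 or esp >= rv:
        raise BeatRejected("systolic peak at beat boundary")

    amp = xa[esp] - xa.min()

    def _obvious(c: float) -> bool:
        i = int(round(c))
        if d2[i] >= 0 or xa[i] > xa[esp]:
            return False
        dip = xa[esp + 1 : i].min() if i > esp + 1 else xa[i]
        return (xa[i] - dip) >= DIP_FRAC * amp

    crossings = [c for c in _down_crossings(d1, esp + 1, rv) if _obvious(c)]
    if crossings:
        has_second_peak = True
        dp_cross = crossings[0]
        dp = int(round(dp_cross))
        dp = min(max(dp, esp + 1), rv)
        dp_sub = float(dp_cross)
    else:
        has_second_peak = False
        dp = _argmin_in(d2, esp + 1, rv)
        dp_sub = _parabolic_vertex(d2, dp)

    dn = _argmin_in(x, esp + 1, dp)
    if dn is None:
        dn = dp

    used_ip_as_dn = False
    if crossings:
        # IP: last positive->negative d1 transition strictly before the
        # second-peak crossing; with none, the crossing itself serves.
        strictly_before = [c for c in crossings if c < dp_cross - 1e-9]
        ip = int(round(strictly_before[-1])) if strictly_before else dp
    else:
        ip = dn
        used_ip_as_dn = True

    return BeatFiducials(
        lv=0,
        esp=esp,
        dn=dn,
        dp=dp,
        ip=ip,
        rv=rv,
        has_second_peak=has_second_peak,
        used_ip_as_dn=used_ip_as_dn,
        esp_sub=_parabolic_vertex(x, esp),
        dp_sub=dp_sub,
    )


def locate_second_derivative_points(
    beat: BeatSegment, fid: BeatFiducials, d2: np.ndarray
) -> BeatFiducials:
    """Fill the acceleration-plethysmogram points A-H on ``fid``.

    Search windows follow the landmark dependency order (F before E and H;
    H before G); ties break to the earliest index.  An empty window leaves
    the point as None, which marks dependent features missing downstream.
    """
    esp, rv = fid.esp, fid.rv
    fid.a = _argmax_in(d2, 0, esp - 1)
    if fid.a is not None:
        fid.b = _argmin_in(d2, fid.a + 1, esp - 1)
    fid.f = _argmin_in(d2, esp + 1, rv)
    if fid.f is not None:
        fid.e = _argmax_in(d2, esp + 1, fid.f - 1)
        fid.h = _argmin_in(d2, fid.f + 1, rv)
        if fid.h is not None:
            fid.g = _argmax_in(d2, fid.f + 1, fid.h - 1)
    if fid.b is not None and fid.e is not None:
        fid.c_pt = _argmax_in(d2, fid.b + 1, fid.e - 1)
        if fid.c_pt is not None:
            fid.d_pt = _argmin_in(d2, fid.c_pt + 1, fid.e - 1)
    return fid


def locate_all(beat: BeatSegment) -> tuple[BeatFiducials, np.ndarray, np.ndarray]:
    """Convenience wrapper: derivatives, primary landmarks, A-H points."""
    d1, d2 = smooth_derivatives(beat)
    fid = locate_primary_fiducials(beat, d1, d2)
    fid = locate_second_derivative_points(beat, fid, d2)
    return fid, d1, d2
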