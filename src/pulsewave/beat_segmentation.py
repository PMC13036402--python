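"""Beat detection, BBI segmentation, heart rate, and signal-quality gating.

A beat-to-beat interval (BBI) runs valley to valley: the right valley (RV)
is the lowest point of the interval and the preceding interval's RV is the
left valley (LV), so every BBI contains one full systolic-diastolic complex.
Samples whose beats correlate poorly with their own median template are
gated out at SQI < 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signal_ingest import PPGSignal

logger = logging.getLogger("pulsewave")

# Plausible human beat duration window, seconds (30-200 bpm).
BEAT_DURATION_RANGE_S = (0.3, 2.0)
# SQI gate; samples strictly below are discarded.
SQI_THRESHOLD = 0.5
# Template length for length-normalised beat comparison.
_TEMPLATE_LEN = 100
# Minimum relative length for an edge segment to be trusted to hold a valley.
_EDGE_FRAC = 0.15


@dataclass
class BeatSegment:
    """One valley-to-valley beat: half-open sample range [start_idx, end_idx)."""

    start_idx: int
    end_idx: int
    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        if self.start_idx >= self.end_idx:
            raise ValueError("start_idx must precede end_idx")
        self.values = np.asarray(self.values, dtype=float)

    @property
    def duration(self) -> float:
        return (self.end_idx - self.start_idx) / self.fs

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class SampleQuality:
    sqi: float
    n_beats: int
    hr_bpm: float
    pct_fallback_beats: float = 0.0


def _adaptive_prominence(values: np.ndarray) -> float:
    """Prominence threshold from the robust signal range."""
    p10, p90 = np.percentile(values, [10, 90])
    return 0.3 * (p90 - p10)


def _autocorr_period(x: np.ndarray, fs: float) -> float:
    """Dominant beat period from the autocorrelation's strongest lag.

    The full beat pattern repeats at the cardiac period, so the global
    autocorrelation maximum over plausible lags tracks the period even when
    large diastolic waves would fool a naive peak counter.
    """
    x = x - x.mean()
    ac = sps.correlate(x, x, mode="full")[len(x) - 1 :]
    lo = int(BEAT_DURATION_RANGE_S[0] * fs)
    hi = min(int(BEAT_DURATION_RANGE_S[1] * fs), len(ac) - 1)
    if hi <= lo:
        raise ValueError("signal too short to estimate a beat period")
    return (lo + int(np.argmax(ac[lo : hi + 1]))) / fs


def detect_beats(
    sig: PPGSignal,
    min_duration_s: float = BEAT_DURATION_RANGE_S[0],
    max_duration_s: float = BEAT_DURATION_RANGE_S[1],
    valley_signal: PPGSignal | None = None,
) -> list[BeatSegment]:
    """Segment a detrended signal into valley-delimited beats.

    Systolic peaks are found with an adaptive-prominence detector whose
    minimum peak spacing comes from the autocorrelation period estimate (so
    prominent diastolic waves are not counted as beats); valleys are the
    minima between consecutive peaks, plus edge minima when the leading/
    trailing segments are long enough to plausibly contain one.  Beats with
    implausible durations are discarded and logged.

    When ``valley_signal`` is given (a same-length, less aggressively
    filtered copy), valley positions and beat amplitudes are taken from it:
    the narrow detection band stabilises peak finding but displaces the
    diastolic foot, so boundaries are best read off the wider band.
    """
    x = sig.values
    v = valley_signal.values if valley_signal is not None else x
    if valley_signal is not None and len(v) != len(x):
        raise ValueError("valley_signal must match the detection signal length")
    # valley positions are argmin decisions between near-equal minima (beat
    # foot vs dicrotic notch); a smoothed copy keeps noise from flipping them
    win = max(5, int(round(0.15 * sig.fs)))
    if win % 2 == 0:
        win += 1
    vs = sps.savgol_filter(v, win, 3) if len(v) > win else v
    prom = _adaptive_prominence(x)
    if prom <= 0:
        raise ValueError("no beats detected: signal has no oscillatory range")
    period = _autocorr_period(x, sig.fs)
    min_dist = max(1, int(round(max(min_duration_s, 0.7 * period) * sig.fs)))
    peaks, _ = sps.find_peaks(x, prominence=prom, distance=min_dist)
    if len(peaks) < 2:
        raise ValueError("no beats detected: fewer than 2 systolic peaks")

    valleys: list[int] = []
    ipi = float(np.median(np.diff(peaks)))
    if peaks[0] >= _EDGE_FRAC * ipi:
        valleys.append(int(np.argmin(vs[: peaks[0]])))
    for a, b in zip(peaks[:-1], peaks[1:]):
        valleys.append(int(a + np.argmin(vs[a:b])))
    if len(vs) - 1 - peaks[-1] >= _EDGE_FRAC * ipi:
        valleys.append(int(peaks[-1] + np.argmin(vs[peaks[-1] :])))

    beats: list[BeatSegment] = []
    n_dropped = 0
    for s, e in zip(valleys[:-1], valleys[1:]):
        dur = (e - s) / sig.fs
        if not (min_duration_s <= dur <= max_duration_s):
            n_dropped += 1
            continue
        beats.append(BeatSegment(start_idx=s, end_idx=e, values=v[s : e + 1], fs=sig.fs))
    if n_dropped:
        logger.info("discarded %d beats with implausible duration", n_dropped)
    if len(beats) < 1:
        raise ValueError("no beats detected after duration filtering")
    return beats


def segment_signal(sig: PPGSignal) -> list[BeatSegment]:
    """Dual-band beat segmentation of a raw uniformly sampled signal.

    Detects beats on the narrow detection band and reads boundaries and
    amplitudes from the wider analysis band, with a consistent polarity
    decision across both.
    """
    from scipy.stats import skew

    from .signal_ingest import ANALYSIS_BAND_HZ, detrend_filter

    det = detrend_filter(sig, auto_flip=False)
    flip = bool(skew(det.values) < 0)
    hi = min(ANALYSIS_BAND_HZ[1], 0.45 * sig.fs)
    analysis = detrend_filter(sig, band_hz=(ANALYSIS_BAND_HZ[0], hi), auto_flip=False)
    if flip:
        det = PPGSignal(values=-det.values, fs=sig.fs, t0=sig.t0, source=sig.source)
        analysis = PPGSignal(
            values=-analysis.values, fs=sig.fs, t0=sig.t0, source=sig.source
        )
    return detect_beats(det, valley_signal=analysis)


def compute_hr(beats: list[BeatSegment]) -> float:
    """Heart rate in bpm as 60 / median BBI duration."""
    if not beats:
        raise ValueError("cannot compute HR from an empty beat list")
    return 60.0 / float(np.median([b.duration for b in beats]))


def _normalize_beat(values: np.ndarray, n: int = _TEMPLATE_LEN) -> np.ndarray:
    grid = np.linspace(0, 1, n)
    src = np.linspace(0, 1, len(values))
    return np.interp(grid, src, values)


def compute_sqi(beats: list[BeatSegment]) -> float:
    """Signal quality index in [0, 1]: waveform self-similarity x rhythm regularity.

    Each beat is resampled to a common length and correlated with the
    element-wise median template; the mean correlation is multiplied by a
    rhythm-regularity factor, 1 minus the coefficient of variation of beat
    durations, and clipped to [0, 1].  The second factor matters because
    valley-delimited segments of pure noise still share a generic rise-fall
    envelope (each contains one detected peak by construction) and would
    otherwise correlate spuriously; erratic segment durations expose them.
    Zero-variance beats are excluded from the template.
    """
    if len(beats) < 2:
        raise ValueError("SQI needs at least 2 beats")
    norm = [_normalize_beat(b.values) for b in beats]
    usable = [v for v in norm if np.std(v) > 0]
    if not usable:
        raise ValueError("all beats have zero variance")
    template = np.median(np.stack(usable), axis=0)
    if np.std(template) == 0:
        return 0.0
    corrs = [
        np.corrcoef(v, template)[0, 1] for v in norm if np.std(v) > 0
    ]
    durations = np.array([b.duration for b in beats])
    regularity = 1.0 - durations.std(ddof=0) / durations.mean()
    return float(np.clip(np.mean(corrs) * np.clip(regularity, 0.0, 1.0), 0.0, 1.0))


def sample_quality(beats: list[BeatSegment], pct_fallback: float = 0.0) -> SampleQuality:
    return SampleQuality(
        sqi=compute_sqi(beats),
        n_beats=len(beats),
        hr_bpm=compute_hr(beats),
        pct_fallback_beats=pct_fallback,
    )


@dataclass
class FilterReport:
    """Accounting for the sample-filtering pipeline.

    Percentages are rounded to 1 decimal; the per-participant and per-sample
    means use 2 decimals and nearest integer respectively, matching the
    precision conventions of cohort bookkeeping tables.
    """

    n_initial: int
    n_participants: int | None
    total_bbis: int | None
    n_feature_loss: int
    n_after_feature_loss: int
    pct_after_feature_loss: float
    n_low_sqi: int
    n_final: int

    @property
    def mean_samples_per_participant(self) -> float | None:
        if not self.n_participants:
            return None
        return round(self.n_initial / self.n_participants, 2)

    @property
    def mean_bbis_per_sample(self) -> int | None:
        if self.total_bbis is None or self.n_initial == 0:
            return None
        return int(round(self.total_bbis / self.n_initial))

    @property
    def pct_final(self) -> float:
        return round(100.0 * self.n_final / self.n_initial, 1) if self.n_initial else 0.0


def filter_samples(records: list, sqi_threshold: float = SQI_THRESHOLD):
    """Drop incomplete records, then low-SQI records; return survivors + report.

    ``records`` are sample feature records exposing ``incomplete``, ``sqi``,
    ``participant_id`` and ``n_beats`` attributes.  Feature-loss exclusion
    (any missing core feature) is applied before the SQI gate, mirroring the
    two-stage exclusion of the acquisition pipeline.
    """
    n0 = len(records)
    participants = {r.participant_id for r in records if r.participant_id is not None}
    bbi_counts = [r.n_beats for r in records if r.n_beats is not None]
    complete = [r for r in records if not r.incomplete]
    survivors = [r for r in complete if r.sqi is None or r.sqi >= sqi_threshold]
    report = FilterReport(
        n_initial=n0,
        n_participants=len(participants) or None,
        total_bbis=int(sum(bbi_counts)) if bbi_counts else None,
        n_feature_loss=n0 - len(complete),
        n_after_feature_loss=len(complete),
        pct_after_feature_loss=round(100.0 * len(complete) / n0, 1) if n0 else 0.0,
        n_low_sqi=len(complete) - len(survivors),
        n_final=len(survivors),
    )
    if not survivors:
        logger.warning("all %d records filtered out", n0)
    return survivors, report
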