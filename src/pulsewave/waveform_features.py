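"""Per-beat waveform features, HR/stature normalization, sample aggregation.

Three feature domains are computed per beat and summarised per sample by the
median across beats:

* time domain — intervals between landmarks (crest time CT, notch time NT,
  diastolic time DT, peak-to-peak time PPT, ...), landmark heights above the
  valley-to-valley baseline, reflection indices (RI = diastolic peak height /
  systolic peak height), stiffness index SI = body height / PPT, and the
  areas A1/A2 flanking the dicrotic notch with their ratio IPA = A2/A1;
* curvature domain — ratios of the acceleration-plethysmogram extrema B..H
  to the first maximum A, plus the (modified) aging index AI = B/A - E/A;
* frequency domain — band-integrated harmonic strengths of the Welch power
  spectral density, their relative shares rPSD_i, the Fourier-series weights
  V_0..V_6 of the median beat template, the normalized harmonic area NHA and
  IHAR = (1 - NHA) / IPA.

Duration-type features are normalized to a reference heart rate of 75 bpm
and PPT-like transit intervals additionally to a reference stature of
170 cm, to suppress HR- and height-driven between-person variability.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .beat_segmentation import BeatSegment, compute_hr, compute_sqi, detect_beats
from .fiducials import (
    SAVGOL_POLYORDER,
    BeatFiducials,
    BeatRejected,
    _savgol_window,
    locate_all,
)
from .signal_ingest import PPGSignal

logger = logging.getLogger("pulsewave")

REF_HR_BPM = 75.0
REF_HEIGHT_CM = 170.0
N_HARMONICS = 6
# Minimum beats for a sample-level median to be considered stable.
MIN_BEATS_PER_SAMPLE = 5
# A core feature covered in fewer than this fraction of beats marks the
# sample incomplete (feature-loss exclusion path).
MIN_FEATURE_COVERAGE = 0.5

# Features measured in seconds, rescaled by hr/75.
DURATION_FEATURES = ("ppt", "eppt", "ct", "nt", "dt", "fn", "sr", "nv")
# Transit-time features additionally rescaled by 170/height.
PATHLENGTH_FEATURES = ("ppt", "eppt")

TIME_FEATURES = (
    "si", "ppt", "eppt", "ri", "eri", "esi", "ct", "nt", "dt", "is_slope",
    "rca", "rda", "fn", "sr", "nv", "nh", "sph", "a1", "a2", "ipa",
)
CURVATURE_FEATURES = ("b_a", "e_a", "f_a", "g_a", "h_a", "ai")
SPECTRAL_FEATURES = tuple(
    [f"s{i}" for i in range(1, N_HARMONICS + 1)]
    + [f"rpsd{i}" for i in range(1, N_HARMONICS + 1)]
    + [f"v{i}" for i in range(N_HARMONICS + 1)]
    + ["nha", "ihar"]
)

#: Domain label for each feature, used by correlation-based selection.
FEATURE_DOMAINS: dict[str, str] = (
    {f: "time" for f in TIME_FEATURES}
    | {"ipp": "time"}
    | {f: "curvature" for f in CURVATURE_FEATURES}
    | {f: "frequency" for f in SPECTRAL_FEATURES}
)

# Features whose absence in a beat counts toward feature loss.  Excluded:
# the optional C/D points; IHAR (undefined whenever IPA is 0); and the
# curvature points that live in few-sample windows and are frequently
# unidentifiable at modest sampling rates — E (pinched between the systolic
# apex and the F-wave, hence E/A and AI) and G (absent whenever the
# diastolic tail has no fourth curvature oscillation).  The robust trio
# |B/A|, |F/A|, |H/A| carries the curvature domain's completeness gate.
CORE_BEAT_FEATURES = (
    "si", "ppt", "ri", "ct", "nt", "dt", "fn", "sr", "nv", "nh", "sph",
    "a1", "a2", "b_a", "f_a", "h_a",
)


@dataclass
class SampleFeatureRecord:
    """One recording's aggregated, normalized feature vector."""

    participant_id: str
    sample_id: str
    hr_bpm: float
    sqi: float | None
    n_beats: int
    features: dict[str, float]
    height_cm: float = REF_HEIGHT_CM
    sbp: float = np.nan
    dbp: float = np.nan
    incomplete: bool = False
    missing: tuple[str, ...] = ()

    def to_row(self) -> dict:
        row = {
            "participant_id": self.participant_id,
            "sample_id": self.sample_id,
            "hr_bpm": self.hr_bpm,
            "sqi": self.sqi,
            "n_beats": self.n_beats,
            "height_cm": self.height_cm,
            "sbp": self.sbp,
            "dbp": self.dbp,
            "incomplete": self.incomplete,
        }
        row.update(self.features)
        return row


def _shoelace(pts: list[tuple[float, float]]) -> float:
    """Polygon area by the shoelace formula (vertices in order)."""
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def _baseline(beat: BeatSegment) -> np.ndarray:
    """Linear LV->RV baseline under the beat."""
    x = beat.values
    n = len(x)
    return x[0] + (x[-1] - x[0]) * np.arange(n) / (n - 1)


def _estimate_esp(
    beat: BeatSegment, fid: BeatFiducials, d1: np.ndarray, base: np.ndarray
) -> tuple[float, float]:
    """Tangent-intersection estimate of the undistorted systolic peak.

    Camera auto-exposure smooths the systolic apex, so the peak's true
    height/timing are estimated by intersecting the tangent at the point of
    maximal upstroke with the tangent at the steepest early decay.  Returns
    (time_s, height-above-baseline); NaNs when the tangents are parallel.
    """
    fs = beat.fs
    up = int(np.argmax(d1[: fid.esp + 1]))
    dec_end = max(fid.dn, fid.esp + 1)
    dec = fid.esp + int(np.argmin(d1[fid.esp : dec_end + 1]))
    m1, m2 = d1[up], d1[dec]
    if m1 <= 0 or m1 == m2:
        return np.nan, np.nan
    t1, y1 = up / fs, beat.values[up]
    t2, y2 = dec / fs, beat.values[dec]
    t_star = (y2 - y1 + m1 * t1 - m2 * t2) / (m1 - m2)
    y_star = y1 + m1 * (t_star - t1)
    # baseline value at t_star by linear interpolation
    base_star = np.interp(t_star * fs, np.arange(len(base)), base)
    return t_star, y_star - base_star


def compute_time_features(
    beat: BeatSegment, fid: BeatFiducials, d1: np.ndarray, height_m: float
) -> dict[str, float]:
    """Time-domain features of one beat (heights above the LV-RV baseline)."""
    fs = beat.fs
    t = lambda i: i / fs
    base = _baseline(beat)
    # heights read off a lightly smoothed beat so single-sample noise does
    # not bias peak-height ratios; same window as the derivative smoothing
    win = _savgol_window(len(beat.values), fs)
    smooth = sps.savgol_filter(beat.values, win, SAVGOL_POLYORDER)
    h = smooth - base

    # sub-sample landmark times where available, for quantization-free
    # intervals at modest sampling rates
    t_esp = (fid.esp_sub if fid.esp_sub is not None else fid.esp) / fs
    t_dp = (fid.dp_sub if fid.dp_sub is not None else fid.dp) / fs

    ct = t_esp - t(fid.lv)
    nt = t(fid.dn - fid.lv)
    dt = t(fid.rv) - t_esp
    ppt = t_dp - t_esp
    fn = t(fid.dn) - t_esp
    sr = t(fid.rv) - t_dp
    nv = t(fid.rv - fid.dn)

    esph = h[fid.esp]
    dph = h[fid.dp]
    nh = h[fid.dn]

    t_est, esph_est = _estimate_esp(beat, fid, d1, base)
    eppt = t_dp - t_est if np.isfinite(t_est) else np.nan

    a1 = _shoelace(
        [(t(fid.lv), 0.0), (t(fid.esp), esph), (t(fid.dn), nh), (t(fid.dn), 0.0)]
    )
    a2 = _shoelace([(t(fid.ip), h[fid.ip]), (t(fid.dn), nh), (t(fid.rv), 0.0)])

    def _ratio(num, den):
        return num / den if den and np.isfinite(den) and den != 0 else np.nan

    return {
        "si": _ratio(height_m, ppt),
        "ppt": ppt,
        "eppt": eppt,
        "ri": _ratio(dph, esph),
        "eri": _ratio(dph, esph_est),
        "esi": _ratio(height_m, eppt),
        "ct": ct,
        "nt": nt,
        "dt": dt,
        "is_slope": d1[fid.ip],
        "rca": _ratio(ct, nt),
        "rda": _ratio(nt, ct + dt),
        "fn": fn,
        "sr": sr,
        "nv": nv,
        "nh": nh,
        "sph": dph,
        "a1": a1,
        "a2": a2,
        "ipa": _ratio(a2, a1),
    }


def compute_curvature_features(fid: BeatFiducials, d2: np.ndarray) -> dict[str, float]:
    """Acceleration-plethysmogram ratios |B/A| ... |H/A| and the aging index.

    B/A, F/A and H/A are physiologically negative and are reported as
    absolute values; AI keeps the signed ratios: AI = B/A - E/A.
    """
    out = {k: np.nan for k in CURVATURE_FEATURES}
    if fid.a is None or d2[fid.a] == 0:
        return out
    d2a = d2[fid.a]
    ratios = {}
    for name, idx in (("b", fid.b), ("e", fid.e), ("f", fid.f), ("g", fid.g), ("h", fid.h)):
        ratios[name] = d2[idx] / d2a if idx is not None else np.nan
    out["b_a"] = abs(ratios["b"])
    out["e_a"] = abs(ratios["e"])
    out["f_a"] = abs(ratios["f"])
    out["g_a"] = abs(ratios["g"])
    out["h_a"] = abs(ratios["h"])
    out["ai"] = ratios["b"] - ratios["e"]
    return out


# ---------------------------------------------------------------------------
# Frequency domain
# ---------------------------------------------------------------------------

_F0_BAND_HZ = (40.0 / 60.0, 180.0 / 60.0)  # plausible HR fundamentals
_WELCH_SEG_S = 20.0
_TEMPLATE_LEN = 200


def _harmonic_peaks(freqs: np.ndarray, psd: np.ndarray, f0: float, n: int) -> np.ndarray:
    """Refine the locations of harmonics 1..n+1 as local PSD maxima."""
    peaks = []
    for i in range(1, n + 2):
        lo, hi = (i - 0.4) * f0, (i + 0.4) * f0
        m = (freqs >= lo) & (freqs <= hi)
        peaks.append(freqs[m][np.argmax(psd[m])] if m.any() else i * f0)
    return np.asarray(peaks)


def _fit_fourier_template(template: np.ndarray, n: int) -> np.ndarray:
    """Least-squares Fourier-series weights V_0..V_n of a one-period template."""
    L = len(template)
    tau = np.arange(L) / L
    cols = [np.ones(L)]
    for i in range(1, n + 1):
        cols.append(np.sin(2 * np.pi * i * tau))
        cols.append(np.cos(2 * np.pi * i * tau))
    X = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(X, template, rcond=None)
    v = [coef[0]]
    for i in range(n):
        v.append(float(np.hypot(coef[1 + 2 * i], coef[2 + 2 * i])))
    return np.asarray(v)


def _median_template(beats: list[BeatSegment], length: int = _TEMPLATE_LEN) -> np.ndarray:
    grid = np.linspace(0, 1, length, endpoint=False)
    stack = [
        np.interp(grid, np.linspace(0, 1, len(b.values)), b.values) for b in beats
    ]
    return np.median(np.stack(stack), axis=0)


def compute_spectral_features(
    sig: PPGSignal,
    ipa_median: float | None = None,
    beats: list[BeatSegment] | None = None,
    n_harmonics: int = N_HARMONICS,
) -> dict[str, float]:
    """Harmonic-band PSD strengths, rPSD shares, Fourier weights, NHA, IHAR.

    The strength S_i of the i-th cardiac harmonic is the PSD area between
    the midpoints flanking its spectral peak (the first band starts halfway
    between DC and the fundamental peak); integrating over bands rather than
    reading peak heights makes the measure robust to noise.  Shares are
    normalized over harmonics 1..6 (the DC band reflects total energy, not
    contour, and harmonics above 6 are negligible).
    """
    if sig.duration < 30.0:
        raise ValueError("spectral features need >= 30 s of signal")
    nperseg = min(len(sig.values), int(round(_WELCH_SEG_S * sig.fs)))
    freqs, psd = sps.welch(sig.values, fs=sig.fs, nperseg=nperseg)

    band = (freqs >= _F0_BAND_HZ[0]) & (freqs <= _F0_BAND_HZ[1])
    if not band.any() or psd[band].max() <= 0:
        raise ValueError("fundamental not detectable in PSD")
    f0 = float(freqs[band][np.argmax(psd[band])])

    peaks = _harmonic_peaks(freqs, psd, f0, n_harmonics)
    mids = np.empty(n_harmonics + 1)
    mids[0] = peaks[0] / 2.0  # midpoint between DC and the fundamental
    for i in range(1, n_harmonics + 1):
        mids[i] = (peaks[i - 1] + peaks[i]) / 2.0

    s = np.empty(n_harmonics)
    for i in range(n_harmonics):
        m = (freqs >= mids[i]) & (freqs <= mids[i + 1])
        s[i] = np.trapezoid(psd[m], freqs[m]) if m.sum() >= 2 else 0.0
    total = s.sum()
    if total <= 0:
        raise ValueError("empty harmonic spectrum")
    rpsd = s / total
    nha = s[1:].sum() / total

    if beats is None:
        beats = detect_beats(sig)
    v = _fit_fourier_template(_median_template(beats), n_harmonics)

    out: dict[str, float] = {}
    for i in range(n_harmonics):
        out[f"s{i + 1}"] = float(s[i])
        out[f"rpsd{i + 1}"] = float(rpsd[i])
    for i in range(n_harmonics + 1):
        out[f"v{i}"] = float(v[i])
    out["nha"] = float(nha)
    out["ihar"] = (
        (1.0 - nha) / ipa_median
        if ipa_median is not None and np.isfinite(ipa_median) and ipa_median > 0
        else np.nan
    )
    return out


# ---------------------------------------------------------------------------
# Normalization and aggregation
# ---------------------------------------------------------------------------

def normalize_features(
    feats: dict[str, float],
    hr_bpm: float,
    height_cm: float,
    ref_hr: float = REF_HR_BPM,
    ref_height_cm: float = REF_HEIGHT_CM,
) -> dict[str, float]:
    """Rescale duration features to 75 bpm and transit times to 170 cm.

    Durations are multiplied by hr/75, mapping each beat onto the 0.8 s
    reference period; PPT-like intervals get a further 170/height factor
    since reflected-wave transit scales with vascular path length.  SI and
    ESI are recomputed from the normalized intervals at the reference
    stature; pure ratios and spectral features are untouched.
    """
    if hr_bpm <= 0 or height_cm <= 0:
        raise ValueError("hr_bpm and height_cm must be positive")
    out = dict(feats)
    f_hr = hr_bpm / ref_hr
    f_h = ref_height_cm / height_cm
    for name in DURATION_FEATURES:
        if name in out and np.isfinite(out[name]):
            out[name] = out[name] * f_hr
    for name in PATHLENGTH_FEATURES:
        if name in out and np.isfinite(out[name]):
            out[name] = out[name] * f_h
    ref_height_m = ref_height_cm / 100.0
    if "ppt" in out:
        out["si"] = ref_height_m / out["ppt"] if out.get("ppt") else np.nan
    if "eppt" in out:
        out["esi"] = ref_height_m / out["eppt"] if out.get("eppt") else np.nan
    logger.debug("normalization factors hr=%.3f height=%.3f", f_hr, f_h)
    return out


def aggregate_sample(
    per_beat_feats: list[dict[str, float]],
    fallback_flags: list[bool],
    participant_id: str,
    sample_id: str,
    hr_bpm: float,
    sqi: float | None = None,
    height_cm: float = REF_HEIGHT_CM,
    sbp: float = np.nan,
    dbp: float = np.nan,
    min_beats: int = MIN_BEATS_PER_SAMPLE,
) -> SampleFeatureRecord:
    """Median-aggregate per-beat features into one sample record.

    Medians skip missing values; a core feature present in fewer than half
    the beats, or fewer than ``min_beats`` beats overall, flags the record
    incomplete (the feature-loss exclusion path).  IPP is the percentage of
    beats without an obvious second peak.
    """
    n = len(per_beat_feats)
    names: set[str] = set()
    for f in per_beat_feats:
        names.update(f)
    agg: dict[str, float] = {}
    missing: list[str] = []
    for name in sorted(names):
        vals = np.array([f.get(name, np.nan) for f in per_beat_feats], dtype=float)
        ok = np.isfinite(vals)
        agg[name] = float(np.median(vals[ok])) if ok.any() else np.nan
        if name in CORE_BEAT_FEATURES and ok.mean() < MIN_FEATURE_COVERAGE:
            missing.append(name)
    agg["ipp"] = 100.0 * (sum(fallback_flags) / n) if n else np.nan
    incomplete = n < min_beats or bool(missing)
    return SampleFeatureRecord(
        participant_id=participant_id,
        sample_id=sample_id,
        hr_bpm=hr_bpm,
        sqi=sqi,
        n_beats=n,
        features=agg,
        height_cm=height_cm,
        sbp=sbp,
        dbp=dbp,
        incomplete=incomplete,
        missing=tuple(missing),
    )


def extract_sample_record(
    sig: PPGSignal,
    participant_id: str,
    sample_id: str,
    height_cm: float = REF_HEIGHT_CM,
    sbp: float = np.nan,
    dbp: float = np.nan,
    spectral: bool = True,
    normalize: bool = True,
) -> SampleFeatureRecord:
    """Full per-sample pipeline: beats -> fiducials -> features -> record.

    ``sig`` is a uniformly sampled signal (raw or pre-filtered).  Beats are
    detected on the narrow detection band, whose aggressive low-pass
    stabilises peak finding but subtly shifts summit timing; morphology is
    therefore measured on a second, wider-band copy sliced at the detected
    beat boundaries, with residual noise handled by the Savitzky-Golay
    smoothing of the fiducial stage.
    """
    from scipy import stats as _spstats

    from .signal_ingest import ANALYSIS_BAND_HZ, detrend_filter

    det = detrend_filter(sig, auto_flip=False)
    flip = bool(_spstats.skew(det.values) < 0)
    if flip:
        det = PPGSignal(values=-det.values, fs=det.fs, t0=det.t0, source=det.source)
    hi = min(ANALYSIS_BAND_HZ[1], 0.45 * sig.fs)
    analysis = detrend_filter(sig, band_hz=(ANALYSIS_BAND_HZ[0], hi), auto_flip=False)
    if flip:
        analysis = PPGSignal(
            values=-analysis.values, fs=sig.fs, t0=sig.t0, source=sig.source
        )

    beats = detect_beats(det, valley_signal=analysis)
    hr = compute_hr(beats)
    sqi = compute_sqi(beats) if len(beats) >= 2 else None
    height_m = height_cm / 100.0

    per_beat: list[dict[str, float]] = []
    flags: list[bool] = []
    kept_beats: list[BeatSegment] = []
    for beat in beats:
        try:
            fid, d1, d2 = locate_all(beat)
        except BeatRejected:
            continue
        feats = compute_time_features(beat, fid, d1, height_m)
        feats.update(compute_curvature_features(fid, d2))
        if normalize:
            feats = normalize_features(feats, hr, height_cm)
        per_beat.append(feats)
        flags.append(not fid.has_second_peak)
        kept_beats.append(beat)

    record = aggregate_sample(
        per_beat, flags, participant_id, sample_id, hr, sqi,
        height_cm=height_cm, sbp=sbp, dbp=dbp,
    )
    if spectral and per_beat:
        try:
            spec = compute_spectral_features(
                analysis, ipa_median=record.features.get("ipa"), beats=kept_beats
            )
            record.features.update(spec)
        except ValueError as err:
            logger.info("spectral features unavailable: %s", err)
    return record
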