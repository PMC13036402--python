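"""Ground-truth-labelled synthetic signals, frame stacks, and cohorts.

The beat model superposes a forward (systolic) wave, a diastolic runoff
pedestal, and a delayed, attenuated reflected wave — the minimal morphology
that produces a systolic peak, dicrotic notch and diastolic peak at
realistic heights, and therefore exposes every landmark the extractor looks
for.  Each generated train ships a manifest of true landmark times and the
derived PPT/RI/CT/DT, which are the ground truth for recovery tests.
Cohort generation layers the study's nested design on top: participants
carry latent waveform parameters, repeated samples vary around them, and
psychological scores depend linearly on participant-mean features with
controllable effect sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .signal_ingest import FrameStack, PPGSignal

logger = logging.getLogger("pulsewave")

#: Instrument score ranges (SWLS 5-35, SVS 7-49, PANAS subscales 10-50,
#: PHQ-9 0-27, GAD-7 0-21, SAM 1-9).
SCALE_RANGES: dict[str, tuple[int, int]] = {
    "swls": (5, 35),
    "svs": (7, 49),
    "panas_p": (10, 50),
    "panas_n": (10, 50),
    "phq9": (0, 27),
    "gad7": (0, 21),
    "valence": (1, 9),
    "arousal": (1, 9),
}

_DENSE_PER_PERIOD = 4000  # dense-grid resolution for ground-truth landmarks


@dataclass
class BeatModelParams:
    """Forward + runoff + reflected beat model with noise and sampling settings.

    ``reflection_lag``/``reflection_ratio`` program the reflected wave and
    approximately set the landmark PPT and RI (the exact values, which
    include the small summit shifts induced by wave superposition, are in
    the generated manifest).  ``noise_snr_db=None`` disables noise;
    ``drift_amp`` adds slow sinusoidal baseline wander.
    """

    period: float = 0.8
    systolic_amp: float = 1.0
    systolic_center: float = 0.25
    systolic_width: float = 0.10
    systolic_decay_width: float = 0.065
    systolic_power: float = 4.0
    reflection_ratio: float = 0.45
    reflection_lag: float = 0.26
    reflection_width: float = 0.06
    runoff_amp: float = 0.25
    runoff_center_offset: float = 0.10
    runoff_width: float = 0.15
    notch_depth: float = 0.0
    noise_snr_db: float | None = 20.0
    drift_amp: float = 0.3
    drift_freq: float = 0.1
    fs: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.reflection_ratio <= 1:
            raise ValueError("reflection_ratio must lie in [0, 1]")
        if self.reflection_lag >= self.period:
            raise ValueError("reflection_lag must be below the beat period")
        if self.fs < 20:
            raise ValueError("fs must be at least 20 Hz")
        min_width = min(self.systolic_width, self.reflection_width)
        # Gaussian of width sigma has ~all energy below 3/(2*pi*sigma) Hz
        if self.fs < 3.0 / (np.pi * min_width):
            raise ValueError("fs below Nyquist for the chosen Gaussian widths")


def _beat_template(p: BeatModelParams, t: np.ndarray) -> np.ndarray:
    """Noiseless beat waveform at within-beat times t (0 = LV).

    Three components: an asymmetric generalized Gaussian (exponent
    ``systolic_power``) for the systolic wave — its flat, rounded summit and
    steep flanks mimic the fast anacrotic limb and broad apex of arterial
    pulses and keep the strongest curvature off the summit itself, as in
    measured acceleration plethysmograms; a broad diastolic runoff pedestal
    that keeps the dicrotic notch well above the valley floor; and a
    delayed, scaled Gaussian reflected wave riding on that runoff.
    """
    sys_c = p.systolic_center
    refl_c = sys_c + p.reflection_lag
    # smooth rise->decay width transition keeps curvature continuous
    blend = 0.5 * (1.0 + np.tanh((t - sys_c) / 0.04))
    width = p.systolic_width + (p.systolic_decay_width - p.systolic_width) * blend
    z = np.abs(t - sys_c) / width
    out = p.systolic_amp * np.exp(-0.5 * z**p.systolic_power)
    out += (
        p.runoff_amp
        * p.systolic_amp
        * np.exp(-0.5 * ((t - sys_c - p.runoff_center_offset) / p.runoff_width) ** 2)
    )
    out += (
        p.reflection_ratio
        * p.systolic_amp
        * np.exp(-0.5 * ((t - refl_c) / p.reflection_width) ** 2)
    )
    if p.notch_depth:
        notch_c = (sys_c + refl_c) / 2.0
        out -= (
            p.notch_depth
            * p.systolic_amp
            * np.exp(-0.5 * ((t - notch_c) / (p.reflection_lag / 4)) ** 2)
        )
    return out


from .fiducials import DIP_FRAC as _DIP_FRAC  # same "obvious second peak" rule as the extractor


def _template_truth(p: BeatModelParams) -> dict:
    """Dense-grid landmark ground truth for one noiseless periodic beat.

    Works on the wrapped (periodic) waveform so the true valleys — which
    may sit slightly off the nominal beat boundary where adjacent tails
    overlap — delimit the beat, and heights are measured above the
    valley-to-valley chord, matching the extractor's convention.
    """
    # dense grid over one period plus margins, with neighbour-beat tails
    t = np.linspace(-0.5 * p.period, 1.5 * p.period, 2 * _DENSE_PER_PERIOD)
    y = np.zeros_like(t)
    for shift in (-1.0, 0.0, 1.0):
        y += _beat_template(p, t + shift * p.period)
    # true valleys near the nominal boundaries 0 and period
    m0 = (t >= -0.3 * p.period) & (t <= 0.3 * p.period)
    i_lv = np.flatnonzero(m0)[np.argmin(y[m0])]
    m1 = (t >= 0.7 * p.period) & (t <= 1.3 * p.period)
    i_rv = np.flatnonzero(m1)[np.argmin(y[m1])]
    seg = slice(i_lv, i_rv + 1)
    ts, ys = t[seg], y[seg]
    chord = ys[0] + (ys[-1] - ys[0]) * (ts - ts[0]) / (ts[-1] - ts[0])
    h = ys - chord

    i_esp = int(np.argmax(h))
    d1 = np.gradient(ys, ts)
    after = np.arange(i_esp + 1, len(ts) - 1)
    down = after[(d1[after] > 0) & (d1[after + 1] <= 0)]
    amp = h[i_esp] - h.min()
    i_dp = None
    for cand in down:
        cand = int(cand) + 1
        dip = h[i_esp + 1 : cand].min() if cand > i_esp + 1 else h[cand]
        if h[cand] <= h[i_esp] and (h[cand] - dip) >= _DIP_FRAC * amp:
            i_dp = cand
            break
    has_second_peak = i_dp is not None
    if not has_second_peak:
        d2 = np.gradient(d1, ts)
        i_dp = i_esp + 1 + int(np.argmin(d2[i_esp + 1 :]))
    i_dn = i_esp + 1 + int(np.argmin(ys[i_esp + 1 : i_dp + 1]))
    return {
        "t_lv": float(ts[0]),
        "t_rv": float(ts[-1]),
        "t_esp": float(ts[i_esp]),
        "t_dp": float(ts[i_dp]),
        "t_dn": float(ts[i_dn]),
        "ppt": float(ts[i_dp] - ts[i_esp]),
        "ri": float(h[i_dp] / h[i_esp]),
        "ct": float(ts[i_esp] - ts[0]),
        "dt": float(ts[-1] - ts[i_esp]),
        "nt": float(ts[i_dn] - ts[0]),
        "has_second_peak": bool(has_second_peak),
    }


def generate_beat_train(
    params: BeatModelParams, duration_s: float = 60.0
) -> tuple[PPGSignal, pd.DataFrame]:
    """Periodic beat train with drift and noise, plus a ground-truth table.

    The truth table has one row per complete (valley-to-valley) beat with
    the true LV/ESP/DP/DN times in absolute seconds and the true PPT, RI,
    CT and DT of the noiseless template.  A beat counts as complete when
    its right valley falls on or before the last sample.
    """
    p = params
    n = int(round(duration_s * p.fs)) + 1
    t = np.arange(n) / p.fs
    phase = np.mod(t, p.period)
    # sum neighbouring-beat contributions so Gaussian tails wrap correctly
    values = np.zeros(n)
    for shift in (-1.0, 0.0, 1.0):
        values += _beat_template(p, phase + shift * p.period)
    if p.drift_amp:
        values = values + p.drift_amp * np.sin(2 * np.pi * p.drift_freq * t)
    if p.noise_snr_db is not None and np.isfinite(p.noise_snr_db):
        rng = np.random.default_rng(p.seed)
        sig_power = np.var(_beat_template(p, np.mod(t, p.period)))
        noise_sd = np.sqrt(sig_power / 10 ** (p.noise_snr_db / 10))
        values = values + rng.normal(0, noise_sd, size=n)

    base = _template_truth(p)
    n_beats = int(np.floor((n - 1) / p.fs / p.period + 1e-9))
    rows = []
    for k in range(n_beats):
        t0 = k * p.period
        rows.append(
            {
                "beat": k,
                "t_lv": t0 + base["t_lv"],
                "t_esp": t0 + base["t_esp"],
                "t_dp": t0 + base["t_dp"],
                "t_dn": t0 + base["t_dn"],
                "t_rv": t0 + base["t_rv"],
                "ppt": base["ppt"],
                "ri": base["ri"],
                "ct": base["ct"],
                "nt": base["nt"],
                "dt": base["dt"],
                "has_second_peak": base["has_second_peak"],
            }
        )
    sig = PPGSignal(values=values, fs=p.fs, t0=0.0, source="synthetic")
    return sig, pd.DataFrame(rows)


def generate_frame_stack(
    ppg: PPGSignal,
    h: int = 12,
    w: int = 16,
    channel_gains: tuple[float, float, float] = (0.4, 1.0, 0.6),
    jitter_pct: float = 0.0,
    seed: int = 0,
    baselines: tuple[float, float, float] = (120.0, 100.0, 80.0),
    channel_noise_sd: float = 0.0,
) -> FrameStack:
    """Render a PPG trace as an RGB frame stack with jittered timestamps.

    Each frame's per-channel spatial mean equals baseline + gain * ppg(t)
    (+ optional per-frame channel noise); frame timestamps are perturbed by
    up to ``jitter_pct`` percent of the nominal frame interval.
    """
    if h <= 0 or w <= 0:
        raise ValueError("frame dimensions must be positive")
    gains = np.asarray(channel_gains, dtype=float)
    if np.all(gains == 0):
        raise ValueError("at least one channel gain must be non-zero")
    rng = np.random.default_rng(seed)
    n = len(ppg.values)
    dt = 1.0 / ppg.fs
    ts = ppg.times.copy()
    if jitter_pct:
        ts = ts + rng.uniform(-1, 1, size=n) * (jitter_pct / 100.0) * dt
        ts = np.sort(ts)
        ts[0] = ppg.t0
    vals = np.interp(ts, ppg.times, ppg.values)

    means = baselines + gains * vals[:, None]  # (T, 3)
    if channel_noise_sd:
        means = means + rng.normal(0, channel_noise_sd, size=means.shape)
    frames = np.broadcast_to(means[:, None, None, :], (n, h, w, 3)).copy()
    # spatial texture with exactly zero spatial mean keeps channel means exact
    texture = rng.normal(0, 1.0, size=(h, w, 3))
    texture -= texture.mean(axis=(0, 1), keepdims=True)
    frames += texture
    np.clip(frames, 0.0, 255.0, out=frames)
    return FrameStack(frames=frames, timestamps=ts, color_space="RGB")


@dataclass
class CohortParams:
    """Nested-cohort design: participants x repeated samples, linked scores."""

    n_participants: int = 113
    samples_per_participant: int = 7
    effect_map: dict[str, dict[str, float]] = field(default_factory=dict)
    noise_sd: float | dict[str, float] = 1.0
    score_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(SCALE_RANGES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        for outcome, fmap in self.effect_map.items():
            for feat, slope in fmap.items():
                if not np.isfinite(slope):
                    raise ValueError(f"slope for {feat}->{outcome} not finite")
        for name, (lo, hi) in self.score_ranges.items():
            if hi <= lo:
                raise ValueError(f"degenerate score range for {name}")


#: name -> (population mean, between-participant SD, within-participant SD)
#: for the parametric cohort mode; values in each feature's natural units.
PARAMETRIC_FEATURES: dict[str, tuple[float, float, float]] = {
    "ct": (0.17, 0.03, 0.01),
    "ppt": (0.26, 0.04, 0.012),
    "nt": (0.35, 0.04, 0.012),
    "dt": (0.55, 0.05, 0.015),
    "ri": (0.45, 0.10, 0.03),
    "eri": (0.55, 0.10, 0.03),
    "ipa": (0.35, 0.08, 0.03),
    "b_a": (0.85, 0.15, 0.05),
    "f_a": (0.6, 0.15, 0.05),
    "h_a": (0.3, 0.10, 0.04),
    "ai": (-0.6, 0.2, 0.06),
    "rpsd1": (0.55, 0.08, 0.03),
    "rpsd2": (0.25, 0.05, 0.02),
    "v0": (0.35, 0.06, 0.02),
    "v1": (0.45, 0.06, 0.02),
    "nha": (0.45, 0.08, 0.03),
}


def _noise_sd_for(cp: CohortParams, outcome: str) -> float:
    if isinstance(cp.noise_sd, dict):
        return float(cp.noise_sd.get(outcome, 1.0))
    return float(cp.noise_sd)


def _scores_from_means(
    cp: CohortParams, participant_means: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Psych scores linear in centred participant-mean features, clipped."""
    n = len(participant_means)
    centred = participant_means - participant_means.mean(axis=0)
    scores = {}
    for outcome, (lo, hi) in cp.score_ranges.items():
        mid = (lo + hi) / 2.0
        y = np.full(n, mid, dtype=float)
        for feat, slope in cp.effect_map.get(outcome, {}).items():
            if feat not in centred.columns:
                raise KeyError(f"effect_map feature {feat!r} not generated")
            y = y + slope * centred[feat].to_numpy()
        y = y + rng.normal(0, _noise_sd_for(cp, outcome), size=n)
        scores[outcome] = np.clip(np.rint(y), lo, hi).astype(int)
    return pd.DataFrame(scores, index=participant_means.index)


def generate_cohort(
    cp: CohortParams,
    beat_param_sampler=None,
    mode: str = "parametric",
    sample_duration_s: float = 35.0,
) -> tuple[pd.DataFrame, dict]:
    """Cohort table of repeated feature samples plus participant scores.

    ``parametric`` mode draws feature values directly from participant
    latents (fast; exercises the statistical layer).  ``extract`` mode
    synthesises a beat train per sample from latent waveform parameters and
    runs the full extraction pipeline, so features carry realistic
    extraction error.  Returns (cohort table, truth record); the truth
    record stores all latents and the programmed slopes.
    """
    rng = np.random.default_rng(cp.seed)
    if mode == "parametric":
        rows, latents = _parametric_rows(cp, rng)
    elif mode == "extract":
        rows, latents = _extracted_rows(cp, rng, beat_param_sampler, sample_duration_s)
    else:
        raise ValueError(f"unknown cohort mode {mode!r}")

    table = pd.DataFrame(rows)
    feature_cols = [
        c
        for c in table.columns
        if c not in ("participant_id", "sample_id", "height_cm", "sbp", "dbp",
                     "hr_bpm", "sqi", "n_beats", "incomplete")
    ]
    means = table.groupby("participant_id")[feature_cols].mean()
    scores = _scores_from_means(cp, means, rng)
    table = table.merge(scores, left_on="participant_id", right_index=True)
    truth = {
        "mode": mode,
        "effect_map": cp.effect_map,
        "participant_latents": latents,
        "participant_means": means,
        "scores": scores,
    }
    return table, truth


def _parametric_rows(cp: CohortParams, rng: np.random.Generator):
    rows = []
    latents = {}
    for p in range(cp.n_participants):
        pid = f"P{p:03d}"
        mu = {
            name: rng.normal(m, b) for name, (m, b, _) in PARAMETRIC_FEATURES.items()
        }
        height = rng.normal(170.0, 8.0)
        sbp = rng.normal(118.0, 10.0)
        dbp = rng.normal(75.0, 8.0)
        latents[pid] = {"features": mu, "height_cm": height, "sbp": sbp, "dbp": dbp}
        for s in range(cp.samples_per_participant):
            row = {
                "participant_id": pid,
                "sample_id": f"{pid}-S{s}",
                "height_cm": height,
                "sbp": sbp,
                "dbp": dbp,
            }
            for name, (_, _, w) in PARAMETRIC_FEATURES.items():
                row[name] = mu[name] + rng.normal(0, w)
            rows.append(row)
    return rows, latents


def _default_param_sampler(rng: np.random.Generator) -> BeatModelParams:
    hr = np.clip(rng.normal(72.0, 7.0), 50.0, 100.0)
    return BeatModelParams(
        period=60.0 / hr,
        reflection_lag=float(np.clip(rng.normal(0.26, 0.03), 0.18, 0.35)),
        reflection_ratio=float(np.clip(rng.normal(0.45, 0.12), 0.05, 0.9)),
        noise_snr_db=20.0,
        fs=60.0,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def _extracted_rows(cp, rng, beat_param_sampler, sample_duration_s):
    from .waveform_features import extract_sample_record

    sampler = beat_param_sampler or _default_param_sampler
    rows = []
    latents = {}
    for p in range(cp.n_participants):
        pid = f"P{p:03d}"
        base = sampler(rng)
        height = float(rng.normal(170.0, 8.0))
        sbp = float(rng.normal(118.0, 10.0))
        dbp = float(rng.normal(75.0, 8.0))
        latents[pid] = {"params": base, "height_cm": height, "sbp": sbp, "dbp": dbp}
        for s in range(cp.samples_per_participant):
            jittered = replace(
                base,
                reflection_lag=float(
                    np.clip(base.reflection_lag + rng.normal(0, 0.008),
                            0.12, base.period * 0.9)
                ),
                reflection_ratio=float(
                    np.clip(base.reflection_ratio + rng.normal(0, 0.03), 0.0, 1.0)
                ),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            sig, _ = generate_beat_train(jittered, duration_s=sample_duration_s)
            rec = extract_sample_record(
                sig, pid, f"{pid}-S{s}", height_cm=height, sbp=sbp, dbp=dbp
            )
            row = rec.to_row()
            row.pop("sqi", None)
            rows.append(row)
    return rows, latents


def worked_example_fixtures() -> dict:
    """Deterministic bundle of small fixtures covering both code paths.

    Returns a dict with a clean 10-beat train, a train without a second
    peak (fallback path), a noise-dominated low-SQI trace, a 3-frame toy
    stack, and a 20-participant parametric cohort, each paired with its
    ground-truth manifest.
    """
    clean_params = BeatModelParams(noise_snr_db=None, drift_amp=0.0, fs=60.0, seed=1)
    clean_sig, clean_truth = generate_beat_train(clean_params, duration_s=8.0)

    flat_params = BeatModelParams(
        reflection_ratio=0.0, noise_snr_db=None, drift_amp=0.0, fs=60.0, seed=2
    )
    flat_sig, flat_truth = generate_beat_train(flat_params, duration_s=8.0)

    noisy_params = BeatModelParams(noise_snr_db=-10.0, drift_amp=0.0, fs=60.0, seed=3)
    noisy_sig, noisy_truth = generate_beat_train(noisy_params, duration_s=30.0)

    toy_ppg = PPGSignal(values=np.array([0.0, 1.0, 0.5]), fs=30.0, source="synthetic")
    toy_stack = generate_frame_stack(toy_ppg, h=2, w=2, seed=4)

    cohort, cohort_truth = generate_cohort(
        CohortParams(n_participants=20, samples_per_participant=4, seed=5)
    )
    return {
        "clean_train": (clean_sig, clean_truth),
        "no_second_peak_train": (flat_sig, flat_truth),
        "noisy_low_sqi": (noisy_sig, noisy_truth),
        "toy_stack": toy_stack,
        "cohort": (cohort, cohort_truth),
    }
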