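"""Per-beat features, spectral decomposition, normalization, aggregation."""

import numpy as np
import pytest

import pulsewave as pw
from pulsewave.beat_segmentation import BeatSegment
from pulsewave.fiducials import locate_all
from pulsewave.waveform_features import (
    _shoelace,
    aggregate_sample,
    compute_curvature_features,
    compute_spectral_features,
    compute_time_features,
    normalize_features,
)


def _shoelace_oracle(pts):
    """Textbook shoelace sum, written independently of the implementation."""
    area = 0.0
    for (x1, y1), (x2, y2) in zip(pts, pts[1:] + pts[:1]):
        area += x1 * y2 - x2 * y1
    return abs(area) / 2.0


class TestTimeFeatureArithmetic:
    def test_si_from_height_and_ppt(self):
        assert 1.70 / 0.25 == pytest.approx(6.8)

    def test_per_beat_ratios_obey_definitions(self, clean_beats):
        """RCA = CT/NT, RDA = NT/(CT+DT), SI = height/PPT per beat."""
        for b in clean_beats[1:4]:
            fid, d1, _ = locate_all(b)
            f = compute_time_features(b, fid, d1, 1.70)
            assert f["rca"] == pytest.approx(f["ct"] / f["nt"], rel=1e-9)
            assert f["rda"] == pytest.approx(f["nt"] / (f["ct"] + f["dt"]), rel=1e-9)
            assert f["si"] == pytest.approx(1.70 / f["ppt"], rel=1e-9)

    def test_aggregated_si_consistent_with_ppt(self, default_record):
        """SI = height/PPT survives median aggregation (monotone transform)."""
        rec, _ = default_record
        assert rec.features["si"] == pytest.approx(1.70 / rec.features["ppt"], rel=0.01)

    def test_hand_arithmetic_rca_rda(self):
        # CT 0.12, NT 0.30, DT 0.50 -> RCA 0.4, RDA 0.30/0.62
        assert 0.12 / 0.30 == pytest.approx(0.4)
        assert 0.30 / (0.12 + 0.50) == pytest.approx(0.484, abs=1e-3)

    def test_areas_match_shoelace_oracle(self, clean_beats):
        for b in clean_beats[1:3]:
            fid, d1, d2 = locate_all(b)
            feats = compute_time_features(b, fid, d1, 1.70)
            from pulsewave.fiducials import _savgol_window, SAVGOL_POLYORDER
            from scipy.signal import savgol_filter

            win = _savgol_window(len(b.values), b.fs)
            smooth = savgol_filter(b.values, win, SAVGOL_POLYORDER)
            base = b.values[0] + (b.values[-1] - b.values[0]) * np.arange(len(b)) / (len(b) - 1)
            h = smooth - base
            t = lambda i: i / b.fs
            a1 = _shoelace_oracle(
                [(t(0), 0.0), (t(fid.esp), h[fid.esp]), (t(fid.dn), h[fid.dn]), (t(fid.dn), 0.0)]
            )
            a2 = _shoelace_oracle(
                [(t(fid.ip), h[fid.ip]), (t(fid.dn), h[fid.dn]), (t(fid.rv), 0.0)]
            )
            assert feats["a1"] == pytest.approx(a1, rel=1e-9)
            assert feats["a2"] == pytest.approx(a2, rel=1e-9)

    def test_eri_uses_extrapolated_peak(self, default_record):
        """Tangent-intersection peak estimate exceeds the smoothed apex, so ERI < RI."""
        rec, _ = default_record
        assert rec.features["eri"] < rec.features["ri"]

    def test_ppt_ri_recovery_against_manifest(self, default_record):
        rec, truth = default_record
        assert rec.features["ppt"] == pytest.approx(truth.ppt[0], rel=0.10)
        assert rec.features["ri"] == pytest.approx(truth.ri[0], rel=0.10)


class TestCurvatureFeatures:
    def test_signed_ratio_arithmetic(self):
        d2 = np.array([0.0, 2.0, -1.0, 0.4, 0.3, -0.6, 0.1, -0.2])
        fid = pw.BeatFiducials(lv=0, esp=4, dn=5, dp=6, ip=5, rv=7,
                               a=1, b=2, e=3, f=5, g=6, h=7)
        out = compute_curvature_features(fid, d2)
        assert out["b_a"] == pytest.approx(0.5)
        assert out["e_a"] == pytest.approx(0.2)
        assert out["f_a"] == pytest.approx(0.3)
        # AI keeps signs: B/A - E/A = -0.5 - 0.2
        assert out["ai"] == pytest.approx(-0.7)

    def test_zero_reference_marks_missing(self):
        d2 = np.zeros(8)
        fid = pw.BeatFiducials(lv=0, esp=4, dn=5, dp=6, ip=5, rv=7, a=1, b=2)
        out = compute_curvature_features(fid, d2)
        assert all(np.isnan(v) for v in out.values())

    def test_ratios_match_dense_oracle_on_clean_beats(self, clean_beats):
        for b in clean_beats[1:4]:
            fid, _, d2 = locate_all(b)
            out = compute_curvature_features(fid, d2)
            assert out["b_a"] == pytest.approx(abs(d2[fid.b] / d2[fid.a]))
            assert out["f_a"] == pytest.approx(abs(d2[fid.f] / d2[fid.a]))
            assert out["b_a"] >= 0 and out["f_a"] >= 0 and out["h_a"] >= 0


class TestSpectralFeatures:
    def _sig(self, fn, fs=60.0, dur=60.0):
        t = np.arange(int(fs * dur) + 1) / fs
        return pw.PPGSignal(values=fn(t), fs=fs)

    def test_pure_sinusoid_single_harmonic(self):
        f0 = 1.25
        sig = self._sig(lambda t: np.sin(2 * np.pi * f0 * t))
        out = compute_spectral_features(sig)
        assert out["rpsd1"] == pytest.approx(1.0, abs=0.01)
        for i in range(2, 7):
            assert out[f"rpsd{i}"] == pytest.approx(0.0, abs=0.01)
        assert out["nha"] == pytest.approx(0.0, abs=0.01)

    def test_two_harmonic_parseval_split(self):
        """Amplitudes 1 and 0.5 give powers 1 : 0.25 -> shares 0.8 / 0.2."""
        f0 = 1.25
        sig = self._sig(
            lambda t: np.sin(2 * np.pi * f0 * t) + 0.5 * np.sin(4 * np.pi * f0 * t)
        )
        out = compute_spectral_features(sig)
        assert out["rpsd1"] == pytest.approx(0.8, abs=0.01)
        assert out["rpsd2"] == pytest.approx(0.2, abs=0.01)
        assert out["nha"] == pytest.approx(0.2, abs=0.01)

    def test_rpsd_simplex(self, default_record):
        rec, _ = default_record
        total = sum(rec.features[f"rpsd{i}"] for i in range(1, 7))
        assert total == pytest.approx(1.0, abs=1e-9)
        assert all(rec.features[f"s{i}"] >= 0 for i in range(1, 7))

    def test_fourier_roundtrip_on_bandlimited_beat(self):
        """V0..V6 reconstruct a beat composed of 6 harmonics to <1% RMSE."""
        rs = np.random.default_rng(2)
        L = 200
        tau = np.arange(L) / L
        template = 0.3 + sum(
            a * np.sin(2 * np.pi * i * tau + ph)
            for i, (a, ph) in enumerate(
                zip(rs.uniform(0.1, 1, 6), rs.uniform(0, 2 * np.pi, 6)), start=1
            )
        )
        from pulsewave.waveform_features import _fit_fourier_template

        v = _fit_fourier_template(template, 6)
        # reconstruct with the same least-squares basis
        cols = [np.ones(L)]
        for i in range(1, 7):
            cols.append(np.sin(2 * np.pi * i * tau))
            cols.append(np.cos(2 * np.pi * i * tau))
        X = np.column_stack(cols)
        coef, *_ = np.linalg.lstsq(X, template, rcond=None)
        rmse = np.sqrt(np.mean((X @ coef - template) ** 2))
        assert rmse < 0.01 * np.ptp(template)
        assert v[0] == pytest.approx(0.3, abs=1e-6)

    def test_short_signal_rejected(self):
        sig = self._sig(lambda t: np.sin(2 * np.pi * t), dur=10.0)
        with pytest.raises(ValueError, match="30 s"):
            compute_spectral_features(sig)

    def test_ihar_definition(self, default_record):
        rec, _ = default_record
        f = rec.features
        assert f["ihar"] == pytest.approx((1 - f["nha"]) / f["ipa"], rel=1e-6)


class TestNormalization:
    FEATS = {"ppt": 0.25, "ct": 0.20, "nt": 0.35, "dt": 0.5, "ri": 0.5,
             "rca": 0.57, "si": 6.8, "eppt": 0.28, "esi": 1.70 / 0.28, "ipa": 0.4,
             "fn": 0.1, "sr": 0.3, "nv": 0.2, "b_a": 0.9}

    def test_reference_point_is_identity(self):
        out = normalize_features(dict(self.FEATS), hr_bpm=75.0, height_cm=170.0)
        for k, v in self.FEATS.items():
            assert out[k] == pytest.approx(v, rel=1e-9), k

    def test_duration_scaling(self):
        out = normalize_features(dict(self.FEATS), hr_bpm=60.0, height_cm=170.0)
        assert out["ct"] == pytest.approx(0.20 * 60 / 75)
        assert out["nt"] == pytest.approx(0.35 * 60 / 75)

    def test_ratios_scale_invariant(self):
        for hr, h in [(55, 150), (95, 190)]:
            out = normalize_features(dict(self.FEATS), hr_bpm=hr, height_cm=h)
            assert out["ri"] == self.FEATS["ri"]
            assert out["rca"] == self.FEATS["rca"]
            assert out["ipa"] == self.FEATS["ipa"]
            assert out["b_a"] == self.FEATS["b_a"]

    def test_stature_scaling_on_transit_times(self):
        out = normalize_features(dict(self.FEATS), hr_bpm=75.0, height_cm=150.0)
        assert out["ppt"] == pytest.approx(0.25 * 170 / 150)
        assert out["ct"] == pytest.approx(0.20)  # not a transit feature
        assert out["si"] == pytest.approx(1.70 / out["ppt"])

    def test_idempotence_after_normalizing(self):
        once = normalize_features(dict(self.FEATS), hr_bpm=60.0, height_cm=180.0)
        twice = normalize_features(dict(once), hr_bpm=75.0, height_cm=170.0)
        for k in once:
            assert twice[k] == pytest.approx(once[k], rel=1e-9)

    def test_invalid_inputs_error(self):
        with pytest.raises(ValueError):
            normalize_features(dict(self.FEATS), hr_bpm=0.0, height_cm=170.0)


class TestAggregation:
    def test_median_rule(self):
        feats = [{"ct": v} for v in (1.0, 2.0, 3.0, np.nan, np.nan)]
        rec = aggregate_sample(feats, [False] * 5, "P0", "s", 75.0)
        assert rec.features["ct"] == 2.0

    @pytest.mark.parametrize("n, k, expected", [(299, 0, 0.0), (10, 3, 30.0)])
    def test_ipp_percentage(self, n, k, expected):
        feats = [{"ct": 0.2}] * n
        flags = [True] * k + [False] * (n - k)
        rec = aggregate_sample(feats, flags, "P0", "s", 75.0)
        assert rec.features["ipp"] == pytest.approx(expected)

    def test_few_beats_flagged_incomplete(self):
        rec = aggregate_sample([{"ct": 0.2}] * 3, [False] * 3, "P0", "s", 75.0)
        assert rec.incomplete

    def test_low_core_coverage_flagged(self):
        feats = [{"ppt": np.nan, "ct": 0.2}] * 6
        rec = aggregate_sample(feats, [False] * 6, "P0", "s", 75.0)
        assert rec.incomplete and "ppt" in rec.missing

    def test_order_invariance_and_outlier_robustness(self):
        base = [{"ct": v} for v in (0.18, 0.19, 0.20, 0.21, 0.22, 0.19, 0.2)]
        rec1 = aggregate_sample(base, [False] * 7, "P", "s", 75.0)
        rec2 = aggregate_sample(base[::-1], [False] * 7, "P", "s", 75.0)
        assert rec1.features["ct"] == rec2.features["ct"]
        polluted = base[:-1] + [{"ct": 9.9}]
        rec3 = aggregate_sample(polluted, [False] * 7, "P", "s", 75.0)
        assert rec3.features["ct"] == pytest.approx(0.20, abs=0.01)


class TestParameterRecovery:
    @pytest.mark.parametrize("lag, ratio", [(0.20, 0.3), (0.30, 0.7)])
    def test_ppt_ri_within_ten_percent_at_20db(self, lag, ratio):
        """Spot checks of the recovery grid (full sweep in the acceptance suite)."""
        p = pw.BeatModelParams(
            reflection_lag=lag, reflection_ratio=ratio,
            noise_snr_db=20.0, drift_amp=0.3, fs=60.0, seed=5,
        )
        sig, truth = pw.generate_beat_train(p, duration_s=16.0)
        rec = pw.extract_sample_record(sig, "P", "s", spectral=False)
        assert rec.features["ppt"] == pytest.approx(truth.ppt[0], rel=0.10)
        assert rec.features["ri"] == pytest.approx(truth.ri[0], rel=0.10)
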