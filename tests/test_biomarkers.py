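"""Biomarker formulas, cardinality and summary statistics."""
import math

import numpy as np
import pytest
from scipy import stats

from pulsewave import PipelineConfig, SynthConfig, analyze, generate_synthetic_ppg
from pulsewave.biomarkers import (BIOMARKER_CATEGORIES, SUMMARY_STATS,
                                  biomarker_names, compute_beat_biomarkers,
                                  pulse_width_at_x, summarize_biomarkers)
from pulsewave.fiducials import FiducialSet
from pulsewave.preprocess import ProcessedSignal
import pandas as pd


def make_proc(ppg, d1=None, d2=None, d3=None, fs=1000.0):
    n = len(ppg)
    z = np.zeros(n)
    return ProcessedSignal(ppg=np.asarray(ppg, float),
                           d1=z if d1 is None else np.asarray(d1, float),
                           d2=z if d2 is None else np.asarray(d2, float),
                           d3=z if d3 is None else np.asarray(d3, float),
                           fs=fs, ppg_75=np.zeros(10))


class TestCardinality:
    def test_74_names_in_four_categories(self):
        names = biomarker_names()
        assert len(names) == 74
        assert len(set(names)) == 74
        sizes = [len(names[s]) for s in BIOMARKER_CATEGORIES.values()]
        assert sizes == [17, 12, 15, 30]

    def test_full_fiducial_set_yields_74_values(self, default_result):
        res = default_result
        assert res.per_beat.shape[1] == 74
        assert len(res.per_beat) >= 10
        # a full fiducial set leaves no absent biomarkers
        complete = res.per_beat.dropna(axis=0)
        assert len(complete) >= 1

    def test_nine_summary_statistics(self, default_result):
        assert list(default_result.summary.columns) == list(SUMMARY_STATS)
        assert len(default_result.summary) == 74


class TestWidths:
    def triangle(self):
        # symmetric triangle: onset 0, peak 1.0 at 100 ms, offset 200 ms
        up = np.linspace(0, 1, 101)
        down = np.linspace(1, 0, 101)[1:]
        ppg = np.concatenate([up, down, np.zeros(50)])
        fid = FiducialSet(on=0, sp=100, off=200)
        return ppg, fid

    def test_symmetric_triangle_at_50(self):
        ppg, fid = self.triangle()
        tsw, tdw, tpw = pulse_width_at_x(ppg, fid, 50.0, fs=1000.0)
        assert (tsw, tdw, tpw) == (pytest.approx(50.0), pytest.approx(50.0),
                                   pytest.approx(100.0))

    def test_threshold_at_peak_gives_zero(self):
        ppg, fid = self.triangle()
        tsw, tdw, tpw = pulse_width_at_x(ppg, fid, 100.0, fs=1000.0)
        assert tsw == pytest.approx(0.0, abs=1e-9)
        assert tdw == pytest.approx(0.0, abs=1e-9)

    def test_coarse_sampling_interpolates(self):
        # same triangle sampled at 50 Hz: widths within 1 ms via interpolation
        t = np.arange(0, 0.25, 0.02)
        ppg = np.interp(t, [0, 0.1, 0.2, 0.25], [0, 1, 0, 0])
        fid = FiducialSet(on=0, sp=5, off=10)
        tsw, tdw, tpw = pulse_width_at_x(ppg, fid, 50.0, fs=50.0)
        assert tsw == pytest.approx(50.0, abs=1.0)
        assert tdw == pytest.approx(50.0, abs=1.0)
        assert tpw == pytest.approx(100.0, abs=2.0)

    def test_never_crossed_side_absent(self):
        # downslope plateaus above the threshold: diastolic width absent
        ppg = np.concatenate([np.linspace(0, 1, 101), np.full(100, 0.95)])
        fid = FiducialSet(on=0, sp=100, off=200)
        tsw, tdw, tpw = pulse_width_at_x(ppg, fid, 50.0, fs=1000.0)
        assert not math.isnan(tsw)
        assert math.isnan(tdw) and math.isnan(tpw)


class TestFormulas:
    def test_ipr_from_pulse_interval(self):
        # Tpi = 1000 ms -> instantaneous pulse rate 60 bpm
        ppg = np.zeros(1100)
        ppg[:1001] = np.sin(np.linspace(0, np.pi, 1001))
        fid = FiducialSet(on=0, sp=500, off=1000)
        out = compute_beat_biomarkers(make_proc(ppg), fid)
        assert out["Tpi"] == pytest.approx(1000.0)
        assert out["IPR"] == pytest.approx(60.0)

    def test_aging_indices(self):
        # Aa=1.0, Ab=-0.8, Ac=-0.2, Ad=-0.3, Ae=0.4
        n = 1000
        ppg = np.sin(np.linspace(0, np.pi, n))
        d2 = np.zeros(n)
        idx = {"a": 100, "b": 200, "c": 300, "d": 400, "e": 500}
        vals = {"a": 1.0, "b": -0.8, "c": -0.2, "d": -0.3, "e": 0.4}
        for k, i in idx.items():
            d2[i] = vals[k]
        fid = FiducialSet(on=0, sp=450, off=900, **idx)
        out = compute_beat_biomarkers(make_proc(ppg, d2=d2), fid)
        assert out["AGI"] == pytest.approx(-0.7)
        assert out["AGImod"] == pytest.approx(-0.3)
        assert out["AGIinf"] == pytest.approx(-1.2)
        assert out["Ad/Aa"] == pytest.approx(-0.3)

    def test_area_ratios(self, default_result):
        # IPA = AUCdia/AUCsys and IPAD = IPA + Ad/Aa on real pulses
        row = default_result.per_beat.dropna(axis=0).iloc[0]
        assert row["IPA"] == pytest.approx(row["AUCdia"] / row["AUCsys"], rel=1e-9)
        assert row["IPAD"] == pytest.approx(row["IPA"] + row["Ad/Aa"], rel=1e-9)

    def test_missing_fiducial_propagates_nan(self):
        ppg = np.sin(np.linspace(0, np.pi, 1000))
        fid = FiducialSet(on=0, sp=500, off=900)  # no dn, dp, derivatives
        out = compute_beat_biomarkers(make_proc(ppg), fid)
        assert math.isnan(out["Tsys"])
        assert math.isnan(out["Adn"])
        assert math.isnan(out["Adp/Asp"])
        assert not math.isnan(out["Asp"])

    def test_division_by_zero_absent(self):
        ppg = np.sin(np.linspace(0, np.pi, 1000))
        fid = FiducialSet(on=0, sp=500, off=900, dp=500)  # dT = 0
        out = compute_beat_biomarkers(make_proc(ppg), fid)
        assert math.isnan(out["Asp/dT"])


class TestConsistency:
    def test_identities_on_pipeline_output(self, default_result):
        beats = default_result.per_beat.dropna(axis=0)
        assert len(beats) >= 5
        np.testing.assert_allclose(beats["Tpw50"], beats["Tsw50"] + beats["Tdw50"],
                                   rtol=1e-9)
        np.testing.assert_allclose(beats["AUCpi"], beats["AUCsys"] + beats["AUCdia"],
                                   rtol=1e-6)
        np.testing.assert_allclose(beats["IPA"] * beats["AUCsys"], beats["AUCdia"],
                                   rtol=1e-9)

    def test_amplitude_scale_invariance(self, default_record):
        raw, _ = default_record
        res1 = analyze(raw, PipelineConfig())
        scaled = type(raw)(samples=raw.samples * 3.7, fs=raw.fs)
        res2 = analyze(scaled, PipelineConfig())
        time_cols = ["Tpi", "Tsp", "Tsw50", "Tu", "Tb", "Tp1"]
        ratio_cols = ["Adp/Asp", "Ab/Aa", "AI", "IPA", "Tsp/Tpi"]
        a = res1.per_beat.dropna(axis=0).reset_index(drop=True)
        b = res2.per_beat.dropna(axis=0).reset_index(drop=True)
        n = min(len(a), len(b))
        for col in time_cols + ratio_cols:
            np.testing.assert_allclose(a[col][:n], b[col][:n], rtol=1e-6,
                                       err_msg=col)


class TestSummary:
    def test_known_small_sample(self):
        frame = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0, 5.0]})
        s = summarize_biomarkers(frame).loc["x"]
        assert s["AVG"] == 3 and s["MED"] == 3
        assert s["Q1"] == 2 and s["Q3"] == 4 and s["IQR"] == 2
        assert s["MAD"] == pytest.approx(1.2)
        assert s["SD"] == pytest.approx(np.std([1, 2, 3, 4, 5], ddof=1))

    def test_constant_column_degenerate_convention(self):
        frame = pd.DataFrame({"x": [2.5] * 8})
        s = summarize_biomarkers(frame).loc["x"]
        assert s["SD"] == 0 and s["IQR"] == 0
        assert s["SKW"] == 0 and s["KUR"] == 0

    def test_all_absent_column_omitted(self):
        frame = pd.DataFrame({"x": [1.0, 2.0], "y": [np.nan, np.nan]})
        summary = summarize_biomarkers(frame)
        assert "x" in summary.index and "y" not in summary.index

    def test_lognormal_moments_match_reference(self):
        # adjusted Fisher-Pearson skewness / excess kurtosis of a log-normal
        rng = np.random.default_rng(12345)
        sigma = 0.4
        draws = rng.lognormal(mean=0.0, sigma=sigma, size=100_000)
        s = summarize_biomarkers(pd.DataFrame({"x": draws})).loc["x"]
        w = math.exp(sigma ** 2)
        skew_ref = (w + 2) * math.sqrt(w - 1)
        kurt_ref = w ** 4 + 2 * w ** 3 + 3 * w ** 2 - 6
        assert s["SKW"] == pytest.approx(skew_ref, rel=0.05)
        assert s["KUR"] == pytest.approx(kurt_ref, rel=0.05)
        assert s["SKW"] == pytest.approx(stats.skew(draws, bias=False), rel=1e-9)
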