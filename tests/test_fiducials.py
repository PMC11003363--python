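"""Fiducial detection against analytic pulse models and a brute-force oracle."""
import numpy as np
import pytest

from pulsewave import (PipelineConfig, SynthConfig, detect_beats,
                       detect_onsets_offsets, generate_synthetic_ppg,
                       preprocess)
from pulsewave.fiducials import (FiducialSet, correct_fiducials,
                                 detect_derivative_points,
                                 detect_diastolic_peak, detect_dicrotic_notch,
                                 detect_fiducials)
from pulsewave.preprocess import ProcessedSignal
from pulsewave.segmentation import PulseWave


def gauss_proc(gaussians, fs=1000.0, duration_s=1.0):
    """Analytic signal + derivatives for a sum of Gaussians (no filtering)."""
    t = np.arange(int(duration_s * fs)) / fs
    s = [np.zeros_like(t) for _ in range(4)]
    for amp, mu, sig in gaussians:
        x = (t - mu) / sig
        g = np.exp(-x * x / 2)
        s[0] += amp * g
        s[1] += -amp * x * g / sig
        s[2] += amp * (x * x - 1) * g / sig ** 2
        s[3] += -amp * (x ** 3 - 3 * x) * g / sig ** 3
    return ProcessedSignal(ppg=s[0], d1=s[1], d2=s[2], d3=s[3], fs=fs,
                           ppg_75=np.zeros(10))


class TestDerivativePoints:
    def test_single_gaussian_first_derivative_extrema(self):
        # Gaussian(mu=400 ms, sigma=80 ms): PPG' extrema at mu -/+ sigma
        proc = gauss_proc([(1.0, 0.4, 0.08)])
        pulse = PulseWave(on_idx=50, sp_idx=400, off_idx=900)
        fid = detect_derivative_points(proc, pulse)
        assert fid.u == pytest.approx(320, abs=2)
        assert fid.v == pytest.approx(480, abs=2)

    def test_single_gaussian_second_derivative(self):
        # a at mu - sigma*sqrt(3) ~ 261 ms; b at mu (first PPG'' minimum)
        proc = gauss_proc([(1.0, 0.4, 0.08)])
        pulse = PulseWave(on_idx=50, sp_idx=400, off_idx=900)
        fid = detect_derivative_points(proc, pulse)
        assert fid.a == pytest.approx(400 - 80 * np.sqrt(3), abs=2)
        assert fid.b == pytest.approx(400, abs=2)

    def test_flat_pulse_has_no_points(self):
        z = np.zeros(1000)
        proc = ProcessedSignal(ppg=z, d1=z, d2=z, d3=z, fs=1000.0,
                               ppg_75=np.zeros(10))
        fid = detect_derivative_points(proc, PulseWave(100, 500, 900))
        for pt in ("u", "v", "w", "a", "b", "c", "d", "e", "f", "p1", "p2"):
            assert getattr(fid, pt) is None


def two_gaussian_proc():
    # systolic hump at 300 ms, diastolic 0.4x at 600 ms
    return gauss_proc([(1.0, 0.3, 0.07), (0.4, 0.6, 0.09)])


class TestDicroticNotch:
    def test_two_gaussian_incisura(self):
        proc = two_gaussian_proc()
        # numeric minimization oracle on the continuous model
        t = np.linspace(0.35, 0.55, 200001)
        model = (np.exp(-((t - 0.3) / 0.07) ** 2 / 2)
                 + 0.4 * np.exp(-((t - 0.6) / 0.09) ** 2 / 2))
        t_min = t[np.argmin(model)] * 1000.0
        pulse = PulseWave(on_idx=80, sp_idx=300, off_idx=950)
        fid = detect_derivative_points(proc, pulse)
        fid = detect_dicrotic_notch(proc, pulse, fid)
        assert fid.dn_class == 1
        assert fid.dn == pytest.approx(t_min, abs=10)

    def test_single_gaussian_no_notch(self):
        proc = gauss_proc([(1.0, 0.4, 0.08)])
        pulse = PulseWave(on_idx=50, sp_idx=400, off_idx=900)
        fid = detect_derivative_points(proc, pulse)
        fid = detect_dicrotic_notch(proc, pulse, fid)
        assert fid.dn is None and fid.dn_class == 4

    def test_shallow_merged_wave_gradient_change(self):
        # diastolic wave merged into the downslope: no PPG minimum, the
        # PPG'' zero-crossing route applies (class 2 or 3)
        proc = gauss_proc([(1.0, 0.3, 0.09), (0.22, 0.52, 0.09)])
        pulse = PulseWave(on_idx=80, sp_idx=307, off_idx=950)
        fid = detect_derivative_points(proc, pulse)
        fid = detect_dicrotic_notch(proc, pulse, fid)
        assert fid.dn is not None and fid.dn_class in (2, 3)
        # oracle: sign-change scan of the analytic second derivative over
        # the downslope region preceding the e-wave
        lo_ms = fid.d if fid.d is not None else max(fid.b, fid.sp)
        t = np.linspace(lo_ms / 1000.0, fid.e / 1000.0, 200001)
        d2 = ((((t - 0.3) / 0.09) ** 2 - 1) * np.exp(-((t - 0.3) / 0.09) ** 2 / 2) / 0.09 ** 2
              + 0.22 * ((((t - 0.52) / 0.09) ** 2 - 1)
                        * np.exp(-((t - 0.52) / 0.09) ** 2 / 2) / 0.09 ** 2))
        crossings = t[:-1][np.diff(np.sign(d2)) > 0] * 1000.0
        assert len(crossings) > 0
        assert abs(fid.dn - crossings[0]) < 10


class TestDiastolicPeak:
    def test_two_gaussian_peak_near_600(self):
        proc = two_gaussian_proc()
        pulse = PulseWave(on_idx=80, sp_idx=300, off_idx=950)
        fid = detect_derivative_points(proc, pulse)
        fid = detect_dicrotic_notch(proc, pulse, fid)
        fid = detect_diastolic_peak(proc, pulse, fid)
        assert fid.dp == pytest.approx(600, abs=10)

    def test_monotone_decay_no_peak(self):
        proc = gauss_proc([(1.0, 0.4, 0.08)])
        pulse = PulseWave(on_idx=50, sp_idx=400, off_idx=900)
        fid = detect_derivative_points(proc, pulse)
        fid = detect_dicrotic_notch(proc, pulse, fid)
        fid = detect_diastolic_peak(proc, pulse, fid)
        assert fid.dp is None

    def test_late_maximum_outside_bound_rejected(self):
        # secondary wave at 0.85 of the pulse interval: outside the 0.8 bound
        proc = gauss_proc([(1.0, 0.25, 0.06), (0.4, 0.875, 0.05)])
        pulse = PulseWave(on_idx=25, sp_idx=250, off_idx=1025 - 26)
        fid = detect_derivative_points(proc, pulse)
        fid = detect_dicrotic_notch(proc, pulse, fid)
        fid = detect_diastolic_peak(proc, pulse, fid)
        assert fid.dp is None


class TestCorrection:
    def test_disabled_is_passthrough(self):
        fid = FiducialSet(on=10, sp=50, dn=40, dp=30, off=100)  # inconsistent
        out = correct_fiducials([fid], enabled=False)
        assert out[0] is fid

    def test_consistent_set_unchanged(self):
        fid = FiducialSet(on=10, sp=50, dn=70, dp=85, off=120, u=30, a=25,
                          b=48, e=72, f=90, dn_class=1)
        out = correct_fiducials([fid], enabled=True)
        assert out[0] == fid
        # idempotence
        assert correct_fiducials(out, enabled=True)[0] == fid

    def test_dp_before_dn_discarded_without_signal(self):
        fid = FiducialSet(on=10, sp=50, dn=70, dp=60, off=120)
        out = correct_fiducials([fid], enabled=True)
        assert out[0].dp is None

    def test_out_of_window_points_dropped(self):
        fid = FiducialSet(on=10, sp=50, off=120, u=5, a=60, b=55, p1=150)
        out = correct_fiducials([fid], enabled=True)
        assert out[0].u is None        # before onset
        assert out[0].a is None        # after sp
        assert out[0].p1 is None       # after offset


# ---------------------------------------------------------------------------
# Brute-force oracle: naive sample-by-sample scans of the point definitions
# ---------------------------------------------------------------------------

def _naive_local_max(x, i):
    return 0 < i < len(x) - 1 and x[i] > x[i - 1] and x[i] >= x[i + 1]


def _naive_local_min(x, i):
    return 0 < i < len(x) - 1 and x[i] < x[i - 1] and x[i] <= x[i + 1]


def brute_force_points(proc, pulse, cfg):
    """Independent implementation of the fiducial definitions by exhaustive
    scan, used only as a test oracle."""
    on, sp, off = pulse.on_idx, pulse.sp_idx, pulse.off_idx
    d1, d2, d3, ppg = proc.d1, proc.d2, proc.d3, proc.ppg
    dur = off - on
    out = {}
    seg = range(on, sp + 1)
    out["u"] = max(seg, key=lambda i: d1[i])
    out["a"] = max((i for i in seg if d1[i] > 0), key=lambda i: d2[i], default=None)
    b = next((i for i in range(out["a"] + 1, off) if _naive_local_min(d2, i)), None)
    out["b"] = b
    e_hi = on + int(round(cfg.e_bound_frac * dur))
    e_cands = [i for i in range(max(b, sp) + 1, e_hi + 1) if _naive_local_max(d2, i)]
    e = max(e_cands, key=lambda i: d2[i], default=None)
    out["e"] = e
    if e is not None:
        c_cands = [i for i in range(b + 1, e) if _naive_local_max(d2, i)]
        c = max(c_cands, key=lambda i: d2[i], default=None)
        out["c"] = c
        if c is not None:
            d_cands = [i for i in range(c + 1, e) if _naive_local_min(d2, i)]
            out["d"] = min(d_cands, key=lambda i: d2[i], default=None)
        f_hi = on + int(round(cfg.f_bound_frac * dur))
        out["f"] = next((i for i in range(e + 1, f_hi + 1)
                         if _naive_local_min(d2, i) and d2[i] < 0), None)
    out["p1"] = next((i for i in range(b + 1, off) if _naive_local_max(d3, i)), None)
    if out.get("d") is not None:
        p2_cands = [i for i in range(b + 1, out["d"] + 1) if _naive_local_min(d3, i)]
        out["p2"] = p2_cands[-1] if p2_cands else out["d"]
    v_hi = e if e is not None else on + int(round(cfg.f_bound_frac * dur))
    out["v"] = min(range(out["u"], v_hi + 1), key=lambda i: d1[i])
    if e is not None and out["v"] is not None:
        w_hi = out.get("f") or on + int(round(cfg.f_bound_frac * dur))
        out["w"] = next((i for i in range(max(e, out["v"]) + 1, w_hi + 1)
                         if _naive_local_max(d1, i)), None)
    # notch: first PPG minimum after sp that precedes a diastolic rebound
    dn_hi = on + int(round(cfg.dp_bound_frac * dur))
    dn = None
    for i in range(sp + 1, dn_hi + 1):
        if _naive_local_min(ppg, i):
            rebound = next((j for j in range(i + 1, dn_hi + 1)
                            if _naive_local_max(ppg, j)), None)
            if rebound is not None and ppg[rebound] - ppg[i] >= 0.005 * (ppg[sp] - ppg[on]):
                dn = i
                break
    out["dn"] = dn
    if dn is not None:
        out["dp"] = next((j for j in range(dn + 1, dn_hi + 1)
                          if _naive_local_max(ppg, j)), None)
    return out


class TestOracleEquivalence:
    def test_brute_force_scan_agrees_within_one_sample(self):
        cfg = PipelineConfig()
        scfg = SynthConfig(hr=60.0, duration=10.0, fs=1000.0)
        raw, _ = generate_synthetic_ppg(scfg, points="sp")
        proc = preprocess(raw, cfg.filter)
        pulses = detect_onsets_offsets(proc, detect_beats(proc, cfg.detector), cfg)
        fids = detect_fiducials(proc, pulses, cfg)
        assert len(pulses) >= 5
        checked = 0
        for pulse, fid in zip(pulses, fids):
            oracle = brute_force_points(proc, pulse, cfg)
            for pt, want in oracle.items():
                got = getattr(fid, pt)
                if want is None:
                    assert got is None, f"{pt}: oracle absent, detector {got}"
                else:
                    assert got is not None, f"{pt}: oracle {want}, detector absent"
                    assert abs(got - want) <= 1, f"{pt}: oracle {want} vs {got}"
                    checked += 1
        assert checked >= 5 * 10
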