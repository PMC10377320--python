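"""Filtering, envelope, MVC normalisation and trial segmentation."""

import numpy as np
import pytest

from limbmanip.emg_pipeline import (
    EMGRecording,
    Marker,
    MVCTable,
    TrialSegmentation,
    TrialWindow,
    bandpass_filter,
    compute_mvc,
    envelope,
    mvc_normalize,
    read_emg_csv,
    read_markers_csv,
    read_mvc_csv,
    rectify,
    resample_trials,
    segment_trials,
    write_emg_csv,
    write_markers_csv,
    write_mvc_csv,
)

FS = 1500.0


def sine(freq, seconds=3.0, amp=1.0, fs=FS):
    t = np.arange(int(seconds * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestBandpass:
    def test_zeros_stay_zero(self):
        assert np.allclose(bandpass_filter(np.zeros(5000), FS), 0.0)

    def test_stopband_5hz(self):
        x = sine(5.0)
        y = bandpass_filter(x, FS)
        assert np.std(y) < 0.05 * np.std(x)

    def test_passband_100hz(self):
        x = sine(100.0)
        y = bandpass_filter(x, FS)
        core = slice(len(x) // 4, -len(x) // 4)  # steady state
        assert np.std(y[core]) == pytest.approx(np.std(x[core]), rel=0.05)

    def test_rate_too_low(self):
        with pytest.raises(ValueError, match="too low"):
            bandpass_filter(np.zeros(1000), 500.0)

    def test_too_short(self):
        with pytest.raises(ValueError, match="too short"):
            bandpass_filter(np.zeros(10), FS)


class TestRectify:
    def test_elementwise_abs(self):
        assert np.array_equal(rectify([-1.0, 2.0, -3.0]), [1.0, 2.0, 3.0])

    def test_nonnegative_unchanged(self, rng):
        x = rng.uniform(0, 5, 100)
        assert np.array_equal(rectify(x), x)

    def test_mean_of_rectified_is_mav(self, rng):
        from limbmanip.emg_metrics import mav

        x = rng.normal(size=200)
        assert np.mean(rectify(x)) == pytest.approx(mav(x), abs=1e-12)


def brute_force_shrinking_median(x, window):
    """Oracle: sort the in-range samples and pick the nearest-rank middle."""
    h = window // 2
    out = np.empty_like(x)
    for i in range(len(x)):
        seg = sorted(x[max(0, i - h) : i + h + 1])
        out[i] = seg[(len(seg) + 1) // 2 - 1]
    return out


class TestEnvelope:
    def test_constant_preserved(self):
        assert np.allclose(envelope(np.full(100, 3.3), 7), 3.3)

    def test_isolated_spike_rejected(self):
        x = np.zeros(50)
        x[25] = 10.0
        assert np.array_equal(envelope(x, 5), np.zeros(50))

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            x = rng.uniform(0, 10, size=rng.integers(10, 40))
            assert np.array_equal(envelope(x, 7), brute_force_shrinking_median(x, 7))

    def test_even_window_coerced_odd(self, rng):
        x = rng.uniform(0, 1, 200)
        assert np.array_equal(envelope(x, 6), envelope(x, 7))

    def test_never_exceeds_input_max(self, rng):
        x = rng.uniform(0, 100, 500)
        assert envelope(x, 31).max() <= x.max()

    def test_window_longer_than_signal(self):
        with pytest.raises(ValueError, match="exceeds"):
            envelope(np.zeros(10), 21)


class TestMVC:
    def test_normalize_arithmetic(self):
        assert mvc_normalize(np.array([250.0]), 500.0) == pytest.approx([0.5])

    def test_normalize_by_own_max_peaks_at_one(self, rng):
        env = rng.uniform(0, 400, 1000)
        assert mvc_normalize(env, env.max()).max() == pytest.approx(1.0)

    def test_nonpositive_mvc_rejected(self):
        with pytest.raises(ValueError):
            mvc_normalize(np.ones(3), 0.0)
        with pytest.raises(ValueError):
            MVCTable({"fcu": -1.0})

    def test_designed_plateau_recovered(self, rng):
        # 40 % of a 500 uV MVC, held long enough for full median windows
        t = np.arange(int(14 * FS)) / FS
        level = np.interp(t, [0, 2, 2.4, 11.6, 12, 14], [0, 0, 0.4, 0.4, 0, 0])
        carrier = bandpass_filter(rng.normal(size=len(t)), FS)
        carrier /= np.median(np.abs(carrier))
        x = carrier * level * 500.0 + rng.normal(scale=5.0, size=len(t))
        env = envelope(rectify(bandpass_filter(x, FS)), 3500)
        plateau = env[int(4.5 * FS) : int(9.5 * FS)] / 500.0
        assert np.mean(plateau) == pytest.approx(0.40, abs=0.05)

    def test_compute_mvc_finds_injected_burst(self):
        # a 100 Hz, 800 uV burst sits in the passband and survives filtering
        x = sine(100.0, seconds=3.0, amp=50.0)
        burst = slice(int(1.0 * FS), int(2.0 * FS))
        x[burst] = sine(100.0, seconds=1.0, amp=800.0)
        rec = EMGRecording(rate=FS, channels={"fcu": x, "ecu": x, "bb": x, "dm": x})
        assert compute_mvc(rec, "dm") == pytest.approx(800.0, rel=0.05)

    def test_compute_mvc_zero_recording(self):
        z = np.zeros(5000)
        rec = EMGRecording(rate=FS, channels={"fcu": z, "ecu": z, "bb": z, "dm": z})
        assert compute_mvc(rec, "fcu") == 0.0
        with pytest.raises(ValueError):
            MVCTable({"fcu": compute_mvc(rec, "fcu")})


class TestSegmentTrials:
    def _rec(self, n=400):
        z = np.zeros(n)
        return EMGRecording(rate=FS, channels={"fcu": z, "ecu": z, "bb": z, "dm": z})

    def test_two_windows(self):
        markers = [
            Marker(0, "trigger_start", 0),
            Marker(0, "trigger_end", 100),
            Marker(1, "trigger_start", 200),
            Marker(1, "trigger_end", 300),
        ]
        seg = segment_trials(self._rec(), markers)
        assert [(w.start, w.end) for w in seg.trials] == [(0, 100), (200, 300)]

    def test_empty_markers_zero_trials(self, caplog):
        seg = segment_trials(self._rec(), [])
        assert len(seg.trials) == 0

    def test_unpaired_markers_rejected(self):
        with pytest.raises(ValueError, match="unpaired"):
            segment_trials(self._rec(), [Marker(0, "trigger_start", 0)])

    def test_generator_markers_round_trip(self):
        from limbmanip.synthetic_data import EXERCISE_1, GeneratorConfig, generate_emg

        cfg = GeneratorConfig(seed=7, n_trials=3)
        rec, markers, truth = generate_emg(EXERCISE_1, cfg, rng_key=(0, 0))
        seg = segment_trials(
            rec, markers, phase_fractions=EXERCISE_1.phase_fractions
        )
        got = [(w.start, w.end, w.activity_start, w.activity_end) for w in seg.trials]
        want = [
            tuple(t["window"]) + tuple(t["activity"]) for t in truth["trials"]
        ]
        assert got == want

    def test_phase_windows_partition_activity(self):
        w = TrialWindow(0, 0, 1000, 100, 900)
        seg = TrialSegmentation((w,), (0.25, 0.5, 0.75))
        windows = seg.phase_windows(w)
        assert windows[0][0] == 100 and windows[-1][1] == 900
        assert all(a < b for a, b in windows)
        assert [b for _, b in windows[:-1]] == [a for a, _ in windows[1:]]


class TestResampleTrials:
    def test_equal_lengths_unchanged(self, rng):
        trials = [rng.normal(size=50) for _ in range(3)]
        out, n = resample_trials(trials)
        assert n == 50
        for a, b in zip(out, trials):
            assert np.allclose(a, b, atol=1e-12)

    def test_mean_length(self):
        out, n = resample_trials([np.zeros(90), np.zeros(110)])
        assert n == 100 and all(len(t) == 100 for t in out)

    def test_ramp_closed_form(self):
        ramp = np.linspace(0.0, 1.0, 90)
        out, n = resample_trials([ramp, np.linspace(0.0, 1.0, 110)])
        for t in out:
            assert np.allclose(t, np.linspace(0, 1, n), atol=1e-10)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            resample_trials([])


def test_pipeline_composition_preserves_nonnegativity(rng):
    # rectification's nonnegativity must survive envelope + normalisation
    x = rng.normal(scale=50, size=8000)
    y = mvc_normalize(envelope(rectify(bandpass_filter(x, FS)), 501), 400.0)
    assert np.all(y >= 0)


def test_sensor_range_enforced():
    bad = np.full(100, 6000.0)
    with pytest.raises(ValueError, match="sensor range"):
        EMGRecording(rate=FS, channels={"fcu": bad, "ecu": bad, "bb": bad, "dm": bad})


def test_file_dialect_round_trips(tmp_path, rng):
    n = 3000
    channels = {m: rng.normal(scale=50, size=n) for m in ("fcu", "ecu", "bb", "dm")}
    rec = EMGRecording(rate=FS, channels=channels)
    write_emg_csv(rec, tmp_path / "emg.csv")
    back = read_emg_csv(tmp_path / "emg.csv")
    assert back.rate == pytest.approx(FS, rel=1e-3)
    assert np.allclose(back.channels["dm"], rec.channels["dm"], atol=1e-3)

    markers = [Marker(0, "trigger_start", 0), Marker(0, "trigger_end", n)]
    write_markers_csv(markers, tmp_path / "markers.csv")
    assert read_markers_csv(tmp_path / "markers.csv") == markers

    table = MVCTable({"fcu": 400.0, "ecu": 450.0, "bb": 500.0, "dm": 350.0})
    write_mvc_csv(table, tmp_path / "mvc.csv")
    assert read_mvc_csv(tmp_path / "mvc.csv").values == table.values
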