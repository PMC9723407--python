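import numpy as np
import pytest

from nremscope.events import (detect_slow_waves, detect_spindles,
                              summarize_events)
from nremscope.synthsleep import (NoiseSpec, _background_noise, _spindle_wave,
                                  _sw_wave)

FS = 100.0
NPER = 3000


def _background(n_epochs, sd=2.0, seed=0):
    rng = np.random.default_rng(seed)
    return rng.normal(0, sd, size=n_epochs * NPER)


def _inject(sig, t0_s, wave):
    i0 = int(round(t0_s * FS))
    sig[i0:i0 + wave.size] += wave
    return t0_s, t0_s + wave.size / FS


def test_spindle_detection_recovers_injection():
    sig = _background(4)
    onset, offset = _inject(sig, 40.0,
                            _spindle_wave(120, FS, 13.5, 60.0, 0.3))
    events = detect_spindles(sig, range(4), center_freq=13.5)
    hits = [e for e in events if e.onset_s < offset and e.offset_s > onset]
    assert len(hits) == 1
    e = hits[0]
    assert e.amplitude_uv == pytest.approx(60.0, rel=0.10)
    assert e.frequency_hz == pytest.approx(13.5, abs=0.3)
    assert onset <= e.envelope_peak_s <= offset
    assert e.duration_s == pytest.approx(e.offset_s - e.onset_s)


def test_spindle_duration_filter():
    sig = _background(4)
    onset, offset = _inject(sig, 40.0,
                            _spindle_wave(300, FS, 13.5, 60.0, 0.0))  # 3 s
    events = detect_spindles(sig, range(4), center_freq=13.5)
    assert not [e for e in events if e.onset_s < offset and e.offset_s > onset]
    # the same 1.2-s injection is rejected when the duration floor is raised
    sig2 = _background(4)
    onset2, offset2 = _inject(sig2, 40.0,
                              _spindle_wave(120, FS, 13.5, 60.0, 0.0))
    strict = detect_spindles(sig2, range(4), center_freq=13.5,
                             min_duration_s=1.8)
    assert not [e for e in strict
                if e.onset_s < offset2 and e.offset_s > onset2]


def test_spindle_gap_merging():
    sig = _background(4)
    # two 0.4-s bursts, 0.05-s gap: individually too short, merged long enough
    _inject(sig, 40.0, _spindle_wave(40, FS, 13.5, 60.0, 0.0))
    _inject(sig, 40.45, _spindle_wave(40, FS, 13.5, 60.0, 0.0))
    events = detect_spindles(sig, range(4), center_freq=13.5)
    hits = [e for e in events if e.onset_s < 40.85 and e.offset_s > 40.0]
    assert len(hits) == 1


def test_spindle_outside_usable_epochs_not_detected():
    sig = _background(4)
    _inject(sig, 40.0, _spindle_wave(120, FS, 13.5, 60.0, 0.0))  # epoch 1
    events = detect_spindles(sig, [0, 2, 3], center_freq=13.5)
    assert not [e for e in events if e.onset_s < 42 and e.offset_s > 40]


def test_spindle_center_frequency_range_enforced():
    with pytest.raises(ValueError):
        detect_spindles(np.zeros(NPER), [0], center_freq=11.0)
    with pytest.raises(ValueError):
        detect_spindles(np.zeros(NPER), [], center_freq=13.5)


def _sw_signal(n_epochs=10, seed=1):
    """Slow-free background + large target SWs + small background waves.

    The background must carry no sub-2 Hz stochastic power: slow noise
    oscillations would be unlabeled candidates of the slow-wave class and
    make the small-vs-large assertions below ill-posed.
    """
    rng0 = np.random.default_rng(seed)
    sig = 2.0 * _background_noise(n_epochs * NPER, FS, NoiseSpec(), rng0)
    sig = sig.astype(np.float64)
    rng = np.random.default_rng(seed + 100)
    big, small = [], []
    for e in range(n_epochs):
        t = e * 30.0 + 3.0
        dur = rng.uniform(1.1, 1.4)
        big.append(_inject(sig, t, _sw_wave(int(round(dur * FS)), FS,
                                            rng.uniform(-90, -60),
                                            rng.uniform(30, 60))))
        for j in range(3):
            t2 = e * 30.0 + 8.0 + 6.0 * j
            dur2 = rng.uniform(1.1, 1.4)
            small.append(_inject(sig, t2, _sw_wave(int(round(dur2 * FS)), FS,
                                                   rng.uniform(-10, -4),
                                                   rng.uniform(3, 8))))
    return sig, big, small


def test_sw_detection_selects_large_waves():
    sig, big, small = _sw_signal()
    events = detect_slow_waves(sig, range(10))

    def covering(t0, t1):
        return [e for e in events if e.start_s < t1 and e.end_s > t0]

    assert all(len(covering(*iv)) == 1 for iv in big)
    assert not any(covering(*iv) for iv in small)


def test_sw_frequency_is_reciprocal_duration():
    sig, big, _ = _sw_signal()
    events = detect_slow_waves(sig, range(10))
    assert events
    for e in events:
        assert e.frequency_hz == 1.0 / e.duration_s
        assert e.start_s < e.trough_s < e.up_crossing_s < e.peak_s < e.end_s
        assert e.trough_uv < 0 < e.peak_uv
        assert e.amplitude_uv == pytest.approx(e.peak_uv - e.trough_uv)


def test_sw_amplitude_threshold_is_relative():
    sig, big, small = _sw_signal()
    strict = detect_slow_waves(sig, range(10), amp_factor=1.25)
    lax = detect_slow_waves(sig, range(10), amp_factor=0.0)
    assert len(lax) > len(strict)     # zero factor admits the candidate floor


def test_sw_unusable_epoch_excluded():
    sig, big, _ = _sw_signal()
    events = detect_slow_waves(sig, [e for e in range(10) if e != 0])
    t0, t1 = big[0]
    assert not [e for e in events if e.start_s < t1 and e.end_s > t0]


def test_sw_empty_signal():
    assert detect_slow_waves(np.zeros(NPER), [0]) == []
    with pytest.raises(ValueError):
        detect_slow_waves(np.zeros(NPER), [])


def test_summarize_events():
    sig, big, _ = _sw_signal()
    events = detect_slow_waves(sig, range(10))
    s = summarize_events(events, 10)
    assert s.count == len(events)
    assert s.density_per_epoch == pytest.approx(len(events) / 10)
    assert s.mean_amplitude_uv == pytest.approx(
        np.mean([e.amplitude_uv for e in events]))
    empty = summarize_events([], 10)
    assert empty.count == 0 and empty.mean_amplitude_uv is None
    with pytest.raises(ValueError):
        summarize_events([], 0)
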