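import numpy as np
import pytest

from nremscope import spectral
from nremscope.spectral import (FREQ_LO, FREQ_STEP, PowerSpectrum, band_power,
                                db_transform, find_spindle_peak_frequency,
                                mean_spectrum, permutation_spectral_test,
                                welch_psd)

FS = 100.0
NPER = 3000  # samples per 30-s epoch


def _tone(freq, n_epochs=2, amp=1.0):
    t = np.arange(n_epochs * NPER) / FS
    return amp * np.sin(2 * np.pi * freq * t)


def test_tone_localizes_with_half_squared_amplitude():
    amp = 5.0
    spec = welch_psd(_tone(13.0, amp=amp), [0, 1])
    k = int(np.argmax(spec.power))
    assert spec.freqs[k] == pytest.approx(13.0)
    assert spec.power[k] == pytest.approx(amp ** 2 / 2, rel=1e-3)
    # frequency grid: 0.6..30 in 0.2 Hz steps
    assert spec.freqs[0] == pytest.approx(FREQ_LO)
    assert np.allclose(np.diff(spec.freqs), FREQ_STEP)


def test_interval_count():
    spec = welch_psd(np.zeros(3 * NPER), [0, 1, 2])
    assert spec.n_intervals == 3 * 26


def test_excluded_epochs_do_not_leak():
    sig = np.zeros(3 * NPER)
    sig[NPER:2 * NPER] = _tone(13.0, n_epochs=1, amp=100.0)
    spec = welch_psd(sig, [0, 2])   # epoch 1 (the tone) excluded
    assert spec.power.max() < 1e-12


def test_welch_psd_errors():
    with pytest.raises(ValueError, match="no usable"):
        welch_psd(np.zeros(NPER), [])
    with pytest.raises(ValueError, match="cover"):
        welch_psd(np.zeros(NPER), [3])


def test_db_transform_exact():
    np.testing.assert_array_equal(db_transform([0.0, 9.0, 99.0]),
                                  [0.0, 10.0, 20.0])
    with pytest.raises(ValueError):
        db_transform([-1.0])


def test_band_power_inclusive_bounds():
    freqs = np.arange(FREQ_LO, 30.0 + 1e-9, FREQ_STEP)
    power = np.zeros_like(freqs)
    power[(freqs >= 1.0 - 1e-9) & (freqs <= 2.0 + 1e-9)] = 9.0   # -> 10 dB
    spec = PowerSpectrum(freqs=freqs, power=power, n_intervals=1)
    assert band_power(spec, 1.0, 2.0) == pytest.approx(10.0)
    with pytest.raises(ValueError):
        band_power(spec, 2.0, 1.0)


def test_mean_spectrum():
    freqs = np.arange(FREQ_LO, 30.0 + 1e-9, FREQ_STEP)
    a = PowerSpectrum(freqs=freqs, power=np.full_like(freqs, 2.0), n_intervals=4)
    b = PowerSpectrum(freqs=freqs, power=np.full_like(freqs, 4.0), n_intervals=6)
    m = mean_spectrum([a, b])
    assert np.allclose(m.power, 3.0)
    assert m.n_intervals == 10


def _null_spectra(rng, n, n_epochs=2):
    return [welch_psd(rng.standard_normal(n_epochs * NPER), range(n_epochs))
            for _ in range(n)]


def test_permutation_test_null_and_effect():
    rng = np.random.default_rng(42)
    group_a = _null_spectra(rng, 6)
    group_b = _null_spectra(rng, 6)
    # inject a large group difference into a narrow band for group B
    band = (group_a[0].freqs >= 12.9) & (group_a[0].freqs <= 13.1)
    for s in group_b:
        s.power[band] += 50.0
    res = permutation_spectral_test(group_a, group_b, n_perm=499, rng=rng)
    # random label permutations can redraw the true split, so the smallest
    # achievable p is (1 + #identical splits) / (n_perm + 1)
    assert res.p[band].max() <= 0.02
    assert np.all(res.p >= 1.0 / 500.0)
    assert np.all(res.p <= 1.0)
    # far from the injected band, most bins are unremarkable
    assert np.median(res.p[~band]) > 0.2


def test_permutation_test_needs_two_per_group():
    rng = np.random.default_rng(0)
    s = _null_spectra(rng, 3)
    with pytest.raises(ValueError):
        permutation_spectral_test(s[:1], s[1:], n_perm=19)


def _bump_spectrum(center, height_db=3.0, width=0.5):
    freqs = np.arange(FREQ_LO, 30.0 + 1e-9, FREQ_STEP)
    base_db = 5.0 - 0.1 * freqs
    db = base_db + height_db * np.exp(-0.5 * ((freqs - center) / width) ** 2)
    return PowerSpectrum(freqs=freqs, power=10 ** (db / 10) - 1, n_intervals=1)


def test_spindle_peak_found_and_confident():
    peak = find_spindle_peak_frequency(_bump_spectrum(13.4))
    assert peak.frequency_hz == pytest.approx(13.4)
    assert peak.confident


def test_spindle_peak_not_confident_on_flat_spectrum():
    freqs = np.arange(FREQ_LO, 30.0 + 1e-9, FREQ_STEP)
    spec = PowerSpectrum(freqs=freqs, power=np.full_like(freqs, 2.0),
                         n_intervals=1)
    peak = find_spindle_peak_frequency(spec)
    assert not peak.confident
    assert 12.0 <= peak.frequency_hz <= 15.0


def test_spindle_peak_outside_search_band_ignored():
    # bump at 11 Hz sits in the fit window but outside the 12-15 Hz search
    peak = find_spindle_peak_frequency(_bump_spectrum(11.0, height_db=6.0))
    assert not (11.0 - 0.3 <= peak.frequency_hz <= 11.0 + 0.3)
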