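"""Welch spectra of artifact-free non-REM sleep and per-bin permutation tests.

Spectra are computed from Hann-tapered 5-s intervals advancing in 1-s steps
inside usable 30-s epochs (26 intervals per epoch; intervals never straddle
an epoch boundary, so excluded epochs cannot leak samples).  At 100 Hz this
gives 500-sample FFTs and a 0.2 Hz grid, reported over 0.6-30 Hz.

Power is one-sided per-bin power in µV² (window power normalization: an
on-grid sine of amplitude A lands A²/2 in its bin).  Group comparisons are
run on dB-transformed values, 10*log10(power + 1), with a label-permutation
Welch t-test per frequency bin and the (1+k)/(1+n) p-value estimator.  No
multiple-comparison correction is applied across bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft
from scipy import signal as sp_signal

__all__ = [
    "PowerSpectrum",
    "SpectralTestResult",
    "SpindlePeak",
    "FREQ_LO",
    "FREQ_HI",
    "FREQ_STEP",
    "welch_psd",
    "db_transform",
    "band_power",
    "permutation_spectral_test",
    "find_spindle_peak_frequency",
    "mean_spectrum",
]

FREQ_LO = 0.6
FREQ_HI = 30.0
FREQ_STEP = 0.2


@dataclass
class PowerSpectrum:
    freqs: np.ndarray         # Hz, 0.6..30.0 step 0.2
    power: np.ndarray         # µV² per bin
    n_intervals: int
    channel: str = ""

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs/power shape mismatch")
        if np.any(self.power < 0):
            raise ValueError("negative power")

    @property
    def power_db(self) -> np.ndarray:
        return db_transform(self.power)


@dataclass
class SpectralTestResult:
    freqs: np.ndarray
    t: np.ndarray             # observed Welch t per bin
    p: np.ndarray             # two-tailed permutation p per bin
    n_permutations: int


@dataclass
class SpindlePeak:
    frequency_hz: float
    confident: bool
    prominence_db: float


def welch_psd(signal: np.ndarray, usable_epochs, fs: float = 100.0,
              channel: str = "", epoch_s: float = 30.0,
              window_s: float = 5.0, step_s: float = 1.0) -> PowerSpectrum:
    """Welch power spectrum over the given usable 30-s epochs."""
    signal = np.asarray(signal)
    usable_epochs = np.asarray(usable_epochs, dtype=int)
    if usable_epochs.size == 0:
        raise ValueError("empty spectrum: no usable epochs")
    nper_epoch = int(round(epoch_s * fs))
    nwin = int(round(window_s * fs))
    nstep = int(round(step_s * fs))
    if (usable_epochs.max() + 1) * nper_epoch > signal.shape[-1]:
        raise ValueError("signal does not cover the usable epochs")

    epochs = signal[usable_epochs[:, None] * nper_epoch
                    + np.arange(nper_epoch)[None, :]]
    # sliding 5-s intervals confined within each epoch
    segs = np.lib.stride_tricks.sliding_window_view(epochs, nwin, axis=1)[:, ::nstep, :]
    segs = segs.reshape(-1, nwin)          # materializes a writable copy
    win = sp_signal.get_window("hann", nwin)
    np.multiply(segs, win.astype(segs.dtype, copy=False), out=segs)
    spec = sp_fft.rfft(segs, axis=-1)
    # one-sided per-bin power, window power normalization (µV² per bin);
    # accumulate the across-interval mean in float64 regardless of the
    # signal dtype
    power = ((np.abs(spec) ** 2).mean(axis=0, dtype=np.float64)
             * 2.0 / win.sum() ** 2)

    freqs = np.fft.rfftfreq(nwin, d=1.0 / fs)
    keep = (freqs >= FREQ_LO - 1e-9) & (freqs <= FREQ_HI + 1e-9)
    return PowerSpectrum(freqs=freqs[keep], power=power[keep],
                         n_intervals=segs.shape[0], channel=channel)


def db_transform(power) -> np.ndarray:
    """dB transform with unit offset: 10*log10(power + 1)."""
    power = np.asarray(power, dtype=float)
    if np.any(power < 0):
        raise ValueError("negative power")
    return 10.0 * np.log10(power + 1.0)


def band_power(spec: PowerSpectrum, lo: float, hi: float) -> float:
    """Mean dB value over bins with lo <= f <= hi (inclusive)."""
    if not (lo < hi or np.isclose(lo, hi)):
        raise ValueError("need lo <= hi")
    sel = (spec.freqs >= lo - 1e-9) & (spec.freqs <= hi + 1e-9)
    if not sel.any():
        raise ValueError(f"empty band [{lo}, {hi}] Hz")
    return float(spec.power_db[sel].mean())


def mean_spectrum(spectra: list[PowerSpectrum]) -> PowerSpectrum:
    """Average spectra across channels (subject-level spectrum)."""
    if not spectra:
        raise ValueError("no spectra to average")
    freqs = spectra[0].freqs
    for s in spectra[1:]:
        if not np.allclose(s.freqs, freqs):
            raise ValueError("spectra not on a common grid")
    return PowerSpectrum(freqs=freqs,
                         power=np.mean([s.power for s in spectra], axis=0),
                         n_intervals=sum(s.n_intervals for s in spectra),
                         channel="mean")


def _welch_t_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Welch t between two matrices (rows = subjects)."""
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    denom = np.sqrt(va / a.shape[0] + vb / b.shape[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / denom
    return np.where(denom > 0, t, 0.0)


def permutation_spectral_test(group_a: list[PowerSpectrum],
                              group_b: list[PowerSpectrum],
                              n_perm: int = 10_000,
                              rng=None) -> SpectralTestResult:
    """Per-bin two-tailed permutation Welch t-test on dB spectra.

    p per bin = (1 + #{|t_perm| >= |t_obs|}) / (n_perm + 1) over random
    group-label permutations.
    """
    na, nb = len(group_a), len(group_b)
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 subjects per group")
    rng = np.random.default_rng(rng)
    freqs = group_a[0].freqs
    # float64 throughout: the permutation variance uses the E[x^2]-E[x]^2
    # form, which cancels catastrophically in single precision
    x = np.vstack([s.power_db for s in group_a + group_b]).astype(
        np.float64, copy=False)
    if x.shape[1] != freqs.size:
        raise ValueError("spectra not on a common grid")
    n = na + nb
    t_obs = _welch_t_matrix(x[:na], x[na:])

    # vectorized label permutations: selection matrices for group A
    perm = np.argsort(rng.random((n_perm, n)), axis=1)
    sel = np.zeros((n_perm, n), dtype=x.dtype)
    np.put_along_axis(sel, perm[:, :na], 1.0, axis=1)
    sx, sx2 = x, x * x
    sum_a = sel @ sx
    sum_a2 = sel @ sx2
    tot = sx.sum(axis=0)
    tot2 = sx2.sum(axis=0)
    mean_a = sum_a / na
    mean_b = (tot - sum_a) / nb
    var_a = (sum_a2 - na * mean_a ** 2) / (na - 1)
    var_b = (tot2 - sum_a2 - nb * mean_b ** 2) / (nb - 1)
    denom = np.sqrt(np.maximum(var_a, 0) / na + np.maximum(var_b, 0) / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = (mean_a - mean_b) / denom
    t_perm = np.where(denom > 0, t_perm, 0.0)

    exceed = (np.abs(t_perm) >= np.abs(t_obs)[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (n_perm + 1.0)
    return SpectralTestResult(freqs=freqs, t=t_obs, p=p, n_permutations=n_perm)


def find_spindle_peak_frequency(spec: PowerSpectrum,
                                search_lo: float = 12.0,
                                search_hi: float = 15.0,
                                fit_lo: float = 9.0,
                                fit_hi: float = 17.0,
                                prominence_db: float = 0.5) -> SpindlePeak:
    """Automated fast-spindle peak estimate (surrogate for visual scoring).

    The dB spectrum in the 9-17 Hz fit window is detrended by a linear fit;
    the peak is the largest local maximum of the residual inside the 12-15 Hz
    search band.  ``confident`` is True iff that residual exceeds
    ``prominence_db``; non-confident subjects should be re-run with the
    group-average peak.  Ties break to the lower frequency.
    """
    sel = (spec.freqs >= fit_lo - 1e-9) & (spec.freqs <= fit_hi + 1e-9)
    f, y = spec.freqs[sel], spec.power_db[sel]
    if f.size < 3:
        raise ValueError("spectrum does not cover the fit window")
    coef = np.polyfit(f, y, 1)
    resid = y - np.polyval(coef, f)

    inside = (f >= search_lo - 1e-9) & (f <= search_hi + 1e-9)
    # local maxima of the residual (plateaus count once, at their left edge)
    peaks, _ = sp_signal.find_peaks(resid)
    peaks = [i for i in peaks if inside[i]]
    if not peaks:
        # fall back to the best in-band bin, flagged not confident
        idx = np.flatnonzero(inside)
        best = idx[np.argmax(resid[idx])]
        return SpindlePeak(float(f[best]), False, float(resid[best]))
    best = max(peaks, key=lambda i: (resid[i], -f[i]))
    return SpindlePeak(frequency_hz=float(f[best]),
                       confident=bool(resid[best] > prominence_db),
                       prominence_db=float(resid[best]))
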