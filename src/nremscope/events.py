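"""Sleep spindle and slow-wave detection in artifact-free non-REM sleep.

Spindles: band-pass around the individual fast-spindle peak (default ±1 Hz),
RMS envelope in a 0.2-s sliding window, threshold at 1.5 standard deviations
of the band-passed signal over the usable epochs; candidate runs separated
by less than 0.1 s are merged before the 0.5-2.0 s duration filter.
Amplitude is the maximal trough-to-peak excursion of the signal band-passed
in a fixed 10-16 Hz sigma band (independent of the individualized detection
band, so amplitude is comparable across subjects), and frequency is counted
from zero crossings of the detection-band signal.

Slow waves: band-pass 0.3-1.5 Hz, delineation by positive-to-negative zero
crossings with exactly one up-crossing inside, duration filter 0.9-2.0 s
(the 0.5-1.11 Hz target range), then the two relative amplitude criteria:
|trough| and trough-to-peak amplitude must each exceed 1.25 times their
candidate means (per channel, per night).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .filters import ZeroPhaseFilterBank, zerophase_bandpass

__all__ = [
    "SpindleEvent",
    "SlowWaveEvent",
    "EventSummary",
    "detect_spindles",
    "detect_slow_waves",
    "summarize_events",
]


@dataclass
class SpindleEvent:
    channel: str
    onset_s: float
    offset_s: float
    duration_s: float
    amplitude_uv: float       # max trough-to-peak of band-passed signal
    frequency_hz: float       # cycles within event / duration
    envelope_peak_s: float    # time of max smoothed envelope


@dataclass
class SlowWaveEvent:
    channel: str
    start_s: float            # positive-to-negative zero crossing
    trough_s: float
    trough_uv: float          # down-state peak (negative)
    up_crossing_s: float      # negative-to-positive crossing
    peak_s: float
    peak_uv: float            # up-state maximum after the up-crossing
    end_s: float              # next positive-to-negative crossing
    duration_s: float
    amplitude_uv: float       # peak - trough
    frequency_hz: float       # 1 / duration


@dataclass
class EventSummary:
    count: int
    density_per_epoch: float
    mean_amplitude_uv: float | None
    mean_duration_ms: float | None
    mean_frequency_hz: float | None


def _usable_sample_mask(n_samples: int, usable_epochs, fs: float,
                        epoch_s: float = 30.0) -> np.ndarray:
    nper = int(round(epoch_s * fs))
    mask = np.zeros(n_samples, dtype=bool)
    for e in np.asarray(usable_epochs, dtype=int):
        mask[e * nper:(e + 1) * nper] = True
    return mask


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of True runs (stop exclusive)."""
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        stops = np.r_[stops, mask.size]
    return list(zip(starts.tolist(), stops.tolist()))


def detect_spindles(signal: np.ndarray, usable_epochs, center_freq: float,
                    fs: float = 100.0, threshold_sd: float = 1.5,
                    band_halfwidth_hz: float = 1.0,
                    min_duration_s: float = 0.5, max_duration_s: float = 2.0,
                    merge_gap_s: float = 0.1, envelope_window_s: float = 0.2,
                    measure_band=(10.0, 16.0), channel: str = "",
                    bank: ZeroPhaseFilterBank | None = None) -> list[SpindleEvent]:
    """Detect fast spindles around ``center_freq`` within usable epochs.

    ``bank`` optionally supplies a precomputed zero-phase filter bank for
    the signal (shared across detectors to avoid repeated forward FFTs).
    """
    if not 12.0 <= center_freq <= 15.0:
        raise ValueError("center frequency must lie in 12-15 Hz")
    usable_epochs = np.asarray(usable_epochs, dtype=int)
    if usable_epochs.size == 0:
        raise ValueError("no usable epochs")
    signal = np.asarray(signal)
    if bank is None:
        bank = ZeroPhaseFilterBank(signal, fs,
                                   pad_s=4.0 / min(measure_band[0],
                                                   center_freq - band_halfwidth_hz))
    filt = bank.bandpass(center_freq - band_halfwidth_hz,
                         center_freq + band_halfwidth_hz, order=4)
    nwin = max(1, int(round(envelope_window_s * fs)))
    env = uniform_filter1d(filt * filt, size=nwin, mode="nearest")
    np.sqrt(env, out=env)
    usable = _usable_sample_mask(signal.size, usable_epochs, fs)

    sd = float(filt[usable].std(dtype=np.float64))
    if sd == 0.0:
        return []
    thr = threshold_sd * sd

    above = (env >= thr) & usable
    if not above.any():
        return []
    runs = _runs(above)
    # merge runs separated by short gaps, then apply the duration filter
    merged = [list(runs[0])]
    max_gap = int(round(merge_gap_s * fs))
    for s, e in runs[1:]:
        if s - merged[-1][1] < max_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    meas = None
    events = []
    min_n = int(round(min_duration_s * fs))
    max_n = int(round(max_duration_s * fs))
    for s, e in merged:
        n = e - s
        if not (min_n <= n <= max_n):
            continue
        if not usable[s:e].all():
            continue
        if meas is None:
            meas = bank.bandpass(*measure_band, order=4)
        seg = filt[s:e]
        peak_rel = 1 + int(np.argmax(env[s + 1:e - 1])) if n > 2 else n // 2
        crossings = int(np.count_nonzero(np.signbit(seg[:-1]) != np.signbit(seg[1:])))
        duration = n / fs
        events.append(SpindleEvent(
            channel=channel,
            onset_s=s / fs,
            offset_s=e / fs,
            duration_s=duration,
            amplitude_uv=float(meas[s:e].max() - meas[s:e].min()),
            frequency_hz=(crossings / 2.0) / duration,
            envelope_peak_s=(s + peak_rel) / fs,
        ))
    return events


def _interp_crossing(x: np.ndarray, i: int) -> float:
    """Sub-sample crossing position between samples i and i+1."""
    denom = x[i] - x[i + 1]
    return i + (x[i] / denom if denom != 0 else 0.5)


def detect_slow_waves(signal: np.ndarray, usable_epochs, fs: float = 100.0,
                      band=(0.3, 1.5), min_duration_s: float = 0.9,
                      max_duration_s: float = 2.0, amp_factor: float = 1.25,
                      channel: str = "",
                      bank: ZeroPhaseFilterBank | None = None) -> list[SlowWaveEvent]:
    """Detect slow waves within usable epochs (empty list if no candidates)."""
    usable_epochs = np.asarray(usable_epochs, dtype=int)
    if usable_epochs.size == 0:
        raise ValueError("no usable epochs")
    signal = np.asarray(signal)
    if bank is None:
        filt = zerophase_bandpass(signal, fs, band[0], band[1], order=3)
    else:
        filt = bank.bandpass(band[0], band[1], order=3)

    pos = filt > 0
    down = np.flatnonzero(pos[:-1] & ~pos[1:])   # positive-to-negative
    up = np.flatnonzero(~pos[:-1] & pos[1:])     # negative-to-positive
    if down.size < 2:
        return []

    a, b = down[:-1], down[1:]
    # vectorized candidate prefilter: interpolated duration, exactly one
    # up-crossing inside, all samples usable
    denom_a = filt[a] - filt[a + 1]
    denom_b = filt[b] - filt[b + 1]
    t_start = (a + np.where(denom_a != 0, filt[a] / denom_a, 0.5)) / fs
    t_end = (b + np.where(denom_b != 0, filt[b] / denom_b, 0.5)) / fs
    duration = t_end - t_start
    n_ups = (np.searchsorted(up, b, side="left")
             - np.searchsorted(up, a, side="right"))
    # usability is epoch-granular: a candidate (using samples a..b+1) is
    # usable iff every epoch it touches is usable (a trailing partial epoch
    # counts as unusable)
    nper = int(round(30.0 * fs))
    n_full = signal.size // nper
    good = np.zeros(n_full + 1, dtype=bool)
    good[usable_epochs[usable_epochs < n_full]] = True
    bad_prefix = np.concatenate([[0], np.cumsum(~good)])
    e_lo = a // nper
    e_hi = np.minimum((b + 1) // nper, n_full)
    all_usable = bad_prefix[e_hi + 1] - bad_prefix[e_lo] == 0
    keep = ((duration >= min_duration_s) & (duration <= max_duration_s)
            & (n_ups == 1) & all_usable)

    ks = np.flatnonzero(keep)
    if ks.size == 0:
        return []
    t_start_k, t_end_k, duration_k = t_start[ks], t_end[ks], duration[ks]
    A, B = a[ks], b[ks]
    U = up[np.searchsorted(up, A, side="right")]
    # segmented extrema via reduceat (segments interleave with the gaps
    # between candidates; keep every other result)
    tvals = np.minimum.reduceat(filt, np.column_stack([A + 1, U + 1]).ravel())[::2]
    pvals = np.maximum.reduceat(filt, np.column_stack([U + 1, B + 1]).ravel())[::2]
    troughs = np.abs(tvals)
    amps = pvals - tvals
    thr_trough = amp_factor * troughs.mean(dtype=np.float64)
    thr_amp = amp_factor * amps.mean(dtype=np.float64)

    events = []
    for i in np.flatnonzero((troughs >= thr_trough) & (amps >= thr_amp)):
        ai, bi, u = int(A[i]), int(B[i]), int(U[i])
        tr = ai + 1 + int(np.argmin(filt[ai + 1:u + 1]))
        pk = u + 1 + int(np.argmax(filt[u + 1:bi + 1]))
        duration = float(duration_k[i])
        events.append(SlowWaveEvent(
            channel=channel,
            start_s=float(t_start_k[i]),
            trough_s=tr / fs,
            trough_uv=float(filt[tr]),
            up_crossing_s=_interp_crossing(filt, u) / fs,
            peak_s=pk / fs,
            peak_uv=float(filt[pk]),
            end_s=float(t_end_k[i]),
            duration_s=duration,
            amplitude_uv=float(amps[i]),
            frequency_hz=1.0 / duration,
        ))
    return events


def summarize_events(events, n_usable_epochs: int) -> EventSummary:
    """Density, count, and mean amplitude/duration/frequency of events."""
    if n_usable_epochs < 1:
        raise ValueError("need at least one usable epoch")
    count = len(events)
    if count == 0:
        return EventSummary(count=0, density_per_epoch=0.0,
                            mean_amplitude_uv=None, mean_duration_ms=None,
                            mean_frequency_hz=None)
    return EventSummary(
        count=count,
        density_per_epoch=count / n_usable_epochs,
        mean_amplitude_uv=float(np.mean([e.amplitude_uv for e in events])),
        mean_duration_ms=float(np.mean([e.duration_s for e in events]) * 1000.0),
        mean_frequency_hz=float(np.mean([e.frequency_hz for e in events])),
    )
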