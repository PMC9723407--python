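"""Synthetic polysomnography cohorts with ground-truth event logs.

The generator produces everything the pipeline consumes: a Markov-chain
hypnogram, two central EEG channels (plus mastoid references constructed so
contralateral re-referencing reproduces the target signals) carrying
stage-scaled 1/f^alpha background noise with injected spindle bursts
(Hann-enveloped sinusoids at a per-subject center frequency) and slow waves
(one asymmetric biphasic sine period, trough before peak, so zero-crossing
delineation holds exactly), a configurable fraction of spindles coupled to
slow waves with truncated-normal delays, an artifact mask, and behavioral
(finger-tapping) plus clinical (HAMD) tables with configurable group
effects.  Every injection is logged, with realized (post-truncation,
sample-aligned) times and delays, so detector recovery can be scored
against ground truth.

The default noise regime is a clean validation regime (band SNR well above
the detectability floor); see the package methods note for what that does
and does not establish about real recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import fft as sp_fft
from scipy import stats as sp_stats

from .behavior import ClinicalCourse, TappingSession
from .filters import _fast_len
from .psg_io import (ArtifactMask, Hypnogram, Recording, EPOCH_S,
                     NONREM_STAGES, write_artifact_mask, write_edf,
                     write_hypnogram)

__all__ = [
    "NoiseSpec", "SpindleSpec", "SlowWaveSpec", "CouplingSpec",
    "TappingSpec", "HamdSpec", "GroupEffects", "SimConfig",
    "SyntheticSubject", "STAGE_ORDER", "DEFAULT_TRANSITION",
    "stationary_distribution", "gen_hypnogram", "gen_psg",
    "gen_artifact_mask", "gen_behavior", "gen_subject", "gen_cohort",
    "iter_cohort",
    "write_subject",
]

STAGE_ORDER = ("Wake", "N1", "N2", "SWS", "REM")

#: default first-order stage-transition matrix (rows follow STAGE_ORDER)
DEFAULT_TRANSITION = np.array([
    # Wake   N1     N2     SWS    REM
    [0.50, 0.40, 0.10, 0.00, 0.00],   # Wake
    [0.05, 0.50, 0.45, 0.00, 0.00],   # N1
    [0.01, 0.02, 0.85, 0.08, 0.04],   # N2
    [0.00, 0.01, 0.14, 0.84, 0.01],   # SWS
    [0.02, 0.05, 0.08, 0.00, 0.85],   # REM
])


@dataclass
class NoiseSpec:
    """Stage-structured 1/f^alpha Gaussian background.

    The stochastic background is high-passed below ``slow_cutoff_hz``
    (cosine-squared ramp from zero at half the cutoff): sub-cutoff activity
    belongs to the slow-wave class under test, so leaving it in the noise
    would constitute unlabeled events of exactly that class and make
    precision against the injection log ill-defined.  Slow activity is
    instead modeled explicitly -- large logged slow waves plus a logged
    population of small background waves (see :class:`SlowWaveSpec`)."""
    exponent: float = 1.0
    # stationary across sleep stages: stage differences in real EEG are
    # dominated by the slow/oscillatory classes, which this generator
    # injects explicitly rather than leaving in the background
    stage_rms: dict = field(default_factory=lambda: {
        "Wake": 10.0, "N1": 6.0, "N2": 6.0, "SWS": 6.0, "REM": 6.0,
        "Movement": 10.0})
    low_corner_hz: float = 0.5    # 1/f shaping flattens below this corner
    slow_cutoff_hz: float = 2.0   # background high-pass (full power above)
    mastoid_rms: float = 1.0


@dataclass
class SpindleSpec:
    density_per_epoch: float = 0.6     # per usable non-REM epoch
    center_freq_mean: float = 13.5     # Hz, across subjects
    center_freq_sd: float = 0.3
    amplitude_uv: float = 60.0         # peak-to-peak at the envelope maximum
    duration_range: tuple = (0.9, 1.5)


@dataclass
class SlowWaveSpec:
    """Large target slow waves plus a population of small background waves.

    The background waves stand in for the small delta/slow waves that real
    non-REM sleep always contains: the detector's amplitude criterion is
    *relative* (1.25x the candidate means), so it only behaves as designed
    when large target waves sit on top of a candidate population of smaller
    waves.  Background waves are logged (kind ``bg_sw``) but are not
    recovery targets."""
    density_per_epoch: float = 0.5
    trough_uv_range: tuple = (-90.0, -60.0)
    peak_uv_range: tuple = (30.0, 60.0)
    duration_range: tuple = (1.1, 1.4)
    bg_density_per_epoch: float = 2.0
    bg_trough_uv_range: tuple = (-10.0, -4.0)
    bg_peak_uv_range: tuple = (3.0, 8.0)


@dataclass
class CouplingSpec:
    coupled_fraction: float = 0.5
    delay_mean_s: float = 0.35
    delay_sd_s: float = 0.10


@dataclass
class TappingSpec:
    asymptote: float = 16.0      # saturating-curve ceiling (correct sequences)
    rate: float = 0.35           # learning rate per run
    noise_sd: float = 1.0
    overnight_gain: float = 0.05  # relative overnight change
    round_counts: bool = True


@dataclass
class HamdSpec:
    baseline_mean: float = 22.0
    baseline_sd: float = 3.0
    day7_frac: float = 0.8
    day28_frac: float = 0.55
    noise_sd: float = 1.5


@dataclass
class GroupEffects:
    """Multiplicative/additive group manipulations applied at generation."""
    delay_sd_mult: float = 1.0
    sw_amplitude_mult: float = 1.0
    spindle_density_mult: float = 1.0
    spindle_amplitude_mult: float = 1.0
    overnight_gain_delta: float = 0.0
    hamd_baseline_shift: float = 0.0


@dataclass
class SimConfig:
    seed: int = 0
    n_subjects: int = 20
    n_epochs: int = 960            # 8 h of 30-s epochs
    fs: float = 100.0
    transition: np.ndarray = field(default_factory=lambda: DEFAULT_TRANSITION.copy())
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    spindles: SpindleSpec = field(default_factory=SpindleSpec)
    slow_waves: SlowWaveSpec = field(default_factory=SlowWaveSpec)
    coupling: CouplingSpec = field(default_factory=CouplingSpec)
    tapping: TappingSpec = field(default_factory=TappingSpec)
    hamd: HamdSpec = field(default_factory=HamdSpec)
    artifact_fraction: float = 0.02
    channels: tuple = ("C3", "C4")


@dataclass
class SyntheticSubject:
    subject_id: str
    group: str
    recording: Recording
    hypnogram: Hypnogram
    artifact_mask: ArtifactMask
    ground_truth: pd.DataFrame
    tapping: TappingSession
    clinical: ClinicalCourse
    center_freq_hz: float = float("nan")


# ---------------------------------------------------------------------------
# Hypnogram
# ---------------------------------------------------------------------------

def _validate_transition(P: np.ndarray) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.shape != (5, 5) or np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0):
        raise ValueError("transition matrix must be 5x5 with nonnegative rows "
                         "summing to 1 (order Wake,N1,N2,SWS,REM)")
    return P


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of the stage chain (left eigenvector)."""
    P = _validate_transition(P)
    w, v = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    return pi / pi.sum()


def gen_hypnogram(cfg: SimConfig, rng: np.random.Generator) -> Hypnogram:
    """First-order Markov hypnogram at 30-s resolution, starting in Wake."""
    P = _validate_transition(cfg.transition)
    cum = np.cumsum(P, axis=1)
    u = rng.random(cfg.n_epochs)
    states = np.empty(cfg.n_epochs, dtype=int)
    s = 0  # Wake
    for i in range(cfg.n_epochs):
        states[i] = s
        s = int(np.searchsorted(cum[s], u[i], side="right"))
        s = min(s, 4)
    labels = np.array(STAGE_ORDER, dtype=object)[states]
    return Hypnogram(stages=labels)


# ---------------------------------------------------------------------------
# EEG synthesis
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _noise_shape(n: int, fs: float, exponent: float, low_corner_hz: float,
                 slow_cutoff_hz: float) -> np.ndarray:
    """Target amplitude spectrum of the background (cached across calls)."""
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.maximum(f, low_corner_hz) ** (-exponent / 2.0)
    # high-pass the stochastic background below the slow cutoff (slow-wave
    # class activity is injected explicitly, never left in the noise)
    f1, f2 = 0.5 * slow_cutoff_hz, slow_cutoff_hz
    ramp = np.clip((f - f1) / max(f2 - f1, 1e-12), 0.0, 1.0)
    shape *= np.sin(0.5 * np.pi * ramp) ** 2
    shape[0] = 0.0
    shape = shape.astype(np.float32)
    shape.setflags(write=False)
    return shape


def _background_noise(n: int, fs: float, spec: NoiseSpec,
                      rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f^alpha Gaussian noise, synthesized in the frequency
    domain (independent complex-Gaussian bins scaled by the target
    amplitude spectrum)."""
    nfft = _fast_len(n)   # synthesize at a fast length, keep the first n
    nf = nfft // 2 + 1
    z = rng.standard_normal(2 * nf, dtype=np.float32).view(np.complex64)
    z *= _noise_shape(nfft, fs, spec.exponent, spec.low_corner_hz,
                      spec.slow_cutoff_hz)
    y = sp_fft.irfft(z, n=nfft)[:n]
    y /= y.std(dtype=np.float64)
    return y


@lru_cache(maxsize=512)
def _hann_env(n: int) -> np.ndarray:
    env = np.sin(np.pi * np.arange(n) / max(n - 1, 1)) ** 2
    env.setflags(write=False)
    return env


@lru_cache(maxsize=512)
def _sine_period(n: int) -> np.ndarray:
    s = np.sin(2 * np.pi * np.arange(n) / n)
    s.setflags(write=False)
    return s


def _spindle_wave(n: int, fs: float, freq: float, amp_p2p: float,
                  phase: float) -> np.ndarray:
    t = np.arange(n) / fs
    return (0.5 * amp_p2p) * _hann_env(n) * np.sin(2 * np.pi * freq * t + phase)


def _sw_wave(n: int, fs: float, trough_uv: float, peak_uv: float) -> np.ndarray:
    """One biphasic sine period: trough at T/4, up-crossing at T/2, peak at
    3T/4; half-waves scaled to the requested trough/peak values."""
    s = _sine_period(n)
    h = n // 2
    out = np.empty(n)
    np.multiply(s[:h], -abs(trough_uv), out=out[:h])
    np.multiply(s[h:], -peak_uv, out=out[h:])
    return out


def _place_in_epochs(spans, epochs, rng, epoch_s=EPOCH_S, margin=1.0, gap=0.3):
    """Assign items (by span, seconds) to epochs and non-overlapping starts.

    Returns a list of (epoch_index, local_start_s) per item, aligned with the
    input order.  Raises when the configured density cannot be placed.
    """
    epoch_list = np.asarray(epochs, dtype=int)
    capacity = np.full(epoch_list.size, epoch_s - 2 * margin)
    order = rng.permutation(len(spans))
    assignment = [None] * len(spans)
    per_epoch = {int(e): [] for e in epoch_list}
    first_try = rng.integers(capacity.size, size=len(spans))
    for idx in order:
        span = spans[idx] + gap
        # uniform draw over all epochs, falling back to a uniform draw over
        # the epochs that still have room
        j = int(first_try[idx])
        if capacity[j] < span:
            ok = np.flatnonzero(capacity >= span)
            if ok.size == 0:
                raise ValueError("event density too high: "
                                 "no epoch has room left")
            j = int(ok[rng.integers(ok.size)])
        capacity[j] -= span
        per_epoch[int(epoch_list[j])].append(idx)

    for e, idxs in per_epoch.items():
        if not idxs:
            continue
        free = epoch_s - 2 * margin - np.array([spans[i] for i in idxs]).sum()
        u = rng.random(len(idxs) + 1)
        gaps = free * u / u.sum()
        pos = margin
        for j, i in enumerate(rng.permutation(idxs)):
            pos += gaps[j]
            assignment[i] = (e, pos)
            pos += spans[i]
    return assignment


def _truncnorm_delays(mu, sigma, lo, hi, rng) -> np.ndarray:
    """Truncated-normal draws on per-event intervals [lo, hi_i]."""
    hi = np.asarray(hi, dtype=float)
    if sigma == 0:
        return np.clip(mu, lo, hi)
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return np.atleast_1d(sp_stats.truncnorm.rvs(a, b, loc=mu, scale=sigma,
                                                size=hi.shape,
                                                random_state=rng))


def gen_psg(hyp: Hypnogram, cfg: SimConfig, rng: np.random.Generator,
            subject_id: str = "s0",
            effects: GroupEffects | None = None,
            center_freq: float | None = None):
    """Synthesize a Recording (C3, C4, A1, A2) plus the ground-truth log."""
    effects = effects or GroupEffects()
    fs = cfg.fs
    nper = int(round(EPOCH_S * fs))
    n = cfg.n_epochs * nper
    if len(hyp) != cfg.n_epochs:
        raise ValueError("hypnogram length does not match config")
    nonrem = hyp.epochs_in(NONREM_STAGES)
    stage_rms = np.array([cfg.noise.stage_rms[s] for s in hyp.stages],
                         dtype=np.float32)

    if center_freq is None:
        center_freq = rng.normal(cfg.spindles.center_freq_mean,
                                 cfg.spindles.center_freq_sd)
        center_freq = float(np.clip(center_freq, 12.2, 14.8))

    n_sw = int(round(cfg.slow_waves.density_per_epoch * nonrem.size))
    n_bg = int(round(cfg.slow_waves.bg_density_per_epoch * nonrem.size))
    n_sp = int(round(cfg.spindles.density_per_epoch
                     * effects.spindle_density_mult * nonrem.size))
    n_coupled = min(int(round(cfg.coupling.coupled_fraction * n_sp)), n_sw)
    sigma = cfg.coupling.delay_sd_s * effects.delay_sd_mult

    cols = ["event_id", "channel", "kind", "onset_s", "duration_s",
            "anchor_s", "amplitude_uv", "frequency_hz", "coupled_sw_id",
            "delay_s"]
    rows = []
    eeg = {}
    event_id = 0
    for ch in cfg.channels:
        sig = _background_noise(n, fs, cfg.noise, rng)
        sig = (sig.reshape(cfg.n_epochs, nper) * stage_rms[:, None]).reshape(n)

        if nonrem.size == 0:
            if n_sw or n_sp:
                raise ValueError("no non-REM epochs to place events in")
            eeg[ch] = sig
            continue

        # draw event parameters (fixed draw order)
        nc = n_coupled
        sw_T = rng.uniform(*cfg.slow_waves.duration_range, size=n_sw)
        sw_tr = rng.uniform(*cfg.slow_waves.trough_uv_range, size=n_sw) \
            * effects.sw_amplitude_mult
        sw_pk = rng.uniform(*cfg.slow_waves.peak_uv_range, size=n_sw) \
            * effects.sw_amplitude_mult
        sp_D = rng.uniform(*cfg.spindles.duration_range, size=n_sp)
        sp_amp = np.full(n_sp, cfg.spindles.amplitude_uv
                         * effects.spindle_amplitude_mult)
        sp_phase = rng.uniform(0, 2 * np.pi, size=n_sp)
        delays = (_truncnorm_delays(cfg.coupling.delay_mean_s, sigma, 0.0,
                                    0.75 * sw_T[:nc], rng)
                  if nc else np.empty(0))
        # small background slow waves (candidate-population floor; logged
        # but not recovery targets)
        bg_T = rng.uniform(*cfg.slow_waves.duration_range, size=n_bg)
        bg_tr = rng.uniform(*cfg.slow_waves.bg_trough_uv_range, size=n_bg)
        bg_pk = rng.uniform(*cfg.slow_waves.bg_peak_uv_range, size=n_bg)

        # spans and origins in item order: pairs, plain SWs, plain spindles,
        # background waves (a pair's span covers the SW plus the spindle
        # placed at trough + delay)
        peak_local = 0.25 * sw_T[:nc] + delays
        pair_s0 = np.minimum(0.0, peak_local - sp_D[:nc] / 2)
        pair_s1 = np.maximum(sw_T[:nc], peak_local + sp_D[:nc] / 2)
        span = np.concatenate([pair_s1 - pair_s0, sw_T[nc:], sp_D[nc:], bg_T])
        origin = np.concatenate([-pair_s0, np.zeros(n_sw - nc),
                                 np.zeros(n_sp - nc), np.zeros(n_bg)])
        placement = _place_in_epochs(span, nonrem, rng)
        e_arr = np.array([p[0] for p in placement], dtype=np.float64)
        loc_arr = np.array([p[1] for p in placement])
        t0 = (e_arr * EPOCH_S + loc_arr) + origin

        def sw_ints(t0g, Tg):
            """Sample-aligned SW geometry: length, start, trough time."""
            nsw = np.rint(Tg * fs).astype(np.int64)
            i0 = np.rint(t0g * fs).astype(np.int64)
            return nsw, i0, (i0 + nsw // 4) / fs

        # pairs: SW then spindle centered at trough + delay (sample-aligned)
        nsw_p, i0_p, trough_p = sw_ints(t0[:nc], sw_T[:nc])
        nsp_p = np.rint(sp_D[:nc] * fs).astype(np.int64)
        c_p = np.rint((trough_p + delays) * fs).astype(np.int64)
        i0sp_p = c_p - nsp_p // 2
        delay_log = c_p / fs - trough_p
        for k in range(nc):
            i0, nsw = int(i0_p[k]), int(nsw_p[k])
            sig[i0:i0 + nsw] += _sw_wave(nsw, fs, sw_tr[k], sw_pk[k])
            rows.append((event_id, ch, "sw", i0 / fs, nsw / fs, trough_p[k],
                         sw_pk[k] - sw_tr[k], fs / nsw, np.nan, np.nan))
            i0s, nsp = int(i0sp_p[k]), int(nsp_p[k])
            sig[i0s:i0s + nsp] += _spindle_wave(nsp, fs, center_freq,
                                                sp_amp[k], sp_phase[k])
            rows.append((event_id + 1, ch, "spindle", i0s / fs, nsp / fs,
                         (i0s + nsp // 2) / fs, sp_amp[k], center_freq,
                         event_id, delay_log[k]))
            event_id += 2

        # plain slow waves
        nsw_s, i0_s, trough_s = sw_ints(t0[nc:n_sw], sw_T[nc:])
        for k in range(n_sw - nc):
            i0, nsw = int(i0_s[k]), int(nsw_s[k])
            sig[i0:i0 + nsw] += _sw_wave(nsw, fs, sw_tr[nc + k], sw_pk[nc + k])
            rows.append((event_id, ch, "sw", i0 / fs, nsw / fs, trough_s[k],
                         sw_pk[nc + k] - sw_tr[nc + k], fs / nsw,
                         np.nan, np.nan))
            event_id += 1

        # plain spindles, centered in their placed slot
        t0_sp = t0[n_sw:n_sw + (n_sp - nc)]
        nsp_s = np.rint(sp_D[nc:] * fs).astype(np.int64)
        c_s = np.rint((t0_sp + sp_D[nc:] / 2) * fs).astype(np.int64)
        i0sp_s = c_s - nsp_s // 2
        for k in range(n_sp - nc):
            i0s, nsp = int(i0sp_s[k]), int(nsp_s[k])
            sig[i0s:i0s + nsp] += _spindle_wave(nsp, fs, center_freq,
                                                sp_amp[nc + k],
                                                sp_phase[nc + k])
            rows.append((event_id, ch, "spindle", i0s / fs, nsp / fs,
                         (i0s + nsp // 2) / fs, sp_amp[nc + k], center_freq,
                         np.nan, np.nan))
            event_id += 1

        # background waves (candidate floor; same geometry, own kind)
        nsw_b, i0_b, trough_b = sw_ints(t0[n_sw + n_sp - nc:], bg_T)
        for k in range(n_bg):
            i0, nsw = int(i0_b[k]), int(nsw_b[k])
            sig[i0:i0 + nsw] += _sw_wave(nsw, fs, bg_tr[k], bg_pk[k])
            rows.append((event_id, ch, "bg_sw", i0 / fs, nsw / fs,
                         trough_b[k], bg_pk[k] - bg_tr[k], fs / nsw,
                         np.nan, np.nan))
            event_id += 1
        eeg[ch] = sig

    a1 = np.float32(cfg.noise.mastoid_rms) * rng.standard_normal(n, dtype=np.float32)
    a2 = np.float32(cfg.noise.mastoid_rms) * rng.standard_normal(n, dtype=np.float32)
    data = np.empty((4, n), dtype=np.float32)
    np.add(eeg["C3"], a2, out=data[0])
    np.add(eeg["C4"], a1, out=data[1])
    data[2] = a1
    data[3] = a2
    rec = Recording(data=data, fs=fs, ch_names=["C3", "C4", "A1", "A2"])
    gt = pd.DataFrame.from_records(rows, columns=cols)
    gt.attrs["center_freq_hz"] = center_freq
    gt.attrs["subject_id"] = subject_id
    return rec, gt


def gen_artifact_mask(hyp: Hypnogram, cfg: SimConfig,
                      rng: np.random.Generator) -> ArtifactMask:
    """Flag a random fraction of non-REM epochs per channel."""
    flags = np.zeros((len(hyp), len(cfg.channels)), dtype=bool)
    nonrem = hyp.epochs_in(NONREM_STAGES)
    n_flag = int(round(cfg.artifact_fraction * nonrem.size))
    for j in range(len(cfg.channels)):
        if n_flag and nonrem.size:
            flags[rng.choice(nonrem, size=n_flag, replace=False), j] = True
    return ArtifactMask(flags=flags, channels=list(cfg.channels))


# ---------------------------------------------------------------------------
# Behavior / clinical
# ---------------------------------------------------------------------------

def gen_behavior(cfg: SimConfig, rng: np.random.Generator,
                 effects: GroupEffects | None = None):
    """Tapping session (saturating learning curve + overnight gain) and a
    HAMD course."""
    effects = effects or GroupEffects()
    tp = cfg.tapping
    runs = np.arange(1, 13)
    curve = tp.asymptote * (1 - np.exp(-tp.rate * runs))
    train = curve + rng.normal(0, tp.noise_sd, size=12)
    gain = tp.overnight_gain + effects.overnight_gain_delta
    if tp.round_counts:
        train = np.maximum(np.round(train), 0)
    test = train[-3:].mean() * (1 + gain) + rng.normal(0, tp.noise_sd, size=3)
    if tp.round_counts:
        test = np.maximum(np.round(test), 0)
    session = TappingSession(training_runs=[int(v) if tp.round_counts else v
                                            for v in train],
                             test_runs=[int(v) if tp.round_counts else v
                                        for v in test])

    hd = cfg.hamd
    base = max(1.0, rng.normal(hd.baseline_mean + effects.hamd_baseline_shift,
                               hd.baseline_sd))
    day7 = max(0.0, base * hd.day7_frac + rng.normal(0, hd.noise_sd))
    day28 = max(0.0, base * hd.day28_frac + rng.normal(0, hd.noise_sd))
    course = ClinicalCourse(hamd_baseline=round(base), hamd_day7=round(day7),
                            hamd_day28=round(day28))
    return session, course


# ---------------------------------------------------------------------------
# Subjects and cohorts
# ---------------------------------------------------------------------------

def gen_subject(cfg: SimConfig, rng: np.random.Generator,
                subject_id: str = "s0", group: str = "control",
                effects: GroupEffects | None = None) -> SyntheticSubject:
    hyp = gen_hypnogram(cfg, rng)
    rec, gt = gen_psg(hyp, cfg, rng, subject_id=subject_id, effects=effects)
    mask = gen_artifact_mask(hyp, cfg, rng)
    session, course = gen_behavior(cfg, rng, effects)
    return SyntheticSubject(subject_id=subject_id, group=group, recording=rec,
                            hypnogram=hyp, artifact_mask=mask,
                            ground_truth=gt, tapping=session, clinical=course,
                            center_freq_hz=gt.attrs["center_freq_hz"])


def iter_cohort(cfg: SimConfig, effects_by_group: dict[str, GroupEffects]):
    """Yield ``cfg.n_subjects`` subjects per group one at a time, all
    randomness flowing from ``cfg.seed``.

    Streaming keeps only one subject's recording in memory, which matters
    for large replication runs; the per-subject seed streams (and therefore
    the subjects themselves) are identical to :func:`gen_cohort`.
    """
    ss = np.random.SeedSequence(cfg.seed)
    groups = sorted(effects_by_group)
    children = ss.spawn(len(groups) * cfg.n_subjects)
    k = 0
    for group in groups:
        for i in range(cfg.n_subjects):
            rng = np.random.default_rng(children[k])
            yield gen_subject(cfg, rng, subject_id=f"{group}_{i:03d}",
                              group=group, effects=effects_by_group[group])
            k += 1


def gen_cohort(cfg: SimConfig, effects_by_group: dict[str, GroupEffects]
               ) -> list[SyntheticSubject]:
    """Generate ``cfg.n_subjects`` subjects per group, all randomness flowing
    from ``cfg.seed``."""
    return list(iter_cohort(cfg, effects_by_group))


def write_subject(sub: SyntheticSubject, outdir) -> dict[str, Path]:
    """Write EDF + hypnogram/artifact/ground-truth/behavior TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sid = sub.subject_id
    paths = {
        "edf": outdir / f"{sid}.edf",
        "hypnogram": outdir / f"{sid}_hypnogram.tsv",
        "artifacts": outdir / f"{sid}_artifacts.tsv",
        "ground_truth": outdir / f"{sid}_ground_truth.tsv",
        "tapping": outdir / f"{sid}_tapping.tsv",
        "hamd": outdir / f"{sid}_hamd.tsv",
    }
    write_edf(sub.recording, paths["edf"])
    write_hypnogram(sub.hypnogram, paths["hypnogram"])
    write_artifact_mask(sub.artifact_mask, paths["artifacts"])
    sub.ground_truth.to_csv(paths["ground_truth"], sep="\t", index=False)
    tap_rows = ([{"subject_id": sid, "session_id": 1, "run_type": "train",
                  "run_index": i + 1, "correct_count": c}
                 for i, c in enumerate(sub.tapping.training_runs)]
                + [{"subject_id": sid, "session_id": 1, "run_type": "test",
                    "run_index": i + 1, "correct_count": c}
                   for i, c in enumerate(sub.tapping.test_runs)])
    pd.DataFrame(tap_rows).to_csv(paths["tapping"], sep="\t", index=False)
    hamd_rows = [{"subject_id": sid, "timepoint_days": d, "score": v}
                 for d, v in ((0, sub.clinical.hamd_baseline),
                              (7, sub.clinical.hamd_day7),
                              (28, sub.clinical.hamd_day28))
                 if v is not None]
    pd.DataFrame(hamd_rows).to_csv(paths["hamd"], sep="\t", index=False)
    return paths
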