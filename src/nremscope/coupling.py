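"""Slow-wave / spindle coupling: assignment, delay, and delay dispersion.

A spindle couples to a slow wave when its time marker (by default the
envelope peak) falls in the window from the SW down-state trough to the SW
end (the next up-to-down zero crossing).  Each spindle is counted only once,
for the slow wave with the earliest trough among those whose windows contain
it.  Delay = marker time - trough time; delay dispersion is the sample
standard deviation (n-1) of delays, the cohort index of coupling accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import SlowWaveEvent, SpindleEvent

__all__ = ["CoupledPair", "CouplingSummary", "couple", "coupling_summary"]

MARKERS = ("peak", "onset", "midpoint")


@dataclass
class CoupledPair:
    sw_index: int
    spindle_index: int
    delay_s: float


@dataclass
class CouplingSummary:
    n_pairs: int
    mean_delay_ms: float | None
    delay_dispersion_s: float | None
    coupled_spindle: dict = field(default_factory=dict)
    uncoupled_spindle: dict = field(default_factory=dict)
    coupled_sw: dict = field(default_factory=dict)
    uncoupled_sw: dict = field(default_factory=dict)
    differences: dict = field(default_factory=dict)


def _marker_time(sp: SpindleEvent, marker: str) -> float:
    if marker == "peak":
        return sp.envelope_peak_s
    if marker == "onset":
        return sp.onset_s
    if marker == "midpoint":
        return 0.5 * (sp.onset_s + sp.offset_s)
    raise ValueError(f"unknown coupling marker {marker!r}; use one of {MARKERS}")


def couple(sws: list[SlowWaveEvent], spindles: list[SpindleEvent],
           marker: str = "peak") -> list[CoupledPair]:
    """Assign each spindle to at most one slow wave.

    A spindle whose marker lies inside several overlapping SW windows is
    assigned to the SW with the earliest trough.
    """
    if not sws or not spindles:
        return []
    order = np.argsort([w.trough_s for w in sws])
    troughs = np.array([sws[i].trough_s for i in order])
    ends = np.array([sws[i].end_s for i in order])

    pairs = []
    seen_spindles = set()
    for j, sp in enumerate(spindles):
        m = _marker_time(sp, marker)
        # earliest-trough SW whose [trough, end] window contains the marker;
        # windows are at most max_duration long, so only nearby SWs qualify
        hi = int(np.searchsorted(troughs, m, side="right"))
        lo = int(np.searchsorted(troughs, m - (ends - troughs).max()))
        for k in range(lo, hi):
            if ends[k] >= m:
                assert j not in seen_spindles
                seen_spindles.add(j)
                pairs.append(CoupledPair(sw_index=int(order[k]),
                                         spindle_index=j,
                                         delay_s=float(m - troughs[k])))
                break
    return pairs


def _means(items, fields) -> dict:
    if not items:
        return {f: None for f in fields}
    return {f: float(np.mean([getattr(it, f) for it in items])) for f in fields}


def coupling_summary(pairs: list[CoupledPair], sws: list[SlowWaveEvent],
                     spindles: list[SpindleEvent]) -> CouplingSummary:
    """Delay statistics and coupled/uncoupled event property contrasts.

    Dispersion needs at least two pairs (absent otherwise, never zero by
    convention); with zero pairs all coupling fields are absent.
    """
    delays = np.array([p.delay_s for p in pairs])
    n = len(pairs)
    mean_delay = float(delays.mean() * 1000.0) if n >= 1 else None
    dispersion = float(delays.std(ddof=1)) if n >= 2 else None

    sp_fields = ("amplitude_uv", "duration_s", "frequency_hz")
    sw_fields = ("amplitude_uv", "duration_s")
    coupled_sp_idx = {p.spindle_index for p in pairs}
    coupled_sw_idx = {p.sw_index for p in pairs}
    c_sp = _means([spindles[i] for i in sorted(coupled_sp_idx)], sp_fields)
    u_sp = _means([s for i, s in enumerate(spindles) if i not in coupled_sp_idx],
                  sp_fields)
    c_sw = _means([sws[i] for i in sorted(coupled_sw_idx)], sw_fields)
    u_sw = _means([w for i, w in enumerate(sws) if i not in coupled_sw_idx],
                  sw_fields)

    diffs = {}
    for label, c, u in (("spindle", c_sp, u_sp), ("sw", c_sw, u_sw)):
        for f in c:
            diffs[f"{label}_{f}"] = (c[f] - u[f]
                                     if c[f] is not None and u[f] is not None
                                     else None)
    return CouplingSummary(n_pairs=n, mean_delay_ms=mean_delay,
                           delay_dispersion_s=dispersion,
                           coupled_spindle=c_sp, uncoupled_spindle=u_sp,
                           coupled_sw=c_sw, uncoupled_sw=u_sw,
                           differences=diffs)
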