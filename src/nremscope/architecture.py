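"""Sleep macrostructure metrics from the hypnogram.

All stage percentages are expressed relative to total sleep time (TST =
summed N1+N2+SWS+REM epoch time), including WASO -- an unconventional but
deliberate denominator choice so the whole metric row shares one scale.
Analysis non-REM percentage is N2 + SWS (without N1).  Movement/unscored
epochs count toward neither TST nor WASO.  Latencies: sleep onset is the
first epoch of any sleep stage (configurable to first N2); SWS and REM
onsets are measured from sleep onset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .psg_io import Hypnogram, SLEEP_STAGES

__all__ = ["ArchitectureSummary", "architecture_summary"]


@dataclass
class ArchitectureSummary:
    tst_min: float
    pct_n1: float
    pct_n2: float
    pct_sws: float
    pct_nonrem: float         # N2 + SWS, without N1
    pct_rem: float
    pct_waso: float           # wake between sleep onset and last sleep epoch, % of TST
    sleep_onset_min: float
    sws_onset_min: float | None
    rem_onset_min: float | None


def architecture_summary(hyp: Hypnogram,
                         onset_rule: str = "any_sleep") -> ArchitectureSummary:
    """Compute the sleep-architecture metric row for one night."""
    stages = hyp.stages
    ep_min = hyp.epoch_length_s / 60.0
    sleep = np.isin(stages, list(SLEEP_STAGES))
    if not sleep.any():
        raise ValueError("no sleep: hypnogram contains no sleep-stage epochs")

    if onset_rule == "any_sleep":
        onset_idx = int(np.argmax(sleep))
    elif onset_rule == "first_n2":
        n2 = stages == "N2"
        if not n2.any():
            raise ValueError("no sleep: no N2 epoch for first_n2 onset rule")
        onset_idx = int(np.argmax(n2))
    else:
        raise ValueError(f"unknown onset rule {onset_rule!r}")

    counts = {s: int(np.sum(stages == s)) for s in ("N1", "N2", "SWS", "REM")}
    tst_epochs = sum(counts.values())
    tst_min = tst_epochs * ep_min

    last_sleep = int(len(stages) - 1 - np.argmax(sleep[::-1]))
    within = stages[onset_idx:last_sleep + 1]
    waso_epochs = int(np.sum(within == "Wake"))

    def pct(n):
        return 100.0 * n / tst_epochs

    def latency(stage):
        rel = np.flatnonzero(stages[onset_idx:] == stage)
        return float(rel[0] * ep_min) if rel.size else None

    return ArchitectureSummary(
        tst_min=tst_min,
        pct_n1=pct(counts["N1"]),
        pct_n2=pct(counts["N2"]),
        pct_sws=pct(counts["SWS"]),
        pct_nonrem=pct(counts["N2"] + counts["SWS"]),
        pct_rem=pct(counts["REM"]),
        pct_waso=pct(waso_epochs),
        sleep_onset_min=onset_idx * ep_min,
        sws_onset_min=latency("SWS"),
        rem_onset_min=latency("REM"),
    )
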