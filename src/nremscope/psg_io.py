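"""Polysomnography I/O and preprocessing.

Reads EDF recordings (via MNE), 30-s hypnograms, and epoch-by-channel
artifact annotations; applies contralateral-mastoid re-referencing, the
100 Hz / 35 Hz low-pass preprocessing, and the channel-level artifact
exclusion rule (a channel is dropped when more than 20% of its non-REM
epochs are artifact-flagged).

A minimal EDF 16-bit writer is included so the synthetic generator can
produce files the reader consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .filters import zerophase_lowpass

__all__ = [
    "Recording",
    "Hypnogram",
    "ArtifactMask",
    "ChannelUsability",
    "STAGES",
    "NONREM_STAGES",
    "SLEEP_STAGES",
    "read_recording",
    "write_edf",
    "rereference_contralateral_mastoid",
    "preprocess",
    "read_hypnogram",
    "write_hypnogram",
    "read_artifact_mask",
    "write_artifact_mask",
    "apply_artifact_rules",
]

EPOCH_S = 30.0

#: canonical stage labels
STAGES = ("Wake", "N1", "N2", "SWS", "REM", "Movement")
SLEEP_STAGES = ("N1", "N2", "SWS", "REM")
#: analysis non-REM (N2 + SWS, without N1)
NONREM_STAGES = ("N2", "SWS")

# Rechtschaffen & Kales numeric codes; stages 3 and 4 merge into SWS
_RK_MAP = {"0": "Wake", "1": "N1", "2": "N2", "3": "SWS", "4": "SWS",
           "5": "REM", "6": "Movement", "7": "Movement"}
_AASM_MAP = {"W": "Wake", "N1": "N1", "N2": "N2", "N3": "SWS", "R": "REM",
             "M": "Movement", "U": "Movement", "?": "Movement"}


@dataclass
class Recording:
    """Multichannel EEG in microvolts at a single sampling rate."""

    data: np.ndarray          # (n_channels, n_samples), µV
    fs: float
    ch_names: list[str]
    start_time: float = 0.0   # seconds offset, 0 at record start

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.shape[0] != len(self.ch_names):
            raise ValueError("channel count mismatch between data and labels")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def n_epochs(self) -> int:
        return int(self.n_samples // round(EPOCH_S * self.fs))

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.data[self.ch_names.index(name)]
        except ValueError:
            raise KeyError(f"channel {name} not present") from None


@dataclass
class Hypnogram:
    """Ordered 30-s epoch stage labels (canonical dialect)."""

    stages: np.ndarray        # array of canonical labels
    epoch_length_s: float = 30.0
    dialect: str = "AASM"

    def __post_init__(self):
        self.stages = np.asarray(self.stages, dtype=object)
        if self.epoch_length_s != 30.0:
            raise ValueError("epoch length must be 30 s")
        if len(self.stages) == 0:
            raise ValueError("empty hypnogram")
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.stages)

    def epochs_in(self, stages) -> np.ndarray:
        """Indices of epochs whose stage is in ``stages``."""
        return np.flatnonzero(np.isin(self.stages, list(stages)))


@dataclass
class ArtifactMask:
    """Epoch x channel artifact flags (True = artifact)."""

    flags: np.ndarray         # (n_epochs, n_channels) bool
    channels: list[str]

    def __post_init__(self):
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.flags.ndim != 2 or self.flags.shape[1] != len(self.channels):
            raise ValueError("flag grid does not match channel list")

    def column(self, channel: str) -> np.ndarray:
        try:
            return self.flags[:, self.channels.index(channel)]
        except ValueError:
            raise KeyError(f"channel {channel} not in artifact mask") from None


@dataclass
class ChannelUsability:
    """Result of the artifact exclusion rule."""

    usable_epochs: dict       # channel -> np.ndarray of usable non-REM epoch indices
    excluded: list            # channels with >20% artifact non-REM epochs
    no_data: list             # channels with zero non-REM epochs
    n_nonrem: int = 0


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

_MASTOID_ALIASES = {"M1": "A1", "M2": "A2"}


def _normalize_label(label: str) -> str:
    lab = label.strip().upper()
    if lab.startswith("EEG "):
        lab = lab[4:]
    lab = lab.split("-")[0].strip()
    return _MASTOID_ALIASES.get(lab, lab)


def _parse_edf_header(path):
    with open(path, "rb") as f:
        head = f.read(256)
        if len(head) < 256:
            raise ValueError(f"{path}: truncated EDF header")
        n_sig = int(head[252:256].decode("ascii"))
        sig = f.read(256 * n_sig)
    rec_dur = float(head[244:252].decode("ascii"))
    labels = [sig[16 * i:16 * (i + 1)].decode("ascii").strip() for i in range(n_sig)]
    off = n_sig * 216
    n_samps = [int(sig[off + 8 * i:off + 8 * (i + 1)].decode("ascii")) for i in range(n_sig)]
    return labels, n_samps, rec_dur


def read_recording(path, required=("C3", "C4", "A1", "A2")) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording` (signals in µV).

    Channel labels are normalized case-insensitively; M1/M2 are accepted as
    mastoid aliases for A1/A2.  Missing required channels and per-channel
    sampling-rate mismatches are hard errors.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    labels, n_samps, rec_dur = _parse_edf_header(path)
    rates = {}
    for lab, ns in zip(labels, n_samps):
        norm = _normalize_label(lab)
        if norm.upper() in ("EDF ANNOTATIONS", "ANNOTATIONS"):
            continue
        rates[norm] = ns / rec_dur
    if len(set(rates.values())) > 1:
        raise ValueError(f"{path}: inconsistent per-channel sampling rates {rates}")

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    norm_names = [_normalize_label(ch) for ch in raw.ch_names]
    for ch in required:
        if _normalize_label(ch) not in norm_names:
            raise ValueError(f"required channel {ch} not found in {path.name}")
    data = raw.get_data() * 1e6  # volts -> µV
    return Recording(data=data, fs=float(raw.info["sfreq"]), ch_names=norm_names)


def write_edf(rec: Recording, path, physical_max: float | None = None) -> None:
    """Write a Recording as a plain 16-bit EDF file (1-s data records).

    ``physical_max`` sets the symmetric physical scaling range per channel;
    by default it is the per-channel absolute maximum (padded 1%), which
    minimizes quantization error.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n = rec.n_samples
    if n % fs != 0:
        raise ValueError("EDF writer requires a whole number of seconds")
    n_rec = n // fs
    n_sig = len(rec.ch_names)

    def f(text, width):
        s = str(text)[:width]
        return s.ljust(width).encode("ascii")

    header = b"".join([
        f("0", 8), f("X X X X", 80), f("Startdate X X X X", 80),
        f("01.01.00", 8), f("00.00.00", 8),
        f(256 * (1 + n_sig), 8), f("", 44), f(n_rec, 8), f("1", 8), f(n_sig, 4),
    ])
    phys_max = []
    for i in range(n_sig):
        if physical_max is not None:
            pm = float(physical_max)
        else:
            pm = float(np.max(np.abs(rec.data[i]))) * 1.01
            pm = max(pm, 1.0)
        phys_max.append(pm)

    def col(vals, width):
        return b"".join(f(v, width) for v in vals)

    header += col(rec.ch_names, 16)
    header += col([""] * n_sig, 80)
    header += col(["uV"] * n_sig, 8)
    header += col([f"{-pm:.6g}"[:8] for pm in phys_max], 8)
    header += col([f"{pm:.6g}"[:8] for pm in phys_max], 8)
    header += col([-32768] * n_sig, 8)
    header += col([32767] * n_sig, 8)
    header += col([""] * n_sig, 80)
    header += col([fs] * n_sig, 8)
    header += col([""] * n_sig, 32)

    # physical range as re-parsed from the truncated ascii fields, so that
    # the stored gain matches what readers will compute
    pmin = np.array([float(f"{-pm:.6g}"[:8]) for pm in phys_max])
    pmax = np.array([float(f"{pm:.6g}"[:8]) for pm in phys_max])
    gain = (pmax - pmin) / 65535.0
    dig = np.clip(np.round((rec.data - pmin[:, None]) / gain[:, None]) - 32768,
                  -32768, 32767).astype("<i2")
    blocks = dig.reshape(n_sig, n_rec, fs).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(blocks.tobytes())


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def rereference_contralateral_mastoid(rec: Recording) -> Recording:
    """Re-reference C3 against A2/M2 and C4 against A1/M1; drop mastoids."""
    for ch in ("C3", "C4", "A1", "A2"):
        if ch not in rec.ch_names:
            raise ValueError(f"required channel {ch} not found")
    data = np.empty((2, rec.n_samples), dtype=rec.data.dtype)
    np.subtract(rec.channel("C3"), rec.channel("A2"), out=data[0])
    np.subtract(rec.channel("C4"), rec.channel("A1"), out=data[1])
    return Recording(data=data, fs=rec.fs, ch_names=["C3", "C4"],
                     start_time=rec.start_time)


def preprocess(rec: Recording, target_fs: float = 100.0,
               lowpass_hz: float = 35.0, stop_hz: float = 45.0) -> Recording:
    """Zero-phase 35 Hz low-pass, then resample to 100 Hz.

    Upsampling is not supported (fs must be >= target).  Duration is
    preserved to within one sample.
    """
    if rec.fs < target_fs:
        raise ValueError(f"sampling rate {rec.fs} Hz < {target_fs} Hz; "
                         "upsampling not supported")
    data = zerophase_lowpass(rec.data, rec.fs, lowpass_hz, stop_hz)
    if rec.fs != target_fs:
        frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
        data = sp_signal.resample_poly(data, frac.numerator, frac.denominator, axis=-1)
    return Recording(data=data, fs=target_fs, ch_names=list(rec.ch_names),
                     start_time=rec.start_time)


# ---------------------------------------------------------------------------
# Hypnogram / artifact TSVs
# ---------------------------------------------------------------------------

def read_hypnogram(path, dialect: str = "AASM") -> Hypnogram:
    """Read a hypnogram TSV (columns epoch_index, stage) in the R&K or AASM
    dialect; R&K stages 3 and 4 are merged into SWS."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"epoch_index", "stage"} <= set(df.columns):
        raise ValueError("hypnogram TSV needs columns epoch_index, stage")
    df = df.assign(epoch_index=df["epoch_index"].astype(int)).sort_values("epoch_index")
    if not np.array_equal(df["epoch_index"].to_numpy(), np.arange(len(df))):
        raise ValueError("epoch_index must be consecutive from 0")
    mapping = {"RK": _RK_MAP, "AASM": _AASM_MAP}.get(dialect.upper())
    if mapping is None:
        raise ValueError(f"unknown hypnogram dialect {dialect!r}")
    try:
        stages = [mapping[s.strip()] for s in df["stage"]]
    except KeyError as exc:
        raise ValueError(f"unknown {dialect} stage code {exc.args[0]!r}") from None
    return Hypnogram(stages=np.array(stages, dtype=object), dialect=dialect.upper())


def write_hypnogram(hyp: Hypnogram, path) -> None:
    inv = {"Wake": "W", "N1": "N1", "N2": "N2", "SWS": "N3", "REM": "R",
           "Movement": "M"}
    pd.DataFrame({"epoch_index": np.arange(len(hyp)),
                  "stage": [inv[s] for s in hyp.stages]}
                 ).to_csv(path, sep="\t", index=False)


def read_artifact_mask(path, n_epochs: int, channels: list[str]) -> ArtifactMask:
    """Read an artifact TSV (epoch_index, channel, flag) into a full grid."""
    df = pd.read_csv(path, sep="\t")
    flags = np.zeros((n_epochs, len(channels)), dtype=bool)
    for _, row in df.iterrows():
        ch = str(row["channel"])
        if ch in channels and bool(int(row["flag"])):
            flags[int(row["epoch_index"]), channels.index(ch)] = True
    return ArtifactMask(flags=flags, channels=list(channels))


def write_artifact_mask(mask: ArtifactMask, path) -> None:
    ep, ch = np.nonzero(mask.flags)
    pd.DataFrame({"epoch_index": ep,
                  "channel": [mask.channels[c] for c in ch],
                  "flag": np.ones(len(ep), dtype=int)}
                 ).to_csv(path, sep="\t", index=False)


def apply_artifact_rules(mask: ArtifactMask, hyp: Hypnogram,
                         max_artifact_frac: float = 0.20) -> ChannelUsability:
    """Channel-level exclusion and usable non-REM epochs per channel.

    A channel is excluded when strictly more than ``max_artifact_frac`` of
    its non-REM (N2+SWS) epochs are artifact-flagged; otherwise its usable
    epochs are the unflagged non-REM epochs.  Channels facing zero non-REM
    epochs are reported as having no usable data, not as an error.
    """
    if mask.flags.shape[0] != len(hyp):
        raise ValueError("artifact mask length does not match hypnogram")
    nonrem = hyp.epochs_in(NONREM_STAGES)
    usable, excluded, no_data = {}, [], []
    for j, ch in enumerate(mask.channels):
        if len(nonrem) == 0:
            no_data.append(ch)
            continue
        flagged = mask.flags[nonrem, j]
        if flagged.mean() > max_artifact_frac:
            excluded.append(ch)
        else:
            usable[ch] = nonrem[~flagged]
    return ChannelUsability(usable_epochs=usable, excluded=excluded,
                            no_data=no_data, n_nonrem=len(nonrem))
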