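"""Polysomnography I/O: EDF reading, stage-label mapping, 30-s epoch segmentation.

A sleep recording is scored in 30-second *epochs*, each assigned one stage.
Legacy annotations use the R&K vocabulary (W, S1–S4, R); the modern AASM
scheme merges S3 and S4 into N3, giving the five classes W, N1, N2, N3, REM.
This module reads a single EEG channel from an EDF/EDF+ file (or accepts an
in-memory :class:`Recording`), expands stage annotations into labelled
:class:`SleepEpoch` objects, and persists epoch tensors to NPZ containers for
the downstream spectrogram and model stages.
"""

from __future__ import annotations

import csv
import datetime as _dt
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

__all__ = [
    "Stage",
    "StageLabel",
    "Recording",
    "SleepEpoch",
    "STAGE_ORDER",
    "EPOCH_SECONDS",
    "map_stage",
    "load_recording",
    "segment_epochs",
    "write_edf",
    "read_hypnogram_csv",
    "write_hypnogram_csv",
    "save_epochs_npz",
    "load_epochs_npz",
]

EPOCH_SECONDS = 30.0


class Stage(Enum):
    """AASM 5-class sleep stage."""

    W = 0
    N1 = 1
    N2 = 2
    N3 = 3
    REM = 4


#: Canonical class order used for labels, confusion matrices and reports.
STAGE_ORDER = (Stage.W, Stage.N1, Stage.N2, Stage.N3, Stage.REM)

# R&K / annotation vocabulary -> AASM stage (None = excluded from scoring).
# S3 and S4 merge into N3 under the AASM rule.
_SOURCE_MAP: dict[str, Stage | None] = {
    "W": Stage.W,
    "WAKE": Stage.W,
    "SLEEP STAGE W": Stage.W,
    "S1": Stage.N1,
    "N1": Stage.N1,
    "SLEEP STAGE 1": Stage.N1,
    "S2": Stage.N2,
    "N2": Stage.N2,
    "SLEEP STAGE 2": Stage.N2,
    "S3": Stage.N3,
    "N3": Stage.N3,
    "SLEEP STAGE 3": Stage.N3,
    "S4": Stage.N3,
    "SLEEP STAGE 4": Stage.N3,
    "R": Stage.REM,
    "REM": Stage.REM,
    "SLEEP STAGE R": Stage.REM,
    "MOVEMENT": None,
    "MOVEMENT TIME": None,
    "SLEEP STAGE MOVEMENT TIME": None,
    "UNKNOWN": None,
    "SLEEP STAGE ?": None,
    "?": None,
}


@dataclass(frozen=True)
class StageLabel:
    """An AASM label together with the raw annotation string it came from.

    ``value`` is ``None`` for excluded annotations (movement time, unscored).
    """

    value: Stage | None
    source: str

    @property
    def excluded(self) -> bool:
        return self.value is None


def map_stage(source_label: str) -> StageLabel:
    """Map an R&K / annotation stage string to the 5-class AASM scheme.

    W→W, S1→N1, S2→N2, S3→N3, S4→N3, R→REM.  Movement time and unscored
    epochs carry no AASM value and are flagged ``excluded``.

    Raises
    ------
    ValueError
        If the label string is not in the recognised vocabulary.
    """
    key = source_label.strip().upper()
    if key not in _SOURCE_MAP:
        raise ValueError(f"unrecognised sleep-stage label: {source_label!r}")
    return StageLabel(value=_SOURCE_MAP[key], source=source_label)


@dataclass
class Recording:
    """A single-channel EEG recording in microvolts."""

    subject_id: str
    channel: str
    sample_rate: float
    samples: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        self.samples = np.asarray(self.samples, dtype=np.float64).ravel()

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass
class SleepEpoch:
    """One 30-s labelled EEG segment — the unit of classification."""

    subject_id: str
    epoch_index: int
    samples: np.ndarray
    label: StageLabel
    sample_rate: float = field(default=100.0)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64).ravel()
        expect = int(round(EPOCH_SECONDS * self.sample_rate))
        if len(self.samples) != expect:
            raise ValueError(
                f"epoch must hold exactly {expect} samples "
                f"(30 s at {self.sample_rate} Hz), got {len(self.samples)}"
            )


def load_recording(path: str | Path, channel: str) -> Recording:
    """Read the named channel of an EDF/EDF+ file.

    Other channels are ignored.  Raises ``FileNotFoundError`` for a missing
    file and ``ValueError`` (listing the available channel labels) when the
    requested channel is absent.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"EDF file not found: {path}")
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=False, verbose="error")
    if channel not in raw.ch_names:
        raise ValueError(
            f"channel {channel!r} not present in {path.name}; "
            f"available channels: {list(raw.ch_names)}"
        )
    raw = raw.pick([channel])
    raw.load_data(verbose="error")
    data = raw.get_data()[0]
    # mne scales EEG-typed channels to volts; recover microvolts
    unit = raw._orig_units.get(channel, "") if hasattr(raw, "_orig_units") else ""
    if unit in ("µV", "uV", ""):
        data = data * 1e6
    return Recording(
        subject_id=path.stem,
        channel=channel,
        sample_rate=float(raw.info["sfreq"]),
        samples=np.asarray(data, dtype=np.float64),
    )


def segment_epochs(
    rec: Recording,
    annotations: list[tuple[float, float, str]],
    trim_wake_minutes: float | None = None,
) -> list[SleepEpoch]:
    """Expand stage annotations into labelled 30-s epochs.

    Each annotation ``(onset_s, duration_s, stage)`` with duration ``d`` yields
    ``d/30`` epochs carrying the mapped AASM label; excluded labels (movement,
    unscored) are dropped.  Intervals are 0-based half-open
    ``[onset, onset+30)``.  An annotation extending past the end of the signal
    triggers a truncation warning and the partial epoch is dropped.

    ``trim_wake_minutes`` optionally clips long wake runs before the first and
    after the last sleep annotation to that many minutes (off by default: all
    annotated epochs are kept).
    """
    expanded: list[tuple[float, StageLabel]] = []  # (onset, label) per 30-s slot
    last_end = -np.inf
    for onset, duration, stage_text in annotations:
        if duration % EPOCH_SECONDS != 0:
            raise ValueError(
                f"annotation duration {duration} s at onset {onset} s "
                "is not a multiple of 30 s"
            )
        if onset < last_end:
            raise ValueError(f"overlapping annotation at onset {onset} s")
        last_end = onset + duration
        label = map_stage(stage_text)
        for k in range(int(duration // EPOCH_SECONDS)):
            expanded.append((onset + k * EPOCH_SECONDS, label))

    if trim_wake_minutes is not None:
        expanded = _trim_wake(expanded, trim_wake_minutes)

    n_per_epoch = int(round(EPOCH_SECONDS * rec.sample_rate))
    epochs: list[SleepEpoch] = []
    idx = 0
    for onset, label in expanded:
        if label.excluded:
            continue
        start = int(round(onset * rec.sample_rate))
        stop = start + n_per_epoch
        if stop > len(rec.samples):
            warnings.warn(
                f"annotation at {onset} s extends past end of signal "
                f"({rec.duration} s); partial epoch dropped",
                stacklevel=2,
            )
            continue
        epochs.append(
            SleepEpoch(
                subject_id=rec.subject_id,
                epoch_index=idx,
                samples=rec.samples[start:stop],
                label=label,
                sample_rate=rec.sample_rate,
            )
        )
        idx += 1
    return epochs


def _trim_wake(
    slots: list[tuple[float, StageLabel]], minutes: float
) -> list[tuple[float, StageLabel]]:
    keep = int(minutes * 60 // EPOCH_SECONDS)
    sleep_ix = [
        i for i, (_, lab) in enumerate(slots) if lab.value not in (Stage.W, None)
    ]
    if not sleep_ix:
        return slots
    lo = max(0, sleep_ix[0] - keep)
    hi = min(len(slots), sleep_ix[-1] + 1 + keep)
    return slots[lo:hi]


# ---------------------------------------------------------------------------
# Minimal EDF writer (16-bit, single data record per second block).
# Only what the simulate fixtures and the round-trip test need.
# ---------------------------------------------------------------------------

def write_edf(
    path: str | Path,
    rec: Recording,
    physical_range: tuple[float, float] = (-500.0, 500.0),
) -> None:
    """Write a single-channel recording as a plain 16-bit EDF file.

    Samples are clipped to ``physical_range`` and quantised to the 16-bit
    digital range, the usual EDF precision.  One data record per second.
    """
    path = Path(path)
    fs = rec.sample_rate
    spr = int(round(fs))  # samples per 1-s data record
    if abs(spr - fs) > 1e-9:
        raise ValueError(f"EDF writer requires an integer sample rate, got {fs}")
    n_records = int(np.ceil(len(rec.samples) / spr))
    padded = np.zeros(n_records * spr)
    padded[: len(rec.samples)] = rec.samples

    pmin, pmax = physical_range
    dmin, dmax = -32768, 32767
    clipped = np.clip(padded, pmin, pmax)
    digital = np.round((clipped - pmin) / (pmax - pmin) * (dmax - dmin) + dmin)
    digital = digital.astype("<i2")

    start = _dt.datetime(2000, 1, 1, 0, 0, 0)
    header = b""
    header += b"0".ljust(8)
    header += rec.subject_id[:80].ljust(80).encode("ascii", "replace")
    header += b"".ljust(80)  # recording id
    header += start.strftime("%d.%m.%y").encode().ljust(8)
    header += start.strftime("%H.%M.%S").encode().ljust(8)
    header += str(256 + 256).encode().ljust(8)  # header bytes: fixed + 1 signal
    header += b"".ljust(44)
    header += str(n_records).encode().ljust(8)
    header += b"1".ljust(8)  # record duration, seconds
    header += b"1".ljust(4)  # number of signals
    # per-signal fields
    header += rec.channel[:16].ljust(16).encode("ascii", "replace")
    header += b"".ljust(80)  # transducer
    header += b"uV".ljust(8)
    header += f"{pmin:g}".encode().ljust(8)
    header += f"{pmax:g}".encode().ljust(8)
    header += str(dmin).encode().ljust(8)
    header += str(dmax).encode().ljust(8)
    header += b"".ljust(80)  # prefiltering
    header += str(spr).encode().ljust(8)
    header += b"".ljust(32)
    assert len(header) == 512

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(digital.tobytes())


def write_hypnogram_csv(path: str | Path, annotations: list[tuple[float, float, str]]) -> None:
    """Write annotations in the fixture dialect ``onset_s,duration_s,stage``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["onset_s", "duration_s", "stage"])
        for onset, duration, stage in annotations:
            writer.writerow([f"{onset:g}", f"{duration:g}", stage])


def read_hypnogram_csv(path: str | Path) -> list[tuple[float, float, str]]:
    """Read the ``onset_s,duration_s,stage`` hypnogram dialect."""
    out: list[tuple[float, float, str]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(reader.fieldnames) < {
            "onset_s",
            "duration_s",
            "stage",
        }:
            raise ValueError(
                f"{path}: expected columns onset_s,duration_s,stage, "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            out.append((float(row["onset_s"]), float(row["duration_s"]), row["stage"]))
    return out


def save_epochs_npz(path: str | Path, epochs: list[SleepEpoch]) -> None:
    """Persist labelled epochs to an NPZ container (per-subject tensors)."""
    if not epochs:
        raise ValueError("no epochs to save")
    rates = {e.sample_rate for e in epochs}
    if len(rates) != 1:
        raise ValueError(f"mixed sample rates in one container: {sorted(rates)}")
    np.savez_compressed(
        path,
        samples=np.stack([e.samples for e in epochs]).astype(np.float32),
        labels=np.array([e.label.value.value for e in epochs], dtype=np.int64),
        subjects=np.array([e.subject_id for e in epochs]),
        epoch_index=np.array([e.epoch_index for e in epochs], dtype=np.int64),
        sample_rate=np.array(rates.pop()),
    )


def load_epochs_npz(path: str | Path) -> list[SleepEpoch]:
    """Load a container written by :func:`save_epochs_npz`."""
    with np.load(path, allow_pickle=False) as z:
        rate = float(z["sample_rate"])
        out = []
        for samp, lab, subj, idx in zip(
            z["samples"], z["labels"], z["subjects"], z["epoch_index"]
        ):
            stage = Stage(int(lab))
            out.append(
                SleepEpoch(
                    subject_id=str(subj),
                    epoch_index=int(idx),
                    samples=samp.astype(np.float64),
                    label=StageLabel(stage, stage.name),
                    sample_rate=rate,
                )
            )
    return out
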