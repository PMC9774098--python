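"""Readers/writers for the formats the pipeline touches, and bipolar montage.

Signals travel as :class:`Recording` (microvolts throughout).  EDF is read
with :mod:`mne`; writing uses a small built-in EDF writer (16-bit, 1-second
data records) so that synthetic recordings round-trip without any
non-standard dependency.  Contact metadata and event lists are plain TSV.
"""

from __future__ import annotations

import re
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "read_edf",
    "write_edf",
    "to_bipolar",
    "infer_shafts",
    "read_contact_table",
    "write_contact_table",
    "read_events",
    "write_events",
    "SchemaError",
]

CONTACT_COLUMNS = ["contact", "patient_id", "region", "x", "y", "z"]
EVENT_COLUMNS = ["contact", "kind", "onset_s", "duration_s", "frequency_hz"]


class SchemaError(ValueError):
    """A table is missing required columns."""


@dataclass
class Recording:
    """Multi-channel iEEG signal in microvolts.

    Attributes
    ----------
    signal : ndarray, shape (n_channels, n_samples)
    sampling_rate : float, Hz
    channel_names : list of str, unique
    montage : {"referential", "bipolar"}
    """

    signal: np.ndarray
    sampling_rate: float
    channel_names: list[str] = field(default_factory=list)
    montage: str = "referential"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not self.channel_names:
            self.channel_names = [f"CH{i + 1}" for i in range(self.signal.shape[0])]
        if len(self.channel_names) != self.signal.shape[0]:
            raise ValueError("channel_names length must match signal rows")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel_names must be unique")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channel_names.index(name)
        except ValueError as err:
            raise KeyError(f"unknown channel {name!r}") from err
        return self.signal[idx]


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def read_edf(path: str | Path) -> Recording:
    """Read an EDF file into a referential :class:`Recording` (microvolts)."""
    import mne

    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"not a valid EDF file: {path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as err:  # malformed header etc.
        raise ValueError(f"not a valid EDF file: {path}: {err}") from err
    # reject mixed per-channel sampling rates (mne would resample silently)
    extras = (raw._raw_extras or [{}])[0]
    n_samps = extras.get("n_samps")
    if n_samps is not None and len(set(np.asarray(n_samps).tolist())) > 1:
        raise ValueError("mixed sampling rates across channels are unsupported")
    data = raw.get_data() * 1e6  # mne returns volts
    return Recording(
        signal=data,
        sampling_rate=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        montage="referential",
    )


def _pad_ascii(text: str, width: int) -> bytes:
    b = text.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(recording: Recording, path: str | Path) -> None:
    """Write a recording as EDF (16-bit, 1-second data records).

    The recording duration must be an integer number of seconds and the
    sampling rate an integer, which all synthetic recordings satisfy.
    Values are quantized to the 16-bit digital range over the per-channel
    physical range, the usual EDF precision loss.
    """
    fs = recording.sampling_rate
    if fs != int(fs):
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(fs)
    n_records, rem = divmod(recording.n_samples, fs)
    if rem:
        raise ValueError("EDF writer requires an integer number of seconds")
    ns = recording.n_channels

    phys_max = np.maximum(np.abs(recording.signal).max(axis=1), 1.0) * 1.0001
    dig_max = 32767

    header = b"".join(
        [
            _pad_ascii("0", 8),
            _pad_ascii("X X X X", 80),
            _pad_ascii("Startdate X X X X", 80),
            _pad_ascii("01.01.00", 8),
            _pad_ascii("00.00.00", 8),
            _pad_ascii(str(256 * (1 + ns)), 8),
            _pad_ascii("", 44),
            _pad_ascii(str(n_records), 8),
            _pad_ascii("1", 8),
            _pad_ascii(str(ns), 4),
        ]
    )
    per_sig = b"".join(
        [
            b"".join(_pad_ascii(name, 16) for name in recording.channel_names),
            b"".join(_pad_ascii("", 80) for _ in range(ns)),
            b"".join(_pad_ascii("uV", 8) for _ in range(ns)),
            b"".join(_pad_ascii(f"{-m:.6g}"[:8], 8) for m in phys_max),
            b"".join(_pad_ascii(f"{m:.6g}"[:8], 8) for m in phys_max),
            b"".join(_pad_ascii(str(-dig_max - 1), 8) for _ in range(ns)),
            b"".join(_pad_ascii(str(dig_max), 8) for _ in range(ns)),
            b"".join(_pad_ascii("", 80) for _ in range(ns)),
            b"".join(_pad_ascii(str(fs), 8) for _ in range(ns)),
            b"".join(_pad_ascii("", 32) for _ in range(ns)),
        ]
    )

    # round-half-away quantization to the digital range
    phys_parsed = np.array([float(f"{m:.6g}"[:8]) for m in phys_max])
    scale = dig_max / phys_parsed
    digital = np.clip(
        np.round(recording.signal * scale[:, None]), -dig_max - 1, dig_max
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_sig)
        for rec in range(n_records):
            sl = slice(rec * fs, (rec + 1) * fs)
            fh.write(digital[:, sl].tobytes())


# ---------------------------------------------------------------------------
# Bipolar montage
# ---------------------------------------------------------------------------

_SHAFT_RE = re.compile(r"^([A-Za-z']+)\s*0*(\d+)$")


def infer_shafts(channel_names: list[str]) -> dict[str, list[str]]:
    """Group channels into electrode shafts from the `A1..A12` naming scheme.

    Returns a mapping shaft -> channel names ordered along the shaft.
    Channels that do not match the convention form singleton shafts.
    """
    groups: dict[str, list[tuple[int, str]]] = {}
    for name in channel_names:
        m = _SHAFT_RE.match(name.strip())
        if m:
            groups.setdefault(m.group(1), []).append((int(m.group(2)), name))
        else:
            groups.setdefault(name, []).append((0, name))
    return {
        shaft: [nm for _, nm in sorted(members)] for shaft, members in groups.items()
    }


def to_bipolar(
    recording: Recording, shaft_grouping: dict[str, list[str]] | None = None
) -> Recording:
    """Convert a referential recording to an adjacent-pair bipolar montage.

    Each output channel is the difference of two adjacent contacts on the
    same shaft, named ``"A1-A2"``.  Shafts with a single contact contribute
    no channels (warning).  Contacts are never mixed across shafts.
    """
    if recording.montage != "referential":
        raise ValueError("recording is not in referential montage")
    if shaft_grouping is None:
        shaft_grouping = infer_shafts(recording.channel_names)

    rows, names = [], []
    for shaft, members in shaft_grouping.items():
        if len(members) < 2:
            warnings.warn(f"shaft {shaft!r} has a single contact; skipped")
            continue
        for a, b in zip(members[:-1], members[1:]):
            rows.append(recording.channel(a) - recording.channel(b))
            names.append(f"{a}-{b}")
    if not rows:
        raise ValueError("no shaft contributed a bipolar channel")
    return Recording(
        signal=np.vstack(rows),
        sampling_rate=recording.sampling_rate,
        channel_names=names,
        montage="bipolar",
    )


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required columns: {missing}")


def read_contact_table(path: str | Path) -> pd.DataFrame:
    """Read the contact metadata TSV (contact, patient_id, region, x, y, z
    and optionally soz_label)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, CONTACT_COLUMNS, "contact table")
    if not np.isfinite(df[["x", "y", "z"]].to_numpy(float)).all():
        raise ValueError("contact coordinates must be finite")
    return df


def write_contact_table(table: pd.DataFrame, path: str | Path) -> None:
    _require_columns(table, CONTACT_COLUMNS, "contact table")
    table.to_csv(path, sep="\t", index=False)


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    """Write a biomarker event table as TSV."""
    _require_columns(events, EVENT_COLUMNS, "event table")
    events.to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    """Read a biomarker event TSV; rows come back sorted by onset."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, EVENT_COLUMNS, "event table")
    return df.sort_values("onset_s", kind="stable").reset_index(drop=True)


def events_to_frame(events: list) -> pd.DataFrame:
    """Convert a list of event dataclasses to the TSV schema."""
    rows = []
    for ev in events:
        rows.append(
            {
                "contact": ev.contact,
                "kind": getattr(ev, "kind", getattr(ev, "band", "")),
                "onset_s": getattr(ev, "onset", getattr(ev, "start", np.nan)),
                "duration_s": getattr(
                    ev, "duration", getattr(ev, "end", np.nan) - getattr(ev, "start", 0.0)
                ),
                "frequency_hz": getattr(ev, "center_frequency", 0.0),
            }
        )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)
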