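"""Interictal spike detection behind a pluggable registry.

The study design calls for several spike detectors feeding separate rate
columns (index ``j``).  Deep pre-trained detectors are out of scope here;
the package ships one transparent reference detector based on joint
amplitude / slope z-score thresholding with a width constraint, and a
registry so that any detector honoring the :class:`SpikeEvent` contract
can occupy a column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.signal import find_peaks

from sozloc.io import Recording

__all__ = [
    "SpikeEvent",
    "SpikeDetectorConfig",
    "detect_spikes_reference",
    "register_detector",
    "registered_detectors",
    "detect_spikes",
    "extract_segment",
]

SEGMENT_SECONDS = 5.0  # spike segments are 5 s windows


@dataclass
class SpikeEvent:
    """A detected spike: peak time plus the 5 s peak-centered segment."""

    contact: str
    peak_time: float  # s
    segment: np.ndarray = field(repr=False)
    detector_id: str = "reference"


@dataclass(frozen=True)
class SpikeDetectorConfig:
    """Thresholds for the reference detector.

    ``z_amp`` / ``z_slope`` are exceedances in channel standard deviations
    of the signal and its rectified first difference; a candidate peak is
    kept when both fire and the half-height width of the deflection lies
    in ``(width_min, width_max)`` seconds (sharp-transient morphology).
    """

    z_amp: float = 4.0
    z_slope: float = 4.0
    width_min: float = 0.015
    width_max: float = 0.080
    refractory: float = 0.150  # s between detected peaks


def detect_spikes_reference(
    recording: Recording, config: SpikeDetectorConfig | None = None
) -> list[SpikeEvent]:
    """Amplitude + slope z-score spike detector (deterministic).

    Detections are invariant to DC offsets (the channel mean is removed)
    and lowering either z-threshold can only add detections.
    """
    config = config or SpikeDetectorConfig()
    fs = recording.sampling_rate
    events: list[SpikeEvent] = []
    for name in recording.channel_names:
        x = recording.channel(name)
        xc = x - x.mean()
        sd = xc.std() or 1.0
        za = np.abs(xc) / sd
        slope = np.abs(np.diff(xc, prepend=xc[0]))
        zs = slope / (slope.std() or 1.0)
        peaks, _ = find_peaks(
            za, height=config.z_amp, distance=max(int(config.refractory * fs), 1)
        )
        half_win = int(0.05 * fs)
        for p in peaks:
            lo, hi = max(p - half_win, 0), min(p + half_win, x.size)
            if zs[lo:hi].max() < config.z_slope:
                continue
            # half-height width of the deflection around the peak
            level = za[p] / 2.0
            i = p
            while i > lo and za[i] >= level:
                i -= 1
            j = p
            while j < hi - 1 and za[j] >= level:
                j += 1
            width = (j - i) / fs
            if not config.width_min <= width <= config.width_max:
                continue
            events.append(
                SpikeEvent(
                    contact=name,
                    peak_time=p / fs,
                    segment=extract_segment(recording, name, p / fs),
                    detector_id="reference",
                )
            )
    events.sort(key=lambda e: (e.contact, e.peak_time))
    return events


def extract_segment(
    recording: Recording, contact: str, peak_time: float, length: float = SEGMENT_SECONDS
) -> np.ndarray:
    """Peak-centered window of exactly ``length`` seconds, zero-padded at
    the recording edges."""
    if not 0 <= peak_time <= recording.duration:
        raise ValueError(f"peak_time {peak_time} outside recording")
    x = recording.channel(contact)
    fs = recording.sampling_rate
    n = int(round(length * fs))
    center = int(round(peak_time * fs))
    start = center - n // 2
    seg = np.zeros(n)
    lo = max(start, 0)
    hi = min(start + n, x.size)
    seg[lo - start : hi - start] = x[lo:hi]
    return seg


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

DetectorFn = Callable[[Recording], list[SpikeEvent]]
_DETECTORS: dict[str, DetectorFn] = {}


def register_detector(detector_id: str, fn: DetectorFn) -> None:
    """Register a spike detector under ``detector_id``.

    The callable takes a :class:`~sozloc.io.Recording` and returns a list
    of :class:`SpikeEvent` with ``detector_id`` filled in.
    """
    _DETECTORS[detector_id] = fn


def registered_detectors() -> list[str]:
    return sorted(_DETECTORS)


def detect_spikes(recording: Recording, detector_id: str = "reference") -> list[SpikeEvent]:
    """Dispatch to a registered detector; unknown ids raise ``KeyError``."""
    try:
        fn = _DETECTORS[detector_id]
    except KeyError:
        raise KeyError(
            f"unknown spike detector {detector_id!r}; registered: {registered_detectors()}"
        ) from None
    events = fn(recording)
    for ev in events:
        ev.detector_id = detector_id
    return events


def _reference(recording: Recording) -> list[SpikeEvent]:
    return detect_spikes_reference(recording)


register_detector("reference", _reference)
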