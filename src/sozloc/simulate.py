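"""Synthetic SEEG with planted interictal biomarkers.

Emulates the statistical structure the pipeline assumes: 1/f background,
sharp-wave spikes (optionally followed by a slow wave), band-limited
oscillatory bursts in the ripple (80-250 Hz) and fast-ripple (250-500 Hz)
bands with at least six oscillations, co-occurring ripple/fast-ripple
events, and SOZ contacts with elevated event rates under class imbalance.
It does not attempt ictal dynamics, artifacts or volume conduction.

Burst amplitudes are anchored to the background: a burst at ``snr_db`` has
peak amplitude ``10**(snr_db/20)`` times the 95th percentile of the
in-band Hilbert envelope of the pre-injection background on that contact,
so detector-facing contrast is controlled directly.  Bursts use a
Hann-tapered plateau (Tukey) window: the taper keeps edges smooth while
the plateau sustains the envelope long enough that a short fast-ripple
burst still satisfies a 20 ms above-threshold criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import hilbert
from scipy.signal.windows import tukey

from sozloc.io import Recording

__all__ = [
    "SimulationConfig",
    "GroundTruthEvent",
    "generate_background",
    "inject_events",
    "generate_feature_table",
    "simulate_cohort",
    "PlacementError",
]

RIPPLE_BAND = (80.0, 250.0)
FR_BAND = (250.0, 500.0)

#: regions with a published physiological ripple-rate constant
DEFAULT_REGIONS = (2, 7, 8, 9)


class PlacementError(RuntimeError):
    """Requested event rates cannot be placed without overlap."""


@dataclass
class GroundTruthEvent:
    """A planted biomarker occurrence on one contact."""

    contact: str
    kind: str  # spike | ripple | fast_ripple | r_and_fr
    onset: float  # seconds
    duration: float  # seconds
    center_frequency: float = 0.0  # Hz, 0 for spikes
    amplitude: float = 0.0  # microvolts (peak)

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Event rates are per minute; SOZ rates must dominate non-SOZ rates for
    a separable scenario.  Defaults follow the clinical recording setup
    (2048 Hz sampling, ~30 s - minutes long interictal segments) with
    event-rate contrasts typical of SOZ versus non-SOZ contacts.
    """

    n_contacts: int = 10
    soz_fraction: float = 0.2
    duration: float = 60.0  # seconds
    sampling_rate: float = 2048.0
    background_exponent: float = 2.0  # 1/f^exponent
    background_rms: float = 15.0  # microvolts
    spike_rate_soz: float = 10.0
    spike_rate_nsoz: float = 1.0
    ripple_rate_soz: float = 12.0
    ripple_rate_nsoz: float = 2.0
    fr_rate_soz: float = 8.0
    fr_rate_nsoz: float = 1.0
    cooccur_prob: float = 0.5
    snr_db: float = 10.0
    spike_amplitude_factor: float = 8.0  # spike peak in background SDs
    n_cycles: int = 8
    burst_taper: float = 0.5  # Tukey taper fraction of the burst
    ripple_freq_range: tuple[float, float] = (100.0, 200.0)
    fr_freq_range: tuple[float, float] = (260.0, 320.0)
    spike_width: float = 0.070  # seconds, sharp component
    slow_wave_prob: float = 0.5
    region_assignment: dict[str, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        rates = [
            self.spike_rate_soz,
            self.spike_rate_nsoz,
            self.ripple_rate_soz,
            self.ripple_rate_nsoz,
            self.fr_rate_soz,
            self.fr_rate_nsoz,
        ]
        if any(r < 0 for r in rates):
            raise ValueError("event rates must be non-negative")
        if not 0 <= self.soz_fraction <= 1:
            raise ValueError("soz_fraction must be in [0, 1]")
        if self.sampling_rate < 1000:
            raise ValueError(
                "sampling_rate must be >= 1000 Hz so the 250-500 Hz band is representable"
            )
        if not 0 <= self.cooccur_prob <= 1:
            raise ValueError("cooccur_prob must be in [0, 1]")


def generate_background(
    n_contacts: int,
    duration: float,
    sampling_rate: float,
    exponent: float = 2.0,
    seed: int = 0,
    rms: float = 15.0,
) -> Recording:
    """Generate 1/f^exponent background noise, ``rms`` microvolts per channel.

    Spectral shaping is done in the Fourier domain: white Gaussian noise is
    scaled by f^(-exponent/2) (DC removed), giving a PSD that decays as
    1/f^exponent.  Deterministic for a fixed seed.
    """
    if duration <= 0 or sampling_rate <= 0:
        raise ValueError("duration and sampling_rate must be positive")
    n = int(round(duration * sampling_rate))
    if n < 1:
        raise ValueError("duration * sampling_rate must be >= 1")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((n_contacts, n))
    freqs = np.fft.rfftfreq(n, 1.0 / sampling_rate)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    spectrum = np.fft.rfft(white, axis=1) * shaping
    sig = np.fft.irfft(spectrum, n=n, axis=1)
    sd = sig.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    sig = sig / sd * rms
    names = [f"C{i + 1:02d}" for i in range(n_contacts)]
    return Recording(sig, sampling_rate, names, montage="bipolar")


# ---------------------------------------------------------------------------
# event waveforms
# ---------------------------------------------------------------------------

def _burst(freq: float, n_cycles: int, fs: float, amplitude: float, taper: float) -> np.ndarray:
    n = max(int(round(n_cycles / freq * fs)), 4)
    t = np.arange(n) / fs
    return amplitude * np.sin(2 * np.pi * freq * t) * tukey(n, taper)


def _spike(fs: float, width: float, amplitude: float, with_slow: bool) -> np.ndarray:
    """Biphasic sharp transient (one sine period over ``width``) with an
    optional 200 ms half-sine slow wave at 40% amplitude."""
    n_sharp = max(int(round(width * fs)), 4)
    t = np.arange(n_sharp) / n_sharp
    sharp = amplitude * np.sin(2 * np.pi * t) * np.hanning(n_sharp) ** 0.25
    if not with_slow:
        return sharp
    n_slow = int(round(0.200 * fs))
    slow = 0.4 * amplitude * np.sin(np.pi * np.arange(n_slow) / n_slow)
    return np.concatenate([sharp, slow])


def _band_envelope_p95(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    from sozloc.hfo import bandpass

    filt = bandpass(x, fs, band[0], band[1])
    return float(np.percentile(np.abs(hilbert(filt)), 95))


def _place_onsets(
    rng: np.random.Generator,
    n_events: int,
    event_dur: float,
    total_dur: float,
    occupied: list[tuple[float, float]],
    max_tries: int = 200,
) -> list[float]:
    """Uniform random onsets with non-overlap enforcement (0.1 s guard)."""
    onsets: list[float] = []
    margin = 0.25  # keep clear of recording edges
    for _ in range(n_events):
        for attempt in range(max_tries):
            t0 = rng.uniform(margin, total_dur - event_dur - margin)
            span = (t0 - 0.1, t0 + event_dur + 0.1)
            if all(span[1] <= a or span[0] >= b for a, b in occupied):
                occupied.append((t0, t0 + event_dur))
                onsets.append(t0)
                break
        else:
            raise PlacementError(
                f"could not place {n_events} events of {event_dur:.3f}s in {total_dur:.1f}s"
            )
    return onsets


def inject_events(
    recording: Recording, config: SimulationConfig, seed: int | None = None
) -> tuple[Recording, list[GroundTruthEvent]]:
    """Superimpose spikes and HFO bursts onto a recording.

    The first ``round(soz_fraction * n_contacts)`` channels are the SOZ
    contacts and receive events at the SOZ rates.  Event counts per
    contact/kind are Poisson draws at the configured per-minute rate;
    each fast ripple co-occurs with an overlapping ripple burst with
    probability ``cooccur_prob`` (emitting ripple, fast_ripple and
    r_and_fr ground-truth records).  Returns the modified recording and
    the ground truth sorted by onset.
    """
    fs = recording.sampling_rate
    if fs != config.sampling_rate:
        raise ValueError("recording sampling rate does not match config")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sig = recording.signal.copy()
    dur = recording.duration
    minutes = dur / 60.0
    n_soz = int(round(config.soz_fraction * recording.n_channels))
    events: list[GroundTruthEvent] = []

    for ci, name in enumerate(recording.channel_names):
        is_soz = ci < n_soz
        x = sig[ci]
        spike_rate = config.spike_rate_soz if is_soz else config.spike_rate_nsoz
        r_rate = config.ripple_rate_soz if is_soz else config.ripple_rate_nsoz
        fr_rate = config.fr_rate_soz if is_soz else config.fr_rate_nsoz

        occupied: list[tuple[float, float]] = []
        amp_gain = 10 ** (config.snr_db / 20.0)
        r_amp = amp_gain * _band_envelope_p95(x, fs, RIPPLE_BAND)
        fr_amp = amp_gain * _band_envelope_p95(x, fs, FR_BAND)
        spike_amp = config.spike_amplitude_factor * x.std()

        # --- spikes
        n_spk = rng.poisson(spike_rate * minutes)
        for t0 in _place_onsets(rng, n_spk, config.spike_width + 0.2, dur, occupied):
            wave = _spike(fs, config.spike_width, spike_amp, rng.random() < config.slow_wave_prob)
            i0 = int(round(t0 * fs))
            x[i0 : i0 + wave.size] += wave[: x.size - i0]
            events.append(
                GroundTruthEvent(name, "spike", t0, wave.size / fs, 0.0, spike_amp)
            )

        # --- ripples
        n_r = rng.poisson(r_rate * minutes)
        for _ in range(n_r):
            f = rng.uniform(*config.ripple_freq_range)
            wave = _burst(f, config.n_cycles, fs, r_amp, config.burst_taper)
            (t0,) = _place_onsets(rng, 1, wave.size / fs, dur, occupied)
            i0 = int(round(t0 * fs))
            x[i0 : i0 + wave.size] += wave[: x.size - i0]
            events.append(
                GroundTruthEvent(name, "ripple", t0, wave.size / fs, f, r_amp)
            )

        # --- fast ripples, optionally co-occurring with a ripple
        n_fr = rng.poisson(fr_rate * minutes)
        for _ in range(n_fr):
            f = rng.uniform(*config.fr_freq_range)
            wave = _burst(f, config.n_cycles, fs, fr_amp, config.burst_taper)
            fr_dur = wave.size / fs
            cooccur = rng.random() < config.cooccur_prob
            if cooccur:
                fc = rng.uniform(*config.ripple_freq_range)
                rwave = _burst(fc, config.n_cycles, fs, r_amp, config.burst_taper)
                r_dur = rwave.size / fs
                (t0,) = _place_onsets(rng, 1, r_dur, dur, occupied)
                i0 = int(round(t0 * fs))
                x[i0 : i0 + rwave.size] += rwave[: x.size - i0]
                # centre the FR inside the ripple so the spans overlap
                t_fr = t0 + max((r_dur - fr_dur) / 2.0, 0.0)
                j0 = int(round(t_fr * fs))
                x[j0 : j0 + wave.size] += wave[: x.size - j0]
                events.append(GroundTruthEvent(name, "ripple", t0, r_dur, fc, r_amp))
                events.append(GroundTruthEvent(name, "fast_ripple", t_fr, fr_dur, f, fr_amp))
                events.append(
                    GroundTruthEvent(
                        name, "r_and_fr", t0, max(t0 + r_dur, t_fr + fr_dur) - t0, f, fr_amp
                    )
                )
            else:
                (t0,) = _place_onsets(rng, 1, fr_dur, dur, occupied)
                i0 = int(round(t0 * fs))
                x[i0 : i0 + wave.size] += wave[: x.size - i0]
                events.append(GroundTruthEvent(name, "fast_ripple", t0, fr_dur, f, fr_amp))

    events.sort(key=lambda e: (e.onset, e.contact, e.kind))
    out = Recording(sig, fs, list(recording.channel_names), recording.montage)
    return out, events


# ---------------------------------------------------------------------------
# feature-table generator (test harness for selection / classification)
# ---------------------------------------------------------------------------

def generate_feature_table(
    n_soz: int,
    n_nsoz: int,
    n_informative: int,
    n_noise: int,
    effect_size: float,
    seed: int = 0,
    n_patients: int = 1,
) -> pd.DataFrame:
    """Contact-level feature table with planted class structure.

    Informative features are unit-variance Gaussians whose class means
    differ by ``effect_size`` standard deviations; noise features are
    identically distributed across classes.  Rows carry ``contact``,
    ``patient_id`` (round-robin over ``n_patients``), ``region`` and
    ``label`` columns next to the feature columns.
    """
    if n_informative + n_noise < 1:
        raise ValueError("need at least one feature")
    if n_soz < 0 or n_nsoz < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    n = n_soz + n_nsoz
    labels = np.array([1] * n_soz + [0] * n_nsoz)
    X = rng.standard_normal((n, n_informative + n_noise))
    X[labels == 1, :n_informative] += effect_size
    names = [f"f{i:03d}_informative" for i in range(n_informative)] + [
        f"f{i + n_informative:03d}_noise" for i in range(n_noise)
    ]
    df = pd.DataFrame(X, columns=names)
    order = rng.permutation(n)
    df = df.iloc[order].reset_index(drop=True)
    labels = labels[order]
    df.insert(0, "contact", [f"C{i + 1:03d}" for i in range(n)])
    df.insert(1, "patient_id", [f"P{(i % n_patients) + 1:02d}" for i in range(n)])
    df.insert(2, "region", [DEFAULT_REGIONS[i % len(DEFAULT_REGIONS)] for i in range(n)])
    df["label"] = labels
    return df


# ---------------------------------------------------------------------------
# multi-patient cohort for end-to-end runs
# ---------------------------------------------------------------------------

def simulate_cohort(
    n_patients: int,
    config: SimulationConfig,
    seed: int = 0,
    soz_contacts: int | None = None,
) -> list[dict]:
    """Simulate a cohort of patients for an end-to-end pipeline run.

    Each patient gets an independent recording (already channel-per-contact,
    bipolar-equivalent), a contact table with regions, synthetic coordinates
    and SOZ labels, and the planted ground truth.  Returns a list of dicts
    with keys ``patient_id``, ``recording``, ``contacts``, ``events``.
    """
    rng = np.random.default_rng(seed)
    cohort = []
    for p in range(n_patients):
        pid = f"P{p + 1:02d}"
        sub = int(rng.integers(0, 2**31 - 1))
        bg = generate_background(
            config.n_contacts,
            config.duration,
            config.sampling_rate,
            config.background_exponent,
            seed=sub,
            rms=config.background_rms,
        )
        bg.channel_names = [f"{pid}_{c}" for c in bg.channel_names]
        rec, events = inject_events(bg, config, seed=sub + 1)
        n_soz = (
            soz_contacts
            if soz_contacts is not None
            else int(round(config.soz_fraction * config.n_contacts))
        )
        contacts = pd.DataFrame(
            {
                "contact": rec.channel_names,
                "patient_id": pid,
                "region": [
                    config.region_assignment.get(c, DEFAULT_REGIONS[i % len(DEFAULT_REGIONS)])
                    if config.region_assignment
                    else DEFAULT_REGIONS[i % len(DEFAULT_REGIONS)]
                    for i, c in enumerate(rec.channel_names)
                ],
                "x": 10.0 * np.arange(rec.n_channels) - 40.0,
                "y": np.full(rec.n_channels, 5.0 * p),
                "z": np.zeros(rec.n_channels),
                "soz_label": [1 if i < n_soz else 0 for i in range(rec.n_channels)],
            }
        )
        cohort.append(
            {"patient_id": pid, "recording": rec, "contacts": contacts, "events": events}
        )
    return cohort
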