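"""Shared helpers for detector-oriented tests."""

import numpy as np
from scipy.signal.windows import tukey

from sozloc.hfo import (
    DetectorParams,
    bandpass,
    detect_band_events,
    estimate_baseline,
    smoothed_hilbert_envelope,
    stockwell_energy_entropy,
)

FS = 2048.0


def burst_in_noise(noise, freq, n_cycles, gain, at_s, fs=FS, taper=0.5):
    """Add a tapered sinusoidal burst whose peak is ``gain`` times the
    95th percentile of the noise's ripple-band envelope."""
    x = noise.copy()
    amp = gain * np.percentile(
        smoothed_hilbert_envelope(bandpass(noise, fs, 80, 250), fs), 95
    )
    n = int(round(n_cycles / freq * fs))
    t = np.arange(n) / fs
    w = amp * np.sin(2 * np.pi * freq * t) * tukey(n, taper)
    i0 = int(at_s * fs)
    x[i0 : i0 + n] += w
    return x, (at_s, at_s + n / fs)


def detect_ripple_band(x, params=None, fs=FS):
    """Run the single-channel ripple-band screening chain."""
    params = params or DetectorParams.ripple()
    filt = bandpass(x, fs, *params.band)
    env = smoothed_hilbert_envelope(filt, fs, params.smooth_window)
    ent = stockwell_energy_entropy(x, fs, params.st_band, params.st_stride)
    thr = estimate_baseline(filt, env, ent, params, fs)
    return detect_band_events(env, filt, thr, params, fs, contact="A1")
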