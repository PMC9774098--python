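"""Per-event signal features in three domains: time, Fourier, wavelet.

The same registry serves spike energy and HFO energy characterization.
Feature sets are fixed per event kind:

* ``spike`` -- discrete-wavelet features only;
* ``ripple`` -- time + Fourier + discrete-wavelet features;
* ``fast_ripple`` / ``r_and_fr`` -- as ripple, but Kraskov and Renyi
  entropies are dropped in the wavelet domain (the events are too short
  for stable estimates of those two).

Wavelet features default to the a4 and d4 sub-bands of a 4-level db4
decomposition; names embed the sub-band (``a4_hfd``).  The Fourier
``peak_frequency`` follows the convention of this pipeline: the spread
(max - min) of the magnitude spectrum; an argmax-frequency alternative is
available via ``argmax_peak=True``.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pywt

from sozloc import complexity as cx

__all__ = [
    "time_features",
    "fft_features",
    "dwt_features",
    "event_feature_vector",
    "feature_names",
    "feature_manifest",
]

TIME_FEATURE_NAMES = ["time_energy", "time_duration"]
FFT_FEATURE_NAMES = [
    "fft_maximum",
    "fft_mean",
    "fft_minimum",
    "fft_peak_frequency",
    "fft_power",
    "fft_psd",
    "fft_spectral_entropy",
    "fft_spectrum",
    "fft_variance",
]
DWT_FEATURE_NAMES = [
    "kraskov",
    "renyi",
    "permutation",
    "sample",
    "shannon",
    "energy",
    "svd",
    "pfd",
    "kfd",
    "hfd",
]
#: wavelet features dropped for short events (fast ripples, R&FR)
DWT_DROP_SHORT = ("kraskov", "renyi")

DEFAULT_WAVELET = "db4"
DEFAULT_LEVELS = 4
DEFAULT_SUBBANDS = ("a4", "d4")


def time_features(event_signal: np.ndarray, sampling_rate: float) -> dict[str, float]:
    """Energy (sum of squares) and duration (seconds) of the event."""
    x = np.asarray(event_signal, dtype=float)
    if x.size == 0:
        raise ValueError("empty event signal")
    return {
        "time_energy": float((x**2).sum()),
        "time_duration": x.size / sampling_rate,
    }


def fft_features(
    event_signal: np.ndarray, sampling_rate: float, argmax_peak: bool = False
) -> dict[str, float]:
    """Features of the magnitude spectrum of the event.

    ``fft_spectrum`` is the maximum absolute value of the transform,
    ``fft_psd`` the median periodogram value, ``fft_spectral_entropy``
    the Shannon entropy of the normalized PSD (maximum entropy for an
    all-zero event by convention).
    """
    x = np.asarray(event_signal, dtype=float)
    if x.size < 8:
        raise ValueError("event too short for spectral features (need >= 8 samples)")
    mag = np.abs(np.fft.rfft(x))
    psd = mag**2 / x.size
    total = psd.sum()
    if total > 0:
        p = psd / total
        nz = p[p > 0]
        spectral_entropy = float(-(nz * np.log(nz)).sum())
    else:
        spectral_entropy = math.log(psd.size)
    if argmax_peak:
        freqs = np.fft.rfftfreq(x.size, 1.0 / sampling_rate)
        peak = float(freqs[int(np.argmax(mag))])
    else:
        peak = float(mag.max() - mag.min())
    return {
        "fft_maximum": float(mag.max()),
        "fft_mean": float(mag.mean()),
        "fft_minimum": float(mag.min()),
        "fft_peak_frequency": peak,
        "fft_power": float(total),
        "fft_psd": float(np.median(psd)),
        "fft_spectral_entropy": spectral_entropy,
        "fft_spectrum": float(mag.max()),
        "fft_variance": float(mag.var()),
    }


def _subband_coeffs(
    x: np.ndarray, wavelet: str, levels: int, subbands: tuple[str, ...]
) -> dict[str, np.ndarray]:
    max_level = pywt.dwt_max_level(x.size, pywt.Wavelet(wavelet).dec_len)
    if max_level < 1:
        raise ValueError("event too short for any wavelet decomposition")
    eff = min(levels, max_level)
    if eff < levels:
        warnings.warn(
            f"signal of {x.size} samples supports only {eff} wavelet levels; reduced"
        )
    coeffs = pywt.wavedec(x, wavelet, level=eff)
    table = {f"a{eff}": coeffs[0]}
    for i, c in enumerate(coeffs[1:]):
        table[f"d{eff - i}"] = c
    out = {}
    for sb in subbands:
        # a requested deeper band falls back to the deepest computed one
        key = sb if sb in table else (f"a{eff}" if sb.startswith("a") else f"d{eff}")
        out[sb] = table[key]
    return out


def dwt_features(
    event_signal: np.ndarray,
    wavelet: str = DEFAULT_WAVELET,
    levels: int = DEFAULT_LEVELS,
    subbands: tuple[str, ...] = DEFAULT_SUBBANDS,
    kind: str = "ripple",
) -> dict[str, float]:
    """Complexity features of the wavelet sub-band coefficients.

    Per sub-band: Shannon and Renyi(2) entropies of the normalized squared
    coefficients, permutation entropy (order 3), sample entropy (m=2,
    r=0.2*SD), Kraskov KNN differential entropy (k=4), energy, SVD
    entropy, and Petrosian/Katz/Higuchi fractal dimensions.  For the
    ``fast_ripple`` and ``r_and_fr`` kinds Kraskov and Renyi are omitted.
    """
    x = np.asarray(event_signal, dtype=float)
    names = dwt_feature_set(kind)
    funcs = {
        "kraskov": lambda c: cx.kraskov_entropy(c, k=4),
        "renyi": lambda c: cx.renyi_entropy(c, order=2),
        "permutation": lambda c: cx.permutation_entropy(c, order=3, delay=1),
        "sample": lambda c: cx.sample_entropy(c, m=2),
        "shannon": cx.shannon_entropy,
        "energy": lambda c: float((c**2).sum()),
        "svd": lambda c: cx.svd_entropy(c, embedding=10),
        "pfd": cx.petrosian_fd,
        "kfd": cx.katz_fd,
        "hfd": lambda c: cx.higuchi_fd(c, k_max=10),
    }
    out: dict[str, float] = {}
    for sb, c in _subband_coeffs(x, wavelet, levels, subbands).items():
        for feat in names:
            out[f"{sb}_{feat}"] = float(funcs[feat](c))
    return out


def dwt_feature_set(kind: str) -> list[str]:
    if kind in ("fast_ripple", "r_and_fr"):
        return [f for f in DWT_FEATURE_NAMES if f not in DWT_DROP_SHORT]
    return list(DWT_FEATURE_NAMES)


def event_feature_vector(
    event_signal: np.ndarray,
    sampling_rate: float,
    kind: str,
    subbands: tuple[str, ...] = DEFAULT_SUBBANDS,
) -> dict[str, float]:
    """The full named feature map for one event of the given kind."""
    out: dict[str, float] = {}
    if kind != "spike":
        out.update(time_features(event_signal, sampling_rate))
        out.update(fft_features(event_signal, sampling_rate))
    out.update(dwt_features(event_signal, subbands=subbands, kind=kind))
    assert list(out) == feature_names(kind, subbands)
    return out


def feature_names(
    kind: str, subbands: tuple[str, ...] = DEFAULT_SUBBANDS
) -> list[str]:
    """The fixed, ordered feature-name set for an event kind."""
    names: list[str] = []
    if kind != "spike":
        names += TIME_FEATURE_NAMES + FFT_FEATURE_NAMES
    for sb in subbands:
        names += [f"{sb}_{feat}" for feat in dwt_feature_set(kind)]
    return names


def feature_manifest(
    kinds: tuple[str, ...] = ("spike", "ripple", "fast_ripple", "r_and_fr"),
    subbands: tuple[str, ...] = DEFAULT_SUBBANDS,
) -> list[dict]:
    """Provenance manifest: name, domain, sub-band and kind applicability
    of every energy feature."""
    rows = []
    for kind in kinds:
        for name in feature_names(kind, subbands):
            domain = (
                "time"
                if name.startswith("time_")
                else "fourier"
                if name.startswith("fft_")
                else "wavelet"
            )
            sb = name.split("_")[0] if domain == "wavelet" else ""
            rows.append(
                {"kind": kind, "feature": name, "domain": domain, "subband": sb}
            )
    return rows
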