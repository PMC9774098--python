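import numpy as np
import pytest

from sozloc.hfo import DetectorParams, detect_hfos
from sozloc.simulate import SimulationConfig, generate_background, inject_events

FS = 2048.0


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def tone(freq: float, duration: float, fs: float = FS, amplitude: float = 1.0):
    t = np.arange(int(duration * fs)) / fs
    return amplitude * np.sin(2 * np.pi * freq * t)


@pytest.fixture(scope="session")
def noise_channel():
    """One 1/f^2 background channel, 20 s at 2048 Hz."""
    rec = generate_background(1, 20.0, FS, exponent=2.0, seed=77, rms=15.0)
    return rec.signal[0]


@pytest.fixture(scope="session")
def hfo_simulation():
    """Seeded 10-contact, 60 s HFO simulation with its detections.

    Session-scoped because detection over the full recording is the most
    expensive fixture in the suite; several tests share it read-only.
    """
    cfg = SimulationConfig(
        n_contacts=10,
        soz_fraction=0.2,
        duration=60.0,
        seed=7,
        spike_rate_soz=0.0,
        spike_rate_nsoz=0.0,
    )
    bg = generate_background(10, cfg.duration, cfg.sampling_rate, 2.0, seed=7, rms=15.0)
    rec, gt = inject_events(bg, cfg, seed=8)
    detections = detect_hfos(rec)
    return {"recording": rec, "ground_truth": gt, "detections": detections, "config": cfg}
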