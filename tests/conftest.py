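import numpy as np
import pytest

from swblab.io_core import N_BANDS, N_CHANNELS
from swblab.spectral_features import Epoch, ParticipantFeatures

FS = 128.0
WINDOW_SAMPLES = 1281


def make_epoch(samples: np.ndarray, swb: int = 5, fs: float = FS) -> Epoch:
    """Wrap a (14, L) array as an epoch."""
    return Epoch("P1", 0, samples, swb, fs)


def sine_epoch(freqs_hz, amps=None, length=WINDOW_SAMPLES, fs=FS) -> Epoch:
    """Epoch with the same multi-sine waveform on every channel."""
    t = np.arange(length) / fs
    amps = amps if amps is not None else [1.0] * len(freqs_hz)
    wave = sum(a * np.sin(2 * np.pi * f * t) for f, a in zip(freqs_hz, amps))
    return make_epoch(np.tile(wave, (N_CHANNELS, 1)))


def make_feats(
    rp: np.ndarray,
    swb: np.ndarray,
    pid: str = "P1",
    handedness: str = "right",
    faa: np.ndarray | None = None,
    epochs=None,
) -> ParticipantFeatures:
    """Assemble a ParticipantFeatures container from raw arrays."""
    swb = np.asarray(swb, dtype=int)
    return ParticipantFeatures(
        participant_id=pid,
        handedness=handedness,
        rp=np.asarray(rp, dtype=float),
        faa=np.zeros(len(swb)) if faa is None else np.asarray(faa, dtype=float),
        swb=swb,
        epochs=epochs,
    )


def random_feats(rng: np.random.Generator, n: int = 24, pid: str = "P1") -> ParticipantFeatures:
    """Random relative-power features with duplicated rating labels."""
    raw = rng.random((n, N_BANDS, N_CHANNELS))
    rp = raw / raw.sum(axis=1, keepdims=True)
    swb = rng.integers(4, 8, size=n)  # narrow range => labels repeat
    faa = rng.normal(size=n)
    return make_feats(rp, swb, pid=pid, faa=faa)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
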