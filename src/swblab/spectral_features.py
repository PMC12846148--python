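"""Pre-report epochs, band power, relative power, and frontal alpha asymmetry.

Features are computed on the last ``window_s`` seconds of EEG before each
well-being report (default 10 s; at 128 Hz a closed window of 1281 samples).
Band power is estimated with Welch's method (2-s Hann segments, 50% overlap)
and integrated over the band with the trapezoidal rule.  Relative power
normalises the five band powers per channel so that each channel's column
sums to one; the normaliser is the sum of the five band powers rather than
total broadband power, which makes the feature independent of the device
bandwidth.  Frontal alpha asymmetry (FAA) is the natural-log alpha-power
difference between the two most frontal sensors::

    FAA = ln pow(AF4) - ln pow(AF3)

so positive values mean more right-frontal alpha power.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .exceptions import DegenerateSignalError, ParameterError
from .io_core import (
    BANDS,
    BAND_NAMES,
    CHANNELS,
    N_BANDS,
    N_CHANNELS,
    BandSpec,
    Recording,
    channel_index,
)

logger = logging.getLogger("swblab")

__all__ = [
    "Epoch",
    "RelPowerFeature",
    "FaaValue",
    "extract_epochs",
    "bandpass",
    "band_power",
    "relative_power",
    "compute_faa",
    "participant_features",
    "ParticipantFeatures",
]


@dataclass
class Epoch:
    """One pre-report window: 14 x L samples labelled with one SWB integer."""

    participant_id: str
    report_index: int
    samples: np.ndarray  # (14, L) microvolts
    swb: int
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)


@dataclass
class RelPowerFeature:
    """5-band x 14-channel relative power for one epoch; columns sum to 1."""

    participant_id: str
    report_index: int
    rp: np.ndarray  # (5, 14), entries in [0, 1]
    swb: int


@dataclass
class FaaValue:
    """Frontal alpha asymmetry for one epoch (dimensionless log-power diff)."""

    participant_id: str
    report_index: int
    faa: float
    swb: int


def extract_epochs(rec: Recording, window_s: float = 10.0) -> list[Epoch]:
    """Cut the closed pre-report window ending at each report sample.

    The window holds ``round(window_s * fs) + 1`` samples (both endpoints
    included), i.e. 1281 samples for 10 s at 128 Hz.  Reports earlier than
    ``window_s`` into the recording are skipped with a logged warning.
    """
    if not window_s > 0:
        raise ParameterError("window_s must be positive")
    length = int(round(window_s * rec.fs)) + 1
    n_total = rec.samples.shape[1]
    epochs: list[Epoch] = []
    for i, (t, label) in enumerate(zip(rec.report_times, rec.swb)):
        end = int(round(t * rec.fs))
        start = end - length + 1
        if start < 0 or end >= n_total:
            logger.warning(
                "participant %s: report %d at t=%.1f s skipped "
                "(window does not fit the recording)",
                rec.participant_id, i, t,
            )
            continue
        epochs.append(
            Epoch(rec.participant_id, i, rec.samples[:, start : end + 1], int(label), rec.fs)
        )
    return epochs


def bandpass(x: np.ndarray, band: BandSpec, fs: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    Forward-backward filtering preserves epoch alignment; output length
    equals input length.
    """
    if not fs > 2 * band.hi:
        raise ParameterError(
            f"fs={fs} too low to band-pass {band.name} ({band.lo}-{band.hi} Hz)"
        )
    sos = sps.butter(order, [band.lo, band.hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def _welch_psd(x: np.ndarray, fs: float, segment_s: float = 2.0):
    nperseg = int(round(segment_s * fs))
    if x.shape[-1] < nperseg:
        raise ParameterError(
            f"signal of {x.shape[-1]} samples shorter than one "
            f"{segment_s:g}-s Welch segment ({nperseg} samples)"
        )
    return sps.welch(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2, axis=-1
    )


def _integrate_band(freqs: np.ndarray, psd: np.ndarray, band: BandSpec, fs: float):
    hi = min(band.hi, fs / 2)
    if band.hi > fs / 2:
        logger.debug(
            "band %s truncated at Nyquist: integrating %g-%g Hz", band.name, band.lo, hi
        )
    mask = (freqs >= band.lo) & (freqs <= hi)
    return np.trapezoid(psd[..., mask], freqs[mask], axis=-1)


def band_power(x: np.ndarray, band: BandSpec, fs: float, segment_s: float = 2.0) -> np.ndarray:
    """Welch band power (signal units squared), integrated over ``band``.

    Accepts 1-D signals or stacked signals along the last axis.  Bands
    extending past Nyquist are integrated up to ``fs/2``.
    """
    freqs, psd = _welch_psd(np.asarray(x, dtype=float), fs, segment_s)
    return _integrate_band(freqs, psd, band, fs)


def relative_power(epoch: Epoch, segment_s: float = 2.0) -> RelPowerFeature:
    """Per-channel relative power of the five canonical bands.

    ``rp[b, c] = P_b(c) / sum_b' P_b'(c)``; each channel column sums to 1.
    """
    freqs, psd = _welch_psd(epoch.samples, epoch.fs, segment_s)  # (14, nf)
    bp = np.stack([_integrate_band(freqs, psd, b, epoch.fs) for b in BANDS])  # (5, 14)
    totals = bp.sum(axis=0)
    dead = np.flatnonzero(totals <= 0)
    if dead.size:
        raise DegenerateSignalError(
            f"no band power on channel(s): {', '.join(CHANNELS[i] for i in dead)}"
        )
    return RelPowerFeature(epoch.participant_id, epoch.report_index, bp / totals, epoch.swb)


def compute_faa(epoch: Epoch, segment_s: float = 2.0) -> FaaValue:
    """Frontal alpha asymmetry ``ln pow(AF4) - ln pow(AF3)``.

    Alpha power is the Welch band power of the alpha-filtered signal, one
    value per epoch.  Antisymmetric under swapping the two channels and
    invariant to common positive scaling.
    """
    alpha = next(b for b in BANDS if b.name == "alpha")
    i_left, i_right = channel_index("AF3"), channel_index("AF4")
    filt = bandpass(epoch.samples[[i_left, i_right]], alpha, epoch.fs)
    p_left, p_right = band_power(filt, alpha, epoch.fs, segment_s)
    if p_left <= 0 or p_right <= 0:
        raise DegenerateSignalError("zero alpha power on AF3 or AF4")
    return FaaValue(
        epoch.participant_id,
        epoch.report_index,
        float(np.log(p_right) - np.log(p_left)),
        epoch.swb,
    )


@dataclass
class ParticipantFeatures:
    """All per-epoch features of one participant, stacked as arrays.

    ``rp`` has shape (n_epochs, 5, 14); ``faa`` and ``swb`` have length
    n_epochs.  ``epochs`` is retained only when time-series methods need the
    raw windows.
    """

    participant_id: str
    handedness: str
    rp: np.ndarray
    faa: np.ndarray
    swb: np.ndarray
    epochs: list[Epoch] | None = None

    @property
    def n_epochs(self) -> int:
        return len(self.swb)


def participant_features(
    rec: Recording,
    window_s: float = 10.0,
    keep_epochs: bool = False,
    compute_faa_values: bool = True,
) -> ParticipantFeatures:
    """Extract epochs and compute relative power (and FAA) for one recording."""
    epochs = extract_epochs(rec, window_s)
    rp = np.stack([relative_power(e).rp for e in epochs]) if epochs else np.empty((0, N_BANDS, N_CHANNELS))
    if compute_faa_values:
        faa = np.array([compute_faa(e).faa for e in epochs])
    else:
        faa = np.full(len(epochs), np.nan)
    swb = np.array([e.swb for e in epochs], dtype=int)
    return ParticipantFeatures(
        participant_id=rec.participant_id,
        handedness=rec.handedness,
        rp=rp,
        faa=faa,
        swb=swb,
        epochs=epochs if keep_epochs else None,
    )


def features_to_frame(feats: list[ParticipantFeatures]):
    """Long-format DataFrame (participant, report_index, band, channel, rp, swb)."""
    import pandas as pd

    rows = []
    for f in feats:
        for i in range(f.n_epochs):
            for bi, bname in enumerate(BAND_NAMES):
                for ci, ch in enumerate(CHANNELS):
                    rows.append(
                        (f.participant_id, i, bname, ch, f.rp[i, bi, ci], int(f.swb[i]))
                    )
    return pd.DataFrame(
        rows, columns=["participant", "report_index", "band", "channel", "rp", "swb"]
    )
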