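"""Recordings, report tables, matrices, and analysis configuration.

The package analyses 14-channel consumer-grade EEG (10-20 labels, 128 Hz by
default) recorded while a participant reports a subjective well-being (SWB)
rating — an integer from 1 (most uncomfortable) to 10 (most comfortable) —
roughly every 30 seconds.  This module holds the canonical channel order and
frequency-band table, the :class:`Recording` container, CSV/EDF readers, the
square-matrix writer used for transfer-distance matrices, and the YAML
configuration loader.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import (
    ConfigError,
    DimensionError,
    FormatError,
    ValidationError,
)

logger = logging.getLogger("swblab")

#: Canonical channel order; every matrix in the package is indexed by it.
CHANNELS: tuple[str, ...] = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

LEFT_CHANNELS = frozenset({"AF3", "F7", "F3", "FC5", "T7", "P7", "O1"})
RIGHT_CHANNELS = frozenset({"O2", "P8", "T8", "FC6", "F4", "F8", "AF4"})

N_CHANNELS = len(CHANNELS)

SWB_MIN, SWB_MAX = 1, 10


@dataclass(frozen=True)
class BandSpec:
    """A frequency band: half-open limits in Hz, ``lo < hi``."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValidationError(f"band {self.name}: lo must be < hi")


#: Canonical five-band table (Hz).
BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 0.5, 3.0),
    BandSpec("theta", 4.0, 7.0),
    BandSpec("alpha", 8.0, 13.0),
    BandSpec("beta", 14.0, 30.0),
    BandSpec("gamma", 31.0, 55.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in BANDS)
N_BANDS = len(BANDS)

_BAND_BY_NAME = {b.name: b for b in BANDS}


def band(name: str) -> BandSpec:
    """Return the canonical :class:`BandSpec` for ``name``."""
    try:
        return _BAND_BY_NAME[name]
    except KeyError:
        raise ValidationError(f"unknown band name: {name!r}") from None


def channel_index(label: str) -> int:
    """Index of ``label`` in the canonical channel order."""
    try:
        return CHANNELS.index(label)
    except ValueError:
        raise ValidationError(f"unknown channel label: {label!r}") from None


@dataclass
class Recording:
    """One participant's EEG plus time-stamped SWB reports.

    Parameters
    ----------
    participant_id : str
    samples : ndarray, shape (14, n_samples)
        EEG in microvolts, rows in canonical channel order.
    fs : float
        Sampling rate in Hz.
    report_times : ndarray
        Report times in seconds from recording start, strictly increasing.
    swb : ndarray
        Integer well-being reports in 1..10, one per report time.
    handedness : str
        ``"left"`` or ``"right"``; stored for stratified reporting only and
        never used to alter any computation.
    """

    participant_id: str
    samples: np.ndarray
    fs: float
    report_times: np.ndarray
    swb: np.ndarray
    handedness: str = "right"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.report_times = np.asarray(self.report_times, dtype=float)
        self.swb = np.asarray(self.swb)
        if self.samples.ndim != 2 or self.samples.shape[0] != N_CHANNELS:
            raise DimensionError(
                f"samples must be ({N_CHANNELS}, n); got {self.samples.shape}"
            )
        if not self.fs > 0:
            raise ValidationError("fs must be positive")
        if len(self.report_times) != len(self.swb):
            raise DimensionError("report_times and swb lengths differ")
        if np.any(np.diff(self.report_times) <= 0):
            raise ValidationError("report times must be strictly increasing")
        if not np.all(self.swb == np.round(self.swb)):
            raise ValidationError("swb values must be integers")
        self.swb = self.swb.astype(int)
        if np.any((self.swb < SWB_MIN) | (self.swb > SWB_MAX)):
            bad = self.swb[(self.swb < SWB_MIN) | (self.swb > SWB_MAX)]
            raise ValidationError(f"swb values out of range 1..10: {bad.tolist()}")
        if self.handedness not in ("left", "right"):
            raise ValidationError("handedness must be 'left' or 'right'")

    @property
    def n_reports(self) -> int:
        return len(self.swb)

    @property
    def duration_s(self) -> float:
        return (self.samples.shape[1] - 1) / self.fs


def _read_reports(reports_path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    tab = pd.read_csv(reports_path)
    for col in ("time_s", "swb"):
        if col not in tab.columns:
            raise FormatError(f"reports file missing column {col!r}")
    return tab["time_s"].to_numpy(float), tab["swb"].to_numpy()


def _read_wide_csv(eeg_path: Path, fs: float | None) -> tuple[np.ndarray, float]:
    """Wide CSV: one column per channel, header = channel labels.

    An optional first metadata line ``# fs=<rate>`` carries the sampling
    rate; otherwise ``fs`` must be passed explicitly.
    """
    with open(eeg_path) as fh:
        first = fh.readline().strip()
    skiprows = 0
    if first.startswith("#"):
        skiprows = 1
        meta = first.lstrip("#").strip()
        if meta.startswith("fs="):
            fs = float(meta[3:])
    if fs is None:
        raise FormatError("sampling rate not given: pass fs= or add a '# fs=' line")
    tab = pd.read_csv(eeg_path, skiprows=skiprows)
    cols = list(tab.columns)
    missing = [c for c in CHANNELS if c not in cols]
    if missing:
        raise FormatError(f"EEG file missing channel column(s): {', '.join(missing)}")
    extra = [c for c in cols if c not in CHANNELS]
    if extra:
        raise FormatError(f"EEG file has unknown column(s): {', '.join(extra)}")
    samples = tab[list(CHANNELS)].to_numpy(float).T  # reorder to canonical
    return samples, fs


def _read_edf(eeg_path: Path) -> tuple[np.ndarray, float]:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise FormatError("EDF support requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(eeg_path, preload=True, verbose="error")
    present = set(raw.ch_names)
    missing = [c for c in CHANNELS if c not in present]
    if missing:
        raise FormatError(f"EDF file missing channel(s): {', '.join(missing)}")
    raw.pick(list(CHANNELS))
    raw.reorder_channels(list(CHANNELS))
    return raw.get_data() * 1e6, float(raw.info["sfreq"])  # volts -> microvolts


def read_recording(
    eeg_path: str | Path,
    reports_path: str | Path,
    *,
    participant_id: str | None = None,
    fs: float | None = None,
    handedness: str = "right",
) -> Recording:
    """Read one participant's EEG (wide CSV or EDF) and SWB report table.

    Channels are reordered to the canonical order; reports are validated
    (integer SWB in 1..10, strictly increasing times).
    """
    eeg_path = Path(eeg_path)
    if eeg_path.suffix.lower() == ".edf":
        samples, fs = _read_edf(eeg_path)
    else:
        samples, fs = _read_wide_csv(eeg_path, fs)
    times, swb = _read_reports(reports_path)
    pid = participant_id if participant_id is not None else eeg_path.stem
    return Recording(
        participant_id=pid,
        samples=samples,
        fs=fs,
        report_times=times,
        swb=swb,
        handedness=handedness,
    )


def write_recording(rec: Recording, eeg_path: str | Path, reports_path: str | Path) -> None:
    """Write a recording as wide CSV (with ``# fs=`` line) plus reports CSV."""
    eeg_path, reports_path = Path(eeg_path), Path(reports_path)
    with open(eeg_path, "w") as fh:
        fh.write(f"# fs={rec.fs:g}\n")
        pd.DataFrame(rec.samples.T, columns=list(CHANNELS)).to_csv(fh, index=False)
    pd.DataFrame({"time_s": rec.report_times, "swb": rec.swb}).to_csv(
        reports_path, index=False
    )


def write_matrix(ids: Sequence[str], M: np.ndarray, path: str | Path) -> None:
    """Write a square matrix as CSV with id header row and column.

    Round-trips bit-identically through :func:`read_matrix` (pandas writes
    shortest round-trip float representations).
    """
    ids = list(ids)
    if not ids:
        raise ValidationError("empty id list")
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise DimensionError(f"matrix must be square; got shape {M.shape}")
    if M.shape[0] != len(ids):
        raise DimensionError(f"{len(ids)} ids but matrix is {M.shape[0]}x{M.shape[1]}")
    pd.DataFrame(M, index=ids, columns=ids).to_csv(path)


def read_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a square CSV matrix written by :func:`write_matrix`."""
    tab = pd.read_csv(path, index_col=0, float_precision="round_trip")
    ids = [str(i) for i in tab.index]
    if [str(c) for c in tab.columns] != ids:
        raise FormatError("matrix row and column ids differ")
    return ids, tab.to_numpy(float)


@dataclass
class AnalysisConfig:
    """Tunable analysis parameters with their defaults.

    ``window_s`` is the pre-report feature window (seconds); ``knn_k`` the
    neighbour count for the nearest-neighbour classifier (k = 1 because the
    report distributions are heavily imbalanced); ``smote_seeds`` the RNG
    seeds over which SMOTE-balanced regression slopes are averaged;
    ``fdr_q`` the Benjamini-Hochberg level; ``cluster_ks`` the candidate
    cluster counts; ``min_epochs`` the usability floor for a participant to
    enter the cross-participant analysis.
    """

    window_s: float = 10.0
    knn_k: int = 1
    smote_k: int = 5
    smote_seeds: tuple[int, ...] = tuple(range(1, 11))
    fdr_q: float = 0.05
    cluster_ks: tuple[int, ...] = (2, 3, 4, 5, 6)
    isomap_neighbors: int = 1
    embed_dims: int = 2
    min_epochs: int = 20
    kmeans_restarts: int = 50
    master_seed: int = 0
    include_left_handed: bool = False

    def __post_init__(self) -> None:
        if not self.window_s > 0:
            raise ConfigError("window_s must be positive")
        if self.knn_k < 1:
            raise ConfigError("knn_k must be >= 1")
        if not 0 < self.fdr_q < 1:
            raise ConfigError("fdr_q must be in (0, 1)")
        self.cluster_ks = tuple(int(k) for k in self.cluster_ks)
        if any(k < 2 for k in self.cluster_ks):
            raise ConfigError("all cluster_ks must be >= 2")
        self.smote_seeds = tuple(int(s) for s in self.smote_seeds)
        if self.smote_k < 1:
            raise ConfigError("smote_k must be >= 1")
        if self.min_epochs < 0:
            raise ConfigError("min_epochs must be >= 0")


def load_config(path: str | Path | None = None) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML key/value file.

    Unknown keys are rejected; omitted keys take their defaults.  ``None``
    or an empty file yields the all-defaults configuration.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config file must hold a key/value mapping")
        raw = loaded
    known = {f.name for f in fields(AnalysisConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    try:
        cfg = AnalysisConfig(**raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    logger.info("resolved config: %s", cfg)
    return cfg
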