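"""Comfort-coupled synthetic EEG cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a slowly drifting latent comfort level drives both the verbal
well-being reports and the amplitude of band-limited EEG activity.

Model
-----
* The latent comfort ``z(t)`` is a standardized Ornstein-Uhlenbeck process
  sampled on the report grid (one value per report interval): mean-reverting
  and smooth on the minutes scale, so consecutive 10-s windows see nearly
  constant comfort.
* Reports are a monotone squashing of ``z`` onto the integer scale 1..10:
  a sigmoidal compression (strength ``report_bias``) followed by an affine
  map centred at 5.5 and round-half-up.  Larger ``report_bias`` concentrates
  reports on the middle of the scale, reproducing the mid-heavy histograms
  typical of comfort self-reports.
* EEG per channel is a sum over the five canonical bands of unit-variance
  band-limited Gaussian noise whose amplitude is modulated by comfort::

      x_c(t) = sum_b base_amp[b] * (1 + beta[b, c] * z(t)) * n_{b,c}(t) + noise

  ``beta`` (the coupling matrix, |beta| < 1) is the planted ground truth the
  analysis tries to recover: the sign and size of the comfort-to-band-power
  coupling per band and channel.  Band noise is drawn independently per
  channel and synthesized spectrally (complex Gaussian coefficients on the
  band's frequency bins — an ideal band-pass of white noise — scaled so the
  expected time-domain variance is one).  Because the comfort gain is
  constant within a report interval, noise is generated per interval and is
  independent across intervals; the feature window is the last 10 s of an
  interval, so it never straddles an interval boundary.
* A cohort consists of ``n_clusters`` participant subgroups sharing a
  cluster-level coupling matrix, with 10% relative Gaussian jitter per
  participant for within-cluster individuality.

What the generator deliberately does not emulate: eye-blink/EMG artifacts,
volume conduction, 1/f background shape, or non-stationary electrode drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError, ValidationError
from .io_core import BANDS, N_BANDS, N_CHANNELS, Recording

__all__ = [
    "CouplingSpec",
    "CohortSpec",
    "GroundTruth",
    "simulate_latent",
    "latent_to_swb",
    "synthesize_eeg",
    "generate_cohort",
    "uniform_coupling",
]

#: Baseline band amplitudes (microvolts): low-frequency-dominant resting EEG.
DEFAULT_BASE_AMP = np.array([20.0, 10.0, 15.0, 5.0, 3.0])


@dataclass
class CouplingSpec:
    """Coupling of band amplitudes to latent comfort.

    ``beta`` is 5 x 14 (band x channel), dimensionless amplitude-modulation
    slopes with ``|beta| < 1`` so that amplitudes stay positive;
    ``base_amp`` the baseline band amplitudes in microvolts; ``noise_sd``
    the broadband sensor-noise amplitude in microvolts.
    """

    beta: np.ndarray
    base_amp: np.ndarray = field(default_factory=lambda: DEFAULT_BASE_AMP.copy())
    noise_sd: float = 2.0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.base_amp = np.asarray(self.base_amp, dtype=float)
        if self.beta.shape != (N_BANDS, N_CHANNELS):
            raise ParameterError(f"beta must be {N_BANDS}x{N_CHANNELS}; got {self.beta.shape}")
        if np.any(np.abs(self.beta) >= 1):
            raise ParameterError("|beta| must be < 1 (amplitude stays positive)")
        if self.base_amp.shape != (N_BANDS,) or np.any(self.base_amp <= 0):
            raise ParameterError("base_amp must be 5 strictly positive values")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


def uniform_coupling(
    band_name: str | None = None,
    strength: float = 0.0,
    **kwargs,
) -> CouplingSpec:
    """Convenience constructor: one band coupled at ``strength`` everywhere.

    ``band_name=None`` with ``strength=0`` gives the null (uncoupled) spec.
    """
    beta = np.zeros((N_BANDS, N_CHANNELS))
    if band_name is not None:
        idx = [b.name for b in BANDS].index(band_name)
        beta[idx, :] = strength
    return CouplingSpec(beta=beta, **kwargs)


@dataclass
class CohortSpec:
    """Study-design parameters for one synthetic cohort.

    Defaults mirror the study conditions: reports every 30 s, 128 Hz EEG,
    9-minute sessions (18 reports), and a comfort process with a 120-s
    relaxation time so that comfort drifts slowly relative to the 10-s
    feature window.
    """

    n_clusters: int
    participants_per_cluster: int
    cluster_couplings: list[CouplingSpec]
    session_length_s: float = 540.0
    report_interval_s: float = 30.0
    fs: float = 128.0
    latent_tau: float = 120.0
    report_bias: float = 0.6
    beta_jitter: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cluster_couplings) != self.n_clusters:
            raise ValidationError("need one CouplingSpec per cluster")
        if self.report_interval_s <= 0 or self.session_length_s <= 0:
            raise ParameterError("session and report interval must be positive")
        if self.n_clusters < 1 or self.participants_per_cluster < 1:
            raise ParameterError("cluster counts must be >= 1")


@dataclass
class GroundTruth:
    """Planted per-participant truth, the oracle for recovery tests."""

    participant_ids: list[str]
    cluster_labels: np.ndarray  # int, in 0..n_clusters-1
    betas: list[np.ndarray]  # one (5, 14) matrix per participant
    latents: list[np.ndarray]  # latent comfort at report resolution


def simulate_latent(
    length_s: float,
    fs_report: float,
    tau: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Standardized Ornstein-Uhlenbeck comfort path at report resolution.

    Exact discretization: ``z[t+1] = phi z[t] + sqrt(1 - phi^2) eps`` with
    ``phi = exp(-dt / tau)`` and ``z[0] ~ N(0, 1)``, so the marginal is
    stationary N(0, 1) and the lag-one autocorrelation is ``exp(-dt/tau)``.
    ``tau = inf`` is the degenerate constant path.
    """
    if not tau > 0:
        raise ParameterError("tau must be positive")
    if not (length_s > 0 and fs_report > 0):
        raise ParameterError("length_s and fs_report must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(length_s * fs_report))
    dt = 1.0 / fs_report
    phi = np.exp(-dt / tau) if np.isfinite(tau) else 1.0
    innov_sd = np.sqrt(max(0.0, 1.0 - phi * phi))
    z = np.empty(n)
    z[0] = rng.standard_normal()
    eps = rng.standard_normal(n - 1)
    for t in range(1, n):
        z[t] = phi * z[t - 1] + innov_sd * eps[t - 1]
    return z


def latent_to_swb(z: np.ndarray, report_bias: float = 0.6) -> np.ndarray:
    """Map latent comfort to integer reports 1..10.

    The squash ``u = tanh(b z) / b`` (identity at ``b = 0``) compresses
    extreme comfort, then ``5.5 + 1.5 u`` is rounded half-up and clipped to
    the scale.  Monotone in ``z``; ``z = 0`` maps to 6.
    """
    if report_bias < 0:
        raise ParameterError("report_bias must be >= 0")
    z = np.asarray(z, dtype=float)
    u = z if report_bias == 0 else np.tanh(report_bias * z) / report_bias
    raw = 5.5 + 1.5 * u
    return np.clip(np.floor(raw + 0.5), 1, 10).astype(int)


def _band_bins(seg_len: int, fs: float) -> list[np.ndarray]:
    """Frequency-bin index arrays of the five bands for one segment length."""
    freqs = np.fft.rfftfreq(seg_len, 1.0 / fs)
    return [np.flatnonzero((freqs >= b.lo) & (freqs <= b.hi)) for b in BANDS]


def synthesize_eeg(
    z: np.ndarray,
    coupling: CouplingSpec,
    session_length_s: float,
    fs: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Synthesize 14-channel EEG whose band amplitudes track comfort.

    One report interval per entry of ``z``; within an interval each band is
    band-limited Gaussian noise with standard deviation
    ``base_amp[b] * (1 + beta[b, c] * z_i)``, built from complex Gaussian
    spectral coefficients on the band's bins (scaled so the expected
    time-domain variance matches), plus broadband Gaussian sensor noise.
    Returns a (14, round(session_length_s * fs) + 1) array in microvolts —
    one extra trailing sample (a copy of its predecessor) so a report at
    the session end has a full closed window.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = np.asarray(z, dtype=float)
    n_rep = len(z)
    n = int(round(session_length_s * fs)) + 1
    seg_len = (n - 1) // n_rep
    if seg_len < 2 or (n - 1) % n_rep:
        raise ParameterError("session length must be a whole number of report intervals")
    n_bins = seg_len // 2 + 1
    bins = _band_bins(seg_len, fs)
    # spectral amplitudes: sigma = amp * L / (2 sqrt(m)) gives E[var(x)] = amp^2
    coef = np.zeros((N_CHANNELS, n_rep, n_bins), dtype=complex)
    for bi in range(N_BANDS):
        m = len(bins[bi])
        if m == 0:
            continue
        amp = coupling.base_amp[bi] * (1.0 + coupling.beta[bi][:, None] * z[None, :])
        sigma = amp * seg_len / (2.0 * np.sqrt(m))  # (14, n_rep)
        noise = rng.standard_normal((N_CHANNELS, n_rep, m, 2))
        coef[:, :, bins[bi]] = sigma[:, :, None] * (noise[..., 0] + 1j * noise[..., 1])
    segments = np.fft.irfft(coef, seg_len, axis=-1)  # (14, n_rep, seg_len)
    samples = np.empty((N_CHANNELS, n))
    samples[:, : n - 1] = segments.reshape(N_CHANNELS, n - 1)
    samples[:, -1] = samples[:, -2]
    if coupling.noise_sd > 0:
        samples += coupling.noise_sd * rng.standard_normal((N_CHANNELS, n))
    return samples


def generate_cohort(spec: CohortSpec) -> tuple[list[Recording], GroundTruth]:
    """Generate the cohort: recordings plus planted ground truth.

    Participants are ordered cluster-major (all of cluster 0 first).  Each
    participant gets an independent latent path and noise but the cluster's
    coupling matrix plus per-participant jitter (Gaussian, SD =
    ``beta_jitter`` times the cluster beta, re-clipped to |beta| < 1).
    """
    rng = np.random.default_rng(spec.seed)
    n_reports = int(spec.session_length_s // spec.report_interval_s)
    if n_reports < 1:
        raise ParameterError("session too short for a single report")
    report_times = spec.report_interval_s * np.arange(1, n_reports + 1)

    recordings: list[Recording] = []
    ids: list[str] = []
    labels: list[int] = []
    betas: list[np.ndarray] = []
    latents: list[np.ndarray] = []
    n_total = spec.n_clusters * spec.participants_per_cluster
    width = max(2, len(str(n_total)))
    p = 0
    for ci in range(spec.n_clusters):
        base = spec.cluster_couplings[ci]
        for _ in range(spec.participants_per_cluster):
            p += 1
            pid = f"S{p:0{width}d}"
            beta_p = base.beta + spec.beta_jitter * np.abs(base.beta) * rng.standard_normal(
                base.beta.shape
            )
            beta_p = np.clip(beta_p, -0.999, 0.999)
            coupling_p = CouplingSpec(
                beta=beta_p, base_amp=base.base_amp.copy(), noise_sd=base.noise_sd
            )
            z = simulate_latent(
                n_reports * spec.report_interval_s,
                1.0 / spec.report_interval_s,
                spec.latent_tau,
                rng,
            )
            swb = latent_to_swb(z, spec.report_bias)
            samples = synthesize_eeg(
                z, coupling_p, n_reports * spec.report_interval_s, spec.fs, rng
            )
            recordings.append(
                Recording(
                    participant_id=pid,
                    samples=samples,
                    fs=spec.fs,
                    report_times=report_times.copy(),
                    swb=swb,
                )
            )
            ids.append(pid)
            labels.append(ci)
            betas.append(beta_p)
            latents.append(z)
    truth = GroundTruth(ids, np.array(labels, dtype=int), betas, latents)
    return recordings, truth
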