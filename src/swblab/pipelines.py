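"""End-to-end study pipelines on synthetic cohorts.

These drivers wire the modules together the way the analysis is meant to be
run — generate a cohort, extract features, fit per-participant models, and
score recovery against the planted ground truth.  They are used by the test
suite and the reproduction script, and are the quickest way to exercise the
whole package programmatically.
"""

from __future__ import annotations

import numpy as np

from .cluster_consistency import adjusted_rand, isomap_embed, kmeans_partition
from .cross_subject_distance import build_distance_matrix
from .io_core import AnalysisConfig, Recording
from .regression_swb import group_slope_test, participant_mean_slope
from .spectral_features import ParticipantFeatures, participant_features
from .synthetic_cohort import CohortSpec, generate_cohort, uniform_coupling

__all__ = [
    "cohort_features",
    "null_rejection_rate",
    "slope_sign_recovery",
    "cluster_recovery_rate",
    "ClusterRecoveryResult",
]


from dataclasses import dataclass


@dataclass
class ClusterRecoveryResult:
    """Outcome of the planted two-cluster recovery experiment."""

    recovery_rate: float  # fraction of runs with ARI >= threshold
    aris: list[float]
    within_less_than_between_frac: float


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """n reproducible sub-seeds below 2**31 derived from one master seed."""
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def cohort_features(
    recordings: list[Recording],
    window_s: float = 10.0,
    keep_epochs: bool = False,
    compute_faa_values: bool = True,
) -> list[ParticipantFeatures]:
    """Extract per-participant features for a whole cohort."""
    return [
        participant_features(
            rec, window_s, keep_epochs=keep_epochs, compute_faa_values=compute_faa_values
        )
        for rec in recordings
    ]


def null_rejection_rate(
    n_cohorts: int = 200,
    seed: int = 0,
    n_participants: int = 6,
    n_reports: int = 18,
    combos: tuple[tuple[str, str], ...] = (
        ("delta", "AF3"),
        ("theta", "P7"),
        ("alpha", "T7"),
        ("beta", "F4"),
        ("gamma", "O2"),
    ),
    alpha: float = 0.05,
) -> float:
    """Group-test rejection rate on uncoupled (beta = 0) cohorts.

    With no comfort-to-EEG coupling the per-participant regression slopes
    are pure noise centred on zero, so the group t-test should reject at
    about the nominal level.  Participants without at least two repeated
    rating values are excluded, as constant reporters are in the real
    analysis.  Returns the fraction of (cohort, feature) tests with
    uncorrected p < ``alpha``.
    """
    from .exceptions import EmptyDatasetError
    from .io_core import BAND_NAMES, channel_index

    seeds = _child_seeds(seed, n_cohorts)
    cfg = AnalysisConfig()
    n_reject = 0
    n_tests = 0
    for s in seeds:
        spec = CohortSpec(
            n_clusters=1,
            participants_per_cluster=n_participants,
            cluster_couplings=[uniform_coupling()],
            session_length_s=n_reports * 30.0,
            seed=int(s),
        )
        recordings, _ = generate_cohort(spec)
        feats = cohort_features(recordings, compute_faa_values=False)
        for bname, ch in combos:
            slopes = []
            for f in feats:
                try:
                    slopes.append(
                        participant_mean_slope(
                            f.rp[:, BAND_NAMES.index(bname), channel_index(ch)],
                            f.swb,
                            cfg.smote_k,
                            cfg.smote_seeds,
                        )
                    )
                except EmptyDatasetError:
                    continue
            if len(slopes) < 3:
                continue
            stat = group_slope_test(np.array(slopes), band=bname, channel=ch)
            n_tests += 1
            n_reject += stat.p < alpha
    return n_reject / n_tests


def slope_sign_recovery(
    n_runs: int = 100,
    seed: int = 0,
    band_name: str = "gamma",
    channel: str = "AF3",
    strength: float = 0.5,
    n_reports: int = 60,
) -> float:
    """Fraction of runs whose recovered mean slope matches the planted sign.

    One strongly coupled participant per run (|beta| = ``strength`` on one
    band at every channel, at least ``n_reports`` reports); the per-
    participant SMOTE-averaged slope for the coupled band/channel should
    recover the coupling sign.
    """
    from .io_core import BAND_NAMES, channel_index

    seeds = _child_seeds(seed, n_runs)
    cfg = AnalysisConfig()
    hits = 0
    for s in seeds:
        spec = CohortSpec(
            n_clusters=1,
            participants_per_cluster=1,
            cluster_couplings=[uniform_coupling(band_name, strength)],
            session_length_s=n_reports * 30.0,
            seed=int(s),
        )
        recordings, truth = generate_cohort(spec)
        feats = participant_features(recordings[0], compute_faa_values=False)
        slope = participant_mean_slope(
            feats.rp[:, BAND_NAMES.index(band_name), channel_index(channel)],
            feats.swb,
            cfg.smote_k,
            cfg.smote_seeds,
        )
        planted = truth.betas[0][BAND_NAMES.index(band_name), channel_index(channel)]
        hits += np.sign(slope) == np.sign(planted)
    return hits / n_runs


def cluster_recovery_rate(
    n_runs: int = 50,
    seed: int = 0,
    participants_per_cluster: int = 5,
    n_reports: int = 30,
    strength: float = 0.5,
    band_name: str = "gamma",
    channel: str = "AF3",
    ari_threshold: float = 0.8,
) -> "ClusterRecoveryResult":
    """Planted two-cluster recovery through the full transfer pipeline.

    Two subgroups with opposite-sign coupling on one band; per-participant
    regression models on the coupled feature are transferred across the
    cohort, the min-symmetrised distance matrix is embedded with Isomap
    (1 neighbour) and partitioned with k-means at k = 2, and the partition
    is scored against the planted labels with the adjusted Rand index.
    Also records, per run, whether the mean within-cluster symmetrised
    distance is smaller than the mean between-cluster distance.
    """
    seeds = _child_seeds(seed, n_runs)
    cfg = AnalysisConfig(min_epochs=10)
    aris: list[float] = []
    within_less: list[bool] = []
    for s in seeds:
        spec = CohortSpec(
            n_clusters=2,
            participants_per_cluster=participants_per_cluster,
            cluster_couplings=[
                uniform_coupling(band_name, strength),
                uniform_coupling(band_name, -strength),
            ],
            session_length_s=n_reports * 30.0,
            seed=int(s),
        )
        recordings, truth = generate_cohort(spec)
        feats = cohort_features(recordings, compute_faa_values=False)
        dm = build_distance_matrix(
            feats, "rp_linreg_fixed", cfg, band=band_name, channel=channel
        )
        emb = isomap_embed(dm.D_sym, n_neighbors=1, ids=dm.ids)
        labels = kmeans_partition(emb.coords, 2, restarts=cfg.kmeans_restarts, seed=int(s))
        planted = np.array(
            [truth.cluster_labels[truth.participant_ids.index(i)] for i in dm.ids]
        )
        aris.append(adjusted_rand(labels, planted))
        same = planted[:, None] == planted[None, :]
        off_diag = ~np.eye(len(planted), dtype=bool)
        within = dm.D_sym[same & off_diag].mean()
        between = dm.D_sym[~same].mean()
        within_less.append(bool(within < between))
    aris_arr = np.array(aris)
    return ClusterRecoveryResult(
        recovery_rate=float(np.mean(aris_arr >= ari_threshold)),
        aris=aris,
        within_less_than_between_frac=float(np.mean(within_less)),
    )
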