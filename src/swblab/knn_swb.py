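"""1-NN leave-one-out well-being prediction and the count-level tests.

A participant's reports are predicted from relative-power features or from
band-filtered time series with a nearest-neighbour classifier (k = 1, since
the report distributions are heavily imbalanced and more neighbours would
swamp rare ratings).  Three input schemes are evaluated:

1. one relative-power value (one band at one channel),
2. one band at all 14 channels (14 values),
3. all five bands at all channels (70 values),

and analogously for filtered time series.  Performance is scored with the
mean squared error between true and predicted integer ratings, which — unlike
accuracy — penalises distant misclassifications more than near ones.  Ratings
reported only once are removed first (a leave-one-out split could never
predict them).  Winner tallies over bands are tested against uniformity with
a chi-squared goodness-of-fit test (with standardized Pearson residuals) and
an exact binomial test on the most frequent winner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist

from .exceptions import (
    DegenerateSignalError,
    DimensionError,
    EmptyDatasetError,
    ParameterError,
    ValidationError,
)
from .io_core import BAND_NAMES, CHANNELS, band, channel_index
from .spectral_features import Epoch, ParticipantFeatures, bandpass

__all__ = [
    "LabeledInstance",
    "KnnEvaluation",
    "CountTestResult",
    "drop_singleton_labels",
    "loo_1nn",
    "mse",
    "dtw_distance",
    "evaluate_scheme",
    "best_combination",
    "rescale_mse",
    "chi_squared_gof",
    "binomial_winner_test",
]


@dataclass
class LabeledInstance:
    """One feature vector or time-series stack labelled with one SWB value."""

    participant_id: str
    report_index: int
    x: np.ndarray
    swb: int


@dataclass
class KnnEvaluation:
    """LOO 1-NN result for one participant and one input scheme."""

    participant_id: str
    scheme: int
    band: str | None
    channel: str | None
    mse: float
    predictions: list[tuple[int, int]]
    n_used: int


@dataclass
class CountTestResult:
    """Chi-squared goodness-of-fit of winner tallies against uniformity."""

    counts: np.ndarray
    chi2: float
    df: int
    p: float
    residuals: np.ndarray  # standardized Pearson residuals (O-E)/sqrt(E)
    binom_p: float | None = None


def drop_singleton_labels(instances: list[LabeledInstance]) -> list[LabeledInstance]:
    """Remove every instance whose label occurs exactly once; order preserved."""
    if not instances:
        raise EmptyDatasetError("no instances")
    labels = np.array([inst.swb for inst in instances])
    values, counts = np.unique(labels, return_counts=True)
    keep = set(values[counts >= 2])
    kept = [inst for inst in instances if inst.swb in keep]
    if not kept:
        raise EmptyDatasetError("all labels occurred only once")
    return kept


def mse(true: np.ndarray, pred: np.ndarray) -> float:
    """Mean squared difference between true and predicted labels."""
    true = np.asarray(true, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if true.shape != pred.shape:
        raise DimensionError("true and pred lengths differ")
    if true.size == 0:
        raise EmptyDatasetError("empty label vectors")
    return float(np.mean((true - pred) ** 2))


def dtw_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Dynamic time warping distance between (multichannel) time series.

    Classic unconstrained dynamic programme; the local cost at an aligned
    pair of time points is the Euclidean distance across channels
    (dependent-multivariate DTW).  1-D inputs are treated as one channel.
    Symmetric, zero for identical inputs; quadratic in series length.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[0] != y.shape[0]:
        raise DimensionError("channel counts differ")
    if x.shape[1] == 0 or y.shape[1] == 0:
        raise DimensionError("series must have length >= 1")
    cost = cdist(x.T, y.T)  # (Tx, Ty) local costs
    n, m = cost.shape
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            acc[i, j] = cost[i - 1, j - 1] + min(
                acc[i - 1, j], acc[i, j - 1], acc[i - 1, j - 1]
            )
    return float(acc[n, m])


def _pairwise_distances(instances: list[LabeledInstance], metric: str) -> np.ndarray:
    if metric == "euclidean":
        X = np.stack([np.ravel(inst.x) for inst in instances])
        return cdist(X, X)
    if metric == "dtw":
        n = len(instances)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = dtw_distance(instances[i].x, instances[j].x)
        return D
    raise ParameterError(f"unknown metric {metric!r}")


def loo_1nn(instances: list[LabeledInstance], metric: str = "euclidean") -> np.ndarray:
    """Leave-one-out nearest-neighbour predictions.

    Each instance is labelled with the label of the nearest *other*
    instance; ties are broken by the smallest instance index, which makes
    the result order-stable and deterministic.
    """
    if len(instances) < 2:
        raise EmptyDatasetError("need at least 2 instances for leave-one-out")
    D = _pairwise_distances(instances, metric)
    np.fill_diagonal(D, np.inf)
    nn = np.argmin(D, axis=1)  # argmin returns the first (smallest) index on ties
    labels = np.array([inst.swb for inst in instances])
    return labels[nn]


def build_instances(
    feats: ParticipantFeatures,
    scheme: int,
    source: str = "rp",
    band_name: str | None = None,
    channel: str | None = None,
) -> list[LabeledInstance]:
    """Assemble labelled instances for one participant and input scheme.

    ``source="rp"``: scheme 1 is one relative-power value (band + channel),
    scheme 2 one band at all channels (14 values), scheme 3 all bands at all
    channels (70 values).  ``source="ts"``: the same shapes but with
    band-filtered epoch time series (``band_name=None`` leaves the series
    unfiltered, available for schemes 1 and 2).
    """
    if scheme not in (1, 2, 3):
        raise ParameterError("scheme must be 1, 2 or 3")
    if source == "rp":
        if band_name is None and scheme in (1, 2):
            raise ParameterError("relative-power schemes 1 and 2 need a band")
        bi = BAND_NAMES.index(band_name) if band_name is not None else None
        out = []
        for i in range(feats.n_epochs):
            if scheme == 1:
                x = np.array([feats.rp[i, bi, channel_index(channel)]])
            elif scheme == 2:
                x = feats.rp[i, bi, :]
            else:
                x = feats.rp[i].ravel()
            out.append(LabeledInstance(feats.participant_id, i, x, int(feats.swb[i])))
        return out
    if source == "ts":
        if feats.epochs is None:
            raise ValidationError("time-series schemes need retained epochs")
        out = []
        for i, ep in enumerate(feats.epochs):
            if scheme == 1:
                sig = ep.samples[channel_index(channel)][None, :]
                x = bandpass(sig, band(band_name), ep.fs) if band_name else sig
            elif scheme == 2:
                x = (
                    bandpass(ep.samples, band(band_name), ep.fs)
                    if band_name
                    else ep.samples
                )
            else:
                x = np.concatenate(
                    [bandpass(ep.samples, b, ep.fs) for b in map(band, BAND_NAMES)]
                )
            out.append(LabeledInstance(feats.participant_id, i, x, int(ep.swb)))
        return out
    raise ParameterError(f"unknown source {source!r}")


def evaluate_scheme(
    feats: ParticipantFeatures,
    scheme: int,
    source: str = "rp",
    band_name: str | None = None,
    channel: str | None = None,
    metric: str = "euclidean",
) -> KnnEvaluation:
    """Singleton removal, LOO 1-NN, and MSE for one participant/scheme."""
    instances = build_instances(feats, scheme, source, band_name, channel)
    kept = drop_singleton_labels(instances)
    if len({inst.swb for inst in kept}) < 2:
        raise EmptyDatasetError(
            f"participant {feats.participant_id}: fewer than 2 distinct SWB values"
        )
    pred = loo_1nn(kept, metric)
    true = np.array([inst.swb for inst in kept])
    return KnnEvaluation(
        participant_id=feats.participant_id,
        scheme=scheme,
        band=band_name,
        channel=channel,
        mse=mse(true, pred),
        predictions=list(zip(true.tolist(), pred.tolist())),
        n_used=len(kept),
    )


def best_combination(
    evaluations: list[KnnEvaluation],
) -> tuple[list[tuple[str | None, str | None]], bool]:
    """All (band, channel) pairs achieving the minimal MSE, plus uniqueness.

    Downstream winner tallies count only unique winners; ties cannot name a
    single best combination and are excluded from the tallies.
    """
    if not evaluations:
        raise EmptyDatasetError("no evaluations")
    best = min(ev.mse for ev in evaluations)
    winners = [(ev.band, ev.channel) for ev in evaluations if ev.mse == best]
    return winners, len(winners) == 1


def rescale_mse(values: np.ndarray) -> np.ndarray:
    """Divide per-band minimal MSEs by their maximum so the worst band is 1."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise EmptyDatasetError("no values")
    top = values.max()
    if top <= 0:
        raise DegenerateSignalError("all MSE values are zero")
    return values / top


def chi_squared_gof(counts: np.ndarray) -> CountTestResult:
    """Goodness-of-fit of category counts against the uniform distribution.

    Expected counts are ``total / n_categories``; the statistic is
    ``sum (O - E)^2 / E`` on ``n_categories - 1`` degrees of freedom, and
    the standardized Pearson residual per category is ``(O - E)/sqrt(E)``.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValidationError("counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValidationError("counts sum to zero")
    expected = np.full_like(counts, total / counts.size)
    chi2, p = stats.chisquare(counts, expected)
    residuals = (counts - expected) / np.sqrt(expected)
    return CountTestResult(
        counts=counts,
        chi2=float(chi2),
        df=counts.size - 1,
        p=float(p),
        residuals=residuals,
    )


@dataclass
class BinomialWinnerResult:
    k: int
    n: int
    p0: float
    p_one_sided: float  # upper tail: P(X >= k)
    p_two_sided: float


def binomial_winner_test(k_wins: int, n: int, p0: float) -> BinomialWinnerResult:
    """Exact binomial test that one category wins more often than chance.

    The primary p-value is one-sided (upper tail, "exceeds chance"); the
    two-sided value is reported alongside.
    """
    if not 0 < p0 < 1:
        raise ParameterError("p0 must be in (0, 1)")
    if not 0 <= k_wins <= n:
        raise ValidationError("need 0 <= k_wins <= n")
    one = stats.binomtest(k_wins, n, p0, alternative="greater").pvalue
    two = stats.binomtest(k_wins, n, p0, alternative="two-sided").pvalue
    return BinomialWinnerResult(k_wins, n, p0, float(one), float(two))
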