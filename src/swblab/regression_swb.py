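"""SMOTE-balanced per-participant regression and group-level inference.

Well-being reports cluster on the middle of the 1..10 scale, so an ordinary
regression of rating on an EEG feature would be dominated by the frequent
middle ratings.  Each participant's data are therefore balanced with SMOTE
(synthetic minority oversampling: new points are convex combinations of a
minority sample and one of its k nearest same-class neighbours) before an
ordinary least-squares line of SWB on the feature is fit.  Because SMOTE is
stochastic, the fit is repeated over a fixed list of seeds (1..10 by
default) and the slopes averaged per participant.

At the group level, the per-participant mean slopes for each band/channel
feature enter a one-sample two-sided t-test against zero with Cohen's d
(mean/SD) and a 95% confidence interval, and the 70 resulting p-values
(5 bands x 14 channels) are corrected with the Benjamini-Hochberg step-up
procedure at q = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    DegenerateDesignError,
    DimensionError,
    EmptyDatasetError,
    ParameterError,
    ValidationError,
)
from .io_core import BAND_NAMES, CHANNELS, AnalysisConfig
from .spectral_features import ParticipantFeatures

__all__ = [
    "LinearModel",
    "GroupRegressionStat",
    "smote_balance",
    "fit_line",
    "participant_mean_line",
    "participant_mean_slope",
    "group_slope_test",
    "bh_fdr",
    "run_group_regression",
]


@dataclass
class LinearModel:
    """Per-participant line SWB = slope * feature + intercept."""

    participant_id: str
    feature_id: str  # "band/channel" or "FAA"
    slope: float
    intercept: float


@dataclass
class GroupRegressionStat:
    """Group-level slope statistics for one band/channel feature."""

    band: str
    channel: str
    mean_slope: float
    sd_slope: float
    cohens_d: float
    t: float
    df: int
    p: float
    ci_low: float
    ci_high: float
    p_corr: float = np.nan


def _drop_singleton_classes(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    values, counts = np.unique(y, return_counts=True)
    keep = np.isin(y, values[counts >= 2])
    return x[keep], y[keep]


def smote_balance(
    x: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample every class to the majority count by SMOTE interpolation.

    Synthetic points are ``x_i + lam * (x_nn - x_i)`` with ``lam ~ U(0, 1)``
    and ``x_nn`` one of the ``k_neighbors`` nearest same-class members
    (``k`` is shrunk to ``class_size - 1`` for small classes).  Every class
    must have at least 2 members — remove singleton labels first.  The
    output is deterministic for a fixed seed: original samples in their
    input order, synthetic samples appended per class.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if x.shape[0] != y.shape[0]:
        raise DimensionError("x and y lengths differ")
    if x.shape[0] == 0:
        raise EmptyDatasetError("empty input")
    if k_neighbors < 1:
        raise ParameterError("k_neighbors must be >= 1")
    flat = x.ndim == 1
    X = x[:, None] if flat else x
    values, counts = np.unique(y, return_counts=True)
    if np.any(counts < 2):
        bad = values[counts < 2]
        raise ValidationError(f"class(es) with a single member: {bad.tolist()}")
    target = counts.max()
    rng = np.random.default_rng(seed)
    new_X, new_y = [X], [y]
    for value, count in zip(values, counts):
        n_new = int(target - count)
        if n_new == 0:
            continue
        Xc = X[y == value]
        k = min(k_neighbors, count - 1)
        D = np.linalg.norm(Xc[:, None, :] - Xc[None, :, :], axis=-1)
        np.fill_diagonal(D, np.inf)
        nn_idx = np.argsort(D, axis=1, kind="stable")[:, :k]  # (count, k)
        base = rng.integers(0, count, size=n_new)
        pick = rng.integers(0, k, size=n_new)
        lam = rng.random(n_new)
        neighbors = Xc[nn_idx[base, pick]]
        synth = Xc[base] + lam[:, None] * (neighbors - Xc[base])
        new_X.append(synth)
        new_y.append(np.full(n_new, value, dtype=y.dtype))
    X_out = np.concatenate(new_X)
    y_out = np.concatenate(new_y)
    return (X_out.ravel() if flat else X_out), y_out


def fit_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Ordinary least-squares slope and intercept of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DimensionError("x and y lengths differ")
    if x.size < 2:
        raise EmptyDatasetError("need at least 2 points")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("constant regressor")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept)


def participant_mean_line(
    x: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    seeds: tuple[int, ...] = tuple(range(1, 11)),
) -> tuple[float, float]:
    """Seed-averaged SMOTE-balanced regression line for one participant.

    Singleton rating classes are removed first; for each seed the data are
    SMOTE-balanced and an OLS line of SWB on the feature is fit; the
    arithmetic means of the slopes and intercepts are returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    x, y = _drop_singleton_classes(x, y)
    if len(np.unique(y)) < 2:
        raise EmptyDatasetError("fewer than 2 rating classes after singleton removal")
    slopes, intercepts = [], []
    for seed in seeds:
        xb, yb = smote_balance(x, y, k_neighbors=k_neighbors, seed=seed)
        k, d = fit_line(xb, yb.astype(float))
        slopes.append(k)
        intercepts.append(d)
    return float(np.mean(slopes)), float(np.mean(intercepts))


def participant_mean_slope(
    x: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    seeds: tuple[int, ...] = tuple(range(1, 11)),
) -> float:
    """Seed-averaged slope (see :func:`participant_mean_line`)."""
    return participant_mean_line(x, y, k_neighbors, seeds)[0]


def group_slope_test(
    slopes: np.ndarray, band: str = "", channel: str = ""
) -> GroupRegressionStat:
    """One-sample two-sided t-test of per-participant slopes against zero.

    SD uses the n-1 denominator; Cohen's d is mean/SD; the 95% CI is
    ``mean +/- t_{0.975, n-1} * SD / sqrt(n)``.
    """
    slopes = np.asarray(slopes, dtype=float)
    n = slopes.size
    if n < 3:
        raise EmptyDatasetError("need at least 3 slopes")
    sd = float(np.std(slopes, ddof=1))
    if sd == 0:
        raise DegenerateDesignError("zero variance across participants")
    mean = float(np.mean(slopes))
    df = n - 1
    t = mean / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), df)
    half = stats.t.ppf(0.975, df) * sd / np.sqrt(n)
    return GroupRegressionStat(
        band=band,
        channel=channel,
        mean_slope=mean,
        sd_slope=sd,
        cohens_d=mean / sd,
        t=float(t),
        df=df,
        p=float(p),
        ci_low=mean - half,
        ci_high=mean + half,
    )


def bh_fdr(
    pvals: np.ndarray, m_total: int | None = None, q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment with an explicit family size.

    ``m_total`` is the number of tests in the family; p-values not passed in
    are treated as 1 (they can only weaken rejections, never strengthen
    them).  Adjusted values are ``min_{j >= i} p_(j) * m_total / j`` in
    sorted order, clipped to 1; the null is rejected where the adjusted
    value is at most ``q``.  Returns (adjusted p-values, rejection flags) in
    the input order.
    """
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(pvals) if m_total is None else int(m_total)
    if m < len(pvals):
        raise ParameterError("m_total must be >= number of p-values")
    order = np.argsort(pvals, kind="stable")
    ranks = np.arange(1, len(pvals) + 1)
    scaled = pvals[order] * m / ranks
    # implicit unlisted p-values of 1 at ranks len+1..m adjust to >= 1,
    # so the suffix minimum over the listed ranks is unaffected
    adjusted_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    adjusted = np.empty_like(adjusted_sorted)
    adjusted[order] = adjusted_sorted
    return adjusted, adjusted <= q


def run_group_regression(
    cohort: list[ParticipantFeatures],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """The full relative-power regression table over all 70 band/channel pairs.

    Left-handed participants are excluded from the group tests by default
    (``config.include_left_handed`` restores them); participants without at
    least two rating classes after singleton removal are skipped with their
    id recorded.  The returned frame has one row per (band, channel) with
    mean slope, SD, Cohen's d, t, df, p, BH-adjusted p (family size 70), and
    the 95% CI bounds.
    """
    cfg = config or AnalysisConfig()
    usable = [
        f
        for f in cohort
        if cfg.include_left_handed or f.handedness == "right"
    ]
    rows = []
    for bi, bname in enumerate(BAND_NAMES):
        for ci, ch in enumerate(CHANNELS):
            slopes = []
            for f in usable:
                try:
                    slopes.append(
                        participant_mean_slope(
                            f.rp[:, bi, ci], f.swb, cfg.smote_k, cfg.smote_seeds
                        )
                    )
                except EmptyDatasetError:
                    continue
            stat = group_slope_test(np.array(slopes), band=bname, channel=ch)
            rows.append(stat)
    pvals = np.array([r.p for r in rows])
    adjusted, _ = bh_fdr(pvals, m_total=len(BAND_NAMES) * len(CHANNELS), q=cfg.fdr_q)
    for r, pc in zip(rows, adjusted):
        r.p_corr = float(pc)
    return pd.DataFrame(
        {
            "band": [r.band for r in rows],
            "channel": [r.channel for r in rows],
            "k_mean": [r.mean_slope for r in rows],
            "std": [r.sd_slope for r in rows],
            "cohens_d": [r.cohens_d for r in rows],
            "t": [r.t for r in rows],
            "df": [r.df for r in rows],
            "p": [r.p for r in rows],
            "p_corr": [r.p_corr for r in rows],
            "ci_low": [r.ci_low for r in rows],
            "ci_high": [r.ci_high for r in rows],
        }
    )
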