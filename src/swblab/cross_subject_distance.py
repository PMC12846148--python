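"""Cross-participant model transfer and the transfer-distance matrix.

Two participants are considered close when a well-being predictor fitted on
one of them also predicts the other's reports well.  A per-participant
predictor (a SMOTE-balanced regression line on FAA or on a fixed
relative-power feature, or the participant's best-band/channel 1-NN
classifier) is applied to every other participant, and the prediction error
is summarised by a normalised mean absolute error::

    dist(A, B) = (1/n) * sum_i |true_i - pred_i| / unique(true)

where ``true`` are participant B's reports, ``pred`` the predictions from
participant A's model, and ``unique`` counts B's distinct report values —
the normalisation that makes participants with narrow and wide rating
ranges comparable.  The resulting matrix is asymmetric; it is symmetrised
with the elementwise minimum of the two directions.  The transfer distance
is not a metric (no triangle inequality is claimed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import (
    EmptyDatasetError,
    FeatureMismatchError,
    ParameterError,
    ValidationError,
)
from .io_core import BAND_NAMES, CHANNELS, SWB_MAX, SWB_MIN, AnalysisConfig, channel_index
from .knn_swb import LabeledInstance, best_combination, drop_singleton_labels, evaluate_scheme
from .regression_swb import LinearModel, participant_mean_line
from .spectral_features import ParticipantFeatures

logger = logging.getLogger("swblab")

__all__ = [
    "TransferModel",
    "TransferPrediction",
    "DistanceMatrix",
    "is_usable",
    "train_transfer_model",
    "predict_swb",
    "transfer_distance",
    "build_distance_matrix",
]

METHODS = ("faa_linreg", "rp_knn", "rp_linreg_fixed", "ts_knn")


@dataclass
class TransferModel:
    """One participant's fitted SWB predictor, applicable to others."""

    owner_id: str
    method: str
    band: str | None = None
    channel: str | None = None
    line: LinearModel | None = None  # linreg methods
    train_x: np.ndarray | None = None  # knn methods: stored instances
    train_y: np.ndarray | None = None


@dataclass
class TransferPrediction:
    owner_id: str
    target_id: str
    swb_true: np.ndarray
    swb_pred: np.ndarray  # real-valued for linreg, integer for knn

    @property
    def n(self) -> int:
        return len(self.swb_true)


@dataclass
class DistanceMatrix:
    """Raw (asymmetric) and min-symmetrised participant distances."""

    ids: list[str]
    D: np.ndarray
    D_sym: np.ndarray


def _nonsingleton_mask(swb: np.ndarray) -> np.ndarray:
    values, counts = np.unique(swb, return_counts=True)
    return np.isin(swb, values[counts >= 2])


def is_usable(feats: ParticipantFeatures, min_epochs: int = 20) -> bool:
    """Usability filter: enough reports and rating variability.

    Requires at least ``min_epochs`` epochs and at least 2 distinct rating
    values after singleton removal (a constant reporter cannot be scored).
    """
    if feats.n_epochs < min_epochs:
        return False
    swb = feats.swb[_nonsingleton_mask(feats.swb)]
    return len(np.unique(swb)) >= 2


def _feature_vector(feats: ParticipantFeatures, band: str, channel: str) -> np.ndarray:
    return feats.rp[:, BAND_NAMES.index(band), channel_index(channel)]


def train_transfer_model(
    feats: ParticipantFeatures,
    method: str,
    config: AnalysisConfig | None = None,
    band: str | None = None,
    channel: str | None = None,
) -> TransferModel:
    """Fit one participant's transfer model.

    * ``faa_linreg`` — seed-averaged SMOTE-balanced line of SWB on FAA.
    * ``rp_linreg_fixed`` — the same line on one fixed relative-power
      feature, by default relative alpha power at T7 (the feature with the
      lowest group-level p-value).
    * ``rp_knn`` / ``ts_knn`` — the owner's best (band, channel) by LOO
      1-NN MSE, storing the owner's singleton-filtered training set.  Tied
      winners are resolved to the first in canonical band/channel order
      (logged), so training stays deterministic.
    """
    cfg = config or AnalysisConfig()
    if method not in METHODS:
        raise ParameterError(f"unknown method {method!r}")
    if not is_usable(feats, cfg.min_epochs):
        raise EmptyDatasetError(
            f"participant {feats.participant_id} fails the usability filter"
        )
    if method == "faa_linreg":
        k, d = participant_mean_line(feats.faa, feats.swb, cfg.smote_k, cfg.smote_seeds)
        return TransferModel(
            owner_id=feats.participant_id,
            method=method,
            line=LinearModel(feats.participant_id, "FAA", k, d),
        )
    if method == "rp_linreg_fixed":
        band = band or "alpha"
        channel = channel or "T7"
        x = _feature_vector(feats, band, channel)
        k, d = participant_mean_line(x, feats.swb, cfg.smote_k, cfg.smote_seeds)
        return TransferModel(
            owner_id=feats.participant_id,
            method=method,
            band=band,
            channel=channel,
            line=LinearModel(feats.participant_id, f"{band}/{channel}", k, d),
        )
    # knn methods: find the owner's best (band, channel) under scheme 1
    source = "rp" if method == "rp_knn" else "ts"
    if band is None or channel is None:
        evals = [
            evaluate_scheme(feats, 1, source=source, band_name=b, channel=c)
            for b in BAND_NAMES
            for c in CHANNELS
        ]
        winners, unique = best_combination(evals)
        if not unique:
            logger.info(
                "participant %s: %d tied best combinations; keeping %s",
                feats.participant_id, len(winners), winners[0],
            )
        band, channel = winners[0]
    if source == "rp":
        train_x = _feature_vector(feats, band, channel)[:, None]
    else:
        from .io_core import band as band_spec
        from .spectral_features import bandpass

        sigs = [
            bandpass(ep.samples[channel_index(channel)], band_spec(band), ep.fs)
            for ep in feats.epochs
        ]
        train_x = np.stack(sigs)
    instances = [
        LabeledInstance(feats.participant_id, i, train_x[i], int(feats.swb[i]))
        for i in range(len(feats.swb))
    ]
    kept = drop_singleton_labels(instances)
    return TransferModel(
        owner_id=feats.participant_id,
        method=method,
        band=band,
        channel=channel,
        train_x=np.stack([inst.x for inst in kept]),
        train_y=np.array([inst.swb for inst in kept]),
    )


def predict_swb(model: TransferModel, target: ParticipantFeatures) -> TransferPrediction:
    """Apply an owner's model to a target participant.

    Linear models predict ``slope * feature + intercept`` clipped to the
    1..10 scale and left real-valued (rounding would discard error
    information); nearest-neighbour models return the label of the nearest
    stored training instance, ties to the smallest owner index.
    """
    if model.method == "faa_linreg":
        x = target.faa
    elif model.method in ("rp_linreg_fixed", "rp_knn"):
        try:
            x = _feature_vector(target, model.band, model.channel)
        except ValueError as exc:
            raise FeatureMismatchError(str(exc)) from exc
    else:  # ts_knn
        if target.epochs is None:
            raise FeatureMismatchError("target lacks retained epochs for ts_knn")
        from .io_core import band as band_spec
        from .spectral_features import bandpass

        x = np.stack(
            [
                bandpass(ep.samples[channel_index(model.channel)], band_spec(model.band), ep.fs)
                for ep in target.epochs
            ]
        )
    if model.line is not None:
        pred = np.clip(model.line.slope * x + model.line.intercept, SWB_MIN, SWB_MAX)
    else:
        flat_train = model.train_x.reshape(len(model.train_y), -1)
        flat_x = np.asarray(x).reshape(len(target.swb), -1)
        d2 = (
            (flat_x**2).sum(axis=1)[:, None]
            - 2 * flat_x @ flat_train.T
            + (flat_train**2).sum(axis=1)[None, :]
        )
        pred = model.train_y[np.argmin(d2, axis=1)]
    return TransferPrediction(
        owner_id=model.owner_id,
        target_id=target.participant_id,
        swb_true=np.asarray(target.swb, dtype=float),
        swb_pred=np.asarray(pred, dtype=float),
    )


def transfer_distance(swb_true: np.ndarray, swb_pred: np.ndarray) -> float:
    """Normalised mean absolute error between true and predicted reports.

    ``(1/n) * sum |true_i - pred_i| / unique(true)`` with ``unique`` the
    number of distinct values among the true reports.
    """
    swb_true = np.asarray(swb_true, dtype=float)
    swb_pred = np.asarray(swb_pred, dtype=float)
    if swb_true.shape != swb_pred.shape:
        raise ValidationError("true and pred lengths differ")
    if swb_true.size == 0:
        raise EmptyDatasetError("empty report vectors")
    n_unique = len(np.unique(swb_true))
    return float(np.mean(np.abs(swb_true - swb_pred)) / n_unique)


def build_distance_matrix(
    cohort: list[ParticipantFeatures],
    method: str,
    config: AnalysisConfig | None = None,
    band: str | None = None,
    channel: str | None = None,
) -> DistanceMatrix:
    """Train per-participant models and assemble the transfer-distance matrix.

    Participants failing the usability filter are excluded (logged with the
    reason); the diagonal is forced to zero and ``D_sym`` is the elementwise
    minimum of the two transfer directions.
    """
    cfg = config or AnalysisConfig()
    usable = []
    for f in cohort:
        if is_usable(f, cfg.min_epochs):
            usable.append(f)
        else:
            logger.info(
                "participant %s excluded: too few epochs or no rating variability",
                f.participant_id,
            )
    if len(usable) < 3:
        raise EmptyDatasetError("need at least 3 usable participants")
    models = [
        train_transfer_model(f, method, cfg, band=band, channel=channel) for f in usable
    ]
    n = len(usable)
    D = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            pred = predict_swb(models[a], usable[b])
            D[a, b] = transfer_distance(pred.swb_true, pred.swb_pred)
    D_sym = np.minimum(D, D.T)
    np.fill_diagonal(D_sym, 0.0)
    return DistanceMatrix(ids=[f.participant_id for f in usable], D=D, D_sym=D_sym)
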