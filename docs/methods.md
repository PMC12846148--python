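# Methods

## Setting

A participant wears a 14-channel 10–20 headset (AF3 F7 F3 FC5 T7 P7 O1 O2 P8
T8 FC6 F4 F8 AF4, 128 Hz) and reports a subjective well-being / comfort
rating — an integer from 1 (wants to leave the environment) to 10 (fully
comfortable) — roughly every 30 s.  All features are computed on the *closed*
window of the last 10 s before each report: `round(10·fs) + 1 = 1281`
samples, ending exactly at the report sample.  Reports earlier than 10 s into
the recording are skipped with a warning.  The package assumes artifact-clean
input; artifact rejection, ICA and channel interpolation are out of scope.

## Spectral features

* **Band table** (Hz): delta 0.5–3, theta 4–7, alpha 8–13, beta 14–30,
  gamma 31–55.  Bands extending past Nyquist are integrated up to `fs/2`
  with a logged truncation note.
* **Power estimator**: Welch PSD with 2-s Hann segments and 50% overlap
  (9 segments per 10-s window), integrated over the band with the
  trapezoidal rule.  Welch is the community default and stabilises the
  short windows; the segment length trades frequency resolution (0.5 Hz)
  against variance.
* **Relative power** divides each band power by the *sum of the five band
  powers* at that channel, not by total broadband power, so columns sum to
  exactly one and the feature is independent of device bandwidth.  It is
  scale-invariant and lives in [0, 1].
* **Filtering** uses a 4th-order Butterworth band-pass applied
  forward–backward (zero phase), preserving epoch alignment.
* **FAA** is `ln pow(AF4) − ln pow(AF3)` with alpha power computed by the
  same Welch estimator on the alpha-filtered window — one value per epoch.
  It is antisymmetric under swapping the two channels and invariant to
  common positive scaling.

## Rating prediction (1-NN) and count-level tests

The rating distributions are heavily mid-loaded, so the classifier uses
k = 1: with more neighbours, rare ratings could never win a vote.  Ratings
reported only once are deleted (a leave-one-out split could never predict
them), then each instance is labelled by its nearest other instance
(Euclidean on feature vectors or filtered time series; a classic
unconstrained dependent-multivariate DTW is available behind a flag —
Euclidean is the default as DTW is far slower without being materially
better here).  Nearest-neighbour ties break to the smallest instance index,
making results order-stable.  Scoring is MSE over the ordinal labels.

Per-participant winners (the band/channel with minimal MSE) are tallied;
ties are excluded from tallies because no single best combination exists.
Tallies are tested against uniformity with a chi-squared goodness-of-fit
test (`E_i = N/k`, df = k−1) plus standardized Pearson residuals
`(O_i−E_i)/√E_i`, and the most frequent winner with an exact binomial test,
reported one-sided (upper tail, "exceeds chance") with the two-sided value
alongside.

## SMOTE-balanced regression

Per participant and feature: singleton rating classes are removed, every
remaining class is oversampled to the majority count with SMOTE (synthetic
points `x_i + λ(x_nn − x_i)`, `λ ~ U(0,1)`, `x_nn` among the k = 5 nearest
same-class members, k shrunk to class size − 1), and an OLS line of SWB on
the feature is fit.  Because SMOTE is stochastic the fit is averaged over
seeds 1..10.  Group level: one-sample two-sided t-test of the
per-participant mean slopes against zero (SD with n−1 denominator, Cohen's
d = mean/SD, 95% CI `mean ± t_{0.975,n−1}·SD/√n`).  Left-handed
participants are excluded from group tests by default (their couplings tend
to reverse sign, and the reference analysis stratifies on handedness); a
config flag restores them.

**FDR**: Benjamini–Hochberg step-up over the full family of m = 70
band×channel tests — p-values not listed are treated as 1, which can only
weaken rejections.  Adjusted values are `min_{j≥i} p_(j)·m/j`, clipped to 1.
SMOTE and the FDR step are implemented in-package (deterministic, seedable)
and cross-checked in the tests: SMOTE against its convexity/balance
invariants, FDR against statsmodels' `fdr_bh` when the family equals the
list.

## Transfer distance and clustering

A participant's predictor is one of: a SMOTE-averaged regression line on FAA
(`faa_linreg`), the same line on one fixed relative-power feature
(`rp_linreg_fixed`, default alpha at T7 — the feature with the strongest
group-level correlation), or the participant's best band/channel 1-NN
classifier (`rp_knn`, `ts_knn`).  Linear predictions are clipped to [1, 10]
and kept real-valued — rounding would discard error information the distance
uses.  Participants with fewer than `min_epochs` (default 20) reports or
fewer than two rating classes after singleton removal are excluded.

The transfer distance is the mean absolute error divided by the number of
distinct true ratings, making participants with narrow and wide rating
ranges comparable.  The raw matrix is asymmetric; it is symmetrised
entry-wise with the minimum of the two directions, and the diagonal is
forced to zero.  The result is *not* a metric (no triangle inequality).

**Isomap** on the precomputed symmetrised distances: symmetric 1-NN graph;
if disconnected, minimum-distance bridging edges are added until connected
(logged) — this stays closest to the stated neighbourhood size while
guaranteeing an embedding; geodesics by Dijkstra; classical MDS (eigendecomposition
of the double-centred squared-geodesic matrix, negative eigenvalues clipped,
deterministic sign convention).  **k-means** uses k-means++ with 50 restarts
under a fixed seed.  **Silhouette** is computed on Euclidean distances in
the 2-D embedding (the space that was clustered); singleton clusters score
0 by convention, and a flag allows scoring on the raw distances instead.
Partition agreement across distance constructions uses the adjusted Rand
index.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, with
known ground truth:

* **Latent comfort** `z(t)`: standardized Ornstein–Uhlenbeck process sampled
  on the report grid (exact discretization, stationary N(0,1), relaxation
  time τ = 120 s by default) — comfort drifts slowly relative to the 10-s
  windows, as environmentally driven comfort does.
* **Reports**: `swb = clip(round_half_up(5.5 + 1.5·tanh(b·z)/b), 1, 10)`;
  the squashing strength `b` (default 0.6) concentrates reports on the
  middle of the scale, reproducing the mid-heavy histograms of real comfort
  reports; `b = 0` is the identity squash.  Round-half-up keeps the mapping
  deterministic and monotone; neutral comfort maps to 6.
* **EEG**: per channel, the sum over bands of band-limited Gaussian noise
  with standard deviation `base_amp[b]·(1 + beta[b,c]·z)` plus broadband
  sensor noise (2 µV).  Baseline amplitudes (20, 10, 15, 5, 3 µV for
  delta..gamma) give the low-frequency-dominant relative-power profile of
  resting EEG.  `|beta| < 1` keeps amplitudes positive.  Band noise is
  synthesized spectrally — complex Gaussian coefficients on the band's
  frequency bins, i.e. ideal band-pass-filtered white noise, scaled so the
  expected time-domain variance is one — independently per channel and per
  report interval (the comfort gain is constant within an interval, and the
  10-s window never straddles an interval boundary).  One trailing sample is
  duplicated so a report at the session end has a full closed window.
* **Cohorts**: subgroups share a cluster coupling matrix with 10% relative
  Gaussian jitter per participant; participants are ordered cluster-major
  and the planted labels, couplings and latent paths are returned.

What the generator does **not** emulate: blinks/EMG, volume conduction, 1/f
background, electrode drift, non-stationary rating styles.  Recovery tests
passing on this generator therefore show the *pipeline* is correct and
well-calibrated, not that real EEG carries a comfort signal of any given
size.

## Validation experiments and problem sizes

Three seeded experiments exercise the full chain (sizes chosen to keep the
default suite fast while leaving comfortable statistical margins):

* **Null calibration** — 200 uncoupled cohorts (6 participants × 18 reports,
  i.e. 9-minute sessions); the fraction of group tests with uncorrected
  p < 0.05 should be ≈ 0.05 (five band/channel features are tested per
  cohort to stabilise the estimate; near-constant reporters are excluded as
  in the real analysis).
* **Slope-sign recovery** — 100 runs of one participant with |beta| = 0.5 on
  the gamma band and 60 reports; the SMOTE-averaged slope should recover
  the planted coupling sign.
* **Cluster recovery** — 50 runs of two 5-participant subgroups with
  opposite-sign gamma coupling (30 reports each); the
  distance → Isomap → k-means chain at k = 2 is scored with ARI against the
  planted labels, and within- vs between-cluster distances are compared.

## Numerical conventions and edge cases

* Window: closed at both ends, `L = round(window_s·fs) + 1`.
* Degenerate inputs raise typed errors: all-zero channels
  (`DegenerateSignalError`, naming the channel), constant regressors
  (`DegenerateDesignError`), all-singleton label sets (`EmptyDatasetError`).
* All stochastic steps (SMOTE, k-means, the generator) take explicit seeds;
  repeated runs are bit-identical.
* Matrix CSVs round-trip bit-identically (shortest round-trip float
  representation on write, exact parsing on read).

## Known limitations

* The transfer distance depends on each participant's rating diversity; with
  a single distinct rating the denominator is 1 and such participants are
  excluded upstream anyway.
* A 1-neighbour Isomap graph on small cohorts is almost always disconnected;
  the bridging repair makes the embedding well-defined but geodesics across
  bridges reflect only the single bridged edge.
* DTW is quadratic per pair and intended for small instance counts; the
  Euclidean metric is the practical default for 1281-sample windows.
* The regression treats the ordinal rating as numeric, as plain OLS on a
  1..10 scale; no ordinal or mixed-effects model is provided.
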