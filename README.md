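# swblab

EEG analytics for **short-term subjective well-being (SWB)**: how does the
spectral content of a 14-channel scalp EEG relate to a comfort rating that a
person reports, on a 1–10 integer scale, every ~30 seconds?  The package is
aimed at researchers in neuroergonomics, thermal-comfort and affective-EEG
work who want a tested, reproducible implementation of this analysis chain —
and a synthetic cohort generator with known ground truth to validate it on.

## What it computes

Working on the last 10 s of EEG before each report (1281 samples at 128 Hz,
channels AF3 F7 F3 FC5 T7 P7 O1 O2 P8 T8 FC6 F4 F8 AF4):

* **Band relative power** — Welch power in the delta (0.5–3 Hz), theta
  (4–7 Hz), alpha (8–13 Hz), beta (14–30 Hz) and gamma (31–55 Hz) bands,
  normalised per channel: `rp[b, c] = P_b(c) / Σ_b' P_b'(c)`.
* **Frontal alpha asymmetry** — `FAA = ln pow_R(AF4) − ln pow_L(AF3)` on the
  alpha-filtered signal.
* **1-NN rating prediction** — leave-one-out nearest-neighbour classification
  of the SWB label from one relative-power value, one band at all channels,
  or all 70 band×channel values (and analogously from band-filtered time
  series, with Euclidean or DTW distance), scored by MSE so near-misses on
  the ordinal scale cost less than distant ones.  Ratings given only once
  are removed first.  Winner tallies over bands are tested with a
  chi-squared goodness-of-fit test, standardized residuals, and an exact
  binomial test.
* **SMOTE-balanced regression** — per participant, the mid-heavy rating
  distribution is balanced with SMOTE (seeds 1..10) before an OLS line of
  SWB on the feature is fit; seed-averaged slopes enter a group-level
  two-sided one-sample t-test with Cohen's d and 95% CI, corrected across
  the 70 band×channel tests with Benjamini–Hochberg FDR at q = 0.05.
* **Cross-participant transfer distance** — participant A's fitted predictor
  applied to participant B's data, scored as

  `dist_AB = (1/n) Σ_i |SWB_true,i − SWB_pred,i| / unique(SWB_true)`

  then symmetrised with `min(dist_AB, dist_BA)`.
* **Clustering consistency** — Isomap embedding of the symmetrised distance
  matrix (1-NN graph, precomputed distances), k-means for k = 2..6,
  silhouette `s = (b − a)/max(a, b)`, and adjusted Rand indices between
  partitions from different distance constructions.
* **Synthetic cohorts** — an Ornstein–Uhlenbeck latent comfort process
  drives both the integer reports and the amplitude of band-limited EEG
  noise through a planted 5×14 coupling matrix, optionally with participant
  subgroups; the ground truth is returned for recovery testing.

## Worked example

Recover two planted participant subgroups with opposite gamma coupling
through the full transfer-distance pipeline:

```python
from swblab.synthetic_cohort import CohortSpec, generate_cohort, uniform_coupling
from swblab.pipelines import cohort_features
from swblab.cross_subject_distance import build_distance_matrix
from swblab.cluster_consistency import isomap_embed, kmeans_partition, silhouette, adjusted_rand
from swblab.io_core import AnalysisConfig

spec = CohortSpec(
    n_clusters=2, participants_per_cluster=5,
    cluster_couplings=[uniform_coupling("gamma", 0.5), uniform_coupling("gamma", -0.5)],
    session_length_s=900.0, seed=42,
)
recordings, truth = generate_cohort(spec)
feats = cohort_features(recordings, compute_faa_values=False)
cfg = AnalysisConfig(min_epochs=10)
dm = build_distance_matrix(feats, "rp_linreg_fixed", cfg, band="gamma", channel="AF3")
emb = isomap_embed(dm.D_sym, n_neighbors=1, ids=dm.ids)
labels = kmeans_partition(emb.coords, 2, seed=0)
s, _ = silhouette(emb.coords, labels)
print("k=2 labels:   ", labels.tolist())
print("silhouette:   ", round(s, 3))
print("ARI vs truth: ", adjusted_rand(labels, truth.cluster_labels))
```

prints

```
k=2 labels:    [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
silhouette:    0.71
ARI vs truth:  1.0
```

The first five participants (positive comfort→gamma coupling) and the last
five (negative coupling) land in separate clusters; silhouette 0.71 says the
embedded groups are compact and separated; ARI 1.0 is perfect agreement with
the planted labels.

The same steps are available as a CLI:
`swblab simulate | features | knn | regress | distance | cluster | report`,
e.g. `swblab simulate --config cohort.yaml --out cohort/` followed by
`swblab distance --in cohort/ --method rp_linreg_fixed --out D.csv`.

## Documentation

`docs/methods.md` describes the models, the synthetic-data assumptions, the
numerical choices (Welch estimator settings, filter design, tie-breaking,
FDR family size), and known limitations.
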