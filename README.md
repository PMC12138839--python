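# dtwnet

Dynamic-time-warp (DTW) symptom-network analysis for short panel time
series.

Longitudinal studies of mental-health symptoms — for example
eating-disorder cohorts assessed a handful of times over many months —
produce, per person, a short multivariate time series of symptom scores
and related attributes (psychopathology severity, binge eating, anxiety,
depression, social support, well-being, BMI, ...). Two questions drive
the analysis this package implements:

1. **Which attributes change together within people?** For every subject,
   the DTW distance between each pair of (preprocessed) attribute
   trajectories is computed, averaged at the group level, and the
   attributes are hierarchically clustered into *dimensions* — groups
   with similar within-person change patterns — displayed as a signed
   undirected network.
2. **Which attributes change first?** A forward-only DTW variant aligns
   each point of one series only with the same or the next assessment of
   the other (lag 0 or lag 1). For an ordered pair (a, b) the direction
   contrast δ(a→b) = D(b→a) − D(a→b) is positive when a's changes
   precede b's. Group-level one-sided t-tests over subjects yield a
   directed network, and out-/in-strength centralities with 95%
   confidence intervals identify attributes whose changes lead
   (out-strength) or follow (in-strength) the rest of the network.

## The model in brief

Per subject, each attribute is a series x₁..x_T (T ≥ 3, typically 6).
Preprocessing: reverse-code inverted-valence attributes, center within
person, standardize each attribute to unit pooled SD.

**Undirected distance** (symmetric2 step pattern, Sakoe-Chiba band
|i−j| ≤ w, default w = 1):

    g(1,1) = 2c(1,1),
    g(i,j) = min( g(i−1,j−1) + 2c(i,j), g(i−1,j) + c(i,j), g(i,j−1) + c(i,j) ),
    D = g(N,M) / (N+M),      c(i,j) = |xᵢ − yⱼ|.

**Directed distance** (forward-only, lag ≤ 1): every i is matched to one
j(i) ∈ {i, i+1}, j non-decreasing, advancing at most two steps;
D = Σᵢ c(i, j(i)) / N. Small D(a→b) means a's changes align with
same-time-or-later values of b, i.e. a temporally leads b.

**Strengths**: out(j) = Σ_k max(δ(j→k), 0), in(j) = Σ_k max(δ(k→j), 0),
centered across nodes within each subject; group mean ± t-based 95% CI.

With incomplete data (dropout), analyses run on a stack of M complete
imputed replicates and the per-subject distance/contrast matrices are
averaged across replicates before group-level inference.

## Worked example

```python
from dtwnet import DtwNetworkModel, generate_panel, reference_config

cfg = reference_config(seed=1, n_subjects=150)   # 12 attributes, 4 planted dimensions
panel, truth = generate_panel(cfg)               # complete synthetic panel, T = 6
res = DtwNetworkModel(panel, cfg.schema()).fit()
print(res.summary())
```

prints (abridged):

```
DTW Symptom Network Results
================================================================
subjects: 150   timepoints: 6   attributes: 12   imputations pooled: 1
window: 1   max_lag: 1   linkage: ward   alpha: 0.05

Dimensions (k = 4, chosen by mean silhouette width):
  [1] depression, anxiety, ed_psychopathology, quality_of_life, self_rated_health
  [2] social_support, self_efficacy
  [3] binge_eating, vomiting
  [4] bmi, well_being, laxative_use
  silhouette by k: 2: 0.231  3: 0.329  4: 0.401  5: 0.366 ...

Directed edges (one-sided t-test, alpha = 0.05): 5 significant
  social_support -> self_efficacy: mean delta = +0.2405 (se 0.0190, p = 1.295e-25)
  ...

Standardized strengths (mean [95% CI], * CI > 0):
  out-strength (temporal lead):
    social_support       +0.2516 [+0.1402, +0.3629] *
    ...
  in-strength (temporal lag):
    self_efficacy        +0.3870 [+0.2271, +0.5468] *
    ...
```

The four dimensions are exactly the planted clusters; the planted leader
(`social_support`, whose latent factor the follower `self_efficacy`
tracks one assessment later) has the largest — and the only significant
— out-strength, and the follower the largest in-strength. `mean delta`
is the average direction contrast δ in standardized-score units per
aligned point; positive values mean the source's changes precede the
target's.

`res.save_artifacts("outdir")` writes the group distance matrix,
dendrogram (Newick), GraphML/JSON networks, edge and strength tables and
a machine-readable `run_summary.json`; `res.plot_*()` render the
dendrogram, both networks, mean trajectories and a strength forest plot.

## Command line

```bash
dtwnet simulate config.yaml -o sim/    # synthetic panel + ground truth
dtwnet run sim/panel.csv -o run/       # full pipeline, writes all artifacts
dtwnet report run/                     # plots + markdown report
```

`run` accepts a long CSV (`subject,time,attribute,value`) or a stacked
CSV of complete imputed replicates (extra `imputation` column).

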