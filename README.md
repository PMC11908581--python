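# chromqc

Quality-centric evaluation of chromatographic data.

When a machine-learning model is trained on measurements from liquid
chromatography — for example predicting the retention time (tR) of antisense
oligonucleotides (ASOs) separated by ion-pair liquid chromatography — the
model's accuracy depends heavily on the quality of the underlying signals.
`chromqc` implements a quality-centric evaluation pipeline for such data:

1. **Measure** peak quality from raw chromatograms. Each detector trace is
   modelled as Y(t) = B(t) + P(t) + N(t) (baseline + peak + noise), and four
   measurements are extracted per compound:
   - **SNR** — apex height above the baseline over the idle-region noise sd;
   - **ΔtR = tR,1 − tR,2** — retention-time difference between two replicate
     runs;
   - **skewness** Qs,0(x) = WR(x)/WL(x), the ratio of right to left
     half-widths at fraction x (default 0.5) of the apex height: 1 means
     symmetric, < 1 fronting, > 1 tailing;
   - **peak area** — trapezoidal integral of the baseline-subtracted peak.
2. **Cluster** compounds into quality-sensitive groups: the feature table
   (ΔtR, SNR, skewness, area, sequence length, sulfur-modification count) is
   standardized and normalized, reduced by PCA, and partitioned with k-means,
   with k chosen by the elbow method on the within-cluster sum of squares
   and validated by the mean silhouette score.
3. **Validate** the clusters by predictive performance: a grid-searched
   regressor (support vector regression or gradient-boosted trees) predicts
   tR separately inside each cluster; the spread of test RMSE / R² across
   clusters is the evidence that the clusters capture data quality, and the
   per-cluster feature summaries say *which* signal properties distinguish
   good from poor data.

A bundled synthetic chromatogram generator (exponentially modified Gaussian
peaks with tunable noise, tailing and replicate retention-time jitter,
organised into latent quality tiers) makes the entire chain testable end to
end with known ground truth. See `docs/methods.md` for the model details.

## Worked example

```python
from chromqc.simulate import simulate_cohort
from chromqc.pipeline import measure_cohort
from chromqc.dataset import assemble_quality_table
from chromqc.model import QualityClusterModel

cohort = simulate_cohort(300, seed=1)           # 3 latent quality tiers
measurements = measure_cohort(cohort)           # per-compound quality rows
table, _ = assemble_quality_table(
    measurements, cohort.truth[["compound_id", "length", "sulfur_count"]]
)
results = QualityClusterModel(table).fit(seed=1)
print(results.summary())
```

prints

```
Quality-cluster evaluation
==============================================================
n compounds (complete rows): 300
PCA: 2 components (variance ratios 0.460, 0.415, cumulative 0.875)
k (elbow-selected): 3   mean silhouette: 0.680

cluster     n  rmse_test  r2_test  verdict
      0   100      0.008    1.000     high
      1   102      0.050    0.999   medium
      2    98      0.077    0.999      low

features separating best from worst cluster: sulfur_count, snr, peak_area
```

Reading this: two principal components carry 87.5% of the feature variance;
the elbow method picks k = 3 clusters, confirmed by a mean silhouette of
0.68. Cluster 0 (highest mean SNR by construction of the labels) is
predicted almost perfectly (test RMSE 0.008 min), while the lowest-quality
cluster is an order of magnitude worse (0.077 min) — the per-cluster model
performance exposes the quality structure of the data. The feedback section
of the written report names the features separating the best from the worst
cluster, which is what an analyst would act on at the instrument.

The same chain is available from the shell:

```bash
chromqc run --config config.json          # full pipeline from one JSON config
chromqc simulate --n 300 --seed 1 --out-dir runs/
chromqc measure --run1 a.csv --run2 b.csv --out row.csv
chromqc cluster --table table.csv --out-dir out/
chromqc evaluate --table table.csv --model svr --out-dir out/
```

Exit codes: 0 success, 2 configuration error, 3 stage failure. All artifacts
(quality table, transform, assignments, diagnostics, per-cluster summaries,
JSON + Markdown reports) are persisted in the output directory, and a rerun
of the same configuration reproduces them byte-identically.

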