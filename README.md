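# morphloss

Morphological disparity — the spread of taxa in a morphospace built from
discrete character data — is routinely estimated from matrices that mix
living taxa with fossils.  Fossilization does not delete data at random:
soft tissues decay first, then disarticulation, transport and erosion strip
away whole anatomical systems, so the same characters go missing from every
fossil at once.  `morphloss` is a simulation pipeline for palaeobiologists
who want to know how much that structured data loss (and its random
counterparts) distorts disparity estimates, and how the answer depends on
the distance metric and disparity index used.

## What it computes

A fully bifurcating birth–death tree with 32 fossil and 32 extant tips
carries 254 binary characters evolved under the equal-rates Mk model
(q = 0.01), filtered so the per-character consistency-index distribution
matches a configurable empirical target.  The matrix is then degraded in a
nested four-stage schedule — 43% of fossil characters (soft-tissue decay),
then three increments of 20% of the remainder, reaching 77.2% fossil
missingness — under three regimes: whole characters lost from all fossils,
random cell loss within fossils, and random cell loss everywhere.

Distances come from two metrics with opposite missing-data philosophies:

* **MORD** (maximum observable rescaled distance; = Gower for binary
  data): d(i,j) = (differing comparable characters)/(comparable
  characters);
* **GED** (generalized Euclidean distance, Wills variant):
  d(i,j) = √(Σₖ δ²ᵢⱼₖ) with every incalculable δ replaced by the pooled
  mean d̄ of the calculable ones.

Disparity is summarized by six indices — mean, maximum and extant–fossil
mean pairwise distance on the distances; sum of variances, sum of ranges
and extant–fossil centroid distance on PCoA coordinates — over 100
bootstrap subsamples per matrix, for mixed (64-taxon) and fossil-only
(32-taxon) analyses.  Results are ratios of median degraded disparity to
median original disparity: above 1 means data loss inflates the estimate.

## Worked example

```python
import morphloss as ml

config = ml.RunConfig(n_replicates=20, master_seed=0)
result = ml.run_experiment(config)

summary = (
    result.ratios
    .query("scope == 'MIXED' and index == 'mpd'")
    .groupby(["regime", "metric", "stage"])["ratio"]
    .median()
    .unstack("stage")
    .round(3)
)
print(summary)
```

```
stage                               0      1      2      3
regime               metric
NONRANDOM_CHARACTERS ged_wills  0.863  0.815  0.765  0.720
                     mord       1.025  1.012  1.003  1.022
RANDOM_SCORES_ALL    ged_wills  0.823  0.775  0.730  0.687
                     mord       1.001  1.000  0.998  1.001
RANDOM_SCORES_FOSSIL ged_wills  0.828  0.784  0.740  0.700
                     mord       1.000  1.003  1.008  1.013
```

Each cell is the median (over 20 replicates) ratio of degraded to original
mean pairwise distance for mixed fossil+extant matrices.  GED-based
disparity erodes steadily — down 28–31% by the final stage — because its
mean-substitution rule squares values between 0 and 1, pulling distances
toward zero as missingness grows.  MORD stays within ~2% of the true value
at every stage: rescaling by the comparable characters keeps the estimate
unbiased, though its replicate-to-replicate spread widens as fewer
characters remain (visible in `result.ratios` as growing inter-replicate
IQR).  Fossil-only analyses (`scope == 'FOSSIL_ONLY'`) show the flip side:
with no complete taxa to anchor the space, MORD-based sums of variances
overshoot by a factor >2 at the final stage.

The same pipeline runs from the shell:

```sh
morphloss simulate --seed 7 --out simulated/          # tree + matrix
morphloss analyse --replicates 10 --seed 1 --out results/
morphloss report --ratios results/ratios.csv
morphloss degrade --matrix data.nex --status status.tsv --regime RANDOM_SCORES_FOSSIL
```

`analyse` writes a tidy `ratios.csv` (one row per regime × replicate ×
stage × metric × scope × index), a missingness audit, and a JSON manifest
with every seed substream.  `degrade` accepts empirical NEXUS matrices
with pre-existing missing data (fractions then apply to the scores that
remain) and a tab-separated sidecar of FOSSIL/EXTANT labels.

See `docs/methods.md` for the models, defaults and numerical choices.

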