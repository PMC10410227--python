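# Methods

`morphloss` is a simulation pipeline for asking a single question: when
fossilization deletes character data — whole anatomical systems at once, or
scores here and there — how far do the standard estimates of morphological
disparity drift from what complete data would have given?  This note
documents the models, the parameters that matter, the numerical choices,
and what the synthetic data do and do not capture.

## The generating process

**Tree.** A birth–death tree is simulated (dendropy, general sampling
approach) conditioned on an exact number of extant tips; draws are rejected
until the number of extinct tips also matches the request and no branch is
shorter than 1e-9 time units.  Defaults: 32 extant + 32 fossil tips, birth
rate λ = 1.0, death rate μ = 0.5 per lineage per unit time.  Only the tip
counts and full bifurcation are pinned down by the study design; the rates
are free parameters, chosen so that the extinct-tip count lands near 32
often enough for rejection sampling to be cheap (roughly one draw in
fifteen at the defaults).  Extinct tips are "fossils"; tips reaching the
present are "extant".

**Characters.** Binary characters evolve under the equal-rates two-state
Markov (Mk) model at rate q = 0.01 substitutions per unit time.  The root
state is uniform on {0, 1} (the chain's stationary distribution); along a
branch of length t the state flips with probability (1 − e^(−2qt))/2.

**Homoplasy matching.** Raw Mk output is far cleaner than empirical
cladistic data, so characters are filtered: candidates are simulated in
bulk, invariant columns discarded (their consistency index is undefined),
and survivors binned by CI = 1/steps, where steps is the Fitch parsimony
length on the generating tree.  Bins are the ten half-open intervals
(0, 0.1], ..., (0.9, 1] with CI = 1 in the top bin.  Each bin has a quota
(largest-remainder rounding of the target proportions, ties to the lower
bin) and candidates fill quotas in order of arrival until 254 characters
(a 4:1 character:taxon ratio) are accepted.  The default target —
55% CI = 1, 28% CI = 0.5, 12% CI = 1/3, 5% CI = 0.25 — is a documented
placeholder for the homoplasy profile of an average empirical matrix:
mostly clean characters with a tail of homoplastic ones and a mean
per-character CI near 0.73.  It places mass only on bins that binary
characters can reach (CI = 1/steps) at a rate the q = 0.01 process
produces at workable frequency.  Users with a measured histogram should
supply it; assembly raises rather than silently under-filling when a
target is unreachable within the attempt budget.

## Degradation regimes

All regimes share one nested schedule: a soft-tissue stage converts
fraction p0 = 0.43 of each fossil taxon's scored characters to missing
(soft-tissue features average 43% of characters in datasets that code
them), then three increments each remove 20% of what the soft-tissue stage
left, giving nominal fossil missingness 43% → 54.4% → 65.8% → 77.2%
(21.5% → 38.6% of the whole matrix at a 1:1 fossil:extant ratio).  Counts
are rounded half-up; with 254 characters the structured regime blanks
109, then 29 per increment (196 of 254 = 77.17% at the final stage).

* **Structured loss (`NONRANDOM_CHARACTERS`)** removes the *same*
  randomly chosen characters from every fossil taxon — the signature of
  taphonomy, where the characters that decay are gone from all fossils.
* **Random loss within fossils (`RANDOM_SCORES_FOSSIL`)** removes
  individual fossil cell scores uniformly; each fossil taxon loses
  round(nominal × its initially scored cells) per stage.
* **Random loss everywhere (`RANDOM_SCORES_ALL`)** spreads the same total
  number of lost cells uniformly over the whole matrix.

The random regimes match the structured regime's per-stage cell counts (to
rounding), so a given stage always compares like-for-like amounts of
missing data.  Stages are nested within a replicate: a lost cell stays
lost.  Matrices with pre-existing missing entries (empirical data) are
handled by applying the fractions to the cells that remain scored.

## Distance metrics

For binary data the per-character dissimilarity is 0/1, incomparable when
either score is missing.

* **MORD** (maximum observable rescaled distance) = differing/comparable
  over the comparable characters of the pair — the Gower dissimilarity for
  binary data, bounded in [0, 1].  It requires every pair to share at
  least one scored character; otherwise taxa are trimmed, most-missing
  first among the offending taxa, ties to the lexicographically first
  label, until all pairs are comparable.
* **GED** (generalized Euclidean distance, Wills variant) keeps all N
  characters and substitutes each incalculable dissimilarity with the
  pooled mean d̄ of every calculable one, then takes sqrt(Σδ²).  Because
  substituted values are squared, and most fall strictly between 0 and 1,
  GED drifts toward shorter distances as data loss grows — the behavior
  the experiment quantifies.  A per-pair-mean substitution is exposed
  (`substitute="pair"`) but the pooled mean is the named default.

Neither metric guarantees the triangle inequality under missing data; this
is documented, not asserted.

## Ordination

Post-ordination indices need coordinates.  The pipeline square-root
transforms MORD (GED is used as is), then embeds by classical scaling
(PCoA): eigendecompose the double-centred squared-distance matrix, keep
axes with eigenvalue > 1e-8 × the largest, scale eigenvectors by
√eigenvalue.  Axis signs are fixed by making each axis's
largest-magnitude loading positive, so runs are byte-reproducible.

The Cailliez correction — the smallest constant c that, added to every
off-diagonal dissimilarity, makes the matrix Euclidean — is implemented
exactly (largest real eigenvalue of the 2n × 2n companion construction,
verified against an independent bisection-on-PSD oracle and against the
standard R implementation).  It is *not* applied to the coordinates that
feed the disparity indices by default.  Heavily degraded matrices demand
constants of the same order as, or larger than, the distances themselves
(c ≈ 15–57 for stage-3 GED at the default design); adding such a constant
to every pair inflates every axis at once, and the sum of variances then
measures the correction rather than the morphospace (ratios of 10–250×
where the uncorrected embedding moves tens of percent).  The default
therefore ordinates the uncorrected matrix and keeps its positive axes —
which is also what the coordinates consumed by the standard R disparity
stack contain — and `RunConfig(cailliez_corrected_coordinates=True)`
restores the literal corrected-coordinates pipeline for comparison.

## Disparity indices and resampling

Pre-ordination, on the distance matrix: mean pairwise distance (MPD),
maximum pairwise distance (MAXPD), and mean extant–fossil pairwise
distance (MEFD).  Post-ordination, on the coordinates: sum of per-axis
sample variances (SOV, denominator n − 1), sum of per-axis ranges (SOR),
and the Euclidean distance between the extant and fossil centroids.
Bootstrap duplicates are genuine sample members: copies of a taxon sit at
distance 0 and coincide in morphospace, which biases MPD and SOV slightly
downward relative to deduplicated sampling — the plain reading of drawing
taxa with replacement from a distance matrix.  Cross-class indices (MEFD,
centroid distance) are undefined for fossil-only samples and are excluded
from that scope.

Per matrix, metric and scope, 100 subsamples are drawn with replacement
(64 taxa for mixed analyses; 32 after dropping extant rows from the
distance matrix and ordination — fossils are not re-ordinated).  The
median index value over the subsamples is compared with the original
matrix's median (its own subsample stream), and the ratio
degraded/original is reported: above 1 is overestimation, below 1
underestimation.  Medians of even counts average the central two values.
Subsamples where a cross-class index is undefined are skipped and counted;
more than 50% undefined raises.

All randomness descends from one master seed through named substreams
(regime/replicate/stage/metric/scope), so a single integer reproduces a
run bit-for-bit; the manifest records the substructure.

## Problem sizes

The full design is 100 replicates × 3 regimes × 4 stages × 2 metrics ×
2 scopes with 100 subsamples each.  The packaged acceptance tests run the
same pipeline at 20 replicates (directional checks) and 10 replicates
(end-to-end coverage), sizes at which the reported directions are already
stable; the full design runs in minutes via `morphloss analyse`.

## What the synthetic data do not capture

The generator emulates tip counts, bifurcation, branch-length variation,
Mk-style character change and an empirically shaped homoplasy profile.
It does not emulate: multistate or ordered characters, rate heterogeneity
across characters, correlated loss of anatomically linked characters
(each structured draw is uniform over characters, not organized into
modules), taxon-specific preservation probabilities, or character
inapplicability as distinct from missingness.  Passing tests therefore
show that the *metrics and indices* respond to structured versus random
loss as described; they do not certify behavior on data whose missingness
is clustered by anatomy or phylogeny in ways the regimes do not model.

## Known limitations

* CI matching conditions on one generating tree; the realized histogram is
  exact to quota rounding, but character correlations induced by the
  shared tree are inherited, not controlled.
* Trimming is greedy (most-missing-first) and is not guaranteed to remove
  the minimum number of taxa.
* The degraded/original ratio uses independent subsample streams for
  numerator and denominator, so a no-op degradation yields ratios equal to
  1 only up to bootstrap noise.
* GED's pooled mean d̄ is recomputed per degraded matrix, as the metric
  prescribes; comparisons across stages therefore confound distance change
  with substitution-value change — a property of the metric under study,
  not an artifact.
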