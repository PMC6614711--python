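# Methods notes

This note records the models, conventions and numerical choices behind
`agsflow`, in the order data flows through the pipeline.

## Synthetic-data generator

The generator emulates the post-clustering data products of a multi-reactor
AGS amplicon study, not raw reads. Its defaults describe the emulated study
design: 4 reactors inoculated from one shared sludge, sampled weekly for 400
days at a read depth of 50,000, with 50 genus-level taxa, and planted
stable-state onsets of 231/178/231/120 days for R1–R4 (the onset spread
observed in year-long AGS start-ups of increasingly complex feeds).

**Community model.** Each reactor has a latent composition that interpolates
in log-abundance space (then renormalises) from the shared inoculum
composition toward a reactor-specific stable composition. The mixing weight
decays linearly while the community is held at least a *knee distance*
(default Bray-Curtis 0.66) away from its stable composition, and drops to
the stable composition at the planted onset. This gives each series the
two-phase structure the stable-state criterion assumes — a transition phase
whose samples stay > 0.6 from the final community, then a tight stable
plateau — and makes the planted onset a well-defined recoverable quantity.
A generator whose latent path crept smoothly through the 0.6 contour would
make "the" onset ill-posed at exactly the threshold used to detect it; the
knee construction deliberately avoids that degeneracy. Inoculum-to-stable
distances are validated to exceed 0.6 (defaults give ≈ 0.75) and the
expected within-stable distance is validated (analytically, by a half-normal
approximation of E|pᵢ − qᵢ|) to be below 0.3.

**Count noise** is Dirichlet-multinomial: observed proportions are drawn
from Dirichlet(c·latent) with concentration scale c (`overdispersion`,
default 500, giving per-taxon proportion variance ≈ p(1−p)/(c+1), i.e. a
Hellinger-scale noise sd of ≈ 0.022 per sample), then counts from a
multinomial at the configured depth. `overdispersion = inf` and
`read_depth = inf` give the noise-free limit used by exactness tests.

**Planted structure.** Taxon indices are partitioned into an abundant block
(12 taxa, means 1.2–3.0%), a rare-divergent block (4 taxa, ≈ 0.4%), a
neutral geometric tail, and a residual "other" pseudo-taxon that absorbs the
remaining mass so planted effects can never push the composition off the
simplex. Divergent effects are applied round-robin: the "hot" reactor sits
`divergent_effect` (default 0.012) above the other reactors, with
compensating dips of effect/n_reactors, so per-reactor totals — and hence
"other" — stay balanced across reactors whenever the planted counts divide
the reactor count (the defaults do). The first half of the divergent set is
drawn from the abundant block, making the planted discriminant set their
intersection. A configuration is rejected unless every planted divergent
taxon separates its reactors by more than 5 pooled standard errors of the
Hellinger-transformed abundance at the configured stable sample counts —
the generator's detectability contract.

**Floc/granule pairs** share a sampling day: the granule sample is a noisy
draw around the stable composition and the floc sample multiplies planted
taxa by 2^enrichment and renormalises. Default enrichments (±1 log2) are
assigned to the most abundant non-discriminant planted taxa so that the
halved floc proportions still rank inside the default top-20 comparison.

**Sludge trajectories.** SVI₃₀(t) = SVI_∞ + (SVI₀ − SVI_∞)e^(−t/τ) with
Gaussian noise; SVI₁₀ and SVI₅ are built multiplicatively above SVI₃₀ with
non-negative, decaying gaps, so SVI₅ ≥ SVI₁₀ ≥ SVI₃₀ holds by construction
and the SVI ratios approach ~0.95 as granulation proceeds. Sieve size
fractions follow a log-linear simplex path from floc-dominated (80% flocs)
to a reactor-specific end profile; removal efficiencies are truncated-normal
in [0, 100] with reactor-specific means (e.g. COD ≈ 91/93/83/92%, TP ≈
89/89/49/64% for R1–R4) typical of VFA-fed vs complex-fed reactors. The
noise-free curves define a planted start-up crossing day per reactor.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: sequencing artifacts (chimeras, primer bias,
variable library size), temporal autocorrelation of the noise,
compositional interactions beyond renormalisation, mid-run perturbations
(washouts, restarts, operational changes), and taxa appearing de novo.
Recovery rates on synthetic data are upper bounds for field data.

## Taxonomy profiles

Identity thresholds (genus 94.5, family 86.5, order 82.0, class 78.5,
phylum 75.0) are inclusive: an identity exactly at a threshold earns that
rank. Species is never assigned; genus is the deepest reported rank.
Clusters unassigned at the aggregation rank pool under
`uncl_<deepest assigned label>`, which keeps them countable as distinct
taxa. The < 5 mean-reads-per-sample cluster filter is applied before rank
aggregation and averages over all samples of the supplied table (zeros
included); the boundary is strict (mean exactly 5 is retained). Aggregation
conserves per-sample totals exactly.

## Community metrics

Bray-Curtis is computed on relative abundances. Shannon diversity uses the
natural logarithm (ecology convention; no base is otherwise implied). PCoA
is classical scaling: double-centre −½D², eigendecompose, scale
eigenvectors by √eigenvalue; negative eigenvalues are reported for
diagnostics but excluded from coordinates and from the explained-variance
denominator, and no Lingoes/Cailliez correction is applied. The Mantel
statistic is the Pearson correlation of strictly-lower-triangle entries;
the p-value is one-sided (upper tail) with the +1 correction,
`(1 + #{r_perm ≥ r}) / (n_perm + 1)`, permuting rows and columns of the
second matrix jointly.

## Stable state

"All the following sample points" is read as strictly later samples
(j > i). The last sample's forward set is empty, so its maximum is 0 and
the sample is stable by convention. The onset is the start of the maximal
all-stable suffix: isolated early stable samples followed by a later
transition sample are flagged but excluded from the stable dataset, since
the two-state reading implies a single changeover. Raising the threshold
can only flip samples toward stable (monotonicity, property-tested).
Distances are computed at whatever taxonomic level the input table carries;
the pipeline runs it at the level the simulation emits and the CLI accepts
any rank.

## Discriminant taxa

Welch's unequal-variance t-test is the default (a pooled-variance switch
exists); the Hellinger transform is applied per sample *before* group means
and tests. Zero-variance guard: both groups constant and equal → p = 1;
constant and unequal → p = 0 (the limits of the t statistic). The
Bonferroni divisor is the taxon count only — the printed convention of this
analysis — although 10 dataset pairs are tested per taxon. Consequence:
with five datasets the experiment-wide guarantee is FWER ≤ 10α, not α; the
measured family-wise false-call rate under a global null at defaults is
≈ 0.08–0.10, while the per-taxon false-call rate stays ≈ 2·10⁻³ ≪ α. Users
wanting a strict experiment-wide α should pass
`n_tests = n_taxa * n_pairs`. The floc/granule comparison ranks genera by
grand mean over all stable floc+granule samples, tests the top 20 per
reactor (paired on shared days when pairing is complete, Welch otherwise,
logged), and applies the 0.5% pseudo-count to the displayed ratios only —
not to the tests — since the pseudo-count's purpose is to damp ratio noise
in rare genera, not to alter inference.

## Sludge correlates and MFA

Community samples are matched to the nearest sludge measurement of the same
reactor within ±7 days (configurable); correlations are Pearson (Spearman
via config) on Hellinger-transformed abundances, with p-values from the t
distribution with n − 2 df; pairs with fewer than 3 matched samples are
reported missing. Parameters where *small is good* (SVI₅, settling time)
can be flagged for inversion before correlating so that positive
correlations consistently read "associated with good sludge". Taxon
clustering is hierarchical (Euclidean, average linkage), cut at k = 3 by
default, input-order invariant (rows sorted by label first), and clusters
are renumbered by descending mean correlation with the large+medium granule
fractions so cluster 1 is always the granule-associated guild.

MFA: variables are centred and scaled to unit population variance; each
block is divided by its first singular value on the correlation scale (so
every block's leading direction carries unit inertia); the concatenated
weighted matrix is decomposed by SVD. Group contributions per axis are
shares of squared loadings and sum to one; total inertia equals
Σ_g p_g / s1_g², which the tests verify as a trace identity. With one block
the axes reduce to ordinary principal components.

## Reactor metrics

Boundary handling of the start-up classifier follows the criterion wording:
strict for SVI₃₀ < 90 mL/g and SVI₃₀/₁₀ > 0.8, inclusive for the ≥ 50%
granule fraction. "Stable substrate and nutrient removal" has no formula in
the field definition, so it is operationalised as a boolean input, with a
helper computing a rolling coefficient of variation (default: CV < 10% over
5 measurements). The start-up day scan requires the classifier to pass for
a persistence window (default 2 consecutive measurements). Negative removal
efficiencies are reported and logged, never clamped — they are data
anomalies worth surfacing. Cycle counts round half-up to one decimal
(5.6 h → 4.3 cycles/day). A zero solids-wastage denominator in the SRT
balance returns `inf` rather than raising: an SBR that loses no solids has
unbounded retention, which is a meaningful state, not an error.

On noisy sludge series, the *precision* of the detected start-up day is
limited by the slope of the binding criterion at its crossing: a shallow
SVI decay (large τ, asymptote near 90 mL/g) makes the crossing day
ill-determined by tens of days regardless of detector quality. The recovery
test therefore uses steep low-noise curves where "within one sampling
interval" is a meaningful bar; for shallow noisy curves only existence of a
detection is asserted.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data at
the design scale above (4 reactors × 58 weekly samples × 50 taxa). Seed
replication counts are 50 studies for parameter recovery in the test suite
and 20 in the acceptance script, 500 replicates for Mantel-null and type-I
calibration in the suite and 200 in the script — sizes at which the
binomial error of the estimated rates is well below the asserted margins.

## Known limitations

* The pipeline analyses one aggregate fraction per time series; run-restart
  events (a reactor re-seeded mid-study) must be split into separate series
  by the caller.
* BIOM support is v1 (JSON) only; HDF5-based BIOM v2 is out of scope.
* The Mantel test recomputes the permuted statistic in pure Python/NumPy
  per permutation; for matrices beyond a few hundred samples a specialised
  implementation would be faster.
* PCoA explained fractions ignore negative eigenvalues; with strongly
  non-Euclidean dissimilarities the reported fractions overstate the
  variance captured.
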