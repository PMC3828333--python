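# Methods

`cytostrat` implements a cytokine-panel stratification analysis for septic
shock cohorts: patients measured on a 39-analyte multiplex bead panel at two
timepoints (enrollment "baseline" and 24 hours) are clustered into subgroups
by overall cytokine profile, and the subgroups are characterised by
statistical comparison, clinical-feature enrichment, survival, subgroup
transitions, minimal logistic marker models, and severity-matched mortality
contrasts.

## Assay preprocessing

Multiplex bead assays report concentrations in pg/mL with three kinds of
censoring: values below the lower detection limit (`<x`), above the upper
limit (`>x`), and exact zeros. The package resolves these as follows:

* limit-censored cells keep the limit itself as their working value;
* zero cells are replaced by half the smallest nonzero value observed over
  **all** analytes and patients jointly, so that a logarithm is defined.
  When both timepoints are analysed together the minimum is taken over
  their union (per-matrix scoping is a config switch).

Censor flags are preserved after resolution for provenance. Concentrations
are converted to picomolar as `pM = 1000 · (pg/mL) / MW(Da)` using
mature-peptide molecular weights from the analyte catalog shipped with the
package (recomputation from sequences is out of scope; the catalog is a
plain TSV and can be replaced). All downstream statistics operate on
log10 pM values, which are approximately normal for these heavily
right-skewed measurements.

## Patient subgrouping

Patients are clustered agglomeratively on per-analyte z-scored log10 pM
values (z-scoring prevents high-abundance analytes from dominating the
Euclidean distance). The dendrogram is cut at a user-chosen k — k is never
auto-selected; an optional silhouette report aids the choice. Clusters are
then relabelled **Low < (Medium) < High** by the cluster-wise median of each
patient's median standardized level, so labels reflect overall cytokine
burden; exact ties break by cluster size descending, then lowest cluster
index.

Default distance is Euclidean and default linkage is **Ward**. Complete and
average linkage are available via config, but Ward is the default because
in repeated simulations with realistic censoring (a ~20% spike at the lower
limit plus half-minimum zero fills) complete linkage was erratic at
recovering planted compact subgroups, while Ward recovered them reliably.
Analytes are clustered on the transposed standardized matrix with
correlation distance by default.

## Subgroup comparison tables

Per analyte and contrast (e.g. High vs Low): medians and interquartile
ranges in pM, the ratio of unrounded medians, Welch's unequal-variance
t-test on log10 values (Welch–Satterthwaite df, two-sided), and
Benjamini–Hochberg adjustment. The BH family is the 39-analyte set within
one contrast at one timepoint, matching the per-table presentation
convention; pooling across contrasts is a config option.

## Enrichment

Over-representation of categorical clinical features in patient subgroups
(and of pathway memberships in analyte clusters) is tested with the
hypergeometric upper tail P(X ≥ k) for k feature-positives in a cluster of
n, out of K positives among N patients. Only the upper tail is tested;
depletion is reported descriptively via fold-enrichment < 1. Multi-level
categorical features are expanded to one-vs-rest indicators; day-28 and
day-90 death flags are included as features. BH correction is applied over
the full feature × cluster family per timepoint. Pathway membership is a
user-supplied two-column table — no database access is performed.

## Survival and transitions

Kaplan–Meier curves use the product-limit estimator (via lifelines).
Between-group differences use the G-rho family of weighted rank tests with
weights S(t−)^rho from the left-continuous pooled KM estimate; rho = 0 (the
default, and the only setting used by the pipeline) is the standard
log-rank test. The k-sample statistic is the quadratic form of the first
k−1 observed-minus-expected sums in the inverse of their hypergeometric
covariance, referred to chi-squared with k−1 df. The implementation is
cross-checked in the test suite against lifelines' independent log-rank and
against hand-computed small examples.

The transition analysis cross-tabulates each patient's baseline subgroup
against their 24-hour subgroup. Per cell it reports n, day-90 deaths and
mortality %, and compares the cell's survival against (a) the remaining
members of its baseline subgroup and (b) the remaining members of its
24-hour subgroup. A rank test requires disjoint groups, so the reference
excludes the cell's own patients; a cell whose complement is empty gets
p = NaN.

## Marker models

One-vs-rest logistic regression (in-the-subgroup vs not) reduces the panel
to a minimal marker model. Greedy forward selection starts from the best
single analyte by likelihood and accepts an addition only if, after refit,
every non-intercept coefficient remains Wald-significant at 0.05; accepted
terms are never dropped (pure forward). If no single analyte yields an
all-significant model, pairwise concentration products (pM²) join the
candidate pool — a product may coexist with its factors, which is how an
interaction with reversed sign relative to its marginals can be expressed.
If nothing is admissible the intercept-only model is returned flagged
non-converged.

Concentrations enter in raw pM (products in pM²), so reported coefficients
can be of order 10¹² and beyond; internally each column is divided by its
maximum for numerical stability and coefficients are mapped back to the raw
scale (the fit is invariant to this rescaling). The solver is Newton
maximum likelihood with an L-BFGS fallback; quasi-separation (log-likelihood
per observation above −10⁻⁴) or non-finite standard errors set
`converged=False` rather than silently returning a fit.

Discrimination is summarised by the Mann–Whitney AUC (ties count ½). The
permutation test permutes outcome labels, refits the fixed-term model, and
records the training AUC per permutation; the empirical p-value is
(1 + #{null ≥ observed}) / (n_perm + 1). Because the model is refit on each
permutation, the null mean sits slightly above 0.5 (refit optimism, ~0.51 at
n = 363 with one term) — the observed null spread (sd ≈ 0.02–0.03) is what a
significant-but-weak marker must beat.

## Severity-matched mortality

To ask whether subgroups predict death beyond illness severity, patients
are repeatedly subsampled so that every subgroup contributes the identical
multiset of APACHE II scores: for each score present in *all* subgroups,
the minimum per-subgroup count at that score is drawn without replacement
from each subgroup (min-count is the only rule guaranteeing identical
numbers and feasibility). Day-28 mortality (day-90 by config) is compared
between each subgroup and the reference (High) subgroup — and for the
pooled non-reference subgroups ("Low+Medium") — by the two-sided Fisher
exact test. The odds ratio is the sample cross-product ad/bc with a
Haldane–Anscombe 0.5 correction when any cell is zero (a conditional-MLE
variant may differ slightly and is reserved as a config flag). Over
(default) 100 iterations, odds ratios and p-values are summarised by their
medians and empirical 2.5–97.5 percentile intervals; the intervals reflect
resampling variability conditional on the one realized cohort. Iterations
with a degenerate table (zero margin) are redrawn and counted.

## Synthetic cohorts

No public accession exists for the plasma dataset this analysis design
targets, so the `synthetic_cohort` module generates cohorts with the
statistical structure the analysis assumes. The named `vasst_like` spec
emulates a 363-patient paired-timepoint septic-shock cohort:

* **Subgroups and transitions.** Three baseline subgroups with proportions
  192/124/47 and two 24-hour subgroups; the row-stochastic transition
  matrix realises the published cell frequencies (Low stays Low 188/192,
  Medium splits 90/34, High stays High 43/47).
* **Concentrations.** Per analyte and subgroup, log-normal with median
  parameterization (log-mean = log median) so spec medians are directly
  interpretable. Medians for 22 analytes come from the published
  per-subgroup tables (pM); the remaining 17 get plausible scales with
  8× High/Low and 3× Medium/Low ratios. log10 SDs derive from published
  IQRs (IQR/1.349) clipped to [0.05, 0.6]: the widest published IQRs span
  more than 1.5 decades and are treated as heavy-tailed substructure
  rather than pure log-normal spread — modelled as iid noise at that width
  they would erase subgroup structure the source data demonstrably had.
* **Correlation.** A single shared latent severity factor per patient and
  timepoint with loading 0.2 induces within-subgroup inter-analyte
  correlation; combined with the between-subgroup shifts this yields a
  cohort-wide mean inter-analyte log-correlation of ≈ 0.4.
* **Censoring.** Per-analyte detection limits are placed at the 0.20 and
  0.996 quantiles of the baseline concentration mixture (solved by root
  finding on the mixture CDF), producing ~20% below-limit and ~0.4%
  above-limit readings; zeros are injected at 0.5%.
* **Clinical features.** Bernoulli per baseline subgroup, with prevalences
  chosen so cohort-wide rates match the published patient-characteristics
  table (e.g. severe septic shock 0.45/0.67/0.85 per subgroup → ≈ 56%
  overall) and the High subgroup is enriched for shock, renal failure,
  coagulopathy, blood-culture positivity and immunocompromise.
* **Survival.** Exponential per 24-hour subgroup with administrative
  censoring at day 90; rates matched to ≈ 31% (Low) and 60% (High) day-90
  mortality. A constant hazard cannot simultaneously match the published
  day-28 and day-90 High-subgroup rates; day-90 was matched because the
  transition table is reported at day 90.
* **APACHE II.** Integer scores from rounded normals per baseline subgroup
  (means 24/26/29, SDs 5/5/6, clipped to [10, 50]).

What the generator does **not** emulate: mechanistic immune dynamics,
time-continuous trajectories, plate/batch effects, non-log-normal tails,
and structured missingness. Passing recovery tests therefore shows the
pipeline's statistics behave correctly under the assumed generative
structure — not that real plasma data satisfy that structure.

## Numerical choices and degenerate inputs

* Welch's test with zero variance in both groups returns p = 1 when means
  agree and errors otherwise.
* The hypergeometric tail uses the scipy survival function (log-space
  internally), stable for populations up to 10⁵.
* Dendrogram cuts are deterministic given input order; generic exact ties
  in merge heights follow the linkage implementation's lowest-index order.
* The G-rho covariance term skips event times with one subject at risk
  (the hypergeometric variance is 0/0 there); the quadratic form uses a
  pseudo-inverse so collinear groups do not crash.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; resampling iterations use substreams drawn
  from the master generator, making summaries reproducible and
  order-invariant (percentiles are computed on sorted values).

## Problem sizes

The default test suite and the acceptance script run the full synthetic
cohort at its native size (363 patients × 39 analytes), 100 permutations
for the AUC null, 100 matched-resampling iterations, and reduced sizes
(e.g. 120–200 patients, 10–20 iterations) for end-to-end pipeline checks;
convergence checks of the generator use up to 3000 patients. A complete
pipeline run on the default cohort takes well under a minute on one CPU.

## Known limitations

* The ordered Low/Medium/High labelling assumes the clustering axis is
  overall burden; clusters separated by *pattern* rather than level would
  be labelled arbitrarily by this statistic.
* Forward selection never drops previously accepted terms; with strongly
  correlated analytes the selected set is not unique, and no
  cross-validated assessment is performed (deliberately out of scope).
* The matched-mortality intervals are conditional on the realized cohort;
  they quantify resampling noise, not cohort-level sampling error.
* Enrichment tests are marginal per feature; correlated features are not
  jointly modelled.
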