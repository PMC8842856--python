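# Methods

## The model

We treat a COPD cohort as a finite mixture of four latent clinical profiles.
Each profile specifies, for every clinical variable, a truncated-normal
sampling distribution on the instrument's range; counts of yearly
exacerbations and hospitalisations are Poisson; sex and smoking status are
categorical. A cross-sectional cohort is an i.i.d. draw from this mixture
with fixed per-profile counts (77/93/105/77 by default, 352 in total). A
longitudinal subsample (90 participants by default, stratified 26/24/23/17
across baseline profiles) is followed over 6 monthly visits: the latent
profile evolves as a first-order Markov chain that stays put with a
per-profile monthly probability and otherwise moves uniformly to a
clinically adjacent profile (1↔2, 1↔3, 2↔3, 3↔4 by default; the topology is
configuration). At each visit the re-measured variables (CAT, mMRC,
QMS %pred, 1minSTS %pred, and FEV1 %pred in the generator) are redrawn from
the current profile's distribution; everything else is carried from
baseline.

## Calibration of the generator

Published per-profile summaries parameterise the default profiles:

* Median (q1–q3) summaries become truncated normals with
  `scale = (q3 − q1)/1.349` (the normal-equivalent IQR). The stored
  `location` is the target **median**: the sampler solves for the Gaussian
  mean whose truncated distribution has that median, so calibration survives
  asymmetric truncation (pack-years, bounded below at 0, is the extreme
  case). Integer instruments (CAT, mMRC, CCI, HADS, BPAAT) are rounded
  half-up after truncation; boundary medians (e.g. BPAAT 0) keep the
  continuous target 0.3 units inside the range so rounding reproduces them.
* Mean ± SD summaries (SGRQ total) are used directly.
* QMS and 1minSTS %predicted marginals are not published — only the share of
  each profile below the 70 %pred cut-off. The location solves
  P(X < 70) = share at an assumed SD of 20 %pred, a typical between-patient
  spread for these normalised measures.
* Poisson event rates (1.0/1.3/0.55/0.45 exacerbations, 0.12/0.13/0.12/0.045
  hospitalisations per year) reproduce the published exacerbation quartiles
  and the per-profile share of high-risk GOLD groups C+D.
* Monthly stay probabilities {0.93, 0.92, 0.95, 0.97} are a one-off
  calibration chosen so that simulated per-profile stability scores
  approximate the published ordering (profile 2 least stable, profile 4 most
  stable); they are not estimated transition rates.

Variables are sampled independently within a profile by default (only
marginals are published). A Gaussian-copula correlation matrix can be
supplied in the configuration for sensitivity analyses. Independence is the
generator's main idealisation: real severity measures correlate within
profile, so the synthetic eigenvalue spectrum is flatter and the clusters
are somewhat harder to separate than in real data. Passing tests therefore
demonstrate correctness of the pipeline's machinery and recoverability of
the planted structure, not clinical performance on real cohorts. Dropout,
medication classes, oxygen/ventilation therapy and sex-specific
distributions are deliberately not modelled.

## Profile discovery

The 13 clustering variables are z-scored (population SD; a zero-variance or
missing value is an error naming the offending column/row) and decomposed by
PCA on the correlation matrix, with eigenvector signs fixed so the
largest-magnitude loading is positive. Components are retained by the Kaiser
rule (eigenvalue > 1) by default. A fixed cumulative-variance threshold
(e.g. 80%) is available, but on the default generator's flat spectrum it
retains ~8 of 13 components, several of which are noise; that measurably
blurs the planted structure (cluster-vs-latent agreement drops from
~0.85 to ~0.7 and the induced tree's validation accuracy below its floor),
which is why Kaiser is the default here.

Clustering is classic PAM (k-medoids): greedy BUILD seeding, then
best-improvement SWAP passes over all (medoid, non-medoid) exchanges until
no swap strictly decreases the summed Euclidean distance to medoids; ties
break to the lowest row index. PAM, like the canonical R implementation, can
terminate in a local optimum on unstructured data (verified: both return the
identical suboptimal medoid set on such a case); on clustered data it
attains the exhaustive optimum.

k is selected with the gap statistic: `W_k` is the pooled within-cluster sum
of squared distances convention (equivalently the within-cluster sum of
squares about centroids), and B reference datasets (default 100) are drawn
uniformly over the data's principal-axis-aligned bounding box. The default
selection rule is the one-standard-error rule — the smallest k with
`gap(k) ≥ gap(k+1) − s_{k+1}`. This rule is deliberately conservative and
known to undershoot whenever the gap curve is flat or dips before its peak;
on the default synthetic cohort the gap curve's *maximum* sits at k = 4 in
every seed we examined while the one-SE rule frequently stops at k = 2
because the k = 3 → 4 rise is within one standard error (profiles 3 and 4
overlap on most variables). `rule="firstSEmax"` and `rule="globalmax"` are
exposed; no rule choice makes the k = 4 selection robust on these study
conditions, so the conservatism is reported rather than hidden.

Cluster ids are mapped to the canonical numbering deterministically: highest
median CAT → profile 2 (ties by higher median HADS-A); of the rest, lowest
median age → profile 4; of the remaining two, lower median FEV1 %pred →
profile 1, the other → profile 3.

## Treatable traits

Trait predicates follow the instrument cut-offs literally: `≥` at lower
bounds, strict `<` at upper bounds (GOLD grade boundaries at 80/50/30 %pred
are inclusive below). Frequent exacerbations (≥ 2 exacerbations or ≥ 1
hospitalisation per year) and the GOLD high-risk axis share one predicate. A
trait whose inputs are missing is reported as *not evaluable* rather than
absent, and prevalence denominators count evaluable participants only. A CCI
of 0 lies below the published bands and is reported as mild with a warning.

## Decision tree

Variable importance is permutation importance from a bagged ensemble of
fully grown Gini trees (out-of-bag accuracy drop per permuted variable,
averaged over trees; deterministic under seed). The top 3 variables (count
configurable) feed a greedy binary Gini CART with thresholds at midpoints of
sorted unique values and the convention `value < threshold → left`,
`≥ → right`; candidate trees of depth 2..max (default 3) are compared on a
stratified 70/30 validation split and the most accurate kept. Per stratum
the training size is `round(0.7 · n)`, so 352 participants yield 246–247
training rows. Agreement between tree and cluster profiles is Cohen's kappa
with the bands poor (< 0), slight (≤ 0.20), fair (≤ 0.40), moderate
(≤ 0.60), substantial (≤ 0.80), almost perfect (> 0.80); exact observed
agreement is kappa 1 by convention.

The fixed published allocation tree (CAT ≥ 18 → one branch; otherwise age
≥ 65 then FEV1 ≥ 48 %pred) ships with a **reconstructed** leaf-to-profile
map (CAT ≥ 18 → 2; older/low FEV1 → 1; older/preserved FEV1 → 3;
younger → 4), chosen for consistency with the per-profile medians. The
original figure's mapping is not machine-readable, so the map is
configuration, not code, and should not be read as the source tree's exact
leaves.

## Stability

The allocation tree classifies every participant at each of the 6 follow-up
visits; baseline (timepoint 0) is excluded from the score. Monthly visits
re-measure only CAT, mMRC, QMS and 1minSTS in the emulated protocol, so by
default the participant's baseline FEV1 is substituted into the tree at
follow-up (`fev1_source="baseline"`; set `"record"` to use re-measured
values where they exist). Participants missing any required timepoint are
excluded and logged. The stability score is modal-profile months / 6
(tie-break: the profile that reaches the modal count earliest); movement
categories are fully-stable (1 distinct profile), two-profile, and
three-or-more, with a "predominant" flag when the modal profile covers at
least 3 of 6 months. Cohort summaries report category proportions, mean ±
SD of the percentage score, per-modal-profile means, baseline counts and a
textual flow table of month-to-month moves (replacing a flow diagram).

Under the default conditions this yields a mean stability of ~81% with the
per-profile ordering 2 < 1 < 3 < 4 and roughly a third of participants fully
stable; month-to-month label changes come from both latent profile moves and
the i.i.d. re-measurement noise, which makes fully-stable trajectories rarer
than the latent chain alone (~74% of latent trajectories never move) would
suggest.

## Numerical and design notes

* All randomness flows from one root seed; stages derive independent
  generators via spawn keys, so every artifact is bit-reproducible.
* PAM assignment ties go to the lowest medoid index; CART split ties to the
  lowest threshold; modal-profile ties to the earliest profile.
* `gap_statistic` requires B ≥ 10 and returns k = 1 with a warning on
  degenerate (single-point) data; empty clusters contribute zero dispersion
  with a warning.
* The acceptance script reports the CAT/age cut-offs recovered by a depth-3
  CART on one default cohort (n = 352). The population-optimal root CAT
  split of the calibrated mixture is 17.5 (rounding to 18), but the Gini
  profile is nearly flat between 16.5 and 19.5, so single-cohort estimates
  scatter by roughly ±2 points; the test suite therefore checks the 5-seed
  average.
* Problem sizes in the tests (10⁴ draws per profile for calibration
  recovery, B = 25–50 reference draws, 5-seed repetitions) keep the full
  suite around a minute while leaving Monte-Carlo error well inside the
  asserted tolerances.

## Known limitations

Within-profile independence (above) is the dominant simplification; the
one-SE gap rule's conservatism on overlapping profiles follows from it and
from the genuine profile 3/4 overlap in the published summaries. The
published tree's leaf map and the latent transition matrix are
reconstructions; both are configuration. Trait prevalences inherit any
mis-calibration of the marginal distributions, and no treatment-allocation
logic is modelled.
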