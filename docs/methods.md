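# Methods

This note documents the models, the numerical choices, and what the
synthetic-data layer does and does not emulate.

## Signature derivation

The co-expression module is defined by Spearman rank correlation of every
feature against the anchor feature, with membership at |ρ| > τ. The
threshold is two-sided because both positively and negatively co-regulated
genes carry pathway information; τ defaults to 0.3 and is configurable.
Ties are handled by average ranks; constant features have undefined rank
correlation and are excluded with a warning. Because only ranks enter, the
module is invariant under any strictly monotone transform of the anchor.
When several probesets map to the anchor gene, the caller is expected to
pass the highest-variance one.

The knockdown differential fits, per feature, an ordinary least-squares
model `expression ~ condition (+ line)`, the cell line entering as a fixed
blocking factor whenever more than one line is present. This is a plain OLS
with no variance moderation — a deliberate simplification of
moderated-t/empirical-Bayes pipelines; with the strong planted effects used
throughout (|log2FC| ≥ 2 floor) moderation changes little, but the residual
degrees of freedom matter: a paired 3-line design with a single array per
condition leaves 2 d.f. and essentially no multiple-testing power, which is
why the default simulated design has three knockdown clones plus one
control per line (12 arrays, 8 d.f.). Two-sided p-values on the knockdown
coefficient are Benjamini–Hochberg adjusted across features; "significant"
means adjusted p < α (default 0.05) and "signature grade" additionally
|log2FC| ≥ λ (default 2).

The signature intersects the two: high = pos-module ∩ {signature-grade
down}, low = neg-module ∩ {signature-grade up}, each ordered by |ρ|
descending with the gene id as a deterministic tie-break. Every member
therefore satisfies ρ·log2FC < 0 (the inverse-expression law), which the
test suite asserts as an invariant. An empty intersection on both sides is
an explicit error rather than an empty object.

Class-vs-class disease signatures use the same row-wise OLS with a
two-level class indicator, BH control (default FDR < 1e-4 for
disease-signature derivation), direction = sign of the class coefficient,
and ranking by |t|. Note that at FDR q the expected precision against a
planted truth is exactly 1 − q, so recovery assertions are made at a
stricter q than the detection default.

## Nearest template prediction

Genes are standardized to mean 0, SD 1 across the cohort (the classifier is
cohort-calibrated, not single-sample-absolute). The two templates are ±1
vectors over the signature union and are antipodal, so the cosine to one
determines the cosine to the other; the signed score d_high − d_low is
anti-symmetric under swapping templates and negative for high-activation
samples.

Significance uses random gene-sets of the same size drawn from all measured
genes, seeded, with the add-one estimator p = (1 + #{d ≤ d_obs}) /
(n_perm + 1) so p is never zero. One subtlety is load-bearing: the observed
statistic is the distance to the *nearer* of two templates, a minimum over
two correlated statistics. The permuted sets must be scored with the same
min-over-templates statistic (equivalently 1 − |cos|); scoring them against
the selected template only would double the type-I rate (~11% measured at
a nominal 5%). With the min-statistic null, measured confident-call rates
on pure-noise cohorts sit at ~4–6% at α = 0.05 with 1000 permutations.

Confidence is judged on the raw permutation p (the BH-adjusted FDR is
reported alongside); samples with p ≥ α are `unclassified`. A sample with
less than 50% of the signature genes measured is `unclassifiable` rather
than silently scored. The permutation pool changes with gene universe and
seed, so p-values — but not distances or scores — depend on both.

## Survival and diagnostic statistics

Kaplan–Meier estimation, the logrank test and Cox fitting delegate to
lifelines; the package owns what sits on top. The KM median is the first
time S(t) ≤ 0.5 and is reported as infinite when not reached. BIC for a Cox
model is −2·logL + k·ln(n_events): the effective sample size of the partial
likelihood is the event count, and the covariate-free null model (k = 0)
gets its partial log-likelihood from an in-package Efron-ties formula that
matches lifelines' fitted models (cross-checked in the tests via the
likelihood-ratio identity). Categorical covariates are dummy-coded with a
dropped reference level, so k counts estimated coefficients. The best model
is flagged "meaningful" when the runner-up trails by ≥ 10 BIC points.
Non-converging candidates are excluded with a warning rather than failing
the comparison.

Relative odds: samples sorted by score with a stable sort and the sample id
as tie-break; the extreme groups are the top and bottom ⌈n/5⌉ (rank-based
fifths, equal-sized by construction). The odds ratio is computed from the
integer 2×2 counts, so it equals the brute-force table computation exactly;
degenerate proportions (0 or 1) yield 0/∞/NaN with an explicit flag instead
of an exception. Contingency enrichment uses chi-square without continuity
correction, switching to Fisher's exact test for 2×2 tables with any
expected *or observed* cell below 5 (the observed-cell condition covers
perfectly separated tables whose expected counts sit exactly at the
boundary).

## Kinome pipeline

Peptides map many-to-many to kinases via a flat two-column table; measured
but unmapped peptides are kept in an orphan bucket and logged, and a kinase
appears in the output iff at least one of its peptides was measured. The
published description of the rank-based summary is under-specified, so the
concrete reading here is: within each kinase, peptides are clustered as
connected components of the Pearson-correlation graph at r ≥ r_min
(default 0.6, singletons allowed, constant peptides become singletons);
within each condition all peptides are ranked across the whole array
(average ranks, scaled by the peptide count so the top peptide scores 1);
a cluster scores the mean scaled rank of its members and the kinase the
cluster-size-weighted mean — algebraically the mean scaled rank of all its
peptides, with the cluster trace retained for inspection. Ranking across
the full array makes activities comparable between kinases and invariant
under monotone intensity transforms. Differential regulation is an
ordinary per-kinase regression of activity on dose (μM; DMSO = 0), two-sided
p on the slope, significant at raw p < 0.1 (unadjusted, matching the
screening intent), direction = slope sign. Prioritization orders by
(significant, |slope|) and annotates membership and direction-concordance
against the transcriptomic signature (a kinase rising where the
low-activation template rises is a concordant resistance candidate).

## Synergy analytics

The median-effect model fa/fu = (D/Dm)^m is fitted on the log-linearised
form log10(fa/(1−fa)) = m·log10 D − m·log10 Dm. Points with fa outside
[0.005, 0.995] carry no stable logit information and are excluded from this
stage (≥ 3 usable points required). The log-linear least squares is
weighted by (fa(1−fa))² — the delta-method inverse variance of the logit
under additive fa noise — and the parameters are then polished by nonlinear
least squares on the fa scale over all points (the standard dose–response
regression). On noiseless data both stages are exact; on noisy titrations
the fa-scale refinement is what keeps IC50 (= Dm) recovery within ~5%
at fa-noise SD 0.02 on a 10-point titration, because the logit transform
otherwise amplifies noise at the no-effect end of the curve.

The combination index uses the mutually exclusive (two-term, Loewe-form)
expression CI = d₁/Dx₁ + d₂/Dx₂ with Dxᵢ = Dmᵢ·[fa/(1−fa)]^(1/mᵢ); the
three-term non-exclusive variant is not implemented. A sham combination of
a drug with itself is exactly additive at any fa, which the tests assert
across random parameters. Verdicts use an additive band of CI ∈ [0.9, 1.1]
around the theoretical boundary. A combination fa at a clipping boundary is
flagged unreliable. Because dCI/dfa scales as 1/(m·fa(1−fa)), single-point
CI estimates at extreme fa are ill-conditioned; recovery of a planted
interaction is therefore judged on the mean CI of the Fa–CI curve, and the
synthetic combination design samples the well-conditioned fa ≈ 0.3–0.7
region.

Concordance is the fraction of a drug's top-k genes present in the
reference's top-k with the same direction; discordance the fraction of the
disease signature's top-k reversed in the drug's top-k (k default 250,
clamped to the shortest signature in play). These are this package's
concrete, documented reading of "signature concordance/discordance" — the
external platform that popularised the idea does not publish its exact
normalisation, and no numeric equivalence with it is claimed. Ranking is
lexicographic: discordance descending, concordance ascending, drug id.

## The synthetic-data layer

All generators draw from named substreams of one seed
(`SeedSequence(seed, spawn_key)`), so outputs are bit-reproducible and
adding a generator never perturbs another. What they emulate, and the
headline defaults:

- **Cohort**: a latent activation a_s (sign = class, magnitude |N(1, 1)|)
  drives n = 100 planted genes per direction at β = 2 log2-units over
  N(0, 1) gene noise in a 5000-feature, 300-sample cohort; the anchor gene
  is a_s plus small noise, guaranteeing the co-expression module is
  recoverable. Survival is exponential with class medians 8.04 and 57.48
  months — the motivating split between pathway-high and -low glioma
  patients — with uniform censoring on (0, 3× the larger median] applied to
  a 20% subset, independent of class. Covariates (WHO grade, IDH status,
  Karnofsky, age) are class-correlated where the motivating cohorts are
  (grade, IDH) and noise otherwise. Explicit planted gene lists let a
  validation cohort share a discovery cohort's signature biology, which is
  what cross-cohort classification accuracy means.
- **Knockdown**: three lines, each one non-targeting control and three
  knockdown clones; planted responders shift by ∓3 log2-units opposite to
  their co-expression direction over 0.2 noise, with a 0.3-SD line effect.
- **Kinome**: 144 kinases × 4 peptides over doses (0, 0.1, 0.5, 1, 2) μM in
  duplicate. Peptides of one kinase share a latent per-condition wiggle
  with a 9:1 shared/noise variance ratio (within-kinase correlation ≈ 0.9).
  Planted kinases trend at 1.5 intensity units/μM — large against the
  rank-space null slope noise — and start from the array's mid intensity so
  their dynamic range is not censored at the rank ceiling/floor.
- **Dose–response**: 10-point titrations spanning 10⁻⁴–10² μM from known
  (m, Dm); combination points are constructed so the Loewe sum equals ψ
  exactly (ψ = 1 additive, ψ < 1 planted synergy), at nine constant-ratio
  points in the mid-fa region.
- **Library**: uniform random signed rank-signatures plus a planted perfect
  reverser of the disease signature and a planted copy of the reference.

What the generators deliberately do **not** emulate: array-level artifacts
(probe effects, batch structure, normalisation), heavy-tailed or
intensity-dependent noise (all noise is Gaussian in log2/intensity/fa
space — an assumption, since the motivating assays do not state their noise
model), gene–gene correlation beyond the planted module, non-proportional
hazards, or saturating/biphasic dose–response shapes. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated models, not robustness to real-data pathologies.

## Problem sizes and determinism

The test suite and the acceptance script run the pipeline at the sizes
above (cohorts of 200–500 samples, 1000-permutation NTP, 5 × 144-kinase
null arrays aggregated so the binomial error on the 10% calibration rate is
~1%, 20 seeds for planted-kinase recovery, 1000 random instances for the
relative-odds oracle); everything is seeded and completes in well under a
minute on one core. Degenerate inputs (constant features, empty mappings,
saturated fa, zero events, single factor levels) raise typed errors or are
flagged, never silently dropped into results.
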