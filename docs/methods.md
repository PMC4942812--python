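# Methods

`metcouple` implements a two-step machine-learning pipeline for studying
*enzyme–metabolite coupling*: the statistical association, across matched
tissue samples, between a metabolic enzyme gene's expression and the
abundance of a metabolite of the reaction it catalyzes.  The pipeline is
built around a genome-scale metabolic reconstruction in which genes map to
metabolites through shared reactions, and is exercised end to end on
synthetic cohorts with planted couplings so that every stage has a ground
truth.

## The network model

A reaction carries a flat set of catalyzing genes (no boolean
gene–protein–reaction logic), substrate and product metabolite sets,
a pathway label, reversibility, and a predicted standard Gibbs energy
ΔG⁰ (consumed as an input column, kJ/mol).  Metabolites are compartment
instances — `glc[c]` and `glc[e]` are distinct species — and the analysis
layer restricts to cytosolic metabolites by default, with an option to
extend to all compartments.

Two derived objects drive everything downstream:

- a **connected GM pair** (gene *g*, metabolite *m*): *g* catalyzes at
  least one reaction that consumes or produces *m*;
- an **RGM triplet** (reaction *r*, gene *g*, metabolite *m*, role):
  one per (reaction, catalyzing gene, participating metabolite, role);
  a metabolite that is both substrate and product of a reaction (e.g.
  a transporter) yields two triplets, one per role, because the
  substrate/product flag is a role-specific classifier feature.

Every entity receives a deterministic 1-based `network_index`
(lexicographic by identifier).  Reconstructions do not define a canonical
position, and the index only ever serves as a categorical identifier, so
any fixed deterministic ordering is equivalent.  Omics identifiers map
onto the model first through HMDB keys, then KEGG for metabolites, and
through Entrez for genes; an identifier matching two network entities is
an error, never a silent choice.

## Raw-data association layer

Per condition stratum (all / noncancerous / cancer), every measured
connected pair gets a midrank Spearman ρ with a two-sided p-value and a
Benjamini–Hochberg q within the stratum.  For n ≤ 9 samples the p-value
is the exact permutation tail (all n! orderings, midranks under ties);
above that, the usual t approximation with n − 2 degrees of freedom.
Constant vectors make the correlation undefined; such rows are kept with
ρ = 0, p = 1 and a flag so table shapes are stable.

**Coupling enrichment (permutation null).**  The real statistic counts
connected pairs with unadjusted p < α (default 0.05).  Each of n = 1000
permutation rounds permutes gene labels and draws C = #pairs random
gene–metabolite combinations without replacement — because a uniform
pair draw composed with a label permutation is again a uniform pair
draw, the implementation draws C distinct cells of the all-pairs grid
directly.  The empirical p-value is the add-one estimator
(r + 1)/(n + 1), where r counts rounds *strictly* exceeding the real
count (ties do not increment r).  Real and null counts both use the
asymptotic Spearman p so they are exchangeable.

Three further contrasts mirror standard reporting:

- *highly expressed gene enrichment*: upper-tail hypergeometric overlap
  between genes carrying a significant association and genes in the top
  quartile of mean expression (the quartile cut is a parameter; no
  canonical definition exists);
- *substrate vs product shift*: one-sided rank-sum test of product-role
  against substrate-role values (confidences or correlations);
- *differential-expression relation*: per gene, coupling strength is the
  maximum |ρ| over its pairs and differential expression is |rank-sum z|
  between conditions; the two gene-level vectors are correlated by
  Spearman.  Rank-based throughout, for consistency;
- *variance shift*: one-sided rank-sum test of expression variances of
  association-carrying genes against the rest.

## Step 1 — the RGM classifier

Each triplet is represented by 14 features: reaction position, pathway
code, ΔG⁰, reversibility; gene position, expression mean, variance,
minimum and maximum over the stratum; metabolite position, the
reaction's metabolite / substrate / product counts, and the
substrate-or-product flag.  Triplets whose pair is FDR-significant are
labeled by the correlation sign (the pair's label propagates to all its
triplets); everything else is unlabeled.

The four model-position features are categorical identifiers.  A linear
kernel cannot use a bare integer code as a category, so the default
design matrix one-hot encodes them (sized by the network); the raw
integer variant remains available (`categorical="raw"`).  This is the
single most consequential representation choice in the package: with
one-hot identities the classifier can attach evidence to *specific*
genes, metabolites, reactions and pathways and interpolate it to the
~90% of triplets whose metabolite is unmeasured, which is precisely the
role the position features play.

Training balances the classes by subsampling the majority to the
minority size (seeded), standardizes features on the training split
only, and fits a linear-kernel SVM at the conventional C = 1 (not
tuned).  Confidence in [−1, +1] is 2·P(+1|x) − 1 with P from Platt
scaling fitted on internal stratified training folds, with two
robustness guards: Platt's smoothed targets keep the slope finite on
separable folds, and the slope is constrained non-negative because an
unconstrained sigmoid fitted on a handful of fold margins can invert
the SVM's own ranking.  A clipped raw margin is the documented
alternative (`confidence_mapping="margin"`).

Cross-validation is stratified 5-fold with balancing and standardization
redone inside each fold (no leakage).  AUC, sensitivity, specificity and
accuracy are computed from the held-out decision scores — the confidence
mapping is monotone in them, so AUC is identical, but a collapsed
calibration cannot destroy a fold's metric.

**Confidence significance.**  The reference distribution is the pooled
confidence output of classifiers retrained on label-permuted data (20
permutations by default, same pipeline, seeded).  Per triplet the
two-sided empirical p is the add-one fraction of null |confidence| at or
above the observed |confidence|, BH-adjusted across triplets.

*Known limitation.*  A two-class classifier has no "no association"
state: any triplet resembling the labeled ones receives a confidently
signed score, and label-permuted models — whose training-set margins are
indistinguishable from the real ones because a high-capacity linear
model fits any labels — collapse to near-zero confidences once their
calibration sees chance-level folds.  The per-triplet empirical test is
therefore close to a global learnability test: in a learnable regime
most triplets clear it.  Consequences for dense networks are documented
under *Limitations*.

## Step 2 — the metabolite-level regressor

For each metabolite the extreme-confidence gene–reaction anchors are
selected: GR⁺ (argmax confidence over the metabolite's triplets) and
GR⁻ (argmin), ties broken by (reaction index, gene index).  A metabolite
enters prediction only when its best absolute selected confidence
exceeds the reporting threshold (default 0.5); GR⁻ is the argmin
regardless of whether it crosses −0.5.

Each (metabolite, sample) instance concatenates the two anchors'
14-feature blocks (GR⁺ first) with the gene-mean slot replaced by the
anchor gene's expression *in that sample* — the dataset-level summaries
are constant across samples and cannot drive per-sample predictions, and
the method's stated purpose is to predict levels from the pertaining
enzymes' expression.  The pure-summary variant would be sample-constant
and is not offered.  Targets are per-metabolite z-scores of
log abundances (natural log; rows containing non-positive values are
shifted by half their minimum positive value first); the z-scoring
statistics are frozen on the training cohort and reused on application
cohorts.

One pooled ordinary-least-squares model is fitted across all instances
("generalized" read as one shared model); `mode="per-metabolite"` fits
one OLS per metabolite instead.  Rank-deficient designs fall back to the
minimum-norm pseudoinverse solution with a warning.  Evaluation reports
the pooled measured-vs-predicted Spearman, per-metabolite and per-sample
Spearman families with BH within each family, and the meta-correlation
between per-metabolite performance and the metabolite's best selected
confidence.

## Graph, pathway and clinical layers

The **bipartite GM graph** has one edge per FDR-significant measured
pair; isolated measured nodes are retained.  Hubs are nodes with degree
above a threshold (default d > 4, applied to genes and metabolites
alike); hub-gene pathway enrichment is upper-tail hypergeometric with a
gene belonging to every pathway of every reaction it catalyzes, counted
once per pathway.

**Prediction-based pathway enrichment** calls a reaction regulated in a
condition when any of its triplets carries an FDR-significant
confidence, then tests each pathway's regulated-reaction overlap
(population: reactions with enumerable triplets — a triplet-less
reaction can never be called regulated), BH within condition.  The
**raw-data shift test** compares, per pathway with at least 10 measured
pairs, the noncancerous against the cancer per-pair Spearman p-value
sets with a two-sided rank-sum test ("shift" has no stated direction;
the sign is reported as the median p difference).  **Cross-dataset
agreement** is the Spearman correlation of −log₁₀ enrichment p over
pathways significantly enriched (unadjusted p < 0.05) in either dataset;
ρ is invariant to the monotone transform up to sign, so the transform
only fixes the sign convention.

The **clinical screen** dichotomizes each (predicted) metabolite at its
cohort median — ties go to the low group, deterministically — and
applies the two-group log-rank test (via lifelines), BH across
metabolites.  Each metabolite's survival signal is also compared against
the *minimum* log-rank p among its connected genes' expression (the rule
most favorable to the genes; a mean-p rule is available), and metabolites
are tested for ER⁺/ER⁻ differential levels with a two-sided rank-sum
test.

## The synthetic cohort generator

The generator emulates a matched two-condition (noncancerous/cancer)
transcriptome + metabolome study on a random bipartite-via-reactions
network (each reaction: 1–3 genes, 1–3 substrates, 1–2 products;
reversibility Bernoulli(0.3); ΔG⁰ ~ Normal(0, 10) kJ/mol; pathways as
contiguous reaction blocks; a trailing 15% of metabolites extracellular).

**Couplings.**  A condition-specific fraction of connected cytosolic
metabolites (defaults: 0 noncancerous, 0.4 cancer — emulating markedly
stronger coupling in tumors) receives a latent coupling factor f.  The
metabolite's latent value in the target condition is r·f + √(1−r²)·ε and
independent noise elsewhere; abundances are exponentiated latents, so
couplings ride a Gaussian copula under a monotone transform and planted
strengths are interpretable as population Spearman.  Strengths are drawn
from `strength_range` (default U(0.5, 0.9)) on the Spearman scale and
converted to the copula's Pearson scale via r = 2 sin(πρ/6), making the
attained population Spearman *exactly* the recorded strength.  The
primary driver gene tracks the factor exactly; up to 5 further connected
genes are co-regulated with attenuation λ ~ U(0.4, 0.8) (attained
Spearman (6/π)·asin(λr/2), recorded per pair), emulating a co-expressed
enzyme module around the metabolite.  Each gene drives at most one
metabolite, so every recorded pair strength is exact.  Planted genes
carry a ×2 expression-variance multiplier, reproducing the elevated
variance of association-carrying genes.

Signs follow `sign_policy`: `"metabolite"` (default — one random sign
shared by a metabolite's pairs, the configuration under which the
sign is learnable from metabolite identity), `"role"` (products +,
substrates −, used to plant the substrate-vs-product contrast) or
`"random"`.  Couplings are preferentially drawn (bias 0.5) from one
"hot" pathway to emulate pathway-localized coupling.

**Clinical tables.**  Survival times are exponential proportional
hazards with linear predictor Σ coef·z(metabolite) over planted hazard
links (default: 3 metabolites at log-hazard ln 2 per SD, drawn from the
coupled set); censoring is independent Uniform(0, 3.2/λ₀), ≈30% at
linear predictor zero (closed form (1−e⁻ˣ)/x = 0.3 at x ≈ 3.2).  Note
that dichotomizing a continuous ln 2-per-SD effect at the median spreads
the groups by ≈1.6 SD, so the *median-split* hazard ratio concentrates
near 2.8, not 2 — the test suite's calibration band is frozen around
that Monte-Carlo asymptote.  An ER-like binary label is Bernoulli with
logit = shift·z(one linked metabolite), default shift 2.

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: mass-spectrometry noise structure
(batch effects, drift, limits of detection, non-MCAR missingness),
boolean gene–protein–reaction logic, isoenzyme redundancy, many-to-many
coupling (a metabolite driven jointly by several independent factors),
covariate structure in survival, and the identifier messiness of real
HMDB/KEGG/Entrez mappings.  Recovery results on these cohorts bound what
the pipeline can do when its assumptions hold; they do not certify
performance on real cohorts.

## Numerical conventions

- Midranks everywhere; all rank statistics are well defined under ties.
- Exact enumeration thresholds: Spearman permutation p for n ≤ 9;
  rank-sum assignment enumeration for groups ≤ 10; asymptotics above
  (tie-corrected normal z without continuity correction, so identical
  samples give a one-sided p of exactly 0.5).
- Add-one convention for every empirical permutation p; the minimum
  reportable value at n = 1000 permutations is 1/1001.
- BH is statsmodels' step-up, capped at 1; NaN inputs are an error.
- Selection tie-breaks are (reaction index, gene index) ascending;
  median-split ties go to the low group.
- All randomness flows through explicitly passed integer seeds and
  numpy Generators; identical seeds give byte-identical outputs.

## Problem sizes in the test suite

The planted-recovery tests run on a 300-reaction / 200-gene /
60-metabolite network with 50 samples per condition (the fixed study
design), the permutation-contrast checks on a 200-pair set over a
sparser 150/250/350 network at 60 samples per stratum, and the survival
calibration on 60 metabolites at 200 samples over 50 seeds; Monte-Carlo
calibrations of the generator use up to 10⁵ samples.  These sizes were
chosen so each check has adequate power at the planted effect sizes.

## Limitations

- **Confidence scale.**  Absolute confidence thresholds inherit the
  two-class limitation described above.  On dense networks (tens of
  connected genes per metabolite) the maximum confidence over a
  metabolite's many triplets exceeds the 0.5 reporting threshold even
  for uncoupled metabolites, so the selection filter does not prune
  them; their noise rows dilute the pooled measured-vs-predicted
  correlation of step 2 well below what the coupled metabolites alone
  achieve.  Likewise the FDR-significant triplet set saturates in a
  learnable regime, flattening prediction-based pathway enrichment.
  Both effects are measured honestly by the planted-recovery tests; a
  confidence with a genuine "no-association" state would require a
  three-state or one-class formulation outside this design.
- The permutation coupling test is slightly anticonservative on
  strongly dependent pair sets (pairs sharing metabolites or co-regulated
  genes inflate the real count's variance relative to the independent
  null draws).
- The pooled regressor shares one coefficient vector across metabolites
  with heterogeneous anchor-gene scales; per-metabolite fits avoid the
  attenuation but overfit small cohorts and are therefore non-default.
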