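# Methods

This note documents the models and procedures implemented in
`darcsign`, the parameters that matter, and the choices made where the
design was genuinely open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Somatic and germline filtering

Candidate small variants carry tumour (plasma cfDNA) and normal
(leukocyte) pileup evidence. A candidate is called somatic only if all
of the following hold (`somatic_filters.FilterConfig` defaults in
brackets):

* tumour VAF strictly greater than `min_vaf` [0.02];
* at least `min_alt_reads` [10] supporting unique reads;
* depth strictly greater than `min_depth` [30×] in **both** samples —
  the wording "loci with >30× depth" is read as strict and applied to
  both sides;
* tumour VAF at least `tumour_vs_normal_ratio` [3] times the leukocyte
  VAF ("discard if less than 3×" makes the pass condition non-strict;
  a leukocyte VAF of 0 satisfies the rule trivially);
* tumour VAF at least `error_multiplier` [20] times the background
  error rate, or `repeat_error_multiplier` [40] times it when the
  variant is repeat-adjacent or its ±20 bp context is dominated
  (> 80 %, strict) by a single nucleotide. For SNVs the variant base is
  excluded from the dominance count. The error rate at a site/base is
  the mean VAF of that base across all leukocyte panel samples
  (zero-depth rows excluded); unmodelled positions use rate 0, so the
  rule passes vacuously where no panel data exist;
* mean distance from supporting-read ends to the variant of at least
  `min_end_distance` [6 bp].

Verdicts record every failed rule, so attrition is auditable; relaxing
any single threshold can only grow the pass set (property-tested).
Germline calls keep leukocyte variants with VAF in [0.30, 0.70] and
depth ≥ 40×. Indels run through the same rule set as SNVs, with the
dominance window anchored at the indel start. `repeat_adjacent` is an
input flag computed upstream; repeat discovery is out of scope.

## Mutation channels

SBS96: substitutions are normalized to the pyrimidine strand and keyed
by the flanking bases, giving the canonical 96 channels in
substitution-major order.

ID83: the 83-channel scheme. For 1 bp events the channel encodes the
(complement-normalized, C/T) base and the homopolymer context: for
deletions the label is (reference run length including the deleted
base) − 1, capped at 5 — so `1:Del:C:5` means a run of six or more C's —
and for insertions the pre-existing run length capped at 5. For ≥ 2 bp
events the length class is {2,3,4,5+} and the repeat class counts full
adjacent tandem copies of the indel sequence (both directions; capped
at 5). Deletions with at least one extra copy are repeat-mediated and
never tested for microhomology (standard precedence). Otherwise
microhomology is the longest overlap (capped at length − 1, then at 5)
between either end of the deleted sequence and the adjoining flank.
Complex substitutions and N-containing contexts are tallied as
`unclassified`, never silently dropped, so catalog counts are conserved
exactly. Double-base substitution channels are intentionally absent.

Catalogs feed the models as raw counts (not proportions); per-sample
burden is itself informative for the phenotypes of interest.

## Copy-number features

The 45-feature default schema (6+6+9+9+10+5) reconstructs the six
published category definitions with the module's own bin edges, since
the canonical per-feature list lives in controlled supplementary data;
the schema is configurable and the defaults reproduce the printed
feature names (`SegSize_10`, `CNCP_1/3/5`, `BCper10Mb`). Specific
choices:

* `BCper10Mb` tiles each chromosome independently into fixed 10 Mb
  windows and counts 3′ segment endpoints per window, excluding each
  chromosome's terminal endpoint (a chromosome end is not a break);
* `BCperCA` counts segments overlapping each arm minus one;
  centromere-straddling segments count in both arms;
* `CN`/`CopyFraction` use integer states {0..7, ≥8}; copy fractions are
  length-weighted and sum to 1 whenever segments exist;
* `SegSize` bin upper edges: 5 kb, 50 kb, 500 kb, 1 Mb, 3 Mb, 5 Mb,
  10 Mb, 20 Mb, 50 Mb, ∞;
* `CNCP` bins |Δ total copies| between 5′-adjacent segments into
  {1,2,3,4,≥5}; Δ = 0 (same total, different allelic split) is not a
  change point, because the definition operates on total ploidy.

Scar scores: HRD-LOH merges directly adjacent LOH segments (minor copy
0, total ≥ 1; gap tolerance 0) and counts merged regions > 15 Mb not
spanning the chromosome's full segmented extent. LST counts adjacent
pairs of ≥ 10 Mb segments separated by ≤ 3 Mb whose (total, minor)
state differs; an optional flag first merges sub-3 Mb interruptions
(off by default, matching the literal caption definition). Telomeric
allelic imbalance counts major ≠ minor segments reaching within 10 kb
(configurable) of either chromosome end, excluding whole-chromosome
imbalances — segment tables rarely reach base 1, hence the tolerance.
The segmentation-solution acceptance rule trusts mean ploidies outside
[1.1, 2.9] only when cellularity exceeds 0.18.

## Signature refitting

Catalog proportions are decomposed against a 96-row reference matrix by
non-negative least squares with total weight constrained to ≤ 1
(unconstrained NNLS, then an SLSQP projection only if the sum exceeds
1). Weights below the cutoff (default 0.06, matching the reference
tool's convention) are zeroed and the surviving set refit once; the
residual is the RMSE between the fitted mixture and the catalog
proportions. This replaces the reference tool's forward-selection
heuristic: the downstream rules depend on the weights and thresholds,
not on the selection path. Deficiency rules: combined weight of
signatures 6+15+20+26 ≥ 0.05 flags MMRd; signature 3 ≥ 0.05 flags
BRCA2d. The reference matrix is always an input file; nothing is
fetched.

## Classification protocol

One binary model per target label; positives are the target phenotype
and negatives everything else, including the other defect labels. The
cohort is split 40:60 (test:train) stratified on the binary label. An
exhaustive grid over the four subsampling fractions (`subsample`,
`colsample_bytree`, `colsample_bylevel`, `colsample_bynode`; values in
[0.5, 1.0], default grid {0.5, 0.75, 1.0}, test profile {0.5, 1.0}) is
scored by stratified K-fold cross-validation — 10 folds for BRCA2d, 6
for CDK12d and MMRd, reflecting positive-class availability — and
ranked lexicographically on (mean AUC desc, mean error asc, mean log
loss asc), ties resolving to the earlier grid point. "Error" is 1 −
accuracy at probability 0.5, the conventional meaning of the metric
name in boosted-tree tooling. Trees have depth 3 and learning rate
0.001 with a binary logistic objective.

Early stopping monitors validation **log loss**, not AUC: with a
learning rate of 0.001 the fold AUC reaches its plateau while margins
are still nearly zero, so AUC-based patience would fire degenerately
after a handful of trees; log loss keeps improving as the ensemble
grows. The winner is refit on the full training split for the mean
early-stopped round count of its folds. The production profile honours
the 10⁶-round cap with patience 50; the test profile caps rounds at 300
with patience 30 so desk-scale runs finish — acceptance runs use the
test profile and its results are reported as such.

The decision threshold scans F1 over {0, 0.001, …, 1} on the training
split, predicting positive at probability ≥ threshold, and returns the
minimum grid point achieving the maximum F1; the same ≥ rule is used
downstream. Feature attributions use the tree-path-dependent Shapley
decomposition built into XGBoost (`pred_contribs`); local accuracy —
per-sample attributions plus base value equal the model margin — is
asserted to 1e-4 at every use, and feature impact is the sum over
samples of absolute attributions. Models persist as a directory of
`ensemble.json` plus `metadata.json` (feature order, threshold, label,
seed, grid results); prediction enforces the stored feature order and
never reorders silently. A DDRwt model can be trained with the same
machinery but is not part of the default three-model bundle; ATMd
samples only ever appear as negatives.

## Synthetic cohort

The generator emulates the four phenotype classes (plus an
APOBEC-enriched bladder-like comparator) on a five-chromosome
coordinate genome (80–200 Mb per chromosome, defined by an arm map and
emitted as a cytoband file). Variant records carry their own ±20 bp
contexts, so no full-length reference sequence is needed; a small
synthetic FASTA (three ~1 Mb contigs with embedded homopolymers and
tandem repeats) can be written to exercise context fetching end to end.
Class programs ("strong" profile defaults):

* **MMRd** — ~1400 SNVs concentrated in C>T at NpCpG with a channel
  shape deliberately close to the ageing spectrum (their similarity is
  what makes C>T features nonspecific), ~130 one-bp C deletions in ≥6 bp
  homopolymers, ~60 T counterparts, near-diploid segments;
* **CDK12d** — ~110 SNVs, diploid backbone with ~4 focal 1–4 kb tandem
  duplications per arm, mostly +1 total copy (occasionally +3), giving
  `CNCP_1`/`CNCP_3` steps and sub-5 kb segments;
* **BRCA2d** — ~260 SNVs with a C>G-enriched spectrum peaking at
  `A[C>G]G`, ~35 microhomology deletions and ~25 long deletions,
  10–20 Mb arm pieces with 45 % LOH and 50 % whole-genome doubling;
* **DDRwt** — ~130 ageing-spectrum SNVs with a heavy-tailed burden
  (lognormal σ = 1.2, emulating wide age-related variation whose upper
  tail overlaps hypermutated burdens), 30–80 Mb aneuploid pieces, 40 %
  whole-genome doubling;
* all non-CDK12d aneuploid classes also receive sparse 20 kb–2 Mb focal
  events, so breakpoint counts alone do not identify CDK12d — only the
  sub-5 kb segment size and single-copy steps do.

Per-sample burdens are drawn as Poisson counts scaled by independent
per-program lognormal factors (σ = 0.5 unless stated): real somatic
burdens are far more dispersed than Poisson, and without that overlap a
boosted ensemble collapses onto a single perfectly separating feature
with degenerate two-valued probabilities. Every emitted record
satisfies the somatic filters by construction; a configurable fraction
of deliberate failures (sub-threshold VAF, read-end artifact, shallow
normal) supports filter testing. A "hard" profile attenuates
copy-number signal and pulls burdens toward the DDRwt range, mimicking
low tumour fraction. All randomness flows from explicit
`numpy.random.Generator` streams spawned per (seed, class, sample), so
cohorts are byte-identical across runs and platforms.

What passing tests on this generator do **not** show: robustness to
segmentation noise and purity estimation error, to alignment and
pileup artifacts, to inter-laboratory batch effects, or to phenotype
heterogeneity beyond the programmed mechanisms. The simulated classes
are cleanly separable by construction ("strong" profile); real-cohort
performance claims cannot be made from them.

## Problem sizes and numerics

Desk-scale runs use 40 samples per class (160 total), the {0.5, 1.0}
subsampling grid and the 300-round cap; these sizes keep the acceptance
run to a few minutes on one CPU while leaving every protocol element —
stratified split, grid search, lexicographic scoring, F1 scan,
attribution checks — identical to the production profile. Signature
recovery tolerances: pure columns to 1e-6, 60/40 mixtures (500
mutations) to 0.02. Copy fractions sum to 1 within 1e-9. Threshold
grids are exact rational multiples of 0.001. Cohen's d uses the pooled
(n−1–weighted) standard deviation and returns 0 for identical
degenerate groups.

## Known limitations

* The 45-feature bin edges are a reconstruction (canonical lists are in
  controlled supplementary data); the schema is configurable for users
  who have them.
* VCF ingestion expects tumour/normal `DP`/`AD` fields and a resolvable
  context; symbolic and multi-allelic ALTs are excluded with a warning
  rather than decomposed.
* The LST definition is taken literally from its caption; the common
  practice of merging sub-3 Mb interruptions first is available behind
  a flag but off by default.
* Mean read-end distance and repeat adjacency must be supplied by the
  upstream pileup stage; the package does not compute them from BAMs.
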