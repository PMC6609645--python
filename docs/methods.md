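# Methods

`metmap` implements an intra-/inter-individual metabolomics analysis for a
multi-tissue type-2-diabetes (T2D) cohort design: five tissues (visceral
adipose tissue, liver, pancreatic islets, skeletal muscle, serum) profiled
on two untargeted MS platforms (GC-MS and LC-MS) for the same donors, with
three phenotype groups defined by glycated haemoglobin (HbA1c < 5.7 % —
normoglycemic control; 5.7–6.5 % inclusive — pre-diabetes; > 6.5 % or a
medical-record diagnosis — T2D).  The primary comparison pools control and
pre-diabetes into a non-diabetes group against T2D; secondary analyses
compare the three groups pairwise and regress HbA1c on single metabolites.

## Synthetic cohorts

Because tissue-resolved human data cannot ship with a package, every stage
is exercised on synthetic cohorts whose defaults mirror the study design:
17/13/13 donors with group-wise covariate distributions (age 59±10 / 64±8 /
65±7 y; BMI 26.5±3.8 / 27.6±5.6 / 27.9±5.6 kg/m²; HbA1c 36.2±1.9 /
40.8±1.8 / 56.5±15.5 mmol/mol; GSIS 11.8±5.6 / 15.1±30.8 / 5.0±2.5), gender
fractions 7F/17, 4F/13, 4F/13, and 142 + 144 platform-disjoint metabolites.
HbA1c is generated on the IFCC mmol/mol scale, constrained into each group's
defining band, and converted to NGSP % with the master equation
(% = 0.09148·mmol/mol + 2.152); both representations are stored and the %
value is authoritative for grouping.  Tissue sample weight (100±15 mg) is a
repository choice — the design tables do not report it.

The data model is log-normal: per metabolite-tissue, log2 intensity =
μ + σ·z with μ ~ U[10, 20] and σ ~ U[0.3, 1.2] (typical MS dynamic range),
z standard normal.  Three kinds of structure can be planted, and the exact
realisation is recorded in a `truth` object:

- **Group effects** add a constant to z for the shifted group(s), so an
  effect size reads directly as a standardized difference on the analysis
  scale.  For the `PD_vs_CTRL` comparison the shift is applied to both
  pre-diabetes and T2D, producing the early-marker pattern (change appears
  at pre-diabetes and persists).
- **Correlation blocks** use a shared-factor construction
  (z = √ρ·f + √(1−ρ)·ε); a block-level shift enters through the factor, so
  each member's marginal shift is shift·√ρ.
- **Missingness** is left-censored: P(missing) is a logistic function of the
  within-table intensity rank with slope 8·w (w = `left_censor_weight`;
  w = 0 gives MCAR), intercept calibrated by bisection so the mean equals
  `overall_rate` (default 0.15 — the real data's rate is unreported, this is
  a typical untargeted-MS figure).

What the generator does *not* emulate: chromatographic peaks and spectra,
retention-time drift, run-order and batch effects, heavy-tailed or skewed
intensity noise, and biologically structured covariate–metabolite coupling.
Passing tests therefore demonstrate the statistical machinery under the
assumed model, not robustness to instrument artefacts.

## Transformation chain

Order-fixed per tissue: (1) drop metabolites missing in strictly more than
25 % of samples, computed within each (tissue, platform) table — the
profiling was batched per tissue; (2) replace remaining missing cells by the
constant 1.00001 and take log2 of every cell (imputed cells land at
log2(1.00001) ≈ 1.44e−5, far below real intensities — a deliberate property
of constant imputation under left-censoring, but one that can dominate means
when missingness is heavy; see "Known limitations"); (3) stack the two
platform matrices without cross-platform deduplication (shared ids get
platform suffixes); (4) z-score each metabolite row (sd with ddof = 1;
zero-variance rows dropped and logged).  Scaling is per tissue because all
downstream tests are tissue-specific.

Covariate screening follows two routes: an elastic-net logistic model
(mixing 0.5, penalty by stratified seeded 10-fold CV on log-loss) of the
non-diabetes/T2D outcome on age, BMI, gender and sample weight (HbA1c and
GSIS are excluded — they define or track the outcome), and per-tissue
Spearman correlations of every metabolite with every covariate under
Benjamini–Hochberg control.  Tissue-specific PCA (deterministic sign
convention: the largest-magnitude loading of each component is positive)
inspects sample structure.

## Differential statistics

The primary test is a two-sided Mann–Whitney U with a Monte-Carlo
permutation null: 100 000 relabelings by default, p = (b+1)/(n_perms+1)
(add-one estimator, so the smallest attainable p is 1/(n_perms+1)),
significance at p < 0.1 without multiplicity correction (FDR is used only in
the covariate and enrichment screens; an optional BH layer exists but is
off).  Ties use mid-ranks.  Resampling draws from the sorted rank multiset,
which makes the Monte-Carlo p invariant to sample ordering at fixed seed.
For group sizes up to ~16 an exact enumeration over all C(n, n₁)
relabelings in rational arithmetic serves as the oracle; the Monte-Carlo
path is validated against it to three Monte-Carlo standard errors.

The reported "fold-change" is the difference of group means of the scaled
log2 intensities (alternative minus reference) — on zero-centred data a
ratio is undefined, and the mean difference is the standardized effect the
bar plots encode.  Its 90 % interval is a Welch t-interval by default;
a within-group percentile bootstrap is selectable (`ci_method`), but at
group sizes near 13 it measurably undercovers (~0.85 at nominal 0.90 in our
simulations), which is why it is not the default.

HbA1c association uses simple linear regression per metabolite with the
response-permutation p (statistic |Pearson r|, same add-one estimator) and
adjusted R² = 1 − (1−R²)(n−1)/(n−2).  Metabolite-pair concentration ratios
are tested as differences of scaled log2 profiles; the gain statistic
p_gain = min(single p) / p_ratio flags pairs (default threshold 10) whose
ratio is far more discriminative than either member.  An explicit pair cap
guards the quadratic blow-up; the pipeline restricts default ratio testing
to the top significant metabolites per tissue.

## Enrichment

One-sided hypergeometric upper-tail overrepresentation of classes,
sub-classes, pathways and biological roles among the significant
metabolites, with the per-tissue background equal to the metabolites tested
(post-filter) in that tissue, and BH adjustment within term-type × tissue.
Reported p-values floor at the smallest positive double rather than 0.

## Phenotype-driven modules

All (metabolite, tissue) nodes enter one Gaussian graphical model.  The
covariance is Ledoit–Wolf-shrunk toward a scaled identity (the design has
far more nodes than samples), with the shrinkage intensity capped at 0.95 —
at the cap the covariance would be exactly diagonal and all partial
correlations identically zero, whereas only their relative magnitudes are
needed.  Edge significance is hybrid: when n − p + 1 ≥ 10 and shrinkage is
negligible (≤ 0.1), the parametric null r² ~ Beta(½, (k−1)/2) with
k = n − p + 1; otherwise a scale-free empirical null — shrinkage rescales
all partial correlations roughly uniformly, so r²/median(r²) is a scaled
χ²(1) under the null, and the median calibration is robust to a minority of
true edges.  Edges kept at p < 0.1 are labelled intra-/inter-tissue.

Modules grow greedily from every seed node; the representative is the first
principal component of the member profiles ("eigenmetabolite", sign-anchored
to the seed; a mean summary is available), and phenotype association is a
logistic score test (avoids separation failures of full MLE at n ≈ 43).
Two design choices depart from a textbook greedy and exist because the
textbook version demonstrably fails at this sample size:

- **Strong-edge expansion.** Candidates are neighbours over edges with raw
  p < 0.01 only.  At n ≈ 43–65 the p < 0.1 edge set is dominated by false
  edges, and minimising over dozens of null candidates per step drifts the
  module through noise (measured: modules hit the size cap with Jaccard
  ~0.1 against planted truth).  The exported network keeps the p < 0.1
  threshold.
- **Explore-then-cut with a coherence plateau.** The walk continues to
  `max_size` even across non-improving steps; the reported module is the
  longest prefix that (a) has smaller association p than every one of its
  members individually — a combination is only worth reporting while it
  beats each constituent — and (b) stays within `plateau_factor` (default 2)
  of the best p on the path.  Cutting exactly at the p minimum truncates
  correlated sets whose late members sit on a statistical plateau.  The
  reported module still strictly improves on its seed; the recorded
  `gain_trace` is the p trajectory of the walk and is not necessarily
  monotone.

Under a null design this yields mostly singletons with a significant
fraction near the 0.1 level; with a planted 6-member block (ρ = 0.5,
members shifted 0.8 SD, 56 metabolites, 65 donors) the module is recovered
with Jaccard ≥ 0.6 and a module p below every member's single-node p in
8/10 seeds.

## Rule classification

All-relevant selection follows the shadow-probe scheme: per round, a
shuffled copy of every undecided feature joins the design, a 500-tree
random forest (mean-impurity-decrease importance) is fit, a feature scores a
hit when it beats the best shadow, and a Bonferroni-corrected binomial test
on hit counts confirms or rejects.  Confirmed features are discretized by
equal-frequency cuts into low/average/high (training cuts reapplied at test
time; degenerate attributes fall back to 2 bins, then 1).  Reducts use
Johnson greedy set cover over the discernibility pairs (object pairs with
different decisions and at least one differing attribute; fully
indiscernible conflicting pairs are excluded via the generalized decision),
with a pruning pass that guarantees irreducibility, and an exhaustive
enumeration mode (≤ 12 attributes) as oracle.  Rules instantiate each
object over each reduct, merge duplicates, and carry support/accuracy/
coverage computed by direct counting.  Classification is support × accuracy
weighted voting (plain support selectable); no matching rule falls back to
the training majority class with a flag, ties resolve to the
lexicographically smaller class with a flag.  Cross-validation refits the
whole chain inside each stratified fold (selection optional — it is costly
and is validated separately).

## Pipeline

`run_all` executes simulate → ingest → preprocess → screens → enrichment →
modules → rules → report from one validated config (unknown keys rejected).
Per-stage seeds derive from the global seed by stable hashing of the stage
name, so disabling one stage leaves the others' randomness untouched.  All
tabular outputs are TSV with fixed float formatting and JSON sidecar
schemas; the manifest records config, version, per-file sha256, and
wall-clock, and two runs with equal config and seed are byte-identical.
Pipeline-level defaults follow the published-methods values (25 % filter,
1.00001, 100 000 permutations, α = 0.1, 90 % CI, elastic-net mixing 0.5,
10-fold CV); the selection stage defaults to 150 trees × 30 rounds at
pipeline level to keep a full run in minutes — `select_all_relevant` itself
defaults to the 500-tree setting.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` regenerate everything they
measure: oracle comparisons at 100 000 permutations; type-I calibration on
~1000 post-filter null metabolites at 10 000 permutations; power and
early-marker runs on 12 planted LPCs (complete data — with 15 %
left-censoring the constant-imputation outliers can flip the sign of a
scaled-mean-difference effect, an artefact of the published chain worth
knowing about); CI coverage over 500 simulations at 30 vs 13; module
recovery over 10 seeds at the planted-block design above; classifier CV
over 10 seeds at n = 43.

## Known limitations

- Constant imputation plus z-scoring makes heavily censored metabolites'
  effects sensitive to which group happened to be censored more; the
  rank-based test is unaffected, but the reported effect sign can flip.
- The empirical edge null assumes most node pairs are null; designs where
  most pairs are truly dependent would miscalibrate it.
- Greedy module search is order-deterministic but not globally optimal; at
  n = 43 its power for weakly shifted blocks (≤ 0.5 SD per member) is low.
- The rough-set classifier consumes discretized levels only; monotone
  transformations of features do not matter, but information between cut
  points is discarded.
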