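# Methods

## The question and the model

Genes whose somatic mutations are frequently observed in cancer tend to be
the same genes whose germline mutations cause abnormal phenotypes.
`germscore` operationalizes this as a supervised prediction problem at the
gene level. The binary response is **IPA** (involvement in phenotypic
abnormality): a gene is positive when, after annotation expansion, it is
associated with the root phenotype term or any descendant. The predictor of
primary interest is **TSM** (total somatic mutations): the number of cancer
patients carrying at least one somatic mutation in the gene, counted once
per patient per (gene, tumor type) cell and summed over tumor types. The
covariates are the gene's evolutionary age (20 ordered phylostrata, where a
lower stratum number means an older gene) and 81 genomic/epigenomic
variables — CDS length, overlap fractions with regulatory interval tracks,
base-weighted signal averages, and the 64 trinucleotide frequencies of the
coding sequence.

Inference proceeds in four layers:

1. **Annotation expansion** (ontology module). Gene–phenotype annotations
   obey the true-path rule: an annotation to a term implies annotation to
   all its ancestors. Before expansion, every annotation to the designated
   neoplasm subtree (the term and all its descendants) is deleted, so that
   somatic–germline overlap in cancer phenotypes themselves cannot drive
   the signal. Order matters and is enforced: a gene annotated to a
   neoplasm term that also descends from a non-neoplasm ancestor does *not*
   reach that ancestor unless it has a second, non-excluded annotation.

2. **Logistic regression** (models module). The univariable model regresses
   IPA on standardized TSM; the odds ratio is per 1 SD. The multivariable
   model adds age (standardized numeric, or a 20-level categorical with the
   first level as reference) and the principal components of the 80
   genomic/epigenomic features (the TTT trinucleotide frequency is removed
   first — the 64 frequencies sum to 1, so one column is exactly collinear;
   all 80 components are retained, making the rotation orthonormal and the
   fit equivalent to using the raw standardized features while keeping the
   design well-conditioned). Wald 95% CIs and two-sided p-values are
   reported; perfect or quasi-perfect separation raises a hard error.

3. **Classifier bench** (models module). Six paradigms are registered
   (logistic regression, random forest, SVM, AdaBoost, histogram gradient
   boosting, Gaussian naive Bayes); logistic and random forest are the two
   used throughout. Performance is estimated by nested cross-validation:
   10 stratified outer folds for evaluation, 3 inner folds for grid-search
   hyperparameter tuning maximizing AUROC. Class imbalance is handled by
   random oversampling of the minority class to parity, applied strictly
   inside training partitions; the implementation returns the drawn row
   indices, and the tests assert that oversampled training rows never
   intersect a test fold. The AUPRC baseline is the positive prevalence;
   the fractional gain over that baseline is the prevalence-free
   performance measure used for per-phenotype models.

4. **Per-phenotype models and disease scores** (models + disease modules).
   One classifier is trained per phenotype term with at least `min_genes`
   (default 100) annotated genes. Each term's model probabilities over the
   whole gene universe are rank-transformed: the highest probability gets
   rank 1, ties get the midrank, and ranks are divided by the number of
   genes so they lie in (0, 1] — lower is stronger. A disease's score for a
   gene is the geometric mean of the gene's normalized ranks over the
   disease's phenotype terms, after mapping each unmodelled phenotype to
   its closest scored ancestor (minimal upward edge distance by BFS; ties
   broken by higher annotated-gene count, then term id) and collapsing
   duplicates. Significance is assessed by permuting the gene column of
   the gene–disease association list (100 permutations; both marginals of
   the bipartite graph preserved), binning scores into 20 equal-width
   intervals on [0, 1], and computing per-bin add-one empirical p-values
   p = (1 + #{null counts ≥ observed}) / (1 + #permutations); bins with
   p < 0.01 are flagged, and an aggregate count of scores below 0.15 is
   tested the same way.

## The synthetic data generator

The generator (synth module) emits every input the pipeline consumes, in
the exact file dialects the production readers parse, from one explicit
parameter set and seed. Defaults mirror the real study's scale and the
published effect size; they are the study conditions of the test suite, not
tunables.

- **Ontology**: a random rooted DAG; each non-root term draws 1–2 parents
  among earlier terms of its own branch, with one child of the root heading
  a closed "neoplasm-like" subtree covering ≈15% of terms.
- **Mutations**: per-(gene, tumor type) patient counts are negative
  binomial (variance = μ + 0.5·μ²) with mean proportional to gene length —
  longer genes accumulate more mutations, reproducing the central
  confounder of the real data. Gene lengths are log-normal (median 20 kb,
  σ = 1). Counts are expanded into MAF-like records with random variant
  classifications (≈25% Silent) and deliberate duplicate records per
  patient so that per-patient deduplication is exercised.
- **Age**: 20 strata with mildly decaying frequencies (ancient genes
  predominate, as in real phylostratigraphies).
- **Features**: CDS sequences are random with gene-specific Dirichlet base
  composition (median length 1.3 kb); their trinucleotide frequencies are
  computed with the production counting code. The 17 scalar features come
  from a compound-symmetric Gaussian latent (correlation 0.3, plus a 0.2
  loading on log gene length) mapped to each feature's natural scale —
  logistic for overlap fractions, exponential for non-negative signals.
- **Labels**: IPA is Bernoulli with
  logit p = −1.4 + ln(1.9)·z(TSM) + 0.1·(age − mean age).
  The TSM coefficient is anchored to the published per-SD odds ratio
  (≈1.9); this is a planted simulation value, not a reproduction of the
  TCGA estimate. The intercept −1.4 calibrates prevalence to ≈22%, the
  real fraction of IPA-positive genes. The age effect (0.1 per level,
  ≈1.8 per SD) makes age comparable in strength to TSM, matching the
  qualitative finding that the two are the dominant predictors. Positive
  genes are annotated to 1–5 random leaf terms outside the neoplasm-like
  subtree; 10% of all genes additionally receive a neoplasm-subtree
  annotation so the exclusion step has real work to do.
- **Release pairs** for temporal holdout follow a censoring model: the
  newer release is the full annotation set, the older release hides a
  uniformly chosen subset of positive genes. Annotation catalogs grow by
  filling in missing knowledge rather than re-drawing biology, so newly
  annotated genes are typical positives, and the older release carries
  them as false negatives — exactly the label noise a model trained on an
  incomplete catalog faces. (The alternative — sampling "new" genes from
  the negatives weighted by the latent probability — selects genes that
  are systematically weaker positives and depresses holdout AUROC by a
  structural ≈0.04.)
- **Disease catalogs**: each disease draws a fixed number of distinct
  scored phenotype terms; its causal gene is drawn with probability ∝
  exp(sharpness · z(mean model probability over the disease's terms)).
  Sharpness 0 is an exact null (causal genes uniform); large sharpness
  concentrates causal genes among the model's top predictions for that
  disease's own phenotypes, which is what makes permutation (which
  mismatches genes and diseases) destroy the signal.

What the generator does **not** emulate: real HPO topology or term depth
distribution, mutational signatures, genomic coordinates on a real
assembly, inter-phenotype annotation correlation beyond shared IPA status,
and driver-gene structure. Passing tests therefore demonstrate that the
machinery recovers planted effects and controls error rates under
realistic-scale, confounded data — not that the published effect sizes are
reproduced from the original TCGA/HPO/ENCODE data, which would require
those external datasets.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere; interval tracks are merged
  before intersection so overlapping peaks are not double counted; signal
  averages are base-weighted within a cell line, then averaged with equal
  weight across cell lines; cell lines with no coverage are skipped and a
  gene with no coverage anywhere gets a missing value (genes with any
  missing variable are dropped listwise, never imputed).
- Trinucleotide windows containing non-ACGT characters are skipped with the
  denominator reduced, keeping the 64 frequencies a proper distribution.
- "Closest scored node" uses upward edge distance (BFS over parent edges).
  Edge distance, not a semantic-similarity measure, is assumed; ties are
  broken deterministically (more annotated genes, then lexicographic id).
- Rank direction: rank 1 = highest model probability. This is the only
  reading under which low aggregate scores indicate true associations, and
  it is what makes low-score enrichment the signal of interest.
- Normalized rank = midrank / N ∈ (0, 1]; the geometric mean is computed
  as exp(mean(log rank)) for stability.
- Empirical p-values use the add-one correction, so p is never 0 with a
  finite number of permutations and the minimum attainable p with 100
  permutations is 1/101 ≈ 0.0099.
- The CI on a mean fold AUROC uses a normal approximation over the fold
  values. Stratified folds are used throughout (preserves prevalence in
  small phenotype models). All stochastic steps take explicit seeds;
  per-term seeds are spawned from the master seed.
- Scale-sensitive estimators (logistic regression, SVM) carry an in-
  pipeline standardizer so scaling is always fit on training partitions
  only. Default hyperparameter grids are small (e.g. random forest:
  100/300 trees × depth ∞/10 × min leaf 1/5); the bench accepts any grid.
- Temporal holdout re-tunes hyperparameters on the training portion (the
  alternative — reusing the original tuned values — is equally defensible;
  re-tuning keeps the holdout a fully fresh fit).
- The per-phenotype probabilities used for ranking come from a final model
  refit on the full universe (with oversampling); external candidate-list
  evaluation excludes a term's training positives before the Mann–Whitney
  rank-uniformity test, so the refit does not bias that test.
- Problem sizes in the test suite: the univariable recovery experiment runs
  at the full 18,170-gene scale (500 replicates); nested-CV calibration and
  signal-detection experiments run at 2,000–5,000 genes; the end-to-end
  reproducibility run uses 2,000 genes, 50 terms, 100 diseases. These sizes
  are the package's chosen balance between statistical resolution and a
  test suite that runs in minutes.

## Known limitations

- With all 80 PCs retained, the multivariable logistic model is only
  well-conditioned because the components are orthonormal; passing raw
  collinear features would fail the rank check by design.
- Wald CIs for the TSM odds ratio are mildly anticonservative under the
  heavy-tailed TSM distribution (empirical coverage ≈94–95% at n = 18,170
  in the recovery experiment); profile-likelihood intervals would be more
  accurate but are not needed at this scale.
- AUPRC gain over baseline is noisy for terms whose prevalence is near the
  `min_genes` threshold; the median across terms is the stable summary.
- The permutation null conditions on the observed catalog structure
  (phenotype lists and per-disease association counts); it does not model
  uncertainty in the phenotype lists themselves.
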