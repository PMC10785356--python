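# Methods

This note records the models, conventions, defaults and design decisions
behind `pathact`, in the order data flows through the package.

## Expression data and per-gene statistics

The universal input is a genes × samples matrix of continuous expression
values with a binary phenotype per sample (`normal` / `tumour`). Gene ids are
case-normalised to uppercase at parse time so expression matrices, gene sets
and networks share a namespace; duplicate gene rows are collapsed by their
mean; missing entries are mean-imputed per gene row (rows that are entirely
missing are dropped and counted).

All statistics share one set of conventions:

- **t-score**: pooled-variance two-sample t, oriented tumour minus normal, so
  positive t means up-regulated in tumour. The two-tailed p-value uses the t
  distribution with n₁+n₂−2 degrees of freedom. Zero pooled variance gives
  t = 0, p = 1, flagged. The orientation is a convention the source
  formulas leave open; it only has to be consistent, and it is applied
  identically to genes and to pathway-activity rows.
- **sign(0) → +1**, so signed products stay defined for t = 0 genes (the
  p-filter usually removes them anyway).
- **Standard deviations** use the n−1 denominator everywhere, matching the
  t statistic's pooled variance.
- **z-scores**: per-row (x − mean)/sd across all samples of the portion being
  scored. Constant rows become all-zero rows and are flagged rather than
  raising, because downstream sums must stay finite.
- **Point-biserial correlation (pbc)** is the Pearson correlation of a gene
  row with the 0/1 tumour indicator.
- **PCTscore = pbc + t**, the *signed* sum. The source description ("the
  summation of PBC ... and t-test statistics") names no absolute value, and
  the signed form is also the only reading under which the entropy-walk
  activity discriminates pathways containing both up- and down-regulated
  genes: with |t| the two directions cancel in the numerator.
- **Entropy**: Shannon entropy (bits) of an equal-width histogram over
  [min, max] with ⌈log₂(n)+1⌉ bins by default (Sturges), configurable. The
  entropy estimator behind the published entropy-walk initialisation is not
  specified anywhere reconstructible; this histogram estimator is a
  documented stand-in, not a verified reconstruction.

## Pathway resources

Gene sets (GMT) are deduplicated preserving first occurrence; after
restriction to measured genes, sets below `min_size = 2` are dropped (a
1-gene "pathway" makes the SVD decomposition and the variance-stabilised mean
degenerate; configurable down to 1). Directed networks (SIF / edge TSV) are
simple digraphs: parallel duplicate edges collapse to one, self-loops are
kept (the walk formalism tolerates them), unweighted edges get weight 1, and
interaction-type strings are preserved but never interpreted — no equation
here uses activation/inhibition semantics. Restriction keeps all network
nodes but marks unmeasured ones, which then receive zero seed weight.

Row-normalisation produces the transition matrix M with
`M[u,v] = w(u→v)/Σ_out(u)`; nodes without positive out-weight are dangling
(all-zero rows) and listed.

## The four gene-set schemes

- **combiner**: member genes with p ≤ 0.05 are ranked by descending |t| (ties
  broken by gene id so the top-20 cap is deterministic) and capped at 20;
  activity per sample is Σ z·sign(t)/√j. Pathways with no qualifying gene are
  dropped and recorded.
- **pac**: Σ z/√k over *all* measured members. The original condition-
  responsive-genes formulation describes a greedy member-subset search, but
  the quantity evaluated here is the plain z-score aggregation (the form the
  published comparison actually computed); the greedy CORG search is out of
  scope and not reconstructible from the available description.
- **plage**: SVD of the member z sub-matrix; the activity is the first right
  singular vector. SVD sign is arbitrary, so the vector is oriented to
  correlate non-negatively with the mean member z profile — this matters
  because reproducibility t-scores depend on a consistent orientation across
  folds. All-zero sub-matrices are dropped with a warning.
- **gsva**: per gene, each sample's value becomes a cumulative-density score
  across samples (empirical CDF by default; a Gaussian-kernel CDF with
  bandwidth sd/4 is available). Per sample, genes are ordered by decreasing
  score (ties by the rank statistic, then gene id); the gene at position l
  carries the symmetric rank weight |p − l + 1 − p/2|^τ with τ = 1 by
  default. The running sum accumulates in-set weight share minus out-of-set
  count share; ES⁺/ES⁻ are its extreme excursions and the activity is
  ESdiff = |ES⁺| − |ES⁻| = ES⁺ + ES⁻. (The printed equation in the source
  equates this with max − min of the walk, which is algebraically |ES⁺| +
  |ES⁻|; the |ES⁺| − |ES⁻| form is the one consistent with the cited method
  and is implemented.) Because the walk only rises at in-set positions, the
  default path evaluates the deviation only there (O(k) per set per sample);
  the full O(p) sequence is computed when walks are requested and the two
  paths are tested to agree to 1e-12. A set equal to the whole gene universe
  has an empty complement and is rejected.

## The walk engine and the three topology schemes

The restart walk iterates `W_{t+1} = (1−r)MᵀW_t + rW_0` with r = 0.7
everywhere (the published comparison fixes this value for comparability) and
stops when the L1 change falls below 1e-10 (cap 10⁵ iterations; with r = 0.7
the map contracts by 0.3 per step, so convergence takes ~25 iterations). L1
is used both for the seed normalisation ("unit vector") and the convergence
norm because the iteration is a Markov mixture on the probability simplex.
Mass sitting on dangling nodes is redistributed to the restart distribution
each step — a stand-in for the unexplained "ground node" in the source —
which keeps ΣW = 1 exactly and guarantees a unique fixed point; the fixed
point equals the closed-form solve `r(I − (1−r)M̃ᵀ)⁻¹W_0` where M̃ replaces
dangling rows with W₀, and the engine is tested against that solve.

- **drw** seeds with L1-normalised |t| (unmeasured nodes 0; an all-zero seed
  is an error). Activity over member DEGs (strict p < 0.05, as printed for
  the walk methods, vs. p ≤ 0.05 for combiner — both honoured, both
  configurable) that sit on the network:
  Σ W∞·sign(t)·z / √(Σ W∞²). Genes measured but absent from the network
  never qualify.
- **sdrw**: the printed recursion restarts to W_t and multiplies M by a
  scalar, which is not a fixed-point scheme; following the stated intent
  ("enhance the connectivity between nodes"), it is implemented as edge
  re-weighting — each edge weight becomes the mean of its endpoint node
  weights (raw |t|) — followed by re-normalisation and the standard
  iteration with r = 0.7. Zero-weight edges are allowed; nodes whose
  out-edges all drop to zero become dangling and are listed.
- **edrw** seeds with per-gene entropy and runs one walk per input network
  (two in the published setting; the walks never interact, and a pathway id
  occurring under several networks is suffixed with its network tag).
  The denominator symbol in the printed activity formula is read as the
  normalised complement of converged entropy probabilities over member
  genes: weight(g) = (1 − H∞(g)) / Σ_members (1 − H∞), and the denominator
  is the L2 norm of those weights.

## Assessment 1 — reproducibility power

Stratified k-fold (the source says only "randomly divided into five subsets
of equal size"; stratification keeps every fold estimable), repeated over
random partitions with per-partition child seeds fanned out from one master
seed. "Fit on training" means: gene t/p/pbc/entropy statistics, DEG
membership, walk vectors and sDRW edge weights come from the training folds
only; each portion is z-scored within itself (the source never states how
test activities are standardised; per-portion scoring avoids leaking test
labels and matches the cited walk-method practice). Label-free methods
(gsva; also pac and plage, which have no fitted parameters) are recomputed
per portion. Test-portion DEG filters reuse training p-values.

Cscore(N) averages t_train·t_test over the top-N pathways by |t_train| (ties
by pathway id); the summary reports the mean per top-k and the coefficient
of variation (sd/mean, percent; flagged undefined for non-positive means).

The label-permuted null draws a *fresh* benchmark with freshly permuted
labels per partition. Repeated partitions of one fixed dataset would not be a
null: the dataset's chance gene–label associations are shared between
complementary train/test portions and bias the product of t-scores (both
signs of bias were observed; the anti-correlation of complementary portions
of a fixed total can even make it negative). With fresh data per partition
the training and held-out t-scores are genuinely independent and the
expectation is exactly 0; the standard error of the mean is clustered at the
partition level because folds within a partition share a dataset.

## Assessment 2 — marker identification

Stratified 60/20/20 split (largest-remainder rounding per class, so the
split is exhaustive), re-randomised every repeat. Candidates are the top-50
training pathways by |t|, recomputed per repeat from that repeat's training
portion. Selection is greedy: starting from an empty set with baseline AUC
0.5, each candidate is added, the classifier refit on training, and the
validation AUC computed; the candidate is kept iff the AUC *strictly*
increases (the keep/drop sentence in the source names AUC; accuracy is
reported on test). Strictness prevents unbounded sets under ties but also
means a perfectly separating early candidate blocks everything after it.
AUC is the Mann–Whitney rank statistic (ties count half), tested against
brute-force pairwise concordance; accuracy and the confusion counts use the
0.5 score threshold.

Classifier specifics are not fixed by the source: Gaussian naive Bayes, KNN
with k = 5 and Euclidean distance, and logistic regression with the default
L2 ridge (so separable activity features stay estimable). All are
configurable and recorded in provenance. Per method, the reported classifier
is the one with the highest mean test accuracy, ties broken toward the one
selecting more pathways. Marker frequencies are ranked by selection count,
ties by mean selection rank then id; the top-6 markers and their member
genes are checked against the literature index (terms are case-folded,
punctuation-stripped, whitespace-collapsed), and query strings follow
`<marker> AND prognostic AND "<cancer type>"`. Live PubMed retrieval is out
of scope.

## Synthetic benchmarks

The generator emulates a two-class microarray study in z-space: per-gene
Gaussian baseline (mean 0, sd 1), with the tumour mean of each planted DE
gene shifted by ±δ·sd. Defaults — the study conditions for all benchmark
results — are 2000 genes, 50+50 samples, 100 pathways, 10 risk pathways,
δ = 1.5, and half of each risk pathway's members differentially expressed
with a 50/50 up/down sign mixture drawn per gene (so signed aggregation is
exercised in both directions). Pathway sizes are uniform on 20–60: the range
of curated canonical-pathway collections, and large enough that nearly all
pathways keep ≥ 1 member after a p < 0.05 DEG filter, keeping top-50
selections well defined. Neighbouring sets share members at ≈ 0.1 Jaccard so
pathway t-scores are correlated, as in real collections. The directed
network is a preferential-attachment digraph (spanning arborescence for weak
connectivity, then biased attachment) with 3 edges per gene and DE genes
preferentially hubbed; exact node/edge counts, deterministic per seed.

What the generator does *not* model: probe/batch effects, count noise,
log-normal intensity scales, coherent pathway-level regulation, or survival
outcomes. Passing benchmarks therefore show that the methods recover planted
mean-shift structure through the full pipeline — not that they rank real
cancer pathways correctly.

Two structural consequences of the mixed-sign planting are worth stating
because they are visible in the benchmark results: the direction-blind
aggregations (plain z-sum and the symmetric-rank enrichment) lose balanced
mixed-sign pathways — the net signal of a pathway scales with the chance
imbalance of its up/down genes — so their planted-pathway recovery is far
below the signed methods', mirroring the published finding that the z-sum
scheme is the weakest. And the strict-increase selection rule saturates on a
20-sample validation portion (AUC granularity 1/100), so full 3-of-3 signal
recovery by forward selection happens in roughly half of runs, with either
late signals unable to strictly improve, or (with larger validation sets)
noise candidates strictly improving by tiny margins.

A separate direct generator draws 3-signal activity profiles (unit Gaussian
rows, effect 1.5 on the signal pathways, 30+30 training and 10+10 validation
samples — the 60/20/20 geometry of the default study) to exercise forward
selection in isolation. The synthetic literature index covers a stated
fraction of truth terms (exactly ⌊coverage·n + ½⌋ per category) with random
PMIDs.

## Numerical and engineering choices

- Determinism: every stochastic step derives from an explicit seed;
  per-partition/per-repeat child seeds are fanned out with SeedSequence, so
  any record is independently reproducible. Re-runs are byte-identical.
- Ties anywhere (gene ranking, pathway ranking, candidate order, marker
  frequency) break lexicographically by id after the primary key.
- The benchmark harness (`pathact.benchmark`) runs the trend sweep at 20
  seeds × 10 partitions × 5 folds and the null at 20 fresh-dataset
  partitions; these sizes keep the full sweep within a few minutes on one
  CPU while leaving the per-method comparisons stable.
- Heavy paths are vectorised (row-wise histogram entropy via one flat
  bincount; enrichment walks evaluated only at in-set positions; sparse
  matrix power iteration); the brute-force counterparts live in the tests
  as oracles.

## Known limitations

- The sDRW recursion and the e-DRW denominator are printed ambiguously in
  the source; both receive documented interpretations (edge re-weighting +
  standard iteration; normalised complement-entropy weights). Results for
  those two methods are faithful to these readings, not to the unpublished
  originals.
- The entropy estimator for e-DRW seeds is a stand-in (see above).
- Restart-probability grids, interaction-sign-aware propagation, live
  database/PubMed access, and array preprocessing beyond mean imputation are
  out of scope.
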