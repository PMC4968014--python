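# Methods

`modulesig` implements a two-tissue, function-level comparison of disease
transcriptomes: co-expression modules per tissue, literature concept-profile
annotation per module, annotation-overlap scoring of all cross-tissue module
pairs, and permutation-based familywise error control. This note records the
model and its assumptions, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the numerical conventions.

## Module detection

The network stage follows the classic weighted co-expression recipe. Pearson
correlation across samples is computed for every gene pair (at least 3 samples;
zero-variance gene rows are dropped at ingestion with a warning — they carry no
co-expression signal and would make the correlation undefined). The unsigned
adjacency is `a_ij = |r_ij|^β`; a signed variant `((1 + r)/2)^β` is available
behind a flag but unsigned is the default, the historical default of the
method. The soft power β is a *user input*: different platforms need different
powers (β = 9 is typical for blood-type data, 3–5 for the brain arrays), so the
package validates a chosen β via the scale-free topology index — the signed R²
of the log₁₀(frequency) on log₁₀(mean connectivity) regression over 10
equal-width connectivity bins, negated when the slope is positive — rather than
auto-selecting it. Degenerate inputs (constant connectivity, nearly empty bins)
return R² = 0 with a warning.

The topological overlap matrix

    TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)

(unit diagonal) measures shared neighbourhood; `1 − TOM` feeds average-linkage
hierarchical clustering. The branch cut is a deliberately simplified dynamic
cut: branches below `cut_height` with at least `min_module_size` genes become
modules; with `deep_split ≥ 1` a branch is recursively split when the gap
between its merge height and its children's exceeds `(0.25 / deep_split) ×`
branch height and both halves reach the minimum size (so deeper splitting can
only increase the module count). Genes left outside any branch are rescued into
the module with the highest mean TOM to its members only if (a) that mean
exceeds their mean TOM to all non-members and (b) their mean dissimilarity to
the module is below `cut_height`. Condition (b) matters: module genes are
network hubs, so condition (a) alone would absorb pure-noise genes into
whichever module is nearest. The reference dynamic-hybrid implementation (with
its PAM stage) is intentionally not replicated; the accuracy target for this
stage is planted-module recovery, not label-exact agreement with that
implementation.

Modules whose eigengenes are nearly parallel are merged iteratively: closest
pair first (eigengene dissimilarity `1 − cor < MEDissThres`), eigengenes
recomputed after every merge, until no pair qualifies; the procedure is
idempotent and `MEDissThres = 0` is the identity. The module eigengene is the
first right singular vector of the per-gene z-scored module submatrix, unit
norm, with its sign fixed so that its correlation with the module's mean
expression profile is non-negative (PCA sign is otherwise arbitrary, and a
deterministic orientation is required for reproducible downstream output).

Eigengene–trait association uses Pearson correlation with the exact two-sided
t-test on n − 2 degrees of freedom; a module is *trait-associated* when its
smallest trait p-value is below 0.05. No multiplicity adjustment is applied at
this stage — each module–trait cell is reported on its own, and the stringent
FWER control happens at the pair level where the scientific claim is made.
Constant traits yield an undefined correlation, reported as r = NaN, p = 1 with
a warning. Ordinal staging traits are treated as numeric.

## Concept profiles and annotation

A corpus is a list of documents, each a deduplicated set of concept
identifiers, plus a vocabulary mapping each concept to a semantic category
(gene, biological process, cellular component, molecular function, disease or
syndrome). For every concept with document frequency ≥ `min_docs` (default 5) a
profile is built: weights `U(X, Y)` for every concept Y co-occurring with X in
at least one document, where U is the symmetric uncertainty coefficient of the
binary occurrence indicators,

    U = 2·I(X;Y) / (H(X) + H(Y)),

entropies in bits from the 2×2 table implied by (n_X, n_Y, n_XY, N). The base
cancels in the ratio; `0·log 0 := 0`; U = 0 is returned when H(X) + H(Y) = 0;
tiny negative mutual information from floating point is clipped to 0. Zero
weights are dropped and a profile never contains its own owner. Profiles are
matched by the inner product over shared concepts — because owners are excluded
from their own profiles, a direct X–Y co-occurrence contributes only through
shared neighbours, which is exactly the "indirect relation" mechanism the
profile representation is designed to expose.

A module is annotated per category by scoring every annotation concept with the
sum of gene-profile/annotation-profile matches over the module's genes (genes
without profiles contribute zero and are logged), then keeping the top
`K = 20` concepts, sorted by score descending with ties broken by concept ID
ascending. The tie-break is load-bearing: the permutation null re-annotates
thousands of random modules and must be bit-reproducible. Zero-score concepts
are dropped (an opt-in flag can retain them to pad short lists). Scores are raw
sums, not normalized by module size — ranking within a module is unaffected by
a common factor. The bulk annotator precomputes the gene × annotation match
matrix once, so annotating a module (real or random) is a row-sum plus a
top-K selection; it is tested to agree exactly with the per-module path.

## Pair scoring and significance

For n blood modules and m brain-region modules, the observed score S_ij is the
size of the intersection of the two top-K annotation lists (scores ignored), a
number in 0…K. A gene-overlap baseline replaces the top-K list by the module's
(identifier-mapped) gene set; both routes implement the same mask-intersection
interface and therefore share all permutation code, including the random draws.

The null: for k = 1…K_A and l = 1…K_B (defaults 100 × 100), random module sets
are generated by permuting the tissue's gene universe and slicing consecutive
blocks of the original module sizes — each replicate is a disjoint partition
with exact size match, mirroring the partition structure of the real module
sets (independent per-module sampling is available behind a flag). The
universe is every gene that entered module detection, assigned or not — the
larger universe is the more conservative choice. All K_A × K_B combinations
are scored, giving R = K_A·K_B null scores per pair (10,000 at the defaults).
Annotation of random modules reuses the cached profiles (profiles are
deterministic given the corpus).

Raw p-values use the `≥` convention with a +1 correction:
`p_ij = (1 + #{(k,l): S_ijkl ≥ S_ij}) / (1 + R)`. Ties count as extreme, which
is conservative for discrete scores, and the +1 means p is never zero: at the
10% level with R = 10,000 a pair can only be significant when its observed
score is the most extreme among all permutations. The Westfall–Young
step-down minP adjustment orders hypotheses by raw p (ties by pair index,
fixed), computes per-replicate empirical p-values from each pair's own null
with the same `≥` and +1 conventions, and sets the h-th adjusted p to the
+1-corrected fraction of replicates whose minimum per-replicate p over
hypotheses h…last is ≤ raw p_h, followed by a running-maximum monotonization.
The implementation is vectorized but is tested for exact agreement with a
brute-force enumeration on small instances, and its familywise error rate is
exactly calibrated on exchangeable synthetic scores.

The analysis is run separately per semantic category (and for the gene
baseline), so FWER is controlled within a category; no cross-category pooling
is performed, and the 10% strict / 50% marginal thresholds apply per category.
A *common signature* is a pair with adjusted p ≤ 0.10 (marginal: in
(0.10, 0.50]) whose two modules are each trait-associated; each signature
reports its shared annotation concepts.

## Synthetic-data generator

The generator is first-class, tested code; it defines the study conditions all
simulation-based checks run under.

**Expression.** Each planted module is driven by one latent factor per sample —
the eigengene analogue, which makes ground-truth recovery well-defined. Traits
are drawn first: carrier status balanced binary, CAG and motor standard
normal, TFC = −0.7·motor plus noise (severity scales run in opposite
directions). A module factor with trait targets r is `z·(Σ⁻¹r) + c·ε` with z
the standardized trait matrix and Σ its empirical correlation matrix, so
empirical factor–trait correlations converge to the targets (the construction
requires rᵀΣ⁻¹r ≤ 1 and rejects jointly infeasible targets; a target of
magnitude 1 combined with nonzero expression noise is also rejected). Module
genes are `loading × factor + N(0, noise_sd)`; background genes are pure
standard normal noise. Everything is seeded through `numpy` `SeedSequence`
streams keyed by (seed, tissue, stage), so outputs are bit-reproducible and
the two tissues are independent given the seed.

**Corpus.** Documents are bags of concept IDs; no text is generated, since
profiles only need co-occurrence counts. Every gene of both tissues and every
annotation concept (40 per category by default) occurs independently in each
document at a base rate of 0.02. On top of this, every annotation concept owns
a small topic literature: topic documents containing the concept and a random
~60% subset of its linked genes. Shared-function concepts (10 per function per
category) link to the genes of the modules carrying that function in *both*
tissues — so the two tissues' planted modules share annotation concepts while
sharing zero gene identifiers. Background concepts link to 12 random genes.
The topic-document count is calibrated so a linked gene–annotation pair
co-occurs at `cooccurrence_enrichment` times the independence rate; enrichment
1 produces zero topic documents, leaving a fully unstructured corpus (the
global-null condition). A final top-up pass guarantees every concept reaches
the `docs_per_concept ≥ 5` profile-eligibility floor.

**What is not emulated.** Sequencing count distributions, normalization,
probe/platform structure, batch effects, correlated noise between genes outside
modules, polysemous concepts, citation skew, and document length variation.
Passing tests therefore demonstrate that the pipeline recovers the designed
signal under a faithful but idealized factor-model/topic-model world; they do
not certify performance on real accessions, where module boundaries are fuzzy
and literature co-occurrence is far more heterogeneous.

## Scales and default scenarios

Two fixed scenarios define the simulation studies. The *strong* scenario
plants three 15-gene modules per tissue (two carrying shared functions, one
tissue-specific), 60 background genes, 40 samples, noise_sd 0.5, enrichment 5,
1,500 documents. The *global-null* scenario keeps trait-associated modules but
no shared functions and enrichment 1. Simulation studies analyze these with
soft power 9, minimum module size 10, cut height 0.98, eigengene-merge
threshold 0.15, top-10 annotation lists over the 40-concept categories, and
20 × 20 permutation sets (400 null scores per pair): the smaller annotation
lists keep the discrete overlap score discriminative at this vocabulary size,
and 400 replicates resolve the p-values the recovery and error-rate checks
need. Library defaults are unchanged from the full-scale procedure: top-20
annotations, 100 × 100 permutation sets, minimum module size 15, profile
eligibility at 5 documents, thresholds 0.10/0.50/0.05. Repeated-run studies
(200 global-null runs for the error rate, 50 strong runs for recovery) finish
in well under a minute in total; a single full-default null build on the
scenario data takes a few seconds.

## Known limitations

* The tree cut is a simplified dynamic cut, not the reference dynamic-hybrid
  algorithm; very unbalanced or nested module structures may split differently.
* Annotation scoring ignores any ontology hierarchy; parent and child terms
  count as distinct concepts both in ranking and in overlap counting.
* The discrete overlap score makes minP conservative (the motivation for the
  10% strict level); with few candidate concepts per category the score
  saturates and loses resolution — the category vocabulary should be
  comfortably larger than K.
* Gene-overlap comparison requires an external identifier mapping between the
  two platforms' namespaces; with no mapping the baseline is skipped.
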