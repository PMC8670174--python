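# Methods

## Scope and model

`fegfs` turns a cells × genes scRNA-seq matrix into a functional feature
matrix in four stages — GO enrichment, SimRel semantic reduction,
repetitive-rate reduction, and per-set cosine-kernel KPCA — then clusters
cells agglomeratively. This note records the modelling assumptions, the
parameters that matter, the numerical conventions, and what the synthetic
test fixtures do and do not establish.

## Ontology and annotation model

The ontology is a per-namespace DAG over `is_a` and `part_of` edges; the
regulates-family relations are ignored, as is standard in enrichment
tooling. Annotations are closed upward under the true-path rule before
anything else runs. A term's frequency `P(t)` is the fraction of genes
annotated anywhere in `t`'s namespace that carry `t` after propagation;
it is monotone along ancestry and equals 1 at each namespace root.

`P(t)` is computed from the *supplied* annotation corpus rather than an
external reference database. This keeps a run fully reproducible from its
inputs; `propagate(..., frequency_override=...)` accepts a precomputed
frequency table when a fixed external corpus (e.g. a UniProt snapshot) is
preferred. Gene identifiers are matched as exact strings — no identifier
conversion is attempted.

## Enrichment

Over-representation of the input gene list (by default, all genes
surviving the noise filter) is tested per namespace with the upper
hypergeometric tail `P(X ≥ k)`; the pmf alone cannot rank
over-representation, so the tail convention is used. The background `N`
is the number of corpus genes annotated in the namespace — there is no
separate genome universe parameter. BH-FDR is applied within each
namespace because `n` and `N` are namespace-specific quantities; the
default significance threshold is q ≤ 0.05 and terms with fewer than
`min_genes = 2` input genes are not tested (singleton terms carry no
clustering signal and inflate the test count). Each significant term
carries its *input-gene intersection*, not its full corpus set: these
k-sets are what the downstream stages operate on, which matches the scale
of the worked examples the reduction stage is anchored to (set sizes of
order 10–10², far below corpus annotation sizes).

## Semantic reduction

SimRel scales Lin similarity by `(1 − P(MIA))`, so similarity mediated
only through a namespace root (P = 1) is zero; similarity across
namespaces is undefined and treated as an error. Ties among minimal-
frequency common ancestors are broken lexicographically. Reduction is
greedy best-pair-first at cutoff 0.4, mirroring REVIGO's published
procedure; the member discarded from a pair is the descendant when one
term is an ancestor of the other (the "father" term is the natural
representative), otherwise the weaker p-value, with ties broken by
smaller corpus size then term id. `representative="pvalue"` switches to a
pure p-value rule. The survivor set is returned in input order and every
surviving same-namespace pair is below the cutoff.

## Repetitive-rate reduction

`R(A,B) = |A∩B| / min(|A|,|B|)` (not Jaccard — the minimum denominator is
deliberate, so a subset scores 1 regardless of the size gap). One
screening pass removes fully covered sets (keeping the larger set; among
identical sets the lexicographically smallest id) and then merges pairs
best-first at threshold 0.8, recomputing rates after every merge; merged
sets take the union of genes and are named `merged:<sorted term ids>`.
Two passes are the default. Because merging runs to exhaustion and
coverage implies a rate of 1 ≥ threshold, a single pass already leaves
all pairwise rates below the threshold, so the second pass is a
verifiable no-op; the default is kept at two for interface stability and
`until_converged` makes the fixpoint explicit. The union of genes over
all sets is invariant under the whole stage.

## Feature extraction

The noise filter drops genes with a strictly positive value in fewer than
`3 · max(1, ⌊0.01 · n_cells⌋)` cells; the inner floor is clamped at 1 so
datasets under 100 cells still use a threshold of 3 rather than 0. The
log transform is `log10(x + 1)`.

Per functional gene set, KPCA runs on the cells × set-genes submatrix of
the log-transformed data: cosine kernel, double centering
(`K − 1K/n − K1/n + 1K1/n²`), symmetric eigendecomposition. Eigenvalues
below `1e−10 ×` the largest are treated as numerical zeros. The retained
dimension `d` is the smallest prefix of descending eigenvalues whose sum
reaches the retention ratio times the positive eigenvalue mass (`d ≥ 1`).
The ratio is read as an explained-variance fraction — the common meaning
of "principal component retention ratio", and a component-count reading
would multiply feature width by the number of sets; `mode="count"`
preserves that alternative reading. The ratio defaults to 0.40 for
≤ 1000 cells, 0.60 for ≤ 3000 and 0.80 above: the printed source brackets
for the two large regimes overlap ambiguously, and this reading honours
the "greater than 3000" rule. Projections are eigenvectors scaled by
`√λ`; each component's sign is fixed so its largest-magnitude coordinate
is positive (KPCA signs are otherwise arbitrary, and the convention makes
runs bit-identical). Gene sets are intersected with the matrix's genes in
matrix order; per-set submatrices are not re-centred per gene before the
kernel — the kernel operates on raw log values, and the cosine kernel is
already invariant to per-cell positive rescaling. Zero-norm cells (all
set genes dropped out) get zero kernel rows off the diagonal with a
warning rather than NaNs.

## Clustering and metrics

Clustering is scikit-learn agglomerative merging under Euclidean distance;
Ward linkage is the default because it pairs naturally with Euclidean
geometry — the linkage is configurable and reported alongside results.
`k` is a required input; no cluster-number estimation is attempted.

ARI is the Hubert–Arabie pair-counting index. NMI is
`2·I/(H(F) + H(G))` with plug-in (non-negative) mutual information; two
trivial identical partitions score 1 by convention, a constant prediction
scores 0. HOM and COM are the matching-based variants, *not* the
entropy-based V-measure scores: each predicted cluster is matched to its
majority class (ties to the smallest class index; an optimal one-to-one
Hungarian assignment is available via `matching="hungarian"`), and the
matched-class fraction is averaged over cluster sizes (HOM) or matched
class sizes (COM), over the `k` predicted clusters. When the predicted
and reference cluster counts differ the average still runs over predicted
clusters; several classes may then share a matched cluster, so COM is not
guaranteed to reach 1 even for a refinement.

## Synthetic fixtures

The generator emulates exactly the input structure the pipeline assumes,
not realistic scRNA-seq data. The ontology is a layered DAG with two
disjoint branches under the root; the annotated corpus holds twice as
many genes as the expression matrix so the input list is a proper subset
of the background. Three leaf roles plant work for each stage: *cluster
leaves* (branch 0) hold one cluster's marker genes plus other expression
genes, so they are strongly enriched; *twin leaves* (branch 1) copy ~90%
of a cluster leaf's genes — a repetitive rate above 0.8 with near-zero
SimRel, feeding the overlap-merging stage; *background leaves* sample the
whole corpus uniformly and stay non-significant. Enriched leaves coexist
with their enriched ancestors, giving the SimRel stage parent–child pairs
above 0.4.

Expression is log-normal (`exp(N(1, 1))`) with each cluster's marker
block multiplied by `10^effect` and Bernoulli dropout zeroing entries;
defaults are 200 cells, 400 genes, 4 equal clusters, 10% marker genes,
effect 2 (a 100× shift), dropout 0.2. The model has no batch effects,
library-size gradients, gene–gene correlation structure, or realistic
mean–variance relationships — passing end-to-end tests therefore shows
the pipeline's machinery is correct and that strong planted signal is
recovered (ARI ≥ 0.9) while a zero-effect null yields |ARI| ≤ 0.1; it
does not certify clustering accuracy on real tissues. Problem sizes in
the test suite (up to 200 cells × 400 genes, 40 terms) were chosen as the
smallest configurations in which every stage has non-trivial work.

## Degenerate inputs and tie-breaks (summary)

- Obsolete ontology terms keep no edges and are excluded everywhere;
  `alt_id`s resolve to their primary term; unknown annotation terms are
  dropped with a warning.
- All greedy orders (SimRel pair choice, merge order, covered-set
  retention, MIA choice, majority-matching ties) carry deterministic
  lexicographic tie-breaks; the whole pipeline is a pure function of its
  inputs and two identical runs produce byte-identical artifacts.
- Empty gene sets are rejected by the repetitive rate; gene sets with no
  genes in the matrix are skipped with a warning; a constant expression
  submatrix yields a single zero feature column rather than an error.

## Known limitations

- Enriching the full post-filter gene list (rather than a differential
  subset) makes significance depend on how the dataset's gene panel
  relates to the annotation corpus; with a corpus identical to the input
  list nothing can be significant.
- SimRel is undefined across namespaces, so redundancy between, say, a
  BP and a CC term is only caught later by the gene-overlap stage.
- The cosine kernel ignores per-gene scale entirely; a gene set dominated
  by one highly expressed gene can mask subtler structure.
- No identifier mapping: expression gene ids must match the annotation
  corpus verbatim.
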