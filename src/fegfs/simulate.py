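"""Self-contained synthetic fixtures: toy ontology, annotations, expression.

The generator builds a small layered GO-like DAG (one root per namespace,
every non-root term with 1-2 parents from the level above) plus a gene
corpus annotated to the leaf terms, and an expression matrix with planted
cell clusters whose marker genes sit inside specific leaf-term gene sets.
The construction guarantees work for every pipeline stage:

* cluster leaves draw their genes almost entirely from the expression
  genes, so the hypergeometric test finds them over-represented;
* each cluster leaf has a "twin" leaf in a disjoint DAG branch sharing
  ~90% of its genes — high repetitive rate but near-zero SimRel — so the
  overlap-merging stage has pairs to merge;
* enriched leaves coexist with their enriched ancestors, giving the
  SimRel reduction parent-child pairs above the 0.4 cutoff;
* background leaves sample the whole corpus uniformly and stay
  non-significant.

Expression is log-normal with a multiplicative 10**effect marker shift per
cluster and Bernoulli dropout — the simplest model with the positivity and
sparsity the pipeline assumes, not a realistic scRNA-seq simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .features import ExpressionMatrix
from .ontology import AnnotationMap, OntologyGraph

_NS_LONG = {"BP": "biological_process", "MF": "molecular_function",
            "CC": "cellular_component"}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic fixture; equal seeds give equal output."""

    n_cells: int = 200
    n_genes: int = 400           # genes in the expression matrix
    n_clusters: int = 4
    n_terms: int = 40            # terms in the primary namespace
    depth: int = 4               # DAG levels including the root
    frac_marker: float = 0.10    # fraction of expression genes that mark a cluster
    effect: float = 2.0          # marker shift in log10 units
    dropout: float = 0.2         # probability an expressed value is zeroed
    seed: int = 0
    namespaces: tuple[str, ...] = ("BP",)

    def __post_init__(self) -> None:
        for name in ("n_cells", "n_genes", "n_clusters", "n_terms", "depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("frac_marker", "dropout"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_terms < self.depth:
            raise ValueError("need n_terms >= depth")
        if self.n_clusters > self.n_cells:
            raise ValueError("more clusters than cells")


def _term_id(ns: str, i: int) -> str:
    return f"ST:{ns}{i:05d}"


def make_ontology(spec: FixtureSpec) -> tuple[OntologyGraph, AnnotationMap]:
    """Build the DAG and direct annotations described in the module docs.

    The corpus holds twice as many genes as the expression matrix, so the
    expression genes form a proper subset of the annotation universe and
    over-representation is possible at all.
    """
    rng = np.random.default_rng(spec.seed)
    corpus = 2 * spec.n_genes
    width = max(4, len(str(corpus - 1)))
    genes = [f"g{i:0{width}d}" for i in range(corpus)]

    terms: set[str] = set()
    name: dict[str, str] = {}
    namespace: dict[str, str] = {}
    parents: dict[str, set[str]] = {}
    annot = AnnotationMap()

    primary = spec.namespaces[0]
    _build_namespace(spec, rng, primary, genes, terms, name, namespace,
                     parents, annot)
    for ns in spec.namespaces[1:]:
        _build_small_namespace(spec, rng, ns, genes, terms, name, namespace,
                               parents, annot)

    graph = OntologyGraph(terms=terms, name=name, namespace=namespace,
                          parents=parents)
    graph.validate()
    return graph, annot


def _build_namespace(spec, rng, ns, genes, terms, name, namespace, parents,
                     annot) -> None:
    depth = spec.depth
    n_inter_levels = max(0, depth - 2)
    inter_per_level = 4 if depth >= 3 else 0
    n_leaves = spec.n_terms - 1 - n_inter_levels * inter_per_level
    if n_leaves < 2 * spec.n_clusters + 1:
        raise ValueError(
            f"infeasible spec: {spec.n_terms} terms at depth {depth} leave "
            f"only {n_leaves} leaf terms; need at least "
            f"{2 * spec.n_clusters + 1} (cluster leaves, twins, background)"
        )

    counter = 0

    def new_term(label: str, branch_parents: list[str]) -> str:
        nonlocal counter
        tid = _term_id(ns, counter)
        counter += 1
        terms.add(tid)
        name[tid] = label
        namespace[tid] = ns
        if branch_parents:
            n_par = 1 if len(branch_parents) == 1 else int(rng.integers(1, 3))
            chosen = rng.choice(len(branch_parents), size=n_par, replace=False)
            parents[tid] = {branch_parents[c] for c in chosen}
        else:
            parents[tid] = set()
        return tid

    root = new_term(f"{ns} root", [])
    # two disjoint branches so twin leaves share no ancestor but the root
    levels: list[dict[int, list[str]]] = [{0: [root], 1: [root]}]
    for lv in range(1, depth - 1):
        level: dict[int, list[str]] = {0: [], 1: []}
        for branch in (0, 1):
            for j in range(inter_per_level // 2):
                level[branch].append(new_term(
                    f"{ns} level{lv} branch{branch} #{j}",
                    levels[lv - 1][branch]))
        levels.append(level)

    n_expr = spec.n_genes
    n_markers = max(spec.n_clusters, round(spec.frac_marker * n_expr))
    per_cluster = n_markers // spec.n_clusters
    block = max(2 * per_cluster, round(0.08 * n_expr), 4)
    nonmarker_expr = np.arange(n_markers, n_expr)

    cluster_blocks: list[np.ndarray] = []
    leaf_parents = levels[-1]
    # cluster leaves (branch 0): markers + random expression genes
    for c in range(spec.n_clusters):
        markers = np.arange(c * per_cluster, (c + 1) * per_cluster)
        extra = rng.choice(nonmarker_expr, size=block - per_cluster,
                           replace=False)
        idx = np.concatenate([markers, extra])
        cluster_blocks.append(idx)
        tid = new_term(f"{ns} cluster-leaf {c}", leaf_parents[0])
        for g in idx:
            annot.add(genes[g], tid)
    # twin leaves (branch 1): ~90% of the matching cluster block
    for c in range(spec.n_clusters):
        src = cluster_blocks[c]
        n_shared = max(1, math.ceil(0.9 * len(src)))
        shared = rng.choice(src, size=n_shared, replace=False)
        candidates = np.setdiff1d(nonmarker_expr, src, assume_unique=False)
        fresh = rng.choice(candidates, size=len(src) - n_shared, replace=False)
        tid = new_term(f"{ns} twin-leaf {c}", leaf_parents[1])
        for g in np.concatenate([shared, fresh]):
            annot.add(genes[g], tid)
    # background leaves: uniform draws over the whole corpus
    n_background = n_leaves - 2 * spec.n_clusters
    for b in range(n_background):
        idx = rng.choice(len(genes), size=block, replace=False)
        tid = new_term(f"{ns} background-leaf {b}",
                       leaf_parents[b % 2])
        for g in idx:
            annot.add(genes[g], tid)


def _build_small_namespace(spec, rng, ns, genes, terms, name, namespace,
                           parents, annot) -> None:
    # a minimal root + two leaves, enough to exercise per-namespace logic
    root = _term_id(ns, 0)
    terms.add(root)
    name[root] = f"{ns} root"
    namespace[root] = ns
    parents[root] = set()
    for j in (1, 2):
        tid = _term_id(ns, j)
        terms.add(tid)
        name[tid] = f"{ns} leaf {j}"
        namespace[tid] = ns
        parents[tid] = {root}
        idx = rng.choice(spec.n_genes, size=max(4, spec.n_genes // 20),
                         replace=False)
        for g in idx:
            annot.add(genes[g], tid)


def make_expression(
    spec: FixtureSpec, annot: AnnotationMap
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Log-normal expression with planted clusters and dropout.

    Cells are split as evenly as possible into ``n_clusters`` groups; each
    group's marker block (disjoint across groups, drawn from annotated
    genes) is multiplied by 10**effect before dropout zeroes a Bernoulli
    fraction of entries.  Returns the raw (not log-transformed) matrix and
    the planted integer labels.
    """
    rng = np.random.default_rng(spec.seed + 1)
    n, g = spec.n_cells, spec.n_genes
    width = max(4, len(str(2 * g - 1)))
    gene_ids = [f"g{i:0{width}d}" for i in range(g)]
    n_markers = max(spec.n_clusters, round(spec.frac_marker * g))
    per_cluster = n_markers // spec.n_clusters
    missing = [gid for gid in gene_ids[:spec.n_clusters * per_cluster]
               if gid not in annot.direct]
    if missing:
        raise ValueError(f"marker genes not annotated: {missing[:5]}")

    values = rng.lognormal(mean=1.0, sigma=1.0, size=(n, g))
    sizes = [n // spec.n_clusters + (1 if i < n % spec.n_clusters else 0)
             for i in range(spec.n_clusters)]
    labels = np.repeat(np.arange(spec.n_clusters), sizes)

    for c in range(spec.n_clusters):
        cells = labels == c
        cols = slice(c * per_cluster, (c + 1) * per_cluster)
        values[np.ix_(cells, np.arange(g)[cols])] *= 10.0 ** spec.effect

    if spec.dropout > 0:
        values[rng.random(values.shape) < spec.dropout] = 0.0

    cell_ids = [f"cell{i:04d}" for i in range(n)]
    return ExpressionMatrix(values=values, cell_ids=cell_ids,
                            gene_ids=gene_ids), labels


def write_obo(graph: OntologyGraph, path: str | Path) -> None:
    """Emit the DAG as a minimal OBO 1.2 document (sorted, deterministic)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n")
        for tid in sorted(graph.terms):
            fh.write(f"\n[Term]\nid: {tid}\nname: {graph.name[tid]}\n")
            fh.write(f"namespace: {_NS_LONG[graph.namespace[tid]]}\n")
            for p in sorted(graph.parents.get(tid, ())):
                fh.write(f"is_a: {p}\n")


def write_annotations_tsv(annot: AnnotationMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gene in sorted(annot.direct):
            for term in sorted(annot.direct[gene]):
                fh.write(f"{gene}\t{term}\n")


def write_fixture(spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Generate and persist a complete fixture bundle; returns the paths."""
    from .cluster import write_labels
    from .features import write_expression

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    graph, annot = make_ontology(spec)
    expr, labels = make_expression(spec, annot)
    paths = {
        "obo": outdir / "fixture.obo",
        "annotations": outdir / "annotations.tsv",
        "expression": outdir / "expression.csv",
        "labels": outdir / "labels.tsv",
    }
    write_obo(graph, paths["obo"])
    write_annotations_tsv(annot, paths["annotations"])
    write_expression(expr, paths["expression"])
    write_labels(expr.cell_ids, labels, paths["labels"])
    return paths
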