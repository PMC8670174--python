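"""Hypergeometric over-representation test with BH-FDR control.

Each GO namespace (BP/MF/CC) is tested independently: for a term with M
corpus genes out of N annotated in the namespace, and an input list with n
genes annotated in the namespace of which k carry the term, the p-value is
the upper hypergeometric tail P(X >= k).  Benjamini-Hochberg adjustment is
applied within each namespace and terms with q <= alpha are reported, each
carrying its input-gene intersection — the gene set that all downstream
redundancy reduction and feature extraction operates on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .ontology import AnnotationMap, OntologyGraph, annotated_input

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichedTerm:
    """A significantly enriched term and its hypergeometric bookkeeping."""

    term: str
    genes: frozenset[str]   # input genes carrying the term (the k-set)
    k: int                  # |genes|
    n: int                  # input genes annotated in this namespace
    M: int                  # corpus genes carrying the term
    N: int                  # corpus genes annotated in this namespace
    p_value: float
    q_value: float
    namespace: str = ""
    name: str = ""


def hypergeom_pvalue(k: int, n: int, M: int, N: int) -> float:
    """Upper-tail probability P(X >= k) of drawing k term genes.

    X ~ Hypergeometric(N population, M successes, n draws).
    """
    if not (0 <= M <= N and 0 <= k <= n <= N):
        raise ValueError(f"invalid hypergeometric bounds k={k} n={n} M={M} N={N}")
    if k > min(n, M):
        raise ValueError(f"k={k} exceeds min(n={n}, M={M})")
    # sf(k-1) = P(X > k-1) = P(X >= k)
    return float(hypergeom.sf(k - 1, N, M, n))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    genes: Iterable[str],
    graph: OntologyGraph,
    annot: AnnotationMap,
    alpha: float = 0.05,
    min_genes: int = 2,
) -> list[EnrichedTerm]:
    """Test every namespace term against the input list; keep q <= alpha.

    ``annot`` must already be propagated.  Terms with fewer than
    ``min_genes`` input genes are not tested.  Results are sorted by
    (namespace, q, p, term) for deterministic output.
    """
    input_genes = set(genes)
    if not any(annot.propagated.get(g) for g in input_genes):
        raise ValueError(
            "no input gene carries any annotation; check that gene "
            "identifiers match the annotation corpus"
        )

    ns_corpus: dict[str, set[str]] = {}
    for gene, terms in annot.propagated.items():
        for t in terms:
            ns_corpus.setdefault(graph.namespace[t], set()).add(gene)

    results: list[EnrichedTerm] = []
    for ns in sorted(ns_corpus):
        corpus = ns_corpus[ns]
        N = len(corpus)
        input_ns = annotated_input(annot, input_genes, ns, graph)
        n = len(input_ns)
        if n == 0:
            continue
        tested: list[EnrichedTerm] = []
        for term in sorted(t for t in annot.term_genes
                           if graph.namespace[t] == ns):
            term_set = annot.term_genes[term]
            hit = frozenset(term_set & input_ns)
            k = len(hit)
            if k < min_genes:
                continue
            p = hypergeom_pvalue(k, n, len(term_set), N)
            tested.append(EnrichedTerm(
                term=term, genes=hit, k=k, n=n, M=len(term_set), N=N,
                p_value=p, q_value=p, namespace=ns,
                name=graph.name.get(term, term),
            ))
        if not tested:
            continue
        qvals = bh_fdr([t.p_value for t in tested])
        for t, q in zip(tested, qvals):
            if q <= alpha:
                results.append(EnrichedTerm(
                    term=t.term, genes=t.genes, k=t.k, n=t.n, M=t.M, N=t.N,
                    p_value=t.p_value, q_value=float(q),
                    namespace=t.namespace, name=t.name,
                ))
        logger.info("namespace %s: tested %d terms, %d significant at %g",
                    ns, len(tested), sum(
                        1 for r in results if r.namespace == ns), alpha)

    results.sort(key=lambda t: (t.namespace, t.q_value, t.p_value, t.term))
    return results


def write_enrichment_tsv(terms: Sequence[EnrichedTerm], path) -> None:
    """Persist results as a TSV with one row per enriched term."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term\tname\tnamespace\tk\tn\tM\tN\tp_value\tq_value\tgenes\n")
        for t in terms:
            fh.write(
                f"{t.term}\t{t.name}\t{t.namespace}\t{t.k}\t{t.n}\t{t.M}\t"
                f"{t.N}\t{t.p_value:.6g}\t{t.q_value:.6g}\t"
                f"{','.join(sorted(t.genes))}\n"
            )
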