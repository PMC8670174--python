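"""Shared fixtures: tiny hand-built ontologies and seeded pipeline runs."""

import numpy as np
import pytest

from fegfs.ontology import AnnotationMap, OntologyGraph, propagate
from fegfs.simulate import FixtureSpec, make_expression, make_ontology


def build_graph(parents: dict[str, set[str]],
                namespace: dict[str, str] | None = None) -> OntologyGraph:
    """Construct an OntologyGraph from a parents dict (default all-BP)."""
    terms = set(parents)
    ns = namespace or {t: "BP" for t in terms}
    return OntologyGraph(terms=terms, name={t: t for t in terms},
                         namespace=ns, parents={t: set(p) for t, p in
                                                parents.items()})


@pytest.fixture
def diamond():
    """Root R, children A/B, leaf D with both A and B as parents, leaf C.

    Annotated corpus: four genes, chosen so P(A) = 0.5 and P(C) = P(D) = 0.25.
    """
    graph = build_graph({
        "R": set(), "A": {"R"}, "B": {"R"}, "C": {"A"}, "D": {"A", "B"},
    })
    annot = AnnotationMap()
    annot.add("w", "C")
    annot.add("x", "D")
    annot.add("y", "B")
    annot.add("z", "R")
    return graph, propagate(graph, annot)


@pytest.fixture(scope="session")
def strong_spec():
    return FixtureSpec(n_cells=200, n_clusters=4, effect=2.0, seed=11)


@pytest.fixture(scope="session")
def strong_fixture(strong_spec):
    graph, annot = make_ontology(strong_spec)
    expr, labels = make_expression(strong_spec, annot)
    return graph, annot, expr, labels


def run_stages(graph, annot, expr, k):
    """Library-level pipeline: filter -> log -> enrich -> reduce -> cluster."""
    from fegfs import (FunctionalGeneSet, agglomerative, build_feature_matrix,
                       enrich, filter_noise_genes, log_transform,
                       reduce_redundancy, reduce_terms, retention_ratio)

    amap = propagate(graph, annot)
    e = log_transform(filter_noise_genes(expr))
    terms = enrich(e.gene_ids, graph, amap)
    terms = reduce_terms(terms, graph, amap)
    sets = reduce_redundancy([FunctionalGeneSet.from_enriched(t)
                              for t in terms])
    fm = build_feature_matrix(e, sets, retention_ratio(e.n_cells))
    return agglomerative(fm, k=k).labels


@pytest.fixture(scope="session")
def strong_run(strong_fixture, strong_spec):
    graph, annot, expr, labels = strong_fixture
    pred = run_stages(graph, annot, expr, k=strong_spec.n_clusters)
    return labels, pred


@pytest.fixture(scope="session")
def null_run():
    spec = FixtureSpec(n_cells=200, n_clusters=4, effect=0.0, seed=11)
    graph, annot = make_ontology(spec)
    expr, labels = make_expression(spec, annot)
    pred = run_stages(graph, annot, expr, k=spec.n_clusters)
    return labels, pred


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
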