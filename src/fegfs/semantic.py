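"""SimRel semantic similarity and representative-term selection.

SimRel between two terms g1, g2 in the same namespace is the Lin similarity
scaled by how informative their most informative common ancestor (MIA) is:

    sim(g1, g2) = [2 log P(MIA) / (log P(g1) + log P(g2))] * (1 - P(MIA))

where P(t) is the annotation frequency of t and the MIA is the common
ancestor with minimal P.  The (1 - P(MIA)) factor zeroes out similarity
mediated only by a namespace root (P = 1), so terms related only through
"biological_process" count as unrelated.

``reduce_terms`` collapses an enriched-term list the way REVIGO does:
repeatedly take the most similar remaining pair at or above the cutoff and
discard one member — the descendant if one term is an ancestor of the other
(the ancestor is the natural representative), otherwise the term with the
weaker p-value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

from .enrichment import EnrichedTerm
from .ontology import AnnotationMap, OntologyGraph

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TermCluster:
    """A representative term and the similar terms it absorbed."""

    representative: str
    members: frozenset[str]
    cutoff: float


def simrel(graph: OntologyGraph, annot: AnnotationMap,
           g1: str, g2: str) -> float:
    """SimRel similarity in [0, 1] between two same-namespace terms."""
    if graph.namespace[g1] != graph.namespace[g2]:
        raise ValueError(
            f"SimRel is undefined across namespaces: {g1} is "
            f"{graph.namespace[g1]}, {g2} is {graph.namespace[g2]}"
        )
    p1 = annot.frequency.get(g1, 0.0)
    p2 = annot.frequency.get(g2, 0.0)
    if p1 <= 0.0 or p2 <= 0.0:
        raise ValueError(f"terms must have positive frequency: {g1}, {g2}")

    common = graph.ancestors(g1) & graph.ancestors(g2)
    common = {t for t in common if annot.frequency.get(t, 0.0) > 0.0}
    if not common:
        return 0.0
    # MIA: minimal frequency; ties broken lexicographically for determinism
    mia = min(common, key=lambda t: (annot.frequency[t], t))
    p_mia = annot.frequency[mia]
    if p_mia >= 1.0:
        return 0.0
    denom = math.log(p1) + math.log(p2)
    if denom == 0.0:
        return 0.0
    return (2.0 * math.log(p_mia) / denom) * (1.0 - p_mia)


def _keep_of_pair(a: EnrichedTerm, b: EnrichedTerm,
                  graph: OntologyGraph) -> EnrichedTerm:
    # ancestor-first: the "father" term represents its descendant
    if graph.is_ancestor(a.term, b.term):
        return a
    if graph.is_ancestor(b.term, a.term):
        return b
    key = lambda t: (t.p_value, -t.M, t.term)
    return min(a, b, key=key)


def reduce_terms(
    terms: Sequence[EnrichedTerm],
    graph: OntologyGraph,
    annot: AnnotationMap,
    cutoff: float = 0.4,
    representative: str = "ancestor_first",
    report: list[tuple[str, str, float]] | None = None,
) -> list[EnrichedTerm]:
    """Greedy within-namespace collapse of similar terms at ``cutoff``.

    The most similar pair >= cutoff is resolved first (ties broken by term
    id); its discarded member is recorded in ``report`` as
    (discarded, representative, similarity) when a list is supplied.
    ``representative="pvalue"`` disables the ancestor-first rule and keeps
    the stronger p-value unconditionally (REVIGO's behaviour).

    Survivors keep their gene sets and input order.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must be in [0, 1], got {cutoff}")
    if representative not in ("ancestor_first", "pvalue"):
        raise ValueError(f"unknown representative rule {representative!r}")

    alive: dict[str, EnrichedTerm] = {t.term: t for t in terms}
    sims: dict[tuple[str, str], float] = {}
    for a, b in combinations(sorted(alive), 2):
        if graph.namespace[a] != graph.namespace[b]:
            continue
        s = simrel(graph, annot, a, b)
        if s >= cutoff:
            sims[(a, b)] = s

    while sims:
        s = max(sims.values())
        a, b = min(p for p, v in sims.items() if v == s)  # ties: smallest ids
        ta, tb = alive[a], alive[b]
        if representative == "ancestor_first":
            keep = _keep_of_pair(ta, tb, graph)
        else:
            keep = min(ta, tb, key=lambda t: (t.p_value, -t.M, t.term))
        drop = tb if keep is ta else ta
        if report is not None:
            report.append((drop.term, keep.term, s))
        del alive[drop.term]
        sims = {pair: v for pair, v in sims.items() if drop.term not in pair}

    survivors = [t for t in terms if t.term in alive]
    logger.info("semantic reduction: %d -> %d terms at cutoff %.2f",
                len(terms), len(survivors), cutoff)
    return survivors


def clusters_from_report(
    survivors: Sequence[EnrichedTerm],
    report: Sequence[tuple[str, str, float]],
    cutoff: float,
) -> list[TermCluster]:
    """Reconstruct representative->members clusters from a reduction report."""
    absorbed: dict[str, set[str]] = {t.term: {t.term} for t in survivors}
    # walk the report backwards so chains resolve to final representatives
    redirect: dict[str, str] = {}
    for dropped, rep, _ in reversed(report):
        final = redirect.get(rep, rep)
        redirect[dropped] = final
        if final in absorbed:
            absorbed[final].add(dropped)
    return [
        TermCluster(representative=rep, members=frozenset(members),
                    cutoff=cutoff)
        for rep, members in sorted(absorbed.items())
    ]
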