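"""Ontology and annotation handling.

Parses an OBO ontology into a queryable DAG, reads gene->term annotations
(GAF 2.x or two-column TSV), propagates annotations up the DAG under the
true-path rule, and computes per-term annotation frequencies P(t) — the
fraction of annotated genes in a namespace carrying term t.  These
frequencies are the information-content basis of the SimRel semantic
similarity used downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: canonical short namespace codes
NAMESPACES = ("BP", "MF", "CC")

_NS_ALIASES = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
    "BP": "BP",
    "MF": "MF",
    "CC": "CC",
}


class OboParseError(ValueError):
    """Raised for malformed OBO input; carries the offending line number."""


class OntologyValidationError(ValueError):
    """Raised when the parsed ontology violates DAG structure."""


@dataclass
class OntologyGraph:
    """A Gene-Ontology-style DAG: terms, labels, namespaces and parent edges.

    ``parents`` holds is_a and part_of edges only; each namespace restricted
    subgraph is acyclic with a single root.  Obsolete terms are kept in
    ``obsolete`` for bookkeeping but carry no edges and are excluded from
    every query.
    """

    terms: set[str]
    name: dict[str, str]
    namespace: dict[str, str]
    parents: dict[str, set[str]]
    obsolete: set[str] = field(default_factory=set)
    alt_ids: dict[str, str] = field(default_factory=dict)
    _ancestor_cache: dict[str, frozenset[str]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def resolve(self, term: str) -> str | None:
        """Map a term or alt_id to its primary identifier, None if unknown."""
        if term in self.terms:
            return term
        return self.alt_ids.get(term)

    def ancestors(self, term: str) -> frozenset[str]:
        """All ancestors of ``term`` including the term itself (reflexive)."""
        cached = self._ancestor_cache.get(term)
        if cached is not None:
            return cached
        if term not in self.terms:
            raise KeyError(f"unknown term {term!r}")
        result = {term}
        for p in self.parents.get(term, ()):
            result |= self.ancestors(p)
        out = frozenset(result)
        self._ancestor_cache[term] = out
        return out

    def roots(self, namespace: str | None = None) -> set[str]:
        """Terms with no parents, optionally restricted to one namespace."""
        out = set()
        for t in self.terms:
            if namespace is not None and self.namespace.get(t) != namespace:
                continue
            if not self.parents.get(t):
                out.add(t)
        return out

    def is_ancestor(self, anc: str, term: str) -> bool:
        """True if ``anc`` is a strict ancestor of ``term``."""
        return anc != term and anc in self.ancestors(term)

    def validate(self) -> None:
        """Check acyclicity and per-namespace rooting; raise on a cycle."""
        g = nx.DiGraph(
            (child, parent)
            for child, ps in self.parents.items()
            for parent in ps
        )
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OntologyValidationError(
                f"cyclic parent chain involving {cycle[0][0]!r}"
            )
        for ns in sorted({self.namespace[t] for t in self.terms}):
            roots = self.roots(ns)
            if len(roots) != 1:
                logger.warning(
                    "namespace %s has %d roots (expected 1): %s",
                    ns, len(roots), sorted(roots),
                )


@dataclass
class AnnotationMap:
    """Gene <-> term membership, before and after ancestor propagation.

    ``frequency[t]`` is P(t): |genes annotated to t after propagation| over
    the number of genes annotated anywhere in t's namespace.
    """

    direct: dict[str, set[str]] = field(default_factory=dict)
    propagated: dict[str, set[str]] = field(default_factory=dict)
    term_genes: dict[str, set[str]] = field(default_factory=dict)
    frequency: dict[str, float] = field(default_factory=dict)

    @property
    def genes(self) -> set[str]:
        return set(self.direct)

    def add(self, gene: str, term: str) -> None:
        self.direct.setdefault(gene, set()).add(term)


def _pre_scan(path: Path) -> None:
    # obonet's errors carry no positions; validate line shape first so a
    # malformed stanza is reported with its line number.
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("!"):
                continue
            if line.startswith("["):
                if not line.endswith("]"):
                    raise OboParseError(
                        f"{path}:{lineno}: malformed stanza header {line!r}"
                    )
                continue
            if ":" not in line:
                raise OboParseError(
                    f"{path}:{lineno}: expected 'tag: value', got {line!r}"
                )


def parse_obo(path: str | Path) -> OntologyGraph:
    """Read an OBO 1.2/1.4 file into an :class:`OntologyGraph`.

    is_a and ``relationship: part_of`` lines become parent edges; the
    regulates family is deliberately ignored (standard enrichment practice).
    alt_id values are recorded so stale identifiers resolve to their primary
    term.  Raises :class:`OboParseError` with a line number on malformed
    input and :class:`OntologyValidationError` on a cyclic is_a chain.
    """
    path = Path(path)
    _pre_scan(path)
    g = obonet.read_obo(path, ignore_obsolete=False)

    default_ns = "BP"
    dns = g.graph.get("default-namespace")
    if dns:
        default_ns = _NS_ALIASES.get(dns[0], default_ns)

    terms: set[str] = set()
    name: dict[str, str] = {}
    namespace: dict[str, str] = {}
    parents: dict[str, set[str]] = {}
    obsolete: set[str] = set()
    alt_ids: dict[str, str] = {}

    for tid, data in g.nodes(data=True):
        name[tid] = data.get("name", tid)
        namespace[tid] = _NS_ALIASES.get(data.get("namespace", ""), default_ns)
        for alt in data.get("alt_id", []):
            alt_ids[alt] = tid
        if data.get("is_obsolete") == "true":
            obsolete.add(tid)
            continue
        terms.add(tid)
        parents[tid] = set()
        for parent in data.get("is_a", []):
            parents[tid].add(parent.split("!")[0].strip())
        for rel in data.get("relationship", []):
            fields = rel.split("!")[0].split()
            if len(fields) == 2 and fields[0] == "part_of":
                parents[tid].add(fields[1])

    # drop dangling edges (e.g. parents that are obsolete or absent)
    for tid in parents:
        parents[tid] = {p for p in parents[tid] if p in terms}

    graph = OntologyGraph(
        terms=terms, name=name, namespace=namespace,
        parents=parents, obsolete=obsolete, alt_ids=alt_ids,
    )
    graph.validate()
    logger.info(
        "parsed %s: %d terms (%d obsolete)", path, len(terms), len(obsolete)
    )
    return graph


def parse_annotations(path: str | Path, fmt: str = "tsv") -> AnnotationMap:
    """Read gene->term annotations from GAF 2.x or a two-column TSV.

    Gene and term identifiers are taken verbatim (case preserved).  GAF rows
    whose qualifier contains NOT are skipped, as are comment lines.  Returns
    a map with only ``direct`` populated; run :func:`propagate` next.
    """
    path = Path(path)
    if fmt not in ("gaf", "tsv"):
        raise ValueError(f"unknown annotation format {fmt!r}; use 'gaf' or 'tsv'")
    annot = AnnotationMap()
    skipped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("!") or line.startswith("#"):
                continue
            cols = line.split("\t")
            if fmt == "gaf":
                if len(cols) < 5:
                    logger.warning("%s:%d: short GAF row skipped", path, lineno)
                    skipped += 1
                    continue
                qualifier, gene, term = cols[3], cols[2], cols[4]
                if "NOT" in qualifier.split("|"):
                    continue
            else:
                if len(cols) < 2 or not cols[1].strip():
                    logger.warning("%s:%d: row lacks a term column, skipped",
                                   path, lineno)
                    skipped += 1
                    continue
                gene, term = cols[0].strip(), cols[1].strip()
            if not gene or not term:
                skipped += 1
                continue
            annot.add(gene, term)
    logger.info("parsed %s: %d genes, %d rows skipped",
                path, len(annot.direct), skipped)
    return annot


def propagate(
    graph: OntologyGraph,
    annot: AnnotationMap,
    frequency_override: Mapping[str, float] | None = None,
) -> AnnotationMap:
    """Close annotations under ancestry and compute term frequencies.

    Unknown terms (not in the graph, not resolvable via alt_id) are dropped
    with a warning.  Frequencies are computed per namespace over the genes
    annotated in that namespace; pass ``frequency_override`` to substitute
    an external corpus (e.g. precomputed UniProt frequencies).

    Idempotent: propagating an already-propagated map changes nothing.
    """
    out = AnnotationMap(direct={g: set(ts) for g, ts in annot.direct.items()})
    dropped: set[str] = set()
    for gene, terms in annot.direct.items():
        closed: set[str] = set()
        for t in terms:
            primary = graph.resolve(t)
            if primary is None or primary in graph.obsolete:
                dropped.add(t)
                continue
            closed |= graph.ancestors(primary)
        out.propagated[gene] = closed
    if dropped:
        logger.warning("dropped %d unknown/obsolete terms: %s",
                       len(dropped), sorted(dropped)[:10])

    for gene, terms in out.propagated.items():
        for t in terms:
            out.term_genes.setdefault(t, set()).add(gene)

    ns_genes: dict[str, set[str]] = {}
    for gene, terms in out.propagated.items():
        for t in terms:
            ns_genes.setdefault(graph.namespace[t], set()).add(gene)

    for t, genes in out.term_genes.items():
        denom = len(ns_genes[graph.namespace[t]])
        out.frequency[t] = len(genes) / denom

    if frequency_override is not None:
        for t, f in frequency_override.items():
            if not 0.0 < f <= 1.0 or not math.isfinite(f):
                raise ValueError(f"override frequency for {t} out of (0,1]: {f}")
            out.frequency[t] = float(f)
    return out


def annotated_input(annot: AnnotationMap, genes: Iterable[str],
                    namespace: str, graph: OntologyGraph) -> set[str]:
    """Input genes carrying at least one propagated term in ``namespace``."""
    out = set()
    for g in genes:
        for t in annot.propagated.get(g, ()):
            if graph.namespace[t] == namespace:
                out.add(g)
                break
    return out
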