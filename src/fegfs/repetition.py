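"""Gene repetitive-rate reduction of functional gene sets.

After semantic reduction the surviving terms' gene sets still overlap
heavily.  The repetitive rate between two sets is

    R(A, B) = |A ∩ B| / min(|A|, |B|)

so R = 1 means the smaller set is fully covered by the larger.  Reduction
alternates two steps: drop fully covered sets (keeping the larger of each
pair), then best-first merge pairs whose rate reaches the threshold (0.8 by
default) into union sets.  Two such screening rounds are the default; a
convergence mode repeats until nothing changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .enrichment import EnrichedTerm

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FunctionalGeneSet:
    """A (possibly merged) gene set derived from one or more GO terms."""

    id: str
    genes: frozenset[str]
    source_terms: frozenset[str]

    @classmethod
    def from_enriched(cls, term: EnrichedTerm) -> "FunctionalGeneSet":
        return cls(id=term.term, genes=term.genes,
                   source_terms=frozenset({term.term}))

    def merge(self, other: "FunctionalGeneSet") -> "FunctionalGeneSet":
        sources = self.source_terms | other.source_terms
        return FunctionalGeneSet(
            id="merged:" + "+".join(sorted(sources)),
            genes=self.genes | other.genes,
            source_terms=sources,
        )


def repetitive_rate(a: Iterable[str], b: Iterable[str]) -> float:
    """|a ∩ b| / min(|a|, |b|); both sets must be non-empty."""
    sa, sb = set(a), set(b)
    if not sa or not sb:
        raise ValueError("repetitive rate is undefined for empty gene sets")
    return len(sa & sb) / min(len(sa), len(sb))


def rate_matrix(sets: Sequence[FunctionalGeneSet]) -> np.ndarray:
    """Symmetric pairwise repetitive-rate matrix with unit diagonal."""
    if not sets:
        raise ValueError("need at least one gene set")
    m = len(sets)
    R = np.eye(m)
    for i, j in combinations(range(m), 2):
        R[i, j] = R[j, i] = repetitive_rate(sets[i].genes, sets[j].genes)
    return R


def remove_covered(sets: Sequence[FunctionalGeneSet]) -> list[FunctionalGeneSet]:
    """Drop every set fully covered (rate 1) by a larger surviving set.

    Among identical equal-size sets the lexicographically smallest id is
    kept.  Survivors' genes are unchanged; original order is preserved.
    """
    order = sorted(sets, key=lambda s: (-len(s.genes), s.id))
    kept: list[FunctionalGeneSet] = []
    for s in order:
        if any(s.genes <= k.genes for k in kept):
            continue
        kept.append(s)
    kept_ids = {s.id for s in kept}
    return [s for s in sets if s.id in kept_ids]


def merge_round(
    sets: Sequence[FunctionalGeneSet], threshold: float = 0.8
) -> list[FunctionalGeneSet]:
    """Best-first pairwise merging of sets with rate >= threshold.

    The highest-rate pair merges first (ties: larger union, then smaller
    ids); the union replaces the pair and its rates are recomputed.  Stops
    when no remaining pair reaches the threshold.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    pool = list(sets)
    while len(pool) > 1:
        candidates = []
        for i, j in combinations(range(len(pool)), 2):
            a, b = pool[i], pool[j]
            r = repetitive_rate(a.genes, b.genes)
            if r >= threshold:
                candidates.append((-r, -len(a.genes | b.genes),
                                   sorted([a.id, b.id]), i, j))
        if not candidates:
            break
        _, _, _, i, j = min(candidates)
        merged = pool[i].merge(pool[j])
        pool = [s for idx, s in enumerate(pool) if idx not in (i, j)]
        pool.append(merged)
    return pool


def reduce_redundancy(
    sets: Sequence[FunctionalGeneSet],
    threshold: float = 0.8,
    rounds: int = 2,
    until_converged: bool = False,
) -> list[FunctionalGeneSet]:
    """Alternate covered-set removal and merging for ``rounds`` screenings.

    Two rounds are the default.  With ``until_converged`` the pass repeats
    until a fixpoint, guaranteeing all final pairwise rates < threshold.
    The union of genes over all sets is invariant under this operation.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    current = list(sets)
    done = 0
    while True:
        before = [(s.id, s.genes) for s in current]
        current = remove_covered(current)
        current = merge_round(current, threshold)
        done += 1
        if until_converged:
            if [(s.id, s.genes) for s in current] == before:
                break
        elif done >= rounds:
            break
    if len(current) > 1:
        worst = max(
            repetitive_rate(a.genes, b.genes)
            for a, b in combinations(current, 2)
        )
        if worst >= threshold:
            logger.warning(
                "redundancy reduction did not converge in %d rounds: "
                "max pairwise rate %.3f >= %.3f", done, worst, threshold
            )
    logger.info("repetition reduction: %d -> %d sets after %d round(s)",
                len(sets), len(current), done)
    return current


def write_gmt(sets: Sequence[FunctionalGeneSet], path,
              description: str = "fegfs") -> None:
    """Write gene sets in GMT format (id, description, genes...)."""
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.id, description, *sorted(s.genes)]) + "\n")


def read_gmt(path) -> list[FunctionalGeneSet]:
    """Read gene sets from a GMT file."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 3:
                continue
            out.append(FunctionalGeneSet(
                id=cols[0], genes=frozenset(cols[2:]),
                source_terms=frozenset(cols[0].removeprefix("merged:").split("+")),
            ))
    return out
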