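"""Generation of GeneTerm-sets by singular and concurrent enrichment.

A GeneTerm-set ``E = (G, A, p)`` pairs a set of query genes ``G`` with the
set of terms ``A`` they are all annotated with, plus the hypergeometric
enrichment p-value ``p``.  Singular enrichment (SEA) emits one element per
term (``|A| = 1``); concurrent enrichment (MEA) enumerates closed frequent
itemsets of terms over the query genes' annotation transactions, so
synonymous terms annotating the same genes land in one element.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from scipy.stats import hypergeom

from gtlinker.annotation_space import SOURCE_SEP, AnnotationSpace

__all__ = [
    "GeneTermSet",
    "QueryContext",
    "hypergeometric_tail",
    "singular_enrichment",
    "concurrent_enrichment",
    "load_genetermsets",
    "write_genetermsets",
]

logger = logging.getLogger(__name__)

#: queries smaller than this make gene/term linkage hard to achieve;
#: we warn but do not fail.
MIN_COMFORTABLE_QUERY = 7


@dataclass(frozen=True)
class GeneTermSet:
    """One enrichment element: genes, their co-annotated terms, p-value."""

    element_id: str
    genes: frozenset[str]
    terms: frozenset[str]  # term ids with source prefixes, e.g. "KEGG::03050"
    p_value: float

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"{self.element_id}: empty gene set")
        if not self.terms:
            raise ValueError(f"{self.element_id}: empty term set")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(
                f"{self.element_id}: p_value {self.p_value} outside (0, 1]"
            )


@dataclass(frozen=True)
class QueryContext:
    """The query gene list; its order defines the element-vector axes."""

    query_genes: tuple[str, ...]
    universe_size: int

    def __post_init__(self) -> None:
        if len(self.query_genes) == 0:
            raise ValueError("empty query")
        if len(set(self.query_genes)) != len(self.query_genes):
            seen: set[str] = set()
            deduped = []
            for g in self.query_genes:
                if g not in seen:
                    seen.add(g)
                    deduped.append(g)
            logger.warning(
                "query contains %d duplicate gene id(s); removed",
                len(self.query_genes) - len(deduped),
            )
            object.__setattr__(self, "query_genes", tuple(deduped))
        if self.universe_size < len(self.query_genes):
            raise ValueError("universe smaller than query")
        if len(self.query_genes) < MIN_COMFORTABLE_QUERY:
            logger.warning(
                "query has only %d genes; linkage is unreliable below %d",
                len(self.query_genes),
                MIN_COMFORTABLE_QUERY,
            )

    @classmethod
    def from_genes(cls, genes: Sequence[str], universe_size: int) -> "QueryContext":
        return cls(tuple(str(g).strip() for g in genes), universe_size)

    @property
    def M(self) -> int:
        """Number of genes in the query list."""
        return len(self.query_genes)


def hypergeometric_tail(k: int, n: int, K: int, N: int) -> float:
    """Exact upper-tail probability P(X >= k), X ~ Hypergeom(N, K, n).

    ``k`` observed successes in a sample of ``n`` draws from a population of
    ``N`` containing ``K`` successes.  ``k = 0`` gives 1.0 by definition.
    """
    if not (0 <= K <= N):
        raise ValueError(f"need 0 <= K <= N, got K={K}, N={N}")
    if not (0 <= n <= N):
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"need 0 <= k <= min(n, K), got k={k}, n={n}, K={K}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def _query_term_support(
    query: QueryContext, spaces: Sequence[AnnotationSpace]
) -> tuple[dict[str, frozenset[str]], dict[str, int]]:
    """Prefixed term -> supporting query genes; and prefixed term -> Ng."""
    query_set = set(query.query_genes)
    support: dict[str, frozenset[str]] = {}
    ng: dict[str, int] = {}
    for space in spaces:
        for term, genes in space.term_to_genes.items():
            pref = space.prefixed(term)
            support[pref] = frozenset(genes & query_set)
            ng[pref] = len(genes)
    return support, ng


def singular_enrichment(
    query: QueryContext,
    spaces: Sequence[AnnotationSpace],
    min_support: int = 3,
    p_max: float = 0.05,
) -> list[GeneTermSet]:
    """One-term-at-a-time (SEA) enrichment.

    For each term with at least ``min_support`` query genes, tests the
    overlap against Hypergeom(N=universe, K=Ng, n=M) and keeps elements with
    ``p <= p_max``.  Output is sorted by (p, terms) and ids are ``E1..En``.
    """
    support, ng = _query_term_support(query, spaces)
    candidates = []
    for term in sorted(support):
        genes = support[term]
        if len(genes) < min_support:
            continue
        p = hypergeometric_tail(len(genes), query.M, ng[term], query.universe_size)
        if p <= p_max:
            candidates.append((p, (term,), genes))
    return _finalize_elements(candidates)


def concurrent_enrichment(
    query: QueryContext,
    spaces: Sequence[AnnotationSpace],
    min_support: int = 3,
    p_max: float = 0.05,
) -> list[GeneTermSet]:
    """Closed-frequent-itemset (MEA) enrichment over co-annotations.

    Transactions are the query genes, items the prefixed terms.  Each closed
    itemset ``A`` with support >= ``min_support`` yields a candidate element
    with ``G`` = query genes carrying every term of ``A`` and
    ``K`` = universe genes carrying every term of ``A``; elements with
    ``p <= p_max`` are kept.

    Closed itemsets are enumerated through their transaction sets: the
    family of term supports is closed under pairwise intersection, and every
    closed itemset is recovered as the full set of terms covering one such
    intersection.  Support pruning is safe because intersections only shrink.
    """
    support, _ = _query_term_support(query, spaces)
    frequent = {t: g for t, g in support.items() if len(g) >= min_support}

    tidsets: set[frozenset[str]] = set(frequent.values())
    frontier = set(tidsets)
    seeds = list(frequent.values())
    while frontier:
        new: set[frozenset[str]] = set()
        for g in frontier:
            for s in seeds:
                inter = g & s
                if len(inter) >= min_support and inter not in tidsets:
                    new.add(inter)
        tidsets.update(new)
        frontier = new

    # universe-wide carriers of all terms of an itemset, for K
    def universe_support(terms: Iterable[str]) -> int:
        carriers: frozenset[str] | None = None
        for space in spaces:
            for term, genes in space.term_to_genes.items():
                if space.prefixed(term) in terms:
                    carriers = genes if carriers is None else carriers & genes
        return len(carriers) if carriers is not None else 0

    candidates = []
    for genes in tidsets:
        itemset = tuple(sorted(t for t, g in frequent.items() if genes <= g))
        if not itemset:
            continue
        K = universe_support(set(itemset))
        p = hypergeometric_tail(len(genes), query.M, K, query.universe_size)
        if p <= p_max:
            candidates.append((p, itemset, genes))
    return _finalize_elements(candidates)


def _finalize_elements(
    candidates: list[tuple[float, tuple[str, ...], frozenset[str]]]
) -> list[GeneTermSet]:
    candidates.sort(key=lambda c: (c[0], c[1]))
    return [
        GeneTermSet(
            element_id=f"E{i}",
            genes=genes,
            terms=frozenset(terms),
            p_value=p,
        )
        for i, (p, terms, genes) in enumerate(candidates, start=1)
    ]


_LIST_SEP = ";"


def write_genetermsets(elements: Iterable[GeneTermSet], path: str | Path) -> None:
    """Write elements as TSV (element_id, genes, terms, p_value)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("element_id\tgenes\tterms\tp_value\n")
        for e in elements:
            fh.write(
                f"{e.element_id}\t{_LIST_SEP.join(sorted(e.genes))}\t"
                f"{_LIST_SEP.join(sorted(e.terms))}\t{e.p_value:.10g}\n"
            )


def load_genetermsets(
    path: str | Path, spaces: Sequence[AnnotationSpace] | None = None
) -> list[GeneTermSet]:
    """Load a precomputed GeneTerm-set table.

    Columns: element_id, genes, terms, p_value; gene and term lists
    separated by ``;`` or ``,``.  If ``spaces`` are given, every term must
    exist in them and the co-annotation invariant (every gene annotated with
    every term) is verified; otherwise the table is trusted with a warning.
    """
    path = Path(path)
    known: dict[str, frozenset[str]] = {}
    if spaces is not None:
        for space in spaces:
            for term, genes in space.term_to_genes.items():
                known[space.prefixed(term)] = genes
    else:
        warnings.warn(
            f"{path}: no annotation spaces loaded; co-annotation not verified",
            stacklevel=2,
        )

    elements = []
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"{path}: empty file")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}: row {lineno}: expected 4 columns")
            eid, genes_s, terms_s, p_s = fields
            try:
                p = float(p_s)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: row {lineno}: non-numeric p_value {p_s!r}"
                ) from exc
            if not (0.0 < p <= 1.0):
                raise ValueError(f"{path}: row {lineno}: p_value {p} outside (0, 1]")
            genes = frozenset(
                g.strip() for g in genes_s.replace(",", _LIST_SEP).split(_LIST_SEP) if g.strip()
            )
            terms = frozenset(
                t.strip() for t in terms_s.replace(",", _LIST_SEP).split(_LIST_SEP) if t.strip()
            )
            if spaces is not None:
                for t in terms:
                    if t not in known:
                        raise ValueError(
                            f"{path}: row {lineno}: unknown term {t!r} "
                            f"(terms must carry the source prefix, e.g. GO-BP{SOURCE_SEP}...)"
                        )
                    if not genes <= known[t]:
                        bad = sorted(genes - known[t])[:3]
                        raise ValueError(
                            f"{path}: row {lineno}: gene(s) {bad} not annotated "
                            f"with term {t!r}"
                        )
            elements.append(GeneTermSet(eid.strip(), genes, terms, p))
    if not elements:
        raise ValueError(f"{path}: no elements found")
    return elements
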