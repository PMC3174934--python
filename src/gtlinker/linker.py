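"""Core four-step linkage of GeneTerm-sets into scored metagroups.

Step 1 removes elements annotated only with generic terms.  Step 2 embeds
each element as a gene-occurrence vector (plus a p-value component weighted
by the query size M), clusters the cosine distances with Ward linkage, cuts
the tree at a fraction of its depth, and greedily merges clusters sharing
non-generic terms.  Step 3 removes redundant elements inside each metagroup
(complete cover).  Step 4 scores metagroups with a hypergeometric test
(BH-FDR adjusted), silhouette width, diameter and similarity coefficient,
using gene-only distances.

The whole pipeline is deterministic: no randomness, and every tie has a
documented break rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from gtlinker.annotation_space import (
    SOURCE_SEP,
    AnnotationSpace,
    GenericTermPolicy,
    prefixed_generic_terms,
)
from gtlinker.enrichment import GeneTermSet, QueryContext, hypergeometric_tail

__all__ = [
    "ElementVector",
    "WardTree",
    "Metagroup",
    "filter_generic_only",
    "build_element_vectors",
    "cosine_distance_matrix",
    "ward_tree",
    "cut_pre_metagroups",
    "greedy_term_merge",
    "complete_cover",
    "score_metagroups",
    "link_elements",
]


@dataclass(frozen=True)
class ElementVector:
    """Numeric embedding of one element against the query gene axes.

    Components ``0..M-1`` are 1/0 gene-occurrence indicators in query order;
    component ``M`` is the p-value weighted by M (or 0 in gene-only mode).
    """

    element_id: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", c)
        if np.any(c < 0):
            raise ValueError(f"{self.element_id}: negative vector component")
        if not np.linalg.norm(c) > 0:
            raise ValueError(f"{self.element_id}: zero vector")


@dataclass(frozen=True)
class WardTree:
    """Agglomeration result: leaf labels and a linkage table.

    ``merges`` has one row per merge: (cluster_a, cluster_b, height, size).
    Original observations are clusters ``0..n-1``; merge ``i`` creates
    cluster ``n + i``.
    """

    labels: tuple[str, ...]
    merges: np.ndarray  # shape (n-1, 4)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def max_height(self) -> float:
        return float(self.merges[:, 2].max()) if len(self.merges) else 0.0


@dataclass
class Metagroup:
    """A set of linked GeneTerm-sets with union genes/terms and scores."""

    metagroup_id: str
    elements: list[GeneTermSet]
    raw_p: float | None = None
    adjusted_p: float | None = None
    silhouette: float | None = None  # None = undefined (single metagroup)
    diameter: float | None = None
    similarity_coefficient: float | None = None

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError(f"{self.metagroup_id}: empty metagroup")

    @property
    def union_genes(self) -> frozenset[str]:
        return frozenset().union(*(e.genes for e in self.elements))

    @property
    def union_terms(self) -> frozenset[str]:
        return frozenset().union(*(e.terms for e in self.elements))


def _as_policy_map(
    policies: Mapping[str, GenericTermPolicy] | Iterable[GenericTermPolicy],
) -> dict[str, GenericTermPolicy]:
    if isinstance(policies, Mapping):
        return dict(policies)
    return {p.space_id: p for p in policies}


def filter_generic_only(
    elements: Sequence[GeneTermSet],
    policies: Mapping[str, GenericTermPolicy] | Iterable[GenericTermPolicy],
) -> list[GeneTermSet]:
    """Step 1: drop elements whose entire term set is generic.

    Elements mixing generic and specific terms are retained unchanged.
    Every referenced source must have a policy.
    """
    pmap = _as_policy_map(policies)
    generic = prefixed_generic_terms(pmap)
    for e in elements:
        for t in e.terms:
            source = t.split(SOURCE_SEP, 1)[0] if SOURCE_SEP in t else ""
            if source not in pmap:
                raise ValueError(
                    f"{e.element_id}: term {t!r} references unknown space {source!r}"
                )
    return [e for e in elements if not e.terms <= generic]


def build_element_vectors(
    elements: Sequence[GeneTermSet],
    query: QueryContext,
    p_weight_mode: str = "literal",
) -> list[ElementVector]:
    """Embed elements as M+1 vectors against the query gene order.

    ``literal``: last component is ``p * M``; ``off``: 0 (the gene-only
    geometry used for step-4 statistics).
    """
    if p_weight_mode not in ("literal", "off"):
        raise ValueError(f"unknown p_weight_mode {p_weight_mode!r}")
    index = {g: i for i, g in enumerate(query.query_genes)}
    vectors = []
    for e in elements:
        coords = np.zeros(query.M + 1)
        for g in e.genes:
            if g not in index:
                raise ValueError(f"{e.element_id}: gene {g!r} not in query list")
            coords[index[g]] = 1.0
        if p_weight_mode == "literal":
            coords[query.M] = e.p_value * query.M
        vectors.append(ElementVector(e.element_id, coords))
    return vectors


def cosine_distance_matrix(vectors: Sequence[ElementVector]) -> np.ndarray:
    """Pairwise 1 - cosine similarity; in [0, 1] for non-negative vectors."""
    if len(vectors) == 0:
        raise ValueError("no vectors")
    X = np.vstack([v.coords for v in vectors])
    if len(vectors) == 1:
        return np.zeros((1, 1))
    D = squareform(pdist(X, metric="cosine"))
    np.clip(D, 0.0, 1.0, out=D)
    np.fill_diagonal(D, 0.0)
    return D


def ward_tree(dist: np.ndarray) -> WardTree:
    """Agglomerative Ward linkage on the given dissimilarities.

    Applies the Lance-Williams update directly to the supplied distances
    (the classical "Ward.D" convention), which is well defined for cosine
    dissimilarities even though they need not be Euclidean-embeddable.
    Ties at equal merge distance are broken by the lexicographically
    smallest pair of cluster indices, so the tree is fully deterministic.
    """
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    labels = tuple(str(i) for i in range(n))
    if n == 1:
        return WardTree(labels, np.empty((0, 4)))

    big = 2 * n - 1
    work = np.full((big, big), np.inf)
    work[:n, :n] = D
    np.fill_diagonal(work, np.inf)
    sizes = np.zeros(big, dtype=int)
    sizes[:n] = 1
    active = list(range(n))
    merges = np.zeros((n - 1, 4))

    for step in range(n - 1):
        # minimum over active pairs, tie-broken by smallest (i, j)
        best = None
        for ai in range(len(active)):
            i = active[ai]
            for aj in range(ai + 1, len(active)):
                j = active[aj]
                d = work[i, j]
                if best is None or (d, i, j) < best:
                    best = (d, i, j)
        d, i, j = best
        new = n + step
        ni, nj = sizes[i], sizes[j]
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            denom = ni + nj + nk
            work[new, k] = work[k, new] = (
                (ni + nk) * work[i, k] + (nj + nk) * work[j, k] - nk * d
            ) / denom
        sizes[new] = ni + nj
        active.remove(i)
        active.remove(j)
        active.append(new)
        merges[step] = (i, j, d, ni + nj)
    return WardTree(labels, merges)


def _components_at(tree: WardTree, cutoff: float) -> list[list[int]]:
    """Leaf components induced by merges at height <= cutoff (union-find)."""
    n = tree.n_leaves
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step, (a, b, h, _) in enumerate(tree.merges):
        if h <= cutoff + 1e-12:
            new = n + step
            parent[find(int(a))] = new
            parent[find(int(b))] = new
    comps: dict[int, list[int]] = {}
    for leaf in range(n):
        comps.setdefault(find(leaf), []).append(leaf)
    return [comps[root] for root in sorted(comps, key=lambda r: min(comps[r]))]


def cut_pre_metagroups(
    tree: WardTree,
    depth_fraction: float = 0.20,
    step: float = 0.10,
    min_elements: int = 2,
) -> list[list[int]]:
    """Cut the Ward tree into preliminary metagroups.

    The cut height is ``depth_fraction`` times the maximum merge height
    (tree depth).  If no resulting cluster has at least ``min_elements``
    members, the fraction is raised in absolute ``step`` increments
    (20% -> 30% -> ...) until one qualifies or the fraction reaches 1.0, at
    which point the whole tree is returned as one pre-metagroup.  Singleton
    components are carried along as candidates for the term-merge step.

    Returns leaf-index clusters, ordered by smallest member index.
    """
    if not (0.0 < depth_fraction <= 1.0):
        raise ValueError(f"depth_fraction must be in (0, 1], got {depth_fraction}")
    if step <= 0:
        raise ValueError(f"step must be > 0, got {step}")
    max_h = tree.max_height
    fraction = depth_fraction
    while True:
        comps = _components_at(tree, fraction * max_h)
        if any(len(c) >= min_elements for c in comps) or fraction >= 1.0:
            return comps
        fraction = min(1.0, fraction + step)


def greedy_term_merge(
    pre_groups: Sequence[Sequence[GeneTermSet]],
    policies: Mapping[str, GenericTermPolicy] | Iterable[GenericTermPolicy],
) -> list[Metagroup]:
    """Step 2b: merge pre-metagroups that share non-generic terms.

    Repeatedly merges the pair of groups sharing the most non-generic terms
    (ties: the smaller pair of group indices) until no two groups share any
    non-generic term.  Generic terms never count toward sharing.
    """
    generic = prefixed_generic_terms(_as_policy_map(policies))
    groups: list[list[GeneTermSet]] = [list(g) for g in pre_groups if g]
    term_sets = [
        frozenset().union(*(e.terms for e in g)) - generic for g in groups
    ]
    while True:
        best = None  # (shared, i, j)
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                shared = len(term_sets[i] & term_sets[j])
                if shared >= 1 and (best is None or shared > best[0]):
                    best = (shared, i, j)
        if best is None:
            break
        _, i, j = best
        groups[i].extend(groups[j])
        term_sets[i] = term_sets[i] | term_sets[j]
        del groups[j]
        del term_sets[j]
    return [
        Metagroup(metagroup_id=f"MG{k}", elements=g)
        for k, g in enumerate(groups, start=1)
    ]


def complete_cover(group: Metagroup) -> Metagroup:
    """Step 3: remove redundant elements while preserving the unions.

    Elements are visited from the least significant (largest p; ties broken
    by ascending element id) and removed iff both their genes and their
    terms are covered by the union of the currently retained other
    elements.  The result keeps union_genes and union_terms intact and no
    single retained element can still be removed.
    """
    order = sorted(group.elements, key=lambda e: (-e.p_value, e.element_id))
    retained = list(group.elements)
    for e in order:
        others = [o for o in retained if o is not e]
        if not others:
            continue
        genes = frozenset().union(*(o.genes for o in others))
        terms = frozenset().union(*(o.terms for o in others))
        if e.genes <= genes and e.terms <= terms:
            retained = others
    kept = [e for e in group.elements if any(e is r for r in retained)]
    return replace_elements(group, kept)


def replace_elements(group: Metagroup, elements: list[GeneTermSet]) -> Metagroup:
    return Metagroup(
        metagroup_id=group.metagroup_id,
        elements=elements,
        raw_p=group.raw_p,
        adjusted_p=group.adjusted_p,
        silhouette=group.silhouette,
        diameter=group.diameter,
        similarity_coefficient=group.similarity_coefficient,
    )


def _term_carriers(spaces: Sequence[AnnotationSpace]) -> dict[str, frozenset[str]]:
    carriers: dict[str, frozenset[str]] = {}
    for space in spaces:
        for term, genes in space.term_to_genes.items():
            carriers[space.prefixed(term)] = genes
    return carriers


def score_metagroups(
    groups: Sequence[Metagroup],
    query: QueryContext,
    spaces: Sequence[AnnotationSpace],
) -> list[Metagroup]:
    """Step 4: score and rank metagroups.

    raw_p tests the union genes against the universe genes annotated with at
    least one union term (Hypergeom(N=universe, K=carriers, n=M)); adjusted_p
    is Benjamini-Hochberg across metagroups.  Silhouette, diameter and
    similarity coefficient use gene-only cosine distances (no p component).
    Ranking: adjusted_p ascending, then silhouette descending, then id.
    With a single metagroup the silhouette is undefined (None).
    """
    if len(groups) == 0:
        raise ValueError("no metagroups to score")
    carriers = _term_carriers(spaces)

    raw_ps = []
    for g in groups:
        union_genes, union_terms = g.union_genes, g.union_terms
        if not union_genes <= set(query.query_genes):
            bad = sorted(union_genes - set(query.query_genes))[:3]
            raise ValueError(f"{g.metagroup_id}: gene(s) {bad} not in query")
        K_set: set[str] = set()
        for t in union_terms:
            if t not in carriers:
                raise ValueError(f"{g.metagroup_id}: unknown term {t!r}")
            K_set |= carriers[t]
        raw_ps.append(
            hypergeometric_tail(
                len(union_genes), query.M, len(K_set), query.universe_size
            )
        )
    adjusted = multipletests(raw_ps, method="fdr_bh")[1]

    # gene-only geometry for silhouette / diameter / similarity
    all_vecs: list[np.ndarray] = []
    owner: list[int] = []
    for gi, g in enumerate(groups):
        vecs = build_element_vectors(g.elements, query, p_weight_mode="off")
        for v in vecs:
            all_vecs.append(v.coords)
            owner.append(gi)
    X = np.vstack(all_vecs)
    if len(all_vecs) > 1:
        D = squareform(pdist(X, metric="cosine"))
        np.clip(D, 0.0, 1.0, out=D)
        np.fill_diagonal(D, 0.0)
    else:
        D = np.zeros((1, 1))
    owner_arr = np.array(owner)

    scored = []
    single_group = len(groups) == 1
    for gi, g in enumerate(groups):
        idx = np.where(owner_arr == gi)[0]
        within = D[np.ix_(idx, idx)]
        if len(idx) > 1:
            diameter = float(within.max())
            similarity = float(1.0 - within[np.triu_indices(len(idx), k=1)].mean())
        else:
            diameter, similarity = 0.0, 1.0

        if single_group:
            sil = None
        else:
            svals = []
            for i in idx:
                if len(idx) == 1:
                    svals.append(0.0)  # singleton-element convention
                    continue
                a = float(D[i, idx[idx != i]].mean())
                b = min(
                    float(D[i, np.where(owner_arr == gj)[0]].mean())
                    for gj in range(len(groups))
                    if gj != gi
                )
                m = max(a, b)
                svals.append(0.0 if m == 0 else (b - a) / m)
            sil = float(np.mean(svals))

        scored.append(
            Metagroup(
                metagroup_id=g.metagroup_id,
                elements=list(g.elements),
                raw_p=raw_ps[gi],
                adjusted_p=float(adjusted[gi]),
                silhouette=sil,
                diameter=diameter,
                similarity_coefficient=similarity,
            )
        )

    def rank_key(g: Metagroup):
        sil = g.silhouette if g.silhouette is not None else float("-inf")
        return (g.adjusted_p, -sil, g.metagroup_id)

    return sorted(scored, key=rank_key)


def link_elements(
    elements: Sequence[GeneTermSet],
    query: QueryContext,
    spaces: Sequence[AnnotationSpace],
    policies: Mapping[str, GenericTermPolicy] | Iterable[GenericTermPolicy],
    *,
    depth_fraction: float = 0.20,
    step: float = 0.10,
    min_elements: int = 2,
    p_weight_mode: str = "literal",
) -> tuple[list[Metagroup], dict[str, int]]:
    """Run steps 1-4 and return (ranked metagroups, per-step counts)."""
    pmap = _as_policy_map(policies)
    counts = {"elements_in": len(elements)}

    filtered = filter_generic_only(elements, pmap)
    counts["after_generic_filter"] = len(filtered)
    if not filtered:
        counts.update(pre_metagroups=0, merged_metagroups=0,
                      elements_after_cover=0, final_metagroups=0)
        return [], counts

    vectors = build_element_vectors(filtered, query, p_weight_mode=p_weight_mode)
    dist = cosine_distance_matrix(vectors)
    tree = ward_tree(dist)
    clusters = cut_pre_metagroups(
        tree, depth_fraction=depth_fraction, step=step, min_elements=min_elements
    )
    counts["pre_metagroups"] = len(clusters)

    pre_groups = [[filtered[i] for i in cluster] for cluster in clusters]
    merged = greedy_term_merge(pre_groups, pmap)
    counts["merged_metagroups"] = len(merged)

    covered = [complete_cover(g) for g in merged]
    counts["elements_after_cover"] = sum(len(g.elements) for g in covered)

    ranked = score_metagroups(covered, query, spaces)
    counts["final_metagroups"] = len(ranked)
    return ranked, counts
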