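"""Seeded synthetic annotation spaces with planted gene modules.

Emulates the structure the pipeline is designed for without any download:
disjoint gene modules annotated by small specific terms, the same terms
duplicated across pseudo-databases (synonymous cross-source annotations),
and a few promiscuous generic terms covering a large random slice of the
universe.  The planted truth table maps every term to its module (or to
"generic"), and the module gene sets double as a reference partition for
evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from gtlinker.annotation_space import AnnotationSpace
from gtlinker.evaluation import ReferencePartition

__all__ = ["SyntheticDesign", "generate_space"]

GENERIC_LABEL = "generic"


@dataclass(frozen=True)
class SyntheticDesign:
    """Parameters of one synthetic annotation benchmark.

    ``modules`` lists (module size, number of specific terms per source).
    Each specific term is replicated under a distinct id in each of the
    ``n_synonym_sources`` pseudo-databases.  Each generic term annotates a
    ``generic_coverage`` fraction of the universe, sampled at random.
    """

    n_universe: int
    modules: tuple[tuple[int, int], ...]
    n_synonym_sources: int = 2
    n_generic_terms: int = 2
    generic_coverage: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_universe < 1:
            raise ValueError("n_universe must be >= 1")
        if not self.modules:
            raise ValueError("at least one module required")
        for size, n_terms in self.modules:
            if size < 1:
                raise ValueError("module sizes must be >= 1")
            if n_terms < 1:
                raise ValueError("n_specific_terms must be >= 1")
        if sum(size for size, _ in self.modules) > self.n_universe:
            raise ValueError("modules do not fit in the universe")
        if self.n_synonym_sources < 1:
            raise ValueError("need >= 1 source")
        if not (0.0 < self.generic_coverage <= 1.0):
            raise ValueError("generic_coverage must be in (0, 1]")
        if self.n_generic_terms < 0:
            raise ValueError("n_generic_terms must be >= 0")


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"g{i:0{width}d}" for i in range(n)]


def generate_space(
    design: SyntheticDesign,
) -> tuple[list[AnnotationSpace], ReferencePartition, dict[str, str]]:
    """Build annotation spaces, the planted reference partition and truth.

    Each module's first specific term annotates the whole module; further
    terms annotate random proper subsets (>= 3 genes where possible), so a
    module yields several distinct co-annotation patterns.  Term gene
    content is identical across the synonym sources; generic-term genes are
    sampled independently per source.  Deterministic for a given seed.

    Returns (spaces, reference partition over the planted modules, truth
    table mapping every prefixed term id to its module label or
    ``"generic"``).
    """
    rng = np.random.default_rng(design.seed)
    universe = _gene_names(design.n_universe)
    uni_set = frozenset(universe)

    # disjoint module gene blocks over a shuffled universe
    shuffled = [universe[i] for i in rng.permutation(design.n_universe)]
    module_genes: list[list[str]] = []
    cursor = 0
    for size, _ in design.modules:
        module_genes.append(sorted(shuffled[cursor : cursor + size]))
        cursor += size

    # per-module specific term contents, shared by all synonym sources
    module_terms: list[list[tuple[str, frozenset[str]]]] = []
    for m, ((size, n_terms), genes) in enumerate(
        zip(design.modules, module_genes), start=1
    ):
        terms = [(f"M{m}T1", frozenset(genes))]
        min_size = min(3, size)
        for j in range(2, n_terms + 1):
            if size == 1:
                subset = list(genes)
            else:
                keep = rng.random(size) < 0.75
                subset = [g for g, k in zip(genes, keep) if k]
                while len(subset) < min_size:
                    extra = [g for g in genes if g not in subset]
                    subset.append(extra[int(rng.integers(len(extra)))])
                if len(subset) == size:  # force a proper subset
                    subset.pop(int(rng.integers(len(subset))))
            terms.append((f"M{m}T{j}", frozenset(subset)))
        module_terms.append(terms)

    n_generic_genes = max(1, round(design.generic_coverage * design.n_universe))
    spaces: list[AnnotationSpace] = []
    truth: dict[str, str] = {}
    for s in range(1, design.n_synonym_sources + 1):
        source_id = f"S{s}"
        term_to_genes: dict[str, frozenset[str]] = {}
        for m, terms in enumerate(module_terms, start=1):
            for term_id, genes in terms:
                term_to_genes[term_id] = genes
                truth[f"{source_id}::{term_id}"] = f"module{m}"
        for k in range(1, design.n_generic_terms + 1):
            idx = rng.choice(design.n_universe, n_generic_genes, replace=False)
            term_id = f"GEN{k}"
            term_to_genes[term_id] = frozenset(universe[i] for i in idx)
            truth[f"{source_id}::{term_id}"] = GENERIC_LABEL
        spaces.append(
            AnnotationSpace(
                source_id=source_id,
                term_to_genes=term_to_genes,
                universe=uni_set,
                organism="synthetic",
            )
        )

    reference = ReferencePartition(
        name=f"planted-seed{design.seed}",
        groups={
            f"module{m}": frozenset(genes)
            for m, genes in enumerate(module_genes, start=1)
        },
        universe=uni_set,
    )
    return spaces, reference, truth
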