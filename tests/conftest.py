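from __future__ import annotations

import pytest

from gtlinker.annotation_space import AnnotationSpace
from gtlinker.enrichment import GeneTermSet, QueryContext


@pytest.fixture
def tiny_space() -> AnnotationSpace:
    """Universe of 10 genes; term Ng values 4, 3, 2."""
    return AnnotationSpace(
        source_id="SRC",
        term_to_genes={
            "T1": frozenset({"a", "b", "c", "d"}),
            "T2": frozenset({"b", "c", "e"}),
            "T3": frozenset({"e", "f"}),
        },
        universe=frozenset("abcdefghij"),
    )


@pytest.fixture
def skewed_space() -> AnnotationSpace:
    """Ng = [1, 1, 1, 1, 20]: one clear promiscuous outlier."""
    genes = [f"g{i}" for i in range(24)]
    return AnnotationSpace(
        source_id="SK",
        term_to_genes={
            "t1": frozenset({genes[0]}),
            "t2": frozenset({genes[1]}),
            "t3": frozenset({genes[2]}),
            "t4": frozenset({genes[3]}),
            "big": frozenset(genes[4:24]),
        },
        universe=frozenset(genes),
    )


def make_element(eid, genes, terms, p) -> GeneTermSet:
    return GeneTermSet(eid, frozenset(genes), frozenset(terms), p)


@pytest.fixture
def query8() -> QueryContext:
    return QueryContext.from_genes([f"q{i}" for i in range(8)], 100)
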