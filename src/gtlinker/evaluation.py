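"""Benchmark statistics: pair-based partition agreement, precision/recall,
and the random-noise injection protocol.

Partition agreement is measured over all unordered gene pairs: a pair is
co-grouped in a (possibly overlapping) grouping iff both genes share at
least one group.  From the TP/FP/FN/TN pair counts we derive the Rand
accuracy and the Jaccard coefficient.  Gene-level precision/recall/F-score
compare a retrieved gene set against a reference set, reported in percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ReferencePartition",
    "PairConfusion",
    "pair_confusion",
    "partition_accuracy_jaccard",
    "precision_recall_f",
    "inject_noise",
]


@dataclass(frozen=True)
class ReferencePartition:
    """Named reference grouping of genes; groups may overlap."""

    name: str
    groups: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        covered: set[str] = set()
        for gid, genes in self.groups.items():
            if not genes:
                raise ValueError(f"{self.name}: group {gid!r} is empty")
            covered |= genes
        if not covered <= self.universe:
            object.__setattr__(self, "universe", self.universe | frozenset(covered))

    @classmethod
    def from_groups(
        cls,
        groups: Mapping[str, Iterable[str]],
        name: str = "reference",
        universe: Iterable[str] | None = None,
    ) -> "ReferencePartition":
        gmap = {k: frozenset(v) for k, v in groups.items()}
        uni = frozenset(universe) if universe is not None else frozenset()
        return cls(name=name, groups=gmap, universe=uni)


@dataclass(frozen=True)
class PairConfusion:
    """TP/FP/FN/TN over all unordered pairs of the evaluated genes."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total_pairs(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _comembership(groups: Iterable[Iterable[str]]) -> set[frozenset[str]]:
    pairs: set[frozenset[str]] = set()
    for group in groups:
        for a, b in combinations(sorted(set(group)), 2):
            pairs.add(frozenset((a, b)))
    return pairs


def pair_confusion(
    found: Iterable[Iterable[str]],
    reference: ReferencePartition,
    genes: Iterable[str],
) -> PairConfusion:
    """Classify every unordered pair of ``genes`` by co-membership.

    A pair is co-grouped iff both genes appear together in at least one
    group (fuzzy/overlapping groupings allowed).  TP = co-grouped in both
    found and reference; FP = found only; FN = reference only; TN = neither.
    """
    gene_list = sorted(set(genes))
    if len(gene_list) < 2:
        raise ValueError(f"need >= 2 genes to form pairs, got {len(gene_list)}")
    found_pairs = _comembership(found)
    ref_pairs = _comembership(reference.groups.values())
    tp = fp = fn = tn = 0
    for a, b in combinations(gene_list, 2):
        pair = frozenset((a, b))
        in_found = pair in found_pairs
        in_ref = pair in ref_pairs
        if in_found and in_ref:
            tp += 1
        elif in_found:
            fp += 1
        elif in_ref:
            fn += 1
        else:
            tn += 1
    return PairConfusion(tp=tp, fp=fp, fn=fn, tn=tn)


def partition_accuracy_jaccard(conf: PairConfusion) -> tuple[float, float]:
    """Rand accuracy (TP+TN)/total and Jaccard TP/(TP+FN+FP) over pairs.

    Jaccard is 0 by convention when no pair is co-grouped anywhere.
    """
    if conf.total_pairs == 0:
        raise ValueError("no pairs to evaluate")
    accuracy = (conf.tp + conf.tn) / conf.total_pairs
    denom = conf.tp + conf.fn + conf.fp
    jaccard = conf.tp / denom if denom > 0 else 0.0
    return accuracy, jaccard


def precision_recall_f(
    retrieved: Iterable[str], relevant: Iterable[str]
) -> tuple[float, float, float]:
    """Gene-level precision, recall and F-score, in percent.

    Precision is NaN (undefined) when nothing was retrieved; the F-score is
    0 when precision + recall is 0.
    """
    ret = frozenset(retrieved)
    rel = frozenset(relevant)
    if not rel:
        raise ValueError("empty relevant set")
    hits = len(ret & rel)
    recall = 100.0 * hits / len(rel)
    if not ret:
        return float("nan"), recall, float("nan")
    precision = 100.0 * hits / len(ret)
    f = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f


def inject_noise(
    reference_genes: Iterable[str],
    pool: Iterable[str],
    fraction: float,
    seed: int,
) -> list[str]:
    """Add ``round(fraction * n_reference)`` random pool genes to a query.

    Noise genes are drawn uniformly without replacement from
    ``pool - reference``; rounding is half-up (10 genes at 20% -> 2 noise
    genes).  Deterministic for a given seed.  Returns the reference genes
    (sorted) followed by the noise genes in draw order.
    """
    ref = frozenset(reference_genes)
    if fraction < 0:
        raise ValueError(f"fraction must be >= 0, got {fraction}")
    candidates = sorted(frozenset(pool) - ref)
    n_noise = math.floor(fraction * len(ref) + 0.5)
    if n_noise > len(candidates):
        raise ValueError(
            f"pool has only {len(candidates)} genes outside the reference, "
            f"need {n_noise}"
        )
    rng = np.random.default_rng(seed)
    noise = [candidates[i] for i in rng.choice(len(candidates), n_noise, replace=False)]
    return sorted(ref) + noise
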