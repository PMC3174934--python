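"""Annotation catalogs (term -> genes) and generic-term outlier detection.

An :class:`AnnotationSpace` indexes one annotation source (e.g. a GO branch
or KEGG) for one organism against a gene universe.  Terms whose gene count
``Ng`` deviates strongly from the per-space average (``Ng > mean + n * sigma``)
are tagged as *generic* (promiscuous, low information content); they are
never deleted, only tagged, so that downstream steps can still use them in
co-occurrence with specific terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "AnnotationSpace",
    "GenericTermPolicy",
    "TermFrequencyStats",
    "load_gmt",
    "load_two_column_tsv",
    "load_universe",
    "term_frequency_stats",
    "detect_generic_terms",
]

#: separator between a declared source id and a term id inside a GMT set id,
#: e.g. ``GO-BP::GO:0007165``.  A plain ``:`` cannot be used because GO term
#: ids contain one.
SOURCE_SEP = "::"


class GmtParseError(ValueError):
    """Raised for malformed GMT / TSV annotation input."""


@dataclass
class AnnotationSpace:
    """Term -> gene catalog for one annotation source and organism.

    Parameters
    ----------
    source_id:
        Label of the annotation source (``"GO-BP"``, ``"KEGG"``, ...).
    term_to_genes:
        Mapping from term id to the set of annotated gene ids.
    universe:
        Total organism gene list; the denominator for per-term fractions.
        Must contain every annotated gene.
    """

    source_id: str
    term_to_genes: dict[str, frozenset[str]]
    universe: frozenset[str]
    organism: str = "unspecified"
    term_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.term_to_genes = {
            str(t).strip(): frozenset(str(g).strip() for g in gs)
            for t, gs in self.term_to_genes.items()
        }
        annotated = set().union(*self.term_to_genes.values()) if self.term_to_genes else set()
        self.universe = frozenset(str(g).strip() for g in self.universe)
        missing = annotated - self.universe
        if missing:
            raise ValueError(
                f"space {self.source_id!r}: {len(missing)} annotated gene(s) "
                f"missing from universe (e.g. {sorted(missing)[:3]})"
            )

    @property
    def n_terms(self) -> int:
        return len(self.term_to_genes)

    def ng(self, term: str) -> int:
        """Number of genes annotated with ``term``."""
        return len(self.term_to_genes[term])

    def prefixed(self, term: str) -> str:
        """Term id carrying its source prefix, e.g. ``GO-BP::GO:0007165``."""
        return f"{self.source_id}{SOURCE_SEP}{term}"


@dataclass(frozen=True)
class GenericTermPolicy:
    """Outlier statistics and the resulting generic-term tags for one space."""

    space_id: str
    mean_ng: float
    sigma_ng: float
    n_factor: float
    generic_terms: frozenset[str]

    @property
    def threshold(self) -> float:
        return self.mean_ng + self.n_factor * self.sigma_ng


@dataclass(frozen=True)
class TermFrequencyStats:
    """Summary of the per-term gene-count distribution of one space."""

    space_id: str
    ng: dict[str, int]
    fraction: dict[str, float]  # Ng / |universe|
    mean: float
    sigma: float
    quartiles: tuple[float, float, float]  # q1, median, q3

    @property
    def n_terms(self) -> int:
        return len(self.ng)


def _parse_gmt_lines(
    lines: Iterable[str], *, path: str
) -> dict[str, list[tuple[str, str, frozenset[str]]]]:
    """Group raw GMT records by declared source (``SRC::term`` set ids)."""
    by_source: dict[str, list[tuple[str, str, frozenset[str]]]] = {}
    n_records = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise GmtParseError(
                f"{path}: line {lineno}: expected >=3 tab-separated fields "
                f"(set id, description, genes...), got {len(fields)}"
            )
        set_id, description = fields[0].strip(), fields[1].strip()
        genes = frozenset(g.strip() for g in fields[2:] if g.strip())
        if not genes:
            raise GmtParseError(f"{path}: line {lineno}: set {set_id!r} has no genes")
        if SOURCE_SEP in set_id:
            source, term = set_id.split(SOURCE_SEP, 1)
        else:
            source, term = "", set_id
        by_source.setdefault(source, []).append((term, description, genes))
        n_records += 1
    if n_records == 0:
        raise GmtParseError(f"{path}: no gene sets found")
    return by_source


def load_gmt(
    path: str | Path,
    *,
    source_id: str | None = None,
    universe: Iterable[str] | None = None,
    organism: str = "unspecified",
) -> list[AnnotationSpace]:
    """Load annotation spaces from a GMT file (set id, description, genes...).

    Set ids of the form ``SRC::term`` are split into one space per declared
    source ``SRC``; ids without the ``::`` separator all go into a single
    space named ``source_id`` (default: the file stem).  The universe
    defaults to the union of all genes in the file unless ``universe`` is
    given.

    Raises
    ------
    GmtParseError
        On a line with fewer than three fields (with its line number) or an
        empty file.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        by_source = _parse_gmt_lines(fh, path=str(path))

    all_genes: set[str] = set()
    for records in by_source.values():
        for _, _, genes in records:
            all_genes.update(genes)
    uni = frozenset(universe) if universe is not None else frozenset(all_genes)

    spaces = []
    for source in sorted(by_source):
        records = by_source[source]
        label = source if source else (source_id or path.stem)
        term_to_genes: dict[str, frozenset[str]] = {}
        term_names: dict[str, str] = {}
        for term, description, genes in records:
            if term in term_to_genes:
                raise GmtParseError(
                    f"{path}: duplicate term id {term!r} in source {label!r}"
                )
            term_to_genes[term] = genes
            if description:
                term_names[term] = description
        spaces.append(
            AnnotationSpace(
                source_id=label,
                term_to_genes=term_to_genes,
                universe=uni,
                organism=organism,
                term_names=term_names,
            )
        )
    return spaces


def write_gmt(spaces: Iterable[AnnotationSpace], path: str | Path) -> None:
    """Write spaces to a GMT file using ``SRC::term`` set ids."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for space in spaces:
            for term in sorted(space.term_to_genes):
                desc = space.term_names.get(term, "na") or "na"
                genes = "\t".join(sorted(space.term_to_genes[term]))
                fh.write(f"{space.prefixed(term)}\t{desc}\t{genes}\n")


def load_two_column_tsv(
    path: str | Path,
    *,
    source_id: str | None = None,
    universe: Iterable[str] | None = None,
    organism: str = "unspecified",
) -> AnnotationSpace:
    """Load a single space from two-column ``gene<TAB>term`` lines."""
    path = Path(path)
    term_to_genes: dict[str, set[str]] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected 2 tab-separated fields"
                )
            gene, term = fields[0].strip(), fields[1].strip()
            term_to_genes.setdefault(term, set()).add(gene)
    if not term_to_genes:
        raise GmtParseError(f"{path}: no annotations found")
    all_genes = set().union(*term_to_genes.values())
    uni = frozenset(universe) if universe is not None else frozenset(all_genes)
    return AnnotationSpace(
        source_id=source_id or path.stem,
        term_to_genes={t: frozenset(g) for t, g in term_to_genes.items()},
        universe=uni,
        organism=organism,
    )


def load_universe(path: str | Path) -> frozenset[str]:
    """Read a universe file: one gene id per line, ``#`` comments ignored."""
    genes = set()
    with Path(path).open("r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                genes.add(line)
    if not genes:
        raise ValueError(f"{path}: empty universe file")
    return frozenset(genes)


def _ng_stats(ng_values: np.ndarray, ddof: int) -> tuple[float, float]:
    mean = float(np.mean(ng_values))
    if len(ng_values) > ddof:
        sigma = float(np.std(ng_values, ddof=ddof))
    else:
        sigma = 0.0
    return mean, sigma


def term_frequency_stats(space: AnnotationSpace, *, ddof: int = 1) -> TermFrequencyStats:
    """Per-term gene counts with mean, standard deviation and quartiles.

    ``fraction`` is each term's share of the universe, ``Ng / |universe|``.
    ``ddof=1`` (sample standard deviation) by default.
    """
    if space.n_terms == 0:
        raise ValueError(f"space {space.source_id!r} has no terms")
    ng = {t: len(g) for t, g in space.term_to_genes.items()}
    n_universe = len(space.universe)
    values = np.array(sorted(ng.values()), dtype=float)
    mean, sigma = _ng_stats(values, ddof)
    q1, med, q3 = (float(q) for q in np.percentile(values, [25, 50, 75]))
    return TermFrequencyStats(
        space_id=space.source_id,
        ng=ng,
        fraction={t: v / n_universe for t, v in ng.items()},
        mean=mean,
        sigma=sigma,
        quartiles=(q1, med, q3),
    )


def detect_generic_terms(
    space: AnnotationSpace, n_factor: float = 4.0, *, ddof: int = 1
) -> GenericTermPolicy:
    """Tag generic (promiscuous) terms of one space by the Z-score rule.

    A term is generic iff ``Ng > mean + n_factor * sigma`` (strict), with
    mean and sigma taken over all terms of the space.  Default deviation
    factor is 4.  Terms are tagged, never removed.
    """
    if n_factor < 0:
        raise ValueError(f"n_factor must be >= 0, got {n_factor}")
    if math.isnan(n_factor):
        raise ValueError("n_factor must not be NaN")
    if space.n_terms < 2:
        raise ValueError(
            f"space {space.source_id!r} needs >=2 terms for outlier detection"
        )
    stats = term_frequency_stats(space, ddof=ddof)
    threshold = stats.mean + n_factor * stats.sigma
    generic = frozenset(t for t, v in stats.ng.items() if v > threshold)
    return GenericTermPolicy(
        space_id=space.source_id,
        mean_ng=stats.mean,
        sigma_ng=stats.sigma,
        n_factor=n_factor,
        generic_terms=generic,
    )


def generic_policies(
    spaces: Iterable[AnnotationSpace], n_factor: float = 4.0, *, ddof: int = 1
) -> dict[str, GenericTermPolicy]:
    """Detect generic terms independently in each space; keyed by source id."""
    return {s.source_id: detect_generic_terms(s, n_factor, ddof=ddof) for s in spaces}


def prefixed_generic_terms(policies: Mapping[str, GenericTermPolicy]) -> frozenset[str]:
    """All generic terms across policies, carrying their source prefixes."""
    out: set[str] = set()
    for space_id, policy in policies.items():
        out.update(f"{space_id}{SOURCE_SEP}{t}" for t in policy.generic_terms)
    return frozenset(out)
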