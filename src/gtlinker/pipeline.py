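"""End-to-end orchestration: enrich -> filter -> cluster -> cover -> score.

``run_pipeline`` drives the whole tool from a configuration mapping (the
CLI and the YAML config file both feed into it) and writes the metagroup
report, the element table and an optional JSON report.  Per-step element
counts are logged and returned.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Any, Mapping, Sequence

from gtlinker.annotation_space import (
    AnnotationSpace,
    generic_policies,
    load_gmt,
    load_universe,
)
from gtlinker.enrichment import (
    GeneTermSet,
    QueryContext,
    concurrent_enrichment,
    load_genetermsets,
    singular_enrichment,
)
from gtlinker.linker import Metagroup, link_elements
from gtlinker.reports import (
    write_element_table,
    write_json_report,
    write_metagroup_report,
)

__all__ = ["run_pipeline", "load_query", "PipelineError"]

logger = logging.getLogger("gtlinker")

DEFAULTS: dict[str, Any] = {
    "mode": "mea",
    "min_support": 3,
    "p_max": 0.05,
    "n_factor": 4.0,
    "depth_fraction": 0.20,
    "step": 0.10,
    "min_elements": 2,
    "p_weight": "literal",
    "write_json": False,
}


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def load_query(path: str | Path) -> list[str]:
    """Read a query gene list: one id per line, '#' comments ignored."""
    genes = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                genes.append(line)
    if not genes:
        raise ValueError("empty query")
    return genes


def _load_spaces(config: Mapping[str, Any]) -> list[AnnotationSpace]:
    paths = config.get("spaces")
    if not paths:
        raise PipelineError("load", "no annotation spaces configured")
    if isinstance(paths, (str, Path)):
        paths = [paths]
    universe = None
    if config.get("universe"):
        universe = load_universe(config["universe"])
    spaces: list[AnnotationSpace] = []
    for p in paths:
        spaces.extend(load_gmt(p, universe=universe))
    if universe is None:
        # shared universe across files: union of all annotated genes
        union = frozenset().union(*(s.universe for s in spaces))
        spaces = [
            AnnotationSpace(
                source_id=s.source_id,
                term_to_genes=dict(s.term_to_genes),
                universe=union,
                organism=s.organism,
                term_names=dict(s.term_names),
            )
            for s in spaces
        ]
    return spaces


def run_pipeline(config: Mapping[str, Any]) -> dict[str, Any]:
    """Run the full pipeline from a config mapping.

    Required keys: ``spaces`` (GMT path or list) and either ``query`` (gene
    list path) or ``elements`` (precomputed GeneTerm-set TSV); optional
    keys mirror :data:`DEFAULTS` plus ``universe`` and ``out_prefix``.

    Returns a dict with the ranked metagroups, per-step counts and any
    report paths written.
    """
    cfg = {**DEFAULTS, **dict(config)}

    try:
        spaces = _load_spaces(cfg)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("load", str(exc)) from exc

    universe_size = len(spaces[0].universe)

    elements: Sequence[GeneTermSet]
    if cfg.get("elements"):
        try:
            elements = load_genetermsets(cfg["elements"], spaces)
        except Exception as exc:
            raise PipelineError("load", str(exc)) from exc
        query_genes = sorted(frozenset().union(*(e.genes for e in elements)))
        query = QueryContext.from_genes(query_genes, universe_size)
    elif cfg.get("query") is not None:
        try:
            q = cfg["query"]
            genes = list(q) if not isinstance(q, (str, Path)) else load_query(q)
            if not genes:
                raise ValueError("empty query")
            query = QueryContext.from_genes(genes, universe_size)
        except Exception as exc:
            raise PipelineError("query", str(exc)) from exc
        enrich = concurrent_enrichment if cfg["mode"] == "mea" else singular_enrichment
        try:
            elements = enrich(
                query,
                spaces,
                min_support=int(cfg["min_support"]),
                p_max=float(cfg["p_max"]),
            )
        except Exception as exc:
            raise PipelineError("enrich", str(exc)) from exc
        logger.info("enrichment: %d elements (%s)", len(elements), cfg["mode"])
    else:
        raise PipelineError("load", "need either 'query' or 'elements' in config")

    try:
        policies = generic_policies(spaces, n_factor=float(cfg["n_factor"]))
    except Exception as exc:
        raise PipelineError("generic-terms", str(exc)) from exc
    for pid, pol in sorted(policies.items()):
        logger.info(
            "space %s: %d generic term(s), threshold %.2f",
            pid, len(pol.generic_terms), pol.threshold,
        )

    try:
        groups, counts = link_elements(
            elements,
            query,
            spaces,
            policies,
            depth_fraction=float(cfg["depth_fraction"]),
            step=float(cfg["step"]),
            min_elements=int(cfg["min_elements"]),
            p_weight_mode=str(cfg["p_weight"]),
        )
    except Exception as exc:
        raise PipelineError("link", str(exc)) from exc
    for key, value in counts.items():
        logger.info("%s: %d", key, value)

    result: dict[str, Any] = {
        "metagroups": groups,
        "counts": counts,
        "query": query,
        "reports": {},
    }
    prefix = cfg.get("out_prefix")
    if prefix:
        prefix = str(prefix)
        mg_path = f"{prefix}.metagroups.tsv"
        el_path = f"{prefix}.elements.tsv"
        write_metagroup_report(groups, mg_path)
        write_element_table(groups, el_path)
        result["reports"] = {"metagroups": mg_path, "elements": el_path}
        if cfg.get("write_json"):
            js_path = f"{prefix}.json"
            write_json_report(groups, js_path, counts)
            result["reports"]["json"] = js_path
    return result
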