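"""Deterministic report writers for metagroups and their elements."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

from gtlinker.linker import Metagroup

__all__ = ["write_metagroup_report", "write_element_table", "write_json_report"]

_NA = "NA"

METAGROUP_COLUMNS = (
    "metagroup_id",
    "n_genes",
    "n_genetermsets",
    "adjusted_p",
    "silhouette",
    "diameter",
    "similarity_coefficient",
    "genes",
    "terms",
)


def _fmt_score(x: float | None) -> str:
    return _NA if x is None else f"{x:.4f}"


def _fmt_p(x: float | None) -> str:
    return _NA if x is None else f"{x:.4e}"


def _metagroup_row(g: Metagroup) -> list[str]:
    return [
        g.metagroup_id,
        str(len(g.union_genes)),
        str(len(g.elements)),
        _fmt_p(g.adjusted_p),
        _fmt_score(g.silhouette),
        _fmt_score(g.diameter),
        _fmt_score(g.similarity_coefficient),
        ";".join(sorted(g.union_genes)),
        ";".join(sorted(g.union_terms)),
    ]


def write_metagroup_report(groups: Sequence[Metagroup], path: str | Path) -> None:
    """TSV with one row per metagroup; genes/terms sorted, fixed precision,
    so identical runs produce byte-identical files."""
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(METAGROUP_COLUMNS) + "\n")
        for g in groups:
            fh.write("\t".join(_metagroup_row(g)) + "\n")


def write_element_table(groups: Sequence[Metagroup], path: str | Path) -> None:
    """Long-format TSV: one row per (metagroup, element)."""
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("metagroup_id\telement_id\tp_value\tgenes\tterms\n")
        for g in groups:
            for e in g.elements:
                fh.write(
                    f"{g.metagroup_id}\t{e.element_id}\t{e.p_value:.10g}\t"
                    f"{';'.join(sorted(e.genes))}\t{';'.join(sorted(e.terms))}\n"
                )


def write_json_report(
    groups: Sequence[Metagroup], path: str | Path, counts: dict | None = None
) -> None:
    payload = {
        "metagroups": [
            {
                "metagroup_id": g.metagroup_id,
                "n_genes": len(g.union_genes),
                "n_genetermsets": len(g.elements),
                "raw_p": g.raw_p,
                "adjusted_p": g.adjusted_p,
                "silhouette": g.silhouette,
                "diameter": g.diameter,
                "similarity_coefficient": g.similarity_coefficient,
                "genes": sorted(g.union_genes),
                "terms": sorted(g.union_terms),
                "elements": [
                    {
                        "element_id": e.element_id,
                        "p_value": e.p_value,
                        "genes": sorted(e.genes),
                        "terms": sorted(e.terms),
                    }
                    for e in g.elements
                ],
            }
            for g in groups
        ],
    }
    if counts is not None:
        payload["step_counts"] = counts
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
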