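"""Writers for pathway and result files (TSV, JSON, GMT)."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .model import ModelNetwork
from .pathways import MetabolitePathway


def pathways_to_tsv(
    pathways: list[MetabolitePathway], path: str | Path
) -> None:
    """Long-format TSV: metabolite_id, direction, reaction_id, weight,
    condition."""
    rows = []
    for pw in pathways:
        for rid, w in sorted(pw.reaction_weights.items()):
            rows.append(
                {
                    "metabolite_id": pw.metabolite_id,
                    "direction": pw.direction,
                    "reaction_id": rid,
                    "weight": w,
                    "condition": pw.condition_name,
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "metabolite_id", "direction", "reaction_id", "weight",
            "condition",
        ],
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def pathways_to_json(
    pathways: list[MetabolitePathway], path: str | Path
) -> None:
    doc = [
        {
            "metabolite": pw.metabolite_id,
            "direction": pw.direction,
            "condition": pw.condition_name,
            "distance": pw.distance,
            "weights": dict(sorted(pw.reaction_weights.items())),
        }
        for pw in pathways
    ]
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def pathways_from_json(path: str | Path) -> list[MetabolitePathway]:
    doc = json.loads(Path(path).read_text())
    return [
        MetabolitePathway(
            metabolite_id=d["metabolite"],
            direction=d["direction"],
            condition_name=d.get("condition", ""),
            reaction_weights=dict(d["weights"]),
            distance=int(d.get("distance", 0) or 1),
        )
        for d in doc
    ]


def pathways_to_gmt(
    pathways: list[MetabolitePathway],
    model: ModelNetwork,
    path: str | Path,
) -> None:
    """GMT export (one gene set per pathway) for generic gene-set tools.

    Set name is ``<metabolite>__<direction>``, description the source
    condition; members are the genes of the pathway's reactions."""
    lines = []
    for pw in pathways:
        genes = sorted(pw.gene_ids(model))
        if not genes:
            continue
        name = f"{pw.metabolite_id}__{pw.direction}"
        lines.append(
            "\t".join([name, pw.condition_name or "na", *genes])
        )
    Path(path).write_text("\n".join(lines) + "\n")
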