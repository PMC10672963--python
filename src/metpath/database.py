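"""Multi-condition universal pathway database.

Pathways are condition specific; to analyse expression data whose
underlying flux state is unknown, a database is built by running flux
estimation and pathway extraction over a panel of growth-condition
presets and merging the pathways that come out (nearly) identical.
Similarity between two pathways for the same metabolite and direction is
the Matthews correlation coefficient (MCC) of their reaction-membership
vectors over a common reaction universe; pathways with MCC strictly
greater than the merge threshold (default 0.9) are combined
(single-linkage), their weights averaged and renormalized, and the
source conditions recorded as provenance.  Dissimilar pathways stay
separate, so one metabolite can legitimately carry several
condition-variants of a production pathway.

The built-in *E. coli* panel (``builtin_conditions("iJO1366")``)
reconstructs 64 growth conditions: a standard glucose minimal medium,
20 single amino-acid supplements (exchange lower bound -0.5) under
aerobic and anaerobic regimes, and 8 carbon sources under normoxia,
hypoxia and anoxia-with-nitrate (the glucose/normoxia entry coincides
with the standard medium and is not duplicated).  In every preset,
biomass is first maximized and fixed as a minimum, then ATP production
is the objective.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import matthews_corrcoef

from .errors import MetPathError
from .fluxes import estimate_flux_state
from .model import (
    ConditionSpec,
    ExpressionTable,
    GrowthConstraint,
    ModelNetwork,
)
from .pathways import (
    CONSUMPTION,
    DEFAULT_DISTANCE,
    PRODUCTION,
    MetabolitePathway,
    extract_pathway,
)
from .scoring import pathway_score, reaction_scores

logger = logging.getLogger(__name__)

DEFAULT_MERGE_THRESHOLD = 0.9


@dataclass
class DatabaseEntry:
    """A pathway variant with the conditions it was observed in."""

    pathway: MetabolitePathway
    provenance: list[str]


@dataclass
class PathwayDatabase:
    entries: list[DatabaseEntry]
    conditions: list[ConditionSpec]
    merge_threshold: float = DEFAULT_MERGE_THRESHOLD
    distance: int = DEFAULT_DISTANCE

    def variants(
        self, metabolite_id: str, direction: str
    ) -> list[DatabaseEntry]:
        return [
            e
            for e in self.entries
            if e.pathway.metabolite_id == metabolite_id
            and e.pathway.direction == direction
        ]

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "merge_threshold": self.merge_threshold,
            "distance": self.distance,
            "conditions": [c.to_dict() for c in self.conditions],
            "entries": [
                {
                    "metabolite": e.pathway.metabolite_id,
                    "direction": e.pathway.direction,
                    "weights": {
                        k: v
                        for k, v in sorted(
                            e.pathway.reaction_weights.items()
                        )
                    },
                    "provenance": sorted(e.provenance),
                }
                for e in self.entries
            ],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=1, sort_keys=True)
        )

    @classmethod
    def load(cls, path: str | Path) -> "PathwayDatabase":
        d = json.loads(Path(path).read_text())
        entries = [
            DatabaseEntry(
                pathway=MetabolitePathway(
                    metabolite_id=e["metabolite"],
                    direction=e["direction"],
                    condition_name=";".join(e["provenance"]),
                    reaction_weights=dict(e["weights"]),
                    distance=d.get("distance", DEFAULT_DISTANCE),
                ),
                provenance=list(e["provenance"]),
            )
            for e in d["entries"]
        ]
        return cls(
            entries=entries,
            conditions=[
                ConditionSpec.from_dict(c) for c in d.get("conditions", [])
            ],
            merge_threshold=d.get(
                "merge_threshold", DEFAULT_MERGE_THRESHOLD
            ),
            distance=d.get("distance", DEFAULT_DISTANCE),
        )


# ---------------------------------------------------------------------------
# Condition presets
# ---------------------------------------------------------------------------

_AA_EXCHANGES = [
    "EX_ala__L_e", "EX_arg__L_e", "EX_asn__L_e", "EX_asp__L_e",
    "EX_cys__L_e", "EX_gln__L_e", "EX_glu__L_e", "EX_gly_e",
    "EX_his__L_e", "EX_ile__L_e", "EX_leu__L_e", "EX_lys__L_e",
    "EX_met__L_e", "EX_phe__L_e", "EX_pro__L_e", "EX_ser__L_e",
    "EX_thr__L_e", "EX_trp__L_e", "EX_tyr__L_e", "EX_val__L_e",
]

_CARBON_EXCHANGES = {
    "glucose": "EX_glc__D_e",
    "lactate": "EX_lac__D_e",
    "galactose": "EX_gal_e",
    "mannose": "EX_man_e",
    "acetate": "EX_ac_e",
    "fumarate": "EX_fum_e",
    "succinate": "EX_succ_e",
    "glycolate": "EX_glyclt_e",
}

_O2_BOUNDS = {"normoxia": -20.0, "hypoxia": -2.0, "anoxia": 0.0}

_IJO1366_BIOMASS = "BIOMASS_Ec_iJO1366_core_53p95M"
_IJO1366_ATP = "ATPM"
_AA_UPTAKE = -0.5
_CARBON_UPTAKE = -10.0
_NITRATE_UPTAKE = -10.0


def builtin_conditions(model_tag: str) -> list[ConditionSpec]:
    """The built-in growth-condition panel for a model tag.

    Currently only ``"iJO1366"`` is provided (64 conditions, see module
    docstring)."""
    if model_tag != "iJO1366":
        raise MetPathError(
            f"unknown model tag {model_tag!r}; available tags: iJO1366"
        )
    growth = GrowthConstraint(
        reaction_id=_IJO1366_BIOMASS, value="max", kind="minimum"
    )

    def spec(name: str, bounds: dict[str, tuple[float, float]]):
        return ConditionSpec(
            name=name,
            exchange_bounds=bounds,
            objective_reaction=_IJO1366_ATP,
            growth_constraint=growth,
        )

    base = {
        "EX_glc__D_e": (_CARBON_UPTAKE, 1000.0),
        "EX_o2_e": (_O2_BOUNDS["normoxia"], 1000.0),
    }
    out = [spec("standard_minimal_glucose_aerobic", dict(base))]
    for ex in _AA_EXCHANGES:
        aa = ex[3:].replace("__L_e", "").replace("_e", "")
        for o2_name, o2_lb in (("aerobic", _O2_BOUNDS["normoxia"]),
                               ("anaerobic", _O2_BOUNDS["anoxia"])):
            b = dict(base)
            b[ex] = (_AA_UPTAKE, 1000.0)
            b["EX_o2_e"] = (o2_lb, 1000.0)
            out.append(spec(f"{aa}_supplement_{o2_name}", b))
    for cname, ex in _CARBON_EXCHANGES.items():
        for o2_name, o2_lb in _O2_BOUNDS.items():
            if cname == "glucose" and o2_name == "normoxia":
                continue  # identical to the standard condition
            b = {
                "EX_glc__D_e": (0.0, 1000.0),
                ex: (_CARBON_UPTAKE, 1000.0),
                "EX_o2_e": (o2_lb, 1000.0),
            }
            if o2_name == "anoxia":
                b["EX_no3_e"] = (_NITRATE_UPTAKE, 1000.0)
            out.append(spec(f"{cname}_{o2_name}", b))
    assert len(out) == 64
    return out


def standard_condition(model_tag: str = "iJO1366") -> ConditionSpec:
    """Aerobic glucose minimal-medium reference condition.

    Growth is constrained to 0.4 1/h and ATP production maximized —
    the reference state for case-study pathway extraction.
    """
    if model_tag != "iJO1366":
        raise MetPathError(
            f"unknown model tag {model_tag!r}; available tags: iJO1366"
        )
    return ConditionSpec(
        name="standard_aerobic_glucose",
        exchange_bounds={
            "EX_glc__D_e": (-10.0, 1000.0),
            "EX_o2_e": (-20.0, 1000.0),
        },
        objective_reaction=_IJO1366_ATP,
        growth_constraint=GrowthConstraint(
            reaction_id=_IJO1366_BIOMASS, value=0.4, kind="minimum"
        ),
    )


def anaerobic_condition(model_tag: str = "iJO1366") -> ConditionSpec:
    """Anaerobic-shift condition: growth 0.26, O2 uptake limited to -2."""
    if model_tag != "iJO1366":
        raise MetPathError(
            f"unknown model tag {model_tag!r}; available tags: iJO1366"
        )
    return ConditionSpec(
        name="anaerobic_glucose",
        exchange_bounds={
            "EX_glc__D_e": (-10.0, 1000.0),
            "EX_o2_e": (-2.0, 1000.0),
        },
        objective_reaction=_IJO1366_ATP,
        growth_constraint=GrowthConstraint(
            reaction_id=_IJO1366_BIOMASS, value=0.26, kind="minimum"
        ),
    )


# ---------------------------------------------------------------------------
# MCC and merging
# ---------------------------------------------------------------------------

def pathway_mcc(
    a: MetabolitePathway,
    b: MetabolitePathway,
    universe: set[str] | list[str],
) -> float:
    """Matthews correlation of two pathways' reaction membership.

    Computed over the given reaction universe; degenerate cases (either
    pathway empty, or membership constant over the universe) return 0.
    """
    if a.metabolite_id != b.metabolite_id or a.direction != b.direction:
        raise ValueError(
            "MCC is only defined between pathways for the same "
            "metabolite and direction"
        )
    if a.is_empty or b.is_empty:
        return 0.0
    uni = sorted(universe)
    va = np.array([rid in a.reaction_weights for rid in uni], dtype=int)
    vb = np.array([rid in b.reaction_weights for rid in uni], dtype=int)
    if va.min() == va.max() or vb.min() == vb.max():
        return 1.0 if np.array_equal(va, vb) else 0.0
    return float(matthews_corrcoef(va, vb))


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def merge_database(
    per_condition: list[MetabolitePathway],
    threshold: float = DEFAULT_MERGE_THRESHOLD,
    universe: set[str] | None = None,
    conditions: list[ConditionSpec] | None = None,
    distance: int = DEFAULT_DISTANCE,
) -> PathwayDatabase:
    """Merge per-condition pathways into a database.

    Within each (metabolite, direction) group, pathways with pairwise
    MCC strictly greater than ``threshold`` are merged transitively
    (single linkage, order independent); the merged entry's weights are
    the per-reaction mean of the member weights, renormalized to sum to
    1.  ``universe`` defaults to the union of all reaction ids seen.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    if universe is None:
        universe = set()
        for pw in per_condition:
            universe |= set(pw.reaction_weights)
    groups: dict[tuple[str, str], list[MetabolitePathway]] = {}
    for pw in per_condition:
        if pw.is_empty:
            continue
        groups.setdefault(
            (pw.metabolite_id, pw.direction), []
        ).append(pw)

    entries: list[DatabaseEntry] = []
    for key in sorted(groups):
        members = sorted(groups[key], key=lambda p: p.condition_name)
        uf = _UnionFind(len(members))
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if pathway_mcc(members[i], members[j], universe) > threshold:
                    uf.union(i, j)
        clusters: dict[int, list[MetabolitePathway]] = {}
        for i, pw in enumerate(members):
            clusters.setdefault(uf.find(i), []).append(pw)
        for root in sorted(clusters):
            entries.append(_merge_cluster(clusters[root], distance))
    return PathwayDatabase(
        entries=entries,
        conditions=conditions or [],
        merge_threshold=threshold,
        distance=distance,
    )


def _merge_cluster(
    members: list[MetabolitePathway], distance: int
) -> DatabaseEntry:
    weights: dict[str, float] = {}
    for pw in members:
        for rid, w in pw.reaction_weights.items():
            weights[rid] = weights.get(rid, 0.0) + w / len(members)
    total = sum(weights.values())
    weights = {rid: w / total for rid, w in sorted(weights.items())}
    provenance = sorted(pw.condition_name for pw in members)
    first = members[0]
    return DatabaseEntry(
        pathway=MetabolitePathway(
            metabolite_id=first.metabolite_id,
            direction=first.direction,
            condition_name=";".join(provenance),
            reaction_weights=weights,
            distance=distance,
        ),
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Building and consensus scoring
# ---------------------------------------------------------------------------

def build_database(
    model: ModelNetwork,
    conditions: list[ConditionSpec],
    metabolites: list[str] | None = None,
    D: int = DEFAULT_DISTANCE,
    threshold: float = DEFAULT_MERGE_THRESHOLD,
) -> PathwayDatabase:
    """Run flux estimation + pathway extraction over a condition panel
    and merge the results.

    ``metabolites`` defaults to every non-cofactor metabolite.  Empty
    pathways (metabolite inactive under a condition) are skipped.
    """
    if metabolites is None:
        metabolites = [
            m.id for m in model.metabolites if not m.is_cofactor
        ]
    collected: list[MetabolitePathway] = []
    for cond in conditions:
        state = estimate_flux_state(model, cond)
        for mid in metabolites:
            for direction in (PRODUCTION, CONSUMPTION):
                pw = extract_pathway(model, state, mid, direction, D=D)
                if not pw.is_empty:
                    collected.append(pw)
        logger.info("condition %s: pathways extracted", cond.name)
    universe = {r.id for r in model.reactions}
    return merge_database(
        collected, threshold=threshold, universe=universe,
        conditions=conditions, distance=D,
    )


def consensus_score(
    database: PathwayDatabase,
    expr: ExpressionTable,
    model: ModelNetwork,
) -> pd.DataFrame:
    """Consensus perturbation scores across database variants.

    For each (metabolite, direction): every condition-variant is scored;
    the consensus score is the mean over scorable variants and the
    reported reaction set comes from the highest-scoring variant.
    Returns a table ranked by |log consensus score| descending.
    """
    rs = reaction_scores(model, expr)
    rows = []
    keys = sorted(
        {
            (e.pathway.metabolite_id, e.pathway.direction)
            for e in database.entries
        }
    )
    for mid, direction in keys:
        variants = database.variants(mid, direction)
        scored = []
        for e in variants:
            res = pathway_score(e.pathway, rs)
            if res.scorable:
                scored.append((res.score, e))
        if not scored:
            continue
        mean_score = float(np.mean([s for s, _ in scored]))
        best_score, best = max(
            scored, key=lambda se: (se[0], se[1].provenance)
        )
        rows.append(
            {
                "metabolite": mid,
                "direction": direction,
                "consensus_score": mean_score,
                "n_variants": len(variants),
                "best_variant_score": best_score,
                "best_variant_conditions": ";".join(best.provenance),
                "reactions": ";".join(
                    sorted(best.pathway.reaction_weights)
                ),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["abs_log_score"] = np.abs(
        np.log(df["consensus_score"].astype(float))
    )
    return df.sort_values(
        ["abs_log_score", "metabolite", "direction"],
        ascending=[False, True, True],
    ).reset_index(drop=True)
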