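"""Metabolic model containers and readers.

The central object is :class:`ModelNetwork`: an ordered list of metabolites
and reactions together with the sparse stoichiometric matrix ``S``
(metabolites x reactions).  Models are read from SBML Level 3 (FBC) or
BiGG-style JSON through COBRApy and converted into this lightweight,
immutable-by-convention representation.  Gene-protein-reaction rules are
flattened to the set of participating genes: downstream scoring averages
expression fold changes over all genes catalysing a reaction, so the
AND/OR structure is not needed.

Currency metabolites ("cofactors": ATP, NAD(H), protons, water, ...) link
otherwise unrelated parts of the network and would create spurious
shortcuts during pathway traversal; they are flagged here, by
compartment-stripped base id, and skipped during traversal.
"""

from __future__ import annotations

import gzip
import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import (
    ExpressionError,
    ModelFormatError,
    ModelValidationError,
)

logger = logging.getLogger(__name__)

#: Default currency-metabolite base names (compartment-stripped).  The set
#: is the standard one used in constraint-based network analyses; it can be
#: overridden per run via a cofactor list file or the config.
DEFAULT_COFACTORS: frozenset[str] = frozenset(
    {
        "atp", "adp", "amp", "nad", "nadh", "nadp", "nadph", "fad",
        "fadh2", "coa", "h", "h2o", "pi", "ppi", "co2", "o2", "nh4",
        "q8", "q8h2",
    }
)

_COMPARTMENT_SUFFIX = re.compile(r"_([a-z][a-z0-9]?)$")


def base_id(metabolite_id: str) -> str:
    """Strip a BiGG-style compartment suffix: ``atp_c`` -> ``atp``."""
    return _COMPARTMENT_SUFFIX.sub("", metabolite_id)


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""
    is_cofactor: bool = False


@dataclass
class Reaction:
    """A stoichiometric reaction.

    ``stoichiometry`` maps metabolite id to its signed coefficient
    (negative = consumed when the reaction runs forward).  Bounds are in
    mmol/gDW/h.  ``gene_ids`` is the flattened GPR gene set.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -1000.0
    upper_bound: float = 1000.0
    gene_ids: frozenset[str] = frozenset()
    subsystem: str = ""

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} "
                f"exceeds upper bound {self.upper_bound}"
            )
        self.gene_ids = frozenset(self.gene_ids)

    @property
    def is_exchange(self) -> bool:
        """Exchange/demand/sink reactions touch exactly one metabolite."""
        return len(self.stoichiometry) == 1


@dataclass
class ModelNetwork:
    """A metabolic network with assembled stoichiometric matrix."""

    id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    S: sp.csc_matrix = field(repr=False, default=None)

    def __post_init__(self) -> None:
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: j for j, r in enumerate(self.reactions)}
        if len(self._met_index) != len(self.metabolites):
            raise ModelValidationError("duplicate metabolite ids in model")
        if len(self._rxn_index) != len(self.reactions):
            raise ModelValidationError("duplicate reaction ids in model")
        for r in self.reactions:
            if not r.stoichiometry:
                raise ModelValidationError(
                    f"reaction {r.id!r} has empty stoichiometry"
                )
            for mid in r.stoichiometry:
                if mid not in self._met_index:
                    raise ModelValidationError(
                        f"reaction {r.id!r} cites undeclared metabolite "
                        f"{mid!r}"
                    )
        if self.S is None:
            self.S = build_stoichiometric_matrix(
                self.metabolites, self.reactions
            )
        if self.S.shape != (len(self.metabolites), len(self.reactions)):
            raise ModelValidationError(
                f"S has shape {self.S.shape}, expected "
                f"({len(self.metabolites)}, {len(self.reactions)})"
            )

    # -- lookups -----------------------------------------------------------
    def metabolite_index(self, metabolite_id: str) -> int:
        try:
            return self._met_index[metabolite_id]
        except KeyError:
            raise ModelValidationError(
                f"unknown metabolite {metabolite_id!r}"
            ) from None

    def reaction_index(self, reaction_id: str) -> int:
        try:
            return self._rxn_index[reaction_id]
        except KeyError:
            raise ModelValidationError(
                f"unknown reaction {reaction_id!r}"
            ) from None

    def metabolite(self, metabolite_id: str) -> Metabolite:
        return self.metabolites[self.metabolite_index(metabolite_id)]

    def reaction(self, reaction_id: str) -> Reaction:
        return self.reactions[self.reaction_index(reaction_id)]

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for r in self.reactions:
            out |= r.gene_ids
        return frozenset(out)

    @property
    def exchange_ids(self) -> list[str]:
        return [r.id for r in self.reactions if r.is_exchange]

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub


def build_stoichiometric_matrix(
    metabolites: list[Metabolite], reactions: list[Reaction]
) -> sp.csc_matrix:
    """Assemble S column-by-column from the reactions' stoichiometry maps."""
    met_index = {m.id: i for i, m in enumerate(metabolites)}
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for j, r in enumerate(reactions):
        for mid, coeff in r.stoichiometry.items():
            rows.append(met_index[mid])
            cols.append(j)
            vals.append(float(coeff))
    return sp.csc_matrix(
        (vals, (rows, cols)), shape=(len(metabolites), len(reactions))
    )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def from_cobra(cobra_model) -> ModelNetwork:
    """Convert a loaded COBRApy model into a :class:`ModelNetwork`.

    Subsystems come from ``reaction.subsystem`` when set; otherwise from
    SBML group membership (COBRApy stores SBML groups separately).
    """
    mets = [
        Metabolite(
            id=m.id,
            name=m.name or "",
            compartment=m.compartment or "",
        )
        for m in cobra_model.metabolites
    ]
    group_of: dict[str, str] = {}
    for g in getattr(cobra_model, "groups", []):
        for member in g.members:
            group_of.setdefault(member.id, g.name or g.id)
    rxns = []
    for r in cobra_model.reactions:
        stoich = {m.id: float(c) for m, c in r.metabolites.items()}
        rxns.append(
            Reaction(
                id=r.id,
                stoichiometry=stoich,
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                gene_ids=frozenset(g.id for g in r.genes),
                subsystem=(r.subsystem or group_of.get(r.id, "")),
            )
        )
    return ModelNetwork(id=cobra_model.id or "model", metabolites=mets,
                        reactions=rxns)


def load_model(path: str | Path, format: str | None = None) -> ModelNetwork:
    """Load a metabolic model from SBML (L3/FBC) or BiGG-style JSON.

    The format is inferred from the file extension when not given
    (``.xml``/``.sbml``/``.xml.gz`` -> sbml, ``.json`` -> json).
    """
    path = Path(path)
    if not path.exists():
        raise ModelFormatError(f"model file not found: {path}")
    if format is None:
        name = path.name.lower()
        if name.endswith((".json",)):
            format = "json"
        elif name.endswith((".xml", ".sbml", ".xml.gz", ".sbml.gz")):
            format = "sbml"
        else:
            raise ModelFormatError(
                f"cannot infer model format from file name {path.name!r}; "
                "pass format='sbml' or 'json'"
            )
    import cobra.io

    try:
        if format == "json":
            cm = cobra.io.load_json_model(str(path))
        elif format == "sbml":
            cm = cobra.io.read_sbml_model(str(path))
        else:
            raise ModelFormatError(f"unknown model format {format!r}")
    except ModelFormatError:
        raise
    except KeyError as exc:
        # cobra's JSON reader raises KeyError for undeclared references
        raise ModelValidationError(
            f"{path}: reaction cites undeclared metabolite or gene: {exc}"
        ) from exc
    except Exception as exc:  # noqa: BLE001 - wrap parser errors uniformly
        raise ModelFormatError(f"failed to parse {path}: {exc}") from exc
    return from_cobra(cm)


def write_model_json(model: ModelNetwork, path: str | Path) -> None:
    """Write a ModelNetwork as BiGG-style JSON (readable by COBRApy)."""
    genes = sorted(model.genes)
    doc = {
        "id": model.id,
        "version": "1",
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.id,
                "metabolites": {k: v for k, v in sorted(
                    r.stoichiometry.items())},
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": " or ".join(sorted(r.gene_ids)),
                "subsystem": r.subsystem,
            }
            for r in model.reactions
        ],
        "genes": [{"id": g, "name": g} for g in genes],
        "compartments": {
            m.compartment: m.compartment
            for m in model.metabolites
            if m.compartment
        },
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def flag_cofactors(
    model: ModelNetwork,
    cofactor_ids: Iterable[str] = DEFAULT_COFACTORS,
) -> ModelNetwork:
    """Return a model with ``is_cofactor`` set from base-name membership.

    ``cofactor_ids`` are compartment-free base names (e.g. ``"atp"``)
    matched against every compartment instance (``atp_c``, ``atp_p``, ...).
    Names matching no metabolite are ignored with a logged warning.
    All metabolites not matched are flagged False.
    """
    wanted = set(cofactor_ids)
    seen: set[str] = set()
    new_mets = []
    for m in model.metabolites:
        b = base_id(m.id)
        hit = b in wanted
        if hit:
            seen.add(b)
        new_mets.append(replace(m, is_cofactor=hit))
    for unknown in sorted(wanted - seen):
        logger.warning("cofactor base name %r matches no metabolite", unknown)
    return ModelNetwork(
        id=model.id, metabolites=new_mets, reactions=model.reactions,
        S=model.S,
    )


def load_cofactor_list(path: str | Path) -> frozenset[str]:
    """Read a cofactor list: one base name per line, '#' comments."""
    names = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            names.append(line)
    return frozenset(names)


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

@dataclass
class ExpressionTable:
    """Gene-level differential expression on the ratio scale.

    ``fold_changes`` maps gene id to a positive fold change where 1.0
    means unchanged.  ``raw`` optionally holds per-sample expression
    values (genes x samples) for rank normalization.
    """

    fold_changes: dict[str, float]
    raw: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for g, f in self.fold_changes.items():
            if not np.isfinite(f) or f <= 0:
                raise ExpressionError(
                    f"gene {g!r}: fold change must be positive and finite, "
                    f"got {f}"
                )

    def __len__(self) -> int:
        return len(self.fold_changes)

    def scaled(self, k: float) -> "ExpressionTable":
        return ExpressionTable(
            {g: f * k for g, f in self.fold_changes.items()}, raw=self.raw
        )


def load_expression(
    path: str | Path, log2: bool = False
) -> ExpressionTable:
    """Load an expression table (TSV or CSV).

    Requires columns ``gene`` and ``fold_change``; any further numeric
    columns are kept as per-sample raw expression.  With ``log2=True``
    fold changes are exponentiated on load (input on the log2 scale).
    Duplicate gene ids and non-positive fold changes are fatal.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    missing = {"gene", "fold_change"} - set(df.columns)
    if missing:
        raise ExpressionError(
            f"{path}: missing required column(s) {sorted(missing)}"
        )
    dup = df["gene"][df["gene"].duplicated()]
    if len(dup):
        raise ExpressionError(
            f"{path}: duplicated gene id {dup.iloc[0]!r}"
        )
    fc = df["fold_change"].astype(float)
    if log2:
        fc = np.exp2(fc)
    bad = df["gene"][~(fc > 0) | ~np.isfinite(fc)]
    if len(bad):
        raise ExpressionError(
            f"{path}: non-positive fold change for gene {bad.iloc[0]!r}"
        )
    extra = [c for c in df.columns if c not in ("gene", "fold_change")]
    raw = None
    if extra:
        raw = df.set_index("gene")[extra]
    return ExpressionTable(
        dict(zip(df["gene"].astype(str), fc)), raw=raw
    )


# ---------------------------------------------------------------------------
# Condition specifications
# ---------------------------------------------------------------------------

@dataclass
class GrowthConstraint:
    """Constrain a (biomass) reaction before the main objective is solved.

    ``value`` is a flux, or the string ``"max"`` meaning "first maximize
    this reaction, then fix the optimum".  ``kind`` selects whether the
    value becomes a lower bound (``minimum``) or pins the flux (``fixed``).
    """

    reaction_id: str
    value: float | str
    kind: str = "minimum"  # or "fixed"

    def __post_init__(self) -> None:
        if self.kind not in ("minimum", "fixed"):
            raise ValueError(f"unknown growth-constraint kind {self.kind!r}")


@dataclass
class ConditionSpec:
    """A growth condition: exchange bounds, objective, optional growth
    constraint, and the flux-length penalty magnitude."""

    name: str
    exchange_bounds: dict[str, tuple[float, float]] = field(
        default_factory=dict
    )
    objective_reaction: str = ""
    objective_sense: str = "maximize"
    growth_constraint: GrowthConstraint | None = None
    flux_length_penalty: float = 1e-6

    def __post_init__(self) -> None:
        if self.flux_length_penalty <= 0:
            raise ValueError("flux_length_penalty must be > 0")
        if self.objective_sense != "maximize":
            raise ValueError("only objective_sense='maximize' is supported")

    # -- serialization (YAML/JSON preset files) ---------------------------
    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "exchange_bounds": {
                k: list(v) for k, v in sorted(self.exchange_bounds.items())
            },
            "objective_reaction": self.objective_reaction,
            "objective_sense": self.objective_sense,
            "flux_length_penalty": self.flux_length_penalty,
        }
        if self.growth_constraint is not None:
            gc = self.growth_constraint
            d["growth_constraint"] = {
                "reaction_id": gc.reaction_id,
                "value": gc.value,
                "kind": gc.kind,
            }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ConditionSpec":
        gc = d.get("growth_constraint")
        return cls(
            name=d["name"],
            exchange_bounds={
                k: (float(v[0]), float(v[1]))
                for k, v in d.get("exchange_bounds", {}).items()
            },
            objective_reaction=d.get("objective_reaction", ""),
            objective_sense=d.get("objective_sense", "maximize"),
            growth_constraint=(
                GrowthConstraint(
                    reaction_id=gc["reaction_id"],
                    value=gc["value"],
                    kind=gc.get("kind", "minimum"),
                )
                if gc
                else None
            ),
            flux_length_penalty=float(d.get("flux_length_penalty", 1e-6)),
        )


def load_conditions(path: str | Path) -> list[ConditionSpec]:
    """Read condition presets from a YAML or JSON file (list of specs)."""
    import yaml

    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if isinstance(data, Mapping):
        data = [data]
    return [ConditionSpec.from_dict(d) for d in data]
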