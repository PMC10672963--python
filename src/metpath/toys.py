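"""Synthetic toy networks with analytically known elementary flux modes.

These small models (<= 12 reactions) exercise every stage of the
pipeline and double as test oracles: their complete elementary flux mode
(EFM) set is computed by exhaustive enumeration
(:func:`enumerate_efms`), which is independent of the iterative
decomposition used on real subnetworks.

Topologies
----------
chain
    EX_A (fixed uptake) -> R1: A->B -> R2: B->.  One EFM.
diamond
    Uptake of A, two parallel branches A->B, sink for B.  Two EFMs; the
    quadratic flux-length penalty splits flux evenly across the
    branches.
branch
    A->B and A->C with separate sinks.  Two EFMs.
cycle
    A->B->C->A loop with input to A and output from B: a throughput
    mode plus the internal loop.
cofactor_trap
    Two linear pathways coupled only through the atp_c/adp_c pair;
    cofactor stripping must keep them separate during traversal.

Every reaction carries a synthetic gene (``g_<reaction id>``, plus
``g2_<id>``/``g3_<id>`` when ``genes_per_reaction`` > 1) and a subsystem
tag so scoring and subsystem aggregation can be tested end to end.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.linalg import null_space
from scipy.optimize import linprog

from .model import Metabolite, ModelNetwork, Reaction

TOPOLOGIES = ("chain", "diamond", "branch", "cycle", "cofactor_trap")


@dataclass
class ToySpec:
    topology: str
    n_reactions: int | None = None
    seed: int = 0
    genes_per_reaction: int = 1

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValueError(
                f"unknown topology {self.topology!r}; "
                f"choose from {TOPOLOGIES}"
            )


def _rxn(rid, stoich, lb, ub, subsystem, genes_per_reaction):
    prefixes = ["g", "g2", "g3", "g4", "g5"]
    genes = frozenset(
        f"{prefixes[i]}_{rid}" for i in range(genes_per_reaction)
    )
    return Reaction(
        id=rid, stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
        gene_ids=genes, subsystem=subsystem,
    )


def make_toy_model(spec: ToySpec) -> tuple[ModelNetwork, list[dict[str, float]]]:
    """Build a toy model and its exhaustively enumerated EFM set.

    Returns ``(model, efms)`` where each EFM is a map reaction id ->
    coefficient on the direction-split network (all non-negative, scaled
    to max coefficient 1).
    """
    g = spec.genes_per_reaction
    mets: list[Metabolite]
    rxns: list[Reaction]
    if spec.topology == "chain":
        mets = [Metabolite(f"{x}_c", compartment="c") for x in "AB"]
        rxns = [
            _rxn("EX_A", {"A_c": -1.0}, -1.0, -1.0, "Transport", g),
            _rxn("R1", {"A_c": -1.0, "B_c": 1.0}, 0.0, 1000.0, "Core", g),
            _rxn("R2", {"B_c": -1.0}, 0.0, 1000.0, "Transport", g),
        ]
    elif spec.topology == "diamond":
        mets = [Metabolite(f"{x}_c", compartment="c") for x in "AB"]
        rxns = [
            _rxn("EX_A", {"A_c": -1.0}, -1.0, 0.0, "Transport", g),
            _rxn("R1", {"A_c": -1.0, "B_c": 1.0}, 0.0, 1000.0, "Core", g),
            _rxn("R2", {"A_c": -1.0, "B_c": 1.0}, 0.0, 1000.0, "Core", g),
            _rxn("EX_B", {"B_c": -1.0}, 1.0, 1.0, "Transport", g),
        ]
    elif spec.topology == "branch":
        mets = [Metabolite(f"{x}_c", compartment="c") for x in "ABC"]
        rxns = [
            _rxn("EX_A", {"A_c": -1.0}, -1.0, -1.0, "Transport", g),
            _rxn("R1", {"A_c": -1.0, "B_c": 1.0}, 0.0, 0.5, "Upper", g),
            _rxn("R2", {"A_c": -1.0, "C_c": 1.0}, 0.0, 1000.0, "Lower", g),
            _rxn("EX_B", {"B_c": -1.0}, 0.0, 1000.0, "Transport", g),
            _rxn("EX_C", {"C_c": -1.0}, 0.0, 1000.0, "Transport", g),
        ]
    elif spec.topology == "cycle":
        mets = [Metabolite(f"{x}_c", compartment="c") for x in "ABC"]
        rxns = [
            _rxn("EX_A", {"A_c": -1.0}, -1.0, -1.0, "Transport", g),
            _rxn("R1", {"A_c": -1.0, "B_c": 1.0}, 0.0, 1000.0, "Loop", g),
            _rxn("R2", {"B_c": -1.0, "C_c": 1.0}, 0.0, 1000.0, "Loop", g),
            _rxn("R3", {"C_c": -1.0, "A_c": 1.0}, 0.0, 1000.0, "Loop", g),
            _rxn("EX_B", {"B_c": -1.0}, 0.0, 1000.0, "Transport", g),
        ]
    elif spec.topology == "cofactor_trap":
        mets = [
            Metabolite(f"{x}_c", compartment="c")
            for x in ("A", "B", "C", "D", "atp", "adp")
        ]
        rxns = [
            _rxn("EX_A", {"A_c": -1.0}, -1.0, -1.0, "Transport", g),
            _rxn(
                "R1",
                {"A_c": -1.0, "atp_c": -1.0, "B_c": 1.0, "adp_c": 1.0},
                0.0, 1000.0, "Pathway1", g,
            ),
            _rxn("EX_B", {"B_c": -1.0}, 0.0, 1000.0, "Transport", g),
            _rxn("EX_C", {"C_c": -1.0}, -1.0, -1.0, "Transport", g),
            _rxn(
                "R2",
                {"C_c": -1.0, "adp_c": -1.0, "D_c": 1.0, "atp_c": 1.0},
                0.0, 1000.0, "Pathway2", g,
            ),
            _rxn("EX_D", {"D_c": -1.0}, 0.0, 1000.0, "Transport", g),
        ]
    model = ModelNetwork(id=f"toy_{spec.topology}", metabolites=mets,
                         reactions=rxns)
    return model, enumerate_efms(model)


# ---------------------------------------------------------------------------
# Exhaustive EFM enumeration (independent oracle)
# ---------------------------------------------------------------------------

def _split_columns(model: ModelNetwork):
    """Direction-split column list: (reaction_id, orientation, column).

    Reversible reactions contribute a forward and a reverse column;
    reactions restricted to v <= 0 contribute a single negated column.
    """
    S = model.S.toarray()
    cols = []
    for j, r in enumerate(model.reactions):
        fwd = r.upper_bound > 0
        rev = r.lower_bound < 0
        if fwd:
            cols.append((r.id, +1, S[:, j]))
        if rev:
            cols.append((r.id, -1, -S[:, j]))
    return cols


def enumerate_efms(
    model: ModelNetwork, tol: float = 1e-9
) -> list[dict[str, float]]:
    """Enumerate all elementary flux modes by exhaustive support search.

    On the direction-split network, supports are enumerated in order of
    increasing size; a support is an EFM support iff a steady-state flux
    strictly positive on exactly that support exists (LP feasibility)
    and no smaller feasible support is contained in it.  The flux
    pattern itself spans the one-dimensional null space of the support's
    columns.  Spurious two-cycles pairing the forward and reverse copy
    of one reversible reaction are excluded.  Practical for <= ~12
    reactions only — which is the point: it is an oracle, not the
    production decomposition.
    """
    cols = _split_columns(model)
    n = len(cols)
    if n > 16:
        raise ValueError("exhaustive enumeration limited to small networks")
    A = np.column_stack([c for _, _, c in cols]) if n else np.zeros((0, 0))
    found: list[tuple[frozenset[int], dict[str, float]]] = []
    for size in range(1, n + 1):
        for subset in itertools.combinations(range(n), size):
            T = frozenset(subset)
            if any(supp < T or supp == T for supp, _ in found):
                continue
            ids = [cols[i][0] for i in subset]
            if len(set(ids)) < size:
                continue  # contains a forward/reverse pair of one reaction
            if not _support_feasible(A, subset, tol):
                continue
            flux = _support_flux(A, subset)
            if flux is None:
                continue
            efm: dict[str, float] = {}
            for i, f in zip(subset, flux):
                rid, orient, _ = cols[i]
                efm[rid] = efm.get(rid, 0.0) + orient * f
            scale = max(abs(v) for v in efm.values())
            efm = {k: v / scale for k, v in efm.items() if abs(v) > tol}
            found.append((T, efm))
    return [efm for _, efm in found]


def _support_feasible(A: np.ndarray, subset, tol: float) -> bool:
    """Does a steady flux exist with v_i >= 1 exactly on ``subset``?"""
    sub = A[:, list(subset)]
    res = linprog(
        np.zeros(len(subset)),
        A_eq=sub, b_eq=np.zeros(A.shape[0]),
        bounds=(1, None), method="highs",
    )
    return res.status == 0


def _support_flux(A: np.ndarray, subset) -> np.ndarray | None:
    """The (unique up to scale) positive steady flux on the support."""
    sub = A[:, list(subset)]
    ns = null_space(sub, rcond=1e-10)
    if ns.shape[1] != 1:
        return None  # not support-minimal after all
    v = ns[:, 0]
    if np.all(v < 0):
        v = -v
    if np.any(v <= 0):
        return None
    return v


def is_subset_of_oracle(
    mode_support: dict[str, float],
    oracle: list[dict[str, float]],
    tol: float = 1e-6,
) -> bool:
    """Check that a decomposition mode matches one enumerated EFM.

    Supports must match exactly and coefficients agree after scaling to
    max 1 (sign-insensitively: the oracle reports signed fluxes on the
    original reactions, the decomposition non-negative split ones)."""
    supp = {k for k, v in mode_support.items() if abs(v) > tol}
    scale = max(abs(v) for v in mode_support.values())
    norm = {k: abs(v) / scale for k, v in mode_support.items()
            if abs(v) > tol}
    for efm in oracle:
        if set(efm) != supp:
            continue
        if all(
            abs(abs(efm[k]) - norm[k]) <= 1e-6 * max(1.0, norm[k])
            for k in supp
        ):
            return True
    return False
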