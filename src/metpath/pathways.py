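"""Condition-specific production and consumption pathways.

Given a solved flux state, the pathway for a metabolite is built in four
steps:

1. **Traversal** (:func:`extract_subnetwork`): orient every flux-carrying
   reaction by the sign of its flux, then walk the directed
   metabolite-reaction graph from the target metabolite — backwards for a
   production pathway, forwards for a consumption pathway — collecting all
   reactions within ``D`` reaction steps.  Currency metabolites (flagged
   ``is_cofactor``) are never traversed, except for the target itself,
   so that e.g. two pathways sharing only ATP are not joined.

2. **Closure** (:func:`close_mass_balance`): the extracted subnetwork is
   generally not at steady state on its own; a synthetic boundary
   reaction carrying exactly the imbalance is added for every unbalanced
   metabolite, making ``S_sub . v_sub = 0`` hold exactly.

3. **Decomposition** (:func:`decompose_elementary_modes`): the closed
   subnetwork flux is written as a non-negative combination of elementary
   flux modes.  Reactions are direction-split so all fluxes are
   non-negative; then, repeatedly, a support-minimal steady-state mode
   through the largest-residual reaction is found as a vertex of the
   polytope {S.e = 0, e >= 0 on the residual support, e_pivot = 1} (dual
   simplex), and the largest multiple keeping the residual non-negative
   is subtracted.  Each round zeroes at least one reaction, so the loop
   terminates and the weighted modes sum back to the subnetwork flux.

4. **Assembly** (:func:`assemble_pathway`): modes that actually produce
   (or consume) the target are summed with their weights, boundary
   reactions are dropped, and the reaction weights are normalized to sum
   to 1, giving the relative flux contribution of each reaction to the
   metabolite's production or consumption.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .errors import DecompositionError
from .fluxes import FluxState, active_reactions
from .model import ModelNetwork

logger = logging.getLogger(__name__)

PRODUCTION = "production"
CONSUMPTION = "consumption"

#: Flux below this is treated as zero during decomposition; also the
#: tolerance on the conservation residual.
RESIDUAL_TOLERANCE = 1e-8

#: Default traversal distance (reaction steps).  Distances 2-5 behave
#: similarly in practice; 1 is too local.
DEFAULT_DISTANCE = 3

BOUNDARY_PREFIX = "BD_"


def _check_direction(direction: str) -> None:
    if direction not in (PRODUCTION, CONSUMPTION):
        raise ValueError(
            f"direction must be {PRODUCTION!r} or {CONSUMPTION!r}, "
            f"got {direction!r}"
        )


@dataclass
class SubnetworkProblem:
    """The local active network around one metabolite.

    ``stoichiometry`` holds the signed coefficients of each included
    reaction restricted to the included metabolites (cofactor rows are
    dropped, except the target's own row).  ``flux`` is the parent flux
    state restricted to the subnetwork; synthetic boundary reactions added
    by closure are listed in ``boundary_reactions`` and always carry
    positive flux.
    """

    metabolite_id: str
    direction: str
    distance: int
    stoichiometry: dict[str, dict[str, float]]
    flux: dict[str, float]
    boundary_reactions: set[str] = field(default_factory=set)

    @property
    def reaction_ids(self) -> list[str]:
        return sorted(self.stoichiometry)

    @property
    def model_reaction_ids(self) -> list[str]:
        return [r for r in self.reaction_ids
                if r not in self.boundary_reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        mets: set[str] = set()
        for st in self.stoichiometry.values():
            mets.update(st)
        return sorted(mets)

    def __len__(self) -> int:
        return len(self.stoichiometry)

    def imbalance(self) -> dict[str, float]:
        """Net production (+) / consumption (-) per metabolite."""
        out: dict[str, float] = {m: 0.0 for m in self.metabolite_ids}
        for rid, st in self.stoichiometry.items():
            v = self.flux[rid]
            for mid, coeff in st.items():
                out[mid] += coeff * v
        return out

    def is_closed(self, tol: float = RESIDUAL_TOLERANCE) -> bool:
        return all(abs(b) <= tol for b in self.imbalance().values())


def extract_subnetwork(
    model: ModelNetwork,
    state: FluxState,
    metabolite_id: str,
    direction: str,
    D: int = DEFAULT_DISTANCE,
) -> SubnetworkProblem:
    """Breadth-first traversal of the flux-oriented network.

    Production pathways traverse backwards (towards the reactions that
    make the metabolite and their upstream suppliers), consumption
    pathways forwards.  Distance is counted in reactions.  Cofactor
    metabolites other than the target are not expanded.  A metabolite
    with no active producing (resp. consuming) reaction yields an empty
    subnetwork with a logged notice.
    """
    _check_direction(direction)
    if D < 1:
        raise ValueError("distance D must be >= 1")
    model.metabolite_index(metabolite_id)  # existence check
    active = active_reactions(state)

    # oriented adjacency over active reactions
    producers: dict[str, list[str]] = {}  # metabolite -> reactions making it
    consumers: dict[str, list[str]] = {}  # metabolite -> reactions using it
    oriented: dict[str, dict[str, float]] = {}  # rid -> {met: signed coeff}
    for rid in active:
        r = model.reaction(rid)
        sign = 1.0 if state.flux(rid) > 0 else -1.0
        ost = {m: sign * c for m, c in r.stoichiometry.items()}
        oriented[rid] = ost
        for mid, c in ost.items():
            if c > 0:
                producers.setdefault(mid, []).append(rid)
            elif c < 0:
                consumers.setdefault(mid, []).append(rid)

    step_from = producers if direction == PRODUCTION else consumers
    reached: set[str] = set()
    frontier = {metabolite_id}
    for _ in range(D):
        next_frontier: set[str] = set()
        for mid in frontier:
            if mid != metabolite_id and model.metabolite(mid).is_cofactor:
                continue  # cofactors block traversal
            for rid in step_from.get(mid, ()):
                if rid in reached:
                    continue
                reached.add(rid)
                for m2, c in oriented[rid].items():
                    # production: continue upstream via the reaction's
                    # substrates; consumption: downstream via its products
                    if (direction == PRODUCTION and c < 0) or (
                        direction == CONSUMPTION and c > 0
                    ):
                        if not model.metabolite(m2).is_cofactor:
                            next_frontier.add(m2)
        frontier = next_frontier
        if not frontier and not reached:
            break

    if not reached:
        logger.info(
            "metabolite %s has no active %s reaction; pathway undefined "
            "under condition %s",
            metabolite_id, direction, state.condition_name,
        )

    keep_met = lambda m: (  # noqa: E731
        m == metabolite_id or not model.metabolite(m).is_cofactor
    )
    stoich = {
        rid: {m: c for m, c in model.reaction(rid).stoichiometry.items()
              if keep_met(m)}
        for rid in sorted(reached)
    }
    # a reaction touching only cofactors would leave an empty row set
    stoich = {rid: st for rid, st in stoich.items() if st}
    flux = {rid: state.flux(rid) for rid in stoich}
    return SubnetworkProblem(
        metabolite_id=metabolite_id,
        direction=direction,
        distance=D,
        stoichiometry=stoich,
        flux=flux,
    )


def close_mass_balance(
    sub: SubnetworkProblem,
    model: ModelNetwork | None = None,
    tol: float = RESIDUAL_TOLERANCE,
) -> SubnetworkProblem:
    """Add compensating boundary reactions for unbalanced metabolites.

    For each metabolite with net production b > 0 an export reaction
    (coefficient -1) with flux b is added; net consumption gets an import
    (coefficient +1).  The result satisfies steady state exactly.  An
    already-closed subnetwork is returned unchanged.
    """
    if len(sub) == 0:
        return sub
    imb = sub.imbalance()
    stoich = dict(sub.stoichiometry)
    flux = dict(sub.flux)
    boundary = set(sub.boundary_reactions)
    changed = False
    for mid in sorted(imb):
        b = imb[mid]
        if abs(b) <= tol:
            continue
        rid = f"{BOUNDARY_PREFIX}{mid}"
        if rid in stoich:  # fold into an existing boundary reaction
            flux[rid] += b if stoich[rid][mid] < 0 else -b
            changed = True
            continue
        if b > 0:
            stoich[rid] = {mid: -1.0}
            flux[rid] = b
        else:
            stoich[rid] = {mid: 1.0}
            flux[rid] = -b
        boundary.add(rid)
        changed = True
    if not changed:
        return sub
    return SubnetworkProblem(
        metabolite_id=sub.metabolite_id,
        direction=sub.direction,
        distance=sub.distance,
        stoichiometry=stoich,
        flux=flux,
        boundary_reactions=boundary,
    )


@dataclass
class ElementaryMode:
    """One support-minimal steady-state mode on the direction-split
    subnetwork, with the multiple subtracted during decomposition."""

    support: dict[str, float]  # reaction id -> non-negative coefficient
    weight: float


def _split_matrix(
    sub: SubnetworkProblem,
) -> tuple[list[str], list[str], sp.csc_matrix, np.ndarray]:
    """Direction-split representation: columns oriented so fluxes >= 0."""
    rids = sub.reaction_ids
    mets = sub.metabolite_ids
    met_index = {m: i for i, m in enumerate(mets)}
    rows, cols, vals = [], [], []
    f = np.zeros(len(rids))
    for j, rid in enumerate(rids):
        v = sub.flux[rid]
        sign = 1.0 if v >= 0 else -1.0
        f[j] = abs(v)
        for mid, c in sub.stoichiometry[rid].items():
            rows.append(met_index[mid])
            cols.append(j)
            vals.append(sign * c)
    S = sp.csc_matrix((vals, (rows, cols)), shape=(len(mets), len(rids)))
    return rids, mets, S, f


def decompose_elementary_modes(
    sub: SubnetworkProblem, tol: float = RESIDUAL_TOLERANCE
) -> list[ElementaryMode]:
    """Write the closed subnetwork flux as weighted elementary modes.

    Iteratively picks the reaction with the largest residual flux
    (lexicographically smallest id on ties) as pivot, finds a
    support-minimal mode through it by dual simplex (vertex solutions of
    the steady-state polytope are elementary), and subtracts the largest
    multiple that keeps the residual non-negative.  The weighted modes
    sum to the subnetwork flux within ``tol`` per reaction.
    """
    if len(sub) == 0:
        return []
    rids, mets, S, f = _split_matrix(sub)
    if len(mets) and np.abs(S @ f).max() > tol:
        raise DecompositionError(
            f"subnetwork for {sub.metabolite_id} ({sub.direction}) is not "
            "mass-balance closed; call close_mass_balance first"
        )
    n = len(rids)
    # the termination tolerance (tol) bounds the conservation residual;
    # support clipping must be far tighter or zeroing a genuinely tiny
    # flux (trace-nutrient scale) would unbalance its metabolite rows
    clip = min(tol * 1e-4, 1e-12)
    residual = f.copy()
    residual[residual <= clip] = 0.0
    modes: list[ElementaryMode] = []
    for _ in range(2 * n):
        if residual.max() <= tol:
            break
        # pivot: max residual, ties -> lexicographically smallest id
        mx = residual.max()
        candidates = [j for j in range(n) if residual[j] >= mx - 1e-12]
        pivot = min(candidates, key=lambda j: rids[j])
        supp = np.flatnonzero(residual > clip)
        try:
            e = _minimal_mode(S, n, supp, pivot)
        except DecompositionError:
            # no exact mode exists within the remaining support: the
            # leftover is arithmetic dust from earlier subtractions
            # (clipped support), not real flux.  Tolerated only at
            # noise scale relative to the subnetwork flux.
            if residual[pivot] <= 1e-6 * max(1.0, f.max()):
                logger.debug(
                    "dropping %.2e residual on %s (no exact mode)",
                    residual[pivot], rids[pivot],
                )
                residual[pivot] = 0.0
                continue
            raise
        on = e > tol
        lam = float(np.min(residual[on] / e[on]))
        if lam <= 0:
            raise DecompositionError(
                "non-positive step in mode subtraction (degenerate "
                "residual)"
            )
        modes.append(
            ElementaryMode(
                support={rids[j]: float(e[j]) for j in np.flatnonzero(on)},
                weight=lam,
            )
        )
        residual = residual - lam * e
        residual[residual <= clip] = 0.0
    if residual.max() > tol:
        raise DecompositionError(
            f"decomposition residual {residual.max():.2e} above tolerance"
        )
    return modes


def _minimal_mode(
    S: sp.csc_matrix, n: int, supp: np.ndarray, pivot: int
) -> np.ndarray:
    """Vertex of {S.e=0, e>=0 on supp, 0 elsewhere, e_pivot=1}, found by
    dual simplex with objective min sum(e)."""
    ns = len(supp)
    S_supp = S[:, supp].tocsr()
    pivot_pos = int(np.where(supp == pivot)[0][0])
    pivot_row = np.zeros(ns)
    pivot_row[pivot_pos] = 1.0
    A_eq = sp.vstack([S_supp, sp.csr_matrix(pivot_row)], format="csr")
    b_eq = np.zeros(S_supp.shape[0] + 1)
    b_eq[-1] = 1.0
    res = linprog(
        np.ones(ns), A_eq=A_eq, b_eq=b_eq, bounds=(0, None),
        method="highs-ds",
        options={"primal_feasibility_tolerance": 1e-10,
                 "dual_feasibility_tolerance": 1e-10},
    )
    if res.status != 0:
        raise DecompositionError(
            f"pivot LP failed (status {res.status}): {res.message}; "
            "subnetwork appears unclosed"
        )
    e = np.zeros(n)
    e[supp] = res.x
    e[e < 0] = 0.0
    return _purify_mode(S, e, pivot)


def _purify_mode(S: sp.csc_matrix, e: np.ndarray, pivot: int) -> np.ndarray:
    """Recompute a support-minimal mode exactly from its null space.

    The LP vertex satisfies steady state only to solver tolerance;
    accumulated over many subtractions that drift can render later
    pivot LPs infeasible.  A support-minimal mode spans a
    one-dimensional null space on its support, so the exact coefficients
    are recovered by a dense null-space solve and rescaled to the
    pivot.  Degenerate cases fall back to the LP solution.
    """
    from scipy.linalg import null_space

    supp = np.flatnonzero(e > 1e-9 * max(1.0, e.max()))
    if pivot not in supp:
        return e
    ns = null_space(S[:, supp].toarray(), rcond=1e-10)
    if ns.shape[1] != 1:
        return e
    x = ns[:, 0]
    pivot_pos = int(np.where(supp == pivot)[0][0])
    if x[pivot_pos] == 0.0:
        return e
    x = x / x[pivot_pos]
    if np.any(x < -1e-9):
        return e
    exact = np.zeros_like(e)
    exact[supp] = np.maximum(x, 0.0)
    return exact


@dataclass
class MetabolitePathway:
    """A flux-weighted production or consumption pathway.

    ``reaction_weights`` are the relative flux contributions of each
    model reaction to the metabolite's production (or consumption),
    normalized to sum to 1.
    """

    metabolite_id: str
    direction: str
    condition_name: str
    reaction_weights: dict[str, float]
    distance: int

    def __post_init__(self) -> None:
        _check_direction(self.direction)

    @property
    def reaction_ids(self) -> frozenset[str]:
        return frozenset(self.reaction_weights)

    def __len__(self) -> int:
        return len(self.reaction_weights)

    @property
    def is_empty(self) -> bool:
        return not self.reaction_weights

    def gene_ids(self, model: ModelNetwork) -> frozenset[str]:
        out: set[str] = set()
        for rid in self.reaction_weights:
            out |= model.reaction(rid).gene_ids
        return frozenset(out)


def assemble_pathway(
    modes: list[ElementaryMode],
    sub: SubnetworkProblem,
    condition_name: str = "",
) -> MetabolitePathway:
    """Sum the modes that involve the target metabolite into one pathway.

    A mode counts for a production pathway when at least one of its
    non-boundary reactions produces the target in the flux orientation
    (symmetrically for consumption).  Synthetic boundary reactions are
    dropped; surviving weights are normalized to sum to 1.
    """
    target = sub.metabolite_id
    direction = sub.direction
    signs = {
        rid: (1.0 if sub.flux[rid] >= 0 else -1.0)
        for rid in sub.stoichiometry
    }
    weights: dict[str, float] = {}
    for mode in modes:
        touches = False
        for rid, coeff in mode.support.items():
            if rid in sub.boundary_reactions:
                continue
            sc = signs[rid] * sub.stoichiometry[rid].get(target, 0.0)
            if direction == PRODUCTION and sc > 0:
                touches = True
            elif direction == CONSUMPTION and sc < 0:
                touches = True
        if not touches:
            continue
        for rid, coeff in mode.support.items():
            if rid in sub.boundary_reactions:
                continue
            weights[rid] = weights.get(rid, 0.0) + mode.weight * coeff
    total = sum(weights.values())
    if total <= 0:
        if modes:
            logger.info(
                "no elementary mode involves %s of %s; empty pathway",
                direction, target,
            )
        weights = {}
    else:
        weights = {rid: w / total for rid, w in weights.items()}
    return MetabolitePathway(
        metabolite_id=target,
        direction=direction,
        condition_name=condition_name,
        reaction_weights=weights,
        distance=sub.distance,
    )


def extract_pathway(
    model: ModelNetwork,
    state: FluxState,
    metabolite_id: str,
    direction: str,
    D: int = DEFAULT_DISTANCE,
) -> MetabolitePathway:
    """Run the full traversal/closure/decomposition/assembly chain."""
    sub = extract_subnetwork(model, state, metabolite_id, direction, D)
    sub = close_mass_balance(sub, model)
    modes = decompose_elementary_modes(sub)
    return assemble_pathway(modes, sub, condition_name=state.condition_name)
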