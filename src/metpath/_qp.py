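"""Sparse primal-dual interior-point solver for box-constrained QPs.

Solves

    min  F * v'v - c'v    s.t.  S v = b,   lb <= v <= ub

with F > 0 (strictly convex), by a Mehrotra predictor-corrector method
on the perturbed KKT conditions.  The Newton step reduces to the
quasi-definite augmented system

    [2F I + D   S'] [dv]   [r1]
    [S         -d I] [dy] = [r2]

with D the diagonal barrier curvature z/s accumulated from both bounds
and d = 1e-10 a static regularization absorbing the row-rank deficiency
of stoichiometric matrices (conserved moieties); the regularization
only perturbs the non-unique dual, not the primal step.  After
convergence the active bounds are read off the complementarity pairs
and the solution is polished by one equality-constrained KKT solve, so
inactive-at-bound variables come out exactly on their bounds (clean
zeros) and the equality residual reaches ~1e-10.

Fixed variables (lb == ub) are handled as extra equality rows so the
log-barrier never sees an empty interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu


@dataclass
class QPResult:
    v: np.ndarray
    status: str  # "optimal" | "max_iter"
    iterations: int
    mu: float
    primal_residual: float
    dual_residual: float
    polished: bool
    n_active: int = 0


def solve_box_qp(
    S: sp.spmatrix,
    b: np.ndarray,
    c: np.ndarray,
    F: float,
    lb: np.ndarray,
    ub: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-9,
) -> QPResult:
    n = S.shape[1]
    lb = np.asarray(lb, dtype=float).copy()
    ub = np.asarray(ub, dtype=float).copy()
    c = np.asarray(c, dtype=float)
    b = np.asarray(b, dtype=float)

    # fixed variables become equality rows; their box is dropped
    pinned = np.isfinite(lb) & (lb == ub)
    if pinned.any():
        idx = np.flatnonzero(pinned)
        E = sp.csr_matrix(
            (np.ones(len(idx)), (np.arange(len(idx)), idx)), shape=(len(idx), n)
        )
        S = sp.vstack([S, E], format="csr")
        b = np.concatenate([b, lb[idx]])
        lb[idx] = -np.inf
        ub[idx] = np.inf
    S = S.tocsr()
    m = S.shape[0]
    ST = S.T.tocsr()

    has_lo = np.isfinite(lb)
    has_up = np.isfinite(ub)

    # starting point: minimum-norm solution of the equalities, pulled
    # strictly inside the box; duals sized to the stationarity scale
    v = _equality_qp(S, np.zeros(n), b)
    if v is None:
        v = np.zeros(n)
    span = np.where(has_lo & has_up, ub - lb, np.inf)
    margin = 0.1 * np.minimum(1.0, span / 2.0)
    margin[~np.isfinite(margin)] = 1.0
    v = np.clip(v, np.where(has_lo, lb + margin, -np.inf),
                np.where(has_up, ub - margin, np.inf))
    y = np.zeros(m)
    g0 = c - 2.0 * F * v
    zl = np.where(has_lo, np.maximum(1.0, g0), 0.0)
    zu = np.where(has_up, np.maximum(1.0, -g0), 0.0)

    n_bounds = int(has_lo.sum() + has_up.sum())
    delta = 1e-10
    status = "max_iter"
    it = 0
    # the iteration can destabilize numerically once slacks reach the
    # roundoff floor; keep the best (primal residual + gap) iterate
    best = None
    best_merit = np.inf
    best_it = 0
    for it in range(1, max_iter + 1):
        # floors prevent overflow when a slack collapses numerically;
        # a variable in that state is effectively fixed by a huge D
        sl = np.where(has_lo, np.maximum(v - lb, 1e-250), 1.0)
        su = np.where(has_up, np.maximum(ub - v, 1e-250), 1.0)
        r_d = 2.0 * F * v - c + ST @ y - zl + zu
        r_p = S @ v - b
        mu = (
            (np.sum(zl * sl * has_lo) + np.sum(zu * su * has_up)) / n_bounds
            if n_bounds
            else 0.0
        )
        pr = np.abs(r_p).max(initial=0.0)
        dr = np.abs(r_d).max(initial=0.0)
        obj_scale = 1.0 + np.abs(c).max(initial=0.0) + 2.0 * F * np.abs(
            v
        ).max(initial=0.0)
        b_scale = 1.0 + np.abs(b).max(initial=0.0)
        merit = pr / b_scale + mu / obj_scale
        if merit < best_merit:
            best_merit = merit
            best = (v.copy(), y.copy(), zl.copy(), zu.copy(), pr, dr)
            best_it = it
        if (
            pr <= tol * b_scale
            and dr <= tol * obj_scale
            and mu <= 1e-12 * obj_scale
        ):
            status = "optimal"
            break
        if it - best_it > 40:  # stagnation: fall back to best iterate
            break

        D = np.where(has_lo, zl / sl, 0.0) + np.where(has_up, zu / su, 0.0)
        D = np.minimum(D, 1e18)
        H = sp.diags(2.0 * F + D, format="csc")
        M = sp.bmat([[H, ST], [S, -sp.eye(m) * delta]], format="csc")
        try:
            lu = splu(M)
        except RuntimeError:
            break

        def newton(rc_l: np.ndarray, rc_u: np.ndarray):
            r1 = -r_d + np.where(has_lo, rc_l / sl, 0.0) - np.where(
                has_up, rc_u / su, 0.0
            )
            rhs = np.concatenate([r1, -r_p])
            sol = lu.solve(rhs)
            dv = sol[:n]
            dy = sol[n:]
            dzl = np.where(has_lo, (rc_l - zl * dv) / sl, 0.0)
            dzu = np.where(has_up, (rc_u + zu * dv) / su, 0.0)
            return dv, dy, dzl, dzu

        def step_lengths(dv, dzl, dzu, tau):
            with np.errstate(divide="ignore", invalid="ignore"):
                ap = [1.0]
                neg = has_lo & (dv < 0)
                if neg.any():
                    ap.append((tau * sl[neg] / -dv[neg]).min())
                pos = has_up & (dv > 0)
                if pos.any():
                    ap.append((tau * su[pos] / dv[pos]).min())
                ad = [1.0]
                nl = has_lo & (dzl < 0)
                if nl.any():
                    ad.append((tau * zl[nl] / -dzl[nl]).min())
                nu = has_up & (dzu < 0)
                if nu.any():
                    ad.append((tau * zu[nu] / -dzu[nu]).min())
            return min(ap), min(ad)

        # predictor (affine)
        rc_l_aff = -sl * zl
        rc_u_aff = -su * zu
        dv_a, dy_a, dzl_a, dzu_a = newton(rc_l_aff, rc_u_aff)
        ap_a, ad_a = step_lengths(dv_a, dzl_a, dzu_a, tau=1.0)
        a_aff = min(ap_a, ad_a)  # single step length: primal and dual
        mu_aff = (
            np.sum(
                np.where(has_lo, (sl + a_aff * dv_a) * (zl + a_aff * dzl_a),
                         0)
            )
            + np.sum(
                np.where(has_up, (su - a_aff * dv_a) * (zu + a_aff * dzu_a),
                         0)
            )
        ) / max(n_bounds, 1)
        sigma = min(1.0, (max(mu_aff, 0.0) / mu) ** 3) if mu > 0 else 0.0

        # corrector
        rc_l = sigma * mu - sl * zl - dv_a * dzl_a
        rc_u = sigma * mu - su * zu + dv_a * dzu_a
        dv, dy, dzl, dzu = newton(rc_l, rc_u)
        tau = 0.995 if mu > 1e-8 else 0.9995
        ap, ad = step_lengths(dv, dzl, dzu, tau)
        alpha = min(ap, ad)
        v = v + alpha * dv
        y = y + alpha * dy
        zl = np.where(has_lo, zl + alpha * dzl, 0.0)
        zu = np.where(has_up, zu + alpha * dzu, 0.0)

    if best is not None:
        v, y, zl, zu, pr_best, dr_best = best
        if status != "optimal" and best_merit <= 1e-6:
            status = "near_optimal"
    sl = np.where(has_lo, v - lb, 1.0)
    su = np.where(has_up, ub - v, 1.0)
    # ladder of active-set classification thresholds: tight first (keeps
    # genuine trace fluxes free), coarser as fallback
    polished = False
    v_pol = v
    for act_thr in (1e-7, 1e-6, 1e-5):
        v_pol, polished = _polish(
            S, b, c, F, lb, ub, v, sl, su, zl, zu, has_lo, has_up,
            act_thr=act_thr,
        )
        if polished:
            break
    if polished:
        v = v_pol
    r_p = S @ v - b
    result_v = np.clip(v, lb, ub)
    if pinned.any():
        result_v[pinned] = np.where(pinned, np.clip(result_v, lb, ub),
                                    result_v)[pinned]
    sl = np.where(has_lo, v - lb, 1.0)
    su = np.where(has_up, ub - v, 1.0)
    mu = (
        (np.sum(zl * sl * has_lo) + np.sum(zu * su * has_up))
        / max(n_bounds, 1)
    )
    return QPResult(
        v=result_v,
        status=status,
        iterations=it,
        mu=float(mu),
        primal_residual=float(np.abs(r_p).max(initial=0.0)),
        dual_residual=float(
            np.abs(2.0 * F * v - c + S.T @ y - zl + zu).max(initial=0.0)
        ),
        polished=polished,
    )


def _polish(
    S, b, c, F, lb, ub, v, sl, su, zl, zu, has_lo, has_up,
    act_thr: float = 1e-7,
) -> tuple[np.ndarray, bool]:
    """Snap the interior-point solution onto its active set.

    Near-zero slacks identify the active bounds; the equality-
    constrained QP on the free variables is then solved exactly.
    Misclassified bounds are repaired without consulting the (possibly
    degenerate) dual: an active bound that makes a metabolite balance
    unsatisfiable is released, a free variable pushed past its bound is
    activated, until the reduced solution is feasible.  The polished
    point is accepted only if it is feasible and does not worsen the
    objective beyond the interior-point accuracy, otherwise the
    interior-point iterate stands.
    """
    lo_scale = np.maximum(1.0, np.abs(np.where(has_lo, lb, 0.0)))
    up_scale = np.maximum(1.0, np.abs(np.where(has_up, ub, 0.0)))
    at_lo = has_lo & (sl <= act_thr * lo_scale)
    at_up = has_up & (su <= act_thr * up_scale) & ~at_lo
    S_csr = S.tocsr()
    eps = 1e-9
    seen: set[bytes] = set()
    for _ in range(100):
        key = np.packbits(at_lo).tobytes() + np.packbits(at_up).tobytes()
        if key in seen:
            return v, False
        seen.add(key)
        active = at_lo | at_up
        free = ~active
        v_act = np.where(at_up, ub, np.where(at_lo, lb, 0.0))
        b_f = b - (S_csr[:, active] @ v_act[active] if active.any()
                   else 0.0)
        S_free = S_csr[:, free]
        # least-distance projection of the interior-point iterate: keeps
        # the polish local so snapping the active set cannot excite
        # penalty-neutral cycles through distant reactions
        sol = _equality_qp(S_free, v[free], b_f)
        if sol is None:
            # release active bounds feeding the unbalanced rows
            occ = np.diff(S_free.tocsr().indptr) > 0
            bad = np.flatnonzero(~occ & (np.abs(b_f) > 1e-9))
            released = False
            for i in bad:
                for j in S_csr.getrow(i).indices:
                    if active[j]:
                        at_lo[j] = False
                        at_up[j] = False
                        released = True
            if not released:
                return v, False
            continue
        v_new = v_act.copy()
        v_new[free] = sol
        lo_bad = free & has_lo & (v_new < lb - eps * lo_scale)
        up_bad = free & has_up & (v_new > ub + eps * up_scale)
        if lo_bad.any() or up_bad.any():
            at_lo |= lo_bad
            at_up |= up_bad
            continue
        r = S_csr @ v_new - b
        if np.abs(r).max(initial=0.0) > 1e-8 * (
            1.0 + np.abs(b).max(initial=0.0)
        ):
            # residual rows expose misclassified active bounds (true
            # fluxes below the classification threshold): release them
            released = False
            for i in np.flatnonzero(np.abs(r) > 1e-9):
                for j in S_csr.getrow(i).indices:
                    if at_lo[j] or at_up[j]:
                        at_lo[j] = False
                        at_up[j] = False
                        released = True
            if not released:
                return v, False
            continue
        f_old = F * (v @ v) - c @ v
        f_new = F * (v_new @ v_new) - c @ v_new
        # the interior-point iterate is itself only accurate to ~mu, so
        # a comparable objective concession is acceptable in exchange
        # for exact feasibility and clean zeros
        if f_new > f_old + 1e-4 * (1.0 + abs(f_old)):
            return v, False
        return np.clip(v_new, lb, ub), True
    return v, False


def _equality_qp(S_f, t_f, b_f) -> np.ndarray | None:
    """min ||v - t||^2 s.t. S_f v = b_f, via regularized KKT + refinement."""
    m = S_f.shape[0]
    csr = S_f.tocsr()
    occupied = np.diff(csr.indptr) > 0
    if not occupied.all():
        if np.abs(b_f[~occupied]).max(initial=0.0) > 1e-9:
            return None
        csr = csr[occupied]
        b_f = b_f[occupied]
        m = csr.shape[0]
    nf = S_f.shape[1]
    if nf == 0:
        return np.zeros(0)
    delta = 1e-12
    M = sp.bmat(
        [[sp.eye(nf), csr.T], [csr, -sp.eye(m) * delta]], format="csc"
    )
    M0 = sp.bmat([[sp.eye(nf), csr.T], [csr, None]], format="csc")
    rhs = np.concatenate([t_f, b_f])
    try:
        lu = splu(M)
    except RuntimeError:
        return None
    sol = lu.solve(rhs)
    stat_tol = 1e-12 * max(1.0, float(np.abs(t_f).max(initial=0.0)))
    for _ in range(10):
        resid = rhs - M0 @ sol
        if (
            np.abs(resid[:nf]).max(initial=0.0) < stat_tol
            and np.abs(resid[nf:]).max(initial=0.0) < 1e-10
        ):
            break
        sol = sol + lu.solve(resid)
    x = sol[:nf]
    # LU refinement can stall on near-dependent rows; a minimum-norm
    # LSQR correction on the (tiny) remaining equality residual is
    # well-scaled and preserves the projection property
    from scipy.sparse.linalg import lsqr

    for _ in range(3):
        eq_resid = b_f - csr @ x
        if np.abs(eq_resid).max(initial=0.0) < 1e-10:
            break
        dx = lsqr(csr, eq_resid, atol=1e-13, btol=1e-13,
                  iter_lim=5000)[0]
        x = x + dx
    return x
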