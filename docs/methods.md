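# Methods

## Flux-state estimation

The flux state for a condition is the unique optimum of

    max  c·v − ε‖v‖²   s.t.  S·v = 0,  lb ≤ v ≤ ub

with `c` a unit vector on the condition's objective reaction and
`ε = flux_length_penalty = 1e-6` (per-condition, must be positive).
The quadratic term is a flux-length (enzyme-economy) penalty: among
the typically degenerate optima of the linear program it selects the
flux vector of minimal Euclidean norm, which also makes every
downstream pathway deterministic.  The sign convention matters: a
*maximization* with a positive-definite quadratic term would be
unbounded, so the penalty enters negatively (equivalently, the
diagonal scaling matrix on the quadratic term is −ε·I).

Conditions are imposed in `apply_condition`: exchange bounds overwrite
model bounds; a growth constraint is installed before the main solve.
A growth value of `"max"` triggers a two-stage procedure — maximize
the growth reaction as a plain LP (HiGHS), back the optimum off by a
relative 1e-9 so the quadratic problem stays strictly feasible, and
install it as a lower bound — used by the built-in condition panel
(biomass first, then ATP production as objective).  `"fixed"` pins the
flux; `"minimum"` sets the lower bound only.

### Numerical solution

No installed convex-QP solver reaches the accuracy this pipeline
needs at genome scale (the downstream traversal treats every flux
above `zero_tolerance = 1e-9` as active, so solver noise on true zeros
would flood the pathways with spurious reactions).  The QP is
therefore solved by a dedicated sparse primal-dual interior-point
method (`metpath._qp`, Mehrotra predictor-corrector with a single
combined step length):

- Newton systems are quasi-definite augmented systems factorized with
  SuperLU; a static −1e-10 dual regularization absorbs the row-rank
  deficiency of stoichiometric matrices (conserved moieties) without
  touching the primal step.
- Fixed variables (lb = ub) become extra equality rows so the barrier
  never sees an empty interval.
- The iteration can destabilize in floating point once slacks hit the
  roundoff floor; the best iterate (primal residual + scaled gap) is
  retained and iteration stops after 40 stagnant rounds.
- The final *polish* classifies active bounds by slack size (threshold
  ladder 1e-7, 1e-6, 1e-5 relative to the bound magnitude), projects
  the interior-point iterate onto the resulting equality system
  (least-distance, solved by LU plus iterative refinement and an LSQR
  mop-up), and repairs misclassifications without consulting the —
  possibly degenerate — duals: bounds whose fixation makes a
  metabolite balance unsatisfiable are released, free variables pushed
  past a bound are activated.  The polished point is accepted only if
  it is feasible and concedes at most 1e-4 (relative) of objective,
  comparable to the interior-point iterate's own accuracy.

The result: steady-state residual ‖S·v‖∞ ≈ 1e-9 on iJO1366 (required:
≤ 1e-6), inactive reactions at exactly zero, and bitwise-identical
repeated solves.  On the toy networks the optimum is exact to machine
precision (e.g. the symmetric-diamond even split 0.5/0.5).  An
independent cross-check against OSQP on the toy problems is part of
the test suite.  Infeasible or unbounded conditions are diagnosed by
an LP pre-solve with actionable messages (which exchange bounds to
check).

## Pathway extraction

- **Traversal.**  Breadth-first over the flux-oriented
  metabolite-reaction graph restricted to active reactions
  (|v| > 1e-9).  Distance counts reactions: D=1 reaches exactly the
  directly producing (consuming) reactions.  Cofactor metabolites are
  never expanded — except the target itself when the target is a
  cofactor (e.g. FADH2), so that carrier metabolites still get
  pathways while unrelated routes sharing only ATP stay disconnected.
  Cofactor rows are also dropped from the subnetwork stoichiometry
  (they are removed from the network, not merely skipped), again
  keeping the target's own row.
- **Default cofactor list** (the standard currency set; overridable
  via config or a one-name-per-line file): atp, adp, amp, nad, nadh,
  nadp, nadph, fad, fadh2, coa, h, h2o, pi, ppi, co2, o2, nh4, q8,
  q8h2, matched on the compartment-stripped base id in every
  compartment.
- **Closure.**  Every metabolite with net imbalance |b| > 1e-8 gets a
  synthetic boundary reaction (`BD_<met>`) carrying exactly the
  imbalance, so the subnetwork satisfies steady state.
- **Decomposition.**  On the direction-split (all-non-negative)
  representation, iteratively: pick the largest-residual reaction as
  pivot (ties broken to the lexicographically smallest id), find a
  support-minimal steady-state mode through it as a vertex of
  {S·e = 0, e ≥ 0 on the residual support, e_pivot = 1} by dual
  simplex, re-derive the vertex coefficients exactly from the
  one-dimensional null space of its support (LP tolerance would
  otherwise accumulate across subtractions), and subtract the largest
  multiple keeping the residual non-negative.  Each round zeroes at
  least one reaction.  Tolerances: termination at residual 1e-8,
  support clipping at 1e-12 (much tighter, because trace-nutrient
  fluxes of order 1e-7 are genuine).  If no exact mode exists within
  the remaining support — arithmetic dust after many subtractions —
  residuals up to 1e-6 relative to the largest subnetwork flux are
  dropped with a debug log; anything larger is an error.
- **Assembly.**  Modes with at least one non-boundary reaction
  producing (consuming) the target are summed with their multipliers;
  boundary reactions are dropped (they are bookkeeping, not
  biology); weights normalized to sum to 1.

Default distance `D = 3`; distances 2–5 behave similarly for
co-expression purposes while 1 is too local.  The iJO1366 succinate
case study in the tests uses `D = 6`, the span of the TCA loop from
citrate synthase to succinate under this reaction-step counting —
with smaller D the upstream third of the cycle is simply out of
range.

## Scoring

Reaction score = arithmetic mean fold change over the reaction's
genes that have data; GPR rules are flattened to the participating
gene set, since the average does not distinguish complexes from
isozymes.  Pathway score = weight-normalized mean of reaction scores,
restricted to scored reactions (weights renormalized; missing data is
dropped rather than imputed at 1.0, which would shrink real signals
by an annotation-coverage-dependent factor).  The weighted mean is
computed from raw weights (fsum ratio) so all-neutral input yields
*exactly* 1.0.

Permutation test: fold-change values are shuffled globally across the
model's genes with data, pathway scores recomputed (vectorized over
permutations), and

    p = (1 + #{ |log s_null| ≥ |log s_obs| }) / (n_perm + 1)

two-sided on the log scale because up- and down-regulation are both
perturbations.  Default `n_perm = 10000`; the seed is explicit
everywhere.  Calibration under an i.i.d. log-normal null is asserted
by a KS test in the acceptance suite.

Subsystem hit scores: per pathway, hits(subsystem) = number of scored
pathway reactions annotated to it; contribution = hits × pathway
score; the reported value is the mean contribution over the pathways
that hit the subsystem (pathways without annotated reactions
contribute nothing).  Rank normalization replaces expression values
with their 1-based ascending rank, ties broken lexicographically by
gene id for determinism.

## Pathway database

`builtin_conditions("iJO1366")` reconstructs a 64-condition panel:
one standard glucose minimal medium, 20 single amino-acid supplements
(exchange lower bound −0.5 mmol/gDW/h) under aerobic and anaerobic
regimes, and 8 carbon sources (glucose, D-lactate, galactose,
mannose, acetate, fumarate, succinate, glycolate; uptake −10) under
normoxia (O₂ ≥ −20), hypoxia (−2, the reduced-oxygen value also used
by the anaerobic-shift case) and anoxia (0, with nitrate opened at
−10 as the electron acceptor).  The glucose/normoxia cell of the
carbon grid coincides with the standard medium and is not
duplicated.  Every preset maximizes biomass first, fixes it as a
minimum, then maximizes ATP production (ATPM).  Values not pinned by
the condition definitions (the carbon/nitrate uptake of 10, the
normoxic O₂ of 20) are standard minimal-medium simulation settings
and are deliberate preset constants, documented here rather than
buried in code.

Merging: within each (metabolite, direction) group, pathways whose
binary reaction memberships have MCC strictly greater than the
threshold (default 0.9) over the model's reaction universe are merged
transitively (single linkage via union-find — order independent);
merged weights are the per-reaction mean of member weights,
renormalized.  Degenerate MCC cases: an empty pathway compares as 0;
constant membership vectors compare as 1 when identical, else 0.
Consensus scoring over the database reports, per metabolite and
direction, the mean score across condition-variants and the reaction
set of the highest-scoring variant.

## What the synthetic fixtures do and do not show

The toy topologies (chain, diamond, branch, cycle, cofactor trap) are
small enough for the complete elementary-flux-mode set to be
enumerated exhaustively (null-space + support-minimality over all
supports), giving an oracle that is independent of the iterative
decomposition.  They exercise flux forcing, degenerate-optimum
resolution, internal cycles, and cofactor shortcuts.  They do not
emulate genome-scale properties — rank-deficient stoichiometry,
trace-nutrient flux scales spanning nine orders of magnitude,
thousands of blocked reactions — which is why the suite additionally
runs the succinate/TCA case study on iJO1366 (read from COBRApy's
bundled copy of the reconstruction, so no download is involved).

Pathway-size statistics on iJO1366 depend strongly on the traversal
distance parameterization; the survey in the acceptance suite reports
the median production/consumption pathway sizes over the TCA-cycle
metabolites at D = 3 and checks their qualitative structure (dozens
of metabolites carry TCA-involving pathways; the FADH2 consumption
pathway, a redox-carrier hub, is larger than typical) rather than any
particular size.

## Known limitations

- The elementary-mode decomposition is deterministic but not unique;
  a different pivot rule can produce a different (equally valid)
  weighting that still reconstructs the subnetwork flux exactly.
- Problem sizes in the test and acceptance runs (≤ 12-reaction
  oracles, 500-draw calibration at 1000 permutations, one
  genome-scale condition) were chosen so the full suite completes in
  minutes; all of them scale up by changing the obvious parameters.
- Genome-scale database builds (64 conditions × ~2000 metabolites ×
  2 directions) run at roughly a minute per condition for the flux
  state plus a fraction of a second per pathway; the toy-model
  database exercised in the tests covers the merging logic itself.
- No thermodynamic or regulatory constraints: a flux state is what
  the penalized FBA problem says it is.
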