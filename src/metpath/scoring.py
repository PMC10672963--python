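"""Perturbation scoring of pathways with differential expression.

A reaction's score is the arithmetic mean of the expression fold changes
of the genes catalysing it (ratio scale, 1 = unchanged):

    reaction_score = (1/n) * sum_i f_i

and a pathway's perturbation score is the flux-weighted average of its
reaction scores,

    pathway_score = sum_i w_i * reaction_score_i

with the weights w_i taken from the pathway (relative flux contribution,
summing to 1).  Reactions without any expression data are dropped and the
weights renormalized over the scored reactions — imputing a neutral 1.0
would dilute real signals by an amount depending on annotation coverage.

Scores above and below 1 both indicate perturbation; significance is
assessed by a nonparametric permutation test that shuffles the
fold-change assignment across the model's genes and recomputes the
pathway score, two-sided on the log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ExpressionTable, ModelNetwork
from .pathways import MetabolitePathway

DEFAULT_N_PERMUTATIONS = 10_000


@dataclass
class ReactionScore:
    reaction_id: str
    score: float
    n_genes: int


@dataclass
class PathwayScoreResult:
    """Perturbation score for one pathway, with per-reaction breakdown.

    ``per_reaction`` lists (reaction_id, renormalized weight, reaction
    score).  ``p_value`` is None until a permutation test is run, and for
    unscorable pathways (no reaction with expression data).
    """

    metabolite_id: str
    direction: str
    score: float | None
    n_reactions_scored: int
    per_reaction: list[tuple[str, float, float]]
    p_value: float | None = None
    condition_name: str = ""

    @property
    def scorable(self) -> bool:
        return self.score is not None


def reaction_scores(
    model: ModelNetwork, expr: ExpressionTable
) -> dict[str, ReactionScore]:
    """Mean fold change over each reaction's genes with data.

    Reactions whose genes all lack expression data (or that have no
    genes) are absent from the result.
    """
    fc = expr.fold_changes
    out: dict[str, ReactionScore] = {}
    for r in model.reactions:
        vals = [fc[g] for g in r.gene_ids if g in fc]
        if vals:
            out[r.id] = ReactionScore(
                reaction_id=r.id,
                score=float(np.mean(vals)),
                n_genes=len(vals),
            )
    return out


def pathway_score(
    pathway: MetabolitePathway,
    rscores: dict[str, ReactionScore],
) -> PathwayScoreResult:
    """Flux-weighted mean reaction score, renormalized over scored
    reactions.  Pathways with no scored reaction are flagged unscorable
    (score None)."""
    scored = [
        (rid, w, rscores[rid].score)
        for rid, w in sorted(pathway.reaction_weights.items())
        if rid in rscores
    ]
    wsum = sum(w for _, w, _ in scored)
    if not scored or wsum <= 0:
        return PathwayScoreResult(
            metabolite_id=pathway.metabolite_id,
            direction=pathway.direction,
            score=None,
            n_reactions_scored=0,
            per_reaction=[],
            condition_name=pathway.condition_name,
        )
    per_reaction = [(rid, w / wsum, s) for rid, w, s in scored]
    # weighted mean from the raw weights: when every reaction score is
    # exactly s0 this yields exactly s0 (w * 1.0 == w in floating point)
    score = float(
        math.fsum(w * s for _, w, s in scored)
        / math.fsum(w for _, w, _ in scored)
    )
    return PathwayScoreResult(
        metabolite_id=pathway.metabolite_id,
        direction=pathway.direction,
        score=score,
        n_reactions_scored=len(per_reaction),
        per_reaction=per_reaction,
        condition_name=pathway.condition_name,
    )


def permutation_test(
    pathway: MetabolitePathway,
    rscores: dict[str, ReactionScore],
    expr: ExpressionTable,
    model: ModelNetwork,
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
) -> float | None:
    """Two-sided permutation p-value for a pathway's score.

    The null distribution is built by permuting the fold-change values
    across all model genes that have expression data and recomputing the
    reaction and pathway scores each round.  Two-sidedness is taken on
    the log scale:  p = (1 + #{|log s_null| >= |log s_obs|}) / (n_perm+1).
    Returns None for unscorable pathways.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    obs = pathway_score(pathway, rscores)
    if not obs.scorable:
        return None

    genes = sorted(g for g in model.genes if g in expr.fold_changes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    values = np.array([expr.fold_changes[g] for g in genes])

    # per scored reaction: indices of its genes with data
    rxn_gene_idx = []
    weights = []
    for rid, w, _ in obs.per_reaction:
        idx = [gene_pos[g] for g in model.reaction(rid).gene_ids
               if g in gene_pos]
        rxn_gene_idx.append(np.array(idx, dtype=int))
        weights.append(w)
    weights = np.array(weights)

    rng = np.random.default_rng(seed)
    perm = np.empty((n_perm, len(values)))
    for i in range(n_perm):
        perm[i] = rng.permutation(values)
    null_scores = np.zeros(n_perm)
    for w, idx in zip(weights, rxn_gene_idx):
        null_scores += w * perm[:, idx].mean(axis=1)

    obs_stat = abs(math.log(obs.score))
    null_stat = np.abs(np.log(null_scores))
    exceed = int(np.sum(null_stat >= obs_stat - 1e-12))
    return (1 + exceed) / (n_perm + 1)


def score_pathways(
    pathways: list[MetabolitePathway],
    model: ModelNetwork,
    expr: ExpressionTable,
    n_perm: int | None = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
) -> list[PathwayScoreResult]:
    """Score every pathway; optionally attach permutation p-values
    (``n_perm=None`` skips the tests)."""
    rs = reaction_scores(model, expr)
    results = []
    for pw in pathways:
        res = pathway_score(pw, rs)
        if n_perm is not None and res.scorable:
            res.p_value = permutation_test(
                pw, rs, expr, model, n_perm=n_perm, seed=seed
            )
        results.append(res)
    return results


def results_table(
    results: list[PathwayScoreResult], fdr: bool = False
) -> pd.DataFrame:
    """Tabulate results ranked by |log score| descending.

    With ``fdr=True`` a Benjamini-Hochberg adjusted q-value column is
    added (over the pathways that have a p-value).
    """
    rows = []
    for r in results:
        rows.append(
            {
                "metabolite": r.metabolite_id,
                "direction": r.direction,
                "score": r.score,
                "p_value": r.p_value,
                "n_reactions": r.n_reactions_scored,
                "condition": r.condition_name,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["abs_log_score"] = np.abs(np.log(df["score"].astype(float)))
    df = df.sort_values(
        ["abs_log_score", "metabolite", "direction"],
        ascending=[False, True, True],
    ).reset_index(drop=True)
    if fdr and df["p_value"].notna().any():
        from statsmodels.stats.multitest import multipletests

        mask = df["p_value"].notna()
        q = np.full(len(df), np.nan)
        q[mask.to_numpy()] = multipletests(
            df.loc[mask, "p_value"], method="fdr_bh"
        )[1]
        df["q_value"] = q
    return df


def subsystem_scores(
    results: list[PathwayScoreResult], model: ModelNetwork
) -> dict[str, float]:
    """Subsystem hit scores.

    For each pathway, a subsystem's hit count is the number of pathway
    reactions annotated to it; the contribution is hit x pathway score.
    Contributions are averaged over the pathways that hit the subsystem.
    """
    contributions: dict[str, list[float]] = {}
    for res in results:
        if not res.scorable:
            continue
        hits: dict[str, int] = {}
        for rid, _, _ in res.per_reaction:
            ss = model.reaction(rid).subsystem
            if ss:
                hits[ss] = hits.get(ss, 0) + 1
        for ss, h in hits.items():
            contributions.setdefault(ss, []).append(h * res.score)
    return {ss: float(np.mean(v)) for ss, v in sorted(contributions.items())}


def rank_normalize(expr_values: dict[str, float]) -> dict[str, int]:
    """Replace expression values by their 1-based ascending rank.

    Ties are broken by gene id (lexicographic) so the result is
    deterministic.
    """
    ordered = sorted(expr_values.items(), key=lambda kv: (kv[1], kv[0]))
    return {g: i + 1 for i, (g, _) in enumerate(ordered)}
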