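"""Pathway extraction: traversal, closure, decomposition, assembly."""

import numpy as np
import pytest

from metpath import (
    CONSUMPTION,
    PRODUCTION,
    assemble_pathway,
    close_mass_balance,
    decompose_elementary_modes,
    extract_pathway,
    extract_subnetwork,
)
from metpath.errors import DecompositionError
from metpath.pathways import SubnetworkProblem
from metpath.toys import is_subset_of_oracle

ALL_TOYS = ["chain", "diamond", "branch", "cycle", "cofactor_trap"]


class TestTraversal:
    def test_one_forward_step(self, chain):
        model, state, _ = chain
        sub = extract_subnetwork(model, state, "B_c", CONSUMPTION, D=1)
        assert set(sub.stoichiometry) == {"R2"}

    def test_two_reverse_steps(self, chain):
        model, state, _ = chain
        sub = extract_subnetwork(model, state, "B_c", PRODUCTION, D=2)
        assert set(sub.stoichiometry) == {"EX_A", "R1"}

    def test_cofactor_blocks_traversal(self, cofactor_trap):
        """Pathways linked only through atp/adp must stay separate."""
        model, state, _ = cofactor_trap
        for D in (1, 3, 5):
            sub = extract_subnetwork(model, state, "B_c", PRODUCTION, D=D)
            assert set(sub.stoichiometry) <= {"EX_A", "R1"}
            assert "R2" not in sub.stoichiometry

    def test_cofactor_target_is_itself_traversable(self, cofactor_trap):
        # atp_c is a cofactor, but its own pathway must reach the
        # reactions producing it (stripping skips only the target)
        model, state, _ = cofactor_trap
        sub = extract_subnetwork(model, state, "atp_c", PRODUCTION, D=1)
        assert "R2" in sub.stoichiometry

    def test_inactive_metabolite_yields_empty_subnetwork(self, branch):
        # no flux ever produces B in the EX_C-driven state
        model, state, _ = branch
        sub = extract_subnetwork(model, state, "B_c", PRODUCTION, D=3)
        assert len(sub) == 0

    def test_distance_must_be_positive(self, chain):
        model, state, _ = chain
        with pytest.raises(ValueError):
            extract_subnetwork(model, state, "B_c", PRODUCTION, D=0)

    def test_direction_validated(self, chain):
        model, state, _ = chain
        with pytest.raises(ValueError, match="direction"):
            extract_subnetwork(model, state, "B_c", "sideways", D=1)

    @pytest.mark.parametrize("fixture", ALL_TOYS)
    @pytest.mark.parametrize("direction", [PRODUCTION, CONSUMPTION])
    def test_monotone_in_distance(self, fixture, direction, request):
        model, state, _ = request.getfixturevalue(fixture)
        for met in [m.id for m in model.metabolites][:4]:
            previous = set()
            for D in (1, 2, 3, 4):
                sub = extract_subnetwork(model, state, met, direction, D)
                assert previous <= set(sub.stoichiometry)
                previous = set(sub.stoichiometry)


class TestClosure:
    def test_single_reaction_gets_both_boundaries(self):
        sub = SubnetworkProblem(
            metabolite_id="B_c", direction=PRODUCTION, distance=1,
            stoichiometry={"R1": {"A_c": -1.0, "B_c": 1.0}},
            flux={"R1": 1.0},
        )
        closed = close_mass_balance(sub)
        assert closed.boundary_reactions == {"BD_A_c", "BD_B_c"}
        assert closed.flux["BD_A_c"] == pytest.approx(1.0)
        assert closed.flux["BD_B_c"] == pytest.approx(1.0)
        assert closed.is_closed()

    def test_already_closed_returned_unchanged(self, chain):
        model, state, _ = chain
        sub = extract_subnetwork(model, state, "B_c", PRODUCTION, D=3)
        # full chain incl. both exchanges is already balanced except B
        closed = close_mass_balance(sub)
        again = close_mass_balance(closed)
        assert again is closed

    def test_branch_split_boundaries(self):
        sub = SubnetworkProblem(
            metabolite_id="A_c", direction=CONSUMPTION, distance=1,
            stoichiometry={
                "IN": {"A_c": 1.0},
                "R1": {"A_c": -1.0, "B_c": 1.0},
                "R2": {"A_c": -1.0, "C_c": 1.0},
            },
            flux={"IN": 1.0, "R1": 0.5, "R2": 0.5},
        )
        closed = close_mass_balance(sub)
        assert closed.flux["BD_B_c"] == pytest.approx(0.5)
        assert closed.flux["BD_C_c"] == pytest.approx(0.5)
        assert closed.is_closed()


class TestDecomposition:
    def test_single_chain_single_mode(self, chain):
        model, state, _ = chain
        sub = close_mass_balance(
            extract_subnetwork(model, state, "B_c", PRODUCTION, D=2)
        )
        modes = decompose_elementary_modes(sub)
        assert len(modes) == 1
        assert modes[0].weight == pytest.approx(1.0, abs=1e-9)

    def test_diamond_two_equal_modes(self, diamond):
        model, state, _ = diamond
        sub = close_mass_balance(
            extract_subnetwork(model, state, "B_c", PRODUCTION, D=2)
        )
        modes = decompose_elementary_modes(sub)
        assert len(modes) == 2
        assert sorted(m.weight for m in modes) == pytest.approx(
            [0.5, 0.5], abs=1e-8
        )

    def test_unclosed_subnetwork_rejected(self):
        sub = SubnetworkProblem(
            metabolite_id="B_c", direction=PRODUCTION, distance=1,
            stoichiometry={"R1": {"A_c": -1.0, "B_c": 1.0}},
            flux={"R1": 1.0},
        )
        with pytest.raises(DecompositionError, match="closed"):
            decompose_elementary_modes(sub)

    @pytest.mark.parametrize("fixture", ALL_TOYS)
    @pytest.mark.parametrize("direction", [PRODUCTION, CONSUMPTION])
    def test_conservation_property(self, fixture, direction, request):
        """The weighted modes reproduce the subnetwork flux exactly."""
        model, state, _ = request.getfixturevalue(fixture)
        for met in [m.id for m in model.metabolites]:
            sub = close_mass_balance(
                extract_subnetwork(model, state, met, direction, D=4)
            )
            modes = decompose_elementary_modes(sub)
            recovered = {rid: 0.0 for rid in sub.stoichiometry}
            for mode in modes:
                for rid, coeff in mode.support.items():
                    recovered[rid] += mode.weight * coeff
            for rid in sub.stoichiometry:
                assert recovered[rid] == pytest.approx(
                    abs(sub.flux[rid]), abs=1e-8
                ), (fixture, met, direction, rid)

    @pytest.mark.parametrize("fixture", ALL_TOYS)
    def test_modes_match_enumeration_oracle(self, fixture, request):
        """Every decomposition mode must be one of the exhaustively
        enumerated elementary modes of the closed subnetwork."""
        model, state, _ = request.getfixturevalue(fixture)
        from metpath.model import Metabolite, ModelNetwork, Reaction
        from metpath.toys import enumerate_efms

        for met in [m.id for m in model.metabolites][:3]:
            sub = close_mass_balance(
                extract_subnetwork(model, state, met, PRODUCTION, D=4)
            )
            modes = decompose_elementary_modes(sub)
            if not modes:
                continue
            # oracle on the direction-split closed subnetwork
            mets = [Metabolite(m) for m in sub.metabolite_ids]
            rxns = []
            for rid in sub.reaction_ids:
                sign = 1.0 if sub.flux[rid] >= 0 else -1.0
                rxns.append(
                    Reaction(
                        rid,
                        {k: sign * v
                         for k, v in sub.stoichiometry[rid].items()},
                        0.0, 1000.0,
                    )
                )
            closed_model = ModelNetwork(
                id="sub", metabolites=mets, reactions=rxns
            )
            oracle = enumerate_efms(closed_model)
            for mode in modes:
                assert is_subset_of_oracle(mode.support, oracle), (
                    fixture, met, mode.support,
                )


class TestAssembly:
    def test_chain_production_weights(self, chain):
        model, state, _ = chain
        pw = extract_pathway(model, state, "B_c", PRODUCTION, D=2)
        assert pw.reaction_weights == pytest.approx(
            {"EX_A": 0.5, "R1": 0.5}, abs=1e-9
        )

    def test_boundary_reactions_dropped(self, diamond):
        model, state, _ = diamond
        pw = extract_pathway(model, state, "B_c", PRODUCTION, D=2)
        assert not any(r.startswith("BD_") for r in pw.reaction_weights)

    @pytest.mark.parametrize("fixture", ALL_TOYS)
    @pytest.mark.parametrize("direction", [PRODUCTION, CONSUMPTION])
    def test_weights_normalized(self, fixture, direction, request):
        model, state, _ = request.getfixturevalue(fixture)
        for met in [m.id for m in model.metabolites]:
            pw = extract_pathway(model, state, met, direction, D=3)
            if not pw.is_empty:
                assert sum(pw.reaction_weights.values()) == pytest.approx(
                    1.0, abs=1e-9
                )
                assert all(w >= 0 for w in pw.reaction_weights.values())

    def test_empty_pathway_for_inactive_metabolite(self, branch):
        model, state, _ = branch
        pw = extract_pathway(model, state, "B_c", PRODUCTION, D=3)
        assert pw.is_empty

    def test_direction_coherence(self, cycle):
        """Production-pathway reactions must lie upstream of the target
        in the flux-oriented graph (within D)."""
        model, state, _ = cycle
        pw = extract_pathway(model, state, "B_c", PRODUCTION, D=3)
        sub = extract_subnetwork(model, state, "B_c", PRODUCTION, D=3)
        assert set(pw.reaction_weights) <= set(sub.stoichiometry)

    def test_gene_sets_follow_reactions(self, chain):
        model, state, _ = chain
        pw = extract_pathway(model, state, "B_c", PRODUCTION, D=2)
        assert pw.gene_ids(model) == {"g_EX_A", "g_R1"}


def test_gmt_export_lists_pathway_genes(tmp_path, chain):
    from metpath import export

    model, state, _ = chain
    pw = extract_pathway(model, state, "B_c", PRODUCTION, D=2)
    out = tmp_path / "sets.gmt"
    export.pathways_to_gmt([pw], model, out)
    name, desc, *genes = out.read_text().strip().split("\t")
    assert name == "B_c__production"
    assert set(genes) == {"g_EX_A", "g_R1"}
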