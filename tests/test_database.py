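"""Multi-condition pathway database: MCC merging, presets, consensus."""

import math
import random

import numpy as np
import pytest

from metpath import (
    CONSUMPTION,
    ConditionSpec,
    ExpressionTable,
    MetabolitePathway,
    PRODUCTION,
    build_database,
    builtin_conditions,
    consensus_score,
    merge_database,
    pathway_mcc,
)
from metpath.database import PathwayDatabase, standard_condition
from metpath.errors import MetPathError


def pw(weights, metabolite="A_c", direction=PRODUCTION, condition="c1"):
    return MetabolitePathway(
        metabolite_id=metabolite, direction=direction,
        condition_name=condition, reaction_weights=weights, distance=3,
    )


class TestMCC:
    UNIVERSE = [f"r{i}" for i in range(10)]

    def test_identical_sets(self):
        a = pw({"r0": 0.5, "r1": 0.5})
        b = pw({"r0": 0.9, "r1": 0.1}, condition="c2")
        assert pathway_mcc(a, b, self.UNIVERSE) == 1.0

    def test_disjoint_sets(self):
        """Disjoint size-3 sets in a universe of 10: TP=0, FP=FN=3,
        TN=4, so MCC = -9/sqrt(3*3*7*7) = -3/7."""
        a = pw({f"r{i}": 1 / 3 for i in (0, 1, 2)})
        b = pw({f"r{i}": 1 / 3 for i in (3, 4, 5)}, condition="c2")
        assert pathway_mcc(a, b, self.UNIVERSE) == pytest.approx(
            -3 / 7, abs=1e-12
        )

    def test_subset_matches_confusion_matrix_formula(self):
        a = pw({"r0": 0.5, "r1": 0.5})
        b = pw({f"r{i}": 0.25 for i in range(4)}, condition="c2")
        tp, fp, fn, tn = 2, 2, 0, 6
        expected = (tp * tn - fp * fn) / math.sqrt(
            (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        )
        assert pathway_mcc(a, b, self.UNIVERSE) == pytest.approx(
            expected, abs=1e-12
        )

    def test_empty_pathway_gives_zero(self):
        a = pw({})
        b = pw({"r0": 1.0}, condition="c2")
        assert pathway_mcc(a, b, self.UNIVERSE) == 0.0

    def test_mismatched_metabolites_rejected(self):
        a = pw({"r0": 1.0})
        b = pw({"r0": 1.0}, metabolite="B_c")
        with pytest.raises(ValueError):
            pathway_mcc(a, b, self.UNIVERSE)


class TestMerging:
    def test_identical_pathways_merge_with_provenance(self):
        db = merge_database(
            [pw({"r0": 0.5, "r1": 0.5}, condition="c1"),
             pw({"r0": 0.4, "r1": 0.6}, condition="c2")],
            threshold=0.9,
        )
        assert len(db.entries) == 1
        assert db.entries[0].provenance == ["c1", "c2"]
        merged = db.entries[0].pathway.reaction_weights
        assert merged["r0"] == pytest.approx(0.45)
        assert merged["r1"] == pytest.approx(0.55)

    def test_dissimilar_pathways_kept_separate(self):
        db = merge_database(
            [pw({"r0": 0.5, "r1": 0.5}, condition="aerobic"),
             pw({"r7": 0.5, "r8": 0.5}, condition="anaerobic")],
            threshold=0.9,
            universe=set(TestMCC.UNIVERSE),
        )
        assert len(db.entries) == 2

    def test_threshold_one_is_strict(self):
        """MCC of identical supports is exactly 1.0, which is not > 1.0:
        with threshold 1.0 nothing merges."""
        db = merge_database(
            [pw({"r0": 0.5, "r1": 0.5}, condition="c1"),
             pw({"r0": 0.9, "r1": 0.1}, condition="c2")],
            threshold=1.0,
        )
        assert len(db.entries) == 2

    def test_order_independent(self):
        pathways = [
            pw({"r0": 0.5, "r1": 0.5}, condition="c1"),
            pw({"r0": 0.45, "r1": 0.55}, condition="c2"),
            pw({"r7": 1.0}, condition="c3"),
            pw({"r2": 0.2, "r3": 0.8}, metabolite="B_c", condition="c1"),
        ]
        reference = merge_database(
            pathways, threshold=0.9, universe=set(TestMCC.UNIVERSE)
        ).to_dict()
        rng = random.Random(13)
        for _ in range(5):
            shuffled = pathways[:]
            rng.shuffle(shuffled)
            db = merge_database(
                shuffled, threshold=0.9, universe=set(TestMCC.UNIVERSE)
            )
            assert db.to_dict() == reference

    def test_threshold_validated(self):
        with pytest.raises(ValueError):
            merge_database([], threshold=0.0)


class TestBuiltinConditions:
    def test_panel_has_64_conditions(self):
        conditions = builtin_conditions("iJO1366")
        assert len(conditions) == 64
        assert len({c.name for c in conditions}) == 64

    def test_amino_acid_uptake_bound(self):
        conditions = {c.name: c for c in builtin_conditions("iJO1366")}
        trp = conditions["trp_supplement_aerobic"]
        assert trp.exchange_bounds["EX_trp__L_e"][0] == -0.5

    def test_carbon_sources_include_glycolate(self):
        names = {c.name for c in builtin_conditions("iJO1366")}
        assert "glycolate_normoxia" in names
        assert "glycolate_anoxia" in names

    def test_anoxia_opens_nitrate(self):
        conditions = {c.name: c for c in builtin_conditions("iJO1366")}
        assert conditions["acetate_anoxia"].exchange_bounds[
            "EX_no3_e"
        ][0] == -10.0
        assert conditions["acetate_anoxia"].exchange_bounds[
            "EX_o2_e"
        ][0] == 0.0

    def test_every_preset_maximizes_atp_after_growth(self):
        for cond in builtin_conditions("iJO1366"):
            assert cond.objective_reaction == "ATPM"
            assert cond.growth_constraint.value == "max"

    def test_unknown_tag_lists_available(self):
        with pytest.raises(MetPathError, match="iJO1366"):
            builtin_conditions("iBurrito")
        with pytest.raises(MetPathError, match="iJO1366"):
            standard_condition("iBurrito")


class TestBuildDatabase:
    def conditions(self):
        # branch toy: closing one sink forces flux down the other branch
        return [
            ConditionSpec(
                name="via_B",
                exchange_bounds={"EX_A": (-0.5, 0.0),
                                 "EX_C": (0.0, 0.0)},
                objective_reaction="EX_B",
            ),
            ConditionSpec(
                name="via_C",
                exchange_bounds={"EX_B": (0.0, 0.0)},
                objective_reaction="EX_C",
            ),
        ]

    def test_condition_specific_variants_kept_separate(self, branch):
        model, _, _ = branch
        db = build_database(
            model, self.conditions(), metabolites=["A_c"], D=2
        )
        cons = db.variants("A_c", CONSUMPTION)
        assert len(cons) == 2  # R1-route and R2-route do not merge
        supports = {frozenset(e.pathway.reaction_weights) for e in cons}
        assert supports == {frozenset({"R1", "EX_B"}),
                            frozenset({"R2", "EX_C"})}

    def test_serialization_round_trip(self, branch, tmp_path):
        model, _, _ = branch
        db = build_database(
            model, self.conditions(), metabolites=["A_c"], D=2
        )
        path = tmp_path / "db.json"
        db.save(path)
        again = PathwayDatabase.load(path)
        assert again.to_dict() == db.to_dict()

    def test_build_is_deterministic(self, branch, tmp_path):
        model, _, _ = branch
        a = build_database(model, self.conditions(), metabolites=["A_c"])
        b = build_database(model, self.conditions(), metabolites=["A_c"])
        pa, pb = tmp_path / "a.json", tmp_path / "b.json"
        a.save(pa)
        b.save(pb)
        assert pa.read_bytes() == pb.read_bytes()


class TestConsensus:
    def database(self):
        entries = [
            pw({"r1": 1.0}, condition="c1"),
            pw({"r2": 1.0}, condition="c2"),
        ]
        return merge_database(entries, threshold=0.9,
                              universe={"r1", "r2", "r3"})

    def test_two_variants_mean_and_argmax(self):
        from test_scoring import scoring_model  # reuse builder

        db = self.database()
        model = scoring_model({"r1": ["g1"], "r2": ["g2"]})
        expr = ExpressionTable({"g1": 1.2, "g2": 1.8})
        table = consensus_score(db, expr, model)
        row = table[
            (table.metabolite == "A_c")
            & (table.direction == PRODUCTION)
        ].iloc[0]
        assert row.consensus_score == pytest.approx(1.5)
        assert row.best_variant_score == pytest.approx(1.8)
        assert row.reactions == "r2"

    def test_single_variant_equals_its_score(self):
        from test_scoring import scoring_model

        db = merge_database([pw({"r1": 1.0}, condition="c1")])
        model = scoring_model({"r1": ["g1"]})
        table = consensus_score(db, ExpressionTable({"g1": 2.0}), model)
        assert table.iloc[0].consensus_score == pytest.approx(2.0)

    def test_neutral_expression_gives_unit_consensus(self):
        from test_scoring import scoring_model

        db = self.database()
        model = scoring_model({"r1": ["g1"], "r2": ["g2"]})
        table = consensus_score(
            db, ExpressionTable({"g1": 1.0, "g2": 1.0}), model
        )
        assert (table.consensus_score == 1.0).all()
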