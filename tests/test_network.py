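"""Model data structures, GPR parsing, JSON/SBML I/O and curation."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pyriflux.network import (
    GprAnd,
    GprGene,
    GprOr,
    MetabolicModel,
    Metabolite,
    ModelFormatError,
    ModelValidationError,
    Reaction,
    add_sink_reaction,
    find_dead_end_metabolites,
    load_model,
    parse_gpr,
    prune_dead_ends,
    stoichiometric_matrix,
    write_model,
)


class TestGpr:
    @pytest.mark.parametrize(
        "text,genes",
        [
            ("g1", {"g1"}),
            ("g1 and g2", {"g1", "g2"}),
            ("g1 AND g2 or g3", {"g1", "g2", "g3"}),
            ("(g1 or g2) and (g3 or g4)", {"g1", "g2", "g3", "g4"}),
        ],
    )
    def test_parse_collects_genes(self, text, genes):
        assert parse_gpr(text).genes() == genes

    def test_and_binds_tighter_than_or(self):
        rule = parse_gpr("g1 and g2 or g3")
        assert isinstance(rule, GprOr)
        assert isinstance(rule.children[0], GprAnd)

    def test_empty_rule_is_none(self):
        assert parse_gpr("") is None
        assert parse_gpr("   ") is None

    @pytest.mark.parametrize("bad", ["(g1", "g1 and", "and g1", "g1 or or g2", "()"])
    def test_malformed_rules_raise(self, bad):
        with pytest.raises(ModelFormatError):
            parse_gpr(bad)

    def test_roundtrip_through_string(self):
        rule = parse_gpr("(g1 and g2) or g3")
        assert parse_gpr(rule.to_string()) == rule

    def test_boolean_semantics(self):
        rule = parse_gpr("(g1 and g2) or g3")
        assert rule.evaluate_bool(lambda g: g != "g1")  # g3 rescues
        assert not rule.evaluate_bool(lambda g: g in ("g1",))  # only g1 on


class TestInvariants:
    def test_reaction_rejects_bad_bounds(self):
        with pytest.raises(ModelValidationError):
            Reaction("r", {"m": 1}, lb=1, ub=0)

    def test_reaction_rejects_empty_or_zero_stoichiometry(self):
        with pytest.raises(ModelValidationError):
            Reaction("r", {})
        with pytest.raises(ModelValidationError):
            Reaction("r", {"m": 0.0})

    def test_model_rejects_unknown_metabolite(self):
        with pytest.raises(ModelValidationError):
            MetabolicModel([Metabolite("A")], [Reaction("r", {"B": 1})], "r")

    def test_model_rejects_missing_objective(self):
        with pytest.raises(ModelValidationError):
            MetabolicModel([Metabolite("A")], [Reaction("r", {"A": 1})], "nope")


class TestJsonIO:
    def test_three_reaction_toy_roundtrip(self, tmp_path, chain_model):
        path = tmp_path / "m.json"
        write_model(chain_model, path)
        back = load_model(path)
        assert back.reaction_ids == chain_model.reaction_ids
        assert back.metabolite_ids == chain_model.metabolite_ids
        assert back.objective_reaction_id == "r3"
        for a, b in zip(back.reactions, chain_model.reactions):
            assert (a.lb, a.ub) == (b.lb, b.ub)
            assert a.stoichiometry == b.stoichiometry

    def test_gpr_and_sink_flags_survive_roundtrip(self, tmp_path):
        model = MetabolicModel(
            [Metabolite("A")],
            [
                Reaction("r", {"A": 1}, 0, 5, gpr=parse_gpr("(g1 and g2) or g3")),
                Reaction("sink_A", {"A": -1}, -1000, 1000, is_sink=True),
            ],
            "r",
        )
        path = tmp_path / "m.json"
        write_model(model, path)
        back = load_model(path)
        assert back.reaction("r").gpr == model.reaction("r").gpr
        assert back.reaction("sink_A").is_sink
        assert back.genes == {"g1", "g2", "g3"}

    def test_missing_stoichiometry_is_format_error(self, tmp_path):
        payload = {
            "metabolites": [{"id": "A"}],
            "reactions": [{"id": "r", "lower_bound": 0, "upper_bound": 1,
                           "objective_coefficient": 1}],
            "genes": [],
        }
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(payload))
        with pytest.raises(ModelFormatError, match="r"):
            load_model(path)

    def test_undeclared_gpr_gene_is_validation_error(self, tmp_path):
        payload = {
            "metabolites": [{"id": "A"}],
            "reactions": [{"id": "r", "metabolites": {"A": 1}, "upper_bound": 1,
                           "gene_reaction_rule": "gX", "objective_coefficient": 1}],
            "genes": [{"id": "gY"}],
        }
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(payload))
        with pytest.raises(ModelValidationError, match="gX"):
            load_model(path)


class TestSbmlIO:
    def test_read_sbml_fbc_via_cobra_export(self, tmp_path, diamond_model):
        """Write SBML with cobra, read with our parser, compare field-by-field."""
        cobra = pytest.importorskip("cobra")
        cm = cobra.Model("d")
        mets = {m.id: cobra.Metabolite(m.id, compartment="c")
                for m in diamond_model.metabolites}
        for r in diamond_model.reactions:
            cr = cobra.Reaction(r.id)
            cm.add_reactions([cr])
            cr.add_metabolites({mets[k]: v for k, v in r.stoichiometry.items()})
            cr.bounds = (r.lb, r.ub)
        cm.objective = "ex"
        path = tmp_path / "d.xml"
        cobra.io.write_sbml_model(cm, str(path))
        back = load_model(path, dialect="sbml-fbc")
        assert set(back.reaction_ids) == set(diamond_model.reaction_ids)
        assert back.objective_reaction_id == "ex"
        for r in diamond_model.reactions:
            br = back.reaction(r.id)
            assert (br.lb, br.ub) == (r.lb, r.ub)
            assert br.stoichiometry == r.stoichiometry


class TestStoichiometricMatrix:
    def test_chain_columns_balance(self, chain_model):
        S = stoichiometric_matrix(chain_model)
        assert S.shape == (2, 3)
        # internal conversion column has one -1 and one +1
        col = S[:, 1]
        assert sorted(col) == [-1, 1]
        # exchange columns have exactly one nonzero
        assert np.count_nonzero(S[:, 0]) == 1
        assert np.count_nonzero(S[:, 2]) == 1


class TestDeadEnds:
    def test_balanced_chain_has_none(self, chain_model):
        assert find_dead_end_metabolites(chain_model) == set()

    def test_unconsumed_terminal_is_dead(self):
        m = MetabolicModel(
            [Metabolite("A"), Metabolite("B"), Metabolite("C")],
            [Reaction("r1", {"A": 1}, 0, 10), Reaction("r2", {"A": -1, "B": 1}, 0, 10),
             Reaction("r3", {"B": -1, "C": 1}, 0, 10)],
            "r3",
        )
        assert find_dead_end_metabolites(m) == {"C"}
        with_sink = add_sink_reaction(m, "C")
        assert find_dead_end_metabolites(with_sink) == set()

    def test_reversible_reaction_counts_both_ways(self):
        m = MetabolicModel(
            [Metabolite("A"), Metabolite("B")],
            [Reaction("r1", {"A": 1}, 0, 10), Reaction("r2", {"A": -1, "B": 1}, -10, 10),
             Reaction("r3", {"B": -1}, 0, 10)],
            "r3",
        )
        assert find_dead_end_metabolites(m) == set()


class TestPrune:
    def test_clean_model_unchanged(self, chain_model):
        pruned, log = prune_dead_ends(chain_model)
        assert log == []
        assert pruned.reaction_ids == chain_model.reaction_ids

    def test_cascade_removal(self):
        # keep -> (objective path); B unconsumed, its removal orphans A
        m = MetabolicModel(
            [Metabolite("X"), Metabolite("A"), Metabolite("B")],
            [
                Reaction("src", {"X": 1}, 0, 10),
                Reaction("obj", {"X": -1}, 0, 10),
                Reaction("xa", {"X": -1, "A": 1}, 0, 10),
                Reaction("ab", {"A": -1, "B": 1}, 0, 10),
            ],
            "obj",
        )
        pruned, log = prune_dead_ends(m)
        assert set(pruned.reaction_ids) == {"src", "obj"}
        assert set(pruned.metabolite_ids) == {"X"}
        # B removed first, cascading to A
        assert log.index("B") < log.index("A")

    def test_idempotent(self, chain_model):
        once, _ = prune_dead_ends(chain_model)
        twice, log = prune_dead_ends(once)
        assert log == []
        assert twice.reaction_ids == once.reaction_ids

    def test_declaration_order_invariance(self):
        mets = [Metabolite("X"), Metabolite("A"), Metabolite("B")]
        rxns = [
            Reaction("src", {"X": 1}, 0, 10),
            Reaction("obj", {"X": -1}, 0, 10),
            Reaction("xa", {"X": -1, "A": 1}, 0, 10),
            Reaction("ab", {"A": -1, "B": 1}, 0, 10),
        ]
        a, _ = prune_dead_ends(MetabolicModel(mets, rxns, "obj"))
        b, _ = prune_dead_ends(MetabolicModel(mets[::-1], rxns, "obj"))
        assert set(a.reaction_ids) == set(b.reaction_ids)
        assert set(a.metabolite_ids) == set(b.metabolite_ids)

    def test_objective_removal_is_error(self):
        m = MetabolicModel(
            [Metabolite("A"), Metabolite("B")],
            [Reaction("r1", {"A": 1}, 0, 10), Reaction("obj", {"A": -1, "B": 1}, 0, 10)],
            "obj",
        )
        with pytest.raises(ModelValidationError, match="objective"):
            prune_dead_ends(m)


class TestSinks:
    def test_sink_shape_and_default_reversibility(self, chain_model):
        m = add_sink_reaction(chain_model, "A")
        sink = m.reaction("sink_A")
        assert sink.stoichiometry == {"A": -1.0}
        assert sink.is_sink and sink.lb < 0 < sink.ub

    def test_duplicate_sink_rejected(self, chain_model):
        m = add_sink_reaction(chain_model, "A")
        with pytest.raises(ModelValidationError, match="duplicate"):
            add_sink_reaction(m, "A")

    def test_unknown_metabolite_rejected(self, chain_model):
        with pytest.raises(ModelValidationError, match="unknown"):
            add_sink_reaction(chain_model, "Z")


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_prune_idempotence_on_random_models(seed):
    from pyriflux.simulate import random_feasible_model

    model = random_feasible_model(n_reactions=6, seed=seed)
    try:
        once, _ = prune_dead_ends(model)
    except ModelValidationError:
        return  # objective itself dead-ended; nothing to check
    twice, log = prune_dead_ends(once)
    assert log == []
    assert twice.reaction_ids == once.reaction_ids
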