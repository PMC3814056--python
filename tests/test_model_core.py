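"""Model data structures, GPR evaluation, knockouts, and SBML/JSON I/O."""

import itertools

import numpy as np
import pytest

from tisnet.model_core import (
    GprRule,
    Metabolite,
    MetabolicModel,
    ModelError,
    Reaction,
    apply_knockout,
    evaluate_gpr,
    metabolites_table,
    model_from_dict,
    model_to_dict,
    reactions_table,
    read_sbml,
    toy9,
    write_sbml,
)


class TestGpr:
    @pytest.mark.parametrize(
        "rule, inactive, expected",
        [
            ("g2 or g3", {"g2"}, True),
            ("g4 and g5", {"g4"}, False),
            ("(g1 and g2) or g3", {"g1", "g3"}, False),
            ("(g1 and g2) or g3", {"g1"}, True),
            ("", {"g1"}, True),
            ("G1 AND g2", {"g2"}, False),  # case-insensitive operators
        ],
    )
    def test_examples(self, rule, inactive, expected):
        assert evaluate_gpr(rule, inactive) is expected

    @pytest.mark.parametrize("bad", ["g1 and", "and g1", "(g1 or g2", "g1 g2", "()"])
    def test_malformed(self, bad):
        with pytest.raises(ModelError):
            GprRule(bad)

    def test_genes_and_rendering(self):
        rule = GprRule("(g1 and g2) or g3")
        assert rule.genes == {"g1", "g2", "g3"}
        assert GprRule(rule.to_string()).tree == rule.tree

    def test_agrees_with_python_boolean_oracle(self):
        """Random rules over <= 6 genes match brute-force evaluation on every
        knockout subset (the oracle is Python's own and/or semantics)."""
        genes = [f"g{i}" for i in range(1, 7)]
        rng = np.random.default_rng(7)

        def random_expr(depth):
            if depth == 0 or rng.random() < 0.4:
                return genes[rng.integers(len(genes))]
            op = "and" if rng.random() < 0.5 else "or"
            return f"({random_expr(depth - 1)} {op} {random_expr(depth - 1)})"

        for _ in range(25):
            text = random_expr(3)
            rule = GprRule(text)
            for r in range(len(genes) + 1):
                for inactive in itertools.combinations(genes, r):
                    env = {g: g not in inactive for g in genes}
                    assert rule.evaluate(inactive) == eval(text, {}, env)


class TestKnockout:
    def test_or_redundancy_keeps_reaction(self, toy):
        ko = apply_knockout(toy, {"g2"})
        assert model_to_dict(ko) == model_to_dict(toy)

    def test_or_pair_disables(self, toy):
        ko = apply_knockout(toy, {"g2", "g3"})
        assert (ko.reaction("R2").lower_bound, ko.reaction("R2").upper_bound) == (0.0, 0.0)
        for rid in ("EX_A", "R1", "R3", "BIOMASS", "EX_D", "R5", "EX_E"):
            assert ko.reaction(rid).upper_bound == toy.reaction(rid).upper_bound

    def test_and_rule_disables(self, toy):
        ko = apply_knockout(toy, {"g4"})
        assert ko.reaction("R3").upper_bound == 0.0

    def test_empty_set_is_identity_and_monotone(self, toy):
        assert model_to_dict(apply_knockout(toy, set())) == model_to_dict(toy)

        def disabled(genes):
            ko = apply_knockout(toy, genes)
            return {r.id for r in ko.reactions if r.upper_bound == 0.0 == r.lower_bound}

        rng = np.random.default_rng(0)
        genes = sorted(toy.genes)
        for _ in range(20):
            g = set(rng.choice(genes, size=2, replace=False))
            h = g | set(rng.choice(genes, size=2, replace=False))
            assert disabled(g) <= disabled(h)

    def test_unknown_genes_ignored(self, toy, caplog):
        ko = apply_knockout(toy, {"nonexistent"})
        assert model_to_dict(ko) == model_to_dict(toy)


class TestSbml:
    def test_packaged_fixture_contents(self):
        from importlib import resources

        path = resources.files("tisnet") / "data" / "toy9.xml"
        model = read_sbml(str(path))
        assert len(model.reactions) == 8
        assert len(model.metabolites) == 5
        assert len(model.genes) == 6
        assert model.objective_reaction_id == "BIOMASS"
        assert model == toy9()

    def test_round_trip(self, toy, tmp_path):
        path = tmp_path / "m.xml"
        write_sbml(toy, path)
        again = read_sbml(path)
        assert again == toy
        write_sbml(again, tmp_path / "m2.xml")
        assert read_sbml(tmp_path / "m2.xml") == toy

    def test_bounds_gpr_preserved_exactly(self, toy, tmp_path):
        toy.reaction("R2").lower_bound = -3.25
        write_sbml(toy, tmp_path / "m.xml")
        again = read_sbml(tmp_path / "m.xml")
        assert again.reaction("R2").lower_bound == -3.25
        assert again.reaction("R2").gpr.to_string() == "g2 or g3"
        assert again.reaction("BIOMASS").gpr.is_empty

    def test_truncated_file_errors_with_name(self, toy, tmp_path):
        path = tmp_path / "broken.xml"
        write_sbml(toy, path)
        path.write_text(path.read_text()[:200])
        with pytest.raises(ModelError, match="broken.xml"):
            read_sbml(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_sbml(tmp_path / "nope.xml")

    def test_no_objective_errors(self, toy, tmp_path):
        path = tmp_path / "m.xml"
        write_sbml(toy, path)
        text = path.read_text()
        start = text.index("<fbc:listOfObjectives")
        end = text.index("</fbc:listOfObjectives>") + len("</fbc:listOfObjectives>")
        path.write_text(text[:start] + text[end:])
        with pytest.raises(ModelError, match="objective"):
            read_sbml(path)

    def test_refuses_empty_model(self, tmp_path):
        model = MetabolicModel([Metabolite("A")], [], "x")
        with pytest.raises(ModelError):
            write_sbml(model, tmp_path / "m.xml")


class TestJsonAndTables:
    def test_json_round_trip(self, toy):
        assert model_from_dict(model_to_dict(toy)) == toy

    def test_tables(self, toy):
        rt = reactions_table(toy)
        assert set(rt["reaction"]) == set(toy.reaction_ids)
        assert rt.loc[rt["reaction"] == "EX_A", "is_exchange"].item()
        assert not rt.loc[rt["reaction"] == "R1", "is_exchange"].item()
        assert len(metabolites_table(toy)) == 5


class TestValidation:
    def test_duplicate_reaction_ids(self):
        r = Reaction("R", {"A": -1.0})
        model = MetabolicModel([Metabolite("A")], [r, Reaction("R", {"A": 1.0})], "R")
        with pytest.raises(ModelError, match="duplicate"):
            model.validate()

    def test_unknown_metabolite(self):
        model = MetabolicModel([Metabolite("A")], [Reaction("R", {"B": -1.0})], "R")
        with pytest.raises(ModelError, match="unknown metabolite"):
            model.validate()

    def test_bad_bounds_and_missing_objective(self):
        model = MetabolicModel(
            [Metabolite("A")], [Reaction("R", {"A": -1.0}, 5.0, 1.0)], "R"
        )
        with pytest.raises(ModelError, match="lower_bound"):
            model.validate()
        model2 = MetabolicModel([Metabolite("A")], [Reaction("R", {"A": -1.0})], "Q")
        with pytest.raises(ModelError, match="objective"):
            model2.validate()

    def test_restrict_drops_orphans(self, toy):
        sub = toy.restrict(["EX_A", "R1", "R2", "BIOMASS"])
        assert set(sub.metabolite_ids) == {"A", "B", "C"}
        with pytest.raises(ModelError):
            toy.restrict(["EX_A", "R1"])  # objective removed
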