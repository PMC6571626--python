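"""Reaction-system data model, dialect, and reference simulator."""

import itertools

import pytest

import rescirc as rc
from rescirc.rs_core import ParseError, RSError


class TestReactionModel:
    def test_reactant_inhibitor_overlap_rejected(self):
        with pytest.raises(RSError, match="overlap"):
            rc.Reaction(["a", "b"], ["b"], ["c"])

    @pytest.mark.parametrize("r, i, p", [([], ["i"], ["p"]),
                                         (["r"], ["i"], [])])
    def test_empty_reactants_or_products_rejected(self, r, i, p):
        with pytest.raises(RSError, match="nonempty"):
            rc.Reaction(r, i, p)

    def test_empty_inhibitor_set_permitted_internally(self):
        r = rc.Reaction(["a"], [], ["b"])
        assert r.inhibitors == frozenset()

    def test_background_must_cover_reaction_species(self):
        with pytest.raises(RSError, match="outside background"):
            rc.ReactionSystem(["a", "b"], [rc.Reaction(["a"], [], ["c"])])

    def test_system_with_no_reactions_is_valid(self):
        system = rc.ReactionSystem(["a"], [])
        assert system.produced() == frozenset()
        assert rc.result(system, {"a"}) == frozenset()


class TestParser:
    def test_vimentin_dialect(self):
        text = "T , d , O\nO , d , H\nH , d , F\nF , d , F\n"
        system, contexts = rc.parse_rs(text)
        assert len(system.background) == 5
        assert len(system.reactions) == 4
        assert contexts is None

    def test_directives_and_contexts(self):
        text = ("#input: T\n#output: F\n"
                "T , d , O\nO , d , F\nF , d , F\n"
                "#context[0]: T\n#context[2]: T\n")
        system, contexts = rc.parse_rs(text)
        assert system.declared_inputs == {"T"}
        assert system.declared_outputs == {"F"}
        # missing index 1 defaults to the empty context
        assert contexts.contexts == (frozenset("T"), frozenset(),
                                     frozenset("T"))

    def test_reactant_inhibitor_overlap_is_a_parse_error(self):
        with pytest.raises(ParseError, match="line 1"):
            rc.parse_rs("a b , b , c\n")

    def test_context_species_outside_background_rejected(self):
        with pytest.raises(ParseError, match="not in background"):
            rc.parse_rs("a , b , c\n#context[0]: z\n")

    def test_strict_mode_rejects_empty_inhibitors(self):
        assert rc.parse_rs("a ,  , c\n")[0]
        with pytest.raises(ParseError, match="strict"):
            rc.parse_rs("a ,  , c\n", strict=True)

    def test_duplicate_reaction_warns(self):
        with pytest.warns(UserWarning, match="duplicate"):
            rc.parse_rs("a , b , c\na , b , c\n")

    @pytest.mark.parametrize("bad", ["a , b\n", "a ; b ; c\n",
                                     "#bogus: x\n", "1a , b , c\n"])
    def test_syntax_errors_carry_line_info(self, bad):
        with pytest.raises(ParseError, match="line 1"):
            rc.parse_rs(bad)

    def test_round_trip_through_dialect(self, vimentin):
        contexts = rc.ContextSequence([{"T"}, set(), set()])
        text = rc.serialize_rs(vimentin, contexts)
        system, parsed_contexts = rc.parse_rs(text)
        assert system == vimentin
        assert parsed_contexts == contexts

    def test_serialize_reinserts_dummy_inhibitor(self):
        system = rc.ReactionSystem(["a", "c", "d"],
                                   [rc.Reaction(["a"], [], ["c"])])
        text = rc.serialize_rs(system, dummy="d")
        assert "a , d , c" in text
        reparsed, _ = rc.parse_rs(text, strict=True)
        assert len(reparsed.reactions) == 1


class TestResultFunction:
    def test_vimentin_single_reaction(self, vimentin):
        assert rc.result(vimentin, {"T"}) == {"O"}

    def test_two_enabled_reactions_same_product(self, vimentin):
        # ({H},{d},{F}) and ({F},{d},{F}) both fire
        assert rc.result(vimentin, {"H", "F"}) == {"F"}

    def test_no_enabled_reaction_yields_empty(self, vimentin):
        assert rc.result(vimentin, {"d"}) == frozenset()

    def test_state_outside_background_rejected(self, vimentin):
        with pytest.raises(RSError):
            rc.result(vimentin, {"Z"})

    def test_enabling_is_exact(self):
        """Products appear iff reactants present and inhibitors absent —
        exhaustively over all states of a small system."""
        system = rc.random_rs(n_species=6, n_reactions=8, n_inputs=0,
                              max_products=2, seed=7)
        species = sorted(system.background)
        for k in range(len(species) + 1):
            for combo in itertools.combinations(species, k):
                state = frozenset(combo)
                res = rc.result(system, state)
                for r in system.reactions:
                    if r.enabled(state):
                        assert r.products <= res
                fired = frozenset().union(
                    *(r.products for r in system.reactions
                      if r.enabled(state)), frozenset())
                assert res == fired


class TestInteractiveProcess:
    def test_vimentin_assembly_trace(self, vimentin):
        trace = rc.run_process(vimentin, [{"T"}, set(), set(), set(), set()])
        assert trace.results == (frozenset(), frozenset("O"), frozenset("H"),
                                 frozenset("F"), frozenset("F"))

    def test_single_context_gives_d0_only(self, vimentin):
        trace = rc.run_process(vimentin, [set()])
        assert trace.results == (frozenset(),)

    def test_empty_context_sequence_rejected(self, vimentin):
        with pytest.raises(RSError, match="nonempty"):
            rc.run_process(vimentin, [])

    def test_context_outside_background_rejected(self, vimentin):
        with pytest.raises(RSError, match="outside background"):
            rc.run_process(vimentin, [{"Z"}])

    def test_state_accessor_is_result_union_context(self, vimentin):
        trace = rc.run_process(vimentin, [{"T"}, {"T"}, set()])
        for i in range(len(trace)):
            assert trace.state(i) == trace.results[i] | trace.contexts[i]

    @pytest.mark.parametrize("seed", range(10))
    def test_non_permanency(self, seed):
        """D0 = ∅ and every Di lies inside the union of all products."""
        system = rc.random_rs(n_species=7, n_reactions=9, n_inputs=2,
                              max_products=2, seed=seed)
        io = rc.infer_io(system)
        import random
        rng = random.Random(seed)
        gamma = [frozenset(s for s in io.inputs if rng.random() < 0.5)
                 for _ in range(6)]
        trace = rc.run_process(system, gamma)
        assert trace.results[0] == frozenset()
        for d in trace.results:
            assert d <= system.produced()

    def test_result_is_order_independent(self):
        """Same state → same result regardless of reaction iteration
        order (result is a pure union over enabled reactions)."""
        reactions = [rc.Reaction(["a"], ["b"], ["c"]),
                     rc.Reaction(["a"], [], ["b", "d"]),
                     rc.Reaction(["c"], ["d"], ["a"])]
        s1 = rc.ReactionSystem("abcd", reactions)
        s2 = rc.ReactionSystem("abcd", list(reversed(reactions)))
        for k in range(5):
            for combo in itertools.combinations("abcd", k):
                assert rc.result(s1, combo) == rc.result(s2, combo)
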