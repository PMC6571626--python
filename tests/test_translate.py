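"""Both translations: reaction system → circuit and circuit → RS."""

import itertools
import random
import warnings

import pytest

import rescirc as rc
from rescirc.translate import TranslationError

from conftest import DETECTOR_REACTIONS


def random_context_run(system, circuit, gamma):
    """Run the RS and its circuit side by side; compare δ with the state
    trajectory's characteristic vectors."""
    trace = rc.run_process(system, gamma)
    xs = rc.contexts_to_inputs(circuit, list(gamma)[:-1])
    states, _ = rc.simulate(circuit, xs)
    for t in range(1, len(gamma)):
        expected = tuple(1 if s in trace.results[t] else 0
                         for s in circuit.states)
        assert states[t - 1] == expected, f"step {t}"


class TestInferIo:
    def test_binary_counter_roles(self):
        io = rc.infer_io(rc.binary_counter(4))
        assert io.inputs == {"e0"}
        assert io.outputs == {"e1", "e2", "e3", "e4"}
        assert io.dummies == frozenset()

    def test_vimentin_roles(self, vimentin):
        io = rc.infer_io(vimentin)
        assert io.inputs == {"T"}
        assert io.outputs == {"O", "H", "F"}
        assert io.dummies == {"d"}

    def test_roles_inferred_without_annotations(self):
        system, _ = rc.parse_rs("T , d , O\nO , d , F\nF , d , F\n")
        io = rc.infer_io(system)
        assert io.inputs == {"T"}
        assert io.dummies == {"d"}
        assert io.outputs == {"O", "F"}

    def test_fully_produced_system_has_no_inputs(self):
        system = rc.ReactionSystem(
            "ab", [rc.Reaction("a", "", "b"), rc.Reaction("b", "", "a")])
        io = rc.infer_io(system)
        assert io.inputs == frozenset()


class TestSplitIo:
    def test_identity_when_no_overlap(self, vimentin):
        assert rc.split_io(vimentin) is vimentin

    def test_single_overlapping_species(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            system = rc.ReactionSystem(
                "xd", [rc.Reaction("x", "d", "x")], declared_inputs="x")
        split = rc.split_io(system)
        assert split.reactions == {rc.Reaction("x", "d", "x"),
                                   rc.Reaction(["x_in"], "d", "x")}
        assert split.declared_inputs == {"x_in"}

    def test_combination_count_per_occurrence(self):
        """Each reactant occurrence of an overlapping species doubles the
        reaction; inhibitor occurrences stay single (both names inhibit)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            system = rc.ReactionSystem(
                "xyab",
                [rc.Reaction(["x", "a"], "b", "x"),   # reactant occurrence
                 rc.Reaction("a", "x", "y")],          # inhibitor occurrence
                declared_inputs=["x", "a", "b"])
        split = rc.split_io(system)
        producing = [r for r in split.reactions if r.products == {"x"}]
        inhibited = [r for r in split.reactions if r.products == {"y"}]
        assert len(producing) == 2  # 2^(1 occurrence)
        assert len(inhibited) == 1
        assert inhibited[0].inhibitors == {"x", "x_in"}

    def test_split_preserves_behaviour(self):
        """Co-simulation: contexts renamed to x_in drive the split system
        to the exact original trace."""
        rng = random.Random(3)
        for seed in range(20):
            base = rc.random_rs(n_species=6, n_reactions=8, n_inputs=0,
                                max_products=1, seed=seed)
            produced = sorted(base.produced())
            if not produced:
                continue
            x = produced[0]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                system = rc.ReactionSystem(base.background, base.reactions,
                                           declared_inputs=[x])
            split = rc.split_io(system)
            xin = x + "_in"
            for _ in range(5):
                gamma = [frozenset([x]) if rng.random() < 0.5
                         else frozenset() for _ in range(6)]
                renamed = [frozenset(xin if s == x else s for s in c)
                           for c in gamma]
                assert rc.run_process(system, gamma).results == \
                    rc.run_process(split, renamed).results

    def test_blowup_cap(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            system = rc.ReactionSystem(
                "xyd", [rc.Reaction("x", "d", "x"),
                        rc.Reaction("x", "d", "y")],
                declared_inputs="x")
        with pytest.raises(TranslationError, match="manually"):
            rc.split_io(system, cap=2)


class TestRsToCircuit:
    def test_vimentin_equation_block(self, vimentin):
        circuit = rc.rs_to_circuit(vimentin)
        assert circuit.inputs == ("T",)
        assert set(circuit.states) == {"O", "H", "F", "d"}
        assert circuit.next_state["d"].is_zero()
        assert circuit.next_state["O"] == rc.DNF(
            [rc.Conjunction(["T"], ["d"])])
        assert circuit.next_state["H"] == rc.DNF(
            [rc.Conjunction(["O"], ["d"])])
        assert circuit.next_state["F"] == rc.DNF(
            [rc.Conjunction(["H"], ["d"]), rc.Conjunction(["F"], ["d"])])
        # outputs are identity projections of the like-named states
        for y in ("O", "H", "F"):
            assert circuit.output_fn[y] == rc.DNF([rc.Conjunction([y])])

    @pytest.mark.parametrize("n", [2, 3])
    def test_counter_equations(self, n):
        circuit = rc.rs_to_circuit(rc.binary_counter(n))
        for i in range(1, n + 1):
            expected = {rc.Conjunction([f"e{i}"], [f"e{j}"])
                        for j in range(i)}
            expected.add(rc.Conjunction([f"e{j}" for j in range(i)],
                                        [f"e{i}"]))
            assert circuit.next_state[f"e{i}"].terms == expected

    def test_single_reaction_single_term(self):
        system = rc.ReactionSystem("abc", [rc.Reaction("a", "b", "c")],
                                   declared_inputs="a")
        circuit = rc.rs_to_circuit(system)
        assert circuit.next_state["c"] == rc.DNF(
            [rc.Conjunction(["a"], ["b"])])

    def test_non_normal_form_rejected(self):
        system = rc.ReactionSystem("abcd", [rc.Reaction("a", "b", "cd")])
        with pytest.raises(TranslationError, match="normal form"):
            rc.rs_to_circuit(system)

    def test_term_count_conservation(self):
        for seed in range(10):
            system = rc.random_normal_rs(n_species=8, n_reactions=10,
                                         n_inputs=2, seed=seed)
            circuit = rc.rs_to_circuit(system)
            n_terms = sum(len(circuit.next_state[q].terms)
                          for q in circuit.states)
            # duplicate (R, I) pairs for the same product collapse into
            # one conjunction; count distinct reactions instead
            assert n_terms == len(system.reactions)


class TestCircuitToRs:
    def test_detector_reactions_match_published_list(self, detector):
        system, c0 = rc.circuit_to_rs(detector)
        expected = {rc.Reaction(r, i, p) for r, i, p in DETECTOR_REACTIONS}
        assert system.reactions == expected
        assert c0 == frozenset()
        assert system.declared_inputs == {"x"}

    def test_initial_context_from_initial_state(self):
        circuit = rc.SequentialCircuit(
            ["x"], ["a", "b"], [],
            {"a": rc.DNF([rc.Conjunction(["x"], ["b"])]),
             "b": rc.DNF([rc.Conjunction(["a"], ["x"])])},
            {}, (1, 0))
        _, c0 = rc.circuit_to_rs(circuit)
        assert c0 == {"a"}

    def test_constant_one_term_rejected(self):
        circuit = rc.SequentialCircuit(
            [], ["q"], [], {"q": rc.DNF.one()}, {})
        with pytest.raises(TranslationError, match="positive"):
            rc.circuit_to_rs(circuit)

    def test_pure_negative_term_rejected(self):
        circuit = rc.SequentialCircuit(
            ["x"], ["q"], [],
            {"q": rc.DNF([rc.Conjunction([], ["x"])])}, {})
        with pytest.raises(TranslationError, match="positive"):
            rc.circuit_to_rs(circuit)

    def test_term_count_inverted(self, detector):
        system, _ = rc.circuit_to_rs(detector)
        n_terms = sum(len(f.terms) for f in
                      list(detector.next_state.values()) +
                      list(detector.output_fn.values()))
        assert len(system.reactions) == n_terms


class TestFaithfulness:
    @pytest.mark.parametrize("seed", range(30))
    def test_rs_circuit_lockstep(self, seed):
        """The circuit state trajectory equals the characteristic vectors
        of δ for random normal-form systems and contexts."""
        rng = random.Random(seed)
        system = rc.random_normal_rs(n_species=9, n_reactions=11,
                                     n_inputs=2, seed=seed)
        io = rc.infer_io(system)
        circuit = rc.rs_to_circuit(system, io)
        for _ in range(5):
            gamma = [frozenset(s for s in io.inputs if rng.random() < 0.5)
                     for _ in range(rng.randint(2, 6))]
            random_context_run(system, circuit, gamma)

    def test_vimentin_round_trip_behavioural(self, vimentin):
        """circuit_to_rs(rs_to_circuit(vimentin)) reproduces the original
        reactions and co-simulates identically on every T-sequence ≤ 5."""
        circuit = rc.rs_to_circuit(vimentin)
        system2, c0 = rc.circuit_to_rs(circuit)
        assert system2.reactions == vimentin.reactions
        assert c0 == frozenset()
        for length in range(1, 6):
            for bits in itertools.product((0, 1), repeat=length):
                gamma = [frozenset("T") if b else frozenset() for b in bits]
                assert rc.run_process(vimentin, gamma).results == \
                    rc.run_process(system2, gamma).results

    @pytest.mark.parametrize("seed", range(15))
    def test_circuit_round_trip_modulo_delay(self, seed):
        """circuit → RS → circuit preserves state trajectories exactly and
        output trajectories with the documented one-step delay."""
        circuit = rc.random_circuit(n_inputs=1, n_states=3, n_outputs=1,
                                    seed=seed)
        system, c0 = rc.circuit_to_rs(circuit)
        circuit2 = rc.rs_to_circuit(system, rc.infer_io(system), initial=c0)
        qi = {q: circuit2.states.index(q) for q in circuit.states}
        zero = tuple(0 for _ in circuit.inputs)
        for bits in itertools.product((0, 1), repeat=5):
            xs = [(b,) for b in bits]
            st1, out1 = rc.simulate(circuit, xs)
            st2, out2 = rc.simulate(circuit2, xs + [zero])
            for t in range(len(xs)):
                embedded = tuple(st2[t][qi[q]] for q in circuit.states)
                assert embedded == st1[t]
                assert out2[t + 1] == out1[t]


class TestDnfFromFunction:
    def test_exhaustive_expansion_matches_function(self):
        fn = lambda a: (a["p"] and not a["q"]) or a["r"]
        f = rc.dnf_from_function(fn, ["p", "q", "r"])
        for bits in itertools.product((0, 1), repeat=3):
            a = dict(zip("pqr", bits))
            assert rc.eval_dnf(f, a) == (1 if fn(a) else 0)

    def test_cap(self):
        with pytest.raises(TranslationError, match="cap"):
            rc.dnf_from_function(lambda a: 0, [f"v{i}" for i in range(17)])
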