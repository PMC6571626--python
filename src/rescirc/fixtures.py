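"""Programmatic fixtures: the worked examples and seeded random systems.

The three canonical examples — an ``n``-bit binary counter reaction
system, the vimentin intermediate-filament self-assembly model, and the
``1101`` sequence-detector circuit — are built exactly from their
published descriptions and are used throughout the test suite.  Random
generators produce structurally valid (but biologically meaningless)
systems and circuits for property tests and scale checks; the same spec
and seed always yield the identical object.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Any, Optional

from .circuit import DNF, Conjunction, SequentialCircuit
from .rs_core import Reaction, ReactionSystem, RSError


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a random fixture (identical spec → identical system)."""

    name: str = "random"
    n_species: int = 8
    n_reactions: int = 12
    max_reactants: int = 3
    max_inhibitors: int = 3
    max_products: int = 1
    n_inputs: int = 2
    seed: int = 0


def binary_counter(n: int) -> ReactionSystem:
    """The ``n``-bit binary counter reaction system (``n > 1``).

    Species ``e0..en``; ``e0`` is the input (the "count" signal), ``e1..en``
    the output bits.  Reactions::

        ({ei}, {ej}, {ei})            for 0 <= j < i <= n   (carry-free hold)
        ({e0..e(i-1)}, {ei}, {ei})    for 0 <  i <= n       (ripple carry)

    giving ``n(n+1)/2 + n`` reactions.  With ``e0`` supplied in every
    context the result set after ``t`` steps encodes ``t mod 2^n`` in the
    bits ``e1..en`` (``e1`` least significant).
    """
    if n <= 1:
        raise RSError("the binary counter requires n > 1")
    species = [f"e{i}" for i in range(n + 1)]
    reactions = []
    for i in range(1, n + 1):
        for j in range(i):
            reactions.append(Reaction([f"e{i}"], [f"e{j}"], [f"e{i}"]))
        reactions.append(
            Reaction([f"e{j}" for j in range(i)], [f"e{i}"], [f"e{i}"]))
    return ReactionSystem(species, reactions,
                          declared_inputs=["e0"],
                          declared_outputs=species[1:])


def vimentin_model() -> ReactionSystem:
    """The vimentin filament self-assembly model.

    Background ``{O, H, F, d}`` plus the input ``T`` (tetramers); ``d`` is
    the dummy inhibitor.  ``T`` assembles into octamers ``O``, then
    hexadecamers ``H``, then filaments ``F``, and filaments persist once
    formed::

        ({T},{d},{O}), ({O},{d},{H}), ({H},{d},{F}), ({F},{d},{F})
    """
    reactions = [
        Reaction(["T"], ["d"], ["O"]),
        Reaction(["O"], ["d"], ["H"]),
        Reaction(["H"], ["d"], ["F"]),
        Reaction(["F"], ["d"], ["F"]),
    ]
    return ReactionSystem(["O", "H", "F", "d", "T"], reactions,
                          declared_inputs=["T"],
                          declared_outputs=["O", "H", "F"])


def sequence_detector_circuit() -> SequentialCircuit:
    """The ``1101`` sequence-detector circuit (Mealy, 2 state bits).

    State order ``(q2, q1)``, initial ``(0, 0)``; ``y`` fires on the final
    1 of an input subsequence ``1101``::

        q2' = !q2 & q1 & x | q2 & !q1
        q1' = !q2 & !q1 & x | q2 & !q1 & !x | q2 & q1 & x
        y   = q2 & q1 & x
    """
    next_state = {
        "q2": DNF([Conjunction(["q1", "x"], ["q2"]),
                   Conjunction(["q2"], ["q1"])]),
        "q1": DNF([Conjunction(["x"], ["q1", "q2"]),
                   Conjunction(["q2"], ["q1", "x"]),
                   Conjunction(["q1", "q2", "x"], [])]),
    }
    output_fn = {"y": DNF([Conjunction(["q1", "q2", "x"], [])])}
    return SequentialCircuit(["x"], ["q2", "q1"], ["y"],
                             next_state, output_fn, (0, 0))


def mealy_example_circuit() -> SequentialCircuit:
    """The classic two-state-bit Mealy example circuit::

        q1' = !q1 & !q2 | !x1 & !q2
        q2' = q1 & !q2 | x1 & q1
        y1  = !q1 & !q2

    States ordered ``(q1, q2)``, one input ``x1``, one output ``y1``.
    """
    next_state = {
        "q1": DNF([Conjunction([], ["q1", "q2"]),
                   Conjunction([], ["x1", "q2"])]),
        "q2": DNF([Conjunction(["q1"], ["q2"]),
                   Conjunction(["x1", "q1"], [])]),
    }
    output_fn = {"y1": DNF([Conjunction([], ["q1", "q2"])])}
    return SequentialCircuit(["x1"], ["q1", "q2"], ["y1"],
                             next_state, output_fn, (0, 0))


def random_rs(spec: Optional[FixtureSpec] = None, **overrides: Any,
              ) -> ReactionSystem:
    """A seeded random reaction system (structural, not biological).

    All reactions are valid: nonempty reactants and products, reactants
    disjoint from inhibitors.  The first ``n_inputs`` species are reserved
    as never-produced declared inputs.
    """
    spec = _with_overrides(spec, overrides)
    if spec.n_species < 2 or spec.n_species <= spec.n_inputs:
        raise RSError("need at least two species and more species "
                      "than inputs")
    if spec.max_reactants > spec.n_species:
        raise RSError("max_reactants exceeds species count")
    rng = random.Random(spec.seed)
    species = [f"s{i}" for i in range(spec.n_species)]
    inputs = species[:spec.n_inputs]
    internal = species[spec.n_inputs:]
    reactions = []
    for _ in range(spec.n_reactions):
        n_r = rng.randint(1, spec.max_reactants)
        reactants = rng.sample(species, n_r)
        rest = [s for s in species if s not in reactants]
        n_i = rng.randint(0, min(spec.max_inhibitors, len(rest)))
        inhibitors = rng.sample(rest, n_i)
        n_p = rng.randint(1, spec.max_products)
        products = rng.sample(internal, min(n_p, len(internal)))
        reactions.append(Reaction(reactants, inhibitors, products))
    return ReactionSystem(species, reactions, declared_inputs=inputs)


def random_normal_rs(spec: Optional[FixtureSpec] = None, **overrides: Any,
                     ) -> ReactionSystem:
    """A seeded random system already in normal form for its inputs:
    single-product reactions, products never in the input alphabet."""
    spec = _with_overrides(spec, overrides)
    if spec.max_products != 1:
        spec = _with_overrides(spec, {"max_products": 1})
    return random_rs(spec)


def random_circuit(n_inputs: int = 2, n_states: int = 3, n_outputs: int = 1,
                   max_terms: int = 3, seed: int = 0,
                   state_only_outputs: bool = False,
                   positive_terms: bool = True,
                   random_initial: bool = True) -> SequentialCircuit:
    """A seeded random DNF circuit.

    ``positive_terms`` guarantees every conjunction has at least one
    positive literal (required for translation to a reaction system);
    ``state_only_outputs`` restricts output functions to state variables
    (required for a Moore presentation).
    """
    rng = random.Random(seed)
    inputs = [f"x{i}" for i in range(n_inputs)]
    states = [f"q{i}" for i in range(n_states)]
    outputs = [f"y{i}" for i in range(n_outputs)]

    def random_dnf(variables: list[str]) -> DNF:
        terms = []
        for _ in range(rng.randint(1, max_terms)):
            size = rng.randint(1, min(3, len(variables)))
            chosen = rng.sample(variables, size)
            if positive_terms:
                n_pos = rng.randint(1, size)
            else:
                n_pos = rng.randint(0, size)
            terms.append(Conjunction(chosen[:n_pos], chosen[n_pos:]))
        return DNF(terms)

    all_vars = states + inputs
    next_state = {q: random_dnf(all_vars) for q in states}
    out_vars = states if state_only_outputs else all_vars
    output_fn = {y: random_dnf(out_vars) for y in outputs}
    initial = tuple(rng.randint(0, 1) if random_initial else 0
                    for _ in states)
    return SequentialCircuit(inputs, states, outputs,
                             next_state, output_fn, initial)


def _with_overrides(spec: Optional[FixtureSpec],
                    overrides: dict[str, Any]) -> FixtureSpec:
    base = spec if spec is not None else FixtureSpec()
    if overrides:
        from dataclasses import replace
        base = replace(base, **overrides)
    return base
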