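"""Translations between reaction systems and sequential switching circuits.

Forward direction (reaction system → circuit): each produced species ``p``
becomes a state variable whose next-state DNF has one conjunction per
reaction producing ``p`` — reactants as positive literals, inhibitors as
negative literals:

    p(t+1) = ⋁_{(R,I,{p})} ( ⋀_{r∈R} r(t) ∧ ⋀_{i∈I} ¬i(t) )

Reactants and inhibitors are disjoint, so each conjunction is well-formed
and the formula is already in DNF.  Input species become circuit inputs
(contexts map to input bit vectors, one bit per species per step); species
that are never produced and are used only as inhibitors ("dummy
inhibitors") become constant-0 state variables.  Outputs are identity
projections of the like-named state variables, so the produced output is
visible one step after the context that caused it — exactly the reaction
system's own timing.

Reverse direction (circuit → reaction system): every DNF conjunction ``c``
of a next-state or output equation for variable ``v`` becomes a reaction
``(pos(c), neg(c), {v})``; a conjunction with no negated literals receives
a designated dummy inhibitor so the inhibitor set is nonempty.  The
circuit's initial state gives the initial context ``C0``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .circuit import DNF, Conjunction, SequentialCircuit
from .normalize import fresh_name, is_normal_form, rewrite_with_aliases
from .rs_core import Reaction, ReactionSystem, RSError

logger = logging.getLogger("rescirc")

#: Refuse input/output splitting past this many resulting reactions.
SPLIT_REACTION_CAP = 100_000

#: Default name for the dummy inhibitor inserted by circuit_to_rs.
DEFAULT_DUMMY = "d"


class TranslationError(RSError):
    """A system or circuit cannot be translated as requested."""


@dataclass(frozen=True)
class IoInference:
    """Classification of species into circuit roles.

    ``inputs`` are context-supplied (never produced), ``outputs`` are the
    observable produced species, ``dummies`` are never produced and occur
    only as inhibitors — they compile to constant-0 state variables.
    """

    inputs: frozenset[str]
    outputs: frozenset[str]
    dummies: frozenset[str]

    def __post_init__(self):
        if self.inputs & self.outputs or self.inputs & self.dummies \
                or self.outputs & self.dummies:
            raise TranslationError("input/output/dummy sets must be disjoint")


def infer_io(system: ReactionSystem) -> IoInference:
    """Classify species as inputs, outputs, and dummy inhibitors.

    Declared annotations win.  Otherwise, species never appearing in a
    product are inputs — except those used *only* in inhibitor positions,
    which are dummies; all produced species are outputs.
    """
    produced = system.produced()
    never_produced = system.background - produced
    used_as_reactant = frozenset().union(
        *(r.reactants for r in system.reactions)) if system.reactions \
        else frozenset()
    used_as_inhibitor = frozenset().union(
        *(r.inhibitors for r in system.reactions)) if system.reactions \
        else frozenset()

    if system.declared_inputs is not None:
        inputs = system.declared_inputs
    else:
        inputs = frozenset(
            s for s in never_produced
            if not (s in used_as_inhibitor and s not in used_as_reactant))
    if system.declared_outputs is not None:
        outputs = system.declared_outputs
    else:
        outputs = produced
    dummies = frozenset(
        s for s in never_produced - inputs - outputs
        if s in used_as_inhibitor and s not in used_as_reactant)
    return IoInference(inputs, outputs - inputs, dummies)


def split_io(system: ReactionSystem,
             io: Optional[IoInference] = None,
             cap: int = SPLIT_REACTION_CAP) -> ReactionSystem:
    """Separate species that are simultaneously inputs and outputs.

    For each species ``x`` that is both context-supplied and produced, a
    fresh input ``x_in`` is introduced; reactions testing ``x`` are
    rewritten so either arrival form behaves like ``x`` did (reactant
    occurrences duplicated over all replacement subsets, inhibitor
    occurrences inhibited by both names).  Context sets driving the split
    system must then name ``x_in`` instead of ``x``.

    The duplication is exponential in overlapping reactants per reaction;
    past ``cap`` resulting reactions an error recommends annotating inputs
    and outputs manually.
    """
    if io is None:
        io = infer_io(system)
    overlap = io.inputs & system.produced()
    if not overlap:
        return system
    taken = set(system.background)
    alias: dict[str, str] = {}
    for x in sorted(overlap):
        alias[x] = fresh_name(x, taken, suffix="_in")
        taken.add(alias[x])
    # Products of the overlapping species stay on the original name (it
    # remains the produced/state form); the fresh name is the pure input.
    # rewrite_with_aliases retargets products to the alias, so invert the
    # mapping direction: here the *produced* form keeps the original name
    # and context arrivals use x_in, which is exactly the alias rewrite
    # with products left alone.
    rewritten: list[Reaction] = []
    for r in rewrite_with_aliases(system.reactions, alias):
        # undo the product retargeting: x stays the produced symbol
        products = frozenset(
            {v: k for k, v in alias.items()}.get(p, p) for p in r.products)
        rewritten.append(Reaction(r.reactants, r.inhibitors, products))
    if len(rewritten) > cap:
        raise TranslationError(
            f"input/output splitting produced {len(rewritten)} reactions "
            f"(cap {cap}); annotate input and output symbols manually")
    declared_inputs = system.declared_inputs
    if declared_inputs is not None:
        declared_inputs = (declared_inputs - overlap) | \
            frozenset(alias.values())
    return ReactionSystem(
        system.background | frozenset(alias.values()),
        rewritten,
        declared_inputs=declared_inputs,
        declared_outputs=system.declared_outputs)


def rs_to_circuit(system: ReactionSystem,
                  io: Optional[IoInference] = None,
                  initial: Iterable[str] = (),
                  ) -> SequentialCircuit:
    """Translate a normal-form reaction system into a sequential circuit.

    One state variable per non-input species, one DNF conjunction per
    reaction (reactants positive, inhibitors negative); outputs are
    identity projections of the like-named state variables.  ``initial``
    lists species present initially (characteristic bits of the circuit's
    initial state; default all-zero, matching ``D0 = ∅``).

    The system must have single-product reactions and no produced input
    (run :func:`rescirc.normalize.normalize` / :func:`split_io` first).
    """
    if io is None:
        io = infer_io(system)
    if io.inputs & system.produced():
        raise TranslationError(
            f"input species are produced: "
            f"{sorted(io.inputs & system.produced())}; run split_io first")
    if not is_normal_form(system, io.inputs):
        raise TranslationError(
            "system is not in normal form for its input alphabet; "
            "run normalize first")
    if not io.outputs <= system.produced():
        raise TranslationError(
            f"declared outputs are never produced: "
            f"{sorted(io.outputs - system.produced())}")

    states = tuple(sorted(system.background - io.inputs))
    inputs = tuple(sorted(io.inputs))
    outputs = tuple(sorted(io.outputs))
    next_state: dict[str, DNF] = {}
    for p in states:
        terms = [Conjunction(r.reactants, r.inhibitors)
                 for r in system.sorted_reactions() if p in r.products]
        next_state[p] = DNF(terms)  # empty -> constant 0 (dummies etc.)
    output_fn = {y: DNF([Conjunction([y])]) for y in outputs}
    initial = frozenset(initial)
    if not initial <= set(states):
        raise TranslationError(
            f"initial species are not state variables: "
            f"{sorted(initial - set(states))}")
    init_bits = tuple(1 if s in initial else 0 for s in states)
    return SequentialCircuit(inputs, states, outputs,
                             next_state, output_fn, init_bits)


def circuit_to_rs(circuit: SequentialCircuit,
                  dummy: str = DEFAULT_DUMMY,
                  ) -> tuple[ReactionSystem, frozenset[str]]:
    """Translate a DNF circuit into a reaction system plus initial context.

    Background is ``Q ∪ Y`` (plus the dummy inhibitor when some
    conjunction has no negated literals), inputs are ``X``; each
    conjunction of each equation becomes one reaction producing the
    equation's variable.  Identity output projections of a like-named
    state variable are skipped (the state *is* the output).  Returns
    ``(system, C0)`` where ``C0`` is the set of state variables initially
    1 — the first context of any interactive process simulating the
    circuit.

    Conjunctions without positive literals (including the constant-1 term)
    cannot form a reaction, whose reactant set must be nonempty.
    """
    equations: list[tuple[str, DNF]] = [
        (q, circuit.next_state[q]) for q in circuit.states]
    for y in circuit.outputs:
        f = circuit.output_fn[y]
        if y in circuit.states and f == DNF([Conjunction([y])]):
            continue  # identity projection: the state variable is the output
        equations.append((y, f))

    needs_dummy = any(
        not term.negative
        for _, f in equations for term in f.terms)
    taken = set(circuit.states) | set(circuit.inputs) | set(circuit.outputs)
    if needs_dummy and dummy in taken:
        dummy = fresh_name(dummy, taken, suffix="")

    reactions: list[Reaction] = []
    for target, f in equations:
        for term in f.sorted_terms():
            if not term.positive:
                raise TranslationError(
                    f"equation for {target!r} has a conjunction without "
                    f"positive literals ({term!r}); it cannot become a "
                    f"reaction (reactant sets are nonempty)")
            inhibitors = term.negative or frozenset([dummy])
            reactions.append(Reaction(term.positive, inhibitors, [target]))

    background = set(circuit.states) | set(circuit.outputs) | \
        set(circuit.inputs)
    if needs_dummy:
        background.add(dummy)
    system = ReactionSystem(
        background, reactions,
        declared_inputs=circuit.inputs,
        declared_outputs=circuit.outputs)
    c0 = frozenset(s for s, b in zip(circuit.states, circuit.initial_state)
                   if b)
    return system, c0


def contexts_to_inputs(circuit: SequentialCircuit,
                       contexts: Iterable[Iterable[str]],
                       ) -> list[tuple[int, ...]]:
    """Encode context sets as input bit vectors (bit 1 iff species ∈ Ci)."""
    vectors = []
    for c in contexts:
        c = frozenset(c)
        extra = c - set(circuit.inputs)
        if extra:
            raise TranslationError(
                f"context species are not circuit inputs: {sorted(extra)}")
        vectors.append(tuple(1 if x in c else 0 for x in circuit.inputs))
    return vectors


def dnf_from_function(fn, variables: Sequence[str],
                      cap: int = 16) -> DNF:
    """Build a minterm DNF for an arbitrary boolean function by exhaustive
    expansion (convenience helper for small formulas, ≤ ``cap`` variables).

    ``fn`` receives a dict mapping each variable to a bit.
    """
    from itertools import product as iter_product
    variables = list(variables)
    if len(variables) > cap:
        raise TranslationError(
            f"{len(variables)} variables exceed the expansion cap ({cap})")
    terms = []
    for bits in iter_product((0, 1), repeat=len(variables)):
        assignment = dict(zip(variables, bits))
        if fn(assignment):
            terms.append(Conjunction(
                [v for v, b in assignment.items() if b],
                [v for v, b in assignment.items() if not b]))
    return DNF(terms)
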