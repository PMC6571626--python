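"""Synchronous sequential switching circuits in disjunctive normal form.

A circuit has input variables ``X``, state variables ``Q`` and output
variables ``Y``, with next-state and output functions

    Q(t+1) = F(Q(t), X(t))        Y(t) = G(Q(t), X(t))

where every component of ``F`` and ``G`` is stored as a DNF — a set of
conjunctions, each a set of positive and a set of negative literals.  The
empty DNF is the constant 0; a DNF containing the empty conjunction is the
constant 1.  Output timing is Mealy-style (``Y`` may read the current
input); circuits obtained from reaction systems have state-only outputs,
which makes a Moore presentation natural (see :mod:`rescirc.automata`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import product as iter_product
from typing import Iterable, Mapping, Optional, Sequence

from .rs_core import NAME_RE, ParseError

Bit = int
BitVector = tuple[int, ...]

#: Refuse exhaustive truth tables beyond this many total variables.
TRUTH_TABLE_CAP = 20


class CircuitError(ValueError):
    """Invalid circuit structure or evaluation request."""


@dataclass(frozen=True)
class Conjunction:
    """A conjunction of literals: positive and negated variable sets.

    A conjunction mentioning a variable both positively and negatively is
    the constant 0; :class:`DNF` normalizes such terms away.  The empty
    conjunction is the constant 1.
    """

    positive: frozenset[str]
    negative: frozenset[str]

    def __init__(self, positive: Iterable[str] = (),
                 negative: Iterable[str] = ()):
        object.__setattr__(self, "positive", frozenset(positive))
        object.__setattr__(self, "negative", frozenset(negative))

    def is_contradictory(self) -> bool:
        return bool(self.positive & self.negative)

    def variables(self) -> frozenset[str]:
        return self.positive | self.negative

    def evaluate(self, assignment: Mapping[str, Bit]) -> Bit:
        try:
            if all(assignment[v] for v in self.positive) and \
                    not any(assignment[v] for v in self.negative):
                return 1
            return 0
        except KeyError as exc:
            raise CircuitError(f"unassigned variable {exc.args[0]!r}") from exc

    def sort_key(self) -> tuple:
        return (sorted(self.positive), sorted(self.negative))

    def __repr__(self) -> str:
        lits = sorted(self.positive) + [f"!{v}" for v in sorted(self.negative)]
        return " & ".join(lits) if lits else "1"


@dataclass(frozen=True)
class DNF:
    """A disjunction of :class:`Conjunction` terms (a set; order-free).

    Contradictory terms (``x & !x``) are dropped at construction, which
    never changes the function's value.
    """

    terms: frozenset[Conjunction]

    def __init__(self, terms: Iterable[Conjunction] = ()):
        object.__setattr__(
            self, "terms",
            frozenset(t for t in terms if not t.is_contradictory()))

    @classmethod
    def zero(cls) -> "DNF":
        return cls(())

    @classmethod
    def one(cls) -> "DNF":
        return cls((Conjunction(),))

    def is_zero(self) -> bool:
        return not self.terms

    def variables(self) -> frozenset[str]:
        return frozenset().union(*(t.variables() for t in self.terms)) \
            if self.terms else frozenset()

    def evaluate(self, assignment: Mapping[str, Bit]) -> Bit:
        return 1 if any(t.evaluate(assignment) for t in self.terms) else 0

    def sorted_terms(self) -> list[Conjunction]:
        return sorted(self.terms, key=Conjunction.sort_key)

    def __repr__(self) -> str:
        if not self.terms:
            return "0"
        return " | ".join(repr(t) for t in self.sorted_terms())


def eval_dnf(f: DNF, assignment: Mapping[str, Bit]) -> Bit:
    """Evaluate ``f`` under a variable→bit assignment.

    1 iff some conjunction has all positive variables 1 and all negative
    variables 0.  Raises :class:`CircuitError` on an unassigned variable.
    """
    for v in f.variables():
        if v not in assignment:
            raise CircuitError(f"unassigned variable {v!r}")
    return f.evaluate(assignment)


@dataclass(frozen=True)
class SequentialCircuit:
    """A sequential switching circuit with DNF transition/output functions.

    Variable order in ``inputs`` / ``states`` / ``outputs`` fixes the bit
    order of all vectors (state labels, truth-table rows, Verilog ports).
    """

    inputs: tuple[str, ...]
    states: tuple[str, ...]
    outputs: tuple[str, ...]
    next_state: dict[str, DNF]
    output_fn: dict[str, DNF]
    initial_state: BitVector = ()

    def __init__(self, inputs: Sequence[str], states: Sequence[str],
                 outputs: Sequence[str],
                 next_state: Mapping[str, DNF],
                 output_fn: Mapping[str, DNF],
                 initial_state: Optional[Sequence[int]] = None):
        object.__setattr__(self, "inputs", tuple(inputs))
        object.__setattr__(self, "states", tuple(states))
        object.__setattr__(self, "outputs", tuple(outputs))
        object.__setattr__(self, "next_state", dict(next_state))
        object.__setattr__(self, "output_fn", dict(output_fn))
        if initial_state is None:
            initial_state = (0,) * len(self.states)
        object.__setattr__(self, "initial_state", tuple(initial_state))

        declared = set(self.inputs) | set(self.states)
        for name in self.inputs + self.states + self.outputs:
            if not NAME_RE.fullmatch(name):
                raise CircuitError(f"invalid variable name {name!r}")
        if len(declared) != len(self.inputs) + len(self.states):
            raise CircuitError("input/state variable names not distinct")
        missing = set(self.states) - self.next_state.keys()
        if missing:
            raise CircuitError(f"no next-state equation for {sorted(missing)}")
        missing = set(self.outputs) - self.output_fn.keys()
        if missing:
            raise CircuitError(f"no output equation for {sorted(missing)}")
        for name, f in list(self.next_state.items()) + \
                list(self.output_fn.items()):
            undeclared = f.variables() - declared
            if undeclared:
                raise CircuitError(
                    f"equation for {name!r} references undeclared "
                    f"variables {sorted(undeclared)}")
        if len(self.initial_state) != len(self.states):
            raise CircuitError("initial state length mismatch")

    @property
    def n_inputs(self) -> int:
        return len(self.inputs)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def assignment(self, state: Sequence[int], inp: Sequence[int],
                   ) -> dict[str, Bit]:
        if len(state) != len(self.states):
            raise CircuitError(
                f"state vector length {len(state)} != {len(self.states)}")
        if len(inp) != len(self.inputs):
            raise CircuitError(
                f"input vector length {len(inp)} != {len(self.inputs)}")
        a = dict(zip(self.states, state))
        a.update(zip(self.inputs, inp))
        return a

    def outputs_state_only(self) -> bool:
        """True when no output function reads an input variable."""
        inp = set(self.inputs)
        return all(not (f.variables() & inp)
                   for f in self.output_fn.values())


@dataclass(frozen=True)
class TruthTable:
    """Exhaustive rows ``(Q(t), X(t), Q(t+1), Y(t))`` ordered by ``(Q, X)``
    as ascending binary numbers."""

    rows: tuple[tuple[BitVector, BitVector, BitVector, BitVector], ...]

    def __len__(self) -> int:
        return len(self.rows)


def step(circuit: SequentialCircuit, state: Sequence[int],
         inp: Sequence[int]) -> tuple[BitVector, BitVector]:
    """One synchronous step: ``(F(Q, X), G(Q, X))``.

    The output is computed from the *current* state and input (Mealy
    timing).
    """
    a = circuit.assignment(state, inp)
    nxt = tuple(circuit.next_state[q].evaluate(a) for q in circuit.states)
    out = tuple(circuit.output_fn[y].evaluate(a) for y in circuit.outputs)
    return nxt, out


def truth_table(circuit: SequentialCircuit,
                cap: int = TRUTH_TABLE_CAP) -> TruthTable:
    """All ``2^(s+n)`` rows of the circuit, consistent with :func:`step`."""
    total = circuit.n_states + circuit.n_inputs
    if total > cap:
        raise CircuitError(
            f"{total} variables exceed the truth-table cap ({cap}); "
            "sample with step()/simulate() instead")
    rows = []
    for q in iter_product((0, 1), repeat=circuit.n_states):
        for x in iter_product((0, 1), repeat=circuit.n_inputs):
            nxt, out = step(circuit, q, x)
            rows.append((q, x, nxt, out))
    return TruthTable(tuple(rows))


def simulate(circuit: SequentialCircuit,
             input_sequence: Sequence[Sequence[int]],
             initial: Optional[Sequence[int]] = None,
             ) -> tuple[list[BitVector], list[BitVector]]:
    """Iterate :func:`step` from ``initial`` (default the circuit's initial
    state) over an input sequence.

    Returns ``(states, outputs)`` where ``states[t]`` is the state *after*
    consuming ``input_sequence[t]`` and ``outputs[t]`` is the Mealy output
    emitted while consuming it.  Both lists have the input length.
    """
    state = tuple(circuit.initial_state if initial is None else initial)
    states: list[BitVector] = []
    outputs: list[BitVector] = []
    for x in input_sequence:
        state, out = step(circuit, state, x)
        states.append(state)
        outputs.append(out)
    return states, outputs


# ---------------------------------------------------------------------------
# Circuit text format
# ---------------------------------------------------------------------------
#
# One equation per line; state equations use a primed left-hand side:
#   q' = a & !b | c
#   y  = q & x
#   d' = 0
# Terms are '&'-joined literals with '!' negation, joined by '|'; the bare
# constants 0 and 1 are accepted.  Directives:
#   #input x1 x2      ordered input variables
#   #output y1 y2     ordered output variables
#   #init 010         initial state bits, in state-equation order
# State variable order is the order of the primed equations in the file.

def _parse_dnf(text: str, lineno: int) -> DNF:
    text = text.strip()
    if text == "0":
        return DNF.zero()
    if text == "1":
        return DNF.one()
    terms = []
    for term_text in text.split("|"):
        positive, negative = [], []
        for lit in term_text.split("&"):
            lit = lit.strip()
            if not lit:
                raise ParseError("empty literal", lineno)
            if lit.startswith("!"):
                name = lit[1:].strip()
                negative.append(name)
            else:
                name = lit
                positive.append(name)
            if not NAME_RE.fullmatch(name):
                raise ParseError(f"invalid variable name {name!r}", lineno)
        terms.append(Conjunction(positive, negative))
    return DNF(terms)


def parse_circuit(text: str) -> SequentialCircuit:
    """Parse the circuit text format."""
    inputs: list[str] = []
    outputs: list[str] = []
    init_bits: Optional[str] = None
    state_order: list[str] = []
    next_state: dict[str, DNF] = {}
    output_fn: dict[str, DNF] = {}

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("//"):
            continue
        if line.startswith("#"):
            head, _, rest = line.partition(" ")
            if head == "#input":
                inputs.extend(rest.split())
            elif head == "#output":
                outputs.extend(rest.split())
            elif head == "#init":
                init_bits = rest.strip()
            else:
                raise ParseError(f"unknown directive {head!r}", lineno)
            continue
        lhs, eq, rhs = line.partition("=")
        if not eq:
            raise ParseError("expected an equation", lineno)
        lhs = lhs.strip()
        f = _parse_dnf(rhs, lineno)
        if lhs.endswith("'"):
            name = lhs[:-1].strip()
            if name in next_state:
                raise ParseError(f"duplicate state equation for {name!r}",
                                 lineno)
            state_order.append(name)
            next_state[name] = f
        else:
            if lhs in output_fn:
                raise ParseError(f"duplicate output equation for {lhs!r}",
                                 lineno)
            output_fn[lhs] = f

    if not outputs:
        outputs = sorted(output_fn)
    for y in outputs:
        if y not in output_fn:
            raise ParseError(f"#output variable {y!r} has no equation")
    initial = None
    if init_bits is not None:
        if not re.fullmatch(r"[01]*", init_bits) or \
                len(init_bits) != len(state_order):
            raise ParseError(
                f"#init needs {len(state_order)} bits, got {init_bits!r}")
        initial = tuple(int(b) for b in init_bits)
    try:
        return SequentialCircuit(inputs, state_order, outputs,
                                 next_state, output_fn, initial)
    except CircuitError as exc:
        raise ParseError(str(exc)) from exc


def serialize_circuit(circuit: SequentialCircuit) -> str:
    """Serialize in the circuit text format (deterministic)."""
    lines = []
    if circuit.inputs:
        lines.append("#input " + " ".join(circuit.inputs))
    if circuit.outputs:
        lines.append("#output " + " ".join(circuit.outputs))
    lines.append("#init " + "".join(str(b) for b in circuit.initial_state))
    for q in circuit.states:
        lines.append(f"{q}' = {circuit.next_state[q]!r}")
    for y in circuit.outputs:
        lines.append(f"{y} = {circuit.output_fn[y]!r}")
    return "\n".join(lines) + "\n"
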