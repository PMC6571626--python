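"""Mealy/Moore automata of a sequential circuit, and GraphViz DOT export.

A circuit's dynamics form a deterministic finite-state machine over binary
state vectors.  The Mealy presentation labels each transition with
``input/output`` where the output is ``G(Q, X)`` of the *source* state;
the Moore presentation (valid only when ``G`` reads no input variable)
labels each node with its output ``G(Q)``.  Both describe the same run;
reading Mealy edge labels along a run and reading Moore node labels on the
states being *entered* are offset by exactly one step — the classic
one-step output delay between the two presentations.

Construction is a breadth-first closure from the initial state (or from
all ``2^s`` states in exhaustive mode) over all ``2^n`` input values, so
it is exponential; state counts are capped (default: fewer than 32 state
variables, mirroring the enumeration limit a practical tool needs).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from itertools import product as iter_product
from typing import Optional, Sequence

import networkx as nx

from .circuit import BitVector, CircuitError, SequentialCircuit, step

#: Refuse automaton construction at or above this many state variables.
GRAPH_STATE_CAP = 32
#: Refuse automaton construction above this many input variables.
GRAPH_INPUT_CAP = 16

MEALY = "mealy"
MOORE = "moore"


def _bits(label_bits: Sequence[int]) -> str:
    return "".join(str(b) for b in label_bits)


@dataclass(frozen=True)
class StateAutomaton:
    """A Mealy or Moore machine over binary state labels.

    ``edges`` are ``(source, input_label, target, output_label)`` with
    ``output_label`` ``None`` for Moore machines (whose outputs live on
    nodes, in ``node_outputs``).  Labels concatenate state bits in
    ``label_order`` (default: the circuit's declared state order).
    Deterministic: one edge per ``(source, input)``.
    """

    flavor: str
    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str, str, Optional[str]], ...]
    initial: tuple[str, ...]
    node_outputs: dict[str, str] = field(default_factory=dict)
    label_order: tuple[str, ...] = ()

    def successors(self, node: str) -> dict[str, str]:
        return {x: dst for src, x, dst, _ in self.edges if src == node}

    def graph(self) -> "nx.MultiDiGraph":
        """The automaton as a networkx multi-digraph (edge keys are input
        labels; Mealy edges carry an ``output`` attribute)."""
        g = nx.MultiDiGraph(flavor=self.flavor)
        for n in self.nodes:
            g.add_node(n, output=self.node_outputs.get(n),
                       initial=n in self.initial)
        for src, x, dst, out in self.edges:
            g.add_edge(src, dst, key=x, input=x, output=out)
        return g

    def run(self, input_labels: Sequence[str],
            start: Optional[str] = None) -> tuple[list[str], list[str]]:
        """Replay an input-label sequence from ``start`` (default: the
        first initial state).

        Returns ``(visited, outputs)`` where ``visited`` lists the states
        entered after each transition.  Mealy outputs are read off the
        traversed edges; Moore outputs are the labels of the states
        entered — hence offset one step later than the Mealy reading of
        the same run.
        """
        node = start if start is not None else self.initial[0]
        transitions = {(src, x): (dst, out)
                       for src, x, dst, out in self.edges}
        visited: list[str] = []
        outputs: list[str] = []
        for x in input_labels:
            if (node, x) not in transitions:
                raise CircuitError(
                    f"no transition from {node!r} on input {x!r}")
            node, edge_out = transitions[(node, x)]
            visited.append(node)
            outputs.append(edge_out if self.flavor == MEALY
                           else self.node_outputs[node])
        return visited, outputs


def build_automaton(circuit: SequentialCircuit,
                    flavor: str = MOORE,
                    exhaustive: bool = False,
                    label_order: Optional[Sequence[str]] = None,
                    state_cap: int = GRAPH_STATE_CAP,
                    input_cap: int = GRAPH_INPUT_CAP) -> StateAutomaton:
    """Build the state automaton of ``circuit``.

    Reachable mode closes over all inputs from the circuit's initial
    state; ``exhaustive`` starts from all ``2^s`` states.  ``label_order``
    selects and orders the state variables used for node labels (e.g., to
    match a published figure's bit order); it must keep labels unique over
    the constructed states.  Moore flavor requires input-independent
    output functions.
    """
    if flavor not in (MEALY, MOORE):
        raise CircuitError(f"unknown automaton flavor {flavor!r}")
    if circuit.n_states >= state_cap:
        raise CircuitError(
            f"{circuit.n_states} state variables reach the automaton cap "
            f"({state_cap} species): enumeration is exponential")
    if circuit.n_inputs > input_cap:
        raise CircuitError(
            f"{circuit.n_inputs} inputs exceed the automaton input cap "
            f"({input_cap})")
    if flavor == MOORE and not circuit.outputs_state_only():
        raise CircuitError(
            "output functions read input variables; a Moore machine "
            "cannot present them — build the Mealy automaton instead")

    if label_order is None:
        label_order = circuit.states
    label_order = tuple(label_order)
    extra = set(label_order) - set(circuit.states)
    if extra:
        raise CircuitError(f"label_order names unknown state variables: "
                           f"{sorted(extra)}")
    index = {q: i for i, q in enumerate(circuit.states)}

    def label_of(state: BitVector) -> str:
        return _bits([state[index[q]] for q in label_order])

    if exhaustive:
        starts = [tuple(bits) for bits in
                  iter_product((0, 1), repeat=circuit.n_states)]
    else:
        starts = [tuple(circuit.initial_state)]

    all_inputs = [tuple(bits) for bits in
                  iter_product((0, 1), repeat=circuit.n_inputs)]
    seen: dict[BitVector, str] = {}
    labels_used: dict[str, BitVector] = {}
    edges: list[tuple[str, str, str, Optional[str]]] = []
    node_outputs: dict[str, str] = {}
    queue = deque()

    def visit(state: BitVector) -> str:
        if state in seen:
            return seen[state]
        label = label_of(state)
        if label in labels_used and labels_used[label] != state:
            raise CircuitError(
                f"label_order {label_order} does not distinguish states "
                f"{labels_used[label]} and {state}")
        seen[state] = label
        labels_used[label] = state
        queue.append(state)
        return label

    for s in starts:
        visit(s)
    initial_labels = tuple(dict.fromkeys(seen[s] for s in starts))

    while queue:
        state = queue.popleft()
        src = seen[state]
        if flavor == MOORE and src not in node_outputs:
            # G is input-independent here; evaluate with arbitrary input.
            _, out = step(circuit, state, all_inputs[0])
            node_outputs[src] = _bits(out)
        for x in all_inputs:
            nxt, out = step(circuit, state, x)
            dst = visit(nxt)
            edges.append((src, _bits(x), dst,
                          _bits(out) if flavor == MEALY else None))

    nodes = tuple(sorted(seen.values()))
    edges.sort()
    return StateAutomaton(flavor=flavor, nodes=nodes, edges=tuple(edges),
                          initial=initial_labels,
                          node_outputs=node_outputs,
                          label_order=label_order)


def to_dot(automaton: StateAutomaton, name: str = "automaton") -> str:
    """Render the automaton as GraphViz DOT text.

    Moore nodes are labeled ``state/output``; Mealy edges are labeled
    ``input/output``.  Node and edge ordering is deterministic; the
    initial state is marked with an arrow from a point node.
    """
    lines = [f"digraph {name} {{", "  rankdir=LR;",
             '  node [shape=circle];']
    for i, init in enumerate(automaton.initial):
        lines.append(f'  __start{i} [shape=point, label=""];')
    for node in automaton.nodes:
        if automaton.flavor == MOORE:
            label = f"{node}/{automaton.node_outputs[node]}"
        else:
            label = node
        lines.append(f'  "{node}" [label="{label}"];')
    for i, init in enumerate(automaton.initial):
        lines.append(f'  __start{i} -> "{init}";')
    for src, x, dst, out in automaton.edges:
        label = x if out is None else f"{x}/{out}"
        lines.append(f'  "{src}" -> "{dst}" [label="{label}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"
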