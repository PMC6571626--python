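"""Reaction-system data model, text dialect, and reference set-based simulator.

A reaction system is a qualitative model of a biochemical environment: a
finite background set of species ``S`` and a set of reactions ``(R, I, P)``
(reactants, inhibitors, products).  A reaction is *enabled* in a state
``X ⊆ S`` when ``R ⊆ X`` and ``I ∩ X = ∅``; the next state is the union of
the products of all enabled reactions.  Nothing persists unless actively
produced (non-permanency).  The environment drives the system through a
sequence of *contexts* — species injected at each step — yielding an
interactive process ``D0 = ∅, Di = res(D(i-1) ∪ C(i-1))``.

Species are represented as plain strings (identifiers); reactions and
systems are immutable, hashable dataclasses.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

logger = logging.getLogger("rescirc")

#: Valid species / variable identifiers.
NAME_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")


class RSError(ValueError):
    """Invalid reaction-system structure."""


class ParseError(RSError):
    """Syntax or semantic error in a source file, with position info."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def _check_name(name: str, line: Optional[int] = None) -> str:
    if not NAME_RE.fullmatch(name):
        raise ParseError(f"invalid species name {name!r}", line)
    return name


def _names(items: Iterable[str]) -> frozenset[str]:
    return frozenset(items)


@dataclass(frozen=True)
class Reaction:
    """A reaction ``(R, I, P)``: reactants, inhibitors, products.

    ``R`` and ``P`` must be nonempty and ``R ∩ I = ∅``.  The strict
    definition also requires ``I`` nonempty; internally an empty inhibitor
    set is permitted (the text dialect can re-insert a dummy inhibitor so
    serialized systems remain strictly valid).
    """

    reactants: frozenset[str]
    inhibitors: frozenset[str]
    products: frozenset[str]

    def __init__(self, reactants: Iterable[str], inhibitors: Iterable[str],
                 products: Iterable[str]):
        object.__setattr__(self, "reactants", _names(reactants))
        object.__setattr__(self, "inhibitors", _names(inhibitors))
        object.__setattr__(self, "products", _names(products))
        if not self.reactants:
            raise RSError("reactant set must be nonempty")
        if not self.products:
            raise RSError("product set must be nonempty")
        if self.reactants & self.inhibitors:
            raise RSError(
                f"reactants and inhibitors overlap: "
                f"{sorted(self.reactants & self.inhibitors)}")

    # frozensets are not ordered; sort deterministically via an explicit key
    def sort_key(self) -> tuple:
        return (sorted(self.reactants), sorted(self.inhibitors),
                sorted(self.products))

    def __lt__(self, other: "Reaction") -> bool:  # type: ignore[override]
        return self.sort_key() < other.sort_key()

    def species(self) -> frozenset[str]:
        return self.reactants | self.inhibitors | self.products

    def enabled(self, state: frozenset[str]) -> bool:
        return self.reactants <= state and not (self.inhibitors & state)

    def __repr__(self) -> str:
        def f(s: frozenset[str]) -> str:
            return "{" + ",".join(sorted(s)) + "}"
        return f"({f(self.reactants)},{f(self.inhibitors)},{f(self.products)})"


@dataclass(frozen=True)
class ReactionSystem:
    """A reaction system ``(S, A)`` with optional input/output annotations.

    ``declared_inputs`` / ``declared_outputs`` carry the source-file
    annotations used by I/O inference; an input that is also produced is
    tolerated here (with a warning) and repaired by ``translate.split_io``.
    """

    background: frozenset[str]
    reactions: frozenset[Reaction]
    declared_inputs: Optional[frozenset[str]] = None
    declared_outputs: Optional[frozenset[str]] = None

    def __init__(self, background: Iterable[str],
                 reactions: Iterable[Reaction],
                 declared_inputs: Optional[Iterable[str]] = None,
                 declared_outputs: Optional[Iterable[str]] = None):
        object.__setattr__(self, "background", _names(background))
        object.__setattr__(self, "reactions", frozenset(reactions))
        object.__setattr__(
            self, "declared_inputs",
            None if declared_inputs is None else _names(declared_inputs))
        object.__setattr__(
            self, "declared_outputs",
            None if declared_outputs is None else _names(declared_outputs))
        mentioned = frozenset().union(
            *(r.species() for r in self.reactions)) if self.reactions \
            else frozenset()
        if not mentioned <= self.background:
            raise RSError(
                f"species outside background: "
                f"{sorted(mentioned - self.background)}")
        for decl, label in ((self.declared_inputs, "input"),
                            (self.declared_outputs, "output")):
            if decl is not None and not decl <= self.background:
                raise RSError(
                    f"declared {label} species outside background: "
                    f"{sorted(decl - self.background)}")
        if self.declared_inputs is not None:
            overlap = self.declared_inputs & self.produced()
            if overlap:
                warnings.warn(
                    f"declared inputs also appear as products: "
                    f"{sorted(overlap)}; run split_io before translating",
                    stacklevel=2)

    def produced(self) -> frozenset[str]:
        """Species appearing in at least one product set."""
        return frozenset().union(
            *(r.products for r in self.reactions)) if self.reactions \
            else frozenset()

    def sorted_reactions(self) -> list[Reaction]:
        return sorted(self.reactions)

    def sorted_background(self) -> list[str]:
        return sorted(self.background)


@dataclass(frozen=True)
class ContextSequence:
    """An ordered sequence of context sets ``C0, ..., Cn``."""

    contexts: tuple[frozenset[str], ...]

    def __init__(self, contexts: Iterable[Iterable[str]]):
        object.__setattr__(
            self, "contexts", tuple(_names(c) for c in contexts))

    def __len__(self) -> int:
        return len(self.contexts)

    def __iter__(self) -> Iterator[frozenset[str]]:
        return iter(self.contexts)

    def __getitem__(self, i: int) -> frozenset[str]:
        return self.contexts[i]

    def alphabet(self) -> frozenset[str]:
        return frozenset().union(*self.contexts) if self.contexts \
            else frozenset()

    def validate(self, system: ReactionSystem) -> None:
        extra = self.alphabet() - system.background
        if extra:
            raise RSError(f"context species outside background: "
                          f"{sorted(extra)}")


@dataclass(frozen=True)
class InteractiveProcessTrace:
    """An interactive process ``π = (γ, δ)``.

    ``results[i]`` is ``Di`` (0-based, ``D0 = ∅``); the full state
    ``Wi = Di ∪ Ci`` is exposed through :meth:`state`, not stored.
    """

    contexts: ContextSequence
    results: tuple[frozenset[str], ...]

    def __len__(self) -> int:
        return len(self.results)

    def state(self, i: int) -> frozenset[str]:
        """``Wi = Di ∪ Ci`` — the state the result function is applied to."""
        return self.results[i] | self.contexts[i]


# ---------------------------------------------------------------------------
# Simulation (the reference, set-based semantics)
# ---------------------------------------------------------------------------

def result(system: ReactionSystem, state: Iterable[str]) -> frozenset[str]:
    """``res_A(X)``: union of products of all reactions enabled in ``X``."""
    x = _names(state)
    extra = x - system.background
    if extra:
        raise RSError(f"state species outside background: {sorted(extra)}")
    out: set[str] = set()
    for r in system.reactions:
        if r.enabled(x):
            out |= r.products
    return frozenset(out)


def run_process(system: ReactionSystem,
                contexts: ContextSequence | Iterable[Iterable[str]],
                ) -> InteractiveProcessTrace:
    """Run an interactive process: ``D0 = ∅``, ``Di = res(D(i-1) ∪ C(i-1))``.

    The trace has the same length as ``contexts`` (the final context does
    not influence any recorded result).
    """
    if not isinstance(contexts, ContextSequence):
        contexts = ContextSequence(contexts)
    if len(contexts) == 0:
        raise RSError("context sequence must be nonempty")
    contexts.validate(system)
    results = [frozenset()]  # D0
    for i in range(1, len(contexts)):
        results.append(result(system, results[i - 1] | contexts[i - 1]))
    return InteractiveProcessTrace(contexts, tuple(results))


# ---------------------------------------------------------------------------
# Text dialect
# ---------------------------------------------------------------------------
#
# One reaction per line:   reactants , inhibitors , products
# with species space-separated inside each field.  Directive lines:
#   #input: a b        explicit input annotation
#   #output: a b       explicit output annotation
#   #context[i]: a b   context set Ci (missing indices default to ∅)
# Blank lines and lines starting with "//" are ignored.  In strict mode an
# empty inhibitor field is rejected (pure Definition-1 compliance).

_CONTEXT_RE = re.compile(r"#context\[(\d+)\]:\s*(.*)$")


def _split_field(text: str, line: int) -> list[str]:
    return [_check_name(tok, line) for tok in text.split()]


def parse_rs(text: str, strict: bool = False,
             ) -> tuple[ReactionSystem, Optional[ContextSequence]]:
    """Parse the reaction-system text dialect.

    Returns the system and the declared context sequence (``None`` when the
    file declares no contexts).  Species are auto-collected into the
    background set.  Raises :class:`ParseError` with a line number on bad
    syntax; warns on duplicate reactions.
    """
    reactions: list[Reaction] = []
    seen: set[Reaction] = set()
    inputs: Optional[list[str]] = None
    outputs: Optional[list[str]] = None
    context_map: dict[int, frozenset[str]] = {}
    mentioned: set[str] = set()

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("//"):
            continue
        if line.startswith("#"):
            m = _CONTEXT_RE.match(line)
            if m:
                idx = int(m.group(1))
                if idx in context_map:
                    raise ParseError(f"duplicate context index {idx}", lineno)
                context_map[idx] = frozenset(_split_field(m.group(2), lineno))
            elif line.startswith("#input:"):
                inputs = _split_field(line[len("#input:"):], lineno)
                mentioned.update(inputs)
            elif line.startswith("#output:"):
                outputs = _split_field(line[len("#output:"):], lineno)
                mentioned.update(outputs)
            else:
                raise ParseError(f"unknown directive {line.split(':')[0]!r}",
                                 lineno)
            continue
        fields = line.split(",")
        if len(fields) != 3:
            raise ParseError(
                "expected 'reactants , inhibitors , products'", lineno)
        r, i, p = (_split_field(f, lineno) for f in fields)
        if strict and not i:
            raise ParseError("empty inhibitor field (strict mode)", lineno)
        try:
            reaction = Reaction(r, i, p)
        except RSError as exc:
            raise ParseError(str(exc), lineno) from exc
        if reaction in seen:
            warnings.warn(f"line {lineno}: duplicate reaction {reaction!r}",
                          stacklevel=2)
        seen.add(reaction)
        reactions.append(reaction)
        mentioned.update(reaction.species())

    system = ReactionSystem(mentioned, reactions,
                            declared_inputs=inputs, declared_outputs=outputs)
    contexts: Optional[ContextSequence] = None
    if context_map:
        top = max(context_map)
        contexts = ContextSequence(
            [context_map.get(i, frozenset()) for i in range(top + 1)])
        extra = contexts.alphabet() - system.background
        if extra:
            raise ParseError(
                f"context species not in background: {sorted(extra)}")
    return system, contexts


def serialize_rs(system: ReactionSystem,
                 contexts: Optional[ContextSequence] = None,
                 dummy: Optional[str] = None) -> str:
    """Serialize in the text dialect, deterministically ordered.

    When ``dummy`` is given, reactions with an empty inhibitor set are
    written with that species as inhibitor so the output is strict-mode
    parseable (the dummy must not occur elsewhere in those reactions).
    """
    lines: list[str] = []
    if system.declared_inputs is not None:
        lines.append("#input: " + " ".join(sorted(system.declared_inputs)))
    if system.declared_outputs is not None:
        lines.append("#output: " + " ".join(sorted(system.declared_outputs)))
    for r in system.sorted_reactions():
        inhibitors = r.inhibitors
        if not inhibitors and dummy is not None:
            if dummy in r.reactants:
                raise RSError(f"dummy {dummy!r} is a reactant of {r!r}")
            inhibitors = frozenset([dummy])
        lines.append("{} , {} , {}".format(
            " ".join(sorted(r.reactants)),
            " ".join(sorted(inhibitors)),
            " ".join(sorted(r.products))))
    if contexts is not None:
        for i, c in enumerate(contexts):
            lines.append(f"#context[{i}]: " + " ".join(sorted(c)))
    return "\n".join(lines) + "\n"
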