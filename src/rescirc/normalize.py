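"""Normal form of a reaction system with respect to its contexts.

A system is in *normal form* for a context alphabet ``Z`` when

1. every reaction has a single product, and
2. no product species occurs in ``Z`` (products disjoint from contexts).

Both conditions can always be established constructively while preserving
behaviour: multi-product reactions are split into one reaction per product,
and each species ``X`` that is both context-supplied and produced is given
a fresh alias ``X'`` — producing reactions are retargeted to ``X'``, and
every reaction testing ``X`` is rewritten so that availability of either
form behaves like availability of ``X`` in the original system:

* reactant occurrences: one copy per subset of aliased reactants replaced
  (``X`` present *or* ``X'`` present enables);
* inhibitor occurrences: both ``X`` and ``X'`` are inhibitors of the same
  reaction (``X`` present *or* ``X'`` present inhibits).

Projecting the normalized trace back onto the original background (with
aliases collapsed onto their originals) reproduces the original trace
exactly.  The reactant-side duplication is combinatorial, so the number of
reactions can blow up exponentially in the number of aliased reactants per
reaction; a warning is logged past a configurable threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional

from .rs_core import (ContextSequence, InteractiveProcessTrace, Reaction,
                      ReactionSystem, RSError)

logger = logging.getLogger("rescirc")

#: Log a warning when normalization grows a system past this many reactions.
BLOWUP_WARN_THRESHOLD = 10_000


@dataclass(frozen=True)
class NormalizationResult:
    """A normalized system plus the alias bookkeeping.

    ``alias_map`` maps each fresh alias species back to the original
    species it stands for (injective).
    """

    system: ReactionSystem
    alias_map: dict[str, str]

    def project(self, species: Iterable[str]) -> frozenset[str]:
        """Project a normalized state onto the original background,
        collapsing aliases onto their originals."""
        original = self.system.background - frozenset(self.alias_map)
        out = set()
        for s in species:
            if s in self.alias_map:
                out.add(self.alias_map[s])
            elif s in original:
                out.add(s)
        return frozenset(out)

    def project_trace(self, trace: InteractiveProcessTrace,
                      ) -> tuple[frozenset[str], ...]:
        return tuple(self.project(d) for d in trace.results)


def is_normal_form(system: ReactionSystem,
                   context_alphabet: Iterable[str]) -> bool:
    """True iff every reaction has one product and no product is a
    possible context symbol."""
    z = frozenset(context_alphabet)
    if not z <= system.background:
        raise RSError("context alphabet outside background")
    if any(len(r.products) != 1 for r in system.reactions):
        return False
    return not (system.produced() & z)


def fresh_name(base: str, taken: Iterable[str], suffix: str = "__alias",
               ) -> str:
    """``base + suffix``, with a counter appended on collision."""
    taken = set(taken)
    candidate = base + suffix
    counter = 1
    while candidate in taken:
        candidate = f"{base}{suffix}{counter}"
        counter += 1
    return candidate


def rewrite_with_aliases(reactions: Iterable[Reaction],
                         alias: dict[str, str]) -> list[Reaction]:
    """Rewrite reactions so a species may arrive either as itself or as its
    alias (``alias`` maps original -> alias name).

    Products are retargeted to the alias (the original is no longer
    produced).  Reactant occurrences are duplicated over all replacement
    subsets; inhibitor occurrences inhibit under both names.
    """
    out: list[Reaction] = []
    for r in reactions:
        inhibitors = set(r.inhibitors)
        for x in r.inhibitors & alias.keys():
            inhibitors.add(alias[x])
        products = frozenset(alias.get(p, p) for p in r.products)
        aliased_reactants = sorted(r.reactants & alias.keys())
        for k in range(len(aliased_reactants) + 1):
            for subset in combinations(aliased_reactants, k):
                reactants = set(r.reactants)
                for x in subset:
                    reactants.discard(x)
                    reactants.add(alias[x])
                out.append(Reaction(reactants, inhibitors, products))
    return out


def normalize(system: ReactionSystem,
              context_alphabet: Iterable[str],
              warn_threshold: Optional[int] = BLOWUP_WARN_THRESHOLD,
              ) -> NormalizationResult:
    """Transform ``system`` into normal form for ``context_alphabet``.

    Idempotent on already-normal systems (returned unchanged with an empty
    alias map).  Behaviour is preserved in the projection sense: for any
    context sequence over the alphabet, the normalized trace projected
    through :meth:`NormalizationResult.project_trace` equals the original
    trace.
    """
    z = frozenset(context_alphabet)
    if not z <= system.background:
        raise RSError("context alphabet outside background")
    if is_normal_form(system, z):
        return NormalizationResult(system, {})

    # Step 1: split multi-product reactions into single-product ones.
    split: list[Reaction] = []
    for r in system.reactions:
        if len(r.products) == 1:
            split.append(r)
        else:
            for p in sorted(r.products):
                split.append(Reaction(r.reactants, r.inhibitors, [p]))

    # Step 2: alias every produced context symbol.
    produced = frozenset().union(*(r.products for r in split)) if split \
        else frozenset()
    taken = set(system.background)
    alias: dict[str, str] = {}
    for x in sorted(z & produced):
        alias[x] = fresh_name(x, taken)
        taken.add(alias[x])
    rewritten = rewrite_with_aliases(split, alias)

    if warn_threshold is not None and len(rewritten) > warn_threshold:
        logger.warning(
            "normalization grew the system to %d reactions "
            "(threshold %d): aliasing duplication is exponential in the "
            "number of aliased reactants per reaction",
            len(rewritten), warn_threshold)

    normalized = ReactionSystem(
        system.background | frozenset(alias.values()),
        rewritten,
        declared_inputs=system.declared_inputs,
        declared_outputs=system.declared_outputs)
    return NormalizationResult(
        normalized, {v: k for k, v in alias.items()})


def run_normalized(norm: NormalizationResult,
                   contexts: ContextSequence | Iterable[Iterable[str]],
                   ) -> tuple[frozenset[str], ...]:
    """Run the normalized system on original-alphabet contexts and return
    the trace projected back onto the original background."""
    from .rs_core import run_process
    trace = run_process(norm.system, contexts)
    return norm.project_trace(trace)
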