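"""Enumeration of catabolic enzyme chains and the organisms encoding them.

An enzymatic chain is an ordered sequence of enzyme-catalyzed steps in
which each step consumes a product of the previous one, starting from the
seed compound. The traversal is a depth-first expansion of the written
reaction directions: for every reaction consuming the current compound,
each product spawns an independent continuation (co-products are recorded
on the step but not traversed within the same chain). Chains of every
length between ``min_len`` and ``max_len`` are returned, so requesting
length 3 also yields the length-2 chains, and each returned chain has a
unique ordered EC sequence.

Cycle rule: a chain never revisits a compound already on its own
consumed path (the seed included). Continuations through ubiquitous
currency metabolites (cofactor-regeneration loops) are NOT filtered by
default; pass ``exclude_compounds`` to suppress them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import AbstractSet, Iterable

from .knowledge_base import (
    KnowledgeBase,
    ReactionRecord,
    is_partial_ec,
    reactions_consuming,
)

logger = logging.getLogger(__name__)

DEFAULT_CHAIN_CAP = 10_000


@dataclass(frozen=True)
class ChainStep:
    """One catalytic step: EC number, source reaction, and the compound it
    consumes / the product the chain continues through."""

    ec: str
    reaction_id: str
    consumed: str
    produced: str


@dataclass(frozen=True)
class EnzymeChain:
    """Ordered catalytic steps degrading ``seed``.

    Invariants: ``steps[0].consumed == seed`` and each later step consumes
    the previous step's product.
    """

    seed: str
    steps: tuple[ChainStep, ...]

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("a chain needs at least one step")
        if self.steps[0].consumed != self.seed:
            raise ValueError("first step must consume the seed compound")
        for prev, nxt in zip(self.steps, self.steps[1:]):
            if nxt.consumed != prev.produced:
                raise ValueError(
                    f"broken linkage: step consuming {nxt.consumed} does not "
                    f"follow product {prev.produced}"
                )

    @property
    def length(self) -> int:
        return len(self.steps)

    @property
    def ec_sequence(self) -> tuple[str, ...]:
        return tuple(s.ec for s in self.steps)

    def to_dict(self) -> dict:
        """JSON-serializable form for report writers."""
        return {
            "seed": self.seed,
            "length": self.length,
            "ecs": list(self.ec_sequence),
            "steps": [
                {
                    "ec": s.ec,
                    "reaction_id": s.reaction_id,
                    "consumed": s.consumed,
                    "produced": s.produced,
                }
                for s in self.steps
            ],
        }


@dataclass(frozen=True)
class ChainOrganismSet:
    """Organisms encoding every step of one chain.

    ``organisms`` maps organism code to per-step candidate gene lists
    (one list per chain step, in step order); every listed organism has at
    least one gene for every step.
    """

    chain: EnzymeChain
    organisms: dict[str, tuple[tuple[str, ...], ...]]


def _consuming(
    kb: KnowledgeBase, compound: str, treat_reversible: bool
) -> list[tuple[ReactionRecord, tuple[tuple[str, int], ...]]]:
    """(record, effective products) pairs for reactions usable from ``compound``.

    With ``treat_reversible`` the right-to-left reading is added for
    reactions that list the compound only on the product side.
    """
    out = [(rec, rec.products) for rec in reactions_consuming(kb, compound)]
    if treat_reversible:
        for rid in sorted(kb.reactions_for_compound(compound)):
            rec = kb.reaction(rid)
            if compound in rec.product_ids and compound not in rec.substrate_ids:
                out.append((rec, rec.substrates))
        out.sort(key=lambda pair: pair[0].reaction_id)
    return out


def enumerate_chains(
    kb: KnowledgeBase,
    seed: str,
    max_len: int,
    min_len: int = 2,
    *,
    exclude_compounds: AbstractSet[str] = frozenset(),
    include_partial_ec: bool = False,
    treat_reversible: bool = False,
    chain_cap: int = DEFAULT_CHAIN_CAP,
) -> list[EnzymeChain]:
    """Enumerate unique enzymatic chains of length ``min_len..max_len``.

    Reactions and products are expanded in lexicographic id order so the
    output order is reproducible; chains are deduplicated by their ordered
    EC sequence, keeping the first-found reaction assignment. Partial EC
    numbers (``1.1.1.-``) are excluded from steps unless
    ``include_partial_ec`` is set (they carry no reliable gene linkage).
    Enumeration stops with a warning once ``chain_cap`` chains are
    collected.
    """
    if min_len < 2:
        raise ValueError(f"min_len must be >= 2, got {min_len}")
    if max_len < min_len:
        raise ValueError(f"max_len ({max_len}) must be >= min_len ({min_len})")

    chains: list[EnzymeChain] = []
    seen_ec_seqs: set[tuple[str, ...]] = set()
    capped = False

    def record(steps: tuple[ChainStep, ...]) -> None:
        nonlocal capped
        if capped:
            return
        seq = tuple(s.ec for s in steps)
        if seq in seen_ec_seqs:
            return
        if len(chains) >= chain_cap:
            capped = True
            logger.warning(
                "chain cap of %d reached for seed %s; enumeration truncated",
                chain_cap,
                seed,
            )
            return
        seen_ec_seqs.add(seq)
        chains.append(EnzymeChain(seed=seed, steps=steps))

    def extend(compound: str, path: frozenset[str], steps: tuple[ChainStep, ...]) -> None:
        if capped or len(steps) == max_len:
            return
        for rec, products in _consuming(kb, compound, treat_reversible):
            ecs = sorted(
                ec for ec in rec.ec_numbers if include_partial_ec or not is_partial_ec(ec)
            )
            if not ecs:
                continue
            continuations = sorted(
                cid for cid, _ in products if cid not in path and cid not in exclude_compounds
            )
            for ec in ecs:
                for produced in continuations:
                    step = ChainStep(
                        ec=ec, reaction_id=rec.reaction_id, consumed=compound, produced=produced
                    )
                    new_steps = steps + (step,)
                    if len(new_steps) >= min_len:
                        record(new_steps)
                    extend(produced, path | {produced}, new_steps)

    extend(seed, frozenset({seed}), ())
    return chains


def organisms_with_chain(kb: KnowledgeBase, chain: EnzymeChain) -> ChainOrganismSet:
    """Organisms encoding genes for every step of ``chain``.

    The organism set is the intersection, over steps, of the organisms
    encoding that step's EC; per-step gene lists are preserved. A step
    whose EC has no gene links in the provider makes the intersection
    empty (logged).
    """
    per_step_maps = []
    for step in chain.steps:
        gm = kb.genes_for_ec(step.ec)
        if gm is None:
            logger.info(
                "EC %s (chain %s) has no gene links; no organism encodes the full chain",
                step.ec,
                "->".join(chain.ec_sequence),
            )
            return ChainOrganismSet(chain=chain, organisms={})
        per_step_maps.append(gm)

    shared: set[str] = set(per_step_maps[0].organisms)
    for gm in per_step_maps[1:]:
        shared &= gm.organisms

    organisms = {
        org: tuple(tuple(gm.genes_by_organism[org]) for gm in per_step_maps)
        for org in sorted(shared)
    }
    return ChainOrganismSet(chain=chain, organisms=organisms)
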