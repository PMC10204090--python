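"""Compound/reaction/enzyme knowledge base.

Houses the reaction graph and enzyme-to-gene links that chain enumeration
walks. The data model mirrors the flat-file dialect of the KEGG COMPOUND,
REACTION and ENZYME databases: compounds are ``C`` + 5 digits, reactions
carry an equation string (``substrates <=> products``) plus EC numbers, and
each EC maps to the organisms and genes that encode it.

Access goes through the :class:`KnowledgeBase` provider contract so the
same traversal code runs against local fixture dumps or, in principle, a
live REST-backed provider. All lookups are pure; an unknown compound is a
"no biology" answer (empty result plus a logged notice) while malformed
records are hard errors.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Standard compound identifier: C followed by five digits. Synthetic
#: fixture identifiers use a CX prefix and are accepted everywhere.
COMPOUND_ID_RE = re.compile(r"^(C\d{5}|CX\w+)$")

#: Reaction identifier: R followed by five digits, or a fixture code.
REACTION_ID_RE = re.compile(r"^(R\d{5}|RX?\w+)$")

#: Full EC number (four numeric fields); partial ECs replace trailing
#: fields with "-".
EC_RE = re.compile(r"^\d+\.(\d+|-)\.(\d+|-)\.(\d+|-)$")


class KnowledgeBaseError(Exception):
    """Base class for knowledge-base failures."""


class EquationParseError(KnowledgeBaseError):
    """A reaction equation string could not be parsed."""


class DumpLoadError(KnowledgeBaseError):
    """A flat-file dump directory is missing or malformed."""


class UnknownReactionError(KeyError, KnowledgeBaseError):
    """Lookup of a reaction id that is not in the provider."""


def is_valid_compound_id(compound_id: str) -> bool:
    return bool(COMPOUND_ID_RE.match(compound_id))


def is_partial_ec(ec: str) -> bool:
    """True for ECs with unresolved fields, e.g. ``1.1.1.-``."""
    return "-" in ec


@dataclass(frozen=True)
class ReactionRecord:
    """One directed biochemical reaction as written in the source record.

    ``substrates`` and ``products`` keep the written left/right sides with
    integer stoichiometric coefficients. A compound appearing on both sides
    is retained verbatim and listed in ``both_side_compounds`` so callers
    can flag it.
    """

    reaction_id: str
    substrates: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    ec_numbers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.substrates or not self.products:
            raise ValueError(
                f"reaction {self.reaction_id}: substrates and products must be non-empty"
            )
        for cid, coeff in (*self.substrates, *self.products):
            if coeff < 1:
                raise ValueError(
                    f"reaction {self.reaction_id}: coefficient of {cid} must be >= 1"
                )

    @property
    def substrate_ids(self) -> tuple[str, ...]:
        return tuple(cid for cid, _ in self.substrates)

    @property
    def product_ids(self) -> tuple[str, ...]:
        return tuple(cid for cid, _ in self.products)

    @property
    def both_side_compounds(self) -> frozenset[str]:
        return frozenset(self.substrate_ids) & frozenset(self.product_ids)

    @property
    def is_flagged(self) -> bool:
        """True when a compound appears on both sides as written."""
        return bool(self.both_side_compounds)


@dataclass(frozen=True)
class EnzymeGeneMap:
    """Genes encoding one EC number, keyed by organism code.

    Organism codes are lowercase KEGG-style 3-4 letter codes; every listed
    organism maps to at least one gene identifier (locus-tag-like string).
    """

    ec: str
    genes_by_organism: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for org, genes in self.genes_by_organism.items():
            if not genes:
                raise ValueError(f"EC {self.ec}: organism {org} maps to zero genes")

    @property
    def organisms(self) -> frozenset[str]:
        return frozenset(self.genes_by_organism)


_EQ_SEPARATOR = "<=>"
_TERM_RE = re.compile(r"^(?:(\d+)\s+)?(\S+)$")


def parse_reaction_equation(text: str) -> tuple[list[tuple[str, int]], list[tuple[str, int]]]:
    """Parse a reaction equation into (substrates, products) with coefficients.

    The dialect joins terms with ``+`` and separates sides with ``<=>``;
    an optional leading integer is the stoichiometric coefficient
    (default 1), e.g. ``"2 C00001 + C90001 <=> C90002"``.

    Raises :class:`EquationParseError` if the separator count is not
    exactly one, a side is empty, or a term is malformed.
    """
    if text.count(_EQ_SEPARATOR) != 1:
        raise EquationParseError(
            f"equation must contain exactly one '{_EQ_SEPARATOR}': {text!r}"
        )
    left, right = text.split(_EQ_SEPARATOR)
    sides = []
    for side_name, side in (("substrate", left), ("product", right)):
        side = side.strip()
        if not side:
            raise EquationParseError(f"empty {side_name} side in equation {text!r}")
        terms = []
        for raw in side.split("+"):
            raw = raw.strip()
            m = _TERM_RE.match(raw)
            if not m:
                raise EquationParseError(
                    f"malformed term {raw!r} on {side_name} side of {text!r}"
                )
            coeff = int(m.group(1)) if m.group(1) else 1
            terms.append((m.group(2), coeff))
        sides.append(terms)
    return sides[0], sides[1]


def format_reaction_equation(record: ReactionRecord) -> str:
    """Inverse of :func:`parse_reaction_equation` (coefficient 1 implicit)."""

    def side(terms: Sequence[tuple[str, int]]) -> str:
        return " + ".join(cid if c == 1 else f"{c} {cid}" for cid, c in terms)

    return f"{side(record.substrates)} {_EQ_SEPARATOR} {side(record.products)}"


class KnowledgeBase:
    """In-memory provider over compounds, reactions and enzyme-gene links.

    Satisfies the provider contract used by chain enumeration:

    - ``reactions_for_compound(cid)`` -- ids of all reactions mentioning
      the compound on either side;
    - ``reaction(rid)`` -- the :class:`ReactionRecord`, or
      :class:`UnknownReactionError`;
    - ``genes_for_ec(ec)`` -- the :class:`EnzymeGeneMap`, or ``None``.

    Lookups are pure within a session.
    """

    def __init__(self) -> None:
        self._reactions: dict[str, ReactionRecord] = {}
        self._by_compound: dict[str, set[str]] = {}
        self._enzymes: dict[str, EnzymeGeneMap] = {}
        self._compound_names: dict[str, str] = {}

    # -- construction -------------------------------------------------
    def add_compound(self, compound_id: str, name: str = "") -> None:
        if not is_valid_compound_id(compound_id):
            raise KnowledgeBaseError(f"invalid compound id {compound_id!r}")
        self._compound_names[compound_id] = name
        self._by_compound.setdefault(compound_id, set())

    def add_reaction(self, record: ReactionRecord, *, source: str = "<memory>") -> None:
        if record.reaction_id in self._reactions:
            raise DumpLoadError(
                f"duplicate reaction id {record.reaction_id}: already loaded, "
                f"second definition from {source}"
            )
        self._reactions[record.reaction_id] = record
        for cid in (*record.substrate_ids, *record.product_ids):
            self._by_compound.setdefault(cid, set()).add(record.reaction_id)
        if record.is_flagged:
            logger.warning(
                "reaction %s lists compound(s) %s on both sides; retained and flagged",
                record.reaction_id,
                ",".join(sorted(record.both_side_compounds)),
            )

    def add_enzyme(self, ec: str, organism: str, genes: Iterable[str]) -> None:
        genes = tuple(genes)
        if not EC_RE.match(ec):
            raise KnowledgeBaseError(f"invalid EC number {ec!r}")
        existing = self._enzymes.get(ec)
        merged = dict(existing.genes_by_organism) if existing else {}
        merged[organism] = tuple(dict.fromkeys((*merged.get(organism, ()), *genes)))
        self._enzymes[ec] = EnzymeGeneMap(ec=ec, genes_by_organism=merged)

    # -- provider contract --------------------------------------------
    def knows_compound(self, compound_id: str) -> bool:
        return compound_id in self._by_compound

    def reactions_for_compound(self, compound_id: str) -> frozenset[str]:
        """All reaction ids in which the compound appears on either side."""
        if compound_id not in self._by_compound:
            logger.info("compound %s not found in knowledge base", compound_id)
            return frozenset()
        return frozenset(self._by_compound[compound_id])

    def reaction(self, reaction_id: str) -> ReactionRecord:
        try:
            return self._reactions[reaction_id]
        except KeyError:
            raise UnknownReactionError(reaction_id) from None

    def genes_for_ec(self, ec: str) -> EnzymeGeneMap | None:
        """Gene links for one EC; ``None`` signals an explicit not-found."""
        return self._enzymes.get(ec)

    @property
    def reaction_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self._reactions))

    @property
    def ec_numbers(self) -> tuple[str, ...]:
        return tuple(sorted(self._enzymes))

    @property
    def compound_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self._by_compound))

    def compound_name(self, compound_id: str) -> str:
        return self._compound_names.get(compound_id, "")


def reactions_consuming(kb: KnowledgeBase, compound_id: str) -> list[ReactionRecord]:
    """Reactions with the compound on the substrate (left) side as written.

    The directional rule is strict: a reaction listing the compound only
    as a product is excluded. This is what makes the traversal miss
    compounds that the source database writes exclusively as products (the
    documented behavior for R-mandelate, which appears only as the product
    of its racemase). A compound appearing on both sides of one reaction is
    included (and the record carries the flag).

    An unknown compound yields an empty list plus a logged notice -- the
    absence of reactions means "no chains", not failure.
    """
    out = []
    for rid in sorted(kb.reactions_for_compound(compound_id)):
        rec = kb.reaction(rid)
        if compound_id in rec.substrate_ids:
            out.append(rec)
    return out


# -- flat-file dump dialect -------------------------------------------
#
# Three UTF-8 TSV files with header rows:
#   compounds.tsv  compound_id, name, reaction_ids (semicolon-joined)
#   reactions.tsv  reaction_id, equation, ec_numbers (semicolon-joined)
#   enzymes.tsv    ec, organism_code, gene_ids (space-joined); one row per
#                  ec-organism pair.

_DUMP_FILES = ("compounds.tsv", "reactions.tsv", "enzymes.tsv")


def load_kegg_dump(dir_path: str | Path) -> KnowledgeBase:
    """Load a flat-file snapshot directory into a :class:`KnowledgeBase`.

    Raises :class:`DumpLoadError` on a missing mandatory file or a
    duplicate reaction id (naming both sources).
    """
    dir_path = Path(dir_path)
    missing = [f for f in _DUMP_FILES if not (dir_path / f).is_file()]
    if missing:
        raise DumpLoadError(
            f"dump directory {dir_path} is missing mandatory file(s): {', '.join(missing)}"
        )
    kb = KnowledgeBase()

    compounds = pd.read_csv(dir_path / "compounds.tsv", sep="\t", dtype=str).fillna("")
    _require_columns(compounds, ["compound_id", "name"], dir_path / "compounds.tsv")
    for row in compounds.itertuples(index=False):
        kb.add_compound(row.compound_id, row.name)

    reactions = pd.read_csv(dir_path / "reactions.tsv", sep="\t", dtype=str).fillna("")
    _require_columns(
        reactions, ["reaction_id", "equation", "ec_numbers"], dir_path / "reactions.tsv"
    )
    for i, row in enumerate(reactions.itertuples(index=False)):
        substrates, products = parse_reaction_equation(row.equation)
        ecs = tuple(e for e in row.ec_numbers.split(";") if e)
        rec = ReactionRecord(
            reaction_id=row.reaction_id,
            substrates=tuple(substrates),
            products=tuple(products),
            ec_numbers=ecs,
        )
        kb.add_reaction(rec, source=f"{dir_path / 'reactions.tsv'} row {i + 2}")

    enzymes = pd.read_csv(dir_path / "enzymes.tsv", sep="\t", dtype=str).fillna("")
    _require_columns(enzymes, ["ec", "organism_code", "gene_ids"], dir_path / "enzymes.tsv")
    for row in enzymes.itertuples(index=False):
        genes = [g for g in row.gene_ids.split(" ") if g]
        if not genes:
            raise DumpLoadError(
                f"enzymes.tsv: EC {row.ec} / organism {row.organism_code} lists no genes"
            )
        kb.add_enzyme(row.ec, row.organism_code, genes)

    logger.info(
        "loaded knowledge base from %s: %d compounds, %d reactions, %d ECs",
        dir_path,
        len(kb.compound_ids),
        len(kb.reaction_ids),
        len(kb.ec_numbers),
    )
    return kb


def write_kegg_dump(kb: KnowledgeBase, dir_path: str | Path) -> None:
    """Write a :class:`KnowledgeBase` back to the flat-file dialect.

    Round-trips: reloading the written directory yields identical lookup
    results for every key.
    """
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)

    comp_rows = []
    for cid in kb.compound_ids:
        rids = ";".join(sorted(kb.reactions_for_compound(cid)))
        comp_rows.append((cid, kb.compound_name(cid), rids))
    pd.DataFrame(comp_rows, columns=["compound_id", "name", "reaction_ids"]).to_csv(
        dir_path / "compounds.tsv", sep="\t", index=False
    )

    rxn_rows = []
    for rid in kb.reaction_ids:
        rec = kb.reaction(rid)
        rxn_rows.append((rid, format_reaction_equation(rec), ";".join(rec.ec_numbers)))
    pd.DataFrame(rxn_rows, columns=["reaction_id", "equation", "ec_numbers"]).to_csv(
        dir_path / "reactions.tsv", sep="\t", index=False
    )

    enz_rows = []
    for ec in kb.ec_numbers:
        gm = kb.genes_for_ec(ec)
        assert gm is not None
        for org in sorted(gm.genes_by_organism):
            enz_rows.append((ec, org, " ".join(gm.genes_by_organism[org])))
    pd.DataFrame(enz_rows, columns=["ec", "organism_code", "gene_ids"]).to_csv(
        dir_path / "enzymes.tsv", sep="\t", index=False
    )


def _require_columns(df: pd.DataFrame, cols: Sequence[str], source: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DumpLoadError(f"{source}: missing mandatory column(s): {', '.join(missing)}")
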