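"""Divergent-regulator search and proximity scoring.

The biosensor model rewards the classic divergent architecture: a
transcriptional regulator gene transcribed away from the catabolic operon
from a shared intergenic region. Regulator genes are recognized by
case-insensitive keyword search in the annotation column (default
keywords: "regulator", "activator", "repressor").

The proximity score starts at 0 for a regulator adjacent to the operon's
upstream gene and deducts integer points per intervening gene: 1 point if
the intervening gene shares the operon's strand (it may simply be an
unrecognized operon member), 2 points if it shares the regulator's
strand. Scores are clamped to the predefined floor of -500; higher scores
indicate a higher likelihood that the regulator controls the operon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .chains import EnzymeChain
from .genome import FeatureTable, GeneFeature, OperonCandidate

logger = logging.getLogger(__name__)

DEFAULT_KEYWORDS = ("regulator", "activator", "repressor")
SCORE_FLOOR = -500


@dataclass(frozen=True)
class RegulatorCandidate:
    """A keyword-matched regulator gene divergent from an operon.

    ``distance_genes`` counts the genes strictly between the regulator and
    the operon's upstream member (0 = adjacent).
    """

    gene: GeneFeature
    matched_keyword: str
    distance_genes: int


@dataclass(frozen=True)
class BiosensorCandidate:
    """An operon-regulator pair with its proximity score (in [-500, 0])."""

    organism_code: str
    chain: EnzymeChain
    operon: OperonCandidate
    regulator: RegulatorCandidate
    score: int

    def __post_init__(self) -> None:
        if not (SCORE_FLOOR <= self.score <= 0):
            raise ValueError(f"score {self.score} outside [{SCORE_FLOOR}, 0]")


def is_regulator_annotation(text: str, keywords: Sequence[str] = DEFAULT_KEYWORDS) -> bool:
    """True iff any keyword is a case-insensitive substring of ``text``."""
    low = text.casefold()
    return any(kw.casefold() in low for kw in keywords)


def _matched_keyword(text: str, keywords: Sequence[str]) -> str:
    low = text.casefold()
    for kw in keywords:
        if kw.casefold() in low:
            return kw
    raise ValueError("no keyword matched")  # pragma: no cover - guarded by caller


def _scan(
    genes: list[GeneFeature],
    start_index: int,
    direction: int,
    operon_strand: str,
    keywords: Sequence[str],
) -> RegulatorCandidate | None:
    """Walk gene indices from ``start_index`` in ``direction`` until a
    divergent keyword-matched gene is found or the replicon ends."""
    i = start_index + direction
    walked = 0
    while 0 <= i < len(genes):
        gene = genes[i]
        if gene.strand != operon_strand and is_regulator_annotation(gene.annotation, keywords):
            return RegulatorCandidate(
                gene=gene,
                matched_keyword=_matched_keyword(gene.annotation, keywords),
                distance_genes=walked,
            )
        walked += 1
        i += direction
    return None


def find_nearest_divergent_regulator(
    table: FeatureTable,
    operon: OperonCandidate,
    keywords: Sequence[str] = DEFAULT_KEYWORDS,
    *,
    search_both_sides: bool = False,
) -> RegulatorCandidate | None:
    """Nearest opposite-strand regulator on the operon's promoter side.

    The scan proceeds upstream of the operon's 5' member (decreasing gene
    index for a ``+`` strand operon, increasing for ``-``) -- the side a
    divergent promoter would occupy -- and returns the first gene that is
    both on the opposite strand and keyword-matched. ``search_both_sides``
    additionally scans downstream of the 3' member; an equidistant tie
    prefers the upstream side, then the lower start coordinate.
    """
    genes = table.replicons[operon.replicon]
    upstream_dir = -1 if operon.strand == "+" else +1
    hit = _scan(genes, operon.upstream_gene.index, upstream_dir, operon.strand, keywords)
    if not search_both_sides:
        return hit

    three_prime = operon.member_genes[-1] if operon.strand == "+" else operon.member_genes[0]
    down = _scan(genes, three_prime.index, -upstream_dir, operon.strand, keywords)
    if hit is None:
        return down
    if down is None or hit.distance_genes <= down.distance_genes:
        return hit
    return down


def score_pair(
    operon: OperonCandidate,
    regulator: RegulatorCandidate,
    table: FeatureTable,
    score_floor: int = SCORE_FLOOR,
) -> int:
    """Proximity score for one operon-regulator pair.

    0 minus 1 per intervening gene on the operon's strand and 2 per
    intervening gene on the regulator's strand, clamped to
    ``score_floor``. Intervening genes are those whose gene index lies
    strictly between the regulator's and the upstream member's (CDS
    features only -- the only features loaded).
    """
    return max(score_floor, -_deduction(operon, regulator, table))


def raw_deduction(
    operon: OperonCandidate, regulator: RegulatorCandidate, table: FeatureTable
) -> int:
    """Unclamped total deduction (used by the pipeline's floor cut)."""
    return _deduction(operon, regulator, table)


def _deduction(
    operon: OperonCandidate, regulator: RegulatorCandidate, table: FeatureTable
) -> int:
    genes = table.replicons[operon.replicon]
    lo, hi = sorted((regulator.gene.index, operon.upstream_gene.index))
    total = 0
    for gene in genes[lo + 1 : hi]:
        total += 1 if gene.strand == operon.strand else 2
    return total
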