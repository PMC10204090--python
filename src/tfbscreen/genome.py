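"""Genome feature tables and operon detection.

Genomes are consumed as NCBI-Assembly-style tab-delimited feature tables
(``*_feature_table.txt``): one row per feature with genomic accession,
1-based inclusive coordinates, strand, locus tag and product name. Only
CDS rows are retained. Per replicon, features are sorted by start and
given a dense gene index 0..n-1; all proximity logic (operon gaps,
regulator distances, proximity scores) counts in gene-index space, not
base pairs.

An operon candidate is a set of chain genes that share a replicon and
strand and sit within ``gap_tolerance`` intervening genes of one another.
The member at the 5' end relative to the strand (smallest start on ``+``,
largest end on ``-``) is the operon's upstream gene -- the promoter side
used for regulator search and scoring.
"""

from __future__ import annotations

import io
import itertools
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Sequence

import pandas as pd

from .chains import EnzymeChain

logger = logging.getLogger(__name__)

DEFAULT_GAP_TOLERANCE = 2
DEFAULT_ASSIGNMENT_CAP = 50
#: Hard bound on enumerated gene-copy combinations before span sorting.
_COMBINATION_ENUMERATION_LIMIT = 10_000


class FeatureTableError(Exception):
    """A feature table stream is malformed."""


@dataclass(frozen=True)
class GeneFeature:
    """One annotated CDS.

    Coordinates are 1-based inclusive (feature-table convention); strand
    is ``"+"`` or ``"-"``; ``index`` is the gene's dense position within
    its replicon after sorting by start.
    """

    genomic_accession: str
    start: int
    end: int
    strand: str
    locus_tag: str
    annotation: str
    index: int = -1

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"{self.locus_tag}: start must be >= 1")
        if self.end < self.start:
            raise ValueError(f"{self.locus_tag}: end ({self.end}) < start ({self.start})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.locus_tag}: strand must be '+' or '-', got {self.strand!r}")


@dataclass
class FeatureTable:
    """One genome's CDS features, grouped per replicon and index-sorted."""

    organism_code: str
    assembly_accession: str
    replicons: dict[str, list[GeneFeature]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._by_locus: dict[str, GeneFeature] = {}
        for acc in list(self.replicons):
            feats = sorted(self.replicons[acc], key=lambda f: (f.start, f.end, f.locus_tag))
            self.replicons[acc] = [replace(f, index=i) for i, f in enumerate(feats)]
            for f in self.replicons[acc]:
                key = f.locus_tag.casefold()
                if key in self._by_locus:
                    raise FeatureTableError(
                        f"duplicate locus_tag {f.locus_tag!r} in table for "
                        f"{self.organism_code or self.assembly_accession}"
                    )
                self._by_locus[key] = f

    def find_locus_tag(self, gene_id: str) -> GeneFeature | None:
        """Case-insensitive exact locus-tag lookup."""
        return self._by_locus.get(gene_id.casefold())

    @property
    def n_genes(self) -> int:
        return sum(len(v) for v in self.replicons.values())


_MANDATORY_COLUMNS = ("feature", "genomic_accession", "start", "end", "strand", "locus_tag")
_ANNOTATION_COLUMNS = ("name", "product")
_STRAND_MAP = {"+": "+", "-": "-", "−": "-"}  # tolerate unicode minus


def parse_feature_table(
    source: str | Path | IO[str],
    organism_code: str = "",
    assembly_accession: str = "",
) -> FeatureTable:
    """Parse an NCBI-style feature table into a :class:`FeatureTable`.

    The header row may carry the conventional leading ``# `` (as in
    ``# feature``). Only CDS rows are kept; rows without a locus tag are
    dropped with a logged count. Missing mandatory columns raise
    :class:`FeatureTableError` listing them.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            return parse_feature_table(fh, organism_code, assembly_accession)

    header = source.readline()
    if header.startswith("# "):
        header = header[2:]
    elif header.startswith("#"):
        header = header[1:]
    df = pd.read_csv(
        io.StringIO(header + source.read()), sep="\t", dtype=str, keep_default_na=False
    )

    missing = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    annotation_col = next((c for c in _ANNOTATION_COLUMNS if c in df.columns), None)
    if annotation_col is None:
        missing.append("name|product")
    if missing:
        raise FeatureTableError(f"feature table missing mandatory column(s): {', '.join(missing)}")

    cds = df[df["feature"] == "CDS"]
    n_missing_tag = int((cds["locus_tag"] == "").sum())
    if n_missing_tag:
        logger.info("dropped %d CDS row(s) lacking a locus_tag", n_missing_tag)
        cds = cds[cds["locus_tag"] != ""]

    replicons: dict[str, list[GeneFeature]] = {}
    for row in cds.itertuples(index=False):
        strand = _STRAND_MAP.get(getattr(row, "strand"))
        if strand is None:
            raise FeatureTableError(f"unrecognized strand symbol {getattr(row, 'strand')!r}")
        feat = GeneFeature(
            genomic_accession=row.genomic_accession,
            start=int(row.start),
            end=int(row.end),
            strand=strand,
            locus_tag=row.locus_tag,
            annotation=getattr(row, annotation_col),
        )
        replicons.setdefault(feat.genomic_accession, []).append(feat)

    return FeatureTable(
        organism_code=organism_code,
        assembly_accession=assembly_accession,
        replicons=replicons,
    )


@dataclass(frozen=True)
class OperonCandidate:
    """A chain's genes arranged as a plausible operon.

    ``member_genes`` are in genomic order, which need not equal chain
    step order; ``upstream_gene`` is the 5'-most member relative to the
    shared strand.
    """

    replicon: str
    member_genes: tuple[GeneFeature, ...]
    strand: str
    upstream_gene: GeneFeature
    chain: EnzymeChain


def locate_chain_genes(
    table: FeatureTable,
    per_step_gene_ids: Sequence[Sequence[str]],
    cap: int = DEFAULT_ASSIGNMENT_CAP,
) -> list[tuple[GeneFeature, ...]]:
    """Map per-step gene ids onto feature-table loci.

    Returns one assignment (a tuple of features, one per chain step) per
    combination of gene copies, ordered by genomic span ascending
    (assignments spread over several replicons sort last) and capped at
    ``cap`` with a warning. A step with zero matching locus tags yields an
    empty list.
    """
    per_step_feats: list[list[GeneFeature]] = []
    for step_ids in per_step_gene_ids:
        feats = []
        for gid in step_ids:
            f = table.find_locus_tag(gid)
            if f is None:
                logger.debug(
                    "gene id %s not found as locus_tag in %s",
                    gid,
                    table.organism_code or table.assembly_accession,
                )
            else:
                feats.append(f)
        if not feats:
            return []
        per_step_feats.append(sorted(feats, key=lambda f: f.locus_tag))

    assignments = []
    for combo in itertools.product(*per_step_feats):
        assignments.append(combo)
        if len(assignments) > _COMBINATION_ENUMERATION_LIMIT:
            logger.warning(
                "gene-copy combinations exceed %d in %s; enumeration truncated",
                _COMBINATION_ENUMERATION_LIMIT,
                table.organism_code or table.assembly_accession,
            )
            break

    def span(combo: tuple[GeneFeature, ...]) -> float:
        if len({f.genomic_accession for f in combo}) > 1:
            return math.inf
        return max(f.end for f in combo) - min(f.start for f in combo)

    assignments.sort(key=lambda c: (span(c), tuple(f.locus_tag for f in c)))
    if len(assignments) > cap:
        logger.warning(
            "capping %d gene-copy assignments to %d (tightest span kept)",
            len(assignments),
            cap,
        )
        assignments = assignments[:cap]
    return assignments


def detect_operon(
    assignment: Sequence[GeneFeature],
    chain: EnzymeChain,
    gap_tolerance: int = DEFAULT_GAP_TOLERANCE,
    *,
    require_collinear: bool = False,
) -> OperonCandidate | None:
    """Decide whether one gene assignment forms a plausible operon.

    Requires all genes on one replicon and one strand, pairwise distinct,
    with at most ``gap_tolerance`` non-member genes between genomic
    neighbors. With ``require_collinear`` the genomic order of members
    must additionally follow chain step order (5' to 3'). The decision is
    invariant to the input order of the assignment.
    """
    genes = list(assignment)
    if len({f.locus_tag.casefold() for f in genes}) != len(genes):
        return None
    if len({f.genomic_accession for f in genes}) != 1:
        return None
    if len({f.strand for f in genes}) != 1:
        return None
    strand = genes[0].strand

    in_genomic_order = sorted(genes, key=lambda f: f.index)
    for a, b in zip(in_genomic_order, in_genomic_order[1:]):
        if b.index - a.index - 1 > gap_tolerance:
            return None

    if require_collinear:
        step_order = list(genes)  # input order == chain step order
        expected = step_order if strand == "+" else list(reversed(step_order))
        if [f.locus_tag for f in in_genomic_order] != [f.locus_tag for f in expected]:
            return None

    upstream = in_genomic_order[0] if strand == "+" else in_genomic_order[-1]
    return OperonCandidate(
        replicon=genes[0].genomic_accession,
        member_genes=tuple(in_genomic_order),
        strand=strand,
        upstream_gene=upstream,
        chain=chain,
    )


# -- organism map ------------------------------------------------------


def load_organism_map(path: str | Path) -> dict[str, tuple[str, Path]]:
    """Load the organism-code -> (assembly accession, feature-table path) map.

    TSV with header columns ``organism_code``, ``assembly_accession``,
    ``feature_table_path``; relative paths resolve against the map file's
    directory.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["organism_code", "assembly_accession", "feature_table_path"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FeatureTableError(
            f"organism map {path}: missing mandatory column(s): {', '.join(missing)}"
        )
    out: dict[str, tuple[str, Path]] = {}
    for row in df.itertuples(index=False):
        p = Path(row.feature_table_path)
        if not p.is_absolute():
            p = path.parent / p
        out[row.organism_code] = (row.assembly_accession, p)
    return out
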