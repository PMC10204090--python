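"""End-to-end mining orchestration and report writing.

A mine run takes a seed compound and a maximum chain length, enumerates
the catabolic enzyme chains, finds the organisms encoding each chain,
screens their genomes for operon arrangements, attaches the nearest
divergent regulator and writes one ranked CSV per chain that produced at
least one biosensor candidate. Runs are deterministic given fixed inputs:
rerunning the same configuration produces byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .chains import (
    DEFAULT_CHAIN_CAP,
    EnzymeChain,
    enumerate_chains,
    organisms_with_chain,
)
from .genome import (
    DEFAULT_ASSIGNMENT_CAP,
    DEFAULT_GAP_TOLERANCE,
    FeatureTable,
    detect_operon,
    load_organism_map,
    locate_chain_genes,
    parse_feature_table,
)
from .knowledge_base import is_valid_compound_id, load_kegg_dump
from .scoring import (
    DEFAULT_KEYWORDS,
    SCORE_FLOOR,
    BiosensorCandidate,
    find_nearest_divergent_regulator,
    raw_deduction,
)

logger = logging.getLogger(__name__)

OUTPUT_COLUMNS = (
    "organism_code",
    "assembly_accession",
    "replicon",
    "enzyme_locus_tags",
    "regulator_locus_tag",
    "regulator_annotation",
    "score",
)


class ConfigError(ValueError):
    """A mine configuration is invalid (bad ranges or missing paths)."""


@dataclass
class MineConfig:
    """Configuration of one mine run."""

    seed_compound: str
    kb_path: Path
    genomes_dir: Path
    organism_map_path: Path
    out_dir: Path
    max_len: int = 3
    min_len: int = 2
    gap_tolerance: int = DEFAULT_GAP_TOLERANCE
    keywords: tuple[str, ...] = DEFAULT_KEYWORDS
    score_floor: int = SCORE_FLOOR
    combination_cap: int = DEFAULT_ASSIGNMENT_CAP
    chain_cap: int = DEFAULT_CHAIN_CAP
    treat_reversible: bool = False
    require_collinear: bool = False
    search_both_sides: bool = False
    exclude_compounds: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.kb_path = Path(self.kb_path)
        self.genomes_dir = Path(self.genomes_dir)
        self.organism_map_path = Path(self.organism_map_path)
        self.out_dir = Path(self.out_dir)
        if not is_valid_compound_id(self.seed_compound):
            raise ConfigError(f"invalid seed compound id {self.seed_compound!r}")
        if self.min_len < 2:
            raise ConfigError("min_len must be >= 2")
        if self.max_len < self.min_len:
            raise ConfigError("max_len must be >= min_len")
        if self.gap_tolerance < 0:
            raise ConfigError("gap_tolerance must be >= 0")
        if self.score_floor > 0:
            raise ConfigError("score_floor must be <= 0")
        if not self.keywords:
            raise ConfigError("keyword list must not be empty")
        for p, label in (
            (self.kb_path, "knowledge base directory"),
            (self.genomes_dir, "genomes directory"),
            (self.organism_map_path, "organism map"),
        ):
            if not p.exists():
                raise ConfigError(f"{label} not found: {p}")


@dataclass
class MineSummary:
    """Counts and outputs of one mine run."""

    seed_compound: str
    chains_enumerated: int
    chains_with_output: int
    candidates_total: int
    output_files: list[Path] = field(default_factory=list)


def rank_candidates(candidates: Sequence[BiosensorCandidate]) -> list[BiosensorCandidate]:
    """Descending score; ties by organism code then regulator locus tag."""
    return sorted(
        candidates,
        key=lambda c: (-c.score, c.organism_code, c.regulator.gene.locus_tag),
    )


def chain_output_name(chain: EnzymeChain) -> str:
    """``<seed>_len<k>_<EC1>_<EC2>[...].csv`` -- unique per chain because
    EC sequences are unique among enumerated chains."""
    ecs = "_".join(chain.ec_sequence)
    return f"{chain.seed}_len{chain.length}_{ecs}.csv"


def candidates_for_chain(
    chain: EnzymeChain,
    organisms: dict[str, tuple[tuple[str, ...], ...]],
    tables: dict[str, FeatureTable],
    config: MineConfig,
) -> list[BiosensorCandidate]:
    """Screen every organism encoding ``chain`` for operon-regulator pairs."""
    candidates: list[BiosensorCandidate] = []
    seen: set[tuple] = set()
    for org in sorted(organisms):
        table = tables.get(org)
        if table is None:
            continue
        assignments = locate_chain_genes(table, organisms[org], cap=config.combination_cap)
        for assignment in assignments:
            operon = detect_operon(
                assignment,
                chain,
                gap_tolerance=config.gap_tolerance,
                require_collinear=config.require_collinear,
            )
            if operon is None:
                continue
            regulator = find_nearest_divergent_regulator(
                table,
                operon,
                keywords=config.keywords,
                search_both_sides=config.search_both_sides,
            )
            if regulator is None:
                continue
            deduction = raw_deduction(operon, regulator, table)
            if -deduction < config.score_floor:
                logger.debug(
                    "dropping %s candidate in %s: deduction %d exceeds floor %d",
                    "->".join(chain.ec_sequence),
                    org,
                    deduction,
                    config.score_floor,
                )
                continue
            key = (
                org,
                operon.replicon,
                tuple(g.locus_tag for g in operon.member_genes),
                regulator.gene.locus_tag,
            )
            if key in seen:
                continue
            seen.add(key)
            candidates.append(
                BiosensorCandidate(
                    organism_code=org,
                    chain=chain,
                    operon=operon,
                    regulator=regulator,
                    score=-deduction,
                )
            )
    return rank_candidates(candidates)


def _candidate_row(c: BiosensorCandidate, table: FeatureTable) -> dict:
    return {
        "organism_code": c.organism_code,
        "assembly_accession": table.assembly_accession,
        "replicon": c.operon.replicon,
        "enzyme_locus_tags": ";".join(g.locus_tag for g in c.operon.member_genes),
        "regulator_locus_tag": c.regulator.gene.locus_tag,
        "regulator_annotation": c.regulator.gene.annotation,
        "score": c.score,
    }


def mine(config: MineConfig) -> MineSummary:
    """Run the full mining workflow and write one CSV per productive chain.

    An organism whose genome cannot be read is skipped with a logged
    warning; the run continues. Returns a :class:`MineSummary` with the
    chain and candidate counts.
    """
    kb = load_kegg_dump(config.kb_path)
    chains = enumerate_chains(
        kb,
        config.seed_compound,
        config.max_len,
        config.min_len,
        exclude_compounds=config.exclude_compounds,
        treat_reversible=config.treat_reversible,
        chain_cap=config.chain_cap,
    )
    logger.info("enumerated %d chain(s) from seed %s", len(chains), config.seed_compound)

    org_map = load_organism_map(config.organism_map_path)

    # load each referenced genome once
    tables: dict[str, FeatureTable] = {}
    needed_orgs: set[str] = set()
    chain_orgs = []
    for chain in chains:
        cos = organisms_with_chain(kb, chain)
        chain_orgs.append(cos)
        needed_orgs.update(cos.organisms)
    for org in sorted(needed_orgs):
        if org not in org_map:
            logger.warning("organism %s has no genome in the organism map; skipped", org)
            continue
        assembly, path = org_map[org]
        try:
            tables[org] = parse_feature_table(path, organism_code=org, assembly_accession=assembly)
        except Exception as exc:  # noqa: BLE001 - skip-and-continue contract
            logger.warning("genome for %s unreadable (%s); skipped", org, exc)
    logger.info("loaded %d genome(s) for %d organism(s)", len(tables), len(needed_orgs))

    config.out_dir.mkdir(parents=True, exist_ok=True)
    summary = MineSummary(
        seed_compound=config.seed_compound,
        chains_enumerated=len(chains),
        chains_with_output=0,
        candidates_total=0,
    )
    for chain, cos in zip(chains, chain_orgs):
        candidates = candidates_for_chain(chain, cos.organisms, tables, config)
        if not candidates:
            continue
        rows = [_candidate_row(c, tables[c.organism_code]) for c in candidates]
        out_path = config.out_dir / chain_output_name(chain)
        pd.DataFrame(rows, columns=list(OUTPUT_COLUMNS)).to_csv(
            out_path, index=False, lineterminator="\n"
        )
        summary.chains_with_output += 1
        summary.candidates_total += len(candidates)
        summary.output_files.append(out_path)
        logger.info(
            "chain %s: %d candidate(s) -> %s",
            "->".join(chain.ec_sequence),
            len(candidates),
            out_path.name,
        )
    return summary
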