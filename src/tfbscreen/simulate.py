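"""Synthetic inputs: fixture knowledge bases, genomes with planted
operon-regulator arrangements, and noisy dose-response datasets.

Everything the test surface consumes is generated here, deterministically
per seed, in the same dump/feature-table/CSV dialects the other modules
read. Simulated genomes contain only coordinates, strands, locus tags and
annotation strings -- no sequence content -- because that is all the
operon/regulator logic consumes.

Decoy annotations come from a keyword-free enzyme vocabulary so that
negative-control genomes cannot produce false keyword hits by
construction; a separate adversarial pool contains regulator-like decoys
for stress tests.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dose_response import CSV_COLUMNS, HillFit, hill_response
from .knowledge_base import KnowledgeBase, ReactionRecord, write_kegg_dump

logger = logging.getLogger(__name__)

#: Keyword-free decoy annotations (safe for negative controls).
DECOY_ANNOTATIONS = (
    "alcohol dehydrogenase",
    "enoyl-CoA hydratase",
    "aldolase class II",
    "ABC transporter permease",
    "phosphoglycerate kinase",
    "aminotransferase class V",
    "acyl-CoA synthetase",
    "outer membrane porin",
    "methyltransferase domain protein",
    "hypothetical protein",
)

#: Adversarial decoys containing regulator-like vocabulary (stress tests).
ADVERSARIAL_ANNOTATIONS = DECOY_ANNOTATIONS + (
    "putative transcriptional regulator fragment",
    "anti-sigma factor antagonist",
    "two-component response regulator",
)


# -- worked-example knowledge base ------------------------------------

ARABINOSE_SEED = "C02479"  # beta-L-arabinose
#: Intermediates use standard compound identifiers: L-ribulose (C00508),
#: L-ribulose 5-phosphate (C01101), D-xylulose 5-phosphate (C00231),
#: L-xylulose 5-phosphate (C03291). Reaction ids are synthetic (R9xxxx).
ARABINOSE_REACTIONS = (
    ("R90001", "C02479 <=> C00508", "5.3.1.4"),  # L-arabinose isomerase
    ("R90002", "C00508 <=> C01101", "2.7.1.16"),  # ribulokinase
    ("R90003", "C01101 <=> C00231", "5.1.3.4"),  # L-ribulose-5-P 4-epimerase
    ("R90004", "C01101 <=> C03291", "5.1.3.22"),  # L-ribulose-5-P 3-epimerase
)
ARABINOSE_COMPOUND_NAMES = {
    "C02479": "beta-L-arabinose",
    "C00508": "L-ribulose",
    "C01101": "L-ribulose 5-phosphate",
    "C00231": "D-xylulose 5-phosphate",
    "C03291": "L-xylulose 5-phosphate",
}


def build_arabinose_fixture(
    out_dir: str | Path | None = None,
    gene_links: dict[str, dict[str, Sequence[str]]] | None = None,
) -> KnowledgeBase:
    """The four-reaction arabinose-catabolism knowledge base.

    Seeded at beta-L-arabinose, the graph supports exactly three chains up
    to length 3: isomerase -> ribulokinase (length 2) extended by either
    of two L-ribulose-5-phosphate epimerases (two length-3 chains).

    ``gene_links`` optionally attaches EC -> organism -> gene-id links;
    ``out_dir`` additionally writes the flat-file dump.
    """
    from .knowledge_base import parse_reaction_equation

    kb = KnowledgeBase()
    for cid, name in ARABINOSE_COMPOUND_NAMES.items():
        kb.add_compound(cid, name)
    for rid, equation, ec in ARABINOSE_REACTIONS:
        substrates, products = parse_reaction_equation(equation)
        kb.add_reaction(
            ReactionRecord(
                reaction_id=rid,
                substrates=tuple(substrates),
                products=tuple(products),
                ec_numbers=(ec,),
            )
        )
    if gene_links:
        for ec, orgs in gene_links.items():
            for org, genes in orgs.items():
                kb.add_enzyme(ec, org, genes)
    if out_dir is not None:
        write_kegg_dump(kb, out_dir)
    return kb


# -- genome simulation -------------------------------------------------


@dataclass(frozen=True)
class PlantedOperon:
    """A run of chain-enzyme genes to embed in a simulated genome.

    ``ecs`` are in chain-step order; genes are placed in genomic order
    following the strand (step 1 is 5'-most). ``gaps[i]`` decoy genes are
    inserted between members i and i+1.
    """

    ecs: tuple[str, ...]
    start_index: int
    strand: str = "+"
    gaps: tuple[int, ...] = ()

    def member_count(self) -> int:
        return len(self.ecs)

    def span_indices(self) -> range:
        gaps = self.gaps or (0,) * (len(self.ecs) - 1)
        width = len(self.ecs) + sum(gaps)
        return range(self.start_index, self.start_index + width)


@dataclass(frozen=True)
class PlantedRegulator:
    """A regulator gene planted divergently upstream of a planted operon.

    ``offset`` is the number of genes strictly between the regulator and
    the operon's 5' member; their strands default to the operon's strand
    (1-point deductions) unless ``intervening_strands`` is given.
    """

    operon_index: int
    offset: int = 0
    strand: str = "-"
    annotation: str = "LysR family transcriptional regulator"
    intervening_strands: tuple[str, ...] | None = None


@dataclass(frozen=True)
class GenomeSpec:
    """Blueprint for one simulated genome."""

    n_genes: int
    organism_code: str = "syn"
    assembly_accession: str = "GCA_900000001.1"
    replicon_accession: str = "SYN_CHR01"
    locus_prefix: str = "SYN"
    planted_operons: tuple[PlantedOperon, ...] = ()
    planted_regulators: tuple[PlantedRegulator, ...] = ()
    decoy_pool: tuple[str, ...] = DECOY_ANNOTATIONS
    seed: int = 0


class GenomeSpecError(ValueError):
    """The planted elements do not fit the genome."""


@dataclass
class PlantedTruth:
    """Ground truth for one planted operon (and its regulator, if any)."""

    operon_index: int
    ecs: tuple[str, ...]
    member_locus_tags: tuple[str, ...]  # chain-step order
    strand: str
    regulator_locus_tag: str | None
    regulator_annotation: str | None
    expected_score: int | None


def simulate_genome(
    spec: GenomeSpec, out_path: str | Path | None = None
) -> tuple[pd.DataFrame, list[PlantedTruth]]:
    """Generate a feature table with planted operons/regulators plus truth.

    Returns the table as a DataFrame in the feature-table dialect (and
    writes it to ``out_path`` if given) together with one
    :class:`PlantedTruth` per planted operon; expected scores are computed
    by the proximity formula applied to the planted arrangement (strand
    mix of the intervening genes), clamped at -500. Coordinates are
    1-based and non-overlapping; a fixed seed reproduces the genome
    exactly.
    """
    rng = np.random.default_rng(spec.seed)

    # slot assignment: index -> (strand, annotation, role)
    slots: dict[int, tuple[str, str]] = {}

    def claim(index: int, strand: str, annotation: str) -> None:
        if index < 0 or index >= spec.n_genes:
            raise GenomeSpecError(
                f"planted gene index {index} outside genome of {spec.n_genes} genes"
            )
        if index in slots:
            raise GenomeSpecError(f"planted elements overlap at gene index {index}")
        slots[index] = (strand, annotation)

    truths: list[PlantedTruth] = []
    operon_member_indices: list[list[int]] = []

    for operon in spec.planted_operons:
        if operon.strand not in ("+", "-"):
            raise GenomeSpecError(f"bad operon strand {operon.strand!r}")
        gaps = operon.gaps or (0,) * (len(operon.ecs) - 1)
        if len(gaps) != len(operon.ecs) - 1:
            raise GenomeSpecError("gaps must have one entry per adjacent member pair")
        # genomic order follows transcription: step order on +, reversed on -
        ordered_ecs = list(operon.ecs) if operon.strand == "+" else list(reversed(operon.ecs))
        ordered_gaps = list(gaps) if operon.strand == "+" else list(reversed(gaps))
        idx = operon.start_index
        member_idx_genomic: list[int] = []
        for k, ec in enumerate(ordered_ecs):
            claim(idx, operon.strand, f"{_enzyme_annotation(ec)}")
            member_idx_genomic.append(idx)
            if k < len(ordered_gaps):
                for _ in range(ordered_gaps[k]):
                    idx += 1
                    claim(idx, operon.strand, str(rng.choice(spec.decoy_pool)))
                idx += 1
            else:
                idx += 1
        # back to chain-step order for the truth table
        step_order_idx = (
            member_idx_genomic if operon.strand == "+" else list(reversed(member_idx_genomic))
        )
        operon_member_indices.append(step_order_idx)

    for reg in spec.planted_regulators:
        operon = spec.planted_operons[reg.operon_index]
        members = operon_member_indices[reg.operon_index]
        if reg.strand == operon.strand:
            raise GenomeSpecError("planted regulator must be divergent (opposite strand)")
        five_prime_idx = members[0]
        direction = -1 if operon.strand == "+" else +1
        inter = reg.intervening_strands or (operon.strand,) * reg.offset
        if len(inter) != reg.offset:
            raise GenomeSpecError("intervening_strands length must equal offset")
        pos = five_prime_idx
        for s in inter:
            pos += direction
            claim(pos, s, str(rng.choice(spec.decoy_pool)))
        pos += direction
        claim(pos, reg.strand, reg.annotation)

    # ground truth per operon
    reg_by_operon = {r.operon_index: r for r in spec.planted_regulators}
    for i, operon in enumerate(spec.planted_operons):
        members = operon_member_indices[i]
        reg = reg_by_operon.get(i)
        if reg is None:
            truths.append(
                PlantedTruth(
                    operon_index=i,
                    ecs=operon.ecs,
                    member_locus_tags=tuple(_locus_tag(spec, j) for j in members),
                    strand=operon.strand,
                    regulator_locus_tag=None,
                    regulator_annotation=None,
                    expected_score=None,
                )
            )
            continue
        inter = reg.intervening_strands or (operon.strand,) * reg.offset
        deduction = sum(1 if s == operon.strand else 2 for s in inter)
        direction = -1 if operon.strand == "+" else +1
        reg_idx = members[0] + direction * (reg.offset + 1)
        truths.append(
            PlantedTruth(
                operon_index=i,
                ecs=operon.ecs,
                member_locus_tags=tuple(_locus_tag(spec, j) for j in members),
                strand=operon.strand,
                regulator_locus_tag=_locus_tag(spec, reg_idx),
                regulator_annotation=reg.annotation,
                expected_score=max(-500, -deduction),
            )
        )

    # fill remaining slots with decoys, lay out coordinates left to right
    rows = []
    pos = 1
    for index in range(spec.n_genes):
        strand, annotation = slots.get(
            index,
            (
                "+" if rng.random() < 0.5 else "-",
                str(rng.choice(spec.decoy_pool)),
            ),
        )
        length = int(rng.integers(100, 800)) * 3  # plausible CDS lengths
        start = pos
        end = pos + length - 1
        pos = end + 1 + int(rng.integers(20, 200))
        rows.append(
            {
                "feature": "CDS",
                "class": "with_protein",
                "genomic_accession": spec.replicon_accession,
                "start": start,
                "end": end,
                "strand": strand,
                "locus_tag": _locus_tag(spec, index),
                "name": annotation,
            }
        )

    df = pd.DataFrame(rows)
    if out_path is not None:
        write_feature_table(df, out_path)
    return df, truths


def _locus_tag(spec: GenomeSpec, index: int) -> str:
    return f"{spec.locus_prefix}_{index:05d}"


def _enzyme_annotation(ec: str) -> str:
    # keyword-free enzyme product name tied to its EC
    return f"catabolic enzyme (EC {ec})"


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write the feature-table dialect with its conventional '# ' header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    body = df.to_csv(sep="\t", index=False, lineterminator="\n")
    path.write_text("# " + body, encoding="utf-8")


def write_truth_table(truths: Sequence[PlantedTruth], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = [
        {
            "operon_index": t.operon_index,
            "ecs": list(t.ecs),
            "member_locus_tags": list(t.member_locus_tags),
            "strand": t.strand,
            "regulator_locus_tag": t.regulator_locus_tag,
            "regulator_annotation": t.regulator_annotation,
            "expected_score": t.expected_score,
        }
        for t in truths
    ]
    path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def genome_spec_from_dict(data: dict) -> GenomeSpec:
    """Build a :class:`GenomeSpec` from a plain dict (YAML/JSON spec file)."""
    operons = tuple(
        PlantedOperon(
            ecs=tuple(o["ecs"]),
            start_index=int(o["start_index"]),
            strand=o.get("strand", "+"),
            gaps=tuple(o.get("gaps", ())),
        )
        for o in data.get("planted_operons", ())
    )
    regulators = tuple(
        PlantedRegulator(
            operon_index=int(r["operon_index"]),
            offset=int(r.get("offset", 0)),
            strand=r.get("strand", "-"),
            annotation=r.get("annotation", "LysR family transcriptional regulator"),
            intervening_strands=(
                tuple(r["intervening_strands"]) if "intervening_strands" in r else None
            ),
        )
        for r in data.get("planted_regulators", ())
    )
    return GenomeSpec(
        n_genes=int(data["n_genes"]),
        organism_code=data.get("organism_code", "syn"),
        assembly_accession=data.get("assembly_accession", "GCA_900000001.1"),
        replicon_accession=data.get("replicon_accession", "SYN_CHR01"),
        locus_prefix=data.get("locus_prefix", "SYN"),
        planted_operons=operons,
        planted_regulators=regulators,
        decoy_pool=tuple(data.get("decoy_pool", DECOY_ANNOTATIONS)),
        seed=int(data.get("seed", 0)),
    )


# -- planted-truth study ----------------------------------------------


@dataclass
class PlantedStudy:
    """A ready-to-mine directory tree plus its ground truth."""

    kb_dir: Path
    genomes_dir: Path
    organism_map_path: Path
    truths_by_organism: dict[str, list[PlantedTruth]]


def build_planted_study(out_dir: str | Path, seed: int = 0) -> PlantedStudy:
    """Arabinose knowledge base plus five simulated genomes with known truth.

    Organisms (all encode the planted locus tags in the enzyme links):

    - ``org1``: 2-step operon (+), adjacent divergent regulator -> score 0.
    - ``org2``: 3-step operon via EC 5.1.3.4 (+), regulator behind two
      operon-strand genes -> score -2 (for the length-2 sub-chain too).
    - ``org3``: 3-step operon via EC 5.1.3.22 (-), regulator behind one
      operon-strand and one regulator-strand gene -> score -3.
    - ``org4``: negative control -- operon planted but no regulator and a
      keyword-free decoy pool.
    - ``org5``: negative control -- chain genes present but scattered
      (intra-operon gap exceeding any reasonable tolerance).
    """
    out_dir = Path(out_dir)
    base_seed = int(seed) % (2**31 - 1)
    kb_dir = out_dir / "kb"
    genomes_dir = out_dir / "genomes"
    genomes_dir.mkdir(parents=True, exist_ok=True)

    ec2 = ("5.3.1.4", "2.7.1.16")
    ec3a = ec2 + ("5.1.3.4",)
    ec3b = ec2 + ("5.1.3.22",)

    specs = {
        "org1": GenomeSpec(
            n_genes=60,
            organism_code="org1",
            assembly_accession="GCA_900000101.1",
            replicon_accession="ORG1_CHR01",
            locus_prefix="ORG1",
            planted_operons=(PlantedOperon(ecs=ec2, start_index=25, strand="+"),),
            planted_regulators=(PlantedRegulator(operon_index=0, offset=0, strand="-"),),
            seed=base_seed + 1,
        ),
        "org2": GenomeSpec(
            n_genes=80,
            organism_code="org2",
            assembly_accession="GCA_900000102.1",
            replicon_accession="ORG2_CHR01",
            locus_prefix="ORG2",
            planted_operons=(PlantedOperon(ecs=ec3a, start_index=40, strand="+"),),
            planted_regulators=(
                PlantedRegulator(
                    operon_index=0, offset=2, strand="-", intervening_strands=("+", "+")
                ),
            ),
            seed=base_seed + 2,
        ),
        "org3": GenomeSpec(
            n_genes=80,
            organism_code="org3",
            assembly_accession="GCA_900000103.1",
            replicon_accession="ORG3_CHR01",
            locus_prefix="ORG3",
            planted_operons=(PlantedOperon(ecs=ec3b, start_index=30, strand="-"),),
            planted_regulators=(
                PlantedRegulator(
                    operon_index=0, offset=2, strand="+", intervening_strands=("-", "+")
                ),
            ),
            seed=base_seed + 3,
        ),
        "org4": GenomeSpec(
            n_genes=60,
            organism_code="org4",
            assembly_accession="GCA_900000104.1",
            replicon_accession="ORG4_CHR01",
            locus_prefix="ORG4",
            planted_operons=(PlantedOperon(ecs=ec2, start_index=20, strand="+"),),
            planted_regulators=(),
            seed=base_seed + 4,
        ),
        "org5": GenomeSpec(
            n_genes=60,
            organism_code="org5",
            assembly_accession="GCA_900000105.1",
            replicon_accession="ORG5_CHR01",
            locus_prefix="ORG5",
            planted_operons=(
                PlantedOperon(ecs=ec2, start_index=10, strand="+", gaps=(20,)),
            ),
            planted_regulators=(),
            seed=base_seed + 5,
        ),
    }

    gene_links: dict[str, dict[str, list[str]]] = {}
    truths_by_org: dict[str, list[PlantedTruth]] = {}
    map_rows = []
    for org, spec in specs.items():
        path = genomes_dir / f"{spec.assembly_accession}_feature_table.txt"
        _, truths = simulate_genome(spec, out_path=path)
        truths_by_org[org] = truths
        write_truth_table(truths, genomes_dir / f"{org}_truth.json")
        map_rows.append((org, spec.assembly_accession, path.name))
        for truth in truths:
            for ec, tag in zip(truth.ecs, truth.member_locus_tags):
                gene_links.setdefault(ec, {}).setdefault(org, []).append(tag)

    build_arabinose_fixture(out_dir=kb_dir, gene_links=gene_links)

    organism_map_path = out_dir / "organism_map.tsv"
    pd.DataFrame(
        map_rows, columns=["organism_code", "assembly_accession", "feature_table_path"]
    ).assign(
        feature_table_path=lambda d: "genomes/" + d["feature_table_path"]
    ).to_csv(organism_map_path, sep="\t", index=False)

    return PlantedStudy(
        kb_dir=kb_dir,
        genomes_dir=genomes_dir,
        organism_map_path=organism_map_path,
        truths_by_organism=truths_by_org,
    )


# -- dose-response simulation -----------------------------------------


def simulate_dose_response(
    fit: HillFit,
    doses: Sequence[float],
    noise_cv: float = 0.02,
    n_reps: int = 1,
    seed: int = 0,
    out_path: str | Path | None = None,
    od: float = 0.5,
    od_blank: float = 0.05,
    fluorescence_blank: float = 100.0,
) -> pd.DataFrame:
    """Noisy dose-response readings drawn from a Hill curve.

    Noise is multiplicative log-normal with coefficient of variation
    ``noise_cv`` and unit mean (mean-preserving), applied to the
    normalized response; raw fluorescence is reconstructed so that
    blank correction and OD normalization recover the noisy value
    exactly. Deterministic per seed.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(noise_cv**2)))
    rows = []
    for rep in range(1, n_reps + 1):
        for dose in doses:
            y = float(hill_response(fit, dose))
            if sigma > 0:
                y *= float(np.exp(rng.normal(-(sigma**2) / 2.0, sigma)))
            fluorescence = y * (od - od_blank) + fluorescence_blank
            rows.append(
                {
                    "inducer_conc_uM": dose,
                    "fluorescence": fluorescence,
                    "od": od,
                    "fluorescence_blank": fluorescence_blank,
                    "od_blank": od_blank,
                    "replicate": rep,
                }
            )
    df = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
    if out_path is not None:
        Path(out_path).parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_path, index=False, lineterminator="\n")
    return df


#: The assay's dose ladder: 12 log-spaced concentrations over the
#: 7.8125-2000 uM titration window.
ASSAY_DOSES_UM = tuple(float(x) for x in np.geomspace(7.8125, 2000.0, 12))
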