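"""Shared fixtures: knowledge bases, synthetic feature tables, planted studies."""

from __future__ import annotations

import pytest
from hypothesis import settings

from tfbscreen.chains import ChainStep, EnzymeChain
from tfbscreen.genome import FeatureTable, GeneFeature
from tfbscreen.simulate import build_arabinose_fixture, build_planted_study

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def arabinose_kb():
    """Four-reaction arabinose-catabolism knowledge base."""
    return build_arabinose_fixture()


@pytest.fixture(scope="session")
def planted_study(tmp_path_factory):
    """Arabinose KB dump + five simulated genomes with known truth."""
    out = tmp_path_factory.mktemp("study")
    return build_planted_study(out, seed=7)


def make_table(
    genes,
    organism_code: str = "tst",
    assembly_accession: str = "GCA_000000001.1",
    replicon: str = "CHR01",
    gene_length: int = 900,
    spacer: int = 100,
) -> FeatureTable:
    """Build a FeatureTable from (strand, annotation) or
    (strand, annotation, locus_tag) tuples laid out left to right."""
    feats = []
    pos = 1
    for i, gene in enumerate(genes):
        strand, annotation = gene[0], gene[1]
        tag = gene[2] if len(gene) > 2 else f"TST_{i:05d}"
        feats.append(
            GeneFeature(
                genomic_accession=replicon,
                start=pos,
                end=pos + gene_length - 1,
                strand=strand,
                locus_tag=tag,
                annotation=annotation,
            )
        )
        pos += gene_length + spacer
    return FeatureTable(
        organism_code=organism_code,
        assembly_accession=assembly_accession,
        replicons={replicon: feats},
    )


def make_chain(ecs, seed: str = "CX_SEED") -> EnzymeChain:
    """A structurally valid chain with synthetic reaction/compound ids."""
    steps = []
    current = seed
    for i, ec in enumerate(ecs):
        produced = f"CX_I{i}"
        steps.append(
            ChainStep(ec=ec, reaction_id=f"RX{i:04d}", consumed=current, produced=produced)
        )
        current = produced
    return EnzymeChain(seed=seed, steps=tuple(steps))
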