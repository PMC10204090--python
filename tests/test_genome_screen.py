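"""Feature-table parsing, gene location and operon detection."""

from __future__ import annotations

import io
import itertools

import numpy as np
import pytest

from tfbscreen.genome import (
    FeatureTableError,
    detect_operon,
    load_organism_map,
    locate_chain_genes,
    parse_feature_table,
)
from tfbscreen.simulate import (
    DECOY_ANNOTATIONS,
    GenomeSpec,
    PlantedOperon,
    PlantedRegulator,
    simulate_genome,
    write_feature_table,
)

from conftest import make_chain, make_table

HEADER = "# feature\tclass\tgenomic_accession\tstart\tend\tstrand\tlocus_tag\tname\n"


def table_text(rows):
    return HEADER + "".join(
        f"{r[0]}\twith_protein\t{r[1]}\t{r[2]}\t{r[3]}\t{r[4]}\t{r[5]}\t{r[6]}\n" for r in rows
    )


class TestParseFeatureTable:
    def test_three_gene_table_gets_dense_indices(self):
        text = table_text(
            [
                ("CDS", "CHR1", 100, 400, "+", "TAG_A", "protein A"),
                ("CDS", "CHR1", 500, 900, "-", "TAG_B", "protein B"),
                ("CDS", "CHR1", 1000, 1500, "+", "TAG_C", "protein C"),
            ]
        )
        table = parse_feature_table(io.StringIO(text))
        feats = table.replicons["CHR1"]
        assert [f.index for f in feats] == [0, 1, 2]
        assert [f.locus_tag for f in feats] == ["TAG_A", "TAG_B", "TAG_C"]

    def test_interleaved_replicons_index_independently(self):
        text = table_text(
            [
                ("CDS", "CHR1", 100, 400, "+", "A1", "p"),
                ("CDS", "PLAS1", 50, 300, "+", "B1", "p"),
                ("CDS", "CHR1", 500, 900, "+", "A2", "p"),
                ("CDS", "PLAS1", 400, 700, "-", "B2", "p"),
            ]
        )
        table = parse_feature_table(io.StringIO(text))
        assert [f.index for f in table.replicons["CHR1"]] == [0, 1]
        assert [f.index for f in table.replicons["PLAS1"]] == [0, 1]
        assert table.find_locus_tag("b2").index == 1

    def test_duplicate_locus_tag_is_an_error(self):
        text = table_text(
            [
                ("CDS", "CHR1", 100, 400, "+", "TAG_A", "p"),
                ("CDS", "CHR1", 500, 900, "+", "TAG_A", "p"),
            ]
        )
        with pytest.raises(FeatureTableError, match="duplicate locus_tag"):
            parse_feature_table(io.StringIO(text))

    def test_missing_columns_are_listed(self):
        with pytest.raises(FeatureTableError, match="strand"):
            parse_feature_table(io.StringIO("# feature\tgenomic_accession\tstart\tend\n"))

    def test_non_cds_rows_and_tagless_rows_are_dropped(self):
        text = table_text(
            [
                ("gene", "CHR1", 100, 400, "+", "TAG_A", "p"),
                ("CDS", "CHR1", 100, 400, "+", "TAG_A", "p"),
                ("rRNA", "CHR1", 450, 480, "+", "TAG_R", "16S"),
                ("CDS", "CHR1", 500, 900, "+", "", "orphan"),
            ]
        )
        table = parse_feature_table(io.StringIO(text))
        assert table.n_genes == 1

    def test_unicode_minus_strand_accepted(self):
        text = table_text([("CDS", "CHR1", 100, 400, "−", "TAG_A", "p")])
        table = parse_feature_table(io.StringIO(text))
        assert table.replicons["CHR1"][0].strand == "-"

    def test_simulated_genome_round_trips_through_parser(self, tmp_path):
        spec = GenomeSpec(n_genes=30, seed=11)
        df, _ = simulate_genome(spec, out_path=tmp_path / "ft.txt")
        table = parse_feature_table(tmp_path / "ft.txt", organism_code="syn")
        assert table.n_genes == 30
        feats = table.replicons[spec.replicon_accession]
        assert [f.locus_tag for f in feats] == list(df["locus_tag"])


class TestLocateChainGenes:
    def test_single_copy_per_step_gives_one_assignment(self):
        table = make_table([("+", "a"), ("+", "b"), ("+", "c")])
        got = locate_chain_genes(table, [["TST_00000"], ["TST_00001"], ["TST_00002"]])
        assert len(got) == 1
        assert [f.locus_tag for f in got[0]] == ["TST_00000", "TST_00001", "TST_00002"]

    def test_matching_is_case_insensitive(self):
        table = make_table([("+", "a")])
        assert locate_chain_genes(table, [["tst_00000"]])

    def test_copies_enumerate_with_tighter_span_first(self):
        # second step present twice: adjacent copy and a distant copy
        table = make_table(
            [("+", "s1", "G1"), ("+", "s2", "G2A"), ("+", "x", "D1"), ("+", "s2", "G2B")]
        )
        got = locate_chain_genes(table, [["G1"], ["G2A", "G2B"]])
        assert len(got) == 2
        assert [f.locus_tag for f in got[0]] == ["G1", "G2A"]

    def test_step_with_no_matches_yields_empty(self):
        table = make_table([("+", "a")])
        assert locate_chain_genes(table, [["TST_00000"], ["ABSENT"]]) == []

    def test_cap_limits_combinations(self, caplog):
        import logging

        copies = [f"G{i}" for i in range(8)]
        table = make_table([("+", "x", tag) for tag in copies] * 1)
        with caplog.at_level(logging.WARNING):
            got = locate_chain_genes(table, [copies, copies], cap=10)
        assert len(got) == 10
        assert any("capping" in r.message for r in caplog.records)


class TestDetectOperon:
    def test_contiguous_same_strand_run_is_an_operon(self):
        chain = make_chain(["1.1.1.1", "2.2.2.2", "3.3.3.3"])
        table = make_table([("+", "x")] * 10 + [("+", "a"), ("+", "b"), ("+", "c")])
        genes = table.replicons["CHR01"][10:13]
        op = detect_operon(genes, chain)
        assert op is not None
        assert op.upstream_gene.index == 10
        assert [g.index for g in op.member_genes] == [10, 11, 12]

    def test_gap_beyond_tolerance_rejects(self):
        chain = make_chain(["1.1.1.1", "2.2.2.2", "3.3.3.3"])
        table = make_table([("+", "x")] * 16)
        feats = table.replicons["CHR01"]
        assignment = [feats[10], feats[11], feats[15]]  # 3 intervening genes
        assert detect_operon(assignment, chain, gap_tolerance=2) is None
        assert detect_operon(assignment, chain, gap_tolerance=3) is not None

    def test_mixed_strands_reject(self):
        chain = make_chain(["1.1.1.1", "2.2.2.2"])
        table = make_table([("+", "a"), ("-", "b")])
        assert detect_operon(table.replicons["CHR01"], chain) is None

    def test_minus_strand_upstream_gene_is_rightmost(self):
        chain = make_chain(["1.1.1.1", "2.2.2.2"])
        table = make_table([("-", "a"), ("-", "b")])
        op = detect_operon(table.replicons["CHR01"], chain)
        assert op is not None and op.upstream_gene.index == 1

    def test_decision_invariant_to_assignment_order(self):
        chain = make_chain(["1.1.1.1", "2.2.2.2", "3.3.3.3"])
        table = make_table([("+", "x")] * 3 + [("+", "a"), ("+", "b"), ("+", "c")])
        genes = table.replicons["CHR01"][3:6]
        results = []
        for perm in itertools.permutations(genes):
            op = detect_operon(list(perm), chain)
            assert op is not None
            results.append(tuple(g.locus_tag for g in op.member_genes))
        assert len(set(results)) == 1

    def test_collinearity_flag_enforces_step_order(self):
        chain = make_chain(["1.1.1.1", "2.2.2.2"])
        table = make_table([("+", "a"), ("+", "b")])
        g0, g1 = table.replicons["CHR01"]
        # assignment in step order (step1 -> g1, step2 -> g0): genomically reversed
        assert detect_operon([g1, g0], chain, require_collinear=True) is None
        assert detect_operon([g0, g1], chain, require_collinear=True) is not None
        assert detect_operon([g1, g0], chain) is not None  # relaxed by default


class TestPlantedOperonRecall:
    """Operon detection on simulated genomes with known truth."""

    @pytest.mark.parametrize("seed", range(5))
    def test_planted_operons_recalled_and_scrambles_rejected(self, seed, tmp_path):
        rng = np.random.default_rng(seed)
        gaps = tuple(int(g) for g in rng.integers(0, 3, size=2))
        strand = "+" if rng.random() < 0.5 else "-"
        spec = GenomeSpec(
            n_genes=40,
            planted_operons=(
                PlantedOperon(
                    ecs=("1.1.1.1", "2.2.2.2", "3.3.3.3"),
                    start_index=15,
                    strand=strand,
                    gaps=gaps,
                ),
            ),
            seed=int(seed),
        )
        df, truths = simulate_genome(spec)
        write_feature_table(df, tmp_path / "ft.txt")
        table = parse_feature_table(tmp_path / "ft.txt", organism_code="syn")
        chain = make_chain(list(truths[0].ecs))
        assignment = [table.find_locus_tag(t) for t in truths[0].member_locus_tags]
        # recall: planted gaps <= tolerance 2 by construction
        op = detect_operon(assignment, chain, gap_tolerance=2)
        assert op is not None and op.strand == strand

        # strand-scramble the members: no operon may be reported
        scrambled = [
            g if i % 2 == 0 else type(g)(
                genomic_accession=g.genomic_accession,
                start=g.start,
                end=g.end,
                strand="-" if g.strand == "+" else "+",
                locus_tag=g.locus_tag,
                annotation=g.annotation,
                index=g.index,
            )
            for i, g in enumerate(assignment)
        ]
        assert detect_operon(scrambled, chain, gap_tolerance=2) is None


class TestOrganismMap:
    def test_relative_paths_resolve_against_map_directory(self, tmp_path):
        (tmp_path / "genomes").mkdir()
        (tmp_path / "map.tsv").write_text(
            "organism_code\tassembly_accession\tfeature_table_path\n"
            "eco\tGCA_1\tgenomes/eco_ft.txt\n"
        )
        got = load_organism_map(tmp_path / "map.tsv")
        assert got["eco"][0] == "GCA_1"
        assert got["eco"][1] == tmp_path / "genomes" / "eco_ft.txt"

    def test_missing_columns_rejected(self, tmp_path):
        (tmp_path / "map.tsv").write_text("organism_code\tpath\n")
        with pytest.raises(FeatureTableError, match="assembly_accession"):
            load_organism_map(tmp_path / "map.tsv")
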