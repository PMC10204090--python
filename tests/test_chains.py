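"""Chain enumeration: worked example, brute-force oracle, invariants."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from tfbscreen.chains import enumerate_chains, organisms_with_chain
from tfbscreen.knowledge_base import KnowledgeBase, ReactionRecord

from conftest import make_chain


def brute_force_paths(kb: KnowledgeBase, seed: str, min_len: int, max_len: int):
    """Independent oracle: exhaustive recursive path enumeration returning
    the set of unique ordered EC sequences of each length in range."""
    sequences: set[tuple[str, ...]] = set()

    def walk(compound, visited, ecs):
        if len(ecs) >= min_len:
            sequences.add(tuple(ecs))
        if len(ecs) == max_len:
            return
        for rid in kb.reaction_ids:
            rec = kb.reaction(rid)
            if compound not in rec.substrate_ids:
                continue
            for ec in rec.ec_numbers:
                if "-" in ec:
                    continue
                for prod in rec.product_ids:
                    if prod in visited:
                        continue
                    walk(prod, visited | {prod}, ecs + [ec])

    walk(seed, {seed}, [])
    return sequences


def random_graph_kb(rng: np.random.Generator, n_compounds: int = 10, n_reactions: int = 14):
    kb = KnowledgeBase()
    compounds = [f"C9{i:04d}" for i in range(n_compounds)]
    for i in range(n_reactions):
        subs = rng.choice(n_compounds, size=rng.integers(1, 3), replace=False)
        prods = rng.choice(n_compounds, size=rng.integers(1, 3), replace=False)
        kb.add_reaction(
            ReactionRecord(
                reaction_id=f"R9{i:04d}",
                substrates=tuple((compounds[j], 1) for j in subs),
                products=tuple((compounds[j], 1) for j in prods),
                ec_numbers=(f"{1 + i % 6}.{1 + i % 3}.{1 + i % 4}.{1 + i}",),
            )
        )
    return kb, compounds


class TestArabinoseWorkedExample:
    def test_three_chains_at_max_len_3(self, arabinose_kb):
        chains = enumerate_chains(arabinose_kb, "C02479", max_len=3)
        assert len(chains) == 3
        by_len = sorted(c.length for c in chains)
        assert by_len == [2, 3, 3]

    def test_all_chains_share_the_first_two_enzymes(self, arabinose_kb):
        chains = enumerate_chains(arabinose_kb, "C02479", max_len=3)
        for c in chains:
            assert c.ec_sequence[:2] == ("5.3.1.4", "2.7.1.16")
        length3 = {c.ec_sequence[2] for c in chains if c.length == 3}
        assert length3 == {"5.1.3.4", "5.1.3.22"}

    def test_max_len_2_truncates_to_single_chain(self, arabinose_kb):
        chains = enumerate_chains(arabinose_kb, "C02479", max_len=2)
        assert [c.ec_sequence for c in chains] == [("5.3.1.4", "2.7.1.16")]


class TestEnumerateChains:
    def test_seed_without_consuming_reactions_yields_nothing(self, arabinose_kb):
        assert enumerate_chains(arabinose_kb, "C00231", max_len=3) == []

    @pytest.mark.parametrize("max_len", [0, 1])
    def test_max_len_below_two_is_an_argument_error(self, arabinose_kb, max_len):
        with pytest.raises(ValueError):
            enumerate_chains(arabinose_kb, "C02479", max_len=max_len)

    def test_parallel_routes_with_shared_third_step_match_oracle(self):
        # two parallel 2-step routes converging on one shared 3rd step
        kb = KnowledgeBase()
        rows = [
            ("R90101", ("C90000",), ("C90001",), "1.1.1.1"),
            ("R90102", ("C90000",), ("C90002",), "2.2.2.2"),
            ("R90103", ("C90001",), ("C90003",), "3.3.3.3"),
            ("R90104", ("C90002",), ("C90003",), "4.4.4.4"),
            ("R90105", ("C90003",), ("C90004",), "5.5.5.5"),
        ]
        for rid, subs, prods, ec in rows:
            kb.add_reaction(
                ReactionRecord(
                    reaction_id=rid,
                    substrates=tuple((c, 1) for c in subs),
                    products=tuple((c, 1) for c in prods),
                    ec_numbers=(ec,),
                )
            )
        got = {c.ec_sequence for c in enumerate_chains(kb, "C90000", max_len=3)}
        expected = brute_force_paths(kb, "C90000", 2, 3)
        assert got == expected
        assert len(got) == 4  # two 2-chains + two 3-chains

    @pytest.mark.parametrize("graph_seed", range(8))
    def test_random_graphs_match_brute_force_oracle(self, graph_seed):
        rng = np.random.default_rng(1000 + graph_seed)
        kb, compounds = random_graph_kb(rng)
        seed = compounds[0]
        got = [c.ec_sequence for c in enumerate_chains(kb, seed, max_len=4)]
        assert set(got) == brute_force_paths(kb, seed, 2, 4)
        assert len(got) == len(set(got))  # EC sequences unique in output

    @pytest.mark.parametrize("graph_seed", range(4))
    def test_chain_set_monotone_in_max_len(self, graph_seed):
        rng = np.random.default_rng(2000 + graph_seed)
        kb, compounds = random_graph_kb(rng)
        seed = compounds[0]
        shorter = {c.ec_sequence for c in enumerate_chains(kb, seed, max_len=3)}
        longer = {c.ec_sequence for c in enumerate_chains(kb, seed, max_len=4)}
        assert shorter <= longer

    def test_structural_linkage_invariant(self, arabinose_kb):
        for chain in enumerate_chains(arabinose_kb, "C02479", max_len=3):
            assert chain.steps[0].consumed == chain.seed
            for prev, nxt in itertools.pairwise(chain.steps):
                assert nxt.consumed == prev.produced

    def test_no_compound_revisited_on_consumed_path(self):
        # a cycle back to the seed must not recurse forever
        kb = KnowledgeBase()
        kb.add_reaction(
            ReactionRecord(
                "R90201", (("C90000", 1),), (("C90001", 1),), ec_numbers=("1.1.1.1",)
            )
        )
        kb.add_reaction(
            ReactionRecord(
                "R90202", (("C90001", 1),), (("C90000", 1),), ec_numbers=("2.2.2.2",)
            )
        )
        chains = enumerate_chains(kb, "C90000", max_len=5)
        assert chains == []  # the only continuation revisits the seed

    def test_exclude_compounds_blocks_currency_continuation(self):
        kb = KnowledgeBase()
        kb.add_reaction(
            ReactionRecord(
                "R90301",
                (("C90000", 1),),
                (("C90001", 1), ("C00008", 1)),  # main product + currency co-product
                ec_numbers=("1.1.1.1",),
            )
        )
        kb.add_reaction(
            ReactionRecord("R90302", (("C90001", 1),), (("C90002", 1),), ec_numbers=("2.2.2.2",))
        )
        kb.add_reaction(
            ReactionRecord("R90303", (("C00008", 1),), (("C00002", 1),), ec_numbers=("3.3.3.3",))
        )
        default = {c.ec_sequence for c in enumerate_chains(kb, "C90000", max_len=2)}
        assert ("1.1.1.1", "3.3.3.3") in default  # cofactor loop kept by default
        filtered = {
            c.ec_sequence
            for c in enumerate_chains(kb, "C90000", max_len=2, exclude_compounds={"C00008"})
        }
        assert filtered == {("1.1.1.1", "2.2.2.2")}

    def test_chain_cap_truncates_with_warning(self, caplog):
        import logging

        rng = np.random.default_rng(5)
        kb, compounds = random_graph_kb(rng, n_compounds=8, n_reactions=20)
        with caplog.at_level(logging.WARNING):
            chains = enumerate_chains(kb, compounds[0], max_len=4, chain_cap=2)
        assert len(chains) == 2
        assert any("chain cap" in r.message for r in caplog.records)


class TestOrganismsWithChain:
    def _kb_with_links(self, links):
        kb = KnowledgeBase()
        for ec, orgs in links.items():
            for org, genes in orgs.items():
                kb.add_enzyme(ec, org, genes)
        return kb

    def test_intersection_keeps_only_complete_organisms(self):
        chain = make_chain(["1.1.1.1", "2.2.2.2", "3.3.3.3"])
        kb = self._kb_with_links(
            {
                "1.1.1.1": {"orga": ["a1"], "orgb": ["b1"]},
                "2.2.2.2": {"orga": ["a2"], "orgb": ["b2"]},
                "3.3.3.3": {"orga": ["a3"]},
            }
        )
        cos = organisms_with_chain(kb, chain)
        assert set(cos.organisms) == {"orga"}
        assert cos.organisms["orga"] == (("a1",), ("a2",), ("a3",))

    def test_disjoint_organism_sets_give_empty_result(self):
        chain = make_chain(["1.1.1.1", "2.2.2.2"])
        kb = self._kb_with_links(
            {"1.1.1.1": {"orga": ["a1"]}, "2.2.2.2": {"orgb": ["b1"]}}
        )
        assert organisms_with_chain(kb, chain).organisms == {}

    def test_unresolvable_ec_empties_the_set_with_log(self, caplog):
        import logging

        chain = make_chain(["1.1.1.1", "9.9.9.9"])
        kb = self._kb_with_links({"1.1.1.1": {"orga": ["a1"]}})
        with caplog.at_level(logging.INFO):
            assert organisms_with_chain(kb, chain).organisms == {}
        assert any("9.9.9.9" in r.message for r in caplog.records)

    @pytest.mark.parametrize("trial", range(5))
    def test_random_subsets_match_naive_intersection(self, trial):
        rng = np.random.default_rng(3000 + trial)
        orgs = [f"org{i}" for i in range(5)]
        ecs = ["1.1.1.1", "2.2.2.2", "3.3.3.3"]
        links = {
            ec: {
                org: [f"{org}_{ec}_g"]
                for org in orgs
                if rng.random() < 0.6
            }
            for ec in ecs
        }
        links = {ec: v for ec, v in links.items()}
        chain = make_chain(ecs)
        kb = self._kb_with_links(links)
        expected = set(orgs)
        for ec in ecs:
            expected &= set(links.get(ec, {}))
        got = organisms_with_chain(kb, chain)
        if any(not links.get(ec) for ec in ecs):
            # an EC with zero organisms means no organism encodes the chain
            assert got.organisms == {}
        else:
            assert set(got.organisms) == expected
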