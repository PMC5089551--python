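"""Parsimony and pairwise mutation counting."""

import itertools

import networkx as nx
import numpy as np
import pytest

from rmystr.counting import count_pedigree_mutations, pair_mutation_count, parsimony_event_count
from rmystr.haplotypes import Haplotype
from rmystr.pedigree import PedigreeGraph, meioses_between, steiner_subtree
from rmystr.simulate import generate_pedigree, simulate_haplotypes, uniform_model


def brute_force_parsimony(pedigree, leaf_alleles, allele_range):
    """Exhaustive minimum over all assignments of alleles from
    *allele_range* to unsampled subtree nodes; any-size change costs 1."""
    informative = {k: v for k, v in leaf_alleles.items() if v is not None}
    if len(informative) < 2:
        return 0
    sub = steiner_subtree(pedigree, informative.keys())
    free = sorted(set(sub.nodes) - set(informative))
    edges = list(sub.edges)
    best = None
    for combo in itertools.product(allele_range, repeat=len(free)):
        assign = dict(informative)
        assign.update(zip(free, combo))
        cost = sum(1 for u, v in edges if assign[u] != assign[v])
        best = cost if best is None else min(best, cost)
    return best


def random_tree_with_alleles(rng, n_sampled, alleles=range(12, 17)):
    ped = generate_pedigree(
        n_sampled, max_depth=3, branching=1.5, seed=rng, pedigree_id="T"
    )
    leaf_alleles = {
        sid: int(rng.choice(list(alleles))) for sid in ped.sampled
    }
    return ped, leaf_alleles


class TestParsimony:
    def test_multistep_difference_is_one_event(self, chain_pedigree):
        # 36 vs 34 through any chain: one multi-step mutation event
        assert parsimony_event_count(chain_pedigree, {"A": 36, "C": 34}) == 1

    def test_identical_leaves_zero_events(self, brothers_pedigree):
        assert parsimony_event_count(brothers_pedigree, {"A": 14, "B": 14}) == 0

    def test_single_informative_leaf_counts_zero(self, chain_pedigree):
        assert parsimony_event_count(chain_pedigree, {"A": 36, "C": None}) == 0

    def test_three_leaf_star_resolves_parallel_events(self):
        ped = PedigreeGraph("star", {"A": "R", "B": "R", "C": "R"}, {"A", "B", "C"})
        assert parsimony_event_count(ped, {"A": 13, "B": 14, "C": 15}) == 2
        # two leaves share the derived state: one event suffices on this star
        assert parsimony_event_count(ped, {"A": 14, "B": 14, "C": 13}) == 1

    def test_matches_exhaustive_oracle_on_random_trees(self, rng):
        checked = 0
        while checked < 120:
            ped, leaf_alleles = random_tree_with_alleles(rng, int(rng.integers(2, 6)))
            sub = steiner_subtree(ped)
            free = set(sub.nodes) - ped.sampled
            if len(free) > 6:
                continue
            expected = brute_force_parsimony(ped, leaf_alleles, range(12, 17))
            assert parsimony_event_count(ped, leaf_alleles) == expected
            checked += 1

    def test_invariant_under_relabeling_internal_nodes(self, rng):
        for _ in range(20):
            ped, leaf_alleles = random_tree_with_alleles(rng, 3)
            count = parsimony_event_count(ped, leaf_alleles)
            mapping = {
                n: (n if n in ped.sampled else f"X{n}") for n in ped.individuals
            }
            relabeled = PedigreeGraph(
                "relabel",
                {mapping[c]: mapping[f] for c, f in ped.father_of.items()},
                set(ped.sampled),
            )
            assert parsimony_event_count(relabeled, leaf_alleles) == count


class TestPedigreeCounts:
    def test_zero_mutation_pedigree(self, chain_pedigree, yfiler, founder):
        haps = {
            sid: Haplotype(sid, dict(founder.alleles))
            for sid in chain_pedigree.sampled
        }
        mc = count_pedigree_mutations(chain_pedigree, haps, yfiler)
        assert mc.total_events == 0
        assert mc.total_meioses == 2
        assert mc.convention == "related"

    def test_father_son_three_step_difference_is_one_event(self, yfiler, founder):
        ped = PedigreeGraph("fs", {"S": "F"}, {"F", "S"})
        hf = Haplotype("F", dict(founder.alleles))
        alleles = dict(founder.alleles)
        alleles["DYS448"] = (alleles["DYS448"][0] + 3,)
        hs = Haplotype("S", alleles)
        mc = count_pedigree_mutations(ped, {"F": hf, "S": hs}, yfiler)
        assert mc.total_events == 1
        assert mc.total_meioses == 1
        assert mc.per_locus_events["DYS448"] == 1

    def test_missing_haplotype_names_the_sample(self, chain_pedigree, yfiler, founder):
        haps = {"A": Haplotype("A", dict(founder.alleles))}
        with pytest.raises(ValueError, match="C"):
            count_pedigree_mutations(chain_pedigree, haps, yfiler)

    def test_ngen_is_steiner_subtree_not_full_genealogy(self, yfiler, founder):
        # unsampled side branch must not inflate the meiosis count
        ped = PedigreeGraph(
            "side", {"A": "R", "B": "R", "C": "R", "D": "C"}, {"A", "B"}
        )
        haps = {s: Haplotype(s, dict(founder.alleles)) for s in ("A", "B")}
        assert count_pedigree_mutations(ped, haps, yfiler).total_meioses == 2

    def test_counts_bounded_by_truth_log(self, rm13, founder, rng):
        """Parsimony can only undercount: homoplasy hides events."""
        model = uniform_model(rm13, 0.05)
        for _ in range(20):
            ped = generate_pedigree(3, 4, 1.4, seed=rng, pedigree_id="S")
            haps, truth = simulate_haplotypes(ped, founder, model, rng, rm13)
            mc = count_pedigree_mutations(ped, haps, rm13)
            sub_nodes = set(steiner_subtree(ped).nodes)
            visible = sum(1 for e in truth if e.child in sub_nodes)
            assert mc.total_events <= visible

    def test_two_leaf_pedigree_equals_related_pair_count(self, rm13, founder, rng):
        model = uniform_model(rm13, 0.08)
        ped = PedigreeGraph("pair", {"A": "X", "X": "Y", "B": "Y"}, {"A", "B"})
        for _ in range(10):
            haps, _ = simulate_haplotypes(ped, founder, model, rng, rm13)
            mc = count_pedigree_mutations(ped, haps, rm13)
            pc = pair_mutation_count(haps["A"], haps["B"], rm13, "related")
            assert mc.total_events == pc.total_events


class TestPairCounts:
    def test_multistep_conventions(self, rm13, founder):
        a = dict(founder.alleles)
        b = dict(founder.alleles)
        a["DYF387S1"] = (36,)
        b["DYF387S1"] = (34,)
        ha, hb = Haplotype("a", a), Haplotype("b", b)
        assert pair_mutation_count(ha, hb, rm13, "related").total_events == 1
        assert pair_mutation_count(ha, hb, rm13, "unrelated").total_events == 2

    def test_identical_haplotypes_zero_under_both_conventions(self, rm13, founder):
        h = Haplotype("a", dict(founder.alleles))
        for conv in ("related", "unrelated"):
            assert pair_mutation_count(h, h, rm13, conv).total_events == 0

    def test_related_never_exceeds_unrelated(self, both_panels, founder, rng, rm13):
        model = uniform_model(rm13, 0.1)
        ped = PedigreeGraph("pair", {"A": "R", "B": "R"}, {"A", "B"})
        for _ in range(20):
            haps, _ = simulate_haplotypes(ped, founder, model, rng, rm13)
            rel = pair_mutation_count(haps["A"], haps["B"], rm13, "related")
            unrel = pair_mutation_count(haps["A"], haps["B"], rm13, "unrelated")
            for col in rm13.columns:
                assert rel.per_locus_events[col] <= unrel.per_locus_events[col]
            assert rel.total_events <= unrel.total_events

    def test_multi_copy_compared_after_sorting(self, yfiler):
        ha = Haplotype("a", {"DYS385": (14, 13)})
        hb = Haplotype("b", {"DYS385": (13, 15)})
        mc = pair_mutation_count(ha, hb, yfiler, "unrelated")
        # sorted matching: (13,14) vs (13,15) -> 0 + 1
        assert mc.per_locus_events["DYS385a"] == 0
        assert mc.per_locus_events["DYS385b"] == 1

    def test_missing_locus_skipped_symmetrically(self, yfiler, founder):
        a = dict(founder.alleles)
        b = dict(founder.alleles)
        del a["DYS392"]
        ha, hb = Haplotype("a", a), Haplotype("b", b)
        mc = pair_mutation_count(ha, hb, yfiler, "related")
        assert "DYS392" not in mc.per_locus_events
        assert mc.total_events == 0

    def test_copy_count_mismatch_rejected(self, yfiler):
        ha = Haplotype("a", {"DYS385": (13, 14)})
        hb = Haplotype("b", {"DYS385": (13,)})
        with pytest.raises(ValueError, match="copy count"):
            pair_mutation_count(ha, hb, yfiler, "related")

    def test_unknown_convention_rejected(self, yfiler, founder):
        h = Haplotype("a", dict(founder.alleles))
        with pytest.raises(ValueError, match="convention"):
            pair_mutation_count(h, h, yfiler, "bogus")


class TestMeioses:
    def test_canonical_relationships(self):
        fs = PedigreeGraph("fs", {"S": "F"}, {"F", "S"})
        assert meioses_between(fs, "F", "S") == 1
        br = PedigreeGraph("br", {"A": "F", "B": "F"}, {"A", "B"})
        assert meioses_between(br, "A", "B") == 2
        cz = PedigreeGraph(
            "cz", {"F1": "G", "F2": "G", "C1": "F1", "C2": "F2"}, {"C1", "C2"}
        )
        assert meioses_between(cz, "C1", "C2") == 4

    def test_matches_networkx_shortest_path(self, rng):
        for _ in range(20):
            ped = generate_pedigree(4, 4, 1.4, seed=rng, pedigree_id="M")
            g = ped.to_undirected()
            ids = sorted(ped.sampled)
            for a, b in itertools.combinations(ids, 2):
                assert meioses_between(ped, a, b) == nx.shortest_path_length(g, a, b)

    def test_disconnected_pair_rejected(self):
        ped = PedigreeGraph("d", {"A": "B", "C": "D"}, set())
        with pytest.raises(Exception, match="not connected"):
            meioses_between(ped, "A", "C")
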