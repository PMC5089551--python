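"""Stepwise-mutation simulator and study-design generators."""

import itertools

import numpy as np
import pytest
import yaml

from rmystr.counting import pair_mutation_count
from rmystr.haplotypes import Haplotype
from rmystr.pedigree import PedigreeGraph, steiner_subtree
from rmystr.simulate import (
    CLOSE_COUPLE_MIX,
    MutationModel,
    R_M269_SUBLINEAGES,
    build_star_pedigree,
    couples_from_pedigree,
    default_founder,
    default_model,
    generate_close_couples,
    generate_lineage_dataset,
    generate_pedigree,
    generate_study_pedigrees,
    make_couples,
    simulate_haplotypes,
    uniform_model,
)


class TestMutationModel:
    def test_yaml_round_trip(self, tmp_path, model):
        path = tmp_path / "model.yaml"
        model.to_yaml(path)
        back = MutationModel.from_yaml(path)
        assert back == model

    def test_parameter_validation(self):
        with pytest.raises(ValueError, match="rate"):
            MutationModel({"DYS393": 1.5})
        with pytest.raises(ValueError, match="p_multistep"):
            MutationModel({"DYS393": 0.01}, p_multistep=1.0)

    def test_default_rates_are_published_direct_counts(self, model):
        assert model.rates["DYF399S1"] == pytest.approx(30 / 470)
        assert model.rates["DYS448"] == 0.0


class TestGeneratePedigree:
    def test_deterministic_under_seed(self):
        a = generate_pedigree(3, 4, 1.4, seed=7)
        b = generate_pedigree(3, 4, 1.4, seed=7)
        assert a.father_of == b.father_of
        assert a.sampled == b.sampled

    def test_minimal_case_gives_one_or_two_meioses(self):
        ped = generate_pedigree(2, 1, 2.5, seed=3)
        assert steiner_subtree(ped).number_of_edges() in (1, 2)

    def test_infeasible_parameters_rejected(self):
        with pytest.raises(ValueError, match="could not grow"):
            generate_pedigree(50, 2, 0.2, seed=0, _max_attempts=5)

    def test_thousand_random_pedigrees_validate(self, rng):
        # construction runs full validation; just exercise it broadly
        for k in range(1000):
            ped = generate_pedigree(
                int(rng.integers(2, 6)), int(rng.integers(2, 5)), 1.5, seed=rng
            )
            assert len(ped.sampled) >= 2
            assert steiner_subtree(ped).number_of_edges() >= 1

    def test_star_pedigree_meioses_equal_depth_sum(self):
        ped = build_star_pedigree("S", [3, 5, 2])
        assert steiner_subtree(ped).number_of_edges() == 10
        assert len(ped.sampled) == 3


class TestSimulateHaplotypes:
    def test_zero_rate_model_copies_founder(self, chain_pedigree, yfiler, founder):
        model = uniform_model(yfiler, 0.0)
        haps, truth = simulate_haplotypes(chain_pedigree, founder, model, 1, yfiler)
        assert truth == []
        for h in haps.values():
            for locus in yfiler.locus_names:
                assert h.alleles[locus] == founder.alleles[locus]

    def test_seed_determinism(self, yfiler, founder):
        ped = generate_pedigree(3, 3, 1.5, seed=5)
        model = uniform_model(yfiler, 0.3)
        h1, t1 = simulate_haplotypes(ped, founder, model, 99, yfiler)
        h2, t2 = simulate_haplotypes(ped, founder, model, 99, yfiler)
        assert t1 == t2
        assert all(h1[k].alleles == h2[k].alleles for k in h1)

    def test_event_frequency_on_single_edge(self, yfiler, founder, rng):
        """mu = 0.5 on one meiosis: event frequency within 3 SE over 1e4
        replicates, per column."""
        ped = PedigreeGraph("fs", {"S": "F"}, {"F", "S"})
        model = uniform_model(yfiler, 0.5)
        n = 10_000
        hits = 0
        for _ in range(n):
            _, truth = simulate_haplotypes(ped, founder, model, rng, yfiler)
            hits += sum(1 for e in truth if e.locus == "DYS393")
        se = (0.5 * 0.5 / n) ** 0.5
        assert abs(hits / n - 0.5) < 3 * se

    def test_truth_log_total_matches_analytic_expectation(self, rm13, founder, model, rng):
        """Published per-column rates over the study pedigrees: mean total
        RM event count approximates edges x sum(mu) over 200 replicates."""
        peds = generate_study_pedigrees(11)
        total_edges = sum(len(p.father_of) for p in peds)
        mu_sum = sum(model.rates[c] for c in rm13.columns)
        expected = total_edges * mu_sum
        reps = 200
        counts = []
        for _ in range(reps):
            total = 0
            for ped in peds:
                _, truth = simulate_haplotypes(ped, founder, model, rng, rm13)
                total += len(truth)
            counts.append(total)
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / reps**0.5
        assert abs(mean - expected) < 4 * se + 1

    def test_events_always_change_the_allele(self, rm13, founder, rng):
        model = uniform_model(rm13, 0.2)
        ped = generate_pedigree(3, 3, 1.5, seed=1)
        _, truth = simulate_haplotypes(ped, founder, model, rng, rm13)
        assert truth, "expected some events at mu=0.2"
        for e in truth:
            assert e.from_allele != e.to_allele

    def test_multiple_roots_rejected(self, yfiler, founder):
        ped = PedigreeGraph("two", {"A": "R", "B": "Q"}, set())
        with pytest.raises(ValueError, match="one founder"):
            simulate_haplotypes(ped, founder, uniform_model(yfiler, 0.0), 0, yfiler)


class TestStudyDesigns:
    def test_study_pedigree_scale(self):
        peds = generate_study_pedigrees(0)
        assert len(peds) == 26
        total = sum(steiner_subtree(p).number_of_edges() for p in peds)
        assert 380 <= total <= 560  # ~470 meioses
        assert sum(len(p.sampled) for p in peds) == 66

    def test_close_couples_match_published_design(self, model, both_panels):
        haps, couples, peds = generate_close_couples(model, 4, panel=both_panels)
        assert len(couples) == 27
        assert sum(c.meioses for c in couples) == 45
        by_rel = {
            rel: sum(1 for c in couples if c.relationship == rel)
            for rel, _ in CLOSE_COUPLE_MIX
        }
        assert by_rel == dict(CLOSE_COUPLE_MIX)
        assert set(haps) == {s for c in couples for s in (c.sample_a, c.sample_b)}

    def test_lineage_dataset_degenerate_parameters(self, model, both_panels):
        haps, labels = generate_lineage_dataset(
            3, 4, divergence_meioses=0, within_meioses=0,
            model=model, seed=0, panel=both_panels,
        )
        ref = next(iter(haps.values())).alleles
        assert all(h.alleles == ref for h in haps.values())
        assert len(set(labels.values())) == 3

    def test_nine_group_dataset_uses_sublineage_labels(self, model, both_panels):
        _, labels = generate_lineage_dataset(
            9, 2, 5, 5, model=model, seed=1, panel=both_panels
        )
        assert set(labels.values()) == set(R_M269_SUBLINEAGES)

    def test_couples_from_pedigree_enumerates_sampled_pairs(self):
        ped = build_star_pedigree("P", [2, 3, 4])
        couples = couples_from_pedigree(ped)
        assert len(couples) == 3
        assert sorted(c.meioses for c in couples) == [5, 6, 7]


class TestMakeCouples:
    def test_matches_brute_force_all_pairs_filter(self, yfiler, model, both_panels):
        haps, labels = generate_lineage_dataset(
            2, 3, 3, 2, model=model, seed=8, panel=both_panels
        )
        for cutoff in (0, 1, 3):
            got = {
                c.key for c in make_couples(haps, yfiler, cutoff, labels)
            }
            expected = set()
            for a, b in itertools.combinations(sorted(haps), 2):
                d = pair_mutation_count(haps[a], haps[b], yfiler, "unrelated").total_events
                if d <= cutoff:
                    expected.add(tuple(sorted((a, b))))
            assert got == expected

    def test_threshold_edge_excludes_two_step_pair(self, yfiler, founder):
        a = dict(founder.alleles)
        b = dict(founder.alleles)
        b["DYS393"] = (b["DYS393"][0] + 2,)
        haps = {"A": Haplotype("A", a), "B": Haplotype("B", b)}
        assert make_couples(haps, yfiler, 1) == []
        assert len(make_couples(haps, yfiler, 2)) == 1

    def test_same_vs_cross_group_tagging(self, yfiler, founder):
        haps = {k: Haplotype(k, dict(founder.alleles)) for k in "ABC"}
        labels = {"A": "G1", "B": "G1", "C": "G2"}
        tags = {c.key: c.dataset_tag for c in make_couples(haps, yfiler, 0, labels)}
        assert tags[("A", "B")] == "C1"
        assert tags[("A", "C")] == tags[("B", "C")] == "C2"
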