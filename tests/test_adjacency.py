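"""Link inference: endpoints, phylogenetic weights, candidates, matching,
chains.  Matching is checked against brute-force enumeration."""

from __future__ import annotations

import itertools
import random

import dendropy
import pytest

from scaffolink.adjacency import (
    CandidateLink,
    Chain,
    Endpoint,
    Extremity,
    build_chains,
    candidate_links,
    genome_weights,
    left_endpoint,
    reference_adjacencies,
    right_endpoint,
    select_links,
)
from scaffolink.errors import DataError
from scaffolink.gene_orders import Occurrence

from .conftest import make_order


def get_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def adj(a_fam, a_side, b_fam, b_side):
    return frozenset((Endpoint(a_fam, a_side), Endpoint(b_fam, b_side)))


def link(sa, da, sb, db, support):
    ea, eb = sorted([Extremity(sa, da), Extremity(sb, db)], key=lambda e: e.key)
    return CandidateLink(ea, eb, support)


def brute_force_max_matching(cands):
    """Max total matching weight by exhaustive recursion over extremities:
    the first unmatched extremity is either left unmatched or matched to
    each available partner in turn."""
    edges = {}
    for c in cands:
        edges.setdefault(c.ext_a.key, []).append((c.ext_b.key, c.total_weight))
        edges.setdefault(c.ext_b.key, []).append((c.ext_a.key, c.total_weight))
    vertices = sorted(edges)

    def best(i, used):
        if i >= len(vertices):
            return 0.0
        v = vertices[i]
        if v in used:
            return best(i + 1, used)
        score = best(i + 1, used)  # leave v unmatched
        for partner, weight in edges[v]:
            if partner not in used:
                score = max(
                    score, weight + best(i + 1, used | {v, partner})
                )
        return score

    return best(0, frozenset())


class TestEndpoints:
    def test_sign_aware_left_right(self):
        plus, minus = Occurrence("g", 1), Occurrence("g", -1)
        assert right_endpoint(plus) == Endpoint("g", "head")
        assert left_endpoint(plus) == Endpoint("g", "tail")
        assert right_endpoint(minus) == Endpoint("g", "tail")
        assert left_endpoint(minus) == Endpoint("g", "head")


class TestGenomeWeights:
    def test_all_ones_without_branch_lengths(self):
        tree = get_tree("((T,R1),(R2,(R3,(R4,(R5,R6)))));")
        weights = genome_weights(tree, "T", [f"R{i}" for i in range(1, 7)])
        assert weights == {f"R{i}": 1.0 for i in range(1, 7)}

    def test_inverse_patristic_distance(self):
        tree = get_tree("((T:1,R1:1):1,R2:3);")
        weights = genome_weights(tree, "T", ["R1", "R2"])
        assert weights["R1"] == pytest.approx(0.5)
        assert weights["R2"] == pytest.approx(0.2)

    def test_unknown_reference_is_an_error(self):
        tree = get_tree("((T:1,R1:1):1,R2:3);")
        with pytest.raises(DataError, match="R9"):
            genome_weights(tree, "T", ["R9"])


class TestReferenceAdjacencies:
    def test_forward_run(self):
        order = make_order("R", {"c": ["+a", "+b", "+c"]})
        assert reference_adjacencies(order) == {
            adj("a", "head", "b", "tail"),
            adj("b", "head", "c", "tail"),
        }

    def test_single_gene_sequence_has_no_adjacency(self):
        assert reference_adjacencies(make_order("R", {"c": ["+a"]})) == set()

    def test_sign_aware_adjacencies(self):
        order = make_order("R", {"c": ["+a", "+b", "-d", "-c", "+e"]})
        assert reference_adjacencies(order) == {
            adj("a", "head", "b", "tail"),
            adj("b", "head", "d", "head"),
            adj("d", "tail", "c", "head"),
            adj("c", "tail", "e", "tail"),
        }


class TestCandidateLinks:
    def test_toy1_candidates_and_weights(self, toy1):
        target, refs, weights = toy1
        cands = candidate_links(target, refs, weights)
        by_pair = {c.pair_key: c for c in cands}
        assert len(cands) == 4
        strong_a = by_pair[(("S1", "3p"), ("S2", "5p"))]
        assert strong_a.total_weight == pytest.approx(2.0)
        assert set(strong_a.support) == {"R1", "R2"}
        strong_b = by_pair[(("S2", "3p"), ("S3", "5p"))]
        assert strong_b.total_weight == pytest.approx(2.0)
        weak_a = by_pair[(("S1", "3p"), ("S2", "3p"))]
        weak_b = by_pair[(("S2", "5p"), ("S3", "5p"))]
        assert weak_a.total_weight == pytest.approx(1.0)
        assert weak_b.support == {"R3": 1.0}

    def test_exposed_endpoints_recorded(self, toy1):
        target, refs, weights = toy1
        cands = candidate_links(target, refs, weights)
        strong = next(c for c in cands if c.pair_key == (("S1", "3p"), ("S2", "5p")))
        assert strong.ext_a.exposed == Endpoint("b", "head")
        assert strong.ext_b.exposed == Endpoint("c", "tail")

    def test_window_decay_recovers_link_behind_terminal_insertion(self):
        # target S1 ends ...a,z where z is target-specific noise; with k=2 the
        # sub-terminal endpoint of 'a' still matches the reference adjacency.
        target = make_order("T", {"S1": ["+a", "+z"], "S2": ["+b"]})
        ref = make_order("R", {"c": ["+a", "+b"]})
        refs = [("R", reference_adjacencies(ref))]
        assert candidate_links(target, refs, {"R": 1.0}, window=1) == []
        cands = candidate_links(target, refs, {"R": 1.0}, window=2, decay=0.5)
        assert [c.pair_key for c in cands] == [(("S1", "3p"), ("S2", "5p"))]
        assert cands[0].total_weight == pytest.approx(0.5)  # offset 1 on one side


class TestSelectLinks:
    def test_no_candidates(self):
        assert select_links([], min_genomes=1) == []

    def test_toy1_accepts_the_two_strong_links(self, toy1):
        target, refs, weights = toy1
        accepted = select_links(candidate_links(target, refs, weights), min_genomes=2)
        assert [c.pair_key for c in accepted] == [
            (("S1", "3p"), ("S2", "5p")),
            (("S2", "3p"), ("S3", "5p")),
        ]

    def test_shared_extremity_keeps_heavier_link(self):
        cands = [
            link("S1", "3p", "S2", "5p", {"R1": 3.0}),
            link("S1", "3p", "S3", "5p", {"R1": 2.0}),
        ]
        accepted = select_links(cands, min_genomes=1)
        assert [c.total_weight for c in accepted] == [3.0]

    def test_equal_weight_tie_prefers_lexicographically_smallest(self):
        cands = [
            link("S1", "3p", "S2", "5p", {"R1": 1.0}),
            link("S1", "3p", "S3", "5p", {"R1": 1.0}),
        ]
        accepted = select_links(cands, min_genomes=1)
        assert [c.pair_key for c in accepted] == [(("S1", "3p"), ("S2", "5p"))]

    def test_matches_brute_force_on_random_instances(self):
        rng = random.Random(11)
        for _ in range(60):
            n_ext = rng.randint(2, 10)
            exts = [(f"S{i}", rng.choice(["5p", "3p"])) for i in range(n_ext)]
            cands = []
            for a, b in itertools.combinations(range(n_ext), 2):
                if rng.random() < 0.4:
                    cands.append(
                        link(*exts[a], *exts[b], {"R1": rng.randint(1, 8) / 2})
                    )
            accepted = select_links(cands, min_genomes=1)
            got = sum(c.total_weight for c in accepted)
            assert got == pytest.approx(brute_force_max_matching(cands))

    def test_raising_thresholds_never_adds_links(self):
        rng = random.Random(5)
        for _ in range(30):
            cands = []
            for a, b in itertools.combinations(range(8), 2):
                if rng.random() < 0.5:
                    support = {
                        f"R{g}": rng.randint(1, 4) / 2
                        for g in range(rng.randint(1, 4))
                    }
                    cands.append(link(f"S{a}", "3p", f"S{b}", "5p", support))
            counts_g = [
                len(select_links(cands, min_genomes=g)) for g in (1, 2, 3)
            ]
            assert counts_g == sorted(counts_g, reverse=True)
            counts_w = [
                len(select_links(cands, min_genomes=1, min_weight=w))
                for w in (0.0, 1.0, 2.0)
            ]
            assert counts_w == sorted(counts_w, reverse=True)


class TestBuildChains:
    def test_toy1_chain_orientation(self, toy1):
        target, refs, weights = toy1
        accepted = select_links(candidate_links(target, refs, weights), min_genomes=2)
        chains = build_chains(accepted, ["S1", "S2", "S3"])
        assert [c.members for c in chains] == [
            (("S1", "+"), ("S2", "+"), ("S3", "+"))
        ]

    def test_3p_3p_join_flips_second_scaffold(self):
        chains = build_chains(
            [link("S1", "3p", "S2", "3p", {"R1": 1.0})], ["S1", "S2"]
        )
        assert chains[0].members == (("S1", "+"), ("S2", "-"))

    def test_cycle_broken_at_weakest_link(self):
        chains = build_chains(
            [
                link("S1", "3p", "S2", "5p", {"R1": 2.0}),
                link("S2", "3p", "S1", "5p", {"R1": 1.0}),
            ],
            ["S1", "S2"],
        )
        assert chains[0].members == (("S1", "+"), ("S2", "+"))

    def test_non_matching_input_is_an_error(self):
        with pytest.raises(DataError, match="matching"):
            build_chains(
                [
                    link("S1", "3p", "S2", "5p", {"R1": 1.0}),
                    link("S1", "3p", "S3", "5p", {"R1": 1.0}),
                ],
                ["S1", "S2", "S3"],
            )

    def test_chains_partition_scaffolds_with_singletons(self):
        chains = build_chains(
            [link("S1", "3p", "S2", "5p", {"R1": 1.0})], ["S1", "S2", "S3"]
        )
        seen = sorted(sid for c in chains for sid in c.scaffolds)
        assert seen == ["S1", "S2", "S3"]
        assert Chain((("S3", "+"),)) in chains

    def test_no_scaffold_exceeds_two_links(self, toy1):
        target, refs, weights = toy1
        accepted = select_links(candidate_links(target, refs, weights), min_genomes=1)
        per_scaffold = {}
        for c in accepted:
            for e in (c.ext_a, c.ext_b):
                per_scaffold[e.scaffold_id] = per_scaffold.get(e.scaffold_id, 0) + 1
        assert all(n <= 2 for n in per_scaffold.values())


class TestPerfectConservationLimit:
    def test_true_adjacencies_recovered_exactly(self):
        """References identical to the unfragmented target, boundaries between
        shared single-copy genes: inference returns exactly the truth."""
        rng = random.Random(3)
        for _ in range(10):
            n = rng.randint(6, 24)
            tokens = [rng.choice("+-") + f"f{i}" for i in range(n)]
            cuts = sorted(rng.sample(range(1, n), rng.randint(1, min(5, n - 1))))
            bounds = [0, *cuts, n]
            seqs = {
                f"S{i}": tokens[a:b]
                for i, (a, b) in enumerate(zip(bounds, bounds[1:]))
            }
            target = make_order("T", seqs)
            ref = make_order("R1", {"c": tokens})
            refs = [
                ("R1", reference_adjacencies(ref)),
                ("R2", reference_adjacencies(make_order("R2", {"c": tokens}))),
            ]
            accepted = select_links(
                candidate_links(target, refs, {"R1": 1.0, "R2": 1.0}), min_genomes=2
            )
            expected = {
                frozenset(((f"S{i}", "3p"), (f"S{i+1}", "5p")))
                for i in range(len(bounds) - 2)
            }
            assert {c.extremity_frozenset() for c in accepted} == expected
            chains = build_chains(accepted, sorted(seqs))
            assert len(chains) == 1
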