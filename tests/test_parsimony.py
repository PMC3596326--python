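"""Parsimony engine: scorers vs independent oracles, TBR, ratchet, search."""

import itertools

import dendropy
import numpy as np
import pytest

import foldchron as fc
from foldchron import parsimony as P
from foldchron.coding import ANCESTRAL_STATE

from conftest import random_character_matrix


def brute_force_score(adj, states, n_leaves):
    """Independent oracle: minimize total |state change| over every
    assignment of internal states, per character."""
    internals = [n for n in adj if n >= n_leaves]
    edges = P._edges(adj)
    total = 0
    for c in range(states.shape[1]):
        best = np.inf
        for assign in itertools.product(range(ANCESTRAL_STATE + 1), repeat=len(internals)):
            st = dict(zip(internals, assign))
            for leaf in range(n_leaves):
                if leaf in adj:
                    st[leaf] = states[leaf, c]
            cost = sum(abs(st[u] - st[v]) for u, v in edges)
            best = min(best, cost)
        total += best
    return total


def quartet_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")


class TestParsimonyScore:
    def test_no_change_when_all_ancestral(self):
        states = np.full((3, 2), ANCESTRAL_STATE, dtype=np.int16)
        cm = fc.CharacterMatrix(states, ["A", "B", "C"], ["p", "q"])
        tree = quartet_tree("((A,B),C);")
        assert fc.parsimony_score(tree, cm) == 0

    def test_quartet_equals_character_range(self):
        # ordered character with leaves {0,1,3} and the ancestor pinned at
        # 23: the ladder-compatible grouping (A,B | C,ancestor) costs
        # exactly the character's range including the ancestor, 23 - 0
        cm = fc.CharacterMatrix(
            np.array([[0], [1], [3]], dtype=np.int16), ["A", "B", "C"], ["p"]
        )
        tree = quartet_tree("((A,B),(C,ANCESTOR));")
        assert fc.parsimony_score(tree, cm) == 23

    def test_single_character_minimum_is_range(self):
        # over all topologies the best achievable length of one ordered
        # character is max - min state (ancestor included)
        rng = np.random.default_rng(5)
        for _ in range(10):
            states = rng.integers(0, 24, (4, 1)).astype(np.int16)
            cm = fc.CharacterMatrix(states, list("ABCD"), ["p"])
            lo = min(int(states.min()), ANCESTRAL_STATE)
            hi = max(int(states.max()), ANCESTRAL_STATE)
            assert fc.exhaustive_mp(cm).score == hi - lo

    @pytest.mark.parametrize("seed", range(8))
    def test_engines_agree_with_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n_taxa = int(rng.integers(3, 5))
        cm = random_character_matrix(seed, n_taxa=n_taxa, n_chars=int(rng.integers(1, 4)))
        states = np.vstack(
            [cm.states, np.full((1, cm.n_characters), ANCESTRAL_STATE, np.int16)]
        )
        w = np.ones(cm.n_characters)
        anc = n_taxa
        for adj in P.enumerate_topologies(n_taxa + 1):
            wagner = P._wagner_score(adj, states, w, anc)
            sankoff = P._sankoff_score(adj, states, w, anc)
            brute = brute_force_score(adj, states, n_taxa + 1)
            assert wagner == sankoff == brute

    def test_interval_method_matches_sankoff_api(self):
        cm = random_character_matrix(9, n_taxa=6, n_chars=5)
        tree = fc.search_mp(cm, fc.SearchConfig(n_addition_replicates=1, ratchet_iterations=0, seed=0)).tree
        assert fc.parsimony_score(tree, cm, method="interval") == fc.parsimony_score(
            tree, cm, method="sankoff"
        )

    def test_leaf_taxon_mismatch_rejected(self):
        cm = random_character_matrix(0, n_taxa=4)
        tree = quartet_tree("((T0,T1),(T2,UNKNOWN));")
        with pytest.raises(ValueError, match="UNKNOWN"):
            fc.parsimony_score(tree, cm)

    def test_score_invariant_under_relabeling(self):
        cm = random_character_matrix(3, n_taxa=5)
        perm = [4, 2, 0, 1, 3]
        cm_perm = fc.CharacterMatrix(
            cm.states[perm], [cm.taxa[i] for i in perm], cm.characters
        )
        assert fc.exhaustive_mp(cm).score == fc.exhaustive_mp(cm_perm).score


class TestSearch:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_oracle(self, seed):
        cm = random_character_matrix(seed, n_taxa=5, n_chars=6)
        exact = fc.exhaustive_mp(cm)
        found = fc.search_mp(
            cm, fc.SearchConfig(n_addition_replicates=3, ratchet_iterations=2, seed=seed)
        )
        assert found.score == exact.score

    def test_duplicate_taxon_leaves_score_unchanged(self):
        cm = random_character_matrix(1, n_taxa=4, n_chars=5)
        dup = fc.CharacterMatrix(
            np.vstack([cm.states, cm.states[[0]]]), cm.taxa + ["T0_copy"], cm.characters
        )
        assert fc.exhaustive_mp(dup).score == fc.exhaustive_mp(cm).score

    def test_same_seed_same_newick(self):
        cm = random_character_matrix(2, n_taxa=7, n_chars=6)
        cfg = fc.SearchConfig(n_addition_replicates=2, ratchet_iterations=2, seed=99)
        r1 = fc.search_mp(cm, cfg)
        r2 = fc.search_mp(cm, cfg)
        assert r1.newick == r2.newick
        assert r1.score == r2.score
        assert r1.n_cooptimal == r2.n_cooptimal

    def test_requires_three_taxa_and_characters(self):
        cm = random_character_matrix(0, n_taxa=2)
        with pytest.raises(ValueError):
            fc.search_mp(cm)

    def test_most_abundant_family_sits_at_root(self, small_matrix):
        # pinning the ancestor at all-'N' places the family closest to the
        # maximal abundance profile basally
        cm = fc.encode_abundance(small_matrix)
        res = fc.search_mp(
            cm, fc.SearchConfig(n_addition_replicates=3, ratchet_iterations=2, seed=0)
        )
        ages = fc.node_distances(res.tree)
        assert ages["F1"] == 0.0


class TestTBR:
    def test_optimal_quartet_returned_unchanged(self):
        cm = fc.CharacterMatrix(
            np.array([[0], [1], [3], [2]], dtype=np.int16), list("ABCD"), ["p"]
        )
        best = fc.exhaustive_mp(cm)
        out = fc.tbr_neighborhood(best.tree, cm)
        assert out is best.tree

    def test_single_move_rescues_suboptimal_quartet(self):
        # (A,C | B,ancestor) costs 25 on the {0,1,3} character; the optimal
        # grouping (A,B | C,ancestor) at 23 is one rearrangement away
        cm = fc.CharacterMatrix(
            np.array([[0], [1], [3]], dtype=np.int16), ["A", "B", "C"], ["p"]
        )
        bad = quartet_tree("((A,C),(B,ANCESTOR));")
        assert fc.parsimony_score(bad, cm) == 25
        better = fc.tbr_neighborhood(bad, cm)
        assert fc.parsimony_score(better, cm) == 23

    @pytest.mark.parametrize("seed", range(5))
    def test_never_worsens(self, seed):
        cm = random_character_matrix(seed, n_taxa=6, n_chars=4)
        start = fc.search_mp(
            cm, fc.SearchConfig(n_addition_replicates=1, ratchet_iterations=0, seed=seed)
        ).tree
        before = fc.parsimony_score(start, cm)
        after = fc.parsimony_score(fc.tbr_neighborhood(start, cm), cm)
        assert after <= before


class TestRatchet:
    def test_zero_iterations_is_identity(self):
        cm = random_character_matrix(4, n_taxa=6, n_chars=5)
        res = fc.search_mp(
            cm, fc.SearchConfig(n_addition_replicates=1, ratchet_iterations=0, seed=1)
        )
        cfg = fc.SearchConfig(ratchet_iterations=0, seed=1)
        out = fc.ratchet(res.tree, cm, cfg)
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=res.tree.as_string(schema="newick"), schema="newick", taxon_namespace=tns)
        t2 = dendropy.Tree.get(data=out.as_string(schema="newick"), schema="newick", taxon_namespace=tns)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(t1, t2) == 0

    def test_never_worse_than_start(self):
        cfg = fc.SimulationConfig(n_families=12, n_proteomes=8, seed=5)
        m, _ = fc.simulate_domain_evolution(cfg)
        cm = fc.encode_abundance(fc.drop_empty_proteomes(m))
        start = fc.search_mp(
            cm, fc.SearchConfig(n_addition_replicates=1, ratchet_iterations=0, seed=5)
        )
        out = fc.ratchet(start.tree, cm, fc.SearchConfig(ratchet_iterations=3, seed=5))
        assert fc.parsimony_score(out, cm) <= start.score

    def test_beats_plain_tbr_in_most_replicates(self):
        """Ratchet refinement should match or beat addition+TBR alone in
        at least 90% of simulated 12-taxon replicates."""
        wins = 0
        n = 20
        for seed in range(n):
            cfg = fc.SimulationConfig(n_families=12, n_proteomes=8, seed=seed)
            m, _ = fc.simulate_domain_evolution(cfg)
            cm = fc.encode_abundance(fc.drop_empty_proteomes(m))
            plain = fc.search_mp(
                cm, fc.SearchConfig(n_addition_replicates=2, ratchet_iterations=0, seed=seed)
            )
            ratcheted = fc.search_mp(
                cm, fc.SearchConfig(n_addition_replicates=2, ratchet_iterations=5, seed=seed)
            )
            if ratcheted.score <= plain.score:
                wins += 1
        assert wins >= 0.9 * n


class TestTopologyEnumeration:
    def test_counts_match_double_factorial(self):
        # (2n-5)!! unrooted binary topologies on n terminals
        assert sum(1 for _ in P.enumerate_topologies(4)) == 3
        assert sum(1 for _ in P.enumerate_topologies(5)) == 15
        assert sum(1 for _ in P.enumerate_topologies(6)) == 105
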