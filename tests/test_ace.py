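import math
import random

import numpy as np
import pandas as pd
import pytest

from phylotrait.ace import (
    SubtreeStats,
    ace_continuous,
    ace_discrete,
    correlate_ancestral,
    enumerate_subtrees,
    fit_mk_rate,
    index_tree,
    score_candidates,
    score_subtree,
    select_subtrees,
    summarize_ace,
)
from phylotrait.io import read_tree

from _oracles import (
    bm_gls_estimate,
    mk_loglik_bruteforce,
    mk_marginals_bruteforce,
    random_newick,
    spearman_bruteforce,
)


def leaf_traits_from_states(itree, states01):
    return {
        itree.leaf_labels[i]: ("positive" if states01[k] else "negative")
        for k, i in enumerate(itree.leaf_indices)
    }


class TestSimilarityScore:
    REF = SubtreeStats(10, 10, 0.5, 2.0)

    def test_identity(self):
        assert score_subtree(self.REF, self.REF) == pytest.approx(1.0)

    def test_single_twofold_ratio(self):
        b = SubtreeStats(20, 10, 0.5, 2.0)
        assert score_subtree(b, self.REF) == pytest.approx(0.5)

    def test_two_twofold_ratios(self):
        b = SubtreeStats(20, 5, 0.5, 2.0)
        assert score_subtree(b, self.REF) == pytest.approx(0.25)

    def test_reciprocal_symmetry(self):
        b = SubtreeStats(7, 13, 0.8, 3.5)
        assert score_subtree(b, self.REF) == pytest.approx(score_subtree(self.REF, b))

    def test_zero_statistic_rejected(self):
        with pytest.raises(ValueError):
            score_subtree(SubtreeStats(0, 10, 0.5, 2.0), self.REF)


class TestEnumerateSubtrees:
    def test_small_tree_empty_for_large_bounds(self):
        tree = read_tree("((((A:1,B:1):1,(C:1,D:1):1):1,(E:1,F:1):1):1,(G:1,(H:1,(I:1,J:1):1):1):1);")
        assert enumerate_subtrees(tree, 50, 300) == []

    def test_cherries_found(self):
        tree = read_tree("((A:1,B:1):1,(C:1,D:1):1);")
        nodes = enumerate_subtrees(tree, 2, 3)
        leafsets = {tuple(sorted(l.taxon.label for l in n.leaf_iter())) for n in nodes}
        assert leafsets == {("A", "B"), ("C", "D")}

    def test_matches_exhaustive_scan(self):
        """Random trees: candidate set equals a from-scratch node scan."""
        rng = random.Random(31)
        for _ in range(20):
            tree = read_tree(random_newick(rng.randint(8, 40), rng))
            lo, hi = 3, 10
            got = {id(n) for n in enumerate_subtrees(tree, lo, hi)}
            expected = set()
            for node in tree.preorder_node_iter():
                if node.is_leaf():
                    continue
                n = len([1 for _ in node.leaf_iter()])
                if lo <= n <= hi:
                    expected.add(id(node))
            assert got == expected


class TestSelectSubtrees:
    def traits_all(self, tree, frac=0.5, seed=0):
        rng = random.Random(seed)
        return {
            l.taxon.label: ("positive" if rng.random() < frac else "negative")
            for l in tree.leaf_node_iter()
        }

    def test_nested_candidates_outer_wins(self):
        tree = read_tree("(((A:1,B:1):1,(C:1,D:1):1):1,(E:1,(F:1,(G:1,H:1):1):1):1);")
        traits = {lab: ("positive" if lab in "ACEG" else "negative")
                  for lab in "ABCDEFGH"}
        ref = SubtreeStats(2, 2, 0.3, 2.0)
        candidates = enumerate_subtrees(tree, 2, 8)
        scored = score_candidates(candidates, traits, ref)
        selected = select_subtrees(scored)
        chosen_ids = {id(s.node) for s in selected}
        for s in selected:
            others = chosen_ids - {id(s.node)}
            nodes = {id(n) for n in s.node.preorder_iter()}
            for t in selected:
                if id(t.node) in others:
                    assert not nodes & {id(n) for n in t.node.preorder_iter()}
        scores = [s.score for s in selected]
        assert scores == sorted(scores, reverse=True)

    def test_matches_rescan_oracle(self):
        """Greedy selection equals a brute-force re-scan at every step."""
        rng = random.Random(77)
        for _ in range(20):
            tree = read_tree(random_newick(rng.randint(10, 30), rng))
            traits = self.traits_all(tree, seed=rng.randint(0, 999))
            ref = SubtreeStats(3, 3, 0.5, 2.0)
            scored = score_candidates(enumerate_subtrees(tree, 2, 10), traits, ref)
            got = [id(s.node) for s in select_subtrees(scored)]
            # oracle: re-scan the full candidate list each round
            remaining = [s for s in scored if s.score is not None]
            taken: set[int] = set()
            expected = []
            while True:
                def key(c):
                    return (-c.score, min(l.taxon.label for l in c.node.leaf_iter()))
                viable = [
                    c for c in remaining
                    if not ({id(n) for n in c.node.preorder_iter()} & taken)
                ]
                if not viable:
                    break
                best = min(viable, key=key)
                expected.append(id(best.node))
                taken |= {id(n) for n in best.node.preorder_iter()}
                remaining.remove(best)
            assert got == expected


class TestAceDiscrete:
    def test_uniform_leaves_certain(self):
        tree = read_tree("((A:1,B:1):1,(C:1,D:1):1);")
        lk = ace_discrete(tree, {l: "positive" for l in "ABCD"})
        assert np.allclose(lk.values, 1.0, atol=1e-6)
        lk0 = ace_discrete(tree, {l: "negative" for l in "ABCD"})
        assert np.allclose(lk0.values, 0.0, atol=1e-6)

    def test_symmetric_cherries_root_half(self):
        """One positive cherry vs one negative cherry: the root cannot tell."""
        tree = read_tree("((A:1,B:1):1,(C:1,D:1):1);")
        lk = ace_discrete(
            tree, {"A": "positive", "B": "positive", "C": "negative", "D": "negative"}
        )
        itree = index_tree(tree)
        root_label = itree.labels[itree.root]
        assert lk[root_label] == pytest.approx(0.5, abs=1e-6)

    def test_state_relabeling_swaps_likelihoods(self):
        tree = read_tree("((A:1,B:2):0.5,(C:0.7,D:1.2):1);")
        t1 = {"A": "positive", "B": "negative", "C": "negative", "D": "positive"}
        t2 = {k: ("negative" if v == "positive" else "positive") for k, v in t1.items()}
        lk1, lk2 = ace_discrete(tree, t1), ace_discrete(tree, t2)
        assert np.allclose(lk1.values, 1.0 - lk2.values, atol=1e-9)

    def test_marginals_match_enumeration_oracle(self):
        """Random 3-5 leaf instances agree with exhaustive state enumeration."""
        rng = random.Random(5)
        checked = 0
        for _ in range(40):
            n = rng.randint(3, 5)
            tree = read_tree(random_newick(n, rng))
            itree = index_tree(tree)
            states = np.zeros(itree.n_nodes, dtype=int)
            leaf_states = [rng.randint(0, 1) for _ in itree.leaf_indices]
            if len(set(leaf_states)) < 2:
                continue
            for k, i in enumerate(itree.leaf_indices):
                states[i] = leaf_states[k]
            traits = leaf_traits_from_states(itree, leaf_states)
            q = fit_mk_rate(itree, states)
            lk = ace_discrete(itree, traits, rate=q)
            oracle = mk_marginals_bruteforce(itree, states, q)
            for i in itree.internal_indices:
                assert lk[itree.labels[i]] == pytest.approx(oracle[i], abs=1e-6)
            checked += 1
        assert checked >= 20

    def test_pruning_likelihood_matches_enumeration(self):
        from phylotrait.ace import _mk_partials

        rng = random.Random(9)
        for _ in range(20):
            tree = read_tree(random_newick(rng.randint(3, 5), rng))
            itree = index_tree(tree)
            states = np.zeros(itree.n_nodes, dtype=int)
            for i in itree.leaf_indices:
                states[i] = rng.randint(0, 1)
            q = 10 ** rng.uniform(-2, 1)
            _, ll = _mk_partials(itree, states, q)
            assert ll == pytest.approx(mk_loglik_bruteforce(itree, states, q), abs=1e-9)

    def test_likelihoods_are_probabilities(self, benchmark_dataset):
        sim = benchmark_dataset
        node = next(
            n for n in sim.tree.preorder_node_iter()
            if 20 <= sum(1 for _ in n.leaf_iter()) <= 60
        )
        traits = {l.taxon.label: sim.node_states[l.taxon.label] for l in node.leaf_iter()}
        lk = ace_discrete(node, traits)
        assert ((lk.values >= 0) & (lk.values <= 1)).all()


class TestAceContinuous:
    def test_constant_leaves(self):
        tree = read_tree("((A:1,B:1):1,(C:1,D:1):1);")
        vals = pd.DataFrame({"f": [3.5] * 4}, index=list("ABCD"))
        anc = ace_continuous(tree, vals)
        assert np.allclose(anc["f"].values, 3.5, atol=1e-12)

    def test_two_leaf_closed_form(self):
        """Precision-weighted mean: (0/1 + 3/2)/(1/1 + 1/2) = 1.0."""
        tree = read_tree("(A:1,B:2);")
        anc = ace_continuous(tree, pd.DataFrame({"f": [0.0, 3.0]}, index=["A", "B"]))
        assert anc["f"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_matches_gls_oracle(self):
        """Random 6-leaf instances agree with the BM covariance GLS formula."""
        rng = random.Random(13)
        nprng = np.random.default_rng(13)
        for _ in range(25):
            tree = read_tree(random_newick(6, rng))
            itree = index_tree(tree)
            y = nprng.normal(0, 2, size=6)
            leaves = [itree.leaf_labels[i] for i in itree.leaf_indices]
            anc = ace_continuous(itree, pd.DataFrame({"f": y}, index=leaves))
            yv = np.array(y)
            for i in itree.internal_indices:
                expected = bm_gls_estimate(itree, yv, i)
                assert anc["f"][itree.labels[i]] == pytest.approx(expected, abs=1e-6)

    def test_linearity(self):
        """Scaling all leaf values by k scales every ancestral estimate by k."""
        rng = random.Random(21)
        tree = read_tree(random_newick(8, rng))
        leaves = [l.taxon.label for l in tree.leaf_node_iter()]
        y = np.random.default_rng(21).normal(1, 3, size=8)
        a1 = ace_continuous(tree, pd.DataFrame({"f": y}, index=leaves))
        a2 = ace_continuous(tree, pd.DataFrame({"f": 4.0 * y}, index=leaves))
        assert np.allclose(4.0 * a1["f"].values, a2["f"].values, atol=1e-9)


class TestCorrelateAncestral:
    def idx(self, n):
        return [f"N{i}" for i in range(n)]

    def test_counts_equal_likelihoods(self):
        lk = pd.Series([0.1, 0.4, 0.7, 0.9], index=self.idx(4))
        r, p, _ = correlate_ancestral(lk, lk.copy())
        assert r == pytest.approx(1.0)

    def test_rank_identity(self):
        lk = pd.Series([0.9, 0.8, 0.2, 0.1], index=self.idx(4))
        ct = pd.Series([4.0, 3.0, 2.0, 1.0], index=self.idx(4))
        r, _, _ = correlate_ancestral(lk, ct)
        assert r == pytest.approx(1.0)

    def test_matches_bruteforce_spearman(self):
        rng = np.random.default_rng(37)
        for _ in range(30):
            n = int(rng.integers(4, 9))
            lk = pd.Series(rng.random(n), index=self.idx(n))
            ct = pd.Series(rng.integers(0, 4, n).astype(float), index=self.idx(n))
            if ct.nunique() < 2:
                continue
            r, _, _ = correlate_ancestral(lk, ct)
            assert r == pytest.approx(
                spearman_bruteforce(lk.values, ct.values), abs=1e-9
            )

    def test_empty_class_gives_missing_wilcoxon(self):
        lk = pd.Series([0.6, 0.7, 0.8, 0.9], index=self.idx(4))
        ct = pd.Series([1.0, 2.0, 3.0, 4.0], index=self.idx(4))
        _, _, p_w = correlate_ancestral(lk, ct)
        assert math.isnan(p_w)

    def test_tie_at_half_goes_negative(self):
        lk = pd.Series([0.5, 0.5, 0.9, 0.8], index=self.idx(4))
        ct = pd.Series([1.0, 2.0, 3.0, 4.0], index=self.idx(4))
        _, _, p_w = correlate_ancestral(lk, ct)
        assert not math.isnan(p_w)  # 0.5-likelihood nodes fall in the negative class


class TestSummarizeAce:
    def table(self, rows):
        return pd.DataFrame(
            rows,
            columns=["Feature", "r", "p_Correlation", "p_Wilcox", "Subtree",
                     "q_Correlation", "q_Wilcox", "Significant"],
        )

    def test_direct_equation_evaluation(self):
        """Single subtree, r=0.5, all q=0.01: weight ln(0.02)/ln(0.01)."""
        per = self.table([["PF00001", 0.5, 0.01, 0.01, 1, 0.01, 0.01, 0]])
        types = pd.Series({"PF00001": "Pfam"})
        out = summarize_ace(per, types)
        w = math.log(0.02) / math.log(0.01)
        assert w == pytest.approx(0.84948, abs=1e-5)
        assert out.loc[0, "sum_abs_rw"] == pytest.approx(0.5 * w * w, abs=1e-6)
        assert out.loc[0, "sum_abs_rw"] == pytest.approx(0.3608, abs=1e-3)

    def test_vanishing_q_weight_limit(self):
        """q_c,n -> 0 drives its weight to 1, leaving |r| * w_W."""
        per = self.table(
            [
                ["PF00001", 0.5, 1e-290, 0.01, 1, 1e-290, 0.01, 1],
                ["PF00002", 0.2, 0.01, 0.01, 1, 0.01, 0.01, 0],
            ]
        )
        types = pd.Series({"PF00001": "Pfam", "PF00002": "Pfam"})
        out = summarize_ace(per, types).set_index("Feature")
        q_c = 0.005 + 0.5e-290  # median of the two correlation q-values
        w_w = math.log(0.01 + 0.01) / math.log(0.01)
        w_c_for_pf1 = min(math.log(1e-290 + q_c) / math.log(q_c), 1.0)
        assert w_c_for_pf1 == pytest.approx(1.0, abs=1e-2)
        assert out.loc["PF00001", "sum_abs_rw"] == pytest.approx(
            0.5 * w_c_for_pf1 * w_w, rel=1e-3
        )

    def test_absent_feature_bottom_rank(self):
        per = self.table([["PF00001", 0.5, 0.01, 0.01, 1, 0.01, 0.01, 0]])
        types = pd.Series({"PF00001": "Pfam", "PF00002": "Pfam"})
        out = summarize_ace(per, types).set_index("Feature")
        assert out.loc["PF00002", "sum_abs_rw"] == 0.0
        assert out.loc["PF00002", "Rank"] > out.loc["PF00001", "Rank"]

    def test_weights_clamped_nonnegative(self):
        """A q-value near 1 would give a negative raw weight; clamped to 0."""
        per = self.table(
            [
                ["PF00001", 0.9, 0.99, 0.99, 1, 0.99, 0.99, 0],
                ["PF00002", 0.9, 0.001, 0.001, 1, 0.001, 0.001, 1],
            ]
        )
        types = pd.Series({"PF00001": "Pfam", "PF00002": "Pfam"})
        out = summarize_ace(per, types).set_index("Feature")
        assert out.loc["PF00001", "sum_abs_rw"] >= 0.0
        assert out.loc["PF00002", "sum_abs_rw"] > out.loc["PF00001", "sum_abs_rw"]
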