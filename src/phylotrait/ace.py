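"""Ancestral character estimation on phylogenetic subtrees.

The ACE stage "rewinds" evolution: on each analysis subtree it estimates

* the likelihood that every ancestral node was trait-positive, under a
  2-state equal-rates (ER) Mk model fitted by maximum likelihood
  (Felsenstein pruning for the likelihood, bounded 1-D search for the
  rate, marginal states by the re-rooting method); and
* the ancestral copy number of every feature under Brownian motion,
  computed by Gaussian message passing on the tree — equivalent to the
  GLS/BM conditional expectation obtained by re-rooting at each node.

Per subtree and feature, the two reconstructions are compared by Spearman
correlation and by a Wilcoxon rank-sum test between nodes classified
trait-positive (likelihood > 0.5) and trait-negative.  P-values are BH
adjusted per subtree and test type.  Per feature, subtree correlations
are summarised as a sum of absolute r values down-weighted by their
q-values relative to the median q across all subtrees and features:

    sum |r_w| = sum_n |r_n| * w(q_c,n; q_c) * w(q_W,n; q_W),
    w(q_n; q_med) = ln(q_n + q_med) / ln(q_med),  clamped to [0, 1].

The raw weight formula goes negative as q_n approaches 1 (a log of a
value above 1 divided by a negative log); clamping preserves the intended
monotone down-weighting while keeping the statistic non-negative.

Analysis subtrees are chosen by similarity to a reference tree: the score
``s = exp(-(|ln(P_B/P_A)| + |ln(N_B/N_A)| + |ln(cv_B/cv_A)| + |ln(h_B/h_A)|))``
compares trait-positive and -negative leaf counts, edge-length
coefficient of variation, and maximum root-to-tip height between the
candidate (B) and the reference (A); candidates are accepted greedily by
descending score, skipping any whose node set overlaps an accepted one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats

from phylotrait.enrichment import bh_adjust, wilcoxon_rank_sum
from phylotrait.io import POSITIVE
from phylotrait.simulate import node_label

#: Floor for zero-length edges: keeps BM precisions finite and Mk
#: transition matrices non-degenerate.
BRANCH_LENGTH_FLOOR = 1e-9


# ---------------------------------------------------------------------------
# tree indexing


@dataclass
class IndexedTree:
    """Array view of a (sub)tree: postorder nodes, parents, edge lengths."""

    nodes: list[dendropy.Node]  # postorder
    parent: np.ndarray  # index into nodes, -1 for root
    children: list[list[int]]
    edge_length: np.ndarray  # length of edge above each node (floored)
    leaf_labels: dict[int, str]  # node index -> taxon label
    labels: list[str]  # label of every node (taxon or internal label)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def internal_indices(self) -> list[int]:
        return [i for i in range(self.n_nodes) if self.children[i]]

    @property
    def leaf_indices(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]


def index_tree(tree_or_node: dendropy.Tree | dendropy.Node) -> IndexedTree:
    root = (
        tree_or_node.seed_node
        if isinstance(tree_or_node, dendropy.Tree)
        else tree_or_node
    )
    nodes = [nd for nd in root.postorder_iter()]
    pos = {id(nd): i for i, nd in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=int)
    children: list[list[int]] = [[] for _ in nodes]
    edge_length = np.zeros(len(nodes))
    leaf_labels: dict[int, str] = {}
    labels: list[str] = []
    for i, nd in enumerate(nodes):
        if nd is not root and nd.parent_node is not None:
            parent[i] = pos[id(nd.parent_node)]
            children[parent[i]].append(i)
            edge_length[i] = max(nd.edge.length or 0.0, BRANCH_LENGTH_FLOOR)
        if nd.is_leaf():
            leaf_labels[i] = nd.taxon.label
        lab = node_label(nd)
        # unlabeled internal nodes get a stable postorder-position label so
        # per-node estimates never collide on a shared None key
        labels.append(lab if lab is not None else f"_node{i}")
    return IndexedTree(nodes, parent, children, edge_length, leaf_labels, labels)


def extract_clade(node: dendropy.Node) -> dendropy.Tree:
    """A standalone copy of the clade rooted at ``node``."""
    nwk = _node_newick(node) + ";"
    tree = dendropy.Tree.get(
        data=nwk, schema="newick", preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    tree.is_rooted = True
    return tree


def _node_newick(node: dendropy.Node) -> str:
    if node.is_leaf():
        core = node.taxon.label
    else:
        core = "(" + ",".join(_node_newick(c) for c in node.child_nodes()) + ")"
        if node.label:
            core += node.label
    length = node.edge.length if node.edge is not None and node.edge.length else 0.0
    return f"{core}:{length!r}"


# ---------------------------------------------------------------------------
# subtree statistics, scoring, selection


@dataclass
class SubtreeStats:
    """Similarity-score ingredients for one (sub)tree."""

    n_positive: int
    n_negative: int
    cv_edges: float  # SD/mean over all internal edges of the subtree
    height: float  # maximum root-to-tip path length

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.n_positive, self.n_negative, self.cv_edges, self.height)


@dataclass
class ScoredSubtree:
    node: dendropy.Node
    stats: SubtreeStats
    score: float | None  # None when the score is undefined (a zero statistic)
    n_leaves: int


def subtree_stats(node: dendropy.Node, traits: dict[str, str]) -> SubtreeStats:
    """Leaf trait counts, edge-length CV, and height of the clade at ``node``."""
    edges = []
    n_pos = n_neg = 0
    heights: dict[int, float] = {id(node): 0.0}
    max_height = 0.0
    for nd in node.preorder_iter():
        if nd is not node:
            length = nd.edge.length or 0.0
            edges.append(length)
            heights[id(nd)] = heights[id(nd.parent_node)] + length
            max_height = max(max_height, heights[id(nd)])
        if nd.is_leaf():
            if traits[nd.taxon.label] == POSITIVE:
                n_pos += 1
            else:
                n_neg += 1
    arr = np.asarray(edges)
    cv = float(arr.std(ddof=1) / arr.mean()) if len(arr) > 1 and arr.mean() > 0 else 0.0
    return SubtreeStats(n_pos, n_neg, cv, max_height)


def score_subtree(stats_b: SubtreeStats, stats_a: SubtreeStats) -> float:
    """Similarity score in (0, 1]; 1 iff all four statistics match."""
    num = stats_b.as_tuple()
    den = stats_a.as_tuple()
    if min(num) <= 0 or min(den) <= 0:
        raise ValueError("similarity score undefined: a statistic is zero or negative")
    total = sum(abs(math.log(b / a)) for b, a in zip(num, den))
    return math.exp(-total)


def enumerate_subtrees(
    tree: dendropy.Tree, min_taxa: int = 50, max_taxa: int = 300
) -> list[dendropy.Node]:
    """All internal nodes whose clade has a leaf count within the bounds."""
    out = []
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        n = sum(1 for _ in node.leaf_iter())
        if min_taxa <= n <= max_taxa:
            out.append(node)
    return out


def score_candidates(
    candidates: list[dendropy.Node],
    traits: dict[str, str],
    reference: SubtreeStats,
) -> list[ScoredSubtree]:
    scored = []
    for node in candidates:
        st = subtree_stats(node, traits)
        try:
            s = score_subtree(st, reference)
        except ValueError:
            s = None  # e.g. a one-class subtree cannot be scored
        scored.append(ScoredSubtree(node, st, s, st.n_positive + st.n_negative))
    return scored


def select_subtrees(candidates: list[ScoredSubtree]) -> list[ScoredSubtree]:
    """Greedy selection by descending score with node-set disjointness.

    Repeatedly accepts the highest-scoring remaining candidate whose node
    set (itself plus all descendants) is disjoint from every accepted
    candidate's node set.  Unscorable candidates are skipped.  Ties are
    broken by the smallest leaf label, so the result is deterministic.
    """
    scorable = [c for c in candidates if c.score is not None]

    def sort_key(c: ScoredSubtree):
        first_leaf = min(leaf.taxon.label for leaf in c.node.leaf_iter())
        return (-c.score, first_leaf)

    selected: list[ScoredSubtree] = []
    taken: set[int] = set()
    for cand in sorted(scorable, key=sort_key):
        nodes = {id(nd) for nd in cand.node.preorder_iter()}
        if nodes & taken:
            continue
        selected.append(cand)
        taken |= nodes
    return selected


# ---------------------------------------------------------------------------
# discrete (Mk) ancestral estimation


def _er_transition(q: float, t: float) -> np.ndarray:
    """ER 2-state transition matrix: off-diagonal rate q both ways."""
    same = 0.5 * (1.0 + math.exp(-2.0 * q * t))
    return np.array([[same, 1.0 - same], [1.0 - same, same]])


def _mk_partials(itree: IndexedTree, leaf_state: np.ndarray, q: float) -> tuple[np.ndarray, float]:
    """Postorder conditional likelihoods (scaled); returns (partials, loglik)."""
    n = itree.n_nodes
    down = np.zeros((n, 2))
    loglik = 0.0
    for i in range(n):
        if not itree.children[i]:
            down[i, leaf_state[i]] = 1.0
        else:
            vec = np.ones(2)
            for c in itree.children[i]:
                p = _er_transition(q, itree.edge_length[c])
                vec *= p @ down[c]
            scale = vec.sum()
            if scale <= 0 or not np.isfinite(scale):
                raise FloatingPointError("non-finite Mk likelihood")
            down[i] = vec / scale
            loglik += math.log(scale)
    root = itree.root
    loglik += math.log(float(down[root] @ np.array([0.5, 0.5])))
    return down, loglik


def _mk_loglik(itree: IndexedTree, leaf_state: np.ndarray, q: float) -> float:
    return _mk_partials(itree, leaf_state, q)[1]


def fit_mk_rate(
    itree: IndexedTree, leaf_state: np.ndarray,
    bounds: tuple[float, float] = (1e-8, 1e3),
) -> float:
    """ML rate of the ER Mk model: log-grid scan then bounded refinement."""
    lo, hi = bounds
    grid = np.geomspace(lo, hi, 40)
    lls = [_mk_loglik(itree, leaf_state, q) for q in grid]
    best = int(np.argmax(lls))
    left = grid[max(best - 1, 0)]
    right = grid[min(best + 1, len(grid) - 1)]
    if left == right:
        return float(grid[best])
    res = optimize.minimize_scalar(
        lambda lq: -_mk_loglik(itree, leaf_state, math.exp(lq)),
        bounds=(math.log(left), math.log(right)),
        method="bounded",
    )
    return float(math.exp(res.x))


def ace_discrete(
    tree: dendropy.Tree | IndexedTree,
    leaf_traits: dict[str, str],
    rate: float | None = None,
) -> pd.Series:
    """Marginal trait-positive likelihood at every internal node.

    Fits the ER Mk rate by maximum likelihood, then computes marginal
    ancestral state likelihoods by combining, at every node, the
    conditional likelihood of the clade below it with the likelihood of
    the rest of the tree (the re-rooting method).  A uniform root prior
    is used, as for a symmetric-rate model.  All-one-state input
    short-circuits to likelihood 1 for that state (the ML rate sits at
    the boundary and every reconstruction is certain).
    """
    itree = tree if isinstance(tree, IndexedTree) else index_tree(tree)
    leaf_state = np.zeros(itree.n_nodes, dtype=int)
    for i, lab in itree.leaf_labels.items():
        leaf_state[i] = 1 if leaf_traits[lab] == POSITIVE else 0
    internal = itree.internal_indices
    observed = {int(leaf_state[i]) for i in itree.leaf_indices}
    if len(observed) == 1:
        value = 1.0 if observed == {1} else 0.0
        return pd.Series({itree.labels[i]: value for i in internal}, name="trait_likelihood")

    q = fit_mk_rate(itree, leaf_state) if rate is None else rate
    down, _ = _mk_partials(itree, leaf_state, q)

    # preorder "outside" messages: likelihood of everything except the clade
    # below each node, as a function of the node's state
    out = np.ones((itree.n_nodes, 2))
    out[itree.root] = np.array([0.5, 0.5])
    order = list(range(itree.n_nodes - 1, -1, -1))  # reverse postorder = preorder
    child_msg: dict[int, np.ndarray] = {}
    for i in order:
        for c in itree.children[i]:
            p = _er_transition(q, itree.edge_length[c])
            child_msg[c] = p @ down[c]
    for i in order:
        kids = itree.children[i]
        for c in kids:
            sib = np.ones(2)
            for w in kids:
                if w != c:
                    sib *= child_msg[w]
            parent_term = out[i] * sib
            p = _er_transition(q, itree.edge_length[c])
            msg = p.T @ parent_term
            total = msg.sum()
            out[c] = msg / total if total > 0 else msg

    likelihoods = {}
    for i in internal:
        joint = down[i] * out[i]
        total = joint.sum()
        if total <= 0 or not np.isfinite(total):
            raise FloatingPointError("non-finite marginal likelihood")
        likelihoods[itree.labels[i]] = float(joint[1] / total)
    return pd.Series(likelihoods, name="trait_likelihood")


# ---------------------------------------------------------------------------
# continuous (Brownian motion) ancestral estimation


def ace_continuous(
    tree: dendropy.Tree | IndexedTree, leaf_values: pd.DataFrame
) -> pd.DataFrame:
    """ML ancestral values under Brownian motion at every internal node.

    ``leaf_values`` is leaves x features.  The estimate at a node is the
    precision-weighted mean of Gaussian messages arriving from all
    adjacent directions (children clades and the rest of the tree), each
    message's variance growing linearly with path length — exactly the
    estimate obtained by re-rooting at the node and taking the GLS/BM
    root value.  Linear in the leaf values, so all features are
    reconstructed in one pass.  Zero-length edges are floored at
    ``BRANCH_LENGTH_FLOOR``.
    """
    itree = tree if isinstance(tree, IndexedTree) else index_tree(tree)
    n = itree.n_nodes
    n_feat = leaf_values.shape[1]
    mu_up = np.zeros((n, n_feat))
    var_up = np.zeros(n)  # variance of the up message *above* each node's edge
    for i in range(n):
        kids = itree.children[i]
        if not kids:
            mu_up[i] = leaf_values.loc[itree.leaf_labels[i]].to_numpy(dtype=float)
            var_here = 0.0
        else:
            prec = np.array([1.0 / var_up[c] for c in kids])
            mu_up[i] = (prec[:, None] * mu_up[kids]).sum(axis=0) / prec.sum()
            var_here = 1.0 / prec.sum()
        var_up[i] = var_here + itree.edge_length[i]

    mu_down = np.zeros((n, n_feat))
    var_down = np.full(n, np.inf)  # root has an uninformative prior
    for i in range(n - 1, -1, -1):
        kids = itree.children[i]
        for c in kids:
            mus = [mu_up[w] for w in kids if w != c]
            precs = [1.0 / var_up[w] for w in kids if w != c]
            if np.isfinite(var_down[i]):
                mus.append(mu_down[i])
                precs.append(1.0 / var_down[i])
            total_prec = sum(precs)
            combined = sum(p * m for p, m in zip(precs, mus)) / total_prec
            mu_down[c] = combined
            var_down[c] = 1.0 / total_prec + itree.edge_length[c]

    rows = {}
    for i in itree.internal_indices:
        kids = itree.children[i]
        mus = [mu_up[c] for c in kids]
        precs = [1.0 / var_up[c] for c in kids]
        if np.isfinite(var_down[i]):
            mus.append(mu_down[i])
            precs.append(1.0 / var_down[i])
        total = sum(precs)
        rows[itree.labels[i]] = sum(p * m for p, m in zip(precs, mus)) / total
    return pd.DataFrame.from_dict(rows, orient="index", columns=leaf_values.columns)


# ---------------------------------------------------------------------------
# correlation and summary


def correlate_ancestral(
    trait_likelihood: pd.Series, ancestral_counts: pd.Series
) -> tuple[float, float, float]:
    """Spearman r / p and class-wise Wilcoxon p across internal nodes.

    Nodes are split at likelihood > 0.5 into trait-positive and
    -negative classes (ties to negative) and their ancestral counts
    compared.  Returns (r, p_corr, p_wilcox); entries are NaN when
    undefined (constant input, or an empty class).
    """
    lk = trait_likelihood.to_numpy(dtype=float)
    ct = ancestral_counts.loc[trait_likelihood.index].to_numpy(dtype=float)
    if lk.size < 4:
        raise ValueError("need >= 4 internal nodes")
    if np.unique(lk).size < 2 or np.unique(ct).size < 2:
        r, p_corr = float("nan"), float("nan")
    else:
        r, p_corr = stats.spearmanr(lk, ct)
    pos = ct[lk > 0.5]
    neg = ct[lk <= 0.5]
    if pos.size == 0 or neg.size == 0:
        p_wilcox = float("nan")
    else:
        p_wilcox = wilcoxon_rank_sum(pos, neg)
    return float(r), float(p_corr), float(p_wilcox)


def run_ace_subtree(
    subtree: dendropy.Tree | dendropy.Node,
    traits: dict[str, str],
    counts: pd.DataFrame,
    subtree_id: int | str,
) -> pd.DataFrame:
    """Reconstruct and correlate every feature on one subtree.

    Returns the per-feature table (r, p/q for both tests) with BH
    adjustment across this subtree's testing universe, separately per
    test type.
    """
    itree = index_tree(subtree)
    leaves = [itree.leaf_labels[i] for i in itree.leaf_indices]
    lk = ace_discrete(itree, {lab: traits[lab] for lab in leaves})
    anc = ace_continuous(itree, counts.loc[leaves])
    records = []
    for feat in counts.columns:
        r, p_corr, p_wilcox = correlate_ancestral(lk, anc[feat])
        records.append((feat, r, p_corr, p_wilcox))
    df = pd.DataFrame(records, columns=["Feature", "r", "p_Correlation", "p_Wilcox"])
    df["Subtree"] = subtree_id
    for col in ("p_Correlation", "p_Wilcox"):
        qcol = col.replace("p_", "q_")
        mask = df[col].notna()
        df[qcol] = np.nan
        if mask.any():
            df.loc[mask, qcol] = bh_adjust(df.loc[mask, col].to_numpy())
    df["Significant"] = (
        (df["q_Correlation"] < 0.001) & (df["q_Wilcox"] < 0.001)
    ).astype(int)
    return df


def _weight(q_n: np.ndarray, q_med: float) -> np.ndarray:
    """Correlation down-weight ln(q_n + q_med)/ln(q_med), clamped to [0, 1]."""
    q_med = min(max(q_med, 1e-300), 1.0 - 1e-12)
    w = np.log(q_n + q_med) / math.log(q_med)
    return np.clip(w, 0.0, 1.0)


def summarize_ace(per_subtree: pd.DataFrame, feature_types: pd.Series) -> pd.DataFrame:
    """Per-feature weighted |r| sum across subtrees, ranked descending.

    Medians ``q_c`` and ``q_W`` are taken across all subtrees and
    features jointly.  Subtree entries with an undefined r or q
    contribute nothing.  Features absent from every subtree get
    sum 0 and the bottom rank.
    """
    valid = per_subtree.dropna(subset=["r", "q_Correlation", "q_Wilcox"]).copy()
    if valid.empty:
        q_c = q_w = 0.5
    else:
        q_c = float(valid["q_Correlation"].median())
        q_w = float(valid["q_Wilcox"].median())
    if not valid.empty:
        valid["w"] = (
            valid["r"].abs()
            * _weight(valid["q_Correlation"].to_numpy(), q_c)
            * _weight(valid["q_Wilcox"].to_numpy(), q_w)
        )
        sums = valid.groupby("Feature")["w"].sum()
    else:
        sums = pd.Series(dtype=float)
    out = pd.DataFrame({"Feature": feature_types.index})
    out["Feature_Type"] = feature_types.values
    out["sum_abs_rw"] = out["Feature"].map(sums).fillna(0.0)
    out["Rank"] = out["sum_abs_rw"].rank(method="average", ascending=False)
    out = out.sort_values(["Rank", "Feature"], kind="stable").reset_index(drop=True)
    return out[["Rank", "Feature_Type", "Feature", "sum_abs_rw"]]
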