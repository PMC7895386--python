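"""Independent brute-force oracles used across the test suite.

Every oracle recomputes its quantity from first principles (exhaustive
enumeration, closed forms, or direct simulation) without touching the
implementation paths it checks.
"""

from __future__ import annotations

import itertools
import math
import random

import numpy as np

from phylotrait.pairing import DistanceMatrix, Pair


# ---------------------------------------------------------------------------
# random small trees (newick strings) for reconstruction oracles


def random_newick(n_leaves: int, rng: random.Random) -> str:
    """Random binary topology over n labelled leaves, random branch lengths."""
    subtrees = [f"L{i}" for i in range(n_leaves)]
    while len(subtrees) > 1:
        i, j = rng.sample(range(len(subtrees)), 2)
        a, b = subtrees[i], subtrees[j]
        la, lb = rng.uniform(0.1, 2.0), rng.uniform(0.1, 2.0)
        merged = f"({a}:{la:.4f},{b}:{lb:.4f})"
        subtrees = [s for k, s in enumerate(subtrees) if k not in (i, j)]
        subtrees.append(merged)
    return subtrees[0] + ";"


# ---------------------------------------------------------------------------
# Mk model: exhaustive state enumeration


def er_transition(q: float, t: float) -> np.ndarray:
    same = 0.5 * (1.0 + math.exp(-2.0 * q * t))
    return np.array([[same, 1.0 - same], [1.0 - same, same]])


def mk_marginals_bruteforce(itree, leaf_state: np.ndarray, q: float) -> dict[int, float]:
    """Marginal P(node = state 1) by summing over all internal assignments.

    For every assignment of states to internal nodes, the joint
    probability is the root prior (uniform) times the product of edge
    transition probabilities; marginals are ratios of restricted sums.
    """
    internal = itree.internal_indices
    leaves = itree.leaf_indices
    totals = {i: 0.0 for i in internal}
    grand = 0.0
    for assignment in itertools.product((0, 1), repeat=len(internal)):
        state = dict(zip(internal, assignment))
        for i in leaves:
            state[i] = int(leaf_state[i])
        prob = 0.5  # uniform root prior
        for i in range(itree.n_nodes - 1):  # root is last in postorder
            p = itree.parent[i]
            trans = er_transition(q, itree.edge_length[i])
            prob_edge = trans[state[p], state[i]]
            prob *= prob_edge
        grand += prob
        for i in internal:
            if state[i] == 1:
                totals[i] += prob
    return {i: totals[i] / grand for i in internal}


def mk_loglik_bruteforce(itree, leaf_state: np.ndarray, q: float) -> float:
    internal = itree.internal_indices
    leaves = itree.leaf_indices
    grand = 0.0
    for assignment in itertools.product((0, 1), repeat=len(internal)):
        state = dict(zip(internal, assignment))
        for i in leaves:
            state[i] = int(leaf_state[i])
        prob = 0.5
        for i in range(itree.n_nodes - 1):
            p = itree.parent[i]
            prob *= er_transition(q, itree.edge_length[i])[state[p], state[i]]
        grand += prob
    return math.log(grand)


# ---------------------------------------------------------------------------
# Brownian motion: GLS from the covariance of shared path lengths


def bm_gls_estimate(itree, leaf_values: np.ndarray, node_index: int) -> float:
    """BM ancestral estimate at a node from the re-rooted GLS closed form.

    V[i, j] is the shared path length from the focal node towards leaves
    i and j; the estimate is (1' V^-1 y) / (1' V^-1 1).
    """
    dist = _all_pairs_distances(itree)
    leaves = itree.leaf_indices
    n = len(leaves)
    V = np.empty((n, n))
    for a, la in enumerate(leaves):
        for b, lb in enumerate(leaves):
            V[a, b] = 0.5 * (
                dist[node_index][la] + dist[node_index][lb] - dist[la][lb]
            )
    Vinv = np.linalg.inv(V)
    ones = np.ones(n)
    return float(ones @ Vinv @ leaf_values / (ones @ Vinv @ ones))


def _all_pairs_distances(itree) -> dict[int, dict[int, float]]:
    """Path lengths between all node pairs via adjacency BFS."""
    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(itree.n_nodes)}
    for i in range(itree.n_nodes - 1):
        p = itree.parent[i]
        adj[i].append((p, itree.edge_length[i]))
        adj[p].append((i, itree.edge_length[i]))
    out = {}
    for start in range(itree.n_nodes):
        seen = {start: 0.0}
        frontier = [start]
        while frontier:
            nxt = []
            for u in frontier:
                for v, w in adj[u]:
                    if v not in seen:
                        seen[v] = seen[u] + w
                        nxt.append(v)
            frontier = nxt
        out[start] = seen
    return out


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum: full enumeration of rank assignments


def wilcoxon_exact_bruteforce(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact p by enumerating all C(n+m, n) group assignments.

    Tie-free input only.  Matches the convention p = 2 * min(P(U <= u),
    P(U >= u)), capped at 1.
    """
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    ranks = pooled.argsort().argsort() + 1
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    us = []
    for combo in itertools.combinations(range(n + m), n):
        r = ranks[list(combo)].sum() - n * (n + 1) / 2
        us.append(r)
    us = np.array(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# greedy pairing: re-scan global minimum each iteration


def greedy_pairs_bruteforce(d: DistanceMatrix) -> list[Pair]:
    """Re-finds the global minimum from scratch at every iteration."""
    remaining_rows = sorted(d.data.index)
    remaining_cols = sorted(d.data.columns)
    pairs = []
    while remaining_rows:
        best = None
        for r in remaining_rows:
            for c in remaining_cols:
                val = float(d.data.loc[r, c])
                key = (val, r, c)
                if best is None or key < best:
                    best = key
        val, r, c = best
        pairs.append(Pair(r, c, val))
        remaining_rows.remove(r)
        remaining_cols.remove(c)
    return pairs


# ---------------------------------------------------------------------------
# Spearman: rank then Pearson


def spearman_bruteforce(x: np.ndarray, y: np.ndarray) -> float:
    def avg_ranks(v: np.ndarray) -> np.ndarray:
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v), dtype=float)
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / math.sqrt((rx @ rx) * (ry @ ry)))
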