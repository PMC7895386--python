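import numpy as np
import pytest

from phylotrait.io import NEGATIVE, POSITIVE
from phylotrait.simulate import (
    SimulationConfig,
    simulate_counts,
    simulate_dataset,
    simulate_orfs,
    simulate_trait,
    simulate_tree,
    transition_matrix,
)
from phylotrait.io import tree_to_newick


def test_tree_shape_and_determinism():
    cfg = SimulationConfig(n_genomes=4, seed=1)
    tree = simulate_tree(cfg)
    assert sum(1 for _ in tree.leaf_node_iter()) == 4
    assert sum(1 for n in tree.preorder_node_iter() if not n.is_leaf()) == 3
    assert all(
        (n.edge.length or 0) > 0 for n in tree.preorder_node_iter() if n.parent_node
    )
    assert tree_to_newick(simulate_tree(cfg)) == tree_to_newick(simulate_tree(cfg))


def test_tree_height_matches_pure_birth_expectation():
    """Mean root-to-tip height agrees with a direct Monte-Carlo oracle.

    The oracle resimulates only the waiting times of the birth process
    (sums of exponentials), independent of the tree-building code.
    """
    n, lam, reps = 8, 1.0, 500
    heights = []
    for seed in range(reps):
        tree = simulate_tree(SimulationConfig(n_genomes=n, birth_rate=lam, seed=seed))
        leaf = next(tree.leaf_node_iter())
        h = 0.0
        while leaf.parent_node is not None:
            h += leaf.edge.length
            leaf = leaf.parent_node
        heights.append(h)
    rng = np.random.default_rng(12345)
    oracle = np.zeros(20000)
    for k in range(2, n + 1):
        oracle += rng.exponential(1.0 / (lam * k), size=oracle.size)
    oracle += rng.exponential(1.0 / (lam * n), size=oracle.size)
    se = np.std(heights, ddof=1) / np.sqrt(reps)
    assert abs(np.mean(heights) - oracle.mean()) < 3 * se + 3 * oracle.std() / np.sqrt(oracle.size)


def test_trait_absorbing_case():
    """Zero gain rate and a negative root leave every node negative."""
    cfg = SimulationConfig(n_genomes=20, q01=0.0, q10=0.5, seed=3)
    tree = simulate_tree(cfg)
    states = simulate_trait(tree, cfg)
    assert set(states.values()) == {NEGATIVE}


def test_trait_symmetric_rates_half_positive():
    """Equal gain/loss on long branches yields a ~50% positive fraction."""
    n = 4096
    cfg = SimulationConfig(
        n_genomes=n, q01=1.0, q10=1.0, birth_rate=0.1, seed=5
    )  # slow birth -> long branches -> leaves near stationarity
    tree = simulate_tree(cfg)
    states = simulate_trait(tree, cfg)
    frac = np.mean(
        [states[l.taxon.label] == POSITIVE for l in tree.leaf_node_iter()]
    )
    assert abs(frac - 0.5) < 4 * np.sqrt(0.25 / n)


@pytest.mark.parametrize("q01,q10,t", [(0.3, 0.7, 0.8), (1.0, 1.0, 0.25)])
def test_transition_matrix_vs_small_step_simulation(q01, q10, t):
    """Matrix-exponential probabilities match a brute-force Euler chain."""
    rng = np.random.default_rng(7)
    reps, dt = 40000, 1e-3
    steps = int(round(t / dt))
    for start in (0, 1):
        states = np.full(reps, start)
        for _ in range(steps):
            u = rng.random(reps)
            go_up = (states == 0) & (u < q01 * dt)
            go_down = (states == 1) & (u < q10 * dt)
            states = np.where(go_up, 1, np.where(go_down, 0, states))
        p1 = states.mean()
        expected = transition_matrix(q01, q10, t)[start, 1]
        se = np.sqrt(expected * (1 - expected) / reps)
        assert abs(p1 - expected) < 4 * se + q01 * dt + q10 * dt


def test_counts_degenerate_poisson():
    """No BM and no effect: every cell is Poisson(exp(base_log_mean))."""
    cfg = SimulationConfig(
        n_genomes=100, n_features=100, bm_sigma2=0.0, effect_beta=0.0,
        base_log_mean=1.0, frac_linked=0.1, seed=9,
    )
    rng = np.random.default_rng(cfg.seed)
    tree = simulate_tree(cfg, rng)
    traits = simulate_trait(tree, cfg, rng)
    matrix, _, _ = simulate_counts(tree, traits, cfg, rng)
    values = matrix.counts.values.ravel()
    mean = np.exp(1.0)
    se = np.sqrt(mean / values.size)
    assert abs(values.mean() - mean) < 3 * se


def test_counts_effect_ratio():
    """effect_beta=2 multiplies expected copies in positive leaves by e^2."""
    cfg = SimulationConfig(
        n_genomes=400, n_features=200, bm_sigma2=0.001, effect_beta=2.0,
        base_log_mean=0.5, frac_linked=0.5, q01=1.0, q10=1.0, seed=13,
    )
    rng = np.random.default_rng(cfg.seed)
    tree = simulate_tree(cfg, rng)
    traits = simulate_trait(tree, cfg, rng)
    matrix, linked, _ = simulate_counts(tree, traits, cfg, rng)
    leaves = matrix.genomes
    pos = [l for l in leaves if traits[l] == POSITIVE]
    neg = [l for l in leaves if traits[l] == NEGATIVE]
    ratio = (
        matrix.counts.loc[pos, linked].values.mean()
        / matrix.counts.loc[neg, linked].values.mean()
    )
    assert ratio == pytest.approx(np.exp(2.0), rel=0.15)


def test_null_effect_features_indistinguishable(small_dataset):
    """With effect_beta=0 linked and unlinked features look alike."""
    cfg = SimulationConfig(
        n_genomes=100, n_features=100, effect_beta=0.0, frac_linked=0.5, seed=21
    )
    sim = simulate_dataset(cfg)
    linked = set(sim.linked_features)
    linked_mean = sim.matrix.counts[sorted(linked)].values.mean()
    other = [f for f in sim.matrix.features if f not in linked]
    other_mean = sim.matrix.counts[other].values.mean()
    assert linked_mean == pytest.approx(other_mean, rel=0.25)


def test_orf_feature_multiset_conservation(small_dataset):
    """Per-genome ORF annotations carry exactly the matrix row's copies."""
    sim = small_dataset
    for g in sim.genomes:
        from collections import Counter

        placed = Counter()
        for orf in sim.orfs:
            if orf.genome == g.accession:
                for f in orf.features:
                    placed[f] += 1
        row = sim.matrix.counts.loc[g.accession]
        expected = Counter({f: int(c) for f, c in row.items() if c > 0})
        if g.trait_status == POSITIVE:
            for m in sim.marker_features:
                expected[m] += 1
        assert placed == expected


def test_orf_colocation_places_markers_adjacent():
    """Certain co-location puts linked features right next to the markers."""
    cfg = SimulationConfig(
        n_genomes=30, n_features=10, frac_linked=0.2, colocation_prob=1.0,
        effect_beta=2.0, seed=17,
    )
    sim = simulate_dataset(cfg)
    marker_idx = {}
    for orf in sim.orfs:
        for m in sim.marker_features:
            if m in orf.features:
                marker_idx.setdefault((orf.genome, orf.contig), []).append(orf.index)
    found_adjacent = 0
    for orf in sim.orfs:
        key = (orf.genome, orf.contig)
        if key not in marker_idx:
            continue
        for f in orf.features:
            if f in set(sim.linked_features):
                d = min(abs(orf.index - mi) for mi in marker_idx[key])
                assert d <= 2 + sum(
                    1 for o in sim.orfs
                    if o.genome == orf.genome and o.contig == orf.contig
                    and set(o.features) & set(sim.linked_features)
                )
                found_adjacent += 1
    assert found_adjacent > 0


def test_dataset_determinism_and_sidecar(tmp_path):
    cfg = SimulationConfig(n_genomes=20, n_features=20, seed=2)
    a, b = simulate_dataset(cfg), simulate_dataset(cfg)
    assert a.matrix.counts.equals(b.matrix.counts)
    assert a.node_states == b.node_states
    assert a.orfs == b.orfs
    paths = a.write(tmp_path)
    assert paths["truth"].exists() and paths["truth_states"].exists()
    text = paths["truth"].read_text()
    assert text.count("\t1\n") == len(a.linked_features)


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(n_genomes=3)
    with pytest.raises(ValueError):
        SimulationConfig(frac_linked=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(q01=-0.1)
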