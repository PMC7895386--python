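"""Synthetic trees, traits, copy-number matrices, and ORF tables.

The generator emulates the pipeline's real inputs: a rooted ultrametric
pure-birth (Yule) tree over ``n_genomes`` genomes, a binary trait evolved
along it under a 2-state continuous-time Markov chain, and a genomes x
features copy-number matrix in which a stated fraction of features have
trait-dependent expected copy number while the rest evolve neutrally.

Copy-number model: each feature's latent log-mean evolves by Brownian
motion (variance rate ``bm_sigma2`` per unit branch length) from
``base_log_mean``; for trait-linked features, ``effect_beta`` is added to
the log-mean of trait-positive leaves (the trait acts multiplicatively on
expected copies, matching the log2 copy-number-ratio scale on which
enrichment is interpreted).  Observed leaf counts are Poisson around the
exponentiated latent mean.

Ground truth (internal trait states, linked-feature list, latent means)
is retained on the returned dataset and written to a sidecar file, so
parameter-recovery tests are self-describing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from phylotrait.io import (
    NEGATIVE,
    POSITIVE,
    FeatureMatrix,
    GenomeRecord,
    OrfRecord,
    write_feature_table,
    write_orf_table,
    write_tree,
)

#: Marker features planted in trait-positive genomes' ORF tables.  The two
#: ids stand for the Calvin-cycle markers (Rubisco, phosphoribulokinase).
DEFAULT_MARKERS = ("4.1.1.39", "2.7.1.19")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Defaults are the benchmark conditions used throughout the test suite:
    200 genomes, 300 features of which 10% are trait-linked with a log-scale
    effect of 1.5 (≈ 4.5-fold change in expected copies).
    """

    n_genomes: int = 200
    birth_rate: float = 1.0
    q01: float = 0.2  # trait gain rate per unit branch length
    q10: float = 0.4  # trait loss rate (gain < loss: the trait is the minority state)
    n_features: int = 300
    frac_linked: float = 0.1
    base_log_mean: float = 0.0
    effect_beta: float = 1.5
    bm_sigma2: float = 0.1
    seed: int = 1
    frac_pfam: float = 0.5
    colocation_prob: float = 0.8
    seed_orfs: int | None = None  # derived from seed when None

    def __post_init__(self) -> None:
        if self.n_genomes < 4:
            raise ValueError("n_genomes must be >= 4")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be positive")
        if min(self.q01, self.q10, self.bm_sigma2) < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.frac_linked <= 1.0:
            raise ValueError("frac_linked must be in [0, 1]")


@dataclass
class SyntheticDataset:
    """A complete simulated input set plus its ground truth."""

    config: SimulationConfig
    tree: dendropy.Tree
    genomes: list[GenomeRecord]
    matrix: FeatureMatrix
    orfs: list[OrfRecord]
    node_states: dict[str, str]  # node label -> positive/negative (incl. internal)
    linked_features: list[str]
    marker_features: tuple[str, ...] = DEFAULT_MARKERS
    latent_means: pd.DataFrame | None = None  # leaves x features log-means

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write feature table, newick tree, ORF table, and truth sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "feature_table": outdir / "features.tsv",
            "tree": outdir / "tree.nwk",
            "orfs": outdir / "orfs.tsv",
            "truth": outdir / "truth.tsv",
        }
        write_feature_table(paths["feature_table"], self.genomes, self.matrix)
        write_tree(self.tree, paths["tree"])
        write_orf_table(paths["orfs"], self.orfs)
        truth = pd.DataFrame(
            {
                "feature": self.matrix.features,
                "type": [self.matrix.types[f] for f in self.matrix.features],
                "linked": [int(f in set(self.linked_features)) for f in self.matrix.features],
            }
        )
        truth.to_csv(paths["truth"], sep="\t", index=False)
        states = pd.DataFrame(
            sorted(self.node_states.items()), columns=["node", "state"]
        )
        states.to_csv(outdir / "truth_states.tsv", sep="\t", index=False)
        paths["truth_states"] = outdir / "truth_states.tsv"
        return paths


# ---------------------------------------------------------------------------
# tree


def simulate_tree(config: SimulationConfig, rng: np.random.Generator | None = None) -> dendropy.Tree:
    """Simulate a rooted ultrametric pure-birth tree with ``n_genomes`` leaves.

    Forward Yule process: starting from a root bifurcation, every extant
    lineage splits at rate ``birth_rate``; after the n-th lineage appears
    one further exponential waiting time is appended so leaves are
    contemporaneous.  Leaf labels are ``G0001..Gnnnn`` in birth order.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n, lam = config.n_genomes, config.birth_rate
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    root = tree.seed_node
    active: list[dendropy.Node] = []
    for _ in range(2):
        child = root.new_child(edge_length=0.0)
        active.append(child)
    while len(active) < n:
        wait = rng.exponential(1.0 / (lam * len(active)))
        for node in active:
            node.edge.length += wait
        idx = int(rng.integers(len(active)))
        parent = active.pop(idx)
        for _ in range(2):
            child = parent.new_child(edge_length=0.0)
            active.append(child)
    final = rng.exponential(1.0 / (lam * n))
    for node in active:
        node.edge.length += final
    for i, node in enumerate(active):
        node.taxon = taxa.new_taxon(label=f"G{i + 1:04d}")
    _label_internal_nodes(tree)
    return tree


def _label_internal_nodes(tree: dendropy.Tree) -> None:
    """Give every internal node a stable label (preorder N0, N1, ...)."""
    counter = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if not node.label:
            node.label = f"N{counter}"
        counter += 1


def node_label(node: dendropy.Node) -> str:
    return node.taxon.label if node.taxon is not None else node.label


# ---------------------------------------------------------------------------
# trait


def transition_matrix(q01: float, q10: float, t: float) -> np.ndarray:
    """2-state CTMC transition probabilities over branch length ``t``.

    Rows index the starting state (0 = negative, 1 = positive).
    """
    s = q01 + q10
    if s == 0:
        return np.eye(2)
    decay = math.exp(-s * t)
    pi1 = q01 / s
    pi0 = 1.0 - pi1
    return np.array(
        [
            [pi0 + pi1 * decay, pi1 - pi1 * decay],
            [pi0 - pi0 * decay, pi1 + pi0 * decay],
        ]
    )


def simulate_trait(
    tree: dendropy.Tree,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, str]:
    """Evolve the binary trait along the tree; return node label -> state.

    The root state is drawn from the stationary distribution
    ``q01/(q01+q10)``; when both rates are zero the root is negative and
    the trait never changes.  Internal-node states are retained so
    ancestral-reconstruction accuracy can be measured against truth.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    _label_internal_nodes(tree)
    s = config.q01 + config.q10
    pi1 = config.q01 / s if s > 0 else 0.0
    states: dict[str, str] = {}
    node_state: dict[int, int] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            state = int(rng.random() < pi1)
        else:
            parent_state = node_state[id(node.parent_node)]
            p = transition_matrix(config.q01, config.q10, node.edge.length or 0.0)
            state = int(rng.random() < p[parent_state, 1])
        node_state[id(node)] = state
        states[node_label(node)] = POSITIVE if state else NEGATIVE
    return states


# ---------------------------------------------------------------------------
# counts


def _feature_ids(config: SimulationConfig) -> list[str]:
    n_pfam = int(round(config.n_features * config.frac_pfam))
    n_ec = config.n_features - n_pfam
    ec = [f"9.9.{i // 100 + 1}.{i % 100 + 1}" for i in range(n_ec)]
    pfam = [f"PF9{i:04d}" for i in range(n_pfam)]
    return ec + pfam


def simulate_counts(
    tree: dendropy.Tree,
    traits: dict[str, str],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[FeatureMatrix, list[str], pd.DataFrame]:
    """Simulate the copy-number matrix; return (matrix, linked ids, latents).

    Latent log-means follow Brownian motion down the tree; linked features
    additionally receive ``effect_beta`` on trait-positive leaves.  Leaf
    counts are Poisson around the exponentiated latent mean.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    features = _feature_ids(config)
    n_linked = int(round(config.n_features * config.frac_linked))
    linked_idx = rng.choice(config.n_features, size=n_linked, replace=False)
    linked = sorted(features[i] for i in linked_idx)
    linked_mask = np.zeros(config.n_features, dtype=bool)
    linked_mask[linked_idx] = True

    leaves = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    latent: dict[int, np.ndarray] = {}
    leaf_latent = np.zeros((len(leaves), config.n_features))
    leaf_pos = {lab: i for i, lab in enumerate(leaves)}
    sd_unit = math.sqrt(config.bm_sigma2)
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            latent[id(node)] = np.full(config.n_features, config.base_log_mean)
        else:
            t = node.edge.length or 0.0
            step = rng.normal(0.0, sd_unit * math.sqrt(t), size=config.n_features)
            latent[id(node)] = latent[id(node.parent_node)] + step
        if node.is_leaf():
            leaf_latent[leaf_pos[node.taxon.label]] = latent[id(node)]

    log_mean = leaf_latent.copy()
    positive = np.array([traits[lab] == POSITIVE for lab in leaves])
    log_mean[np.ix_(positive, linked_mask)] += config.effect_beta
    counts = rng.poisson(np.exp(log_mean))
    matrix = FeatureMatrix(
        pd.DataFrame(counts, index=pd.Index(leaves, name="Accession"), columns=features)
    )
    latents = pd.DataFrame(log_mean, index=leaves, columns=features)
    return matrix, linked, latents


# ---------------------------------------------------------------------------
# ORFs


def simulate_orfs(
    genomes: list[GenomeRecord],
    matrix: FeatureMatrix,
    config: SimulationConfig,
    marker_features: tuple[str, ...] = DEFAULT_MARKERS,
    colocated_features: set[str] | None = None,
    rng: np.random.Generator | None = None,
) -> list[OrfRecord]:
    """Place every feature copy on an ORF; plant marker operons.

    Each genome receives 1-3 contigs.  Trait-positive genomes carry one
    ORF per marker feature, adjacent to each other on the first contig
    (same strand).  Copies of ``colocated_features`` are placed directly
    downstream of the marker block with probability ``colocation_prob``,
    emulating operon-like clustering; all other copies land on random
    ORFs.  Each copy occupies its own ORF, so the per-genome ORF feature
    multiset equals the matrix row.
    """
    seed = config.seed_orfs if config.seed_orfs is not None else config.seed + 7
    rng = rng if rng is not None else np.random.default_rng(seed)
    colocated = colocated_features or set()
    orfs: list[OrfRecord] = []
    molecule_choices = ("chromosome", "plasmid", "unknown")
    for genome in genomes:
        row = matrix.counts.loc[genome.accession]
        copies: list[str] = []
        for feat, cnt in row.items():
            copies.extend([feat] * int(cnt))
        n_contigs = int(rng.integers(1, 4))
        is_positive = genome.trait_status == POSITIVE
        # contig sizes: enough room for all copies plus markers plus padding
        n_padding = int(rng.integers(5, 15))
        total = len(copies) + (len(marker_features) if is_positive else 0) + n_padding
        cuts = sorted(rng.choice(max(total - 1, 1), size=n_contigs - 1, replace=False).tolist())
        sizes = np.diff([0, *[c + 1 for c in cuts], total]).tolist()
        sizes = [s for s in sizes if s > 0] or [total]
        contigs = []
        for ci, size in enumerate(sizes):
            molecule = "chromosome" if ci == 0 else molecule_choices[int(rng.integers(1, 3))]
            contigs.append({"name": f"{genome.accession}_c{ci}", "molecule": molecule, "size": size})
        # slot assignment: list of (contig_idx, index, strand, features)
        assignments: list[tuple[int, int, str, frozenset[str]]] = []
        used: dict[int, set[int]] = {i: set() for i in range(len(contigs))}
        cursor = 0
        if is_positive:
            # marker operon at the start of contig 0
            strand = "+" if rng.random() < 0.5 else "-"
            for mi, marker in enumerate(marker_features):
                assignments.append((0, mi, strand, frozenset([marker])))
                used[0].add(mi)
            cursor = len(marker_features)
            pending = []
            for feat in copies:
                if feat in colocated and rng.random() < config.colocation_prob:
                    assignments.append((0, cursor, strand, frozenset([feat])))
                    used[0].add(cursor)
                    cursor += 1
                else:
                    pending.append(feat)
            copies = pending
            contigs[0]["size"] = max(contigs[0]["size"], cursor)
        # random placement for remaining copies
        for feat in copies:
            ci = int(rng.integers(len(contigs)))
            size = contigs[ci]["size"]
            free = [i for i in range(size + len(copies)) if i not in used[ci]]
            idx = free[int(rng.integers(len(free)))]
            strand = "+" if rng.random() < 0.5 else "-"
            assignments.append((ci, idx, strand, frozenset([feat])))
            used[ci].add(idx)
        for ci, idx, strand, feats in assignments:
            orfs.append(
                OrfRecord(
                    genome=genome.accession,
                    contig=contigs[ci]["name"],
                    molecule=contigs[ci]["molecule"],
                    index=idx,
                    strand=strand,
                    features=feats,
                )
            )
    return orfs


# ---------------------------------------------------------------------------
# orchestration


def simulate_dataset(config: SimulationConfig | None = None, **overrides) -> SyntheticDataset:
    """Generate a complete synthetic input set (tree, traits, counts, ORFs).

    Deterministic for a fixed config: all stages draw from one seeded
    generator in a fixed order.
    """
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config, rng)
    states = simulate_trait(tree, config, rng)
    matrix, linked, latents = simulate_counts(tree, states, config, rng)
    genomes = [
        GenomeRecord(
            accession=leaf.taxon.label,
            trait_status=states[leaf.taxon.label],
            completeness=100.0,
            taxonomy="d__Synthetica;p__Simulata;c__;o__;f__;g__;s__",
        )
        for leaf in tree.leaf_node_iter()
    ]
    orf_rng = np.random.default_rng(
        config.seed_orfs if config.seed_orfs is not None else config.seed + 7
    )
    orfs = simulate_orfs(
        genomes, matrix, config,
        colocated_features=set(linked), rng=orf_rng,
    )
    return SyntheticDataset(
        config=config,
        tree=tree,
        genomes=genomes,
        matrix=matrix,
        orfs=orfs,
        node_states=states,
        linked_features=linked,
        latent_means=latents,
    )
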