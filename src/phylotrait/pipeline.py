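"""End-to-end orchestration of the trait-association pipeline.

Stage order: (simulate) -> classify -> pair -> enrich -> ace -> forest ->
consensus -> proximity.  Stages communicate through in-memory containers;
``run_pipeline`` optionally writes every stage's table plus a manifest
recording seeds, thresholds, and per-stage row counts.  Enrichment, ACE,
and consensus are fully deterministic; the forest stage is deterministic
for a fixed master seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from phylotrait import ace as ace_mod
from phylotrait.consensus import consensus_rank, rank_method
from phylotrait.enrichment import DEFAULT_EXCLUDED_FEATURES, run_enrichment
from phylotrait.forest import ForestConfig, run_forest
from phylotrait.io import (
    NEGATIVE,
    POSITIVE,
    FeatureMatrix,
    GenomeRecord,
    OrfRecord,
    read_feature_table,
    read_orf_table,
    read_tree,
)
from phylotrait.pairing import DistanceMatrix, pairs_table, select_pairs, summarize_pair_distances
from phylotrait.proximity import orf_distances, summarize_proximity
from phylotrait.simulate import DEFAULT_MARKERS, SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds and knobs for a full pipeline run."""

    completeness_min: float = 95.0
    min_taxa: int = 50
    max_taxa: int = 300
    enrichment_q_max: float = 0.05
    ace_q_max: float = 0.001
    exclude_features: frozenset[str] = DEFAULT_EXCLUDED_FEATURES
    marker_features: tuple[str, ...] = DEFAULT_MARKERS
    forest: ForestConfig = field(default_factory=ForestConfig)
    seed: int = 0


@dataclass
class PipelineResult:
    genomes: list[GenomeRecord]
    pairs: pd.DataFrame
    pair_summary: dict[str, float]
    enrichment: pd.DataFrame
    ace_per_subtree: pd.DataFrame
    ace_summary: pd.DataFrame
    subtree_info: pd.DataFrame
    forest: pd.DataFrame
    forest_accuracy: dict[str, float]
    consensus: pd.DataFrame
    proximity: pd.DataFrame | None
    manifest: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.pairs.to_csv(outdir / "pairs.tsv", sep="\t", index=False)
        self.enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        self.ace_per_subtree.to_csv(outdir / "ace_subtrees.tsv", sep="\t", index=False)
        self.ace_summary.to_csv(outdir / "ace_summary.tsv", sep="\t", index=False)
        self.subtree_info.to_csv(outdir / "subtree_info.tsv", sep="\t", index=False)
        self.forest.to_csv(outdir / "forest.tsv", sep="\t", index=False)
        self.consensus.to_csv(outdir / "consensus.tsv", sep="\t")
        if self.proximity is not None:
            self.proximity.to_csv(outdir / "proximity.tsv", sep="\t", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)


def pair_genomes(
    genomes: list[GenomeRecord], tree: dendropy.Tree
) -> tuple[list[GenomeRecord], pd.DataFrame, dict[str, float]]:
    """Pair every trait-positive genome with its closest unused negative.

    Distances are patristic on the supplied tree.  Returns the paired
    genome records (positives plus their selected relatives, with
    ``relative`` and ``distance`` filled in), the pairs table, and the
    distance summary.
    """
    positives = [g.accession for g in genomes if g.trait_status == POSITIVE]
    negatives = [g.accession for g in genomes if g.trait_status == NEGATIVE]
    if not positives:
        raise ValueError("no trait-positive genomes to pair")
    d = DistanceMatrix.from_tree(tree, positives, negatives)
    pairs = select_pairs(d)
    by_acc = {g.accession: g for g in genomes}
    kept: list[GenomeRecord] = []
    for p in pairs:
        pos, neg = by_acc[p.positive], by_acc[p.negative]
        pos.relative, pos.distance = p.negative, p.distance
        neg.relative, neg.distance = p.positive, p.distance
        kept.extend([pos, neg])
    return kept, pairs_table(pairs), summarize_pair_distances(pairs)


def choose_reference_clade(
    tree: dendropy.Tree, traits: dict[str, str]
) -> tuple[dendropy.Node | None, ace_mod.SubtreeStats]:
    """Pick the held-out reference clade for subtree scoring.

    The smaller root child acts as the reference (playing the role a
    separate domain, e.g. the archaeal tree, plays on real data) when its
    statistics are all strictly positive; otherwise the whole tree's
    statistics are the reference and no clade is held out.
    """
    children = tree.seed_node.child_nodes()
    if len(children) >= 2:
        sized = sorted(children, key=lambda c: sum(1 for _ in c.leaf_iter()))
        candidate = sized[0]
        st = ace_mod.subtree_stats(candidate, traits)
        if min(st.as_tuple()) > 0 and st.n_positive + st.n_negative >= 8:
            return candidate, st
    return None, ace_mod.subtree_stats(tree.seed_node, traits)


def run_ace_stage(
    tree: dendropy.Tree,
    genomes: list[GenomeRecord],
    matrix: FeatureMatrix,
    config: PipelineConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Subtree selection plus per-subtree ancestral reconstruction.

    The tree is pruned to the analysed genomes first.  The reference
    clade (when one exists) is analysed as subtree 0; accepted candidates
    follow as subtrees 1..k in selection order.  Genome records get their
    subtree id filled in.
    """
    accessions = [g.accession for g in genomes]
    pruned = tree.clone(depth=1)
    pruned.retain_taxa_with_labels(accessions)
    traits = {g.accession: g.trait_status for g in genomes}
    reference, ref_stats = choose_reference_clade(pruned, traits)
    # the full tree is the universe being partitioned, never an analysis
    # subtree of itself: whole-tree reconstruction is exactly the regime in
    # which ancestral trait signal washes out
    all_candidates = [
        nd for nd in ace_mod.enumerate_subtrees(pruned, config.min_taxa, config.max_taxa)
        if nd is not pruned.seed_node
    ]
    if reference is not None:
        held_out = {id(nd) for nd in reference.preorder_iter()}
        candidates = [
            nd for nd in all_candidates
            if id(nd) not in held_out
            and not any(id(d) in held_out for d in nd.preorder_iter())
        ]
    else:
        candidates = all_candidates
    scored = ace_mod.score_candidates(candidates, traits, ref_stats)
    selected = ace_mod.select_subtrees(scored)

    analysis: list[tuple[int, dendropy.Node, ace_mod.SubtreeStats, float | None]] = []
    if reference is not None:
        analysis.append((0, reference, ref_stats, 1.0))
    analysis.extend(
        (i + 1, c.node, c.stats, c.score) for i, c in enumerate(selected)
    )

    counts = matrix.counts.astype(float)
    tables = []
    info_rows = []
    by_acc = {g.accession: g for g in genomes}
    for subtree_id, node, st, score in analysis:
        leaves = [leaf.taxon.label for leaf in node.leaf_iter()]
        for lab in leaves:
            if lab in by_acc:
                by_acc[lab].subtree = subtree_id
        n_internal = sum(1 for nd in node.preorder_iter() if not nd.is_leaf())
        if n_internal < 4 or st.n_positive == 0 or st.n_negative == 0:
            logger.info("skipping degenerate subtree %s", subtree_id)
            continue
        tables.append(
            ace_mod.run_ace_subtree(node, traits, counts.loc[leaves], subtree_id)
        )
        info_rows.append(
            {
                "Subtree": subtree_id,
                "n_leaves": len(leaves),
                "n_positive": st.n_positive,
                "n_negative": st.n_negative,
                "cv_edges": st.cv_edges,
                "height": st.height,
                "score": score,
            }
        )
    per_subtree = (
        pd.concat(tables, ignore_index=True)
        if tables
        else pd.DataFrame(columns=["Feature", "r", "p_Correlation", "p_Wilcox",
                                   "Subtree", "q_Correlation", "q_Wilcox", "Significant"])
    )
    summary = ace_mod.summarize_ace(per_subtree, matrix.types)
    info = pd.DataFrame(info_rows)
    return per_subtree, summary, info


def run_pipeline(
    genomes: list[GenomeRecord],
    matrix: FeatureMatrix,
    tree: dendropy.Tree,
    orfs: list[OrfRecord] | None = None,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run pair -> enrich -> ace -> forest -> consensus -> proximity.

    ``genomes`` must carry trait status (from the classification stage or
    the input table).  When ``orfs`` is None the proximity stage is
    skipped.  When ``outdir`` is given, all stage tables and a manifest
    are written there.
    """
    config = config or PipelineConfig()
    paired, pairs, pair_summary = pair_genomes(genomes, tree)
    paired_acc = [g.accession for g in paired]
    sub_matrix = matrix.subset_genomes(paired_acc)

    enrich = run_enrichment(
        paired, sub_matrix,
        completeness_min=config.completeness_min,
        exclude_features=config.exclude_features,
    )
    ace_matrix = FeatureMatrix(
        sub_matrix.counts.drop(columns=[f for f in config.exclude_features
                                        if f in sub_matrix.counts.columns]),
    )
    per_subtree, ace_summary, subtree_info = run_ace_stage(tree, paired, ace_matrix, config)
    forest_table, accuracy = run_forest(paired, ace_matrix, config.forest)

    ranks = {
        "enrichment": rank_method(enrich.set_index("Feature")["q"], "ascending"),
        "ace": rank_method(ace_summary.set_index("Feature")["sum_abs_rw"], "descending"),
        "forest": forest_table.set_index("Feature")["Rank"],
    }
    consensus = consensus_rank(ranks)
    consensus["Feature_Type"] = consensus.index.map(matrix.types)
    consensus["mean_Negative"] = consensus.index.map(enrich.set_index("Feature")["mean_Negative"])
    consensus["mean_Positive"] = consensus.index.map(enrich.set_index("Feature")["mean_Positive"])
    consensus["weighted_r"] = consensus.index.map(ace_summary.set_index("Feature")["sum_abs_rw"])
    consensus["Importance"] = consensus.index.map(forest_table.set_index("Feature")["Importance"])

    prox = None
    if orfs is not None:
        positive_acc = {g.accession for g in paired if g.trait_status == POSITIVE}
        pos_orfs = [o for o in orfs if o.genome in positive_acc]
        tuples = orf_distances(pos_orfs, set(config.marker_features))
        prox = summarize_proximity(tuples)

    manifest = {
        "seed": config.seed,
        "thresholds": {
            "completeness_min": config.completeness_min,
            "min_taxa": config.min_taxa,
            "max_taxa": config.max_taxa,
            "enrichment_q_max": config.enrichment_q_max,
            "ace_q_max": config.ace_q_max,
        },
        "forest_config": asdict(config.forest),
        "excluded_features": sorted(config.exclude_features),
        "rows": {
            "genomes_in": len(genomes),
            "pairs": len(pairs),
            "enrichment": len(enrich),
            "ace_subtrees": int(per_subtree["Subtree"].nunique()) if len(per_subtree) else 0,
            "forest": len(forest_table),
            "consensus": len(consensus),
            "proximity": 0 if prox is None else len(prox),
        },
        "pair_distance": pair_summary,
        "forest_accuracy": accuracy,
    }
    result = PipelineResult(
        genomes=paired,
        pairs=pairs,
        pair_summary=pair_summary,
        enrichment=enrich,
        ace_per_subtree=per_subtree,
        ace_summary=ace_summary,
        subtree_info=subtree_info,
        forest=forest_table,
        forest_accuracy=accuracy,
        consensus=consensus,
        proximity=prox,
        manifest=manifest,
    )
    if outdir is not None:
        result.write(outdir)
    return result


def run_pipeline_from_files(
    feature_table: str | Path,
    tree_path: str | Path,
    orf_table: str | Path | None = None,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    genomes, matrix = read_feature_table(feature_table)
    tree = read_tree(tree_path)
    orfs = read_orf_table(orf_table) if orf_table is not None else None
    return run_pipeline(genomes, matrix, tree, orfs, config, outdir)


# ---------------------------------------------------------------------------
# benchmark entry points (shared by the test suite and the acceptance script)


def recovery_pipeline_config(seed: int) -> PipelineConfig:
    """Pipeline settings for the 200-genome recovery benchmark.

    Subtree bounds of 20-100 taxa suit a 200-leaf tree (the 50-300 default
    targets trees an order of magnitude larger); the forest stage uses 20
    forests of 200 trees, which stabilises mean importances at this
    feature count while keeping the benchmark fast.
    """
    return PipelineConfig(
        min_taxa=20,
        max_taxa=100,
        forest=ForestConfig(n_forests=20, n_estimators=200, seed=seed % (2**31)),
        seed=seed,
    )


def run_recovery_benchmark(seed: int = 1) -> dict:
    """Full-pipeline planted-signal recovery under the benchmark conditions.

    Simulates 200 genomes x 300 features with 10% trait-linked features
    (log-scale effect 1.5), runs the complete pipeline, and measures the
    fraction of planted features recovered in the top decile of the
    consensus ranking.
    """
    sim = simulate_dataset(SimulationConfig(seed=seed % (2**31)))
    result = run_pipeline(
        sim.genomes, sim.matrix, sim.tree, sim.orfs,
        config=recovery_pipeline_config(seed),
    )
    n_features = len(sim.matrix.features)
    decile = int(np.ceil(n_features / 10))
    top = set(result.consensus.head(decile).index)
    linked = set(sim.linked_features)
    captured = len(top & linked) / len(linked)
    n_sig = int((result.enrichment["q"] < 0.05).sum())
    return {
        "dataset": sim,
        "result": result,
        "top_decile_capture": captured,
        "n_linked": len(linked),
        "n_significant_enrichment": n_sig,
        "forest_accuracy": result.forest_accuracy,
        "pair_median_distance": result.pair_summary["median"],
    }


def run_null_calibration(seed: int = 1, n_features: int = 500) -> dict:
    """Type-I error check: no trait effect, no phylogenetic count signal.

    With ``effect_beta = 0`` and ``bm_sigma2 = 0`` every count is an
    independent Poisson draw, so the enrichment p-values should be
    calibrated: the fraction below 0.05 should sit near 0.05.
    """
    sim = simulate_dataset(
        SimulationConfig(
            effect_beta=0.0, bm_sigma2=0.0, n_features=n_features,
            frac_linked=0.1, seed=seed % (2**31),
        )
    )
    enrich = run_enrichment(sim.genomes, sim.matrix, completeness_min=0.0,
                            exclude_features=frozenset())
    rate = float((enrich["p"] < 0.05).mean())
    return {"p_lt_05_rate": rate, "n_features": len(enrich)}


def run_permuted_forest(seed: int = 1) -> dict:
    """Forest-accuracy null: labels shuffled, held-out accuracy should be ~0.5.

    Run on the *paired* dataset, which is class-balanced by construction
    (as the real contrast set is); on an unbalanced genome set a
    majority-vote classifier would beat 0.5 even with permuted labels.

    Any single permutation carries sampling noise of its own (a lucky
    label assignment can be genuinely learnable in a ~100-genome sample),
    so the null is averaged over several independent permutations.
    """
    n_permutations = 10
    sim = simulate_dataset(SimulationConfig(seed=seed % (2**31)))
    paired, _, _ = pair_genomes(sim.genomes, sim.tree)
    matrix = sim.matrix.subset_genomes([g.accession for g in paired])
    rng = np.random.default_rng(seed % (2**31) + 1)
    labels = [g.trait_status for g in paired]
    per_perm: list[float] = []
    for p in range(n_permutations):
        shuffled = list(rng.permutation(labels))
        permuted = [
            GenomeRecord(accession=g.accession, trait_status=s)
            for g, s in zip(paired, shuffled)
        ]
        _, accuracy = run_forest(
            permuted, matrix,
            ForestConfig(n_forests=4, n_estimators=100, seed=seed % (2**31) + p),
        )
        per_perm.append(float(np.mean(list(accuracy.values()))))
    return {
        "per_permutation": per_perm,
        "mean_accuracy": float(np.mean(per_perm)),
        "n_permutations": n_permutations,
    }
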