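"""Greedy closest-relative pairing of trait-positive and -negative genomes.

Each trait-positive genome is paired with its closest unused
trait-negative genome by repeatedly taking the globally minimal remaining
distance and removing both genomes from further consideration.  The loop
is greedy, not optimal (Hungarian) matching, mirroring the original
selection procedure; ties are broken lexicographically by
(positive accession, negative accession) so the result is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean, median

import dendropy
import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Pair:
    positive: str
    negative: str
    distance: float


class DistanceMatrix:
    """Rectangular positive x negative distance matrix (substitutions/site)."""

    def __init__(self, data: pd.DataFrame):
        values = data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("distance matrix contains non-finite cells")
        if (values < 0).any():
            raise ValueError("distance matrix contains negative cells")
        self.data = data

    @property
    def positives(self) -> list[str]:
        return list(self.data.index)

    @property
    def negatives(self) -> list[str]:
        return list(self.data.columns)

    @classmethod
    def from_tree(
        cls, tree: dendropy.Tree, positives: list[str], negatives: list[str]
    ) -> "DistanceMatrix":
        """Patristic distances between the two groups on a given tree."""
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        rows = np.empty((len(positives), len(negatives)))
        for i, p in enumerate(positives):
            for j, n in enumerate(negatives):
                rows[i, j] = pdm.patristic_distance(taxa[p], taxa[n])
        return cls(pd.DataFrame(rows, index=positives, columns=negatives))


def select_pairs(d: DistanceMatrix) -> list[Pair]:
    """Greedily pair every positive with a distinct closest negative.

    Repeatedly selects the globally minimal remaining cell and removes its
    row and column, until every positive genome is paired.  Requires at
    least as many negatives as positives.
    """
    n_pos, n_neg = d.data.shape
    if n_neg < n_pos:
        raise ValueError(f"cannot pair {n_pos} positives with only {n_neg} negatives")
    values = d.data.to_numpy(dtype=float).copy()
    pos = list(d.data.index)
    neg = list(d.data.columns)
    # lexicographic tie-break: pre-sort axes, keep original values aligned
    pos_order = np.argsort(pos, kind="stable")
    neg_order = np.argsort(neg, kind="stable")
    values = values[np.ix_(pos_order, neg_order)]
    pos = [pos[i] for i in pos_order]
    neg = [neg[j] for j in neg_order]
    pairs: list[Pair] = []
    alive_rows = np.ones(len(pos), dtype=bool)
    alive_cols = np.ones(len(neg), dtype=bool)
    masked = values.copy()
    for _ in range(len(pos)):
        flat = np.argmin(masked)
        i, j = np.unravel_index(flat, masked.shape)
        pairs.append(Pair(pos[i], neg[j], float(values[i, j])))
        alive_rows[i] = False
        alive_cols[j] = False
        masked[i, :] = np.inf
        masked[:, j] = np.inf
    pairs.sort(key=lambda p: p.distance)
    return pairs


def summarize_pair_distances(pairs: list[Pair]) -> dict[str, float]:
    """Median/mean pair distance and pair count."""
    if not pairs:
        raise ValueError("no pairs to summarize")
    dists = [p.distance for p in pairs]
    return {"median": median(dists), "mean": mean(dists), "n": len(pairs)}


def pairs_table(pairs: list[Pair]) -> pd.DataFrame:
    """Pairs as a table with the feature-table's pairing columns."""
    return pd.DataFrame(
        {
            "Accession": [p.positive for p in pairs],
            "Relative": [p.negative for p in pairs],
            "Distance": [p.distance for p in pairs],
        }
    )
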