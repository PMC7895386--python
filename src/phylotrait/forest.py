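"""Random-forest importance ranking with recursive feature elimination.

EC and Pfam feature universes are processed entirely separately:
importance values are only comparable within a feature type.  Per type,
a linear logistic classifier first prunes the matrix to the ``n_keep``
most promising features by recursive elimination (drop the ``rfe_step``
features with smallest absolute coefficients, refit, repeat); then
``n_forests`` random forests of ``n_estimators`` trees each are trained
on independent random 3/4 splits, and the impurity importances are
averaged.  Held-out accuracy on the remaining 1/4 is reported per type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE
from sklearn.linear_model import LogisticRegression

from phylotrait.io import POSITIVE, FeatureMatrix, GenomeRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ForestConfig:
    n_keep: int = 600  # features retained per type after elimination
    rfe_step: int = 10  # features removed per elimination iteration
    n_forests: int = 100
    n_estimators: int = 500
    train_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_keep < self.rfe_step:
            raise ValueError("n_keep must be >= rfe_step")


def _labels_vector(genomes: list[GenomeRecord], accessions: list[str]) -> np.ndarray:
    status = {g.accession: g.trait_status for g in genomes}
    return np.array([1 if status[a] == POSITIVE else 0 for a in accessions])


def rfe_select(
    counts: pd.DataFrame, labels: np.ndarray, config: ForestConfig
) -> list[str]:
    """Recursive feature elimination down to ``n_keep`` features.

    Uses raw counts without standardization: the coefficients feed only a
    rank-based elimination.  Constant columns carry no signal and are
    dropped first.
    """
    constant = counts.columns[(counts.nunique() <= 1)].tolist()
    if constant:
        logger.info("dropping %d constant feature column(s) before RFE", len(constant))
        counts = counts.drop(columns=constant)
    if counts.shape[1] <= config.n_keep:
        return list(counts.columns)
    estimator = LogisticRegression(solver="liblinear", random_state=config.seed)
    rfe = RFE(estimator, n_features_to_select=config.n_keep, step=config.rfe_step)
    rfe.fit(counts.to_numpy(dtype=float), labels)
    return list(counts.columns[rfe.support_])


def train_forests(
    counts: pd.DataFrame, labels: np.ndarray, config: ForestConfig
) -> tuple[pd.DataFrame, float]:
    """Train ``n_forests`` seeded forests; return (importance table, accuracy).

    Each repetition draws an unstratified random ``train_fraction`` split,
    fits a forest, and records held-out accuracy and per-feature impurity
    importances.  A split that misses a class is resampled (logged).
    Per-repetition seeds are ``config.seed * 10000 + repetition`` so any
    single repetition can be re-run in isolation.
    """
    if np.unique(labels).size < 2:
        raise ValueError("both trait classes must be present")
    n = len(labels)
    n_train = int(round(n * config.train_fraction))
    X = counts.to_numpy(dtype=float)
    importances = np.zeros((config.n_forests, counts.shape[1]))
    accuracies = np.zeros(config.n_forests)
    for rep in range(config.n_forests):
        rep_seed = config.seed * 10000 + rep
        rng = np.random.default_rng(rep_seed)
        for _ in range(100):
            perm = rng.permutation(n)
            train, test = perm[:n_train], perm[n_train:]
            if np.unique(labels[train]).size == 2 and test.size > 0:
                break
            logger.info("resampling split %d: a class was missing", rep)
        forest = RandomForestClassifier(
            n_estimators=config.n_estimators, random_state=rep_seed
        )
        forest.fit(X[train], labels[train])
        importances[rep] = forest.feature_importances_
        accuracies[rep] = float((forest.predict(X[test]) == labels[test]).mean())
    mean_imp = importances.mean(axis=0)
    sd_imp = importances.std(axis=0, ddof=1) if config.n_forests > 1 else np.zeros_like(mean_imp)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean_imp > 0, sd_imp / mean_imp, np.nan)
    table = pd.DataFrame(
        {
            "Feature": counts.columns,
            "Importance": mean_imp,
            "CV_Importance": cv,
        }
    )
    table["Rank"] = table["Importance"].rank(method="average", ascending=False)
    table = table.sort_values(["Rank", "Feature"], kind="stable").reset_index(drop=True)
    return table, float(accuracies.mean())


def run_forest(
    genomes: list[GenomeRecord],
    matrix: FeatureMatrix,
    config: ForestConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Full stage: per-type RFE + forest training; combined results table.

    Returns the importance table (with ``Feature_Type`` and within-type
    ranks) and the mean held-out accuracy per feature type.
    """
    config = config or ForestConfig()
    accessions = matrix.genomes
    labels = _labels_vector(genomes, accessions)
    tables = []
    accuracies: dict[str, float] = {}
    for ftype in ("EC", "Pfam"):
        sub = matrix.of_type(ftype)
        if sub.counts.shape[1] == 0:
            continue
        selected = rfe_select(sub.counts, labels, config)
        if not selected:
            continue
        table, acc = train_forests(sub.counts[selected], labels, config)
        table.insert(1, "Feature_Type", ftype)
        tables.append(table)
        accuracies[ftype] = acc
    if not tables:
        raise ValueError("no features to train on")
    combined = pd.concat(tables, ignore_index=True)
    return combined[["Rank", "Feature_Type", "Feature", "Importance", "CV_Importance"]], accuracies
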