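"""Per-feature copy-number enrichment between trait groups.

Each gene family's copy numbers are compared between trait-positive and
trait-negative genomes with a two-sided Wilcoxon rank-sum test, and the
resulting p-values are Benjamini-Hochberg adjusted jointly across EC and
Pfam features.  Genomes below a completeness threshold (default 95%) are
excluded, as are the trait-defining marker features themselves (present
in positive genomes by construction, so their enrichment is circular).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from phylotrait.io import POSITIVE, FeatureMatrix, GenomeRecord

#: Features excluded by default: the Calvin-cycle markers (Rubisco and
#: phosphoribulokinase EC numbers and their Pfam domains).
DEFAULT_EXCLUDED_FEATURES = frozenset(
    {"2.7.1.19", "4.1.1.39", "PF02788", "PF00016", "PF00101", "PF00485"}
)


@dataclass
class EnrichmentResult:
    feature: str
    feature_type: str
    mean_positive: float
    mean_negative: float
    cv_positive: float  # SD/mean; NaN when the mean is 0
    cv_negative: float
    log2_ratio: float  # +/-inf when one group mean is 0
    p: float
    q: float = float("nan")
    rank: float = float("nan")


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null enumeration when the pooled sample is small (n+m <= 20)
    and tie-free; otherwise the tie-corrected normal approximation with
    continuity correction.  Copy-number data is heavily tied, so the
    approximation is the dominant path.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    ties = np.unique(pooled).size < pooled.size
    if x.size + y.size <= 20 and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(min(res.pvalue, 1.0))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _cv(values: np.ndarray) -> float:
    m = values.mean()
    if m == 0 or values.size < 2:
        return float("nan")
    return float(values.std(ddof=1) / m)


def _log2_ratio(mean_pos: float, mean_neg: float) -> float:
    if mean_neg == 0 and mean_pos == 0:
        return 0.0
    if mean_neg == 0:
        return float("inf")
    if mean_pos == 0:
        return float("-inf")
    return float(np.log2(mean_pos / mean_neg))


def run_enrichment(
    genomes: list[GenomeRecord],
    matrix: FeatureMatrix,
    completeness_min: float = 95.0,
    exclude_features: frozenset[str] | set[str] = DEFAULT_EXCLUDED_FEATURES,
    drop_all_zero: bool = True,
) -> pd.DataFrame:
    """Run the full enrichment stage; return the ranked results table.

    Features with all-zero counts in both groups are dropped from the
    testing pool by default (they carry no information and would dilute
    the BH correction with p = 1 entries).  BH adjustment is performed
    jointly across both feature types; the output is ranked by ascending
    q with average ties.
    """
    keep = [g for g in genomes if g.completeness >= completeness_min]
    pos = [g.accession for g in keep if g.trait_status == POSITIVE]
    neg = [g.accession for g in keep if g.trait_status != POSITIVE]
    if not pos or not neg:
        raise ValueError(
            f"a trait group is empty after completeness filter "
            f"(positives={len(pos)}, negatives={len(neg)})"
        )
    features = [f for f in matrix.features if f not in exclude_features]
    counts = matrix.counts.loc[pos + neg, features]
    if drop_all_zero:
        observed = counts.sum(axis=0) > 0
        features = [f for f in features if observed[f]]
    results: list[EnrichmentResult] = []
    xs = matrix.counts.loc[pos, features].to_numpy(dtype=float)
    ys = matrix.counts.loc[neg, features].to_numpy(dtype=float)
    for j, feat in enumerate(features):
        x, y = xs[:, j], ys[:, j]
        results.append(
            EnrichmentResult(
                feature=feat,
                feature_type=matrix.types[feat],
                mean_positive=float(x.mean()),
                mean_negative=float(y.mean()),
                cv_positive=_cv(x),
                cv_negative=_cv(y),
                log2_ratio=_log2_ratio(x.mean(), y.mean()),
                p=wilcoxon_rank_sum(x, y),
            )
        )
    qs = bh_adjust([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    table = pd.DataFrame(
        {
            "Feature_Type": [r.feature_type for r in results],
            "Feature": [r.feature for r in results],
            "mean_Negative": [r.mean_negative for r in results],
            "mean_Positive": [r.mean_positive for r in results],
            "CV_Negative": [r.cv_negative for r in results],
            "CV_Positive": [r.cv_positive for r in results],
            "log2_ratio": [r.log2_ratio for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
        }
    )
    table["Rank"] = table["q"].rank(method="average")
    table = table.sort_values(["q", "Feature"], kind="stable").reset_index(drop=True)
    cols = ["Rank"] + [c for c in table.columns if c != "Rank"]
    return table[cols]
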