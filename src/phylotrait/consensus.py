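"""Consensus rank aggregation across the three analysis methods.

Each method contributes a rank per feature: enrichment by ascending q,
ACE by descending weighted |r| sum, random forest by descending
importance (within feature type).  The consensus rank is the rank of the
sum of the three, with average ties throughout; a feature absent from a
method carries that method's maximum rank plus one, so missing evidence
penalises without disqualifying.
"""

from __future__ import annotations

import pandas as pd


def rank_method(scores: pd.Series, direction: str = "ascending") -> pd.Series:
    """Average-tie ranks of finite scores, in the given direction."""
    if direction not in ("ascending", "descending"):
        raise ValueError(f"direction must be ascending/descending, got {direction!r}")
    return scores.rank(method="average", ascending=direction == "ascending")


def consensus_rank(method_ranks: dict[str, pd.Series]) -> pd.DataFrame:
    """Merge per-method ranks into the consensus table.

    ``method_ranks`` maps a method name to a feature-indexed rank series.
    Output columns: one rank column per method (missing features filled
    with max+1), ``rank_sum``, and ``Rank`` (consensus).
    """
    if not method_ranks or all(s.empty for s in method_ranks.values()):
        raise ValueError("at least one method must provide ranks")
    all_features = pd.Index(sorted(set().union(*(s.index for s in method_ranks.values()))))
    table = pd.DataFrame(index=all_features)
    for method, ranks in method_ranks.items():
        penalty = (ranks.max() + 1) if len(ranks) else 1.0
        table[f"rank_{method}"] = ranks.reindex(all_features).fillna(penalty)
    table["rank_sum"] = table.sum(axis=1)
    table["Rank"] = table["rank_sum"].rank(method="average")
    table.index.name = "Feature"
    return table.sort_values(["Rank", "Feature"], kind="stable")
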