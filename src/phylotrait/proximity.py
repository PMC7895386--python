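"""Gene-neighborhood distance between features and the trait markers.

For every contig of a trait-positive genome that carries at least one
marker ORF (e.g. Rubisco or phosphoribulokinase), the distance from each
feature-bearing ORF to each marker ORF is the absolute difference of
their ordinal positions, in ORF counts.  Contigs are treated as linear
(no wrap-around), even for known-circular chromosomes, mirroring the
fact that most assemblies are unplaced scaffolds.  Distances are
summarised per (feature, marker, strand relation) with counts broken
down by molecule type.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from phylotrait.io import OrfRecord


@dataclass(frozen=True)
class ProximityTuple:
    feature: str
    marker: str
    distance: int
    strand_relation: str  # Same | Opposite
    molecule: str  # chromosome | plasmid | unknown


def orf_distances(
    orfs: list[OrfRecord],
    marker_features: set[str],
    include_self: bool = False,
) -> list[ProximityTuple]:
    """All (feature ORF, marker ORF) distances on marker-bearing contigs.

    Every feature copy is measured against every marker copy on the same
    contig ("all copies", matching the per-occurrence counts in the
    summaries).  A marker feature measured against itself on the same ORF
    (distance 0) is excluded unless ``include_self``; marker-to-marker
    distances between distinct ORFs are kept, so the mutual proximity of
    the markers themselves is reported.
    """
    by_contig: dict[tuple[str, str], list[OrfRecord]] = defaultdict(list)
    for orf in orfs:
        by_contig[(orf.genome, orf.contig)].append(orf)
    tuples: list[ProximityTuple] = []
    for contig_orfs in by_contig.values():
        markers = [
            (o, m) for o in contig_orfs for m in sorted(o.features & marker_features)
        ]
        if not markers:
            continue
        for orf in contig_orfs:
            for feat in sorted(orf.features):
                for marker_orf, marker in markers:
                    if marker_orf is orf and feat == marker and not include_self:
                        continue
                    tuples.append(
                        ProximityTuple(
                            feature=feat,
                            marker=marker,
                            distance=abs(orf.index - marker_orf.index),
                            strand_relation="Same" if orf.strand == marker_orf.strand else "Opposite",
                            molecule=orf.molecule,
                        )
                    )
    return tuples


def summarize_proximity(tuples: list[ProximityTuple]) -> pd.DataFrame:
    """Min/median/max/mean distances per (feature, marker, strand relation).

    Occurrence counts are split by molecule type; ``frac_psm`` is the
    plasmid fraction among placed (chromosome or plasmid) occurrences,
    NaN when no occurrence is placed.
    """
    groups: dict[tuple[str, str, str], list[ProximityTuple]] = defaultdict(list)
    for t in tuples:
        groups[(t.feature, t.marker, t.strand_relation)].append(t)
    rows = []
    for (feature, marker, strand), members in sorted(groups.items()):
        dists = np.array([m.distance for m in members])
        loc_chr = sum(1 for m in members if m.molecule == "chromosome")
        loc_psm = sum(1 for m in members if m.molecule == "plasmid")
        loc_unk = sum(1 for m in members if m.molecule == "unknown")
        placed = loc_chr + loc_psm
        rows.append(
            {
                "Feature": feature,
                "cFeature": marker,
                "Strand": strand,
                "minD": int(dists.min()),
                "medD": float(np.median(dists)),
                "maxD": int(dists.max()),
                "meanD": float(dists.mean()),
                "Count": len(members),
                "locChr": loc_chr,
                "locPsm": loc_psm,
                "locUnk": loc_unk,
                "fracPsm": (loc_psm / placed) if placed else float("nan"),
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(
            ["medD", "Count"], ascending=[True, False], kind="stable"
        ).reset_index(drop=True)
    return df
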