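"""Trait calling from marker homology hits.

A genome is trait-positive iff it retains at least one filtered hit for
*every* required marker (for the Calvin cycle: Rubisco large subunit and
phosphoribulokinase).  Hits are filtered by full-sequence E-value and,
for Rubisco, by presence of the catalytic lysine at a fixed column of a
reference alignment — form IV Rubisco-like proteins lack this residue and
must not count as the CO2-fixing enzyme.  Genomes from excluded taxa
(e.g. Cyanobacteria in the original study) are dropped entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

from phylotrait.io import NEGATIVE, POSITIVE, FeatureMatrix, GenomeRecord, HitRecord


@dataclass(frozen=True)
class MarkerSpec:
    """Filtering rules for one marker gene family."""

    marker_name: str
    evalue_max: float = 0.01
    catalytic_column: int | None = None  # 1-based column in the reference alignment
    required_residue: str | None = None  # single amino-acid letter

    def __post_init__(self) -> None:
        if not self.evalue_max > 0:
            raise ValueError("evalue_max must be positive")
        if self.catalytic_column is not None and self.catalytic_column < 1:
            raise ValueError("catalytic_column is 1-based and must be >= 1")


def filter_hits(hits: list[HitRecord], spec: MarkerSpec) -> list[HitRecord]:
    """Retain hits for ``spec.marker_name`` with E-value below threshold."""
    return [
        h for h in hits
        if h.model_id == spec.marker_name and h.evalue < spec.evalue_max
    ]


def filter_catalytic_residue(aligned_seqs: dict[str, str], spec: MarkerSpec) -> set[str]:
    """Retain aligned sequences carrying the required catalytic residue.

    The check is case-insensitive at the 1-based ``catalytic_column``;
    a gap character never matches.  Raises on ragged alignments.
    """
    if spec.catalytic_column is None or spec.required_residue is None:
        raise ValueError("spec must define catalytic_column and required_residue")
    lengths = {len(s) for s in aligned_seqs.values()}
    if len(lengths) > 1:
        raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
    if lengths and min(lengths) < spec.catalytic_column:
        raise ValueError("alignment shorter than catalytic_column")
    want = spec.required_residue.upper()
    col = spec.catalytic_column - 1
    return {
        name for name, seq in aligned_seqs.items()
        if seq[col].upper() == want
    }


def call_trait_status(
    genomes: list[GenomeRecord],
    marker_hits: dict[str, list[HitRecord]],
    required_markers: set[str],
    exclude_taxa: set[str] | None = None,
) -> list[GenomeRecord]:
    """Assign trait status; drop genomes from excluded taxa.

    ``marker_hits`` maps marker name to its retained (already filtered)
    hits.  A genome is positive iff it has >= 1 retained hit for every
    required marker.  Genomes whose taxonomy string contains any excluded
    label are removed from the output entirely.
    """
    exclude_taxa = exclude_taxa or set()
    by_marker_genomes = {
        marker: {h.genome for h in hits} for marker, hits in marker_hits.items()
    }
    out: list[GenomeRecord] = []
    for g in genomes:
        if any(label in g.taxonomy for label in exclude_taxa):
            continue
        positive = all(
            g.accession in by_marker_genomes.get(marker, set())
            for marker in required_markers
        )
        g.trait_status = POSITIVE if positive else NEGATIVE
        out.append(g)
    return out


def flag_photosynthetic(
    matrix: FeatureMatrix, photo_features: set[str], min_distinct: int = 3
) -> dict[str, bool]:
    """Flag genomes carrying >= ``min_distinct`` *distinct* photo features.

    Distinct families are counted, not copies: one family at high copy
    number does not make a genome photosynthetic.
    """
    if not photo_features:
        raise ValueError("photo_features must be nonempty")
    present = [f for f in photo_features if f in matrix.counts.columns]
    flags: dict[str, bool] = {}
    for genome in matrix.genomes:
        n_distinct = int((matrix.counts.loc[genome, present] >= 1).sum()) if present else 0
        flags[genome] = n_distinct >= min_distinct
    return flags
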