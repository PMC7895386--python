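"""Readers and writers for every external representation the pipeline touches.

All tables are UTF-8, tab-delimited, with '.' as the decimal separator and
newline-agnostic reading.  Trees are newick with branch lengths.  Homology
hits are hmmer ``--tblout`` tables.  ORF location tables use the package's
own TSV dialect (one row per ORF).

The feature-table dialect has seven mandatory leading columns
(``Accession``, ``Relative``, ``Distance``, ``Subtree``, ``CBB_status``,
``checkm_completeness``, ``gtdb_taxonomy``) followed by one integer
copy-number column per gene-family feature.
"""

from __future__ import annotations

import io as _stdio
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"

MANDATORY_COLUMNS = (
    "Accession",
    "Relative",
    "Distance",
    "Subtree",
    "CBB_status",
    "checkm_completeness",
    "gtdb_taxonomy",
)

_EC_RE = re.compile(r"^(?:\d+|-)(?:\.(?:\d+|-)){3}$")
_PFAM_PREFIX = "PF"


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def feature_type(feature_id: str) -> str:
    """Classify a feature id as ``"EC"`` or ``"Pfam"``.

    Ids beginning ``PF`` are Pfam domains; dot-separated numeric ids
    (with ``-`` allowed for unspecified levels, e.g. ``1.1.1.-``) are EC
    numbers.  Anything else is rejected: the two feature universes must
    be separable for the per-type random-forest stage.
    """
    if feature_id.startswith(_PFAM_PREFIX):
        return "Pfam"
    if _EC_RE.match(feature_id):
        return "EC"
    raise FormatError(f"feature id {feature_id!r} is neither a Pfam nor an EC number")


@dataclass
class GenomeRecord:
    """One genome's identity, pairing info, and trait status."""

    accession: str
    trait_status: str = NEGATIVE
    relative: str | None = None
    distance: float = float("nan")
    subtree: int | None = None
    completeness: float = 100.0
    taxonomy: str = ""

    def __post_init__(self) -> None:
        if self.trait_status not in (POSITIVE, NEGATIVE):
            raise ValueError(f"trait_status must be positive/negative, got {self.trait_status!r}")
        if not (0.0 <= self.completeness <= 100.0):
            raise ValueError(f"completeness {self.completeness} outside [0, 100]")
        if self.distance == self.distance and self.distance < 0:  # NaN-safe
            raise ValueError("distance must be non-negative")


@dataclass
class FeatureMatrix:
    """Genomes x features copy-number matrix with per-feature type tags.

    ``counts`` is indexed by genome accession with one integer column per
    feature; ``types`` maps each feature id to ``"EC"`` or ``"Pfam"``.
    """

    counts: pd.DataFrame
    types: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise FormatError(f"duplicate feature id {dup!r}")
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate genome accession {dup!r}")
        if (self.counts.values < 0).any():
            raise FormatError("feature matrix contains negative cells")
        if self.types is None:
            self.types = pd.Series(
                {f: feature_type(f) for f in self.counts.columns}, dtype=object
            )

    @property
    def genomes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def features(self) -> list[str]:
        return list(self.counts.columns)

    def of_type(self, ftype: str) -> "FeatureMatrix":
        """Restrict to one feature universe (``"EC"`` or ``"Pfam"``)."""
        cols = [f for f in self.counts.columns if self.types[f] == ftype]
        return FeatureMatrix(self.counts[cols], self.types[cols])

    def subset_genomes(self, accessions: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(self.counts.loc[list(accessions)], self.types)


@dataclass
class HitRecord:
    """One profile-HMM homology hit (full-sequence E-value and score)."""

    orf_id: str
    genome: str
    model_id: str
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not self.evalue > 0:
            raise ValueError(f"E-value must be positive, got {self.evalue}")


@dataclass
class OrfRecord:
    """One ORF's location: contig, 0-based ordinal index, strand, annotations."""

    genome: str
    contig: str
    molecule: str  # chromosome | plasmid | unknown
    index: int
    strand: str  # '+' or '-'
    features: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError("ORF index must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.molecule not in ("chromosome", "plasmid", "unknown"):
            raise ValueError(f"unknown molecule type {self.molecule!r}")
        self.features = frozenset(self.features)


# ---------------------------------------------------------------------------
# feature tables


def read_feature_table(path: str | Path) -> tuple[list[GenomeRecord], FeatureMatrix]:
    """Read a feature table into genome records and a copy-number matrix.

    Trait status is decoded from the ``CBB_status`` column: 0 is negative,
    1 is positive.  Taxonomy strings are stored verbatim.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r} in {path}")
    feature_cols = [c for c in df.columns if c not in MANDATORY_COLUMNS]
    records = []
    for _, row in df.iterrows():
        subtree = row["Subtree"]
        records.append(
            GenomeRecord(
                accession=row["Accession"],
                trait_status=_decode_status(row["CBB_status"], path),
                relative=row["Relative"] or None,
                distance=float(row["Distance"]) if row["Distance"] else float("nan"),
                subtree=int(subtree) if subtree not in ("", "NA") else None,
                completeness=float(row["checkm_completeness"]),
                taxonomy=row["gtdb_taxonomy"],
            )
        )
    cells = pd.DataFrame(index=pd.Index(df["Accession"], name="Accession"))
    for col in feature_cols:
        try:
            cells[col] = df[col].astype(np.int64).values
        except ValueError as exc:
            bad = df.index[~df[col].str.fullmatch(r"-?\d+")][0]
            raise FormatError(
                f"non-integer feature cell at row {bad + 2}, column {col!r}"
            ) from exc
    return records, FeatureMatrix(cells)


def _decode_status(value: str, path: str | Path) -> str:
    if value == "1":
        return POSITIVE
    if value == "0":
        return NEGATIVE
    raise FormatError(f"CBB_status must be 0 or 1, got {value!r} in {path}")


def write_feature_table(
    path: str | Path, genomes: Iterable[GenomeRecord], matrix: FeatureMatrix
) -> None:
    """Write genome records and a copy-number matrix in the table dialect."""
    genomes = list(genomes)
    meta = pd.DataFrame(
        {
            "Accession": [g.accession for g in genomes],
            "Relative": [g.relative or "" for g in genomes],
            "Distance": ["" if g.distance != g.distance else repr(g.distance) for g in genomes],
            "Subtree": ["" if g.subtree is None else g.subtree for g in genomes],
            "CBB_status": [1 if g.trait_status == POSITIVE else 0 for g in genomes],
            "checkm_completeness": [g.completeness for g in genomes],
            "gtdb_taxonomy": [g.taxonomy for g in genomes],
        }
    )
    body = matrix.counts.loc[[g.accession for g in genomes]].reset_index(drop=True)
    pd.concat([meta, body], axis=1).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# trees


def read_tree(source: str | Path) -> dendropy.Tree:
    """Read a rooted newick tree with branch lengths.

    Raises :class:`FormatError` on unparsable newick or duplicate leaf
    labels.  Leaf labels map 1:1 to genome accessions.
    """
    text = Path(source).read_text() if not str(source).lstrip().startswith("(") else str(source)
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"unparsable newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise FormatError(f"duplicate leaf label {lab!r}")
        seen.add(lab)
    tree.is_rooted = True
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True, unquoted_underscores=True)


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True)


# ---------------------------------------------------------------------------
# hmmer tblout

# tblout columns (whitespace-delimited): target name, target accession,
# query name, query accession, full-sequence E-value, score, bias, ...
_TBLOUT_MIN_FIELDS = 7


def read_tblout(path: str | Path, genome_delimiter: str = "|") -> list[HitRecord]:
    """Parse an hmmer ``--tblout`` table into hit records.

    The full-sequence E-value and score columns are used.  The genome of a
    hit is taken as the part of the target name before the first
    ``genome_delimiter`` (empty when the delimiter is absent).  Malformed
    lines are skipped with a logged warning.
    """
    hits: list[HitRecord] = []
    skipped = 0
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        try:
            if len(fields) < _TBLOUT_MIN_FIELDS:
                raise ValueError("too few fields")
            orf_id = fields[0]
            genome = orf_id.split(genome_delimiter, 1)[0] if genome_delimiter in orf_id else ""
            hits.append(
                HitRecord(
                    orf_id=orf_id,
                    genome=genome,
                    model_id=fields[2],
                    evalue=float(fields[4]),
                    bitscore=float(fields[5]),
                )
            )
        except ValueError:
            skipped += 1
            logger.warning("skipping malformed tblout line: %r", line)
    if skipped:
        logger.warning("skipped %d malformed tblout line(s) in %s", skipped, path)
    return hits


# ---------------------------------------------------------------------------
# ORF tables (pipeline's own TSV dialect)

_ORF_COLUMNS = ("genome", "contig", "molecule", "index", "strand", "features")


def read_orf_table(path: str | Path) -> list[OrfRecord]:
    """Read an ORF location table (one row per ORF, features comma-joined)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _ORF_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r} in {path}")
    orfs = []
    seen: set[tuple[str, str, int]] = set()
    for _, row in df.iterrows():
        key = (row["genome"], row["contig"], int(row["index"]))
        if key in seen:
            raise FormatError(f"duplicate ORF position {key}")
        seen.add(key)
        feats = frozenset(f for f in row["features"].split(",") if f)
        orfs.append(
            OrfRecord(
                genome=row["genome"],
                contig=row["contig"],
                molecule=row["molecule"],
                index=int(row["index"]),
                strand=row["strand"],
                features=feats,
            )
        )
    return orfs


def write_orf_table(path: str | Path, orfs: Iterable[OrfRecord]) -> None:
    rows = [
        {
            "genome": o.genome,
            "contig": o.contig,
            "molecule": o.molecule,
            "index": o.index,
            "strand": o.strand,
            "features": ",".join(sorted(o.features)),
        }
        for o in orfs
    ]
    pd.DataFrame(rows, columns=list(_ORF_COLUMNS)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# aligned FASTA (for the catalytic-residue filter)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence mapping (order-preserving)."""
    seqs: dict[str, str] = {}
    current: str | None = None
    chunks: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            if current is not None:
                seqs[current] = "".join(chunks)
            current = line[1:].split()[0]
            chunks = []
        elif current is not None:
            chunks.append(line.strip())
    if current is not None:
        seqs[current] = "".join(chunks)
    return seqs


def write_fasta(path: str | Path, seqs: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")
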