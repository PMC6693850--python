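"""Reading, filtering and concatenating per-gene CDS alignments.

The pipeline starts from one aligned multi-FASTA per mitochondrial
protein-coding gene (headers are specimen IDs) plus a specimen metadata
table.  This module reads those files into :class:`GeneAlignment` objects,
applies the coverage-based specimen inclusion rule, concatenates genes into
a single specimen x site character matrix with a partition table, and
computes basic per-sequence statistics (GC content).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Canonical order of the 13 insect mitochondrial protein-coding genes used
#: for concatenation when the caller does not supply an explicit order.
CANONICAL_GENE_ORDER = (
    "atp6", "atp8", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
)

_UNAMBIGUOUS = frozenset(b"ACGT")


class AlignmentFormatError(ValueError):
    """Raised when an input alignment violates basic format requirements."""


class MissingMetadataError(KeyError):
    """Raised when a specimen present in the alignments lacks metadata."""


@dataclass
class GeneAlignment:
    """A single gene's aligned sequences for a set of specimens.

    Sequences are upper-case strings over ``A C G T``, IUPAC ambiguity
    codes and ``-`` (alignment gap), all of equal length.
    """

    gene_name: str
    specimen_ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.specimen_ids) != len(self.sequences):
            raise AlignmentFormatError(
                f"{self.gene_name}: {len(self.specimen_ids)} ids but "
                f"{len(self.sequences)} sequences"
            )
        if len(set(self.specimen_ids)) != len(self.specimen_ids):
            dupes = {s for s in self.specimen_ids if self.specimen_ids.count(s) > 1}
            raise AlignmentFormatError(
                f"{self.gene_name}: duplicate specimen IDs {sorted(dupes)}"
            )
        widths = {len(s) for s in self.sequences}
        if len(widths) > 1:
            raise AlignmentFormatError(
                f"{self.gene_name}: unequal sequence lengths {sorted(widths)}"
            )

    @property
    def width(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def divisible_by_three(self) -> bool:
        """Whether the aligned width is a whole number of codons."""
        return self.width % 3 == 0

    def subset(self, specimen_ids: Sequence[str]) -> "GeneAlignment":
        """Restrict to the given specimens, preserving the given order."""
        index = {s: i for i, s in enumerate(self.specimen_ids)}
        missing = [s for s in specimen_ids if s not in index]
        if missing:
            raise KeyError(f"{self.gene_name}: specimens not present: {missing}")
        return GeneAlignment(
            gene_name=self.gene_name,
            specimen_ids=list(specimen_ids),
            sequences=[self.sequences[index[s]] for s in specimen_ids],
        )


@dataclass
class ConcatenatedAlignment:
    """Specimen x site character matrix with named gene partitions.

    ``matrix`` is a 2-D numpy array of single-byte characters (dtype S1);
    ``partitions`` is an ordered list of ``(gene_name, start, end)``
    half-open 0-based column intervals that tile the matrix exactly.
    """

    specimen_ids: list[str]
    matrix: np.ndarray
    partitions: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        expected = 0
        for gene, start, end in self.partitions:
            if start != expected or end <= start:
                raise ValueError(
                    f"partitions must tile the matrix contiguously; "
                    f"{gene} spans [{start}, {end}) but expected start {expected}"
                )
            expected = end
        if self.partitions and expected != self.matrix.shape[1]:
            raise ValueError(
                f"partitions cover {expected} columns, matrix has "
                f"{self.matrix.shape[1]}"
            )

    @property
    def width(self) -> int:
        """Total alignment width in columns, gap columns included."""
        return int(self.matrix.shape[1])

    @property
    def n_specimens(self) -> int:
        return int(self.matrix.shape[0])

    def gene_of_column(self, column: int) -> tuple[str, int]:
        """Map a global 0-based column to ``(gene, 1-based local position)``."""
        for gene, start, end in self.partitions:
            if start <= column < end:
                return gene, column - start + 1
        raise IndexError(f"column {column} outside all partitions")

    def row(self, specimen_id: str) -> str:
        i = self.specimen_ids.index(specimen_id)
        return self.matrix[i].tobytes().decode("ascii")


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_gene_alignments(
    file_map: Mapping[str, str | Path],
    gene_order: Sequence[str] | None = None,
) -> list[GeneAlignment]:
    """Read one aligned multi-FASTA per gene into :class:`GeneAlignment`.

    Sequences are upper-cased and ``U`` is mapped to ``T``.  Specimens
    missing from any gene are dropped from all genes with a warning, so
    every returned alignment covers the same specimen set.

    Parameters
    ----------
    file_map
        Mapping gene name -> FASTA path.
    gene_order
        Order of the returned alignments.  Defaults to
        :data:`CANONICAL_GENE_ORDER` restricted to the supplied genes,
        with unknown genes appended alphabetically.
    """
    if gene_order is None:
        known = [g for g in CANONICAL_GENE_ORDER if g in file_map]
        extra = sorted(set(file_map) - set(CANONICAL_GENE_ORDER))
        gene_order = known + extra
    else:
        missing = set(gene_order) - set(file_map)
        if missing:
            raise KeyError(f"gene_order names genes without files: {sorted(missing)}")

    alignments: list[GeneAlignment] = []
    for gene in gene_order:
        ids: list[str] = []
        seqs: list[str] = []
        for rec in SeqIO.parse(str(file_map[gene]), "fasta"):
            ids.append(rec.id)
            seqs.append(_normalize(str(rec.seq)))
        if not ids:
            raise AlignmentFormatError(f"{gene}: empty FASTA {file_map[gene]}")
        alignments.append(GeneAlignment(gene, ids, seqs))

    common = set(alignments[0].specimen_ids)
    for aln in alignments[1:]:
        common &= set(aln.specimen_ids)
    dropped = sorted(set().union(*(a.specimen_ids for a in alignments)) - common)
    if dropped:
        warnings.warn(
            f"{len(dropped)} specimen(s) missing from at least one gene "
            f"and dropped: {dropped}",
            stacklevel=2,
        )
    if not common:
        raise AlignmentFormatError("no specimen is present in every gene")
    # keep the first gene's order for determinism
    order = [s for s in alignments[0].specimen_ids if s in common]
    return [a.subset(order) for a in alignments]


def write_fasta(
    alignment: GeneAlignment | ConcatenatedAlignment,
    path: str | Path,
    line_width: int = 70,
) -> None:
    """Write an alignment to FASTA (one record per specimen)."""
    if isinstance(alignment, ConcatenatedAlignment):
        pairs: Iterable[tuple[str, str]] = (
            (sid, alignment.matrix[i].tobytes().decode("ascii"))
            for i, sid in enumerate(alignment.specimen_ids)
        )
    else:
        pairs = zip(alignment.specimen_ids, alignment.sequences)
    records = [SeqRecord(Seq(seq), id=sid, description="") for sid, seq in pairs]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=line_width)
        writer.write_file(records)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the specimen metadata TSV.

    Expected columns: specimen_id, species, country, locality,
    mean_coverage, breadth.  Empty localities become "unknown".
    """
    meta = pd.read_csv(path, sep="\t", dtype={"specimen_id": str})
    required = {"specimen_id", "species", "country", "locality",
                "mean_coverage", "breadth"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if meta["specimen_id"].duplicated().any():
        dupes = meta.loc[meta["specimen_id"].duplicated(), "specimen_id"]
        raise ValueError(f"duplicate specimen IDs in metadata: {list(dupes)}")
    if (meta["breadth"] > 1).any():
        raise ValueError("breadth must be a fraction in [0, 1]")
    meta["locality"] = meta["locality"].fillna("unknown")
    return meta


def filter_specimens(
    meta: pd.DataFrame,
    min_mean_coverage: float = 10.0,
    min_breadth: float = 1.0,
    specimen_ids: Sequence[str] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Apply the coverage inclusion rule to the metadata table.

    A specimen is kept iff ``mean_coverage >= min_mean_coverage`` and
    ``breadth >= min_breadth`` (both bounds inclusive).  Returns the kept
    specimen IDs (metadata row order) and an exclusion report with one row
    per dropped specimen naming the failing criterion.

    If ``specimen_ids`` is given (specimens present in the alignments),
    every one of them must have a metadata row; otherwise a
    :class:`MissingMetadataError` is raised.
    """
    if specimen_ids is not None:
        known = set(meta["specimen_id"])
        orphans = [s for s in specimen_ids if s not in known]
        if orphans:
            raise MissingMetadataError(
                f"no metadata for specimen(s): {orphans}"
            )
    cov_ok = meta["mean_coverage"] >= min_mean_coverage
    breadth_ok = meta["breadth"] >= min_breadth
    kept = meta.loc[cov_ok & breadth_ok, "specimen_id"].tolist()

    reasons = []
    for _, row in meta.loc[~(cov_ok & breadth_ok)].iterrows():
        why = []
        if row["mean_coverage"] < min_mean_coverage:
            why.append(f"mean_coverage {row['mean_coverage']} < {min_mean_coverage}")
        if row["breadth"] < min_breadth:
            why.append(f"breadth {row['breadth']} < {min_breadth}")
        reasons.append({"specimen_id": row["specimen_id"],
                        "reason": "; ".join(why)})
    report = pd.DataFrame(reasons, columns=["specimen_id", "reason"])
    logger.info("filter_specimens kept %d / %d specimens", len(kept), len(meta))
    return kept, report


def concatenate(
    alignments: Sequence[GeneAlignment],
    specimen_ids: Sequence[str] | None = None,
) -> ConcatenatedAlignment:
    """Concatenate per-gene alignments into one matrix with partitions.

    Column order follows the order of ``alignments``.  The reported total
    width counts every column, including gap columns.
    """
    if not alignments:
        raise ValueError("no alignments to concatenate")
    if specimen_ids is None:
        specimen_ids = alignments[0].specimen_ids
    if len(specimen_ids) == 0:
        raise ValueError("empty specimen subset")
    parts = [a.subset(specimen_ids) for a in alignments]
    arrays = [
        np.frombuffer("".join(p.sequences).encode("ascii"), dtype="S1").reshape(
            len(specimen_ids), p.width
        )
        for p in parts
    ]
    matrix = np.concatenate(arrays, axis=1).copy()
    partitions: list[tuple[str, int, int]] = []
    offset = 0
    for p in parts:
        partitions.append((p.gene_name, offset, offset + p.width))
        offset += p.width
    return ConcatenatedAlignment(list(specimen_ids), matrix, partitions)


def gc_content(sequence: str) -> float:
    """GC fraction over unambiguous bases only.

    Ambiguity codes and gaps are excluded from numerator and denominator.
    """
    if not sequence:
        raise ValueError("empty sequence")
    data = np.frombuffer(_normalize(sequence).encode("ascii"), dtype="S1")
    a = int((data == b"A").sum())
    c = int((data == b"C").sum())
    g = int((data == b"G").sum())
    t = int((data == b"T").sum())
    total = a + c + g + t
    if total == 0:
        raise ValueError("sequence contains no unambiguous A/C/G/T bases")
    return (g + c) / total
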