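"""Column masking, haplotype collapsing and alignment statistics.

Distances between haplotypes are meant to be read as integer "numbers of
mutations", so before collapsing, every column that carries a gap or an
ambiguity code in any specimen is removed globally.  This makes pairwise
Hamming distances comparable across all haplotype pairs at the cost of
ignoring variation hidden inside masked columns (two specimens differing
only there collapse into one haplotype).  The raw alignment width is kept
on the source object for reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .seq_io import ConcatenatedAlignment

logger = logging.getLogger(__name__)

_ACGT = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class MaskedMatrix:
    """A concatenated alignment restricted to clean A/C/G/T columns."""

    source: ConcatenatedAlignment
    kept_columns: np.ndarray  # sorted original column indices
    matrix: np.ndarray        # n_specimens x n_kept, dtype S1
    dropped_per_gene: dict[str, int] = field(default_factory=dict)

    @property
    def specimen_ids(self) -> list[str]:
        return self.source.specimen_ids

    @property
    def n_kept(self) -> int:
        return int(self.matrix.shape[1])

    def row(self, i: int) -> str:
        return self.matrix[i].tobytes().decode("ascii")


@dataclass
class Haplotype:
    haplotype_id: str
    key: str                 # sequence over masked columns
    members: list[str]       # specimen IDs

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass
class HaplotypeTable:
    """Unique masked sequences with their member specimens."""

    haplotypes: list[Haplotype]
    specimen_to_index: dict[str, int]
    masked: MaskedMatrix | None = None

    def __len__(self) -> int:
        return len(self.haplotypes)

    @property
    def ids(self) -> list[str]:
        return [h.haplotype_id for h in self.haplotypes]

    @property
    def n_multi_member(self) -> int:
        return sum(1 for h in self.haplotypes if h.n_members > 1)

    @property
    def n_specimens(self) -> int:
        return sum(h.n_members for h in self.haplotypes)

    def sequences(self) -> np.ndarray:
        """Haplotype sequences as an n_hap x n_sites S1 matrix."""
        joined = "".join(h.key for h in self.haplotypes)
        width = len(self.haplotypes[0].key)
        return np.frombuffer(joined.encode("ascii"), dtype="S1").reshape(
            len(self.haplotypes), width
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "haplotype_id": self.ids,
                "n_members": [h.n_members for h in self.haplotypes],
                "member_ids": [",".join(h.members) for h in self.haplotypes],
                "sequence": [h.key for h in self.haplotypes],
            }
        )


@dataclass
class DistanceMatrix:
    """Square symmetric integer Hamming distances between haplotypes."""

    ids: list[str]
    matrix: np.ndarray  # int array, zero diagonal

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.ids):
            raise ValueError("distance matrix shape does not match ids")
        if not np.array_equal(m, m.T) or np.diag(m).any():
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        self.matrix = m.astype(np.int64)

    def __getitem__(self, pair: tuple[str, str]) -> int:
        i = self.ids.index(pair[0])
        j = self.ids.index(pair[1])
        return int(self.matrix[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)


def mask_columns(alignment: ConcatenatedAlignment) -> MaskedMatrix:
    """Drop every column containing a gap or non-ACGT code in any specimen."""
    matrix = alignment.matrix
    clean = np.isin(matrix, _ACGT).all(axis=0)
    kept = np.flatnonzero(clean)
    if kept.size == 0:
        raise ValueError("every column contains a gap or ambiguity code")
    dropped_cols = np.flatnonzero(~clean)
    dropped_per_gene: dict[str, int] = {g: 0 for g, _, _ in alignment.partitions}
    for col in dropped_cols:
        gene, _ = alignment.gene_of_column(int(col))
        dropped_per_gene[gene] += 1
    logger.info(
        "mask_columns kept %d / %d columns", kept.size, alignment.width
    )
    return MaskedMatrix(
        source=alignment,
        kept_columns=kept,
        matrix=matrix[:, kept].copy(),
        dropped_per_gene=dropped_per_gene,
    )


def collapse_haplotypes(masked: MaskedMatrix) -> HaplotypeTable:
    """Group specimens with identical masked rows into haplotypes.

    Haplotypes are numbered ``H01, H02, ...`` in order of first occurrence
    of a member specimen, which makes the collapse deterministic for a
    fixed specimen order.
    """
    if masked.matrix.shape[0] == 0:
        raise ValueError("no specimens to collapse")
    rows = [masked.row(i) for i in range(masked.matrix.shape[0])]
    order: dict[str, int] = {}
    members: list[list[str]] = []
    for sid, row in zip(masked.specimen_ids, rows):
        idx = order.get(row)
        if idx is None:
            order[row] = len(members)
            members.append([sid])
        else:
            members[idx].append(sid)
    pad = max(2, len(str(len(members))))
    haplotypes = [
        Haplotype(f"H{i + 1:0{pad}d}", key, mem)
        for i, (key, mem) in enumerate(zip(order, members))
    ]
    specimen_to_index = {
        sid: i for i, h in enumerate(haplotypes) for sid in h.members
    }
    return HaplotypeTable(haplotypes, specimen_to_index, masked)


def pairwise_distances(table: HaplotypeTable) -> DistanceMatrix:
    """Integer Hamming distances between haplotype sequences."""
    if len(table) < 1:
        raise ValueError("empty haplotype table")
    seqs = table.sequences().view(np.uint8)
    if len(table) == 1:
        return DistanceMatrix(table.ids, np.zeros((1, 1), dtype=np.int64))
    d = squareform(pdist(seqs, metric="hamming")) * seqs.shape[1]
    return DistanceMatrix(table.ids, np.rint(d).astype(np.int64))


def hamming(a: str | np.ndarray, b: str | np.ndarray) -> int:
    """Hamming distance between two equal-length sequences."""
    if isinstance(a, str):
        a = np.frombuffer(a.encode("ascii"), dtype="S1")
    if isinstance(b, str):
        b = np.frombuffer(b.encode("ascii"), dtype="S1")
    if a.shape != b.shape:
        raise ValueError("sequences of unequal length")
    return int((a != b).sum())


def parsimony_informative_sites(
    masked: MaskedMatrix,
) -> tuple[int, list[int]]:
    """Count columns with >=2 states each carried by >=2 specimens.

    Returns the count and the list of original (global) column indices of
    the informative sites.
    """
    matrix = masked.matrix.view(np.uint8)
    informative: list[int] = []
    for j in range(matrix.shape[1]):
        _, counts = np.unique(matrix[:, j], return_counts=True)
        if (counts >= 2).sum() >= 2:
            informative.append(int(masked.kept_columns[j]))
    return len(informative), informative


def pi_sites_frame(masked: MaskedMatrix) -> pd.DataFrame:
    """Parsimony-informative sites with gene-local 1-based coordinates."""
    _, cols = parsimony_informative_sites(masked)
    rows = []
    for col in cols:
        gene, pos = masked.source.gene_of_column(col)
        rows.append({"gene": gene, "position": pos, "global_column": col})
    return pd.DataFrame(rows, columns=["gene", "position", "global_column"])


def divergence_summary(
    masked: MaskedMatrix,
    species: dict[str, str],
) -> pd.DataFrame:
    """Min/max percent p-distance within and between species groups.

    ``species`` maps specimen ID -> species label.  p-distance is the
    Hamming distance over kept columns divided by the number of kept
    columns, in percent.  Intra rows for groups with fewer than two
    members are skipped with a warning.
    """
    ids = masked.specimen_ids
    labels = [species[s] for s in ids]
    mat = masked.matrix.view(np.uint8)
    pdistances = squareform(pdist(mat, metric="hamming")) * 100.0

    groups = sorted(set(labels))
    rows = []
    for gi, ga in enumerate(groups):
        idx_a = [i for i, lab in enumerate(labels) if lab == ga]
        for gb in groups[gi:]:
            idx_b = [i for i, lab in enumerate(labels) if lab == gb]
            if ga == gb:
                if len(idx_a) < 2:
                    logger.warning(
                        "species %s has < 2 specimens; intra-distance skipped", ga
                    )
                    continue
                sub = pdistances[np.ix_(idx_a, idx_a)]
                vals = sub[np.triu_indices(len(idx_a), k=1)]
                mode = "intra"
            else:
                vals = pdistances[np.ix_(idx_a, idx_b)].ravel()
                mode = "inter"
            rows.append(
                {
                    "species_a": ga,
                    "species_b": gb,
                    "mode": mode,
                    "min_pct": float(vals.min()),
                    "max_pct": float(vals.max()),
                }
            )
    return pd.DataFrame(
        rows, columns=["species_a", "species_b", "mode", "min_pct", "max_pct"]
    )
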