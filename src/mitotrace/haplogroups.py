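"""Threshold-based hierarchical haplogroup nomenclature.

Haplotypes separated by more than ``main_threshold`` mutations form main
haplogroups (numbered 1, 2, 3, ...); within a main group, separation by
more than ``sub_threshold`` mutations defines subgroups (lettered A, B,
C, ...), and haplotypes within a subgroup are numbered sequentially, so a
full label reads e.g. "1D2".  "Separated by more than T mutations" is
interpreted as single-linkage: two haplotypes belong to the same cluster
iff a chain of haplotypes connects them with every consecutive pair at
distance <= T, so distinct clusters are guaranteed to be > T apart.

Ordering rules (all deterministic):

* main groups are numbered by descending total specimen count, ties by the
  lexicographically smallest member haplotype sequence;
* within a main group, subgroup "A" contains the haplotype closest to any
  other main group, remaining letters follow by ascending such distance;
* within a subgroup, index 1 is the haplotype closest to the nearest other
  main group, then ascending by that distance (ties: descending member
  count, then lexicographic sequence).

When there is a single main group there is no "other" group to measure
against; subgroups then order by descending specimen count and haplotypes
by descending member count, with the same lexicographic tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass
from string import ascii_uppercase

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .haplotypes import DistanceMatrix, HaplotypeTable


@dataclass
class HaplogroupLabel:
    main: int
    sub: str
    index: int

    def __str__(self) -> str:
        return f"{self.main}{self.sub}{self.index}"


@dataclass
class HaplogroupAssignment:
    """Per-haplotype hierarchical label (main number, letter, index)."""

    labels: dict[str, HaplogroupLabel]  # haplotype_id -> label

    def label(self, haplotype_id: str) -> str:
        return str(self.labels[haplotype_id])

    @property
    def n_main_groups(self) -> int:
        return len({lab.main for lab in self.labels.values()})

    def n_subgroups(self, main: int | None = None) -> int:
        pairs = {
            (lab.main, lab.sub)
            for lab in self.labels.values()
            if main is None or lab.main == main
        }
        return len(pairs)

    def main_partition(self) -> list[set[str]]:
        groups: dict[int, set[str]] = {}
        for hid, lab in self.labels.items():
            groups.setdefault(lab.main, set()).add(hid)
        return [groups[k] for k in sorted(groups)]

    def subgroup_partition(self) -> list[set[str]]:
        groups: dict[tuple[int, str], set[str]] = {}
        for hid, lab in self.labels.items():
            groups.setdefault((lab.main, lab.sub), set()).add(hid)
        return [groups[k] for k in sorted(groups)]

    def to_frame(self, table: HaplotypeTable | None = None) -> pd.DataFrame:
        rows = []
        for hid, lab in self.labels.items():
            row = {
                "haplotype_id": hid,
                "label": str(lab),
                "main": lab.main,
                "sub": lab.sub,
                "index": lab.index,
            }
            rows.append(row)
        frame = pd.DataFrame(rows).sort_values(
            ["main", "sub", "index"], ignore_index=True
        )
        if table is not None:
            extra = table.to_frame()[["haplotype_id", "n_members", "member_ids"]]
            frame = frame.merge(extra, on="haplotype_id", how="left")
        return frame


def cluster_by_threshold(
    distances: DistanceMatrix, threshold: int
) -> list[set[str]]:
    """Single-linkage components linking pairs at distance <= threshold.

    Any two haplotypes in different components are separated by more than
    ``threshold`` mutations (no bridging pair exists by construction).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    adj = csr_matrix(distances.matrix <= threshold)
    n_comp, assignment = connected_components(adj, directed=False)
    comps: list[set[str]] = [set() for _ in range(n_comp)]
    for hid, c in zip(distances.ids, assignment):
        comps[c].add(hid)
    return comps


def assign_names(
    distances: DistanceMatrix,
    main_partition: list[set[str]],
    sub_partitions: dict[int, list[set[str]]],
    member_counts: dict[str, int],
    sequences: dict[str, str],
) -> HaplogroupAssignment:
    """Apply the deterministic numbering/lettering rules to the partitions.

    ``sub_partitions`` maps the index of each main component (as given in
    ``main_partition``) to its subgroup components.
    """
    idx = {hid: i for i, hid in enumerate(distances.ids)}
    mat = distances.matrix

    def min_seq(group: set[str]) -> str:
        return min(sequences[h] for h in group)

    def outside_distance(hid: str, main: set[str]) -> int:
        """Distance from hid to the nearest haplotype in another main group."""
        outside = [idx[h] for h in idx if h not in main]
        if not outside:
            return 0
        return int(mat[idx[hid], outside].min())

    main_order = sorted(
        range(len(main_partition)),
        key=lambda i: (
            -sum(member_counts[h] for h in main_partition[i]),
            min_seq(main_partition[i]),
        ),
    )

    single_main = len(main_partition) == 1
    labels: dict[str, HaplogroupLabel] = {}
    for main_number, part_i in enumerate(main_order, start=1):
        main_set = main_partition[part_i]
        subs = sub_partitions[part_i]
        if single_main:
            sub_order = sorted(
                range(len(subs)),
                key=lambda s: (
                    -sum(member_counts[h] for h in subs[s]),
                    min_seq(subs[s]),
                ),
            )
        else:
            sub_order = sorted(
                range(len(subs)),
                key=lambda s: (
                    min(outside_distance(h, main_set) for h in subs[s]),
                    min_seq(subs[s]),
                ),
            )
        if len(sub_order) > len(ascii_uppercase):
            raise ValueError(
                f"main group {main_number} has {len(sub_order)} subgroups; "
                f"the letter format supports at most {len(ascii_uppercase)}"
            )
        for letter, sub_i in zip(ascii_uppercase, sub_order):
            if single_main:
                hap_order = sorted(
                    subs[sub_i],
                    key=lambda h: (-member_counts[h], sequences[h]),
                )
            else:
                hap_order = sorted(
                    subs[sub_i],
                    key=lambda h: (
                        outside_distance(h, main_set),
                        -member_counts[h],
                        sequences[h],
                    ),
                )
            for index, hid in enumerate(hap_order, start=1):
                labels[hid] = HaplogroupLabel(main_number, letter, index)
    return HaplogroupAssignment(labels)


def classify(
    table: HaplotypeTable,
    distances: DistanceMatrix,
    main_threshold: int = 50,
    sub_threshold: int = 5,
) -> HaplogroupAssignment:
    """Cluster at both thresholds and assign systematic labels."""
    if main_threshold <= 0 or sub_threshold <= 0:
        raise ValueError("thresholds must be positive")
    if sub_threshold >= main_threshold:
        raise ValueError("sub_threshold must be smaller than main_threshold")

    main_partition = cluster_by_threshold(distances, main_threshold)
    idx = {hid: i for i, hid in enumerate(distances.ids)}
    sub_partitions: dict[int, list[set[str]]] = {}
    for i, main_set in enumerate(main_partition):
        ids = sorted(main_set, key=idx.__getitem__)
        rows = [idx[h] for h in ids]
        sub_dm = DistanceMatrix(ids, distances.matrix[np.ix_(rows, rows)])
        sub_partitions[i] = cluster_by_threshold(sub_dm, sub_threshold)

    member_counts = {h.haplotype_id: h.n_members for h in table.haplotypes}
    sequences = {h.haplotype_id: h.key for h in table.haplotypes}
    assignment = assign_names(
        distances, main_partition, sub_partitions, member_counts, sequences
    )

    # separation guarantees, asserted on every output
    _check_separation(distances, assignment, main_threshold, sub_threshold)
    return assignment


def _check_separation(
    distances: DistanceMatrix,
    assignment: HaplogroupAssignment,
    main_threshold: int,
    sub_threshold: int,
) -> None:
    idx = {hid: i for i, hid in enumerate(distances.ids)}
    mat = distances.matrix
    for i, hid_a in enumerate(distances.ids):
        for hid_b in distances.ids[i + 1:]:
            a, b = assignment.labels[hid_a], assignment.labels[hid_b]
            d = mat[idx[hid_a], idx[hid_b]]
            if a.main != b.main and d <= main_threshold:
                raise AssertionError(
                    f"main groups not separated: {hid_a}/{hid_b} at {d}"
                )
            if a.main == b.main and a.sub != b.sub and d <= sub_threshold:
                raise AssertionError(
                    f"subgroups not separated: {hid_a}/{hid_b} at {d}"
                )
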