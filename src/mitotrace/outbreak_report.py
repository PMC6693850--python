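"""Per-origin haplotype diversity and outbreak linkage assessment.

Two outbreak locations sharing a haplotype is direct sequence evidence of
a common source ("linked").  Locations whose closest haplotypes differ by
no more than the subgroup threshold are "proximate" — single-mutation
neighbours, as seen within one greenhouse outbreak, plausibly represent
one introduction.  Anything farther apart is "unlinked" at the resolution
of the marker.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .haplogroups import HaplogroupAssignment
from .haplotypes import DistanceMatrix, HaplotypeTable


@dataclass
class OriginSummary:
    origin: str
    n_specimens: int
    n_haplotypes: int
    main_groups: set[int]
    haplotype_freqs: dict[str, int] = field(default_factory=dict)

    @property
    def haplotype_diversity(self) -> float:
        """1 - sum(p_i^2): probability two random specimens differ."""
        n = self.n_specimens
        if n == 0:
            return 0.0
        return 1.0 - sum((f / n) ** 2 for f in self.haplotype_freqs.values())


@dataclass
class LinkageReport:
    origin_a: str
    origin_b: str
    shared_haplotypes: list[str]
    min_distance: int
    closest_pair: tuple[str, str]
    verdict: str  # "linked" | "proximate" | "unlinked"


def _origin_of(meta: pd.DataFrame, group_by: str) -> dict[str, str]:
    if group_by not in {"country", "locality"}:
        raise ValueError("group_by must be 'country' or 'locality'")
    col = meta[group_by].fillna("unknown").replace("", "unknown")
    return dict(zip(meta["specimen_id"], col))


def origin_diversity(
    table: HaplotypeTable,
    assignment: HaplogroupAssignment,
    meta: pd.DataFrame,
    group_by: str = "country",
) -> list[OriginSummary]:
    """One summary per origin, sorted by descending haplotype count."""
    origin = _origin_of(meta, group_by)
    missing = [s for h in table.haplotypes for s in h.members if s not in origin]
    if missing:
        raise KeyError(f"specimens without metadata: {missing}")

    per_origin: dict[str, dict[str, int]] = {}
    for hap in table.haplotypes:
        for sid in hap.members:
            freqs = per_origin.setdefault(origin[sid], {})
            freqs[hap.haplotype_id] = freqs.get(hap.haplotype_id, 0) + 1

    summaries = []
    for o, freqs in per_origin.items():
        summaries.append(
            OriginSummary(
                origin=o,
                n_specimens=sum(freqs.values()),
                n_haplotypes=len(freqs),
                main_groups={assignment.labels[h].main for h in freqs},
                haplotype_freqs=freqs,
            )
        )
    summaries.sort(key=lambda s: (-s.n_haplotypes, s.origin))
    return summaries


def shared_haplotype_matrix(
    table: HaplotypeTable, meta: pd.DataFrame, group_by: str = "country"
) -> pd.DataFrame:
    """Origin x origin counts of shared haplotypes.

    The diagonal holds each origin's own haplotype count; off-diagonal
    entries count haplotypes sampled in both origins.
    """
    origin = _origin_of(meta, group_by)
    origins = sorted(set(origin.values()))
    if len(origins) < 2:
        raise ValueError("need at least two origins")
    hap_sets: dict[str, set[str]] = {o: set() for o in origins}
    for hap in table.haplotypes:
        for sid in hap.members:
            hap_sets[origin[sid]].add(hap.haplotype_id)
    mat = np.zeros((len(origins), len(origins)), dtype=int)
    for i, a in enumerate(origins):
        for j, b in enumerate(origins):
            mat[i, j] = len(hap_sets[a] & hap_sets[b])
    return pd.DataFrame(mat, index=origins, columns=origins)


def linkage_assessment(
    origin_a: str,
    origin_b: str,
    table: HaplotypeTable,
    distances: DistanceMatrix,
    meta: pd.DataFrame,
    sub_threshold: int = 5,
    group_by: str = "country",
) -> LinkageReport:
    """Assess sequence-level linkage between two origins.

    Verdict is "linked" iff the origins share at least one haplotype,
    "proximate" if their closest haplotypes are within ``sub_threshold``
    mutations, and "unlinked" otherwise.
    """
    origin = _origin_of(meta, group_by)
    haps_a = {
        h.haplotype_id for h in table.haplotypes
        if any(origin.get(s) == origin_a for s in h.members)
    }
    haps_b = {
        h.haplotype_id for h in table.haplotypes
        if any(origin.get(s) == origin_b for s in h.members)
    }
    if not haps_a or not haps_b:
        raise ValueError(
            f"origin without specimens: "
            f"{origin_a if not haps_a else origin_b}"
        )
    shared = sorted(haps_a & haps_b)
    idx = {hid: i for i, hid in enumerate(distances.ids)}
    best = None
    for ha in sorted(haps_a):
        for hb in sorted(haps_b):
            d = int(distances.matrix[idx[ha], idx[hb]])
            if best is None or d < best[0]:
                best = (d, ha, hb)
    assert best is not None
    min_distance, ha, hb = best
    if shared:
        verdict = "linked"
    elif min_distance <= sub_threshold:
        verdict = "proximate"
    else:
        verdict = "unlinked"
    return LinkageReport(
        origin_a=origin_a,
        origin_b=origin_b,
        shared_haplotypes=shared,
        min_distance=min_distance,
        closest_pair=(ha, hb),
        verdict=verdict,
    )


def full_report(
    table: HaplotypeTable,
    assignment: HaplogroupAssignment,
    distances: DistanceMatrix,
    meta: pd.DataFrame,
    group_by: str = "country",
    sub_threshold: int = 5,
) -> dict:
    """JSON-serializable bundle: origin summaries, matrix, all linkages."""
    summaries = origin_diversity(table, assignment, meta, group_by)
    matrix = shared_haplotype_matrix(table, meta, group_by)
    origins = list(matrix.index)
    linkages = []
    for i, a in enumerate(origins):
        for b in origins[i + 1:]:
            rep = linkage_assessment(
                a, b, table, distances, meta, sub_threshold, group_by
            )
            linkages.append(
                {
                    "origin_a": rep.origin_a,
                    "origin_b": rep.origin_b,
                    "shared_haplotypes": rep.shared_haplotypes,
                    "min_distance": rep.min_distance,
                    "closest_pair": list(rep.closest_pair),
                    "verdict": rep.verdict,
                }
            )
    return {
        "group_by": group_by,
        "origins": [
            {
                "origin": s.origin,
                "n_specimens": s.n_specimens,
                "n_haplotypes": s.n_haplotypes,
                "main_groups": sorted(s.main_groups),
                "haplotype_freqs": s.haplotype_freqs,
                "haplotype_diversity": round(s.haplotype_diversity, 6),
            }
            for s in summaries
        ],
        "shared_haplotype_matrix": {
            "origins": origins,
            "counts": matrix.values.tolist(),
        },
        "linkages": linkages,
    }


def write_report(report: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
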