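"""Synthetic haplotype populations with planted haplogroup structure.

The generator emulates the structure the analysis assumes in real
mitochondrial outbreak data: a handful of deeply separated maternal
lineages (main haplogroups), lettered subgroups within them, and shallow
outbreak radiations of one or two mutations, sampled with skewed specimen
counts across named origins.  Mutations are placed at globally distinct
columns (infinite-sites style), so planted mutation counts equal Hamming
distances exactly and threshold-based recovery is deterministic.

Distances arise additively: each main-group founder sits ``main_sep``
mutations from the shared root, so two founders are between twice the
lower and twice the upper bound apart; likewise for subgroup founders
within a group.  The defaults put main groups 56-120 mutations apart
(> 50) and subgroups 12-30 apart (> 5), with leaf haplotypes radiating
0-2 mutations from their subgroup founder.

What this generator does *not* emulate: recurrent or back mutation,
recombination (absent in animal mtDNA anyway), selection, and realistic
codon usage — the root is an i.i.d. base sequence at a fixed GC fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .codon_effects import INVERTEBRATE_MITO, GeneticCode, classify_substitution
from .seq_io import GeneAlignment

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: Gene partition plan: 13 insect mitochondrial protein-coding genes with
#: codon-complete lengths summing to 10,914 nt.
DEFAULT_GENE_LENGTHS: dict[str, int] = {
    "atp6": 672, "atp8": 162, "cob": 1140, "cox1": 1536, "cox2": 684,
    "cox3": 786, "nad1": 879, "nad2": 960, "nad3": 351, "nad4": 1338,
    "nad4L": 288, "nad5": 1599, "nad6": 519,
}

DEFAULT_ORIGINS = (
    "Mexico", "Netherlands", "USA-NJ", "Dominican Republic", "Italy",
)


@dataclass
class SimConfig:
    """Generator parameters; the defaults define the study conditions."""

    seed: int
    gene_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GENE_LENGTHS)
    )
    n_main_groups: int = 4
    #: mutations from the root per main-group founder; pairwise main-group
    #: separations are the sum of two draws (defaults: 56..120 > 50)
    main_sep_range: tuple[int, int] = (28, 60)
    #: subgroups per main group (inclusive range)
    subgroups_per_main: tuple[int, int] = (2, 4)
    #: mutations from the group founder per subgroup founder
    #: (pairwise subgroup separations 12..30 > 5)
    sub_sep_range: tuple[int, int] = (6, 15)
    #: haplotypes per subgroup (inclusive range); the first haplotype of a
    #: subgroup is its founder, the rest radiate
    haplotypes_per_subgroup: tuple[int, int] = (1, 4)
    #: outbreak radiation distance per extra haplotype
    radiation_range: tuple[int, int] = (1, 2)
    #: geometric(p) specimen count per haplotype, capped
    specimen_geometric_p: float = 1 / 3
    max_specimens_per_haplotype: int = 24
    gc_content: float = 0.26
    origins: tuple[str, ...] = DEFAULT_ORIGINS
    #: origin pairs forced to share one haplotype (shared-source scenario)
    shared_source_pairs: tuple[tuple[str, str], ...] = ()
    #: fraction of specimens given sub-threshold coverage metadata
    low_coverage_rate: float = 0.0

    @property
    def alignment_length(self) -> int:
        return sum(self.gene_lengths.values())

    def validate(self) -> None:
        for g, n in self.gene_lengths.items():
            if n % 3 != 0:
                raise ValueError(f"gene {g} length {n} not divisible by 3")
        if 2 * self.main_sep_range[0] <= 50:
            raise ValueError("main separations must exceed 50 mutations")
        if 2 * self.sub_sep_range[0] <= 5:
            raise ValueError("subgroup separations must exceed 5 mutations")
        worst = (
            self.n_main_groups
            * (self.main_sep_range[1]
               + self.subgroups_per_main[1]
               * (self.sub_sep_range[1]
                  + self.haplotypes_per_subgroup[1] * self.radiation_range[1]))
        )
        if worst > self.alignment_length:
            raise ValueError(
                f"planted mutations ({worst} worst case) exceed alignment "
                f"length {self.alignment_length}"
            )


@dataclass
class Mutation:
    column: int          # global 0-based alignment column
    gene: str
    position: int        # 1-based within the gene
    ref: str
    alt: str
    synonymous: bool


@dataclass
class PlantedHaplotype:
    hap_id: str
    main: int            # planted main-group number, 1-based
    sub: int             # planted subgroup number within the main, 1-based
    index: int           # haplotype number within the subgroup, 1-based
    sequence: np.ndarray  # full-length S1 array
    mutations: list[Mutation]  # from the root, replayable
    origins: list[str] = field(default_factory=list)


@dataclass
class SimTruth:
    """Ground truth of a simulated population."""

    config: SimConfig
    root_sequence: str
    partitions: list[tuple[str, int, int]]
    haplotypes: list[PlantedHaplotype]
    specimen_haplotype: dict[str, str]   # specimen -> hap_id
    specimen_origin: dict[str, str]
    corrupted_columns: list[int] = field(default_factory=list)

    def planted_main_partition(self) -> list[set[str]]:
        groups: dict[int, set[str]] = {}
        for h in self.haplotypes:
            groups.setdefault(h.main, set()).add(h.hap_id)
        return [groups[k] for k in sorted(groups)]

    def planted_subgroup_partition(self) -> list[set[str]]:
        groups: dict[tuple[int, int], set[str]] = {}
        for h in self.haplotypes:
            groups.setdefault((h.main, h.sub), set()).add(h.hap_id)
        return [groups[k] for k in sorted(groups)]

    def mutations_between(self, hap_a: str, hap_b: str) -> list[Mutation]:
        """Symmetric difference of the two haplotypes' root mutations."""
        by_id = {h.hap_id: h for h in self.haplotypes}
        cols_a = {m.column: m for m in by_id[hap_a].mutations}
        cols_b = {m.column: m for m in by_id[hap_b].mutations}
        out = [m for c, m in cols_a.items() if c not in cols_b]
        out += [m for c, m in cols_b.items() if c not in cols_a]
        return sorted(out, key=lambda m: m.column)


def _partitions(gene_lengths: dict[str, int]) -> list[tuple[str, int, int]]:
    parts = []
    offset = 0
    for gene, n in gene_lengths.items():
        parts.append((gene, offset, offset + n))
        offset += n
    return parts


def _gene_of(parts: list[tuple[str, int, int]], col: int) -> tuple[str, int]:
    for gene, start, end in parts:
        if start <= col < end:
            return gene, col - start + 1
    raise IndexError(col)


def simulate_population(
    config: SimConfig,
    code: GeneticCode = INVERTEBRATE_MITO,
) -> tuple[list[GeneAlignment], pd.DataFrame, SimTruth]:
    """Generate per-gene alignments, metadata, and ground truth.

    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    parts = _partitions(config.gene_lengths)
    length = config.alignment_length

    gc = config.gc_content
    root = rng.choice(
        _BASES, size=length, p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    )

    # globally distinct mutated columns (infinite-sites style)
    column_pool = iter(rng.permutation(length))

    def mutate(parent: np.ndarray, n_mut: int,
               inherited: list[Mutation]) -> tuple[np.ndarray, list[Mutation]]:
        seq = parent.copy()
        muts = list(inherited)
        for _ in range(n_mut):
            col = int(next(column_pool))
            ref = seq[col].decode()
            alt = rng.choice([b for b in "ACGT" if b != ref])
            gene, pos = _gene_of(parts, col)
            g_start = next(s for g, s, _ in parts if g == gene)
            cds = parent[g_start:g_start + config.gene_lengths[gene]]
            effect = classify_substitution(
                cds.tobytes().decode(), pos, alt, code, gene=gene
            )
            seq[col] = alt.encode()
            muts.append(Mutation(col, gene, pos, ref, alt,
                                 bool(effect.synonymous)))
        return seq, muts

    haplotypes: list[PlantedHaplotype] = []
    hap_counter = 0
    for g in range(1, config.n_main_groups + 1):
        n_mut = int(rng.integers(config.main_sep_range[0],
                                 config.main_sep_range[1] + 1))
        g_seq, g_muts = mutate(root, n_mut, [])
        n_subs = int(rng.integers(config.subgroups_per_main[0],
                                  config.subgroups_per_main[1] + 1))
        for s in range(1, n_subs + 1):
            n_mut = int(rng.integers(config.sub_sep_range[0],
                                     config.sub_sep_range[1] + 1))
            s_seq, s_muts = mutate(g_seq, n_mut, g_muts)
            n_haps = int(rng.integers(config.haplotypes_per_subgroup[0],
                                      config.haplotypes_per_subgroup[1] + 1))
            for k in range(1, n_haps + 1):
                if k == 1:
                    h_seq, h_muts = s_seq, s_muts
                else:
                    n_mut = int(rng.integers(config.radiation_range[0],
                                             config.radiation_range[1] + 1))
                    h_seq, h_muts = mutate(s_seq, n_mut, s_muts)
                hap_counter += 1
                origin = str(rng.choice(config.origins))
                haplotypes.append(
                    PlantedHaplotype(
                        hap_id=f"T{hap_counter:03d}",
                        main=g, sub=s, index=k,
                        sequence=h_seq, mutations=h_muts,
                        origins=[origin],
                    )
                )

    # shared-source scenario: both origins sample the same haplotype
    for a, b in config.shared_source_pairs:
        hap = haplotypes[int(rng.integers(len(haplotypes)))]
        hap.origins = [a, b]

    # sample specimens per haplotype, skewed counts
    specimen_haplotype: dict[str, str] = {}
    specimen_origin: dict[str, str] = {}
    rows_ids: list[str] = []
    rows_seq: list[np.ndarray] = []
    sp = 0
    for hap in haplotypes:
        n = min(int(rng.geometric(config.specimen_geometric_p)),
                config.max_specimens_per_haplotype)
        n = max(n, len(hap.origins))  # shared haplotypes need >= 1 per origin
        for i in range(n):
            sp += 1
            sid = f"SP{sp:04d}"
            specimen_haplotype[sid] = hap.hap_id
            specimen_origin[sid] = hap.origins[i % len(hap.origins)]
            rows_ids.append(sid)
            rows_seq.append(hap.sequence)

    matrix = np.stack(rows_seq)
    alignments = []
    for gene, start, end in parts:
        sub = matrix[:, start:end]
        alignments.append(
            GeneAlignment(
                gene,
                list(rows_ids),
                [row.tobytes().decode("ascii") for row in sub],
            )
        )

    n_specimens = len(rows_ids)
    coverage = np.round(np.exp(rng.normal(4.5, 0.7, n_specimens)), 1)
    coverage = np.clip(coverage, 10.5, 450.0)
    breadth = np.ones(n_specimens)
    if config.low_coverage_rate > 0:
        bad = rng.random(n_specimens) < config.low_coverage_rate
        fail_cov = rng.random(n_specimens) < 0.5
        coverage[bad & fail_cov] = np.round(
            rng.uniform(0.5, 9.9, int((bad & fail_cov).sum())), 1
        )
        breadth[bad & ~fail_cov] = np.round(
            rng.uniform(0.5, 0.99, int((bad & ~fail_cov).sum())), 3
        )
    meta = pd.DataFrame(
        {
            "specimen_id": rows_ids,
            "species": "A. eugenii",
            "country": [specimen_origin[s] for s in rows_ids],
            "locality": [
                f"{specimen_origin[s]}-loc{1 + int(s[2:]) % 3}" for s in rows_ids
            ],
            "mean_coverage": coverage,
            "breadth": breadth,
        }
    )

    truth = SimTruth(
        config=config,
        root_sequence=root.tobytes().decode("ascii"),
        partitions=parts,
        haplotypes=haplotypes,
        specimen_haplotype=specimen_haplotype,
        specimen_origin=specimen_origin,
    )
    return alignments, meta, truth


def simulate_outbreak_trio(
    seed: int,
    counts: tuple[int, int, int] = (24, 7, 1),
    n_greenhouses: int = 6,
    gene_lengths: dict[str, int] | None = None,
) -> tuple[list[GeneAlignment], pd.DataFrame, SimTruth]:
    """A single-introduction greenhouse outbreak: three haplotypes.

    The central haplotype differs by one mutation from each of the other
    two (pairwise distances 1, 1, 2), with skewed specimen counts spread
    over greenhouse localities — the canonical shape of a clonal outbreak
    radiation.  ``counts`` are for (central, first, second neighbour).
    """
    config = SimConfig(
        seed=seed,
        gene_lengths=gene_lengths or dict(DEFAULT_GENE_LENGTHS),
        n_main_groups=1,
        subgroups_per_main=(1, 1),
        haplotypes_per_subgroup=(3, 3),
        radiation_range=(1, 1),
        origins=("Netherlands",),
    )
    alignments, _, truth = simulate_population(config)
    # resample specimens with the requested counts and greenhouse origins
    rng = np.random.default_rng(seed + 1)
    haps = truth.haplotypes
    rows_ids, rows_seq = [], []
    specimen_haplotype, specimen_origin = {}, {}
    sp = 0
    for hap, n in zip(haps, counts):
        for _ in range(n):
            sp += 1
            sid = f"SP{sp:04d}"
            rows_ids.append(sid)
            rows_seq.append(hap.sequence)
            specimen_haplotype[sid] = hap.hap_id
            specimen_origin[sid] = f"greenhouse-{1 + int(rng.integers(n_greenhouses))}"
    matrix = np.stack(rows_seq)
    alignments = [
        GeneAlignment(
            gene,
            list(rows_ids),
            [row.tobytes().decode("ascii") for row in matrix[:, start:end]],
        )
        for gene, start, end in truth.partitions
    ]
    meta = pd.DataFrame(
        {
            "specimen_id": rows_ids,
            "species": "A. eugenii",
            "country": "Netherlands",
            "locality": [specimen_origin[s] for s in rows_ids],
            "mean_coverage": 100.0,
            "breadth": 1.0,
        }
    )
    truth.specimen_haplotype = specimen_haplotype
    truth.specimen_origin = specimen_origin
    return alignments, meta, truth


@dataclass
class CorruptionResult:
    alignments: list[GeneAlignment]
    #: (gene, specimen_id, gene-local 0-based column, injected char)
    injected: list[tuple[str, str, int, str]]

    def affected_global_columns(
        self, partitions: list[tuple[str, int, int]]
    ) -> set[int]:
        starts = {g: s for g, s, _ in partitions}
        return {starts[g] + col for g, _, col, _ in self.injected}


def corrupt(
    alignments: list[GeneAlignment],
    gap_rate: float,
    ambiguity_rate: float,
    seed: int,
    truth: SimTruth | None = None,
) -> CorruptionResult:
    """Inject '-' and 'N' characters at random positions.

    Rates are per-character probabilities in [0, 1).  If ``truth`` is
    given, the affected global columns are appended to its ledger.
    """
    if not 0 <= gap_rate < 1 or not 0 <= ambiguity_rate < 1:
        raise ValueError("rates must be in [0, 1)")
    rng = np.random.default_rng(seed)
    out: list[GeneAlignment] = []
    injected: list[tuple[str, str, int, str]] = []
    for aln in alignments:
        new_seqs = []
        for sid, seq in zip(aln.specimen_ids, aln.sequences):
            arr = np.frombuffer(seq.encode("ascii"), dtype="S1").copy()
            r = rng.random(arr.size)
            gaps = r < gap_rate
            ambigs = (r >= gap_rate) & (r < gap_rate + ambiguity_rate)
            arr[gaps] = b"-"
            arr[ambigs] = b"N"
            for col in np.flatnonzero(gaps):
                injected.append((aln.gene_name, sid, int(col), "-"))
            for col in np.flatnonzero(ambigs):
                injected.append((aln.gene_name, sid, int(col), "N"))
            new_seqs.append(arr.tobytes().decode("ascii"))
        out.append(GeneAlignment(aln.gene_name, list(aln.specimen_ids), new_seqs))
    result = CorruptionResult(out, injected)
    if truth is not None:
        truth.corrupted_columns = sorted(
            result.affected_global_columns(truth.partitions)
        )
    return result


def write_population(
    alignments: list[GeneAlignment],
    meta: pd.DataFrame,
    truth: SimTruth,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write per-gene FASTA files, metadata TSV and a truth JSON."""
    import json

    from .seq_io import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for aln in alignments:
        p = outdir / f"{aln.gene_name}.fasta"
        write_fasta(aln, p)
        paths[aln.gene_name] = p
    meta_path = outdir / "metadata.tsv"
    meta.to_csv(meta_path, sep="\t", index=False)
    paths["metadata"] = meta_path
    truth_doc = {
        "seed": truth.config.seed,
        "partitions": truth.partitions,
        "haplotypes": [
            {
                "hap_id": h.hap_id,
                "main": h.main,
                "sub": h.sub,
                "index": h.index,
                "origins": h.origins,
                "n_mutations_from_root": len(h.mutations),
            }
            for h in truth.haplotypes
        ],
        "specimen_haplotype": truth.specimen_haplotype,
        "specimen_origin": truth.specimen_origin,
        "corrupted_columns": truth.corrupted_columns,
    }
    truth_path = outdir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(truth_doc, fh, indent=2)
    paths["truth"] = truth_path
    return paths
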