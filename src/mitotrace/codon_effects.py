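"""Synonymous / non-synonymous classification under the invertebrate
mitochondrial genetic code.

Insect mitochondrial protein-coding genes translate with NCBI translation
table 5, which reassigns AGA/AGG to Ser, ATA to Met and TGA to Trp
relative to the standard code.  Positions are 1-based within each gene's
aligned CDS, matching how substitutions are conventionally reported
(e.g. "position 37 in nad2" falls in codon 13, codon position 1).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data import CodonTable

from .haplotypes import MaskedMatrix

_BASES = frozenset("ACGT")

#: Three-letter names for reporting, keyed by one-letter code.
AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "Ter", "X": "Xaa",
}


class GeneticCode:
    """A complete 64-codon translation table with stop codons flagged."""

    def __init__(self, table_id: int = 5):
        table = CodonTable.unambiguous_dna_by_id[table_id]
        self.name = table.names[0]
        self.table_id = table_id
        self.codon_to_aa: dict[str, str] = dict(table.forward_table)
        for stop in table.stop_codons:
            self.codon_to_aa[stop] = "*"
        if len(self.codon_to_aa) != 64:
            raise ValueError(f"incomplete codon table {table_id}")
        self.stop_codons = frozenset(table.stop_codons)


#: The invertebrate mitochondrial code (AGA/AGG->Ser, ATA->Met, TGA->Trp).
INVERTEBRATE_MITO = GeneticCode(5)


def translate(codon: str, code: GeneticCode = INVERTEBRATE_MITO) -> str:
    """Translate one codon; returns '*' for stop, 'X' for ambiguity.

    A codon containing any non-ACGT character translates to 'X' (unknown)
    rather than guessing among the compatible amino acids.
    """
    if len(codon) != 3:
        raise ValueError(f"codon must have 3 bases, got {codon!r}")
    codon = codon.upper().replace("U", "T")
    if not set(codon) <= _BASES:
        return "X"
    return code.codon_to_aa[codon]


@dataclass
class SubstitutionEffect:
    """A single-nucleotide substitution and its coding consequence."""

    gene: str
    position: int          # 1-based within the gene CDS
    ref_base: str
    alt_base: str
    codon_index: int       # 1-based
    codon_position: int    # 1, 2 or 3
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    synonymous: bool | None  # None when undetermined

    @property
    def determined(self) -> bool:
        return self.synonymous is not None

    def describe(self) -> str:
        if not self.determined:
            return (
                f"{self.gene}:{self.position} {self.ref_base}>{self.alt_base} "
                f"undetermined"
            )
        kind = "synonymous" if self.synonymous else "non-synonymous"
        return (
            f"{self.gene}:{self.position} {self.ref_base}>{self.alt_base} "
            f"({AA3[self.ref_aa]}{self.codon_index}>"
            f"{AA3[self.alt_aa]}{self.codon_index}, {kind})"
        )


def classify_substitution(
    cds: str,
    position: int,
    alt_base: str,
    code: GeneticCode = INVERTEBRATE_MITO,
    gene: str = "",
) -> SubstitutionEffect:
    """Classify a single-base change at a 1-based CDS position.

    The CDS must be in coding orientation with length divisible by 3.
    """
    cds = cds.upper().replace("U", "T")
    alt_base = alt_base.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    if not 1 <= position <= len(cds):
        raise ValueError(f"position {position} outside CDS of length {len(cds)}")
    ref_base = cds[position - 1]
    if alt_base == ref_base:
        raise ValueError(f"alt base {alt_base!r} equals the reference base")
    codon_index = (position - 1) // 3 + 1
    codon_position = (position - 1) % 3 + 1
    start = (codon_index - 1) * 3
    ref_codon = cds[start:start + 3]
    alt_codon = (
        ref_codon[: codon_position - 1] + alt_base + ref_codon[codon_position:]
    )
    ref_aa = translate(ref_codon, code)
    alt_aa = translate(alt_codon, code)
    synonymous: bool | None
    if ref_aa == "X" or alt_aa == "X":
        synonymous = None
    else:
        synonymous = ref_aa == alt_aa
    return SubstitutionEffect(
        gene=gene,
        position=position,
        ref_base=ref_base,
        alt_base=alt_base,
        codon_index=codon_index,
        codon_position=codon_position,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        synonymous=synonymous,
    )


def annotate_haplotype_differences(
    hap_a: str,
    hap_b: str,
    masked: MaskedMatrix,
    code: GeneticCode = INVERTEBRATE_MITO,
) -> list[SubstitutionEffect]:
    """Annotate every differing masked column between two haplotypes.

    Both haplotypes must be sequences over the masked columns of
    ``masked``.  Each differing column is resolved back through the mask
    and partition tables to a gene and a 1-based gene-local position.  The
    codon context is taken from haplotype A; if any base of the codon
    falls in a masked-out column (or in a trailing partial codon), the
    effect is reported with ``synonymous=None`` (undetermined).

    Multi-hit codons are reported per differing site, each against the
    haplotype-A codon.
    """
    if len(hap_a) != len(hap_b):
        raise ValueError("haplotypes of unequal length")
    if len(hap_a) != masked.n_kept:
        raise ValueError("haplotype length does not match masked matrix")
    source = masked.source
    kept = masked.kept_columns
    col_to_masked = {int(c): i for i, c in enumerate(kept)}

    effects: list[SubstitutionEffect] = []
    for i in range(len(hap_a)):
        if hap_a[i] == hap_b[i]:
            continue
        global_col = int(kept[i])
        gene, local_pos = source.gene_of_column(global_col)
        g_start, g_end = next(
            (s, e) for g, s, e in source.partitions if g == gene
        )
        gene_width = g_end - g_start
        codon_index = (local_pos - 1) // 3 + 1
        codon_position = (local_pos - 1) % 3 + 1
        codon_cols = [
            g_start + (codon_index - 1) * 3 + k for k in range(3)
        ]
        # trailing partial codon: last complete codon ends at 3*(width//3)
        complete = codon_cols[-1] - g_start < (gene_width // 3) * 3
        if complete and all(c in col_to_masked for c in codon_cols):
            ref_codon = "".join(hap_a[col_to_masked[c]] for c in codon_cols)
            alt_codon = (
                ref_codon[: codon_position - 1]
                + hap_b[i]
                + ref_codon[codon_position:]
            )
            ref_aa = translate(ref_codon, code)
            alt_aa = translate(alt_codon, code)
            synonymous: bool | None = (
                None if "X" in (ref_aa, alt_aa) else ref_aa == alt_aa
            )
        else:
            ref_codon = alt_codon = ""
            ref_aa = alt_aa = "X"
            synonymous = None
        effects.append(
            SubstitutionEffect(
                gene=gene,
                position=local_pos,
                ref_base=hap_a[i],
                alt_base=hap_b[i],
                codon_index=codon_index,
                codon_position=codon_position,
                ref_codon=ref_codon,
                alt_codon=alt_codon,
                ref_aa=ref_aa,
                alt_aa=alt_aa,
                synonymous=synonymous,
            )
        )
    return effects
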