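from itertools import product

import numpy as np
import pytest
from Bio.Seq import Seq

import mitotrace as mt
from mitotrace.codon_effects import INVERTEBRATE_MITO

from test_haplotypes import concat_of


class TestTranslate:
    @pytest.mark.parametrize(
        "codon,aa",
        [("AGA", "S"), ("AGG", "S"), ("ATA", "M"), ("TGA", "W"),
         ("GGA", "G"), ("CTA", "L"), ("TTA", "L")],
    )
    def test_invertebrate_code_reassignments(self, codon, aa):
        assert mt.translate(codon) == aa

    @pytest.mark.parametrize("codon", ["TAA", "TAG"])
    def test_stops_flagged(self, codon):
        assert mt.translate(codon) == "*"
        assert codon in INVERTEBRATE_MITO.stop_codons

    def test_ambiguity_never_guessed(self):
        assert mt.translate("ANA") == "X"
        assert mt.translate("A-A") == "X"

    def test_malformed_codon_rejected(self):
        with pytest.raises(ValueError):
            mt.translate("AC")

    def test_full_table_matches_biopython(self):
        for codon in map("".join, product("ACGT", repeat=3)):
            expected = str(Seq(codon).translate(table=5))
            assert mt.translate(codon) == expected


class TestClassifySubstitution:
    def test_position_37_is_codon_13_nonsynonymous(self):
        """A>G at the first base of an AGA codon: Ser -> Gly."""
        cds = "ATG" * 12 + "AGA" + "ATG" * 7
        eff = mt.classify_substitution(cds, 37, "G", gene="nad2")
        assert (eff.codon_index, eff.codon_position) == (13, 1)
        assert (eff.ref_codon, eff.alt_codon) == ("AGA", "GGA")
        assert (eff.ref_aa, eff.alt_aa) == ("S", "G")
        assert eff.synonymous is False

    def test_position_172_is_codon_58_synonymous(self):
        """C>T at the first base of a CTA codon: Leu -> Leu."""
        cds = "ATG" * 57 + "CTA" + "ATG" * 2
        eff = mt.classify_substitution(cds, 172, "T", gene="nad4")
        assert eff.codon_index == 58
        assert (eff.ref_codon, eff.alt_codon) == ("CTA", "TTA")
        assert eff.synonymous is True

    def test_fourfold_degenerate_third_position(self):
        eff = mt.classify_substitution("GGA", 3, "G")
        assert eff.synonymous is True and eff.ref_aa == "G"

    def test_same_base_rejected(self):
        with pytest.raises(ValueError, match="equals"):
            mt.classify_substitution("ATG", 1, "A")

    def test_position_outside_cds_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            mt.classify_substitution("ATG", 4, "C")

    def test_partial_codon_cds_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            mt.classify_substitution("ATGA", 1, "C")

    def test_verdict_symmetric_under_ref_alt_swap(self, rng):
        for _ in range(60):
            cds = "".join(rng.choice(list("ACGT"), size=9))
            pos = int(rng.integers(1, 10))
            ref = cds[pos - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            fwd = mt.classify_substitution(cds, pos, alt)
            swapped = cds[: pos - 1] + alt + cds[pos:]
            rev = mt.classify_substitution(swapped, pos, ref)
            assert fwd.synonymous == rev.synonymous

    def test_every_single_base_change_matches_translation_oracle(self):
        """Exhaustive 64 x 9 sweep against Biopython translation."""
        for codon in map("".join, product("ACGT", repeat=3)):
            for pos in (1, 2, 3):
                for alt in "ACGT":
                    if alt == codon[pos - 1]:
                        continue
                    eff = mt.classify_substitution(codon, pos, alt)
                    alt_codon = codon[: pos - 1] + alt + codon[pos:]
                    expected = (
                        str(Seq(codon).translate(table=5))
                        == str(Seq(alt_codon).translate(table=5))
                    )
                    assert eff.synonymous == expected


class TestAnnotateHaplotypeDifferences:
    def test_identical_haplotypes_empty(self):
        masked = mt.mask_columns(concat_of(["ATGATG", "ATGATG"]))
        assert mt.annotate_haplotype_differences("ATGATG", "ATGATG", masked) == []

    def test_single_synonymous_difference(self):
        # two-gene alignment; difference in gene 2 codon 1 third base
        rows = ["ATGCTA", "ATGCTG"]
        masked = mt.mask_columns(
            concat_of(rows, gene_widths={"nad2": 3, "nad4": 3})
        )
        effs = mt.annotate_haplotype_differences(rows[0], rows[1], masked)
        assert len(effs) == 1
        eff = effs[0]
        assert (eff.gene, eff.position) == ("nad4", 3)
        assert eff.synonymous is True  # CTA and CTG are both Leu

    def test_two_differences_both_reported(self):
        rows = ["AGACTA", "GGATTA"]
        masked = mt.mask_columns(
            concat_of(rows, gene_widths={"nad2": 3, "nad4": 3})
        )
        effs = mt.annotate_haplotype_differences(rows[0], rows[1], masked)
        assert [(e.gene, e.position, e.synonymous) for e in effs] == [
            ("nad2", 1, False),  # AGA(S) -> GGA(G)
            ("nad4", 1, True),   # CTA(L) -> TTA(L)
        ]

    def test_masked_codon_base_gives_undetermined(self):
        # gap at the codon's second base masks that column out
        rows = ["A-GATG", "A-AATG"]
        masked = mt.mask_columns(
            concat_of(rows, gene_widths={"g": 6})
        )
        # masked rows keep columns 0,2,3,4,5 -> "AGATG" vs "AAATG"
        effs = mt.annotate_haplotype_differences("AGATG", "AAATG", masked)
        assert len(effs) == 1
        assert effs[0].synonymous is None
        assert effs[0].determined is False

    def test_unequal_lengths_rejected(self):
        masked = mt.mask_columns(concat_of(["ATG", "ATG"]))
        with pytest.raises(ValueError):
            mt.annotate_haplotype_differences("ATG", "AT", masked)

    def test_coordinate_round_trip_identity(self, small_pipeline):
        """global column -> (gene, local) -> global column is the identity."""
        masked, table, dm, meta, truth = small_pipeline
        source = masked.source
        starts = {g: s for g, s, _ in source.partitions}
        rng = np.random.default_rng(3)
        for col in rng.choice(masked.kept_columns, size=50, replace=False):
            gene, pos = source.gene_of_column(int(col))
            assert starts[gene] + pos - 1 == int(col)

    def test_ledger_mutations_recovered(self, small_pipeline):
        """Differences between planted haplotypes equal the ledger's
        symmetric difference (infinite sites, no corruption)."""
        masked, table, dm, meta, truth = small_pipeline
        a, b = truth.haplotypes[0], truth.haplotypes[1]
        expected = truth.mutations_between(a.hap_id, b.hap_id)
        key = {h.hap_id: h.sequence.tobytes().decode() for h in truth.haplotypes}
        seq_to_hap = {h.key: h for h in table.haplotypes}
        hap_a = seq_to_hap[key[a.hap_id]]
        hap_b = seq_to_hap[key[b.hap_id]]
        effs = mt.annotate_haplotype_differences(hap_a.key, hap_b.key, masked)
        assert len(effs) == len(expected)
        assert {(e.gene, e.position) for e in effs} == {
            (m.gene, m.position) for m in expected
        }
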