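import numpy as np
import pandas as pd
import pytest

from cryptaxon.core import GenotypeMatrix, VariantTable
from cryptaxon.resistance import (
    TranscriptModel,
    annotate_aa_changes,
    cohort_substitution_frequencies,
)
from .conftest import gm_from_calls

# independent oracle: the standard genetic code, written out by hand
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def plus_transcript(cds, offset=20, contig="2L"):
    seq = "A" * offset + cds + "T" * 20
    tm = TranscriptModel("TX", contig, "+", [(offset + 1, offset + len(cds))])
    return tm, seq


class TestAnnotate:
    def test_leucine_to_phenylalanine(self):
        tm, seq = plus_transcript("ATGTTATAA")  # M L *
        vt = VariantTable(["2L"], [26], ["A"], ["T"], [True])  # TTA -> TTT
        ann = annotate_aa_changes(vt, tm, {"2L": seq})
        row = ann.iloc[0]
        assert (row["ref_aa"], row["alt_aa"], row["effect"]) == ("L", "F", "nonsynonymous")
        assert row["codon_number"] == 2

    def test_synonymous_third_position(self):
        tm, seq = plus_transcript("ATGTTATAA")
        vt = VariantTable(["2L"], [26], ["A"], ["G"], [True])  # TTA -> TTG, both L
        ann = annotate_aa_changes(vt, tm, {"2L": seq})
        assert ann.iloc[0]["effect"] == "synonymous"

    def test_noncoding_snp(self):
        tm, seq = plus_transcript("ATGTTATAA")
        vt = VariantTable(["2L"], [5], ["A"], ["C"], [True])
        ann = annotate_aa_changes(vt, tm, {"2L": seq})
        assert ann.iloc[0]["effect"] == "noncoding"

    def test_reference_mismatch_names_position(self):
        tm, seq = plus_transcript("ATGTTATAA")
        vt = VariantTable(["2L"], [26], ["G"], ["T"], [True])
        with pytest.raises(ValueError, match="2L:26"):
            annotate_aa_changes(vt, tm, {"2L": seq})

    def test_agrees_with_codon_table_oracle(self):
        """All 9 single-base changes of 50 random codons classify correctly."""
        rng = np.random.default_rng(6)
        bases = "ACGT"
        codons = ["".join(rng.choice(list(bases), 3)) for _ in range(50)]
        cds = "ATG" + "".join(codons) + "TAA"
        tm, seq = plus_transcript(cds)
        rows = []
        for ci, codon in enumerate(codons):
            for within in range(3):
                for alt in bases:
                    if alt == codon[within]:
                        continue
                    pos = 20 + 3 + ci * 3 + within + 1
                    rows.append((pos, codon, within, alt))
        for pos, codon, within, alt in rows:
            vt = VariantTable(["2L"], [pos], [codon[within]], [alt], [True])
            ann = annotate_aa_changes(vt, tm, {"2L": seq}).iloc[0]
            alt_codon = codon[:within] + alt + codon[within + 1:]
            expect = (
                "synonymous"
                if CODON_TABLE[codon] == CODON_TABLE[alt_codon]
                else "nonsynonymous"
            )
            assert ann["effect"] == expect, (codon, within, alt)
            assert ann["ref_aa"] == CODON_TABLE[codon]

    def test_minus_strand_matches_reverse_complement_equivalent(self):
        """A minus-strand gene yields the same AA calls as its RC'd plus twin."""
        cds = "ATGGGCAAATGC"  # M G K C
        # plus-strand layout
        tm_p, seq_p = plus_transcript(cds)
        # minus strand: genome holds the reverse complement of the CDS
        rc = "".join(COMP[b] for b in reversed(cds))
        offset = 20
        seq_m = "A" * offset + rc + "T" * 20
        tm_m = TranscriptModel("TXm", "2L", "-", [(offset + 1, offset + len(cds))])
        # mutate codon 2 position 1 (G -> A): GGC -> AGC, G -> S
        vt_p = VariantTable(["2L"], [offset + 4], ["G"], ["A"], [True])
        ann_p = annotate_aa_changes(vt_p, tm_p, {"2L": seq_p}).iloc[0]
        # same coding change on the minus strand: genomic base is the
        # complement (C -> T) at the mirrored position
        pos_m = offset + len(cds) - 3  # coding offset 3 -> genomic from the right
        vt_m = VariantTable(["2L"], [pos_m], ["C"], ["T"], [True])
        ann_m = annotate_aa_changes(vt_m, tm_m, {"2L": seq_m}).iloc[0]
        for col in ("codon_number", "ref_aa", "alt_aa", "effect"):
            assert ann_p[col] == ann_m[col]

    def test_cds_length_must_be_codon_multiple(self):
        with pytest.raises(ValueError):
            TranscriptModel("T", "2L", "+", [(1, 4)])


class TestFrequencies:
    def _setup(self, freqs):
        """Three coding SNPs at given alt frequencies; 10-sample cohorts A, B."""
        from cryptaxon.synthetic import simulate_genotypes

        tm, seq = plus_transcript("ATGTTAGGCTAA")  # M L G *
        vt = VariantTable(
            ["2L"] * 2, [26, 27], ["A", "G"], ["T", "A"], [True] * 2
        )  # TTA->TTT (L->F, codon 2) and GGC->AGC (G->S, codon 3)
        ann = annotate_aa_changes(vt, tm, {"2L": seq})
        gm = simulate_genotypes(np.asarray(freqs), 20, seed=1)
        cohorts = {"A": gm.sample_ids[:10], "B": gm.sample_ids[10:]}
        return ann, gm, cohorts

    def test_low_frequency_substitution_dropped(self):
        ann, gm, cohorts = self._setup([0.0, 0.0])
        out = cohort_substitution_frequencies(ann, gm, cohorts, retain_min=0.05)
        assert len(out) == 0

    def test_retained_when_any_cohort_exceeds_threshold(self):
        ann, gm, cohorts = self._setup([0.5, 0.0])
        out = cohort_substitution_frequencies(ann, gm, cohorts, retain_min=0.05)
        assert set(out["cohort"]) == {"A", "B"}
        assert (out["substitution"] == "L2F").all()

    def test_two_snps_same_change_aggregate(self):
        tm, seq = plus_transcript("ATGCATTAA")  # M H *: CAT codon 2
        # CAT -> CGT (R) via pos 25 A>G ... also CAT->CGT only one route; use
        # two routes to one AA: CAT->AAT? that changes codon1 pos. Use H->Q:
        # CAT->CAA (pos 26 T>A) and CAT->CAG (pos 26 T>G): same codon pos —
        # a single site with two alts, recorded as two variant rows
        vt = VariantTable(["2L"] * 2, [26, 26], ["T", "T"], ["A", "G"], [True] * 2)
        ann = annotate_aa_changes(vt, tm, {"2L": seq})
        assert (ann["effect"] == "nonsynonymous").all()
        calls = np.zeros((2, 4, 2), dtype=np.int8)
        calls[0, 0] = 1   # variant 1 hom in sample 0
        calls[1, 1] = 1   # variant 2 hom in sample 1
        gm = gm_from_calls(calls)
        out = cohort_substitution_frequencies(
            ann, gm, {"A": gm.sample_ids}, retain_min=0.05
        )
        assert len(out) == 1
        assert out.iloc[0]["substitution"] == "H2Q"
        assert out.iloc[0]["n_variants"] == 2
        assert out.iloc[0]["frequency"] == pytest.approx(0.25 + 0.25)
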