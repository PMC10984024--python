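"""Target-site resistance reporting: predicted amino-acid changes at SNPs in
a chosen transcript and their per-cohort frequencies.

A SNP inside the transcript's CDS is placed into its codon using the ordered
CDS intervals (strand-aware: on the minus strand coding coordinates run
backwards and bases are complemented), the reference codon is read from the
genome FASTA, the alternate codon substitutes the variant base, and both are
translated with the standard genetic code. Only non-synonymous changes enter
the frequency report; a substitution is retained when its allele frequency
exceeds the retention threshold (default 5%, strict) in at least one cohort.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, VariantTable, allele_counts

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


@dataclass
class TranscriptModel:
    """A coding transcript: ordered CDS intervals on one contig."""

    transcript_id: str
    contig: str
    strand: str
    cds_intervals: list[tuple[int, int]]  # 1-based inclusive, genomic order

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError("strand must be '+' or '-'")
        iv = sorted(self.cds_intervals)
        for (s1, e1), (s2, e2) in zip(iv, iv[1:]):
            if s2 <= e1:
                raise ValueError("overlapping CDS intervals")
        self.cds_intervals = iv
        if self.cds_length % 3 != 0:
            raise ValueError("CDS length not a multiple of 3")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    def cds_offset(self, pos: int) -> int | None:
        """0-based position within the coding sequence, or None if non-coding."""
        off = 0
        for s, e in self.cds_intervals:
            if s <= pos <= e:
                genomic = off + (pos - s)
                if self.strand == "+":
                    return genomic
                return self.cds_length - 1 - genomic
            off += e - s + 1
        return None

    def genomic_positions(self) -> np.ndarray:
        """Genomic position of each coding base, in coding order."""
        pos = np.concatenate([np.arange(s, e + 1) for s, e in self.cds_intervals])
        return pos[::-1] if self.strand == "-" else pos

    @classmethod
    def from_gff(cls, gff_path, transcript_id: str) -> "TranscriptModel":
        import gffutils

        db = gffutils.create_db(
            str(gff_path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        tr = db[transcript_id]
        cds = [(c.start, c.end) for c in db.children(tr, featuretype="CDS")]
        if not cds:
            raise ValueError(f"transcript {transcript_id!r} has no CDS features")
        return cls(transcript_id, tr.seqid, tr.strand, cds)


def _translate(codon: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(codon).translate())


def annotate_aa_changes(
    vt: VariantTable,
    transcript: TranscriptModel,
    reference,
) -> pd.DataFrame:
    """Predicted amino-acid change per variant against a transcript.

    ``reference`` is a mapping contig -> sequence string (or a pyfaidx.Fasta).
    Returns variant_idx, codon_number (1-based), ref_aa, alt_aa, effect in
    {"nonsynonymous", "synonymous", "noncoding"}. A reference-allele mismatch
    with the FASTA raises, naming the position.
    """
    seq = str(reference[transcript.contig][:])
    coding_pos = transcript.genomic_positions()
    rows = []
    for i in range(vt.n_variants):
        if vt.contig[i] != transcript.contig:
            rows.append((i, 0, "", "", "noncoding"))
            continue
        pos = int(vt.pos[i])
        off = transcript.cds_offset(pos)
        if off is None:
            rows.append((i, 0, "", "", "noncoding"))
            continue
        ref_base = seq[pos - 1].upper()
        if ref_base != str(vt.ref_allele[i]).upper():
            raise ValueError(
                f"reference mismatch at {transcript.contig}:{pos}: "
                f"FASTA {ref_base}, variant table {vt.ref_allele[i]}"
            )
        codon_i = off // 3
        within = off % 3
        codon_genomic = coding_pos[codon_i * 3: codon_i * 3 + 3]
        bases = [seq[p - 1].upper() for p in codon_genomic]
        if transcript.strand == "-":
            bases = [b.translate(_COMPLEMENT) for b in bases]
        ref_codon = "".join(bases)
        alt_base = str(vt.alt_allele[i]).upper()
        if transcript.strand == "-":
            alt_base = alt_base.translate(_COMPLEMENT)
        alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1:]
        ref_aa = _translate(ref_codon)
        alt_aa = _translate(alt_codon)
        effect = "synonymous" if ref_aa == alt_aa else "nonsynonymous"
        rows.append((i, codon_i + 1, ref_aa, alt_aa, effect))
    return pd.DataFrame(
        rows, columns=["variant_idx", "codon_number", "ref_aa", "alt_aa", "effect"]
    )


def cohort_substitution_frequencies(
    annotated: pd.DataFrame,
    gm: GenotypeMatrix,
    cohorts: Mapping[str, Sequence[str]],
    retain_min: float = 0.05,
) -> pd.DataFrame:
    """Non-synonymous substitution frequencies per cohort.

    Frequencies are alt-allele frequencies over called alleles. Several SNPs
    causing the same amino-acid change are aggregated (frequencies summed;
    they are alternative routes to one substitution). A substitution is
    retained iff its frequency strictly exceeds ``retain_min`` in at least
    one cohort. Output is long form: substitution x cohort.
    """
    ns = annotated[annotated["effect"] == "nonsynonymous"]
    freq_by_cohort = {}
    for name, members in cohorts.items():
        ac = allele_counts(gm, list(members))
        freq_by_cohort[name] = ac.alt_freq()
    rows = []
    for (codon, ref_aa, alt_aa), grp in ns.groupby(["codon_number", "ref_aa", "alt_aa"]):
        vidx = grp["variant_idx"].to_numpy()
        sub = f"{ref_aa}{codon}{alt_aa}"
        freqs = {
            name: float(np.nansum(f[vidx])) for name, f in freq_by_cohort.items()
        }
        if max(freqs.values(), default=0.0) > retain_min:
            for name, fval in freqs.items():
                rows.append((sub, ref_aa, int(codon), alt_aa, name, fval, len(vidx)))
    return pd.DataFrame(
        rows,
        columns=["substitution", "ref_aa", "codon_number", "alt_aa",
                 "cohort", "frequency", "n_variants"],
    )
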