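"""File I/O: VCF, BED accessibility masks, sample metadata TSV, GFF3 genes.

VCF is read with cyvcf2 and written as plain VCF 4.2 text. BED is 0-based
half-open on disk and converted to the package's 1-based convention on read.
"""
from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    MISSING,
    AccessibilityMask,
    GenotypeMatrix,
    VariantTable,
    validate_sample_frame,
)


def read_vcf(
    path,
    region: str | None = None,
    drop_multiallelic: bool = True,
):
    """Read a VCF into (VariantTable, GenotypeMatrix, skeleton SampleFrame).

    Multiallelic records are dropped when ``drop_multiallelic`` (default);
    otherwise each alternate allele becomes its own biallelic record with
    other-alt calls set missing. ``region`` is ``contig`` or
    ``contig:start-end`` (1-based inclusive) and is applied by filtering.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    rcontig, rlo, rhi = None, None, None
    if region:
        if ":" in region:
            rcontig, span = region.split(":", 1)
            lo, hi = span.split("-", 1)
            rlo, rhi = int(lo), int(hi)
        else:
            rcontig = region

    contigs, poss, refs, alts, flt = [], [], [], [], []
    calls = []
    for var in vcf:
        if rcontig is not None:
            if var.CHROM != rcontig:
                continue
            if rlo is not None and not (rlo <= var.POS <= rhi):
                continue
        try:
            gts = np.array(var.genotypes, dtype=np.int16)[:, :2]
        except Exception as exc:
            raise ValueError(f"VCF record without usable GT at {var.CHROM}:{var.POS}") from exc
        n_alt = len(var.ALT)
        if n_alt != 1:
            if drop_multiallelic or n_alt == 0:
                continue
            for ai, alt in enumerate(var.ALT, start=1):
                g = gts.copy()
                g[(g > 0) & (g != ai)] = MISSING
                g[g == ai] = 1
                contigs.append(var.CHROM)
                poss.append(var.POS)
                refs.append(var.REF)
                alts.append(alt)
                flt.append(var.FILTER is None)
                calls.append(g)
            continue
        contigs.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        flt.append(var.FILTER is None)  # None == PASS in cyvcf2
        calls.append(gts)
    vcf.close()

    if calls:
        arr = np.stack(calls).astype(np.int8)
        arr[arr < 0] = MISSING
    else:
        arr = np.empty((0, len(samples), 2), dtype=np.int8)
    vt = VariantTable(contigs, poss, refs, alts, flt)
    gm = GenotypeMatrix(arr, samples)
    meta = pd.DataFrame(
        {
            "sample_id": samples,
            "cohort": "unknown",
            "country": "unknown",
            "site": "unknown",
            "sex": "unknown",
            "year": 0,
        }
    )
    return vt, gm, meta


def write_vcf(vt: VariantTable, gm: GenotypeMatrix, path, contig_lengths: Mapping[str, int] | None = None) -> None:
    """Write biallelic genotypes as uncompressed VCF 4.2."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if contig_lengths:
            for ctg, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={ctg},length={ln}>\n")
        else:
            for ctg in pd.unique(vt.contig):
                fh.write(f"##contig=<ID={ctg}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.sample_ids) + "\n")
        for i in range(vt.n_variants):
            filt = "PASS" if vt.pass_site_filter[i] else "FAIL"
            gts = "\t".join(
                "./." if a0 == MISSING else f"{a0}/{a1}"
                for a0, a1 in gm.calls[i]
            )
            fh.write(
                f"{vt.contig[i]}\t{vt.pos[i]}\t.\t{vt.ref_allele[i]}\t"
                f"{vt.alt_allele[i]}\t.\t{filt}\t.\tGT\t{gts}\n"
            )


def read_phased_vcf(path, region: str | None = None):
    """Read phased genotypes into (VariantTable, haplotype matrix, haplotype ids).

    Haplotypes are columns ``sample_a`` and ``sample_b``. Any missing or
    unphasable call raises, matching the phased-input contract of the
    haplotype statistics.
    """
    vt, gm, meta = read_vcf(path, region=region)
    if (gm.calls == MISSING).any():
        raise ValueError("phased VCF contains missing calls")
    haps = gm.calls.reshape(gm.n_variants, -1)
    hap_ids = [f"{s}_{ab}" for s in gm.sample_ids for ab in ("a", "b")]
    return vt, haps.astype(np.int8), hap_ids


def read_bed_mask(path, contig_lengths: Mapping[str, int]) -> AccessibilityMask:
    """Read accessible intervals from BED (0-based half-open) into a mask."""
    bed = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2],
        names=["contig", "start", "end"], comment="#",
    )
    masks = {c: np.zeros(int(l), dtype=bool) for c, l in contig_lengths.items()}
    for row in bed.itertuples(index=False):
        if row.contig not in masks:
            warnings.warn(f"BED contig {row.contig!r} not in contig_lengths; skipped")
            continue
        masks[row.contig][int(row.start): int(row.end)] = True
    return AccessibilityMask(masks)


def write_bed_mask(mask: AccessibilityMask, path) -> None:
    with Path(path).open("w") as fh:
        for ctg in mask.contigs():
            m = mask[ctg]
            # runs of True -> 0-based half-open intervals
            d = np.diff(np.concatenate([[0], m.view(np.int8), [0]]))
            starts = np.flatnonzero(d == 1)
            ends = np.flatnonzero(d == -1)
            for s, e in zip(starts, ends):
                fh.write(f"{ctg}\t{s}\t{e}\n")


def read_sample_frame(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return validate_sample_frame(df)


def write_sample_frame(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gff3_genes(path) -> pd.DataFrame:
    """Gene features from GFF3: contig, start, end (1-based incl.), strand, gene_id."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = [
        (g.seqid, g.start, g.end, g.strand, g.id)
        for g in db.features_of_type("gene")
    ]
    return pd.DataFrame(rows, columns=["contig", "start", "end", "strand", "gene_id"])


def read_coverage_tsv(path):
    """Windowed coverage TSV: contig, start, end, gc[, mappability], one column per sample."""
    df = pd.read_csv(path, sep="\t")
    fixed = ["contig", "start", "end", "gc"]
    if "mappability" in df.columns:
        fixed.append("mappability")
    sample_cols = [c for c in df.columns if c not in fixed]
    return df[fixed], df[sample_cols].to_numpy(dtype=np.float64), sample_cols


def write_coverage_tsv(windows: pd.DataFrame, counts: np.ndarray, sample_ids: Sequence[str], path) -> None:
    out = windows.copy()
    for j, s in enumerate(sample_ids):
        out[s] = counts[:, j]
    out.to_csv(path, sep="\t", index=False)


def read_aim_panel(path) -> pd.DataFrame:
    """AIM panel TSV: contig, pos, allele_a, allele_b."""
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "allele_a": str, "allele_b": str})
    need = {"contig", "pos", "allele_a", "allele_b"}
    if not need <= set(df.columns):
        raise ValueError(f"AIM panel must have columns {sorted(need)}")
    if (df["allele_a"] == df["allele_b"]).any():
        raise ValueError("AIM panel rows with identical diagnostic alleles")
    return df
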