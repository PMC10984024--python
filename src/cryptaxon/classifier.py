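"""Diagnostic-marker discovery by allele-frequency difference (DAF) and
individual classification by allelic percentage.

Markers separating a focal taxon A from a reference taxon B are SNPs with a
large absolute allele-frequency difference between the two cohorts. Tiers:

* ``fixed`` — |dAF| = 1 (a fixed difference),
* ``ge98``  — |dAF| > 0.98,
* ``ge85``  — |dAF| > 0.85,

nested so ``fixed`` is contained in ``ge98`` is contained in ``ge85``. SNPs
whose overall genotyping success (fraction of samples in the two cohorts
with a called genotype) is below 10% are excluded before tiering.

Each selected marker is oriented toward cohort A: the marker allele is the
allele commoner in A. An individual's *allelic percentage* is
``100 * (# A-oriented alleles carried) / (2 * # called markers)``; samples
above the high cut-off (default >80) are assigned to taxon A, below the low
cut-off (default <20) to taxon B, and otherwise left unassigned. Missing
genotypes shrink the denominator rather than counting toward either taxon.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, VariantTable, allele_counts

TIER_RANK = {"none": 0, "ge85": 1, "ge98": 2, "fixed": 3}


def compute_daf(
    gm: GenotypeMatrix,
    vt: VariantTable,
    samples_a: list[str],
    samples_b: list[str],
    min_success: float = 0.10,
) -> pd.DataFrame:
    """Per-variant allele-frequency difference table between cohorts A and B.

    Returns a DataFrame with variant_idx, contig, pos, freq_a, freq_b (alt
    frequencies), daf = |freq_a - freq_b|, success, tier and the A-oriented
    allele code (0 = ref, 1 = alt). Sites with genotyping success below
    ``min_success`` or with no called alleles in either cohort are excluded.
    """
    ia = gm.sample_indices(samples_a)
    ib = gm.sample_indices(samples_b)
    both = np.concatenate([ia, ib])
    aca = allele_counts(gm, samples_a)
    acb = allele_counts(gm, samples_b)
    called = gm.called_mask()[:, both]
    success = called.mean(axis=1)
    pa = aca.alt_freq()
    pb = acb.alt_freq()
    daf = np.abs(pa - pb)
    keep = (success >= min_success) & ~np.isnan(daf)
    tier = np.full(len(daf), "none", dtype=object)
    tier[daf > 0.85] = "ge85"
    tier[daf > 0.98] = "ge98"
    tier[daf == 1.0] = "fixed"
    a_allele = np.where(pa > pb, 1, 0)
    df = pd.DataFrame(
        {
            "variant_idx": np.arange(gm.n_variants),
            "contig": vt.contig,
            "pos": vt.pos,
            "freq_a": pa,
            "freq_b": pb,
            "daf": daf,
            "success": success,
            "tier": tier,
            "a_allele": a_allele,
        }
    )
    return df[keep].reset_index(drop=True)


@dataclass
class MarkerPanel:
    """Selected diagnostic markers oriented toward the focal taxon."""

    table: pd.DataFrame  # variant_idx, contig, pos, a_allele, tier, daf

    def __len__(self) -> int:
        return len(self.table)

    def per_contig_summary(self) -> pd.DataFrame:
        return (
            self.table.groupby("contig", as_index=False)
            .size()
            .rename(columns={"size": "n_markers"})
        )


def build_panel(daf: pd.DataFrame, tier: str = "ge85") -> MarkerPanel:
    """All variants at or above a DAF tier (tiers are nested)."""
    if tier not in TIER_RANK or tier == "none":
        raise ValueError(f"invalid tier {tier!r}")
    rank = daf["tier"].map(TIER_RANK)
    sel = daf[rank >= TIER_RANK[tier]]
    if len(sel) == 0:
        warnings.warn("empty marker panel at requested tier")
    cols = ["variant_idx", "contig", "pos", "a_allele", "tier", "daf"]
    return MarkerPanel(sel[cols].reset_index(drop=True))


def allelic_percentage(gm: GenotypeMatrix, panel: MarkerPanel) -> pd.DataFrame:
    """Per-sample percentage of A-oriented alleles over called panel markers.

    Samples with zero called markers get NaN. Returns sample_id,
    allelic_pct, n_called_markers, n_missing_markers.
    """
    if len(panel) == 0:
        raise ValueError("empty marker panel")
    vidx = panel.table["variant_idx"].to_numpy()
    acode = panel.table["a_allele"].to_numpy(dtype=np.int8)
    calls = gm.calls[vidx]
    called = (calls != MISSING).all(axis=2)
    n_a = ((calls == acode[:, None, None]) & called[:, :, None]).sum(axis=(0, 2))
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(n_called > 0, 100.0 * n_a / (2.0 * n_called), np.nan)
    return pd.DataFrame(
        {
            "sample_id": gm.sample_ids,
            "allelic_pct": pct,
            "n_called_markers": n_called,
            "n_missing_markers": len(panel) - n_called,
        }
    )


def classify(
    percentages: pd.DataFrame,
    hi_cutoff: float = 80.0,
    lo_cutoff: float = 20.0,
    truth: pd.Series | None = None,
) -> pd.DataFrame:
    """Assign taxon labels from allelic percentages (strict cut-offs).

    ``truth`` optionally maps sample_id -> {"taxon_a", "taxon_b"}; when given,
    an ``accuracy`` attribute records the fraction of truth-labelled samples
    assigned to their true taxon (unassigned counts as an error).
    """
    if hi_cutoff <= lo_cutoff:
        raise ValueError("hi_cutoff must exceed lo_cutoff")
    out = percentages.copy()
    pct = out["allelic_pct"]
    out["label"] = np.select(
        [pct > hi_cutoff, pct < lo_cutoff], ["taxon_a", "taxon_b"], default="unassigned"
    )
    out.loc[pct.isna(), "label"] = "unassigned"
    if truth is not None:
        t = out["sample_id"].map(truth)
        mask = t.notna()
        acc = float((out.loc[mask, "label"] == t[mask]).mean()) if mask.any() else np.nan
        out.attrs["accuracy"] = acc
    return out


def genotype_class_matrix(gm: GenotypeMatrix, panel: MarkerPanel) -> pd.DataFrame:
    """Samples x markers genotype-class export for marker-plot style figures.

    Classes: 2 = homozygous A-allele, 1 = heterozygous, 0 = homozygous
    B-allele, -1 = missing; plus the allelic-percentage column.
    """
    vidx = panel.table["variant_idx"].to_numpy()
    acode = panel.table["a_allele"].to_numpy(dtype=np.int8)
    calls = gm.calls[vidx]
    called = (calls != MISSING).all(axis=2)
    n_a = ((calls == acode[:, None, None]) & called[:, :, None]).sum(axis=2)
    cls = np.where(called, n_a, -1).T
    cols = [f"{c}:{p}" for c, p in zip(panel.table["contig"], panel.table["pos"])]
    df = pd.DataFrame(cls, index=gm.sample_ids, columns=cols)
    df.insert(0, "sample_id", gm.sample_ids)
    ap = allelic_percentage(gm, panel)
    df["allelic_pct"] = ap["allelic_pct"].to_numpy()
    return df.reset_index(drop=True)
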